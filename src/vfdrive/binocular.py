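"""Binocular visual field integration by quadratic summation (OU-VFI).

A monocular Humphrey field reports, per tested location, a threshold value
TV (dB of stimulus attenuation) and a total deviation TD = TV − age-normal
expected TV.  A theoretical binocular field is built by converting each
eye's TV out of log space, combining the two linear sensitivities in
quadrature, and converting back:

    bTV  = 10·log10 √( (10^(lTV/10))² + (10^(rTV/10))² )
    b̄TV  = the same with each eye's expected TV (TV − TD) substituted
    bTD  = bTV − b̄TV

so the binocular summation gain is at most 10·log10 √2 ≈ 1.505 dB over the
better eye.  Per-location sensitivity S rescales the deficit against the
normative binocular threshold,

    S = 100 − 100·|bTD| / b̄TV   for bTD < 0   (floored at 0),
    S = 100                      for bTD ≥ 0,

and the binocular visual field index OU-VFI is the eccentricity-weighted
mean of S, scaled so a fully intact field scores 100% and a fully impaired
one 0%.

Locations seen by only one eye — the fellow eye's blind spot, or the nasal
points of mismatched 24-2/30-2 patterns — keep the seeing eye's TV/TD
unchanged: the quadratic sum has no attainable single-eye limit in dB space
(a truly blind eye would contribute 10^(−∞)), so the monocular value is the
consistent degenerate rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    DEFAULT_RING_BOUNDARIES,
    RING_WEIGHTS,
    Eye,
    Pattern,
    TestPatternGrid,
    WeightMatrix,
    ring_of,
)

__all__ = [
    "IntegrationError",
    "MonocularField",
    "BinocularField",
    "binocular_threshold",
    "expected_binocular_threshold",
    "binocular_total_deviation",
    "sensitivity",
    "weighted_vfi",
    "integrate_fields",
    "MAX_SUMMATION_GAIN_DB",
]

#: Largest possible binocular gain over the better eye, 10·log10(√2) dB.
MAX_SUMMATION_GAIN_DB: float = 10.0 * np.log10(np.sqrt(2.0))


class IntegrationError(ValueError):
    """Raised for inputs that violate the integration contracts."""


@dataclass(frozen=True)
class MonocularField:
    """One eye's threshold-value and total-deviation maps on a test pattern.

    ``tv`` and ``td`` align with ``grid.points``; they may be NaN only at the
    eye's own blind-spot locations (the instrument reports no deviation
    there).  ``reliability`` optionally carries fixation-loss / false-positive
    / false-negative fractions as metadata.
    """

    eye: Eye
    grid: TestPatternGrid
    tv: np.ndarray
    td: np.ndarray
    reliability: dict | None = None

    def __post_init__(self) -> None:
        tv = np.asarray(self.tv, dtype=float)
        td = np.asarray(self.td, dtype=float)
        n = self.grid.n_locations
        if tv.shape != (n,) or td.shape != (n,):
            raise IntegrationError(f"tv/td must have one value per grid location ({n})")
        if self.eye is not self.grid.eye:
            raise IntegrationError(f"field eye {self.eye} does not match grid eye {self.grid.eye}")
        seeing = ~self.grid.blind_spot_mask
        if not (np.isfinite(tv[seeing]).all() and np.isfinite(td[seeing]).all()):
            raise IntegrationError("tv and td must be finite at every non-blind-spot location")
        object.__setattr__(self, "tv", tv)
        object.__setattr__(self, "td", td)

    @property
    def expected_tv(self) -> np.ndarray:
        """Age-normal expected threshold, TV − TD."""
        return self.tv - self.td

    def to_frame(self) -> pd.DataFrame:
        frame = self.grid.to_frame()[["x_deg", "y_deg"]].copy()
        frame.insert(0, "eye", self.eye.value)
        frame.insert(1, "pattern", self.grid.pattern.value)
        frame["tv_db"] = self.tv
        frame["td_db"] = self.td
        return frame


@dataclass(frozen=True)
class BinocularField:
    """Per-location binocular field and its scalar OU-VFI (percent)."""

    pattern: Pattern
    x: np.ndarray
    y: np.ndarray
    btv: np.ndarray
    expected_btv: np.ndarray
    btd: np.ndarray
    s: np.ndarray
    weights: np.ndarray
    vfi: float

    @property
    def n_locations(self) -> int:
        return self.x.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_deg": self.x,
                "y_deg": self.y,
                "btv_db": self.btv,
                "expected_btv_db": self.expected_btv,
                "btd_db": self.btd,
                "sensitivity_pct": self.s,
                "weight": self.weights,
            }
        )

    def summary(self) -> dict:
        return {
            "ou_vfi": float(self.vfi),
            "n_locations": int(self.n_locations),
            "pattern": self.pattern.value,
        }


def _require_finite(name: str, *values) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise IntegrationError(f"{name} requires finite dB inputs")


def binocular_threshold(l_tv, r_tv):
    """Quadratic binocular summation of two monocular thresholds (dB).

    Accepts scalars or aligned arrays.  The result is always at least the
    better eye's threshold and at most 10·log10(√2) ≈ 1.505 dB above it.
    """
    l_tv = np.asarray(l_tv, dtype=float)
    r_tv = np.asarray(r_tv, dtype=float)
    _require_finite("binocular_threshold", l_tv, r_tv)
    # hypot of the linear sensitivities, computed in log space for stability
    out = 10.0 * np.log10(np.hypot(10.0 ** (l_tv / 10.0), 10.0 ** (r_tv / 10.0)))
    return float(out) if out.ndim == 0 else out


def expected_binocular_threshold(l_tv, l_td, r_tv, r_td):
    """Normative binocular threshold from each eye's expected TV (TV − TD)."""
    l_tv, l_td = np.asarray(l_tv, dtype=float), np.asarray(l_td, dtype=float)
    r_tv, r_td = np.asarray(r_tv, dtype=float), np.asarray(r_td, dtype=float)
    _require_finite("expected_binocular_threshold", l_tv, l_td, r_tv, r_td)
    return binocular_threshold(l_tv - l_td, r_tv - r_td)


def binocular_total_deviation(l_tv=None, l_td=None, r_tv=None, r_td=None):
    """Binocular total deviation bTD = bTV − b̄TV at one location.

    Pass both eyes' (tv, td) for a binocular location; pass a single eye's
    pair (the other eye ``None``) for a location the fellow eye cannot see,
    in which case the seeing eye's TD is returned unchanged.
    """
    left = l_tv is not None and l_td is not None
    right = r_tv is not None and r_td is not None
    if left and right:
        btv = binocular_threshold(l_tv, r_tv)
        ebtv = expected_binocular_threshold(l_tv, l_td, r_tv, r_td)
        return btv - ebtv
    if left:
        _require_finite("binocular_total_deviation", l_tv, l_td)
        return float(l_td)
    if right:
        _require_finite("binocular_total_deviation", r_tv, r_td)
        return float(r_td)
    raise IntegrationError("location undefined in both eyes")


def sensitivity(btd, expected_btv):
    """Per-location sensitivity S ∈ [0, 100] from bTD and the normative b̄TV.

    S is 100 wherever the observed binocular threshold meets or exceeds the
    normative one (bTD ≥ 0); below that it falls linearly with the relative
    deficit and is floored at 0 (deep absolute defects can otherwise drive
    the ratio past 100%).
    """
    btd = np.asarray(btd, dtype=float)
    expected_btv = np.asarray(expected_btv, dtype=float)
    _require_finite("sensitivity", btd, expected_btv)
    if np.any(expected_btv <= 0):
        raise IntegrationError("expected binocular threshold must be positive (degenerate normative value)")
    s = np.where(btd >= 0, 100.0, 100.0 - 100.0 * np.abs(btd) / expected_btv)
    s = np.clip(s, 0.0, 100.0)
    return float(s) if s.ndim == 0 else s


def weighted_vfi(s, weights) -> float:
    """Eccentricity-weighted VFI (percent): Σ S·W / Σ 100·W, scaled to %."""
    s = np.asarray(s, dtype=float)
    w = np.asarray(weights, dtype=float)
    if s.shape != w.shape:
        raise IntegrationError("sensitivity and weight vectors must align")
    if np.any(w < 0):
        raise IntegrationError("weights must be non-negative")
    active = w > 0
    if not active.any():
        raise IntegrationError("all weights are zero; VFI undefined")
    if not np.all(np.isfinite(s[active])):
        raise IntegrationError("sensitivity must be defined wherever weight > 0")
    return float(100.0 * np.sum(s[active] * w[active]) / np.sum(100.0 * w[active]))


def _seeing_locations(field: MonocularField) -> dict[tuple[float, float], tuple[float, float]]:
    """Map (x, y) -> (tv, td) over the field's non-blind-spot locations."""
    mask = ~field.grid.blind_spot_mask
    xy = field.grid.xy
    return {
        (float(xy[i, 0]), float(xy[i, 1])): (float(field.tv[i]), float(field.td[i]))
        for i in np.flatnonzero(mask)
    }


def integrate_fields(
    left: MonocularField,
    right: MonocularField,
    weights: WeightMatrix | None = None,
    ring_boundaries=DEFAULT_RING_BOUNDARIES,
    ring_weights=RING_WEIGHTS,
) -> BinocularField:
    """Derive the full binocular field and OU-VFI from an OS/OD field pair.

    The two fields are overlaid in the shared visual-field frame.  Locations
    seen by both eyes are combined by quadratic summation; locations seen by
    one eye only (fellow blind spot, nasal 24-2 points, 24-2/30-2 mismatch)
    fall back to the seeing eye's values.  Argument order does not matter —
    the formulas are symmetric in the eyes — but the pair must contain one
    OS and one OD field.

    VFI weights come from ``weights`` where its grid covers a location and
    from the ring convention elsewhere; by default they are ring weights on
    the merged grid.
    """
    if {left.eye, right.eye} != {Eye.OS, Eye.OD}:
        raise IntegrationError("integration needs one OS field and one OD field")
    os_field = left if left.eye is Eye.OS else right
    od_field = left if left.eye is Eye.OD else right

    os_map = _seeing_locations(os_field)
    od_map = _seeing_locations(od_field)
    usable = set(os_map) | set(od_map)
    if os_field.grid.pattern is not od_field.grid.pattern:
        # mixed 24-2/30-2 pair: integrate on the 24-2 lattice only
        narrow = os_field if os_field.grid.pattern is Pattern.P24_2 else od_field
        lattice = {(float(x), float(y)) for x, y in narrow.grid.xy}
        usable &= lattice
    locs = sorted(usable, key=lambda p: (-p[1], p[0]))
    if not locs:
        raise IntegrationError("no usable locations in either field")

    weight_lookup: dict[tuple[float, float], float] = {}
    if weights is not None:
        wxy = weights.grid.xy
        for i in range(weights.grid.n_locations):
            weight_lookup[(float(wxy[i, 0]), float(wxy[i, 1]))] = float(weights.weights[i])

    n = len(locs)
    btv = np.empty(n)
    ebtv = np.empty(n)
    w = np.empty(n)
    for i, (x, y) in enumerate(locs):
        in_os, in_od = (x, y) in os_map, (x, y) in od_map
        if in_os and in_od:
            ltv, ltd = os_map[(x, y)]
            rtv, rtd = od_map[(x, y)]
            btv[i] = binocular_threshold(ltv, rtv)
            ebtv[i] = expected_binocular_threshold(ltv, ltd, rtv, rtd)
        else:
            tv, td = os_map[(x, y)] if in_os else od_map[(x, y)]
            btv[i] = tv
            ebtv[i] = tv - td
        w[i] = weight_lookup.get(
            (x, y), ring_weights[ring_of(np.hypot(x, y), ring_boundaries) - 1]
        )
    btd = btv - ebtv
    s = sensitivity(btd, ebtv)
    vfi = weighted_vfi(s, w)
    if os_field.grid.pattern is od_field.grid.pattern:
        pattern = os_field.grid.pattern
    else:
        pattern = Pattern.P24_2  # mixed pairs integrate on the 24-2 core
    return BinocularField(
        pattern=pattern,
        x=np.array([p[0] for p in locs]),
        y=np.array([p[1] for p in locs]),
        btv=btv,
        expected_btv=ebtv,
        btd=btd,
        s=np.asarray(s, dtype=float),
        weights=w,
        vfi=vfi,
    )
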