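"""Synthetic cohorts: monocular field pairs with glaucomatous defect
archetypes, drive outcomes with plantable regression effects, and telemetry
that reproduces them.

No clinical dataset accompanies the analysis, so this module generates one
with the statistical structure the pipeline assumes: a glaucoma group (n=25
by default) with visual-field defects spanning early arcuate loss to
advanced bilateral damage, and a suspect control group (n=18) with normal
fields.  Vehicle-control outcomes are lognormal with subject-level random
intercepts and linear fixed effects of age, acuity, logit OU-VFI, MoCA and
VFQ-driving, so mixed-model parameter recovery can be tested against known
truth.  Default effect sizes are the magnitudes a driving-simulator study
of this design reports.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binocular import MonocularField, integrate_fields
from .geometry import Eye, Pattern, TestPatternGrid, build_pattern

__all__ = [
    "Archetype",
    "DefectArchetype",
    "CohortSpec",
    "SyntheticError",
    "archetype_offsets",
    "normal_hill",
    "simulate_monocular_pair",
    "simulate_cohort",
    "DEFAULT_BETAS",
]


class SyntheticError(ValueError):
    """Raised for invalid generator specifications."""


class Archetype(str, enum.Enum):
    """Named glaucomatous defect patterns, mild to severe."""

    NORMAL = "normal"
    EARLY_ARCUATE = "early_arcuate"
    NASAL_STEP = "nasal_step"
    MODERATE_DIFFUSE = "moderate_diffuse"
    ADVANCED = "advanced"


def normal_hill(eccentricity, peak_db: float = 30.0, slope_db_per_deg: float = 0.5 / 3.0):
    """Age-normal expected threshold: ``peak`` dB at fixation, declining
    linearly with eccentricity (default 0.5 dB per 3°)."""
    return peak_db - slope_db_per_deg * np.asarray(eccentricity, dtype=float)


def archetype_offsets(archetype: Archetype | str, grid: TestPatternGrid) -> np.ndarray:
    """Mean total-deviation offset (dB, ≤ 0) of an archetype on a grid.

    Regions are defined in the grid's own visual-field frame; "nasal" is
    resolved from the grid's eye (x < 0 for OD, x > 0 for OS).
    """
    archetype = Archetype(archetype)
    xy = grid.xy
    x, y = xy[:, 0], xy[:, 1]
    ecc = grid.eccentricity
    nasal = x < 0 if grid.eye is Eye.OD else x > 0
    offsets = np.zeros(grid.n_locations)
    if archetype is Archetype.NORMAL:
        return offsets
    if archetype is Archetype.EARLY_ARCUATE:
        # superior arcuate bundle defect sweeping around fixation
        offsets[(y > 0) & (ecc >= 9) & (ecc <= 22)] = -8.0
        return offsets
    if archetype is Archetype.NASAL_STEP:
        # step along the superior nasal horizontal meridian
        offsets[nasal & (y > 0) & (y <= 9)] = -10.0
        return offsets
    if archetype is Archetype.MODERATE_DIFFUSE:
        offsets[:] = -6.0
        return offsets
    # advanced: deep superior-hemifield loss over moderate diffuse loss
    offsets[:] = -10.0
    offsets[y > 0] = -25.0
    return offsets


@dataclass(frozen=True)
class DefectArchetype:
    """An archetype plus its measurement-noise level (Gaussian in dB)."""

    name: Archetype
    td_noise_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.td_noise_sd < 0:
            raise SyntheticError("td_noise_sd must be non-negative")
        object.__setattr__(self, "name", Archetype(self.name))


def _simulate_field(
    grid: TestPatternGrid,
    offsets: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
    peak_db: float,
    slope_db_per_deg: float,
) -> MonocularField:
    expected = normal_hill(grid.eccentricity, peak_db, slope_db_per_deg)
    noise = rng.normal(0.0, noise_sd, size=grid.n_locations) if noise_sd > 0 else 0.0
    tv = expected + offsets + noise
    td = tv - expected  # exact by construction
    return MonocularField(eye=grid.eye, grid=grid, tv=tv, td=td)


def simulate_monocular_pair(
    archetype: DefectArchetype | Archetype | str,
    asymmetry: float = 0.0,
    pattern_id: Pattern | str = Pattern.P24_2,
    seed: int | np.random.SeedSequence | None = 0,
    peak_db: float = 30.0,
    slope_db_per_deg: float = 0.5 / 3.0,
) -> tuple[MonocularField, MonocularField]:
    """Simulate an (OS, OD) field pair sharing one defect archetype.

    ``asymmetry`` deepens the right eye's defect offsets by that many dB
    everywhere, emulating the inter-eye asymmetry typical of glaucoma.
    Thresholds are the age-normal hill of vision plus the archetype offset
    plus Gaussian noise; total deviation is TV minus the hill exactly.
    """
    if not isinstance(archetype, DefectArchetype):
        archetype = DefectArchetype(Archetype(archetype))
    if asymmetry < 0:
        raise SyntheticError("asymmetry must be non-negative (dB deepening of the right eye)")
    rng = np.random.default_rng(seed)
    left_grid = build_pattern(pattern_id, Eye.OS)
    right_grid = build_pattern(pattern_id, Eye.OD)
    left = _simulate_field(
        left_grid, archetype_offsets(archetype.name, left_grid),
        archetype.td_noise_sd, rng, peak_db, slope_db_per_deg,
    )
    right = _simulate_field(
        right_grid, archetype_offsets(archetype.name, right_grid) - asymmetry,
        archetype.td_noise_sd, rng, peak_db, slope_db_per_deg,
    )
    return left, right


#: Fixed-effect defaults (log-outcome scale) for the steering-variability
#: and lateral-acceleration-variability generators.
DEFAULT_BETAS: dict[str, dict[str, float]] = {
    "steering_sd": {
        "intercept": 3.1881,
        "age": 0.0141,
        "va_worst": -1.9879,
        "logit_ou": -0.1875,
        "moca_total": -0.0632,
        "vfq_driving": -0.0308,
    },
    "lat_accel_sd": {
        "intercept": -1.6206,
        "age": 0.0144,
        "va_worst": -1.9368,
        "logit_ou": -0.1966,
        "moca_total": -0.0753,
        "vfq_driving": -0.0293,
    },
}

_GLAUCOMA_MIX: dict[Archetype, float] = {
    Archetype.EARLY_ARCUATE: 0.30,
    Archetype.NASAL_STEP: 0.20,
    Archetype.MODERATE_DIFFUSE: 0.30,
    Archetype.ADVANCED: 0.20,
}


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate a reproducible synthetic cohort.

    Group sizes, ages and clinical score distributions default to the values
    typical of a glaucoma driving-simulation cohort; effect coefficients are
    on the log-outcome scale (per logit of OU-VFI, per year, per point).
    ``residual_sd`` and ``subject_sd`` are the within-subject residual and
    the between-subject random-intercept SDs on the log scale.
    """

    n_glaucoma: int = 25
    n_suspect: int = 18
    drives_per_subject: int = 2
    age_mean_glaucoma: float = 69.8
    age_sd_glaucoma: float = 11.3
    age_mean_suspect: float = 60.3
    age_sd_suspect: float = 13.1
    betas: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BETAS.items()})
    residual_sd: float = 0.35
    subject_sd: float = 0.30
    td_noise_sd: float = 1.5
    logit_eps: float = 0.005
    glaucoma_mix: dict = field(default_factory=lambda: dict(_GLAUCOMA_MIX))
    pattern: Pattern = Pattern.P24_2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_glaucoma < 1 or self.n_suspect < 1:
            raise SyntheticError("both groups need at least one subject")
        if self.drives_per_subject < 1:
            raise SyntheticError("drives_per_subject must be >= 1")
        if self.residual_sd <= 0:
            raise SyntheticError("residual_sd must be positive")
        if self.subject_sd < 0:
            raise SyntheticError("subject_sd must be non-negative")
        probs = np.array(list(self.glaucoma_mix.values()), dtype=float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise SyntheticError("glaucoma archetype mixture must be a probability vector")


def _logit(p: np.ndarray, eps: float) -> np.ndarray:
    p = np.clip(p, eps, 1.0 - eps)
    return np.log(p / (1.0 - p))


def simulate_cohort(spec: CohortSpec, return_fields: bool = False):
    """Generate a subject × drive cohort table with planted effects.

    Per subject: group, age, gender, worst-eye acuity (logMAR), MoCA total,
    VFQ scores, a simulated monocular field pair (suspects: normal fields;
    glaucoma: archetype mixture) integrated into an OU-VFI, and one row per
    drive with lognormal steering / lateral-acceleration variability whose
    log-scale mean is the linear combination of covariates in ``spec.betas``
    plus a subject random intercept.  Pure function of the spec.

    Returns the cohort ``DataFrame``; with ``return_fields=True`` also a
    dict of subject_id -> (OS field, OD field).
    """
    rng = np.random.default_rng(spec.seed)
    groups = ["glaucoma"] * spec.n_glaucoma + ["suspect"] * spec.n_suspect
    mix_names = list(spec.glaucoma_mix.keys())
    mix_probs = np.array([spec.glaucoma_mix[a] for a in mix_names], dtype=float)

    subjects = []
    fields: dict[str, tuple[MonocularField, MonocularField]] = {}
    for idx, group in enumerate(groups):
        sid = f"S{idx + 1:03d}"
        if group == "glaucoma":
            age = rng.normal(spec.age_mean_glaucoma, spec.age_sd_glaucoma)
            va = max(0.0, rng.normal(0.13, 0.12))
            moca = float(np.clip(np.round(rng.normal(24.7, 3.0)), 0, 30))
            vfq_driving = float(np.clip(rng.normal(80.9, 13.5), 0, 100))
            vfq_peripheral = float(np.clip(rng.normal(84.1, 16.4), 0, 100))
            vfq_total = float(np.clip(rng.normal(87.8, 7.0), 0, 100))
            gender = "F" if rng.random() < 0.44 else "M"
            archetype = Archetype(mix_names[rng.choice(len(mix_names), p=mix_probs)])
            asymmetry = float(rng.uniform(0.0, 4.0))
        else:
            age = rng.normal(spec.age_mean_suspect, spec.age_sd_suspect)
            va = max(0.0, rng.normal(0.06, 0.09))
            moca = float(np.clip(np.round(rng.normal(25.4, 2.4)), 0, 30))
            vfq_driving = float(np.clip(rng.normal(87.8, 15.1), 0, 100))
            vfq_peripheral = float(np.clip(rng.normal(93.3, 11.4), 0, 100))
            vfq_total = float(np.clip(rng.normal(91.6, 7.6), 0, 100))
            gender = "F" if rng.random() < 0.78 else "M"
            archetype = Archetype.NORMAL
            asymmetry = 0.0
        age = float(np.clip(age, 25.0, 95.0))
        left, right = simulate_monocular_pair(
            DefectArchetype(archetype, spec.td_noise_sd),
            asymmetry=asymmetry,
            pattern_id=spec.pattern,
            seed=rng.integers(0, 2**31 - 1),
        )
        fields[sid] = (left, right)
        ou_vfi = integrate_fields(left, right).vfi
        subjects.append(
            {
                "subject_id": sid,
                "group": group,
                "archetype": archetype.value,
                "age": age,
                "gender": gender,
                "va_worst": va,
                "moca_total": moca,
                "vfq_total": vfq_total,
                "vfq_peripheral": vfq_peripheral,
                "vfq_driving": vfq_driving,
                "ou_vfi": ou_vfi,
            }
        )

    table = pd.DataFrame(subjects)
    table["logit_ou"] = _logit(table["ou_vfi"].to_numpy() / 100.0, spec.logit_eps)

    rows = []
    for _, subj in table.iterrows():
        intercepts = {
            out: rng.normal(0.0, spec.subject_sd) for out in spec.betas
        }
        for drive in range(1, spec.drives_per_subject + 1):
            row = dict(subj)
            row["drive"] = drive
            for out, b in spec.betas.items():
                lp = (
                    b["intercept"]
                    + b["age"] * subj["age"]
                    + b["va_worst"] * subj["va_worst"]
                    + b["logit_ou"] * subj["logit_ou"]
                    + b["moca_total"] * subj["moca_total"]
                    + b["vfq_driving"] * subj["vfq_driving"]
                )
                row[out] = float(np.exp(lp + intercepts[out] + rng.normal(0.0, spec.residual_sd)))
            rows.append(row)
    cohort = pd.DataFrame(rows)
    if return_fields:
        return cohort, fields
    return cohort
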