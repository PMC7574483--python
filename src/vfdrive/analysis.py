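"""Statistical stages: transforms, group comparisons, and mixed models of
vehicle control.

The workflow mirrors a standard clinical driving-simulation analysis:

* descriptive group comparisons — pooled or Welch t-tests (chosen by a
  Levene variance-equality pre-check), Wilcoxon rank-sum for bounded ordinal
  scores (MoCA), chi-square for categorical variables, Spearman correlation
  screens;
* a logit transform of the binocular visual field index (bounded at 100% in
  healthy suspects) and a natural-log transform of the right-skewed
  vehicle-control outcomes;
* linear mixed models of log outcome on age, worst-eye acuity, the disease
  exposure (logit OU-VFI or diagnostic group), MoCA total and VFQ driving
  sub-score, with a random intercept per subject for repeated drives.

Denominator degrees of freedom use a between-within (BW) allocation: every
model covariate here is constant within subject, so each fixed effect is
tested against n_subjects − rank(between design).  Cohen's d for continuous
terms is 2t/√df; for the two-level group term it is the difference in
adjusted means over the pooled residual SD.
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "AnalysisError",
    "logit_ou",
    "log_outcome",
    "group_comparisons",
    "fit_vehicle_control_model",
    "MODEL_COVARIATES",
]


class AnalysisError(ValueError):
    """Raised for invalid analysis inputs (out-of-range values, bad designs)."""


DEFAULT_LOGIT_EPS = 0.005

#: Covariates entering the multivariable vehicle-control models besides the
#: disease exposure.
MODEL_COVARIATES = ("age", "va_worst", "moca_total", "vfq_driving")


def logit_ou(vfi, eps: float = DEFAULT_LOGIT_EPS):
    """Logit transform of a VFI percentage, expanding its compressed upper range.

    ``p = vfi/100`` is clamped into [eps, 1−eps] before ln(p/(1−p)) so that
    fully intact fields (VFI = 100%) stay finite and keep their ordering.
    """
    vfi = np.asarray(vfi, dtype=float)
    if np.any(vfi < 0) or np.any(vfi > 100):
        raise AnalysisError("VFI values must lie in [0, 100]")
    if not 0 < eps < 0.5:
        raise AnalysisError("logit clamp eps must be in (0, 0.5)")
    p = np.clip(vfi / 100.0, eps, 1.0 - eps)
    out = np.log(p / (1.0 - p))
    return float(out) if out.ndim == 0 else out


def log_outcome(y):
    """Natural log of a positive outcome; ``exp`` is its exact inverse."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise AnalysisError("log transform requires strictly positive outcomes")
    out = np.log(y)
    return float(out) if out.ndim == 0 else out


def _cohens_d_groups(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


DEFAULT_CONTINUOUS = ("age", "va_worst", "ou_vfi", "vfq_total", "vfq_peripheral", "vfq_driving")
DEFAULT_RANK = ("moca_total",)
DEFAULT_CATEGORICAL = ("gender",)
DEFAULT_SPEARMAN = (("ou_vfi", "moca_total"),)


def group_comparisons(
    cohort: pd.DataFrame,
    continuous: tuple = DEFAULT_CONTINUOUS,
    rank: tuple = DEFAULT_RANK,
    categorical: tuple = DEFAULT_CATEGORICAL,
    spearman: tuple = DEFAULT_SPEARMAN,
    levene_alpha: float = 0.05,
) -> pd.DataFrame:
    """Between-group descriptive tests on a subject-level cohort table.

    Continuous variables get an independent-sample t-test, pooled when a
    Levene pre-check accepts equal variances at ``levene_alpha`` and Welch
    otherwise.  Rank variables get a Wilcoxon rank-sum (Mann-Whitney) test,
    categorical variables a chi-square test of the contingency table, and
    each ``spearman`` pair a correlation over all subjects.  Variables with
    zero variance in both groups are flagged and skipped with a warning.
    Repeated drive rows are collapsed to one row per subject first.
    """
    if "group" not in cohort.columns:
        raise AnalysisError("cohort table needs a 'group' column")
    subj = cohort.drop_duplicates("subject_id") if "subject_id" in cohort.columns else cohort
    levels = sorted(subj["group"].unique())
    if len(levels) != 2:
        raise AnalysisError(f"exactly two groups required, found {levels}")
    ga = subj[subj["group"] == levels[0]]
    gb = subj[subj["group"] == levels[1]]
    if ga.empty or gb.empty:
        raise AnalysisError("both groups must be non-empty")

    rows = []
    for var in continuous:
        a = ga[var].dropna().to_numpy(dtype=float)
        b = gb[var].dropna().to_numpy(dtype=float)
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            warnings.warn(f"variable {var!r} has zero variance in both groups; test skipped")
            rows.append({"variable": var, "test": "t", "note": "zero variance; skipped"})
            continue
        _, p_lev = stats.levene(a, b)
        equal_var = p_lev >= levene_alpha
        t = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append(
            {
                "variable": var,
                "test": "t (pooled)" if equal_var else "t (Welch)",
                "estimate": float(a.mean() - b.mean()),
                "statistic": float(t.statistic),
                "df": float(t.df),
                "p_value": float(t.pvalue),
                "cohens_d": _cohens_d_groups(a, b),
            }
        )
    for var in rank:
        a = ga[var].dropna().to_numpy(dtype=float)
        b = gb[var].dropna().to_numpy(dtype=float)
        if np.var(np.concatenate([a, b])) == 0:
            warnings.warn(f"variable {var!r} has zero variance; rank test skipped")
            rows.append({"variable": var, "test": "wilcoxon_rank_sum", "note": "zero variance; skipped"})
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "variable": var,
                "test": "wilcoxon_rank_sum",
                "estimate": float(np.median(a) - np.median(b)),
                "statistic": float(res.statistic),
                "p_value": float(res.pvalue),
            }
        )
    for var in categorical:
        contingency = pd.crosstab(subj["group"], subj[var])
        if contingency.shape[1] < 2:
            warnings.warn(f"variable {var!r} has a single level; chi-square skipped")
            rows.append({"variable": var, "test": "chi2", "note": "single level; skipped"})
            continue
        chi2, p, dof, _ = stats.chi2_contingency(contingency)
        rows.append(
            {"variable": var, "test": "chi2", "statistic": float(chi2), "df": float(dof), "p_value": float(p)}
        )
    for var_a, var_b in spearman:
        sub = subj[[var_a, var_b]].dropna()
        rho, p = stats.spearmanr(sub[var_a], sub[var_b])
        rows.append(
            {
                "variable": f"{var_a}~{var_b}",
                "test": "spearman",
                "estimate": float(rho),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)


def _check_rank(design: pd.DataFrame) -> None:
    mat = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name the offending columns by dropping each in turn
        collinear = [
            col
            for col in design.columns
            if np.linalg.matrix_rank(design.drop(columns=[col]).to_numpy(dtype=float)) == rank
        ]
        raise AnalysisError(f"rank-deficient design; collinear terms: {collinear}")


def fit_vehicle_control_model(
    cohort: pd.DataFrame,
    outcome: str = "steering_sd",
    exposure: str = "logit_ou",
    covariates: tuple = MODEL_COVARIATES,
    logit_eps: float = DEFAULT_LOGIT_EPS,
) -> pd.DataFrame:
    """Multivariable model of a log-transformed vehicle-control outcome.

    Fits ``log(outcome) ~ covariates + exposure`` with a random intercept
    per subject when subjects have repeated drives; with a single drive per
    subject the model degrades to ordinary least squares (the random
    intercept is unidentifiable) and a notice is logged.  ``exposure`` is
    either ``"logit_ou"`` (computed from ``ou_vfi`` if absent) or
    ``"group"`` (glaucoma vs suspect indicator).

    Returns a tidy table with one row per fixed effect: Effect, Estimate,
    SE, DF (between-within), F, t, p, and Cohen's d for non-intercept terms.
    Rows with missing model variables are dropped listwise with a warning.
    """
    if outcome not in cohort.columns:
        raise AnalysisError(f"outcome column {outcome!r} not in cohort")
    data = cohort.copy()
    if exposure == "logit_ou" and "logit_ou" not in data.columns:
        data["logit_ou"] = logit_ou(data["ou_vfi"].to_numpy(dtype=float), eps=logit_eps)
    if exposure == "group":
        if set(data["group"].unique()) - {"glaucoma", "suspect"}:
            raise AnalysisError("group exposure expects levels {'glaucoma', 'suspect'}")
        data["group_glaucoma"] = (data["group"] == "glaucoma").astype(float)
        exposure_col = "group_glaucoma"
        exposure_label = "Group: glaucoma vs suspect"
    elif exposure == "logit_ou":
        exposure_col = "logit_ou"
        exposure_label = "Logit (OU)"
    else:
        raise AnalysisError(f"unknown exposure {exposure!r}; use 'logit_ou' or 'group'")

    terms = list(covariates) + [exposure_col]
    model_cols = ["subject_id", outcome] + terms
    missing_cols = [c for c in model_cols if c not in data.columns]
    if missing_cols:
        raise AnalysisError(f"cohort table missing columns: {missing_cols}")
    n_before = len(data)
    data = data.dropna(subset=model_cols)
    if len(data) < n_before:
        warnings.warn(f"dropped {n_before - len(data)} rows with missing model variables")
    if data.empty:
        raise AnalysisError("no complete cases to fit")

    data = data.sort_values(["subject_id"]).reset_index(drop=True)
    y = log_outcome(data[outcome].to_numpy(dtype=float))
    design = data[terms].astype(float).copy()
    design.insert(0, "Intercept", 1.0)
    _check_rank(design)

    # standardize covariates for the optimizer; map estimates back afterwards
    means = design.mean().to_numpy()
    scales = design.std(ddof=0).to_numpy()
    means[0], scales[0] = 0.0, 1.0  # leave the intercept column alone
    scaled = (design - means) / scales
    k = design.shape[1]
    # beta_orig = T @ beta_scaled: slopes divide by their scale, the
    # intercept absorbs the centering offsets
    transform = np.zeros((k, k))
    transform[0, 0] = 1.0
    for j in range(1, k):
        transform[j, j] = 1.0 / scales[j]
        transform[0, j] = -means[j] / scales[j]

    groups = data["subject_id"].to_numpy()
    n_subjects = data["subject_id"].nunique()
    max_drives = data.groupby("subject_id").size().max()

    if max_drives >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(endog=y, exog=scaled, groups=groups)
            try:
                fit = model.fit(reml=True)
            except np.linalg.LinAlgError:
                fit = model.fit(reml=True, method="powell")
        params_scaled = fit.fe_params.to_numpy()
        cov_scaled = np.asarray(fit.cov_params())[:k, :k]
    else:
        warnings.warn("single drive per subject: fitting ordinary least squares instead of a mixed model")
        fit = sm.OLS(y, scaled).fit()
        params_scaled = fit.params.to_numpy()
        cov_scaled = np.asarray(fit.cov_params())

    params_vec = transform @ params_scaled
    cov = transform @ cov_scaled @ transform.T
    params = pd.Series(params_vec, index=design.columns)
    ses = pd.Series(np.sqrt(np.diag(cov)), index=design.columns)

    # between-within denominator df: every covariate is subject-level here
    p_between = design.shape[1]
    df_denom = max(n_subjects - p_between, 1)

    rows = []
    label_map = {
        "Intercept": "Intercept",
        "age": "Age",
        "va_worst": "VA worst",
        "moca_total": "MoCA total",
        "vfq_driving": "VFQ driving",
        exposure_col: exposure_label,
    }
    for name in design.columns:
        est = float(params[name])
        se = float(ses[name])
        tval = est / se
        pval = float(2 * stats.t.sf(abs(tval), df_denom))
        row = {
            "effect": label_map.get(name, name),
            "term": name,
            "estimate": est,
            "se": se,
            "df": float(df_denom),
            "t": float(tval),
            "F": float(tval**2),
            "p_value": pval,
        }
        if name != "Intercept":
            if name == "group_glaucoma":
                ga = data.loc[data[name] == 1.0, outcome]
                gb = data.loc[data[name] == 0.0, outcome]
                row["cohens_d"] = _cohens_d_groups(np.log(ga.to_numpy()), np.log(gb.to_numpy()))
            else:
                row["cohens_d"] = float(2 * tval / np.sqrt(df_denom))
        rows.append(row)
    return pd.DataFrame(rows)
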