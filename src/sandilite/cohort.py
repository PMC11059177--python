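"""Synthetic patient/control cohort and the study's statistical stages.

The generator emulates the effect structure of a multiple-sclerosis
imaging cohort: a small group difference in whole-cortex soma fraction
(healthy controls 0.34 ± 0.01 vs patients 0.33 ± 0.02), layer-specific
offsets (outer-layer increase, largest in progressive MS; inner-layer
decrease in MS), a subpial-vs-leukocortical lesion contrast present in
relapsing–remitting MS only, correlations of lesion soma fraction with
quantitative T1 (negative) and MTsat (positive), and a serum
neurofilament (sNfL) z-score driven linearly by white-matter lesion
volume (slope 0.334 per 10 cl) and lesion soma fraction (slope 0.738 per
5 percentage points).

Analysis stages: Welch's t-test for the whole-cortex comparison, a
random-intercept-per-patient mixed model for lesion-wise Δf_soma,
Pearson correlations for the qMRI comparisons, and an ordinary linear
model with a nested likelihood-ratio comparison for the sNfL variance
decomposition.

Tables are pandas DataFrames; see SUBJECT_COLUMNS / LESION_COLUMNS for
the CSV schemas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "CohortConfig",
    "SUBJECT_COLUMNS",
    "LESION_COLUMNS",
    "generate_cohort",
    "welch_test",
    "delta_fsoma",
    "lesionwise_model",
    "pearson_corr",
    "snfl_model",
]

SUBJECT_COLUMNS = [
    "subject_id", "group", "age", "sex", "treatment",
    "cortex_fsoma_mean", "inner_fsoma_mean", "outer_fsoma_mean",
    "wm_lesion_volume", "snfl_z",
]

LESION_COLUMNS = [
    "subject_id", "lesion_type", "lesion_fsoma_mean",
    "perilesion_fsoma_mean", "qt1", "mtsat",
]

GROUPS = ("HC", "RRMS", "PMS")
LESION_TYPES = ("subpial", "leukocortical")
TREATMENTS = ("untreated", "oral", "monoclonal")


@dataclass(frozen=True)
class CohortConfig:
    """Generator calibration.

    Group sizes and cortical means follow the study cohort (80 HC, 98
    RRMS, 57 progressive MS; HC cortex 0.34 ± 0.01, MS 0.33 ± 0.02).
    Layer offsets and lesion effects encode directions the study reports
    without printing magnitudes, at plausible small values.  sNfL slopes
    are 0.334 per 10 cl of WM lesion volume and 0.738 per 5-point f_soma
    increase.
    """

    n_hc: int = 80
    n_rrms: int = 98
    n_pms: int = 57
    cortex_mean: dict = field(default_factory=lambda: {
        "HC": 0.34, "RRMS": 0.33, "PMS": 0.33})
    cortex_sd: dict = field(default_factory=lambda: {
        "HC": 0.01, "RRMS": 0.02, "PMS": 0.02})
    outer_offset: dict = field(default_factory=lambda: {
        "HC": 0.0, "RRMS": 0.005, "PMS": 0.010})
    inner_offset: dict = field(default_factory=lambda: {
        "HC": 0.0, "RRMS": -0.005, "PMS": -0.005})
    layer_sd: float = 0.005
    age_mean: dict = field(default_factory=lambda: {
        "HC": 37.0, "RRMS": 44.0, "PMS": 50.0})
    age_sd: float = 13.0
    # lesions (MS only)
    mean_lesions_per_patient: float = 7.0
    p_subpial: float = 0.07
    lesion_delta_base: float = -0.01           # leukocortical Δf_soma
    subpial_delta_extra: dict = field(default_factory=lambda: {
        "RRMS": 0.03, "PMS": 0.0})
    lesion_patient_sd: float = 0.01            # per-patient random intercept
    lesion_noise_sd: float = 0.02
    qt1_corr: float = -0.5
    qt1_mean: float = 1.8                      # s
    qt1_sd: float = 0.2
    mtsat_corr: float = 0.5
    mtsat_mean: float = 1.5                    # p.u.
    mtsat_sd: float = 0.4
    # sNfL model
    snfl_intercept: float = 0.5
    snfl_slope_wm: float = 0.334               # per 10 cl
    snfl_slope_fsoma: float = 0.738            # per 5 points of f_soma
    snfl_noise_sd: float = 1.0
    wm_volume_mean: float = 5.0                # cl
    seed: int = 0

    def __post_init__(self):
        for g in GROUPS:
            if self.cortex_sd[g] <= 0:
                raise ValueError("cortical SDs must be > 0")
        for n in (self.n_hc, self.n_rrms, self.n_pms):
            if n and n < 2:
                raise ValueError("group sizes must be 0 or >= 2")


def generate_cohort(config: CohortConfig = CohortConfig()
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic cohort: (subjects, lesions) tables.

    Deterministic for a given ``config.seed``.  Lesion records and sNfL
    values exist only for MS subjects; HC lesion fields are absent from
    the lesion table and HC ``wm_lesion_volume``/``snfl_z`` are NaN.
    """
    rng = np.random.default_rng(config.seed)
    subj_rows = []
    lesion_rows = []
    sid = 0
    for group, n in (("HC", config.n_hc), ("RRMS", config.n_rrms),
                     ("PMS", config.n_pms)):
        for _ in range(n):
            sid += 1
            cortex = float(np.clip(
                rng.normal(config.cortex_mean[group], config.cortex_sd[group]),
                0.0, 1.0))
            inner = float(np.clip(
                cortex + config.inner_offset[group]
                + rng.normal(0, config.layer_sd), 0.0, 1.0))
            outer = float(np.clip(
                cortex + config.outer_offset[group]
                + rng.normal(0, config.layer_sd), 0.0, 1.0))
            age = float(rng.normal(config.age_mean[group], config.age_sd))
            sex = str(rng.choice(["F", "M"], p=[0.6, 0.4]))
            treatment = ("none" if group == "HC"
                         else str(rng.choice(TREATMENTS, p=[0.2, 0.4, 0.4])))
            row = {
                "subject_id": f"S{sid:04d}", "group": group, "age": age,
                "sex": sex, "treatment": treatment,
                "cortex_fsoma_mean": cortex, "inner_fsoma_mean": inner,
                "outer_fsoma_mean": outer,
                "wm_lesion_volume": np.nan, "snfl_z": np.nan,
            }
            if group != "HC":
                wm = float(rng.gamma(2.0, config.wm_volume_mean / 2.0))
                row["wm_lesion_volume"] = wm
                row["snfl_z"] = float(
                    config.snfl_intercept
                    + config.snfl_slope_wm * (wm / 10.0)
                    + config.snfl_slope_fsoma
                    * ((cortex - config.cortex_mean[group]) / 0.05)
                    + rng.normal(0, config.snfl_noise_sd))
                n_lesions = int(rng.poisson(config.mean_lesions_per_patient))
                patient_shift = float(rng.normal(0, config.lesion_patient_sd))
                for _ in range(n_lesions):
                    ltype = ("subpial" if rng.random() < config.p_subpial
                             else "leukocortical")
                    peri = float(np.clip(
                        cortex + rng.normal(0, config.lesion_noise_sd), 0, 1))
                    delta = (config.lesion_delta_base + patient_shift
                             + (config.subpial_delta_extra[group]
                                if ltype == "subpial" else 0.0)
                             + rng.normal(0, config.lesion_noise_sd))
                    lesion = float(np.clip(peri + delta, 0, 1))
                    # latent standardized lesion f_soma drives the qMRI draws
                    z = (lesion - cortex) / max(config.lesion_noise_sd, 1e-9)
                    qt1 = float(
                        config.qt1_mean + config.qt1_sd
                        * (config.qt1_corr * z
                           + np.sqrt(1 - config.qt1_corr ** 2) * rng.normal()))
                    mtsat = float(
                        config.mtsat_mean + config.mtsat_sd
                        * (config.mtsat_corr * z
                           + np.sqrt(1 - config.mtsat_corr ** 2) * rng.normal()))
                    lesion_rows.append({
                        "subject_id": row["subject_id"], "lesion_type": ltype,
                        "lesion_fsoma_mean": lesion,
                        "perilesion_fsoma_mean": peri,
                        "qt1": qt1, "mtsat": mtsat,
                    })
            subj_rows.append(row)
    subjects = pd.DataFrame(subj_rows, columns=SUBJECT_COLUMNS)
    lesions = pd.DataFrame(lesion_rows, columns=LESION_COLUMNS)
    return subjects, lesions


def welch_test(values_a, values_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-tailed p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def delta_fsoma(lesion) -> float:
    """Δf_soma = lesion mean − perilesion mean for one lesion record
    (mapping or Series); NaN inputs flag the record as missing."""
    l = lesion["lesion_fsoma_mean"]
    p = lesion["perilesion_fsoma_mean"]
    if pd.isna(l) or pd.isna(p):
        return float("nan")
    return float(l - p)


def lesionwise_model(lesions: pd.DataFrame, subjects: pd.DataFrame,
                     reml: bool = False) -> pd.DataFrame:
    """Random-intercept-per-patient model of lesion Δf_soma.

    Fixed effects: age, sex, treatment and lesion type; random intercept
    per subject; fitted by maximum likelihood (``reml=True`` for REML).
    Returns the fixed-effect table (estimate, SE, z, two-tailed p) with
    the ``lesion_type`` row carrying the subpial-vs-leukocortical
    contrast.
    """
    df = lesions.merge(
        subjects[["subject_id", "age", "sex", "treatment", "group"]],
        on="subject_id", how="left")
    if df[["age", "sex", "treatment", "lesion_type"]].isna().any().any():
        raise ValueError("covariates incomplete")
    df = df.assign(delta=df["lesion_fsoma_mean"] - df["perilesion_fsoma_mean"])
    df["lesion_type"] = pd.Categorical(df["lesion_type"],
                                       categories=list(LESION_TYPES)[::-1])
    n_per = df.groupby("subject_id").size()
    if not (n_per >= 2).any():
        raise ValueError("need repeated lesions within subjects")
    terms = ["age", "C(sex)", "C(treatment)", "C(lesion_type)"]
    # drop constant covariates to keep the design non-singular
    terms = [t for t in terms
             if not t.startswith("C(") or df[t[2:-1]].nunique() > 1]
    formula = "delta ~ " + " + ".join(terms)
    exog = smf.ols(formula, df).fit().model.exog
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError(
            f"singular design (rank {np.linalg.matrix_rank(exog)} < "
            f"{exog.shape[1]} columns)")
    try:
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            model = smf.mixedlm(formula, df, groups=df["subject_id"])
            fit = model.fit(reml=reml, method="lbfgs")
        params, bse = fit.fe_params, fit.bse_fe
    except np.linalg.LinAlgError:
        # random-intercept variance on the boundary (≈0): the mixed model
        # degenerates to OLS, whose estimates are then the MLE
        fit = smf.ols(formula, df).fit()
        params, bse = fit.params, fit.bse
    out = pd.DataFrame({
        "estimate": params,
        "se": bse,
        "z": params / bse,
    })
    out["p"] = 2 * stats.norm.sf(np.abs(out["z"]))
    return out


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson correlation with the two-tailed t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need n >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def snfl_model(subjects: pd.DataFrame,
               fsoma_reference: float = 0.33) -> dict:
    """Linear model of sNfL z on scaled f_soma, WM volume and covariates.

    f_soma enters per 5 percentage points above ``fsoma_reference``, WM
    lesion volume per 10 cl; MS subtype and treatment are categorical
    covariates.  Returns the full-model coefficient table, adjusted R² of
    the full and f_soma-free reduced models, their difference, and the
    likelihood-ratio p-value for the nested pair.
    """
    df = subjects[subjects["group"].isin(["RRMS", "PMS"])].dropna(
        subset=["snfl_z", "wm_lesion_volume"]).copy()
    if len(df) < 5:
        raise ValueError("too few MS subjects with sNfL data")
    df["fsoma_per5"] = (df["cortex_fsoma_mean"] - fsoma_reference) / 0.05
    df["wm_per10"] = df["wm_lesion_volume"] / 10.0
    terms = ["wm_per10", "C(group)", "C(treatment)"]
    terms = [t for t in terms
             if not t.startswith("C(") or df[t[2:-1]].nunique() > 1]
    reduced = smf.ols("snfl_z ~ " + " + ".join(terms), df).fit()
    cond = np.linalg.cond(reduced.model.exog)
    if cond > 1e8:
        raise ValueError(f"collinear design (condition number {cond:.2e})")
    if df["fsoma_per5"].nunique() > 1:
        full = smf.ols("snfl_z ~ fsoma_per5 + " + " + ".join(terms), df).fit()
    else:
        # constant f_soma carries no information: full model = reduced
        full = reduced
    lr = 2 * (full.llf - reduced.llf)
    lr_df = full.df_model - reduced.df_model
    lr_p = float(stats.chi2.sf(lr, lr_df)) if lr_df > 0 else 1.0
    table = pd.DataFrame({
        "estimate": full.params, "se": full.bse,
        "t": full.tvalues, "p": full.pvalues,
        "ci_low": full.conf_int()[0], "ci_high": full.conf_int()[1],
    })
    return {
        "coefficients": table,
        "adj_r2_full": float(full.rsquared_adj),
        "adj_r2_reduced": float(reduced.rsquared_adj),
        "adj_r2_difference": float(full.rsquared_adj - reduced.rsquared_adj),
        "lr_statistic": float(lr),
        "lr_p": lr_p,
        "n": int(len(df)),
    }
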