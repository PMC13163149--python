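"""Confounder-adjusted group comparison of RV metrics.

Stage order, per metric:

1. **GAM residualisation** — each metric is regressed on the pooled cohort
   (patients + controls together, *without* a group term, so the adjustment
   cannot absorb a genuine group effect) as
   ``metric ~ s(age) + sex + temperature + heart_rate + pulse_pressure``
   with a penalised B-spline smooth of age (basis dimension 5); the adjusted
   value is the residual plus the pooled mean.  The smoothing penalty is
   chosen per metric by generalised cross-validation over a log-spaced grid.
2. **Shapiro-Wilk screen** — per-group normality p-values, reported only:
   inference is fixed to the Mann-Whitney U test regardless, because RV
   metrics are typically non-normal.
3. **Bootstrap** — B resamples (default 1000) of subjects with replacement
   within each group give a percentile 95% CI of the patient-minus-control
   difference of medians (effect size).
4. **Mann-Whitney U** — two-sided p per metric (exact null distribution for
   small tie-free samples, tie-corrected normal approximation otherwise),
   then Benjamini-Hochberg FDR q-values across the metric panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.stats.multitest import multipletests

from .errors import AdjustmentError, ParameterError

logger = logging.getLogger(__name__)

COVARIATES = ["age", "sex", "temperature", "heart_rate", "pulse_pressure"]


@dataclass
class SubjectRecord:
    """Covariates, group label and clinical annotations for one subject."""

    subject_id: str
    group: str  # 'patient' or 'control'
    age: float
    sex: int  # 0 female, 1 male
    temperature: float  # deg C
    heart_rate: float  # beats/min
    pulse_pressure: float  # mmHg
    crsr_total: int | None = None  # 0-23, patients only
    outcome: str | None = None  # 'improved'/'unimproved', patients only
    crsr_latent: float | None = None  # pre-clamp linear-link value (synthetic cohorts)

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ParameterError(f"group must be patient/control, got {self.group!r}")
        if self.group == "control" and (
            self.crsr_total is not None or self.outcome is not None
        ):
            raise ParameterError("controls carry no CRS-R score or outcome label")


def subjects_to_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age,
                "sex": s.sex,
                "temperature": s.temperature,
                "heart_rate": s.heart_rate,
                "pulse_pressure": s.pulse_pressure,
                "crsr_total": s.crsr_total,
                "outcome": s.outcome,
            }
        )
    return pd.DataFrame(rows).set_index("subject_id")


# -- GAM adjustment -----------------------------------------------------------

ALPHA_GRID = np.logspace(-3, 4, 6)


def _fit_gam_gcv(y: np.ndarray, exog: np.ndarray, smoother: BSplines) -> np.ndarray:
    """Fit the Gaussian GAM at each grid alpha, keep the GCV-best fit."""
    n = len(y)
    best = None
    best_gcv = np.inf
    for alpha in ALPHA_GRID:
        try:
            res = GLMGam(y, exog=exog, smoother=smoother, alpha=float(alpha)).fit()
        except (np.linalg.LinAlgError, ValueError) as exc:  # pragma: no cover
            raise AdjustmentError(str(exc)) from exc
        rss = float(np.sum((y - res.fittedvalues) ** 2))
        edf = float(np.sum(res.edf))
        denom = max(n - edf, 1e-8)
        gcv = n * rss / denom**2
        if gcv < best_gcv:
            best_gcv, best = gcv, res
    return np.asarray(best.fittedvalues)


def gam_adjust(
    features: pd.DataFrame,
    subjects: pd.DataFrame,
    spline_df: int = 5,
) -> pd.DataFrame:
    """Residualise each metric on the covariates; returns the adjusted table.

    ``features`` and ``subjects`` are joined on their (subject_id) index.
    Rows with any missing covariate are dropped with a logged count.
    Adjusted value = residual + pooled metric mean, so adjusted metrics stay
    on their original scale.
    """
    if isinstance(subjects, list):
        subjects = subjects_to_frame(subjects)
    cov = subjects[COVARIATES].apply(pd.to_numeric, errors="coerce")
    complete = cov.dropna().index.intersection(features.index)
    n_dropped = len(features.index) - len(complete)
    if n_dropped:
        logger.warning("gam_adjust: dropped %d subject(s) with missing covariates", n_dropped)
    if len(complete) < 20:
        raise AdjustmentError(f"only {len(complete)} complete subjects; need >= 20")
    feats = features.loc[complete]
    cov = cov.loc[complete]

    age = cov["age"].to_numpy()[:, None]
    smoother = BSplines(age, df=[spline_df], degree=[3])
    lin = sm.add_constant(
        cov[["sex", "temperature", "heart_rate", "pulse_pressure"]].to_numpy()
    )

    adjusted = pd.DataFrame(index=feats.index, columns=feats.columns, dtype=float)
    for metric in feats.columns:
        y = feats[metric].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            adjusted[metric] = y  # constant metric passes through untouched
            continue
        try:
            fitted = _fit_gam_gcv(y, lin, smoother)
        except AdjustmentError as exc:
            raise AdjustmentError(f"adjustment failed for metric {metric!r}: {exc}") from exc
        adjusted[metric] = y - fitted + y.mean()
    return adjusted


# -- screening and tests ------------------------------------------------------


def shapiro_screen(adjusted: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Shapiro-Wilk normality p per metric per group (NaN for degenerate samples)."""
    out = {}
    for grp in ("patient", "control"):
        vals = []
        sub = adjusted.loc[groups.reindex(adjusted.index) == grp]
        for metric in adjusted.columns:
            x = sub[metric].dropna().to_numpy()
            if len(x) < 3 or np.ptp(x) == 0:
                vals.append(np.nan)
            else:
                vals.append(stats.shapiro(x).pvalue)
        out[f"shapiro_p_{grp}"] = vals
    return pd.DataFrame(out, index=adjusted.columns)


def mann_whitney(adjusted: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per metric, patient sample first.

    Exact null distribution when min(n1, n2) <= 8 and there are no ties;
    tie-corrected normal approximation otherwise.
    """
    groups = groups.reindex(adjusted.index)
    rows = []
    for metric in adjusted.columns:
        x = adjusted.loc[groups == "patient", metric].dropna().to_numpy()
        y = adjusted.loc[groups == "control", metric].dropna().to_numpy()
        if min(len(x), len(y)) < 3:
            raise ParameterError(f"metric {metric!r}: both groups need n >= 3")
        no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
        method = "exact" if (min(len(x), len(y)) <= 8 and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append({"metric": metric, "U": float(res.statistic), "p": float(res.pvalue)})
    return pd.DataFrame(rows).set_index("metric")


def bootstrap_compare(
    adjusted: pd.DataFrame,
    groups: pd.Series,
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Percentile bootstrap CI of the patient-minus-control median difference.

    Subjects are resampled with replacement within each group B times; the
    CI bounds are the 2.5/97.5 percentiles of the resampled statistic.
    """
    if B < 1:
        raise ParameterError("B must be >= 1")
    groups = groups.reindex(adjusted.index)
    rng = np.random.default_rng(seed)
    rows = []
    pat = adjusted.loc[groups == "patient"]
    ctl = adjusted.loc[groups == "control"]
    for metric in adjusted.columns:
        x = pat[metric].dropna().to_numpy()
        y = ctl[metric].dropna().to_numpy()
        if min(len(x), len(y)) < 5:
            raise ParameterError(f"metric {metric!r}: both groups need n >= 5")
        bx = x[rng.integers(0, len(x), size=(B, len(x)))]
        by = y[rng.integers(0, len(y), size=(B, len(y)))]
        stat = np.median(bx, axis=1) - np.median(by, axis=1)
        lo, hi = np.percentile(stat, [2.5, 97.5])
        rows.append(
            {
                "metric": metric,
                "median_patient": float(np.median(x)),
                "median_control": float(np.median(y)),
                "diff": float(np.median(x) - np.median(y)),
                "ci_lo": float(lo),
                "ci_hi": float(hi),
            }
        )
    return pd.DataFrame(rows).set_index("metric")


def fdr_correct(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# -- orchestration ------------------------------------------------------------


@dataclass
class ComparisonResult:
    """Per-metric adjusted group comparison table plus run parameters."""

    table: pd.DataFrame  # indexed by metric
    B: int
    alpha: float
    seed: int
    n_patient: int
    n_control: int

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def to_json_dict(self) -> dict:
        return {
            "B": self.B,
            "alpha": self.alpha,
            "seed": self.seed,
            "n_patient": self.n_patient,
            "n_control": self.n_control,
            "n_significant": int(self.table["significant"].sum()),
            "significant_metrics": sorted(self.table.index[self.table["significant"]]),
        }


def compare_groups(
    features: pd.DataFrame,
    subjects: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    adjust: bool = True,
) -> ComparisonResult:
    """Full comparison stage: adjust, screen, bootstrap, test, FDR-correct.

    The Mann-Whitney test supplies the primary p-value; the bootstrap supplies
    the effect-size CI.  Both are computed on the adjusted metrics.
    """
    if isinstance(subjects, list):
        subjects = subjects_to_frame(subjects)
    groups = subjects["group"]
    adjusted = gam_adjust(features, subjects) if adjust else features.copy()
    groups = groups.reindex(adjusted.index)
    shapiro = shapiro_screen(adjusted, groups)
    boot = bootstrap_compare(adjusted, groups, B=B, seed=seed)
    mw = mann_whitney(adjusted, groups)
    table = boot.join(mw).join(shapiro)
    table["q"] = fdr_correct(table["p"].to_numpy())
    table["significant"] = table["q"] < alpha
    return ComparisonResult(
        table=table,
        B=B,
        alpha=alpha,
        seed=seed,
        n_patient=int((groups == "patient").sum()),
        n_control=int((groups == "control").sum()),
    )
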