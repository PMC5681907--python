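"""Biomarker preparation: cohort filter, covariate adjustment, c-scores, screening.

The modeling cohort is amyloid-negative cognitively-normal controls versus
amyloid-positive patients (PET SUVR cut-point, default 1.10). Biomarkers are
regressed on healthy covariates (fit on controls only, residuals kept for
everyone), standardized to control-referenced "c-scores" whose sign is chosen
so abnormality increases, and screened for disease signal with a two-sided
Mann-Whitney rank-sum test at a Bonferroni-corrected threshold.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CovariateCollinearityError, DegenerateBiomarkerError
from .graph_metrics import GlobalMetricSet

__all__ = [
    "select_cohort",
    "adjust_covariates",
    "to_cscores",
    "rank_sum_test",
    "disease_signal_filter",
    "compare_global_metrics",
]

log = logging.getLogger(__name__)


def select_cohort(
    table: pd.DataFrame, suvr_cutoff: float = 1.10
) -> tuple[pd.Series, pd.Series]:
    """Boolean masks for controls (CN, SUVR < cutoff) and patients (AD, SUVR >= cutoff).

    SUVR at exactly the cutoff counts as amyloid-positive. Subjects with a
    missing SUVR are excluded from both groups with a logged warning; other
    diagnoses (EMCI/LMCI) are excluded from model fitting but keep their rows.
    """
    suvr = pd.to_numeric(table["amyloid_suvr"], errors="coerce")
    missing = suvr.isna()
    if missing.any():
        log.warning(
            "%d subjects lack amyloid SUVR and are excluded: %s",
            int(missing.sum()),
            ", ".join(map(str, table.loc[missing, "subject_id"].head(10))),
        )
    controls = (table["diagnosis"] == "CN") & (suvr < suvr_cutoff) & ~missing
    patients = (table["diagnosis"] == "AD") & (suvr >= suvr_cutoff) & ~missing
    return controls, patients


def adjust_covariates(
    table: pd.DataFrame,
    biomarkers: list[str],
    covariates: list[str],
    controls_mask: pd.Series,
    *,
    volume_biomarkers: tuple[str, ...] = (),
    icv_column: str = "icv",
) -> pd.DataFrame:
    """Replace biomarker values by residuals of an OLS fit on controls only.

    Each biomarker is regressed (with intercept) on the covariates using the
    control subjects; all subjects are then replaced by observed minus
    predicted. Volume-type biomarkers additionally include intracranial
    volume as a covariate. Raises if the control design matrix is rank
    deficient, naming the covariates.
    """
    out = table.copy()
    ctrl = np.asarray(controls_mask, dtype=bool)
    for b in biomarkers:
        covs = list(covariates)
        if b in volume_biomarkers:
            covs = covs + [icv_column]
        X = np.column_stack(
            [np.ones(len(table))] + [pd.to_numeric(table[c]).to_numpy(float) for c in covs]
        )
        Xc = X[ctrl]
        if np.linalg.matrix_rank(Xc) < X.shape[1]:
            raise CovariateCollinearityError(
                f"covariates {covs} are collinear/constant among controls (biomarker {b})"
            )
        y = pd.to_numeric(table[b]).to_numpy(float)
        beta, *_ = np.linalg.lstsq(Xc, y[ctrl], rcond=None)
        out[b] = y - X @ beta
    return out


def to_cscores(
    table: pd.DataFrame,
    biomarkers: list[str],
    controls_mask: pd.Series,
    patients_mask: pd.Series,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Standardize to control mean/sd with sign chosen so abnormality increases.

    c = s * (x - mean_controls) / sd_controls with s in {-1, +1} such that the
    patient mean c-score is >= the control mean (ties break toward +1).
    Returns the scored table and the chosen sign per biomarker.
    """
    out = table.copy()
    ctrl = np.asarray(controls_mask, dtype=bool)
    pat = np.asarray(patients_mask, dtype=bool)
    signs: dict[str, int] = {}
    for b in biomarkers:
        x = pd.to_numeric(table[b]).to_numpy(float)
        mu, sd = x[ctrl].mean(), x[ctrl].std(ddof=1)
        if not sd > 0:
            raise DegenerateBiomarkerError(f"biomarker {b}: zero variance in controls")
        z = (x - mu) / sd
        s = -1 if z[pat].mean() < z[ctrl].mean() else 1
        signs[b] = s
        out[b] = s * z
    return out, signs


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney rank-sum p-value.

    Exact enumeration when both groups have <= 10 observations (and no ties
    force the asymptotic path), otherwise the normal approximation with tie
    correction and continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    method = "exact" if (len(x) <= 10 and len(y) <= 10) else "asymptotic"
    if method == "exact" and len(np.unique(np.concatenate([x, y]))) < len(x) + len(y):
        method = "asymptotic"  # exact null assumes no ties
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def disease_signal_filter(
    cscores: pd.DataFrame,
    biomarkers: list[str],
    controls_mask: pd.Series,
    patients_mask: pd.Series,
    alpha: float = 0.05,
    n_tests_per_region: int = 12,
) -> tuple[list[str], pd.DataFrame]:
    """Retain biomarkers whose groups differ at p < alpha / n_tests_per_region.

    The Bonferroni divisor is the number of metrics tested within each region
    (12 for the nodal connectivity set). Returns the retained names plus a
    per-biomarker frame of p-values and verdicts; biomarkers whose groups are
    too small (< 2 each) are dropped with a warning.
    """
    ctrl = np.asarray(controls_mask, dtype=bool)
    pat = np.asarray(patients_mask, dtype=bool)
    threshold = alpha / n_tests_per_region
    rows = []
    retained = []
    for b in biomarkers:
        x = pd.to_numeric(cscores.loc[ctrl, b]).to_numpy(float)
        y = pd.to_numeric(cscores.loc[pat, b]).to_numpy(float)
        if len(x) < 2 or len(y) < 2:
            log.warning("biomarker %s: group too small, test skipped and dropped", b)
            rows.append({"biomarker": b, "p_value": np.nan, "retained": False})
            continue
        p = rank_sum_test(x, y)
        keep = p < threshold
        if keep:
            retained.append(b)
        log.info("biomarker %s: p=%.3g %s", b, p, "retained" if keep else "dropped")
        rows.append({"biomarker": b, "p_value": p, "retained": keep})
    report = pd.DataFrame(rows)
    report.attrs["threshold"] = threshold
    return retained, report


def compare_global_metrics(
    gm_controls: list[GlobalMetricSet] | pd.DataFrame,
    gm_patients: list[GlobalMetricSet] | pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank-sum comparison of the four global metrics at the alpha/4 threshold."""
    def _frame(g):
        if isinstance(g, pd.DataFrame):
            return g
        return pd.DataFrame([m.as_dict() for m in g])

    a, b = _frame(gm_controls), _frame(gm_patients)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    metrics = [c for c in a.columns if c in b.columns]
    threshold = alpha / len(metrics)
    rows = []
    for m in metrics:
        x = a[m].to_numpy(float)
        y = b[m].to_numpy(float)
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        p = rank_sum_test(x, y)
        rows.append(
            {"metric": m, "p_value": p, "threshold": threshold,
             "significant": p < threshold}
        )
    return pd.DataFrame(rows)
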