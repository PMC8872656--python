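"""Two-group comparison of APV parameters.

Each parameter is compared between cohorts with a pooled-variance Student
t-test when both samples pass Shapiro-Wilk normality, and with the
Mann-Whitney U-test otherwise; p values are two-sided.  No multiple-testing
correction is applied by default (parameters are reported individually),
but Benjamini-Hochberg can be switched on for reuse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateVarianceError, InsufficientDataError

SIG_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_tier(p: float) -> str:
    for thr, tier in SIG_THRESHOLDS:
        if p < thr:
            return tier
    return "ns"


def test_normality(x: np.ndarray, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Shapiro-Wilk; returns (W, p, is_normal) with is_normal = (p >= alpha)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise InsufficientDataError("normality testing needs n >= 3")
    if np.ptp(x) == 0.0:
        raise InsufficientDataError("zero-variance sample: normality undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p), bool(p >= alpha)


def student_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sample t-test, two-sided, df = n_x + n_y - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("t-test needs n >= 2 per group")
    sx2 = x.var(ddof=1)
    sy2 = y.var(ddof=1)
    if sx2 == 0.0 and sy2 == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise DegenerateVarianceError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    z: float  # tie-corrected normal deviate (nan on the exact path)
    p: float
    method: str  # 'exact' | 'asymptotic'


def mann_whitney(x: np.ndarray, y: np.ndarray) -> MannWhitneyResult:
    """Mann-Whitney U, two-sided.

    Exact null distribution when n_x + n_y <= 12 without ties; otherwise the
    normal approximation with tie correction and continuity correction.
    U exactly at its null mean is reported as p = 1 (z = 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise InsufficientDataError("Mann-Whitney needs n >= 1 per group")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    mu = nx * ny / 2.0
    if nx + ny <= 12 and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return MannWhitneyResult(float(res.statistic), np.nan, float(res.pvalue), "exact")
    ranks = sps.rankdata(pooled)
    u1 = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    n = nx + ny
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = nx * ny / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0 or u1 == mu:
        return MannWhitneyResult(float(u1), 0.0, 1.0, "asymptotic")
    z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / np.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(abs(z))
    return MannWhitneyResult(float(u1), float(z), min(1.0, float(p)), "asymptotic")


def compare_groups(
    features_a: pd.DataFrame,
    features_b: pd.DataFrame,
    alpha_normality: float = 0.05,
    alpha_sig: float = 0.05,
    label_a: str = "A",
    label_b: str = "B",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-(passage, parameter) two-group comparison of per-subject features.

    Inputs are long-format feature tables (one row per subject x passage x
    parameter).  Missing values are dropped per parameter; a parameter
    present in only one group is skipped with a warning.  Returns one row
    per passage x parameter with means, SDs, the test used, its signed
    statistic, the two-sided p and a significance tier.
    """
    keys_a = set(map(tuple, features_a[["passage", "parameter"]].drop_duplicates().values))
    keys_b = set(map(tuple, features_b[["passage", "parameter"]].drop_duplicates().values))
    for missing in sorted(keys_a ^ keys_b):
        warnings.warn(f"parameter {missing} present in only one group; skipped", stacklevel=2)
    rows = []
    for passage, parameter in _ordered_keys(features_a, keys_a & keys_b):
        a = _values(features_a, passage, parameter)
        b = _values(features_b, passage, parameter)
        if len(a) < 2 or len(b) < 2:
            warnings.warn(
                f"({passage}, {parameter}): fewer than 2 subjects per group; skipped",
                stacklevel=2,
            )
            continue
        use_t = False
        if len(a) >= 3 and len(b) >= 3:
            try:
                use_t = test_normality(a, alpha_normality)[2] and test_normality(b, alpha_normality)[2]
            except InsufficientDataError:
                use_t = False
        if use_t:
            stat, p = student_t(a, b)
            test_used = "t"
        else:
            res = mann_whitney(a, b)
            stat = res.z if res.method == "asymptotic" else res.u
            p = res.p
            test_used = "mann-whitney"
        rows.append(
            {
                "passage": passage,
                "parameter": parameter,
                "n_a": len(a),
                "n_b": len(b),
                "mean_a": a.mean(),
                "sd_a": a.std(ddof=1),
                "mean_b": b.mean(),
                "sd_b": b.std(ddof=1),
                "test_used": test_used,
                "statistic": stat,
                "p_value": p,
            }
        )
    report = pd.DataFrame(rows)
    if report.empty:
        return report
    if bh_correct:
        report["p_value"] = _benjamini_hochberg(report["p_value"].to_numpy())
    report["significance"] = [significance_tier(p) for p in report["p_value"]]
    report.attrs["label_a"] = label_a
    report.attrs["label_b"] = label_b
    return report


def _values(features: pd.DataFrame, passage: str, parameter: str) -> np.ndarray:
    sel = features[(features["passage"] == passage) & (features["parameter"] == parameter)]
    return sel["value"].dropna().to_numpy(dtype=float)


def _ordered_keys(features: pd.DataFrame, keys: set) -> list[tuple[str, str]]:
    seen, out = set(), []
    for key in map(tuple, features[["passage", "parameter"]].values):
        if key in keys and key not in seen:
            seen.add(key)
            out.append(key)
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj
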