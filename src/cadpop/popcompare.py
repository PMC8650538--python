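"""Between-population statistics.

Prevalences and categorical covariates are compared with Pearson's
chi-squared test (no continuity correction, so the statistic equals the
squared pooled two-proportion z); approximately normal scores (risk
allele counts, weighted scores) with Welch's t; skewed scores
(Framingham-style risks) with the Mann-Whitney test; whole
distributions with the two-sample Kolmogorov-Smirnov test.

The per-SNP risk-allele-frequency scan builds, for every variant, the
2x2 allele-count table (risk vs other allele; chromosomes = 2 x
non-missing samples per population), applies the Pearson test, adjusts
the m p-values by Bonferroni, and labels each variant by the direction
of the frequency difference. The scan's chi-squared is computed in
closed form across all variants at once; it is numerically identical to
the scalar routine (which delegates to scipy) and the two routes are
cross-checked in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix, ValidationError, VariantWeight

DIRECTION_NONE = "none"


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    df: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"{self.method}: p-value {self.p_value} outside [0, 1]")


def chi2_two_by_two(counts: Sequence[Sequence[float]] | np.ndarray) -> TestResult:
    """Pearson chi-squared on a 2x2 count table, df = 1, no continuity correction."""
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("chi2_two_by_two expects a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("chi2_two_by_two: zero marginal, test undefined")
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return TestResult("chi2", float(stat), float(p), int(t[0].sum()), int(t[1].sum()), df=float(df))


def prevalence_table(n_cases_a: int, n_a: int, n_cases_b: int, n_b: int) -> np.ndarray:
    """Cases/non-cases 2x2 from per-population counts."""
    return np.array([[n_cases_a, n_a - n_cases_a], [n_cases_b, n_b - n_cases_b]], dtype=float)


def welch_ttest(x: np.ndarray, y: np.ndarray) -> TestResult:
    x, y = _clean_pair(x, y, "welch_t")
    res = stats.ttest_ind(x, y, equal_var=False)
    return TestResult("welch_t", float(res.statistic), float(res.pvalue), len(x), len(y), df=float(res.df))


def mannwhitney(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sided Mann-Whitney, normal approximation with tie correction."""
    x, y = _clean_pair(x, y, "mannwhitney")
    if np.ptp(np.concatenate([x, y])) == 0:
        warnings.warn("mannwhitney: all observations tied; p = 1", stacklevel=2)
        return TestResult("mannwhitney", float(len(x) * len(y) / 2.0), 1.0, len(x), len(y))
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult("mannwhitney", float(res.statistic), float(res.pvalue), len(x), len(y))


def ks_two_sample(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sample Kolmogorov-Smirnov: sup-distance D with asymptotic p."""
    x, y = _clean_pair(x, y, "ks")
    res = stats.ks_2samp(x, y, method="asymp")
    return TestResult("ks", float(res.statistic), float(res.pvalue), len(x), len(y))


def _clean_pair(x, y, method: str) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValidationError(f"{method}: need at least 2 observations per sample")
    if method == "ks" and (len(x) < 8 or len(y) < 8):
        warnings.warn("ks: asymptotic p unreliable below 8 observations per side", stacklevel=3)
    return x, y


# ---------------------------------------------------------------------------
# risk-allele-frequency scan

def _allele_counts(m: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(risk-allele count, genotyped chromosome count) per variant."""
    d = m.dosages
    n_obs = (~np.isnan(d)).sum(axis=0)
    if (n_obs == 0).any():
        bad = m.variant_ids[int(np.flatnonzero(n_obs == 0)[0])]
        raise ValidationError(f"af_scan: variant {bad} has no genotyped sample")
    return np.nansum(d, axis=0, dtype=np.float64), 2.0 * n_obs


def af_scan(
    matrix_a: GenotypeMatrix,
    matrix_b: GenotypeMatrix,
    weights: Sequence[VariantWeight] | None = None,
    alpha_adj: float = 0.001,
) -> pd.DataFrame:
    """Per-variant two-population allele-frequency comparison.

    Returns one row per variant: ``rsid raf_a raf_b diff chi2 p_raw
    p_adj direction significant`` with Bonferroni ``p_adj = min(1, m *
    p_raw)`` over the m scanned variants and ``significant = (p_adj <
    alpha_adj)``. Variants monomorphic in both populations get p = 1
    and direction 'none' rather than an error.
    """
    if list(matrix_a.variant_ids) != list(matrix_b.variant_ids):
        raise ValidationError("af_scan: the two matrices must cover the same variants in the same order")
    ids = list(matrix_a.variant_ids)
    if weights is not None:
        wanted = [w.rsid for w in weights]
        if set(wanted) != set(ids):
            raise ValidationError("af_scan: weight table variants do not match the matrices")
    risk_a, chrom_a = _allele_counts(matrix_a)
    risk_b, chrom_b = _allele_counts(matrix_b)
    raf_a, raf_b = risk_a / chrom_a, risk_b / chrom_b
    diff = raf_a - raf_b

    a, b = risk_a, chrom_a - risk_a
    c, d = risk_b, chrom_b - risk_b
    n = chrom_a + chrom_b
    margin = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(margin > 0, n * (a * d - b * c) ** 2 / np.where(margin > 0, margin, 1.0), 0.0)
    p_raw = np.where(margin > 0, stats.chi2.sf(stat, df=1), 1.0)
    m = len(ids)
    p_adj = np.minimum(1.0, m * p_raw)
    significant = p_adj < alpha_adj
    direction = np.where(diff > 0, "higher_A", np.where(diff < 0, "higher_B", DIRECTION_NONE))
    direction = np.where(margin > 0, direction, DIRECTION_NONE)
    return pd.DataFrame({
        "rsid": ids, "raf_a": raf_a, "raf_b": raf_b, "diff": diff,
        "chi2": stat, "p_raw": p_raw, "p_adj": p_adj,
        "direction": direction, "significant": significant,
    })


def summarize_scan(scan: pd.DataFrame) -> dict:
    """Counts and extremes of a scan: direction split among significant rows.

    Returns ``n_higher_A``/``n_higher_B`` (significant rows only),
    ``n_nonsignificant``, and min/max absolute frequency difference
    among significant rows (None when nothing is significant), plus the
    number of variants tested.
    """
    if scan.empty:
        raise ValidationError("summarize_scan: empty scan")
    sig = scan[scan["significant"]]
    absdiff = sig["diff"].abs()
    return {
        "m": int(len(scan)),
        "n_higher_A": int((sig["direction"] == "higher_A").sum()),
        "n_higher_B": int((sig["direction"] == "higher_B").sum()),
        "n_nonsignificant": int(len(scan) - len(sig)),
        "min_abs_diff": float(absdiff.min()) if len(sig) else None,
        "max_abs_diff": float(absdiff.max()) if len(sig) else None,
    }


def dumbbell_table(scan: pd.DataFrame) -> pd.DataFrame:
    """Significant rows ordered for a paired-point (dumbbell) display."""
    sig = scan[scan["significant"]].copy()
    sig["abs_diff"] = sig["diff"].abs()
    return sig.sort_values(["direction", "abs_diff"], ascending=[True, False]).reset_index(drop=True)
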