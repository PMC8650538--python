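"""Unweighted and weighted genetic risk scores from risk-allele dosages.

The additive polygenic model scores each person as

    GRS = sum_k b_k * X_k

where X_k in {0, 1, 2} counts copies of the risk allele at SNP k and b_k
is its weight. With all b_k = 1 the score is the raw risk-allele count
(uGRS); with b_k = ln(OR_k) it is the log-odds-weighted score (wGRS).
Missing genotypes are imputed by their Hardy-Weinberg expectation,
2 x RAF, where RAF is the risk-allele frequency among non-missing
genotypes in the analysis population. Mean imputation at the column's
own RAF leaves every column mean unchanged, so population-mean scores
are insensitive to (random) missingness.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, ValidationError, VariantWeight


def compute_raf(matrix: GenotypeMatrix, variant: str) -> float:
    """Risk-allele frequency at one variant: allele count over genotyped chromosomes."""
    return float(compute_all_rafs(matrix)[variant])


def compute_all_rafs(matrix: GenotypeMatrix) -> pd.Series:
    """RAF per variant, indexed by variant id.

    RAF = (sum of non-missing dosages) / (2 x number of non-missing
    samples). A variant with no genotyped sample has no defined
    frequency and raises.
    """
    d = matrix.dosages
    n_obs = (~np.isnan(d)).sum(axis=0)
    if (n_obs == 0).any():
        bad = matrix.variant_ids[int(np.flatnonzero(n_obs == 0)[0])]
        raise ValidationError(f"variant {bad}: all genotypes missing, RAF undefined")
    sums = np.nansum(d, axis=0, dtype=np.float64)
    return pd.Series(sums / (2.0 * n_obs), index=matrix.variant_ids, name="raf")


def impute_missing(matrix: GenotypeMatrix, rafs: Mapping[str, float] | pd.Series | None = None) -> GenotypeMatrix:
    """Replace every missing dosage by 2 x RAF of its variant.

    ``rafs`` defaults to frequencies computed from ``matrix`` itself
    (the analysis-cohort convention); pass per-population or pooled
    frequencies explicitly to change the imputation scope. Non-missing
    entries are untouched; imputed values are generally non-integer.
    """
    if not matrix.missing_mask().any():
        return matrix
    if rafs is None:
        rafs = compute_all_rafs(matrix)
    try:
        fill = np.array([2.0 * float(rafs[v]) for v in matrix.variant_ids])
    except KeyError as exc:
        raise ValidationError(f"no RAF supplied for variant {exc.args[0]} with missing genotypes") from exc
    d = matrix.dosages.astype(np.float64, copy=True)
    mask = np.isnan(d)
    d[mask] = np.broadcast_to(fill, d.shape)[mask]
    return GenotypeMatrix(
        sample_ids=matrix.sample_ids,
        variant_ids=matrix.variant_ids,
        dosages=d,
        imputed=True,
        n_imputed=mask.sum(axis=1),
    )


def compute_scores(matrix: GenotypeMatrix, weights: Sequence[VariantWeight]) -> pd.DataFrame:
    """Per-sample uGRS and wGRS over the supplied variants.

    The matrix must be complete (run :func:`impute_missing` first) and
    its variant order must match the weight table exactly, so each b_k
    multiplies the dosage it belongs to. Returns a frame with columns
    ``sample_id ugrs wgrs n_imputed``.
    """
    if [w.rsid for w in weights] != list(matrix.variant_ids):
        raise ValidationError("variant order of matrix does not match weight table; align before scoring")
    d = matrix.dosages
    if np.isnan(d).any():
        raise ValidationError("matrix contains missing dosages; run impute_missing first")
    d = d.astype(np.float64, copy=False)
    b = np.array([w.log_or for w in weights])
    n_imp = matrix.n_imputed if matrix.n_imputed is not None else np.zeros(matrix.n_samples, dtype=int)
    return pd.DataFrame({
        "sample_id": matrix.sample_ids,
        "ugrs": d.sum(axis=1),
        "wgrs": d @ b,
        "n_imputed": np.asarray(n_imp, dtype=int),
    })


def raf_report(matrices: Mapping[str, GenotypeMatrix]) -> pd.DataFrame:
    """Long-format RAF table over populations: ``rsid population raf n_nonmissing``."""
    rows = []
    for pop, m in matrices.items():
        rafs = compute_all_rafs(m)
        n_obs = (~np.isnan(m.dosages)).sum(axis=0)
        for v, raf, n in zip(m.variant_ids, rafs.to_numpy(), n_obs):
            rows.append((v, pop, raf, int(n)))
    return pd.DataFrame(rows, columns=["rsid", "population", "raf", "n_nonmissing"])
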