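"""Readers and writers for the external representations the pipeline touches.

Four table kinds flow through an analysis: a risk-variant weight table
(one GWAS lead SNP per row with its risk allele and per-allele odds
ratio), genotypes (VCF 4.x, biallelic SNVs with a GT field), a phenotype
table (one participant per row: clinical covariates, disease status,
population label), and generic results tables.

The genotype container orients every call against the *risk* allele of
the weight table, so a dosage is always "copies of the risk allele"
regardless of which strand of REF/ALT the risk allele landed on in the
VCF. Alleles must match literally; no strand flipping is attempted, and
palindromic (A/T, C/G) variants trigger a warning because orientation
for them is unprovable from allele letters alone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.nan

VALID_BASES = frozenset("ACGT")
PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})

WEIGHT_COLUMNS = ["rsid", "chrom", "pos", "risk_allele", "other_allele", "odds_ratio"]
PHENOTYPE_COLUMNS = [
    "sample_id", "population", "sex", "age", "bmi", "sbp", "tc", "hdl",
    "smoker", "diabetic", "antihypertensive", "cad",
]
_PHENO_NUMERIC = ["age", "bmi", "sbp", "tc", "hdl"]
_PHENO_BOOL = ["smoker", "diabetic", "antihypertensive", "cad"]


class SchemaError(ValueError):
    """A file is missing a required column or has a malformed layout."""


class ValidationError(ValueError):
    """A file parsed but a value violates a domain constraint."""


@dataclass(frozen=True)
class VariantWeight:
    """One risk locus: identifiers, risk/other allele and per-allele odds ratio."""

    rsid: str
    chrom: str
    pos: int
    risk_allele: str
    other_allele: str
    odds_ratio: float

    def __post_init__(self) -> None:
        if self.risk_allele not in VALID_BASES:
            raise ValidationError(f"{self.rsid}: risk_allele {self.risk_allele!r} not in A/C/G/T")
        if self.other_allele not in VALID_BASES:
            raise ValidationError(f"{self.rsid}: other_allele {self.other_allele!r} not in A/C/G/T")
        if self.risk_allele == self.other_allele:
            raise ValidationError(f"{self.rsid}: risk and other allele are identical")
        if not (self.odds_ratio > 0 and math.isfinite(self.odds_ratio)):
            raise ValidationError(f"{self.rsid}: odds_ratio must be a positive finite real, got {self.odds_ratio}")
        if self.pos < 1:
            raise ValidationError(f"{self.rsid}: pos must be 1-based positive, got {self.pos}")

    @property
    def log_or(self) -> float:
        """Natural-log odds ratio; the weight b_k of the additive score."""
        return math.log(self.odds_ratio)

    @property
    def is_palindromic(self) -> bool:
        return {self.risk_allele, self.other_allele} in PALINDROMIC_PAIRS


@dataclass
class GenotypeMatrix:
    """Samples x variants risk-allele dosages.

    ``dosages`` holds floats; NaN marks a missing genotype. Raw matrices
    carry only {0, 1, 2, NaN}; after mean imputation entries may be any
    value in [0, 2] and ``imputed`` is True, with ``n_imputed`` counting
    the replaced entries per sample.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray
    imputed: bool = False
    n_imputed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be a 2-D samples x variants array")
        n, k = self.dosages.shape
        if n != len(self.sample_ids) or k != len(self.variant_ids):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if len(set(self.variant_ids)) != k:
            raise ValidationError("duplicate variant ids")
        if not self.imputed and self.dosages.size:
            vals = self.dosages[~np.isnan(self.dosages)]
            if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
                bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][0]
                raise ValidationError(f"non-missing dosage {bad!r} outside {{0,1,2}}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)


@dataclass(frozen=True)
class PhenotypeRecord:
    """One participant's clinical covariates, disease status and population."""

    sample_id: str
    population: str
    sex: str
    age: float
    bmi: float
    sbp: float
    tc: float
    hdl: float
    smoker: bool
    diabetic: bool
    antihypertensive: bool
    cad: bool

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValidationError(f"{self.sample_id}: sex must be F or M, got {self.sex!r}")
        for name in ("age", "bmi", "sbp", "tc", "hdl"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValidationError(f"{self.sample_id}: {name} must be positive, got {v}")


# ---------------------------------------------------------------------------
# weight tables

def read_weights_table(path: str | Path) -> list[VariantWeight]:
    """Read a TSV of risk variants into validated :class:`VariantWeight` rows.

    Expects columns ``rsid chrom pos risk_allele other_allele odds_ratio``;
    rows are returned in file order and the log odds ratio is derived from
    the odds ratio.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in WEIGHT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"weight table {path}: missing required column {col!r}")
    out: list[VariantWeight] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        rsid = str(row.rsid)
        if rsid in seen:
            raise ValidationError(f"weight table {path} line {i}: duplicate rsid {rsid}")
        seen.add(rsid)
        try:
            odds_ratio = float(row.odds_ratio)
            pos = int(row.pos)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"weight table {path} line {i}: {exc}") from exc
        try:
            out.append(VariantWeight(
                rsid=rsid, chrom=str(row.chrom), pos=pos,
                risk_allele=str(row.risk_allele), other_allele=str(row.other_allele),
                odds_ratio=odds_ratio,
            ))
        except ValidationError as exc:
            raise ValidationError(f"weight table {path} line {i}: {exc}") from exc
    return out


def write_weights_table(weights: Sequence[VariantWeight], path: str | Path) -> None:
    df = pd.DataFrame(
        [(w.rsid, w.chrom, w.pos, w.risk_allele, w.other_allele, w.odds_ratio) for w in weights],
        columns=WEIGHT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF genotypes

def _parse_gt(gt: str, where: str) -> float:
    """Risk-unoriented ALT-allele count from a GT string, NaN if missing."""
    core = gt.split(":", 1)[0]
    if core in (".", "./.", ".|."):
        return MISSING
    sep = "|" if "|" in core else "/"
    alleles = core.split(sep)
    if len(alleles) == 1 and alleles[0] in ("0", "1"):  # haploid call: treat as malformed
        raise ValidationError(f"{where}: haploid GT {gt!r} not supported")
    if len(alleles) != 2:
        raise ValidationError(f"{where}: malformed GT {gt!r}")
    if "." in alleles:
        logger.warning("%s: half-call %r treated as missing", where, gt)
        return MISSING
    try:
        a, b = int(alleles[0]), int(alleles[1])
    except ValueError as exc:
        raise ValidationError(f"{where}: malformed GT {gt!r}") from exc
    if not (0 <= a <= 1 and 0 <= b <= 1):
        raise ValidationError(f"{where}: allele index out of range in GT {gt!r}")
    return float(a + b)


def read_vcf_genotypes(
    path: str | Path,
    weights: Sequence[VariantWeight],
    mismatch_policy: str = "error",
) -> GenotypeMatrix:
    """Read risk-allele dosages for the weight-table variants from a VCF.

    Variants are matched to weights by rsid first, then by (chrom, pos).
    Dosage is the number of risk-allele copies: the ALT count when the
    risk allele is ALT, ``2 - ALT count`` when it is REF. Records whose
    REF/ALT pair does not equal {risk, other} are dropped with a warning
    under ``mismatch_policy='skip'`` and abort under ``'error'``. The
    returned variant order follows the weight table (matched subset).
    """
    if mismatch_policy not in ("error", "skip"):
        raise ValueError(f"mismatch_policy must be 'error' or 'skip', got {mismatch_policy!r}")
    by_rsid = {w.rsid: w for w in weights}
    by_pos = {(w.chrom, w.pos): w for w in weights}

    sample_ids: list[str] = []
    per_variant: dict[str, np.ndarray] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10:
                    raise SchemaError(f"{path}: VCF header has no sample columns")
                sample_ids = cols[9:]
                continue
            if not sample_ids:
                raise SchemaError(f"{path}: data line before #CHROM header")
            fields = line.split("\t")
            if len(fields) != 9 + len(sample_ids):
                raise SchemaError(f"{path} line {lineno}: expected {9 + len(sample_ids)} columns, got {len(fields)}")
            chrom, pos_s, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            where = f"{path} line {lineno} ({chrom}:{pos_s})"
            w = by_rsid.get(vid) or by_pos.get((chrom, int(pos_s)))
            if w is None:
                continue
            if "," in alt:
                raise ValidationError(f"{where}: multi-allelic record matched to weight {w.rsid}")
            fmt = fields[8].split(":")
            if "GT" not in fmt:
                raise SchemaError(f"{where}: no GT in FORMAT")
            gt_idx = fmt.index("GT")
            if {ref, alt} != {w.risk_allele, w.other_allele}:
                msg = (f"{where}: REF/ALT {ref}/{alt} does not match weight alleles "
                       f"{w.risk_allele}/{w.other_allele} for {w.rsid}")
                if mismatch_policy == "error":
                    raise ValidationError(msg)
                logger.warning("%s -- variant skipped", msg)
                continue
            if w.is_palindromic:
                logger.warning("%s: palindromic alleles %s/%s matched literally for %s",
                               where, ref, alt, w.rsid)
            alt_counts = np.empty(len(sample_ids))
            for j, cell in enumerate(fields[9:]):
                parts = cell.split(":")
                alt_counts[j] = _parse_gt(parts[gt_idx] if gt_idx < len(parts) else ".", where)
            if w.risk_allele == alt:
                dos = alt_counts
            else:
                dos = 2.0 - alt_counts  # NaN propagates
            if w.rsid in per_variant:
                raise ValidationError(f"{where}: variant {w.rsid} appears more than once")
            per_variant[w.rsid] = dos

    absent = [w.rsid for w in weights if w.rsid not in per_variant]
    if absent:
        logger.warning("%s: %d weight-table variants absent from VCF: %s",
                       path, len(absent), ", ".join(absent[:10]))
    kept = [w.rsid for w in weights if w.rsid in per_variant]
    dosages = (np.column_stack([per_variant[v] for v in kept])
               if kept else np.empty((len(sample_ids), 0)))
    return GenotypeMatrix(sample_ids=list(sample_ids), variant_ids=kept, dosages=dosages)


def write_vcf(
    matrix: GenotypeMatrix,
    weights: Sequence[VariantWeight],
    path: str | Path,
    risk_as_alt: bool = True,
) -> None:
    """Write a raw (unimputed) genotype matrix as a minimal VCF 4.2 file.

    With ``risk_as_alt`` the risk allele is written as ALT, so the ALT
    count in each GT equals the stored risk-allele dosage.
    """
    if matrix.imputed:
        raise ValidationError("cannot write an imputed (non-integer) matrix as VCF genotypes")
    by_rsid = {w.rsid: w for w in weights}
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_ids) + "\n")
        for j, vid in enumerate(matrix.variant_ids):
            w = by_rsid[vid]
            ref, alt = (w.other_allele, w.risk_allele) if risk_as_alt else (w.risk_allele, w.other_allele)
            col = matrix.dosages[:, j]
            if not risk_as_alt:
                col = 2.0 - col
            gts = "\t".join("./." if np.isnan(d) else gt_code[float(d)] for d in col)
            fh.write(f"{w.chrom}\t{w.pos}\t{vid}\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# phenotype and results tables

def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Read a phenotype TSV into a validated DataFrame (one row per sample).

    Booleans are encoded 0/1 on disk; unknown columns are preserved but
    ignored downstream. A header-only file yields an empty frame.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in PHENOTYPE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"phenotype table {path}: missing required column {col!r}")
    if df.empty:
        return _empty_phenotype_frame(df.columns)
    bad_sex = ~df["sex"].isin(["F", "M"])
    if bad_sex.any():
        i = int(np.flatnonzero(bad_sex.to_numpy())[0])
        raise ValidationError(f"phenotype table {path} row {i + 2}: sex must be F or M, got {df['sex'].iloc[i]!r}")
    out = df.copy()
    for col in _PHENO_NUMERIC:
        try:
            out[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"phenotype table {path} row {i + 2}, column {col!r}: non-numeric value {df[col].iloc[i]!r}"
            ) from None
        if (out[col] <= 0).any():
            i = int(np.flatnonzero((out[col] <= 0).to_numpy())[0])
            raise ValidationError(f"phenotype table {path} row {i + 2}: {col} must be > 0")
    for col in _PHENO_BOOL:
        if not df[col].isin(["0", "1"]).all():
            bad = ~df[col].isin(["0", "1"])
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"phenotype table {path} row {i + 2}, column {col!r}: booleans must be 0/1, got {df[col].iloc[i]!r}"
            )
        out[col] = df[col].astype(int).astype(bool)
    if out["sample_id"].duplicated().any():
        raise ValidationError(f"phenotype table {path}: duplicate sample_id")
    return out


def _empty_phenotype_frame(columns: Iterable[str]) -> pd.DataFrame:
    out = pd.DataFrame(columns=list(columns))
    for col in _PHENO_NUMERIC:
        out[col] = out[col].astype(float)
    for col in _PHENO_BOOL:
        out[col] = out[col].astype(bool)
    return out


def write_phenotype_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a phenotype frame as TSV; write-then-read is the identity."""
    out = df.copy()
    for col in _PHENO_BOOL:
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False)


def write_results_table(df: pd.DataFrame, path: str | Path, float_format: str | None = None) -> None:
    """Write a generic results table as TSV (fixed float format for determinism)."""
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def records_to_frame(records: Sequence[PhenotypeRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=PHENOTYPE_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[PhenotypeRecord]:
    return [PhenotypeRecord(**{k: row[k] for k in PHENOTYPE_COLUMNS}) for _, row in df.iterrows()]
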