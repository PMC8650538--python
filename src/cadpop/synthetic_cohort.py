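"""Two-population biobank-style cohort generator with known ground truth.

Emulates the structure of a large national cohort split into two
birth-country populations of very different sizes (the study conditions:
~318k vs ~32k participants, scaled 10x down by default for desk runs):

* a panel of GWAS lead SNPs (default 163) with per-allele odds ratios,
* per-population risk-allele frequencies with *planted* differences —
  a chosen number of variants shifted up in each population by an
  offset in the published 0.3-3.3 percentage-point range,
* Hardy-Weinberg genotypes at those frequencies with optional missing
  calls,
* clinical covariates drawn from truncated normals / Bernoullis matched
  to the published per-population marginals (age, BMI, blood pressure,
  lipids, smoking, diabetes, antihypertensive use, sex),
* disease status from a logistic liability model whose intercept is
  calibrated by bisection so the expected prevalence hits the published
  7.68% / 8.98% targets.

Genotypes and covariates are independent by design; the only
genotype-phenotype link is the disease model. Every draw is
reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .io_formats import GenotypeMatrix, ValidationError, VariantWeight

DIRECTION_HIGHER_A = "higher_A"
DIRECTION_HIGHER_B = "higher_B"
DIRECTION_NULL = "null"

#: wide physiologic truncation bounds; wide enough that truncation
#: perturbs the configured means by < 0.05 of a unit
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "age": (30.0, 90.0),
    "bmi": (12.0, 70.0),
    "sbp": (60.0, 260.0),
    "tc": (20.0, 500.0),
    "hdl": (3.0, 150.0),
}


@dataclass(frozen=True)
class PopulationProfile:
    """Marginal distributions of one population's phenotype table."""

    label: str
    n_default: int
    n_full: int
    female_rate: float
    age: tuple[float, float]          # (mean, sd)
    bmi: tuple[float, float]
    sbp: tuple[float, float]
    tc: tuple[float, float]
    hdl: tuple[float, float]
    smoker_rate: float
    diabetic_rate: float
    antihypertensive_rate: float
    cad_prevalence: float
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))

    def __post_init__(self) -> None:
        for name in ("female_rate", "smoker_rate", "diabetic_rate",
                     "antihypertensive_rate", "cad_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{self.label}: {name} = {v} outside [0, 1]")


# Published per-population marginals of the emulated cohort. The lipid
# means reproduce the source table verbatim (its mg/dL labelling is
# internally implausible; see the *_mgdl profiles for realistic lipids).
ENGLAND = PopulationProfile(
    label="England", n_default=30_000, n_full=317_889,
    female_rate=0.534, age=(56.7, 8.1), bmi=(27.4, 4.7), sbp=(138.0, 18.5),
    tc=(102.8, 20.6), hdl=(26.2, 6.9),
    smoker_rate=0.102, diabetic_rate=0.078, antihypertensive_rate=0.229,
    cad_prevalence=0.0768,
)
SCOTLAND = PopulationProfile(
    label="Scotland", n_default=3_000, n_full=31_963,
    female_rate=0.545, age=(56.6, 8.0), bmi=(27.49, 4.7), sbp=(139.0, 18.9),
    tc=(103.1, 20.7), hdl=(26.1, 6.9),
    smoker_rate=0.128, diabetic_rate=0.060, antihypertensive_rate=0.237,
    cad_prevalence=0.0898,
)
# Same populations with realistic mg/dL lipids (for Framingham examples).
ENGLAND_MGDL = replace(ENGLAND, tc=(220.0, 42.0), hdl=(55.0, 14.0))
SCOTLAND_MGDL = replace(SCOTLAND, tc=(221.0, 42.0), hdl=(55.0, 14.0))

PROFILES: dict[str, PopulationProfile] = {
    "England": ENGLAND, "Scotland": SCOTLAND,
    "England_mgdl": ENGLAND_MGDL, "Scotland_mgdl": SCOTLAND_MGDL,
}


@dataclass
class PopulationFreqTable:
    """Per-variant risk-allele frequencies for two populations, with the planted truth."""

    variant_ids: list[str]
    raf_a: np.ndarray
    raf_b: np.ndarray
    planted_direction: list[str]
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        self.raf_a = np.asarray(self.raf_a, dtype=float)
        self.raf_b = np.asarray(self.raf_b, dtype=float)
        for arr, name in ((self.raf_a, "raf_a"), (self.raf_b, "raf_b")):
            if ((arr <= 0) | (arr >= 1)).any():
                raise ValidationError(f"{name}: frequencies must lie strictly inside (0, 1)")
        for va, vb, d, vid in zip(self.raf_a, self.raf_b, self.planted_direction, self.variant_ids):
            sign = np.sign(va - vb)
            want = {DIRECTION_HIGHER_A: 1, DIRECTION_HIGHER_B: -1, DIRECTION_NULL: 0}[d]
            if sign != want:
                raise ValidationError(f"{vid}: planted_direction {d} inconsistent with raf_a - raf_b = {va - vb:+.4f}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rsid": self.variant_ids,
            f"raf_{self.label_a}": self.raf_a,
            f"raf_{self.label_b}": self.raf_b,
            "planted_direction": self.planted_direction,
        })


@dataclass
class DiseaseModel:
    """Logistic liability model linking the weighted score and covariates to disease.

    ``betas_clinical`` maps covariate names (numeric or boolean phenotype
    columns, plus the derived indicator ``male``) to log-odds-per-unit
    coefficients. The weighted genetic score enters centred at its
    cohort mean so the intercept directly controls the baseline odds.
    """

    beta_grs: float = 0.0
    betas_clinical: Mapping[str, float] = field(default_factory=dict)
    intercept: float | None = None
    target_prevalence: float | None = None

    def __post_init__(self) -> None:
        if self.intercept is None and self.target_prevalence is None:
            raise ValidationError("DiseaseModel needs an intercept or a target_prevalence to calibrate one")
        if self.target_prevalence is not None and not (0.0 < self.target_prevalence < 1.0):
            raise ValidationError(f"target_prevalence {self.target_prevalence} outside (0, 1)")


def _rng(seed: int | np.random.SeedSequence, *key: int) -> np.random.Generator:
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(np.random.SeedSequence(entropy=seed.entropy, spawn_key=key))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def make_weights(n_variants: int, seed: int, or_range: tuple[float, float] = (1.03, 1.12)) -> list[VariantWeight]:
    """Synthetic GWAS lead-SNP table: odds ratios uniform on ``or_range``.

    Lead-SNP effects for common complex disease are small; the default
    range starts at the panel's published floor of 1.03 and stays below
    1.12, which puts the weighted score's population mean near the
    reported magnitude for a 163-SNP panel.
    """
    rng = _rng(seed, 0)
    bases = np.array(list("ACGT"))
    out = []
    pos = 10_000
    for i in range(n_variants):
        ors = float(rng.uniform(*or_range))
        risk, other = rng.choice(bases, size=2, replace=False)
        pos += int(rng.integers(10_000, 500_000))
        out.append(VariantWeight(
            rsid=f"rs{1_000_000 + i}", chrom=str(i % 22 + 1), pos=pos,
            risk_allele=str(risk), other_allele=str(other), odds_ratio=round(ors, 4),
        ))
    return out


def make_frequency_table(
    n_variants: int,
    n_higher_a: int,
    n_higher_b: int,
    delta: float | tuple[float, float],
    base_freq_range: tuple[float, float] = (0.1, 0.9),
    seed: int = 0,
    variant_ids: Sequence[str] | None = None,
    labels: tuple[str, str] = ("A", "B"),
) -> PopulationFreqTable:
    """Plant per-population frequency differences of known direction.

    Baseline frequencies are uniform on ``base_freq_range`` and shared;
    the first ``n_higher_a`` selected variants are shifted *down* in
    population B and the next ``n_higher_b`` shifted *up*, each by
    ``delta`` (a scalar, or a (low, high) range sampled per variant —
    the published differences span 0.3 to 3.3 percentage points). The
    remainder are identical between populations. Deterministic given
    the seed.
    """
    if n_higher_a + n_higher_b > n_variants:
        raise ValidationError("n_higher_a + n_higher_b exceeds n_variants")
    rng = _rng(seed, 1)
    lo, hi = base_freq_range
    base = rng.uniform(lo, hi, size=n_variants)
    if np.isscalar(delta):
        deltas = np.full(n_variants, float(delta))
    else:
        dlo, dhi = delta
        deltas = rng.uniform(dlo, dhi, size=n_variants)
    idx = rng.permutation(n_variants)
    ids = list(variant_ids) if variant_ids is not None else [f"rs{1_000_000 + i}" for i in range(n_variants)]
    if len(ids) != n_variants:
        raise ValidationError("variant_ids length does not match n_variants")

    raf_a = base.copy()
    raf_b = base.copy()
    direction = [DIRECTION_NULL] * n_variants
    for j in idx[:n_higher_a]:
        raf_b[j] = base[j] - deltas[j]
        direction[j] = DIRECTION_HIGHER_A
    for j in idx[n_higher_a:n_higher_a + n_higher_b]:
        raf_b[j] = base[j] + deltas[j]
        direction[j] = DIRECTION_HIGHER_B
    bad = (raf_b <= 0) | (raf_b >= 1)
    if bad.any():
        j = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"planted offset {deltas[j]:.4f} pushes {ids[j]} to frequency {raf_b[j]:.4f} outside (0, 1); "
            "shrink delta or the base frequency range"
        )
    if np.isscalar(delta) and float(delta) == 0.0:
        direction = [DIRECTION_NULL] * n_variants
    return PopulationFreqTable(variant_ids=ids, raf_a=raf_a, raf_b=raf_b,
                               planted_direction=direction, label_a=labels[0], label_b=labels[1])


def simulate_genotypes(
    rafs: Sequence[float] | np.ndarray,
    n_samples: int,
    variant_ids: Sequence[str],
    missing_rate: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    sample_prefix: str = "S",
) -> GenotypeMatrix:
    """Hardy-Weinberg dosages: 2 w.p. p^2, 1 w.p. 2p(1-p), 0 w.p. (1-p)^2.

    Equivalently Binomial(2, p) per chromosome pair. Entries are masked
    missing independently at ``missing_rate``.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValidationError(f"missing_rate {missing_rate} outside [0, 1)")
    rafs = np.asarray(rafs, dtype=float)
    rng = _rng(seed, 2)
    dos = rng.binomial(2, rafs[None, :], size=(n_samples, len(rafs))).astype(np.float32)
    if missing_rate > 0:
        mask = rng.random(dos.shape) < missing_rate
        dos[mask] = np.nan
    ids = [f"{sample_prefix}{i:06d}" for i in range(n_samples)]
    return GenotypeMatrix(sample_ids=ids, variant_ids=list(variant_ids), dosages=dos)


def _trunc_draw(rng: np.random.Generator, mean: float, sd: float,
                bounds: tuple[float, float], n: int) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_phenotypes(
    n: int,
    profile: PopulationProfile,
    seed: int | np.random.SeedSequence = 0,
    sample_prefix: str | None = None,
) -> pd.DataFrame:
    """Clinical covariates for one population (disease status filled later).

    Continuous covariates are truncated normals at the profile's
    mean/SD within its physiologic bounds; binaries are Bernoulli at
    the profile's rates.
    """
    rng = _rng(seed, 3)
    prefix = sample_prefix if sample_prefix is not None else profile.label[:3].upper()
    df = pd.DataFrame({"sample_id": [f"{prefix}{i:06d}" for i in range(n)]})
    df["population"] = profile.label
    df["sex"] = np.where(rng.random(n) < profile.female_rate, "F", "M")
    for col in ("age", "bmi", "sbp", "tc", "hdl"):
        mean, sd = getattr(profile, col)
        df[col] = _trunc_draw(rng, mean, sd, profile.bounds[col], n)
    df["smoker"] = rng.random(n) < profile.smoker_rate
    df["diabetic"] = rng.random(n) < profile.diabetic_rate
    df["antihypertensive"] = rng.random(n) < profile.antihypertensive_rate
    df["cad"] = False
    return df


def _linear_predictor(wgrs: np.ndarray, phenotypes: pd.DataFrame, model: DiseaseModel) -> np.ndarray:
    eta = model.beta_grs * (wgrs - wgrs.mean()) if len(wgrs) else np.zeros(0)
    for name, beta in model.betas_clinical.items():
        if name == "male":
            x = (phenotypes["sex"] == "M").to_numpy(dtype=float)
        else:
            x = phenotypes[name].to_numpy(dtype=float)
        eta = eta + beta * x
    return eta


def calibrate_intercept(eta: np.ndarray, target: float, bounds: tuple[float, float] = (-40.0, 40.0)) -> float:
    """Intercept such that the *expected* prevalence mean(expit(a + eta)) hits the target.

    Bisection on the (monotone) expected prevalence, accurate to 1e-4 in
    prevalence; sampling noise never enters the calibration.
    """
    def f(a: float) -> float:
        return float(np.mean(expit(a + eta))) - target
    lo, hi = bounds
    if f(lo) > 0 or f(hi) < 0:
        raise ValidationError(
            f"intercept bracket {bounds} does not contain the solution for prevalence {target}; widen bounds"
        )
    return float(brentq(f, lo, hi, xtol=1e-6))


def simulate_disease(
    wgrs: Sequence[float] | np.ndarray,
    phenotypes: pd.DataFrame,
    model: DiseaseModel,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, float]:
    """Bernoulli disease status from the liability model.

    Returns (cad flags, intercept actually used). When the model has a
    target prevalence and no intercept, the intercept is calibrated so
    the expected prevalence matches the target to 1e-4.
    """
    wgrs = np.asarray(wgrs, dtype=float)
    if len(wgrs) != len(phenotypes):
        raise ValidationError("wgrs and phenotypes length mismatch")
    eta = _linear_predictor(wgrs, phenotypes, model)
    if model.intercept is not None:
        alpha = float(model.intercept)
    else:
        alpha = calibrate_intercept(eta, float(model.target_prevalence))
    p = expit(alpha + eta)
    rng = _rng(seed, 4)
    return rng.random(len(p)) < p, alpha


# ---------------------------------------------------------------------------
# whole-cohort convenience layer

@dataclass
class CohortConfig:
    """Study-condition knobs for a two-population cohort."""

    profile_a: PopulationProfile = ENGLAND
    profile_b: PopulationProfile = SCOTLAND
    n_a: int | None = None            # None -> profile defaults
    n_b: int | None = None
    full_scale: bool = False
    n_variants: int = 163
    n_higher_a: int = 37
    n_higher_b: int = 35
    delta: float | tuple[float, float] = (0.003, 0.033)
    base_freq_range: tuple[float, float] = (0.1, 0.9)
    missing_rate: float = 0.002
    beta_grs: float = 0.4
    betas_clinical: Mapping[str, float] = field(default_factory=lambda: {
        "male": 0.65, "age": 0.055, "smoker": 0.55, "diabetic": 0.85,
        "sbp": 0.010, "bmi": 0.03,
    })

    def sizes(self) -> tuple[int, int]:
        if self.n_a is not None or self.n_b is not None:
            return (self.n_a or self.profile_a.n_default, self.n_b or self.profile_b.n_default)
        if self.full_scale:
            return (self.profile_a.n_full, self.profile_b.n_full)
        return (self.profile_a.n_default, self.profile_b.n_default)


@dataclass
class Cohort:
    """Everything one simulated study run produced, plus the ground truth."""

    weights: list[VariantWeight]
    freq_table: PopulationFreqTable
    genotypes: dict[str, GenotypeMatrix]
    phenotypes: pd.DataFrame
    intercepts: dict[str, float]
    config: CohortConfig


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> Cohort:
    """One full two-population cohort under the configured study conditions."""
    from .grs_engine import compute_scores, impute_missing  # local import; no cycle at module load

    cfg = config or CohortConfig()
    n_a, n_b = cfg.sizes()
    la, lb = cfg.profile_a.label, cfg.profile_b.label
    root = np.random.SeedSequence(seed)

    weights = make_weights(cfg.n_variants, seed)
    freqs = make_frequency_table(
        cfg.n_variants, cfg.n_higher_a, cfg.n_higher_b, cfg.delta,
        cfg.base_freq_range, seed=seed,
        variant_ids=[w.rsid for w in weights], labels=(la, lb),
    )
    genotypes = {
        la: simulate_genotypes(freqs.raf_a, n_a, freqs.variant_ids, cfg.missing_rate,
                               seed=np.random.SeedSequence(entropy=seed, spawn_key=(10,)), sample_prefix="A"),
        lb: simulate_genotypes(freqs.raf_b, n_b, freqs.variant_ids, cfg.missing_rate,
                               seed=np.random.SeedSequence(entropy=seed, spawn_key=(11,)), sample_prefix="B"),
    }
    phen = pd.concat([
        simulate_phenotypes(n_a, cfg.profile_a, sample_prefix="A",
                            seed=np.random.SeedSequence(entropy=seed, spawn_key=(12,))),
        simulate_phenotypes(n_b, cfg.profile_b, sample_prefix="B",
                            seed=np.random.SeedSequence(entropy=seed, spawn_key=(13,))),
    ], ignore_index=True)

    intercepts: dict[str, float] = {}
    for i, (label, profile, n) in enumerate([(la, cfg.profile_a, n_a), (lb, cfg.profile_b, n_b)]):
        m = genotypes[label]
        scores = compute_scores(impute_missing(m), weights)
        model = DiseaseModel(beta_grs=cfg.beta_grs, betas_clinical=cfg.betas_clinical,
                             target_prevalence=profile.cad_prevalence)
        sub = phen[phen["population"] == label]
        cad, alpha = simulate_disease(
            scores["wgrs"].to_numpy(), sub, model,
            seed=np.random.SeedSequence(entropy=seed, spawn_key=(14 + i,)),
        )
        phen.loc[sub.index, "cad"] = cad
        intercepts[label] = alpha
    return Cohort(weights=weights, freq_table=freqs, genotypes=genotypes,
                  phenotypes=phen, intercepts=intercepts, config=cfg)
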