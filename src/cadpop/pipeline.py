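"""Config-driven orchestration: simulate/ingest -> score -> compare -> report.

A run is described by a :class:`RunConfig` (YAML or JSON on disk) with
exactly one input source — a simulation block, or paths to a weight
table, two VCFs and a phenotype table — plus scoring and comparison
options and a seed. Stages execute in the order the analysis reads:
cohort, genetic scores, clinical scores, population comparison,
allele-frequency scan, report. Every output file carries the config
hash and seed in a header comment, floats are written with a fixed
format, and a re-run with identical config and seed reproduces every
output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import clinical_risk, grs_engine, io_formats, popcompare, synthetic_cohort
from .io_formats import GenotypeMatrix, ValidationError, VariantWeight

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class InputPaths:
    weights: str
    vcf_a: str
    vcf_b: str
    phenotypes: str
    population_a: str
    population_b: str


@dataclass
class RunConfig:
    seed: int = 0
    simulate: synthetic_cohort.CohortConfig | None = None
    inputs: InputPaths | None = None
    imputation_scope: str = "pooled"          # or "per_population"
    mismatch_policy: str = "error"
    clinical_specs: tuple[str, ...] = ("frs_lipids", "frs_bmi")
    alpha: float = 0.05
    alpha_adj: float = 0.001
    yates_correction: bool = False
    write_cohort_files: bool = True

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValidationError("config must provide exactly one of a simulation block or real input paths")
        if self.imputation_scope not in ("pooled", "per_population"):
            raise ValidationError(f"imputation_scope {self.imputation_scope!r} not recognised")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        kwargs: dict[str, Any] = {k: raw[k] for k in (
            "seed", "imputation_scope", "mismatch_policy", "alpha", "alpha_adj",
            "yates_correction", "write_cohort_files",
        ) if k in raw}
        if "clinical_specs" in raw:
            kwargs["clinical_specs"] = tuple(raw["clinical_specs"])
        if raw.get("simulate") is not None and raw.get("inputs") is not None:
            raise ValidationError("config must provide exactly one of a simulation block or real input paths")
        if raw.get("simulate") is not None:
            sim = dict(raw["simulate"])
            for key in ("profile_a", "profile_b"):
                if key in sim and isinstance(sim[key], str):
                    try:
                        sim[key] = synthetic_cohort.PROFILES[sim[key]]
                    except KeyError:
                        raise ValidationError(f"unknown population profile {sim[key]!r}") from None
            if "delta" in sim and isinstance(sim["delta"], list):
                sim["delta"] = tuple(sim["delta"])
            if "base_freq_range" in sim and isinstance(sim["base_freq_range"], list):
                sim["base_freq_range"] = tuple(sim["base_freq_range"])
            kwargs["simulate"] = synthetic_cohort.CohortConfig(**sim)
        if raw.get("inputs") is not None:
            kwargs["inputs"] = InputPaths(**raw["inputs"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        def enc(o: Any) -> Any:
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
            if isinstance(o, Mapping):
                return {k: enc(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            return o
        blob = json.dumps(enc(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunReport:
    config: RunConfig
    out_dir: Path
    labels: tuple[str, str]
    n: dict[str, int]
    prevalence: dict[str, float]
    comparisons: pd.DataFrame
    score_summary: pd.DataFrame
    scan_summary: dict
    files: dict[str, Path] = field(default_factory=dict)
    warning_count: int = 0


def _header(config: RunConfig) -> str:
    return f"# cadpop run config_hash={config.config_hash()} seed={config.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def pooled_rafs(matrices: Sequence[GenotypeMatrix]) -> pd.Series:
    """RAF per variant over the union of samples in several matrices."""
    ids = list(matrices[0].variant_ids)
    sums = np.zeros(len(ids))
    n_obs = np.zeros(len(ids))
    for m in matrices:
        if list(m.variant_ids) != ids:
            raise ValidationError("pooled_rafs: variant sets differ between matrices")
        sums += np.nansum(m.dosages, axis=0, dtype=np.float64)
        n_obs += (~np.isnan(m.dosages)).sum(axis=0)
    if (n_obs == 0).any():
        raise ValidationError("pooled_rafs: a variant has no genotyped sample in any matrix")
    return pd.Series(sums / (2.0 * n_obs), index=ids)


class _WarningCounter(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record: logging.LogRecord) -> None:
        self.count += 1


def run_pipeline(config: RunConfig, out_dir: str | Path) -> RunReport:
    """Execute all stages; returns the report object after writing all outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counter = _WarningCounter()
    logging.getLogger("cadpop").addHandler(counter)
    try:
        return _run(config, out, counter)
    finally:
        logging.getLogger("cadpop").removeHandler(counter)


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("cohort")
def _stage_cohort(config: RunConfig, out: Path, files: dict):
    if config.simulate is not None:
        cohort = synthetic_cohort.generate_cohort(config.simulate, seed=config.seed)
        weights, phen = cohort.weights, cohort.phenotypes
        la, lb = cohort.freq_table.label_a, cohort.freq_table.label_b
        matrices = cohort.genotypes
        if config.write_cohort_files:
            io_formats.write_weights_table(weights, out / "weights.tsv")
            io_formats.write_phenotype_table(phen, out / "phenotypes.tsv")
            for lab, tag in ((la, "a"), (lb, "b")):
                io_formats.write_vcf(matrices[lab], weights, out / f"genotypes_{tag}.vcf")
            _write_tsv(cohort.freq_table.to_frame(), out / "ground_truth.tsv", config)
            files.update({k: out / v for k, v in {
                "weights": "weights.tsv", "phenotypes": "phenotypes.tsv",
                "ground_truth": "ground_truth.tsv",
            }.items()})
    else:
        ip = config.inputs
        weights = io_formats.read_weights_table(ip.weights)
        phen = io_formats.read_phenotype_table(ip.phenotypes)
        la, lb = ip.population_a, ip.population_b
        known = set(phen["population"].unique())
        if not {la, lb} <= known:
            raise ValidationError(f"phenotype table lacks populations {la!r}/{lb!r} (has {sorted(known)})")
        matrices = {
            la: io_formats.read_vcf_genotypes(ip.vcf_a, weights, config.mismatch_policy),
            lb: io_formats.read_vcf_genotypes(ip.vcf_b, weights, config.mismatch_policy),
        }
        shared = [w for w in weights if w.rsid in set(matrices[la].variant_ids) & set(matrices[lb].variant_ids)]
        if len(shared) < len(weights):
            logger.warning("scoring restricted to %d/%d variants present in both VCFs", len(shared), len(weights))
        weights = shared
        for lab in (la, lb):
            m = matrices[lab]
            keep = [m.variant_ids.index(w.rsid) for w in weights]
            matrices[lab] = GenotypeMatrix(m.sample_ids, [w.rsid for w in weights], m.dosages[:, keep])
    return weights, matrices, phen, (la, lb)


@_stage("grs")
def _stage_grs(config, out, weights, matrices, labels, files):
    la, lb = labels
    if config.imputation_scope == "pooled":
        rafs = {lab: pooled_rafs([matrices[la], matrices[lb]]) for lab in labels}
    else:
        rafs = {lab: grs_engine.compute_all_rafs(matrices[lab]) for lab in labels}
    scores = {}
    for lab in labels:
        imputed = grs_engine.impute_missing(matrices[lab], rafs[lab])
        s = grs_engine.compute_scores(imputed, weights)
        s.insert(1, "population", lab)
        scores[lab] = s
    all_scores = pd.concat(scores.values(), ignore_index=True)
    _write_tsv(all_scores, out / "scores_grs.tsv", config)
    _write_tsv(grs_engine.raf_report({lab: matrices[lab] for lab in labels}),
               out / "raf_report.tsv", config)
    files["scores_grs"] = out / "scores_grs.tsv"
    files["raf_report"] = out / "raf_report.tsv"
    return scores


@_stage("clinical")
def _stage_clinical(config, out, phen, labels, files):
    cols = {"sample_id": phen["sample_id"], "population": phen["population"]}
    for name in config.clinical_specs:
        spec = clinical_risk.builtin_spec(name) if name in ("frs_lipids", "frs_bmi") \
            else clinical_risk.load_score_spec(name)
        cols[spec.name] = clinical_risk.score_cohort(phen, spec)
    df = pd.DataFrame(cols)
    _write_tsv(df, out / "scores_clinical.tsv", config)
    files["scores_clinical"] = out / "scores_clinical.tsv"
    return df


@_stage("compare")
def _stage_compare(config, out, phen, grs_scores, clin, labels, files):
    la, lb = labels
    pa = phen[phen["population"] == la]
    pb = phen[phen["population"] == lb]
    rows = []

    def add(quantity: str, res: popcompare.TestResult) -> None:
        rows.append((quantity, res.method, res.statistic,
                     res.df if res.df is not None else np.nan, res.p_value, res.n_a, res.n_b))

    table = popcompare.prevalence_table(int(pa["cad"].sum()), len(pa), int(pb["cad"].sum()), len(pb))
    add("cad_prevalence", popcompare.chi2_two_by_two(table))
    for score in ("ugrs", "wgrs"):
        x = grs_scores[la][score].to_numpy()
        y = grs_scores[lb][score].to_numpy()
        add(score, popcompare.welch_ttest(x, y))
        add(f"{score}_distribution", popcompare.ks_two_sample(x, y))
    for name in (c for c in clin.columns if c not in ("sample_id", "population")):
        x = clin.loc[clin["population"] == la, name].to_numpy()
        y = clin.loc[clin["population"] == lb, name].to_numpy()
        add(name, popcompare.mannwhitney(x, y))
        add(f"{name}_distribution", popcompare.ks_two_sample(x, y))
    df = pd.DataFrame(rows, columns=["quantity", "method", "statistic", "df", "p_value", "n_a", "n_b"])
    _write_tsv(df, out / "comparisons.tsv", config)
    files["comparisons"] = out / "comparisons.tsv"
    return df


@_stage("scan")
def _stage_scan(config, out, matrices, weights, labels, files):
    la, lb = labels
    scan = popcompare.af_scan(matrices[la], matrices[lb], weights, alpha_adj=config.alpha_adj)
    summary = popcompare.summarize_scan(scan)
    summary["alpha_adj"] = config.alpha_adj
    summary["labels"] = {"A": la, "B": lb}
    _write_tsv(scan, out / "af_scan.tsv", config)
    with open(out / "scan_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files["af_scan"] = out / "af_scan.tsv"
    files["scan_summary"] = out / "scan_summary.json"
    return scan, summary


def _run(config: RunConfig, out: Path, counter: _WarningCounter) -> RunReport:
    files: dict[str, Path] = {}
    weights, matrices, phen, labels = _stage_cohort(config, out, files)
    grs_scores = _stage_grs(config, out, weights, matrices, labels, files)
    clin = _stage_clinical(config, out, phen, labels, files)
    comparisons = _stage_compare(config, out, phen, grs_scores, clin, labels, files)
    scan, scan_summary = _stage_scan(config, out, matrices, weights, labels, files)

    la, lb = labels
    n = {lab: int((phen["population"] == lab).sum()) for lab in labels}
    prev = {lab: float(phen.loc[phen["population"] == lab, "cad"].mean()) for lab in labels}
    score_summary = _score_summary_table(grs_scores, clin, comparisons, labels)
    report = RunReport(
        config=config, out_dir=out, labels=labels, n=n, prevalence=prev,
        comparisons=comparisons, score_summary=score_summary,
        scan_summary=scan_summary, files=files, warning_count=counter.count,
    )
    render_report(report, phen, scan)
    logger.info("run complete: %d warnings, outputs in %s", counter.count, out)
    return report


def _score_summary_table(grs_scores, clin, comparisons, labels) -> pd.DataFrame:
    """Per-score Mean/SD/Median/Min/Max per population, with the comparison p."""
    rows = []
    pmap = dict(zip(comparisons["quantity"], comparisons["p_value"]))
    for score in ("ugrs", "wgrs"):
        for lab in labels:
            v = grs_scores[lab][score]
            rows.append((score, lab, v.mean(), v.std(), v.median(), v.min(), v.max(), pmap[score]))
    for name in (c for c in clin.columns if c not in ("sample_id", "population")):
        for lab in labels:
            v = clin.loc[clin["population"] == lab, name]
            rows.append((name, lab, v.mean(), v.std(), v.median(), v.min(), v.max(), pmap[name]))
    return pd.DataFrame(rows, columns=["score", "population", "mean", "sd", "median", "min", "max", "p_value"])


def format_p(p: float) -> str:
    return "< 0.001" if p < 0.001 else f"{p:.4g}"


def render_report(report: RunReport, phenotypes: pd.DataFrame, scan: pd.DataFrame) -> Path:
    """Write report.md (+ dumbbell.png when anything is significant)."""
    out = report.out_dir
    la, lb = report.labels
    lines = [
        "# Two-population CAD risk comparison",
        "",
        f"Config hash `{report.config.config_hash()}`, seed {report.config.seed}.",
        "",
        "## Cohort",
        "",
        f"| | {la} | {lb} |",
        "|---|---|---|",
        f"| n | {report.n[la]:,} | {report.n[lb]:,} |",
        f"| CAD prevalence | {100 * report.prevalence[la]:.2f}% | {100 * report.prevalence[lb]:.2f}% |",
    ]
    for col, fmt in (("age", ".1f"), ("bmi", ".1f"), ("sbp", ".1f"), ("tc", ".1f"), ("hdl", ".1f")):
        va = phenotypes.loc[phenotypes["population"] == la, col]
        vb = phenotypes.loc[phenotypes["population"] == lb, col]
        lines.append(f"| {col} mean (SD) | {va.mean():{fmt}} ({va.std():.1f}) | {vb.mean():{fmt}} ({vb.std():.1f}) |")
    for col in ("smoker", "diabetic", "antihypertensive"):
        va = phenotypes.loc[phenotypes["population"] == la, col].mean()
        vb = phenotypes.loc[phenotypes["population"] == lb, col].mean()
        lines.append(f"| {col} | {100 * va:.1f}% | {100 * vb:.1f}% |")

    lines += ["", "## Score summaries", "",
              "| Score | Population | Mean | SD | Median | Min | Max | p |", "|---|---|---|---|---|---|---|---|"]
    for r in report.score_summary.itertuples(index=False):
        lines.append(f"| {r.score} | {r.population} | {r.mean:.4g} | {r.sd:.4g} | "
                     f"{r.median:.4g} | {r.min:.4g} | {r.max:.4g} | {format_p(r.p_value)} |")

    lines += ["", "## Statistical comparisons", "",
              "| Quantity | Test | Statistic | p | n_A | n_B |", "|---|---|---|---|---|---|"]
    for r in report.comparisons.itertuples(index=False):
        lines.append(f"| {r.quantity} | {r.method} | {r.statistic:.4g} | {format_p(r.p_value)} | {r.n_a} | {r.n_b} |")

    s = report.scan_summary
    lines += ["", "## Risk-allele-frequency scan", ""]
    if s["m"] == 0 or (s["n_higher_A"] + s["n_higher_B"]) == 0:
        lines.append("No variants tested reached significance."
                     if s["m"] else "No variants tested.")
    else:
        lines += [
            f"Of {s['m']} variants, {s['n_higher_A']} had significantly higher risk-allele "
            f"frequency in {la} and {s['n_higher_B']} in {lb} "
            f"(Bonferroni-adjusted p < {s['alpha_adj']}); {s['n_nonsignificant']} showed no significant difference.",
            f"Absolute frequency differences among significant variants span "
            f"{100 * s['min_abs_diff']:.1f} to {100 * s['max_abs_diff']:.1f} percentage points.",
        ]
        fig_path = out / "dumbbell.png"
        _dumbbell_figure(scan, (la, lb), fig_path)
        lines += ["", f"![dumbbell]({fig_path.name})"]
    lines += ["", f"Warnings during run: {report.warning_count}", ""]
    path = out / "report.md"
    path.write_text("\n".join(lines))
    report.files["report"] = path
    return path


def _dumbbell_figure(scan: pd.DataFrame, labels: tuple[str, str], path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sig = popcompare.dumbbell_table(scan)
    if sig.empty:
        return
    fig, ax = plt.subplots(figsize=(7, max(3, 0.16 * len(sig))))
    ypos = np.arange(len(sig))
    for y, row in zip(ypos, sig.itertuples(index=False)):
        ax.plot([row.raf_a, row.raf_b], [y, y], color="grey", lw=1, zorder=1)
    ax.scatter(sig["raf_a"], ypos, s=12, label=labels[0], zorder=2)
    ax.scatter(sig["raf_b"], ypos, s=12, label=labels[1], zorder=2)
    ax.set_yticks(ypos)
    ax.set_yticklabels(sig["rsid"], fontsize=5)
    ax.set_xlabel("risk-allele frequency")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
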