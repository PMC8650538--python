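"""Sex-stratified Cox-survival 10-year risk scores from declarative specs.

A score spec is data, not code: per sex it lists linear-predictor terms
(variable, transform, optional boolean condition, coefficient), a
baseline 10-year survival S0 and the derivation-cohort mean linear
predictor L-bar. A record's risk is the standard survival-model form

    risk% = (1 - S0 ** exp(L - L_bar)) * 100

with L the sum of beta * transform(value) over the terms whose condition
holds. Two Framingham-style general-CVD specs ship with the package
(``frs_lipids`` and ``frs_bmi``); the engine itself is generic and is
exercised against synthetic closed-form specs in the tests.

Antihypertensive treatment is handled the published way: systolic blood
pressure enters through exactly one of two condition-guarded terms
(treated vs untreated), while smoking and diabetes are unguarded binary
terms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import PhenotypeRecord, SchemaError, ValidationError

_TRANSFORMS = ("identity", "ln")
_ALLOWED_VARIABLES = ("age", "bmi", "sbp", "tc", "hdl", "smoker", "diabetic", "antihypertensive")
_CONDITION_FIELDS = ("smoker", "diabetic", "antihypertensive", "cad")


@dataclass(frozen=True)
class CoxTerm:
    variable: str
    beta: float
    transform: str = "identity"
    condition: tuple[tuple[str, bool], ...] = ()

    def __post_init__(self) -> None:
        if self.variable not in _ALLOWED_VARIABLES:
            raise SchemaError(f"unknown variable {self.variable!r} in score spec")
        if self.transform not in _TRANSFORMS:
            raise SchemaError(f"unknown transform {self.transform!r} (use identity or ln)")
        for name, _ in self.condition:
            if name not in _CONDITION_FIELDS:
                raise SchemaError(f"condition field {name!r} is not a boolean phenotype field")
        if not math.isfinite(self.beta):
            raise SchemaError(f"non-finite beta for {self.variable}")

    def condition_holds(self, record: Mapping[str, Any]) -> bool:
        return all(bool(record[name]) == want for name, want in self.condition)


@dataclass(frozen=True)
class SexBlock:
    terms: tuple[CoxTerm, ...]
    s0: float
    mean_lp: float

    def __post_init__(self) -> None:
        if not (0.0 < self.s0 < 1.0):
            raise SchemaError(f"baseline survival s0 must lie in (0,1), got {self.s0}")
        if not math.isfinite(self.mean_lp):
            raise SchemaError("mean_lp must be finite")
        seen = set()
        for t in self.terms:
            key = (t.variable, t.condition)
            if key in seen:
                raise SchemaError(f"duplicate term for variable {t.variable!r} with identical condition")
            seen.add(key)


@dataclass(frozen=True)
class CoxScoreSpec:
    """A named 10-year risk score: one coefficient block per sex."""

    name: str
    blocks: Mapping[str, SexBlock]

    def __post_init__(self) -> None:
        if set(self.blocks) != {"F", "M"}:
            raise SchemaError(f"score spec {self.name!r} must define both sexes F and M")

    @property
    def variables(self) -> set[str]:
        return {t.variable for b in self.blocks.values() for t in b.terms}


def _term_from_dict(d: Mapping[str, Any]) -> CoxTerm:
    cond = d.get("condition") or {}
    return CoxTerm(
        variable=d["variable"],
        beta=float(d["beta"]),
        transform=d.get("transform", "identity"),
        condition=tuple(sorted((k, bool(v)) for k, v in cond.items())),
    )


def load_score_spec(path: str | Path) -> CoxScoreSpec:
    """Load a score spec from JSON or YAML."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    return spec_from_dict(raw)


def spec_from_dict(raw: Mapping[str, Any]) -> CoxScoreSpec:
    try:
        blocks = {
            sex: SexBlock(
                terms=tuple(_term_from_dict(t) for t in blk["terms"]),
                s0=float(blk["s0"]),
                mean_lp=float(blk["mean_lp"]),
            )
            for sex, blk in raw["sex"].items()
        }
        return CoxScoreSpec(name=raw["name"], blocks=blocks)
    except KeyError as exc:
        raise SchemaError(f"score spec missing key {exc.args[0]!r}") from None


def builtin_spec(name: str) -> CoxScoreSpec:
    """Load one of the shipped specs: ``frs_lipids`` or ``frs_bmi``."""
    ref = resources.files("cadpop.data").joinpath(f"{name}.json")
    return spec_from_dict(json.loads(ref.read_text()))


def evaluate_cox_risk(record: PhenotypeRecord | Mapping[str, Any], spec: CoxScoreSpec) -> float:
    """10-year risk in percent for one participant.

    Monotone increasing in any positive-beta variable; bounded in
    [0, 100] for all finite inputs (the survival power saturates rather
    than producing NaN in the tails).
    """
    rec = vars(record) if isinstance(record, PhenotypeRecord) else dict(record)
    block = spec.blocks[rec["sex"]]
    lp = 0.0
    for t in block.terms:
        if not t.condition_holds(rec):
            continue
        v = float(rec[t.variable])
        if t.transform == "ln":
            if v <= 0:
                raise ValidationError(f"ln transform of non-positive {t.variable} = {v}")
            v = math.log(v)
        lp += t.beta * v
    expo = math.exp(min(lp - block.mean_lp, 700.0))
    return (1.0 - block.s0 ** expo) * 100.0


def score_cohort(
    phenotypes: pd.DataFrame,
    spec: CoxScoreSpec,
    skip_invalid: bool = False,
) -> pd.Series:
    """Vectorized :func:`evaluate_cox_risk` over a phenotype frame.

    Invalid rows (non-positive value under a ln transform) abort with a
    row-level report unless ``skip_invalid``, which scores them NaN.
    """
    risk = pd.Series(np.nan, index=phenotypes.index, name=spec.name)
    bad_rows: list[str] = []
    for sex, block in spec.blocks.items():
        sel = phenotypes["sex"] == sex
        if not sel.any():
            continue
        sub = phenotypes.loc[sel]
        lp = np.zeros(len(sub))
        invalid = np.zeros(len(sub), dtype=bool)
        for t in block.terms:
            holds = np.ones(len(sub), dtype=bool)
            for name, want in t.condition:
                holds &= sub[name].to_numpy(dtype=bool) == want
            vals = sub[t.variable].to_numpy(dtype=float)
            if t.transform == "ln":
                nonpos = vals <= 0
                invalid |= holds & nonpos
                vals = np.log(np.where(nonpos, 1.0, vals))
            lp += np.where(holds, t.beta * vals, 0.0)
        if invalid.any():
            bad_rows.extend(str(s) for s in sub.loc[invalid, "sample_id"].head(20))
            if not skip_invalid:
                continue
        expo = np.exp(np.minimum(lp - block.mean_lp, 700.0))
        out = (1.0 - block.s0 ** expo) * 100.0
        out[invalid] = np.nan
        risk.loc[sel] = out
    if bad_rows and not skip_invalid:
        raise ValidationError(
            f"{spec.name}: non-positive input under ln transform for samples "
            f"{', '.join(bad_rows)}; rerun with skip_invalid to score them NaN"
        )
    valid = risk.dropna()
    if len(valid) and not ((valid >= 0) & (valid <= 100)).all():
        raise ValidationError(f"{spec.name}: risk outside [0, 100] produced; spec is inconsistent")
    return risk
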