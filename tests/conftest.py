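import numpy as np
import pandas as pd
import pytest

from cadpop.io_formats import GenotypeMatrix, VariantWeight


@pytest.fixture
def weights3():
    return [
        VariantWeight("rs1", "1", 1000, "A", "G", 1.2),
        VariantWeight("rs2", "2", 2000, "C", "T", 1.5),
        VariantWeight("rs3", "3", 3000, "G", "A", 1.1),
    ]


@pytest.fixture
def weights_tsv(tmp_path, weights3):
    path = tmp_path / "weights.tsv"
    lines = ["rsid\tchrom\tpos\trisk_allele\tother_allele\todds_ratio"]
    for w in weights3:
        lines.append(f"{w.rsid}\t{w.chrom}\t{w.pos}\t{w.risk_allele}\t{w.other_allele}\t{w.odds_ratio}")
    path.write_text("\n".join(lines) + "\n")
    return path


def make_matrix(dosages, variant_ids=None, sample_prefix="s", **kw):
    dosages = np.asarray(dosages, dtype=float)
    n, k = dosages.shape
    return GenotypeMatrix(
        sample_ids=[f"{sample_prefix}{i}" for i in range(n)],
        variant_ids=variant_ids or [f"v{j}" for j in range(k)],
        dosages=dosages, **kw,
    )


@pytest.fixture
def phenotypes5():
    return pd.DataFrame({
        "sample_id": [f"p{i}" for i in range(5)],
        "population": ["England", "England", "Scotland", "Scotland", "England"],
        "sex": ["F", "M", "F", "M", "F"],
        "age": [45.0, 60.0, 52.5, 66.0, 58.0],
        "bmi": [24.0, 31.5, 27.0, 29.0, 22.5],
        "sbp": [118.0, 145.0, 132.0, 160.0, 126.0],
        "tc": [180.0, 240.0, 210.0, 200.0, 190.0],
        "hdl": [60.0, 38.0, 52.0, 45.0, 70.0],
        "smoker": [False, True, False, True, False],
        "diabetic": [False, False, True, False, False],
        "antihypertensive": [False, True, False, True, False],
        "cad": [False, True, False, True, False],
    })
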