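import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
import pytest

from ewaskit.core import MethylationMatrix, SampleSheet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_glm_data():
    """n=60 samples, 30 probes, 5 causal with a continuous exposure."""
    import ewaskit as ek

    return ek.simulate_ewas_dataset(
        n_samples=60, n_probes=30, n_causal=5, effect_size=0.4, seed=11
    )


@pytest.fixture
def single_probe(rng):
    """One probe with a known planted slope for bootstrap tests."""
    n = 120
    x = rng.normal(0, 1, n)
    y = 0.2 + 0.05 * x + rng.normal(0, 0.1, n)
    ids = [f"S{i:03d}" for i in range(n)]
    matrix = MethylationMatrix(
        pd.DataFrame([y], index=["cg_test"], columns=ids), value_type="m"
    )
    sheet = SampleSheet(pd.DataFrame({"exposure": x}, index=pd.Index(ids, name="sample_id")))
    return matrix, sheet


@pytest.fixture
def manifest_csv(tmp_path):
    """Small 450K-style manifest; includes a well-known island probe."""
    rows = [
        # probe, CHR, MAPINFO, gene, group, island relation
        ("cg00394712", "1", 145575831, "NUDT17", "TSS200", "Island"),
        ("cg02449698", "1", 44117544, "EFCAB7", "Body", "OpenSea"),
        ("cg04529486", "3", 5022631, "", "", "S_Shelf"),
        ("cg23835894", "22", 39563965, "GATSL3", "TSS200", "Island"),
        ("cg99000001", "7", 1500321, "", "", "OpenSea"),
    ]
    df = pd.DataFrame(
        rows,
        columns=["IlmnID", "CHR", "MAPINFO", "UCSC_RefGene_Name",
                 "UCSC_RefGene_Group", "Relation_to_UCSC_CpG_Island"],
    )
    path = tmp_path / "manifest.csv"
    df.to_csv(path, index=False)
    return path


@pytest.fixture
def gmt_file(tmp_path, rng):
    genes = [f"GENE{i}" for i in range(97)]
    path = tmp_path / "sets.gmt"
    with open(path, "w") as fh:
        for t in range(25):
            members = rng.choice(genes, size=rng.integers(10, 40), replace=False)
            fh.write(f"T{t:03d}\tsynthetic term {t}\t" + "\t".join(members) + "\n")
    return path
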