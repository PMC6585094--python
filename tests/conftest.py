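import numpy as np
import pandas as pd
import pytest

from reactnorm.pedkin import Pedigree
from reactnorm.simdata import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """Small half-sib dataset with genotypes, shared across tests."""
    cfg = SimConfig(
        n_founders=20,
        n_sires_per_gen=20,
        progeny_per_sire=30,
        n_cg=40,
        n_snps=300,
        n_qtl_per_coefficient=15,
        qtl_var_fraction=0.2,
        seed=42,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_records(small_sim):
    rec = small_sim.phenotypes.copy()
    rec["pwg300"] = rec["gain"] * 300.0 / rec["days"]
    return rec


@pytest.fixture(scope="session")
def w_truth(small_sim):
    return small_sim.true_cg.set_index("cg")["w"]


@pytest.fixture()
def toy_pedigree():
    """Five animals incl. a parent-offspring mating (inbred offspring)."""
    df = pd.DataFrame(
        {
            "animal": ["A", "B", "C", "D", "E"],
            "sire": ["0", "0", "A", "A", "C"],
            "dam": ["0", "0", "B", "C", "D"],
        }
    )
    return Pedigree.from_frame(df)


def random_pedigree(rng, n_founders=10, n_off=40):
    """Random multi-generation pedigree for oracle tests."""
    rows = [(f"F{i}", "0", "0") for i in range(n_founders)]
    ids = [r[0] for r in rows]
    for k in range(n_off):
        s, d = rng.choice(len(ids), size=2, replace=False)
        rows.append((f"X{k}", ids[s], ids[d]))
        ids.append(f"X{k}")
    return Pedigree.from_frame(pd.DataFrame(rows, columns=["animal", "sire", "dam"]))
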