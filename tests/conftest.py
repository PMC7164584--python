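import numpy as np
import pandas as pd
import pytest

from ecoparallel.synth import SynthConfig, simulate_study


@pytest.fixture(scope="session")
def small_bundle():
    """A compact two-lineage study with planted signals of every kind."""
    cfg = SynthConfig(n_lineages=2, lakes_per_lineage=2, ecotypes_per_lake=2,
                      n_per_group=12, n_snps=400, n_genes=300,
                      n_assoc_snps=15, assoc_delta=0.4,
                      n_de_genes=40, de_log2fc=2.0, n_eqtl=4, seed=11)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def null_bundle():
    """A study with no planted ecotype signal anywhere."""
    cfg = SynthConfig(n_lineages=1, lakes_per_lineage=2, ecotypes_per_lake=2,
                      n_per_group=15, n_snps=500, n_genes=200,
                      shared_effect_scale=0.0, lake_noise_scale=0.0,
                      n_assoc_snps=0, n_de_genes=0, n_eqtl=0, seed=5)
    return simulate_study(cfg)


@pytest.fixture
def tiny_samples():
    """Balanced 2 lineages x 2 lakes x 2 ecotypes x 4 individuals."""
    rows = []
    for lin in ("A", "B"):
        for lake in (f"{lin}_l1", f"{lin}_l2"):
            for eco in ("planktivorous", "benthivorous"):
                for k in range(4):
                    rows.append({"id": f"{lake}_{eco[:4]}_{k}", "lake": lake,
                                 "lineage": lin, "ecotype": eco})
    return pd.DataFrame(rows)
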