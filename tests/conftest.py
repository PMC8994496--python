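import numpy as np
import pandas as pd
import pytest

from stressnet import simulate as sim
from stressnet.preprocess import NormalizedMatrix


@pytest.fixture(scope="session")
def small_cfg() -> sim.SimConfig:
    """A scaled-down study: same structure, few hundred probes."""
    return sim.SimConfig(
        n_probes=600,
        n_control_probes=100,
        n_genes=250,
        n_de_genes=12,
        n_animals_per_group=4,
        n_modules=15,
        n_planted_modules=3,
        n_qtl_genes=5,
        n_go_terms=15,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg) -> sim.SimOutput:
    return sim.generate_all(small_cfg)


@pytest.fixture(scope="session")
def default_sim() -> sim.SimOutput:
    """One full-size bundle (10,064 probes), shared across tests."""
    return sim.generate_all(sim.SimConfig(seed=7))


def make_norm(values: np.ndarray, design: pd.DataFrame,
              probe_ids=None) -> NormalizedMatrix:
    """Wrap a plain log2 matrix as a NormalizedMatrix for direct model fits."""
    probe_ids = probe_ids or [f"P{i:04d}" for i in range(values.shape[0])]
    log2 = pd.DataFrame(values, index=probe_ids, columns=design.index)
    return NormalizedMatrix(
        log2=log2,
        stage1=log2,
        array_control_median=pd.Series(dtype=float),
        probe_median=pd.Series(dtype=float),
        is_control=pd.Series(False, index=log2.index),
        design=design,
    )


def two_group_design(n_per_group: int = 8, muscle: str = "LT") -> pd.DataFrame:
    """Balanced stress x diet design for one muscle."""
    rows = []
    i = 0
    for stress in ("stress", "limited"):
        for diet in ("control", "EP"):
            for _ in range(n_per_group // 2):
                i += 1
                rows.append({"sample": f"S{i:02d}", "muscle": muscle,
                             "stress": stress, "diet": diet})
    return pd.DataFrame(rows).set_index("sample")
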