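import numpy as np
import pandas as pd
import pytest

from epihet import build_matrix, extract_signature, per_cpg_group_stats
from epihet.methylio import MethylationMatrix
from epihet.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def sim_result():
    """Default-condition synthetic cohort shared across the suite."""
    return simulate_all(SimulationConfig())


@pytest.fixture(scope="session")
def sim_matrix(sim_result):
    return build_matrix(sim_result.profiles, groups=sim_result.groups)


@pytest.fixture(scope="session")
def sim_stats(sim_matrix):
    return per_cpg_group_stats(sim_matrix)


@pytest.fixture(scope="session")
def sim_signature(sim_stats):
    return extract_signature(sim_stats)


def toy_matrix(values: dict[str, list[float]], groups: dict[str, str] | None = None,
               chrom: str = "chr1") -> MethylationMatrix:
    """Small in-memory matrix from per-sample value lists."""
    df = pd.DataFrame(values, dtype=float)
    n = len(df)
    keys = [f"{chrom}:{100 + 10 * i}:+" for i in range(n)]
    df.index = pd.Index(keys, name="site")
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": [100 + 10 * i for i in range(n)], "strand": "+"},
        index=df.index,
    )
    return MethylationMatrix(values=df, sites=sites, groups=dict(groups or {}))


def random_matrix(rng: np.random.Generator, n_sites: int = 20,
                  n_samples: int = 4) -> MethylationMatrix:
    values = {f"s{i}": rng.random(n_sites) for i in range(n_samples)}
    return toy_matrix(values)
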