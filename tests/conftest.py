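import pytest

from ptbstrat import (
    DBSCANParams,
    EnsembleConfig,
    PTBStratification,
    benchmark_config,
)
from ptbstrat.synthdata import generate_microdata, generate_municipality_table


@pytest.fixture(scope="session")
def bench_cfg():
    """Four planted strata (two high-PMR, two low-PMR), 50 municipalities each."""
    return benchmark_config(n_per_stratum=50, seed=7)


@pytest.fixture(scope="session")
def bench_a0(bench_cfg):
    table, labels = generate_municipality_table(bench_cfg)
    return table, labels


@pytest.fixture(scope="session")
def fitted(bench_a0):
    """A fitted small-ensemble pipeline shared across read-only tests."""
    a0, _ = bench_a0
    model = PTBStratification(
        a0,
        ensemble=EnsembleConfig(
            nc_values=tuple(range(2, 9)), reps_per_nc=3, seed=7
        ),
        dbscan=DBSCANParams(eps=0.06, min_points=5),
        seed=7,
    )
    return model.fit()


@pytest.fixture(scope="session")
def micro():
    """Small four-table record-level draw (15 municipalities per stratum)."""
    return generate_microdata(benchmark_config(n_per_stratum=15, seed=21))
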