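import numpy as np
import pytest

from evmodsig.preprocessing import ztransform
from evmodsig.simulate import SyntheticCohortConfig, generate_cohort, generate_network


def small_config(**overrides) -> SyntheticCohortConfig:
    """A compact cohort for unit tests: 3 planted modules, 80 tumors."""
    kwargs = dict(
        n_genes=160,
        n_tumor=80,
        n_normal=40,
        background_edge_prob=0.03,
        planted_module_sizes=(6, 4, 3),
        de_gene_count=80,
        biomarker_set_sizes={"hypoxia": 8, "angiogenesis": 6, "inflammation": 6},
        n_cell_types=4,
        seed=11,
    )
    kwargs.update(overrides)
    return SyntheticCohortConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cfg():
    return small_config()


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return generate_cohort(small_cfg, generate_network(small_cfg))


@pytest.fixture(scope="session")
def small_z(small_bundle):
    return ztransform(small_bundle.tumor)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
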