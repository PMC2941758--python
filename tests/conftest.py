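import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from estsplice.model import GenomeInterval
from estsplice.simulate import CohortConfig, PlantedEvent, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def iv(start: int, end: int, chrom: str = "chr1") -> GenomeInterval:
    return GenomeInterval(chrom, start, end)


@pytest.fixture(scope="session")
def small_cohort_config() -> CohortConfig:
    """A reduced cohort (same planted archetypes, ~10x fewer ESTs) for
    fast end-to-end tests; junction support stays in the hundreds."""
    return CohortConfig(
        libraries_per_tissue_per_condition=2,
        est_count_mean=120.0,
        n_genes=5,
        planted_events=[
            PlantedEvent("G000", "cassette", 2, 0.9, 0.1, "CNS"),
            PlantedEvent("G001", "double_cassette", 2, 0.1, 0.9, "CNS"),
            PlantedEvent("G002", "mutually_exclusive", 2, 0.9, 0.1, "CNS"),
        ],
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cohort_config):
    return generate_cohort(small_cohort_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


TOY_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: biological_process
namespace: biological_process

[Term]
id: GO:0000002
name: metabolic process
namespace: biological_process
is_a: GO:0000001 ! biological_process

[Term]
id: GO:0000003
name: catabolic process
namespace: biological_process
is_a: GO:0000002 ! metabolic process

[Term]
id: GO:0000004
name: small molecule catabolism
namespace: biological_process
is_a: GO:0000003 ! catabolic process
is_a: GO:0000005 ! small molecule process

[Term]
id: GO:0000005
name: small molecule process
namespace: biological_process
is_a: GO:0000002 ! metabolic process

[Term]
id: GO:0000100
name: membrane
namespace: cellular_component
"""


@pytest.fixture()
def toy_obo_path(tmp_path):
    path = tmp_path / "toy.obo"
    path.write_text(TOY_OBO)
    return str(path)
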