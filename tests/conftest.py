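import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make _oracles importable

from bestop.design import PAM_PRESETS
from bestop.simulate import SyntheticGenomeSpec, generate_annotated_genome

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")

NGG = PAM_PRESETS["NGG"]
NG = PAM_PRESETS["NG"]
NAA = PAM_PRESETS["NAA"]


@pytest.fixture(scope="session")
def small_genome():
    """~12 kb circular genome with mixed-strand CDSs (random content)."""
    spec = SyntheticGenomeSpec(n_genes=12)
    genome, _ = generate_annotated_genome(spec, seed=7)
    return genome


@pytest.fixture(scope="session")
def linear_genome():
    spec = SyntheticGenomeSpec(n_genes=8, circular=False)
    genome, _ = generate_annotated_genome(spec, seed=11)
    return genome


@pytest.fixture(scope="session")
def at_genome():
    """Genome whose CDSs are A/T-only: no STOP-capable protospacer can occur
    anywhere except where one is planted."""
    spec = SyntheticGenomeSpec(n_genes=10, cds_alphabet="AT")
    genome, _ = generate_annotated_genome(spec, seed=3)
    return genome
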