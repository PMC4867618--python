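import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from hed.synthetic import SyntheticSpec, build_ideal_peptide

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")

#: hairpin geometry with a real two-bridge ladder (type I' turn)
HAIRPIN_STRAND = (-120.0, 135.0)
HAIRPIN_TURN = ((60.0, 30.0), (90.0, 0.0))


@pytest.fixture(scope="session")
def helix_model():
    spec = SyntheticSpec(sequence="A" * 20, ss_string="H" * 20)
    return build_ideal_peptide(spec)


@pytest.fixture(scope="session")
def strand_model():
    spec = SyntheticSpec(sequence="A" * 20, ss_string="E" * 20)
    return build_ideal_peptide(spec)


@pytest.fixture(scope="session")
def hairpin_model():
    n = 18
    dih = [HAIRPIN_STRAND] * 8 + list(HAIRPIN_TURN) + [HAIRPIN_STRAND] * 8
    spec = SyntheticSpec(sequence="V" * n, ss_string="E" * 8 + "CC" + "E" * 8)
    return build_ideal_peptide(spec, dihedrals=dih)
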