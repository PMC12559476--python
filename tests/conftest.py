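import numpy as np
import pytest

from t3pks.records import STANDARD_AA, SequenceRecord
from t3pks.synthetic import SyntheticSpec, generate_activity, generate_families


def random_protein(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    letters = np.array(list(STANDARD_AA))
    return "".join(letters[rng.integers(0, 20, size=length)])


@pytest.fixture(scope="session")
def study_spec() -> SyntheticSpec:
    """The default study shape: 31 enzymes in 3 families, 11 substrates,
    planted motif x substructure rule, no label noise."""
    return SyntheticSpec(seed=2024)


@pytest.fixture(scope="session")
def study_families(study_spec):
    return generate_families(study_spec)


@pytest.fixture(scope="session")
def study_activity(study_spec, study_families):
    return generate_activity(study_spec, study_families)


@pytest.fixture(scope="session")
def study_features(study_spec, study_families):
    from t3pks.featurize import featurize_pairs

    return featurize_pairs(study_families, study_spec.substrate_panel)


@pytest.fixture(scope="session")
def synthetic_reference() -> SequenceRecord:
    """A synthetic stand-in for a CHS-numbering reference: a random
    400-residue protein with the catalytic triad planted at the
    conventional positions (C164, H303, N336)."""
    residues = list(random_protein(400, seed=164303336))
    residues[163], residues[302], residues[335] = "C", "H", "N"
    return SequenceRecord(
        id="ref_synthetic",
        residues="".join(residues),
        description="synthetic reference with planted catalytic triad",
    )
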