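"""Active-site extraction, reference numbering, logos, triad flags."""

import numpy as np
import pytest

from t3pks.active_site import (
    ActiveSiteError,
    ActiveSitePositionMap,
    SitePosition,
    extract_profiles,
    flag_triad,
    map_reference_positions,
    residue_logo,
)
from t3pks.records import SequenceRecord

from .conftest import random_protein


@pytest.fixture(scope="module")
def posmap(synthetic_reference):
    return ActiveSitePositionMap(
        reference=synthetic_reference,
        positions=[
            SitePosition(164, "catalytic_C", "C"),
            SitePosition(197, "pocket"),
            SitePosition(256, "pocket_G"),
            SitePosition(265, "gatekeeper"),
            SitePosition(303, "catalytic_H", "H"),
            SitePosition(336, "catalytic_N", "N"),
        ],
    )


def test_reference_maps_to_itself(synthetic_reference, posmap):
    profile = map_reference_positions(synthetic_reference, posmap)
    for pos in posmap.ref_positions:
        assert profile[pos] == synthetic_reference.residues[pos - 1]


def test_n_terminal_insertion_does_not_shift_numbering(synthetic_reference, posmap):
    inserted = SequenceRecord(
        id="ins", residues="MKTAY" + synthetic_reference.residues
    )
    profile = map_reference_positions(inserted, posmap)
    for pos in posmap.ref_positions:
        assert profile[pos] == synthetic_reference.residues[pos - 1]


def test_internal_insertion_does_not_shift_numbering(synthetic_reference, posmap):
    ref = synthetic_reference.residues
    inserted = SequenceRecord(id="ins2", residues=ref[:200] + "GGSGG" + ref[200:])
    profile = map_reference_positions(inserted, posmap)
    for pos in posmap.ref_positions:
        assert profile[pos] == ref[pos - 1]


def test_deletion_yields_gap_symbol(synthetic_reference):
    ref = synthetic_reference.residues
    posmap = ActiveSitePositionMap(
        reference=synthetic_reference, positions=[SitePosition(10)]
    )
    deleted = SequenceRecord(id="del", residues=ref[:9] + ref[10:])
    assert map_reference_positions(deleted, posmap)[10] == "-"


def test_position_beyond_reference_rejected(synthetic_reference):
    with pytest.raises(ActiveSiteError, match="beyond reference"):
        ActiveSitePositionMap(
            reference=synthetic_reference, positions=[SitePosition(401)]
        )


def test_logo_frequencies(synthetic_reference, posmap):
    # 10 mutants: 3 carry A at 256, 7 carry G; everyone keeps the triad
    ref = list(synthetic_reference.residues)
    members = []
    for k in range(10):
        seq = list(ref)
        seq[255] = "A" if k < 3 else "G"
        seq[264] = "F" if k % 2 else "V"
        members.append(SequenceRecord(id=f"m{k}", residues="".join(seq)))
    profiles = extract_profiles(members, posmap)
    logo = residue_logo(profiles)
    assert logo.loc[256, "A"] == pytest.approx(0.3)
    assert logo.loc[256, "G"] == pytest.approx(0.7)
    assert logo.loc[265, "F"] == pytest.approx(0.5)
    np.testing.assert_allclose(logo.sum(axis=1), 1.0, atol=1e-9)


def test_empty_group_rejected(posmap):
    import pandas as pd

    with pytest.raises(ActiveSiteError, match="empty"):
        residue_logo(pd.DataFrame())


@pytest.mark.parametrize(
    "observed, expected",
    [
        ({164: "C", 303: "H", 336: "N"}, []),
        ({164: "C", 303: "D", 336: "S"}, ["H303D", "N336S"]),
        ({164: "-", 303: "H", 336: "N"}, ["C164-"]),
    ],
)
def test_triad_flags_formatting(observed, expected):
    assert flag_triad(observed) == expected


def test_triad_conserved_across_synthetic_family(study_families, study_spec):
    # family generation freezes the triad columns, so extraction against a
    # family member as reference must find the triad intact everywhere
    reference = study_families[0]
    posmap = ActiveSitePositionMap(
        reference=reference,
        positions=[SitePosition(p, expected_residue=r)
                   for p, r in study_spec.frozen_positions.items()],
    )
    profiles = extract_profiles(study_families, posmap)
    for seq_id in profiles.index:
        assert flag_triad(profiles.loc[seq_id].to_dict()) == []
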