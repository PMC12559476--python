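"""Embedding, fingerprints and pair feature construction."""

import numpy as np
import pytest

from t3pks.featurize import (
    MACCS_BITS,
    PHYSCHEM_TABLE,
    FeaturizeError,
    all_pairs,
    build_pair_features,
    embed_enzyme,
    featurize_pairs,
    fingerprint_substrate,
    get_embedder,
    load_feature_cache,
    save_feature_cache,
    tanimoto,
)
from t3pks.records import SequenceRecord
from t3pks.synthetic import default_substrate_panel


def _rec(i, residues):
    return SequenceRecord(id=i, residues=residues)


# --- enzyme embedding -------------------------------------------------------

def test_single_residue_embedding_is_the_feature_row():
    feats = embed_enzyme(_rec("e", "W"))
    np.testing.assert_allclose(feats.vector, PHYSCHEM_TABLE.loc["W"].to_numpy())


def test_homopolymer_embeds_like_its_monomer():
    one = embed_enzyme(_rec("a", "A"))
    many = embed_enzyme(_rec("aaa", "A" * 57))
    np.testing.assert_allclose(one.vector, many.vector)


def test_mean_pooling_matches_hand_computation():
    # arithmetic mean of the A, C and D rows of the published table
    expected = (
        PHYSCHEM_TABLE.loc["A"].to_numpy()
        + PHYSCHEM_TABLE.loc["C"].to_numpy()
        + PHYSCHEM_TABLE.loc["D"].to_numpy()
    ) / 3.0
    feats = embed_enzyme(_rec("acd", "ACD"))
    np.testing.assert_allclose(feats.vector, expected)
    assert feats.dim == PHYSCHEM_TABLE.shape[1]


def test_unknown_embedder_lists_registered_tags():
    with pytest.raises(FeaturizeError, match="fallback-physchem"):
        get_embedder("no-such-model")


def test_prottrans_tag_degrades_to_fallback_without_torch(caplog):
    import logging

    with caplog.at_level(logging.WARNING):
        emb = get_embedder("prottrans-x5")
    assert emb.tag == "fallback-physchem"
    assert "falling back" in caplog.text


def test_identical_sequences_identical_vectors():
    a = embed_enzyme(_rec("x", "MKTAYIAKQR"))
    b = embed_enzyme(_rec("y", "MKTAYIAKQR"))
    np.testing.assert_array_equal(a.vector, b.vector)


# --- substrate fingerprints -------------------------------------------------

def test_maccs_length_is_167():
    fp = fingerprint_substrate("OC(=O)c1ccccc1", "benzoate")
    assert fp.n_bits == MACCS_BITS == 167


def test_equivalent_smiles_give_identical_bits():
    a = fingerprint_substrate("OC(=O)c1ccccc1", "x")
    b = fingerprint_substrate("c1ccccc1C(O)=O", "y")
    np.testing.assert_array_equal(a.bits, b.bits)


def test_tanimoto_self_is_one():
    fp = fingerprint_substrate("CCCC(O)=O", "butyrate", fingerprint_type="ecfp")
    assert tanimoto(fp, fp) == 1.0


def test_ecfp_respects_bit_count():
    fp = fingerprint_substrate("CCO", "etoh", fingerprint_type="ecfp", n_bits=512)
    assert fp.n_bits == 512
    assert fp.params == {"radius": 2, "n_bits": 512}


def test_unparsable_structure_names_substrate():
    with pytest.raises(FeaturizeError, match="sub99"):
        fingerprint_substrate("not-a-smiles(((", "sub99")


# --- pair features ----------------------------------------------------------

def test_pair_vector_length_is_sum_of_parts():
    enzyme = embed_enzyme(_rec("e1", "MKTAY"))
    substrate = fingerprint_substrate("CCCC(O)=O", "s1")
    pairs = build_pair_features([enzyme], [substrate], [("e1", "s1")])
    assert len(pairs[0].vector) == enzyme.dim + 167


def test_full_grid_of_31_by_11_gives_341_vectors(study_families, study_spec):
    feats = featurize_pairs(study_families, study_spec.substrate_panel)
    assert len(feats) == 31 * 11 == 341


def test_dangling_pair_reference_rejected():
    enzyme = embed_enzyme(_rec("e1", "MKTAY"))
    substrate = fingerprint_substrate("CCCC(O)=O", "s1")
    with pytest.raises(FeaturizeError, match=r"pair \(e1, ghost\)"):
        build_pair_features([enzyme], [substrate], [("e1", "ghost")])


def test_featurization_is_pure(study_families, study_spec):
    panel = study_spec.substrate_panel.head(3)
    seqs = study_families[:3]
    a = featurize_pairs(seqs, panel)
    b = featurize_pairs(seqs, panel)
    for key in a.vectors:
        np.testing.assert_array_equal(a.vectors[key], b.vectors[key])


def test_all_pairs_enumeration():
    assert len(all_pairs(list("abc"), list("xy"))) == 6


def test_feature_cache_roundtrip(tmp_path):
    feats = [embed_enzyme(_rec("e1", "MKTAY")), embed_enzyme(_rec("e2", "ACDEF"))]
    path = tmp_path / "cache.npz"
    save_feature_cache(path, feats)
    back = load_feature_cache(path)
    np.testing.assert_allclose(back["e1"].vector, feats[0].vector)
    assert back["e2"].embedder_tag == "fallback-physchem"


def test_default_panel_all_parse():
    panel = default_substrate_panel()
    for _, row in panel.iterrows():
        fp = fingerprint_substrate(row["structure"], row["substrate_id"])
        assert fp.bits.sum() > 0
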