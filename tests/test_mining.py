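"""Candidate mining: hit detection, thresholds, merge/dereplicate."""

import pytest

from t3pks.mining import MiningError, merge_dereplicate, mine_candidates
from t3pks.records import SequenceRecord

from .conftest import random_protein
from .oracles import oracle_local


def _rec(i, residues):
    return SequenceRecord(id=i, residues=residues)


@pytest.fixture(scope="module")
def query():
    return _rec("Q", random_protein(80, seed=1))


def test_verbatim_query_is_perfect_hit(query):
    proteome = [_rec("t1", query.residues), _rec("t2", random_protein(80, seed=2))]
    hits = mine_candidates([query], proteome, min_identity=0.9, min_coverage=0.9)
    assert len(hits) == 1
    hit = hits[0]
    assert hit.target_id == "t1"
    assert hit.percent_identity == 1.0
    assert hit.query_coverage == 1.0


def test_unrelated_proteome_yields_no_hits_confirmed_by_oracle():
    # 20 random length-300 targets vs an unrelated length-50 query: the
    # brute-force local aligner confirms no alignment clears the bar
    query = _rec("Q", random_protein(50, seed=77))
    proteome = [_rec(f"t{k}", random_protein(300, seed=100 + k)) for k in range(20)]
    hits = mine_candidates([query], proteome, min_identity=0.4, min_coverage=0.5)
    assert hits == []
    for target in proteome:
        _, oa, ob = oracle_local(query.residues, target.residues)
        coverage = sum(c != "-" for c in oa) / len(query.residues)
        identity = sum(x == y and x != "-" for x, y in zip(oa, ob)) / len(oa)
        assert not (identity >= 0.4 and coverage >= 0.5)  # oracle agrees


def test_best_scoring_query_wins(query):
    # a near-copy of the target scores higher than a distant query
    target = _rec("T", query.residues)
    distant = list(query.residues)
    for k in range(0, 80, 3):
        distant[k] = "W" if distant[k] != "W" else "Y"
    q2 = _rec("Q2", "".join(distant))
    hits = mine_candidates([q2, query], [target], min_identity=0.1, min_coverage=0.1)
    assert len(hits) == 1
    assert hits[0].query_id == "Q"  # exact match outscores the mutant


def test_raising_thresholds_never_adds_hits(query):
    proteome = [_rec(f"t{k}", random_protein(120, seed=500 + k)) for k in range(8)]
    proteome.append(_rec("near", query.residues[:60] + random_protein(60, seed=9)))
    loose = {h.target_id for h in mine_candidates([query], proteome, 0.1, 0.1)}
    tight = {h.target_id for h in mine_candidates([query], proteome, 0.5, 0.5)}
    assert tight <= loose


def test_self_search_returns_everything(study_families):
    seqs = study_families[:6]
    hits = mine_candidates(seqs, seqs, min_identity=0.99, min_coverage=0.99)
    assert {h.target_id for h in hits} == {s.id for s in seqs}
    assert all(h.percent_identity == 1.0 for h in hits)


def test_empty_inputs_rejected(query):
    with pytest.raises(MiningError, match="empty"):
        mine_candidates([], [query], 0.5, 0.5)
    with pytest.raises(MiningError, match="empty"):
        mine_candidates([query], [], 0.5, 0.5)


# --- merge_dereplicate ------------------------------------------------------

def test_merge_is_idempotent():
    coll = [_rec("a", "MKTAY"), _rec("b", "ACDEF")]
    merged = merge_dereplicate([coll, coll])
    assert [(r.id, r.residues) for r in merged] == [(r.id, r.residues) for r in coll]


def test_merge_collapses_shared_record():
    one = [_rec("A", "MKTAY"), _rec("B", "ACDEF")]
    two = [_rec("B", "ACDEF"), _rec("C", "WYHKL")]
    merged = merge_dereplicate([one, two])
    assert len(merged) == 3


def test_merge_counts_unique_sequences():
    base = [_rec(f"s{k}", random_protein(40, seed=k)) for k in range(90)]
    dups = [_rec(f"dup{k}", base[k].residues) for k in range(10)]
    merged = merge_dereplicate([base + dups])
    assert len(merged) == 90
    assert merged[0].metadata.get("merged_ids") == ["dup0"]


def test_merge_rejects_id_collision_with_different_sequences():
    with pytest.raises(MiningError, match="collision.*'A'"):
        merge_dereplicate([[_rec("A", "MKTAY")], [_rec("A", "ACDEF")]])


def test_merge_order_insensitive_up_to_tiebreak():
    one = [_rec("A", "MKTAY")]
    two = [_rec("B", "MKTAY")]
    first = merge_dereplicate([one, two])
    second = merge_dereplicate([two, one])
    # same unique sequence content; kept id follows first-seen order
    assert {r.residues for r in first} == {r.residues for r in second}
    assert first[0].id == "A" and second[0].id == "B"
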