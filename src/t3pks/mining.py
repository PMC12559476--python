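"""Candidate mining: similarity search of proteomes against seed queries.

Mimics the first stage of a genome-mining campaign: every sequence in a
proteome is locally aligned (Smith-Waterman, BLOSUM62, gap open 11 /
extend 1 — the BLAST defaults) against a set of seed queries of known
function; targets whose best alignment clears both an identity and a
query-coverage threshold are reported as hits.  Hit sets from several
sources (e.g. different databases) are then merged with exact-duplicate
dereplication.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .align import align_local
from .records import SequenceRecord, check_unique_ids


class MiningError(ValueError):
    pass


@dataclass(frozen=True)
class MiningHit:
    """Best-query local-alignment hit for one proteome sequence.

    ``percent_identity`` is identical aligned columns over local alignment
    length (gaps included); ``query_coverage`` is the fraction of query
    residues inside the aligned region.  Both are fractions in [0, 1].
    """

    query_id: str
    target_id: str
    percent_identity: float
    query_coverage: float
    alignment_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 1.0:
            raise MiningError(f"percent_identity out of [0,1]: {self.percent_identity}")
        if not 0.0 <= self.query_coverage <= 1.0:
            raise MiningError(f"query_coverage out of [0,1]: {self.query_coverage}")


def mine_candidates(
    queries: Sequence[SequenceRecord],
    proteome: Sequence[SequenceRecord],
    min_identity: float,
    min_coverage: float,
) -> list[MiningHit]:
    """Report every proteome sequence similar enough to any query.

    Each target appears at most once, attributed to its best-scoring query;
    a hit requires the best alignment to satisfy both ``min_identity`` and
    ``min_coverage``.  Results are ordered by descending score, then
    target id, so reruns are reproducible.
    """
    if not queries:
        raise MiningError("empty query collection")
    if not proteome:
        raise MiningError("empty proteome collection")
    for thr, name in ((min_identity, "min_identity"), (min_coverage, "min_coverage")):
        if not 0.0 <= thr <= 1.0:
            raise MiningError(f"{name} must be in [0,1], got {thr}")
    check_unique_ids(queries)
    check_unique_ids(proteome)

    hits: list[MiningHit] = []
    for target in proteome:
        best: MiningHit | None = None
        for query in queries:
            aln = align_local(query, target)
            if aln.length == 0:
                continue
            hit = MiningHit(
                query_id=query.id,
                target_id=target.id,
                percent_identity=aln.identity,
                query_coverage=aln.coverage_of_a(),
                alignment_score=aln.score,
            )
            if best is None or hit.alignment_score > best.alignment_score:
                best = hit
        if (
            best is not None
            and best.percent_identity >= min_identity
            and best.query_coverage >= min_coverage
        ):
            hits.append(best)
    hits.sort(key=lambda h: (-h.alignment_score, h.target_id))
    return hits


def merge_dereplicate(
    hit_sets: Sequence[Sequence[SequenceRecord]],
) -> list[SequenceRecord]:
    """Union of collections with byte-identical sequences collapsed.

    The first-seen record keeps its id; ids of collapsed duplicates are
    recorded under ``metadata["merged_ids"]``.  The same id occurring with
    two different sequences is an error.
    """
    if not hit_sets:
        raise MiningError("at least one collection required")
    by_seq: dict[str, SequenceRecord] = {}
    id_to_seq: dict[str, str] = {}
    out: list[SequenceRecord] = []
    for collection in hit_sets:
        for rec in collection:
            if rec.id in id_to_seq and id_to_seq[rec.id] != rec.residues:
                raise MiningError(
                    f"id collision: {rec.id!r} maps to two different sequences"
                )
            id_to_seq[rec.id] = rec.residues
            kept = by_seq.get(rec.residues)
            if kept is None:
                kept = SequenceRecord(
                    id=rec.id,
                    residues=rec.residues,
                    description=rec.description,
                    metadata=dict(rec.metadata),
                )
                by_seq[rec.residues] = kept
                out.append(kept)
            elif rec.id != kept.id:
                merged = kept.metadata.setdefault("merged_ids", [])
                if rec.id not in merged:
                    merged.append(rec.id)
    return out


def hits_to_table(hits: Sequence[MiningHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "target_id": h.target_id,
                "query_id": h.query_id,
                "identity": h.percent_identity,
                "coverage": h.query_coverage,
                "score": h.alignment_score,
            }
            for h in hits
        ],
        columns=["target_id", "query_id", "identity", "coverage", "score"],
    )
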