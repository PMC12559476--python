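"""Sequence similarity networks with representative-node collapsing.

The network construction follows the convention popularised by web SSN
tools: near-identical sequences (pairwise identity above a high
``repnode_threshold``, by default 0.95) are collapsed into representative
nodes; edges connect representatives whose global-alignment identity
meets the display ``cutoff``; connected components of the resulting graph
are the clusters.  Identity is computed from a global Needleman-Wunsch
alignment (BLOSUM62, gap open 10 / extend 1) as identical columns over
alignment length — a symmetric, reproducible metric rather than the
BLAST-score proxy some web tools use.

Cluster ids are assigned 1..K by descending member count (members, not
representatives), ties broken by the lexicographically smallest member id,
so ids are stable across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .align import align_global
from .records import SequenceRecord, check_unique_ids


class NetworkError(ValueError):
    pass


def pairwise_identity(a: SequenceRecord | str, b: SequenceRecord | str) -> float:
    """Global-alignment identity in [0, 1].

    The aligner's deterministic tie-breaks are orientation-dependent, so
    arguments are put in lexicographic order before aligning to make the
    value exactly symmetric.
    """
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    if sb < sa:
        sa, sb = sb, sa
    return align_global(sa, sb).identity


@dataclass
class RepNode:
    rep_id: str
    member_ids: list[str]


@dataclass
class SimilarityNetwork:
    repnodes: list[RepNode]
    edges: list[tuple[str, str, float]]  # (rep_a, rep_b, identity), rep_a < rep_b
    clusters: dict[int, list[str]]  # cluster_id -> rep_ids
    cutoff: float
    repnode_threshold: float
    members_of: dict[str, list[str]] = field(default_factory=dict)

    def cluster_of(self, rep_id: str) -> int:
        for cid, reps in self.clusters.items():
            if rep_id in reps:
                return cid
        raise KeyError(rep_id)

    def cluster_members(self, cluster_id: int) -> list[str]:
        out: list[str] = []
        for rep in self.clusters[cluster_id]:
            out.extend(self.members_of[rep])
        return sorted(out)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def _kmer_set(seq: str, k: int = 4) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def identity_matrix(
    seqs: Sequence[SequenceRecord],
    kmer_prefilter: bool = False,
    kmer_min_shared: float = 0.02,
) -> np.ndarray:
    """All-vs-all global identity; optional 4-mer prefilter skips pairs
    sharing fewer than ``kmer_min_shared`` of their 4-mers (skipped pairs
    get identity 0)."""
    n = len(seqs)
    ident = np.eye(n)
    kmers = [_kmer_set(s.residues) for s in seqs] if kmer_prefilter else None
    for i in range(n):
        for j in range(i + 1, n):
            if kmers is not None:
                shared = len(kmers[i] & kmers[j])
                denom = min(len(kmers[i]), len(kmers[j])) or 1
                if shared / denom < kmer_min_shared:
                    continue
            ident[i, j] = ident[j, i] = pairwise_identity(seqs[i], seqs[j])
    return ident


def build_network(
    seqs: Sequence[SequenceRecord],
    cutoff: float,
    repnode_threshold: float = 0.95,
    kmer_prefilter: bool | None = None,
) -> SimilarityNetwork:
    """Collapse near-identical sequences and connect representatives.

    Repnode membership is single-linkage: sequences joined whenever their
    identity exceeds ``repnode_threshold`` (strictly), i.e. connected
    components of the >threshold graph.  The longest member represents
    each repnode (ties to the lexicographically smallest id).  Edges are
    kept at identity >= ``cutoff``.
    """
    if not seqs:
        raise NetworkError("empty sequence collection")
    if not 0.0 < cutoff <= 1.0:
        raise NetworkError(f"cutoff must be in (0,1], got {cutoff}")
    if repnode_threshold < cutoff:
        warnings.warn(
            f"repnode_threshold ({repnode_threshold}) below cutoff ({cutoff}): "
            "representative nodes will be coarser than the edge network",
            stacklevel=2,
        )
    check_unique_ids(seqs)
    if kmer_prefilter is None:
        kmer_prefilter = len(seqs) > 2000

    ident = identity_matrix(seqs, kmer_prefilter=kmer_prefilter)
    n = len(seqs)

    # repnodes: connected components at identity strictly above the threshold
    collapse = nx.Graph()
    collapse.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if ident[i, j] > repnode_threshold:
                collapse.add_edge(i, j)
    repnodes: list[RepNode] = []
    rep_index: dict[str, int] = {}
    for comp in nx.connected_components(collapse):
        members = sorted(comp)
        rep = min(members, key=lambda k: (-len(seqs[k].residues), seqs[k].id))
        node = RepNode(
            rep_id=seqs[rep].id,
            member_ids=sorted(seqs[k].id for k in members),
        )
        repnodes.append(node)
        rep_index[node.rep_id] = rep
    repnodes.sort(key=lambda r: r.rep_id)

    # edges between representatives at identity >= cutoff
    edges: list[tuple[str, str, float]] = []
    rep_ids = [r.rep_id for r in repnodes]
    for i, ra in enumerate(rep_ids):
        for rb in rep_ids[i + 1:]:
            idv = ident[rep_index[ra], rep_index[rb]]
            if idv >= cutoff:
                a, b = sorted((ra, rb))
                edges.append((a, b, float(idv)))
    edges.sort()

    # connected components -> clusters, numbered by descending member count
    graph = nx.Graph()
    graph.add_nodes_from(rep_ids)
    graph.add_edges_from((a, b) for a, b, _ in edges)
    members_of = {r.rep_id: r.member_ids for r in repnodes}
    comps = []
    for comp in nx.connected_components(graph):
        reps = sorted(comp)
        total = sum(len(members_of[r]) for r in reps)
        smallest = min(m for r in reps for m in members_of[r])
        comps.append((total, smallest, reps))
    comps.sort(key=lambda c: (-c[0], c[1]))
    clusters = {cid: reps for cid, (_, _, reps) in enumerate(comps, start=1)}

    return SimilarityNetwork(
        repnodes=repnodes,
        edges=edges,
        clusters=clusters,
        cutoff=cutoff,
        repnode_threshold=repnode_threshold,
        members_of=members_of,
    )


def cluster_composition(
    network: SimilarityNetwork,
    metadata: Mapping[str, str],
) -> pd.DataFrame:
    """Per-cluster tallies of a metadata field (e.g. genus or class).

    Member ids missing from *metadata* are tallied as ``"unknown"``.  The
    ``monotaxon`` flag marks clusters whose members all share one value.
    """
    rows = []
    for cid in sorted(network.clusters):
        members = network.cluster_members(cid)
        tally: dict[str, int] = {}
        for mid in members:
            value = metadata.get(mid, "unknown") or "unknown"
            tally[value] = tally.get(value, 0) + 1
        for value, count in sorted(tally.items()):
            rows.append(
                {
                    "cluster_id": cid,
                    "value": value,
                    "count": count,
                    "cluster_size": len(members),
                    "monotaxon": len(tally) == 1,
                }
            )
    return pd.DataFrame(rows, columns=["cluster_id", "value", "count", "cluster_size", "monotaxon"])


def to_edge_table(network: SimilarityNetwork) -> pd.DataFrame:
    return pd.DataFrame(network.edges, columns=["rep_a", "rep_b", "identity"])


def to_node_table(
    network: SimilarityNetwork, metadata: Mapping[str, str] | None = None
) -> pd.DataFrame:
    rows = []
    for rep in network.repnodes:
        row = {
            "rep_id": rep.rep_id,
            "member_count": len(rep.member_ids),
            "cluster_id": network.cluster_of(rep.rep_id),
            "members": ";".join(rep.member_ids),
        }
        if metadata is not None:
            row["annotation"] = metadata.get(rep.rep_id, "unknown")
        rows.append(row)
    rows.sort(key=lambda r: (r["cluster_id"], r["rep_id"]))
    return pd.DataFrame(rows)


def to_graphml(network: SimilarityNetwork, path: str) -> None:
    """Export the repnode graph for network viewers (Cytoscape-compatible)."""
    graph = nx.Graph()
    for rep in network.repnodes:
        graph.add_node(
            rep.rep_id,
            member_count=len(rep.member_ids),
            cluster_id=network.cluster_of(rep.rep_id),
        )
    for a, b, idv in network.edges:
        graph.add_edge(a, b, identity=idv)
    nx.write_graphml(graph, path)
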