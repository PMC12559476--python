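"""Active-site residue extraction against a reference numbering.

Chalcone-synthase-family enzymes are conventionally numbered after MsCHS,
the model chalcone synthase from *Medicago sativa*: the catalytic triad
sits at C164 / H303 / N336 and well-studied pocket positions include
G256, F265 and 197.  Each candidate is globally aligned to the reference
(same BLOSUM62 / gap 10,1 parameters as the network module) and the
residue occupying each reference column is read off; insertions in the
candidate never shift the reference numbering, and deletions yield the
gap symbol ``-``.  Per-group residue frequencies at those positions are
the data behind sequence-logo panels, and triad substitutions are
reported in the conventional ``H303D`` style.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .align import align_global
from .records import SequenceRecord

GAP = "-"

#: MsCHS-numbered catalytic triad (Cys-His-Asn)
DEFAULT_TRIAD: dict[int, str] = {164: "C", 303: "H", 336: "N"}

#: MsCHS-numbered positions routinely inspected in this enzyme family
DEFAULT_POSITIONS: list[tuple[int, str, str]] = [
    (164, "catalytic_C", "C"),
    (197, "pocket_197", ""),
    (256, "pocket_G", "G"),
    (265, "gatekeeper_F", "F"),
    (303, "catalytic_H", "H"),
    (336, "catalytic_N", "N"),
]


class ActiveSiteError(ValueError):
    pass


@dataclass(frozen=True)
class SitePosition:
    ref_position: int  # 1-based position in the reference sequence
    label: str = ""
    expected_residue: str = ""


@dataclass
class ActiveSitePositionMap:
    """A reference sequence plus the 1-based positions to extract."""

    reference: SequenceRecord
    positions: list[SitePosition] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = sorted(self.positions, key=lambda p: p.ref_position)
        for pos in self.positions:
            if not 1 <= pos.ref_position <= len(self.reference):
                raise ActiveSiteError(
                    f"position {pos.ref_position} beyond reference length "
                    f"{len(self.reference)}"
                )
            if pos.expected_residue and len(pos.expected_residue) != 1:
                raise ActiveSiteError(
                    f"expected_residue must be one letter, got {pos.expected_residue!r}"
                )

    @property
    def ref_positions(self) -> list[int]:
        return [p.ref_position for p in self.positions]

    @classmethod
    def from_table(cls, reference: SequenceRecord, path: str | Path) -> "ActiveSitePositionMap":
        """Load positions from a TSV (ref_position, label, expected_residue)
        or a YAML list of mappings."""
        path = Path(path)
        if path.suffix in {".yml", ".yaml"}:
            entries = yaml.safe_load(path.read_text())
            rows = [
                SitePosition(
                    ref_position=int(e["ref_position"]),
                    label=str(e.get("label", "")),
                    expected_residue=str(e.get("expected_residue", "") or ""),
                )
                for e in entries
            ]
        else:
            table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
            rows = [
                SitePosition(
                    ref_position=int(r["ref_position"]),
                    label=r.get("label", ""),
                    expected_residue=r.get("expected_residue", ""),
                )
                for _, r in table.iterrows()
            ]
        return cls(reference=reference, positions=rows)


def map_reference_positions(
    seq: SequenceRecord,
    posmap: ActiveSitePositionMap,
) -> dict[int, str]:
    """Residue of *seq* at each reference position, ``-`` for deletions.

    The query is globally aligned to the reference; reference numbering is
    anchored to reference columns, so insertions in the query do not shift
    it.  Each reference column pairs with at most one query residue in a
    global alignment, so the extraction is unambiguous.
    """
    aln = align_global(seq, posmap.reference)
    wanted = set(posmap.ref_positions)
    out = {p: GAP for p in wanted}
    for qi, ri in zip(aln.a_indices, aln.b_indices):
        if ri >= 0 and (ri + 1) in wanted:
            out[ri + 1] = seq.residues[qi] if qi >= 0 else GAP
    return out


def extract_profiles(
    seqs: Sequence[SequenceRecord],
    posmap: ActiveSitePositionMap,
) -> pd.DataFrame:
    """Per-sequence extraction table: rows = sequences, columns = positions."""
    rows = {s.id: map_reference_positions(s, posmap) for s in seqs}
    table = pd.DataFrame.from_dict(rows, orient="index")
    return table[posmap.ref_positions]


def residue_logo(profiles: pd.DataFrame) -> pd.DataFrame:
    """Residue frequencies per reference position (gap is its own category).

    Rows are positions, columns residues; every row sums to 1.
    """
    if profiles.empty:
        raise ActiveSiteError("empty group: no sequences to summarise")
    freq = {}
    for pos in profiles.columns:
        counts = profiles[pos].value_counts()
        freq[pos] = (counts / counts.sum()).to_dict()
    table = pd.DataFrame.from_dict(freq, orient="index").fillna(0.0)
    return table[sorted(table.columns)]


def flag_triad(
    profile: Mapping[int, str],
    triad: Mapping[int, str] = DEFAULT_TRIAD,
) -> list[str]:
    """Substitution strings for non-conserved triad positions.

    Conserved triad -> ``[]``; a substitution is formatted expected +
    position + observed (e.g. ``"H303D"``), a deletion as ``"C164-"``.
    """
    flags = []
    for pos in sorted(triad):
        if pos not in profile:
            raise ActiveSiteError(f"triad position {pos} missing from profile")
        expected, observed = triad[pos], profile[pos]
        if observed != expected:
            flags.append(f"{expected}{pos}{observed}")
    return flags


def flag_triad_all(
    profiles: pd.DataFrame,
    triad: Mapping[int, str] = DEFAULT_TRIAD,
) -> dict[str, list[str]]:
    return {
        seq_id: flag_triad(profiles.loc[seq_id].to_dict(), triad)
        for seq_id in profiles.index
    }
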