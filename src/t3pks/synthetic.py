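"""Synthetic fixtures: homologous families, substrate panels, planted rules.

Every other module is testable offline against data from here.  The
generator emulates the statistical shape of a cell-free activity
profiling campaign: a few homologous enzyme families at controlled
within/between identity, a small panel of CoA-ligatable carboxylic acids,
and a binary activity matrix produced by a planted rule that couples a
specificity-determining residue (the "motif" column) to a chemical
substructure of the substrate.  The default configuration yields 31
enzymes x 11 substrates = 341 pairs with 146 (43%) active.

Sequences evolve by point substitution only (uniform over the 19
alternative residues, no indels, no rate heterogeneity): adequate for
controlling identity levels while keeping the maths of expected
divergence exact — the number of differences from an ancestor is
Binomial(L_free, rate).  The catalytic-triad columns (C164/H303/N336 in
reference numbering) and the motif column are never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .model import PairDataset
from .records import STANDARD_AA, SequenceRecord


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# substrate panel and planted activity rule
# ---------------------------------------------------------------------------

def default_substrate_panel() -> pd.DataFrame:
    """Eleven small achiral carboxylic acids: 5 aromatic, 3 unsaturated
    aliphatic, 3 saturated aliphatic — mirroring the diversity of a
    starter-unit panel without reproducing any specific chemistry."""
    rows = [
        ("sub01", "benzoic acid", "OC(=O)c1ccccc1"),
        ("sub02", "phenylacetic acid", "OC(=O)Cc1ccccc1"),
        ("sub03", "4-hydroxybenzoic acid", "OC(=O)c1ccc(O)cc1"),
        ("sub04", "anthranilic acid", "OC(=O)c1ccccc1N"),
        ("sub05", "2-furoic acid", "OC(=O)c1ccco1"),
        ("sub06", "crotonic acid", "C/C=C/C(O)=O"),
        ("sub07", "4-pentenoic acid", "C=CCCC(O)=O"),
        ("sub08", "sorbic acid", "C/C=C/C=C/C(O)=O"),
        ("sub09", "butyric acid", "CCCC(O)=O"),
        ("sub10", "hexanoic acid", "CCCCCC(O)=O"),
        ("sub11", "3-methylbutanoic acid", "CC(C)CC(O)=O"),
    ]
    return pd.DataFrame(rows, columns=["substrate_id", "name", "structure"])


@dataclass(frozen=True)
class RuleClause:
    """One motif -> substructure coupling: enzymes whose motif-column
    residue is in ``residues`` accept substrates matching ``smarts``
    (or NOT matching it when ``negate`` is set)."""

    residues: frozenset
    smarts: str
    negate: bool = False

    def substrate_matches(self, mol: Chem.Mol) -> bool:
        hit = mol.HasSubstructMatch(Chem.MolFromSmarts(self.smarts))
        return (not hit) if self.negate else hit


@dataclass
class ActivityRule:
    """Planted ground truth: label = OR over clauses of
    (motif residue in clause) AND (substrate matches clause fragment)."""

    motif_column: int  # 1-based sequence position
    clauses: tuple[RuleClause, ...]

    def label(self, residue: str, mol: Chem.Mol) -> int:
        for clause in self.clauses:
            if residue in clause.residues and clause.substrate_matches(mol):
                return 1
        return 0


def default_rule(motif_column: int = 197) -> ActivityRule:
    """V at the motif column accepts aliphatic substrates, F aromatic ones,
    A only substrates with a non-aromatic C=C.  On the default panel and
    family sizes (11, 10, 10) this yields exactly 146/341 = 43% active."""
    return ActivityRule(
        motif_column=motif_column,
        clauses=(
            RuleClause(residues=frozenset("V"), smarts="[a]", negate=True),
            RuleClause(residues=frozenset("F"), smarts="[a]"),
            RuleClause(residues=frozenset("A"), smarts="C=C"),
        ),
    )


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study; ``seed`` is mandatory."""

    seed: int
    n_families: int = 3
    family_sizes: Sequence[int] | int = (11, 10, 10)
    seq_length: int = 380
    within_family_mutation_rate: float = 0.05
    between_family_divergence: float = 0.41
    frozen_positions: dict = field(
        default_factory=lambda: {164: "C", 303: "H", 336: "N"}
    )
    motif_column: int = 197
    family_motifs: Sequence[str] = ("V", "F", "A")
    substrate_panel: pd.DataFrame | None = None
    rule: ActivityRule | None = None
    label_noise_rate: float = 0.0
    target_active_fraction: float = 0.43  # expectation of the default rule

    def __post_init__(self) -> None:
        for rate, name in (
            (self.within_family_mutation_rate, "within_family_mutation_rate"),
            (self.between_family_divergence, "between_family_divergence"),
            (self.label_noise_rate, "label_noise_rate"),
        ):
            if not 0.0 <= rate <= 1.0:
                raise SyntheticError(f"{name} must be in [0,1], got {rate}")
        if isinstance(self.family_sizes, int):
            self.family_sizes = tuple([self.family_sizes] * self.n_families)
        else:
            self.family_sizes = tuple(self.family_sizes)
        if len(self.family_sizes) != self.n_families:
            raise SyntheticError(
                f"{len(self.family_sizes)} family sizes given for "
                f"{self.n_families} families"
            )
        for pos in list(self.frozen_positions) + [self.motif_column]:
            if not 1 <= pos <= self.seq_length:
                raise SyntheticError(
                    f"position {pos} beyond sequence length {self.seq_length}"
                )
        if self.substrate_panel is None:
            self.substrate_panel = default_substrate_panel()
        if self.rule is None:
            self.rule = default_rule(self.motif_column)
        if self.rule.motif_column > self.seq_length:
            raise SyntheticError(
                f"rule column {self.rule.motif_column} beyond sequence length"
            )


# ---------------------------------------------------------------------------
# sequence generation
# ---------------------------------------------------------------------------

_AA = np.array(list(STANDARD_AA))
_AA_TO_I = {aa: i for i, aa in enumerate(STANDARD_AA)}


def _mutate(seq: np.ndarray, rate: float, protected: np.ndarray, rng) -> np.ndarray:
    """Point-mutate each unprotected position with probability *rate*,
    substituting a uniform choice among the 19 alternatives."""
    out = seq.copy()
    hit = (rng.random(len(seq)) < rate) & ~protected
    for i in np.flatnonzero(hit):
        shift = rng.integers(1, len(_AA))  # skip the current residue
        out[i] = (seq[i] + shift) % len(_AA)
    return out


def generate_families(spec: SyntheticSpec) -> list[SequenceRecord]:
    """Homologous families grown from per-family ancestors.

    A random root is mutated at ``between_family_divergence`` into each
    family ancestor; members are the ancestor mutated at
    ``within_family_mutation_rate``.  Frozen positions (catalytic triad)
    and the motif column are exempt; the motif column carries each
    family's diagnostic residue.  Family labels and the ancestor flag are
    recorded in metadata; reproducible from the seed alone.
    """
    rng = np.random.default_rng(spec.seed)
    length = spec.seq_length
    protected = np.zeros(length, dtype=bool)
    for pos in spec.frozen_positions:
        protected[pos - 1] = True
    protected[spec.motif_column - 1] = True

    root = rng.integers(0, len(_AA), size=length)
    for pos, residue in spec.frozen_positions.items():
        root[pos - 1] = _AA_TO_I[residue]

    records: list[SequenceRecord] = []
    for fam_i in range(spec.n_families):
        motif = spec.family_motifs[fam_i % len(spec.family_motifs)]
        ancestor = _mutate(root, spec.between_family_divergence, protected, rng)
        ancestor[spec.motif_column - 1] = _AA_TO_I[motif]
        family = f"fam{fam_i + 1}"
        for member_j in range(spec.family_sizes[fam_i]):
            seq = _mutate(ancestor, spec.within_family_mutation_rate, protected, rng)
            records.append(
                SequenceRecord(
                    id=f"{family}_s{member_j + 1:02d}",
                    residues="".join(_AA[seq]),
                    description=f"synthetic family {family} motif {motif}",
                    metadata={"family": family, "motif": motif},
                )
            )
    return records


def generate_decoys(n: int, length: int, seed: int) -> list[SequenceRecord]:
    """Unrelated random sequences, e.g. as proteome background for mining."""
    rng = np.random.default_rng(seed)
    return [
        SequenceRecord(
            id=f"decoy_{k + 1:03d}",
            residues="".join(_AA[rng.integers(0, len(_AA), size=length)]),
            description="synthetic decoy (no homology)",
            metadata={"family": "decoy"},
        )
        for k in range(n)
    ]


# ---------------------------------------------------------------------------
# activity generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticActivity:
    observed: PairDataset  # rule XOR Bernoulli(label_noise_rate)
    truth: PairDataset  # exact rule labels


def generate_activity(
    spec: SyntheticSpec,
    sequences: Sequence[SequenceRecord],
    substrates: pd.DataFrame | None = None,
) -> SyntheticActivity:
    """Binary activity for every sequence x substrate pair.

    The planted rule reads the residue at the motif column straight off
    the (ungapped) sequence; observed labels flip with probability
    ``label_noise_rate``; the exact rule labels are returned alongside as
    ground truth.
    """
    if substrates is None:
        substrates = spec.substrate_panel
    rule = spec.rule
    mols = {}
    for _, row in substrates.iterrows():
        mol = Chem.MolFromSmiles(row["structure"])
        if mol is None:
            raise SyntheticError(
                f"substrate {row['substrate_id']!r}: unparsable structure"
            )
        mols[row["substrate_id"]] = mol
    rng = np.random.default_rng(spec.seed + 1)
    observed, truth = [], []
    for rec in sequences:
        if rule.motif_column > len(rec.residues):
            raise SyntheticError(
                f"rule column {rule.motif_column} beyond sequence {rec.id!r}"
            )
        residue = rec.residues[rule.motif_column - 1]
        for substrate_id in substrates["substrate_id"]:
            clean = rule.label(residue, mols[substrate_id])
            flip = int(rng.random() < spec.label_noise_rate)
            observed.append((rec.id, substrate_id, clean ^ flip))
            truth.append((rec.id, substrate_id, clean))
    return SyntheticActivity(
        observed=PairDataset(pairs=observed, provenance="synthetic-observed"),
        truth=PairDataset(pairs=truth, provenance="synthetic-truth"),
    )
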