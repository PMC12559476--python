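"""Enzyme, substrate and pair feature construction.

Enzymes become fixed-length vectors by mean-pooling a per-residue feature
matrix (L x d -> d); substrates become binary chemical fingerprints
(MACCS keys or Morgan/ECFP); an enzyme-substrate pair is represented by
the concatenation of the two.  All constructions are pure: the same
inputs and parameters always produce byte-identical vectors.

Per-residue featurizers ("embedders") are pluggable through a registry.
The built-in ``fallback-physchem`` embedder needs no model download: each
residue maps to eight z-scored physicochemical properties (Kyte-Doolittle
hydropathy, side-chain volume, residue mass, isoelectric point, charge at
pH 7, aromaticity, polarity, Chou-Fasman helix propensity) concatenated
with a 21-letter one-hot indicator, so mean pooling yields property
averages plus the amino-acid composition.  An adapter slot exists for
transformer protein language models (e.g. ProtTrans-X5); when the heavy
dependencies are missing the registry degrades to the fallback with a
logged warning instead of failing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .records import ALPHABET, SequenceRecord

logger = logging.getLogger(__name__)


class FeaturizeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# per-residue physicochemical table (raw literature scales)
# ---------------------------------------------------------------------------

_RAW_PROPERTIES: dict[str, list[float]] = {
    # hydropathy (Kyte-Doolittle), volume A^3, residue mass Da, pI,
    # charge at pH 7, aromatic, polar, helix propensity (Chou-Fasman)
    "A": [1.8, 88.6, 71.08, 6.00, 0.0, 0.0, 0.0, 1.42],
    "C": [2.5, 108.5, 103.14, 5.07, 0.0, 0.0, 1.0, 0.70],
    "D": [-3.5, 111.1, 115.09, 2.77, -1.0, 0.0, 1.0, 1.01],
    "E": [-3.5, 138.4, 129.12, 3.22, -1.0, 0.0, 1.0, 1.51],
    "F": [2.8, 189.9, 147.18, 5.48, 0.0, 1.0, 0.0, 1.13],
    "G": [-0.4, 60.1, 57.05, 5.97, 0.0, 0.0, 0.0, 0.57],
    "H": [-3.2, 153.2, 137.14, 7.59, 0.1, 1.0, 1.0, 1.00],
    "I": [4.5, 166.7, 113.16, 6.02, 0.0, 0.0, 0.0, 1.08],
    "K": [-3.9, 168.6, 128.17, 9.74, 1.0, 0.0, 1.0, 1.16],
    "L": [3.8, 166.7, 113.16, 5.98, 0.0, 0.0, 0.0, 1.21],
    "M": [1.9, 162.9, 131.19, 5.74, 0.0, 0.0, 0.0, 1.45],
    "N": [-3.5, 114.1, 114.10, 5.41, 0.0, 0.0, 1.0, 0.67],
    "P": [-1.6, 112.7, 97.12, 6.30, 0.0, 0.0, 0.0, 0.57],
    "Q": [-3.5, 143.8, 128.13, 5.65, 0.0, 0.0, 1.0, 1.11],
    "R": [-4.5, 173.4, 156.19, 10.76, 1.0, 0.0, 1.0, 0.98],
    "S": [-0.8, 89.0, 87.08, 5.68, 0.0, 0.0, 1.0, 0.77],
    "T": [-0.7, 116.1, 101.10, 5.60, 0.0, 0.0, 1.0, 0.83],
    "V": [4.2, 140.0, 99.13, 5.96, 0.0, 0.0, 0.0, 1.06],
    "W": [-0.9, 227.8, 186.21, 5.89, 0.0, 1.0, 0.0, 1.08],
    "Y": [-1.3, 193.6, 163.18, 5.66, 0.0, 1.0, 1.0, 0.69],
}

PROPERTY_NAMES = [
    "hydropathy", "volume", "mass", "pI", "charge", "aromatic", "polar", "helix",
]


def _build_physchem_table() -> pd.DataFrame:
    """Z-score each property over the 20 standard residues; X gets the
    column mean (zero after scaling); a 21-letter one-hot block follows."""
    raw = pd.DataFrame.from_dict(_RAW_PROPERTIES, orient="index", columns=PROPERTY_NAMES)
    scaled = (raw - raw.mean()) / raw.std(ddof=0)
    scaled.loc["X"] = 0.0
    onehot = pd.DataFrame(
        np.eye(len(ALPHABET)),
        index=list(ALPHABET),
        columns=[f"is_{aa}" for aa in ALPHABET],
    )
    table = pd.concat([scaled.loc[list(ALPHABET)], onehot], axis=1)
    return table


#: the fallback embedder's per-residue feature table (one row per letter)
PHYSCHEM_TABLE: pd.DataFrame = _build_physchem_table()


class Embedder(Protocol):
    tag: str
    dim: int

    def per_residue(self, seq: SequenceRecord) -> np.ndarray: ...


class PhysChemEmbedder:
    """Deterministic per-residue featurizer built from PHYSCHEM_TABLE."""

    tag = "fallback-physchem"

    def __init__(self) -> None:
        self._matrix = PHYSCHEM_TABLE.to_numpy(dtype=np.float64)
        self._index = {aa: i for i, aa in enumerate(PHYSCHEM_TABLE.index)}
        self.dim = self._matrix.shape[1]

    def per_residue(self, seq: SequenceRecord) -> np.ndarray:
        try:
            rows = [self._index[c] for c in seq.residues]
        except KeyError as exc:
            raise FeaturizeError(
                f"record {seq.id!r}: residue {exc.args[0]!r} outside embedder alphabet"
            ) from None
        return self._matrix[rows]


def _prottrans_factory() -> Embedder:
    try:
        import torch  # noqa: F401
        import transformers  # noqa: F401
    except ImportError:
        logger.warning(
            "prottrans-x5 requested but torch/transformers are not installed; "
            "falling back to the deterministic physicochemical embedder"
        )
        return PhysChemEmbedder()
    from .plm import ProtTransEmbedder  # pragma: no cover - optional heavy path

    return ProtTransEmbedder()  # pragma: no cover


_EMBEDDERS: dict[str, Callable[[], Embedder]] = {
    "fallback-physchem": PhysChemEmbedder,
    "prottrans-x5": _prottrans_factory,
}


def register_embedder(tag: str, factory: Callable[[], Embedder]) -> None:
    _EMBEDDERS[tag] = factory


def get_embedder(tag: str) -> Embedder:
    if tag not in _EMBEDDERS:
        raise FeaturizeError(
            f"unknown embedder {tag!r}; registered: {sorted(_EMBEDDERS)}"
        )
    return _EMBEDDERS[tag]()


@dataclass(frozen=True)
class EnzymeFeatures:
    seq_id: str
    vector: np.ndarray
    embedder_tag: str

    @property
    def dim(self) -> int:
        return len(self.vector)


def embed_enzyme(seq: SequenceRecord, embedder: Embedder | str = "fallback-physchem") -> EnzymeFeatures:
    """Mean-pool the embedder's per-residue matrix (L x d) into a d-vector."""
    emb = get_embedder(embedder) if isinstance(embedder, str) else embedder
    matrix = emb.per_residue(seq)
    if matrix.ndim != 2 or matrix.shape[0] != len(seq.residues) or matrix.shape[1] != emb.dim:
        raise FeaturizeError(
            f"embedder {emb.tag!r} returned shape {matrix.shape}, "
            f"expected ({len(seq.residues)}, {emb.dim})"
        )
    return EnzymeFeatures(seq_id=seq.id, vector=matrix.mean(axis=0), embedder_tag=emb.tag)


# ---------------------------------------------------------------------------
# substrate fingerprints
# ---------------------------------------------------------------------------

MACCS_BITS = 167  # standard MACCS key count (bit 0 unused by convention)


@dataclass(frozen=True)
class SubstrateFeatures:
    substrate_id: str
    bits: np.ndarray  # uint8 binary vector
    fingerprint_type: str  # "maccs" or "ecfp"
    params: dict = field(default_factory=dict)

    @property
    def n_bits(self) -> int:
        return len(self.bits)


def fingerprint_substrate(
    structure: str,
    substrate_id: str = "",
    fingerprint_type: str = "maccs",
    radius: int = 2,
    n_bits: int = 2048,
) -> SubstrateFeatures:
    """Binary fingerprint of a molecule given as a SMILES string.

    ``maccs`` yields the fixed 167-key vector; ``ecfp`` a Morgan
    fingerprint (default radius 2, 2048 bits).  RDKit canonicalisation
    makes the result independent of input atom ordering.
    """
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise FeaturizeError(
            f"substrate {substrate_id or structure!r}: unparsable structure {structure!r}"
        )
    if fingerprint_type == "maccs":
        fp = MACCSkeys.GenMACCSKeys(mol)
        bits = np.zeros(MACCS_BITS, dtype=np.uint8)
        for bit in fp.GetOnBits():
            bits[bit] = 1
        params = {}
    elif fingerprint_type == "ecfp":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
        fp = gen.GetFingerprint(mol)
        bits = np.zeros(n_bits, dtype=np.uint8)
        for bit in fp.GetOnBits():
            bits[bit] = 1
        params = {"radius": radius, "n_bits": n_bits}
    else:
        raise FeaturizeError(f"unknown fingerprint type {fingerprint_type!r}")
    return SubstrateFeatures(
        substrate_id=substrate_id or structure,
        bits=bits,
        fingerprint_type=fingerprint_type,
        params=params,
    )


def tanimoto(a: SubstrateFeatures, b: SubstrateFeatures) -> float:
    inter = int(np.sum((a.bits == 1) & (b.bits == 1)))
    union = int(np.sum((a.bits == 1) | (b.bits == 1)))
    return inter / union if union else 1.0


def read_substrates(path: str | Path) -> pd.DataFrame:
    """Substrate table CSV with columns substrate_id, name, structure."""
    table = pd.read_csv(path, dtype=str)
    missing = {"substrate_id", "structure"} - set(table.columns)
    if missing:
        raise FeaturizeError(f"substrate table missing columns {sorted(missing)}")
    return table


# ---------------------------------------------------------------------------
# pair features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairFeatures:
    enzyme_id: str
    substrate_id: str
    vector: np.ndarray


def build_pair_features(
    enzymes: Sequence[EnzymeFeatures] | Mapping[str, EnzymeFeatures],
    substrates: Sequence[SubstrateFeatures] | Mapping[str, SubstrateFeatures],
    pairs: Sequence[tuple[str, str]],
) -> list[PairFeatures]:
    """Concatenate enzyme vector and substrate bits for each pair.

    Output is sorted by (enzyme_id, substrate_id) so the ordering is
    stable regardless of the order pairs were supplied in.
    """
    emap = enzymes if isinstance(enzymes, Mapping) else {e.seq_id: e for e in enzymes}
    smap = substrates if isinstance(substrates, Mapping) else {s.substrate_id: s for s in substrates}
    out = []
    for enzyme_id, substrate_id in sorted(pairs):
        if enzyme_id not in emap:
            raise FeaturizeError(f"pair ({enzyme_id}, {substrate_id}): unknown enzyme")
        if substrate_id not in smap:
            raise FeaturizeError(f"pair ({enzyme_id}, {substrate_id}): unknown substrate")
        vector = np.concatenate(
            [emap[enzyme_id].vector, smap[substrate_id].bits.astype(np.float64)]
        )
        out.append(PairFeatures(enzyme_id=enzyme_id, substrate_id=substrate_id, vector=vector))
    return out


def all_pairs(enzyme_ids: Sequence[str], substrate_ids: Sequence[str]) -> list[tuple[str, str]]:
    return [(e, s) for e in enzyme_ids for s in substrate_ids]


@dataclass
class PairFeatureSet:
    """Pair vectors plus the provenance tags they were computed under.

    Mixing feature sets computed with different embedders or fingerprint
    settings is a silent way to invalidate a model, so downstream code
    compares these tags and refuses mismatches.
    """

    vectors: dict[tuple[str, str], np.ndarray]
    embedder_tag: str
    fingerprint_type: str
    fingerprint_params: dict = field(default_factory=dict)

    def __getitem__(self, pair: tuple[str, str]) -> np.ndarray:
        return self.vectors[pair]

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def compatible_with(self, other: "PairFeatureSet") -> bool:
        return (
            self.embedder_tag == other.embedder_tag
            and self.fingerprint_type == other.fingerprint_type
            and self.fingerprint_params == other.fingerprint_params
        )


def featurize_pairs(
    sequences: Sequence[SequenceRecord],
    substrate_table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] | None = None,
    embedder: Embedder | str = "fallback-physchem",
    fingerprint_type: str = "maccs",
    radius: int = 2,
    n_bits: int = 2048,
) -> PairFeatureSet:
    """End-to-end featurization: embed enzymes, fingerprint substrates,
    concatenate per pair (all enzyme x substrate pairs when *pairs* is None)."""
    emb = get_embedder(embedder) if isinstance(embedder, str) else embedder
    enzymes = {s.id: embed_enzyme(s, emb) for s in sequences}
    substrates = {}
    for _, row in substrate_table.iterrows():
        substrates[row["substrate_id"]] = fingerprint_substrate(
            row["structure"],
            substrate_id=row["substrate_id"],
            fingerprint_type=fingerprint_type,
            radius=radius,
            n_bits=n_bits,
        )
    if pairs is None:
        pairs = all_pairs(sorted(enzymes), list(substrate_table["substrate_id"]))
    feats = build_pair_features(enzymes, substrates, pairs)
    params = {"radius": radius, "n_bits": n_bits} if fingerprint_type == "ecfp" else {}
    return PairFeatureSet(
        vectors={(f.enzyme_id, f.substrate_id): f.vector for f in feats},
        embedder_tag=emb.tag,
        fingerprint_type=fingerprint_type,
        fingerprint_params=params,
    )


# ---------------------------------------------------------------------------
# feature cache
# ---------------------------------------------------------------------------

def save_feature_cache(path: str | Path, features: Sequence[EnzymeFeatures]) -> None:
    """NPZ archive keyed by embedder tag and sequence id."""
    arrays = {f"{f.embedder_tag}::{f.seq_id}": f.vector for f in features}
    np.savez(path, **arrays)


def load_feature_cache(path: str | Path) -> dict[str, EnzymeFeatures]:
    data = np.load(path)
    out = {}
    for key in data.files:
        tag, seq_id = key.split("::", 1)
        out[seq_id] = EnzymeFeatures(seq_id=seq_id, vector=data[key], embedder_tag=tag)
    return out
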