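"""Descriptive ranking of alignment positions behind substrate specificity.

Given per-enzyme residues at reference-numbered positions (from the
active-site module) and binary activity labels, an interpretable
classifier is fitted on one-hot-encoded columns and positions are scored
by grouped permutation importance: all indicator columns belonging to one
position are shuffled together (same permutation), and the importance is
the resulting drop in training-set accuracy.  Scores are averaged over
bootstrap replicates of the enzyme set; the ``stability`` of a position
is the fraction of replicates in which it stays in the top decile.

This is a descriptive tool: a highly ranked position is associated with
the activity pattern, which is not a claim of mechanistic causality.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .model import PairDataset


class ImportanceError(ValueError):
    pass


def enzyme_labels(dataset: PairDataset, substrate_id: str | None = None) -> dict[str, int]:
    """Per-enzyme binary labels for one substrate, or pooled by majority
    over the enzyme's substrates (ties count as active)."""
    table = dataset.to_long()
    if substrate_id is not None:
        sub = table[table["substrate_id"] == substrate_id]
        if sub.empty:
            raise ImportanceError(f"no pairs for substrate {substrate_id!r}")
        return dict(zip(sub["enzyme_id"], sub["label"].astype(int)))
    pooled = table.groupby("enzyme_id")["label"].mean()
    return {e: int(v >= 0.5) for e, v in pooled.items()}


def _one_hot(profiles: pd.DataFrame) -> tuple[np.ndarray, list[int], list[slice]]:
    """One-hot encode residue columns; returns the matrix, the position
    list and, per position, the slice of its indicator block."""
    blocks, slices, positions = [], [], []
    start = 0
    for pos in profiles.columns:
        residues = sorted(profiles[pos].unique())
        block = np.zeros((len(profiles), len(residues)))
        for k, residue in enumerate(residues):
            block[:, k] = (profiles[pos] == residue).to_numpy()
        blocks.append(block)
        slices.append(slice(start, start + len(residues)))
        positions.append(int(pos))
        start += len(residues)
    return np.hstack(blocks), positions, slices


def rank_positions(
    profiles: pd.DataFrame,
    labels: Mapping[str, int],
    seed: int,
    n_boot: int = 10,
    n_permutations: int = 3,
    classifier: str = "random_forest",
    n_estimators: int = 100,
) -> pd.DataFrame:
    """Rank reference positions by association with enzyme activity.

    Parameters
    ----------
    profiles:
        Rows = enzyme ids, columns = reference positions, cells = residues
        (gap symbol allowed), e.g. from ``active_site.extract_profiles``.
    labels:
        Enzyme id -> binary label, e.g. from :func:`enzyme_labels`.
    seed:
        Controls bootstrap resampling, model seeds and permutations; the
        full ranking is deterministic given it.

    Returns a table (ref_position, score, rank, stability) sorted by rank.
    Positions constant across enzymes receive score exactly 0.
    """
    missing = set(profiles.index) - set(labels)
    if missing:
        raise ImportanceError(f"labels missing for enzymes {sorted(missing)[:5]}")
    y = np.array([labels[e] for e in profiles.index], dtype=np.int64)
    if len(profiles) < 2 or len(np.unique(y)) < 2:
        raise ImportanceError("no signal to attribute: need >=2 enzymes with differing labels")

    X, positions, slices = _one_hot(profiles)
    variable = [len(profiles[c].unique()) > 1 for c in profiles.columns]
    rng = np.random.default_rng(seed)
    n = len(y)
    scores = np.zeros((n_boot, len(positions)))
    top_k = max(1, int(np.ceil(len(positions) / 10)))
    in_top = np.zeros((n_boot, len(positions)), dtype=bool)

    for boot in range(n_boot):
        for _ in range(100):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
        else:
            raise ImportanceError("could not draw a bootstrap sample with both classes")
        Xb, yb = X[idx], y[idx]
        est_seed = int(rng.integers(0, 2**31 - 1))
        if classifier == "random_forest":
            est = RandomForestClassifier(
                n_estimators=n_estimators, random_state=est_seed, n_jobs=1
            )
        elif classifier == "decision_tree":
            est = DecisionTreeClassifier(random_state=est_seed)
        else:
            raise ImportanceError(f"unsupported classifier {classifier!r}")
        est.fit(Xb, yb)
        baseline = float(np.mean(est.predict(Xb) == yb))
        for p, block in enumerate(slices):
            if not variable[p]:
                continue  # no variance, no signal: score stays 0
            drop = 0.0
            for _ in range(n_permutations):
                perm = rng.permutation(len(yb))
                Xp = Xb.copy()
                Xp[:, block] = Xb[perm][:, block]
                drop += baseline - float(np.mean(est.predict(Xp) == yb))
            scores[boot, p] = drop / n_permutations
        order = np.argsort(-scores[boot], kind="stable")
        in_top[boot, order[:top_k]] = True

    mean_scores = scores.mean(axis=0)
    order = np.argsort(-mean_scores, kind="stable")
    table = pd.DataFrame(
        {
            "ref_position": [positions[i] for i in order],
            "score": mean_scores[order],
            "rank": np.arange(1, len(positions) + 1),
            "stability": in_top.mean(axis=0)[order],
        }
    )
    return table
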