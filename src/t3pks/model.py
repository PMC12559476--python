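"""Binary enzyme-substrate activity classifiers with seeded protocols.

Three scikit-learn classifier families are supported (decision tree,
random forest, MLP).  Evaluation follows a seed-repeated protocol: one
"run" is a stratified k-fold cross-validation with its own seed, scored
on the pooled out-of-fold predictions, and a report collects the per-run
accuracy and F1 (positive class = active) as mean +/- sd.  Deployment
averages predicted probabilities over ``n_prediction_runs`` (default 100)
models trained with distinct seeds, then binarises at the decision
threshold — the convention behind "averaged over 100 model runs with a
random seed" prediction heatmaps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .featurize import PairFeatureSet

CLASSIFIERS = ("decision_tree", "random_forest", "mlp")


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

@dataclass
class PairDataset:
    """Binary enzyme x substrate activity labels."""

    pairs: list[tuple[str, str, int]]  # (enzyme_id, substrate_id, label)
    provenance: str = "train"

    def __post_init__(self) -> None:
        seen = set()
        for enzyme_id, substrate_id, label in self.pairs:
            if label not in (0, 1):
                raise ModelError(
                    f"pair ({enzyme_id}, {substrate_id}): label must be 0 or 1, got {label!r}"
                )
            key = (enzyme_id, substrate_id)
            if key in seen:
                raise ModelError(f"duplicate pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def labels(self) -> np.ndarray:
        return np.array([label for _, _, label in self.pairs], dtype=np.int64)

    @property
    def active_fraction(self) -> float:
        return float(self.labels.mean())

    @property
    def enzyme_ids(self) -> list[str]:
        return sorted({e for e, _, _ in self.pairs})

    @property
    def substrate_ids(self) -> list[str]:
        return sorted({s for _, s, _ in self.pairs})

    @classmethod
    def from_long(cls, table: pd.DataFrame, provenance: str = "train") -> "PairDataset":
        """Long format: columns enzyme_id, substrate_id, label."""
        pairs = [
            (str(r["enzyme_id"]), str(r["substrate_id"]), int(r["label"]))
            for _, r in table.iterrows()
        ]
        return cls(pairs=pairs, provenance=provenance)

    @classmethod
    def from_wide(cls, table: pd.DataFrame, provenance: str = "train") -> "PairDataset":
        """Wide format: index enzymes, columns substrates, binary cells."""
        pairs = []
        for enzyme_id, row in table.iterrows():
            for substrate_id, value in row.items():
                pairs.append((str(enzyme_id), str(substrate_id), int(value)))
        return cls(pairs=pairs, provenance=provenance)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "train") -> "PairDataset":
        table = pd.read_csv(path)
        if {"enzyme_id", "substrate_id", "label"} <= set(table.columns):
            return cls.from_long(table, provenance)
        return cls.from_wide(pd.read_csv(path, index_col=0), provenance)

    def to_long(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["enzyme_id", "substrate_id", "label"])

    def to_csv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    classifier: str = "random_forest"
    hyperparams: dict = field(default_factory=dict)
    cv_folds: int = 5
    cv_repeats: int = 20
    n_prediction_runs: int = 100
    base_seed: int = 0
    decision_threshold: float = 0.5
    class_weight: str | None = None  # None or "balanced"
    #: standardise features inside each fit (fitted on the training split
    #: only); essential for the MLP, harmless for the tree models
    scale_features: bool = True

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIERS:
            raise ModelError(
                f"unknown classifier {self.classifier!r}; choose from {CLASSIFIERS}"
            )
        if self.cv_folds < 2:
            raise ModelError("cv_folds must be >= 2")
        if self.n_prediction_runs < 1:
            raise ModelError("n_prediction_runs must be >= 1")

    def echo(self) -> dict:
        return asdict(self)


def run_seeds(base_seed: int, n: int) -> list[int]:
    """Distinct per-run seeds derived deterministically from a base seed."""
    rng = np.random.default_rng(base_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _make_estimator(config: ModelConfig, seed: int):
    hp = dict(config.hyperparams)
    if config.classifier == "decision_tree":
        est = DecisionTreeClassifier(
            random_state=seed, class_weight=config.class_weight, **hp
        )
    elif config.classifier == "random_forest":
        hp.setdefault("n_estimators", 100)
        est = RandomForestClassifier(
            random_state=seed, class_weight=config.class_weight, n_jobs=1, **hp
        )
    else:
        hp.setdefault("hidden_layer_sizes", (100,))
        hp.setdefault("activation", "relu")
        hp.setdefault("solver", "adam")
        hp.setdefault("early_stopping", True)
        hp.setdefault("n_iter_no_change", 10)
        hp.setdefault("max_iter", 500)
        est = MLPClassifier(random_state=seed, **hp)
    if config.scale_features:
        return make_pipeline(StandardScaler(), est)
    return est


def _design(
    dataset: PairDataset,
    features: PairFeatureSet | Mapping[tuple[str, str], np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    rows, y = [], []
    for enzyme_id, substrate_id, label in dataset.pairs:
        key = (enzyme_id, substrate_id)
        if key not in features:
            raise ModelError(f"no feature vector for pair {key}")
        rows.append(features[key])
        y.append(label)
    return np.asarray(rows, dtype=np.float64), np.asarray(y, dtype=np.int64)


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------

def train_classifier(
    dataset: PairDataset,
    features: PairFeatureSet | Mapping[tuple[str, str], np.ndarray],
    config: ModelConfig,
    seed: int,
):
    """Fit one classifier on the full dataset; deterministic given seed."""
    X, y = _design(dataset, features)
    if len(np.unique(y)) < 2:
        raise ModelError("dataset contains a single class; nothing to learn")
    est = _make_estimator(config, seed)
    est.fit(X, y)
    return est


@dataclass
class EvaluationReport:
    per_run_accuracy: list[float]
    per_run_f1: list[float]
    seeds: list[int]
    pooled_confusion: list[list[int]]  # [[TN, FP], [FN, TP]]
    config: dict
    note: str = ""

    @property
    def n_runs(self) -> int:
        return len(self.per_run_accuracy)

    @property
    def accuracy_mean(self) -> float:
        return float(np.mean(self.per_run_accuracy))

    @property
    def accuracy_sd(self) -> float:
        return float(np.std(self.per_run_accuracy, ddof=1)) if self.n_runs > 1 else 0.0

    @property
    def f1_mean(self) -> float:
        return float(np.mean(self.per_run_f1))

    @property
    def f1_sd(self) -> float:
        return float(np.std(self.per_run_f1, ddof=1)) if self.n_runs > 1 else 0.0

    def summary(self) -> str:
        return (
            f"accuracy {100 * self.accuracy_mean:.0f} ± {100 * self.accuracy_sd:.0f}%, "
            f"F1 score {self.f1_mean:.2f} ± {self.f1_sd:.2f}"
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "per_run_accuracy": self.per_run_accuracy,
            "per_run_f1": self.per_run_f1,
            "seeds": self.seeds,
            "pooled_confusion": self.pooled_confusion,
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "f1_mean": self.f1_mean,
            "f1_sd": self.f1_sd,
            "config": self.config,
            "note": self.note,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def cross_validate(
    dataset: PairDataset,
    features: PairFeatureSet | Mapping[tuple[str, str], np.ndarray],
    config: ModelConfig,
) -> EvaluationReport:
    """Seed-repeated stratified k-fold cross-validation.

    Each of ``cv_repeats`` runs shuffles the data with its own seed,
    performs stratified ``cv_folds``-fold CV and scores the pooled
    out-of-fold predictions; the variability axis of the reported sd is
    therefore across repeats.
    """
    X, y = _design(dataset, features)
    if len(y) < config.cv_folds:
        raise ModelError("dataset smaller than the number of folds")
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < config.cv_folds:
        raise ModelError(
            f"minority class has {class_counts.min()} members, fewer than "
            f"{config.cv_folds} folds: stratification would leave a fold "
            "without both classes"
        )
    seeds = run_seeds(config.base_seed, config.cv_repeats)
    per_acc, per_f1 = [], []
    pooled = np.zeros((2, 2), dtype=np.int64)
    for seed in seeds:
        splitter = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
        pred = np.empty_like(y)
        for fold_i, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
            est = _make_estimator(config, seed + fold_i)
            est.fit(X[train_idx], y[train_idx])
            pred[test_idx] = est.predict(X[test_idx])
        per_acc.append(float(accuracy_score(y, pred)))
        per_f1.append(float(f1_score(y, pred, pos_label=1, zero_division=0)))
        pooled += confusion_matrix(y, pred, labels=[0, 1])
    return EvaluationReport(
        per_run_accuracy=per_acc,
        per_run_f1=per_f1,
        seeds=seeds,
        pooled_confusion=pooled.tolist(),
        config=config.echo(),
        note="cv: sd across repeats of stratified k-fold",
    )


def compare_models(report_a: EvaluationReport, report_b: EvaluationReport, alpha: float = 0.05) -> dict:
    """Paired two-sided test on per-run F1 between two matched reports.

    Wilcoxon signed-rank (zero-split handling of ties) for >= 6 runs, a
    paired t-test below that.  Reports must share run count and seeds so
    the pairing is meaningful.
    """
    if report_a.n_runs != report_b.n_runs:
        raise ModelError("reports have different run counts")
    if report_a.seeds != report_b.seeds:
        raise ModelError("reports were produced with different seed lists")
    a = np.asarray(report_a.per_run_f1)
    b = np.asarray(report_b.per_run_f1)
    diff = a - b
    if np.allclose(diff, 0.0):
        statistic, p_value = 0.0, 1.0
    elif len(diff) < 6:
        statistic, p_value = stats.ttest_rel(a, b)
    else:
        statistic, p_value = stats.wilcoxon(a, b, zero_method="zsplit", alternative="two-sided")
    return {
        "statistic": float(statistic),
        "p_value": float(p_value),
        "significant": bool(p_value < alpha),
        "alpha": alpha,
        "n_runs": report_a.n_runs,
    }


# ---------------------------------------------------------------------------
# deployment
# ---------------------------------------------------------------------------

@dataclass
class PredictionMatrix:
    mean_probability: pd.DataFrame  # enzymes x substrates
    binary_call: pd.DataFrame
    n_runs: int
    decision_threshold: float

    def to_csv(self, prob_path: str | Path, call_path: str | Path) -> None:
        self.mean_probability.to_csv(prob_path, float_format="%.6f")
        self.binary_call.to_csv(call_path)


def predict_matrix(
    dataset: PairDataset,
    features: PairFeatureSet | Mapping[tuple[str, str], np.ndarray],
    config: ModelConfig,
    target_features: PairFeatureSet | Mapping[tuple[str, str], np.ndarray],
    target_enzymes: Sequence[str],
    target_substrates: Sequence[str],
) -> PredictionMatrix:
    """Seed-averaged activity probabilities for a target enzyme x substrate grid.

    ``n_prediction_runs`` models are trained on the full training set with
    distinct seeds; their predicted probabilities are averaged per pair and
    binarised at the decision threshold.
    """
    _check_tags(features, target_features)
    target_pairs = [(e, s) for e in target_enzymes for s in target_substrates]
    rows = []
    for key in target_pairs:
        if key not in target_features:
            raise ModelError(f"no feature vector for target pair {key}")
        rows.append(target_features[key])
    X_target = np.asarray(rows, dtype=np.float64)
    seeds = run_seeds(config.base_seed, config.n_prediction_runs)
    prob_sum = np.zeros(len(target_pairs))
    for seed in seeds:
        est = train_classifier(dataset, features, config, seed)
        positive = list(est.classes_).index(1)
        prob_sum += est.predict_proba(X_target)[:, positive]
    mean_prob = prob_sum / config.n_prediction_runs
    grid = pd.DataFrame(
        mean_prob.reshape(len(target_enzymes), len(target_substrates)),
        index=list(target_enzymes),
        columns=list(target_substrates),
    )
    calls = (grid >= config.decision_threshold).astype(int)
    return PredictionMatrix(
        mean_probability=grid,
        binary_call=calls,
        n_runs=config.n_prediction_runs,
        decision_threshold=config.decision_threshold,
    )


def evaluate_external(
    training: PairDataset,
    training_features: PairFeatureSet | Mapping[tuple[str, str], np.ndarray],
    external: PairDataset,
    external_features: PairFeatureSet | Mapping[tuple[str, str], np.ndarray],
    config: ModelConfig,
) -> EvaluationReport:
    """Train on the full training set (repeated over seeds), score an
    external dataset; mean +/- sd across the seeded runs."""
    _check_tags(training_features, external_features)
    X_ext, y_ext = _design(external, external_features)
    seeds = run_seeds(config.base_seed, config.cv_repeats)
    per_acc, per_f1 = [], []
    pooled = np.zeros((2, 2), dtype=np.int64)
    for seed in seeds:
        est = train_classifier(training, training_features, config, seed)
        pred = est.predict(X_ext)
        per_acc.append(float(accuracy_score(y_ext, pred)))
        per_f1.append(float(f1_score(y_ext, pred, pos_label=1, zero_division=0)))
        pooled += confusion_matrix(y_ext, pred, labels=[0, 1])
    return EvaluationReport(
        per_run_accuracy=per_acc,
        per_run_f1=per_f1,
        seeds=seeds,
        pooled_confusion=pooled.tolist(),
        config=config.echo(),
        note=f"external evaluation on {external.provenance!r} set; sd across seeded runs",
    )


def _check_tags(a, b) -> None:
    if isinstance(a, PairFeatureSet) and isinstance(b, PairFeatureSet):
        if not a.compatible_with(b):
            raise ModelError(
                "feature sets were computed under different settings: "
                f"({a.embedder_tag}, {a.fingerprint_type}, {a.fingerprint_params}) vs "
                f"({b.embedder_tag}, {b.fingerprint_type}, {b.fingerprint_params})"
            )
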