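"""Classifier training, cross-validation, comparison, prediction matrices."""

import numpy as np
import pandas as pd
import pytest

from t3pks.model import (
    EvaluationReport,
    ModelConfig,
    ModelError,
    PairDataset,
    compare_models,
    cross_validate,
    evaluate_external,
    predict_matrix,
    run_seeds,
    train_classifier,
)

# --- datasets ---------------------------------------------------------------

def test_labels_must_be_binary():
    with pytest.raises(ModelError, match="label"):
        PairDataset(pairs=[("e", "s", 2)])


def test_duplicate_pairs_rejected():
    with pytest.raises(ModelError, match="duplicate"):
        PairDataset(pairs=[("e", "s", 1), ("e", "s", 0)])


def test_active_fraction_and_round_trip(tmp_path):
    dataset = PairDataset(pairs=[("e1", "s1", 1), ("e1", "s2", 0), ("e2", "s1", 1)])
    assert dataset.active_fraction == pytest.approx(2 / 3)
    path = tmp_path / "pairs.csv"
    dataset.to_csv(path)
    back = PairDataset.from_csv(path)
    assert back.pairs == dataset.pairs


def test_wide_format_parsing():
    wide = pd.DataFrame([[1, 0], [0, 1]], index=["e1", "e2"], columns=["s1", "s2"])
    dataset = PairDataset.from_wide(wide)
    assert len(dataset) == 4
    assert dataset.active_fraction == 0.5


# --- training ---------------------------------------------------------------

def _toy_features(n_enzymes=8, n_substrates=6, seed=0):
    """Pair features where the label is a linear rule on one coordinate."""
    rng = np.random.default_rng(seed)
    feats, pairs = {}, []
    for e in range(n_enzymes):
        for s in range(n_substrates):
            vec = rng.normal(size=12)
            vec[0] = 1.0 if (e + s) % 2 else -1.0  # separating coordinate
            feats[(f"e{e}", f"s{s}")] = vec
            pairs.append((f"e{e}", f"s{s}", int(vec[0] > 0)))
    return PairDataset(pairs=pairs), feats


def test_separable_data_trains_to_perfect_accuracy():
    dataset, feats = _toy_features()
    # early stopping off: with 48 samples the validation split would
    # otherwise halt the fit before the separating rule is learned
    config = ModelConfig(classifier="mlp", hyperparams={"early_stopping": False})
    est = train_classifier(dataset, feats, config, seed=0)
    X = np.array([feats[(e, s)] for e, s, _ in dataset.pairs])
    assert (est.predict(X) == dataset.labels).mean() == 1.0


def test_constant_features_predict_base_rate():
    pairs = [(f"e{k}", "s", int(k < 7)) for k in range(10)]
    feats = {(f"e{k}", "s"): np.ones(4) for k in range(10)}
    dataset = PairDataset(pairs=pairs)
    est = train_classifier(dataset, feats, ModelConfig(classifier="random_forest"), seed=1)
    prob = est.predict_proba(np.ones((1, 4)))[0, list(est.classes_).index(1)]
    assert prob == pytest.approx(0.7, abs=0.1)  # prevalence 7/10


def test_same_seed_same_predictions():
    dataset, feats = _toy_features()
    X = np.array([feats[(e, s)] for e, s, _ in dataset.pairs])
    p1 = train_classifier(dataset, feats, ModelConfig(classifier="mlp"), 7).predict_proba(X)
    p2 = train_classifier(dataset, feats, ModelConfig(classifier="mlp"), 7).predict_proba(X)
    np.testing.assert_array_equal(p1, p2)


def test_single_class_dataset_rejected():
    pairs = [(f"e{k}", "s", 1) for k in range(6)]
    feats = {(f"e{k}", "s"): np.ones(3) for k in range(6)}
    with pytest.raises(ModelError, match="single class"):
        train_classifier(PairDataset(pairs=pairs), feats, ModelConfig(), 0)


def test_missing_feature_vector_rejected():
    dataset = PairDataset(pairs=[("e", "s", 1), ("e2", "s", 0)])
    with pytest.raises(ModelError, match="no feature vector"):
        train_classifier(dataset, {("e", "s"): np.ones(3)}, ModelConfig(), 0)


# --- cross-validation -------------------------------------------------------

@pytest.fixture(scope="module")
def toy_cv():
    dataset, feats = _toy_features(n_enzymes=10, n_substrates=6, seed=3)
    config = ModelConfig(classifier="decision_tree", cv_folds=5, cv_repeats=8, base_seed=5)
    return dataset, feats, config


def test_report_means_match_per_run_values(toy_cv):
    dataset, feats, config = toy_cv
    report = cross_validate(dataset, feats, config)
    assert report.accuracy_mean == pytest.approx(np.mean(report.per_run_accuracy))
    assert report.f1_sd == pytest.approx(np.std(report.per_run_f1, ddof=1))
    assert report.n_runs == 8
    assert all(0 <= v <= 1 for v in report.per_run_accuracy + report.per_run_f1)


def test_cv_is_deterministic(toy_cv):
    dataset, feats, config = toy_cv
    a = cross_validate(dataset, feats, config)
    b = cross_validate(dataset, feats, config)
    assert a.per_run_f1 == b.per_run_f1 and a.seeds == b.seeds


def test_shuffled_labels_score_near_chance(toy_cv):
    dataset, feats, _ = toy_cv
    rng = np.random.default_rng(0)
    labels = dataset.labels.copy()
    rng.shuffle(labels)
    shuffled = PairDataset(
        pairs=[(e, s, int(l)) for (e, s, _), l in zip(dataset.pairs, labels)]
    )
    config = ModelConfig(classifier="decision_tree", cv_folds=5, cv_repeats=10, base_seed=1)
    report = cross_validate(shuffled, feats, config)
    prevalence = max(shuffled.active_fraction, 1 - shuffled.active_fraction)
    sd = max(report.accuracy_sd, 1e-3)
    assert abs(report.accuracy_mean - prevalence) <= 3 * sd + 0.05


def test_minority_class_smaller_than_folds_rejected():
    pairs = [(f"e{k}", "s", int(k < 2)) for k in range(20)]
    feats = {(f"e{k}", "s"): np.ones(3) for k in range(20)}
    with pytest.raises(ModelError, match="minority class"):
        cross_validate(PairDataset(pairs=pairs), feats, ModelConfig(cv_folds=5))


# --- model comparison -------------------------------------------------------

def _report(f1s, seeds=None):
    seeds = seeds if seeds is not None else list(range(len(f1s)))
    return EvaluationReport(
        per_run_accuracy=list(f1s),
        per_run_f1=list(f1s),
        seeds=seeds,
        pooled_confusion=[[1, 0], [0, 1]],
        config={},
    )


def test_compare_with_itself_is_not_significant():
    report = _report([0.8, 0.82, 0.79, 0.81, 0.8, 0.83])
    result = compare_models(report, report)
    assert result["p_value"] == 1.0
    assert not result["significant"]


def test_clearly_different_reports_are_significant():
    a = _report([0.90, 0.91, 0.89, 0.90, 0.92])
    b = _report([0.50, 0.52, 0.49, 0.51, 0.50])
    result = compare_models(a, b)  # 5 runs -> paired t-test path
    assert result["significant"]


def test_wilcoxon_path_detects_consistent_gap():
    rng = np.random.default_rng(1)
    base = rng.uniform(0.7, 0.8, size=12)
    a = _report(list(base + 0.1), seeds=list(range(12)))
    b = _report(list(base), seeds=list(range(12)))
    assert compare_models(a, b)["significant"]


def test_mismatched_runs_rejected():
    with pytest.raises(ModelError, match="run counts"):
        compare_models(_report([0.8] * 4), _report([0.8] * 5))
    with pytest.raises(ModelError, match="seed"):
        compare_models(_report([0.8] * 4), _report([0.8] * 4, seeds=[9, 8, 7, 6]))


# --- prediction matrices ----------------------------------------------------

def test_prediction_matrix_reproducible_and_threshold_consistent():
    dataset, feats = _toy_features(n_enzymes=6, n_substrates=4, seed=9)
    config = ModelConfig(classifier="random_forest", n_prediction_runs=3, base_seed=2)
    enzymes = dataset.enzyme_ids
    substrates = dataset.substrate_ids
    m1 = predict_matrix(dataset, feats, config, feats, enzymes, substrates)
    m2 = predict_matrix(dataset, feats, config, feats, enzymes, substrates)
    pd.testing.assert_frame_equal(m1.mean_probability, m2.mean_probability)
    assert ((m1.mean_probability.to_numpy() >= 0) & (m1.mean_probability.to_numpy() <= 1)).all()
    expected = (m1.mean_probability >= config.decision_threshold).astype(int)
    pd.testing.assert_frame_equal(m1.binary_call, expected)


def test_external_equal_to_training_matches_resubstitution():
    dataset, feats = _toy_features(n_enzymes=8, n_substrates=5, seed=4)
    config = ModelConfig(classifier="random_forest", cv_repeats=3, base_seed=6)
    report = evaluate_external(dataset, feats, dataset, feats, config)
    # expressive model resubstitutes perfectly on separable data
    assert report.accuracy_mean == pytest.approx(1.0)
    assert report.f1_mean == pytest.approx(1.0)


def test_all_positive_external_accuracy_equals_recall():
    dataset, feats = _toy_features(n_enzymes=8, n_substrates=5, seed=4)
    positives = [(e, s, l) for e, s, l in dataset.pairs if l == 1]
    external = PairDataset(pairs=positives, provenance="external")
    config = ModelConfig(classifier="decision_tree", cv_repeats=2, base_seed=3)
    report = evaluate_external(dataset, feats, external, feats, config)
    (tn, fp), (fn, tp) = report.pooled_confusion
    assert tn == 0 and fp == 0
    assert report.accuracy_mean == pytest.approx(tp / (tp + fn))


def test_feature_tag_mismatch_rejected(study_families, study_spec):
    from t3pks.featurize import featurize_pairs

    seqs = study_families[:4]
    panel = study_spec.substrate_panel.head(3)
    maccs = featurize_pairs(seqs, panel, fingerprint_type="maccs")
    ecfp = featurize_pairs(seqs, panel, fingerprint_type="ecfp")
    dataset = PairDataset(
        pairs=[(s.id, p, (i + j) % 2) for i, s in enumerate(seqs)
               for j, p in enumerate(panel["substrate_id"])]
    )
    with pytest.raises(ModelError, match="different settings"):
        evaluate_external(dataset, maccs, dataset, ecfp, ModelConfig(cv_repeats=2))


def test_run_seeds_are_deterministic_and_bounded():
    seeds = run_seeds(13, 100)
    assert seeds == run_seeds(13, 100)
    assert len(set(seeds)) == 100
    assert all(0 <= s < 2**31 for s in seeds)
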