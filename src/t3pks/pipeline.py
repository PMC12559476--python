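"""End-to-end pipeline driver: mine -> cluster -> sites -> featurize ->
train -> predict, with a manifest of every artefact produced.

A single global seed fans out to per-stage seeds by stable hashing of
(global_seed, stage_name), so enabling or disabling one stage never
shifts another stage's randomness.  All outputs are plain text (FASTA,
TSV/CSV, JSON, GraphML) with fixed float formatting, which makes
"rerun with the same config is byte-identical" a checkable contract: the
manifest records a sha256 checksum per output file.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import active_site, featurize, mining, ssn, synthetic
from .model import ModelConfig, PairDataset, cross_validate, predict_matrix
from .records import SequenceRecord, read_fasta, write_fasta


class PipelineError(ValueError):
    pass


def stage_seed(global_seed: int, stage_name: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage_name}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateStage(_Strict):
    n_families: int = 3
    family_sizes: list[int] = [11, 10, 10]
    seq_length: int = 380
    within_family_mutation_rate: float = 0.05
    between_family_divergence: float = 0.41
    label_noise_rate: float = 0.0
    n_decoys: int = 10


class MineStage(_Strict):
    queries: Optional[str] = None  # FASTA path; default: simulated queries
    proteome: Optional[str] = None
    min_identity: float = 0.3
    min_coverage: float = 0.5


class SsnStage(_Strict):
    sequences: Optional[str] = None  # default: mined (or simulated) sequences
    cutoff: float = 0.8
    repnode_threshold: float = 0.95


class SitesStage(_Strict):
    sequences: Optional[str] = None
    reference: Optional[str] = None  # FASTA with one reference record


class FeaturizeStage(_Strict):
    sequences: Optional[str] = None
    substrates: Optional[str] = None  # CSV substrate table
    embedder: str = "fallback-physchem"
    fingerprint: str = "maccs"
    radius: int = 2
    n_bits: int = 2048


class TrainStage(_Strict):
    pairs: Optional[str] = None  # CSV; default: simulated activity
    classifier: str = "mlp"
    cv_folds: int = 5
    cv_repeats: int = 20


class PredictStage(_Strict):
    n_prediction_runs: int = 100
    decision_threshold: float = 0.5


class PipelineConfig(_Strict):
    """Strict-schema pipeline configuration; a stage runs iff its block is
    present.  Round-trips through YAML identically."""

    seed: int = 0
    outdir: str = "t3pks_out"
    simulate: Optional[SimulateStage] = None
    mine: Optional[MineStage] = None
    ssn: Optional[SsnStage] = None
    sites: Optional[SitesStage] = None
    featurize: Optional[FeaturizeStage] = None
    train: Optional[TrainStage] = None
    predict: Optional[PredictStage] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(exclude_none=True), sort_keys=True)
        )


STAGE_ORDER = ("simulate", "mine", "ssn", "sites", "featurize", "train", "predict")


class _Run:
    """Mutable state threaded through the stages of one pipeline run."""

    def __init__(self, config: PipelineConfig, outdir: Path):
        self.config = config
        self.outdir = outdir
        self.manifest: list[dict[str, Any]] = []
        self.sequences: list[SequenceRecord] | None = None
        self.queries: list[SequenceRecord] | None = None
        self.proteome: list[SequenceRecord] | None = None
        self.reference: SequenceRecord | None = None
        self.substrates: pd.DataFrame | None = None
        self.dataset: PairDataset | None = None
        self.features: featurize.PairFeatureSet | None = None
        self.model_config: ModelConfig | None = None

    def record(self, name: str, seed: int, params: dict, inputs: list[str], outputs: list[Path]) -> None:
        self.manifest.append(
            {
                "stage": name,
                "seed": seed,
                "parameters": params,
                "inputs": sorted(inputs),
                "outputs": [
                    {"path": str(p.relative_to(self.outdir)), "sha256": _sha256(p)}
                    for p in sorted(outputs)
                ],
            }
        )


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute the enabled stages in order and write a manifest.

    Returns the manifest (also written to ``manifest.json``): per stage
    the parameters, derived seed, inputs and sha256-checksummed outputs.
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = _Run(config, outdir)
    for name in STAGE_ORDER:
        block = getattr(config, name)
        if block is None:
            continue
        _STAGES[name](run, block, stage_seed(config.seed, name))
    manifest = {"global_seed": config.seed, "stages": run.manifest}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

_CSV_FLOAT = "%.10g"


def _stage_simulate(run: _Run, cfg: SimulateStage, seed: int) -> None:
    spec = synthetic.SyntheticSpec(
        seed=seed,
        n_families=cfg.n_families,
        family_sizes=cfg.family_sizes,
        seq_length=cfg.seq_length,
        within_family_mutation_rate=cfg.within_family_mutation_rate,
        between_family_divergence=cfg.between_family_divergence,
        label_noise_rate=cfg.label_noise_rate,
    )
    families = synthetic.generate_families(spec)
    decoys = synthetic.generate_decoys(cfg.n_decoys, cfg.seq_length, seed + 1)
    activity = synthetic.generate_activity(spec, families)
    out = run.outdir
    write_fasta(families, out / "enzymes.faa")
    write_fasta(families + decoys, out / "proteome.faa")
    # family ancestors are unknown to downstream stages; one member per
    # family serves as the mining query set
    queries = [rec for rec in families if rec.id.endswith("_s01")]
    write_fasta(queries, out / "queries.faa")
    spec.substrate_panel.to_csv(out / "substrates.csv", index=False)
    activity.observed.to_csv(out / "pairs.csv")
    activity.truth.to_csv(out / "pairs_truth.csv")
    meta = pd.DataFrame(
        [{"id": r.id, "family": r.metadata["family"]} for r in families + decoys]
    )
    meta.to_csv(out / "meta.tsv", sep="\t", index=False)

    run.sequences, run.queries, run.proteome = families, queries, families + decoys
    run.substrates = spec.substrate_panel
    run.dataset = activity.observed
    run.reference = families[0]
    run.record(
        "simulate", seed, cfg.model_dump(), [],
        [out / f for f in (
            "enzymes.faa", "proteome.faa", "queries.faa", "substrates.csv",
            "pairs.csv", "pairs_truth.csv", "meta.tsv",
        )],
    )


def _need(value, stage: str, what: str, enable: str):
    if value is None:
        raise PipelineError(
            f"stage {stage!r} needs {what}: provide a path in the config or "
            f"enable the {enable!r} stage"
        )
    return value


def _stage_mine(run: _Run, cfg: MineStage, seed: int) -> None:
    inputs = []
    if cfg.queries:
        queries = read_fasta(cfg.queries)
        inputs.append(cfg.queries)
    else:
        queries = _need(run.queries, "mine", "a query set", "simulate")
    if cfg.proteome:
        proteome = read_fasta(cfg.proteome)
        inputs.append(cfg.proteome)
    else:
        proteome = _need(run.proteome, "mine", "a proteome", "simulate")
    hits = mining.mine_candidates(queries, proteome, cfg.min_identity, cfg.min_coverage)
    table = mining.hits_to_table(hits)
    out = run.outdir
    table.to_csv(out / "hits.tsv", sep="\t", index=False, float_format=_CSV_FLOAT)
    by_id = {rec.id: rec for rec in proteome}
    mined = mining.merge_dereplicate([[by_id[h.target_id] for h in hits]]) if hits else []
    write_fasta(mined, out / "mined.faa")
    run.sequences = mined or run.sequences
    run.record("mine", seed, cfg.model_dump(), inputs, [out / "hits.tsv", out / "mined.faa"])


def _stage_ssn(run: _Run, cfg: SsnStage, seed: int) -> None:
    inputs = []
    if cfg.sequences:
        seqs = read_fasta(cfg.sequences)
        inputs.append(cfg.sequences)
    else:
        seqs = _need(run.sequences, "ssn", "sequences", "simulate")
    network = ssn.build_network(seqs, cutoff=cfg.cutoff, repnode_threshold=cfg.repnode_threshold)
    out = run.outdir
    ssn.to_edge_table(network).to_csv(
        out / "edges.tsv", sep="\t", index=False, float_format=_CSV_FLOAT
    )
    ssn.to_node_table(network).to_csv(out / "nodes.tsv", sep="\t", index=False)
    ssn.to_graphml(network, str(out / "network.graphml"))
    run.record(
        "ssn", seed, cfg.model_dump(), inputs,
        [out / "edges.tsv", out / "nodes.tsv", out / "network.graphml"],
    )


def _stage_sites(run: _Run, cfg: SitesStage, seed: int) -> None:
    inputs = []
    if cfg.sequences:
        seqs = read_fasta(cfg.sequences)
        inputs.append(cfg.sequences)
    else:
        seqs = _need(run.sequences, "sites", "sequences", "simulate")
    if cfg.reference:
        reference = read_fasta(cfg.reference)[0]
        inputs.append(cfg.reference)
    else:
        reference = _need(run.reference, "sites", "a reference sequence", "simulate")
    posmap = active_site.ActiveSitePositionMap(
        reference=reference,
        positions=[
            active_site.SitePosition(ref_position=p, label=lab, expected_residue=exp)
            for p, lab, exp in active_site.DEFAULT_POSITIONS
            if p <= len(reference)
        ],
    )
    profiles = active_site.extract_profiles(seqs, posmap)
    logo = active_site.residue_logo(profiles)
    flags = active_site.flag_triad_all(profiles)
    out = run.outdir
    profiles.to_csv(out / "sites.tsv", sep="\t")
    logo.to_csv(out / "logo.tsv", sep="\t", float_format=_CSV_FLOAT)
    pd.DataFrame(
        [{"id": k, "substitutions": ";".join(v)} for k, v in sorted(flags.items())]
    ).to_csv(out / "triad_flags.tsv", sep="\t", index=False)
    run.record(
        "sites", seed, cfg.model_dump(), inputs,
        [out / "sites.tsv", out / "logo.tsv", out / "triad_flags.tsv"],
    )


def _stage_featurize(run: _Run, cfg: FeaturizeStage, seed: int) -> None:
    inputs = []
    if cfg.sequences:
        seqs = read_fasta(cfg.sequences)
        inputs.append(cfg.sequences)
    else:
        seqs = _need(run.sequences, "featurize", "sequences", "simulate")
    if cfg.substrates:
        substrates = featurize.read_substrates(cfg.substrates)
        inputs.append(cfg.substrates)
    else:
        substrates = _need(run.substrates, "featurize", "a substrate table", "simulate")
    features = featurize.featurize_pairs(
        seqs, substrates,
        embedder=cfg.embedder,
        fingerprint_type=cfg.fingerprint,
        radius=cfg.radius,
        n_bits=cfg.n_bits,
    )
    out = run.outdir
    rows = [
        {"enzyme_id": e, "substrate_id": s,
         **{f"f{k}": v for k, v in enumerate(vec)}}
        for (e, s), vec in sorted(features.vectors.items())
    ]
    pd.DataFrame(rows).to_csv(
        out / "pair_features.csv", index=False, float_format=_CSV_FLOAT
    )
    run.features = features
    run.record("featurize", seed, cfg.model_dump(), inputs, [out / "pair_features.csv"])


def _stage_train(run: _Run, cfg: TrainStage, seed: int) -> None:
    inputs = []
    if cfg.pairs:
        dataset = PairDataset.from_csv(cfg.pairs)
        inputs.append(cfg.pairs)
    else:
        dataset = _need(run.dataset, "train", "an activity dataset", "simulate")
    features = _need(run.features, "train", "pair features", "featurize")
    config = ModelConfig(
        classifier=cfg.classifier,
        cv_folds=cfg.cv_folds,
        cv_repeats=cfg.cv_repeats,
        base_seed=seed,
    )
    report = cross_validate(dataset, features, config)
    out = run.outdir
    report.to_json(out / "report.json")
    run.dataset = dataset
    run.model_config = config
    run.record("train", seed, cfg.model_dump(), inputs, [out / "report.json"])


def _stage_predict(run: _Run, cfg: PredictStage, seed: int) -> None:
    if run.model_config is None:
        raise PipelineError(
            "stage 'predict' needs a trained model configuration: enable the "
            "'train' stage"
        )
    dataset = run.dataset
    features = _need(run.features, "predict", "pair features", "featurize")
    config = ModelConfig(
        classifier=run.model_config.classifier,
        cv_folds=run.model_config.cv_folds,
        cv_repeats=run.model_config.cv_repeats,
        n_prediction_runs=cfg.n_prediction_runs,
        decision_threshold=cfg.decision_threshold,
        base_seed=seed,
    )
    enzymes = dataset.enzyme_ids
    substrates = dataset.substrate_ids
    matrix = predict_matrix(dataset, features, config, features, enzymes, substrates)
    out = run.outdir
    matrix.to_csv(out / "predictions.csv", out / "calls.csv")
    run.record(
        "predict", seed, cfg.model_dump(), [],
        [out / "predictions.csv", out / "calls.csv"],
    )


_STAGES = {
    "simulate": _stage_simulate,
    "mine": _stage_mine,
    "ssn": _stage_ssn,
    "sites": _stage_sites,
    "featurize": _stage_featurize,
    "train": _stage_train,
    "predict": _stage_predict,
}
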