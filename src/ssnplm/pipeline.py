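"""End-to-end orchestration: simulate/load -> reduce -> SSN -> labels ->
MLM pre-train -> task-train -> evaluate, with one global seed fanned out
deterministically per stage and a machine-readable run manifest."""

from __future__ import annotations

import json
import logging
import platform
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .plm.classifier import ClassifierConfig
from .plm.checkpoint import save_checkpoint
from .plm.splits import SplitSpec
from .plm.train import (
    HEAD_EPOCHS_DEFAULT,
    HEAD_LR_DEFAULT,
    OptimSettings,
    classifier_split_ids,
    predict,
    pretrain_mlm,
    train_classifier,
)
from .nn.encoder import EncoderConfig
from .seqio import SequenceSet, read_fasta, write_fasta
from .similarity import RedundancyParams, reduce_redundancy
from .ssn import SSNParams, build_ssn, export_graph, find_clusters, top_k_labels
from .synthetic import FamilyConfig, generate_families, write_truth_tsv

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, from one global seed."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2**31)


@dataclass
class PipelineConfig:
    """Everything one run needs; every stochastic stage derives its seed
    from ``seed`` via :func:`stage_seed`."""

    out_dir: Path
    input_fasta: Path | None = None
    simulate: FamilyConfig | None = None
    redundancy: RedundancyParams = field(default_factory=RedundancyParams)
    ssn: SSNParams = field(default_factory=SSNParams)
    top_k: int = 45
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    pretrain_split: float = 0.95
    train_split: float = 0.80
    pretrain_settings: OptimSettings = field(default_factory=OptimSettings)
    train_settings: OptimSettings = field(
        default_factory=lambda: OptimSettings(
            epochs=HEAD_EPOCHS_DEFAULT, learning_rate=HEAD_LR_DEFAULT
        )
    )
    freeze_backbone: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_fasta is None) == (self.simulate is None):
            raise ValueError("provide exactly one of input_fasta or simulate")


class StageError(RuntimeError):
    """Wraps a failure with the name of the pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapped
    return deco


def run_semisupervised(cfg: PipelineConfig) -> dict:
    """Execute the whole workflow; returns the run report dict (also
    written to ``out_dir/report.json``) with an EvalReport inside."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    seqs, truth = _load_or_simulate(cfg, out)
    reps, membership = _reduce(cfg, seqs, out)
    graph, partition = _network(cfg, reps, out)
    if len(partition.clusters) < cfg.top_k:
        k = len(partition.clusters)
        if k == 0:
            raise StageError("labels", ValueError("no clusters of size >= 2; "
                                                  "lower the identity threshold"))
        logger.warning("only %d clusters available; using k=%d", k, k)
    k = min(cfg.top_k, len(partition.clusters))
    labels = top_k_labels(partition, k)
    _write_labels(labels, out / "labels.tsv")

    encoder, mlm_head, tok, history = _pretrain(cfg, seqs)
    (out / "pretrain_history.json").write_text(json.dumps(history, indent=1))
    save_checkpoint(out / "encoder.npz", encoder, tok, mlm_head=mlm_head)

    head, report = _task_train(cfg, encoder, labels, reps, tok, k)
    save_checkpoint(out / "model.npz", encoder, tok, head=head, mlm_head=mlm_head)

    labelled_ids = set(labels.labels)
    labelled_seqs = SequenceSet([s for s in reps if s.id in labelled_ids])
    preds = predict(encoder, head, labelled_seqs, tok)
    with open(out / "predictions.tsv", "w") as fh:
        fh.write("id\tpredicted_cluster\tmax_probability\n")
        for p in preds:
            fh.write(f"{p.id}\t{p.predicted_cluster}\t{p.probabilities.max():.6f}\n")

    run_report = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "stage_seeds": {s: stage_seed(cfg.seed, s)
                        for s in ("simulate", "pretrain", "train")},
        "n_sequences": len(seqs),
        "n_representatives": len(reps),
        "n_edges": graph.n_edges,
        "n_clusters": len(partition.clusters),
        "n_singletons": len(partition.singletons),
        "k": k,
        "n_labelled": len(labels),
        "eval": {"n": report.n, "accuracy": report.accuracy, "ece": report.ece},
        "test_ids": classifier_split_ids(
            labels, reps, SplitSpec(cfg.train_split, seed=stage_seed(cfg.seed, "train"))
        )[1],
        "params": {
            "redundancy_threshold": cfg.redundancy.threshold,
            "identity_threshold": cfg.ssn.identity_threshold,
            "encoder": cfg.encoder.to_dict(),
            "classifier": cfg.classifier.to_dict(),
            "pretrain": vars(cfg.pretrain_settings),
            "train": vars(cfg.train_settings),
            "pretrain_split": cfg.pretrain_split,
            "train_split": cfg.train_split,
            "freeze_backbone": cfg.freeze_backbone,
        },
    }
    (out / "report.json").write_text(json.dumps(run_report, indent=1))
    return run_report


@_stage("input")
def _load_or_simulate(cfg: PipelineConfig, out: Path):
    if cfg.simulate is not None:
        sim = FamilyConfig(
            cfg.simulate.n_families, cfg.simulate.members_per_family,
            cfg.simulate.length, cfg.simulate.p_sub,
            seed=stage_seed(cfg.seed, "simulate"),
        )
        corpus = generate_families(sim)
        write_fasta(corpus.sequences, out / "corpus.fasta")
        write_truth_tsv(corpus, out / "truth.tsv")
        return corpus.sequences, corpus.truth
    return read_fasta(cfg.input_fasta), None


@_stage("reduce")
def _reduce(cfg: PipelineConfig, seqs, out: Path):
    reps, membership = reduce_redundancy(seqs, cfg.redundancy)
    write_fasta(reps, out / "representatives.fasta")
    with open(out / "membership.tsv", "w") as fh:
        fh.write("id\trepresentative\n")
        for sid, rep in membership.items():
            fh.write(f"{sid}\t{rep}\n")
    return reps, membership


@_stage("ssn")
def _network(cfg: PipelineConfig, reps, out: Path):
    graph = build_ssn(reps, cfg.ssn)
    partition = find_clusters(graph)
    export_graph(graph, partition, out / "network.graphml", format="graphml")
    export_graph(graph, partition, out / "edges.tsv", format="edge-tsv")
    with open(out / "clusters.tsv", "w") as fh:
        fh.write("cluster_id\tsize\tn_edges\tconvergence_ratio\n")
        for c in partition.clusters:
            fh.write(f"{c.cluster_id}\t{c.size}\t{c.n_edges}\t{c.convergence_ratio:.6f}\n")
    return graph, partition


def _write_labels(labels, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tcluster_id\n")
        for sid in sorted(labels.labels):
            fh.write(f"{sid}\t{labels.labels[sid]}\n")


@_stage("pretrain")
def _pretrain(cfg: PipelineConfig, seqs):
    seed = stage_seed(cfg.seed, "pretrain")
    return pretrain_mlm(
        seqs, cfg.encoder,
        split=SplitSpec(cfg.pretrain_split, seed=seed),
        settings=cfg.pretrain_settings, seed=seed,
    )


@_stage("train")
def _task_train(cfg: PipelineConfig, encoder, labels, reps, tok, k: int):
    from .plm.train import build_classifier

    seed = stage_seed(cfg.seed, "train")
    head_cfg = cfg.classifier
    if head_cfg.n_classes != k:
        head_cfg = ClassifierConfig(
            head_cfg.n_attention_layers, head_cfg.n_dense_layers, k,
            head_cfg.d_attn, head_cfg.n_heads, head_cfg.hidden_dims, head_cfg.dropout,
        )
    head = build_classifier(head_cfg, cfg.encoder.d_model, seed=seed)
    return train_classifier(
        encoder, head, labels, seqs=reps,
        split=SplitSpec(cfg.train_split, seed=seed),
        freeze_backbone=cfg.freeze_backbone,
        settings=cfg.train_settings, tok=tok, seed=seed,
    )
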