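"""End-to-end orchestration: variants -> raw sequences -> encoding ->
training -> evaluation -> gene ranking.

One :class:`RunConfig` fixes every input path, the embedding mode
(GERMLINE or CANCER raw sequences), the architecture and optimisation
hyper-parameters, the replicate count and the baselines to compare
against. :func:`run_pipeline` executes the replicate protocol for the
convolutional model and each baseline on identical splits and seeds and
writes metric, confusion, comparison and ranking reports into the run
directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import baselines as bl
from . import evaluation as ev
from . import ranking as rk
from .encoding import EncodedCohort, encode_cohort
from .network import (
    ConvNetClassifier,
    EncoderConfig,
    TrainConfig,
    build_model,
    predict,
    split_dataset,
    train,
)
from .simulate import read_labels
from .variants import (
    DEFAULT_ALLOWED_EFFECTS,
    ReferenceTranscript,
    build_sample_sequences,
    filter_by_effect,
    read_transcript_fasta,
    read_variant_table,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    reference_path: str
    germline_path: str
    somatic_path: str
    labels_path: str
    out_dir: str
    mode: str = "CANCER"  # or GERMLINE
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    replicates: int = 10
    base_seed: int = 0
    ranking_k: int = 20
    baseline_kinds: tuple[str, ...] = ("LR_L1",)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def prepare_dataset(
    reference: list[ReferenceTranscript],
    germline,
    somatic,
    labels: dict[str, str],
    mode: str,
    class_names: list[str] | None = None,
) -> tuple[EncodedCohort, list[str]]:
    """Embed variants per sample and encode the whole cohort.

    Only MODERATE/HIGH variants enter sequence construction. Returns the
    encoded cohort (labels as class indices) and the class-name order.
    """
    germline = filter_by_effect(germline, DEFAULT_ALLOWED_EFFECTS)
    somatic = filter_by_effect(somatic, DEFAULT_ALLOWED_EFFECTS)
    germ_by_sample: dict[str, list] = {}
    som_by_sample: dict[str, list] = {}
    for v in germline:
        germ_by_sample.setdefault(v.sample_id, []).append(v)
    for v in somatic:
        som_by_sample.setdefault(v.sample_id, []).append(v)
    if class_names is None:
        class_names = sorted(set(labels.values()))
    class_index = {c: i for i, c in enumerate(class_names)}
    sample_sets = [
        build_sample_sequences(
            reference,
            germ_by_sample.get(sid, []),
            som_by_sample.get(sid, []),
            mode=mode,
            sample_id=sid,
        )
        for sid in labels
    ]
    cohort = encode_cohort(
        sample_sets, reference, labels={sid: class_index[labels[sid]] for sid in labels}
    )
    return cohort, class_names


@dataclass
class PipelineResult:
    run_dir: Path
    class_names: list[str]
    cnn_summary: ev.ReplicateSummary
    baseline_summaries: dict[str, ev.ReplicateSummary]
    comparison_pvalues: dict[str, float]
    rankings: dict[str, rk.GeneRanking]
    models: list[ConvNetClassifier]


def run_pipeline(config: RunConfig) -> PipelineResult:
    t0 = time.monotonic()
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)

    reference = read_transcript_fasta(config.reference_path)
    germline = read_variant_table(config.germline_path)
    somatic = read_variant_table(config.somatic_path)
    labels = read_labels(config.labels_path)
    logger.info(
        "pipeline %s: %d transcripts, %d samples, mode=%s, seed=%d",
        config.digest(), len(reference), len(labels), config.mode, config.base_seed,
    )

    cohort, class_names = prepare_dataset(
        reference, germline, somatic, labels, config.mode
    )
    k = len(class_names)
    transcripts = [(t.transcript_id, t.codon_count) for t in reference]

    models: list[ConvNetClassifier] = []

    def run_cnn(seed: int):
        train_idx, val_idx, test_idx = split_dataset(
            cohort.n_samples, config.training.split_ratio, seed=seed
        )
        model = build_model(transcripts, config.encoder, class_count=k)
        train(
            model,
            cohort,
            train_idx,
            val_idx,
            dataclasses.replace(config.training, seed=seed),
        )
        _, pred = predict(model, cohort, test_idx)
        models.append(model)
        return cohort.labels[test_idx], pred, {"seed": seed, "test_idx": test_idx}

    class_indices = list(range(k))
    cnn_summary = ev.replicate_experiment(
        run_cnn, class_indices, replicates=config.replicates, base_seed=config.base_seed
    )
    ev.write_metrics_report(cnn_summary, run_dir / "cnn_metrics.tsv")
    ev.write_confusion_report(cnn_summary.mean_confusion, run_dir / "cnn_confusion.tsv")
    for i, model in enumerate(models):
        model.save(run_dir / f"cnn_replicate_{i}.npz")

    # baselines on the same splits and seeds
    count_X = bl.mutation_count_features(
        germline + somatic, reference, list(labels), normalize=True
    ).table.to_numpy()
    mlp_X = (
        bl.mlp_sequence_features(cohort) if "MLP" in config.baseline_kinds else None
    )
    y = cohort.labels

    baseline_summaries: dict[str, ev.ReplicateSummary] = {}
    comparison_pvalues: dict[str, float] = {}
    for kind in config.baseline_kinds:
        X = mlp_X if kind == "MLP" else count_X

        def run_baseline(seed: int, kind=kind, X=X):
            train_idx, _val_idx, test_idx = split_dataset(
                cohort.n_samples, config.training.split_ratio, seed=seed
            )
            _, _, pred = bl.train_baseline(X, y, kind, seed, train_idx, test_idx)
            return y[test_idx], pred, {"seed": seed}

        summary = ev.replicate_experiment(
            run_baseline,
            class_indices,
            replicates=config.replicates,
            base_seed=config.base_seed,
        )
        baseline_summaries[kind] = summary
        comparison_pvalues[kind] = ev.compare_models(
            cnn_summary.accuracies, summary.accuracies
        )
        ev.write_metrics_report(summary, run_dir / f"baseline_{kind}_metrics.tsv")

    with open(run_dir / "comparison.tsv", "w") as fh:
        fh.write("method\tmean_accuracy\tse_accuracy\tp_vs_cnn\n")
        fh.write(
            f"CNN\t{cnn_summary.mean_accuracy:.6f}\t{cnn_summary.se_accuracy:.6f}\t\n"
        )
        for kind, summary in baseline_summaries.items():
            fh.write(
                f"{kind}\t{summary.mean_accuracy:.6f}\t{summary.se_accuracy:.6f}\t"
                f"{comparison_pvalues[kind]:.3e}\n"
            )

    transcript_to_gene = {t.transcript_id: t.gene_symbol for t in reference}
    rankings: dict[str, rk.GeneRanking] = {}
    for c, name in enumerate(class_names):
        ranking = rk.rank_from_models(
            models, c, class_label=name, k=min(config.ranking_k, len(reference))
        )
        rankings[name] = ranking
        rk.write_ranking_report(
            ranking, run_dir / f"ranking_{name}.tsv", transcript_to_gene
        )

    with open(run_dir / "run_manifest.json", "w") as fh:
        json.dump(
            {
                "config": dataclasses.asdict(config),
                "config_digest": config.digest(),
                "class_names": class_names,
                "wall_time_s": round(time.monotonic() - t0, 2),
            },
            fh,
            indent=2,
            default=str,
        )
    return PipelineResult(
        run_dir=run_dir,
        class_names=class_names,
        cnn_summary=cnn_summary,
        baseline_summaries=baseline_summaries,
        comparison_pvalues=comparison_pvalues,
        rankings=rankings,
        models=models,
    )
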