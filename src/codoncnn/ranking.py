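"""Driver-gene prioritization from the fully connected head.

The class head is linear in the concatenated encoder outputs, so the C
weights linking one transcript's encoder block to one class output measure
how much that transcript can move that class's score. Their L1 norm is the
transcript's importance for the class. Because a single training run is
noisy, importance is stabilised across independently seeded replicates:
each replicate contributes its top-k transcripts, and transcripts are
ranked by how many replicates placed them in the top k (replicate-frequency
ranking).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .network import ConvNetClassifier

logger = logging.getLogger(__name__)


@dataclass
class GeneRanking:
    """Replicate-frequency consensus ranking for one class."""

    class_label: str
    per_replicate_top_k: list[list[str]]
    frequency: dict[str, int]
    consensus: list[str]
    mean_scores: dict[str, float] = field(default_factory=dict)

    @property
    def replicates(self) -> int:
        return len(self.per_replicate_top_k)


def transcript_importance(
    model: ConvNetClassifier, class_index: int, norm: str = "l1"
) -> dict[str, float]:
    """Importance of each transcript for one class from the head weights.

    score(t, c) is the L1 norm (or L2, behind the ``norm`` switch) of the C
    head weights linking transcript t's encoder block to class output c.
    """
    if not 0 <= class_index < model.class_count:
        raise ValueError(
            f"class_index {class_index} out of range [0, {model.class_count})"
        )
    if norm not in ("l1", "l2"):
        raise ValueError(f"norm must be 'l1' or 'l2', got {norm!r}")
    scores: dict[str, float] = {}
    for tid in model.transcript_ids:
        block = model.head_block(tid)[:, class_index]
        if norm == "l1":
            scores[tid] = float(np.abs(block).sum())
        else:
            scores[tid] = float(np.sqrt((block**2).sum()))
    return scores


def top_k_per_replicate(scores: dict[str, float], k: int = 20) -> list[str]:
    """The k highest-scoring transcripts, descending.

    Ties are broken by lexicographically ascending transcript_id so the
    result is deterministic.
    """
    if len(scores) < k:
        raise ValueError(f"need at least k={k} scored transcripts, have {len(scores)}")
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [tid for tid, _ in ordered[:k]]


def rank_by_frequency(
    per_replicate_lists: list[list[str]],
    class_label: str = "",
    mean_scores: dict[str, float] | None = None,
) -> GeneRanking:
    """Aggregate per-replicate top-k lists into a frequency-ranked consensus.

    Consensus order: descending frequency; ties by descending mean
    importance score when provided, then ascending transcript_id.
    """
    if not per_replicate_lists:
        raise ValueError("need at least one replicate list")
    frequency: dict[str, int] = {}
    for lst in per_replicate_lists:
        if len(set(lst)) != len(lst):
            raise ValueError("a replicate top-k list contains duplicates")
        for tid in lst:
            frequency[tid] = frequency.get(tid, 0) + 1
    mean_scores = mean_scores or {}
    consensus = sorted(
        frequency,
        key=lambda tid: (-frequency[tid], -mean_scores.get(tid, 0.0), tid),
    )
    return GeneRanking(
        class_label=class_label,
        per_replicate_top_k=[list(lst) for lst in per_replicate_lists],
        frequency=frequency,
        consensus=consensus,
        mean_scores=dict(mean_scores),
    )


def overlap_count(
    consensus_top_k: list[str],
    reference_gene_list: list[str],
    k: int,
    transcript_to_gene: dict[str, str] | None = None,
) -> int:
    """Size of the intersection between a consensus top-k and a known-driver list.

    Transcript ids are mapped to gene symbols first; transcripts without a
    mapping are excluded with a warning. Genes of one transcript family
    count once.
    """
    if not reference_gene_list:
        raise ValueError("reference gene list must be non-empty")
    transcript_to_gene = transcript_to_gene or {}
    genes: set[str] = set()
    for tid in consensus_top_k[:k]:
        gene = transcript_to_gene.get(tid, tid if not transcript_to_gene else None)
        if gene is None:
            logger.warning("transcript %r has no gene mapping; excluded", tid)
            continue
        genes.add(gene)
    return len(genes & set(reference_gene_list))


def gene_level_ranking(
    ranking: GeneRanking, transcript_to_gene: dict[str, str]
) -> GeneRanking:
    """Collapse transcripts of one gene by maximum frequency."""
    freq: dict[str, int] = {}
    for tid, f in ranking.frequency.items():
        gene = transcript_to_gene.get(tid, tid)
        freq[gene] = max(freq.get(gene, 0), f)
    consensus = sorted(freq, key=lambda g: (-freq[g], g))
    seen: set[str] = set()
    per_rep = []
    for lst in ranking.per_replicate_top_k:
        genes = []
        seen = set()
        for tid in lst:
            g = transcript_to_gene.get(tid, tid)
            if g not in seen:
                genes.append(g)
                seen.add(g)
        per_rep.append(genes)
    return GeneRanking(
        class_label=ranking.class_label,
        per_replicate_top_k=per_rep,
        frequency=freq,
        consensus=consensus,
    )


def rank_from_models(
    models: list[ConvNetClassifier],
    class_index: int,
    class_label: str = "",
    k: int = 20,
    norm: str = "l1",
) -> GeneRanking:
    """Full prioritization over replicate models for one class."""
    per_replicate = []
    score_sums: dict[str, float] = {}
    for model in models:
        scores = transcript_importance(model, class_index, norm=norm)
        per_replicate.append(top_k_per_replicate(scores, k=k))
        for tid, s in scores.items():
            score_sums[tid] = score_sums.get(tid, 0.0) + s
    mean_scores = {tid: s / len(models) for tid, s in score_sums.items()}
    ranking = rank_by_frequency(per_replicate, class_label, mean_scores)
    return ranking


def write_ranking_report(
    ranking: GeneRanking,
    path: str | Path,
    transcript_to_gene: dict[str, str] | None = None,
    mean_scores: dict[str, float] | None = None,
) -> None:
    """TSV report: class, rank, gene_symbol, transcript_id, frequency, mean_score."""
    transcript_to_gene = transcript_to_gene or {}
    mean_scores = mean_scores or ranking.mean_scores
    with open(path, "w") as fh:
        fh.write("class\trank\tgene_symbol\ttranscript_id\tfrequency\tmean_score\n")
        for rank, tid in enumerate(ranking.consensus, start=1):
            fh.write(
                f"{ranking.class_label}\t{rank}\t{transcript_to_gene.get(tid, tid)}\t"
                f"{tid}\t{ranking.frequency[tid]}\t{mean_scores.get(tid, float('nan')):.6g}\n"
            )
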