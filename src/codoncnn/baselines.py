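"""Count-feature baselines and transcript pre-selection.

The comparison methods consume per-transcript mutation *counts* rather than
raw sequences: for every (sample, transcript) pair the number of germline
and somatic MODERATE/HIGH variants, optionally normalised by transcript
length in kilobases. Four reference classifiers are wrapped behind one
interface — L1-penalised logistic regression, linear SVM, gradient-boosted
trees, and an MLP over position-averaged codon frequencies — all trained
under the same split/seed discipline as the convolutional model.

Transcript pre-selection screens transcripts by a per-transcript univariate
multinomial logistic regression of disease class on the normalised mutation
count, ranked by the likelihood-ratio p-value against the intercept-only
model (chi-square, k-1 degrees of freedom).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

from .encoding import EncodedCohort
from .variants import DEFAULT_ALLOWED_EFFECTS, Origin, ReferenceTranscript, VariantRecord

logger = logging.getLogger(__name__)

BASELINE_KINDS = ("LR_L1", "LINEAR_SVM", "GBDT", "MLP")


@dataclass
class FeatureTable:
    """Per-sample count features: two columns per transcript.

    Columns are ordered ``<tid>__germline, <tid>__somatic`` following the
    reference transcript order; values are raw counts or, when normalised,
    counts per kilobase of transcript.
    """

    table: pd.DataFrame  # index: sample_id
    normalized: bool

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


def mutation_count_features(
    variants: list[VariantRecord],
    reference_set: list[ReferenceTranscript],
    sample_ids: list[str],
    normalize: bool = False,
    allowed_effects=DEFAULT_ALLOWED_EFFECTS,
) -> FeatureTable:
    """Count MODERATE/HIGH variants per (sample, transcript, origin)."""
    known = {t.transcript_id: t for t in reference_set}
    columns = []
    for t in reference_set:
        columns.extend([f"{t.transcript_id}__germline", f"{t.transcript_id}__somatic"])
    table = pd.DataFrame(
        0.0, index=pd.Index(sample_ids, name="sample_id"), columns=columns
    )
    for v in variants:
        if v.transcript_id not in known:
            raise ValueError(f"variant on unknown transcript {v.transcript_id!r}")
        if v.effect not in allowed_effects:
            continue
        if v.sample_id not in table.index:
            raise ValueError(f"variant for unknown sample {v.sample_id!r}")
        suffix = "germline" if v.origin is Origin.GERMLINE else "somatic"
        table.loc[v.sample_id, f"{v.transcript_id}__{suffix}"] += 1
    if normalize:
        for t in reference_set:
            kb = t.length_bases / 1000.0
            for suffix in ("germline", "somatic"):
                table[f"{t.transcript_id}__{suffix}"] /= kb
    return FeatureTable(table=table, normalized=normalize)


def total_count_features(
    variants: list[VariantRecord],
    reference_set: list[ReferenceTranscript],
    sample_ids: list[str],
    normalize: bool = True,
    allowed_effects=DEFAULT_ALLOWED_EFFECTS,
) -> pd.DataFrame:
    """One column per transcript: germline+somatic count (per kb if normalised)."""
    ft = mutation_count_features(
        variants, reference_set, sample_ids, normalize=False,
        allowed_effects=allowed_effects,
    ).table
    out = pd.DataFrame(index=ft.index)
    for t in reference_set:
        total = ft[f"{t.transcript_id}__germline"] + ft[f"{t.transcript_id}__somatic"]
        if normalize:
            total = total / (t.length_bases / 1000.0)
        out[t.transcript_id] = total
    return out


def mlp_sequence_features(cohort: EncodedCohort) -> np.ndarray:
    """Position-averaged codon-frequency vectors, 64 values per transcript.

    The per-row one-hot matrix of each transcript is averaged over rows,
    giving the codon usage profile of the (possibly mutated) sequence; the T
    per-transcript 64-vectors are concatenated.
    """
    parts = []
    for tid in cohort.transcript_ids:
        idx = cohort.indices[tid]  # (n, N)
        n, N = idx.shape
        freq = np.zeros((n, 64), dtype=np.float64)
        for c in range(64):
            freq[:, c] = (idx == c).sum(axis=1)
        parts.append(freq / max(N, 1))
    return np.concatenate(parts, axis=1)


def _make_classifier(kind: str, seed: int):
    if kind == "LR_L1":
        return LogisticRegression(
            l1_ratio=1.0, solver="saga", max_iter=2000, random_state=seed
        )
    if kind == "LINEAR_SVM":
        return LinearSVC(random_state=seed)
    if kind == "GBDT":
        return GradientBoostingClassifier(random_state=seed)
    if kind == "MLP":
        return MLPClassifier(random_state=seed, max_iter=500)
    raise ValueError(f"unknown baseline kind {kind!r}; expected one of {BASELINE_KINDS}")


def train_baseline(
    X: np.ndarray,
    y: np.ndarray,
    kind: str,
    seed: int,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
):
    """Fit one baseline on the training rows, score it on the test rows.

    Returns (fitted classifier, test accuracy, test predictions). The split
    indices come from the same 7:1:2 split used for the convolutional model
    so the comparison is like for like.
    """
    if kind not in BASELINE_KINDS:
        raise ValueError(
            f"unknown baseline kind {kind!r}; expected one of {BASELINE_KINDS}"
        )
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(np.unique(y[train_idx])) == 1:
        # degenerate single-class training data: predict that class
        clf = DummyClassifier(strategy="most_frequent")
    else:
        clf = _make_classifier(kind, seed)
    clf.fit(X[train_idx], y[train_idx])
    pred = clf.predict(X[test_idx])
    accuracy = float(np.mean(pred == y[test_idx]))
    return clf, accuracy, pred


def _multinomial_llf(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """Maximised log-likelihood of a univariate multinomial logistic model."""
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
    clf.fit(x.reshape(-1, 1), y)
    probs = clf.predict_proba(x.reshape(-1, 1))
    class_order = {c: i for i, c in enumerate(clf.classes_)}
    col = np.asarray([class_order[v] for v in y])
    return float(np.log(probs[np.arange(len(y)), col] + 1e-300).sum())


def select_transcripts(
    count_features: pd.DataFrame,
    labels: np.ndarray,
    m: int,
) -> tuple[list[str], dict[str, float]]:
    """Rank transcripts by per-transcript multinomial LRT p-value.

    ``count_features`` holds one length-normalised mutation-count column per
    transcript. For each, disease ~ count is fit as a univariate multinomial
    logistic regression and compared against the intercept-only model with a
    likelihood-ratio chi-square test on k-1 degrees of freedom. Returns the
    m smallest-p transcript ids (ties by id) and the full p-value map.
    A constant column cannot be fit and gets p = 1 by convention.
    """
    if m > count_features.shape[1]:
        raise ValueError(
            f"m={m} exceeds candidate transcript count {count_features.shape[1]}"
        )
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    k = len(classes)
    if k < 2:
        raise ValueError("need at least two classes")
    n = len(labels)
    llnull = float((counts * np.log(counts / n)).sum())

    pvalues: dict[str, float] = {}
    for tid in count_features.columns:
        x = count_features[tid].to_numpy(dtype=np.float64)
        if np.all(x == x[0]):
            logger.warning("transcript %r: constant counts, p set to 1", tid)
            pvalues[tid] = 1.0
            continue
        llf = _multinomial_llf(x, labels, k)
        lr_stat = max(0.0, 2.0 * (llf - llnull))
        pvalues[tid] = float(stats.chi2.sf(lr_stat, df=k - 1))
    ranked = sorted(pvalues, key=lambda t: (pvalues[t], t))
    return ranked[:m], pvalues
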