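"""Codon-level one-hot encoding of nucleotide sequences.

Every non-overlapping nucleotide triplet, read in the reference frame from
base 1, is one of 4^3 = 64 codons, so a sequence of N codons becomes an
N x 64 binary matrix — a 1-D signal with 64 channels. Codons are indexed
lexicographically with A < C < G < T (config key ``codon_order = lex-ACGT``),
so index = 16*b1 + 4*b2 + b3.

The matrix row count is fixed per transcript at the *reference* codon count,
so one network architecture serves every sample: after an insertion the
mutated sequence is tail-truncated, after a deletion it is zero-padded at
the tail. A trailing incomplete codon (possible after a frameshift) is
dropped. Codons containing N encode as all-zero rows. Downstream of a
frameshift the codons are deliberately shifted relative to the reference
frame — that shift is signal, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Index assigned to codons containing N (encoded as an all-zero row).
AMBIGUOUS = -1

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

_INVALID = 127
_BASE_LUT = np.full(256, _INVALID, dtype=np.int16)
for _b, _i in _BASE_INDEX.items():
    _BASE_LUT[ord(_b)] = _i

#: All 64 codons in encoding order; CODONS[i] has codon_index i.
CODONS = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
)


def codon_index(triplet: str) -> int:
    """Lexicographic (A<C<G<T) index of a codon, or AMBIGUOUS for N-containing."""
    if len(triplet) != 3:
        raise ValueError(f"codon must have length 3, got {triplet!r}")
    try:
        return (
            16 * _BASE_INDEX[triplet[0]]
            + 4 * _BASE_INDEX[triplet[1]]
            + _BASE_INDEX[triplet[2]]
        )
    except KeyError:
        if set(triplet) <= set("ACGTN"):
            return AMBIGUOUS
        raise ValueError(f"invalid nucleotide in codon {triplet!r}") from None


def sequence_to_codon_indices(sequence: str, target_rows: int) -> np.ndarray:
    """Codon indices of a sequence, truncated/padded to ``target_rows``.

    Padding rows and ambiguous codons carry the AMBIGUOUS sentinel; they both
    expand to all-zero rows in the one-hot matrix.
    """
    if target_rows < 1:
        raise ValueError("target_rows must be >= 1")
    n_codons = min(len(sequence) // 3, target_rows)
    out = np.full(target_rows, AMBIGUOUS, dtype=np.int16)
    if n_codons == 0:
        return out
    # vectorised base→index lookup over the used prefix
    raw = np.frombuffer(sequence[: 3 * n_codons].encode("ascii"), dtype=np.uint8)
    base = _BASE_LUT[raw]
    for bad in np.nonzero(base == _INVALID)[0]:
        if sequence[bad] != "N":
            raise ValueError(f"invalid nucleotide {sequence[bad]!r} at offset {bad}")
    triplets = base.reshape(n_codons, 3).astype(np.int16)
    idx = 16 * triplets[:, 0] + 4 * triplets[:, 1] + triplets[:, 2]
    idx[np.any(triplets == _INVALID, axis=1)] = AMBIGUOUS
    out[:n_codons] = idx
    return out


@dataclass
class CodonMatrix:
    """One transcript's codon one-hot encoding for one sample."""

    transcript_id: str
    matrix: np.ndarray  # (rows, 64) float32 binary
    pad_rows: int

    @property
    def rows(self) -> int:
        return self.matrix.shape[0]


def indices_to_onehot(indices: np.ndarray) -> np.ndarray:
    """(..., N) codon indices → (..., N, 64) float32 one-hot; sentinel → zero row."""
    out = np.zeros(indices.shape + (64,), dtype=np.float32)
    valid = indices >= 0
    out[(*np.nonzero(valid), indices[valid])] = 1.0
    return out


def encode_sequence(
    sequence: str, target_rows: int, transcript_id: str = ""
) -> CodonMatrix:
    """One-hot encode a nucleotide sequence into a fixed-shape codon matrix."""
    idx = sequence_to_codon_indices(sequence, target_rows)
    n_complete = min(len(sequence) // 3, target_rows)
    return CodonMatrix(
        transcript_id=transcript_id,
        matrix=indices_to_onehot(idx),
        pad_rows=target_rows - n_complete,
    )


def decode_matrix(matrix: np.ndarray) -> str:
    """Argmax-decode the non-pad rows of a codon one-hot matrix."""
    out = []
    for row in matrix:
        if row.sum() == 0:
            break
        out.append(CODONS[int(np.argmax(row))])
    return "".join(out)


def write_sparse_matrix(cm: CodonMatrix, path: str | Path) -> None:
    """Write a codon matrix as coordinate text (transcript_id, row, column)."""
    rows, cols = np.nonzero(cm.matrix)
    with open(path, "w") as fh:
        fh.write("transcript_id\trow\tcolumn\n")
        for r, c in zip(rows, cols):
            fh.write(f"{cm.transcript_id}\t{r}\t{c}\n")


@dataclass
class EncodedCohort:
    """Codon-index encodings of a whole cohort, one array per transcript.

    ``indices[tid]`` has shape (n_samples, codon_count(tid)) and stores codon
    indices (AMBIGUOUS for pad/N rows); one-hot matrices are expanded lazily
    per mini-batch, which keeps a cohort of hundreds of samples small in
    memory.
    """

    sample_ids: list[str]
    transcript_ids: list[str]
    codon_counts: dict[str, int]
    indices: dict[str, np.ndarray]
    labels: np.ndarray | None = None  # (n_samples,) int class labels

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def onehot_batch(self, transcript_id: str, sample_idx: np.ndarray) -> np.ndarray:
        """(batch, N, 64) one-hot channel-last array for one transcript."""
        idx = self.indices[transcript_id][sample_idx]
        return indices_to_onehot(idx)

    def subset(self, sample_idx: np.ndarray) -> "EncodedCohort":
        return EncodedCohort(
            sample_ids=[self.sample_ids[i] for i in sample_idx],
            transcript_ids=list(self.transcript_ids),
            codon_counts=dict(self.codon_counts),
            indices={t: a[sample_idx] for t, a in self.indices.items()},
            labels=None if self.labels is None else self.labels[sample_idx],
        )


def encode_cohort(
    sample_sets: list,
    reference_set: list,
    labels: dict[str, int] | None = None,
) -> EncodedCohort:
    """Encode per-sample raw sequences against the reference row counts.

    ``sample_sets`` are SampleSequenceSet objects; every transcript's row
    count is the reference transcript's codon count.
    """
    transcript_ids = [t.transcript_id for t in reference_set]
    codon_counts = {t.transcript_id: t.codon_count for t in reference_set}
    sample_ids = [s.sample_id for s in sample_sets]
    indices = {
        tid: np.empty((len(sample_sets), codon_counts[tid]), dtype=np.int16)
        for tid in transcript_ids
    }
    for i, s in enumerate(sample_sets):
        for tid in transcript_ids:
            indices[tid][i] = sequence_to_codon_indices(
                s.sequences[tid], codon_counts[tid]
            )
    label_arr = None
    if labels is not None:
        label_arr = np.asarray([labels[sid] for sid in sample_ids], dtype=np.int64)
    return EncodedCohort(
        sample_ids=sample_ids,
        transcript_ids=transcript_ids,
        codon_counts=codon_counts,
        indices=indices,
        labels=label_arr,
    )
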