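"""Reference transcripts, variant records, and variant embedding.

The classifier does not consume variant calls directly: each sample's
germline variants (and, for the cancer view, its somatic mutations) are
spliced into the reference transcript sequences, producing per-sample
"raw sequences" that carry SNVs and indels — including frameshifts —
as literal sequence changes.

Coordinates are 1-based and inclusive on the transcript coding strand.
Indels use VCF-style anchored alleles: ref and alt are both non-empty
and share their first base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

VARIANT_TABLE_COLUMNS = (
    "sample_id",
    "transcript_id",
    "position",
    "ref_allele",
    "alt_allele",
    "origin",
    "effect",
)


class Origin(str, Enum):
    GERMLINE = "GERMLINE"
    SOMATIC = "SOMATIC"


class Effect(str, Enum):
    """SnpEff-style impact class.

    MODERATE covers missense and in-frame indels, HIGH covers nonsense and
    frameshift events; everything else is OTHER and is excluded from
    sequence construction by default.
    """

    MODERATE = "MODERATE"
    HIGH = "HIGH"
    OTHER = "OTHER"


#: Effect classes that enter raw-sequence construction.
DEFAULT_ALLOWED_EFFECTS = frozenset({Effect.MODERATE, Effect.HIGH})


@dataclass(frozen=True)
class ReferenceTranscript:
    """One coding-strand transcript sequence, 5'→3'."""

    transcript_id: str
    gene_symbol: str
    sequence: str

    @property
    def length_bases(self) -> int:
        return len(self.sequence)

    @property
    def codon_count(self) -> int:
        return len(self.sequence) // 3


@dataclass(frozen=True)
class VariantRecord:
    """One anchored allele change in transcript coordinates."""

    sample_id: str
    transcript_id: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    origin: Origin
    effect: Effect

    @property
    def ref_span(self) -> tuple[int, int]:
        """Inclusive 1-based interval of reference bases this variant replaces."""
        return self.position, self.position + len(self.ref_allele) - 1

    @property
    def length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)


@dataclass
class SampleSequenceSet:
    """All raw sequences for one sample under one embedding mode."""

    sample_id: str
    mode: str  # "GERMLINE" or "CANCER"
    sequences: dict[str, str]
    provenance: dict[str, int] = field(default_factory=dict)


def read_transcript_fasta(path: str | Path) -> list[ReferenceTranscript]:
    """Read reference transcripts from FASTA.

    Record IDs are parsed as ``transcript_id`` or ``transcript_id|gene_symbol``;
    without a gene symbol the transcript id doubles as the symbol. Sequences
    are upper-cased and validated against the {A,C,G,T,N} alphabet.
    """
    transcripts: list[ReferenceTranscript] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        tid, _, gene = record.id.partition("|")
        if tid in seen:
            raise ValueError(f"duplicate transcript ID in {path}: {tid!r}")
        seen.add(tid)
        seq = str(record.seq).upper()
        for offset, base in enumerate(seq):
            if base not in VALID_BASES:
                raise ValueError(
                    f"invalid base {base!r} in record {tid!r} at offset {offset} "
                    f"(1-based position {offset + 1})"
                )
        transcripts.append(
            ReferenceTranscript(transcript_id=tid, gene_symbol=gene or tid, sequence=seq)
        )
    return transcripts


def write_transcript_fasta(
    transcripts: list[ReferenceTranscript], path: str | Path
) -> None:
    records = [
        SeqRecord(
            Seq(t.sequence),
            id=f"{t.transcript_id}|{t.gene_symbol}" if t.gene_symbol != t.transcript_id else t.transcript_id,
            description="",
        )
        for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def write_sample_sequences_fasta(
    sample_set: SampleSequenceSet, path: str | Path
) -> None:
    """Dump one sample's mutated sequences as multi-FASTA for inspection."""
    records = [
        SeqRecord(Seq(seq), id=f"{sample_set.sample_id}|{tid}|{sample_set.mode}", description="")
        for tid, seq in sample_set.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a tab-separated variant table.

    Expected header columns: sample_id, transcript_id, position, ref_allele,
    alt_allele, origin, effect. Unknown effect strings map to OTHER with a
    warning; a malformed position is an error naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise ValueError(f"{path}: empty file, expected a header line")
        header = header_line.split("\t")
        missing = [c for c in VARIANT_TABLE_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        col = {name: header.index(name) for name in VARIANT_TABLE_COLUMNS}

        records: list[VariantRecord] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            raw_pos = fields[col["position"]]
            try:
                position = int(raw_pos)
            except ValueError:
                raise ValueError(
                    f"{path}: non-integer position {raw_pos!r} on line {lineno}"
                ) from None
            raw_effect = fields[col["effect"]].upper()
            try:
                effect = Effect(raw_effect)
            except ValueError:
                logger.warning(
                    "%s line %d: unknown effect %r mapped to OTHER", path, lineno, raw_effect
                )
                effect = Effect.OTHER
            records.append(
                VariantRecord(
                    sample_id=fields[col["sample_id"]],
                    transcript_id=fields[col["transcript_id"]],
                    position=position,
                    ref_allele=fields[col["ref_allele"]].upper(),
                    alt_allele=fields[col["alt_allele"]].upper(),
                    origin=Origin(fields[col["origin"]].upper()),
                    effect=effect,
                )
            )
    return records


def write_variant_table(records: list[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(VARIANT_TABLE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.sample_id}\t{r.transcript_id}\t{r.position}\t{r.ref_allele}\t"
                f"{r.alt_allele}\t{r.origin.value}\t{r.effect.value}\n"
            )


def read_variant_vcf(path: str | Path) -> list[VariantRecord]:
    """Read variants from a (possibly multi-sample) VCF.

    CHROM is interpreted as transcript_id and POS as the 1-based transcript
    coordinate. Per-record INFO keys ORIGIN and EFFECT carry the variant
    origin and SnpEff-style impact; SAMPLE names the sample for single-column
    files without genotypes.
    """
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    for v in VCF(str(path)):
        try:
            effect = Effect(str(v.INFO.get("EFFECT", "OTHER")).upper())
        except ValueError:
            effect = Effect.OTHER
        records.append(
            VariantRecord(
                sample_id=str(v.INFO.get("SAMPLE", "")),
                transcript_id=v.CHROM,
                position=v.POS,
                ref_allele=v.REF.upper(),
                alt_allele=v.ALT[0].upper(),
                origin=Origin(str(v.INFO.get("ORIGIN", "SOMATIC")).upper()),
                effect=effect,
            )
        )
    return records


def filter_by_effect(
    variants: list[VariantRecord],
    allowed: frozenset[Effect] | set[Effect] = DEFAULT_ALLOWED_EFFECTS,
) -> list[VariantRecord]:
    """Order-preserving subset of variants whose effect class is allowed."""
    allowed = {Effect(a) for a in allowed}
    return [v for v in variants if v.effect in allowed]


def _check_variants(
    reference: ReferenceTranscript, variants: list[VariantRecord]
) -> None:
    """Validate ref-allele match and pairwise-disjoint reference spans."""
    for v in variants:
        start, end = v.ref_span
        if start < 1 or end > reference.length_bases:
            raise ValueError(
                f"variant out of bounds: sample {v.sample_id!r} transcript "
                f"{v.transcript_id!r} span {start}-{end} on a "
                f"{reference.length_bases}-base transcript"
            )
        observed = reference.sequence[start - 1 : end]
        if observed != v.ref_allele:
            raise ValueError(
                f"ref allele mismatch: sample {v.sample_id!r} transcript "
                f"{v.transcript_id!r} position {v.position}: expected "
                f"{v.ref_allele!r}, reference has {observed!r}"
            )
    spans = sorted((v.ref_span, v) for v in variants)
    for (span_a, a), (span_b, b) in zip(spans, spans[1:]):
        if span_b[0] <= span_a[1]:
            raise ValueError(
                f"overlapping variant spans on transcript {a.transcript_id!r} "
                f"sample {a.sample_id!r}: {span_a} ({a.origin.value}) and "
                f"{span_b} ({b.origin.value})"
            )


def apply_variants(
    reference: ReferenceTranscript, variants: list[VariantRecord]
) -> str:
    """Splice one sample's variants on one transcript into its reference.

    Variants are applied in descending reference position, which keeps every
    remaining coordinate valid regardless of upstream length changes. Spans
    must be pairwise disjoint and every ref allele must match the reference;
    violations raise with sample/transcript context rather than guessing a
    precedence.
    """
    _check_variants(reference, variants)
    seq = reference.sequence
    for v in sorted(variants, key=lambda v: v.position, reverse=True):
        start, end = v.ref_span
        seq = seq[: start - 1] + v.alt_allele + seq[end:]
    return seq


def invert_variant(v: VariantRecord) -> VariantRecord:
    """The variant that undoes ``v`` on the mutated sequence (ref/alt swapped)."""
    return VariantRecord(
        sample_id=v.sample_id,
        transcript_id=v.transcript_id,
        position=v.position,
        ref_allele=v.alt_allele,
        alt_allele=v.ref_allele,
        origin=v.origin,
        effect=v.effect,
    )


def build_sample_sequences(
    reference_set: list[ReferenceTranscript],
    germline: list[VariantRecord],
    somatic: list[VariantRecord],
    mode: str,
    sample_id: str | None = None,
) -> SampleSequenceSet:
    """Construct one sample's raw sequences.

    mode "GERMLINE" embeds germline variants only; mode "CANCER" embeds the
    union of germline and somatic variants (their spans must be disjoint,
    which makes joint descending-position application equivalent to
    germline-then-somatic embedding with coordinate lifting).
    """
    mode = mode.upper()
    if mode not in ("GERMLINE", "CANCER"):
        raise ValueError(f"mode must be GERMLINE or CANCER, got {mode!r}")
    applied = list(germline) + (list(somatic) if mode == "CANCER" else [])
    sample_ids = {v.sample_id for v in applied}
    if sample_id is None:
        if len(sample_ids) > 1:
            raise ValueError(f"variants from multiple samples: {sorted(sample_ids)}")
        sample_id = next(iter(sample_ids), "")
    elif sample_ids - {sample_id}:
        raise ValueError(
            f"variants for sample(s) {sorted(sample_ids - {sample_id})} passed "
            f"while building sample {sample_id!r}"
        )

    by_transcript: dict[str, list[VariantRecord]] = {}
    for v in applied:
        by_transcript.setdefault(v.transcript_id, []).append(v)
    known = {t.transcript_id for t in reference_set}
    unknown = set(by_transcript) - known
    if unknown:
        raise ValueError(
            f"sample {sample_id!r}: variants on unknown transcript(s) {sorted(unknown)}"
        )

    provenance = {
        f"{origin.value}_{effect.value}": 0
        for origin in Origin
        for effect in Effect
    }
    for v in applied:
        provenance[f"{v.origin.value}_{v.effect.value}"] += 1

    sequences: dict[str, str] = {}
    for t in reference_set:
        variants = by_transcript.get(t.transcript_id, [])
        try:
            sequences[t.transcript_id] = apply_variants(t, variants)
        except ValueError as exc:
            raise ValueError(f"sample {sample_id!r}: {exc}") from exc
    return SampleSequenceSet(
        sample_id=sample_id, mode=mode, sequences=sequences, provenance=provenance
    )
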