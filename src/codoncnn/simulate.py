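"""Synthetic multi-class cohorts with controllable class signal.

The generator emulates the statistical shape of a tumor/normal WES cohort
at desk scale: a set of random reference transcripts, per-sample germline
and somatic variant tables with Poisson background rates per kilobase
(SNVs plus in-frame and frameshift indels, VCF-anchored), and a designated
set of "driver" transcripts per class that carries the class signal.

Two signal regimes bracket what count-based and sequence-based classifiers
can see:

* COUNT — driver transcripts of a sample's class receive a somatic rate
  multiplied by ``driver_effect_multiplier``; per-transcript mutation counts
  alone identify the class.
* PATTERN — every sample receives exactly one somatic substitution motif at
  a fixed position of every driver transcript; the substituted codons (not
  the count, which is equal across classes) encode whether the sample
  belongs to the driver's class. Class is a deterministic function of the
  raw sequence but statistically independent of all count features. The
  motif spans ``motif_codons`` consecutive codons (default 3 — the
  receptive field of a kernel-3 convolution over codon rows, which keeps
  the motif detectable even when background indels rewrite the codon frame
  elsewhere in the transcript).

MIXED applies both. All randomness flows from one seed; regenerating with
the same spec yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .encoding import CODONS
from .variants import (
    Effect,
    Origin,
    ReferenceTranscript,
    VariantRecord,
    write_transcript_fasta,
    write_variant_table,
)

_BASES = "ACGT"

# SNV substitution spectrum: deamination-dominated (C:G -> T:A), the dominant
# signature in human tumors, with a mild overall transition bias. Rows: ref
# base; columns: alt base in ACGT order (self weight 0).
_SNV_WEIGHTS = {
    "A": np.array([0.0, 1.0, 2.0, 1.0]),
    "C": np.array([1.0, 0.0, 1.0, 8.0]),
    "G": np.array([8.0, 1.0, 0.0, 1.0]),
    "T": np.array([1.0, 2.0, 1.0, 0.0]),
}
_SNV_PROBS = {b: w / w.sum() for b, w in _SNV_WEIGHTS.items()}

_STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    Rates are variants per kilobase of transcript per sample. The default
    driver map assigns ``drivers_per_class`` consecutive transcripts to each
    class. ``indel_fraction`` is the probability that a background variant
    is an indel; ``frameshift_fraction`` is the probability that an indel
    shifts the frame (length 1-2) rather than being in-frame (length 3).
    ``moderate_fraction`` is the MODERATE share of the MODERATE/HIGH effect
    mix for background SNVs; frameshift indels are always HIGH and in-frame
    indels MODERATE.
    """

    class_count: int = 3
    samples_per_class: int = 70
    transcript_count: int = 30
    length_range: tuple[int, int] = (60, 1500)
    germline_rate: float = 1.0
    somatic_rate: float = 0.5
    drivers_per_class: int = 3
    driver_map: dict[str, list[str]] | None = None
    driver_effect_multiplier: float = 20.0
    signal_mode: str = "PATTERN"  # COUNT, PATTERN, or MIXED
    motif_codons: int = 3
    indel_fraction: float = 0.1
    frameshift_fraction: float = 0.5
    moderate_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signal_mode not in ("COUNT", "PATTERN", "MIXED"):
            raise ValueError(f"unknown signal_mode {self.signal_mode!r}")
        for name in ("germline_rate", "somatic_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("indel_fraction", "frameshift_fraction", "moderate_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def class_names(self) -> list[str]:
        return [f"class_{c}" for c in range(self.class_count)]

    def resolved_driver_map(self, transcripts: list[ReferenceTranscript]) -> dict[str, list[str]]:
        if self.driver_map is not None:
            known = {t.transcript_id for t in transcripts}
            for cls, tids in self.driver_map.items():
                missing = set(tids) - known
                if missing:
                    raise ValueError(
                        f"driver transcripts absent from reference for {cls}: {sorted(missing)}"
                    )
            return self.driver_map
        need = self.class_count * self.drivers_per_class
        if need > len(transcripts):
            raise ValueError("not enough transcripts for the default driver map")
        return {
            name: [
                transcripts[c * self.drivers_per_class + j].transcript_id
                for j in range(self.drivers_per_class)
            ]
            for c, name in enumerate(self.class_names)
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["length_range"] = list(self.length_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["length_range"] = tuple(d["length_range"])
        return cls(**d)


def generate_reference(
    transcript_count: int,
    length_range: tuple[int, int] = (60, 1500),
    seed: int = 0,
) -> list[ReferenceTranscript]:
    """Uniform random transcripts; lengths forced to multiples of 3."""
    lo, hi = length_range
    if transcript_count < 1 or lo < 9:
        raise ValueError("need transcript_count >= 1 and lengths >= 9")
    rng = np.random.default_rng(seed)
    transcripts = []
    width = max(4, len(str(transcript_count)))
    for i in range(transcript_count):
        length = int(rng.integers(lo, hi + 1)) // 3 * 3
        length = max(length, 9)
        seq = "".join(_BASES[b] for b in rng.integers(0, 4, size=length))
        transcripts.append(
            ReferenceTranscript(
                transcript_id=f"T{i:0{width}d}",
                gene_symbol=f"GENE{i:0{width}d}",
                sequence=seq,
            )
        )
    return transcripts


@dataclass
class Cohort:
    spec: CohortSpec
    reference: list[ReferenceTranscript]
    germline: list[VariantRecord]
    somatic: list[VariantRecord]
    labels: dict[str, str]  # sample_id -> class name

    @property
    def label_indices(self) -> dict[str, int]:
        order = {name: i for i, name in enumerate(self.spec.class_names)}
        return {sid: order[cls] for sid, cls in self.labels.items()}


def _pattern_sites(
    spec: CohortSpec,
    reference: list[ReferenceTranscript],
    driver_map: dict[str, list[str]],
    rng: np.random.Generator,
) -> dict[str, tuple[int, str, dict[str, str]]]:
    """Per driver transcript: (position, ref motif, class name -> alt motif).

    The site is centred on the transcript's middle codons and spans
    ``motif_codons`` codons. The driver's own class gets one fixed alt motif
    and every other class a second, shared alt motif (each motif codon
    differs from the reference codon at that position), so each driver marks
    its class one-vs-rest while total variant counts stay equal.
    """
    by_id = {t.transcript_id: t for t in reference}
    sites: dict[str, tuple[int, str, dict[str, str]]] = {}
    for cls, tids in sorted(driver_map.items()):
        for tid in tids:
            t = by_id[tid]
            m = min(spec.motif_codons, t.codon_count)
            codon_start = max(0, t.codon_count // 2 - m // 2)
            pos = 3 * codon_start + 1
            ref_motif = t.sequence[pos - 1 : pos - 1 + 3 * m]
            own_parts, rest_parts = [], []
            for j in range(m):
                ref_codon = ref_motif[3 * j : 3 * j + 3]
                others = [c for c in CODONS if c != ref_codon]
                a, b = rng.choice(len(others), size=2, replace=False)
                own_parts.append(others[a])
                rest_parts.append(others[b])
            alt_by_class = {
                name: ("".join(own_parts) if name == cls else "".join(rest_parts))
                for name in spec.class_names
            }
            sites[tid] = (pos, ref_motif, alt_by_class)
    return sites


def _draw_nonsense_site(
    t: ReferenceTranscript, rng: np.random.Generator
) -> tuple[int, str, str] | None:
    """A random single-base change creating a stop codon, or None.

    Tries random reference-frame codons and enumerates their single-base
    stop mutants; roughly a third of codons have one, so a handful of tries
    almost always succeeds.
    """
    n_codons = t.codon_count
    for _ in range(20):
        ci = int(rng.integers(0, n_codons))
        codon = t.sequence[3 * ci : 3 * ci + 3]
        options = []
        for stop in _STOP_CODONS:
            diffs = [j for j in range(3) if codon[j] != stop[j]]
            if len(diffs) == 1:
                j = diffs[0]
                options.append((3 * ci + j + 1, codon[j], stop[j]))
        if options:
            return options[int(rng.integers(0, len(options)))]
    return None


def _draw_background_variant(
    t: ReferenceTranscript,
    occupied: set[int],
    spec: CohortSpec,
    rng: np.random.Generator,
    sample_id: str,
    origin: Origin,
) -> VariantRecord | None:
    """One background variant with a free reference span, or None after 100 tries."""
    L = t.length_bases
    for _ in range(100):
        is_indel = rng.random() < spec.indel_fraction
        if is_indel:
            frameshift = rng.random() < spec.frameshift_fraction
            ell = int(rng.integers(1, 3)) if frameshift else 3
            is_insertion = rng.random() < 0.5
            if is_insertion:
                pos = int(rng.integers(1, L + 1))
                ref = t.sequence[pos - 1]
                alt = ref + "".join(_BASES[b] for b in rng.integers(0, 4, size=ell))
                span = {pos}
            else:
                if L - ell < 1:
                    continue
                pos = int(rng.integers(1, L - ell + 1))
                ref = t.sequence[pos - 1 : pos + ell]
                alt = ref[0]
                span = set(range(pos, pos + ell + 1))
            effect = Effect.HIGH if frameshift else Effect.MODERATE
        else:
            effect = (
                Effect.MODERATE
                if rng.random() < spec.moderate_fraction
                else Effect.HIGH
            )
            if effect is Effect.HIGH:
                # nonsense: a single-base change that turns a reference-frame
                # codon into a stop codon
                hit = _draw_nonsense_site(t, rng)
                if hit is None:
                    effect = Effect.MODERATE
                else:
                    pos, ref, alt = hit
                    span = {pos}
            if effect is Effect.MODERATE:
                # missense: substitution following the spectrum
                pos = int(rng.integers(1, L + 1))
                ref = t.sequence[pos - 1]
                alt = _BASES[int(rng.choice(4, p=_SNV_PROBS[ref]))]
                span = {pos}
        if span & occupied:
            continue
        occupied |= span
        return VariantRecord(
            sample_id=sample_id,
            transcript_id=t.transcript_id,
            position=pos,
            ref_allele=ref,
            alt_allele=alt,
            origin=origin,
            effect=effect,
        )
    return None


def generate_cohort(
    spec: CohortSpec, reference: list[ReferenceTranscript] | None = None
) -> Cohort:
    """Generate germline/somatic variant tables and labels for one cohort."""
    rng = np.random.default_rng(spec.seed)
    if reference is None:
        reference = generate_reference(
            spec.transcript_count, spec.length_range, seed=spec.seed
        )
    driver_map = spec.resolved_driver_map(reference)
    driver_class = {
        tid: cls for cls, tids in driver_map.items() for tid in tids
    }
    pattern = spec.signal_mode in ("PATTERN", "MIXED")
    count_signal = spec.signal_mode in ("COUNT", "MIXED")
    sites = _pattern_sites(spec, reference, driver_map, rng) if pattern else {}

    germline: list[VariantRecord] = []
    somatic: list[VariantRecord] = []
    labels: dict[str, str] = {}
    n_total = spec.class_count * spec.samples_per_class
    width = max(4, len(str(n_total)))
    sample_no = 0
    for c, cls in enumerate(spec.class_names):
        for _ in range(spec.samples_per_class):
            sample_id = f"S{sample_no:0{width}d}"
            sample_no += 1
            labels[sample_id] = cls
            for t in reference:
                occupied: set[int] = set()
                if t.transcript_id in sites:
                    pos, ref_motif, alt_by_class = sites[t.transcript_id]
                    occupied |= set(range(pos, pos + len(ref_motif)))
                    somatic.append(
                        VariantRecord(
                            sample_id=sample_id,
                            transcript_id=t.transcript_id,
                            position=pos,
                            ref_allele=ref_motif,
                            alt_allele=alt_by_class[cls],
                            origin=Origin.SOMATIC,
                            effect=Effect.MODERATE,
                        )
                    )
                kb = t.length_bases / 1000.0
                som_rate = spec.somatic_rate
                if count_signal and driver_class.get(t.transcript_id) == cls:
                    som_rate *= spec.driver_effect_multiplier
                for origin, rate in (
                    (Origin.GERMLINE, spec.germline_rate),
                    (Origin.SOMATIC, som_rate),
                ):
                    for _i in range(rng.poisson(rate * kb)):
                        v = _draw_background_variant(
                            t, occupied, spec, rng, sample_id, origin
                        )
                        if v is not None:
                            (germline if origin is Origin.GERMLINE else somatic).append(v)
    return Cohort(
        spec=spec,
        reference=reference,
        germline=germline,
        somatic=somatic,
        labels=labels,
    )


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tcancer_type\n")
        for sid in labels:
            fh.write(f"{sid}\t{labels[sid]}\n")


def read_labels(path: str | Path) -> dict[str, str]:
    labels: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["sample_id", "cancer_type"]:
            raise ValueError(f"{path}: expected columns sample_id, cancer_type")
        for line in fh:
            if line.strip():
                sid, cls = line.rstrip("\n").split("\t")[:2]
                labels[sid] = cls
    return labels


def write_fixture(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA + variant/label TSVs + a YAML manifest; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": out / "reference.fasta",
        "germline": out / "germline.tsv",
        "somatic": out / "somatic.tsv",
        "labels": out / "labels.tsv",
        "manifest": out / "manifest.yaml",
    }
    write_transcript_fasta(cohort.reference, paths["reference"])
    write_variant_table(cohort.germline, paths["germline"])
    write_variant_table(cohort.somatic, paths["somatic"])
    write_labels(cohort.labels, paths["labels"])
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump({"cohort_spec": cohort.spec.to_dict()}, fh, sort_keys=True)
    return paths


def regenerate_from_manifest(manifest_path: str | Path) -> Cohort:
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    return generate_cohort(CohortSpec.from_dict(manifest["cohort_spec"]))
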