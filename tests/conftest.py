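"""Shared fixtures: small synthetic references and cohorts, all seeded."""

from __future__ import annotations

import numpy as np
import pytest

from codoncnn.simulate import CohortSpec, generate_cohort, generate_reference
from codoncnn.variants import Effect, Origin, ReferenceTranscript, VariantRecord


@pytest.fixture(scope="session")
def small_reference() -> list[ReferenceTranscript]:
    return generate_reference(10, (60, 600), seed=7)


@pytest.fixture(scope="session")
def tiny_cohort_spec() -> CohortSpec:
    """A fast cohort for pipeline-level tests: 3x20 samples, 10 transcripts."""
    return CohortSpec(
        class_count=3,
        samples_per_class=20,
        transcript_count=10,
        length_range=(60, 600),
        drivers_per_class=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cohort_spec):
    return generate_cohort(tiny_cohort_spec)


def make_variant(
    transcript_id: str,
    position: int,
    ref: str,
    alt: str,
    sample_id: str = "S1",
    origin: Origin = Origin.SOMATIC,
    effect: Effect = Effect.MODERATE,
) -> VariantRecord:
    return VariantRecord(
        sample_id=sample_id,
        transcript_id=transcript_id,
        position=position,
        ref_allele=ref,
        alt_allele=alt,
        origin=origin,
        effect=effect,
    )


def random_disjoint_variants(
    reference: ReferenceTranscript, rng: np.random.Generator, max_variants: int = 4
) -> list[VariantRecord]:
    """Random non-overlapping SNVs/indels on one transcript (test helper)."""
    L = reference.length_bases
    n = int(rng.integers(0, max_variants + 1))
    variants: list[VariantRecord] = []
    occupied: set[int] = set()
    bases = "ACGT"
    for _ in range(n):
        for _try in range(50):
            kind = rng.integers(0, 3)  # 0 snv, 1 ins, 2 del
            if kind == 2:
                ell = int(rng.integers(1, 4))
                if L - ell < 1:
                    continue
                pos = int(rng.integers(1, L - ell + 1))
                span = set(range(pos, pos + ell + 1))
                if span & occupied:
                    continue
                ref = reference.sequence[pos - 1 : pos + ell]
                alt = ref[0]
            else:
                pos = int(rng.integers(1, L + 1))
                if pos in occupied:
                    continue
                span = {pos}
                ref = reference.sequence[pos - 1]
                if kind == 0:
                    alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
                else:
                    alt = ref + "".join(
                        bases[b] for b in rng.integers(0, 4, int(rng.integers(1, 4)))
                    )
            occupied |= span
            variants.append(make_variant(reference.transcript_id, pos, ref, alt))
            break
    return variants


def naive_splice(sequence: str, variants: list[VariantRecord]) -> str:
    """Left-to-right splice oracle with explicit offset tracking."""
    out = sequence
    offset = 0
    for v in sorted(variants, key=lambda v: v.position):
        start = v.position - 1 + offset
        assert out[start : start + len(v.ref_allele)] == v.ref_allele
        out = out[:start] + v.alt_allele + out[start + len(v.ref_allele) :]
        offset += len(v.alt_allele) - len(v.ref_allele)
    return out
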