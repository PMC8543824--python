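# Methods

This note documents the model, the conventions the implementation fixes
where the method description leaves freedom, the synthetic cohorts used for
validation, and known limitations. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Raw-sequence construction

Per-sample sequences are built by splicing variant alleles into reference
transcript sequences (coding strand, 5'→3'). Coordinates are 1-based and
inclusive in transcript space; indels use VCF-style anchoring (ref and alt
non-empty, shared first base), so records round-trip through standard VCF.
Only MODERATE and HIGH impact variants (missense/in-frame ≈ MODERATE,
nonsense/frameshift ≈ HIGH) enter construction; other impact classes are
read but excluded.

Two views exist per sample: **germline** (germline variants only) and
**cancer** (germline plus somatic). Somatic coordinates are
reference-relative, and all variant reference spans within a sample must be
pairwise disjoint; under that precondition, applying the combined set in
descending position order is exactly equivalent to embedding germline
first and somatic second with coordinate lifting. Overlapping spans —
including a germline/somatic collision at one locus — are a hard error
rather than a silent precedence: any tie-break would corrupt provenance
and no principled order exists.

## Codon encoding

Sequences are read as non-overlapping triplets from base 1 in the
*reference* reading frame. Codons are indexed lexicographically with
A<C<G<T (`codon_index = 16·b₁+4·b₂+b₃`); the ordering is arbitrary but is
part of the model/file contract (`codon_order = lex-ACGT`). The row count
of every sample's matrix is pinned to the reference transcript's codon
count ⌊length/3⌋ so a single architecture serves all samples: insertions
that extend the sequence are tail-truncated, deletions leave all-zero tail
padding, and a trailing incomplete codon (after a net frameshift) is
dropped. Codons containing `N` encode as all-zero rows. Downstream of a
frameshift the encoded codons no longer align with the reference frame;
this is intentional — frame disruption is part of what the classifier may
learn.

## Architecture

Per transcript of N codons, d = ⌈log₆ N⌉ blocks (minimum 1) of

    same-padded 1-D convolution, kernel 3, stride 1
    → LeakyReLU (negative slope 0.01)
    → average pooling, kernel 6, stride 6, ceil mode

with 64→C channels in the first block and C→C afterwards; C defaults to 6
(3 is available — the architecture description and the parameter listing
the implementation follows disagree on this value, so it is exposed as
configuration). Ceil rounding of the depth is chosen because it reproduces
the quoted 3–4 blocks at the 1 125-codon average length and guarantees the
pooled length reaches exactly 1; the implementation computes the depth by
iterated ceil division so exact powers of six are never misrounded. The
trailing partial pooling window averages over the elements actually
present (not over zero padding). After the final pool a per-channel affine
produces a C-vector per transcript; the T vectors concatenate into a
(T·C)-input fully connected layer with k outputs. Encoders do **not**
share weights across transcripts: lengths and depths differ, and the
parallel-encoder reading of the architecture is the natural one.

Convolutions are evaluated as K shifted GEMMs in channel-last layout; the
first layer exploits the one-hot input and is computed as an index-gather
over codon indices. Backward passes are hand-derived and verified against
numerical differentiation.

## Initialisation and calibration

The method description fixes the optimiser but not the initialisation,
which turned out to be decisive at this depth. Conv weights are drawn
uniformly with variance gain²/(fan-in·K), with gain² = 2/(1+slope²) ·
pool_kernel — the LeakyReLU gain times a factor compensating the ~1/6
variance reduction of each average pool. Because the exact variance each
block preserves depends on the data's correlation structure, a
layer-sequential calibration pass then runs on the training samples: each
layer's pre-activations are standardised per channel (mean/SD folded into
that layer's weights and bias), and the per-channel affine is set to
standardise the final encoder output. Centering matters as much as
scaling: a channel whose pre-activations sit wholly below the LeakyReLU
kink trains ~100× slower through the 0.01 slope. The head starts at zero,
giving uniform class probabilities at step 0. The calibration is
deterministic given the split and changes only the starting point of
optimisation, not the function class.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), learning rate 0.001, batch size
32, 30 epochs, softmax cross-entropy. Samples are split 7:1:2 into
train/validation/test uniformly at random (no stratification); the
validation set is only monitored, the reported parameters are those of the
last epoch, and no regularisation or class re-weighting is applied.
Everything — split, initialisation, calibration, batch order — is a pure
function of one seed; runs are bitwise reproducible. The replicate
protocol repeats the whole procedure with seeds base+0…base+9 and reports
mean ± SE, where SE = sd/√replicates.

## Gene prioritization

score(t, c) = Σ|w| over the C head weights linking transcript t's encoder
block to class output c (L1 norm; L2 behind a switch — L1 is
scale-faithful for sparse heads). Per replicate the top-20 transcripts are
recorded (ties broken by ascending transcript id); the consensus ranks
transcripts by descending replicate frequency, then descending
replicate-mean importance, then id. Gene-level reports collapse multiple
transcripts of one gene by maximum frequency.

## Baselines and transcript pre-selection

LR (L1, saga solver), linear SVM, and GBDT consume per-transcript
germline and somatic counts of MODERATE+HIGH variants, optionally
normalised per kilobase of transcript (two columns per transcript;
per-variant indicators were rejected as dimensionally explosive). The MLP
consumes position-averaged codon-frequency vectors (64 values per
transcript) — a sequence-derived feature that stays tractable at desk
scale. All baselines run under the same splits and seeds as the
convolutional model. scikit-learn's documented defaults are used
otherwise.

Transcript pre-selection fits, per transcript, a univariate multinomial
logistic regression of disease class on the length-normalised mutation
count and ranks by the likelihood-ratio p-value against the intercept-only
model (χ², k−1 df). A joint multinomial over thousands of transcripts
would be unidentifiable at cohort sizes of interest. Constant-count
transcripts get p = 1 by convention (logged). Under a global null the
p-values are approximately uniform (checked by KS statistic in the test
suite). Model comparison uses a two-sided Welch t-test on replicate
accuracies — chosen over a pooled-variance test because variances across
methods differ; the replicates share splits, so this is conservative.

## Synthetic cohorts

The generator emulates the statistical shape of a tumor/normal WES cohort
at desk scale; its defaults define the validation conditions used by the
acceptance tests:

| parameter | default | rationale |
| --- | --- | --- |
| classes × samples | 3 × 70 | desk-scale analogue of a multi-cancer cohort |
| transcripts | 30, 60–1 500 bases (multiples of 3) | spans 1–4 encoder depths |
| germline background | 1.0 /kb/sample | of the order of per-transcript germline loads in tumor cohorts |
| somatic background | 0.5 /kb/sample | somatic ≪ germline |
| indel fraction | 0.1, half frameshift | indels a minority of calls |
| SNV spectrum | C→T/G→A weight 8, other transitions 2, transversions 1 | deamination-dominated, the dominant tumor signature |
| HIGH SNVs | create actual stop codons | HIGH ≈ nonsense by definition |
| drivers | 3 per class, multiplier 20 (COUNT) | class-specific enrichment |
| PATTERN motif | 3 consecutive codons at a fixed mid-transcript site | matches the kernel-3 receptive field over codon rows, so the motif survives indel-induced frame changes elsewhere |

In PATTERN mode every sample receives exactly one substitution motif per
driver transcript — the driver's own class gets one fixed alt motif,
every other class a second shared one — so per-transcript counts are
identical across classes while class remains a (nearly) deterministic
function of the raw sequence; only upstream frameshift background events
(~3% per driver per sample) can corrupt a motif. In COUNT mode the
somatic rate in a sample's class drivers is multiplied by 20, so class is
readable from counts alone. Positions are uniform, counts Poisson,
collisions resampled (≤100 tries, then the variant is dropped), and
generation is byte-deterministic given the seed.

What the generator does **not** emulate: trinucleotide context signatures
beyond the global spectrum, population allele-frequency structure and
linkage, transcript-specific mutability, codon-usage bias (references are
uniform random), and realistic gene lengths beyond the stated range.
Passing tests therefore demonstrate that the pipeline recovers the signal
classes it is designed to detect under controlled conditions, not
performance on real tumor cohorts.

## Problem sizes used by the validation suite

The end-to-end checks train 10 replicates × 30 epochs on the 210-sample
default cohorts (a few minutes each on one CPU); the splice-oracle and
metric-identity properties run on ≥1 000 random small instances; the
pooling shape law is checked for every codon count from 1 to 10⁴; the
p-value calibration uses 500 null transcripts at n = 200.

## Known limitations

- **Load is read only through its traces.** On count-driven cohorts the
  linear count baseline saturates exactly (it sees the count columns
  directly) while the sequence model reads mutation load through stop-codon
  gains, spectrum-shifted composition and frame disruption, and retains a
  residual error of a few percent on short or frame-scrambled driver
  transcripts — training longer does not close the gap. The corresponding
  parity check in the acceptance suite fails by this margin and is left
  failing deliberately; it quantifies a real property of the architecture.
- Insertions beyond the reference codon count are tail-truncated, so
  signal within the truncated tail is lost.
- The per-transcript encoders give the model O(T·d·C²·K) parameters;
  at hundreds of samples the head can memorise the training set, and
  nothing in the protocol regularises it beyond the architecture itself.
- `N` bases silently zero their codon row; a reference full of `N` yields
  all-pad inputs and an uninformative transcript.
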