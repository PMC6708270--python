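# Methods

## Pipeline model

A carrier-sequencing run is modelled as a mixture of read populations: a
dominant carrier population sequenced from a small known genome, rare
target and contaminant reads from unknown genomes, and channel-localised
noise reads from malfunctioning pores. The pipeline assigns each read a
single label — `carrier`, `low_quality`, `low_complexity`, `hqnr`,
`target` — in that stage order; labels are single-assignment, so a read
failing both quality and complexity is recorded as `low_quality`. The
order of the two QC filters is arbitrary but fixed and documented; the
partition counts always sum to the input count.

### Carrier subtraction

The original workflow mapped reads to the carrier with an external
aligner. Here the decision is made by a canonical k-mer classifier: the
carrier index holds the lexicographic minimum of each genome k-mer and its
reverse complement (k = 17, odd so no k-mer is self-complementary), and a
read's *shared fraction* is the number of its windows whose canonical
k-mer is in the index divided by `len − k + 1`. Windows containing an
ambiguous base count as misses in both index and read. This makes the
classifier exactly strand-symmetric, self-contained, and testable against
an exhaustive string-set oracle; it deliberately provides no base-level
alignments, CIGARs, or mapping qualities, which nothing downstream needs.

The carrier call threshold is a shared fraction ≥ 0.05, set by separating
two regimes computable in closed form:

* a read unrelated to the carrier collides with a 48.5 kb index at
  ≈ 2·(48,486)/4¹⁷ ≈ 6×10⁻⁶ per window — shared fractions pile up at 0;
* a genuine carrier read with per-base error rate *e* keeps a window
  intact with probability (1−e)¹⁷: ≈ 0.09 at the simulator's 13% combined
  error rate, ≈ 0.17 at 10%, ≈ 0.24 at 8%.

0.05 sits three-plus orders of magnitude above the collision floor and a
factor ≈ 2 below the expected shared fraction at the harshest error rate
considered realistic here. A higher threshold (e.g. 0.25) would reject
genuine carrier reads at any error rate above ~8% and is incompatible with
nanopore-like error; the margin matters most for short reads, where the
shared fraction has high variance because errors kill runs of up to 17
consecutive windows. With the default fragment model (median 6.5 kb,
log-normal σ = 1.0) reads short enough to be at risk are rare, and
measured carrier recall is ≥ 99% per seed with target loss ≈ 0.

### Quality filter

A read's quality is the probability-domain mean of its per-base Phred
scores, −10·log₁₀(mean 10^(−q/10)) — the convention basecaller toolchains
report, which weights bad bases more than an arithmetic mean (Jensen).
Reads with Q < 9 are discarded; the comparison is strict, so a read at
exactly 9 survives. Zero-length reads are assigned Q = 0 and fall here.

### Complexity filter

The DUST score is the maximum over 64-base windows (step 32, final
partial window included) of `sum(c_t*(c_t-1)/2) / (n_triplets - 1)` where
`c_t` counts each overlapping 3-mer in the window; triplets containing N
are skipped, windows with fewer than two countable triplets contribute
nothing, and sequences under 4 bases score 0. A 64-base homopolymer
scores exactly 31; typical non-repetitive sequence scores ~1–2.5. The
screening threshold is score > 7, the conventional default for
DUST-family maskers; window size, step and threshold are all
configurable because the exact dialect behind any given published score
column is generally unspecified.

### Channel noise (HQNR) test

Surviving candidates are tallied per flowcell channel (512 channels). If
candidate reads arose uniformly at random, each channel's count would be
Poisson with λ = total/512; a channel whose upper tail P(X ≥ x) — computed
via the survival function, never 1 − CDF — falls below p = 0.05 is flagged
and **all** of its candidate reads are labelled `hqnr`. This is
deliberately conservative: a true detection sitting on a bad pore is
sacrificed. Three choices are worth making explicit:

* λ is estimated from the post-QC candidate population, because HQNRs are
  defined as high-quality non-carrier reads — that is the population whose
  per-pore concentration the test interrogates.
* No multiple-testing correction is applied by default (Bonferroni is a
  config option). The test is a screen, and at realistic candidate totals
  (tens of reads) the uncorrected false-flag rate is far below 5% of
  channels because counts of ≥ 2 are already improbable.
* Reads whose IDs carry no parseable channel skip the test and fail open
  into the target set: metadata parsing fails open, channel statistics
  fail closed.

Note the test's knife edge at small candidate totals: with total ≥ 27,
1 − e^(−λ) ≥ 0.05 and single-read channels survive; at total ≤ 26 every
occupied channel would be flagged. This is a property of the published
test itself, reproduced faithfully. HQNRs that arrive on otherwise quiet
channels are undetectable by construction; no remedy is attempted.

## Quantitation arithmetic

* ddPCR: with p̂ the positive-droplet fraction, λ̂ = −ln(1 − p̂) copies per
  droplet and copies-per-reaction = n·λ̂. A 95% interval comes from a
  Wilson score interval on p̂ mapped through −ln(1−·) (monotone, so
  endpoints transform directly); Wilson is stable at the near-zero p̂
  where low-input samples live. A saturated plate (p̂ = 1) raises an
  error — the estimator diverges and real practice re-dilutes.
* Genome mass uses 650 Da per double-stranded base pair; a 4,215,606 bp
  genome weighs 4.55 fg, and 1.6×10⁴ single-copy genomes weigh 72.8 pg
  (≈ 70 pg at 10 pg precision).
* Sensitivity in ppb is input DNA mass over sample mass: 10⁴ cells of a
  4.2 Mb organism in 50 mg of soil ≈ 0.9 ≈ 1 ppb.
* Expected target reads per 10⁶ carrier reads follow molecule counts,
  (m_t/m_c)·(L_c/L_t)·10⁶ for masses m and mean fragment lengths L.

## Synthetic runs

The generator emulates the statistical structure the analysis assumes, at
desk scale, with every read truth-labelled:

* genomes: i.i.d. bases at configurable GC (default 0.5); carrier 48,502
  bp; target 100 kb (a stand-in scale — a 4.2 Mb genome is reachable by
  config but buys the tests nothing); one independent 50 kb genome per
  contaminant read.
* run shape: 5,000 carrier / 5 target / 3 contaminant reads by default —
  preserving the "overwhelming carrier, parts-per-million-scale target"
  ratio structure at 250× reduced depth — plus 2 bad-pore channels
  emitting 10 noise reads each. Genuine reads land uniformly on the other
  510 channels; read IDs use the `channel_<N>_<uuid>_template` layout.
* fragments: log-normal, parameterised by median (carrier 6,493 bp,
  σ = 1.0, matching the reference run's median; target 900 bp and
  contaminant 700 bp with σ = 0.4, matching the 267–1,559 bp band in
  which real target reads were observed), clipped to [100 bp, genome
  length].
* errors: substitution/insertion/deletion at 6/3/4% — a nominal
  R9.4-like profile, configurable and not claimed faithful; no
  homopolymer bias.
* quality: per-read mean Phred ~ Normal(10.5, 1.0) truncated to [6, 14]
  (the 9.2–12.7 band observed for real surviving reads sits inside it),
  per-base jitter σ = 1.5. Because shifting all Phred values by d scales
  every error probability by 10^(−d/10), one additive correction makes
  the emitted string's probability-domain mean match the drawn per-read
  mean exactly up to integer rounding.
* bad-pore reads: uniformly random bases (so they share nothing with any
  genome), lengths uniform in 267–865 bp (the band real HQNRs occupied —
  known from only six observations, so a modelling choice), per-read mean
  quality uniform in 9.5–12.7 so that only the channel test can remove
  them.
* ddPCR droplets: each positive with probability 1 − e^(−copies/n),
  one binomial draw.

Passing tests on this generator demonstrate the pipeline's behaviour
under its own assumptions — they do not certify performance on real
flowcell data, where error profiles are position- and context-dependent,
channels die over time, and HQNRs can arrive on quiet channels (six did
in the reference run, and passed).

## Problem sizes and determinism

Everything is driven by `numpy.random.default_rng` seeds; identical
configs give byte-identical FASTQ. The test suite uses one shared
fixed-seed end-to-end run (seed 42, 5,028 reads), five seeds × 2,100 reads
for classifier recall, 1,000 Monte Carlo replicates for the channel-test
null, and 4 × 500 replicates for ddPCR λ recovery — sizes chosen so the
whole suite runs in about a minute while every statistical assertion
retains ≥ 3σ headroom.

## Known limitations

* The carrier classifier is binary; it reports no alignment coordinates
  and cannot distinguish a chimeric carrier/target read.
* The HQNR test shares the published method's blind spots: bad pores
  emitting few reads, and HQNRs on good pores, pass.
* Taxonomic identification of target reads is out of scope; the target
  FASTQ is the hand-off surface.
* Printed summary-table medians follow the convention mean-of-middle-two
  rounded half-up, chosen because it reproduces the reference tables'
  printed medians from their own per-read lengths; no convention was
  stated at the source.
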