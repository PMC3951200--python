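# Methods

## The composite divergence statistic

For each assembly contig with at least one alignment to a reference
genome, the top HSP (high-scoring segment pair) is selected as the hit
with minimum E-value, ties broken by maximum bitscore; remaining full
ties are broken by lexicographically smallest subject name and smallest
subject start, an arbitrary but deterministic rule so that re-running on
a shuffled file gives identical output. The composite statistic is

    composite = (percent_identity / 100) / alignment_length,

the identity fraction normalized by alignment length, mathematically akin
to a per-site distance. Two published anchor values pin this form: a
19 bp alignment at 100% identity scores exactly 1/19 = 0.052631579, and a
20 bp perfect alignment exactly 0.050. An algebraically different
normalization, 1/((identity/100)·length), reproduces the same anchors at
100% identity and diverges from the implemented form only as identity
drops; since in practice every near-boundary hit has ~100% identity the
two coincide where it matters. The implemented direction is the one kept
throughout.

The statistic is strictly increasing in identity at fixed length and
strictly decreasing in length at fixed identity, bounded in (0, 1].
Extremely low values are long, high-identity (conserved) alignments;
extremely high values are short perfect (putatively diverged) hits.

## Outlier definition

The composite distribution is heavily right-skewed and resists standard
transformation, so outliers are defined by order statistics: bounds at
the 0.02th and 99.98th percentiles of the ordered per-comparison
distribution. The percentile convention is linear interpolation between
closest ranks (position (n−1)·q/100 on the sorted sample) — the dominant
default in scientific software; a nearest-rank variant is available via
`percentile_bounds(..., method="nearest")`. Calls are boundary-inclusive
(composite ≥ upper ⇒ diverged, ≤ lower ⇒ conserved) so the printed
boundary values themselves are outliers. A degenerate constant
distribution makes both comparisons true for every point and is resolved
to "no outliers" by rule.

Tail-width arithmetic worth knowing: with the linear convention the
number of points at-or-beyond each bound is determined by (n−1)·0.0002.
For n = 10,000 exactly two points sit in each tail; for n = 10,002 three
do. A planted-outlier experiment with 9,998 background + 2 + 2 planted
rows therefore recovers the planted ids *within* each tail together with
one boundary background contig, rather than matching the planted set
exactly — the recovery tests assert containment, not set equality.

Bounds are computed independently per comparative alignment (one
reference genome at a time); distributions are never pooled.

## E-value step-down acceptance

Hits are accepted through a ladder of E-value thresholds, strictest
first. A query satisfied at a stricter threshold never re-enters later
rounds; each accepted top hit is annotated with the index of the first
threshold its E-value meets, and queries beyond the final threshold are
reported on an explicit no-hit list rather than dropped. The default
ladder [1e-30, 1e-10, 1e-4] is a configuration default, not a scientific
constant: the procedure's published description does not fix its
thresholds, and the 1e-4 floor mirrors the floor used for protein-level
annotation screening in the same kind of pipeline. With a single
threshold t the ladder reduces exactly to top-hit selection on hits
filtered at E ≤ t (a tested invariant).

## Quality control

**Non-overlapping recomputation (conserved outliers).** Large conserved
contigs typically carry appended HSPs below the top hit. These are tiled
greedily in descending bitscore order (ties by ascending query start), an
HSP being accepted iff its query interval — treated as 0-based half-open
to avoid ±1 drift — overlaps no previously accepted member by ≥ 1 bp.
Overlap is judged on the query only; subject overlap is permitted, since
the concern is contig coverage. The combined identity is the
length-weighted mean of member identities (recomputing from raw match
counts is impossible without per-HSP match counts when gaps are present),
and the composite is recomputed as (weighted identity/100)/(summed
length). A conserved call is confirmed iff the recomputed composite stays
at or below the conserved bound. Adding aligned length at identity within
a few points of the top hit can only shrink the statistic — the relative
identity gain is bounded by δ/identity ≪ 1 while the length grows
proportionally — so comparable-identity appended data confirms, never
overturns, conservation; the suite verifies 100% confirmation on
synthetic conserved outliers with appended HSPs within ±5 identity
points.

**Trace false positives (diverged outliers).** A diverged call is
overturned when any alternative-database alignment scores at least 15%
more bits than the original top hit (boundary inclusive: 1.15× exactly is
a false positive). Alternative bitscores are supplied as a table; no live
database queries are performed.

**Correlation controls.** Pairwise Pearson r and Kendall τ over contig
size, contig GC fraction, top-hit percent identity and alignment length,
joined on contig id (≥ 3 rows required). τ is the tie-corrected τ-b
variant — the published analysis says only "nonparametric τ", and τ-b is
the standard choice in the presence of ties. A constant column has
undefined correlation and is reported missing with a warning rather than
silently zeroed.

**Size percentile control.** The same extreme-percentile machinery
applied to the raw contig-size distribution, intersected with the
composite outlier ids. A small overlap argues that contig size is not
deterministic for outlier status.

## Genome summaries and PSMC preparation

Variant filtering retains records with coverage inside a closed window
and call probability at or above a floor; it is order-preserving and
idempotent. Heterozygosity density is variants per Kbp of assembled
length; reports present the value rounded to two decimals (round-half-
even) alongside the unrounded number. The documented denominator for the
published worked examples is the 1.172 × 10⁹ bp scaffolded assembly
length (including gap N's), which reproduces both printed densities
(3.22 total, 2.99 SNP-only) from the printed variant counts.

PSMC input binning maps each 100 bp window to 'K' if it contains at least
one retained heterozygote, otherwise to 'N' if more than 50% of its
positions are uncallable, otherwise to 'T'; the final window may be
short (ceil rule). The >50%-uncallable threshold is a documented stand-in
for the reference preparation tool's internal default, which is not
stated anywhere authoritative. Output is FASTA-like, wrapped at 60
symbols.

Repeat-class and microsatellite summaries are plain grouped sums with
validation (motif lengths restricted to 2–10 bp, matching the tandem-
repeat search settings they summarize). Genome size from the haploid
C-value uses the standard conversion 0.978 × 10⁹ bp per picogram.

## Demography

Generation time g = a + s/(1−s): age at sexual maturity plus the expected
remaining adult lifespan under constant annual survival s (diverges as
s → 1, rejected at s ≥ 1). A helper takes a list of survival rates from
independent field studies and returns the median g, the way a species
value is summarized across surveys; no literature data is bundled. PSMC
axis conversions take the time axis literally as per-site pairwise
divergence x = 2µT (T in generations), so years(x) = g·x/(2µ), and the
population axis as the scaled mutation rate θ with Ne = θ/(4µ). Peak-Ne
values read off published figures are not encoded as truths anywhere in
the package. Default mutation-rate scenarios are 1.1 × 10⁻⁸ and
2.5 × 10⁻⁸ per site per generation.

## Synthetic data

The generator emulates a draft-assembly-versus-reference comparison at
the alignment-summary level (no sequences are simulated — the pipeline
consumes alignment summaries, so that is where simulation happens):

* background top hits: identity ~ Normal(83, 5) clipped to [60, 100]
  percent (centering near the ~83% level seen in a quail-to-chicken
  comparison), alignment length ~ lognormal(6.55, 0.70) clipped to
  ≥ 25 bp (median ≈ 700 bp with the heavy right tail characteristic of
  real composite distributions; the bulk's true distributional form is
  unknown, and the lognormal is an explicit stand-in whose parameters are
  exposed on the spec so tests can shape tails);
* planted diverged contigs: a single 19–20 bp alignment at 100% identity
  on a 300–1,471 bp contig;
* planted conserved contigs: a single 9,647–89,591 bp alignment at
  95–100% identity.

Planted diverged rows are separable from background by construction:
their composite is ≥ 1/20 = 0.05 while any background row (length ≥ 25)
scores ≤ 0.04. Conserved-side separation is distributional rather than
absolute — the background length tail is thin enough that the two planted
conserved contigs are the smallest composites in almost all tables — and
the suite measures recovery across 100 seeds (≥ 95 required; 98 observed
at the frozen defaults). Coverage in the variant generator is
negative-binomial (mean 77, matching a ~77× assembly; dispersion 5)
rather than Poisson, to emulate the overdispersion implied by wide
real-data coverage filters. Each table draws from its own stream,
`default_rng([stream_code, seed])`, so generating one table never
perturbs another; identical spec + seed is byte-identical.

What passing on synthetic data does *not* show: the generator plants one
HSP per contig with independent rows, clean separability classes and no
paralogy, repeat-induced multi-mapping, chimeric contigs or reference
assembly gaps — the phenomena the QC battery exists to catch in real
data. Green tests demonstrate the machinery is correct, not that any
particular real genome's outlier list is.

## Problem sizes

The test suite and the acceptance script run the recovery and capture
experiments on tables of 10,000–10,002 contigs across 100 seeds, and QC
confirmation on 10 seeds of 10,000 — sizes at which the tail arithmetic
(2–3 points per tail) is meaningful and the full suite completes in well
under a minute, chosen as the package's own desk-scale defaults.

## Known limitations

* The composite formula's normalization direction is reconstructed from
  printed anchor values (see above); both candidate forms agree at the
  anchors.
* The percentile convention of the original analysis is unknowable from
  its description; linear interpolation is frozen as the default and the
  nearest-rank alternative is one switch away.
* The E-value ladder thresholds live in configuration, not code.
* No coalescent inference, bootstrap, variant calling, repeat detection
  or aligner execution: the package prepares inputs for and rescales
  outputs of those tools only.
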