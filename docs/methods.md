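# Methods

## Problem setting

A rare risk allele observed in several members of a population isolate is
presumed to descend from one founder haplotype. Recombination whittles
that haplotype down each generation, so the segment still shared by all
present-day carriers around the variant is short relative to the
chromosome but long relative to chance sharing — and its length carries
information about the age of the founder event. `founderhap` delimits
this segment at variant-level resolution, bounds it when phase is
unavailable, compares it across genotyping platforms, and quantifies the
allele's enrichment relative to an outbred reference cohort.

## Data model and conventions

Panels hold ordered biallelic SNVs on a single chromosome with allele
codes 0 (ref), 1 (alt) and −1 (missing). Coordinates are 1-based; all
reported intervals are closed `[left_pos, right_pos]`, and the base-pair
length of a closed interval is defined as `right_pos − left_pos` — the
distance spanned between the boundary variants, not a site count. Genetic
lengths come from a piecewise-linear map (bp → cumulative cM),
interpolated linearly and clamped at the terminal anchors.

VCF parsing rules: multi-allelic and non-SNV records are dropped (the
analysis is defined on biallelic SNP haplotypes; splitting multi-allelics
would create ambiguous dosage semantics); duplicate positions keep the
first record; a record containing an *unphased heterozygote* in any
sample is dropped panel-wide, keeping every haplotype sequence
index-aligned on identical site support. Unphased homozygotes are kept —
their phase is unambiguous, and real VCFs routinely emit hom-ref calls
with `/`. Missing alleles are preserved as missing; a half-called
genotype keeps its called allele only when the separator is phased
(otherwise the haplotype assignment of the called allele is unknown and
the genotype becomes fully missing).

## Stepwise shared-haplotype search (phased data)

For each listed carrier the haplotype bearing the risk allele at the
focal site is identified (heterozygotes contribute one haplotype,
homozygous-risk carriers both; listed samples without the risk allele are
excluded with a warning). For a pair of carrier haplotypes the shared
segment grows outward from the focal index one variant at a time, in each
direction independently, stopping at the first site with two called,
unequal alleles. The segment boundary is the last *matching* variant (the
inner bound); the positions of the first mismatches are retained so the
outer span can be recovered.

Missing data policy: the source studies of this design do not state one,
so the default treats a site with a missing allele as *non-informative* —
it is included, counted in `n_missing_skipped`, and the scan continues.
Array data have low missingness and a single dropped call should not
truncate a long founder haplotype. A `strict` mode (missing is a stop) is
provided for sensitivity analysis.

Over all pairs (same-sample haplotype pairs excluded — a homozygote's two
haplotypes are evidence about the lineage, but their self-comparison is
not an inter-individual observation), the result records every pairwise
segment, the shortest (ties broken lexicographically by sample and
haplotype index, so output is byte-stable), and the *core*: the closed
intersection of all pairwise intervals, which always contains the focal
site.

Chance matching in flanking markers can extend a detected segment beyond
the true IBD boundary but — absent genotyping error — can never truncate
it; this containment (detected ⊇ truth) is the central invariant the
simulator verifies. Containment is evaluated at marker resolution: the
continuous true IBD interval is clipped to the outermost markers it
contains, since a stepwise search can only place boundaries at genotyped
sites and the true breakpoint generically falls between markers.

## Opposing-homozygote bound (unphased data)

Two samples homozygous for different alleles at a site share no haplotype
there under any phasing — the only certain contradiction available
without phase. Scanning outward from the focal site, each direction
terminates at the nearest such site; missing dosages are counted but
never terminate (they cannot prove non-sharing — the operation computes
an upper bound, and only certain contradictions may shrink it). If a
panel end is reached the bound is the terminal site position with an
explicit `open` flag rather than a fabricated coordinate — the typical
outcome when comparing a distant cohort's carrier with no exclusions in
the covered region. `n_variants_between` counts the sites where sharing
remains possible: strictly inside a closed bound (the opposing site
itself is an exclusion), inclusive at an open end. A multi-sample
consensus bound is the intersection of the pairwise bounds.

## Cross-panel matching

Two panels are intersected on position and allele-harmonized against the
first panel: identical ref/alt pass through, swapped ref/alt flips the
second panel's codes, strand complements relabel, and strand-ambiguous
(A/T, C/G) sites are kept only on exact match. Each panel's shared
segment is represented by the consensus allele sequence of its defining
pair, and the two representatives are compared over the intersected sites
inside both segments. The verdict is a match iff no compared site has two
called, unequal alleles; zero informative overlapping sites is reported
as a distinct error, not a verdict.

## Frequency and enrichment statistics

Frequencies use exact Clopper–Pearson intervals (beta quantiles; default
95%). The allele-frequency denominator is 2N; carriers are assumed
heterozygous unless an explicit allele count is given — the situation of
a rare dominant-risk founder allele, where carrier frequency ≈ 2× allele
frequency. Fold enrichment is the allele-frequency ratio with the Katz
log-ratio normal interval (`SE² = 1/a₁ − 1/n₁ + 1/a₂ − 1/n₂`) and a
two-sided Fisher exact test on the 2×2 allele table (summing all tables
with probability ≤ the observed). A zero-count reference yields an
infinite ratio with a continuity-corrected one-sided bound. The point
estimates reproduce printed cohort arithmetic exactly; the intervals and
test are an added minimal inferential layer, clearly separable from that
reproduction. The grandparental-ancestry summary counts birthplaces over
each carrier's four grandparents (exactly four required; "unknown"
allowed) and orders places by descending count, ties by name.

## Gene-dropping simulator

The simulator exists so every stage can be tested with known truth, since
individual-level cohort data of this kind are access-controlled.

- **Founders.** Haplotypes are drawn site-wise independently from
  background allele frequencies (default uniform on [0.1, 0.5],
  array-like common variants). There is deliberately no background LD:
  chance-sharing behaviour is controlled through the frequencies and the
  marker density, which suffices for validating the sharing algorithms. A
  single designated founder haplotype carries the focal allele; its
  background frequency is zero elsewhere.
- **Meiosis.** Crossover counts are Poisson(map length in Morgans) with
  positions uniform in genetic distance (Haldane, no interference — the
  simplest model consistent with the closed-form expectations used in
  testing); the transmitted gamete alternates parental haplotypes across
  crossovers, starting from a fair coin.
- **Truth.** Founder-origin intervals are propagated exactly alongside
  alleles as half-open bp intervals; for any two sampled haplotypes the
  true IBD segment around the focal position is the intersection of their
  focal-founder-origin intervals. Origin intervals tile the chromosome
  exactly (tested).
- **Conditioning.** Listed individuals are made carriers by
  rejection-sampling each meiosis on their lineage path until it
  transmits the focal founder haplotype at the focal position. Because
  crossover positions are independent of which haplotype is present at a
  point (the starting phase is a fair coin), this conditioning leaves the
  recombination process unbiased given carriage; the 2/m-Morgan
  closed-form check runs on conditioned pairs and confirms it.
- **Observation.** After truth is recorded: symmetric allele flips at
  rate ε per allele call, then missingness at rate μ per genotype
  (both alleles). Defaults ε = 10⁻³, μ = 2×10⁻³ — typical residual rates
  after array QC; no source values exist for them. Chips subset the
  marker panel to emulate cross-cohort array differences.
- **Reproducibility.** All randomness flows from the single config seed;
  identical inputs give byte-identical VCFs.

Expected IBD length: for two carriers separated by m meioses, the
distance from the conditioned focal point to the nearest crossover in any
of the m meioses is Exp(m) per side (in Morgans), so the two-sided
segment length has mean 2/m Morgans, truncated by the chromosome ends;
the end-corrected expectation `Σ_side (1 − e^{−m·c_side})/m` is verified
by Monte Carlo at m ∈ {2, 4, 8}.

### The packaged demo (`westray_demo`)

Five kindreds descend from one founder couple eight generations up; four
sampled members per kindred (20 conditioned carriers) plus 2000 unrelated
background samples, 2000 markers on an 80 Mb chromosome-17-like region at
1 cM/Mb with the focal variant at 41,196,408 bp. Cross-kindred carrier
pairs are separated by 16 meioses (expected pairwise sharing
2/16 Morgans = 12.5 Mb at 1 cM/Mb); intersecting 190 pairwise segments
leaves a core of a few megabases — the same order as published founder
haplotypes of this age. The sampled carrier fraction is 20/2020 ≈ 1%.

What passing tests on this generator do *not* show about real data: no
background LD (real chance sharing is longer-range), no phasing errors
(real phased panels contain switch errors that truncate detected
segments), a sex-averaged uniform map, and no ascertainment bias in the
background samples. The unphased bound and the missing-data policies are
the components least affected by these simplifications.

## Numerical and degenerate-input choices

- Interval arithmetic is integer bp end-to-end; cM values are float64
  linear interpolation (monotone by construction).
- Ties for the shortest segment break lexicographically; pair enumeration
  is sorted; JSON output is key-sorted with fixed float formatting — all
  outputs byte-stable across reruns.
- Degenerate inputs are fatal with diagnostics rather than silently
  absorbed: focal site absent, all listed carriers discordant, fewer than
  two carrier haplotypes, self-comparison in the unphased scan, empty
  harmonized intersection, zero retained VCF records, pedigree cycles,
  non-founder focal founder, non-monotone genetic maps.
- A mismatch *at the focal site itself* between two carrier haplotypes is
  a phase/carrier inconsistency and is fatal, not a zero-length segment.

## Problem sizes

Defaults throughout (2000 markers, ~2000 background samples, 190 carrier
pairs, 5000 replicates per meiosis count in the recovery checks, 2000
binomial replicates for interval coverage) are desk-scale choices that
keep the full validation suite in the low minutes on one core while
leaving Monte-Carlo standard errors well below the tested tolerances.

## Known limitations

- Sharing detection reports the inner bound (last matching variant); the
  outer span is only logged via first-mismatch positions. Whether a
  published "minimum shared length" refers to inner or outer span varies
  between studies; both are available here.
- The stepwise search assumes correctly phased input; it does not detect
  or correct switch errors, and there is no windowed/coarse prefilter —
  at regional scale none is needed.
- No genotype likelihoods: the unphased scan treats called dosages as
  true, so a single genotyping error can spuriously close a bound (the
  error-rate sensitivity of truncation is itself tested and reported, not
  corrected).
- Enrichment inference conditions on published counts; it does not model
  relatedness within the isolate cohort, which inflates the effective
  variance of the isolate frequency estimate.
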