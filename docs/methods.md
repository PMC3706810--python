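# Methods

`popseqsim` simulates mapping-by-sequencing experiments at **marker
resolution**: no nucleotide sequence is ever represented. A genome is an
ordered list of chromosomes with lengths; a marker map is an ordered list of
1-based positions with per-marker coverage-normalization weights. This
matches what the downstream analyses consume — read counts at marker and
mutation loci — and makes whole-design sweeps (hundreds of thousands of
simulated experiments) cheap.

## Recombination model

Crossover counts per chromosome per meiosis are drawn from a three-category
model: probabilities (p₁, p₂, p₃) of none, one, and two-or-more crossovers.
The two-or-more category is resolved to a realized count 2 + G with G
geometric (continuation probability 0.1, so ≥3 crossovers occur ~10% of the
time within that category) — empirical plant data contain very few triple
crossovers, and the continuation probability is a configuration key
(`tail_continuation`).

Crossover placement follows per-marker-interval recombination frequencies
p_mᵢ: a crossover falls in the half-open interval (posᵢ₋₁, posᵢ] with
probability p_mᵢ and uniformly per bp inside it (density p_mᵢ/lᵢ). Entry 0
covers the chromosome start up to the first marker. Because nothing
constrains crossovers beyond the outermost marker, a terminal interval from
the last marker to the chromosome end is appended internally, weighted by
its length under the last interval's local rate — a documented choice, not
an empirical claim.

The first crossover of a meiosis is drawn from the marginal density;
each subsequent crossover sits a gamma(shape, scale)-distributed distance
beyond the previous one in *normalized genetic coordinates* (the cumulative
p_mᵢ scale), modelling crossover interference between all successive pairs.
With shape k the inter-crossover spacing has coefficient of variation 1/√k;
the default shape 2 gives moderate interference, and the scale defaults to
1/(shape·(c+1)) for mean crossover count c, so the mean spacing matches the
expected inter-crossover distance. Draws overrunning the chromosome end are
redrawn up to 8 times and then truncated to a uniform point in the
remainder (logged at DEBUG); near chromosome ends this slightly compresses
spacings, which is why the spacing-CV property is checked at short spacing
scales where truncation is negligible.

Gametes are spliced from the two parental homologs, starting from either
homolog with probability 1/2 and switching at every crossover. A haplotype
is a breakpoint list plus the origin label of the first segment; mutation
genotypes are *derived* from segment origins (founder-origin segments carry
all founder mutations), so genotypes and breakpoints cannot disagree by
construction.

## Synthetic landscapes

`synthesize_landscape` generates species-like inputs: Arabidopsis-like
(5 chromosomes, 119.1 Mb), rice-like (12 chromosomes, ~373 Mb) and
barley-like (7 chromosomes, ~4.6 Gb) presets with standard reference
chromosome lengths. Markers sit on a jittered grid; coverage weights are
gamma-distributed with mean 1 and CV 0.3, a coarse stand-in for the
locus-to-locus coverage variability (GC content, mappability) of Illumina
resequencing. The `peaked` hotspot profile suppresses recombination around
the chromosome midpoint and elevates it distally — a caricature of plant
landscapes, selectable per experiment; `uniform` gives a constant per-bp
rate. The default mean of 1 crossover per chromosome per meiosis
corresponds to a ~100 cM chromosome, the right scale for Arabidopsis.
What the generator does **not** emulate: real hotspot fine structure,
centromeric marker deserts, segregation distortion, and real repeat/CNV
architecture. Passing tests therefore demonstrate correctness of the
machinery and the qualitative design trade-offs, not quantitative
transferability of interval sizes to any particular cross.

Marker filtering reproduces standard high-quality SNP selection: drop
quality < 25 and CNV-overlapping markers, then iteratively remove markers
closer than 50 bp, scanning left to right and dropping the right member of
each offending pair until a fixed point — deterministic, order-stable, and
idempotent.

## Breeding and pools

Outcross: founder × diverged accession, self the F1. Backcross: n rounds of
crossing to the isogenic parent followed by one selfing. The individual
carried into each backcross round must normally be a heterozygous carrier of
the causal allele (`carrier_parent=True`) — otherwise the final F2 could
contain no mutants; homozygous carriers cannot occur in BC generations. The
unconditioned mode (`carrier_parent=False`) drops this requirement and is
the regime in which the mean foreground (founder-derived) genome fraction
follows the classical halving formula exactly: recurrent fraction
(2ⁿ⁺¹−1)/2ⁿ⁺¹ after n rounds.

This distinction matters quantitatively. Conditioning on the causal allele
drags linked founder genome along: selected causal-homozygous BC2F2
individuals retain ~21% foreground on the Arabidopsis-like landscape versus
12.5% unconditioned (and ~14% vs 6.25% for BC3F2) — linkage drag of tens of
centimorgans around a selected locus is a classical introgression result.
The headline foreground percentages reproduced by `scripts/acceptance.py`
(~12.5% and ~6.25%) are therefore the *population-level* quantities of
unconditioned backcross lineages, the only regime consistent with the
halving theory they are compared against; the selected-mutant elevation is
asserted qualitatively in the test suite.

Mis-scored plants are real phenotypically wild-type siblings (heterozygous
and homozygous wild-type in their natural proportions) substituted into the
pool — `round(rate · n)` of them — rather than synthetic allele flips,
because that is what mis-phenotyping does in practice.

## Sequencing model

Total reads m = round(coverage × number of sequenced loci) are allocated to
loci by a single multinomial draw over normalized coverage weights, so
coverages sum to m exactly and locus-to-locus variability follows the weight
landscape. Mutation loci absent from the marker map get weight 1 (genome
average). Allele assignment is trinomial with probabilities
(a₁(1−s), a₂(1−s), s): the naive triple [a₁, a₂, s] is improper since
a₁+a₂=1, so the allele masses are scaled by (1−s), preserving the error mass
exactly. Error-category reads are then re-assigned to the two parental
alleles with probability 1/2 each (`error_mode="split"`, default) or
entirely to the allele the sampled chromosome does not carry
(`error_mode="flip"`); the split rule is the minimal symmetric model, and
the observable consequence — an other-allele read floor of s/2 at fixed
loci — is tested. Target-enrichment mode restricts reads to loci flagged
`enriched` and zeroes the rest.

## Candidate-mutation calling (backcross)

A mutation is called homozygous iff coverage ≥ `min_coverage` (default 2;
at c_p = 1 the read threshold is vacuous) and its observed mutant read
frequency strictly exceeds both

* g_f = 1 − (2m + 1)/(2n) — frequency if one wild-type chromosome hid among
  the 2n chromosomes of a pool with m mis-scored plants, and
* r_f = 1 − e − 1/c_p — frequency if one read of c_p came from a wild-type
  chromosome, at per-read error rate e (default 0.003).

m defaults to 0; experiments studying mis-scoring must set it. Both
thresholds are < 1 for all valid inputs; g_f decreases with m, r_f
increases with coverage.

## Mapping interval (outcross)

The interval estimator is this package's own construction (the published
pipelines delegate to external tools); its contract is *calibration*: the
causal mutation must lie inside the P = 0.99 interval in ≥ 99% of simulated
experiments. Read counts are aggregated over a sliding window of W markers
(W = "auto": ~2% of the chromosome's markers, capped at 201, keeping the
smoothing span near the centimorgan scale at any marker density). The
window's binomial log-likelihood ratio against the genome-wide null
frequency 0.5 is computed on an **effective** count scale

    n_eff = 1 / (1/reads + 1/(2·pool_size)),

because reads within a window repeatedly sample the same 2N pool
chromosomes: information about the local allele frequency saturates at the
chromosome count no matter how deep the sequencing. The peak (leftmost tie)
locates the linked region, and the interval is the maximal contiguous run
around the peak where the peak-vs-position test statistic stays below a
chi-square(1) quantile at P. The test is applied in its studentized (Wald)
form on the frequency scale — asymptotically equivalent to the
likelihood-ratio drop but numerically robust where frequencies approach 1
and the KL divergence's curvature diverges — with a dispersion inflation
κ = 2 compensating for selecting the peak as a maximum over many correlated
windows. κ was fixed once by a coverage-calibration study on simulated
outcross pools (pool sizes 50–400, coverages 15–200x) and is not exposed as
a tuning knob. If no window reaches an elevated frequency (default 0.6) the
whole genome is returned with a warning flag. Windowing makes the estimator
deliberately conservative: intervals on the sparse synthetic maps are a few
Mb, wider than what dense empirical marker sets support, but their
*responses* — shrinking with pool size, nearly flat in coverage — are the
design-relevant outputs.

CAMs of an outcross experiment are the induced mutations inside the
interval; of a direct-sequencing experiment, the homozygous calls on a
single genome treated as a pool of size 1 (g_f = 0.5, so heterozygous
background mutations are rejected by the read-frequency threshold at any
reasonable coverage).

## Single-end vs paired-end comparison

100,000 random alignment locations per configuration, uniform over the
space where the full span fits (read length for SE; 3× read length for PE —
the fixed insert multiplier, with no variance, as the only stated
constraint). A draw is informative iff at least one marker falls inside the
read, or inside either mate of a pair — a pair counts once, since both
mates report the same sampled chromosome; a marker inside the unsequenced
inner gap does not count. Multi-mapping is modelled as an excluded-region
mask whose overlapping draws are discarded before scoring; computing real
alignability from sequence is out of scope, so the published excess
percentages for Arabidopsis (which depend on its repeat structure) are not
reproduction targets.

## Orchestration, RNG and problem sizes

A sweep is a pure function of (config, seed): every replicate draws from a
child `SeedSequence` keyed by the root seed, the (pool size, coverage) cell
and the replicate index, so any replicate can be reproduced in isolation.
Population sizes are chosen adaptively (expected 1/4 mutant fraction plus a
safety margin, regrown if selection falls short). Defaults follow the
design-study conditions: 1,400 mutations, 500 replicates per cell for
production sweeps; the test suite and the acceptance script use 100–300
replicates per comparison and 1,000 markers per chromosome, sizes chosen so
the full suite completes in a few minutes while keeping Monte-Carlo error
well inside the asserted tolerances (replicate counts are always recorded
in outputs).

## Known limitations

No four-strand chromatid modelling, gene conversion, or sex-specific maps;
no fitness or viability effects; no de-novo mutation during breeding; no
read-level artefacts beyond the flat error rate (no indels, base-quality
models, or non-random error spectra); recombination-landscape inference
from genotype data is out of scope — empirical landscapes enter only
through the input files.
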