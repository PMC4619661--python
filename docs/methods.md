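# Methods

This note documents the models behind `flm-sweepmap`, the parameter
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical conventions a reimplementer would
need.

## Extreme-pool mapping model

**Cross and phenotype.** The mapping simulator models an F2 population
from a cross between a reference line and a line carrying a recessive
early-flowering allele. Each individual receives two recombinant gametes;
crossovers follow the Haldane model (count ~ Poisson(genetic length in
Morgans), positions uniform on the physical map, no interference) — the
simplest standard model, adequate for parameter-recovery testing.
Phenotype is `base_days − effect_days·I(genotype at causal locus = 2) +
N(0, noise_sd)`: strictly recessive, with Gaussian measurement/environment
noise. An optional `self_once` flag interposes one selfing round so pools
of selfed (F3-style) recombinant families can be mimicked; the mapping
statistic itself is agnostic to the generation.

**Defaults as study conditions.** `n_f2 = 1000`, pools of 15 early / 9
late plants, 300 evenly placed SNP markers over 1 Mb, causal locus at the
center, `effect_days = 10`, `noise_sd = 1` day, pool depth 60×. The
flowering-time baseline of 60 days is arbitrary and configurable. The
region's genetic length defaults to **100 cM**: the simulated 1 Mb is
stylized as one full linkage group (about one crossover per gamete, the
scale of an *A. thaliana* chromosome). This choice is forced by the
biology of extreme-pool mapping: localizing a peak requires recombinant
gametes segregating *inside* the scanned window — with a literal ~4 cM/Mb
physical ratio, 24 pooled plants carry essentially no informative
breakpoints and the Δf profile is a flat plateau. The original fine-mapping
experiment solved the same problem by selecting plants with recombination
events inside the interval before pooling.

**Pool sequencing.** Per SNP and pool, sequenced depth is
Poisson(mean depth) and the alt count Binomial(depth, true pool allele
frequency). Base-calling error is folded into the binomial sampling (no
explicit error model): the Δf statistic operates on called allele counts.
An `analytic=True` mode returns the infinite-depth limit plus the exact
pool frequencies for oracle tests.

**Expected signal.** With a recessive early allele and noise ≪ effect, the
early pool is fixed for the alternative allele (f = 1) and the late pool —
a 1:2 mix of homozygous-reference and heterozygous plants — sits at
f = 1/3, so Δf = f_early − f_late peaks at 2/3 and decays with
recombination distance. The sign convention (early minus late) makes the
recessive early allele produce positive peaks.

## Δf scan

**Filters** (all configurable; defaults are the analysis constants of the
study design): per-pool coverage within [30, 120] inclusive — per-pool
rather than combined is the stricter reading; alt frequency strictly
greater than 0.20 in at least one pool; a variant call present in both
pools (`called_in_both`, set upstream — variant calling itself is out of
scope); parental alternative-allele frequency ≥ 0.80. Rejections are
logged with the first failing rule in the fixed order coverage →
frequency → presence → parental. Filtering is idempotent and
order-independent.

**LOESS.** Tricube-weighted local polynomial regression on genomic
position, span 0.75, degree 2 (the common defaults of the R routine),
no robustness iterations. Neighborhood size is `q = ceil(span·n)` (at
least degree+1); distances are scaled by the q-th nearest distance, so
the furthest neighbor receives weight (1−1³)³ = 0. Duplicate positions
are allowed; an all-zero weight row falls back to uniform weights over
the q nearest points. The local design matrix is centered at the
evaluation point and distance-scaled for conditioning; each fit solves
the 3×3 weighted normal equations (batched over evaluation points), with
a least-squares fallback for singular neighborhoods. Degree-2 LOESS
reproduces polynomials up to degree 2 exactly, which the tests exploit.

**Confidence band.** The 95% band around each smoothed pool track is a
case-resampling bootstrap: SNPs resampled with replacement, curve re-fit,
pointwise 2.5%/97.5% quantiles across 200 seeded replicates. Chosen for
being assumption-light and reproducible.

**Interval and peak calling.** Maximal runs of consecutive SNP positions
with Δf strictly above the threshold (default 0.25) become half-open
intervals `[first, last+1)`; each carries Δf_max at the leftmost position
attaining the run maximum (leftmost tie-break). Coordinates are 0-based
half-open internally and 1-based in text reports.

**Rough-mapping marker scan.** For genotyped extreme plants, per-marker
group allele frequency is mean(genotype)/2 and the p-value is a two-sided
Fisher exact test on the 2×2 allele-count table (scipy); monomorphic
markers give p = 1.

## Insertion genotyping

Two breakpoint targets are spliced from 140 bp of genomic flank plus
140 bp of insertion end (left: flank + insert start; right: insert end +
flank), each with the junction at offset 140 (0-based index of the first
base 3' of the breakpoint). Reads and their reverse complements are
aligned end-to-end against both targets with unit-cost edit distance,
gaps allowed (edlib, infix mode: free target ends). Placements within
`floor(0.05·L)` edits are retained; a read is *unique* when exactly one
placement across both targets, both strands and all offsets attains the
minimal retained distance. The 5%-of-read-length budget maps the
"single base pair differences including gaps" tolerance directly onto
edit distance.

A retained alignment is **core** when the junction offset within the read,
o = junction_offset − start, satisfies `ceil(L/4) ≤ o ≤ floor(3L/4)` —
inclusive bounds, so for L = 100 the core offsets are exactly 25..75. The
boundary inclusivity is this package's documented convention. Presence
requires at least `min_reads = 2` unique core reads at *both* breakpoints;
raising `min_reads` can only flip calls from present to absent. An
optional `dedup` flag counts reads with identical sequence and identical
placement once (whether the original analysis deduplicated is unknown;
default off).

The read simulator draws uniform fixed-length (default 100 bp, single-end)
read starts at a target depth from either the carrier allele
(ref[:pos] + insert + ref[pos:]) or the reference, applies i.i.d.
substitution errors, and records per-read truth (source offset, junction
spanning). No quality-score modeling, indel errors, GC bias or
mappability structure is simulated.

## Expression quantification

- **Profile normalization**: per-nucleotide counts divided by the profile
  maximum, so values span 0 (no expression) to 1 (maximum); all-zero
  profiles map to zeros. Replicate bands use a single divisor — the
  maximum of the replicate-mean profile — so all replicates share one
  scale (per-replicate scaling by flag).
- **Replicate band**: pointwise mean and empirical 5%/95% quantiles with
  numpy's linear-interpolation rule; with three replicates these approach
  the pointwise min/max.
- **Exon usage**: per replicate, counts summed over each exon interval;
  the diagnostic ratio is exon-1 sum over the summed downstream exons
  (2..K), reported as mean ± sample SD (ddof = 1). Raw within-replicate
  counts are used — the ratio is scale-invariant within a replicate.
  Zero-denominator replicates are excluded with a warning. Premature
  termination of a fraction t of transcripts downstream of intron 1
  inflates the ratio by 1/(1−t) relative to a control, which the
  coverage simulator (piecewise-constant expectation, gamma-Poisson
  overdispersion) reproduces.
- **ΔΔCt**: ΔCt = Ct_target − Ct_reference per replicate; ΔΔCt = mean ΔCt
  minus the calibrator's mean ΔCt; fold change 2^(−ΔΔCt), amplification
  efficiency assumed exactly 2 (no efficiency correction). SE of ΔΔCt
  combines the two samples' replicate ΔCt variances; the fold-change SE is
  delta-method propagated (ln2 · fold · SE). The calibrator's fold is
  exactly 1 by construction. Shifting all Ct values by a constant leaves
  fold changes unchanged.
- **Isoform ratios**: (δ/β) per accession divided by the reference
  accession's δ/β; zero β flagged as undefined rather than dropped.
- **Regression**: ordinary least squares of flowering time on expression
  (scipy `linregress`); R² = 1 − SSE/SST, defined as 0 for a constant
  response; constant expression is an error.
- **Mann-Whitney association test**: for n1+n2 ≤ 20 the null distribution
  of the mid-rank U statistic is enumerated over all C(n1+n2, n1)
  labelings of the pooled observations (ties handled exactly by
  mid-ranks), and the two-sided p is min(1, 2·min(P(U ≤ u), P(U ≥ u))).
  Larger samples use scipy's tie-corrected normal approximation.

## Allele dating

Star divergence of two lineages from a common ancestor: expected pairwise
differences 2μLT, hence T = k/(2μL) generations; no multiple-hit
correction (k ≪ L in the regime of interest). k and L are means over all
sequence pairs; alignment gaps and ambiguity codes are excluded from both
counts of a pair. Interval parameters combine at their extremes to the
widest bracket; k = 0 returns age 0 flagged unresolved. With k = 2,
L = 5700, μ ∈ [6, 7]×10⁻⁹ and 1–3 generations/year, the bracket is
≈ 8,354–29,240 calendar years.

## Orchestration

All randomness derives from a single configured seed (numpy
`default_rng` seeded with (seed, stage-tag) sequences), so equal
configurations produce byte-identical outputs. Configuration is one
declarative TOML/YAML file plus CLI overrides (CLI wins); unknown keys
and out-of-range parameters are rejected before any stage runs, as are
stage selections whose inputs are not produced in the same run.
Simulation stages are selected with `run --stages pools|reads|coverage|
ct|phenotype`; analysis stages with `mapdelta|genotype|exonusage|ddct|
correlate|age`. Outputs: TSV/VCF SNP tables, FASTQ/FASTA reads and loci,
bedGraph coverage, GFF3 gene models, BED intervals (0-based half-open),
JSON results, and a JSON manifest with sha256 checksums. Numeric plots
are not produced; all plottable tracks are written as TSV.

## Problem sizes in tests

The test and acceptance workloads use: 100 simulated mapping populations
for peak recovery (~7 s), 200 populations for the causal-SNP Δf
expectation, 50 random instances (≤ 100 points) for LOESS oracle
equivalence, 100 carrier + 100 non-carrier samples at 20× for caller
operating characteristics, 200 ΔΔCt and 200 regression simulations, and
500 clock round-trips. The whole suite runs in well under a minute on one
CPU.

## What the generators do not show

Passing tests demonstrate correctness of the statistics under the
generators' assumptions — Mendelian segregation, Haldane recombination,
Poisson/binomial pool counts, uniform read sampling with substitution-only
errors, gamma-Poisson coverage noise, Gaussian Ct noise. They do not
validate behavior under real-data pathologies: variant-calling artifacts,
segmental duplications or mapping bias at the insertion site, paired-end
information (reads are single-end), PCR duplicates (beyond the optional
dedup flag), qPCR efficiency ≠ 2, or selection acting on the dated allele
(the clock assumes neutrality). Headline interval sizes from the original
experiment (e.g. a 31.3 kb final interval) depend on that experiment's
recombination events and SNP density and are not reproduction targets at
desk scale.

## Known limitations

- Peak localization from phenotype-only-selected pools of 15/9 plants is
  precise to roughly 100 kb at the default design (the 90th-percentile
  peak error is ~110 kb over repeated simulations): with two dozen pooled
  plants, gamete sampling noise dominates near the peak. Experimental
  designs that pool *recombinant-selected* plants concentrate informative
  breakpoints near the locus and localize far better; the simulator's
  `self_once` flag plus caller-side selection of recombinants can emulate
  this but is not the default.
- LOESS neighbor-count convention `ceil(span·n)` can differ by one point
  from other implementations; results are insensitive at n ≈ 300.
- The bootstrap band is pointwise, not simultaneous.
- The insertion caller reports support counts, not zygosity; heterozygous
  carriers simply show roughly half the support depth.
- The exact Mann-Whitney enumerates up to C(20,10) ≈ 1.8×10⁵ labelings;
  beyond that the asymptotic branch takes over.
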