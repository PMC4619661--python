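# flm-sweepmap

Tools for mapping and characterizing a natural structural variant that
accelerates flowering in *Arabidopsis thaliana*: a ~5.7 kb LINE
retrotransposon insertion in the first intron of the MADS-box flowering
repressor *FLM* (*FLOWERING LOCUS M*). The package reimplements, as a
tested and reusable pipeline, the computational procedures needed to

1. **map a recessive flowering-time locus** from pooled sequencing of
   phenotypically extreme segregants (bulked segregant analysis /
   mapping-by-sequencing),
2. **genotype the insertion** in any short-read sample from
   breakpoint-junction targets,
3. **quantify its molecular effect** on *FLM* expression (per-nucleotide
   coverage profiles, exon usage, ΔΔCt qPCR fold changes, isoform ratios,
   expression–flowering regression), and
4. **date the insertion allele** under a neutral mutation clock.

A synthetic-data module generates every input with the statistical
structure the analysis assumes, so the full pipeline is testable without
any sequencing download.

## The core statistic

For two DNA pools of early- and late-flowering segregants, each SNP *i*
yields pool allele frequencies *f*ᵢ = altᵢ/depthᵢ. After filtering
(30–120× coverage in both pools, *f* > 20% in at least one pool, a call in
both pools, parental allele frequency ≥ 80%), both pool frequency tracks
are LOESS-smoothed along the chromosome (tricube-weighted local
polynomials, span 0.75, degree 2) and subtracted:

Δ*f*(x) = *f̂*_early(x) − *f̂*_late(x)

Runs with Δ*f* > 25% define the mapping interval; the position of the
maximal Δ*f* (Δ*f*_max) is the point estimate of the causal locus. For a
recessive early allele, the early pool is fixed (*f* = 1) while the late
pool sits at *f* = 1/3, so Δ*f* peaks at 2/3 at the causal site and decays
with recombination distance.

The insertion caller maps reads end-to-end (edit distance ≤ 5% of read
length, gaps included) against two 280 bp junction targets (140 bp genomic
flank + 140 bp insertion end per breakpoint); only reads placing the
junction within their inner 50% ("core-mapping"), with a unique best
placement, count as support, and presence requires ≥ 2 such reads at
*both* breakpoints.

The allele age from mean pairwise divergence *k* over *L* compared sites is
T = *k* / (2 μ *L*) generations, with the mutation rate interval
μ ∈ [6×10⁻⁹, 7×10⁻⁹] per site per generation and 1–3 seed generations per
year propagated to the widest calendar-year bracket.

## Worked example

Simulate a mapping population at the study design (1000 F2 plants, 15
early / 9 late pooled extremes, 300 SNPs over 1 Mb, 60× pool depth,
recessive 10-day effect) and scan it:

```python
from flm_sweepmap.simulate import F2SimConfig, simulate_f2_population, pool_and_count
from flm_sweepmap.bsa import analyze_pools

cfg = F2SimConfig(seed=42)
truth = simulate_f2_population(cfg)
table = pool_and_count(truth, cfg)
result = analyze_pools(table, prefiltered=True)
best = max(result.intervals, key=lambda iv: iv.peak_delta)
print(f"true causal position: {truth.causal_pos}")
print(f"interval: {best.start}-{best.end}  peak: {best.peak_pos}  "
      f"delta_f_max: {best.peak_delta:.3f}")
```

prints

```
true causal position: 501672
interval: 180602-1000000  peak: 568561  delta_f_max: 0.704
```

— the Δ*f* > 0.25 interval contains the causal marker, the peak lands
~67 kb from it, and Δ*f*_max ≈ 0.70 is near the analytic 2/3 expectation
for a recessive locus under extreme-pool selection. The same scan is
available from the shell:

```bash
flm-sweepmap run --stages pools,mapdelta --seed 42 --out-dir out/
flm-sweepmap mapdelta --vcf out/snp_pools.vcf --prefiltered
flm-sweepmap age --k 2 --sites 5700 --mu 6e-9:7e-9 --gen-per-year 1:3
```

The `age` call above prints a bracket of ≈ 8,354–29,240 calendar years for
an allele with 2 mean pairwise differences over 5,700 compared sites.

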