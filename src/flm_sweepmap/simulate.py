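"""Synthetic data generators for every pipeline stage.

The generators emulate the statistical structure of the study design the
analysis assumes: an F2 (optionally once-selfed, F3-style) Col-0 × Kil-0
cross segregating one recessive major-effect flowering locus, with
phenotypic extremes pooled and pool-sequenced to binomial allele counts;
100 bp reads tiling an insertion junction; replicated per-nucleotide
coverage with reduced downstream-exon coverage (premature termination);
qPCR Ct tables with specified fold changes; and paired expression/flowering
observations with a specified linear relationship.

All generators are pure functions of (configuration, seed): identical
inputs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import CoverageProfile, GeneModelAnnot

__all__ = [
    "F2SimConfig",
    "TruthRecord",
    "SimulatedRead",
    "ReadSet",
    "simulate_f2_population",
    "pool_and_count",
    "simulate_breakpoint_reads",
    "simulate_coverage_profiles",
    "simulate_ct_table",
    "simulate_expression_phenotype",
    "simulate_divergent_pair",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class F2SimConfig:
    """Study conditions for the extreme-pool mapping simulation.

    The simulated region is stylized as one full linkage group: 1 Mb of
    sequence carrying ``genetic_len`` centimorgans (default 100 cM, about one
    crossover per gamete — the scale of an A. thaliana chromosome), with
    ``n_snps`` biallelic markers and a recessive causal flowering locus at
    ``causal_pos``. Homozygous-alternative plants flower ``effect_days``
    earlier; phenotypic noise is Gaussian. The ``n_early_pool`` earliest and
    ``n_late_pool`` latest plants are pooled and pool-sequenced at
    ``mean_depth`` expected coverage per SNP (Poisson depth, binomial allele
    counts). Pool sizes default to the 15 early / 9 late plants of the
    original mapping pools.
    """

    n_f2: int = 1000
    genome_len: int = 1_000_000
    genetic_len: float = 100.0  # centimorgans across the region
    n_snps: int = 300
    causal_pos: int = 500_000
    effect_days: float = 10.0
    noise_sd: float = 1.0
    base_days: float = 60.0  # arbitrary flowering-time baseline
    n_early_pool: int = 15
    n_late_pool: int = 9
    mean_depth: float = 60.0
    self_once: bool = False  # one round of selfing (F3-style pools)
    snp_placement: str = "even"  # "even" or "random"
    seed: int = 0

    def validate(self) -> None:
        if self.n_f2 <= 0 or self.n_snps <= 0:
            raise ValueError("n_f2 and n_snps must be positive")
        if not 0 < self.causal_pos <= self.genome_len:
            raise ValueError("causal_pos must lie in (0, genome_len]")
        if self.n_early_pool <= 0 or self.n_late_pool <= 0:
            raise ValueError("pool sizes must be positive")
        if self.n_early_pool + self.n_late_pool > self.n_f2:
            raise ValueError("pools may not exceed the population")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.effect_days <= 0:
            raise ValueError("effect_days must be positive")
        if self.genetic_len < 0 or self.noise_sd < 0:
            raise ValueError("genetic_len and noise_sd must be non-negative")
        if self.snp_placement not in ("even", "random"):
            raise ValueError("snp_placement must be 'even' or 'random'")


@dataclass
class TruthRecord:
    """Ground truth of one simulated population."""

    snp_positions: np.ndarray  # bp, sorted
    genotypes: np.ndarray  # (n_f2, n_snps) alternative-allele copies 0/1/2
    phenotype: np.ndarray  # days to flowering
    causal_index: int  # marker index of the causal locus
    causal_pos: int  # actual (snapped-to-marker) causal position


def _gametes(rng: np.random.Generator, n: int, positions: np.ndarray, morgans: float) -> np.ndarray:
    """n recombinant gamete haplotypes (0 = reference parent, 1 = alternative).

    Haldane model: crossover count ~ Poisson(morgans), positions uniform on
    the physical map, no interference; the starting parental phase is fair.
    """
    genome_len = positions[-1] + 1 if positions.size else 1
    out = np.empty((n, positions.size), dtype=np.int8)
    n_x = rng.poisson(morgans, size=n)
    start = rng.integers(0, 2, size=n)
    for i in range(n):
        if n_x[i] == 0:
            out[i] = start[i]
            continue
        xpos = np.sort(rng.uniform(0, genome_len, size=n_x[i]))
        # phase at marker m flips once per crossover to its left
        flips = np.searchsorted(xpos, positions, side="right")
        out[i] = (start[i] + flips) % 2
    return out


def simulate_f2_population(cfg: F2SimConfig) -> TruthRecord:
    """Simulate genotypes and flowering phenotypes of an F2 population.

    Each F2 individual receives two independently recombined gametes; its
    phenotype is ``base_days − effect_days·I(causal genotype == 2) +
    N(0, noise_sd)`` — the causal allele is recessive. With
    ``cfg.self_once`` each F2 is selfed once and replaced by one F3
    offspring (two recombinant gametes drawn from the same F2 parent), which
    mirrors pooling selfed recombinant families.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0x5EED])
    if cfg.snp_placement == "even":
        positions = np.linspace(0, cfg.genome_len - 1, cfg.n_snps).round().astype(np.int64)
    else:
        positions = np.sort(rng.choice(cfg.genome_len, size=cfg.n_snps, replace=False))
    causal_index = int(np.argmin(np.abs(positions - cfg.causal_pos)))
    causal_pos = int(positions[causal_index])

    morgans = cfg.genetic_len / 100.0
    hap_a = _gametes(rng, cfg.n_f2, positions, morgans)
    hap_b = _gametes(rng, cfg.n_f2, positions, morgans)

    if cfg.self_once:
        # One selfing round: each offspring gamete recombines the parent's
        # own two haplotypes, using fresh Haldane crossovers.
        def _self(parent_a: np.ndarray, parent_b: np.ndarray) -> np.ndarray:
            chooser = _gametes(rng, cfg.n_f2, positions, morgans)
            return np.where(chooser == 0, parent_a, parent_b)

        hap_a, hap_b = _self(hap_a, hap_b), _self(hap_a, hap_b)

    genotypes = (hap_a + hap_b).astype(np.int8)
    is_hom_alt = genotypes[:, causal_index] == 2
    noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_f2) if cfg.noise_sd > 0 else np.zeros(cfg.n_f2)
    phenotype = cfg.base_days - cfg.effect_days * is_hom_alt + noise
    return TruthRecord(
        snp_positions=positions,
        genotypes=genotypes,
        phenotype=phenotype,
        causal_index=causal_index,
        causal_pos=causal_pos,
    )


def pool_and_count(
    truth: TruthRecord,
    cfg: F2SimConfig,
    analytic: bool = False,
    chrom: str = "chr1",
) -> pd.DataFrame:
    """Pool phenotypic extremes and draw pooled-sequencing allele counts.

    The early pool holds the ``n_early_pool`` lowest phenotypes, the late
    pool the ``n_late_pool`` highest (ties broken by stable order). Per SNP
    and pool the true allele frequency is (alt copies)/(2·pool size); the
    sequenced depth is Poisson(``mean_depth``) and the alt count
    Binomial(depth, p). The parental alternative line is homozygous, so
    ``parental_alt_freq`` is 1.0 throughout. With ``analytic=True`` the
    infinite-depth limit is returned instead: counts are scaled true
    frequencies at a fixed large depth, and the exact pool frequencies are
    attached as ``true_f_early``/``true_f_late`` columns.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0xB00])
    order = np.argsort(truth.phenotype, kind="stable")
    early_idx = order[: cfg.n_early_pool]
    late_idx = order[::-1][: cfg.n_late_pool]

    p_early = truth.genotypes[early_idx].sum(axis=0) / (2.0 * cfg.n_early_pool)
    p_late = truth.genotypes[late_idx].sum(axis=0) / (2.0 * cfg.n_late_pool)

    n = truth.snp_positions.size
    if analytic:
        depth = 1_000_000
        de = np.full(n, depth)
        dl = np.full(n, depth)
        ae = np.round(p_early * depth).astype(np.int64)
        al = np.round(p_late * depth).astype(np.int64)
    else:
        de = rng.poisson(cfg.mean_depth, size=n)
        dl = rng.poisson(cfg.mean_depth, size=n)
        ae = rng.binomial(de, p_early)
        al = rng.binomial(dl, p_late)

    table = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": truth.snp_positions,
            "ref": "C",
            "alt": "T",
            "depth_early": de,
            "alt_early": ae,
            "depth_late": dl,
            "alt_late": al,
            "parental_alt_freq": 1.0,
            "called_in_both": (de > 0) & (dl > 0),
        }
    )
    if analytic:
        table["true_f_early"] = p_early
        table["true_f_late"] = p_late
    return table


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    source: str  # "carrier" or "reference"
    start: int  # 0-based offset on the source allele
    strand: str  # "+" or "-"
    spans_left_junction: bool
    spans_right_junction: bool


@dataclass
class ReadSet:
    reads: list[SimulatedRead]
    carrier_allele: str
    read_len: int

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.reads])


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_breakpoint_reads(
    ref_seq: str,
    insert_seq: str,
    insertion_pos: int,
    read_len: int = 100,
    depth: float = 30.0,
    error_rate: float = 0.0,
    carrier: bool = True,
    seed: int = 0,
    stranded: bool = True,
) -> ReadSet:
    """Fixed-length single-end reads from the carrier or reference allele.

    The carrier allele is ``ref[:pos] + insert + ref[pos:]``; its two
    junctions sit at offsets ``pos`` (left) and ``pos + len(insert)``
    (right). Read starts are uniform over the source; substitution errors
    are applied i.i.d. per base at ``error_rate``; with ``stranded`` half
    the reads (in expectation) are reverse-complemented. Truth records each
    read's source offset and which junction(s) its span contains strictly
    inside.
    """
    if read_len > len(ref_seq):
        raise ValueError("read_len must not exceed the reference length")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    if not 0 <= insertion_pos <= len(ref_seq):
        raise ValueError("insertion_pos outside the reference")
    rng = np.random.default_rng([seed, 0xF1])
    carrier_allele = ref_seq[:insertion_pos] + insert_seq + ref_seq[insertion_pos:]
    source_seq = carrier_allele if carrier else ref_seq
    source_name = "carrier" if carrier else "reference"
    left_j = insertion_pos
    right_j = insertion_pos + len(insert_seq)

    n_reads = int(round(depth * len(source_seq) / read_len))
    starts = rng.integers(0, len(source_seq) - read_len + 1, size=n_reads)
    flip = rng.random(n_reads) < 0.5 if stranded else np.zeros(n_reads, dtype=bool)
    src = np.frombuffer(source_seq.encode(), dtype=np.uint8)

    reads: list[SimulatedRead] = []
    for i in range(n_reads):
        s = int(starts[i])
        base = src[s : s + read_len].copy()
        if error_rate > 0:
            errs = np.flatnonzero(rng.random(read_len) < error_rate)
            for e in errs:
                choices = _BASES[_BASES != base[e]]
                base[e] = rng.choice(choices)
        seq = base.tobytes().decode()
        strand = "+"
        if flip[i]:
            seq = reverse_complement(seq)
            strand = "-"
        spans_left = carrier and (s < left_j < s + read_len)
        spans_right = carrier and (s < right_j < s + read_len)
        reads.append(
            SimulatedRead(
                read_id=f"read_{i}",
                sequence=seq,
                source=source_name,
                start=s,
                strand=strand,
                spans_left_junction=spans_left,
                spans_right_junction=spans_right,
            )
        )
    return ReadSet(reads=reads, carrier_allele=carrier_allele, read_len=read_len)


def simulate_coverage_profiles(
    gene_model: GeneModelAnnot,
    n_reps: int = 3,
    base_depth: float = 100.0,
    termination_fraction: float = 0.8,
    termination_pos: int | None = None,
    noise: float = 0.05,
    seed: int = 0,
) -> list[CoverageProfile]:
    """Replicated per-nucleotide coverage with premature-termination dropoff.

    Expected per-nucleotide count is ``base_depth`` upstream of
    ``termination_pos`` and ``base_depth·(1 − termination_fraction)``
    downstream, emulating transcripts that terminate inside intron 1.
    Counts are negative-binomial per replicate with gamma-Poisson
    overdispersion ``noise`` (variance = μ + noise·μ²); ``noise = 0`` gives
    Poisson counts.
    """
    if not 0.0 <= termination_fraction <= 1.0:
        raise ValueError("termination_fraction must be in [0, 1]")
    span_start, span_end = gene_model.span
    if termination_pos is None:
        termination_pos = gene_model.exons[0][1]  # end of exon 1
    if not span_start <= termination_pos <= span_end:
        raise ValueError("termination_pos outside the gene span")
    rng = np.random.default_rng([seed, 0xC0])
    length = span_end - span_start
    mu = np.full(length, base_depth, dtype=float)
    mu[termination_pos - span_start :] *= 1.0 - termination_fraction
    profiles = []
    for r in range(n_reps):
        if noise > 0:
            lam = rng.gamma(shape=1.0 / noise, scale=mu * noise)
        else:
            lam = mu
        counts = rng.poisson(lam).astype(float)
        profiles.append(
            CoverageProfile(
                gene_id=gene_model.gene_id,
                replicate=f"rep{r + 1}",
                counts=counts,
                offset=span_start,
            )
        )
    return profiles


def simulate_ct_table(
    true_fold_changes: dict[str, float],
    target_gene: str = "FLM",
    reference_gene: str = "ACT8",
    n_replicates: int = 3,
    ct_noise_sd: float = 0.1,
    base_ct_target: float = 24.0,
    base_ct_reference: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """qPCR Ct table consistent with perfect doubling per cycle.

    For each sample the target gene's expected Ct is
    ``base_ct_target − log2(fold change)`` (one cycle fewer per doubling of
    expression) and the reference gene's is constant; i.i.d. Gaussian noise
    of ``ct_noise_sd`` cycles is added per well. The calibrator is whichever
    sample carries fold change 1.
    """
    if any(f <= 0 for f in true_fold_changes.values()):
        raise ValueError("fold changes must be positive")
    rng = np.random.default_rng([seed, 0xC7])
    rows = []
    for sample, fold in true_fold_changes.items():
        for rep in range(1, n_replicates + 1):
            ct_t = base_ct_target - np.log2(fold) + rng.normal(0.0, ct_noise_sd)
            ct_r = base_ct_reference + rng.normal(0.0, ct_noise_sd)
            rows.append({"sample": sample, "gene": target_gene, "replicate": rep, "ct": ct_t})
            rows.append({"sample": sample, "gene": reference_gene, "replicate": rep, "ct": ct_r})
    return pd.DataFrame(rows)


def simulate_expression_phenotype(
    n: int = 50,
    slope: float = 2.0,
    intercept: float = 60.0,
    noise_sd: float = 1.0,
    expr_mean: float = 1.0,
    expr_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired expression/flowering observations with a linear relationship.

    flowering = intercept + slope·expression + N(0, noise_sd); expression is
    Gaussian with the given mean and SD. The theoretical R² of the implied
    regression is slope²·expr_sd² / (slope²·expr_sd² + noise_sd²).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    rng = np.random.default_rng([seed, 0xE9])
    x = rng.normal(expr_mean, expr_sd, size=n)
    y = intercept + slope * x + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame({"expression": x, "flowering_days": y})


def simulate_divergent_pair(
    length: int,
    generations: float,
    mu: float,
    seed: int = 0,
) -> tuple[str, str]:
    """Two sequences diverged from a common ancestor under a neutral clock.

    Each lineage accumulates Poisson(μ·L·T) substitutions at uniform sites
    (multiple hits possible but negligible when μ·T ≪ 1), mirroring the
    star-divergence model behind the allele-age estimator.
    """
    rng = np.random.default_rng([seed, 0xA6E])
    ancestor = rng.choice(_BASES, size=length)
    seqs = []
    for _ in range(2):
        lineage = ancestor.copy()
        n_mut = rng.poisson(mu * length * generations)
        sites = rng.integers(0, length, size=n_mut)
        for s in sites:
            lineage[s] = rng.choice(_BASES[_BASES != lineage[s]])
        seqs.append(lineage.tobytes().decode())
    return seqs[0], seqs[1]
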