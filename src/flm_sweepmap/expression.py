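"""Coverage-profile normalization, exon usage, ΔΔCt and association statistics.

This module quantifies the expression phenotypes around the FLM locus:
per-nucleotide RNA-seq coverage profiles scaled to [0, 1], replicate
confidence bands, the exon-1 / exons-2..K read-count ratio diagnostic for
premature transcript termination, ΔΔCt relative qPCR quantification against
a reference gene (ACT8 in the original assays), isoform (δ/β) ratios
normalized to a reference accession, flowering-time-on-expression OLS
regression, and an exact small-sample Mann-Whitney test for
polymorphism/expression association.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneModelAnnot",
    "CoverageProfile",
    "ExonUsageResult",
    "RegressionResult",
    "normalize_profile",
    "replicate_band",
    "exon_usage",
    "ddct_relative_expression",
    "isoform_ratio",
    "regress_flowering_on_expression",
    "polymorphism_association",
]


@dataclass(frozen=True)
class GeneModelAnnot:
    """A gene model: ordered, non-overlapping exons in gene-oriented coordinates.

    Exons are half-open (start, end) intervals in 5'→3' order relative to the
    *gene* (coverage profiles are stored in the same orientation, so minus
    strand genes are flipped by the GFF3 reader before they reach here).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"empty exon ({start}, {end})")
            if start < prev_end:
                raise ValueError("exons must be ordered and non-overlapping")
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class CoverageProfile:
    """Per-nucleotide read counts over a gene span for one replicate."""

    gene_id: str
    replicate: str
    counts: np.ndarray
    offset: int = 0  # gene-span start coordinate of counts[0]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("coverage counts must be non-negative")


@dataclass
class ExonUsageResult:
    """Per-exon summed counts and the exon-1 usage ratio across replicates."""

    per_exon: pd.DataFrame  # replicates × exons
    ratios: dict[str, float]  # replicate -> exon1 / sum(exon2..K)
    mean_ratio: float
    sd_ratio: float
    excluded: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def normalize_profile(counts: np.ndarray) -> np.ndarray:
    """Scale counts to [0, 1] by the profile maximum.

    0 means no expression and 1 the maximum observed expression; an all-zero
    profile maps to all zeros (no division by zero).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty profile")
    m = counts.max()
    if m <= 0:
        return np.zeros_like(counts)
    return counts / m


def replicate_band(
    profiles: list[np.ndarray] | np.ndarray,
    normalize: bool = True,
    shared_scale: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise mean and empirical 5%/95% quantiles across replicates.

    With ``normalize`` the replicates are first scaled to [0, 1]; with
    ``shared_scale`` (default) a single divisor — the maximum of the
    replicate-mean profile — is used for every replicate so that bands share
    one scale, otherwise each replicate is scaled by its own maximum.
    Quantiles use numpy's linear-interpolation rule; with few replicates
    (e.g. three) they approach the pointwise min/max.
    """
    arr = np.asarray(profiles, dtype=float)
    if arr.ndim != 2:
        raise ValueError("replicate profiles must have equal length")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 replicates")
    if normalize:
        if shared_scale:
            m = arr.mean(axis=0).max()
            arr = arr / m if m > 0 else np.zeros_like(arr)
        else:
            arr = np.stack([normalize_profile(p) for p in arr])
    mean = arr.mean(axis=0)
    q05 = np.quantile(arr, 0.05, axis=0)
    q95 = np.quantile(arr, 0.95, axis=0)
    return mean, q05, q95


def exon_usage(profiles: list[CoverageProfile], model: GeneModelAnnot) -> ExonUsageResult:
    """Exon-level read sums and the exon-1 vs exons-2..K ratio per replicate.

    The ratio is exon-1 summed counts over the summed counts of all remaining
    exons; it rises above its control value when transcripts terminate
    prematurely inside intron 1. Replicates with a zero denominator are
    excluded with a warning. Mean ± sample SD (ddof=1) across replicates.
    """
    span_start, span_end = model.span
    rows = {}
    ratios: dict[str, float] = {}
    excluded: list[str] = []
    labels = [f"exon{i + 1}" for i in range(len(model.exons))]
    for prof in profiles:
        lo = prof.offset
        hi = prof.offset + prof.counts.size
        if span_start < lo or span_end > hi:
            raise ValueError(f"gene model exceeds profile span for replicate {prof.replicate}")
        sums = [prof.counts[s - lo : e - lo].sum() for s, e in model.exons]
        rows[prof.replicate] = sums
        denom = sum(sums[1:])
        if denom <= 0:
            warnings.warn(
                f"replicate {prof.replicate}: zero downstream-exon counts; ratio undefined",
                stacklevel=2,
            )
            excluded.append(prof.replicate)
        else:
            ratios[prof.replicate] = sums[0] / denom
    per_exon = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    vals = np.array(list(ratios.values()), dtype=float)
    mean = float(vals.mean()) if vals.size else math.nan
    sd = float(vals.std(ddof=1)) if vals.size > 1 else math.nan
    return ExonUsageResult(per_exon=per_exon, ratios=ratios, mean_ratio=mean, sd_ratio=sd, excluded=excluded)


def ddct_relative_expression(
    table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_sample: str,
) -> pd.DataFrame:
    """ΔΔCt relative quantification with a reference gene as control.

    ``table`` has columns (sample, gene, replicate, ct). Per replicate,
    ΔCt = Ct_target − Ct_reference; per sample, ΔΔCt = mean ΔCt − mean ΔCt of
    the calibrator sample, and fold change = 2^(−ΔΔCt) (amplification
    efficiency assumed exactly 2). The standard error of ΔΔCt combines the
    replicate ΔCt variances of sample and calibrator; the fold-change SE is
    propagated as ln(2)·fold·SE(ΔΔCt).
    """
    required = {"sample", "gene", "replicate", "ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    samples = table["sample"].unique()
    if calibrator_sample not in samples:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not in table")

    def _dcts(sample: str) -> np.ndarray:
        sub = table[table["sample"] == sample]
        tgt = sub[sub["gene"] == target_gene].set_index("replicate")["ct"]
        ref = sub[sub["gene"] == reference_gene].set_index("replicate")["ct"]
        if ref.empty:
            raise ValueError(f"reference gene {reference_gene!r} missing for sample {sample!r}")
        if tgt.empty:
            raise ValueError(f"target gene {target_gene!r} missing for sample {sample!r}")
        common = tgt.index.intersection(ref.index)
        if common.empty:
            raise ValueError(f"no shared replicates for sample {sample!r}")
        return (tgt.loc[common] - ref.loc[common]).to_numpy(dtype=float)

    cal = _dcts(calibrator_sample)
    cal_mean = cal.mean()
    cal_var = cal.var(ddof=1) / cal.size if cal.size > 1 else 0.0
    rows = []
    for sample in samples:
        d = _dcts(sample)
        if sample == calibrator_sample:
            ddct, var = 0.0, 0.0  # exact by definition of the calibrator
        else:
            ddct = d.mean() - cal_mean
            var = (d.var(ddof=1) / d.size if d.size > 1 else 0.0) + cal_var
        fold = 2.0 ** (-ddct)
        se_ddct = math.sqrt(var)
        rows.append(
            {
                "sample": sample,
                "n_replicates": d.size,
                "ddct": ddct,
                "fold_change": fold,
                "se_fold": math.log(2.0) * fold * se_ddct,
            }
        )
    return pd.DataFrame(rows)


def isoform_ratio(
    table: pd.DataFrame,
    reference_accession: str,
    beta_col: str = "beta_fold",
    delta_col: str = "delta_fold",
) -> pd.DataFrame:
    """δ/β isoform ratios normalized so the reference accession equals 1.

    ratio = (delta/beta) / (delta_ref/beta_ref). Accessions with zero or
    negative β are flagged (ratio NaN, ``undefined`` true) rather than
    silently dropped.
    """
    if reference_accession not in set(table["accession"]):
        raise ValueError(f"reference accession {reference_accession!r} not in table")
    ref = table[table["accession"] == reference_accession].iloc[0]
    if ref[beta_col] <= 0 or ref[delta_col] <= 0:
        raise ValueError("reference accession must have positive isoform folds")
    ref_ratio = ref[delta_col] / ref[beta_col]
    out = []
    for _, row in table.iterrows():
        undefined = row[beta_col] <= 0
        ratio = math.nan if undefined else (row[delta_col] / row[beta_col]) / ref_ratio
        out.append({"accession": row["accession"], "ratio": ratio, "undefined": undefined})
    return pd.DataFrame(out)


def regress_flowering_on_expression(
    expression: np.ndarray,
    flowering: np.ndarray,
) -> RegressionResult:
    """OLS of flowering time on expression; R² = 1 − SSE/SST."""
    x = np.asarray(expression, dtype=float)
    y = np.asarray(flowering, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("zero expression variance; slope undefined")
    res = stats.linregress(x, y)
    # constant response: SST = 0, r is undefined; the fit explains nothing
    r2 = 0.0 if np.ptp(y) == 0 else float(res.rvalue**2)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n=int(x.size),
    )


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of group x vs y via mid-ranks."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def polymorphism_association(
    group_a: np.ndarray,
    group_b: np.ndarray,
    exact_limit: int = 20,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of a quantitative trait between alleles.

    For n1+n2 <= ``exact_limit`` the null distribution of U is enumerated
    over all C(n1+n2, n1) group labelings of the pooled observations
    (mid-ranks, so ties are handled exactly), and the two-sided p-value is
    min(1, 2·min(P(U ≤ u), P(U ≥ u))). Larger samples use the tie-corrected
    normal approximation.
    """
    x = np.asarray(group_a, dtype=float)
    y = np.asarray(group_b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    u_obs = _u_statistic(x, y)
    n1, n2 = x.size, y.size
    n = n1 + n2
    if n <= exact_limit:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        offset = n1 * (n1 + 1) / 2.0
        us = np.array(
            [sum(ranks[i] for i in comb) - offset for comb in itertools.combinations(range(n), n1)]
        )
        eps = 1e-9
        p_le = np.mean(us <= u_obs + eps)
        p_ge = np.mean(us >= u_obs - eps)
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        _, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(p)
    return u_obs, p
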