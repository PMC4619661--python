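"""Pooled-segregant allele-frequency mapping (bulked segregant analysis).

The mapping statistic works on per-SNP allele counts from two DNA pools of
phenotypically extreme segregants (an "early" and a "late" flowering pool).
Per-pool allele frequencies are LOESS-smoothed along the chromosome, their
difference Δf = f_early − f_late is computed, and maximal runs with
Δf above a threshold (default 25%) are reported as mapping intervals, each
with the position of the maximal Δf (Δf_max) as the point estimate of the
causal locus.

Coordinates are 0-based half-open internally; readers/writers in
:mod:`flm_sweepmap.io` convert to and from the 1-based text conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SNP_TABLE_COLUMNS",
    "SnpPoolRecord",
    "SmoothedProfile",
    "DeltaFProfile",
    "MappingInterval",
    "FilterReport",
    "compute_pool_frequency",
    "filter_snps",
    "loess_smooth",
    "loess_predict",
    "bootstrap_band",
    "compute_delta_f",
    "call_mapping_interval",
    "marker_frequency_scan",
    "analyze_pools",
]

#: Canonical column order of a SNP pool table (a pandas DataFrame).
SNP_TABLE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "depth_early",
    "alt_early",
    "depth_late",
    "alt_late",
    "parental_alt_freq",
    "called_in_both",
]


@dataclass(frozen=True)
class SnpPoolRecord:
    """One biallelic site with per-pool depth/alt counts.

    ``pos`` is 0-based. ``parental_alt_freq`` is the alternative-allele
    frequency observed in the resequenced homozygous alternative parent
    (ideally 1.0; low values indicate unreliable calls).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depth_early: int
    alt_early: int
    depth_late: int
    alt_late: int
    parental_alt_freq: float
    called_in_both: bool

    def __post_init__(self) -> None:
        if not (0 <= self.alt_early <= self.depth_early):
            raise ValueError("alt_early must satisfy 0 <= alt <= depth")
        if not (0 <= self.alt_late <= self.depth_late):
            raise ValueError("alt_late must satisfy 0 <= alt <= depth")
        if not (0.0 <= self.parental_alt_freq <= 1.0):
            raise ValueError("parental_alt_freq must be in [0, 1]")


@dataclass
class SmoothedProfile:
    """Raw and LOESS-smoothed pool allele frequencies along one chromosome."""

    positions: np.ndarray
    raw_f: np.ndarray
    smooth_f: np.ndarray
    band_lo: np.ndarray | None = None
    band_hi: np.ndarray | None = None


@dataclass
class DeltaFProfile:
    """Δf = smoothed early-pool minus smoothed late-pool frequency."""

    positions: np.ndarray
    delta_f: np.ndarray


@dataclass(frozen=True)
class MappingInterval:
    """Contiguous region with Δf above threshold; half-open coordinates."""

    chrom: str
    start: int
    end: int
    peak_pos: int
    peak_delta: float
    threshold: float


@dataclass
class FilterReport:
    """Per-rule rejection bookkeeping for :func:`filter_snps`.

    ``first_failure`` maps each rejected row's index to the first rule it
    failed, in the fixed evaluation order coverage → frequency → presence →
    parental.
    """

    n_input: int = 0
    n_retained: int = 0
    counts: dict[str, int] = field(default_factory=dict)
    first_failure: dict[int, str] = field(default_factory=dict)


def compute_pool_frequency(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-pool alternative-allele frequencies f = alt / depth.

    Raises ``ValueError`` on zero depth in either pool — such records must be
    removed by :func:`filter_snps` first.
    """
    de = table["depth_early"].to_numpy(dtype=float)
    dl = table["depth_late"].to_numpy(dtype=float)
    if np.any(de <= 0) or np.any(dl <= 0):
        raise ValueError("zero depth encountered; filter records before computing frequencies")
    return table["alt_early"].to_numpy(dtype=float) / de, table["alt_late"].to_numpy(dtype=float) / dl


_RULE_ORDER = ("coverage", "frequency", "presence", "parental")


def filter_snps(
    table: pd.DataFrame,
    cov_min: int = 30,
    cov_max: int = 120,
    min_freq: float = 0.20,
    parental_min: float = 0.80,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the SNP selection filters used for allele-frequency mapping.

    A record survives iff

    * coverage: ``cov_min <= depth <= cov_max`` in *both* pools (inclusive),
    * frequency: f > ``min_freq`` in at least one pool,
    * presence: ``called_in_both`` is true,
    * parental: ``parental_alt_freq >= parental_min``.

    The report logs, per rejected record, the first failing rule in the order
    above, plus aggregate counts per rule.
    """
    if not cov_min <= cov_max:
        raise ValueError("cov_min must be <= cov_max")
    if not (0.0 <= min_freq <= 1.0 and 0.0 <= parental_min <= 1.0):
        raise ValueError("min_freq and parental_min must be in [0, 1]")

    report = FilterReport(n_input=len(table), counts={r: 0 for r in _RULE_ORDER})
    if len(table) == 0:
        return table.copy(), report

    de = table["depth_early"].to_numpy(dtype=float)
    dl = table["depth_late"].to_numpy(dtype=float)
    cov_ok = (de >= cov_min) & (de <= cov_max) & (dl >= cov_min) & (dl <= cov_max)
    with np.errstate(divide="ignore", invalid="ignore"):
        fe = np.where(de > 0, table["alt_early"].to_numpy(dtype=float) / np.maximum(de, 1), 0.0)
        fl = np.where(dl > 0, table["alt_late"].to_numpy(dtype=float) / np.maximum(dl, 1), 0.0)
    freq_ok = (fe > min_freq) | (fl > min_freq)
    pres_ok = table["called_in_both"].to_numpy(dtype=bool)
    par_ok = table["parental_alt_freq"].to_numpy(dtype=float) >= parental_min

    checks = {"coverage": cov_ok, "frequency": freq_ok, "presence": pres_ok, "parental": par_ok}
    keep = cov_ok & freq_ok & pres_ok & par_ok
    for i, (idx, retained) in enumerate(zip(table.index, keep)):
        if retained:
            continue
        for rule in _RULE_ORDER:
            if not checks[rule][i]:
                report.counts[rule] += 1
                report.first_failure[idx] = rule
                break
    report.n_retained = int(keep.sum())
    return table.loc[keep].copy(), report


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    w[np.abs(u) >= 1.0] = 0.0
    return w


def loess_predict(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_eval: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
) -> np.ndarray:
    """Tricube-weighted local polynomial regression, evaluated at ``x_eval``.

    At each evaluation point the ``q = ceil(span * n)`` nearest training
    points (by |Δx|) receive tricube weights on distance scaled by the q-th
    nearest distance, and a weighted polynomial of the given degree is fit;
    the fitted value at the point is returned. No robustness iterations.

    Duplicate x values are allowed. When the q nearest neighbors are all at
    distance zero the fit degenerates to their plain weighted mean.
    """
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    x_eval = np.asarray(x_eval, dtype=float)
    n = x_train.size
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    if degree < 0:
        raise ValueError("degree must be >= 0")
    if n < degree + 2:
        raise ValueError(f"need at least degree+2={degree + 2} points, got {n}")

    q = max(degree + 1, int(np.ceil(span * n)))
    q = min(q, n)

    # Batched weighted least squares: for m eval points, D is (m, n) distances,
    # V is the per-point centered Vandermonde basis (m, n, degree+1).
    d = np.abs(x_eval[:, None] - x_train[None, :])
    dq = np.partition(d, q - 1, axis=1)[:, q - 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(dq[:, None] > 0, d / dq[:, None], np.where(d > 0, np.inf, 0.0))
    w = _tricube(u)
    # Guard: every eval point needs positive total weight (q >= 1 neighbors at
    # u < 1 unless ties at the boundary removed them; include boundary ties
    # with weight 0 — fall back to nearest points with uniform weight).
    dead = w.sum(axis=1) <= 0
    if np.any(dead):
        w[dead] = (d[dead] <= dq[dead, None]).astype(float)

    xc = x_train[None, :] - x_eval[:, None]
    # scale for conditioning
    scale = np.maximum(dq, 1.0)[:, None]
    xs = xc / scale
    powers = np.arange(degree + 1)
    V = xs[:, :, None] ** powers[None, None, :]  # (m, n, p)
    Wv = w[:, :, None] * V
    A = np.einsum("mnp,mnq->mpq", V, Wv)  # (m, p, p)
    b = np.einsum("mnp,n->mp", Wv, y_train)  # (m, p)
    # Solve with pseudo-inverse fallback for singular neighborhoods
    fitted = np.empty(x_eval.size)
    for i in range(x_eval.size):
        try:
            coef = np.linalg.solve(A[i], b[i])
        except np.linalg.LinAlgError:
            coef = np.linalg.lstsq(A[i], b[i], rcond=None)[0]
        fitted[i] = coef[0]  # basis centered at x_eval[i]
    return fitted


def loess_smooth(
    positions: np.ndarray,
    values: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
) -> np.ndarray:
    """LOESS-smooth ``values`` against ``positions`` at the data points."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 1 or positions.size != np.asarray(values).size:
        raise ValueError("positions and values must be 1-D arrays of equal length")
    return loess_predict(positions, values, positions, span=span, degree=degree)


def bootstrap_band(
    positions: np.ndarray,
    values: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
    n_boot: int = 200,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise bootstrap confidence band around the LOESS curve.

    SNPs are case-resampled with replacement, the curve is re-fit and
    evaluated at the original positions, and the pointwise
    ((1−level)/2, 1−(1−level)/2) quantiles over replicates form the band.
    """
    if n_boot < 50:
        raise ValueError("n_boot must be >= 50")
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    n = positions.size
    fits = np.empty((n_boot, n))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        fits[b] = loess_predict(positions[idx], values[idx], positions, span=span, degree=degree)
    alpha = (1.0 - level) / 2.0
    return np.quantile(fits, alpha, axis=0), np.quantile(fits, 1.0 - alpha, axis=0)


def compute_delta_f(early: SmoothedProfile, late: SmoothedProfile) -> DeltaFProfile:
    """Δf profile = early smoothed frequency minus late, on a shared grid."""
    if early.positions.shape != late.positions.shape or np.any(early.positions != late.positions):
        raise ValueError("early and late profiles must share the same position grid")
    return DeltaFProfile(positions=early.positions.copy(), delta_f=early.smooth_f - late.smooth_f)


def call_mapping_interval(
    profile: DeltaFProfile,
    threshold: float = 0.25,
    chrom: str = "chr1",
) -> list[MappingInterval]:
    """Maximal runs of consecutive positions with Δf > threshold.

    Each run becomes a half-open interval [first position, last position + 1)
    carrying the leftmost position attaining the run's maximum Δf (Δf_max).
    Returns an empty list when nothing exceeds the threshold.
    """
    pos = np.asarray(profile.positions)
    dv = np.asarray(profile.delta_f)
    if pos.size == 0:
        raise ValueError("empty profile")
    above = dv > threshold
    intervals: list[MappingInterval] = []
    i = 0
    n = pos.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        run = slice(i, j + 1)
        peak_idx = i + int(np.argmax(dv[run]))  # argmax returns leftmost tie
        intervals.append(
            MappingInterval(
                chrom=chrom,
                start=int(pos[i]),
                end=int(pos[j]) + 1,
                peak_pos=int(pos[peak_idx]),
                peak_delta=float(dv[peak_idx]),
                threshold=threshold,
            )
        )
        i = j + 1
    return intervals


def marker_frequency_scan(
    genotypes_early: np.ndarray,
    genotypes_late: np.ndarray,
    positions: np.ndarray,
    marker_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Rough-mapping marker scan on extreme plants' genotypes.

    ``genotypes_*`` are (plants × markers) arrays of alternative-allele
    copies (0/1/2). Per marker the group allele frequency is
    mean(genotype)/2, and a two-sided Fisher exact test on the 2×2 allele
    count table (alt/ref × early/late) gives the p-value. Monomorphic markers
    get p = 1.
    """
    ge = np.asarray(genotypes_early)
    gl = np.asarray(genotypes_late)
    if ge.ndim != 2 or gl.ndim != 2 or ge.shape[1] != gl.shape[1]:
        raise ValueError("genotype arrays must be 2-D with matching marker counts")
    if ge.shape[0] < 2 or gl.shape[0] < 2:
        raise ValueError("need at least 2 plants per group")
    m = ge.shape[1]
    positions = np.asarray(positions)
    if marker_ids is None:
        marker_ids = [f"M{k + 1}" for k in range(m)]
    rows = []
    for k in range(m):
        alt_e = int(ge[:, k].sum())
        alt_l = int(gl[:, k].sum())
        tot_e = 2 * ge.shape[0]
        tot_l = 2 * gl.shape[0]
        table = [[alt_e, tot_e - alt_e], [alt_l, tot_l - alt_l]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "marker": marker_ids[k],
                "pos": int(positions[k]),
                "freq_early": alt_e / tot_e,
                "freq_late": alt_l / tot_l,
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PoolScanResult:
    """Bundle of the full Δf scan over one filtered SNP table."""

    table: pd.DataFrame
    early: SmoothedProfile
    late: SmoothedProfile
    delta: DeltaFProfile
    intervals: list[MappingInterval]
    filter_report: FilterReport


def analyze_pools(
    table: pd.DataFrame,
    span: float = 0.75,
    degree: int = 2,
    threshold: float = 0.25,
    n_boot: int = 0,
    seed: int = 0,
    cov_min: int = 30,
    cov_max: int = 120,
    min_freq: float = 0.20,
    parental_min: float = 0.80,
    prefiltered: bool = False,
) -> PoolScanResult:
    """Run filter → smooth → Δf → interval calling on a SNP pool table.

    With ``n_boot > 0`` a bootstrap band is attached to each pool profile.
    ``prefiltered=True`` skips the SNP filters (useful when counts were
    generated rather than called).
    """
    if prefiltered:
        filtered, report = table.copy(), FilterReport(n_input=len(table), n_retained=len(table))
    else:
        filtered, report = filter_snps(
            table, cov_min=cov_min, cov_max=cov_max, min_freq=min_freq, parental_min=parental_min
        )
    if len(filtered) == 0:
        raise ValueError("no SNPs survive filtering; nothing to smooth")
    filtered = filtered.sort_values("pos", kind="stable").reset_index(drop=True)
    pos = filtered["pos"].to_numpy(dtype=float)
    fe, fl = compute_pool_frequency(filtered)
    se = loess_smooth(pos, fe, span=span, degree=degree)
    sl = loess_smooth(pos, fl, span=span, degree=degree)
    early = SmoothedProfile(positions=pos, raw_f=fe, smooth_f=se)
    late = SmoothedProfile(positions=pos, raw_f=fl, smooth_f=sl)
    if n_boot > 0:
        early.band_lo, early.band_hi = bootstrap_band(
            pos, fe, span=span, degree=degree, n_boot=n_boot, seed=seed
        )
        late.band_lo, late.band_hi = bootstrap_band(
            pos, fl, span=span, degree=degree, n_boot=n_boot, seed=seed + 1
        )
    delta = compute_delta_f(early, late)
    chrom = str(filtered["chrom"].iloc[0]) if "chrom" in filtered else "chr1"
    intervals = call_mapping_interval(delta, threshold=threshold, chrom=chrom)
    return PoolScanResult(
        table=filtered,
        early=early,
        late=late,
        delta=delta,
        intervals=intervals,
        filter_report=report,
    )
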