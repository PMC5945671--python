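"""Tumor cell content, ploidy and allele-specific copy number estimation.

Segments carrying coverage ratios and heterozygous-SNP B-allele frequencies
are classified as balanced/imbalanced/ambiguous from the shape of their
allele-fraction density. A 2-D grid search over (TCC, ploidy) inverts the
coverage-ratio mixture model segment-wise, derives allele-specific copy
numbers and decrease of heterozygosity, and scores every grid point by the
length-weighted mean distance to the nearest allowed integer state. Local
minima of that objective are reported as candidate solutions. A second,
independent purity estimate is taken from the mode of the somatic mutant
allele fraction distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import signal, stats

__all__ = [
    "SnpSite",
    "Segment",
    "SegmentFit",
    "PurityPloidyFit",
    "MafTccEstimate",
    "select_het_snps",
    "classify_allelic_state",
    "b_allele_read_count",
    "expected_coverage_ratio",
    "coverage_ratio_to_cn",
    "allele_specific_cn",
    "fit_tcc_ploidy",
    "tcc_from_maf",
]

EXCLUDE_NEGATIVE_CN = "negative copy number"
EXCLUDE_DH = "DH larger than 1"


@dataclass
class SnpSite:
    """Allele counts at a polymorphic site in a tumor/normal pair."""

    chrom: str
    pos: int
    normal_af: float
    tumor_depth: int
    tumor_b_reads: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.normal_af <= 1.0:
            raise ValueError("normal_af must lie in [0, 1]")
        if self.tumor_b_reads > self.tumor_depth:
            raise ValueError("tumor_b_reads cannot exceed tumor_depth")

    @property
    def tumor_af(self) -> float:
        return self.tumor_b_reads / self.tumor_depth if self.tumor_depth else np.nan


@dataclass
class Segment:
    """Genomic interval with coverage ratio and het-SNP BAF summary."""

    chrom: str
    start: int
    end: int
    coverage_ratio: float
    n_het_snps: int = 0
    allelic_class: str = "insufficient"   # balanced | imbalanced | ambiguous | insufficient
    mean_baf: float | None = None
    mean_coverage: float | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start must not exceed end")
        if self.coverage_ratio < 0:
            raise ValueError("coverage_ratio must be non-negative")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def select_het_snps(
    sites: Iterable[SnpSite], low: float = 0.3, high: float = 0.7
) -> list[SnpSite]:
    """Sites heterozygous in the normal: allele fraction within [low, high]."""
    return [s for s in sites if low <= s.normal_af <= high]


def _kde_peaks(
    values: np.ndarray,
    bandwidth: float | str = "silverman",
    prominence_frac: float = 0.05,
    grid_size: int = 512,
):
    """Density peaks of allele fractions on [0, 1] with relative prominence."""
    grid = np.linspace(0.0, 1.0, grid_size)
    if np.ptp(values) < 1e-12:
        # degenerate sample: single spike at the common value
        dens = np.zeros(grid_size)
        dens[np.argmin(np.abs(grid - values[0]))] = 1.0
        return grid, dens, np.array([np.argmax(dens)])
    kde = stats.gaussian_kde(values, bw_method=bandwidth)
    dens = kde(grid)
    peaks, _ = signal.find_peaks(dens, prominence=prominence_frac * dens.max())
    # a maximum at the grid edge is not found by find_peaks; include it
    if dens[0] > dens[1]:
        peaks = np.concatenate([[0], peaks])
    if dens[-1] > dens[-2]:
        peaks = np.concatenate([peaks, [grid_size - 1]])
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(dens))])
    return grid, dens, peaks


def classify_allelic_state(
    segment: Segment,
    snps: Sequence[SnpSite],
    min_snps: int = 20,
    balanced_band: tuple[float, float] = (0.45, 0.55),
    bandwidth: float | str = "silverman",
    prominence_frac: float = 0.05,
) -> Segment:
    """Classify a segment as balanced/imbalanced/ambiguous from het-SNP BAFs.

    The tumor allele-fraction density is estimated by KDE. A global maximum
    inside ``balanced_band`` calls the segment balanced; otherwise a single
    peak makes it ambiguous (excluded downstream) and two or more peaks make
    it imbalanced, with the folded mean BAF recorded (the higher-count allele
    is the B-allele).
    """
    segment.n_het_snps = len(snps)
    if len(snps) < min_snps:
        segment.allelic_class = "insufficient"
        return segment
    afs = np.array([s.tumor_af for s in snps], dtype=float)
    afs = afs[~np.isnan(afs)]
    grid, dens, peaks = _kde_peaks(afs, bandwidth, prominence_frac)
    gmax = grid[int(np.argmax(dens))]
    if balanced_band[0] <= gmax <= balanced_band[1]:
        segment.allelic_class = "balanced"
        segment.mean_baf = None
    elif len(peaks) >= 2:
        segment.allelic_class = "imbalanced"
        segment.mean_baf = float(np.mean(np.maximum(afs, 1.0 - afs)))
    else:
        segment.allelic_class = "ambiguous"
        segment.mean_baf = None
    segment.mean_coverage = float(np.mean([s.tumor_depth for s in snps]))
    return segment


def b_allele_read_count(segment: Segment) -> float:
    """Mean B-allele read count = mean coverage x folded segment BAF."""
    if segment.mean_baf is None or segment.mean_coverage is None:
        raise ValueError("segment lacks mean BAF / coverage; classify it first")
    return segment.mean_coverage * segment.mean_baf


def expected_coverage_ratio(cn_total: float, tcc: float, ploidy: float) -> float:
    """Tumor/normal coverage ratio expected for a segment of given total CN."""
    if not 0.0 < tcc <= 1.0:
        raise ValueError("tcc must lie in (0, 1]")
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    return (tcc * cn_total + 2.0 * (1.0 - tcc)) / (tcc * ploidy + 2.0 * (1.0 - tcc))


def coverage_ratio_to_cn(ratio: float, tcc: float, ploidy: float) -> float:
    """Inverse of :func:`expected_coverage_ratio`: observed ratio -> real CN."""
    if not 0.0 < tcc <= 1.0:
        raise ValueError("tcc must lie in (0, 1]")
    return (ratio * (tcc * ploidy + 2.0 * (1.0 - tcc)) - 2.0 * (1.0 - tcc)) / tcc


def allele_specific_cn(
    segment: Segment, cn_total: float, tcc: float
) -> tuple[float, float, float]:
    """Allele-specific copies (A >= B) and decrease of heterozygosity.

    Balanced segments split the total copy number evenly (DH = 0). For
    imbalanced segments the major allele copy number is recovered from the
    folded BAF of the tumor/normal mixture and DH = |A - B| / (A + B).
    """
    if segment.allelic_class == "balanced":
        return cn_total / 2.0, cn_total / 2.0, 0.0
    if segment.allelic_class != "imbalanced":
        raise ValueError(f"cannot derive allele CNs for {segment.allelic_class} segment")
    if cn_total <= 0:
        raise ValueError("cn_total must be positive for an imbalanced segment")
    if segment.mean_baf is None:
        raise ValueError("imbalanced segment lacks mean_baf")
    major = (segment.mean_baf * (tcc * cn_total + 2.0 * (1.0 - tcc)) - (1.0 - tcc)) / tcc
    minor = cn_total - major
    dh = abs(major - minor) / cn_total
    a, b = max(major, minor), min(major, minor)
    return a, b, dh


@dataclass
class SegmentFit:
    """Per-segment result at one (TCC, ploidy) grid point."""

    segment: Segment
    cn_real: float
    cn_total: int
    a_cn: float
    b_cn: float
    dh: float


@dataclass
class PurityPloidyFit:
    """One candidate (TCC, ploidy) solution with its objective and segments."""

    tcc: float
    ploidy: float
    objective: float
    segments: list[SegmentFit] = field(default_factory=list)


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step))
    return np.round(lo + step * np.arange(n + 1), 10)


def fit_tcc_ploidy(
    segments: Sequence[Segment],
    tcc_min: float = 0.15,
    tcc_max: float = 1.0,
    tcc_step: float = 0.01,
    ploidy_min: float = 1.0,
    ploidy_max: float = 6.5,
    ploidy_step: float = 0.05,
    dh_tol: float = 0.05,
    max_fits: int | None = None,
) -> list[PurityPloidyFit]:
    """Grid search over (TCC, ploidy) for allele-specific copy number fits.

    At every grid point each balanced/imbalanced segment's coverage ratio is
    inverted to a real total copy number; balanced segments are scored by the
    distance to the nearest even integer state, imbalanced segments by the
    mean distance of total, major and minor copy numbers to the nearest
    non-negative integers. The objective is the segment-length-weighted mean
    distance. Grid points at which any segment would require a negative
    integer copy number state, or a DH above 1 (beyond ``dh_tol``), are
    excluded. All local minima of the objective (strictly below their 8 grid
    neighbors; plateaus collapsed to their lowest-ploidy members) are
    returned, ranked by objective.
    """
    used = [s for s in segments if s.allelic_class in ("balanced", "imbalanced")]
    if not used:
        raise ValueError("no balanced or imbalanced segment available for fitting")
    lengths = np.array([s.length_bp for s in used], dtype=float)
    ratios = np.array([s.coverage_ratio for s in used])
    balanced = np.array([s.allelic_class == "balanced" for s in used])
    bafs = np.array([s.mean_baf if s.mean_baf is not None else np.nan for s in used])
    if np.any(~balanced & np.isnan(bafs)):
        raise ValueError("imbalanced segment without mean BAF")

    tccs = _grid(tcc_min, tcc_max, tcc_step)
    ploidies = _grid(ploidy_min, ploidy_max, ploidy_step)
    T = tccs[:, None, None]
    P = ploidies[None, :, None]
    denom = T * P + 2.0 * (1.0 - T)                         # (t, p, 1)
    cn = (ratios[None, None, :] * denom - 2.0 * (1.0 - T)) / T   # (t, p, s)

    # balanced: distance to nearest non-negative even state
    even = np.maximum(2.0 * np.round(cn / 2.0), 0.0)
    d_bal = np.abs(cn - even)

    # imbalanced: BAF inversion to major/minor allele copies
    with np.errstate(invalid="ignore", divide="ignore"):
        major = (bafs[None, None, :] * ratios[None, None, :] * denom - (1.0 - T)) / T
        minor = cn - major
        dh = np.abs(major - minor) / cn
    d_imb = (
        np.abs(cn - np.maximum(np.round(cn), 0.0))
        + np.abs(major - np.maximum(np.round(major), 0.0))
        + np.abs(minor - np.maximum(np.round(minor), 0.0))
    ) / 3.0

    dist = np.where(balanced[None, None, :], d_bal, np.where(np.isnan(d_imb), 0.0, d_imb))
    objective = (dist * lengths[None, None, :]).sum(axis=2) / lengths.sum()

    neg_total = np.round(cn) < 0
    neg_allele = ~balanced[None, None, :] & (
        (np.round(np.where(np.isnan(minor), 0.0, minor)) < 0)
        | (np.round(np.where(np.isnan(major), 0.0, major)) < 0)
    )
    bad_dh = ~balanced[None, None, :] & (
        np.where(np.isnan(dh), 0.0, dh) > 1.0 + dh_tol
    ) | (~balanced[None, None, :] & (cn <= 0))
    excl_neg = (neg_total | neg_allele).any(axis=2)
    excl_dh = bad_dh.any(axis=2)
    excluded = excl_neg | excl_dh

    obj = np.where(excluded, np.inf, objective)
    if not np.isfinite(obj).any():
        raise ValueError("all (TCC, ploidy) grid points excluded; no solution")

    minima = _local_minima(obj)
    fits: list[PurityPloidyFit] = []
    for ti, pi in minima:
        tcc, ploidy = float(tccs[ti]), float(ploidies[pi])
        segfits = []
        for si, seg in enumerate(used):
            c = float(cn[ti, pi, si])
            if balanced[si]:
                a = b = c / 2.0
                d = 0.0
            else:
                a = float(max(major[ti, pi, si], minor[ti, pi, si]))
                b = float(min(major[ti, pi, si], minor[ti, pi, si]))
                d = float(np.clip(dh[ti, pi, si], 0.0, 1.0))
            segfits.append(
                SegmentFit(
                    segment=seg,
                    cn_real=c,
                    cn_total=int(max(round(c), 0)),
                    a_cn=a,
                    b_cn=max(b, 0.0),
                    dh=d,
                )
            )
        fits.append(PurityPloidyFit(tcc, ploidy, float(obj[ti, pi]), segfits))
    fits.sort(key=lambda f: (f.objective, f.ploidy, f.tcc))
    return fits[:max_fits] if max_fits else fits


def grid_exclusion_reason(
    segments: Sequence[Segment], tcc: float, ploidy: float, dh_tol: float = 0.05
) -> str | None:
    """Why a single (TCC, ploidy) point would be excluded, or None if allowed."""
    for seg in segments:
        if seg.allelic_class not in ("balanced", "imbalanced"):
            continue
        cn = coverage_ratio_to_cn(seg.coverage_ratio, tcc, ploidy)
        if round(cn) < 0:
            return EXCLUDE_NEGATIVE_CN
        if seg.allelic_class == "imbalanced":
            if cn <= 0:
                return EXCLUDE_DH
            a, b, dh = allele_specific_cn(seg, cn, tcc)
            if round(b) < 0 or round(a) < 0:
                return EXCLUDE_NEGATIVE_CN
            if dh > 1.0 + dh_tol:
                return EXCLUDE_DH
    return None


def _local_minima(obj: np.ndarray) -> list[tuple[int, int]]:
    """Indices of local minima on a 2-D grid (<= all 8 neighbors).

    Plateaus (connected runs of equal objective that are local minima as a
    set) are collapsed to their lowest-ploidy members.
    """
    padded = np.full((obj.shape[0] + 2, obj.shape[1] + 2), np.inf)
    padded[1:-1, 1:-1] = obj
    neigh = np.full(obj.shape, np.inf)
    for dt in (-1, 0, 1):
        for dp in (-1, 0, 1):
            if dt == 0 and dp == 0:
                continue
            neigh = np.minimum(
                neigh, padded[1 + dt : 1 + dt + obj.shape[0], 1 + dp : 1 + dp + obj.shape[1]]
            )
    cand = np.isfinite(obj) & (obj <= neigh)
    if not cand.any():
        return []
    # connected components (8-connectivity) among equal-valued candidates
    labels = -np.ones(obj.shape, dtype=int)
    comp = 0
    coords = list(zip(*np.nonzero(cand)))
    cand_set = set(coords)
    for start in coords:
        if labels[start] >= 0:
            continue
        stack = [start]
        labels[start] = comp
        while stack:
            t, p = stack.pop()
            for dt in (-1, 0, 1):
                for dp in (-1, 0, 1):
                    q = (t + dt, p + dp)
                    if q in cand_set and labels[q] < 0 and np.isclose(obj[q], obj[t, p]):
                        labels[q] = comp
                        stack.append(q)
        comp += 1
    minima: list[tuple[int, int]] = []
    for c in range(comp):
        members = np.argwhere(labels == c)
        min_p = members[:, 1].min()
        minima.extend((int(t), int(p)) for t, p in members if p == min_p)
    return minima


@dataclass
class MafTccEstimate:
    """Purity estimate from the somatic mutant allele fraction mode."""

    tcc_maf: float
    maf_mode: float
    reliable: bool = True


def tcc_from_maf(
    somatic_mafs: Sequence[float],
    bandwidth: float | str = "silverman",
    min_snvs: int = 10,
) -> MafTccEstimate:
    """Purity from the MAF density mode: TCC = min(1, 2 x mode).

    Assumes the mode is carried by clonal heterozygous mutations on a diploid
    background.
    """
    mafs = np.asarray(somatic_mafs, dtype=float)
    mafs = mafs[~np.isnan(mafs)]
    if len(mafs) == 0:
        raise ValueError("no somatic MAFs provided")
    reliable = len(mafs) >= min_snvs
    if not reliable:
        warnings.warn(
            f"only {len(mafs)} somatic SNVs; MAF-based TCC estimate is unreliable",
            stacklevel=2,
        )
    grid, dens, _ = _kde_peaks(mafs, bandwidth)
    mode = float(grid[int(np.argmax(dens))])
    return MafTccEstimate(tcc_maf=min(1.0, 2.0 * mode), maf_mode=mode, reliable=reliable)
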