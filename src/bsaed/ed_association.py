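"""The Euclidean-distance association scan.

Per retained SNP, each pool's reads are reduced to a four-base frequency
vector and the pools are compared with

    ED = sqrt( sum_{b in A,C,G,T} (f_high,b - f_low,b)^2 )

ED is bounded by sqrt(2) for biallelic sites and by 2 in general; it is
raised to the fourth power (ED^4) to suppress background noise, smoothed
along each chromosome with a tricube-weighted local polynomial (degree 2,
span = fraction of that chromosome's SNPs), and thresholded genome-wide
at median + 3 * sample SD of the fitted values.  Maximal above-threshold
SNP runs become candidate regions; in-region SNPs with high-pool alt
frequency > 0.75 and raw ED > 0.5 become candidate SNPs.

Note on the statistic: some descriptions of this method print "+" signs
inside three of the four squared terms; a Euclidean distance requires
differences throughout (with plus signs the statistic would be nonzero
for identical pools), so differences are used for all four bases.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from bsaed.pool_io import BASE_INDEX, AnnotationRecord, PooledSiteCounts
from bsaed.site_filtering import GenotypeCall, classify_genotype

__all__ = [
    "AssociationScore",
    "AssociationThreshold",
    "CandidateRegion",
    "CandidateSNP",
    "call_regions",
    "compute_ed",
    "compute_threshold",
    "ed_to_association",
    "fit_local_polynomial",
    "fit_scores",
    "pool_frequencies",
    "score_sites",
    "select_candidates",
]

logger = logging.getLogger(__name__)


def pool_frequencies(site: PooledSiteCounts) -> tuple[np.ndarray, np.ndarray]:
    """Per-pool four-base frequency vectors (A,C,G,T order), each summing to 1."""
    if site.high_depth == 0 or site.low_depth == 0:
        raise ValueError(
            f"zero pool depth at {site.chrom}:{site.pos}; "
            "apply the depth filter before scoring"
        )
    high = np.asarray(site.high_counts, dtype=float) / site.high_depth
    low = np.asarray(site.low_counts, dtype=float) / site.low_depth
    return high, low


def compute_ed(high: Sequence[float], low: Sequence[float]) -> float:
    """Euclidean distance between two four-base frequency vectors."""
    h = np.asarray(high, dtype=float)
    l = np.asarray(low, dtype=float)
    return float(np.sqrt(np.sum((h - l) ** 2)))


def ed_to_association(ed: float) -> float:
    """ED^4, the per-site association value."""
    if ed < 0:
        raise ValueError("ED must be non-negative")
    return float(ed) ** 4


@dataclass(frozen=True)
class AssociationScore:
    """Per-site scan values: ED, ED^4, smoothed ED^4 and pool alt frequencies."""

    chrom: str
    pos: int
    ed: float
    ed4: float
    high_alt_freq: float
    low_alt_freq: float
    fitted: float = math.nan


def score_sites(sites: Sequence[PooledSiteCounts]) -> list[AssociationScore]:
    """Compute ED and ED^4 for every (pre-filtered) site."""
    scores = []
    for site in sites:
        high, low = pool_frequencies(site)
        ed = compute_ed(high, low)
        ai = BASE_INDEX[site.alt]
        scores.append(
            AssociationScore(
                chrom=site.chrom,
                pos=site.pos,
                ed=ed,
                ed4=ed_to_association(ed),
                high_alt_freq=float(high[ai]),
                low_alt_freq=float(low[ai]),
            )
        )
    return scores


# --------------------------------------------------------------------------
# smoothing


def _neighbour_windows(x: np.ndarray, k: int) -> np.ndarray:
    """Start index of each point's k-nearest-neighbour window in sorted x."""
    n = len(x)
    starts = np.empty(n, dtype=np.intp)
    s = 0
    for i in range(n):
        if s < i - k + 1:
            s = i - k + 1
        # slide right while the incoming right neighbour is closer than the
        # outgoing left one
        while s + k < n and s < i and x[s + k] - x[i] < x[i] - x[s]:
            s += 1
        starts[i] = s
    return starts


def fit_local_polynomial(
    positions: Sequence[float],
    values: Sequence[float],
    span: float = 0.05,
    degree: int = 2,
    _block: int = 2048,
) -> np.ndarray:
    """Tricube-weighted local polynomial fit evaluated at every input position.

    ``span`` is the fraction of points in each local window (k-nearest
    neighbours along genomic position).  Positions must be sorted
    ascending.  With fewer than ``degree + 2`` points the chromosome mean
    is returned with a warning.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("positions and values must be 1-D and equal length")
    if np.any(np.diff(x) < 0):
        raise ValueError("positions must be sorted ascending")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    n = len(x)
    if n < degree + 2:
        logger.warning(
            "only %d sites on chromosome: falling back to the mean", n
        )
        return np.full(n, y.mean() if n else np.nan)

    k = int(np.ceil(span * n))
    k = min(n, max(k, degree + 2))
    starts = _neighbour_windows(x, k)
    cols = np.arange(k)
    fitted = np.empty(n)
    ridge = 1e-10 * np.eye(degree + 1)

    for lo in range(0, n, _block):
        hi = min(lo + _block, n)
        idx = starts[lo:hi, None] + cols  # (b, k)
        xw = x[idx]
        yw = y[idx]
        d = np.abs(xw - x[lo:hi, None])
        dmax = d.max(axis=1)
        dmax[dmax == 0] = 1.0  # coincident positions: uniform weights
        u = np.minimum(d / dmax[:, None], 1.0)
        w = (1.0 - u**3) ** 3
        t = (xw - x[lo:hi, None]) / dmax[:, None]  # centred, scaled for conditioning
        V = np.ones(t.shape + (degree + 1,))  # Vandermonde (b, k, p)
        for p in range(1, degree + 1):
            V[..., p] = V[..., p - 1] * t
        Vw = (V * w[..., None]).transpose(0, 2, 1)
        A = Vw @ V + ridge
        rhs = Vw @ yw[..., None]
        beta = np.linalg.solve(A, rhs)[..., 0]
        fitted[lo:hi] = beta[:, 0]  # prediction at t == 0
    return fitted


def fit_scores(
    scores: Sequence[AssociationScore], span: float = 0.05, degree: int = 2
) -> list[AssociationScore]:
    """Smooth ED^4 per chromosome; returns new scores with ``fitted`` set."""
    out: list[AssociationScore] = [None] * len(scores)  # type: ignore[list-item]
    by_chrom: dict[str, list[int]] = {}
    for i, s in enumerate(scores):
        by_chrom.setdefault(s.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        idx.sort(key=lambda i: scores[i].pos)
        pos = [scores[i].pos for i in idx]
        ed4 = [scores[i].ed4 for i in idx]
        fitted = fit_local_polynomial(pos, ed4, span=span, degree=degree)
        for i, f in zip(idx, fitted):
            out[i] = replace(scores[i], fitted=float(f))
    return out


# --------------------------------------------------------------------------
# thresholding and region calling


@dataclass(frozen=True)
class AssociationThreshold:
    median_fitted: float
    sd_fitted: float
    k: float = 3.0

    @property
    def threshold(self) -> float:
        return self.median_fitted + self.k * self.sd_fitted


def compute_threshold(fitted: Sequence[float], k: float = 3.0) -> AssociationThreshold:
    """median + k * sample SD (ddof=1) over all chromosomes pooled."""
    arr = np.asarray(fitted, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 fitted values for a threshold")
    return AssociationThreshold(
        median_fitted=float(np.median(arr)),
        sd_fitted=float(np.std(arr, ddof=1)),
        k=k,
    )


@dataclass
class CandidateRegion:
    """A maximal run of above-threshold SNPs on one chromosome (1-based, inclusive)."""

    chrom: str
    start_pos: int
    end_pos: int
    members: list[AssociationScore] = field(default_factory=list)
    peak_fitted: float = math.nan


def call_regions(
    scores: Sequence[AssociationScore],
    threshold: AssociationThreshold | float,
    max_gap_snps: int = 0,
    min_region_snps: int = 1,
) -> list[CandidateRegion]:
    """Maximal runs of consecutive SNPs with fitted > threshold.

    Runs separated by at most ``max_gap_snps`` below-threshold SNPs are
    merged (the gap SNPs are not members); runs with fewer than
    ``min_region_snps`` members are dropped.
    """
    cut = threshold.threshold if isinstance(threshold, AssociationThreshold) else float(threshold)
    by_chrom: dict[str, list[AssociationScore]] = {}
    for s in scores:
        by_chrom.setdefault(s.chrom, []).append(s)

    regions: list[CandidateRegion] = []
    for chrom in sorted(by_chrom):
        chrom_scores = sorted(by_chrom[chrom], key=lambda s: s.pos)
        members: list[AssociationScore] = []
        gap = 0
        for s in chrom_scores:
            if s.fitted > cut:
                members.append(s)
                gap = 0
            elif members:
                gap += 1
                if gap > max_gap_snps:
                    regions.append(_make_region(chrom, members))
                    members = []
                    gap = 0
        if members:
            regions.append(_make_region(chrom, members))
    regions = [r for r in regions if len(r.members) >= min_region_snps]
    regions.sort(key=lambda r: (r.chrom, r.start_pos))
    return regions


def _make_region(chrom: str, members: list[AssociationScore]) -> CandidateRegion:
    return CandidateRegion(
        chrom=chrom,
        start_pos=members[0].pos,
        end_pos=members[-1].pos,
        members=list(members),
        peak_fitted=max(m.fitted for m in members),
    )


@dataclass(frozen=True)
class CandidateSNP:
    """An in-region SNP passing the frequency and ED cuts, with its annotation."""

    score: AssociationScore
    high_call: GenotypeCall
    low_call: GenotypeCall
    annotation: AnnotationRecord | None = None


def select_candidates(
    regions: Sequence[CandidateRegion],
    sites: Iterable[PooledSiteCounts],
    annotations: Iterable[AnnotationRecord] = (),
    freq_cut: float = 0.75,
    ed_cut: float = 0.5,
) -> list[CandidateSNP]:
    """In-region SNPs with high-pool alt frequency > ``freq_cut`` and ED > ``ed_cut``."""
    site_map: Mapping[tuple[str, int], PooledSiteCounts] = {
        (s.chrom, s.pos): s for s in sites
    }
    ann_map = {(a.chrom, a.pos): a for a in annotations}
    candidates: list[CandidateSNP] = []
    for region in regions:
        for score in region.members:
            if not (score.high_alt_freq > freq_cut and score.ed > ed_cut):
                continue
            site = site_map.get((score.chrom, score.pos))
            if site is None:
                raise KeyError(f"no site counts for {score.chrom}:{score.pos}")
            candidates.append(
                CandidateSNP(
                    score=score,
                    high_call=classify_genotype(*site.high_ref_alt),
                    low_call=classify_genotype(*site.low_ref_alt),
                    annotation=ann_map.get((score.chrom, score.pos)),
                )
            )
    return candidates
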