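"""Per-sample genotype classification and the three pre-scan site filters.

Genotype rule (per sample, from AD-derived ref/alt read counts):

* depth < 5 -> NA ("deletion")
* alt frequency >= 0.8 -> hom_alt; <= 0.2 -> hom_ref (purity confirmed)
* 0.2 < freq < 0.8 with >= 4 reads supporting EACH allele -> het
* anything else -> NA

Pre-scan filters, applied in order with first-match attribution:

1. drop non-biallelic sites;
2. drop sites whose wild-type (low) pool has any base at frequency >= 95%;
3. drop sites where either pool's depth is below 10X.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from bsaed.pool_io import PooledSiteCounts

__all__ = [
    "FilterReport",
    "GenotypeCall",
    "apply_pre_ed_filters",
    "classify_genotype",
]

MIN_CALL_DEPTH = 5
MIN_HET_READS = 4
HOM_FREQ = 0.8


@dataclass(frozen=True)
class GenotypeCall:
    """A per-sample call: NA / hom_ref / hom_alt / het, with the alt frequency."""

    call: str
    alt_frequency: float  # NaN when depth == 0

    def __post_init__(self) -> None:
        assert self.call in {"NA", "hom_ref", "hom_alt", "het"}


def classify_genotype(ref_reads: int, alt_reads: int) -> GenotypeCall:
    """Classify one sample at one SNP from its ref/alt read counts."""
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    depth = ref_reads + alt_reads
    freq = alt_reads / depth if depth > 0 else math.nan
    if depth < MIN_CALL_DEPTH:
        return GenotypeCall("NA", freq)
    # integer comparisons keep the 0.8 / 0.2 boundaries exact
    if alt_reads * 5 >= depth * 4:
        return GenotypeCall("hom_alt", freq)
    if alt_reads * 5 <= depth:
        return GenotypeCall("hom_ref", freq)
    if ref_reads >= MIN_HET_READS and alt_reads >= MIN_HET_READS:
        return GenotypeCall("het", freq)
    return GenotypeCall("NA", freq)


@dataclass
class FilterReport:
    n_input: int = 0
    n_removed_multiallelic: int = 0
    n_removed_wt_fixed: int = 0
    n_removed_low_depth: int = 0
    n_retained: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        removed = (
            self.n_removed_multiallelic
            + self.n_removed_wt_fixed
            + self.n_removed_low_depth
        )
        if self.n_input != self.n_retained + removed:
            raise ValueError("filter report counts do not conserve")

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_removed_multiallelic": self.n_removed_multiallelic,
            "n_removed_wt_fixed": self.n_removed_wt_fixed,
            "n_removed_low_depth": self.n_removed_low_depth,
            "n_retained": self.n_retained,
        }


def _wt_fixed(counts: Sequence[int], cutoff: float) -> bool:
    depth = sum(counts)
    if depth == 0:
        return False
    return max(counts) / depth >= cutoff


def apply_pre_ed_filters(
    sites: Iterable[PooledSiteCounts],
    wt_fixation_cutoff: float = 0.95,
    min_pool_depth: int = 10,
) -> tuple[list[PooledSiteCounts], FilterReport]:
    """Apply the three ordered site filters; attribute each removal to its first match."""
    retained: list[PooledSiteCounts] = []
    n_multi = n_fixed = n_depth = n_input = 0
    for site in sites:
        n_input += 1
        if site.n_alleles != 2:
            n_multi += 1
            continue
        if _wt_fixed(site.low_counts, wt_fixation_cutoff):
            n_fixed += 1
            continue
        if site.high_depth < min_pool_depth or site.low_depth < min_pool_depth:
            n_depth += 1
            continue
        retained.append(site)
    report = FilterReport(
        n_input=n_input,
        n_removed_multiallelic=n_multi,
        n_removed_wt_fixed=n_fixed,
        n_removed_low_depth=n_depth,
        n_retained=len(retained),
    )
    return retained, report
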