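"""Phenotype-side statistics: trait grouping, bulk selection and marker tests.

Implements the study-design helpers (low/mid/high trait grouping at
0.5 / 1.0 ng/mL, top-k / bottom-k bulk selection) and the validation
statistics (per-genotype trait means, genotype proportions, and a Pearson
correlation between allele dosage and trait with a two-sided t test).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import pearsonr

from bsaed.pool_io import ParseError, PhenotypeRecord

__all__ = [
    "GenotypeTable",
    "MarkerTestResult",
    "classify_trait_groups",
    "genotype_proportions",
    "marker_trait_pearson",
    "per_genotype_trait_means",
    "select_bulks",
]

_ALLELES = set("ACGT")


class DegenerateInputError(ValueError):
    """Constant dosage or constant trait: the Pearson test is undefined."""


def _normalize_genotype(g: str) -> str:
    g = g.strip().upper()
    if len(g) != 2 or not set(g) <= _ALLELES:
        raise ValueError(f"malformed genotype {g!r}")
    return "".join(sorted(g))


class GenotypeTable:
    """animal_id x marker_id -> two-allele genotype string (alphabetical order)."""

    def __init__(self, calls: Mapping[tuple[str, str], str] | None = None):
        self._calls: dict[tuple[str, str], str] = {}
        for (animal, marker), g in (calls or {}).items():
            self._calls[(str(animal), str(marker))] = _normalize_genotype(g)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("animal_id", "marker_id", "genotype"):
            if col not in df.columns:
                raise ParseError(f"genotype file missing required column {col!r}")
        calls = {}
        for r in df.itertuples(index=False):
            if pd.isna(r.genotype) or r.genotype in {".", "NA", ""}:
                continue
            calls[(r.animal_id, r.marker_id)] = r.genotype
        return cls(calls)

    def markers(self) -> list[str]:
        return sorted({m for _, m in self._calls})

    def genotypes_at(self, marker: str) -> dict[str, str]:
        """Non-missing animal -> genotype calls at one marker."""
        return {a: g for (a, m), g in self._calls.items() if m == marker}

    def set(self, animal_id: str, marker_id: str, genotype: str) -> None:
        self._calls[(animal_id, marker_id)] = _normalize_genotype(genotype)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"animal_id": a, "marker_id": m, "genotype": g}
            for (a, m), g in sorted(self._calls.items())
        ]
        pd.DataFrame(rows, columns=["animal_id", "marker_id", "genotype"]).to_csv(
            path, sep="\t", index=False
        )


def classify_trait_groups(
    records: Sequence[PhenotypeRecord],
    low_max: float = 0.5,
    high_min: float = 1.0,
    channel: str = "milk",
) -> tuple[dict[str, str], dict[str, float]]:
    """Label each animal low (<= low_max), high (> high_min) or mid.

    Returns (animal_id -> label, label -> proportion).  The boundaries
    follow the printed ranges: 0-0.5 inclusive is low, strictly above 1
    is high.
    """
    if low_max > high_min:
        raise ValueError("low_max must not exceed high_min")
    labels: dict[str, str] = {}
    for rec in records:
        v = rec.value(channel)
        if v <= low_max:
            labels[rec.animal_id] = "low"
        elif v > high_min:
            labels[rec.animal_id] = "high"
        else:
            labels[rec.animal_id] = "mid"
    n = len(labels)
    counts = Counter(labels.values())
    proportions = {g: counts.get(g, 0) / n for g in ("low", "mid", "high")} if n else {}
    return labels, proportions


def select_bulks(
    records: Sequence[PhenotypeRecord],
    k: int = 3,
    channel: str = "milk",
) -> tuple[list[str], list[str]]:
    """Top-k and bottom-k animal IDs by trait value (ties broken by ID ascending)."""
    if len(records) < 2 * k:
        raise ValueError(f"need at least {2 * k} records, got {len(records)}")
    high = sorted(records, key=lambda r: (-r.value(channel), r.animal_id))[:k]
    low = sorted(records, key=lambda r: (r.value(channel), r.animal_id))[:k]
    return [r.animal_id for r in high], [r.animal_id for r in low]


def genotype_proportions(
    table: GenotypeTable, marker: str
) -> tuple[dict[str, float], str]:
    """Genotype -> fraction over non-missing calls, plus the dominant genotype."""
    calls = table.genotypes_at(marker)
    if not calls:
        raise ValueError(f"no genotype calls at marker {marker!r}")
    counts = Counter(calls.values())
    total = sum(counts.values())
    fractions = {g: c / total for g, c in counts.items()}
    dominant = max(counts, key=lambda g: (counts[g], g))
    return fractions, dominant


def per_genotype_trait_means(
    table: GenotypeTable,
    marker: str,
    phenotypes: Sequence[PhenotypeRecord],
    channel: str = "milk",
) -> dict[str, float]:
    """Arithmetic mean trait value per genotype class at one marker."""
    calls = table.genotypes_at(marker)
    values: dict[str, list[float]] = {}
    for rec in phenotypes:
        g = calls.get(rec.animal_id)
        if g is not None:
            values.setdefault(g, []).append(rec.value(channel))
    if not values:
        raise ValueError(f"no animals with both genotype and phenotype at {marker!r}")
    return {g: sum(v) / len(v) for g, v in values.items()}


@dataclass(frozen=True)
class MarkerTestResult:
    marker_id: str
    coding: Mapping[str, int]
    pearson_r: float
    p_value: float
    n_used: int


def _infer_alt_allele(genotypes: Iterable[str]) -> str:
    """Default dosage coding counts the minor allele (ties: lexicographic)."""
    alleles = Counter()
    for g in genotypes:
        alleles.update(g)
    if len(alleles) < 2:
        raise DegenerateInputError("marker has a single allele; dosage is constant")
    return min(alleles, key=lambda a: (alleles[a], a))


def marker_trait_pearson(
    table: GenotypeTable,
    marker: str,
    phenotypes: Sequence[PhenotypeRecord],
    channel: str = "milk",
    alt_allele: str | None = None,
    binary_carrier: bool = False,
) -> MarkerTestResult:
    """Pearson correlation of allele dosage (0/1/2) against the trait.

    ``alt_allele`` fixes which allele is counted; by default the minor
    allele at the marker is used.  ``binary_carrier`` collapses dosage to
    a 0/1 carrier indicator.  The p-value is two-sided from the t
    distribution with n - 2 df (as computed by scipy's pearsonr).
    """
    calls = table.genotypes_at(marker)
    paired = [
        (calls[rec.animal_id], rec.value(channel))
        for rec in phenotypes
        if rec.animal_id in calls
    ]
    if len(paired) < 3:
        raise ValueError(f"need >= 3 animals with genotype and trait at {marker!r}")
    if alt_allele is None:
        alt_allele = _infer_alt_allele(g for g, _ in paired)
    dosages = [g.count(alt_allele) for g, _ in paired]
    if binary_carrier:
        dosages = [min(d, 1) for d in dosages]
    traits = [t for _, t in paired]
    if len(set(dosages)) < 2:
        raise DegenerateInputError(f"constant dosage at marker {marker!r}")
    if len(set(traits)) < 2:
        raise DegenerateInputError(f"constant trait values at marker {marker!r}")
    r, p = pearsonr(dosages, traits)
    coding = {g: g.count(alt_allele) for g in sorted(set(g for g, _ in paired))}
    if binary_carrier:
        coding = {g: min(d, 1) for g, d in coding.items()}
    return MarkerTestResult(
        marker_id=marker,
        coding=coding,
        pearson_r=float(r),
        p_value=float(p),
        n_used=len(paired),
    )
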