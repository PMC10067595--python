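"""Readers and writers for the pooled-sequencing scan.

Input side: a two-sample VCF carrying per-pool allele depths (FORMAT
``GT:AD:DP``), a per-SNP functional annotation TSV, an animal phenotype
CSV and a two-column gene-set TSV.  Output side: candidate-SNP TSV,
region BED (0-based half-open) and the per-site scan track TSV.

Base counts are assembled from the AD field only: the ref count goes to
the REF base, each alt count to its ALT base, zeros elsewhere.  AD is
authoritative even when DP disagrees; DP is kept for reporting only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BASES",
    "BASE_INDEX",
    "AnnotationRecord",
    "PhenotypeRecord",
    "PooledSiteCounts",
    "read_annotation",
    "read_gene_sets",
    "read_phenotypes",
    "read_pool_vcf",
    "write_candidates_tsv",
    "write_regions_bed",
    "write_track_tsv",
]

BASES = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

REGION_CLASSES = frozenset(
    {"exonic", "intronic", "ncRNA", "UTR5", "UTR3", "intergenic", "splicing"}
)
MUTATION_CLASSES = frozenset(
    {"synonymous", "non-synonymous", "stopgain", "stoploss", "NA"}
)


class ParseError(ValueError):
    """Malformed input file."""


class ConfigurationError(ValueError):
    """Inconsistent caller-supplied configuration (e.g. unknown sample name)."""


@dataclass(frozen=True)
class PooledSiteCounts:
    """One biallelic (or to-be-filtered multiallelic) site with per-pool base counts.

    ``high_counts`` / ``low_counts`` are length-4 tuples in A,C,G,T order;
    the high-trait bulk plays the "mutant pool" role of the ED statistic
    and the low-trait bulk the "wild-type pool" role.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    high_counts: tuple[int, int, int, int]
    low_counts: tuple[int, int, int, int]
    n_alleles: int = 2

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def high_depth(self) -> int:
        return int(sum(self.high_counts))

    @property
    def low_depth(self) -> int:
        return int(sum(self.low_counts))

    def _pair(self, counts: Sequence[int]) -> tuple[int, int]:
        return int(counts[BASE_INDEX[self.ref]]), int(counts[BASE_INDEX[self.alt]])

    @property
    def high_ref_alt(self) -> tuple[int, int]:
        """(ref reads, alt reads) in the high bulk."""
        return self._pair(self.high_counts)

    @property
    def low_ref_alt(self) -> tuple[int, int]:
        return self._pair(self.low_counts)


@dataclass(frozen=True)
class AnnotationRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    region_class: str
    mutation_class: str = "NA"
    aa_change: str = "."

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ParseError(
                f"unknown region_class {self.region_class!r} at {self.chrom}:{self.pos}"
            )
        if self.mutation_class not in MUTATION_CLASSES:
            raise ParseError(
                f"unknown mutation_class {self.mutation_class!r} at {self.chrom}:{self.pos}"
            )


@dataclass(frozen=True)
class PhenotypeRecord:
    animal_id: str
    milk_trait: float
    blood_trait: float

    def __post_init__(self) -> None:
        if self.milk_trait < 0 or self.blood_trait < 0:
            raise ValueError(f"negative trait value for {self.animal_id}")

    def value(self, channel: str) -> float:
        if channel == "milk":
            return self.milk_trait
        if channel == "blood":
            return self.blood_trait
        raise ValueError(f"unknown channel {channel!r}")


def read_pool_vcf(
    path: str | Path,
    high_sample_name: str = "HIGH_BULK",
    low_sample_name: str = "LOW_BULK",
) -> list[PooledSiteCounts]:
    """Read a two-pool VCF into :class:`PooledSiteCounts`.

    Counts are derived from AD; records with missing AD in either sample
    get zero counts (depth 0) so the downstream 10X filter removes them.
    Non-SNP alleles (length != 1 or not ACGT) raise a parse error.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in (high_sample_name, low_sample_name):
        if name not in samples:
            raise ConfigurationError(
                f"sample {name!r} not in VCF header (samples: {samples})"
            )
    hi = samples.index(high_sample_name)
    lo = samples.index(low_sample_name)

    sites: list[PooledSiteCounts] = []
    for var in vcf:
        alts = list(var.ALT)
        alleles = [var.REF] + alts
        for a in alleles:
            if len(a) != 1 or a not in BASE_INDEX:
                raise ParseError(
                    f"non-SNP allele {a!r} at {var.CHROM}:{var.POS}"
                )
        ad = var.format("AD")
        counts = {hi: [0, 0, 0, 0], lo: [0, 0, 0, 0]}
        if ad is not None:
            ad = np.asarray(ad)
            for s in (hi, lo):
                row = ad[s]
                if np.any(row < 0):  # cyvcf2 encodes missing as large negatives
                    continue
                for allele, n in zip(alleles, row):
                    counts[s][BASE_INDEX[allele]] += int(n)
        sites.append(
            PooledSiteCounts(
                chrom=var.CHROM,
                pos=int(var.POS),
                ref=var.REF,
                alt=alts[0] if alts else var.REF,
                high_counts=tuple(counts[hi]),
                low_counts=tuple(counts[lo]),
                n_alleles=1 + len(alts),
            )
        )
    return sites


_ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene_id",
    "region_class",
    "mutation_class",
    "aa_change",
]


def read_annotation(path: str | Path) -> list[AnnotationRecord]:
    """Read the per-SNP annotation TSV (one row per SNP)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _ANNOTATION_COLUMNS[:6]:
        if col not in df.columns:
            raise ParseError(f"annotation file missing required column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            AnnotationRecord(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                gene_id=str(row.gene_id),
                region_class=str(row.region_class),
                mutation_class=str(getattr(row, "mutation_class", "NA") or "NA"),
                aa_change=str(getattr(row, "aa_change", ".") or "."),
            )
        )
    return records


def read_phenotypes(path: str | Path) -> list[PhenotypeRecord]:
    """Read the animal phenotype CSV (animal_id, milk_trait, blood_trait)."""
    df = pd.read_csv(path, dtype={"animal_id": str})
    for col in ("animal_id", "milk_trait", "blood_trait"):
        if col not in df.columns:
            raise ParseError(f"phenotype file missing required column {col!r}")
    return [
        PhenotypeRecord(str(r.animal_id), float(r.milk_trait), float(r.blood_trait))
        for r in df.itertuples(index=False)
    ]


def read_gene_sets(path: str | Path):
    """Read a two-column term_id<TAB>gene_id file into a :class:`GeneSetDatabase`."""
    from bsaed.annotation_enrichment import GeneSetDatabase

    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return GeneSetDatabase(terms={}, background=0)
        if [c.strip() for c in header[:2]] != ["term_id", "gene_id"]:
            raise ParseError("gene-set file must have columns term_id, gene_id")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ParseError(f"gene-set line {lineno}: expected 2 columns")
            terms.setdefault(row[0], set()).add(row[1])
    genes = set().union(*terms.values()) if terms else set()
    return GeneSetDatabase(
        terms={t: frozenset(g) for t, g in terms.items()}, background=len(genes)
    )


# --------------------------------------------------------------------------
# writers


def write_regions_bed(regions: Iterable, path: str | Path) -> None:
    """Write candidate regions as BED3+ (0-based half-open, from 1-based SNP anchors)."""
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tn_snps\tpeak_fitted\n")
        for reg in regions:
            fh.write(
                f"{reg.chrom}\t{reg.start_pos - 1}\t{reg.end_pos}\t"
                f"{len(reg.members)}\t{reg.peak_fitted:.6g}\n"
            )


_TRACK_COLUMNS = ["chrom", "pos", "ed", "ed4", "fitted", "high_alt_freq", "low_alt_freq"]


def write_track_tsv(scores: Iterable, path: str | Path) -> None:
    rows = [
        {
            "chrom": s.chrom,
            "pos": s.pos,
            "ed": s.ed,
            "ed4": s.ed4,
            "fitted": s.fitted,
            "high_alt_freq": s.high_alt_freq,
            "low_alt_freq": s.low_alt_freq,
        }
        for s in scores
    ]
    pd.DataFrame(rows, columns=_TRACK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_track_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_candidates_tsv(candidates: Iterable, path: str | Path) -> None:
    cols = [
        "chrom",
        "pos",
        "ed",
        "ed4",
        "fitted",
        "high_alt_freq",
        "high_call",
        "low_call",
        "gene_id",
        "region_class",
        "mutation_class",
        "aa_change",
    ]
    rows = []
    for c in candidates:
        ann = c.annotation
        rows.append(
            {
                "chrom": c.score.chrom,
                "pos": c.score.pos,
                "ed": c.score.ed,
                "ed4": c.score.ed4,
                "fitted": c.score.fitted,
                "high_alt_freq": c.score.high_alt_freq,
                "high_call": c.high_call.call,
                "low_call": c.low_call.call,
                "gene_id": ann.gene_id if ann else ".",
                "region_class": ann.region_class if ann else ".",
                "mutation_class": ann.mutation_class if ann else ".",
                "aa_change": ann.aa_change if ann else ".",
            }
        )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
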