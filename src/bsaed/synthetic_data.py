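"""Synthetic pooled-sequencing generator with a planted causal locus.

Two phenotype-extreme pools are simulated over biallelic SNPs: outside
the causal interval both pools share one background alt frequency drawn
per site; inside it the expected frequency interpolates linearly from the
background to the configured core values with distance from the causal
center (a simple monotone linkage-decay model).  Read counts are
binomial at the site frequency with per-pool Poisson depths, and
sequencing error redistributes miscalled reads uniformly over the three
other bases.  Animal-level phenotypes carry an additive effect of the
causal-allele dosage.

``write_fixture_bundle`` serialises a run as the plain-text inputs the
pipeline consumes: a two-sample VCF, phenotype CSV, genotype TSV at the
causal marker, per-SNP annotation TSV and a gene-set TSV whose first term
contains the causal gene.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from bsaed.pool_io import BASES, BASE_INDEX, PhenotypeRecord, PooledSiteCounts
from bsaed.site_filtering import classify_genotype

__all__ = ["SimConfig", "TruthRecord", "simulate_phenotypes", "simulate_pools", "write_fixture_bundle"]


@dataclass(frozen=True)
class SimConfig:
    n_chromosomes: int = 2
    chrom_length_bp: int = 100_000_000
    n_snps_per_chrom: int = 10_000
    causal_chrom: int = 1  # 1-based chromosome index
    causal_center_bp: int = 50_000_000
    causal_halfwidth_bp: int = 2_000_000
    p_high_core: float = 0.85
    p_low_core: float = 0.15
    background_freq_law: str = "uniform:0.2:0.8"
    mean_depth: float = 30.0
    depth_law: str = "poisson"
    error_rate: float = 0.001
    triallelic_fraction: float = 0.0
    n_animals: int = 103
    bulk_size: int = 3
    population_alt_freq: float = 0.3
    baseline: float = 0.8
    effect_size: float = 4.0
    trait_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_high_core <= 1 and 0 <= self.p_low_core <= 1):
            raise ValueError("core allele frequencies must lie in [0, 1]")
        if self.bulk_size * 2 > self.n_animals:
            raise ValueError("bulk_size * 2 must not exceed n_animals")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        for name in ("n_chromosomes", "chrom_length_bp", "n_snps_per_chrom", "n_animals", "bulk_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must lie in [0, 1)")
        if not 1 <= self.causal_chrom <= self.n_chromosomes:
            raise ValueError("causal_chrom out of range")


@dataclass
class TruthRecord:
    """Ground truth of one simulation run, for parameter-recovery tests."""

    causal_chrom: str
    causal_start: int
    causal_end: int
    causal_marker: str  # "chrom:pos" of the SNP nearest the causal center
    site_keys: list[tuple[str, int]] = field(default_factory=list)
    high_freqs: np.ndarray = field(default_factory=lambda: np.empty(0))
    low_freqs: np.ndarray = field(default_factory=lambda: np.empty(0))
    dosages: dict[str, int] = field(default_factory=dict)

    def in_causal_interval(self, chrom: str, pos: int) -> bool:
        return chrom == self.causal_chrom and self.causal_start <= pos <= self.causal_end


def _background_freqs(law: str, n: int, rng: np.random.Generator) -> np.ndarray:
    kind, *args = law.split(":")
    if kind == "uniform":
        lo, hi = (float(a) for a in args) if args else (0.2, 0.8)
        return rng.uniform(lo, hi, size=n)
    if kind == "constant":
        return np.full(n, float(args[0]))
    raise ValueError(f"unknown background_freq_law {law!r}")


def _depths(law: str, mean: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if law == "poisson":
        return rng.poisson(mean, size=n)
    if law == "constant":
        return np.full(n, int(round(mean)))
    if law.startswith("negbin:"):  # negbin:<dispersion r>
        r = float(law.split(":")[1])
        return rng.negative_binomial(r, r / (r + mean), size=n)
    raise ValueError(f"unknown depth_law {law!r}")


def _pool_counts(
    depth: int,
    alt_freq: float,
    ref_i: int,
    alt_i: int,
    error_rate: float,
    rng: np.random.Generator,
) -> list[int]:
    counts = [0, 0, 0, 0]
    alt_reads = rng.binomial(depth, alt_freq)
    counts[ref_i] = depth - alt_reads
    counts[alt_i] = alt_reads
    if error_rate > 0:
        for i in (ref_i, alt_i):
            errs = rng.binomial(counts[i], error_rate)
            if errs:
                counts[i] -= errs
                others = [b for b in range(4) if b != i]
                spread = rng.multinomial(errs, [1 / 3] * 3)
                for b, e in zip(others, spread):
                    counts[b] += int(e)
    return counts


def simulate_pools(config: SimConfig) -> tuple[list[PooledSiteCounts], TruthRecord]:
    """Simulate the two-pool site table and its ground truth."""
    rng = np.random.default_rng(config.seed)
    sites: list[PooledSiteCounts] = []
    keys: list[tuple[str, int]] = []
    high_freqs: list[float] = []
    low_freqs: list[float] = []
    causal_chrom_name = f"chr{config.causal_chrom}"
    start = max(1, config.causal_center_bp - config.causal_halfwidth_bp)
    end = min(config.chrom_length_bp, config.causal_center_bp + config.causal_halfwidth_bp)

    for c in range(1, config.n_chromosomes + 1):
        chrom = f"chr{c}"
        pos = np.sort(
            rng.choice(
                config.chrom_length_bp, size=config.n_snps_per_chrom, replace=False
            )
            + 1
        )
        bg = _background_freqs(config.background_freq_law, len(pos), rng)
        if chrom == causal_chrom_name:
            w = np.clip(
                1.0 - np.abs(pos - config.causal_center_bp) / config.causal_halfwidth_bp,
                0.0,
                1.0,
            )
        else:
            w = np.zeros(len(pos))
        f_high = bg + w * (config.p_high_core - bg)
        f_low = bg + w * (config.p_low_core - bg)
        d_high = _depths(config.depth_law, config.mean_depth, len(pos), rng)
        d_low = _depths(config.depth_law, config.mean_depth, len(pos), rng)
        base_pairs = rng.integers(0, 4, size=(len(pos), 2))
        base_pairs[:, 1] = (base_pairs[:, 0] + 1 + rng.integers(0, 3, size=len(pos))) % 4
        tri = rng.random(len(pos)) < config.triallelic_fraction

        for i in range(len(pos)):
            ref_i, alt_i = int(base_pairs[i, 0]), int(base_pairs[i, 1])
            hc = _pool_counts(int(d_high[i]), f_high[i], ref_i, alt_i, config.error_rate, rng)
            lc = _pool_counts(int(d_low[i]), f_low[i], ref_i, alt_i, config.error_rate, rng)
            n_alleles = 2
            if tri[i]:
                third = next(b for b in range(4) if b not in (ref_i, alt_i))
                for counts in (hc, lc):
                    moved = max(1, counts[ref_i] // 5)
                    moved = min(moved, counts[ref_i])
                    counts[ref_i] -= moved
                    counts[third] += moved
                n_alleles = 3
            sites.append(
                PooledSiteCounts(
                    chrom=chrom,
                    pos=int(pos[i]),
                    ref=BASES[ref_i],
                    alt=BASES[alt_i],
                    high_counts=tuple(hc),
                    low_counts=tuple(lc),
                    n_alleles=n_alleles,
                )
            )
            keys.append((chrom, int(pos[i])))
            high_freqs.append(float(f_high[i]))
            low_freqs.append(float(f_low[i]))

    causal_positions = [p for ch, p in keys if ch == causal_chrom_name]
    marker_pos = min(causal_positions, key=lambda p: abs(p - config.causal_center_bp))
    dosages = {
        f"G{i:03d}": int(d)
        for i, d in enumerate(
            rng.binomial(2, config.population_alt_freq, size=config.n_animals), start=1
        )
    }
    truth = TruthRecord(
        causal_chrom=causal_chrom_name,
        causal_start=start,
        causal_end=end,
        causal_marker=f"{causal_chrom_name}:{marker_pos}",
        site_keys=keys,
        high_freqs=np.asarray(high_freqs),
        low_freqs=np.asarray(low_freqs),
        dosages=dosages,
    )
    return sites, truth


def simulate_phenotypes(config: SimConfig, truth: TruthRecord) -> list[PhenotypeRecord]:
    """Trait = baseline + effect_size * dosage + Normal(0, sd), truncated at 0."""
    if len(truth.dosages) != config.n_animals:
        raise ValueError(
            f"truth has {len(truth.dosages)} animals, config expects {config.n_animals}"
        )
    rng = np.random.default_rng([config.seed, 1])
    records = []
    for animal_id, dosage in truth.dosages.items():
        milk = config.baseline + config.effect_size * dosage
        blood = 0.6 * config.baseline + 0.5 * config.effect_size * dosage
        if config.trait_noise_sd > 0:
            milk += rng.normal(0, config.trait_noise_sd)
            blood += rng.normal(0, config.trait_noise_sd)
        records.append(
            PhenotypeRecord(animal_id, max(0.0, float(milk)), max(0.0, float(blood)))
        )
    return records


_REGION_CYCLE = ["intronic", "intronic", "ncRNA", "exonic", "intergenic", "UTR3", "intronic", "UTR5"]

SNPS_PER_GENE = 25


def _gene_for(chrom: str, index_on_chrom: int) -> str:
    return f"GENE_{chrom}_{index_on_chrom // SNPS_PER_GENE:04d}"


def write_fixture_bundle(
    sites: list[PooledSiteCounts],
    truth: TruthRecord,
    phenotypes: list[PhenotypeRecord],
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Write VCF + CSV/TSV inputs for a full pipeline run; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    vcf_path = out / "pools.vcf"
    _write_vcf(sites, vcf_path)

    pheno_path = out / "phenotypes.csv"
    with open(pheno_path, "w") as fh:
        fh.write("animal_id,milk_trait,blood_trait\n")
        for rec in phenotypes:
            fh.write(f"{rec.animal_id},{rec.milk_trait:.6g},{rec.blood_trait:.6g}\n")

    marker_chrom, marker_pos = truth.causal_marker.split(":")
    marker_site = next(
        s for s in sites if s.chrom == marker_chrom and s.pos == int(marker_pos)
    )
    geno_path = out / "genotypes.tsv"
    with open(geno_path, "w") as fh:
        fh.write("animal_id\tmarker_id\tgenotype\n")
        for animal_id, dosage in truth.dosages.items():
            alleles = [marker_site.ref] * (2 - dosage) + [marker_site.alt] * dosage
            fh.write(f"{animal_id}\t{truth.causal_marker}\t{''.join(sorted(alleles))}\n")

    ann_path = out / "annotation.tsv"
    causal_gene = None
    with open(ann_path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene_id\tregion_class\tmutation_class\taa_change\n")
        chrom_counter: dict[str, int] = {}
        for s in sites:
            i = chrom_counter.get(s.chrom, 0)
            chrom_counter[s.chrom] = i + 1
            gene = _gene_for(s.chrom, i)
            is_marker = s.chrom == marker_chrom and s.pos == int(marker_pos)
            if is_marker:
                causal_gene = gene
                region, mut, aa = "exonic", "non-synonymous", "E/Q"
            else:
                region, mut, aa = _REGION_CYCLE[i % len(_REGION_CYCLE)], "NA", "."
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t{gene}\t{region}\t{mut}\t{aa}\n")

    gs_path = out / "gene_sets.tsv"
    all_genes = sorted(
        {_gene_for(ch, i) for ch, n in chrom_counter.items() for i in range(0, n, SNPS_PER_GENE)}
    )
    with open(gs_path, "w") as fh:
        fh.write("term_id\tgene_id\n")
        causal_term = [causal_gene] + [g for g in all_genes if g != causal_gene][:4]
        for g in causal_term:
            fh.write(f"TERM_CAUSAL\t{g}\n")
        for t in range(20):
            for g in all_genes[t * 7 % len(all_genes): t * 7 % len(all_genes) + 12]:
                fh.write(f"TERM_{t:03d}\t{g}\n")

    manifest = {
        "seed": seed,
        "causal_marker": truth.causal_marker,
        "causal_interval": [truth.causal_chrom, truth.causal_start, truth.causal_end],
        "causal_gene": causal_gene,
        "files": {
            "vcf": vcf_path.name,
            "phenotypes": pheno_path.name,
            "genotypes": geno_path.name,
            "annotation": ann_path.name,
            "gene_sets": gs_path.name,
        },
        "n_sites": len(sites),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


_GT = {"NA": "./.", "hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1"}


def _write_vcf(sites: list[PooledSiteCounts], path: Path) -> None:
    chrom_max: dict[str, int] = {}
    for s in sites:
        chrom_max[s.chrom] = max(chrom_max.get(s.chrom, 0), s.pos)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bsaed-simulate\n")
        for chrom in sorted(chrom_max):
            fh.write(f"##contig=<ID={chrom},length={chrom_max[chrom] + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tHIGH_BULK\tLOW_BULK\n")
        for s in sorted(sites, key=lambda s: (s.chrom, s.pos)):
            alt_alleles = [s.alt]
            if s.n_alleles == 3:
                combined = [h + l for h, l in zip(s.high_counts, s.low_counts)]
                third = max(
                    (b for b in range(4) if BASES[b] not in (s.ref, s.alt)),
                    key=lambda b: combined[b],
                )
                alt_alleles.append(BASES[third])
            alleles = [s.ref] + alt_alleles
            cols = []
            for counts in (s.high_counts, s.low_counts):
                ad = [counts[BASE_INDEX[a]] for a in alleles]
                ref_n, alt_n = counts[BASE_INDEX[s.ref]], counts[BASE_INDEX[s.alt]]
                gt = _GT[classify_genotype(ref_n, alt_n).call]
                cols.append(f"{gt}:{','.join(map(str, ad))}:{sum(counts)}")
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{','.join(alt_alleles)}\t.\tPASS\t.\t"
                f"GT:AD:DP\t{cols[0]}\t{cols[1]}\n"
            )
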