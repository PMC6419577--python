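"""Variant I/O: genotype matrices, VCF read/write, site filters, SNP effects.

The pipeline starts from a multi-sample VCF of biallelic SNPs (upstream read
mapping and variant calling are not handled here).  Genotypes are coded as
alternate-allele dosage 0/1/2 with -1 for missing.  Site filtering follows
the standard population-genetic defaults for crop resequencing panels:
minor allele frequency > 0.05 and per-site missingness < 0.2.

SNP effect annotation classifies each site against a coding annotation into
intergenic / upstream / downstream / intron / exon, and for coding sites into
synonymous / nonsynonymous / stop_gained / stop_lost by translating the ref
and alt codons under the standard genetic code.  The dN/dS ratio is the raw
count ratio of (nonsynonymous + stop_gained + stop_lost) to synonymous SNPs;
stop-gained/lost sites are additionally reported as "large-effect" SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "GenotypeMatrix",
    "CodingGene",
    "EffectAnnotation",
    "read_genotypes",
    "write_genotypes",
    "filter_sites",
    "annotate_snp_effects",
    "dnds_ratio",
]


@dataclass
class GenotypeMatrix:
    """Samples x biallelic sites matrix of alt-allele dosages.

    ``codes[i, j]`` is 0 (hom ref), 1 (het), 2 (hom alt) or -1 (missing) for
    sample ``samples[i]`` at site ``sites.iloc[j]``.  ``sites`` carries chrom,
    pos (1-based), ref, alt; positions are sorted within each chromosome.
    """

    samples: list[str]
    sites: pd.DataFrame  # columns: chrom, pos, ref, alt
    codes: np.ndarray  # (n_samples, n_sites) int8

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.samples), len(self.sites)):
            raise ValueError("codes shape does not match samples x sites")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, name: str) -> int:
        return self.samples.index(name)

    def row(self, name: str) -> np.ndarray:
        return self.codes[self.sample_index(name)]

    def subset_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(n) for n in names]
        return GenotypeMatrix(list(names), self.sites.copy(), self.codes[idx])

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            list(self.samples), self.sites.loc[mask].copy(), self.codes[:, mask]
        )

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, total called allele count)."""
        called = self.codes != MISSING
        alt = np.where(called, self.codes, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * called.sum(axis=0).astype(np.int64)

    def site_ids(self) -> pd.Series:
        """Site identifiers in the SNP_<chrom>_<pos> convention."""
        return "SNP_" + self.sites["chrom"].astype(str) + "_" + self.sites["pos"].astype(str)


def read_genotypes(path, pass_only: bool = False) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix` via cyvcf2.

    Multiallelic records are skipped (count logged).  ``./.`` becomes the
    missing code.  With ``pass_only`` records failing FILTER are dropped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms, poss, refs, alts = [], [], [], []
    rows = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if pass_only and v.FILTER is not None:
            continue
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        gt = v.gt_types.astype(np.int8)  # gts012: 0,1,2, 3=unknown
        gt[gt == 3] = MISSING
        rows.append(gt)
    if n_multi:
        logger.info("skipped %d multiallelic records", n_multi)
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    codes = (
        np.vstack(rows).T if rows else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, sites, codes)


def write_genotypes(gm: GenotypeMatrix, path, phased_haplotypes=None) -> None:
    """Write a GenotypeMatrix (optionally phased) as a VCF 4.2 text file.

    ``phased_haplotypes`` is an optional (2*n_samples, n_sites) 0/1 array in
    sample order; when given, calls are written phased (``0|1``).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(gm.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        unphased = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in range(gm.n_sites):
            s = gm.sites.iloc[j]
            if phased_haplotypes is not None:
                calls = []
                for i in range(gm.n_samples):
                    if gm.codes[i, j] == MISSING:
                        calls.append(".|.")
                    else:
                        a, b = phased_haplotypes[2 * i, j], phased_haplotypes[2 * i + 1, j]
                        calls.append(f"{a}|{b}")
            else:
                calls = [unphased[int(c)] for c in gm.codes[:, j]]
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def filter_sites(
    gm: GenotypeMatrix, maf_min: float = 0.05, missing_max: float = 0.2
) -> GenotypeMatrix:
    """Keep sites with MAF > ``maf_min`` and missing fraction < ``missing_max``.

    MAF is computed from non-missing allele counts.  Both comparisons are
    strict, matching the convention "MAF greater than 0.05 and missing less
    than 0.2".  Site order is preserved and the filter is idempotent.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be within [0, 0.5]")
    if not 0 <= missing_max <= 1:
        raise ValueError("missing_max must be within [0, 1]")
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    alt, total = gm.allele_counts()
    freq = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
    maf = np.minimum(freq, 1 - freq)
    miss_frac = (gm.codes == MISSING).mean(axis=0)
    # a threshold of 0 (MAF) or 1 (missing) disables that filter entirely
    keep_maf = (maf > maf_min) & (total > 0) if maf_min > 0 else np.ones(gm.n_sites, bool)
    keep_miss = miss_frac < missing_max if missing_max < 1 else np.ones(gm.n_sites, bool)
    keep = keep_maf & keep_miss
    logger.info("filter_sites kept %d / %d sites", int(keep.sum()), gm.n_sites)
    return gm.subset_sites(keep)


# ---------------------------------------------------------------------------
# SNP effect annotation

STOP = "*"


@dataclass
class CodingGene:
    """Minimal coding-gene model: strand-aware CDS over a reference sequence.

    ``cds`` holds 1-based inclusive (start, end) exon-CDS pieces in genomic
    order.  The spliced CDS read 5'->3' (reverse-complemented on the minus
    strand) must represent the reading frame starting at phase 0.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'
    cds: list[tuple[int, int]]

    def cds_positions(self) -> list[int]:
        """Genomic positions of CDS bases in translation (5'->3') order."""
        pos = [p for s, e in sorted(self.cds) for p in range(s, e + 1)]
        return pos[::-1] if self.strand == "-" else pos


@dataclass
class EffectAnnotation:
    """Per-site region class and, for CDS sites, a coding effect."""

    table: pd.DataFrame  # columns: chrom, pos, region, effect, gene_id
    n_skipped: int = 0

    def counts(self) -> pd.Series:
        return self.table["effect"].value_counts()

    def large_effect(self) -> pd.DataFrame:
        return self.table[self.table["effect"].isin(["stop_gained", "stop_lost"])]


def _codon_effect(ref_codon: str, alt_codon: str) -> str:
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa != STOP and alt_aa == STOP:
        return "stop_gained"
    if ref_aa == STOP and alt_aa != STOP:
        return "stop_lost"
    return "synonymous" if ref_aa == alt_aa else "nonsynonymous"


def annotate_snp_effects(
    sites: pd.DataFrame,
    genes: Sequence[CodingGene],
    reference: dict[str, str],
    flank: int = 2000,
) -> EffectAnnotation:
    """Classify SNPs against coding genes and a reference sequence.

    Each site receives exactly one region class: ``exon`` (within a CDS piece;
    coding effect computed from its codon), ``intron`` (inside the gene body
    but not CDS), ``upstream``/``downstream`` (within ``flank`` bp of the gene
    bounds, strand-aware) or ``intergenic``.  When several genes cover a site
    the first by genomic order wins.
    """
    by_chrom: dict[str, list[CodingGene]] = {}
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        by_chrom.setdefault(g.chrom, []).append(g)

    records = []
    for row in sites.itertuples(index=False):
        chrom, pos, ref, alt = row.chrom, int(row.pos), row.ref, row.alt
        region, effect, gene_id = "intergenic", None, None
        # gene bodies take priority over any other gene's flank
        for g in by_chrom.get(chrom, []):
            if g.start <= pos <= g.end:
                gene_id = g.gene_id
                if any(s <= pos <= e for s, e in g.cds):
                    region = "exon"
                    effect = _site_effect(g, pos, ref, alt, reference)
                else:
                    region = "intron"
                break
        if gene_id is None:
            for g in by_chrom.get(chrom, []):
                near_start = g.start - flank <= pos < g.start
                near_end = g.end < pos <= g.end + flank
                if near_start or near_end:
                    gene_id = g.gene_id
                    region = (
                        "upstream" if near_start == (g.strand == "+") else "downstream"
                    )
                    break
        records.append(
            {"chrom": chrom, "pos": pos, "region": region, "effect": effect, "gene_id": gene_id}
        )
    return EffectAnnotation(pd.DataFrame(records))


_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _site_effect(g: CodingGene, pos: int, ref: str, alt: str, reference: dict[str, str]) -> str:
    order = g.cds_positions()
    if len(order) % 3 != 0:
        raise ValueError(f"CDS of {g.gene_id} is not a multiple of 3")
    idx = order.index(pos)
    codon_idx = idx // 3
    codon_pos = order[3 * codon_idx : 3 * codon_idx + 3]
    seq = reference[g.chrom]

    def base(p: int, subst: str | None = None) -> str:
        b = subst if subst is not None else seq[p - 1]
        return b.translate(_COMP) if g.strand == "-" else b

    ref_codon = "".join(base(p) for p in codon_pos)
    alt_codon = "".join(base(p, alt if p == pos else None) for p in codon_pos)
    expected_ref = base(pos, ref)
    if ref_codon[codon_pos.index(pos)] != expected_ref:
        logger.warning("reference mismatch at %s:%d", g.chrom, pos)
    return _codon_effect(ref_codon, alt_codon)


def dnds_ratio(annotation: EffectAnnotation) -> tuple[float, int, int]:
    """Raw-count dN/dS: (nonsyn + stop_gained + stop_lost) / synonymous.

    Returns (ratio, n_nonsynonymous_like, n_synonymous).  Raw counts (not
    per-site normalized) are used because the comparison of interest is the
    ratio of SNP class counts across a panel, which reads as directional
    selection when > 1.
    """
    counts = annotation.counts()
    n_syn = int(counts.get("synonymous", 0))
    n_non = int(
        counts.get("nonsynonymous", 0)
        + counts.get("stop_gained", 0)
        + counts.get("stop_lost", 0)
    )
    if n_syn == 0:
        raise ZeroDivisionError("no synonymous sites: dN/dS undefined")
    return n_non / n_syn, n_non, n_syn
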