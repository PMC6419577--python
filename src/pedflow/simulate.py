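"""Synthetic pedigree genotypes, sweeps, phenotypes and ground truth.

The generator emulates the statistical structure of a resequenced breeding
pedigree contrasted against a wild panel, so that every downstream scan can
be exercised against a known truth:

* a *wild* panel of outbred accessions whose windowed nucleotide diversity is
  calibrated to pi ~ 1.32e-3 (the wild Upland cotton level);
* a *pedigree* group descended from a small set of inbred founder cultivars
  through recorded crosses, with a domestication bottleneck that scales its
  diversity toward pi ~ 0.37e-3;
* planted selective sweeps, zero-diversity segments and a causal
  lint-percentage QTL.

Breeding lines are modeled as inbred: each founder is a doubled haplotype
and each cross is resolved to a fixed line by drawing one recombinant gamete
from the two parental contributions and doubling it (single-seed descent to
homozygosity).  Descent is therefore a positional mosaic: the child's
haplotype over an interval is a verbatim copy of one parent's haplotype over
that interval, which is exactly the structure the SNP-identity-ratio IBD scan
assumes.  Setting ``fix_lines=False`` instead keeps each non-founder as the
heterozygous union of one gamete per recorded parent.

All randomness flows from ``SimConfig.seed`` through per-purpose child
streams (sites, founders, meioses, sweeps, phenotypes, missingness), so
enlarging one stage does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeMap, Interval, PedigreeGraph, ekangmian9_pedigree, validate_pedigree
from .vcfio import MISSING, GenotypeMatrix

__all__ = [
    "HaplotypeMatrix",
    "SimConfig",
    "SimTruth",
    "TransmittedSegment",
    "StudyData",
    "simulate_founder_haplotypes",
    "simulate_gamete",
    "simulate_pedigree_genotypes",
    "plant_sweep_region",
    "simulate_phenotypes",
    "simulate_study",
    "neutral_expected_heterozygosity",
    "calibrated_snp_counts",
    "default_genome",
    "WILD_PI",
    "PEDIGREE_PI",
]

# Calibration targets for windowed nucleotide diversity (per bp): the wild
# Upland cotton panel and the domesticated pedigree group.
WILD_PI = 1.32e-3
PEDIGREE_PI = 0.37e-3

BASES = np.array(list("ACGT"))


def default_genome() -> GenomeMap:
    """Two-chromosome toy genome (one per sub-genome), 2 Mb each."""
    return GenomeMap([("A01", 2_000_000), ("D01", 2_000_000)])


def neutral_expected_heterozygosity(n_haplotypes: int) -> float:
    """Expected per-site pi under the neutral SFS P(i) ~ 1/i on n haplotypes.

    Site frequencies are drawn as i/n with P(i) proportional to 1/i for
    i = 1..n-1 and haplotypes Bernoulli(i/n); the expected sample
    heterozygosity c(n-c)/C(n,2) then works out to (n-1)/(n * a) with
    a = sum_{i<n} 1/i.
    """
    if n_haplotypes < 2:
        raise ValueError("need >= 2 haplotypes")
    a = np.sum(1.0 / np.arange(1, n_haplotypes))
    return (n_haplotypes - 1) / (n_haplotypes * a)


def calibrated_snp_counts(
    genome: GenomeMap, target_pi: float, n_haplotypes: int
) -> dict[str, int]:
    """SNP count per chromosome so the expected windowed pi hits target_pi."""
    density = target_pi / neutral_expected_heterozygosity(n_haplotypes)
    return {name: max(2, round(density * length)) for name, length in genome}


@dataclass
class HaplotypeMatrix:
    """2 x n_samples phased haplotypes over biallelic sites (0/1 codes).

    Haplotypes ``2*i`` and ``2*i + 1`` belong to ``samples[i]``.  Site
    metadata mirrors :class:`~pedflow.vcfio.GenotypeMatrix`.
    """

    samples: list[str]
    sites: pd.DataFrame
    haplotypes: np.ndarray  # (2 * n_samples, n_sites) uint8

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.shape != (2 * len(self.samples), len(self.sites)):
            raise ValueError("haplotype shape does not match 2*samples x sites")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def sample_pair(self, name: str) -> np.ndarray:
        i = self.samples.index(name)
        return self.haplotypes[2 * i : 2 * i + 2]

    def to_genotypes(
        self, missing_rate: float = 0.0, rng: np.random.Generator | None = None
    ) -> GenotypeMatrix:
        codes = (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)
        if missing_rate > 0:
            if rng is None:
                raise ValueError("missing_rate > 0 requires an rng")
            mask = rng.random(codes.shape) < missing_rate
            codes = np.where(mask, np.int8(MISSING), codes)
        return GenotypeMatrix(list(self.samples), self.sites.copy(), codes)

    def subset_samples(self, names: Sequence[str]) -> "HaplotypeMatrix":
        idx = [self.samples.index(n) for n in names]
        rows = np.ravel([(2 * i, 2 * i + 1) for i in idx])
        return HaplotypeMatrix(list(names), self.sites.copy(), self.haplotypes[rows])

    def chrom_slice(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(positions, haplotype columns) for one chromosome."""
        mask = (self.sites["chrom"] == chrom).to_numpy()
        return self.sites.loc[mask, "pos"].to_numpy(), self.haplotypes[:, mask]


@dataclass
class SimConfig:
    """Study conditions for the synthetic pedigree experiment.

    Defaults encode the emulated study: a 31-accession wild panel whose
    expected windowed pi matches the wild cotton level, a recorded breeding
    pedigree of inbred lines, a domestication bottleneck scaling pedigree
    diversity to the published pedigree/wild ratio, 2% missing genotype
    calls, and a recombination rate of 1 cM/Mb.
    """

    genome: GenomeMap = field(default_factory=default_genome)
    snp_count: Optional[dict[str, int]] = None  # None => calibrate to WILD_PI
    founder_count: int = 31  # wild-panel accessions
    freq_law: tuple = ("neutral",)  # or ("fixed", p)
    # The 2 Mb toy chromosomes stand in for ~100 Mb cotton chromosomes; the
    # per-Mb rate is scaled up so each keeps a realistic ~1.5 crossovers per
    # meiosis (map length preserved under physical down-scaling).
    recomb_rate: float = 75.0  # cM/Mb
    pedigree: PedigreeGraph = field(default_factory=ekangmian9_pedigree)
    fix_lines: bool = True  # resolve each cross to a homozygous line
    pedigree_diversity_factor: float = PEDIGREE_PI / WILD_PI
    sweep_specs: list[tuple[Interval, float]] = field(default_factory=list)
    qtl_specs: list[tuple[int, float]] = field(default_factory=list)  # (site idx, effect)
    heritability: float = 0.6
    missing_rate: float = 0.02
    ld_block_bp: Optional[int] = None  # founder haplotypes as ancestral-block mosaics
    n_ancestral: int = 12
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.heritability <= 1:
            raise ValueError("heritability must be in [0, 1]")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be >= 0")
        for _, intensity in self.sweep_specs:
            if not 0 <= intensity <= 1:
                raise ValueError("sweep intensity must be in [0, 1]")
        if self.snp_count is not None and any(c <= 0 for c in self.snp_count.values()):
            raise ValueError("snp_count must be positive")

    def streams(self) -> dict[str, np.random.Generator]:
        names = ["sites", "founders", "meiosis", "sweep", "phenotype", "missing", "wild"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}

    def resolved_snp_count(self, n_haplotypes: int | None = None) -> dict[str, int]:
        if self.snp_count is not None:
            return dict(self.snp_count)
        return calibrated_snp_counts(
            self.genome, WILD_PI, n_haplotypes or 2 * self.founder_count
        )


@dataclass(frozen=True)
class TransmittedSegment:
    """A child-genome interval truly copied from one parent's line haplotype."""

    interval: Interval
    parent: str
    hap_index: int = 0  # which child haplotype carries it (fixed lines: both)


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator; the oracle for every scan."""

    transmitted: dict[str, list[TransmittedSegment]] = field(default_factory=dict)
    crossovers: dict[str, dict[str, list[int]]] = field(default_factory=dict)
    sweeps: list[tuple[Interval, float]] = field(default_factory=list)
    qtl: list[tuple[int, float]] = field(default_factory=list)
    noise_variance: Optional[float] = None
    genome: Optional[GenomeMap] = None
    founders: list[str] = field(default_factory=list)

    def tiling(self, child: str) -> list[TransmittedSegment]:
        return self.transmitted.get(child, [])

    def ancestor_segments(self, child: str, ancestor: str) -> list[Interval]:
        """Intervals of ``child``'s genome that descend from ``ancestor``.

        Descent is positional: a transmitted segment from parent P over
        interval I means the child's haplotype equals P's over I, so the part
        of I that P itself owes to the ancestor is traced recursively.
        """
        from .genome import intersect_interval_sets, merge_intervals

        cache: dict[str, list[Interval]] = {}

        def own(acc: str) -> list[Interval]:
            if acc == ancestor:
                return [Interval(c, 1, l) for c, l in self.genome]
            if acc in cache:
                return cache[acc]
            segs: list[Interval] = []
            for ts in self.transmitted.get(acc, []):
                if ts.parent == ancestor:
                    segs.append(ts.interval)
                else:
                    segs.extend(
                        intersect_interval_sets(own(ts.parent), [ts.interval])
                    )
            cache[acc] = merge_intervals(segs)
            return cache[acc]

        return own(child)

    def transmitted_fraction(self, child: str, ancestor: str) -> float:
        segs = self.ancestor_segments(child, ancestor)
        return sum(len(s) for s in segs) / self.genome.total_bp


# ---------------------------------------------------------------------------
# Founder haplotypes


def _draw_sites(genome: GenomeMap, snp_count: dict[str, int], rng) -> pd.DataFrame:
    frames = []
    for chrom, length in genome:
        n = snp_count[chrom]
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=n, replace=False))
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": BASES[ref_idx],
                    "alt": BASES[alt_idx],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _draw_frequencies(freq_law: tuple, n_haps: int, n_sites: int, rng) -> np.ndarray:
    if freq_law[0] == "fixed":
        return np.full(n_sites, float(freq_law[1]))
    if freq_law[0] == "neutral":
        classes = np.arange(1, n_haps)
        p = (1.0 / classes) / np.sum(1.0 / classes)
        return rng.choice(classes, size=n_sites, p=p) / n_haps
    raise ValueError(f"unknown frequency law {freq_law[0]!r}")


def _draw_haplotypes(
    freqs: np.ndarray,
    n_haps: int,
    rng,
    positions: np.ndarray | None = None,
    ld_block_bp: int | None = None,
    n_ancestral: int = 12,
) -> np.ndarray:
    """Haplotypes i.i.d. per site, or block mosaics of ancestral haplotypes.

    The mosaic option copies contiguous blocks (exponential length,
    mean ``ld_block_bp``) from a small pool of ancestral haplotypes, inducing
    the non-trivial haplotype structure that EHH-type statistics require.
    """
    if ld_block_bp is None:
        return (rng.random((n_haps, len(freqs))) < freqs).astype(np.uint8)
    anc = (rng.random((n_ancestral, len(freqs))) < freqs).astype(np.uint8)
    out = np.empty((n_haps, len(freqs)), dtype=np.uint8)
    for h in range(n_haps):
        j = 0
        while j < len(freqs):
            src = rng.integers(n_ancestral)
            span_bp = rng.exponential(ld_block_bp)
            j_end = int(np.searchsorted(positions, positions[j] + span_bp)) + 1
            out[h, j:j_end] = anc[src, j:j_end]
            j = j_end
    return out


def simulate_founder_haplotypes(
    config: SimConfig, n_accessions: int | None = None, rng=None, sites: pd.DataFrame | None = None
) -> HaplotypeMatrix:
    """Draw an outbred panel of ``n_accessions`` diploid accessions.

    Site alternate-allele frequencies follow the configured law (neutral SFS
    by default); haplotypes are independent per site given the frequency.
    Deterministic under a fixed seed.
    """
    streams = config.streams()
    rng = rng or streams["founders"]
    n_acc = n_accessions or config.founder_count
    n_haps = 2 * n_acc
    if sites is None:
        sites = _draw_sites(config.genome, config.resolved_snp_count(n_haps), streams["sites"])
    freqs = _draw_frequencies(config.freq_law, n_haps, len(sites), rng)
    haps = np.empty((n_haps, len(sites)), dtype=np.uint8)
    for chrom in config.genome.names:
        mask = (sites["chrom"] == chrom).to_numpy()
        haps[:, mask] = _draw_haplotypes(
            freqs[mask],
            n_haps,
            rng,
            positions=sites.loc[mask, "pos"].to_numpy(),
            ld_block_bp=config.ld_block_bp,
            n_ancestral=config.n_ancestral,
        )
    samples = [f"W{i + 1:02d}" for i in range(n_acc)]
    return HaplotypeMatrix(samples, sites, haps)


# ---------------------------------------------------------------------------
# Meiosis


def simulate_gamete(
    hap_pair: np.ndarray,
    sites: pd.DataFrame,
    genome: GenomeMap,
    recomb_rate: float,
    rng,
) -> tuple[np.ndarray, dict[str, list[int]], dict[str, int]]:
    """One gamete from a diploid haplotype pair.

    Crossover counts per chromosome are Poisson(length_Mb * rate_cM_per_Mb /
    100); breakpoint positions are uniform.  A crossover at position b means
    sites at positions >= b switch source haplotype.  Returns the gamete, the
    sorted breakpoints per chromosome and the starting haplotype per
    chromosome (0 or 1), which together fully determine the transmission.
    """
    gamete = np.empty(hap_pair.shape[1], dtype=np.uint8)
    breakpoints: dict[str, list[int]] = {}
    starts: dict[str, int] = {}
    chroms = sites["chrom"].to_numpy()
    positions = sites["pos"].to_numpy()
    for chrom, length in genome:
        mask = chroms == chrom
        if not mask.any():
            breakpoints[chrom] = []
            starts[chrom] = int(rng.integers(2))
            continue
        expected = (length / 1e6) * recomb_rate / 100.0
        n_x = rng.poisson(expected)
        bps = sorted(int(b) for b in rng.integers(2, length + 1, size=n_x))
        start = int(rng.integers(2))
        pos = positions[mask]
        source = (start + np.searchsorted(bps, pos, side="right")) % 2
        cols = np.flatnonzero(mask)
        gamete[cols] = hap_pair[source, cols]
        breakpoints[chrom] = bps
        starts[chrom] = start
    return gamete, breakpoints, starts


def _segments_from_breakpoints(
    chrom: str, length: int, bps: list[int], start: int, labels: tuple[str, str]
) -> list[tuple[Interval, str]]:
    bounds = [1] + list(bps) + [length + 1]
    out = []
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1] - 1
        if lo <= hi:
            out.append((Interval(chrom, lo, hi), labels[(start + k) % 2]))
    return out


# ---------------------------------------------------------------------------
# Pedigree transmission


def simulate_pedigree_genotypes(
    config: SimConfig,
    sites: pd.DataFrame | None = None,
    founder_haps: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, HaplotypeMatrix, SimTruth]:
    """Simulate genotypes for every pedigree node plus the transmission truth.

    Founders are drawn fresh as inbred lines (one haplotype each, doubled);
    every non-founder is formed from one gamete per recorded parent (selfing
    when only one parent is recorded) and, under ``fix_lines``, resolved to a
    homozygous line by one further meiosis on that union.  The truth records,
    per child, the exact parental origin of every genome interval.
    """
    order = validate_pedigree(config.pedigree)
    for node in order:
        parents = config.pedigree.parents(node)
        if not parents and config.pedigree.role(node) != "exotic_founder":
            raise ValueError(
                f"{node!r} has no recorded parents but role "
                f"{config.pedigree.role(node)!r} (expected exotic_founder)"
            )

    streams = config.streams()
    founders = config.pedigree.founders
    n_founder_haps = max(2, len(founders))
    if sites is None:
        sites = _draw_sites(
            config.genome, config.resolved_snp_count(), streams["sites"]
        )
    if founder_haps is None:
        freqs = _draw_frequencies(
            config.freq_law, n_founder_haps, len(sites), streams["founders"]
        )
        founder_haps = _draw_haplotypes(freqs, n_founder_haps, streams["founders"])

    rng_m = streams["meiosis"]
    line_haps: dict[str, np.ndarray] = {}
    pair_haps: dict[str, np.ndarray] = {}
    truth = SimTruth(genome=config.genome, founders=list(founders))

    founder_idx = 0
    for node in order:
        parents = config.pedigree.parents(node)
        if not parents:
            h = founder_haps[founder_idx % n_founder_haps]
            founder_idx += 1
            pair_haps[node] = np.vstack([h, h])
            line_haps[node] = h
            continue
        if len(parents) == 1:
            parents = [parents[0], parents[0]]
        gametes, labels = [], []
        xovers: dict[str, list[int]] = {c: [] for c in config.genome.names}
        for p in parents:
            g, bps, _ = simulate_gamete(
                pair_haps[p], sites, config.genome, config.recomb_rate, rng_m
            )
            gametes.append(g)
            labels.append(p)
            for c, b in bps.items():
                xovers[c].extend(b)
        union = np.vstack(gametes)
        if config.fix_lines:
            # single-seed descent: one recombinant of the two parental gametes,
            # doubled to a homozygous line
            line, bps, starts = simulate_gamete(
                union, sites, config.genome, config.recomb_rate, rng_m
            )
            pair_haps[node] = np.vstack([line, line])
            line_haps[node] = line
            segs = []
            for chrom, length in config.genome:
                for iv, parent in _segments_from_breakpoints(
                    chrom, length, bps[chrom], starts[chrom], (labels[0], labels[1])
                ):
                    segs.append(TransmittedSegment(iv, parent))
                xovers[chrom].extend(bps[chrom])
            truth.transmitted[node] = segs
        else:
            pair_haps[node] = union
            segs = []
            for hap_idx, p in enumerate(parents):
                for chrom, length in config.genome:
                    segs.append(
                        TransmittedSegment(Interval(chrom, 1, length), p, hap_idx)
                    )
            truth.transmitted[node] = segs
        truth.crossovers[node] = {c: sorted(b) for c, b in xovers.items()}

    samples = list(order)
    hap_rows = np.vstack([pair_haps[s] for s in samples])
    haps = HaplotypeMatrix(samples, sites, hap_rows)
    gm = haps.to_genotypes(config.missing_rate, streams["missing"])
    return gm, haps, truth


# ---------------------------------------------------------------------------
# Sweeps, phenotypes


def plant_sweep_region(
    haps: HaplotypeMatrix,
    region: Interval,
    intensity: float,
    rng,
    swept_hap: int = 0,
) -> HaplotypeMatrix:
    """Plant a selective sweep: haplotypes converge on one pattern in a region.

    Inside ``region`` each haplotype is replaced by the designated swept
    haplotype's alleles with probability ``intensity``; the matrix is
    unchanged outside the region.
    """
    if not 0 <= intensity <= 1:
        raise ValueError("intensity must be in [0, 1]")
    mask = (
        (haps.sites["chrom"] == region.chrom)
        & (haps.sites["pos"] >= region.start)
        & (haps.sites["pos"] <= region.end)
    ).to_numpy()
    if intensity == 0 or not mask.any():
        return HaplotypeMatrix(list(haps.samples), haps.sites.copy(), haps.haplotypes.copy())
    new = haps.haplotypes.copy()
    pattern = haps.haplotypes[swept_hap, mask]
    replaced = rng.random(haps.n_haplotypes) < intensity
    new[np.ix_(replaced, mask)] = pattern
    return HaplotypeMatrix(list(haps.samples), haps.sites.copy(), new)


def simulate_phenotypes(
    gm: GenotypeMatrix,
    qtl_specs: Sequence[tuple[int, float]],
    h2: float,
    rng,
    environments: Sequence[str] = ("E1",),
    trait: str = "lint_percentage",
    baseline: float = 0.0,
) -> pd.DataFrame:
    """Phenotypes from additive QTL effects at a requested heritability.

    The genetic value of accession *i* is sum_q effect_q * dosage_iq (missing
    dosages count as the site mean).  Noise variance is set from the realized
    genetic variance so that Var(g) / (Var(g) + Var(e)) = h2; environment
    replicates share the genetic value and draw independent noise.  Returns a
    long table (accession, trait, environment, value).
    """
    if not 0 <= h2 <= 1:
        raise ValueError("h2 must be in [0, 1]")
    n = gm.n_samples
    g = np.zeros(n)
    for site_idx, effect in qtl_specs:
        dose = gm.codes[:, site_idx].astype(float)
        dose[dose == MISSING] = np.nan
        dose = np.where(np.isnan(dose), np.nanmean(dose), dose)
        g += effect * dose
    var_g = float(np.var(g))
    if h2 == 1.0:
        if var_g == 0:
            raise ValueError("h2 = 1 requires non-zero genetic variance")
        noise_sd = 0.0
    elif h2 == 0.0:
        g = np.zeros(n)
        noise_sd = 1.0
    else:
        noise_sd = np.sqrt(var_g * (1 - h2) / h2) if var_g > 0 else 1.0
    rows = []
    for env in environments:
        noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
        for i, acc in enumerate(gm.samples):
            rows.append(
                {
                    "accession": acc,
                    "trait": trait,
                    "environment": env,
                    "value": baseline + g[i] + noise[i],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full study


@dataclass
class StudyData:
    """Everything the end-to-end pipeline consumes, on one shared site set."""

    config: SimConfig
    wild_haps: HaplotypeMatrix
    pedigree_haps: HaplotypeMatrix
    pedigree_gm: GenotypeMatrix
    truth: SimTruth

    @property
    def sites(self) -> pd.DataFrame:
        return self.wild_haps.sites


def simulate_study(config: SimConfig) -> StudyData:
    """Simulate the wild panel and pedigree group on one shared site set.

    The wild panel is an outbred sample at the calibrated diversity level.
    Pedigree founder lines are drawn at the same site frequencies but with a
    domestication bottleneck: a fraction ``1 - pedigree_diversity_factor`` of
    sites is fixed within the pedigree founder pool, scaling pedigree
    diversity toward the published pedigree/wild ratio.  Sweeps from
    ``sweep_specs`` are planted into the pedigree haplotypes afterwards.
    """
    streams = config.streams()
    n_wild_haps = 2 * config.founder_count
    sites = _draw_sites(config.genome, config.resolved_snp_count(n_wild_haps), streams["sites"])
    wild_freqs = _draw_frequencies(config.freq_law, n_wild_haps, len(sites), streams["wild"])
    wild_rows = _draw_haplotypes(wild_freqs, n_wild_haps, streams["wild"])
    wild = HaplotypeMatrix(
        [f"W{i + 1:02d}" for i in range(config.founder_count)], sites, wild_rows
    )

    founders = config.pedigree.founders
    n_f = max(2, len(founders))
    rng_f = streams["founders"]
    founder_rows = (rng_f.random((n_f, len(sites))) < wild_freqs).astype(np.uint8)
    fixed = rng_f.random(len(sites)) >= config.pedigree_diversity_factor
    fixed_allele = (rng_f.random(len(sites)) < wild_freqs).astype(np.uint8)
    founder_rows[:, fixed] = fixed_allele[fixed]

    gm, haps, truth = simulate_pedigree_genotypes(
        config, sites=sites, founder_haps=founder_rows
    )
    for region, intensity in config.sweep_specs:
        haps = plant_sweep_region(haps, region, intensity, streams["sweep"])
        truth.sweeps.append((region, intensity))
    if config.sweep_specs:
        gm = haps.to_genotypes(config.missing_rate, streams["missing"])
    truth.qtl = list(config.qtl_specs)
    return StudyData(config, wild, haps, gm, truth)
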