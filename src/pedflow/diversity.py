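"""Windowed diversity statistics, LD decay, genetic distances and NJ trees.

Window convention: windows are anchored at position 1 and advance by ``step``
bp; a window's value is attributed to its full interval, and a partial
terminal window is normalized by the base pairs it actually covers.

Per-site nucleotide diversity is the unbiased pairwise heterozygosity
pi_s = c_ref * c_alt / C(n, 2) over the n non-missing allele calls at the
site; a window's pi is the sum of per-site values divided by the window
length in bp.  Fst uses the Weir–Cockerham variance components with the
ratio-of-sums window estimator.  LD is r^2 from haplotype frequencies when
phased input is available, with a genotype-correlation fallback otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genome import GenomeMap, Interval, merge_intervals
from .simulate import HaplotypeMatrix
from .vcfio import MISSING, GenotypeMatrix

__all__ = [
    "WindowStat",
    "DistanceMatrix",
    "iter_windows",
    "snp_density_scan",
    "zero_diversity_segments",
    "pi_scan",
    "mean_pi",
    "fst_scan",
    "ld_decay",
    "genetic_distance_matrix",
    "neighbor_joining",
    "windows_to_frame",
]

Matrix = Union[GenotypeMatrix, HaplotypeMatrix]


@dataclass(frozen=True)
class WindowStat:
    """A windowed statistic over a genome interval."""

    interval: Interval
    n_snps: int
    value: float

    def __post_init__(self):
        if self.n_snps < 0:
            raise ValueError("n_snps must be >= 0")


def windows_to_frame(stats: Sequence[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.interval.chrom for w in stats],
            "start": [w.interval.start for w in stats],
            "end": [w.interval.end for w in stats],
            "n_snps": [w.n_snps for w in stats],
            "value": [w.value for w in stats],
        }
    )


def iter_windows(genome: GenomeMap, window: int, step: int) -> list[Interval]:
    """Sliding windows anchored at 1; terminal windows clipped to the chrom."""
    if not window >= step > 0:
        raise ValueError("need window >= step > 0")
    out = []
    for chrom, length in genome:
        start = 1
        while start <= length:
            out.append(Interval(chrom, start, min(start + window - 1, length)))
            start += step
    return out


def _allele_arrays(m: Matrix) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """(alt allele count, called allele count) per site for either container."""
    if isinstance(m, HaplotypeMatrix):
        alt = m.haplotypes.sum(axis=0).astype(np.int64)
        total = np.full(m.n_sites, m.n_haplotypes, dtype=np.int64)
        return alt, total, m.sites
    alt, total = m.allele_counts()
    return alt, total, m.sites


def _per_site_pi(alt: np.ndarray, total: np.ndarray) -> np.ndarray:
    n = total.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = alt * (n - alt) / (n * (n - 1) / 2.0)
    pi[n < 2] = 0.0
    return pi


def _window_sums(
    genome: GenomeMap,
    sites: pd.DataFrame,
    values: np.ndarray,
    window: int,
    step: int,
    counts: np.ndarray | None = None,
) -> list[tuple[Interval, int, float]]:
    """Sum ``values`` (and count sites) in each sliding window via cumsums."""
    out = []
    chroms = sites["chrom"].to_numpy()
    pos_all = sites["pos"].to_numpy()
    counts = counts if counts is not None else np.ones(len(sites))
    for iv in iter_windows(genome, window, step):
        mask_idx = np.flatnonzero(chroms == iv.chrom)
        pos = pos_all[mask_idx]
        lo = np.searchsorted(pos, iv.start, side="left")
        hi = np.searchsorted(pos, iv.end, side="right")
        idx = mask_idx[lo:hi]
        out.append((iv, int(counts[idx].sum()), float(values[idx].sum())))
    return out


def snp_density_scan(
    gm: Matrix, genome: GenomeMap, window: int = 100_000, step: int | None = None
) -> list[WindowStat]:
    """Polymorphic-site count per bp in sliding (default non-overlapping) windows."""
    step = step or window
    alt, total, sites = _allele_arrays(gm)
    poly = ((alt > 0) & (alt < total)).astype(float)
    return [
        WindowStat(iv, n, n / len(iv))
        for iv, n, _ in _window_sums(genome, sites, poly, window, step, counts=poly)
    ]


def zero_diversity_segments(
    density: Sequence[WindowStat], min_len: int = 100_000
) -> list[Interval]:
    """Maximal runs of consecutive zero-SNP bins, merged, each >= min_len.

    Input must be non-overlapping bins (the non-overlapping density scan);
    overlapping bins make the merge ambiguous and raise an error.
    """
    by_chrom: dict[str, list[WindowStat]] = {}
    for w in density:
        by_chrom.setdefault(w.interval.chrom, []).append(w)
    zero_bins = []
    for chrom, bins in by_chrom.items():
        bins = sorted(bins, key=lambda w: w.interval.start)
        for a, b in itertools.pairwise(bins):
            if a.interval.end >= b.interval.start:
                raise ValueError("zero_diversity_segments requires non-overlapping bins")
        zero_bins.extend(w.interval for w in bins if w.n_snps == 0)
    merged = merge_intervals(zero_bins, max_gap=0)
    return [iv for iv in merged if len(iv) >= min_len]


def pi_scan(
    m: Matrix, genome: GenomeMap, window: int = 100_000, step: int = 20_000
) -> list[WindowStat]:
    """Sliding-window nucleotide diversity (pi per bp).

    Defaults follow the standard resequencing practice of 100 kb windows
    sliding by 20 kb.
    """
    alt, total, sites = _allele_arrays(m)
    pi = _per_site_pi(alt, total)
    return [
        WindowStat(iv, n, s / len(iv))
        for iv, n, s in _window_sums(genome, sites, pi, window, step)
    ]


def mean_pi(stats: Sequence[WindowStat]) -> float:
    """Mean windowed pi across a scan (the group-level diversity summary)."""
    return float(np.mean([w.value for w in stats])) if stats else float("nan")


# ---------------------------------------------------------------------------
# Fst (Weir & Cockerham 1984, two populations, ratio-of-sums windows)


def _wc_components(gm: GenotypeMatrix, idx_a, idx_b) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Weir–Cockerham a and (a + b + c) for two diploid samples."""
    r = 2
    comps = []
    for idx in (idx_a, idx_b):
        codes = gm.codes[idx]
        called = codes != MISSING
        n_i = called.sum(axis=0)  # diploid individuals genotyped
        alt = np.where(called, codes, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_i = alt / (2.0 * n_i)
            h_i = np.where(called, codes == 1, False).sum(axis=0) / n_i
        comps.append((n_i.astype(float), p_i, h_i))
    n1, p1, h1 = comps[0]
    n2, p2, h2 = comps[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1))
            * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - ((r - 1) / r) * s2
            - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        c = h_bar / 2.0
    denom = a + b + c
    bad = (
        ~np.isfinite(a)
        | ~np.isfinite(denom)
        | (n1 < 1)
        | (n2 < 1)
        | (n_bar <= 1)
    )
    a = np.where(bad, np.nan, a)
    denom = np.where(bad, np.nan, denom)
    return a, denom


def fst_scan(
    gm: GenotypeMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    genome: GenomeMap,
    window: int = 100_000,
    step: int = 20_000,
) -> list[WindowStat]:
    """Windowed Weir–Cockerham Fst between two sample groups.

    The window estimate is the ratio of sums sum(a) / sum(a + b + c) over
    sites with defined components; a window with no usable site gets NaN.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need >= 2 samples")
    idx_a = [gm.sample_index(s) for s in group_a]
    idx_b = [gm.sample_index(s) for s in group_b]
    a, denom = _wc_components(gm, idx_a, idx_b)
    usable = np.isfinite(a) & np.isfinite(denom) & (denom != 0)
    a_v = np.where(usable, a, 0.0)
    d_v = np.where(usable, denom, 0.0)
    out = []
    num_sums = _window_sums(genome, gm.sites, a_v, window, step, counts=usable.astype(float))
    den_sums = _window_sums(genome, gm.sites, d_v, window, step)
    for (iv, n, num), (_, _, den) in zip(num_sums, den_sums):
        value = num / den if den != 0 and n > 0 else float("nan")
        out.append(WindowStat(iv, n, value))
    return out


# ---------------------------------------------------------------------------
# LD decay


def ld_decay(
    m: Matrix,
    max_dist: int = 1_000_000,
    bin_width: int = 10_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """r^2 for all intra-chromosomal site pairs within ``max_dist``.

    Phased input uses the haplotype-frequency definition
    r^2 = D^2 / (pA pa pB pb); unphased genotypes fall back to the squared
    Pearson correlation of dosages.  Returns (decay curve, pairwise table);
    the curve is mean r^2 per distance bin (bin midpoint reported).
    Monomorphic sites are skipped.
    """
    phased = isinstance(m, HaplotypeMatrix)
    sites = m.sites
    data = m.haplotypes if phased else m.codes
    rows = []
    for chrom in pd.unique(sites["chrom"]):
        mask = (sites["chrom"] == chrom).to_numpy()
        pos = sites.loc[mask, "pos"].to_numpy()
        X = data[:, mask].astype(float)
        if not phased:
            X[X == MISSING] = np.nan
        keep = np.nanstd(X, axis=0) > 0
        pos, X = pos[keep], X[:, keep]
        for i in range(len(pos)):
            j_hi = np.searchsorted(pos, pos[i] + max_dist, side="right")
            for j in range(i + 1, j_hi):
                r2 = _pair_r2(X[:, i], X[:, j], phased)
                if np.isfinite(r2):
                    rows.append((chrom, pos[i], pos[j], pos[j] - pos[i], r2))
    pairs = pd.DataFrame(rows, columns=["chrom", "pos1", "pos2", "dist", "r2"])
    if len(pairs):
        bins = (pairs["dist"] // bin_width).astype(int)
        curve = (
            pairs.assign(bin=bins)
            .groupby("bin")
            .agg(mean_r2=("r2", "mean"), n_pairs=("r2", "size"))
            .reset_index()
        )
        curve["dist_mid"] = curve.pop("bin") * bin_width + bin_width // 2
        curve = curve[["dist_mid", "mean_r2", "n_pairs"]]
    else:
        curve = pd.DataFrame(columns=["dist_mid", "mean_r2", "n_pairs"])
    return curve, pairs


def _pair_r2(x: np.ndarray, y: np.ndarray, phased: bool) -> float:
    if phased:
        pA, pB = x.mean(), y.mean()
        if pA in (0.0, 1.0) or pB in (0.0, 1.0):
            return float("nan")
        d = (x * y).mean() - pA * pB
        return d * d / (pA * (1 - pA) * pB * (1 - pB))
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return float("nan")
    r = np.corrcoef(x[ok], y[ok])[0, 1]
    return r * r


# ---------------------------------------------------------------------------
# Genetic distance and neighbour joining


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal; NaN = undefined pair

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")

    def dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def genetic_distance_matrix(
    gm: GenotypeMatrix, samples: Sequence[str] | None = None
) -> DistanceMatrix:
    """Allele-sharing distance d(i,j) = 1 - shared allele fraction.

    The shared fraction at a site is 1 - |dosage_i - dosage_j| / 2, averaged
    over sites non-missing in both samples.  Pairs with no jointly called
    site get NaN (flagged undefined).
    """
    names = list(samples) if samples is not None else list(gm.samples)
    if len(names) < 2:
        raise ValueError("need >= 2 samples")
    codes = gm.codes[[gm.sample_index(s) for s in names]].astype(float)
    codes[codes == MISSING] = np.nan
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(codes[i]) & ~np.isnan(codes[j])
            if not ok.any():
                d[i, j] = d[j, i] = np.nan
                continue
            shared = 1.0 - np.abs(codes[i, ok] - codes[j, ok]) / 2.0
            d[i, j] = d[j, i] = 1.0 - shared.mean()
    return DistanceMatrix(names, d)


def neighbor_joining(dm: DistanceMatrix) -> str:
    """Saitou–Nei neighbour joining; returns an unrooted newick string.

    Ties in the Q criterion are broken by the lowest index pair.  Negative
    branch lengths are clamped to zero with the deficit moved to the sibling
    branch, a standard post-hoc adjustment that preserves the pairwise path
    length between the joined taxa.
    """
    if len(dm.ids) < 3:
        raise ValueError("neighbour joining needs >= 3 taxa")
    if not np.all(np.isfinite(dm.values)):
        raise ValueError("all pairwise distances must be defined")
    labels = [str(x) for x in dm.ids]
    D = dm.values.astype(float).copy()
    nodes = list(range(len(labels)))  # active indices into D
    newick = {i: _escape(labels[i]) for i in nodes}

    while len(nodes) > 3:
        n = len(nodes)
        sub = D[np.ix_(nodes, nodes)]
        totals = sub.sum(axis=1)
        q = (n - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        fi, fj = np.unravel_index(np.argmin(q), q.shape)  # argmin -> lowest index pair
        if fi > fj:
            fi, fj = fj, fi
        i, j = nodes[fi], nodes[fj]
        dij = D[i, j]
        li = 0.5 * dij + (totals[fi] - totals[fj]) / (2 * (n - 2))
        lj = dij - li
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = li + lj, 0.0
        # new node u
        u = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for fk, k in enumerate(nodes):
            if k in (i, j):
                continue
            D[u, k] = D[k, u] = 0.5 * (D[i, k] + D[j, k] - dij)
        newick[u] = f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g})"
        nodes = [k for k in nodes if k not in (i, j)] + [u]

    i, j, k = nodes
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    branches = [li, lj, lk]
    for a in range(3):
        if branches[a] < 0:
            for b in range(3):
                if b != a:
                    branches[b] += branches[a] / 2
            branches[a] = 0.0
    li, lj, lk = branches
    return f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g},{newick[k]}:{lk:.10g});"


def _escape(label: str) -> str:
    if any(c in label for c in "():;, '"):
        return "'" + label.replace("'", "''") + "'"
    return label
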