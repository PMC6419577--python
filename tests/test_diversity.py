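"""Oracles for pi, Fst, LD, distances, density and neighbour joining."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pedflow.genome import GenomeMap, Interval
from pedflow.diversity import (
    DistanceMatrix,
    WindowStat,
    fst_scan,
    genetic_distance_matrix,
    iter_windows,
    ld_decay,
    neighbor_joining,
    pi_scan,
    snp_density_scan,
    zero_diversity_segments,
)
from pedflow.simulate import HaplotypeMatrix, SimConfig, simulate_founder_haplotypes
from pedflow.vcfio import MISSING, GenotypeMatrix


def hap_matrix(haps: np.ndarray, positions, chrom="A01"):
    n_samp = haps.shape[0] // 2
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * len(positions),
            "pos": positions,
            "ref": ["A"] * len(positions),
            "alt": ["G"] * len(positions),
        }
    )
    return HaplotypeMatrix([f"s{i}" for i in range(n_samp)], sites, haps)


def brute_force_pi(haps: np.ndarray, window_bp: int) -> float:
    """Mean pairwise difference count over all haplotype pairs, per bp."""
    total = 0
    pairs = 0
    for a, b in itertools.combinations(range(haps.shape[0]), 2):
        total += int(np.sum(haps[a] != haps[b]))
        pairs += 1
    return total / pairs / window_bp


class TestPiScan:
    def test_monomorphic_window_zero(self):
        haps = np.zeros((4, 10), dtype=np.uint8)
        m = hap_matrix(haps, np.arange(1, 11))
        out = pi_scan(m, GenomeMap([("A01", 1000)]), window=1000, step=1000)
        assert out[0].value == 0.0

    def test_two_haplotypes_one_difference(self):
        haps = np.array([[0], [1]], dtype=np.uint8)
        m = hap_matrix(haps, [500])
        out = pi_scan(m, GenomeMap([("A01", 100_000)]), window=100_000, step=100_000)
        assert out[0].value == pytest.approx(1e-5, abs=0)

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(20):
            haps = (rng.random((10, 50)) < rng.random(50)).astype(np.uint8)
            pos = np.sort(rng.choice(np.arange(1, 100_000), size=50, replace=False))
            m = hap_matrix(haps, pos)
            out = pi_scan(m, GenomeMap([("A01", 100_000)]), window=100_000, step=100_000)
            assert out[0].value == pytest.approx(brute_force_pi(haps, 100_000), abs=1e-12)

    def test_sample_order_invariant(self, rng):
        haps = (rng.random((8, 30)) < 0.4).astype(np.uint8)
        pos = np.arange(1, 31)
        m1 = hap_matrix(haps, pos)
        perm = rng.permutation(8)
        m2 = hap_matrix(haps[perm], pos)
        g = GenomeMap([("A01", 1000)])
        assert pi_scan(m1, g, 1000, 1000)[0].value == pi_scan(m2, g, 1000, 1000)[0].value

    def test_partial_terminal_window_normalized_by_true_bp(self):
        haps = np.array([[0, 1], [1, 0]], dtype=np.uint8)
        m = hap_matrix(haps, [100, 1400])
        out = pi_scan(m, GenomeMap([("A01", 1500)]), window=1000, step=1000)
        assert len(out) == 2
        assert out[1].interval == Interval("A01", 1001, 1500)
        assert out[1].value == pytest.approx(1.0 / 500)


class TestDensityAndZeroDiversity:
    def test_simple_counts(self, rng):
        cfg = SimConfig(
            seed=3, genome=GenomeMap([("A01", 500_000)]), snp_count={"A01": 800},
            founder_count=10,
        )
        haps = simulate_founder_haplotypes(cfg)
        out = snp_density_scan(haps, cfg.genome, window=100_000)
        # brute-force per-window polymorphic count
        pos = haps.sites["pos"].to_numpy()
        poly = (haps.haplotypes.sum(axis=0) > 0) & (
            haps.haplotypes.sum(axis=0) < haps.n_haplotypes
        )
        for w in out:
            n = int(np.sum(poly & (pos >= w.interval.start) & (pos <= w.interval.end)))
            assert w.n_snps == n
            assert w.value == pytest.approx(n / len(w.interval))

    def test_zero_diversity_runs(self):
        g = GenomeMap([("A01", 1_000_000)])
        bins = [
            WindowStat(iv, 0 if 300_001 <= iv.start <= 500_001 else 5, 0.0)
            for iv in iter_windows(g, 100_000, 100_000)
        ]
        segs = zero_diversity_segments(bins, min_len=100_000)
        assert segs == [Interval("A01", 300_001, 600_000)]

    def test_monomorphic_chromosome_single_segment(self):
        g = GenomeMap([("A01", 1_000_000)])
        bins = [WindowStat(iv, 0, 0.0) for iv in iter_windows(g, 100_000, 100_000)]
        assert zero_diversity_segments(bins) == [Interval("A01", 1, 1_000_000)]

    def test_no_zero_bins_empty(self):
        g = GenomeMap([("A01", 300_000)])
        bins = [WindowStat(iv, 1, 0.0) for iv in iter_windows(g, 100_000, 100_000)]
        assert zero_diversity_segments(bins) == []

    def test_overlapping_bins_rejected(self):
        g = GenomeMap([("A01", 300_000)])
        bins = [WindowStat(iv, 0, 0.0) for iv in iter_windows(g, 100_000, 50_000)]
        with pytest.raises(ValueError):
            zero_diversity_segments(bins)


def genotype_matrix(codes, positions=None, chrom="A01"):
    codes = np.asarray(codes, dtype=np.int8)
    n, s = codes.shape
    positions = positions if positions is not None else np.arange(1, s + 1)
    sites = pd.DataFrame(
        {"chrom": [chrom] * s, "pos": positions, "ref": ["A"] * s, "alt": ["G"] * s}
    )
    return GenotypeMatrix([f"s{i}" for i in range(n)], sites, codes)


class TestFst:
    def test_fixed_difference_is_one(self):
        codes = np.array([[2, 2], [2, 2], [0, 0], [0, 0]], dtype=np.int8)
        gm = genotype_matrix(codes)
        out = fst_scan(gm, ["s0", "s1"], ["s2", "s3"], GenomeMap([("A01", 100)]), 100, 100)
        assert out[0].value == pytest.approx(1.0)

    def test_panmictic_halves_near_zero(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            p = rng.uniform(0.1, 0.9, size=300)
            codes = rng.binomial(2, p, size=(40, 300)).astype(np.int8)
            gm = genotype_matrix(codes)
            out = fst_scan(
                gm, [f"s{i}" for i in range(20)], [f"s{i}" for i in range(20, 40)],
                GenomeMap([("A01", 300)]), 300, 300,
            )
            vals.append(out[0].value)
        assert abs(np.mean(vals)) < 0.02

    def test_matches_hand_computed_components(self):
        """Small case checked against the Weir-Cockerham per-site algebra
        written out independently (no shared code path)."""
        codes = np.array(
            [[0, 1], [1, 2], [2, 2], [0, 0], [0, 1], [1, 0]], dtype=np.int8
        )
        gm = genotype_matrix(codes)
        ga = ["s0", "s1", "s2"]
        gb = ["s3", "s4", "s5"]
        out = fst_scan(gm, ga, gb, GenomeMap([("A01", 10)]), 10, 10)

        def site_components(col):
            a_codes, b_codes = codes[:3, col], codes[3:, col]
            n1 = n2 = 3.0
            r = 2
            p1, p2 = a_codes.sum() / 6, b_codes.sum() / 6
            h1 = np.mean(a_codes == 1)
            h2 = np.mean(b_codes == 1)
            n_bar = 3.0
            n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
            p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
            s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
            h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
            a = (n_bar / n_c) * (
                s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
            )
            b = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
            )
            c = h_bar / 2
            return a, a + b + c

        num = den = 0.0
        for col in range(2):
            a, t = site_components(col)
            num += a
            den += t
        assert out[0].value == pytest.approx(num / den, abs=1e-12)

    def test_group_size_guard(self):
        gm = genotype_matrix(np.zeros((3, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            fst_scan(gm, ["s0"], ["s1", "s2"], GenomeMap([("A01", 10)]), 10, 10)


class TestLdDecay:
    def test_identical_sites_r2_one(self):
        haps = np.array([[0, 0], [1, 1], [0, 0], [1, 1]], dtype=np.uint8)
        m = hap_matrix(haps, [10, 20])
        curve, pairs = ld_decay(m)
        assert pairs["r2"].iloc[0] == pytest.approx(1.0)

    def test_equilibrium_four_gametes_r2_zero(self):
        haps = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.uint8)
        m = hap_matrix(haps, [10, 20])
        _, pairs = ld_decay(m)
        assert pairs["r2"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_correlation_oracle(self, rng):
        haps = (rng.random((20, 40)) < rng.uniform(0.2, 0.8, 40)).astype(np.uint8)
        pos = np.sort(rng.choice(np.arange(1, 10_000), 40, replace=False))
        m = hap_matrix(haps, pos)
        _, pairs = ld_decay(m)
        checked = 0
        pos_to_col = {p: i for i, p in enumerate(pos)}
        for row in pairs.itertuples(index=False):
            x = haps[:, pos_to_col[row.pos1]].astype(float)
            y = haps[:, pos_to_col[row.pos2]].astype(float)
            r = np.corrcoef(x, y)[0, 1]
            assert row.r2 == pytest.approx(r * r, abs=1e-10)
            checked += 1
        assert checked >= 100


class TestDistance:
    def test_identical_samples_zero(self):
        codes = np.array([[0, 1, 2], [0, 1, 2]], dtype=np.int8)
        dm = genetic_distance_matrix(genotype_matrix(codes))
        assert dm.values[0, 1] == 0.0

    def test_opposite_homozygotes_one(self):
        codes = np.array([[0, 0], [2, 2]], dtype=np.int8)
        dm = genetic_distance_matrix(genotype_matrix(codes))
        assert dm.values[0, 1] == 1.0

    def test_matches_counting_oracle(self, rng):
        codes = rng.integers(0, 3, size=(6, 50)).astype(np.int8)
        codes[rng.random(codes.shape) < 0.1] = MISSING
        gm = genotype_matrix(codes)
        dm = genetic_distance_matrix(gm)
        for i, j in itertools.combinations(range(6), 2):
            num = cnt = 0
            for s in range(50):
                if codes[i, s] == MISSING or codes[j, s] == MISSING:
                    continue
                cnt += 1
                num += 1 - abs(int(codes[i, s]) - int(codes[j, s])) / 2
            assert dm.values[i, j] == pytest.approx(1 - num / cnt, abs=1e-12)
            assert dm.values[i, j] == dm.values[j, i]


def parse_newick_topology(nwk: str):
    """Leaf bipartitions of an unrooted newick tree via scikit-bio."""
    import io
    from skbio import TreeNode

    tree = TreeNode.read(io.StringIO(nwk))
    tips = {t.name for t in tree.tips()}
    splits = set()
    for node in tree.non_tips():
        clade = frozenset(t.name for t in node.tips())
        splits.add(clade)
        splits.add(frozenset(tips - clade))
    return splits


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        nwk = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        # closed form: lA = (dAB + dAC - dBC)/2 = 1, lB = 3, lC = 5
        assert "A:1" in nwk and "B:3" in nwk and "C:5" in nwk

    def test_four_taxon_additive_topology(self):
        # additive tree ((A,B),(C,D)) with internal branch 3
        d = np.array(
            [
                [0, 2, 7, 8],
                [2, 0, 7, 8],
                [7, 7, 0, 3],
                [8, 8, 3, 0],
            ],
            dtype=float,
        )
        nwk = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        splits = parse_newick_topology(nwk)
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits

    def test_five_taxon_additive_recovers_known_tree(self):
        # tree: ((A,B),C,(D,E)) with all external branches 1, internals 2
        # path lengths: dAB=2, dAC=4, dAD=dAE=6, dCD=4, dDE=2 ...
        d = np.array(
            [
                [0, 2, 4, 6, 6],
                [2, 0, 4, 6, 6],
                [4, 4, 0, 4, 4],
                [6, 6, 4, 0, 2],
                [6, 6, 4, 2, 0],
            ],
            dtype=float,
        )
        nwk = neighbor_joining(DistanceMatrix(list("ABCDE"), d))
        splits = parse_newick_topology(nwk)
        assert frozenset({"A", "B"}) in splits
        assert frozenset({"D", "E"}) in splits

    def test_matches_skbio_topology_on_random_additive_metric(self, rng):
        """Cross-check against the independent scikit-bio NJ implementation
        on a metric perturbed from additivity."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        n = 7
        coords = rng.random((n, 4)) * 10
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        ids = [f"t{i}" for i in range(n)]
        ours = parse_newick_topology(neighbor_joining(DistanceMatrix(ids, d)))
        theirs_tree = skbio_nj(SkbioDM(d, ids))
        theirs = parse_newick_topology(str(theirs_tree).strip())
        assert ours == theirs

    def test_two_groups_form_two_clades(self):
        """Simulated wild-like and pedigree-like panels split into two taxa."""
        cfg = SimConfig(
            seed=5, genome=GenomeMap([("A01", 200_000)]), snp_count={"A01": 600},
            founder_count=5,
        )
        wild = simulate_founder_haplotypes(cfg, n_accessions=5)
        # pedigree-like: low-diversity perturbed copies of one wild accession
        base = wild.haplotypes[0]
        rng = np.random.default_rng(1)
        ped_rows = np.vstack([
            np.where(rng.random(len(base)) < 0.01, 1 - base, base) for _ in range(10)
        ]).astype(np.uint8)
        all_haps = np.vstack([wild.haplotypes, ped_rows])
        names = [f"wild{i}" for i in range(5)] + [f"ped{i}" for i in range(5)]
        m = HaplotypeMatrix(names, wild.sites, all_haps)
        dm = genetic_distance_matrix(m.to_genotypes())
        splits = parse_newick_topology(neighbor_joining(dm))
        assert frozenset({f"ped{i}" for i in range(5)}) in splits

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.zeros((2, 2))))
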