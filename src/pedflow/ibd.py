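"""Sliding-window SNP-identity IBD detection and pedigree genome-flow tracing.

The procedure scans windows of 200 SNPs (step 20 SNPs) along each
chromosome and, for each descendant/candidate-parent pair, computes the
fraction of jointly called sites with identical genotype codes.  A window
with identity ratio >= 0.99 is an inheritable IBD window, provided it is
informative (enough jointly called sites) and not masked as low-diversity
(windows where two candidate source founders are themselves mutually
near-identical cannot attribute origin).  Qualifying windows are merged into
segments; overlaying the per-parent segments splits the genome into regions
attributable to exactly one parent (unique) or to several (shared).

Origin tracing works in two modes: *direct* (descendant compared against
each ancestor independently) and *chained* (a region counts only if a
qualifying segment covers it at every parent-child link on some pedigree
path from the ancestor to the target, i.e. stably inherited).  Contributions
are reported as unique bp per ancestor over the assembled genome, with the
remainder labelled unknown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import (
    GenomeMap,
    Interval,
    PedigreeGraph,
    intersect_interval_sets,
    merge_intervals,
)
from .vcfio import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "IbdParams",
    "SnpWindow",
    "IdentityRatio",
    "IbdSegment",
    "ContributionReport",
    "snp_windows",
    "window_identity_ratio",
    "uninformative_window_mask",
    "detect_ibd_segments",
    "trace_contributions",
    "common_ibd_intersection",
    "segments_to_frame",
]


@dataclass(frozen=True)
class IbdParams:
    """Tuning of the IBD scan (defaults follow the published procedure)."""

    window_size: int = 200  # SNPs per window
    window_step: int = 20  # SNPs between window starts
    ratio_threshold: float = 0.99
    min_informative: Optional[int] = None  # default: window_size // 2
    founder_identity_cutoff: float = 0.99  # low-diversity window mask
    allele_level: bool = False  # match alleles instead of genotype codes

    @property
    def informative(self) -> int:
        return self.min_informative if self.min_informative is not None else self.window_size // 2


@dataclass(frozen=True)
class SnpWindow:
    """A window over site indices of one chromosome."""

    index: int
    chrom: str
    first: int  # site index (chromosome-local)
    last: int  # inclusive
    interval: Interval  # position of first to position of last site
    truncated: bool = False

    @property
    def n_sites(self) -> int:
        return self.last - self.first + 1


@dataclass(frozen=True)
class IdentityRatio:
    window: SnpWindow
    descendant: str
    parent: str
    n_compared: int
    n_identical: int
    qualifies: bool

    @property
    def ratio(self) -> float:
        return self.n_identical / self.n_compared if self.n_compared else float("nan")


@dataclass(frozen=True)
class IbdSegment:
    descendant: str
    sources: frozenset
    interval: Interval
    n_snps: int

    @property
    def unique(self) -> bool:
        return len(self.sources) == 1


@dataclass
class ContributionReport:
    """Per-ancestor genome shares of a traced target, in percent."""

    target: str
    unique_pct: dict[str, float]
    shared_pct: float
    unknown_pct: float
    unique_bp: dict[str, int] = field(default_factory=dict)
    shared_bp: int = 0
    total_bp: int = 0

    def dataframe(self) -> pd.DataFrame:
        rows = [
            {"ancestor": a, "unique_bp": self.unique_bp.get(a, 0), "percent": p}
            for a, p in sorted(self.unique_pct.items())
        ]
        rows.append({"ancestor": "<shared>", "unique_bp": self.shared_bp, "percent": self.shared_pct})
        rows.append(
            {
                "ancestor": "<unknown>",
                "unique_bp": self.total_bp - self.shared_bp - sum(self.unique_bp.values()),
                "percent": self.unknown_pct,
            }
        )
        return pd.DataFrame(rows)


def snp_windows(
    positions: np.ndarray, chrom: str, size: int = 200, step: int = 20
) -> list[SnpWindow]:
    """Windows over sorted site indices; never cross a chromosome boundary.

    Full windows start at indices 0, step, 2*step, ... while they fit.  When
    the chromosome has fewer sites than one full window, a single truncated
    window covering all sites is emitted if at least ``step`` sites exist;
    otherwise the chromosome yields no window.
    """
    if not size >= step >= 1:
        raise ValueError("need size >= step >= 1")
    s = len(positions)
    out: list[SnpWindow] = []
    if s >= size:
        start = 0
        while start + size <= s:
            out.append(
                SnpWindow(
                    len(out),
                    chrom,
                    start,
                    start + size - 1,
                    Interval(chrom, int(positions[start]), int(positions[start + size - 1])),
                )
            )
            start += step
    elif s >= step:
        out.append(
            SnpWindow(0, chrom, 0, s - 1, Interval(chrom, int(positions[0]), int(positions[-1])), truncated=True)
        )
    return out


def _identity_vector(
    a: np.ndarray, b: np.ndarray, allele_level: bool
) -> tuple[np.ndarray, np.ndarray]:
    """(compared mask, identical mask) between two genotype code rows."""
    compared = (a != MISSING) & (b != MISSING)
    if allele_level:
        # fraction of shared alleles >= half, scored as full/half match:
        # here "identical" means sharing both alleles (codes equal) or
        # overlapping by one (|diff| == 1) counted as half.
        diff = np.abs(a.astype(np.int16) - b.astype(np.int16))
        identical = compared & (diff == 0)
    else:
        identical = compared & (a == b)
    return compared, identical


def window_identity_ratio(
    gm: GenotypeMatrix,
    descendant: str,
    parent: str,
    window: SnpWindow,
    params: IbdParams = IbdParams(),
    _chrom_cols: np.ndarray | None = None,
) -> IdentityRatio:
    """Identity ratio between two samples over one window.

    Compared sites are those non-missing in both samples; identical means the
    same unordered genotype code.  The window qualifies iff ratio >=
    ``ratio_threshold`` and at least ``min_informative`` sites were compared.
    """
    cols = _chrom_cols if _chrom_cols is not None else np.flatnonzero(
        (gm.sites["chrom"] == window.chrom).to_numpy()
    )
    sl = cols[window.first : window.last + 1]
    a = gm.row(descendant)[sl]
    b = gm.row(parent)[sl]
    compared, identical = _identity_vector(a, b, params.allele_level)
    n_c, n_i = int(compared.sum()), int(identical.sum())
    qualifies = n_c >= params.informative and n_c > 0 and n_i / n_c >= params.ratio_threshold
    return IdentityRatio(window, descendant, parent, n_c, n_i, qualifies)


def uninformative_window_mask(
    gm: GenotypeMatrix,
    founders: Sequence[str],
    windows: Sequence[SnpWindow],
    identity_cutoff: float = 0.99,
) -> np.ndarray:
    """True where ANY founder pair is near-identical within the window.

    Where two candidate source lines are mutually IBD-indistinguishable the
    origin of a matching descendant window cannot be resolved, so the window
    is dropped from tracing (the low-diversity filter).
    """
    if len(founders) < 2:
        raise ValueError("need >= 2 founders for the low-diversity mask")
    rows = {f: gm.row(f) for f in founders}
    cols_by_chrom = {
        c: np.flatnonzero((gm.sites["chrom"] == c).to_numpy())
        for c in {w.chrom for w in windows}
    }
    mask = np.zeros(len(windows), dtype=bool)
    pairs = [
        (founders[i], founders[j])
        for i in range(len(founders))
        for j in range(i + 1, len(founders))
    ]
    for wi, w in enumerate(windows):
        sl = cols_by_chrom[w.chrom][w.first : w.last + 1]
        for fa, fb in pairs:
            compared, identical = _identity_vector(rows[fa][sl], rows[fb][sl], False)
            n_c = compared.sum()
            if n_c > 0 and identical.sum() / n_c >= identity_cutoff:
                mask[wi] = True
                break
    return mask


def _qualifying_segments(
    gm: GenotypeMatrix,
    descendant: str,
    parent: str,
    windows_by_chrom: dict[str, list[SnpWindow]],
    masks_by_chrom: dict[str, np.ndarray],
    cols_by_chrom: dict[str, np.ndarray],
    params: IbdParams,
) -> list[tuple[Interval, int]]:
    """Merged runs of qualifying unmasked windows, per chromosome."""
    segs: list[tuple[Interval, int]] = []
    a_all = gm.row(descendant)
    b_all = gm.row(parent)
    for chrom, windows in windows_by_chrom.items():
        cols = cols_by_chrom[chrom]
        a = a_all[cols]
        b = b_all[cols]
        compared = (a != MISSING) & (b != MISSING)
        identical = compared & (a == b) if not params.allele_level else _identity_vector(a, b, True)[1]
        c_cum = np.concatenate([[0], np.cumsum(compared)])
        i_cum = np.concatenate([[0], np.cumsum(identical)])
        mask = masks_by_chrom[chrom]
        pos = gm.sites["pos"].to_numpy()[cols]
        run: Optional[list] = None  # [first_site, last_site]
        for wi, w in enumerate(windows):
            n_c = int(c_cum[w.last + 1] - c_cum[w.first])
            n_i = int(i_cum[w.last + 1] - i_cum[w.first])
            ok = (
                not mask[wi]
                and n_c >= params.informative
                and n_c > 0
                and n_i / n_c >= params.ratio_threshold
            )
            if ok:
                if run is not None and w.first <= run[1] + 1:
                    run[1] = max(run[1], w.last)
                else:
                    if run is not None:
                        segs.append(_close_run(chrom, pos, run))
                    run = [w.first, w.last]
            elif run is not None and w.first > run[1]:
                segs.append(_close_run(chrom, pos, run))
                run = None
        if run is not None:
            segs.append(_close_run(chrom, pos, run))
    return segs


def _close_run(chrom: str, pos: np.ndarray, run: list) -> tuple[Interval, int]:
    first, last = run
    return Interval(chrom, int(pos[first]), int(pos[last])), last - first + 1


def detect_ibd_segments(
    gm: GenotypeMatrix,
    descendant: str,
    parents: Sequence[str],
    params: IbdParams = IbdParams(),
    mask_founders: Sequence[str] | None = None,
    genome: GenomeMap | None = None,
) -> list[IbdSegment]:
    """IBD segments of a descendant against candidate parents, overlaid.

    Per parent, qualifying unmasked windows whose site spans overlap or abut
    are merged into runs; segment coordinates span the first to last SNP of
    the run.  The per-parent segments are then overlaid: regions qualifying
    for exactly one parent become unique segments, regions qualifying for
    several carry the full source set.
    """
    if descendant in parents:
        raise ValueError("descendant cannot be its own candidate parent")
    chroms = list(pd.unique(gm.sites["chrom"]))
    cols_by_chrom = {c: np.flatnonzero((gm.sites["chrom"] == c).to_numpy()) for c in chroms}
    windows_by_chrom = {
        c: snp_windows(
            gm.sites["pos"].to_numpy()[cols_by_chrom[c]], c, params.window_size, params.window_step
        )
        for c in chroms
    }
    if mask_founders is not None and len(mask_founders) >= 2:
        masks_by_chrom = {
            c: uninformative_window_mask(
                gm, mask_founders, windows_by_chrom[c], params.founder_identity_cutoff
            )
            for c in chroms
        }
    else:
        masks_by_chrom = {c: np.zeros(len(windows_by_chrom[c]), dtype=bool) for c in chroms}

    per_parent: dict[str, list[tuple[Interval, int]]] = {}
    for p in parents:
        per_parent[p] = _qualifying_segments(
            gm, descendant, p, windows_by_chrom, masks_by_chrom, cols_by_chrom, params
        )
    return _overlay(descendant, per_parent, gm)


def _overlay(
    descendant: str,
    per_parent: dict[str, list[tuple[Interval, int]]],
    gm: GenotypeMatrix,
) -> list[IbdSegment]:
    """Split per-parent segment sets into elementary source-set regions."""
    events: dict[str, list[tuple[int, int, str]]] = {}
    for p, segs in per_parent.items():
        for iv, _ in segs:
            events.setdefault(iv.chrom, []).append((iv.start, iv.end, p))
    out: list[IbdSegment] = []
    chrom_pos = {
        c: gm.sites.loc[gm.sites["chrom"] == c, "pos"].to_numpy()
        for c in events
    }
    for chrom, evs in events.items():
        bounds = sorted({e[0] for e in evs} | {e[1] + 1 for e in evs})
        pos = chrom_pos[chrom]
        prev_sources: Optional[frozenset] = None
        seg_start = None
        for k in range(len(bounds) - 1):
            lo, hi = bounds[k], bounds[k + 1] - 1
            sources = frozenset(p for s, e, p in evs if s <= lo and e >= hi)
            if sources != prev_sources:
                if prev_sources:
                    out.append(_make_segment(descendant, prev_sources, chrom, seg_start, bounds[k] - 1, pos))
                seg_start = lo
                prev_sources = sources
        if prev_sources:
            out.append(_make_segment(descendant, prev_sources, chrom, seg_start, bounds[-1] - 1, pos))
    return sorted(out, key=lambda s: (s.interval.chrom, s.interval.start))


def _make_segment(
    descendant: str, sources: frozenset, chrom: str, start: int, end: int, pos: np.ndarray
) -> IbdSegment:
    n = int(np.searchsorted(pos, end, "right") - np.searchsorted(pos, start, "left"))
    return IbdSegment(descendant, sources, Interval(chrom, start, end), n)


def trace_contributions(
    pedigree: PedigreeGraph,
    gm: GenotypeMatrix,
    target: str,
    ancestors: Sequence[str],
    genome: GenomeMap,
    params: IbdParams = IbdParams(),
    mode: str = "direct",
    mask_founders: Sequence[str] | None = None,
) -> tuple[dict[str, list[IbdSegment]], ContributionReport]:
    """Trace the genomic origin of a target accession through the pedigree.

    direct mode: the target is compared against each ancestor independently.
    chained mode: a region is credited to an ancestor only when a qualifying
    IBD segment covers it at every parent-child link along some pedigree path
    from the ancestor to the target (stable inheritance).  Unique percentages
    are per-ancestor over the assembled genome; shared (multi-source) bp are
    reported separately; the remainder is unknown.
    """
    for a in ancestors:
        if not pedigree.is_ancestor(a, target):
            raise ValueError(f"{a!r} is not a pedigree ancestor of {target!r}")
    if mode not in ("direct", "chained"):
        raise ValueError("mode must be 'direct' or 'chained'")

    if mode == "direct":
        segments = detect_ibd_segments(
            gm, target, list(ancestors), params, mask_founders=mask_founders
        )
        per_anc: dict[str, list[IbdSegment]] = {a: [] for a in ancestors}
        for seg in segments:
            for src in seg.sources:
                per_anc[src].append(seg)
    else:
        link_cache: dict[tuple[str, str], list[Interval]] = {}

        def link_ivs(parent: str, child: str) -> list[Interval]:
            key = (parent, child)
            if key not in link_cache:
                segs = detect_ibd_segments(
                    gm, child, [parent], params, mask_founders=mask_founders
                )
                link_cache[key] = merge_intervals([s.interval for s in segs])
            return link_cache[key]

        per_anc = {}
        covered: dict[str, list[Interval]] = {}
        for a in ancestors:
            ivs: list[Interval] = []
            for path in pedigree.paths(a, target):
                path_ivs = [Interval(c, 1, l) for c, l in genome]
                for parent, child in zip(path, path[1:]):
                    path_ivs = intersect_interval_sets(path_ivs, link_ivs(parent, child))
                    if not path_ivs:
                        break
                ivs = merge_intervals(ivs + path_ivs)
            covered[a] = ivs
        # overlay the chained coverages to split unique vs shared
        per_parent = {a: [(iv, 0) for iv in covered[a]] for a in ancestors}
        segments = _overlay(target, per_parent, gm)
        per_anc = {a: [] for a in ancestors}
        for seg in segments:
            for src in seg.sources:
                per_anc[src].append(seg)

    total_bp = genome.total_bp
    unique_bp = {
        a: sum(len(s.interval) for s in per_anc[a] if s.unique) for a in ancestors
    }
    shared_bp = sum(len(s.interval) for s in {s for segs in per_anc.values() for s in segs if not s.unique})
    unique_pct = {a: 100.0 * b / total_bp for a, b in unique_bp.items()}
    shared_pct = 100.0 * shared_bp / total_bp
    unknown_pct = 100.0 - shared_pct - sum(unique_pct.values())
    report = ContributionReport(
        target, unique_pct, shared_pct, unknown_pct, unique_bp, shared_bp, total_bp
    )
    return per_anc, report


def common_ibd_intersection(
    segment_sets: Sequence[Sequence[IbdSegment]], min_len: int = 10_000
) -> list[IbdSegment]:
    """Base-pair intersection of IBD segment sets across descendants.

    All sets must be traced from the same ancestor; the result contains the
    fragments of length >= ``min_len`` present in EVERY input set.  Any empty
    input set empties the intersection.
    """
    if not segment_sets:
        raise ValueError("need at least one segment set")
    sources = frozenset().union(*(s.sources for ss in segment_sets for s in ss)) or frozenset({"?"})
    current = merge_intervals([s.interval for s in segment_sets[0]])
    for ss in segment_sets[1:]:
        current = intersect_interval_sets(current, [s.interval for s in ss])
        if not current:
            break
    return [
        IbdSegment("<common>", sources, iv, 0)
        for iv in current
        if len(iv) >= min_len
    ]


def segments_to_frame(segments: Sequence[IbdSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "descendant": [s.descendant for s in segments],
            "chrom": [s.interval.chrom for s in segments],
            "start": [s.interval.start for s in segments],
            "end": [s.interval.end for s in segments],
            "length_bp": [len(s.interval) for s in segments],
            "n_snps": [s.n_snps for s in segments],
            "sources": ["|".join(sorted(s.sources)) for s in segments],
            "unique": [s.unique for s in segments],
        }
    )
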