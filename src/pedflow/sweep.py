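"""Selective-sweep detection: pi-ratio scan with XP-EHH confirmation.

A sweep in the domesticated (pedigree) group shows up as windows where
log10(pi_wild / pi_pedigree) falls in the upper tail of its genome-wide
distribution.  Candidate windows from the top-quantile pi-ratio cutoff are
confirmed by an independent cross-population extended-haplotype-homozygosity
(XP-EHH) scan: the standardized log-ratio of integrated EHH between the two
panels, aggregated per window, must also fall in its top quantile.

EHH at a marker x around a core site is the probability that two randomly
chosen haplotypes are identical at every marker between the core and x
(inclusive); it starts at 1 and is non-increasing outward.  iHH is the
trapezoidal integral of EHH over physical distance, summed over both
directions, with curves truncated once EHH drops below 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome import Interval, merge_intervals
from .simulate import HaplotypeMatrix
from .diversity import WindowStat

logger = logging.getLogger(__name__)

EHH_CUTOFF = 0.05

__all__ = [
    "SweepWindow",
    "EhhCurve",
    "pi_ratio_scan",
    "ehh_curve",
    "site_ihh",
    "xpehh_scan",
    "confirm_sweeps",
    "confirmed_segments",
]


@dataclass
class SweepWindow:
    interval: Interval
    pi_wild: float
    pi_ped: float
    log10_ratio: float
    xpehh_score: float = float("nan")
    pi_flagged: bool = False
    xpehh_flagged: bool = False

    @property
    def confirmed(self) -> bool:
        return self.pi_flagged and self.xpehh_flagged


@dataclass
class EhhCurve:
    core_index: int
    direction: int  # +1 (increasing positions) or -1
    distances: list[int] = field(default_factory=list)  # bp from core, >= 0
    values: list[float] = field(default_factory=list)
    truncation: str = "threshold"  # threshold | chrom_end | window_end


def pi_ratio_scan(
    pi_wild: Sequence[WindowStat],
    pi_ped: Sequence[WindowStat],
    quantile: float = 0.05,
) -> list[SweepWindow]:
    """Flag windows in the top ``quantile`` of log10(pi_wild / pi_ped).

    The threshold is the empirical (1 - quantile) quantile of the finite
    ratios; ties at the threshold are flagged inclusively.  Windows with
    pi_ped = 0 < pi_wild have ratio +inf and are always flagged; windows with
    both diversities zero carry no signal, are excluded from the quantile and
    never flagged.
    """
    if len(pi_wild) != len(pi_ped) or any(
        a.interval != b.interval for a, b in zip(pi_wild, pi_ped)
    ):
        raise ValueError("pi window lists must be aligned on identical intervals")
    out = []
    for w, p in zip(pi_wild, pi_ped):
        if w.value == 0 and p.value == 0:
            ratio = float("nan")
        elif p.value == 0:
            ratio = float("inf")
        else:
            ratio = float(np.log10(w.value / p.value))
        out.append(SweepWindow(w.interval, w.value, p.value, ratio))
    finite = [s.log10_ratio for s in out if np.isfinite(s.log10_ratio)]
    threshold = float(np.quantile(finite, 1 - quantile)) if finite else float("inf")
    for s in out:
        if np.isinf(s.log10_ratio) and s.log10_ratio > 0:
            s.pi_flagged = True
        elif np.isfinite(s.log10_ratio):
            s.pi_flagged = s.log10_ratio >= threshold
    return out


# ---------------------------------------------------------------------------
# EHH / XP-EHH


def _group_sizes_step(labels: np.ndarray, alleles: np.ndarray) -> np.ndarray:
    """Refine haplotype grouping by one more marker; return new labels."""
    combined = labels * 2 + alleles
    _, new = np.unique(combined, return_inverse=True)
    return new


def _ehh_from_labels(labels: np.ndarray) -> float:
    h = len(labels)
    _, counts = np.unique(labels, return_counts=True)
    return float(np.sum(counts * (counts - 1)) / (h * (h - 1)))


def ehh_curve(
    haps: np.ndarray,
    positions: np.ndarray,
    core: int,
    direction: int,
    cutoff: float = EHH_CUTOFF,
    max_extend_bp: int | None = None,
) -> EhhCurve:
    """EHH outward from a core site over one chromosome's phased haplotypes.

    ``haps`` is (n_haplotypes, n_sites) 0/1; the curve starts at EHH(0) = 1
    by convention; from the first marker outward the core marker itself is
    included in the identity requirement.  Evaluation stops when EHH < cutoff
    (truncation ``threshold``), at the chromosome boundary (``chrom_end``) or
    beyond ``max_extend_bp`` from the core (``window_end``) -- highly related
    panels can hold EHH above the cutoff over arbitrarily long ranges, so a
    bounded integration radius keeps the scan well defined.
    """
    if haps.shape[0] < 2:
        raise ValueError("need >= 2 haplotypes")
    h = haps.shape[0]
    curve = EhhCurve(core, +1 if direction >= 0 else -1)
    labels = np.zeros(h, dtype=np.int64)
    # include the core marker in the homozygosity requirement
    labels = _group_sizes_step(labels, haps[:, core])
    curve.distances.append(0)
    curve.values.append(1.0)
    step = curve.direction
    j = core + step
    while 0 <= j < haps.shape[1]:
        dist = int(abs(positions[j] - positions[core]))
        if max_extend_bp is not None and dist > max_extend_bp:
            curve.truncation = "window_end"
            return curve
        labels = _group_sizes_step(labels, haps[:, j])
        e = _ehh_from_labels(labels)
        curve.distances.append(dist)
        curve.values.append(e)
        if e < cutoff:
            curve.truncation = "threshold"
            return curve
        j += step
    curve.truncation = "chrom_end"
    return curve


def site_ihh(
    haps: np.ndarray,
    positions: np.ndarray,
    core: int,
    cutoff: float = EHH_CUTOFF,
    max_extend_bp: int | None = None,
) -> float:
    """Integrated EHH: trapezoidal integral over bp, both directions summed."""
    total = 0.0
    for direction in (+1, -1):
        c = ehh_curve(haps, positions, core, direction, cutoff, max_extend_bp)
        total += float(np.trapezoid(c.values, c.distances))
    return total


def panel_ihh(
    haps: np.ndarray,
    positions: np.ndarray,
    cutoff: float = EHH_CUTOFF,
    max_extend_bp: int | None = None,
) -> np.ndarray:
    """iHH at every site of one chromosome, via pairwise mismatch survival.

    EHH at marker core+k equals the fraction of haplotype pairs whose first
    mismatch beyond the core lies past core+k, i.e. the survival function of
    the per-pair first-mismatch index.  Precomputing, for every pair and
    column, the next and previous mismatch index turns each site's EHH curve
    into a histogram lookup; the result is numerically identical to
    integrating :func:`ehh_curve` per site.
    """
    h, s = haps.shape
    if h < 2:
        raise ValueError("need >= 2 haplotypes")
    ii, jj = np.triu_indices(h, k=1)
    mism = haps[ii] != haps[jj]  # (n_pairs, n_sites)
    n_pairs = len(ii)

    nxt = np.empty((n_pairs, s + 1), dtype=np.int32)
    nxt[:, s] = s
    for c in range(s - 1, -1, -1):
        nxt[:, c] = np.where(mism[:, c], c, nxt[:, c + 1])
    prv = np.empty((n_pairs, s + 1), dtype=np.int32)
    prv[:, 0] = -1
    for c in range(s):
        prv[:, c + 1] = np.where(mism[:, c], c, prv[:, c])

    out = np.zeros(s)
    for c in range(s):
        total = 0.0
        for direction in (+1, -1):
            if direction == +1:
                t = nxt[:, c] - c  # first dead extension step per pair
                m_max = s - 1 - c
            else:
                t = c - prv[:, c + 1]
                m_max = c
            if max_extend_bp is not None:
                if direction == +1:
                    lim = int(np.searchsorted(positions, positions[c] + max_extend_bp, "right")) - 1 - c
                else:
                    lim = c - int(np.searchsorted(positions, positions[c] - max_extend_bp, "left"))
                m_max = min(m_max, lim)
            counts = np.bincount(np.minimum(t, m_max + 1), minlength=m_max + 2)
            surv = n_pairs - np.cumsum(counts)
            values = [1.0]
            k_stop = m_max
            ehh = surv[1 : m_max + 1] / n_pairs
            below = np.flatnonzero(ehh < cutoff)
            if len(below):
                k_stop = int(below[0]) + 1
            values = np.concatenate([[1.0], ehh[:k_stop]])
            idx = np.arange(c, c + direction * (k_stop + 1), direction)
            dists = np.abs(positions[idx] - positions[c])
            total += float(np.trapezoid(values, dists))
        out[c] = total
    return out


def xpehh_scan(
    hap_ped: HaplotypeMatrix,
    hap_wild: HaplotypeMatrix,
    windows: Sequence[Interval],
    quantile: float = 0.05,
    cutoff: float = EHH_CUTOFF,
    aggregate: str = "max",
    max_extend_bp: int | None = 2_000_000,
) -> tuple[np.ndarray, list[WindowStat], np.ndarray]:
    """Cross-population EHH scan; per-site scores and flagged windows.

    Raw score per site = ln(iHH_ped / iHH_wild); standardized genome-wide to
    mean 0 / SD 1.  A window's score is the maximum (or mean) standardized
    score among its sites; the top ``quantile`` of windows is flagged.
    Returns (per-site standardized scores, window stats, window flag mask).
    """
    if not hap_ped.sites[["chrom", "pos"]].equals(hap_wild.sites[["chrom", "pos"]]):
        raise ValueError("panels must share an identical site set")
    sites = hap_ped.sites
    raw = np.full(len(sites), np.nan)
    for chrom in sites["chrom"].unique():
        mask = (sites["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(mask)
        pos = sites.loc[mask, "pos"].to_numpy()
        ihh_p = panel_ihh(hap_ped.haplotypes[:, mask], pos, cutoff, max_extend_bp)
        ihh_w = panel_ihh(hap_wild.haplotypes[:, mask], pos, cutoff, max_extend_bp)
        ok = (ihh_p > 0) & (ihh_w > 0)
        n_skip = int((~ok).sum())
        if n_skip:
            logger.debug("%d sites with zero iHH on %s skipped", n_skip, chrom)
        raw[idx[ok]] = np.log(ihh_p[ok] / ihh_w[ok])
    ok = np.isfinite(raw)
    mu, sd = np.nanmean(raw[ok]), np.nanstd(raw[ok])
    std = (raw - mu) / sd if sd > 0 else raw - mu

    chroms = sites["chrom"].to_numpy()
    pos_all = sites["pos"].to_numpy()
    win_stats = []
    scores = []
    for iv in windows:
        sel = (chroms == iv.chrom) & (pos_all >= iv.start) & (pos_all <= iv.end)
        vals = std[sel]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            score = float("nan")
        elif aggregate == "max":
            score = float(np.max(vals))
        else:
            score = float(np.mean(vals))
        win_stats.append(WindowStat(iv, int(sel.sum()), score))
        scores.append(score)
    scores = np.array(scores)
    finite = scores[np.isfinite(scores)]
    thr = float(np.quantile(finite, 1 - quantile)) if len(finite) else float("inf")
    flags = np.isfinite(scores) & (scores >= thr)
    return std, win_stats, flags


def confirm_sweeps(
    pi_windows: list[SweepWindow],
    xpehh_windows: Sequence[WindowStat],
    xpehh_flags: np.ndarray,
) -> list[SweepWindow]:
    """Attach XP-EHH flags; a window is confirmed iff both scans flag it."""
    if len(pi_windows) != len(xpehh_windows) or any(
        s.interval != w.interval for s, w in zip(pi_windows, xpehh_windows)
    ):
        raise ValueError("window lists must be aligned")
    for s, w, f in zip(pi_windows, xpehh_windows, xpehh_flags):
        s.xpehh_score = w.value
        s.xpehh_flagged = bool(f)
    return pi_windows


def confirmed_segments(sweeps: Sequence[SweepWindow], step: int) -> list[Interval]:
    """Merge adjacent confirmed windows into sweep segments (gap <= step)."""
    return merge_intervals([s.interval for s in sweeps if s.confirmed], max_gap=step)
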