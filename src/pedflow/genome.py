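"""Genome coordinate system, interval algebra, pedigree graph and feature overlap.

Coordinates are 1-based inclusive everywhere inside the package, matching the
segment notation used in cotton genomics (e.g. ``D02:2204597-2360776``).  BED
export converts to 0-based half-open at the boundary only.

Chromosome names of allotetraploid Upland cotton come in two dialects,
``A1``/``D13`` and ``A01``/``D13``; both are accepted and normalized to the
zero-padded form.  The sub-genome (A or D) is derived from the name prefix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "normalize_chrom",
    "subgenome",
    "GenomeMap",
    "Interval",
    "PedigreeGraph",
    "Feature",
    "FeatureSet",
    "PedigreeError",
    "validate_pedigree",
    "overlap_bp",
    "merge_intervals",
    "intersect_interval_sets",
    "overlap_features",
    "load_pedigree_tsv",
    "load_features_bed",
    "ekangmian9_pedigree",
]

ROLES = frozenset({"exotic_founder", "backbone", "elite", "hybrid"})

_CHROM_RE = re.compile(r"^([A-Za-z]+?)(\d+)$")


class PedigreeError(ValueError):
    """Structural problem in a pedigree graph (cycle, >2 parents, bad role)."""


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name: ``A1`` and ``A01`` both become ``A01``."""
    m = _CHROM_RE.match(name.strip())
    if m is None:
        return name.strip()
    prefix, num = m.groups()
    return f"{prefix}{int(num):02d}"


def subgenome(chrom: str) -> str:
    """Sub-genome label (``A`` or ``D``) from a chromosome name prefix."""
    m = _CHROM_RE.match(chrom)
    return (m.group(1) if m else chrom)[:1].upper()


class GenomeMap:
    """Ordered chromosome name -> length (bp) map with name normalization."""

    def __init__(self, chromosomes: Iterable[tuple[str, int]]):
        self._lengths: dict[str, int] = {}
        for name, length in chromosomes:
            name = normalize_chrom(name)
            if name in self._lengths:
                raise ValueError(f"duplicate chromosome name {name!r}")
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            self._lengths[name] = int(length)

    @property
    def names(self) -> list[str]:
        return list(self._lengths)

    def length(self, chrom: str) -> int:
        return self._lengths[normalize_chrom(chrom)]

    def __contains__(self, chrom: str) -> bool:
        return normalize_chrom(chrom) in self._lengths

    def __iter__(self):
        return iter(self._lengths.items())

    def __len__(self) -> int:
        return len(self._lengths)

    @property
    def total_bp(self) -> int:
        return sum(self._lengths.values())

    def subgenome_bp(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for name, length in self._lengths.items():
            out[subgenome(name)] = out.get(subgenome(name), 0) + length
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenomeMap({len(self)} chromosomes, {self.total_bp} bp)"


@dataclass(frozen=True, order=True)
class Interval:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"start {self.start} < 1")

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def validate(self, genome: GenomeMap) -> None:
        if self.chrom not in genome:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if self.end > genome.length(self.chrom):
            raise ValueError(
                f"{self} extends past chromosome end {genome.length(self.chrom)}"
            )

    def to_bed(self) -> tuple[str, int, int]:
        """Convert to BED (0-based half-open) at the export boundary."""
        return self.chrom, self.start - 1, self.end

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_bp(a: Interval, b: Interval) -> int:
    """Base pairs shared by two intervals (0 if different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def merge_intervals(intervals: Sequence[Interval], max_gap: int = 0) -> list[Interval]:
    """Sort and merge intervals, bridging gaps of at most ``max_gap`` bp.

    Two intervals merge iff the gap between them (bp strictly between the end
    of one and the start of the next) is <= max_gap.  Output is sorted and
    pairwise non-overlapping; idempotent.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    if not intervals:
        return []
    out: list[Interval] = []
    for iv in sorted(intervals):
        if out and iv.chrom == out[-1].chrom and iv.start - out[-1].end - 1 <= max_gap:
            if iv.end > out[-1].end:
                out[-1] = Interval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def intersect_interval_sets(
    a: Sequence[Interval], b: Sequence[Interval]
) -> list[Interval]:
    """Base-pair intersection of two interval sets (each treated as a union)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        x, y = a[i], b[j]
        if x.chrom == y.chrom:
            lo, hi = max(x.start, y.start), min(x.end, y.end)
            if lo <= hi:
                out.append(Interval(x.chrom, lo, hi))
            if (x.chrom, x.end) <= (y.chrom, y.end):
                i += 1
            else:
                j += 1
        elif (x.chrom, x.end) < (y.chrom, y.end):
            i += 1
        else:
            j += 1
    return out


# ---------------------------------------------------------------------------
# Pedigree graph


class PedigreeGraph:
    """DAG of accessions with breeding roles and parent -> child edges.

    Each node has a role in {exotic_founder, backbone, elite, hybrid} and at
    most two recorded parents; parentless nodes are the founders of the
    recorded pedigree.  Composite crosses (three or more contributing parents)
    are modeled by inserting unnamed intermediate nodes so that every node
    keeps at most two parents.
    """

    def __init__(self) -> None:
        self.graph = nx.DiGraph()

    def add_accession(self, name: str, role: str, parents: Sequence[str] = ()) -> None:
        if role not in ROLES:
            raise PedigreeError(f"unknown role {role!r} for {name!r}")
        parents = [p for p in parents if p]
        if len(parents) > 2:
            raise PedigreeError(f"{name!r} has {len(parents)} parents (max 2)")
        self.graph.add_node(name, role=role)
        for p in parents:
            if p not in self.graph:
                raise PedigreeError(f"parent {p!r} of {name!r} not yet declared")
            self.graph.add_edge(p, name)

    def role(self, name: str) -> str:
        return self.graph.nodes[name]["role"]

    def parents(self, name: str) -> list[str]:
        return sorted(self.graph.predecessors(name))

    def children(self, name: str) -> list[str]:
        return sorted(self.graph.successors(name))

    @property
    def accessions(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def founders(self) -> list[str]:
        return [n for n in self.graph.nodes if self.graph.in_degree(n) == 0]

    def ancestors(self, name: str) -> set[str]:
        return nx.ancestors(self.graph, name)

    def is_ancestor(self, ancestor: str, descendant: str) -> bool:
        return ancestor in nx.ancestors(self.graph, descendant)

    def paths(self, ancestor: str, descendant: str) -> list[list[str]]:
        return [list(p) for p in nx.all_simple_paths(self.graph, ancestor, descendant)]

    def by_role(self, role: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["role"] == role]

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def validate_pedigree(ped: PedigreeGraph) -> list[str]:
    """Validate a pedigree and return a topological order of accessions.

    Every parent precedes its children in the returned order; ties are broken
    by name so the order is deterministic.  Raises :class:`PedigreeError` on a
    cycle (naming one offending edge) or a node with more than two parents.
    """
    g = ped.graph
    if g.number_of_nodes() == 0:
        raise PedigreeError("empty pedigree")
    for n in g.nodes:
        if g.in_degree(n) > 2:
            raise PedigreeError(f"{n!r} has {g.in_degree(n)} parents (max 2)")
    try:
        order = list(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible:
        edge = nx.find_cycle(g)[0]
        raise PedigreeError(f"pedigree contains a cycle through edge {edge[0]!r} -> {edge[1]!r}")
    return order


# ---------------------------------------------------------------------------
# Features


@dataclass(frozen=True)
class Feature:
    interval: Interval
    kind: str  # gene | qtl | gwas_site
    name: str
    trait: Optional[str] = None


@dataclass
class FeatureSet:
    features: list[Feature] = field(default_factory=list)

    def add(self, interval: Interval, kind: str, name: str, trait: str | None = None):
        self.features.append(Feature(interval, kind, name, trait))

    def validate(self, genome: GenomeMap) -> None:
        for f in self.features:
            f.interval.validate(genome)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)


def overlap_features(
    segments: Sequence[Interval], features: FeatureSet, min_bp: int = 1
) -> pd.DataFrame:
    """All (segment, feature) pairs overlapping by at least ``min_bp``.

    Returns a table with one row per qualifying pair: segment coordinates,
    feature name/kind/trait and the overlap in bp.  This is the overlap used
    to ask which QTLs or genes fall inside detected sweep or IBD segments.
    """
    rows = []
    for seg in segments:
        for f in features:
            ov = overlap_bp(seg, f.interval)
            if ov >= max(1, min_bp):
                rows.append(
                    {
                        "chrom": seg.chrom,
                        "start": seg.start,
                        "end": seg.end,
                        "feature": f.name,
                        "kind": f.kind,
                        "trait": f.trait,
                        "overlap_bp": ov,
                    }
                )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "feature", "kind", "trait", "overlap_bp"]
    )


# ---------------------------------------------------------------------------
# External formats


def load_pedigree_tsv(path) -> PedigreeGraph:
    """Read a pedigree from TSV columns child, parent1, parent2, role.

    A blank parent field means the parent is unknown/unrecorded.  Rows must be
    ordered so parents appear before their children (the packaged fixture is).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"child", "parent1", "parent2", "role"}
    if not required.issubset(df.columns):
        raise ValueError(f"pedigree TSV must have columns {sorted(required)}")
    ped = PedigreeGraph()
    for row in df.itertuples(index=False):
        ped.add_accession(row.child, row.role, [row.parent1, row.parent2])
    return ped


def load_features_bed(path, genome: GenomeMap | None = None) -> FeatureSet:
    """Read features from a BED-like TSV: chrom, start0, end, kind, name, trait."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start0", "end", "kind", "name", "trait"],
        dtype={"chrom": str, "start0": int, "end": int},
        keep_default_na=False,
        comment="#",
    )
    fs = FeatureSet()
    for row in df.itertuples(index=False):
        iv = Interval(row.chrom, int(row.start0) + 1, int(row.end))
        fs.add(iv, row.kind, row.name, row.trait or None)
    if genome is not None:
        fs.validate(genome)
    return fs


def ekangmian9_pedigree() -> PedigreeGraph:
    """The packaged Ekangmian 9 breeding-pedigree fixture.

    Encodes the breeding history of the elite cotton cultivar Ekangmian 9 and
    the seven elite strains derived from it: 26 sequenced accessions (the
    published analysis counts 27 pedigree accessions but resequences 26) plus
    unnamed intermediate crosses inserted so every node has at most two
    parents.
    """
    from importlib.resources import files

    return load_pedigree_tsv(files("pedflow.data").joinpath("ekangmian9_pedigree.tsv"))
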