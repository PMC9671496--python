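"""Domain types for genomes, genes, and transposon insertion sites.

Coordinates are 1-based inclusive throughout (the GFF3 convention); any
half-open input dialect is converted on read.  A "site" is a genomic
position carrying transposon-junction reads; by default the two insertion
orientations at a position are collapsed into a single site, because a
transposon disrupts a gene regardless of orientation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "GeneRecord",
    "GenomeAnnotation",
    "InsertionCountTable",
    "GeneSiteProfile",
    "assign_sites_to_genes",
    "INTERGENIC",
]

#: Bucket id for sites falling outside every annotated gene.
INTERGENIC = "_intergenic"


@dataclass(frozen=True)
class GeneRecord:
    """A gene on a contig, 1-based inclusive coordinates."""

    gene_id: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""
    sim_attrs: object | None = None  # per-gene simulation parameters, if any

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start {self.start} < 1")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAnnotation:
    """An ordered gene annotation on a single contig.

    Genes are kept sorted by (start, gene_id) and gene ids must be unique.
    """

    contig_id: str
    contig_length: int
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.gene_id))
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.end > self.contig_length:
                raise ValueError(
                    f"gene {g.gene_id} end {g.end} exceeds contig length "
                    f"{self.contig_length}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def get(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def interval_tree(self, edge_trim: float = 0.0) -> IntervalTree:
        """IntervalTree over gene bodies (half-open internally).

        ``edge_trim`` removes that fraction of each gene's length from both
        termini before building the tree (0 disables trimming, the default:
        all positions in the annotated span count).
        """
        tree = IntervalTree()
        for g in self.genes:
            start, end = g.start, g.end
            if edge_trim > 0:
                trim = int(g.length * edge_trim)
                start, end = start + trim, end - trim
                if start > end:
                    continue
            tree.addi(start, end + 1, g.gene_id)
        return tree


@dataclass
class InsertionCountTable:
    """Per-sample map of genomic insertion site -> read count.

    ``counts`` maps 1-based position -> count when strands are collapsed
    (the default for this package) or ``(position, strand)`` -> count when
    they are preserved.  Counts may be floats after normalization.
    """

    sample_id: str
    condition: str  # "control" or "phage"
    counts: dict = field(default_factory=dict)
    contig_id: str = ""
    phage_label: str = ""
    replicate: int = 1
    paired_control_id: str = ""

    def __post_init__(self) -> None:
        if self.condition not in {"control", "phage"}:
            raise ValueError(f"condition must be control|phage, got {self.condition!r}")
        for site, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count {c} at site {site}")

    @property
    def total_reads(self) -> float:
        total = sum(self.counts.values())
        return int(total) if float(total).is_integer() else total

    def positions(self) -> np.ndarray:
        """Sorted array of positions (strand collapsed)."""
        pos = {s[0] if isinstance(s, tuple) else s for s in self.counts}
        return np.array(sorted(pos), dtype=np.int64)

    def collapsed_counts(self) -> dict[int, float]:
        """Position -> count with strands summed (no-op if already collapsed)."""
        out: dict[int, float] = {}
        for site, c in self.counts.items():
            pos = site[0] if isinstance(site, tuple) else site
            out[pos] = out.get(pos, 0) + c
        return out

    def scaled(self, factor: float, sample_id: str | None = None) -> "InsertionCountTable":
        """A copy with every count multiplied by ``factor``."""
        new = dataclasses.replace(
            self,
            counts={s: c * factor for s, c in self.counts.items()},
        )
        if sample_id is not None:
            new.sample_id = sample_id
        return new

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[int, str, float]],
        *,
        collapse_strands: bool = True,
        **meta,
    ) -> "InsertionCountTable":
        """Build from (position, strand, count) records.

        With ``collapse_strands`` (default) the + and - counts at a position
        are summed into one site; otherwise each (position, strand) is its
        own site.
        """
        counts: dict = {}
        for pos, strand, count in records:
            key = pos if collapse_strands else (pos, strand)
            counts[key] = counts.get(key, 0) + count
        return cls(counts=counts, **meta)


@dataclass
class GeneSiteProfile:
    """Per-gene view of insertion sites: ordered (position, count) pairs."""

    gene_id: str
    sites: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sites = sorted(self.sites)

    @property
    def unique_insertions(self) -> int:
        """Number of distinct sites carrying at least one read."""
        return sum(1 for _, c in self.sites if c >= 1)

    @property
    def gene_total(self) -> float:
        total = sum(c for _, c in self.sites)
        return int(total) if float(total).is_integer() else total

    def site_counts(self) -> dict[int, float]:
        return dict(self.sites)


def assign_sites_to_genes(
    table: InsertionCountTable,
    annotation: GenomeAnnotation,
    *,
    edge_trim: float = 0.0,
) -> dict[str, GeneSiteProfile]:
    """Assign each insertion site to the gene(s) whose span contains it.

    A site at position p belongs to gene g iff g.start <= p <= g.end
    (closed interval); insertion strand is ignored.  Sites inside no gene go
    to the ``INTERGENIC`` bucket; a site inside several overlapping genes is
    assigned to each of them.  Every annotated gene appears in the result,
    with an empty profile if it carries no reads.
    """
    if table.contig_id and annotation.contig_id and table.contig_id != annotation.contig_id:
        raise ValueError(
            f"contig mismatch: table {table.contig_id!r} vs "
            f"annotation {annotation.contig_id!r}"
        )
    tree = annotation.interval_tree(edge_trim=edge_trim)
    profiles: dict[str, list[tuple[int, float]]] = {g.gene_id: [] for g in annotation}
    profiles[INTERGENIC] = []
    for pos, count in sorted(table.collapsed_counts().items()):
        hits = tree[pos]
        if hits:
            for iv in hits:
                profiles[iv.data].append((pos, count))
        else:
            profiles[INTERGENIC].append((pos, count))
    return {gid: GeneSiteProfile(gid, sites) for gid, sites in profiles.items()}


def union_site_values(
    a: Mapping[int, float], b: Mapping[int, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Paired count vectors over the union of sites with a read in either map.

    Sites absent from one map contribute 0 there.  Sites with zero counts in
    both maps are dropped (they carry no evidence).
    """
    sites = sorted(p for p in set(a) | set(b) if a.get(p, 0) or b.get(p, 0))
    va = np.array([a.get(p, 0.0) for p in sites], dtype=float)
    vb = np.array([b.get(p, 0.0) for p in sites], dtype=float)
    return va, vb
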