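"""Cluster-relative annotation of scanned elements.

Places each hit relative to the gene cluster: which compartment it falls
in (flank, intergenic interval, or gene body), the nearest downstream
gene, the distance to that gene's start codon, and its orientation
relative to the cluster axis.

Conventions
-----------
Gene coordinates follow the start-codon / stop-codon convention: for a
plus-strand gene the body is ``[start_codon_pos, stop_codon_end)``; for a
minus-strand gene ``start_codon_pos`` is the assembly coordinate of the
first base of the ATG (the rightmost body base) and ``stop_codon_end`` is
one past the last stop-codon base walking in gene direction (one left of
the leftmost body base), so the body is
``[stop_codon_end + 1, start_codon_pos + 1)``.  This makes annotation of a
reverse-complemented cluster the exact mirror of the original.

The distance to a start codon counts the bases strictly between the hit's
proximal edge and the first base of the ATG, exclusive of both (a hit
abutting the codon is at distance 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .scanner import DRElementHit

__all__ = [
    "GeneModel",
    "Compartment",
    "ElementAnnotation",
    "NotUpstreamError",
    "assign_compartment",
    "distance_to_start",
    "cluster_orientation",
    "annotate_hit",
    "annotate_hits",
    "cluster_axis_strand",
]


class NotUpstreamError(ValueError):
    """The hit is not upstream of the gene's start codon."""


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    species: str
    seq_id: str
    strand: str  # strand of the gene on the assembly
    start_codon_pos: int  # 0-based, first base of ATG (assembly coordinate)
    stop_codon_end: int  # one past the last stop-codon base, in gene direction
    cluster_rank: int  # 1-based order along the cluster axis

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        if self.body_end <= self.body_start:
            raise ValueError(
                f"gene {self.gene_id!r}: empty body "
                f"[{self.body_start}, {self.body_end})"
            )

    @property
    def body_start(self) -> int:
        return self.start_codon_pos if self.strand == "+" else self.stop_codon_end + 1

    @property
    def body_end(self) -> int:
        return self.stop_codon_end if self.strand == "+" else self.start_codon_pos + 1


@dataclass(frozen=True)
class Compartment:
    """One interval of the cluster partition.

    ``kind`` is one of upstream / intergenic / intragenic / downstream;
    ``ranks`` identifies the flanking (or containing) genes by cluster
    rank, which is what corresponds across species.
    """

    kind: str
    ranks: tuple[int, ...]
    gene_ids: tuple[str, ...]
    start: int
    end: int  # assembly coordinates, half-open

    @property
    def key(self) -> tuple:
        return (self.kind,) + self.ranks

    @property
    def order_index(self) -> int:
        """Position of the compartment along the cluster axis."""
        if self.kind == "upstream":
            return 0
        if self.kind == "intragenic":
            return 2 * self.ranks[0] - 1
        if self.kind == "intergenic":
            return 2 * self.ranks[0]
        return 2 * max(self.ranks, default=0) + 100  # downstream sorts last

    def label(self) -> str:
        if self.kind in ("upstream", "downstream"):
            return f"{self.kind}-of-cluster"
        if self.kind == "intragenic":
            return f"intragenic({self.gene_ids[0]})"
        return f"intergenic({self.gene_ids[0]},{self.gene_ids[1]})"


@dataclass(frozen=True)
class ElementAnnotation:
    hit: DRElementHit
    compartment: Compartment
    nearest_downstream_gene: Optional[str]
    distance_to_start_codon: Optional[int]
    cluster_orientation: str
    normalized_position: float  # position within compartment, along the axis


def cluster_axis_strand(genes: Sequence[GeneModel]) -> str:
    """Cluster axis = strand of the rank-1 gene (tandem clusters share it)."""
    ranked = sorted(genes, key=lambda g: g.cluster_rank)
    return ranked[0].strand


def _compartments(genes: Sequence[GeneModel], seq_length: int) -> list[Compartment]:
    """Partition [0, seq_length) into flanks, gene bodies and intergenic gaps."""
    axis = cluster_axis_strand(genes)
    ranked = sorted(genes, key=lambda g: g.cluster_rank)
    by_coord = ranked if axis == "+" else list(reversed(ranked))
    parts: list[Compartment] = []
    left_kind = "upstream" if axis == "+" else "downstream"
    right_kind = "downstream" if axis == "+" else "upstream"
    parts.append(
        Compartment(left_kind, (), (), 0, by_coord[0].body_start)
    )
    for i, g in enumerate(by_coord):
        parts.append(
            Compartment("intragenic", (g.cluster_rank,), (g.gene_id,), g.body_start, g.body_end)
        )
        if i + 1 < len(by_coord):
            nxt = by_coord[i + 1]
            lo_rank_gene, hi_rank_gene = (
                (g, nxt) if g.cluster_rank < nxt.cluster_rank else (nxt, g)
            )
            parts.append(
                Compartment(
                    "intergenic",
                    (lo_rank_gene.cluster_rank, hi_rank_gene.cluster_rank),
                    (lo_rank_gene.gene_id, hi_rank_gene.gene_id),
                    g.body_end,
                    nxt.body_start,
                )
            )
    parts.append(
        Compartment(right_kind, (), (), by_coord[-1].body_end, seq_length)
    )
    return parts


def assign_compartment(
    hit: DRElementHit, genes: Sequence[GeneModel], seq_length: int
) -> Compartment:
    """Exactly one compartment per hit.

    A hit overlapping any part of a gene body is intragenic, even when the
    overlap is partial (ties broken toward the larger overlap, then the
    lower rank).  Otherwise the intergenic or flanking interval containing
    the hit's midpoint wins.
    """
    if not genes:
        raise ValueError("assign_compartment requires a non-empty gene list")
    overlaps = []
    for g in genes:
        ov = min(hit.end, g.body_end) - max(hit.start, g.body_start)
        if ov > 0:
            overlaps.append((-ov, g.cluster_rank, g))
    if overlaps:
        g = min(overlaps)[2]
        return Compartment(
            "intragenic", (g.cluster_rank,), (g.gene_id,), g.body_start, g.body_end
        )
    mid = (hit.start + hit.end) / 2
    for part in _compartments(genes, seq_length):
        if part.kind == "intragenic":
            continue
        if part.start <= mid < part.end or (
            part.end == seq_length and mid >= part.end
        ):
            return part
    # midpoint beyond the sequence end can only happen for out-of-window
    # hits; fall back to the right flank
    return _compartments(genes, seq_length)[-1]


def distance_to_start(hit: DRElementHit, gene: GeneModel) -> int:
    """Bases strictly between the hit's proximal edge and the ATG."""
    if gene.strand == "+":
        d = gene.start_codon_pos - hit.end
    else:
        d = hit.start - gene.start_codon_pos - 1
    if d < 0:
        raise NotUpstreamError(
            f"hit [{hit.start}, {hit.end}) is not upstream of the start codon "
            f"of gene {gene.gene_id!r}; assign a compartment first"
        )
    return d


def cluster_orientation(hit: DRElementHit, cluster_axis: str) -> str:
    return "+" if hit.strand == cluster_axis else "-"


def _nearest_downstream_gene(
    hit: DRElementHit, genes: Sequence[GeneModel]
) -> Optional[GeneModel]:
    """First gene (by cluster rank) whose start codon lies downstream of the
    hit along the cluster axis."""
    for g in sorted(genes, key=lambda x: x.cluster_rank):
        if g.strand == "+":
            if hit.end <= g.start_codon_pos:
                return g
        else:
            if hit.start >= g.start_codon_pos + 1:
                return g
    return None


def annotate_hit(
    hit: DRElementHit, genes: Sequence[GeneModel], seq_length: int
) -> ElementAnnotation:
    axis = cluster_axis_strand(genes)
    comp = assign_compartment(hit, genes, seq_length)
    target = _nearest_downstream_gene(hit, genes)
    dist = distance_to_start(hit, target) if target is not None else None
    mid = (hit.start + hit.end) / 2
    width = comp.end - comp.start
    if width > 0:
        frac = (mid - comp.start) / width
        frac = min(max(frac, 0.0), 1.0)
    else:
        frac = 0.5
    if axis == "-":
        frac = 1.0 - frac
    return ElementAnnotation(
        hit=hit,
        compartment=comp,
        nearest_downstream_gene=target.gene_id if target is not None else None,
        distance_to_start_codon=dist,
        cluster_orientation=cluster_orientation(hit, axis),
        normalized_position=frac,
    )


def annotate_hits(
    hits: Sequence[DRElementHit], genes: Sequence[GeneModel], seq_length: int
) -> list[ElementAnnotation]:
    return [annotate_hit(h, genes, seq_length) for h in hits]
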