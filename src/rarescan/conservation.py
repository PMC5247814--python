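"""Cross-species conservation filtering.

Two elements in different species are the "same" element when they agree
in DR class and motif sequence (at a configurable stringency) and sit at
corresponding relative positions in the cluster: same compartment by
ortholog rank, same orientation relative to the cluster axis, and
normalized intra-compartment positions within a tolerance.

The grouping is greedy and deterministic: species are processed in sorted
label order, anchor elements in cluster order, and candidate partners by
positional discrepancy then coordinate, so the result is invariant under
permutation of the input species.  A group is emitted only if every
pairwise check passes (full transitive consistency, not just a spanning
chain).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .annotation import ElementAnnotation
from .motif import DRPattern
from .scanner import DRElementHit, GenomicSequence, ScanConfig, scan_collection

__all__ = [
    "ConservationCriteria",
    "ConservedGroup",
    "elements_match",
    "find_conserved",
    "signature_search",
    "SEQUENCE_STRINGENCIES",
]

logger = logging.getLogger(__name__)

# ordered loosest -> strictest
SEQUENCE_STRINGENCIES = (
    "class-only",
    "half-sites-and-spacer-length",
    "exact-element",
)


@dataclass(frozen=True)
class ConservationCriteria:
    require_all_species: bool = True
    sequence_stringency: str = "exact-element"
    require_same_compartment: bool = True
    require_same_orientation: bool = True
    position_tolerance: float = 0.25  # fraction of compartment length

    def __post_init__(self) -> None:
        if self.sequence_stringency not in SEQUENCE_STRINGENCIES:
            raise ValueError(
                f"unknown sequence stringency {self.sequence_stringency!r}; "
                f"expected one of {SEQUENCE_STRINGENCIES}"
            )
        if not (0.0 <= self.position_tolerance <= 1.0):
            raise ValueError("position_tolerance must lie in [0, 1]")


@dataclass(frozen=True)
class ConservedGroup:
    group_id: str
    members: Mapping[str, ElementAnnotation]  # species -> annotated hit
    dr_class: str
    criteria: ConservationCriteria
    identity_level: str  # strictest stringency all member pairs satisfy


def observed_identity_level(a: ElementAnnotation, b: ElementAnnotation) -> str:
    """Strictest sequence stringency satisfied by the pair (class assumed equal)."""
    ha, hb = a.hit, b.hit
    if ha.element == hb.element:
        return "exact-element"
    if ha.half_site_1 == hb.half_site_1 and ha.half_site_2 == hb.half_site_2:
        return "half-sites-and-spacer-length"
    return "class-only"


def elements_match(
    a: ElementAnnotation, b: ElementAnnotation, criteria: ConservationCriteria
) -> bool:
    """Pairwise conservation test between annotated hits of two species."""
    if not isinstance(a, ElementAnnotation) or not isinstance(b, ElementAnnotation):
        raise TypeError(
            "elements_match expects annotated hits; run annotation first"
        )
    ha, hb = a.hit, b.hit
    if ha.species == hb.species:
        return False
    if ha.dr_class != hb.dr_class:
        return False
    level = observed_identity_level(a, b)
    if SEQUENCE_STRINGENCIES.index(level) < SEQUENCE_STRINGENCIES.index(
        criteria.sequence_stringency
    ):
        return False
    if criteria.require_same_compartment and a.compartment.key != b.compartment.key:
        return False
    if criteria.require_same_orientation and (
        a.cluster_orientation != b.cluster_orientation
    ):
        return False
    if abs(a.normalized_position - b.normalized_position) > criteria.position_tolerance:
        return False
    return True


def _anchor_sort_key(ann: ElementAnnotation) -> tuple:
    return (
        ann.compartment.order_index,
        ann.normalized_position,
        ann.hit.start,
        ann.hit.end,
        ann.hit.strand,
    )


def find_conserved(
    by_species: Mapping[str, Sequence[ElementAnnotation]],
    criteria: ConservationCriteria = ConservationCriteria(),
) -> list[ConservedGroup]:
    """Assemble maximal one-per-species groups of conserved elements.

    Greedy: the species with the smallest label anchors; its elements are
    visited in cluster order; for every other species the unused candidate
    with the smallest positional discrepancy (ties by coordinate) is
    chosen.  Each hit belongs to at most one group.
    """
    species = sorted(by_species)
    if len(species) < 2:
        raise ValueError("conservation filtering requires at least 2 species")
    if criteria.require_all_species:
        empty = [sp for sp in species if not by_species[sp]]
        if empty:
            logger.info(
                "species %s have no hits; no all-species groups possible", empty
            )
            return []
    anchor_sp, others = species[0], species[1:]
    used: set[tuple[str, int, int, str]] = set()
    groups: list[ConservedGroup] = []

    def hit_key(ann: ElementAnnotation) -> tuple[str, int, int, str]:
        h = ann.hit
        return (h.species, h.start, h.end, h.strand)

    for anchor in sorted(by_species[anchor_sp], key=_anchor_sort_key):
        if hit_key(anchor) in used:
            continue
        members = {anchor_sp: anchor}
        for sp in others:
            candidates = [
                c
                for c in by_species[sp]
                if hit_key(c) not in used and elements_match(anchor, c, criteria)
            ]
            if not candidates:
                continue
            best = min(
                candidates,
                key=lambda c: (
                    abs(c.normalized_position - anchor.normalized_position),
                    c.hit.start,
                    c.hit.end,
                    c.hit.strand,
                ),
            )
            members[sp] = best
        if criteria.require_all_species and len(members) != len(species):
            continue
        if len(members) < 2:
            continue
        member_list = list(members.values())
        ok = all(
            elements_match(member_list[i], member_list[j], criteria)
            for i in range(len(member_list))
            for j in range(i + 1, len(member_list))
        )
        if not ok:
            continue
        level = min(
            (
                observed_identity_level(member_list[i], member_list[j])
                for i in range(len(member_list))
                for j in range(i + 1, len(member_list))
            ),
            key=SEQUENCE_STRINGENCIES.index,
        )
        for ann in member_list:
            used.add(hit_key(ann))
        groups.append(
            ConservedGroup(
                group_id=f"G{len(groups) + 1:03d}",
                members=dict(sorted(members.items())),
                dr_class=anchor.hit.dr_class,
                criteria=criteria,
                identity_level=level,
            )
        )
    return groups


def signature_search(
    sequences: Sequence[GenomicSequence], signature: DRPattern
) -> list[DRElementHit]:
    """Scan for one fixed literal signature (e.g. AGTTCA + N{5} + AGTTCA)
    on both strands; same output contract as :func:`scan_collection`."""
    config = ScanConfig(patterns=(signature,), strand_mode="both")
    return scan_collection(sequences, config)
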