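"""Synthetic multi-species gene clusters with planted DR elements.

Benchmark generator emulating a three-gene tandem cluster compared across
three species: per-species i.i.d. background DNA of configurable GC, three
plus-strand gene bodies laid out along the cluster axis, a set of
conserved elements planted at corresponding relative positions in every
species, and per-species decoy elements planted in one species only.  A
ground-truth table records every planted element with realized
coordinates, so each pipeline stage can be scored without any downloads.

The default spec mirrors the study conditions the pipeline is meant for:
cluster spans of 85/56/79 kb (start codon of the first gene to the stop
codon of the last), 20 kb flanks, 16 conserved elements with class tally
13 DR5 / 1 DR2 / 2 DR3, and 5 decoys per species.

With ``clean_background`` the generator destroys every accidental
background match of the canonical pattern by resampling the background
bases inside it, so planted truth is the complete hit set.  The i.i.d.
background carries no repeats or compositional structure; the expected
accidental-hit rate under it is reported so precision expectations are
explicit when cleaning is off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, _compartments
from .motif import DRPattern, builtin_pattern, reverse_complement
from .scanner import GenomicSequence, ScanConfig, scan_sequence

__all__ = [
    "Placement",
    "PlantedElement",
    "SyntheticClusterSpec",
    "SyntheticClusterSet",
    "generate_background",
    "plant_element",
    "generate_cluster_set",
    "expected_background_hit_count",
    "DEFAULT_CONSERVED_PLAN",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# class, compartment key, normalized axis position, strand (vs cluster axis)
DEFAULT_CONSERVED_PLAN: tuple[tuple[str, tuple, float, str], ...] = (
    ("DR5", ("upstream",), 0.35, "+"),
    ("DR5", ("upstream",), 0.60, "-"),
    ("DR5", ("intragenic", 1), 0.30, "+"),
    ("DR3", ("intragenic", 1), 0.70, "+"),
    ("DR5", ("intergenic", 1, 2), 0.20, "-"),
    ("DR5", ("intergenic", 1, 2), 0.45, "+"),
    ("DR5", ("intergenic", 1, 2), 0.70, "-"),
    ("DR2", ("intergenic", 1, 2), 0.85, "+"),
    ("DR5", ("intragenic", 2), 0.50, "-"),
    ("DR5", ("intergenic", 2, 3), 0.25, "+"),
    ("DR5", ("intergenic", 2, 3), 0.50, "-"),
    ("DR5", ("intergenic", 2, 3), 0.75, "+"),
    ("DR3", ("intergenic", 2, 3), 0.90, "-"),
    ("DR5", ("intragenic", 3), 0.40, "+"),
    ("DR5", ("downstream",), 0.30, "-"),
    ("DR5", ("downstream",), 0.65, "+"),
)

_MIN_PLANT_GAP = 30  # bp between planted intervals; no scan window can bridge two


@dataclass(frozen=True)
class Placement:
    compartment: tuple  # compartment key, e.g. ("intergenic", 1, 2)
    position: float  # normalized position along the cluster axis, in [0, 1]
    strand: str  # relative to the cluster axis


@dataclass(frozen=True)
class PlantedElement:
    name: str
    dr_class: str
    sequence: str  # the element string as read 5'->3' on its own strand
    placements: Mapping[str, Placement]  # species -> placement
    conserved: bool

    def __post_init__(self) -> None:
        expected = f"DR{len(self.sequence) - 12}"
        if expected != self.dr_class:
            raise ValueError(
                f"element {self.name!r}: sequence length {len(self.sequence)} "
                f"implies {expected}, declared {self.dr_class}"
            )


@dataclass(frozen=True)
class SyntheticClusterSpec:
    species: tuple[str, ...] = ("B_floridae", "B_belcheri", "B_lanceolatum")
    cluster_spans: tuple[int, ...] = (85_000, 56_000, 79_000)
    n_genes: int = 3
    flank: int = 20_000
    gene_fraction: float = 0.15  # gene-body length as a fraction of the span
    background_gc: float = 0.4
    conserved_plan: tuple[tuple[str, tuple, float, str], ...] = DEFAULT_CONSERVED_PLAN
    n_decoys_per_species: int = 5
    clean_background: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.species) != len(self.cluster_spans):
            raise ValueError("one cluster span per species is required")
        if not (0.0 <= self.background_gc <= 1.0):
            raise ValueError("background_gc must lie in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("at least one gene is required")


@dataclass
class SyntheticClusterSet:
    spec: SyntheticClusterSpec
    sequences: dict[str, GenomicSequence]
    genes: dict[str, list[GeneModel]]
    elements: list[PlantedElement]
    truth: pd.DataFrame
    expected_background_hits: dict[str, float]


def generate_background(length: int, gc: float, seed) -> str:
    """i.i.d. background DNA: P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if length < 0:
        raise ValueError("length must be non-negative")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def plant_element(sequence: str, element: str, position: int, strand: str) -> str:
    """Overwrite ``sequence[position:position+len(element)]`` with the
    element (its reverse complement when strand is '-'); length preserved."""
    if position < 0 or position + len(element) > len(sequence):
        raise ValueError(
            f"planting window [{position}, {position + len(element)}) out of "
            f"bounds for sequence of length {len(sequence)}"
        )
    insert = element if strand == "+" else reverse_complement(element)
    return sequence[:position] + insert + sequence[position + len(element) :]


def expected_background_hit_count(pattern: DRPattern, gc: float, length: int) -> float:
    """Expected number of accidental matches of ``pattern`` on both strands
    of an i.i.d. background of the given length (edge effects ignored)."""
    base_p = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}

    def seg_p(positions) -> float:
        out = 1.0
        for s in positions:
            out *= sum(base_p[b] for b in s)
        return out

    halves = seg_p(pattern.half_site_5p.positions) * seg_p(
        pattern.half_site_3p.positions
    )
    sp = pattern.spacer
    if sp.mode == "fixed":
        per_offset = halves * seg_p(sp.positions)
    else:
        per_offset = halves * (sp.max_len - sp.min_len + 1)
    return 2.0 * per_offset * length


def _sample_from_sets(rng: np.random.Generator, positions) -> str:
    return "".join(sorted(s)[rng.integers(len(s))] for s in positions)


def _sample_element(
    rng: np.random.Generator,
    spacer_len: int,
    scan_pattern: DRPattern,
    taken: set[str],
) -> str:
    """Sample a canonical element of the given class whose bare string scans
    to exactly one full-length plus-strand hit (no internal or palindromic
    self-matches), distinct from every previously drawn element."""
    half = scan_pattern.half_site_5p.positions
    half2 = scan_pattern.half_site_3p.positions
    config = ScanConfig(patterns=(scan_pattern,), strand_mode="both")
    for _ in range(10_000):
        elem = (
            _sample_from_sets(rng, half)
            + _sample_from_sets(rng, [frozenset("ACGT")] * spacer_len)
            + _sample_from_sets(rng, half2)
        )
        if elem in taken:
            continue
        hits = scan_sequence(
            GenomicSequence(id="probe", species="probe", residues=elem), config
        )
        if (
            len(hits) == 1
            and hits[0].start == 0
            and hits[0].end == len(elem)
            and hits[0].strand == "+"
        ):
            taken.add(elem)
            return elem
    raise RuntimeError("could not sample a clean element (pattern too permissive?)")


def _gene_layout(
    species: str, seq_id: str, span: int, flank: int, n_genes: int, fraction: float
) -> list[GeneModel]:
    body_len = int(round(span * fraction))
    if n_genes == 1:
        starts = [flank]
        body_len = span
    else:
        gap = (span - n_genes * body_len) / (n_genes - 1)
        if gap <= 0:
            raise ValueError("gene_fraction too large: gene bodies would overlap")
        starts = [int(round(flank + i * (body_len + gap))) for i in range(n_genes)]
        starts[-1] = flank + span - body_len  # last stop codon ends the span
    genes = []
    for i, s in enumerate(starts):
        gene_id = f"CYP26-{i + 1}" if n_genes == 3 else f"gene_{i + 1}"
        genes.append(
            GeneModel(
                gene_id=gene_id,
                species=species,
                seq_id=seq_id,
                strand="+",
                start_codon_pos=s,
                stop_codon_end=s + body_len,
                cluster_rank=i + 1,
            )
        )
    return genes


def _resolve_position(
    comp, element_len: int, position: float
) -> int:
    width = comp.end - comp.start
    if width < element_len:
        raise ValueError(
            f"compartment {comp.key} too narrow ({width} bp) for a "
            f"{element_len} bp element"
        )
    return comp.start + int(round(position * (width - element_len)))


def _overlaps(iv: tuple[int, int], taken: Sequence[tuple[int, int]], gap: int) -> bool:
    return any(iv[0] < b + gap and a < iv[1] + gap for a, b in taken)


def generate_cluster_set(spec: SyntheticClusterSpec) -> SyntheticClusterSet:
    """Build the full benchmark: sequences, gene models, planted elements
    and the ground-truth table.  Byte-identical output per seed."""
    rng = np.random.default_rng(spec.seed)
    pattern = builtin_pattern("canonical-RARE")
    taken_seqs: set[str] = set()

    # 1. conserved elements: one sequence each, same relative placement in
    #    every species
    elements: list[PlantedElement] = []
    class_counter: dict[str, int] = {}
    for cls, comp_key, pos, strand in spec.conserved_plan:
        spacer_len = int(cls[2:])
        seq = _sample_element(rng, spacer_len, pattern, taken_seqs)
        class_counter[cls] = class_counter.get(cls, 0) + 1
        name = f"cons_{cls}_{class_counter[cls]:02d}"
        placement = Placement(compartment=comp_key, position=pos, strand=strand)
        elements.append(
            PlantedElement(
                name=name,
                dr_class=cls,
                sequence=seq,
                placements={sp: placement for sp in spec.species},
                conserved=True,
            )
        )

    # 2. per-species gene layouts and compartment maps
    genes: dict[str, list[GeneModel]] = {}
    seq_ids: dict[str, str] = {}
    comps: dict[str, list] = {}
    seq_lengths: dict[str, int] = {}
    for sp, span in zip(spec.species, spec.cluster_spans):
        seq_id = f"{sp}_cluster"
        seq_ids[sp] = seq_id
        seq_lengths[sp] = span + 2 * spec.flank
        genes[sp] = _gene_layout(
            sp, seq_id, span, spec.flank, spec.n_genes, spec.gene_fraction
        )
        comps[sp] = _compartments(genes[sp], seq_lengths[sp])

    def comp_by_key(sp: str, key: tuple):
        for c in comps[sp]:
            if c.key == key:
                return c
        raise ValueError(f"unknown compartment {key} for species {sp}")

    # 3. resolve conserved placements to absolute coordinates
    placed: dict[str, list[tuple[int, int]]] = {sp: [] for sp in spec.species}
    rows: list[dict] = []
    conflicts: list[str] = []
    start_codons = {
        sp: {g.start_codon_pos for g in genes[sp]} for sp in spec.species
    }
    for el in elements:
        for sp in spec.species:
            pl = el.placements[sp]
            comp = comp_by_key(sp, pl.compartment)
            start = _resolve_position(comp, len(el.sequence), pl.position)
            iv = (start, start + len(el.sequence))
            if _overlaps(iv, placed[sp], _MIN_PLANT_GAP):
                conflicts.append(f"{el.name} at {iv} in {sp}")
                continue
            if any(iv[0] <= c < iv[1] for c in start_codons[sp]):
                conflicts.append(f"{el.name} covers a start codon in {sp}")
                continue
            placed[sp].append(iv)
            rows.append(
                dict(
                    element=el.name,
                    conserved=True,
                    species=sp,
                    seq_id=seq_ids[sp],
                    start=iv[0],
                    end=iv[1],
                    strand=pl.strand,
                    dr_class=el.dr_class,
                    compartment="/".join(map(str, pl.compartment)),
                    sequence=el.sequence,
                )
            )
    if conflicts:
        raise ValueError("infeasible placements: " + "; ".join(conflicts))

    # 4. decoys: planted in a single species each, unique sequences
    comp_keys = [c.key for c in comps[spec.species[0]] if c.end > c.start]
    for sp in spec.species:
        for d in range(spec.n_decoys_per_species):
            spacer_len = int(rng.choice([2, 3, 5]))
            seq = _sample_element(rng, spacer_len, pattern, taken_seqs)
            for _attempt in range(200):
                key = comp_keys[rng.integers(len(comp_keys))]
                pos = float(rng.uniform(0.05, 0.95))
                strand = "+" if rng.integers(2) == 0 else "-"
                comp = comp_by_key(sp, key)
                if comp.end - comp.start < len(seq):
                    continue
                start = _resolve_position(comp, len(seq), pos)
                iv = (start, start + len(seq))
                if _overlaps(iv, placed[sp], _MIN_PLANT_GAP):
                    continue
                if any(iv[0] <= c < iv[1] for c in start_codons[sp]):
                    continue
                break
            else:
                raise ValueError(f"could not place decoy {d} in species {sp}")
            name = f"decoy_{sp}_{d + 1:02d}"
            elements.append(
                PlantedElement(
                    name=name,
                    dr_class=f"DR{spacer_len}",
                    sequence=seq,
                    placements={sp: Placement(key, pos, strand)},
                    conserved=False,
                )
            )
            placed[sp].append(iv)
            rows.append(
                dict(
                    element=name,
                    conserved=False,
                    species=sp,
                    seq_id=seq_ids[sp],
                    start=iv[0],
                    end=iv[1],
                    strand=strand,
                    dr_class=f"DR{spacer_len}",
                    compartment="/".join(map(str, key)),
                    sequence=seq,
                )
            )

    # 5. backgrounds + planting
    residues: dict[str, str] = {}
    for sp in spec.species:
        bg_seed = int(rng.integers(2**31))
        s = generate_background(seq_lengths[sp], spec.background_gc, bg_seed)
        for row in rows:
            if row["species"] == sp:
                s = plant_element(s, row["sequence"], row["start"], row["strand"])
        residues[sp] = s

    truth = pd.DataFrame(rows).sort_values(
        ["conserved", "element", "species"], ascending=[False, True, True]
    )
    truth = truth.reset_index(drop=True)

    # 6. optional cleaning: destroy accidental background matches
    if spec.clean_background:
        config = ScanConfig(patterns=(pattern,), strand_mode="both")
        truth_keys = {
            sp: {
                (r.start, r.end, r.strand)
                for r in truth[truth.species == sp].itertuples()
            }
            for sp in spec.species
        }
        planted_mask = {
            sp: sorted(
                (r.start, r.end) for r in truth[truth.species == sp].itertuples()
            )
            for sp in spec.species
        }
        p = [
            (1 - spec.background_gc) / 2,
            spec.background_gc / 2,
            spec.background_gc / 2,
            (1 - spec.background_gc) / 2,
        ]
        for sp in spec.species:
            for _round in range(100):
                gseq = GenomicSequence(
                    id=seq_ids[sp], species=sp, residues=residues[sp]
                )
                extra = [
                    h
                    for h in scan_sequence(gseq, config)
                    if (h.start, h.end, h.strand) not in truth_keys[sp]
                ]
                if not extra:
                    break
                chars = list(residues[sp])
                for h in extra:
                    for i in range(h.start, h.end):
                        if any(a <= i < b for a, b in planted_mask[sp]):
                            continue
                        chars[i] = "ACGT"[rng.choice(4, p=p)]
                residues[sp] = "".join(chars)
            else:
                raise RuntimeError(
                    f"background cleaning did not converge for species {sp}"
                )

    sequences = {
        sp: GenomicSequence(id=seq_ids[sp], species=sp, residues=residues[sp])
        for sp in spec.species
    }
    expected = {
        sp: expected_background_hit_count(
            pattern, spec.background_gc, seq_lengths[sp]
        )
        for sp in spec.species
    }
    return SyntheticClusterSet(
        spec=spec,
        sequences=sequences,
        genes=genes,
        elements=elements,
        truth=truth,
        expected_background_hits=expected,
    )
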