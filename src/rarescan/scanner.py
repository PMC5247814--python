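"""Exhaustive direct-repeat element scanning.

Enumerates every (offset, spacer length, strand) combination matching a
:class:`~rarescan.motif.DRPattern` on a genomic sequence.  All matches are
reported, including overlapping, nested, and shared-half-site matches (one
upstream half-site can pair with several downstream half-sites at
different spacings); downstream stages may filter.

Minus-strand elements are detected by matching the reverse-complemented
pattern on the plus strand; coordinates are always reported on the plus
strand, 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .motif import (
    AlphabetError,
    DRPattern,
    PatternError,
    reverse_complement,
    reverse_complement_pattern,
)

__all__ = [
    "GenomicSequence",
    "ScanConfig",
    "DRElementHit",
    "scan_sequence",
    "scan_collection",
    "cluster_window",
]

_SEQ_RE = re.compile(r"^[ACGTNacgtn]*$")

# base -> code; N gets its own code so constrained positions can reject it
_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in _CODES.items():
    _CODE_LUT[ord(_b)] = _c
    _CODE_LUT[ord(_b.lower())] = _c


@dataclass(frozen=True)
class GenomicSequence:
    """One input sequence with species provenance."""

    id: str
    species: str
    residues: str

    def __post_init__(self) -> None:
        if not _SEQ_RE.match(self.residues):
            bad = re.search(r"[^ACGTNacgtn]", self.residues)
            raise AlphabetError(
                f"sequence {self.id!r}: non-nucleotide character "
                f"{bad.group()!r} at position {bad.start()}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ScanConfig:
    """Scan settings.

    ``masked_policy``: ``"match"`` treats soft-masked (lowercase) residues
    like uppercase; ``"skip"`` rejects any window containing a masked base.
    ``window`` restricts hits to a half-open interval on the sequence.
    """

    patterns: tuple[DRPattern, ...]
    strand_mode: str = "both"  # "plus" | "both"
    masked_policy: str = "match"  # "match" | "skip"
    window: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.patterns:
            raise PatternError("ScanConfig requires at least one pattern")
        if self.strand_mode not in ("plus", "both"):
            raise PatternError(f"unknown strand_mode {self.strand_mode!r}")
        if self.masked_policy not in ("match", "skip"):
            raise PatternError(f"unknown masked_policy {self.masked_policy!r}")


@dataclass(frozen=True)
class DRElementHit:
    """One matched direct-repeat element.

    Coordinates are 0-based half-open on the plus strand of the source
    sequence.  ``half_site_1``, ``spacer`` and ``half_site_2`` are read
    5'->3' on the matching strand, so their concatenation equals the
    genomic substring when ``strand == '+'`` and its reverse complement
    when ``strand == '-'``.
    """

    sequence_id: str
    species: str
    start: int
    end: int
    strand: str
    half_site_1: str
    spacer: str
    half_site_2: str
    pattern_name: str
    validated: Optional[bool] = None

    @property
    def spacer_length(self) -> int:
        return len(self.spacer)

    @property
    def dr_class(self) -> str:
        return f"DR{self.spacer_length}"

    @property
    def element(self) -> str:
        return self.half_site_1 + self.spacer + self.half_site_2

    def reconstructs(self, residues: str) -> bool:
        sub = residues[self.start : self.end].upper()
        if self.strand == "-":
            sub = reverse_complement(sub)
        return sub == self.element


def _encode(residues: str) -> tuple[np.ndarray, np.ndarray]:
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    codes = _CODE_LUT[raw]
    masked = (raw >= ord("a")) & (raw <= ord("z"))
    return codes, masked


def _segment_match(
    codes: np.ndarray,
    masked: np.ndarray,
    positions: Sequence[frozenset[str]],
    skip_masked: bool,
) -> np.ndarray:
    """Boolean vector: does the segment pattern match at each offset?"""
    L, m = len(codes), len(positions)
    n = L - m + 1
    if n <= 0:
        return np.zeros(0, dtype=bool)
    ok = np.ones(n, dtype=bool)
    for j, allowed in enumerate(positions):
        lut = np.zeros(5, dtype=bool)
        for b in allowed:
            lut[_CODES[b]] = True
        lut[4] = len(allowed) == 4  # genomic N only matches fully degenerate
        ok &= lut[codes[j : j + n]]
        if skip_masked:
            ok &= ~masked[j : j + n]
    return ok


def _pattern_matches(
    codes: np.ndarray, masked: np.ndarray, pattern: DRPattern, skip_masked: bool
) -> Iterable[tuple[int, int]]:
    """Yield (offset, total_length) for every match of the pattern."""
    L = len(codes)
    sp = pattern.spacer
    if sp.mode == "fixed":
        sets = (
            pattern.half_site_5p.positions + sp.positions + pattern.half_site_3p.positions
        )
        hit = _segment_match(codes, masked, sets, skip_masked)
        tl = len(sets)
        for o in np.nonzero(hit)[0]:
            yield int(o), tl
        return
    h1 = _segment_match(codes, masked, pattern.half_site_5p.positions, skip_masked)
    h2 = _segment_match(codes, masked, pattern.half_site_3p.positions, skip_masked)
    cum_masked = np.concatenate(([0], np.cumsum(masked))) if skip_masked else None
    for s in range(sp.min_len, sp.max_len + 1):
        tl = 12 + s
        n = L - tl + 1
        if n <= 0:
            continue
        ok = h1[:n] & h2[6 + s : 6 + s + n]
        if skip_masked and s > 0:
            spacer_masked = (
                cum_masked[6 + s : 6 + s + n] - cum_masked[6 : 6 + n]
            ) > 0
            ok &= ~spacer_masked
        for o in np.nonzero(ok)[0]:
            yield int(o), tl


def scan_sequence(seq: GenomicSequence, config: ScanConfig) -> list[DRElementHit]:
    """Enumerate every element matching the configured patterns.

    Returns all position/spacer-length/strand combinations, deduplicated on
    (start, end, strand, pattern name) and sorted by (start, end, strand).
    A plus and a minus hit at the same locus are both reported only when
    their read-out element strings differ (a perfect palindrome is one
    element, reported once on the plus strand).
    """
    L = len(seq)
    w0, w1 = config.window if config.window is not None else (0, L)
    if not (0 <= w0 <= w1 <= L):
        raise ValueError(
            f"window [{w0}, {w1}) out of bounds for sequence {seq.id!r} of length {L}"
        )
    sub = seq.residues[w0:w1]
    codes, masked = _encode(sub)
    skip = config.masked_policy == "skip"

    found: dict[tuple[int, int, str, str], DRElementHit] = {}
    for pattern in config.patterns:
        strands = [("+", pattern)]
        if config.strand_mode == "both":
            strands.append(("-", reverse_complement_pattern(pattern)))
        for strand, pat in strands:
            for off, tl in _pattern_matches(codes, masked, pat, skip):
                start, end = w0 + off, w0 + off + tl
                piece = seq.residues[start:end].upper()
                element = piece if strand == "+" else reverse_complement(piece)
                key = (start, end, strand, pattern.name)
                if key in found:
                    continue
                plus_key = (start, end, "+", pattern.name)
                if (
                    strand == "-"
                    and plus_key in found
                    and found[plus_key].element == element
                ):
                    continue  # palindromic self-overlap: one element
                found[key] = DRElementHit(
                    sequence_id=seq.id,
                    species=seq.species,
                    start=start,
                    end=end,
                    strand=strand,
                    half_site_1=element[:6],
                    spacer=element[6:-6],
                    half_site_2=element[-6:],
                    pattern_name=pattern.name,
                )
    return sorted(found.values(), key=lambda h: (h.start, h.end, h.strand, h.pattern_name))


def scan_collection(
    sequences: Sequence[GenomicSequence], config: ScanConfig
) -> list[DRElementHit]:
    """Scan every sequence; provenance kept, ordering stable.

    Hits are ordered by (species, sequence_id, start, end, strand).
    """
    seen: set[tuple[str, str]] = set()
    for s in sequences:
        key = (s.species, s.id)
        if key in seen:
            raise ValueError(f"duplicate sequence id {s.id!r} for species {s.species!r}")
        seen.add(key)
    hits: list[DRElementHit] = []
    for s in sorted(sequences, key=lambda x: (x.species, x.id)):
        hits.extend(scan_sequence(s, config))
    return hits


def cluster_window(
    genes: Sequence["GeneModel"], up: int, down: int, seq_length: int
) -> tuple[int, int]:
    """Survey window around a gene cluster.

    Spans from ``up`` bp upstream of the first gene's start codon to
    ``down`` bp downstream of the last gene's stop codon ("first"/"last"
    by cluster rank, along the cluster axis), clipped to the sequence.
    Default survey settings use up = down = 20 000 bp.
    """
    if not genes:
        raise ValueError("cluster_window requires a non-empty gene list")
    ranked = sorted(genes, key=lambda g: g.cluster_rank)
    first, last = ranked[0], ranked[-1]
    if first.strand == "+":
        lo = first.start_codon_pos - up
        hi = last.stop_codon_end + down
    else:
        # cluster axis on the minus strand: upstream flank is at high coords
        lo = last.body_start - down
        hi = first.start_codon_pos + 1 + up
    return (max(0, lo), min(seq_length, hi))
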