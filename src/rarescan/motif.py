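"""Degenerate direct-repeat motif grammar.

A nuclear-receptor direct-repeat (DR) response element is two hexameric
half-sites separated by a short spacer; the spacer length defines the DR
class (DR1, DR2, DR5 are the classical retinoic-acid response elements).
This module defines the pattern types -- half-site, spacer, full DR
pattern -- parses them from IUPAC degenerate strings, and provides the
nucleotide-level matching primitives used by every other stage.

Matching is exact set-membership: a genomic residue matches a pattern
position iff it belongs to that position's allowed-nucleotide set.  There
is no position-weight-matrix scoring and no mismatch budget.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "HalfSitePattern",
    "SpacerSpec",
    "DRPattern",
    "PatternError",
    "AlphabetError",
    "parse_iupac_pattern",
    "parse_half_site",
    "half_site_matches",
    "reverse_complement",
    "sets_to_iupac",
    "iupac_to_sets",
    "reverse_complement_pattern",
    "builtin_pattern",
    "BUILTIN_PATTERNS",
]

# 15-letter IUPAC nucleotide alphabet (gap letter excluded).
IUPAC_TO_SET: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

SET_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_SET.items()}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_FULL_SET = frozenset("ACGT")

MAX_SPACER = 15  # hard clamp on configurable spacer length, bounds scan cost


class PatternError(ValueError):
    """Raised for malformed pattern specifications."""


class AlphabetError(ValueError):
    """Raised when a sequence contains a non-nucleotide character."""


@dataclass(frozen=True)
class HalfSitePattern:
    """A hexameric half-site: six ordered allowed-nucleotide sets."""

    name: str
    positions: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.positions) != 6:
            raise PatternError(
                f"half-site {self.name!r} must have exactly 6 positions, "
                f"got {len(self.positions)}"
            )
        for i, s in enumerate(self.positions):
            if not s:
                raise PatternError(f"half-site {self.name!r} position {i} is empty")

    @property
    def iupac(self) -> str:
        return sets_to_iupac(self.positions)


@dataclass(frozen=True)
class SpacerSpec:
    """Spacer between the two half-sites.

    ``variable`` mode matches any bases over a length range (the canonical
    (N)0-9 spacer); ``fixed`` mode constrains each spacer position to a
    nucleotide set (used for derived signatures such as NNNRV).
    """

    mode: str  # "variable" | "fixed"
    min_len: int = 0
    max_len: int = 0
    positions: tuple[frozenset[str], ...] = ()

    def __post_init__(self) -> None:
        if self.mode == "variable":
            if not (0 <= self.min_len <= self.max_len <= MAX_SPACER):
                raise PatternError(
                    f"variable spacer bounds must satisfy 0 <= min <= max <= "
                    f"{MAX_SPACER}, got [{self.min_len}, {self.max_len}]"
                )
        elif self.mode == "fixed":
            if len(self.positions) > MAX_SPACER:
                raise PatternError(
                    f"fixed spacer longer than {MAX_SPACER} nt: {len(self.positions)}"
                )
            for i, s in enumerate(self.positions):
                if not s:
                    raise PatternError(f"fixed spacer position {i} is empty")
            object.__setattr__(self, "min_len", len(self.positions))
            object.__setattr__(self, "max_len", len(self.positions))
        else:
            raise PatternError(f"unknown spacer mode {self.mode!r}")

    @property
    def iupac(self) -> str:
        if self.mode == "fixed":
            return sets_to_iupac(self.positions)
        if self.min_len == self.max_len:
            return f"N{{{self.min_len}}}"
        return f"N{{{self.min_len},{self.max_len}}}"


@dataclass(frozen=True)
class DRPattern:
    """Full direct-repeat pattern: 5' half-site + spacer + 3' half-site."""

    name: str
    half_site_5p: HalfSitePattern
    spacer: SpacerSpec
    half_site_3p: HalfSitePattern

    @property
    def min_length(self) -> int:
        return 12 + self.spacer.min_len

    @property
    def max_length(self) -> int:
        return 12 + self.spacer.max_len

    def describe(self) -> str:
        return (
            f"{self.half_site_5p.iupac}+{self.spacer.iupac}+{self.half_site_3p.iupac}"
        )


def iupac_to_sets(s: str, *, context: str = "pattern") -> tuple[frozenset[str], ...]:
    """Expand an IUPAC string into per-position nucleotide sets."""
    out = []
    for i, ch in enumerate(s.upper()):
        try:
            out.append(IUPAC_TO_SET[ch])
        except KeyError:
            raise PatternError(
                f"invalid IUPAC character {ch!r} at position {i} in {context} {s!r}"
            ) from None
    return tuple(out)


def sets_to_iupac(positions: Sequence[Iterable[str]]) -> str:
    """Serialize per-position nucleotide sets to an IUPAC string.

    Inverse of :func:`iupac_to_sets`; round-trips for every IUPAC letter.
    """
    letters = []
    for i, s in enumerate(positions):
        fs = frozenset(s)
        if not fs:
            raise PatternError(f"empty nucleotide set at position {i}")
        try:
            letters.append(SET_TO_IUPAC[fs])
        except KeyError:
            raise PatternError(
                f"set {sorted(fs)} at position {i} is not a nucleotide subset"
            ) from None
    return "".join(letters)


def parse_half_site(iupac: str, name: str = "half-site") -> HalfSitePattern:
    if len(iupac) != 6:
        raise PatternError(
            f"half-site {iupac!r} must be 6 characters long, got {len(iupac)}"
        )
    return HalfSitePattern(name=name, positions=iupac_to_sets(iupac, context=name))


_VARIABLE_SPACER_RE = re.compile(r"^N\{(\d+)(?:,(\d+))?\}$")


def parse_spacer(expr: str) -> SpacerSpec:
    """Parse a spacer expression: ``N{a,b}``, ``N{k}`` or a fixed IUPAC string."""
    m = _VARIABLE_SPACER_RE.match(expr)
    if m:
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) is not None else lo
        if not (0 <= lo <= hi <= 9):
            raise PatternError(
                f"spacer range bounds must satisfy 0 <= a <= b <= 9, got {expr!r}"
            )
        return SpacerSpec(mode="variable", min_len=lo, max_len=hi)
    if len(expr) > 9:
        raise PatternError(f"fixed spacer {expr!r} longer than 9 nt")
    return SpacerSpec(mode="fixed", positions=iupac_to_sets(expr, context="spacer"))


def parse_iupac_pattern(
    half1: str, spacer: str, half2: str, name: str = "DR-pattern"
) -> DRPattern:
    """Build a :class:`DRPattern` from IUPAC half-site strings and a spacer
    expression.

    >>> p = parse_iupac_pattern("RGKTCA", "N{0,9}", "RGKTCA")
    >>> p.half_site_5p.positions[0] == frozenset("AG")
    True
    """
    return DRPattern(
        name=name,
        half_site_5p=parse_half_site(half1, name=f"{name}/5p"),
        spacer=parse_spacer(spacer),
        half_site_3p=parse_half_site(half2, name=f"{name}/3p"),
    )


def residue_matches(residue: str, allowed: frozenset[str]) -> bool:
    """Set-membership test for one genomic residue.

    A genomic ``N`` is an unknown base: it satisfies only a fully
    degenerate position (conservative policy; avoids phantom elements in
    gappy assemblies).
    """
    r = residue.upper()
    if r == "N":
        return allowed == _FULL_SET
    return r in allowed


def half_site_matches(sequence: str, offset: int, pattern: HalfSitePattern) -> bool:
    """True iff the six residues at ``offset`` all satisfy the half-site."""
    if offset < 0 or offset + 6 > len(sequence):
        raise IndexError(
            f"half-site window [{offset}, {offset + 6}) out of bounds for "
            f"sequence of length {len(sequence)}"
        )
    return all(
        residue_matches(sequence[offset + j], pattern.positions[j]) for j in range(6)
    )


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}; case preserved."""
    bad = re.search(r"[^ACGTNacgtn]", sequence)
    if bad:
        raise AlphabetError(
            f"non-nucleotide character {bad.group()!r} at position {bad.start()}"
        )
    return sequence.translate(_RC_TABLE)[::-1]


def _complement_sets(positions: Sequence[frozenset[str]]) -> tuple[frozenset[str], ...]:
    return tuple(
        frozenset(_COMPLEMENT[b] for b in s) for s in reversed(list(positions))
    )


def reverse_complement_pattern(pattern: DRPattern) -> DRPattern:
    """The pattern matched on the plus strand by a minus-strand element."""
    spacer = pattern.spacer
    if spacer.mode == "fixed":
        rc_spacer = SpacerSpec(mode="fixed", positions=_complement_sets(spacer.positions))
    else:
        rc_spacer = spacer
    return DRPattern(
        name=pattern.name,
        half_site_5p=HalfSitePattern(
            name=pattern.half_site_3p.name,
            positions=_complement_sets(pattern.half_site_3p.positions),
        ),
        spacer=rc_spacer,
        half_site_3p=HalfSitePattern(
            name=pattern.half_site_5p.name,
            positions=_complement_sets(pattern.half_site_5p.positions),
        ),
    )


# Built-in patterns.
#
# "canonical-RARE" is the classical vertebrate consensus: the hexamer
# (A/G)G(G/T)TCA repeated with a fully degenerate 0-9 nt spacer.  It is the
# default scan pattern.
#
# "amphioxus-validated-DR5" is the degenerate signature summarising the
# in-vitro validated amphioxus DR5 elements -- half-site-1 (A/G)G(G/T)T(C/G)A,
# fixed spacer NNN(A/G)(A/C/G), half-site-2 (A/G)G(G/T)(T/A)CA.  It is a
# derived summary of validated hits, not the default scan input.
BUILTIN_PATTERNS: dict[str, DRPattern] = {
    "canonical-RARE": parse_iupac_pattern(
        "RGKTCA", "N{0,9}", "RGKTCA", name="canonical-RARE"
    ),
    "amphioxus-validated-DR5": parse_iupac_pattern(
        "RGKTSA", "NNNRV", "RGKWCA", name="amphioxus-validated-DR5"
    ),
}


def builtin_pattern(name: str) -> DRPattern:
    try:
        return BUILTIN_PATTERNS[name]
    except KeyError:
        raise PatternError(
            f"unknown built-in pattern {name!r}; available: "
            f"{sorted(BUILTIN_PATTERNS)}"
        ) from None
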