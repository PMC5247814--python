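"""Degenerate consensus and information content from aligned sites.

Direct-repeat elements of one spacer class are fixed-structure and hence
pre-aligned (6 + spacer + 6); a degenerate IUPAC consensus therefore
follows from per-position nucleotide counting, with no motif-discovery
step.  Position j includes nucleotide x iff its frequency exceeds the
threshold theta; theta = 0 gives the union consensus, which by
construction matches every training site.

Information content per column is the usual logo quantity
IC_j = 2 + sum_x p(x,j) log2 p(x,j), in bits, from (optionally
pseudocount-smoothed) frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .motif import residue_matches, sets_to_iupac

__all__ = [
    "ConsensusModel",
    "build_consensus",
    "information_content",
    "consensus_matches_site",
    "consensus_by_class",
]

_ALPHABET = "ACGT"
_INDEX = {b: i for i, b in enumerate(_ALPHABET)}


@dataclass(frozen=True)
class ConsensusModel:
    counts: np.ndarray  # 4 x L, rows in ACGT order
    n_sites: int
    theta: float
    iupac: str
    position_sets: tuple[frozenset, ...]

    @property
    def site_length(self) -> int:
        return self.counts.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_sites


def build_consensus(sites: Sequence[str], theta: float = 0.0) -> ConsensusModel:
    """Count-based degenerate consensus over equal-length aligned sites.

    A nucleotide enters a position's set iff its frequency strictly
    exceeds ``theta``.  If ``theta`` is so high that no nucleotide
    qualifies at some position, the set falls back to the maximal-count
    nucleotides there (so the set is never empty, and raising theta still
    never enlarges any set).
    """
    if not sites:
        raise ValueError("build_consensus requires at least one site")
    if not (0.0 <= theta < 1.0):
        raise ValueError(f"theta must lie in [0, 1), got {theta}")
    L = len(sites[0])
    for s in sites:
        if len(s) != L:
            raise ValueError(
                f"ragged site lengths: expected {L}, got {len(s)} for {s!r}"
            )
    counts = np.zeros((4, L), dtype=np.int64)
    for s in sites:
        su = s.upper()
        for j, ch in enumerate(su):
            try:
                counts[_INDEX[ch], j] += 1
            except KeyError:
                raise ValueError(
                    f"site {s!r}: non-ACGT character {ch!r} at position {j}"
                ) from None
    n = len(sites)
    sets = []
    for j in range(L):
        freqs = counts[:, j] / n
        included = frozenset(_ALPHABET[i] for i in range(4) if freqs[i] > theta)
        if not included:
            top = counts[:, j].max()
            included = frozenset(_ALPHABET[i] for i in range(4) if counts[i, j] == top)
        sets.append(included)
    return ConsensusModel(
        counts=counts,
        n_sites=n,
        theta=theta,
        iupac=sets_to_iupac(sets),
        position_sets=tuple(sets),
    )


def information_content(model: ConsensusModel, pseudocount: float = 0.0) -> np.ndarray:
    """Per-position information content in bits, in [0, 2].

    Frequencies are smoothed as (count + pseudocount) / (n + 4*pseudocount).
    The default pseudocount of 0 reports the raw small-sample IC.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    p = (model.counts + pseudocount) / (model.n_sites + 4 * pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    ic = 2.0 + plogp.sum(axis=0)
    return np.clip(ic, 0.0, 2.0)


def consensus_matches_site(model: ConsensusModel, site: str) -> bool:
    """True iff each residue belongs to the position's consensus set."""
    if len(site) != model.site_length:
        raise ValueError(
            f"site length {len(site)} != consensus length {model.site_length}"
        )
    return all(
        residue_matches(site[j], model.position_sets[j])
        for j in range(model.site_length)
    )


def consensus_by_class(
    sites_by_class: Mapping[str, Sequence[str]], theta: float = 0.0
) -> dict[str, ConsensusModel]:
    """One consensus per DR class.

    Sites of different spacer lengths are not column-aligned, so they are
    summarised separately, keyed by class label (e.g. ``"DR5"``).
    """
    return {
        cls: build_consensus(list(sites), theta=theta)
        for cls, sites in sorted(sites_by_class.items())
        if sites
    }
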