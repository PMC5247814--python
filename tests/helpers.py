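"""Independent oracles and input transforms shared by the tests.

The scan oracle here is deliberately naive: it enumerates every
(offset, spacer length, strand) triple and tests residues one by one.
It shares no code path with the package's vectorized scanner.
"""

from __future__ import annotations

from rarescan.annotation import GeneModel
from rarescan.scanner import GenomicSequence

IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_rc(s: str) -> str:
    return "".join(_RC[c] for c in reversed(s.upper()))


def _residue_ok(residue: str, allowed: str) -> bool:
    if residue == "N":
        return len(allowed) == 4
    return residue in allowed


def _half_ok(seq: str, half: str) -> list[bool]:
    """Per-offset half-site membership, by per-residue check."""
    L = len(seq)
    out = []
    for o in range(L - 5):
        ok = True
        for j, ch in enumerate(half):
            if not _residue_ok(seq[o + j], IUPAC_EXPAND[ch]):
                ok = False
                break
        out.append(ok)
    return out


def oracle_scan(
    residues: str,
    half1: str = "RGKTCA",
    half2: str = "RGKTCA",
    smin: int = 0,
    smax: int = 9,
    both_strands: bool = True,
    window: tuple[int, int] | None = None,
) -> set[tuple[int, int, str]]:
    """Brute-force hit set {(start, end, strand)} on plus-strand coordinates:
    every (offset, spacer, strand) triple is tested."""
    seq = residues.upper()
    if window is not None:
        w0, w1 = window
        seq = seq[w0:w1]
    else:
        w0 = 0
    L = len(seq)
    hits: set[tuple[int, int, str]] = set()
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        s = seq if strand == "+" else naive_rc(seq)
        h1 = _half_ok(s, half1)
        h2 = _half_ok(s, half1) if half2 == half1 else _half_ok(s, half2)
        for spacer in range(smin, smax + 1):
            tl = 12 + spacer
            for o in range(L - tl + 1):
                if h1[o] and h2[o + 6 + spacer]:
                    if strand == "+":
                        hits.add((w0 + o, w0 + o + tl, "+"))
                    else:
                        hits.add((w0 + L - (o + tl), w0 + L - o, "-"))
    return hits


def hit_keys(hits) -> set[tuple[int, int, str]]:
    return {(h.start, h.end, h.strand) for h in hits}


def reflect_sequence(seq: GenomicSequence) -> GenomicSequence:
    from rarescan.motif import reverse_complement

    return GenomicSequence(
        id=seq.id, species=seq.species, residues=reverse_complement(seq.residues)
    )


def reflect_gene(g: GeneModel, L: int) -> GeneModel:
    """Mirror a gene under the coordinate map x -> L - 1 - x, flipping strand."""
    return GeneModel(
        gene_id=g.gene_id,
        species=g.species,
        seq_id=g.seq_id,
        strand="-" if g.strand == "+" else "+",
        start_codon_pos=L - 1 - g.start_codon_pos,
        stop_codon_end=L - 1 - g.stop_codon_end,
        cluster_rank=g.cluster_rank,
    )


# Printed cross-taxa element sequences: (label, sequence, DR class).
TABLE1_ELEMENTS = [
    ("S_purpuratus", "AGTTCAATAGTTCA", "DR2"),
    ("S_kowalevskii", "AGTTCATACCCAGTTCA", "DR5"),
    ("B_floridae_DR5-6", "AGTTCAACAAAAGTTCA", "DR5"),
    ("B_belcheri_DR5-6", "AGTTCAACAAAAGTTCA", "DR5"),
    ("B_lanceolatum_DR5-6", "AGTTCAACAAAAGTTCA", "DR5"),
    ("H_sapiens_R1", "AGTTCACCCAAAGTTCA", "DR5"),
    ("M_musculus_R1", "AGTTCACCCAAAGTTCA", "DR5"),
    ("D_rerio_R1", "AGTTCACACAAAGTTCA", "DR5"),
    ("D_rerio_R2", "AGTTCAAGGATAGTTCA", "DR5"),
    ("T_rubripes_R1", "AGTTCATTCAAAGTTCA", "DR5"),
]
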