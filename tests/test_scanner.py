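import numpy as np
import pytest
from hypothesis import given, strategies as st

from rarescan.annotation import GeneModel
from rarescan.motif import (
    AlphabetError,
    PatternError,
    builtin_pattern,
    parse_iupac_pattern,
    reverse_complement,
)
from rarescan.scanner import (
    DRElementHit,
    GenomicSequence,
    ScanConfig,
    cluster_window,
    scan_collection,
    scan_sequence,
)

from helpers import hit_keys, oracle_scan

CANONICAL = builtin_pattern("canonical-RARE")


def canonical_config(**kw):
    return ScanConfig(patterns=(CANONICAL,), **kw)


def seq(residues, sid="s", species="sp"):
    return GenomicSequence(id=sid, species=species, residues=residues)


def random_seq(rng, length, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


class TestScanSequenceExamples:
    def test_single_dr5_element(self):
        hits = scan_sequence(seq("AGTTCAACAAAAGTTCA"), canonical_config())
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (0, 17, "+")
        assert (h.half_site_1, h.spacer, h.half_site_2) == ("AGTTCA", "ACAAA", "AGTTCA")
        assert h.dr_class == "DR5"

    def test_single_dr2_element(self):
        hits = scan_sequence(seq("AGTTCAATAGTTCA"), canonical_config())
        assert len(hits) == 1
        assert hits[0].spacer == "AT"
        assert hits[0].dr_class == "DR2"

    def test_no_half_site_no_hits(self):
        assert scan_sequence(seq("A" * 20), canonical_config()) == []

    def test_overlapping_and_nested_matches_all_reported(self):
        # three half-sites in a row: two DR0 pairings plus one nested DR6
        hits = scan_sequence(seq("AGTTCAAGTTCAAGTTCA"), canonical_config())
        assert hit_keys(hits) == {(0, 12, "+"), (6, 18, "+"), (0, 18, "+")}
        assert hit_keys(hits) == oracle_scan("AGTTCAAGTTCAAGTTCA")

    def test_minus_strand_element(self):
        s = reverse_complement("AGTTCAACAAAAGTTCA")
        hits = scan_sequence(seq(s), canonical_config())
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (0, 17, "-")
        assert h.element == "AGTTCAACAAAAGTTCA"

    def test_hits_sorted_and_deduplicated(self):
        hits = scan_sequence(seq("AGTTCAAGTTCAAGTTCA"), canonical_config())
        keys = [(h.start, h.end, h.strand, h.pattern_name) for h in hits]
        assert keys == sorted(keys)
        assert len(keys) == len(set(keys))


class TestScanErrors:
    def test_alphabet_error(self):
        with pytest.raises(AlphabetError):
            seq("ACGU")

    def test_empty_pattern_list_config_error(self):
        with pytest.raises(PatternError):
            ScanConfig(patterns=())

    def test_window_out_of_bounds(self):
        with pytest.raises(ValueError, match="window"):
            scan_sequence(seq("ACGT" * 10), canonical_config(window=(0, 100)))


class TestOracleEquivalence:
    @pytest.mark.parametrize("gc", [0.3, 0.5, 0.7])
    def test_random_sequences_match_brute_force(self, gc):
        rng = np.random.default_rng(hash(gc) % 2**31)
        for _ in range(15):
            s = random_seq(rng, 2000, gc)
            got = hit_keys(scan_sequence(seq(s), canonical_config()))
            assert got == oracle_scan(s)

    def test_sequence_with_ambiguous_bases(self):
        rng = np.random.default_rng(7)
        base = list(random_seq(rng, 1500, 0.5))
        for i in rng.choice(len(base), size=30, replace=False):
            base[i] = "N"
        s = "".join(base)
        assert hit_keys(scan_sequence(seq(s), canonical_config())) == oracle_scan(s)

    def test_fixed_spacer_pattern_matches_oracle(self):
        extended = parse_iupac_pattern("RGKTSA", "NNNRV", "RGKWCA", name="ext")
        rng = np.random.default_rng(13)
        s = random_seq(rng, 4000, 0.5)
        got = hit_keys(scan_sequence(seq(s), ScanConfig(patterns=(extended,))))
        # oracle: treat the 5-nt spacer constraint by filtering spacer residues
        expected = set()
        for start, end, strand in oracle_scan(s, "RGKTSA", "RGKWCA", 5, 5):
            piece = s[start:end] if strand == "+" else reverse_complement(s[start:end])
            spacer = piece[6:11]
            if spacer[3] in "AG" and spacer[4] in "ACG":
                expected.add((start, end, strand))
        assert got == expected


class TestScanInvariants:
    def test_strand_symmetry(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            s = random_seq(rng, 1500, 0.5)
            L = len(s)
            fwd = scan_sequence(seq(s), canonical_config())
            rev = scan_sequence(seq(reverse_complement(s)), canonical_config())
            minus = {(h.start, h.end) for h in fwd if h.strand == "-"}
            mapped = {(L - h.end, L - h.start) for h in rev if h.strand == "+"}
            assert minus == mapped

    def test_every_hit_reconstructs_from_the_genome(self):
        rng = np.random.default_rng(5)
        s = list(random_seq(rng, 5000, 0.6))
        for pos, elem in [(100, "AGTTCAACAAAAGTTCA"), (900, "GGGTCAATGGTTCA"),
                          (2000, reverse_complement("AGTTCATTCAAAGTTCA"))]:
            s[pos : pos + len(elem)] = elem
        s = "".join(s)
        hits = scan_sequence(seq(s), canonical_config())
        assert len(hits) >= 3
        assert all(h.reconstructs(s) for h in hits)
        assert all(h.end - h.start == 12 + h.spacer_length for h in hits)
        assert all(h.dr_class == f"DR{h.spacer_length}" for h in hits)

    def test_spacer_range_monotonicity(self):
        rng = np.random.default_rng(21)
        s = random_seq(rng, 3000, 0.5)
        narrow = parse_iupac_pattern("RGKTCA", "N{2,5}", "RGKTCA", name="c")
        wide = parse_iupac_pattern("RGKTCA", "N{0,9}", "RGKTCA", name="c")
        got_narrow = hit_keys(scan_sequence(seq(s), ScanConfig(patterns=(narrow,))))
        got_wide = hit_keys(scan_sequence(seq(s), ScanConfig(patterns=(wide,))))
        assert got_narrow <= got_wide

    def test_window_restriction_monotonicity(self):
        rng = np.random.default_rng(22)
        s = random_seq(rng, 3000, 0.5)
        full = hit_keys(scan_sequence(seq(s), canonical_config()))
        windowed = hit_keys(scan_sequence(seq(s), canonical_config(window=(500, 2500))))
        assert windowed <= full
        assert windowed == {(a, b, st_) for a, b, st_ in full if 500 <= a and b <= 2500}

    def test_masked_skip_policy(self):
        s = "t" * 10 + "agttcaacaaaagttca".upper() + "t" * 10
        soft = s[:15].lower() + s[15:]  # mask part of the element
        assert len(scan_sequence(seq(soft), canonical_config(masked_policy="match"))) == 1
        assert scan_sequence(seq(soft), canonical_config(masked_policy="skip")) == []


class TestScanCollection:
    def test_provenance_and_order(self):
        s1 = seq("AGTTCAACAAAAGTTCA", sid="c1", species="spB")
        s2 = seq("TTTTTAGTTCAATAGTTCATTT", sid="c2", species="spA")
        hits = scan_collection([s1, s2], canonical_config())
        assert [(h.species, h.sequence_id) for h in hits] == [("spA", "c2"), ("spB", "c1")]

    def test_empty_collection(self):
        assert scan_collection([], canonical_config()) == []

    def test_duplicate_ids_rejected(self):
        a = seq("ACGTACGTACGT", sid="x", species="sp")
        with pytest.raises(ValueError, match="duplicate"):
            scan_collection([a, a], canonical_config())


class TestClusterWindow:
    def gene(self, start, end, rank, strand="+"):
        return GeneModel(
            gene_id=f"g{rank}", species="sp", seq_id="c", strand=strand,
            start_codon_pos=start, stop_codon_end=end, cluster_rank=rank,
        )

    def test_survey_window_arithmetic(self):
        genes = [self.gene(25_000, 40_000, 1), self.gene(80_000, 95_000, 3)]
        assert cluster_window(genes, 20_000, 20_000, 130_000) == (5_000, 115_000)

    def test_clipped_at_sequence_start(self):
        genes = [self.gene(10_000, 40_000, 1)]
        assert cluster_window(genes, 20_000, 0, 130_000) == (0, 40_000)

    def test_minus_axis_window_mirrors_plus_axis(self):
        L = 130_000
        plus = [self.gene(25_000, 40_000, 1), self.gene(80_000, 95_000, 3)]
        minus = [
            GeneModel(
                gene_id=g.gene_id, species="sp", seq_id="c", strand="-",
                start_codon_pos=L - 1 - g.start_codon_pos,
                stop_codon_end=L - 1 - g.stop_codon_end,
                cluster_rank=g.cluster_rank,
            )
            for g in plus
        ]
        lo, hi = cluster_window(plus, 20_000, 20_000, L)
        assert cluster_window(minus, 20_000, 20_000, L) == (L - hi, L - lo)

    def test_empty_gene_list_error(self):
        with pytest.raises(ValueError):
            cluster_window([], 0, 0, 100)
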