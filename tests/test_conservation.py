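import itertools

import pytest

from rarescan.annotation import GeneModel, annotate_hit
from rarescan.conservation import (
    ConservationCriteria,
    elements_match,
    find_conserved,
    signature_search,
)
from rarescan.motif import parse_iupac_pattern
from rarescan.scanner import DRElementHit, GenomicSequence

DR5_SIGNATURE = parse_iupac_pattern("AGTTCA", "N{5}", "AGTTCA", name="DR5-signature")
DR2_SIGNATURE = parse_iupac_pattern("AGTTCA", "N{2}", "AGTTCA", name="DR2-signature")


def genes_for(species, scale=1.0):
    mk = lambda s, e, r: GeneModel(  # noqa: E731
        gene_id=f"g{r}", species=species, seq_id=f"{species}_c", strand="+",
        start_codon_pos=int(s * scale), stop_codon_end=int(e * scale), cluster_rank=r,
    )
    return [mk(20_000, 30_000, 1), mk(45_000, 55_000, 2), mk(70_000, 80_000, 3)]


def annotated(species, start, element, strand="+", scale=1.0, seq_len=100_000):
    h = DRElementHit(
        sequence_id=f"{species}_c", species=species, start=start,
        end=start + len(element), strand=strand,
        half_site_1=element[:6], spacer=element[6:-6], half_site_2=element[-6:],
        pattern_name="canonical-RARE",
    )
    return annotate_hit(h, genes_for(species, scale), int(seq_len * scale))


ELEMENT = "AGTTCAACAAAAGTTCA"  # the letter-identical cross-species DR5


class TestElementsMatch:
    def test_identical_element_same_relative_position(self):
        a = annotated("sp1", 40_000, ELEMENT)
        b = annotated("sp2", 40_000, ELEMENT)
        assert elements_match(a, b, ConservationCriteria())

    def test_different_compartments_fail_when_required(self):
        a = annotated("sp1", 40_000, ELEMENT)  # intergenic(1,2)
        b = annotated("sp2", 60_000, ELEMENT)  # intergenic(2,3)
        crit = ConservationCriteria()
        assert not elements_match(a, b, crit)
        loose = ConservationCriteria(
            require_same_compartment=False, position_tolerance=1.0
        )
        assert elements_match(a, b, loose)

    def test_class_mismatch_always_fails(self):
        a = annotated("sp1", 40_000, ELEMENT)
        b = annotated("sp2", 40_000, "AGTTCAATAGTTCA")  # DR2
        assert not elements_match(
            a, b, ConservationCriteria(sequence_stringency="class-only",
                                       require_same_compartment=False,
                                       position_tolerance=1.0)
        )

    def test_orientation_gate(self):
        a = annotated("sp1", 40_000, ELEMENT, strand="+")
        b = annotated("sp2", 40_000, ELEMENT, strand="-")
        assert not elements_match(a, b, ConservationCriteria())
        assert elements_match(
            a, b, ConservationCriteria(require_same_orientation=False)
        )

    def test_position_tolerance_gate(self):
        a = annotated("sp1", 31_000, ELEMENT)   # near the start of intergenic(1,2)
        b = annotated("sp2", 43_000, ELEMENT)   # near the end
        assert not elements_match(a, b, ConservationCriteria(position_tolerance=0.25))
        assert elements_match(a, b, ConservationCriteria(position_tolerance=1.0))

    def test_stringency_ladder(self):
        a = annotated("sp1", 40_000, "AGTTCAACAAAAGTTCA")
        b = annotated("sp2", 40_000, "AGTTCACCCCCAGTTCA")  # same halves, other spacer
        assert not elements_match(
            a, b, ConservationCriteria(sequence_stringency="exact-element")
        )
        assert elements_match(
            a, b,
            ConservationCriteria(sequence_stringency="half-sites-and-spacer-length"),
        )

    def test_same_species_never_matches(self):
        a = annotated("sp1", 40_000, ELEMENT)
        b = annotated("sp1", 40_000, ELEMENT)
        assert not elements_match(a, b, ConservationCriteria())

    def test_unannotated_input_rejected(self):
        a = annotated("sp1", 40_000, ELEMENT)
        with pytest.raises(TypeError, match="annotation"):
            elements_match(a, a.hit, ConservationCriteria())


class TestFindConserved:
    def test_planted_truth_recovered_exactly(self, benchmark_set):
        from rarescan.annotation import annotate_hits
        from rarescan.scanner import ScanConfig, scan_sequence
        from rarescan.motif import builtin_pattern

        cfg = ScanConfig(patterns=(builtin_pattern("canonical-RARE"),))
        by_species = {}
        for sp, seq in benchmark_set.sequences.items():
            hits = scan_sequence(seq, cfg)
            by_species[sp] = annotate_hits(hits, benchmark_set.genes[sp], len(seq))
        groups = find_conserved(by_species, ConservationCriteria())
        truth = benchmark_set.truth
        conserved_names = sorted(truth[truth.conserved].element.unique())
        assert len(groups) == len(conserved_names) == 16
        # every group maps onto one planted conserved element, exactly
        truth_by_key = {
            (r.species, r.start, r.end, r.strand): r.element
            for r in truth[truth.conserved].itertuples()
        }
        recovered = set()
        for g in groups:
            names = {
                truth_by_key.get((sp, a.hit.start, a.hit.end, a.hit.strand))
                for sp, a in g.members.items()
            }
            assert len(names) == 1 and None not in names
            recovered.add(names.pop())
        assert recovered == set(conserved_names)

    def test_species_order_invariance(self):
        anns = {
            f"sp{i}": [annotated(f"sp{i}", 40_000, ELEMENT),
                       annotated(f"sp{i}", 2_000, "AGTTCATTCAAAGTTCA")]
            for i in (1, 2, 3)
        }
        reference = None
        for order in itertools.permutations(anns):
            permuted = {sp: anns[sp] for sp in order}
            groups = find_conserved(permuted, ConservationCriteria())
            snapshot = [
                (g.group_id, g.dr_class,
                 tuple((sp, a.hit.start) for sp, a in sorted(g.members.items())))
                for g in groups
            ]
            if reference is None:
                reference = snapshot
            assert snapshot == reference
        assert reference and len(reference) == 2

    def test_missing_species_yields_no_groups(self):
        anns = {
            "sp1": [annotated("sp1", 40_000, ELEMENT)],
            "sp2": [annotated("sp2", 40_000, ELEMENT)],
            "sp3": [],
        }
        assert find_conserved(anns, ConservationCriteria()) == []

    def test_fewer_than_two_species_is_an_error(self):
        with pytest.raises(ValueError, match="2 species"):
            find_conserved({"sp1": []}, ConservationCriteria())

    def test_tightening_criteria_never_adds_groups(self, benchmark_set):
        from rarescan.annotation import annotate_hits
        from rarescan.scanner import ScanConfig, scan_sequence
        from rarescan.motif import builtin_pattern

        cfg = ScanConfig(patterns=(builtin_pattern("canonical-RARE"),))
        by_species = {
            sp: annotate_hits(
                scan_sequence(seq, cfg), benchmark_set.genes[sp], len(seq)
            )
            for sp, seq in benchmark_set.sequences.items()
        }
        counts = []
        for stringency, tol in [
            ("class-only", 1.0),
            ("half-sites-and-spacer-length", 0.5),
            ("exact-element", 0.25),
            ("exact-element", 0.01),
        ]:
            crit = ConservationCriteria(
                sequence_stringency=stringency, position_tolerance=tol
            )
            counts.append(len(find_conserved(by_species, crit)))
        assert counts == sorted(counts, reverse=True)

    def test_group_members_identical_at_exact_stringency(self, benchmark_set):
        from rarescan.annotation import annotate_hits
        from rarescan.scanner import ScanConfig, scan_sequence
        from rarescan.motif import builtin_pattern

        cfg = ScanConfig(patterns=(builtin_pattern("canonical-RARE"),))
        by_species = {
            sp: annotate_hits(
                scan_sequence(seq, cfg), benchmark_set.genes[sp], len(seq)
            )
            for sp, seq in benchmark_set.sequences.items()
        }
        for g in find_conserved(by_species, ConservationCriteria()):
            elements = {a.hit.element for a in g.members.values()}
            assert len(elements) == 1
            assert g.identity_level == "exact-element"
            assert len({a.hit.dr_class for a in g.members.values()}) == 1


class TestSignatureSearch:
    def seqs(self, residues):
        return [GenomicSequence(id="probe", species="probe", residues=residues)]

    @pytest.mark.parametrize(
        "residues", ["AGTTCATACCCAGTTCA", "AGTTCACCCAAAGTTCA"]
    )
    def test_dr5_signature_finds_printed_elements(self, residues):
        assert len(signature_search(self.seqs(residues), DR5_SIGNATURE)) == 1

    def test_dr5_signature_rejects_dr2_element(self):
        assert signature_search(self.seqs("AGTTCAATAGTTCA"), DR5_SIGNATURE) == []

    def test_dr2_signature_finds_dr2_element(self):
        hits = signature_search(self.seqs("AGTTCAATAGTTCA"), DR2_SIGNATURE)
        assert len(hits) == 1 and hits[0].dr_class == "DR2"
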