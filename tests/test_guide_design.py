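"""Construct geometry, strand symmetry, and the prime-editing round trip."""

import numpy as np
import pytest

from tspeg import (
    DesignParams,
    EditSpec,
    ReferenceSequence,
    apply_edit,
    design_actrna_t,
    design_hdr_ssdna_donor,
    design_pegrna,
    design_sgrna,
    design_tsp_pegrna,
    qc_construct,
    reverse_complement,
    scan_pams,
    simulate_genome,
    simulate_prime_edit,
    simulate_proximal_edit,
)
from tspeg.editable_space import usable_sites
from tspeg.errors import DesignError, PrimingFailureError, WrongArchitectureError
from tspeg.guide_design import GuideConstruct


def _interior_sites(genome, margin=60):
    return [s for s in usable_sites(genome) if margin <= s.cut <= len(genome) - margin]


class TestSgrna:
    def test_toyref_spacer(self, toyref, toy_site):
        sg = design_sgrna(toyref, toy_site)
        assert sg.parts["spacer"] == "GTCACCTTGAAGATGCTGAA"
        assert sg.parts["spacer"] == toyref.seq[5:25]

    def test_reverse_strand_spacer_is_revcomp_of_forward_slice(self, toyref):
        # CCN at forward 2: protospacer occupies forward [5, 25), 3' of the CCN
        site = next(
            s for s in scan_pams(toyref) if s.strand == "reverse" and s.pam_start == 2
        )
        sg = design_sgrna(toyref, site)
        assert sg.parts["spacer"] == reverse_complement(toyref.seq[5:25])

    def test_spacer_length_always_20(self):
        genome = simulate_genome(500, seed=5)
        for site in _interior_sites(genome)[:10]:
            assert len(design_sgrna(genome, site).parts["spacer"]) == 20

    def test_out_of_bounds_protospacer(self):
        ref = ReferenceSequence("short", "AAAAATGGAAAAAAAAAAAAAAAA")
        site = next(s for s in scan_pams(ref) if s.strand == "forward")
        with pytest.raises(DesignError):
            design_sgrna(ref, site)


class TestPegrna:
    def test_toyref_hand_construction(self, toyref, toy_site, cut_insertion):
        peg = design_pegrna(toyref, toy_site, cut_insertion)
        assert peg.parts["pbs"] == "AGCATCTTCAAGG"
        assert peg.parts["rtt"] == "GAGATCCTGCAATGCCATTCT"
        assert len(peg.extension) == 34
        assert list(peg.parts) == ["spacer", "scaffold", "rtt", "pbs"]
        assert peg.full_seq == "".join(peg.parts.values())

    def test_pbs_definition(self, toyref, toy_site, cut_insertion):
        peg = design_pegrna(toyref, toy_site, cut_insertion)
        assert reverse_complement(peg.parts["pbs"]) == toyref.seq[22 - 13 : 22]

    def test_extension_length_arithmetic(self, toyref, toy_site):
        # 1-bp substitution at +1: extension = pbs_len + homology_len + 1
        edit = EditSpec(
            "substitution", 22, 23, ref_allele=toyref.seq[22], alt_allele="C"
        )
        peg = design_pegrna(toyref, toy_site, edit)
        assert len(peg.extension) == 13 + 20 + 1

    def test_upstream_edit_rejected(self, toyref, toy_site):
        edit = EditSpec(
            "substitution", 15, 16, ref_allele=toyref.seq[15], alt_allele="C"
        )
        with pytest.raises(WrongArchitectureError):
            design_pegrna(toyref, toy_site, edit)


class TestTspPegrna:
    def test_toyref_hand_construction(self, toyref, toy_site, cut_insertion):
        tsp = design_tsp_pegrna(toyref, toy_site, cut_insertion)
        assert tsp.parts["pbs"] == "GAATGGCATTGCA"
        assert tsp.parts["rtt"] == "CCGGTCACCTTGAAGATGCTA"
        assert len(tsp.extension) == 34

    def test_pbs_definition(self, toyref, toy_site, cut_insertion):
        tsp = design_tsp_pegrna(toyref, toy_site, cut_insertion)
        assert tsp.parts["pbs"] == toyref.seq[22 : 22 + 13]

    def test_downstream_edit_rejected(self, toyref, toy_site):
        edit = EditSpec(
            "substitution", 25, 26, ref_allele=toyref.seq[25], alt_allele="C"
        )
        with pytest.raises(WrongArchitectureError):
            design_tsp_pegrna(toyref, toy_site, edit)

    def test_polarity_identity_on_random_loci(self):
        """With pbs_len == homology_len, the tsp extension is the reverse
        complement of the canonical extension for the same cut-site insertion."""
        params = DesignParams(pbs_len=16, homology_len=16)
        rng = np.random.default_rng(21)
        checked = 0
        for seed in range(40):
            genome = simulate_genome(300, seed=1000 + seed)
            for site in _interior_sites(genome)[:3]:
                ins = EditSpec(
                    "insertion", site.cut, site.cut,
                    alt_allele="ACGT"[int(rng.integers(4))],
                )
                peg = design_pegrna(genome, site, ins, params)
                tsp = design_tsp_pegrna(genome, site, ins, params)
                assert tsp.extension == reverse_complement(peg.extension)
                checked += 1
        assert checked >= 100

    def test_tsp_extension_is_substring_of_edited_pam_strand(self, toyref, toy_site,
                                                            cut_insertion):
        edited = apply_edit(toyref, cut_insertion)
        tsp = design_tsp_pegrna(toyref, toy_site, cut_insertion)
        peg = design_pegrna(toyref, toy_site, cut_insertion)
        assert tsp.extension in edited
        assert peg.extension in reverse_complement(edited)


class TestActRna:
    def test_extension_identical_to_tsp(self, toyref, toy_site, cut_insertion):
        tsp = design_tsp_pegrna(toyref, toy_site, cut_insertion)
        sg, act = design_actrna_t(toyref, toy_site, cut_insertion)
        assert act.extension == tsp.extension
        assert sg.parts["spacer"] == design_sgrna(toyref, toy_site).parts["spacer"]

    def test_anchor_spacer_is_15nt(self, toyref, toy_site, cut_insertion):
        _, act = design_actrna_t(toyref, toy_site, cut_insertion)
        assert len(act.parts["spacer"]) == 15

    def test_orthogonal_policy_uses_supplied_15mer(self, toyref, toy_site,
                                                   cut_insertion):
        mer = "ACGTACGTACGTACG"
        _, act = design_actrna_t(
            toyref, toy_site, cut_insertion,
            anchor_policy="orthogonal", orthogonal_spacer=mer,
        )
        assert act.parts["spacer"] == mer

    def test_genomic_fallback_when_no_downstream_pam(self, cut_insertion):
        # single PAM, nothing downstream to anchor on -> orthogonal fallback
        ref = ReferenceSequence("lonely", "A" * 40 + "TGG" + "A" * 40)
        site = next(s for s in scan_pams(ref) if s.strand == "forward")
        edit = EditSpec("insertion", site.cut, site.cut, alt_allele="C")
        _, act = design_actrna_t(ref, site, edit)
        assert any("orthogonal" in w for w in act.qc_warnings)
        assert act.parts["spacer"] not in ref.seq
        assert reverse_complement(act.parts["spacer"]) not in ref.seq


class TestHdrDonor:
    @pytest.fixture
    def hdr_locus(self):
        genome = simulate_genome(300, seed=8)
        site = next(s for s in _interior_sites(genome) if s.strand == "forward")
        return genome, site

    def test_insertion_donor_length(self, hdr_locus):
        genome, site = hdr_locus
        edit = EditSpec("insertion", site.cut, site.cut, alt_allele="A")
        donor = design_hdr_ssdna_donor(genome, site, edit)
        assert len(donor.full_seq) == 35 + 1 + 35

    def test_deletion_donor_length(self, hdr_locus):
        genome, site = hdr_locus
        edit = EditSpec(
            "deletion", site.cut - 1, site.cut,
            ref_allele=genome.seq[site.cut - 1 : site.cut],
        )
        donor = design_hdr_ssdna_donor(genome, site, edit)
        assert len(donor.full_seq) == 70

    def test_arms_match_reference(self, hdr_locus):
        genome, site = hdr_locus
        edit = EditSpec("insertion", site.cut, site.cut, alt_allele="A")
        donor = design_hdr_ssdna_donor(genome, site, edit)
        without_edit = donor.parts["left_arm"] + donor.parts["right_arm"]
        assert without_edit == genome.seq[site.cut - 35 : site.cut + 35]


class TestRoundTrip:
    @pytest.mark.parametrize("side", ["plus", "minus"])
    def test_random_loci_all_kinds_both_strands(self, side):
        """Designed constructs, replayed through the editing oracle,
        reproduce apply_edit exactly for all three edit kinds."""
        rng = np.random.default_rng(hash(side) % (2**31))
        done = 0
        seed = 0
        while done < 60:
            seed += 1
            genome = simulate_genome(300, seed=2000 + seed)
            sites = _interior_sites(genome)
            if not sites:
                continue
            site = sites[int(rng.integers(len(sites)))]
            edit = simulate_proximal_edit(genome, site, side, rng=rng)
            truth = apply_edit(genome, edit)
            if side == "plus":
                construct = design_pegrna(genome, site, edit)
            else:
                construct = design_tsp_pegrna(genome, site, edit)
                _, act = design_actrna_t(genome, site, edit)
                assert simulate_prime_edit(genome, act) == truth
            assert simulate_prime_edit(genome, construct) == truth
            done += 1

    def test_both_architectures_converge_on_cut_site_insertion(
        self, toyref, toy_site, cut_insertion
    ):
        truth = apply_edit(toyref, cut_insertion)
        peg = design_pegrna(toyref, toy_site, cut_insertion)
        tsp = design_tsp_pegrna(toyref, toy_site, cut_insertion)
        assert simulate_prime_edit(toyref, peg) == truth
        assert simulate_prime_edit(toyref, tsp) == truth

    def test_planted_pbs_mismatch_fails_priming(self, toyref, toy_site,
                                                cut_insertion):
        tsp = design_tsp_pegrna(toyref, toy_site, cut_insertion)
        pbs = tsp.parts["pbs"]
        bad = pbs[:5] + ("A" if pbs[5] != "A" else "C") + pbs[6:]
        broken = GuideConstruct(
            construct_type=tsp.construct_type,
            parts={**tsp.parts, "pbs": bad},
            site=tsp.site,
            edit=tsp.edit,
            params=tsp.params,
        )
        with pytest.raises(PrimingFailureError) as err:
            simulate_prime_edit(toyref, broken)
        assert err.value.mismatch_positions == [6]

    def test_strand_symmetry(self):
        """Designing on the mirrored reference yields identical part strings."""
        genome = simulate_genome(300, seed=77)
        mirrored = ReferenceSequence("m", reverse_complement(genome.seq))
        for site in _interior_sites(genome)[:5]:
            edit = simulate_proximal_edit(genome, site, "minus", seed=1)
            tsp = design_tsp_pegrna(genome, site, edit)
            m_sites = {
                (s.pam_start, s.pam_end, s.strand): s for s in scan_pams(mirrored)
            }
            L = len(genome)
            flipped_strand = "reverse" if site.strand == "forward" else "forward"
            m_site = m_sites[(L - site.pam_end, L - site.pam_start, flipped_strand)]
            m_tsp = design_tsp_pegrna(mirrored, m_site, edit.mirror(L))
            assert m_tsp.parts == tsp.parts


class TestQc:
    def test_clean_design_has_no_pbs_warnings(self, toyref, toy_site, cut_insertion):
        tsp = design_tsp_pegrna(toyref, toy_site, cut_insertion)
        warnings = qc_construct(tsp, toyref)
        assert not any("PBS mismatch" in w for w in warnings)

    def test_5prime_pbs_mismatch_flagged_critical(self, toyref, toy_site,
                                                  cut_insertion):
        tsp = design_tsp_pegrna(toyref, toy_site, cut_insertion)
        pbs = tsp.parts["pbs"]
        bad = ("A" if pbs[0] != "A" else "C") + pbs[1:]
        broken = GuideConstruct(
            "tsp_pegrna", {**tsp.parts, "pbs": bad}, tsp.site, tsp.edit, tsp.params
        )
        warnings = qc_construct(broken, toyref)
        assert any("position 1" in w and "5'-critical" in w for w in warnings)

    def test_polyt_warning(self, toyref, toy_site, cut_insertion):
        tsp = design_tsp_pegrna(toyref, toy_site, cut_insertion)
        broken = GuideConstruct(
            "tsp_pegrna", {**tsp.parts, "rtt": "TTTT" + tsp.parts["rtt"]},
            tsp.site, tsp.edit, tsp.params,
        )
        assert any("poly-T" in w for w in qc_construct(broken, toyref))

    def test_edge_proximity_warning(self, single_pam_ref):
        site = next(s for s in scan_pams(single_pam_ref) if s.strand == "forward")
        sg = design_sgrna(single_pam_ref, site)
        assert any("edge" in w for w in qc_construct(sg, single_pam_ref))


def test_rna_output_mode(toyref, toy_site, cut_insertion):
    params = DesignParams(output_alphabet="RNA")
    tsp = design_tsp_pegrna(toyref, toy_site, cut_insertion, params)
    assert "T" not in tsp.emit_seq()
    assert "U" in tsp.emit_seq()
    # DNA parts themselves are unchanged
    assert "U" not in tsp.full_seq
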