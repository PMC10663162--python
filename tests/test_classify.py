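"""Decision-tree classification and mass-sum validation of cross-links."""

import itertools

import pytest

from xlsurf.chem import DSSO, Modification, Peptide, mz_from_neutral_mass, peptide_mass
from xlsurf.classify import (
    CSM_CATEGORY,
    ClassifierConfig,
    FdrEstimate,
    INCOMPLETE_CSM,
    MONOLINK,
    ResidueLink,
    SINGLE,
    UNKNOWN,
    ClassifiedGroup,
    classify_group,
    estimate_fdr,
    summarize,
    to_residue_links,
    validate_interlink,
)
from xlsurf.grouping import SpectralGroup
from xlsurf.msio import SearchHit, SpectrumRecord

ALKENE = DSSO.remnant("alkene")
THIOL = DSSO.remnant("thiol")
STRIP = ("fixed", "variable", "dead_end")


def make_group(ms2_hit=None, ms3_hits=(), precursor_mass=None, charge=4, mz=600.0):
    scan = SpectrumRecord("scan=2", 2, "scan=1", mz, charge)
    return SpectralGroup(
        ms2_scan=scan,
        precursor_charge=charge,
        precursor_neutral_mass=precursor_mass,
        ms2_hit=ms2_hit,
        ms3_hits=list(ms3_hits),
    )


def remnant_hit(scan, sequence, link_pos, prob=0.9, remnant=ALKENE,
                accession="SP1", decoy=False):
    return SearchHit(
        scan,
        Peptide(sequence, [(link_pos, remnant)], accession, is_decoy=decoy),
        prob,
    )


class TestDecisionTree:
    def test_confident_unlinked_ms2_peptide_is_single(self):
        hit = SearchHit("scan=2", Peptide("GAVLDESR", [], "SP1"), 0.9)
        result = classify_group(make_group(ms2_hit=hit), ClassifierConfig())
        assert result.category == SINGLE

    def test_internal_dead_end_lysine_is_monolink(self):
        peptide = Peptide("GAKVLDR", [(3, DSSO.dead_end_mod)], "SP1")
        hit = SearchHit("scan=2", peptide, 0.95)
        result = classify_group(make_group(ms2_hit=hit), ClassifierConfig())
        assert result.category == MONOLINK

    def test_cterminal_dead_end_is_not_a_monolink(self):
        # Trypsin cleaved after this K, so it cannot carry a cross-linker.
        peptide = Peptide("GAVLDRK", [(7, DSSO.dead_end_mod)], "SP1")
        hit = SearchHit("scan=2", peptide, 0.95)
        result = classify_group(make_group(ms2_hit=hit), ClassifierConfig())
        assert result.category == UNKNOWN

    def test_low_probability_ms2_hit_does_not_gate(self):
        hit = SearchHit("scan=2", Peptide("GAVLDESR", [], "SP1"), 0.5)
        result = classify_group(make_group(ms2_hit=hit), ClassifierConfig())
        assert result.category == UNKNOWN

    def test_empty_group_is_unknown(self):
        assert classify_group(make_group(), ClassifierConfig()).category == UNKNOWN

    def test_exact_mass_pair_is_csm_at_zero_ppm(self):
        pep_a, pep_b = "GAKVLDR", "TTKWER"
        observed = (
            peptide_mass(Peptide(pep_a)) + peptide_mass(Peptide(pep_b))
            + DSSO.bridge_mass
        )
        group = make_group(
            ms3_hits=[
                remnant_hit("scan=3", pep_a, 3, remnant=ALKENE),
                remnant_hit("scan=4", pep_b, 3, remnant=THIOL),
            ],
            precursor_mass=observed,
            mz=mz_from_neutral_mass(observed, 4),
        )
        result = classify_group(group, ClassifierConfig())
        assert result.category == CSM_CATEGORY
        assert result.csm.mass_error == pytest.approx(0.0, abs=1e-9)
        assert {result.csm.link_pos_a, result.csm.link_pos_b} == {3}

    def test_candidates_that_never_sum_are_incomplete(self):
        pep_a, pep_b = "GAKVLDR", "TTKWER"
        observed = (
            peptide_mass(Peptide(pep_a)) + peptide_mass(Peptide(pep_b))
            + DSSO.bridge_mass + 5.0
        )
        group = make_group(
            ms3_hits=[
                remnant_hit("scan=3", pep_a, 3),
                remnant_hit("scan=4", pep_b, 3, remnant=THIOL),
            ],
            precursor_mass=observed,
        )
        assert classify_group(group, ClassifierConfig()).category == INCOMPLETE_CSM

    def test_single_qualifying_ms3_hit_is_unknown(self):
        group = make_group(
            ms3_hits=[
                remnant_hit("scan=3", "GAKVLDR", 3, prob=0.95),
                remnant_hit("scan=4", "TTKWER", 3, prob=0.5),
            ],
            precursor_mass=2000.0,
        )
        assert classify_group(group, ClassifierConfig()).category == UNKNOWN

    def test_unknown_charge_tries_hypothesis_range(self):
        pep_a, pep_b = "GAKVLDR", "TTKWER"
        mass = (
            peptide_mass(Peptide(pep_a)) + peptide_mass(Peptide(pep_b))
            + DSSO.bridge_mass
        )
        group = make_group(
            ms3_hits=[
                remnant_hit("scan=3", pep_a, 3),
                remnant_hit("scan=4", pep_b, 3, remnant=THIOL),
            ],
            precursor_mass=None,
            charge=0,
            mz=mz_from_neutral_mass(mass, 5),
        )
        result = classify_group(group, ClassifierConfig())
        assert result.category == CSM_CATEGORY
        assert result.csm.inferred_charge == 5

    def test_csm_presence_enforced(self):
        with pytest.raises(ValueError):
            ClassifiedGroup(make_group(), CSM_CATEGORY, csm=None)


class TestValidateInterlink:
    def test_shifted_precursor_beyond_tolerance_rejected(self):
        pep_a, pep_b = "GAKVLDR", "TTKWER"
        exact = (
            peptide_mass(Peptide(pep_a)) + peptide_mass(Peptide(pep_b))
            + DSSO.bridge_mass
        )
        hits = [
            remnant_hit("scan=3", pep_a, 3),
            remnant_hit("scan=4", pep_b, 3, remnant=THIOL),
        ]
        config = ClassifierConfig()
        assert validate_interlink(hits, exact, config) is not None
        assert validate_interlink(hits, exact * (1 + 50e-6), config) is None

    def test_only_correct_pair_among_three_candidates(self):
        sequences = {"scan=3": "GAKVLDR", "scan=4": "TTKWER", "scan=5": "MMKYYR"}
        hits = [remnant_hit(scan, seq, 3) for scan, seq in sequences.items()]
        observed = (
            peptide_mass(Peptide("GAKVLDR")) + peptide_mass(Peptide("MMKYYR"))
            + DSSO.bridge_mass
        )
        config = ClassifierConfig()
        # Brute-force oracle over all three pairs.
        passing = [
            frozenset((a.scan_id, b.scan_id))
            for a, b in itertools.combinations(hits, 2)
            if abs(
                peptide_mass(a.assigned_peptide, STRIP)
                + peptide_mass(b.assigned_peptide, STRIP)
                + DSSO.bridge_mass - observed
            ) / observed * 1e6 <= config.precursor_tol_ppm
        ]
        assert passing == [frozenset({"scan=3", "scan=5"})]
        csm = validate_interlink(hits, observed, config)
        assert {csm.peptide_a.sequence, csm.peptide_b.sequence} == {
            "GAKVLDR", "MMKYYR"
        }

    def test_same_scan_pairs_excluded(self):
        pep_a, pep_b = "GAKVLDR", "TTKWER"
        observed = (
            peptide_mass(Peptide(pep_a)) + peptide_mass(Peptide(pep_b))
            + DSSO.bridge_mass
        )
        hits = [
            remnant_hit("scan=3", pep_a, 3),
            remnant_hit("scan=3", pep_b, 3, remnant=THIOL),
        ]
        assert validate_interlink(hits, observed, ClassifierConfig()) is None

    def test_remnant_pair_choice_does_not_change_the_sum(self):
        # Stripping remnants makes alkene/thiol vs alkene/sulfenic reports
        # equivalent under the mass-sum test.
        pep_a, pep_b = "GAKVLDR", "TTKWER"
        observed = (
            peptide_mass(Peptide(pep_a)) + peptide_mass(Peptide(pep_b))
            + DSSO.bridge_mass
        )
        config = ClassifierConfig()
        for remnant_b in (THIOL, DSSO.remnant("sulfenic_acid")):
            hits = [
                remnant_hit("scan=3", pep_a, 3, remnant=ALKENE),
                remnant_hit("scan=4", pep_b, 3, remnant=remnant_b),
            ]
            csm = validate_interlink(hits, observed, config)
            assert csm is not None and csm.mass_error == pytest.approx(0, abs=1e-9)


class TestFdrAndLinks:
    def _csm_group(self, decoy_a=False, decoy_b=False, start_a=190, start_b=100):
        pep_a, pep_b = "GAKVLDR", "TTKWER"
        observed = (
            peptide_mass(Peptide(pep_a)) + peptide_mass(Peptide(pep_b))
            + DSSO.bridge_mass
        )
        hit_a = remnant_hit("scan=3", pep_a, 3, accession="SP1", decoy=decoy_a)
        hit_b = remnant_hit("scan=4", pep_b, 3, remnant=THIOL,
                            accession="SP2", decoy=decoy_b)
        hit_a.assigned_peptide.start_position = start_a
        hit_b.assigned_peptide.start_position = start_b
        group = make_group(ms3_hits=[hit_a, hit_b], precursor_mass=observed)
        return classify_group(group, ClassifierConfig())

    def test_fdr_arithmetic(self):
        assert FdrEstimate(100, 1, 0).fdr == pytest.approx(0.01)
        assert FdrEstimate(0, 0, 0).fdr == 0.0

    def test_decoy_classes_counted(self):
        results = [
            self._csm_group(),
            self._csm_group(decoy_a=True),
            self._csm_group(decoy_a=True, decoy_b=True),
        ]
        fdr = estimate_fdr(results)
        assert (fdr.tt, fdr.td, fdr.dd) == (1, 1, 1)
        assert results[1].csm.decoy_class == "TD"

    def test_link_positions_project_to_protein_coordinates(self):
        # Peptide at protein start 190 linked at peptide position 5 -> 194.
        result = self._csm_group(start_a=192, start_b=303)
        links = to_residue_links([result])
        assert links == [ResidueLink("SP1", 194, "SP2", 305)]

    def test_duplicate_links_collapse(self):
        results = [self._csm_group(), self._csm_group()]
        assert len(to_residue_links(results)) == 1

    def test_unmapped_peptides_flagged(self):
        result = self._csm_group()
        result.csm.peptide_a.start_position = None
        (link,) = to_residue_links([result])
        assert not link.mapped

    def test_summary_counts_partition_groups(self):
        results = [
            self._csm_group(),
            classify_group(make_group(), ClassifierConfig()),
            classify_group(
                make_group(
                    ms2_hit=SearchHit("scan=2", Peptide("GAVLDESR", [], "SP1"), 0.9)
                ),
                ClassifierConfig(),
            ),
        ]
        text = summarize(results)
        assert "CSM: 1" in text
        assert "UNKNOWN: 1" in text
        assert "SINGLE: 1" in text
        assert "total groups: 3" in text

    def test_empty_summary(self):
        text = summarize([])
        assert "total groups: 0" in text
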