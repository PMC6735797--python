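"""Peptide adjudication: uniqueness, alignment filter, tiers, targeted MS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_min_diffs
from conftest import random_protein

from lncproteo.config import PipelineConfig
from lncproteo.database import DbEntry, build_reference_db
from lncproteo.orfs import OrfCandidate, ProteomeEntry
from lncproteo.peptides import (
    DEFAULT_EQUIVALENCES,
    IL_ONLY,
    EquivalenceTable,
    TransitionMeasurement,
    assign_peptides,
    check_targeted_verification,
    evidence_tier,
    min_alignment_diffs,
    sw_uniqueness_filter,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _db_from(*proteins_with_sources):
    known, orfs, genes = [], [], set()
    for i, (protein, source) in enumerate(proteins_with_sources):
        if source == "known":
            known.append(DbEntry(f"KP_{i}", "known_translating", protein, f"g{i}", "PE1"))
            genes.add(f"g{i}")
        else:
            orfs.append(ProteomeEntry(protein, [
                OrfCandidate(f"t{i}", 0, 0, 3 * (len(protein) + 1), protein)]))
            genes.add(f"t{i}")  # lncRNA gene called translating
    return build_reference_db(genes, known, orfs)


class TestEquivalenceTable:
    def test_rejects_reflexive_pair(self):
        with pytest.raises(ValueError):
            EquivalenceTable([("I", "I")])

    def test_collapse_is_idempotent_and_symmetric(self):
        eq = DEFAULT_EQUIVALENCES
        assert eq.collapse("ILND") == eq.collapse(eq.collapse("ILND"))
        assert eq.equivalent("N", "D") and eq.equivalent("D", "N")
        assert not eq.equivalent("A", "G")


class TestAssignPeptides:
    def test_unique_to_single_orf(self):
        prot = "M" + "W" * 30 + "PEPTIDEKW" + "W" * 30
        db = _db_from((prot, "orf"), ("M" + "A" * 60, "known"))
        (ev,) = assign_peptides(["PEPTIDEKW"], db)
        assert ev.is_unique and len(ev.assigned_accessions) == 1

    def test_shared_with_known_is_supportive(self):
        shared = "QWETYPKSR"
        db = _db_from(("M" + "A" * 30 + shared + "C" * 30, "orf"),
                      ("M" + "G" * 30 + shared + "V" * 30, "known"))
        (ev,) = assign_peptides([shared], db)
        assert not ev.is_unique
        assert ev.verdict == "supportive"

    def test_il_substitution_still_matches(self):
        db = _db_from(("M" + "A" * 30 + "PEPTIDEKW" + "C" * 30, "orf"),)
        (ev,) = assign_peptides(["PEPTLDEKW"], db)  # I -> L
        assert ev.assigned_accessions

    def test_entries_identical_under_il_count_once(self):
        p1 = "M" + "A" * 30 + "PEPTIDEKW"
        p2 = p1.replace("I", "L")
        db = _db_from((p1, "orf"), (p2, "known"))
        (ev,) = assign_peptides(["PEPTIDEKW"], db)
        assert ev.is_unique  # both entries collapse to one I/L group

    def test_nonstandard_residues_rejected(self):
        db = _db_from(("M" + "A" * 60, "known"),)
        (ev,) = assign_peptides(["PEPTIBEK"], db)
        assert ev.verdict == "rejected_nonstandard"


class TestMinAlignmentDiffs:
    def test_exact_substring(self):
        assert min_alignment_diffs("PEPTIDEK", "MAAPEPTIDEKGG", IL_ONLY) == 0

    def test_one_substitution(self):
        assert min_alignment_diffs("PEPTIDEK", "MAAPEPTADEKGG", IL_ONLY) == 1

    def test_indel_counts_one(self):
        assert min_alignment_diffs("PEPTIDEK", "MAAPEPTDEKGG", IL_ONLY) == 1

    def test_nd_equivalence_gives_zero(self):
        # config-dependent: with the default table N and D are one class
        assert min_alignment_diffs("PENTIDEK", "MAAPEDTIDEKGG".replace("D", "D")) \
            == min_alignment_diffs("PENTIDEK", "MAAPENTIDEKGG")
        assert min_alignment_diffs("PEPTINEK", "MAAPEPTIDEKGG", DEFAULT_EQUIVALENCES) == 0
        assert min_alignment_diffs("PEPTINEK", "MAAPEPTIDEKGG", IL_ONLY) == 1

    def test_empty_protein_costs_peptide_length(self):
        assert min_alignment_diffs("PEPTIDEK", "") == 8

    def test_exhaustive_oracle_500_cases(self):
        """Semi-global DP equals substring-enumeration edit distance."""
        rng = np.random.default_rng(99)
        eq = DEFAULT_EQUIVALENCES
        for _ in range(500):
            pep = random_protein(rng, int(rng.integers(1, 13)))
            prot = random_protein(rng, int(rng.integers(0, 61)))
            assert min_alignment_diffs(pep, prot, eq) == \
                brute_force_min_diffs(pep, prot, eq), (pep, prot)

    @given(st.text(alphabet=AA, min_size=1, max_size=12),
           st.text(alphabet=AA, min_size=0, max_size=40))
    @settings(max_examples=150, derandomize=True)
    def test_invariant_under_equivalent_substitution(self, pep, prot):
        swapped = pep.replace("I", "L").replace("N", "D").replace("Q", "E")
        assert min_alignment_diffs(pep, prot) == min_alignment_diffs(swapped, prot)

    def test_score_based_local_mode_agrees_on_clear_cases(self):
        from lncproteo.peptides import local_alignment_diffs

        assert local_alignment_diffs("PEPTIDEK", "MAAPEPTIDEKGG", IL_ONLY) == 0
        assert local_alignment_diffs("PEPTIDEK", "MAAPEPTADEKGG", IL_ONLY) == 1
        assert local_alignment_diffs("PEPTIDEK", "") == 8
        # both modes agree when a near-exact region exists
        rng = np.random.default_rng(17)
        for _ in range(30):
            pep = random_protein(rng, 10)
            prot = random_protein(rng, 20) + pep + random_protein(rng, 20)
            assert local_alignment_diffs(pep, prot) == min_alignment_diffs(pep, prot) == 0


class TestSwUniquenessFilter:
    def _run(self, peptide, db, background, **config_kwargs):
        config = PipelineConfig(**config_kwargs) if config_kwargs else PipelineConfig()
        evs = assign_peptides([peptide], db)
        return sw_uniqueness_filter(evs, background, db, config)[0]

    def test_eight_mer_rejected_short(self):
        prot = "M" + "W" * 30 + "PEPTIDKW" + "W" * 30
        db = _db_from((prot, "orf"))
        ev = self._run("PEPTIDKW", db, [("bg", "M" + "A" * 50)])
        assert ev.verdict == "rejected_short"

    def test_nine_mer_eligible(self):
        prot = "M" + "W" * 30 + "PEPTIDEKW" + "W" * 30
        db = _db_from((prot, "orf"))
        ev = self._run("PEPTIDEKW", db, [("bg", "M" + "A" * 50)])
        assert ev.verdict == "accepted_unique"

    def test_one_edit_from_background_rejected(self):
        prot = "M" + "W" * 30 + "PEPTIDEKW" + "W" * 30
        db = _db_from((prot, "orf"))
        bg = [("bg", "M" + "G" * 20 + "PEPTADEKW" + "G" * 20)]  # 1 substitution away
        ev = self._run("PEPTIDEKW", db, bg)
        assert ev.verdict == "rejected_similar"
        assert ev.min_diffs == 1

    def test_two_edits_accepted(self):
        prot = "M" + "W" * 30 + "PEPTIDEKW" + "W" * 30
        db = _db_from((prot, "orf"))
        bg = [("bg", "M" + "G" * 20 + "PEATADEKW" + "G" * 20)]  # 2 substitutions away
        ev = self._run("PEPTIDEKW", db, bg)
        assert ev.verdict == "accepted_unique"
        assert ev.min_diffs == 2

    def test_own_source_excluded_from_background(self):
        prot = "M" + "W" * 30 + "PEPTIDEKW" + "W" * 30
        db = _db_from((prot, "orf"))
        # background contains the source protein itself: must not self-reject
        ev = self._run("PEPTIDEKW", db, [("self", prot)])
        assert ev.verdict == "accepted_unique"

    def test_monotone_in_threshold(self):
        prot = "M" + "W" * 30 + "PEPTIDEKW" + "W" * 30
        db = _db_from((prot, "orf"))
        bg = [("bg", "M" + "G" * 20 + "PEATADEKW" + "G" * 20)]
        accepted_at_2 = self._run("PEPTIDEKW", db, bg, min_alignment_diffs=2)
        rejected_at_3 = self._run("PEPTIDEKW", db, bg, min_alignment_diffs=3)
        assert accepted_at_2.verdict == "accepted_unique"
        assert rejected_at_3.verdict == "rejected_similar"


class TestEvidenceTier:
    @pytest.mark.parametrize(
        "uniq,supp,tier",
        [(2, 0, "two_plus_unique"), (3, 5, "two_plus_unique"),
         (1, 1, "one_unique_plus_supportive"), (1, 0, "one_unique_only"),
         (0, 3, "insufficient"), (0, 0, "insufficient")],
    )
    def test_tiers(self, uniq, supp, tier):
        assert evidence_tier(uniq, supp) == tier


def _meas(precursor="p1", fragment="y3", light=100.0, heavy=100.0, sn=5.0, coel=True):
    return TransitionMeasurement(precursor, fragment, light, heavy, sn, coel)


class TestTargetedVerification:
    def test_three_good_transitions_verified(self):
        ms = [
            _meas(fragment="y3", light=105.0, sn=5.0),
            _meas(fragment="y4", light=110.0, sn=6.0),
            _meas(fragment="y5", light=115.0, sn=7.0),
        ]
        verdict, reasons = check_targeted_verification(ms)
        assert verdict == "verified" and reasons == []

    def test_two_transitions_not_verified(self):
        ms = [_meas(fragment="y3"), _meas(fragment="y4")]
        verdict, reasons = check_targeted_verification(ms)
        assert verdict == "not_verified"
        assert any("(b)" in r for r in reasons)

    def test_low_sn_transitions_do_not_count(self):
        ms = [_meas(fragment=f"y{i}", sn=sn) for i, sn in enumerate([5.0, 6.0, 2.0])]
        verdict, reasons = check_targeted_verification(ms)
        assert verdict == "not_verified"

    def test_sn_boundary_is_strict(self):
        # S/N > 3 required: exactly 3.0 does not qualify
        ms = [_meas(fragment=f"y{i}", sn=3.0) for i in range(3)]
        verdict, _ = check_targeted_verification(ms)
        assert verdict == "not_verified"

    def test_one_pair_deviating_25pct_fails(self):
        ms = [
            _meas(fragment="y3", light=100.0),
            _meas(fragment="y4", light=100.0),
            _meas(fragment="y5", light=125.0),  # 25% off the median ratio
        ]
        verdict, reasons = check_targeted_verification(ms)
        assert verdict == "not_verified"
        assert any("(c)" in r for r in reasons)

    def test_deviation_boundary_strictly_below_20pct(self):
        # ratios 1.25, 1.25, 1.5: the odd pair deviates exactly 20% from the
        # median ratio (0.25 / 1.25), which is not "less than 20%"
        exactly = [_meas(fragment="y3", light=125.0), _meas(fragment="y4", light=125.0),
                   _meas(fragment="y5", light=150.0)]
        verdict, _ = check_targeted_verification(exactly)
        assert verdict == "not_verified"
        just_below = [_meas(fragment="y3", light=125.0), _meas(fragment="y4", light=125.0),
                      _meas(fragment="y5", light=148.0)]
        verdict, _ = check_targeted_verification(just_below)
        assert verdict == "verified"

    def test_non_coeluting_pair_fails(self):
        ms = [_meas(fragment="y3"), _meas(fragment="y4"),
              _meas(fragment="y5", coel=False)]
        verdict, reasons = check_targeted_verification(ms)
        assert verdict == "not_verified"
        assert any("(a)" in r for r in reasons)

    def test_zero_heavy_area_fails_with_reason(self):
        ms = [_meas(fragment="y3"), _meas(fragment="y4"),
              _meas(fragment="y5", heavy=0.0)]
        verdict, reasons = check_targeted_verification(ms)
        assert verdict == "not_verified"
        assert any("zero heavy" in r for r in reasons)

    def test_generator_truth_labels_agree(self):
        """check_targeted_verification reproduces the generator's planted outcomes."""
        from lncproteo.simulate import SimulationParams, simulate_transitions

        params = SimulationParams(seed=21)
        peptides = [f"PEPTIDE{aa}K" for aa in AA]
        df = simulate_transitions(peptides, params)
        for precursor, group in df.groupby("precursor_id"):
            ms = [
                TransitionMeasurement(precursor, r.fragment_id, r.light_area,
                                      r.heavy_area, r.light_sn, r.coelutes)
                for r in group.itertuples()
            ]
            verdict, _ = check_targeted_verification(ms)
            expected = "verified" if group["truth_verified"].iloc[0] else "not_verified"
            assert verdict == expected, precursor
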