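from functools import reduce

import pytest
from hypothesis import given
from hypothesis import strategies as st

import macplan as mp
from macplan.enzymes import FIVE_PRIME, THREE_PRIME
from macplan.simulate import SimFragment

from conftest import at_background

dna = st.text(alphabet="ACGT", min_size=0, max_size=400)


class TestDigest:
    def test_single_site_two_fragments(self, enzymes):
        frags = mp.digest("AAGGATCCTT", enzymes.get("BamHI"))
        assert [f.top for f in frags] == ["AAG", "GATCCTT"]
        assert frags[0].right_overhang == ("GATC", FIVE_PRIME)
        assert frags[1].left_overhang == ("GATC", FIVE_PRIME)

    def test_no_site_single_uncut_fragment(self, enzymes):
        frags = mp.digest("ACGTACGT", enzymes.get("BamHI"))
        assert len(frags) == 1 and frags[0].top == "ACGTACGT"

    def test_two_sites_three_fragments(self, enzymes):
        frags = mp.digest("GGATCCAAGGATCC", enzymes.get("BamHI"))
        assert len(frags) == 3

    def test_three_prime_cutter(self, enzymes):
        frags = mp.digest("AAGAGCTCTT", enzymes.get("SacI"))
        assert [f.top for f in frags] == ["AAGAGCT", "CTT"]
        assert frags[0].right_overhang == ("AGCT", THREE_PRIME)


class TestLigate:
    def test_hybrid_junction_reads_ccatgt(self, enzymes):
        left = mp.digest("AACCATGG", enzymes.get("NcoI"))[0]
        right = mp.digest("ACATGTAA", enzymes.get("PciI"))[1]
        joined = mp.ligate(left, right)
        assert "CCATGT" in joined.top

    def test_mismatched_overhangs_rejected(self):
        a = SimFragment("AAA", right_overhang=("CTAG", FIVE_PRIME))
        b = SimFragment("TTT", left_overhang=("GATC", FIVE_PRIME))
        with pytest.raises(mp.IncompatibleEndsError):
            mp.ligate(a, b)

    def test_polarity_must_match(self):
        a = SimFragment("AAA", right_overhang=("AGCT", THREE_PRIME))
        b = SimFragment("TTT", left_overhang=("AGCT", FIVE_PRIME))
        with pytest.raises(mp.IncompatibleEndsError):
            mp.ligate(a, b)
        ok = mp.ligate(
            SimFragment("AAAGCT", right_overhang=("AGCT", THREE_PRIME)),
            SimFragment("TTT", left_overhang=("AGCT", THREE_PRIME)),
        )
        assert ok.top == "AAAGCTTTT"

    def test_blunt_ligation_unsupported(self):
        with pytest.raises(mp.IncompatibleEndsError):
            mp.ligate(SimFragment("AAA"), SimFragment("TTT"))


@given(dna)
def test_digest_ligate_round_trip(seq):
    """Re-ligating a digest in order reconstructs the input exactly."""
    enzymes = mp.load_default_enzymes()
    for name in ("BamHI", "NcoI", "SacI"):
        frags = mp.digest(seq, enzymes.get(name))
        assert reduce(mp.ligate, frags).top == seq


def _two_module_plan(bam_bcl, residues, junction_at):
    rows = [
        (1, junction_at + 4, "", "BamHI"),
        (junction_at + 1, len(residues), "BclI", ""),
    ]
    return mp.build_plan_from_flanks(rows, bam_bcl)


class TestSimulateAssembly:
    def test_toy_two_module_plan_is_seamless(self, bam_bcl):
        residues = at_background(1200, seed=9)
        residues = residues[:599] + "GGATCA" + residues[605:]
        plan = _two_module_plan(bam_bcl, residues, 600)
        assembled, report = mp.simulate_assembly(plan, residues, enzymes=bam_bcl)
        assert assembled == residues
        assert report.ok

    def test_single_module_plan_unchanged(self, bam_bcl):
        residues = at_background(700, seed=2)
        plan = mp.build_plan_from_flanks([(51, 650, "", "")], bam_bcl)
        assembled, report = mp.simulate_assembly(plan, residues)
        assert assembled == residues[50:650] and report.ok

    def test_enzyme_reuse_after_palindromic_junction_is_flagged(self, bam_bcl):
        # BamHI forms a palindromic junction at 600, then re-opens the
        # assembly at the hybrid junction near 1200: the earlier junction
        # site is re-cut and must be reported, yet assembly stays seamless.
        residues = at_background(1800, seed=4)
        residues = residues[:599] + "GGATCC" + residues[605:]
        residues = residues[:1199] + "GGATCA" + residues[1205:]
        rows = [
            (1, 605, "", "BamHI"),
            (600, 1204, "BamHI", "BamHI"),
            (1201, 1800, "BclI", ""),
        ]
        plan = mp.build_plan_from_flanks(rows, bam_bcl)
        assembled, report = mp.simulate_assembly(plan, residues, enzymes=bam_bcl)
        assert assembled == residues
        assert [(v.step, v.enzyme, v.position) for v in report.violations] == [
            (2, "BamHI", 600)
        ]

    def test_intended_site_missing_raises(self, bam_bcl):
        residues = at_background(1200, seed=9)  # junction site never planted
        plan = _two_module_plan(bam_bcl, residues, 600)
        with pytest.raises(mp.SimulationError):
            mp.simulate_assembly(plan, residues)


class TestSafetyConsistency:
    def test_static_equals_dynamic_on_flagged_plan(self, bam_bcl):
        residues = at_background(1800, seed=4)
        residues = residues[:599] + "GGATCC" + residues[605:]
        residues = residues[:1199] + "GGATCA" + residues[1205:]
        rows = [
            (1, 605, "", "BamHI"),
            (600, 1204, "BamHI", "BamHI"),
            (1201, 1800, "BclI", ""),
        ]
        plan = mp.build_plan_from_flanks(rows, bam_bcl)
        _, dynamic = mp.simulate_assembly(plan, residues, enzymes=bam_bcl)
        static = mp.assembly_safety_check(plan, residues, enzymes=bam_bcl, strict=True)
        assert static.violations == dynamic.violations

    @pytest.mark.parametrize("seed", range(5))
    def test_static_equals_dynamic_on_planner_output(self, enzymes, pairs, seed):
        target = mp.planted_target(3600, seed)
        plan = mp.plan_partition(
            target, (1, len(target.residues)), mp.PlannerConfig(), enzymes, pairs
        )
        assembled, dynamic = mp.simulate_assembly(plan, target, enzymes=enzymes)
        static = mp.assembly_safety_check(plan, target, enzymes=enzymes, strict=True)
        assert assembled == target.residues
        assert dynamic.ok and static.violations == dynamic.violations

    def test_lenient_static_check_scopes_to_left_module(self, bam_bcl):
        residues = at_background(1800, seed=4)
        residues = residues[:599] + "GGATCC" + residues[605:]
        residues = residues[:1199] + "GGATCA" + residues[1205:]
        rows = [
            (1, 605, "", "BamHI"),
            (600, 1204, "BamHI", "BamHI"),
            (1201, 1800, "BclI", ""),
        ]
        plan = mp.build_plan_from_flanks(rows, bam_bcl)
        lenient = mp.assembly_safety_check(plan, residues, strict=False)
        assert lenient.ok  # the re-cut lies outside the adjacent modules


def test_surrogate_published_plan_reproduces_terminal_reuse(enzymes):
    """On a surrogate of the upstream fragment, the published plan assembles
    seamlessly, but strict checking flags the terminal-XhoI reuse at the
    fourth junction (XhoI re-cuts the primer-added 5' vector site)."""
    surrogate = mp.chef1_surrogate("upstream", seed=7)
    plan = mp.chef1_published_plan("upstream", local=True)
    assembled, report = mp.simulate_assembly(plan, surrogate, enzymes=enzymes)
    region = surrogate.residues[plan.region[0] - 1 : plan.region[1]]
    assert assembled == region
    assert [(v.step, v.enzyme) for v in report.violations] == [(4, "XhoI")]
    static = mp.assembly_safety_check(plan, surrogate, enzymes=enzymes, strict=True)
    assert static.violations == report.violations


def test_surrogate_downstream_plan_is_clean(enzymes):
    surrogate = mp.chef1_surrogate("downstream", seed=7)
    plan = mp.chef1_published_plan("downstream", local=True)
    assembled, report = mp.simulate_assembly(plan, surrogate, enzymes=enzymes)
    region = surrogate.residues[plan.region[0] - 1 : plan.region[1]]
    assert assembled == region and report.ok
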