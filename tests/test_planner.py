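import pytest

import macplan as mp
from macplan.scanner import HYBRID, PALINDROMIC
from macplan.seqtools import occurrences
from macplan.synthetic import (
    CHEF1_DOWNSTREAM_MODULES,
    CHEF1_UPSTREAM_MODULES,
)

from conftest import act_background


@pytest.mark.parametrize(
    "start,end,length", [(8532, 9117, 586), (11205, 12491, 1287), (7, 7, 1)]
)
def test_module_length_inclusive_convention(start, end, length):
    assert mp.module_length(start, end) == length


def test_module_length_rejects_reversed_coordinates():
    with pytest.raises(mp.MacPlanError):
        mp.module_length(8, 7)


class TestPublishedPlans:
    """The worked example: two CHEF1 flanking fragments, 5 + 6 modules."""

    def test_junction_classification_three_palindromic_six_hybrid(self):
        up = mp.classify_junctions(mp.chef1_published_plan("upstream"))
        down = mp.classify_junctions(mp.chef1_published_plan("downstream"))
        assert (up[0] + down[0], up[1] + down[1]) == (3, 6)

    @pytest.mark.parametrize("which,rows", [
        ("upstream", CHEF1_UPSTREAM_MODULES),
        ("downstream", CHEF1_DOWNSTREAM_MODULES),
    ])
    def test_overlap_geometry_matches_printed_coordinates(self, which, rows):
        plan = mp.chef1_published_plan(which)
        printed_overlaps = [e1 - s2 + 1 for (_, e1, _, _), (s2, _, _, _) in zip(rows, rows[1:])]
        assert [j.overlap_len for j in plan.junctions] == printed_overlaps
        for junction in plan.junctions:
            assert junction.overlap_len == (6 if junction.kind == PALINDROMIC else 4)

    def test_printed_module_lengths(self):
        plan = mp.chef1_published_plan("upstream")
        assert [m.length for m in plan.modules] == [586, 687, 779, 639, 1287]

    def test_primer_termini_of_first_hybrid_junction(self, enzymes):
        # module 1 ends at a genomic CCTAGA (AvrII/XbaI hybrid): its primer
        # appends G to read ...CCTAGG (a true AvrII site); module 2's primer
        # prepends T completing TCTAGA (XbaI).
        plan = mp.chef1_published_plan("upstream")
        assert mp.primer_termini(plan.modules[0], plan) == (enzymes.get("XhoI").site, "G")
        assert mp.primer_termini(plan.modules[1], plan)[0] == "T"

    def test_palindromic_junction_adds_no_bases(self):
        plan = mp.chef1_published_plan("upstream")
        # junction 2 (BamHI/BamHI) is fully genomic on both sides
        assert plan.modules[1].right_added == ""
        assert plan.modules[2].left_added == ""

    def test_foreign_module_rejected(self):
        plan = mp.chef1_published_plan("upstream")
        other = mp.chef1_published_plan("downstream")
        with pytest.raises(mp.MacPlanError):
            mp.primer_termini(other.modules[0], plan)


class TestCandidateJunctions:
    def test_planted_hybrid_found_and_attributed(self, enzymes, pairs):
        seq = "A" * 699 + "CCATGT" + "A" * 295
        cands = mp.candidate_junctions(seq, (600, 800), enzymes, pairs)
        assert [(c.site_position, c.left_enzyme.name, c.right_enzyme.name) for c in cands] == [
            (700, "NcoI", "PciI")
        ]

    def test_empty_window(self, enzymes, pairs):
        assert mp.candidate_junctions("A" * 1000, (600, 800), enzymes, pairs) == []

    def test_midpoint_proximity_wins(self, enzymes, pairs):
        seq = "A" * 689 + "GGATCC" + "AAAA" + "CCATGT" + "A" * 295
        # GGATCC at 690, CCATGT at 700; window midpoint 700
        cands = mp.candidate_junctions(seq, (600, 800), enzymes, pairs)
        assert cands[0].site_position == 700 and cands[0].kind == HYBRID
        assert cands[1].site_position == 690 and cands[1].kind == PALINDROMIC


class TestPlanPartition:
    def test_planted_sites_give_three_modules(self, bam_bcl):
        residues = act_background(3000, seed=5)
        residues = (
            residues[:999] + "GGATCA" + residues[1005:1999] + "GGATCA" + residues[2005:]
        )
        seq = mp.CleanSequence(residues)
        plan = mp.plan_partition(
            seq, (1, 3000), mp.PlannerConfig(), bam_bcl, mp.all_hybrid_sites(bam_bcl)
        )
        assert len(plan.modules) == 3
        assert [j.site_position for j in plan.junctions] == [1000, 2000]
        assert plan.safety.ok

    def test_short_region_single_module(self, enzymes, pairs):
        seq = mp.random_sequence(800, seed=3)
        plan = mp.plan_partition(seq, (100, 699), mp.PlannerConfig(), enzymes, pairs)
        assert len(plan.modules) == 1 and plan.junctions == ()
        assert plan.modules[0].start == 100 and plan.modules[0].end == 699

    def test_region_below_minimum_is_flagged(self, enzymes, pairs):
        seq = mp.random_sequence(400, seed=3)
        plan = mp.plan_partition(seq, (1, 400), mp.PlannerConfig(), enzymes, pairs)
        assert plan.modules[0].undersized

    def test_self_cutting_candidate_rejected(self, bam_bcl):
        # the only junction site's left enzyme (BamHI) also cuts inside the
        # left module, so no valid strict plan exists
        residues = act_background(3000, seed=5)
        residues = residues[:499] + "GGATCC" + residues[505:999] + "GGATCA" + residues[1005:]
        seq = mp.CleanSequence(residues)
        with pytest.raises(mp.NoJunctionFound):
            mp.plan_partition(
                seq, (1, 3000), mp.PlannerConfig(), bam_bcl, mp.all_hybrid_sites(bam_bcl)
            )

    def test_lenient_mode_permits_enzyme_reuse(self, bam_bcl):
        residues = act_background(3000, seed=5)
        residues = residues[:499] + "GGATCC" + residues[505:999] + "GGATCA" + residues[1005:]
        residues = residues[:1999] + "GGATCA" + residues[2005:]
        seq = mp.CleanSequence(residues)
        plan = mp.plan_partition(
            seq,
            (1, 3000),
            mp.PlannerConfig(strict_sequential=False),
            bam_bcl,
            mp.all_hybrid_sites(bam_bcl),
        )
        assert len(plan.modules) >= 3

    def test_methylation_avoidance_excludes_bcli(self, bam_bcl):
        residues = act_background(3000, seed=5)
        residues = residues[:999] + "GGATCA" + residues[1005:1999] + "GGATCA" + residues[2005:]
        seq = mp.CleanSequence(residues)
        with pytest.raises(mp.NoJunctionFound):
            mp.plan_partition(
                seq,
                (1, 3000),
                mp.PlannerConfig(avoid_methylation=True),
                bam_bcl,
                mp.all_hybrid_sites(bam_bcl),
            )

    def test_terminal_enzyme_with_internal_site_rejected(self, bam_bcl):
        residues = act_background(1500, seed=5)
        residues = residues[:699] + "GGATCC" + residues[705:]
        seq = mp.CleanSequence(residues)
        with pytest.raises(mp.MacPlanError, match="BamHI"):
            mp.plan_partition(
                seq,
                (1, 1500),
                mp.PlannerConfig(terminal_5_enzyme=bam_bcl.get("BamHI")),
                bam_bcl,
                mp.all_hybrid_sites(bam_bcl),
            )

    def test_invalid_size_window_rejected(self):
        with pytest.raises(mp.MacPlanError):
            mp.PlannerConfig(min_module=800, max_module=700)


class TestPlanProperties:
    @pytest.mark.parametrize("seed", range(8))
    def test_tiling_safety_and_internal_cleanliness(self, enzymes, pairs, seed):
        target = mp.planted_target(3600, seed)
        plan = mp.plan_partition(
            target, (1, len(target.residues)), mp.PlannerConfig(), enzymes, pairs
        )
        # modules tile the region under the overlap rule
        total = sum(m.length for m in plan.modules) - sum(
            j.overlap_len for j in plan.junctions
        )
        assert total == plan.region[1] - plan.region[0] + 1
        for prev, nxt, junction in zip(plan.modules, plan.modules[1:], plan.junctions):
            assert nxt.start == prev.end - junction.overlap_len + 1
        # the emitted plan passes the static safety check
        assert plan.safety.ok
        # constraint re-verified post hoc: junction enzymes have no interior
        # occurrence in their adjacent modules
        for module, junction in zip(plan.modules, plan.junctions):
            span = target.residues[module.start - 1 : module.end]
            interior = [
                p for p in occurrences(span, junction.left_enzyme.site)
                if p not in (0, len(span) - 6)
            ]
            assert interior == []
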