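"""Static-structure scoring, MC refinement, enumeration and ranking."""

import itertools

import networkx as nx
import numpy as np
import pytest

from npcassembly import (CopyNumberRestraint, ScoreWeights, density_correlation,
                         enumerate_copy_combinations, enumerate_pathways,
                         mc_refine, rank_pathways, score_static,
                         structure_density)
from npcassembly.geometry import (Pose, StaticStructure, SubcomplexInstance,
                                  rotation_about_axis)
from npcassembly.pathway import transition_allowed
from npcassembly.toysystem import model_toy_system, planted_indices


class TestScoring:
    def test_ground_state_scores_zero_harmonics(self, toy_system):
        """The mature structure with copy means at mature values violates
        no restraint."""
        ctx = toy_system.scoring_context()
        br = score_static(toy_system.mature, ctx, len(toy_system.planted) - 1)
        for term in ("go", "excluded_volume", "envelope", "membrane",
                     "copy_number"):
            assert br.terms[term] == pytest.approx(0.0, abs=1e-9)
        assert br.terms["density"] == pytest.approx(0.0, abs=1e-9)

    def test_score_is_additive(self, toy_system):
        ctx = toy_system.scoring_context()
        br = score_static(toy_system.planted[1], ctx, 1)
        assert br.total == pytest.approx(sum(br.terms.values()))

    def test_copy_term_gaussian_algebra(self):
        restraint = CopyNumberRestraint(means={"Y": 16.0}, sds={"Y": 8.0})
        assert restraint.penalty({"Y": 16}) == 0.0
        # one SD away -> +0.5 in -log-likelihood units
        assert restraint.penalty({"Y": 24}) == pytest.approx(0.5)

    def test_separated_beads_have_no_excluded_volume(self, toy_system):
        ctx = toy_system.scoring_context()
        for t, s in enumerate(toy_system.planted):
            br = score_static(s, ctx, t)
            assert br.terms["excluded_volume"] == 0.0

    def test_overlap_penalized(self, toy_system):
        ctx = toy_system.scoring_context()
        s = toy_system.planted[1]
        # ram one instance into another
        inst = s.instances[0]
        target = s.instances[-1]
        clash = s.with_pose(inst.instance_id, target.pose)
        br = score_static(clash, ctx, 1)
        assert br.terms["excluded_volume"] > 0.0

    def test_go_term_ramps_with_time(self, toy_system, rng):
        ctx = toy_system.scoring_context()
        s = toy_system.planted[4]
        inst = s.instances[1]
        moved = s.with_pose(inst.instance_id, inst.pose.perturbed(
            np.eye(3), np.array([0.0, 0.0, 2.0])))
        early = score_static(moved, ctx, 4, time_scale=0.2).terms["go"]
        late = score_static(moved, ctx, 4, time_scale=1.0).terms["go"]
        assert late == pytest.approx(5 * early)
        assert ctx.time_scale(0) == 0.0 and ctx.time_scale(5) == 1.0

    def test_c8_expansion_invariance(self, toy_system):
        """Scoring the asymmetric unit with implicit symmetry equals
        scoring the explicitly expanded structure."""
        ctx = toy_system.scoring_context()
        for t in (1, 3):
            unit = toy_system.planted[t]
            expanded = unit.expanded_structure(toy_system.types)
            a = score_static(unit, ctx, t)
            b = score_static(expanded, ctx, t)
            assert a.total == pytest.approx(b.total, abs=1e-8)
            assert a.terms == pytest.approx(b.terms, abs=1e-8)


class TestMcRefine:
    def test_zero_width_moves_leave_structure_unchanged(self, toy_system):
        ctx = toy_system.scoring_context()
        start = toy_system.planted[2]
        refined, br = mc_refine(start, ctx, 2, n_moves=20, seed=0,
                                max_rotation=0.0, max_translation=0.0)
        for a, b in zip(start.instances, refined.instances):
            np.testing.assert_allclose(a.pose.translation, b.pose.translation)
        assert br.total == pytest.approx(score_static(start, ctx, 2).total)

    def test_best_never_worse_than_start(self, toy_system):
        ctx = toy_system.scoring_context()
        start = toy_system.planted[2]
        inst = start.instances[0]
        perturbed = start.with_pose(inst.instance_id, inst.pose.perturbed(
            rotation_about_axis(np.array([0, 0, 1.0]), 0.06),
            np.array([1.5, -1.0, 1.0])))
        s0 = score_static(perturbed, ctx, 2).total
        refined, br = mc_refine(perturbed, ctx, 2, n_moves=150, seed=3)
        assert br.total <= s0

    def test_refinement_recovers_planted_density(self, toy_system):
        """Refinement moves a perturbed start back toward the planted
        target density."""
        ctx = toy_system.scoring_context()
        start = toy_system.planted[2]
        inst = start.instances[0]
        perturbed = start.with_pose(inst.instance_id, inst.pose.perturbed(
            rotation_about_axis(np.array([0, 1.0, 0]), 0.05),
            np.array([2.0, 1.0, -1.0])))
        refined, _ = mc_refine(perturbed, ctx, 2, n_moves=250, seed=1)
        target = toy_system.target_densities[2]
        cc_before = density_correlation(
            structure_density(perturbed, toy_system.types), target)
        cc_after = density_correlation(
            structure_density(refined, toy_system.types), target)
        assert cc_after > cc_before

    def test_deterministic_given_seed(self, toy_system):
        ctx = toy_system.scoring_context()
        start = toy_system.planted[1]
        a, br_a = mc_refine(start, ctx, 1, n_moves=40, seed=9)
        b, br_b = mc_refine(start, ctx, 1, n_moves=40, seed=9)
        assert br_a.total == br_b.total
        for ia, ib in zip(a.instances, b.instances):
            np.testing.assert_array_equal(ia.pose.translation,
                                          ib.pose.translation)


class TestCopyEnumeration:
    def test_exact_mean_ranks_first(self):
        restraint = CopyNumberRestraint(means={"Y": 16.0}, sds={"Y": 2.0})
        ranked = enumerate_copy_combinations(restraint, {"Y": 32}, top_k=3)
        assert ranked[0][0] == {"Y": 16}
        assert ranked[0][1] == 0.0

    def test_top_k_capped_by_admissible_set(self):
        restraint = CopyNumberRestraint(means={"Y": 8.0}, sds={"Y": 2.0})
        ranked = enumerate_copy_combinations(restraint, {"Y": 16}, top_k=99)
        assert len(ranked) == 3          # 0, 8, 16

    def test_matches_brute_force_ordering(self):
        restraint = CopyNumberRestraint(means={"A": 11.0, "B": 5.0},
                                        sds={"A": 3.0, "B": 4.0})
        mature = {"A": 16, "B": 16}
        ranked = enumerate_copy_combinations(restraint, mature, top_k=100)
        brute = sorted(
            (dict(zip(("A", "B"), combo))
             for combo in itertools.product(range(0, 17, 8), repeat=2)),
            key=lambda c: (restraint.penalty(c), tuple(sorted(c.items()))))
        assert [a for a, _ in ranked] == brute

    def test_empty_type_set_rejected(self):
        with pytest.raises(ValueError):
            enumerate_copy_combinations(
                CopyNumberRestraint(means={}, sds={}), {})


def _abstract_structure(label, keys):
    instances = tuple(SubcomplexInstance("T", k, Pose.identity())
                      for k in keys)
    return StaticStructure(time_label=label, instances=instances, n_fold=1)


def _dag_path_count(stages):
    """Independent oracle: count source->sink paths in the transition DAG."""
    g = nx.DiGraph()
    for t, stage in enumerate(stages):
        for i in range(len(stage)):
            g.add_node((t, i))
    for t in range(len(stages) - 1):
        for i, a in enumerate(stages[t]):
            for j, b in enumerate(stages[t + 1]):
                if transition_allowed(a, b):
                    g.add_edge((t, i), (t + 1, j))
    return sum(1 for i in range(len(stages[0]))
               for j in range(len(stages[-1]))
               for _ in nx.all_simple_paths(g, (0, i),
                                            (len(stages) - 1, j))) \
        if len(stages) > 1 else len(stages[0])


class TestPathwayEnumeration:
    def test_single_chain(self):
        stages = [[_abstract_structure(0, ["a"])],
                  [_abstract_structure(1, ["a", "b"])]]
        assert enumerate_pathways(stages) == [(0, 0)]

    def test_two_valid_intermediates(self):
        stages = [[_abstract_structure(0, ["a"])],
                  [_abstract_structure(1, ["a", "b"]),
                   _abstract_structure(1, ["a", "c"])],
                  [_abstract_structure(2, ["a", "b", "c"])]]
        assert len(enumerate_pathways(stages)) == 2

    def test_inclusion_violations_pruned(self):
        stages = [[_abstract_structure(0, ["a", "b"])],
                  [_abstract_structure(1, ["a", "c"])]]   # loses b
        assert enumerate_pathways(stages) == []

    def test_counts_match_dag_oracle_on_random_lattices(self, rng):
        """Enumeration equals a brute-force DAG path count on all random
        toy instances up to 4 time points x 4 structures."""
        labels = list("abcdefgh")
        for trial in range(30):
            n_stages = int(rng.integers(2, 5))
            stages = []
            for t in range(n_stages):
                stage = []
                for i in range(int(rng.integers(1, 5))):
                    k = int(rng.integers(1, len(labels) + 1))
                    keys = sorted(rng.choice(labels, size=k, replace=False))
                    stage.append(_abstract_structure(t, keys))
                stages.append(stage)
            assert len(enumerate_pathways(stages)) == _dag_path_count(stages)

    def test_empty_stage_rejected(self):
        with pytest.raises(ValueError):
            enumerate_pathways([[], [_abstract_structure(1, ["a"])]])


class TestRanking:
    stages = [[_abstract_structure(0, ["a"]), _abstract_structure(0, ["b"])],
              [_abstract_structure(1, ["a", "b"])]]

    def test_single_pathway_share_is_one(self):
        model = rank_pathways([self.stages[1]], [[1.7]])
        assert model.best.share == 1.0

    def test_equal_scores_split_evenly(self):
        model = rank_pathways(self.stages, [[2.0, 2.0], [1.0]])
        assert [round(p.share, 12) for p in model.ranked] == [0.5, 0.5]

    def test_shares_sum_to_one_and_offset_invariant(self):
        scores = [[0.3, 2.1], [0.7]]
        model = rank_pathways(self.stages, scores)
        shifted = rank_pathways(self.stages,
                                [[s + 5.0 for s in st] for st in scores])
        assert sum(p.share for p in model.ranked) == pytest.approx(1.0)
        assert [p.indices for p in model.ranked] \
            == [p.indices for p in shifted.ranked]
        assert model.best.share == pytest.approx(shifted.best.share)

    def test_planted_toy_pathway_ranks_first(self, toy_system):
        model = model_toy_system(toy_system)
        planted = planted_indices(toy_system, model)
        assert planted is not None
        assert model.best.indices == planted
        assert model.best.share > 0.5
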