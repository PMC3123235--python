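"""Fitch labeling vs exhaustive oracle, event flags, cross-tab, rates."""

import dendropy
import numpy as np
import pytest

from mtphylo.alignment import Alignment
from mtphylo.annotate import (BranchStats, CrossTab, MutationEvent,
                              branch_stats, conservation_profile, crosstab,
                              extract_events, fitch_label, flag_events,
                              generation_points, perfect_phylogeny_bound,
                              summary_rates)
from mtphylo.sequences import iupac_set
from mtphylo.synthdata import SynthSpec, generate, simulate_tree

from oracle_utils import exhaustive_parsimony, random_instance


class TestConservation:
    def test_uniform_column_alpha_one(self):
        aln = Alignment.from_rows([("a", "A"), ("b", "A"), ("c", "A")])
        prof = conservation_profile(aln)
        assert prof.alpha[0] == 1.0

    def test_nine_to_one_column(self):
        rows = [(f"s{i}", "A") for i in range(9)] + [("s9", "C")]
        prof = conservation_profile(Alignment.from_rows(rows))
        assert prof.alpha[0] == pytest.approx(0.9)
        assert prof.dominant[0] == "A"

    def test_gaps_and_ambiguity_excluded_from_denominator(self):
        aln = Alignment.from_rows([("a", "A"), ("b", "A"), ("c", "N"),
                                   ("d", "-")])
        prof = conservation_profile(aln)
        assert prof.alpha[0] == 1.0
        assert prof.effective_depth[0] == 2

    def test_zero_depth_column_flagged_undefined(self):
        aln = Alignment.from_rows([("a", "N-"), ("b", "-N")])
        prof = conservation_profile(aln)
        assert not prof.defined[0] and not prof.defined[1]
        assert np.isnan(prof.alpha[0])


class TestFitch:
    def test_uniform_leaves_score_zero(self):
        tree = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        tree.is_rooted = True
        aln = Alignment.from_rows([(x, "ACGT") for x in "abcd"])
        lab = fitch_label(tree, aln)
        assert lab.score == 0
        assert all((lab.resolved[n] == list("ACGT")).all()
                   for n in lab.resolved)

    def test_known_four_leaf_column_score(self):
        tree = dendropy.Tree.get(data="((l1,l2),(l3,l4));", schema="newick")
        tree.is_rooted = True
        aln = Alignment.from_rows([("l1", "A"), ("l2", "C"), ("l3", "A"),
                                   ("l4", "G")])
        assert fitch_label(tree, aln).score == 2

    def test_compatible_ambiguity_costs_nothing(self):
        tree = dendropy.Tree.get(data="((l1,l2),l3);", schema="newick")
        tree.is_rooted = True
        aln = Alignment.from_rows([("l1", "A"), ("l2", "A"), ("l3", "R")])
        assert fitch_label(tree, aln).score == 0

    def test_score_matches_exhaustive_enumeration(self, rng):
        for _ in range(200):
            tree, aln = random_instance(rng)
            lab = fitch_label(tree, aln)
            for j in range(aln.ncols):
                oracle = exhaustive_parsimony(tree, {
                    i: iupac_set(aln.rows[i][j]) for i in aln.ids})
                assert lab.score_per_column[j] == oracle, (
                    tree.as_string(schema="newick"), aln.rows, j)

    def test_unsequenced_padding_never_generates_events(self):
        tree = dendropy.Tree.get(data="((a,b),c);", schema="newick")
        tree.is_rooted = True
        rows = {"a": "A-", "b": "AC", "c": "AC"}
        aln = Alignment(list(rows), rows,
                        unsequenced={"a": np.array([False, True])})
        lab = fitch_label(tree, aln)
        events = extract_events(lab, tree)
        assert lab.score == 0 and events == []

    def test_missing_leaf_is_an_error(self):
        tree = dendropy.Tree.get(data="((a,b),c);", schema="newick")
        tree.is_rooted = True
        aln = Alignment.from_rows([("a", "A"), ("b", "A")])
        with pytest.raises(ValueError, match="c"):
            fitch_label(tree, aln)


class TestEvents:
    def _label(self, newick, rows):
        tree = dendropy.Tree.get(data=newick, schema="newick")
        tree.is_rooted = True
        aln = Alignment.from_rows(rows)
        lab = fitch_label(tree, aln)
        return tree, aln, lab, extract_events(lab, tree)

    def test_zero_change_labeling_has_no_events(self):
        _, _, lab, events = self._label("((a,b),c);",
                                        [("a", "AC"), ("b", "AC"),
                                         ("c", "AC")])
        assert events == []

    def test_single_substitution_single_event(self):
        _, _, _, events = self._label("((a,b),c);",
                                      [("a", "AC"), ("b", "AC"), ("c", "AT")])
        assert len(events) == 1
        e = events[0]
        assert (e.from_state, e.to_state) == ("C", "T") and e.child == "c"

    def test_event_count_per_column_equals_column_score(self, rng):
        for _ in range(40):
            tree, aln = random_instance(rng)
            lab = fitch_label(tree, aln)
            events = extract_events(lab, tree)
            per_col = np.zeros(aln.ncols, dtype=int)
            for e in events:
                per_col[e.column] += 1
            assert (per_col == lab.score_per_column).all()

    def test_ambiguity_effects_stay_local_to_the_leaf(self, rng):
        for _ in range(20):
            tree, aln = random_instance(rng, max_leaves=6, max_cols=4)
            plain_rows = {i: r.replace("R", "A").replace("Y", "C")
                          .replace("N", "G") for i, r in aln.rows.items()}
            base = Alignment(list(plain_rows), dict(plain_rows))
            lab0 = fitch_label(tree, base)
            victim = aln.ids[0]
            mutated = dict(plain_rows)
            mutated[victim] = "N" * base.ncols
            lab1 = fitch_label(tree, Alignment(list(mutated), mutated))
            # masking one leaf can only reduce the score, never grow it
            assert lab1.score <= lab0.score


class TestBackMutation:
    def _events(self, newick, rows, scope="path"):
        tree = dendropy.Tree.get(data=newick, schema="newick")
        tree.is_rooted = True
        aln = Alignment.from_rows(rows)
        lab = fitch_label(tree, aln)
        prof = conservation_profile(aln)
        return flag_events(extract_events(lab, tree), tree, prof,
                           back_mutation_scope=scope)

    def test_restoring_a_replaced_state_is_flagged(self):
        # root(A) -> internal(C) -> leaf(A): hand-traced reversal
        events = self._events("((a,b),(c,(d,e)));",
                              [("a", "A"), ("b", "A"), ("c", "C"),
                               ("d", "C"), ("e", "A")])
        back = [e for e in events if "back_mutation" in e.flags]
        assert len(back) == 1
        assert (back[0].from_state, back[0].to_state) == ("C", "A")

    def test_change_to_third_state_is_not_a_reversal(self):
        events = self._events("((a,b),(c,(d,e)));",
                              [("a", "A"), ("b", "A"), ("c", "C"),
                               ("d", "C"), ("e", "G")])
        assert not any("back_mutation" in e.flags for e in events)

    def test_root_scope_is_stricter_than_path_scope(self, rng):
        for _ in range(20):
            tree, aln = random_instance(rng, max_leaves=6, max_cols=6)
            lab = fitch_label(tree, aln)
            path = flag_events(extract_events(lab, tree), tree, None,
                               back_mutation_scope="path")
            root = flag_events(extract_events(lab, tree), tree, None,
                               back_mutation_scope="root")
            n_path = sum("back_mutation" in e.flags for e in path)
            n_root = sum("back_mutation" in e.flags for e in root)
            assert n_root <= n_path

    def test_conserved_flag_follows_alpha_threshold(self):
        rows = [(f"s{i}", "AA") for i in range(19)] + [("s19", "CA")]
        tree = simulate_tree(20, 0)
        relabel = dict(zip([lf.taxon.label for lf in tree.leaf_node_iter()],
                           [r[0] for r in rows]))
        for lf in tree.leaf_node_iter():
            lf.taxon.label = relabel[lf.taxon.label]
        aln = Alignment.from_rows(rows)
        lab = fitch_label(tree, aln)
        prof = conservation_profile(aln)
        events = flag_events(extract_events(lab, tree), tree, prof,
                             alpha_threshold=0.94)
        assert events and all("conserved" in e.flags for e in events)


class TestCrossTab:
    def test_empty_event_list_all_zeros(self):
        ct = crosstab([])
        assert all(v == 0 for row in ct.cells.values() for v in row.values())

    def test_identities_on_random_flag_sets(self, rng):
        flag_pool = ["conserved", "back_mutation", "ambiguous", "indel"]
        events = []
        for i in range(1000):
            flags = {f for f in flag_pool if rng.random() < 0.4}
            to = "R" if "ambiguous" in flags else "G"
            frm = "-" if "indel" in flags else "A"
            e = MutationEvent("p", f"c{i}", 0, None, frm, to)
            e.flags = flags
            events.append(e)
        ct = crosstab(events)
        ct.check_identities()  # raises on violation
        total = ct.cells["total"]
        assert total["total"] == 1000
        assert (total["conserved"] + total["back_mutation"]
                - total["conserved_and_back"] + total["remaining"]) == 1000

    def test_generator_known_counts_match(self, clean_result):
        truth = clean_result.truth
        tree = truth.tree
        lab = fitch_label(tree, truth.alignment)
        events = flag_events(extract_events(lab, tree), tree, None)
        ct = crosstab(events)
        assert ct.cells["total"]["total"] == truth.n_point_events


class TestBranchStats:
    def test_star_tree_one_mutation_per_leaf(self):
        tree = dendropy.Tree.get(data="(a,b,c,d);", schema="newick")
        tree.is_rooted = True
        events = [MutationEvent("root", c, 0, None, "A", "C")
                  for c in "abcd"]
        from mtphylo.annotate import ensure_node_names
        ensure_node_names(tree)
        events = [MutationEvent(tree.seed_node.name, c, 0, None, "A", "C")
                  for c in "abcd"]
        bs = branch_stats(events, tree, threshold=50)
        assert set(bs.counts.values()) == {1}
        assert bs.outliers == set()
        assert bs.total == 4

    def test_divergent_leaf_flagged_at_default_threshold(self, rng):
        spec = SynthSpec(n_leaves=10, n_outliers=1, outlier_extra_subs=60,
                         seed=5)
        res = generate(spec)
        victim = next(i for i, d in res.truth.registry.items()
                      if d.kind == "outlier")
        from mtphylo.workflow import WorkflowConfig, run_pipeline
        out = run_pipeline(res.dataset, res.annotation,
                           WorkflowConfig(qc=res.qc_config),
                           "scratch/branchstats")
        assert victim in out.stats["branch_outliers"]

    def test_counts_conserve_total(self, rng):
        tree, aln = random_instance(rng, max_leaves=6, max_cols=8)
        lab = fitch_label(tree, aln)
        events = extract_events(lab, tree)
        bs = branch_stats(events, tree)
        assert bs.total == len(events)


class TestGenerationPoints:
    def _ev(self, parent, child, col, frm, to):
        return MutationEvent(parent, child, col, None, frm, to)

    def test_unique_mutations_count_one(self):
        events = [self._ev("r", "a", 0, "A", "C"),
                  self._ev("r", "b", 1, "A", "G")]
        counts, hist = generation_points(events)
        assert set(counts.values()) == {1}
        assert hist == {1: 2}

    def test_recurrent_mutation_counts_branches(self):
        events = [self._ev("r", c, 3, "A", "G") for c in "abc"]
        counts, _ = generation_points(events, "by_position_and_states")
        assert counts[(3, "A", "G")] == 3
        counts_pos, _ = generation_points(events, "by_position")
        assert counts_pos[(3,)] == 3

    def test_position_grouping_dominates_state_grouping(self, rng):
        tree, aln = random_instance(rng, max_leaves=6, max_cols=6)
        lab = fitch_label(tree, aln)
        events = extract_events(lab, tree)
        by_pos, _ = generation_points(events, "by_position")
        by_state, _ = generation_points(events, "by_position_and_states")
        for (col, frm, to), count in by_state.items():
            assert by_pos[(col,)] >= count


class TestPerfectPhylogenyBound:
    def test_identical_alignment_bound_zero(self):
        aln = Alignment.from_rows([("a", "ACGT"), ("b", "ACGT")])
        assert perfect_phylogeny_bound(aln) == 0

    def test_three_symbols_need_two_events(self):
        aln = Alignment.from_rows([("a", "A"), ("b", "C"), ("c", "G")])
        assert perfect_phylogeny_bound(aln) == 2

    def test_gap_counts_as_a_symbol(self):
        aln = Alignment.from_rows([("a", "A"), ("b", "-"), ("c", "A")])
        assert perfect_phylogeny_bound(aln) == 1

    def test_bound_never_exceeds_fitch_score(self, rng):
        for _ in range(500):
            tree, aln = random_instance(rng, max_leaves=5, max_cols=5)
            assert perfect_phylogeny_bound(aln) <= fitch_label(tree, aln).score

    def test_equality_without_recurrent_mutation(self, clean_result):
        truth = clean_result.truth
        lab = fitch_label(truth.tree, truth.alignment)
        assert perfect_phylogeny_bound(truth.alignment) == lab.score


class TestRates:
    def test_reference_scale_rates(self):
        # the worked-example inputs: 67900 events, 7390 leaves, 16832 columns
        r = summary_rates(67900, 7390, 16832)
        assert round(r.per_leaf, 2) == 9.19
        assert round(r.per_character, 2) == 4.03

    def test_zero_events_zero_rates(self):
        r = summary_rates(0, 10, 100, {("a", "b"): 0})
        assert r.per_leaf == 0 and r.per_character == 0

    def test_zero_denominators_rejected(self):
        with pytest.raises(ValueError):
            summary_rates(5, 0, 100)
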