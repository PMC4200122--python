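"""Mk2 likelihood, ancestral reconstruction, shift counting, and the random-tree null."""

import math

import numpy as np
import pytest

from silkshift import phylo
from silkshift.phylo import (
    NON_SILK,
    SILK,
    build_distance_tree,
    cooption_test,
    count_shifts,
    fit_rate,
    marginal_states,
    midpoint_root,
    prune_likelihood,
    random_rooted_tree,
    read_newick,
    transition_matrix,
)

from _oracles import enumerate_likelihood_and_marginals


def _random_states(tree, rng, p_silk=0.5):
    return {
        t.name: (SILK if rng.random() < p_silk else NON_SILK) for t in tree.tips()
    }


class TestTransitionMatrix:
    def test_rows_sum_to_one_and_change_below_half(self, rng):
        for _ in range(50):
            q, t = rng.uniform(0, 5, size=2)
            P = transition_matrix(q, t)
            assert np.allclose(P.sum(axis=1), 1.0)
            assert 0.0 <= P[0, 1] < 0.5 + 1e-12


class TestPruneLikelihood:
    def test_zero_rate_mixed_states_impossible(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        states = {"A": SILK, "B": SILK, "C": NON_SILK, "D": NON_SILK}
        assert prune_likelihood(tree, states, 0.0) == -math.inf

    def test_zero_rate_uniform_states_gives_root_prior(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        states = {n: SILK for n in "ABCD"}
        assert prune_likelihood(tree, states, 0.0) == pytest.approx(math.log(0.5))

    def test_missing_tip_state_rejected(self):
        tree = read_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="B"):
            prune_likelihood(tree, {"A": SILK}, 1.0)

    def test_matches_enumeration_on_random_trees(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 9))
            tree = random_rooted_tree(n, rng)
            states = _random_states(tree, rng)
            q = float(rng.uniform(0.05, 3.0))
            total, _ = enumerate_likelihood_and_marginals(tree, states, q)
            assert prune_likelihood(tree, states, q) == pytest.approx(
                math.log(total), abs=1e-10
            )

    def test_invariant_to_rerooting(self, rng):
        # the ER model is reversible, so the likelihood cannot depend on the
        # position of the root along any edge
        tree = random_rooted_tree(8, rng)
        states = _random_states(tree, rng)
        ll = prune_likelihood(tree, states, 0.7)
        work = tree.copy()
        target = next(
            n for n in work.postorder() if not n.is_tip() and n.parent is not None
        )
        rerooted = work.root_at(target, reset=True)
        assert prune_likelihood(rerooted, states, 0.7) == pytest.approx(ll, abs=1e-8)


class TestFitRate:
    def test_uniform_states_drive_rate_to_lower_bound(self, rng):
        tree = random_rooted_tree(6, rng)
        states = {t.name: SILK for t in tree.tips()}
        fit = fit_rate(tree, states)
        assert fit.at_bound
        assert fit.q < 1e-6

    def test_fitted_rate_is_local_optimum(self, rng):
        for _ in range(5):
            tree = random_rooted_tree(10, rng)
            states = _random_states(tree, rng)
            fit = fit_rate(tree, states)
            if fit.at_bound:
                continue
            ll = prune_likelihood(tree, states, fit.q)
            assert ll >= prune_likelihood(tree, states, 0.5 * fit.q) - 1e-9
            assert ll >= prune_likelihood(tree, states, 2.0 * fit.q) - 1e-9

    def test_rate_recovery_on_simulated_characters(self, rng):
        # evolve a binary character at q=0.5 down 200-tip trees; the ML
        # estimate should concentrate near the truth
        q_true = 0.5
        estimates = []
        for _ in range(20):
            tree = random_rooted_tree(200, rng)
            states = {}
            state_of = {id(tree): int(rng.random() < 0.5)}
            for node in tree.preorder():
                if node.parent is None:
                    continue
                P = transition_matrix(q_true, node.length or 0.0)
                parent_state = state_of[id(node.parent)]
                state_of[id(node)] = int(rng.random() < P[parent_state, 1])
                if node.is_tip():
                    states[node.name] = SILK if state_of[id(node)] else NON_SILK
            fit = fit_rate(tree, states)
            estimates.append(fit.q)
        med = float(np.median(estimates))
        assert 0.35 <= med <= 0.7


class TestMarginalStates:
    def test_symmetric_cherry_worked_example(self):
        # ((A,B),(C,D)) with equal branch lengths, A,B silk vs C,D non-silk:
        # the root posterior is exactly 1/2 by symmetry -> tie -> non-silk,
        # while the AB ancestor is silk; exactly one gain is counted
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        states = {"A": SILK, "B": SILK, "C": NON_SILK, "D": NON_SILK}
        rec = marginal_states(tree, states, q=0.3)
        ab = tree.lca(["A", "B"])
        cd = tree.lca(["C", "D"])
        assert rec.posterior_silk[id(tree)] == pytest.approx(0.5, abs=1e-12)
        assert rec.labels[id(tree)] == NON_SILK
        assert rec.labels[id(ab)] == SILK
        assert rec.labels[id(cd)] == NON_SILK
        assert count_shifts(tree, rec, states) == 1

    def test_all_silk_tips_make_all_internals_silk(self, rng):
        tree = random_rooted_tree(7, rng)
        states = {t.name: SILK for t in tree.tips()}
        rec = marginal_states(tree, states, q=0.8)
        assert all(label == SILK for label in rec.labels.values())

    def test_matches_enumeration_on_random_trees(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 9))
            tree = random_rooted_tree(n, rng)
            states = _random_states(tree, rng)
            q = float(rng.uniform(0.05, 3.0))
            _, marg = enumerate_likelihood_and_marginals(tree, states, q)
            rec = marginal_states(tree, states, q)
            for node_id, expected in marg.items():
                assert rec.posterior_silk[node_id] == pytest.approx(expected, abs=1e-10)


class TestCountShifts:
    def test_all_non_silk_gives_zero(self, rng):
        tree = random_rooted_tree(6, rng)
        states = {t.name: NON_SILK for t in tree.tips()}
        rec = marginal_states(tree, states, q=0.1)
        assert count_shifts(tree, rec, states) == 0

    def test_single_silk_tip_counts_one_gain(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        states = {"A": SILK, "B": NON_SILK, "C": NON_SILK, "D": NON_SILK}
        rec = marginal_states(tree, states, q=0.2)
        assert count_shifts(tree, rec, states) == 1


class TestRandomRootedTree:
    def test_structural_invariants(self, rng):
        for n in (2, 3, 7, 15):
            tree = random_rooted_tree(n, rng)
            tips = list(tree.tips())
            assert len(tips) == n
            assert len(list(tree.postorder())) == 2 * n - 1
            for node in tree.non_tips(include_self=True):
                assert len(node.children) == 2
            for node in tree.postorder():
                if node.parent is not None:
                    assert 0.0 <= node.length <= 1.0

    def test_two_tips_unique_topology(self, rng):
        tree = random_rooted_tree(2, rng)
        assert sorted(t.name for t in tree.tips()) == ["t1", "t2"]

    def test_root_split_sizes_uniform(self, rng):
        # left-subtree size at the root should be uniform on {1..9} for n=10
        counts = np.zeros(9)
        for _ in range(10000):
            tree = random_rooted_tree(10, rng)
            left = len(list(tree.children[0].tips()) or [tree.children[0]])
            counts[left - 1] += 1
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        # chi2 critical value, 8 df, alpha=0.01
        assert chi2 < 20.09

    def test_too_few_tips_rejected(self, rng):
        with pytest.raises(ValueError):
            random_rooted_tree(1, rng)


class TestDistanceTreeAndRooting:
    def test_nj_recovers_additive_four_taxon_topology(self):
        # additive distances on ((A,B),(C,D)): d(A,B)=2, d(C,D)=2, cross=6
        seqs = {
            "A": "AAAAAAAAAA" * 5,
            "B": "AAAAAAAAAC" * 5,
            "C": "GGGGGGGGGG" * 5,
            "D": "GGGGGGGGGT" * 5,
        }
        tree = build_distance_tree(seqs)
        names = {frozenset(t.name for t in st.tips()) for st in tree.non_tips()}
        assert frozenset({"A", "B"}) in names or frozenset({"C", "D"}) in names

    def test_identical_sequences_give_zero_lengths(self):
        seqs = {x: "MSILKMSILK" for x in "ABC"}
        tree = build_distance_tree(seqs)
        assert all((n.length or 0.0) == 0.0 for n in tree.postorder())

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError):
            build_distance_tree({"A": "MM", "B": "MM"})

    def test_two_tip_midpoint_splits_path_evenly(self):
        tree = read_newick("(A:1,B:3);")
        rooted = midpoint_root(tree)
        dists = {t.name: rooted.distance(t) for t in rooted.tips()}
        assert dists["A"] == pytest.approx(2.0)
        assert dists["B"] == pytest.approx(2.0)

    def test_midpoint_idempotent(self):
        tree = read_newick("((A:1,B:1):0.5,(C:1,D:1):0.5);")
        rooted = midpoint_root(tree)
        again = midpoint_root(rooted)
        d1 = {t.name: rooted.distance(t) for t in rooted.tips()}
        d2 = {t.name: again.distance(t) for t in again.tips()}
        assert d1 == pytest.approx(d2)

    def test_midpoint_balances_longest_path(self, rng):
        for _ in range(10):
            tree = random_rooted_tree(8, rng)
            rooted = midpoint_root(tree)
            tip_dists = sorted(
                (rooted.distance(t) for t in rooted.tips()), reverse=True
            )
            diameter = max(
                a.distance(b)
                for a in rooted.tips()
                for b in rooted.tips()
            )
            assert tip_dists[0] == pytest.approx(diameter / 2, abs=1e-9)


class TestCooptionTest:
    def test_all_silk_null_is_degenerate_zero(self, rng):
        tree = random_rooted_tree(5, rng)
        states = {t.name: SILK for t in tree.tips()}
        res = cooption_test(tree, states, reps=20, rng=rng)
        assert res.observed == 0
        assert res.mean == 0.0
        assert res.sd == 0.0
        assert res.degenerate

    def test_reproducible_under_fixed_seed(self, rng):
        tree = random_rooted_tree(10, rng)
        states = _random_states(tree, rng)
        r1 = cooption_test(tree, states, reps=15, rng=np.random.default_rng(7))
        r2 = cooption_test(tree, states, reps=15, rng=np.random.default_rng(7))
        assert r1.null_counts == r2.null_counts
        assert r1.observed == r2.observed

    def test_single_origin_family_observed_below_null(self):
        # a clustered (single-origin) silk clade should show fewer gains than
        # the same labels scattered over random trees
        from silkshift.simulate import FamilySpec, simulate_family

        wins = 0
        for seed in range(12):
            fam = simulate_family(
                FamilySpec(n_tips=20, n_silk_tips=8, n_origins=1), seed=seed
            )
            res = cooption_test(
                fam.tree, fam.tip_states, reps=30, rng=np.random.default_rng(seed)
            )
            assert res.observed >= 1
            if res.observed < res.mean:
                wins += 1
        assert wins >= 11

    def test_empirical_p_uses_add_one_smoothing(self, rng):
        tree = random_rooted_tree(6, rng)
        states = {t.name: SILK if i < 3 else NON_SILK for i, t in enumerate(tree.tips())}
        res = cooption_test(tree, states, reps=10, rng=rng)
        assert 1 / 11 <= res.p_empirical <= 1.0


class TestNullMonotonicity:
    def test_null_mean_non_decreasing_in_silk_tips(self, rng):
        # more silk tips scattered on random trees cannot make gains rarer
        n = 20
        means = []
        for n_silk in (1, 3, 5, 8):
            counts = []
            for _ in range(60):
                tree = random_rooted_tree(n, rng)
                names = [t.name for t in tree.tips()]
                silk_set = rng.choice(names, size=n_silk, replace=False)
                states = {x: (SILK if x in silk_set else NON_SILK) for x in names}
                c, _ = phylo.reconstruct_and_count(tree, states)
                counts.append(c)
            means.append(np.mean(counts))
        assert all(b >= a - 0.5 for a, b in zip(means, means[1:]))
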