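import numpy as np
import pytest

from phylodiff.felsenstein import (
    ColumnModelMap,
    LeafProfiles,
    PhyloTree,
    TreeError,
    brute_force_likelihood,
    loglik_and_grad,
    pruning_forward,
    reverse_pass,
)
from phylodiff.io_cli import read_newick_string
from phylodiff.matexp_grad import expm_spectral
from phylodiff.reversible_model import ReversibleParams, spectral_decompose
from phylodiff.simulate import SimSpec, random_tree, simulate_alignment

from conftest import make_params


def one_hot(n, idx):
    v = np.zeros(n)
    v[idx] = 1.0
    return v


def global_map(params, normalize=False):
    return ColumnModelMap.global_model(spectral_decompose(params, normalize=normalize))


def random_instance(num_taxa, num_cols, n, rng, mean=0.2, normalize=False):
    seed = int(rng.integers(2**31 - 1))
    tree = random_tree(SimSpec(num_taxa, num_cols, mean, seed))
    params = make_params(n, rng)
    sf = spectral_decompose(params, normalize=normalize)
    sim_map = ColumnModelMap([sf], np.zeros(num_cols, dtype=int))
    profiles, _ = simulate_alignment(tree, sim_map, seed + 1)
    return tree, profiles, ColumnModelMap.global_model(sf), params


class TestPruningForward:
    def test_single_leaf_at_root_gives_log_pi(self, params4):
        # root with one child at distance 0, one-hot residue a
        tree = PhyloTree(np.array([-1, 0]), np.array([0.0, 0.0]), [None, "A"])
        for a in range(4):
            profiles = LeafProfiles(["A"], one_hot(4, a)[None, None, :])
            col, _ = pruning_forward(tree, profiles, global_map(params4))
            assert col[0] == pytest.approx(np.log(params4.pi[a]), rel=1e-12)

    def test_all_unknown_column_has_likelihood_one(self, params4):
        tree = read_newick_string("(A:0.1,(B:0.2,C:0.3):0.4);")
        profiles = LeafProfiles(["A", "B", "C"], np.ones((3, 2, 4)))
        col, _ = pruning_forward(tree, profiles, global_map(params4))
        np.testing.assert_allclose(col, 0.0, atol=1e-12)

    def test_two_leaf_closed_form(self, params4, rng):
        t1, t2 = 0.3, 0.9
        tree = read_newick_string(f"(A:{t1},B:{t2});")
        sf = spectral_decompose(params4)
        x, y = 1, 3
        profiles = LeafProfiles(
            ["A", "B"], np.stack([one_hot(4, x)[None], one_hot(4, y)[None]])
        )
        col, _ = pruning_forward(tree, profiles, ColumnModelMap.global_model(sf))
        p1, p2 = expm_spectral(sf, t1), expm_spectral(sf, t2)
        expected = np.log(np.sum(params4.pi * p1[:, x] * p2[:, y]))
        assert col[0] == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("num_taxa", [4, 5])
    def test_matches_brute_force_enumeration(self, num_taxa, rng):
        for _ in range(10):
            tree, profiles, models, _ = random_instance(num_taxa, 3, 4, rng)
            col, _ = pruning_forward(tree, profiles, models)
            bf = brute_force_likelihood(tree, profiles, models)
            np.testing.assert_allclose(col, bf, rtol=1e-10)

    def test_ambiguity_profiles_match_brute_force(self, rng):
        tree, profiles, models, _ = random_instance(4, 4, 4, rng)
        prof = profiles.profiles.copy()
        prof[0, 0] = [1, 0, 1, 0]  # purine-style indicator
        prof[1, 2] = 1.0  # gap
        profiles = LeafProfiles(profiles.taxa, prof)
        col, _ = pruning_forward(tree, profiles, models)
        bf = brute_force_likelihood(tree, profiles, models)
        np.testing.assert_allclose(col, bf, rtol=1e-10)

    def test_multifurcating_root_matches_brute_force(self, rng):
        tree = read_newick_string("(A:0.1,B:0.3,(C:0.2,D:0.15):0.25);")
        params = make_params(4, rng)
        models = global_map(params)
        sim = ColumnModelMap(models.specs, np.zeros(5, dtype=int))
        profiles, _ = simulate_alignment(tree, sim, 99)
        col, _ = pruning_forward(tree, profiles, models)
        bf = brute_force_likelihood(tree, profiles, models)
        np.testing.assert_allclose(col, bf, rtol=1e-10)

    def test_rerooting_invariance(self, rng):
        # pulley principle: likelihood of a reversible model does not depend
        # on where the root sits along an edge
        params = make_params(4, rng)
        a, b, c, d, e, f = 0.11, 0.23, 0.17, 0.31, 0.09, 0.27
        center = read_newick_string(f"((A:{a},B:{b}):{c},(C:{d},D:{e}):{f});")
        unrooted = read_newick_string(f"(A:{a},B:{b},(C:{d},D:{e}):{c + f});")
        shifted = read_newick_string(
            f"((B:{b},(C:{d},D:{e}):{c + f}):{a * 0.25},A:{a * 0.75});"
        )
        sim = ColumnModelMap([spectral_decompose(params)], np.zeros(6, dtype=int))
        profiles, _ = simulate_alignment(center, sim, 5)
        lls = []
        for tree in (center, unrooted, shifted):
            col, _ = pruning_forward(tree, profiles, global_map(params))
            lls.append(col)
        np.testing.assert_allclose(lls[1], lls[0], rtol=1e-10)
        np.testing.assert_allclose(lls[2], lls[0], rtol=1e-10)

    def test_taxon_mismatch_raises(self, params4):
        tree = read_newick_string("(A:0.1,B:0.2);")
        profiles = LeafProfiles(["A", "X"], np.ones((2, 1, 4)))
        with pytest.raises(TreeError, match="mismatch"):
            pruning_forward(tree, profiles, global_map(params4))

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            LeafProfiles(["A"], np.zeros((1, 1, 4)))

    def test_column_weights_scale_loglik_and_gradients(self, rng):
        tree, profiles, models, _ = random_instance(5, 4, 4, rng)
        w = np.array([1.0, 2.0, 3.0, 0.5])
        weighted = LeafProfiles(profiles.taxa, profiles.profiles, w)
        b1 = loglik_and_grad(tree, weighted, models)
        # oracle: duplicate columns according to weight using integer weights
        w_int = np.array([1, 2, 3, 1])
        reps = np.repeat(np.arange(4), w_int)
        expanded = LeafProfiles(profiles.taxa, profiles.profiles[:, reps])
        b2 = loglik_and_grad(tree, expanded, models)
        half_col3 = loglik_and_grad(
            tree, LeafProfiles(profiles.taxa, profiles.profiles[:, [3]], np.array([0.5])), models
        )
        assert b1.loglik == pytest.approx(
            b2.loglik - half_col3.loglik, rel=1e-12
        )
        np.testing.assert_allclose(
            b1.g_exch[0], b2.g_exch[0] - half_col3.g_exch[0], rtol=1e-9
        )


class TestReversePass:
    def test_all_unknown_columns_have_zero_gradients(self, params4):
        tree = read_newick_string("(A:0.1,(B:0.2,C:0.3):0.4);")
        profiles = LeafProfiles(["A", "B", "C"], np.ones((3, 2, 4)))
        b = loglik_and_grad(tree, profiles, global_map(params4))
        # dL/dQ vanishes along every admissible direction (zero row sums):
        # its rows are constant, so <g_q, dQ> = 0 whenever dQ rows sum to 0
        np.testing.assert_allclose(b.g_q[0] - b.g_q[0][:, :1], 0.0, atol=1e-12)
        np.testing.assert_allclose(b.g_exch[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(b.g_sqrt_pi[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(b.g_t, 0.0, atol=1e-12)

    @pytest.mark.parametrize("n,num_taxa,num_cols", [(4, 8, 6), (4, 16, 3), (20, 4, 2)])
    @pytest.mark.parametrize("normalize", [False, True])
    def test_gradients_match_finite_differences(self, n, num_taxa, num_cols, normalize, rng):
        tree, profiles, models, params = random_instance(
            num_taxa, num_cols, n, rng, normalize=normalize
        )
        b = loglik_and_grad(tree, profiles, models)

        def loglik(pp, lengths=None):
            t2 = tree if lengths is None else PhyloTree(tree.parent, lengths, tree.names)
            m = ColumnModelMap.global_model(spectral_decompose(pp, normalize=normalize))
            col, _ = pruning_forward(t2, profiles, m)
            return float(col.sum())

        h = 1e-6
        k = n * (n - 1) // 2
        check = rng.choice(k, size=min(k, 8), replace=False)
        for i in check:
            e = params.exch.copy()
            e[i] += h
            hi = loglik(ReversibleParams(n, e, params.sqrt_pi))
            e[i] -= 2 * h
            lo = loglik(ReversibleParams(n, e, params.sqrt_pi))
            fd = (hi - lo) / (2 * h)
            assert fd == pytest.approx(b.g_exch[0][i], rel=1e-6, abs=1e-7)
        for i in range(min(n, 6)):
            r = params.sqrt_pi.copy()
            r[i] += h
            hi = loglik(ReversibleParams(n, params.exch, r))
            r[i] -= 2 * h
            lo = loglik(ReversibleParams(n, params.exch, r))
            fd = (hi - lo) / (2 * h)
            assert fd == pytest.approx(b.g_sqrt_pi[0][i], rel=1e-6, abs=1e-7)
        for node in range(tree.num_nodes):
            if node == tree.root:
                continue
            l = tree.lengths.copy()
            l[node] += h
            hi = loglik(params, l)
            l[node] -= 2 * h
            lo = loglik(params, l)
            fd = (hi - lo) / (2 * h)
            assert fd == pytest.approx(b.g_t[node], rel=1e-6, abs=1e-7)

    def test_per_column_models_do_not_leak_across_columns(self, rng):
        tree, profiles, _, _ = random_instance(5, 2, 4, rng)
        pa, pb = make_params(4, rng), make_params(4, rng)
        specs = [spectral_decompose(pa), spectral_decompose(pb)]
        both = loglik_and_grad(tree, profiles, ColumnModelMap.per_column(specs))
        for m in range(2):
            alone = loglik_and_grad(
                tree,
                LeafProfiles(profiles.taxa, profiles.profiles[:, [m]]),
                ColumnModelMap.global_model(specs[m]),
            )
            np.testing.assert_allclose(both.g_q[m], alone.g_q[0], rtol=1e-12, atol=1e-15)
            np.testing.assert_allclose(both.g_exch[m], alone.g_exch[0], rtol=1e-12, atol=1e-15)

    def test_unused_model_gets_zero_gradient(self, rng):
        tree, profiles, _, _ = random_instance(4, 2, 4, rng)
        specs = [spectral_decompose(make_params(4, rng)) for _ in range(3)]
        models = ColumnModelMap(specs, np.array([0, 0]))
        b = loglik_and_grad(tree, profiles, models)
        np.testing.assert_array_equal(b.g_q[1], 0.0)
        np.testing.assert_array_equal(b.g_q[2], 0.0)

    def test_gradient_additivity_over_columns(self, rng):
        tree, profiles, models, _ = random_instance(6, 4, 4, rng)
        whole = loglik_and_grad(tree, profiles, models)
        parts = [
            loglik_and_grad(
                tree, LeafProfiles(profiles.taxa, profiles.profiles[:, [c]]), models
            )
            for c in range(4)
        ]
        np.testing.assert_allclose(
            whole.g_exch[0], np.sum([p.g_exch[0] for p in parts], axis=0), rtol=1e-9
        )
        np.testing.assert_allclose(
            whole.g_t, np.sum([p.g_t for p in parts], axis=0), rtol=1e-9, atol=1e-12
        )

    def test_global_path_equals_per_column_path_with_shared_model(self, rng):
        tree, profiles, models, params = random_instance(6, 5, 4, rng)
        sf = models.specs[0]
        shared = ColumnModelMap([sf], np.zeros(5, dtype=int))
        a = loglik_and_grad(tree, profiles, models)  # assignment=None fast path
        bperc = loglik_and_grad(tree, profiles, shared)
        assert a.loglik == pytest.approx(bperc.loglik, rel=1e-12)
        np.testing.assert_allclose(a.g_q[0], bperc.g_q[0], rtol=1e-12, atol=1e-15)
        np.testing.assert_allclose(a.g_t, bperc.g_t, rtol=1e-12, atol=1e-15)

    def test_composition_is_deterministic(self, rng):
        tree, profiles, models, _ = random_instance(6, 3, 4, rng)
        b1 = loglik_and_grad(tree, profiles, models)
        b2 = loglik_and_grad(tree, profiles, models)
        assert b1.loglik == b2.loglik
        np.testing.assert_array_equal(b1.g_exch[0], b2.g_exch[0])
        np.testing.assert_array_equal(b1.g_t, b2.g_t)


def test_reverse_pass_scales_roughly_linearly_in_leaf_count(rng):
    # coarse sanity check, not a benchmark: doubling leaves should not blow
    # up the per-call time by more than ~2.5x
    import time

    params = make_params(4, rng)

    def time_for(num_taxa):
        tree, profiles, models, _ = random_instance(num_taxa, 50, 4, rng)
        loglik_and_grad(tree, profiles, models)  # warm up
        best = np.inf
        for _ in range(3):
            t0 = time.perf_counter()
            loglik_and_grad(tree, profiles, models)
            best = min(best, time.perf_counter() - t0)
        return best

    t64, t128 = time_for(64), time_for(128)
    assert t128 / t64 < 2.5


def test_brute_force_rejects_large_trees(rng):
    tree, profiles, models, _ = random_instance(8, 1, 4, rng)
    with pytest.raises(TreeError):
        brute_force_likelihood(tree, profiles, models)


def test_zero_branch_lengths_identical_leaves(rng):
    params = make_params(4, rng)
    tree = read_newick_string("((A:0.0,B:0.0):0.0,C:0.0);")
    prof = np.zeros((3, 1, 4))
    prof[:, 0, 2] = 1.0
    profiles = LeafProfiles(["A", "B", "C"], prof)
    col, _ = pruning_forward(tree, profiles, global_map(params))
    assert col[0] == pytest.approx(np.log(params.pi[2]), rel=1e-12)
    bf = brute_force_likelihood(tree, profiles, global_map(params))
    assert bf[0] == pytest.approx(col[0], rel=1e-12)
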