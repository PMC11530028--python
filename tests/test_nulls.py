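"""Fingerprint substitution, degree-preserving rewiring, max-T inference."""

import numpy as np
import pytest

import activityflow as af


def _random_fc(n=40, density=0.15, seed=0):
    rng = np.random.default_rng(seed)
    W = (rng.random((n, n)) < density) * rng.normal(0, 1, (n, n))
    np.fill_diagonal(W, 0.0)
    return W


class TestSubstitution:
    def test_identity_substitution_zeroes_self_block(self, model):
        t = model.complex_units("EBA_FBA")
        out = af.substitute_fingerprint(model.weights, t, t)
        assert np.all(out.weights[np.ix_(t, t)] == 0)
        other = np.setdiff1d(np.arange(model.n_units), t)
        np.testing.assert_array_equal(out.weights[np.ix_(other, other)],
                                      model.weights[np.ix_(other, other)])

    def test_target_rows_become_donor_rows(self, model):
        t = model.complex_units("EBA_FBA")
        d = model.complex_units("FFA_pSTS")
        out = af.substitute_fingerprint(model.weights, t, d)
        neither = np.setdiff1d(np.arange(model.n_units),
                               np.concatenate([t, d]))
        np.testing.assert_array_equal(out.weights[np.ix_(t, neither)],
                                      model.weights[np.ix_(d, neither)])
        # donor-column entries are the transposed original estimates
        np.testing.assert_array_equal(out.weights[np.ix_(t, d)],
                                      model.weights[np.ix_(d, t)].T)
        assert np.all(out.weights[np.ix_(t, t)] == 0)
        assert np.all(np.diag(out.weights) == 0)

    def test_rows_outside_both_blocks_untouched(self, model):
        t = model.complex_units("PPA_RSC")
        d = model.complex_units("LOC")
        out = af.substitute_fingerprint(model.weights, t, d)
        others = np.setdiff1d(np.arange(model.n_units), t)
        np.testing.assert_array_equal(out.weights[others],
                                      model.weights[others])

    def test_overlapping_complexes_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            af.substitute_fingerprint(np.zeros((6, 6)), [0, 1], [1, 2])

    def test_unequal_sizes_rejected(self):
        with pytest.raises(ValueError, match="sizes"):
            af.substitute_fingerprint(np.zeros((6, 6)), [0, 1], [2, 3, 4])

    def test_true_fingerprint_beats_donors(self):
        # direction of the fingerprint-substitution control: mapped
        # selectivity is highest under the complex's own fingerprint
        cfg = af.SimulationConfig(seed=5, n_participants=12)
        m = af.generate_ground_truth(cfg)
        ds = af.simulate_task(m, cfg, include_bold=False)
        names = list(m.complexes)
        for name in names:
            cx = m.complexes[name]
            cat = cx["category"]
            cc = cfg.category_conditions[cat]
            nc = af.noncategory_conditions(cfg.category_conditions, cat)

            def mapped_sel(fc, p):
                act = ds.truth_activations[p]
                fm = af.map_activity(act, fc, targets=cx["units"])
                full = act.copy()
                full[cx["units"]] = fm.mapped
                _, ms = af.category_selectivity(
                    act, full, cc, nc, units=cx["units"],
                    unit_aggregation="average-then-ratio",
                )
                return ms

            true = np.mean([mapped_sel(m.weights, p) for p in range(12)])
            for donor in names:
                if donor == name:
                    continue
                fc_null = af.substitute_fingerprint(
                    m.weights, cx["units"], m.complexes[donor]["units"]
                )
                null = np.mean([mapped_sel(fc_null, p) for p in range(12)])
                assert true > null


class TestPermutedArchitecture:
    def test_weight_multiset_and_degrees_preserved(self):
        W = _random_fc(seed=1)
        nulls = af.permute_architecture(W, n_perms=3, seed=0)
        for variant in nulls.variants:
            V = variant.weights
            np.testing.assert_allclose(
                np.sort(V[V != 0]), np.sort(W[W != 0])
            )
            np.testing.assert_array_equal((V != 0).sum(axis=1),
                                          (W != 0).sum(axis=1))
            np.testing.assert_array_equal((V != 0).sum(axis=0),
                                          (W != 0).sum(axis=0))
            assert np.all(np.diag(V) == 0)

    def test_architecture_actually_changes(self):
        W = _random_fc(n=100, density=0.1, seed=2)
        nulls = af.permute_architecture(W, n_perms=5, seed=3)
        n_edges = np.count_nonzero(W)
        for variant in nulls.variants:
            shared = np.count_nonzero((variant.weights != 0) & (W != 0))
            assert shared / n_edges < 0.5

    def test_mask_respected(self):
        W = _random_fc(n=30, seed=4)
        mask = np.zeros_like(W, dtype=bool)
        mask[:, 5] = True  # unit 5 can never be a source
        W[mask] = 0.0
        fc = af.FCMatrix(weights=W, mask=mask)
        nulls = af.permute_architecture(fc, n_perms=3, seed=5)
        for variant in nulls.variants:
            assert np.all(variant.weights[mask] == 0)

    def test_degenerate_graph_rejected(self):
        W = np.ones((5, 5)) - np.eye(5)  # complete: nothing to swap
        with pytest.raises(ValueError, match="rewire|edges"):
            af.permute_architecture(W, n_perms=1, seed=0)


class TestMaxT:
    def test_identical_values_give_p_one(self):
        data = np.zeros((10, 4))  # zero paired differences everywhere
        res = af.maxt_test(data, scheme="paired", n_perm=500, seed=0)
        np.testing.assert_array_equal(res.corrected_p, 1.0)

    def test_corrected_p_bounds(self):
        rng = np.random.default_rng(1)
        res = af.maxt_test(rng.normal(size=(20, 6)), n_perm=200, seed=2)
        assert np.all(res.corrected_p >= 1 / 201)
        assert np.all(res.corrected_p <= 1.0)

    def test_max_statistic_p_equals_its_own_permutation_p(self):
        rng = np.random.default_rng(3)
        data = rng.normal(0.2, 1.0, size=(30, 5))
        res = af.maxt_test(data, n_perm=1000, seed=4)
        k = np.argmax(res.observed_t)
        direct = (1 + (res.maxt_distribution >= res.observed_t[k]).sum()) / (
            1 + res.n_permutations
        )
        assert res.corrected_p[k] == pytest.approx(direct)

    def test_power_for_large_effect(self):
        rng = np.random.default_rng(5)
        data = rng.normal(0, 1, size=(50, 3))
        data[:, 0] += 2.0  # standardized effect ~2
        res = af.maxt_test(data, n_perm=1000, seed=6)
        assert res.corrected_p[0] < 0.01

    def test_threshold_is_null_quantile(self):
        rng = np.random.default_rng(7)
        res = af.maxt_test(rng.normal(size=(25, 4)), n_perm=400,
                           alpha=0.1, seed=8)
        assert res.threshold == pytest.approx(
            np.quantile(res.maxt_distribution, 0.9)
        )

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            af.maxt_test(np.zeros((5, 2)), scheme="bootstrap")

    def test_nonzero_null_mean(self):
        rng = np.random.default_rng(9)
        data = rng.normal(50.0, 5.0, size=(40, 2))  # true mean = null mean
        res = af.maxt_test(data, null_mean=50.0, n_perm=500, seed=10)
        assert np.all(res.corrected_p > 0.01)
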