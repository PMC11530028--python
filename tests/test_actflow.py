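"""Activity-flow mapping variants and accuracy scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import activityflow as af
from activityflow.config import DivergenceError


def _fc3():
    # one target (unit 0) fed by three sources with fixed weights
    W = np.zeros((4, 4))
    W[0, 1:] = [0.5, 1.0, -2.0]
    return W


class TestMapActivity:
    def test_weighted_sum_arithmetic(self):
        acts = np.array([[0.0], [2.0], [-1.0], [0.5]])
        out = af.map_activity(acts, _fc3(), targets=[0])
        assert out.mapped[0, 0] == pytest.approx(-1.0)

    def test_zero_sources_map_to_zero(self):
        out = af.map_activity(np.zeros((4, 3)), _fc3(), targets=[0])
        np.testing.assert_array_equal(out.mapped, 0.0)

    def test_flows_sum_to_mapped(self, model, dataset):
        out = af.map_activity(dataset.truth_activations[0], model.weights,
                              targets=model.target_units)
        np.testing.assert_allclose(out.flows.sum(axis=1), out.mapped,
                                   atol=1e-12)

    def test_target_never_its_own_source(self, model, dataset):
        acts = dataset.truth_activations[0].copy()
        W = model.weights.copy()
        W[5, 5] = 99.0  # corrupt the diagonal
        out = af.map_activity(acts, W, targets=[5])
        assert not out.source_mask[0, 5]
        assert np.all(out.flows[0, 5, :] == 0)

    def test_explicit_circularity_rejected(self):
        with pytest.raises(ValueError, match="source set"):
            af.map_activity(np.zeros((4, 2)), _fc3(), targets=[1],
                            sources=[1, 2])

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_linearity(self, seed):
        rng = np.random.default_rng(seed)
        W = rng.normal(size=(6, 6))
        a = rng.normal(size=(6, 3))
        b = rng.normal(size=(6, 3))
        mab = af.map_activity(a + b, W).mapped
        ma = af.map_activity(a, W).mapped
        mb = af.map_activity(b, W).mapped
        np.testing.assert_allclose(mab, ma + mb, atol=1e-9)


class TestV1Map:
    def test_single_source_centering(self):
        W = np.zeros((2, 2))
        W[1, 0] = 0.7
        acts = np.array([[3.0], [0.0]])
        # one V1 vertex: its own mean is itself, so centered drive is 0
        out = af.v1_initialized_map(acts, W, v1_units=[0], targets=[1],
                                    center_conditions=[0])
        assert out[0, 0] == pytest.approx(0.0)
        out2 = af.v1_initialized_map(acts, W, v1_units=[0], targets=[1])
        assert out2[0, 0] == pytest.approx(0.7 * 3.0)

    def test_uniform_v1_maps_to_zero(self):
        W = np.zeros((3, 3))
        W[2, 0] = 1.5
        W[2, 1] = -0.4
        acts = np.array([[2.0], [2.0], [0.0]])
        out = af.v1_initialized_map(acts, W, v1_units=[0, 1], targets=[2],
                                    center_conditions=[0])
        assert out[0, 0] == pytest.approx(0.0)

    def test_two_source_arithmetic(self):
        acts = np.array([[3.0], [1.0], [0.0]])
        W = np.zeros((3, 3))
        W[2, 0] = W[2, 1] = 1.0
        out = af.v1_initialized_map(acts, W, v1_units=[0, 1], targets=[2],
                                    center_conditions=[0])
        assert out[0, 0] == pytest.approx(0.0)  # weights [1, 1]
        W[2, 1] = -1.0
        out = af.v1_initialized_map(acts, W, v1_units=[0, 1], targets=[2],
                                    center_conditions=[0])
        assert out[0, 0] == pytest.approx(2.0)  # weights [1, -1]

    def test_empty_v1_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            af.v1_initialized_map(np.zeros((3, 1)), np.zeros((3, 3)),
                                  v1_units=[], targets=[2])

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            af.v1_initialized_map(np.zeros((3, 1)), np.zeros((3, 3)),
                                  v1_units=[0, 1], targets=[1])


class TestPropagate:
    def _system(self, rho, seed=0, n=20):
        rng = np.random.default_rng(seed)
        W = rng.normal(size=(n, n))
        np.fill_diagonal(W, 0.0)
        W *= rho / max(abs(np.linalg.eigvals(W)))
        x0 = rng.normal(size=(n, 3))
        return W, x0

    def test_zero_fc_pure_relaxation_settles_to_zero(self):
        x0 = np.ones((4, 2))
        tr = af.propagate(x0, np.zeros((4, 4)), inject=False)
        assert tr.settled
        np.testing.assert_array_equal(tr.final, 0.0)

    def test_zero_fc_injected_settles_at_input(self):
        x0 = np.ones((4, 2))
        tr = af.propagate(x0, np.zeros((4, 4)))
        assert tr.settled and tr.settle_step == 1
        np.testing.assert_array_equal(tr.final, x0)

    def test_fixed_point_matches_closed_form(self):
        W, x0 = self._system(0.5)
        tr = af.propagate(x0, W)
        assert tr.settled
        closed = np.linalg.solve(np.eye(len(W)) - W, x0)
        rel = np.abs(tr.final - closed).max() / np.abs(closed).max()
        assert rel < 1e-3
        # settled state is a fixed point of the injected recurrence
        np.testing.assert_allclose(W @ tr.final + x0, tr.final, atol=1e-3)

    def test_divergence_reports_spectral_radius(self):
        W, x0 = self._system(1.5)
        with pytest.raises(DivergenceError, match="1.5"):
            af.propagate(x0, W)

    def test_trace_settle_step_is_first_below_tolerance(self):
        W, x0 = self._system(0.5, seed=3)
        tr = af.propagate(x0, W, tolerance=0.5e-4)
        deltas = [
            np.abs(b - a).max() for a, b in zip(tr.steps, tr.steps[1:])
        ]
        below = [i + 1 for i, d in enumerate(deltas) if d < 0.5e-4]
        assert tr.settle_step == below[0]


class TestTwoStep:
    def test_self_exclusion_zero_case(self):
        # region-level fc rows that are one-hot on self map to zero
        n = 4
        acts = np.random.default_rng(0).normal(size=(n, 2))
        fc_region = np.eye(n)  # diagonal is removed by the circularity guard
        out = af.two_step_map(
            acts, fc_vertex=np.zeros((n, n)), fc_region=fc_region,
            v1_units=[0], vis_units=[2, 3],
            vertex_to_region={2: 2, 3: 3},
            region_activations=acts, region_targets=[1],
        )
        np.testing.assert_array_equal(out, 0.0)

    def test_single_driver_region(self):
        # region 1 wholly driven by region 2 with weight 1: step-2 output
        # equals region 2's step-1 aggregated value
        n = 4
        fc_vertex = np.zeros((n, n))
        fc_vertex[2, 0] = 2.0  # V1 (unit 0) drives vertex 2
        fc_region = np.zeros((n, n))
        fc_region[1, 2] = 1.0
        acts = np.zeros((n, 1))
        acts[0, 0] = 3.0
        out = af.two_step_map(
            acts, fc_vertex=fc_vertex, fc_region=fc_region,
            v1_units=[0], vis_units=[2],
            vertex_to_region={2: 2},
            region_activations=acts.copy(), region_targets=[1],
        )
        assert out[0, 0] == pytest.approx(6.0)

    def test_missing_aggregation_rejected(self):
        with pytest.raises(ValueError, match="aggregation"):
            af.two_step_map(
                np.zeros((3, 1)), np.zeros((3, 3)), np.zeros((3, 3)),
                v1_units=[0], vis_units=[2], vertex_to_region={},
                region_activations=np.zeros((3, 1)), region_targets=[1],
            )

    def test_two_step_beats_v1_only_on_pure_flow_truth(self, model):
        cfg = af.SimulationConfig(seed=7, n_participants=3, local_fraction=0.0)
        ds = af.simulate_task(model, cfg, include_bold=False)
        t = model.target_units
        ident = {int(u): int(u) for u in range(model.n_units)}
        vis = np.setdiff1d(np.arange(model.n_units), model.v1_units)
        r_v1, r_two = [], []
        for p in range(cfg.n_participants):
            act = ds.truth_activations[p]
            v1_map = af.v1_initialized_map(act, model.weights,
                                           model.v1_units, targets=t)
            two = af.two_step_map(
                act, fc_vertex=model.weights, fc_region=model.weights,
                v1_units=model.v1_units, vis_units=vis,
                vertex_to_region=ident,
                region_activations=act, region_targets=t,
            )
            truth = ds.truth_activations[p][t]
            r_v1.append(np.corrcoef(truth.ravel(), v1_map.ravel())[0, 1])
            r_two.append(np.corrcoef(truth.ravel(), two.ravel())[0, 1])
        assert np.mean(r_two) > np.mean(r_v1)


class TestAccuracy:
    def test_perfect_mapping(self):
        a = np.arange(12.0).reshape(3, 4)
        rep = af.accuracy(a, a.copy())
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.mae == pytest.approx(0.0)
        assert rep.r_squared == pytest.approx(1.0)

    def test_constant_offset_closed_form(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        c = 0.5
        rep = af.accuracy(a, a + c)
        ss_tot = ((a - a.mean()) ** 2).sum()
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.mae == pytest.approx(c)
        assert rep.r_squared == pytest.approx(1 - len(a) * c**2 / ss_tot)

    def test_sign_flip_gives_negative_r(self):
        a = np.array([1.0, -2.0, 3.0])
        assert af.accuracy(a, -a).pearson_r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            af.accuracy(np.ones(5), np.arange(5.0))

    def test_participant_averaging(self):
        a1, a2 = np.array([1.0, 2.0, 3.0]), np.array([1.0, 3.0, 5.0])
        rep = af.accuracy([a1, a2], [a1 + 1.0, a2 + 3.0])
        assert rep.mae == pytest.approx(2.0)
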