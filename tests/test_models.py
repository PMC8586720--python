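"""The 28-model family: parameter accounting, update rules, simulation."""

import numpy as np
import pytest

from reachlearn.kinematics import EACondition, EA_NORMAL
from reachlearn.models import (
    MODEL_IDS,
    LearningCurveSet,
    ModelParams,
    ModelSpec,
    TrialEntry,
    TrialSchedule,
    count_free_parameters,
    delta_f,
    generalized_error,
    initial_state,
    perceived_error,
    separation_deg,
    simulate_learning_curves,
    step,
)

# printed free-parameter counts for every candidate structure
PRINTED_COUNTS = {
    "ds.1.1G": 18, "ds.1.3": 24, "ds.1.2": 18, "ds.1.1": 12, "ds.1.1L": 6,
    "ds.2.1": 18, "ds.3.1": 24, "ds.4.1": 30, "ds.5.1": 36, "ds.6.1": 42,
    "ds.7.1": 48, "ds.8.1": 54, "ds.2.2": 24, "ds.3.2": 30, "ds.4.2": 36,
    "g.1.3": 29, "g.1.2": 23, "g.1.1": 17, "g.1.1L": 11, "g.2.1": 23, "g.3.1": 29,
    "m.1.3": 35, "m.1.2": 29, "m.1.1": 23, "m.1.1L": 17, "m.2.1": 29,
    "m.3.1": 35, "m.4.1": 41,
}


def constant_schedule(direction=1, n=100, ea=EA_NORMAL, vision=True):
    return TrialSchedule.constant_ea(
        np.full(n, direction), np.full(n, vision, dtype=bool), ea)


class TestModelRegistry:
    def test_exactly_28_structures(self):
        assert len(MODEL_IDS) == 28
        assert set(MODEL_IDS) == set(PRINTED_COUNTS)

    @pytest.mark.parametrize("model_id, expected", sorted(PRINTED_COUNTS.items()))
    def test_free_parameter_counts(self, model_id, expected):
        assert count_free_parameters(ModelSpec.from_id(model_id)) == expected

    @pytest.mark.parametrize("bad", ["ds.2.3", "g.4.1", "m.5.1", "g.1.1G", "x.1.1"])
    def test_invalid_structures_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelSpec.from_id(bad)

    def test_vector_round_trip_all_models(self, rng):
        for mid in MODEL_IDS:
            spec = ModelSpec.from_id(mid)
            n = count_free_parameters(spec)
            vec = rng.uniform(0.1, 0.5, n) * rng.choice([-1.0, 1.0], n)
            if spec.has_h:   # widths must be nonzero; keep them positive
                vec[-spec.n_directions:] = np.abs(vec[-spec.n_directions:])
            p = ModelParams.from_vector(spec, vec)
            np.testing.assert_array_equal(p.to_vector(), vec)
            assert len(p.parameter_names()) == n

    def test_w_bounds_enforced(self):
        spec = ModelSpec.from_id("m.1.1")
        with pytest.raises(ValueError, match="W"):
            ModelParams(spec=spec, w=np.array([0.0, 0.0, 1.5, 0.0, 0.0]))


class TestErrorTransforms:
    def test_perceived_error_normal_feedback(self):
        assert perceived_error(7.0, 99.0, EA_NORMAL, vision=True) == 7.0

    def test_perceived_error_augmented(self):
        assert perceived_error(3.0, 5.0, EACondition(2, 1), vision=True) == 11.0

    def test_perceived_error_zero_without_vision(self):
        assert perceived_error(3.0, 5.0, EACondition(3, 2), vision=False) == 0.0

    def test_generalized_error_identity_at_zero_separation(self):
        w = np.zeros(5)
        assert generalized_error(4.0, 0, w) == 4.0

    def test_generalized_error_scales_by_weight(self):
        w = np.array([0.0, 0.0, 0.5, 0.0, 0.0])  # W(60) = 0.5
        assert generalized_error(4.0, 60, w) == 2.0

    def test_generalized_error_rejects_off_grid_separation(self):
        with pytest.raises(ValueError):
            generalized_error(4.0, 90, np.zeros(5))

    def test_separation_wraps_to_sixty_degree_grid(self):
        seps = {separation_deg(d, p) for d in range(1, 7) for p in range(1, 7)}
        assert seps == {-120, -60, 0, 60, 120, 180}
        assert separation_deg(1, 2) == -60
        assert separation_deg(4, 1) == 180


class TestDeltaF:
    def test_linear_rate(self):
        spec = ModelSpec.from_id("ds.1.1L")
        p = ModelParams(spec=spec, b=np.full(6, -0.2))
        assert delta_f(spec, p, 1, [10.0]) == pytest.approx(-2.0)

    def test_second_order_history(self):
        spec = ModelSpec.from_id("ds.2.1")
        p = ModelParams(spec=spec, a=np.ones(6),
                        b=np.column_stack([np.full(6, -0.1), np.full(6, -0.05)]))
        # 1 + (-0.1)(10) + (-0.05)(20) = -1
        assert delta_f(spec, p, 3, [10.0, 20.0]) == pytest.approx(-1.0)

    def test_gaussian_rate_wide_width_limits_to_linear(self):
        """As H -> inf the Gaussian-weighted rate reduces to the linear model."""
        g = ModelSpec.from_id("ds.1.1G")
        lin = ModelSpec.from_id("ds.1.1L")
        pg = ModelParams(spec=g, a=np.zeros(6), b=np.full(6, -0.3), h=np.full(6, 1e6))
        pl = ModelParams(spec=lin, b=np.full(6, -0.3))
        for e in (0.5, 5.0, 25.0):
            assert delta_f(g, pg, 1, [e]) == pytest.approx(
                delta_f(lin, pl, 1, [e]), abs=1e-6)

    def test_gaussian_rate_shrinks_for_large_errors(self):
        g = ModelSpec.from_id("ds.1.1G")
        pg = ModelParams(spec=g, a=np.zeros(6), b=np.full(6, -0.3), h=np.full(6, 10.0))
        small = abs(delta_f(g, pg, 1, [5.0]) / 5.0)
        large = abs(delta_f(g, pg, 1, [30.0]) / 30.0)
        assert large < small

    def test_zero_gaussian_width_rejected(self):
        g = ModelSpec.from_id("ds.1.1G")
        with pytest.raises(ValueError, match="H"):
            ModelParams(spec=g, h=np.zeros(6))


class TestStep:
    def test_all_directions_update_under_momentum(self):
        """With a linear rate of -0.5 and all latent errors at 10, one trial
        halves every direction: the practiced one from its feedback, the
        others through the normal-feedback momentum rule."""
        spec = ModelSpec.from_id("ds.1.1L")
        p = ModelParams(spec=spec, b=np.full(6, -0.5))
        state = initial_state(spec, np.full(6, 10.0))
        new = step(spec, p, state, TrialEntry(1, True, EA_NORMAL))
        np.testing.assert_allclose(new.e, np.full(6, 5.0))

    def test_mixed_model_effective_rate_at_practiced_direction(self):
        """At the practiced direction W(0)=1, so the one-trial change is
        A + (B + Z) * e_hat."""
        spec = ModelSpec.from_id("m.1.1")
        a, b, z = 0.4, 0.1, -0.5
        p = ModelParams(spec=spec, a=np.full(6, a), b=np.full(6, b),
                        z=np.full(6, z), w=np.zeros(5))
        e = np.array([8.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        state = initial_state(spec, e)
        new = step(spec, p, state, TrialEntry(1, True, EA_NORMAL))
        assert new.e[0] - e[0] == pytest.approx(a + (b + z) * e[0])

    def test_no_vision_practiced_trial_changes_by_offset_only(self):
        spec = ModelSpec.from_id("ds.1.1")
        p = ModelParams(spec=spec, a=np.full(6, 0.7), b=np.full(6, -0.3))
        state = initial_state(spec, np.full(6, 10.0))
        new = step(spec, p, state, TrialEntry(2, False, EACondition(2, 1)))
        assert new.e[1] - 10.0 == pytest.approx(0.7)   # f(0) = A

    def test_repeat_delta_momentum_freezes_unpracticed_on_first_trial(self):
        spec = ModelSpec.from_id("ds.1.1")
        p = ModelParams(spec=spec, a=np.full(6, 0.5), b=np.full(6, -0.3))
        state = initial_state(spec, np.full(6, 10.0))
        new = step(spec, p, state, TrialEntry(1, True, EA_NORMAL),
                   momentum_mode="repeat_delta")
        assert new.e[0] != 10.0
        np.testing.assert_array_equal(new.e[1:], np.full(5, 10.0))


class TestSimulation:
    def test_zero_rate_keeps_curves_constant(self, schedule_250):
        spec = ModelSpec.from_id("ds.1.1L")
        p = ModelParams(spec=spec, b=np.zeros(6))
        e0 = np.array([20.0, -20, 20, -20, 20, -20])
        curves = simulate_learning_curves(spec, p, e0, schedule_250)
        np.testing.assert_array_equal(curves.latent, np.tile(e0, (250, 1)))

    def test_geometric_decay_closed_form(self):
        """Continuous practice of one direction under normal feedback decays
        as e0 * (1 + B)^n — and so does every unpracticed direction under
        the momentum rule."""
        spec = ModelSpec.from_id("ds.1.1L")
        b = -0.15
        p = ModelParams(spec=spec, b=np.full(6, b))
        e0 = np.array([20.0, -20, 10, -10, 5, -5])
        sched = constant_schedule(direction=1, n=60)
        curves = simulate_learning_curves(spec, p, e0, sched)
        n = np.arange(60)
        expected = e0[None, :] * (1 + b) ** n[:, None]
        np.testing.assert_allclose(curves.latent, expected, rtol=1e-12)

    def test_affine_fixed_point_minus_a_over_b(self):
        spec = ModelSpec.from_id("ds.1.1")
        a, b = 1.2, -0.3
        p = ModelParams(spec=spec, a=np.full(6, a), b=np.full(6, b))
        sched = constant_schedule(direction=1, n=400)
        curves = simulate_learning_curves(spec, p, np.full(6, 20.0), sched)
        np.testing.assert_allclose(curves.latent[-1], np.full(6, -a / b), atol=1e-9)

    def test_linear_stability_boundary(self):
        spec = ModelSpec.from_id("ds.1.1L")
        e0 = np.full(6, 10.0)
        sched = constant_schedule(direction=1, n=200)
        stable = simulate_learning_curves(
            spec, ModelParams(spec=spec, b=np.full(6, -0.5)), e0, sched)
        divergent = simulate_learning_curves(
            spec, ModelParams(spec=spec, b=np.full(6, 0.5)), e0, sched)
        assert np.all(np.abs(stable.latent) <= 10.0)
        assert np.max(np.abs(divergent.latent)) > 1e10

    def test_mixed_with_zero_generalization_equals_direction_specific(
            self, schedule_250):
        """Scheme nesting: m.x.y with Z = 0 reproduces ds.x.y exactly."""
        e0 = np.array([20.0, -20, 20, -20, 20, -20])
        for pair in (("m.1.1", "ds.1.1"), ("m.2.1", "ds.2.1")):
            m_spec, d_spec = map(ModelSpec.from_id, pair)
            kw = dict(a=np.full(6, 0.3),
                      b=np.tile(np.full(6, -0.1)[:, None], (1, m_spec.order)))
            pm = ModelParams(spec=m_spec, z=np.zeros(6), w=np.full(5, 0.7), **kw)
            pd = ModelParams(spec=d_spec, **kw)
            cm = simulate_learning_curves(m_spec, pm, e0, schedule_250)
            cd = simulate_learning_curves(d_spec, pd, e0, schedule_250)
            np.testing.assert_array_equal(cm.latent, cd.latent)

    def test_zero_offgrid_weights_reduce_mixed_to_self_generalization(
            self, schedule_250):
        """With W(theta)=0 for theta != 0 the mixed model's generalization
        term only acts at the practiced direction (W(0) = 1)."""
        spec = ModelSpec.from_id("m.1.1")
        e0 = np.array([20.0, -20, 20, -20, 20, -20])
        p = ModelParams(spec=spec, a=np.full(6, 0.2), b=np.full(6, 0.05),
                        z=np.full(6, -0.4), w=np.zeros(5))
        ds_spec = ModelSpec.from_id("ds.1.1")
        curves = simulate_learning_curves(spec, p, e0, schedule_250)
        # manual replay: ds update + Z only when practiced
        pd = ModelParams(spec=ds_spec, a=np.full(6, 0.2), b=np.full(6, 0.05))
        e = e0.copy().astype(float)
        for i, tr in enumerate(schedule_250):
            np.testing.assert_allclose(curves.latent[i], e, rtol=1e-12, atol=1e-12)
            for d in range(6):
                ehat = e[d] if (d != tr.direction - 1 or tr.vision) else 0.0
                delta = 0.2 + 0.05 * ehat
                if d == tr.direction - 1:
                    delta += -0.4 * ehat
                e[d] += delta

    def test_direction_permutation_equivariance(self, rng):
        """Relabelling directions and permuting per-direction parameters the
        same way permutes the simulated curves and nothing else."""
        spec = ModelSpec.from_id("ds.1.1")
        a = rng.uniform(-0.5, 0.5, 6)
        b = rng.uniform(-0.4, -0.1, 6)
        e0 = rng.uniform(10, 25, 6) * np.array([1, -1, 1, -1, 1, -1])
        sched = TrialSchedule.constant_ea(
            rng.integers(1, 7, 120), np.ones(120, dtype=bool), EA_NORMAL)
        perm = rng.permutation(6)
        p1 = ModelParams(spec=spec, a=a, b=b)
        c1 = simulate_learning_curves(spec, p1, e0, sched)
        sched2 = TrialSchedule.constant_ea(
            np.argsort(perm)[sched.direction - 1] + 1,
            sched.vision, EA_NORMAL)
        p2 = ModelParams(spec=spec, a=a[perm], b=b[perm])
        c2 = simulate_learning_curves(spec, p2, e0[perm], sched2)
        np.testing.assert_allclose(c2.latent, c1.latent[:, perm], rtol=1e-12)

    def test_python_engine_matches_jit_kernel(self, schedule_250, rng):
        """The readable step-based engine and the jitted kernel agree
        exactly for a representative structure from each family."""
        e0 = np.array([20.0, -20, 20, -20, 20, -20])
        for mid in ("ds.1.1", "ds.3.1", "ds.1.1G", "ds.2.2", "g.2.1", "m.3.1",
                    "m.1.3"):
            spec = ModelSpec.from_id(mid)
            n = count_free_parameters(spec)
            vec = rng.uniform(-0.05, 0.05, n)   # small rates keep curves finite
            if spec.has_h:
                vec[-6:] = np.abs(vec[-6:]) + 5.0   # H block is last for ds.1.1G
            params = ModelParams.from_vector(spec, vec)
            for mode in ("normal_feedback", "repeat_delta"):
                c_jit = simulate_learning_curves(
                    spec, params, e0, schedule_250, momentum_mode=mode)
                c_py = simulate_learning_curves(
                    spec, params, e0, schedule_250, momentum_mode=mode,
                    engine="python")
                np.testing.assert_array_equal(c_jit.latent, c_py.latent)

    def test_practiced_curve_indexes_latent(self, schedule_250, ground_truth):
        e0 = np.array([20.0, -20, 20, -20, 20, -20])
        curves = simulate_learning_curves(
            ground_truth.spec, ground_truth, e0, schedule_250)
        for i in (0, 100, 249):
            d = schedule_250.direction[i]
            assert curves.practiced_curve[i] == curves.latent[i, d - 1]
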