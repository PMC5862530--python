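"""Exit decisions: decision-point extraction, kNN surfaces, logistic fits,
separation of variables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from antflow.exits import (
    extract_decision_points,
    fit_exit_logistic,
    knn_exit_surface,
    separation_of_variables_test,
)
from antflow.macro import compute_colony_state

from conftest import make_tiny_experiment


def _visit_experiment(crop_steps, dt=2.0):
    """One forager, one nest visit with a prescribed crop trace, then exit."""
    n = len(crop_steps) + 4
    exp = make_tiny_experiment(n_steps=n)
    tl = exp.timelines
    f = tl["ant_id"] == "f00"
    crops = np.concatenate([crop_steps, [crop_steps[-1]] * (n + 1 - len(crop_steps))])
    tl.loc[f, "crop"] = crops
    # visit spans the prescribed steps; the forager then leaves the nest
    exit_mask = f & (tl["t"] >= dt * len(crop_steps))
    tl.loc[exit_mask, "in_nest"] = False
    return exp


class TestExtractDecisionPoints:
    def test_unloading_increments_hand_trace(self):
        # crop 0.95 -> 0.60 in one visit: floor(0.35/0.10) = 3 decision
        # points from unloading, the last one labelled exit
        trace = np.linspace(0.95, 0.60, 15)
        exp = _visit_experiment(trace / 0.95)  # per-forager normalization
        state = compute_colony_state(exp, intake_target=1.0)
        pts = extract_decision_points(exp, "unloading_rate", 0.10, state)
        pts = pts[pts["forager_id"] == "f00"]
        assert len(pts) == 3
        assert pts["exit"].tolist() == [False, False, True]

    def test_constant_model_one_point_per_sample(self):
        trace = np.linspace(1.0, 0.8, 10)
        exp = _visit_experiment(trace)
        state = compute_colony_state(exp, intake_target=1.0)
        pts = extract_decision_points(exp, "constant", 0.10, state)
        assert len(pts) == 10
        assert pts["exit"].sum() == 1 and bool(pts["exit"].iloc[-1])

    def test_trophallaxis_samples_excluded_from_constant_model(self):
        trace = np.linspace(1.0, 0.8, 10)
        exp = _visit_experiment(trace)
        tl = exp.timelines
        sel = (tl["ant_id"] == "f00") & (tl["t"] == 4.0)
        tl.loc[sel, "in_trophallaxis"] = True
        state = compute_colony_state(exp, intake_target=1.0)
        pts = extract_decision_points(exp, "constant", 0.10, state)
        assert len(pts) == 9 and 4.0 not in pts["time"].tolist()

    def test_record_end_visit_has_no_exit_label(self):
        exp = make_tiny_experiment(n_steps=20)  # in nest to the very end
        tl = exp.timelines
        f = tl["ant_id"] == "f00"
        tl.loc[f, "crop"] = np.linspace(1.0, 0.5, f.sum())
        state = compute_colony_state(exp, intake_target=1.0)
        pts = extract_decision_points(exp, "unloading_rate", 0.10, state)
        assert len(pts) > 0 and not pts["exit"].any()

    def test_unknown_model_rejected(self, default_sim):
        with pytest.raises(ValueError):
            extract_decision_points(default_sim.experiment, "oracle")

    def test_crop_rise_resets_accumulator(self):
        # 0.9 -> 0.84 (0.06 down), up to 0.95, then to 0.80: only the final
        # 0.15 descent crosses the 0.10 increment
        trace = np.array([0.9, 0.87, 0.84, 0.95, 0.90, 0.85, 0.80, 0.80])
        exp = _visit_experiment(trace)
        state = compute_colony_state(exp, intake_target=1.0)
        pts = extract_decision_points(exp, "unloading_rate", 0.10, state)
        assert len(pts) == 1

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.0, 0.2), min_size=3, max_size=40),
           st.floats(0.05, 0.3))
    def test_point_count_matches_total_unloaded(self, drops, delta):
        """On a monotone trace the number of unloading-rate decision points
        is exactly floor(total unloaded / delta)."""
        start = 1.0
        trace = start - np.cumsum([0.0] + drops)
        trace = np.clip(trace, 0.0, None)
        exp = _visit_experiment(trace)
        state = compute_colony_state(exp, intake_target=1.0)
        pts = extract_decision_points(exp, "unloading_rate", delta, state)
        total = trace[0] - trace[-1]
        # exact up to one point of float accumulation at increment boundaries
        assert abs(len(pts) - int(total / delta + 1e-9)) <= 1

    def test_interaction_model_points_follow_interaction_ends(self, default_sim,
                                                              default_state):
        exp = default_sim.experiment
        pts = extract_decision_points(exp, "interaction_rate", 0.10,
                                      default_state)
        n_int = len(exp.interactions)
        assert 0 < len(pts) <= n_int
        assert pts["crop"].between(0, 1).all()
        assert pts["colony"].between(0, 1).all()


class TestKnnSurface:
    def test_all_exits_surface_is_one(self):
        pts = pd.DataFrame({"crop": np.linspace(0, 1, 30), "colony": 0.5,
                            "exit": True})
        surf = knn_exit_surface(pts, 5)
        assert np.allclose(surf["p_exit"], 1.0)

    def test_two_separated_clusters(self):
        pts = pd.DataFrame({
            "crop": [0.1, 0.12, 0.9, 0.92],
            "colony": [0.1, 0.12, 0.9, 0.92],
            "exit": [True, True, False, False]})
        surf = knn_exit_surface(pts, 2,
                                grid=np.array([[0.1, 0.1], [0.9, 0.9]]))
        assert surf["p_exit"].tolist() == [1.0, 0.0]
        assert surf["crop"].tolist() == pytest.approx([0.11, 0.91])

    def test_probabilities_bounded(self, default_sim, default_state):
        pts = extract_decision_points(default_sim.experiment, "unloading_rate",
                                      0.10, default_state)
        surf = knn_exit_surface(pts, 30)
        assert surf["p_exit"].between(0, 1).all()

    def test_more_neighbors_never_rougher(self):
        """Total variation of the surface along a crop transect does not
        increase with the neighbourhood size on fixed toy data."""
        rng = np.random.default_rng(13)
        x = np.linspace(0, 1, 80)
        pts = pd.DataFrame({
            "crop": x, "colony": 0.5,
            "exit": rng.random(80) < (1 - x) ** 2})
        grid = np.column_stack([np.linspace(0, 1, 40), np.full(40, 0.5)])
        tv = []
        for n in (3, 6, 12, 24):
            surf = knn_exit_surface(pts, n, grid=grid)
            tv.append(float(np.abs(np.diff(surf["p_exit"])).sum()))
        assert all(a >= b - 1e-12 for a, b in zip(tv, tv[1:]))

    def test_excessive_neighbors_rejected(self):
        pts = pd.DataFrame({"crop": [0.1, 0.2], "colony": [0.1, 0.2],
                            "exit": [True, False]})
        with pytest.raises(ValueError):
            knn_exit_surface(pts, 3)


def _logistic_points(rng, n, intercept, crop_coef, colony_coef=0.0):
    crop = rng.uniform(0, 1, n)
    colony = rng.uniform(0, 1, n)
    p = 1 / (1 + np.exp(-(intercept + crop_coef * crop
                          + colony_coef * colony)))
    return pd.DataFrame({"crop": crop, "colony": colony,
                         "exit": rng.random(n) < p})


class TestFitExitLogistic:
    def test_generator_coefficients_within_ci(self):
        rng = np.random.default_rng(19)
        pts = _logistic_points(rng, 5000, -0.5, -1.93, 0.8)
        fit = fit_exit_logistic(pts, ("crop", "colony"))
        for name, truth in [("crop", -1.93), ("colony", 0.8)]:
            lo, hi = fit.conf_int[name]
            assert lo <= truth <= hi

    def test_independent_labels_give_null_coefficients(self):
        rng = np.random.default_rng(21)
        pts = _logistic_points(rng, 5000, -1.0, 0.0, 0.0)
        fit = fit_exit_logistic(pts, ("crop", "colony"))
        assert fit.covers_zero("crop") and fit.covers_zero("colony")

    def test_crop_only_projection_excludes_lowest_interval(self):
        rng = np.random.default_rng(23)
        pts = _logistic_points(rng, 3000, -0.1, -3.0)
        fit = fit_exit_logistic(pts, ("crop",))
        assert fit.n == int((pts["crop"] >= 0.1).sum())

    def test_single_class_rejected(self):
        pts = pd.DataFrame({"crop": [0.5, 0.6], "colony": [0.5, 0.6],
                            "exit": [True, True]})
        with pytest.raises(ValueError):
            fit_exit_logistic(pts)

    def test_surface_mode_recovers_strong_slope_sign(self):
        rng = np.random.default_rng(29)
        pts = _logistic_points(rng, 2000, 0.5, -3.0)
        fit = fit_exit_logistic(pts, ("crop",), mode="surface",
                                exclude_lowest_crop=False)
        assert fit.params["crop"] < -1.0


class TestSeparationOfVariables:
    def test_crop_rule_colony_effect_shrinks(self, rate_sim):
        """With crop-only exit decisions at unloading increments and the
        measured interaction-rate decline, the relative colony effect
        shrinks monotonically across decision-rate schedules and its CI
        covers zero under the unloading-rate schedule."""
        state = compute_colony_state(
            rate_sim.experiment, intake_target=sum(rate_sim.targets.values()))
        rep = separation_of_variables_test(rate_sim.experiment, 0.10, state)
        assert rep["ratio_shrinks_monotonically"]
        assert rep["unloading_colony_covers_zero"]
        t = rep["table"]
        assert abs(t.loc["unloading_rate", "crop_coef"]) > \
            abs(t.loc["unloading_rate", "colony_coef"])

    def test_colony_rule_negative_control_does_not_shrink(self, negctrl_sim):
        state = compute_colony_state(
            negctrl_sim.experiment,
            intake_target=sum(negctrl_sim.targets.values()))
        rep = separation_of_variables_test(negctrl_sim.experiment, 0.10, state)
        t = rep["table"]
        assert not rep["unloading_colony_covers_zero"]
        assert t.loc["unloading_rate", "colony_coef"] < 0

    def test_recovered_crop_slope_matches_generator(self, rate_sim):
        """The crop coefficient fitted under the unloading-rate schedule
        recovers the generator's exit-rule slope."""
        state = compute_colony_state(
            rate_sim.experiment, intake_target=sum(rate_sim.targets.values()))
        pts = extract_decision_points(rate_sim.experiment, "unloading_rate",
                                      0.10, state)
        fit = fit_exit_logistic(pts, ("crop", "colony"))
        lo, hi = fit.conf_int["crop"]
        assert lo <= rate_sim.config.exit_crop_coef <= hi

    def test_ci_coverage_across_replicates(self):
        """Across seeded replicate colonies the generator's crop slope lies
        in the fitted 95% CI in at least 9 of 10 runs."""
        from antflow.simulate import SimulationConfig, simulate_colony
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(n_ants=40, n_foragers=6, duration=10800.0,
                                   seed=300 + seed)
            sx = simulate_colony(cfg)
            state = compute_colony_state(
                sx.experiment, intake_target=sum(sx.targets.values()))
            pts = extract_decision_points(sx.experiment, "unloading_rate",
                                          0.10, state)
            fit = fit_exit_logistic(pts, ("crop", "colony"))
            lo, hi = fit.conf_int["crop"]
            hits += lo <= cfg.exit_crop_coef <= hi
        assert hits >= 9
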