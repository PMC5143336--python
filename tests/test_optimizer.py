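"""Coordinate-descent sweeps, cyclic refinement, greedy order selection."""

import itertools

import numpy as np
import pytest

from multiexp import (
    DecompositionModel,
    FitFeasibilityError,
    OptimizerConfig,
    SampledSignal,
    add_component,
    default_decrement_grid,
    dispersion,
    evaluate_basis,
    fit,
    project_weights,
    refine_cycle,
    sweep_decrement,
)
from multiexp.synthetic import generate_signal, table1_fixture

from conftest import draw_separated_model, make_signal


# ---------------------------------------------------------------- grid


def test_default_grid_bounds_derive_from_sampling():
    signal = SampledSignal(np.linspace(0.0, 1.0, 1001), np.exp(-np.linspace(0, 1, 1001)))
    grid = default_decrement_grid(signal)
    assert grid[0] == pytest.approx(0.1, rel=1e-9)
    assert grid[-1] == pytest.approx(2000.0, rel=1e-6)
    assert np.all(np.diff(grid) > 0)


def test_default_grid_one_point_per_decade_gives_endpoints():
    signal = SampledSignal([0.0, 1.0, 2.0], [1.0, 0.5, 0.25])
    grid = default_decrement_grid(
        signal, OptimizerConfig(k_min=1.0, k_max=10.0, points_per_decade=1)
    )
    np.testing.assert_allclose(grid, [1.0, 10.0], rtol=1e-12)


def test_default_grid_rejects_empty_range():
    signal = SampledSignal([0.0, 1.0, 2.0], [1.0, 0.5, 0.25])
    with pytest.raises(ValueError):
        OptimizerConfig(k_min=5.0, k_max=5.0)
    with pytest.raises(ValueError):
        default_decrement_grid(signal, OptimizerConfig(k_min=5.0, k_max=4.0))


def test_config_rejects_out_of_range_settings():
    with pytest.raises(ValueError):
        OptimizerConfig(max_components=8)
    with pytest.raises(ValueError):
        OptimizerConfig(max_components=0)
    with pytest.raises(ValueError):
        OptimizerConfig(points_per_decade=0)


# ---------------------------------------------------------------- sweeps


def test_sweep_selects_true_decrement_with_true_weight(grid_401):
    candidates = np.geomspace(0.1, 100.0, 61)
    k_true = candidates[30]
    signal = make_signal(DecompositionModel([2.0], [k_true]), grid_401)
    start = DecompositionModel([1.0], [candidates[10]])
    swept, feasible = sweep_decrement(signal, start, 0, candidates)
    assert feasible
    assert swept.decrements[0] == k_true
    assert swept.weights[0] == pytest.approx(2.0, rel=1e-12)


def test_sweep_is_idempotent(grid_401):
    rng = np.random.default_rng(7)
    candidates = np.geomspace(0.1, 100.0, 61)
    model = draw_separated_model(rng, 2)
    signal = make_signal(model, grid_401, noise_sd=0.01, rng=rng)
    once, _ = sweep_decrement(signal, model, 0, candidates)
    twice, _ = sweep_decrement(signal, once, 0, candidates)
    np.testing.assert_array_equal(once.decrements, twice.decrements)
    np.testing.assert_array_equal(once.weights, twice.weights)


def test_sweep_rejects_bad_index(grid_401):
    signal = make_signal(DecompositionModel([1.0], [2.0]), grid_401)
    with pytest.raises(IndexError):
        sweep_decrement(signal, DecompositionModel([1.0], [2.0]), 1, [1.0, 3.0])


def test_sweep_agrees_with_exhaustive_candidate_scan(grid_401):
    """The sweep must pick exactly the candidate an exhaustive positivity-
    constrained projection scan would pick."""
    rng = np.random.default_rng(19)
    candidates = np.geomspace(0.05, 120.0, 73)
    for _ in range(5):
        truth = draw_separated_model(rng, 2)
        signal = make_signal(truth, grid_401, noise_sd=0.005, rng=rng)
        # start from an on-grid model so the candidate scan covers the incumbent
        start = DecompositionModel([0.5, 0.5], [candidates[55], candidates[25]])
        swept, _ = sweep_decrement(signal, start, 1, candidates)

        # exhaustive oracle: component 0 stays fixed, scan every admissible
        # candidate (collision and minimum-separation rules mirrored)
        fixed = start.decrements[0]
        min_ratio = OptimizerConfig().min_separation_ratio
        best_d = np.inf
        for k in candidates:
            if max(fixed, k) / min(fixed, k) < min_ratio:
                continue
            ks = np.sort([fixed, k])
            basis = evaluate_basis(ks, grid_401)
            w = project_weights(signal, basis)
            if np.any(w <= 0):
                continue
            d = dispersion(signal, DecompositionModel(w, ks))
            best_d = min(best_d, d)
        assert dispersion(signal, swept) == pytest.approx(best_d, rel=1e-12)


# ---------------------------------------------------------------- refinement


def test_refine_cycle_dispersion_nonincreasing(grid_401):
    rng = np.random.default_rng(23)
    candidates = np.geomspace(0.05, 120.0, 73)
    for _ in range(20):
        n = int(rng.integers(2, 4))
        truth = draw_separated_model(rng, n)
        signal = make_signal(truth, grid_401, noise_sd=0.01, rng=rng)
        start = draw_separated_model(rng, n)
        d = dispersion(signal, start)
        model = start
        for _cycle in range(3):
            for i in range(model.n):
                model, _ = sweep_decrement(signal, model, i, candidates)
                d_new = dispersion(signal, model)
                assert d_new <= d * (1 + 1e-12)
                d = d_new
        refined = refine_cycle(signal, start, candidates)
        assert dispersion(signal, refined) <= dispersion(signal, start) * (1 + 1e-12)


def test_refine_cycle_finds_exact_decrements_on_grid(grid_401):
    """Noiseless two-component signal with both rates in the candidate set:
    refinement must land exactly on them (the zero-residual pair wins)."""
    candidates = np.geomspace(0.1, 100.0, 61)
    k_true = np.array([candidates[45], candidates[20]])  # ~x18 separation
    truth = DecompositionModel([0.7, 0.3], k_true)
    signal = make_signal(truth, grid_401)
    start = DecompositionModel([0.5, 0.5], [candidates[47], candidates[18]])
    refined = refine_cycle(signal, start, candidates)
    np.testing.assert_array_equal(np.sort(refined.decrements), np.sort(k_true))
    np.testing.assert_allclose(refined.weights, [0.7, 0.3], rtol=1e-9)


def test_refine_cycle_stops_at_coordinate_minimum(grid_401):
    candidates = np.geomspace(0.1, 100.0, 61)
    truth = DecompositionModel([1.0], [candidates[30]])
    signal = make_signal(truth, grid_401)
    refined = refine_cycle(signal, truth, candidates)
    np.testing.assert_array_equal(refined.decrements, truth.decrements)


# ---------------------------------------------------------------- greedy stages


def test_add_component_to_empty_model_is_grid_search(grid_401):
    candidates = np.geomspace(0.1, 100.0, 61)
    truth = DecompositionModel([1.5], [candidates[25]])
    signal = make_signal(truth, grid_401)
    grown, feasible = add_component(
        signal, DecompositionModel.empty(), candidates,
        OptimizerConfig(local_refine_levels=0),
    )
    assert feasible
    assert grown.n == 1
    assert grown.decrements[0] == candidates[25]


def test_add_component_cannot_improve_exact_fit(grid_401):
    candidates = np.geomspace(0.1, 100.0, 61)
    model = DecompositionModel([1.0], [candidates[30]])
    signal = make_signal(model, grid_401)
    d_before = dispersion(signal, model)
    grown, feasible = add_component(signal, model, candidates)
    if feasible:
        assert dispersion(signal, grown) <= max(d_before, 1e-25)


def test_add_component_lowers_dispersion_for_two_exponential_signal(grid_401):
    candidates = np.geomspace(0.1, 100.0, 61)
    truth = DecompositionModel([0.6, 0.4], [30.0, 1.5])
    signal = make_signal(truth, grid_401)
    one, _ = add_component(signal, DecompositionModel.empty(), candidates)
    two, feasible = add_component(signal, one, candidates)
    assert feasible
    assert dispersion(signal, two) < dispersion(signal, one)


def test_add_component_respects_cap(grid_401):
    signal = make_signal(DecompositionModel([1.0], [2.0]), grid_401)
    model = DecompositionModel([0.6, 0.4], [10.0, 1.0])
    with pytest.raises(ValueError):
        add_component(signal, model, [1.0, 5.0], OptimizerConfig(max_components=2))


# ---------------------------------------------------------------- full fits


def test_fit_single_exponential_recovers_parameters(grid_401):
    truth = DecompositionModel([2.0], [7.3])
    signal = make_signal(truth, grid_401)
    result = fit(signal)
    assert result.n_components == 1
    assert result.model.decrements[0] == pytest.approx(7.3, rel=1e-3)
    assert result.model.weights[0] == pytest.approx(2.0, rel=1e-3)


def test_fit_recovers_published_pdl_parameters():
    """Three-component wheat-fluorescence parameters (59/29/7 %, 400/87/11 1/s)
    are recovered from the noiseless synthetic curve."""
    signal = generate_signal(table1_fixture("Pdl"))
    result = fit(signal, max_components=3)
    assert result.n_components == 3
    np.testing.assert_allclose(result.model.decrements, [400.0, 87.0, 11.0], rtol=0.05)
    np.testing.assert_allclose(result.model.weights, [0.59, 0.29, 0.07], rtol=0.01)
    assert result.dispersion < 1e-9


def test_fit_matches_exhaustive_joint_grid_oracle(grid_401):
    """Restricted to the pure coarse grid, the greedy fit's final dispersion
    equals the exhaustive minimum over all candidate decrement pairs."""
    rng = np.random.default_rng(31)
    config = OptimizerConfig(
        k_min=0.5, k_max=50.0, points_per_decade=8,
        max_components=2, local_refine_levels=0,
    )
    for _ in range(3):
        truth = draw_separated_model(rng, 2, k_lo=1.0, k_hi=40.0, separation=5.0)
        signal = make_signal(truth, grid_401, noise_sd=0.002, rng=rng)
        candidates = default_decrement_grid(signal, config)

        best_d = np.inf
        best_pair = None
        for ka, kb in itertools.combinations(candidates, 2):
            basis = evaluate_basis((ka, kb), grid_401)
            w = project_weights(signal, basis)
            if np.any(w <= 0):
                continue
            d = dispersion(signal, DecompositionModel(w, (ka, kb)))
            if d < best_d:
                best_d, best_pair = d, (kb, ka)  # descending

        result = fit(signal, config)
        assert result.n_components == 2
        assert result.dispersion == pytest.approx(best_d, rel=1e-10)
        np.testing.assert_allclose(result.model.decrements, best_pair, rtol=1e-12)


def test_fit_positivity_and_strictly_decreasing_trace(grid_1001):
    rng = np.random.default_rng(37)
    for _ in range(10):
        n = int(rng.integers(1, 4))
        truth = draw_separated_model(rng, n)
        signal = make_signal(truth, grid_1001, noise_sd=0.005, rng=rng)
        result = fit(signal, max_components=4)
        assert np.all(result.model.weights > 0)
        assert np.all(result.model.decrements > 0)
        disps = [d for _, d in result.stage_trace]
        assert all(b < a for a, b in zip(disps, disps[1:]))
        assert result.dispersion == disps[-1]


def test_fit_recovers_separated_components_property(grid_401):
    """Noiseless 2- and 3-component signals with >= x4 separated decrements and
    weights >= 5% of the total: decrements within one grid step, weights
    within 1% after refinement (50 seeded draws)."""
    rng = np.random.default_rng(41)
    for draw in range(50):
        n = 2 + draw % 2
        truth = draw_separated_model(rng, n)
        signal = make_signal(truth, grid_401)
        config = OptimizerConfig(max_components=n)
        result = fit(signal, config)
        grid = default_decrement_grid(signal, config)
        step = np.log(grid[1] / grid[0])
        assert result.n_components == n
        log_err = np.abs(np.log(result.model.decrements / truth.decrements))
        assert np.all(log_err <= step + 1e-12)
        np.testing.assert_allclose(result.model.weights, truth.weights, rtol=0.01)


def test_fit_selects_generating_order_under_noise(grid_1001):
    """With additive noise at <= 1% of the initial amplitude the stopping rule
    recovers the generating component count in >= 90% of 50 seeded draws."""
    rng = np.random.default_rng(43)
    hits = 0
    for draw in range(50):
        n = 2 + draw % 2
        truth = draw_separated_model(rng, n)
        noise_sd = rng.uniform(0.002, 0.01) * truth.predict(np.zeros(1))[0]
        signal = make_signal(truth, grid_1001, noise_sd=noise_sd, rng=rng)
        result = fit(signal, max_components=5)
        hits += result.n_components == n
    assert hits >= 45


# ---------------------------------------------------------------- edge cases


def test_fit_rejects_too_short_signal():
    signal = SampledSignal(np.linspace(0, 1, 5), np.exp(-np.linspace(0, 1, 5)))
    with pytest.raises(ValueError):
        fit(signal, max_components=7)


def test_fit_rejects_nonpositive_initial_amplitude(grid_401):
    signal = SampledSignal(grid_401, -np.exp(-grid_401))
    with pytest.raises(FitFeasibilityError):
        fit(signal, max_components=2)


def test_fit_warns_for_non_decaying_signal():
    t = np.linspace(0.0, 1.0, 64)
    signal = SampledSignal(t, 1.0 + t)
    with pytest.warns(UserWarning, match="decay"):
        try:
            fit(signal, max_components=2)
        except FitFeasibilityError:
            pass


def test_fit_agrees_with_continuous_nonlinear_least_squares(grid_401):
    """Cross-check against an independent continuous-parameter fit (lmfit)."""
    lmfit = pytest.importorskip("lmfit")
    truth = DecompositionModel([0.65, 0.35], [25.0, 1.8])
    signal = make_signal(truth, grid_401)

    def biexp(t, a1, k1, a2, k2):
        return a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)

    lm_model = lmfit.Model(biexp)
    params = lm_model.make_params(a1=0.5, k1=40.0, a2=0.5, k2=1.0)
    lm_fit = lm_model.fit(signal.amplitudes, params, t=signal.times)
    ours = fit(signal, max_components=2)
    np.testing.assert_allclose(
        ours.model.decrements,
        sorted([lm_fit.params["k1"].value, lm_fit.params["k2"].value], reverse=True),
        rtol=1e-3,
    )
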