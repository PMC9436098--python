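"""Tests of the exact frequency recursions (Models A1 and A2).

The agent-based oracle used here is an explicit per-cell simulation that
draws each division's amplification outcome individually; averaged over
replicates it must agree with the deterministic recursions, which evolve
the expected state frequencies directly.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rdnasim.core import (
    CopyNumberDistribution,
    ModelParams,
    NonConvergenceError,
    ParameterError,
    delta_split_weights,
)
from rdnasim.deterministic import (
    RampSpec,
    advance_generation_a1,
    advance_generation_a2,
    fit_delta_a2,
    noamp_probability,
    run_to_saturation,
    scan_delta,
)


def a1_step(params):
    return lambda d: advance_generation_a1(d, params)


def a2_step(params, ramp):
    return lambda d: advance_generation_a2(d, params, ramp)


# ---------------------------------------------------------------------------
# independent agent-based oracle
# ---------------------------------------------------------------------------


def agent_based_frequencies(
    params: ModelParams,
    ramp: RampSpec | None,
    n_cells: int,
    n_generations: int,
    n_replicates: int,
    seed: int,
) -> np.ndarray:
    """Average state frequencies from explicit per-cell simulation.

    Every generation each cell divides; one offspring keeps the parental
    copy number and the other amplifies by an individually drawn jump
    (under the ramp, a drawn fraction of divisions amplifies nothing).  The
    population is resampled back to ``n_cells`` each generation, which is
    unbiased for the expected frequencies.
    """
    rng = np.random.default_rng(seed)
    w = delta_split_weights(params.delta)
    jumps = np.array(sorted(w))
    jump_p = np.array([w[j] for j in sorted(w)])
    acc = np.zeros(params.n_states)
    for _ in range(n_replicates):
        cells = np.full(n_cells, params.c_start)
        for _ in range(n_generations):
            at_cap = cells == params.c_max
            keep = cells.copy()
            amplified = cells.copy()
            sub = ~at_cap
            n_sub = int(sub.sum())
            if n_sub:
                inc = rng.choice(jumps, size=n_sub, p=jump_p)
                target = np.minimum(cells[sub] + inc, params.c_max)
                if ramp is not None:
                    p_no = np.array(
                        [
                            ramp.probability(int(c), params.c_start, params.c_max)
                            for c in cells[sub]
                        ]
                    )
                    no_amp = rng.random(n_sub) < p_no
                    target = np.where(no_amp, cells[sub], target)
                amplified[sub] = target
            pool = np.concatenate([keep, amplified])
            cells = rng.choice(pool, size=n_cells, replace=True)
        acc += np.bincount(cells - params.c_start, minlength=params.n_states)
    return acc / (n_replicates * n_cells)


# ---------------------------------------------------------------------------
# Model A1
# ---------------------------------------------------------------------------


class TestModelA1Step:
    def test_founder_split(self, default_params):
        d = CopyNumberDistribution.point_mass(125, default_params)
        out = advance_generation_a1(d, default_params)
        assert out.as_dict() == pytest.approx({125: 0.5, 126: 0.35, 127: 0.15})

    def test_cap_state_is_absorbing(self, default_params):
        d = CopyNumberDistribution.point_mass(220, default_params)
        out = advance_generation_a1(d, default_params)
        assert out.as_dict() == pytest.approx({220: 1.0})

    def test_overflow_clamps_to_cap(self, default_params):
        d = CopyNumberDistribution.point_mass(219, default_params)
        out = advance_generation_a1(d, default_params)
        assert out.as_dict() == pytest.approx({219: 0.5, 220: 0.5})

    @given(
        delta=st.floats(min_value=0.1, max_value=4.0),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_mass_conservation(self, delta, seed):
        params = ModelParams(delta=delta)
        rng = np.random.default_rng(seed)
        w = rng.random(params.n_states)
        d = CopyNumberDistribution(125, 220, w / w.sum())
        out = advance_generation_a1(d, params)
        assert out.total == pytest.approx(1.0, abs=1e-9)

    def test_mean_drifts_by_half_delta_before_the_cap(self, default_params):
        # each division yields one unamplified and one amplified offspring,
        # so the population mean climbs by Delta/2 per generation while no
        # mass is near the cap
        d = CopyNumberDistribution.point_mass(125, default_params)
        for g in range(1, 21):
            d = advance_generation_a1(d, default_params)
            assert d.mean() == pytest.approx(125 + g * 1.3 / 2, abs=1e-6)

    def test_saturation_fraction_never_decreases(self, default_params):
        d = CopyNumberDistribution.point_mass(125, default_params)
        prev = 0.0
        for _ in range(220):
            d = advance_generation_a1(d, default_params)
            assert d.frac_at_cap() >= prev - 1e-12
            prev = d.frac_at_cap()

    def test_agrees_with_agent_based_oracle(self, default_params):
        recursion = CopyNumberDistribution.point_mass(125, default_params)
        for _ in range(15):
            recursion = advance_generation_a1(recursion, default_params)
        oracle = agent_based_frequencies(
            default_params, None, n_cells=200, n_generations=15,
            n_replicates=40, seed=7,
        )
        assert np.abs(oracle - recursion.weights).max() < 0.02


class TestSaturationRun:
    def test_default_run_saturates_near_175_generations(self, default_params):
        traj = run_to_saturation(a1_step(default_params), default_params)
        assert traj.final_generation == pytest.approx(175, abs=2)
        assert traj.frac_at_cap[-1] >= 0.98
        assert traj.frac_at_cap[-2] < 0.98

    @pytest.mark.parametrize(
        "c_start, c_max, delta, expected",
        [(80, 150, 2.3, 80), (35, 80, 2.05, 60)],
    )
    def test_published_amplification_experiments(self, c_start, c_max, delta, expected):
        # the no-selection rows of the fits to Kobayashi 1998 / Jack 2015
        params = ModelParams(c_start=c_start, c_max=c_max, delta=delta)
        traj = run_to_saturation(a1_step(params), params)
        assert traj.final_generation == expected

    def test_already_saturated_start(self):
        params = ModelParams(c_start=220, c_max=220)
        traj = run_to_saturation(a1_step(params), params)
        assert traj.final_generation == 0

    def test_nonconvergence_is_an_explicit_error(self):
        params = ModelParams(max_generations=50)
        with pytest.raises(NonConvergenceError):
            run_to_saturation(a1_step(params), params)


class TestScanDelta:
    def test_generations_decrease_with_delta_under_a1(self, default_params):
        table = scan_delta([1.2, 1.3, 1.4, 2.0], default_params)
        gens = table["generations"].tolist()
        assert gens == sorted(gens, reverse=True)
        assert table.attrs["monotone_decreasing"]
        # frozen values from this recursion; the 1.3 entry is the headline
        # 'about 175 generations' prediction
        assert gens == [189, 176, 164, 118]

    def test_observed_window_is_reached_between_delta_1p3_and_1p4(self, default_params):
        table = scan_delta([1.3, 1.4], default_params)
        assert all(160 <= g <= 180 for g in table["generations"])

    def test_empty_grid_gives_empty_table(self, default_params):
        table = scan_delta([], default_params)
        assert len(table) == 0

    def test_nonconvergent_rows_are_nan_not_fatal(self):
        params = ModelParams(max_generations=150)
        table = scan_delta([0.3, 2.0], params)
        assert np.isnan(table["generations"][0])
        assert table["generations"][1] == 118


# ---------------------------------------------------------------------------
# Model A2 (linear Sir2 ramp)
# ---------------------------------------------------------------------------


class TestRamp:
    @pytest.mark.parametrize(
        "c, expected",
        [(125, 0.0), (126, 0.01), (173, 0.505), (220, 1.0), (300, 1.0)],
    )
    def test_noamp_probability(self, c, expected, default_params):
        assert noamp_probability(c, RampSpec(), default_params) == pytest.approx(
            expected
        )

    def test_monotone_in_copy_number(self, default_params):
        ramp = RampSpec()
        ps = [
            noamp_probability(c, ramp, default_params) for c in range(125, 221)
        ]
        assert all(b >= a for a, b in zip(ps, ps[1:]))

    def test_invalid_ramp_rejected(self):
        with pytest.raises(ParameterError):
            RampSpec(p_next=0.5, p_cap=0.2)


class TestModelA2Step:
    def test_founder_state_behaves_like_a1(self, default_params):
        d = CopyNumberDistribution.point_mass(125, default_params)
        a1 = advance_generation_a1(d, default_params)
        a2 = advance_generation_a2(d, default_params, RampSpec())
        assert a2.as_dict() == pytest.approx(a1.as_dict())

    def test_zero_ramp_reduces_to_a1_exactly(self, default_params):
        zero = RampSpec(p_next=0.0, p_cap=0.0)
        d1 = CopyNumberDistribution.point_mass(125, default_params)
        d2 = CopyNumberDistribution.point_mass(125, default_params)
        for _ in range(30):
            d1 = advance_generation_a1(d1, default_params)
            d2 = advance_generation_a2(d2, default_params, zero)
            np.testing.assert_allclose(d2.weights, d1.weights, atol=1e-12)

    def test_cap_state_inert(self, default_params):
        d = CopyNumberDistribution.point_mass(220, default_params)
        out = advance_generation_a2(d, default_params, RampSpec())
        assert out.as_dict() == pytest.approx({220: 1.0})

    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_mass_conservation(self, seed):
        params = ModelParams(delta=2.7)
        rng = np.random.default_rng(seed)
        w = rng.random(params.n_states)
        d = CopyNumberDistribution(125, 220, w / w.sum())
        out = advance_generation_a2(d, params, RampSpec())
        assert out.total == pytest.approx(1.0, abs=1e-9)

    def test_ramp_slows_amplification(self, default_params):
        d1 = CopyNumberDistribution.point_mass(125, default_params)
        d2 = CopyNumberDistribution.point_mass(125, default_params)
        for _ in range(60):
            d1 = advance_generation_a1(d1, default_params)
            d2 = advance_generation_a2(d2, default_params, RampSpec())
        assert d2.mean() < d1.mean()

    def test_agrees_with_agent_based_oracle(self):
        params = ModelParams(delta=3.0)
        ramp = RampSpec()
        recursion = CopyNumberDistribution.point_mass(125, params)
        for _ in range(15):
            recursion = advance_generation_a2(recursion, params, ramp)
        oracle = agent_based_frequencies(
            params, ramp, n_cells=200, n_generations=15, n_replicates=40, seed=11,
        )
        assert np.abs(oracle - recursion.weights).max() < 0.02


class TestFitDelta:
    def test_returns_smallest_candidate_inside_window(self, default_params):
        # frozen from this recursion: Delta 2 -> 1130, Delta 3 -> 597,
        # Delta 4 -> 401 generations
        result = fit_delta_a2([2, 3, 4], (400, 700), default_params)
        assert result.delta == 3
        assert list(result.table["delta"]) == [2.0, 3.0, 4.0]

    def test_no_fit_carries_the_table(self, default_params):
        result = fit_delta_a2([2, 3], (10, 20), default_params)
        assert result.delta is None
        assert not result.fitted
        assert len(result.table) == 2

    def test_unbounded_window_returns_smallest_converging(self, default_params):
        result = fit_delta_a2([2, 3], (0, float("inf")), default_params)
        assert result.delta == 2

    def test_empty_candidates_rejected(self, default_params):
        with pytest.raises(ParameterError):
            fit_delta_a2([], (160, 180), default_params)
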