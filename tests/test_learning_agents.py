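import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arrowsim.learning_agents import (
    AgentParams,
    csi_update,
    init_agent,
    reverse_update,
    win_stay_step,
)
from arrowsim.task_environment import (
    CONTINUOUS_ATTRIBUTES,
    Arrowhead,
    expected_fitness,
)

from conftest import one_d_landscape, random_landscape

ONE_D = AgentParams(step_size=5, attributes=("length",))


def win_stay_oracle(start: int, optimum: int, width: float, direction0: int,
                    step: int, n_trials: int) -> list[tuple[int, int]]:
    """Independent brute-force reference for noise-free 1-D Win-Stay:
    returns the (value, direction-after-update) sequence."""
    f = lambda x: 1000.0 * math.exp(-((x - optimum) ** 2) / (2.0 * width**2))
    value, direction, prev = start, direction0, None
    out = []
    for _ in range(n_trials):
        value = min(100, max(1, value + direction * step))
        score = f(value)
        if prev is not None and score < prev:
            direction = -direction
        prev = score
        out.append((value, direction))
    return out


class TestInitAgent:
    def test_seeding_is_reproducible_and_design_echoed(self):
        d = Arrowhead(10, 20, 30)
        s1 = init_agent(AgentParams(), d, np.random.default_rng(5))
        s2 = init_agent(AgentParams(), d, np.random.default_rng(5))
        assert s1.direction_memory == s2.direction_memory
        assert s1.design == d
        assert s1.previous_perceived_score is None

    def test_direction_memory_covers_all_sign_configurations(self):
        """All 8 sign configurations over 3 attributes appear under many
        seeds — i.e. directions are genuinely uniform per attribute."""
        seen = {
            tuple(
                init_agent(AgentParams(), Arrowhead(50, 50, 50),
                           np.random.default_rng(seed)).direction_memory.values()
            )
            for seed in range(200)
        }
        assert len(seen) == 8


class TestWinStay:
    def test_direction_kept_on_improvement_flipped_on_decline(self):
        ls = one_d_landscape(optimum=80, noise_sd=0.0)
        # toward the optimum: score rises, direction kept
        state = init_agent(ONE_D, Arrowhead(40, 50, 50), np.random.default_rng(0))
        state.direction_memory["length"] = +1
        state.previous_perceived_score = expected_fitness(state.design, ls)
        state, _ = win_stay_step(state, ls, np.random.default_rng(0), ONE_D)
        assert state.direction_memory["length"] == +1
        # away from the optimum: score falls, direction flipped
        state.direction_memory["length"] = -1
        state, _ = win_stay_step(state, ls, np.random.default_rng(0), ONE_D)
        assert state.direction_memory["length"] == +1

    def test_first_trial_stores_score_without_flipping(self):
        ls = one_d_landscape(optimum=10, noise_sd=0.0)
        state = init_agent(ONE_D, Arrowhead(90, 50, 50), np.random.default_rng(1))
        state.direction_memory["length"] = +1  # a worsening direction
        state, rec = win_stay_step(state, ls, np.random.default_rng(1), ONE_D)
        assert state.direction_memory["length"] == +1  # no flip without a previous score
        assert state.previous_perceived_score == rec["perceived_score"]

    @pytest.mark.parametrize("start", [10, 95])
    def test_trajectory_matches_brute_force_oracle(self, start):
        """Noise-free 1-D trajectories equal an independent 10-line reference
        and end within one step of the optimum."""
        optimum, width, trials = 57, 20.0, 30
        ls = one_d_landscape(optimum=optimum, width=width, noise_sd=0.0)
        state = init_agent(ONE_D, Arrowhead(start, 50, 50), np.random.default_rng(9))
        d0 = state.direction_memory["length"]
        expected = win_stay_oracle(start, optimum, width, d0, 5, trials)
        rng = np.random.default_rng(123)
        for exp_value, exp_dir in expected:
            state, rec = win_stay_step(state, ls, rng, ONE_D)
            assert rec["design"].length == exp_value
            assert state.direction_memory["length"] == exp_dir
        assert abs(state.design.length - optimum) <= 5

    def test_one_direction_update_per_trial(self, landscape):
        params = AgentParams()
        state = init_agent(params, Arrowhead(50, 50, 50), np.random.default_rng(2))
        rng = np.random.default_rng(2)
        for _ in range(50):
            before = dict(state.direction_memory)
            state, _ = win_stay_step(state, landscape, rng, params)
            changed = [a for a in CONTINUOUS_ATTRIBUTES
                       if before[a] != state.direction_memory[a]]
            assert len(changed) <= 1


class TestSocialUpdates:
    def test_csi_applies_all_deltas_at_once(self):
        ref = Arrowhead(50, 50, 50)
        out = csi_update(ref, {"length": 5, "width": -5, "thickness": 5})
        assert (out.length, out.width, out.thickness) == (55, 45, 55)

    def test_all_zero_deltas_are_identity(self):
        ref = Arrowhead(12, 34, 56, shape=2, color=3)
        assert csi_update(ref, {a: 0 for a in CONTINUOUS_ATTRIBUTES}) == ref
        assert reverse_update(ref, {a: 0 for a in CONTINUOUS_ATTRIBUTES}) == ref

    def test_reverse_is_csi_of_negated_deltas(self):
        ref = Arrowhead(50, 50, 50)
        deltas = {"length": 5, "width": -5, "thickness": 5}
        negated = {a: -d for a, d in deltas.items()}
        assert reverse_update(ref, deltas) == csi_update(ref, negated)
        assert reverse_update(ref, deltas) == Arrowhead(45, 55, 45)

    def test_missing_or_extra_attributes_rejected(self):
        ref = Arrowhead(50, 50, 50)
        with pytest.raises(ValueError, match="delta"):
            csi_update(ref, {"length": 5})
        with pytest.raises(ValueError, match="delta"):
            csi_update(ref, {"length": 5, "width": 1, "thickness": 2, "shape": 1})

    def test_csi_dominates_every_single_delta_design(self):
        """Improving single-attribute deltas combined: on an additive
        landscape the combination beats each single-delta design (away from
        bounds)."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            ls = random_landscape(rng)
            ref = Arrowhead(*(int(v) for v in rng.integers(25, 76, 3)))
            deltas = {}
            for attr in CONTINUOUS_ATTRIBUTES:
                opt = ls.optima[attr]
                cur = getattr(ref, attr)
                step = int(rng.integers(1, 8))
                # improving direction: toward the optimum, never overshooting
                sign = 0 if cur == opt else (1 if opt > cur else -1)
                deltas[attr] = sign * min(step, abs(int(opt) - cur))
            combined = csi_update(ref, deltas)
            combined_fit = expected_fitness(combined, ls)
            for attr, delta in deltas.items():
                single = ref.with_value(attr, getattr(ref, attr) + delta)
                assert combined_fit >= expected_fitness(single, ls) - 1e-9

    def test_reverse_improves_when_hunters_worsen_far_from_optimum(self):
        """Worsening deltas reversed move toward the optimum, so far from it
        (no overshoot) the Reverse result is at least as fit as the
        reference."""
        rng = np.random.default_rng(13)
        improved = 0
        for _ in range(200):
            ls = random_landscape(rng)
            ref_vals, deltas = {}, {}
            for attr in CONTINUOUS_ATTRIBUTES:
                opt = int(ls.optima[attr])
                # place the reference well away from the optimum and bounds
                lo, hi = (5, max(6, opt - 15)) if opt > 50 else (min(95, opt + 15), 96)
                ref_vals[attr] = int(rng.integers(lo, hi + 1))
                step = int(rng.integers(1, 11))
                # worsening direction: away from the optimum
                deltas[attr] = step if ref_vals[attr] > opt else -step
            ref = Arrowhead(**ref_vals)
            out = reverse_update(ref, deltas)
            if expected_fitness(out, ls) >= expected_fitness(ref, ls) - 1e-9:
                improved += 1
        assert improved == 200

    @settings(derandomize=True, max_examples=100)
    @given(
        ref=st.tuples(*[st.integers(1, 100)] * 3),
        deltas=st.tuples(*[st.integers(-150, 150)] * 3),
    )
    def test_updates_always_stay_inside_bounds(self, ref, deltas):
        d = {a: delta for a, delta in zip(CONTINUOUS_ATTRIBUTES, deltas)}
        for update in (csi_update, reverse_update):
            out = update(Arrowhead(*ref), d)
            assert all(1 <= getattr(out, a) <= 100 for a in CONTINUOUS_ATTRIBUTES)
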