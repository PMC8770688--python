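"""Synthetic trial-level datasets emulating the experiment's deposited data.

Two modes.  *Target* mode draws each participant's season-mean score from a
per-condition, per-season normal target and fills the 30 trials with a noisy
rising trend recentred so the participant's season mean is exact — a cheap,
score-level emulation that gives the statistics pipeline a realistic test
surface.  *Simulate* mode runs the full agent-based engine per condition.

The default targets are the experiment's printed condition-by-season group
summaries (mean, SD) with 40 participants per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .simulation_engine import TRIAL_COLUMNS, run_conditions

#: (mean, SD) of participant season-mean scores, per condition and season —
#: the experiment's group summaries (n = 40 per condition).
DEFAULT_SEASON_TARGETS: dict[str, dict[int, tuple[float, float]]] = {
    "asocial": {1: (543.4, 120.9), 2: (625.88, 97.4), 3: (639.0, 146.8)},
    "positive": {1: (599.9, 126.2), 2: (822.32, 87.0), 3: (796.9, 116.2)},
    "negative": {1: (613.3, 162.9), 2: (638.2, 111.3), 3: (626.9, 176.4)},
}

_TRIAL_NOISE_SD = 60.0  # within-participant per-trial scatter, calories
_TREND_SPAN = 120.0  # rise of the within-season trend, calories


@dataclass(frozen=True)
class FixtureSpec:
    """What to generate: cohort sizes, conditions, and either summary
    targets or a full simulation."""

    n_per_condition: int = 40
    conditions: tuple[str, ...] = ("asocial", "positive", "negative")
    season_targets: Optional[Mapping[str, Mapping[int, tuple[float, float]]]] = None
    simulate: bool = False
    n_seasons: int = 3
    trials_per_season: int = 30

    def __post_init__(self) -> None:
        if self.n_per_condition < 2:
            raise ValueError("n_per_condition must be >= 2")
        if not self.conditions:
            raise ValueError("at least one condition required")

    def resolved_targets(self) -> dict[str, dict[int, tuple[float, float]]]:
        targets = self.season_targets or DEFAULT_SEASON_TARGETS
        out: dict[str, dict[int, tuple[float, float]]] = {}
        for cond in self.conditions:
            if cond not in targets:
                raise ValueError(f"no season targets for condition {cond!r}")
            out[cond] = {int(s): tuple(map(float, ms)) for s, ms in targets[cond].items()}
            missing = set(range(1, self.n_seasons + 1)) - set(out[cond])
            if missing:
                raise ValueError(f"condition {cond!r} missing targets for seasons {sorted(missing)}")
        return out


def generate_fixture(spec: FixtureSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Build a trial-level dataset in the standard CSV schema.

    Target mode vectorizes over (participant, season, trial): scores are a
    linear within-season trend plus trial noise, recentred so each
    participant's season mean equals their drawn target; scores are left
    unclipped so the targets' first two moments are exact.  ``true_fitness``
    mirrors ``perceived_score`` (target mode emulates displayed scores, not
    the landscape), and attribute columns hold midpoint placeholders.
    """
    if spec.simulate:
        df, _ = run_conditions(
            conditions=spec.conditions,
            n_agents=spec.n_per_condition,
            seed=int(rng.integers(2**31)),
        )
        return df[TRIAL_COLUMNS + ["algorithm"]].copy()

    targets = spec.resolved_targets()
    n, s, t = spec.n_per_condition, spec.n_seasons, spec.trials_per_season
    trend = np.linspace(-_TREND_SPAN / 2, _TREND_SPAN / 2, t)

    frames = []
    for cond in spec.conditions:
        mean_sd = np.array([targets[cond][season] for season in range(1, s + 1)])
        participant_means = rng.normal(mean_sd[:, 0], mean_sd[:, 1], size=(n, s))
        scores = participant_means[:, :, None] + trend[None, None, :]
        scores = scores + rng.normal(0.0, _TRIAL_NOISE_SD, size=scores.shape)
        # recentre so each participant-season mean is exactly the drawn target
        scores += (participant_means - scores.mean(axis=2))[:, :, None]

        frames.append(
            pd.DataFrame(
                {
                    "agent_id": np.repeat(np.arange(n), s * t),
                    "condition": cond,
                    "season": np.tile(np.repeat(np.arange(1, s + 1), t), n),
                    "trial": np.tile(np.arange(1, t + 1), n * s),
                    "length": 50, "width": 50, "thickness": 50,
                    "shape": 1, "color": 1,
                    "true_fitness": scores.ravel(),
                    "perceived_score": scores.ravel(),
                    "social_event": False,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def null_fixture_spec(n_per_condition: int = 40) -> FixtureSpec:
    """A zero-effect spec: every condition shares the asocial targets."""
    base = DEFAULT_SEASON_TARGETS["asocial"]
    return FixtureSpec(
        n_per_condition=n_per_condition,
        season_targets={c: base for c in ("asocial", "positive", "negative")},
    )
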