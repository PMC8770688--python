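"""Cohort simulation of the 3-season x 30-trial arrowhead task.

Agents run the Win-Stay rule on every trial except the scheduled social
trials of Seasons 2-3 (every third trial), where — depending on condition —
they observe exemplar hunters derived from their previous design and apply
the CSI (positive condition) or Reverse (negative condition) update instead.
Season 1 is always asocial.  Cohort trajectories are summarized on true
fitness (perception noise excluded), as mean / SD / SE per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .learning_agents import (
    AgentParams,
    AgentState,
    csi_update,
    init_agent,
    reverse_update,
    win_stay_step,
)
from .social_information import SocialInfoParams, deltas_by_attribute, generate_hunters
from .task_environment import (
    Arrowhead,
    FitnessLandscape,
    default_landscapes,
    expected_fitness,
    perceived_score,
)

COHORT_CONDITIONS = ("asocial", "positive", "negative")

#: trial-level CSV schema shared with the analysis pipeline and fixtures
TRIAL_COLUMNS = [
    "agent_id",
    "condition",
    "season",
    "trial",
    "length",
    "width",
    "thickness",
    "shape",
    "color",
    "true_fitness",
    "perceived_score",
    "social_event",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one cohort run.

    ``social_phase`` fixes which trials of the social seasons carry a social
    learning opportunity: trials ``phase, phase + period, ...``.  The default
    (phase 2, period 3) puts the first opportunity on the earliest trial that
    has a previous design to build the hunters from.
    """

    condition: str = "asocial"
    n_agents: int = 100
    seed: int = 0
    landscapes: Optional[Sequence[FitnessLandscape]] = None
    n_seasons: int = 3
    trials_per_season: int = 30
    social_period: int = 3
    social_phase: int = 2
    social_seasons: frozenset[int] = frozenset({2, 3})
    step_size: int = 5
    initial_design: Arrowhead = Arrowhead(50, 50, 50, 1, 1)
    social_params: Optional[SocialInfoParams] = None

    def __post_init__(self) -> None:
        if self.condition not in COHORT_CONDITIONS:
            raise ValueError(f"condition must be one of {COHORT_CONDITIONS}")
        if self.social_period < 2:
            raise ValueError("social_period must be >= 2 (hunters derive from a previous trial)")
        if self.social_phase < 2:
            raise ValueError("social_phase must be >= 2 (no previous design exists on trial 1)")
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")

    def resolved_landscapes(self) -> list[FitnessLandscape]:
        landscapes = list(self.landscapes) if self.landscapes is not None else default_landscapes()
        if len(landscapes) != self.n_seasons:
            raise ValueError(
                f"need {self.n_seasons} season landscapes, got {len(landscapes)}"
            )
        return landscapes

    def resolved_social_params(self) -> SocialInfoParams:
        if self.social_params is not None:
            return self.social_params
        return SocialInfoParams(condition=self.condition, mode="simulation")


def is_social_trial(config: SimulationConfig, season: int, trial: int) -> bool:
    """Whether this (season, trial) carries a social learning opportunity."""
    if config.condition == "asocial" or season not in config.social_seasons:
        return False
    return trial >= config.social_phase and (trial - config.social_phase) % config.social_period == 0


def run_agent(
    config: SimulationConfig,
    agent_id: int,
    rng: np.random.Generator,
    params: Optional[AgentParams] = None,
) -> list[dict]:
    """Simulate one agent through all seasons; returns one record per trial.

    On a social trial the hunters are generated from the previous trial's
    design and displayed score, the CSI or Reverse update replaces the
    Win-Stay modification (one design change per trial), the new design is
    hunted, and the previous-score memory is refreshed; direction memory is
    left untouched.  At each season boundary the design carries over but the
    previous-score memory resets, since the landscape changed.
    """
    if params is None:
        algorithm = {"asocial": "asocial", "positive": "CSI", "negative": "Reverse"}[
            config.condition
        ]
        params = AgentParams(step_size=config.step_size, algorithm=algorithm)
    social_params = (
        config.resolved_social_params() if config.condition != "asocial" else None
    )
    landscapes = config.resolved_landscapes()

    state = init_agent(params, config.initial_design, rng)
    records: list[dict] = []
    for season_idx, landscape in enumerate(landscapes, start=1):
        state.previous_perceived_score = None  # new landscape: bootstrap anew
        for trial in range(1, config.trials_per_season + 1):
            social = is_social_trial(config, season_idx, trial)
            if social:
                hunters = generate_hunters(
                    state.design, state.previous_perceived_score, landscape,
                    social_params, rng,
                )
                deltas = deltas_by_attribute(hunters)
                update = csi_update if params.algorithm == "CSI" else reverse_update
                new_design = update(state.design, deltas)
                score = perceived_score(new_design, landscape, rng)
                state.design = new_design
                state.previous_perceived_score = score
                true_fit = expected_fitness(new_design, landscape)
                algorithm_used = params.algorithm
            else:
                state, rec = win_stay_step(state, landscape, rng, params)
                true_fit = rec["true_fitness"]
                score = rec["perceived_score"]
                algorithm_used = "win_stay"

            records.append(
                {
                    "agent_id": agent_id,
                    "condition": config.condition,
                    "season": season_idx,
                    "trial": trial,
                    **state.design.as_dict(),
                    "true_fitness": true_fit,
                    "perceived_score": score,
                    "social_event": social,
                    "algorithm": algorithm_used,
                }
            )
    return records


def run_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run ``n_agents`` independent agents and summarize their trajectories.

    Each agent gets its own child stream spawned from the master seed, so
    cohorts are reproducible and agents statistically independent.  Returns
    (trial-level records, per-trial summary on true fitness).
    """
    seed_seq = np.random.SeedSequence(config.seed)
    records: list[dict] = []
    for agent_id, child in enumerate(seed_seq.spawn(config.n_agents)):
        records.extend(run_agent(config, agent_id, np.random.default_rng(child)))
    df = pd.DataFrame.from_records(records)
    return df, summarize_trajectories(df)


def summarize_trajectories(records: pd.DataFrame) -> pd.DataFrame:
    """Per (condition, season, trial) mean / SD / SE / n of true fitness —
    the quantities plotted as cohort trajectories (noise excluded)."""
    grouped = records.groupby(["condition", "season", "trial"])["true_fitness"]
    summary = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    summary["se"] = summary["sd"] / np.sqrt(summary["n"])
    return summary


def run_conditions(
    conditions: Sequence[str] = COHORT_CONDITIONS,
    n_agents: int = 100,
    seed: int = 0,
    **config_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run one cohort per condition on a shared landscape set and pool the
    records; per-condition seeds are spawned from the master seed."""
    seed_seq = np.random.SeedSequence(seed)
    children = seed_seq.generate_state(len(conditions))
    frames = []
    for condition, child_seed in zip(conditions, children):
        cfg = SimulationConfig(
            condition=condition, n_agents=n_agents, seed=int(child_seed) % (2**31),
            **config_kwargs,
        )
        df, _ = run_cohort(cfg)
        frames.append(df)
    pooled = pd.concat(frames, ignore_index=True)
    return pooled, summarize_trajectories(pooled)
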