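"""Learning algorithms: the Win-Stay asocial rule and the CSI / Reverse
social-learning updates.

Win-Stay is a Skinnerian trial-and-error rule: each trial the agent picks one
of its continuous attributes at random, moves it by a fixed step in the
direction it memorized for that attribute, hunts, and keeps the direction if
the (noisy) score did not decrease relative to the previous trial — flipping
it otherwise.  CSI (copy-successful-individuals) adopts all of the
single-attribute modifications shown by better-performing exemplars at once;
Reverse applies the negation of each modification shown by worse-performing
exemplars.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .task_environment import (
    ATTR_MAX,
    ATTR_MIN,
    CONTINUOUS_ATTRIBUTES,
    Arrowhead,
    FitnessLandscape,
    expected_fitness,
    perceived_score,
)

ALGORITHMS = ("asocial", "CSI", "Reverse")


@dataclass(frozen=True)
class AgentParams:
    """Tunables of a simulated learner.

    ``step_size`` is the Win-Stay modification size L_i in attribute units
    (default 5, the median of empirically observed modification sizes).
    ``attributes`` restricts which continuous attributes Win-Stay samples;
    the default is all three.
    """

    step_size: int = 5
    algorithm: str = "asocial"
    attributes: tuple[str, ...] = CONTINUOUS_ATTRIBUTES
    flip_at_wall: bool = False

    def __post_init__(self) -> None:
        if self.step_size < 1:
            raise ValueError("step_size must be >= 1")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")
        if not self.attributes or any(a not in CONTINUOUS_ATTRIBUTES for a in self.attributes):
            raise ValueError("attributes must be a non-empty subset of the continuous attributes")


@dataclass
class AgentState:
    """A learner's memory: current design, last perceived score (``None``
    before the first hunt of a season), and a +/-1 direction per continuous
    attribute."""

    design: Arrowhead
    previous_perceived_score: Optional[float]
    direction_memory: dict[str, int]

    def __post_init__(self) -> None:
        if set(self.direction_memory) != set(CONTINUOUS_ATTRIBUTES):
            raise ValueError("direction_memory must hold exactly one sign per continuous attribute")
        if any(s not in (-1, 1) for s in self.direction_memory.values()):
            raise ValueError("direction_memory entries must be +1 or -1")


def init_agent(
    params: AgentParams, initial_design: Arrowhead, rng: np.random.Generator
) -> AgentState:
    """Fresh agent state: the given design, no previous score, and a uniform
    random +/-1 direction memory per continuous attribute."""
    directions = {a: int(rng.choice((-1, 1))) for a in CONTINUOUS_ATTRIBUTES}
    return AgentState(design=initial_design, previous_perceived_score=None,
                      direction_memory=directions)


def win_stay_step(
    state: AgentState,
    landscape: FitnessLandscape,
    rng: np.random.Generator,
    params: AgentParams = AgentParams(),
) -> tuple[AgentState, dict]:
    """One Win-Stay trial: modify one randomly chosen attribute by the step
    size in the memorized direction (clamped to [1, 100]), hunt, and update
    the focal attribute's direction memory.

    The direction is kept if the new perceived score did not decrease
    relative to the previous trial's and flipped if it did.  On the first
    trial of a season no previous score exists, so the score is stored
    without any flip.  Exactly one attribute's direction can change per call.
    Mutates ``state`` in place and returns it with a per-trial record.
    """
    attr = params.attributes[int(rng.integers(len(params.attributes)))]
    direction = state.direction_memory[attr]
    old_value = getattr(state.design, attr)
    new_value = int(np.clip(old_value + direction * params.step_size, ATTR_MIN, ATTR_MAX))
    new_design = state.design.with_value(attr, new_value)

    score = perceived_score(new_design, landscape, rng)
    if state.previous_perceived_score is not None and score < state.previous_perceived_score:
        state.direction_memory[attr] = -direction
    elif params.flip_at_wall and new_value == old_value:
        # Optional variant: a step absorbed entirely by the attribute bound
        # flips the direction even though the score cannot have decreased.
        state.direction_memory[attr] = -direction

    state.design = new_design
    state.previous_perceived_score = score
    record = {
        "attribute": attr,
        "design": new_design,
        "true_fitness": expected_fitness(new_design, landscape),
        "perceived_score": score,
    }
    return state, record


def _apply_deltas(reference: Arrowhead, deltas: Mapping[str, int], sign: int) -> Arrowhead:
    if set(deltas) != set(CONTINUOUS_ATTRIBUTES):
        raise ValueError(
            "deltas must contain exactly one entry per continuous attribute; "
            f"got keys {sorted(deltas)}"
        )
    design = reference
    for attr, delta in deltas.items():
        value = int(np.clip(getattr(reference, attr) + sign * int(delta), ATTR_MIN, ATTR_MAX))
        design = design.with_value(attr, value)
    return design


def csi_update(reference: Arrowhead, hunter_deltas: Mapping[str, int]) -> Arrowhead:
    """Copy-successful-individuals: apply every hunter's single-attribute
    modification to the reference at once (clamped to bounds).

    On an additive landscape with improving deltas the combined design is at
    least as fit as any single hunter's design, except where clamping binds.
    """
    return _apply_deltas(reference, hunter_deltas, +1)


def reverse_update(reference: Arrowhead, hunter_deltas: Mapping[str, int]) -> Arrowhead:
    """Negative observational learning: apply the negation of every hunter's
    modification (clamped to bounds)."""
    return _apply_deltas(reference, hunter_deltas, -1)
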