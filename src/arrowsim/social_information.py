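"""Generation of the "other hunters" — the positive or negative exemplars.

Each hunter's arrowhead is the learner's previous ("reference") design with a
single continuous attribute perturbed.  Modification magnitudes are drawn as
|N(10, 10^2)| (rounded to integer attribute units) and the sign is chosen to
strictly increase (positive condition) or strictly reduce (negative
condition) expected fitness.  A fresh perception-noise draw then produces the
displayed score, and the (magnitude, noise) pair is rejection-resampled — up
to 10,000 times — until the hunter's arrowhead beats (or trails) the
reference in *both* true and perceived score strictly.  If no acceptable pair
is found the hunter falls back to an exact copy of the reference, which
typically happens when the learner sits at the landscape optimum (positive)
or in a fitness desert (negative).

Experiment mode shows 4 hunters (one per continuous attribute plus one on a
random attribute); simulation mode shows 3, one per attribute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .task_environment import (
    ATTR_MAX,
    ATTR_MIN,
    CONTINUOUS_ATTRIBUTES,
    Arrowhead,
    FitnessLandscape,
    expected_fitness,
    expected_fitness_1d,
)

CONDITIONS = ("positive", "negative")
MODES = ("experiment", "simulation")

# Rejection sampling draws attempts in fixed-size batches; the batch size is
# a constant so that a given rng seed always yields the same hunters.
_BATCH = 512


@dataclass(frozen=True)
class SocialInfoParams:
    """Knobs of the exemplar generator."""

    condition: str = "positive"
    mode: str = "simulation"
    n_hunters: Optional[int] = None  # default: 4 experiment / 3 simulation
    magnitude_mean: float = 10.0
    magnitude_sd: float = 10.0
    max_resamples: int = 10_000

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.max_resamples < 1:
            raise ValueError("max_resamples must be >= 1")
        if self.n_hunters is not None and self.n_hunters < 1:
            raise ValueError("n_hunters must be >= 1")

    @property
    def resolved_n_hunters(self) -> int:
        if self.n_hunters is not None:
            return self.n_hunters
        return 3 if self.mode == "simulation" else 4


@dataclass(frozen=True)
class HunterObservation:
    """One exemplar: the modified design, which attribute moved and by how
    much, its true fitness, and the noisy score that was displayed."""

    design: Arrowhead
    modified_attribute: str
    delta: int
    true_fitness: float
    displayed_score: float
    fallback: bool = False


def choose_sign(
    reference: Arrowhead,
    attribute: str,
    magnitude: int,
    landscape: FitnessLandscape,
    condition: str,
) -> Optional[int]:
    """Sign of a single-attribute modification of the given magnitude that
    strictly increases (positive) or strictly reduces (negative) expected
    fitness, evaluated at the bound-clamped candidate values.

    Returns ``None`` when neither direction qualifies (e.g. at a 1-D optimum
    in the positive condition).  If both qualify, the direction with the
    larger effect wins; ties break to +.
    """
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    ref_value = getattr(reference, attribute)
    ref_fit = expected_fitness(reference, landscape)
    candidates = np.clip([ref_value + magnitude, ref_value - magnitude], ATTR_MIN, ATTR_MAX)
    fits = expected_fitness_1d(landscape, reference, attribute, candidates)
    if condition == "positive":
        best = int(np.argmax(fits))  # ties -> index 0 -> sign +
        return (+1, -1)[best] if fits[best] > ref_fit else None
    best = int(np.argmin(fits))
    return (+1, -1)[best] if fits[best] < ref_fit else None


def _sample_hunter(
    reference: Arrowhead,
    reference_perceived: float,
    ref_true: float,
    attribute: str,
    landscape: FitnessLandscape,
    params: SocialInfoParams,
    rng: np.random.Generator,
) -> HunterObservation:
    """Rejection-sample one hunter on one attribute (vectorized in batches).

    Each attempt draws a fresh magnitude and a fresh perception noise; the
    first attempt whose sign-chosen candidate strictly beats/trails the
    reference in both true and displayed score is accepted.
    """
    positive = params.condition == "positive"
    ref_value = getattr(reference, attribute)
    remaining = params.max_resamples
    while remaining > 0:
        k = min(_BATCH, remaining)
        remaining -= k
        magnitudes = np.rint(np.abs(rng.normal(params.magnitude_mean, params.magnitude_sd, k)))
        noises = rng.normal(0.0, landscape.noise_sd, k)

        up = np.clip(ref_value + magnitudes, ATTR_MIN, ATTR_MAX)
        down = np.clip(ref_value - magnitudes, ATTR_MIN, ATTR_MAX)
        fit_up = expected_fitness_1d(landscape, reference, attribute, up)
        fit_down = expected_fitness_1d(landscape, reference, attribute, down)

        if positive:
            take_up = fit_up >= fit_down  # ties -> +, mirroring choose_sign
            true_fit = np.where(take_up, fit_up, fit_down)
            ok_true = true_fit > ref_true
        else:
            take_up = fit_up <= fit_down
            true_fit = np.where(take_up, fit_up, fit_down)
            ok_true = true_fit < ref_true

        displayed = np.clip(true_fit + noises, landscape.score_floor, landscape.score_ceiling)
        ok_disp = displayed > reference_perceived if positive else displayed < reference_perceived
        ok = ok_true & ok_disp
        if ok.any():
            i = int(np.argmax(ok))
            value = int((up if take_up[i] else down)[i])
            return HunterObservation(
                design=reference.with_value(attribute, value),
                modified_attribute=attribute,
                delta=value - ref_value,
                true_fitness=float(true_fit[i]),
                displayed_score=float(displayed[i]),
            )

    # Resampling budget exhausted: the hunter copies the reference.
    displayed = float(
        np.clip(
            ref_true + rng.normal(0.0, landscape.noise_sd),
            landscape.score_floor,
            landscape.score_ceiling,
        )
    )
    return HunterObservation(
        design=reference,
        modified_attribute=attribute,
        delta=0,
        true_fitness=ref_true,
        displayed_score=displayed,
        fallback=True,
    )


def generate_hunters(
    reference: Arrowhead,
    reference_perceived: float,
    landscape: FitnessLandscape,
    params: SocialInfoParams,
    rng: np.random.Generator,
) -> list[HunterObservation]:
    """Generate the condition's exemplar hunters from the reference design.

    The first three hunters cover length, width and thickness (one each); any
    further hunters (experiment mode's fourth) perturb a uniformly random
    attribute.
    """
    n = params.resolved_n_hunters
    attributes = list(CONTINUOUS_ATTRIBUTES[: min(n, 3)])
    while len(attributes) < n:
        attributes.append(CONTINUOUS_ATTRIBUTES[int(rng.integers(3))])

    ref_true = expected_fitness(reference, landscape)
    return [
        _sample_hunter(reference, reference_perceived, ref_true, attr, landscape, params, rng)
        for attr in attributes
    ]


def deltas_by_attribute(hunters: list[HunterObservation]) -> dict[str, int]:
    """Map each continuous attribute to its hunter's delta (0 for fallbacks
    and for attributes no hunter modified).  With duplicate attributes the
    first hunter wins."""
    deltas = {a: 0 for a in CONTINUOUS_ATTRIBUTES}
    seen: set[str] = set()
    for h in hunters:
        if h.modified_attribute not in seen:
            deltas[h.modified_attribute] = h.delta
            seen.add(h.modified_attribute)
    return deltas
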