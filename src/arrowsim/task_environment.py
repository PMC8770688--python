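"""Arrowhead designs, season-specific fitness landscapes, and noisy scoring.

The virtual arrowhead task asks a learner to tune five attributes of a
projectile point — three bounded integers (length, width, thickness in
[1, 100]) and two four-option categorical traits (shape, color) — and pays
out a "calorie" score drawn from a hidden fitness landscape.  The landscape
is additive and independent across attributes and unimodal per continuous
attribute; the displayed score is the expected fitness perturbed by
zero-mean Gaussian perception noise (SD 5 calories) and clamped to the
printed range [1, 1000].

The per-attribute contribution function is pluggable.  The default is a
Gaussian bump ``c_i * exp(-(x - mu_i)^2 / (2 w_i^2))`` — smooth, unimodal,
and additive, satisfying every constraint the task places on the landscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

CONTINUOUS_ATTRIBUTES: tuple[str, ...] = ("length", "width", "thickness")
CATEGORICAL_ATTRIBUTES: tuple[str, ...] = ("shape", "color")
ALL_ATTRIBUTES: tuple[str, ...] = CONTINUOUS_ATTRIBUTES + CATEGORICAL_ATTRIBUTES

ATTR_MIN, ATTR_MAX = 1, 100
N_CATEGORICAL_OPTIONS = 4
SCORE_FLOOR, SCORE_CEILING = 1.0, 1000.0


@dataclass(frozen=True)
class Arrowhead:
    """A candidate arrowhead design.

    Continuous attributes are integers in [1, 100]; categorical attributes
    are one of four options (coded 1-4).
    """

    length: int
    width: int
    thickness: int
    shape: int = 1
    color: int = 1

    def __post_init__(self) -> None:
        for attr in CONTINUOUS_ATTRIBUTES:
            v = getattr(self, attr)
            if not (ATTR_MIN <= v <= ATTR_MAX):
                raise ValueError(
                    f"attribute {attr!r} must lie in [{ATTR_MIN}, {ATTR_MAX}], got {v}"
                )
        for attr in CATEGORICAL_ATTRIBUTES:
            v = getattr(self, attr)
            if v not in range(1, N_CATEGORICAL_OPTIONS + 1):
                raise ValueError(
                    f"attribute {attr!r} must be one of 1..{N_CATEGORICAL_OPTIONS}, got {v}"
                )

    def with_value(self, attribute: str, value: int) -> "Arrowhead":
        """Return a copy with one attribute replaced (revalidated)."""
        return replace(self, **{attribute: int(value)})

    def continuous(self) -> dict[str, int]:
        return {a: getattr(self, a) for a in CONTINUOUS_ATTRIBUTES}

    def as_dict(self) -> dict[str, int]:
        return {a: getattr(self, a) for a in ALL_ATTRIBUTES}


def gaussian_bump(x, optimum: float, width: float, maximum: float):
    """Default unimodal per-attribute contribution: a Gaussian bump.

    Vectorized over ``x``; peaks at ``maximum`` when ``x == optimum`` and
    decays monotonically with ``|x - optimum|``.
    """
    x = np.asarray(x, dtype=float)
    return maximum * np.exp(-((x - optimum) ** 2) / (2.0 * width**2))


ContributionFn = Callable[..., np.ndarray]


@dataclass(frozen=True)
class FitnessLandscape:
    """Season-specific additive mapping from designs to expected calories.

    ``optima``, ``maxima`` and ``widths`` are per-continuous-attribute;
    ``categorical_contributions`` maps each categorical attribute to four
    per-option calorie contributions (all zero by default — the simulation
    ignores the discrete attributes).  Calibration (continuous maxima summing
    to the 1000-calorie ceiling) is enforced by :func:`make_landscape`, not
    here, so tests can build degenerate landscapes directly.
    """

    season: int
    optima: Mapping[str, float]
    maxima: Mapping[str, float]
    widths: Mapping[str, float]
    categorical_contributions: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {a: (0.0,) * N_CATEGORICAL_OPTIONS for a in CATEGORICAL_ATTRIBUTES}
    )
    noise_sd: float = 5.0
    score_floor: float = SCORE_FLOOR
    score_ceiling: float = SCORE_CEILING
    contribution: ContributionFn = gaussian_bump

    def __post_init__(self) -> None:
        for attr in CONTINUOUS_ATTRIBUTES:
            if attr not in self.optima or attr not in self.maxima or attr not in self.widths:
                raise ValueError(f"landscape missing parameters for attribute {attr!r}")
            if self.widths[attr] <= 0:
                raise ValueError(f"width for {attr!r} must be positive")
            if self.maxima[attr] < 0:
                raise ValueError(f"maximum contribution for {attr!r} must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def attribute_contribution(self, attribute: str, values) -> np.ndarray:
        """Expected contribution of one continuous attribute (vectorized)."""
        return self.contribution(
            values, self.optima[attribute], self.widths[attribute], self.maxima[attribute]
        )


def expected_fitness(design: Arrowhead, landscape: FitnessLandscape) -> float:
    """Noise-free expected calorie score of a design: the sum of per-attribute
    contributions (continuous bumps plus categorical option contributions)."""
    total = 0.0
    for attr in CONTINUOUS_ATTRIBUTES:
        total += float(landscape.attribute_contribution(attr, getattr(design, attr)))
    for attr in CATEGORICAL_ATTRIBUTES:
        total += float(landscape.categorical_contributions[attr][getattr(design, attr) - 1])
    return total


def expected_fitness_1d(
    landscape: FitnessLandscape, design: Arrowhead, attribute: str, values
) -> np.ndarray:
    """Expected fitness of ``design`` with ``attribute`` replaced by each of
    ``values`` (vectorized); exploits additivity to avoid re-summing."""
    base = expected_fitness(design, landscape)
    cur = float(landscape.attribute_contribution(attribute, getattr(design, attribute)))
    return base - cur + landscape.attribute_contribution(attribute, values)


def perceived_score(
    design: Arrowhead, landscape: FitnessLandscape, rng: np.random.Generator
) -> float:
    """Noisy displayed score: expected fitness plus one N(0, noise_sd^2) draw,
    clamped to [score_floor, score_ceiling].

    A noise draw is consumed even when ``noise_sd`` is 0, so trajectories
    remain stream-compatible across noise settings.
    """
    noise = rng.normal(0.0, landscape.noise_sd) if landscape.noise_sd > 0 else rng.normal(0.0, 0.0)
    raw = expected_fitness(design, landscape) + noise
    return float(np.clip(raw, landscape.score_floor, landscape.score_ceiling))


def make_landscape(config: Mapping, *, auto_rescale: bool = False) -> FitnessLandscape:
    """Build a calibrated landscape from a configuration mapping.

    Expected keys: ``season``, ``optima``, ``maxima``, ``widths`` (each of the
    latter three a mapping over length/width/thickness), and optionally
    ``categorical_contributions``, ``noise_sd``.

    The continuous maxima must sum to the 1000-calorie ceiling so that the
    expected score at the joint optimum equals the ceiling; with
    ``auto_rescale=True`` they are rescaled proportionally instead of
    rejected.
    """
    optima = {a: float(config["optima"][a]) for a in CONTINUOUS_ATTRIBUTES}
    maxima = {a: float(config["maxima"][a]) for a in CONTINUOUS_ATTRIBUTES}
    widths = {a: float(config["widths"][a]) for a in CONTINUOUS_ATTRIBUTES}
    for attr, w in widths.items():
        if w <= 0:
            raise ValueError(f"width for {attr!r} must be positive, got {w}")

    total = sum(maxima.values())
    if abs(total - SCORE_CEILING) > 1e-9:
        if not auto_rescale:
            raise ValueError(
                f"continuous maxima sum to {total}, not {SCORE_CEILING}; "
                "pass auto_rescale=True to rescale proportionally"
            )
        if total <= 0:
            raise ValueError("cannot rescale maxima with non-positive sum")
        maxima = {a: m * SCORE_CEILING / total for a, m in maxima.items()}

    kwargs: dict = {}
    if "categorical_contributions" in config:
        kwargs["categorical_contributions"] = {
            a: tuple(float(v) for v in config["categorical_contributions"][a])
            for a in CATEGORICAL_ATTRIBUTES
        }
    if "noise_sd" in config:
        kwargs["noise_sd"] = float(config["noise_sd"])

    return FitnessLandscape(
        season=int(config["season"]),
        optima=optima,
        maxima=maxima,
        widths=widths,
        **kwargs,
    )


# Demo season configurations.  The per-season optima of the original
# experiment were never published (the figures show them only as dotted
# lines), so these are package choices: three seasons with distinct optima,
# equal-thirds maxima, and widths wide enough that the score gradient is
# informative across most of the attribute range.
DEFAULT_SEASON_CONFIGS: tuple[dict, ...] = (
    {
        "season": 1,
        "optima": {"length": 57, "width": 24, "thickness": 76},
        "maxima": {"length": 400.0, "width": 300.0, "thickness": 300.0},
        "widths": {"length": 18.0, "width": 18.0, "thickness": 18.0},
    },
    {
        "season": 2,
        "optima": {"length": 30, "width": 81, "thickness": 46},
        "maxima": {"length": 400.0, "width": 300.0, "thickness": 300.0},
        "widths": {"length": 18.0, "width": 18.0, "thickness": 18.0},
    },
    {
        "season": 3,
        "optima": {"length": 72, "width": 40, "thickness": 15},
        "maxima": {"length": 400.0, "width": 300.0, "thickness": 300.0},
        "widths": {"length": 18.0, "width": 18.0, "thickness": 18.0},
    },
)


def default_landscapes() -> list[FitnessLandscape]:
    """The three demo season landscapes used by the CLI and cohort defaults."""
    return [make_landscape(cfg) for cfg in DEFAULT_SEASON_CONFIGS]


def load_landscape_configs(path) -> list[FitnessLandscape]:
    """Load per-season landscape configs from a YAML file.

    The file holds either a list of season configs or a mapping with a
    ``seasons`` key; each entry follows the :func:`make_landscape` schema.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["seasons"] if isinstance(doc, Mapping) else doc
    landscapes = [make_landscape(entry, auto_rescale=bool(entry.get("auto_rescale", False)))
                  for entry in entries]
    if len({ls.season for ls in landscapes}) != len(landscapes):
        raise ValueError("duplicate season ids in landscape config")
    return sorted(landscapes, key=lambda ls: ls.season)
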