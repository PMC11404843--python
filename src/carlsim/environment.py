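"""Static two-armed Bernoulli bandit with ±1 payoffs and scarcity presets.

Arms are indexed 0 and 1; every preset satisfies ``p1 > p2``, so index 0 is
always the objectively better arm. Analysis code relies on this convention
when it defines the Q-value gap as ``Q(best) - Q(worst)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ARM_BEST",
    "ARM_WORST",
    "BanditTask",
    "ConfigurationError",
    "SCARCITY_PRESETS",
    "as_task",
    "expected_random_performance",
    "sample_payoffs",
    "scarcity_preset",
]

ARM_BEST = 0
ARM_WORST = 1

#: Reward probabilities (p1, p2) for the three scarcity regimes.
SCARCITY_PRESETS: dict[str, tuple[float, float]] = {
    "poor": (0.3, 0.1),
    "mixed": (0.6, 0.4),
    "rich": (0.9, 0.7),
}


class ConfigurationError(ValueError):
    """Raised for invalid task / experiment configuration."""


@dataclass(frozen=True)
class BanditTask:
    """A two-armed bandit returning +1 with probability ``p`` and −1 otherwise.

    Parameters
    ----------
    p1 : float
        Reward probability of arm 0.
    p2 : float
        Reward probability of arm 1.
    """

    p1: float
    p2: float

    def __post_init__(self) -> None:
        for name, p in (("p1", self.p1), ("p2", self.p2)):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"{name} must lie in [0, 1], got {p!r}"
                )

    @property
    def probs(self) -> np.ndarray:
        """Reward probabilities as an array indexed by arm."""
        return np.array([self.p1, self.p2])

    def expected_payoffs(self) -> np.ndarray:
        """Expected payoff ``2p - 1`` for each arm."""
        return 2.0 * self.probs - 1.0


def scarcity_preset(name: str) -> BanditTask:
    """Return the bandit for a named scarcity regime.

    >>> scarcity_preset("poor")
    BanditTask(p1=0.3, p2=0.1)
    """
    try:
        p1, p2 = SCARCITY_PRESETS[name]
    except KeyError:
        valid = ", ".join(sorted(SCARCITY_PRESETS))
        raise ConfigurationError(
            f"unknown scarcity preset {name!r}; valid presets: {valid}"
        ) from None
    return BanditTask(p1, p2)


def as_task(task: BanditTask | str | tuple[float, float]) -> BanditTask:
    """Coerce a preset name, (p1, p2) pair, or task into a :class:`BanditTask`."""
    if isinstance(task, BanditTask):
        return task
    if isinstance(task, str):
        return scarcity_preset(task)
    p1, p2 = task
    return BanditTask(float(p1), float(p2))


def sample_payoffs(
    task: BanditTask, actions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw independent ±1 payoffs for each agent's chosen arm.

    Agents choosing the same arm in the same trial receive independent
    draws; the per-agent outcome is what feeds the confirmatory /
    disconfirmatory bookkeeping downstream.
    """
    actions = np.asarray(actions)
    if actions.size and not np.isin(actions, (0, 1)).all():
        raise ValueError("actions must be arm indices in {0, 1}")
    p = task.probs[actions]
    return np.where(rng.random(actions.shape) < p, 1, -1)


def expected_random_performance(task: BanditTask) -> float:
    """Expected payoff per trial under a uniform-random policy.

    Equals ``0.5*(2*p1 - 1) + 0.5*(2*p2 - 1) = p1 + p2 - 1``:
    −0.6 / 0.0 / 0.6 for the poor / mixed / rich presets.
    """
    return task.p1 + task.p2 - 1.0
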