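"""Agent state, softmax choice, feedback classification, and the asymmetric
collective update rule.

Every agent observes all group members' actions and payoffs each trial and
sorts them into four sets relative to its own choice: rewards on its chosen
arm and penalties on the unchosen arm are *confirmatory* (learning rate
``alpha_plus``); penalties on the chosen arm and rewards on the unchosen arm
are *disconfirmatory* (``alpha_minus``). Each prediction error is scaled by
``1/n`` so no single update exceeds the classic Rescorla–Wagner step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AgentState",
    "BiasSpec",
    "FeedbackPartition",
    "carl_update",
    "choose_actions",
    "classify_feedback",
    "resolve_bias",
    "softmax_policy",
]

_EXP_CLAMP = 500.0


@dataclass
class AgentState:
    """Per-agent Q-values and learning parameters.

    Q-values stay inside [−1, 1] for payoffs in {+1, −1}: each update moves
    the value toward a payoff by a convex step of size ≤ alpha.
    """

    q: np.ndarray
    alpha_plus: float
    alpha_minus: float
    beta: float

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (2,):
            raise ValueError("q must have one value per arm (shape (2,))")
        if not (-1.0 <= self.q).all() or not (self.q <= 1.0).all():
            raise ValueError("Q-values must lie in [-1, 1]")
        for name, a in (("alpha_plus", self.alpha_plus), ("alpha_minus", self.alpha_minus)):
            if not 0.0 < a <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {a!r}")
        if self.beta < 0.0:
            raise ValueError("beta must be >= 0")


@dataclass(frozen=True)
class BiasSpec:
    """Specification of the learning-rate pair via a bias strength.

    Schemes
    -------
    ``fixed_sum``
        Rates satisfy ``alpha_plus + alpha_minus = 0.2`` with ratio ``b``,
        i.e. ``(0.2*b/(1+b), 0.2/(1+b))``. Reproduces the printed pairs:
        b=3 → (0.15, 0.05); b=17/3 → (0.17, 0.03); b=9 → (0.18, 0.02);
        b=1 → (0.1, 0.1).
    ``fixed_minus``
        ``alpha_minus = 0.1`` and ``alpha_plus = b * 0.1``.
    ``explicit``
        The rates are given directly.
    """

    scheme: str = "fixed_sum"
    b: float | None = None
    alpha_plus: float | None = None
    alpha_minus: float | None = None

    def resolve(self) -> tuple[float, float]:
        return resolve_bias(self)

    @property
    def strength(self) -> float:
        """Bias strength b = alpha_plus / alpha_minus."""
        ap, am = self.resolve()
        return ap / am


def resolve_bias(spec: BiasSpec) -> tuple[float, float]:
    """Return the ``(alpha_plus, alpha_minus)`` pair encoded by ``spec``."""
    if spec.scheme == "explicit":
        if spec.alpha_plus is None or spec.alpha_minus is None:
            raise ValueError("explicit scheme requires alpha_plus and alpha_minus")
        ap, am = float(spec.alpha_plus), float(spec.alpha_minus)
    else:
        if spec.b is None:
            raise ValueError(f"scheme {spec.scheme!r} requires bias strength b")
        b = float(spec.b)
        if b <= 0.0:
            raise ValueError(f"bias strength must be > 0, got {b!r}")
        if spec.scheme == "fixed_sum":
            ap, am = 0.2 * b / (1.0 + b), 0.2 / (1.0 + b)
        elif spec.scheme == "fixed_minus":
            ap, am = 0.1 * b, 0.1
        else:
            raise ValueError(
                f"unknown bias scheme {spec.scheme!r}; "
                "expected fixed_sum, fixed_minus, or explicit"
            )
    for name, a in (("alpha_plus", ap), ("alpha_minus", am)):
        if not 0.0 < a <= 1.0:
            raise ValueError(f"resolved {name}={a!r} outside (0, 1]")
    return ap, am


def softmax_policy(q: np.ndarray, beta: float, arm: int) -> float:
    """Probability of choosing ``arm`` given the Q-value pair.

    Logistic in the Q-value difference: ``1 / (1 + exp(-beta*(Q(arm) -
    Q(other))))``. The exponent is clamped at ±500 so arbitrarily large
    ``beta`` stays finite; an exact tie yields exactly 0.5.
    """
    if beta < 0.0:
        raise ValueError("beta must be >= 0")
    d = beta * (q[arm] - q[1 - arm])
    d = min(max(d, -_EXP_CLAMP), _EXP_CLAMP)
    return 1.0 / (1.0 + math.exp(-d))


def choose_actions(states: list[AgentState], rng: np.random.Generator) -> np.ndarray:
    """Sample each agent's arm independently from its own softmax policy."""
    p_best = np.array([softmax_policy(s.q, s.beta, 0) for s in states])
    return (rng.random(len(states)) >= p_best).astype(np.int64)


@dataclass(frozen=True)
class FeedbackPartition:
    """The four observation sets from one focal agent's point of view.

    ``r_c``/``p_c`` hold agents (the focal one included) who chose the focal
    agent's arm and were rewarded / penalized; ``r_u``/``p_u`` the same for
    the other arm. The sets are disjoint and cover the whole group.
    """

    chosen_arm: int
    r_c: frozenset[int] = field(default_factory=frozenset)
    p_c: frozenset[int] = field(default_factory=frozenset)
    r_u: frozenset[int] = field(default_factory=frozenset)
    p_u: frozenset[int] = field(default_factory=frozenset)

    def sizes(self) -> tuple[int, int, int, int]:
        return len(self.r_c), len(self.p_c), len(self.r_u), len(self.p_u)


def classify_feedback(
    focal: int, actions: np.ndarray, payoffs: np.ndarray
) -> FeedbackPartition:
    """Partition the group's observations relative to ``focal``'s choice."""
    actions = np.asarray(actions)
    payoffs = np.asarray(payoffs)
    if actions.shape != payoffs.shape:
        raise ValueError(
            f"actions and payoffs must have equal length, "
            f"got {actions.shape} vs {payoffs.shape}"
        )
    n = len(actions)
    if not 0 <= focal < n:
        raise ValueError(f"focal index {focal} out of range for group of {n}")
    chosen = int(actions[focal])
    same = actions == chosen
    rewarded = payoffs == 1
    return FeedbackPartition(
        chosen_arm=chosen,
        r_c=frozenset(np.flatnonzero(same & rewarded).tolist()),
        p_c=frozenset(np.flatnonzero(same & ~rewarded).tolist()),
        r_u=frozenset(np.flatnonzero(~same & rewarded).tolist()),
        p_u=frozenset(np.flatnonzero(~same & ~rewarded).tolist()),
    )


def carl_update(state: AgentState, partition: FeedbackPartition, n: int) -> np.ndarray:
    """One trial's Q-value update for the focal agent.

    Chosen arm:   ΔQ = (1/n)·[α⁺·|r_c|·(1−Q) + α⁻·|p_c|·(−1−Q)]
    Unchosen arm: ΔQ = (1/n)·[α⁺·|p_u|·(−1−Q) + α⁻·|r_u|·(1−Q)]

    All prediction errors use the start-of-trial Q-values (the observations
    within a trial are summed, not chained). Returns the new Q pair.
    """
    if len(partition.r_c) + len(partition.p_c) + len(partition.r_u) + len(partition.p_u) != n:
        raise ValueError("partition does not cover a group of size n")
    c = partition.chosen_arm
    u = 1 - c
    ap, am = state.alpha_plus, state.alpha_minus
    q = state.q.copy()
    q[c] += (ap * len(partition.r_c) * (1.0 - q[c])
             + am * len(partition.p_c) * (-1.0 - q[c])) / n
    q[u] += (ap * len(partition.p_u) * (-1.0 - q[u])
             + am * len(partition.r_u) * (1.0 - q[u])) / n
    return q
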