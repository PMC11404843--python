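"""Deterministic (expected-update) two-agent model.

Averages the stochastic update over choice and payoff randomness, giving
noise-free trajectories of both agents' Q-values. For arm ``a`` of agent
``i`` (agent ``j`` mirror-image), with behavior profiles ``X`` from the
softmax at the current Q-values:

    Q'_i(a) = Q_i(a) + (1/2) * [ X_i(a)*(1 + X_j(a)) * delta_c(a)
                                 + (1 - X_i(a))*X_j(a) * delta_u(a) ]

where ``delta_c`` / ``delta_u`` are the per-observation expected updates of a
chosen / unchosen arm. The bracket enumerates the three scenarios: both
choose ``a`` (two confirmatory-side samples), only ``i`` chooses ``a`` (one),
only ``j`` does (one counterfactual sample). The leading 1/2 is the 1/n
group scaling of the stochastic rule; a 10⁵-draw Monte-Carlo expected-update
oracle confirms this normalization (the unscaled bracket would double the
true one-trial expectation; see the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .agents import softmax_policy

__all__ = [
    "DeterministicParams",
    "DeterministicState",
    "deterministic_step",
    "expected_update_chosen",
    "expected_update_unchosen",
    "find_fixed_point",
    "stationary_chosen_q",
    "stationary_unchosen_q",
    "trajectory",
    "trajectory_frame",
]


@dataclass(frozen=True)
class DeterministicParams:
    alpha_plus: float
    alpha_minus: float
    beta: float
    p1: float
    p2: float

    @property
    def probs(self) -> np.ndarray:
        return np.array([self.p1, self.p2])


@dataclass(frozen=True)
class DeterministicState:
    """Q-values of both agents plus shared parameters."""

    q_i: np.ndarray  # (2,)
    q_j: np.ndarray  # (2,)
    params: DeterministicParams

    def __post_init__(self) -> None:
        object.__setattr__(self, "q_i", np.asarray(self.q_i, dtype=float))
        object.__setattr__(self, "q_j", np.asarray(self.q_j, dtype=float))
        for q in (self.q_i, self.q_j):
            if q.shape != (2,):
                raise ValueError("Q-value vectors must have shape (2,)")
            if (np.abs(q) > 1.0).any():
                raise ValueError("Q-values must lie in [-1, 1]")

    def profiles(self) -> tuple[np.ndarray, np.ndarray]:
        """Each agent's probability of choosing arm 0 and arm 1."""
        b = self.params.beta
        x_i = np.array([softmax_policy(self.q_i, b, a) for a in (0, 1)])
        x_j = np.array([softmax_policy(self.q_j, b, a) for a in (0, 1)])
        return x_i, x_j


def expected_update_chosen(q_a: float, p_a: float, alpha_plus: float,
                           alpha_minus: float) -> float:
    """Expected per-observation update of a *chosen* arm's Q-value.

    ``alpha_plus * p_a * (1 - q_a) + alpha_minus * (1 - p_a) * (-1 - q_a)``
    """
    return alpha_plus * p_a * (1.0 - q_a) + alpha_minus * (1.0 - p_a) * (-1.0 - q_a)


def expected_update_unchosen(q_a: float, p_a: float, alpha_plus: float,
                             alpha_minus: float) -> float:
    """Expected per-observation update of an *unchosen* arm (rates swapped)."""
    return alpha_minus * p_a * (1.0 - q_a) + alpha_plus * (1.0 - p_a) * (-1.0 - q_a)


def stationary_chosen_q(p: float, alpha_plus: float, alpha_minus: float) -> float:
    """Root of the chosen-arm expected update in q."""
    num = alpha_plus * p - alpha_minus * (1.0 - p)
    den = alpha_plus * p + alpha_minus * (1.0 - p)
    return num / den


def stationary_unchosen_q(p: float, alpha_plus: float, alpha_minus: float) -> float:
    """Root of the unchosen-arm expected update in q."""
    return stationary_chosen_q(p, alpha_minus, alpha_plus)


def _increments(state: DeterministicState) -> tuple[np.ndarray, np.ndarray]:
    p = state.params
    x_i, x_j = state.profiles()
    probs = p.probs
    inc_i = np.empty(2)
    inc_j = np.empty(2)
    for a in (0, 1):
        dc_i = expected_update_chosen(state.q_i[a], probs[a], p.alpha_plus, p.alpha_minus)
        du_i = expected_update_unchosen(state.q_i[a], probs[a], p.alpha_plus, p.alpha_minus)
        dc_j = expected_update_chosen(state.q_j[a], probs[a], p.alpha_plus, p.alpha_minus)
        du_j = expected_update_unchosen(state.q_j[a], probs[a], p.alpha_plus, p.alpha_minus)
        inc_i[a] = 0.5 * (x_i[a] * (1.0 + x_j[a]) * dc_i
                          + (1.0 - x_i[a]) * x_j[a] * du_i)
        inc_j[a] = 0.5 * (x_j[a] * (1.0 + x_i[a]) * dc_j
                          + (1.0 - x_j[a]) * x_i[a] * du_j)
    return inc_i, inc_j


def deterministic_step(state: DeterministicState) -> DeterministicState:
    """One expected-update step; all four arm-values advance simultaneously."""
    inc_i, inc_j = _increments(state)
    return replace(state, q_i=state.q_i + inc_i, q_j=state.q_j + inc_j)


def trajectory(state0: DeterministicState, steps: int) -> list[DeterministicState]:
    """Iterate ``deterministic_step``; returns ``steps + 1`` states incl. start."""
    if steps < 1:
        raise ValueError("steps must be >= 1")
    states = [state0]
    s = state0
    for _ in range(steps):
        s = deterministic_step(s)
        states.append(s)
    return states


def trajectory_frame(state0: DeterministicState, steps: int):
    """Trajectory as a tidy table: step, agent, arm, q, x."""
    import pandas as pd

    rows = []
    for step, s in enumerate(trajectory(state0, steps)):
        x_i, x_j = s.profiles()
        for agent, (q, x) in enumerate(((s.q_i, x_i), (s.q_j, x_j))):
            for arm in (0, 1):
                rows.append(dict(step=step, agent=agent, arm=arm,
                                 q=q[arm], x=x[arm]))
    return pd.DataFrame(rows)


def find_fixed_point(
    params: DeterministicParams,
    q0: np.ndarray | None = None,
    tol: float = 1e-10,
    damping: float = 0.5,
    max_iter: int = 200_000,
) -> DeterministicState:
    """Damped fixed-point iteration from a symmetric start.

    Stability is probed elsewhere by ε-perturbation of the result, not by
    Jacobian eigenvalues.
    """
    q = np.zeros(2) if q0 is None else np.asarray(q0, dtype=float)
    state = DeterministicState(q_i=q.copy(), q_j=q.copy(), params=params)
    for _ in range(max_iter):
        inc_i, inc_j = _increments(state)
        if max(np.abs(inc_i).max(), np.abs(inc_j).max()) < tol:
            return state
        state = replace(
            state,
            q_i=np.clip(state.q_i + damping * inc_i, -1.0, 1.0),
            q_j=np.clip(state.q_j + damping * inc_j, -1.0, 1.0),
        )
    raise RuntimeError(f"fixed-point iteration did not converge below {tol}")
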