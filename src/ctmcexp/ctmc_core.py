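"""Rate-matrix containers, transition probabilities and path simulation.

A continuous-time Markov chain (CTMC) on ``n`` states is parameterized by an
``n x n`` generator ``Q`` with non-negative off-diagonal rates ``q_cd`` and
diagonal entries ``q_cc = -q_c`` fixing the row sums to zero.  This module
provides validated containers for generators, transition matrices
``P(t) = exp(Qt)`` and sampled trajectories, together with the stationary
distribution, a detailed-balance (reversibility) check and Gillespie path
simulation.  The simulators are the Monte-Carlo oracle for the analytic
endpoint-conditioned expectations in :mod:`ctmcexp.expectations`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, null_space

logger = logging.getLogger("ctmcexp")

#: relative tolerance (times max|Q|) for "rows sum to zero" on user matrices
ROW_SUM_RTOL = 1e-12
#: default relative tolerance for the detailed-balance check
REVERSIBILITY_RTOL = 1e-10
#: row-sum / range tolerance on validated transition matrices
TRANSITION_TOL = 1e-10
#: minimum acceptance probability for the rejection sampler
REJECTION_FLOOR = 1e-6


@dataclass(frozen=True)
class RateMatrix:
    """A validated CTMC generator.

    Use :func:`validate_rate_matrix` to construct one from a raw array.
    """

    Q: np.ndarray
    state_labels: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    @property
    def exit_rates(self) -> np.ndarray:
        """The total rates ``q_c = -q_cc`` of leaving each state."""
        return -np.diag(self.Q)

    def index_of(self, label: str) -> int:
        return self.state_labels.index(label)


@dataclass(frozen=True)
class TransitionMatrix:
    """``P(t) = exp(Qt)``; entries in [0, 1], rows summing to one."""

    P: np.ndarray
    t: float

    def __post_init__(self):
        P = self.P
        if np.min(P) < -TRANSITION_TOL or np.max(P) > 1 + TRANSITION_TOL:
            raise ValueError("transition probabilities outside [0, 1]")
        if np.max(np.abs(P.sum(axis=1) - 1.0)) > TRANSITION_TOL:
            raise ValueError("transition-matrix rows do not sum to 1")


@dataclass(frozen=True)
class StationaryDistribution:
    """The probability vector ``pi`` with ``pi Q = 0``."""

    pi: np.ndarray

    def __post_init__(self):
        if np.any(self.pi <= -1e-12):
            raise ValueError("stationary distribution has negative entries")
        if abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError("stationary distribution does not sum to 1")


@dataclass(frozen=True)
class SampledPath:
    """A complete trajectory on ``[0, t]``.

    ``T`` is the per-state dwell-time vector and ``N`` the matrix of jump
    counts; together they are the sufficient statistics of the complete-data
    likelihood.
    """

    states: tuple[int, ...]
    jump_times: np.ndarray
    T: np.ndarray
    N: np.ndarray
    t: float


@dataclass(frozen=True)
class ConditionedSample:
    """Endpoint-conditioned replicates from the rejection sampler.

    ``T`` has shape ``(n_samples, n)`` (dwell times per replicate) and ``N``
    shape ``(n_samples, n, n)`` (jump counts); their empirical means are
    unbiased estimates of the endpoint-conditioned expectations
    ``E[T_c | t, a, b]`` and ``E[N_cd | t, a, b]``.
    """

    T: np.ndarray
    N: np.ndarray
    t: float
    a: int
    b: int
    n_proposed: int
    paths: tuple[SampledPath, ...] = field(default=(), repr=False)

    @property
    def acceptance_rate(self) -> float:
        return self.T.shape[0] / self.n_proposed


def validate_rate_matrix(M, labels=None, row_sum_rtol: float = ROW_SUM_RTOL) -> RateMatrix:
    """Validate a raw square array as a CTMC generator.

    Raises ``ValueError`` (naming the offending row) for negative off-diagonal
    entries or rows that do not sum to zero within ``row_sum_rtol * max|Q|``.
    """
    Q = np.asarray(M, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("rate matrix must be square")
    n = Q.shape[0]
    if n < 2:
        raise ValueError("rate matrix needs at least 2 states")
    off = Q.copy()
    np.fill_diagonal(off, 0.0)
    if np.min(off) < 0:
        row = int(np.argwhere(off < 0)[0, 0])
        raise ValueError(f"negative off-diagonal rate in row {row}")
    scale = max(np.max(np.abs(Q)), 1.0)
    rows = np.abs(Q.sum(axis=1))
    if np.max(rows) > row_sum_rtol * scale:
        row = int(np.argmax(rows))
        raise ValueError(f"row {row} does not sum to zero (residual {rows[row]:.3g})")
    if labels is None:
        labels = tuple(str(i) for i in range(n))
    else:
        labels = tuple(str(x) for x in labels)
        if len(labels) != n:
            raise ValueError("label count does not match matrix dimension")
    return RateMatrix(Q=Q, state_labels=labels)


def transition_probabilities(Q: RateMatrix, t: float) -> TransitionMatrix:
    """``P(t) = exp(Qt)`` by scaling-and-squaring Pade (scipy's expm)."""
    if t < 0:
        raise ValueError("time must be non-negative")
    if t == 0:
        return TransitionMatrix(P=np.eye(Q.n), t=0.0)
    P = expm(Q.Q * t)
    # clip tiny negative round-off so the validated container accepts it
    P = np.clip(P, 0.0, None)
    return TransitionMatrix(P=P, t=float(t))


def stationary_distribution(Q: RateMatrix) -> StationaryDistribution:
    """Solve ``pi Q = 0`` via the null space of ``Q^T``.

    Raises for reducible chains (null-space dimension above one).
    """
    ns = null_space(Q.Q.T)
    if ns.shape[1] != 1:
        raise ValueError(
            f"chain is reducible: null space of Q^T has dimension {ns.shape[1]}"
        )
    pi = ns[:, 0]
    pi = pi / pi.sum()
    if np.any(pi < -1e-10):
        raise ValueError("stationary solve produced negative entries")
    pi = np.clip(pi, 0.0, None)
    return StationaryDistribution(pi=pi / pi.sum())


def is_reversible(
    Q: RateMatrix,
    pi: StationaryDistribution | None = None,
    tol: float = REVERSIBILITY_RTOL,
) -> bool:
    """Detailed balance: ``max_ab |pi_a q_ab - pi_b q_ba| <= tol * max|Q|``."""
    if pi is None:
        pi = stationary_distribution(Q)
    F = pi.pi[:, None] * Q.Q
    return float(np.max(np.abs(F - F.T))) <= tol * max(np.max(np.abs(Q.Q)), 1.0)


def _gillespie(Q: np.ndarray, a: int, t: float, rng: np.random.Generator):
    """One trajectory; returns (states, jump_times, T, N)."""
    n = Q.shape[0]
    rates = -np.diag(Q)
    # cumulative jump distributions per state
    P_jump = Q.copy()
    np.fill_diagonal(P_jump, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        P_jump = P_jump / rates[:, None]
    cum = np.nancumsum(P_jump, axis=1)
    states = [a]
    times = []
    T = np.zeros(n)
    N = np.zeros((n, n), dtype=np.int64)
    now = 0.0
    state = a
    while True:
        r = rates[state]
        if r <= 0:
            break  # absorbing state
        dt = rng.exponential(1.0 / r)
        if now + dt >= t:
            break
        now += dt
        nxt = int(np.searchsorted(cum[state], rng.random() * cum[state, -1]))
        times.append(now)
        N[state, nxt] += 1
        state = nxt
        states.append(state)
    # dwell times: differences of jump times padded with 0 and t
    edges = np.concatenate(([0.0], times, [t]))
    for s, dt in zip(states, np.diff(edges)):
        T[s] += dt
    # force exact conservation sum(T) == t
    T[state] += t - T.sum()
    return tuple(states), np.asarray(times), T, N


def simulate_path(Q: RateMatrix, a: int, t: float, rng_seed=None) -> SampledPath:
    """Gillespie simulation from state ``a`` for duration ``t``."""
    if t < 0:
        raise ValueError("time must be non-negative")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    states, times, T, N = _gillespie(Q.Q, a, t, rng)
    return SampledPath(states=states, jump_times=times, T=T, N=N, t=float(t))


def simulate_endpoint_conditioned(
    Q: RateMatrix,
    a: int,
    b: int,
    t: float,
    n_samples: int,
    rng_seed=None,
    keep_paths: bool = False,
) -> ConditionedSample:
    """Rejection sampling of paths from ``a`` over ``[0, t]`` ending in ``b``.

    Proposals are unconditional Gillespie paths; a proposal is retained iff its
    final state is ``b``, so the retained paths are exact draws from the
    endpoint-conditioned path distribution.  Raises if the acceptance
    probability ``p_ab(t)`` is below ``REJECTION_FLOOR``.
    """
    p_ab = transition_probabilities(Q, t).P[a, b]
    if p_ab < REJECTION_FLOOR:
        raise ValueError(
            f"acceptance probability p_ab(t)={p_ab:.3g} below {REJECTION_FLOOR}; "
            "use a smaller problem or shorter time"
        )
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    n = Q.n
    T_out = np.empty((n_samples, n))
    N_out = np.empty((n_samples, n, n), dtype=np.int64)
    paths: list[SampledPath] = []
    accepted = 0
    proposed = 0
    limit = int(20 * n_samples / p_ab) + 100
    while accepted < n_samples:
        if proposed > limit:  # pragma: no cover - statistical safety valve
            raise RuntimeError("rejection sampler exceeded proposal budget")
        states, times, T, N = _gillespie(Q.Q, a, t, rng)
        proposed += 1
        if states[-1] != b:
            continue
        T_out[accepted] = T
        N_out[accepted] = N
        if keep_paths:
            paths.append(SampledPath(states=states, jump_times=times, T=T, N=N, t=float(t)))
        accepted += 1
    return ConditionedSample(
        T=T_out, N=N_out, t=float(t), a=a, b=b, n_proposed=proposed, paths=tuple(paths)
    )
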