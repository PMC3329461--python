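"""Endpoint-conditioned expectations of CTMC sufficient statistics.

Given a generator ``Q``, a weight matrix ``C`` and a time ``t``, the central
object is the matrix ``Sigma(C; t)`` with entries

    Sigma(C; a, b, t) = sum_{c,d} C_cd I_cd^ab(t),
    I_cd^ab(t) = int_0^t p_ac(u) p_db(t-u) du,

from which the endpoint-conditioned expected dwell times
``E[T_c | t, a, b] = I_cc^ab(t) / p_ab(t)`` and jump counts
``E[N_cd | t, a, b] = q_cd I_cd^ab(t) / p_ab(t)`` are read off by choosing
``C`` as a single-entry indicator, and arbitrary linear combinations (numbers
of transitions, synonymous substitutions, labeled jumps, ...) by a general
``C``.  Three O(n^3) backends are provided:

``evd``
    eigenvalue decomposition ``Q = U Lambda U^-1`` with the auxiliary
    divided-difference matrix ``J(t)``; uses a symmetric decomposition of
    ``Pi^{1/2} Q Pi^{-1/2}`` when the chain is reversible.
``uni``
    uniformization ``R = Q/mu + I`` with a Poisson-weighted power series
    truncated so the neglected tail is below a stated bound; supports batched
    evaluation at several times from one precomputation.
``expm``
    the auxiliary-block-matrix method: ``Sigma(C; t)`` is the upper-right
    block of ``expm([[Q, C], [0, Q]] t)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.stats import poisson

from .ctmc_core import RateMatrix, is_reversible, stationary_distribution

logger = logging.getLogger("ctmcexp")

#: default bound on the neglected Poisson tail in uniformization
DEFAULT_TAIL_BOUND = 1e-8
#: eigenvalues closer than this (relative to max |lambda|) share the
#: degenerate branch of the J matrix, avoiding catastrophic cancellation
DEGENERACY_RTOL = 1e-9
#: condition number of the eigenvector matrix above which EVD refuses
EVD_CONDITION_LIMIT = 1e12
#: relative ceiling on imaginary residues when realifying EVD output
IMAG_RTOL = 1e-8

BACKENDS = ("evd", "uni", "expm")


@dataclass(frozen=True)
class WeightMatrix:
    """The combination matrix ``C``; no sign restriction."""

    C: np.ndarray


def _as_weight(C, n: int) -> np.ndarray:
    C = C.C if isinstance(C, WeightMatrix) else np.asarray(C, dtype=float)
    if C.shape != (n, n):
        raise ValueError(f"weight matrix shape {C.shape} does not match n={n}")
    return C


@dataclass(frozen=True)
class EigenSystem:
    """``Q = U diag(eigenvalues) U_inv``.

    ``symmetrized`` records whether the decomposition went through the
    symmetric matrix ``S = Pi^{1/2} Q Pi^{-1/2}`` available for reversible
    chains (real spectrum, orthogonal eigenvectors, better conditioning).
    """

    eigenvalues: np.ndarray
    U: np.ndarray
    U_inv: np.ndarray
    symmetrized: bool


@dataclass(frozen=True)
class JMatrix:
    """Divided differences ``J_ij(t)`` of the exponential over the spectrum."""

    J: np.ndarray
    t: float


@dataclass(frozen=True)
class ExpectationResult:
    """``Sigma(C;t)`` together with ``P(t)`` from the same backend.

    ``P`` is produced by the backend itself (e.g. the truncated Poisson sum
    for uniformization) so that ratios ``Sigma / P`` benefit from cancelling
    truncation errors.
    """

    Sigma: np.ndarray
    P: np.ndarray
    t: float
    method: str


# --------------------------------------------------------------------------
# EVD backend
# --------------------------------------------------------------------------

def decompose_rate_matrix(Q: RateMatrix, force_general: bool = False) -> EigenSystem:
    """Eigendecomposition of ``Q``, symmetrized when reversible.

    For a reversible chain with stationary distribution ``pi`` the similar
    matrix ``S = Pi^{1/2} Q Pi^{-1/2}`` is symmetric, so a real orthogonal
    decomposition exists and ``U = Pi^{-1/2} V``, ``U^-1 = V^T Pi^{1/2}``.
    Otherwise a general (possibly complex) decomposition is used; an
    ill-conditioned eigenvector matrix raises, naming the EXPM fallback.
    """
    A = Q.Q
    if not force_general:
        try:
            pi = stationary_distribution(Q).pi
        except ValueError:
            pi = None
        if pi is not None and np.all(pi > 0) and is_reversible(Q, None):
            d = np.sqrt(pi)
            S = (A * d[:, None]) / d[None, :]
            S = (S + S.T) / 2.0
            lam, V = np.linalg.eigh(S)
            U = V / d[:, None]
            U_inv = V.T * d[None, :]
            return EigenSystem(eigenvalues=lam, U=U, U_inv=U_inv, symmetrized=True)
    lam, U = np.linalg.eig(A)
    cond = np.linalg.cond(U)
    if not np.isfinite(cond) or cond > EVD_CONDITION_LIMIT:
        raise np.linalg.LinAlgError(
            f"eigenvector matrix is ill-conditioned (cond={cond:.3g}); the rate "
            "matrix may be non-diagonalizable -- use the EXPM backend instead"
        )
    U_inv = np.linalg.inv(U)
    return EigenSystem(eigenvalues=lam, U=U, U_inv=U_inv, symmetrized=False)


def build_j_matrix(
    eigs: EigenSystem | np.ndarray,
    t: float,
    degeneracy_tol: float | None = None,
) -> JMatrix:
    """The auxiliary integrals ``J_ij(t)``.

    ``J_ij = t e^{lambda_i t}`` when ``lambda_i`` and ``lambda_j`` coincide
    (within ``degeneracy_tol``, by default relative to the spectral radius),
    else the divided difference ``(e^{lambda_i t} - e^{lambda_j t}) /
    (lambda_i - lambda_j)``.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    lam = eigs.eigenvalues if isinstance(eigs, EigenSystem) else np.asarray(eigs)
    if degeneracy_tol is None:
        degeneracy_tol = DEGENERACY_RTOL * max(float(np.max(np.abs(lam))), 1.0)
    e = np.exp(lam * t)
    diff = lam[:, None] - lam[None, :]
    degenerate = np.abs(diff) <= degeneracy_tol
    safe = np.where(degenerate, 1.0, diff)
    J = np.where(degenerate, t * e[:, None], (e[:, None] - e[None, :]) / safe)
    return JMatrix(J=J, t=float(t))


def _realify(M: np.ndarray, what: str) -> np.ndarray:
    if not np.iscomplexobj(M):
        return M
    scale = max(float(np.max(np.abs(M))), 1e-300)
    resid = float(np.max(np.abs(M.imag)))
    if resid > IMAG_RTOL * scale:
        raise ValueError(f"{what} has imaginary residue {resid:.3g} above tolerance")
    return np.ascontiguousarray(M.real)


def evd_statistics(Q: RateMatrix, C, t: float, force_general: bool = False) -> ExpectationResult:
    """``Sigma(C;t) = U [J(t) o (U^-1 C U)] U^-1`` (``o`` entrywise)."""
    Cm = _as_weight(C, Q.n)
    eigs = decompose_rate_matrix(Q, force_general=force_general)
    J = build_j_matrix(eigs, t).J
    inner = J * (eigs.U_inv @ Cm @ eigs.U)
    Sigma = eigs.U @ inner @ eigs.U_inv
    P = eigs.U @ (np.exp(eigs.eigenvalues * t)[:, None] * eigs.U_inv)
    Sigma = _realify(Sigma, "Sigma(C;t)")
    P = _realify(P, "P(t)")
    _log_call("evd", Q.n, t, None, None)
    return ExpectationResult(Sigma=Sigma, P=P, t=float(t), method="evd")


# --------------------------------------------------------------------------
# UNI backend
# --------------------------------------------------------------------------

def truncation_point(lam: float, tail_bound: float = DEFAULT_TAIL_BOUND) -> int:
    """Number of Poisson terms retained in uniformization.

    For the default tail bound 1e-8 this is the conservative closed-form rule
    ``ceil(4 + 6 sqrt(lambda) + lambda)`` (a regression fit to the exact
    Poisson-tail quantile, rounded up to stay conservative).  Any other bound
    falls back to :func:`exact_truncation_point`.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if tail_bound == DEFAULT_TAIL_BOUND:
        return int(math.ceil(4.0 + 6.0 * math.sqrt(lam) + lam))
    return exact_truncation_point(lam, tail_bound)


def exact_truncation_point(lam: float, tail_bound: float) -> int:
    """Smallest ``s`` with Poisson tail ``P(X >= s) <= tail_bound``."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if not 0 < tail_bound < 1:
        raise ValueError("tail bound must be in (0, 1)")
    s = max(int(lam), 0)
    while poisson.sf(s - 1, lam) > tail_bound:
        s += 1
    return s


@dataclass(frozen=True)
class UniformizationState:
    """Precomputation shared across time points for one ``(Q, C)`` pair.

    ``R = Q/mu + I`` with ``mu = max_i q_i``; ``R_powers[m] = R^m`` and
    ``A[m] = sum_{l<=m} R^l C R^{m-l}`` (recursion ``A(m+1) = A(m) R +
    R^{m+1} C``) for all ``m`` up to the truncation point at the largest time.
    """

    mu: float
    R: np.ndarray
    s: int
    R_powers: np.ndarray
    A: np.ndarray


def prepare_uniformization(Q: RateMatrix, C, t_max: float,
                           tail_bound: float = DEFAULT_TAIL_BOUND) -> UniformizationState:
    Cm = _as_weight(C, Q.n)
    mu = float(np.max(Q.exit_rates))
    s = truncation_point(mu * t_max, tail_bound)
    n = Q.n
    R = Q.Q / mu + np.eye(n)
    R_powers = np.empty((s + 1, n, n))
    R_powers[0] = np.eye(n)
    for m in range(1, s + 1):
        R_powers[m] = R_powers[m - 1] @ R
    A = np.empty((s + 1, n, n))
    A[0] = Cm
    for m in range(1, s + 1):
        A[m] = A[m - 1] @ R + R_powers[m] @ Cm
    return UniformizationState(mu=mu, R=R, s=s, R_powers=R_powers, A=A)


def uni_statistics(Q: RateMatrix, C, times,
                   tail_bound: float = DEFAULT_TAIL_BOUND):
    """Uniformization evaluation of ``Sigma(C;t)``.

    ``times`` may be a scalar or a sequence; the power/partial-sum
    precomputation is done once at ``max(times)`` and each time point is then
    an O(s n^2) weighted sum.  Returns one :class:`ExpectationResult` for a
    scalar, else a list in the order given.
    """
    scalar = np.isscalar(times)
    ts = [float(times)] if scalar else [float(x) for x in times]
    if any(t < 0 for t in ts):
        raise ValueError("times must be non-negative")
    Cm = _as_weight(C, Q.n)
    n = Q.n
    mu = float(np.max(Q.exit_rates))
    if mu == 0.0:
        # Q = 0: P(u) = I so I_cd^ab(t) = t 1(a=c) 1(b=d) and Sigma = t C
        out = [ExpectationResult(Sigma=t * Cm, P=np.eye(n), t=t, method="uni") for t in ts]
        return out[0] if scalar else out
    state = prepare_uniformization(Q, Cm, max(ts), tail_bound)
    out = []
    for t in ts:
        lam = state.mu * t
        s_t = min(truncation_point(lam, tail_bound), state.s)
        m = np.arange(s_t + 1)
        w_P = poisson.pmf(m, lam)
        w_S = poisson.pmf(m + 1, lam)
        P = np.einsum("m,mij->ij", w_P, state.R_powers[: s_t + 1])
        Sigma = np.einsum("m,mij->ij", w_S, state.A[: s_t + 1]) / state.mu
        _log_call("uni", n, t, lam, s_t)
        out.append(ExpectationResult(Sigma=Sigma, P=P, t=t, method="uni"))
    return out[0] if scalar else out


# --------------------------------------------------------------------------
# EXPM backend
# --------------------------------------------------------------------------

def expm_statistics(Q: RateMatrix, C, t: float) -> ExpectationResult:
    """Auxiliary-matrix method: exponentiate ``[[Q, C], [0, Q]] t``.

    The upper-right n x n block of the exponential is ``Sigma(C;t)``; the
    lower-right block is ``P(t)`` and is reused rather than recomputed.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    n = Q.n
    Cm = _as_weight(C, n)
    A = np.zeros((2 * n, 2 * n))
    A[:n, :n] = Q.Q
    A[:n, n:] = Cm
    A[n:, n:] = Q.Q
    E = expm(A * t)
    _log_call("expm", n, t, None, None)
    return ExpectationResult(Sigma=E[:n, n:], P=E[n:, n:], t=float(t), method="expm")


# --------------------------------------------------------------------------
# dispatch and conditional expectations
# --------------------------------------------------------------------------

def expected_statistics(Q: RateMatrix, C, t: float, method: str = "uni",
                        **kwargs) -> ExpectationResult:
    """Compute ``Sigma(C;t)`` with the selected backend (default ``uni``)."""
    if method == "evd":
        return evd_statistics(Q, C, t, **kwargs)
    if method == "uni":
        return uni_statistics(Q, C, t, **kwargs)
    if method == "expm":
        return expm_statistics(Q, C, t, **kwargs)
    raise ValueError(f"unknown method {method!r}; choose from {BACKENDS}")


def _endpoint_probability(res: ExpectationResult, a: int, b: int) -> float:
    p = res.P[a, b]
    if p <= 0:
        raise ValueError(f"endpoint pair ({a}, {b}) unreachable: p_ab(t) = {p}")
    return float(p)


def conditional_dwell_time(Q: RateMatrix, t: float, c: int, a: int, b: int,
                           method: str = "uni") -> float:
    """``E[T_c | t, a, b] = I_cc^ab(t) / p_ab(t)``."""
    C = np.zeros((Q.n, Q.n))
    C[c, c] = 1.0
    res = expected_statistics(Q, C, t, method=method)
    return res.Sigma[a, b] / _endpoint_probability(res, a, b)


def conditional_jump_count(Q: RateMatrix, t: float, c: int, d: int, a: int, b: int,
                           method: str = "uni") -> float:
    """``E[N_cd | t, a, b] = q_cd I_cd^ab(t) / p_ab(t)`` for ``c != d``."""
    if c == d:
        raise ValueError("jump counts require c != d")
    q_cd = Q.Q[c, d]
    if q_cd == 0.0:
        return 0.0
    C = np.zeros((Q.n, Q.n))
    C[c, d] = 1.0
    res = expected_statistics(Q, C, t, method=method)
    return q_cd * res.Sigma[a, b] / _endpoint_probability(res, a, b)


def _log_call(method: str, n: int, t: float, mu_t, s):
    if logger.isEnabledFor(logging.DEBUG):
        extra = "" if mu_t is None else f" mu*t={mu_t:.4g} s={s}"
        logger.debug("Sigma(C;t): method=%s n=%d t=%.6g%s", method, n, t, extra)
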