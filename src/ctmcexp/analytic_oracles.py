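"""Closed-form ground truth and the accuracy experiment.

For two nucleotide models the integrals ``I_cd^ab(t)`` have analytic
expressions, giving an exact reference value of ``Sigma(C;t)`` against which
the three numerical backends can be compared:

* the equal-rates (Jukes-Cantor-type) chain on ``n`` states, whose spectrum
  is ``{0, -n/(n-1)}`` and whose transition probabilities and integrals have
  simple exponential closed forms;
* the HKY chain (states ordered A, G, C, T), whose 4x4 eigensystem is known
  in closed form, from which ``Sigma(C;t)`` is assembled exactly via the
  divided-difference (J-matrix) identity.

The module also generates random reversible rate matrices (stationary vector
from Dirichlet(1), lower-triangle rates from Exp(1), upper triangle by
detailed balance) and runs the accuracy experiment: normalized deviation
``|estimate - truth| / truth`` averaged over endpoint pairs and replicate
random binary weight matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ctmc_core import RateMatrix, validate_rate_matrix
from .expectations import (
    EigenSystem,
    build_j_matrix,
    evd_statistics,
    expm_statistics,
    uni_statistics,
)

NUCLEOTIDES = ("A", "G", "C", "T")  # row/column order of the HKY and GTR displays


@dataclass(frozen=True)
class AccuracyRecord:
    """One cell of the accuracy experiment."""

    model: str
    n: int
    t: float
    method: str
    normalized_deviation: float


# --------------------------------------------------------------------------
# Jukes-Cantor closed forms (general state count n)
# --------------------------------------------------------------------------

def jc_rate_matrix(n: int) -> RateMatrix:
    """Equal-rates chain: ``q_ij = 1/(n-1)`` off-diagonal, ``q_ii = -1``."""
    if n < 2:
        raise ValueError("need at least 2 states")
    Q = np.full((n, n), 1.0 / (n - 1))
    np.fill_diagonal(Q, -1.0)
    return validate_rate_matrix(Q)


def jc_transition_closed_form(n: int, t: float, i: int, j: int) -> float:
    """``p_ij(t) = 1/n + ((n-1)/n) e^{-nt/(n-1)}`` on the diagonal, else
    ``1/n - (1/n) e^{-nt/(n-1)}``."""
    if n < 2 or t < 0:
        raise ValueError("need n >= 2 and t >= 0")
    e = np.exp(-n * t / (n - 1))
    return 1.0 / n + ((n - 1) / n) * e if i == j else 1.0 / n - e / n


def jc_integral_closed_form(n: int, t: float, a: int, b: int, c: int, d: int) -> float:
    """Closed form of ``I_cd^ab(t)`` for the equal-rates chain.

    Three cases depending on whether ``a = c`` and/or ``d = b``.
    """
    if n < 2 or t < 0:
        raise ValueError("need n >= 2 and t >= 0")
    e = np.exp(-n * t / (n - 1))
    if a != c and d != b:
        v = t + t * e - (2 * (n - 1) / n) * (1 - e)
    elif a == c and d == b:
        v = t + (n - 1) ** 2 * t * e + (2 * (n - 1) ** 2 / n) * (1 - e)
    else:
        v = t - (n - 1) * t * e + ((n - 2) * (n - 1) / n) * (1 - e)
    return v / n**2


def jc_sigma_closed_form(C: np.ndarray, t: float) -> np.ndarray:
    """Exact ``Sigma(C;t)`` for the equal-rates chain, vectorized.

    ``I_cd^ab`` takes only three values (by the case of ``(a=c, d=b)``), so
    the double sum collapses to row sums, column sums and the total of ``C``.
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    v_both_diff = jc_integral_closed_form(n, t, 0, 0, 1, 2)  # a != c, d != b
    v_both_eq = jc_integral_closed_form(n, t, 0, 0, 0, 0)    # a = c, d = b
    v_mixed = jc_integral_closed_form(n, t, 0, 0, 0, 1)      # exactly one
    total = C.sum()
    row = C.sum(axis=1)[:, None]  # sum over d of C_{a d}
    col = C.sum(axis=0)[None, :]  # sum over c of C_{c b}
    return (
        v_both_diff * (total - row - col + C)
        + v_both_eq * C
        + v_mixed * (row + col - 2 * C)
    )


# --------------------------------------------------------------------------
# HKY closed forms
# --------------------------------------------------------------------------

def hky_rate_matrix(pi, kappa: float) -> RateMatrix:
    """HKY generator in A, G, C, T order; transitions (A<->G, C<->T) scaled
    by ``kappa``."""
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-10:
        raise ValueError("pi must be a positive probability 4-vector")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    pA, pG, pC, pT = pi
    Q = np.array(
        [
            [0.0, kappa * pG, pC, pT],
            [kappa * pA, 0.0, pC, pT],
            [pA, pG, 0.0, kappa * pT],
            [pA, pG, kappa * pC, 0.0],
        ]
    )
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return validate_rate_matrix(Q, labels=NUCLEOTIDES)


def hky_eigensystem_closed_form(pi, kappa: float) -> EigenSystem:
    """The known 4x4 eigensystem of the HKY generator.

    Eigenvalues ``(0, -1, -pi_Y kappa - pi_R, -pi_R kappa - pi_Y)`` with
    ``pi_R = pi_A + pi_G`` and ``pi_Y = pi_C + pi_T``; the eigenvector matrix
    and its inverse are rational in ``pi``.
    """
    pi = np.asarray(pi, dtype=float)
    pA, pG, pC, pT = pi
    pR, pY = pA + pG, pC + pT
    lam = np.array([0.0, -1.0, -pY * kappa - pR, -pR * kappa - pY])
    U = np.array(
        [
            [1.0, -pY / pR, 0.0, -pG / pA],
            [1.0, -pY / pR, 0.0, 1.0],
            [1.0, 1.0, -pT / pC, 0.0],
            [1.0, 1.0, 1.0, 0.0],
        ]
    )
    U_inv = np.array(
        [
            [pA, pG, pC, pT],
            [-pA, -pG, pC * pR / pY, pT * pR / pY],
            [0.0, 0.0, -pC / pY, pC / pY],
            [-pA / pR, pA / pR, 0.0, 0.0],
        ]
    )
    return EigenSystem(eigenvalues=lam, U=U, U_inv=U_inv, symmetrized=False)


def hky_sigma_closed_form(C: np.ndarray, t: float, pi, kappa: float) -> np.ndarray:
    """Exact ``Sigma(C;t)`` for HKY, assembled from the closed eigensystem."""
    eigs = hky_eigensystem_closed_form(pi, kappa)
    J = build_j_matrix(eigs, t, degeneracy_tol=0.0).J
    return eigs.U @ (J * (eigs.U_inv @ np.asarray(C, float) @ eigs.U)) @ eigs.U_inv


def hky_transition_closed_form(t: float, pi, kappa: float) -> np.ndarray:
    """Exact ``P(t)`` for HKY from the closed eigensystem."""
    eigs = hky_eigensystem_closed_form(pi, kappa)
    return eigs.U @ (np.exp(eigs.eigenvalues * t)[:, None] * eigs.U_inv)


# --------------------------------------------------------------------------
# random matrices and the accuracy experiment
# --------------------------------------------------------------------------

def random_reversible_matrix(n: int, rng_seed=None):
    """Random reversible generator; returns ``(RateMatrix, pi)``.

    ``pi`` is drawn from Dirichlet(1, ..., 1), the rates ``q_ij`` with
    ``i > j`` from Exp(1), the upper triangle from detailed balance
    ``q_ij = pi_j q_ji / pi_i`` and the diagonal fixes the row sums.
    """
    if n < 2:
        raise ValueError("need at least 2 states")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    pi = rng.dirichlet(np.ones(n))
    Q = np.zeros((n, n))
    lower = np.tril_indices(n, k=-1)
    Q[lower] = rng.exponential(1.0, size=len(lower[0]))
    iu = np.triu_indices(n, k=1)
    Q[iu] = (pi[None, :] * Q.T / pi[:, None])[iu]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return validate_rate_matrix(Q), pi


def random_binary_weight_matrix(n: int, rng: np.random.Generator, p: float = 0.5) -> np.ndarray:
    """Binary C with entries 1 w.p. ``p``; the all-zero draw is resampled."""
    while True:
        C = (rng.random((n, n)) < p).astype(float)
        if C.any():
            return C


def normalized_deviation(estimate: np.ndarray, truth: np.ndarray) -> float:
    """Mean of ``|estimate - truth| / |truth|`` over entries with nonzero truth."""
    truth = np.asarray(truth, float)
    mask = truth != 0
    if not mask.any():
        raise ValueError("truth matrix is identically zero")
    dev = np.abs((np.asarray(estimate, float)[mask] - truth[mask]) / truth[mask])
    return float(dev.mean())


_BACKEND_FUNCS = {
    "evd": evd_statistics,
    "uni": uni_statistics,
    "expm": expm_statistics,
}


def run_accuracy_experiment(
    model: str = "JC",
    n_values=None,
    t_values=None,
    reps: int = 5,
    binary_prob: float = 0.5,
    rng_seed=None,
) -> list[AccuracyRecord]:
    """Accuracy of all three backends against the closed forms.

    For the equal-rates model the state count varies (default every ``n``
    from 5 to 100 at ``t = 0.1``); for HKY (``pi = (0.2, 0.2, 0.3, 0.3)``,
    ``kappa = 2.15``) the time varies (default 10 log-spaced points in
    ``[0.01, 10]``).  Each setting draws ``reps`` random binary weight
    matrices; the recorded statistic is the normalized deviation averaged
    over endpoint pairs and replicates.
    """
    rng = np.random.default_rng(rng_seed)
    records: list[AccuracyRecord] = []
    if model.upper() == "JC":
        ns = list(n_values) if n_values is not None else list(range(5, 101))
        t = 0.1 if t_values is None else float(np.atleast_1d(t_values)[0])
        settings = [(n, t) for n in ns]
        def truth_fn(n, t, C):
            return jc_sigma_closed_form(C, t)
        def Q_fn(n):
            return jc_rate_matrix(n)
    elif model.upper() == "HKY":
        pi = np.array([0.2, 0.2, 0.3, 0.3])
        kappa = 2.15
        ts = list(t_values) if t_values is not None else list(np.logspace(-2, 1, 10))
        settings = [(4, t) for t in ts]
        def truth_fn(n, t, C):
            return hky_sigma_closed_form(C, t, pi, kappa)
        def Q_fn(n):
            return hky_rate_matrix(pi, kappa)
    else:
        raise ValueError("model must be 'JC' or 'HKY'")

    for n, t in settings:
        Q = Q_fn(n)
        Cs = [random_binary_weight_matrix(n, rng, binary_prob) for _ in range(reps)]
        truths = [truth_fn(n, t, C) for C in Cs]
        for method, fn in _BACKEND_FUNCS.items():
            devs = [
                normalized_deviation(fn(Q, C, t).Sigma, truth)
                for C, truth in zip(Cs, truths)
            ]
            records.append(
                AccuracyRecord(
                    model=model.upper(),
                    n=n,
                    t=float(t),
                    method=method,
                    normalized_deviation=float(np.mean(devs)),
                )
            )
    return records
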