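"""Robust labeled evolutionary distances from pairwise alignments.

A labeling is a set ``L`` of ordered state pairs (e.g. all substitutions to
or from nucleotide A, or all transitions); the labeled distance between two
aligned sequences is the expected number of labeled substitutions per site.
The robust estimator averages the endpoint-conditioned expectation over the
*empirical* site-pattern distribution,

    d_L = (1/m) sum_s E[ N_L | X(0) = y1_s, X(1) = y2_s ],

taking ``t = 1`` since only ``Q t`` is identifiable from a pair.  Averaging
over observed rather than model-predicted patterns makes the distance robust
to misspecification of ``Q``.  A single ``Sigma(C;1)`` evaluation with
``C_ij = q_ij 1((i,j) in L)`` serves all sites.

The module also builds the general time-reversible (GTR) nucleotide
generator (states ordered A, G, C, T; six exchangeability rates) and
estimates its parameters from a pairwise alignment by maximum likelihood at
fixed ``t = 1``, with the stationary distribution taken as the pooled
empirical base frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .analytic_oracles import NUCLEOTIDES
from .ctmc_core import RateMatrix, validate_rate_matrix
from .expectations import expected_statistics


@dataclass(frozen=True)
class LabelSet:
    """Ordered state pairs defining a labeled substitution type."""

    pairs: frozenset

    def __post_init__(self):
        if any(i == j for i, j in self.pairs):
            raise ValueError("label set must not contain self-pairs")

    @classmethod
    def all_pairs(cls, n: int) -> "LabelSet":
        return cls(frozenset((i, j) for i in range(n) for j in range(n) if i != j))

    @classmethod
    def to_from_state(cls, n: int, state: int) -> "LabelSet":
        """All jumps into or out of one state."""
        return cls(
            frozenset(
                (i, j)
                for i in range(n)
                for j in range(n)
                if i != j and (i == state or j == state)
            )
        )

    @classmethod
    def transitions(cls) -> "LabelSet":
        """A<->G and C<->T in the A, G, C, T nucleotide ordering."""
        return cls(frozenset({(0, 1), (1, 0), (2, 3), (3, 2)}))

    @classmethod
    def from_preset(cls, name: str, state_labels=NUCLEOTIDES) -> "LabelSet":
        """Named presets: ``all``, ``transitions``, ``to-from:<label>``."""
        n = len(state_labels)
        if name == "all":
            return cls.all_pairs(n)
        if name == "transitions":
            return cls.transitions()
        if name.startswith("to-from:"):
            return cls.to_from_state(n, list(state_labels).index(name.split(":", 1)[1]))
        raise ValueError(f"unknown label preset {name!r}")


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two equal-length state-index sequences."""

    seq1: np.ndarray
    seq2: np.ndarray
    n_states: int
    n_masked: int = 0

    def __post_init__(self):
        if self.seq1.shape != self.seq2.shape or self.seq1.ndim != 1:
            raise ValueError("sequences must be equal-length 1-d arrays")

    @property
    def m(self) -> int:
        return self.seq1.shape[0]

    def pattern_counts(self) -> np.ndarray:
        """``counts[a, b]`` = number of sites with pattern ``(a, b)``."""
        n = self.n_states
        return np.bincount(self.seq1 * n + self.seq2, minlength=n * n).reshape(n, n).astype(float)


@dataclass(frozen=True)
class GTRParams:
    """Six exchangeability rates (upper-triangle order AG, AC, AT, GC, GT,
    CT) and the stationary base composition in A, G, C, T order."""

    r: np.ndarray
    pi: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.r, float)
        pi = np.asarray(self.pi, float)
        if r.shape != (6,) or np.any(r <= 0):
            raise ValueError("r must be 6 positive rates")
        if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
            raise ValueError("pi must be a positive probability 4-vector")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "pi", pi)


def gtr_rate_matrix(params: GTRParams) -> RateMatrix:
    """GTR generator ``q_ij = r_ij pi_j`` in A, G, C, T order."""
    r1, r2, r3, r4, r5, r6 = params.r
    pA, pG, pC, pT = params.pi
    Q = np.array(
        [
            [0.0, r1 * pG, r2 * pC, r3 * pT],
            [r1 * pA, 0.0, r4 * pC, r5 * pT],
            [r2 * pA, r4 * pG, 0.0, r6 * pT],
            [r3 * pA, r5 * pG, r6 * pC, 0.0],
        ]
    )
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return validate_rate_matrix(Q, labels=NUCLEOTIDES)


def label_weight_from_rates(Q: RateMatrix, L: LabelSet) -> np.ndarray:
    """``C_ij = q_ij 1((i,j) in L)`` with a zero diagonal."""
    C = np.zeros((Q.n, Q.n))
    for i, j in L.pairs:
        C[i, j] = Q.Q[i, j]
    return C


def robust_labeled_distance(
    aln: PairwiseAlignment,
    Q: RateMatrix,
    L: LabelSet,
    method: str = "uni",
    return_site_values: bool = False,
):
    """Average endpoint-conditioned expected labeled jump count at ``t = 1``.

    Raises (naming the first offending site) if an observed site pattern is
    unreachable under ``P(1)``.  With ``return_site_values`` the per-site
    expectations are also returned, from which a standard error of the
    distance can be formed.
    """
    C = label_weight_from_rates(Q, L)
    res = expected_statistics(Q, C, 1.0, method=method)
    counts = aln.pattern_counts()
    observed = counts > 0
    if np.any(res.P[observed] <= 0):
        a, b = np.argwhere(observed & (res.P <= 0))[0]
        site = int(np.argmax((aln.seq1 == a) & (aln.seq2 == b)))
        raise ValueError(f"site {site} has unreachable endpoint pair ({a}, {b})")
    with np.errstate(invalid="ignore", divide="ignore"):
        H = np.where(res.P > 0, res.Sigma / np.where(res.P > 0, res.P, 1.0), 0.0)
    distance = float(np.sum(counts * H) / aln.m)
    if return_site_values:
        return distance, H[aln.seq1, aln.seq2]
    return distance


def estimate_gtr(aln: PairwiseAlignment, r_init=None) -> GTRParams:
    """Pairwise maximum-likelihood GTR estimation at fixed ``t = 1``.

    ``pi`` is set to the pooled empirical base frequencies of both
    sequences; the six exchangeability rates maximize
    ``sum_s log( pi_{y1_s} p_{y1_s, y2_s}(1) )`` (all six are identifiable
    because the divergence time is pinned to one).
    """
    if aln.n_states != 4:
        raise ValueError("GTR estimation expects nucleotide data (4 states)")
    counts = aln.pattern_counts()
    pooled = counts.sum(axis=1) + counts.sum(axis=0)
    if np.any(pooled == 0):
        raise ValueError("all four bases must be observed to estimate GTR")
    pi = pooled / pooled.sum()
    log_pi = np.log(pi)

    def negloglik(log_r):
        Q = gtr_rate_matrix(GTRParams(r=np.exp(log_r), pi=pi))
        P = expm(Q.Q)
        with np.errstate(divide="ignore"):
            ll = counts * (log_pi[:, None] + np.log(np.clip(P, 1e-300, None)))
        return -float(ll.sum())

    x0 = np.log(r_init if r_init is not None else np.full(6, 0.3))
    opt = minimize(negloglik, x0, method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
    if not opt.success:
        warnings.warn(f"GTR optimizer did not report convergence: {opt.message}")
    return GTRParams(r=np.exp(opt.x), pi=pi)
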