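"""EM estimation of the GY codon model on a fixed phylogeny.

Given a codon alignment at the leaves of a tree with known branch lengths,
the parameters ``theta = (alpha, kappa, omega)`` are estimated by
expectation-maximization:

* E-step: the peeling (pruning) algorithm yields, per branch ``k`` of length
  ``t_k``, the joint posterior ``P(parent = a, child = b | data)`` of the
  branch's endpoint states; expected labeled times and substitution counts
  are then sums over branches and endpoint pairs of posterior-weighted
  endpoint-conditioned expectations ``Sigma(C; a, b, t_k) / p_ab(t_k)``
  computed by :mod:`ctmcexp.expectations` with the weight matrices of
  :mod:`ctmcexp.codon_model`.
* M-step: closed form.  With ``beta = alpha kappa`` the complete-data log
  likelihood is maximized at ``alpha = N_tv / (L_s,tv + omega L_ns,tv)``,
  ``beta = N_ts / (L_s,ts + omega L_ns,ts)`` and ``omega`` the positive root
  of the quadratic ``a w^2 + b w + c = 0`` with
  ``a = -L_ns,tv L_ns,ts N_s``,
  ``b = L_ns,tv L_s,ts (N_ns - N_tv) + L_ns,ts L_s,tv (N_ns - N_ts)``,
  ``c = L_s,tv L_s,ts N_ns``.

The observed-data log likelihood is non-decreasing across iterations, which
is asserted (with small numerical slack) in the test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .ctmc_core import RateMatrix, transition_probabilities
from .codon_model import (
    CodonModelParams,
    GeneticCode,
    codon_frequencies,
    gy_rate_matrix,
    label_weight_matrices,
    COUNT_WEIGHT_KEYS,
    TIME_WEIGHT_KEYS,
)
from .expectations import uni_statistics

logger = logging.getLogger("ctmcexp")

#: probabilities below this are treated as unreachable endpoint pairs when
#: dividing Sigma by P in the E-step (the matching posterior mass is ~ 0)
ENDPOINT_PROB_FLOOR = 1e-300


class PhyloTree:
    """A rooted tree with branch lengths, indexed for postorder peeling.

    Nodes are integers; every non-root node ``v`` carries the branch of
    length ``blen[v]`` to its parent.  Leaves carry taxon labels matching
    alignment row names.  Unrooted (trifurcating) Newick inputs are handled
    by treating the basal polytomy as the root.
    """

    def __init__(self, children, parent, blen, labels):
        self.children = tuple(tuple(c) for c in children)
        self.parent = np.asarray(parent, dtype=int)
        self.blen = np.asarray(blen, dtype=float)
        self.labels = tuple(labels)
        self.n_nodes = len(self.children)
        roots = [v for v in range(self.n_nodes) if self.parent[v] < 0]
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        self.root = roots[0]
        self.leaf_nodes = {
            self.labels[v]: v for v in range(self.n_nodes) if not self.children[v]
        }
        if len(self.leaf_nodes) != sum(1 for c in self.children if not c):
            raise ValueError("leaf labels must be unique")
        for v in range(self.n_nodes):
            if v != self.root and not (self.blen[v] > 0):
                raise ValueError(f"missing or non-positive branch length above node {v}")
        # postorder: children before parents
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        self.postorder = tuple(reversed(order))
        #: non-root nodes, each identifying the branch above it
        self.branch_nodes = tuple(v for v in self.postorder if v != self.root)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_nodes)

    @property
    def total_length(self) -> float:
        return float(self.blen[list(self.branch_nodes)].sum())

    @classmethod
    def from_dendropy(cls, tree) -> "PhyloTree":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        children = [[index[id(c)] for c in nd.child_nodes()] for nd in nodes]
        parent = [
            index[id(nd.parent_node)] if nd.parent_node is not None else -1
            for nd in nodes
        ]
        blen = []
        labels = []
        for nd in nodes:
            if nd.parent_node is None:
                blen.append(np.nan)
            else:
                if nd.edge.length is None:
                    raise ValueError("tree has a branch without a length")
                blen.append(float(nd.edge.length))
            labels.append(nd.taxon.label if nd.taxon is not None else None)
        return cls(children, parent, blen, labels)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    def check_alignment(self, names) -> None:
        """Leaves and alignment rows must carry the same names."""
        missing = set(self.leaf_nodes) - set(names)
        extra = set(names) - set(self.leaf_nodes)
        if missing or extra:
            raise ValueError(
                f"tree/alignment name mismatch: tree-only={sorted(missing)}, "
                f"alignment-only={sorted(extra)}"
            )


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-free state-index alignment: ``data[s, site]`` indexes the codons.

    ``n_masked`` records how many columns were dropped (gaps / ambiguity)
    while reading.
    """

    names: tuple[str, ...]
    data: np.ndarray
    n_states: int
    n_masked: int = 0

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def patterns(self):
        """Distinct site patterns: ``(columns (n_seqs, n_pat), weights,
        first_site)``."""
        cols, first, inverse = np.unique(
            self.data, axis=1, return_index=True, return_inverse=True
        )
        weights = np.bincount(inverse.ravel(), minlength=cols.shape[1]).astype(float)
        return cols, weights, first


@dataclass(frozen=True)
class BranchPosterior:
    """Joint endpoint posteriors ``P(parent=a, child=b | data)`` per branch.

    When ``aggregated`` the per-branch matrix is the posterior summed over
    sites (it totals the site count); otherwise ``joint[k]`` has one matrix
    per site pattern and ``site_weights`` gives pattern multiplicities.
    """

    branch_nodes: tuple[int, ...]
    branch_lengths: np.ndarray
    joint: tuple[np.ndarray, ...]
    aggregated: bool
    site_weights: np.ndarray | None = None


@dataclass(frozen=True)
class ExpectedSufficientStats:
    """Posterior expectations of the labeled times and substitution counts."""

    L_s_ts: float
    L_s_tv: float
    L_ns_ts: float
    L_ns_tv: float
    N: float
    N_ts: float
    N_ns: float

    @property
    def N_tv(self) -> float:
        return self.N - self.N_ts

    @property
    def N_s(self) -> float:
        return self.N - self.N_ns


@dataclass
class EMTrace:
    """Per-iteration parameters and observed-data log likelihood."""

    params: list = field(default_factory=list)
    loglik: list = field(default_factory=list)
    converged: bool = False

    @property
    def n_iter(self) -> int:
        return len(self.loglik)

    @property
    def final(self) -> CodonModelParams:
        return self.params[-1]


def _peel(tree: PhyloTree, Q: RateMatrix, aln: CodonAlignment, root_dist):
    """Inside (postorder) pass over site patterns.

    Returns ``(cols, weights, first, P_by_node, inside, msg, site_lik)``.
    """
    tree.check_alignment(aln.names)
    cols, weights, first = aln.patterns()
    n_pat = cols.shape[1]
    n = Q.n
    row_of = {name: i for i, name in enumerate(aln.names)}
    P_by_node = {
        v: transition_probabilities(Q, float(tree.blen[v])).P
        for v in tree.branch_nodes
    }
    inside = [None] * tree.n_nodes
    msg = [None] * tree.n_nodes
    for v in tree.postorder:
        if not tree.children[v]:
            states = cols[row_of[tree.labels[v]]]
            I = np.zeros((n_pat, n))
            I[np.arange(n_pat), states] = 1.0
            inside[v] = I
        else:
            I = np.ones((n_pat, n))
            for w in tree.children[v]:
                I = I * msg[w]
            inside[v] = I
        if v != tree.root:
            msg[v] = inside[v] @ P_by_node[v].T
    site_lik = inside[tree.root] @ np.asarray(root_dist, float)
    if np.any(site_lik <= 0):
        bad = int(first[int(np.argmax(site_lik <= 0))])
        raise ValueError(f"site {bad} has zero likelihood under the model")
    return cols, weights, first, P_by_node, inside, msg, site_lik


def branch_endpoint_posteriors(
    tree: PhyloTree,
    Q: RateMatrix,
    aln: CodonAlignment,
    root_dist,
    aggregate: bool = True,
) -> BranchPosterior:
    """Joint posterior of each branch's endpoint states via inside-outside.

    The outside pass propagates, from the root prior, the probability of the
    data not below each node jointly with the node's state; combining it with
    the inside partial likelihood of the child gives the joint endpoint law
    of every branch, each summing to one over the ``n x n`` state pairs.
    """
    cols, weights, first, P_by_node, inside, msg, site_lik = _peel(
        tree, Q, aln, root_dist
    )
    n_pat = cols.shape[1]
    n = Q.n
    outside = [None] * tree.n_nodes
    outside[tree.root] = np.broadcast_to(np.asarray(root_dist, float), (n_pat, n))
    joint: dict[int, np.ndarray] = {}
    scale = weights / site_lik
    for u in reversed(tree.postorder):  # preorder
        for v in tree.children[u]:
            other = outside[u].copy()
            for w in tree.children[u]:
                if w != v:
                    other = other * msg[w]
            outside[v] = other @ P_by_node[v]
            if aggregate:
                joint[v] = P_by_node[v] * ((scale[:, None] * other).T @ inside[v])
            else:
                joint[v] = (
                    P_by_node[v][None, :, :]
                    * other[:, :, None]
                    * inside[v][:, None, :]
                    / site_lik[:, None, None]
                )
    branch_nodes = tree.branch_nodes
    return BranchPosterior(
        branch_nodes=branch_nodes,
        branch_lengths=tree.blen[list(branch_nodes)],
        joint=tuple(joint[v] for v in branch_nodes),
        aggregated=aggregate,
        site_weights=None if aggregate else weights,
    )


def e_step(
    tree: PhyloTree,
    Q: RateMatrix,
    aln: CodonAlignment,
    posteriors: BranchPosterior,
    C_matrices: dict,
    tail_bound: float = 1e-8,
) -> ExpectedSufficientStats:
    """Posterior expectations of the labeled sufficient statistics.

    For each weight matrix the distinct branch lengths are served by a single
    batched uniformization precomputation; the per-branch endpoint-conditioned
    expectation ``H(a,b) = Sigma(C; a, b, t_k) / p_ab(t_k)`` is then
    contracted against the aggregated endpoint posterior.
    """
    if not posteriors.aggregated:
        raise ValueError("e_step expects aggregated posteriors")
    lengths = posteriors.branch_lengths
    distinct = np.unique(lengths)
    totals: dict[str, float] = {}
    for key, C in C_matrices.items():
        results = uni_statistics(Q, C, list(distinct), tail_bound=tail_bound)
        by_t = {float(t): r for t, r in zip(distinct, results)}
        total = 0.0
        for t_k, W in zip(lengths, posteriors.joint):
            r = by_t[float(t_k)]
            H = np.where(r.P > ENDPOINT_PROB_FLOOR, r.Sigma, 0.0) / np.where(
                r.P > ENDPOINT_PROB_FLOOR, r.P, 1.0
            )
            total += float(np.sum(W * H))
        totals[key] = total
    # statistics whose weight matrix was not supplied stay NaN
    return ExpectedSufficientStats(
        **{k: totals.get(k, float("nan")) for k in (*TIME_WEIGHT_KEYS, *COUNT_WEIGHT_KEYS)}
    )


def m_step(stats: ExpectedSufficientStats, pi) -> CodonModelParams:
    """Closed-form maximizer of the expected complete-data log likelihood.

    ``omega`` is the positive root of ``a w^2 + b w + c = 0`` (there is
    exactly one when all expected statistics are positive, since ``a < 0``
    and ``c > 0``); then ``alpha`` and ``beta = alpha kappa`` follow.
    """
    for name in ("L_s_ts", "L_s_tv", "L_ns_ts", "L_ns_tv", "N", "N_ts", "N_ns"):
        if getattr(stats, name) <= 0:
            raise ValueError(f"degenerate statistics: {name} is not positive")
    a = -stats.L_ns_tv * stats.L_ns_ts * stats.N_s
    b = stats.L_ns_tv * stats.L_s_ts * (stats.N_ns - stats.N_tv) + stats.L_ns_ts * stats.L_s_tv * (
        stats.N_ns - stats.N_ts
    )
    c = stats.L_s_tv * stats.L_s_ts * stats.N_ns
    disc = b * b - 4.0 * a * c
    if disc <= 0:
        raise ValueError("degenerate statistics: non-positive discriminant")
    roots = ((-b + math.sqrt(disc)) / (2 * a), (-b - math.sqrt(disc)) / (2 * a))
    positive = [r for r in roots if r > 0]
    if not positive:
        raise ValueError("degenerate statistics: no positive root for omega")
    omega = positive[0]
    alpha = stats.N_tv / (stats.L_s_tv + omega * stats.L_ns_tv)
    beta = stats.N_ts / (stats.L_s_ts + omega * stats.L_ns_ts)
    return CodonModelParams(alpha=alpha, kappa=beta / alpha, omega=omega, pi=np.asarray(pi, float))


def observed_log_likelihood(tree: PhyloTree, Q: RateMatrix, aln: CodonAlignment, root_dist) -> float:
    """Pruning log likelihood, summed over sites."""
    _, weights, _, _, _, _, site_lik = _peel(tree, Q, aln, root_dist)
    return float(np.sum(weights * np.log(site_lik)))


DEFAULT_INIT = dict(alpha=1.0, kappa=2.0, omega=0.5)


def em_fit(
    aln: CodonAlignment,
    tree: PhyloTree,
    init: CodonModelParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    code: GeneticCode | None = None,
    pseudocount: float = 0.1,
) -> EMTrace:
    """EM estimation of ``(alpha, kappa, omega)`` on a fixed tree.

    Codon frequencies ``pi`` are the observed frequencies (with a
    pseudo-count for unseen codons) and stay fixed; the root distribution is
    ``pi``, valid because the GY chain is reversible.  Iterates E/M steps
    until the maximum relative parameter change drops below ``tol``.
    """
    code = code or GeneticCode.standard()
    pi = codon_frequencies(aln.data, code.n, pseudocount=pseudocount)
    if init is None:
        params = CodonModelParams(pi=pi, **DEFAULT_INIT)
    else:
        params = CodonModelParams(
            alpha=init.alpha, kappa=init.kappa, omega=init.omega, pi=pi
        )
    trace = EMTrace()
    for iteration in range(max_iter):
        Q = gy_rate_matrix(params, code)
        C_matrices = label_weight_matrices(code, pi, Q)
        posts = branch_endpoint_posteriors(tree, Q, aln, pi)
        ll = observed_log_likelihood(tree, Q, aln, pi)
        trace.params.append(params)
        trace.loglik.append(ll)
        stats = e_step(tree, Q, aln, posts, C_matrices)
        new = m_step(stats, pi)
        rel = max(
            abs(new.alpha - params.alpha) / params.alpha,
            abs(new.kappa - params.kappa) / params.kappa,
            abs(new.omega - params.omega) / params.omega,
        )
        logger.debug(
            "EM iter %d: alpha=%.4g kappa=%.4g omega=%.4g ll=%.6f rel=%.3g",
            iteration, new.alpha, new.kappa, new.omega, ll, rel,
        )
        params = new
        if rel < tol:
            trace.converged = True
            break
    Q = gy_rate_matrix(params, code)
    trace.params.append(params)
    trace.loglik.append(observed_log_likelihood(tree, Q, aln, pi))
    if not trace.converged:
        logger.warning("EM did not converge within %d iterations", max_iter)
    return trace
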