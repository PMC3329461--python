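"""Goldman-Yang codon substitution model and its labeled weight matrices.

The model acts on the 61 sense codons of the standard genetic code (stop
codons excluded).  Instantaneous rates allow only single-nucleotide changes:

    q_ij = alpha kappa pi_j         synonymous transition
           alpha pi_j               synonymous transversion
           alpha omega kappa pi_j   non-synonymous transition
           alpha omega pi_j         non-synonymous transversion
           0                        more than one position differs

with scale ``alpha``, transition/transversion ratio ``kappa``, selection
ratio ``omega`` and codon frequencies ``pi``.  Transitions are the
within-class nucleotide changes A<->G and C<->T.  The module also builds the
weight matrices that turn the generic ``Sigma(C;t)`` machinery into the
expected labeled times (L_{s,ts}, L_{s,tv}, L_{ns,ts}, L_{ns,tv}) and labeled
substitution counts (N, N_ts, N_ns) needed by the EM estimator.

Codons are ordered lexicographically over the alphabet A, C, G, T with the
three stops (TAA, TAG, TGA) removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product

import numpy as np
from Bio.Data import CodonTable

from .ctmc_core import RateMatrix, validate_rate_matrix

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

CATEGORIES = ("identical", "multi", "s_ts", "s_tv", "ns_ts", "ns_tv")

#: default pseudo-count added to observed codon tallies so that no codon has
#: zero frequency (keeps the generator irreducible)
FREQUENCY_PSEUDOCOUNT = 0.1


@dataclass(frozen=True, eq=False)  # identity hash: instances cache their pair classification
class GeneticCode:
    """Sense codons of a genetic code and their amino-acid translation."""

    codons: tuple[str, ...]
    amino_acid: dict
    stop_codons: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.codons)

    def index(self, codon: str) -> int:
        return self.codons.index(codon)

    @classmethod
    def standard(cls) -> "GeneticCode":
        """The standard (universal) code: 61 sense codons."""
        table = CodonTable.unambiguous_dna_by_id[1]
        stops = tuple(sorted(table.stop_codons))
        codons = tuple(
            "".join(c) for c in product("ACGT", repeat=3) if "".join(c) not in stops
        )
        return cls(
            codons=codons,
            amino_acid={c: table.forward_table[c] for c in codons},
            stop_codons=stops,
        )

    @classmethod
    def from_table(cls, path) -> "GeneticCode":
        """Read a two-column text table ``codon amino_acid`` ('*' = stop)."""
        aa = {}
        stops = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                codon, acid = line.split()[:2]
                codon = codon.upper()
                if acid == "*":
                    stops.append(codon)
                else:
                    aa[codon] = acid
        codons = tuple(sorted(aa))
        return cls(codons=codons, amino_acid=aa, stop_codons=tuple(sorted(stops)))


@dataclass(frozen=True)
class CodonModelParams:
    """GY parameters; ``beta = alpha * kappa`` is the transition scale."""

    alpha: float
    kappa: float
    omega: float
    pi: np.ndarray

    def __post_init__(self):
        if min(self.alpha, self.kappa, self.omega) <= 0:
            raise ValueError("alpha, kappa and omega must be positive")
        pi = np.asarray(self.pi, dtype=float)
        if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be a probability vector")
        object.__setattr__(self, "pi", pi)

    @property
    def beta(self) -> float:
        return self.alpha * self.kappa


def _is_transition(x: str, y: str) -> bool:
    return {x, y} <= PURINES or {x, y} <= PYRIMIDINES


def classify_substitution(i: str, j: str, code: GeneticCode) -> str:
    """Category of the ordered codon pair: identical, multi, or one of the
    four synonymous/non-synonymous x transition/transversion classes."""
    for c in (i, j):
        if c not in code.amino_acid:
            raise ValueError(f"{c!r} is not a sense codon")
    if i == j:
        return "identical"
    diffs = [(x, y) for x, y in zip(i, j) if x != y]
    if len(diffs) > 1:
        return "multi"
    x, y = diffs[0]
    ts = "ts" if _is_transition(x, y) else "tv"
    syn = "s" if code.amino_acid[i] == code.amino_acid[j] else "ns"
    return f"{syn}_{ts}"


@lru_cache(maxsize=4)
def _classification_matrix(code: GeneticCode) -> np.ndarray:
    """Category index (into CATEGORIES) for every ordered codon pair."""
    n = code.n
    M = np.empty((n, n), dtype=np.int8)
    for a, ci in enumerate(code.codons):
        for b, cj in enumerate(code.codons):
            M[a, b] = CATEGORIES.index(classify_substitution(ci, cj, code))
    return M


def gy_rate_matrix(params: CodonModelParams, code: GeneticCode | None = None) -> RateMatrix:
    """Build the 61x61 GY generator; rows sum to zero, reversible wrt pi."""
    code = code or GeneticCode.standard()
    cls = _classification_matrix(code)
    a, k, w = params.alpha, params.kappa, params.omega
    factor = np.zeros(len(CATEGORIES))
    factor[CATEGORIES.index("s_ts")] = a * k
    factor[CATEGORIES.index("s_tv")] = a
    factor[CATEGORIES.index("ns_ts")] = a * w * k
    factor[CATEGORIES.index("ns_tv")] = a * w
    Q = factor[cls] * params.pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return validate_rate_matrix(Q, labels=code.codons, row_sum_rtol=1e-10)


#: keys of the seven weight matrices used by the EM E-step
TIME_WEIGHT_KEYS = ("L_s_ts", "L_s_tv", "L_ns_ts", "L_ns_tv")
COUNT_WEIGHT_KEYS = ("N", "N_ts", "N_ns")


def label_weight_matrices(code: GeneticCode, pi, Q: RateMatrix) -> dict:
    """The weight matrices of the EM sufficient statistics.

    Time weights are diagonal: ``C_ii = sum_j pi_j 1((i,j) in L_x)`` for each
    of the four substitution classes ``x``.  Count weights are off-diagonal:
    ``C_ij = q_ij 1((i,j) in L)`` for the labelings "all single-step pairs",
    "transitions" and "non-synonymous".
    """
    pi = np.asarray(pi, dtype=float)
    cls = _classification_matrix(code)
    Qm = Q.Q
    out: dict[str, np.ndarray] = {}
    for key in TIME_WEIGHT_KEYS:
        member = cls == CATEGORIES.index(key[2:])
        out[key] = np.diag(member @ pi)
    single = np.isin(cls, [CATEGORIES.index(k) for k in ("s_ts", "s_tv", "ns_ts", "ns_tv")])
    ts = np.isin(cls, [CATEGORIES.index("s_ts"), CATEGORIES.index("ns_ts")])
    ns = np.isin(cls, [CATEGORIES.index("ns_ts"), CATEGORIES.index("ns_tv")])
    for key, member in (("N", single), ("N_ts", ts), ("N_ns", ns)):
        C = np.where(member, Qm, 0.0)
        np.fill_diagonal(C, 0.0)
        out[key] = C
    return out


def codon_frequencies(states: np.ndarray, n_codons: int,
                      pseudocount: float = FREQUENCY_PSEUDOCOUNT) -> np.ndarray:
    """Observed codon frequencies with a pseudo-count for unseen codons."""
    counts = np.bincount(np.asarray(states).ravel(), minlength=n_codons).astype(float)
    counts += pseudocount
    return counts / counts.sum()
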