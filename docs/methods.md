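# Methods

## Model and quantities computed

A continuous-time Markov chain on `n` states is given by a generator `Q`
with non-negative off-diagonal rates and zero row sums.  For a chain
observed only at the ends of an interval of length `t`, inference needs the
endpoint-conditioned expectations of the sufficient statistics — dwell
times `T_c` and jump counts `N_cd` — which reduce to the convolution
integrals `I_cd^ab(t) = ∫₀ᵗ p_ac(u) p_db(t−u) du`.  All package
functionality is built on the weighted sum
`Σ(C; a, b, t) = Σ_cd C_cd I_cd^ab(t)`, computed as a full `n × n` matrix
in O(n³) by three backends (EVD, UNI, EXPM).  Conditionals follow by
dividing by `p_ab(t)`; a diagonal `C` yields expected weighted times, an
off-diagonal `C` with entries `q_cd` yields expected weighted jump counts.

Every `Σ` result carries the `P(t)` produced by the *same* backend.  This
matters for UNI: term-by-term, the truncated series for `Σ(I;t)` equals
`t ×` the truncated series for `P(t)` exactly, so ratios `Σ/P` benefit from
cancelling truncation errors, and the conservation identity
`Σ(I;t) = t·P(t)` holds to machine precision rather than to the tail bound.

## Backends and numerical choices

**EVD.**  For reversible `Q` (detected by a detailed-balance check with
relative tolerance 1e-10) the decomposition is done on the symmetric
`S = Π^{1/2} Q Π^{−1/2}` via `eigh` — real spectrum, orthonormal
eigenvectors, no conditioning issues; a flag forces the general path.
Otherwise `eig` is used; eigenvector condition numbers above 1e12 raise an
error directing the caller to EXPM (non-diagonalizable generators are out
of scope).  Complex arithmetic is carried to the end; the imaginary residue
must stay below 1e-8 of the result's magnitude before it is discarded
(conjugate eigenpairs cancel analytically).  The divided-difference matrix
`J_ij(t)` switches to its degenerate branch `t·e^{λ_i t}` when
`|λ_i − λ_j| ≤ 1e-9·max|λ|`, avoiding catastrophic cancellation; the branch
point is continuous to ~1e-9.

**UNI.**  `μ = max_i q_i` exactly (no padding).  The truncation point for
`λ = μt` at the default tail bound `b = 1e-8` is the conservative
closed-form rule `s(λ) = ⌈4 + 6√λ + λ⌉`; its shape comes from the normal
approximation to the Poisson tail, whose `1 − 10⁻⁸` quantile is 5.6
standard deviations.  Any other bound is served by an exact quantile
search (`exact_truncation_point`), also available directly for
verification.  Poisson weights come from `scipy.stats.poisson.pmf`, which
works in log space internally and is over/underflow-safe at any `μt`.
Batched evaluation precomputes powers `R^m` and partial sums
`A(m) = A(m−1)R + R^m C` once at the largest requested time; each further
time point is an O(s·n²) weighted sum.  The degenerate `μ = 0` (zero
generator) returns `Σ = t·C`, `P = I`, which is the analytic limit
(`P(u) ≡ I` makes `I_cd^ab(t) = t·1(a=c)1(b=d)`).

**EXPM.**  `scipy.linalg.expm` (Padé scaling-and-squaring) applied to the
`2n × 2n` block matrix `[[Q, C], [0, Q]]·t`; the upper-right block is
`Σ(C;t)` and the lower-right block is reused as `P(t)`.

Rate-matrix validation accepts rows summing to zero within
`1e-12·max|Q|` (configurable) and rejects any negative off-diagonal entry,
naming the offending row.

## Analytic oracles and the accuracy experiment

The equal-rates chain (uniform rates `1/(n−1)`, spectrum `{0, −n/(n−1)}`)
and the HKY chain (states ordered **A, G, C, T**; transitions A↔G, C↔T
scaled by κ) admit closed forms for `P(t)` and `I_cd^ab(t)`.  The JC
integral takes only three values by the case of `(a=c, d=b)`, so
`Σ(C;t)` collapses to row/column/total sums of `C` — an O(n²) oracle.  The
HKY oracle is assembled exactly from the known eigensystem (eigenvalues
`(0, −1, −π_Y κ − π_R, −π_R κ − π_Y)`), which reconstructs `Q` to 1e-16.

The accuracy experiment compares all three backends against these oracles
with the normalized deviation `|Σ̂ − Σ|/Σ`, averaged over endpoint pairs
(entries with `Σ = 0` are excluded to avoid 0/0) and over five random
binary weight matrices per setting (entries 1 with probability 1/2; an
all-zero draw is resampled).  Grids: every `n` from 5 to 100 at `t = 0.1`
for JC; `π = (0.2, 0.2, 0.3, 0.3)`, `κ = 2.15` and 10 log-spaced times in
`[0.01, 10]` for HKY (the time grid is a package choice; deviations grow
mildly with `μt` and stay within the documented 3e-9 bound across it).
Cross-backend agreement is additionally checked on random reversible
generators: stationary vector from Dirichlet(1,…,1), sub-diagonal rates
from Exp(1), the rest by detailed balance.

## Simulation as ground truth

`simulate_path` is a plain Gillespie sampler; dwell times are forced to
sum exactly to `t`.  `simulate_endpoint_conditioned` proposes unconditional
paths and keeps those ending in the required state — exact draws from the
conditioned path law, at the cost of an acceptance probability `p_ab(t)`
(a floor of 1e-6 guards against hopeless settings).  More efficient
conditioned samplers are deliberately out of scope: rejection is the
simplest correct oracle.  `simulate_alignment` evolves sites down a tree
and returns the realized complete-data statistics alongside the leaf
states, so simulated data carry their own truth;
`simulate_pairwise_sites` draws endpoint pairs directly from `π` and
`P(t)` — the exact marginal of path simulation — for large-`m` runs.

The simulators emulate i.i.d. sites under a homogeneous, stationary chain.
Real alignments violate this (rate variation across sites, non-stationary
composition, indels and alignment error are all absent), so passing tests
demonstrate correctness of the computations under the model, not fit of
the model to biological data.

## EM estimation of the Goldman–Yang model

The 61-state codon generator (standard genetic code; codons ordered
lexicographically over A, C, G, T with stops removed) allows only
single-nucleotide changes, with rates `ακπ_j`, `απ_j`, `αωκπ_j`, `αωπ_j`
by synonymous/non-synonymous × transition/transversion class.  Detailed
balance with `π` holds by construction.  Codon frequencies are estimated
as observed frequencies with a pseudo-count of 0.1 per codon (keeps the
generator irreducible when some codons are unobserved) and held fixed; no
mean-rate normalization is imposed, since `α` absorbs the scale and branch
lengths are fixed.

E-step: site patterns are collapsed with multiplicities; an inside
(postorder) and outside (preorder) pass over each pattern give the joint
endpoint posterior of every branch, aggregated over sites on the fly.  The
seven expected statistics (four diagonal time-weights
`C_ii = Σ_j π_j 1((i,j) ∈ L_x)`, three count-weights `C_ij = q_ij 1(...)`
for all/transition/non-synonymous substitutions) are posterior-weighted
sums of `Σ(C;a,b,t_k)/p_ab(t_k)`, served per weight matrix by one batched
UNI precomputation over the distinct branch lengths.

M-step: with `β = ακ`, the expected complete-data log likelihood is
maximized in closed form; `ω` solves `aω² + bω + c = 0` with
`a = −L_ns,tv L_ns,ts N_s < 0` and `c = L_s,tv L_s,ts N_ns > 0`, which has
exactly one positive root (selected; it is `(−b − √(b²−4ac))/(2a)` for
negative `a`), then `α = N_tv/(L_s,tv + ωL_ns,tv)`,
`β = N_ts/(L_s,ts + ωL_ns,ts)`, `κ = β/α`.  The M-step inverts exact
complete-data expectations to 1e-12 and zeroes the numerical score.

Defaults: initialization `(α, κ, ω) = (1, 2, 0.5)`; convergence when the
maximum relative parameter change drops below 1e-6, capped at 200
iterations (non-convergence is flagged, not fatal).  Unrooted trees are
rooted at the basal polytomy and the root distribution is `π`; by
reversibility the fit is root-invariant.  The parameter-recovery
experiment uses a symmetric 4-leaf tree with all branches 0.1 and 2000
sites generated at truth `(10.5, 4.27, 0.6)` with uniform codon
frequencies — at these values the largest exit rate is ≈ 2.67, so
uniformization needs at most 8 terms per branch and a full fit converges
in ~10 iterations.

## Robust labeled distances

For a labeling `ℒ` (named presets: to/from a base, transitions, all
pairs), `d̂_ℒ = (1/m) Σ_s E[N_ℒ | X(0)=y₁ₛ, X(1)=y₂ₛ]` with `t` pinned to 1
(only `Qt` is identifiable from a pair).  One `Σ(C;1)` evaluation with
`C_ij = q_ij 1((i,j) ∈ ℒ)` serves all sites via the pattern count table.
The estimator is linear in `ℒ` (additive over disjoint labelings) and
converges, under data generated by `Q`, to `Σ_{(i,j)∈ℒ} π_i q_ij`.  Sites
with gaps or ambiguity codes are dropped when reading; an observed pattern
with `p_ab(1) = 0` raises an error naming the site.

GTR parameters (six exchangeabilities, A, G, C, T order) are estimated by
pairwise maximum likelihood at fixed `t = 1`: `π` is the pooled empirical
base composition, and the six log-rates maximize
`Σ_s log(π_{y₁ₛ} p_{y₁ₛy₂ₛ}(1))` by Nelder–Mead.  The original
labeled-distance work delegated its estimation procedure to an external
reference; pairwise ML at unit time is this package's documented
substitute, and all six rates are identifiable because the time is pinned.

## Problem sizes and tolerances in the test suite

Unit tests use 4–8-state chains with enumeration, quadrature
(`scipy.integrate.quad` on the defining convolution integral) and
Monte-Carlo oracles; stochastic checks are seeded and asserted within
3 standard errors.  The end-to-end checks run the full accuracy grids, 20
random reversible matrices up to `n = 20`, 100 conservation draws, 1e5
endpoint-conditioned rejection samples (JC, `t = 0.5`), a 2000-site EM
recovery (15% tolerance on all three parameters), and a 1e5-site robust
distance comparison — the whole suite completes in well under a minute on
one core.

## Known limitations

* Non-diagonalizable generators are rejected by EVD rather than handled by
  a Jordan-form extension; UNI and EXPM cover them.
* No derivatives or higher moments of `Σ(C;t)`; no time-inhomogeneous
  chains; no branch-length or topology estimation; no among-site rate
  variation; codon models with multi-nucleotide instantaneous changes are
  excluded by construction.
* Alternative genetic codes are supported only through a user-supplied
  codon→amino-acid table.
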