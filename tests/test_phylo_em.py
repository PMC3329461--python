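import numpy as np
import pytest

from ctmcexp import (
    CodonAlignment,
    CodonModelParams,
    GeneticCode,
    PhyloTree,
    branch_endpoint_posteriors,
    e_step,
    em_fit,
    gy_rate_matrix,
    jc_rate_matrix,
    jc_transition_closed_form,
    label_weight_matrices,
    m_step,
    observed_log_likelihood,
    simulate_alignment,
    transition_probabilities,
)
from ctmcexp.phylo_em import ExpectedSufficientStats

UNIFORM4 = np.full(4, 0.25)


def nucleotide_alignment(columns):
    """Tiny 4-state alignment from a list of per-site leaf-state tuples."""
    data = np.asarray(columns, dtype=int).T
    names = tuple(f"S{i}" for i in range(data.shape[0]))
    return CodonAlignment(names=names, data=data, n_states=4)


class TestPhyloTree:
    def test_two_leaf_tree(self):
        tree = PhyloTree.from_newick("(S0:0.1,S1:0.2);")
        assert tree.n_leaves == 2
        assert abs(tree.total_length - 0.3) < 1e-12

    def test_nested_tree_structure(self):
        tree = PhyloTree.from_newick("(A:0.1,(B:0.2,C:0.3):0.1);")
        assert tree.n_leaves == 3
        assert len(tree.branch_nodes) == 4

    def test_missing_branch_length_rejected(self):
        with pytest.raises(ValueError, match="branch"):
            PhyloTree.from_newick("(A:0.1,B);")

    def test_alignment_name_mismatch_rejected(self):
        tree = PhyloTree.from_newick("(A:0.1,B:0.1);")
        with pytest.raises(ValueError, match="mismatch"):
            tree.check_alignment(("A", "C"))


class TestBranchPosteriors:
    def test_two_leaf_tree_is_point_mass_at_observation(self, jc4):
        tree = PhyloTree.from_newick("(S0:0.2,S1:0.3);")
        aln = nucleotide_alignment([(0, 2)])
        post = branch_endpoint_posteriors(tree, jc4, aln, UNIFORM4, aggregate=False)
        # marginals at the two leaves concentrate on the observed states
        for k, v in enumerate(post.branch_nodes):
            J = post.joint[k][0]
            assert abs(J.sum() - 1) < 1e-10
            marg_child = J.sum(axis=0)
            observed = aln.data[[tree.labels[v] == n for n in aln.names].index(True)][0]
            assert abs(marg_child[observed] - 1) < 1e-10

    def test_star_tree_matches_exhaustive_enumeration(self, jc4):
        tree = PhyloTree.from_newick("(S0:0.1,S1:0.4,S2:0.7);")
        leaves = (0, 1, 3)
        aln = nucleotide_alignment([leaves])
        post = branch_endpoint_posteriors(tree, jc4, aln, UNIFORM4, aggregate=False)
        Ps = {v: transition_probabilities(jc4, float(tree.blen[v])).P for v in tree.branch_nodes}
        # brute force over the internal (root) state r
        name_to_state = dict(zip(("S0", "S1", "S2"), leaves))
        site_terms = np.array(
            [
                0.25 * np.prod([Ps[v][r, name_to_state[tree.labels[v]]] for v in tree.branch_nodes])
                for r in range(4)
            ]
        )
        lik = site_terms.sum()
        for k, v in enumerate(post.branch_nodes):
            obs = name_to_state[tree.labels[v]]
            expected = np.zeros((4, 4))
            expected[:, obs] = site_terms / lik
            assert np.abs(post.joint[k][0] - expected).max() < 1e-12

    def test_aggregated_posteriors_total_site_count(self, jc4):
        tree = PhyloTree.from_newick("((S0:0.1,S1:0.1):0.2,S2:0.3);")
        aln = nucleotide_alignment([(0, 1, 2), (3, 3, 3), (0, 0, 0), (0, 1, 2)])
        post = branch_endpoint_posteriors(tree, jc4, aln, UNIFORM4)
        for J in post.joint:
            assert abs(J.sum() - aln.n_sites) < 1e-9
            assert J.min() >= 0

    def test_zero_likelihood_site_named(self):
        # state 0 is absorbing, so an observed 0 -> 1 site is impossible
        two_state = CodonAlignment(names=("S0", "S1"), data=np.array([[0], [1]]), n_states=2)
        from ctmcexp import validate_rate_matrix

        frozen = validate_rate_matrix(np.array([[0.0, 0.0], [1.0, -1.0]]))
        with pytest.raises(ValueError, match="site 0"):
            branch_endpoint_posteriors(
                PhyloTree.from_newick("(S0:1.0,S1:1.0);"), frozen, two_state, np.array([1.0, 0.0])
            )


class TestEStep:
    def test_identity_time_weights_recover_total_tree_length(self, jc4):
        tree = PhyloTree.from_newick("((S0:0.1,S1:0.2):0.15,S2:0.25);")
        aln = nucleotide_alignment([(0, 1, 2), (3, 0, 1), (2, 2, 2)])
        post = branch_endpoint_posteriors(tree, jc4, aln, UNIFORM4)
        stats = e_step(tree, jc4, aln, post, {"N": np.eye(4)})
        expected = tree.total_length * aln.n_sites
        assert abs(stats.N - expected) < 1e-8

    def test_single_branch_observed_endpoints_reduce_to_direct_conditional(self, jc4):
        from ctmcexp import conditional_jump_count

        tree = PhyloTree.from_newick("(S0:0.5,S1:0.5);")
        aln = nucleotide_alignment([(0, 1)])
        post = branch_endpoint_posteriors(tree, jc4, aln, UNIFORM4)
        C = np.zeros((4, 4))
        C[2, 3] = jc4.Q[2, 3]
        stats = e_step(tree, jc4, aln, post, {"N": C})
        # both branches join at the root: enumerate the root state posterior
        P = transition_probabilities(jc4, 0.5).P
        root_post = np.array([0.25 * P[r, 0] * P[r, 1] for r in range(4)])
        root_post /= root_post.sum()
        expected = sum(
            root_post[r]
            * (
                conditional_jump_count(jc4, 0.5, 2, 3, r, 0)
                + conditional_jump_count(jc4, 0.5, 2, 3, r, 1)
            )
            for r in range(4)
        )
        assert abs(stats.N - expected) < 1e-7

    def test_posterior_expected_counts_unbiased_against_simulation(self, jc4):
        # E_y[ E[N | y] ] equals the unconditional E[N] = total length * mean rate
        tree = PhyloTree.from_newick("((S0:0.3,S1:0.3):0.2,(S2:0.3,S3:0.3):0.2);")
        C = jc4.Q.copy()
        np.fill_diagonal(C, 0.0)
        m, reps = 25, 120
        rng = np.random.default_rng(8)
        vals, realized = [], []
        for _ in range(reps):
            sim = simulate_alignment(tree, jc4, m, root_dist=UNIFORM4, rng_seed=rng)
            aln = sim.to_codon_alignment(4)
            post = branch_endpoint_posteriors(tree, jc4, aln, UNIFORM4)
            vals.append(e_step(tree, jc4, aln, post, {"N": C}).N)
            realized.append(sim.N_total.sum())
        truth = tree.total_length * m  # unit total rate per state
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(reps)
        assert abs(vals.mean() - truth) < 3 * se
        realized = np.array(realized, dtype=float)
        se_r = realized.std(ddof=1) / np.sqrt(reps)
        assert abs(realized.mean() - truth) < 3 * se_r


@pytest.fixture(scope="module")
def exact_gy_stats():
    """Complete-data expectations at stationarity: the M-step must invert them."""
    code = GeneticCode.standard()
    pi = np.full(61, 1 / 61)
    truth = CodonModelParams(alpha=10.5, kappa=4.27, omega=0.6, pi=pi)
    Q = gy_rate_matrix(truth, code)
    W = label_weight_matrices(code, pi, Q)
    tau = 2.0
    stats = ExpectedSufficientStats(
        **{k: float(tau * np.sum(pi * np.diag(W[k]))) for k in ("L_s_ts", "L_s_tv", "L_ns_ts", "L_ns_tv")},
        **{k: float(tau * np.sum(pi[:, None] * W[k])) for k in ("N", "N_ts", "N_ns")},
    )
    return truth, stats, pi


class TestMStep:
    def test_inverts_exact_complete_data_expectations(self, exact_gy_stats):
        truth, stats, pi = exact_gy_stats
        est = m_step(stats, pi)
        assert abs(est.alpha - truth.alpha) / truth.alpha < 1e-12
        assert abs(est.kappa - truth.kappa) / truth.kappa < 1e-12
        assert abs(est.omega - truth.omega) / truth.omega < 1e-12

    def test_estimate_zeroes_complete_data_score(self, exact_gy_stats):
        _, stats, pi = exact_gy_stats
        est = m_step(stats, pi)

        def ell(a, k, w):
            return (
                -a * stats.L_s_tv
                - a * w * stats.L_ns_tv
                - a * k * stats.L_s_ts
                - a * k * w * stats.L_ns_ts
                + stats.N * np.log(a)
                + stats.N_ts * np.log(k)
                + stats.N_ns * np.log(w)
            )

        eps = 1e-6
        for i, x in enumerate((est.alpha, est.kappa, est.omega)):
            args_hi = [est.alpha, est.kappa, est.omega]
            args_lo = list(args_hi)
            args_hi[i] = x * (1 + eps)
            args_lo[i] = x * (1 - eps)
            grad = (ell(*args_hi) - ell(*args_lo)) / (2 * x * eps)
            assert abs(grad) < 1e-6

    def test_time_scaling_homogeneity(self, exact_gy_stats):
        _, stats, pi = exact_gy_stats
        est = m_step(stats, pi)
        doubled = ExpectedSufficientStats(
            L_s_ts=2 * stats.L_s_ts,
            L_s_tv=2 * stats.L_s_tv,
            L_ns_ts=2 * stats.L_ns_ts,
            L_ns_tv=2 * stats.L_ns_tv,
            N=stats.N,
            N_ts=stats.N_ts,
            N_ns=stats.N_ns,
        )
        est2 = m_step(doubled, pi)
        assert abs(est2.alpha - est.alpha / 2) < 1e-10
        assert abs(est2.omega - est.omega) < 1e-10
        assert abs(est2.kappa - est.kappa) < 1e-10

    def test_degenerate_statistics_rejected(self, exact_gy_stats):
        _, stats, pi = exact_gy_stats
        bad = ExpectedSufficientStats(
            L_s_ts=stats.L_s_ts, L_s_tv=stats.L_s_tv, L_ns_ts=stats.L_ns_ts,
            L_ns_tv=stats.L_ns_tv, N=stats.N, N_ts=stats.N_ts, N_ns=0.0,
        )
        with pytest.raises(ValueError, match="degenerate"):
            m_step(bad, pi)


class TestObservedLogLikelihood:
    def test_single_sequence_single_site(self, jc4):
        tree = PhyloTree.from_newick("(S0:0.1,S1:0.1);")
        aln = nucleotide_alignment([(2, 2)])
        ll = observed_log_likelihood(tree, jc4, aln, UNIFORM4)
        P = transition_probabilities(jc4, 0.2).P
        # two leaves at distance 0.2 (reversibility collapses the root)
        assert abs(ll - np.log(0.25 * P[2, 2])) < 1e-10

    def test_two_leaves_match_jc_closed_form(self, jc4):
        tree = PhyloTree.from_newick("(S0:0.15,S1:0.25);")
        aln = nucleotide_alignment([(0, 3), (1, 1)])
        ll = observed_log_likelihood(tree, jc4, aln, UNIFORM4)
        expected = np.log(0.25 * jc_transition_closed_form(4, 0.4, 0, 3)) + np.log(
            0.25 * jc_transition_closed_form(4, 0.4, 1, 1)
        )
        assert abs(ll - expected) < 1e-10


@pytest.fixture(scope="module")
def small_fit():
    code = GeneticCode.standard()
    pi = np.full(61, 1 / 61)
    truth = CodonModelParams(alpha=10.5, kappa=4.27, omega=0.6, pi=pi)
    Q = gy_rate_matrix(truth, code)
    tree = PhyloTree.from_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
    sim = simulate_alignment(tree, Q, 300, root_dist=pi, rng_seed=77)
    aln = sim.to_codon_alignment(61)
    return truth, em_fit(aln, tree, tol=1e-4, max_iter=40)


class TestEMFit:
    def test_loglik_monotone(self, small_fit):
        _, trace = small_fit
        assert np.all(np.diff(trace.loglik) >= -1e-8)

    def test_converges_and_lands_near_truth(self, small_fit):
        truth, trace = small_fit
        assert trace.converged
        f = trace.final
        # 300 sites: loose recovery only
        assert abs(f.omega - truth.omega) / truth.omega < 0.5
        assert abs(f.kappa - truth.kappa) / truth.kappa < 0.5
        assert abs(f.alpha - truth.alpha) / truth.alpha < 0.5

    def test_trace_records_every_iteration(self, small_fit):
        _, trace = small_fit
        assert len(trace.params) == len(trace.loglik) == trace.n_iter
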