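"""Structure MCMC and the guided hierarchical sampler."""
import numpy as np
import pytest

from bnggm import (
    BGeScorer,
    DAG,
    GaussianSimConfig,
    MCMCState,
    SamplerConfig,
    edge_posterior,
    energy,
    log_partition_bound,
    mh_accept_beta,
    mh_accept_structure,
    neighborhood,
    neighborhood_size,
    propose_beta,
    run_chain,
    simulate_gaussian,
)
from bnggm.exact import enumerate_dags, exact_log_partition
from bnggm.graphs import is_acyclic


class ConstantScorer:
    """Flat data term: every structure has the same marginal likelihood."""

    N = None

    def __init__(self, n_nodes):
        self.N = n_nodes
        self.max_parents = None

    def local_score(self, node, parents):
        return 0.0

    def graph_score(self, adj):
        return 0.0


def make_tau(n, rng=None, values=None):
    if values is not None:
        tau = np.asarray(values, dtype=float)
    else:
        rng = rng or np.random.default_rng(0)
        tau = rng.uniform(size=(n, n))
        tau = (tau + tau.T) / 2
    np.fill_diagonal(tau, 0.0)
    return tau


class TestNeighborhood:
    def test_empty_two_node_graph_has_exactly_two_additions(self):
        moves = neighborhood(np.zeros((2, 2), dtype=int))
        assert sorted(moves) == [("add", 0, 1), ("add", 1, 0)]

    def test_reversals_respect_acyclicity(self):
        # graph 1->2->3 plus 1->3: reversing 1->2 is legal, reversing 1->3 is not
        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = adj[1, 2] = adj[0, 2] = 1
        moves = neighborhood(adj)
        assert ("reverse", 0, 1) in moves
        assert ("reverse", 0, 2) not in moves
        assert ("reverse", 1, 2) in moves

    @pytest.mark.parametrize("seed", range(5))
    def test_every_neighbor_is_acyclic_and_differs_by_one_operation(self, seed):
        from bnggm import random_dag
        from bnggm.sampler import _apply_move

        dag = random_dag(6, 8, seed=seed)
        for move in neighborhood(dag.adjacency):
            prop = _apply_move(dag.adjacency, move)
            assert is_acyclic(prop)
            assert np.abs(prop - dag.adjacency).sum() in (1, 2)

    def test_size_matches_enumeration(self):
        from bnggm import random_dag

        for seed in range(5):
            dag = random_dag(5, 6, seed=seed)
            assert neighborhood_size(dag.adjacency) == len(neighborhood(dag.adjacency))


class TestEnergy:
    def test_binary_tau_equal_to_adjacency_gives_zero(self):
        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = 1
        assert energy(adj, adj.astype(float)) == 0.0

    def test_hand_computed_two_node_case(self):
        tau = make_tau(2, values=[[0.0, 0.8], [0.8, 0.0]])
        adj = np.zeros((2, 2), dtype=int)
        adj[0, 1] = 1
        assert energy(adj, tau) == pytest.approx(1.0)  # |0.8-1| + |0.8-0|

    def test_edge_addition_direction_of_energy_change(self):
        tau_hi = make_tau(2, values=[[0.0, 0.9], [0.9, 0.0]])
        tau_lo = make_tau(2, values=[[0.0, 0.1], [0.1, 0.0]])
        empty = np.zeros((2, 2), dtype=int)
        with_edge = empty.copy()
        with_edge[0, 1] = 1
        assert energy(with_edge, tau_hi) < energy(empty, tau_hi)
        assert energy(with_edge, tau_lo) > energy(empty, tau_lo)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            energy(np.zeros((3, 3), dtype=int), np.zeros((2, 2)))


class TestPartitionBound:
    def test_beta_zero_counts_all_directed_slots(self):
        tau = make_tau(4)
        assert log_partition_bound(tau, 0.0) == pytest.approx(12 * np.log(2))

    def test_equals_brute_force_all_graphs_sum_at_n2(self):
        tau = make_tau(2, values=[[0.0, 0.7], [0.3, 0.0]])
        for beta in (0.0, 1.0, 5.0, 30.0):
            # enumerate all 4 directed graphs on the 2 off-diagonal slots
            total = []
            for b01 in (0, 1):
                for b10 in (0, 1):
                    adj = np.array([[0, b01], [b10, 0]])
                    total.append(-beta * energy(adj, tau))
            from scipy.special import logsumexp

            assert log_partition_bound(tau, beta) == pytest.approx(logsumexp(total))

    def test_upper_bounds_dag_only_sum_at_n3(self):
        tau = make_tau(3, rng=np.random.default_rng(4))
        dags = enumerate_dags(3)
        for beta in (0.0, 1.0, 5.0, 30.0):
            bound = log_partition_bound(tau, beta)
            exact = exact_log_partition(tau, beta, dags)
            assert bound >= exact - 1e-12


class TestProposeBeta:
    def test_interior_proposal_stays_within_window(self, rng):
        for _ in range(200):
            b = propose_beta(15.0, 1.0, (0.0, 30.0), rng)
            assert 14.0 <= b <= 16.0

    def test_reflection_keeps_proposal_in_bounds_and_symmetric(self, rng):
        draws = np.array([propose_beta(0.2, 1.0, (0.0, 30.0), rng) for _ in range(20_000)])
        assert np.all((draws >= 0.0) & (draws <= 1.2))
        # symmetry R(b'|b) = R(b|b'): the reflected kernel density at y from
        # x equals the density at x from y; check via a pairwise histogram
        # against the closed-form reflected density
        hist, edges = np.histogram(draws, bins=24, range=(0.0, 1.2), density=True)
        centers = (edges[:-1] + edges[1:]) / 2
        expected = np.where(centers <= 0.8, 2 * 0.5, 0.5)  # fold below 0
        assert np.abs(hist - expected).max() < 0.12

    def test_deterministic_for_fixed_seed(self):
        a = [propose_beta(5.0, 0.5, (0.0, 30.0), np.random.default_rng(3)) for _ in range(1)]
        b = [propose_beta(5.0, 0.5, (0.0, 30.0), np.random.default_rng(3)) for _ in range(1)]
        assert a == b


class TestAcceptance:
    def test_uphill_flat_prior_move_always_accepted(self, scorer3, rng):
        # empty -> add the true edge A->B: higher score; neighborhood sizes
        # are both accounted for explicitly in the ratio, so force them equal
        # by checking the raw log ratio instead
        from bnggm.sampler import _log_accept_structure

        assert _log_accept_structure(2.0, 0.0, 0.0, 6, 6) > 0

    def test_proposal_must_be_a_neighbor(self, scorer3, rng):
        state = MCMCState(np.zeros((3, 3), dtype=np.int8), 0.0, 0.0, 0.0)
        bad = np.zeros((3, 3), dtype=np.int8)
        bad[0, 1] = bad[1, 2] = 1  # two edges away
        with pytest.raises(ValueError, match="neighbor"):
            mh_accept_structure(state, bad, scorer3, rng=rng)

    def test_accepted_state_caches_match_recomputation(self, scorer3, rng):
        tau = make_tau(3, rng)
        adj = np.zeros((3, 3), dtype=np.int8)
        state = MCMCState(adj, 1.5, scorer3.graph_score(adj), energy(adj, tau))
        prop = adj.copy()
        prop[0, 1] = 1
        for _ in range(50):
            accepted, new = mh_accept_structure(state, prop, scorer3, tau=tau, rng=rng)
            if accepted:
                assert new.log_score == pytest.approx(scorer3.graph_score(prop), abs=1e-10)
                assert new.energy == pytest.approx(energy(prop, tau), abs=1e-12)
                break
        else:
            pytest.fail("uphill-or-random move never accepted in 50 tries")

    def test_beta_submove_identity_proposal_always_accepted(self, rng):
        tau = make_tau(3, rng)
        adj = np.zeros((3, 3), dtype=np.int8)
        state = MCMCState(adj, 2.0, 0.0, energy(adj, tau))
        accepted, new = mh_accept_beta(state, 2.0, tau, rng)
        assert accepted and new.beta == 2.0

    def test_beta_submove_leaves_graph_unchanged(self, rng):
        tau = make_tau(3, rng)
        adj = np.zeros((3, 3), dtype=np.int8)
        adj[0, 1] = 1
        state = MCMCState(adj, 2.0, 0.0, energy(adj, tau))
        _, new = mh_accept_beta(state, 2.7, tau, rng)
        np.testing.assert_array_equal(new.adjacency, adj)

    def test_prior_only_two_node_frequencies_match_enumeration(self):
        """With a flat data term the chain samples the Gibbs prior exactly:
        long-run graph frequencies over the 3-DAG space match enumeration."""
        beta = 1.3
        tau = make_tau(2, values=[[0.0, 0.8], [0.4, 0.0]])
        scorer = ConstantScorer(2)
        cfg = SamplerConfig(
            n_steps=60_000, thin=5, mode="bnggm", fixed_beta=beta, seed=17
        )
        trace = run_chain(np.zeros((5, 2)), cfg, tau=tau, scorer=scorer)
        # exact probabilities over {empty, 0->1, 1->0}
        graphs = [np.zeros((2, 2), dtype=int)]
        for i, k in [(0, 1), (1, 0)]:
            g = np.zeros((2, 2), dtype=int)
            g[i, k] = 1
            graphs.append(g)
        w = np.array([np.exp(-beta * energy(g, tau)) for g in graphs])
        w /= w.sum()
        counts = np.zeros(3)
        for adj in trace.adjacencies:
            for j, g in enumerate(graphs):
                if (adj == g).all():
                    counts[j] += 1
        freq = counts / counts.sum()
        assert np.abs(freq - w).max() < 0.02


class TestRunChain:
    def test_schedule_and_burn_in_marker(self, gauss3):
        trace = run_chain(gauss3, SamplerConfig(n_steps=1000, thin=10, seed=1))
        assert len(trace) == 100
        assert trace.burn_in_index == 50
        assert trace.steps[0] == 10 and trace.steps[-1] == 1000

    def test_same_seed_gives_identical_traces(self, gauss3):
        cfg = SamplerConfig(n_steps=500, thin=5, seed=9)
        a = run_chain(gauss3, cfg)
        b = run_chain(gauss3, cfg)
        np.testing.assert_array_equal(a.adjacencies, b.adjacencies)
        np.testing.assert_array_equal(a.log_scores, b.log_scores)

    def test_all_sampled_graphs_acyclic(self, gauss3):
        tau = make_tau(3, np.random.default_rng(2))
        trace = run_chain(
            gauss3, SamplerConfig(n_steps=2000, thin=10, mode="bnggm", seed=4), tau=tau
        )
        assert all(is_acyclic(adj) for adj in trace.adjacencies)

    def test_cached_score_and_energy_match_recomputation(self, gauss3):
        tau = make_tau(3, np.random.default_rng(5))
        trace = run_chain(
            gauss3, SamplerConfig(n_steps=1000, thin=50, mode="bnggm", seed=6), tau=tau
        )
        scorer = BGeScorer(gauss3)
        for s in range(len(trace)):
            assert trace.log_scores[s] == pytest.approx(
                scorer.graph_score(trace.adjacencies[s]), abs=1e-9
            )
            assert trace.energies[s] == pytest.approx(
                energy(trace.adjacencies[s], tau), abs=1e-9
            )

    def test_bnggm_with_beta_zero_reduces_to_bn(self, gauss3):
        tau = make_tau(3, np.random.default_rng(7))
        cfg_bn = SamplerConfig(n_steps=800, thin=8, mode="bn", seed=11)
        cfg_guided = SamplerConfig(
            n_steps=800, thin=8, mode="bnggm", fixed_beta=0.0, seed=11
        )
        a = run_chain(gauss3, cfg_bn)
        b = run_chain(gauss3, cfg_guided, tau=tau)
        np.testing.assert_array_equal(a.adjacencies, b.adjacencies)

    def test_bnggm_requires_tau(self, gauss3):
        with pytest.raises(ValueError, match="tau"):
            run_chain(gauss3, SamplerConfig(mode="bnggm"))

    def test_strong_prior_concentrates_on_minimum_energy_structure(self, chain3):
        """beta -> infinity limit: with tau equal to the true binarized
        structure and a large fixed beta, sampled graphs collapse onto it."""
        tau = chain3.adjacency.astype(float)
        scorer = ConstantScorer(3)
        cfg = SamplerConfig(n_steps=4000, thin=10, mode="bnggm", fixed_beta=30.0, seed=8)
        trace = run_chain(np.zeros((5, 3)), cfg, tau=tau, scorer=scorer)
        post = edge_posterior(trace)
        assert np.abs(post - tau).max() < 0.05

    def test_initial_dag_controls_the_starting_point(self, gauss3, chain3):
        # one step from the given initialization: the first recorded sample
        # differs from it by at most one edge operation
        trace = run_chain(
            gauss3,
            SamplerConfig(n_steps=1, thin=1, seed=0),
            initial_dag=chain3,
        )
        assert np.abs(trace.adjacencies[0] - chain3.adjacency).sum() <= 2

    def test_trace_roundtrip_and_summary(self, gauss3, tmp_path):
        from bnggm import ChainTrace

        trace = run_chain(gauss3, SamplerConfig(n_steps=200, thin=10, seed=2))
        path = tmp_path / "trace.npz"
        trace.save(path)
        back = ChainTrace.load(path)
        np.testing.assert_array_equal(back.adjacencies, trace.adjacencies)
        assert back.config.n_steps == 200
        df = back.to_dataframe()
        assert list(df.columns) == ["step", "beta", "log_score", "energy", "n_edges"]
        assert len(df) == 20
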