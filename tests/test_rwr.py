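"""Restart walk on the integrated network: seeding, convergence, ranking."""

import numpy as np
import pytest
import scipy.sparse as sp

from inpadr.network import LabelIndex, assemble
from inpadr.rwr import (
    RankResult,
    SeedSpec,
    initial_probability,
    rank_adr,
    rank_candidates,
    top_k,
    walk,
)
from inpadr.transition import build_transition

from conftest import dense_stable, make_random_net


class TestInitialProbability:
    def test_two_seeds_eta_half(self, tiny_net):
        spec = SeedSpec("a1", frozenset({"p1", "p2"}), eta=0.5)
        p0 = initial_probability(spec, tiny_net)
        assert p0[:2].tolist() == [0.25, 0.25]
        assert p0[2] == 0.5
        assert p0.sum() == pytest.approx(1.0)

    def test_eta_one_all_mass_on_adr(self, tiny_net):
        spec = SeedSpec("a1", frozenset({"p1"}), eta=1.0)
        p0 = initial_probability(spec, tiny_net)
        assert p0[2] == 1.0 and p0[:2].sum() == 0.0

    def test_no_seed_proteins_reassigns_to_adr_with_warning(self, tiny_net):
        spec = SeedSpec("a1", frozenset(), eta=0.5)
        with pytest.warns(UserWarning, match="no seed proteins"):
            p0 = initial_probability(spec, tiny_net)
        assert p0[2] == 1.0

    def test_unknown_focus_adr_rejected(self, tiny_net):
        with pytest.raises(ValueError, match="unknown focus ADR"):
            initial_probability(SeedSpec("nope", frozenset({"p1"})), tiny_net)


class TestWalk:
    def test_restart_one_returns_p0(self, tiny_net):
        model = build_transition(tiny_net, 0.5)
        p0 = np.array([0.5, 0.0, 0.5])
        res = walk(model, p0, r=1.0)
        assert res.converged and np.array_equal(res.p, p0)

    def test_fixed_point_residual(self, tiny_net):
        model = build_transition(tiny_net, 0.5)
        p0 = np.array([0.25, 0.25, 0.5])
        tol = 1e-10
        res = walk(model, p0, r=0.7, tol=tol)
        MT = model.M.T.toarray()
        resid = np.abs((1 - 0.7) * MT @ res.p + 0.7 * p0 - res.p).sum()
        assert res.converged and resid < 10 * tol

    def test_matches_dense_linear_solve(self):
        """30-node random network: iterate == closed-form solve to 1e-8."""
        rng = np.random.default_rng(17)
        net = make_random_net(rng, 20, 10, density=0.25)
        model = build_transition(net, 0.5)
        p0 = np.zeros(30)
        p0[[0, 1, 25]] = [0.25, 0.25, 0.5]
        res = walk(model, p0, r=0.7, tol=1e-14)
        expected = dense_stable(model, p0, 0.7)
        assert np.abs(res.p - expected).max() < 1e-8

    @pytest.mark.parametrize("t", [1, 2, 5, 20])
    def test_mass_conserved_every_iteration_with_isolated_nodes(self, t):
        rng = np.random.default_rng(23)
        net = make_random_net(rng, 10, 5, density=0.3, isolated=2)
        model = build_transition(net, 0.5)
        p0 = np.zeros(15)
        p0[[2, 10]] = 0.5
        with pytest.warns(UserWarning, match="did not converge"):
            res = walk(model, p0, r=0.7, tol=1e-300, max_iter=t)
        assert res.p.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.p.min() >= 0

    def test_seeded_isolated_protein_keeps_restart_mass(self):
        rng = np.random.default_rng(29)
        net = make_random_net(rng, 8, 4, density=0.4, isolated=1)
        model = build_transition(net, 0.5)
        p0 = np.zeros(12)
        p0[0] = 1.0  # the isolated protein
        res = walk(model, p0, r=0.7)
        assert res.p.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.p[0] > 0.7  # restart keeps it there

    def test_nonconvergence_warns_not_raises(self):
        rng = np.random.default_rng(37)
        net = make_random_net(rng, 12, 6, density=0.3)
        model = build_transition(net, 0.5)
        p0 = np.zeros(18)
        p0[[0, 15]] = 0.5
        with pytest.warns(UserWarning, match="did not converge"):
            res = walk(model, p0, r=0.1, tol=1e-300, max_iter=3)
        assert not res.converged

    def test_bad_p0_rejected(self, tiny_net):
        model = build_transition(tiny_net, 0.5)
        with pytest.raises(ValueError, match="sums to"):
            walk(model, np.array([0.5, 0.0, 0.0]))


def test_monotone_locality_on_chain():
    """Seeded at one chain end with lambda=0, eta=0: stable probability is
    non-increasing with distance from the seed."""
    n = 7
    A = sp.lil_matrix((n, n))
    for i in range(n - 1):
        A[i, i + 1] = A[i + 1, i] = 1.0
    B = sp.lil_matrix((n, 1))
    B[0, 0] = 1.0
    net = assemble(A.tocsr(), B.tocsr(), sp.csr_matrix((1, 1)),
                   LabelIndex([f"p{i}" for i in range(n)]), LabelIndex(["a1"]))
    result = rank_adr(net, "a1", seed_proteins={"p0"}, lam=0.0, eta=0.0,
                      exclude=frozenset())
    scores = [result.score_of(f"p{i}") for i in range(n)]
    assert all(s1 >= s2 - 1e-15 for s1, s2 in zip(scores, scores[1:]))


def test_walk_equivariant_under_network_automorphism():
    """On a layer-symmetric network (A == C, B symmetric), swapping the two
    layers and the eta-split (1-eta <-> eta) permutes the stable vector."""
    rng = np.random.default_rng(31)
    n = 6
    X = np.triu((rng.random((n, n)) < 0.5) * rng.uniform(0.2, 1, (n, n)), 1)
    X = X + X.T
    Bm = np.zeros((n, n))
    for i in range(n):  # symmetric bipartite cycle
        Bm[i, (i + 1) % n] = Bm[(i + 1) % n, i] = 1.0
    net = assemble(sp.csr_matrix(X), sp.csr_matrix(Bm), sp.csr_matrix(X),
                   LabelIndex([f"p{i}" for i in range(n)]),
                   LabelIndex([f"a{i}" for i in range(n)]))
    model = build_transition(net, 0.5)
    eta = 0.3
    p0 = np.zeros(2 * n)
    p0[[1, 2]] = (1 - eta) / 2   # protein seeds
    p0[n + 0] = eta              # ADR seed
    swapped = np.concatenate([p0[n:], p0[:n]])
    res = walk(model, p0, r=0.7, tol=1e-14)
    res_sw = walk(model, swapped, r=0.7, tol=1e-14)
    assert np.abs(res_sw.p - np.concatenate([res.p[n:], res.p[:n]])).max() < 1e-10


class TestRanking:
    def _result(self, scores, net, exclude):
        stable = np.concatenate([scores, np.zeros(net.n_adrs)])
        return rank_candidates(stable, net, "a1", exclude=exclude)

    @pytest.fixture()
    def net3(self):
        A = sp.csr_matrix(np.ones((3, 3)) - np.eye(3))
        B = sp.csr_matrix(np.array([[1.0], [0.0], [0.0]]))
        return assemble(A * 0.5, B, sp.csr_matrix((1, 1)),
                        LabelIndex(["p1", "p2", "p3"]), LabelIndex(["a1"]))

    def test_exclusion_and_order(self, net3):
        res = self._result(np.array([0.3, 0.2, 0.1]), net3, {"p1"})
        assert res.proteins == ("p2", "p3")
        assert res.rank_of("p2") == 1 and res.rank_of("p3") == 2

    def test_ties_get_average_rank(self, net3):
        res = self._result(np.array([0.3, 0.2, 0.2]), net3, {"p1"})
        assert res.rank_of("p2") == res.rank_of("p3") == 1.5

    def test_exclude_all_warns_empty(self, net3):
        with pytest.warns(UserWarning, match="no candidate"):
            res = self._result(np.array([0.3, 0.2, 0.1]), net3,
                               {"p1", "p2", "p3"})
        assert len(res) == 0

    def test_top_k_truncation(self, net3):
        res = self._result(np.array([0.3, 0.2, 0.1]), net3, {"p1"})
        assert top_k(res, 50) == ["p2", "p3"]
        assert top_k(res, 1) == ["p2"]
        with pytest.raises(ValueError):
            top_k(res, 0)

    def test_default_exclude_is_known_proteins(self, net3):
        res = self._result(np.array([0.3, 0.2, 0.1]), net3, None)
        assert "p1" not in res.proteins  # p1 is the known protein of a1


def test_rank_adr_deterministic(planted_net):
    adr = planted_net.adr_index[0]
    r1 = rank_adr(planted_net, adr)
    r2 = rank_adr(planted_net, adr)
    assert r1.proteins == r2.proteins
    assert np.array_equal(r1.scores, r2.scores)
    assert np.array_equal(r1.ranks, r2.ranks)
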