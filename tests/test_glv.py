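"""gLV simulation, candidate inference, consensus and network algebra."""

import warnings

import networkx as nx
import numpy as np
import pytest

import tsen
from tsen.glv import GLVDivergenceError

from conftest import make_stable_model


class TestSimulate:
    def test_logistic_carrying_capacity(self):
        model = tsen.GLVModel(["x"], [1.0], [[-1.0]])
        ts = tsen.simulate_glv(model, [0.01], [0.0, 20.0])
        assert ts.values[0, -1] == pytest.approx(1.0, abs=1e-6)

    def test_interior_fixed_point_is_constant(self):
        model, x_star = make_stable_model(4, seed=3)
        np.testing.assert_allclose(model.fixed_point(), x_star, atol=1e-10)
        ts = tsen.simulate_glv(model, x_star, np.linspace(0, 5, 11))
        np.testing.assert_allclose(
            ts.values, np.broadcast_to(x_star[:, None], ts.values.shape),
            rtol=1e-6,
        )

    def test_against_rk4_reference_oracle(self):
        # 3-species competitive community vs a hand-stepped RK4 integrator
        r = np.array([1.0, 0.8, 1.2])
        A = np.array([[-1.0, -0.3, -0.2],
                      [-0.2, -1.0, -0.3],
                      [-0.3, -0.2, -1.0]])
        model = tsen.GLVModel(list("abc"), r, A)
        x0 = np.array([0.2, 0.3, 0.1])
        times = np.linspace(0, 10, 21)

        def rhs(x):
            return x * (r + A @ x)

        x = x0.copy()
        ref = [x0.copy()]
        h = 1e-4
        t = 0.0
        for t_next in times[1:]:
            while t < t_next - 1e-12:
                step = min(h, t_next - t)
                k1 = rhs(x)
                k2 = rhs(x + step / 2 * k1)
                k3 = rhs(x + step / 2 * k2)
                k4 = rhs(x + step * k3)
                x = x + step / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                t += step
            ref.append(x.copy())
        ts = tsen.simulate_glv(model, x0, times)
        assert np.max(np.abs(ts.values - np.array(ref).T)) < 1e-4

    def test_divergence_raises(self):
        model = tsen.GLVModel(["x"], [1.0], [[1.0]])  # positive feedback
        with pytest.raises(GLVDivergenceError):
            tsen.simulate_glv(model, [1.0], [0.0, 100.0], overflow=1e6)


def _recovery_study(seed: int, n_genera: int = 6, n_timepoints: int = 24):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        design = tsen.StudyDesign(n_sites=3, n_timepoints=n_timepoints, seed=seed)
        return tsen.generate_study(
            design, n_genera=n_genera, rb_target=0.0, core_fraction=1.0,
            noise_sd=0.0, seed=seed, x0_jitter=1.0, n_internal_steps=48,
        )


def strong_edge_mask(A_true: np.ndarray) -> np.ndarray:
    """Off-diagonal entries above the weakest-tertile |a_ij| cutoff."""
    off = ~np.eye(A_true.shape[0], dtype=bool)
    mags = np.abs(A_true[off])
    cut = np.quantile(mags[mags > 0], 1 / 3)
    return (np.abs(A_true) >= cut) & off & (A_true != 0)


class TestInferCandidates:
    def test_sign_recovery_noise_free(self):
        study = _recovery_study(seed=1)
        series = [study.observed_series[s] for s in study.design.site_labels]
        cands = tsen.infer_candidates(series, n_candidates=40, seed=1)
        best = min(cands, key=lambda c: c.bcd_score)
        strong = strong_edge_mask(study.truth_model.A)
        acc = np.mean(
            np.sign(best.A[strong]) == np.sign(study.truth_model.A[strong])
        )
        assert acc >= 0.8

    def test_constant_series_gives_null_interactions(self):
        ts = tsen.TimeSeries(["a", "b"], [0.0, 1.0, 2.0, 3.0],
                             np.tile([[0.4], [0.6]], (1, 4)))
        cands = tsen.infer_candidates(ts, n_candidates=5, seed=0)
        for c in cands:
            assert np.abs(c.A).max() < 1e-6
            assert np.abs(c.model.r).max() < 1e-6

    def test_deterministic_given_seed(self):
        study = _recovery_study(seed=2, n_timepoints=8)
        ts = study.observed_series["A"]
        a = tsen.infer_candidates(ts, n_candidates=12, seed=99)
        b = tsen.infer_candidates(ts, n_candidates=12, seed=99)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.A, cb.A)
            assert ca.bcd_score == cb.bcd_score

    def test_too_few_time_points_rejected(self):
        ts = tsen.TimeSeries(["a"], [0.0, 1.0], [[1.0, 2.0]])
        with pytest.raises(ValueError):
            tsen.infer_candidates(ts, n_candidates=2)

    def test_all_zero_taxon_dropped_with_warning(self):
        values = np.array([[1.0, 2.0, 3.0, 4.0], [0.0, 0.0, 0.0, 0.0]])
        ts = tsen.TimeSeries(["a", "zero"], [0, 1, 2, 3], values)
        with pytest.warns(UserWarning, match="zero"):
            cands = tsen.infer_candidates(ts, n_candidates=2, seed=0)
        assert cands[0].model.taxa == ["a"]


class TestScoreCandidate:
    def test_generating_model_scores_zero(self):
        model, x_star = make_stable_model(4, seed=5)
        x0 = x_star * 1.2
        ts = tsen.simulate_glv(model, x0, np.linspace(0, 3, 7))
        cand = tsen.CandidateNetwork(model)
        assert tsen.score_candidate(ts, cand) < 1e-6

    def test_frozen_candidate_matches_hand_bcd(self):
        values = np.array([[1.0, 2.0], [3.0, 2.0]])
        ts = tsen.TimeSeries(["a", "b"], [0.0, 1.0], values)
        zero = tsen.CandidateNetwork(
            tsen.GLVModel(["a", "b"], [0.0, 0.0], np.zeros((2, 2)))
        )
        # regenerated profile stays at t1: rel (0.25, 0.75) vs observed (0.5, 0.5)
        expected = (abs(0.5 - 0.25) + abs(0.5 - 0.75)) / 2.0
        assert tsen.score_candidate(ts, zero) == pytest.approx(expected)

    def test_score_in_unit_interval_and_noise_monotone(self, rng):
        model, x_star = make_stable_model(5, seed=8)
        ts = tsen.simulate_glv(model, x_star * 1.3, np.linspace(0, 3, 9))
        prev = tsen.score_candidate(ts, tsen.CandidateNetwork(model))
        for sigma in (0.05, 0.5, 5.0):
            noisy = tsen.GLVModel(
                model.taxa, model.r,
                model.A * (1 + sigma * np.random.default_rng(0).normal(
                    size=model.A.shape)),
            )
            s = tsen.score_candidate(ts, tsen.CandidateNetwork(noisy))
            assert 0.0 <= s <= 1.0
            assert s >= prev - 1e-12
            prev = s


def _candidate_from_A(A, score):
    n = A.shape[0]
    taxa = [f"t{i}" for i in range(n)]
    return tsen.CandidateNetwork(tsen.GLVModel(taxa, np.zeros(n), A),
                                 bcd_score=score)


class TestConsensus:
    def test_unanimous_candidates(self):
        A = np.array([[0.0, 1.5], [-2.0, 0.0]])
        cands = [_candidate_from_A(A, 0.1) for _ in range(6)]
        net = tsen.consensus_network(cands, top_k=6, agreement=0.5)
        # a_01 = +1.5 is the effect of t1 on t0 -> edge t1 -> t0
        assert net.graph.edges[("t1", "t0")]["weight"] == pytest.approx(1.5)
        assert net.graph.edges[("t0", "t1")]["weight"] == pytest.approx(-2.0)
        assert net.n_edges == 2

    def test_split_vote_below_agreement_drops_edge(self):
        pos = np.array([[0.0, 1.0], [0.0, 0.0]])
        neg = np.array([[0.0, -1.0], [0.0, 0.0]])
        cands = [_candidate_from_A(pos, 0.1)] * 5 + [_candidate_from_A(neg, 0.1)] * 5
        net = tsen.consensus_network(cands, top_k=10, agreement=0.6)
        assert net.n_edges == 0

    def test_planted_agreement_matches_counting_oracle(self, rng):
        # 10 candidates, 4 taxa; plant 5 edges agreed by exactly 7/10
        n = 4
        planted = [(0, 1, 1.0), (1, 2, -1.0), (2, 3, 1.0), (3, 0, -1.0),
                   (0, 2, 1.0)]
        cands = []
        for k in range(10):
            A = np.zeros((n, n))
            for i, j, s in planted:
                if k < 7:
                    A[i, j] = s * rng.uniform(0.5, 1.5)
                else:
                    A[i, j] = -s * rng.uniform(0.5, 1.5)
            cands.append(_candidate_from_A(A, 0.1))
        net = tsen.consensus_network(cands, top_k=10, agreement=0.6)
        # oracle: count sign agreement explicitly over the candidate stack
        stack = np.stack([c.A for c in cands])
        expected_edges = set()
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if (np.mean(stack[:, i, j] > 0) >= 0.6
                        or np.mean(stack[:, i, j] < 0) >= 0.6):
                    expected_edges.add((f"t{j}", f"t{i}"))
        assert set(net.graph.edges) == expected_edges
        assert net.n_edges == 5

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            tsen.consensus_network([], top_k=0)


def _net_from_weights(weights: dict, kind="consensus") -> tsen.InteractionNetwork:
    g = nx.DiGraph()
    for (u, v), w in weights.items():
        g.add_edge(u, v, weight=w, sign=int(np.sign(w)))
    return tsen.InteractionNetwork(g, kind=kind, rank="family")


class TestSignSplitAndGlobal:
    def test_split_counts(self):
        net = _net_from_weights({("a", "b"): 2.0, ("b", "c"): -1.0,
                                 ("c", "a"): 0.5})
        pos, neg = tsen.split_by_sign(net)
        assert pos.n_edges == 2 and neg.n_edges == 1

    def test_all_positive_gives_empty_negative(self):
        net = _net_from_weights({("a", "b"): 1.0, ("b", "a"): 3.0})
        _, neg = tsen.split_by_sign(net)
        assert neg.n_edges == 0

    def test_partition_is_exhaustive_and_conservative(self, rng):
        weights = {
            (f"n{i}", f"n{j}"): float(rng.normal())
            for i in range(8) for j in range(8) if i != j
        }
        net = _net_from_weights(weights)
        pos, neg = tsen.split_by_sign(net)
        assert pos.n_edges + neg.n_edges == net.n_edges
        union = set(pos.graph.edges) | set(neg.graph.edges)
        assert union == set(net.graph.edges)
        assert not (set(pos.graph.edges) & set(neg.graph.edges))
        for u, v in net.graph.edges:
            src = pos if net.graph.edges[u, v]["weight"] > 0 else neg
            assert src.graph.edges[u, v]["weight"] == net.graph.edges[u, v]["weight"]

    def test_global_disjoint_union(self):
        n1 = _net_from_weights({("a", "b"): 1.0})
        n2 = _net_from_weights({("c", "d"): -1.0})
        g = tsen.global_network([n1, n2])
        assert g.n_nodes == 4 and g.n_edges == 2
        assert g.kind == "global"

    def test_global_merges_to_mean(self):
        n1 = _net_from_weights({("a", "b"): 1.0})
        n2 = _net_from_weights({("a", "b"): 3.0})
        g = tsen.global_network([n1, n2])
        assert g.graph.edges[("a", "b")]["weight"] == pytest.approx(2.0)

    def test_global_zero_mean_edge_dropped(self):
        n1 = _net_from_weights({("a", "b"): 1.0})
        n2 = _net_from_weights({("a", "b"): -1.0})
        with pytest.warns(UserWarning, match="sign-indeterminate"):
            g = tsen.global_network([n1, n2])
        assert g.n_edges == 0

    def test_global_rank_mismatch_rejected(self):
        n1 = _net_from_weights({("a", "b"): 1.0})
        n2 = tsen.InteractionNetwork(n1.graph.copy(), rank="order")
        with pytest.raises(ValueError):
            tsen.global_network([n1, n2])


class TestInteractionFractions:
    def test_all_negative(self):
        net = _net_from_weights({("a", "b"): -1.0, ("b", "a"): -2.0})
        assert tsen.interaction_fractions(net) == (0.0, 1.0)

    def test_three_to_one(self):
        net = _net_from_weights({("a", "b"): 1.0, ("b", "c"): 1.0,
                                 ("c", "a"): 1.0, ("a", "c"): -1.0})
        assert tsen.interaction_fractions(net) == (0.75, 0.25)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tsen.interaction_fractions(_net_from_weights({}))

    def test_mean_over_networks(self):
        nets = [
            _net_from_weights({("a", "b"): 1.0, ("b", "a"): -1.0}),
            _net_from_weights({("a", "b"): 1.0, ("b", "c"): 1.0,
                               ("c", "a"): 1.0, ("a", "c"): -1.0}),
        ]
        mp, sp, mn, sn = tsen.mean_interaction_fractions(nets)
        assert mp == pytest.approx((0.5 + 0.75) / 2)
        assert mp + mn == pytest.approx(1.0)


class TestSaveCandidates:
    def test_writes_edge_lists_and_scores(self, tmp_path):
        A = np.array([[0.0, 1.5], [-2.0, 0.0]])
        cands = [_candidate_from_A(A, 0.1), _candidate_from_A(-A, 0.3)]
        tsen.save_candidates(cands, tmp_path)
        assert (tmp_path / "candidate_0000.tsv").exists()
        assert (tmp_path / "candidate_0001.tsv").exists()
        scores = (tmp_path / "scores.tsv").read_text()
        assert "0.1" in scores and "0.3" in scores
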