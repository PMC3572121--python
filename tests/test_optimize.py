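import networkx as nx
import numpy as np
import pandas as pd
import pytest

from emailnet import builders, ingest, optimize
from emailnet.network import TieNetwork
from emailnet.synthetic import SyntheticConfig, generate_population


def _net(edges, nodes=None, directed=False):
    g = nx.DiGraph() if directed else nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return TieNetwork(g, method="toy")


class TestAdjacencyCorrelation:
    def test_identical_networks_correlate_perfectly(self):
        net = _net([("a", "b"), ("c", "d")], nodes="abcd")
        assert optimize.adjacency_correlation(net, net, set("abcd")) == pytest.approx(1.0)

    def test_complement_networks_correlate_minus_one(self):
        nodes = list("abcd")
        a = _net([("a", "b"), ("c", "d")], nodes)
        comp_edges = [
            (u, v)
            for i, u in enumerate(nodes)
            for v in nodes[i + 1:]
            if not a.graph.has_edge(u, v)
        ]
        b = _net(comp_edges, nodes)
        # tie vectors are exact complements over the 6 pairs -> r = -1
        assert optimize.adjacency_correlation(a, b, set(nodes)) == pytest.approx(-1.0)

    def test_independent_networks_correlate_near_zero(self):
        rs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            nodes = [f"n{i}" for i in range(500)]
            def rand_net(r):
                g = nx.gnp_random_graph(500, 0.01, seed=r)
                g = nx.relabel_nodes(g, dict(enumerate(nodes)))
                return TieNetwork(g, method="rand")
            a, b = rand_net(int(rng.integers(1e6))), rand_net(int(rng.integers(1e6)))
            rs.append(optimize.adjacency_correlation(a, b, set(nodes)))
        assert abs(np.mean(rs)) < 0.05

    def test_zero_variance_rejected(self):
        empty = _net([], nodes="abcd")
        other = _net([("a", "b")], nodes="abcd")
        with pytest.raises(ValueError, match="variance"):
            optimize.adjacency_correlation(empty, other, set("abcd"))

    def test_directed_networks_symmetrized_by_union(self):
        d = _net([("a", "b")], nodes="abc", directed=True)
        u = _net([("a", "b")], nodes="abc")
        assert optimize.adjacency_correlation(d, u, set("abc")) == pytest.approx(1.0)


class TestConfusionCounts:
    def test_toy_enumeration(self):
        nodes = list("abcde")
        survey = _net([("a", "b"), ("b", "c"), ("d", "e")], nodes)
        email = _net([("a", "b"), ("d", "e"), ("a", "c")], nodes)
        tp, fp, fn, tn = optimize.confusion_counts(email, survey, set(nodes))
        assert (tp, fp, fn, tn) == (2, 1, 1, 6)

    def test_identical_networks_have_full_recovery(self):
        nodes = list("abcd")
        net = _net([("a", "b"), ("c", "d")], nodes)
        tp, fp, fn, tn = optimize.confusion_counts(net, net, set(nodes))
        assert fp == 0 and fn == 0 and tp == 2

    def test_empty_email_network(self):
        nodes = list("abcd")
        survey = _net([("a", "b")], nodes)
        email = _net([], nodes)
        tp, fp, fn, tn = optimize.confusion_counts(email, survey, set(nodes))
        assert (tp, fp) == (0, 0)
        assert tn == 5 and fn == 1

    def test_fp_rate_and_ratio_identity(self, small_pairs, small_survey_net, small_pop):
        node_set = (set(small_pairs["sender_id"]) | set(small_pairs["recipient_id"])) & set(
            small_survey_net.nodes
        )
        d = optimize.network_diagnostics(
            builders.single_recipient_network(small_pairs, 1.0, 22),
            small_survey_net,
            node_set,
        )
        if d["tp"]:
            lhs = d["fp_rate"]
            rhs = d["fp_tp_ratio"] * d["tp"] / (d["fp"] + d["tn"])
            assert lhs == pytest.approx(rhs)


class TestSweep:
    def test_single_value_grid_is_best(self, small_pairs, small_survey_net):
        node_set = (set(small_pairs["sender_id"]) | set(small_pairs["recipient_id"])) & set(
            small_survey_net.nodes
        )
        res = optimize.sweep(
            lambda t: builders.single_recipient_network(small_pairs, t, 22),
            [1.0], small_survey_net, node_set, method="single_recipient",
        )
        assert res.best_threshold == 1.0

    def test_diagnostics_conserve_survey_ties(self, small_pairs, small_survey_net):
        node_set = (set(small_pairs["sender_id"]) | set(small_pairs["recipient_id"])) & set(
            small_survey_net.nodes
        )
        res = optimize.sweep(
            lambda t: builders.single_recipient_network(small_pairs, t, 22),
            optimize.default_single_recipient_grid(10),
            small_survey_net, node_set, method="single_recipient",
        )
        t = res.table
        assert np.isfinite(t["correlation"]).any()
        assert (t["tp"] + t["fn"]).nunique() == 1  # TP+FN = survey tie count
        assert t["recovery"].between(0, 1).all()
        assert t["density"].between(0, 1).all()

    def test_best_threshold_separates_tied_from_base_rate(self):
        cfg = SyntheticConfig(
            n_people=150, tied_email_rate_per_week=3.0, base_email_rate_per_week=0.05,
            target_tie_density=0.03, response_rate=1.0, seed=42,
        )
        pop = generate_population(cfg)
        pairs = ingest.aggregate_pairs(pop.email_log)
        survey_net = builders.build_survey_network(pop.survey)
        node_set = (set(pairs["sender_id"]) | set(pairs["recipient_id"])) & set(survey_net.nodes)
        res = optimize.sweep(
            lambda t: builders.single_recipient_network(pairs, t, cfg.n_weeks),
            optimize.default_single_recipient_grid(40),
            survey_net, node_set, method="single_recipient",
        )
        # tied pairs exchange ~6/wk total, untied ~0.1/wk: the optimum sits between
        assert 0.1 < res.best_threshold < 6.0

    def test_empty_grid_rejected(self, small_survey_net):
        with pytest.raises(ValueError, match="empty"):
            optimize.sweep(lambda t: small_survey_net, [], small_survey_net,
                           set(list(small_survey_net.nodes)), method="x")


class TestRespondentsOnly:
    def test_full_response_equals_all_individuals(self):
        cfg = SyntheticConfig(n_people=150, response_rate=1.0, target_tie_density=0.03,
                              seed=13)
        pop = generate_population(cfg)
        pairs = ingest.aggregate_pairs(
            ingest.filter_internal(pop.email_log, pop.survey.people)
        )
        survey_net = builders.build_survey_network(pop.survey)
        email_nodes = set(pairs["sender_id"]) | set(pairs["recipient_id"])
        node_set = email_nodes & set(survey_net.nodes)
        grid = optimize.default_single_recipient_grid(8)
        fn = {"single_recipient": lambda t: builders.single_recipient_network(pairs, t, cfg.n_weeks)}
        all_ind = optimize.sweep(fn["single_recipient"], grid, survey_net, node_set,
                                 method="single_recipient")
        resp = optimize.respondents_only_view(
            fn, {"single_recipient": grid}, survey_net, pop.survey.respondents, email_nodes
        )["single_recipient"]
        # respondents = everyone in the survey -> identical node set, identical sweep
        pd.testing.assert_frame_equal(all_ind.table, resp.table)

    def test_empty_respondent_set_rejected(self, small_survey_net):
        with pytest.raises(ValueError, match="no respondents"):
            optimize.respondents_only_view({}, {}, small_survey_net, set(), {"zzz"})


class TestStabilityCurve:
    def test_identical_weeks_are_perfectly_stable(self):
        # same 3 heavy pairs every week for 6 weeks
        t0 = pd.Timestamp("2011-01-03")
        rows = []
        for week in range(6):
            for s, r in [("a", "b"), ("c", "d"), ("e", "f")]:
                for k in range(5):
                    rows.append((s, r, t0 + pd.Timedelta(days=7 * week + k), 1, 10))
        log = pd.DataFrame(rows, columns=["sender_id", "recipient_id", "timestamp",
                                          "n_recipients", "file_size"])
        curve = optimize.stability_curve(
            log, lambda p, w: builders.single_recipient_network(p, 0.5, w)
        )
        assert len(curve) == 5
        assert np.allclose(curve["correlation"], 1.0)

    def test_stationary_log_converges_toward_one(self, small_pop):
        curve = optimize.stability_curve(
            small_pop.email_log,
            lambda p, w: builders.single_recipient_network(p, 2.0, w),
        )
        assert len(curve) == small_pop.config.n_weeks - 1
        assert curve["correlation"].iloc[-1] > curve["correlation"].iloc[0]
        assert curve["correlation"].iloc[-1] > 0.95

    def test_too_short_log_rejected(self):
        t0 = pd.Timestamp("2011-01-03")
        log = pd.DataFrame(
            {"sender_id": ["a"], "recipient_id": ["b"], "timestamp": [t0],
             "n_recipients": [1], "file_size": [1]}
        )
        with pytest.raises(ValueError, match="2 weeks"):
            optimize.stability_curve(log, lambda p, w: None)
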