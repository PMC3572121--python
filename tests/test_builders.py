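import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import irls_logit
from emailnet import builders
from emailnet.ingest import SurveyTable


def logit_fixture(rng, n=200) -> pd.DataFrame:
    """Well-conditioned feature rows with labels from a known logistic model."""
    ft = pd.DataFrame(
        {
            "sender_id": "S",
            "recipient_id": "R",
            "z_sent_single": rng.normal(size=n),
            "log_single": np.log1p(rng.poisson(5, size=n).astype(float)),
            "asym_single": rng.random(n),
            "shared_contacts": rng.poisson(2, size=n).astype(float),
        }
    )
    eta = (-1.0 + 0.8 * ft["z_sent_single"] + 0.5 * ft["log_single"]
           - 0.7 * ft["asym_single"] + 0.2 * ft["shared_contacts"])
    ft["tie_label"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return ft


class TestSurveyNetwork:
    def test_duplicate_and_reciprocal_namings_collapse(self):
        sv = SurveyTable(pd.DataFrame(
            {"respondent_id": ["r1", "r1", "a1"], "named_id": ["a1", "a1", "r1"]}
        ))
        net = builders.build_survey_network(sv)
        assert net.ties() == {("a1", "r1")}
        assert not net.directed

    def test_named_nonrespondents_are_nodes(self):
        sv = SurveyTable(pd.DataFrame(
            {"respondent_id": ["r1"], "named_id": ["silent"]}
        ))
        net = builders.build_survey_network(sv)
        assert "silent" in net.nodes


class TestSingleRecipientNetwork:
    def test_strict_threshold_arithmetic(self):
        pairs = pd.DataFrame(
            {
                "sender_id": ["A", "B", "C"],
                "recipient_id": ["B", "A", "D"],
                "n_single": [30, 15, 44],
                "n_multi": [0, 0, 0],
                "size_sum": [1, 1, 1],
            }
        )
        # A-B: 45/22 ~ 2.05 > 2 -> tie; C-D: 44/22 = 2.0 exactly -> no tie
        net = builders.single_recipient_network(pairs, 2.0, 22)
        assert net.ties() == {("A", "B")}

    def test_multi_recipient_email_never_counts(self):
        pairs = pd.DataFrame(
            {
                "sender_id": ["A"], "recipient_id": ["B"],
                "n_single": [0], "n_multi": [500], "size_sum": [1],
            }
        )
        net = builders.single_recipient_network(pairs, 0.5, 22)
        assert net.n_ties == 0
        assert {"A", "B"} <= net.nodes

    def test_tie_set_shrinks_as_threshold_rises(self, small_pairs):
        previous = None
        for thr in [0.25, 0.5, 1.0, 2.0, 5.0]:
            ties = builders.single_recipient_network(small_pairs, thr, 22).ties()
            if previous is not None:
                assert ties <= previous
            previous = ties


class TestAsymmetryIndex:
    @pytest.mark.parametrize(
        "a,b,expect", [(5, 5, 0.0), (10, 0, 1.0), (0, 10, 1.0), (6, 2, 0.5)]
    )
    def test_known_values(self, a, b, expect):
        assert builders.asymmetry_index(a, b) == pytest.approx(expect)

    @given(st.integers(0, 10**6), st.integers(0, 10**6))
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        if a + b == 0:
            with pytest.raises(ValueError):
                builders.asymmetry_index(a, b)
            return
        v = builders.asymmetry_index(a, b)
        assert v == pytest.approx(builders.asymmetry_index(b, a))
        assert 0.0 <= v <= 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero email"):
            builders.asymmetry_index(0, 0)


class TestSenderZscores:
    def _pairs(self, counts):
        return pd.DataFrame(
            {
                "sender_id": ["S"] * len(counts),
                "recipient_id": [f"R{i}" for i in range(len(counts))],
                "n_single": counts,
                "n_multi": [0] * len(counts),
                "size_sum": [1] * len(counts),
            }
        )

    def test_equal_counts_give_zero(self):
        z = builders.sender_zscores(self._pairs([3, 3, 3]), "single")
        assert z == {}  # zero variance -> z omitted (treated as 0 downstream)

    def test_two_partner_zscores_use_sample_sd(self):
        e = np.e
        z = builders.sender_zscores(self._pairs([round(e), round(e**3)]), "single")
        # logs ~ (1, 3): mean 2, sample sd sqrt(2) -> z = -+1/sqrt(2)
        got = sorted(z.values())
        assert got == pytest.approx([-1 / np.sqrt(2), 1 / np.sqrt(2)], rel=1e-2)

    def test_single_partner_degenerate(self):
        assert builders.sender_zscores(self._pairs([7]), "single") == {}

    def test_zero_count_partners_excluded(self):
        z = builders.sender_zscores(self._pairs([0, 2, 8]), "single")
        assert ("S", "R0") not in z
        assert len(z) == 2


class TestSharedAndSecondary:
    def test_shared_contacts_intersection(self):
        pairs = pd.DataFrame(
            {
                "sender_id": ["A", "A", "A", "B", "B", "B"],
                "recipient_id": ["c1", "c2", "B", "c2", "c3", "A"],
                "n_single": [1] * 6,
                "n_multi": [0] * 6,
                "size_sum": [1] * 6,
            }
        )
        assert builders.shared_contacts(("A", "B"), pairs) == 1  # only c2
        assert builders.shared_contacts(("A", "c3"), pairs) == 0

    def test_secondary_ties_counts_multi_shared_partners(self):
        # sender S shares 2 contacts with j1, 1 with j2
        rows = [("S", c) for c in ["x", "y", "z"]] + [("j1", "x"), ("j1", "y"),
                                                      ("j2", "z")]
        pairs = pd.DataFrame(
            {
                "sender_id": [r[0] for r in rows],
                "recipient_id": [r[1] for r in rows],
                "n_single": [1] * len(rows),
                "n_multi": [0] * len(rows),
                "size_sum": [1] * len(rows),
            }
        )
        assert builders.secondary_ties("S", pairs) == 1

    def test_clique_of_mutual_emailers(self):
        # 4 people all emailing each other: each shares 2 contacts with each
        # of the 3 others
        people = list("ABCD")
        rows = [(a, b) for a in people for b in people if a != b]
        pairs = pd.DataFrame(
            {
                "sender_id": [r[0] for r in rows],
                "recipient_id": [r[1] for r in rows],
                "n_single": [1] * len(rows),
                "n_multi": [0] * len(rows),
                "size_sum": [1] * len(rows),
            }
        )
        for p in people:
            assert builders.secondary_ties(p, pairs) == 3


class TestFeatureTable:
    def test_row_count_matches_brute_force(self, small_pairs, small_survey_net,
                                           small_features):
        # brute force: unordered pairs with any email, two rows each
        seen = set()
        for r in small_pairs.itertuples(index=False):
            if r.n_single + r.n_multi > 0:
                seen.add(tuple(sorted((r.sender_id, r.recipient_id))))
        assert len(small_features) == 2 * len(seen)

    def test_zero_channel_gets_dummy_and_zero_log(self, toy_pairs, small_survey_net):
        from emailnet.network import TieNetwork
        import networkx as nx

        survey = TieNetwork(nx.Graph([("A", "B")]), method="name_generator")
        ft = builders.build_feature_table(toy_pairs, survey).set_index(
            ["sender_id", "recipient_id"]
        )
        row = ft.loc[("B", "C")]  # B-C pair: multi only
        assert row["dummy_single_zero"] == 1
        assert row["log_single"] == 0.0
        assert row["dummy_multi_zero"] == 0
        assert row["log_multi"] == pytest.approx(np.log(3))
        assert row["asym_single"] == 0.0
        # tie labels symmetric and from the survey
        assert ft.loc[("A", "B"), "tie_label"] == 1
        assert ft.loc[("B", "A"), "tie_label"] == 1
        assert ft.loc[("B", "C"), "tie_label"] == 0

    def test_dummy_rows_have_zeroed_transforms(self, small_features):
        f = small_features
        # dummy=1 marks a zero raw count; its log stand-in is 0 (log(1)=0 rows
        # legitimately also sit at 0 with dummy=0)
        assert (f.loc[f["dummy_single_zero"] == 1, "log_single"] == 0).all()
        assert (f.loc[f["dummy_multi_zero"] == 1, "log_multi"] == 0).all()
        assert (f.loc[f["dummy_single_zero"] == 1, "asym_single"] == 0).all()
        assert f["asym_single"].between(0, 1).all()
        assert f["asym_multi"].between(0, 1).all()


class TestTieLogit:
    def test_null_model_recovers_base_rate(self, rng):
        n = 4000
        ft = pd.DataFrame(
            {
                "sender_id": "S",
                "recipient_id": "R",
                "z_sent_single": rng.normal(size=n),
                "shared_contacts": rng.poisson(2, size=n),
                "tie_label": rng.random(n) < 0.2,
            }
        )
        ft["tie_label"] = ft["tie_label"].astype(int)
        model = builders.fit_tie_logit(ft, features=["z_sent_single", "shared_contacts"])
        base = ft["tie_label"].mean()
        assert model.params["z_sent_single"] == pytest.approx(0.0, abs=0.1)
        assert model.params["const"] == pytest.approx(np.log(base / (1 - base)), abs=0.2)

    def test_matches_from_scratch_irls(self, rng):
        ft = logit_fixture(rng, n=200)
        cols = ["z_sent_single", "log_single", "asym_single", "shared_contacts"]
        model = builders.fit_tie_logit(ft, features=cols)
        X = np.column_stack([np.ones(len(ft)), ft[cols].to_numpy(float)])
        oracle = irls_logit(ft["tie_label"].to_numpy(float), X)
        np.testing.assert_allclose(model.params.to_numpy(), oracle, atol=1e-6)

    def test_perfect_separation_raises_and_ridge_recovers(self):
        x = np.r_[np.zeros(30), np.ones(30)]
        ft = pd.DataFrame(
            {"sender_id": "S", "recipient_id": "R", "log_single": x, "tie_label": x.astype(int)}
        )
        with pytest.raises(builders.PerfectSeparationError, match="ridge"):
            builders.fit_tie_logit(ft, features=["log_single"])
        model = builders.fit_tie_logit(ft, features=["log_single"], ridge=1.0)
        p = model.predict(ft)
        assert ((p > 0.5) == (x > 0.5)).all()

    def test_single_label_rejected(self):
        ft = pd.DataFrame(
            {"sender_id": "S", "recipient_id": "R", "log_single": [1.0, 2.0],
             "tie_label": [1, 1]}
        )
        with pytest.raises(ValueError, match="both tie and non-tie"):
            builders.fit_tie_logit(ft, features=["log_single"])


class TestLogisticNetwork:
    def test_threshold_extremes_and_monotonicity(self, small_features):
        model = builders.fit_tie_logit(small_features)
        pmax = model.predict(small_features).max()
        top = builders.logistic_network(model, small_features, min(0.99, pmax + 0.001))
        assert top.n_ties == 0
        p = model.predict(small_features)
        below_min = max(float(p.min()) * 0.9, 5e-324)
        everything = builders.logistic_network(model, small_features, below_min)
        assert everything.n_ties == len(small_features)
        prev = None
        for thr in [0.02, 0.05, 0.1, 0.3]:
            ties = builders.logistic_network(model, small_features, thr).ties()
            if prev is not None:
                assert ties <= prev
            prev = ties

    def test_direction_can_be_one_sided(self, small_features):
        model = builders.fit_tie_logit(small_features)
        net = builders.logistic_network(model, small_features, 0.3)
        one_sided = [
            (u, v) for u, v in net.graph.edges if not net.graph.has_edge(v, u)
        ]
        assert net.directed
        assert one_sided  # asymmetric volumes yield one-directional ties


class TestRankedPartnerNetwork:
    def _pairs(self, vols):
        rows = [("E", p, v) for p, v in vols.items()]
        return pd.DataFrame(
            {
                "sender_id": [r[0] for r in rows],
                "recipient_id": [r[1] for r in rows],
                "n_single": [r[2] for r in rows],
                "n_multi": [0] * len(rows),
                "size_sum": [1] * len(rows),
            }
        )

    def test_top_k_by_volume(self):
        net = builders.ranked_partner_network(self._pairs({"B": 10, "C": 7, "D": 3}), 2)
        assert set(net.graph.successors("E")) == {"B", "C"}

    def test_volume_ties_share_the_better_rank(self):
        net = builders.ranked_partner_network(self._pairs({"B": 5, "C": 5, "D": 1}), 1)
        assert set(net.graph.successors("E")) == {"B", "C"}

    def test_single_partner_any_threshold(self):
        net = builders.ranked_partner_network(self._pairs({"B": 2}), 13)
        assert set(net.graph.successors("E")) == {"B"}

    def test_tie_set_grows_with_rank_threshold(self, small_pairs):
        prev = None
        for k in [1, 3, 6, 13]:
            ties = builders.ranked_partner_network(small_pairs, k).ties()
            if prev is not None:
                assert ties >= prev
            prev = ties
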