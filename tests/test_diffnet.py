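"""Differential networks: gain/loss edges, in-degrees, consistency filter."""

import numpy as np
import pandas as pd
import pytest

from methnet import (
    InferenceParams,
    consistency_filter,
    differential_edges,
    gain_loss_table,
    in_degrees,
    rank_targets,
)
from methnet.diffnet import methylation_direction
from methnet.grn import PhenotypeNetwork


def _net(weights: pd.DataFrame, phenotype="x") -> PhenotypeNetwork:
    return PhenotypeNetwork(
        phenotype=phenotype,
        weights=weights,
        candidate_mask=weights >= 0,
        params=InferenceParams(),
        seed=0,
    )


@pytest.fixture()
def toy_pair():
    tumor = pd.DataFrame(
        [[0.9, 0.0], [0.0, 0.1]], index=["tfA", "tfB"], columns=["g1", "g2"]
    )
    normal = pd.DataFrame(
        [[0.1, 0.0], [0.0, 0.9]], index=["tfA", "tfB"], columns=["g1", "g2"]
    )
    return _net(tumor, "I"), _net(normal, "normal")


class TestDifferentialEdges:
    def test_identical_networks_empty(self, toy_pair):
        net, _ = toy_pair
        assert len(differential_edges(net, net)) == 0

    def test_two_by_two_hand_case(self, toy_pair):
        tumor, normal = toy_pair
        edges = differential_edges(tumor, normal, k=2)
        assert len(edges) == 2
        first, second = edges.iloc[0], edges.iloc[1]
        assert (first.tf, first.target, first.direction) == ("tfA", "g1", "gain")
        assert first.delta_w == pytest.approx(0.8)
        assert (second.tf, second.target, second.direction) == ("tfB", "g2", "loss")
        assert second.delta_w == pytest.approx(-0.8)
        assert list(edges["rank"]) == [1, 2]

    def test_k_clipping_and_exact_k(self, rng):
        wt = pd.DataFrame(rng.random((40, 40)) + 0.01)
        wn = pd.DataFrame(rng.random((40, 40)) + 0.01)
        wt.index = wn.index = [f"tf{i}" for i in range(40)]
        wt.columns = wn.columns = [f"g{i}" for i in range(40)]
        assert len(differential_edges(_net(wt), _net(wn), k=10_000)) == 1600
        assert len(differential_edges(_net(wt), _net(wn), k=1000)) == 1000

    def test_antisymmetry(self, rng):
        wt = pd.DataFrame(rng.random((5, 5)))
        wn = pd.DataFrame(rng.random((5, 5)))
        for w in (wt, wn):
            w.index = [f"tf{i}" for i in range(5)]
            w.columns = [f"g{i}" for i in range(5)]
        fwd = differential_edges(_net(wt), _net(wn), k=100)
        rev = differential_edges(_net(wn), _net(wt), k=100)
        merged = fwd.merge(rev, on=["tf", "target"], suffixes=("_f", "_r"))
        assert len(merged) == len(fwd)
        assert np.allclose(merged["delta_w_f"], -merged["delta_w_r"])
        assert (
            merged["direction_f"].map({"gain": "loss", "loss": "gain"})
            == merged["direction_r"]
        ).all()
        assert (merged["rank_f"] == merged["rank_r"]).all()

    def test_missing_edges_treated_as_zero(self):
        wt = pd.DataFrame([[0.5]], index=["tfA"], columns=["g1"])
        wn = pd.DataFrame([[0.3]], index=["tfB"], columns=["g2"])
        edges = differential_edges(_net(wt), _net(wn))
        got = {(r.tf, r.target): r.delta_w for r in edges.itertuples()}
        assert got == {("tfA", "g1"): pytest.approx(0.5), ("tfB", "g2"): pytest.approx(-0.3)}


class TestInDegrees:
    def test_empty_and_counted(self):
        w = pd.DataFrame(0.0, index=["tfA", "tfB", "tfC"], columns=["g1", "g2"])
        assert (in_degrees(_net(w)) == 0).all()
        w.loc[:, "g1"] = [0.2, 0.3, 0.4]
        deg = in_degrees(_net(w))
        assert deg["g1"] == 3 and deg["g2"] == 0

    def test_matches_edge_list_recount(self, rng):
        w = pd.DataFrame(
            rng.random((6, 7)),
            index=[f"tf{i}" for i in range(6)],
            columns=[f"g{i}" for i in range(7)],
        )
        w[w < 0.5] = 0.0
        net = _net(w)
        recount = net.edge_list().groupby("target").size()
        deg = in_degrees(net)
        for t in w.columns:
            assert deg[t] == recount.get(t, 0)


class TestConsistencyFilter:
    @staticmethod
    def _dm(probe, delta, significant=True):
        return pd.DataFrame(
            {
                "probe_id": [probe], "stage": "I", "delta_mean": [delta],
                "p": [1e-5 if significant else 0.5],
                "p_adj": [1e-4 if significant else 0.9],
                "significant": [significant],
                "direction": [
                    ("hyper" if delta > 0 else "hypo") if significant else "none"
                ],
            }
        )

    @pytest.mark.parametrize(
        "deg_n,deg_t,delta,retained",
        [
            (5, 8, -0.5, True),    # in-degree up + hypo -> keep
            (5, 8, +0.5, False),   # in-degree up + hyper -> drop
            (8, 5, +0.5, True),    # in-degree down + hyper -> keep
            (5, 5, -0.5, False),   # unchanged -> drop
        ],
    )
    def test_retention_rule(self, deg_n, deg_t, delta, retained):
        tfs = [f"tf{i}" for i in range(10)]
        wn = pd.DataFrame(0.0, index=tfs, columns=["g1"])
        wt = wn.copy()
        wn.iloc[:deg_n, 0] = 1.0
        wt.iloc[:deg_t, 0] = 1.0
        dm = self._dm("p1", delta)
        pairs = pd.DataFrame({"probe_id": ["p1"], "gene_id": ["g1"]})
        summary = consistency_filter(_net(wt, "I"), _net(wn, "normal"), dm, pairs)
        assert summary.loc[summary["target"] == "g1", "retained"].iloc[0] == retained

    def test_direction_from_most_significant_probe(self):
        dm = pd.concat(
            [self._dm("p1", +0.5), self._dm("p2", -0.6)], ignore_index=True
        )
        dm.loc[0, ["p", "p_adj"]] = [1e-8, 1e-7]  # p1 (hyper) more significant
        pairs = pd.DataFrame({"probe_id": ["p1", "p2"], "gene_id": ["g1", "g1"]})
        assert methylation_direction(dm, pairs)["g1"] == "hyper"

    def test_raw_sign_fallback_and_none(self):
        dm = self._dm("p1", -0.05, significant=False)
        pairs = pd.DataFrame({"probe_id": ["p1"], "gene_id": ["g1"]})
        assert methylation_direction(dm, pairs)["g1"] == "hypo"
        assert methylation_direction(dm, pairs).reindex(["g2"]).isna().all()


class TestRankTargets:
    @pytest.fixture()
    def edges(self):
        rows = []
        for i in range(4):
            rows.append(("tf%d" % i, "gBig", 0.5, "gain"))
        rows += [
            ("tf0", "gTieA", 0.4, "loss"), ("tf1", "gTieA", 0.4, "loss"),
            ("tf0", "gTieB", 0.4, "loss"), ("tf1", "gTieB", 0.4, "loss"),
            ("tf0", "gDrop", 0.9, "gain"),
        ]
        df = pd.DataFrame(rows, columns=["tf", "target", "delta_w", "direction"])
        df["rank"] = range(1, len(df) + 1)
        return df

    def test_top_gain_and_tie_break(self, edges):
        retained = {"gBig", "gTieA", "gTieB"}
        gain, loss, sub = rank_targets(edges, retained, top_n=10)
        assert list(gain["target"]) == ["gBig"] and gain["count"].iloc[0] == 4
        assert list(loss["target"]) == ["gTieA", "gTieB"]  # tie -> id order
        assert set(sub["target"]) <= retained

    def test_unretained_targets_excluded(self, edges):
        gain, _, _ = rank_targets(edges, {"gTieA"}, top_n=10)
        assert "gDrop" not in set(gain["target"]) and "gBig" not in set(gain["target"])


class TestGainLossTable:
    def test_partition_and_all_gain(self, toy_pair, rng):
        tumor, normal = toy_pair
        edges_I = differential_edges(tumor, normal, k=100)
        table = gain_loss_table({"I": edges_I})
        assert table["I"].sum() == len(edges_I)
        wt = pd.DataFrame(rng.random((3, 3)) + 1.0)
        wn = pd.DataFrame(np.zeros((3, 3)))
        for w in (wt, wn):
            w.index = [f"tf{i}" for i in range(3)]
            w.columns = [f"g{i}" for i in range(3)]
        all_gain = gain_loss_table({"II": differential_edges(_net(wt), _net(wn), k=100)})
        assert all_gain.loc["loss", "II"] == 0
        assert all_gain.loc["gain", "II"] == 9
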