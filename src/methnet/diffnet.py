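"""Tumor-vs-normal differential networks: regulation gain and loss.

Subtracting the normal weight matrix from a tumor stage's matrix gives a
differential network whose top-k edges by |weight difference| are treated
as true regulatory alterations: a positive difference is a *gain* of
regulation in the tumor, a negative one a *loss*.  Targets are screened
for consistency with the promoter methylation change under the assumption
that hyper-methylation reduces TF binding affinity (so in-degree should
drop) while hypo-methylation enables binding (in-degree should rise).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .grn import PhenotypeNetwork


def _aligned(net_tumor: PhenotypeNetwork, net_normal: PhenotypeNetwork):
    tfs = sorted(set(net_tumor.weights.index) | set(net_normal.weights.index))
    targets = sorted(set(net_tumor.weights.columns) | set(net_normal.weights.columns))
    wt = net_tumor.weights.reindex(index=tfs, columns=targets, fill_value=0.0)
    wn = net_normal.weights.reindex(index=tfs, columns=targets, fill_value=0.0)
    return wt, wn


def differential_edges(
    net_tumor: PhenotypeNetwork,
    net_normal: PhenotypeNetwork,
    k: int = 1000,
    targets: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Top-k edges of the tumor-minus-normal weight difference.

    Edge universes are unioned with missing weights as 0.  Edges are
    ranked by |delta_w| descending with a deterministic (tf, target)
    tie-break; exactly min(k, number of nonzero-delta edges) rows are
    returned with 1-based ranks and gain/loss labels.  ``targets``
    optionally restricts the universe (consistency-filter-first order).
    """
    wt, wn = _aligned(net_tumor, net_normal)
    delta = (wt - wn).stack().rename("delta_w").reset_index()
    delta.columns = ["tf", "target", "delta_w"]
    if targets is not None:
        delta = delta[delta["target"].isin(set(targets))]
    delta = delta[delta["delta_w"] != 0.0].copy()
    delta["absd"] = delta["delta_w"].abs()
    delta = delta.sort_values(
        ["absd", "tf", "target"], ascending=[False, True, True], kind="stable"
    ).head(k)
    delta = delta.drop(columns="absd").reset_index(drop=True)
    delta["direction"] = np.where(delta["delta_w"] > 0, "gain", "loss")
    delta["rank"] = np.arange(1, len(delta) + 1)
    return delta


def in_degrees(net: PhenotypeNetwork) -> pd.Series:
    """Number of nonzero incoming edges per target of a sparsified network."""
    return (net.weights > 0).sum(axis=0).rename("in_degree")


def methylation_direction(
    diffmeth: pd.DataFrame,
    pairs: pd.DataFrame,
) -> pd.Series:
    """Per-gene methylation change direction for one stage.

    Each gene inherits the direction of its most significant assigned
    probe (smallest p_adj, ties by largest |delta_mean| then probe_id);
    if no assigned probe is significant the raw delta_mean sign of that
    probe is used, and genes without assigned probes get ``none``.
    """
    merged = diffmeth.merge(pairs[["probe_id", "gene_id"]], on="probe_id")
    if merged.empty:
        return pd.Series(dtype=object, name="meth_direction")
    merged = merged.copy()
    merged["absd"] = merged["delta_mean"].abs()
    merged["p_adj_filled"] = merged["p_adj"].fillna(np.inf)
    merged = merged.sort_values(
        ["gene_id", "p_adj_filled", "absd", "probe_id"],
        ascending=[True, True, False, True],
        kind="stable",
    )
    best = merged.drop_duplicates("gene_id", keep="first").set_index("gene_id")
    direction = np.where(
        best["significant"],
        best["direction"],
        np.select(
            [best["delta_mean"] > 0, best["delta_mean"] < 0],
            ["hyper", "hypo"],
            default="none",
        ),
    )
    return pd.Series(direction, index=best.index, name="meth_direction")


def consistency_filter(
    net_tumor: PhenotypeNetwork,
    net_normal: PhenotypeNetwork,
    diffmeth: pd.DataFrame,
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Target summaries with the methylation-consistency retention flag.

    A target is retained when its in-degree rises while its promoter is
    hypo-methylated, or falls while hyper-methylated; equal in-degrees or
    mismatched directions are discarded.
    """
    ind_t = in_degrees(net_tumor)
    ind_n = in_degrees(net_normal)
    targets = sorted(set(ind_t.index) | set(ind_n.index))
    summary = pd.DataFrame(index=pd.Index(targets, name="target"))
    summary["in_deg_normal"] = ind_n.reindex(targets, fill_value=0)
    summary["in_deg_tumor"] = ind_t.reindex(targets, fill_value=0)
    meth = methylation_direction(diffmeth, pairs)
    summary["meth_direction"] = meth.reindex(targets).fillna("none")
    summary["retained"] = (
        (summary["in_deg_tumor"] > summary["in_deg_normal"])
        & (summary["meth_direction"] == "hypo")
    ) | (
        (summary["in_deg_tumor"] < summary["in_deg_normal"])
        & (summary["meth_direction"] == "hyper")
    )
    return summary.reset_index()


def rank_targets(
    diff_edges: pd.DataFrame,
    retained_targets: Iterable[str],
    top_n: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Rank retained targets by number of gained and of lost regulations.

    Returns (gain_table, loss_table, subgraph_edges): the two ranked
    tables have columns target, count with deterministic (count desc,
    target asc) ordering and only targets with at least one edge of the
    direction; the subgraph lists every differential edge incident to a
    top-ranked target.
    """
    retained = set(retained_targets)
    edges = diff_edges[diff_edges["target"].isin(retained)]
    tables = {}
    for direction in ("gain", "loss"):
        counts = (
            edges[edges["direction"] == direction]
            .groupby("target")
            .size()
            .rename("count")
            .reset_index()
            .sort_values(["count", "target"], ascending=[False, True], kind="stable")
            .head(top_n)
            .reset_index(drop=True)
        )
        tables[direction] = counts
    top = set(tables["gain"]["target"]) | set(tables["loss"]["target"])
    subgraph = edges[edges["target"].isin(top)].reset_index(drop=True)
    return tables["gain"], tables["loss"], subgraph


def gain_loss_table(
    diff_networks: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """2 x stages table of gain and loss edge counts per tumor stage."""
    stages = list(diff_networks)
    data = {
        stage: [
            int((diff_networks[stage]["direction"] == "gain").sum()),
            int((diff_networks[stage]["direction"] == "loss").sum()),
        ]
        for stage in stages
    }
    return pd.DataFrame(data, index=["gain", "loss"])
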