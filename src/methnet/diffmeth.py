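"""Differential methylation: trimmed Wilcoxon rank-sum per stage vs normal.

For each probe, the 10% most and least methylated samples of each group
are excluded (a guard against molecular-subtype outliers), the trimmed
tumor and normal groups are compared with a two-sided Wilcoxon rank-sum
test, p-values are BH-adjusted across all probes of the stage comparison,
and a probe is called significantly differential only when additionally
the absolute trimmed mean difference exceeds 0.2.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .assign import benjamini_hochberg

log = logging.getLogger(__name__)

TUMOR_STAGES = ("I", "II", "III", "IV")


def trim_extremes(values: np.ndarray, frac: float = 0.10) -> np.ndarray:
    """Drop the floor(frac*n) smallest and largest values.

    Ties are resolved stably (lowest original indices removed first); the
    retained values keep their original order.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("values must be a non-empty 1-D vector")
    if not 0.0 <= frac < 0.5:
        raise ValueError("frac must lie in [0, 0.5)")
    k = int(np.floor(frac * v.size))
    if k == 0:
        return v.copy()
    order = np.argsort(v, kind="stable")
    keep = np.ones(v.size, dtype=bool)
    keep[order[:k]] = False
    keep[order[-k:]] = False
    return v[keep]


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses exact null enumeration when n_x + n_y <= 12 with no ties, and
    the normal approximation with tie and continuity correction
    otherwise.  Returns (U statistic of x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return (float(res.statistic), float(res.pvalue))


def differential_probes(
    beta: pd.DataFrame,
    phenotypes: pd.Series,
    stage: str,
    alpha: float = 0.05,
    min_diff: float = 0.2,
    trim: float = 0.10,
    trim_mode: str = "pooled",
    normal_label: str = "normal",
) -> pd.DataFrame:
    """Per-probe differential methylation of one tumor stage vs normal.

    For each probe the 10% most and least methylated samples are
    excluded before testing.  With ``trim_mode='pooled'`` (default) the
    extremes are taken over the pooled tumor+normal samples, which keeps
    the rank-sum test calibrated under the null (removing each group's
    own extremes shrinks within-group dispersion and inflates the
    statistic); ``'per_group'`` trims each group independently.
    delta_mean is the trimmed tumor mean minus the trimmed normal mean.
    ``significant`` requires both BH-adjusted p < alpha and
    |delta_mean| > min_diff; ``direction`` is hyper/hypo for significant
    probes and none otherwise.
    """
    if trim_mode not in ("pooled", "per_group"):
        raise ValueError("trim_mode must be 'pooled' or 'per_group'")
    for label in (stage, normal_label):
        if label not in set(phenotypes):
            raise ValueError(f"phenotype {label!r} absent from the sample table")
    s_cols = [c for c in beta.columns if phenotypes.get(c) == stage]
    n_cols = [c for c in beta.columns if phenotypes.get(c) == normal_label]
    k_s = len(s_cols) - 2 * int(np.floor(trim * len(s_cols)))
    k_n = len(n_cols) - 2 * int(np.floor(trim * len(n_cols)))
    if min(k_s, k_n) < 3:
        raise ValueError(
            f"post-trim group sizes ({k_s}, {k_n}) too small for testing"
        )
    rows = []
    for probe in beta.index:
        sv = beta.loc[probe, s_cols].dropna().to_numpy()
        nv = beta.loc[probe, n_cols].dropna().to_numpy()
        if sv.size == 0 or nv.size == 0:
            rows.append((probe, np.nan, np.nan))
            continue
        if trim_mode == "pooled":
            pooled = np.concatenate([sv, nv])
            group = np.repeat([True, False], [sv.size, nv.size])
            k = int(np.floor(trim * pooled.size))
            if k > 0:
                order = np.argsort(pooled, kind="stable")
                keep = np.ones(pooled.size, dtype=bool)
                keep[order[:k]] = False
                keep[order[-k:]] = False
                sv = pooled[keep & group]
                nv = pooled[keep & ~group]
        else:
            sv = trim_extremes(sv, trim)
            nv = trim_extremes(nv, trim)
        if sv.size == 0 or nv.size == 0:
            rows.append((probe, np.nan, np.nan))
            continue
        delta = float(sv.mean() - nv.mean())
        _, p = wilcoxon_rank_sum(sv, nv)
        rows.append((probe, delta, p))
    out = pd.DataFrame(rows, columns=["probe_id", "delta_mean", "p"])
    out.insert(1, "stage", stage)
    tested = out["p"].notna()
    out["p_adj"] = np.nan
    out.loc[tested, "p_adj"] = benjamini_hochberg(out.loc[tested, "p"].to_numpy())
    out["significant"] = (out["p_adj"] < alpha) & (out["delta_mean"].abs() > min_diff)
    out["direction"] = np.select(
        [out["significant"] & (out["delta_mean"] > 0),
         out["significant"] & (out["delta_mean"] < 0)],
        ["hyper", "hypo"],
        default="none",
    )
    return out


def top_differential(
    results: pd.DataFrame,
    pairs: pd.DataFrame,
    k: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k genes by largest positive and negative trimmed mean difference.

    Each gene is scored by the delta_mean of its most extreme significant
    probe (among its assigned probes); ties break by |delta_mean|
    descending then probe_id ascending.  Returns (hyper_table, hypo_table)
    with columns gene_id, probe_id, delta_mean.
    """
    sig = results[results["significant"]]
    merged = sig.merge(pairs[["probe_id", "gene_id"]], on="probe_id")
    if merged.empty:
        empty = pd.DataFrame(columns=["gene_id", "probe_id", "delta_mean"])
        return empty, empty.copy()

    def _top(df: pd.DataFrame, sign: int) -> pd.DataFrame:
        part = df[np.sign(df["delta_mean"]) == sign].copy()
        part["absd"] = part["delta_mean"].abs()
        part = part.sort_values(
            ["absd", "probe_id"], ascending=[False, True], kind="stable"
        )
        best = part.drop_duplicates("gene_id", keep="first")
        return best.head(k)[["gene_id", "probe_id", "delta_mean"]].reset_index(drop=True)

    return _top(merged, 1), _top(merged, -1)


def stage_venn(
    results_by_stage: Mapping[str, pd.DataFrame],
    pairs: pd.DataFrame,
) -> dict[str, dict[str, set[str]]]:
    """Venn partitions of hyper- and hypo-linked genes across stages I-IV.

    Returns ``{"hyper": partition, "hypo": partition}`` where each
    partition maps a region label (``"I&II"`` etc.) to its gene set.
    """
    probe_genes: dict[str, list[str]] = {}
    for row in pairs.itertuples():
        probe_genes.setdefault(row.probe_id, []).append(row.gene_id)
    stages = [s for s in TUMOR_STAGES if s in results_by_stage]
    out: dict[str, dict[str, set[str]]] = {}
    for direction in ("hyper", "hypo"):
        sets: dict[str, set[str]] = {}
        for stage in stages:
            res = results_by_stage[stage]
            probes = res.loc[res["direction"] == direction, "probe_id"]
            genes: set[str] = set()
            for probe in probes:
                genes.update(probe_genes.get(probe, ()))
            sets[stage] = genes
        union = set().union(*sets.values()) if sets else set()
        partition: dict[str, set[str]] = {}
        for gene in union:
            members = tuple(s for s in stages if gene in sets[s])
            partition.setdefault("&".join(members), set()).add(gene)
        out[direction] = partition
    return out
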