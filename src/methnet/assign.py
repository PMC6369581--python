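"""Probe-to-gene assignment by promoter location and negative correlation.

A probe is a candidate for a gene when it lies within +/-2 kb of the gene's
TSS; the pair is confirmed when the probe's methylation and the gene's
expression are significantly negatively Spearman-correlated (BH-adjusted
p < alpha) in at least one tumor stage, computed over samples with both
measurements.  The normal phenotype is excluded by default because a
TCGA-like cohort has no matched normal methylation/expression samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

TUMOR_STAGES = ("I", "II", "III", "IV")


@dataclass
class ProbeGenePair:
    """A confirmed probe -> gene link."""

    probe_id: str
    gene_id: str
    confirming_phenotypes: set[str] = field(default_factory=set)


def filter_probes(probes: pd.DataFrame) -> list[str]:
    """Retain probes that are unmasked and autosomal, preserving order.

    Masked probes (SNP/repeat overlap or NA-containing) and probes on the
    X or Y chromosome are removed.
    """
    if probes.empty:
        return []
    chrom = probes["chrom"].astype(str).str.removeprefix("chr").str.upper()
    sex = probes.get("sex_chrom", pd.Series(False, index=probes.index))
    keep = ~probes["masked"].astype(bool) & ~sex.astype(bool) & ~chrom.isin(["X", "Y"])
    return probes.loc[keep, "probe_id"].tolist()


def candidate_pairs(
    probes: pd.DataFrame,
    genes: pd.DataFrame,
    half_window: int = 2000,
) -> pd.DataFrame:
    """All (probe, gene) pairs with the probe within +/-half_window of the TSS.

    The window is inclusive on both boundaries (|position - tss| <=
    half_window) and strand-symmetric.  A probe may map to several genes
    and a gene may receive several probes.  Raises if the two tables use
    disjoint chromosome naming (e.g. ``chr1`` vs ``1``).
    """
    if probes.empty or genes.empty:
        return pd.DataFrame(columns=["probe_id", "gene_id", "distance"])
    pc = set(probes["chrom"].astype(str))
    gc = set(genes["chrom"].astype(str))
    if not pc & gc:
        raise ValueError(
            f"no shared chromosome names between probe ({sorted(pc)[:3]}...) "
            f"and gene ({sorted(gc)[:3]}...) tables: inconsistent naming?"
        )
    merged = probes[["probe_id", "chrom", "position"]].merge(
        genes[["gene_id", "chrom", "tss"]], on="chrom"
    )
    dist = (merged["position"] - merged["tss"]).abs()
    out = merged.loc[dist <= half_window, ["probe_id", "gene_id"]].copy()
    out["distance"] = dist[dist <= half_window]
    return out.reset_index(drop=True)


def spearman_t(meth: np.ndarray, expr: np.ndarray) -> tuple[float, float, float]:
    """Spearman correlation with its t-statistic and two-sided p-value.

    t = r * sqrt(n - 2) / sqrt(1 - r^2), referred to a Student t with
    n - 2 degrees of freedom.  Ties get average ranks.  |r| = 1 maps to
    t = +/-inf and p = 0.  A constant input vector has no defined rank
    correlation; (nan, nan, nan) is returned so callers can exclude the
    pair rather than fail.
    """
    x = np.asarray(meth, dtype=float)
    y = np.asarray(expr, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("meth and expr must be 1-D vectors of equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (np.nan, np.nan, np.nan)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = min(1.0, max(-1.0, r))
    if abs(r) >= 1.0 - 1e-15:
        return (float(np.sign(r)), float(np.sign(r) * np.inf), 0.0)
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return (r, float(t), float(min(p, 1.0)))


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    np.clip(adj, 0.0, 1.0, out=adj)
    out = np.empty(m)
    out[order] = adj
    return out


def _stage_correlations(
    cand: pd.DataFrame,
    beta: pd.DataFrame,
    expr: pd.DataFrame,
    samples: list[str],
) -> pd.DataFrame:
    """Vectorized Spearman r/t/p for every candidate pair over ``samples``."""
    n = len(samples)
    b = beta.loc[cand["probe_id"], samples].to_numpy()
    e = expr.loc[cand["gene_id"], samples].to_numpy()
    rb = stats.rankdata(b, axis=1)
    re = stats.rankdata(e, axis=1)
    rb -= rb.mean(axis=1, keepdims=True)
    re -= re.mean(axis=1, keepdims=True)
    denom = np.sqrt((rb**2).sum(axis=1) * (re**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (rb * re).sum(axis=1) / denom, np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = np.where(
            np.isnan(r),
            np.nan,
            np.where(np.abs(r) >= 1.0 - 1e-15, 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2)),
        )
    out = cand[["probe_id", "gene_id"]].copy()
    out["r"] = r
    out["n"] = n
    out["t"] = t
    out["p"] = np.minimum(p, 1.0)
    return out


def confirm_pairs(
    candidates: pd.DataFrame,
    beta: pd.DataFrame,
    expr: pd.DataFrame,
    phenotypes: pd.Series,
    alpha: float = 0.05,
    include_normal: bool = False,
    bh_family: str = "per_stage",
    min_samples: int = 4,
) -> tuple[list[ProbeGenePair], pd.DataFrame]:
    """Confirm candidate pairs by negative methylation-expression correlation.

    For each tumor stage (and optionally normal, for non-TCGA-like data),
    Spearman r/t/p is computed over the samples present in both matrices,
    p-values are BH-adjusted across all candidates tested in that stage
    (``bh_family='per_stage'``) or across all stages jointly
    (``'pooled'``), and a pair is confirmed when p_adj < alpha with r < 0
    in at least one stage.  Stages with fewer than ``min_samples`` matched
    samples are skipped with a warning; constant vectors yield NaN results
    and are excluded from confirmation.
    """
    if bh_family not in ("per_stage", "pooled"):
        raise ValueError("bh_family must be 'per_stage' or 'pooled'")
    stages = list(TUMOR_STAGES) + (["normal"] if include_normal else [])
    stages = [s for s in stages if s in set(phenotypes)]
    cand = candidates[["probe_id", "gene_id"]].drop_duplicates().reset_index(drop=True)
    cand = cand[
        cand["probe_id"].isin(beta.index) & cand["gene_id"].isin(expr.index)
    ].reset_index(drop=True)

    results = []
    for stage in stages:
        samples = sorted(
            set(phenotypes.index[phenotypes == stage]) & set(beta.columns) & set(expr.columns)
        )
        if len(samples) < min_samples:
            log.warning(
                "stage %s skipped: only %d matched samples (< %d)",
                stage, len(samples), min_samples,
            )
            continue
        res = _stage_correlations(cand, beta, expr, samples)
        res.insert(2, "phenotype", stage)
        results.append(res)
    if not results:
        empty = pd.DataFrame(
            columns=["probe_id", "gene_id", "phenotype", "r", "n", "t", "p", "p_adj"]
        )
        return [], empty
    table = pd.concat(results, ignore_index=True)

    table["p_adj"] = np.nan
    if bh_family == "per_stage":
        for stage in table["phenotype"].unique():
            sel = (table["phenotype"] == stage) & table["p"].notna()
            table.loc[sel, "p_adj"] = benjamini_hochberg(table.loc[sel, "p"].to_numpy())
    else:
        sel = table["p"].notna()
        table.loc[sel, "p_adj"] = benjamini_hochberg(table.loc[sel, "p"].to_numpy())

    confirmed = table[(table["p_adj"] < alpha) & (table["r"] < 0)]
    pairs: dict[tuple[str, str], ProbeGenePair] = {}
    for row in confirmed.itertuples():
        key = (row.probe_id, row.gene_id)
        if key not in pairs:
            pairs[key] = ProbeGenePair(row.probe_id, row.gene_id, set())
        pairs[key].confirming_phenotypes.add(row.phenotype)
    return [pairs[k] for k in sorted(pairs)], table


def pairs_to_frame(pairs: list[ProbeGenePair]) -> pd.DataFrame:
    """Tabular form of confirmed pairs (phenotypes comma-joined, sorted)."""
    return pd.DataFrame(
        {
            "probe_id": [p.probe_id for p in pairs],
            "gene_id": [p.gene_id for p in pairs],
            "confirming_phenotypes": [
                ",".join(sorted(p.confirming_phenotypes)) for p in pairs
            ],
        }
    )
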