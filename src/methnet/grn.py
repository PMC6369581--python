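"""Motif-restricted gene regulatory network inference per phenotype.

Each target gene's (standardised) expression is regressed on its candidate
TFs' expression with a tree ensemble, GENIE3-style, in two passes: a first
ensemble yields preliminary importances, and a second, guided ensemble
samples each tree's feature subset with probabilities proportional to
``(1 - gamma) + gamma * imp0/max(imp0)`` so that features that looked
informative in the first pass are revisited more often.  Edge weights are
the mean impurity reduction attributed to each TF; per-target vectors are
then q-norm normalized so targets are comparable, and the network is
refined to a fixed edge density, reflecting the sparsity of large-scale
regulatory networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .motifs import CandidateEdgeSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class InferenceParams:
    """Tunable parameters of the per-target ensemble regression.

    n_trees
        trees per pass and per target.
    guide_strength
        gamma in [0, 1]; 0 disables guiding (plain ensemble), 1 makes the
        second pass sample features purely by first-pass importance.
    q
        order of the per-target norm used to normalize weight vectors.
    density
        fraction of candidate edges retained after sparsity refinement.
    min_samples_leaf
        leaf size of each regression tree.
    max_features
        per-split feature subsample: "sqrt" or an int.
    """

    n_trees: int = 500
    guide_strength: float = 0.5
    q: float = 2.0
    density: float = 0.05
    min_samples_leaf: int = 2
    max_features: str | int = "sqrt"

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.min_samples_leaf < 1:
            raise ValueError("n_trees and min_samples_leaf must be positive")
        if not 0.0 <= self.guide_strength <= 1.0:
            raise ValueError("guide_strength must lie in [0, 1]")
        if self.q <= 0:
            raise ValueError("q must be positive")
        if not 0.0 < self.density <= 1.0:
            raise ValueError("density must lie in (0, 1]")


@dataclass
class PhenotypeNetwork:
    """A TF x target weight matrix for one phenotype."""

    phenotype: str
    weights: pd.DataFrame          # TF x target, nonnegative
    candidate_mask: pd.DataFrame   # TF x target boolean
    params: InferenceParams
    seed: int

    def edge_list(self) -> pd.DataFrame:
        stacked = self.weights.stack()
        nz = stacked[stacked > 0]
        out = nz.rename("weight").reset_index()
        out.columns = ["tf", "target", "weight"]
        out.insert(0, "phenotype", self.phenotype)
        return out.sort_values(["tf", "target"]).reset_index(drop=True)


def _ensemble_importances(
    X: np.ndarray,
    y: np.ndarray,
    params: InferenceParams,
    feature_probs: np.ndarray | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean per-feature impurity reduction over a bagged tree ensemble.

    Each tree sees a bootstrap of the rows and, when ``feature_probs`` is
    given, a weighted-sampled feature subset (the guided pass); splits
    within a tree additionally subsample ``max_features`` candidates.
    """
    n, p = X.shape
    if params.max_features == "sqrt":
        k = max(1, int(round(np.sqrt(p))))
    else:
        k = min(p, int(params.max_features))
    subset_size = min(p, max(k, 3 * k)) if feature_probs is not None else p
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    y32 = np.ascontiguousarray(y, dtype=np.float64)
    total = np.zeros(p)
    for _ in range(params.n_trees):
        if feature_probs is not None and subset_size < p:
            feats = np.sort(
                rng.choice(p, size=subset_size, replace=False, p=feature_probs)
            )
        else:
            feats = np.arange(p)
        rows = rng.integers(0, n, size=n)
        tree = DecisionTreeRegressor(
            max_features=min(k, len(feats)),
            min_samples_leaf=params.min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(
            np.ascontiguousarray(X32[np.ix_(rows, feats)]),
            y32[rows],
            check_input=False,
        )
        imp = tree.tree_.compute_feature_importances(normalize=False)
        total[feats] += imp
    return total / params.n_trees


def fit_target(
    expr_target: np.ndarray,
    expr_tfs: np.ndarray,
    params: InferenceParams,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Importance of each candidate TF for one target gene.

    ``expr_tfs`` is samples x TFs.  The target is standardised to unit
    variance so importances are comparable across targets (they sum to
    roughly the explained variance).  A zero-variance target returns
    all-zero importances; deterministic under a fixed seed.
    """
    y = np.asarray(expr_target, dtype=float)
    X = np.asarray(expr_tfs, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("expr_tfs must be samples x TFs aligned with expr_target")
    if X.shape[1] == 0:
        return np.zeros(0)
    sd = y.std()
    if sd == 0:
        return np.zeros(X.shape[1])
    y = (y - y.mean()) / sd
    rng = np.random.default_rng(seed)

    imp0 = _ensemble_importances(X, y, params, None, rng)
    gamma = params.guide_strength
    if gamma > 0 and imp0.max() > 0:
        guide = (1.0 - gamma) + gamma * imp0 / imp0.max()
        probs = guide / guide.sum()
    else:
        probs = None
    imp = _ensemble_importances(X, y, params, probs, rng)
    return np.maximum(imp, 0.0)


def q_normalize(
    weights: pd.DataFrame,
    q: float = 2.0,
    mode: str = "per_target",
) -> pd.DataFrame:
    """Normalize the TF x target weight matrix to make targets comparable.

    ``per_target`` divides each target's column by its q-norm (all-zero
    columns are left untouched), so every nonzero column ends with unit
    q-norm; idempotent.  ``global_quantile`` divides the whole matrix by
    the median of its nonzero weights instead, preserving relative target
    magnitudes when per-target rescaling is undesirable.
    """
    if q <= 0:
        raise ValueError("q must be positive")
    w = weights.astype(float)
    if mode == "per_target":
        norms = (w.abs() ** q).sum(axis=0) ** (1.0 / q)
        safe = norms.replace(0.0, 1.0)
        return w / safe
    if mode == "global_quantile":
        nz = w.to_numpy()[w.to_numpy() > 0]
        scale = float(np.median(nz)) if nz.size else 1.0
        return w / scale
    if mode == "none":
        return w.copy()
    raise ValueError("mode must be 'per_target', 'global_quantile' or 'none'")


def refine_sparsity(
    weights: pd.DataFrame,
    density: float = 0.05,
    candidate_mask: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Keep the globally top ceil(density * n_candidate_edges) edges.

    Ranking is by weight descending with a deterministic (tf, target)
    lexicographic tie-break; everything else is zeroed.  The candidate
    count defaults to the number of positive weights when no mask is
    given.
    """
    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    if density == 1.0:
        return weights.copy()
    n_cand = (
        int(candidate_mask.to_numpy().sum())
        if candidate_mask is not None
        else int((weights.to_numpy() > 0).sum())
    )
    m = int(np.ceil(density * n_cand))
    stacked = weights.stack().rename("weight").reset_index()
    stacked.columns = ["tf", "target", "weight"]
    stacked = stacked[stacked["weight"] > 0]
    stacked = stacked.sort_values(
        ["weight", "tf", "target"], ascending=[False, True, True], kind="stable"
    ).head(m)
    out = pd.DataFrame(0.0, index=weights.index, columns=weights.columns)
    for row in stacked.itertuples():
        out.loc[row.tf, row.target] = row.weight
    return out


def build_phenotype_network(
    expr: pd.DataFrame,
    phenotypes: pd.Series,
    phenotype: str,
    candidates: CandidateEdgeSet,
    params: InferenceParams | None = None,
    seed: int = 0,
    normalize_mode: str = "per_target",
) -> PhenotypeNetwork:
    """Infer the motif-restricted network of one phenotype.

    Fits :func:`fit_target` per target over the phenotype's samples
    (canonically ordered, so the result is invariant to input sample
    order), assembles the TF x target weight matrix, q-normalizes it and
    refines it to the configured density.  TFs or targets absent from the
    expression matrix are dropped with a logged count; self-regulation is
    excluded.
    """
    params = params or InferenceParams()
    samples = sorted(s for s in expr.columns if phenotypes.get(s) == phenotype)
    if len(samples) < 5:
        raise ValueError(
            f"phenotype {phenotype!r} has {len(samples)} samples; at least 5 required"
        )
    if len(samples) < 10:
        log.warning(
            "phenotype %s has only %d samples; proceeding", phenotype, len(samples)
        )
    present = set(expr.index)
    dropped_tfs = {tf for tfs in candidates.targets.values() for tf in tfs} - present
    if dropped_tfs:
        log.info("%d candidate TFs absent from expression matrix", len(dropped_tfs))
    target_tfs = {
        t: sorted((set(tfs) & present) - {t})
        for t, tfs in candidates.targets.items()
        if t in present
    }
    target_tfs = {t: tfs for t, tfs in target_tfs.items() if tfs}
    all_tfs = sorted({tf for tfs in target_tfs.values() for tf in tfs})
    all_targets = sorted(target_tfs)

    weights = pd.DataFrame(0.0, index=all_tfs, columns=all_targets)
    mask = pd.DataFrame(False, index=all_tfs, columns=all_targets)
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(all_targets))
    X_all = expr.loc[:, samples]
    for i, target in enumerate(all_targets):
        tfs = target_tfs[target]
        mask.loc[tfs, target] = True
        imp = fit_target(
            X_all.loc[target].to_numpy(),
            X_all.loc[tfs].to_numpy().T,
            params,
            seed=children[i],
        )
        weights.loc[tfs, target] = imp
    weights = q_normalize(weights, q=params.q, mode=normalize_mode)
    weights = refine_sparsity(weights, params.density, candidate_mask=mask)
    weights = weights.where(mask, 0.0)
    return PhenotypeNetwork(
        phenotype=phenotype,
        weights=weights,
        candidate_mask=mask,
        params=params,
        seed=seed,
    )
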