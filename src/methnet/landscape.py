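"""Methylation-state landscape: three-state classification and conservation.

Probes are classified per phenotype from their mean beta value into
unmethylated (< t_low), hemi-methylated, or fully methylated (> t_high);
boundary values fall into the hemi class so the extreme classes stay
strict.  Cross-phenotype conservation is the fraction of probes with the
same state, and phenotype-exclusive gene sets come from a full Venn
partition of state-linked genes.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STATES = ("unmethylated", "hemi", "full")
PHENOTYPES = ("normal", "I", "II", "III", "IV")


def phenotype_mean(
    beta: pd.DataFrame, phenotypes: pd.Series, phenotype: str
) -> pd.Series:
    """Per-probe arithmetic mean beta over one phenotype's samples.

    Missing values are ignored; a probe missing in every sample gets NaN
    and is excluded from downstream classification.
    """
    samples = [s for s in beta.columns if phenotypes.get(s) == phenotype]
    if not samples:
        raise ValueError(f"unknown or empty phenotype: {phenotype!r}")
    return beta[samples].mean(axis=1, skipna=True)


def classify(
    mean_beta: pd.Series | np.ndarray,
    t_low: float = 0.25,
    t_high: float = 0.75,
) -> pd.Series:
    """Map mean beta values to {unmethylated, hemi, full}.

    ``< t_low`` is unmethylated, ``> t_high`` fully methylated, anything
    else (boundaries included) hemi-methylated.  NaN stays NaN.
    """
    if t_low >= t_high:
        raise ValueError(f"t_low ({t_low}) must be below t_high ({t_high})")
    values = pd.Series(mean_beta, copy=True).astype(float)
    if ((values < 0) | (values > 1)).any():
        raise ValueError("mean beta values must lie in [0, 1]")
    out = pd.Series(
        np.select(
            [values < t_low, values > t_high],
            ["unmethylated", "full"],
            default="hemi",
        ),
        index=values.index,
        dtype=object,
    )
    out[values.isna()] = np.nan
    return out


def state_table(
    beta: pd.DataFrame,
    phenotypes: pd.Series,
    t_low: float = 0.25,
    t_high: float = 0.75,
    order: Sequence[str] = PHENOTYPES,
) -> pd.DataFrame:
    """Probe x phenotype table of methylation states."""
    cols = {}
    for ph in order:
        cols[ph] = classify(phenotype_mean(beta, phenotypes, ph), t_low, t_high)
    return pd.DataFrame(cols)


def conservation(states_a: pd.Series, states_b: pd.Series) -> float:
    """Fraction of shared probes with identical state in both phenotypes.

    Computed on the intersection of non-missing probes; disagreement in
    the probe universes is logged, an empty intersection is an error.
    """
    common = states_a.dropna().index.intersection(states_b.dropna().index)
    if len(common) == 0:
        raise ValueError("no shared probes between the two state vectors")
    if len(common) < len(states_a) or len(common) < len(states_b):
        log.info(
            "conservation computed on %d shared probes (of %d / %d)",
            len(common), len(states_a), len(states_b),
        )
    return float((states_a[common] == states_b[common]).mean())


def conservation_matrix(states: pd.DataFrame) -> pd.DataFrame:
    """Symmetric phenotype x phenotype agreement matrix with unit diagonal."""
    phs = list(states.columns)
    mat = pd.DataFrame(np.eye(len(phs)), index=phs, columns=phs)
    for a, b in combinations(phs, 2):
        c = conservation(states[a], states[b])
        mat.loc[a, b] = c
        mat.loc[b, a] = c
    return mat


def exclusive_sets(
    states: pd.DataFrame,
    pairs: pd.DataFrame,
    state_of_interest: str,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Genes linked to probes in a given state, per phenotype, plus Venn regions.

    A gene belongs to a phenotype's set when at least one of its assigned
    probes (per ``pairs`` with columns probe_id, gene_id) has the state of
    interest there.  Returns ``(per_phenotype_sets, venn_partition)``
    where the partition maps a region label like ``"I&II&normal"`` to the
    genes exactly in those phenotypes' sets.
    """
    if state_of_interest not in STATES:
        raise ValueError(f"state_of_interest must be one of {STATES}")
    probe_genes: dict[str, list[str]] = {}
    for row in pairs.itertuples():
        probe_genes.setdefault(row.probe_id, []).append(row.gene_id)
    sets: dict[str, set[str]] = {ph: set() for ph in states.columns}
    for ph in states.columns:
        hot = states.index[states[ph] == state_of_interest]
        for probe in hot:
            sets[ph].update(probe_genes.get(probe, ()))
    union = set().union(*sets.values()) if sets else set()
    partition: dict[str, set[str]] = {}
    for gene in union:
        members = tuple(ph for ph in states.columns if gene in sets[ph])
        partition.setdefault("&".join(members), set()).add(gene)
    return sets, partition


def venn_to_frame(partition: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Tabular Venn partition: region label, size, comma-joined gene list."""
    rows = [
        {"region": region, "n_genes": len(set(genes)),
         "genes": ",".join(sorted(genes))}
        for region, genes in sorted(partition.items())
    ]
    return pd.DataFrame(rows, columns=["region", "n_genes", "genes"])
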