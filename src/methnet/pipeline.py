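"""End-to-end orchestration: simulate -> assign -> landscape -> diffmeth ->
scan -> infer -> diffnet, with one global seed and a reproducibility manifest.

Each stage writes its outputs to a numbered sub-directory of the result
directory; ``manifest.json`` records package and library versions, every
parameter, the per-stage seeds derived from the global seed, and a SHA-256
checksum of every output file, so a re-run with the same configuration can
be verified byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from importlib.metadata import version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assign import candidate_pairs, confirm_pairs, filter_probes, pairs_to_frame
from .cohort import Cohort, CohortConfig, generate_cohort, read_cohort, write_cohort
from .diffmeth import differential_probes, stage_venn, top_differential
from .diffnet import (
    consistency_filter,
    differential_edges,
    gain_loss_table,
    rank_targets,
)
from .grn import InferenceParams, build_phenotype_network
from .landscape import conservation_matrix, exclusive_sets, state_table, venn_to_frame
from .motifs import candidate_regulators

log = logging.getLogger("methnet.pipeline")

PHENOTYPES = ("normal", "I", "II", "III", "IV")
TUMOR_STAGES = ("I", "II", "III", "IV")


@dataclass
class PipelineConfig:
    """All parameters of an end-to-end run."""

    out_dir: str = "methnet_results"
    cohort_dir: str | None = None       # load instead of simulating when set
    cohort: CohortConfig = field(default_factory=CohortConfig)
    half_window: int = 2000
    alpha: float = 0.05
    t_low: float = 0.25
    t_high: float = 0.75
    min_diff: float = 0.2
    trim: float = 0.10
    p_thresh: float = 1e-4
    inference: InferenceParams = field(default_factory=InferenceParams)
    k: int = 1000
    top_n: int = 10
    filter_order: str = "filter_first"  # or "rank_first"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", {})
        if "beta_modes" in cohort_raw:
            cohort_raw["beta_modes"] = tuple(cohort_raw["beta_modes"])
        inference_raw = raw.pop("inference", {})
        cfg = cls(**raw)
        seed = raw.get("seed", cfg.seed)
        cohort_raw.setdefault("seed", _stage_seed(seed, 0))
        return dataclasses.replace(
            cfg,
            cohort=CohortConfig(**cohort_raw),
            inference=InferenceParams(**inference_raw),
        )


def _stage_seed(global_seed: int, stage_index: int) -> int:
    """Deterministically derive a per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(global_seed), int(stage_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _setup_logging(out: Path) -> None:
    root = logging.getLogger("methnet")
    for h in list(root.handlers):  # avoid duplicates across runs in one process
        root.removeHandler(h)
        h.close()
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    root.addHandler(logging.StreamHandler(sys.stderr))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    manifest: dict = {
        "package": "methnet",
        "version": version("methnet"),
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "parameters": json.loads(
            json.dumps(dataclasses.asdict(config), default=str)
        ),
        "stages": [],
        "checksums": {},
    }

    def record(stage: str, files: dict[str, Path], stage_seed: int | None = None) -> None:
        manifest["stages"].append({"stage": stage, "seed": stage_seed})
        for name, path in files.items():
            manifest["checksums"][f"{stage}/{name}"] = _sha256(Path(path))
        log.info("stage %s complete (%d files)", stage, len(files))

    # 1. cohort -----------------------------------------------------------
    cohort_seed = config.cohort.seed
    if config.cohort_dir is not None:
        cohort = read_cohort(config.cohort_dir)
        log.info("loaded cohort from %s", config.cohort_dir)
    else:
        cohort = generate_cohort(config.cohort)
    files = write_cohort(cohort, out / "00_cohort")
    record("simulate", files, cohort_seed)

    # 2. probe-gene assignment -------------------------------------------
    retained = filter_probes(cohort.probes)
    probes_kept = cohort.probes[cohort.probes["probe_id"].isin(retained)]
    cands = candidate_pairs(probes_kept, cohort.genes, config.half_window)
    pair_objs, corr = confirm_pairs(
        cands, cohort.beta, cohort.expr, cohort.phenotypes, alpha=config.alpha
    )
    pairs = pairs_to_frame(pair_objs)
    adir = out / "01_assign"
    adir.mkdir(exist_ok=True)
    pairs.to_csv(adir / "pairs.tsv", sep="\t", index=False)
    corr.to_csv(adir / "correlations.tsv", sep="\t", index=False)
    record("assign", {"pairs": adir / "pairs.tsv", "correlations": adir / "correlations.tsv"})
    log.info(
        "assignment: %d retained probes, %d candidates, %d confirmed pairs "
        "(%d probes, %d genes)",
        len(retained), len(cands), len(pairs),
        pairs["probe_id"].nunique() if len(pairs) else 0,
        pairs["gene_id"].nunique() if len(pairs) else 0,
    )

    # 3. methylation landscape -------------------------------------------
    ldir = out / "02_landscape"
    ldir.mkdir(exist_ok=True)
    states = state_table(
        cohort.beta.loc[cohort.beta.index.isin(retained)],
        cohort.phenotypes, config.t_low, config.t_high,
    )
    cons = conservation_matrix(states)
    states.to_csv(ldir / "states.tsv", sep="\t", index_label="probe_id")
    cons.to_csv(ldir / "conservation.tsv", sep="\t")
    lfiles = {"states": ldir / "states.tsv", "conservation": ldir / "conservation.tsv"}
    for state in ("full", "unmethylated"):
        _, venn = exclusive_sets(states, pairs, state)
        path = ldir / f"venn_{state}.tsv"
        venn_to_frame(venn).to_csv(path, sep="\t", index=False)
        lfiles[f"venn_{state}"] = path
    record("landscape", lfiles)

    # 4. differential methylation ----------------------------------------
    ddir = out / "03_diffmeth"
    ddir.mkdir(exist_ok=True)
    dm: dict[str, pd.DataFrame] = {}
    dfiles = {}
    for stage in TUMOR_STAGES:
        dm[stage] = differential_probes(
            cohort.beta.loc[cohort.beta.index.isin(retained)],
            cohort.phenotypes, stage,
            alpha=config.alpha, min_diff=config.min_diff, trim=config.trim,
        )
        path = ddir / f"dm_{stage}.tsv"
        dm[stage].to_csv(path, sep="\t", index=False)
        dfiles[f"dm_{stage}"] = path
        hyper, hypo = top_differential(dm[stage], pairs, k=20)
        hyper.to_csv(ddir / f"top_hyper_{stage}.tsv", sep="\t", index=False)
        hypo.to_csv(ddir / f"top_hypo_{stage}.tsv", sep="\t", index=False)
        dfiles[f"top_hyper_{stage}"] = ddir / f"top_hyper_{stage}.tsv"
        dfiles[f"top_hypo_{stage}"] = ddir / f"top_hypo_{stage}.tsv"
    venns = stage_venn(dm, pairs)
    for direction, partition in venns.items():
        path = ddir / f"venn_{direction}.tsv"
        venn_to_frame(partition).to_csv(path, sep="\t", index=False)
        dfiles[f"venn_{direction}"] = path
    record("diffmeth", dfiles)

    # 5. motif scan -------------------------------------------------------
    sdir = out / "04_scan"
    sdir.mkdir(exist_ok=True)
    candidates = candidate_regulators(
        cohort.promoter_windows, pairs, cohort.motifs, p_thresh=config.p_thresh
    )
    candidates.hits.to_csv(sdir / "hits.tsv", sep="\t", index=False)
    edge_rows = pd.DataFrame(
        sorted(candidates.edges), columns=["tf", "target"]
    )
    edge_rows.to_csv(sdir / "candidate_edges.tsv", sep="\t", index=False)
    record("scan", {"hits": sdir / "hits.tsv", "candidate_edges": sdir / "candidate_edges.tsv"})
    log.info("scan: %d candidate edges over %d targets",
             len(edge_rows), len(candidates.targets))

    # 6. per-phenotype networks ------------------------------------------
    ndir = out / "05_networks"
    ndir.mkdir(exist_ok=True)
    nets = {}
    nfiles = {}
    manifest["network_seeds"] = {}
    for i, ph in enumerate(PHENOTYPES):
        ph_seed = _stage_seed(config.seed, 10 + i)
        nets[ph] = build_phenotype_network(
            cohort.expr, cohort.phenotypes, ph, candidates,
            params=config.inference, seed=ph_seed,
        )
        path = ndir / f"net_{ph}.tsv"
        nets[ph].edge_list().to_csv(path, sep="\t", index=False)
        nfiles[f"net_{ph}"] = path
        manifest["network_seeds"][ph] = ph_seed
    record("infer", nfiles)

    # 7. differential networks -------------------------------------------
    xdir = out / "06_diffnet"
    xdir.mkdir(exist_ok=True)
    xfiles = {}
    diff_nets: dict[str, pd.DataFrame] = {}
    for stage in TUMOR_STAGES:
        summary = consistency_filter(nets[stage], nets["normal"], dm[stage], pairs)
        retained_targets = summary.loc[summary["retained"], "target"]
        if config.filter_order == "filter_first":
            edges = differential_edges(
                nets[stage], nets["normal"], k=config.k, targets=retained_targets
            )
        else:
            edges = differential_edges(nets[stage], nets["normal"], k=config.k)
            edges = edges[edges["target"].isin(set(retained_targets))]
        diff_nets[stage] = edges
        gain, loss, subgraph = rank_targets(edges, retained_targets, config.top_n)
        for name, df in [
            (f"diff_{stage}", edges), (f"summary_{stage}", summary),
            (f"gain_targets_{stage}", gain), (f"loss_targets_{stage}", loss),
            (f"subgraph_{stage}", subgraph),
        ]:
            path = xdir / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=False)
            xfiles[name] = path
    gl = gain_loss_table(diff_nets)
    gl.to_csv(xdir / "gain_loss.tsv", sep="\t", index_label="direction")
    xfiles["gain_loss"] = xdir / "gain_loss.tsv"
    record("diffnet", xfiles)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline complete: %s", manifest_path)
    return manifest
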