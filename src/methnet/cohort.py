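"""Synthetic multi-phenotype methylation + expression cohorts with planted truth.

The generator emulates the statistical structure of a stomach-cancer-style
cohort: five phenotypes (normal and tumor stages I-IV), bimodal promoter
methylation (beta values), negatively coupled probe-gene pairs, and
TF->target regulation that is gated by promoter methylation so that
stage-specific methylation flips rewire edges.  Every planted feature is
returned as ground truth so downstream stages can be scored without any
external data.

Model summary
-------------
* Each probe has a methylation *mode* per phenotype, low (unmethylated) or
  high (methylated); samples draw beta from a Beta distribution centred on
  the mode mean with a common concentration.  This reproduces the familiar
  bimodal beta-value histogram.
* For a planted probe-gene pair, the gene's expression within each
  phenotype is built to have Pearson correlation ``-coupling_strength``
  with the probe's beta values (Spearman follows closely).
* Regulated targets receive a linear combination of their planted TFs'
  (standardised) expression; each TF term is multiplied by a smooth
  sigmoid gate of the target's promoter beta, so the edge is effectively
  absent in phenotypes where the promoter sits in the methylated mode.
* A subset of regulated-target promoters flips mode in exactly one tumor
  stage: high->low flips enable regulation there (edge *gain* vs normal),
  low->high flips silence it (*loss*).
* Each TF gets a synthetic motif (a sharply peaked PFM around a random
  consensus); the consensus is embedded, on a random strand, in the
  +/-100 bp promoter window of every target it regulates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import Motif, read_meme, write_meme

PHENOTYPES = ("normal", "I", "II", "III", "IV")
TUMOR_STAGES = ("I", "II", "III", "IV")

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror a desk-scale version of a TCGA-like stomach-cancer
    cohort: five phenotypes with the matched tumor sample counts (and the
    methylation-array normal count), bimodal beta values with modes near
    0.1 and 0.85, strong negative promoter coupling, and methylation-gated
    regulation with unit effect size.
    """

    n_probes: int = 500
    n_genes: int = 400
    n_tfs: int = 30
    samples_per_phenotype: Mapping[str, int] = field(
        default_factory=lambda: {"normal": 27, "I": 35, "II": 93, "III": 92, "IV": 23}
    )
    beta_modes: tuple[float, float] = (0.10, 0.85)
    beta_concentration: float = 20.0
    coupling_strength: float = 0.8
    n_planted_pairs: int = 50
    n_regulated_targets: int = 60
    tfs_per_target: int = 3
    n_flipped_promoters_per_stage: int = 10
    edge_effect_size: float = 1.0
    noise_sd: float = 0.3
    target_meth_coupling: float = 1.0
    motif_length: int = 8
    seed: int = 0
    # secondary knobs
    frac_high: float = 0.2          # baseline probability of the methylated mode
    frac_masked: float = 0.04       # fraction of intergenic probes flagged masked
    frac_sex: float = 0.04          # fraction of intergenic probes on chrX/chrY
    gate_midpoint: float = 0.5      # beta at which the TF gate is half open
    gate_width: float = 0.1         # softness of the gate
    window_halfwidth: int = 100     # promoter scan window is 2*hw + 1 bp
    probes_per_promoter: int = 1    # >1 exercises multi-probe assignment rules

    def __post_init__(self) -> None:
        counts = {
            "n_probes": self.n_probes,
            "n_genes": self.n_genes,
            "n_tfs": self.n_tfs,
            "n_planted_pairs": self.n_planted_pairs,
            "tfs_per_target": self.tfs_per_target,
            "motif_length": self.motif_length,
            "probes_per_promoter": self.probes_per_promoter,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.n_regulated_targets < 0 or self.n_flipped_promoters_per_stage < 0:
            raise ValueError("target/flip counts must be non-negative")
        if set(self.samples_per_phenotype) != set(PHENOTYPES):
            raise ValueError(
                f"samples_per_phenotype must cover exactly {set(PHENOTYPES)}"
            )
        if any(n <= 0 for n in self.samples_per_phenotype.values()):
            raise ValueError("all phenotype sample counts must be positive")
        low, high = self.beta_modes
        if not (0.0 <= low < high <= 1.0):
            raise ValueError("beta_modes must satisfy 0 <= low < high <= 1")
        if self.beta_concentration <= 0 or self.noise_sd <= 0:
            raise ValueError("beta_concentration and noise_sd must be positive")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.n_planted_pairs > self.n_genes:
            raise ValueError("n_planted_pairs cannot exceed n_genes")
        if self.n_tfs + self.n_planted_pairs + self.n_regulated_targets > self.n_genes:
            raise ValueError(
                "n_tfs + n_planted_pairs + n_regulated_targets must not exceed n_genes"
            )
        if self.n_probes < self.n_genes * self.probes_per_promoter:
            raise ValueError("need at least one probe per gene promoter")
        if self.motif_length > 2 * self.window_halfwidth + 1:
            raise ValueError("motif_length exceeds the promoter scan window")
        if 4 * self.n_flipped_promoters_per_stage > self.n_regulated_targets:
            raise ValueError(
                "4 * n_flipped_promoters_per_stage must not exceed n_regulated_targets"
            )


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    planted_pairs: set[tuple[str, str]]
    planted_diff_probes: dict[str, set[tuple[str, str]]]
    planted_edges: dict[str, set[tuple[str, str]]]
    rewired_edges: dict[str, set[tuple[str, str, str]]]


@dataclass
class Cohort:
    """In-memory synthetic cohort: matrices, annotations, sequences, truth."""

    config: CohortConfig | None
    beta: pd.DataFrame               # probes x samples, values in [0, 1]
    expr: pd.DataFrame               # genes x samples
    probes: pd.DataFrame             # probe_id, chrom, position, masked, sex_chrom
    genes: pd.DataFrame              # gene_id, chrom, tss, strand
    phenotypes: pd.Series            # sample id -> phenotype
    promoter_windows: dict[str, str]  # probe id -> window sequence
    motifs: list[Motif]
    truth: GroundTruth | None


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _sigmoid_gate(beta: np.ndarray, midpoint: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp((beta - midpoint) / width))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort with planted ground truth.

    Deterministic: identical configs (including seed) produce identical
    cohorts, byte for byte once written.
    """
    rng = np.random.default_rng(config.seed)
    low_mean, high_mean = config.beta_modes

    # ---- samples -------------------------------------------------------
    sample_ids: list[str] = []
    sample_pheno: list[str] = []
    for ph in PHENOTYPES:
        for i in range(config.samples_per_phenotype[ph]):
            sample_ids.append(f"{ph}-{i:03d}")
            sample_pheno.append(ph)
    phenotypes = pd.Series(sample_pheno, index=sample_ids, name="phenotype")
    pheno_cols = {ph: np.flatnonzero(phenotypes.to_numpy() == ph) for ph in PHENOTYPES}

    # ---- genes ---------------------------------------------------------
    gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]
    chroms = [f"chr{(i % 8) + 1}" for i in range(config.n_genes)]
    tss = [100_000 + 20_000 * (i // 8) for i in range(config.n_genes)]
    strands = rng.choice(["+", "-"], size=config.n_genes)
    genes = pd.DataFrame(
        {"gene_id": gene_ids, "chrom": chroms, "tss": tss, "strand": strands}
    )

    tf_ids = gene_ids[: config.n_tfs]
    non_tf = gene_ids[config.n_tfs :]
    shuffled = list(rng.permutation(non_tf))
    pair_genes = sorted(shuffled[: config.n_planted_pairs])
    regulated = sorted(
        shuffled[config.n_planted_pairs : config.n_planted_pairs + config.n_regulated_targets]
    )

    # ---- probes --------------------------------------------------------
    ppp = config.probes_per_promoter
    probe_rows: list[dict] = []
    promoter_probe: dict[str, list[str]] = {}
    idx = 0
    for g, chrom, pos in zip(gene_ids, chroms, tss):
        promoter_probe[g] = []
        for _ in range(ppp):
            pid = f"cg{idx:05d}"
            offset = int(rng.integers(-1500, 1501))
            probe_rows.append(
                {"probe_id": pid, "chrom": chrom, "position": pos + offset,
                 "masked": False, "sex_chrom": False}
            )
            promoter_probe[g].append(pid)
            idx += 1
    n_extra = config.n_probes - idx
    n_masked = int(round(config.frac_masked * n_extra))
    n_sex = int(round(config.frac_sex * n_extra))
    for j in range(n_extra):
        pid = f"cg{idx:05d}"
        if j < n_sex:
            chrom = "chrX" if j % 2 == 0 else "chrY"
        else:
            chrom = f"chr{int(rng.integers(1, 9))}"
        probe_rows.append(
            {"probe_id": pid, "chrom": chrom,
             "position": int(rng.integers(5_000_000, 9_000_000)),
             "masked": n_sex <= j < n_sex + n_masked, "sex_chrom": j < n_sex}
        )
        idx += 1
    probes = pd.DataFrame(probe_rows)
    probe_ids = probes["probe_id"].tolist()

    # first promoter probe of each gene anchors coupling / gating / motifs
    anchor = {g: promoter_probe[g][0] for g in gene_ids}

    # ---- rewiring design ----------------------------------------------
    reg_perm = list(rng.permutation(regulated))
    nf = config.n_flipped_promoters_per_stage
    rewired_by_stage: dict[str, list[tuple[str, str]]] = {}
    gain_targets: set[str] = set()
    for k, stage in enumerate(TUMOR_STAGES):
        group = reg_perm[k * nf : (k + 1) * nf]
        labelled = []
        for j, t in enumerate(group):
            direction = "gain" if j < (nf + 1) // 2 else "loss"
            if direction == "gain":
                gain_targets.add(t)
            labelled.append((t, direction))
        rewired_by_stage[stage] = labelled

    # ---- per-probe, per-phenotype methylation modes --------------------
    probe_index = {p: i for i, p in enumerate(probe_ids)}
    base_high = rng.random(config.n_probes) < config.frac_high
    for t in regulated:
        base_high[probe_index[anchor[t]]] = t in gain_targets
    mode_high = np.tile(base_high[:, None], (1, len(PHENOTYPES)))
    ph_index = {ph: i for i, ph in enumerate(PHENOTYPES)}
    planted_diff: dict[str, set[tuple[str, str]]] = {s: set() for s in TUMOR_STAGES}
    for stage, labelled in rewired_by_stage.items():
        for t, direction in labelled:
            pi = probe_index[anchor[t]]
            flipped = not base_high[pi]
            mode_high[pi, ph_index[stage]] = flipped
            planted_diff[stage].add((anchor[t], "hyper" if flipped else "hypo"))

    # ---- beta values ---------------------------------------------------
    mode_mean = np.where(mode_high, high_mean, low_mean)   # probes x phenotypes
    mean_by_sample = mode_mean[:, [ph_index[p] for p in sample_pheno]]
    conc = config.beta_concentration
    beta_vals = rng.beta(mean_by_sample * conc, (1.0 - mean_by_sample) * conc)
    beta = pd.DataFrame(beta_vals, index=probe_ids, columns=sample_ids)

    # ---- expression ----------------------------------------------------
    baseline = rng.uniform(4.0, 8.0, size=config.n_genes)
    expr_vals = baseline[:, None] + rng.normal(size=(config.n_genes, len(sample_ids)))
    expr = pd.DataFrame(expr_vals, index=gene_ids, columns=sample_ids)
    gene_row = {g: i for i, g in enumerate(gene_ids)}

    # planted probe-gene pairs: phenotype-wise correlation -coupling_strength
    c = config.coupling_strength
    for g in pair_genes:
        b = beta.loc[anchor[g]].to_numpy()
        vals = np.empty(len(sample_ids))
        eps = rng.normal(size=len(sample_ids))
        for ph, cols in pheno_cols.items():
            bb = b[cols]
            sd = bb.std()
            z = (bb - bb.mean()) / sd if sd > 0 else np.zeros_like(bb)
            vals[cols] = -c * z + np.sqrt(max(0.0, 1.0 - c * c)) * eps[cols]
        expr.iloc[gene_row[g]] = baseline[gene_row[g]] + vals

    # regulated targets: methylation-gated linear TF effects plus a direct
    # silencing term (promoter methylation lowers expression), so these
    # targets are themselves confirmable probe-gene pairs
    planted_tfs: dict[str, list[str]] = {}
    for t in regulated:
        planted_tfs[t] = sorted(
            rng.choice(tf_ids, size=config.tfs_per_target, replace=False)
        )
        b = beta.loc[anchor[t]].to_numpy()
        gate = _sigmoid_gate(b, config.gate_midpoint, config.gate_width)
        signal = np.zeros(len(sample_ids))
        for tf in planted_tfs[t]:
            z_tf = expr.iloc[gene_row[tf]].to_numpy() - baseline[gene_row[tf]]
            signal += config.edge_effect_size * gate * z_tf
        for ph, cols in pheno_cols.items():
            bb = b[cols]
            sd = bb.std()
            if sd > 0:
                signal[cols] -= config.target_meth_coupling * (bb - bb.mean()) / sd
        expr.iloc[gene_row[t]] = (
            baseline[gene_row[t]] + signal
            + rng.normal(scale=config.noise_sd, size=len(sample_ids))
        )

    # ---- ground-truth edge sets ---------------------------------------
    planted_edges: dict[str, set[tuple[str, str]]] = {ph: set() for ph in PHENOTYPES}
    for t in regulated:
        pi = probe_index[anchor[t]]
        for ph in PHENOTYPES:
            if not mode_high[pi, ph_index[ph]]:  # gate open in the low mode
                planted_edges[ph].update((tf, t) for tf in planted_tfs[t])
    rewired_edges: dict[str, set[tuple[str, str, str]]] = {}
    for stage, labelled in rewired_by_stage.items():
        rewired_edges[stage] = {
            (tf, t, direction) for t, direction in labelled for tf in planted_tfs[t]
        }

    # ---- motifs --------------------------------------------------------
    motifs: list[Motif] = []
    consensus: dict[str, str] = {}
    for tf in tf_ids:
        word = "".join(rng.choice(_BASES, size=config.motif_length))
        consensus[tf] = word
        pfm = np.full((config.motif_length, 4), 0.05)
        for i, b in enumerate(word):
            pfm[i, "ACGT".index(b)] = 0.85
        motifs.append(Motif(name=tf, matrix=pfm, source="synthetic"))

    # ---- promoter window sequences ------------------------------------
    win_len = 2 * config.window_halfwidth + 1
    windows: dict[str, str] = {}
    for g in gene_ids:
        for pid in promoter_probe[g]:
            windows[pid] = "".join(rng.choice(_BASES, size=win_len))
    for t in regulated:
        pid = anchor[t]
        seq = list(windows[pid])
        occupied: list[tuple[int, int]] = []
        for tf in planted_tfs[t]:
            word = consensus[tf]
            if rng.random() < 0.5:
                word = _revcomp(word)
            off = None
            for _ in range(30):  # avoid clobbering previously planted sites
                cand = int(rng.integers(0, win_len - len(word) + 1))
                if all(cand + len(word) <= a or cand >= b for a, b in occupied):
                    off = cand
                    break
            if off is None:
                off = int(rng.integers(0, win_len - len(word) + 1))
            occupied.append((off, off + len(word)))
            seq[off : off + len(word)] = list(word)
        windows[pid] = "".join(seq)

    truth = GroundTruth(
        planted_pairs={(anchor[g], g) for g in pair_genes}
        | {(anchor[t], t) for t in regulated},
        planted_diff_probes=planted_diff,
        planted_edges=planted_edges,
        rewired_edges=rewired_edges,
    )
    return Cohort(
        config=config,
        beta=beta,
        expr=expr,
        probes=probes,
        genes=genes,
        phenotypes=phenotypes,
        promoter_windows=windows,
        motifs=motifs,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort to plain-text files; returns the file map.

    Matrices go to TSV (first column = feature id), annotations to BED
    (0-based half-open), promoter windows to FASTA, motifs to MEME
    minimal format, and the ground truth to TSV tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    files["beta"] = out / "beta.tsv"
    cohort.beta.to_csv(files["beta"], sep="\t", index_label="probe_id")
    files["expr"] = out / "expr.tsv"
    cohort.expr.to_csv(files["expr"], sep="\t", index_label="gene_id")

    files["probes"] = out / "probes.bed"
    pb = cohort.probes.copy()
    probe_bed = pd.DataFrame(
        {
            "chrom": pb["chrom"],
            "start": pb["position"],
            "end": pb["position"] + 1,
            "name": pb["probe_id"],
            "score": 0,
            "strand": "+",
            "masked": pb["masked"].astype(int),
            "sex_chrom": pb["sex_chrom"].astype(int),
        }
    )
    probe_bed.to_csv(files["probes"], sep="\t", header=False, index=False)

    files["genes"] = out / "genes.bed"
    gb = cohort.genes
    gene_bed = pd.DataFrame(
        {
            "chrom": gb["chrom"],
            "start": gb["tss"],
            "end": gb["tss"] + 1,
            "name": gb["gene_id"],
            "score": 0,
            "strand": gb["strand"],
        }
    )
    gene_bed.to_csv(files["genes"], sep="\t", header=False, index=False)

    files["phenotypes"] = out / "phenotypes.tsv"
    cohort.phenotypes.rename_axis("sample_id").to_frame().to_csv(
        files["phenotypes"], sep="\t"
    )

    files["promoters"] = out / "promoters.fa"
    records = [
        SeqRecord(Seq(seq), id=pid, description="")
        for pid, seq in cohort.promoter_windows.items()
    ]
    SeqIO.write(records, files["promoters"], "fasta")

    files["motifs"] = out / "motifs.meme"
    write_meme(cohort.motifs, files["motifs"])

    if cohort.truth is not None:
        tdir = out / "truth"
        tdir.mkdir(exist_ok=True)
        files["planted_pairs"] = tdir / "planted_pairs.tsv"
        pd.DataFrame(
            sorted(cohort.truth.planted_pairs), columns=["probe_id", "gene_id"]
        ).to_csv(files["planted_pairs"], sep="\t", index=False)
        files["planted_diff_probes"] = tdir / "planted_diff_probes.tsv"
        rows = [
            {"stage": s, "probe_id": p, "direction": d}
            for s in sorted(cohort.truth.planted_diff_probes)
            for p, d in sorted(cohort.truth.planted_diff_probes[s])
        ]
        pd.DataFrame(rows, columns=["stage", "probe_id", "direction"]).to_csv(
            files["planted_diff_probes"], sep="\t", index=False
        )
        files["planted_edges"] = tdir / "planted_edges.tsv"
        rows = [
            {"phenotype": ph, "tf": tf, "target": t}
            for ph in sorted(cohort.truth.planted_edges)
            for tf, t in sorted(cohort.truth.planted_edges[ph])
        ]
        pd.DataFrame(rows, columns=["phenotype", "tf", "target"]).to_csv(
            files["planted_edges"], sep="\t", index=False
        )
        files["rewired_edges"] = tdir / "rewired_edges.tsv"
        rows = [
            {"stage": s, "tf": tf, "target": t, "direction": d}
            for s in sorted(cohort.truth.rewired_edges)
            for tf, t, d in sorted(cohort.truth.rewired_edges[s])
        ]
        pd.DataFrame(rows, columns=["stage", "tf", "target", "direction"]).to_csv(
            files["rewired_edges"], sep="\t", index=False
        )

    if cohort.config is not None:
        files["config"] = out / "config.yaml"
        cfg = dataclasses.asdict(cohort.config)
        cfg["samples_per_phenotype"] = dict(cfg["samples_per_phenotype"])
        cfg["beta_modes"] = list(cfg["beta_modes"])
        files["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    return files


def read_cohort(in_dir: str | Path) -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    d = Path(in_dir)
    beta = pd.read_csv(d / "beta.tsv", sep="\t", index_col=0)
    beta.index.name = None
    expr = pd.read_csv(d / "expr.tsv", sep="\t", index_col=0)
    expr.index.name = None
    probe_bed = pd.read_csv(
        d / "probes.bed", sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand", "masked", "sex_chrom"],
    )
    probes = pd.DataFrame(
        {
            "probe_id": probe_bed["name"],
            "chrom": probe_bed["chrom"],
            "position": probe_bed["start"],
            "masked": probe_bed["masked"].astype(bool),
            "sex_chrom": probe_bed["sex_chrom"].astype(bool),
        }
    )
    gene_bed = pd.read_csv(
        d / "genes.bed", sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    genes = pd.DataFrame(
        {
            "gene_id": gene_bed["name"],
            "chrom": gene_bed["chrom"],
            "tss": gene_bed["start"],
            "strand": gene_bed["strand"],
        }
    )
    phenotypes = pd.read_csv(d / "phenotypes.tsv", sep="\t", index_col=0)["phenotype"]
    phenotypes.index.name = None
    windows = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(d / "promoters.fa"), "fasta")
    }
    motifs = read_meme(d / "motifs.meme")

    truth = None
    tdir = d / "truth"
    if tdir.is_dir():
        pairs = pd.read_csv(tdir / "planted_pairs.tsv", sep="\t")
        diff = pd.read_csv(tdir / "planted_diff_probes.tsv", sep="\t")
        edges = pd.read_csv(tdir / "planted_edges.tsv", sep="\t")
        rewired = pd.read_csv(tdir / "rewired_edges.tsv", sep="\t")
        truth = GroundTruth(
            planted_pairs={(r.probe_id, r.gene_id) for r in pairs.itertuples()},
            planted_diff_probes={
                s: {(r.probe_id, r.direction) for r in g.itertuples()}
                for s, g in diff.groupby("stage")
            },
            planted_edges={
                ph: {(r.tf, r.target) for r in g.itertuples()}
                for ph, g in edges.groupby("phenotype")
            },
            rewired_edges={
                s: {(r.tf, r.target, r.direction) for r in g.itertuples()}
                for s, g in rewired.groupby("stage")
            },
        )

    config = None
    cfg_path = d / "config.yaml"
    if cfg_path.exists():
        raw = yaml.safe_load(cfg_path.read_text())
        raw["beta_modes"] = tuple(raw["beta_modes"])
        config = CohortConfig(**raw)
    return Cohort(
        config=config,
        beta=beta,
        expr=expr,
        probes=probes,
        genes=genes,
        phenotypes=phenotypes,
        promoter_windows=windows,
        motifs=motifs,
        truth=truth,
    )
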