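"""PWM motif scanning with exact dynamic-programming p-values.

A from-scratch scanner in the FIMO tradition: position frequency matrices
are converted to log-odds scores (bits) against a 0-order background, every
offset of a promoter window is scored on both strands, and the p-value of a
score — the probability that a random background-distributed L-mer scores at
least as high — is computed exactly by dynamic programming over a
discretized score lattice.

Conventions
-----------
* Alphabet order is A, C, G, T; ``N`` contributes 0 to a score
  (background-equivalent).
* Scores are log2 ratios (bits) of the pseudocount-regularized position
  frequencies over the background.
* Minus-strand matches are reported at their leftmost plus-strand
  coordinate.
* For both-strand scanning the per-hit p-value is Bonferroni-combined over
  strands (``min(1, 2p)``) before thresholding.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

_ALPHABET = "ACGT"
_CODE = {b: i for i, b in enumerate("ACGT")}
_CODE["N"] = 4
_COMP = np.array([3, 2, 1, 0])  # A<->T, C<->G

UNIFORM_BACKGROUND = np.full(4, 0.25)


@dataclass
class Motif:
    """A TF binding motif as an L x 4 position frequency matrix.

    ``matrix`` may hold counts or frequencies; rows are normalized (and
    pseudocount-regularized) on scoring.
    """

    name: str
    matrix: np.ndarray
    pseudocount: float = 0.01
    source: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or len(self.matrix) < 1:
            raise ValueError("motif matrix must be L x 4 with L >= 1")
        if (self.matrix < 0).any():
            raise ValueError("motif matrix entries must be non-negative")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")

    def __len__(self) -> int:
        return len(self.matrix)

    @property
    def frequencies(self) -> np.ndarray:
        """Row-normalized, pseudocount-regularized frequencies (rows sum to 1)."""
        rows = self.matrix / self.matrix.sum(axis=1, keepdims=True)
        return (rows + self.pseudocount) / (1.0 + 4.0 * self.pseudocount)

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.matrix.argmax(axis=1))


@dataclass
class MotifHit:
    tf_name: str
    probe_id: str | None
    offset: int          # leftmost position in plus-strand coordinates
    strand: str          # '+' or '-'
    score: float         # log-odds, bits
    p: float | None = None  # single-strand p-value of the score


def _validate_background(background: np.ndarray | None) -> np.ndarray:
    if background is None:
        return UNIFORM_BACKGROUND.copy()
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any():
        raise ValueError("background must be a strictly positive 4-vector")
    if abs(bg.sum() - 1.0) > 1e-8:
        raise ValueError("background must sum to 1")
    return bg


def logodds(motif: Motif, background: np.ndarray | None = None) -> np.ndarray:
    """L x 4 log2 score matrix of the regularized PFM against the background."""
    bg = _validate_background(background)
    return np.log2(motif.frequencies / bg)


def encode(seq: str) -> np.ndarray:
    """Map a DNA string over {A,C,G,T,N} (case-insensitive) to integer codes."""
    try:
        return np.fromiter((_CODE[b] for b in seq.upper()), dtype=np.int64, count=len(seq))
    except KeyError as exc:  # pragma: no cover - message only
        raise ValueError(f"invalid base {exc} in sequence") from None


def _window_scores(codes: np.ndarray, smat: np.ndarray) -> np.ndarray:
    """Scores of every offset of ``codes`` under score matrix ``smat`` (N -> 0)."""
    L = len(smat)
    ext = np.hstack([smat, np.zeros((L, 1))])  # column 4 = N
    wins = np.lib.stride_tricks.sliding_window_view(codes, L)
    return ext[np.arange(L)[None, :], wins].sum(axis=1)


def scan_window(
    seq: str,
    motif: Motif,
    background: np.ndarray | None = None,
    both_strands: bool = True,
    pvalues: "ScoreDistribution | None" = None,
    probe_id: str | None = None,
) -> list[MotifHit]:
    """Score every offset of ``seq`` (and its reverse complement).

    Returns one hit per (offset, strand) with the log-odds score; if a
    :class:`ScoreDistribution` is supplied each hit also carries its
    single-strand p-value.  Sequences shorter than the motif yield an
    empty list.
    """
    smat = logodds(motif, background)
    L = len(smat)
    if len(seq) < L:
        return []
    codes = encode(seq)
    hits: list[MotifHit] = []
    strands = [("+", smat)]
    if both_strands:
        # scoring the + sequence with the reverse-complemented matrix is
        # equivalent to scoring the reverse complement with the original
        strands.append(("-", smat[::-1][:, _COMP]))
    for strand, mat in strands:
        scores = _window_scores(codes, mat)
        for off, s in enumerate(scores):
            hits.append(
                MotifHit(
                    tf_name=motif.name,
                    probe_id=probe_id,
                    offset=off,
                    strand=strand,
                    score=float(s),
                    p=float(pvalues(s)) if pvalues is not None else None,
                )
            )
    return hits


@dataclass
class ScoreDistribution:
    """Exact null distribution of a PWM score on a discretized lattice.

    ``sf[j]`` is the probability that a random background L-mer scores at
    least ``(offset + j) * granularity`` bits.  Queries allow a slack of
    one lattice unit per motif position to absorb per-position rounding.
    """

    granularity: float
    offset: int
    sf: np.ndarray
    length: int

    def __call__(self, score: float) -> float:
        idx = int(round(score / self.granularity)) - self.offset - self.length
        idx = min(max(idx, 0), len(self.sf) - 1)
        return float(self.sf[idx])


def score_pvalue_table(
    score_matrix: np.ndarray,
    background: np.ndarray | None = None,
    granularity: float = 1e-3,
) -> ScoreDistribution:
    """Exact score -> p-value map by DP over the discretized score lattice.

    The distribution of the total score of a random background L-mer is
    built position by position as a convolution of the per-position score
    distributions, each rounded to ``granularity`` bits.
    """
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    bg = _validate_background(background)
    smat = np.asarray(score_matrix, dtype=float)
    if not np.isfinite(smat).all():
        raise ValueError("score matrix must be finite")
    ints = np.round(smat / granularity).astype(np.int64)
    lo = int(ints.min(axis=1).sum())
    hi = int(ints.max(axis=1).sum())
    dist = np.zeros(hi - lo + 1)
    dist[0] = 1.0
    cur_lo = 0
    width = 1
    for row in ints:
        rmin = int(row.min())
        new_width = width + int(row.max()) - rmin
        new = np.zeros(new_width)
        for b in range(4):
            shift = int(row[b]) - rmin
            new[shift : shift + width] += bg[b] * dist[:width]
        dist[:new_width] = new
        dist[new_width:] = 0.0
        width = new_width
        cur_lo += rmin
    assert cur_lo == lo and width == hi - lo + 1
    sf = np.cumsum(dist[:width][::-1])[::-1]
    np.clip(sf, 0.0, 1.0, out=sf)
    return ScoreDistribution(
        granularity=granularity, offset=lo, sf=sf, length=len(smat)
    )


@dataclass
class CandidateEdgeSet:
    """Motif-permitted TF -> target candidate edges with supporting hits."""

    targets: dict[str, set[str]]      # target gene -> candidate TFs
    hits: pd.DataFrame                # tf, probe_id, gene_id, offset, strand, score, p

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {(tf, t) for t, tfs in self.targets.items() for tf in tfs}

    def to_mask(self, tf_order: list[str], target_order: list[str]) -> pd.DataFrame:
        mask = pd.DataFrame(False, index=tf_order, columns=target_order)
        for t, tfs in self.targets.items():
            for tf in tfs:
                if tf in mask.index and t in mask.columns:
                    mask.loc[tf, t] = True
        return mask

    @classmethod
    def full(cls, tfs: Iterable[str], targets: Iterable[str]) -> "CandidateEdgeSet":
        """All-pairs candidate set (no motif restriction), self-loops excluded."""
        tfs = list(tfs)
        mapping = {t: {tf for tf in tfs if tf != t} for t in targets}
        empty = pd.DataFrame(
            columns=["tf", "probe_id", "gene_id", "offset", "strand", "score", "p"]
        )
        return cls(targets=mapping, hits=empty)


def candidate_regulators(
    windows: Mapping[str, str],
    pairs: pd.DataFrame,
    motifs: Iterable[Motif],
    p_thresh: float = 1e-4,
    background: np.ndarray | None = None,
    both_strands: bool = True,
    granularity: float = 1e-3,
) -> CandidateEdgeSet:
    """Candidate TF -> gene edges from motif hits in assigned-probe windows.

    A TF becomes a candidate regulator of a gene if any window of a probe
    assigned to the gene (per ``pairs`` with columns probe_id, gene_id)
    contains a motif occurrence with strand-combined p-value below
    ``p_thresh``.  Probes without a window sequence are skipped.
    """
    bg = _validate_background(background)
    probe_genes: dict[str, list[str]] = {}
    for row in pairs.itertuples():
        probe_genes.setdefault(row.probe_id, []).append(row.gene_id)
    scanned = [(p, encode(windows[p])) for p in sorted(probe_genes) if p in windows]

    n_strands = 2 if both_strands else 1
    records: list[dict] = []
    targets: dict[str, set[str]] = {}
    for motif in motifs:
        smat = logodds(motif, bg)
        table = score_pvalue_table(smat, bg, granularity)
        mats = [("+", smat)]
        if both_strands:
            mats.append(("-", smat[::-1][:, _COMP]))
        for probe_id, codes in scanned:
            if len(codes) < len(smat):
                continue
            for strand, mat in mats:
                scores = _window_scores(codes, mat)
                idxs = np.clip(
                    np.round(scores / table.granularity).astype(np.int64)
                    - table.offset
                    - table.length,
                    0,
                    len(table.sf) - 1,
                )
                ps = table.sf[idxs]
                for off in np.flatnonzero(
                    np.minimum(1.0, n_strands * ps) < p_thresh
                ):
                    for gene in probe_genes[probe_id]:
                        targets.setdefault(gene, set()).add(motif.name)
                        records.append(
                            {
                                "tf": motif.name,
                                "probe_id": probe_id,
                                "gene_id": gene,
                                "offset": int(off),
                                "strand": strand,
                                "score": float(scores[off]),
                                "p": float(ps[off]),
                            }
                        )
    hits = pd.DataFrame(
        records, columns=["tf", "probe_id", "gene_id", "offset", "strand", "score", "p"]
    )
    return CandidateEdgeSet(targets=targets, hits=hits)


# ---------------------------------------------------------------------------
# motif file formats
# ---------------------------------------------------------------------------

def write_meme(
    motifs: Iterable[Motif],
    path: str | Path,
    background: np.ndarray | None = None,
) -> None:
    """Write motifs in MEME minimal format (probability matrices)."""
    bg = _validate_background(background)
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {f:.6f}" for b, f in zip(_ALPHABET, bg)),
        "",
    ]
    for m in motifs:
        freqs = m.matrix / m.matrix.sum(axis=1, keepdims=True)
        lines.append(f"MOTIF {m.name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {len(m)} nsites= 20 E= 0"
        )
        for row in freqs:
            lines.append(" " + " ".join(f"{v:.6f}" for v in row))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def read_meme(path: str | Path) -> list[Motif]:
    """Read motifs from MEME minimal format."""
    motifs: list[Motif] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                i += 1
            if i >= len(lines):
                raise ValueError(f"motif {name}: missing probability matrix")
            m = re.search(r"w=\s*(\d+)", lines[i])
            if m is None:
                raise ValueError(f"motif {name}: matrix header lacks w=")
            width = int(m.group(1))
            rows = []
            for j in range(width):
                rows.append([float(x) for x in lines[i + 1 + j].split()[:4]])
            motifs.append(Motif(name=name, matrix=np.array(rows), source=str(path)))
            i += width + 1
        else:
            i += 1
    return motifs


def read_jaspar(path: str | Path) -> list[Motif]:
    """Read motifs from JASPAR PFM format (``>id name`` + 4 count rows)."""
    motifs: list[Motif] = []
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"expected header line, got: {lines[i]!r}")
        name = lines[i][1:].split()[0]
        rows = {}
        for j in range(4):
            parts = lines[i + 1 + j].replace("[", " ").replace("]", " ").split()
            rows[parts[0].upper()] = [float(x) for x in parts[1:]]
        matrix = np.array([rows[b] for b in _ALPHABET]).T
        motifs.append(Motif(name=name, matrix=matrix, source=str(path)))
        i += 5
    return motifs
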