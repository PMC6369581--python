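"""PWM scoring, scanning, DP p-values, candidate regulators, motif IO."""

import numpy as np
import pandas as pd
import pytest

from methnet import (
    Motif,
    candidate_regulators,
    logodds,
    read_jaspar,
    read_meme,
    scan_window,
    score_pvalue_table,
    write_meme,
)

COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s):
    return s.translate(COMP)[::-1]


def _one_hot(word):
    m = np.zeros((len(word), 4))
    for i, b in enumerate(word):
        m[i, "ACGT".index(b)] = 1.0
    return m


def _enumerate_scores(S):
    """Exact scores of all 4^L words (independent of the DP)."""
    scores = np.zeros(1)
    for row in S:
        scores = (scores[:, None] + row[None, :]).ravel()
    return scores


class TestLogOdds:
    def test_uniform_pfm_scores_zero(self):
        m = Motif("u", np.full((4, 4), 0.25), pseudocount=1e-9)
        assert np.allclose(logodds(m), 0.0, atol=1e-6)

    def test_one_hot_column_scores_two_bits(self):
        m = Motif("o", _one_hot("ACGT"), pseudocount=1e-12)
        S = logodds(m)
        assert S[0, 0] == pytest.approx(2.0, abs=1e-6)
        assert S[1, 1] == pytest.approx(2.0, abs=1e-6)

    def test_hand_computed_half_half_column(self):
        m = Motif("h", np.array([[0.5, 0.5, 0.0, 0.0]]), pseudocount=0.01)
        S = logodds(m)
        expected_hot = np.log2(((0.5 + 0.01) / 1.04) / 0.25)
        expected_cold = np.log2((0.01 / 1.04) / 0.25)
        assert S[0, 0] == pytest.approx(expected_hot)
        assert S[0, 2] == pytest.approx(expected_cold)

    def test_bad_background_raises(self):
        m = Motif("x", _one_hot("ACG"))
        with pytest.raises(ValueError):
            logodds(m, np.array([0.5, 0.5, 0.0, 0.0]))


class TestScanWindow:
    def test_consensus_scores_maximally_on_plus_strand(self):
        word = "ACGTG"
        m = Motif("c", _one_hot(word), pseudocount=1e-12)
        hits = scan_window("TT" + word + "AATT", m)
        best = max(hits, key=lambda h: h.score)
        assert (best.offset, best.strand) == (2, "+")
        assert best.score == pytest.approx(10.0, abs=1e-5)

    def test_strand_symmetry(self):
        word = "ACGTG"
        m = Motif("c", _one_hot(word), pseudocount=1e-12)
        seq = "TT" + word + "AATT"
        fwd_best = max(h.score for h in scan_window(seq, m))
        rc_best_hit = max(scan_window(_revcomp(seq), m), key=lambda h: h.score)
        assert rc_best_hit.score == pytest.approx(fwd_best, abs=1e-9)
        assert rc_best_hit.strand == "-"

    def test_matches_naive_rescoring(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 60))
        m = Motif("r", rng.dirichlet(np.ones(4), size=7), pseudocount=0.05)
        S = logodds(m)
        hits = {(h.offset, h.strand): h.score for h in scan_window(seq, m)}
        code = {b: i for i, b in enumerate("ACGT")}
        for off in range(len(seq) - 7 + 1):
            window = seq[off : off + 7]
            fwd = sum(S[i, code[b]] for i, b in enumerate(window))
            rev = sum(S[i, code[b]] for i, b in enumerate(_revcomp(window)))
            assert hits[(off, "+")] == pytest.approx(fwd, abs=1e-9)
            assert hits[(off, "-")] == pytest.approx(rev, abs=1e-9)

    def test_n_bases_score_as_background(self):
        m = Motif("c", _one_hot("AC"), pseudocount=1e-12)
        hits = {h.offset: h.score for h in scan_window("NN", m, both_strands=False)}
        assert hits[0] == pytest.approx(0.0)

    def test_short_sequence_yields_empty(self):
        m = Motif("c", _one_hot("ACGTA"))
        assert scan_window("ACG", m) == []


class TestScorePvalueTable:
    def test_one_hot_l3_max_pvalue(self):
        m = Motif("o", _one_hot("ACG"), pseudocount=1e-9)
        S = logodds(m)
        table = score_pvalue_table(S)
        assert table(S.max(axis=1).sum()) == pytest.approx(1 / 64)

    def test_minimum_score_has_p_one(self):
        m = Motif("o", _one_hot("ACG"), pseudocount=0.01)
        S = logodds(m)
        assert score_pvalue_table(S)(S.min(axis=1).sum()) == pytest.approx(1.0)

    def test_monotone_nonincreasing_in_score(self, rng):
        m = Motif("r", rng.dirichlet(np.ones(4), size=5), pseudocount=0.02)
        table = score_pvalue_table(logodds(m))
        qs = np.linspace(-10, 8, 50)
        ps = [table(q) for q in qs]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_dp_brackets_enumeration_for_short_motifs(self, rng):
        g = 1e-3
        for L in range(1, 7):
            m = Motif("r", rng.dirichlet(np.ones(4) * 0.7, size=L), pseudocount=0.01)
            S = logodds(m)
            scores = _enumerate_scores(S)
            table = score_pvalue_table(S, granularity=g)
            for q in rng.choice(scores, size=25):
                lo = (scores >= q + 2 * g * L).mean()
                hi = (scores >= q - 2 * g * L).mean()
                assert lo - 1e-12 <= table(q) <= hi + 1e-12

    def test_bad_granularity_raises(self):
        with pytest.raises(ValueError):
            score_pvalue_table(np.zeros((2, 4)), granularity=0.0)


class TestCandidateRegulators:
    def test_planted_consensus_creates_edge(self, rng):
        word = "ACGTACGT"
        m = Motif("TF1", _one_hot(word), pseudocount=1e-6)
        win = "".join(rng.choice(list("ACGT"), 40)) + word + "".join(
            rng.choice(list("ACGT"), 40)
        )
        pairs = pd.DataFrame({"probe_id": ["cg1"], "gene_id": ["g1"]})
        cand = candidate_regulators({"cg1": win}, pairs, [m])
        assert ("TF1", "g1") in cand.edges

    def test_any_probe_rule_with_two_probes(self, rng):
        word = "ACGTACGT"
        m = Motif("TF1", _one_hot(word), pseudocount=1e-6)
        scrambled = "".join(rng.choice(list("ACGT"), 88))
        planted = "".join(rng.choice(list("ACGT"), 40)) + word + "".join(
            rng.choice(list("ACGT"), 40)
        )
        pairs = pd.DataFrame(
            {"probe_id": ["cgA", "cgB"], "gene_id": ["g1", "g1"]}
        )
        cand = candidate_regulators({"cgA": scrambled, "cgB": planted}, pairs, [m])
        assert cand.targets["g1"] == {"TF1"}
        assert set(cand.hits["probe_id"]) == {"cgB"}

    def test_background_hit_rate_bounded(self):
        """Edges in scrambled windows appear at most at ~ p_thresh x positions."""
        word = "ACGTACGTAC"
        m = Motif("TF1", _one_hot(word), pseudocount=1e-6)
        n_windows, hits = 200, 0
        for seed in range(n_windows):
            rng = np.random.default_rng(seed)
            win = "".join(rng.choice(list("ACGT"), 201))
            pairs = pd.DataFrame({"probe_id": ["cg"], "gene_id": ["g"]})
            cand = candidate_regulators({"cg": win}, pairs, [m], p_thresh=1e-4)
            hits += len(cand.edges)
        # expected edge rate <= 2 strands * 192 offsets * 1e-4 ~ 0.04/window
        assert hits <= 25

    def test_probe_without_sequence_skipped(self):
        m = Motif("TF1", _one_hot("ACGTACGT"), pseudocount=1e-6)
        pairs = pd.DataFrame({"probe_id": ["missing"], "gene_id": ["g1"]})
        cand = candidate_regulators({}, pairs, [m])
        assert cand.edges == set()


class TestMotifIO:
    def test_meme_round_trip(self, tmp_path, small_cohort):
        path = tmp_path / "motifs.meme"
        write_meme(small_cohort.motifs, path)
        back = read_meme(path)
        assert [m.name for m in back] == [m.name for m in small_cohort.motifs]
        for a, b in zip(back, small_cohort.motifs):
            freq_b = b.matrix / b.matrix.sum(axis=1, keepdims=True)
            assert np.allclose(a.matrix, freq_b, atol=1e-5)

    def test_jaspar_reader(self, tmp_path):
        text = (
            ">MA0001.1 TFX\n"
            "A  [ 4 19  0 ]\n"
            "C  [16  0 20 ]\n"
            "G  [ 0  1  0 ]\n"
            "T  [ 0  0  0 ]\n"
        )
        path = tmp_path / "m.jaspar"
        path.write_text(text)
        (m,) = read_jaspar(path)
        assert m.name == "MA0001.1"
        assert m.matrix.shape == (3, 4)
        assert m.matrix[0, 1] == 16  # C counts land in column 1
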