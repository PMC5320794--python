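"""Forward/Viterbi DP against the enumeration oracle, plus the bias mask."""
import math

import numpy as np
import pytest

from lpmominer.hmm import NullModel, ProfileHMM
from lpmominer.scoring import (bias_mask, bit_score, forward, forward_batch,
                               encode, null_logprob, score, viterbi)

from helpers_oracle import enumerate_paths, random_small_model


def single_path_model(p_flank=0.0, e_letter="A", alphabet="ACGT"):
    """M=1 model that deterministically emits one letter."""
    K = len(alphabet)
    q = np.full(K, 1.0 / K)
    mat = np.zeros((2, K))
    mat[0] = q
    mat[1, alphabet.index(e_letter)] = 1.0
    ins = np.tile(q, (2, 1))
    t = {key: np.zeros(2) for key in
         ("MM", "MI", "MD", "ME", "IM", "II", "ID", "DM", "DI", "DD")}
    t["ME"][1] = 1.0
    return ProfileHMM(alphabet=alphabet, match_emissions=mat,
                      insert_emissions=ins, transitions=t,
                      null=NullModel(q, 0.5, alphabet), epsilon=0.0,
                      p_flank=p_flank)


class TestNullModel:
    def test_direct_arithmetic(self):
        null = NullModel(np.full(20, 0.05), 0.5)
        assert np.isclose(null_logprob("A", null), math.log(0.5 * 0.5 * 0.05))

    def test_empty_sequence(self):
        null = NullModel(np.full(20, 0.05), 0.3)
        assert np.isclose(null_logprob("", null), math.log(0.7))

    def test_appending_recurrence(self):
        null = NullModel.standard()
        base = null_logprob("ACD", null)
        ext = null_logprob("ACDG", null)
        g = null.alphabet.index("G")
        assert np.isclose(ext - base, math.log(null.p1 * null.q[g]))


class TestDPOracle:
    def test_single_path_identity(self):
        m = single_path_model()
        assert abs(forward(m, "A")) < 1e-12
        lv, path = viterbi(m, "A")
        assert abs(lv) < 1e-12
        kinds = [s[0] for s in path.steps]
        assert kinds == ["B", "M", "E"]

    def test_forward_and_viterbi_match_enumeration(self):
        rng = np.random.default_rng(123)
        for _ in range(60):
            m = random_small_model(rng)
            L = int(rng.integers(0, 7))
            x = rng.integers(0, 4, size=L)
            seq = "".join("ACGT"[i] for i in x)
            lf_or, lv_or = enumerate_paths(m, list(x))
            lf, (lv, path) = forward(m, seq), viterbi(m, seq)
            if math.isinf(lf_or):
                assert math.isinf(lf)
                continue
            assert abs(lf - lf_or) < 1e-9
            assert abs(lv - lv_or) < 1e-9
            # the returned path is itself an argmax: recompute its probability
            assert path_logprob(m, path, x) == pytest.approx(lv, abs=1e-9)

    def test_forward_at_least_viterbi(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            m = random_small_model(rng)
            L = int(rng.integers(1, 7))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=L))
            lf = forward(m, seq)
            lv, _ = viterbi(m, seq)
            assert lf >= lv - 1e-12

    def test_batch_matches_scalar(self):
        rng = np.random.default_rng(7)
        m = random_small_model(rng, M=4)
        X = rng.integers(0, 4, size=(20, 6))
        batch = forward_batch(m, X)
        for i in range(20):
            seq = "".join("ACGT"[j] for j in X[i])
            assert np.isclose(batch[i], forward(m, seq), atol=1e-10)

    def test_total_probability_bounded(self):
        from itertools import product

        rng = np.random.default_rng(11)
        m = random_small_model(rng, M=2)
        for L in (1, 2, 3):
            total = sum(math.exp(forward(m, "".join(s)))
                        for s in product("ACGT", repeat=L))
            assert total <= 1.0 + 1e-9


class TestViterbiTies:
    def test_duplicate_optimum_prefers_match_state(self):
        # two match states with identical emissions; a 1-residue sequence can
        # enter at node 1 or node 2 with equal probability -> lower node wins
        K = 4
        q = np.full(K, 0.25)
        mat = np.zeros((3, K))
        mat[0] = q
        mat[1] = mat[2] = [1.0, 0.0, 0.0, 0.0]
        ins = np.tile(q, (3, 1))
        t = {key: np.zeros(3) for key in
             ("MM", "MI", "MD", "ME", "IM", "II", "ID", "DM", "DI", "DD")}
        # both 1-residue paths (enter at node 1 and exit, or at node 2)
        # then have probability (1/2) * 1 * 1 -- an exact tie
        t["ME"][1] = 1.0
        t["IM"][1] = 1.0
        t["ME"][2] = 1.0
        m = ProfileHMM(alphabet="ACGT", match_emissions=mat,
                       insert_emissions=ins, transitions=t,
                       null=NullModel(q, 0.5, "ACGT"), epsilon=0.5,
                       p_flank=0.0)
        _, path = viterbi(m, "A")
        m_steps = [s for s in path.steps if s[0] == "M"]
        assert m_steps == [("M", 1, 1)]


class TestBitScore:
    def test_null_samples_score_nonpositive_on_average(self, calibrated_model):
        rng = np.random.default_rng(42)
        m = calibrated_model
        X = rng.choice(m.K, size=(200, 120), p=m.null.q)
        from lpmominer.scoring import bit_scores_batch

        assert bit_scores_batch(m, X).mean() <= 0.0

    def test_consensus_scores_positive(self, calibrated_model):
        assert bit_score(calibrated_model,
                         calibrated_model.consensus()) > 0.0

    def test_flank_invariance_exact(self):
        # letter 'T' has zero probability in every core state, so added T
        # flanks can only be emitted by N/C; with p_flank = p1 their
        # log-odds contribution cancels exactly
        rng = np.random.default_rng(3)
        m = random_small_model(rng, M=3)
        for arr in (m.match_emissions, m.insert_emissions):
            arr[1:, 3] = 0.0
            arr[1:] /= arr[1:].sum(axis=1, keepdims=True)
        m.p_flank = m.null.p1
        m.__dict__.pop("_log_cache", None)
        core = "ACGA"
        base = bit_score(m, core)
        for k in (1, 3, 7):
            assert abs(bit_score(m, "T" * k + core + "T" * k) - base) < 1e-9

    def test_monotone_response_of_aligned_emission(self):
        rng = np.random.default_rng(17)
        m = random_small_model(rng, M=3)
        seq = "ACG"
        lv, path = viterbi(m, seq)
        kind, node, pos = next(s for s in path.steps if s[0] == "M")
        r = "ACGT".index(seq[pos - 1])
        boosted = m.match_emissions.copy()
        boosted[node] = boosted[node] * 0.5
        boosted[node, r] += 0.5
        m2 = ProfileHMM(alphabet=m.alphabet, match_emissions=boosted,
                        insert_emissions=m.insert_emissions,
                        transitions=m.transitions, null=m.null,
                        epsilon=m.epsilon, p_flank=m.p_flank)
        lv2, _ = viterbi(m2, seq)
        assert lv2 > lv


class TestBiasMask:
    def test_homopolymer_fully_masked(self):
        res = bias_mask("S" * 60)
        assert res.masked == "X" * 60
        assert res.intervals == [(1, 60)]

    def test_uniform_random_unmasked(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
        res = bias_mask(seq)
        assert res.intervals == []
        assert res.masked == seq

    def test_planted_low_complexity_insert(self):
        rng = np.random.default_rng(9)
        flank1 = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))
        flank2 = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))
        insert = "ST" * 25
        res = bias_mask(flank1 + insert + flank2)
        assert len(res.intervals) == 1
        s, e = res.intervals[0]
        assert s >= 60 and e <= 140  # mask stays around the planted insert
        assert res.masked[:55] == flank1[:55]
        assert res.masked[-55:] == flank2[-55:]

    def test_short_sequence_single_window(self):
        assert bias_mask("SSSSSSSSSS").intervals == [(1, 10)]
        assert bias_mask("ACDEFGHIKLMNPQRSTVWY").intervals == []


def path_logprob(hmm, path, x):
    """Probability of one explicit path, recomputed from first principles."""
    t = hmm.transitions
    lp = 0.0
    steps = [s for s in path.steps]
    lp += math.log1p(-hmm.p_flank)              # N -> B
    for kind, node, pos in steps:
        if kind in "NC":
            lp += math.log(hmm.p_flank) + math.log(hmm.null.q[x[pos - 1]])
        elif kind == "M":
            lp += math.log(hmm.match_emissions[node][x[pos - 1]])
        elif kind == "I":
            lp += math.log(hmm.insert_emissions[node][x[pos - 1]])
    core = [(k, n) for k, n, _ in steps if k in "MID"]
    lp += math.log(1.0 / hmm.M)                 # B -> M_entry
    for (k1, n1), (k2, n2) in zip(core, core[1:]):
        lp += math.log(t[k1 + k2][n1])
    k_last, n_last = core[-1]
    if k_last == "M" and n_last < hmm.M:
        lp += math.log(t["ME"][n_last])
    lp += math.log1p(-hmm.p_flank)              # C -> end
    return lp
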