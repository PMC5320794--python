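"""Model construction: match columns, weights, pseudocounts, persistence."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lpmominer.hmm import (AnnotationRules, BuildConfig, ModelError,
                           NullModel, annotate_model, assign_match_columns,
                           build_hmm, henikoff_weights, load_hmm, save_hmm)
from lpmominer.io_formats import AMINO_ACIDS, Alignment, aligned_row

from helpers_oracle import random_small_model


def aln_of(*rows):
    return Alignment([aligned_row(f"s{i}", r) for i, r in enumerate(rows)])


class TestMatchColumns:
    def test_gap_fraction_threshold(self):
        # gap fractions 0.0, 0.6, 0.4 -> columns 1 and 3
        aln = aln_of("A-C", "A-C", "AA-", "AAC", "A-C")
        assert assign_match_columns(aln) == [1, 3]

    def test_exact_half_excluded(self):
        aln = aln_of("A-", "AC", "A-", "AC")
        assert assign_match_columns(aln) == [1]

    def test_gap_free_keeps_all(self):
        aln = aln_of("ACD", "ACD")
        assert assign_match_columns(aln) == [1, 2, 3]

    def test_all_gappy_errors(self):
        aln = aln_of("A-", "-C")
        with pytest.raises(ModelError, match="no match columns"):
            assign_match_columns(aln)


class TestHenikoffWeights:
    def test_identical_sequences_equal_weights(self):
        aln = aln_of("ACDE", "ACDE")
        w = henikoff_weights(aln, [1, 2, 3, 4])
        assert np.allclose(w, [1.0, 1.0])

    def test_hand_computed_column(self):
        # column A/A/C: r=2 types, so A rows get 1/(2*2), C gets 1/(2*1);
        # normalized to sum to 3 -> [0.75, 0.75, 1.5]
        aln = aln_of("A", "A", "C")
        w = henikoff_weights(aln, [1])
        assert np.allclose(w, [0.75, 0.75, 1.5])

    def test_permutation_equivariance(self):
        rows = ["ACDE", "AGDE", "TCWE"]
        w1 = henikoff_weights(aln_of(*rows), [1, 2, 3, 4])
        w2 = henikoff_weights(aln_of(*rows[::-1]), [1, 2, 3, 4])
        assert np.allclose(w1, w2[::-1])

    def test_gap_contributes_nothing(self):
        aln = aln_of("A-", "AC", "AC")
        w = henikoff_weights(aln, [1, 2])
        assert w[0] < w[1] or np.isclose(w[0], w[1])
        assert np.isclose(w.sum(), 3.0)


class TestBuildHMM:
    def test_pseudocount_arithmetic_single_column(self):
        # 4 H rows, alpha=1, uniform q: e(H) = (4 + 0.05) / (4 + 1) = 0.81
        aln = aln_of("H", "H", "H", "H")
        q = np.full(20, 0.05)
        null = NullModel(q, 0.9)
        m = build_hmm(aln, BuildConfig(alpha=1.0, null=null))
        h = AMINO_ACIDS.index("H")
        assert m.M == 1
        assert np.isclose(m.match_emissions[1, h], 0.81)

    def test_rows_normalized(self, combined_model):
        m = combined_model
        assert np.allclose(m.match_emissions[1:].sum(axis=1), 1, atol=1e-12)
        t = m.transitions
        mid = slice(1, m.M)
        assert np.allclose(
            t["MM"][mid] + t["MI"][mid] + t["MD"][mid] + t["ME"][mid], 1,
            atol=1e-12)
        assert np.allclose(t["IM"][mid] + t["II"][mid] + t["ID"][mid], 1,
                           atol=1e-12)

    def test_alpha_to_infinity_approaches_background(self):
        aln = aln_of("HG", "HG", "HA")
        null = NullModel.standard()
        tvs = []
        for alpha in (1.0, 10.0, 100.0, 1000.0):
            m = build_hmm(aln, BuildConfig(alpha=alpha, null=null))
            tvs.append(np.abs(m.match_emissions[1:] - null.q).sum() / 2)
        assert all(a > b for a, b in zip(tvs, tvs[1:]))
        assert tvs[-1] < 0.01

    def test_order_invariance(self):
        rows = ["ACDE-", "AC-EG", "TCDEG", "ACDEG"]
        m1 = build_hmm(aln_of(*rows))
        m2 = build_hmm(Alignment(
            [aligned_row(f"s{i}", r) for i, r in enumerate(rows[::-1])]))
        assert np.allclose(m1.match_emissions, m2.match_emissions)
        for key in m1.transitions:
            assert np.allclose(m1.transitions[key], m2.transitions[key])

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_random_msa_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        n, C = int(rng.integers(2, 7)), int(rng.integers(2, 25))
        rows = []
        for i in range(n):
            chars = rng.choice(list(AMINO_ACIDS + "---"), size=C)
            rows.append("".join(chars))
        try:
            m = build_hmm(aln_of(*rows))
        except ModelError:
            return  # all-gappy alignment: no match columns, rejected
        assert np.allclose(m.match_emissions[1:].sum(axis=1), 1, atol=1e-12)
        t = m.transitions
        if m.M > 1:
            mid = slice(1, m.M)
            assert np.allclose(t["MM"][mid] + t["MI"][mid] + t["MD"][mid]
                               + t["ME"][mid], 1, atol=1e-12)


class TestAnnotateModel:
    def test_planted_hallmarks_found(self, combined_model, training):
        aln, _ = training
        ann = annotate_model(combined_model, aln)
        assert (ann.brace1_col, ann.brace2_col) == (1, 60)
        assert ann.motif_cols == (80, 81, 82)
        assert set(ann.conserved_cols) == {20, 40, 50, 70}

    def test_motif_tolerates_single_variant_row(self, combined_model,
                                                training):
        # one training row carries A at the first motif position, yet the
        # frequency-maximizing rule still selects that triple
        aln, _ = training
        col = aln.column(assign_match_columns(aln)[79])
        assert "A" in col and col.count("N") == 13
        ann = annotate_model(combined_model, aln)
        assert ann.motif_cols[0] == 80

    def test_no_histidine_columns_error(self):
        aln = aln_of("ACDE", "ACDE", "ACDE")
        m = build_hmm(aln)
        with pytest.raises(ModelError, match="manually"):
            annotate_model(m, aln)

    def test_override_wins(self, combined_model, training):
        aln, _ = training
        ann = annotate_model(combined_model, aln,
                             AnnotationRules(brace_override=(2, 50),
                                             motif_override=(70, 71, 72)))
        assert (ann.brace1_col, ann.brace2_col) == (2, 50)
        assert ann.motif_cols == (70, 71, 72)


class TestPersistence:
    def test_round_trip_random_model(self, tmp_path):
        rng = np.random.default_rng(5)
        m = random_small_model(rng, M=3)
        p = tmp_path / "m.lphmm"
        save_hmm(m, p)
        back = load_hmm(p)
        assert back.M == m.M and back.alphabet == m.alphabet
        assert np.abs(back.match_emissions[1:]
                      - m.match_emissions[1:]).max() < 1e-9
        assert np.abs(back.insert_emissions[1:]
                      - m.insert_emissions[1:]).max() < 1e-9
        for key in m.transitions:
            assert np.abs(back.transitions[key] - m.transitions[key]).max() < 1e-9
        assert abs(back.null.p1 - m.null.p1) < 1e-12

    def test_round_trip_full_model(self, tmp_path, calibrated_model):
        p = tmp_path / "m.lphmm"
        save_hmm(calibrated_model, p)
        back = load_hmm(p)
        assert np.abs(back.match_emissions[1:]
                      - calibrated_model.match_emissions[1:]).max() < 1e-9
        a, b = back.annotations, calibrated_model.annotations
        assert (a.brace1_col, a.brace2_col, a.motif_cols) == \
            (b.brace1_col, b.brace2_col, b.motif_cols)
        assert abs(back.gumbel.lam - calibrated_model.gumbel.lam) < 1e-9
        assert abs(back.thresholds.trusted_E
                   - calibrated_model.thresholds.trusted_E) < 1e-20

    def test_truncated_file_rejected(self, tmp_path):
        rng = np.random.default_rng(6)
        m = random_small_model(rng, M=3)
        p = tmp_path / "m.lphmm"
        save_hmm(m, p)
        lines = p.read_text().splitlines()
        # drop the last NODE block but keep the header's M=3
        p.write_text("\n".join(lines[:-5] + ["END"]) + "\n")
        with pytest.raises(ModelError):
            load_hmm(p)

    def test_wrong_magic_rejected(self, tmp_path):
        p = tmp_path / "m.lphmm"
        p.write_text("HMMER3/f\n")
        with pytest.raises(ModelError, match="LPHMM1"):
            load_hmm(p)
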