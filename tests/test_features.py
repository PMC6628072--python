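import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from antiangio import (FEATURE_COMBINATIONS, PSE_PRESETS, Peptide,
                       PropertyTable, PseParams, concat, encode_aac,
                       encode_ampseaac, encode_dpc, encode_pcp, encode_pseaac,
                       feature_matrix, optimize_pse_params, pse_correlation)
from antiangio.alphabet import AMINO_ACIDS
from antiangio.features import EncodingError, HYDROPHOBICITY, standardize_scale

from oracles import (ampseaac_oracle, pseaac_oracle, random_peptide,
                     theta_oracle)

peptide_seqs = st.text(alphabet=AMINO_ACIDS, min_size=5, max_size=50)


class TestAAC:
    def test_homopolymer(self):
        v = encode_aac(Peptide("p", "AAAA"))
        assert v.values[0] == 1.0 and v.values[1:].sum() == 0.0

    def test_uniform_four(self):
        v = encode_aac(Peptide("p", "ACDE"))
        assert dict(zip(v.names, v.values))["A"] == pytest.approx(0.25)
        assert v.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_fixed_order(self):
        assert encode_aac(Peptide("p", "AC")).names == tuple(AMINO_ACIDS)


class TestDPC:
    def test_homopolymer(self):
        v = encode_dpc(Peptide("p", "AAA"))
        assert dict(zip(v.names, v.values))["AA"] == 1.0

    def test_overlapping_windows(self):
        v = encode_dpc(Peptide("p", "ACAC"))
        d = dict(zip(v.names, v.values))
        assert d["AC"] == pytest.approx(2 / 3)
        assert d["CA"] == pytest.approx(1 / 3)

    def test_too_short_rejected(self):
        with pytest.raises(EncodingError, match="too short"):
            encode_dpc(Peptide("p", "A"))


class TestPCP:
    def test_homopolymer_equals_property_row(self):
        table = PropertyTable.bundled()
        v = encode_pcp(Peptide("p", "GGGG"), table, standardize=False)
        for acc, value in zip(v.names, v.values):
            assert value == pytest.approx(table.entries[acc]["G"], abs=1e-12)

    def test_two_residue_mean(self):
        table = PropertyTable.bundled()
        v = encode_pcp(Peptide("p", "AC"), table, standardize=False)
        for acc, value in zip(v.names, v.values):
            row = table.entries[acc]
            assert value == pytest.approx((row["A"] + row["C"]) / 2, abs=1e-12)

    def test_dimension_matches_table(self):
        table = PropertyTable.bundled().subset(["KYTJ820101", "HOPT810101"])
        assert len(encode_pcp(Peptide("p", "ACDE"), table)) == 2

    def test_standardized_scales_have_zero_mean_unit_sd(self):
        std = standardize_scale(HYDROPHOBICITY)
        vals = np.array([std[a] for a in AMINO_ACIDS])
        assert vals.mean() == pytest.approx(0.0, abs=1e-12)
        assert vals.std(ddof=0) == pytest.approx(1.0, abs=1e-12)


class TestAAindexParser:
    def test_bundled_table_drops_na_entry(self):
        table = PropertyTable.bundled()
        assert "SYNTNA0001" not in table.entries
        assert len(table) == 6
        for row in table.entries.values():
            assert len(row) == 20
            assert all(np.isfinite(list(row.values())))

    def test_known_value(self):
        # spot-check the parser against the flat file's residue ordering
        table = PropertyTable.bundled()
        assert table.entries["KYTJ820101"]["I"] == pytest.approx(4.5)
        assert table.entries["KYTJ820101"]["R"] == pytest.approx(-4.5)
        assert table.entries["HOPT810101"]["K"] == pytest.approx(3.0)


class TestCorrelationFactor:
    def test_homopolymer_zero(self):
        assert pse_correlation(Peptide("p", "AAAAAA"), 2) == 0.0

    def test_matches_direct_substitution(self):
        p = Peptide("p", "AC")
        assert pse_correlation(p, 1) == pytest.approx(theta_oracle("AC", 1),
                                                      abs=1e-12)

    def test_reversal_invariant(self, rng):
        for _ in range(10):
            seq = random_peptide(rng, 6, 20)
            for k in (1, 2, 3):
                assert pse_correlation(Peptide("f", seq), k) == pytest.approx(
                    pse_correlation(Peptide("r", seq[::-1]), k), abs=1e-12)

    def test_k_out_of_range_rejected(self):
        with pytest.raises(EncodingError):
            pse_correlation(Peptide("p", "ACD"), 3)


class TestPseAAC:
    def test_zero_weight_reduces_to_aac(self):
        p = Peptide("p", "ACDEFGHIKL")
        pse = encode_pseaac(p, PseParams(lam=3, weight=0.0))
        aac = encode_aac(p)
        assert np.allclose(pse.values[:20], aac.values, atol=1e-12)
        assert np.all(pse.values[20:] == 0.0)

    def test_zero_lambda_is_aac(self):
        p = Peptide("p", "ACDEFGHIKL")
        pse = encode_pseaac(p, PseParams(lam=0, weight=0.9))
        assert np.allclose(pse.values, encode_aac(p).values, atol=1e-12)

    def test_lambda_too_large_rejected(self):
        with pytest.raises(EncodingError, match="lambda"):
            encode_pseaac(Peptide("p", "ACD"), PseParams(lam=3, weight=0.5))

    def test_matches_naive_oracle(self, rng):
        for _ in range(50):
            seq = random_peptide(rng, 6, 30)
            lam = int(rng.integers(1, 5))
            w = float(rng.uniform(0, 1))
            got = encode_pseaac(Peptide("p", seq), PseParams(lam=lam, weight=w))
            want = pseaac_oracle(seq, lam, w)
            assert np.max(np.abs(got.values - np.array(want))) <= 1e-12

    def test_order_sensitivity(self):
        # equal AAC, different residue order -> different correlation terms
        a = encode_pseaac(Peptide("a", "AACC"), PseParams(lam=1, weight=0.9))
        b = encode_pseaac(Peptide("b", "ACAC"), PseParams(lam=1, weight=0.9))
        assert np.allclose(encode_aac(Peptide("a", "AACC")).values,
                           encode_aac(Peptide("b", "ACAC")).values)
        assert not np.allclose(a.values, b.values)


class TestAmPseAAC:
    def test_dimension(self):
        v = encode_ampseaac(Peptide("p", "ACDEFGHIKL"), PseParams(lam=1, weight=0.5))
        assert len(v) == 22

    def test_zero_weight_reduces_to_aac(self):
        p = Peptide("p", "ACDEFGHIKL")
        v = encode_ampseaac(p, PseParams(lam=3, weight=0.0))
        assert np.allclose(v.values[:20], encode_aac(p).values, atol=1e-12)

    def test_matches_naive_oracle(self, rng):
        for _ in range(50):
            seq = random_peptide(rng, 6, 30)
            lam = int(rng.integers(1, 5))
            w = float(rng.uniform(0, 1))
            got = encode_ampseaac(Peptide("p", seq), PseParams(lam=lam, weight=w))
            want = ampseaac_oracle(seq, lam, w)
            assert np.max(np.abs(got.values - np.array(want))) <= 1e-12


@settings(max_examples=200, deadline=None, derandomize=True)
@given(seq=peptide_seqs)
def test_all_normalized_encodings_sum_to_one(seq):
    p = Peptide("p", seq)
    for vec in (encode_aac(p), encode_dpc(p),
                encode_pseaac(p, PseParams(lam=2, weight=0.7)),
                encode_ampseaac(p, PseParams(lam=2, weight=0.3))):
        assert vec.values.sum() == pytest.approx(1.0, abs=1e-9)


class TestConcat:
    def test_dimensions_add(self):
        p = Peptide("p", "ACDEFGHIKL")
        v = concat([encode_aac(p), encode_pseaac(p, PseParams(lam=1, weight=0.9))])
        assert len(v) == 41
        assert v.scheme == "AAC+PseAAC"
        assert v.names[0] == "AAC:A"

    def test_single_input_identity(self):
        p = Peptide("p", "ACDE")
        v = encode_aac(p)
        assert concat([v]) is v

    def test_id_mismatch_rejected(self):
        with pytest.raises(EncodingError, match="mismatch"):
            concat([encode_aac(Peptide("a", "ACDE")),
                    encode_aac(Peptide("b", "ACDE"))])

    def test_dedupe_drops_repeated_aac_blocks(self):
        p = Peptide("p", "ACDEFGHIKL")
        v = concat([encode_aac(p), encode_aac(p),
                    encode_pseaac(p, PseParams(lam=2, weight=0.1))],
                   dedupe_aac=True)
        assert len(v) == 20 + 22


class TestFeatureMatrix:
    def test_registry_covers_nine_combinations(self, small_labeled):
        assert len(FEATURE_COMBINATIONS) == 9
        X, y = feature_matrix(small_labeled, "AAC+PseAAC+Am-PseAAC",
                              pse_params=PSE_PRESETS["nt15"]["pseaac"],
                              am_params=PSE_PRESETS["nt15"]["ampseaac"])
        # NT15 presets: 20 + (20+2) + (20+6)
        assert X.shape == (len(small_labeled), 68)
        assert set(y.unique()) == {0, 1}

    def test_unknown_combination_rejected(self, small_labeled):
        with pytest.raises(EncodingError, match="AAC"):
            feature_matrix(small_labeled, "TPC")

    def test_presets(self):
        assert PSE_PRESETS["benchmark"]["pseaac"] == PseParams(lam=1, weight=0.9)
        assert PSE_PRESETS["benchmark"]["ampseaac"] == PseParams(lam=1, weight=0.9)
        assert PSE_PRESETS["nt15"]["pseaac"] == PseParams(lam=2, weight=0.1)
        assert PSE_PRESETS["nt15"]["ampseaac"] == PseParams(lam=3, weight=0.2)


class TestOptimizePseParams:
    def test_single_point_grid(self, small_labeled):
        params, trace = optimize_pse_params(small_labeled, "PseAAC",
                                            weights=[0.5], lambdas=[2], seed=1)
        assert params == PseParams(lam=2, weight=0.5)
        assert len(trace) == 1

    def test_winner_matches_trace_maximum(self, small_labeled):
        params, trace = optimize_pse_params(small_labeled, "PseAAC",
                                            weights=[0.1, 0.9], lambdas=[1, 2],
                                            seed=1)
        best = trace.loc[trace["cv_accuracy"].idxmax()]
        assert trace[(trace["lambda"] == params.lam)
                     & (trace["weight"] == params.weight)]["cv_accuracy"].iloc[0] \
            == best["cv_accuracy"]

    def test_infeasible_lambdas_skipped(self, small_labeled):
        # shortest sequence is 8, so lambda 9 is infeasible and skipped
        params, trace = optimize_pse_params(small_labeled, "PseAAC",
                                            weights=[0.5], lambdas=[1, 9], seed=1)
        assert set(trace["lambda"]) == {1}
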