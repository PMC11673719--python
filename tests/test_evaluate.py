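import math

import numpy as np
import pytest

from chemnmt.evaluate import (EvaluationReport, LengthBin, RoundTripOutcome,
                              bleu_suite, brevity_penalty, exact_match,
                              length_stratified, name_pair_tanimoto,
                              pubchem_fp, retranslate, round_trip_eval,
                              sentence_bleu, summarize, tanimoto,
                              _modified_precision, _bleu_tokens)


class TestExactMatch:
    def test_strictness(self):
        assert exact_match("ethanol", "ethanol")
        assert not exact_match("Ethanol", "ethanol")
        assert not exact_match("ethanol ", "ethanol")


class TestBleu:
    def test_perfect_predictions(self):
        out = bleu_suite(["a b c d"] * 3, ["a b c d"] * 3)
        assert out["bleu1"] == out["bleu4"] == out["average"] == 1.0
        assert out["perfect_fraction"] == 1.0

    def test_disjoint_unigrams(self):
        out = bleu_suite(["x y z"], ["a b c"])
        assert out["bleu1"] == 0.0

    def test_hand_computed_case(self):
        """ref 'a b c d', pred 'a b c': unigram precision 1, BP=e^(1-4/3)."""
        pred, ref = "a b c", "a b c d"
        assert _modified_precision(_bleu_tokens(pred), _bleu_tokens(ref), 1) \
            == pytest.approx(1.0)
        assert brevity_penalty(pred, ref) == pytest.approx(math.exp(1 - 4 / 3))
        assert sentence_bleu(pred, ref, max_n=1) == pytest.approx(
            math.exp(1 - 4 / 3))

    def test_clipping(self):
        # 'a a a' vs 'a': clipped unigram precision is 1/3
        assert _modified_precision(["a", "a", "a"], ["a"], 1) == \
            pytest.approx(1 / 3)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            bleu_suite(["a"], ["a", "b"])


class TestTanimoto:
    def test_hand_counted_formula(self):
        a = np.zeros(8, dtype=np.uint8)
        b = np.zeros(8, dtype=np.uint8)
        a[[0, 1, 2]] = 1
        b[[1, 2, 5]] = 1
        # |a&b|=2, |a|=3, |b|=3 -> 2/(3+3-2)
        assert tanimoto(a, b) == pytest.approx(0.5)

    def test_identity_and_symmetry(self):
        rng = np.random.default_rng(0)
        a = (rng.random(100) < 0.3).astype(np.uint8)
        b = (rng.random(100) < 0.3).astype(np.uint8)
        assert tanimoto(a, a) == 1.0
        assert tanimoto(a, b) == tanimoto(b, a)

    def test_disjoint_and_empty(self):
        a = np.array([1, 1, 0, 0], dtype=np.uint8)
        b = np.array([0, 0, 1, 1], dtype=np.uint8)
        assert tanimoto(a, b) == 0.0
        z = np.zeros(4, dtype=np.uint8)
        assert tanimoto(z, z) == 1.0  # documented all-zero convention

    def test_width_mismatch_raises(self):
        with pytest.raises(ValueError, match="width"):
            tanimoto(np.zeros(4), np.zeros(5))


class TestFingerprints:
    def test_width_is_881(self):
        assert pubchem_fp("CCO").shape == (881,)

    def test_structure_level_determinism(self):
        np.testing.assert_array_equal(pubchem_fp("OCC"), pubchem_fp("CCO"))
        np.testing.assert_array_equal(
            pubchem_fp("c1ccccc1O"), pubchem_fp("Oc1ccccc1"))

    def test_stereo_agnostic(self):
        np.testing.assert_array_equal(
            pubchem_fp("N[C@@H](C)C(=O)O"), pubchem_fp("N[C@H](C)C(=O)O"))

    def test_different_structures_differ(self):
        assert tanimoto(pubchem_fp("CCO"), pubchem_fp("c1ccccc1")) < 1.0

    def test_unparseable_raises(self):
        with pytest.raises(ValueError):
            pubchem_fp("C(")


class TestRetranslate:
    def test_success_and_failure(self):
        smiles, err = retranslate("ethanol")
        assert err is None and smiles == "CCO"
        smiles, err = retranslate("notachemical")
        assert smiles is None and err is not None

    def test_identical_structures_score_one(self):
        assert name_pair_tanimoto("ethanol", "ethan-1-ol") == 1.0


class TestRoundTripEval:
    def test_perfect_prediction_list(self):
        refs = ["ethanol", "propan-2-ol", "2-methylpropane"]
        outcomes, report = round_trip_eval(refs, list(refs))
        assert report.exact_match_pct == 100.0
        assert report.valid_pct == 100.0
        assert report.mean_tanimoto == pytest.approx(1.0)
        assert all(o.identical_structure for o in outcomes)

    def test_failure_assigned_zero_and_pulls_mean(self):
        refs = ["ethanol", "propan-2-ol"]
        preds = ["ethanol", "gibberishol"]
        outcomes, report = round_trip_eval(refs, preds)
        assert outcomes[1].parse_error is not None
        assert outcomes[1].tanimoto == 0.0
        assert report.valid_pct == 50.0
        assert report.mean_tanimoto == pytest.approx(0.5)
        parseable_only = np.mean(
            [o.tanimoto for o in outcomes if o.parse_error is None])
        assert report.mean_tanimoto <= parseable_only

    def test_exact_match_implies_tanimoto_one(self):
        refs = ["5-bromopentan-2-one", "hexane-1,6-diol"]
        outcomes, _ = round_trip_eval(refs, list(refs))
        for o in outcomes:
            assert o.identical_name and o.tanimoto == 1.0

    def test_reference_smiles_column_wins(self):
        outcomes, _ = round_trip_eval(["bogusname"], ["ethanol"],
                                      reference_smiles=["OCC"])
        assert outcomes[0].tanimoto == 1.0
        assert outcomes[0].identical_structure

    def test_report_recomputes_from_outcomes(self):
        refs = ["ethanol", "butan-2-ol", "pentan-3-one", "wrongzz"]
        preds = ["ethanol", "butan-1-ol", "nonsense", "wrongzz"]
        outcomes, report = round_trip_eval(refs, preds)
        re_report = summarize(outcomes, report.bleu)
        assert re_report == report


class TestLengthStratified:
    def _outcome(self):
        return RoundTripOutcome("x", "C", None, 1.0, True, True)

    def test_window_boundaries(self):
        outcomes = [self._outcome() for _ in range(4)]
        smiles = ["C" * 60, "C" * 61, "C" * 541, "C" * 600]
        bins = length_stratified(outcomes, smiles)
        populated = {b.bin_index: b.n for b in bins if b.n}
        assert populated == {1: 1, 2: 1, 10: 2}

    def test_empty_bins_report_absent_metrics(self):
        bins = length_stratified([self._outcome()], ["C" * 30])
        empty = [b for b in bins if b.n == 0]
        assert empty and all(b.mean_tanimoto is None for b in empty)

    def test_overflow_bin_flagged(self):
        bins = length_stratified([self._outcome()], ["C" * 601])
        assert bins[-1].overflow and bins[-1].n == 1

    def test_partition(self):
        outcomes = [self._outcome() for _ in range(25)]
        smiles = ["C" * (10 + 25 * i) for i in range(25)]
        bins = length_stratified(outcomes, smiles)
        assert sum(b.n for b in bins) == 25
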