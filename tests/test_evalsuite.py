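"""Local-accuracy metrics: ASE, AUC, ULR detection/matching, aggregation,
GDT filtering and Z-rankings."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from resqa import evalsuite
from resqa.evalsuite import Ulr
from resqa.nets import deviation_to_s

binary_strings = st.text(alphabet="01", min_size=1, max_size=40)


class TestAse:
    def test_perfect_prediction_scores_100(self):
        d = np.array([0.5, 2.0, 7.0])
        assert evalsuite.ase(d, d) == 100.0

    def test_constant_s_error_is_linear(self):
        # |dS| = 0.25 everywhere -> ASE 75
        true = np.array([5.0, 5.0, 5.0, 5.0])   # S = 0.5
        s_pred = 0.75                            # S error 0.25
        pred = 5.0 * np.sqrt(1 / s_pred - 1) * np.ones(4)
        assert evalsuite.ase(pred, true) == pytest.approx(75.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        pred = rng.uniform(0, 15, size=50)
        true = rng.uniform(0, 15, size=50)
        total = 0.0
        for p, t in zip(pred, true):
            total += abs(1 / (1 + (p / 5) ** 2) - 1 / (1 + (t / 5) ** 2))
        assert evalsuite.ase(pred, true) == pytest.approx(
            (1 - total / 50) * 100)

    def test_all_missing_returns_none(self):
        assert evalsuite.ase(np.array([np.nan]), np.array([1.0])) is None


class TestClassify:
    def test_strict_threshold(self):
        assert evalsuite.classify_accurate(np.array([3.79])) == "0"
        assert evalsuite.classify_accurate(np.array([3.8])) == "1"

    def test_vector_matches_loop(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 8, size=30)
        s = evalsuite.classify_accurate(d)
        assert s == "".join("0" if x < 3.8 else "1" for x in d)


class TestAuc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        assert evalsuite.auc(scores, "0011") == 1.0

    def test_all_ties_give_half(self):
        assert evalsuite.auc(np.ones(6), "000111") == 0.5

    def test_single_class_is_none(self):
        assert evalsuite.auc(np.arange(4.0), "0000") is None

    def test_matches_concordance_oracle_and_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        for _ in range(25):
            n = int(rng.integers(5, 40))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)
            labels = "".join(rng.choice(["0", "1"], size=n))
            if len(set(labels)) < 2:
                continue
            got = evalsuite.auc(scores, labels)
            pos = [s for s, l in zip(scores, labels) if l == "0"]
            neg = [s for s, l in zip(scores, labels) if l == "1"]
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert got == pytest.approx(conc / (len(pos) * len(neg)))
            ref = roc_auc_score([1 if l == "0" else 0 for l in labels],
                                scores)
            assert got == pytest.approx(ref)


class TestUlrDetect:
    @pytest.mark.parametrize("labels,mode,expected", [
        ("1110111", "ULR1", [(1, 7)]),
        ("1110111", "ULR2", [(1, 7)]),
        ("1110100", "ULR1", [(1, 3)]),
        ("1110100", "ULR2", [(1, 5)]),
        ("110", "ULR1", []),
        ("110", "ULR2", []),
        # 0-1-0 between two regions is not "one accurate residue between
        # two ULRs": the strict rule leaves them separate, the loose rule
        # chains through the stray inaccurate residue
        ("0111010111000", "ULR1", [(2, 4), (8, 10)]),
        ("0111010111000", "ULR2", [(2, 10)]),
        ("11101010", "ULR2", [(1, 7)]),
    ])
    def test_examples(self, labels, mode, expected):
        assert evalsuite.ulr_detect(labels, mode).intervals == expected

    def test_empty_string_is_error(self):
        with pytest.raises(ValueError):
            evalsuite.ulr_detect("")

    @given(binary_strings)
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_idempotent(self, labels):
        for mode in ("ULR1", "ULR2"):
            ulr = evalsuite.ulr_detect(labels, mode)
            again = evalsuite.ulr_detect(
                ulr.to_string(len(labels)) if ulr.intervals else "0" *
                len(labels), mode)
            assert again.intervals == ulr.intervals

    @given(binary_strings)
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_ulr2_covers_ulr1(self, labels):
        c1 = evalsuite.ulr_detect(labels, "ULR1").coverage()
        c2 = evalsuite.ulr_detect(labels, "ULR2").coverage()
        assert c1 <= c2


class TestUlrMatch:
    def test_within_two_residues_matches(self):
        p, r, f1 = evalsuite.ulr_match(Ulr([(10, 20)]), Ulr([(12, 18)]))
        assert p == r == f1 == 1.0

    def test_three_residues_off_does_not_match(self):
        p, r, f1 = evalsuite.ulr_match(Ulr([(10, 20)]), Ulr([(13, 20)]))
        assert f1 == 0.0

    def test_one_of_three_worked_example(self):
        # one of three predictions correct, one of three true detected:
        # precision = recall = 1/3 and F1 = 2*(1/3)*(1/3)/(2/3) = 0.33
        pred = Ulr([(5, 9), (30, 34), (60, 64)])
        true = Ulr([(5, 10), (45, 50), (80, 85)])
        p, r, f1 = evalsuite.ulr_match(pred, true)
        assert p == pytest.approx(1 / 3)
        assert r == pytest.approx(1 / 3)
        assert round(f1, 2) == 0.33

    def test_greedy_left_to_right_one_to_one(self):
        # the single prediction is within tolerance of the first true
        # interval only; the second true interval stays undetected
        pred = Ulr([(10, 16)])
        true = Ulr([(8, 14), (16, 22)])
        p, r, f1 = evalsuite.ulr_match(pred, true)
        assert p == 1.0 and r == 0.5

    def test_both_empty_is_absent(self):
        assert evalsuite.ulr_match(Ulr([]), Ulr([])) == (None, None, None)


class TestSovStringEval:
    def test_identical_deviations(self):
        d = np.array([1.0, 5.0, 5.0, 5.0, 1.0])
        assert evalsuite.sov_string_eval(d, d) == (1.0, 1.0)

    def test_swapped_classes_score_low(self):
        true = np.array([1.0] * 4 + [6.0] * 4)
        pred = np.array([6.0] * 4 + [1.0] * 4)
        s99, sref = evalsuite.sov_string_eval(pred, true)
        assert s99 == 0.0 and sref == 0.0


class TestAggregate:
    def test_single_model_is_its_own_eu_mean(self):
        rep = {"ASE": 80.0, "AUC": 0.7, "ULR1_F1": 0.5, "ULR2_F1": 0.5,
               "SOV99": 0.6, "SOV_refine": 0.4}
        eu_means, overall = evalsuite.aggregate([rep], ["E1"])
        assert eu_means["E1"] == rep
        assert overall["ASE"] == 80.0

    def test_eus_weighted_equally(self):
        def rep(a):
            return {"ASE": a, "AUC": None, "ULR1_F1": None,
                    "ULR2_F1": None, "SOV99": None, "SOV_refine": None}
        # EU1 has 3 models (mean 60), EU2 has 1 model (mean 90):
        # overall = (60 + 90) / 2, not the pooled model mean 67.5
        reports = [rep(50), rep(60), rep(70), rep(90)]
        _, overall = evalsuite.aggregate(reports, ["E1", "E1", "E1", "E2"])
        assert overall["ASE"] == pytest.approx(75.0)

    def test_absent_values_excluded(self):
        reps = [{"ASE": 80.0, "AUC": None, "ULR1_F1": 0.2, "ULR2_F1": 0.2,
                 "SOV99": 0.5, "SOV_refine": 0.3},
                {"ASE": 60.0, "AUC": 0.8, "ULR1_F1": 0.4, "ULR2_F1": 0.4,
                 "SOV99": 0.5, "SOV_refine": 0.3}]
        eu_means, _ = evalsuite.aggregate(reps, ["E1", "E1"])
        assert eu_means["E1"]["AUC"] == 0.8
        assert eu_means["E1"]["ASE"] == 70.0


class TestFilter:
    def test_boundaries(self):
        g = [40.0, 41.0, 59.9, 60.0, 90.0, 90.1, 100.0]
        assert list(evalsuite.filter_models(g, "gt40")) == [
            False, True, True, True, True, True, True]
        assert list(evalsuite.filter_models(g, "between40and60")) == [
            False, True, True, False, False, False, False]
        assert list(evalsuite.filter_models(g, "gt90")) == [
            False, False, False, False, False, True, True]
        assert all(evalsuite.filter_models(g, "all"))


class TestZRank:
    @staticmethod
    def _scores(vals_by_group, metric="AUC"):
        base = {"ASE": None, "AUC": None, "ULR1_F1": None,
                "ULR2_F1": None, "SOV_refine": None}
        return {g: {"E1": {**base, metric: v}}
                for g, v in vals_by_group.items()}

    def test_two_groups_hand_z(self):
        ranked = evalsuite.z_rank(self._scores({"A": 0.8, "B": 0.6}), "Z1")
        assert ranked == [("A", pytest.approx(1.0)),
                          ("B", pytest.approx(-1.0))]

    def test_per_metric_z_sums_to_zero(self):
        rng = np.random.default_rng(0)
        groups = {f"G{i}": {} for i in range(4)}
        for eu in ("E1", "E2", "E3"):
            for g in groups:
                groups[g][eu] = {"ASE": rng.uniform(50, 95),
                                 "AUC": rng.uniform(0.4, 0.9),
                                 "ULR1_F1": rng.uniform(0, 1),
                                 "ULR2_F1": rng.uniform(0, 1),
                                 "SOV_refine": rng.uniform(0, 1)}
        for flavor in ("Z1", "Z2"):
            ranked = evalsuite.z_rank(groups, flavor)
            assert abs(sum(z for _, z in ranked)) < 1e-9

    def test_identical_groups_all_zero(self):
        ranked = evalsuite.z_rank(self._scores({"A": 0.7, "B": 0.7}), "Z1")
        assert all(z == 0.0 for _, z in ranked)

    def test_single_group_is_error(self):
        with pytest.raises(ValueError):
            evalsuite.z_rank(self._scores({"A": 0.7}), "Z1")
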