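"""Confusion accounting, the seven statistics and cross-validation."""

import numpy as np
import pytest

from proterna.evaluation import (
    CVConfig,
    ConfusionCounts,
    assign_folds,
    category_breakdown,
    confusion,
    cross_validate,
    metrics,
    pooled_metrics,
    report_to_tsv,
)

HALF_PCT = 0.005 + 1e-9   # half-ulp of a percentage printed to 2 decimals
HALF_VAL = 0.00005 + 1e-9  # half-ulp of a value printed to 4 decimals
ULP_PCT = 0.01 + 1e-9      # published tables contain a few rounding slips
ULP_VAL = 0.0001 + 1e-9

# Benchmark rows: counts plus the published derived statistics
# (sens%, spec%, prec%, acc%, MCC, F1, F0.5).  A handful of published cells
# are off by one rounding ulp from their own counts; those rows carry
# loose=True and are compared at one ulp instead of half.
TABLE_ROWS = [
    # independent test set comparison
    ("rb33 ProteRNA", (222, 340, 8563, 660), (25.17, 96.18, 39.50, 89.78, 0.2628, 0.3075, 0.3546), False),
    ("rb33 PiRaNhA", (265, 538, 8365, 617), (30.05, 93.96, 33.00, 88.20, 0.2504, 0.3145, 0.3236), False),
    ("rb33 Pprint", (447, 1782, 7121, 435), (50.68, 79.98, 20.05, 77.34, 0.2094, 0.2873, 0.2281), True),
    ("rb33 BindN", (348, 1613, 7290, 534), (39.46, 81.88, 17.75, 78.06, 0.1527, 0.2449, 0.1994), True),
    ("rb33 PRIP", (131, 835, 8068, 751), (14.85, 90.62, 13.56, 83.79, 0.0526, 0.1418, 0.1380), False),
    # per-RNA-category breakdown, SVM component
    ("svm rRNA", (2060, 537, 5814, 1856), (52.60, 91.54, 79.32, 76.69, 0.4933, 0.6326, 0.7201), False),
    ("svm mRNA", (27, 16, 1606, 229), (10.55, 99.01, 62.79, 86.95, 0.2193, 0.1806, 0.3154), False),
    ("svm tRNA", (234, 171, 11000, 996), (19.02, 98.47, 57.78, 90.59, 0.2942, 0.2862, 0.4105), False),
    ("svm others", (109, 93, 6930, 646), (14.44, 98.68, 53.96, 90.50, 0.2441, 0.2278, 0.3487), False),
    ("svm Total", (2430, 823, 25344, 3727), (39.47, 96.86, 74.70, 85.92, 0.4741, 0.5165, 0.6338), True),
    # conservation component
    ("cons rRNA", (554, 412, 5939, 3362), (14.15, 93.51, 57.35, 63.24, 0.1274, 0.2270, 0.3560), False),
    ("cons mRNA", (67, 121, 1501, 189), (26.17, 92.54, 35.64, 83.49, 0.2139, 0.3018, 0.3323), False),
    ("cons tRNA", (50, 173, 10998, 1180), (4.07, 98.45, 22.42, 89.09, 0.0566, 0.0688, 0.1178), False),
    ("cons others", (85, 272, 6751, 670), (11.26, 96.13, 23.81, 87.89, 0.1045, 0.1529, 0.1947), False),
    ("cons Total", (756, 978, 25189, 5401), (12.28, 96.26, 43.60, 80.27, 0.1489, 0.1916, 0.2887), False),
    # combined predictor
    ("comb rRNA", (2256, 878, 5473, 1660), (57.61, 86.18, 71.98, 75.28, 0.4618, 0.6400, 0.6856), False),
    ("comb mRNA", (89, 138, 1484, 167), (34.77, 91.49, 39.21, 83.76, 0.2764, 0.3685, 0.3823), False),
    ("comb tRNA", (238, 304, 10867, 992), (19.35, 97.28, 43.91, 89.55, 0.2431, 0.2686, 0.3502), False),
    ("comb others", (177, 366, 6657, 578), (23.44, 94.79, 32.60, 87.86, 0.2118, 0.2727, 0.3024), False),
    ("comb Total", (2760, 1686, 24481, 3397), (44.83, 93.56, 62.08, 84.28, 0.4376, 0.5206, 0.5764), True),
]


class TestConfusion:
    def test_all_positive_agreement(self):
        assert confusion([1, 1, 1, 1], [1, 1, 1, 1]) == ConfusionCounts(4, 0, 0, 0)

    def test_enumerated_quadrants(self):
        assert confusion([1, 1, 0, 0], [1, 0, 1, 0]) == ConfusionCounts(1, 1, 1, 1)

    def test_matches_naive_tally(self, rng):
        y = rng.integers(0, 2, size=1000)
        p = rng.integers(0, 2, size=1000)
        c = confusion(y, p)
        tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for yi, pi in zip(y, p):
            key = ("t" if yi == pi else "f") + ("p" if pi else "n")
            tally[key] += 1
        assert (c.TP, c.FP, c.TN, c.FN) == (
            tally["tp"], tally["fp"], tally["tn"], tally["fn"],
        )
        assert c.total == 1000

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestMetrics:
    @pytest.mark.parametrize(
        "name,counts,expected,loose", TABLE_ROWS, ids=[r[0] for r in TABLE_ROWS]
    )
    def test_reproduces_benchmark_tables(self, name, counts, expected, loose):
        """Every derived cell of the benchmark tables follows from its
        printed TP/FP/TN/FN to the printed precision."""
        r = metrics(ConfusionCounts(*counts))
        sens, spec, prec, acc, mcc, f1, f05 = expected
        tol_pct = ULP_PCT if loose else HALF_PCT
        tol_val = ULP_VAL if loose else HALF_VAL
        assert abs(100 * r.sensitivity - sens) <= tol_pct
        assert abs(100 * r.specificity - spec) <= tol_pct
        assert abs(100 * r.precision - prec) <= tol_pct
        assert abs(100 * r.accuracy - acc) <= tol_pct
        assert abs(r.mcc - mcc) <= tol_val
        assert abs(r.f1 - f1) <= tol_val
        assert abs(r.f05 - f05) <= tol_val

    def test_perfect_prediction(self):
        r = metrics(ConfusionCounts(10, 0, 20, 0))
        assert r.mcc == 1.0 and r.f1 == 1.0

    def test_balanced_random_counts_give_zero_mcc(self):
        r = metrics(ConfusionCounts(7, 7, 7, 7))
        assert r.mcc == 0.0

    def test_zero_denominator_flagged(self):
        r = metrics(ConfusionCounts(0, 0, 5, 0))
        assert r.precision == 0.0
        assert "precision" in r.undefined

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_mcc_symmetric_under_class_swap_fbeta_not(self, rng):
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(1, 200, size=4)
            r = metrics(ConfusionCounts(tp, fp, tn, fn))
            swapped = metrics(ConfusionCounts(tn, fn, tp, fp))
            assert r.mcc == pytest.approx(swapped.mcc)
        asym = metrics(ConfusionCounts(5, 50, 100, 10))
        asym_swapped = metrics(ConfusionCounts(100, 10, 5, 50))
        assert asym.f1 != pytest.approx(asym_swapped.f1)

    def test_accuracy_prevalence_identity(self, rng):
        for _ in range(20):
            tp, fp, tn, fn = (int(v) for v in rng.integers(1, 500, size=4))
            r = metrics(ConfusionCounts(tp, fp, tn, fn))
            prevalence = (tp + fn) / (tp + fp + tn + fn)
            assert r.accuracy == pytest.approx(
                prevalence * r.sensitivity + (1 - prevalence) * r.specificity
            )


class TestPooledMetrics:
    def test_single_element_identity(self):
        c = ConfusionCounts(5, 3, 10, 2)
        assert pooled_metrics([c]).as_dict() == metrics(c).as_dict()

    def test_category_counts_sum_to_published_total(self):
        per_category = [
            ConfusionCounts(2060, 537, 5814, 1856),
            ConfusionCounts(27, 16, 1606, 229),
            ConfusionCounts(234, 171, 11000, 996),
            ConfusionCounts(109, 93, 6930, 646),
        ]
        pooled = pooled_metrics(per_category)
        # the published Total row prints FP=823/TN=25344, which its own
        # category rows do not sum to (they give 817/25350, a 6-count slip);
        # TP and FN do agree with the published Total
        assert (pooled.counts.TP, pooled.counts.FN) == (2430, 3727)
        assert (pooled.counts.FP, pooled.counts.TN) == (817, 25350)
        assert pooled.counts.FP + pooled.counts.TN == 823 + 25344

    def test_partition_invariance(self, rng):
        y = rng.integers(0, 2, size=400)
        p = rng.integers(0, 2, size=400)
        whole = confusion(y, p)
        cuts = np.sort(rng.choice(np.arange(1, 400), size=5, replace=False))
        pieces = [
            confusion(y[a:b], p[a:b])
            for a, b in zip(np.r_[0, cuts], np.r_[cuts, 400])
        ]
        assert pooled_metrics(pieces).as_dict() == metrics(whole).as_dict()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pooled_metrics([])


class TestAssignFolds:
    def test_balanced_chain_split(self):
        folds = assign_folds(list("abcdefghij"), CVConfig(k=5, repeats=1, seed=3))[0]
        counts = np.bincount(folds, minlength=5)
        assert (counts == 2).all()

    def test_deterministic_per_seed(self):
        config = CVConfig(k=4, repeats=3, seed=17)
        a = assign_folds(list(range(23)), config)
        b = assign_folds(list(range(23)), config)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_fold_sizes_differ_by_at_most_one(self):
        folds = assign_folds(list(range(23)), CVConfig(k=5, repeats=1, seed=0))[0]
        counts = np.bincount(folds, minlength=5)
        assert counts.max() - counts.min() <= 1

    def test_sequence_mode_chains_never_split(self):
        """No residue of any chain lands in two folds when assignment is at
        the chain level."""
        chain_ids = [f"c{i}" for i in range(11)]
        lengths = [7, 3, 9, 4, 5, 8, 2, 6, 10, 3, 5]
        folds = assign_folds(chain_ids, CVConfig(k=5, repeats=1, seed=9))[0]
        row_fold = np.repeat(folds, lengths)
        offset = 0
        for cid, length, fold in zip(chain_ids, lengths, folds):
            assert (row_fold[offset : offset + length] == fold).all()
            offset += length

    def test_too_few_chains_rejected(self):
        with pytest.raises(ValueError):
            assign_folds(["a", "b"], CVConfig(k=5, repeats=1))


class TestCrossValidate:
    @staticmethod
    def _dataset(rng, n_chains=8, length=30):
        return [
            (
                f"c{i}",
                rng.normal(size=(length, 4)),
                rng.integers(0, 2, size=length),
            )
            for i in range(n_chains)
        ]

    def test_constant_negative_predictor_closed_form(self, rng):
        dataset = self._dataset(rng)
        trainer = lambda X, y, seed: (lambda Xt: np.zeros(len(Xt), dtype=int))
        out = cross_validate(dataset, trainer, CVConfig(k=4, repeats=3, seed=1))
        y_all = np.concatenate([y for _, _, y in dataset])
        neg_fraction = float((y_all == 0).mean())
        assert out["sensitivity"][0] == pytest.approx(0.0)
        assert out["specificity"][0] == pytest.approx(1.0)
        assert out["accuracy"][0] == pytest.approx(neg_fraction)

    def test_single_repeat_zero_std(self, rng):
        dataset = self._dataset(rng)
        trainer = lambda X, y, seed: (lambda Xt: np.zeros(len(Xt), dtype=int))
        out = cross_validate(dataset, trainer, CVConfig(k=4, repeats=1, seed=1))
        assert all(std == 0.0 for _, std in out.values())


class TestCategoryBreakdown:
    def test_single_category_equals_pooled(self):
        per_chain = {"a": ConfusionCounts(5, 2, 10, 3), "b": ConfusionCounts(1, 1, 8, 2)}
        annotation = {"a": "rRNA", "b": "rRNA"}
        reports = category_breakdown(per_chain, annotation)
        pooled = pooled_metrics(list(per_chain.values()))
        assert reports["rRNA"].as_dict() == pooled.as_dict()
        assert reports["Total"].as_dict() == pooled.as_dict()

    def test_published_rRNA_sensitivity_from_counts(self):
        reports = category_breakdown(
            {"x": ConfusionCounts(2060, 537, 5814, 1856)}, {"x": "rRNA"}
        )
        assert 100 * reports["rRNA"].sensitivity == pytest.approx(
            100 * 2060 / (2060 + 1856), abs=HALF_PCT
        )
        assert round(100 * reports["rRNA"].sensitivity, 2) == 52.60

    def test_relabeling_leaves_total_unchanged(self, rng):
        per_chain = {
            f"c{i}": ConfusionCounts(*(int(v) for v in rng.integers(0, 50, size=4)))
            for i in range(6)
        }
        cats = ["rRNA", "mRNA", "tRNA", "others"]
        ann1 = {c: cats[i % 4] for i, c in enumerate(per_chain)}
        ann2 = {c: cats[(i + 2) % 4] for i, c in enumerate(per_chain)}
        r1 = category_breakdown(per_chain, ann1)
        r2 = category_breakdown(per_chain, ann2)
        assert r1["Total"].as_dict() == r2["Total"].as_dict()

    def test_unannotated_chain_rejected(self):
        with pytest.raises(ValueError):
            category_breakdown({"a": ConfusionCounts(1, 1, 1, 1)}, {})

    def test_tsv_report_contains_counts(self):
        reports = category_breakdown(
            {"x": ConfusionCounts(10, 5, 80, 5)}, {"x": "tRNA"}
        )
        tsv = report_to_tsv(reports)
        assert "tRNA\t10\t5\t80\t5" in tsv
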