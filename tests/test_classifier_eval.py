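import math

import numpy as np
import pandas as pd
import pytest

from gd2sig.classifier_eval import (
    ConfusionCounts,
    equal_error_threshold,
    evaluate_panel,
    evaluate_predictor,
    mcc_from_counts,
    random_pair_null,
)
from gd2sig.classifier_eval import _scan_thresholds
from gd2sig.errors import DegenerateDataError, InputError
from gd2sig.signature import FLAGSHIP_SIGNATURE, GANGLIOSIDE_PANEL, SignatureSpec

from _oracles import confusion_matrices_up_to, equal_error_oracle, mcc_oracle


def _series(values, prefix="s"):
    return pd.Series({f"{prefix}{i}": v for i, v in enumerate(values)})


def _labels(series, positives):
    return {s: s in positives for s in series.index}


class TestMCC:
    def test_perfect(self):
        assert mcc_from_counts(ConfusionCounts(tp=5, fp=0, tn=5, fn=0)) == 1.0

    def test_perfectly_wrong(self):
        assert mcc_from_counts(ConfusionCounts(tp=0, fp=5, tn=0, fn=5)) == -1.0

    def test_hand_computed(self):
        c = ConfusionCounts(tp=3, fp=1, tn=4, fn=2)
        assert mcc_from_counts(c) == pytest.approx(10 / math.sqrt(600), abs=1e-12)

    def test_zero_marginal_is_zero(self):
        assert mcc_from_counts(ConfusionCounts(tp=3, fp=2, tn=0, fn=0)) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            mcc_from_counts(ConfusionCounts(tp=0, fp=0, tn=0, fn=0))

    def test_negative_count_rejected(self):
        with pytest.raises(InputError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)

    def test_matches_pearson_oracle_small(self):
        for tp, fp, tn, fn in confusion_matrices_up_to(10):
            got = mcc_from_counts(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            assert got == pytest.approx(mcc_oracle(tp, fp, tn, fn), abs=1e-10)

    def test_symmetry(self):
        for tp, fp, tn, fn in confusion_matrices_up_to(8):
            m = mcc_from_counts(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            # swap both predicted and true classes
            both = mcc_from_counts(ConfusionCounts(tp=tn, fp=fn, tn=tp, fn=fp))
            assert both == pytest.approx(m, abs=1e-12)
            # swap predictions only
            pred = mcc_from_counts(ConfusionCounts(tp=fn, fp=tn, tn=fp, fn=tp))
            assert pred == pytest.approx(-m, abs=1e-12)


class TestEqualErrorThreshold:
    def test_separable_midpoint(self):
        scores = _series([3.0, 4.0, 1.0, 2.0])
        labels = _labels(scores, {"s0", "s1"})
        assert equal_error_threshold(scores, labels) == 2.5

    def test_interleaved_matches_oracle(self):
        scores = _series([1.0, 3.0, 2.0, 4.0])
        labels = _labels(scores, {"s0", "s1"})
        expected, _ = equal_error_oracle(scores.to_numpy(), [True, True, False, False])
        assert equal_error_threshold(scores, labels) == expected

    def test_anti_predictive_matches_oracle(self):
        scores = _series([1.0, 2.0, 3.0, 4.0])
        labels = _labels(scores, {"s0", "s1"})  # positives score low
        x = scores.to_numpy()
        y = np.array([True, True, False, False])
        threshold, conf, mcc, degenerate = _scan_thresholds(x, y)
        exp_t, exp_conf = equal_error_oracle(x, y)
        assert threshold == exp_t
        assert (conf.tp, conf.fp, conf.tn, conf.fn) == exp_conf
        assert mcc <= 0 and not degenerate

    def test_degenerate_identical_scores(self):
        x = np.array([2.0, 2.0, 2.0])
        y = np.array([True, False, True])
        threshold, conf, mcc, degenerate = _scan_thresholds(x, y)
        assert degenerate and threshold == 2.0
        assert (conf.tp, conf.fp, conf.tn, conf.fn) == (2, 1, 0, 0)
        assert mcc == 0.0

    def test_single_class_rejected(self):
        scores = _series([1.0, 2.0])
        with pytest.raises(DegenerateDataError):
            equal_error_threshold(scores, {"s0": True, "s1": True})

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            x = np.round(rng.normal(size=n), 2)  # rounding provokes ties
            y = rng.random(n) < 0.5
            if y.all() or not y.any() or np.unique(x).size == 1:
                continue
            threshold, conf, _, _ = _scan_thresholds(x, y)
            exp_t, exp_conf = equal_error_oracle(x, y)
            assert threshold == exp_t
            assert (conf.tp, conf.fp, conf.tn, conf.fn) == exp_conf


class TestEvaluatePredictor:
    def test_perfect_separation_no_permutations(self):
        scores = _series([5.0, 6.0, 1.0, 2.0])
        labels = _labels(scores, {"s0", "s1"})
        result = evaluate_predictor(scores, labels, n_perm=0, seed=0)
        assert result.mcc == 1.0
        assert result.p_perm == 1.0
        assert result.confusion == ConfusionCounts(tp=2, fp=0, tn=2, fn=0)

    def test_mcc_recomputable_from_confusion(self):
        rng = np.random.default_rng(5)
        scores = _series(rng.normal(size=30))
        labels = {s: rng.random() < 0.5 for s in scores.index}
        if all(labels.values()) or not any(labels.values()):
            labels["s0"] = not labels["s0"]
        result = evaluate_predictor(scores, labels, n_perm=0, seed=0)
        assert result.mcc == pytest.approx(mcc_from_counts(result.confusion), abs=1e-12)

    def test_add_one_permutation_formula(self):
        # perfectly anti-predictive scores reach MCC -1, which every
        # permutation matches or beats: p = (1 + n_perm) / (1 + n_perm)
        scores = _series([1.0, 2.0, 3.0, 4.0])
        labels = _labels(scores, {"s0", "s1"})
        result = evaluate_predictor(scores, labels, n_perm=50, seed=1)
        assert result.mcc == -1.0
        assert result.p_perm == 1.0

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        scores = _series(rng.normal(size=40))
        labels = {s: i % 2 == 0 for i, s in enumerate(scores.index)}
        a = evaluate_predictor(scores, labels, n_perm=99, seed=3)
        b = evaluate_predictor(scores, labels, n_perm=99, seed=3)
        assert a == b

    def test_negative_n_perm_rejected(self):
        scores = _series([1.0, 2.0])
        with pytest.raises(InputError):
            evaluate_predictor(scores, _labels(scores, {"s1"}), n_perm=-1)


class TestRandomPairNull:
    @staticmethod
    def _cohort(seed=0, n=40, n_pool=20):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(n)]
        labels = {s: i < n // 2 for i, s in enumerate(samples)}
        genes = ["ST8SIA1", "B4GALNT1"] + [f"P{i}" for i in range(n_pool)]
        logexpr = pd.DataFrame(
            rng.normal(size=(len(genes), n)), index=genes, columns=samples
        )
        # make the flagship genes separate the classes perfectly
        bump = np.array([3.0 if labels[s] else -3.0 for s in samples])
        logexpr.loc["ST8SIA1"] += bump
        logexpr.loc["B4GALNT1"] += bump
        return logexpr, labels, [g for g in genes if g.startswith("P")]

    def test_observed_beats_all_nulls(self):
        logexpr, labels, pool = self._cohort()
        null = random_pair_null(
            logexpr, labels, pool, n_pairs=100, seed=0, observed=FLAGSHIP_SIGNATURE
        )
        assert null.observed_mcc == 1.0
        assert all(m < 1.0 for m in null.null_mccs)
        assert null.p_value == 0.0

    def test_observed_below_all_nulls(self):
        logexpr, labels, pool = self._cohort()
        # an anti-predictive observed signature: minus the informative genes
        anti = SignatureSpec(terms=(("ST8SIA1", -1), ("B4GALNT1", -1)))
        null = random_pair_null(
            logexpr, labels, pool, n_pairs=100, seed=0, observed=anti
        )
        assert null.p_value == 1.0

    def test_strictly_greater_ignores_ties(self):
        # two-gene pool: every draw is the same pair as the observed signature,
        # so all null MCCs tie with the observed and none is strictly greater
        logexpr, labels, _ = self._cohort(n_pool=0)
        null = random_pair_null(
            logexpr,
            labels,
            ["ST8SIA1", "B4GALNT1"],
            n_pairs=50,
            seed=0,
            observed=FLAGSHIP_SIGNATURE,
        )
        assert len(set(null.null_mccs)) == 1
        assert null.null_mccs[0] == null.observed_mcc
        assert null.p_value == 0.0

    def test_degenerate_pool_p_in_zero_one(self):
        logexpr, labels, pool = self._cohort()
        null = random_pair_null(
            logexpr, labels, pool[:2], n_pairs=25, seed=0, observed=FLAGSHIP_SIGNATURE
        )
        assert len({frozenset(p) for p in null.pairs}) == 1
        assert len(set(null.null_mccs)) == 1
        assert null.p_value in (0.0, 1.0)

    def test_absent_pool_genes_dropped(self, caplog):
        logexpr, labels, pool = self._cohort()
        null = random_pair_null(
            logexpr,
            labels,
            pool + ["ABSENT1", "ABSENT2"],
            n_pairs=10,
            seed=0,
            observed=FLAGSHIP_SIGNATURE,
        )
        assert all(g in logexpr.index for pair in null.pairs for g in pair)

    def test_too_few_present_genes_fatal(self):
        logexpr, labels, _ = self._cohort()
        with pytest.raises(DegenerateDataError):
            random_pair_null(
                logexpr,
                labels,
                ["ABSENT1", "ABSENT2"],
                n_pairs=10,
                seed=0,
                observed=FLAGSHIP_SIGNATURE,
            )

    def test_deterministic(self):
        logexpr, labels, pool = self._cohort()
        a = random_pair_null(
            logexpr, labels, pool, n_pairs=50, seed=7, observed=FLAGSHIP_SIGNATURE
        )
        b = random_pair_null(
            logexpr, labels, pool, n_pairs=50, seed=7, observed=FLAGSHIP_SIGNATURE
        )
        assert a == b


class TestEvaluatePanel:
    @staticmethod
    def _panel_cohort(seed=11, n=30):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(n)]
        labels = {s: i < n // 2 for i, s in enumerate(samples)}
        logexpr = pd.DataFrame(
            rng.normal(size=(6, n)),
            index=list(GANGLIOSIDE_PANEL.genes),
            columns=samples,
        )
        return logexpr, labels

    def test_seven_rows_in_panel_order(self):
        logexpr, labels = self._panel_cohort()
        results = evaluate_panel(
            logexpr, labels, GANGLIOSIDE_PANEL, FLAGSHIP_SIGNATURE, n_perm=0, seed=0
        )
        names = [r.predictor for r in results]
        assert names == list(GANGLIOSIDE_PANEL.genes) + [FLAGSHIP_SIGNATURE.name]

    def test_single_gene_row_matches_direct_evaluation(self):
        logexpr, labels = self._panel_cohort()
        results = evaluate_panel(
            logexpr, labels, GANGLIOSIDE_PANEL, FLAGSHIP_SIGNATURE, n_perm=20, seed=4
        )
        direct = evaluate_predictor(
            logexpr.loc["ST8SIA1"], labels, n_perm=20, seed=4, name="ST8SIA1"
        )
        assert results[list(GANGLIOSIDE_PANEL.genes).index("ST8SIA1")] == direct

    def test_missing_panel_gene_rejected(self):
        logexpr, labels = self._panel_cohort()
        with pytest.raises(InputError, match="ST3GAL5"):
            evaluate_panel(
                logexpr.drop(index="ST3GAL5"),
                labels,
                GANGLIOSIDE_PANEL,
                FLAGSHIP_SIGNATURE,
                n_perm=0,
                seed=0,
            )
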