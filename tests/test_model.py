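"""Evaluation statistics and classifier training."""

import math
from fractions import Fraction

import numpy as np
import pytest

from nphosite.dataset import LabeledDataset, SplitPlan, encode_examples
from nphosite.model import (
    ConfusionCounts,
    MetricsReport,
    TrainingError,
    confusion_at_cutoff,
    cross_validate,
    evaluate_repeated,
    load_bundle,
    metrics_at_cutoff,
    metrics_from_confusion,
    save_bundle,
    train_model,
)
from nphosite.seqio import PeptideWindow
from nphosite.dataset import LabeledExample


def oracle_metrics(tp, fp, tn, fn):
    """Independent exact-rational implementation of the six statistics."""
    def frac(num, den):
        return float(Fraction(num, den)) if den else math.nan

    sens = frac(tp, tp + fn)
    spec = frac(tn, tn + fp)
    prec = frac(tp, tp + fp)
    if math.isnan(sens) or math.isnan(prec) or (tp + fp + fn) == 0 or \
            prec + sens == 0:
        f1 = math.nan
    else:
        f1 = float(2 * Fraction(tp, tp + fp) * Fraction(tp, tp + fn) /
                   (Fraction(tp, tp + fp) + Fraction(tp, tp + fn)))
    acc = frac(tp + tn, tp + fp + tn + fn)
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(den) if den else math.nan
    return {"sensitivity": sens, "specificity": spec, "precision": prec,
            "f1": f1, "accuracy": acc, "mcc": mcc}


def assert_metrics_equal(got, want):
    for name, expected in want.items():
        if math.isnan(expected):
            assert math.isnan(got[name]), name
        else:
            assert got[name] == pytest.approx(expected, abs=1e-12), name


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        got = metrics_from_confusion(ConfusionCounts(tp=1, fp=0, tn=1, fn=0))
        assert all(v == 1.0 for v in got.values())

    def test_degenerate_all_negative_predictor(self):
        got = metrics_from_confusion(ConfusionCounts(tp=0, fp=0, tn=27, fn=3))
        assert got["sensitivity"] == 0.0
        assert got["specificity"] == 1.0
        assert math.isnan(got["precision"])  # undefined, never reported as 0

    def test_worked_example(self):
        got = metrics_from_confusion(ConfusionCounts(tp=9, fn=3, fp=1, tn=27))
        assert got["sensitivity"] == pytest.approx(0.75)
        assert got["specificity"] == pytest.approx(27 / 28)
        assert got["precision"] == pytest.approx(0.9)
        assert got["f1"] == pytest.approx(0.8182, abs=5e-5)
        assert got["accuracy"] == pytest.approx(0.9)
        # 240 / sqrt(10*12*28*30), the Matthews coefficient
        assert got["mcc"] == pytest.approx(0.7559, abs=5e-5)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(ConfusionCounts(tp=0, fp=0, tn=0, fn=0))

    def test_exhaustive_sweep_against_rational_oracle(self):
        for tp in range(7):
            for fp in range(7):
                for tn in range(7):
                    for fn in range(7):
                        if tp + fp + tn + fn == 0:
                            continue
                        got = metrics_from_confusion(
                            ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
                        assert_metrics_equal(got, oracle_metrics(tp, fp, tn, fn))

    def test_random_tables_against_sklearn(self):
        from sklearn.metrics import (accuracy_score, f1_score,
                                     matthews_corrcoef, precision_score,
                                     recall_score)
        rng = np.random.default_rng(2)
        for _ in range(60):
            tp, fp, tn, fn = (int(x) for x in rng.integers(1, 40, size=4))
            y_true = np.r_[np.ones(tp + fn), np.zeros(fp + tn)]
            y_pred = np.r_[np.ones(tp), np.zeros(fn), np.ones(fp),
                           np.zeros(tn)]
            got = metrics_from_confusion(
                ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            assert got["sensitivity"] == pytest.approx(
                recall_score(y_true, y_pred))
            assert got["precision"] == pytest.approx(
                precision_score(y_true, y_pred))
            assert got["f1"] == pytest.approx(f1_score(y_true, y_pred))
            assert got["accuracy"] == pytest.approx(
                accuracy_score(y_true, y_pred))
            assert got["mcc"] == pytest.approx(
                matthews_corrcoef(y_true, y_pred))

    def test_mcc_extremes(self):
        for tp in range(5):
            for fp in range(5):
                for tn in range(5):
                    for fn in range(5):
                        if tp + fp + tn + fn == 0:
                            continue
                        mcc = metrics_from_confusion(
                            ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))["mcc"]
                        if not math.isnan(mcc):
                            if mcc == 1.0:
                                assert fp == fn == 0 and tp > 0 and tn > 0
                            if mcc == -1.0:
                                assert tp == tn == 0 and fp > 0 and fn > 0
        assert metrics_from_confusion(
            ConfusionCounts(tp=3, fp=0, tn=5, fn=0))["mcc"] == 1.0
        assert metrics_from_confusion(
            ConfusionCounts(tp=0, fp=4, tn=0, fn=2))["mcc"] == -1.0


class TestScoredMetrics:
    def test_confusion_at_cutoff(self):
        y = np.array([1, 1, 0, 0, 1])
        p = np.array([0.9, 0.4, 0.6, 0.1, 0.51])
        c = confusion_at_cutoff(y, p, 0.5)
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 1, 1)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, size=200)
        y[:5] = 1
        y[5:10] = 0
        p = rng.uniform(size=200) * 0.5 + y * 0.25
        a = metrics_at_cutoff(y, p)["auc"]
        b = metrics_at_cutoff(y, p ** 3)["auc"]  # cutoff metrics change, AUC not
        assert a == pytest.approx(b, abs=1e-12)


class TestMetricsReport:
    def test_single_repeat_has_zero_std(self):
        report = MetricsReport()
        report.add_repeat({"auc": 0.9, "accuracy": 0.8})
        assert report.std("auc") == 0.0
        assert report.mean("auc") == 0.9

    def test_table_format_is_percent_two_decimals(self):
        report = MetricsReport()
        report.add_repeat({"accuracy": 0.8916})
        report.add_repeat({"accuracy": 0.8814})
        lines = report.to_table().splitlines()
        assert lines[1].startswith("accuracy\t88.65\t")


def separable_examples(n=30):
    """Positives are K-rich pLys windows, negatives A-rich: trivially
    separable by composition."""
    out = []
    for i in range(n):
        pos_pep = "K" * 31
        neg_pep = "A" * 15 + "K" + "A" * 15
        out.append(LabeledExample(
            window=PeptideWindow(peptide=pos_pep, protein_id=f"P{i}",
                                 position=16),
            label=1, site_type="pLys"))
        out.append(LabeledExample(
            window=PeptideWindow(peptide=neg_pep, protein_id=f"N{i}",
                                 position=16),
            label=0, site_type="pLys"))
    return out


class TestTraining:
    def test_separable_toy_set_fits_perfectly(self):
        data = encode_examples(separable_examples(), "AAC")
        bundle = train_model(data, seed=0,
                             hyperparameters={"n_estimators": 20})
        prob = bundle.predict_proba(data.X)
        assert ((prob > 0.5).astype(int) == data.y).all()

    def test_single_class_input_rejected(self):
        data = encode_examples([e for e in separable_examples() if e.label],
                               "AAC")
        with pytest.raises(TrainingError):
            train_model(data, seed=0)

    def test_grid_search_selects_from_grid(self):
        data = encode_examples(separable_examples(60), "AAC")
        bundle = train_model(data, seed=0,
                             hyper_grid={"n_estimators": [10, 20]})
        assert bundle.hyperparameters["n_estimators"] in (10, 20)

    def test_bundle_round_trip_and_version_guard(self, tmp_path):
        data = encode_examples(separable_examples(), "AAC")
        bundle = train_model(data, seed=0,
                             hyperparameters={"n_estimators": 10})
        path = tmp_path / "model.joblib"
        save_bundle(bundle, path)
        back = load_bundle(path)
        assert back.site_type == "pLys"
        assert back.combo == "AAC"
        assert back.training_fingerprint == bundle.training_fingerprint
        assert np.array_equal(back.predict_proba(data.X),
                              bundle.predict_proba(data.X))
        import joblib
        payload = joblib.load(path)
        payload["format_version"] = 99
        joblib.dump(payload, path)
        with pytest.raises(ValueError, match="format version"):
            load_bundle(path)


class TestEvaluationProtocols:
    @pytest.fixture()
    def examples(self, small_benchmark):
        return small_benchmark["pHis"]

    def test_repeated_evaluation_is_deterministic(self, examples):
        plan = SplitPlan(n_repeats=2, seed=11)
        kwargs = dict(site_type="pHis", plan=plan, combo="AAC")
        a = evaluate_repeated(examples, **kwargs)
        b = evaluate_repeated(examples, **kwargs)
        assert a.to_dict() == b.to_dict()

    def test_report_carries_seven_metrics_with_std(self, examples):
        plan = SplitPlan(n_repeats=2, seed=11)
        report = evaluate_repeated(examples, "pHis", plan, combo="AAC")
        assert sorted(report.values) == sorted(
            ["sensitivity", "specificity", "precision", "f1", "accuracy",
             "mcc", "auc"])
        assert report.n_repeats == 2
        assert all(report.std(m) >= 0 for m in report.values)

    def test_cross_validation_pools_every_example_once(self, examples):
        mixed = examples[:40] + examples[-40:]  # positives lead the list
        data = encode_examples(mixed, "AAC")
        report = cross_validate(data, "pHis", k=4, repeats=2, seed=3)
        assert report.n_repeats == 2
        assert 0.0 <= report.mean("auc") <= 1.0

    def test_minimal_two_fold_case_runs(self):
        data = encode_examples(separable_examples(2), "AAC")  # 2 per class
        report = cross_validate(data, "pLys", k=2, repeats=1, seed=0)
        assert report.n_repeats == 1

    def test_fold_count_exceeding_class_size_rejected(self):
        data = encode_examples(separable_examples(3), "AAC")
        with pytest.raises(TrainingError):
            cross_validate(data, "pLys", k=10, repeats=1, seed=0)
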