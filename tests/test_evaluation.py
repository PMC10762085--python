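"""Metric correctness, acceptability labels, and the total-SD ROC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasegan import phantom
from phasegan.evaluation import (
    MetricRecord,
    acceptability_labels,
    comparison_table,
    evaluate_deterministic,
    evaluate_test_set,
    linear_predictor,
    nmse,
    psnr,
    roc_auc,
    ssim,
    summary_table,
)
from phasegan.linear_recon import fit_linear_models
from phasegan.phantom import build_dataset

from test_posterior import StubGenerator


class TestNmse:
    def test_identical_images_give_zero(self, rng):
        x = rng.normal(size=(5, 5))
        assert nmse(x, x) == 0.0

    def test_zero_prediction_gives_one(self, rng):
        x = rng.normal(size=(5, 5))
        assert nmse(x, np.zeros_like(x)) == pytest.approx(1.0)

    def test_hand_computed_3x3(self):
        x = np.arange(1, 10, dtype=float).reshape(3, 3)
        y = x.copy()
        y[0, 0] += 2.0
        y[2, 2] -= 1.0
        want = (4.0 + 1.0) / float((x**2).sum())
        assert nmse(x, y) == pytest.approx(want, abs=1e-15)

    def test_zero_norm_reference_rejected(self):
        with pytest.raises(ValueError):
            nmse(np.zeros((3, 3)), np.ones((3, 3)))

    def test_invariant_under_simultaneous_permutation(self, rng):
        x = rng.normal(size=(4, 4))
        y = rng.normal(size=(4, 4))
        perm = rng.permutation(16)
        assert nmse(x, y) == pytest.approx(
            nmse(x.ravel()[perm], y.ravel()[perm])
        )


class TestSsim:
    def test_self_similarity_is_one(self, rng):
        x = rng.uniform(-1, 1, size=(16, 16))
        assert ssim(x, x) == pytest.approx(1.0)

    def test_negated_locally_zero_mean_image_scores_negative(self):
        # pattern with ~zero mean inside every window, so the luminance term
        # stays ~1 and the sign is carried by the (negated) structure term
        r = np.arange(32)
        x = 0.5 * np.sin(2 * np.pi * r / 4.0)[:, None] * np.ones((1, 32))
        assert ssim(x, -x) < 0

    def test_image_smaller_than_window_rejected(self, rng):
        x = rng.normal(size=(8, 8))
        with pytest.raises(ValueError):
            ssim(x, x)


class TestPsnr:
    def test_mse_equal_to_squared_range_gives_zero_db(self):
        x = np.zeros((4, 4))
        y = np.full((4, 4), 2.0)
        assert psnr(x, y, data_range=2.0) == pytest.approx(0.0)

    def test_halving_rmse_adds_six_db(self, rng):
        x = rng.normal(size=(8, 8))
        e = rng.normal(size=(8, 8))
        a = psnr(x, x + e)
        b = psnr(x, x + 0.5 * e)
        assert b - a == pytest.approx(20 * np.log10(2), abs=1e-9)

    def test_hand_computed_2x2(self):
        x = np.array([[0.0, 1.0], [1.0, 0.0]])
        y = np.array([[0.5, 1.0], [1.0, -0.5]])
        mse = (0.25 + 0.25) / 4
        assert psnr(x, y, data_range=2.0) == pytest.approx(
            10 * np.log10(4.0 / mse), abs=1e-12
        )

    def test_identical_images_flagged_infinite(self, rng):
        x = rng.normal(size=(4, 4))
        assert np.isinf(psnr(x, x))

    def test_invalid_data_range_rejected(self, rng):
        x = rng.normal(size=(4, 4))
        with pytest.raises(ValueError):
            psnr(x, x, data_range=0.0)


def _records(nmses):
    return [
        MetricRecord(f"s{i}", 1 + i % 4, v, 0.5, 20.0, total_sd=float(i))
        for i, v in enumerate(nmses)
    ]


class TestAcceptability:
    def test_threshold_binning_with_inclusive_tie(self):
        labels = acceptability_labels(_records([0.05, 0.1, 0.2]), threshold=0.1)
        np.testing.assert_array_equal(labels, [True, True, False])

    def test_infinite_threshold_accepts_all(self):
        labels = acceptability_labels(_records([0.5, 3.0]), threshold=np.inf)
        assert labels.all()

    def test_labels_invariant_under_reordering(self, rng):
        vals = list(rng.uniform(0, 0.3, size=10))
        recs = _records(vals)
        a = acceptability_labels(recs)
        perm = rng.permutation(10)
        b = acceptability_labels([recs[i] for i in perm])
        np.testing.assert_array_equal(a[perm], b)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            acceptability_labels(_records([0.1]), threshold=0.0)


def _mann_whitney_auc(scores, labels):
    """Brute-force pair enumeration; lower score predicts the positive class."""
    pos = [-s for s, l in zip(scores, labels) if l]
    neg = [-s for s, l in zip(scores, labels) if not l]
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation_gives_one(self):
        sd = np.array([0.1, 0.2, 0.9, 1.4])
        acc = np.array([True, True, False, False])
        assert roc_auc(sd, acc).auc == 1.0

    def test_uninformative_scores_give_half(self, rng):
        sd = rng.uniform(size=4000)
        acc = rng.uniform(size=4000) < 0.5
        assert roc_auc(sd, acc).auc == pytest.approx(0.5, abs=0.05)

    def test_six_item_toy_equals_pair_enumeration(self):
        sd = [3.0, 1.0, 2.0, 2.0, 5.0, 4.0]
        acc = [True, True, False, True, False, False]
        got = roc_auc(np.array(sd), np.array(acc)).auc
        assert got == pytest.approx(_mann_whitney_auc(sd, acc), abs=1e-12)

    @given(
        scores=st.lists(
            st.integers(min_value=0, max_value=6), min_size=4, max_size=12
        ),
        labels=st.lists(st.booleans(), min_size=4, max_size=12),
    )
    @settings(max_examples=60, deadline=None)
    def test_auc_equals_mann_whitney_on_random_fixtures(self, scores, labels):
        n = min(len(scores), len(labels))
        scores, labels = scores[:n], labels[:n]
        if all(labels) or not any(labels):
            return
        got = roc_auc(np.array(scores, dtype=float), np.array(labels)).auc
        assert got == pytest.approx(_mann_whitney_auc(scores, labels), abs=1e-12)

    def test_rates_are_monotone(self, rng):
        sd = rng.uniform(size=50)
        acc = rng.uniform(size=50) < 0.4
        roc = roc_auc(sd, acc)
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="one class"):
            roc_auc(np.array([1.0, 2.0]), np.array([True, True]))


@pytest.fixture(scope="module")
def small_eval():
    train, _, test = build_dataset(20, image_size=16, seed=13)
    models = fit_linear_models(train)
    gen = StubGenerator(amplitude=0.05)
    records, table, roc = evaluate_test_set(gen, test, models, n_samples=8, seed=0)
    return test, models, records, table, roc


class TestEvaluateTestSet:

    def test_one_record_per_subject_and_phase(self, small_eval):
        test, _, records, _, _ = small_eval
        assert len(records) == 4 * test.n_subjects
        combos = {(r.subject_id, r.missing_index) for r in records}
        assert len(combos) == len(records)

    def test_combined_column_is_mean_over_all_records(self, small_eval):
        _, _, records, table, _ = small_eval
        assert table.loc["nmse", "combined"] == pytest.approx(
            np.mean([r.nmse for r in records])
        )
        j2 = [r.ssim for r in records if r.missing_index == 2]
        assert table.loc["ssim", "corticomedullary"] == pytest.approx(np.mean(j2))

    def test_deterministic_evaluation_of_linear_fill(self, small_eval):
        test, models, _, _, _ = small_eval
        recs = evaluate_deterministic(linear_predictor(models), test)
        assert len(recs) == 4 * test.n_subjects
        assert all(r.total_sd == 0.0 for r in recs)
        assert all(np.isfinite(r.nmse) for r in recs)

    def test_comparison_table_stacks_methods(self, small_eval):
        test, models, records, _, _ = small_eval
        lin = evaluate_deterministic(linear_predictor(models), test)
        table = comparison_table({"cGAN": records, "linear": lin})
        assert set(table.index.get_level_values("method")) == {"cGAN", "linear"}
        assert {"combined", "pre-contrast"} <= set(table.columns)


def test_reports_reproducible_byte_for_byte(tmp_path):
    train, _, test = build_dataset(12, image_size=16, seed=21)
    models = fit_linear_models(train)
    gen = StubGenerator(amplitude=0.05)
    outputs = []
    for _ in range(2):
        records, table, _ = evaluate_test_set(gen, test, models, n_samples=6, seed=4)
        p = tmp_path / f"t{_}.csv"
        table.to_csv(p)
        outputs.append(p.read_bytes())
    assert outputs[0] == outputs[1]
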