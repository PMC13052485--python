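"""Evaluation harness: LOPO folds, AUC vs a brute-force oracle, metrics,
aggregation, significance tests, per-peak analysis, benchmark plumbing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ramanadapt import synthetic as syn
from ramanadapt.baselines import PeakFeatureSet
from ramanadapt.cohort import Cohort, Spectrum
from ramanadapt.evaluation import (
    aggregate_repetitions,
    compare_models,
    compute_auc,
    compute_metrics,
    lopo_folds,
    univariate_peak_analysis,
    _parse_variant,
)


def brute_force_auc(scores, labels):
    """Independent oracle: enumerate every positive-negative pair; ties
    count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def _toy_cohort(patient_sizes: dict[str, int]) -> Cohort:
    wn = np.linspace(400, 2000, 32)
    spectra = []
    rng = np.random.default_rng(0)
    for pid, n in patient_sizes.items():
        for i in range(n):
            spectra.append(
                Spectrum(wn, rng.normal(size=32), pid, f"{pid}_{i}", int(rng.random() < 0.5))
            )
    return Cohort(spectra)


class TestLopoFolds:
    def test_ten_patients_ten_folds(self):
        cohort = _toy_cohort({f"P{i}": 3 for i in range(10)})
        plan = lopo_folds(cohort)
        assert len(plan.folds) == 10

    def test_two_patients_cross_train(self):
        plan = lopo_folds(_toy_cohort({"A": 2, "B": 2}))
        assert plan.folds == ((("B",), ("A",)), (("A",), ("B",)))

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError, match="2 patients"):
            lopo_folds(_toy_cohort({"A": 5}))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(1, 6), min_size=2, max_size=10))
    def test_partition_properties(self, sizes):
        cohort = _toy_cohort({f"P{i}": n for i, n in enumerate(sizes)})
        plan = lopo_folds(cohort)
        all_test = [p for _, test in plan.folds for p in test]
        assert sorted(all_test) == sorted(cohort.patients)  # each exactly once
        for train, test in plan.folds:
            assert not (set(train) & set(test))
            assert set(train) | set(test) == set(cohort.patients)


class TestAUC:
    def test_perfect_ranking(self):
        assert compute_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_half(self):
        assert compute_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_known_value_three_quarters(self):
        # pairs: (.9,.8)+, (.9,.2)+, (.7,.8)-, (.7,.2)+ -> 3/4
        assert compute_auc([0.9, 0.8, 0.7, 0.2], [1, 0, 1, 0]) == 0.75

    def test_matches_bruteforce_oracle_on_200_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(2, 31))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # quantized scores force ties regularly
            scores = np.round(rng.normal(size=n), 1)
            assert compute_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_auc([0.1, 0.2], [1, 1])


class TestMetrics:
    def test_confusion_count_example(self):
        # TP=83 FN=17 TN=72 FP=28 -> sensitivity .83, specificity .72
        scores = np.concatenate([np.ones(83), np.zeros(17), np.zeros(72), np.ones(28)])
        labels = np.concatenate([np.ones(100, int), np.zeros(100, int)])
        m = compute_metrics(scores, labels)
        assert m.sensitivity == pytest.approx(0.83)
        assert m.specificity == pytest.approx(0.72)
        assert m.accuracy == pytest.approx(0.775)
        assert m.ppv == pytest.approx(83 / 111)
        assert m.confusion == (83, 17, 72, 28)

    def test_all_correct_gives_ones(self):
        m = compute_metrics([0.9, 0.8, 0.1], [1, 1, 0])
        for name in ("auc", "accuracy", "sensitivity", "specificity", "ppv"):
            assert getattr(m, name) == 1.0

    def test_threshold_behaviour(self):
        assert compute_metrics([0.6, 0.4], [1, 0]).accuracy == 1.0

    def test_metrics_recomputable_from_confusion(self):
        rng = np.random.default_rng(5)
        scores = rng.random(40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        m = compute_metrics(scores, labels)
        tp, fn, tn, fp = m.confusion
        assert m.accuracy == (tp + tn) / (tp + fn + tn + fp)
        assert m.sensitivity == tp / (tp + fn)
        assert m.specificity == tn / (tn + fp)


class TestAggregationAndComparison:
    def _ms(self, v):
        from ramanadapt.evaluation import MetricSet
        return MetricSet(auc=v, accuracy=v, sensitivity=v, specificity=v, ppv=v)

    def test_identical_repetitions_sd_zero(self):
        agg = aggregate_repetitions([self._ms(0.8)] * 5)
        assert agg["auc"]["mean"] == 0.8 and agg["auc"]["sd"] == 0.0
        assert len(agg["auc"]["values"]) == 5

    def test_closed_form_mean_sd(self):
        agg = aggregate_repetitions([self._ms(0.7), self._ms(0.8)])
        assert agg["auc"]["mean"] == pytest.approx(0.75)
        assert agg["auc"]["sd"] == pytest.approx(0.0707106781, abs=1e-9)

    def test_single_repetition_rejected(self):
        with pytest.raises(ValueError, match="2 repetitions"):
            aggregate_repetitions([self._ms(0.5)])

    def test_identical_samples_p_one(self):
        out = compare_models([0.9, 0.9, 0.9], [0.9, 0.9, 0.9])
        assert out["difference"] == 0.0 and out["p_value"] == 1.0

    def test_separated_samples_tiny_p(self):
        rng = np.random.default_rng(1)
        a = 0.9 + rng.normal(0, 1e-3, 3)
        b = 0.1 + rng.normal(0, 1e-3, 3)
        out = compare_models(a, b)
        assert out["p_value"] < 1e-3
        assert out["difference"] == pytest.approx(0.8, abs=0.01)

    def test_against_scipy_oracle(self):
        from scipy import stats
        rng = np.random.default_rng(2)
        a = rng.normal(0.7, 0.05, 5)
        b = rng.normal(0.6, 0.08, 5)
        out = compare_models(a, b)
        t, p = stats.ttest_ind(a, b, equal_var=False)
        assert out["t"] == pytest.approx(t)
        assert out["p_value"] == pytest.approx(p)

    def test_ci_ordered(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            out = compare_models(rng.random(4), rng.random(4))
            assert out["ci_low"] <= out["ci_high"]


@pytest.fixture(scope="module")
def signal_cohort():
    from dataclasses import replace
    from ramanadapt.preprocessing import PreprocessConfig, preprocess_pipeline

    # Sharp lines (HWHM 2.5 cm^-1) keep the 994/997/1007 cluster
    # resolvable so the injected signal stays attributable to 997 alone;
    # moderate noise keeps per-band AUCs off saturation.
    peaks = tuple(
        replace(p, class_effect=1.5 if p.center == 997.0 else 1.0,
                shape="gaussian", width=2.5)
        for p in syn.DEFAULT_PEAKS
    )
    spec = syn.DomainSpec(name="uni", peaks=peaks, baseline_amplitude=2.0,
                          noise_sd=0.1, cosmic_ray_rate=0.0,
                          patient_effect_sd=0.05)
    cohort = syn.generate_cohort(spec, 12, 8, seed=31)
    cfg = PreprocessConfig(normalization="vector")
    return cohort.map(lambda s: preprocess_pipeline(s, cfg))


class TestUnivariatePeakAnalysis:
    def test_signal_peak_ranks_first_by_auc(self, signal_cohort):
        stats_list = univariate_peak_analysis(signal_cohort)
        best = max(stats_list, key=lambda s: s.auc)
        assert best.wavenumber == 997.0

    def test_shuffled_labels_cis_cover_zero(self, signal_cohort):
        rng = np.random.default_rng(9)
        labels = signal_cohort.labels()
        cover = []
        for _ in range(20):
            perm = rng.permutation(len(labels))
            shuffled = Cohort(
                [
                    Spectrum(s.wavenumbers, s.intensities, s.patient_id,
                             s.sample_id, int(labels[perm[i]]))
                    for i, s in enumerate(signal_cohort.spectra)
                ]
            )
            for ps in univariate_peak_analysis(shuffled):
                cover.append(ps.ci_low <= 0.0 <= ps.ci_high)
        assert np.mean(cover) >= 0.9

    def test_identical_distributions_zero_difference(self):
        wn = np.linspace(400, 2000, 64)
        s = np.sin(wn / 200) + 2
        spectra = [
            Spectrum(wn, s, f"P{i % 4}", f"S{i}", i % 2) for i in range(12)
        ]
        stats_list = univariate_peak_analysis(
            Cohort(spectra), PeakFeatureSet("one", (997.0,))
        )
        assert stats_list[0].mean_difference == 0.0
        assert stats_list[0].distribution_distance == 0.0

    def test_peak_outside_grid_rejected(self, signal_cohort):
        with pytest.raises(ValueError, match="outside grid"):
            univariate_peak_analysis(signal_cohort, PeakFeatureSet("bad", (9999.0,)))


class TestBenchmarkPlumbing:
    def test_grid_shape_and_determinism(self):
        """A 2-variant x 2-repetition grid yields 2x2 metric entries and a
        rerun with the same config reproduces them bit-identically."""
        from ramanadapt.evaluation import BenchmarkConfig, run_benchmark

        cfg = BenchmarkConfig(variants=("svm", "rf"), n_repetitions=2,
                              n_target_patients=4, spectra_per_patient=(5, 8),
                              seed=11)
        r1 = run_benchmark(cfg)
        r2 = run_benchmark(cfg)
        assert set(r1.summary) == {"svm", "rf"}
        for variant in ("svm", "rf"):
            for metric in ("auc", "accuracy", "sensitivity", "specificity", "ppv"):
                v1 = r1.summary[variant][metric]["values"]
                v2 = r2.summary[variant][metric]["values"]
                assert len(v1) == 2
                np.testing.assert_array_equal(v1, v2)  # NaN-aware equality
        table = r1.to_table()
        assert len(table) == 2 * 5
        assert "svm" in r1.render_text()


class TestVariantParsing:
    @pytest.mark.parametrize("name,expected", [
        ("no_p", ((), False, False)),
        ("no_p+F", ((), True, False)),
        ("pB+pC+F", (("pB", "pC"), True, False)),
        ("pC+TTA", (("pC",), False, True)),
        ("pB+pC+F+TTA", (("pB", "pC"), True, True)),
    ])
    def test_known_variants(self, name, expected):
        p = _parse_variant(name)
        assert (p["pretrain"], p["finetune"], p["tta"]) == expected

    def test_unknown_variant_lists_valid(self):
        with pytest.raises(ValueError, match="known variants"):
            _parse_variant("pX+F")
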