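"""Training, fine-tuning and test-time adaptation contracts."""

import numpy as np
import pytest

from ramanadapt import synthetic as syn
from ramanadapt.adaptation import (
    FinetuneConfig,
    TTAConfig,
    TrainConfig,
    entropy,
    finetune_efficient,
    pretrain,
    tta_adapt,
    train_supervised,
)
from ramanadapt.cohort import Cohort, Spectrum
from ramanadapt.resnet1d import ModelConfig, build_model, count_parameters


# ---------------------------------------------------------------- entropy

class TestEntropy:
    def test_uniform_is_ln2(self):
        assert entropy([0.5, 0.5]) == pytest.approx(np.log(2), abs=1e-12)

    def test_degenerate_is_zero(self):
        assert entropy([1.0, 0.0]) == 0.0

    def test_skewed_value(self):
        # independent evaluation: -(0.9 ln 0.9 + 0.1 ln 0.1) = 0.325083...
        assert entropy([0.9, 0.1]) == pytest.approx(0.3250829734, abs=1e-9)

    def test_bad_sum_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            entropy([0.5, 0.4])

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            entropy([1.2, -0.2])


# ------------------------------------------------------- synthetic helpers

def _separable_cohort(n_patients: int, per_patient: int, input_length: int,
                      seed: int, domain: str = "toy") -> Cohort:
    """Linearly separable two-peak problem: class decides which of two
    disjoint bands carries the signal."""
    rng = np.random.default_rng(seed)
    wn = np.linspace(400.0, 2000.0, input_length)
    band0 = np.exp(-0.5 * ((wn - 700) / 30) ** 2)
    band1 = np.exp(-0.5 * ((wn - 1500) / 30) ** 2)
    spectra = []
    for p in range(n_patients):
        pid = f"{domain}_P{p:02d}"
        for s in range(per_patient):
            label = s % 2  # balanced within every patient
            y = (band1 if label else band0) + rng.normal(0, 0.05, input_length)
            spectra.append(Spectrum(wn, y, pid, f"{pid}_S{s:02d}", label, domain))
    return Cohort(spectra, domain=domain)


@pytest.fixture(scope="module")
def toy_model_cfg():
    return ModelConfig(input_length=256, initial_filters=4, block_channels=(4,) * 6)


# ------------------------------------------------------------- pretraining

class TestPretrain:
    def test_always_improving_runs_max_epochs(self, toy_model_cfg, monkeypatch):
        model = build_model(toy_model_cfg, seed=0)
        cohort = _separable_cohort(10, 4, 256, seed=1)
        accs = iter(np.linspace(0.1, 0.9, 100))
        monkeypatch.setattr("ramanadapt.adaptation._accuracy", lambda *a, **k: next(accs))
        _, hist = pretrain(model, [cohort], TrainConfig(max_epochs=6, patience=3, seed=0))
        assert hist.n_epochs == 6 and not hist.stopped_early

    def test_constant_accuracy_stops_after_patience_plus_one(self, toy_model_cfg, monkeypatch):
        model = build_model(toy_model_cfg, seed=0)
        cohort = _separable_cohort(10, 4, 256, seed=1)
        monkeypatch.setattr("ramanadapt.adaptation._accuracy", lambda *a, **k: 0.5)
        _, hist = pretrain(model, [cohort], TrainConfig(max_epochs=25, patience=3, seed=0))
        assert hist.n_epochs == 4 and hist.stopped_early

    def test_best_weights_restored(self, toy_model_cfg, monkeypatch):
        model = build_model(toy_model_cfg, seed=0)
        cohort = _separable_cohort(10, 4, 256, seed=1)
        # accuracy peaks at epoch 2 then collapses
        accs = iter([0.5, 0.9, 0.2, 0.2, 0.2, 0.2])
        monkeypatch.setattr("ramanadapt.adaptation._accuracy", lambda *a, **k: next(accs, 0.2))
        _, hist = pretrain(model, [cohort], TrainConfig(max_epochs=6, patience=4, seed=0))
        assert hist.best_epoch == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_separable_problem_reaches_high_validation_accuracy(self, seed):
        cfg = ModelConfig(input_length=256, initial_filters=8, block_channels=(8,) * 6)
        model = build_model(cfg, seed=seed)
        cohort = _separable_cohort(20, 10, 256, seed=seed)
        _, hist = pretrain(
            model, [cohort], TrainConfig(max_epochs=12, patience=12, batch_size=16, seed=seed)
        )
        assert max(hist.val_accuracy) > 0.95

    def test_patients_never_split_across_partitions(self, toy_model_cfg):
        model = build_model(toy_model_cfg, seed=0)
        cohort = _separable_cohort(12, 5, 256, seed=3)
        _, hist = pretrain(model, [cohort], TrainConfig(max_epochs=1, patience=1, seed=0))
        test_idx = set(hist.test_indices.tolist())
        pids = [s.patient_id for s in cohort]
        test_pats = {pids[i] for i in test_idx}
        other_pats = {pids[i] for i in range(len(cohort)) if i not in test_idx}
        assert not (test_pats & other_pats)

    def test_empty_sources_rejected(self, toy_model_cfg):
        with pytest.raises(ValueError, match="nonempty"):
            pretrain(build_model(toy_model_cfg, seed=0), [], TrainConfig())


# ------------------------------------------------------------- fine-tuning

class TestFinetune:
    def test_frozen_groups_bitwise_unchanged(self, toy_model_cfg):
        model = build_model(toy_model_cfg, seed=1)
        before = {k: v.copy() for k, v in model.parameters().items()}
        target = _separable_cohort(8, 6, 256, seed=4)
        tuned, _ = finetune_efficient(
            model, target, FinetuneConfig(max_epochs=2, patience=2, seed=0)
        )
        frozen = [n for g in ("stem", "block_1", "block_2", "block_3")
                  for n in model.group_map[g]]
        trainable = [n for g in ("block_4", "block_5", "block_6", "head")
                     for n in model.group_map[g]]
        tuned_params = tuned.parameters()
        for n in frozen:
            np.testing.assert_array_equal(tuned_params[n], before[n])
        assert any(not np.array_equal(tuned_params[n], before[n]) for n in trainable)

    def test_input_model_not_mutated(self, toy_model_cfg):
        model = build_model(toy_model_cfg, seed=1)
        before = {k: v.copy() for k, v in model.parameters().items()}
        finetune_efficient(model, _separable_cohort(8, 6, 256, seed=4),
                           FinetuneConfig(max_epochs=1, patience=1, seed=0))
        for k, v in model.parameters().items():
            np.testing.assert_array_equal(v, before[k])

    def test_trainable_fraction_about_half(self, toy_model_cfg):
        model = build_model(toy_model_cfg, seed=0)
        tuned, _ = finetune_efficient(
            model, _separable_cohort(8, 6, 256, seed=5),
            FinetuneConfig(max_epochs=1, patience=1, seed=0),
        )
        frac = count_parameters(tuned, trainable_only=True) / count_parameters(tuned)
        assert frac <= 0.55

    def test_unknown_group_lists_valid_names(self, toy_model_cfg):
        model = build_model(toy_model_cfg, seed=0)
        cfg = FinetuneConfig(max_epochs=1, patience=1,
                             frozen_groups=("stem", "block_1", "block_2", "block_3"),
                             trainable_groups=("block_4", "block_5", "block_6", "head",
                                               "block_9"))
        with pytest.raises(ValueError, match="block_9"):
            finetune_efficient(model, _separable_cohort(8, 6, 256, seed=5), cfg)

    def test_uncovered_group_rejected(self, toy_model_cfg):
        model = build_model(toy_model_cfg, seed=0)
        cfg = FinetuneConfig(max_epochs=1, patience=1,
                             frozen_groups=("stem",),
                             trainable_groups=("head",))
        with pytest.raises(ValueError, match="neither frozen nor trainable"):
            finetune_efficient(model, _separable_cohort(8, 6, 256, seed=5), cfg)


# -------------------------------------------------- test-time adaptation

def _single_patient(cohort: Cohort) -> Cohort:
    return cohort.select_patients([cohort.patients[0]])


class TestTTA:
    def test_zero_steps_equals_unadapted(self, toy_model_cfg):
        model = build_model(toy_model_cfg, seed=2)
        patient = _single_patient(_separable_cohort(2, 6, 256, seed=6))
        res = tta_adapt(model, patient,
                        TTAConfig(n_steps=0, use_batch_statistics=False))
        np.testing.assert_array_equal(
            res.predictions, model.predict_proba(patient.intensity_matrix())
        )

    def test_entropy_trace_length_and_descent(self, toy_model_cfg):
        model = build_model(toy_model_cfg, seed=2)
        patient = _single_patient(_separable_cohort(2, 10, 256, seed=7))
        res = tta_adapt(model, patient, TTAConfig(n_steps=5))
        assert res.entropy_trace.shape == (len(patient), 6)
        frac = np.mean(res.entropy_trace[:, -1] <= res.entropy_trace[:, 0] + 1e-12)
        assert frac >= 0.9

    def test_model_restored_after_adaptation(self, toy_model_cfg):
        model = build_model(toy_model_cfg, seed=2)
        state_before = model.state_dict()
        patient = _single_patient(_separable_cohort(2, 8, 256, seed=8))
        tta_adapt(model, patient, TTAConfig())
        state_after = model.state_dict()
        for k, v in state_before.items():
            np.testing.assert_array_equal(v, state_after[k])

    def test_patient_order_does_not_matter(self, toy_model_cfg):
        model = build_model(toy_model_cfg, seed=3)
        cohort = _separable_cohort(2, 9, 256, seed=9)
        pa, pb = cohort.patients
        only_b = tta_adapt(model, cohort.select_patients([pb]), TTAConfig())
        tta_adapt(model, cohort.select_patients([pa]), TTAConfig())
        after_a_then_b = tta_adapt(model, cohort.select_patients([pb]), TTAConfig())
        np.testing.assert_array_equal(only_b.predictions, after_a_then_b.predictions)

    def test_multiple_patients_rejected(self, toy_model_cfg):
        model = build_model(toy_model_cfg, seed=3)
        cohort = _separable_cohort(2, 4, 256, seed=10)
        with pytest.raises(ValueError, match="single patient"):
            tta_adapt(model, cohort, TTAConfig())

    def test_wrong_length_rejected(self, toy_model_cfg):
        model = build_model(toy_model_cfg, seed=3)
        patient = _single_patient(_separable_cohort(1, 4, 128, seed=11))
        with pytest.raises(ValueError, match="input_length"):
            tta_adapt(model, patient, TTAConfig())

    def test_batch_statistics_replaced_then_restored(self, toy_model_cfg):
        model = build_model(toy_model_cfg, seed=4)
        patient = _single_patient(_separable_cohort(1, 12, 256, seed=12))
        rm_before = model.buffers()["stem.bn.running_mean"].copy()
        res_bs = tta_adapt(model, patient, TTAConfig(n_steps=0, use_batch_statistics=True))
        res_rs = tta_adapt(model, patient, TTAConfig(n_steps=0, use_batch_statistics=False))
        np.testing.assert_array_equal(model.buffers()["stem.bn.running_mean"], rm_before)
        assert not np.array_equal(res_bs.predictions, res_rs.predictions)


# --------------------------------------------- reproducibility end to end

def test_full_reproducibility_same_seeds(toy_model_cfg):
    def run():
        model = build_model(toy_model_cfg, seed=5)
        cohort = _separable_cohort(8, 5, 256, seed=13)
        model, _ = pretrain(model, [cohort],
                            TrainConfig(max_epochs=2, patience=2, seed=5))
        target = _separable_cohort(3, 5, 256, seed=14, domain="tgt")
        model, _ = finetune_efficient(model, target,
                                      FinetuneConfig(max_epochs=2, patience=2, seed=5))
        res = tta_adapt(model, _single_patient(target), TTAConfig())
        return res.predictions

    np.testing.assert_array_equal(run(), run())
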