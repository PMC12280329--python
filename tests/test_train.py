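"""Splitting, the multitask objective, and seeded two-stage training."""

import numpy as np
import pytest

from cystovit import (
    EncoderConfig,
    PhantomConfig,
    TrainConfig,
    generate_exams,
    multitask_loss,
    split_patients,
    train_image_model,
    train_patient_model,
)
from cystovit.image_model import TASKS
from cystovit.nn import Tensor, state_checksum


class TestSplitPatients:
    def test_cohort_sizes_at_seven_to_three(self):
        ids = [f"P{i}" for i in range(1270)]
        split = split_patients(ids, ratio=0.7, seed=0)
        assert (len(split.train_ids), len(split.val_ids)) == (889, 381)

    def test_small_cohort_rounding(self):
        split = split_patients([str(i) for i in range(10)], ratio=0.7, seed=1)
        assert (len(split.train_ids), len(split.val_ids)) == (7, 3)

    def test_deterministic_and_disjoint(self):
        ids = [f"P{i}" for i in range(41)]
        a = split_patients(ids, seed=9)
        b = split_patients(ids, seed=9)
        assert a.train_ids == b.train_ids and a.val_ids == b.val_ids
        assert not (a.train_ids & a.val_ids)
        assert a.train_ids | a.val_ids == set(ids)

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            split_patients(["a", "b", "a"])


def _fake_logits(targets, n_classes, scale):
    z = np.zeros((len(targets), n_classes), dtype=np.float32)
    z[np.arange(len(targets)), targets] = scale
    return Tensor(z)


class TestMultitaskLoss:
    def _targets(self):
        return dict(bladder=np.array([1, 0]), urethra=np.array([0, 0]),
                    lvur=np.array([3, 0]), rvur=np.array([0, 5]))

    def test_loss_floor_at_perfect_prediction(self):
        cfg = TrainConfig(label_smoothing=0.0, class_weighting="none")
        targets = self._targets()
        logits = {t: _fake_logits(targets[t], 2 if t in ("bladder", "urethra")
                                  else 6, 60.0) for t in TASKS}
        mask = np.zeros((2, 4096), dtype=int)
        mask[:, :500] = 1
        pixel_logits = np.full((2, 4096, 4), -60.0, dtype=np.float32)
        pixel_logits[np.arange(2)[:, None], np.arange(4096)[None], mask] = 60.0
        total, terms = multitask_loss(logits, targets, cfg,
                                      pixel_logits=Tensor(pixel_logits),
                                      mask_targets=mask)
        assert float(total.data) <= 1e-5
        assert terms["seg_dice"] <= 1e-6
        assert all(terms[f"ce_{t}"] <= 1e-6 for t in TASKS)

    def test_lambda_seg_zero_gives_classification_only(self):
        cfg = TrainConfig(lambda_seg=0.0, class_weighting="none")
        targets = self._targets()
        logits = {t: _fake_logits(targets[t], 2 if t in ("bladder", "urethra")
                                  else 6, 1.0) for t in TASKS}
        total, terms = multitask_loss(logits, targets, cfg)
        assert float(total.data) == pytest.approx(
            sum(terms[f"ce_{t}"] for t in TASKS), abs=1e-6)
        assert "seg_ce" not in terms

    def test_uniform_six_class_prediction_costs_ln6(self):
        cfg = TrainConfig(lambda_task=(1, 1, 1, 1), lambda_seg=0.0,
                          class_weighting="none")
        targets = self._targets()
        logits = {t: Tensor(np.zeros((2, 2 if t in ("bladder", "urethra")
                                      else 6))) for t in TASKS}
        _, terms = multitask_loss(logits, targets, cfg)
        assert terms["ce_lvur"] == pytest.approx(np.log(6), abs=1e-6)
        assert terms["ce_bladder"] == pytest.approx(np.log(2), abs=1e-6)

    def test_breakdown_sums_to_total(self, rng):
        cfg = TrainConfig()
        targets = self._targets()
        logits = {t: Tensor(rng.normal(size=(2, 2 if t in ("bladder", "urethra")
                                              else 6)).astype(np.float32))
                  for t in TASKS}
        mask = rng.integers(0, 4, size=(2, 4096))
        pl = Tensor(rng.normal(size=(2, 4096, 4)).astype(np.float32))
        total, terms = multitask_loss(logits, targets, cfg, pixel_logits=pl,
                                      mask_targets=mask)
        assert float(total.data) == pytest.approx(
            sum(v for k, v in terms.items() if k != "total"), abs=1e-5)

    def test_out_of_range_label_rejected(self):
        cfg = TrainConfig(lambda_seg=0.0)
        targets = self._targets()
        targets["lvur"] = np.array([6, 0])
        logits = {t: Tensor(np.zeros((2, 2 if t in ("bladder", "urethra")
                                      else 6))) for t in TASKS}
        with pytest.raises(ValueError, match="label"):
            multitask_loss(logits, targets, cfg)


@pytest.fixture(scope="module")
def smoke_exams():
    return generate_exams(PhantomConfig(n_patients=8, seed=31))


class TestTrainingLoops:
    def test_image_training_reduces_loss_and_is_seeded(self, smoke_exams):
        cfg = TrainConfig(stage="image", epochs=3, batch_size=8, lr=3e-3,
                          seed=4, seg_warmup_epochs=0)
        enc = EncoderConfig.tiny()
        model_a, hist_a = train_image_model(smoke_exams, enc, cfg)
        assert hist_a[-1]["total"] < hist_a[0]["total"]
        model_b, hist_b = train_image_model(smoke_exams, enc, cfg)
        assert hist_b[-1]["total"] == pytest.approx(hist_a[-1]["total"], abs=1e-5)
        sa = model_a.named_state()
        sb = model_b.named_state()
        assert all(np.array_equal(sa[k], sb[k]) for k in sa)

    def test_patient_stage_never_touches_backbone(self, smoke_exams):
        enc = EncoderConfig.tiny()
        image_cfg = TrainConfig(stage="image", epochs=1, batch_size=8, seed=4,
                                seg_warmup_epochs=0)
        model, _ = train_image_model(smoke_exams, enc, image_cfg)
        checksum = state_checksum(model)
        patient_cfg = TrainConfig(stage="patient", epochs=5, batch_size=4,
                                  lr=5e-3, seed=4)
        net, hist = train_patient_model(smoke_exams, model, patient_cfg)
        assert state_checksum(model) == checksum
        assert hist[-1]["loss"] < hist[0]["loss"]


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(stage="finetune")
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(lambda_seg=-1.0)
    with pytest.raises(ValueError):
        TrainConfig(class_weighting="focal")
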