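"""Patient-level attention pooling: oracle equivalence and set invariances."""

import numpy as np
import pytest

from cystovit import ExamBundle, PatientNet, attention_pool, predict_patient
from cystovit.image_model import TASKS
from cystovit.nn import state_checksum
from cystovit.patient_model import ExamFeatures, WeightMap, export_weight_map, extract_features


def loop_attention_oracle(features, queries, wk, wv):
    """Independent loop-based softmax-weighted-sum reference."""
    n, d = features.shape
    pooled = np.zeros((len(queries), d))
    weights = np.zeros((len(queries), n))
    for t, q in enumerate(queries):
        scores = []
        for i in range(n):
            k_i = features[i] @ wk[t]
            scores.append(float(q @ k_i) / np.sqrt(d))
        scores = np.asarray(scores)
        e = np.exp(scores - scores.max())
        w = e / e.sum()
        weights[t] = w
        for i in range(n):
            pooled[t] += w[i] * (features[i] @ wv[t])
    return pooled, weights


class TestAttentionPool:
    def test_matches_loop_oracle_on_100_random_instances(self, rng):
        bank = PatientNet(embed_dim=16, seed=1)
        for trial in range(100):
            n = int(rng.integers(1, 8))
            feats = rng.normal(size=(n, 16)).astype(np.float32)
            pooled, wm = attention_pool(feats, bank)
            ref_pooled, ref_w = loop_attention_oracle(
                feats.astype(np.float64), bank.queries.data.astype(np.float64),
                bank.key_proj.data.astype(np.float64),
                bank.value_proj.data.astype(np.float64))
            np.testing.assert_allclose(wm.weights, ref_w, atol=1e-6)
            np.testing.assert_allclose(pooled, ref_pooled, atol=1e-5)

    def test_identity_projection_oracle(self, rng):
        bank = PatientNet(embed_dim=8, seed=0, identity_proj=True)
        feats = rng.normal(size=(3, 8)).astype(np.float32)
        pooled, wm = attention_pool(feats, bank)
        q = bank.queries.data
        scores = feats @ q.T / np.sqrt(8)               # (3, 4)
        e = np.exp(scores - scores.max(axis=0))
        w = (e / e.sum(axis=0)).T                       # (4, 3)
        np.testing.assert_allclose(wm.weights, w, atol=1e-6)
        np.testing.assert_allclose(pooled, w @ feats, atol=1e-5)

    def test_single_image_gets_weight_one(self, rng):
        bank = PatientNet(embed_dim=8, seed=0)
        _, wm = attention_pool(rng.normal(size=(1, 8)), bank)
        np.testing.assert_allclose(wm.weights, np.ones((4, 1)))

    def test_identical_rows_get_uniform_weights(self, rng):
        bank = PatientNet(embed_dim=8, seed=0)
        row = rng.normal(size=8)
        _, wm = attention_pool(np.stack([row] * 5), bank)
        np.testing.assert_allclose(wm.weights, np.full((4, 5), 0.2), atol=1e-6)

    def test_rows_are_distributions(self, rng):
        bank = PatientNet(embed_dim=8, seed=0)
        _, wm = attention_pool(rng.normal(size=(6, 8)), bank)
        assert (wm.weights >= 0).all()
        np.testing.assert_allclose(wm.weights.sum(axis=1), 1.0, atol=1e-6)

    def test_empty_exam_rejected(self, rng):
        bank = PatientNet(embed_dim=8, seed=0)
        with pytest.raises(ValueError):
            attention_pool(np.zeros((0, 8)), bank)


class TestPredictPatient:
    def test_feature_extraction_shape_frozen_deterministic(self, tiny_model, small_exams):
        exam = small_exams[0]
        before = state_checksum(tiny_model)
        f1 = extract_features(exam, tiny_model)
        f2 = extract_features(exam, tiny_model)
        assert f1.matrix.shape == (len(exam.images), 64)
        np.testing.assert_array_equal(f1.matrix, f2.matrix)
        assert state_checksum(tiny_model) == before

    def test_permutation_equivariance_and_invariance(self, tiny_model, small_exams):
        exam = next(e for e in small_exams if len(e.images) >= 3)
        net = PatientNet(embed_dim=64, seed=2)
        pred = predict_patient(exam, tiny_model, net)
        perm = [len(exam.images) - 1 - i for i in range(len(exam.images))]
        flipped = ExamBundle(exam.patient_truth, [exam.images[i] for i in perm])
        pred_f = predict_patient(flipped, tiny_model, net)
        np.testing.assert_allclose(pred_f.weight_map.weights,
                                   pred.weight_map.weights[:, perm], atol=1e-6)
        for t in TASKS:
            np.testing.assert_allclose(getattr(pred_f.probs, t),
                                       getattr(pred.probs, t), atol=1e-6)

    def test_duplicating_images_halves_weights_keeps_probs(self, tiny_model, small_exams):
        exam = small_exams[1]
        net = PatientNet(embed_dim=64, seed=2)
        pred = predict_patient(exam, tiny_model, net)
        doubled = ExamBundle(exam.patient_truth, list(exam.images) * 2)
        pred_d = predict_patient(doubled, tiny_model, net)
        n = len(exam.images)
        np.testing.assert_allclose(pred_d.weight_map.weights[:, :n],
                                   pred.weight_map.weights / 2.0, atol=1e-6)
        for t in TASKS:
            np.testing.assert_allclose(getattr(pred_d.probs, t),
                                       getattr(pred.probs, t), atol=1e-6)

    def test_predicted_labels_in_codomain(self, tiny_model, small_exams):
        net = PatientNet(embed_dim=64, seed=2)
        for exam in small_exams:
            pred = predict_patient(exam, tiny_model, net)
            assert pred.labels["bladder"] in (0, 1)
            assert pred.labels["urethra"] in (0, 1)
            assert pred.labels["lvur"] in range(6)
            assert pred.labels["rvur"] in range(6)
            assert pred.n_images == len(exam.images)


def test_export_weight_map_roundtrip(tmp_path, tiny_model, small_exams):
    import pandas as pd
    net = PatientNet(embed_dim=64, seed=2)
    pred = predict_patient(small_exams[0], tiny_model, net)
    out = tmp_path / "wm.csv"
    df = export_weight_map(pred, out)
    assert len(df) == 4
    back = pd.read_csv(out, index_col=0)
    np.testing.assert_allclose(back.to_numpy(), pred.weight_map.weights,
                               atol=1e-4)
    assert (out.with_suffix(".json")).exists()


def test_weight_map_validation():
    with pytest.raises(ValueError):
        WeightMap(np.array([[0.5, 0.6]] * 4))      # rows must sum to 1
    with pytest.raises(ValueError):
        WeightMap(np.array([[1.0], [1.0]]))        # needs 4 task rows
    with pytest.raises(ValueError):
        ExamFeatures(matrix=np.zeros((0, 8)), image_ids=[])
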