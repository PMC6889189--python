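"""Eigenvector construction, RBF kernel, subsampling and grid-search training."""

import numpy as np
import pytest

from indelfuse.callset_io import REPEAT_CLASSES
from indelfuse.errors import ConfigError, TrainingError
from indelfuse.matching import MergedCall
from indelfuse.svmm import (
    SvmConfig,
    build_features,
    classify,
    grid_search_train,
    rbf_kernel,
    subsample_training,
    train,
)

CALLERS = ("alpha", "beta", "gamma", "delta", "epsilon")


def merged(callers_reads, vtype="DEL", size=3, rt="NonRepeat", pos=100):
    return MergedCall(
        chrom="chr1",
        pos=pos,
        ref_allele="A" * size if vtype == "DEL" else "",
        alt_allele="" if vtype == "DEL" else "A" * size,
        vtype=vtype,
        size=size,
        repeat_class=rt,
        region_length=0 if rt == "NonRepeat" else 20,
        reads_by_caller=tuple(callers_reads),
    )


class TestBuildFeatures:
    def test_single_detector_reads_passthrough(self):
        x = build_features([merged([("alpha", 12)])], CALLERS)
        assert x[0, -1] == 12

    def test_multi_detector_reads_sum(self):
        x = build_features([merged([("alpha", 10), ("beta", 7)])], CALLERS)
        assert x[0, -1] == 17

    def test_ds_indicator_encoding(self):
        cand = merged([("alpha", 5), ("gamma", 5)], vtype="DEL", size=3,
                      rt="SimpleRepeat")
        x = build_features([cand], CALLERS)
        assert x[0, :5].tolist() == [1, 0, 1, 0, 0]
        assert x[0, 5] == 0  # DEL encodes as 0
        assert x[0, 6] == 3  # size
        rt_block = x[0, 7 : 7 + len(REPEAT_CLASSES)]
        assert rt_block.sum() == 1
        assert rt_block[REPEAT_CLASSES.index("SimpleRepeat")] == 1

    def test_zero_detectors_rejected(self):
        with pytest.raises(ConfigError):
            build_features([merged([])], CALLERS)


class TestRbfKernel:
    def test_identical_vectors_give_one(self):
        u = np.array([1.0, 2.0, 3.0])
        assert rbf_kernel(u, u, gamma=0.7) == 1.0

    def test_unit_distance_closed_form(self):
        assert rbf_kernel(np.array([0.0]), np.array([1.0]), 1.0) == pytest.approx(
            np.exp(-1)
        )

    def test_matches_elementwise_formula(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            u, v = rng.normal(size=6), rng.normal(size=6)
            gamma = float(rng.uniform(0.01, 3))
            expected = np.exp(-gamma * sum((a - b) ** 2 for a, b in zip(u, v)))
            assert rbf_kernel(u, v, gamma) == pytest.approx(expected)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            u, v = rng.normal(size=4), rng.normal(size=4)
            k = rbf_kernel(u, v, 0.5)
            assert k == pytest.approx(rbf_kernel(v, u, 0.5))
            assert 0 < k <= 1

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel(np.zeros(3), np.zeros(4), 1.0)


class TestSubsample:
    def test_under_cap_returns_everything(self):
        x = np.arange(500).reshape(-1, 1).astype(float)
        y = np.where(np.arange(500) % 3 == 0, 1, -1)
        xs, ys = subsample_training(x, y, cap=100_000, seed=0)
        assert len(xs) == 500

    def test_stratification_preserves_label_ratio(self):
        y = np.array([1] * 600 + [-1] * 400)
        x = np.arange(1000).reshape(-1, 1).astype(float)
        xs, ys = subsample_training(x, y, cap=100, seed=0)
        assert len(ys) == 100
        assert abs(int(np.sum(ys == 1)) - 60) <= 1
        assert abs(int(np.sum(ys == -1)) - 40) <= 1

    def test_same_seed_same_subset(self):
        y = np.array([1, -1] * 500)
        x = np.arange(1000).reshape(-1, 1).astype(float)
        a = subsample_training(x, y, cap=50, seed=9)
        b = subsample_training(x, y, cap=50, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


def separable_candidates(rng, n=200):
    """True calls carry >= 10 reads, false ones <= 2: linearly separable."""
    cands, labels = [], []
    for i in range(n):
        positive = i % 2 == 0
        reads = int(rng.integers(10, 40)) if positive else int(rng.integers(0, 3))
        cands.append(merged([("alpha", reads)], pos=100 + i))
        labels.append("TP" if positive else "FP")
    return cands, labels


class TestGridSearchTrain:
    def test_separable_toy_reaches_perfect_cv_and_heldout(self):
        rng = np.random.default_rng(6)
        cands, labels = separable_candidates(rng, n=200)
        config = SvmConfig(folds=3, seed=0)
        model = train(cands, labels, CALLERS, config)
        assert model.cv_accuracy == 1.0
        held, held_labels = separable_candidates(np.random.default_rng(7), n=100)
        accepted, rejected = classify(model, held)
        accepted_set = {id(c) for c in accepted}
        for cand, lab in zip(held, held_labels):
            assert (id(cand) in accepted_set) == (lab == "TP")

    def test_single_grid_point_is_chosen(self):
        rng = np.random.default_rng(8)
        cands, labels = separable_candidates(rng, n=60)
        config = SvmConfig(c_grid=(4.0,), gamma_grid=(0.25,), folds=2, seed=0)
        model = train(cands, labels, CALLERS, config)
        assert (model.chosen_c, model.chosen_gamma) == (4.0, 0.25)

    def test_permuted_labels_score_near_majority_rate(self):
        rng = np.random.default_rng(9)
        cands, labels = separable_candidates(rng, n=800)
        permuted = list(labels)
        rng.shuffle(permuted)
        majority = max(permuted.count("TP"), permuted.count("FP")) / len(permuted)
        config = SvmConfig(
            c_grid=(1.0,), gamma_grid=(0.5,), folds=5, seed=0
        )
        model = train(cands, permuted, CALLERS, config)
        assert model.cv_accuracy == pytest.approx(majority, abs=0.05)

    def test_single_class_training_rejected(self):
        x = np.ones((10, 3))
        y = np.ones(10)
        with pytest.raises(TrainingError):
            grid_search_train(x, y, SvmConfig(), CALLERS)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(10)
        cands, labels = separable_candidates(rng, n=120)
        config = SvmConfig(folds=3, seed=5)
        m1 = train(cands, labels, CALLERS, config)
        m2 = train(cands, labels, CALLERS, config)
        assert (m1.chosen_c, m1.chosen_gamma) == (m2.chosen_c, m2.chosen_gamma)
        probe = build_features(cands, CALLERS)
        assert np.array_equal(m1.predict(probe), m2.predict(probe))


def test_classify_empty_candidates():
    rng = np.random.default_rng(11)
    cands, labels = separable_candidates(rng, n=60)
    model = train(cands, labels, CALLERS, SvmConfig(c_grid=(4.0,), gamma_grid=(0.25,), folds=2))
    assert classify(model, []) == ([], [])


def test_model_roundtrip(tmp_path):
    rng = np.random.default_rng(12)
    cands, labels = separable_candidates(rng, n=80)
    model = train(cands, labels, CALLERS, SvmConfig(c_grid=(4.0,), gamma_grid=(0.25,), folds=2))
    path = str(tmp_path / "model.joblib")
    model.save(path)
    from indelfuse.svmm import SvmModel

    again = SvmModel.load(path)
    probe = build_features(cands, CALLERS)
    assert np.array_equal(again.predict(probe), model.predict(probe))
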