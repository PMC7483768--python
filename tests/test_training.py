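"""Augmentation, balanced batching, SGD training and fold packing."""

import itertools
import numpy as np
import pytest

from cribnet.annotations import BiopsyRecord
from cribnet.labels import LabelSet
from cribnet.nn import NetworkConfig, build_network
from cribnet.preprocess import PatchSample, pool_mask
from cribnet.training import (AugmentConfig, Checkpoint, TrainConfig,
                              TrainingRun, apply_geometric, apply_photometric,
                              augment, balanced_batches, bin_pack_folds,
                              sample_augment_params, select_checkpoint,
                              train_one)
from tests.conftest import one_hot_from_labelmap


def make_patch(label, size=32, factor=2, color=0.5, rng=None):
    """A PatchSample dominated by one label (with a non-labelled border)."""
    rng = rng or np.random.default_rng(0)
    labelmap = np.zeros((size, size), dtype=np.uint8)
    labelmap[4:-4, 4:-4] = label
    y_full = one_hot_from_labelmap(labelmap)
    img = np.full((size, size, 3), color, dtype=np.float32)
    img += 0.05 * rng.standard_normal(img.shape).astype(np.float32)
    img = np.clip(img, 0, 1)
    return PatchSample(image=img, origin=(0, 0), y_full=y_full,
                       y_pooled=pool_mask(y_full, factor),
                       labels_present=tuple(np.unique(labelmap)))


class TestAugment:
    def _identity_params(self):
        return {"flip_v": False, "flip_h": False, "angle_deg": 0.0,
                "scale": 1.0, "translate": (0.0, 0.0),
                "channel_shift": (0.0, 0.0, 0.0),
                "range_lo": 0.0, "range_hi": 1.0}

    def test_horizontal_flip_is_involution(self):
        rng = np.random.default_rng(0)
        img = rng.random((32, 32, 3)).astype(np.float32)
        y = one_hot_from_labelmap(rng.integers(0, 7, (32, 32)))
        params = self._identity_params()
        params["flip_h"] = True
        cfg = AugmentConfig()
        img1, y1 = apply_geometric(params, img, y, cfg)
        img2, y2 = apply_geometric(params, img1, y1, cfg)
        assert np.allclose(img2, img, atol=1e-6)
        assert np.array_equal(y2, y)

    def test_identity_params_are_identity(self):
        rng = np.random.default_rng(1)
        img = rng.random((16, 16, 3)).astype(np.float32)
        y = one_hot_from_labelmap(rng.integers(0, 7, (16, 16)))
        img1, y1 = apply_geometric(self._identity_params(), img, y,
                                   AugmentConfig())
        assert np.allclose(img1, img, atol=1e-6)
        assert np.array_equal(y1, y)

    def test_sampled_parameters_within_ranges(self):
        cfg = AugmentConfig()
        rng = np.random.default_rng(2)
        for _ in range(10000):
            p = sample_augment_params(cfg, rng)
            assert -5.0 <= p["angle_deg"] <= 5.0
            assert 0.9 <= p["scale"] <= 1.1
            assert all(-0.1 <= t <= 0.1 for t in p["translate"])
            assert all(-0.05 <= s <= 0.05 for s in p["channel_shift"])
            assert 0.0 <= p["range_lo"] <= 0.1
            assert 0.9 <= p["range_hi"] <= 1.0

    def test_landmark_transported_with_mask(self):
        # the same draw moves an image landmark and its mask pixel together,
        # and both land where the forward affine predicts
        params = {"flip_v": False, "flip_h": True, "angle_deg": 4.0,
                  "scale": 1.05, "translate": (0.04, -0.06),
                  "channel_shift": (0, 0, 0), "range_lo": 0.0, "range_hi": 1.0}
        size = 64
        img = np.zeros((size, size, 3), dtype=np.float32)
        y = np.zeros((7, size, size), dtype=np.uint8)
        y[0] = 1
        landmark = (40, 22)
        img[landmark] = 1.0
        y[0][landmark] = 0
        y[3][landmark] = 1
        img_t, y_t = apply_geometric(params, img, y, AugmentConfig(
            fill_rgb=(0.0, 0.0, 0.0)))
        # forward affine: flip -> rotate -> scale -> translate about center
        c = np.array([(size - 1) / 2] * 2)
        f = np.diag([1.0, -1.0])
        th = np.deg2rad(4.0)
        r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        expected = 1.05 * (r @ f) @ (np.array(landmark) - c) + c \
            + np.array([0.04 * size, -0.06 * size])
        got_mask = np.argwhere(y_t[3])
        assert len(got_mask) >= 1
        d_mask = np.abs(got_mask - expected).sum(axis=1).min()
        got_img = np.argwhere(img_t[..., 0] > 0.05)
        d_img = np.abs(got_img - expected).sum(axis=1).min()
        assert d_mask <= 1.5 and d_img <= 1.5

    def test_photometric_range_rescale(self):
        img = np.array([[[0.0, 0.5, 1.0]]], dtype=np.float32)
        params = self._identity_params()
        params["range_lo"], params["range_hi"] = 0.1, 0.9
        out = apply_photometric(params, img)
        # linear map of the full [0,1] range onto [lo, hi]
        assert np.allclose(out, [0.1, 0.5, 0.9], atol=1e-6)

    def test_augment_preserves_pooled_normalization(self):
        rng = np.random.default_rng(3)
        img = rng.random((32, 32, 3)).astype(np.float32)
        y = one_hot_from_labelmap(rng.integers(0, 7, (32, 32)))
        img_a, y_a = augment(img, y, AugmentConfig(), rng)
        pooled = pool_mask(y_a, 8)
        assert np.abs(pooled.sum(axis=0) - 1.0).max() < 1e-6


class TestBalancedBatches:
    def test_seven_single_label_patches_form_permutations(self, labelset):
        samples = [make_patch(l) for l in range(7)]
        # patch l contains label l and the non-labelled border
        gen = balanced_batches(samples, labelset, np.random.default_rng(0))
        for _ in range(5):
            batch = next(gen)
            assert len(batch) == 7
            union = set()
            for s in batch:
                union.update(s.labels_present)
            assert union == set(range(7))

    def test_empty_pool_names_label(self, labelset):
        samples = [make_patch(0)]       # only non-labelled
        with pytest.raises(ValueError, match="G3"):
            next(balanced_batches(samples, labelset, np.random.default_rng(0)))

    def test_draw_frequencies_uniform_within_pool(self, labelset):
        # two patches carry the cribriform label; over many batches each is
        # drawn for the cribriform slot equally often (3-sigma binomial)
        samples = [make_patch(l) for l in range(7)] + [make_patch(6)]
        gen = balanced_batches(samples, labelset, np.random.default_rng(1))
        counts = {6: 0, 7: 0}
        n = 2000
        for _ in range(n):
            batch = next(gen)
            crib = [s for s in batch if 6 in s.labels_present]
            assert crib
            for s in crib:
                idx = next(i for i, t in enumerate(samples) if t is s)
                counts[idx] += 1
        total = counts[6] + counts[7]
        sigma = np.sqrt(total * 0.5 * 0.5)
        assert abs(counts[6] - total / 2) <= 3 * sigma


class TestSelection:
    def _ckpt(self, it, v):
        return Checkpoint(iteration=it, weights={}, dice=v, specificity=v,
                          v={1.0: v})

    def test_single_checkpoint(self):
        run = TrainingRun(checkpoints=[self._ckpt(0, -0.5)], log=[])
        assert select_checkpoint(run, 1.0).iteration == 0

    def test_monotone_decreasing_takes_last(self):
        run = TrainingRun(checkpoints=[self._ckpt(i, -0.1 * i)
                                       for i in range(5)], log=[])
        assert select_checkpoint(run, 1.0).iteration == 4

    def test_interior_minimum(self):
        vs = [-0.1, -0.5, -0.9, -0.4, -0.2]
        run = TrainingRun(checkpoints=[self._ckpt(i, v)
                                       for i, v in enumerate(vs)], log=[])
        assert select_checkpoint(run, 1.0).iteration == 2

    def test_tie_takes_earliest(self):
        vs = [-0.3, -0.9, -0.9, -0.5]
        run = TrainingRun(checkpoints=[self._ckpt(i, v)
                                       for i, v in enumerate(vs)], log=[])
        assert select_checkpoint(run, 1.0).iteration == 1


@pytest.fixture(scope="module")
def tiny_setup():
    labelset = LabelSet()
    rng = np.random.default_rng(0)
    # color-coded classes: trivially separable, good for smoke testing
    samples = [make_patch(l, color=0.15 + 0.1 * l, rng=rng)
               for l in range(7) for _ in range(2)]
    cfg = NetworkConfig(n_blocks=2, base_features=4, input_size=32,
                        se_reduction=4)
    return labelset, samples, cfg


class TestTrainOne:
    def test_zero_iterations_initial_checkpoint_only(self, tiny_setup):
        labelset, samples, ncfg = tiny_setup
        net = build_network(ncfg, seed=0)
        run = train_one(net, samples, samples[:7],
                        TrainConfig(iterations=0, seed=0), labelset)
        assert len(run.checkpoints) == 1
        assert run.checkpoints[0].iteration == 0

    def test_loss_decreases_on_separable_data(self, tiny_setup):
        labelset, samples, ncfg = tiny_setup
        net = build_network(ncfg, seed=1)
        run = train_one(net, samples, samples[:7],
                        TrainConfig(iterations=50, checkpoint_interval=50,
                                    seed=1), labelset)
        first = np.mean([r["loss"] for r in run.log[:5]])
        last = np.mean([r["loss"] for r in run.log[-5:]])
        assert last < first

    def test_identical_seeds_identical_trajectories(self, tiny_setup):
        labelset, samples, ncfg = tiny_setup
        runs = []
        for _ in range(2):
            net = build_network(ncfg, seed=3)
            runs.append(train_one(net, samples, samples[:7],
                                  TrainConfig(iterations=10,
                                              checkpoint_interval=5, seed=3),
                                  labelset))
        va = [ck.v[1.0] for ck in runs[0].checkpoints]
        vb = [ck.v[1.0] for ck in runs[1].checkpoints]
        assert np.allclose(va, vb, atol=1e-6)
        la = [r["loss"] for r in runs[0].log]
        lb = [r["loss"] for r in runs[1].log]
        assert np.allclose(la, lb, atol=1e-6)

    def test_checkpoint_cadence(self, tiny_setup):
        labelset, samples, ncfg = tiny_setup
        net = build_network(ncfg, seed=4)
        run = train_one(net, samples, samples[:7],
                        TrainConfig(iterations=7, checkpoint_interval=3,
                                    seed=4), labelset)
        assert [ck.iteration for ck in run.checkpoints] == [0, 3, 6, 7]


def record(bid, crib=0, g3=0, fused=0):
    counts = {}
    if crib:
        counts["G4 cribriform"] = crib
    if g3:
        counts["G3"] = g3
    if fused:
        counts["G4 fused"] = fused
    return BiopsyRecord(image_path=f"{bid}.png", region_counts=counts,
                        biopsy_id=bid)


class TestBinPacking:
    def test_sixteen_singletons_two_per_fold(self):
        records = [record(f"b{i:02d}", crib=1) for i in range(16)]
        fa = bin_pack_folds(records, k=8)
        loads = [fa.tallies[f]["G4 cribriform"] for f in range(1, 9)]
        assert loads == [2] * 8

    def test_known_instance_matches_exhaustive_optimum(self):
        counts = [5, 4, 3, 2, 1, 1]
        records = [record(f"b{i}", crib=c) for i, c in enumerate(counts)]
        fa = bin_pack_folds(records, k=3)
        loads = sorted((fa.tallies[f]["G4 cribriform"] for f in range(1, 4)),
                       reverse=True)
        best = min(max(sum(c for c, a in zip(counts, assign) if a == f)
                       for f in range(3))
                   for assign in itertools.product(range(3), repeat=6))
        assert loads[0] == best == 6

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            bin_pack_folds([record("a"), record("b")], k=3)

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_and_tallies_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 24))
        k = int(rng.integers(2, min(8, n)))
        records = [record(f"b{i:02d}", crib=int(rng.integers(0, 4)),
                          g3=int(rng.integers(0, 6)),
                          fused=int(rng.integers(0, 3))) for i in range(n)]
        fa = bin_pack_folds(records, k=k)
        # partition: each biopsy in exactly one fold
        assert sorted(fa.folds) == sorted(r.biopsy_id for r in records)
        assert set(fa.folds.values()) <= set(range(1, k + 1))
        # tallies recomputed from scratch match stored tallies
        by_id = {r.biopsy_id: r for r in records}
        for f in range(1, k + 1):
            for lab in fa.tallies[f]:
                expected = sum(by_id[bid].count(lab)
                               for bid, ff in fa.folds.items() if ff == f)
                assert fa.tallies[f][lab] == expected
        # greedy bound on cribriform imbalance
        crib_loads = [fa.tallies[f].get("G4 cribriform", 0)
                      for f in range(1, k + 1)]
        max_single = max((r.count("G4 cribriform") for r in records),
                         default=0)
        if max_single:
            assert max(crib_loads) - min(crib_loads) <= max_single
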