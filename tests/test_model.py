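"""Architecture-level contracts of the MIB ST-GCN."""

import numpy as np
import pytest

import gaitgcn.nn as nn
from gaitgcn.graph import SkeletonGraph, kinect_v2_graph, partition_adjacency
from gaitgcn.model import (
    MIBNetwork,
    ModelConfig,
    build_mib_network,
    count_parameters,
    load_checkpoint,
    save_checkpoint,
    temporal_weight_count,
)

SMALL = ModelConfig(branch_width=8, main_width=8, num_classes=6, seed=3)


def random_batch(rng, n=2, t=16, v=25, branches=("joint", "velocity", "bone")):
    return {
        name: rng.normal(size=(n, 6, t, v)).astype(np.float32)
        for name in branches
    }


class TestForwardContracts:
    def test_logit_shape_and_finiteness(self, rng):
        model = build_mib_network(SMALL)
        logits = model.forward(random_batch(rng, n=3))
        assert logits.shape == (3, 6)
        assert np.all(np.isfinite(logits))

    def test_zero_input_zero_bias_gives_zero_logits(self):
        model = build_mib_network(SMALL)
        batch = {
            name: np.zeros((2, 6, 16, 25), dtype=np.float32)
            for name in model.branch_names
        }
        logits = model.forward(batch)
        assert np.abs(logits).max() == 0.0

    def test_missing_branch_rejected(self, rng):
        model = build_mib_network(SMALL)
        batch = random_batch(rng)
        del batch["bone"]
        with pytest.raises(ValueError, match="missing input branches"):
            model.forward(batch)

    def test_stride_two_blocks_quarter_the_frames(self, rng):
        model = build_mib_network(SMALL)
        model.forward(random_batch(rng, t=64))
        assert model.feature_map.shape[1] == 16  # 64 / 2 / 2

    def test_single_branch_architecture(self, rng):
        cfg = ModelConfig(branch_width=8, main_width=8,
                          branches=("velocity",), seed=0)
        model = build_mib_network(cfg)
        logits = model.forward(
            random_batch(rng, branches=("velocity",))
        )
        assert logits.shape == (2, 6)


class TestPermutationInvariance:
    def test_logits_invariant_under_joint_relabeling(self, rng, kinect):
        perm = rng.permutation(25)
        inv = np.argsort(perm)
        remapped_edges = tuple(
            (int(inv[i]), int(inv[j])) for i, j in kinect.edges
        )
        permuted_graph = SkeletonGraph(
            num_joints=25,
            edges=remapped_edges,
            center_joint=int(inv[kinect.center_joint]),
        )
        model_a = MIBNetwork(SMALL, kinect)
        model_b = MIBNetwork(SMALL, permuted_graph)
        model_b.load_state(model_a.state())  # identical weights

        batch = random_batch(rng, t=16)
        permuted = {k: v[:, :, :, perm] for k, v in batch.items()}
        model_a.set_training(False)
        model_b.set_training(False)
        la = model_a.forward(batch)
        lb = model_b.forward(permuted)
        assert np.abs(la - lb).max() <= 1e-4


class TestAttentionAblation:
    def test_identity_mask_reproduces_attention_free_network(self, rng):
        cfg_on = SMALL
        cfg_off = ModelConfig(branch_width=8, main_width=8, num_classes=6,
                              seed=3, attention_on=False)
        model_on = build_mib_network(cfg_on)
        model_off = build_mib_network(cfg_off)
        model_on.set_attention_identity(True)
        batch = random_batch(rng, t=16)
        model_on.set_training(False)
        model_off.set_training(False)
        la = model_on.forward(batch)
        lb = model_off.forward(batch)
        # same seed stream per layer slot → identical shared weights,
        # identity attention → bit-identical logits
        assert np.array_equal(la, lb)

    def test_attention_sites_report_scores(self, rng):
        model = build_mib_network(SMALL)
        model.forward(random_batch(rng, t=16))
        scores = model.attention_scores()
        assert len(scores) == 9  # 3 branches × 3 attention blocks
        for fs, js in scores:
            assert fs.min() > 0.0 and fs.max() < 1.0
            assert js.min() > 0.0 and js.max() < 1.0


class TestParameterCounting:
    def test_total_matches_closed_form_enumeration(self):
        cfg = ModelConfig(branch_width=8, main_width=8, num_classes=6,
                          seed=0, separable=False, attention_on=False,
                          branches=("joint",))
        model = build_mib_network(cfg)
        V, K, k = 25, 3, cfg.temporal_kernel

        def gcn(ci, co):
            return K * ci * co + co

        def tc(ci, co, kern):
            return kern * ci * co + co

        def bn(c):
            return 2 * c

        def block(ci, co, residual):
            n = gcn(ci, co) + bn(co)
            n += 2 * (tc(co, co, k) + bn(co))  # block_depth = 2
            if residual:
                n += tc(ci, co, 1) + bn(co)
            return n

        expected = bn(V * 6)              # input batchnorm over V·C
        expected += block(6, 8, True)     # initial
        expected += block(8, 4, True) + block(4, 4, False) + block(4, 8, True)
        expected += block(8, 8, True) + block(8, 16, True)  # stride-2 main
        expected += 16 * 6 + 6            # classifier
        assert count_parameters(model)["total"] == expected

    def test_wider_model_has_strictly_more_parameters(self):
        small = count_parameters(
            build_mib_network(ModelConfig(branch_width=8, main_width=8))
        )["total"]
        doubled = count_parameters(
            build_mib_network(ModelConfig(branch_width=16, main_width=16))
        )["total"]
        assert doubled > small

    def test_separable_counts_at_64_channels_kernel_9(self):
        assert temporal_weight_count(64, 64, 9, False) == 36864
        assert temporal_weight_count(64, 64, 9, True) == 4672

    def test_separable_smaller_whenever_kernel_exceeds_one(self):
        for ci, co, k in [(4, 8, 3), (16, 16, 9), (32, 64, 5)]:
            assert temporal_weight_count(ci, co, k, True) < \
                temporal_weight_count(ci, co, k, False)

    def test_1x1_kernel_separable_offers_no_reduction(self):
        std = temporal_weight_count(16, 16, 1, False)
        sep = temporal_weight_count(16, 16, 1, True)
        assert sep == std + 16  # depthwise overhead only

    def test_comparison_report_lists_temporal_layers(self):
        model = build_mib_network(SMALL)
        report = count_parameters(model, separable_comparison=True)
        rows = report["temporal_layers"]
        assert len(rows) == 2 * 14  # block_depth=2 × (4×3 branch + 2 main)
        for row in rows:
            assert row["separable"] < row["standard"]


class TestConfigValidation:
    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            ModelConfig(temporal_kernel=8)

    def test_empty_branches_rejected(self):
        with pytest.raises(ValueError, match="branch"):
            ModelConfig(branches=())

    def test_unknown_branch_rejected(self):
        with pytest.raises(ValueError, match="unknown branches"):
            ModelConfig(branches=("joint", "torque"))

    def test_reduction_must_divide_width(self):
        with pytest.raises(ValueError, match="divide"):
            ModelConfig(branch_width=6, attention_reduction=4)


class TestCheckpoint:
    def test_round_trip_reproduces_logits(self, tmp_path, rng):
        model = build_mib_network(SMALL)
        batch = random_batch(rng, t=16)
        model.set_training(False)
        before = model.forward(batch)
        path = tmp_path / "ckpt.h5"
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        restored.set_training(False)
        after = restored.forward(batch)
        assert np.array_equal(before, after)
        assert restored.config == model.config
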