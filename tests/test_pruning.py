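"""Structured pruning: importance accumulation, plan arithmetic, surgery
correctness via the masking-equivalence oracle, and the iterative
schedule's bookkeeping."""

import copy

import numpy as np
import pytest

from octlayers.network import ModelSpec, build_model, count_parameters
from octlayers.pruning import (ImportanceTable, accumulate_importance,
                               apply_prune, iterative_prune,
                               mask_pruned_channels, plan_prune)


@pytest.fixture
def small_net():
    return build_model(ModelSpec(n_classes=3, channels=(8, 8, 16, 16, 16)),
                       seed=1)


@pytest.fixture
def batches(rng):
    return [rng.random((2, 32, 32), dtype=np.float32) for _ in range(3)]


class TestAccumulateImportance:
    def test_single_batch_equals_alpha(self, small_net, batches):
        table = accumulate_importance(small_net, batches[:1])
        small_net.eval()
        small_net(batches[0])
        for g, unit in small_net.attention_units.items():
            np.testing.assert_allclose(table.scores[g],
                                       unit.ca.last_alpha.sum(axis=0),
                                       rtol=1e-6)

    def test_duplicated_dataset_doubles_scores(self, small_net, batches):
        one = accumulate_importance(small_net, batches)
        two = accumulate_importance(small_net, batches + batches)
        for g in one.scores:
            np.testing.assert_allclose(two.scores[g], 2 * one.scores[g],
                                       rtol=1e-6)

    def test_batch_order_invariance(self, small_net, batches):
        fwd = accumulate_importance(small_net, batches)
        rev = accumulate_importance(small_net, batches[::-1])
        for g in fwd.scores:
            np.testing.assert_allclose(fwd.scores[g], rev.scores[g],
                                       rtol=1e-6)

    def test_empty_dataset_rejected(self, small_net):
        with pytest.raises(ValueError, match="nonempty"):
            accumulate_importance(small_net, [])

    def test_dead_kernel_ranks_low(self, batches):
        """A kernel whose weights and bias are zero produces a constant
        zero channel; on nonnegative inputs its pooled statistic is
        minimal among channels, so its attention-derived score is low
        within its group."""
        net = build_model(ModelSpec(n_classes=2, channels=(8, 8, 8, 8, 8)),
                          seed=0)
        unit = net.registry["enc1.conv1"]
        unit.conv.weight.data[3] = 0.0
        # make the attention MLP order-preserving in z so the score
        # reflects the pooled statistic directly
        ca = unit.ca
        ca.fc1.weight.data[...] = np.eye(ca.fc1.weight.data.shape[0],
                                         ca.fc1.weight.data.shape[1])
        ca.fc2.weight.data[...] = np.eye(ca.fc2.weight.data.shape[0],
                                         ca.fc2.weight.data.shape[1])
        table = accumulate_importance(net, batches)
        scores = table.scores["enc1.mid"]
        assert scores[3] == scores.min()


class TestPlanPrune:
    def make_table(self, scores):
        return ImportanceTable(scores={"g": np.asarray(scores, dtype=float)},
                               kept={"g": list(range(len(scores)))},
                               batches_seen=1)

    def test_worked_example(self):
        plan = plan_prune(self.make_table([0.1, 0.9, 0.5, 0.2]), 0.25,
                          min_kept=1)
        assert plan.kept["g"] == [1, 2, 3]

    def test_zero_ratio_is_identity(self):
        plan = plan_prune(self.make_table([0.3, 0.1, 0.2]), 0.0)
        assert plan.kept["g"] == [0, 1, 2]

    def test_floor_arithmetic_n32_r20(self):
        rng = np.random.default_rng(0)
        plan = plan_prune(self.make_table(rng.random(32)), 0.2, min_kept=4)
        assert len(plan.kept["g"]) == 26  # 32 - floor(0.2*32) = 26

    def test_tie_removes_lower_index_first(self):
        plan = plan_prune(self.make_table([0.5, 0.5, 0.5, 0.9]), 0.25,
                          min_kept=1)
        assert plan.kept["g"] == [1, 2, 3]

    def test_min_kept_floor(self):
        plan = plan_prune(self.make_table([0.1, 0.2, 0.3, 0.4]), 0.9,
                          min_kept=3)
        assert len(plan.kept["g"]) == 3

    def test_invalid_ratio(self):
        with pytest.raises(ValueError, match="ratio"):
            plan_prune(self.make_table([0.1]), 1.0)


class TestApplyPrune:
    def test_identity_surgery_exact(self, small_net, batches):
        table = accumulate_importance(small_net, batches)
        pruned = apply_prune(small_net, plan_prune(table, 0.0))
        small_net.eval()
        pruned.eval()
        s0, t0 = small_net(batches[0])
        s1, t1 = pruned(batches[0])
        np.testing.assert_array_equal(s0.data, s1.data)
        np.testing.assert_array_equal(t0.data, t1.data)

    @pytest.mark.parametrize("ratio", [0.2, 0.4])
    def test_masking_equivalence_oracle(self, small_net, batches, ratio):
        """Zeroing the to-be-pruned kernels (weights, bias, BN affine) in
        the original model reproduces the pruned model's forward output."""
        table = accumulate_importance(small_net, batches)
        plan = plan_prune(table, ratio, min_kept=2)
        pruned = apply_prune(small_net, plan)
        masked = copy.deepcopy(small_net)
        mask_pruned_channels(masked, plan)
        pruned.eval()
        masked.eval()
        for x in batches[:2]:
            sp, tp = pruned(x)
            sm, tm = masked(x)
            np.testing.assert_allclose(sp.data, sm.data, atol=1e-5)
            np.testing.assert_allclose(tp.data, tm.data, atol=1e-5)

    def test_random_plan_masking_equivalence(self, small_net, batches, rng):
        """Arbitrary (not importance-derived) plans also satisfy the
        oracle, exercising the full dependency graph."""
        plan = plan_prune(accumulate_importance(small_net, batches), 0.0)
        for g in plan.kept:
            n = len(plan.kept[g])
            keep = max(2, n - int(rng.integers(0, n - 1)))
            plan.kept[g] = sorted(
                rng.choice(n, size=keep, replace=False).tolist())
        pruned = apply_prune(small_net, plan)
        masked = copy.deepcopy(small_net)
        mask_pruned_channels(masked, plan)
        pruned.eval()
        masked.eval()
        sp, tp = pruned(batches[0])
        sm, tm = masked(batches[0])
        np.testing.assert_allclose(sp.data, sm.data, atol=1e-5)
        np.testing.assert_allclose(tp.data, tm.data, atol=1e-5)

    def test_parameter_count_decreases(self, small_net, batches):
        table = accumulate_importance(small_net, batches)
        pruned = apply_prune(small_net, plan_prune(table, 0.25, min_kept=2))
        assert count_parameters(pruned) < count_parameters(small_net)

    def test_output_shapes_unchanged(self, small_net, batches):
        table = accumulate_importance(small_net, batches)
        pruned = apply_prune(small_net, plan_prune(table, 0.3, min_kept=2))
        pruned.eval()
        s, t = pruned(batches[0])
        assert s.data.shape == (2, 3, 32, 32)
        assert t.data.shape == (2, 3, 32, 32)

    def test_inconsistent_plan_names_layer(self, small_net, batches):
        plan = plan_prune(accumulate_importance(small_net, batches), 0.0)
        plan.kept["enc1.out"] = [0, 99]
        with pytest.raises(ValueError):
            apply_prune(small_net, plan)

    def test_encoder_prune_propagates_to_consumers(self, small_net, batches):
        """Dependency closure: pruning an encoder group shrinks the input
        of every consumer (next encoder block, both branch fusion levels
        and their gates)."""
        plan = plan_prune(accumulate_importance(small_net, batches), 0.0)
        plan.kept["enc1.out"] = [0, 2, 4, 6]
        pruned = apply_prune(small_net, plan)
        reg = pruned.registry
        consumers = [n for n, u in small_net.registry.items()
                     if "enc1.out" in u.in_groups]
        assert sorted(consumers) == sorted(
            ["enc2.conv1", "enc2.proj",
             "seg1.gf.w2", "bou1.gf.w2", "seg1.fuse", "bou1.fuse"])
        for name in consumers:
            old_in = small_net.registry[name].conv.in_ch
            assert reg[name].conv.in_ch == old_in - 4


class TestIterativeSchedule:
    def test_noop_schedule(self, easy_dataset):
        tr, va = easy_dataset
        from octlayers.training import TrainConfig
        net = build_model(ModelSpec(n_classes=5, channels=(8, 8, 16, 16, 16)),
                          seed=1)
        cfg = TrainConfig(epochs=1, batch_size=4, crop=64, seed=0)
        before = count_parameters(net)
        # r=0 with a zero-epoch fine-tune is pure bookkeeping
        model, history = iterative_prune(
            net, tr[:4], va[:2], 0.0, n_iters=1, finetune_epochs=0,
            train_config=cfg)
        assert count_parameters(model) == before
        assert len(history) == 1

    def test_retention_follows_geometric_decay(self, easy_dataset):
        """After i iterations at ratio r each group keeps about
        n*(1-r)^i kernels (exactly, given per-iteration flooring)."""
        tr, va = easy_dataset
        from octlayers.training import TrainConfig
        net = build_model(ModelSpec(n_classes=5, channels=(8, 8, 16, 16, 16)),
                          seed=0)
        cfg = TrainConfig(epochs=0, batch_size=4, crop=64, seed=0)
        r = 0.25
        n_iters = 3
        model, history = iterative_prune(
            net, tr[:4], va[:2], r, n_iters=n_iters, finetune_epochs=0,
            train_config=cfg, min_kept=2)
        assert len(history) == n_iters
        assert history["params"].is_monotonic_decreasing
        spec = history["spec"].iloc[-1]   # final iteration (not best ckpt)
        for g, nominal in spec.groups.items():
            expect = nominal
            for _ in range(n_iters):
                expect = max(2, expect - int(np.floor(r * expect)))
            assert spec.width(g) == expect
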