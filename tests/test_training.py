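"""Training loop behaviour at toy scale: stages, logging, prediction."""

from dataclasses import replace

import numpy as np
import pytest

from curriseg import RunConfig, ablate, predict, train
from curriseg.training import ABLATION_MODES, _MODE_MASKS


@pytest.fixture(scope="module")
def short_run(tiny_pools_module, tiny_config_module, tmp_path_factory):
    labeled, unlabeled, val = tiny_pools_module
    run_dir = tmp_path_factory.mktemp("run")
    result = train(tiny_config_module, labeled, unlabeled, val=val,
                   run_dir=run_dir, mode="full")
    return result, run_dir


@pytest.fixture(scope="module")
def tiny_pools_module(request):
    return request.getfixturevalue("tiny_pools")


@pytest.fixture(scope="module")
def tiny_config_module():
    from curriseg import BackboneConfig, CurriculumSchedule
    return RunConfig(
        backbone=BackboneConfig(base_width=4, depth=2, embed_dim=8),
        schedule=CurriculumSchedule(stage1_epochs=1, patch_counts=(4, 16),
                                    trigger_epochs=(2, 4), total_epochs=4),
        resolution=32, seed=0, eval_every=2)


class TestTwoStageRegime:
    def test_stage1_has_no_consistency_and_stage2_no_contrast(self, short_run):
        result, _ = short_run
        stage1 = [r for r in result.loss_log if r["epoch"] < 1]
        stage2 = [r for r in result.loss_log if r["epoch"] >= 1]
        assert stage1 and stage2
        assert all(r["l_cc"] == 0.0 for r in stage1)
        assert all(r["l_msc"] > 0.0 for r in stage1)
        assert all(r["l_msc"] == 0.0 for r in stage2)
        assert all(r["l_cc"] > 0.0 for r in stage2)

    def test_m_t_follows_schedule(self, short_run):
        result, _ = short_run
        by_epoch = {}
        for r in result.loss_log:
            by_epoch.setdefault(r["epoch"], set()).add(r["m_t"])
        assert by_epoch[0] == {0}
        assert by_epoch[1] == {4}
        assert by_epoch[2] == {16} and by_epoch[3] == {16}

    def test_losses_finite_at_every_step(self, short_run):
        result, _ = short_run
        for r in result.loss_log:
            assert np.isfinite(r["total"])

    def test_logs_and_checkpoint_written(self, short_run):
        result, run_dir = short_run
        assert (run_dir / "losses.csv").exists()
        assert (run_dir / "metrics.csv").exists()
        header = (run_dir / "losses.csv").read_text().splitlines()[0]
        assert header == "epoch,step,l_sup,l_cc,l_msc,total,m_t"
        assert (run_dir / "best.ckpt.npz").exists()


class TestDeterminism:
    def test_seeded_runs_produce_identical_loss_curves(
            self, tiny_pools_module, tiny_config_module):
        labeled, unlabeled, val = tiny_pools_module
        cfg = replace(tiny_config_module,
                      schedule=replace(tiny_config_module.schedule,
                                       total_epochs=2, trigger_epochs=(1, 2),
                                       patch_counts=(4, 16)))
        # identical seeds -> bit-identical curves; different seed -> different
        curves = []
        for seed in (5, 5, 6):
            res = train(replace(cfg, seed=seed), labeled, unlabeled, val=val)
            curves.append([r["total"] for r in res.loss_log])
        assert curves[0] == curves[1]
        assert curves[0] != curves[2]


class TestPredict:
    def test_output_shapes_probabilities_and_threshold(self, short_run,
                                                       tiny_pools_module):
        result, _ = short_run
        _, _, val = tiny_pools_module
        masks, probs = predict(result.model, val.images)
        n, _, h, w = val.images.shape
        assert masks.shape == probs.shape == (n, h, w)
        assert probs.min() >= 0.0 and probs.max() <= 1.0
        np.testing.assert_array_equal(masks, (probs >= 0.5).astype(np.uint8))

    def test_repeated_calls_identical(self, short_run, tiny_pools_module):
        result, _ = short_run
        _, _, val = tiny_pools_module
        _, a = predict(result.model, val.images)
        _, b = predict(result.model, val.images)
        np.testing.assert_array_equal(a, b)


class TestValidationCarving:
    def test_val_carved_from_labeled_when_absent(self, tiny_dataset):
        from curriseg import ArrayDataset
        ds = tiny_dataset
        labeled = ArrayDataset(ds.images[:4], ds.masks[:4], ds.stems[:4])
        unlabeled = ArrayDataset(ds.images[4:], None, ds.stems[4:])
        from curriseg import BackboneConfig, CurriculumSchedule
        cfg = RunConfig(
            backbone=BackboneConfig(base_width=4, depth=2, embed_dim=8),
            schedule=CurriculumSchedule(stage1_epochs=1, patch_counts=(4,),
                                        trigger_epochs=(1,), total_epochs=1),
            resolution=32, seed=0, eval_every=1)
        result = train(cfg, labeled, unlabeled, mode="supervised_only")
        assert result.init_report.n_images == 1  # 10% of 4, floored to one

    def test_val_without_masks_rejected(self, tiny_pools, tiny_config):
        from curriseg import ArrayDataset
        labeled, unlabeled, val = tiny_pools
        bad_val = ArrayDataset(val.images, None, val.stems)
        with pytest.raises(ValueError, match="masks"):
            train(tiny_config, labeled, unlabeled, val=bad_val)


class TestAblation:
    def test_mode_masks_match_contract(self):
        assert _MODE_MASKS["supervised_only"] == (0.0, 0.0)
        assert _MODE_MASKS["no_cc"] == (0.0, 1.0)
        assert _MODE_MASKS["no_msc"] == (1.0, 0.0)
        assert set(ABLATION_MODES) == set(_MODE_MASKS)

    def test_supervised_only_never_computes_unsup_losses(
            self, tiny_pools_module, tiny_config_module):
        labeled, unlabeled, val = tiny_pools_module
        res = train(tiny_config_module, labeled, unlabeled, val=val,
                    mode="supervised_only")
        assert all(r["l_cc"] == 0.0 and r["l_msc"] == 0.0
                   for r in res.loss_log)

    def test_no_cc_zeroes_alpha_throughout(self, tiny_pools_module,
                                           tiny_config_module):
        labeled, unlabeled, val = tiny_pools_module
        res = train(tiny_config_module, labeled, unlabeled, val=val,
                    mode="no_cc")
        assert all(r["l_cc"] == 0.0 for r in res.loss_log)
        assert any(r["l_msc"] > 0.0 for r in res.loss_log)

    def test_ablate_tabulates_modes_on_shared_seeds(self, tiny_pools_module,
                                                    tiny_config_module):
        labeled, unlabeled, val = tiny_pools_module
        table = ablate(tiny_config_module, labeled, unlabeled, val=val,
                       modes=("supervised_only",), seeds=(0, 1))
        row = table["supervised_only"]
        assert {"dice_mean", "dice_sd", "miou_mean", "mae_mean",
                "per_seed"} <= set(row)
        assert len(row["per_seed"]) == 2
        assert row["dice_mean"] == pytest.approx(
            np.mean([r["dice"] for r in row["per_seed"]]))


def test_invalid_mode_rejected(tiny_pools, tiny_config):
    labeled, unlabeled, val = tiny_pools
    with pytest.raises(ValueError, match="mode"):
        train(tiny_config, labeled, unlabeled, val=val, mode="bogus")
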