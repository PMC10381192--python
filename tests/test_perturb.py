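import math

import numpy as np
import pytest

from _oracles import dice_oracle
from conftest import make_mask
from segstab.core import GridMismatchError
from segstab.perturb import (
    AugmentationConfig,
    SliceParams,
    apply_inplane,
    apply_outplane,
    augment,
    dice,
    sample_inplane_params,
    sample_outplane_shift,
)
from segstab.phantom import PhantomSpec, generate_phantom_mask


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dw_bound": -1},
            {"n_contours": 0},
            {"scenario": "diagonal"},
            {"bias": "none"},
            {"slice_shift_max": -1},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            AugmentationConfig(**kwargs)


class TestDice:
    def test_identical_masks(self, block_mask):
        assert dice(block_mask, block_mask) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((6, 6, 2), dtype=np.uint8)
        b = np.zeros((6, 6, 2), dtype=np.uint8)
        a[0:2, 0:2, 0] = 1
        b[4:6, 4:6, 0] = 1
        assert dice(make_mask(a), make_mask(b)) == 0.0

    def test_hand_counted_overlap(self):
        # two 2x2x1 blocks overlapping in 2 voxels -> 2*2/(4+4) = 0.5
        a = np.zeros((4, 4, 1), dtype=np.uint8)
        b = np.zeros((4, 4, 1), dtype=np.uint8)
        a[0:2, 0:2, 0] = 1
        b[1:3, 0:2, 0] = 1
        assert dice(make_mask(a), make_mask(b)) == 0.5

    def test_both_empty_is_undefined(self):
        z = make_mask(np.zeros((3, 3, 3)))
        assert math.isnan(dice(z, z))

    def test_grid_mismatch(self, block_mask):
        other = make_mask(np.zeros(block_mask.shape), spacing=(2, 2, 2))
        with pytest.raises(GridMismatchError):
            dice(block_mask, other)

    def test_symmetry_and_matches_oracle(self, default_mask):
        cfg = AugmentationConfig(scenario="in_plane", n_contours=1, seed=3)
        p = augment(default_mask, cfg).perturbed[0]
        d = dice(default_mask, p)
        assert d == dice(p, default_mask)
        assert d == pytest.approx(dice_oracle(default_mask.data, p.data))


class TestSampleInplane:
    def test_zero_bounds_give_identity(self):
        cfg = AugmentationConfig(dw_bound=0, dh_bound=0, alpha_bound=0)
        params = sample_inplane_params(cfg, np.arange(5), "random", np.random.default_rng(0))
        assert all(p.is_identity for p in params)

    def test_systematic_signs_shared_across_slices(self):
        cfg = AugmentationConfig(bias="systematic")
        for seed in range(20):
            params = sample_inplane_params(
                cfg, np.arange(12), "systematic", np.random.default_rng(seed)
            )
            assert len({np.sign(p.dw) for p in params if p.dw != 0}) <= 1
            assert len({np.sign(p.dh) for p in params if p.dh != 0}) <= 1
            assert len({np.sign(p.alpha) for p in params if p.alpha != 0}) <= 1

    def test_random_draws_follow_uniform_law(self):
        cfg = AugmentationConfig()
        params = sample_inplane_params(
            cfg, np.arange(10_000), "random", np.random.default_rng(1)
        )
        dw = np.array([p.dw for p in params])
        se = 2.7 / np.sqrt(3) / np.sqrt(len(dw))  # std of U(-2.7, 2.7) / sqrt(n)
        assert abs(dw.mean()) < 3 * se
        assert np.abs(dw).max() <= 2.7

    def test_random_bias_mixes_signs_per_slice(self):
        cfg = AugmentationConfig()
        params = sample_inplane_params(
            cfg, np.arange(50), "random", np.random.default_rng(2)
        )
        signs = {np.sign(p.dw) for p in params}
        assert signs == {-1.0, 1.0}

    def test_bounds_respected(self):
        cfg = AugmentationConfig(dw_bound=1.0, dh_bound=0.5, alpha_bound=2.0)
        for bias in ("random", "systematic"):
            params = sample_inplane_params(
                cfg, np.arange(200), bias, np.random.default_rng(3)
            )
            assert all(abs(p.dw) <= 1.0 and abs(p.dh) <= 0.5 and abs(p.alpha) <= 2.0
                       for p in params)


def disc_mask(diameter_mm=20.0, spacing=0.25, pad_mm=5.0):
    n = int((diameter_mm + 2 * pad_mm) / spacing)
    c = (n - 1) / 2 * spacing
    xx, yy = np.meshgrid(np.arange(n) * spacing - c, np.arange(n) * spacing - c,
                         indexing="ij")
    arr = ((xx**2 + yy**2) <= (diameter_mm / 2) ** 2).astype(np.uint8)
    return make_mask(arr[:, :, None], spacing=(spacing, spacing, 3.0))


class TestApplyInplane:
    def test_identity_params_identity_output(self, default_mask):
        params = [SliceParams(int(k)) for k in default_mask.foreground_slices()]
        out = apply_inplane(default_mask, params)
        np.testing.assert_array_equal(out.data, default_mask.data)

    def test_disc_area_scaling(self):
        # dw = dh = +2.7 on a 20 mm disc: area ratio ~ (22.7/20)^2 = 1.288
        m = disc_mask()
        out = apply_inplane(m, [SliceParams(0, dw=2.7, dh=2.7)])
        ratio = out.n_foreground / m.n_foreground
        assert ratio == pytest.approx((22.7 / 20.0) ** 2, rel=0.02)

    def test_pure_rotation_preserves_disc(self):
        m = disc_mask()
        # nearest-neighbour resampling costs ~1% dice on a rotation-invariant disc
        out = apply_inplane(m, [SliceParams(0, alpha=5.0)])
        assert dice(m, out) > 0.99

    def test_output_binary_and_same_grid(self, default_mask):
        cfg = AugmentationConfig()
        params = sample_inplane_params(
            cfg, default_mask.foreground_slices(), "random", np.random.default_rng(0)
        )
        out = apply_inplane(default_mask, params)
        assert out.same_grid(default_mask)
        assert set(np.unique(out.data)) <= {0, 1}

    def test_default_bounds_keep_dice_above_088(self, default_mask):
        cfg = AugmentationConfig(scenario="in_plane", n_contours=100, seed=0)
        result = augment(default_mask, cfg)
        dices = [dice(default_mask, p) for p in result.perturbed]
        assert min(dices) >= 0.88

    def test_negative_width_raises(self):
        arr = np.zeros((8, 8, 1), dtype=np.uint8)
        arr[4, 4, 0] = 1  # w = h = 1.25 mm at this spacing
        m = make_mask(arr, spacing=(1.25, 1.25, 3.0))
        with pytest.raises(ValueError, match="not positive"):
            apply_inplane(m, [SliceParams(0, dw=-2.7)])

    def test_missing_slice_params_raise(self, default_mask):
        with pytest.raises(ValueError, match="missing SliceParams"):
            apply_inplane(default_mask, [SliceParams(0)])


class TestOutplane:
    def test_shift_sampler_uniform_over_nine_pairs(self):
        cfg = AugmentationConfig()
        rng = np.random.default_rng(0)
        draws = [sample_outplane_shift(cfg, rng) for _ in range(9000)]
        counts = {}
        for d in draws:
            counts[d] = counts.get(d, 0) + 1
        assert len(counts) == 9
        se = np.sqrt(9000 * (1 / 9) * (8 / 9))
        for c in counts.values():
            assert abs(c - 1000) < 3 * se

    def test_zero_max_always_zero(self):
        cfg = AugmentationConfig(slice_shift_max=0)
        rng = np.random.default_rng(0)
        assert all(sample_outplane_shift(cfg, rng) == (0, 0) for _ in range(50))

    def test_identity(self, block_mask):
        out = apply_outplane(block_mask, 0, 0)
        np.testing.assert_array_equal(out.data, block_mask.data)

    def test_shrink_both_ends(self, block_mask):
        # block spans slices 3..8; shrinking both ends leaves 4..7
        out = apply_outplane(block_mask, -1, -1)
        assert out.foreground_slices().tolist() == [4, 5, 6, 7]

    def test_grow_superior_replicates_boundary(self, block_mask):
        out = apply_outplane(block_mask, +1, 0)
        assert out.foreground_slices().tolist() == list(range(3, 10))
        np.testing.assert_array_equal(out.data[:, :, 9], block_mask.data[:, :, 8])

    def test_grow_inferior_replicates_boundary(self, block_mask):
        out = apply_outplane(block_mask, 0, +1)
        assert out.foreground_slices().tolist() == list(range(2, 9))
        np.testing.assert_array_equal(out.data[:, :, 2], block_mask.data[:, :, 3])

    def test_grow_past_edge_raises(self):
        arr = np.zeros((4, 4, 5), dtype=np.uint8)
        arr[1:3, 1:3, 2:5] = 1  # touches the top slice
        with pytest.raises(ValueError, match="grid edge"):
            apply_outplane(make_mask(arr), +1, 0)

    def test_too_thin_mask_raises(self):
        arr = np.zeros((4, 4, 5), dtype=np.uint8)
        arr[1:3, 1:3, 2] = 1
        with pytest.raises(ValueError, match=">= 3 slices"):
            apply_outplane(make_mask(arr), -1, 0)


class TestAugment:
    def test_default_emits_15_contours(self, default_mask):
        result = augment(default_mask, AugmentationConfig())
        assert len(result.perturbed) == 15
        assert len(result.logs) == 15

    def test_zero_bounds_reproduce_ground_truth(self, default_mask):
        cfg = AugmentationConfig(dw_bound=0, dh_bound=0, alpha_bound=0,
                                 slice_shift_max=0)
        result = augment(default_mask, cfg)
        for p in result.perturbed:
            assert dice(default_mask, p) == 1.0

    def test_seed_determinism(self, default_mask):
        cfg = AugmentationConfig(seed=123)
        a = augment(default_mask, cfg)
        b = augment(default_mask, cfg)
        for pa, pb in zip(a.perturbed, b.perturbed):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_logs_cover_every_in_roi_slice(self, default_mask):
        cfg = AugmentationConfig(scenario="in_out_plane", seed=5)
        result = augment(default_mask, cfg)
        gt_slices = set(default_mask.foreground_slices().tolist())
        for log, pm in zip(result.logs, result.perturbed):
            logged = {p.slice_index for p in log.slice_params}
            # in-plane params are sampled on the extent AFTER the out-plane shift
            lo = min(gt_slices) - max(log.delta_inf, 0) + max(-log.delta_inf, 0)
            hi = max(gt_slices) + max(log.delta_sup, 0) - max(-log.delta_sup, 0)
            assert logged == set(range(lo, hi + 1))
            assert abs(log.delta_sup) <= 1 and abs(log.delta_inf) <= 1

    def test_grid_never_changes(self, default_mask):
        for scenario in ("in_plane", "out_plane", "in_out_plane"):
            cfg = AugmentationConfig(scenario=scenario, n_contours=2, seed=1)
            for p in augment(default_mask, cfg).perturbed:
                assert p.same_grid(default_mask)

    def test_systematic_volume_change_sign_consistent(self, default_mask):
        cfg = AugmentationConfig(scenario="in_plane", bias="systematic",
                                 n_contours=20, seed=8)
        result = augment(default_mask, cfg)
        for log, pm in zip(result.logs, result.perturbed):
            s_dw = np.sign(log.slice_params[0].dw)
            s_dh = np.sign(log.slice_params[0].dh)
            if s_dw == s_dh and s_dw != 0:
                dv = pm.n_foreground - default_mask.n_foreground
                assert np.sign(dv) == s_dw

    def test_save_log(self, tmp_path, default_mask):
        cfg = AugmentationConfig(n_contours=2, seed=4)
        result = augment(default_mask, cfg)
        result.save_log(tmp_path / "log.json")
        import json

        payload = json.loads((tmp_path / "log.json").read_text())
        assert payload["seed"] == 4
        assert len(payload["contours"]) == 2
        assert payload["contours"][0]["slices"]


def mean_dice_for_bounds(mask, bound_scale, seed=0, n=10):
    cfg = AugmentationConfig(
        dw_bound=2.7 * bound_scale,
        dh_bound=2.7 * bound_scale,
        alpha_bound=5.0 * bound_scale,
        scenario="in_plane",
        n_contours=n,
        seed=seed,
    )
    result = augment(mask, cfg)
    return float(np.mean([dice(mask, p) for p in result.perturbed]))


class TestDistributionProperties:
    def test_mean_dice_monotone_in_bounds(self, default_mask):
        means = [mean_dice_for_bounds(default_mask, s, n=15) for s in (0.0, 0.5, 1.0, 2.0)]
        assert means[0] == 1.0
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_scenario_ordering(self):
        per_scenario = {"in_plane": [], "out_plane": [], "in_out_plane": []}
        for s in range(8):
            spec = PhantomSpec(spacing=(1.25, 1.25, 3.0), surface_irregularity=0.1,
                               seed=100 + s)
            mask = generate_phantom_mask(spec)
            for scenario in per_scenario:
                bias = "systematic" if scenario == "in_out_plane" else "random"
                cfg = AugmentationConfig(scenario=scenario, bias=bias,
                                         n_contours=10, seed=200 + s)
                result = augment(mask, cfg)
                per_scenario[scenario] += [dice(mask, p) for p in result.perturbed]
        means = {k: np.mean(v) for k, v in per_scenario.items()}
        assert means["out_plane"] > means["in_plane"] > means["in_out_plane"]
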