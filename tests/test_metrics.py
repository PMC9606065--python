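"""Body-masked image-quality metrics against brute-force/reference oracles."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity

from petsynth.grid import VolumeGrid
from petsynth.metrics import (
    BodyMask,
    derive_body_mask,
    masked_mae_suv,
    masked_psnr,
    masked_ssim,
)
from petsynth.phantom import make_phantom, simulate_pet


def _random_case(rng, shape=(16, 16, 16)):
    pred = VolumeGrid(rng.uniform(0, 20, shape))
    ref = pred.with_values(rng.uniform(0, 20, shape))
    mask_arr = np.zeros(shape, dtype=np.int32)
    mask_arr[2:-2, 2:-2, 2:-2] = 1
    return pred, ref, BodyMask(pred.with_values(mask_arr, is_label=True))


class TestDeriveBodyMask:
    def test_recovers_phantom_body_within_boundary_band(self, small_truth):
        derived = derive_body_mask(small_truth.ct_hu)
        truth = small_truth.body_mask.values.astype(bool)
        got = derived.values
        # symmetric difference confined to a 1-voxel boundary band
        import scipy.ndimage as ndi

        band = ndi.binary_dilation(truth) & ~ndi.binary_erosion(truth)
        mismatch = got ^ truth
        assert mismatch[~band].sum() == 0
        assert derived.provenance == "from-ct-threshold"

    def test_all_air_ct_rejected(self):
        ct = VolumeGrid(np.full((8, 8, 8), -1000.0))
        with pytest.raises(ValueError, match="empty"):
            derive_body_mask(ct)

    def test_idempotent_on_binary_body(self):
        ct = np.full((10, 12, 12), -1000.0)
        ct[2:8, 3:9, 3:9] = 40.0
        vol = VolumeGrid(ct)
        mask = derive_body_mask(vol)
        np.testing.assert_array_equal(mask.values, ct > -500)


class TestMaskedMae:
    def test_exact_cases(self, rng):
        pred, ref, mask = _random_case(rng)
        assert masked_mae_suv(pred, pred, mask) == 0.0
        shifted = pred.with_values(pred.values + 0.5)
        assert masked_mae_suv(shifted, pred, mask) == pytest.approx(0.5)

    def test_against_voxel_loop_oracle(self, rng):
        pred = VolumeGrid(rng.uniform(0, 10, (5, 5, 5)))
        ref = pred.with_values(rng.uniform(0, 10, (5, 5, 5)))
        m = rng.integers(0, 2, (5, 5, 5)).astype(np.int32)
        m[0, 0, 0] = 1
        mask = BodyMask(pred.with_values(m, is_label=True))
        total, count = 0.0, 0
        for z in range(5):
            for y in range(5):
                for x in range(5):
                    if m[z, y, x]:
                        total += abs(float(pred.values[z, y, x]) - float(ref.values[z, y, x]))
                        count += 1
        assert masked_mae_suv(pred, ref, mask) == pytest.approx(total / count)

    def test_symmetric(self, rng):
        pred, ref, mask = _random_case(rng)
        assert masked_mae_suv(pred, ref, mask) == pytest.approx(masked_mae_suv(ref, pred, mask))


class TestMaskedPsnr:
    def test_closed_form_values(self, rng):
        pred, ref, mask = _random_case(rng)
        assert masked_psnr(pred, pred, mask) == float("inf")
        # MSE == data_range^2 -> 0 dB
        zero = pred.with_values(np.zeros_like(pred.values))
        fifty = pred.with_values(np.full_like(pred.values, 50.0))
        assert masked_psnr(zero, fifty, mask, data_range=50.0) == pytest.approx(0.0)

    def test_halving_mse_adds_3dB(self, rng):
        ref, _, mask = _random_case(rng)
        base = ref.with_values(ref.values + 1.0)
        closer = ref.with_values(ref.values + 1.0 / np.sqrt(2))
        delta = masked_psnr(closer, ref, mask) - masked_psnr(base, ref, mask)
        assert delta == pytest.approx(10 * np.log10(2), abs=1e-9)


class TestMaskedSsim:
    def test_identical_volumes_score_one(self, rng):
        pred, _, mask = _random_case(rng)
        assert masked_ssim(pred, pred, mask) == pytest.approx(1.0)

    def test_matches_reference_implementation(self, rng):
        # volumes that are zero outside the mask make the zero-fill a no-op,
        # and interior window centers keep every 7^3 window inside the
        # volume, so the reference SSIM map must agree exactly there
        shape = (16, 16, 16)
        a = np.zeros(shape)
        b = np.zeros(shape)
        a[3:13, 3:13, 3:13] = rng.uniform(0, 50, (10, 10, 10))
        b[3:13, 3:13, 3:13] = np.clip(
            a[3:13, 3:13, 3:13] + rng.normal(0, 5, (10, 10, 10)), 0, 50
        )
        mask_arr = np.zeros(shape, dtype=np.int32)
        mask_arr[3:13, 3:13, 3:13] = 1
        va, vb = VolumeGrid(a), VolumeGrid(b)
        mask = BodyMask(va.with_values(mask_arr, is_label=True))
        _, smap = structural_similarity(
            a, b, win_size=7, data_range=50.0, full=True
        )
        expected = smap[3:13, 3:13, 3:13].mean()
        assert masked_ssim(va, vb, mask) == pytest.approx(expected, abs=1e-6)

    def test_masked_semantics_against_windowed_loop_oracle(self, rng):
        # independent oracle of the documented semantics: zero-fill outside
        # the mask, symmetric edge padding, sample moments per 7^3 window,
        # average over in-mask centers
        shape = (10, 10, 10)
        a = rng.uniform(0, 50, shape)
        b = rng.uniform(0, 50, shape)
        m = rng.integers(0, 2, shape).astype(bool)
        m[4:6] = True
        az = np.where(m, a, 0.0)
        bz = np.where(m, b, 0.0)
        r = 3
        ap = np.pad(az, r, mode="symmetric")
        bp = np.pad(bz, r, mode="symmetric")
        c1, c2 = (0.01 * 50) ** 2, (0.03 * 50) ** 2
        vals = []
        for z, y, x in np.argwhere(m):
            wa = ap[z : z + 7, y : y + 7, x : x + 7].ravel()
            wb = bp[z : z + 7, y : y + 7, x : x + 7].ravel()
            mu_a, mu_b = wa.mean(), wb.mean()
            va_, vb_ = wa.var(ddof=1), wb.var(ddof=1)
            cov = ((wa - mu_a) * (wb - mu_b)).sum() / (wa.size - 1)
            vals.append(
                ((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                / ((mu_a**2 + mu_b**2 + c1) * (va_ + vb_ + c2))
            )
        va, vb = VolumeGrid(a), VolumeGrid(b)
        mask = BodyMask(va.with_values(m.astype(np.int32), is_label=True))
        assert masked_ssim(va, vb, mask) == pytest.approx(np.mean(vals), abs=1e-9)

    def test_per_slice_mode_and_window_validation(self, rng):
        pred, ref, mask = _random_case(rng)
        val = masked_ssim(pred, ref, mask, per_slice=True)
        assert -1.0 <= val <= 1.0
        with pytest.raises(ValueError, match="window"):
            masked_ssim(pred, ref, mask, window=99)

    def test_symmetric(self, rng):
        pred, ref, mask = _random_case(rng)
        assert masked_ssim(pred, ref, mask) == pytest.approx(
            masked_ssim(ref, pred, mask), abs=1e-12
        )


class TestSanityOrdering:
    def test_noisefree_activity_beats_raw_extreme(self, small_spec, small_pair):
        # the PSF-smoothed noise-free activity map must score better against
        # the full-time reference than the noisy ultra-short acquisition
        fulltime, extreme, truth = small_pair
        smooth = simulate_pet(truth, 1.0, small_spec, seed=0, noise=False)
        mask = BodyMask.from_truth(truth.body_mask)
        assert masked_mae_suv(smooth, fulltime, mask) < masked_mae_suv(extreme, fulltime, mask)
        assert masked_ssim(smooth, fulltime, mask) > masked_ssim(extreme, fulltime, mask)
        assert masked_psnr(smooth, fulltime, mask) > masked_psnr(extreme, fulltime, mask)
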