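"""Sarcomere texture scores: spectral identities, ordering, geometry."""

import numpy as np
import pytest
from skimage.transform import rotate

from cardiophen.errors import UndefinedScoreError
from cardiophen.synthetic import StriationSpec, make_striation_image
from cardiophen.texture import (
    TextureROI,
    fourier_score,
    gabor_score,
    haralick_correlation,
    sarcomere_length,
    sarcomere_width,
    score_roi,
    score_roi_batch,
)


def _pair(seed, **kwargs):
    """Matched organized / scrambled ROI pair from one seed."""
    base = dict(seed=seed, noise_sd=0.05, image_size=(64, 64))
    base.update(kwargs)
    organized, _ = make_striation_image(StriationSpec(**base))
    scrambled, _ = make_striation_image(StriationSpec(**base, disorganization=1.0))
    return TextureROI(organized), TextureROI(scrambled)


class TestFourierScore:
    def test_pure_grating_concentrates_all_power(self):
        x = np.arange(128)
        grating = 0.5 + 0.4 * np.sin(2 * np.pi * x / 16)[None, :] * np.ones((128, 1))
        assert fourier_score(TextureROI(grating)) > 0.999

    def test_white_noise_score_near_zero(self):
        scores = [
            fourier_score(TextureROI(np.random.default_rng(s).standard_normal((64, 64))))
            for s in range(10)
        ]
        assert np.mean(scores) < 0.05

    def test_organized_beats_scrambled_every_seed(self):
        for seed in range(20):
            org, scr = _pair(seed)
            assert fourier_score(org) > fourier_score(scr)

    def test_constant_image_rejected(self):
        with pytest.raises(UndefinedScoreError):
            fourier_score(TextureROI(np.ones((64, 64))))

    def test_rotation_90_invariance(self, organized_roi):
        image, _ = organized_roi
        a = fourier_score(TextureROI(image))
        b = fourier_score(TextureROI(np.rot90(image).copy()))
        assert a == pytest.approx(b, rel=1e-9)


class TestGaborScore:
    def test_dominant_orientation_tracks_grating(self):
        image, _ = make_striation_image(
            StriationSpec(orientation=30.0, image_size=(96, 96))
        )
        scores = score_roi(TextureROI(image))
        # within half the 22.5-degree orientation-bank step
        assert abs(scores.dominant_orientation - 30.0) <= 11.25

    def test_organized_beats_scrambled_every_seed(self):
        for seed in range(20):
            org, scr = _pair(seed)
            assert gabor_score(org) > gabor_score(scr)

    def test_affine_intensity_invariance(self, organized_roi):
        image, _ = organized_roi
        a = gabor_score(TextureROI(image))
        b = gabor_score(TextureROI(3.0 * image + 7.0))
        assert a == pytest.approx(b, rel=1e-9)

    def test_constant_image_rejected(self):
        with pytest.raises(UndefinedScoreError):
            gabor_score(TextureROI(np.zeros((64, 64))))


class TestHaralickCorrelation:
    def test_checkerboard_perfectly_anticorrelated_horizontally(self):
        cb = (np.indices((64, 64)).sum(axis=0) % 2).astype(float)
        assert haralick_correlation(TextureROI(cb), angles_deg=(0.0,)) == pytest.approx(-1.0)

    def test_iid_noise_uncorrelated(self):
        noise = np.random.default_rng(1).standard_normal((96, 96))
        assert abs(haralick_correlation(TextureROI(noise))) < 0.05

    def test_smooth_gradient_near_one(self):
        grad = np.tile(np.linspace(0.0, 1.0, 64), (64, 1))
        assert haralick_correlation(TextureROI(grad)) > 0.95

    def test_within_bounds_and_ordering(self):
        for seed in range(20):
            org, scr = _pair(seed)
            ho, hs = haralick_correlation(org), haralick_correlation(scr)
            assert -1.0 <= hs <= 1.0 and -1.0 <= ho <= 1.0
            assert ho > hs

    def test_rotation_90_invariance(self, organized_roi):
        image, _ = organized_roi
        a = haralick_correlation(TextureROI(image))
        b = haralick_correlation(TextureROI(np.rot90(image).copy()))
        assert a == pytest.approx(b, rel=1e-9)

    def test_affine_intensity_invariance(self, organized_roi):
        image, _ = organized_roi
        a = haralick_correlation(TextureROI(image))
        b = haralick_correlation(TextureROI(0.5 * image + 2.0))
        assert a == pytest.approx(b, rel=1e-12)


class TestSarcomereLength:
    def test_known_period_and_pixel_size(self):
        image, _ = make_striation_image(StriationSpec(period=10, seed=0))
        length = sarcomere_length(TextureROI(image, pixel_size=0.1))
        assert length == pytest.approx(1.0, abs=0.02)

    def test_downscaled_image_same_physical_length(self):
        image, _ = make_striation_image(
            StriationSpec(period=10, seed=0, image_size=(128, 128))
        )
        halved = image[:, ::2][::2, :]  # 2x downsample: period 5 px
        length = sarcomere_length(TextureROI(halved, pixel_size=0.2))
        assert length == pytest.approx(1.0, abs=0.05)

    def test_recovery_under_noise(self):
        # noise up to 20% of the 0.8 intensity contrast, 20 seeds
        for seed in range(20):
            noise_sd = 0.16 * seed / 19
            image, truth = make_striation_image(
                StriationSpec(seed=seed, noise_sd=noise_sd, image_size=(128, 128))
            )
            length = sarcomere_length(TextureROI(image, pixel_size=0.1))
            err_px = abs(length - truth["true_period_um"]) / 0.1
            assert err_px <= 0.5

    def test_scrambled_roi_flagged_absent(self, scrambled_roi):
        image, _ = scrambled_roi
        assert sarcomere_length(TextureROI(image)) is None


class TestSarcomereWidth:
    def test_segment_length_recovered(self):
        image, _ = make_striation_image(
            StriationSpec(seed=1, band_length=20, band_gap=10, image_size=(96, 96))
        )
        width = sarcomere_width(TextureROI(image, pixel_size=0.1))
        assert width == pytest.approx(2.0, abs=0.1)  # 20 px at 0.1 µm/px, ±1 px

    @pytest.mark.parametrize("angle", [45, 90])
    def test_rotation_leaves_width_unchanged(self, angle):
        image, _ = make_striation_image(
            StriationSpec(seed=1, band_length=20, band_gap=10, image_size=(96, 96))
        )
        w0 = sarcomere_width(TextureROI(image))
        rotated = rotate(image, angle, resize=True, mode="constant", cval=0.2)
        wr = sarcomere_width(TextureROI(rotated))
        assert wr == pytest.approx(w0, rel=0.05)

    def test_scrambled_roi_flagged_absent(self, scrambled_roi):
        image, _ = scrambled_roi
        assert sarcomere_width(TextureROI(image)) is None


class TestBatch:
    def _mixed_rois(self, n_pairs=20):
        rois = []
        for seed in range(n_pairs):
            org, scr = _pair(seed)
            org.organization_call, org.roi_id = "organized", f"o{seed}"
            scr.organization_call, scr.roi_id = "disorganized", f"d{seed}"
            rois += [org, scr]
        return rois

    def test_group_means_lower_for_disorganized(self):
        table = score_roi_batch(self._mixed_rois())
        means = table.groupby("organization_call")[
            ["fourier_score", "gabor_score", "haralick_correlation"]
        ].mean()
        assert (means.loc["disorganized"] < means.loc["organized"]).all()

    def test_batch_of_one_matches_single_call(self, organized_roi):
        image, _ = organized_roi
        roi = TextureROI(image, roi_id="r0")
        table = score_roi_batch([roi])
        single = score_roi(roi)
        assert len(table) == 1
        assert table.loc[0, "fourier_score"] == pytest.approx(single.fourier_score)
        assert table.loc[0, "haralick_correlation"] == pytest.approx(
            single.haralick_correlation
        )

    def test_order_independence(self):
        rois = self._mixed_rois(5)
        a = score_roi_batch(rois).sort_values("roi_id").reset_index(drop=True)
        b = score_roi_batch(rois[::-1]).sort_values("roi_id").reset_index(drop=True)
        assert a.equals(b)

    def test_per_roi_failure_becomes_flagged_row(self, organized_roi):
        image, _ = organized_roi
        rois = [TextureROI(image, roi_id="good"),
                TextureROI(np.full((64, 64), 0.5), roi_id="flat")]
        table = score_roi_batch(rois).set_index("roi_id")
        assert table.loc["good", "error"] == ""
        assert table.loc["flat", "error"] != ""
        assert np.isnan(table.loc["flat", "fourier_score"])
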