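"""Phantom simulator: presets, rendering, datasets, beating clips."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from cardiogan.phantom import (CLASSES, PhantomParams, contraction_profile,
                               make_class_presets, make_clip_dataset,
                               make_image_dataset, render_beating_clip,
                               render_cell_field, shift_params)


class TestPresets:
    def test_morphology_increases_with_maturation_at_any_difficulty(self):
        for d in (0.0, 0.3, 0.7, 1.0):
            p = make_class_presets(d)
            for attr in ("cell_density", "area_mean", "elongation_mean"):
                v = [getattr(p[c], attr) for c in CLASSES]
                assert v[0] < v[1] < v[2], (d, attr, v)

    def test_difficulty_zero_keeps_day2_day6_areas_disjoint(self):
        p = make_class_presets(0.0)
        assert p["day2"].cell_area_range[1] < p["day6"].cell_area_range[0]

    def test_difficulty_one_overlaps_most_of_the_day2_area_interval(self):
        p = make_class_presets(1.0)
        lo2, hi2 = p["day2"].cell_area_range
        lo6, hi6 = p["day6"].cell_area_range
        overlap = min(hi2, hi6) - max(lo2, lo6)
        assert overlap >= 0.5 * (hi2 - lo2)

    def test_out_of_range_difficulty_rejected(self):
        with pytest.raises(ValueError):
            make_class_presets(1.5)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PhantomParams(cell_density=5, cell_area_range=(100, 50),
                          elongation_range=(1, 2), alignment_kappa=1,
                          intensity_fg=0.5, intensity_bg=0.1, noise_sd=0.02,
                          texture_scale=5)
        with pytest.raises(ValueError):
            PhantomParams(cell_density=5, cell_area_range=(50, 100),
                          elongation_range=(0.5, 2), alignment_kappa=1,
                          intensity_fg=0.5, intensity_bg=0.1, noise_sd=0.02,
                          texture_scale=5)

    def test_unseen_shift_moves_means_one_direction(self, day6_params):
        s = shift_params(day6_params, 1.0)
        assert s.cell_density > day6_params.cell_density
        assert s.area_mean > day6_params.area_mean
        assert s.elongation_mean > day6_params.elongation_mean
        assert shift_params(day6_params, 0.0) == day6_params


class TestRendering:
    def test_same_seed_is_bitwise_identical(self, day6_params):
        a = render_cell_field(day6_params, seed=11, label="day6")
        b = render_cell_field(day6_params, seed=11, label="day6")
        assert np.array_equal(a.pixels, b.pixels)

    def test_no_cells_no_noise_gives_flat_background(self, noiseless_day6):
        p = dataclasses.replace(noiseless_day6, cell_density=0.0)
        img = render_cell_field(p, seed=3)
        # channel-constant up to the 8-bit quantization grid and tint
        for ch in range(3):
            assert np.unique(img.pixels[ch]).size == 1

    def test_rendered_area_matches_independent_rasterization(self,
                                                             noiseless_day6):
        # 20 explicitly placed, non-overlapping equal-area cells: the
        # thresholded foreground must match skimage's ellipse rasterization
        from skimage.draw import ellipse
        area = 900.0
        cells = [(45 + 52 * (i // 5), 45 + 52 * (i % 5), area, 1.0, 0.0)
                 for i in range(20)]
        img = render_cell_field(noiseless_day6, seed=3, cells=cells)
        gray = img.pixels.mean(axis=0)
        counted = int((gray > noiseless_day6.intensity_bg + 0.05).sum())
        oracle = 0
        for (cy, cx, a, e, th) in cells:
            rr, _ = ellipse(cy, cx, np.sqrt(a / np.pi), np.sqrt(a / np.pi),
                            shape=(300, 300))
            oracle += len(rr)
        assert abs(counted - 20 * area) <= 0.10 * 20 * area
        assert abs(counted - oracle) <= 0.10 * oracle

    def test_rejects_tiny_fields(self, day6_params):
        with pytest.raises(ValueError):
            render_cell_field(day6_params, size=(32, 32), seed=0)

    def test_foreground_fraction_monotone_in_density(self, noiseless_day6):
        fracs = []
        for density in (4.0, 12.0, 30.0):
            p = dataclasses.replace(noiseless_day6, cell_density=density)
            vals = [
                (render_cell_field(p, seed=s).pixels.mean(axis=0)
                 > p.intensity_bg + 0.05).mean()
                for s in range(10)]
            fracs.append(np.mean(vals))
        assert fracs[0] < fracs[1] < fracs[2]

    def test_area_threshold_separates_day2_day14_at_difficulty_zero(self):
        presets = make_class_presets(0.0)
        fractions, labels = [], []
        for c in ("day2", "day14"):
            for s in range(100):
                img = render_cell_field(presets[c], seed=s, label=c)
                g = img.pixels.mean(axis=0)
                fractions.append((g > presets[c].intensity_bg + 0.05).mean())
                labels.append(c)
        fractions = np.array(fractions)
        labels = np.array(labels)
        cut = np.median(fractions)
        pred = np.where(fractions > cut, "day14", "day2")
        assert (pred == labels).mean() >= 0.90


class TestDatasets:
    def test_balanced_counts_per_class_and_domain(self, presets):
        ds = make_image_dataset(presets, 10, unseen_shift=0.5, seed=0,
                                size=(64, 64))
        assert len(ds.images) == 60
        for domain in ("seen", "unseen"):
            for c in CLASSES:
                assert len(ds.subset(domain, c)) == 10
                assert ds.per_class_counts[domain][c] == 10

    def test_study_sized_seen_domain_counts(self, presets):
        # the acquisition campaign sizes: 229 + 227 + 235 = 691 seen images
        counts = {"day2": 229, "day6": 227, "day14": 235}
        ds = make_image_dataset(presets, counts, unseen_shift=0.0, seed=0,
                                size=(64, 64))
        seen = ds.subset("seen")
        assert len(seen) == 691

    def test_zero_shift_keeps_seen_unseen_distributions_equal(self, presets):
        ds = make_image_dataset(presets, 34, unseen_shift=0.0, seed=1,
                                size=(64, 64))
        seen = [im.pixels.mean() for im in ds.subset("seen")]
        unseen = [im.pixels.mean() for im in ds.subset("unseen")]
        assert len(seen) == len(unseen) == 102   # ~100 per side
        assert stats.ks_2samp(seen, unseen).pvalue > 0.01

    def test_empty_presets_rejected(self):
        with pytest.raises(ValueError):
            make_image_dataset({}, 5)

    def test_same_seed_reproduces_dataset_bitwise(self, presets):
        a = make_image_dataset(presets, 3, unseen_shift=1.0, seed=9,
                               size=(64, 64))
        b = make_image_dataset(presets, 3, unseen_shift=1.0, seed=9,
                               size=(64, 64))
        for x, y in zip(a.images, b.images):
            assert x.label == y.label and x.domain == y.domain
            assert np.array_equal(x.pixels, y.pixels)


class TestClips:
    def test_contraction_profile_peaks_at_middle_frame(self):
        prof = contraction_profile(4.0)
        assert np.allclose(prof, [0, 2, 4, 2, 0])

    def test_clip_contract_five_square_frames(self, day6_params):
        clip = render_beating_clip(day6_params, amplitude=3.0, seed=2)
        assert clip.frames.shape == (5, 64, 64)
        assert clip.fps == 5.0
        assert 0.0 <= clip.frames.min() and clip.frames.max() <= 1.0

    def test_zero_amplitude_no_noise_freezes_the_clip(self, noiseless_day6):
        clip = render_beating_clip(noiseless_day6, amplitude=0.0, seed=2)
        for t in range(1, 5):
            assert np.array_equal(clip.frames[0], clip.frames[t])

    def test_centroid_stays_fixed_during_contraction(self, noiseless_day6):
        clip = render_beating_clip(noiseless_day6, amplitude=4.0, seed=2)
        cents = []
        for frame in clip.frames:
            mask = frame > noiseless_day6.intensity_bg + 0.05
            ys, xs = np.nonzero(mask)
            cents.append((ys.mean(), xs.mean()))
        cents = np.array(cents)
        assert np.abs(cents - cents[0]).max() < 0.5

    def test_negative_amplitude_rejected(self, day6_params):
        with pytest.raises(ValueError):
            render_beating_clip(day6_params, amplitude=-1.0)

    def test_clip_dataset_counts_and_determinism(self, day6_params):
        clips = make_clip_dataset(day6_params, 124, seed=3, frame_size=64)
        assert len(clips) == 124
        assert all(c.frames.shape == (5, 64, 64) for c in clips)
        again = make_clip_dataset(day6_params, 1, seed=5)
        once = make_clip_dataset(day6_params, 1, seed=5)
        assert np.array_equal(again[0].frames, once[0].frames)
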