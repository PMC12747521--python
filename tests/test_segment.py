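"""Flat-field, background subtraction, nuclear segmentation, and ring
geometry."""

import numpy as np
import pytest

from ktrcycle import simulate
from ktrcycle.io import ImageStack
from ktrcycle.segment import (SegmentationError, build_rings, flatfield_correct,
                              histogram_curvature_threshold, segment_fixed,
                              segment_live, subtract_background)


def _stack_from(frame, ps=1.0):
    return ImageStack(pixels=frame[None, None].astype(np.float32),
                      pixel_size_um=ps, frame_interval_min=12,
                      channel_roles={"h2b": 0})


class TestFlatfield:
    def test_known_bias_exactly_inverted(self):
        rng = np.random.default_rng(0)
        flat = np.full((64, 64), 500.0)
        yy, xx = np.mgrid[0:64, 0:64] / 63.0
        bias = 1.0 + 0.3 * (xx - 0.5) + 0.2 * (yy - 0.5) ** 2
        bias /= bias.mean()
        observed = flat * bias
        out = flatfield_correct(_stack_from(observed), bias)
        np.testing.assert_allclose(out.pixels[0, 0], flat, rtol=1e-5)

    def test_unit_reference_is_identity(self):
        frame = np.random.default_rng(1).uniform(50, 500, (32, 32))
        out = flatfield_correct(_stack_from(frame), np.ones((32, 32)))
        np.testing.assert_allclose(out.pixels[0, 0], frame, rtol=1e-6)

    def test_nonpositive_reference_rejected(self):
        frame = np.ones((16, 16))
        ref = np.ones((16, 16))
        ref[0, 0] = 0.0
        with pytest.raises(ValueError):
            flatfield_correct(_stack_from(frame), ref)

    def test_estimated_correction_reduces_background_cv(self):
        """On a simulated movie with 30% bias, data-driven flat-fielding
        lowers the coefficient of variation of true-background pixels."""
        cfg = simulate.SimConfig(n_cells=6, duration_hours=6.0,
                                 illumination_bias_amplitude=0.3,
                                 field_size_um=250, rng_seed=21)
        traces, truth = simulate.simulate_traces(cfg)
        stack = simulate.render_movie(traces, truth, cfg)
        corrected = flatfield_correct(stack)
        lm = segment_live(corrected.pixels[5, 0], cfg.pixel_size_um)
        bg = lm.labels == 0
        cv_pre = stack.pixels[5, 0][bg].std() / stack.pixels[5, 0][bg].mean()
        cv_post = corrected.pixels[5, 0][bg].std() / corrected.pixels[5, 0][bg].mean()
        assert cv_post < cv_pre


class TestBackground:
    def test_constant_background_zeroed(self):
        frame = np.full((40, 40), 120.0)
        mask = np.zeros((40, 40), dtype=int)
        mask[10:20, 10:20] = 1
        frame[mask == 1] = 900.0
        out = subtract_background(frame, mask)
        assert np.all(out[mask == 0] == 0.0)

    def test_median_of_nonnuclear_is_zero_for_random_frame(self):
        rng = np.random.default_rng(7)
        frame = rng.normal(100, 15, (50, 50))
        mask = np.zeros((50, 50), dtype=int)
        mask[5:15, 5:15] = 1
        out = subtract_background(frame, mask)
        # independent oracle: recompute the percentile on the output
        assert np.percentile(out[mask == 0], 50) == pytest.approx(0.0, abs=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        frame = rng.uniform(80, 140, (30, 30))
        mask = np.zeros((30, 30), dtype=int)
        once = subtract_background(frame, mask)
        twice = subtract_background(once, mask)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_mask_covering_frame_rejected(self):
        frame = np.ones((20, 20))
        with pytest.raises(SegmentationError):
            subtract_background(frame, np.ones((20, 20), dtype=int))


class TestSegmentLive:
    def test_two_separated_nuclei(self):
        cfg = simulate.SimConfig(n_cells=2, duration_hours=0.4, noise_sd=5.0,
                                 field_size_um=150, rng_seed=2)
        _, truth = simulate.simulate_traces(cfg)
        frame = simulate.render_frame(truth, cfg, 0)
        lm = segment_live(frame[0], cfg.pixel_size_um)
        assert lm.n_labels == 2
        from scipy import ndimage as ndi
        cents = ndi.center_of_mass(np.ones_like(lm.labels), lm.labels, [1, 2])
        tf = truth.frames[truth.frames.frame == 0]
        for cy, cx in cents:
            d = np.hypot(tf.x_um - cx, tf.y_um - cy).min()
            assert d < 2.0

    def test_blank_frame_empty_labelmap(self):
        rng = np.random.default_rng(3)
        frame = rng.normal(100, 10, (128, 128))
        lm = segment_live(frame, 1.0)
        assert lm.n_labels == 0

    def test_touching_nuclei_split(self):
        """Two nuclei rendered one diameter apart produce two labels, and the
        watershed line assigns pixels by majority to the right owners."""
        frame = np.full((80, 80), 100.0)
        yy, xx = np.mgrid[0:80, 0:80]
        c1, c2 = (40, 34), (40, 46)
        for (cy, cx) in (c1, c2):
            d = np.hypot(xx - cx, yy - cy)
            frame += 500.0 / (1 + np.exp((d - 6.0) / 0.3))
        lm = segment_live(frame, 1.0)
        assert lm.n_labels == 2
        l1 = lm.labels[c1[0], c1[1]]
        l2 = lm.labels[c2[0], c2[1]]
        assert l1 != l2 and l1 > 0 and l2 > 0
        # majority ownership: pixels nearer c1 mostly labelled l1
        d1 = np.hypot(xx - c1[1], yy - c1[0])
        d2 = np.hypot(xx - c2[1], yy - c2[0])
        near1 = (d1 < 5)
        assert (lm.labels[near1] == l1).mean() > 0.9

    def test_translation_equivariance(self):
        cfg = simulate.SimConfig(n_cells=3, duration_hours=0.4, noise_sd=0.0,
                                 field_size_um=200, rng_seed=4)
        _, truth = simulate.simulate_traces(cfg)
        frame = simulate.render_frame(truth, cfg, 0)[0]
        shifted = np.roll(np.roll(frame, 7, axis=0), -5, axis=1)
        lm = segment_live(frame, 1.0)
        lm_s = segment_live(shifted, 1.0)
        rolled = np.roll(np.roll(lm.labels, 7, axis=0), -5, axis=1)
        # same foreground footprint after shifting back
        assert lm_s.n_labels == lm.n_labels
        agree = ((rolled > 0) == (lm_s.labels > 0)).mean()
        assert agree > 0.999


class TestSegmentFixed:
    def test_bimodal_threshold_between_modes(self):
        """Synthetic bimodal histogram: background N(100,5) vs nuclei
        N(1000,50).  The curvature threshold must land strictly between the
        modes and recover nuclei pixels at >= 99% IoU."""
        rng = np.random.default_rng(5)
        frame = rng.normal(100, 5, (200, 200))
        mask = np.zeros((200, 200), dtype=bool)
        yy, xx = np.mgrid[0:200, 0:200]
        for cy, cx in [(50, 50), (50, 150), (150, 50), (150, 150), (100, 100)]:
            mask |= np.hypot(xx - cx, yy - cy) < 9
        frame[mask] = rng.normal(1000, 50, mask.sum())
        thr, fallback = histogram_curvature_threshold(frame)
        assert not fallback
        assert 115 < thr < 850
        seg = frame > thr
        iou = (seg & mask).sum() / (seg | mask).sum()
        assert iou >= 0.99

    def test_all_background_zero_labels(self):
        import warnings as _w

        rng = np.random.default_rng(6)
        frame = rng.normal(100, 5, (150, 150))
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # fallback warning allowed, not required
            lm = segment_fixed(frame, 1.0)
        assert lm.n_labels == 0

    def test_rendered_field_count(self):
        stack, truth = simulate.render_fixed_field(
            n_cells=50, puncta_per_cell=0, prb_positive_fraction=0.5,
            edu_positive_fraction=0.5, seed=8, spacing_um=45.0)
        lm = segment_fixed(stack.pixels[0, 0], stack.pixel_size_um)
        assert lm.n_labels == 50


class TestRings:
    def _disc_labels(self, shape, centers, radius):
        lab = np.zeros(shape, dtype=np.int32)
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        for i, (cy, cx) in enumerate(centers, start=1):
            lab[np.hypot(xx - cx, yy - cy) <= radius] = i
        return lab

    def test_annulus_area_matches_geometry(self):
        lab = self._disc_labels((64, 64), [(32, 32)], 10)
        rings = build_rings(lab, pixel_size_um=1.0)
        area = rings.pixels[1].size
        # annulus between r+0.65 and r+3.25 around a radius-10 disc
        # distances are pixel-centre EDT values, so the digitized annulus
        # runs up to ~half a pixel wide of the analytic one
        expect = np.pi * ((10 + 3.25) ** 2 - (10 + 0.65) ** 2)
        assert area == pytest.approx(expect, rel=0.2)
        assert not rings.flags.ring_overlap.iloc[0]

    def test_close_nuclei_both_flagged(self):
        # centres 4 um apart force intersecting annuli
        lab = self._disc_labels((64, 64), [(32, 28), (32, 42)], 6)
        rings = build_rings(lab, pixel_size_um=1.0)
        assert rings.flags.ring_overlap.all()

    def test_rings_exclude_all_nuclear_pixels(self, small_movie):
        from ktrcycle.segment import segment_live

        cfg, traces, truth = small_movie
        frame = simulate.render_frame(truth, cfg, cfg.n_frames - 1)
        lm = segment_live(frame[0], cfg.pixel_size_um)
        rings = build_rings(lm, cfg.pixel_size_um)
        flat = lm.labels.ravel()
        for lab, px in rings.pixels.items():
            assert np.all(flat[px] == 0)

    def test_overlap_flags_match_bruteforce(self):
        """Flagged set equals an O(n^2) pairwise annulus-intersection test."""
        rng = np.random.default_rng(9)
        centers = [(rng.uniform(15, 112), rng.uniform(15, 112)) for _ in range(14)]
        lab = self._disc_labels((128, 128), centers, 6)
        # some discs may merge; use the actual label map
        ids = np.unique(lab)
        ids = ids[ids != 0]
        rings = build_rings(lab, pixel_size_um=1.0)
        from scipy import ndimage as ndi
        brute = {}
        annuli = {}
        for i in ids:
            dist = ndi.distance_transform_edt(lab != i)
            annuli[i] = (dist > 0.65) & (dist <= 3.25)
        for i in ids:
            brute[i] = any((annuli[i] & annuli[j]).any()
                           for j in ids if j != i)
        got = rings.flags.set_index("label").ring_overlap.to_dict()
        assert got == {int(k): bool(v) for k, v in brute.items()}

    def test_invalid_ring_bounds(self):
        lab = self._disc_labels((32, 32), [(16, 16)], 6)
        with pytest.raises(ValueError):
            build_rings(lab, 1.0, inner_um=3.0, outer_um=1.0)
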