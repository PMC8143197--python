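"""Detection: local background, punctum rules, counts, soma aggregates."""

import numpy as np
import pytest

from tautrace import (
    SimulationConfig,
    count_series,
    detect_neurite_seeds,
    detect_soma_aggregate,
    local_background,
    neurite_area,
    render_seed_frame,
    simulate_experiment,
    subtract_baseline,
)
from tautrace.detect import SeedCountSeries, min_area_px, sum_series
from tautrace.simulate import _stamp


def brute_force_seeds(frame, background, pixel_size_um, threshold, band_um):
    """Naive per-pixel threshold + flood fill with the same acceptance rules.

    Independent of the library path: hand-rolled 8-connected flood fill,
    explicit large-object exclusion by Chebyshev-2 dilation.
    """
    fg = frame.astype(float) - background
    h, w = fg.shape
    above = fg > threshold
    seen = np.zeros_like(above)
    comps = []
    for y0 in range(h):
        for x0 in range(w):
            if above[y0, x0] and not seen[y0, x0]:
                stack, px = [(y0, x0)], []
                seen[y0, x0] = True
                while stack:
                    y, x = stack.pop()
                    px.append((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if (
                                0 <= yy < h and 0 <= xx < w
                                and above[yy, xx] and not seen[yy, xx]
                            ):
                                seen[yy, xx] = True
                                stack.append((yy, xx))
                comps.append(px)

    def diam_um(npx):
        return 2.0 * np.sqrt(npx / np.pi) * pixel_size_um

    big_px = set()
    for px in comps:
        if diam_um(len(px)) > band_um[1]:
            for (y, x) in px:
                for dy in range(-2, 3):
                    for dx in range(-2, 3):
                        if dx * dx + dy * dy <= 4:
                            big_px.add((y + dy, x + dx))
    a_min = min_area_px(band_um, pixel_size_um)
    out = []
    for px in comps:
        if diam_um(len(px)) > band_um[1] or len(px) < a_min:
            continue
        if any(p in big_px for p in px):
            continue
        ys, xs = zip(*px)
        out.append((float(np.mean(xs)), float(np.mean(ys)), len(px)))
    return sorted(out)


class TestLocalBackground:
    def test_constant_image_returns_constant(self):
        frame = np.full((64, 64), 777, np.uint16)
        assert np.allclose(local_background(frame, 5), 777)

    def test_median_ignores_single_bright_pixel(self):
        frame = np.full((64, 64), 500, np.uint16)
        frame[30, 30] = 60000
        bg = local_background(frame, 5)
        assert bg[30, 30] == pytest.approx(500)

    def test_recovers_sinusoidal_shading(self, rng):
        yy, xx = np.mgrid[0:128, 0:128]
        shading = 2000 + 800 * np.sin(xx / 40.0) + 500 * np.cos(yy / 50.0)
        noise_sigma = 300.0
        frame = (shading + rng.normal(0, noise_sigma, (128, 128))).astype(
            np.uint16
        )
        bg = local_background(frame, 6)
        assert np.abs(bg - shading).max() < noise_sigma

    def test_strided_estimate_close_to_dense(self, rng):
        frame = (1000 + rng.normal(0, 500, (128, 128))).clip(0, 65535).astype(
            np.uint16
        )
        dense = local_background(frame, 10, stride=1)
        coarse = local_background(frame, 10, stride=3)
        assert np.abs(dense - coarse).max() < 200

    def test_radius_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            local_background(np.zeros((20, 20), np.uint16), 15)


class TestDetectNeuriteSeeds:
    def test_blank_noisy_frame_has_no_detections(self, rng):
        frame = (1000 + rng.normal(0, 500, (128, 128))).clip(0, 65535).astype(
            np.uint16
        )
        assert detect_neurite_seeds(frame, 0.65) == []

    def test_dim_punctum_below_threshold_rejected(self):
        frame = np.full((128, 128), 1000, np.float32)
        _stamp(frame, 64, 64, 5000, 1.5)  # peak 5,000 < 10,000 threshold
        assert detect_neurite_seeds(frame.astype(np.uint16), 0.65) == []

    def test_large_bright_disc_excluded(self):
        frame = np.full((128, 128), 1000, np.float32)
        _stamp(frame, 64, 64, 22000, 7.0)  # footprint ~10 um
        assert detect_neurite_seeds(frame.astype(np.uint16), 0.65) == []

    def test_exact_recovery_of_rendered_puncta(self):
        frame, truth = render_seed_frame(25, n_somata=3, rng=5)
        dets = detect_neurite_seeds(frame, 0.65)
        assert len(dets) == 25
        puncta = truth[truth["kind"] == "punctum"]
        for d in dets:
            dist = np.hypot(
                puncta["x_px"] - d.centroid_px[0],
                puncta["y_px"] - d.centroid_px[1],
            )
            assert dist.min() < 2.0
            assert 0.1 <= d.equivalent_diameter_um <= 4.0
            assert d.peak_minus_background_gray > 10000

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_brute_force_oracle(self, seed):
        frame, _ = render_seed_frame(
            8, image_size_px=96, n_somata=1, rng=seed
        )
        bg = local_background(frame, 15, stride=1)
        dets = detect_neurite_seeds(frame, 0.65, background=bg)
        ours = sorted(
            (d.centroid_px[0], d.centroid_px[1], d.area_px) for d in dets
        )
        ref = brute_force_seeds(frame, bg, 0.65, 10000.0, (0.1, 4.0))
        assert len(ours) == len(ref)
        for a, b in zip(ours, ref):
            assert a[0] == pytest.approx(b[0]) and a[1] == pytest.approx(b[1])
            assert a[2] == b[2]

    def test_count_invariant_to_constant_offset(self):
        frame, _ = render_seed_frame(10, rng=3, background_gray=1000)
        shifted = (frame.astype(np.int64) + 4000).clip(0, 65535).astype(
            np.uint16
        )
        n0 = len(detect_neurite_seeds(frame, 0.65))
        n1 = len(detect_neurite_seeds(shifted, 0.65))
        assert n0 == n1

    def test_raising_threshold_never_increases_count(self):
        frame, _ = render_seed_frame(15, rng=4)
        counts = [
            len(detect_neurite_seeds(frame, 0.65, intensity_threshold_gray=t))
            for t in (8000, 10000, 12000, 14000)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_missing_calibration_rejected(self):
        with pytest.raises(ValueError):
            detect_neurite_seeds(np.zeros((32, 32), np.uint16), 0.0)

    def test_sub_pixel_band_minimum_maps_to_one_pixel(self):
        assert min_area_px((0.1, 4.0), 0.65) == 1


class TestCountSeries:
    def test_series_arithmetic_and_baseline(self):
        s = SeedCountSeries("A", [0.0, 2.0, 4.0], [5.0, 7.0, 9.0])
        ref = SeedCountSeries("B", [0.0, 2.0, 4.0], [2.0, 2.0, 2.0])
        out = subtract_baseline(s, ref)
        assert np.allclose(out.corrected_counts, [3.0, 5.0, 7.0])

    def test_series_minus_its_own_mean_centres_at_zero(self):
        s = SeedCountSeries("A", [0.0, 2.0, 4.0], [1.0, 2.0, 3.0])
        out = subtract_baseline(s, s)
        assert out.corrected_counts.mean() == pytest.approx(0.0)

    def test_grid_mismatch_rejected(self):
        a = SeedCountSeries("A", [0.0, 2.0], [1.0, 1.0])
        b = SeedCountSeries("B", [0.0, 3.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            subtract_baseline(a, b)

    def test_technical_replicates_sum_elementwise(self):
        a = SeedCountSeries("A", [0.0, 2.0], [1.0, 4.0])
        b = SeedCountSeries("B", [0.0, 2.0], [2.0, 5.0])
        assert np.allclose(sum_series(a, b).raw_counts, [3.0, 9.0])

    def test_no_lysate_well_counts_near_zero(self):
        cfg = SimulationConfig(
            n_wells=1, n_cells_per_well=10, image_size_px=160, frames=8,
            lysate_type="none", dose_ug=0.0, rng_seed=2,
        )
        stacks, _ = simulate_experiment(cfg)
        s = count_series(stacks[0])
        assert s.raw_counts.mean() < 1.0  # false-positive floor

    def test_counts_track_rendered_seed_accrual(self):
        cfg = SimulationConfig(
            n_wells=1, n_cells_per_well=12, image_size_px=192, frames=30,
            onset_base_hazard_per_h=0.05, death_base_hazard_per_h=0.0,
            exit_hazard_per_h=0.0, transient_prob=0.0, rng_seed=6,
        )
        stacks, truth = simulate_experiment(cfg)
        s = count_series(stacks[0])
        # counts should grow substantially as seeds accrue after onsets
        assert s.raw_counts[-5:].mean() > s.raw_counts[:5].mean() + 5


class TestSomaAggregate:
    def _patch_series(self, blob_frames, T=30, size=71, amp=15000.0, rng=None):
        rng = np.random.default_rng(rng)
        stack = np.zeros((T, size, size), np.float32) + 1000
        c = size // 2
        for f in blob_frames:
            _stamp(stack[f], c + 4, c, amp, 2.0)
        stack += rng.normal(0, 300, stack.shape)
        return stack.clip(0, 65535)

    def _masks(self, size=71):
        c = size // 2
        yy, xx = np.mgrid[0:size, 0:size]
        soma = (yy - c) ** 2 + (xx - c) ** 2 <= 7.5**2
        nuc = (yy - c) ** 2 + (xx - c) ** 2 <= 3.0**2
        return soma, nuc

    def test_diffuse_reporter_never_flags(self):
        soma, nuc = self._masks()
        stack = self._patch_series([], rng=0)
        flags, _ = detect_soma_aggregate(stack, soma, nuc)
        assert not flags.any()

    def test_blob_appearing_at_frame_20_flags_onward(self):
        soma, nuc = self._masks()
        stack = self._patch_series(range(20, 30), rng=1)
        flags, desc = detect_soma_aggregate(stack, soma, nuc)
        assert not flags[:20].any() and flags[20:].all()
        assert (desc.loc[flags, "largest_area_fraction"] == 1.0).all()

    def test_dissolved_aggregate_flags_exact_window(self):
        soma, nuc = self._masks()
        stack = self._patch_series(range(10, 21), rng=2)
        flags, _ = detect_soma_aggregate(stack, soma, nuc)
        assert not flags[:10].any()
        assert flags[10:21].all()
        assert not flags[21:].any()

    def test_empty_patch_rejected(self):
        with pytest.raises(ValueError):
            detect_soma_aggregate(np.empty((0, 5, 5)), np.ones((5, 5)), np.ones((5, 5)))


class TestNeuriteArea:
    def test_blank_frame_zero_area(self, rng):
        frame = (1000 + rng.normal(0, 50, (128, 128))).astype(np.uint16)
        m = neurite_area(frame, 0.65)
        assert m.neurite_area_um2 == 0.0

    def test_single_cell_area_close_to_rendered_mask(self):
        cfg = SimulationConfig(
            n_wells=1, n_cells_per_well=1, image_size_px=128, frames=2,
            lysate_type="none", dose_ug=0.0, noise_sigma_gray=50.0,
            death_base_hazard_per_h=0.0, exit_hazard_per_h=0.0, rng_seed=4,
        )
        stacks, _ = simulate_experiment(cfg)
        frame = stacks[0].pixels[0, 0]
        measured = neurite_area(frame, cfg.pixel_size_um,
                                neurite_threshold_gray=600.0)
        bg = np.median(frame)
        truth_mask = (frame.astype(float) - bg) > 600.0
        from tautrace.detect import local_background as lb
        from skimage import morphology as skmorph
        from scipy import ndimage
        soma = ndimage.binary_dilation(
            (frame.astype(float) - bg) > 3000.0, structure=skmorph.disk(2)
        )
        truth_area = (truth_mask & ~soma).sum() * cfg.pixel_size_um**2
        assert measured.neurite_area_um2 == pytest.approx(
            truth_area, rel=0.2
        )

    def test_two_cells_roughly_additive(self):
        one = SimulationConfig(
            n_wells=1, n_cells_per_well=1, image_size_px=160, frames=2,
            lysate_type="none", dose_ug=0.0, noise_sigma_gray=50.0,
            death_base_hazard_per_h=0.0, exit_hazard_per_h=0.0, rng_seed=9,
        )
        two = one.replace(n_cells_per_well=2)
        a1 = neurite_area(
            simulate_experiment(one)[0][0].pixels[0, 0], 0.65
        ).neurite_area_um2
        a2 = neurite_area(
            simulate_experiment(two)[0][0].pixels[0, 0], 0.65
        ).neurite_area_um2
        assert a2 == pytest.approx(2 * a1, rel=0.5)
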