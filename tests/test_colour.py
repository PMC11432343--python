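import numpy as np
import pytest

from beeforage.colour import (
    DEFAULT_BANDS,
    ColourBand,
    band_mask,
    build_heatmap,
    circular_colour_distance,
    compute_ofc,
    deviation_histogram,
    flower_cover,
    load_colour_config,
    save_colour_config,
)
from beeforage.detections import Detection, DetectionSet
from beeforage.errors import (
    EmptyRegionError,
    NoFlowerPixelsError,
    ParameterError,
    ScaleMismatchError,
)
from beeforage.geometry import Rect


def uniform_frame(colour, shape=(40, 40)):
    frame = np.empty((*shape, 3), dtype=np.uint8)
    frame[..., 0], frame[..., 1], frame[..., 2] = colour
    return frame


class TestColourBand:
    def test_printed_triplets_shipped(self):
        assert DEFAULT_BANDS["lotus"].lower == (11, 42, 120)
        assert DEFAULT_BANDS["lotus"].upper == (255, 160, 255)
        assert DEFAULT_BANDS["persicaria"].lower == (140, 255, 0)
        assert DEFAULT_BANDS["persicaria"].upper == (140, 40, 255)
        assert DEFAULT_BANDS["trifolium"].lower == (85, 255, 0)
        assert DEFAULT_BANDS["trifolium"].upper == (247, 186, 255)

    def test_lower_above_upper_auto_inverted(self):
        band = ColourBand((140, 255, 0), (140, 40, 255))
        assert band.inverted_channels == (1,)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            ColourBand((0, 0, 0), (256, 0, 0))


class TestBandMask:
    def test_inclusive_at_lower_bound(self, lotus_band):
        frame = uniform_frame(lotus_band.lower)
        assert band_mask(frame, lotus_band).all()

    def test_inclusive_at_upper_bound(self, lotus_band):
        frame = uniform_frame(lotus_band.upper)
        assert band_mask(frame, lotus_band).all()

    def test_one_channel_outside_fails(self, lotus_band):
        frame = uniform_frame((100, 30, 200))  # S below band
        assert not band_mask(frame, lotus_band).any()

    def test_inverted_channel_passes_both_lobes(self):
        band = DEFAULT_BANDS["persicaria"]
        assert band_mask(uniform_frame((140, 255, 100)), band).all()
        assert band_mask(uniform_frame((140, 20, 100)), band).all()
        assert not band_mask(uniform_frame((140, 120, 100)), band).any()

    def test_scale_mismatch_rejected(self, lotus_band):
        bad = np.full((4, 4, 3), 300.0)
        with pytest.raises(ScaleMismatchError):
            band_mask(bad, lotus_band)

    def test_against_per_pixel_brute_force(self, rng, band):
        frame = rng.integers(0, 256, size=(30, 30, 3)).astype(np.uint8)
        mask = band_mask(frame, band)
        inv = band.inverted_channels or ()
        for y in range(30):
            for x in range(30):
                ok = True
                for c in range(3):
                    v = frame[y, x, c]
                    lo, hi = band.lower[c], band.upper[c]
                    passes = (v >= lo or v <= hi) if c in inv else (lo <= v <= hi)
                    ok = ok and passes
                assert mask[y, x] == ok


class TestFlowerCover:
    def test_constructed_quarter_cover(self, lotus_band):
        frame = uniform_frame((100, 30, 200), shape=(40, 40))  # out of band
        frame[:20, :20] = (100, 100, 200)  # in band: exactly 25%
        rect = Rect(0, 0, 40, 40)
        assert flower_cover(frame, lotus_band, rect) == 0.25

    def test_all_background_zero(self, lotus_band):
        frame = uniform_frame((100, 30, 200))
        assert flower_cover(frame, lotus_band, Rect(0, 0, 40, 40)) == 0.0

    def test_all_in_band_is_one(self, lotus_band):
        frame = uniform_frame((100, 100, 200))
        assert flower_cover(frame, lotus_band, Rect(0, 0, 40, 40)) == 1.0

    def test_additive_over_disjoint_regions(self, lotus_band):
        frame = uniform_frame((100, 30, 200), shape=(40, 40))
        frame[:10, :10] = (100, 100, 200)
        frame[30:, 30:] = (100, 100, 200)
        rect = Rect(0, 0, 40, 40)
        total = flower_cover(frame, lotus_band, rect)
        assert total == pytest.approx((100 + 100) / 1600)

    def test_rect_outside_frame_rejected(self, lotus_band):
        frame = uniform_frame((100, 100, 200))
        with pytest.raises(ParameterError):
            flower_cover(frame, lotus_band, Rect(0, 0, 100, 100))


class TestComputeOFC:
    def test_single_colour(self, lotus_band):
        frames = [uniform_frame((100, 100, 200)) for _ in range(3)]
        assert compute_ofc(frames, lotus_band, seed=0) == (100.0, 100.0, 200.0)

    def test_two_colour_split_matches_brute_force(self, lotus_band):
        frame = uniform_frame((100, 100, 200), shape=(10, 10))
        frame[:, 5:] = (120, 80, 180)
        med = np.quantile(
            frame.reshape(-1, 3).astype(float), 0.5, axis=0, method="nearest"
        )
        assert compute_ofc([frame], lotus_band, seed=0) == tuple(med)

    def test_ofc_passes_own_band(self, rng, band):
        # random frames with a sprinkling of in-band pixels
        frames = []
        for _ in range(5):
            frame = rng.integers(0, 256, size=(20, 20, 3)).astype(np.uint8)
            frames.append(frame)
        try:
            ofc = compute_ofc(frames, band, seed=1)
        except NoFlowerPixelsError:
            pytest.skip("no in-band pixels drawn")
        pixel = np.array([[ofc]], dtype=np.uint8)
        assert band_mask(pixel, band).all()

    def test_frame_order_invariant(self, lotus_band):
        a = uniform_frame((100, 100, 200))
        b = uniform_frame((120, 80, 180))
        assert compute_ofc([a, b], lotus_band, n_frames=2, seed=0) == compute_ofc(
            [b, a], lotus_band, n_frames=2, seed=0
        )

    def test_no_flower_pixels_raises(self, lotus_band):
        frames = [uniform_frame((100, 30, 200))]
        with pytest.raises(NoFlowerPixelsError):
            compute_ofc(frames, lotus_band)


class TestCircularColourDistance:
    def test_identical_colours(self):
        assert circular_colour_distance((10, 20, 30), (10, 20, 30)) == 0.0

    def test_hue_wraparound(self):
        assert circular_colour_distance((5, 50, 50), (251, 50, 50)) == pytest.approx(10.0)

    def test_symmetry_and_triangle(self, rng):
        for _ in range(200):
            a, b, c = (tuple(rng.uniform(0, 256, 3)) for _ in range(3))
            dab = circular_colour_distance(a, b)
            dba = circular_colour_distance(b, a)
            assert dab == pytest.approx(dba)
            assert dab <= circular_colour_distance(a, c) + circular_colour_distance(c, b) + 1e-9

    def test_hue_term_bounded_by_half_period(self, rng):
        for _ in range(200):
            h1, h2 = rng.uniform(0, 256, 2)
            d = circular_colour_distance((h1, 0, 0), (h2, 0, 0))
            assert d <= 128.0

    def test_vectorised_matches_scalar(self, rng):
        ofc = (100.0, 50.0, 60.0)
        arr = rng.integers(0, 256, size=(8, 8, 3)).astype(np.uint8)
        vec = circular_colour_distance(arr, ofc)
        for y in range(8):
            for x in range(8):
                assert vec[y, x] == pytest.approx(
                    circular_colour_distance(tuple(arr[y, x]), ofc)
                )


class TestBuildHeatmap:
    def test_constant_video_no_detections(self):
        colour = (100, 100, 200)
        frames = [uniform_frame(colour) for _ in range(4)]
        ofc = (90.0, 100.0, 200.0)
        hm = build_heatmap(frames, DetectionSet([]), ofc, n_frames=4, seed=0)
        assert np.allclose(hm.mean, 10.0)
        assert (hm.counts == 4).all()

    def test_pixel_always_under_box_is_undefined(self):
        frames = [uniform_frame((100, 100, 200), shape=(20, 20)) for _ in range(3)]
        dets = DetectionSet(
            [Detection(t, Rect(5, 5, 10, 10), 0.9) for t in range(3)]
        )
        hm = build_heatmap(frames, dets, (100.0, 100.0, 200.0), n_frames=3, seed=0)
        assert hm.counts[7, 7] == 0
        assert np.isnan(hm.mean[7, 7])
        assert hm.counts[0, 0] == 3

    def test_matches_brute_force_on_toy_video(self, rng):
        frames = [
            rng.integers(0, 256, size=(12, 12, 3)).astype(np.uint8) for _ in range(3)
        ]
        ofc = (64.0, 32.0, 128.0)
        dets = DetectionSet([Detection(1, Rect(2, 2, 6, 6), 0.9)])
        hm = build_heatmap(frames, dets, ofc, n_frames=3, seed=0)
        for y in range(12):
            for x in range(12):
                contrib = []
                for t in range(3):
                    under = t == 1 and 2 <= x < 6 and 2 <= y < 6
                    if not under:
                        contrib.append(
                            circular_colour_distance(tuple(frames[t][y, x]), ofc)
                        )
                assert hm.counts[y, x] == len(contrib)
                assert hm.mean[y, x] == pytest.approx(np.mean(contrib))

    def test_requesting_more_frames_uses_all(self):
        frames = [uniform_frame((100, 100, 200)) for _ in range(2)]
        hm = build_heatmap(frames, DetectionSet([]), (100.0, 100.0, 200.0),
                           n_frames=3000, seed=0)
        assert hm.sampled_frames == (0, 1)


class TestDeviationHistogram:
    @pytest.fixture
    def heatmap(self):
        frames = [uniform_frame((100, 100, 200), shape=(30, 30))]
        return build_heatmap(frames, DetectionSet([]), (90.0, 100.0, 200.0),
                             n_frames=1, seed=0)

    def test_small_region_returns_every_pixel(self, heatmap):
        sample = deviation_histogram(heatmap, "all", n_points=100_000, seed=0)
        assert sample.size == 900

    def test_sample_subset_of_values(self, heatmap):
        sample = deviation_histogram(heatmap, "all", n_points=10, seed=0)
        assert np.isin(sample, heatmap.values()).all()

    def test_full_sampling_mean_equals_region_mean(self, heatmap):
        sample = deviation_histogram(heatmap, "all", n_points=900, seed=0)
        assert sample.mean() == pytest.approx(np.nanmean(heatmap.mean))

    def test_mask_region(self, heatmap):
        mask = np.zeros((30, 30), dtype=bool)
        mask[:5, :5] = True
        sample = deviation_histogram(heatmap, mask, n_points=100, seed=0)
        assert sample.size == 25

    def test_empty_region_raises(self, heatmap):
        with pytest.raises(EmptyRegionError):
            deviation_histogram(heatmap, np.zeros((30, 30), dtype=bool))


class TestColourConfigIO:
    @pytest.mark.parametrize("suffix", [".yaml", ".json"])
    def test_round_trip(self, tmp_path, suffix):
        band = DEFAULT_BANDS["persicaria"]
        path = tmp_path / f"band{suffix}"
        save_colour_config(band, path)
        loaded = load_colour_config(path)
        assert loaded.lower == band.lower
        assert loaded.upper == band.upper
        assert loaded.inverted_channels == band.inverted_channels

    def test_multi_species_selection(self, tmp_path):
        path = tmp_path / "bands.yaml"
        path.write_text(
            "lotus:\n  lower: [11, 42, 120]\n  upper: [255, 160, 255]\n"
            "trifolium:\n  lower: [85, 255, 0]\n  upper: [247, 186, 255]\n"
        )
        band = load_colour_config(path, species="trifolium")
        assert band.species == "trifolium"
        assert band.lower == (85, 255, 0)

    def test_missing_species_rejected(self, tmp_path):
        path = tmp_path / "bands.yaml"
        path.write_text("lotus:\n  lower: [11, 42, 120]\n  upper: [255, 160, 255]\n")
        with pytest.raises(ParameterError):
            load_colour_config(path, species="persicaria")
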