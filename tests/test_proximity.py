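"""Trajectory randomization, distance sampling, and association summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mcsquant.segmentation import EmptyMaskError, Mask
from mcsquant.stats import DegenerateTestError
from mcsquant.proximity import (
    RandomizationConfig,
    association_analysis,
    compare_observed_vs_random,
    cumulative_distribution,
    distance_distribution,
    fraction_within,
    randomize_tracks,
    track_distances,
)
from mcsquant.tracking import Detection, Track, TrackSet
from tests.test_segmentation import brute_force_distances


def make_tracks(points_per_track, pixel_size=80.0, cell_id="c0"):
    tracks = []
    for i, pts in enumerate(points_per_track):
        dets = [Detection(f, tuple(p)) for f, p in enumerate(pts)]
        tracks.append(Track(i, dets, cell_id=cell_id))
    n_frames = max(len(p) for p in points_per_track)
    return TrackSet(tracks, pixel_size=pixel_size, n_frames=n_frames)


def full_mask(shape=(64, 64), pixel_size=80.0):
    return Mask(np.ones(shape, bool), pixel_size)


class TestTrackDistances:
    def test_inside_mask_is_zero(self):
        mask = full_mask((32, 32))
        ts = make_tracks([[(5.2, 7.8), (6.1, 8.0)]])
        df = track_distances(ts, mask)
        assert (df["distance_nm"] == 0).all()

    def test_static_track_three_px_away(self):
        pix = np.zeros((32, 32), bool)
        pix[10, 10] = True
        ts = make_tracks([[(10.0, 13.0)] * 4])
        df = track_distances(ts, Mask(pix, 80.0))
        assert np.allclose(df["distance_nm"], 240.0)

    def test_matches_brute_force_on_random_masks(self, rng):
        pix = rng.random((32, 32)) < 0.1
        pix[0, 0] = True
        mask = Mask(pix, 80.0)
        pts = rng.uniform(0, 31, size=(20, 2))
        ts = make_tracks([[p] for p in pts])
        df = track_distances(ts, mask).sort_values("track_id")
        assert np.allclose(df["distance_nm"].to_numpy(),
                           brute_force_distances(pts, mask), atol=1e-9)

    def test_empty_mask_rejected(self):
        ts = make_tracks([[(5.0, 5.0)]])
        with pytest.raises(EmptyMaskError):
            track_distances(ts, Mask(np.zeros((16, 16), bool), 80.0))

    def test_per_frame_masks_resolved(self):
        masks = []
        for f in range(3):
            pix = np.zeros((32, 32), bool)
            pix[10 + f, 10] = True
            masks.append(Mask(pix, 80.0, frame_index=f))
        ts = make_tracks([[(10.0, 10.0), (11.0, 10.0), (12.0, 10.0)]])
        df = track_distances(ts, masks)
        assert np.allclose(df["distance_nm"], 0.0)


class TestRandomize:
    def test_shape_preserved_translate_rotate(self, rng):
        pts = [rng.uniform(20, 40, size=(6, 2)) for _ in range(4)]
        ts = make_tracks([list(map(tuple, p)) for p in pts])
        cfg = RandomizationConfig(n_replicates=10, seed=5)
        for rep in randomize_tracks(ts, full_mask(), cfg):
            for orig, new in zip(ts.tracks, rep.tracks):
                a = np.sort(orig.displacement_magnitudes()) * ts.pixel_size
                b = np.sort(new.displacement_magnitudes()) * ts.pixel_size
                assert np.allclose(a, b, atol=1e-9, rtol=0)

    def test_translate_mode_preserves_vectors(self, rng):
        pts = rng.uniform(20, 40, size=(5, 2))
        ts = make_tracks([list(map(tuple, pts))])
        cfg = RandomizationConfig(n_replicates=5, mode="translate", seed=2)
        for rep in randomize_tracks(ts, full_mask(), cfg):
            assert np.allclose(rep.tracks[0].displacement_vectors(),
                               ts.tracks[0].displacement_vectors(),
                               atol=1e-9)

    def test_single_point_placements_uniform(self):
        """chi^2 occupancy over a 4x4 grid in a full-rectangle cytoplasm."""
        ts = make_tracks([[(10.0, 10.0)]])
        cfg = RandomizationConfig(n_replicates=2000, mode="translate", seed=7)
        reps = randomize_tracks(ts, full_mask((64, 64)), cfg)
        pos = np.array([r.tracks[0].points[0] for r in reps])
        cells = (np.clip(np.rint(pos[:, 0]), 0, 63) // 16) * 4 \
            + np.clip(np.rint(pos[:, 1]), 0, 63) // 16
        counts = np.bincount(cells.astype(int), minlength=16)
        chi2 = ((counts - len(pos) / 16) ** 2 / (len(pos) / 16)).sum()
        assert chi2 < sps.chi2.ppf(0.99, 15)

    def test_points_stay_inside_cytoplasm(self, rng, small_cell):
        ts = small_cell.truth_tracks
        cyto = small_cell.cytoplasm_mask
        cfg = RandomizationConfig(n_replicates=5, seed=3)
        for rep in randomize_tracks(ts, cyto, cfg):
            pts = np.vstack([t.points for t in rep.tracks])
            rr = np.rint(pts[:, 0]).astype(int)
            cc = np.rint(pts[:, 1]).astype(int)
            assert cyto.pixels[rr, cc].all()

    def test_unplaceable_track_keeps_original_with_warning(self):
        # cytoplasm is a single pixel; a long track cannot fit
        pix = np.zeros((32, 32), bool)
        pix[5, 5] = True
        ts = make_tracks([[(10.0, 10.0), (10.0, 20.0)]])
        cfg = RandomizationConfig(n_replicates=1, max_attempts=10, seed=1)
        with pytest.warns(UserWarning, match="no valid placement"):
            reps = randomize_tracks(ts, Mask(pix, 80.0), cfg)
        assert np.allclose(reps[0].tracks[0].points, ts.tracks[0].points)

    def test_empty_cytoplasm_rejected(self):
        ts = make_tracks([[(1.0, 1.0)]])
        with pytest.raises(EmptyMaskError):
            randomize_tracks(ts, Mask(np.zeros((8, 8), bool), 80.0),
                             RandomizationConfig())

    def test_determinism(self):
        ts = make_tracks([[(10.0, 10.0), (11.0, 10.0)]])
        cfg = RandomizationConfig(n_replicates=3, seed=9)
        a = randomize_tracks(ts, full_mask(), cfg)
        b = randomize_tracks(ts, full_mask(), cfg)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.tracks[0].points, rb.tracks[0].points)


class TestDistributions:
    def test_all_zero_mass_in_first_bin(self):
        dist = distance_distribution(np.zeros(10), bin_width=50.0)
        assert dist.density[0] == pytest.approx(1 / 50.0)
        assert (dist.density[1:] == 0).all()

    def test_two_sample_hand_example(self):
        dist = distance_distribution([50.0, 150.0], bin_width=100.0)
        assert np.allclose(dist.density, [0.005, 0.005])

    def test_normalization_on_random_samples(self, rng):
        for _ in range(5):
            d = rng.exponential(120.0, size=rng.integers(1, 200))
            dist = distance_distribution(d, bin_width=25.0)
            widths = np.diff(dist.bin_edges)
            assert (dist.density >= 0).all()
            assert (dist.density * widths).sum() == pytest.approx(1.0,
                                                                  abs=1e-9)

    def test_nonpositive_bin_width_rejected(self):
        with pytest.raises(ValueError):
            distance_distribution([1.0], bin_width=0.0)

    def test_ecdf_hand_example(self):
        F = cumulative_distribution([50.0, 150.0, 250.0])
        assert F(100.0) == pytest.approx(1 / 3)
        assert F(250.0) == pytest.approx(1.0)

    def test_ecdf_matches_fraction_within(self, rng):
        d = rng.exponential(100.0, size=1000)
        F = cumulative_distribution(d)
        df = pd.DataFrame({"cell_id": "c0", "distance_nm": d})
        assert F(100.0) == pytest.approx(fraction_within(df, 100.0)["c0"])


class TestFractionWithin:
    def test_all_zero_distances(self):
        df = pd.DataFrame({"cell_id": ["a"] * 5, "distance_nm": 0.0})
        assert fraction_within(df, 100.0)["a"] == 1.0

    def test_inclusive_threshold(self):
        df = pd.DataFrame({"cell_id": "a",
                           "distance_nm": [50.0, 150.0, 250.0]})
        assert fraction_within(df, 100.0)["a"] == pytest.approx(1 / 3)
        assert fraction_within(df, 150.0)["a"] == pytest.approx(2 / 3)

    def test_monotone_in_threshold(self, rng):
        df = pd.DataFrame({
            "cell_id": rng.choice(["a", "b"], size=200),
            "distance_nm": rng.exponential(100.0, size=200)})
        prev = fraction_within(df, 0.0)
        for thr in [50.0, 100.0, 200.0, 400.0]:
            cur = fraction_within(df, thr)
            assert (cur >= prev - 1e-12).all()
            prev = cur


class TestCompare:
    def test_equal_fractions_degenerate(self):
        with pytest.raises(DegenerateTestError):
            compare_observed_vs_random([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])

    def test_hand_computed_summary(self):
        s = compare_observed_vs_random([0.7, 0.8, 0.6], [0.4, 0.5, 0.45])
        assert s.mean_observed == pytest.approx(0.7)
        assert s.paired_test.t_stat == pytest.approx(5.0)

    def test_mean_sem_recompute_exactly(self, rng):
        obs = rng.uniform(0.4, 0.9, size=13)
        rand = rng.uniform(0.2, 0.7, size=13)
        s = compare_observed_vs_random(obs, rand)
        assert s.mean_observed == pytest.approx(obs.mean(), abs=1e-15)
        assert s.sem_observed == pytest.approx(
            obs.std(ddof=1) / np.sqrt(13), abs=1e-15)
        assert s.n_cells == 13


class TestAssociationAnalysis:
    def test_null_mean_matches_area_fraction(self):
        """Single-point tracks: mean randomized fraction equals the measured
        occupancy probability of the 100 nm neighborhood (3 SE)."""
        pix = np.zeros((64, 64), bool)
        pix[28:36, 28:36] = True
        organelle = Mask(pix, 80.0)
        cyto = full_mask((64, 64))
        ts = make_tracks([[(5.0, 5.0)] for _ in range(10)])
        cfg = RandomizationConfig(n_replicates=300, mode="translate", seed=4)
        reps = randomize_tracks(ts, cyto, cfg)
        fracs = [(track_distances(r, organelle)["distance_nm"] <= 100).mean()
                 for r in reps]
        # independent oracle: direct uniform sampling of the placement law
        rng = np.random.default_rng(99)
        pts = rng.integers(0, 64, size=(100000, 2)) \
            + rng.uniform(-0.5, 0.5, (100000, 2))
        from mcsquant.segmentation import point_to_mask_distances
        f = (point_to_mask_distances(pts, organelle) <= 100).mean()
        n = len(fracs) * 10
        se = np.sqrt(f * (1 - f) / n) + np.sqrt(f * (1 - f) / 100000)
        assert abs(np.mean(fracs) - f) <= 3 * se

    def test_pipeline_summary_structure(self, small_cell):
        ts = small_cell.truth_tracks
        cells = [(ts, small_cell.er_masks, small_cell.cytoplasm_mask),
                 (ts, small_cell.er_masks, small_cell.cytoplasm_mask)]
        cfg = RandomizationConfig(n_replicates=5, seed=1)
        summary = association_analysis(cells, cfg, threshold=100.0)
        assert summary.n_cells == 2
        assert 0 <= summary.mean_randomized <= 1
        assert summary.mean_observed > summary.mean_randomized
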