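"""Track filtering, drift correction, masking, classification, lifetimes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from velinfer import (
    LocalizationErrorModel,
    RegionMasks,
    Track,
    classify_tracks,
    compute_displacements,
    filter_spot_fits,
    fit_lifetimes,
    read_tracks,
    subtract_drift,
    write_tracks,
)
from velinfer.noise import measured_distance_cdf
from velinfer.synthetic import generate_fixed_cell
from velinfer.tracks import build_masks, top_percent_mask


def _track(frames, x, y, **kw):
    return Track(track_id=kw.pop("track_id", 0), frames=np.asarray(frames),
                 x=np.asarray(x, float), y=np.asarray(y, float), **kw)


class TestSpotFilter:
    def test_acceptance_band_at_study_optics(self):
        # sigma0 = 0.25 * 675 / 1.49 = 113.3 nm; band [75.5, 169.9] nm
        sigma0 = 0.25 * 675.0 / 1.49
        assert sigma0 == pytest.approx(113.3, abs=0.05)
        sig = np.array([75.0, 75.6, 113.3, 169.8, 170.0])
        ok = filter_spot_fits(np.zeros(5), sig, wavelength_nm=675.0, na=1.49)
        np.testing.assert_array_equal(ok, [False, True, True, True, False])

    def test_center_shift_rule(self):
        ok = filter_spot_fits(np.array([2.0, 2.1]), np.array([113.3, 113.3]))
        np.testing.assert_array_equal(ok, [True, False])

    def test_invalid_optics_rejected(self):
        with pytest.raises(ValueError):
            filter_spot_fits([0.0], [100.0], wavelength_nm=0.0)


class TestDriftSubtraction:
    def test_zero_drift_is_identity(self):
        t = _track([0, 1, 2], [0, 100, 200], [0, 0, 0])
        drift = pd.DataFrame({"frame": [0, 1, 2], "dx_nm": 0.0, "dy_nm": 0.0})
        out = subtract_drift([t], drift)[0]
        np.testing.assert_array_equal(out.x, t.x)

    def test_linear_drift_on_stationary_track(self):
        frames = np.arange(5)
        v = 30.0
        t = _track(frames, frames * v, np.zeros(5))
        drift = pd.DataFrame({"frame": frames, "dx_nm": frames * v, "dy_nm": 0.0})
        out = subtract_drift([t], drift)[0]
        np.testing.assert_allclose(out.x, 0.0, atol=1e-12)

    def test_missing_frame_raises(self):
        t = _track([0, 1, 5], [0, 0, 0], [0, 0, 0])
        drift = pd.DataFrame({"frame": [0, 1], "dx_nm": 0.0, "dy_nm": 0.0})
        with pytest.raises(ValueError, match="missing frames"):
            subtract_drift([t], drift)


class TestMasks:
    def test_top_two_percent_on_ramp(self):
        ramp = np.arange(100.0).reshape(10, 10)
        assert top_percent_mask(ramp, 2.0).sum() == 2

    def test_otsu_isolates_bright_square(self, rng):
        img = rng.normal(10.0, 0.5, (64, 64))
        img[20:30, 20:30] += 50.0
        masks = build_masks(img, img, background_radius=10.0, smooth=False)
        # the adhesion mask contains the bright square and little else
        square = np.zeros_like(img, bool)
        square[20:30, 20:30] = True
        assert (masks.adhesion & square).sum() >= 95
        assert (masks.adhesion & ~square).sum() <= 10

    def test_cytosol_excludes_other_masks(self, rng):
        img = rng.normal(10.0, 0.5, (64, 64))
        img[10:20, 10:20] += 50.0
        masks = build_masks(img, rng.random((64, 64)), background_radius=10.0)
        assert not np.any(masks.cytosol & masks.adhesion)
        assert not np.any(masks.cytosol & masks.stress_fiber)
        assert np.all(masks.cytosol <= masks.cell)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            build_masks(np.ones((8, 8)), np.arange(64.0).reshape(8, 8))


class TestClassification:
    @pytest.fixture()
    def masks(self):
        cell = np.ones((20, 20), bool)
        sf = np.zeros((20, 20), bool)
        sf[:, 5:8] = True
        ad = np.zeros((20, 20), bool)
        ad[10:14, 6:12] = True
        return RegionMasks(cell=cell, adhesion=ad, stress_fiber=sf, pixel_size=64.0)

    def test_first_point_rule(self, masks):
        px = 64.0
        t = _track([0, 1], [6 * px, 15 * px], [12 * px, 15 * px])  # starts in SF∩adh
        out = classify_tracks([t], masks)[0]
        assert out.population == "sf_and_adhesion"

    def test_outside_grid_unclassified(self, masks):
        t = _track([0], [-500.0], [0.0])
        assert classify_tracks([t], masks)[0].population == "unclassified"

    def test_idempotent(self, masks):
        t = _track([0], [64.0], [64.0])
        once = classify_tracks([t], masks)
        twice = classify_tracks(once, masks)
        assert once[0].population == twice[0].population == "cortical"

    def test_labels_partition(self, masks, rng):
        px = 64.0
        tracks = [
            _track([0], [rng.uniform(0, 19 * px)], [rng.uniform(0, 19 * px)],
                   track_id=i)
            for i in range(200)
        ]
        labels = {t.population for t in classify_tracks(tracks, masks)}
        assert labels <= {"stress_fiber", "adhesion", "sf_and_adhesion", "cortical"}


class TestDisplacements:
    def test_known_lags(self):
        t = _track([0, 1, 2], [0.0, 100.0, 200.0], [0.0, 0.0, 0.0],
                   population="cortical", frame_interval=2.0)
        mld = compute_displacements([t], max_lag_frames=2)
        np.testing.assert_allclose(sorted(mld.get("cortical", 2.0)), [100.0, 100.0])
        np.testing.assert_allclose(mld.get("cortical", 4.0), [200.0])

    def test_gap_yields_no_spanning_pair(self):
        t = _track([0, 2], [0.0, 100.0], [0.0, 0.0], population="cortical")
        mld = compute_displacements([t], max_lag_frames=2)
        assert mld.get("cortical", 2.0).size == 0
        assert mld.get("cortical", 4.0).size == 1

    def test_short_track_contributes_nothing_at_long_lag(self):
        t = _track([0, 1], [0.0, 50.0], [0.0, 0.0], population="cortical")
        mld = compute_displacements([t], max_lag_frames=5)
        for m in range(2, 6):
            assert mld.get("cortical", 2.0 * m).size == 0

    def test_nonoverlapping_option(self):
        t = _track(np.arange(5), np.arange(5) * 10.0, np.zeros(5),
                   population="cortical")
        allp = compute_displacements([t], max_lag_frames=2, pairing="all")
        nov = compute_displacements([t], max_lag_frames=2, pairing="nonoverlapping")
        assert allp.get("cortical", 4.0).size == 3
        assert nov.get("cortical", 4.0).size == 2

    def test_fixed_cell_displacements_match_noise_model(self, noise_mixture):
        # closes the loop: stationary noisy tracks reproduce the calibrated
        # measured-distance distribution
        tracks = generate_fixed_cell(n_tracks=600, noise=noise_mixture, seed=42)
        mld = compute_displacements(tracks, max_lag_frames=1)
        d = mld.get("fixed", 2.0)
        assert d.size > 10_000
        ks = stats.kstest(d, lambda x: measured_distance_cdf(x, 0.0, noise_mixture))
        assert ks.statistic < 0.02


class TestLifetimes:
    def test_uncensored_recovery(self, rng):
        life = rng.exponential(18.0, size=10_000)
        fit = fit_lifetimes(life, min_detectable=0.0)
        se = 18.0 / np.sqrt(life.size)
        assert abs(fit.mean - 18.0) < 3 * se

    def test_degenerate_flagged(self):
        fit = fit_lifetimes(np.full(100, 6.0), min_detectable=0.0)
        assert fit.flagged

    def test_all_censored_flagged(self):
        fit = fit_lifetimes(np.full(100, 120.0), censored=np.ones(100, bool))
        assert fit.flagged and np.isnan(fit.mean)

    def test_censoring_inflates_over_naive_mean(self, rng):
        life = rng.exponential(30.0, size=5000)
        censored = life > 40.0
        observed = np.minimum(life, 40.0)
        fit = fit_lifetimes(observed, censored=censored, min_detectable=0.0)
        assert fit.mean >= observed.mean()


def test_track_roundtrip(tmp_path):
    tracks = [
        _track([0, 1, 3], [0.0, 10.0, 20.0], [5.0, 5.0, 5.0], track_id=3,
               population="cortical"),
        _track([2, 3], [1.0, 2.0], [3.0, 4.0], track_id=7),
    ]
    path = tmp_path / "tracks.csv"
    write_tracks(tracks, path)
    back = read_tracks(path)
    assert len(back) == 2
    np.testing.assert_allclose(back[0].x, tracks[0].x)
    assert back[0].population == "cortical"
    assert back[0].lifetime == pytest.approx(3 * 2.0)


def test_track_invariants():
    with pytest.raises(ValueError, match="strictly increasing"):
        _track([0, 0, 1], [0, 0, 0], [0, 0, 0])
    with pytest.raises(ValueError, match="finite"):
        _track([0, 1], [0, np.nan], [0, 0])
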