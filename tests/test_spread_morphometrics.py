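"""Calibration, lognormal fitting, cluster detection and mark counting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txfactory.spread_morphometrics import (
    Calibration,
    cluster_statistics,
    detect_clusters,
    estimate_calibration,
    fit_lognormal,
    kb_to_microns,
    marks_per_track,
    microns_to_kb,
    simulate_probe_measurements,
)
from txfactory.synthetic_data import SpreadFibre


def fibre_from_tracks(tracks, transcripts=(), polii=()):
    tracks = np.asarray(tracks, dtype=float)
    return SpreadFibre(
        fibre_id="f", tracks=tracks,
        transcript_marks=np.asarray(transcripts, dtype=float),
        polii_marks=np.asarray(polii, dtype=float),
        truth_cluster_ids=np.zeros(len(tracks), dtype=int),
        total_kb=float(tracks[:, 1].max()) if len(tracks) else 0.0,
    )


class TestCalibration:
    @pytest.mark.parametrize(
        "um, expected",
        [(0.0, 0.0), (1.0, 3.9), (12.117, pytest.approx(47.26, abs=0.01))],
    )
    def test_microns_to_kb(self, um, expected):
        assert microns_to_kb(um, Calibration(kb_per_um=3.9)) == expected

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            microns_to_kb(-1.0, Calibration(kb_per_um=3.9))

    def test_round_trip_is_identity(self):
        cal = Calibration(kb_per_um=3.9)
        x = np.linspace(0.1, 500, 40)
        assert np.allclose(microns_to_kb(kb_to_microns(x, cal), cal), x)

    def test_single_noise_free_measurement(self):
        cal = estimate_calibration([47.26 / 3.9])
        assert cal.kb_per_um == pytest.approx(3.9)
        assert cal.se == 0.0

    def test_equal_measurements_have_zero_se(self):
        cal = estimate_calibration([12.0] * 10)
        assert cal.se == 0.0 and cal.n == 10

    def test_recovery_under_noise(self):
        """100 measurements at 5% multiplicative noise recover 3.9 Kb/um
        within two standard errors."""
        m = simulate_probe_measurements(100, noise_cv=0.05, seed=8)
        cal = estimate_calibration(m)
        assert abs(cal.kb_per_um - 3.9) < 2 * cal.se + 1e-9

    @pytest.mark.parametrize("bad", [[], [0.0], [-1.0, 2.0]])
    def test_invalid_measurements_rejected(self, bad):
        with pytest.raises(ValueError):
            estimate_calibration(bad)


class TestLognormalFit:
    def test_degenerate_constant_sample(self):
        fit = fit_lognormal([7.5] * 20)
        assert fit.sigma_log == pytest.approx(0.0, abs=1e-12)
        assert fit.arith_mean == pytest.approx(7.5)

    def test_matches_grid_search_oracle(self, rng):
        """The closed-form MLE agrees with a brute-force likelihood grid."""
        x = rng.lognormal(2.53, 0.6, size=1000)
        fit = fit_lognormal(x)
        logs = np.log(x)
        mus = np.linspace(2.3, 2.8, 201)
        sigmas = np.linspace(0.4, 0.8, 161)
        mu_g, sig_g = np.meshgrid(mus, sigmas, indexing="ij")
        ll = -x.size * np.log(sig_g) - ((logs[None, None, :] - mu_g[..., None]) ** 2).sum(-1) / (2 * sig_g**2)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        assert abs(fit.mu_log - mus[i]) <= (mus[1] - mus[0])
        assert abs(fit.sigma_log - sigmas[j]) <= (sigmas[1] - sigmas[0])

    def test_default_tracks_recover_15kb(self, default_lengths):
        fit = fit_lognormal(default_lengths)
        assert fit.arith_mean == pytest.approx(15.0, rel=0.05)

    @pytest.mark.parametrize("bad", [[1.0], [1.0, -2.0], [0.0, 1.0]])
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(ValueError):
            fit_lognormal(bad)


class TestClusterDetection:
    def test_single_track_no_cluster(self):
        assert detect_clusters(fibre_from_tracks([(0, 10)])) == []

    def test_gap_pattern_splits_runs(self):
        """Gaps (50, 50, 150, 50) over five tracks give clusters of 3 and 2."""
        tracks = []
        pos = 0.0
        for gap in (50, 50, 150, 50):
            tracks.append((pos, pos + 10))
            pos += 10 + gap
        tracks.append((pos, pos + 10))
        clusters = detect_clusters(fibre_from_tracks(tracks))
        assert [c.n_tus for c in clusters] == [3, 2]

    def test_boundary_gap_is_exclusive(self):
        """A gap of exactly 100 Kb does not cluster (strictly 'less than')."""
        assert detect_clusters(fibre_from_tracks([(0, 10), (110, 120)])) == []
        found = detect_clusters(fibre_from_tracks([(0, 10), (109.99, 120)]))
        assert len(found) == 1 and found[0].n_tus == 2

    def test_overlapping_tracks_rejected(self):
        f = fibre_from_tracks([(0, 10), (20, 30)])
        f.tracks = np.array([[0.0, 10.0], [5.0, 30.0]])  # corrupt post-validation
        with pytest.raises(ValueError):
            detect_clusters(f)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        lengths=st.lists(st.floats(1.0, 40.0), min_size=1, max_size=25),
        gaps=st.lists(st.floats(0.5, 300.0), min_size=0, max_size=24),
    )
    def test_matches_brute_force_rule(self, lengths, gaps):
        """Detected clusters equal a direct re-statement of the rule: split
        the track sequence at every gap >= 100 Kb, keep runs of >= 2."""
        gaps = gaps[: len(lengths) - 1]
        lengths = lengths[: len(gaps) + 1]
        tracks, pos = [], 0.0
        for i, ln in enumerate(lengths):
            tracks.append((pos, pos + ln))
            pos += ln + (gaps[i] if i < len(gaps) else 0.0)
        clusters = detect_clusters(fibre_from_tracks(tracks))
        runs, run = [], [0]
        for i, g in enumerate(gaps):
            if g < 100.0:
                run.append(i + 1)
            else:
                runs.append(run)
                run = [i + 1]
        runs.append(run)
        expected = [tuple(r) for r in runs if len(r) >= 2]
        assert [c.member_track_indices for c in clusters] == expected

    def test_truth_equals_detection_on_generated_fibres(self, default_sample):
        """Round trip: generator truth clusters == detected clusters."""
        for f in default_sample.fibres:
            detected = detect_clusters(f)
            truth_groups = [
                tuple(np.where(f.truth_cluster_ids == cid)[0])
                for cid in np.unique(f.truth_cluster_ids)
            ]
            assert [c.member_track_indices for c in detected] == truth_groups


class TestClusterStatistics:
    def test_closed_form_single_cluster(self):
        tracks, pos = [], 0.0
        for i in range(8):
            tracks.append((pos, pos + 15))
            pos += 15 + 30
        (c,) = detect_clusters(fibre_from_tracks(tracks))
        assert c.span_kb == pytest.approx(330.0)
        stats = cluster_statistics([c])
        assert stats.n_clusters == 1
        assert stats.tus_per_cluster_mean == 8
        assert stats.span_mean_kb == pytest.approx(330.0)

    def test_empty_input_flagged_not_raised(self):
        stats = cluster_statistics([])
        assert stats.n_clusters == 0
        assert math.isnan(stats.span_mean_kb)

    def test_permutation_invariant(self, default_sample, rng):
        clusters = [c for f in default_sample.fibres[:1] for c in detect_clusters(f)]
        import dataclasses

        shuffled = list(clusters)
        rng.shuffle(shuffled)
        a = dataclasses.asdict(cluster_statistics(clusters))
        b = dataclasses.asdict(cluster_statistics(shuffled))
        assert a == pytest.approx(b)  # mean/SD insensitive to summation order


class TestMarksPerTrack:
    def test_no_marks(self):
        out = marks_per_track([fibre_from_tracks([(0, 10), (50, 60)])])
        assert out["transcripts"].mean == 0.0 and out["transcripts"].sd == 0.0

    def test_hand_computed_counts(self):
        f = fibre_from_tracks(
            [(0, 10), (20, 30), (40, 50)],
            transcripts=[21.0, 41.0, 45.0],  # counts (0, 1, 2)
        )
        out = marks_per_track([f])
        assert out["transcripts"].mean == pytest.approx(1.0)
        assert out["transcripts"].sd == pytest.approx(1.0)
        assert out["transcripts"].histogram == {0: 1, 1: 1, 2: 1}

    def test_orphan_marks_reported(self):
        f = fibre_from_tracks([(0, 10)], transcripts=[15.0])
        out = marks_per_track([f])
        assert out["transcripts"].n_orphans == 1
        assert out["transcripts"].mean == 0.0

    def test_default_rates_recovered(self, default_sample):
        out = marks_per_track(default_sample.fibres)
        assert out["transcripts"].mean == pytest.approx(0.7, abs=0.05)
        assert out["polii"].mean == pytest.approx(0.8, abs=0.05)
        assert out["transcripts"].n_orphans == 0
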