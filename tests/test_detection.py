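"""Candidate detection, Gaussian spot fitting, the fusion-signature
classifier and event alignment."""

import numpy as np
import pytest

from tirfex.detection import (
    CandidateEvent,
    ClassifyCriteria,
    FWHM_PER_SIGMA,
    FusionEvent,
    align_events,
    classify_all,
    classify_fusion,
    detect_candidates,
    events_to_frame,
    fit_gaussian_spot,
)
from tirfex.synth import GroundTruthEvent, MovieConfig, render_movie


def gaussian_frame(shape, r0, c0, sigma, peak, offset):
    rr, cc = np.mgrid[0: shape[0], 0: shape[1]]
    return offset + peak * np.exp(
        -(((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))
    )


class TestGaussianFit:
    def test_exact_recovery_on_noiseless_spot(self):
        frame = gaussian_frame((31, 31), 15.4, 14.7, 2.0, 80.0, 10.0)
        fit = fit_gaussian_spot(frame, (15, 15), 11)
        assert fit.fit_ok
        assert fit.row == pytest.approx(15.4, abs=1e-6)
        assert fit.col == pytest.approx(14.7, abs=1e-6)
        assert fit.sigma_px == pytest.approx(2.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(2 * np.pi * 80 * 4, rel=1e-6)
        assert fit.offset == pytest.approx(10.0, abs=1e-6)

    def test_fwhm_closed_form(self):
        # sigma = 2 px at 0.189 um/px
        assert FWHM_PER_SIGMA * 2 * 0.189 == pytest.approx(0.8901, abs=1e-4)

    def test_poisson_noise_width_unbiased(self):
        """Mean fitted sigma over 200 shot-noise replicates within 5%."""
        rng = np.random.default_rng(4)
        clean = gaussian_frame((25, 25), 12.0, 12.0, 2.0, 150.0, 100.0)
        sigmas = []
        for _ in range(200):
            fit = fit_gaussian_spot(rng.poisson(clean).astype(float), (12, 12), 15)
            if fit.fit_ok:
                sigmas.append(fit.sigma_px)
        assert len(sigmas) > 180
        assert np.mean(sigmas) == pytest.approx(2.0, rel=0.05)

    def test_border_clip_flags_fit(self):
        frame = gaussian_frame((31, 31), 2.0, 2.0, 1.5, 50.0, 5.0)
        fit = fit_gaussian_spot(frame, (2, 2), 11)
        assert not fit.fit_ok

    def test_window_validation_and_nonfinite(self):
        frame = np.zeros((21, 21))
        with pytest.raises(ValueError):
            fit_gaussian_spot(frame, (10, 10), 10)  # even window
        frame[10, 10] = np.nan
        with pytest.raises(ValueError):
            fit_gaussian_spot(frame, (10, 10), 11)


def _single_event_movie(diffusion=0.05, vel=(0.0, 0.0), n_after=14):
    cfg = MovieConfig(
        n_frames=12 + n_after, height_px=64, width_px=64, photobleach_frame=4,
        poisson_noise=False, read_noise_sd=0.0,
    )
    cell = np.ones((64, 64), bool)
    fas = np.zeros((64, 64), bool)
    ev = GroundTruthEvent(
        0, 30.0, 33.0, 12, amplitude=4000.0, sigma0_um=0.15,
        diffusion_um2_per_s=diffusion,
        vel_row_px_per_frame=vel[0], vel_col_px_per_frame=vel[1],
    )
    movie, _ = render_movie(cfg, [ev], cell, fas)
    return cfg, cell, ev, movie


class TestDetectCandidates:
    def test_static_noiseless_movie_has_no_candidates(self):
        movie = np.full((20, 32, 32), 100.0, dtype=np.float32)
        cell = np.ones((32, 32), bool)
        assert detect_candidates(movie, cell) == []

    def test_single_clean_event_found_at_true_location_and_frame(self):
        cfg, cell, ev, movie = _single_event_movie(n_after=8)
        cands = detect_candidates(movie, cell, photobleach_frame=4)
        assert len(cands) == 1
        assert cands[0].t0_frame == ev.t0_frame
        assert np.hypot(cands[0].row_px - ev.row_px,
                        cands[0].col_px - ev.col_px) <= 1.0

    def test_translation_equivariance(self, small_sim):
        movie, cell = small_sim["movie"], small_sim["cell"]
        pb = small_sim["config"].photobleach_frame
        dr, dc = 4, 6
        shifted = np.roll(movie, (dr, dc), axis=(1, 2))
        cell_shifted = np.roll(cell, (dr, dc), axis=(0, 1))
        a = detect_candidates(movie, cell, photobleach_frame=pb)
        b = detect_candidates(shifted, cell_shifted, photobleach_frame=pb)
        set_a = {(c.row_px + dr, c.col_px + dc, c.t0_frame) for c in a}
        set_b = {(c.row_px, c.col_px, c.t0_frame) for c in b}
        assert set_a == set_b

    def test_intensity_scale_invariance(self, small_sim):
        movie, cell = small_sim["movie"], small_sim["cell"]
        pb = small_sim["config"].photobleach_frame
        a = detect_candidates(movie, cell, photobleach_frame=pb)
        b = detect_candidates(movie * 3.7, cell, photobleach_frame=pb)
        assert [(c.row_px, c.col_px, c.t0_frame) for c in a] == [
            (c.row_px, c.col_px, c.t0_frame) for c in b
        ]

    def test_requires_frames_and_cell(self):
        movie = np.zeros((4, 16, 16), dtype=np.float32)
        with pytest.raises(ValueError):
            detect_candidates(movie, np.zeros((16, 16), bool))
        with pytest.raises(ValueError):
            detect_candidates(movie, np.ones((16, 16), bool), photobleach_frame=3)


class TestClassifier:
    def test_clean_fusion_event_accepted(self):
        cfg, cell, ev, movie = _single_event_movie(diffusion=0.05)
        cand = CandidateEvent(30, 33, 12, 100.0)
        out = classify_fusion(cand, movie, photobleach_frame=4)
        assert out.accepted and out.rejection_reason is None
        assert out.fwhm_slope_um_per_frame > 0

    def test_docked_vesicle_rejected_for_no_spread(self):
        cfg, cell, ev, movie = _single_event_movie(diffusion=0.0)
        cand = CandidateEvent(30, 33, 12, 100.0)
        out = classify_fusion(cand, movie, photobleach_frame=4)
        assert not out.accepted and out.rejection_reason == "no_spread"

    def test_moving_vesicle_rejected_as_moving(self):
        cfg, cell, ev, movie = _single_event_movie(
            diffusion=0.0, vel=(0.7, 0.7)
        )
        cand = CandidateEvent(30, 33, 12, 100.0)
        out = classify_fusion(cand, movie, photobleach_frame=4)
        assert not out.accepted and out.rejection_reason == "moving"
        assert out.drift_px > 2.0

    def test_classification_scale_invariant(self, small_sim):
        movie, cell = small_sim["movie"], small_sim["cell"]
        pb = small_sim["config"].photobleach_frame
        cands = detect_candidates(movie, cell, photobleach_frame=pb)
        a = events_to_frame(classify_all(cands, movie, cell, photobleach_frame=pb))
        b = events_to_frame(
            classify_all(cands, movie * 2.5, cell, photobleach_frame=pb)
        )
        assert a["accepted"].tolist() == b["accepted"].tolist()
        assert a["rejection_reason"].tolist() == b["rejection_reason"].tolist()

    def test_fwhm_sigma_relation_elementwise(self):
        cfg, cell, ev, movie = _single_event_movie()
        out = classify_fusion(CandidateEvent(30, 33, 12, 100.0), movie,
                              photobleach_frame=4)
        sel = np.isfinite(out.sigma_trace_um)
        assert np.allclose(
            out.fwhm_trace_um[sel], FWHM_PER_SIGMA * out.sigma_trace_um[sel]
        )


def _make_event(amp_value, n=18, pre=5):
    offsets = np.arange(-pre, n - pre)
    return FusionEvent(
        event_id=0, row_px=10.0, col_px=10.0, t0_frame=20, offsets=offsets,
        amplitude_trace=np.full(offsets.size, float(amp_value)),
        sigma_trace_um=np.full(offsets.size, 0.2),
        fwhm_slope_um_per_frame=0.1, drift_px=0.0, accepted=True,
        rejection_reason=None,
    )


class TestAlignEvents:
    def test_identical_events_have_zero_sem(self):
        prof = align_events([_make_event(7.0)] * 5, pre_frames=3, post_frames=6)
        assert np.allclose(prof.amplitude_mean, 7.0)
        assert np.allclose(prof.amplitude_sem, 0.0)
        assert (prof.n_events == 5).all()

    def test_two_event_closed_form(self):
        a, b = 4.0, 10.0
        prof = align_events([_make_event(a), _make_event(b)],
                            pre_frames=3, post_frames=6)
        assert np.allclose(prof.amplitude_mean, (a + b) / 2)
        assert np.allclose(prof.amplitude_sem, abs(a - b) / 2)

    def test_short_events_excluded_and_counted(self):
        long_ev = _make_event(5.0)
        short_ev = _make_event(5.0, n=6, pre=1)
        prof = align_events([long_ev, short_ev], pre_frames=3, post_frames=6)
        assert prof.n_excluded == 1

    def test_noisy_ensemble_tracks_noiseless_template(self):
        """Mean aligned amplitude of noisy replicates of one event stays
        within 2 SEM of the noiseless template at >= 95% of offsets."""
        cfg = MovieConfig(
            n_frames=40, height_px=64, width_px=64, photobleach_frame=4,
            poisson_noise=False, read_noise_sd=0.0,
        )
        cell = np.ones((64, 64), bool)
        fas = np.zeros((64, 64), bool)
        crit = ClassifyCriteria(pre_frames=8)
        template = GroundTruthEvent(0, 30.0, 33.0, 15, amplitude=4000.0)
        clean_movie, _ = render_movie(cfg, [template], cell, fas)
        clean = classify_fusion(CandidateEvent(30, 33, 15, 0.0), clean_movie,
                                criteria=crit, photobleach_frame=4)
        noisy_events = []
        for seed in range(30):
            ncfg = MovieConfig(
                n_frames=40, height_px=64, width_px=64, photobleach_frame=4,
                poisson_noise=True, read_noise_sd=3.0, seed=seed,
            )
            movie, _ = render_movie(ncfg, [template], cell, fas, seed=seed)
            noisy_events.append(
                classify_fusion(CandidateEvent(30, 33, 15, 0.0), movie,
                                criteria=crit, photobleach_frame=4)
            )
        prof = align_events(noisy_events, pre_frames=8, post_frames=11,
                            accepted_only=False)
        sel = np.isin(clean.offsets, prof.offsets_frames)
        resid = np.abs(prof.amplitude_mean - clean.amplitude_trace[sel])
        frac_ok = np.mean(resid <= 2 * np.maximum(prof.amplitude_sem, 1e-9))
        assert frac_ok >= 0.95

    def test_no_accepted_events_is_an_error(self):
        with pytest.raises(ValueError):
            align_events([], pre_frames=2, post_frames=2)
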