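"""Detection and classification of pHluorin exocytic fusion events.

A fusion event has a two-part optical signature: (1) a rapid intensity
rise when the cargo-loaded vesicle de-acidifies at the moment of fusion,
and (2) a subsequent growth of the spot's full width at half maximum as
the cargo diffuses laterally in the plasma membrane.  Candidates are
appearance transients in the post-bleach movie (local maxima of the
frame minus a rolling temporal-median baseline, in robust-noise units);
each candidate is then fitted frame by frame with an isotropic 2D
Gaussian and accepted only if it rises, spreads (positive FWHM slope by
a t-test on the regression slope) and stays put (drift veto against
moving endosomes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

_MAD_TO_SD = 1.4826  # normal-consistency factor for the median absolute deviation


@dataclass(frozen=True)
class CandidateEvent:
    """An appearance transient: integer peak pixel, first frame, jump size."""

    row_px: int
    col_px: int
    t0_frame: int
    peak_delta: float


@dataclass(frozen=True)
class ClassifyCriteria:
    """Thresholds of the fusion-signature classifier.

    min_rise_factor is in single-frame robust-noise units.  The spread
    test regresses the per-frame FWHM against frame offset with weights
    from each fit's covariance (early, bright frames carry more
    information than late, dim ones) and requires a slope above
    ``min_fwhm_slope`` with two-sided p below ``slope_p_value``, with
    usable Gaussian fits on at least ``min_fit_fraction`` of the spread
    window.  max_drift_px bounds the center displacement over the spread
    window, estimated by a weighted linear trajectory fit.  Per-frame
    fits run on baseline-subtracted frames smoothed with a Gaussian of
    ``smooth_sigma_px``; since a Gaussian spot convolved with a Gaussian
    kernel stays Gaussian, the kernel variance is subtracted back out
    exactly.
    """

    min_rise_factor: float = 3.0
    rise_window_frames: int = 2
    spread_window_frames: int = 12
    min_fwhm_slope: float = 0.0  # um / frame
    slope_p_value: float = 0.05
    max_drift_px: float = 2.0
    window_px: int = 15
    min_fit_fraction: float = 2.0 / 3.0
    pre_frames: int = 5
    baseline_frames: int = 10
    smooth_sigma_px: float = 1.0
    aperture_radius_px: float = 4.0


@dataclass
class FusionEvent:
    """One classified candidate with its per-frame traces.

    Trace index k corresponds to frame ``t0_frame + offsets[k]`` with
    offsets running from -pre_frames to spread_window_frames - 1.
    amplitude_trace is background-subtracted aperture photometry
    (defined at every offset); sigma/fwhm traces come from the per-frame
    Gaussian fits and are NaN before fusion or where the fit failed.
    """

    event_id: int
    row_px: float
    col_px: float
    t0_frame: int
    offsets: np.ndarray
    amplitude_trace: np.ndarray
    sigma_trace_um: np.ndarray
    fwhm_slope_um_per_frame: float
    drift_px: float
    accepted: bool
    rejection_reason: str | None

    @property
    def fwhm_trace_um(self) -> np.ndarray:
        return FWHM_PER_SIGMA * self.sigma_trace_um


@dataclass(frozen=True)
class GaussianFit:
    row: float
    col: float
    sigma_px: float
    amplitude: float  # integrated intensity 2*pi*peak*sigma^2
    offset: float
    fit_ok: bool
    # 1-sigma parameter uncertainties from the fit covariance
    row_se: float = np.nan
    col_se: float = np.nan
    sigma_se_px: float = np.nan


def robust_noise_sd(movie: np.ndarray, cell: np.ndarray,
                    t_start: int = 0, t_stop: int | None = None) -> float:
    """Single-frame noise SD from the MAD of temporal frame differences.

    The difference of two consecutive frames doubles the noise variance,
    so the MAD-based SD of the differences is divided by sqrt(2).
    """
    t_stop = movie.shape[0] if t_stop is None else t_stop
    if t_stop - t_start < 2:
        raise ValueError("need at least two frames to estimate noise")
    diffs = np.diff(movie[t_start:t_stop], axis=0)[:, cell]
    mad = np.median(np.abs(diffs - np.median(diffs)))
    return float(_MAD_TO_SD * mad / np.sqrt(2.0))


def detect_candidates(
    movie: np.ndarray,
    cell: np.ndarray,
    photobleach_frame: int = 0,
    rise_sigma_factor: float = 5.0,
    min_separation_px: int = 5,
    refractory_frames: int = 10,
    baseline_frames: int = 5,
    smooth_sigma_px: float = 1.0,
    confirm_sigma_factor: float = 2.5,
) -> list[CandidateEvent]:
    """Find appearance transients in the post-bleach movie.

    Each post-bleach frame is spatially smoothed and compared against the
    pixelwise temporal median of the preceding ``baseline_frames`` smoothed
    frames; local maxima of this excess exceeding ``rise_sigma_factor``
    times the per-frame robust noise SD (scaled MAD within the cell),
    separated by at least ``min_separation_px``, become candidates.  A
    candidate must persist: against the same baseline, the next frame must
    stay above ``confirm_sigma_factor`` noise SDs at the peak (a fused
    vesicle remains bright for several frames; single-frame noise spikes
    do not).  A later transient within ``min_separation_px`` and
    ``refractory_frames`` of an existing candidate is merged into it, so
    each event is reported once with its first frame.
    """
    from skimage.feature import peak_local_max

    cell = np.asarray(cell, bool)
    if not cell.any():
        raise ValueError("cell mask is empty")
    n_frames = movie.shape[0]
    if n_frames - photobleach_frame < 3:
        raise ValueError("need at least 3 frames after the photobleach frame")

    sm = np.empty_like(movie, dtype=float)
    for t in range(photobleach_frame, n_frames):
        sm[t] = ndimage.gaussian_filter(
            np.asarray(movie[t], dtype=float), smooth_sigma_px
        )

    candidates: list[CandidateEvent] = []
    t_first = photobleach_frame + min(baseline_frames, 3)
    for t in range(t_first, n_frames):
        b0 = max(photobleach_frame, t - baseline_frames)
        baseline = np.median(sm[b0:t], axis=0)
        delta = sm[t] - baseline
        vals = delta[cell]
        sd = _MAD_TO_SD * np.median(np.abs(vals - np.median(vals)))
        # noiseless movies have sd == 0; a tiny absolute floor still lets
        # a rendered appearance through while a static scene yields nothing
        peaks = peak_local_max(
            np.where(cell, delta, -np.inf),
            min_distance=min_separation_px,
            threshold_abs=max(rise_sigma_factor * sd, 1e-9),
            exclude_border=False,
        )
        for r, c in peaks:
            merged = False
            for prev in candidates:
                if (
                    t - prev.t0_frame <= refractory_frames
                    and np.hypot(r - prev.row_px, c - prev.col_px)
                    <= min_separation_px
                ):
                    merged = True
                    break
            if merged:
                continue
            if t + 1 < n_frames:
                next_delta = sm[t + 1, r, c] - baseline[r, c]
                if next_delta < confirm_sigma_factor * sd:
                    continue
            candidates.append(
                CandidateEvent(int(r), int(c), int(t), float(delta[r, c]))
            )
    return candidates


def _gauss2d(coords, peak, r0, c0, sigma, offset):
    rr, cc = coords
    return (
        offset
        + peak * np.exp(-(((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma**2)))
    ).ravel()


def fit_gaussian_spot(
    frame: np.ndarray,
    center: tuple[float, float],
    window_px: int = 11,
) -> GaussianFit:
    """Least-squares isotropic 2D Gaussian + constant offset on a window.

    ``window_px`` must be odd.  Windows clipped at the frame border are
    still fitted but flagged ``fit_ok=False``, as are fits where the
    solver fails, sigma exceeds half the window, the center leaves the
    window, or the amplitude is non-positive.  The reported amplitude is
    the integrated intensity 2*pi*peak*sigma^2.
    """
    if window_px % 2 == 0 or window_px < 5:
        raise ValueError("window_px must be odd and >= 5")
    h, w = frame.shape
    half = window_px // 2
    r0, c0 = int(round(center[0])), int(round(center[1]))
    rlo, rhi = r0 - half, r0 + half + 1
    clo, chi = c0 - half, c0 + half + 1
    clipped = rlo < 0 or clo < 0 or rhi > h or chi > w
    rlo, clo = max(rlo, 0), max(clo, 0)
    rhi, chi = min(rhi, h), min(chi, w)
    patch = np.asarray(frame[rlo:rhi, clo:chi], dtype=float)
    if not np.all(np.isfinite(patch)):
        raise ValueError("non-finite pixels in fit window")
    rr, cc = np.mgrid[rlo:rhi, clo:chi]

    offset0 = float(np.median(patch))
    peak0 = max(float(patch.max() - offset0), 1e-6)
    p0 = [peak0, float(center[0]), float(center[1]), 1.5, offset0]
    try:
        popt, pcov = optimize.curve_fit(
            _gauss2d, (rr, cc), patch.ravel(), p0=p0,
            bounds=(
                [0.0, rlo - 1.0, clo - 1.0, 0.2, -np.inf],
                [np.inf, rhi, chi, float(window_px), np.inf],
            ),
            maxfev=2000,
        )
        peak, rf, cf, sigma, offset = (float(x) for x in popt)
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(pcov))
        ok = (
            not clipped
            and peak > 0
            and 0.2 < sigma <= window_px / 2.0
            and rlo - 0.5 <= rf <= rhi - 0.5
            and clo - 0.5 <= cf <= chi - 0.5
        )
        return GaussianFit(rf, cf, sigma, 2.0 * np.pi * peak * sigma**2, offset,
                           ok, float(se[1]), float(se[2]), float(se[3]))
    except RuntimeError:
        return GaussianFit(float(center[0]), float(center[1]), np.nan,
                           np.nan, np.nan, False)


def _aperture_sum(frame: np.ndarray, r0: int, c0: int, radius: float) -> float:
    """Background-subtracted aperture photometry: disc sum minus the
    annulus-mean background times the disc area.  The mean (not the
    median) keeps the estimator unbiased under shot noise."""
    h, w = frame.shape
    half = int(np.ceil(radius)) + 4
    rlo, rhi = max(r0 - half, 0), min(r0 + half + 1, h)
    clo, chi = max(c0 - half, 0), min(c0 + half + 1, w)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    d = np.hypot(rr - r0, cc - c0)
    disc = d <= radius
    annulus = (d > radius + 1) & (d <= radius + 4)
    patch = np.asarray(frame[rlo:rhi, clo:chi], dtype=float)
    bg = float(np.mean(patch[annulus])) if annulus.any() else 0.0
    return float(patch[disc].sum() - bg * disc.sum())


def _weighted_slope(x: np.ndarray, y: np.ndarray, se: np.ndarray
                    ) -> tuple[float, float]:
    """Inverse-variance weighted least-squares slope and its two-sided
    p-value by the slope t-statistic (df = n - 2)."""
    w = 1.0 / np.maximum(se, 1e-6) ** 2
    X = np.column_stack([np.ones_like(x), x])
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ beta
    dof = x.size - 2
    if dof < 1:
        return float(beta[1]), np.nan
    s2 = np.sum(w * resid**2) / dof
    cov = np.linalg.inv(X.T @ (w[:, None] * X)) * s2
    se_slope = np.sqrt(cov[1, 1])
    if se_slope == 0:
        return float(beta[1]), np.nan
    t = beta[1] / se_slope
    return float(beta[1]), float(2.0 * stats.t.sf(abs(t), dof))


def _traj_speed(k: np.ndarray, pos: np.ndarray, se: np.ndarray
                ) -> tuple[float, float, float]:
    """Weighted linear trajectory fit; returns (intercept, ignored, speed)."""
    if k.size < 2 or np.ptp(k) == 0:
        return float(pos[0]), 0.0, 0.0
    coef = np.polyfit(k, pos, 1, w=1.0 / np.maximum(se, 1e-6))
    return float(coef[1]), 0.0, float(coef[0])


def classify_fusion(
    candidate: CandidateEvent,
    movie: np.ndarray,
    criteria: ClassifyCriteria | None = None,
    pixel_size_um: float = 0.189,
    event_id: int = 0,
    noise_sd: float | None = None,
    photobleach_frame: int = 0,
) -> FusionEvent:
    """Apply the fusion signature to one candidate.

    Accepted iff the candidate (a) rises: the peak pixel intensity within
    ``rise_window_frames`` of t0 exceeds the pre-fusion local level (the
    temporal median of the 10 preceding frames at the candidate pixel) by
    at least ``min_rise_factor`` noise SDs; (b) spreads: the weighted
    FWHM-vs-time slope over the spread window is positive with
    p < slope_p_value and usable fits on >= min_fit_fraction of frames;
    and (c) stays put: the fitted-center trajectory displacement over the
    spread window is <= max_drift_px.  Rejections are labelled, in
    precedence order, moving, fit_failure, no_rise or no_spread.

    Per-frame widths are fitted on baseline-subtracted frames (the
    pixelwise mean of up to ``baseline_frames`` pre-fusion frames)
    smoothed with a Gaussian kernel; the kernel variance is subtracted
    from the fitted variance, which is exact for Gaussian spots.
    """
    crit = criteria or ClassifyCriteria()
    n_frames = movie.shape[0]
    t0, r, c = candidate.t0_frame, candidate.row_px, candidate.col_px
    if n_frames - t0 < crit.spread_window_frames:
        raise ValueError("not enough frames after t0 for the spread window")
    if noise_sd is None:
        cell_box = np.zeros(movie.shape[1:], bool)
        half = 16
        cell_box[max(r - half, 0): r + half + 1, max(c - half, 0): c + half + 1] = True
        lo = max(photobleach_frame, t0 - 12)
        hi = max(t0, lo + 3)
        noise_sd = robust_noise_sd(movie, cell_box, lo, min(hi, n_frames))

    offsets = np.arange(-crit.pre_frames, crit.spread_window_frames)
    offsets = offsets[(t0 + offsets >= 0) & (t0 + offsets < n_frames)]
    amp = np.array(
        [_aperture_sum(movie[t0 + k], r, c, crit.aperture_radius_px) for k in offsets]
    )

    base_lo = max(t0 - crit.baseline_frames, photobleach_frame, 0)
    baseline = (
        np.mean(np.asarray(movie[base_lo:t0], dtype=float), axis=0)
        if t0 > base_lo
        else np.zeros(movie.shape[1:], dtype=float)
    )
    sm2 = crit.smooth_sigma_px**2
    sigma_um = np.full(offsets.size, np.nan)
    recs: list[tuple[float, float, float, float, float, float, float]] = []
    for i, k in enumerate(offsets):
        if k < 0:
            continue
        delta = ndimage.gaussian_filter(
            np.asarray(movie[t0 + k], dtype=float) - baseline, crit.smooth_sigma_px
        )
        fit = fit_gaussian_spot(delta, (r, c), crit.window_px)
        if not fit.fit_ok or not fit.sigma_px**2 > sm2 + 1e-9:
            continue
        s_corr = np.sqrt(fit.sigma_px**2 - sm2)
        sigma_um[i] = s_corr * pixel_size_um
        # 1-sigma error of the corrected width, propagated through the
        # variance subtraction
        s_se = (fit.sigma_px / s_corr) * (
            fit.sigma_se_px if np.isfinite(fit.sigma_se_px) else 1e-3
        )
        recs.append((float(k), s_corr, s_se, fit.row, fit.col,
                     fit.row_se if np.isfinite(fit.row_se) else 1e-3,
                     fit.col_se if np.isfinite(fit.col_se) else 1e-3))

    n_spread = len(recs)
    n_needed = int(np.ceil(crit.min_fit_fraction * crit.spread_window_frames))

    fwhm_slope, slope_p, drift = np.nan, np.nan, np.nan
    if n_spread >= 3:
        a = np.array(recs)
        k_arr = a[:, 0]
        fwhm = FWHM_PER_SIGMA * a[:, 1] * pixel_size_um
        fwhm_se = FWHM_PER_SIGMA * a[:, 2] * pixel_size_um
        fwhm_slope, slope_p = _weighted_slope(k_arr, fwhm, fwhm_se)
        span = crit.spread_window_frames - 1
        _, _, vr = _traj_speed(k_arr, a[:, 3], a[:, 5])
        _, _, vc = _traj_speed(k_arr, a[:, 4], a[:, 6])
        drift = float(np.hypot(vr, vc) * span)

    pre_lo = max(t0 - 10, 0)
    pre_level = float(np.median(movie[pre_lo:t0, r, c])) if t0 > pre_lo else 0.0
    rise_hi = min(t0 + crit.rise_window_frames + 1, n_frames)
    peak_val = float(np.max(movie[t0:rise_hi, r, c]))
    rises = peak_val - pre_level >= crit.min_rise_factor * noise_sd

    reason: str | None = None
    if np.isfinite(drift) and drift > crit.max_drift_px:
        reason = "moving"
    elif n_spread < n_needed:
        reason = "fit_failure"
    elif not rises:
        reason = "no_rise"
    elif not (
        fwhm_slope > crit.min_fwhm_slope
        and np.isfinite(slope_p)
        and slope_p < crit.slope_p_value
    ):
        reason = "no_spread"

    if recs:
        sub_r, sub_c = recs[0][3], recs[0][4]
    else:
        sub_r, sub_c = float(r), float(c)
    return FusionEvent(
        event_id=event_id,
        row_px=sub_r,
        col_px=sub_c,
        t0_frame=t0,
        offsets=offsets,
        amplitude_trace=amp,
        sigma_trace_um=sigma_um,
        fwhm_slope_um_per_frame=fwhm_slope,
        drift_px=float(drift),
        accepted=reason is None,
        rejection_reason=reason,
    )


def classify_all(
    candidates: list[CandidateEvent],
    movie: np.ndarray,
    cell: np.ndarray,
    criteria: ClassifyCriteria | None = None,
    pixel_size_um: float = 0.189,
    photobleach_frame: int = 0,
) -> list[FusionEvent]:
    """Classify every candidate with enough remaining frames, sharing one
    global noise estimate; candidates too close to the movie end are
    rejected as fit_failure."""
    crit = criteria or ClassifyCriteria()
    sd = robust_noise_sd(movie, np.asarray(cell, bool), photobleach_frame)
    out = []
    for i, cand in enumerate(candidates):
        if movie.shape[0] - cand.t0_frame < crit.spread_window_frames:
            out.append(
                FusionEvent(
                    event_id=i, row_px=float(cand.row_px), col_px=float(cand.col_px),
                    t0_frame=cand.t0_frame, offsets=np.empty(0, int),
                    amplitude_trace=np.empty(0), sigma_trace_um=np.empty(0),
                    fwhm_slope_um_per_frame=np.nan, drift_px=np.nan,
                    accepted=False, rejection_reason="fit_failure",
                )
            )
            continue
        out.append(
            classify_fusion(
                cand, movie, crit, pixel_size_um, event_id=i, noise_sd=sd,
                photobleach_frame=photobleach_frame,
            )
        )
    return out


@dataclass
class AlignedProfile:
    """Mean +/- SEM traces time-aligned to fusion (offset 0 = t0)."""

    offsets_frames: np.ndarray
    offsets_s: np.ndarray
    amplitude_mean: np.ndarray
    amplitude_sem: np.ndarray
    fwhm_mean_um: np.ndarray
    fwhm_sem_um: np.ndarray
    n_events: np.ndarray
    n_excluded: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset_frames": self.offsets_frames,
                "offset_s": self.offsets_s,
                "amplitude_mean": self.amplitude_mean,
                "amplitude_sem": self.amplitude_sem,
                "fwhm_mean_um": self.fwhm_mean_um,
                "fwhm_sem_um": self.fwhm_sem_um,
                "n": self.n_events,
            }
        )


def _mean_sem(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise mean, SEM (= sample SD / sqrt(n)) and contributor count,
    ignoring NaNs."""
    finite = np.isfinite(stack)
    n = finite.sum(axis=0)
    filled = np.where(finite, stack, 0.0)
    mean = np.where(n > 0, filled.sum(axis=0) / np.maximum(n, 1), np.nan)
    sq = np.where(finite, (stack - mean) ** 2, 0.0).sum(axis=0)
    sd = np.where(n > 1, np.sqrt(sq / np.maximum(n - 1, 1)), 0.0)
    sem = np.where(n > 0, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return mean, sem, n


def align_events(
    events: list[FusionEvent],
    pre_frames: int = 5,
    post_frames: int = 7,
    frame_interval_s: float = 1.0 / 6.0,
    accepted_only: bool = True,
) -> AlignedProfile:
    """Time-align accepted events at their fusion frame and average.

    Events whose traces do not cover [-pre_frames, post_frames] are
    excluded and counted in ``n_excluded``.
    """
    use = [e for e in events if e.accepted] if accepted_only else list(events)
    if not use:
        raise ValueError("no accepted events to align")
    offsets = np.arange(-pre_frames, post_frames + 1)
    amp_rows, fwhm_rows = [], []
    excluded = 0
    for ev in use:
        if ev.offsets.size == 0 or ev.offsets[0] > -pre_frames or ev.offsets[-1] < post_frames:
            excluded += 1
            continue
        sel = np.isin(ev.offsets, offsets)
        amp_rows.append(ev.amplitude_trace[sel])
        fwhm_rows.append(ev.fwhm_trace_um[sel])
    if not amp_rows:
        raise ValueError("no events cover the requested alignment window")
    amp_mean, amp_sem, n = _mean_sem(np.vstack(amp_rows))
    fwhm_mean, fwhm_sem, _ = _mean_sem(np.vstack(fwhm_rows))
    return AlignedProfile(
        offsets_frames=offsets,
        offsets_s=offsets * frame_interval_s,
        amplitude_mean=amp_mean,
        amplitude_sem=amp_sem,
        fwhm_mean_um=fwhm_mean,
        fwhm_sem_um=fwhm_sem,
        n_events=n,
        n_excluded=excluded,
    )


def events_to_frame(events: list[FusionEvent]) -> pd.DataFrame:
    """One row per classified event (CSV-ready)."""
    rows = []
    for ev in events:
        peak = float(np.nanmax(ev.amplitude_trace)) if ev.amplitude_trace.size else np.nan
        rows.append(
            {
                "event_id": ev.event_id,
                "row_px": ev.row_px,
                "col_px": ev.col_px,
                "t0_frame": ev.t0_frame,
                "accepted": ev.accepted,
                "rejection_reason": ev.rejection_reason or "",
                "peak_amplitude": peak,
                "fwhm_slope_um_per_frame": ev.fwhm_slope_um_per_frame,
                "drift_px": ev.drift_px,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id", "row_px", "col_px", "t0_frame", "accepted",
            "rejection_reason", "peak_amplitude", "fwhm_slope_um_per_frame",
            "drift_px",
        ],
    )
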