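"""Integrin pool quantifications: surface-quench endocytosis, dual-label
FA recycling ratios, and the flow-cytometric activation index.

The quench assay measures the internalized fraction of a surface-labelled
receptor: after a membrane-impermeant quenching antibody extinguishes
surface fluorescence, the remaining (internal) signal divided by the
pre-quench level is the endocytosed fraction.  The dual-label assay
follows the ratio of an internal-pool label (e.g. SiR647) to a surface
label (Alexa488) inside each focal adhesion over time; a rising ratio
reports delivery of the internal pool into adhesions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass
class QuenchSeries:
    """A normalized whole-cell intensity trace around the quench step."""

    time_s: np.ndarray
    normalized_intensity: np.ndarray
    quench_frame: int
    bleach_corrected: bool


@dataclass
class QuenchResult:
    fraction: float
    pre_level: float
    post_level: float
    bleach_rate_per_frame: float
    series: QuenchSeries


def _fit_bleach_rate(trace: np.ndarray) -> float:
    """Per-frame exponential decay rate from a log-linear fit; clipped to
    [0, 1) and to 0 when the fit suggests recovery instead of bleaching."""
    t = np.arange(trace.size, dtype=float)
    pos = trace > 0
    if pos.sum() < 3:
        return 0.0
    slope = np.polyfit(t[pos], np.log(trace[pos]), 1)[0]
    rate = 1.0 - np.exp(slope)
    return float(min(max(rate, 0.0), 0.999))


def quench_fraction(
    trace: np.ndarray,
    quench_frame: int,
    bleach_correct: bool = True,
    settle_frames: int = 3,
    pre_frames: int = 5,
    frame_interval_s: float = 30.0,
) -> QuenchResult:
    """Internalized fraction from one whole-cell intensity trace.

    The pre-quench level is the median of the ``pre_frames`` frames before
    the quench; the post-quench plateau is the median from
    ``quench_frame + settle_frames`` (antibody binding is not
    instantaneous) to the end.  With ``bleach_correct`` the trace is first
    divided by an exponential fitted to the pre-quench segment.  The
    fraction is clipped to [0, 1] and is invariant to global intensity
    scaling.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    if quench_frame < 3 or n - quench_frame < settle_frames + 1:
        raise ValueError("quench_frame too close to either end of the trace")
    rate = 0.0
    corrected = trace.copy()
    if bleach_correct:
        rate = _fit_bleach_rate(trace[:quench_frame])
        corrected = trace / (1.0 - rate) ** np.arange(n)
    pre = float(np.median(corrected[max(quench_frame - pre_frames, 0):quench_frame]))
    post = float(np.median(corrected[quench_frame + settle_frames:]))
    if pre <= 0:
        raise ValueError("non-positive pre-quench level")
    frac = float(np.clip(post / pre, 0.0, 1.0))
    series = QuenchSeries(
        time_s=np.arange(n) * frame_interval_s,
        normalized_intensity=corrected / pre,
        quench_frame=quench_frame,
        bleach_corrected=bleach_correct,
    )
    return QuenchResult(frac, pre, post, rate, series)


def quench_fractions(
    traces: list[np.ndarray], quench_frame: int, **kwargs
) -> tuple[np.ndarray, float, float]:
    """Per-cell internalized fractions plus their mean and sample SD."""
    fracs = np.array(
        [quench_fraction(t, quench_frame, **kwargs).fraction for t in traces]
    )
    sd = float(fracs.std(ddof=1)) if fracs.size > 1 else 0.0
    return fracs, float(fracs.mean()), sd


def _annulus_masks(
    fa_labels: np.ndarray, gap_px: int = 2, width_px: int = 3
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per-FA (region, annulus) index masks.  The annulus is a
    ``width_px``-wide ring starting ``gap_px`` outside the label and
    excludes every FA pixel."""
    labels = np.asarray(fa_labels)
    all_fas = labels > 0
    out = {}
    for lab in np.unique(labels[all_fas]):
        region = labels == lab
        inner = ndimage.binary_dilation(region, iterations=gap_px)
        outer = ndimage.binary_dilation(region, iterations=gap_px + width_px)
        annulus = outer & ~inner & ~all_fas
        out[int(lab)] = (region, annulus)
    return out


@dataclass
class FARatioSeries:
    fa_id: int
    time_s: np.ndarray
    channel_a: np.ndarray  # background-subtracted mean, surface label
    channel_b: np.ndarray  # background-subtracted mean, internal-pool label
    ratio: np.ndarray  # B/A, NaN where A is at or below the noise floor

    @property
    def fold_change(self) -> np.ndarray:
        return self.ratio / self.ratio[0]


def fa_ratio_timecourse(
    movie_a: np.ndarray,
    movie_b: np.ndarray,
    fa_labels: np.ndarray,
    background_annulus_px: int = 3,
    annulus_gap_px: int = 2,
    noise_floor: float = 0.0,
    frame_interval_s: float = 60.0,
) -> tuple[list[FARatioSeries], pd.DataFrame]:
    """Per-FA B/A intensity ratios over time.

    For each FA label and frame, the mean intensity inside the label minus
    the median of the surrounding annulus gives the background-subtracted
    signal in each channel; the ratio is B/A, undefined (NaN) where the A
    signal does not exceed ``noise_floor``.  Also returns the population
    mean +/- SD of the ratio per timepoint.
    """
    if movie_a.shape != movie_b.shape:
        raise ValueError("channel movies must be co-registered and equal length")
    if not (np.asarray(fa_labels) > 0).any():
        raise ValueError("no FA labels")
    masks = _annulus_masks(fa_labels, annulus_gap_px, background_annulus_px)
    n_frames = movie_a.shape[0]
    time_s = np.arange(n_frames) * frame_interval_s
    series = []
    for lab, (region, annulus) in masks.items():
        a = np.empty(n_frames)
        b = np.empty(n_frames)
        for t in range(n_frames):
            bg_a = np.median(movie_a[t][annulus]) if annulus.any() else 0.0
            bg_b = np.median(movie_b[t][annulus]) if annulus.any() else 0.0
            a[t] = movie_a[t][region].mean() - bg_a
            b[t] = movie_b[t][region].mean() - bg_b
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(a > noise_floor, b / a, np.nan)
        series.append(FARatioSeries(lab, time_s, a, b, ratio))
    stack = np.vstack([s.ratio for s in series])
    n = np.sum(np.isfinite(stack), axis=0)
    summary = pd.DataFrame(
        {
            "time_s": time_s,
            "ratio_mean": np.nanmean(stack, axis=0),
            "ratio_sd": np.where(n > 1, np.nanstd(stack, axis=0, ddof=1), 0.0),
            "n_fas": n,
        }
    )
    return series, summary


@dataclass(frozen=True)
class ActivationInputs:
    """Extracted geometric-mean fluorescence intensities for the
    activation index: ligand binding (F), binding under inhibitor (F0),
    and normalized integrin surface level (F_integrin)."""

    F: float
    F0: float
    F_integrin: float

    def __post_init__(self) -> None:
        if self.F_integrin <= 0:
            raise ValueError("F_integrin must be > 0")
        if self.F < 0 or self.F0 < 0:
            raise ValueError("fluorescence intensities must be >= 0")


def activation_index(inputs: ActivationInputs) -> float:
    """AI = (F - F0) / F_integrin: specific ligand binding normalized to
    integrin surface expression.  Negative values (F < F0) are reported,
    not clipped."""
    return (inputs.F - inputs.F0) / inputs.F_integrin


def activation_index_table(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the activation index to a (sample, F, F0, F_integrin) table."""
    out = table.copy()
    out["AI"] = [
        activation_index(ActivationInputs(r.F, r.F0, r.F_integrin))
        for r in table.itertuples()
    ]
    return out[["sample", "AI"]] if "sample" in out.columns else out[["AI"]]
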