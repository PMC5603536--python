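"""Self-contained benchmark scenarios on synthetic ground truth.

Each function builds its own inputs with the generator, runs the relevant
part of the analysis and returns the measured quantities.  They define
the package's reference study conditions: the default detection movie
(256 x 256 px, 300 frames at 6 fps, 100 pre-bleach frames, 30 events with
peak SNR 5-8), decoy movies of docked or laterally moving vesicles, a
five-cell FA-targeted cohort against its own CSR null, and closed-loop
recoveries of the generator's diffusion coefficient and internalized
fraction.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .detection import classify_all, detect_candidates
from .evaluation import match_events
from .pipeline import RunConfig, run_pipeline
from .pools import quench_fraction
from .spatial import (
    mean_csr_distance_quadrature,
    nearest_fa_distance,
    simulate_csr,
)
from .synth import (
    FAFieldSpec,
    GroundTruthEvent,
    MovieConfig,
    make_cell_and_fa_masks,
    make_quench_series,
    render_movie,
    simulate_cell,
)


def _spawn(seed: int, n: int) -> list[int]:
    return [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n)
    ]


def detection_benchmark(seed: int = 0) -> dict:
    """Candidate recall/precision on the default synthetic movie
    (Hungarian matching within 3 px and +/-2 frames)."""
    sim = simulate_cell(config=MovieConfig(seed=seed), n_events=30,
                        placement_mode="csr", seed=seed)
    pb = sim["config"].photobleach_frame
    cands = detect_candidates(sim["movie"], sim["cell"], photobleach_frame=pb)
    import pandas as pd

    cand_df = pd.DataFrame(
        [{"row_px": c.row_px, "col_px": c.col_px, "t0_frame": c.t0_frame}
         for c in cands]
    )
    match = match_events(sim["truth"], cand_df)
    return {"recall": match.recall, "precision": match.precision,
            "n_candidates": len(cands), "n_truth": len(sim["truth"])}


def decoy_specificity(kind: str, seed: int = 0, n_events: int = 30) -> dict:
    """Fraction of classified candidates accepted on a movie containing
    only docked (D=0) or moving decoy vesicles."""
    sim = simulate_cell(config=MovieConfig(seed=seed), n_events=n_events,
                        placement_mode="csr", event_kind=kind, seed=seed)
    pb = sim["config"].photobleach_frame
    cands = detect_candidates(sim["movie"], sim["cell"], photobleach_frame=pb)
    events = classify_all(cands, sim["movie"], sim["cell"],
                          photobleach_frame=pb)
    n_acc = sum(e.accepted for e in events)
    return {"acceptance_rate": n_acc / len(events) if events else 0.0,
            "n_candidates": len(events), "n_accepted": n_acc}


def diffusion_recovery_noiseless(seed: int = 0, d_true: float = 0.05) -> float:
    """Slope of refitted sigma^2(t) over 2D for one noiseless event."""
    from .detection import fit_gaussian_spot

    cfg = MovieConfig(n_frames=36, height_px=64, width_px=64,
                      photobleach_frame=4, poisson_noise=False,
                      read_noise_sd=0.0, seed=seed)
    cell = np.ones((64, 64), bool)
    fas = np.zeros((64, 64), bool)
    ev = GroundTruthEvent(0, 31.35, 32.55, 8, amplitude=4000.0,
                          diffusion_um2_per_s=d_true)
    movie, _ = render_movie(cfg, [ev], cell, fas)
    ks = np.arange(0, 16)
    sig2 = []
    for k in ks:
        fit = fit_gaussian_spot(movie[ev.t0_frame + k], (31, 33), 15)
        sig2.append((fit.sigma_px * cfg.pixel_size_um) ** 2)
    slope = np.polyfit(ks * cfg.frame_interval_s, sig2, 1)[0]
    return float(slope / (2 * d_true))


def diffusion_recovery_noisy(seed: int = 0, d_true: float = 0.05,
                             n_events: int = 50) -> float:
    """Slope recovery with shot noise, averaging the pixel data of
    ``n_events`` replicate events before refitting."""
    from .detection import fit_gaussian_spot
    from .synth import default_event_amplitude

    base = MovieConfig(n_frames=30, height_px=48, width_px=48,
                       photobleach_frame=2, poisson_noise=True,
                       read_noise_sd=3.0)
    cell = np.ones((48, 48), bool)
    fas = np.zeros((48, 48), bool)
    rng = np.random.default_rng(seed)
    amp = lambda: default_event_amplitude(base, 0.15, rng.uniform(5.0, 8.0))
    stack = None
    for s in _spawn(seed, n_events):
        cfg = dataclasses.replace(base, seed=s)
        ev = GroundTruthEvent(0, 23.35, 24.55, 5, amplitude=amp(),
                              diffusion_um2_per_s=d_true)
        movie, _ = render_movie(cfg, [ev], cell, fas, seed=s)
        win = movie[5:21].astype(float)
        stack = win if stack is None else stack + win
    mean = stack / n_events
    ks = np.arange(16)
    sig2 = []
    for k in ks:
        fit = fit_gaussian_spot(mean[k], (23, 25), 15)
        if fit.fit_ok:
            sig2.append((k, (fit.sigma_px * base.pixel_size_um) ** 2))
    a = np.array(sig2)
    slope = np.polyfit(a[:, 0] * base.frame_interval_s, a[:, 1], 1)[0]
    return float(slope / (2 * d_true))


FA_COHORT_FLAT = {
    "mode": "simulate",
    "n_cells": 5,
    "n_events": 18,
    "placement_mode": "fa_proximal",
    "decay_um": 0.2,
    "n_reps": 100,
    "n_frames": 220,
    "height_px": 192,
    "width_px": 192,
    "photobleach_frame": 40,
}


def fa_targeting_cohort(seed: int = 0, out_dir=None) -> dict:
    """Five FA-directed cells against their own CSR nulls, end to end
    through the pipeline (detection included)."""
    import tempfile

    cfg = RunConfig.from_flat({**FA_COHORT_FLAT, "seed": seed})
    if out_dir is None:
        with tempfile.TemporaryDirectory() as tmp:
            summary = run_pipeline(cfg, tmp)
    else:
        summary = run_pipeline(cfg, out_dir)
    cells = [c for c in summary["cells"] if c.get("spatial_status") == "ok"]
    n_closer = sum(
        c["observed_median_um"] < c["simulated_mean_median_um"] for c in cells
    )
    return {
        "n_cells": len(cells),
        "n_cells_observed_closer": n_closer,
        "observed_mean_median_um":
            summary["group_comparison"]["observed_mean_median_um"],
        "simulated_mean_median_um":
            summary["group_comparison"]["simulated_mean_median_um"],
        "p_value": summary["group_comparison"]["p_value"],
    }


def csr_disc_benchmark(seed: int = 0, n_rank_draws: int = 150) -> dict:
    """CSR null on a disc cell (radius 20 um) with 10 FAs: pooled mean
    distance vs the dense-grid quadrature oracle, and uniformity of the
    rank of a CSR-drawn 'observed' median among simulated medians."""
    px = 0.189
    radius = int(20 / px)
    h = w = 2 * radius + 12
    rr, cc = np.mgrid[0:h, 0:w]
    cell = (rr - h // 2) ** 2 + (cc - w // 2) ** 2 <= radius**2
    cfg = MovieConfig(height_px=h, width_px=w)
    seeds = _spawn(seed, 3 + n_rank_draws)
    _, fas, _ = make_cell_and_fa_masks(FAFieldSpec(n_fas=10), cfg,
                                       seed=seeds[0])
    fas &= cell

    res = simulate_csr(50, cell, fas, px, n_reps=100, seed=seeds[1])
    pooled = res.pooled
    quad = mean_csr_distance_quadrature(cell, fas, px)
    se = pooled.std(ddof=1) / np.sqrt(pooled.size)

    rows, cols = np.nonzero(cell)
    ranks = []
    n_reps = 50
    for s in seeds[3:]:
        rng = np.random.default_rng(s)
        idx = rng.integers(rows.size, size=20)
        pts = np.column_stack([rows[idx], cols[idx]]) + rng.uniform(
            -0.5, 0.5, size=(20, 2)
        )
        obs_med = float(np.median(
            nearest_fa_distance(pts, fas, px)["nearest_fa_distance_um"]
        ))
        sim = simulate_csr(20, cell, fas, px, n_reps=n_reps, seed=s + 1)
        ranks.append(int(np.sum(sim.per_rep_medians < obs_med)))
    bins = np.histogram(np.asarray(ranks) / (n_reps + 1), bins=10,
                        range=(0, 1))[0]
    rank_p = float(stats.chisquare(bins).pvalue)
    return {
        "mean_distance_um": float(pooled.mean()),
        "quadrature_mean_um": quad,
        "mc_se_um": float(se),
        "abs_error_in_se_units": float(abs(pooled.mean() - quad) / se),
        "rank_uniformity_p": rank_p,
    }


def quench_benchmark(seed: int = 0, internal_fraction: float = 0.25) -> float:
    """Recovered internalized fraction from a bleaching, noisy quench
    series (bleach correction on)."""
    _, trace, _ = make_quench_series(
        n_frames=100, quench_frame=80, internal_fraction=internal_fraction,
        bleach_rate=0.002, noise_sd=0.005, seed=seed,
    )
    return quench_fraction(trace, 80, bleach_correct=True).fraction


def dual_label_benchmark(seed: int = 0, fold_change: float = 2.5) -> float:
    """Measured end-of-series SiR647/Alexa488 fold change on a synthetic
    linear-ramp pair."""
    from .pools import fa_ratio_timecourse
    from .synth import make_dual_label_movies

    cfg = MovieConfig(height_px=160, width_px=160)
    _, _, labels = make_cell_and_fa_masks(FAFieldSpec(n_fas=8), cfg, seed=seed)
    movie_a, movie_b = make_dual_label_movies(
        labels, n_frames=12, fold_change_b=fold_change, noise_sd=2.0, seed=seed
    )
    series, _ = fa_ratio_timecourse(movie_a, movie_b, labels)
    return float(np.mean([s.fold_change[-1] for s in series]))
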