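"""End-to-end orchestration: simulate (or load) movies, segment, detect,
classify, run the CSR spatial analysis, and write a reproducible report
bundle.

Outputs under the chosen directory, per cell (cell_00, cell_01, ...):
fa_mask.tif, cell_mask.tif, fa_labels.tif, candidates.csv, events.csv,
aligned_profile.csv, distances.csv, csr_sims.csv and, in simulate mode,
ground_truth.csv and detection_performance.csv.  A top-level summary.json
carries per-cell medians, the group t-test, event counts, the resolved
parameters, the seed and the package version; identical config + seed
give a byte-identical summary.json.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .detection import (
    ClassifyCriteria,
    align_events,
    classify_all,
    detect_candidates,
    events_to_frame,
)
from .evaluation import match_events
from .io import (
    read_mask,
    read_movie,
    read_polygon_csv,
    write_flat_config,
    write_labels,
    write_mask,
    write_movie,
)
from .segmentation import segment_cell_footprint, segment_fas
from .spatial import (
    compare_median_distances,
    cumulative_frequency,
    nearest_fa_distance,
    simulate_csr,
)
from .synth import FAFieldSpec, MovieConfig, simulate_cell

log = logging.getLogger("tirfex")


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run (one flat config file)."""

    mode: str = "simulate"
    seed: int = 0
    # simulate mode
    n_cells: int = 1
    n_events: int = 30
    placement_mode: str = "fa_proximal"
    decay_um: float = 0.2
    write_movies: bool = False
    # analyze mode inputs
    movie_path: str | None = None
    reference_path: str | None = None
    cell_mask_path: str | None = None
    cell_polygon_path: str | None = None
    # detection
    rise_sigma_factor: float = 5.0
    min_separation_px: int = 5
    refractory_frames: int = 10
    # spatial
    n_reps: int = 100
    cdf_grid_max_um: float = 10.0
    cdf_grid_step_um: float = 0.1
    # segmentation
    min_area_px: int = 8
    movie: MovieConfig = field(default_factory=MovieConfig)
    fa_spec: FAFieldSpec = field(default_factory=FAFieldSpec)
    criteria: ClassifyCriteria = field(default_factory=ClassifyCriteria)

    @classmethod
    def from_flat(cls, flat: dict) -> "RunConfig":
        """Build from a flat mapping; keys are routed to the matching
        sub-config by field name.  Unknown keys raise."""
        own = {f.name for f in dataclasses.fields(cls)} - {
            "movie", "fa_spec", "criteria"
        }
        groups: dict[str, dict] = {"own": {}, "movie": {}, "fa": {}, "crit": {}}
        movie_f = {f.name for f in dataclasses.fields(MovieConfig)}
        fa_f = {f.name for f in dataclasses.fields(FAFieldSpec)}
        crit_f = {f.name for f in dataclasses.fields(ClassifyCriteria)}
        for key, val in flat.items():
            if key in own:
                groups["own"][key] = val
            elif key in movie_f:
                groups["movie"][key] = val
            elif key in fa_f:
                groups["fa"][key] = tuple(val) if isinstance(val, list) else val
            elif key in crit_f:
                groups["crit"][key] = val
            else:
                raise KeyError(f"unknown config key {key!r}")
        return cls(
            movie=MovieConfig(**groups["movie"]),
            fa_spec=FAFieldSpec(**groups["fa"]),
            criteria=ClassifyCriteria(**groups["crit"]),
            **groups["own"],
        )

    def to_flat(self) -> dict:
        flat = {}
        for f in dataclasses.fields(self):
            val = getattr(self, f.name)
            if dataclasses.is_dataclass(val):
                for sub in dataclasses.fields(val):
                    sv = getattr(val, sub.name)
                    flat[sub.name] = list(sv) if isinstance(sv, tuple) else sv
            else:
                flat[f.name] = val
        return flat

    def config_hash(self) -> str:
        blob = json.dumps(self.to_flat(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage


def _analyze_one_cell(
    config: RunConfig,
    movie: np.ndarray,
    cell: np.ndarray,
    out: Path,
    truth: pd.DataFrame | None,
) -> dict:
    """Segmentation -> detection -> classification -> spatial stats for
    one movie; writes the per-cell bundle and returns its summary dict."""
    out.mkdir(parents=True, exist_ok=True)
    mc = config.movie
    pb = mc.photobleach_frame
    t0 = time.perf_counter()

    reference = movie[:pb].mean(axis=0) if pb > 0 else movie[0].astype(float)
    fa_labels, fa_mask = segment_fas(
        reference, min_area_px=config.min_area_px, cell_mask=cell
    )
    if not fa_mask.any():
        raise PipelineError("segmentation", ValueError("no FAs found"))
    write_mask(out / "cell_mask.tif", cell)
    write_mask(out / "fa_mask.tif", fa_mask)
    write_labels(out / "fa_labels.tif", fa_labels)
    log.info("segmentation: %d FAs (%.2fs)", fa_labels.max(), time.perf_counter() - t0)

    candidates = detect_candidates(
        movie, cell, photobleach_frame=pb,
        rise_sigma_factor=config.rise_sigma_factor,
        min_separation_px=config.min_separation_px,
        refractory_frames=config.refractory_frames,
    )
    cand_df = pd.DataFrame(
        [
            {"row_px": c.row_px, "col_px": c.col_px, "t0_frame": c.t0_frame,
             "peak_delta": c.peak_delta}
            for c in candidates
        ],
        columns=["row_px", "col_px", "t0_frame", "peak_delta"],
    )
    cand_df.to_csv(out / "candidates.csv", index=False)

    events = classify_all(
        candidates, movie, cell, config.criteria,
        pixel_size_um=mc.pixel_size_um, photobleach_frame=pb,
    )
    events_df = events_to_frame(events)
    events_df.to_csv(out / "events.csv", index=False)
    accepted = [e for e in events if e.accepted]
    log.info("detection: %d candidates, %d accepted", len(candidates), len(accepted))

    cell_summary: dict = {
        "n_candidates": len(candidates),
        "n_accepted": len(accepted),
        "n_fas": int(fa_labels.max()),
    }

    if truth is not None:
        truth.to_csv(out / "ground_truth.csv", index=False)
        match = match_events(truth, cand_df)
        match.to_frame().to_csv(out / "detection_performance.csv", index=False)
        cell_summary["candidate_recall"] = match.recall
        cell_summary["candidate_precision"] = match.precision

    if not accepted:
        cell_summary["spatial_status"] = "no_events"
        return cell_summary

    try:
        profile = align_events(
            accepted,
            pre_frames=min(config.criteria.pre_frames, 5),
            post_frames=config.criteria.spread_window_frames - 1,
            frame_interval_s=mc.frame_interval_s,
        )
        profile.to_frame().to_csv(out / "aligned_profile.csv", index=False)
    except ValueError:
        pass  # no event covers the alignment window; profile omitted

    points = np.array([[e.row_px, e.col_px] for e in accepted])
    dist = nearest_fa_distance(points, fa_mask, mc.pixel_size_um,
                               event_ids=[e.event_id for e in accepted])
    dist.to_csv(out / "distances.csv", index=False)
    csr = simulate_csr(
        len(accepted), cell, fa_mask, mc.pixel_size_um,
        n_reps=config.n_reps, seed=config.seed + 7919,
    )
    csr.to_frame().to_csv(out / "csr_sims.csv", index=False)

    grid = np.arange(0.0, config.cdf_grid_max_um + config.cdf_grid_step_um,
                     config.cdf_grid_step_um)
    obs_d = dist["nearest_fa_distance_um"].to_numpy()
    pd.DataFrame(
        {
            "distance_um": grid,
            "observed_cdf": cumulative_frequency(obs_d, grid),
            "simulated_cdf": cumulative_frequency(csr.pooled, grid),
        }
    ).to_csv(out / "cdf.csv", index=False)

    cell_summary.update(
        {
            "spatial_status": "ok",
            "observed_median_um": float(np.median(obs_d)),
            "simulated_mean_median_um": csr.mean_median_um,
        }
    )
    return cell_summary


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the full pipeline and write the report bundle; returns the
    summary dict (also written as summary.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_flat_config(out / "config.yaml", config.to_flat())

    per_cell: list[dict] = []
    try:
        if config.mode == "simulate":
            cell_seeds = [
                int(s.generate_state(1)[0] % (2**31))
                for s in np.random.SeedSequence(config.seed).spawn(config.n_cells)
            ]
            for i, cseed in enumerate(cell_seeds):
                sim = simulate_cell(
                    config=dataclasses.replace(config.movie, seed=cseed),
                    fa_spec=config.fa_spec,
                    n_events=config.n_events,
                    placement_mode=config.placement_mode,
                    decay_um=config.decay_um,
                    seed=cseed,
                )
                cell_out = out / f"cell_{i:02d}"
                if config.write_movies:
                    cell_out.mkdir(parents=True, exist_ok=True)
                    write_movie(cell_out / "movie.tif", sim["movie"])
                summary = _analyze_one_cell(
                    dataclasses.replace(config, seed=cseed),
                    sim["movie"], sim["cell"], cell_out, sim["truth"],
                )
                summary["cell"] = i
                per_cell.append(summary)
        elif config.mode == "analyze":
            movie = read_movie(config.movie_path)
            if config.cell_mask_path:
                cell = read_mask(config.cell_mask_path)
            elif config.cell_polygon_path:
                cell = segment_cell_footprint(
                    polygon_vertices=read_polygon_csv(config.cell_polygon_path),
                    reference_frame=movie[0],
                    pixel_size_um=config.movie.pixel_size_um,
                ).pixels
            else:
                ref = (
                    read_movie(config.reference_path)[0]
                    if config.reference_path
                    else movie[: max(config.movie.photobleach_frame, 1)].mean(axis=0)
                )
                cell = segment_cell_footprint(
                    reference_frame=ref,
                    pixel_size_um=config.movie.pixel_size_um,
                ).pixels
            summary = _analyze_one_cell(config, movie, cell, out / "cell_00", None)
            summary["cell"] = 0
            per_cell.append(summary)
        else:
            raise ValueError(f"unknown mode {config.mode!r}")
    except PipelineError:
        raise
    except Exception as exc:  # annotate the failing stage for the CLI
        raise PipelineError("pipeline", exc) from exc

    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "mode": config.mode,
        "parameters": config.to_flat(),
        "cells": per_cell,
    }
    obs = [c["observed_median_um"] for c in per_cell if c.get("spatial_status") == "ok"]
    sim = [
        c["simulated_mean_median_um"]
        for c in per_cell
        if c.get("spatial_status") == "ok"
    ]
    if not obs:
        summary["spatial_status"] = "no_events"
    elif len(obs) >= 2:
        comp = compare_median_distances(obs, sim)
        summary["spatial_status"] = "ok"
        summary["group_comparison"] = {
            "observed_mean_median_um": comp.observed_mean_um,
            "observed_sd_um": comp.observed_sd_um,
            "simulated_mean_median_um": comp.simulated_mean_um,
            "simulated_sd_um": comp.simulated_sd_um,
            "t_statistic": comp.t_statistic,
            "df": comp.df,
            "p_value": comp.p_value,
        }
    else:
        summary["spatial_status"] = "single_cell"
        summary["group_comparison"] = None

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def generate_report(out_dir) -> list[Path]:
    """Regenerate plots from a previously written bundle (convenience)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    written = []
    for cell_dir in sorted(out.glob("cell_*")):
        cdf_path = cell_dir / "cdf.csv"
        if cdf_path.exists():
            cdf = pd.read_csv(cdf_path)
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.plot(cdf.distance_um, cdf.observed_cdf, label="observed")
            ax.plot(cdf.distance_um, cdf.simulated_cdf, label="CSR simulation")
            ax.set_xlabel("distance to nearest FA (um)")
            ax.set_ylabel("cumulative frequency")
            ax.legend()
            fig.tight_layout()
            fig.savefig(cell_dir / "cdf.png", dpi=120)
            plt.close(fig)
            written.append(cell_dir / "cdf.png")
        prof_path = cell_dir / "aligned_profile.csv"
        if prof_path.exists():
            prof = pd.read_csv(prof_path)
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.errorbar(prof.offset_s, prof.amplitude_mean, yerr=prof.amplitude_sem)
            ax.set_xlabel("time from fusion (s)")
            ax.set_ylabel("integrated intensity (a.u.)")
            fig.tight_layout()
            fig.savefig(cell_dir / "aligned_profile.png", dpi=120)
            plt.close(fig)
            written.append(cell_dir / "aligned_profile.png")
    return written
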