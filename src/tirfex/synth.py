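"""Synthetic TIRFM movies with known ground truth.

Emulates the optical structure of a photobleach-then-watch pHluorin
exocytosis experiment: a cell footprint with elongated high-intensity
focal-adhesion (FA) regions, quenched vesicles that de-acidify at a fusion
frame (sudden appearance of a 2D Gaussian spot) and then spread laterally
by free diffusion with conserved integrated intensity, plus Poisson shot
noise, Gaussian read noise and exponential photobleaching.

Coordinates are (row, col), 0-based, with pixel centers at integer
coordinates; pixel (i, j) covers [i-0.5, i+0.5) x [j-0.5, j+0.5).
Time is a 0-based frame index; physical time = frame * frame_interval_s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage


class PlacementError(RuntimeError):
    """Requested FA geometry cannot be placed inside the cell footprint."""


@dataclass(frozen=True)
class MovieConfig:
    """Acquisition and scene constants for a synthetic movie.

    Defaults mirror the live-cell TIRFM protocol the analysis targets:
    189 nm pixels, 6 frames/s, and a pre-bleach reference segment
    (frames [0, photobleach_frame)) in which FA fluorescence is shown at
    full intensity before the surface pool is photobleached.
    """

    n_frames: int = 300
    height_px: int = 256
    width_px: int = 256
    pixel_size_um: float = 0.189
    frame_interval_s: float = 1.0 / 6.0
    background_level: float = 200.0
    cell_level_factor: float = 2.0
    photobleach_frame: int = 100
    fa_postbleach_factor: float = 0.05
    bleach_rate_per_frame: float = 0.0
    poisson_noise: bool = True
    read_noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.height_px < 8 or self.width_px < 8:
            raise ValueError("frame must be at least 8x8 px")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if not 0.0 <= self.bleach_rate_per_frame < 1.0:
            raise ValueError("bleach_rate_per_frame must be in [0, 1)")
        if not 0 <= self.photobleach_frame <= self.n_frames:
            raise ValueError("photobleach_frame must be in [0, n_frames]")


@dataclass(frozen=True)
class FAFieldSpec:
    """Geometry of the synthetic focal-adhesion field.

    FAs are filled ellipses with long axes length_um and short axes
    width_um (each drawn uniformly from its range), oriented at
    orientation_rad +/- orientation_jitter_rad (orientation_rad=None
    draws orientations uniformly). fa_intensity multiplies the
    background level inside FA pixels on pre-bleach frames.
    """

    n_fas: int = 10
    length_um: tuple[float, float] = (1.2, 3.0)
    width_um: tuple[float, float] = (0.4, 0.8)
    orientation_rad: float | None = None
    orientation_jitter_rad: float = 0.3
    fa_intensity: float = 5.0
    min_edge_margin_px: int = 6

    def __post_init__(self) -> None:
        if self.n_fas < 0:
            raise ValueError("n_fas must be >= 0")
        lo_l, hi_l = self.length_um
        lo_w, hi_w = self.width_um
        if not (0 < lo_w <= hi_w and 0 < lo_l <= hi_l):
            raise ValueError("length/width ranges must be positive and ordered")
        if lo_l < lo_w:
            raise ValueError("length must be >= width")


@dataclass(frozen=True)
class GroundTruthEvent:
    """True parameters of one simulated vesicle appearance.

    Before t0_frame the vesicle contributes nothing (quenched at acidic
    vesicular pH); at t0_frame a 2D Gaussian of integrated intensity
    ``amplitude`` appears at (row_px, col_px) with width sigma0_um, and for
    t > t0 its variance grows as sigma^2(t) = sigma0^2 + 2*D*(t - t0) with
    integrated intensity conserved (then scaled by bleaching).
    diffusion_um2_per_s = 0 with zero velocity models a docked vesicle;
    a nonzero velocity models a moving endosome (classifier decoys).
    """

    event_id: int
    row_px: float
    col_px: float
    t0_frame: int
    amplitude: float
    sigma0_um: float = 0.15
    diffusion_um2_per_s: float = 0.05
    placement_mode: str = "csr"
    vel_row_px_per_frame: float = 0.0
    vel_col_px_per_frame: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.sigma0_um <= 0:
            raise ValueError("sigma0_um must be > 0")
        if self.diffusion_um2_per_s < 0:
            raise ValueError("diffusion coefficient must be >= 0")

    @property
    def kind(self) -> str:
        if abs(self.vel_row_px_per_frame) > 0 or abs(self.vel_col_px_per_frame) > 0:
            return "moving"
        return "fusion" if self.diffusion_um2_per_s > 0 else "docked"


GROUND_TRUTH_COLUMNS = [
    "event_id", "row_px", "col_px", "t0_frame", "amplitude",
    "sigma0_um", "diffusion_um2_per_s", "placement_mode", "kind",
]


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent per-purpose generators from one root seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(n)]


def make_cell_and_fa_masks(
    spec: FAFieldSpec,
    config: MovieConfig,
    seed: int | None = None,
    max_tries_per_fa: int = 500,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate a cell footprint, an FA mask and an FA label image.

    The cell is a filled ellipse with smooth low-order boundary noise,
    strictly inside the frame.  FAs are non-touching filled ellipses fully
    inside the cell and at least ``min_edge_margin_px`` from the frame
    edge, so the labeled mask has exactly ``n_fas`` connected components.

    Returns ``(cell, fas, fa_labels)`` where the masks are boolean H x W
    arrays and fa_labels is int32 with labels 1..n_fas (0 = background).

    Raises PlacementError when an FA cannot be placed after
    ``max_tries_per_fa`` rejections.
    """
    if seed is None:
        seed = config.seed
    rng_cell, rng_fa = _rng_streams(seed, 2)
    h, w = config.height_px, config.width_px

    # Cell: ellipse radius modulated by a few random Fourier modes.
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    amp = rng_cell.normal(0.0, 0.03, size=4)
    phase = rng_cell.uniform(0, 2 * np.pi, size=4)
    max_pert = 1.0 + np.abs(amp).sum()
    ay = (h / 2.0 - 3.0) / max_pert
    ax = (w / 2.0 - 3.0) / max_pert
    rr, cc = np.mgrid[0:h, 0:w]
    u = (rr - cy) / ay
    v = (cc - cx) / ax
    rho = np.hypot(u, v)
    theta = np.arctan2(u, v)
    bound = 1.0
    for k, (a, p) in enumerate(zip(amp, phase), start=2):
        bound = bound + a * np.cos(k * theta + p)
    cell = rho <= bound
    cell = ndimage.binary_fill_holes(cell)

    fas = np.zeros((h, w), dtype=bool)
    fa_labels = np.zeros((h, w), dtype=np.int32)
    if spec.n_fas == 0:
        return cell, fas, fa_labels

    # Interior region where an FA center may fall: inside the cell, away
    # from the frame edge.
    margin = spec.min_edge_margin_px
    interior = cell.copy()
    interior[:margin, :] = False
    interior[-margin:, :] = False
    interior[:, :margin] = False
    interior[:, -margin:] = False
    cand_rows, cand_cols = np.nonzero(interior)
    if cand_rows.size == 0:
        raise PlacementError("cell interior too small for requested margin")

    # Occupancy dilated by one pixel keeps placed FAs 8-disconnected.
    struct = np.ones((3, 3), dtype=bool)
    blocked = np.zeros((h, w), dtype=bool)
    px = config.pixel_size_um

    for label in range(1, spec.n_fas + 1):
        placed = False
        for _ in range(max_tries_per_fa):
            i = rng_fa.integers(cand_rows.size)
            r0, c0 = float(cand_rows[i]), float(cand_cols[i])
            length = rng_fa.uniform(*spec.length_um) / px
            width = rng_fa.uniform(*spec.width_um) / px
            if spec.orientation_rad is None:
                ang = rng_fa.uniform(0, np.pi)
            else:
                ang = spec.orientation_rad + rng_fa.normal(
                    0.0, spec.orientation_jitter_rad
                )
            half = int(np.ceil(length / 2)) + 1
            rlo, rhi = int(r0) - half, int(r0) + half + 1
            clo, chi = int(c0) - half, int(c0) + half + 1
            if rlo < 0 or clo < 0 or rhi > h or chi > w:
                continue
            yy, xx = np.mgrid[rlo:rhi, clo:chi]
            dy, dx = yy - r0, xx - c0
            lon = dy * np.sin(ang) + dx * np.cos(ang)
            lat = dy * np.cos(ang) - dx * np.sin(ang)
            ell = (lon / (length / 2)) ** 2 + (lat / (width / 2)) ** 2 <= 1.0
            if not ell.any():
                continue
            patch_cell = cell[rlo:rhi, clo:chi]
            patch_blocked = blocked[rlo:rhi, clo:chi]
            if (ell & ~patch_cell).any() or (ell & patch_blocked).any():
                continue
            fas[rlo:rhi, clo:chi] |= ell
            fa_labels[rlo:rhi, clo:chi][ell] = label
            blocked |= ndimage.binary_dilation(fas, structure=struct)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place FA {label}/{spec.n_fas} after "
                f"{max_tries_per_fa} tries"
            )
    return cell, fas, fa_labels


def sample_event_locations(
    mode: str,
    n_events: int,
    cell: np.ndarray,
    fas: np.ndarray | None = None,
    decay_um: float = 0.2,
    pixel_size_um: float = 0.189,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample subpixel event locations inside the cell footprint.

    mode="csr": uniform over cell pixels with uniform subpixel jitter
    (complete spatial randomness within the footprint).

    mode="fa_proximal": nearest-FA distances follow an exponential with
    scale ``decay_um``, truncated to the distances attainable inside the
    cell: a target distance d ~ Exp(decay_um) is drawn, then a pixel is
    chosen uniformly among cell pixels whose FA distance lies within half
    a pixel of d (redrawing when d exceeds the attainable range).
    decay_um = 0 places every event on the FA mask.

    Returns an (n_events, 2) float array of (row, col) coordinates.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if not cell.any():
        raise ValueError("cell mask is empty")
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    rows, cols = np.nonzero(cell)
    if mode == "csr":
        idx = rng.integers(rows.size, size=n_events)
        jitter = rng.uniform(-0.5, 0.5, size=(n_events, 2))
        return np.column_stack([rows[idx], cols[idx]]).astype(float) + jitter
    if mode != "fa_proximal":
        raise ValueError(f"unknown placement mode {mode!r}")
    if fas is None or not fas.any():
        raise ValueError("fa_proximal placement requires a non-empty FA mask")
    if decay_um < 0:
        raise ValueError("decay_um must be >= 0")

    edt_px = ndimage.distance_transform_edt(~fas)
    d_cell = edt_px[rows, cols]
    order = np.argsort(d_cell, kind="stable")
    d_sorted = d_cell[order]
    rows_s, cols_s = rows[order], cols[order]
    d_max = d_sorted[-1]
    decay_px = decay_um / pixel_size_um

    out = np.empty((n_events, 2), dtype=float)
    k = 0
    while k < n_events:
        d = 0.0 if decay_px == 0 else rng.exponential(decay_px)
        if d > d_max + 0.5:
            continue  # truncated to the cell
        lo = np.searchsorted(d_sorted, d - 0.5, side="left")
        hi = np.searchsorted(d_sorted, d + 0.5, side="right")
        if hi <= lo:
            continue
        j = lo + rng.integers(hi - lo)
        jit = rng.uniform(-0.5, 0.5, size=2)
        out[k] = (rows_s[j] + jit[0], cols_s[j] + jit[1])
        k += 1
    return out


def event_sigma_um(event: GroundTruthEvent, t_frame: int, config: MovieConfig) -> float:
    """Gaussian width at frame t: sigma^2 = sigma0^2 + 2 D (t - t0)."""
    dt = (t_frame - event.t0_frame) * config.frame_interval_s
    return float(np.sqrt(event.sigma0_um**2 + 2.0 * event.diffusion_um2_per_s * max(dt, 0.0)))


def _add_gaussian(frame: np.ndarray, r0: float, c0: float,
                  sigma_px: float, total: float) -> None:
    """Add a 2D Gaussian of integrated intensity ``total`` in place."""
    h, w = frame.shape
    half = int(np.ceil(6 * sigma_px)) + 2
    rlo = max(int(round(r0)) - half, 0)
    rhi = min(int(round(r0)) + half + 1, h)
    clo = max(int(round(c0)) - half, 0)
    chi = min(int(round(c0)) + half + 1, w)
    if rlo >= rhi or clo >= chi:
        return
    yy, xx = np.mgrid[rlo:rhi, clo:chi]
    g = np.exp(-(((yy - r0) ** 2 + (xx - c0) ** 2) / (2.0 * sigma_px**2)))
    frame[rlo:rhi, clo:chi] += total / (2.0 * np.pi * sigma_px**2) * g


def static_scene(config: MovieConfig, cell: np.ndarray, fas: np.ndarray,
                 fa_intensity: float, prebleach: bool) -> np.ndarray:
    """Noiseless background + cell + FA image (no events)."""
    bg = config.background_level
    scene = np.full(cell.shape, bg, dtype=float)
    scene[cell] = bg * config.cell_level_factor
    fa_level = bg * fa_intensity
    if not prebleach:
        cell_level = bg * config.cell_level_factor
        fa_level = cell_level + (fa_level - cell_level) * config.fa_postbleach_factor
    scene[fas] = fa_level
    return scene


def render_movie(
    config: MovieConfig,
    events: list[GroundTruthEvent],
    cell: np.ndarray,
    fas: np.ndarray,
    fa_intensity: float = 5.0,
    seed: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a noiseless scene plus events, then apply the noise model.

    Frames before ``config.photobleach_frame`` show the FA signal at full
    intensity (the pre-bleach reference segment); later frames attenuate FA
    contrast by ``fa_postbleach_factor``, mirroring the bleach-then-watch
    protocol.  Each event appears at its t0 as a sampled 2D Gaussian whose
    integrated intensity equals ``amplitude`` (conserved while the width
    grows, then scaled by (1 - bleach_rate)^(t - t0)).  Poisson shot noise
    is applied per pixel around the noiseless value, then Gaussian read
    noise is added.

    Returns the float32 movie (T x H x W) and the ground-truth table.
    """
    for ev in events:
        if not 0 <= ev.t0_frame < config.n_frames:
            raise ValueError(f"event {ev.event_id}: t0 outside movie")
        r, c = int(round(ev.row_px)), int(round(ev.col_px))
        if not (0 <= r < config.height_px and 0 <= c < config.width_px):
            raise ValueError(f"event {ev.event_id}: location outside frame")

    if seed is None:
        seed = config.seed
    (rng_noise,) = _rng_streams(seed, 1)
    pre = static_scene(config, cell, fas, fa_intensity, prebleach=True)
    post = static_scene(config, cell, fas, fa_intensity, prebleach=False)

    movie = np.empty((config.n_frames, *cell.shape), dtype=np.float64)
    bleach = 1.0 - config.bleach_rate_per_frame
    for t in range(config.n_frames):
        frame = (pre if t < config.photobleach_frame else post).copy()
        for ev in events:
            if t < ev.t0_frame:
                continue
            sigma_px = event_sigma_um(ev, t, config) / config.pixel_size_um
            total = ev.amplitude * bleach ** (t - ev.t0_frame)
            dt = t - ev.t0_frame
            r0 = ev.row_px + ev.vel_row_px_per_frame * dt
            c0 = ev.col_px + ev.vel_col_px_per_frame * dt
            _add_gaussian(frame, r0, c0, sigma_px, total)
        movie[t] = frame

    if config.poisson_noise:
        movie = rng_noise.poisson(movie).astype(np.float64)
    if config.read_noise_sd > 0:
        movie = movie + rng_noise.normal(0.0, config.read_noise_sd, size=movie.shape)

    truth = pd.DataFrame(
        [
            {
                "event_id": ev.event_id,
                "row_px": ev.row_px,
                "col_px": ev.col_px,
                "t0_frame": ev.t0_frame,
                "amplitude": ev.amplitude,
                "sigma0_um": ev.sigma0_um,
                "diffusion_um2_per_s": ev.diffusion_um2_per_s,
                "placement_mode": ev.placement_mode,
                "kind": ev.kind,
            }
            for ev in events
        ],
        columns=GROUND_TRUTH_COLUMNS,
    )
    return movie.astype(np.float32), truth


def default_event_amplitude(config: MovieConfig, sigma0_um: float,
                            peak_snr: float) -> float:
    """Integrated intensity giving the requested peak signal-to-noise.

    SNR is defined as the peak pixel increment at fusion divided by the
    single-frame noise SD inside the cell (shot noise at the cell level
    plus read noise in quadrature).
    """
    noise_sd = np.sqrt(
        config.background_level * config.cell_level_factor
        + config.read_noise_sd**2
    )
    sigma_px = sigma0_um / config.pixel_size_um
    return float(peak_snr * noise_sd * 2.0 * np.pi * sigma_px**2)


def simulate_cell(
    config: MovieConfig | None = None,
    fa_spec: FAFieldSpec | None = None,
    n_events: int = 30,
    placement_mode: str = "csr",
    decay_um: float = 0.2,
    sigma0_um: float = 0.15,
    diffusion_um2_per_s: float = 0.05,
    peak_snr_range: tuple[float, float] = (5.0, 8.0),
    event_kind: str = "fusion",
    moving_speed_px_per_frame: float = 1.0,
    t0_margin_frames: int = 8,
    seed: int = 0,
) -> dict:
    """Simulate one cell end to end: masks, events, rendered movie.

    Event fusion times are uniform over the usable post-bleach window and
    peak SNRs are drawn uniformly from ``peak_snr_range``.  ``event_kind``
    selects bona fide fusion events ("fusion"), docked vesicles that
    appear but do not spread ("docked"), or laterally moving vesicles
    ("moving") for classifier specificity tests.

    Returns a dict with keys: config, cell, fas, fa_labels, events,
    movie, truth.
    """
    config = config or MovieConfig(seed=seed)
    fa_spec = fa_spec or FAFieldSpec()
    rng_mask, rng_place, rng_event, rng_noise = [
        int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(4)
    ]
    cell, fas, fa_labels = make_cell_and_fa_masks(fa_spec, config, seed=rng_mask)
    locs = sample_event_locations(
        placement_mode, n_events, cell, fas,
        decay_um=decay_um, pixel_size_um=config.pixel_size_um, seed=rng_place,
    )
    rng = np.random.default_rng(rng_event)
    t_lo = config.photobleach_frame + t0_margin_frames
    t_hi = config.n_frames - t0_margin_frames
    if n_events > 0 and t_hi <= t_lo:
        raise ValueError("movie too short for requested event margins")
    events = []
    for i in range(n_events):
        snr = rng.uniform(*peak_snr_range)
        d = diffusion_um2_per_s if event_kind == "fusion" else 0.0
        if event_kind == "moving":
            ang = rng.uniform(0, 2 * np.pi)
            vel = (moving_speed_px_per_frame * np.sin(ang),
                   moving_speed_px_per_frame * np.cos(ang))
        else:
            vel = (0.0, 0.0)
        events.append(
            GroundTruthEvent(
                event_id=i,
                row_px=float(locs[i, 0]),
                col_px=float(locs[i, 1]),
                t0_frame=int(rng.integers(t_lo, t_hi)),
                amplitude=default_event_amplitude(config, sigma0_um, snr),
                sigma0_um=sigma0_um,
                diffusion_um2_per_s=d,
                placement_mode=placement_mode,
                vel_row_px_per_frame=vel[0],
                vel_col_px_per_frame=vel[1],
            )
        )
    movie, truth = render_movie(
        config, events, cell, fas, fa_intensity=fa_spec.fa_intensity, seed=rng_noise
    )
    return {
        "config": config,
        "fa_spec": fa_spec,
        "cell": cell,
        "fas": fas,
        "fa_labels": fa_labels,
        "events": events,
        "movie": movie,
        "truth": truth,
    }


@dataclass
class QuenchGroundTruth:
    internal_fraction: float
    quench_frame: int
    bleach_rate_per_frame: float


def make_quench_series(
    n_frames: int = 100,
    quench_frame: int = 80,
    internal_fraction: float = 0.25,
    bleach_rate: float = 0.0,
    noise_sd: float = 0.0,
    frame_interval_s: float = 30.0,
    scale: float = 1000.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, QuenchGroundTruth]:
    """Whole-cell intensity trace for the surface-quench endocytosis assay.

    The surface pool (fraction 1 - internal_fraction) drops to zero at
    ``quench_frame`` (membrane-impermeant anti-fluorophore antibody); the
    internalized pool persists.  Both bleach exponentially.  Returns
    (time_s, intensity, ground_truth).
    """
    if not 0.0 <= internal_fraction <= 1.0:
        raise ValueError("internal_fraction must be in [0, 1]")
    if not 0 <= quench_frame < n_frames:
        raise ValueError("quench_frame must be in [0, n_frames)")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames)
    surface = (1.0 - internal_fraction) * (t < quench_frame)
    internal = internal_fraction * np.ones(n_frames)
    trace = scale * (surface + internal) * (1.0 - bleach_rate) ** t
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd * scale, size=n_frames)
    truth = QuenchGroundTruth(internal_fraction, quench_frame, bleach_rate)
    return t * frame_interval_s, trace, truth


def make_dual_label_movies(
    fa_labels: np.ndarray,
    n_frames: int = 30,
    background: float = 100.0,
    fa_level_a: float = 500.0,
    fa_level_b0: float = 200.0,
    fold_change_b: float = 2.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two co-registered channels for the FA recycling-ratio assay.

    Channel A (surface label) holds a constant FA signal; channel B
    (internal-pool label) ramps linearly from fa_level_b0 to
    fold_change_b * fa_level_b0 across the series, emulating delivery of
    an internal pool into adhesions.
    """
    rng = np.random.default_rng(seed)
    fas = fa_labels > 0
    shape = (n_frames, *fa_labels.shape)
    movie_a = np.full(shape, background, dtype=float)
    movie_b = np.full(shape, background, dtype=float)
    ramp = np.linspace(1.0, fold_change_b, n_frames)
    for t in range(n_frames):
        movie_a[t][fas] += fa_level_a
        movie_b[t][fas] += fa_level_b0 * ramp[t]
    if noise_sd > 0:
        movie_a += rng.normal(0.0, noise_sd, size=shape)
        movie_b += rng.normal(0.0, noise_sd, size=shape)
    return movie_a, movie_b
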