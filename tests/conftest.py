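"""Shared fixtures: small synthetic scenes generated at test time."""

import numpy as np
import pytest

from tirfex.synth import FAFieldSpec, MovieConfig, make_cell_and_fa_masks, simulate_cell

SMALL_CFG = MovieConfig(
    n_frames=140, height_px=160, width_px=160, photobleach_frame=30, seed=42
)


@pytest.fixture(scope="session")
def small_masks():
    """Cell + FA masks on a 160 px frame."""
    cell, fas, labels = make_cell_and_fa_masks(
        FAFieldSpec(n_fas=8), SMALL_CFG, seed=7
    )
    return cell, fas, labels


@pytest.fixture(scope="session")
def small_sim():
    """A small noisy movie with 12 CSR fusion events (known truth)."""
    return simulate_cell(
        config=SMALL_CFG, n_events=12, placement_mode="csr", seed=21,
        t0_margin_frames=16,
    )


@pytest.fixture(scope="session")
def noiseless_single_event():
    """One clean fusion event on a quiet background (fast exact checks)."""
    from tirfex.synth import GroundTruthEvent, render_movie

    cfg = MovieConfig(
        n_frames=40, height_px=64, width_px=64, photobleach_frame=5,
        poisson_noise=False, read_noise_sd=0.0, seed=0,
    )
    cell = np.ones((64, 64), bool)
    fas = np.zeros((64, 64), bool)
    fas[5:8, 5:10] = True
    ev = GroundTruthEvent(
        event_id=0, row_px=31.3, col_px=33.6, t0_frame=12,
        amplitude=4000.0, sigma0_um=0.15, diffusion_um2_per_s=0.05,
    )
    movie, truth = render_movie(cfg, [ev], cell, fas, seed=0)
    return cfg, cell, fas, ev, movie, truth
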