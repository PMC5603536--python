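"""Generator contracts: mask geometry, placement laws, optics, noise."""

import numpy as np
import pytest
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from tirfex.detection import fit_gaussian_spot
from tirfex.synth import (
    FAFieldSpec,
    GroundTruthEvent,
    MovieConfig,
    PlacementError,
    make_cell_and_fa_masks,
    make_quench_series,
    render_movie,
    sample_event_locations,
    static_scene,
)

CFG = MovieConfig(n_frames=40, height_px=128, width_px=128, photobleach_frame=5,
                  poisson_noise=False, read_noise_sd=0.0)


class TestMasks:
    def test_empty_fa_field(self):
        cell, fas, labels = make_cell_and_fa_masks(FAFieldSpec(n_fas=0), CFG, seed=1)
        assert cell.any() and not fas.any() and labels.max() == 0

    @pytest.mark.parametrize("n_fas", [1, 5, 12])
    def test_component_count_and_containment(self, n_fas):
        cell, fas, labels = make_cell_and_fa_masks(
            FAFieldSpec(n_fas=n_fas), CFG, seed=3
        )
        from skimage.measure import label as sk_label

        assert labels.max() == n_fas
        assert sk_label(fas, connectivity=2).max() == n_fas
        assert not (fas & ~cell).any()  # FAs inside the cell
        # labels partition the mask
        assert (labels > 0).sum() == fas.sum()

    def test_determinism(self):
        a = make_cell_and_fa_masks(FAFieldSpec(n_fas=6), CFG, seed=9)
        b = make_cell_and_fa_masks(FAFieldSpec(n_fas=6), CFG, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_placement_failure_is_explicit(self):
        tiny = MovieConfig(n_frames=1, height_px=24, width_px=24,
                           photobleach_frame=0)
        with pytest.raises(PlacementError):
            make_cell_and_fa_masks(
                FAFieldSpec(n_fas=40, length_um=(2.0, 3.0)), tiny, seed=0,
                max_tries_per_fa=50,
            )


class TestEventPlacement:
    def test_csr_membership(self, small_masks):
        cell, fas, _ = small_masks
        pts = sample_event_locations("csr", 200, cell, seed=1)
        r = np.rint(pts[:, 0]).astype(int)
        c = np.rint(pts[:, 1]).astype(int)
        assert cell[r, c].all()

    def test_fa_proximal_zero_decay_lands_on_fas(self, small_masks):
        cell, fas, _ = small_masks
        pts = sample_event_locations(
            "fa_proximal", 100, cell, fas, decay_um=0.0, seed=2
        )
        r = np.rint(pts[:, 0]).astype(int)
        c = np.rint(pts[:, 1]).astype(int)
        assert fas[r, c].all()

    def test_csr_uniform_over_quadrants(self):
        """10^4 CSR draws on a square footprint split into 4 equal
        quadrants: counts consistent with the uniform multinomial."""
        cell = np.zeros((84, 84), bool)
        cell[2:82, 2:82] = True
        pts = sample_event_locations("csr", 10_000, cell, seed=5)
        qr = (pts[:, 0] >= 42).astype(int) * 2 + (pts[:, 1] >= 42).astype(int)
        counts = np.bincount(qr, minlength=4)
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_fa_proximal_distance_law(self, small_masks):
        """Nearest-FA distances of fa_proximal samples match an
        independently coded rejection sampler of the same truncated
        exponential law (two-sample KS, alpha=0.01)."""
        cell, fas, _ = small_masks
        px, decay = 0.189, 0.2
        n = 10_000
        pts = sample_event_locations(
            "fa_proximal", n, cell, fas, decay_um=decay, pixel_size_um=px, seed=3
        )
        tree = cKDTree(np.column_stack(np.nonzero(fas)))
        ri = np.rint(pts).astype(int)
        d_mine = np.where(
            fas[ri[:, 0], ri[:, 1]], 0.0, tree.query(pts)[0] * px
        )
        # oracle: target distance ~ Exp, pixel chosen among the matching
        # brute-force distance band, jittered
        rng = np.random.default_rng(99)
        rows, cols = np.nonzero(cell)
        d_cell = tree.query(np.column_stack([rows, cols]))[0]
        d_cell[fas[rows, cols]] = 0.0
        dmax = d_cell.max()
        d_oracle = []
        while len(d_oracle) < n:
            d = rng.exponential(decay / px)
            if d > dmax + 0.5:
                continue
            band = np.nonzero(np.abs(d_cell - d) <= 0.5)[0]
            if band.size == 0:
                continue
            j = band[rng.integers(band.size)]
            p = np.array([rows[j], cols[j]]) + rng.uniform(-0.5, 0.5, 2)
            rj = np.rint(p).astype(int)
            d_oracle.append(0.0 if fas[rj[0], rj[1]] else tree.query(p)[0] * px)
        assert stats.ks_2samp(d_mine, np.asarray(d_oracle)).pvalue > 0.01

    def test_errors(self, small_masks):
        cell, fas, _ = small_masks
        with pytest.raises(ValueError):
            sample_event_locations("csr", -1, cell)
        with pytest.raises(ValueError):
            sample_event_locations("fa_proximal", 5, cell, np.zeros_like(cell))


class TestRenderMovie:
    def test_static_scene_without_events(self, small_masks):
        cell, fas, _ = small_masks
        cfg = MovieConfig(n_frames=6, height_px=160, width_px=160,
                          photobleach_frame=0, poisson_noise=False,
                          read_noise_sd=0.0)
        movie, truth = render_movie(cfg, [], cell, fas)
        assert truth.empty
        assert all(np.array_equal(movie[0], movie[t]) for t in range(1, 6))

    def test_event_intensity_appears_and_is_conserved(self, small_masks):
        cell, fas, _ = small_masks
        cfg = MovieConfig(n_frames=30, height_px=160, width_px=160,
                          photobleach_frame=2, poisson_noise=False,
                          read_noise_sd=0.0)
        ev = GroundTruthEvent(0, 80.0, 80.0, 10, amplitude=5000.0)
        movie, _ = render_movie(cfg, [ev], cell, fas)
        base = static_scene(cfg, cell, fas, 5.0, prebleach=False).sum()
        # integrated intensity above the static scene = amplitude (<1%)
        for t in (10, 15, 25):
            excess = movie[t].sum() - base
            assert excess == pytest.approx(5000.0, rel=0.01)
        assert movie[9].sum() == pytest.approx(base, rel=1e-6)

    def test_sigma_growth_matches_diffusion(self, noiseless_single_event):
        """Refitting the noiseless render recovers sigma^2 slope = 2D."""
        cfg, cell, fas, ev, movie, _ = noiseless_single_event
        ks = np.arange(0, 14)
        sig2 = []
        for k in ks:
            fit = fit_gaussian_spot(movie[ev.t0_frame + k],
                                    (ev.row_px, ev.col_px), 15)
            assert fit.fit_ok
            sig2.append((fit.sigma_px * cfg.pixel_size_um) ** 2)
        slope = np.polyfit(ks * cfg.frame_interval_s, sig2, 1)[0]
        assert slope == pytest.approx(2 * ev.diffusion_um2_per_s, rel=0.10)

    def test_prebleach_reference_shows_full_fa_contrast(self, small_masks):
        cell, fas, _ = small_masks
        cfg = MovieConfig(n_frames=10, height_px=160, width_px=160,
                          photobleach_frame=4, poisson_noise=False,
                          read_noise_sd=0.0)
        movie, _ = render_movie(cfg, [], cell, fas, fa_intensity=5.0)
        assert movie[0][fas].mean() > 2.0 * movie[5][fas].mean()

    def test_poisson_noise_variance_matches_mean(self):
        """Flat field with shot noise: sample variance/mean ~ 1."""
        cfg = MovieConfig(n_frames=7, height_px=128, width_px=128,
                          photobleach_frame=0, poisson_noise=True,
                          read_noise_sd=0.0, seed=11)
        cell = np.ones((128, 128), bool)
        fas = np.zeros((128, 128), bool)
        movie, _ = render_movie(cfg, [], cell, fas)
        vals = movie.ravel()[: 10**5]
        assert vals.var() / vals.mean() == pytest.approx(1.0, abs=0.05)

    def test_determinism(self, small_masks):
        cell, fas, _ = small_masks
        cfg = MovieConfig(n_frames=8, height_px=160, width_px=160,
                          photobleach_frame=2, seed=13)
        a, _ = render_movie(cfg, [], cell, fas)
        b, _ = render_movie(cfg, [], cell, fas)
        assert np.array_equal(a, b)

    def test_t0_out_of_range_rejected(self, small_masks):
        cell, fas, _ = small_masks
        cfg = MovieConfig(n_frames=8, height_px=160, width_px=160,
                          photobleach_frame=2)
        ev = GroundTruthEvent(0, 80.0, 80.0, 20, amplitude=100.0)
        with pytest.raises(ValueError):
            render_movie(cfg, [ev], cell, fas)


class TestQuenchSeries:
    @pytest.mark.parametrize(
        "frac,expected_post_over_pre", [(0.0, 0.0), (1.0, 1.0), (0.25, 0.25)]
    )
    def test_clean_mixture_ratio(self, frac, expected_post_over_pre):
        _, trace, _ = make_quench_series(
            n_frames=50, quench_frame=30, internal_fraction=frac,
            bleach_rate=0.0, noise_sd=0.0,
        )
        pre = trace[:30].mean()
        post = trace[35:].mean()
        if frac == 0.0:
            assert post == pytest.approx(0.0, abs=1e-9)
        else:
            assert post / pre == pytest.approx(expected_post_over_pre, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            make_quench_series(internal_fraction=1.5)
        with pytest.raises(ValueError):
            make_quench_series(n_frames=10, quench_frame=10)
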