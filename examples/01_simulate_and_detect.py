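"""Simulate a small TIRFM movie with known fusion events and detect them.

Builds one synthetic cell (pre-bleach reference segment + post-bleach
event phase), runs candidate detection and the fusion-signature
classifier, and compares the result against the generator's ground truth.
"""

import numpy as np
import pandas as pd

from tirfex import (
    MovieConfig,
    align_events,
    classify_all,
    detect_candidates,
    match_events,
    simulate_cell,
)
from tirfex.detection import events_to_frame

cfg = MovieConfig(n_frames=180, height_px=192, width_px=192,
                  photobleach_frame=40, seed=8)
sim = simulate_cell(config=cfg, n_events=15, placement_mode="csr", seed=8)
print(f"movie: {sim['movie'].shape} frames x pixels, "
      f"{len(sim['events'])} true fusion events")

cands = detect_candidates(sim["movie"], sim["cell"],
                          photobleach_frame=cfg.photobleach_frame)
events = classify_all(cands, sim["movie"], sim["cell"],
                      photobleach_frame=cfg.photobleach_frame)
accepted = [e for e in events if e.accepted]
match = match_events(sim["truth"],
                     pd.DataFrame([{"row_px": c.row_px, "col_px": c.col_px,
                                    "t0_frame": c.t0_frame} for c in cands]))
print(f"candidates: {len(cands)}  recall {match.recall:.2f}  "
      f"precision {match.precision:.2f} (vs ground truth, 3 px / 2 frames)")
print(f"classifier accepted {len(accepted)} as bona fide fusion "
      f"(rise + FWHM spread + stationary)")

profile = align_events(accepted, pre_frames=3, post_frames=8,
                       frame_interval_s=cfg.frame_interval_s)
peak = np.nanargmax(profile.amplitude_mean)
print(f"aligned profile peak at {profile.offsets_s[peak]:+.2f} s from fusion, "
      f"mean FWHM grows {np.nanmin(profile.fwhm_mean_um):.2f} -> "
      f"{np.nanmax(profile.fwhm_mean_um):.2f} um across the window")
# A growing FWHM after the intensity burst is the full-fusion signature:
# cargo diffuses laterally in the plasma membrane after pore opening.
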