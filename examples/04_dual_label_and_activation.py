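"""Dual-label FA recycling ratio and the flow-cytometric activation index.

Channel A carries the surface label (e.g. Alexa488), channel B the
internal-pool label (e.g. SiR647); a rising B/A ratio inside focal
adhesions reports delivery of the internal receptor pool.  The
activation index AI = (F - F0) / F_integrin normalizes specific ligand
binding to receptor surface expression.
"""

import numpy as np
import pandas as pd

from tirfex import (
    FAFieldSpec,
    MovieConfig,
    fa_ratio_timecourse,
    make_cell_and_fa_masks,
    make_dual_label_movies,
)
from tirfex.pools import activation_index_table

cfg = MovieConfig(height_px=160, width_px=160)
_, _, labels = make_cell_and_fa_masks(FAFieldSpec(n_fas=8), cfg, seed=5)
movie_a, movie_b = make_dual_label_movies(labels, n_frames=12,
                                          fold_change_b=2.5, noise_sd=2.0,
                                          seed=5)
series, summary = fa_ratio_timecourse(movie_a, movie_b, labels)
fold = np.mean([s.fold_change[-1] for s in series])
print(f"{len(series)} FAs tracked; mean B/A ratio "
      f"{summary.ratio_mean.iloc[0]:.3f} -> {summary.ratio_mean.iloc[-1]:.3f}")
print(f"mean end-of-series fold change: {fold:.2f} "
      f"(generator truth 2.5)")

table = pd.DataFrame({
    "sample": ["wild-type", "tagged", "inhibited"],
    "F": [10.0, 9.0, 2.5],
    "F0": [2.0, 2.0, 2.0],
    "F_integrin": [4.0, 3.6, 4.0],
})
print(activation_index_table(table).to_string(index=False))
# Similar AI between wild-type and tagged receptors indicates the tag
# does not perturb activation regulation.
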