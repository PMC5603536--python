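"""Detection-performance scoring against simulated ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment


@dataclass
class MatchResult:
    n_truth: int
    n_detected: int
    n_matched: int
    pairs: list[tuple[int, int]]  # (truth index, detection index)

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else np.nan

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_truth": self.n_truth,
                    "n_detected": self.n_detected,
                    "n_matched": self.n_matched,
                    "recall": self.recall,
                    "precision": self.precision,
                }
            ]
        )


def match_events(
    truth: pd.DataFrame,
    detected: pd.DataFrame,
    max_dist_px: float = 3.0,
    max_dt_frames: int = 2,
) -> MatchResult:
    """One-to-one Hungarian matching of detections to true events.

    A pairing is admissible when the spatial separation is at most
    ``max_dist_px`` and the fusion frames differ by at most
    ``max_dt_frames``; the assignment minimizes total spatial distance
    over admissible pairs.  Both tables need row_px, col_px, t0_frame.
    """
    nt, nd = len(truth), len(detected)
    if nt == 0 or nd == 0:
        return MatchResult(nt, nd, 0, [])
    tr = truth[["row_px", "col_px"]].to_numpy(float)
    de = detected[["row_px", "col_px"]].to_numpy(float)
    dist = np.sqrt(((tr[:, None, :] - de[None, :, :]) ** 2).sum(axis=2))
    dt = np.abs(
        truth["t0_frame"].to_numpy(int)[:, None]
        - detected["t0_frame"].to_numpy(int)[None, :]
    )
    admissible = (dist <= max_dist_px) & (dt <= max_dt_frames)
    big = dist.max() + max_dist_px + 1.0
    cost = np.where(admissible, dist, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = [(int(i), int(j)) for i, j in zip(rows, cols) if admissible[i, j]]
    return MatchResult(nt, nd, len(pairs), pairs)
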