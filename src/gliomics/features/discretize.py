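"""Fixed-bin-width gray-level discretization of an ROI."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DiscretizedROI:
    """Integer gray levels over an ROI; 0 marks background.

    Levels are the consecutive integers ``1..n_levels`` produced by
    fixed-bin-width binning anchored at the ROI minimum:
    ``level(x) = floor((x - min) / bin_width) + 1``.
    """

    gray_levels: np.ndarray  # int array, 0 outside ROI
    n_levels: int
    bin_width: float
    bin_edges: np.ndarray

    @property
    def roi(self) -> np.ndarray:
        return self.gray_levels > 0

    @property
    def n_voxels(self) -> int:
        return int((self.gray_levels > 0).sum())


def discretize(volume: np.ndarray, roi: np.ndarray, bin_width: float) -> DiscretizedROI:
    """Discretize in-ROI intensities with a fixed bin width.

    The value exactly at ``min + k*bin_width`` falls in bin ``k+1``; the ROI
    maximum defines ``n_levels``. A constant ROI yields a single level.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    volume = np.asarray(volume, dtype=np.float64)
    vals = volume[roi]
    lo = vals.min()
    levels = np.zeros(volume.shape, dtype=np.int32)
    levels[roi] = np.floor((vals - lo) / bin_width).astype(np.int64) + 1
    n_levels = int(levels.max())
    edges = lo + bin_width * np.arange(n_levels + 1)
    return DiscretizedROI(gray_levels=levels, n_levels=n_levels,
                          bin_width=float(bin_width), bin_edges=edges)
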