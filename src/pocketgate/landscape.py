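"""Boltzmann-inversion free-energy landscape over (volume, distance).

F_ij = -ln(n_ij / n_max) in kBT units, so the most populated bin sits at
F = 0 and only count ratios matter.  Empty bins are reported as
unsampled (NaN plus a mask) rather than infinite, which keeps summaries
over the surface well-defined.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .pocket import PocketVolumeSeries

KB_KJ_PER_MOL_K = 0.0083144626  # Boltzmann constant, kJ/(mol K)


@dataclasses.dataclass
class FELGrid:
    v_edges: np.ndarray          # bin edges, A^3
    d_edges: np.ndarray          # bin edges, A
    counts: np.ndarray           # 2D histogram (n_v, n_d)
    free_energy: np.ndarray      # kBT units; NaN where unsampled
    unsampled: np.ndarray        # boolean mask of empty bins
    temperature: float           # K, for optional kJ/mol conversion
    minimum_bin: tuple[int, int]
    minimum_frames: np.ndarray   # indices into the input series

    @property
    def free_energy_kj_per_mol(self) -> np.ndarray:
        return self.free_energy * KB_KJ_PER_MOL_K * self.temperature

    def to_dict(self) -> dict:
        return {
            "v_edges": self.v_edges.tolist(),
            "d_edges": self.d_edges.tolist(),
            "counts": self.counts.tolist(),
            "free_energy_kbt": [[None if np.isnan(x) else x for x in row]
                                for row in self.free_energy],
            "temperature_K": self.temperature,
            "minimum_bin": list(self.minimum_bin),
            "minimum_frames": self.minimum_frames.tolist(),
        }


def build_fel(series: PocketVolumeSeries, n_bins: tuple[int, int] = (32, 32),
              temperature: float = 310.0) -> FELGrid:
    """Histogram the (V, d) series and Boltzmann-invert the counts.

    The minimum basin is the most populated bin (ties broken toward the
    lexicographically lowest bin index); its member frames are collected
    for downstream averaging.
    """
    v = np.asarray(series.volume, float)
    d = np.asarray(series.distance, float)
    if len(v) < 10:
        raise ValueError("need at least 10 points for a landscape")
    if n_bins[0] < 2 or n_bins[1] < 2:
        raise ValueError("need at least 2 bins per axis")
    if np.ptp(v) == 0 and np.ptp(d) == 0:
        raise ValueError("degenerate series: all points identical")
    counts, v_edges, d_edges = np.histogram2d(v, d, bins=n_bins)
    n_max = counts.max()
    with np.errstate(divide="ignore"):
        fe = -np.log(counts / n_max)
    unsampled = counts == 0
    fe[unsampled] = np.nan
    # argmax with lexicographic tie-break: flat argmax scans row-major,
    # returning the lowest (i, j) among maxima
    flat = int(np.argmax(counts))
    minimum_bin = np.unravel_index(flat, counts.shape)
    vi = np.clip(np.digitize(v, v_edges) - 1, 0, n_bins[0] - 1)
    di = np.clip(np.digitize(d, d_edges) - 1, 0, n_bins[1] - 1)
    in_min = (vi == minimum_bin[0]) & (di == minimum_bin[1])
    return FELGrid(v_edges, d_edges, counts, fe, unsampled,
                   float(temperature), (int(minimum_bin[0]), int(minimum_bin[1])),
                   np.flatnonzero(in_min))


def basin_summary(fel: FELGrid, series: PocketVolumeSeries) -> tuple[float, float]:
    """(mean volume, mean distance) over the frames in the minimum basin."""
    if len(fel.minimum_frames) == 0:
        raise ValueError("minimum basin holds no frames")
    return (float(np.mean(series.volume[fel.minimum_frames])),
            float(np.mean(series.distance[fel.minimum_frames])))
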