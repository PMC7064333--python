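"""Grid-based pocket volumetrics and the gate-distance reaction coordinate.

The volume algorithm follows the standard inclusion-sphere grid recipe:
lay a cubic lattice over a union of inclusion spheres, delete lattice
points that clash with protein heavy atoms (van der Waals radius plus a
padding, default the hydrogen radius 1.09 A), optionally keep only the
6-connected component reachable from a seed point, and count.  The grid
is anchored at the first inclusion-sphere center so the estimate is
exactly invariant under joint translation of atoms and spheres.
"""

from __future__ import annotations

import dataclasses
from collections import deque

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu, rankdata, norm

from .elements import vdw_radius
from .io import Structure, Trajectory, subsample


@dataclasses.dataclass
class PocketSpec:
    """Geometry of the pocket search region."""

    inclusion_spheres: list[tuple[np.ndarray, float]]  # (center A, radius A)
    grid_spacing: float = 1.0          # A
    exclusion_padding: float = 1.09    # A added to vdW radii
    contiguity_seed: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        self.inclusion_spheres = [
            (np.asarray(c, float), float(r)) for c, r in self.inclusion_spheres]
        for _, r in self.inclusion_spheres:
            if r <= 0:
                raise ValueError("sphere radii must be positive")
        if self.contiguity_seed is not None:
            self.contiguity_seed = np.asarray(self.contiguity_seed, float)

    def shifted(self, rotation: np.ndarray, translation: np.ndarray) -> "PocketSpec":
        """The spec under a rigid motion (for invariance checks)."""
        move = lambda p: rotation @ p + translation
        return PocketSpec(
            [(move(c), r) for c, r in self.inclusion_spheres],
            self.grid_spacing, self.exclusion_padding,
            None if self.contiguity_seed is None else move(self.contiguity_seed))


@dataclasses.dataclass
class PocketVolumeSeries:
    """Per-frame pocket volume (A^3) and gate distance (A)."""

    frames: np.ndarray
    volume: np.ndarray
    distance: np.ndarray
    run_id: str = "run1"

    def __post_init__(self) -> None:
        if not (len(self.frames) == len(self.volume) == len(self.distance)):
            raise ValueError("series components must have equal length")
        if np.any(self.volume < 0):
            raise ValueError("volumes must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"run_id": self.run_id, "frame": self.frames,
                             "volume_A3": self.volume, "distance_A": self.distance})

    @classmethod
    def concat(cls, series: list["PocketVolumeSeries"]) -> "PocketVolumeSeries":
        """Pool several runs; run identity is kept only in to_frame output."""
        return cls(np.concatenate([s.frames for s in series]),
                   np.concatenate([s.volume for s in series]),
                   np.concatenate([s.distance for s in series]),
                   run_id="+".join(s.run_id for s in series))


@dataclasses.dataclass
class RankSumResult:
    statistic: float   # rank-sum z
    p_value: float
    n_a: int
    n_b: int
    method: str = "asymptotic"


def _grid_points(spec: PocketSpec) -> np.ndarray:
    """Lattice points inside the union of inclusion spheres."""
    s = spec.grid_spacing
    anchor = spec.inclusion_spheres[0][0]
    centers = np.array([c for c, _ in spec.inclusion_spheres])
    radii = np.array([r for _, r in spec.inclusion_spheres])
    lo = np.floor((centers - radii[:, None] - anchor).min(axis=0) / s).astype(int)
    hi = np.ceil((centers + radii[:, None] - anchor).max(axis=0) / s).astype(int)
    axes = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    ijk = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    pts = anchor + ijk * s
    keep = np.zeros(len(pts), dtype=bool)
    for c, r in spec.inclusion_spheres:
        keep |= np.sum((pts - c) ** 2, axis=1) <= r * r
    return pts[keep]


def _exclude_atoms(pts: np.ndarray, structure: Structure,
                   padding: float) -> np.ndarray:
    """Mask of grid points NOT clashing with any protein heavy atom."""
    heavy = [(a.position, vdw_radius(a.element)) for a in structure.atoms
             if a.element != "H"]
    if not heavy or len(pts) == 0:
        return np.ones(len(pts), dtype=bool)
    tree = cKDTree(pts)
    alive = np.ones(len(pts), dtype=bool)
    for pos, r in heavy:
        for idx in tree.query_ball_point(pos, r + padding):
            alive[idx] = False
    return alive


def _contiguous(pts: np.ndarray, spacing: float, seed: np.ndarray) -> np.ndarray:
    """Mask of points 6-connected to the point nearest the seed."""
    if len(pts) == 0:
        return np.zeros(0, dtype=bool)
    ijk = np.round(pts / spacing).astype(int)
    index = {tuple(v): i for i, v in enumerate(ijk)}
    start = int(np.argmin(np.sum((pts - seed) ** 2, axis=1)))
    visited = np.zeros(len(pts), dtype=bool)
    visited[start] = True
    queue = deque([tuple(ijk[start])])
    steps = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while queue:
        cur = queue.popleft()
        for dx, dy, dz in steps:
            nb = (cur[0] + dx, cur[1] + dy, cur[2] + dz)
            j = index.get(nb)
            if j is not None and not visited[j]:
                visited[j] = True
                queue.append(nb)
    return visited


def pocket_volume(structure_frame: Structure | None, spec: PocketSpec) -> float:
    """Pocket volume (A^3) of one frame; ``None`` means no atoms (empty box)."""
    if not spec.inclusion_spheres:
        raise ValueError("at least one inclusion sphere required")
    pts = _grid_points(spec)
    if structure_frame is not None:
        pts = pts[_exclude_atoms(pts, structure_frame, spec.exclusion_padding)]
    if spec.contiguity_seed is not None:
        if len(pts) == 0:
            return 0.0
        nearest = np.min(np.linalg.norm(pts - spec.contiguity_seed, axis=1))
        if nearest > spec.grid_spacing * np.sqrt(3.0):
            # seed itself excluded: the pocket is closed at the seed
            return 0.0
        pts = pts[_contiguous(pts, spec.grid_spacing, spec.contiguity_seed)]
    return float(len(pts) * spec.grid_spacing ** 3)


def com_distance(structure_frame: Structure,
                 res_a: tuple[str, int], res_b: tuple[str, int]) -> float:
    """Distance (A) between mass-weighted heavy-atom centers of two residues."""
    def com(chain: str, seq: int) -> np.ndarray:
        atoms = [a for a in structure_frame.residue_atoms(chain, seq)
                 if a.element != "H"]
        if not atoms:
            raise ValueError(f"residue {chain}:{seq} has no heavy atoms")
        w = np.array([a.mass for a in atoms])
        pts = np.array([a.position for a in atoms])
        return (w[:, None] * pts).sum(axis=0) / w.sum()

    return float(np.linalg.norm(com(*res_a) - com(*res_b)))


def volume_distance_series(traj: Trajectory, spec: PocketSpec,
                           res_a: tuple[str, int], res_b: tuple[str, int],
                           n_frames: int | None = None) -> PocketVolumeSeries:
    """Per-frame (volume, distance) over equally spaced frames."""
    sub = subsample(traj, n=n_frames) if n_frames is not None else traj
    vols = np.empty(sub.n_frames)
    dists = np.empty(sub.n_frames)
    for i in range(sub.n_frames):
        frame = sub.frame(i)
        vols[i] = pocket_volume(frame, spec)
        dists[i] = com_distance(frame, res_a, res_b)
    return PocketVolumeSeries(np.arange(sub.n_frames), vols, dists,
                              run_id=traj.run_id)


def ranksum_test(sample_a: np.ndarray, sample_b: np.ndarray) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration for small untied samples (n_a + n_b <= 12),
    otherwise the normal approximation with mid-rank ties and
    tie-corrected variance.  Identical constant samples give p = 1.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per sample")
    pooled = np.concatenate([a, b])
    n_a, n_b = len(a), len(b)
    if np.all(pooled == pooled[0]):
        return RankSumResult(0.0, 1.0, n_a, n_b, method="degenerate")
    ties = len(np.unique(pooled)) < len(pooled)
    exact = (n_a + n_b) <= 12 and not ties
    res = mannwhitneyu(a, b, alternative="two-sided",
                       method="exact" if exact else "asymptotic",
                       use_continuity=True)
    # z statistic from the tie-corrected normal approximation
    ranks = rankdata(pooled)
    w = ranks[:n_a].sum()
    mu = n_a * (n_a + n_b + 1) / 2.0
    n = n_a + n_b
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / ((n * (n - 1)) or 1)
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    z = 0.0 if var == 0 else (w - mu) / np.sqrt(var)
    return RankSumResult(float(z), float(res.pvalue), n_a, n_b,
                         method="exact" if exact else "asymptotic")
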