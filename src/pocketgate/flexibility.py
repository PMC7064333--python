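"""Per-residue Calpha RMSF and aggregation across replicate runs.

RMSF_i = sqrt(mean_t |r_i(t) - <r_i>|^2) over Calpha atoms after removing
global rotation/translation.  The fluctuation reference is the
time-averaged structure: frames are first fitted to frame 0 and averaged,
then every frame is re-fitted to that average before fluctuations are
taken, which removes the arbitrariness of a single-frame reference.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import Trajectory, ResidueSelection
from .structures import kabsch


@dataclasses.dataclass
class RMSFProfile:
    """Replicate-resolved RMSF with mean/min/max envelope (Angstrom)."""

    residues: list[tuple[str, int]]
    per_run: np.ndarray   # (n_runs, n_residues)
    run_ids: list[str]

    @property
    def mean(self) -> np.ndarray:
        return self.per_run.mean(axis=0)

    @property
    def min(self) -> np.ndarray:
        return self.per_run.min(axis=0)

    @property
    def max(self) -> np.ndarray:
        return self.per_run.max(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "chain": [c for c, _ in self.residues],
            "residue_seq": [r for _, r in self.residues],
        })
        for rid, row in zip(self.run_ids, self.per_run):
            df[rid] = row
        df["mean"] = self.mean
        df["min"] = self.min
        df["max"] = self.max
        return df


def _fit_frames(frames: np.ndarray, fit_idx: np.ndarray,
                reference: np.ndarray) -> np.ndarray:
    """Superpose every frame onto ``reference`` using the fit-atom subset."""
    out = np.empty_like(frames)
    ref = reference[fit_idx]
    for t in range(frames.shape[0]):
        rot, trans, _ = kabsch(ref, frames[t][fit_idx])
        out[t] = frames[t] @ rot.T + trans
    return out


def rmsf(traj: Trajectory,
         fit_selection: ResidueSelection | None = None) -> tuple[list[tuple[str, int]], np.ndarray]:
    """Per-residue Calpha RMSF (Angstrom) for one trajectory.

    Frames are superposed on the Calpha atoms of ``fit_selection``
    (default: all residues with a Calpha).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    ca = traj.topology.ca_index()
    if not ca:
        raise ValueError("topology has no Calpha atoms")
    if fit_selection is not None:
        fit_keys = [k for k in fit_selection.members if k in ca]
        if len(fit_keys) < len(fit_selection.members):
            missing = set(fit_selection.members) - set(fit_keys)
            raise ValueError(f"fit selection residues missing Calpha: {missing}")
    else:
        fit_keys = list(ca)
    fit_idx = np.array([ca[k] for k in fit_keys])

    # pass 1: fit to frame 0, average; pass 2: fit to the average
    aligned = _fit_frames(traj.frames, fit_idx, traj.frames[0])
    mean_struct = aligned.mean(axis=0)
    aligned = _fit_frames(traj.frames, fit_idx, mean_struct)
    mean_struct = aligned.mean(axis=0)

    residues = list(ca)
    ca_idx = np.array([ca[k] for k in residues])
    dev = aligned[:, ca_idx, :] - mean_struct[ca_idx]
    values = np.sqrt(np.mean(np.sum(dev ** 2, axis=2), axis=0))
    return residues, values


def aggregate_rmsf(profiles: list[np.ndarray],
                   residues: list[tuple[str, int]],
                   run_ids: list[str] | None = None) -> RMSFProfile:
    """Stack per-run RMSF vectors and expose the mean/min/max envelope."""
    lengths = {len(p) for p in profiles}
    if len(lengths) != 1 or lengths.pop() != len(residues):
        raise ValueError("per-run RMSF vectors must share residue ordering")
    per_run = np.vstack(profiles)
    run_ids = run_ids or [f"run{i + 1}" for i in range(per_run.shape[0])]
    return RMSFProfile(list(residues), per_run, run_ids)


def rmsf_profile(trajs: list[Trajectory],
                 fit_selection: ResidueSelection | None = None) -> RMSFProfile:
    """RMSF for each replicate trajectory, aggregated into one profile."""
    residues = None
    vectors = []
    for traj in trajs:
        res, vals = rmsf(traj, fit_selection)
        if residues is None:
            residues = res
        elif res != residues:
            raise ValueError("replicates disagree on residue ordering")
        vectors.append(vals)
    return aggregate_rmsf(vectors, residues, [t.run_id for t in trajs])
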