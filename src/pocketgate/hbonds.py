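"""Geometric hydrogen-bond detection and occupancy filtering.

A bond is counted when the donor-heavy-atom to acceptor distance is
within ``da_distance_max`` (default 3.5 A) and, when an explicit
hydrogen is bonded to the donor, the D-H...A angle is at least
``dha_angle_min`` (default 120 deg).  Crystal structures and
coarse synthetic models usually lack hydrogens; the heavy-atom
fallback then applies the distance criterion alone.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import Structure, Trajectory, ResidueSelection

# polar atoms per residue type: (donors, acceptors) by atom name.
# backbone N/O handled separately for all residue types.
_SIDECHAIN_POLAR: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "SER": (("OG",), ("OG",)),
    "THR": (("OG1",), ("OG1",)),
    "TYR": (("OH",), ("OH",)),
    "CYS": (("SG",), ("SG",)),
    "ASN": (("ND2",), ("OD1",)),
    "GLN": (("NE2",), ("OE1",)),
    "ASP": ((), ("OD1", "OD2")),
    "GLU": ((), ("OE1", "OE2")),
    "LYS": (("NZ",), ()),
    "ARG": (("NE", "NH1", "NH2"), ()),
    "HIS": (("ND1", "NE2"), ("ND1", "NE2")),
    "TRP": (("NE1",), ()),
}


@dataclasses.dataclass
class HBondCriteria:
    da_distance_max: float = 3.5    # A, donor heavy atom to acceptor
    dha_angle_min: float = 120.0    # deg, applied only when H present
    heavy_only_fallback: bool = True

    def __post_init__(self) -> None:
        if self.da_distance_max <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 <= self.dha_angle_min <= 180:
            raise ValueError("angle cutoff must be in [0, 180]")


AtomId = tuple[str, int, str]  # (chain, residue_seq, atom name)


@dataclasses.dataclass
class HBondRecord:
    donor: AtomId
    acceptor: AtomId
    count: int                 # frames observed, over the best trajectory
    frequency: float           # fraction of frames in that trajectory
    counts_per_run: dict[str, int]
    trajectories_observed: list[str]


def _polar_atoms(structure: Structure) -> tuple[list[int], list[int]]:
    """Indices of donor heavy atoms and acceptor atoms."""
    donors, acceptors = [], []
    for i, a in enumerate(structure.atoms):
        if a.element == "H":
            continue
        side = _SIDECHAIN_POLAR.get(a.residue_name, ((), ()))
        if a.name == "N" and a.residue_name != "PRO":
            donors.append(i)
        elif a.name in ("O", "OXT"):
            acceptors.append(i)
        else:
            if a.name in side[0]:
                donors.append(i)
            if a.name in side[1]:
                acceptors.append(i)
    return donors, acceptors


def _attached_hydrogens(structure: Structure) -> dict[int, list[int]]:
    """Map heavy-atom index -> indices of hydrogens within bonding range."""
    hyd = [(i, a.position) for i, a in enumerate(structure.atoms)
           if a.element == "H"]
    if not hyd:
        return {}
    hpos = np.array([p for _, p in hyd])
    tree = cKDTree(hpos)
    out: dict[int, list[int]] = {}
    for i, a in enumerate(structure.atoms):
        if a.element == "H":
            continue
        near = tree.query_ball_point(a.position, 1.25)
        if near:
            out[i] = [hyd[j][0] for j in near]
    return out


def detect_hbonds(frame: Structure,
                  criteria: HBondCriteria | None = None) -> list[tuple[AtomId, AtomId]]:
    """Donor-acceptor pairs satisfying the geometric criteria in one frame."""
    criteria = criteria or HBondCriteria()
    donors, acceptors = _polar_atoms(frame)
    if not donors or not acceptors:
        return []
    hmap = _attached_hydrogens(frame)
    apos = np.array([frame.atoms[i].position for i in acceptors])
    tree = cKDTree(apos)
    pairs: list[tuple[AtomId, AtomId]] = []
    for di in donors:
        d = frame.atoms[di]
        for k in tree.query_ball_point(d.position, criteria.da_distance_max):
            ai = acceptors[k]
            acc = frame.atoms[ai]
            if acc.residue_key == d.residue_key:
                continue
            hs = hmap.get(di, [])
            if hs:
                ok = False
                for hi in hs:
                    h = frame.atoms[hi].position
                    v1 = d.position - h
                    v2 = acc.position - h
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= criteria.dha_angle_min:
                        ok = True
                        break
                if not ok:
                    continue
            elif not criteria.heavy_only_fallback:
                continue
            pairs.append(((d.chain_id, d.residue_seq, d.name),
                          (acc.chain_id, acc.residue_seq, acc.name)))
    return pairs


def hbond_occupancy(trajs: list[Trajectory],
                    loop: ResidueSelection,
                    criteria: HBondCriteria | None = None,
                    min_frames: int | None = None,
                    min_fraction: float | None = 0.1) -> list[HBondRecord]:
    """High-occupancy hydrogen bonds touching a residue selection.

    Counts each donor-acceptor pair per trajectory and retains pairs with
    at least one loop residue and a count above threshold in at least one
    trajectory.  The threshold is either an absolute frame count
    (``min_frames``) or a fraction of each trajectory's length
    (``min_fraction``, default 0.1).
    """
    criteria = criteria or HBondCriteria()
    if min_frames is not None and min_fraction is not None:
        raise ValueError("give only one of min_frames or min_fraction")
    if min_frames is not None:
        for t in trajs:
            if min_frames > t.n_frames:
                raise ValueError(
                    f"threshold {min_frames} exceeds trajectory {t.run_id} "
                    f"length {t.n_frames}")
    loop_set = set(loop.members)
    counts: dict[tuple[AtomId, AtomId], dict[str, int]] = {}
    lengths: dict[str, int] = {}
    for traj in trajs:
        loop.validate(traj.topology)
        lengths[traj.run_id] = traj.n_frames
        for f in range(traj.n_frames):
            for pair in set(detect_hbonds(traj.frame(f), criteria)):
                per_run = counts.setdefault(pair, {})
                per_run[traj.run_id] = per_run.get(traj.run_id, 0) + 1

    records = []
    for (donor, acceptor), per_run in sorted(counts.items()):
        if (donor[0], donor[1]) not in loop_set and \
           (acceptor[0], acceptor[1]) not in loop_set:
            continue
        keep = False
        best_run, best_count = None, -1
        for rid, c in per_run.items():
            thr = min_frames if min_frames is not None \
                else min_fraction * lengths[rid]
            if c > thr:
                keep = True
            if c > best_count:
                best_run, best_count = rid, c
        if keep:
            records.append(HBondRecord(
                donor, acceptor, best_count,
                best_count / lengths[best_run],
                dict(per_run), sorted(per_run)))
    return records


def occupancy_table(records: list[HBondRecord]) -> pd.DataFrame:
    rows = [{
        "donor": ":".join(map(str, r.donor)),
        "acceptor": ":".join(map(str, r.acceptor)),
        "max_count": r.count,
        "max_frequency": r.frequency,
        "runs_observed": "+".join(r.trajectories_observed),
    } for r in records]
    return pd.DataFrame(rows)
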