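"""Per-residue Kullback-Leibler divergence of torsion-angle distributions.

Two conformational ensembles are compared residue by residue through the
circular distributions of their phi/psi/chi1 torsions.  The estimator is
a transparent histogram KL: equal-width bins over (-180, 180], add-1/2
pseudocounts in both histograms, D = sum p ln(p/q) in nats, summed over
the torsion kinds a residue possesses.  Significance comes from a block
bootstrap: trajectory blocks of one ensemble are resampled and split
into two pseudo-ensembles to build a per-residue null; a residue is
flagged when its observed divergence exceeds the null maximum.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import Trajectory

TORSION_KINDS = ("phi", "psi", "chi1")

# fourth atom of the N-CA-CB-X chi1 torsion, per residue type
CHI1_FOURTH_ATOM = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "PRO": "CG", "SER": "OG", "THR": "OG1",
    "TRP": "CG", "TYR": "CG", "VAL": "CG1",
}


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Signed dihedral angle (degrees, IUPAC convention) of four points.

    Accepts single points or (n, 3) stacks; returns a scalar or vector
    in (-180, 180].
    """
    p0, p1, p2, p3 = (np.atleast_2d(np.asarray(p, float)) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1, axis=1, keepdims=True)
    v = b0 - np.sum(b0 * b1, axis=1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=1, keepdims=True) * b1
    x = np.sum(v * w, axis=1)
    y = np.sum(np.cross(b1, v) * w, axis=1)
    ang = np.degrees(np.arctan2(y, x))
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    return float(ang[0]) if ang.shape == (1,) else ang


@dataclasses.dataclass
class DihedralEnsemble:
    """Blocked torsion samples for a set of residues.

    ``angles[(chain, residue_seq)][kind]`` is an (n_blocks,
    frames_per_block) array in degrees.
    """

    residues: list[tuple[str, int]]
    torsion_kinds: tuple[str, ...]
    angles: dict[tuple[str, int], dict[str, np.ndarray]]
    frames_per_block: int
    n_blocks: int

    def pooled(self, residue: tuple[str, int], kind: str) -> np.ndarray:
        return self.angles[residue][kind].ravel()

    def kinds_for(self, residue: tuple[str, int]) -> list[str]:
        return [k for k in self.torsion_kinds if k in self.angles[residue]]


@dataclasses.dataclass
class KLProfile:
    residues: list[tuple[str, int]]
    kl: np.ndarray              # nats, per residue
    kl_reverse: np.ndarray      # D(b||a), for symmetry diagnostics
    bootstrap_null: np.ndarray  # per-residue null threshold, nats
    significant: np.ndarray     # boolean

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chain": [c for c, _ in self.residues],
            "residue_seq": [r for _, r in self.residues],
            "kl_nats": self.kl,
            "kl_reverse_nats": self.kl_reverse,
            "null_max_nats": self.bootstrap_null,
            "significant": self.significant,
        })


def extract_dihedrals(traj: Trajectory, frames_per_block: int,
                      n_blocks: int = 4,
                      block_bounds: list[tuple[int, int]] | None = None,
                      ) -> DihedralEnsemble:
    """Blocked phi/psi/chi1 samples from a trajectory.

    ``block_bounds`` gives explicit frame-index ranges [start, stop);
    otherwise the trajectory is split into ``n_blocks`` equal blocks.
    Within each block, ``frames_per_block`` equally spaced frames are
    used.  Residues lacking backbone atoms are skipped with a warning;
    Gly/Ala (and anything without the chi1 atom) carry phi/psi only.
    """
    topo = traj.topology
    if block_bounds is None:
        edges = np.linspace(0, traj.n_frames, n_blocks + 1).astype(int)
        block_bounds = [(edges[i], edges[i + 1]) for i in range(n_blocks)]
    n_blocks = len(block_bounds)

    index = {(a.chain_id, a.residue_seq, a.name): i
             for i, a in enumerate(topo.atoms)}
    residues = topo.residues()

    # quadruple atom-index lists per residue and torsion kind
    quads: dict[tuple[str, int], dict[str, tuple[int, int, int, int]]] = {}
    for pos, (chain, seq, name) in enumerate(residues):
        key = (chain, seq)
        entry: dict[str, tuple[int, int, int, int]] = {}
        n = index.get((chain, seq, "N"))
        ca = index.get((chain, seq, "CA"))
        c = index.get((chain, seq, "C"))
        if n is None or ca is None or c is None:
            continue  # missing backbone: skip residue
        if pos > 0:
            pc, ps, _ = residues[pos - 1]
            cprev = index.get((pc, ps, "C")) if pc == chain and ps == seq - 1 else None
            if cprev is not None:
                entry["phi"] = (cprev, n, ca, c)
        if pos + 1 < len(residues):
            nc, ns, _ = residues[pos + 1]
            nnext = index.get((nc, ns, "N")) if nc == chain and ns == seq + 1 else None
            if nnext is not None:
                entry["psi"] = (n, ca, c, nnext)
        cb = index.get((chain, seq, "CB"))
        fourth = CHI1_FOURTH_ATOM.get(name)
        if cb is not None and fourth is not None:
            x = index.get((chain, seq, fourth))
            if x is not None:
                entry["chi1"] = (n, ca, cb, x)
        if entry:
            quads[key] = entry

    angles: dict[tuple[str, int], dict[str, np.ndarray]] = {
        key: {kind: np.empty((n_blocks, frames_per_block)) for kind in entry}
        for key, entry in quads.items()}
    for bi, (start, stop) in enumerate(block_bounds):
        if stop - start < 1:
            raise ValueError(f"empty block {bi}: [{start}, {stop})")
        take = np.round(np.linspace(start, stop - 1, frames_per_block)).astype(int)
        coords = traj.frames[take]  # (frames_per_block, n_atoms, 3)
        for key, entry in quads.items():
            for kind, (i0, i1, i2, i3) in entry.items():
                angles[key][kind][bi] = dihedral(
                    coords[:, i0], coords[:, i1], coords[:, i2], coords[:, i3])

    kept = [k for k in (r[:2] for r in residues) if k in angles]
    return DihedralEnsemble(kept, TORSION_KINDS, angles,
                            frames_per_block, n_blocks)


def kl_divergence(p_angles: np.ndarray, q_angles: np.ndarray,
                  n_bins: int = 30) -> float:
    """Histogram KL divergence D(p||q) in nats for circular angle samples."""
    p_angles = np.asarray(p_angles, float).ravel()
    q_angles = np.asarray(q_angles, float).ravel()
    if len(p_angles) == 0 or len(q_angles) == 0:
        raise ValueError("empty angle sample")
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    cp, _ = np.histogram(p_angles, bins=edges)
    cq, _ = np.histogram(q_angles, bins=edges)
    p = (cp + 0.5) / (cp.sum() + 0.5 * n_bins)
    q = (cq + 0.5) / (cq.sum() + 0.5 * n_bins)
    return float(np.sum(p * np.log(p / q)))


def _residue_kl(ens_a: DihedralEnsemble, ens_b: DihedralEnsemble,
                residue: tuple[str, int], n_bins: int) -> float:
    kinds = [k for k in ens_a.kinds_for(residue) if k in ens_b.angles[residue]]
    return sum(kl_divergence(ens_a.pooled(residue, k),
                             ens_b.pooled(residue, k), n_bins)
               for k in kinds)


def kl_profile(ens_a: DihedralEnsemble, ens_b: DihedralEnsemble,
               n_bootstrap: int = 100, seed: int = 0,
               n_bins: int = 30) -> KLProfile:
    """Observed per-residue D(a||b) with a block-bootstrap null.

    The null resamples ens_a's blocks with replacement, splits them into
    two pseudo-ensembles, and recomputes the divergence; the per-residue
    threshold is the maximum over ``n_bootstrap`` replicates.
    """
    if ens_a.n_blocks < 2 or ens_b.n_blocks < 2:
        raise ValueError("both ensembles need at least 2 blocks")
    shared = [r for r in ens_a.residues if r in set(ens_b.residues)]
    if not shared:
        raise ValueError("no shared residues between ensembles")

    observed = np.array([_residue_kl(ens_a, ens_b, r, n_bins) for r in shared])
    reverse = np.array([_residue_kl(ens_b, ens_a, r, n_bins) for r in shared])

    rng = np.random.default_rng(seed)
    null_max = np.zeros(len(shared))
    nb = ens_a.n_blocks
    half = max(nb // 2, 1)
    for _ in range(n_bootstrap):
        pick = rng.integers(0, nb, size=2 * half)
        ia, ib = pick[:half], pick[half:]
        for ri, r in enumerate(shared):
            total = 0.0
            for kind in ens_a.kinds_for(r):
                blocks = ens_a.angles[r][kind]
                total += kl_divergence(blocks[ia].ravel(),
                                       blocks[ib].ravel(), n_bins)
            null_max[ri] = max(null_max[ri], total)

    return KLProfile(shared, observed, reverse, null_max,
                     observed > null_max)
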