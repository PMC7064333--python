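"""Synthetic ground-truth generators for every pipeline input.

Three generators cover the pipeline's input classes:

* a geometric *gate model* — pseudo-residues on a spherical cage around a
  cavity, with a flexible gate over the cavity mouth whose open/closed
  state couples aperture distance to pocket volume.  It reproduces the
  statistical structure the analyses assume (loop flexibility <->
  pocket aperture <-> volume) without simulating dynamics;
* blocked von Mises torsion ensembles with a known set of shifted
  residues, for divergence power analysis;
* FP and BLI datasets drawn from the exact fitted-model equations plus
  Gaussian noise.

All generators are deterministic under a fixed seed and every dataset is
emitted together with its ground-truth table.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .binding import FPDataset, BLIDataset, fp_model, simulate_bli
from .divergence import DihedralEnsemble, TORSION_KINDS
from .io import Atom, Structure, Trajectory

# local geometry of a 5-atom pseudo-residue (N, CA, C, O, CB), Angstrom
_RESIDUE_TEMPLATE = {
    "N": np.array([-1.46, 0.0, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([0.87, 1.20, 0.0]),
    "O": np.array([2.10, 1.15, 0.2]),
    "CB": np.array([0.55, -1.20, 0.85]),
}
_ELEMENT_OF = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


@dataclasses.dataclass
class GateModelParams:
    """Geometry and statistics of the gated-cavity model."""

    n_scaffold_atoms: int = 40       # scaffold pseudo-residues on the cage
    cavity_radius: float = 8.0       # A
    gate_residues: int = 4
    gate_stiffness_open: float = 1.2    # positional fluctuation scale, A
    gate_stiffness_closed: float = 0.4  # A
    open_fraction: float = 0.5
    coupling: float = 1.0            # gate retraction per unit aperture
    n_frames: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.open_fraction <= 1.0:
            raise ValueError("open_fraction must be in [0, 1]")
        if self.cavity_radius <= 0:
            raise ValueError("cavity_radius must be positive")

    @property
    def scaffold_keys(self) -> list[tuple[str, int]]:
        return [("A", i + 1) for i in range(self.n_scaffold_atoms)]

    @property
    def gate_keys(self) -> list[tuple[str, int]]:
        n0 = self.n_scaffold_atoms
        return [("A", n0 + i + 1) for i in range(self.gate_residues)]

    @property
    def distance_pair(self) -> tuple[tuple[str, int], tuple[str, int]]:
        """Residue pair for the gate-distance coordinate: first gate
        residue vs the scaffold residue at the cavity floor."""
        return self.gate_keys[0], ("A", 1)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly uniform unit vectors."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def _place_residue(center: np.ndarray, seq: int, serial0: int) -> list[Atom]:
    atoms = []
    for k, (name, offset) in enumerate(_RESIDUE_TEMPLATE.items()):
        atoms.append(Atom(
            serial=serial0 + k, name=name, element=_ELEMENT_OF[name],
            residue_name="SER" if name != "CB" else "SER",
            residue_seq=seq, chain_id="A", position=center + offset))
    return atoms


def generate_gate_trajectory(params: GateModelParams
                             ) -> tuple[Trajectory, pd.DataFrame]:
    """One replicate trajectory of the gated cavity, plus its truth table.

    The cavity sits at the origin; the mouth opens toward +z.  Closed
    frames park the gate residues across the mouth inside the inclusion
    region, open frames retract them beyond the cage, so pocket volume
    and gate distance rise together.  The truth table carries the state
    label and the noise-free aperture fraction of every frame.
    """
    rng = np.random.default_rng(params.seed)
    r_wall = params.cavity_radius + 2.0

    # scaffold on the cage, leaving a mouth cone of 45 deg around +z
    mouth_cos = np.cos(np.radians(45.0))
    dirs = _fibonacci_sphere(params.n_scaffold_atoms * 2)
    dirs = dirs[dirs[:, 2] < mouth_cos][:params.n_scaffold_atoms]
    if len(dirs) < params.n_scaffold_atoms:
        raise ValueError("too few scaffold directions; lower n_scaffold_atoms")
    # residue 1 at the cavity floor (-z) for the distance reference
    order = np.argsort(dirs[:, 2])
    scaffold_centers = dirs[order] * r_wall

    # gate rest positions: a ring around the mouth
    ang = 2 * np.pi * np.arange(params.gate_residues) / params.gate_residues
    closed_theta, open_theta = np.radians(20.0), np.radians(45.0)
    r_closed = 0.6 * params.cavity_radius
    r_open = r_wall + 1.5 * params.coupling

    def gate_centers(aperture: float) -> np.ndarray:
        theta = closed_theta + aperture * (open_theta - closed_theta)
        radius = r_closed + aperture * (r_open - r_closed)
        return np.stack([radius * np.sin(theta) * np.cos(ang),
                         radius * np.sin(theta) * np.sin(ang),
                         radius * np.cos(theta) * np.ones_like(ang)], axis=1)

    atoms: list[Atom] = []
    for i, c in enumerate(scaffold_centers):
        atoms.extend(_place_residue(c, i + 1, len(atoms) + 1))
    for i, c in enumerate(gate_centers(0.0)):
        atoms.extend(_place_residue(c, params.n_scaffold_atoms + i + 1,
                                    len(atoms) + 1))
    topo = Structure(atoms, source=f"gate_seed{params.seed}")
    base = topo.coords
    n_scaffold_atoms_total = params.n_scaffold_atoms * len(_RESIDUE_TEMPLATE)

    states = (rng.random(params.n_frames) < params.open_fraction).astype(int)
    frames = np.empty((params.n_frames, len(atoms), 3))
    apertures = np.empty(params.n_frames)
    scaffold_sd = 0.15
    for f in range(params.n_frames):
        coords = base.copy()
        aperture = float(states[f])
        apertures[f] = aperture
        gc = gate_centers(aperture)
        sd = params.gate_stiffness_open if states[f] else params.gate_stiffness_closed
        for gi in range(params.gate_residues):
            lo = n_scaffold_atoms_total + gi * len(_RESIDUE_TEMPLATE)
            hi = lo + len(_RESIDUE_TEMPLATE)
            jitter = rng.normal(0.0, sd, size=3)
            coords[lo:hi] = (coords[lo:hi] - gate_centers(0.0)[gi]
                             + gc[gi] + jitter)
        coords[:n_scaffold_atoms_total] += rng.normal(
            0.0, scaffold_sd, size=(n_scaffold_atoms_total, 3))
        frames[f] = coords

    truth = pd.DataFrame({"frame": np.arange(params.n_frames),
                          "state": np.where(states == 1, "open", "closed"),
                          "aperture": apertures})
    traj = Trajectory(topo, frames, run_id=f"gate_seed{params.seed}")
    return traj, truth


# ---------------------------------------------------------------------------
# Torsion ensembles
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TorsionModelParams:
    """Von Mises torsion ensembles with a known shifted-residue set.

    ``components`` are (mean_deg, kappa, weight) mixture components used
    for every torsion of every residue in ensemble A; in ensemble B the
    residues in ``shifted_residues`` (0-based indices) have all their
    chi1 means shifted by ``shift_deg``.
    """

    n_residues: int = 12
    components: list[tuple[float, float, float]] = dataclasses.field(
        default_factory=lambda: [(-60.0, 8.0, 1.0)])
    shifted_residues: list[int] = dataclasses.field(default_factory=list)
    shift_deg: float = 60.0
    shifted_torsions: tuple[str, ...] = ("chi1",)
    frames_per_block: int = 5000
    n_blocks: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        w = sum(c[2] for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(c[1] <= 0 for c in self.components):
            raise ValueError("kappa must be positive")


def sample_von_mises_mixture(rng: np.random.Generator,
                             components: list[tuple[float, float, float]],
                             size: int) -> np.ndarray:
    """Angles in degrees in (-180, 180] from a von Mises mixture."""
    weights = np.array([c[2] for c in components])
    choice = rng.choice(len(components), size=size, p=weights)
    out = np.empty(size)
    for ci, (mu, kappa, _) in enumerate(components):
        m = choice == ci
        out[m] = np.degrees(rng.vonmises(np.radians(mu), kappa, size=m.sum()))
    out = np.where(out <= -180.0, out + 360.0, out)
    return out


def generate_torsion_ensembles(params: TorsionModelParams
                               ) -> tuple[DihedralEnsemble, DihedralEnsemble, set[int]]:
    """(ensemble A, ensemble B, truth: shifted residue indices)."""
    rng = np.random.default_rng(params.seed)
    shifted = set(params.shifted_residues)
    residues = [("A", i + 1) for i in range(params.n_residues)]

    def make(which: str) -> DihedralEnsemble:
        angles: dict[tuple[str, int], dict[str, np.ndarray]] = {}
        for ri, key in enumerate(residues):
            per_kind = {}
            for kind in TORSION_KINDS:
                comps = params.components
                if which == "B" and ri in shifted and kind in params.shifted_torsions:
                    comps = [(mu + params.shift_deg, k, w) for mu, k, w in comps]
                sample = sample_von_mises_mixture(
                    rng, comps, params.n_blocks * params.frames_per_block)
                per_kind[kind] = sample.reshape(params.n_blocks,
                                                params.frames_per_block)
            angles[key] = per_kind
        return DihedralEnsemble(residues, TORSION_KINDS, angles,
                                params.frames_per_block, params.n_blocks)

    return make("A"), make("B"), shifted


# ---------------------------------------------------------------------------
# Binding data
# ---------------------------------------------------------------------------

FP_TRUTH_DEFAULT = {"Kd": 1e-6, "Bmax": 150.0, "ns": 0.0, "bg": 50.0}
BLI_TRUTH_DEFAULT = {"kon": 1e5, "koff": 6.5e-3, "Rmax": 1.0}


def generate_fp_data(truth: dict[str, float] | None = None,
                     noise_sd: float = 2.0, seed: int = 0,
                     n_points: int = 12, top: float | None = None,
                     dilution: float = 2.0) -> tuple[FPDataset, dict[str, float]]:
    """An FP dose-response from the one-site total model plus noise.

    The titration is an ``n_points``-step ``dilution``-fold series from
    ``top`` (default 50x the true Kd) down, which brackets the Kd.
    """
    truth = dict(FP_TRUTH_DEFAULT, **(truth or {}))
    rng = np.random.default_rng(seed)
    top = top if top is not None else 50.0 * truth["Kd"]
    conc = top / dilution ** np.arange(n_points)
    y = fp_model(conc, truth["Kd"], truth["Bmax"], truth["ns"], truth["bg"])
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return FPDataset(conc, y, replicate_id=f"seed{seed}"), truth


def generate_bli_data(truth: dict[str, float] | None = None,
                      noise_frac: float = 0.01, seed: int = 0,
                      n_concentrations: int = 8, top: float | None = None,
                      dilution: float = 2.0) -> tuple[BLIDataset, dict[str, float]]:
    """BLI sensorgrams from the 1:1 model plus Gaussian noise.

    Concentrations form a 2-fold series from ``top`` (default 10x the
    true Kd); noise is ``noise_frac`` of Rmax.
    """
    truth = dict(BLI_TRUTH_DEFAULT, **(truth or {}))
    kd = truth["koff"] / truth["kon"]
    top = top if top is not None else 10.0 * kd
    conc = top / dilution ** np.arange(n_concentrations)
    data = simulate_bli((truth["kon"], truth["koff"], truth["Rmax"]),
                        conc, noise_sd=noise_frac * truth["Rmax"], seed=seed)
    truth = dict(truth, Kd=kd)
    return data, truth


def generate_binding_data(model: str, truth: dict[str, float] | None = None,
                          noise: float | None = None, seed: int = 0):
    """Dispatch to the FP or BLI generator (``model`` is "fp" or "bli")."""
    if model == "fp":
        kw = {} if noise is None else {"noise_sd": noise}
        return generate_fp_data(truth, seed=seed, **kw)
    if model == "bli":
        kw = {} if noise is None else {"noise_frac": noise}
        return generate_bli_data(truth, seed=seed, **kw)
    raise ValueError("model must be 'fp' or 'bli'")
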