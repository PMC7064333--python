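"""Structures, trajectories and selections.

The in-memory model is deliberately small: an :class:`Atom` is a named
point with an element and a mass, a :class:`Structure` is an ordered atom
list, and a :class:`Trajectory` is a topology plus an ``(n_frames,
n_atoms, 3)`` coordinate array in Angstrom.  Author residue numbering (as
printed in PDB entries) is the public addressing scheme throughout, since
that is how pocket-lining and loop residues are named in the literature.

PDB reading/writing is delegated to :mod:`gemmi`; alternate locations are
resolved to the highest-occupancy conformer (first listed on ties) and
hydrogens are optional everywhere downstream.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

from .elements import atomic_mass, element_from_atom_name

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U",
}


@dataclasses.dataclass
class Atom:
    """One atom: identity plus a position in Angstrom."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray  # shape (3,), Angstrom
    mass: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position components must be finite")
        if self.mass == 0.0:
            self.mass = atomic_mass(self.element)

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_seq)


class Structure:
    """An ordered collection of atoms from one model."""

    def __init__(self, atoms: Sequence[Atom], source: str = "", model: int = 1):
        if not atoms:
            raise ValueError("structure must contain at least one atom")
        self.atoms = list(atoms)
        self.source = source
        self.model = model

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [dataclasses.replace(a, position=coords[i])
                 for i, a in enumerate(self.atoms)]
        return Structure(atoms, source=self.source, model=self.model)

    # ---- lookups -------------------------------------------------------

    def residue_atoms(self, chain_id: str, residue_seq: int) -> list[Atom]:
        out = [a for a in self.atoms
               if a.chain_id == chain_id and a.residue_seq == residue_seq]
        if not out:
            raise KeyError(f"residue {chain_id}:{residue_seq} not in structure")
        return out

    def atom(self, chain_id: str, residue_seq: int, name: str) -> Atom:
        for a in self.residue_atoms(chain_id, residue_seq):
            if a.name == name:
                return a
        raise KeyError(f"atom {chain_id}:{residue_seq}:{name} not found")

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain_id, residue_seq, residue_name) triples."""
        seen: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key, a.residue_name)
        return [(c, r, n) for (c, r), n in seen.items()]

    def ca_index(self) -> dict[tuple[str, int], int]:
        """Map (chain, residue_seq) -> index of the Calpha atom."""
        out: dict[tuple[str, int], int] = {}
        for i, a in enumerate(self.atoms):
            if a.name == "CA" and a.element == "C" and a.residue_key not in out:
                out[a.residue_key] = i
        return out

    def chain_sequence(self, chain_id: str) -> tuple[str, list[int]]:
        """One-letter sequence of a chain's resolved amino acids.

        Returns the sequence and the parallel residue_seq list.
        """
        seq, nums = [], []
        for c, r, name in self.residues():
            if c == chain_id and name in THREE_TO_ONE:
                seq.append(THREE_TO_ONE[name])
                nums.append(r)
        return "".join(seq), nums


@dataclasses.dataclass
class Trajectory:
    """Topology plus ordered frames of coordinates (Angstrom)."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval: float | None = None  # ps between stored frames
    run_id: str = "run1"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.topology):
            raise ValueError("frame/topology atom-count mismatch")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame(self, i: int) -> Structure:
        """The i-th frame as a Structure."""
        return self.topology.with_coords(self.frames[i])


@dataclasses.dataclass
class ResidueSelection:
    """A named set of residues addressed by (chain_id, residue_seq)."""

    label: str
    members: list[tuple[str, int]]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("selection must be non-empty")
        self.members = [(c, int(r)) for c, r in self.members]

    @classmethod
    def from_range(cls, label: str, chain_id: str, first: int, last: int) -> "ResidueSelection":
        return cls(label, [(chain_id, r) for r in range(first, last + 1)])

    @classmethod
    def parse(cls, text: str, label: str = "selection") -> "ResidueSelection":
        """Parse "A:36-49" or "A:36-49,B:10-12" style range strings."""
        members: list[tuple[str, int]] = []
        for part in text.split(","):
            chain, _, rng = part.strip().partition(":")
            if not rng:
                raise ValueError(f"bad selection syntax: {part!r}")
            lo, _, hi = rng.partition("-")
            hi = hi or lo
            members.extend((chain, r) for r in range(int(lo), int(hi) + 1))
        return cls(label, members)

    def validate(self, structure: Structure) -> None:
        present = {a.residue_key for a in structure.atoms}
        missing = [m for m in self.members if m not in present]
        if missing:
            raise ValueError(f"selection residues absent from topology: {missing}")


# ---------------------------------------------------------------------------
# PDB reading / writing (via gemmi)
# ---------------------------------------------------------------------------

def _gemmi_model_to_atoms(model: gemmi.Model) -> list[Atom]:
    atoms: list[Atom] = []
    serial = 0
    for chain in model:
        for residue in chain:
            # resolve altlocs: keep highest-occupancy conformer per atom name,
            # first listed on ties
            best: dict[str, gemmi.Atom] = {}
            for at in residue:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            for at in residue:
                if best.get(at.name) is not at:
                    continue
                serial += 1
                if at.element and at.element.name != "X":
                    element = at.element.name.upper()
                else:
                    element = element_from_atom_name(at.name)
                atoms.append(Atom(
                    serial=serial,
                    name=at.name,
                    element=element,
                    residue_name=residue.name,
                    residue_seq=residue.seqid.num,
                    chain_id=chain.name,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                ))
    return atoms


def read_structure(path: str | Path, model: int | None = None) -> Structure:
    """Read one model of a PDB file.

    ``model`` is the 1-based MODEL number; default is the first model.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    if model is None:
        gm = st[0]
        model_no = 1
    else:
        idx = model - 1
        if idx < 0 or idx >= len(st):
            raise ValueError(f"model {model} absent from {path} ({len(st)} models)")
        gm = st[idx]
        model_no = model
    atoms = _gemmi_model_to_atoms(gm)
    if not atoms:
        raise ValueError(f"no ATOM records in {path}")
    return Structure(atoms, source=path.stem, model=model_no)


def read_trajectory(path: str | Path | Sequence[str | Path],
                    topology: Structure | None = None,
                    run_id: str | None = None) -> Trajectory | list[Trajectory]:
    """Read a conformational ensemble.

    Accepts a multi-model PDB file (each MODEL is one frame), a CSV frame
    table (columns frame, atom_serial, x, y, z — requires ``topology``),
    or a list of paths, which yields one Trajectory per path with
    ``run_id`` taken from each file stem.
    """
    if isinstance(path, (list, tuple)):
        return [read_trajectory(p, topology=topology) for p in path]
    path = Path(path)
    if path.suffix.lower() in (".csv", ".tsv"):
        if topology is None:
            raise ValueError("frame-table input requires a topology")
        return _read_frame_table(path, topology, run_id=run_id or path.stem)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    topo = Structure(_gemmi_model_to_atoms(st[0]), source=path.stem, model=1)
    frames = np.empty((len(st), len(topo), 3))
    for i, gm in enumerate(st):
        atoms = _gemmi_model_to_atoms(gm)
        if len(atoms) != len(topo):
            raise ValueError(f"model {i + 1} of {path} has {len(atoms)} atoms, "
                             f"expected {len(topo)}")
        frames[i] = [a.position for a in atoms]
    return Trajectory(topo, frames, run_id=run_id or path.stem)


def _read_frame_table(path: Path, topology: Structure, run_id: str) -> Trajectory:
    df = pd.read_csv(path)
    required = {"frame", "atom_serial", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"frame table needs columns {sorted(required)}")
    serial_order = {a.serial: i for i, a in enumerate(topology.atoms)}
    n_atoms = len(topology)
    frame_ids = sorted(df["frame"].unique())
    frames = np.empty((len(frame_ids), n_atoms, 3))
    for fi, fid in enumerate(frame_ids):
        sub = df[df["frame"] == fid]
        if len(sub) != n_atoms:
            raise ValueError(f"frame {fid} has {len(sub)} atoms, expected {n_atoms}")
        for _, row in sub.iterrows():
            frames[fi, serial_order[int(row["atom_serial"])]] = (
                row["x"], row["y"], row["z"])
    return Trajectory(topology, frames, run_id=run_id)


def _structure_to_gemmi_model(structure: Structure, coords: np.ndarray,
                              name: str) -> gemmi.Model:
    # gemmi's add_* methods copy their argument, so containers must be
    # fully populated bottom-up before being added
    grouped: dict[str, list[tuple[tuple[str, int], list[int]]]] = {}
    for i, a in enumerate(structure.atoms):
        chain_entries = grouped.setdefault(a.chain_id, [])
        if not chain_entries or chain_entries[-1][0] != a.residue_key:
            chain_entries.append((a.residue_key, []))
        chain_entries[-1][1].append(i)

    model = gemmi.Model(name)
    for chain_id, entries in grouped.items():
        chain = gemmi.Chain(chain_id)
        for (_, seq), atom_indices in entries:
            first = structure.atoms[atom_indices[0]]
            res = gemmi.Residue()
            res.name = first.residue_name
            res.seqid = gemmi.SeqId(seq, " ")
            for i in atom_indices:
                a = structure.atoms[i]
                at = gemmi.Atom()
                at.name = a.name
                at.element = gemmi.Element(a.element.capitalize())
                at.occ = 1.0
                at.pos = gemmi.Position(*coords[i])
                res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)
    return model


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a single-model PDB file."""
    st = gemmi.Structure()
    st.add_model(_structure_to_gemmi_model(structure, structure.coords, "1"))
    st.setup_entities()
    Path(path).write_text(st.make_pdb_string())


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB file, one MODEL per frame."""
    st = gemmi.Structure()
    for i in range(traj.n_frames):
        st.add_model(_structure_to_gemmi_model(traj.topology, traj.frames[i],
                                               str(i + 1)))
    st.setup_entities()
    Path(path).write_text(st.make_pdb_string())


def write_frame_table(traj: Trajectory, path: str | Path) -> None:
    """Write frames as a CSV table (frame, atom_serial, x, y, z)."""
    serials = np.array([a.serial for a in traj.topology.atoms])
    rows = []
    for f in range(traj.n_frames):
        rows.append(pd.DataFrame({
            "frame": f,
            "atom_serial": serials,
            "x": traj.frames[f, :, 0],
            "y": traj.frames[f, :, 1],
            "z": traj.frames[f, :, 2],
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.3f")


# ---------------------------------------------------------------------------
# Subsampling
# ---------------------------------------------------------------------------

def subsample(traj: Trajectory, n: int | None = None,
              stride: int | None = None) -> Trajectory:
    """Equally spaced frame subset, always including frame 0.

    Exactly one of ``n`` (number of frames) or ``stride`` must be given.
    ``n``-mode uses round(linspace) so 251 frames from a 501-frame run
    gives indices 0, 2, 4, ..., 500.
    """
    if (n is None) == (stride is None):
        raise ValueError("give exactly one of n or stride")
    if n is not None:
        if n > traj.n_frames:
            raise ValueError(f"requested {n} frames from {traj.n_frames}")
        if n == 1:
            idx = np.array([0])
        else:
            idx = np.round(np.linspace(0, traj.n_frames - 1, n)).astype(int)
    else:
        if stride < 1:
            raise ValueError("stride must be >= 1")
        idx = np.arange(0, traj.n_frames, stride)
    interval = None
    if traj.frame_interval is not None and len(idx) > 1:
        interval = traj.frame_interval * (idx[1] - idx[0])
    return Trajectory(traj.topology, traj.frames[idx],
                      frame_interval=interval, run_id=traj.run_id)
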