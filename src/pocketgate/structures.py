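"""Pairwise structure comparison: superposition, RMSD, displacements, identity.

Superposition is the least-squares optimal rigid transform (Kabsch).
Cross-protein Calpha pairing is derived from a global sequence alignment
(BLOSUM62, affine gaps 11/1) restricted to columns where both residues
are resolved, so homologous proteins can be compared without a shared
numbering.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import Structure, ResidueSelection

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclasses.dataclass
class SuperpositionResult:
    rotation: np.ndarray      # 3x3, orthonormal, det +1
    translation: np.ndarray   # 3-vector, Angstrom
    rmsd: float               # Angstrom over the fitted atom set
    atom_pairs: list[tuple[int, int]]

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Map coordinates from frame b into frame a."""
        return coords @ self.rotation.T + self.translation


@dataclasses.dataclass
class AlignmentResult:
    aligned_pairs: list[tuple[int, int]]
    percent_identity: float   # % over aligned non-gap columns
    score: float


def align_sequences(seq_a: str, seq_b: str) -> AlignmentResult:
    """Global alignment with affine gaps (BLOSUM62, open 11, extend 1)."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    for s in (seq_a, seq_b):
        bad = set(s) - _STANDARD_AA
        if bad:
            raise ValueError(f"non-standard residues: {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    matches = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            pairs.append((i, j))
            if seq_a[i] == seq_b[j]:
                matches += 1
    if not pairs:
        raise ValueError("alignment produced no aligned columns")
    identity = 100.0 * matches / len(pairs)
    return AlignmentResult(pairs, identity, float(aln.score))


def kabsch(ref: np.ndarray, mov: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rotation/translation mapping ``mov`` onto ``ref``.

    Returns (R, t, rmsd) with mapped points = mov @ R.T + t.
    """
    ref = np.asarray(ref, float)
    mov = np.asarray(mov, float)
    if ref.shape != mov.shape or ref.shape[0] < 3:
        raise ValueError("need >= 3 paired points of equal count")
    cref = ref.mean(axis=0)
    cmov = mov.mean(axis=0)
    a = ref - cref
    b = mov - cmov
    h = b.T @ a
    u, s, vt = np.linalg.svd(h)
    # guard against degenerate (collinear/coincident) point sets
    if s[1] < 1e-9 * max(s[0], 1e-30):
        raise ValueError("degenerate point set: points collinear or coincident")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = cref - rot @ cmov
    moved = mov @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rot, t, rmsd


def superpose(a: Structure, b: Structure,
              pairs: list[tuple[int, int]]) -> SuperpositionResult:
    """Least-squares rigid superposition of b onto a over atom-index pairs."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 atom pairs")
    ref = np.array([a.atoms[i].position for i, _ in pairs])
    mov = np.array([b.atoms[j].position for _, j in pairs])
    rot, t, rmsd = kabsch(ref, mov)
    return SuperpositionResult(rot, t, rmsd, list(pairs))


def ca_pairs_by_alignment(a: Structure, b: Structure,
                          chain_a: str | None = None,
                          chain_b: str | None = None,
                          exclude_a: ResidueSelection | None = None,
                          ) -> list[tuple[int, int]]:
    """Calpha atom-index pairs for two homologous structures.

    Residue equivalence comes from a global sequence alignment of the
    resolved chains; only columns where both Calphas are present are
    paired.  ``exclude_a`` drops pairs whose a-side residue is in the
    selection (e.g. to superpose on the rigid core while a loop moves).
    """
    chain_a = chain_a or a.atoms[0].chain_id
    chain_b = chain_b or b.atoms[0].chain_id
    seq_a, nums_a = a.chain_sequence(chain_a)
    seq_b, nums_b = b.chain_sequence(chain_b)
    aln = align_sequences(seq_a, seq_b)
    ca_a = a.ca_index()
    ca_b = b.ca_index()
    excluded = set(exclude_a.members) if exclude_a else set()
    pairs = []
    for i, j in aln.aligned_pairs:
        key_a = (chain_a, nums_a[i])
        key_b = (chain_b, nums_b[j])
        if key_a in excluded:
            continue
        if key_a in ca_a and key_b in ca_b:
            pairs.append((ca_a[key_a], ca_b[key_b]))
    return pairs


def ca_rmsd(a: Structure, b: Structure,
            residues: list[int] | None = None,
            chain_a: str | None = None,
            chain_b: str | None = None,
            by_alignment: bool = True) -> float:
    """Calpha RMSD after optimal superposition.

    With ``residues`` given, pairing is by shared residue numbers on the
    chosen chains (for the same protein in two crystal forms); otherwise
    sequence-alignment pairing is used.
    """
    chain_a = chain_a or a.atoms[0].chain_id
    chain_b = chain_b or b.atoms[0].chain_id
    if residues is not None:
        ca_a = a.ca_index()
        ca_b = b.ca_index()
        pairs = [(ca_a[(chain_a, r)], ca_b[(chain_b, r)]) for r in residues
                 if (chain_a, r) in ca_a and (chain_b, r) in ca_b]
    elif by_alignment:
        pairs = ca_pairs_by_alignment(a, b, chain_a, chain_b)
    else:
        ca_a = a.ca_index()
        ca_b = b.ca_index()
        shared = [k[1] for k in ca_a if (chain_b, k[1]) in ca_b and k[0] == chain_a]
        pairs = [(ca_a[(chain_a, r)], ca_b[(chain_b, r)]) for r in shared]
    return superpose(a, b, pairs).rmsd


def _probe_point(structure: Structure, chain: str, residue_seq: int,
                 rule: str = "sidechain_centroid") -> np.ndarray:
    """Reference point of a probe residue.

    ``sidechain_centroid``: unweighted centroid of side-chain heavy atoms,
    falling back to Calpha for Gly/Ala-like residues without one;
    ``ca``: the Calpha position; ``com``: mass-weighted all-heavy-atom
    center of mass.
    """
    atoms = structure.residue_atoms(chain, residue_seq)
    heavy = [a for a in atoms if a.element != "H"]
    backbone = {"N", "CA", "C", "O", "OXT"}
    if rule == "ca":
        for a in atoms:
            if a.name == "CA":
                return a.position.copy()
        raise ValueError(f"no CA in probe residue {chain}:{residue_seq}")
    if rule == "com":
        w = np.array([a.mass for a in heavy])
        pts = np.array([a.position for a in heavy])
        return (w[:, None] * pts).sum(axis=0) / w.sum()
    side = [a for a in heavy if a.name not in backbone]
    if not side:
        return _probe_point(structure, chain, residue_seq, rule="ca")
    return np.mean([a.position for a in side], axis=0)


def residue_displacement(a: Structure, b: Structure,
                         core_pairs: list[tuple[int, int]],
                         probe: tuple[str, int],
                         probe_b: tuple[str, int] | None = None,
                         rule: str = "sidechain_centroid") -> float:
    """Displacement (Angstrom) of a probe residue between two structures.

    b is superposed onto a over ``core_pairs`` first, so the probe's
    motion is measured relative to the shared rigid core.  ``probe_b``
    addresses the equivalent residue in b when numbering differs.
    """
    probe_b = probe_b or probe
    sup = superpose(a, b, core_pairs)
    pa = _probe_point(a, *probe, rule=rule)
    pb = _probe_point(b, *probe_b, rule=rule)
    return float(np.linalg.norm(pa - sup.apply(pb[None, :])[0]))
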