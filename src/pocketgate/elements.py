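"""Fixed element tables: atomic masses and van der Waals radii.

A single internal table (rather than a library lookup that may change
between versions) keeps grid-based pocket volumes bit-reproducible.
Radii are the Bondi (1964) consensus values used by most cavity tools;
masses are standard atomic weights rounded to 3 decimals.
"""

from __future__ import annotations

# element symbol -> (mass in Da, van der Waals radius in Angstrom)
_ELEMENTS: dict[str, tuple[float, float]] = {
    "H": (1.008, 1.20),
    "C": (12.011, 1.70),
    "N": (14.007, 1.55),
    "O": (15.999, 1.52),
    "S": (32.06, 1.80),
    "P": (30.974, 1.80),
    "SE": (78.971, 1.90),
    "F": (18.998, 1.47),
    "CL": (35.45, 1.75),
    "BR": (79.904, 1.85),
    "I": (126.904, 1.98),
    "ZN": (65.38, 1.39),
    "MG": (24.305, 1.73),
    "CA": (40.078, 2.31),
    "NA": (22.990, 2.27),
    "K": (39.098, 2.75),
    "FE": (55.845, 2.00),
    "MN": (54.938, 2.00),
}

# fallback for unknown elements: generic heavy-atom values
_DEFAULT = (12.011, 1.70)


def atomic_mass(element: str) -> float:
    """Mass in Da for an element symbol (case-insensitive)."""
    return _ELEMENTS.get(element.upper(), _DEFAULT)[0]


def vdw_radius(element: str) -> float:
    """Van der Waals radius in Angstrom for an element symbol."""
    return _ELEMENTS.get(element.upper(), _DEFAULT)[1]


def element_from_atom_name(name: str) -> str:
    """Infer the element from a PDB atom name when columns 77-78 are blank.

    Two-letter elements in standard residues are rare; the common protein
    cases (C/N/O/S plus H variants like ``1HB``/``HG1``) reduce to the
    first alphabetic character.
    """
    stripped = name.strip()
    # names like "1HB " start with a digit
    for ch in stripped:
        if ch.isalpha():
            first = ch.upper()
            break
    else:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    two = stripped[:2].upper()
    if two in ("SE", "ZN", "MG", "NA", "CL", "BR", "FE", "MN"):
        return two
    return first
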