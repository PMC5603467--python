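"""Bundled periodic-table data.

Single-bond covalent radii (Cordero et al. 2008 consensus values, Å; low-spin
values for the ambiguous first-row transition metals), element-symbol
canonicalization, AutoDock atom-type to element mapping, and the
name-justification rule used to infer elements from PDB atom names when the
element columns are blank.
"""

from __future__ import annotations

import warnings

#: Single-bond covalent radii in Å, H through Rn.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Sc": 1.70, "Ti": 1.60, "V": 1.53, "Cr": 1.39,
    "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24, "Cu": 1.32, "Zn": 1.22,
    "Ga": 1.22, "Ge": 1.20, "As": 1.19, "Se": 1.20, "Br": 1.20, "Kr": 1.16,
    "Rb": 2.20, "Sr": 1.95, "Y": 1.90, "Zr": 1.75, "Nb": 1.64, "Mo": 1.54,
    "Tc": 1.47, "Ru": 1.46, "Rh": 1.42, "Pd": 1.39, "Ag": 1.45, "Cd": 1.44,
    "In": 1.42, "Sn": 1.39, "Sb": 1.39, "Te": 1.38, "I": 1.39, "Xe": 1.40,
    "Cs": 2.44, "Ba": 2.15,
    "La": 2.07, "Ce": 2.04, "Pr": 2.03, "Nd": 2.01, "Pm": 1.99, "Sm": 1.98,
    "Eu": 1.98, "Gd": 1.96, "Tb": 1.94, "Dy": 1.92, "Ho": 1.92, "Er": 1.89,
    "Tm": 1.90, "Yb": 1.87, "Lu": 1.87,
    "Hf": 1.75, "Ta": 1.70, "W": 1.62, "Re": 1.51, "Os": 1.44, "Ir": 1.41,
    "Pt": 1.36, "Au": 1.36, "Hg": 1.32,
    "Tl": 1.45, "Pb": 1.46, "Bi": 1.48, "Po": 1.40, "At": 1.50, "Rn": 1.50,
}

#: Radius used (with a warning) for elements missing from the table.
FALLBACK_RADIUS = 0.77

KNOWN_ELEMENTS = frozenset(COVALENT_RADII)

# Case-normalized lookup: "FE" / "fe" / "Fe" -> "Fe"
_UPPER_TO_SYMBOL = {sym.upper(): sym for sym in KNOWN_ELEMENTS}

#: AutoDock (PDBQT) atom types -> element symbols. Types absent from this map
#: are kept verbatim by the PDBQT reader in an auxiliary column.
AUTODOCK_TYPE_TO_ELEMENT: dict[str, str] = {
    "A": "C", "C": "C", "CG0": "C", "G0": "C",
    "N": "N", "NA": "N", "NS": "N",
    "OA": "O", "OS": "O", "O": "O",
    "SA": "S", "S": "S",
    "H": "H", "HD": "H", "HS": "H",
    "F": "F", "CL": "Cl", "BR": "Br", "I": "I", "P": "P",
    "MG": "Mg", "MN": "Mn", "ZN": "Zn", "CA": "Ca", "FE": "Fe",
    "K": "K", "NI": "Ni", "CU": "Cu", "CO": "Co", "CD": "Cd",
    "SR": "Sr", "NB": "Nb", "CS": "Cs", "HG": "Hg",
}


def canonicalize(symbol: str) -> str:
    """Return the canonical capitalization of ``symbol`` ("FE" -> "Fe").

    Unknown symbols are returned with first-letter capitalization so the
    caller can still store them; radius lookups fall back to
    :data:`FALLBACK_RADIUS` for such atoms.
    """
    s = symbol.strip()
    if not s:
        return ""
    return _UPPER_TO_SYMBOL.get(s.upper(), s.capitalize())


def covalent_radius(symbol: str) -> float:
    """Covalent radius in Å; unknown elements get the fallback with a warning."""
    r = COVALENT_RADII.get(canonicalize(symbol))
    if r is None:
        warnings.warn(
            f"unknown element {symbol!r}: using fallback covalent radius "
            f"{FALLBACK_RADIUS} Å",
            stacklevel=2,
        )
        return FALLBACK_RADIUS
    return r


def infer_element_from_name(raw_name: str) -> str:
    """Infer an element symbol from a raw 4-character PDB atom-name field.

    Rule: strip digits and primes from the name; if the name field starts in
    its first column (no leading blank) and the first two characters of the
    stripped name form a known element symbol (case-normalized), use it;
    otherwise use the first alphabetic character.
    """
    starts_at_first_column = bool(raw_name) and raw_name[0] != " "
    stripped = "".join(
        ch for ch in raw_name.strip() if not (ch.isdigit() or ch in "'′*")
    )
    if not stripped:
        return ""
    if starts_at_first_column and len(stripped) >= 2:
        two = _UPPER_TO_SYMBOL.get(stripped[:2].upper())
        if two is not None:
            return two
    for ch in stripped:
        if ch.isalpha():
            one = _UPPER_TO_SYMBOL.get(ch.upper())
            return one if one is not None else ch.upper()
    return ""
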