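"""Amino-acid atom-name templates and naming-convention utilities.

Templates follow PDB v3 atom nomenclature (heavy atoms plus hydrogens,
neutral protonation states, no terminal variants).  They are used to build
synthetic topologies and to resolve which hydrogens belong to methyl groups.
"""
from __future__ import annotations

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

STANDARD_RESIDUES = frozenset(THREE_TO_ONE.values())

_BACKBONE = [("N", "N"), ("H", "H"), ("CA", "C"), ("HA", "H"), ("C", "C"), ("O", "O")]
_BACKBONE_GLY = [("N", "N"), ("H", "H"), ("CA", "C"), ("HA2", "H"), ("HA3", "H"),
                 ("C", "C"), ("O", "O")]
_BACKBONE_PRO = [("N", "N"), ("CA", "C"), ("HA", "H"), ("C", "C"), ("O", "O")]

# Side-chain (name, element) lists keyed by one-letter code.
_SIDECHAINS: dict[str, list[tuple[str, str]]] = {
    "G": [],
    "A": [("CB", "C"), ("HB1", "H"), ("HB2", "H"), ("HB3", "H")],
    "S": [("CB", "C"), ("HB2", "H"), ("HB3", "H"), ("OG", "O"), ("HG", "H")],
    "C": [("CB", "C"), ("HB2", "H"), ("HB3", "H"), ("SG", "S"), ("HG", "H")],
    "T": [("CB", "C"), ("HB", "H"), ("OG1", "O"), ("HG1", "H"),
          ("CG2", "C"), ("HG21", "H"), ("HG22", "H"), ("HG23", "H")],
    "V": [("CB", "C"), ("HB", "H"),
          ("CG1", "C"), ("HG11", "H"), ("HG12", "H"), ("HG13", "H"),
          ("CG2", "C"), ("HG21", "H"), ("HG22", "H"), ("HG23", "H")],
    "L": [("CB", "C"), ("HB2", "H"), ("HB3", "H"), ("CG", "C"), ("HG", "H"),
          ("CD1", "C"), ("HD11", "H"), ("HD12", "H"), ("HD13", "H"),
          ("CD2", "C"), ("HD21", "H"), ("HD22", "H"), ("HD23", "H")],
    "I": [("CB", "C"), ("HB", "H"),
          ("CG1", "C"), ("HG12", "H"), ("HG13", "H"),
          ("CG2", "C"), ("HG21", "H"), ("HG22", "H"), ("HG23", "H"),
          ("CD1", "C"), ("HD11", "H"), ("HD12", "H"), ("HD13", "H")],
    "M": [("CB", "C"), ("HB2", "H"), ("HB3", "H"),
          ("CG", "C"), ("HG2", "H"), ("HG3", "H"), ("SD", "S"),
          ("CE", "C"), ("HE1", "H"), ("HE2", "H"), ("HE3", "H")],
    "P": [("CB", "C"), ("HB2", "H"), ("HB3", "H"),
          ("CG", "C"), ("HG2", "H"), ("HG3", "H"),
          ("CD", "C"), ("HD2", "H"), ("HD3", "H")],
    "F": [("CB", "C"), ("HB2", "H"), ("HB3", "H"), ("CG", "C"),
          ("CD1", "C"), ("HD1", "H"), ("CD2", "C"), ("HD2", "H"),
          ("CE1", "C"), ("HE1", "H"), ("CE2", "C"), ("HE2", "H"),
          ("CZ", "C"), ("HZ", "H")],
    "Y": [("CB", "C"), ("HB2", "H"), ("HB3", "H"), ("CG", "C"),
          ("CD1", "C"), ("HD1", "H"), ("CD2", "C"), ("HD2", "H"),
          ("CE1", "C"), ("HE1", "H"), ("CE2", "C"), ("HE2", "H"),
          ("CZ", "C"), ("OH", "O"), ("HH", "H")],
    "W": [("CB", "C"), ("HB2", "H"), ("HB3", "H"), ("CG", "C"),
          ("CD1", "C"), ("HD1", "H"), ("CD2", "C"),
          ("NE1", "N"), ("HE1", "H"), ("CE2", "C"), ("CE3", "C"), ("HE3", "H"),
          ("CZ2", "C"), ("HZ2", "H"), ("CZ3", "C"), ("HZ3", "H"),
          ("CH2", "C"), ("HH2", "H")],
    "D": [("CB", "C"), ("HB2", "H"), ("HB3", "H"),
          ("CG", "C"), ("OD1", "O"), ("OD2", "O")],
    "E": [("CB", "C"), ("HB2", "H"), ("HB3", "H"),
          ("CG", "C"), ("HG2", "H"), ("HG3", "H"),
          ("CD", "C"), ("OE1", "O"), ("OE2", "O")],
    "N": [("CB", "C"), ("HB2", "H"), ("HB3", "H"),
          ("CG", "C"), ("OD1", "O"), ("ND2", "N"), ("HD21", "H"), ("HD22", "H")],
    "Q": [("CB", "C"), ("HB2", "H"), ("HB3", "H"),
          ("CG", "C"), ("HG2", "H"), ("HG3", "H"),
          ("CD", "C"), ("OE1", "O"), ("NE2", "N"), ("HE21", "H"), ("HE22", "H")],
    "K": [("CB", "C"), ("HB2", "H"), ("HB3", "H"),
          ("CG", "C"), ("HG2", "H"), ("HG3", "H"),
          ("CD", "C"), ("HD2", "H"), ("HD3", "H"),
          ("CE", "C"), ("HE2", "H"), ("HE3", "H"),
          ("NZ", "N"), ("HZ1", "H"), ("HZ2", "H"), ("HZ3", "H")],
    "R": [("CB", "C"), ("HB2", "H"), ("HB3", "H"),
          ("CG", "C"), ("HG2", "H"), ("HG3", "H"),
          ("CD", "C"), ("HD2", "H"), ("HD3", "H"),
          ("NE", "N"), ("HE", "H"), ("CZ", "C"),
          ("NH1", "N"), ("HH11", "H"), ("HH12", "H"),
          ("NH2", "N"), ("HH21", "H"), ("HH22", "H")],
    "H": [("CB", "C"), ("HB2", "H"), ("HB3", "H"), ("CG", "C"),
          ("ND1", "N"), ("HD1", "H"), ("CD2", "C"), ("HD2", "H"),
          ("CE1", "C"), ("HE1", "H"), ("NE2", "N")],
}


def atom_template(one_letter: str) -> list[tuple[str, str]]:
    """Ordered (atom name, element) list for one residue type."""
    code = one_letter.upper()
    if code not in _SIDECHAINS:
        raise KeyError(f"unknown residue code {one_letter!r}")
    if code == "G":
        backbone = _BACKBONE_GLY
    elif code == "P":
        backbone = _BACKBONE_PRO
    else:
        backbone = _BACKBONE
    return list(backbone) + list(_SIDECHAINS[code])


def _heavy_stem(name: str, element: str) -> str:
    name = name.upper()
    el = element.upper()
    return name[len(el):] if name.startswith(el) else name[1:]


def methyl_hydrogen_flags(names: list[str], elements: list[str]) -> list[bool]:
    """Flag methyl-group hydrogens within one residue by name convention.

    A hydrogen ``H<stem><digit>`` (or ``H<stem>``) belongs to the heavy atom
    whose name is ``<element><stem>``; a carbon carrying exactly three such
    hydrogens is a methyl carbon.  Works for the standard PDB v3 names
    (e.g. LEU CD1/HD11–HD13, ALA CB/HB1–HB3, THR CG2/HG21–HG23) without
    needing connectivity.
    """
    heavy_stems: dict[str, str] = {}  # stem -> element
    for name, el in zip(names, elements):
        if el.upper() != "H":
            heavy_stems.setdefault(_heavy_stem(name, el), el.upper())

    def parent_stem(hname: str) -> str | None:
        rem = hname.upper()[1:]
        if rem in heavy_stems:
            return rem
        if rem and rem[-1].isdigit() and rem[:-1] in heavy_stems:
            return rem[:-1]
        return None

    counts: dict[str, int] = {}
    parents: list[str | None] = []
    for name, el in zip(names, elements):
        if el.upper() == "H":
            stem = parent_stem(name)
            parents.append(stem)
            if stem is not None:
                counts[stem] = counts.get(stem, 0) + 1
        else:
            parents.append(None)
    return [
        el.upper() == "H"
        and stem is not None
        and heavy_stems.get(stem) == "C"
        and counts.get(stem) == 3
        for (name, el), stem in zip(zip(names, elements), parents)
    ]
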