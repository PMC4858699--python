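"""Readers and writers for topologies and multi-frame trajectories.

Text formats only: multi-model PDB (MODEL/ENDMDL delimits frames) and GRO
(single frame for topology; concatenated frames as a trajectory).  Binary
trajectory formats are supported through the frame-adapter contract: any
object with an ``iter_frames()`` method yielding ``(coordinates_A, box_A)``
pairs can be passed to :func:`read_trajectory` in place of a path.

MDAnalysis backs the PDB/GRO parsing; mdtraj backs concatenated GRO
trajectories.  GRO coordinates are nm on disk and converted to Å on read.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .core_model import (ATOMIC_MASSES, AtomRecord, Topology, Trajectory)
from .residues import THREE_TO_ONE, methyl_hydrogen_flags

WATER_RESNAMES = {"HOH", "SOL", "WAT", "TIP3", "TIP4", "TIP5", "SPC"}
ION_CHARGES = {"CL": -1, "CL-": -1, "NA": 1, "NA+": 1, "K": 1, "K+": 1,
               "MG": 2, "CA": 2, "BR": -1, "F": -1, "I": -1}

_TWO_LETTER = {"CL", "NA", "MG", "FE", "ZN", "BR"}


def guess_element(name: str, resname: str = "") -> str:
    """Infer the element from a PDB atom name.

    Leading digits are skipped (old-style hydrogen names like ``1HB``);
    two-letter elements are only accepted for ion residues, so protein atom
    names like ``CD1`` resolve to carbon, not cadmium.
    """
    stripped = name.strip().lstrip("0123456789'")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    upper = stripped.upper()
    if resname.upper().rstrip("+-") in {"CL", "NA", "K", "MG", "CA", "BR", "F", "I"} \
            and upper[:2] in _TWO_LETTER:
        return upper[:2]
    if upper[:2] in _TWO_LETTER and upper[:2] == resname.upper().rstrip("+-"):
        return upper[:2]
    return upper[0]


def _mass_for(element: str, name: str) -> float:
    el = element.upper()
    if el not in ATOMIC_MASSES:
        raise ValueError(f"no mass for element {element!r} (atom {name!r})")
    return ATOMIC_MASSES[el]


def read_topology(path: str | Path) -> Topology:
    """Read a PDB or GRO structure into a :class:`Topology`.

    Protein units are delimited by chain/segment changes or by the residue
    numbering restarting; every unit must share one sequence.  Methyl
    hydrogens are flagged from atom-name conventions (a carbon carrying
    exactly three hydrogens).
    """
    import MDAnalysis as mda

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))

    names = [a.name for a in u.atoms]
    resnames = [a.resname.upper() for a in u.atoms]
    resids = [int(a.resid) for a in u.atoms]
    try:
        chains = [a.chainID for a in u.atoms]
    except (AttributeError, mda.exceptions.NoDataError):
        chains = [a.segid for a in u.atoms]

    records: list[AtomRecord] = []
    water_residues: set[tuple[str, int]] = set()
    ion_records: list[tuple[str, int]] = []
    protein_index = -1
    prev_resid = None
    prev_chain = None
    unit_residues: list[list[int]] = []  # per unit: atom positions grouped later
    sequences: list[str] = []
    current_seq: list[str] = []
    residue_map: dict[tuple[int, int], int] = {}  # (unit, raw resid) -> 1-based index

    # first pass: partition protein atoms into units and renumber residues
    for i, (name, resname, resid, chain) in enumerate(zip(names, resnames, resids, chains)):
        if resname in WATER_RESNAMES:
            water_residues.add((chain, resid))
            continue
        if resname.rstrip("+-") in ION_CHARGES or resname in ION_CHARGES:
            ion_records.append((resname, ION_CHARGES.get(resname, ION_CHARGES.get(resname.rstrip("+-"), 0))))
            continue
        if resname not in THREE_TO_ONE:
            warnings.warn(f"skipping unrecognized residue {resname} (atom {name})")
            continue
        new_unit = (protein_index < 0
                    or chain != prev_chain
                    or (prev_resid is not None and resid < prev_resid))
        if new_unit:
            protein_index += 1
            if current_seq:
                sequences.append("".join(current_seq))
            current_seq = []
        if (protein_index, resid) not in residue_map:
            residue_map[(protein_index, resid)] = len(current_seq) + 1
            current_seq.append(THREE_TO_ONE[resname])
        prev_resid, prev_chain = resid, chain
        element = guess_element(name, resname)
        records.append(AtomRecord(
            atom_id=i + 1, name=name, element=element,
            mass=_mass_for(element, name),
            residue_index=residue_map[(protein_index, resid)],
            residue_name=resname, protein_index=protein_index,
            is_heavy=element.upper() != "H", is_methyl_hydrogen=False))
    if current_seq:
        sequences.append("".join(current_seq))

    if sequences and len(set(sequences)) > 1:
        raise ValueError("protein units do not share a single sequence")
    sequence = sequences[0] if sequences else ""

    # second pass: methyl flags, per residue
    records = _with_methyl_flags(records)
    return Topology(records, n_proteins=protein_index + 1, sequence=sequence,
                    water_count=len(water_residues), ion_records=ion_records)


def _with_methyl_flags(records: list[AtomRecord]) -> list[AtomRecord]:
    from dataclasses import replace
    out = list(records)
    by_res: dict[tuple[int, int], list[int]] = {}
    for pos, a in enumerate(records):
        by_res.setdefault((a.protein_index, a.residue_index), []).append(pos)
    for positions in by_res.values():
        flags = methyl_hydrogen_flags(
            [records[p].name for p in positions],
            [records[p].element for p in positions])
        for p, f in zip(positions, flags):
            if f:
                out[p] = replace(records[p], is_methyl_hydrogen=True)
    return out


def read_trajectory(source, topology: Topology) -> Trajectory:
    """Read a multi-frame trajectory against an existing topology.

    ``source`` may be a multi-model PDB path, a concatenated-frame GRO path,
    or any adapter object exposing ``iter_frames()``.
    """
    if hasattr(source, "iter_frames"):
        return _from_adapter(source.iter_frames(), topology)

    path = Path(source)
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return _read_pdb_frames(path, topology)
    if suffix == ".gro":
        return _read_gro_frames(path, topology)
    raise ValueError(f"unsupported trajectory format {suffix!r}")


def _from_adapter(frames: Iterable, topology: Topology) -> Trajectory:
    coords, boxes = [], []
    for f, item in enumerate(frames):
        xyz, box = item
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (topology.n_atoms, 3):
            raise ValueError(f"frame {f}: atom count {xyz.shape[0]} does not "
                             f"match topology ({topology.n_atoms})")
        coords.append(xyz)
        boxes.append(None if box is None else np.asarray(box, dtype=float))
    if any(b is None for b in boxes):
        box = None
    else:
        box = np.stack(boxes)
    return Trajectory(topology, np.stack(coords), box=box)


def _read_pdb_frames(path: Path, topology: Topology) -> Trajectory:
    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        if u.atoms.n_atoms != topology.n_atoms:
            raise ValueError(f"frame 0: atom count {u.atoms.n_atoms} does not "
                             f"match topology ({topology.n_atoms})")
        coords, boxes = [], []
        for ts in u.trajectory:
            coords.append(ts.positions.astype(float).copy())
            dims = ts.dimensions
            boxes.append(None if dims is None or not np.any(dims[:3]) else dims[:3].copy())
    box = None if any(b is None for b in boxes) else np.stack(boxes).astype(float)
    return Trajectory(topology, np.stack(coords), box=box)


def _read_gro_frames(path: Path, topology: Topology) -> Trajectory:
    import mdtraj
    t = mdtraj.load(str(path))
    if t.n_atoms != topology.n_atoms:
        raise ValueError(f"frame 0: atom count {t.n_atoms} does not match "
                         f"topology ({topology.n_atoms})")
    coords = np.asarray(t.xyz, dtype=float) * 10.0       # nm -> Å
    box = None
    if t.unitcell_lengths is not None:
        box = np.asarray(t.unitcell_lengths, dtype=float) * 10.0
    times = np.asarray(t.time, dtype=float)
    return Trajectory(topology, coords, box=box, times=times)


# ---------------------------------------------------------------------------
# writing

_CHAINS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def _pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                   resseq: int, xyz: np.ndarray, bfactor: float, element: str) -> str:
    nm = name if len(name) >= 4 else f" {name:<3s}"
    b = float(np.clip(bfactor, -9.99, 999.99))
    return (f"ATOM  {serial % 100000:5d} {nm:<4s}{resname:>4s} {chain}"
            f"{resseq % 10000:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{b:6.2f}          {element:>2s}")


def write_pdb(topology: Topology, coordinates: np.ndarray, path: str | Path,
              bfactors: np.ndarray | None = None) -> Path:
    """Write coordinates as a (possibly multi-model) PDB file.

    ``coordinates`` may be (n_atoms, 3) for a single model or
    (N_F, n_atoms, 3) for a multi-model trajectory.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.ndim == 2:
        coordinates = coordinates[None]
    if coordinates.shape[1] != topology.n_atoms:
        raise ValueError("coordinate atom count does not match topology")
    if bfactors is None:
        bfactors = np.zeros(topology.n_atoms)
    path = Path(path)
    multi = coordinates.shape[0] > 1
    with path.open("w") as fh:
        for f in range(coordinates.shape[0]):
            if multi:
                fh.write(f"MODEL     {f + 1:4d}\n")
            for i, atom in enumerate(topology.atoms):
                chain = _CHAINS[atom.protein_index % len(_CHAINS)] if atom.protein_index >= 0 else "w"
                fh.write(_pdb_atom_line(i + 1, atom.name, atom.residue_name, chain,
                                        atom.residue_index, coordinates[f, i],
                                        bfactors[i], atom.element) + "\n")
            fh.write("TER\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")
    return path


def write_bfactor_structure(topology: Topology,
                            per_residue_values: Mapping,
                            path: str | Path,
                            coordinates: np.ndarray | None = None) -> Path:
    """Write a single-model PDB with a per-residue value in the B-factor column.

    ``per_residue_values`` maps 1-based residue indices (or
    ``(protein, residue)`` pairs) to values; every residue must be covered.
    Values are clamped to the fixed-width PDB field (two decimals).
    """
    def value_for(atom: AtomRecord) -> float:
        key_pr = (atom.protein_index, atom.residue_index)
        if key_pr in per_residue_values:
            return float(per_residue_values[key_pr])
        if atom.residue_index in per_residue_values:
            return float(per_residue_values[atom.residue_index])
        raise KeyError(f"no value for residue {key_pr}")

    bfactors = np.array([value_for(a) if a.protein_index >= 0 else 0.0
                         for a in topology.atoms])
    if coordinates is None:
        coordinates = np.zeros((topology.n_atoms, 3))
    return write_pdb(topology, coordinates, path, bfactors=bfactors)


def read_bfactors(path: str | Path) -> np.ndarray:
    """Per-atom B-factor column of a PDB file, in file order."""
    values = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(("ATOM", "HETATM")):
            values.append(float(line[60:66]))
    return np.array(values)
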