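"""Synthetic-data generators standing in for molecular-dynamics output.

Every input the analysis consumes can be generated here with the designed
statistical structure of a powder study: piecewise-linear harmonic MSF(T)
with a slope change at ``t_low``, a quadratic anharmonic excess above
``t_d``, an exponential methyl-hydrogen regime at low temperature, bilinear
enthalpy with a heat-capacity jump, hydration-dependent residue amplitudes,
and per-frame atomic displacements whose computed MSF matches the designed
curves.  All generators are pure functions of (parameters, seed).
"""
from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .core_model import (AtomRecord, HydropathyTable, PowderConfig,
                         SyntheticSpec, TemperatureSeries, Topology,
                         Trajectory, WaterSite, beta_from_temperature,
                         protein_mass, TRPCAGE_SEQUENCE)
from .residues import ONE_TO_THREE, atom_template, methyl_hydrogen_flags
from .core_model import ATOMIC_MASSES


# ---------------------------------------------------------------------------
# topology

def make_topology(sequence: str = TRPCAGE_SEQUENCE, n_proteins: int = 1) -> Topology:
    """Build a topology from standard residue atom-name templates."""
    records: list[AtomRecord] = []
    atom_id = 0
    for k in range(n_proteins):
        for r, code in enumerate(sequence, start=1):
            template = atom_template(code)
            names = [n for n, _ in template]
            elements = [e for _, e in template]
            methyl = methyl_hydrogen_flags(names, elements)
            for (name, element), is_me in zip(template, methyl):
                atom_id += 1
                records.append(AtomRecord(
                    atom_id=atom_id, name=name, element=element,
                    mass=ATOMIC_MASSES[element.upper()],
                    residue_index=r, residue_name=ONE_TO_THREE[code.upper()],
                    protein_index=k, is_heavy=element.upper() != "H",
                    is_methyl_hydrogen=is_me))
    return Topology(records, n_proteins=n_proteins, sequence=sequence)


# ---------------------------------------------------------------------------
# temperature curves

def msf_baseline(spec: SyntheticSpec, t: np.ndarray) -> np.ndarray:
    """Noise-free designed MSF(T) curve."""
    t = np.asarray(t, dtype=float)
    base = (spec.intercept + spec.slope_harm1 * np.minimum(t, spec.t_low)
            + spec.slope_harm2 * np.maximum(0.0, t - spec.t_low))
    if spec.t_d is not None:
        base = base + spec.anharm_coeff * np.maximum(0.0, t - spec.t_d) ** 2
    return base


def make_msf_curve(spec: SyntheticSpec) -> TemperatureSeries:
    """Average-MSF curve: two harmonic slopes hinged at t_low, quadratic
    anharmonic excess above t_d (if present), multiplicative Gaussian noise."""
    base = msf_baseline(spec, spec.t_grid)
    rng = np.random.default_rng(spec.seed)
    values = base * (1.0 + rng.normal(0.0, spec.noise_rel, size=base.shape)) \
        if spec.noise_rel > 0 else base.copy()
    return TemperatureSeries(spec.t_grid, values, errors=spec.noise_rel * base,
                             label=f"msf[{spec.hydration_mode}]")


def make_methyl_curve(spec: SyntheticSpec) -> TemperatureSeries:
    """Methyl-hydrogen MSF: exponential in T below t_low, continued linearly
    (value- and slope-matched) above."""
    t = spec.t_grid
    v_low = spec.methyl_amp * np.exp(spec.methyl_rate * t)
    v_at = spec.methyl_amp * np.exp(spec.methyl_rate * spec.t_low)
    slope_at = spec.methyl_rate * v_at
    v_high = v_at + slope_at * (t - spec.t_low)
    base = np.where(t < spec.t_low, v_low, v_high)
    rng = np.random.default_rng(spec.seed + 7)
    values = base * (1.0 + rng.normal(0.0, spec.noise_rel, size=base.shape)) \
        if spec.noise_rel > 0 else base.copy()
    return TemperatureSeries(t, values, errors=spec.noise_rel * base,
                             label="msf[methyl-h]")


def make_enthalpy_curve(t_d: float | None, cp_low: float, cp_high: float,
                        noise_abs: float, t_grid: np.ndarray,
                        seed: int = 0, h_ref: float = 0.0) -> TemperatureSeries:
    """Continuous bilinear enthalpy hinged at ``t_d`` plus Gaussian noise.

    ``t_d=None`` (or ``cp_high == cp_low``) emulates the single-regime
    behaviour of a dehydrated powder with no dynamical transition.
    """
    t = np.asarray(t_grid, dtype=float)
    t0 = t[0]
    if t_d is None:
        base = h_ref + cp_low * (t - t0)
    else:
        base = (h_ref + cp_low * (np.minimum(t, t_d) - t0)
                + cp_high * np.maximum(0.0, t - t_d))
    rng = np.random.default_rng(seed)
    values = base + rng.normal(0.0, noise_abs, size=base.shape) if noise_abs > 0 \
        else base.copy()
    return TemperatureSeries(t, values,
                             errors=np.full_like(base, float(noise_abs)),
                             label="enthalpy")


# ---------------------------------------------------------------------------
# per-residue dataset

def hydrophilicity_rank(code: str, table: HydropathyTable) -> float:
    """0 (most hydrophobic) to 1 (most hydrophilic) over the 20-residue scale."""
    lo, hi = min(table.values.values()), max(table.values.values())
    return (hi - table[code]) / (hi - lo)


def make_per_residue_dataset(spec: SyntheticSpec,
                             hydropathy: HydropathyTable | None = None,
                             sequence: str = TRPCAGE_SEQUENCE,
                             terminus_bonus: float = 0.5,
                             ) -> dict[int, TemperatureSeries]:
    """Per-residue MSF(T) curves sharing the whole-protein t_low/t_d.

    The anharmonic amplitude scales with hydrophilicity in ``"hydrated"``
    mode and with hydrophobicity in ``"dehydrated"`` mode (amplitude factor
    1–2 across the scale); the chain termini receive a fixed bonus,
    mimicking their weaker bonding restraints.  ``spec.residue_amplitudes``
    additionally rescales whole curves per residue.
    """
    if hydropathy is None:
        hydropathy = HydropathyTable.eisenberg()
    out: dict[int, TemperatureSeries] = {}
    for idx, code in enumerate(sequence, start=1):
        u = hydrophilicity_rank(code, hydropathy)
        scale = 1.0 + (u if spec.hydration_mode == "hydrated" else 1.0 - u)
        if idx in (1, len(sequence)):
            scale += terminus_bonus
        res_spec = replace(spec, anharm_coeff=spec.anharm_coeff * scale,
                           seed=spec.seed + 1000 * idx)
        series = make_msf_curve(res_spec)
        if spec.residue_amplitudes is not None:
            series = series.scaled(float(spec.residue_amplitudes[idx]))
        series.label = f"msf[residue {idx} {code}]"
        out[idx] = series
    return out


# ---------------------------------------------------------------------------
# coordinate trajectories

def make_reference_coordinates(top: Topology, seed: int = 0,
                               protein_spacing: float = 40.0) -> np.ndarray:
    """Random but reproducible reference structure: residues on a loose
    backbone walk, atoms jittered around residue centres, units well
    separated."""
    rng = np.random.default_rng(seed)
    coords = np.zeros((top.n_atoms, 3))
    for k in range(top.n_proteins):
        unit = top.protein_atoms(k)
        offset = np.array([protein_spacing * k, 0.0, 0.0])
        res_centres = {}
        centre = np.zeros(3)
        for r in range(1, top.n_residues + 1):
            step = rng.normal(0.0, 1.0, 3)
            centre = centre + 3.8 * step / np.linalg.norm(step)
            res_centres[r] = centre.copy()
        for i in unit:
            r = top.residue_index[i]
            coords[i] = offset + res_centres[r] + rng.normal(0.0, 1.5, 3)
    return coords


def make_trajectory(top: Topology, per_atom_msf, n_frames: int,
                    anharmonic_atoms: Sequence[int] | None = None,
                    jump_distance: float = 2.0, switch_prob: float = 0.1,
                    seed: int = 0, rigid_motion: bool = True,
                    reference: np.ndarray | None = None) -> Trajectory:
    """Trajectory whose computed MSF matches designed per-atom targets.

    Atoms receive i.i.d. Gaussian displacements with per-axis variance
    target/3; atoms in ``anharmonic_atoms`` additionally hop between two
    sites ±d/2 apart via a two-state Markov chain (switch probability
    ``switch_prob`` per frame), adding occupancy variance p(1-p)d² to their
    MSF.  Each frame then gets a random whole-unit rigid rotation and
    translation, which the alignment stage must remove.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    target = np.broadcast_to(np.asarray(per_atom_msf, dtype=float),
                             (top.n_atoms,)).copy()
    if (target < 0).any():
        raise ValueError("MSF targets must be non-negative")
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = make_reference_coordinates(top, seed=seed)
    sigma = np.sqrt(target / 3.0)
    coords = (reference[None, :, :]
              + rng.normal(size=(n_frames, top.n_atoms, 3)) * sigma[None, :, None])
    if anharmonic_atoms is not None and len(anharmonic_atoms):
        idx = np.asarray(anharmonic_atoms, dtype=int)
        directions = rng.normal(size=(len(idx), 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        states = np.empty((n_frames, len(idx)))
        states[0] = rng.integers(0, 2, size=len(idx))
        flips = rng.random(size=(n_frames - 1, len(idx))) < switch_prob
        for f in range(1, n_frames):
            states[f] = np.where(flips[f - 1], 1 - states[f - 1], states[f - 1])
        coords[:, idx, :] += ((states - 0.5) * jump_distance)[:, :, None] * directions[None, :, :]
    if rigid_motion:
        for k in range(top.n_proteins):
            unit = top.protein_atoms(k)
            centre = reference[unit].mean(axis=0)
            for f in range(n_frames):
                R = Rotation.random(rng=rng).as_matrix()
                t = rng.uniform(-5.0, 5.0, 3)
                coords[f, unit] = (coords[f, unit] - centre) @ R.T + centre + t
    return Trajectory(top, coords)


# ---------------------------------------------------------------------------
# powder configurations

def make_powder_config(n_proteins: int = 16, n_waters: int = 771,
                       bound_fraction: float = 0.3,
                       binding_distance: float = 3.0,
                       box: float | None = None, seed: int = 0,
                       sequence: str = TRPCAGE_SEQUENCE,
                       sites_per_protein: int = 8,
                       temperature: float = 300.0) -> PowderConfig:
    """Toy powder: dummy protein site clusters on a lattice plus waters.

    A ``bound_fraction`` of the waters is placed ``binding_distance`` Å from
    a protein site (tag ``"bound"``); the rest are distributed through the
    box (tag ``"free"``).  Placement is rejection-sampled with a 2.5 Å
    minimum separation; a box too small to host all molecules raises.
    """
    rng = np.random.default_rng(seed)
    if box is None:
        # ~30 Å³ effective volume per particle keeps placement easy
        n_particles = n_proteins * sites_per_protein + n_waters
        box = max(30.0, (60.0 * max(n_particles, 1)) ** (1.0 / 3.0))

    n_cells = max(1, int(np.ceil(n_proteins ** (1.0 / 3.0))))
    spacing = box / n_cells
    protein_positions = []
    for k in range(n_proteins):
        cell = np.array([k % n_cells, (k // n_cells) % n_cells,
                         k // n_cells ** 2], dtype=float)
        centre = (cell + 0.5) * spacing
        protein_positions.append(centre + rng.normal(0.0, 1.0, (sites_per_protein, 3)))
    ppos = (np.vstack(protein_positions) if protein_positions
            else np.zeros((0, 3)))

    placed = [ppos] if len(ppos) else []
    waters: list[WaterSite] = []
    n_bound = int(round(bound_fraction * n_waters))
    min_sep = 2.5
    for w in range(n_waters):
        tag = "bound" if w < n_bound else "free"
        for attempt in range(500):
            if tag == "bound" and len(ppos):
                site = ppos[rng.integers(len(ppos))]
                direction = rng.normal(0.0, 1.0, 3)
                direction /= np.linalg.norm(direction)
                pos = site + binding_distance * direction
            else:
                pos = rng.uniform(0.0, box, 3)
            others = np.vstack(placed) if placed else np.zeros((0, 3))
            if len(others) == 0 or (np.linalg.norm(others - pos, axis=1) >= (
                    1.0 if tag == "bound" else min_sep)).all():
                break
        else:
            raise ValueError(f"box {box:.1f} Å too small to place water {w} "
                             "without overlap")
        placed.append(pos[None, :])
        waters.append(WaterSite(water_id=w, position=tuple(pos), tag=tag))

    n_sites = len(ppos)
    return PowderConfig(
        protein_positions=ppos,
        protein_charges=np.where(np.arange(n_sites) % 2 == 0, 0.2, -0.2),
        protein_sigma=np.full(n_sites, 3.5),
        protein_epsilon=np.full(n_sites, 0.5),
        waters=waters,
        ions=[("CL", -1)] * n_proteins,
        n_proteins=n_proteins,
        protein_mass_total=n_proteins * protein_mass(sequence),
        beta=beta_from_temperature(temperature),
        rng_seed=seed)
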