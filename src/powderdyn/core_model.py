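"""Domain types and elementary sequence operations shared by all stages.

Conventions used throughout the package:

* coordinates and fluctuations are in Å and Å² (file readers convert at the
  I/O boundary — GRO files are nm on disk);
* ``protein_index`` is 0-based across the powder units, ``residue_index`` is
  1-based within each protein chain;
* masses are in Da, temperatures in K, energies in kJ/mol.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import cached_property
from importlib.resources import files
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .residues import STANDARD_RESIDUES

WATER_MASS = 18.0153  # Da, average molecular mass of H2O
K_B = 0.008314462618  # kJ/(mol K)

#: Trp-cage miniprotein TC5b (PDB entry 1L2Y), the bundled reference sequence.
TRPCAGE_SEQUENCE = "NLYIQWLKDGGPSSGRPPPS"


def _load_table(name: str) -> dict[str, float]:
    text = files("powderdyn.data").joinpath(name).read_text()
    table = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, value = line.split()
        table[key.upper()] = float(value)
    return table


ATOMIC_MASSES: dict[str, float] = _load_table("atomic_masses.tsv")
RESIDUE_MASSES: dict[str, float] = _load_table("residue_masses.tsv")


def protein_mass(sequence: str) -> float:
    """Average molecular mass (Da) of a peptide: residue masses + one water
    for the terminal H/OH."""
    if not sequence:
        raise ValueError("empty sequence")
    try:
        total = sum(RESIDUE_MASSES[c.upper()] for c in sequence)
    except KeyError as exc:
        raise ValueError(f"non-standard residue code {exc.args[0]!r}") from None
    return total + WATER_MASS


def net_formal_charge(sequence: str) -> int:
    """Net formal charge (e) of a peptide at neutral pH.

    Lys/Arg count +1, Asp/Glu −1, His neutral; the free N-terminus adds +1
    and the free C-terminus −1.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - STANDARD_RESIDUES
    if bad:
        raise ValueError(f"non-standard residue code(s): {sorted(bad)}")
    positive = seq.count("K") + seq.count("R")
    negative = seq.count("D") + seq.count("E")
    return positive - negative + 1 - 1


# ---------------------------------------------------------------------------
# hydropathy

@dataclass(frozen=True)
class HydropathyTable:
    """Per-residue hydropathy values plus a hydrophobic/hydrophilic cutoff."""

    values: Mapping[str, float]
    threshold: float = 0.0

    @classmethod
    def eisenberg(cls, threshold: float = 0.0) -> "HydropathyTable":
        """The Eisenberg consensus scale bundled with the package."""
        return cls(values=_load_table("eisenberg.tsv"), threshold=threshold)

    def __contains__(self, code: str) -> bool:
        return code.upper() in self.values

    def __getitem__(self, code: str) -> float:
        return self.values[code.upper()]


def classify_residue(code: str, table: HydropathyTable | None = None) -> str:
    """Classify a residue as ``"hydrophobic"`` or ``"hydrophilic"``.

    Hydrophobic iff its hydropathy value exceeds the table threshold.
    """
    if table is None:
        table = HydropathyTable.eisenberg()
    if code.upper() not in table:
        raise KeyError(f"unknown residue code {code!r}")
    return "hydrophobic" if table[code] > table.threshold else "hydrophilic"


# ---------------------------------------------------------------------------
# topology / trajectory containers

@dataclass(frozen=True)
class AtomRecord:
    atom_id: int
    name: str
    element: str
    mass: float
    residue_index: int          # 1-based within its protein unit
    residue_name: str           # 3-letter code
    protein_index: int          # 0-based powder unit; -1 for solvent/ions
    is_heavy: bool
    is_methyl_hydrogen: bool

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.atom_id}: mass must be positive")
        if (self.element.upper() == "H") == self.is_heavy:
            raise ValueError(f"atom {self.atom_id}: is_heavy inconsistent with element")
        if self.is_methyl_hydrogen and self.element.upper() != "H":
            raise ValueError(f"atom {self.atom_id}: methyl flag on a heavy atom")


class Topology:
    """Ordered atom list with protein-unit bookkeeping.

    Atoms must be grouped by protein unit; residue indices run 1..L within
    each unit and every unit shares the same sequence.
    """

    def __init__(self, atoms: Sequence[AtomRecord], n_proteins: int,
                 sequence: str, water_count: int = 0,
                 ion_records: Sequence[tuple[str, int]] = ()) -> None:
        self.atoms = list(atoms)
        self.n_proteins = int(n_proteins)
        self.sequence = sequence
        self.water_count = int(water_count)
        self.ion_records = list(ion_records)
        self._validate()

    def _validate(self) -> None:
        seen = [a.protein_index for a in self.atoms if a.protein_index >= 0]
        if seen and sorted(set(seen)) != list(range(self.n_proteins)):
            raise ValueError("protein_index values do not cover 0..n_proteins-1")
        # atoms grouped by unit
        order = [p for p in seen]
        if order != sorted(order):
            raise ValueError("atoms are not grouped by protein unit")
        L = len(self.sequence)
        for a in self.atoms:
            if a.protein_index >= 0 and not (1 <= a.residue_index <= L):
                raise ValueError(f"atom {a.atom_id}: residue_index outside 1..{L}")

    # -- cached index arrays -------------------------------------------------
    @cached_property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @cached_property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @cached_property
    def protein_index(self) -> np.ndarray:
        return np.array([a.protein_index for a in self.atoms])

    @cached_property
    def residue_index(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms])

    @cached_property
    def is_heavy(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms])

    @cached_property
    def is_methyl_hydrogen(self) -> np.ndarray:
        return np.array([a.is_methyl_hydrogen for a in self.atoms])

    def protein_atoms(self, k: int) -> np.ndarray:
        """Indices (positions in atom order) of the atoms of unit ``k``."""
        return np.flatnonzero(self.protein_index == k)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def methyl_bearing_residues(self) -> set[int]:
        """1-based residue indices carrying at least one methyl hydrogen."""
        return {a.residue_index for a in self.atoms if a.is_methyl_hydrogen}


@dataclass
class Trajectory:
    """N_F frames of coordinates (Å) over a fixed topology."""

    topology: Topology
    coordinates: np.ndarray          # (N_F, n_atoms, 3), Å
    box: np.ndarray | None = None    # (N_F, 3) orthorhombic lengths, Å
    times: np.ndarray | None = None  # ps

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (N_F, n_atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.coordinates.shape[1]} != topology "
                f"atom count {self.topology.n_atoms}")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.n_frames, 3):
                raise ValueError("box must have shape (N_F, 3)")
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class MSFResult:
    """Mean-square fluctuations at all aggregation levels (Å²)."""

    per_atom: pd.Series                  # index: atom_id
    per_residue: pd.Series               # index: (protein, residue), mass-averaged
    per_protein: pd.Series               # index: protein
    ensemble: float                      # unweighted mean over protein units
    block_se: dict | None = None         # same levels, block standard errors
    selection_label: str = ""

    def __post_init__(self) -> None:
        if (self.per_atom < -1e-12).any():
            raise ValueError("negative MSF value")


@dataclass
class TemperatureSeries:
    """(T, value, error) triples; temperatures strictly increasing."""

    temperatures: np.ndarray
    values: np.ndarray
    errors: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.temperatures.shape != self.values.shape:
            raise ValueError("temperatures and values must have equal length")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
            if self.errors.shape != self.values.shape:
                raise ValueError("errors must match values in length")
            if (self.errors < 0).any():
                raise ValueError("errors must be non-negative")

    def __len__(self) -> int:
        return len(self.temperatures)

    def restrict(self, t_min: float = -np.inf, t_max: float = np.inf) -> "TemperatureSeries":
        m = (self.temperatures >= t_min) & (self.temperatures <= t_max)
        return TemperatureSeries(
            self.temperatures[m], self.values[m],
            None if self.errors is None else self.errors[m], self.label)

    def scaled(self, factor: float) -> "TemperatureSeries":
        return TemperatureSeries(
            self.temperatures, self.values * factor,
            None if self.errors is None else self.errors * factor, self.label)


@dataclass
class SegmentedFit:
    """Two independent lines split at a breakpoint (fit space may be log)."""

    breakpoint: float
    slope_low: float
    intercept_low: float
    slope_high: float
    intercept_high: float
    sse: float
    sse_single: float
    p_two_regime: float
    fit_space: str                       # "linear" | "log"
    resid_sigma_low: float = float("nan")
    resid_sigma_high: float = float("nan")
    n_candidates: int = 0
    t_min: float = float("nan")
    t_max: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.t_min < self.breakpoint < self.t_max):
            raise ValueError("breakpoint must lie strictly inside the fitted range")
        if self.sse > self.sse_single + 1e-9 * max(self.sse_single, 1.0):
            raise ValueError("two-segment SSE exceeds single-line SSE")

    def predict_high(self, t: np.ndarray) -> np.ndarray:
        """Upper-segment line evaluated in fit space."""
        return self.intercept_high + self.slope_high * np.asarray(t, dtype=float)


@dataclass
class EnthalpyFit:
    """Bilinear enthalpy fit; T_D is the intersection of the two free lines."""

    t_d: float                           # NaN when no transition detected
    cp_low: float
    cp_high: float
    delta_cp: float
    transition_detected: bool
    p_two_regime: float
    diagnostic: str = ""
    fit: SegmentedFit | None = None

    def __post_init__(self) -> None:
        if self.transition_detected and not math.isfinite(self.t_d):
            raise ValueError("transition_detected requires a finite t_d")
        if not self.transition_detected and math.isfinite(self.t_d):
            raise ValueError("t_d must be NaN when no transition is detected")


# ---------------------------------------------------------------------------
# powder configuration for the dehydration protocol

@dataclass(frozen=True)
class WaterSite:
    """Single-site toy water used by the desk-scale dehydration protocol."""

    water_id: int
    position: tuple[float, float, float]
    charge: float = 0.0
    sigma: float = 3.166       # Å
    epsilon: float = 0.650     # kJ/mol
    tag: str = ""


@dataclass
class PowderConfig:
    """Protein powder state consumed by the Metropolis water-removal loop."""

    protein_positions: np.ndarray        # (n_sites, 3), Å; fixed
    protein_charges: np.ndarray          # e
    protein_sigma: np.ndarray            # Å
    protein_epsilon: np.ndarray          # kJ/mol
    waters: list[WaterSite]
    ions: list[tuple[str, int]] = field(default_factory=list)
    n_proteins: int = 1
    protein_mass_total: float = 0.0      # Da, all units together
    beta: float = 1.0 / (K_B * 300.0)    # mol/kJ
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.protein_positions = np.atleast_2d(np.asarray(self.protein_positions, float))
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.protein_mass_total <= 0:
            raise ValueError("protein mass must be positive")

    @property
    def n_waters(self) -> int:
        return len(self.waters)

    def without_water(self, index: int) -> "PowderConfig":
        waters = self.waters[:index] + self.waters[index + 1:]
        new = replace(self, waters=waters)
        return new


def beta_from_temperature(temperature: float) -> float:
    """Inverse thermal energy 1/(k_B T) in mol/kJ."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return 1.0 / (K_B * temperature)


# ---------------------------------------------------------------------------
# synthetic-study specification

@dataclass
class SyntheticSpec:
    """Design parameters of the synthetic MSF(T)/H(T) study conditions.

    Defaults encode a fully hydrated powder: harmonic slope doubling at
    ``t_low`` = 160 K, anharmonic onset at ``t_d`` = 223 K, and 1% relative
    noise (block errors comparable to plotting symbol sizes).
    """

    t_grid: np.ndarray = field(default_factory=lambda: np.arange(100.0, 301.0, 10.0))
    t_low: float = 160.0
    t_d: float | None = 223.0
    slope_harm1: float = 1.0e-3      # Å²/K below t_low
    slope_harm2: float = 2.0e-3      # Å²/K between t_low and t_d
    intercept: float = 0.02          # Å² at 0 K
    anharm_coeff: float = 1.0e-3     # Å²/K², quadratic excess above t_d
    methyl_amp: float = 0.02         # Å², prefactor of the methyl exponential
    methyl_rate: float = 0.012       # 1/K
    noise_rel: float = 0.01
    seed: int = 0
    hydration_mode: str = "hydrated"     # "hydrated" | "dehydrated"
    residue_amplitudes: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        if self.t_d is not None and not (self.t_low < self.t_d):
            raise ValueError("t_low must be below t_d")
        if not (self.slope_harm2 > self.slope_harm1 > 0):
            raise ValueError("require slope_harm2 > slope_harm1 > 0")
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be non-negative")
        if self.hydration_mode not in ("hydrated", "dehydrated"):
            raise ValueError("hydration_mode must be 'hydrated' or 'dehydrated'")
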