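"""Mean-square fluctuation statistic for protein-powder trajectories.

Each protein unit is treated independently: every frame is rigid-body
superposed onto that unit's frame-0 structure (heavy atoms by default), and
the MSF of atom *i* is the variance of its aligned position about its
post-alignment mean,

    MSF_i = (1/N_F) sum_t |x_i(t) - <x_i>|^2 .

Atomic values are mass-averaged into residue and protein values; the
ensemble value is the unweighted mean over protein units.  Block averaging
over contiguous trajectory segments provides standard errors.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core_model import MSFResult, Topology, Trajectory


def kabsch_align(mobile: np.ndarray, reference: np.ndarray,
                 weights: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Weighted least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t)`` with ``R`` a proper rotation (det = +1) such that
    ``R @ x + t`` maps mobile points onto the reference frame.

    Raises ``ValueError`` for fewer than 3 points or degenerate (coincident
    or collinear) point sets, for which the rotation is not unique.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must share shape (n, 3)")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 points for a rigid fit")
    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    mc = w @ mobile
    rc = w @ reference
    mob_c = mobile - mc
    ref_c = reference - rc
    scale = max(np.abs(mob_c).max(), np.abs(ref_c).max(), 1e-12)
    for pts in (mob_c, ref_c):
        if np.linalg.matrix_rank(pts, tol=1e-8 * scale) < 2:
            raise ValueError("degenerate point set (coincident or collinear)")
    rot, _ = Rotation.align_vectors(ref_c, mob_c, weights=w)
    R = rot.as_matrix()
    t = rc - R @ mc
    return R, t


def select(top: Topology, expression: str) -> np.ndarray:
    """Resolve a selection expression to atom indices (topology order).

    Tokens (joined with ``and``): ``heavy``, ``all-h``, ``methyl-h``,
    ``non-methyl-h``, ``all``, ``residue(i)``, ``protein(k)``.  Selections
    cover protein atoms only; solvent never enters the MSF.
    """
    mask = top.protein_index >= 0
    for token in [t.strip() for t in expression.lower().split(" and ")]:
        if token == "all":
            sub = np.ones(top.n_atoms, bool)
        elif token == "heavy":
            sub = top.is_heavy
        elif token in ("all-h", "hydrogen"):
            sub = ~top.is_heavy
        elif token == "methyl-h":
            sub = top.is_methyl_hydrogen
        elif token == "non-methyl-h":
            sub = ~top.is_heavy & ~top.is_methyl_hydrogen
        elif token.startswith("residue(") and token.endswith(")"):
            sub = top.residue_index == int(token[8:-1])
        elif token.startswith("protein(") and token.endswith(")"):
            sub = top.protein_index == int(token[8:-1])
        else:
            raise ValueError(f"unknown selection token {token!r}")
        mask = mask & sub
    return np.flatnonzero(mask)


def _unwrap_unit(coords: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Make a molecule whole across periodic boundaries (minimum image
    relative to its first atom), frame-wise."""
    if box is None:
        return coords
    anchor = coords[:, :1, :]
    d = coords - anchor
    d -= box[:, None, :] * np.round(d / box[:, None, :])
    return anchor + d


def _aligned_coordinates(traj: Trajectory, align_selection: np.ndarray | None,
                         mass_weighted_fit: bool) -> np.ndarray:
    """Superpose every frame of every protein unit onto its frame-0 structure;
    returns the full coordinate array with protein atoms aligned."""
    top = traj.topology
    if align_selection is None:
        align_selection = select(top, "heavy")
    coords = traj.coordinates.copy()
    for k in range(top.n_proteins):
        unit = top.protein_atoms(k)
        align_k = np.intersect1d(align_selection, unit)
        if len(align_k) < 3:
            raise ValueError(f"protein {k}: alignment selection has "
                             f"{len(align_k)} atoms (need >= 3)")
        X = _unwrap_unit(coords[:, unit, :], traj.box)
        apos = np.searchsorted(unit, align_k)
        ref = X[0, apos]
        w = top.masses[align_k] if mass_weighted_fit else None
        for f in range(traj.n_frames):
            R, t = kabsch_align(X[f, apos], ref, weights=w)
            X[f] = X[f] @ R.T + t
        coords[:, unit, :] = X
    return coords


def _msf_from_window(aligned: np.ndarray, frames: slice) -> np.ndarray:
    X = aligned[frames]
    mean = X.mean(axis=0)
    return ((X - mean) ** 2).sum(axis=-1).mean(axis=0)


def _aggregate(top: Topology, selection: np.ndarray, per_atom: np.ndarray,
               label: str) -> MSFResult:
    masses = top.masses[selection]
    df = pd.DataFrame({
        "protein": top.protein_index[selection],
        "residue": top.residue_index[selection],
        "atom_id": [top.atoms[i].atom_id for i in selection],
        "msf": per_atom,
        "mass": masses,
        "wm": per_atom * masses,
    })
    per_res = (df.groupby(["protein", "residue"])["wm"].sum()
               / df.groupby(["protein", "residue"])["mass"].sum())
    per_prot = df.groupby("protein")["wm"].sum() / df.groupby("protein")["mass"].sum()
    return MSFResult(
        per_atom=pd.Series(per_atom, index=df["atom_id"].to_numpy(), name="msf"),
        per_residue=per_res.rename("msf"),
        per_protein=per_prot.rename("msf"),
        ensemble=float(per_prot.mean()),
        selection_label=label,
    )


def compute_msf(traj: Trajectory, selection: np.ndarray | str | None = None,
                align_selection: np.ndarray | str | None = None,
                mass_weighted_fit: bool = False) -> MSFResult:
    """MSF of the selected atoms after per-unit superposition to frame 0.

    ``selection`` defaults to protein heavy atoms; ``align_selection``
    defaults to heavy atoms of each unit.  The fit is unweighted unless
    ``mass_weighted_fit`` is set (mass enters the residue/protein averaging
    regardless).
    """
    top = traj.topology
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames to compute fluctuations")
    label = selection if isinstance(selection, str) else (
        "heavy" if selection is None else "custom")
    if selection is None:
        selection = select(top, "heavy")
    elif isinstance(selection, str):
        selection = select(top, selection)
    if isinstance(align_selection, str):
        align_selection = select(top, align_selection)
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("empty selection")
    aligned = _aligned_coordinates(traj, align_selection, mass_weighted_fit)
    per_atom = _msf_from_window(aligned[:, selection, :], slice(None))
    return _aggregate(top, selection, per_atom, label)


def block_errors(traj: Trajectory, selection: np.ndarray | str | None = None,
                 n_blocks: int = 5,
                 align_selection: np.ndarray | str | None = None,
                 mass_weighted_fit: bool = False) -> dict:
    """Block-averaged standard errors of the MSF at every aggregation level.

    The trajectory is split into ``n_blocks`` contiguous equal-length blocks
    (remainder frames at the tail are dropped); the MSF is computed
    independently within each block, re-using the global frame-0 alignment
    reference, and the standard error is the sample standard deviation of
    the block values divided by sqrt(n_blocks).
    """
    top = traj.topology
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if traj.n_frames < n_blocks:
        raise ValueError("fewer frames than blocks")
    label = selection if isinstance(selection, str) else "heavy"
    if selection is None or isinstance(selection, str):
        selection = select(top, selection if isinstance(selection, str) else "heavy")
    if isinstance(align_selection, str):
        align_selection = select(top, align_selection)
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("empty selection")

    aligned = _aligned_coordinates(traj, align_selection, mass_weighted_fit)
    L = traj.n_frames // n_blocks
    block_results = []
    for b in range(n_blocks):
        per_atom = _msf_from_window(aligned[:, selection, :], slice(b * L, (b + 1) * L))
        block_results.append(_aggregate(top, selection, per_atom, label))

    def se(values: np.ndarray) -> np.ndarray:
        return np.std(values, axis=0, ddof=1) / np.sqrt(n_blocks)

    per_atom_se = se(np.stack([r.per_atom.to_numpy() for r in block_results]))
    per_res_se = se(np.stack([r.per_residue.to_numpy() for r in block_results]))
    per_prot_se = se(np.stack([r.per_protein.to_numpy() for r in block_results]))
    ens = np.array([r.ensemble for r in block_results])
    return {
        "per_atom": pd.Series(per_atom_se, index=block_results[0].per_atom.index),
        "per_residue": pd.Series(per_res_se, index=block_results[0].per_residue.index),
        "per_protein": pd.Series(per_prot_se, index=block_results[0].per_protein.index),
        "ensemble": float(se(ens)),
        "block_ensemble_values": ens,
        "n_blocks": n_blocks,
        "block_length": L,
    }


def compute_msf_with_errors(traj: Trajectory,
                            selection: np.ndarray | str | None = None,
                            n_blocks: int = 5,
                            align_selection: np.ndarray | str | None = None,
                            mass_weighted_fit: bool = False) -> MSFResult:
    """Full-trajectory MSF with block standard errors attached."""
    result = compute_msf(traj, selection, align_selection, mass_weighted_fit)
    result.block_se = block_errors(traj, selection, n_blocks, align_selection,
                                   mass_weighted_fit)
    return result
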