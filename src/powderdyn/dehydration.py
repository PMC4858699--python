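"""Metropolis water-removal protocol for preparing lower-hydration powders.

Starting from a hydrated powder configuration, one water molecule at a time
is chosen uniformly at random and removed with probability
min(1, exp(-beta * dU)), where dU is the configurational-energy change of
the removal.  Strongly bound waters (dU > 0, removal uphill) are therefore
preferentially retained, limiting the perturbation to the protein.  The
relaxation step between removals (NPT dynamics in a full simulation
pipeline) is a pluggable hook.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core_model import PowderConfig, Topology, WATER_MASS

COULOMB_CONSTANT = 1389.35458  # kJ Å / (mol e²)


def hydration_level(config: PowderConfig, top: Topology | None = None) -> float:
    """Hydration level h in g water / g protein.

    Water mass is ``n_waters * 18.0153`` Da; the protein mass is taken from
    the configuration (or recomputed from a topology's sequence masses when
    one is supplied).
    """
    if top is not None:
        from .core_model import protein_mass
        m_protein = top.n_proteins * protein_mass(top.sequence)
    else:
        m_protein = config.protein_mass_total
    return config.n_waters * WATER_MASS / m_protein


def hydration_from_counts(n_waters: int, n_proteins: int, sequence: str) -> float:
    """Hydration level from molecule counts and the sequence mass alone."""
    from .core_model import protein_mass
    return n_waters * WATER_MASS / (n_proteins * protein_mass(sequence))


def waters_for_hydration(h: float, n_proteins: int, sequence: str) -> int:
    """Number of water molecules giving hydration level ``h`` (nearest int)."""
    from .core_model import protein_mass
    return round(h * n_proteins * protein_mass(sequence) / WATER_MASS)


def removal_acceptance(delta_u: float, beta: float) -> float:
    """Metropolis acceptance probability min(1, exp(-beta * dU)).

    ``delta_u`` is U(without the water) - U(with it): removing a strongly
    bound water costs energy (dU > 0) and is rarely accepted.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    x = -beta * delta_u
    if x >= 0:
        return 1.0
    return math.exp(x)


def dehydrate(config: PowderConfig, target_h: float, energy_fn,
              relax_hook=None, rng=None,
              max_attempts: int = 10 ** 6) -> tuple[PowderConfig, pd.DataFrame]:
    """Remove waters by the Metropolis criterion until h <= ``target_h``.

    ``energy_fn(config) -> kJ/mol`` evaluates the configurational energy;
    ``relax_hook(config) -> config`` runs after every accepted removal (the
    default is a no-op; it must not change the water count).  Rejected
    proposals are simply re-drawn — the same water may be proposed again.
    Returns the dehydrated configuration and the removal log (one row per
    attempt: water_id, delta_u, acceptance probability, accepted flag).
    """
    rng = np.random.default_rng(rng)
    h0 = hydration_level(config)
    if target_h > h0 * (1 + 1e-12):
        raise ValueError(f"target hydration {target_h:.4f} exceeds current {h0:.4f}; "
                         "only removal is supported")
    log: list[dict] = []
    current_energy = None
    attempts = 0
    while hydration_level(config) > target_h * (1 + 1e-12):
        if config.n_waters == 0:
            break
        if attempts >= max_attempts:
            raise RuntimeError(f"no convergence after {max_attempts} attempts; "
                               "partial log available" )
        attempts += 1
        j = int(rng.integers(config.n_waters))
        water = config.waters[j]
        trial = config.without_water(j)
        try:
            if current_energy is None:
                current_energy = energy_fn(config)
            trial_energy = energy_fn(trial)
        except Exception:
            # abort with the partial log attached to the raised error
            raise RuntimeError(
                f"energy function failed at attempt {attempts} "
                f"(water {water.water_id}); {len(log)} attempts logged") from None
        delta_u = trial_energy - current_energy
        p = removal_acceptance(delta_u, config.beta)
        accepted = bool(rng.random() < p)
        log.append({"attempt": attempts, "water_id": water.water_id,
                    "delta_u": delta_u, "p_accept": p, "accepted": accepted,
                    "tag": water.tag})
        if accepted:
            config = trial
            current_energy = trial_energy
            if relax_hook is not None:
                n_before = config.n_waters
                config = relax_hook(config)
                if config.n_waters != n_before:
                    raise ValueError("relax_hook must not change the water count")
                current_energy = None  # positions may have moved
    return config, pd.DataFrame(log)


def toy_energy(config: PowderConfig, cutoff: float = 10.0) -> float:
    """Pairwise Lennard-Jones + Coulomb energy (kJ/mol) of the water sites.

    Sums water–protein and water–water site pairs within ``cutoff`` Å with
    Lorentz–Berthelot mixing.  A desk-scale stand-in for a force-field
    evaluation; deterministic, with an explicit error on overlapping sites.
    """
    if config.n_waters == 0:
        return 0.0
    wpos = np.array([w.position for w in config.waters], dtype=float)
    wq = np.array([w.charge for w in config.waters])
    wsig = np.array([w.sigma for w in config.waters])
    weps = np.array([w.epsilon for w in config.waters])
    if not np.isfinite(wpos).all():
        raise ValueError("non-finite water coordinates")

    def pair_energy(r, sig, eps, qq):
        mask = (r < cutoff) & (r > 0)
        if ((r < 0.5) & (r >= 0)).any():
            raise ValueError("overlapping sites (< 0.5 Å)")
        sr6 = (sig[mask] / r[mask]) ** 6
        lj = 4 * eps[mask] * (sr6 ** 2 - sr6)
        coul = COULOMB_CONSTANT * qq[mask] / r[mask]
        return float(lj.sum() + coul.sum())

    total = 0.0
    ppos = config.protein_positions
    if ppos.size:
        d = np.linalg.norm(wpos[:, None, :] - ppos[None, :, :], axis=-1)
        sig = 0.5 * (wsig[:, None] + config.protein_sigma[None, :])
        eps = np.sqrt(weps[:, None] * config.protein_epsilon[None, :])
        qq = wq[:, None] * config.protein_charges[None, :]
        total += pair_energy(d.ravel(), sig.ravel(), eps.ravel(), qq.ravel())
    if config.n_waters > 1:
        iu = np.triu_indices(config.n_waters, k=1)
        d = np.linalg.norm(wpos[iu[0]] - wpos[iu[1]], axis=-1)
        sig = 0.5 * (wsig[iu[0]] + wsig[iu[1]])
        eps = np.sqrt(weps[iu[0]] * weps[iu[1]])
        qq = wq[iu[0]] * wq[iu[1]]
        total += pair_energy(d, sig, eps, qq)
    return total
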