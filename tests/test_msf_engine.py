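"""Rigid superposition and the mean-square-fluctuation statistic.

The brute-force oracles here are written independently of the engine: the
superposition oracle is an SVD Kabsch (the engine goes through scipy's
rotation machinery) or a random-rotation search, and the MSF oracle is a
direct loop evaluation of the defining variance formula.
"""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from powderdyn import (Trajectory, block_errors, compute_msf, kabsch_align,
                       make_topology, select)
from powderdyn.synthetic_data import make_reference_coordinates, make_trajectory


# ---------------------------------------------------------------------------
# independent oracles

def svd_kabsch(P, Q):
    """Align P onto Q: direct SVD solution, independent of the engine."""
    Pc, Qc = P - P.mean(0), Q - Q.mean(0)
    U, _, Vt = np.linalg.svd(Pc.T @ Qc)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, Q.mean(0) - R @ P.mean(0)


def brute_force_msf(coords, align_idx):
    """Direct evaluation: align every frame to frame 0, then the variance of
    each atom's position about its post-alignment mean."""
    aligned = np.empty_like(coords)
    ref = coords[0, align_idx]
    for f in range(coords.shape[0]):
        R, t = svd_kabsch(coords[f, align_idx], ref)
        aligned[f] = coords[f] @ R.T + t
    mean = aligned.mean(axis=0)
    msf = np.zeros(coords.shape[1])
    for i in range(coords.shape[1]):
        for f in range(coords.shape[0]):
            msf[i] += np.sum((aligned[f, i] - mean[i]) ** 2)
    return msf / coords.shape[0]


# ---------------------------------------------------------------------------
# kabsch_align

class TestKabschAlign:
    def test_identity_on_self(self, rng):
        pts = rng.normal(size=(6, 3))
        R, t = kabsch_align(pts, pts)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t, 0.0, atol=1e-9)

    def test_inverts_exact_rotation(self, rng):
        ref = rng.normal(size=(8, 3))
        rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = ref @ rot90.T
        R, t = kabsch_align(mobile, ref)
        fitted = mobile @ R.T + t
        assert np.sqrt(((fitted - ref) ** 2).sum(1).mean()) < 1e-9
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_reduces_rmsd_under_noise(self, rng):
        for _ in range(10):
            ref = rng.normal(size=(10, 3))
            R0 = Rotation.random(rng=rng).as_matrix()
            mobile = ref @ R0.T + rng.uniform(-3, 3, 3) + rng.normal(0, 0.3, (10, 3))
            R, t = kabsch_align(mobile, ref)
            fitted = mobile @ R.T + t
            rmsd_post = np.sqrt(((fitted - ref) ** 2).sum(1).mean())
            rmsd_pre = np.sqrt(((mobile - ref) ** 2).sum(1).mean())
            assert rmsd_post <= rmsd_pre + 1e-12

    def test_beats_random_rotation_search(self, rng):
        """Optimality against a dense random-rotation sample (small instance)."""
        ref = rng.normal(size=(4, 3))
        mobile = ref @ Rotation.random(rng=rng).as_matrix().T + rng.normal(0, 0.2, (4, 3))
        R, t = kabsch_align(mobile, ref)
        best_fit = np.sqrt((((mobile @ R.T + t) - ref) ** 2).sum(1).mean())
        mc, rc = mobile - mobile.mean(0), ref - ref.mean(0)
        sample = Rotation.random(5000, rng=np.random.default_rng(0)).as_matrix()
        rmsds = np.sqrt(((mc @ sample.transpose(0, 2, 1) - rc) ** 2)
                        .sum(-1).mean(-1))
        assert best_fit <= rmsds.min() + 1e-9

    @pytest.mark.parametrize("bad", [
        np.zeros((5, 3)),                                     # coincident
        np.outer(np.arange(5.0), [1.0, 0.0, 0.0]),            # collinear
        np.zeros((2, 3)),                                     # too few
    ])
    def test_degenerate_sets_raise(self, bad, rng):
        with pytest.raises(ValueError):
            kabsch_align(bad, rng.normal(size=bad.shape))


# ---------------------------------------------------------------------------
# compute_msf

class TestComputeMSF:
    def test_static_trajectory_is_zero(self, tiny_topology, rng):
        ref = rng.normal(size=(5, 3))
        traj = Trajectory(tiny_topology, np.repeat(ref[None], 4, axis=0))
        result = compute_msf(traj)
        assert np.allclose(result.per_atom, 0.0, atol=1e-20)
        assert result.ensemble == pytest.approx(0.0, abs=1e-20)

    def test_alternating_atom_msf_is_one(self, tiny_topology, rng):
        """±1 Å displacement about the mean gives exactly 1 Å² variance."""
        ref = rng.normal(size=(5, 3))
        coords = np.repeat(ref[None], 6, axis=0)
        coords[1::2, 4, 0] += 2.0    # atom 5 alternates by 2 Å along x
        traj = Trajectory(tiny_topology, coords)
        result = compute_msf(traj, align_selection=np.arange(4))
        assert result.per_atom.iloc[4] == pytest.approx(1.0, abs=1e-12)
        assert result.per_atom.iloc[:4].max() < 1e-12

    def test_rigid_per_frame_motion_removed(self, tiny_topology, rng):
        ref = rng.normal(size=(5, 3))
        coords = np.stack([
            ref @ Rotation.random(rng=rng).as_matrix().T + rng.uniform(-10, 10, 3)
            for _ in range(8)])
        result = compute_msf(Trajectory(tiny_topology, coords))
        assert result.per_atom.max() < 1e-12

    def test_global_rigid_motion_invariance(self, tiny_topology, rng):
        coords = rng.normal(size=(8, 5, 3))
        r1 = compute_msf(Trajectory(tiny_topology, coords))
        R = Rotation.random(rng=rng).as_matrix()
        moved = coords @ R.T + np.array([5.0, -3.0, 12.0])
        r2 = compute_msf(Trajectory(tiny_topology, moved))
        np.testing.assert_allclose(r1.per_atom, r2.per_atom, rtol=1e-8, atol=1e-12)

    def test_frame_permutation_invariance(self, tiny_topology, rng):
        coords = rng.normal(size=(8, 5, 3))
        r1 = compute_msf(Trajectory(tiny_topology, coords))
        perm = np.r_[0, rng.permutation(np.arange(1, 8))]  # keep the reference frame
        r2 = compute_msf(Trajectory(tiny_topology, coords[perm]))
        np.testing.assert_allclose(r1.per_atom, r2.per_atom, rtol=1e-9)

    def test_brute_force_oracle_equality(self, tiny_topology, rng):
        """Engine equals the direct formula on <= 5 atoms x <= 8 frames."""
        for n_frames in (2, 5, 8):
            coords = rng.normal(size=(n_frames, 5, 3)) + rng.normal(size=(5, 3)) * 4
            result = compute_msf(Trajectory(tiny_topology, coords))
            expected = brute_force_msf(coords, np.arange(5))
            np.testing.assert_allclose(result.per_atom.to_numpy(), expected,
                                       rtol=1e-8, atol=1e-12)

    def test_gaussian_displacements_give_three_sigma_squared(self):
        """i.i.d. Gaussian jitter with per-axis variance σ² has MSF → 3σ²."""
        top = make_topology("GASLV", n_proteins=1)
        target = np.where(top.residue_index <= 2, 0.0, 0.30)
        anchors = np.intersect1d(np.flatnonzero(target == 0),
                                 select(top, "heavy"))
        traj = make_trajectory(top, target, n_frames=5000, seed=11)
        result = compute_msf(traj, selection=np.flatnonzero(target > 0),
                             align_selection=anchors)
        assert result.per_atom.mean() == pytest.approx(0.30, rel=0.05)

    def test_per_protein_between_atom_extremes(self, trpcage_topology):
        traj = make_trajectory(trpcage_topology,
                               np.linspace(0.1, 0.5, trpcage_topology.n_atoms),
                               n_frames=50, seed=3)
        result = compute_msf(traj)
        for k, value in result.per_protein.items():
            atoms = result.per_atom.to_numpy()[
                trpcage_topology.protein_index[select(trpcage_topology, "heavy")] == k]
            assert atoms.min() <= value <= atoms.max()

    def test_ensemble_is_mean_of_proteins(self, trpcage_topology):
        traj = make_trajectory(trpcage_topology, 0.2, n_frames=40, seed=4)
        result = compute_msf(traj)
        assert result.ensemble == pytest.approx(result.per_protein.mean())

    def test_empty_selection_raises(self, tiny_topology, rng):
        traj = Trajectory(tiny_topology, rng.normal(size=(4, 5, 3)))
        with pytest.raises(ValueError):
            compute_msf(traj, selection=np.array([], dtype=int))

    def test_single_frame_raises(self, tiny_topology, rng):
        traj = Trajectory(tiny_topology, rng.normal(size=(1, 5, 3)))
        with pytest.raises(ValueError):
            compute_msf(traj)


# ---------------------------------------------------------------------------
# select

class TestSelect:
    def test_methyl_hydrogens_in_leu_ile_only(self, trpcage_topology):
        idx = select(trpcage_topology, "methyl-h")
        assert set(trpcage_topology.residue_index[idx]) == {2, 4, 7}

    def test_heavy_and_hydrogen_disjoint(self, trpcage_topology):
        assert select(trpcage_topology, "heavy and all-h").size == 0

    def test_methyl_union_nonmethyl_is_all_h(self, trpcage_topology):
        methyl = select(trpcage_topology, "methyl-h")
        nonmethyl = select(trpcage_topology, "non-methyl-h")
        all_h = select(trpcage_topology, "all-h")
        assert np.intersect1d(methyl, nonmethyl).size == 0
        np.testing.assert_array_equal(np.union1d(methyl, nonmethyl), all_h)

    def test_terminal_residues(self, trpcage_topology):
        terminal = np.union1d(select(trpcage_topology, "residue(1)"),
                              select(trpcage_topology, "residue(20)"))
        names = {trpcage_topology.atoms[i].residue_name for i in terminal}
        assert names == {"ASN", "SER"}

    def test_protein_conjunction(self, trpcage_topology):
        idx = select(trpcage_topology, "heavy and protein(1)")
        assert set(trpcage_topology.protein_index[idx]) == {1}

    def test_unknown_token_raises(self, trpcage_topology):
        with pytest.raises(ValueError):
            select(trpcage_topology, "backbone")


# ---------------------------------------------------------------------------
# block errors

class TestBlockErrors:
    def _block_traj(self, topology, amplitudes, block_len=4):
        """One atom oscillating with per-block amplitude a_b; block MSF = a_b²."""
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(5, 3)) * 3
        n_frames = block_len * len(amplitudes)
        coords = np.repeat(ref[None], n_frames, axis=0)
        for b, a in enumerate(amplitudes):
            frames = np.arange(b * block_len, (b + 1) * block_len)
            coords[frames, 4, 0] += a * np.where(frames % 2 == 0, 1.0, -1.0)
        return Trajectory(topology, coords)

    def test_known_block_values(self, tiny_topology):
        """Block MSFs {1..5} Å² give SE = sqrt(2.5)/sqrt(5) for that atom."""
        amplitudes = np.sqrt([1.0, 2.0, 3.0, 4.0, 5.0])
        traj = self._block_traj(tiny_topology, amplitudes)
        errors = block_errors(traj, selection=np.array([4]),
                              align_selection=np.arange(4), n_blocks=5)
        expected = np.std([1, 2, 3, 4, 5], ddof=1) / np.sqrt(5)
        assert errors["per_atom"].iloc[0] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(np.sqrt(2.5) / np.sqrt(5))

    def test_identical_blocks_zero_se(self, tiny_topology):
        traj = self._block_traj(tiny_topology, np.ones(5))
        errors = block_errors(traj, align_selection=np.arange(4), n_blocks=5)
        assert errors["ensemble"] == pytest.approx(0.0, abs=1e-12)

    def test_remainder_frames_dropped(self, tiny_topology, rng):
        coords = rng.normal(size=(23, 5, 3))
        errors = block_errors(Trajectory(tiny_topology, coords), n_blocks=5)
        assert errors["block_length"] == 4

    def test_se_tracks_trajectory_length_not_block_count(self, tiny_topology, rng):
        """For uncorrelated frames the block SE estimates the error of the
        full-trajectory mean: it shrinks as 1/sqrt(N_F) and is roughly
        invariant to how many blocks the trajectory is cut into."""
        short = Trajectory(tiny_topology, rng.normal(size=(256, 5, 3)) * 0.5)
        long = Trajectory(tiny_topology, rng.normal(size=(4096, 5, 3)) * 0.5)
        se_short = block_errors(short, n_blocks=5)["per_atom"].mean()
        se_long = block_errors(long, n_blocks=5)["per_atom"].mean()
        assert 2.2 < se_short / se_long < 7.3   # ideal ratio 4, Monte-Carlo slack
        se4 = block_errors(long, n_blocks=4)["per_atom"].mean()
        se16 = block_errors(long, n_blocks=16)["per_atom"].mean()
        assert 0.5 < se4 / se16 < 2.0

    def test_too_few_blocks_raises(self, tiny_topology, rng):
        traj = Trajectory(tiny_topology, rng.normal(size=(10, 5, 3)))
        with pytest.raises(ValueError):
            block_errors(traj, n_blocks=1)
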