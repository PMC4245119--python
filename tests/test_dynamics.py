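"""Superposition, RMSF/B-factors, PCA essential dynamics, correlations."""
import numpy as np
import pytest

import psnkit as pk
from psnkit.dynamics import DynamicsError, BFACTOR_PREFACTOR

from conftest import sample_isotropic


def random_rigid_motion(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
    return rot, rng.normal(0, 5.0, 3)


class TestSuperpose:
    def test_removes_planted_rigid_motion(self, helix10, rng):
        mask = pk.select_atoms(helix10, "backbone_heavy")
        frames = []
        for _ in range(4):
            rot, shift = random_rigid_motion(rng)
            frames.append(helix10.coords @ rot.T + shift)
        ens = pk.Ensemble(frames=np.array(frames), model=helix10)
        fitted = pk.superpose(ens, mask=mask)
        dev = np.abs(fitted.frames - helix10.coords).max()
        assert dev < 1e-6

    def test_idempotent(self, helix10, rng):
        ens = sample_isotropic(helix10, 0.2, 10, seed=2)
        mask = pk.select_atoms(helix10, "backbone_heavy")
        once = pk.superpose(ens, mask=mask)
        twice = pk.superpose(once, mask=mask)
        assert np.abs(twice.frames - once.frames).max() < 1e-9

    def test_fit_never_increases_rmsd(self, helix10, rng):
        from psnkit.dynamics import rmsd_per_frame
        ens = sample_isotropic(helix10, 1.0, 20, seed=3)
        shifted = pk.Ensemble(frames=ens.frames + rng.normal(0, 3.0, 3),
                              model=helix10)
        mask = pk.select_atoms(helix10, "backbone_heavy")
        fitted = pk.superpose(shifted, mask=mask)
        pre = rmsd_per_frame(shifted, helix10.coords, mask)
        post = rmsd_per_frame(fitted, helix10.coords, mask)
        assert np.all(post <= pre + 1e-12)

    def test_collinear_mask_is_error(self):
        model = pk.build_toy_structure(
            pk.ToyStructureSpec(n_residues=6, geometry="extended"))
        mask = pk.select_atoms(model, "calpha")  # collinear CA trace
        ens = pk.Ensemble(frames=model.coords[None].repeat(2, 0),
                          model=model)
        with pytest.raises(DynamicsError, match="collinear"):
            pk.superpose(ens, mask=mask)


class TestRmsfBfactors:
    def test_zero_fluctuation(self, helix10):
        ens = pk.Ensemble(frames=helix10.coords[None].repeat(3, 0),
                          model=helix10)
        mask = pk.select_atoms(helix10, "backbone_heavy")
        prof = pk.rmsf_bfactors(ens, mask)
        assert np.abs(prof.rmsf).max() < 1e-12
        assert np.abs(prof.bfactor).max() < 1e-12

    def test_isotropic_analytic_expectation(self, helix10):
        """<dr^2> -> 3 sigma^2 and B -> 8 pi^2 sigma^2 for isotropic
        per-coordinate variance sigma^2."""
        sigma2 = 0.4
        ens = sample_isotropic(helix10, sigma2, 10_000, seed=7)
        mask = pk.select_atoms(helix10, "backbone_heavy")
        prof = pk.rmsf_bfactors(ens, mask)
        msd = prof.rmsf ** 2
        assert np.abs(msd - 3 * sigma2).max() < 0.03 * 3 * sigma2
        assert np.allclose(prof.bfactor,
                           BFACTOR_PREFACTOR * msd, rtol=1e-12)

    def test_doubling_displacements_quadruples_b(self, helix10):
        ens = sample_isotropic(helix10, 0.3, 200, seed=9)
        mask = pk.select_atoms(helix10, "backbone_heavy")
        doubled = pk.Ensemble(
            frames=helix10.coords + 2 * (ens.frames - helix10.coords),
            model=helix10)
        b1 = pk.rmsf_bfactors(ens, mask).bfactor
        b2 = pk.rmsf_bfactors(doubled, mask).bfactor
        assert np.allclose(b2, 4 * b1, rtol=1e-9)

    def test_single_frame_is_error(self, helix10):
        ens = pk.Ensemble(frames=helix10.coords[None], model=helix10)
        with pytest.raises(DynamicsError):
            pk.rmsf_bfactors(ens, pk.select_atoms(helix10, "calpha"))


class TestPCA:
    def test_single_direction_mode(self, helix10, rng):
        direction = np.zeros((helix10.n_atoms, 3))
        direction[:, 0] = 1.0
        amp = rng.normal(0, 1.0, 50)
        frames = helix10.coords[None] + amp[:, None, None] * direction
        ens = pk.Ensemble(frames=frames, model=helix10)
        pca = pk.pca_modes(ens, pk.select_atoms(helix10, "backbone_heavy"))
        assert pca.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_variance_fractions_sum_to_one(self, helix10):
        ens = sample_isotropic(helix10, 0.3, 100, seed=4)
        pca = pk.pca_modes(ens, pk.select_atoms(helix10, "backbone_heavy"))
        assert pca.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_eigenvector_orthonormality(self, helix10):
        ens = sample_isotropic(helix10, 0.3, 100, seed=4)
        pca = pk.pca_modes(ens, pk.select_atoms(helix10, "calpha"))
        gram = pca.eigenvectors.T @ pca.eigenvectors
        assert np.abs(gram - np.eye(len(gram))).max() < 1e-8

    def test_reconstruction_completeness(self, helix10):
        """Sum over all modes of lambda |v|^2 equals the total per-atom
        variance."""
        ens = sample_isotropic(helix10, 0.3, 200, seed=5)
        mask = pk.select_atoms(helix10, "backbone_heavy")
        pca = pk.pca_modes(ens, mask)
        msd_all, _ = pk.mode_mobility(pca, n_modes=pca.n_modes)
        coords = ens.frames[:, mask.indices, :]
        centered = coords - coords.mean(axis=0)
        per_atom = (centered ** 2).sum(axis=2).sum(axis=0) \
            / (ens.n_frames - 1)
        from psnkit.dynamics import _per_residue_mean
        expected = _per_residue_mean(per_atom, pca.atom_residue_index,
                                     len(pca.residue_keys))
        assert np.abs(msd_all - expected).max() < 1e-8 * expected.max()

    def test_rank_one_mode_mobility_proportional_to_loadings(self, helix10):
        direction = np.zeros((helix10.n_atoms, 3))
        loadings = np.linspace(1.0, 2.0, helix10.n_atoms)
        direction[:, 2] = loadings
        amp = np.random.default_rng(0).normal(0, 1.0, 300)
        frames = helix10.coords[None] + amp[:, None, None] * direction
        ens = pk.Ensemble(frames=frames, model=helix10)
        mask = pk.select_atoms(helix10, "calpha")
        pca = pk.pca_modes(ens, mask)
        msd, _ = pk.mode_mobility(pca, n_modes=1)
        expected = loadings[mask.indices] ** 2
        ratio = msd / expected
        assert ratio.std() / ratio.mean() < 1e-9

    def test_mode_count_validation(self, helix10):
        ens = sample_isotropic(helix10, 0.3, 20, seed=6)
        pca = pk.pca_modes(ens, pk.select_atoms(helix10, "calpha"))
        with pytest.raises(DynamicsError):
            pk.mode_mobility(pca, n_modes=0)
        with pytest.raises(DynamicsError):
            pk.mode_mobility(pca, n_modes=pca.n_modes + 1)

    def test_mobility_invariant_under_global_rigid_motion(self, helix10,
                                                          rng):
        ens = sample_isotropic(helix10, 0.5, 300, seed=8)
        rot, shift = random_rigid_motion(rng)
        moved = pk.Ensemble(frames=ens.frames @ rot.T + shift,
                            model=helix10)
        mask = pk.select_atoms(helix10, "backbone_heavy")
        b_orig = pk.rmsf_bfactors(pk.superpose(ens, mask=mask),
                                  mask).bfactor
        b_moved = pk.rmsf_bfactors(pk.superpose(moved, mask=mask),
                                   mask).bfactor
        assert np.allclose(b_orig, b_moved, rtol=1e-6, atol=1e-9)


class TestCrossCorrelation:
    def test_diagonal_is_one(self, helix10):
        ens = sample_isotropic(helix10, 0.2, 50, seed=1)
        corr = pk.cross_correlation(ens)
        assert np.allclose(np.diag(corr.C), 1.0, atol=1e-9)

    def test_identical_displacements_fully_correlated(self, helix10, rng):
        shifts = rng.normal(0, 1.0, (40, 1, 3))
        frames = helix10.coords[None] + shifts
        ens = pk.Ensemble(frames=frames, model=helix10)
        corr = pk.cross_correlation(ens)
        assert np.abs(corr.C - 1.0).max() < 1e-9

    def test_independent_residues_near_zero(self, helix10):
        ens = sample_isotropic(helix10, 0.3, 10_000, seed=12)
        corr = pk.cross_correlation(ens)
        off = corr.C[~np.eye(10, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_zero_fluctuation_residue_is_error(self, helix10, rng):
        frames = helix10.coords[None].repeat(10, 0)
        moving = helix10.group_index != 0   # residue 0 frozen
        frames[:, moving, :] += rng.normal(0, 0.5, (10, moving.sum(), 3))
        ens = pk.Ensemble(frames=frames, model=helix10)
        with pytest.raises(DynamicsError, match="ALA1"):
            pk.cross_correlation(ens)

    def test_planted_rho_recovery(self, helix10):
        spec = pk.PlantedCovarianceSpec(
            per_residue_scale=np.full(10, 0.4),
            modules=(pk.CorrelationModule((2, 3, 4, 5), 0.8),))
        cov = pk.make_planted_covariance(spec, helix10)
        ens = pk.sample_ensemble(helix10, cov, 10_000, seed=21)
        corr = pk.cross_correlation(ens)
        module_pairs = [(i, j) for i in (2, 3, 4, 5) for j in (2, 3, 4, 5)
                        if i < j]
        vals = np.array([corr.C[i, j] for i, j in module_pairs])
        assert np.abs(vals - 0.8).max() < 0.05
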