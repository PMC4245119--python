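"""Superposition, fluctuation statistics, essential dynamics and
residue cross-correlations.

All quantities are computed about the ensemble mean structure.  "Lowest
frequency" modes are identified with the largest-variance principal
components, the standard essential-dynamics convention.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import AtomMask, Ensemble, StructureModel

BFACTOR_PREFACTOR = 8.0 * np.pi ** 2 / 3.0


class DynamicsError(ValueError):
    pass


# ----------------------------------------------------------------------
# Superposition
# ----------------------------------------------------------------------

def _kabsch_rotations(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Batched optimal rotations (F, 3, 3) for centered coordinate sets."""
    h = np.einsum("fai,faj->fij", mobile, target)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("fij,fjk->fik", u, vt))
    d = np.repeat(np.eye(3)[None], len(h), axis=0)
    d[:, 2, 2] = np.sign(det)
    # rotation applied as points @ R
    return np.einsum("fij,fjk,fkl->fil", u, d, vt)


def superpose(ensemble: Ensemble, reference: np.ndarray | None = None,
              mask: AtomMask | None = None) -> Ensemble:
    """Least-squares rigid-body fit of every frame onto the reference.

    The fit is computed over the masked atoms and applied to all atoms.
    ``reference`` defaults to the model coordinates.
    """
    ref = np.asarray(reference if reference is not None
                     else ensemble.model.coords, dtype=float)
    idx = mask.indices if mask is not None else np.arange(ref.shape[0])
    if len(idx) < 3:
        raise DynamicsError("superposition mask needs at least 3 atoms")

    ref_sel = ref[idx]
    ref_center = ref_sel.mean(axis=0)
    ref_c = ref_sel - ref_center
    sv = np.linalg.svd(ref_c, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise DynamicsError(
            "mask geometry is degenerate (collinear reference atoms)")

    mob_sel = ensemble.frames[:, idx, :]
    mob_center = mob_sel.mean(axis=1, keepdims=True)
    rot = _kabsch_rotations(mob_sel - mob_center, ref_c[None].repeat(
        ensemble.n_frames, axis=0))
    fitted = np.einsum("fai,fij->faj",
                       ensemble.frames - mob_center, rot) + ref_center
    return Ensemble(frames=fitted, model=ensemble.model,
                    frame_weights=ensemble.frame_weights,
                    meta={**ensemble.meta, "superposed": True})


def rmsd_per_frame(ensemble: Ensemble, reference: np.ndarray,
                   mask: AtomMask | None = None) -> np.ndarray:
    idx = mask.indices if mask is not None else slice(None)
    diff = ensemble.frames[:, idx, :] - reference[idx]
    return np.sqrt((diff ** 2).sum(axis=2).mean(axis=1))


# ----------------------------------------------------------------------
# Fluctuation statistics
# ----------------------------------------------------------------------

@dataclass
class MobilityProfile:
    residue_keys: list
    rmsf: np.ndarray           # A, per residue
    bfactor: np.ndarray        # A^2, (8 pi^2 / 3) <dr^2>
    msd_per_atom: np.ndarray   # A^2, over masked atoms
    mode_mobility: np.ndarray | None = None   # A^2, from low-frequency modes
    mode_bfactor: np.ndarray | None = None


def _residue_map(model: StructureModel, mask: AtomMask):
    """Masked-atom -> residue mapping plus the residue keys present."""
    res_of_atom = np.full(model.n_atoms, -1, dtype=int)
    for r, g in enumerate(model.residue_groups):
        res_of_atom[model.atoms_of_group(g)] = r
    res_idx = res_of_atom[mask.indices]
    if np.any(res_idx < 0):
        raise DynamicsError("mask contains non-protein atoms")
    present = np.unique(res_idx)
    keys = [model.residue_keys()[r] for r in present]
    local = np.searchsorted(present, res_idx)
    return local, keys


def _per_residue_mean(values: np.ndarray, local_res: np.ndarray,
                      n_res: int) -> np.ndarray:
    sums = np.bincount(local_res, weights=values, minlength=n_res)
    counts = np.bincount(local_res, minlength=n_res)
    return sums / counts


def rmsf_bfactors(ensemble: Ensemble, mask: AtomMask) -> MobilityProfile:
    """Per-residue RMSF and computed B-factors about the ensemble mean.

    The residue value averages the mean-square displacement over the
    residue's masked atoms; B = (8 pi^2 / 3) <dr^2>.
    """
    if ensemble.n_frames < 2:
        raise DynamicsError("need at least 2 frames for fluctuations")
    coords = ensemble.frames[:, mask.indices, :]
    msd_atom = ((coords - coords.mean(axis=0)) ** 2).sum(axis=2).mean(axis=0)
    local, keys = _residue_map(ensemble.model, mask)
    msd_res = _per_residue_mean(msd_atom, local, len(keys))
    return MobilityProfile(
        residue_keys=keys, rmsf=np.sqrt(msd_res),
        bfactor=BFACTOR_PREFACTOR * msd_res, msd_per_atom=msd_atom)


# ----------------------------------------------------------------------
# PCA / essential dynamics
# ----------------------------------------------------------------------

@dataclass
class PCAResult:
    eigenvalues: np.ndarray       # A^2, descending
    eigenvectors: np.ndarray      # (3*A_sel, n_modes), orthonormal columns
    variance_fractions: np.ndarray
    mean_structure: np.ndarray    # (A_sel, 3)
    mask: AtomMask
    atom_residue_index: np.ndarray   # masked atom -> local residue index
    residue_keys: list

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


def pca_modes(ensemble: Ensemble, mask: AtomMask) -> PCAResult:
    """Eigendecomposition of the covariance of mean-centered masked
    coordinates; modes sorted by decreasing variance."""
    if ensemble.n_frames < 2:
        raise DynamicsError("need at least 2 frames for PCA")
    coords = ensemble.frames[:, mask.indices, :]
    mean = coords.mean(axis=0)
    x = (coords - mean).reshape(ensemble.n_frames, -1)
    cov = (x.T @ x) / (ensemble.n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    fractions = evals / total if total > 0 else np.zeros_like(evals)
    local, keys = _residue_map(ensemble.model, mask)
    return PCAResult(eigenvalues=evals, eigenvectors=evecs,
                     variance_fractions=fractions, mean_structure=mean,
                     mask=mask, atom_residue_index=local, residue_keys=keys)


def mode_mobility(pca: PCAResult, n_modes: int = 3):
    """Per-residue mean-square mobility reconstructed from the top modes.

    The default of three modes follows the essential-dynamics practice of
    describing collective motions in the space of the lowest-frequency
    (largest-variance) principal components.  Returns (per-residue <dr^2>,
    pseudo-B-factor).
    """
    if n_modes < 1:
        raise DynamicsError("n_modes must be >= 1")
    if n_modes > pca.n_modes:
        raise DynamicsError(
            f"n_modes {n_modes} exceeds available modes {pca.n_modes}")
    v = pca.eigenvectors[:, :n_modes]
    lam = pca.eigenvalues[:n_modes]
    per_coord = (v ** 2) * lam[None, :]
    msd_atom = per_coord.sum(axis=1).reshape(-1, 3).sum(axis=1)
    msd_res = _per_residue_mean(msd_atom, pca.atom_residue_index,
                                len(pca.residue_keys))
    return msd_res, BFACTOR_PREFACTOR * msd_res


# ----------------------------------------------------------------------
# Cross-correlations
# ----------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    C: np.ndarray
    residue_keys: list
    representative: str

    @property
    def n(self) -> int:
        return self.C.shape[0]


def representative_coordinates(ensemble: Ensemble,
                               representative: str = "CA") -> np.ndarray:
    """(F, N_res, 3) coordinates of the residue representative point."""
    model = ensemble.model
    if representative == "CA":
        idx = []
        for g in model.residue_groups:
            atoms = model.atoms_of_group(g)
            ca = atoms[model.atom_name[atoms] == "CA"]
            if len(ca) == 0:
                raise DynamicsError(
                    f"residue {model.group_key(g)} has no CA atom")
            idx.append(ca[0])
        return ensemble.frames[:, idx, :]
    if representative == "centroid":
        out = np.empty((ensemble.n_frames, model.n_residues, 3))
        for r, g in enumerate(model.residue_groups):
            out[:, r, :] = ensemble.frames[:, model.atoms_of_group(g), :]\
                .mean(axis=1)
        return out
    raise DynamicsError(f"unknown representative {representative!r}")


def cross_correlation(ensemble: Ensemble,
                      representative: str = "CA") -> CorrelationMatrix:
    """Normalized residue cross-correlation matrix.

    C_ij = <dr_i . dr_j> / sqrt(<dr_i^2><dr_j^2>) over displacement vectors
    of the representative atom, averaged over frames.
    """
    if ensemble.n_frames < 2:
        raise DynamicsError("need at least 2 frames for correlations")
    coords = representative_coordinates(ensemble, representative)
    disp = coords - coords.mean(axis=0)
    inner = np.einsum("fnd,fmd->nm", disp, disp) / ensemble.n_frames
    var = np.diag(inner)
    zero = np.flatnonzero(var < 1e-15)
    if len(zero):
        keys = ensemble.model.residue_keys()
        raise DynamicsError(
            f"residue {keys[zero[0]]} has zero total fluctuation")
    denom = np.sqrt(np.outer(var, var))
    c = inner / denom
    c = np.clip(c, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(C=c, residue_keys=ensemble.model.residue_keys(),
                             representative=representative)
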