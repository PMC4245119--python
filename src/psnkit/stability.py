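"""Force-constant rigidity profiles, solvent accessibility and
stabilization-center detection.

The force constant of residue i is the inverse variance of its mean
distance d_i to all sequence-non-neighboring residues over the ensemble,

    k_i = 3 k_B T / <(d_i - <d_i>)^2>,

so rigid residues (small distance fluctuations) receive large constants.
Sequence neighbors are excluded because their distances are nearly
constant and would dilute the signal.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import biotite.structure as struc
from scipy import stats

from .structure import Ensemble, StructureModel
from .dynamics import representative_coordinates

KB_KCAL = 0.0019872041          # kcal / (mol K)
DEFAULT_TEMPERATURE = 300.0     # K
VAR_FLOOR = 1e-6                # A^2; variances below are capped + flagged

RSA_BURIED_MAX = 20.0           # %; buried if below
RSA_EXPOSED_MIN = 50.0          # %; exposed if above
RSA_CAP = 200.0


def _load_table(name: str) -> dict:
    with resources.files("psnkit.data").joinpath(name).open() as fh:
        table = json.load(fh)
    table.pop("_comment", None)
    return table


class StabilityError(ValueError):
    pass


# ----------------------------------------------------------------------
# Force constants
# ----------------------------------------------------------------------

@dataclass
class ForceConstantProfile:
    residue_keys: list
    k: np.ndarray          # kcal mol^-1 A^-2
    d_mean: np.ndarray     # A
    d_var: np.ndarray      # A^2
    capped: np.ndarray     # bool
    temperature: float     # K


def force_constants(ensemble: Ensemble,
                    temperature: float = DEFAULT_TEMPERATURE,
                    exclude_neighbors: int = 1,
                    representative: str = "CA",
                    var_floor: float = VAR_FLOOR,
                    chunk: int = 2000) -> ForceConstantProfile:
    """Per-residue force constants from mean-distance fluctuations.

    ``exclude_neighbors = 1`` drops residues i +/- 1 within the same chain
    from the distance average.  Residues whose distance variance falls
    below ``var_floor`` are capped and flagged rather than reported with a
    divergent constant.
    """
    if ensemble.n_frames < 2:
        raise StabilityError("need at least 2 frames")
    model = ensemble.model
    n = model.n_residues
    if n < 4:
        raise StabilityError("need at least 4 residues")
    coords = representative_coordinates(ensemble, representative)

    chain_pos = model.residue_chain_positions()
    allowed = np.ones((n, n), dtype=bool)
    np.fill_diagonal(allowed, False)
    for i in range(n):
        ci, pi = chain_pos[i]
        for j in range(i + 1, n):
            cj, pj = chain_pos[j]
            if ci == cj and abs(pi - pj) <= exclude_neighbors:
                allowed[i, j] = allowed[j, i] = False
    counts = allowed.sum(axis=1).astype(float)
    if np.any(counts == 0):
        raise StabilityError("a residue has no allowed distance partners")

    n_frames = ensemble.n_frames
    d_sum = np.zeros(n)
    d_sqsum = np.zeros(n)
    for start in range(0, n_frames, chunk):
        block = coords[start:start + chunk]
        diff = block[:, :, None, :] - block[:, None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=3))
        d_i = (dist * allowed).sum(axis=2) / counts
        d_sum += d_i.sum(axis=0)
        d_sqsum += (d_i ** 2).sum(axis=0)
    d_mean = d_sum / n_frames
    # unbiased variance over frames
    d_var = (d_sqsum - n_frames * d_mean ** 2) / (n_frames - 1)
    d_var = np.maximum(d_var, 0.0)

    capped = d_var < var_floor
    k = 3.0 * KB_KCAL * temperature / np.maximum(d_var, var_floor)
    return ForceConstantProfile(
        residue_keys=model.residue_keys(), k=k, d_mean=d_mean, d_var=d_var,
        capped=capped, temperature=temperature)


# ----------------------------------------------------------------------
# SASA / relative solvent accessibility
# ----------------------------------------------------------------------

@dataclass
class RSAProfile:
    residue_keys: list
    sasa: np.ndarray        # A^2
    max_asa: np.ndarray     # A^2 reference
    rsa: np.ndarray         # %
    rsa_class: list         # buried / intermediate / exposed
    capped: np.ndarray      # RSA hit the 200 % cap


def classify_rsa(rsa: float, buried_max: float = RSA_BURIED_MAX,
                 exposed_min: float = RSA_EXPOSED_MIN) -> str:
    if rsa < buried_max:
        return "buried"
    if rsa > exposed_min:
        return "exposed"
    return "intermediate"


def sasa_rsa(model: StructureModel, probe: float = 1.4,
             n_sphere_points: int = 960,
             buried_max: float = RSA_BURIED_MAX,
             exposed_min: float = RSA_EXPOSED_MIN) -> RSAProfile:
    """Shrake-Rupley SASA per residue and relative solvent accessibility.

    RSA = 100 * SASA / reference-maximum ASA of the residue type; residues
    are exposed above ``exposed_min`` %, buried below ``buried_max`` %.
    Extended toy conformers can exceed 100 %; values are capped at 200 %
    with a flag.
    """
    table = _load_table("max_asa.json")
    arr = model.to_biotite()
    atom_sasa = struc.sasa(arr, probe_radius=probe,
                           point_number=n_sphere_points)
    atom_sasa = np.nan_to_num(atom_sasa, nan=0.0)
    keys, sasa_vals, max_vals, rsa_vals, classes, capped = \
        [], [], [], [], [], []
    for g in model.residue_groups:
        res_name = model.groups[g]["res_name"]
        if res_name not in table:
            raise StabilityError(
                f"residue type {res_name!r} missing from max-ASA table")
        total = float(atom_sasa[model.atoms_of_group(g)].sum())
        rsa = 100.0 * total / table[res_name]
        flag = rsa > RSA_CAP
        rsa = min(rsa, RSA_CAP)
        keys.append(model.group_key(g))
        sasa_vals.append(total)
        max_vals.append(table[res_name])
        rsa_vals.append(rsa)
        classes.append(classify_rsa(rsa, buried_max, exposed_min))
        capped.append(flag)
    return RSAProfile(residue_keys=keys, sasa=np.array(sasa_vals),
                      max_asa=np.array(max_vals), rsa=np.array(rsa_vals),
                      rsa_class=classes, capped=np.array(capped))


# ----------------------------------------------------------------------
# Stabilization centers (simplified: no conservation term)
# ----------------------------------------------------------------------

@dataclass
class StabilizationCenterSet:
    residue_keys: list
    long_range_contacts: np.ndarray
    hydrophobicity: np.ndarray
    flagged: np.ndarray
    simplified: bool = True   # conservation / stabilization-center index
                              # components are intentionally not included


def stabilization_centers(model: StructureModel,
                          min_long_range_contacts: int = 2,
                          seq_sep: int = 10,
                          contact_cutoff: float = 4.5,
                          hydrophobicity_min: float = 0.0
                          ) -> StabilizationCenterSet:
    """Flag residues with enough long-range heavy-atom contacts and high
    hydrophobicity (simplified stabilization-center criterion)."""
    scale = _load_table("hydrophobicity.json")
    n = model.n_residues
    chain_pos = model.residue_chain_positions()
    res_groups = model.residue_groups
    atom_lists = [model.atoms_of_group(g) for g in res_groups]
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        ci, pi = chain_pos[i]
        xi = model.coords[atom_lists[i]]
        for j in range(i + 1, n):
            cj, pj = chain_pos[j]
            if ci == cj and abs(pi - pj) < seq_sep:
                continue
            xj = model.coords[atom_lists[j]]
            d2 = ((xi[:, None, :] - xj[None, :, :]) ** 2).sum(axis=2)
            if np.any(d2 <= contact_cutoff ** 2):
                counts[i] += 1
                counts[j] += 1
    hydro = np.array([scale.get(model.groups[g]["res_name"], 0.0)
                      for g in res_groups])
    flagged = (counts >= min_long_range_contacts) \
        & (hydro > hydrophobicity_min)
    return StabilizationCenterSet(
        residue_keys=model.residue_keys(), long_range_contacts=counts,
        hydrophobicity=hydro, flagged=flagged)


# ----------------------------------------------------------------------
# Profile-vs-profile correlation
# ----------------------------------------------------------------------

@dataclass
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int


def profile_correlation(x, y) -> CorrelationResult:
    """Pearson (and Spearman rank) correlation between two per-residue
    metric profiles, with two-sided p-values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise StabilityError("profiles must be equal-length 1-D with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise StabilityError("profiles must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StabilityError("zero-variance profile")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return CorrelationResult(pearson_r=float(pr.statistic),
                             pearson_p=float(pr.pvalue),
                             spearman_rho=float(sr.statistic),
                             spearman_p=float(sr.pvalue), n=len(x))
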