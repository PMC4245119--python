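"""Synthetic structures and Gaussian conformational ensembles.

Stands in for molecular-dynamics ensembles: toy backbones with ideal
CA-CA spacing, a planted residue-level covariance (isotropic per-residue
variance, correlated residue modules), and Gaussian sampling in which every
atom of a residue is displaced rigidly with its CA so that contact topology
stays nearly frame-invariant.  A contact-flicker option expands a chosen
module in a fraction of frame blocks to break its contacts, which exercises
the community-persistence machinery downstream.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import Ensemble, StructureModel, StructureError

GEOMETRIES = ("alpha_helix", "extended", "two_domain")

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class ToyStructureSpec:
    n_residues: int
    geometry: str = "alpha_helix"
    sequence: str | None = None  # one-letter; default poly-Ala
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 4:
            raise ValueError("toy structures need at least 4 residues")
        if self.geometry not in GEOMETRIES:
            raise ValueError(
                f"unknown geometry {self.geometry!r}; valid: {GEOMETRIES}")
        seq = self.sequence or "A" * self.n_residues
        if len(seq) != self.n_residues:
            raise ValueError("sequence length must equal n_residues")
        if any(c not in _ONE_TO_THREE for c in seq):
            raise ValueError("sequence contains unknown residue letters")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class CorrelationModule:
    indices: tuple
    rho: float

    def __post_init__(self):
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("module correlation rho must be in [0, 1)")
        object.__setattr__(self, "indices", tuple(int(i) for i in self.indices))


@dataclass(frozen=True)
class CrossCorrelation:
    """Planted correlation between one residue (e.g. an inter-domain
    bridge) and a set of target residues."""

    index: int
    targets: tuple
    rho: float

    def __post_init__(self):
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("cross-correlation rho must be in [0, 1)")
        object.__setattr__(self, "targets",
                           tuple(int(t) for t in self.targets))


@dataclass(frozen=True)
class PlantedCovarianceSpec:
    """Isotropic per-residue positional variance (A^2 per coordinate) plus
    correlated residue modules and an optional weak background correlation."""

    per_residue_scale: np.ndarray
    modules: tuple = ()
    background_correlation: float = 0.0
    cross_links: tuple = ()

    def __post_init__(self):
        scale = np.asarray(self.per_residue_scale, dtype=float)
        if scale.ndim != 1 or np.any(scale <= 0):
            raise ValueError("per_residue_scale must be a positive 1-D vector")
        if not 0.0 <= self.background_correlation <= 0.2:
            raise ValueError("background_correlation must be in [0, 0.2]")
        object.__setattr__(self, "per_residue_scale", scale)
        object.__setattr__(self, "modules", tuple(self.modules))


# ----------------------------------------------------------------------
# Toy geometries (CA traces with consecutive spacing 3.8 +/- 0.1 A)
# ----------------------------------------------------------------------

def _helix_trace(n: int) -> np.ndarray:
    # radius 2.3 A, 100 deg/residue, 1.5 A rise: CA-CA ~3.82 A
    t = np.arange(n) * np.deg2rad(100.0)
    return np.stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n)],
                    axis=1)


def _extended_trace(n: int) -> np.ndarray:
    trace = np.zeros((n, 3))
    trace[:, 0] = 3.8 * np.arange(n)
    return trace


def two_domain_layout(n: int):
    """Residue-index partition of the two-domain geometry.

    Returns (module_a, bridge_index, module_b).  The single bridge residue
    is the only inter-domain connector in the contact graph, so it carries
    all shortest paths between the domains.
    """
    if n < 30:
        raise ValueError("two_domain geometry needs at least 30 residues")
    a_size = (n - 2) // 2
    bridge = a_size
    return (tuple(range(a_size)), bridge, tuple(range(a_size + 1, n)))


# Bridge "clamp": the bridge residue sits at the origin flanked by two
# gateway residues per domain (atoms within contact range of the bridge),
# so inter-domain traffic splits across the gateways while every shortest
# path still crosses the bridge itself.  Chain steps are all 3.7-3.9 A and
# cross-side atom distances stay above the 4.5 A contact cutoff (checked
# numerically when the geometry was designed, and re-validated on build).
_CLAMP_OFFSETS = {
    -4: (2.0, -4.6, 0.0),           # gateway A1
    -3: (0.0, -5.161, -3.182),
    -2: (-2.0, -4.6, 0.0),          # gateway A2
    -1: (-3.578, -1.179, 0.496),
    0: (0.0, 0.0, 0.0),             # bridge
    1: (1.685, 1.428, -3.092),
    2: (1.732, 4.6, -1.0),          # gateway B1
    3: (1.518, 5.705, 2.629),
    4: (-1.732, 4.6, 1.0),          # gateway B2
}
# Planted bulk anchors adjacent to the clamp, wiring both gateways of each
# side into the domain bulk with |i-j| >= 2 contacts.
_A_ANCHORS = [(4.674, -7.3, 0.0), (1.174, -7.6, 1.4), (-2.526, -7.4, 1.0)]
_B_ANCHORS = [(-4.048, 7.3, 2.337), (-1.717, 7.6, -0.625),
              (1.688, 7.4, -2.129)]


def _grow_globule(n_grow: int, start: np.ndarray, center: np.ndarray,
                  occupied: list, rng: np.random.Generator,
                  y_bound: float, y_sign: float) -> list:
    """Grow a compact self-avoiding CA chain of ``n_grow`` residues from
    ``start`` biased toward ``center``; stays in the half-space
    y_sign * y >= y_sign * y_bound with 3.4 A minimum separation."""
    grown = []
    prev = np.asarray(start, dtype=float)
    occ = np.array(occupied + [list(prev)], dtype=float)
    for _ in range(n_grow):
        direction = rng.standard_normal((300, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        cand = prev + 3.8 * direction
        ok = y_sign * cand[:, 1] >= y_sign * y_bound
        d = np.linalg.norm(cand[:, None, :] - occ[None, :, :], axis=2)
        ok &= d.min(axis=1) >= 3.4
        cand = cand[ok]
        if len(cand) == 0:
            raise ValueError("globule growth stalled")
        score = np.linalg.norm(cand - center, axis=1) \
            + 0.3 * rng.standard_normal(len(cand))
        nxt = cand[np.argmin(score)]
        grown.append(nxt)
        occ = np.vstack([occ, nxt])
        prev = nxt
    return grown


def _two_domain_trace(n: int, seed: int) -> np.ndarray:
    """Two compact globular domains joined by the bridge clamp.

    The construction is validated (and regrown under a derived sub-seed if
    needed) so that each domain percolates into one k = 3 clique community,
    the bridge has at least two gateway edges per side, and no direct
    inter-domain contact exists.
    """
    mod_a, bridge, mod_b = two_domain_layout(n)
    n_bulk_a = len(mod_a) - 4
    n_bulk_b = len(mod_b) - 4
    last_err = "no attempt"
    for attempt in range(40):
        rng = np.random.default_rng([seed % (2 ** 31), attempt])
        coords = np.zeros((n, 3))
        for off, pos in _CLAMP_OFFSETS.items():
            coords[bridge + off] = pos
        clamp = [list(p) for p in _CLAMP_OFFSETS.values()]
        # A side: planted anchors at indices bridge-5..bridge-7, growth on
        a_anchor_idx = [bridge - 5, bridge - 6, bridge - 7]
        for idx, pos in zip(a_anchor_idx, _A_ANCHORS):
            coords[idx] = pos
        b_anchor_idx = [bridge + 5, bridge + 6, bridge + 7]
        for idx, pos in zip(b_anchor_idx, _B_ANCHORS):
            coords[idx] = pos
        try:
            grown_a = _grow_globule(
                n_bulk_a - 3, start=_A_ANCHORS[-1],
                center=np.array([-1.0, -12.0, 0.0]),
                occupied=clamp + [list(p) for p in _A_ANCHORS],
                rng=rng, y_bound=-6.8, y_sign=-1.0)
            grown_b = _grow_globule(
                n_bulk_b - 3, start=_B_ANCHORS[-1],
                center=np.array([-1.0, 12.0, 0.0]),
                occupied=clamp + [list(p) for p in _A_ANCHORS]
                + [list(p) for p in grown_a] + [list(p) for p in _B_ANCHORS],
                rng=rng, y_bound=6.8, y_sign=1.0)
        except ValueError as err:
            last_err = str(err)
            continue
        # growth proceeds away from the clamp: indices descend on A side
        for k, pos in enumerate(grown_a):
            coords[bridge - 8 - k] = pos
        for k, pos in enumerate(grown_b):
            coords[bridge + 8 + k] = pos
        problem = _validate_two_domain(coords, mod_a, bridge, mod_b)
        if problem is None:
            return coords
        last_err = problem
    raise ValueError(
        f"could not construct a valid two-domain fold: {last_err}")


def _validate_two_domain(ca: np.ndarray, mod_a, bridge, mod_b):
    """Check the planted contact-graph properties; returns None or a
    description of the violation."""
    import networkx as nx
    from . import network  # local import avoids a cycle at import time

    model = model_from_ca(ca, "A" * len(ca))
    i_mat, keys = network.interaction_strength_matrix(model)
    edges = i_mat > network.DEFAULT_I_MIN
    a_set, b_set = set(mod_a), set(mod_b)
    a_gate = sum(bool(edges[bridge, j]) for j in mod_a)
    b_gate = sum(bool(edges[bridge, j]) for j in mod_b)
    if a_gate < 2 or b_gate < 2:
        return f"bridge gateways {a_gate}/{b_gate} < 2"
    psn = network.build_psn(i_mat, np.eye(len(ca)), keys)
    # the bridge must be a cut vertex separating the two modules
    cut = psn.graph.copy()
    cut.remove_node(keys[bridge])
    for comp in nx.connected_components(cut):
        idx = {keys.index(k) for k in comp}
        if idx & a_set and idx & b_set:
            return "bridge is not a cut vertex (inter-domain bypass)"
    # ... and the strict betweenness maximum of the static network
    bc = network.betweenness_profile(psn)
    others = np.delete(bc, bridge)
    if not bc[bridge] > 1.02 * others.max():
        return (f"bridge betweenness {bc[bridge]:.3f} not the strict "
                f"maximum (runner-up {others.max():.3f})")
    comms = network.cpm_communities(psn, k=3)
    for name, mod in (("A", a_set), ("B", b_set)):
        other = b_set if name == "A" else a_set
        best = max((len(set(keys.index(m) for m in c.members) & mod)
                    for c in comms), default=0)
        covering = [c for c in comms
                    if len(set(keys.index(m) for m in c.members) & mod)
                    == best]
        if best < 0.7 * len(mod):
            return f"module {name} community covers only {best} residues"
        if covering and set(keys.index(m)
                            for m in covering[0].members) & other:
            return f"module {name} community leaks into the other domain"
    return None


def _place_atoms(ca: np.ndarray, sequence: str):
    """Backbone-heavy atoms (N, CA, CB, C, O; no CB for Gly) in a local
    frame derived from the chain tangent.  Offsets are compact (< 2 A) so
    that contact reach stays close to the CA trace."""
    n_res = len(ca)
    tangents = np.zeros_like(ca)
    tangents[1:-1] = ca[2:] - ca[:-2]
    tangents[0] = ca[1] - ca[0]
    tangents[-1] = ca[-1] - ca[-2]
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)

    names, elements, res_names, resid, coords = [], [], [], [], []
    up = np.array([0.0, 0.0, 1.0])
    for i in range(n_res):
        t = tangents[i]
        b = np.cross(t, up)
        nb = np.linalg.norm(b)
        if nb < 1e-8:  # tangent parallel to z: pick x as normal
            b = np.array([1.0, 0.0, 0.0])
        else:
            b /= nb
        nvec = np.cross(b, t)
        res3 = _ONE_TO_THREE[sequence[i]]
        offsets = [("N", "N", -1.20 * t + 0.50 * nvec),
                   ("CA", "C", np.zeros(3)),
                   ("C", "C", 1.20 * t + 0.50 * nvec),
                   ("O", "O", 1.40 * t + 1.60 * nvec)]
        if res3 != "GLY":
            offsets.insert(2, ("CB", "C", -0.40 * t - 0.80 * nvec + 1.20 * b))
        for name, elem, off in offsets:
            names.append(name)
            elements.append(elem)
            res_names.append(res3)
            resid.append(i + 1)
            coords.append(ca[i] + off)
    return names, elements, res_names, resid, np.array(coords)


def model_from_ca(ca: np.ndarray, sequence: str,
                  chain: str = "A") -> StructureModel:
    """Build a toy StructureModel from an explicit CA trace."""
    ca = np.asarray(ca, dtype=float)
    names, elements, res_names, resid, coords = _place_atoms(ca, sequence)
    n = len(names)
    return StructureModel(
        atom_name=names, element=elements, res_name=res_names,
        chain_id=[chain] * n, author_resid=resid, icode=[""] * n,
        coords=coords, is_ligand=[False] * n)


def build_toy_structure(spec: ToyStructureSpec) -> StructureModel:
    """Deterministic ideal-geometry toy backbone for a given spec."""
    if spec.geometry == "alpha_helix":
        ca = _helix_trace(spec.n_residues)
    elif spec.geometry == "extended":
        ca = _extended_trace(spec.n_residues)
    else:
        ca = _two_domain_trace(spec.n_residues, spec.seed)
    return model_from_ca(ca, spec.sequence)


# ----------------------------------------------------------------------
# Planted covariance and Gaussian sampling
# ----------------------------------------------------------------------

def make_planted_covariance(spec: PlantedCovarianceSpec,
                            model: StructureModel) -> np.ndarray:
    """Assemble the 3N x 3N covariance over CA coordinates.

    Per-residue blocks are isotropic (scale_i * I3); within-module pairs get
    displacement correlation rho, everything else the background value.
    """
    n = model.n_residues
    scale = spec.per_residue_scale
    if len(scale) != n:
        raise ValueError(
            f"per_residue_scale length {len(scale)} != {n} residues")
    claimed = set()
    for mod in spec.modules:
        if any(i < 0 or i >= n for i in mod.indices):
            raise ValueError("module indices out of range")
        if claimed & set(mod.indices):
            raise ValueError("modules must not overlap")
        claimed.update(mod.indices)

    sq = np.sqrt(scale)
    corr = np.full((n, n), spec.background_correlation)
    for mod in spec.modules:
        idx = np.array(mod.indices)
        corr[np.ix_(idx, idx)] = mod.rho
    for link in spec.cross_links:
        if link.index < 0 or link.index >= n \
                or any(t < 0 or t >= n for t in link.targets):
            raise ValueError("cross-link indices out of range")
        for t in link.targets:
            corr[link.index, t] = corr[t, link.index] = link.rho
    np.fill_diagonal(corr, 1.0)
    cov_res = corr * np.outer(sq, sq)

    eigmin = np.linalg.eigvalsh(cov_res).min()
    if eigmin < -1e-10:
        raise ValueError(
            f"assembled covariance is not positive semidefinite "
            f"(min eigenvalue {eigmin:.3e})")
    return np.kron(cov_res, np.eye(3))


@dataclass(frozen=True)
class FlickerSpec:
    """Break a module's contacts in a fraction of frame blocks by expanding
    the module about its centroid."""

    module: tuple
    fraction: float = 0.4
    n_blocks: int = 10
    scale: float = 3.0

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("flicker fraction must be in [0, 1]")
        object.__setattr__(self, "module",
                           tuple(int(i) for i in self.module))


def sample_ensemble(model: StructureModel, covariance: np.ndarray,
                    n_frames: int, seed: int,
                    flicker: FlickerSpec | None = None) -> Ensemble:
    """Sample correlated Gaussian displacements about the reference fold.

    Non-CA atoms of each residue are displaced rigidly with their CA.
    Deterministic for a given seed; the seed is recorded in the ensemble
    metadata.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    n = model.n_residues
    if covariance.shape != (3 * n, 3 * n):
        raise ValueError(
            f"covariance shape {covariance.shape} does not match 3N = {3 * n}")
    rng = np.random.default_rng(seed)
    jitter = 0.0
    for _ in range(6):
        try:
            chol = np.linalg.cholesky(
                covariance + jitter * np.eye(3 * n))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-12)
    else:  # pragma: no cover
        raise ValueError("covariance could not be factorized")

    z = rng.standard_normal((n_frames, 3 * n))
    disp = (z @ chol.T).reshape(n_frames, n, 3)

    frames = np.broadcast_to(model.coords, (n_frames,) + model.coords.shape
                             ).copy()
    res_of_atom = np.full(model.n_atoms, -1, dtype=int)
    for r, g in enumerate(model.residue_groups):
        res_of_atom[model.atoms_of_group(g)] = r
    protein_atoms = res_of_atom >= 0
    frames[:, protein_atoms, :] += disp[:, res_of_atom[protein_atoms], :]

    flicker_blocks: list[int] = []
    if flicker is not None and flicker.fraction > 0:
        n_flicker = int(round(flicker.fraction * flicker.n_blocks))
        flicker_blocks = sorted(rng.choice(
            flicker.n_blocks, size=n_flicker, replace=False).tolist())
        bounds = np.linspace(0, n_frames, flicker.n_blocks + 1).astype(int)
        mod_atoms = protein_atoms & np.isin(res_of_atom,
                                            np.array(flicker.module))
        for blk in flicker_blocks:
            sl = slice(bounds[blk], bounds[blk + 1])
            sub = frames[sl][:, mod_atoms, :]
            centroid = sub.mean(axis=1, keepdims=True)
            frames[sl, mod_atoms] = centroid + flicker.scale * (sub - centroid)

    meta = {"seed": seed, "aligned": True,
            "flicker_blocks": flicker_blocks}
    if flicker is not None:
        meta["flicker"] = {"fraction": flicker.fraction,
                           "n_blocks": flicker.n_blocks,
                           "scale": flicker.scale}
    return Ensemble(frames=frames, model=model, meta=meta)
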