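"""Structure and ensemble containers plus multi-model PDB I/O.

The in-memory model keeps protein residues and ligand groups (non-water
HETATM residues) in a single ordered node table, so that downstream network
stages can treat a bound nucleotide as one extra node.  Hydrogens and
crystallographic waters are discarded on parsing; alternate locations keep
the blank/'A' records only.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "TIP", "TIP3", "SOL", "H2O"})
BACKBONE_NAMES = ("N", "CA", "CB", "C", "O")
SELECTION_NAMES = ("backbone_heavy", "calpha", "heavy", "sidechain_heavy")


class StructureError(ValueError):
    """Raised for malformed structures or inconsistent model blocks."""


@dataclass(frozen=True)
class AtomRecord:
    atom_name: str
    element: str
    residue_index: int
    author_resid: int
    chain_id: str
    coords: np.ndarray
    is_ligand: bool


@dataclass(frozen=True)
class AtomMask:
    """Ordered, unique atom indices for a named selection."""

    indices: np.ndarray
    selection_name: str

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1 or np.any(np.diff(idx) <= 0):
            raise StructureError("mask indices must be sorted and unique")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


class StructureModel:
    """Atoms grouped into ordered residues / ligand groups.

    Parameters are parallel per-atom arrays.  ``group_index`` maps each atom
    to its residue or ligand group; groups are indexed contiguously in order
    of first appearance, protein residues first preserving file order.
    """

    def __init__(self, atom_name, element, res_name, chain_id, author_resid,
                 icode, coords, is_ligand):
        self.atom_name = np.asarray(atom_name, dtype="U6")
        self.element = np.asarray(element, dtype="U2")
        self.res_name = np.asarray(res_name, dtype="U5")
        self.chain_id = np.asarray(chain_id, dtype="U4")
        self.author_resid = np.asarray(author_resid, dtype=int)
        self.icode = np.asarray(icode, dtype="U1")
        self.coords = np.asarray(coords, dtype=float)
        self.is_ligand = np.asarray(is_ligand, dtype=bool)
        n = len(self.atom_name)
        if self.coords.shape != (n, 3):
            raise StructureError("coords must be (n_atoms, 3)")
        if n == 0:
            raise StructureError("structure contains no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        self._build_groups()

    def _build_groups(self):
        keys = list(zip(self.chain_id, self.author_resid, self.icode,
                        self.is_ligand))
        group_of = {}
        group_index = np.empty(len(keys), dtype=int)
        groups = []
        for i, key in enumerate(keys):
            if key not in group_of:
                group_of[key] = len(groups)
                groups.append({
                    "chain_id": key[0], "author_resid": int(key[1]),
                    "icode": key[2], "is_ligand": bool(key[3]),
                    "res_name": self.res_name[i],
                })
            group_index[i] = group_of[key]
        self.group_index = group_index
        self.groups = groups
        self.group_is_ligand = np.array([g["is_ligand"] for g in groups])
        # author numbering must increase strictly within a protein chain
        for chain in dict.fromkeys(g["chain_id"] for g in groups):
            resids = [g["author_resid"] for g in groups
                      if g["chain_id"] == chain and not g["is_ligand"]]
            if any(b <= a for a, b in zip(resids, resids[1:])):
                raise StructureError(
                    f"author residue ids not strictly increasing in chain {chain}")

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_residues(self) -> int:
        """Number of protein residues (ligand groups excluded)."""
        return int(np.sum(~self.group_is_ligand))

    @property
    def residue_groups(self):
        """Indices (into the group table) of protein residues, in order."""
        return np.flatnonzero(~self.group_is_ligand)

    @property
    def ligand_groups(self):
        return np.flatnonzero(self.group_is_ligand)

    def group_key(self, g: int) -> str:
        grp = self.groups[g]
        tag = "LIG:" if grp["is_ligand"] else ""
        return (f"{tag}{grp['chain_id']}:{grp['res_name']}"
                f"{grp['author_resid']}{grp['icode']}")

    def residue_keys(self):
        return [self.group_key(g) for g in self.residue_groups]

    def node_keys(self, include_ligands: bool = False):
        gs = (range(self.n_groups) if include_ligands
              else self.residue_groups)
        return [self.group_key(g) for g in gs]

    def atoms_of_group(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.group_index == g)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            atom_name=str(self.atom_name[i]), element=str(self.element[i]),
            residue_index=int(self.group_index[i]),
            author_resid=int(self.author_resid[i]),
            chain_id=str(self.chain_id[i]), coords=self.coords[i].copy(),
            is_ligand=bool(self.is_ligand[i]))

    # residue-level chain position used for sequence-neighbor exclusions
    def residue_chain_positions(self):
        """Per protein residue: (chain id, 0-based position within chain)."""
        out = []
        counters: dict[str, int] = {}
        for g in self.residue_groups:
            chain = self.groups[g]["chain_id"]
            pos = counters.get(chain, 0)
            counters[chain] = pos + 1
            out.append((chain, pos))
        return out

    def to_biotite(self) -> struc.AtomArray:
        arr = struc.AtomArray(self.n_atoms)
        arr.coord = self.coords.astype(np.float32)
        arr.chain_id = self.chain_id
        arr.res_id = self.author_resid
        arr.ins_code = self.icode
        arr.res_name = self.res_name
        arr.atom_name = self.atom_name
        arr.element = self.element
        arr.hetero = self.is_ligand
        return arr


@dataclass
class Ensemble:
    """Frames x atoms x 3 coordinates tied to a StructureModel."""

    frames: np.ndarray
    model: StructureModel
    frame_weights: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise StructureError("frames must have shape (F, A, 3)")
        if self.frames.shape[0] < 1:
            raise StructureError("ensemble must contain at least one frame")
        if self.frames.shape[1] != self.model.n_atoms:
            raise StructureError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"model atom count {self.model.n_atoms}")
        if not np.all(np.isfinite(self.frames)):
            raise StructureError("non-finite frame coordinates")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# ----------------------------------------------------------------------
# PDB I/O
# ----------------------------------------------------------------------

def _scan_model_blocks(text: str):
    """Per-MODEL lists of (atom name, chain, resid) for consistency checks."""
    blocks = []
    current = None
    seen_model_kw = False
    for line in text.splitlines():
        rec = line[:6]
        if rec.startswith("MODEL"):
            seen_model_kw = True
            current = []
            blocks.append(current)
        elif rec in ("ATOM  ", "HETATM"):
            if current is None:
                current = []
                blocks.append(current)
            current.append((line[12:16].strip(), line[21:22],
                            line[22:27].strip()))
    if not seen_model_kw and len(blocks) > 1:  # pragma: no cover
        blocks = [sum(blocks, [])]
    return blocks


def parse_pdb(text: str):
    """Parse PDB text into a StructureModel and, for multi-model files,
    an Ensemble with one frame per MODEL.

    Keeps blank/'A' altlocs, drops hydrogens and waters.  Raises
    StructureError if MODEL blocks disagree in their atom lists.
    """
    blocks = _scan_model_blocks(text)
    if not blocks or not blocks[0]:
        raise StructureError("no ATOM/HETATM records found")
    for m, block in enumerate(blocks[1:], start=2):
        if block != blocks[0]:
            raise StructureError(
                f"MODEL {m} atom list differs from MODEL 1 "
                f"({len(block)} vs {len(blocks[0])} records or reordered atoms)")

    pdb_file = PDBFile.read(io.StringIO(text))
    n_models = pdb_file.get_model_count()
    atoms = pdb_file.get_structure(model=None, altloc="first")
    first = atoms[0]

    element = np.array([
        e if e else (n.lstrip("0123456789")[:1] or "C")
        for e, n in zip(first.element, first.atom_name)], dtype="U2")
    keep = (element != "H") & (element != "D") \
        & ~np.isin(first.res_name, list(WATER_NAMES))
    if not np.any(keep):
        raise StructureError("no heavy, non-water atoms found")

    model = StructureModel(
        atom_name=first.atom_name[keep], element=element[keep],
        res_name=first.res_name[keep], chain_id=first.chain_id[keep],
        author_resid=first.res_id[keep], icode=first.ins_code[keep],
        coords=first.coord[keep].astype(float),
        is_ligand=first.hetero[keep])

    ensemble = None
    if n_models > 1:
        ensemble = Ensemble(frames=atoms.coord[:, keep, :].astype(float),
                            model=model)
    return model, ensemble


def write_multimodel_pdb(model: StructureModel, ensemble: Ensemble) -> str:
    """Serialize an ensemble as a multi-model PDB string.

    Round-trips through :func:`parse_pdb` within the 0.001 A precision of
    the PDB coordinate fields.
    """
    if ensemble.frames.shape[1] != model.n_atoms:
        raise StructureError("ensemble frame atom count does not match model")
    template = model.to_biotite()
    arrays = []
    for f in range(ensemble.n_frames):
        arr = template.copy()
        arr.coord = ensemble.frames[f].astype(np.float32)
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb_file = PDBFile()
    pdb_file.set_structure(stack)
    buf = io.StringIO()
    pdb_file.write(buf)
    return buf.getvalue()


# ----------------------------------------------------------------------
# Atom selections
# ----------------------------------------------------------------------

def select_atoms(model: StructureModel, selection_name: str) -> AtomMask:
    """Named atom selections over protein residues.

    ``backbone_heavy`` is the extended backbone set N, CA, CB, C, O
    (no CB for glycine); ``calpha`` one CA per residue; ``heavy`` all
    protein heavy atoms; ``sidechain_heavy`` heavy atoms beyond the
    N/CA/C/O backbone.
    """
    if selection_name not in SELECTION_NAMES:
        raise StructureError(
            f"unknown selection {selection_name!r}; valid: {SELECTION_NAMES}")
    indices: list[int] = []
    for g in model.residue_groups:
        atom_idx = model.atoms_of_group(g)
        names = model.atom_name[atom_idx]
        if "CA" not in names:
            raise StructureError(
                f"residue {model.group_key(g)} has no CA atom")
        if selection_name == "calpha":
            indices.extend(atom_idx[names == "CA"][:1])
        elif selection_name == "heavy":
            indices.extend(atom_idx)
        elif selection_name == "backbone_heavy":
            wanted = set(BACKBONE_NAMES)
            if model.groups[g]["res_name"] == "GLY":
                wanted.discard("CB")
            indices.extend(i for i, n in zip(atom_idx, names) if n in wanted)
        else:  # sidechain_heavy
            indices.extend(i for i, n in zip(atom_idx, names)
                           if n not in ("N", "CA", "C", "O"))
    return AtomMask(indices=np.array(sorted(indices), dtype=int),
                    selection_name=selection_name)
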