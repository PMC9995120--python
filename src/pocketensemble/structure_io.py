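"""Structure / trajectory I/O, atom selection and contact-residue detection.

Coordinates are Angstrom everywhere inside the package; nm-based trajectory
formats (XTC) are converted at the boundary.  A residue is identified by the
pair ``(chain_id, res_id)`` throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from pocketensemble.constants import NON_PROTEIN_RESNAMES

ResidueID = tuple[str, int]

__all__ = [
    "Structure",
    "Trajectory",
    "AtomSelection",
    "LigandCoords",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "extract_ligand",
    "select_contact_residues",
]


def _infer_element(atom_name: str) -> str:
    """Guess the element from a PDB atom name (legacy files lack the column).

    Digits and primes are stripped; a leading digit (e.g. ``1HB``) means the
    element is the following letter.  Two-letter candidates are only accepted
    for common hetero elements to avoid mistaking ``CA`` (alpha carbon) for
    calcium.
    """
    name = atom_name.strip()
    if not name:
        return ""
    while name and not name[0].isalpha():
        name = name[1:]
    if not name:
        return ""
    two = name[:2].upper()
    if two in {"CL", "BR", "FE", "ZN", "MG", "MN", "NA", "SE"} and len(atom_name.strip()) > 1:
        # only trust two-letter symbols when the name is not a standard
        # protein atom name (those start with C/N/O/S/H/P + remoteness code)
        if two not in {"CA", "CB", "CD", "CE", "CG", "CZ", "ND", "NE", "NH", "NZ",
                       "OD", "OE", "OG", "OH", "SD", "SG", "HA", "HB", "HD"}:
            return two.capitalize()
    return name[0].upper()


@dataclass
class Structure:
    """A single-model structure: per-atom annotation plus an N x 3 coordinate array."""

    atom_name: np.ndarray  # str
    element: np.ndarray  # str
    res_id: np.ndarray  # int
    res_name: np.ndarray  # str
    chain_id: np.ndarray  # str
    coords: np.ndarray  # (N, 3) float, Angstrom

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        n = self.coords.shape[0]
        if n < 1:
            raise ValueError("a Structure needs at least one atom")
        for name in ("atom_name", "element", "res_id", "res_name", "chain_id"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            setattr(self, name, arr)
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    # -- masks ---------------------------------------------------------
    def heavy_mask(self) -> np.ndarray:
        return np.asarray([e.upper() != "H" for e in self.element], dtype=bool)

    def protein_mask(self, blacklist: frozenset[str] = NON_PROTEIN_RESNAMES) -> np.ndarray:
        return np.asarray([rn.upper() not in blacklist for rn in self.res_name], dtype=bool)

    def residue_ids(self) -> list[ResidueID]:
        """Unique ``(chain, res_id)`` pairs in order of first appearance."""
        seen: dict[ResidueID, None] = {}
        for ch, ri in zip(self.chain_id, self.res_id):
            seen.setdefault((str(ch), int(ri)), None)
        return list(seen)

    def residue_atom_indices(self, residue: ResidueID) -> np.ndarray:
        ch, ri = residue
        mask = (self.chain_id == ch) & (self.res_id == int(ri))
        return np.flatnonzero(mask)

    def subset(self, indices: np.ndarray | "AtomSelection") -> "Structure":
        idx = indices.indices if isinstance(indices, AtomSelection) else np.asarray(indices)
        return Structure(
            atom_name=self.atom_name[idx],
            element=self.element[idx],
            res_id=self.res_id[idx],
            res_name=self.res_name[idx],
            chain_id=self.chain_id[idx],
            coords=self.coords[idx],
        )

    # -- selection expressions -----------------------------------------
    def select(self, expression: str) -> "AtomSelection":
        """Select atoms with a simple expression.

        Clauses joined by ``and``; each clause is one of
        ``chain <id> [<id> ...]``, ``resid <a>[-<b>] [...]``,
        ``name <n> [...]``, ``resname <rn> [...]``, ``protein``, ``heavy``,
        ``backbone`` (N, CA, C, O).
        """
        mask = np.ones(self.n_atoms, dtype=bool)
        for clause in expression.split(" and "):
            tokens = clause.split()
            if not tokens:
                continue
            key, args = tokens[0].lower(), tokens[1:]
            if key == "chain":
                mask &= np.isin(self.chain_id, args)
            elif key == "resid":
                sel = np.zeros(self.n_atoms, dtype=bool)
                for a in args:
                    if "-" in a[1:]:  # range like 5-20 (leading '-' = negative id)
                        lo, hi = a[1:].split("-", 1)
                        lo = a[0] + lo
                        sel |= (self.res_id >= int(lo)) & (self.res_id <= int(hi))
                    else:
                        sel |= self.res_id == int(a)
                mask &= sel
            elif key == "name":
                mask &= np.isin(self.atom_name, args)
            elif key == "resname":
                mask &= np.isin(self.res_name, args)
            elif key == "protein":
                mask &= self.protein_mask()
            elif key == "heavy":
                mask &= self.heavy_mask()
            elif key == "backbone":
                mask &= np.isin(self.atom_name, ["N", "CA", "C", "O"]) & self.protein_mask()
            else:
                raise ValueError(f"unknown selection clause: {clause!r}")
        return AtomSelection(np.flatnonzero(mask))

    # -- interop -------------------------------------------------------
    def to_mdtraj_topology(self):
        """Build an :mod:`mdtraj` Topology mirroring this structure."""
        import mdtraj as md
        from mdtraj.core import element as md_element

        top = md.Topology()
        chain = None
        residue = None
        last_chain = None
        last_res = None
        for i in range(self.n_atoms):
            ch = str(self.chain_id[i])
            res_key = (ch, int(self.res_id[i]), str(self.res_name[i]))
            if ch != last_chain:
                chain = top.add_chain()
                last_chain = ch
                last_res = None
            if res_key != last_res:
                residue = top.add_residue(
                    str(self.res_name[i]), chain, resSeq=int(self.res_id[i])
                )
                last_res = res_key
            try:
                elem = md_element.get_by_symbol(str(self.element[i]).capitalize())
            except KeyError:
                elem = md_element.carbon
            top.add_atom(str(self.atom_name[i]), elem, residue)
        top.create_standard_bonds()
        return top


@dataclass
class AtomSelection:
    """Strictly increasing, unique 0-based atom indices."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("indices must be 1-D")
        if idx.size and (np.any(np.diff(idx) <= 0) or idx[0] < 0):
            raise ValueError("indices must be unique, strictly increasing, non-negative")
        self.indices = idx

    def __len__(self) -> int:
        return self.indices.size

    def validate(self, n_atoms: int) -> None:
        if self.indices.size and self.indices[-1] >= n_atoms:
            raise IndexError("selection indices out of bounds")


@dataclass
class LigandCoords:
    """Ligand atom coordinates (M x 3, Angstrom) and element symbols."""

    coords: np.ndarray
    elements: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.elements = np.asarray(self.elements)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 or self.coords.shape[0] < 1:
            raise ValueError("ligand coords must be (M, 3) with M >= 1")
        if self.elements.shape != (self.coords.shape[0],):
            raise ValueError("elements must match coords")

    def heavy(self) -> "LigandCoords":
        mask = np.asarray([e.upper() != "H" for e in self.elements], dtype=bool)
        if not mask.any():
            raise ValueError("ligand has no heavy atoms")
        return LigandCoords(self.coords[mask], self.elements[mask])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LigandCoords":
        return LigandCoords(self.coords @ rotation.T + translation, self.elements.copy())

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass
class Trajectory:
    """Frames (F x N x 3, Angstrom) over a fixed topology."""

    topology: Structure
    frames: np.ndarray
    frame_interval_ps: float = 1.0
    traj_id: str = "traj0"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (F, N, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology ({self.topology.n_atoms})"
            )
        if self.frame_interval_ps <= 0:
            raise ValueError("frame_interval_ps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ps

    def frame_structure(self, i: int) -> Structure:
        s = self.topology
        return Structure(s.atom_name, s.element, s.res_id, s.res_name, s.chain_id,
                         self.frames[i].copy())

    def to_mdtraj(self):
        import mdtraj as md

        top = self.topology.to_mdtraj_topology()
        return md.Trajectory(self.frames / 10.0, top,
                             time=self.times_ps)


# ----------------------------------------------------------------------
# Readers / writers
# ----------------------------------------------------------------------

def _structure_from_atom_array(arr) -> Structure:
    elements = np.asarray(
        [e if e else _infer_element(n) for e, n in zip(arr.element, arr.atom_name)]
    )
    return Structure(
        atom_name=np.asarray(arr.atom_name),
        element=elements,
        res_id=np.asarray(arr.res_id, dtype=int),
        res_name=np.asarray(arr.res_name),
        chain_id=np.asarray(arr.chain_id),
        coords=np.asarray(arr.coord, dtype=float),
    )


def read_structure(path: str | Path, model: int = 0) -> Structure:
    """Read one model of a PDB file.

    ``model`` is 0-based.  Hydrogens are kept if present; for alternate
    locations the highest-occupancy conformer is retained; blank element
    columns are inferred from atom names.
    """
    import biotite.structure.io.pdb as pdbio

    pdb = pdbio.PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if not 0 <= model < n_models:
        raise IndexError(f"model {model} out of range (file has {n_models} models)")
    arr = pdb.get_structure(model=model + 1, altloc="occupancy")
    if arr.array_length() == 0:
        raise ValueError(f"no atoms in {path}")
    return _structure_from_atom_array(arr)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as a single-model PDB file."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    arr = struc.AtomArray(structure.n_atoms)
    arr.coord = structure.coords
    arr.atom_name = structure.atom_name.astype(str)
    arr.element = structure.element.astype(str)
    arr.res_id = structure.res_id
    arr.res_name = structure.res_name.astype(str)
    arr.chain_id = structure.chain_id.astype(str)
    arr.hetero = ~structure.protein_mask()
    pdb = pdbio.PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def read_trajectory(
    path: str | Path,
    topology: Structure,
    stride: int = 1,
    frame_interval_ps: float | None = None,
    traj_id: str | None = None,
) -> Trajectory:
    """Read an XTC/DCD (or multi-model PDB) trajectory against a topology.

    Frames are strided by ``stride``; the frame interval is read from the
    file's time stamps when available (XTC), scaled by the stride, and falls
    back to ``frame_interval_ps`` (default 1 ps) otherwise.
    """
    path = Path(path)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    suffix = path.suffix.lower()
    if suffix == ".pdb":
        import biotite.structure.io.pdb as pdbio

        pdb = pdbio.PDBFile.read(str(path))
        stack = pdb.get_structure(altloc="occupancy")
        coords = np.atleast_3d(np.asarray(stack.coord, dtype=float))
        if coords.ndim == 2:
            coords = coords[None]
        frames = coords[::stride]
        interval = (frame_interval_ps or 1.0) * stride
    elif suffix in {".xtc", ".dcd"}:
        import mdtraj as md

        top = topology.to_mdtraj_topology()
        try:
            t = md.load(str(path), top=top, stride=stride)
        except ValueError as exc:
            raise ValueError(f"could not read {path} with this topology: {exc}") from exc
        frames = np.asarray(t.xyz, dtype=float) * 10.0
        if t.time is not None and len(t.time) > 1 and np.ptp(t.time) > 0:
            interval = float(np.diff(t.time).mean())
        else:
            interval = (frame_interval_ps or 1.0) * stride
    else:
        raise ValueError(f"unsupported trajectory format: {suffix!r}")
    if frames.shape[1] != topology.n_atoms:
        raise ValueError(
            f"trajectory has {frames.shape[1]} atoms, topology has {topology.n_atoms}"
        )
    return Trajectory(topology, frames, interval, traj_id or path.stem)


def extract_ligand(structure: Structure, resname: str) -> LigandCoords:
    """Pull the coordinates of a named residue (e.g. the bound ligand) out of a structure."""
    mask = structure.res_name == resname
    if not mask.any():
        raise ValueError(f"no residue named {resname!r} in structure")
    return LigandCoords(structure.coords[mask], structure.element[mask])


def select_contact_residues(
    structure: Structure,
    ligand: LigandCoords,
    cutoff: float = 5.0,
    include_hydrogens: bool = False,
    blacklist: frozenset[str] = NON_PROTEIN_RESNAMES,
) -> list[ResidueID]:
    """Residues with at least one (heavy) atom within ``cutoff`` A of the ligand.

    Distances use heavy atoms on both sides by default, matching crystal
    structures where hydrogens are usually absent.  Result sorted by
    (chain, residue index).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    mask = structure.protein_mask(blacklist)
    if not include_hydrogens:
        mask &= structure.heavy_mask()
    if not mask.any():
        raise ValueError("structure has no protein atoms to test")
    lig = ligand if include_hydrogens else ligand.heavy()
    idx = np.flatnonzero(mask)
    tree = cKDTree(lig.coords)
    dmin, _ = tree.query(structure.coords[idx], k=1)
    hit = idx[dmin <= cutoff]
    residues = {
        (str(structure.chain_id[i]), int(structure.res_id[i])) for i in hit
    }
    return sorted(residues)
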