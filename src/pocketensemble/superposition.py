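"""Rigid-body superposition: Kabsch, iterative ensemble alignment, ligand transfer.

The ligand-transfer routine implements the local site alignment used to put a
reference (holo) ligand into every frame of an apo ensemble: superpose the
holo structure onto the target using backbone heavy atoms of the mapped
binding-site residues, then carry the ligand along with that transform.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from pocketensemble.structure_io import (
    AtomSelection,
    LigandCoords,
    ResidueID,
    Structure,
    Trajectory,
)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

__all__ = [
    "AlignmentResult",
    "ResidueMapping",
    "kabsch_superpose",
    "apply_transform",
    "iterative_ensemble_align",
    "place_reference_ligand",
    "rmsd",
    "read_mapping",
]


@dataclass
class AlignmentResult:
    """Rotation (proper, det=+1), translation (A) and post-fit RMSD (A)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    iterations: int = 1


@dataclass
class ResidueMapping:
    """Ordered one-to-one pairing of reference and target residue identifiers."""

    pairs: list[tuple[ResidueID, ResidueID]]

    def __post_init__(self) -> None:
        refs = [p[0] for p in self.pairs]
        tgts = [p[1] for p in self.pairs]
        if len(set(refs)) != len(refs) or len(set(tgts)) != len(tgts):
            raise ValueError("residue mapping must be one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    def target_of(self, ref: ResidueID) -> ResidueID | None:
        for r, t in self.pairs:
            if r == ref:
                return t
        return None

    @classmethod
    def identity(cls, residues: list[ResidueID]) -> "ResidueMapping":
        return cls([(r, r) for r in residues])


def read_mapping(path: str | Path) -> ResidueMapping:
    """Read a two-column ``ref_resid,target_resid`` CSV.

    Residue ids may be plain integers (chain defaults to the file's
    ``chain`` columns if present, else ``A``) or ``chain:resid`` strings.
    """

    def parse(token: str) -> ResidueID:
        token = token.strip()
        if ":" in token:
            ch, ri = token.split(":", 1)
            return (ch, int(ri))
        return ("A", int(token))

    pairs: list[tuple[ResidueID, ResidueID]] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#") or row[0].strip() == "ref_resid":
                continue
            pairs.append((parse(row[0]), parse(row[1])))
    if not pairs:
        raise ValueError(f"no mapping rows in {path}")
    return ResidueMapping(pairs)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> AlignmentResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation R and translation t minimizing
    ``|| (mobile @ R.T + t) - reference ||``; reflections are excluded by
    sign-correcting the smallest singular vector.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, s, vt = np.linalg.svd(h)
    # collinear/coincident sets leave the rotation under-determined
    if s[1] <= 1e-10 * max(s[0], 1e-30):
        raise ValueError("degenerate (collinear or coincident) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    fitted = mobile @ rot.T + trans
    return AlignmentResult(rotation=rot, translation=trans, rmsd=rmsd(fitted, reference))


def apply_transform(coords: np.ndarray, result: AlignmentResult) -> np.ndarray:
    return np.asarray(coords, float) @ result.rotation.T + result.translation


def iterative_ensemble_align(
    traj: Trajectory,
    selection: AtomSelection,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[Trajectory, np.ndarray]:
    """Iteratively align every frame to the evolving mean structure.

    Repeats {superpose each frame onto the current mean over the selected
    atoms; recompute the mean} until the selection mean moves less than
    ``tol`` (A, RMS) or ``max_iter`` is reached.  The reference mean is kept
    centered on the selection centroid, so the aligned coordinate system is
    canonical in translation: the converged selection centroid sits at the
    origin regardless of where the input ensemble was.  Returns the aligned
    trajectory and the final mean coordinates (full atom set).
    """
    selection.validate(traj.topology.n_atoms)
    if len(selection) < 3:
        raise ValueError("alignment selection needs at least 3 atoms")
    frames = traj.frames.copy()
    sel = selection.indices
    mean_sel = frames[:, sel].mean(axis=0)
    mean_sel = mean_sel - mean_sel.mean(axis=0)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for f in range(frames.shape[0]):
            res = kabsch_superpose(frames[f, sel], mean_sel)
            frames[f] = apply_transform(frames[f], res)
        new_mean = frames[:, sel].mean(axis=0)
        new_mean = new_mean - new_mean.mean(axis=0)
        shift = rmsd(new_mean, mean_sel)
        mean_sel = new_mean
        if shift < tol:
            break
    else:
        raise RuntimeError(
            f"ensemble alignment did not converge in {max_iter} iterations "
            f"(final mean shift {shift:.3g} A)"
        )
    aligned = Trajectory(traj.topology, frames, traj.frame_interval_ps, traj.traj_id)
    return aligned, frames.mean(axis=0)


def _site_backbone_pairs(
    holo: Structure,
    target: Structure,
    site_residues: list[ResidueID],
    mapping: ResidueMapping,
    atoms: tuple[str, ...] = BACKBONE_ATOMS,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Paired backbone-heavy-atom coordinates for mapped site residues."""
    holo_pts, tgt_pts = [], []
    n_residues = 0
    for ref_res in site_residues:
        tgt_res = mapping.target_of(ref_res)
        if tgt_res is None:
            continue
        h_idx = holo.residue_atom_indices(ref_res)
        t_idx = target.residue_atom_indices(tgt_res)
        if h_idx.size == 0 or t_idx.size == 0:
            continue
        h_names = {holo.atom_name[i]: i for i in h_idx}
        t_names = {target.atom_name[i]: i for i in t_idx}
        contributed = False
        for an in atoms:
            if an in h_names and an in t_names:
                holo_pts.append(holo.coords[h_names[an]])
                tgt_pts.append(target.coords[t_names[an]])
                contributed = True
        n_residues += contributed
    return np.asarray(holo_pts, float), np.asarray(tgt_pts, float), n_residues


def place_reference_ligand(
    holo: Structure,
    holo_ligand: LigandCoords,
    target: Structure,
    mapping: ResidueMapping,
    site_cutoff: float = 5.0,
) -> LigandCoords:
    """Transfer the holo ligand into the target frame via local site alignment.

    The holo structure is superposed onto the target using backbone heavy
    atoms (N, CA, C, O) of mapped residues within ``site_cutoff`` A of the
    ligand, and the resulting rigid transform is applied to the ligand.
    """
    from pocketensemble.structure_io import select_contact_residues

    site = select_contact_residues(holo, holo_ligand, cutoff=site_cutoff)
    holo_pts, tgt_pts, n_residues = _site_backbone_pairs(holo, target, site, mapping)
    if n_residues < 3 or holo_pts.shape[0] < 3:
        raise ValueError(
            f"only {n_residues} mappable site residues ({holo_pts.shape[0]} atoms); "
            "need at least 3 (is the residue mapping covering the binding site?)"
        )
    res = kabsch_superpose(holo_pts, tgt_pts)
    return holo_ligand.transformed(res.rotation, res.translation)
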