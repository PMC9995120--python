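"""Shared fixtures: tiny hand-built structures and peptides, all generated in-test."""

from __future__ import annotations

import numpy as np
import pytest

from pocketensemble.structure_io import LigandCoords, Structure


def make_structure(rows: list[tuple[str, str, int, str, str, float, float, float]]
                   ) -> Structure:
    """Build a Structure from (atom_name, element, res_id, res_name, chain, x, y, z) rows."""
    return Structure(
        atom_name=np.array([r[0] for r in rows]),
        element=np.array([r[1] for r in rows]),
        res_id=np.array([r[2] for r in rows]),
        res_name=np.array([r[3] for r in rows]),
        chain_id=np.array([r[4] for r in rows]),
        coords=np.array([[r[5], r[6], r[7]] for r in rows], dtype=float),
    )


@pytest.fixture
def tripeptide() -> Structure:
    """ALA-SER-GLY with plausible extended-chain geometry.

    Hand enumeration of rotatable dihedral quadruplets: phi for residues 2-3,
    psi for residues 1-2, chi1 only for SER (N-CA-CB-OG); ALA and GLY have no
    chi angles.  Total 5 dihedrals.
    """
    rows = [
        ("N", "N", 1, "ALA", "A", 0.00, 0.00, 0.00),
        ("CA", "C", 1, "ALA", "A", 1.46, 0.00, 0.00),
        ("CB", "C", 1, "ALA", "A", 2.00, -1.00, 1.00),
        ("C", "C", 1, "ALA", "A", 2.00, 1.40, 0.00),
        ("O", "O", 1, "ALA", "A", 1.30, 2.40, 0.10),
        ("N", "N", 2, "SER", "A", 3.30, 1.50, 0.00),
        ("CA", "C", 2, "SER", "A", 4.00, 2.80, 0.00),
        ("CB", "C", 2, "SER", "A", 4.50, 3.20, 1.40),
        ("OG", "O", 2, "SER", "A", 5.20, 4.40, 1.40),
        ("C", "C", 2, "SER", "A", 5.20, 2.70, -0.90),
        ("O", "O", 2, "SER", "A", 6.20, 2.00, -0.60),
        ("N", "N", 3, "GLY", "A", 5.20, 3.40, -2.00),
        ("CA", "C", 3, "GLY", "A", 6.30, 3.40, -2.90),
        ("C", "C", 3, "GLY", "A", 7.60, 3.90, -2.30),
        ("O", "O", 3, "GLY", "A", 8.60, 3.90, -3.00),
    ]
    return make_structure(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


def point_ligand(xyz=(0.0, 0.0, 0.0)) -> LigandCoords:
    return LigandCoords(np.array([xyz], dtype=float), np.array(["C"]))
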