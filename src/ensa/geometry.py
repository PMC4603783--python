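"""Backbone geometry primitives.

Dihedral angles follow the IUPAC sign convention and are reported in
degrees in ``(-180, 180]``.  The main-chain centre of mass of a residue is
the mass-weighted mean of its N, CA, C and O atoms (backbone heavy atoms).
Optimal superposition uses the Kabsch algorithm restricted to proper
rotations.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Ensemble, Frame, Topology

__all__ = [
    "dihedral",
    "phi_series",
    "psi_series",
    "mainchain_com",
    "mainchain_com_all",
    "kabsch_rmsd",
    "MAINCHAIN_ATOMS",
]

MAINCHAIN_ATOMS = ("N", "CA", "C", "O")


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees) defined by four points.

    The angle is measured between the half-planes (p1,p2,p3) and
    (p2,p3,p4) looking along the p2→p3 axis; clockwise rotations are
    positive (IUPAC convention).  Degenerate geometries (collinear
    central bond with either flanking bond) raise ``ValueError``.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-12 or np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("degenerate dihedral: collinear or coincident points")
    x = n1 @ n2
    y = np.cross(n1, n2) @ b2 / b2n
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def phi_series(frame: Frame, topology: Topology) -> np.ndarray:
    """Backbone φ angle per residue, ``nan`` for residue 1.

    φ of residue *i* is the dihedral C(i−1)–N(i)–CA(i)–C(i).  Returned as
    an array of length ``n_residues`` indexed by ``residue − 1``.
    """
    n = topology.n_residues
    out = np.full(n, np.nan)
    X = frame.coords
    for i in range(2, n + 1):
        try:
            pts = [X[topology.atom_index(i - 1, "C")],
                   X[topology.atom_index(i, "N")],
                   X[topology.atom_index(i, "CA")],
                   X[topology.atom_index(i, "C")]]
        except KeyError as exc:
            raise ValueError(f"phi of residue {i}: {exc}") from exc
        out[i - 1] = dihedral(*pts)
    return out


def psi_series(frame: Frame, topology: Topology) -> np.ndarray:
    """Backbone ψ angle per residue, ``nan`` for the last residue.

    ψ of residue *i* is the dihedral N(i)–CA(i)–C(i)–N(i+1).
    """
    n = topology.n_residues
    out = np.full(n, np.nan)
    X = frame.coords
    for i in range(1, n):
        pts = [X[topology.atom_index(i, "N")],
               X[topology.atom_index(i, "CA")],
               X[topology.atom_index(i, "C")],
               X[topology.atom_index(i + 1, "N")]]
        out[i - 1] = dihedral(*pts)
    return out


def mainchain_com(frame: Frame, topology: Topology, residue: int) -> np.ndarray:
    """Mass-weighted centre of mass of a residue's N, CA, C, O atoms (Å)."""
    idx = []
    for name in MAINCHAIN_ATOMS:
        try:
            idx.append(topology.atom_index(residue, name))
        except KeyError as exc:
            raise ValueError(f"main-chain COM of residue {residue}: {exc}")
    w = topology.masses[idx]
    return (w[:, None] * frame.coords[idx]).sum(axis=0) / w.sum()


def mainchain_com_all(frame: Frame, topology: Topology) -> np.ndarray:
    """Main-chain COM for every residue as an ``(n_residues, 3)`` array."""
    n = topology.n_residues
    idx = np.array([[topology.atom_index(r, nm) for nm in MAINCHAIN_ATOMS]
                    for r in range(1, n + 1)])
    w = topology.masses[idx]                       # (n, 4)
    pts = frame.coords[idx]                        # (n, 4, 3)
    return (w[..., None] * pts).sum(axis=1) / w.sum(axis=1, keepdims=True)


def kabsch_rmsd(X, Y) -> float:
    """Cα RMSD (Å) after optimal proper-rotation superposition.

    Both point sets are centred, then Y is rotated onto X with the
    rotation of determinant +1 that minimises the residual sum of
    squares (Kabsch algorithm, via quaternion alignment).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"point count mismatch: {X.shape} vs {Y.shape}")
    if X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    _, rssd = Rotation.align_vectors(Xc, Yc)
    return float(rssd / np.sqrt(X.shape[0]))
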