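"""Shrake–Rupley solvent-accessible surface area.

Each heavy atom is dressed with a deterministic quasi-uniform lattice of
test points on its probe-expanded sphere (golden-section spiral); a test
point is buried iff it lies strictly inside another atom's expanded
sphere.  The per-atom area is the exposed-point fraction times the full
expanded-sphere area.  Hydrogens carry no radius and are ignored, both as
surfaces and as occluders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from .core import Frame, Topology

try:  # optional JIT acceleration of the burial test
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a soft dependency
    _njit = None

__all__ = ["SasaParams", "sphere_lattice", "shrake_rupley",
           "hydrophobic_sasa", "residue_sasa"]

#: Relative margin of the strict-inequality burial test, so a test point
#: lying exactly on a neighbour's expanded sphere (coincident spheres)
#: stays exposed despite floating-point rounding.
_TIE_EPS = 1e-10


@dataclass(frozen=True)
class SasaParams:
    """Parameters of the surface calculation.

    probe_radius
        Solvent probe radius in Å (water: 1.4).
    n_points
        Test points per atom; the quadrature error shrinks roughly as
        1/n_points.
    radii
        Optional per-element radius override (Å); ``None`` keeps the
        radii stored on the topology.
    """

    probe_radius: float = 1.4
    n_points: int = 960
    radii: dict | None = None

    def __post_init__(self):
        if self.probe_radius < 0:
            raise ValueError("probe radius must be >= 0")
        if self.n_points < 16:
            raise ValueError("need at least 16 points per atom")


@lru_cache(maxsize=8)
def sphere_lattice(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden spiral)."""
    k = np.arange(n) + 0.5
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _atom_radii(topology: Topology, params: SasaParams) -> np.ndarray:
    if params.radii is None:
        return topology.radii
    radii = np.full(topology.n_atoms, np.nan)
    for i, el in enumerate(topology.elements):
        if el == "H":
            continue
        try:
            radii[i] = params.radii[el]
        except KeyError:
            raise ValueError(f"no radius for element {el!r} "
                             f"(atom {topology.atom_names[i]!r})") from None
    return radii


def _exposed_counts_numpy(X: np.ndarray, R: np.ndarray,
                          unit: np.ndarray) -> np.ndarray:
    """Exposed test points per atom (reference numpy implementation)."""
    n = X.shape[0]
    out = np.empty(n, dtype=np.int64)
    tree = cKDTree(X)
    neighbor_lists = tree.query_ball_point(X, R + R.max())
    for a in range(n):
        nbrs = np.asarray([b for b in neighbor_lists[a] if b != a], dtype=int)
        if nbrs.size:
            d = np.linalg.norm(X[nbrs] - X[a], axis=1)
            close = nbrs[d < R[a] + R[nbrs]]
        else:
            close = nbrs
        if close.size == 0:
            out[a] = unit.shape[0]
            continue
        pts = X[a] + R[a] * unit
        Xc = X[close]
        d2 = ((pts * pts).sum(axis=1)[:, None]
              + (Xc * Xc).sum(axis=1)[None, :]
              - 2.0 * pts @ Xc.T)
        lim = (R[close] ** 2) * (1.0 - _TIE_EPS)
        buried = (d2 < lim[None, :]).any(axis=1)
        out[a] = np.count_nonzero(~buried)
    return out


def _exposed_counts_loops(X, R, unit):  # compiled by numba when available
    n = X.shape[0]
    m = unit.shape[0]
    out = np.zeros(n, dtype=np.int64)
    for a in range(n):
        # neighbours whose expanded sphere can reach atom a's surface
        close = np.empty(n, dtype=np.int64)
        n_close = 0
        for b in range(n):
            if b == a:
                continue
            dx = X[b, 0] - X[a, 0]
            dy = X[b, 1] - X[a, 1]
            dz = X[b, 2] - X[a, 2]
            lim = R[a] + R[b]
            if dx * dx + dy * dy + dz * dz < lim * lim:
                close[n_close] = b
                n_close += 1
        exposed = 0
        for p in range(m):
            px = X[a, 0] + R[a] * unit[p, 0]
            py = X[a, 1] + R[a] * unit[p, 1]
            pz = X[a, 2] + R[a] * unit[p, 2]
            buried = False
            for ci in range(n_close):
                b = close[ci]
                dx = px - X[b, 0]
                dy = py - X[b, 1]
                dz = pz - X[b, 2]
                if dx * dx + dy * dy + dz * dz < R[b] * R[b] * (1.0 - _TIE_EPS):
                    buried = True
                    break
            if not buried:
                exposed += 1
        out[a] = exposed
    return out


if _njit is not None:
    _exposed_counts_jit = _njit(cache=False)(_exposed_counts_loops)
else:  # pragma: no cover
    _exposed_counts_jit = None


def _exposed_counts(X: np.ndarray, R: np.ndarray,
                    unit: np.ndarray) -> np.ndarray:
    if _exposed_counts_jit is not None:
        return _exposed_counts_jit(X, R, unit)
    return _exposed_counts_numpy(X, R, unit)


def shrake_rupley(frame: Frame, topology: Topology,
                  params: SasaParams = SasaParams()) -> np.ndarray:
    """Per-atom SASA in Å²; hydrogens get 0.

    A test point on atom *i*'s expanded sphere (radius ``r_i + probe``)
    counts as buried iff its distance to some other heavy atom *j* is
    strictly below ``r_j + probe``; points exactly on a neighbouring
    expanded sphere therefore remain exposed (tie-break by design, so
    coincident expanded spheres do not mutually bury their surfaces).
    """
    radii = _atom_radii(topology, params)
    heavy = np.nonzero(np.isfinite(radii))[0]
    if np.any(~np.isfinite(radii[topology.elements != "H"])):
        bad = np.nonzero(~np.isfinite(radii)
                         & (topology.elements != "H"))[0][0]
        raise ValueError(f"atom {topology.atom_names[bad]!r}: unknown radius")
    X = frame.coords[heavy]
    R = radii[heavy] + params.probe_radius
    n_heavy = len(heavy)
    out = np.zeros(topology.n_atoms)
    if n_heavy == 0:
        return out
    unit = sphere_lattice(params.n_points)
    area_factor = 4.0 * np.pi * R * R / params.n_points
    out[heavy] = area_factor * _exposed_counts(np.ascontiguousarray(X),
                                               np.ascontiguousarray(R), unit)
    return out


def residue_sasa(frame: Frame, topology: Topology,
                 params: SasaParams = SasaParams()) -> np.ndarray:
    """Per-residue SASA (Å²): per-atom areas summed within each residue."""
    per_atom = shrake_rupley(frame, topology, params)
    return np.bincount(topology.residue_of_atom, weights=per_atom,
                       minlength=topology.n_residues + 1)[1:]


def hydrophobic_sasa(frame: Frame, topology: Topology,
                     params: SasaParams = SasaParams()) -> float:
    """Summed SASA (Å²) of all atoms of the topology's hydrophobic residues.

    This is the collapse coordinate: low exposure of the hydrophobic set
    marks a collapsed conformation, high exposure an extended one.
    """
    if not topology.hydrophobic_set:
        raise ValueError("topology has an empty hydrophobic_set")
    per_atom = shrake_rupley(frame, topology, params)
    idx = topology.atom_indices_of_residues(topology.hydrophobic_set)
    return float(per_atom[idx].sum())
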