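"""Simplified Kabsch–Sander secondary-structure assignment.

Backbone hydrogen bonds are scored with the Kabsch–Sander electrostatic
model

    E = 27.888 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

between the N–H of a donor residue and the C=O of an acceptor residue,
with the amide hydrogen placed geometrically (1.01 Å from N, opposite the
bisector of the C(i−1)–N and CA–N bonds).  A hydrogen bond exists when
E < −0.5 kcal/mol.  Labels are collapsed to a 3-letter alphabet:

* ``H`` — α-helix: two consecutive i→i+4 turns;
* ``E`` — β-strand: residues in parallel or antiparallel bridges;
* ``C`` — everything else (coil, bend, turn).

This deliberately drops π/3₁₀ helices and β-bulges; the aim is robust
helix/strand/coil occupancy, not 8-class DSSP fidelity.  Labels can also
be imported from an external DSSP run instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import Ensemble, Frame, Topology

__all__ = ["KS_COUPLING", "HBOND_CUTOFF", "amide_hydrogen",
           "ks_hbond_energy", "hbond_matrix", "assign_ss",
           "occupancy_by_residue", "ss_content", "collapse_dssp_codes",
           "read_dssp_labels"]

#: Kabsch–Sander coupling constant (kcal/mol·Å): 332 * 0.42 * 0.20.
KS_COUPLING = 27.888

#: Hydrogen-bond acceptance threshold, kcal/mol.
HBOND_CUTOFF = -0.5

_NH_BOND = 1.01  # Å


def amide_hydrogen(frame: Frame, topology: Topology, residue: int) -> np.ndarray:
    """Geometric position of the backbone amide hydrogen of ``residue``.

    Placed 1.01 Å from N opposite the bisector of the C(i−1)→N and CA→N
    bond directions.  For residue 1 (no preceding carbonyl) the own-residue
    C is used in place of C(i−1) — a documented fallback that keeps H in
    the N sp² plane pointing away from the chain.
    """
    X = frame.coords
    n = X[topology.atom_index(residue, "N")]
    ca = X[topology.atom_index(residue, "CA")]
    if residue > 1:
        c_ref = X[topology.atom_index(residue - 1, "C")]
    else:
        c_ref = X[topology.atom_index(residue, "C")]
    v1 = c_ref - n
    v2 = ca - n
    v1 /= np.linalg.norm(v1)
    v2 /= np.linalg.norm(v2)
    bis = v1 + v2
    norm = np.linalg.norm(bis)
    if norm < 1e-9:
        raise ValueError(f"residue {residue}: degenerate N geometry")
    return n - _NH_BOND * bis / norm


def ks_hbond_energy(donor: int, acceptor: int, frame: Frame,
                    topology: Topology) -> float:
    """Kabsch–Sander H-bond energy (kcal/mol), donor N–H → acceptor C=O.

    Requires sequence separation |donor − acceptor| ≥ 2; bonded or
    adjacent residues are not scored.
    """
    if abs(donor - acceptor) < 2:
        raise ValueError("donor and acceptor must be >= 2 residues apart")
    X = frame.coords
    N = X[topology.atom_index(donor, "N")]
    H = amide_hydrogen(frame, topology, donor)
    C = X[topology.atom_index(acceptor, "C")]
    O = X[topology.atom_index(acceptor, "O")]
    r_on = np.linalg.norm(O - N)
    r_ch = np.linalg.norm(C - H)
    r_oh = np.linalg.norm(O - H)
    r_cn = np.linalg.norm(C - N)
    if min(r_on, r_ch, r_oh, r_cn) < 1e-6:
        raise ValueError("coincident donor/acceptor atoms")
    return KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def hbond_matrix(frame: Frame, topology: Topology) -> np.ndarray:
    """Boolean matrix ``B[i, j]`` (0-based): N–H of residue i+1 donates a
    hydrogen bond to C=O of residue j+1 (energy below −0.5 kcal/mol)."""
    nres = topology.n_residues
    X = frame.coords
    idx = lambda name: np.array(
        [topology.atom_index(r, name) for r in range(1, nres + 1)]
    )
    N = X[idx("N")]
    C = X[idx("C")]
    O = X[idx("O")]
    H = np.array([amide_hydrogen(frame, topology, r)
                  for r in range(1, nres + 1)])
    dist = lambda A, B: np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
    with np.errstate(divide="ignore"):
        E = KS_COUPLING * (1.0 / dist(N, O) + 1.0 / dist(H, C)
                           - 1.0 / dist(H, O) - 1.0 / dist(N, C))
    ii, jj = np.indices(E.shape)
    E[np.abs(ii - jj) < 2] = 0.0
    return E < HBOND_CUTOFF


def assign_ss(frame: Frame, topology: Topology) -> np.ndarray:
    """Per-residue 3-state secondary-structure labels (H/E/C).

    Helix: residues i+1..i+4 of two consecutive i→i+4 turns.  Strand:
    members of Kabsch–Sander parallel or antiparallel bridges.  Helix
    wins where both apply; everything else is coil/bend/turn (C).
    """
    nres = topology.n_residues
    hb = hbond_matrix(frame, topology)          # hb[d, a], 0-based

    labels = np.full(nres, "C", dtype="<U1")

    # --- bridges -> E
    def bond(i, j):  # 1-based helper with bounds check
        return (1 <= i <= nres and 1 <= j <= nres and hb[i - 1, j - 1])

    is_strand = np.zeros(nres, dtype=bool)
    for i in range(2, nres):          # interior residues, 1-based
        for j in range(i + 3, nres):  # bridges need |i-j| >= 3
            anti = (bond(i, j) and bond(j, i)) or \
                   (bond(i - 1, j + 1) and bond(j - 1, i + 1))
            para = (bond(i - 1, j) and bond(j, i + 1)) or \
                   (bond(j - 1, i) and bond(i, j + 1))
            if anti or para:
                is_strand[i - 1] = True
                is_strand[j - 1] = True
    labels[is_strand] = "E"

    # --- consecutive i -> i+4 turns -> H (priority over E)
    turn4 = np.zeros(nres, dtype=bool)          # turn starting at i (0-based)
    for i in range(nres - 4):
        turn4[i] = hb[i + 4, i]                 # donor i+4 -> acceptor i
    for i in range(nres - 5):
        if turn4[i] and turn4[i + 1]:
            labels[i + 1:i + 5] = "H"
    return labels


def occupancy_by_residue(ensemble: Ensemble) -> pd.DataFrame:
    """Fraction of frames each residue spends in H/E/C.

    Returns a DataFrame indexed by 1-based residue with columns
    ``H``, ``E``, ``C`` summing to 1 per residue.
    """
    topo = ensemble.topology
    counts = np.zeros((topo.n_residues, 3))
    order = {"H": 0, "E": 1, "C": 2}
    for fr in ensemble.frames:
        lab = assign_ss(fr, topo)
        for s, col in order.items():
            counts[:, col] += lab == s
    frac = counts / ensemble.n_frames
    return pd.DataFrame(frac, columns=["H", "E", "C"],
                        index=pd.RangeIndex(1, topo.n_residues + 1,
                                            name="residue"))


def ss_content(ensemble: Ensemble) -> pd.Series:
    """Pooled H/E/C fractions over all residue–frame observations."""
    occ = occupancy_by_residue(ensemble)
    return occ.mean(axis=0)


_DSSP_TO_3STATE = {"H": "H", "G": "H", "I": "H",
                   "E": "E", "B": "E",
                   "T": "C", "S": "C", " ": "C", "-": "C", "": "C",
                   "P": "C"}


def read_dssp_labels(path) -> np.ndarray:
    """Read per-residue labels from a classic DSSP output file.

    Parses the residue block following the ``#  RESIDUE`` header line
    (structure code at column 17) and collapses the 8-class alphabet to
    H/E/C, so an external DSSP run can replace the internal assigner in
    the occupancy statistics.  Chain-break markers (``!``) are skipped.
    """
    codes = []
    in_block = False
    with open(path) as fh:
        for line in fh:
            if not in_block:
                if line.lstrip().startswith("#  RESIDUE"):
                    in_block = True
                continue
            if len(line) < 17:
                continue
            if line[13] == "!":     # chain break pseudo-residue
                continue
            codes.append(line[16])
    if not codes:
        raise ValueError(f"{path}: no residue records found")
    return collapse_dssp_codes(codes)


def collapse_dssp_codes(codes) -> np.ndarray:
    """Collapse 8-class DSSP codes to the 3-state H/E/C alphabet.

    Accepts an iterable of single-character DSSP classes (e.g. parsed from
    an external DSSP output) so externally assigned structures can feed
    the same occupancy statistics.
    """
    return np.array([_DSSP_TO_3STATE.get(str(c).upper(), "C") for c in codes],
                    dtype="<U1")
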