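"""Core domain types and file I/O shared by all analysis stages.

Conventions used throughout the package:

* coordinates are in angstrom (Å), times in picoseconds (ps);
* residues are numbered 1-based, so ``F4`` denotes the fourth residue;
* frames are ordered, and within one trajectory timestamps strictly
  increase;
* van der Waals radii cover heavy atoms only — hydrogens carry no radius
  and are excluded from surface-area calculations, consistent with a
  united-atom provenance of the conformations being analysed.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomRecord",
    "Topology",
    "Frame",
    "Ensemble",
    "ObservableTable",
    "ATOMIC_MASSES",
    "VDW_RADII",
    "DEFAULT_HYDROPHOBIC_SET",
    "AA_THREE_LETTER",
    "ABETA42_SEQUENCE",
    "infer_element",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_observable_table",
]

#: Atomic masses in amu for the elements that occur in peptide backbones
#: and side chains.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}

#: Default van der Waals radii (Å) for heavy atoms.  Hydrogens are absent
#: on purpose: they do not contribute to the solvent-accessible surface in
#: the united-atom convention adopted here.  Overridable per calculation.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
}

#: Hydrophobic residues whose summed side-chain exposure defines the
#: collapsed/extended reaction coordinate for amyloid-beta:
#: F4, V18, F20, A21, I31, L34 and V36 (1-based).
DEFAULT_HYDROPHOBIC_SET: tuple[int, ...] = (4, 18, 20, 21, 31, 34, 36)

AA_THREE_LETTER: dict[str, str] = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: One-letter sequence of the 42-residue amyloid-beta peptide; the
#: 40-residue alloform is the same sequence without the last two residues.
ABETA42_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"


class StructureError(ValueError):
    """Raised for structurally inconsistent multi-model input."""


class ParseError(ValueError):
    """Raised for unparsable records in text input, with location info."""


def infer_element(atom_name: str) -> str:
    """Infer the chemical element from a PDB atom name.

    Leading digits (as in ``1HB``) are skipped; the first alphabetic
    character is taken as the element.  This is adequate for peptide
    backbone and side-chain atoms, which is all this package handles.
    """
    stripped = atom_name.strip()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology: name, element, mass (amu), vdW radius (Å).

    ``radius`` is ``None`` for hydrogens, which are excluded from SASA.
    """

    name: str
    element: str
    mass: float
    radius: float | None

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"atom {self.name}: mass must be positive")
        if self.radius is not None and self.radius <= 0:
            raise ValueError(f"atom {self.name}: radius must be positive")


@dataclass
class Topology:
    """Static description of the peptide: residues, atoms, hydrophobic set.

    Parameters
    ----------
    residue_names
        Three-letter residue codes in chain order; residue ``i`` (1-based)
        is ``residue_names[i - 1]``.
    atoms
        Per-residue atom records, same order as ``residue_names``.
    hydrophobic_set
        1-based indices of the residues whose solvent exposure defines
        the collapsed/extended coordinate.
    """

    residue_names: list[str]
    atoms: list[list[AtomRecord]]
    hydrophobic_set: tuple[int, ...] = ()

    def __post_init__(self):
        if len(self.residue_names) != len(self.atoms):
            raise ValueError("residue_names and atoms length mismatch")
        if not self.residue_names:
            raise ValueError("topology must contain at least one residue")
        for i, recs in enumerate(self.atoms, start=1):
            names = {a.name for a in recs}
            missing = {"N", "CA", "C", "O"} - names
            if missing:
                raise ValueError(
                    f"residue {i} lacks backbone atoms: {sorted(missing)}"
                )
        bad = [r for r in self.hydrophobic_set
               if not 1 <= r <= self.n_residues]
        if bad:
            raise ValueError(f"hydrophobic_set outside residue range: {bad}")
        self.hydrophobic_set = tuple(self.hydrophobic_set)
        # global atom bookkeeping
        self._index: dict[tuple[int, str], int] = {}
        res_of_atom, names, elements, masses, radii = [], [], [], [], []
        for ri, recs in enumerate(self.atoms, start=1):
            for rec in recs:
                self._index[(ri, rec.name)] = len(names)
                res_of_atom.append(ri)
                names.append(rec.name)
                elements.append(rec.element)
                masses.append(rec.mass)
                radii.append(np.nan if rec.radius is None else rec.radius)
        self.residue_of_atom = np.asarray(res_of_atom, dtype=int)
        self.atom_names = np.asarray(names)
        self.elements = np.asarray(elements)
        self.masses = np.asarray(masses, dtype=float)
        self.radii = np.asarray(radii, dtype=float)

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def atom_index(self, residue: int, atom_name: str) -> int:
        """Global atom index of ``atom_name`` in 1-based ``residue``."""
        try:
            return self._index[(residue, atom_name)]
        except KeyError:
            raise KeyError(
                f"residue {residue} has no atom {atom_name!r}"
            ) from None

    def has_atom(self, residue: int, atom_name: str) -> bool:
        return (residue, atom_name) in self._index

    def atom_indices_of_residues(self, residues) -> np.ndarray:
        mask = np.isin(self.residue_of_atom, np.asarray(list(residues)))
        return np.nonzero(mask)[0]


@dataclass
class Frame:
    """One saved conformation: coordinates (Å), timestamp (ps), trajectory."""

    coords: np.ndarray
    time: float = 0.0
    trajectory_id: str = "traj"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.time < 0:
            raise ValueError("time must be non-negative")


@dataclass
class Ensemble:
    """A time-ordered collection of frames sharing one topology."""

    topology: Topology
    frames: list[Frame]
    group_id: str = ""

    def __post_init__(self):
        if not self.frames:
            raise ValueError("ensemble must contain at least one frame")
        n = self.topology.n_atoms
        for k, fr in enumerate(self.frames):
            if fr.coords.shape[0] != n:
                raise StructureError(
                    f"frame {k}: {fr.coords.shape[0]} atoms, "
                    f"topology has {n}"
                )
        last: dict[str, float] = {}
        for k, fr in enumerate(self.frames):
            prev = last.get(fr.trajectory_id)
            if prev is not None and fr.time <= prev:
                raise ValueError(
                    f"frame {k}: time {fr.time} ps not strictly increasing "
                    f"within trajectory {fr.trajectory_id!r}"
                )
            last[fr.trajectory_id] = fr.time

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def trajectory_ids(self) -> np.ndarray:
        return np.array([f.trajectory_id for f in self.frames])

    def coords_stack(self) -> np.ndarray:
        """All coordinates as one ``(n_frames, n_atoms, 3)`` array."""
        return np.stack([f.coords for f in self.frames])


# ---------------------------------------------------------------------------
# multi-model PDB I/O


def _build_topology(atom_names, res_ids, res_names, elements,
                    hydrophobic_set=None, radii=None) -> Topology:
    radii = dict(VDW_RADII if radii is None else radii)
    res_order = []
    seen = set()
    for rid in res_ids:
        if rid not in seen:
            seen.add(rid)
            res_order.append(rid)
    name_of = {}
    atoms_of: dict[int, list[AtomRecord]] = {rid: [] for rid in res_order}
    for an, rid, rn, el in zip(atom_names, res_ids, res_names, elements):
        el = el if el else infer_element(an)
        mass = ATOMIC_MASSES.get(el)
        if mass is None:
            raise StructureError(f"no atomic mass for element {el!r} "
                                 f"(atom {an!r})")
        radius = None if el == "H" else radii.get(el)
        if el != "H" and radius is None:
            raise StructureError(f"no vdW radius for element {el!r} "
                                 f"(atom {an!r})")
        atoms_of[rid].append(AtomRecord(an, el, mass, radius))
        name_of[rid] = rn
    if hydrophobic_set is None:
        n_res = len(res_order)
        hydrophobic_set = tuple(
            r for r in DEFAULT_HYDROPHOBIC_SET if r <= n_res
        ) if n_res >= max(DEFAULT_HYDROPHOBIC_SET) else ()
    return Topology(
        residue_names=[name_of[r] for r in res_order],
        atoms=[atoms_of[r] for r in res_order],
        hydrophobic_set=hydrophobic_set,
    )


def _prescan_pdb(path) -> list[float] | None:
    """Validate ATOM records and model consistency; collect TIME remarks.

    Returns per-model times in ps if ``REMARK ... TIME=<ps>`` lines are
    present (one per model), else ``None``.  Raises :class:`ParseError`
    with a line number for malformed ATOM records and
    :class:`StructureError` naming the model for inconsistent atom counts.
    """
    counts: list[int] = []
    times: list[float] = []
    current = 0
    in_model = False
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                in_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError:
                    raise ParseError(
                        f"{path}: unparsable ATOM record at line {lineno}"
                    ) from None
                current += 1
            elif rec == "REMARK" and "TIME=" in line:
                try:
                    times.append(float(line.split("TIME=")[1].split()[0]))
                except (ValueError, IndexError):
                    raise ParseError(
                        f"{path}: unparsable TIME remark at line {lineno}"
                    ) from None
    if saw_model and in_model:
        counts.append(current)  # unterminated final model
    if not saw_model:
        counts = [current]
    if not any(counts):
        raise StructureError(f"{path}: no ATOM records found")
    ref = counts[0]
    for m, c in enumerate(counts, start=1):
        if c != ref:
            raise StructureError(
                f"{path}: model {m} has {c} atoms, model 1 has {ref}"
            )
    if times and len(times) == len(counts):
        return times
    return None


def read_multimodel_pdb(path, frame_interval_ps: float = 100.0,
                        trajectory_id: str = "traj",
                        hydrophobic_set=None,
                        group_id: str = "") -> Ensemble:
    """Read a multi-model PDB file into an :class:`Ensemble`.

    Model ``k`` (0-based) receives timestamp ``k * frame_interval_ps``
    unless the file carries one ``REMARK ... TIME=<ps>`` line per model,
    in which case those explicit times are used.
    """
    if frame_interval_ps <= 0:
        raise ValueError("frame_interval_ps must be positive")
    explicit_times = _prescan_pdb(path)
    pdb = PDBFile.read(path)
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])
    topo = _build_topology(stack.atom_name, stack.res_id, stack.res_name,
                           stack.element, hydrophobic_set=hydrophobic_set)
    frames = []
    for k in range(stack.stack_depth()):
        t = explicit_times[k] if explicit_times else k * frame_interval_ps
        frames.append(Frame(stack.coord[k], time=t,
                            trajectory_id=trajectory_id))
    return Ensemble(topology=topo, frames=frames, group_id=group_id)


def write_multimodel_pdb(ensemble: Ensemble, path) -> None:
    """Write an ensemble as a standard multi-model PDB (one MODEL/frame).

    Coordinates are written at the PDB fixed-column precision of
    10⁻³ Å; frame order is preserved, so re-reading with the saving
    interval reproduces the timestamps of uniformly saved ensembles.
    """
    topo = ensemble.topology
    n = topo.n_atoms
    arr = struc.AtomArray(n)
    arr.res_id = topo.residue_of_atom
    arr.res_name = np.array(
        [topo.residue_names[r - 1] for r in topo.residue_of_atom]
    )
    arr.atom_name = topo.atom_names.copy()
    arr.element = topo.elements.copy()
    arr.chain_id = np.full(n, "A")
    arr.hetero = np.zeros(n, dtype=bool)
    arrays = []
    for fr in ensemble.frames:
        a = arr.copy()
        a.coord = np.asarray(fr.coords, dtype=np.float32)
        arrays.append(a)
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)


# ---------------------------------------------------------------------------
# observable tables


@dataclass
class ObservableTable:
    """Per-residue experimental vs back-calculated observables (Hz).

    Wraps a DataFrame with columns ``residue`` (1-based, unique),
    ``observed``, and optionally ``calculated`` and ``sd``; rows are kept
    sorted by residue.
    """

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        df = self.data.copy()
        if "residue" not in df.columns or "observed" not in df.columns:
            raise ValueError("table needs 'residue' and 'observed' columns")
        if df["residue"].duplicated().any():
            dups = sorted(df.loc[df["residue"].duplicated(), "residue"])
            raise ValueError(f"duplicate residue indices: {dups}")
        if not np.all(np.isfinite(df["observed"].to_numpy(dtype=float))):
            raise ValueError("observed values must be finite")
        for col in ("calculated", "sd"):
            if col not in df.columns:
                df[col] = np.nan
        df = df.sort_values("residue", kind="stable").reset_index(drop=True)
        df["residue"] = df["residue"].astype(int)
        for col in ("observed", "calculated", "sd"):
            df[col] = df[col].astype(float)
        self.data = df[["residue", "observed", "calculated", "sd"]]

    @classmethod
    def from_arrays(cls, residue, observed, calculated=None, sd=None):
        df = pd.DataFrame({"residue": residue, "observed": observed})
        if calculated is not None:
            df["calculated"] = calculated
        if sd is not None:
            df["sd"] = sd
        return cls(df)

    @property
    def residues(self) -> np.ndarray:
        return self.data["residue"].to_numpy()

    def paired(self) -> pd.DataFrame:
        """Rows holding both an observed and a calculated value."""
        return self.data.dropna(subset=["observed", "calculated"])

    def write(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.8g")


_COLUMN_ALIASES = {
    "residue": "residue", "res": "residue", "resid": "residue",
    "observed": "observed", "obs": "observed", "exp": "observed",
    "experimental": "observed",
    "calculated": "calculated", "calc": "calculated",
    "sd": "sd", "std": "sd", "stdev": "sd", "sigma": "sd",
}


def read_observable_table(path) -> ObservableTable:
    """Read a delimited (comma or tab, sniffed) per-residue observable table.

    The header must name a residue column and an observed-value column
    (aliases like ``res``/``obs``/``exp`` are accepted).  Duplicate
    residues and non-numeric values are rejected with the offending row.
    """
    with open(path) as fh:
        text = fh.read()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, skipinitialspace=True)
    df.columns = [
        _COLUMN_ALIASES.get(str(c).strip().lower(), str(c).strip().lower())
        for c in df.columns
    ]
    if "residue" not in df.columns or "observed" not in df.columns:
        raise ParseError(
            f"{path}: header must name residue and observed columns, "
            f"got {list(df.columns)}"
        )
    for col in ("residue", "observed", "calculated", "sd"):
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ParseError(f"{path}: non-numeric {col!r} value at row {row}")
        df[col] = coerced
    try:
        return ObservableTable(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
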