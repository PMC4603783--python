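"""NMR validation: Karplus back-calculation and comparison statistics.

The three-bond amide–alpha scalar coupling is related to the backbone
dihedral φ by the Karplus equation

    ³J(HN−Hα)(φ) = a·cos²(φ − 60°) + b·cos(φ − 60°) + c   [Hz]

with the −60° phase of the standard ³J(HN−Hα) parameterisation.  Ensemble
(motional) averaging is applied to the trigonometric basis terms before
fitting, so the fitted coefficients describe the ensemble, not a single
conformer.  Agreement with experiment is summarised by the RMSD between
observed and calculated values and by the Pearson correlation
coefficient.  Residual dipolar couplings are not back-calculated here;
externally computed RDC tables feed the same two statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Ensemble, ObservableTable, Topology
from .geometry import phi_series

__all__ = ["KarplusCoefficients", "KARPLUS_SETS", "karplus_j",
           "ensemble_j", "fit_karplus", "rmsd_obs", "pcc"]


@dataclass(frozen=True)
class KarplusCoefficients:
    """Karplus coefficients a, b, c in Hz."""

    a: float = 7.7
    b: float = -1.9
    c: float = 0.06

    def __post_init__(self):
        if not all(np.isfinite([self.a, self.b, self.c])):
            raise ValueError("coefficients must be finite")


#: Published ³J(HN−Hα) coefficient sets selectable by name.  The default
#: set (7.7, −1.9, 0.06) is the one that fits disordered-peptide
#: ensembles best in our hands; the others are classical alternatives.
KARPLUS_SETS: dict[str, KarplusCoefficients] = {
    "default": KarplusCoefficients(7.7, -1.9, 0.06),
    "vuister_bax": KarplusCoefficients(6.51, -1.76, 1.60),
    "hu_bax": KarplusCoefficients(7.09, -1.42, 1.55),
}

_PHASE_DEG = 60.0


def karplus_j(phi_deg, coeffs: KarplusCoefficients = KarplusCoefficients()):
    """³J(HN−Hα) in Hz for backbone dihedral(s) φ in degrees."""
    phi = np.asarray(phi_deg, dtype=float)
    c = np.cos(np.radians(phi - _PHASE_DEG))
    out = coeffs.a * c * c + coeffs.b * c + coeffs.c
    return float(out) if np.isscalar(phi_deg) else out


def ensemble_j(ensemble: Ensemble, coeffs: KarplusCoefficients =
               KarplusCoefficients()) -> "np.ndarray":
    """Per-residue ensemble-mean J (Hz); residue 1 (no φ) is ``nan``.

    Returned as an array of length ``n_residues`` indexed by
    ``residue − 1``; the mean is the arithmetic average of the per-frame
    Karplus values, i.e. the motional average of the coupling.
    """
    topo = ensemble.topology
    acc = np.zeros(topo.n_residues)
    for fr in ensemble.frames:
        phi = phi_series(fr, topo)
        acc += np.where(np.isnan(phi), 0.0, karplus_j(phi, coeffs))
    out = acc / ensemble.n_frames
    out[0] = np.nan
    return out


def fit_karplus(phi_samples: dict[int, np.ndarray],
                observed: dict[int, float]
                ) -> tuple[KarplusCoefficients, float]:
    """Fit Karplus coefficients to observed couplings by least squares.

    ``phi_samples`` maps residue → array of φ draws (degrees) from the
    ensemble; ``observed`` maps residue → measured J (Hz).  The ensemble
    average is taken over the basis terms ⟨cos²(φ−60°)⟩ and ⟨cos(φ−60°)⟩
    per residue first (motional averaging), then one linear system is
    solved over all residues with both data.  Returns the coefficients
    and the residual RMSD of the fit.
    """
    residues = sorted(set(phi_samples) & set(observed))
    if len(residues) < 3:
        raise ValueError("need >= 3 residues with both phi samples and data")
    rows, y = [], []
    for r in residues:
        c = np.cos(np.radians(np.asarray(phi_samples[r], float) - _PHASE_DEG))
        rows.append([np.mean(c * c), np.mean(c), 1.0])
        y.append(observed[r])
    X = np.asarray(rows)
    y = np.asarray(y)
    if np.linalg.matrix_rank(X, tol=1e-8 * np.abs(X).max()) < 3:
        raise ValueError("rank-deficient design: phi distributions too "
                         "similar across residues")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = X @ beta - y
    rmsd = float(np.sqrt(np.mean(resid ** 2)))
    return KarplusCoefficients(*map(float, beta)), rmsd


def rmsd_obs(table: ObservableTable) -> float:
    """Root-mean-square deviation (Hz) between calculated and observed
    values over the residues carrying both."""
    paired = table.paired()
    if len(paired) == 0:
        raise ValueError("no rows with both observed and calculated values")
    diff = paired["calculated"].to_numpy() - paired["observed"].to_numpy()
    return float(np.sqrt(np.mean(diff ** 2)))


def pcc(x, y) -> float:
    """Pearson correlation coefficient Cov(X,Y)/(σ_X σ_Y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in input")
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return float(cov / (sx * sy))
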