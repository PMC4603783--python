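"""Collapsed/extended state analysis from hydrophobic solvent exposure.

A frame is collapsed (CS) when the summed SASA of the hydrophobic residue
set falls below ``cs_max`` and extended (ES) when it rises above
``es_min``; values in between — including the thresholds themselves,
which are read strictly — are intermediate (INT).  The module also trims
the equilibration transient, aggregates state probabilities per group,
and computes per-cluster SASA and appearance-time statistics.

The absolute default thresholds (550/650 Å²) are tied to a particular
force field and SASA convention; for synthetic data, recalibrate them
with :func:`calibrate_thresholds` to the midpoint of the generated
populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Ensemble, Topology
from .sasa import SasaParams, hydrophobic_sasa

__all__ = ["StateThresholds", "trim_equilibration", "classify_state",
           "state_series", "state_probabilities", "cluster_sasa_summary",
           "appearance_times", "calibrate_thresholds", "STATES"]

STATES = ("CS", "ES", "INT")


@dataclass(frozen=True)
class StateThresholds:
    """CS/ES thresholds on hydrophobic SASA (Å²).

    ``cs_max`` — collapsed below this; ``es_min`` — extended above this.
    """

    cs_max: float = 550.0
    es_min: float = 650.0

    def __post_init__(self):
        if not 0 < self.cs_max <= self.es_min:
            raise ValueError("need 0 < cs_max <= es_min")


def trim_equilibration(ensemble: Ensemble,
                       t_cut_ps: float = 200_000.0) -> Ensemble:
    """Drop the equilibration transient: keep frames with time ≥ t_cut.

    Applied per trajectory; a frame at exactly the cut is retained.
    Raises if any trajectory loses all of its frames.
    """
    if t_cut_ps < 0:
        raise ValueError("t_cut_ps must be >= 0")
    kept = [f for f in ensemble.frames if f.time >= t_cut_ps]
    kept_ids = {f.trajectory_id for f in kept}
    for tid in dict.fromkeys(f.trajectory_id for f in ensemble.frames):
        if tid not in kept_ids:
            raise ValueError(
                f"trajectory {tid!r}: no frames remain after trimming at "
                f"{t_cut_ps} ps"
            )
    return Ensemble(topology=ensemble.topology, frames=kept,
                    group_id=ensemble.group_id)


def classify_state(sasa: float, thresholds: StateThresholds = StateThresholds()
                   ) -> str:
    """Classify one hydrophobic-SASA value as CS, ES or INT.

    Strict inequalities: a value exactly at either threshold is INT.
    """
    if sasa < 0:
        raise ValueError("SASA must be non-negative")
    if sasa < thresholds.cs_max:
        return "CS"
    if sasa > thresholds.es_min:
        return "ES"
    return "INT"


def state_series(ensemble: Ensemble,
                 sasa_params: SasaParams = SasaParams(),
                 thresholds: StateThresholds = StateThresholds(),
                 cluster_labels=None) -> pd.DataFrame:
    """Per-frame hydrophobic SASA and state label.

    Returns a DataFrame with columns ``time`` (ps), ``trajectory``,
    ``sasa`` (Å²), ``state`` and optionally ``cluster``.
    """
    topo = ensemble.topology
    sasas = np.array([hydrophobic_sasa(f, topo, sasa_params)
                      for f in ensemble.frames])
    df = pd.DataFrame({
        "time": ensemble.times,
        "trajectory": ensemble.trajectory_ids,
        "sasa": sasas,
        "state": [classify_state(s, thresholds) for s in sasas],
    })
    if cluster_labels is not None:
        labels = np.asarray(cluster_labels)
        if len(labels) != len(df):
            raise ValueError("cluster labels not aligned with frames")
        df["cluster"] = labels
    return df


def state_probabilities(series: pd.DataFrame) -> pd.Series:
    """Fraction of frames in CS, ES and INT (sums to 1)."""
    if len(series) == 0:
        raise ValueError("empty state series")
    counts = series["state"].value_counts()
    return pd.Series({s: counts.get(s, 0) / len(series) for s in STATES})


def cluster_sasa_summary(series: pd.DataFrame, labels=None) -> pd.DataFrame:
    """Per-cluster mean and population standard deviation of SASA.

    ``labels`` may be given separately or as a ``cluster`` column of the
    series.  Clusters with no frames are omitted (with a warning if the
    label range suggests they should exist).
    """
    df = series.copy()
    if labels is not None:
        labels = np.asarray(labels)
        if len(labels) != len(df):
            raise ValueError("labels not aligned with series")
        df["cluster"] = labels
    if "cluster" not in df.columns:
        raise ValueError("no cluster labels provided")
    grouped = df.groupby("cluster")["sasa"]
    out = pd.DataFrame({
        "mean_sasa": grouped.mean(),
        "sd_sasa": grouped.std(ddof=0),
        "n_frames": grouped.size(),
    })
    present = set(out.index)
    expected = set(range(int(df["cluster"].max()) + 1))
    missing = expected - present
    if missing:
        warnings.warn(f"clusters with no frames omitted: {sorted(missing)}")
    return out.reset_index()


def appearance_times(series: pd.DataFrame, labels=None,
                     mode: str = "mean") -> pd.Series:
    """Average appearance time of each cluster, in ns.

    ``mode="mean"`` (default): for every trajectory containing the
    cluster, the mean timestamp of the cluster's frames there; the
    cluster's value is the mean over those trajectories.  ``mode="first"``
    uses the first-occurrence timestamp per trajectory instead — an onset
    statistic.  Clusters absent everywhere are omitted.
    """
    if mode not in ("mean", "first"):
        raise ValueError(f"unknown mode {mode!r}")
    df = series.copy()
    if labels is not None:
        labels = np.asarray(labels)
        if len(labels) != len(df):
            raise ValueError("labels not aligned with series")
        df["cluster"] = labels
    if "cluster" not in df.columns:
        raise ValueError("no cluster labels provided")
    per_traj = df.groupby(["cluster", "trajectory"])["time"]
    stat = per_traj.mean() if mode == "mean" else per_traj.min()
    return stat.groupby("cluster").mean() / 1000.0  # ps -> ns


def calibrate_thresholds(sasa_low: np.ndarray, sasa_high: np.ndarray,
                         gap: float = 0.0) -> StateThresholds:
    """Thresholds at the midpoint between two SASA populations.

    ``gap`` widens an intermediate band of that total width around the
    midpoint (half below ``cs_max``, half above ``es_min``); the default
    gap of zero puts both thresholds at the midpoint so every frame is
    decisively CS or ES.
    """
    mid = 0.5 * (float(np.mean(sasa_low)) + float(np.mean(sasa_high)))
    return StateThresholds(cs_max=mid - gap / 2.0, es_min=mid + gap / 2.0)
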