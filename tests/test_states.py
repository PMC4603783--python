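"""Equilibration trimming, CS/ES classification and state statistics."""

import numpy as np
import pandas as pd
import pytest

from ensa.core import Ensemble, Frame
from ensa.states import (StateThresholds, appearance_times,
                         calibrate_thresholds, classify_state,
                         cluster_sasa_summary, state_probabilities,
                         state_series, trim_equilibration)


def _flat_ensemble(times, topo, coords, trajectory_ids=None):
    tids = trajectory_ids or ["t0"] * len(times)
    return Ensemble(topology=topo, frames=[
        Frame(coords, time=t, trajectory_id=tid)
        for t, tid in zip(times, tids)])


class TestTrim:
    def test_500ns_run_trimmed_at_200ns_keeps_3001_frames(self, helix20):
        topo, frame = helix20
        times = np.arange(0.0, 500_000.0 + 1, 100.0)
        ens = _flat_ensemble(times, topo, frame.coords)
        trimmed = trim_equilibration(ens, 200_000.0)
        assert trimmed.n_frames == 3001

    def test_boundary_frame_is_retained(self, helix20):
        topo, frame = helix20
        ens = _flat_ensemble([199_900.0, 200_000.0, 200_100.0], topo,
                             frame.coords)
        trimmed = trim_equilibration(ens, 200_000.0)
        assert trimmed.times.min() == 200_000.0
        assert trimmed.n_frames == 2

    def test_zero_cut_is_identity(self, helix20):
        topo, frame = helix20
        ens = _flat_ensemble([0.0, 100.0], topo, frame.coords)
        assert trim_equilibration(ens, 0.0).n_frames == 2

    def test_fully_trimmed_trajectory_raises_with_name(self, helix20):
        topo, frame = helix20
        ens = _flat_ensemble([0.0, 300_000.0], topo, frame.coords,
                             ["early", "late"])
        with pytest.raises(ValueError, match="early"):
            trim_equilibration(ens, 200_000.0)


class TestClassify:
    @pytest.mark.parametrize("sasa,state", [
        (500.0, "CS"), (700.0, "ES"), (550.0, "INT"), (650.0, "INT"),
        (600.0, "INT"),
    ])
    def test_thresholds_are_strict(self, sasa, state):
        assert classify_state(sasa) == state

    def test_negative_sasa_rejected(self):
        with pytest.raises(ValueError):
            classify_state(-1.0)

    def test_partition_and_monotonicity(self):
        thr = StateThresholds()
        order = {"CS": 0, "INT": 1, "ES": 2}
        prev = 0
        for sasa in np.linspace(0, 1200, 241):
            s = classify_state(float(sasa), thr)
            assert order[s] >= prev   # increasing SASA never moves backwards
            prev = order[s]

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            StateThresholds(cs_max=700.0, es_min=650.0)


def _series(states, times=None, trajectories=None, sasa=None):
    n = len(states)
    return pd.DataFrame({
        "time": times if times is not None else np.arange(n) * 100.0,
        "trajectory": trajectories if trajectories is not None
        else ["t0"] * n,
        "sasa": sasa if sasa is not None else np.zeros(n),
        "state": states,
    })


class TestProbabilities:
    def test_hand_built_counts(self):
        s = _series(["CS"] * 4 + ["ES"] * 5 + ["INT"])
        p = state_probabilities(s)
        assert p.to_dict() == {"CS": 0.4, "ES": 0.5, "INT": 0.1}

    def test_sum_to_one(self):
        s = _series(["CS", "ES", "INT", "ES"])
        assert state_probabilities(s).sum() == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_concatenation_order(self):
        a = _series(["CS"] * 3 + ["ES"] * 2)
        b = a.iloc[::-1].reset_index(drop=True)
        assert state_probabilities(a).equals(state_probabilities(b))

    def test_planted_mixture_recovered(self, two_state_small):
        ensemble, labels, _ = two_state_small
        series = state_series(
            ensemble, thresholds=calibrate_thresholds(
                *_population_sasas(ensemble, labels)))
        p = state_probabilities(series)
        assert p["CS"] == pytest.approx(np.mean(labels == 0), abs=1e-12)


def _population_sasas(ensemble, labels):
    from ensa.sasa import hydrophobic_sasa
    vals = np.array([hydrophobic_sasa(f, ensemble.topology)
                     for f in ensemble.frames])
    return vals[labels == 0], vals[labels == 1]


class TestClusterSummary:
    def test_two_frame_cluster_mean_and_sd(self):
        s = _series(["CS", "ES"], sasa=[500.0, 700.0])
        out = cluster_sasa_summary(s, labels=[0, 0])
        assert out["mean_sasa"].iloc[0] == pytest.approx(600.0)
        assert out["sd_sasa"].iloc[0] == pytest.approx(100.0)  # population sd

    def test_singleton_cluster_sd_zero(self):
        s = _series(["CS"], sasa=[480.0])
        out = cluster_sasa_summary(s, labels=[0])
        assert out["sd_sasa"].iloc[0] == 0.0

    def test_matches_brute_force_recompute(self, rng):
        sasa = rng.uniform(400, 800, 50)
        labels = rng.integers(0, 4, 50)
        s = _series(["CS"] * 50, sasa=sasa)
        out = cluster_sasa_summary(s, labels=labels).set_index("cluster")
        for c in np.unique(labels):
            vals = sasa[labels == c]
            assert out.loc[c, "mean_sasa"] == pytest.approx(vals.mean(),
                                                            abs=1e-9)
            assert out.loc[c, "sd_sasa"] == pytest.approx(
                np.sqrt(np.mean((vals - vals.mean()) ** 2)), abs=1e-9)

    def test_empty_cluster_warns(self):
        s = _series(["CS", "CS"], sasa=[500.0, 510.0])
        with pytest.warns(UserWarning, match="omitted"):
            cluster_sasa_summary(s, labels=[0, 2])


class TestAppearanceTimes:
    def test_uniform_block_has_midpoint_mean(self):
        times = np.arange(300_000.0, 400_000.0 + 1, 100.0)
        s = _series(["CS"] * len(times), times=times)
        out = appearance_times(s, labels=np.zeros(len(times), dtype=int))
        assert out[0] == pytest.approx(350.0)  # ns

    def test_average_over_trajectories(self):
        s = _series(["CS"] * 4,
                    times=[400_000.0, 500_000.0, 550_000.0, 650_000.0],
                    trajectories=["a", "a", "b", "b"])
        out = appearance_times(s, labels=[0, 0, 0, 0])
        # per-trajectory means 450 and 600 ns -> 525 ns
        assert out[0] == pytest.approx(525.0)

    def test_first_occurrence_mode(self):
        s = _series(["CS"] * 4,
                    times=[400_000.0, 500_000.0, 550_000.0, 650_000.0],
                    trajectories=["a", "a", "b", "b"])
        out = appearance_times(s, labels=[0, 0, 0, 0], mode="first")
        assert out[0] == pytest.approx((400.0 + 550.0) / 2)

    def test_absent_cluster_is_omitted(self):
        s = _series(["CS", "CS"])
        out = appearance_times(s, labels=[1, 1])
        assert 0 not in out.index and 1 in out.index


def test_calibrated_thresholds_sit_at_population_midpoint():
    thr = calibrate_thresholds(np.array([400.0, 420.0]),
                               np.array([700.0, 720.0]), gap=20.0)
    assert thr.cs_max == pytest.approx(550.0)
    assert thr.es_min == pytest.approx(570.0)
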