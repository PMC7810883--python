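"""Distances, contact events, the occurrence criteria and ion bridges."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pdzdyn import (
    ContactSchedule,
    DistanceSeries,
    IonSchedule,
    OccurrenceCriteria,
    SyntheticSpec,
    Topology,
    Trajectory,
    contact_events,
    contact_states,
    distance_series,
    generate_trajectory,
    ion_bridges,
    occurrence_decision,
    occurrence_ratio,
    saltbridge_monitor,
    telegraph_states,
)


def two_atom_traj(pos_a, pos_b, box=None):
    top = Topology(["CA", "CA"], [1, 2], ["ALA", "ALA"], ["A", "A"], ["C", "C"])
    coords = np.array([[pos_a, pos_b]], dtype=float)
    return Trajectory(top, [0.0], coords, None if box is None else np.array([box]))


def brute_force_events(states, times, gap_tol):
    """Independent run-length oracle: linear scan with explicit merging."""
    dt = times[1] - times[0] if len(times) > 1 else 1.0
    runs, start = [], None
    for i, s in enumerate(states):
        if s and start is None:
            start = i
        elif not s and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(states) - 1))
    merged = []
    for run in runs:
        if merged and (run[0] - merged[-1][1] - 1) * dt <= gap_tol:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    return [(times[s], times[s] + (e - s + 1) * dt) for s, e in merged]


class TestDistances:
    def test_unit_separation(self):
        traj = two_atom_traj([0, 0, 0], [1, 0, 0])
        s = distance_series(traj, "resid 1", "resid 2")
        assert np.isclose(s.distances_nm[0], 1.0)

    def test_self_distance_zero(self):
        traj = two_atom_traj([0.3, 0.2, 0.1], [1, 1, 1])
        s = distance_series(traj, "resid 1", "resid 1")
        assert np.allclose(s.distances_nm, 0.0)

    def test_minimum_image_agrees_with_27_image_brute_force(self):
        rng = np.random.default_rng(0)
        box = np.array([7.0, 5.0, 6.0])
        for _ in range(20):
            a, b = rng.uniform(0, box, 3), rng.uniform(0, box, 3)
            traj = two_atom_traj(a, b, box=box)
            s = distance_series(traj, "resid 1", "resid 2")
            images = [b + box * np.array([i, j, k])
                      for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
            expected = min(np.linalg.norm(a - img) for img in images)
            assert np.isclose(s.distances_nm[0], expected, atol=1e-12)

    def test_wrapped_pair_is_close_not_far(self):
        traj = two_atom_traj([0.1, 0, 0], [6.9, 0, 0], box=[7.0, 7.0, 7.0])
        s = distance_series(traj, "resid 1", "resid 2")
        assert np.isclose(s.distances_nm[0], 0.2, atol=1e-12)

    def test_empty_selection_rejected(self):
        traj = two_atom_traj([0, 0, 0], [1, 0, 0])
        with pytest.raises(ValueError, match="empty selection"):
            distance_series(traj, "resid 99", "resid 2")


class TestContactStates:
    def test_thresholding_and_boundary(self):
        crit = OccurrenceCriteria()
        s = DistanceSeries([0.0, 1.0, 2.0], [0.5, 1.5, 1.0])
        states = contact_states(s, crit)
        # boundary d == cutoff is a contact (inclusive rule)
        assert states.tolist() == [True, False, True]

    def test_alternating_occupancy_half(self):
        crit = OccurrenceCriteria()
        s = DistanceSeries(np.arange(10.0), [0.5, 1.5] * 5)
        occ = contact_states(s, crit).mean()
        assert occ == 0.5


class TestContactEvents:
    def test_split_and_merged_runs(self):
        times = np.arange(5.0)
        states = [True, True, False, True, True]
        evs = contact_events(states, times, gap_tolerance_ns=0.0)
        assert [(e.start_ns, e.duration_ns) for e in evs] == [(0.0, 2.0), (3.0, 2.0)]
        merged = contact_events(states, times, gap_tolerance_ns=1.0)
        assert [(e.start_ns, e.duration_ns) for e in merged] == [(0.0, 5.0)]

    @given(st.integers(0, 2**31 - 1), st.integers(0, 2))
    @settings(max_examples=60, deadline=None)
    def test_matches_run_length_oracle(self, seed, gap_tol):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 200))
        states = rng.random(n) < rng.uniform(0.1, 0.9)
        times = np.arange(n, dtype=float)
        got = [(e.start_ns, e.end_ns) for e in contact_events(states, times, gap_tol)]
        assert got == brute_force_events(states, times, gap_tol)


class TestOccurrenceRule:
    CRIT = OccurrenceCriteria()  # 1 nm / 20 ns / >25%

    def _decide(self, states, dt=1.0):
        times = np.arange(len(states)) * dt
        return occurrence_decision(np.array(states), times, self.CRIT)

    def test_long_contiguous_contact_counted(self):
        # 300 ns contiguous out of 1000 ns
        states = [True] * 300 + [False] * 700
        d = self._decide(states)
        assert (d.occupancy, d.max_event_ns, d.counted) == (0.30, 300.0, True)

    def test_fragmented_contact_fails_dwell_clause(self):
        # thirty separate 10 ns contacts: occupancy passes, dwell does not
        states = ([True] * 10 + [False] * 23) * 30 + [False] * 10
        d = self._decide(states)
        assert np.isclose(d.occupancy, 0.30, atol=0.005)
        assert d.max_event_ns == 10.0
        assert not d.counted

    def test_single_short_contact_fails_occupancy_clause(self):
        states = [True] * 20 + [False] * 980
        d = self._decide(states)
        assert d.max_event_ns == 20.0
        assert np.isclose(d.occupancy, 0.02)
        assert not d.counted

    def test_occupancy_at_threshold_not_counted(self):
        # exactly 25% is NOT "more than 25%"
        states = [True] * 250 + [False] * 750
        assert not self._decide(states).counted
        states = [True] * 251 + [False] * 749
        assert self._decide(states).counted

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_added_contact_frames(self, seed):
        rng = np.random.default_rng(seed)
        states = rng.random(400) < 0.3
        d0 = self._decide(states)
        more = states.copy()
        more[rng.integers(0, 400, 60)] = True
        d1 = self._decide(more)
        if d0.counted:
            assert d1.counted  # adding contact never un-counts

    def test_occupancy_equals_event_time_fraction(self):
        rng = np.random.default_rng(3)
        states = rng.random(500) < 0.4
        times = np.arange(500.0)
        d = occurrence_decision(states, times, self.CRIT)
        total = sum(e.duration_ns for e in contact_events(states, times, 0.0))
        assert np.isclose(d.occupancy, total / 500.0)


class TestOccurrenceRatio:
    def test_ratio_strings(self):
        from pdzdyn.contacts import OccurrenceDecision

        yes = OccurrenceDecision(0.5, 100.0, True)
        no = OccurrenceDecision(0.1, 5.0, False)
        assert occurrence_ratio([yes, no]).ratio == "1/2"
        assert occurrence_ratio([yes, yes, yes]).ratio == "3/3"

    def test_telegraph_replicas_mostly_counted(self):
        """Planted occupancy 0.5, mean dwell 50 ns >> 20 ns: nearly all count."""
        crit = OccurrenceCriteria()
        decisions = []
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            states = telegraph_states(rng, 10000, 0.1, 0.02, 0.02)  # dwell 50 ns
            decisions.append(occurrence_decision(states, np.arange(10000) * 0.1, crit))
        result = occurrence_ratio(decisions)
        assert result.n_counted >= 8


class TestIonBridges:
    def test_midpoint_ion_bridges_far_ion_does_not(self):
        top = Topology(["P", "P", "NA", "NA"], [1, 2, 401, 402],
                       ["SEP", "SEP", "NA", "NA"], ["A", "A", "I", "I"],
                       ["P", "P", "NA", "NA"])
        coords = np.array([[[0, 0, 0], [0.5, 0, 0], [0.25, 0, 0], [3, 3, 3]]])
        traj = Trajectory(top, [0.0], coords)
        recs = ion_bridges(traj, "resid 1", "resid 2", "name NA", 0.35)
        assert len(recs) == 1 and recs[0].classification == "stable"

    def test_one_sided_proximity_is_not_a_bridge(self):
        top = Topology(["P", "P", "NA"], [1, 2, 401], ["SEP", "SEP", "NA"],
                       ["A", "A", "I"], ["P", "P", "NA"])
        coords = np.array([[[0, 0, 0], [1.8, 0, 0], [0.3, 0, 0]]])
        traj = Trajectory(top, [0.0], coords)
        assert ion_bridges(traj, "resid 1", "resid 2", "name NA", 0.4) == []

    def test_scheduled_residences_classified(self):
        spec = SyntheticSpec(
            seed=6, n_frames=1000, dt_ns=1.0, sigma_nm=0.01, n_ions=2,
            phospho_sites=(263, 280),
            contact_schedules=(ContactSchedule(
                "resid 263 and name P", "resid 280 and name P",
                mode="intervals", intervals=((0.0, 1000.0),),
                contact_nm=0.5, apart_nm=1.5),),
            ion_schedules=(
                IonSchedule(0, "resid 263 and name P", "resid 280 and name P",
                            intervals=((0.0, 800.0),)),
                IonSchedule(1, "resid 263 and name P", "resid 280 and name P",
                            intervals=((800.0, 850.0),)),
            ),
        )
        traj = generate_trajectory(spec)
        recs = ion_bridges(traj, "resid 263 and name P", "resid 280 and name P",
                           "name NA", 0.35)
        by_class = {r.classification for r in recs}
        assert by_class == {"stable", "diffuse"}
        stable = next(r for r in recs if r.classification == "stable")
        assert stable.residence_fraction > 0.9  # 800 of 850 bridging frames


class TestSaltBridgeMonitor:
    def test_permanent_and_scheduled_break(self):
        crit = OccurrenceCriteria()
        spec = SyntheticSpec(
            seed=12, n_frames=400, dt_ns=2.5, sigma_nm=0.01,
            contact_schedules=(
                ContactSchedule("resid 290 and name CB", "resid 292 and name CB",
                                mode="intervals", intervals=((0.0, 1000.0),),
                                contact_nm=0.35, apart_nm=1.6),
                ContactSchedule("resid 285 and name CB", "resid 300 and name CB",
                                mode="intervals", intervals=((0.0, 500.0),),
                                contact_nm=0.35, apart_nm=1.6),
            ),
        )
        traj = generate_trajectory(spec)
        results = saltbridge_monitor(
            traj,
            [("resid 290 and name CB", "resid 292 and name CB"),
             ("resid 285 and name CB", "resid 300 and name CB"),
             ("resid 250 and name CB", "resid 320 and name CB")],
            crit,
        )
        permanent, broken, never = results
        assert permanent["occurrence"].ratio == "1/1"
        assert permanent["occurrence"].per_replica[0]["occupancy"] == 1.0
        assert broken["occurrence"].ratio == "1/1"
        assert np.isclose(broken["occurrence"].per_replica[0]["occupancy"], 0.5, atol=0.01)
        assert never["occurrence"].ratio == "0/1"
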