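"""Atom-pair distances, contact occupancy and the occurrence criteria.

A monitored interaction (e.g. the guanidinium of R320 reaching across the
binding groove to a phosphate on pS263) is *counted* only when

* at least one contiguous contact event lasts >= 20 ns, AND
* the contact is present in more than 25% of the analysed window,

with contact defined as inter-atom distance <= 1.0 nm (boundary inclusive).
All three thresholds live in :class:`OccurrenceCriteria` and are
configurable; the defaults are the criteria above.  "Lasted at least 20 ns"
is read as one contiguous dwell, not accumulated time — under the 25%
clause the accumulated reading would be redundant for the 300-1000 ns
simulations these criteria were designed for.

Ion-mediated bridges (two anionic sites coordinating the same Na+) are
detected per frame and each ion is classified *stable* or *diffuse* by its
residence fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .selections import AtomSelection, resolve_selection
from .trajectory import Trajectory

__all__ = [
    "OccurrenceCriteria",
    "DistanceSeries",
    "ContactEvent",
    "OccurrenceDecision",
    "OccurrenceResult",
    "IonBridgeRecord",
    "distance_series",
    "contact_states",
    "contact_events",
    "occurrence_decision",
    "occurrence_ratio",
    "ion_bridges",
    "saltbridge_monitor",
]


@dataclass(frozen=True)
class OccurrenceCriteria:
    """Thresholds of the occurrence rule (distance <= cutoff; one event
    >= min_event_ns; occupancy strictly > min_occupancy)."""

    distance_cutoff_nm: float = 1.0
    min_event_ns: float = 20.0
    min_occupancy: float = 0.25
    gap_tolerance_ns: float = 0.0

    def __post_init__(self):
        if self.distance_cutoff_nm <= 0 or self.min_event_ns <= 0:
            raise ValueError("cutoff and minimum event length must be positive")
        if not (0.0 < self.min_occupancy < 1.0):
            raise ValueError("min_occupancy must lie in (0, 1)")
        if self.gap_tolerance_ns < 0:
            raise ValueError("gap tolerance must be >= 0")


@dataclass
class DistanceSeries:
    times_ns: np.ndarray
    distances_nm: np.ndarray
    pair_label: str = ""

    def __post_init__(self):
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.distances_nm = np.asarray(self.distances_nm, dtype=float)
        if len(self.times_ns) != len(self.distances_nm):
            raise ValueError("times and distances differ in length")
        if np.any(self.distances_nm < 0):
            raise ValueError("negative distance")


@dataclass(frozen=True)
class ContactEvent:
    start_ns: float
    end_ns: float

    @property
    def duration_ns(self) -> float:
        return self.end_ns - self.start_ns


@dataclass(frozen=True)
class OccurrenceDecision:
    occupancy: float
    max_event_ns: float
    counted: bool


@dataclass
class OccurrenceResult:
    per_replica: list = field(default_factory=list)
    ratio: str = "0/0"

    @property
    def n_counted(self) -> int:
        return sum(1 for r in self.per_replica if r["counted"])


@dataclass
class IonBridgeRecord:
    ion_id: int
    bridging_series: np.ndarray
    residence_fraction: float
    classification: str  # "stable" | "diffuse"


def _min_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.round(delta / box)


def distance_series(
    traj: Trajectory,
    atom_a: AtomSelection | str,
    atom_b: AtomSelection | str,
    *,
    pair_label: str | None = None,
    use_pbc: bool | None = None,
) -> DistanceSeries:
    """Per-frame distance between two selections.

    Multi-atom selections are reduced by the minimum inter-set distance per
    frame (so "any phosphate oxygen" works); restricting a selection to one
    named atom (e.g. ``name P``) recovers the single-atom convention.
    Minimum-image distances are used when the trajectory carries a box.
    """
    ia = resolve_selection(atom_a, traj.topology)
    ib = resolve_selection(atom_b, traj.topology)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError(f"empty selection ({atom_a!s} -> {len(ia)} atoms, {atom_b!s} -> {len(ib)})")
    pbc = traj.box_nm is not None if use_pbc is None else use_pbc
    a = traj.coords_nm[:, ia, :]          # (F, na, 3)
    b = traj.coords_nm[:, ib, :]          # (F, nb, 3)
    delta = a[:, :, None, :] - b[:, None, :, :]
    if pbc:
        if traj.box_nm is None:
            raise ValueError("use_pbc requested but trajectory has no box")
        delta = _min_image(delta, traj.box_nm[:, None, None, :])
    d = np.sqrt((delta ** 2).sum(axis=3)).min(axis=(1, 2))
    label = pair_label or f"{atom_a!s}--{atom_b!s}"
    return DistanceSeries(traj.times_ns.copy(), d, label)


def contact_states(series: DistanceSeries, criteria: OccurrenceCriteria) -> np.ndarray:
    """Boolean in-contact series; the boundary is inclusive (d <= cutoff)."""
    return series.distances_nm <= criteria.distance_cutoff_nm


def _dt(times: np.ndarray) -> float:
    if len(times) < 2:
        return 1.0
    return float(times[1] - times[0])


def contact_events(
    states: np.ndarray,
    times: np.ndarray,
    gap_tolerance_ns: float = 0.0,
) -> list[ContactEvent]:
    """Maximal runs of contact; false gaps <= gap_tolerance_ns are merged.

    Event duration counts frames inclusively: a run covering frames
    [i, j] has duration (j - i + 1) * dt, so a single contact frame is one
    dt long.  ``start_ns`` is the time of the first frame; ``end_ns`` is
    start + duration.
    """
    states = np.asarray(states, dtype=bool)
    times = np.asarray(times, dtype=float)
    if len(states) != len(times):
        raise ValueError("states and times differ in length")
    if len(states) == 0 or not states.any():
        return []
    dt = _dt(times)
    padded = np.concatenate(([False], states, [False]))
    edges = np.diff(padded.astype(int))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1  # inclusive frame index
    runs = list(zip(starts, ends))
    merged = [runs[0]]
    for s, e in runs[1:]:
        prev_s, prev_e = merged[-1]
        gap_frames = s - prev_e - 1
        if gap_frames * dt <= gap_tolerance_ns:
            merged[-1] = (prev_s, e)
        else:
            merged.append((s, e))
    return [ContactEvent(float(times[s]), float(times[s] + (e - s + 1) * dt)) for s, e in merged]


def occurrence_decision(
    states: np.ndarray,
    times: np.ndarray,
    criteria: OccurrenceCriteria,
) -> OccurrenceDecision:
    """Apply the occurrence rule to one replica's contact series.

    Occupancy is the contact-frame fraction of the full analysed window
    (before any gap merging), and the dwell clause requires at least one
    contiguous event >= min_event_ns.
    """
    states = np.asarray(states, dtype=bool)
    if len(states) == 0:
        raise ValueError("empty contact series")
    occupancy = float(states.mean())
    events = contact_events(states, times, criteria.gap_tolerance_ns)
    max_event = max((e.duration_ns for e in events), default=0.0)
    counted = (max_event >= criteria.min_event_ns) and (occupancy > criteria.min_occupancy)
    return OccurrenceDecision(occupancy, max_event, counted)


def occurrence_ratio(decisions: list[OccurrenceDecision]) -> OccurrenceResult:
    """Summarise per-replica decisions as the "k/n" occurrence ratio."""
    if len(decisions) == 0:
        raise ValueError("need >= 1 replica decision")
    per = [
        {
            "replica_id": i,
            "occupancy": d.occupancy,
            "max_event_ns": d.max_event_ns,
            "counted": bool(d.counted),
        }
        for i, d in enumerate(decisions)
    ]
    k = sum(1 for d in decisions if d.counted)
    return OccurrenceResult(per, f"{k}/{len(decisions)}")


def ion_bridges(
    traj: Trajectory,
    site_a: AtomSelection | str,
    site_b: AtomSelection | str,
    ions: AtomSelection | str = "name NA",
    cutoff_nm: float = 0.35,
    *,
    stable_threshold: float = 0.5,
) -> list[IonBridgeRecord]:
    """Per-ion bridge detection between two anionic sites.

    An ion bridges at a frame iff it is within ``cutoff_nm`` of at least one
    atom of each site (0.35 nm is a typical Na+-oxygen coordination
    distance).  Residence is each ion's share of the frames in which *any*
    bridge exists; ions at or above ``stable_threshold`` are "stable",
    below it "diffuse".  Ions that never bridge are omitted.
    """
    ia = resolve_selection(site_a, traj.topology)
    ib = resolve_selection(site_b, traj.topology)
    ii = resolve_selection(ions, traj.topology)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("empty site selection")
    if len(ii) == 0:
        raise ValueError("empty ion selection")
    pbc = traj.box_nm is not None

    def _dist(pos_i, pos_site):
        delta = pos_i[:, :, None, :] - pos_site[:, None, :, :]
        if pbc:
            delta = _min_image(delta, traj.box_nm[:, None, None, :])
        return np.sqrt((delta ** 2).sum(axis=3)).min(axis=2)  # (F, n_ions)

    pi = traj.coords_nm[:, ii, :]
    da = _dist(pi, traj.coords_nm[:, ia, :])
    db = _dist(pi, traj.coords_nm[:, ib, :])
    bridging = (da <= cutoff_nm) & (db <= cutoff_nm)       # (F, n_ions)
    any_bridge = bridging.any(axis=1)
    denom = int(any_bridge.sum())
    records = []
    for k, atom_idx in enumerate(ii):
        series = bridging[:, k]
        if not series.any():
            continue
        residence = float(series.sum() / denom) if denom else 0.0
        cls = "stable" if residence >= stable_threshold else "diffuse"
        records.append(IonBridgeRecord(int(atom_idx), series, residence, cls))
    return records


def saltbridge_monitor(
    trajs: Trajectory | list[Trajectory],
    pairs: list[tuple[AtomSelection | str, AtomSelection | str]],
    criteria: OccurrenceCriteria = OccurrenceCriteria(),
) -> list[dict]:
    """Composite distance -> contact -> occurrence per pair over replicas.

    Returns one dict per pair with the per-replica distance series and the
    aggregated :class:`OccurrenceResult` ("k/n" over the replicas given).
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    out = []
    for a, b in pairs:
        series_list, decisions = [], []
        for traj in trajs:
            s = distance_series(traj, a, b)
            decisions.append(occurrence_decision(contact_states(s, criteria), s.times_ns, criteria))
            series_list.append(s)
        out.append(
            {
                "pair_label": series_list[0].pair_label,
                "series": series_list,
                "occurrence": occurrence_ratio(decisions),
            }
        )
    return out
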