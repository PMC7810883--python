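"""DSSP-style secondary-structure assignment and helix unfolding detection.

Assignment follows the Kabsch-Sander hydrogen-bond pattern scheme reduced
to four classes: H (alpha-helix), G (3-10 helix), E (strand), C
(everything else — pi-helices, turns and bends are not distinguished).
The backbone amide hydrogen is constructed geometrically when absent
(1.01 A from N, anti to the preceding carbonyl), so trajectories without
explicit hydrogens are handled; an explicit H/HN atom is preferred when
present.  The H-bond energy is the Kabsch-Sander electrostatic model

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol

with a bond assigned when E < -0.5 kcal/mol.  Proline never donates.

Helix unfolding/refolding events are read from a per-frame helical
fraction with hysteresis (default 0.3/0.7) and a minimum dwell, which
suppresses threshold chatter of the kind a fast-breathing short helix
(the PDZ alpha1) produces.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .trajectory import Topology, Trajectory

__all__ = [
    "SSAssignment",
    "FoldingEvent",
    "assign_ss",
    "ss_timeseries",
    "helix_fraction",
    "detect_folding_events",
]

_Q1Q2_F = 0.084 * 332.0  # kcal/mol * A, Kabsch-Sander constant
_HBOND_E_CUT = -0.5      # kcal/mol
_NH_BOND_A = 1.01        # constructed N-H bond length, Angstrom


@dataclass
class SSAssignment:
    times_ns: np.ndarray
    residue_numbers: np.ndarray
    labels: np.ndarray  # (frames, residues) of 'H','G','E','C'


@dataclass(frozen=True)
class FoldingEvent:
    kind: str  # "unfolding" | "refolding"
    start_ns: float
    end_ns: float
    region: tuple[int, int]


def _backbone_index(top: Topology) -> tuple[list[tuple[str, int]], dict]:
    """Map each residue to its backbone atom indices (N, CA, C, O, H?)."""
    residues = top.residue_ids
    table = {rid: {} for rid in residues}
    for i in range(top.n_atoms):
        rid = (str(top.chain_ids[i]), int(top.residue_numbers[i]))
        name = str(top.atom_names[i])
        if name in ("N", "CA", "C", "O", "H", "HN"):
            table[rid]["H" if name == "HN" else name] = i
    return residues, table


def assign_ss(coords_nm: np.ndarray, top: Topology) -> np.ndarray:
    """Assign one of H/G/E/C per residue for a single frame.

    Residues missing any of N, CA, C, O are labelled C (with a warning).
    The assignment is invariant under rigid-body transforms of the frame,
    since only internal distances enter.
    """
    residues, table = _backbone_index(top)
    R = len(residues)
    xyz = np.asarray(coords_nm, dtype=float) * 10.0  # work in Angstrom

    complete = np.zeros(R, dtype=bool)
    N = np.zeros((R, 3)); CA = np.zeros((R, 3)); C = np.zeros((R, 3)); O = np.zeros((R, 3))
    Hc = np.zeros((R, 3)); has_h = np.zeros(R, dtype=bool)
    resname = []
    for k, rid in enumerate(residues):
        atoms = table[rid]
        if all(a in atoms for a in ("N", "CA", "C", "O")):
            complete[k] = True
            N[k] = xyz[atoms["N"]]; CA[k] = xyz[atoms["CA"]]
            C[k] = xyz[atoms["C"]]; O[k] = xyz[atoms["O"]]
            if "H" in atoms:
                Hc[k] = xyz[atoms["H"]]
                has_h[k] = True
        mask = (top.residue_numbers == rid[1]) & (top.chain_ids == rid[0])
        resname.append(str(top.residue_names[np.flatnonzero(mask)[0]]))
    if not complete.all():
        missing = [residues[k] for k in np.flatnonzero(~complete)]
        warnings.warn(f"residues without full backbone labelled C: {missing[:5]}"
                      + ("..." if len(missing) > 5 else ""))

    # construct amide H where absent: anti to the previous carbonyl
    donor_ok = np.zeros(R, dtype=bool)
    for k in range(1, R):
        if not (complete[k] and complete[k - 1]):
            continue
        if resname[k] == "PRO":
            continue
        if not has_h[k]:
            v = C[k - 1] - O[k - 1]
            norm = np.linalg.norm(v)
            if norm < 1e-9:
                continue
            Hc[k] = N[k] + _NH_BOND_A * v / norm
        donor_ok[k] = True
    # a first residue with an explicit H can still donate
    if R > 0 and complete[0] and has_h[0] and resname[0] != "PRO":
        donor_ok[0] = True

    # Kabsch-Sander energies: hb[d, a] = NH(d) donates to CO(a)
    hb = np.zeros((R, R), dtype=bool)
    acceptors = np.flatnonzero(complete)
    donors = np.flatnonzero(donor_ok)
    if len(donors) and len(acceptors):
        d_on = np.linalg.norm(N[donors][:, None, :] - O[acceptors][None, :, :], axis=2)
        d_ch = np.linalg.norm(Hc[donors][:, None, :] - C[acceptors][None, :, :], axis=2)
        d_oh = np.linalg.norm(Hc[donors][:, None, :] - O[acceptors][None, :, :], axis=2)
        d_cn = np.linalg.norm(N[donors][:, None, :] - C[acceptors][None, :, :], axis=2)
        with np.errstate(divide="ignore"):
            E = _Q1Q2_F * (1.0 / d_on + 1.0 / d_ch - 1.0 / d_oh - 1.0 / d_cn)
        ok = E < _HBOND_E_CUT
        # exclude self and directly bonded neighbours
        di = donors[:, None]; aj = acceptors[None, :]
        ok &= np.abs(di - aj) >= 2
        hb[np.ix_(donors, acceptors)] = ok

    labels = np.full(R, "C", dtype="U1")

    def turn(n):
        t = np.zeros(R, dtype=bool)
        idx = np.arange(R - n)
        t[idx] = hb[idx + n, idx]
        return t

    turn3, turn4 = turn(3), turn(4)

    # alpha helix: two consecutive 4-turns cover residues i+1..i+4
    is_h = np.zeros(R, dtype=bool)
    for i in range(R - 5):
        if turn4[i] and turn4[i + 1]:
            is_h[i + 1:i + 5] = True

    # beta bridges/ladders (Kabsch-Sander parallel/antiparallel patterns),
    # evaluated with shifted views: pad[i+1, j+1] == hb[i, j]
    pad = np.zeros((R + 2, R + 2), dtype=bool)
    pad[1:R + 1, 1:R + 1] = hb
    anti = (hb & hb.T) | (pad[2:, :R].T & pad[2:, :R])
    para = (pad[1:R + 1, :R].T & pad[2:, 1:R + 1]) | (pad[1:R + 1, :R] & pad[2:, 1:R + 1].T)
    ii, jj = np.meshgrid(np.arange(R), np.arange(R), indexing="ij")
    bridge = (anti | para) & (np.abs(ii - jj) >= 3)
    is_e = bridge.any(axis=1)

    # 3-10 helix: two consecutive 3-turns cover residues i+1..i+3
    is_g = np.zeros(R, dtype=bool)
    for i in range(R - 4):
        if turn3[i] and turn3[i + 1]:
            is_g[i + 1:i + 4] = True

    labels[is_g] = "G"
    labels[is_e & ~is_h] = "E"
    labels[is_h] = "H"
    labels[~complete] = "C"  # residues without a full backbone are never assigned
    return labels


def ss_timeseries(traj: Trajectory, stride: int = 1) -> SSAssignment:
    """Per-frame secondary-structure assignment (optionally strided)."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    frames = range(0, traj.n_frames, stride)
    residues = traj.topology.residue_ids
    labels = np.empty((len(frames), len(residues)), dtype="U1")
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for row, f in enumerate(frames):
            labels[row] = assign_ss(traj.coords_nm[f], traj.topology)
    return SSAssignment(
        traj.times_ns[::stride].copy(),
        np.array([r for _, r in residues]),
        labels,
    )


def helix_fraction(ss: SSAssignment, region: tuple[int, int]) -> np.ndarray:
    """Per-frame fraction of region residues in a helical state (H or G)."""
    lo, hi = region
    mask = (ss.residue_numbers >= lo) & (ss.residue_numbers <= hi)
    if not mask.any():
        raise ValueError(f"region {region} contains no residues")
    helical = np.isin(ss.labels[:, mask], ("H", "G"))
    return helical.mean(axis=1)


def detect_folding_events(
    fraction: np.ndarray,
    times: np.ndarray,
    *,
    low_thresh: float = 0.3,
    high_thresh: float = 0.7,
    min_dwell_ns: float = 5.0,
    region: tuple[int, int] = (0, 0),
) -> list[FoldingEvent]:
    """Hysteresis detection of unfolding/refolding transitions.

    An unfolding event is emitted when the helical fraction drops below
    ``low_thresh`` and stays there for at least ``min_dwell_ns`` (and
    symmetrically for refolding above ``high_thresh``).  The event spans
    the qualifying dwell.  Events of one region strictly alternate in kind.
    """
    if not low_thresh < high_thresh:
        raise ValueError("need low_thresh < high_thresh (hysteresis)")
    fraction = np.asarray(fraction, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(fraction) != len(times):
        raise ValueError("fraction and times differ in length")
    if len(fraction) == 0:
        return []
    dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    # initial state from the first sample, middle resolves to folded
    state = "folded" if fraction[0] >= (low_thresh + high_thresh) / 2 else "unfolded"
    events: list[FoldingEvent] = []
    i = 0
    n = len(fraction)
    while i < n:
        if state == "folded":
            if fraction[i] < low_thresh:
                j = i
                while j < n and fraction[j] < low_thresh:
                    j += 1
                dwell = (j - i) * dt
                if dwell >= min_dwell_ns:
                    events.append(FoldingEvent("unfolding", float(times[i]),
                                               float(times[i] + dwell), region))
                    state = "unfolded"
                i = j
                continue
        else:
            if fraction[i] > high_thresh:
                j = i
                while j < n and fraction[j] > high_thresh:
                    j += 1
                dwell = (j - i) * dt
                if dwell >= min_dwell_ns:
                    events.append(FoldingEvent("refolding", float(times[i]),
                                               float(times[i] + dwell), region))
                    state = "folded"
                i = j
                continue
        i += 1
    return events
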