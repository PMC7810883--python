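"""Synthetic topologies, trajectories and titrations with planted truth.

Every analysis stage in this package is exercised against data whose
ground truth is known analytically, generated here:

* a toy PDZ-like topology (helices built at ideal alpha dihedrals,
  strands extended, a long flexible loop) with one pseudo side-chain
  atom per residue so that contact schedules and backbone secondary
  structure are independent channels;
* per-atom Ornstein-Uhlenbeck positional noise with a stated stationary
  per-coordinate sigma (so the planted per-residue RMSF is sqrt(3)*sigma)
  and relaxation time tau — OU rather than i.i.d. noise so convergence
  and dwell statistics are nontrivial;
* two-state (telegraph) contact formation between designated atom pairs
  with stated on/off rates, giving stationary occupancy
  k_on/(k_on+k_off) and mean contact dwell 1/k_off;
* scheduled helix unfolding (dihedrals interpolated helix -> coil over a
  stated window);
* ions scripted to bridge two sites over stated intervals;
* two-state fast-exchange titration peak lists: bound fraction from the
  quadratic binding equation, observed shift f*ddmax, and a
  phenomenological exchange-broadening law I = I0*exp(-beta*f*(1-f)*s)
  where s scales inversely with Kd (slower exchange for tighter binding).

All randomness flows from a single integer seed; identical seeds give
bit-identical output.  No physical realism is attempted (no excluded
volume, no force field): the generator targets the statistical structure
the analyses assume, which is what the tests require.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .trajectory import Topology, Trajectory, write_topology, write_trajectory
from .selections import resolve_selection
from .nmr import PeakRecord, TitrationPoint, TitrationSeries, write_peaklist

__all__ = [
    "Segment",
    "ContactSchedule",
    "UnfoldingSchedule",
    "IonSchedule",
    "TitrationTruth",
    "SyntheticSpec",
    "build_backbone",
    "build_toy_topology",
    "generate_trajectory",
    "telegraph_states",
    "generate_titration",
    "emit_fixture_set",
    "ideal_helix",
    "extended_chain",
    "antiparallel_sheet",
]

# ideal backbone internal coordinates (Angstrom / degrees)
_B_NCA, _B_CAC, _B_CN, _B_CO, _B_CACB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_NCAC, _A_CACN, _A_CNCA, _A_CACO, _A_NCACB = 111.2, 116.2, 121.7, 120.5, 110.5

DIHEDRALS = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
    "coil": (-70.0, 150.0),   # PPII-like: extended, no regular H-bond pattern
}


def _nerf(a, b, c, r, theta_deg, chi_deg):
    """Place atom d given three predecessors, bond r, angle b-c-d, dihedral a-b-c-d."""
    theta = np.deg2rad(theta_deg)
    chi = np.deg2rad(chi_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-r * np.cos(theta), r * np.sin(theta) * np.cos(chi),
                  r * np.sin(theta) * np.sin(chi)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(phi_psi: np.ndarray, *, with_cb: bool = True) -> dict:
    """Build an ideal-geometry backbone from per-residue (phi, psi) degrees.

    Returns a dict of (R, 3) coordinate arrays in Angstrom for N, CA, C, O
    (and CB when requested).  Omega is held at 180 deg (trans).
    """
    phi_psi = np.asarray(phi_psi, dtype=float)
    R = phi_psi.shape[0]
    N = np.zeros((R, 3)); CA = np.zeros((R, 3)); C = np.zeros((R, 3)); O = np.zeros((R, 3))
    CB = np.zeros((R, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_NCA, 0.0, 0.0)
    th = np.deg2rad(_A_NCAC)
    C[0] = CA[0] + _B_CAC * np.array([-np.cos(th), np.sin(th), 0.0])
    for i in range(R):
        phi_next = phi_psi[i + 1, 0] if i + 1 < R else None
        psi = phi_psi[i, 1]
        O[i] = _nerf(N[i], CA[i], C[i], _B_CO, _A_CACO, psi + 180.0)
        if with_cb:
            CB[i] = _nerf(C[i], N[i], CA[i], _B_CACB, _A_NCACB, -122.0)
        if i + 1 < R:
            N[i + 1] = _nerf(N[i], CA[i], C[i], _B_CN, _A_CACN, psi)
            CA[i + 1] = _nerf(CA[i], C[i], N[i + 1], _B_NCA, _A_CNCA, 180.0)
            C[i + 1] = _nerf(C[i], N[i + 1], CA[i + 1], _B_CAC, _A_NCAC, phi_next)
    out = {"N": N, "CA": CA, "C": C, "O": O}
    if with_cb:
        out["CB"] = CB
    return out


def _assemble(backbone: dict, residue_numbers, residue_names, chain_id="A",
              extra_atoms=None) -> tuple[Topology, np.ndarray]:
    """Interleave per-residue backbone arrays into a Topology + coords (nm)."""
    order = [k for k in ("N", "CA", "C", "O", "CB") if k in backbone]
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "P": "P"}
    names, resnums, resnames, chains, elems, coords = [], [], [], [], [], []
    extra_atoms = extra_atoms or {}
    for k, resnum in enumerate(residue_numbers):
        for atom in order:
            names.append(atom)
            resnums.append(resnum)
            resnames.append(residue_names[k])
            chains.append(chain_id)
            elems.append(elements[atom])
            coords.append(backbone[atom][k])
        for atom_name, pos in extra_atoms.get(resnum, []):
            names.append(atom_name)
            resnums.append(resnum)
            resnames.append(residue_names[k])
            chains.append(chain_id)
            elems.append(elements.get(atom_name, atom_name[0]))
            coords.append(pos)
    top = Topology(names, resnums, resnames, chains, elems)
    return top, np.array(coords) * 0.1  # A -> nm


# ---------------------------------------------------------------------------
# Stand-alone ideal constructs (oracle suite for the SS assigner)
# ---------------------------------------------------------------------------

def ideal_helix(n_residues: int = 15) -> tuple[Topology, np.ndarray]:
    """Ideal poly-alanine alpha-helix at (phi, psi) = (-57, -47)."""
    pp = np.tile(DIHEDRALS["helix"], (n_residues, 1))
    bb = build_backbone(pp)
    return _assemble(bb, range(1, n_residues + 1), ["ALA"] * n_residues)


def extended_chain(n_residues: int = 12) -> tuple[Topology, np.ndarray]:
    """Fully extended isolated chain (phi = psi = 180): no partner, all coil."""
    pp = np.tile((180.0, 180.0), (n_residues, 1))
    bb = build_backbone(pp)
    return _assemble(bb, range(1, n_residues + 1), ["ALA"] * n_residues)


def _ks_hbond_count(bb1: dict, bb2: dict) -> int:
    """Count inter-strand Kabsch-Sander H-bonds between two backbones."""
    count = 0
    for donor_bb, acc_bb in ((bb1, bb2), (bb2, bb1)):
        R_d = donor_bb["N"].shape[0]
        for i in range(1, R_d):
            v = donor_bb["C"][i - 1] - donor_bb["O"][i - 1]
            h = donor_bb["N"][i] + 1.01 * v / np.linalg.norm(v)
            n = donor_bb["N"][i]
            for j in range(acc_bb["N"].shape[0]):
                c, o = acc_bb["C"][j], acc_bb["O"][j]
                e = 0.084 * 332.0 * (1 / np.linalg.norm(o - n) + 1 / np.linalg.norm(c - h)
                                     - 1 / np.linalg.norm(o - h) - 1 / np.linalg.norm(c - n))
                if e < -0.5:
                    count += 1
    return count


def antiparallel_sheet(n_residues: int = 8) -> tuple[Topology, np.ndarray]:
    """Two ideal antiparallel strands placed in H-bond register.

    The second strand is the first rotated 180 deg about the axis
    perpendicular to the strand direction and translated; the in-register
    placement is found by a deterministic grid scan maximising the number
    of Kabsch-Sander inter-strand H-bonds.
    """
    pp = np.tile(DIHEDRALS["strand"], (n_residues, 1))
    bb1 = build_backbone(pp)
    atoms1 = np.concatenate([bb1[k] for k in ("N", "CA", "C", "O", "CB")])
    center = bb1["CA"].mean(axis=0)
    # strand axis ~ first principal axis of the CA trace
    ca = bb1["CA"] - center
    axis = np.linalg.svd(ca, compute_uv=True)[2][0]
    # rotate 180 deg about the normal that flips chain direction
    best = None
    for flip_axis in (np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 0.0])):
        a = flip_axis / np.linalg.norm(flip_axis)
        Rm = 2.0 * np.outer(a, a) - np.eye(3)  # rotation by pi about a
        for shift_perp in np.arange(4.0, 6.01, 0.1):
            for shift_par in np.arange(-4.0, 4.01, 0.25):
                offset = shift_perp * np.array([0.0, 1.0, 0.0]) + shift_par * axis
                bb2 = {k: (v - center) @ Rm.T + center + offset for k, v in bb1.items()}
                score = _ks_hbond_count(bb1, bb2)
                if best is None or score > best[0]:
                    best = (score, bb2)
    bb2 = best[1]
    merged = {k: np.vstack([bb1[k], bb2[k]]) for k in bb1}
    resnums = list(range(1, n_residues + 1)) + list(range(101, 101 + n_residues))
    return _assemble(merged, resnums, ["ALA"] * (2 * n_residues))


# ---------------------------------------------------------------------------
# Spec dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    name: str
    start: int
    end: int
    kind: str  # helix | strand | coil

    def __post_init__(self):
        if self.kind not in DIHEDRALS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.end < self.start:
            raise ValueError("segment end before start")


#: Toy PDZ-like architecture: 94 residues numbered 243-336 with a long
#: beta2-beta3 loop, a short alpha1 and the groove-flanking alpha2.
DEFAULT_SEGMENTS = (
    Segment("nterm", 243, 244, "coil"),
    Segment("beta1", 245, 250, "strand"),
    Segment("turn1", 251, 255, "coil"),
    Segment("beta2", 256, 263, "strand"),
    Segment("loop", 264, 277, "coil"),
    Segment("beta3", 278, 284, "strand"),
    Segment("alpha1", 285, 292, "helix"),
    Segment("turn2", 293, 297, "coil"),
    Segment("beta4", 298, 303, "strand"),
    Segment("turn3", 304, 309, "coil"),
    Segment("alpha2", 310, 322, "helix"),
    Segment("cterm", 323, 336, "coil"),
)


@dataclass
class ContactSchedule:
    """Planted contact between two single-atom selections.

    ``telegraph`` mode switches with the given on/off rates (per ns);
    ``intervals`` mode is in contact exactly over the listed (t0, t1) ns
    windows.  In-contact frames place atom B at ``contact_nm`` from atom A
    (plus Gaussian jitter), out-of-contact frames at ``apart_nm``.
    """

    pair_a: str
    pair_b: str
    mode: str = "telegraph"  # telegraph | intervals
    k_on_per_ns: float = 0.01
    k_off_per_ns: float = 0.01
    intervals: tuple = ()
    contact_nm: float = 0.3
    apart_nm: float = 2.0
    jitter_nm: float = 0.01

    def __post_init__(self):
        if self.mode not in ("telegraph", "intervals"):
            raise ValueError(f"unknown contact mode {self.mode!r}")
        if not self.contact_nm < self.apart_nm:
            raise ValueError("contact distance must be below apart distance")


@dataclass
class UnfoldingSchedule:
    region: tuple  # (first_resnum, last_resnum)
    t_start_ns: float
    t_end_ns: float

    def __post_init__(self):
        if self.t_end_ns <= self.t_start_ns:
            raise ValueError("unfolding window must have positive length")


@dataclass
class IonSchedule:
    ion_index: int          # which ion atom (0-based among the spec's ions)
    site_a: str
    site_b: str
    intervals: tuple = ()   # ((t0, t1), ...) ns, bridging inside
    jitter_nm: float = 0.01


@dataclass
class TitrationTruth:
    kd_uM: float
    ddmax_h_ppm: dict = field(default_factory=dict)   # residue -> max 1H shift
    ddmax_n_ppm: dict = field(default_factory=dict)


@dataclass
class SyntheticSpec:
    """Full description of one synthetic data set (see module docstring)."""

    seed: int = 0
    n_frames: int = 2000
    dt_ns: float = 0.5
    segments: tuple = DEFAULT_SEGMENTS
    sigma_nm: float = 0.05
    sigma_overrides: dict = field(default_factory=dict)  # residue -> sigma_nm
    tau_ns: float = 1.0
    phospho_sites: tuple = ()           # residues renamed SEP with a P atom
    n_ions: int = 0
    contact_schedules: tuple = ()
    unfolding_schedules: tuple = ()
    ion_schedules: tuple = ()
    ca_only: bool = False
    # titration block
    protein_uM: float = 100.0
    ratios: tuple = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0)
    beta: float = 10.0
    kd_scale_uM: float = 10.0
    detection_threshold: float = 0.05
    shift_noise_ppm: tuple = (0.002, 0.012)   # (1H, 15N)
    intensity_noise: float = 0.02
    titration: dict = field(default_factory=lambda: {
        "wt": TitrationTruth(1.0),
        "S280E": TitrationTruth(10.0),
        "S263E": TitrationTruth(100.0),
    })

    @property
    def total_ns(self) -> float:
        return self.n_frames * self.dt_ns

    def __post_init__(self):
        spans = sorted((s.start, s.end) for s in self.segments)
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            if s1 <= e0:
                raise ValueError("overlapping segment residue ranges")
        windows = [(s.t_start_ns, s.t_end_ns) for s in self.unfolding_schedules]
        for s in self.ion_schedules:
            windows.extend(s.intervals)
        for t0, t1 in windows:
            if t0 < 0 or t1 > self.total_ns:
                raise ValueError("schedule outside the simulated window")

    @property
    def residue_numbers(self) -> np.ndarray:
        out = []
        for seg in sorted(self.segments, key=lambda s: s.start):
            out.extend(range(seg.start, seg.end + 1))
        return np.array(out)


# ---------------------------------------------------------------------------
# Topology / trajectory generation
# ---------------------------------------------------------------------------

def _spec_dihedrals(spec: SyntheticSpec) -> np.ndarray:
    resnums = spec.residue_numbers
    pp = np.empty((len(resnums), 2))
    for seg in spec.segments:
        mask = (resnums >= seg.start) & (resnums <= seg.end)
        pp[mask] = DIHEDRALS[seg.kind]
    return pp


def build_toy_topology(spec: SyntheticSpec) -> tuple[Topology, np.ndarray]:
    """Deterministic ideal-geometry toy topology + reference coords (nm)."""
    resnums = spec.residue_numbers
    pp = _spec_dihedrals(spec)
    bb = build_backbone(pp, with_cb=not spec.ca_only)
    if spec.ca_only:
        bb = {"CA": bb["CA"]}
    resnames = ["SEP" if r in spec.phospho_sites else "ALA" for r in resnums]
    extra = {}
    if not spec.ca_only:
        for r in spec.phospho_sites:
            k = int(np.flatnonzero(resnums == r)[0])
            direction = bb["CB"][k] - bb["CA"][k]
            direction /= np.linalg.norm(direction)
            extra[r] = [("P", bb["CB"][k] + 2.5 * direction)]
    top, coords = _assemble(bb, resnums, resnames, extra_atoms=extra)
    if spec.n_ions:
        center = coords.mean(axis=0)
        ion_pos = [center + (5.0 + 0.5 * k) * np.array([1.0, 0.2 * k, 0.0])
                   for k in range(spec.n_ions)]
        top = Topology(
            np.concatenate([top.atom_names, ["NA"] * spec.n_ions]),
            np.concatenate([top.residue_numbers, 401 + np.arange(spec.n_ions)]),
            np.concatenate([top.residue_names, ["NA"] * spec.n_ions]),
            np.concatenate([top.chain_ids, ["I"] * spec.n_ions]),
            np.concatenate([top.elements, ["NA"] * spec.n_ions]),
        )
        coords = np.vstack([coords, ion_pos])
    return top, coords


def telegraph_states(rng: np.random.Generator, n_frames: int, dt_ns: float,
                     k_on_per_ns: float, k_off_per_ns: float) -> np.ndarray:
    """Sample a stationary two-state telegraph process on the frame grid.

    Continuous-time dwells are exponential with the given rates; the
    returned boolean array is the state at each frame time.  Stationary
    occupancy is k_on/(k_on+k_off); mean contact dwell is 1/k_off.
    """
    p_on = k_on_per_ns / (k_on_per_ns + k_off_per_ns)
    state = bool(rng.random() < p_on)
    states = np.empty(n_frames, dtype=bool)
    t_now, f = 0.0, 0
    while f < n_frames:
        rate = k_off_per_ns if state else k_on_per_ns
        t_next = t_now + rng.exponential(1.0 / rate)
        f_next = min(n_frames, int(np.ceil(t_next / dt_ns - 1e-12)))
        if f_next > f:
            states[f:f_next] = state
            f = f_next
        t_now = t_next
        state = not state
    return states


def _intervals_to_states(intervals, times: np.ndarray) -> np.ndarray:
    states = np.zeros(len(times), dtype=bool)
    for t0, t1 in intervals:
        states |= (times >= t0) & (times < t1)
    return states


def _single_atom(sel: str, top: Topology, what: str) -> int:
    idx = resolve_selection(sel, top)
    if len(idx) == 0:
        raise ValueError(f"{what} selection {sel!r} matches no atom")
    return int(idx[0])


def generate_trajectory(spec: SyntheticSpec) -> Trajectory:
    """Generate the spec's trajectory (see module docstring for the model)."""
    top, ref = build_toy_topology(spec)
    rng = np.random.default_rng(spec.seed)
    F, n = spec.n_frames, top.n_atoms
    times = np.arange(F) * spec.dt_ns

    # base coordinates: static reference, or per-frame rebuilt backbone
    # when an unfolding schedule morphs dihedrals
    if spec.unfolding_schedules:
        if spec.ca_only:
            raise ValueError("unfolding schedules require a full backbone")
        resnums = spec.residue_numbers
        pp0 = _spec_dihedrals(spec)
        coords = np.empty((F, n, 3))
        n_ion = spec.n_ions
        resnames = ["SEP" if r in spec.phospho_sites else "ALA" for r in resnums]
        cache: dict[tuple, np.ndarray] = {}
        for f in range(F):
            weights = tuple(
                round(float(np.clip((times[f] - s.t_start_ns)
                                    / (s.t_end_ns - s.t_start_ns), 0.0, 1.0)), 9)
                for s in spec.unfolding_schedules
            )
            if weights not in cache:
                pp = pp0.copy()
                for w, sched in zip(weights, spec.unfolding_schedules):
                    mask = (resnums >= sched.region[0]) & (resnums <= sched.region[1])
                    pp[mask] = (1 - w) * pp[mask] + w * np.asarray(DIHEDRALS["coil"])
                bb = build_backbone(pp)
                extra = {}
                for r in spec.phospho_sites:
                    k = int(np.flatnonzero(resnums == r)[0])
                    d = bb["CB"][k] - bb["CA"][k]
                    d /= np.linalg.norm(d)
                    extra[r] = [("P", bb["CB"][k] + 2.5 * d)]
                _, cache[weights] = _assemble(bb, resnums, resnames, extra_atoms=extra)
            coords[f, :n - n_ion] = cache[weights]
            if n_ion:
                coords[f, n - n_ion:] = ref[n - n_ion:]
    else:
        coords = np.broadcast_to(ref, (F, n, 3)).copy()

    # per-atom stationary sigma
    sigma_res = {int(r): spec.sigma_nm for r in spec.residue_numbers}
    sigma_res.update({int(k): float(v) for k, v in spec.sigma_overrides.items()})
    sigma_atom = np.array([sigma_res.get(int(r), spec.sigma_nm)
                           for r in top.residue_numbers])

    if np.any(sigma_atom > 0):
        a = np.exp(-spec.dt_ns / spec.tau_ns)
        innov_sd = sigma_atom[:, None] * np.sqrt(1.0 - a * a)
        eps = rng.standard_normal((F, n, 3)) * innov_sd[None, :, :]
        x0 = rng.standard_normal((n, 3)) * sigma_atom[:, None]
        noise, _ = lfilter([1.0], [1.0, -a], eps, axis=0, zi=(a * x0)[None, :, :])
        coords += noise

    # planted contacts override the pair-B atom position
    schedule_states = []
    for sched in spec.contact_schedules:
        ia = _single_atom(sched.pair_a, top, "pair_a")
        ib = _single_atom(sched.pair_b, top, "pair_b")
        if sched.mode == "telegraph":
            states = telegraph_states(rng, F, spec.dt_ns,
                                      sched.k_on_per_ns, sched.k_off_per_ns)
        else:
            states = _intervals_to_states(sched.intervals, times)
        u = ref[ib] - ref[ia]
        norm = np.linalg.norm(u)
        u = u / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        dist = np.where(states, sched.contact_nm, sched.apart_nm)
        jitter = rng.standard_normal((F, 3)) * sched.jitter_nm
        coords[:, ib, :] = coords[:, ia, :] + dist[:, None] * u + jitter
        schedule_states.append(states)

    # scripted ions
    for sched in spec.ion_schedules:
        if sched.ion_index >= spec.n_ions:
            raise ValueError("ion schedule refers to a nonexistent ion")
        ion_atom = n - spec.n_ions + sched.ion_index
        ia = _single_atom(sched.site_a, top, "site_a")
        ib = _single_atom(sched.site_b, top, "site_b")
        states = _intervals_to_states(sched.intervals, times)
        jitter = rng.standard_normal((F, 3)) * sched.jitter_nm
        mid = 0.5 * (coords[:, ia, :] + coords[:, ib, :])
        coords[states, ion_atom, :] = mid[states] + jitter[states]

    traj = Trajectory(top, times, coords)
    traj._schedule_states = schedule_states  # planted truth, for tests
    return traj


# ---------------------------------------------------------------------------
# Titrations
# ---------------------------------------------------------------------------

def bound_fraction(protein_uM: float, ligand_uM: float, kd_uM: float) -> float:
    """Exact two-state bound fraction from the quadratic binding equation."""
    if ligand_uM == 0.0:
        return 0.0
    s = protein_uM + ligand_uM + kd_uM
    return float((s - np.sqrt(s * s - 4.0 * protein_uM * ligand_uM)) / (2.0 * protein_uM))


_DEFAULT_DDMAX_H = {260: 0.18, 261: 0.15, 279: 0.12, 285: 0.10, 250: 0.0, 300: 0.0}
_DEFAULT_DDMAX_N = {260: 0.9, 261: 0.8, 279: 0.6, 285: 0.5, 250: 0.0, 300: 0.0}


def generate_titration(spec: SyntheticSpec, variant: str) -> TitrationSeries:
    """Synthetic HSQC titration peak list for one variant.

    Fast-exchange shifts (delta = f * ddmax) plus the phenomenological
    broadening law; peaks whose relative intensity falls below the
    detection threshold are dropped (broadened beyond detection).
    Deterministic for a given (seed, variant).
    """
    if variant not in spec.titration:
        raise KeyError(f"variant {variant!r} not in the titration truth table")
    truth = spec.titration[variant]
    order = sorted(spec.titration)
    rng = np.random.default_rng([spec.seed, order.index(variant)])
    ddmax_h = truth.ddmax_h_ppm or _DEFAULT_DDMAX_H
    ddmax_n = truth.ddmax_n_ppm or _DEFAULT_DDMAX_N
    residues = sorted(ddmax_h)
    base_h = {r: 8.0 + 0.005 * r for r in residues}
    base_n = {r: 105.0 + 0.1 * r for r in residues}
    i0 = 100.0
    s_exch = spec.kd_scale_uM / truth.kd_uM   # slower exchange for tighter binding
    # exchange broadening scales with each residue's shift difference:
    # residues that do not shift do not broaden
    from .nmr import csp as _csp
    w = {r: _csp(ddmax_h[r], ddmax_n[r]) for r in residues}
    w_max = max(w.values()) or 1.0
    points = []
    for ratio in spec.ratios:
        f = bound_fraction(spec.protein_uM, ratio * spec.protein_uM, truth.kd_uM)
        peaks = {}
        for r in residues:
            rel = np.exp(-spec.beta * f * (1.0 - f) * s_exch * w[r] / w_max)
            rel *= 1.0 + spec.intensity_noise * rng.standard_normal()
            if ratio > 0 and rel < spec.detection_threshold:
                continue  # broadened beyond detection
            peaks[r] = PeakRecord(
                r,
                base_h[r] + f * ddmax_h[r] + spec.shift_noise_ppm[0] * rng.standard_normal(),
                base_n[r] + f * ddmax_n[r] + spec.shift_noise_ppm[1] * rng.standard_normal(),
                max(i0 * rel, 0.0),
            )
        points.append(TitrationPoint(float(ratio), peaks))
    return TitrationSeries(variant, points)


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

def fixture_spec(seed: int = 0) -> SyntheticSpec:
    """The canonical small fixture: a wt-like and a pS263-like condition."""
    return SyntheticSpec(
        seed=seed,
        n_frames=400,
        dt_ns=2.5,           # 1000 ns total, matching the standard run length
        sigma_nm=0.03,
        phospho_sites=(263,),
        contact_schedules=(
            ContactSchedule("resid 320 and name CB", "resid 263 and name P",
                            mode="telegraph", k_on_per_ns=0.02, k_off_per_ns=0.005,
                            contact_nm=0.4, apart_nm=1.8),
            ContactSchedule("resid 290 and name CB", "resid 292 and name CB",
                            mode="intervals", intervals=((0.0, 500.0),),
                            contact_nm=0.35, apart_nm=1.6),
        ),
    )


def emit_fixture_set(outdir: str | Path, seed: int = 0,
                     spec: SyntheticSpec | None = None) -> dict:
    """Write the canonical test fixture bundle and its manifest.

    Produces a toy topology PDB, a "wt" trajectory (no planted contacts),
    a "pS263"-like trajectory with planted contact schedules, titration
    peak lists for wt/S280E/S263E, and ``manifest.json`` holding every
    planted truth.  Re-running with the same seed reproduces the manifest
    bit for bit.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec or fixture_spec(seed)

    top, ref = build_toy_topology(spec)
    write_topology(outdir / "toy.pdb", top, ref)

    wt_spec = SyntheticSpec(seed=seed + 1, n_frames=spec.n_frames, dt_ns=spec.dt_ns,
                            segments=spec.segments, sigma_nm=spec.sigma_nm,
                            phospho_sites=spec.phospho_sites)
    wt = generate_trajectory(wt_spec)
    write_trajectory(outdir / "traj_wt.pdb", wt)

    var = generate_trajectory(spec)
    write_trajectory(outdir / "traj_pS263.pdb", var)
    planted_occ = [float(np.mean(s)) for s in var._schedule_states]

    peaklists = {}
    for variant in sorted(spec.titration):
        path = outdir / f"peaks_{variant}.csv"
        write_peaklist(path, generate_titration(spec, variant))
        peaklists[variant] = path.name

    manifest = {
        "seed": seed,
        "n_frames": spec.n_frames,
        "dt_ns": spec.dt_ns,
        "sigma_nm": spec.sigma_nm,
        "expected_rmsf_nm": float(np.sqrt(3.0) * spec.sigma_nm),
        "phospho_sites": list(spec.phospho_sites),
        "contact_schedules": [asdict(s) for s in spec.contact_schedules],
        "planted_occupancy": planted_occ,
        "titration_kd_uM": {v: t.kd_uM for v, t in spec.titration.items()},
        "affinity_order": sorted(spec.titration, key=lambda v: spec.titration[v].kd_uM),
        "files": {"topology": "toy.pdb", "wt": "traj_wt.pdb",
                  "variant": "traj_pS263.pdb", "peaklists": peaklists},
    }
    manifest = json.loads(json.dumps(manifest, sort_keys=True))  # normalise tuples
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
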