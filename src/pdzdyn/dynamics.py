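"""Superposition, per-residue fluctuations and conformational clustering.

The per-residue RMSF profile (and its variant-minus-wildtype difference,
ΔRMSF) is the primary fluctuation readout: RMSF_i = sqrt(<|x_i(t) - <x_i>|^2>)
computed on an aligned trajectory.  Conformer counting uses the
neighbor-counting ("leader") clustering of Daura et al. with a pairwise-RMSD
cutoff, the standard approach for counting loop conformations in MD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .selections import AtomSelection, resolve_selection
from .trajectory import Topology, Trajectory

__all__ = [
    "SuperpositionResult",
    "RMSFProfile",
    "DeltaRMSF",
    "ClusterResult",
    "kabsch_superpose",
    "align_trajectory",
    "compute_rmsf",
    "combine_replicas",
    "delta_rmsf",
    "rmsd_series",
    "cluster_conformations",
    "convergence_check",
]

# Atomic masses for the mass-weighted per-residue RMSF option.
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974, "NA": 22.990}


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray      # (3, 3), proper (det = +1)
    translation: np.ndarray   # (3,); transformed = x @ rotation.T + translation
    rmsd_nm: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class RMSFProfile:
    residue_numbers: np.ndarray
    rmsf_nm: np.ndarray
    std_nm: np.ndarray | None = None
    n_replicas: int = 1
    selection: str = "name CA"

    def __post_init__(self):
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.rmsf_nm = np.asarray(self.rmsf_nm, dtype=float)
        if len(self.residue_numbers) != len(self.rmsf_nm):
            raise ValueError("residue grid and RMSF array differ in length")
        if np.any(self.rmsf_nm < 0):
            raise ValueError("negative RMSF")
        if (self.std_nm is not None) != (self.n_replicas >= 2):
            raise ValueError("std_nm must be present exactly when n_replicas >= 2")
        if self.std_nm is not None:
            self.std_nm = np.asarray(self.std_nm, dtype=float)
            if len(self.std_nm) != len(self.rmsf_nm) or np.any(self.std_nm < 0):
                raise ValueError("invalid std_nm")


@dataclass
class DeltaRMSF:
    """Signed per-residue difference, variant minus wild type (positive =
    increased fluctuation in the variant)."""

    residue_numbers: np.ndarray
    delta_nm: np.ndarray
    variant_label: str


@dataclass
class ClusterResult:
    frame_labels: np.ndarray   # cluster id per frame, 0 = largest cluster
    n_clusters: int
    cutoff_nm: float
    medoid_frames: np.ndarray  # leader frame per cluster


class DegenerateGeometryError(ValueError):
    """Reference points are too few or collinear for a unique superposition."""


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Optimal weighted rigid-body superposition (Kabsch, via SVD).

    Returns the proper rotation and translation minimising the weighted
    RMSD of ``mobile`` onto ``reference``.  Collinear/degenerate reference
    geometries are rejected rather than resolved by an arbitrary
    reflection-adjacent optimum.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 points, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    cm = w @ mobile
    cr = w @ reference
    M = mobile - cm
    R = reference - cr
    sv = np.linalg.svd(R * np.sqrt(w)[:, None], compute_uv=False)
    if sv[1] < 1e-10 * max(sv[0], 1e-30) or sv[0] < 1e-12:
        raise DegenerateGeometryError("reference points are (near-)collinear")
    H = (M * w[:, None]).T @ R
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    rot = Vt.T @ D @ U.T
    trans = cr - rot @ cm
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.sum(w * np.sum((moved - reference) ** 2, axis=1))))
    return SuperpositionResult(rot, trans, rmsd)


def _fit_indices(traj: Trajectory, fit_selection: AtomSelection | str) -> np.ndarray:
    idx = resolve_selection(fit_selection, traj.topology)
    if len(idx) < 3:
        raise DegenerateGeometryError(
            f"fit selection {fit_selection!s} resolves to {len(idx)} atoms; need >= 3"
        )
    return idx


def align_trajectory(
    traj: Trajectory,
    reference: int | np.ndarray = 0,
    fit_selection: AtomSelection | str = "name CA",
) -> Trajectory:
    """Superpose every frame onto a reference on the fit atoms.

    ``reference`` is a frame index or an external (n_atoms, 3) coordinate
    array.  All atoms are co-transformed.  The whole batch of per-frame
    Kabsch problems is solved with one stacked SVD.
    """
    idx = _fit_indices(traj, fit_selection)
    if isinstance(reference, (int, np.integer)):
        ref = traj.coords_nm[int(reference), idx]
    else:
        reference = np.asarray(reference, dtype=float)
        ref = reference[idx] if reference.shape[0] == traj.n_atoms else reference
        if ref.shape != (len(idx), 3):
            raise ValueError("external reference must cover all atoms or exactly the fit atoms")
    n = len(idx)
    cr = ref.mean(axis=0)
    R = ref - cr
    sv = np.linalg.svd(R, compute_uv=False)
    if sv[1] < 1e-10 * max(sv[0], 1e-30):
        raise DegenerateGeometryError("reference fit atoms are (near-)collinear")
    mob = traj.coords_nm[:, idx, :]                     # (F, n, 3)
    cm = mob.mean(axis=1)                               # (F, 3)
    M = mob - cm[:, None, :]
    H = np.einsum("fni,nj->fij", M, R) / n              # (F, 3, 3)
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("fij,fjk->fik", np.transpose(Vt, (0, 2, 1)),
                                  np.transpose(U, (0, 2, 1))))
    D = np.repeat(np.eye(3)[None, :, :], traj.n_frames, axis=0)
    D[:, 2, 2] = np.sign(det)
    rot = np.einsum("fij,fjk,fkl->fil", np.transpose(Vt, (0, 2, 1)), D,
                    np.transpose(U, (0, 2, 1)))
    out = np.einsum("fij,fnj->fni", rot, traj.coords_nm - cm[:, None, :]) + cr
    return Trajectory(traj.topology, traj.times_ns.copy(), out,
                      None if traj.box_nm is None else traj.box_nm.copy(), aligned=True)


def _per_atom_rmsf(coords: np.ndarray) -> np.ndarray:
    mean = coords.mean(axis=0)
    return np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))


def compute_rmsf(
    traj: Trajectory,
    selection: AtomSelection | str = "name CA",
    *,
    mode: str = "calpha",
    allow_unaligned: bool = False,
) -> RMSFProfile:
    """Per-residue RMSF of an aligned trajectory.

    ``mode="calpha"`` (default) reports each residue's Cα fluctuation —
    the field convention for per-residue profiles; ``mode="heavy"`` reports
    a mass-weighted RMS over the residue's selected heavy atoms.
    """
    if not traj.aligned and not allow_unaligned:
        raise ValueError("trajectory is not aligned; run align_trajectory first "
                         "or pass allow_unaligned=True")
    if mode not in ("calpha", "heavy"):
        raise ValueError(f"unknown mode {mode!r}")
    top = traj.topology
    if mode == "calpha":
        sel = selection if str(selection) != "name CA" else "name CA"
        idx = resolve_selection(sel, top)
        if len(idx) == 0:
            raise ValueError("selection resolves to zero atoms")
        rmsf = _per_atom_rmsf(traj.coords_nm[:, idx, :])
        resnums = top.residue_numbers[idx]
        return RMSFProfile(resnums, rmsf, selection=str(sel))
    idx = resolve_selection(selection, top)
    idx = idx[top.elements[idx] != "H"]
    if len(idx) == 0:
        raise ValueError("selection resolves to zero heavy atoms")
    per_atom = _per_atom_rmsf(traj.coords_nm[:, idx, :])
    masses = np.array([_MASSES.get(str(e).upper(), 12.0) for e in top.elements[idx]])
    resnums_all = top.residue_numbers[idx]
    grid = np.unique(resnums_all)
    rmsf = np.empty(len(grid))
    for k, r in enumerate(grid):
        m = resnums_all == r
        rmsf[k] = np.sqrt(np.sum(masses[m] * per_atom[m] ** 2) / masses[m].sum())
    return RMSFProfile(grid, rmsf, selection=str(selection))


def combine_replicas(profiles: list[RMSFProfile]) -> RMSFProfile:
    """Element-wise mean and sample (n-1) standard deviation across replicas."""
    if len(profiles) < 2:
        raise ValueError("need >= 2 replica profiles")
    grid = profiles[0].residue_numbers
    for p in profiles[1:]:
        if not np.array_equal(p.residue_numbers, grid):
            raise ValueError("replica residue grids differ")
    stack = np.vstack([p.rmsf_nm for p in profiles])
    return RMSFProfile(
        grid.copy(),
        stack.mean(axis=0),
        std_nm=stack.std(axis=0, ddof=1),
        n_replicas=len(profiles),
        selection=profiles[0].selection,
    )


def delta_rmsf(variant: RMSFProfile, wt: RMSFProfile, variant_label: str = "variant") -> DeltaRMSF:
    """Variant minus wild type on the common residue grid."""
    common = np.intersect1d(variant.residue_numbers, wt.residue_numbers)
    if len(common) == 0:
        raise ValueError("profiles share no residues")
    iv = np.searchsorted(variant.residue_numbers, common)
    iw = np.searchsorted(wt.residue_numbers, common)
    return DeltaRMSF(common, variant.rmsf_nm[iv] - wt.rmsf_nm[iw], variant_label)


def rmsd_series(
    traj: Trajectory,
    reference: int | np.ndarray = 0,
    selection: AtomSelection | str = "name CA",
    *,
    pairwise_fit: bool = False,
) -> np.ndarray:
    """Per-frame RMSD to a reference on the selected atoms.

    With ``pairwise_fit`` each frame is optimally superposed onto the
    reference on the selection before the RMSD is taken; otherwise the
    trajectory is assumed already aligned and the RMSD is direct.
    """
    idx = resolve_selection(selection, traj.topology)
    if len(idx) == 0:
        raise ValueError("selection resolves to zero atoms")
    if isinstance(reference, (int, np.integer)):
        ref = traj.coords_nm[int(reference), idx]
    else:
        reference = np.asarray(reference, dtype=float)
        ref = reference[idx] if reference.shape[0] == traj.n_atoms else reference
    if pairwise_fit:
        out = np.empty(traj.n_frames)
        for f in range(traj.n_frames):
            out[f] = kabsch_superpose(traj.coords_nm[f, idx], ref).rmsd_nm
        return out
    diff = traj.coords_nm[:, idx, :] - ref
    return np.sqrt(np.mean(np.sum(diff ** 2, axis=2), axis=1))


def _pairwise_rmsd_matrix(coords: np.ndarray, pairwise_fit: bool) -> np.ndarray:
    F = coords.shape[0]
    mat = np.zeros((F, F))
    if pairwise_fit:
        for i in range(F):
            for j in range(i + 1, F):
                mat[i, j] = mat[j, i] = kabsch_superpose(coords[j], coords[i]).rmsd_nm
        return mat
    # direct RMSD on already-aligned frames, chunked to bound memory
    flat = coords.reshape(F, -1)
    m = coords.shape[1]
    chunk = max(1, int(2e7 / max(flat.shape[1], 1)))
    for start in range(0, F, chunk):
        block = flat[start:start + chunk, None, :] - flat[None, :, :]
        sq = (block.reshape(block.shape[0], F, m, 3) ** 2).sum(axis=3)
        mat[start:start + chunk] = np.sqrt(sq.mean(axis=2))
    return mat


def cluster_conformations(
    traj: Trajectory,
    selection: AtomSelection | str,
    cutoff_nm: float = 0.15,
    *,
    pairwise_fit: bool = False,
) -> ClusterResult:
    """Daura neighbor-counting clustering on pairwise RMSD.

    Iteratively the unassigned frame with the most unassigned neighbors
    within ``cutoff_nm`` (ties broken by lowest frame index) becomes a
    cluster leader; it and its neighbors form the cluster and are removed.
    Clusters are finally relabelled by descending size (ties by leader
    frame index), so label 0 is always the largest cluster.
    """
    if traj.n_frames < 1:
        raise ValueError("empty trajectory")
    idx = resolve_selection(selection, traj.topology)
    if len(idx) == 0:
        raise ValueError("selection resolves to zero atoms")
    mat = _pairwise_rmsd_matrix(traj.coords_nm[:, idx, :], pairwise_fit)
    F = mat.shape[0]
    neighbor = mat <= cutoff_nm
    unassigned = np.ones(F, dtype=bool)
    labels = np.full(F, -1)
    leaders, sizes = [], []
    cid = 0
    while unassigned.any():
        counts = (neighbor & unassigned).sum(axis=1)
        counts[~unassigned] = -1
        leader = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbor[leader] & unassigned)
        labels[members] = cid
        unassigned[members] = False
        leaders.append(leader)
        sizes.append(len(members))
        cid += 1
    order = sorted(range(cid), key=lambda c: (-sizes[c], leaders[c]))
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[l] for l in labels])
    medoids = np.array([leaders[c] for c in order])
    return ClusterResult(labels, cid, float(cutoff_nm), medoids)


def convergence_check(replica_profiles: list[RMSFProfile]) -> dict:
    """Replica-to-replica agreement of RMSF profiles.

    Returns the maximum per-residue absolute difference and the minimum
    Pearson correlation over all replica pairs.
    """
    if len(replica_profiles) < 2:
        raise ValueError("need >= 2 replicas")
    grid = replica_profiles[0].residue_numbers
    for p in replica_profiles[1:]:
        if not np.array_equal(p.residue_numbers, grid):
            raise ValueError("replica residue grids differ")
    max_diff, min_r = 0.0, 1.0
    for i in range(len(replica_profiles)):
        for j in range(i + 1, len(replica_profiles)):
            a, b = replica_profiles[i].rmsf_nm, replica_profiles[j].rmsf_nm
            max_diff = max(max_diff, float(np.max(np.abs(a - b))))
            if np.ptp(a) == 0 and np.ptp(b) == 0:
                r = 1.0
            else:
                r = float(stats.pearsonr(a, b).statistic)
            min_r = min(min_r, r)
    return {"max_abs_diff_nm": max_diff, "pearson_r": min_r}
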