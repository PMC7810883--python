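"""Topology and trajectory containers plus readers/writers.

Internal units are nm and ns throughout the package (the thresholds this
pipeline exists for — a 1.0 nm contact cutoff, a 20 ns minimum dwell — are
stated in those units).  PDB files are read and written in Angstrom and
converted at the boundary; XTC is natively nm.  Angstrom/ps input for the
text formats is accepted behind an explicit ``units``/``time_unit`` flag.

Three trajectory formats are supported:

* multi-model PDB (plain text; per-run times carried in a
  ``REMARK 250 PDZDYN TIMES_NS`` header line, since frame spacing is
  constant by invariant),
* XTC (binary, via the MDAnalysis xdrlib bindings; little-endian XDR as
  defined by the GROMACS format),
* a long-format CSV fallback (``time_ns,atom_index,x_nm,y_nm,z_nm``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = [
    "Topology",
    "Trajectory",
    "read_topology",
    "write_topology",
    "read_trajectory",
    "write_trajectory",
]

#: Relative tolerance on frame-spacing constancy.
FRAME_SPACING_RTOL = 1e-3

_TIMES_REMARK = "REMARK 250 PDZDYN TIMES_NS"


class TopologyError(ValueError):
    """Raised for malformed or inconsistent topologies."""


@dataclass(frozen=True)
class Topology:
    """Ordered atom table of one structure.

    Residue numbering is the author/PDB numbering and is never remapped
    (the hDVL3 PDZ construct runs 243-338; every statement about residues
    S263, S280, R320, ... is in that numbering).  Phosphoserine is the
    three-letter code ``SEP``.
    """

    atom_names: np.ndarray
    residue_numbers: np.ndarray
    residue_names: np.ndarray
    chain_ids: np.ndarray
    elements: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "atom_names", np.asarray(self.atom_names, dtype=object))
        object.__setattr__(self, "residue_numbers", np.asarray(self.residue_numbers, dtype=int))
        object.__setattr__(self, "residue_names", np.asarray(self.residue_names, dtype=object))
        object.__setattr__(self, "chain_ids", np.asarray(self.chain_ids, dtype=object))
        object.__setattr__(self, "elements", np.asarray(self.elements, dtype=object))
        n = len(self.atom_names)
        for name in ("residue_numbers", "residue_names", "chain_ids", "elements"):
            if len(getattr(self, name)) != n:
                raise TopologyError(f"field {name!r} has length {len(getattr(self, name))}, expected {n}")
        if n == 0:
            raise TopologyError("topology contains zero atoms")
        seen = {}
        for i in range(n):
            key = (int(self.residue_numbers[i]), str(self.atom_names[i]), str(self.chain_ids[i]))
            if key in seen:
                raise TopologyError(
                    f"duplicate atom record: residue {key[0]} atom {key[1]!r} chain {key[2]!r} "
                    f"(atom indices {seen[key]} and {i})"
                )
            seen[key] = i
        # residue numbers non-decreasing within each chain
        for chain in np.unique(self.chain_ids.astype(str)):
            resnums = self.residue_numbers[self.chain_ids == chain]
            if np.any(np.diff(resnums) < 0):
                raise TopologyError(f"residue numbers decrease within chain {chain!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def residue_ids(self) -> list[tuple[str, int]]:
        """Unique (chain, residue_number) pairs in order of first appearance."""
        out, seen = [], set()
        for c, r in zip(self.chain_ids, self.residue_numbers):
            key = (str(c), int(r))
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def atom_index(self, residue_number: int, atom_name: str, chain_id: str | None = None) -> int:
        mask = (self.residue_numbers == residue_number) & (self.atom_names == atom_name)
        if chain_id is not None:
            mask &= self.chain_ids == chain_id
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise KeyError(f"no atom {atom_name!r} in residue {residue_number}")
        return int(idx[0])

    def __eq__(self, other) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, f), getattr(other, f))
            for f in ("atom_names", "residue_numbers", "residue_names", "chain_ids", "elements")
        )


@dataclass
class Trajectory:
    """Frames x atoms x xyz coordinates (nm) with times (ns).

    ``aligned`` is set by :func:`pdzdyn.dynamics.align_trajectory`; RMSF
    computation refuses unaligned input unless explicitly overridden.
    """

    topology: Topology
    times_ns: np.ndarray
    coords_nm: np.ndarray
    box_nm: np.ndarray | None = None
    aligned: bool = field(default=False, compare=False)

    def __post_init__(self):
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.coords_nm = np.asarray(self.coords_nm, dtype=float)
        if self.coords_nm.ndim != 3 or self.coords_nm.shape[2] != 3:
            raise ValueError(f"coords must be (frames, atoms, 3), got {self.coords_nm.shape}")
        if self.coords_nm.shape[0] != len(self.times_ns):
            raise ValueError("number of frames differs between times and coordinates")
        if self.coords_nm.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"trajectory has {self.coords_nm.shape[1]} atoms, topology has {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coords_nm)):
            raise ValueError("non-finite coordinates")
        if len(self.times_ns) > 1:
            dt = np.diff(self.times_ns)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if np.ptp(dt) > FRAME_SPACING_RTOL * np.mean(dt):
                raise ValueError("frame spacing is not constant within tolerance")
        if self.box_nm is not None:
            self.box_nm = np.asarray(self.box_nm, dtype=float)
            if self.box_nm.shape != (len(self.times_ns), 3):
                raise ValueError("box must be (frames, 3)")

    @property
    def n_frames(self) -> int:
        return len(self.times_ns)

    @property
    def n_atoms(self) -> int:
        return self.coords_nm.shape[1]

    @property
    def dt_ns(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.times_ns[1] - self.times_ns[0])

    def slice_frames(self, sl: slice) -> "Trajectory":
        return Trajectory(
            self.topology,
            self.times_ns[sl],
            self.coords_nm[sl],
            None if self.box_nm is None else self.box_nm[sl],
            aligned=self.aligned,
        )


# ---------------------------------------------------------------------------
# PDB topology I/O (biotite does the format work)
# ---------------------------------------------------------------------------

def _topology_from_atom_array(arr: struc.AtomArray) -> Topology:
    if arr.array_length() == 0:
        raise TopologyError("PDB file contains zero atoms")
    if np.any(arr.ins_code != ""):
        bad = int(np.flatnonzero(arr.ins_code != "")[0])
        raise TopologyError(
            f"insertion codes are not supported (first at residue {int(arr.res_id[bad])}"
            f"{arr.ins_code[bad]})"
        )
    return Topology(
        atom_names=arr.atom_name.astype(object),
        residue_numbers=arr.res_id.astype(int),
        residue_names=arr.res_name.astype(object),
        chain_ids=arr.chain_id.astype(object),
        elements=arr.element.astype(object),
    )


def read_topology(path: str | Path) -> tuple[Topology, np.ndarray]:
    """Read the first MODEL of a PDB file.

    Returns the :class:`Topology` and the coordinates of that model in nm.
    All ATOM and HETATM records are kept (SEP phosphoserines included);
    alternate locations other than blank/"A" are dropped with a warning;
    insertion codes are a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pdb_file = pdb.PDBFile.read(str(path))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        arr = pdb_file.get_structure(model=1, altloc="first")
    top = _topology_from_atom_array(arr)
    return top, arr.coord * 0.1  # A -> nm


def _atom_array_from(top: Topology, coords_nm: np.ndarray) -> struc.AtomArray:
    n = top.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords_nm, dtype=np.float32) * 10.0  # nm -> A
    arr.atom_name = top.atom_names.astype("U6")
    arr.res_id = top.residue_numbers
    arr.res_name = top.residue_names.astype("U5")
    arr.chain_id = top.chain_ids.astype("U4")
    arr.element = top.elements.astype("U2")
    arr.hetero = np.isin(arr.res_name, ("NA", "CL", "SOD", "HOH"))
    return arr


def write_topology(path: str | Path, top: Topology, coords_nm: np.ndarray) -> None:
    """Write a single-model PDB file (coordinates given in nm)."""
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(_atom_array_from(top, coords_nm))
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------

def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    """Write a trajectory; format chosen by extension (.pdb, .xtc, .csv)."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".pdb":
        _write_pdb_trajectory(path, traj)
    elif ext == ".xtc":
        _write_xtc(path, traj)
    elif ext == ".csv":
        _write_csv_trajectory(path, traj)
    else:
        raise ValueError(f"unsupported trajectory format {ext!r} (use .pdb, .xtc or .csv)")


def read_trajectory(
    path: str | Path,
    topology: Topology,
    *,
    units: str = "nm",
    time_unit: str = "ns",
    dt_ns: float | None = None,
) -> Trajectory:
    """Read a trajectory; format chosen by extension.

    ``units``/``time_unit`` apply to the text formats only ("angstrom" input
    is scaled by 0.1 exactly, "ps" by 1e-3); XTC is natively nm/ps and PDB
    coordinates are Angstrom by definition of the format.  ``dt_ns`` supplies
    frame times for multi-model PDBs that lack the times header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ext = path.suffix.lower()
    if ext == ".pdb":
        traj = _read_pdb_trajectory(path, topology, dt_ns=dt_ns)
    elif ext == ".xtc":
        traj = _read_xtc(path, topology)
    elif ext == ".csv":
        traj = _read_csv_trajectory(path, topology, units=units, time_unit=time_unit)
    else:
        raise ValueError(f"unsupported trajectory format {ext!r}")
    return traj


def _write_pdb_trajectory(path: Path, traj: Trajectory) -> None:
    n = traj.topology.n_atoms
    stack = struc.AtomArrayStack(traj.n_frames, n)
    template = _atom_array_from(traj.topology, traj.coords_nm[0])
    for cat in ("atom_name", "res_id", "res_name", "chain_id", "element", "hetero"):
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = np.asarray(traj.coords_nm, dtype=np.float32) * 10.0
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    t0 = float(traj.times_ns[0])
    dt = traj.dt_ns
    pdb_file.lines = [f"{_TIMES_REMARK} T0={t0:.9g} DT={dt:.9g} N={traj.n_frames}"] + pdb_file.lines
    pdb_file.write(str(path))


def _read_pdb_trajectory(path: Path, topology: Topology, dt_ns: float | None) -> Trajectory:
    pdb_file = pdb.PDBFile.read(str(path))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stack = pdb_file.get_structure(altloc="first")
    if isinstance(stack, struc.AtomArray):
        coords = stack.coord[None, :, :]
    else:
        coords = stack.coord
    if coords.shape[1] != topology.n_atoms:
        raise ValueError(
            f"frame 0 has {coords.shape[1]} atoms, topology has {topology.n_atoms}"
        )
    t0, dt = 0.0, dt_ns
    for line in pdb_file.lines:
        if line.startswith(_TIMES_REMARK):
            fields = dict(tok.split("=") for tok in line[len(_TIMES_REMARK):].split())
            t0, dt = float(fields["T0"]), float(fields["DT"])
            break
    if dt is None:
        dt = 1.0
    n = coords.shape[0]
    times = t0 + dt * np.arange(n) if n > 1 else np.array([t0])
    return Trajectory(topology, times, coords.astype(float) * 0.1)


def _write_xtc(path: Path, traj: Trajectory) -> None:
    from MDAnalysis.lib.formats.libmdaxdr import XTCFile

    with XTCFile(str(path), "w") as f:
        for i in range(traj.n_frames):
            if traj.box_nm is not None:
                box = np.diag(traj.box_nm[i]).astype(np.float32)
            else:
                box = np.zeros((3, 3), dtype=np.float32)
            f.write(
                np.asarray(traj.coords_nm[i], dtype=np.float32),
                box,
                i,
                float(traj.times_ns[i]) * 1000.0,  # ns -> ps
                1000.0,
            )


def _read_xtc(path: Path, topology: Topology) -> Trajectory:
    from MDAnalysis.lib.formats.libmdaxdr import XTCFile

    coords, times, boxes = [], [], []
    with XTCFile(str(path)) as f:
        while True:
            try:
                frame = f.read()
            except (StopIteration, IOError, RuntimeError):
                break
            coords.append(np.array(frame.x, dtype=float))
            times.append(float(frame.time) * 1e-3)  # ps -> ns
            boxes.append(np.diag(np.array(frame.box, dtype=float)))
    coords = np.array(coords)
    for i, c in enumerate(coords):
        if c.shape[0] != topology.n_atoms:
            raise ValueError(f"frame {i} has {c.shape[0]} atoms, topology has {topology.n_atoms}")
    times = np.array(times)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("non-monotonic times in XTC file")
    boxes = np.array(boxes)
    box = boxes if np.any(boxes > 0) else None
    return Trajectory(topology, times, coords, box)


def _write_csv_trajectory(path: Path, traj: Trajectory) -> None:
    F, n = traj.n_frames, traj.n_atoms
    df = pd.DataFrame(
        {
            "time_ns": np.repeat(traj.times_ns, n),
            "atom_index": np.tile(np.arange(n), F),
            "x_nm": traj.coords_nm[:, :, 0].ravel(),
            "y_nm": traj.coords_nm[:, :, 1].ravel(),
            "z_nm": traj.coords_nm[:, :, 2].ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def _read_csv_trajectory(path: Path, topology: Topology, units: str, time_unit: str) -> Trajectory:
    df = pd.read_csv(path)
    scale = {"nm": 1.0, "angstrom": 0.1, "A": 0.1}[units]
    tscale = {"ns": 1.0, "ps": 1e-3}[time_unit]
    times = np.sort(df["time_ns"].unique()) * tscale
    n = topology.n_atoms
    coords = np.empty((len(times), n, 3))
    for f, t in enumerate(times):
        sub = df[df["time_ns"] * tscale == t].sort_values("atom_index")
        if len(sub) != n:
            raise ValueError(f"frame {f} has {len(sub)} atoms, topology has {n}")
        coords[f] = sub[["x_nm", "y_nm", "z_nm"]].to_numpy() * scale
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("non-monotonic times")
    return Trajectory(topology, times, coords)
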