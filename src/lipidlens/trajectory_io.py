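"""Trajectory and selection I/O.

All analysis modules consume the in-memory :class:`Trajectory` /
:class:`Topology` / :class:`SelectionSet` containers defined here.  Readers
normalise on ingest to the package's fixed internal units — lengths in
ångström, times in nanoseconds — so the lateral diffusion coefficients come
out directly in Å²/ns.  Standard MD formats (GRO/PDB topology, XTC/DCD
coordinates) are handled by MDAnalysis; a plain-text columnar format with an
explicit unit header is provided for synthetic data and fixtures.

Only orthorhombic boxes are supported: every analysis here is lateral (XY)
and the bilayer systems of interest use standard rectangular boxes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Trajectory",
    "Topology",
    "SelectionSet",
    "read_trajectory",
    "write_columnar",
    "read_columnar",
    "unwrap",
    "build_selection",
    "TrajectoryError",
    "SelectionError",
]

#: conversion factors into internal units (Å, ns)
_LENGTH_TO_ANGSTROM = {"angstrom": 1.0, "A": 1.0, "nm": 10.0}
_TIME_TO_NS = {"ns": 1.0, "ps": 1e-3, "us": 1e3, "fs": 1e-6}


class TrajectoryError(ValueError):
    """Malformed or unsupported trajectory input."""


class SelectionError(ValueError):
    """Selection specification could not be resolved against the topology."""


@dataclass
class Trajectory:
    """Ordered frames of coordinates in an orthorhombic periodic box.

    Attributes
    ----------
    times : (n_frames,) float array, ns
    box : (n_frames, 3) float array, Å — orthorhombic edge lengths
    coords : (n_frames, n_particles, 3) float array, Å — wrapped coordinates
    unwrapped : optional parallel array of unwrapped coordinates
    """

    times: np.ndarray
    box: np.ndarray
    coords: np.ndarray
    unwrapped: np.ndarray | None = None
    length_unit: str = "angstrom"
    time_unit: str = "ns"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError("coords must have shape (n_frames, n_particles, 3)")
        n = self.n_frames
        if self.box.shape == (3,):
            self.box = np.tile(self.box, (n, 1))
        if self.box.shape != (n, 3):
            raise TrajectoryError("box must have shape (n_frames, 3)")
        if self.times.shape != (n,):
            raise TrajectoryError("times must have shape (n_frames,)")
        if n >= 2 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryError("coordinates contain non-finite values")
        if not np.all(self.box > 0):
            raise TrajectoryError("box edges must be positive")
        if self.unwrapped is not None:
            self.unwrapped = np.asarray(self.unwrapped, dtype=float)
            if self.unwrapped.shape != self.coords.shape:
                raise TrajectoryError("unwrapped must match coords shape")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coords.shape[1]


@dataclass
class Topology:
    """Per-particle annotation: atom/bead names, residues, molecules."""

    atom_names: np.ndarray
    residue_ids: np.ndarray
    residue_names: np.ndarray
    molecule_ids: np.ndarray

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        n = len(self.atom_names)
        for arr in (self.residue_ids, self.residue_names, self.molecule_ids):
            if len(arr) != n:
                raise ValueError("all topology arrays must have equal length")

    @property
    def n_particles(self) -> int:
        return len(self.atom_names)


@dataclass
class SelectionSet:
    """Named index groups with analysis roles.

    ``roles`` maps a role name (``"protein"``, ``"tg_glycerol"``,
    ``"tg_beads"``) to the name of a group in ``groups``.  Molecule identity
    for TG comes from the topology's molecule map, so a multi-chain CG TG
    molecule (three ester chains of Na/C1.../C3 beads) is still one molecule.
    """

    groups: dict[str, np.ndarray]
    topology: Topology
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.topology.n_particles
        for name, idx in self.groups.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise SelectionError(f"group {name!r} has out-of-range indices")
            self.groups[name] = idx
        for role, gname in self.roles.items():
            if gname not in self.groups:
                raise SelectionError(f"role {role!r} points at unknown group {gname!r}")

    def role_indices(self, role: str) -> np.ndarray:
        if role not in self.roles:
            raise SelectionError(f"no group assigned to role {role!r}")
        return self.groups[self.roles[role]]

    def tg_molecules(self) -> np.ndarray:
        """Sorted molecule IDs of the TG glycerol group."""
        gly = self.role_indices("tg_glycerol")
        return np.unique(self.topology.molecule_ids[gly])

    def glycerol_indices(self, molecule_id: int) -> np.ndarray:
        gly = self.role_indices("tg_glycerol")
        sub = gly[self.topology.molecule_ids[gly] == molecule_id]
        if sub.size == 0:
            raise SelectionError(f"molecule {molecule_id} has no glycerol bead")
        return sub


# ---------------------------------------------------------------------------
# columnar text format
# ---------------------------------------------------------------------------

_COLUMNAR_MAGIC = "# lipidlens trajectory v1"


def write_columnar(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as plain text with an explicit unit header."""
    path = Path(path)
    has_unwrapped = traj.unwrapped is not None
    with open(path, "w") as fh:
        fh.write(f"{_COLUMNAR_MAGIC}\n")
        fh.write(f"# length_unit {traj.length_unit}\n")
        fh.write(f"# time_unit {traj.time_unit}\n")
        fh.write(f"# n_particles {traj.n_particles}\n")
        fh.write(f"# n_frames {traj.n_frames}\n")
        fh.write(f"# has_unwrapped {int(has_unwrapped)}\n")
        for f in range(traj.n_frames):
            bx, by, bz = traj.box[f]
            fh.write(f"frame {traj.times[f]:.9g} {bx:.9g} {by:.9g} {bz:.9g}\n")
            block = traj.coords[f]
            if has_unwrapped:
                block = np.hstack([block, traj.unwrapped[f]])
            np.savetxt(fh, block, fmt="%.6f")


def read_columnar(path: str | Path) -> Trajectory:
    """Read the package's columnar text format.

    A truncated file raises :class:`TrajectoryError` naming the last frame
    that parsed completely.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _COLUMNAR_MAGIC:
            raise TrajectoryError(f"{path} is not a lipidlens columnar trajectory")
        header: dict[str, str] = {}
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, val = line[1:].strip().partition(" ")
            header[key] = val
            pos = fh.tell()
        for req in ("length_unit", "time_unit", "n_particles", "n_frames"):
            if req not in header:
                raise TrajectoryError(f"columnar header missing {req!r} in {path}")
        n_particles = int(header["n_particles"])
        n_frames = int(header["n_frames"])
        has_unwrapped = bool(int(header.get("has_unwrapped", "0")))
        ncols = 6 if has_unwrapped else 3

        times, boxes, frames, unwrapped = [], [], [], []
        for fidx in range(n_frames):
            line = fh.readline().split()
            if len(line) != 5 or line[0] != "frame":
                raise TrajectoryError(
                    f"truncated trajectory {path}: last good frame is "
                    f"{fidx - 1} of {n_frames}"
                )
            block = np.empty((n_particles, ncols))
            for p in range(n_particles):
                row = fh.readline().split()
                if len(row) != ncols:
                    raise TrajectoryError(
                        f"truncated trajectory {path}: last good frame is "
                        f"{fidx - 1} of {n_frames}"
                    )
                block[p] = [float(x) for x in row]
            times.append(float(line[1]))
            boxes.append([float(x) for x in line[2:5]])
            frames.append(block[:, :3])
            if has_unwrapped:
                unwrapped.append(block[:, 3:])

    lscale = _LENGTH_TO_ANGSTROM[header["length_unit"]]
    tscale = _TIME_TO_NS[header["time_unit"]]
    return Trajectory(
        times=np.array(times) * tscale,
        box=np.array(boxes) * lscale,
        coords=np.array(frames) * lscale,
        unwrapped=np.array(unwrapped) * lscale if has_unwrapped else None,
    )


# ---------------------------------------------------------------------------
# standard MD formats via MDAnalysis
# ---------------------------------------------------------------------------


def _topology_from_universe(u) -> Topology:
    atoms = u.atoms
    try:
        mol_ids = atoms.molnums
    except Exception:
        # fall back to residue index as molecule identity
        mol_ids = atoms.resindices
    return Topology(
        atom_names=np.array(atoms.names, dtype=object),
        residue_ids=np.array(atoms.resids, dtype=int),
        residue_names=np.array(atoms.resnames, dtype=object),
        molecule_ids=np.array(mol_ids, dtype=int),
    )


def read_trajectory(
    topology_path: str | Path,
    coords_path: str | Path | None = None,
    units: dict[str, str] | None = None,
) -> tuple[Trajectory, Topology | None]:
    """Read a trajectory, converting to internal units (Å, ns).

    GRO/PDB topologies with XTC/DCD coordinates go through MDAnalysis, whose
    native units (Å, ps) are converted here.  A ``.traj.txt`` columnar file
    may be passed as the sole path; its unit header is authoritative and
    missing unit metadata is a hard error — there is no silent default.
    """
    topology_path = Path(topology_path)
    if topology_path.suffix in (".txt", ".dat") or str(topology_path).endswith(
        ".traj.txt"
    ):
        traj = read_columnar(topology_path)
        return traj, None

    import MDAnalysis as mda

    if coords_path is None:
        u = mda.Universe(str(topology_path))
    else:
        u = mda.Universe(str(topology_path), str(coords_path))
    top = _topology_from_universe(u)

    times, boxes, coords = [], [], []
    for ts in u.trajectory:
        dims = ts.dimensions
        if dims is None or np.any(dims[:3] <= 0):
            raise TrajectoryError("frame without a valid box")
        if not np.allclose(dims[3:6], 90.0, atol=1e-3):
            raise TrajectoryError(
                "triclinic boxes are not supported; all analyses here are "
                "lateral and assume an orthorhombic box"
            )
        times.append(ts.time * _TIME_TO_NS["ps"])  # MDAnalysis time is ps
        boxes.append(dims[:3].copy())
        coords.append(ts.positions.copy())

    times = np.asarray(times)
    if len(times) > 1 and np.all(times == times[0]):
        # formats like multi-model GRO carry no time; synthesise frame index
        times = np.arange(len(times), dtype=float)
    traj = Trajectory(times=times, box=np.array(boxes), coords=np.array(coords))
    return traj, top


def write_gro_xtc(
    traj: Trajectory, top: Topology, gro_path: str | Path, xtc_path: str | Path
) -> None:
    """Export to GRO (first frame) + XTC via MDAnalysis."""
    import MDAnalysis as mda

    n = traj.n_particles
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n), trajectory=True)
    u.add_TopologyAttr("names", list(top.atom_names))
    u.add_TopologyAttr("resnames", list(top.residue_names[: n]))
    u.add_TopologyAttr("resids", list(top.residue_ids[: n]))
    u.dimensions = [*traj.box[0], 90, 90, 90]
    u.atoms.positions = traj.coords[0]
    u.atoms.write(str(gro_path))
    with mda.Writer(str(xtc_path), n) as w:
        for f in range(traj.n_frames):
            u.dimensions = [*traj.box[f], 90, 90, 90]
            u.atoms.positions = traj.coords[f]
            u.trajectory.ts.time = traj.times[f] / _TIME_TO_NS["ps"]
            w.write(u.atoms)


# ---------------------------------------------------------------------------
# unwrapping
# ---------------------------------------------------------------------------


def unwrap(traj: Trajectory) -> Trajectory:
    """Accumulate minimum-image displacements into continuous coordinates.

    The wrapped view is preserved; MSD analysis must consume the unwrapped
    coordinates because wrapping destroys displacement statistics.  Idempotent:
    unwrapping a trajectory whose particles never cross a boundary returns the
    same coordinates.
    """
    coords = traj.coords
    box = traj.box[:, None, :]
    disp = np.diff(coords, axis=0)
    disp -= box[1:] * np.round(disp / box[1:])
    if disp.size and np.any(np.abs(disp) > 0.45 * box[1:]):
        warnings.warn(
            "frame-to-frame displacements approach half the box edge; "
            "sampling may be too sparse to unwrap reliably",
            stacklevel=2,
        )
    unwrapped = np.concatenate(
        [coords[:1], coords[:1] + np.cumsum(disp, axis=0)], axis=0
    )
    return Trajectory(
        times=traj.times,
        box=traj.box,
        coords=traj.coords,
        unwrapped=unwrapped,
        length_unit=traj.length_unit,
        time_unit=traj.time_unit,
    )


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

_RESNAME_3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _parse_residue_token(token: str) -> tuple[str, int]:
    """Parse ``"Ser61"`` / ``"SER:61"`` into (resname, resid)."""
    if ":" in token:
        name, _, num = token.partition(":")
        return name.upper(), int(num)
    i = 0
    while i < len(token) and not token[i].isdigit():
        i += 1
    if i == 0 or i == len(token):
        raise SelectionError(f"cannot parse residue token {token!r}")
    return token[:i].upper(), int(token[i:])


def build_selection(spec: dict, topology: Topology) -> SelectionSet:
    """Resolve a selection spec against a topology.

    ``spec`` is a mapping with ``groups`` (name → criteria) and optional
    ``roles`` (role → group name).  Criteria may contain ``residues`` (tokens
    like ``"Ser61"``), ``residue_names``, ``atom_names`` and
    ``molecule_ids``; multiple criteria intersect.  Unresolvable residue
    tokens raise :class:`SelectionError` listing every offender.
    """
    groups: dict[str, np.ndarray] = {}
    resnames_up = np.char.upper(topology.residue_names.astype(str))
    for gname, crit in spec.get("groups", {}).items():
        mask = np.ones(topology.n_particles, dtype=bool)
        if "residues" in crit:
            sub = np.zeros(topology.n_particles, dtype=bool)
            missing = []
            for token in crit["residues"]:
                rname, rid = _parse_residue_token(token)
                hit = (resnames_up == rname) & (topology.residue_ids == rid)
                if not hit.any():
                    missing.append(token)
                sub |= hit
            if missing:
                raise SelectionError(
                    f"group {gname!r}: unresolved residues {', '.join(missing)}"
                )
            mask &= sub
        if "residue_names" in crit:
            wanted = {s.upper() for s in crit["residue_names"]}
            mask &= np.isin(resnames_up, sorted(wanted))
        if "atom_names" in crit:
            mask &= np.isin(topology.atom_names.astype(str), crit["atom_names"])
        if "molecule_ids" in crit:
            mask &= np.isin(topology.molecule_ids, crit["molecule_ids"])
        groups[gname] = np.nonzero(mask)[0]

    roles = dict(spec.get("roles", {}))
    for role, gname in roles.items():
        if gname not in groups:
            raise SelectionError(f"role {role!r} names unknown group {gname!r}")
        if groups[gname].size == 0:
            raise SelectionError(f"required role {role!r} resolved to an empty group")
    return SelectionSet(groups=groups, topology=topology, roles=roles)
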