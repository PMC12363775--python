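"""Periodic geometry: minimum-image distances, radial region classification
in the membrane plane, and the lumenal-domain tilt angle.

The region classifier operationalises the split of TG molecules into those
far from the protein ("bulk") and those inside the protein complex
("complex"): a molecule is assigned per time window, and only if its glycerol
bead stays on one side of the radial boundary for the entire window; boundary
crossers are "excluded" so they contaminate neither diffusion estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory_io import SelectionSet, Trajectory

__all__ = [
    "RegionModel",
    "AngleSeries",
    "min_image_distance",
    "min_image_displacement",
    "glycerol_centroids",
    "classify_regions",
    "tilt_angle",
]


def min_image_displacement(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Vector b − a mapped into the central image of an orthorhombic box.

    Broadcasts over leading axes; the last axis is the spatial dimension and
    may be 2 (lateral) or 3.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    d = b - a
    return d - box * np.round(d / box)


def min_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Euclidean distance under the minimum-image convention."""
    d = min_image_displacement(a, b, box)
    return np.sqrt(np.sum(d * d, axis=-1))


@dataclass
class RegionModel:
    """Radial (cylindrical) two-region model in the membrane plane.

    ``protein_com_xy`` may be a single (2,) point or an (n_frames, 2) series.
    ``r_complex`` is the radius of the "within complex" cylinder and
    ``r_bulk`` the inner radius of the "bulk membrane" region; the annulus in
    between is a buffer whose occupants are excluded.
    """

    protein_com_xy: np.ndarray
    r_complex: float
    r_bulk: float
    mode: str = "radial"

    def __post_init__(self) -> None:
        self.protein_com_xy = np.atleast_2d(np.asarray(self.protein_com_xy, float))
        if not 0 < self.r_complex < self.r_bulk:
            raise ValueError("need 0 < r_complex < r_bulk")
        if self.mode != "radial":
            raise ValueError(f"unknown region mode {self.mode!r}")

    @classmethod
    def from_protein(
        cls,
        traj: Trajectory,
        sel: SelectionSet,
        r_complex: float | None = None,
        buffer: float = 10.0,
    ) -> "RegionModel":
        """Build from the protein beads: centre = XY centroid per frame;
        default r_complex = max radial extent of the protein beads."""
        prot = sel.role_indices("protein")
        xy = traj.coords[:, prot, :2]
        com = xy.mean(axis=1)
        if r_complex is None:
            d = min_image_displacement(com[:, None, :], xy, traj.box[:, None, :2])
            r_complex = float(np.sqrt((d**2).sum(-1)).max())
        return cls(protein_com_xy=com, r_complex=r_complex, r_bulk=r_complex + buffer)


@dataclass
class AngleSeries:
    """Tilt angle (degrees) of an inter-residue vector vs the membrane normal."""

    times: np.ndarray
    theta: np.ndarray
    residue_pair: tuple[str, str]
    normal: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "theta_deg": self.theta})


def glycerol_centroids(traj: Trajectory, sel: SelectionSet, unwrapped: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame centroid of each TG molecule's glycerol beads.

    Returns ``(molecule_ids, centroids)`` with centroids of shape
    (n_frames, n_molecules, 3).  Wrapped coordinates are used unless
    ``unwrapped`` is requested (required for MSD).
    """
    mols = sel.tg_molecules()
    src = traj.unwrapped if unwrapped else traj.coords
    if src is None:
        raise ValueError("trajectory has no unwrapped coordinates; call unwrap() first")
    out = np.empty((traj.n_frames, len(mols), 3))
    for k, mol in enumerate(mols):
        idx = sel.glycerol_indices(mol)
        out[:, k, :] = src[:, idx, :].mean(axis=1)
    return mols, out


def classify_regions(
    traj: Trajectory,
    sel: SelectionSet,
    model: RegionModel,
    window: int,
) -> pd.DataFrame:
    """Assign each TG molecule a category per time window.

    A molecule is ``"complex"`` if its glycerol XY position stays within
    ``r_complex`` of the protein centre for *every* frame of the window,
    ``"bulk"`` if it stays beyond ``r_bulk`` throughout, and ``"excluded"``
    otherwise.  Returns a tidy frame with columns ``molecule``, ``window``,
    ``start``, ``stop`` (frame slice, stop exclusive) and ``category``.
    The three categories always partition the molecules in every window.
    """
    if window < 2:
        raise ValueError("window must span at least 2 frames")
    if np.any(model.r_bulk > traj.box[:, :2].min() / 2):
        raise ValueError("r_bulk exceeds half the smallest lateral box edge")

    mols, cent = glycerol_centroids(traj, sel)
    centers = model.protein_com_xy
    if centers.shape[0] == 1:
        centers = np.broadcast_to(centers, (traj.n_frames, 2))
    d = min_image_displacement(
        centers[:, None, :], cent[:, :, :2], traj.box[:, None, :2]
    )
    r = np.sqrt((d**2).sum(-1))  # (n_frames, n_mols)

    records = []
    n_windows = traj.n_frames // window
    for w in range(n_windows):
        sl = slice(w * window, (w + 1) * window)
        inside = (r[sl] <= model.r_complex).all(axis=0)
        outside = (r[sl] > model.r_bulk).all(axis=0)
        cat = np.where(inside, "complex", np.where(outside, "bulk", "excluded"))
        for k, mol in enumerate(mols):
            records.append(
                {
                    "molecule": int(mol),
                    "window": w,
                    "start": sl.start,
                    "stop": sl.stop,
                    "category": str(cat[k]),
                }
            )
    return pd.DataFrame.from_records(records)


def _residue_centroid(traj: Trajectory, sel: SelectionSet, residue: str) -> np.ndarray:
    from .trajectory_io import SelectionError, _parse_residue_token

    rname, rid = _parse_residue_token(residue)
    top = sel.topology
    mask = (np.char.upper(top.residue_names.astype(str)) == rname) & (
        top.residue_ids == rid
    )
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise SelectionError(f"residue {residue!r} not found in topology")
    return traj.coords[:, idx, :].mean(axis=1)


def tilt_angle(
    traj: Trajectory,
    sel: SelectionSet,
    residue_a: str,
    residue_b: str,
    normal: np.ndarray | None = None,
    signed: bool = False,
) -> AngleSeries:
    """Angle between the membrane normal and the vector joining two residues.

    The vector runs from the centroid of ``residue_a``'s particles to that of
    ``residue_b`` under the minimum image.  By default the unsigned form
    ``arccos(|v·n| / |v|)`` is reported (0–90°); the signed option drops the
    absolute value and spans 0–180°.  The normal defaults to the box z axis,
    the standard bilayer convention.
    """
    n = np.array([0.0, 0.0, 1.0]) if normal is None else np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    ca = _residue_centroid(traj, sel, residue_a)
    cb = _residue_centroid(traj, sel, residue_b)
    v = min_image_displacement(ca, cb, traj.box)
    norm = np.linalg.norm(v, axis=-1)
    if np.any(norm == 0):
        raise ValueError("zero-length inter-residue vector: angle undefined")
    dot = (v * n).sum(-1) / norm
    if not signed:
        dot = np.abs(dot)
    theta = np.degrees(np.arccos(np.clip(dot, -1.0, 1.0)))
    return AngleSeries(
        times=traj.times, theta=theta, residue_pair=(residue_a, residue_b), normal=n
    )
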