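"""TG–residue binding analysis and the dissociation-constant estimator.

The binding picture is two-state: a TG molecule's central glycerol group is
either bound to a named residue group (its minimum-image distance to the
nearest group particle is below a cutoff) or unbound.  From the per-frame
frame counts the dissociation constant follows directly as

    KD = [TG] · N_unbound / N_bound

where [TG] is the TG concentration in whatever unit the configuration
declares (typically mol%); the estimate carries that unit verbatim.  The
bound/unbound criterion itself is a package decision (the underlying
dichotomy is standard, the cutoff is not): a hysteresis rule with an entry
cutoff and a leave cutoff, which collapses to a plain threshold when the two
are equal.  Every report records the cutoffs used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import min_image_distance
from .trajectory_io import SelectionError, SelectionSet, Trajectory

__all__ = [
    "BindingSeries",
    "KDEstimate",
    "distance_series",
    "classify_bound",
    "make_binding_series",
    "estimate_kd",
    "NoBindingError",
]

DEFAULT_CUTOFF = 7.0  # Å — CG bead-contact scale between glycerol centroid and residue bead


class NoBindingError(ValueError):
    """No bound frames: the dissociation constant is unbounded."""


@dataclass
class BindingSeries:
    """Per-frame distances and bound/unbound states for one lipid vs a residue group."""

    times: np.ndarray
    distance: np.ndarray | None
    state: np.ndarray  # bool, True = bound
    cutoff_on: float
    cutoff_off: float
    tg_conc: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.state = np.asarray(self.state, dtype=bool)
        if self.distance is not None:
            self.distance = np.asarray(self.distance, dtype=float)
            if self.distance.shape != self.state.shape:
                raise ValueError("distance and state must be parallel arrays")
        if np.isfinite(self.cutoff_on) and self.cutoff_off < self.cutoff_on:
            raise ValueError("cutoff_off must be ≥ cutoff_on")

    @property
    def n_frames(self) -> int:
        return self.state.size

    @property
    def n_bound(self) -> int:
        return int(self.state.sum())

    @property
    def n_unbound(self) -> int:
        return int(self.n_frames - self.state.sum())

    @property
    def n_events(self) -> int:
        """Number of binding/unbinding transitions."""
        return int(np.count_nonzero(np.diff(self.state)))


@dataclass
class KDEstimate:
    """Point estimate KD = [TG]·N_unbound/N_bound with a block-bootstrap CI."""

    kd: float
    tg_conc: float
    n_bound: int
    n_unbound: int
    n_events: int
    ci: tuple[float, float] | None
    block_length: int | None = None

    def to_dict(self) -> dict:
        return {
            "kd": self.kd,
            "tg_conc": self.tg_conc,
            "n_bound": self.n_bound,
            "n_unbound": self.n_unbound,
            "n_events": self.n_events,
            "ci_low": None if self.ci is None else self.ci[0],
            "ci_high": None if self.ci is None else self.ci[1],
            "block_length": self.block_length,
        }


def distance_series(
    traj: Trajectory,
    sel: SelectionSet,
    lipid_molecule: int,
    residue_group: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-image distance from a lipid's glycerol centroid to the nearest
    particle of a named residue group, per frame.

    Mirrors the distance traces between the central glycerol group of TG and
    key serine residues used to visualise binding/unbinding events.
    """
    if residue_group not in sel.groups:
        raise SelectionError(f"unknown group {residue_group!r}")
    grp = sel.groups[residue_group]
    if grp.size == 0:
        raise SelectionError(f"group {residue_group!r} is empty")
    gly = sel.glycerol_indices(lipid_molecule)
    cent = traj.coords[:, gly, :].mean(axis=1)  # (n_frames, 3)
    d = min_image_distance(
        cent[:, None, :], traj.coords[:, grp, :], traj.box[:, None, :]
    )
    return traj.times, d.min(axis=1)


def classify_bound(
    distances: np.ndarray, cutoff_on: float, cutoff_off: float | None = None
) -> np.ndarray:
    """Hysteresis state classification.

    Enter the bound state when distance < ``cutoff_on``; leave it only when
    distance > ``cutoff_off``.  With equal cutoffs this is a plain threshold.
    The initial state comes from the first frame's threshold test.
    """
    if cutoff_off is None:
        cutoff_off = cutoff_on
    if not 0 < cutoff_on <= cutoff_off:
        raise ValueError("need 0 < cutoff_on ≤ cutoff_off")
    distances = np.asarray(distances, dtype=float)
    state = np.empty(distances.size, dtype=bool)
    bound = distances[0] < cutoff_on
    state[0] = bound
    for i in range(1, distances.size):
        if bound:
            if distances[i] > cutoff_off:
                bound = False
        elif distances[i] < cutoff_on:
            bound = True
        state[i] = bound
    return state


def make_binding_series(
    traj: Trajectory,
    sel: SelectionSet,
    lipid_molecule: int,
    residue_group: str,
    tg_conc: float,
    cutoff_on: float = DEFAULT_CUTOFF,
    cutoff_off: float | None = None,
) -> BindingSeries:
    """Distance series + state classification in one step."""
    times, dist = distance_series(traj, sel, lipid_molecule, residue_group)
    state = classify_bound(dist, cutoff_on, cutoff_off)
    return BindingSeries(
        times=times,
        distance=dist,
        state=state,
        cutoff_on=cutoff_on,
        cutoff_off=cutoff_on if cutoff_off is None else cutoff_off,
        tg_conc=tg_conc,
    )


def _kd_point(tg_conc: float, n_bound: int, n_unbound: int) -> float:
    return tg_conc * n_unbound / n_bound


def estimate_kd(
    series: BindingSeries, n_boot: int = 200, seed: int = 0
) -> KDEstimate:
    """KD = [TG]·N_unbound/N_bound with a block-bootstrap confidence interval.

    The point estimate depends only on the frame counts, so it is invariant
    to frame order; the CI is not, and uses a moving-block bootstrap over
    contiguous segments whose length is at least the mean event (dwell)
    duration, to respect the serial correlation of the chain.  Fewer than two
    transitions triggers an unreliable-estimate warning.
    """
    n_b, n_u = series.n_bound, series.n_unbound
    if n_b == 0:
        raise NoBindingError("no bound frames: KD is unbounded")
    if series.n_events < 2:
        warnings.warn(
            "fewer than 2 binding/unbinding transitions: KD estimate unreliable",
            stacklevel=2,
        )
    kd = _kd_point(series.tg_conc, n_b, n_u)

    ci = None
    block = None
    if n_boot > 0 and series.n_events >= 2:
        n = series.n_frames
        mean_dwell = n / (series.n_events + 1)
        # blocks must span several correlation times to be exchangeable; for
        # a two-state chain the correlation time is the mean dwell, so use
        # 10× the mean dwell (shorter blocks undercover)
        block = int(min(max(np.ceil(10 * mean_dwell), 1), n // 2))
        n_blocks = n // block
        trimmed = series.state[: n_blocks * block].reshape(n_blocks, block)
        block_bound = trimmed.sum(axis=1)  # bound frames per block
        rng = np.random.default_rng(seed)
        picks = rng.integers(0, n_blocks, size=(n_boot, n_blocks))
        boot_bound = block_bound[picks].sum(axis=1)
        boot_total = n_blocks * block
        with np.errstate(divide="ignore"):
            boot_kd = series.tg_conc * (boot_total - boot_bound) / boot_bound
        boot_kd = boot_kd[np.isfinite(boot_kd)]
        if boot_kd.size:
            ci = tuple(np.percentile(boot_kd, [2.5, 97.5]).tolist())
    return KDEstimate(
        kd=kd,
        tg_conc=series.tg_conc,
        n_bound=n_b,
        n_unbound=n_u,
        n_events=series.n_events,
        ci=ci,
        block_length=block,
    )
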