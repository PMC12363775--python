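"""Synthetic trajectory generators with known ground truth.

Real LDAC simulations run for microseconds on ~4000-lipid bilayers and are
not reproducible at desk scale, so every analysis in this package is
validated on synthetic data whose answers are known by construction:

* :func:`gen_brownian_trap` — lateral Brownian motion with a slow disk
  ("trap") emulating the two diffusion regimes of TG far from, and inside,
  the protein complex.  The two input coefficients are the ground truth the
  MSD pipeline must recover.
* :func:`gen_two_state` — a discrete-time bound/unbound Markov chain whose
  stationary odds fix the true dissociation constant KD = k_off/k_on.
* :func:`gen_toroid` — a static, 11-fold symmetric double-ring bead layout
  standing in for the toroidal inner (LDAF1) / outer (seipin) transmembrane
  rings, with TG beads seeded in the chamber annulus between them.
* :func:`gen_planted_lens` — a TG configuration that switches from dispersed
  to a planted chamber cluster at a known onset frame, for nucleation
  detection tests.

Units are Å and ns throughout, declared in every trajectory header.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binding import BindingSeries
from .trajectory_io import SelectionSet, Topology, Trajectory

__all__ = [
    "BrownianConfig",
    "TwoStateConfig",
    "ToroidFixture",
    "gen_brownian_trap",
    "gen_two_state",
    "gen_toroid",
    "gen_planted_lens",
    "brownian_ground_truth",
]


def _check_finite(**kwargs: float) -> None:
    for name, val in kwargs.items():
        if not np.isfinite(val):
            raise ValueError(f"{name} must be finite, got {val!r}")


@dataclass
class BrownianConfig:
    """Lateral Brownian walk with a circular slow region.

    ``d_bulk`` and ``d_trap`` are lateral diffusion coefficients in Å²/ns;
    each step's per-axis variance is 2·D·dt with D chosen by the particle's
    region (inside/outside the trap disk) at the start of the step.  There is
    no barrier at the trap edge — particles cross freely, as TG enters and
    leaves the complex.  ``init_frac_trap`` optionally seeds that fraction of
    particles inside the trap disk (None → uniform over the box).
    """

    n_particles: int = 500
    box_xy: tuple[float, float] = (400.0, 400.0)
    box_z: float = 100.0
    dt: float = 1.0
    n_frames: int = 2000
    d_bulk: float = 1.1
    d_trap: float = 0.2
    trap_center: tuple[float, float] = (200.0, 200.0)
    trap_radius: float = 60.0
    init_frac_trap: float | None = None
    seed: int = 0

    def validate(self) -> None:
        _check_finite(
            dt=self.dt, d_bulk=self.d_bulk, d_trap=self.d_trap,
            trap_radius=self.trap_radius,
        )
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.d_bulk < 0 or self.d_trap < 0:
            raise ValueError("diffusion coefficients must be non-negative")
        if not 0 < self.trap_radius < min(self.box_xy) / 2:
            raise ValueError("need 0 < trap_radius < min(box_xy)/2")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.init_frac_trap is not None and not 0 <= self.init_frac_trap <= 1:
            raise ValueError("init_frac_trap must be in [0, 1]")


def brownian_ground_truth(cfg: BrownianConfig) -> dict:
    """Ground-truth sidecar for test harnesses (true D map, trap geometry)."""
    return {
        "d_bulk": cfg.d_bulk,
        "d_trap": cfg.d_trap,
        "fold_reduction": cfg.d_bulk / cfg.d_trap if cfg.d_trap > 0 else None,
        "trap_center": list(cfg.trap_center),
        "trap_radius": cfg.trap_radius,
        "units": {"d": "angstrom^2/ns", "length": "angstrom", "time": "ns"},
    }


def gen_brownian_trap(cfg: BrownianConfig) -> Trajectory:
    """Simulate the two-regime lateral random walk.

    Returns a trajectory carrying both wrapped and unwrapped coordinates;
    MSD analysis must use the unwrapped set.  Bit-identical for a fixed seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    L = np.asarray(cfg.box_xy, dtype=float)
    center = np.asarray(cfg.trap_center, dtype=float)

    if cfg.init_frac_trap is None:
        pos = rng.uniform(0, 1, size=(cfg.n_particles, 2)) * L
    else:
        n_trap = int(round(cfg.init_frac_trap * cfg.n_particles))
        # uniform over the trap disk for the first n_trap particles
        r = cfg.trap_radius * np.sqrt(rng.uniform(0, 1, n_trap))
        phi = rng.uniform(0, 2 * np.pi, n_trap)
        in_trap = center + np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1)
        rest = rng.uniform(0, 1, size=(cfg.n_particles - n_trap, 2)) * L
        pos = np.vstack([in_trap, rest])

    sig_bulk = np.sqrt(2 * cfg.d_bulk * cfg.dt)
    sig_trap = np.sqrt(2 * cfg.d_trap * cfg.dt)
    steps = rng.standard_normal(size=(cfg.n_frames - 1, cfg.n_particles, 2))

    unwrapped = np.empty((cfg.n_frames, cfg.n_particles, 2))
    unwrapped[0] = pos
    cur = pos.copy()
    for t in range(1, cfg.n_frames):
        wrapped = cur % L
        d = wrapped - center
        d -= L * np.round(d / L)
        in_trap = (d**2).sum(-1) <= cfg.trap_radius**2
        sigma = np.where(in_trap, sig_trap, sig_bulk)[:, None]
        cur = cur + steps[t - 1] * sigma
        unwrapped[t] = cur

    coords3 = np.zeros((cfg.n_frames, cfg.n_particles, 3))
    coords3[:, :, :2] = unwrapped % L
    coords3[:, :, 2] = cfg.box_z / 2
    unwrapped3 = coords3.copy()
    unwrapped3[:, :, :2] = unwrapped

    return Trajectory(
        times=np.arange(cfg.n_frames) * cfg.dt,
        box=np.array([L[0], L[1], cfg.box_z]),
        coords=coords3,
        unwrapped=unwrapped3,
    )


def brownian_selection(cfg: BrownianConfig) -> SelectionSet:
    """One-bead-per-molecule selection for a Brownian walk trajectory.

    Each particle plays the role of one TG molecule's central glycerol bead.
    """
    n = cfg.n_particles
    top = Topology(
        atom_names=np.array(["GL0"] * n, dtype=object),
        residue_ids=np.arange(1, n + 1),
        residue_names=np.array(["TRIO"] * n, dtype=object),
        molecule_ids=np.arange(n),
    )
    idx = np.arange(n)
    return SelectionSet(
        groups={"tg_glycerol": idx, "tg_beads": idx},
        topology=top,
        roles={"tg_glycerol": "tg_glycerol", "tg_beads": "tg_beads"},
    )


# ---------------------------------------------------------------------------
# two-state binding chain
# ---------------------------------------------------------------------------


@dataclass
class TwoStateConfig:
    """Discrete-time bound/unbound chain with known KD = k_off/k_on.

    Per-frame switching probabilities are 1−exp(−k_on·tg_conc·dt) into the
    bound state and 1−exp(−k_off·dt) out of it, so the stationary bound
    fraction is tg_conc/(KD+tg_conc).  ``tg_conc`` carries whatever
    concentration unit the KD estimate should report (e.g. mol%).
    """

    k_on: float = 0.1
    k_off: float = 0.05
    tg_conc: float = 0.5
    dt: float = 1.0
    n_frames: int = 1_000_000
    seed: int = 0

    def validate(self) -> None:
        _check_finite(k_on=self.k_on, k_off=self.k_off, tg_conc=self.tg_conc, dt=self.dt)
        if self.k_on <= 0 or self.k_off < 0:
            raise ValueError("k_on must be positive, k_off non-negative")
        if self.tg_conc <= 0:
            raise ValueError("tg_conc must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")

    @property
    def kd_true(self) -> float:
        return self.k_off / self.k_on


def gen_two_state(cfg: TwoStateConfig) -> BindingSeries:
    """Realise the two-state chain efficiently via geometric dwell times.

    A chain with constant per-frame switch probability p spends geometric
    (support ≥ 1) dwell times in each state, so alternating geometric draws
    reproduce the per-frame Bernoulli chain exactly.  The initial state is
    drawn from the stationary distribution.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    p_on = 1.0 - np.exp(-cfg.k_on * cfg.tg_conc * cfg.dt)
    p_off = 1.0 - np.exp(-cfg.k_off * cfg.dt)

    if p_off == 0.0:
        # the bound state is absorbing: unbound until the first binding
        # event, bound forever after
        first = int(rng.geometric(p_on)) if p_on < 1 else 1
        state = np.ones(cfg.n_frames, dtype=bool)
        state[: min(first, cfg.n_frames)] = False
        return BindingSeries(
            times=np.arange(cfg.n_frames) * cfg.dt,
            distance=None,
            state=state,
            cutoff_on=np.nan,
            cutoff_off=np.nan,
            tg_conc=cfg.tg_conc,
        )

    p_bound = p_on / (p_on + p_off)
    state0 = rng.uniform() < p_bound

    chunks: list[np.ndarray] = []
    total = 0
    cur = state0
    # draw dwell times in batches until the series is covered
    while total < cfg.n_frames:
        batch = 1024
        for _ in range(batch):
            p = p_off if cur else p_on
            dwell = int(rng.geometric(p))
            chunks.append(np.full(min(dwell, cfg.n_frames - total), cur, dtype=bool))
            total += chunks[-1].size
            cur = not cur
            if total >= cfg.n_frames:
                break
    state = np.concatenate(chunks)[: cfg.n_frames]
    return BindingSeries(
        times=np.arange(cfg.n_frames) * cfg.dt,
        distance=None,
        state=state,
        cutoff_on=np.nan,
        cutoff_off=np.nan,
        tg_conc=cfg.tg_conc,
    )


# ---------------------------------------------------------------------------
# toroid fixture
# ---------------------------------------------------------------------------

#: residue names/ids decorating the inner-ring protomers; the conserved
#: contact residues of the inner-ring protein appear once per protomer and
#: face the chamber at the membrane mid-plane, scaffold residues sit offset
#: above/below so they score lower against chamber TG.
_CONTACT_RESIDUES = [("PHE", 57), ("SER", 61), ("LEU", 105), ("SER", 109)]
_SCAFFOLD_RESIDUES = [("ALA", 58), ("VAL", 62), ("ILE", 104), ("GLY", 110)]
_LUMENAL_RESIDUES = [("SER", 126), ("SER", 131)]


@dataclass
class ToroidFixture:
    """Static double-ring bead layout with C11 symmetry.

    ``inner_radius`` < ``chamber`` annulus < ``outer_radius``; TG placed in
    the chamber annulus is "within the complex" by construction.
    """

    topology: Topology
    trajectory: Trajectory
    selection: SelectionSet
    inner_radius: float
    outer_radius: float
    chamber_annulus: tuple[float, float]
    center_xy: np.ndarray = field(default_factory=lambda: np.zeros(2))
    n_protomers: int = 11


def gen_toroid(
    n_protomers: int = 11,
    inner_radius: float = 35.0,
    outer_radius: float = 75.0,
    box: tuple[float, float, float] = (300.0, 300.0, 100.0),
    n_frames: int = 1,
    n_tg: int = 0,
    tg_mode: str = "uniform",
    cluster_frac: float = 0.6,
    seed: int = 0,
    rotate: float = 0.0,
) -> ToroidFixture:
    """Deterministic double-ring toroid stand-in plus optional chamber TG.

    Each inner-ring protomer carries two short helix-like bead columns with
    the four conserved contact residues plus the Ser126/Ser131 lumenal pair;
    the outer ring carries generic beads.  ``tg_mode`` places ``n_tg``
    single-bead TG molecules either ``"uniform"`` over the chamber annulus or
    ``"clustered"`` (a ``cluster_frac`` contiguous blob plus dispersed
    singletons).  ``rotate`` applies a rigid rotation (radians) about the
    ring axis — all distance statistics are invariant under multiples of
    2π/n_protomers.
    """
    if n_protomers < 3:
        raise ValueError("need at least 3 protomers for a ring")
    rng = np.random.default_rng(seed)
    L = np.asarray(box, dtype=float)
    center = L[:2] / 2
    z0 = L[2] / 2

    names, resids, resnames, molids, coords = [], [], [], [], []
    mol = 0
    for k in range(n_protomers):
        phi = 2 * np.pi * k / n_protomers + rotate
        u = np.array([np.cos(phi), np.sin(phi)])
        tangent = np.array([-np.sin(phi), np.cos(phi)])
        # inner protomer: two helices, separated tangentially; contact
        # residues at the mid-plane facing the chamber, scaffold residues
        # displaced vertically and radially inward
        for h, off in enumerate((-3.0, 3.0)):
            base = center + inner_radius * u + off * tangent
            for b, (rname, rid) in enumerate(_CONTACT_RESIDUES):
                coords.append([*(base + 0.8 * b * tangent), z0])
                names.append("BB")
                resnames.append(rname)
                resids.append(rid)
                molids.append(mol)
            for b, (rname, rid) in enumerate(_SCAFFOLD_RESIDUES):
                coords.append([*(base - 2.0 * u + 0.8 * b * tangent), z0 + 6.0])
                names.append("BB")
                resnames.append(rname)
                resids.append(rid)
                molids.append(mol)
        # lumenal pair sits above the membrane mid-plane, tilted outward
        base = center + (inner_radius + 2.0) * u
        for b, (rname, rid) in enumerate(_LUMENAL_RESIDUES):
            coords.append([*(base + 2.0 * b * u), z0 + 12.0 + 4.0 * b])
            names.append("BB")
            resnames.append(rname)
            resids.append(rid)
            molids.append(mol)
        mol += 1
        # outer protomer: generic seipin beads
        for b in range(6):
            base = center + outer_radius * u + (b - 2.5) * 1.2 * tangent
            coords.append([*base, z0 + 1.5 * (b % 3)])
            names.append("BB")
            resnames.append("GLY")
            resids.append(300 + b)
            molids.append(mol)
        mol += 1

    n_prot_beads = len(coords)
    r_in = inner_radius + 6.0
    r_out = outer_radius - 6.0

    tg_first = len(coords)
    if n_tg:
        if tg_mode == "uniform":
            r = np.sqrt(rng.uniform(r_in**2, r_out**2, n_tg))
            phi = rng.uniform(0, 2 * np.pi, n_tg)
        elif tg_mode == "clustered":
            n_cl = int(round(cluster_frac * n_tg))
            phi_c = rng.uniform(0, 2 * np.pi)
            r_c = 0.5 * (r_in + r_out)
            blob = rng.normal(0, 3.0, size=(n_cl, 2))
            blob += center + r_c * np.array([np.cos(phi_c), np.sin(phi_c)])
            # dispersed singletons, kept far apart and away from the blob
            n_disp = n_tg - n_cl
            pts = [blob]
            disp = []
            while len(disp) < n_disp:
                rr = np.sqrt(rng.uniform(r_in**2, r_out**2))
                pp = rng.uniform(0, 2 * np.pi)
                cand = center + rr * np.array([np.cos(pp), np.sin(pp)])
                all_pts = np.vstack(pts + disp) if disp else np.vstack(pts)
                if np.min(np.linalg.norm(all_pts - cand, axis=1)) > 15.0:
                    disp.append(cand[None, :])
            xy = np.vstack([blob] + disp)
            r = None
        else:
            raise ValueError(f"unknown tg_mode {tg_mode!r}")
        if tg_mode == "uniform":
            xy = center + np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1)
        for k in range(n_tg):
            coords.append([xy[k, 0], xy[k, 1], z0])
            names.append("GL0")
            resnames.append("TRIO")
            resids.append(1000 + k)
            molids.append(mol)
            mol += 1

    coords = np.asarray(coords, dtype=float)
    top = Topology(
        atom_names=np.array(names, dtype=object),
        residue_ids=np.array(resids),
        residue_names=np.array(resnames, dtype=object),
        molecule_ids=np.array(molids),
    )
    traj = Trajectory(
        times=np.arange(n_frames, dtype=float),
        box=L,
        coords=np.tile(coords[None, :, :], (n_frames, 1, 1)),
    )
    prot_idx = np.arange(n_prot_beads)
    tg_idx = np.arange(tg_first, len(coords))
    groups = {"protein": prot_idx, "tg_glycerol": tg_idx, "tg_beads": tg_idx}
    roles = {"protein": "protein"}
    if n_tg:
        roles.update({"tg_glycerol": "tg_glycerol", "tg_beads": "tg_beads"})
    sel = SelectionSet(groups=groups, topology=top, roles=roles)
    return ToroidFixture(
        topology=top,
        trajectory=traj,
        selection=sel,
        inner_radius=inner_radius,
        outer_radius=outer_radius,
        chamber_annulus=(r_in, r_out),
        center_xy=center,
        n_protomers=n_protomers,
    )


# ---------------------------------------------------------------------------
# planted nucleation fixture
# ---------------------------------------------------------------------------


def gen_planted_lens(
    n_tg: int = 40,
    onset_frame: int | None = 25,
    n_frames: int = 50,
    box: tuple[float, float, float] = (300.0, 300.0, 100.0),
    cluster_frac: float = 0.6,
    cluster_spacing: float = 6.0,
    min_separation: float = 20.0,
    jitter: float = 0.5,
    seed: int = 0,
) -> tuple[Trajectory, SelectionSet, dict]:
    """TG configuration that coalesces into a chamber cluster at a known frame.

    Before ``onset_frame`` all molecules sit on a dispersed layout whose
    pairwise separations exceed ``min_separation``; from the onset on, a
    ``cluster_frac`` fraction occupies a tight grid (spacing
    ``cluster_spacing``) at the chamber centre while the rest stay dispersed.
    ``onset_frame=None`` keeps the dispersed layout throughout (negative
    control).  Returns the trajectory, a TG selection and a ground-truth dict.
    """
    rng = np.random.default_rng(seed)
    L = np.asarray(box, dtype=float)
    center = L[:2] / 2
    z0 = L[2] / 2

    # dispersed layout: Poisson-disk style rejection sampling
    disp = []
    while len(disp) < n_tg:
        cand = rng.uniform(0.1, 0.9, 2) * L[:2]
        if not disp or np.min(
            np.linalg.norm(np.asarray(disp) - cand, axis=1)
        ) > min_separation:
            disp.append(cand)
    dispersed = np.asarray(disp)

    n_cl = int(round(cluster_frac * n_tg))
    side = int(np.ceil(np.sqrt(n_cl)))
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    grid = np.stack([gx.ravel(), gy.ravel()], axis=1)[:n_cl] * cluster_spacing
    grid = grid - grid.mean(axis=0) + center

    coords = np.empty((n_frames, n_tg, 3))
    coords[:, :, 2] = z0
    truth_members = np.arange(n_cl)
    for f in range(n_frames):
        xy = dispersed.copy()
        if onset_frame is not None and f >= onset_frame:
            xy[:n_cl] = grid
        xy = xy + rng.normal(0, jitter, size=xy.shape)
        coords[f, :, :2] = xy % L[:2]

    top = Topology(
        atom_names=np.array(["GL0"] * n_tg, dtype=object),
        residue_ids=np.arange(1, n_tg + 1),
        residue_names=np.array(["TRIO"] * n_tg, dtype=object),
        molecule_ids=np.arange(n_tg),
    )
    idx = np.arange(n_tg)
    sel = SelectionSet(
        groups={"tg_glycerol": idx, "tg_beads": idx},
        topology=top,
        roles={"tg_glycerol": "tg_glycerol", "tg_beads": "tg_beads"},
    )
    traj = Trajectory(
        times=np.arange(n_frames, dtype=float), box=L, coords=coords
    )
    truth = {
        "onset_frame": onset_frame,
        "cluster_members": truth_members.tolist(),
        "cluster_size": int(n_cl),
        "center_xy": center.tolist(),
    }
    return traj, sel, truth
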