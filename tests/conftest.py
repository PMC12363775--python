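import numpy as np
import pytest

from lipidlens.trajectory_io import SelectionSet, Topology, Trajectory


def make_single_bead_system(coords, box, times=None):
    """Trajectory + selection where each particle is one TG molecule's
    glycerol bead. ``coords`` is (n_frames, n_mol, 2 or 3)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[-1] == 2:
        z = np.full(coords.shape[:-1] + (1,), 0.5 * np.asarray(box)[2])
        coords = np.concatenate([coords, z], axis=-1)
    n_frames, n = coords.shape[:2]
    top = Topology(
        atom_names=np.array(["GL0"] * n, dtype=object),
        residue_ids=np.arange(1, n + 1),
        residue_names=np.array(["TRIO"] * n, dtype=object),
        molecule_ids=np.arange(n),
    )
    idx = np.arange(n)
    sel = SelectionSet(
        groups={"tg_glycerol": idx, "tg_beads": idx},
        topology=top,
        roles={"tg_glycerol": "tg_glycerol", "tg_beads": "tg_beads"},
    )
    traj = Trajectory(
        times=np.arange(n_frames, dtype=float) if times is None else times,
        box=np.asarray(box, dtype=float),
        coords=coords,
        unwrapped=coords.copy(),
    )
    return traj, sel


@pytest.fixture
def toroid():
    from lipidlens.synthetic_data import gen_toroid

    return gen_toroid(n_tg=40, seed=11)
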