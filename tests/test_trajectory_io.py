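"""I/O: columnar round trips, standard formats, unwrapping, selections."""

import numpy as np
import pytest

from lipidlens.synthetic_data import BrownianConfig, gen_brownian_trap
from lipidlens.trajectory_io import (
    SelectionError,
    Topology,
    Trajectory,
    TrajectoryError,
    build_selection,
    read_columnar,
    read_trajectory,
    unwrap,
    write_columnar,
    write_gro_xtc,
)


@pytest.fixture
def small_traj():
    return gen_brownian_trap(BrownianConfig(n_particles=5, n_frames=3, seed=0))


class TestColumnar:
    def test_round_trip_preserves_coordinates(self, small_traj, tmp_path):
        p = tmp_path / "t.traj.txt"
        write_columnar(small_traj, p)
        back = read_columnar(p)
        np.testing.assert_allclose(back.coords, small_traj.coords, atol=1e-3)
        np.testing.assert_allclose(back.unwrapped, small_traj.unwrapped, atol=1e-3)
        np.testing.assert_allclose(back.times, small_traj.times)

    def test_read_trajectory_dispatches_on_extension(self, small_traj, tmp_path):
        p = tmp_path / "t.traj.txt"
        write_columnar(small_traj, p)
        traj, top = read_trajectory(p)
        assert top is None
        assert traj.n_particles == 5

    def test_nm_header_converts_to_angstrom(self, small_traj, tmp_path):
        p = tmp_path / "t.traj.txt"
        write_columnar(small_traj, p)
        text = p.read_text().replace("# length_unit angstrom", "# length_unit nm")
        p.write_text(text)
        back = read_columnar(p)
        np.testing.assert_allclose(back.coords, small_traj.coords * 10, atol=1e-2)

    def test_truncated_file_names_last_good_frame(self, small_traj, tmp_path):
        p = tmp_path / "t.traj.txt"
        write_columnar(small_traj, p)
        lines = p.read_text().splitlines()
        # drop the last two lines: frame 2 becomes incomplete
        p.write_text("\n".join(lines[:-2]) + "\n")
        with pytest.raises(TrajectoryError, match="last good frame is 1"):
            read_columnar(p)

    def test_missing_unit_header_is_hard_error(self, small_traj, tmp_path):
        p = tmp_path / "t.traj.txt"
        write_columnar(small_traj, p)
        text = "\n".join(
            l for l in p.read_text().splitlines() if not l.startswith("# length_unit")
        )
        p.write_text(text + "\n")
        with pytest.raises(TrajectoryError, match="length_unit"):
            read_columnar(p)


class TestStandardFormats:
    def test_gro_xtc_round_trip(self, tmp_path):
        traj = gen_brownian_trap(BrownianConfig(n_particles=8, n_frames=5, seed=2))
        top = Topology(
            atom_names=np.array(["GL0"] * 8, dtype=object),
            residue_ids=np.arange(1, 9),
            residue_names=np.array(["TRIO"] * 8, dtype=object),
            molecule_ids=np.arange(8),
        )
        gro, xtc = tmp_path / "s.gro", tmp_path / "s.xtc"
        write_gro_xtc(traj, top, gro, xtc)
        back, top2 = read_trajectory(gro, xtc)
        assert back.n_frames == 5
        # XTC stores nm at 1e-3 precision → ≤1e-2 Å after conversion
        np.testing.assert_allclose(back.coords, traj.coords, atol=1.5e-2)
        assert list(top2.residue_names[:2]) == ["TRIO", "TRIO"]

    def test_triclinic_box_is_rejected(self, tmp_path):
        import MDAnalysis as mda

        u = mda.Universe.empty(3, trajectory=True)
        u.add_TopologyAttr("names", ["A", "B", "C"])
        u.dimensions = [30.0, 30.0, 30.0, 60.0, 90.0, 90.0]
        u.atoms.positions = np.eye(3) * 5
        p = tmp_path / "tri.gro"
        u.atoms.write(str(p))
        with pytest.raises(TrajectoryError, match="triclinic"):
            read_trajectory(p)


class TestUnwrap:
    def test_boundary_crossing_becomes_monotonic(self):
        # particle walks +1 Å/frame across the +x boundary of a 10 Å box
        x = (np.arange(8.0, 15.0) % 10.0)[:, None, None]
        coords = np.concatenate([x, np.full_like(x, 5.0), np.full_like(x, 5.0)], -1)
        traj = Trajectory(
            times=np.arange(7.0), box=np.array([10.0, 10.0, 10.0]), coords=coords
        )
        out = unwrap(traj)
        assert np.all(np.diff(out.unwrapped[:, 0, 0]) > 0)
        np.testing.assert_allclose(out.unwrapped[:, 0, 0], np.arange(8.0, 15.0))

    def test_stationary_particle_unchanged(self):
        coords = np.full((5, 2, 3), 3.0)
        traj = Trajectory(
            times=np.arange(5.0), box=np.array([10.0, 10.0, 10.0]), coords=coords
        )
        out = unwrap(traj)
        np.testing.assert_array_equal(out.unwrapped, coords)

    def test_idempotent(self):
        traj = gen_brownian_trap(BrownianConfig(n_particles=10, n_frames=40, seed=7))
        once = unwrap(Trajectory(times=traj.times, box=traj.box, coords=traj.coords))
        # feed the unwrapped coordinates back in a huge box (no wrapping)
        big = Trajectory(
            times=traj.times,
            box=np.array([1e6, 1e6, 1e6]),
            coords=once.unwrapped,
        )
        twice = unwrap(big)
        np.testing.assert_allclose(twice.unwrapped, once.unwrapped, atol=1e-9)

    def test_unwrapped_msd_dominates_wrapped_at_large_lag(self):
        cfg = BrownianConfig(
            n_particles=50, n_frames=400, d_bulk=5.0, d_trap=5.0,
            box_xy=(30.0, 30.0), trap_center=(15.0, 15.0), trap_radius=10.0,
            seed=1,
        )
        traj = gen_brownian_trap(cfg)
        lag = 300
        dw = traj.coords[lag:] - traj.coords[:-lag]
        du = traj.unwrapped[lag:] - traj.unwrapped[:-lag]
        assert (du[..., :2] ** 2).sum(-1).mean() > (dw[..., :2] ** 2).sum(-1).mean()


class TestSelections:
    @pytest.fixture
    def topology(self):
        return Topology(
            atom_names=np.array(["BB", "BB", "BB", "GL0"], dtype=object),
            residue_ids=np.array([61, 109, 57, 1]),
            residue_names=np.array(["SER", "SER", "PHE", "TRIO"], dtype=object),
            molecule_ids=np.array([0, 0, 0, 1]),
        )

    def test_residue_groups_resolve(self, topology):
        sel = build_selection(
            {"groups": {"serines": {"residues": ["Ser61", "Ser109"]}}}, topology
        )
        np.testing.assert_array_equal(sel.groups["serines"], [0, 1])

    def test_unresolved_residue_is_listed(self, topology):
        with pytest.raises(SelectionError, match="Ser999"):
            build_selection(
                {"groups": {"bad": {"residues": ["Ser61", "Ser999"]}}}, topology
            )

    def test_empty_required_role_is_error(self, topology):
        with pytest.raises(SelectionError, match="empty"):
            build_selection(
                {
                    "groups": {"none": {"residue_names": ["ARG"]}},
                    "roles": {"protein": "none"},
                },
                topology,
            )

    def test_multichain_cg_tg_is_one_molecule(self):
        """A CG TG molecule has three ester chains of Na/C1×4/C3 beads; all
        18 beads share one molecule ID and the glycerol group is the Na
        beads."""
        names, molids = [], []
        for chain in range(3):
            names += ["Na"] + [f"C1{k}" for k in range(4)] + ["C3"]
            molids += [7] * 6
        top = Topology(
            atom_names=np.array(names, dtype=object),
            residue_ids=np.full(18, 1),
            residue_names=np.array(["TRIO"] * 18, dtype=object),
            molecule_ids=np.array(molids),
        )
        sel = build_selection(
            {
                "groups": {
                    "gly": {"atom_names": ["Na"]},
                    "all_tg": {"residue_names": ["TRIO"]},
                },
                "roles": {"tg_glycerol": "gly", "tg_beads": "all_tg"},
            },
            top,
        )
        assert list(sel.tg_molecules()) == [7]
        assert sel.glycerol_indices(7).size == 3
        assert sel.role_indices("tg_beads").size == 18
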