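"""Logistic interaction score, CG mapping, peak ranking."""

import numpy as np
import pytest

from lipidlens.geometry import min_image_distance
from lipidlens.interaction import (
    CGMapping,
    MappingRule,
    default_distance_cap,
    interaction_score,
    map_to_cg,
    profile_peaks,
)
from lipidlens.trajectory_io import SelectionError, SelectionSet, Topology, Trajectory


def _system(tg_xyz, prot_xyz, prot_resids, prot_resnames, box):
    tg_xyz = np.asarray(tg_xyz, float)  # (n_frames, n_tg, 3)
    n_frames = tg_xyz.shape[0]
    prot_xyz = np.asarray(prot_xyz, float)
    n_tg, n_prot = tg_xyz.shape[1], prot_xyz.shape[0]
    coords = np.concatenate(
        [tg_xyz, np.tile(prot_xyz[None], (n_frames, 1, 1))], axis=1
    )
    top = Topology(
        atom_names=np.array(["GL0"] * n_tg + ["BB"] * n_prot, dtype=object),
        residue_ids=np.array([0] * n_tg + list(prot_resids)),
        residue_names=np.array(["TRIO"] * n_tg + list(prot_resnames), dtype=object),
        molecule_ids=np.array([0] * n_tg + [1] * n_prot),
    )
    sel = SelectionSet(
        groups={"tg": np.arange(n_tg), "prot": np.arange(n_tg, n_tg + n_prot)},
        topology=top,
        roles={"tg_beads": "tg", "tg_glycerol": "tg", "protein": "prot"},
    )
    traj = Trajectory(
        times=np.arange(n_frames, dtype=float), box=np.asarray(box, float),
        coords=coords,
    )
    return traj, sel


def brute_force_score(traj, sel, kernel_scale=0.5):
    """Triple-loop all-pairs oracle."""
    tg = sel.role_indices("tg_beads")
    prot = sel.role_indices("protein")
    top = sel.topology
    keys = []
    for j in prot:
        key = (top.residue_names[j], top.residue_ids[j])
        if key not in keys:
            keys.append(key)
    out = {k: 0.0 for k in keys}
    for f in range(traj.n_frames):
        for i in tg:
            for j in prot:
                r = min_image_distance(traj.coords[f, i], traj.coords[f, j], traj.box[f])
                key = (top.residue_names[j], top.residue_ids[j])
                out[key] += 2.0 / (1.0 + np.exp(kernel_scale * r))
    return np.array([out[k] / traj.n_frames for k in keys])


class TestKernel:
    def test_contact_pair_scores_one(self):
        traj, sel = _system(
            [[[5.0, 5.0, 5.0]]], [[5.0, 5.0, 5.0]], [61], ["SER"], [20.0] * 3
        )
        prof = interaction_score(traj, sel)
        assert prof.score[0] == pytest.approx(1.0)

    def test_distant_pair_scores_nothing(self):
        traj, sel = _system(
            [[[1.0, 1.0, 1.0]]], [[40.0, 40.0, 40.0]], [61], ["SER"], [100.0] * 3
        )
        assert interaction_score(traj, sel).score[0] < 1e-7

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(31)
        box = [30.0, 30.0, 30.0]
        tg = rng.uniform(0, 30, (3, 10, 3))
        prot = rng.uniform(0, 30, (30, 3))
        resids = np.repeat(np.arange(1, 7), 5)
        resnames = np.repeat(["SER", "PHE", "LEU", "ALA", "GLY", "VAL"], 5)
        traj, sel = _system(tg, prot, resids, resnames, box)
        prof = interaction_score(traj, sel)
        np.testing.assert_allclose(prof.score, brute_force_score(traj, sel), atol=1e-12)

    def test_score_decreases_with_distance_and_grows_with_beads(self):
        box = [200.0] * 3
        traj_near, sel_near = _system(
            [[[10.0, 10.0, 10.0]]], [[12.0, 10.0, 10.0]], [61], ["SER"], box
        )
        traj_far, sel_far = _system(
            [[[10.0, 10.0, 10.0]]], [[20.0, 10.0, 10.0]], [61], ["SER"], box
        )
        s_near = interaction_score(traj_near, sel_near).score[0]
        s_far = interaction_score(traj_far, sel_far).score[0]
        assert s_far < s_near
        traj_two, sel_two = _system(
            [[[10.0, 10.0, 10.0], [11.0, 10.0, 10.0]]],
            [[12.0, 10.0, 10.0]], [61], ["SER"], box,
        )
        assert interaction_score(traj_two, sel_two).score[0] > s_near

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(32)
        box = [1000.0] * 3
        tg = rng.uniform(400, 600, (2, 8, 3))
        prot = rng.uniform(400, 600, (12, 3))
        traj, sel = _system(tg, prot, [61] * 12, ["SER"] * 12, box)
        base = interaction_score(traj, sel).score
        th = 0.9
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        moved = (traj.coords - 500.0) @ R.T + 500.0 + np.array([3.0, -2.0, 1.0])
        traj2 = Trajectory(times=traj.times, box=traj.box, coords=moved)
        np.testing.assert_allclose(
            interaction_score(traj2, sel).score, base, atol=1e-9
        )

    def test_distance_cap_error_respects_analytic_bound(self):
        rng = np.random.default_rng(33)
        box = [60.0] * 3
        tg = rng.uniform(0, 60, (1, 20, 3))
        prot = rng.uniform(0, 60, (20, 3))
        traj, sel = _system(tg, prot, [61] * 20, ["SER"] * 20, box)
        cap = default_distance_cap(0.5, tol=1e-6)
        assert 2.0 * np.exp(-0.5 * cap) < 1e-6
        full = interaction_score(traj, sel).score
        capped = interaction_score(traj, sel, distance_cap=cap)
        n_pairs = 20 * 20
        assert np.abs(full - capped.score).max() <= n_pairs * capped.tail_bound


class TestCGMapping:
    def _aa_topology(self):
        return Topology(
            atom_names=np.array(["N", "CA", "C", "O", "CB", "OG"], dtype=object),
            residue_ids=np.full(6, 61),
            residue_names=np.array(["SER"] * 6, dtype=object),
            molecule_ids=np.zeros(6, dtype=int),
        )

    def test_single_atom_bead_is_identity(self):
        top = self._aa_topology()
        coords = np.arange(18, dtype=float).reshape(1, 6, 3)
        traj = Trajectory(times=[0.0], box=np.array([100.0] * 3), coords=coords)
        mapping = CGMapping([MappingRule("SER", "SC1", ["OG"])])
        cg, cg_top = map_to_cg(traj, top, mapping)
        np.testing.assert_array_equal(cg.coords[0, 0], coords[0, 5])
        assert cg_top.atom_names[0] == "SC1"

    def test_two_atom_bead_is_midpoint(self):
        top = self._aa_topology()
        coords = np.zeros((1, 6, 3))
        coords[0, 1, 0] = -1.0  # CA
        coords[0, 4, 0] = +1.0  # CB
        traj = Trajectory(times=[0.0], box=np.array([100.0] * 3), coords=coords)
        cg, _ = map_to_cg(traj, top, CGMapping([MappingRule("SER", "BB", ["CA", "CB"])]))
        np.testing.assert_allclose(cg.coords[0, 0], 0.0, atol=1e-12)

    def test_identity_mapping_on_cg_input_is_noop(self):
        top = Topology(
            atom_names=np.array(["BB"], dtype=object),
            residue_ids=np.array([61]),
            residue_names=np.array(["SER"], dtype=object),
            molecule_ids=np.array([0]),
        )
        coords = np.array([[[1.0, 2.0, 3.0]]])
        traj = Trajectory(times=[0.0], box=np.array([50.0] * 3), coords=coords)
        cg, _ = map_to_cg(traj, top, CGMapping([MappingRule("SER", "BB", ["BB"])]))
        np.testing.assert_array_equal(cg.coords, coords)

    def test_missing_member_atom_names_residue_and_atom(self):
        top = self._aa_topology()
        traj = Trajectory(
            times=[0.0], box=np.array([100.0] * 3), coords=np.zeros((1, 6, 3))
        )
        with pytest.raises(SelectionError, match="SER61.*'CG1'"):
            map_to_cg(traj, top, CGMapping([MappingRule("SER", "SC1", ["CG1"])]))

    def test_map_then_score_equals_handbuilt_cg(self):
        """Scoring an AA fixture after mapping equals scoring the CG fixture
        built directly from the bead centroids."""
        rng = np.random.default_rng(41)
        box = [50.0] * 3
        # AA protein: 2 residues × 4 atoms → 2 beads of 2 atoms each
        aa_prot = rng.uniform(10, 40, (8, 3))
        top_aa = Topology(
            atom_names=np.array(["CA", "CB", "CG", "CD"] * 2, dtype=object),
            residue_ids=np.repeat([61, 109], 4),
            residue_names=np.array(["SER"] * 4 + ["SER"] * 4, dtype=object),
            molecule_ids=np.zeros(8, dtype=int),
        )
        traj_aa = Trajectory(
            times=[0.0], box=np.asarray(box), coords=aa_prot[None]
        )
        mapping = CGMapping(
            [MappingRule("SER", "BB", ["CA", "CB"]), MappingRule("SER", "SC1", ["CG", "CD"])]
        )
        cg, cg_top = map_to_cg(traj_aa, top_aa, mapping)

        tg = rng.uniform(10, 40, (1, 5, 3))
        hand_beads = np.stack(
            [aa_prot[0:2].mean(0), aa_prot[2:4].mean(0),
             aa_prot[4:6].mean(0), aa_prot[6:8].mean(0)]
        )
        traj_hand, sel_hand = _system(tg, hand_beads, [61, 61, 109, 109],
                                      ["SER"] * 4, box)
        coords_mapped = np.concatenate([tg, cg.coords], axis=1)
        traj_mapped = Trajectory(times=[0.0], box=np.asarray(box), coords=coords_mapped)
        np.testing.assert_allclose(
            interaction_score(traj_mapped, sel_hand).score,
            interaction_score(traj_hand, sel_hand).score,
            atol=1e-12,
        )


class TestProfilePeaks:
    def test_pinned_tg_puts_adjacent_residue_first(self):
        box = [100.0] * 3
        prot = np.array([[10.0, 10, 10], [40.0, 10, 10], [70.0, 10, 10]])
        tg = np.array([[[11.0, 10.0, 10.0]]])
        traj, sel = _system(tg, prot, [57, 61, 105], ["PHE", "SER", "LEU"], box)
        ranked = profile_peaks(interaction_score(traj, sel), ["Phe57"], top_quantile=0.5)
        assert ranked.iloc[0]["residue_id"] == 57
        assert ranked.attrs["in_top_quantile"]["Phe57"]

    def test_symmetric_residues_tie(self):
        """TG at the centre of a symmetric square of residues → 4-way tie."""
        box = [100.0] * 3
        prot = np.array(
            [[40.0, 50, 10], [60.0, 50, 10], [50.0, 40, 10], [50.0, 60, 10]]
        )
        tg = np.array([[[50.0, 50.0, 10.0]]])
        traj, sel = _system(tg, prot, [1, 2, 3, 4], ["ALA"] * 4, box)
        scores = interaction_score(traj, sel).score
        assert scores.max() - scores.min() < 1e-6

    def test_absent_residue_is_error(self):
        box = [100.0] * 3
        traj, sel = _system(
            [[[5.0, 5.0, 5.0]]], [[6.0, 5.0, 5.0]], [61], ["SER"], box
        )
        with pytest.raises(SelectionError, match="Ser999"):
            profile_peaks(interaction_score(traj, sel), ["Ser999"])
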