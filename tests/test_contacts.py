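"""Contact detection, occupancy, moieties, H-bonds and structural metrics."""

import numpy as np
import pytest

from cormbind import contacts as ct
from cormbind.synthetic import GeneratorConfig, default_ligand, gen_trajectory_ensemble


def toy_topology(n_res=3, n_lig_atoms=2, copies=1):
    """n_res one-bead residues + `copies` two-atom ligand copies."""
    n = n_res + copies * n_lig_atoms
    lig_copy = [-1] * n_res
    moiety = [""] * n_res
    for c in range(copies):
        lig_copy += [c] * n_lig_atoms
        moiety += (["ring", "carbonyl"] * n_lig_atoms)[:n_lig_atoms]
    return ct.Topology(
        atom_name=np.array(["CA"] * n_res + ["L"] * (n - n_res)),
        element=np.array(["C"] * n),
        res_id=np.array(list(range(1, n_res + 1)) +
                        [c + 1 for c in range(copies) for _ in range(n_lig_atoms)]),
        res_name=np.array(["ALA"] * n_res + ["ALF"] * (n - n_res)),
        chain_id=np.array(["A"] * n_res + ["B"] * (n - n_res)),
        ligand_copy=np.array(lig_copy),
        moiety=np.array(moiety),
    )


class TestResidueContactSet:
    def test_distant_ligand_gives_empty_set(self):
        top = toy_topology()
        coords = np.zeros((5, 3))
        coords[:3, 0] = [0.0, 0.5, 1.0]
        coords[3:, 0] = 100.0
        assert ct.residue_contact_set(coords, top) == set()

    def test_single_pair_within_cutoff(self):
        top = toy_topology()
        coords = np.zeros((5, 3))
        coords[:3, 0] = [0.0, 5.0, 10.0]
        coords[3] = [0.35, 0.0, 0.0]   # near residue 1 only
        coords[4] = [50.0, 0.0, 0.0]
        assert ct.residue_contact_set(coords, top, cutoff=0.4) == {(1, 0)}

    def test_nan_coordinates_rejected(self):
        top = toy_topology()
        coords = np.zeros((5, 3))
        coords[0, 0] = np.nan
        with pytest.raises(ValueError):
            ct.residue_contact_set(coords, top)

    def test_matches_bruteforce_oracle(self):
        """Vectorized contact set equals the all-pairs double loop exactly."""
        rng = np.random.default_rng(0)
        n_res, copies, n_lig_atoms = 30, 3, 4
        top = toy_topology(n_res, n_lig_atoms, copies)
        for _ in range(25):
            coords = rng.uniform(0, 2.0, size=(top.n_atoms, 3))
            expected = set()
            for i in range(top.n_atoms):
                if top.ligand_copy[i] >= 0:
                    continue
                for j in range(top.n_atoms):
                    if top.ligand_copy[j] < 0:
                        continue
                    if np.linalg.norm(coords[i] - coords[j]) <= 0.4:
                        expected.add((int(top.res_id[i]), int(top.ligand_copy[j])))
            assert ct.residue_contact_set(coords, top, 0.4) == expected


class TestOccupancy:
    @staticmethod
    def frames_with_contact(n_frames, contact_frames):
        """One residue + one 2-atom ligand; ligand near residue 1 in
        the chosen frames, far otherwise."""
        top = toy_topology(n_res=1)
        frames = np.zeros((n_frames, top.n_atoms, 3))
        for t in range(n_frames):
            frames[t, 1:, 0] = 0.3 if t in contact_frames else 30.0
        return ct.TrajectoryEnsemble(top, [frames])

    def test_fractional_occupancy(self):
        ens = self.frames_with_contact(10, {0, 4, 7})
        assert ct.occupancy(ens).as_dict()[1] == pytest.approx(0.3)

    def test_full_occupancy(self):
        ens = self.frames_with_contact(5, set(range(5)))
        assert ct.occupancy(ens).as_dict()[1] == 1.0

    def test_replicate_order_and_copy_label_invariance(self, default_ensemble):
        ens = default_ensemble
        base = ct.occupancy(ens)
        flipped = ct.TrajectoryEnsemble(ens.topology, ens.replicates[::-1],
                                        ens.ground_truth)
        np.testing.assert_allclose(base.occupancy, ct.occupancy(flipped).occupancy)
        # relabel ligand copies (permute copy indices)
        top = ens.topology
        perm = {c: (c + 1) % 5 for c in range(5)}
        new_copy = np.array([perm.get(int(c), -1) if c >= 0 else -1
                             for c in top.ligand_copy])
        relabeled_top = ct.Topology(top.atom_name, top.element, top.res_id,
                                    top.res_name, top.chain_id, new_copy, top.moiety)
        relabeled = ct.TrajectoryEnsemble(relabeled_top, ens.replicates)
        np.testing.assert_allclose(base.occupancy, ct.occupancy(relabeled).occupancy)

    def test_pooled_equals_mean_for_equal_length_replicates(self, default_ensemble):
        a = ct.occupancy(default_ensemble, aggregation="pooled")
        b = ct.occupancy(default_ensemble, aggregation="per_replicate_mean")
        np.testing.assert_allclose(a.occupancy, b.occupancy)


class TestBindingResidues:
    def make_table(self, occ):
        res = np.arange(1, len(occ) + 1)
        return ct.OccupancyTable(res, np.asarray(occ), 100, 0.4, "pooled")

    def test_strictly_greater_than_threshold(self):
        table = self.make_table([0.30, 0.31, 0.29])
        assert ct.binding_residues(table, 0.30) == {2}

    def test_all_zero_empty(self):
        assert ct.binding_residues(self.make_table([0.0, 0.0])) == set()

    def test_threshold_sweep_is_monotone(self):
        rng = np.random.default_rng(3)
        table = self.make_table(rng.uniform(0, 1, 50))
        sets = [ct.binding_residues(table, t) for t in (0.1, 0.3, 0.5, 0.9)]
        for large, small in zip(sets, sets[1:]):
            assert large >= small


class TestMoietyProfile:
    def test_far_ligand_all_zero(self):
        top = toy_topology()
        coords = np.zeros((5, 3))
        coords[3:, 0] = 100.0
        ens = ct.TrajectoryEnsemble(top, [coords[None]])
        profile = ct.moiety_interaction_profile(ens)
        assert all(v == 0.0 for v in profile.probabilities.values())

    def test_ring_only_contact_by_construction(self):
        """Ring atom touching, carbonyl atom far -> ring=1, carbonyl=0."""
        top = toy_topology()          # ligand atoms labelled ring, carbonyl
        coords = np.zeros((1, 5, 3))
        coords[0, :3, 0] = [0.0, 5.0, 10.0]
        coords[0, 3] = [0.3, 0.0, 0.0]    # ring
        coords[0, 4] = [3.0, 0.0, 0.0]    # carbonyl
        ens = ct.TrajectoryEnsemble(top, [coords])
        p = ct.moiety_interaction_profile(ens).probabilities
        assert p["ring"] == 1.0 and p["carbonyl"] == 0.0

    def test_probabilities_bounded_by_any_contact(self, default_ensemble):
        cond = ct.moiety_interaction_profile(default_ensemble, conditional=False)
        ens = default_ensemble
        # any-contact probability over (frame, copy) pairs
        n_pairs = n_hit = 0
        for rep in ens.replicates:
            for frame in rep:
                touched = {c for _, c in ct.residue_contact_set(frame, ens.topology)}
                n_pairs += 5
                n_hit += len(touched)
        any_p = n_hit / n_pairs
        for v in cond.probabilities.values():
            assert v <= any_p + 1e-12

    def test_missing_moiety_labels_rejected(self):
        top = toy_topology()
        blank = ct.Topology(top.atom_name, top.element, top.res_id, top.res_name,
                            top.chain_id, np.full(top.n_atoms, -1),
                            np.full(top.n_atoms, ""))
        ens = ct.TrajectoryEnsemble(blank, [np.zeros((1, top.n_atoms, 3))])
        with pytest.raises(ValueError):
            ct.moiety_interaction_profile(ens)


class TestHBonds:
    @staticmethod
    def hb_topology(with_h):
        """Ligand carboxyl O-H (donor) vs a protein SER bead/oxygen."""
        names = ["OG", "OX1"] + (["HX"] if with_h else [])
        n = len(names)
        return ct.Topology(
            atom_name=np.array(names),
            element=np.array(["O", "O"] + (["H"] if with_h else [])),
            res_id=np.array([1] + [1] * (n - 1)),
            res_name=np.array(["SER"] + ["ALF"] * (n - 1)),
            chain_id=np.array(["A"] + ["B"] * (n - 1)),
            ligand_copy=np.array([-1] + [0] * (n - 1)),
            moiety=np.array([""] + ["carboxyl"] * (n - 1)),
        )

    def test_good_geometry_detected(self):
        top = self.hb_topology(with_h=True)
        # donor O at 0.28 nm from acceptor, H on the line (angle 180)
        coords = np.array([[0.0, 0.0, 0.0], [0.28, 0.0, 0.0], [0.18, 0.0, 0.0]])
        hbs = ct.detect_hbonds(coords, top)
        assert len(hbs) == 1
        assert hbs[0].angle_deg > 120.0

    def test_long_distance_rejected(self):
        top = self.hb_topology(with_h=True)
        coords = np.array([[0.0, 0.0, 0.0], [0.40, 0.0, 0.0], [0.30, 0.0, 0.0]])
        assert ct.detect_hbonds(coords, top) == []

    def test_bad_angle_rejected(self):
        top = self.hb_topology(with_h=True)
        # H placed sideways: donor-H-acceptor angle ~90 degrees
        coords = np.array([[0.0, 0.0, 0.0], [0.28, 0.0, 0.0], [0.14, 0.14, 0.0]])
        assert ct.detect_hbonds(coords, top) == []

    def test_coarse_mode_distance_only(self):
        top = self.hb_topology(with_h=False)
        near = np.array([[0.0, 0.0, 0.0], [0.30, 0.0, 0.0]])
        far = np.array([[0.0, 0.0, 0.0], [0.33, 0.0, 0.0]])
        assert len(ct.detect_hbonds(near, top)) == 1
        assert ct.detect_hbonds(far, top) == []


class TestStructureMetrics:
    def test_identical_frames_zero_rmsd(self, default_ensemble):
        top = default_ensemble.topology
        frame = default_ensemble.replicates[0][0]
        ens = ct.TrajectoryEnsemble(top, [np.stack([frame, frame])])
        m = ct.structure_metrics(ens)[0]
        assert m.rmsd_nm[1] == pytest.approx(0.0, abs=1e-9)
        assert np.all(m.radius_of_gyration_nm > 0)

    def test_rigid_motion_invariance(self, default_ensemble):
        from scipy.spatial.transform import Rotation
        top = default_ensemble.topology
        frame = default_ensemble.replicates[0][0]
        rot = Rotation.from_euler("xyz", [0.3, -1.0, 2.2])
        moved = rot.apply(frame) + np.array([1.0, -2.0, 0.5])
        ens = ct.TrajectoryEnsemble(top, [np.stack([frame, moved])])
        assert ct.structure_metrics(ens)[0].rmsd_nm[1] == pytest.approx(0.0, abs=1e-6)

    def test_half_displacement_closed_form_without_superposition(self):
        """Half of N atoms shifted by d -> raw RMSD = d/sqrt(2)."""
        rng = np.random.default_rng(1)
        n = 40
        top = ct.Topology(
            atom_name=np.full(n, "CA"), element=np.full(n, "C"),
            res_id=np.arange(1, n + 1), res_name=np.full(n, "ALA"),
            chain_id=np.full(n, "A"), ligand_copy=np.full(n, -1),
            moiety=np.full(n, ""))
        frame0 = rng.normal(size=(n, 3))
        frame1 = frame0.copy()
        frame1[: n // 2, 0] += 0.1
        ens = ct.TrajectoryEnsemble(top, [np.stack([frame0, frame1])])
        m = ct.structure_metrics(ens, superpose=False)[0]
        assert m.rmsd_nm[1] == pytest.approx(0.1 / np.sqrt(2), rel=1e-12)


class TestTrpReport:
    def table(self, occ_by_res):
        res = np.array(sorted(occ_by_res))
        occ = np.array([occ_by_res[r] for r in res], dtype=float)
        return ct.OccupancyTable(res, occ, 100, 0.4, "pooled")

    def topo(self, trp_res, n=5):
        names = np.array(["ALA"] * n)
        for r in trp_res:
            names[r - 1] = "TRP"
        return ct.Topology(
            atom_name=np.full(n, "CA"), element=np.full(n, "C"),
            res_id=np.arange(1, n + 1), res_name=names,
            chain_id=np.full(n, "A"), ligand_copy=np.full(n, -1),
            moiety=np.full(n, ""))

    def test_one_of_two_trp_binding_predicts_half(self):
        rep = ct.trp_report(self.table({1: 0.5, 2: 0.1, 3: 0.0, 4: 0.0, 5: 0.0}),
                            self.topo([1, 2]))
        assert rep["predicted_fb"] == 0.5
        assert rep["binding_trp_residues"] == [1]

    def test_no_binding_trp(self):
        rep = ct.trp_report(self.table({1: 0.1, 2: 0.2, 3: 0, 4: 0, 5: 0}),
                            self.topo([1, 2]))
        assert rep["predicted_fb"] == 0.0

    def test_all_trp_binding(self):
        rep = ct.trp_report(self.table({1: 0.9, 2: 0.8, 3: 0, 4: 0, 5: 0}),
                            self.topo([1, 2]))
        assert rep["predicted_fb"] == 1.0

    def test_no_trp_rejected(self):
        with pytest.raises(ValueError):
            ct.trp_report(self.table({1: 0.5}), self.topo([]))
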