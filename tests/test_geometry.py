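"""Center-of-mass geometry, contact numbers, and contact maps against
brute-force oracles and rigid-motion invariance."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from abensemble.core import Ensemble
from abensemble.geometry import (
    center_of_mass,
    contact_map,
    contact_number,
    nt_cm_distance,
    radius_of_gyration,
    residue_cm_distances,
)
from abensemble.synthetic import GeneratorConfig, gen_dimer_ensemble

from conftest import make_conformation, random_rigid_motion


def brute_force_cm(conf):
    num = np.zeros(3)
    tot = 0.0
    for m, xyz in zip(conf.mass, conf.coords):
        num += m * xyz
        tot += m
    return num / tot


def brute_force_contacts(conf, cutoff):
    ca1, ca2 = conf.ca_coords(1), conf.ca_coords(2)
    count = 0
    for a in ca1:
        for b in ca2:
            if np.linalg.norm(a - b) < cutoff:
                count += 1
    return count


class TestCenterOfMassAndRg:
    def test_single_atom(self):
        conf = make_conformation([[1.0, 2.0, 3.0]])
        assert np.allclose(center_of_mass(conf), [1, 2, 3])
        assert radius_of_gyration(conf) == pytest.approx(0.0, abs=1e-12)

    def test_equal_masses_midpoint(self):
        conf = make_conformation([[0, 0, 0], [2, 0, 0]], residue_index=[1, 2])
        assert np.allclose(center_of_mass(conf), [1, 0, 0])
        assert np.isclose(radius_of_gyration(conf), 1.0)

    def test_matches_direct_sum(self, rng=np.random.default_rng(42)):
        coords = rng.normal(scale=8.0, size=(100, 3))
        elements = rng.choice(["C", "N", "O", "S"], size=100)
        conf = make_conformation(coords, element=elements,
                                 residue_index=np.arange(1, 101) % 42 + 1)
        assert np.allclose(center_of_mass(conf), brute_force_cm(conf),
                           atol=1e-10)
        cm = brute_force_cm(conf)
        rg = np.sqrt(np.sum(conf.mass * np.sum((coords - cm) ** 2, axis=1))
                     / conf.mass.sum())
        assert np.isclose(radius_of_gyration(conf), rg, atol=1e-10)

    def test_empty_selection_errors(self):
        conf = make_conformation([[0, 0, 0]])
        with pytest.raises(ValueError, match="empty"):
            center_of_mass(conf, lambda c: np.zeros(1, dtype=bool))


class TestResidueCmDistances:
    def test_coincident_atoms_give_zero(self):
        frame = make_conformation(np.zeros((3, 3)))
        ens = Ensemble([[frame], [frame]], 50.0, (0.0, 50.0))
        prof = residue_cm_distances(ens)
        assert np.allclose(prof.values, 0.0)

    def test_linear_trimer_symmetry(self):
        frame = make_conformation([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        ens = Ensemble([[frame], [frame]], 50.0, (0.0, 50.0))
        prof = residue_cm_distances(ens)
        assert np.allclose(prof.values, [1, 0, 1])

    def test_matches_per_frame_loop(self, small_dimer_ensemble):
        prof = residue_cm_distances(small_dimer_ensemble)
        # brute force: per trajectory, per frame, per residue, mean of the
        # two peptides' CA distances from the assembly CM
        per_traj = []
        for traj in small_dimer_ensemble.trajectories:
            rows = []
            for f in traj:
                cm = brute_force_cm(f)
                vals = []
                for r in range(1, 41):
                    ds = []
                    for p in (1, 2):
                        mask = (f.peptide_id == p) & (f.residue_index == r) \
                            & (f.atom_name == "CA")
                        ds.append(np.linalg.norm(f.coords[mask][0] - cm))
                    vals.append(np.mean(ds))
                rows.append(vals)
            per_traj.append(np.mean(rows, axis=0))
        expected = np.mean(per_traj, axis=0)
        assert np.allclose(prof.values, expected, atol=1e-10)


class TestNtCmDistance:
    def test_three_four_five(self):
        coords = [[3.0, 4.0, 0.0], [-3.0, -4.0, 0.0]]
        conf = make_conformation(coords, residue_index=[1, 2])
        assert np.isclose(nt_cm_distance(conf)[0], 5.0)

    def test_mirror_symmetric_dimer(self):
        chain = np.array([[4.0, 0, 0], [8.0, 1.0, 0]])
        coords = np.vstack([chain, -chain])
        conf = make_conformation(coords, residue_index=[1, 2, 1, 2],
                                 peptide_id=[1, 1, 2, 2])
        d = nt_cm_distance(conf)
        assert np.isclose(d[0], d[1])

    def test_exposure_biased_dimer(self, small_dimer_ensemble):
        hits = 0
        frames = small_dimer_ensemble.frames_flat()
        for f in frames:
            cm = center_of_mass(f)
            nt = nt_cm_distance(f).mean()
            ct_mask = f.ca_mask() & (f.residue_index == 40)
            ct = np.linalg.norm(f.coords[ct_mask] - cm, axis=1).mean()
            hits += nt > ct
        assert hits / len(frames) >= 0.95


class TestContactNumber:
    def test_separated_peptides(self):
        coords = [[0, 0, 0], [100, 0, 0]]
        conf = make_conformation(coords, peptide_id=[1, 2],
                                 residue_index=[1, 1])
        assert contact_number(conf, 7.5) == 0

    def test_complete_bipartite(self):
        # all cross distances exactly 5 A with cutoff 7.5: 3x3 = 9 contacts
        a = np.array([[0.0, 0, 0], [0, 0, 0], [0, 0, 0]])
        b = a + np.array([5.0, 0, 0])
        conf = make_conformation(np.vstack([a, b]),
                                 peptide_id=[1, 1, 1, 2, 2, 2],
                                 residue_index=[1, 2, 3, 1, 2, 3])
        assert contact_number(conf, 7.5) == 9

    def test_monomer_errors(self):
        conf = make_conformation([[0, 0, 0]])
        with pytest.raises(ValueError, match="dimer"):
            contact_number(conf, 7.5)

    def test_matches_double_loop(self, small_dimer_ensemble):
        for f in small_dimer_ensemble.frames_flat()[:5]:
            assert contact_number(f, 7.5) == brute_force_contacts(f, 7.5)

    def test_monotone_in_cutoff(self, small_dimer_ensemble):
        f = small_dimer_ensemble.frames_flat()[0]
        counts = [contact_number(f, c) for c in np.linspace(2.0, 15.0, 14)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_two_cutoff_robustness(self, ab40):
        """Ensembles built with no cross-peptide pair inside the cutoff gap
        give the same contact number at both check cutoffs."""
        cfg = GeneratorConfig(seed=29, n_trajectories=1,
                              frames_per_trajectory=5, compactness=10.0,
                              target_contact_number=12,
                              cutoff_gap=(7.5, 8.0))
        ens = gen_dimer_ensemble(cfg, ab40)
        for f in ens.frames():
            assert contact_number(f, 7.5) == contact_number(f, 8.0)


class TestContactMap:
    def test_frozen_ensemble_binary_with_zero_sem(self, small_dimer_ensemble):
        f = small_dimer_ensemble.frames_flat()[0]
        ens = Ensemble([[f], [f]], 50.0, (0.0, 50.0))
        cmap = contact_map(ens, 7.5, kind="inter")
        assert set(np.unique(cmap.matrix)) <= {0.0, 0.5, 1.0}
        assert np.allclose(cmap.sem, 0.0)

    def test_intra_map_symmetric(self, small_dimer_ensemble):
        cmap = contact_map(small_dimer_ensemble, 7.5, kind="intra")
        assert np.array_equal(cmap.matrix, cmap.matrix.T)

    def test_inter_map_symmetrized_over_chain_order(self,
                                                    small_dimer_ensemble):
        cmap = contact_map(small_dimer_ensemble, 7.5, kind="inter")
        assert np.allclose(cmap.matrix, cmap.matrix.T)

    def test_matches_frame_average(self, small_dimer_ensemble):
        sub = Ensemble([small_dimer_ensemble.trajectories[0]], 50.0,
                       small_dimer_ensemble.analysis_window)
        cmap = contact_map(sub, 7.5, kind="inter")
        mats = []
        for f in sub.frames():
            d = cdist(f.ca_coords(1), f.ca_coords(2))
            m = (d < 7.5).astype(float)
            mats.append(0.5 * (m + m.T))
        assert np.allclose(cmap.matrix, np.mean(mats, axis=0), atol=1e-12)

    def test_near_diagonal_saturated(self, small_monomer_ensemble):
        # |i-j| <= 1 entries are always in contact for a connected chain
        # when the cutoff exceeds the bond length
        cmap = contact_map(small_monomer_ensemble, 7.5, kind="intra")
        n = cmap.matrix.shape[0]
        for i in range(n - 1):
            assert cmap.matrix[i, i] == 1.0
            assert cmap.matrix[i, i + 1] == 1.0

    def test_values_in_unit_interval(self, small_dimer_ensemble):
        cmap = contact_map(small_dimer_ensemble, 7.5, kind="inter")
        assert cmap.matrix.min() >= 0.0 and cmap.matrix.max() <= 1.0


class TestRigidMotionInvariance:
    def test_distances_rg_contacts_invariant(self, small_dimer_ensemble):
        rng = np.random.default_rng(3)
        f = small_dimer_ensemble.frames_flat()[0]
        rot, trans = random_rigid_motion(rng)
        moved = f.with_coords(f.coords @ rot.T + trans)
        assert np.isclose(radius_of_gyration(moved), radius_of_gyration(f),
                          atol=1e-8)
        assert contact_number(moved, 7.5) == contact_number(f, 7.5)
        assert np.allclose(nt_cm_distance(moved), nt_cm_distance(f),
                           atol=1e-8)
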