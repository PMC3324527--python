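"""Synthetic-ensemble generators: construction guarantees, determinism,
and parameter recovery."""

import numpy as np
import pytest

from abensemble.core import AlloformSpec
from abensemble.geometry import contact_number, radius_of_gyration
from abensemble.saltbridges import saltbridge_propensity
from abensemble.synthetic import (
    GeneratorConfig,
    SaltBridgePairSpec,
    gen_cg_conformer,
    gen_dimer_ensemble,
    gen_monomer_ensemble,
    gen_saltbridge_telegraph,
    gen_water_shell,
)


def _gly_spec(n: int) -> AlloformSpec:
    return AlloformSpec(name="polyG", sequence="G" * n,
                        positive_residues=frozenset(),
                        negative_residues=frozenset(),
                        hydrophobic_residues=frozenset())


class TestMonomerGenerator:
    def test_unjittered_chain_has_exact_bonds(self, ab42):
        cfg = GeneratorConfig(seed=1, n_trajectories=1,
                              frames_per_trajectory=1, jitter=0.0)
        frame = gen_monomer_ensemble(cfg, ab42).frames_flat()[0]
        bonds = np.linalg.norm(np.diff(frame.ca_coords(), axis=0), axis=1)
        assert np.allclose(bonds, 3.8, atol=1e-6)

    def test_deterministic_under_fixed_seed(self, ab42):
        cfg = GeneratorConfig(seed=5, n_trajectories=2,
                              frames_per_trajectory=3)
        a = gen_monomer_ensemble(cfg, ab42)
        b = gen_monomer_ensemble(cfg, ab42)
        for fa, fb in zip(a.frames(), b.frames()):
            assert np.array_equal(fa.coords, fb.coords)

    def test_different_seeds_decorrelate(self, ab42):
        # Compare the chain step vectors: raw random-walk coordinates are
        # dominated by the (random) drift direction, so the informative
        # decorrelation measure is between increments.
        mk = lambda s: np.diff(gen_monomer_ensemble(
            GeneratorConfig(seed=s, n_trajectories=1,
                            frames_per_trajectory=1), ab42
        ).frames_flat()[0].ca_coords(), axis=0).ravel()
        a, b = mk(1), mk(2)
        corr = np.corrcoef(a, b)[0, 1]
        assert abs(corr) < 0.2

    def test_rg_rescaling_hits_target(self, ab42):
        cfg = GeneratorConfig(seed=3, n_trajectories=4,
                              frames_per_trajectory=50, compactness=9.0)
        ens = gen_monomer_ensemble(cfg, ab42)
        rgs = [radius_of_gyration(f) for f in ens.frames()]
        assert abs(np.mean(rgs) - 9.0) / 9.0 < 0.05

    def test_unattainable_compactness_errors(self, ab42):
        cfg = GeneratorConfig(seed=3, n_trajectories=1,
                              frames_per_trajectory=1, compactness=1.0)
        with pytest.raises(ValueError, match="close packing"):
            gen_monomer_ensemble(cfg, ab42)

    def test_frames_satisfy_conformation_invariants(self, ab42,
                                                    small_monomer_ensemble):
        for frame in small_monomer_ensemble.frames():
            frame.validate(ab42)


class TestDimerGenerator:
    def test_zero_contact_target_fully_separated(self, ab40):
        cfg = GeneratorConfig(seed=7, n_trajectories=1,
                              frames_per_trajectory=3,
                              target_contact_number=0, compactness=10.0)
        for frame in gen_dimer_ensemble(cfg, ab40).frames():
            assert contact_number(frame, cutoff=7.5) == 0

    def test_contact_target_within_two(self, small_dimer_ensemble):
        for frame in small_dimer_ensemble.frames():
            assert 13 <= contact_number(frame, cutoff=7.5) <= 17

    def test_infeasible_contact_target_errors(self, ab40):
        cfg = GeneratorConfig(seed=7, target_contact_number=40 * 40 + 1)
        with pytest.raises(ValueError, match="infeasible"):
            gen_dimer_ensemble(cfg, ab40)

    def test_nt_exposure_bias(self, small_dimer_ensemble):
        """N-terminal residues sit farther from the assembly CM than the
        C-terminal residues in at least 95% of frames."""
        from abensemble.geometry import center_of_mass

        hits = 0
        frames = small_dimer_ensemble.frames_flat()
        for frame in frames:
            cm = center_of_mass(frame)
            ca = frame.ca_mask()
            d = np.linalg.norm(frame.coords[ca] - cm, axis=1)
            res = frame.residue_index[ca]
            n_res = res.max()
            nt = d[res <= 5].mean()
            ct = d[res > n_res - 5].mean()
            hits += nt > ct
        assert hits / len(frames) >= 0.95

    def test_frames_satisfy_invariants(self, ab40, small_dimer_ensemble):
        for frame in small_dimer_ensemble.frames():
            frame.validate(ab40)


class TestTelegraphSaltBridges:
    def _ensemble(self, ab42, p, n_traj=4, frames=150, seed=31):
        cfg = GeneratorConfig(
            seed=seed, n_trajectories=n_traj, frames_per_trajectory=frames,
            saltbridge_spec=[SaltBridgePairSpec(5, 1, p, 5.0)])
        base = gen_monomer_ensemble(cfg, ab42)
        return gen_saltbridge_telegraph(cfg, base)

    @pytest.mark.parametrize("p,expected", [(1.0, 100.0), (0.0, 0.0)])
    def test_degenerate_occupancies(self, ab42, p, expected):
        ens = self._ensemble(ab42, p, n_traj=2, frames=30)
        pair = next(q for q in saltbridge_propensity(ens)
                    if (q.positive, q.negative) == (5, 1))
        assert pair.intra == expected

    def test_occupancy_recovery_within_three_se(self, ab42):
        ens = self._ensemble(ab42, 0.65, n_traj=6, frames=300)
        pair = next(q for q in saltbridge_propensity(ens)
                    if (q.positive, q.negative) == (5, 1))
        assert abs(pair.intra - 65.0) <= 3.0 * pair.intra_sem

    def test_estimator_unbiased_over_replicates(self, ab42):
        """Mean estimate over replicate seeds lies within one standard error
        of the mean of the true occupancy."""
        p = 0.5
        estimates = []
        for rep in range(20):
            ens = self._ensemble(ab42, p, n_traj=3, frames=100,
                                 seed=1000 + rep)
            pair = next(q for q in saltbridge_propensity(ens)
                        if (q.positive, q.negative) == (5, 1))
            estimates.append(pair.intra)
        se_of_mean = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - 100.0 * p) <= se_of_mean * 1.0 + 1e-12

    def test_invalid_occupancy_rejected(self):
        with pytest.raises(ValueError, match="occupancy"):
            SaltBridgePairSpec(5, 1, 1.5)


class TestWaterShell:
    def test_count_matches_poisson_expectation(self, ab42):
        cfg = GeneratorConfig(seed=9, water_density=0.01, box_radius=25.0)
        frame = gen_monomer_ensemble(
            GeneratorConfig(seed=9, n_trajectories=1, frames_per_trajectory=1),
            ab42).frames_flat()[0]
        waters = gen_water_shell(cfg, frame)
        v_box = (2 * cfg.box_radius) ** 3
        # accessible volume: box minus the (small) excluded shell volume
        excluded = frame.n_atoms * 4.0 / 3.0 * np.pi * 2.6 ** 3
        expected = cfg.water_density * (v_box - excluded)
        assert abs(len(waters) - expected) <= 3.5 * np.sqrt(expected)
        # no water sits inside the exclusion zone
        from scipy.spatial.distance import cdist
        d = cdist(waters, frame.coords[frame.heavy_mask()]).min(axis=1)
        assert d.min() >= 2.6

    def test_zero_density_empty(self):
        cfg = GeneratorConfig(seed=9, water_density=0.0)
        assert len(gen_water_shell(cfg, None)) == 0

    def test_excessive_density_refused(self):
        cfg = GeneratorConfig(seed=9, water_density=10.0, box_radius=50.0)
        with pytest.raises(ValueError, match="refusing"):
            gen_water_shell(cfg, None)


class TestFourBeadGenerator:
    def test_gly_only_chain_has_no_sidechain_beads(self):
        cfg = GeneratorConfig(seed=17)
        cg = gen_cg_conformer(cfg, _gly_spec(8))
        assert not np.any(cg.atom_name == "CB")
        assert cg.n_atoms == 3 * 8

    def test_bead_count_formula(self, ab40):
        cfg = GeneratorConfig(seed=17)
        cg = gen_cg_conformer(cfg, ab40)
        n_non_gly = sum(1 for c in ab40.sequence if c != "G")
        assert cg.n_atoms == 3 * 40 + n_non_gly
        assert np.count_nonzero(cg.atom_name == "CA") == 40

    def test_reproducible(self, ab40):
        cfg = GeneratorConfig(seed=23)
        a = gen_cg_conformer(cfg, ab40)
        b = gen_cg_conformer(cfg, ab40)
        assert np.array_equal(a.coords, b.coords)
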