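"""Superposition, RMSD/RMSF, distances, H-bond occupancy, significance tests."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gsmech import (
    Ensemble,
    Frame,
    HBondCriteria,
    core_region,
    distance_series,
    hbond_events,
    occupancy,
    one_sample_t,
    rmsd_series,
    rmsf,
    salt_bridge_occupancy,
    superpose,
    t_test_two_sided,
    welch_test,
)
from gsmech.synth import GeneratorSpec, gen_harmonic_ensemble
from gsmech.topology import Topology

from conftest import make_static_ensemble


class TestSuperpose:
    def test_identity(self, ca_chain):
        _, ref = ca_chain
        res = superpose(ref, ref)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-8)

    def test_translation_removed(self, ca_chain):
        _, ref = ca_chain
        moved = ref.coords + np.array([5.0, 0.0, 0.0])
        assert superpose(moved, ref).rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self, ca_chain):
        """RMSD is invariant under any proper rigid motion of the mobile set."""
        _, ref = ca_chain
        mobile = ref.coords + np.random.default_rng(0).normal(
            scale=0.3, size=ref.coords.shape)
        base = superpose(mobile, ref.coords).rmsd
        for seed in range(10):
            rot = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
            trans = np.random.default_rng(seed + 100).normal(scale=10, size=3)
            assert superpose(mobile @ rot.T + trans, ref.coords).rmsd == \
                pytest.approx(base, abs=1e-8)

    def test_grid_search_oracle(self):
        """Kabsch result matches brute-force minimization over rotations."""
        ref = np.array([[0.0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2]])
        mobile = ref.copy()
        mobile[3] = [0.4, 0.3, 2.2]
        best = superpose(mobile, ref).rmsd

        def rmsd_at(rotvec):
            rot = Rotation.from_rotvec(rotvec).as_matrix()
            moved = (mobile - mobile.mean(0)) @ rot.T
            target = ref - ref.mean(0)
            return np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1)))

        # coarse sweep, then refinement around the best cell
        angles = np.linspace(-0.3, 0.3, 13)
        coarse = min(
            ((rmsd_at(np.array([a, b, c])), (a, b, c))
             for a in angles for b in angles for c in angles))
        center = np.asarray(coarse[1])
        fine = np.linspace(-0.03, 0.03, 13)
        grid_best = min(
            rmsd_at(center + np.array([a, b, c]))
            for a in fine for b in fine for c in fine)
        assert best <= grid_best + 1e-9
        assert grid_best - best < 1e-3

    def test_collinear_rejected(self):
        line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line + 1.0)


class TestRMSDSeries:
    def test_static_zeros(self, ca_chain):
        topo, ref = ca_chain
        ens = make_static_ensemble(topo, ref.coords, n_frames=4)
        series, stat = rmsd_series(ens, np.arange(topo.n_atoms))
        assert np.allclose(series["rep1"], 0.0, atol=1e-9)
        assert stat.grand_mean == pytest.approx(0.0, abs=1e-9)

    def test_comoving_ligand_zero_after_fit(self, ca_chain):
        topo, ref = ca_chain
        rng = np.random.default_rng(1)
        frames = []
        for _ in range(5):
            rot = Rotation.random(rng=rng).as_matrix()
            frames.append(ref.coords @ rot.T + rng.normal(scale=5, size=3))
        ens = Ensemble(topo, {"rep1": np.stack(frames)})
        protein = np.arange(20)
        ligand = np.arange(20, 30)
        series, _ = rmsd_series(ens, protein, ligand, reference=ref)
        assert np.allclose(series["rep1"], 0.0, atol=1e-8)

    def test_gaussian_closed_form(self, ca_chain):
        """Mean RMSD of a sigma-cloud approaches sigma*sqrt(3)."""
        topo, ref = ca_chain
        ens, _ = gen_harmonic_ensemble(
            GeneratorSpec(seed=3, n_frames=800), topo, ref,
            np.full(topo.n_atoms, 0.5))
        _, stat = rmsd_series(ens, np.arange(topo.n_atoms), reference=ref.coords)
        # fitting absorbs ~6 of 3N degrees of freedom
        expected = 0.5 * np.sqrt(3.0) * np.sqrt(1 - 2.0 / topo.n_atoms)
        assert stat.grand_mean == pytest.approx(expected, rel=0.05)


class TestRMSF:
    def test_static_zero(self, ca_chain):
        topo, ref = ca_chain
        ens = make_static_ensemble(topo, ref.coords, n_frames=3)
        profiles, _ = rmsf(ens)
        assert np.allclose(profiles["rep1"], 0.0, atol=1e-9)

    def test_heterogeneous_profile_recovery(self):
        """Designed per-atom amplitudes recovered within 5% at 2000 frames.

        The fixture is large enough (120 atoms) that the degrees of
        freedom absorbed by the mean-structure fit stay negligible.
        """
        n = 120
        topo = Topology(
            atom_names=np.array(["CA"] * n), elements=np.array(["C"] * n),
            res_ids=np.arange(1, n + 1), res_names=np.array(["ALA"] * n),
            chain_ids=np.array(["A"] * n))
        t = np.arange(n)
        ref = Frame(np.stack(
            [2.3 * np.cos(t * 0.6), 2.3 * np.sin(t * 0.6), 1.5 * t], axis=1))
        design = np.linspace(0.4, 1.2, n)
        ens, _ = gen_harmonic_ensemble(
            GeneratorSpec(seed=4, n_frames=2000), topo, ref,
            design / np.sqrt(3.0))
        profiles, _ = rmsf(ens)
        np.testing.assert_allclose(profiles["rep1"], design, rtol=0.05)

    def test_mobility_contrast_recovery(self, ca_chain):
        """Amplitudes 0.74 vs 1.00 A stay separable with replicate SEM."""
        topo, ref = ca_chain
        recovered = {}
        for i, amp in enumerate((0.74, 1.00)):
            ens, _ = gen_harmonic_ensemble(
                GeneratorSpec(seed=5 + i, n_frames=1500, n_replicates=3),
                topo, ref, np.full(topo.n_atoms, amp / np.sqrt(3.0)))
            _, per_res = rmsf(ens, per="residue")
            recovered[amp] = np.mean([s.grand_mean for s in per_res])
        assert recovered[0.74] == pytest.approx(0.74, rel=0.05)
        assert recovered[1.00] == pytest.approx(1.00, rel=0.05)
        assert recovered[1.00] > recovered[0.74]

    def test_single_frame_rejected(self, ca_chain):
        topo, ref = ca_chain
        ens = make_static_ensemble(topo, ref.coords, n_frames=1)
        with pytest.raises(ValueError):
            rmsf(ens)


class TestCoreRegion:
    def test_lowest_ninety_percent(self):
        vals = np.arange(10, dtype=float)[::-1]   # residue 10 has lowest RMSF
        kept = core_region(vals, keep_fraction=0.9)
        assert len(kept) == 9
        assert 1 not in kept        # the single highest-RMSF residue dropped

    def test_full_fraction_keeps_all(self):
        assert len(core_region(np.ones(7), keep_fraction=1.0)) == 7

    def test_tie_break_by_serial(self):
        kept = core_region(np.ones(10), keep_fraction=0.9)
        assert list(kept) == list(range(1, 10))


class TestDistances:
    def test_fixed_pair(self, mini_topology):
        coords = np.zeros((7, 3))
        coords[5] = [3.06, 0, 0]
        ens = make_static_ensemble(mini_topology, coords, n_frames=6)
        _, stat = distance_series(ens, np.array([0]), np.array([5]))
        assert stat.grand_mean == pytest.approx(3.06)
        assert stat.sem == 0.0

    def test_same_group_centroid_zero(self, mini_topology):
        coords = np.random.default_rng(0).normal(size=(7, 3))
        ens = make_static_ensemble(mini_topology, coords)
        with pytest.warns(UserWarning, match="overlap"):
            _, stat = distance_series(ens, np.arange(3), np.arange(3))
        assert stat.grand_mean == pytest.approx(0.0, abs=1e-12)

    def test_min_mode_matches_brute_force(self, mini_topology):
        coords = np.random.default_rng(2).normal(scale=4, size=(7, 3))
        ens = make_static_ensemble(mini_topology, coords, n_frames=1)
        ga, gb = np.array([0, 1, 2]), np.array([5, 6])
        series, _ = distance_series(ens, ga, gb, mode="min")
        brute = min(np.linalg.norm(coords[a] - coords[b]) for a in ga for b in gb)
        assert series["rep1"][0] == pytest.approx(brute)


def _hbond_fixture(d, angle_deg_):
    """donor O with one H, acceptor O at distance d, donor-H-acceptor angle."""
    topo = Topology(
        atom_names=np.array(["OG", "HG", "OX"]),
        elements=np.array(["O", "H", "O"]),
        res_ids=np.array([1, 1, 2]),
        res_names=np.array(["SER", "SER", "HOH"]),
        chain_ids=np.array(["A", "A", "W"]),
    )
    # triangle construction with the requested angle at the hydrogen vertex:
    # H at origin, donor 0.96 A away, acceptor on the alpha-ray with the
    # length solving |D - A| = d (law of cosines)
    alpha = np.radians(angle_deg_)
    hd = 0.96
    ha = hd * np.cos(alpha) + np.sqrt(d ** 2 - hd ** 2 * np.sin(alpha) ** 2)
    h = np.zeros(3)
    donor = np.array([hd, 0.0, 0.0])
    acceptor = ha * np.array([np.cos(alpha), np.sin(alpha), 0.0])
    assert np.linalg.norm(donor - acceptor) == pytest.approx(d)
    coords = np.stack([donor, h, acceptor])
    return topo, make_static_ensemble(topo, coords, n_frames=1)


class TestHBonds:
    @pytest.mark.parametrize("d,angle,expected", [
        (2.7, 150.0, {"strong"}),
        (3.0, 150.0, {"weak"}),
        (2.7, 100.0, set()),
        (2.8, 120.0, {"strong"}),      # boundaries inclusive
        (3.2, 120.0, {"weak"}),
    ])
    def test_criteria_classes(self, d, angle, expected):
        topo, ens = _hbond_fixture(d, angle)
        events = hbond_events(ens, np.array([0]), np.array([2]))
        assert {e.hbond_class for e in events} == expected

    def test_strong_nests_in_weak_occupancy(self):
        topo, ens = _hbond_fixture(2.7, 170.0)
        events = hbond_events(ens, np.array([0]), np.array([2]))
        weak = occupancy(events, 1, ens.labels)
        strong = occupancy(events, 1, ens.labels, strong_only=True)
        assert strong.grand_mean <= weak.grand_mean
        assert weak.grand_mean == 1.0

    def test_missing_hydrogen_distance_fallback(self):
        topo = Topology(
            atom_names=np.array(["OG", "OX"]), elements=np.array(["O", "O"]),
            res_ids=np.array([1, 2]), res_names=np.array(["SER", "HOH"]),
            chain_ids=np.array(["A", "W"]),
        )
        coords = np.array([[0.0, 0, 0], [2.7, 0, 0]])
        ens = make_static_ensemble(topo, coords, n_frames=1)
        with pytest.warns(UserWarning, match="distance-only"):
            events = hbond_events(ens, np.array([0]), np.array([1]))
        assert len(events) == 1

    def test_occupancy_fractions(self):
        series = {"rep1": np.array([1, 1, 0, 0], dtype=bool)}
        assert occupancy(series, 4).grand_mean == 0.5
        assert occupancy({"rep1": np.ones(4, bool)}, 4).grand_mean == 1.0
        assert occupancy({"rep1": np.zeros(4, bool)}, 4).grand_mean == 0.0


class TestSaltBridge:
    def _ens(self, d):
        topo = Topology(
            atom_names=np.array(["NH1", "OD1"]), elements=np.array(["N", "O"]),
            res_ids=np.array([1, 2]), res_names=np.array(["ARG", "ASP"]),
            chain_ids=np.array(["A", "A"]),
        )
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        return make_static_ensemble(topo, coords, n_frames=2)

    def test_close_pair_fully_occupied(self):
        stat = salt_bridge_occupancy(self._ens(2.63), [0], [1])
        assert stat.grand_mean == 1.0

    def test_boundary_strict(self):
        assert salt_bridge_occupancy(self._ens(4.0), [0], [1]).grand_mean == 0.0

    def test_alternating_half(self):
        topo = self._ens(3.0).topology
        coords = np.zeros((4, 2, 3))
        coords[:, 1, 0] = [3.0, 5.0, 3.0, 5.0]
        ens = Ensemble(topo, {"rep1": coords})
        assert salt_bridge_occupancy(ens, [0], [1]).grand_mean == 0.5


class TestSignificance:
    def test_identical_samples(self):
        t, p = t_test_two_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)
        t, p = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_one_sample_closed_form(self):
        sample = [2.0, 2.1, 1.9]
        t, p = one_sample_t(sample, 0.0)
        expected_t = np.mean(sample) / (np.std(sample, ddof=1) / np.sqrt(3))
        assert t == pytest.approx(expected_t)
        assert p < 0.05

    def test_zero_variance_cases(self):
        t, p = t_test_two_sided([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0
        with pytest.raises(ValueError):
            t_test_two_sided([1.0, 1.0], [2.0, 2.0])

    def test_sem_shrinks_with_replicates(self, ca_chain):
        """Replicate SEM of identical generators scales like 1/sqrt(n)."""
        topo, ref = ca_chain
        sems = []
        for n_rep in (3, 12):
            ens, _ = gen_harmonic_ensemble(
                GeneratorSpec(seed=8, n_frames=150, n_replicates=n_rep),
                topo, ref, np.full(topo.n_atoms, 0.5))
            _, per_res = rmsf(ens, per="residue")
            sems.append(np.mean([s.sem for s in per_res]))
        assert sems[1] < sems[0]
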