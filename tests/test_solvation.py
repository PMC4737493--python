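"""Density grids, radial distributions, and water-bridge detection."""

import itertools

import numpy as np
import pytest

from gsmech import (
    Ensemble,
    HBondCriteria,
    bridge_frequency,
    density_grid,
    find_bridges,
    isopleth_threshold,
    rdf,
    select,
    write_opendx,
)
from gsmech.criteria import GEOMETRY_EPS, angle_deg
from gsmech.solvation import _link_ok, _hydrogens_by_heavy
from gsmech.synth import GeneratorSpec, gen_bridge_site
from gsmech.topology import Topology

from conftest import make_static_ensemble


def _water_box(n_waters, box, n_frames, seed=0, center=True):
    names = ["X"] + ["O", "H1", "H2"] * n_waters
    elements = ["C"] + ["O", "H", "H"] * n_waters
    res_ids = [1] + [i // 3 + 2 for i in range(3 * n_waters)]
    res_names = ["CEN"] + ["HOH"] * (3 * n_waters)
    chains = ["A"] + ["W"] * (3 * n_waters)
    topo = Topology(
        atom_names=np.array(names), elements=np.array(elements),
        res_ids=np.array(res_ids), res_names=np.array(res_names),
        chain_ids=np.array(chains), box=np.array([box] * 3))
    rng = np.random.default_rng(seed)
    frames = np.zeros((n_frames, topo.n_atoms, 3))
    frames[:, 0] = box / 2.0
    ox = rng.uniform(0, box, size=(n_frames, n_waters, 3))
    frames[:, 1::3] = ox
    frames[:, 2::3] = ox + [0.96, 0, 0]
    frames[:, 3::3] = ox + [-0.24, 0.93, 0]
    return topo, Ensemble(topo, {"rep1": frames})


class TestDensityGrid:
    def test_single_fixed_water_counting(self):
        topo, ens = _water_box(1, 20.0, 10, seed=1)
        coords = ens.replicates["rep1"].copy()
        coords[:, 1] = [5.0, 5.0, 5.0]
        ens = Ensemble(topo, {"rep1": coords})
        grids = density_grid(ens, select(topo, "water and element O"),
                             (np.zeros(3), np.full(3, 10.0)))
        g = grids["rep1"]
        assert g.total == 10
        assert g.counts.max() == 10

    def test_empty_selection_zero_grid(self):
        topo, ens = _water_box(2, 20.0, 3)
        grids = density_grid(ens, np.array([], dtype=int),
                             (np.zeros(3), np.full(3, 10.0)))
        assert grids["rep1"].total == 0

    def test_count_conservation(self):
        """Sum of cell counts equals in-bounds (water, frame) incidences."""
        topo, ens = _water_box(20, 12.0, 8, seed=3)
        waters = select(topo, "water and element O")
        lo, hi = np.full(3, 2.0), np.full(3, 9.0)
        grids = density_grid(ens, waters, (lo, hi), spacing=0.5)
        g = grids["rep1"]
        coords = ens.replicates["rep1"][:, waters]
        origin = g.origin
        upper = origin + np.array(g.shape) * 0.5
        inside = np.all((coords >= origin) & (coords < upper), axis=-1)
        assert g.total == int(inside.sum())

    def test_poisson_cell_statistics(self):
        """Uniform waters give Poisson-consistent cell counts (chi^2)."""
        from scipy import stats as sps
        topo, ens = _water_box(40, 10.0, 50, seed=5)
        waters = select(topo, "water and element O")
        grids = density_grid(ens, waters, (np.zeros(3), np.full(3, 10.0)),
                             spacing=2.0)
        counts = grids["rep1"].counts.ravel()
        lam = counts.mean()
        # bin into 0..k-1, k+; compare against Poisson expectation
        kmax = int(sps.poisson.ppf(0.995, lam))
        observed = np.array([np.sum(counts == k) for k in range(kmax)]
                            + [np.sum(counts >= kmax)])
        expected = len(counts) * np.append(
            sps.poisson.pmf(np.arange(kmax), lam),
            1 - sps.poisson.cdf(kmax - 1, lam))
        keep = expected > 1.0
        chi2 = np.sum((observed[keep] - expected[keep]) ** 2 / expected[keep])
        dof = keep.sum() - 2
        assert chi2 < sps.chi2.ppf(0.99, max(dof, 1))

    def test_opendx_output(self, tmp_path):
        topo, ens = _water_box(3, 10.0, 2)
        grids = density_grid(ens, select(topo, "water and element O"),
                             (np.zeros(3), np.full(3, 10.0)), spacing=1.0)
        path = tmp_path / "d.dx"
        write_opendx(grids["rep1"], path)
        text = path.read_text()
        assert "gridpositions counts 10 10 10" in text


class TestIsopleth:
    def _grid(self, counts):
        from gsmech.solvation import DensityGrid
        return DensityGrid(np.zeros(3), 1.0, np.asarray(counts), 1)

    def test_eighty_percent_of_max(self):
        counts = np.zeros((3, 3, 1), dtype=int)
        counts[0, 0, 0] = 10
        counts[1, 1, 0] = 8
        counts[2, 2, 0] = 7
        thr, mask = isopleth_threshold(self._grid(counts), 0.8)
        assert thr == 8.0
        assert mask.sum() == 2

    def test_fraction_one_only_argmax(self):
        counts = np.array([[[3, 10, 10, 2]]])
        _, mask = isopleth_threshold(self._grid(counts), 1.0)
        assert mask.sum() == 2

    def test_tiny_fraction_all_nonzero(self):
        counts = np.array([[[0, 1, 5, 0, 2]]])
        _, mask = isopleth_threshold(self._grid(counts), 1e-9)
        assert mask.sum() == 3

    def test_zero_grid_rejected(self):
        with pytest.raises(ValueError):
            isopleth_threshold(self._grid(np.zeros((2, 2, 2), int)), 0.8)


class TestRDF:
    def test_ideal_gas_unity(self):
        """g(r) of uniform waters is 1 within 3 SEM away from the origin."""
        topo, _ = _water_box(150, 24.0, 1)
        rng = np.random.default_rng(7)
        reps = {}
        for r in range(3):
            frames = np.zeros((40, topo.n_atoms, 3))
            frames[:, 0] = 12.0
            ox = rng.uniform(0, 24.0, size=(40, 150, 3))
            frames[:, 1::3] = ox
            frames[:, 2::3] = ox + [0.96, 0, 0]
            frames[:, 3::3] = ox + [-0.24, 0.93, 0]
            reps[f"rep{r+1}"] = frames
        ens = Ensemble(topo, reps)
        prof = rdf(ens, select(topo, "resname CEN"), select(topo, "water and name O"),
                   dr=0.4, r_max=8.0)
        sel = (prof.bin_centers >= 0.8) & (prof.bin_centers <= 4.0)
        # sampling allowance: each bin's count is Poisson with mean
        # rho * shell volume * frames, so g has sd ~ 1/sqrt(count)
        rho = 150 / 24.0 ** 3
        edges = np.arange(0.0, 8.0 + 0.4, 0.4)
        shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        expected = rho * shell_vol * 120
        resid = np.abs(prof.g_mean[sel] - 1.0)
        allowed = 3 * np.maximum(prof.g_sem[sel], 1.0 / np.sqrt(expected[sel]))
        assert np.all(resid <= allowed)

    def test_glued_shell_single_peak(self):
        """Waters pinned at 2.8 A produce one populated bin at 2.8 A."""
        n_w = 12
        topo, _ = _water_box(n_w, 0.0, 1)
        object.__setattr__(topo, "box", None)
        frames = np.zeros((4, topo.n_atoms, 3))
        rng = np.random.default_rng(1)
        dirs = rng.normal(size=(n_w, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        frames[:, 1::3] = 2.8 * dirs
        frames[:, 2::3] = frames[:, 1::3] + [0.96, 0, 0]
        frames[:, 3::3] = frames[:, 1::3] + [-0.24, 0.93, 0]
        ens = Ensemble(topo, {"rep1": frames})
        prof = rdf(ens, np.array([0]), select(topo, "water and name O"),
                   dr=0.2, r_max=6.0)
        populated = np.flatnonzero(prof.g_mean > 0)
        assert len(populated) == 1
        assert prof.bin_centers[populated[0]] == pytest.approx(2.9, abs=0.2)

    def test_peak_ratio_tracks_shell_population(self):
        """First-shell g ratio follows a designed 1.3x water-count ratio."""
        def shell_ens(n_shell, n_far, seed):
            n_w = n_shell + n_far
            topo, _ = _water_box(n_w, 30.0, 1)
            rng = np.random.default_rng(seed)
            frames = np.zeros((30, topo.n_atoms, 3))
            frames[:, 0] = 15.0
            dirs = rng.normal(size=(30, n_w, 3))
            dirs /= np.linalg.norm(dirs, axis=2, keepdims=True)
            radii = np.concatenate([
                np.full((30, n_shell), 2.8), rng.uniform(6, 12, (30, n_far))], axis=1)
            ox = 15.0 + dirs * radii[:, :, None]
            frames[:, 1::3] = ox
            frames[:, 2::3] = ox + [0.96, 0, 0]
            frames[:, 3::3] = ox + [-0.24, 0.93, 0]
            return topo, Ensemble(topo, {"rep1": frames})

        peaks = []
        for n_shell in (10, 13):
            topo, ens = shell_ens(n_shell, 50, seed=n_shell)
            prof = rdf(ens, np.array([0]), select(topo, "water and name O"),
                       dr=0.2, r_max=14.0)
            peaks.append(prof.g_mean.max())
        assert peaks[1] / peaks[0] == pytest.approx(1.3, rel=0.05)


class TestBridges:
    def test_constructed_single_water_chain(self):
        spec = GeneratorSpec(seed=1, n_frames=1)
        ens, truth = gen_bridge_site(spec, gap=5.4, occupancy=1.0,
                                     n_bridge_waters=1, decoy_waters=0)
        topo = ens.topology
        ea = select(topo, truth["endpoint_a"])
        eb = select(topo, truth["endpoint_b"])
        chains = find_bridges(topo, ens.replicates["rep1"][0], ea, eb,
                              hbond_class="strong")
        assert chains and all(c.n_waters == 1 for c in chains)

    def test_weak_only_geometry(self):
        """Links at 3.0 A qualify as weak but not strong chains."""
        spec = GeneratorSpec(seed=1, n_frames=1)
        ens, truth = gen_bridge_site(spec, gap=6.0, occupancy=1.0,
                                     n_bridge_waters=1, decoy_waters=0,
                                     d_strong=3.2)
        topo = ens.topology
        ea = select(topo, truth["endpoint_a"])
        eb = select(topo, truth["endpoint_b"])
        coords = ens.replicates["rep1"][0]
        assert find_bridges(topo, coords, ea, eb, hbond_class="weak")
        assert not find_bridges(topo, coords, ea, eb, hbond_class="strong")

    def test_depth_bound(self):
        """A valid 4-water chain is invisible at max_waters = 3."""
        spec = GeneratorSpec(seed=1, n_frames=1)
        ens, truth = gen_bridge_site(spec, gap=12.5, occupancy=1.0,
                                     n_bridge_waters=4, decoy_waters=0)
        topo = ens.topology
        ea = select(topo, truth["endpoint_a"])
        eb = select(topo, truth["endpoint_b"])
        coords = ens.replicates["rep1"][0]
        assert not find_bridges(topo, coords, ea, eb, max_waters=3)
        assert find_bridges(topo, coords, ea, eb, max_waters=4)

    def test_brute_force_oracle(self):
        """Chain enumeration equals exhaustive search over water subsets."""
        spec = GeneratorSpec(seed=9, n_frames=6)
        ens, truth = gen_bridge_site(spec, gap=7.5, occupancy=0.5,
                                     n_bridge_waters=2, decoy_waters=4)
        topo = ens.topology
        ea = select(topo, truth["endpoint_a"])
        eb = select(topo, truth["endpoint_b"])
        crit = HBondCriteria()
        waters = np.flatnonzero(topo.is_water() & (topo.elements == "O"))
        for f in range(ens.n_frames()):
            coords = ens.replicates["rep1"][f]
            hyd = _hydrogens_by_heavy(topo, coords)
            found = {
                tuple(c.atoms)
                for c in find_bridges(topo, coords, ea, eb, crit, "weak", 3)
            }
            brute = set()
            for k in (1, 2, 3):
                for seq in itertools.permutations(waters.tolist(), k):
                    for a in ea:
                        for b in eb:
                            nodes = [int(a), *seq, int(b)]
                            if all(_link_ok(x, y, coords, hyd, crit, "weak")
                                   for x, y in zip(nodes[:-1], nodes[1:])):
                                brute.add(tuple(nodes))
            assert found == brute

    def test_frequency_recovery_and_nesting(self):
        spec = GeneratorSpec(seed=12, n_frames=600, n_replicates=2)
        ens, truth = gen_bridge_site(spec, occupancy=0.31)
        ea = select(ens.topology, truth["endpoint_a"])
        eb = select(ens.topology, truth["endpoint_b"])
        weak = bridge_frequency(ens, ea, eb, hbond_class="weak")
        strong = bridge_frequency(ens, ea, eb, hbond_class="strong")
        assert strong.grand_mean <= weak.grand_mean
        realized = np.mean([np.mean(v) for v in truth["bridged"].values()])
        assert weak.grand_mean == pytest.approx(realized, abs=1e-12)

    def test_occupancy_zero(self):
        spec = GeneratorSpec(seed=2, n_frames=50)
        ens, truth = gen_bridge_site(spec, occupancy=0.0)
        ea = select(ens.topology, truth["endpoint_a"])
        eb = select(ens.topology, truth["endpoint_b"])
        assert bridge_frequency(ens, ea, eb, hbond_class="weak").grand_mean == 0.0
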