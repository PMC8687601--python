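"""Hydration-shell census against brute-force distance oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hydrodyn import scenes, shells
from hydrodyn.scenes import SceneInfeasibleError, SceneGeometry


def _brute_force(ring, prot, wat):
    """O(N*M) double-loop reference census."""
    counts = dict.fromkeys(shells.CLASSES, 0)
    for w in wat:
        d_ring = min(np.linalg.norm(w - a) for a in ring)
        d_surf = min(np.linalg.norm(w - a) for a in prot)
        if d_ring > 10.0:
            continue
        counts["within_10_of_ring"] += 1
        if d_surf <= 5.0:
            counts["within_5_of_surface"] += 1
        if d_surf <= 7.0:
            counts["within_7_of_surface"] += 1
        else:
            counts["beyond_7_of_surface"] += 1
        if d_ring <= 5.0:
            counts["within_5_of_ring"] += 1
    return counts


class TestShellCounts:
    def test_zero_waters_all_zero(self):
        ring = np.zeros((1, 3))
        counts = shells.shell_counts(ring, ring, np.empty((0, 3)))
        assert all(v == 0 for v in counts.values())

    def test_no_ring_atoms_rejected(self):
        with pytest.raises(ValueError, match="ring"):
            shells.shell_counts(np.empty((0, 3)), np.zeros((1, 3)), np.zeros((1, 3)))

    @pytest.mark.parametrize("preset", ["exposed", "caved", "buried"])
    def test_matches_brute_force_on_scenes(self, preset):
        sc = scenes.generate_scene(preset, seed=3)
        ring, prot, wat = sc.monomer(0)
        fast = shells.shell_counts(ring, prot, wat)
        slow = _brute_force(ring, prot, wat)
        assert fast == slow

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_on_random_points(self, seed):
        rng = np.random.default_rng(seed)
        ring = rng.uniform(-3, 3, (5, 3))
        prot = np.vstack([ring, rng.uniform(-12, 12, (30, 3))])
        wat = rng.uniform(-15, 15, (50, 3))
        assert shells.shell_counts(ring, prot, wat) == _brute_force(ring, prot, wat)

    def test_nesting_and_cutoff_monotonicity(self):
        sc = scenes.generate_scene("exposed", seed=5)
        ring, prot, wat = sc.monomer(0)
        c = shells.shell_counts(ring, prot, wat)
        assert c["within_5_of_surface"] <= c["within_7_of_surface"]
        assert c["within_5_of_ring"] <= c["within_10_of_ring"]
        assert (
            c["beyond_7_of_surface"]
            == c["within_10_of_ring"] - c["within_7_of_surface"]
        )


class TestScenes:
    def test_deterministic_from_seed(self):
        a = scenes.generate_scene("caved", seed=7)
        b = scenes.generate_scene("caved", seed=7)
        assert np.array_equal(a.water_xyz, b.water_xyz)
        assert np.array_equal(a.protein_xyz, b.protein_xyz)

    def test_buried_waters_all_near_ring(self):
        """Construction keeps every water inside the 10 A ring universe."""
        sc = scenes.generate_scene("buried", seed=11)
        ring, prot, wat = sc.monomer(0)
        c = shells.shell_counts(ring, prot, wat)
        assert c["within_10_of_ring"] == len(wat)
        assert c["within_5_of_surface"] == len(wat)

    def test_exposed_outer_layer_occupancy(self):
        """The exposed preset pins 40 waters beyond 7 A of the surface."""
        sc = scenes.generate_scene("exposed", seed=13)
        ring, prot, wat = sc.monomer(0)
        c = shells.shell_counts(ring, prot, wat)
        assert abs(c["beyond_7_of_surface"] - 40) <= 4

    def test_caved_preset_proportions(self):
        """Open-cave preset: ~170 universe, ~125 within 5 A, ~8 beyond 7 A."""
        sc = scenes.generate_scene("caved", seed=17)
        ring, prot, wat = sc.monomer(0)
        c = shells.shell_counts(ring, prot, wat)
        assert abs(c["within_10_of_ring"] - 170) <= 17
        assert abs(c["within_5_of_surface"] - 125) <= 12
        assert abs(c["beyond_7_of_surface"] - 8) <= 1

    def test_infeasible_occupancy_fails_loudly(self):
        geom = SceneGeometry(probe_height=2.0, wall_radius=10.0, wall_top=9.0,
                             occupancies={"outer": 500})
        with pytest.raises(SceneInfeasibleError):
            scenes.generate_scene(geom, seed=1)


class TestMonomerAverage:
    def _census_with(self, n):
        c = shells.ShellCensus(
            frame_times=np.array([0.0]),
            counts={cls: np.array([[n]]) for cls in shells.CLASSES},
        )
        return c

    def test_two_site_mean_and_sd(self):
        avg = shells.monomer_average([self._census_with(10), self._census_with(20)])
        assert avg.monomer_mean["within_10_of_ring"][0] == pytest.approx(15.0)
        assert avg.monomer_sd["within_10_of_ring"][0] == pytest.approx(7.0711, abs=1e-3)

    def test_identical_sites_zero_sd(self):
        avg = shells.monomer_average([self._census_with(12)] * 3)
        assert avg.monomer_mean["within_5_of_ring"][0] == 12.0
        assert avg.monomer_sd["within_5_of_ring"][0] == 0.0

    def test_permutation_invariance(self):
        a = [self._census_with(n) for n in (5, 9, 14)]
        fwd = shells.monomer_average(a)
        rev = shells.monomer_average(a[::-1])
        for cls in shells.CLASSES:
            assert np.allclose(fwd.monomer_mean[cls], rev.monomer_mean[cls])
            assert np.allclose(fwd.monomer_sd[cls], rev.monomer_sd[cls])

    def test_mismatched_grids_rejected(self):
        a = self._census_with(5)
        b = self._census_with(5)
        b.frame_times = np.array([1.0])
        with pytest.raises(ValueError, match="mismatched"):
            shells.monomer_average([a, b])


class TestPdbRoundTrip:
    def test_multi_model_pdb_census_matches_scene(self, tmp_path):
        """Counts from a written multi-model PDB equal the in-memory census."""
        import warnings

        import MDAnalysis as mda

        frames = scenes.generate_frames("caved", 3, seed=21)
        path = tmp_path / "traj.pdb"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scenes.write_pdb(frames, path)
            u = mda.Universe(str(path))
            census = shells.census_universe(u)
        expected = [shells.census_scene(f) for f in frames]
        for i, exp in enumerate(expected):
            for cls in shells.CLASSES:
                assert census.counts[cls][0, i] == exp.counts[cls][0, 0]

    def test_fourteen_site_average(self):
        """A 14-copy scene averages per class across all monomer sites."""
        sc = scenes.generate_scene("buried", seed=23, n_monomers=14)
        census = shells.census_scene(sc)
        assert census.n_sites == 14
        assert census.monomer_mean["within_10_of_ring"][0] == pytest.approx(90.0)
        assert census.counts["within_10_of_ring"].shape == (14, 1)
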