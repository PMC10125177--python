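"""Shell-metric estimators against closed forms and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from aushell.fixtures import FixtureSpec, make_toy_trajectory
from aushell.shellmetrics import (
    AnalysisConfig,
    Frame,
    component_copies,
    component_core_distance,
    masses_for,
    radius_of_gyration,
    rdf,
    read_trajectory,
    sasa_by_component,
    sasa_per_atom,
    time_series_summary,
)
from aushell.structures import Component


class TestRadiusOfGyration:
    def test_point_mass_is_zero(self):
        f = Frame(np.zeros((1, 3)), unit="nm")
        assert radius_of_gyration(f) == 0.0

    def test_two_equal_masses_half_distance(self):
        f = Frame(np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]]), unit="nm")
        assert radius_of_gyration(f, masses=np.array([1.0, 1.0])) == pytest.approx(1.0)

    def test_mass_weighting_shifts_com(self):
        f = Frame(np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]]), unit="nm")
        rg = radius_of_gyration(f, masses=np.array([3.0, 1.0]))
        # com at 0.5; rg = sqrt((3*0.25 + 1*2.25)/4)
        assert rg == pytest.approx(np.sqrt(3.0) / 2.0)

    def test_rigid_transform_invariance(self, rng):
        pos = rng.normal(size=(40, 3))
        masses = rng.uniform(1, 200, size=40)
        base = radius_of_gyration(Frame(pos, unit="nm"), masses=masses)
        rot = Rotation.random(random_state=rng).as_matrix()
        moved = pos @ rot.T + rng.uniform(-3, 3, size=3)
        assert radius_of_gyration(Frame(moved, unit="nm"), masses=masses) \
            == pytest.approx(base, abs=1e-12)

    def test_angstrom_unit_conversion(self):
        f = Frame(np.array([[0.0, 0.0, 0.0], [20.0, 0.0, 0.0]]), unit="angstrom")
        assert radius_of_gyration(f) == pytest.approx(1.0)

    def test_empty_selection_raises(self):
        f = Frame(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            radius_of_gyration(f, selection=np.array([], dtype=int))

    def test_reference_cluster_geometric_rg(self, reference_model):
        f = Frame(reference_model.positions, unit="angstrom")
        rg = radius_of_gyration(f)
        assert abs(rg - 1.17) / 1.17 <= 0.05


class TestSasa:
    def test_isolated_atom_closed_form(self):
        cfg = AnalysisConfig(radii_table={"X": 0.15})
        f = Frame(np.zeros((1, 3)), unit="nm")
        area = sasa_per_atom(f, ["X"], cfg)[0]
        assert area == pytest.approx(4 * np.pi * 0.29 ** 2, rel=1e-12)

    def test_two_sphere_analytic_overlap(self):
        # two equal inflated spheres of radius R at separation d < 2R:
        # exposed area per sphere is 2 pi R (R + d/2)
        r_vdw, probe, d = 0.15, 0.14, 0.35
        R = r_vdw + probe
        cfg = AnalysisConfig(radii_table={"X": r_vdw}, probe_radius=probe)
        f = Frame(np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]), unit="nm")
        areas = sasa_per_atom(f, ["X", "X"], cfg)
        expect = 2 * np.pi * R * (R + d / 2)
        assert np.allclose(areas, expect, rtol=0.01)  # within 1% at 960 points

    def test_convergence_doubling_points(self):
        r_vdw, d = 0.17, 0.3
        f = Frame(np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]), unit="nm")
        vals = []
        for n in (960, 1920):
            cfg = AnalysisConfig(radii_table={"C": r_vdw}, n_sphere_points=n)
            vals.append(sasa_per_atom(f, ["C", "C"], cfg).sum())
        assert abs(vals[1] - vals[0]) / vals[0] < 0.005

    def test_component_additivity(self, reference_model):
        f = Frame(reference_model.positions, unit="angstrom")
        cfg = AnalysisConfig(n_sphere_points=96)  # cheap, additivity is exact
        comp, total = sasa_by_component(f, reference_model.elements,
                                        reference_model.components, cfg)
        assert total == pytest.approx(sum(comp.values()), rel=1e-12)

    def test_separated_molecules_additive(self, rng):
        pos = rng.normal(scale=0.2, size=(8, 3))
        elements = ["C"] * 8
        cfg = AnalysisConfig(n_sphere_points=480)
        lone = sasa_per_atom(Frame(pos, unit="nm"), elements, cfg).sum()
        both = np.vstack([pos, pos + np.array([50.0, 0.0, 0.0])])
        total = sasa_per_atom(Frame(both, unit="nm"), elements * 2, cfg).sum()
        assert total == pytest.approx(2 * lone, rel=1e-9)

    def test_matches_independent_implementation(self, rng):
        mdtraj = pytest.importorskip("mdtraj")
        import mdtraj.core.element as melem

        elements = ["C", "N", "O", "S", "H"] * 6
        pos = rng.uniform(0, 1.0, size=(30, 3))  # nm, crowded
        top = mdtraj.Topology()
        res = top.add_residue("MOL", top.add_chain())
        for e in elements:
            top.add_atom(e, melem.get_by_symbol(e), res)
        traj = mdtraj.Trajectory(pos[None], top)
        ref = mdtraj.shrake_rupley(traj, probe_radius=0.14,
                                   n_sphere_points=960).sum()
        mine = sasa_per_atom(Frame(pos, unit="nm"), elements).sum()
        assert mine == pytest.approx(float(ref), rel=0.01)

    def test_missing_radius_names_element(self):
        cfg = AnalysisConfig(radii_table={"C": 0.17})
        f = Frame(np.zeros((1, 3)), unit="nm")
        with pytest.raises(ValueError, match="Au"):
            sasa_per_atom(f, ["Au"], cfg)

    def test_reference_total_sasa(self, reference_model):
        f = Frame(reference_model.positions, unit="angstrom")
        _, total = sasa_by_component(f, reference_model.elements,
                                     reference_model.components)
        assert abs(total - 56.85) / 56.85 <= 0.10


class TestComponentCoreDistance:
    def test_coincident_coms_give_zero(self):
        pos = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]])
        frames = [Frame(pos, unit="nm", time=float(t)) for t in range(5)]
        copies = [np.array([1, 2])]  # com at origin, same as core
        core = np.array([0])
        masses = np.ones(3)
        cfg = AnalysisConfig(equilibration_cutoff=0.0)
        _, dists, (mean, sd) = component_core_distance(frames, copies, core,
                                                       masses, cfg)
        assert mean == 0.0 and sd == 0.0

    def test_fixed_two_nm_copy(self):
        frames = []
        for t in range(10):
            core = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0],
                             [-1.0, -1.0, -1.0]])
            copy = np.array([[2.0, 0.0, 0.0], [2.0, 0.5, 0.0],
                             [2.0, -0.5, 0.0]])
            frames.append(Frame(np.vstack([core, copy]), unit="nm",
                                time=float(t)))
        cfg = AnalysisConfig(equilibration_cutoff=0.0)
        _, dists, (mean, sd) = component_core_distance(
            frames, [np.arange(3, 6)], np.arange(3), np.ones(6), cfg)
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_all_frames_before_cutoff_raises(self):
        frames = [Frame(np.zeros((2, 3)), time=1.0)]
        with pytest.raises(ValueError):
            component_core_distance(frames, [np.array([0])], np.array([1]),
                                    np.ones(2), AnalysisConfig())


class TestRdf:
    def test_ideal_gas_is_flat(self, rng):
        n_a, n_b, L = 80, 80, 5.0
        frames = [Frame(rng.uniform(0, L, size=(n_a + n_b, 3)), unit="nm",
                        box=np.array([L, L, L]), periodic=True,
                        time=float(t)) for t in range(20)]
        cfg = AnalysisConfig(rdf_bin=0.1, equilibration_cutoff=0.0)
        res = rdf(frames, np.arange(n_a), np.arange(n_a, n_a + n_b), cfg)
        sel = res.bin_centers >= 1.0
        mean_g = res.g[sel].mean()
        # Poisson noise on each bin, averaged over the selected bins
        lam = (n_a * n_b / L ** 3) * 4 * np.pi * res.bin_centers[sel] ** 2 \
            * cfg.rdf_bin * len(frames)
        sigma = np.sqrt((1.0 / lam).mean() / sel.sum())
        assert abs(mean_g - 1.0) < 3 * sigma + 0.01

    def test_shell_fixture_peak_at_quarter_nm(self, tmp_path):
        spec = FixtureSpec("toy_trajectory",
                           {"flavor": "ion_shell", "seed": 5, "n_frames": 40,
                            "shell_radius": 0.27})
        truth = make_toy_trajectory(spec, tmp_path)
        model, frames = read_trajectory(tmp_path / "ion_shell.pdb")
        na = np.flatnonzero(model.elements == "Na")
        s = np.flatnonzero(model.elements == "S")
        cfg = AnalysisConfig(rdf_bin=0.01, rdf_rmax=1.0,
                             equilibration_cutoff=0.0)
        res = rdf(frames, s, na, cfg)
        mode = res.bin_centers[np.argmax(res.g)]
        assert abs(mode - truth["shell_radius_nm"]) <= cfg.rdf_bin / 2 + 1e-12

    def test_pair_counting(self, rng):
        n_a, n_b, L = 10, 12, 4.0
        frames = [Frame(rng.uniform(0, L, size=(n_a + n_b, 3)), unit="nm",
                        box=np.array([L, L, L]), periodic=True,
                        time=float(t)) for t in range(3)]
        cfg = AnalysisConfig(rdf_bin=0.05, equilibration_cutoff=0.0)
        res = rdf(frames, np.arange(n_a), np.arange(n_a, n_a + n_b), cfg)
        assert res.n_pairs == 3 * n_a * n_b
        assert res.frames_used == 3

    def test_rmax_beyond_half_box_raises(self, rng):
        frames = [Frame(rng.uniform(0, 4, size=(6, 3)), unit="nm",
                        box=np.array([4.0, 4.0, 4.0]), periodic=True)]
        cfg = AnalysisConfig(rdf_rmax=3.0, equilibration_cutoff=0.0)
        with pytest.raises(ValueError, match="half"):
            rdf(frames, np.array([0, 1]), np.array([2, 3]), cfg)

    def test_overlapping_groups_rejected(self):
        frames = [Frame(np.zeros((4, 3)))]
        with pytest.raises(ValueError):
            rdf(frames, np.array([0, 1]), np.array([1, 2]))


class TestTimeSeriesSummary:
    def test_constant_series(self):
        mean, sd = time_series_summary(np.arange(5.0), np.full(5, 3.3), 0.0)
        assert (mean, sd) == (pytest.approx(3.3), 0.0)

    def test_hand_arithmetic(self):
        mean, sd = time_series_summary(np.array([31.0, 32.0, 33.0]),
                                       np.array([1.0, 2.0, 3.0]), 30.0)
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(1.0)

    def test_cutoff_slice_oracle(self, rng):
        times = np.arange(0.0, 100.0, 2.5)
        values = np.concatenate([np.linspace(5, 1, 12),
                                 1 + 0.1 * rng.normal(size=28)])
        mean, sd = time_series_summary(times, values, 30.0)
        suffix = values[times >= 30.0]
        assert mean == pytest.approx(suffix.mean())
        assert sd == pytest.approx(suffix.std(ddof=1))

    def test_no_samples_after_cutoff(self):
        with pytest.raises(ValueError):
            time_series_summary(np.array([1.0]), np.array([2.0]), 30.0)


class TestBruteForceAgreement:
    def test_rdf_matches_direct_histogram(self, rng):
        """Estimator equals an O(N^2) per-frame recomputation."""
        n_a, n_b, L = 15, 15, 4.0
        frames = [Frame(rng.uniform(0, L, size=(30, 3)), unit="nm",
                        box=np.array([L, L, L]), periodic=True,
                        time=float(t)) for t in range(4)]
        cfg = AnalysisConfig(rdf_bin=0.1, equilibration_cutoff=0.0)
        res = rdf(frames, np.arange(n_a), np.arange(n_a, 30), cfg)
        edges = np.arange(len(res.g) + 1) * cfg.rdf_bin
        hist = np.zeros(len(res.g))
        for f in frames:
            pos = f.positions_nm()
            for i in range(n_a):
                for j in range(n_a, 30):
                    delta = pos[i] - pos[j]
                    delta -= L * np.round(delta / L)
                    d = np.linalg.norm(delta)
                    if d < edges[-1]:
                        hist[min(int(d / cfg.rdf_bin), len(hist) - 1)] += 1
        shell = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        g_ref = hist / (len(frames) * (n_a * n_b / L ** 3) * shell)
        assert np.allclose(res.g, g_ref, atol=1e-9)
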