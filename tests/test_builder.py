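"""Site selection, nested-grid placement, whole builds, enumeration."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import chisquare

from aushell.builder import (
    BuilderConfig,
    FormulationSpec,
    PlacementFailure,
    attempt_placement,
    build_functionalized_cluster,
    enumerate_formulations,
    min_external_distance,
    select_exchange_sites,
    split_by_ratio,
)
from aushell.fixtures import make_toy_cluster
from aushell.ligands import LigandTemplate
from aushell.structures import ClusterModel, Component
from aushell._geometry import rotation_about_axis


def _minimal_template(component=Component.DL, bent=True):
    """Tiny S-C(-C) template; the bent arm makes orientation matter."""
    elements = ["S", "C", "C"] if bent else ["S", "C"]
    positions = [[0.0, 0.0, 0.0], [0.0, 0.0, 1.8]]
    bonds = [(0, 1)]
    if bent:
        positions.append([1.4, 0.0, 2.6])
        bonds.append((1, 2))
    return LigandTemplate(np.array(elements, dtype=object),
                          np.array(positions, dtype=float),
                          anchor_sulfur=0, axis_carbon=1, bonds=bonds,
                          component=component, name="mini")


class TestSiteSelection:
    def test_default_sites_distinct_units(self, reference_model):
        sites = select_exchange_sites(reference_model, 15, seed=3)
        assert len(sites) == 15
        assert len({s for s, _ in sites}) == 15
        assert all(c in (0, 1) for _, c in sites)

    def test_zero_sites(self, reference_model):
        assert select_exchange_sites(reference_model, 0, seed=1) == []

    def test_too_many_sites_names_counts(self, toy_cluster):
        with pytest.raises(ValueError, match="4.*3|3.*4"):
            select_exchange_sites(toy_cluster, 4, seed=0)

    def test_seed_reproducibility(self, reference_model):
        a = select_exchange_sites(reference_model, 15, seed=42)
        b = select_exchange_sites(reference_model, 15, seed=42)
        c = select_exchange_sites(reference_model, 15, seed=43)
        assert a == b
        assert a != c

    def test_uniformity_chi_square(self):
        toy = make_toy_cluster(6, seed=0)
        counts = np.zeros((6, 2))
        for seed in range(10_000):
            (staple, choice), = select_exchange_sites(toy, 1, seed=seed)
            counts[staple, choice] += 1
        stat, p = chisquare(counts.ravel())
        assert p > 1e-4  # uniform over the 12 (unit, ligand) cells


class TestPlacement:
    def test_unobstructed_site_accepts_first_trial(self):
        toy = make_toy_cluster(1, seed=0)
        result = attempt_placement(toy, (0, 0), _minimal_template(),
                                   BuilderConfig(n_exchange=1))
        assert not isinstance(result, PlacementFailure)
        model, trace = result
        assert trace.trials == 1
        assert trace.accepted_angles == (0.0, 0.0)

    def test_grid_matches_exhaustive_enumeration(self):
        """The accepted orientation equals the first admissible one found by
        an independent full-grid enumeration under the documented loop
        order (outer S-Au, inner S-C, both from 0 upward)."""
        toy = make_toy_cluster(1, seed=0)
        template = _minimal_template()
        cfg = BuilderConfig(n_exchange=1, step_sau=30.0, step_cs=30.0)
        blocked = _block_default_orientation(toy, template, cfg, (0, 0))
        result = attempt_placement(blocked, (0, 0), template, cfg)
        assert not isinstance(result, PlacementFailure)
        _, trace = result
        oracle = _exhaustive_first_acceptable(blocked, template, cfg, (0, 0))
        assert trace.accepted_angles == oracle
        assert trace.trials > 1  # the wall really forced the search on

    def test_trials_bounded_by_grid(self, reference_model, drug_template):
        cfg = BuilderConfig()
        n_sau, n_cs = cfg.grid_shape
        assert (n_sau, n_cs) == (36, 100)
        result = attempt_placement(reference_model, (0, 0), drug_template, cfg)
        assert not isinstance(result, PlacementFailure)
        assert result[1].trials <= n_sau * n_cs

    def test_dmin_monotonicity(self):
        """Raising d_min can only shrink the set of admissible orientations."""
        toy = make_toy_cluster(1, seed=0)
        template = _minimal_template()
        sets = []
        for d_min in (1.0, 1.75, 2.5):
            cfg = BuilderConfig(n_exchange=1, step_sau=45.0, step_cs=45.0,
                                d_min=d_min)
            sets.append(_all_acceptable(toy, template, cfg, (0, 0)))
        assert sets[2] <= sets[1] <= sets[0]


class TestBuild:
    def test_default_build_counts(self, default_build):
        built, traces = default_build
        assert len(built.molecules_with_component(Component.OL)) == 45
        assert len(built.molecules_with_component(Component.PL)) == 10
        assert len(built.molecules_with_component(Component.DL)) == 5
        assert len(traces) == 15

    def test_one_replacement_per_staple(self, default_build):
        built, _ = default_build
        assert all(not (s.replaced[0] and s.replaced[1]) for s in built.staples)
        assert sum(s.replaced[0] + s.replaced[1] for s in built.staples) == 15

    def test_gold_unchanged(self, reference_model, default_build):
        built, _ = default_build
        gold_in = reference_model.positions[reference_model.elements == "Au"]
        gold_out = built.positions[built.elements == "Au"]
        assert np.array_equal(np.sort(gold_in, axis=0), np.sort(gold_out, axis=0))

    def test_noop_build(self, reference_model, peptide_template, drug_template):
        cfg = BuilderConfig(n_exchange=0)
        form = FormulationSpec("p", "d", (1, 1), 0, 0)
        built, traces = build_functionalized_cluster(
            reference_model, form, peptide_template, drug_template, cfg)
        assert traces == []
        assert np.allclose(built.positions, reference_model.positions)
        assert built.n_atoms == reference_model.n_atoms

    def test_determinism_identical_seed(self, reference_model, peptide_template,
                                        drug_template):
        cfg = BuilderConfig(seed=11, n_exchange=4)
        form = FormulationSpec("p", "d", (1, 1), 2, 2)
        a, _ = build_functionalized_cluster(reference_model, form,
                                            peptide_template, drug_template, cfg)
        b, _ = build_functionalized_cluster(reference_model, form,
                                            peptide_template, drug_template, cfg)
        assert np.array_equal(a.positions, b.positions)
        assert list(a.elements) == list(b.elements)

    def test_clash_criterion_across_seeds(self, reference_model,
                                          peptide_template, drug_template):
        form = FormulationSpec("p", "d", (2, 1), 10, 5)
        for seed in range(1, 6):
            cfg = BuilderConfig(seed=seed)
            built, _ = build_functionalized_cluster(
                reference_model, form, peptide_template, drug_template, cfg)
            assert min_external_distance(built) >= cfg.d_min


class TestMinExternalDistance:
    def test_two_molecules_three_angstrom(self):
        m = ClusterModel(
            np.array(["S", "S"], dtype=object),
            np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]]),
            np.array([0, 1]),
            np.array([Component.OL.value, Component.DL.value], dtype=object),
        )
        assert min_external_distance(m) == pytest.approx(3.0)

    def test_tree_equals_brute_force(self, default_build):
        built, _ = default_build
        d_tree = min_external_distance(built, method="tree")
        d_brute = min_external_distance(built, method="brute")
        assert d_tree == pytest.approx(d_brute, abs=1e-12)

    def test_empty_filter_raises(self, reference_model):
        with pytest.raises(ValueError):
            min_external_distance(reference_model)


class TestEnumeration:
    def test_study_design_space_is_28(self):
        specs = enumerate_formulations(
            ["QS13", "RGD4C"],
            ["5FU", "EPI", "LIN", "TAN", "TAS", "CAP", "TOR"],
            [(1, 2), (2, 1)])
        assert len(specs) == 28
        assert len(set(specs)) == 28

    def test_single_point(self):
        specs = enumerate_formulations(["A"], ["B"], [(1, 2)], 15)
        assert len(specs) == 1
        assert (specs[0].n_peptide, specs[0].n_drug) == (5, 10)

    def test_ratio_split(self):
        assert split_by_ratio(15, (1, 2)) == (5, 10)
        assert split_by_ratio(15, (2, 1)) == (10, 5)

    def test_non_integer_split_raises(self):
        with pytest.raises(ValueError):
            enumerate_formulations(["A"], ["B"], [(1, 1)], 15)


# ---------------------------------------------------------------------------
# helpers: independent full-grid enumeration oracle


def _aligned_base(model, site, template):
    staple = model.staples[site[0]]
    old_mol = staple.ligands[site[1]]
    old_s = staple.sulfurs[site[1]]
    s_pos = model.positions[old_s]
    carbons = [j if model.elements[j] == "C" else i
               for i, j in model.bonds
               if old_s in (i, j)
               and model.elements[j if j != old_s else i] == "C"
               and model.molecule_ids[j if j != old_s else i] == old_mol]
    old_c = min(carbons)
    sc_dir = model.positions[old_c] - s_pos
    sc_dir /= np.linalg.norm(sc_dir)
    sau_axis = s_pos - model.positions[staple.apex_gold]
    sau_axis /= np.linalg.norm(sau_axis)
    local = template.positions - template.positions[template.anchor_sulfur]
    a = local[template.axis_carbon] / np.linalg.norm(local[template.axis_carbon])
    v = np.cross(a, sc_dir)
    c = float(a @ sc_dir)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    base = local @ rot.T
    env_mask = model.molecule_ids != old_mol
    return base, s_pos, sau_axis, model.positions[env_mask]


def _orientation_coords(base, s_pos, sau_axis, template, th_sau, th_cs):
    r1 = rotation_about_axis(sau_axis, th_sau)
    coords = base @ r1.T
    cs_axis = coords[template.axis_carbon]
    cs_axis = cs_axis / np.linalg.norm(cs_axis)
    r2 = rotation_about_axis(cs_axis, th_cs)
    return coords @ r2.T + s_pos


def _all_acceptable(model, template, cfg, site):
    base, s_pos, sau_axis, env = _aligned_base(model, site, template)
    n_sau, n_cs = cfg.grid_shape
    acceptable = set()
    for i in range(n_sau):
        for j in range(n_cs):
            coords = _orientation_coords(base, s_pos, sau_axis, template,
                                         i * cfg.step_sau, j * cfg.step_cs)
            d = np.sqrt(((coords[:, None, :] - env[None, :, :]) ** 2).sum(-1))
            if d.min() >= cfg.d_min:
                acceptable.add((i * cfg.step_sau, j * cfg.step_cs))
    return acceptable

def _exhaustive_first_acceptable(model, template, cfg, site):
    base, s_pos, sau_axis, env = _aligned_base(model, site, template)
    n_sau, n_cs = cfg.grid_shape
    for i in range(n_sau):
        for j in range(n_cs):
            coords = _orientation_coords(base, s_pos, sau_axis, template,
                                         i * cfg.step_sau, j * cfg.step_cs)
            d = np.sqrt(((coords[:, None, :] - env[None, :, :]) ** 2).sum(-1))
            if d.min() >= cfg.d_min:
                return (i * cfg.step_sau, j * cfg.step_cs)
    return None


def _block_default_orientation(model, template, cfg, site):
    """Drop a blocking atom where the template's arm sits at (0, 0) so the
    sampler must search past the first orientations."""
    base, s_pos, sau_axis, _ = _aligned_base(model, site, template)
    coords0 = _orientation_coords(base, s_pos, sau_axis, template, 0.0, 0.0)
    block_pos = coords0[-1] + np.array([0.0, 0.0, 0.5])
    m = model.copy()
    new_mol = int(m.molecule_ids.max()) + 1
    m.elements = np.append(m.elements, "O")
    m.positions = np.vstack([m.positions, block_pos])
    m.molecule_ids = np.append(m.molecule_ids, new_mol)
    m.components = np.append(m.components, Component.ION.value)
    return ClusterModel(m.elements, m.positions, m.molecule_ids, m.components,
                        bonds=m.bonds, staples=m.staples,
                        provenance=m.provenance)
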