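"""Ligand-exchange placement and formulation enumeration.

The builder installs incoming PEG-peptide/PEG-drug conjugates on a
protected cluster by thiolate-for-thiolate exchange, one ligand per
RS-Au-SR protective unit, reproducing the nested rotational-sampling
placement procedure:

1. exchange sites (staple, which of its two thiolates) are drawn uniformly
   at random, at most one per staple;
2. the incoming template's anchor sulfur is superposed on the leaving
   thiolate's sulfur with the S->C axis along the original bonding
   direction;
3. orientations are sampled on a nested grid — the outer loop rotates
   about the S-Au bond in 10 degree steps, the inner loop about the S-C
   bond in 3.6 degree steps, the inner sweep repeated for every outer
   trial angle — and the first orientation placing every template atom at
   least 1.75 Angstrom from all atoms outside the template is accepted
   immediately;
4. all peptide conjugates are placed before any drug conjugate; if any
   placement exhausts its grid the whole build restarts with fresh random
   sites, up to a restart cap.

Because the sampler terminates at the first admissible orientation,
placements stay close to the original bonding direction whenever space
permits, exactly as the construction procedure intends.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.spatial import cKDTree

from ._geometry import rotation_about_axis
from .ligands import LigandTemplate
from .structures import ClusterModel, Component, StapleUnit


@dataclass(frozen=True)
class BuilderConfig:
    """All placement-algorithm constants.

    step_cs / step_sau are the S-C and S-Au rotational sampling steps in
    degrees; d_min the hard minimum distance between an incoming ligand's
    atoms and everything outside it; n_exchange the number of staples that
    receive an incoming ligand; max_restarts caps full-build restarts after
    a failed placement.
    """

    n_exchange: int = 15
    step_cs: float = 3.6
    step_sau: float = 10.0
    d_min: float = 1.75
    seed: int = 0
    max_restarts: int = 100

    def __post_init__(self) -> None:
        for step in (self.step_cs, self.step_sau):
            n = 360.0 / step
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"360 must be divisible by step {step}")
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(outer S-Au trials, inner S-C trials)."""
        return int(round(360.0 / self.step_sau)), int(round(360.0 / self.step_cs))


@dataclass(frozen=True)
class FormulationSpec:
    """One design point: peptide x drug x peptide:drug ratio."""

    peptide: str
    drug: str
    ratio: tuple[int, int]
    n_peptide: int
    n_drug: int

    def __post_init__(self) -> None:
        a, b = self.ratio
        if self.n_peptide * b != self.n_drug * a:
            raise ValueError(
                f"counts ({self.n_peptide}, {self.n_drug}) do not realize "
                f"ratio {a}:{b}"
            )

    @property
    def n_exchange(self) -> int:
        return self.n_peptide + self.n_drug


@dataclass
class PlacementTrace:
    """Record of one accepted placement: which site, which ligand of the
    pair was replaced, the accepted (theta_sau, theta_cs) grid angles, and
    how many orientations were tried before acceptance."""

    staple_index: int
    replaced_ligand: int  # 0 or 1 within the staple's pair
    accepted_angles: tuple[float, float]
    trials: int


@dataclass(frozen=True)
class PlacementFailure:
    """A site exhausted its full orientation grid without a clash-free fit.

    Returned (not raised) by :func:`attempt_placement`; the caller decides
    whether to restart the build.
    """

    staple_index: int
    trials: int


# ---------------------------------------------------------------------------
# site selection


def select_exchange_sites(model: ClusterModel, n_sites: int,
                          seed: int) -> list[tuple[int, int]]:
    """Draw ``n_sites`` exchange sites uniformly without replacement.

    Returns (staple index into ``model.staples``, ligand choice 0/1) pairs;
    at most one ligand per staple is ever selected, and within a staple the
    leaving thiolate is chosen uniformly.  Deterministic given ``seed``.
    """
    available = [k for k, s in enumerate(model.staples)
                 if not (s.replaced[0] and s.replaced[1])]
    if n_sites > len(available):
        raise ValueError(
            f"requested {n_sites} exchange sites but only {len(available)} "
            f"protective units are available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(available), size=n_sites, replace=False)
    sites = []
    for c in chosen:
        staple = model.staples[available[int(c)]]
        free = [i for i in (0, 1) if not staple.replaced[i]]
        pick = free[int(rng.integers(len(free)))] if len(free) > 1 else free[0]
        sites.append((available[int(c)], pick))
    return sites


# ---------------------------------------------------------------------------
# single-site placement


def attempt_placement(
    model: ClusterModel, site: tuple[int, int], template: LigandTemplate,
    config: BuilderConfig,
) -> tuple[ClusterModel, PlacementTrace] | PlacementFailure:
    """Try to install ``template`` at one exchange site.

    The anchor sulfur is superposed on the leaving thiolate's sulfur and
    the S->C axis aligned with the original S->C direction; the nested
    rotational grid (outer S-Au, inner S-C, both from 0 degrees upward) is
    scanned and the first orientation whose atoms all clear ``config.d_min``
    from every atom outside the template (the leaving ligand excluded) is
    accepted immediately.

    Returns the updated model and the placement trace, or a
    :class:`PlacementFailure` result when the whole grid is exhausted.
    """
    staple_idx, lig_choice = site
    staple = model.staples[staple_idx]
    if staple.replaced[lig_choice]:
        raise ValueError(f"staple {staple_idx} ligand {lig_choice} already replaced")

    old_mol = staple.ligands[lig_choice]
    old_s = staple.sulfurs[lig_choice]
    old_atoms = model.molecule_atom_indices(old_mol)
    s_pos = model.positions[old_s]
    apex_pos = model.positions[staple.apex_gold]

    # original S->C bonding direction: nearest carbon bonded to the sulfur
    old_c = _sulfur_carbon(model, old_s, old_mol)
    sc_dir = model.positions[old_c] - s_pos
    sc_dir = sc_dir / np.linalg.norm(sc_dir)
    sau_axis = s_pos - apex_pos
    sau_axis = sau_axis / np.linalg.norm(sau_axis)

    # environment: everything except the leaving ligand (the template is
    # checked against the model it joins, original golds and all ligands
    # already present, incoming ones included)
    env_mask = np.ones(model.n_atoms, dtype=bool)
    env_mask[old_atoms] = False
    env_pos = model.positions[env_mask]
    env_tree = cKDTree(env_pos)

    local = template.positions - template.positions[template.anchor_sulfur]
    base = _align_vectors(local, local[template.axis_carbon], sc_dir)

    n_sau, n_cs = config.grid_shape
    trials = 0
    for i_sau in range(n_sau):
        theta_sau = i_sau * config.step_sau
        r_sau = rotation_about_axis(sau_axis, theta_sau)
        coords_sau = base @ r_sau.T
        cs_axis = coords_sau[template.axis_carbon]
        cs_axis = cs_axis / np.linalg.norm(cs_axis)
        for i_cs in range(n_cs):
            theta_cs = i_cs * config.step_cs
            trials += 1
            r_cs = rotation_about_axis(cs_axis, theta_cs)
            coords = coords_sau @ r_cs.T + s_pos
            d, _ = env_tree.query(coords, k=1)
            if d.min() >= config.d_min:
                new_model = _install(model, staple_idx, lig_choice, template, coords)
                trace = PlacementTrace(staple_idx, lig_choice,
                                       (theta_sau, theta_cs), trials)
                return new_model, trace
    return PlacementFailure(staple_idx, trials)


def _sulfur_carbon(model: ClusterModel, s_idx: int, mol: int) -> int:
    cands = []
    for i, j in model.bonds:
        if i == s_idx and model.elements[j] == "C":
            cands.append(j)
        elif j == s_idx and model.elements[i] == "C":
            cands.append(i)
    cands = [c for c in cands if model.molecule_ids[c] == mol]
    if not cands:
        raise ValueError(f"sulfur {s_idx} has no bonded carbon in molecule {mol}")
    return min(cands)


def _align_vectors(local: np.ndarray, from_vec: np.ndarray,
                   to_vec: np.ndarray) -> np.ndarray:
    """Rotate ``local`` (anchored at the origin) so ``from_vec`` aligns with
    ``to_vec`` (minimal rotation)."""
    a = from_vec / np.linalg.norm(from_vec)
    b = to_vec / np.linalg.norm(to_vec)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return local.copy()
        # antiparallel: rotate 180 degrees about any perpendicular
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return local @ rotation_about_axis(perp, 180.0).T
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    return local @ rot.T


def _install(model: ClusterModel, staple_idx: int, lig_choice: int,
             template: LigandTemplate, coords: np.ndarray) -> ClusterModel:
    """Replace the leaving thiolate with the placed template atoms."""
    staple = model.staples[staple_idx]
    old_mol = staple.ligands[lig_choice]
    old_atoms = set(model.molecule_atom_indices(old_mol).tolist())
    keep = [i for i in range(model.n_atoms) if i not in old_atoms]
    remap = {old: new for new, old in enumerate(keep)}

    new_mol_id = int(model.molecule_ids.max()) + 1
    n_new = template.n_atoms
    elements = np.concatenate([model.elements[keep],
                               np.asarray(template.elements, dtype=object)])
    positions = np.vstack([model.positions[keep], coords])
    molecule_ids = np.concatenate([model.molecule_ids[keep],
                                   np.full(n_new, new_mol_id)])
    components = np.concatenate([
        model.components[keep],
        np.full(n_new, template.component.value, dtype=object),
    ])
    bonds = [(remap[i], remap[j]) for i, j in model.bonds
             if i in remap and j in remap]
    offset = len(keep)
    bonds += [(offset + i, offset + j) for i, j in template.bonds]
    # the new thiolate-gold bond
    new_s = offset + template.anchor_sulfur
    apex_new = remap[staple.apex_gold]
    bonds.append(tuple(sorted((apex_new, new_s))))

    staples = []
    for k, s in enumerate(model.staples):
        apex = remap[s.apex_gold]
        sulfurs = tuple(
            remap[s.sulfurs[c]] if (k != staple_idx or c != lig_choice)
            else new_s
            for c in (0, 1)
        )
        ligands = tuple(
            s.ligands[c] if (k != staple_idx or c != lig_choice) else new_mol_id
            for c in (0, 1)
        )
        replaced = tuple(
            s.replaced[c] or (k == staple_idx and c == lig_choice)
            for c in (0, 1)
        )
        staples.append(StapleUnit(apex, sulfurs, ligands, replaced))

    return ClusterModel(elements, positions, molecule_ids, components,
                        bonds=bonds, staples=staples,
                        provenance=model.provenance)


# ---------------------------------------------------------------------------
# whole-build driver


def build_functionalized_cluster(
    model: ClusterModel,
    formulation: FormulationSpec,
    peptide_template: LigandTemplate,
    drug_template: LigandTemplate,
    config: BuilderConfig,
) -> tuple[ClusterModel, list[PlacementTrace]]:
    """Install a full formulation on the cluster.

    Sites are drawn at random (one per staple); every peptide conjugate is
    placed before any drug conjugate, in site-selection order.  When a
    placement exhausts its orientation grid the entire build restarts with
    fresh random sites (seed advanced by one), up to
    ``config.max_restarts`` restarts.  Gold atoms never move.

    Returns the functionalized model and one trace per placement.
    """
    if formulation.n_exchange != config.n_exchange:
        raise ValueError(
            f"formulation places {formulation.n_exchange} ligands but config "
            f"expects n_exchange={config.n_exchange}"
        )
    if peptide_template.component is not Component.PL:
        raise ValueError("peptide_template must carry component PL")
    if drug_template.component is not Component.DL:
        raise ValueError("drug_template must carry component DL")

    failure_counts: dict[int, int] = {}
    for restart in range(config.max_restarts + 1):
        seed = config.seed + restart
        sites = select_exchange_sites(model, config.n_exchange, seed)
        work = model.copy()
        traces: list[PlacementTrace] = []
        # site indices are stable across installs because staples are
        # re-indexed consistently inside _install
        order = ([peptide_template] * formulation.n_peptide
                 + [drug_template] * formulation.n_drug)
        failed = None
        for site, template in zip(sites, order):
            result = attempt_placement(work, site, template, config)
            if isinstance(result, PlacementFailure):
                failed = result
                break
            work, trace = result
            traces.append(trace)
        if failed is not None:
            failure_counts[failed.staple_index] = \
                failure_counts.get(failed.staple_index, 0) + 1
            continue
        return work, traces
    worst = max(failure_counts, key=failure_counts.get)
    raise RuntimeError(
        f"build failed after {config.max_restarts} restarts; most-blocked "
        f"protective unit: {worst} ({failure_counts[worst]} failures)"
    )


def min_external_distance(model: ClusterModel,
                          components: tuple = (Component.PL, Component.DL),
                          method: str = "tree") -> float:
    """Minimum distance between any placed incoming ligand and everything
    outside it, Angstrom.

    For each molecule tagged with one of ``components``, takes the minimum
    distance from its atoms to all atoms not in that molecule; returns the
    global minimum.  ``method`` selects the spatial-index ("tree") or the
    exhaustive double-loop ("brute") evaluation; both give identical
    results.
    """
    mols = model.molecules_with_component(*components)
    if not mols:
        raise ValueError(f"no molecules tagged {[Component(c).value for c in components]}")
    best = np.inf
    if method == "tree":
        for mol in mols:
            inside = model.molecule_ids == mol
            tree = cKDTree(model.positions[~inside])
            d, _ = tree.query(model.positions[inside], k=1)
            best = min(best, float(d.min()))
    elif method == "brute":
        for mol in mols:
            inside = model.molecule_ids == mol
            a = model.positions[inside]
            b = model.positions[~inside]
            for p in a:
                d = np.sqrt(((b - p) ** 2).sum(axis=1))
                best = min(best, float(d.min()))
    else:
        raise ValueError("method must be 'tree' or 'brute'")
    return best


# ---------------------------------------------------------------------------
# formulation enumeration


def split_by_ratio(n_exchange: int, ratio: tuple[int, int]) -> tuple[int, int]:
    """Split ``n_exchange`` into (n_peptide, n_drug) shares of ``ratio``."""
    a, b = ratio
    total = a + b
    frac_p = Fraction(n_exchange * a, total)
    if frac_p.denominator != 1:
        raise ValueError(
            f"ratio {a}:{b} does not split {n_exchange} into whole counts"
        )
    return int(frac_p), n_exchange - int(frac_p)


def enumerate_formulations(peptides: list[str], drugs: list[str],
                           ratios: list[tuple[int, int]],
                           n_exchange: int = 15) -> list[FormulationSpec]:
    """Cartesian product of peptides x drugs x ratios, in deterministic
    lexicographic order, with counts derived as ratio shares of
    ``n_exchange``."""
    if not peptides or not drugs or not ratios:
        raise ValueError("peptides, drugs and ratios must be non-empty")
    specs = []
    for pep, drug, ratio in itertools.product(peptides, drugs, ratios):
        n_p, n_d = split_by_ratio(n_exchange, tuple(ratio))
        specs.append(FormulationSpec(pep, drug, tuple(ratio), n_p, n_d))
    return specs


#: the design space studied for gastric-cancer-targeted clusters:
#: 2 RGD peptides x 7 drugs x 2 peptide:drug ratios = 28 formulations
DEFAULT_PEPTIDES = ["QS13", "RGD4C"]
DEFAULT_DRUGS = ["5FU", "EPI", "LIN", "TAN", "TAS", "CAP", "TOR"]
DEFAULT_RATIOS = [(1, 2), (2, 1)]
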