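"""Structure data model, file I/O, and the idealized reference cluster.

A :class:`ClusterModel` is an array-backed collection of atoms carrying,
per atom, the chemical element, Cartesian position (internally always
Angstrom), an integer molecule id, and a *component* tag that records the
role the atom plays in a protected-cluster model:

``GOLD_CORE``
    every gold atom, core shells and staple adatoms alike;
``OL``
    an original protecting thiolate (p-MBA in the reference cluster);
``PL`` / ``DL``
    incoming PEG-peptide / PEG-drug conjugates installed by ligand
    exchange;
``ION`` / ``SOLVENT``
    counterions and water in solvated analysis systems.

The protective units of a thiolate-protected cluster are RS-Au-SR
"staples": one gold adatom bridging two thiolate sulfurs.  They are the
exchangeable unit of the ligand shell and are detected geometrically here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from . import _geometry as geom
from .elements import KNOWN_ELEMENTS, covalent_cutoff, normalize_element


class Component(str, Enum):
    """Role of an atom in a protected-cluster model."""

    GOLD_CORE = "GOLD_CORE"
    OL = "OL"
    PL = "PL"
    DL = "DL"
    ION = "ION"
    SOLVENT = "SOLVENT"


#: component tag <-> residue name used in PDB/GRO output
COMPONENT_TO_RESNAME = {
    Component.GOLD_CORE: "AUC",
    Component.OL: "MBA",
    Component.PL: "PEP",
    Component.DL: "DRG",
    Component.ION: "ION",
    Component.SOLVENT: "SOL",
}
RESNAME_TO_COMPONENT = {v: k for k, v in COMPONENT_TO_RESNAME.items()}
RESNAME_TO_COMPONENT.update({"HOH": Component.SOLVENT, "WAT": Component.SOLVENT,
                             "TIP3": Component.SOLVENT, "NA": Component.ION,
                             "CL": Component.ION})


@dataclass(frozen=True)
class Atom:
    """One atom: element symbol, position (Angstrom), molecule id, component."""

    element: str
    position: np.ndarray
    molecule_id: int
    component: Component

    def __post_init__(self) -> None:
        object.__setattr__(self, "element", normalize_element(self.element))
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class StapleUnit:
    """One RS-Au-SR protective unit.

    ``apex_gold`` is the bridging adatom's atom index; ``sulfurs`` the two
    thiolate sulfur atom indices; ``ligands`` the molecule ids of the two
    thiolates; ``replaced`` marks, per ligand, whether ligand exchange has
    already installed an incoming ligand there.
    """

    apex_gold: int
    sulfurs: tuple[int, int]
    ligands: tuple[int, int]
    replaced: tuple[bool, bool] = (False, False)


@dataclass
class ClusterModel:
    """Array-backed atomistic model of a (functionalized) protected cluster.

    Attributes
    ----------
    elements : (N,) array of str
        Canonical element symbols.
    positions : (N, 3) float array
        Cartesian coordinates, Angstrom.
    molecule_ids : (N,) int array
        Molecule membership; every ligand is its own molecule, all gold
        shares one molecule.
    components : (N,) array of str
        ``Component`` values, stored as strings for fast masking.
    bonds : list of (i, j)
        Covalent bonds (atom-index pairs, i < j); may be empty.
    staples : list of StapleUnit
    provenance : str
        Free-text origin metadata (generator name, seed, source file).
    """

    elements: np.ndarray
    positions: np.ndarray
    molecule_ids: np.ndarray
    components: np.ndarray
    bonds: list[tuple[int, int]] = field(default_factory=list)
    staples: list[StapleUnit] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        self.components = np.asarray(
            [Component(c).value for c in np.asarray(self.components).ravel()],
            dtype=object,
        )
        n = len(self.elements)
        if not (len(self.positions) == len(self.molecule_ids) == len(self.components) == n):
            raise ValueError("per-atom arrays must share one length")
        if n and not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        for e in set(self.elements.tolist()):
            if e not in KNOWN_ELEMENTS:
                raise ValueError(f"unknown element symbol: {e!r}")

    # -- convenience -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_molecules(self) -> int:
        return len(np.unique(self.molecule_ids)) if self.n_atoms else 0

    def atoms(self) -> Iterable[Atom]:
        for i in range(self.n_atoms):
            yield Atom(self.elements[i], self.positions[i],
                       int(self.molecule_ids[i]), Component(self.components[i]))

    def component_mask(self, *components: Component | str) -> np.ndarray:
        tags = {Component(c).value for c in components}
        return np.isin(self.components, list(tags))

    def molecule_atom_indices(self, molecule_id: int) -> np.ndarray:
        return np.flatnonzero(self.molecule_ids == molecule_id)

    def molecule_component(self, molecule_id: int) -> Component:
        tags = set(self.components[self.molecule_ids == molecule_id].tolist())
        if len(tags) != 1:
            raise ValueError(f"molecule {molecule_id} mixes components {sorted(tags)}")
        return Component(tags.pop())

    def molecules_with_component(self, *components: Component | str) -> list[int]:
        mask = self.component_mask(*components)
        return sorted(int(m) for m in np.unique(self.molecule_ids[mask]))

    def copy(self) -> "ClusterModel":
        return ClusterModel(
            elements=self.elements.copy(),
            positions=self.positions.copy(),
            molecule_ids=self.molecule_ids.copy(),
            components=self.components.copy(),
            bonds=list(self.bonds),
            staples=[replace(s) for s in self.staples],
            provenance=self.provenance,
        )


# ---------------------------------------------------------------------------
# bond detection and molecule partitioning


_NONBONDING = {"Na", "Cl"}  # counterions: never covalently bonded


def detect_bonds(elements: Sequence[str], positions: np.ndarray,
                 scale: float = 1.2) -> list[tuple[int, int]]:
    """Covalent bonds by distance cutoff: sum of covalent radii x ``scale``.

    Gold bonds only to sulfur (fixed 2.6 A thiolate-gold cutoff); Au-Au
    metallic contacts and free counterions (Na, Cl) are not bonds.
    """
    positions = np.asarray(positions, dtype=float)
    if len(positions) == 0:
        return []
    max_cut = 2.6  # upper bound over the admissible pair cutoffs
    tree = cKDTree(positions)
    bonds = []
    for i, j in sorted(tree.query_pairs(max_cut)):
        ei, ej = elements[i], elements[j]
        if ei in _NONBONDING or ej in _NONBONDING:
            continue
        if "Au" in (ei, ej) and {ei, ej} != {"Au", "S"}:
            continue
        d = float(np.linalg.norm(positions[i] - positions[j]))
        if d <= covalent_cutoff(ei, ej, scale):
            bonds.append((i, j))
    return bonds


def molecules_from_bonds(n_atoms: int, bonds: Sequence[tuple[int, int]],
                         elements: Sequence[str] | None = None) -> np.ndarray:
    """Molecule ids as connected components of the bond graph.

    When ``elements`` is given, gold is handled specially: Au-X bonds are
    ignored for partitioning and all gold atoms (core plus staple adatoms)
    form one molecule, so each thiolate stays a molecule of its own even
    though its sulfur is bonded to gold.
    """
    if n_atoms == 0:
        return np.zeros(0, dtype=int)
    gold = None
    part_bonds = list(bonds)
    if elements is not None:
        gold = np.array([e == "Au" for e in elements])
        if gold.any():
            part_bonds = [(i, j) for i, j in part_bonds
                          if not (gold[i] or gold[j])]
    if part_bonds:
        ij = np.array(part_bonds, dtype=int)
        data = np.ones(len(ij), dtype=np.int8)
        adj = coo_matrix((data, (ij[:, 0], ij[:, 1])), shape=(n_atoms, n_atoms))
    else:
        adj = coo_matrix((n_atoms, n_atoms), dtype=np.int8)
    _, labels = connected_components(adj, directed=False)
    labels = labels.astype(int)
    if gold is not None and gold.any():
        sentinel = labels.max() + 1
        labels[gold] = sentinel
    # renumber densely in order of first appearance
    order: dict[int, int] = {}
    out = np.empty(n_atoms, dtype=int)
    for i, lab in enumerate(labels):
        out[i] = order.setdefault(int(lab), len(order))
    return out


def default_components(elements: Sequence[str],
                       molecule_ids: np.ndarray) -> np.ndarray:
    """Element-based component heuristic: Au -> GOLD_CORE, Na/Cl -> ION,
    water molecules -> SOLVENT, any other molecule -> OL."""
    comps = np.empty(len(elements), dtype=object)
    molecule_ids = np.asarray(molecule_ids)
    for mol in np.unique(molecule_ids):
        idx = np.flatnonzero(molecule_ids == mol)
        elems = sorted(elements[i] for i in idx)
        if all(e == "Au" for e in elems):
            tag = Component.GOLD_CORE
        elif elems in (["Na"], ["Cl"]):
            tag = Component.ION
        elif elems == ["H", "H", "O"] or elems == ["O"]:
            tag = Component.SOLVENT
        else:
            tag = Component.OL
        comps[idx] = tag.value
    return comps


def min_intermolecular_distance(model: ClusterModel) -> float:
    """Minimum distance between atoms of distinct molecules, Angstrom."""
    if model.n_molecules < 2:
        raise ValueError("need at least two molecules")
    tree = cKDTree(model.positions)
    best = np.inf
    # expand the query radius until a cross-molecule pair is found
    r = 3.0
    while True:
        for i, j in tree.query_pairs(r):
            if model.molecule_ids[i] != model.molecule_ids[j]:
                d = float(np.linalg.norm(model.positions[i] - model.positions[j]))
                best = min(best, d)
        if np.isfinite(best):
            return best
        r *= 2.0
        if r > 1e4:
            raise RuntimeError("no cross-molecule pair found")


# ---------------------------------------------------------------------------
# file I/O

_FORMATS = {"xyz", "pdb", "gro", "sdf"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported structure format: {fmt!r}")
    return fmt


def read_structure(path: str | Path, format: str | None = None) -> ClusterModel:
    """Read a structure file (xyz, pdb, gro, or sdf) into a ClusterModel.

    Molecule partitioning comes from residue records when the format has
    them (PDB/GRO), otherwise from covalent-radius bond detection.
    Component tags come from residue names where available, else from the
    element heuristic in :func:`default_components`; both are overridable
    by editing the returned model.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "sdf":
        return _read_sdf(path)
    return _read_mda(path, fmt)


def write_structure(model: ClusterModel, path: str | Path,
                    format: str | None = None) -> None:
    """Write a ClusterModel to xyz, pdb, or gro.

    PDB coordinates are Angstrom, GRO nanometres (converted on write); the
    output re-reads through :func:`read_structure` with coordinates equal
    within the format's field precision.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "sdf":
        raise ValueError("sdf output is supported for ligand templates only")
    if fmt == "xyz":
        _write_xyz(model, path)
        return
    if fmt == "pdb" and model.n_atoms > 99999:
        raise ValueError("atom count exceeds PDB serial field width (99999)")
    if fmt == "gro" and model.n_atoms > 99999:
        raise ValueError("atom count exceeds GRO atom-number field width")
    _write_mda(model, path, fmt)


# -- xyz dialect -----------------------------------------------------------
#
# Column layout: element x y z [molecule_id component]; the comment line
# carries key=value metadata (provenance, optional box="bx by bz" in A).


def _read_xyz(path: Path) -> ClusterModel:
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}: line 1: expected atom count") from exc
    comment = lines[1] if len(lines) > 1 else ""
    if len(lines) < 2 + n:
        raise ValueError(f"{path}: expected {n} atom lines, found {len(lines) - 2}")
    elements, positions, mols, comps = [], [], [], []
    tagged = True
    for k in range(n):
        tok = lines[2 + k].split()
        if len(tok) < 4:
            raise ValueError(f"{path}: line {3 + k}: expected >=4 fields")
        try:
            elements.append(normalize_element(tok[0]))
        except ValueError as exc:
            raise ValueError(f"{path}: line {3 + k}: {exc}") from exc
        try:
            positions.append([float(t) for t in tok[1:4]])
        except ValueError as exc:
            raise ValueError(f"{path}: line {3 + k}: bad coordinate") from exc
        if len(tok) >= 6:
            mols.append(int(tok[4]))
            comps.append(tok[5])
        else:
            tagged = False
    positions = np.array(positions, dtype=float).reshape(-1, 3)
    if tagged and n > 0:
        molecule_ids = np.array(mols)
        components = np.array(comps, dtype=object)
        bonds = detect_bonds(elements, positions)
    else:
        bonds = detect_bonds(elements, positions)
        molecule_ids = molecules_from_bonds(n, bonds, elements)
        components = default_components(np.array(elements, dtype=object), molecule_ids)
    return ClusterModel(np.array(elements, dtype=object), positions, molecule_ids,
                        components, bonds=bonds, provenance=comment.strip())


def _write_xyz(model: ClusterModel, path: Path) -> None:
    lines = [str(model.n_atoms)]
    comment = model.provenance.replace("\n", " ") or "aushell"
    lines.append(comment)
    for i in range(model.n_atoms):
        x, y, z = model.positions[i]
        lines.append(
            f"{model.elements[i]:<2s} {x:15.6f} {y:15.6f} {z:15.6f} "
            f"{int(model.molecule_ids[i]):6d} {model.components[i]}"
        )
    path.write_text("\n".join(lines) + "\n")


# -- PDB / GRO via MDAnalysis ---------------------------------------------


def _element_from_name(name: str) -> str:
    stripped = "".join(ch for ch in name if ch.isalpha())
    for cand in (stripped[:2].capitalize(), stripped[:1].upper()):
        if cand in KNOWN_ELEMENTS:
            return cand
    raise ValueError(f"cannot infer element from atom name {name!r}")


def _read_mda(path: Path, fmt: str) -> ClusterModel:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    n = len(u.atoms)
    if hasattr(u.atoms, "elements") and all(e for e in u.atoms.elements):
        elements = [normalize_element(e) for e in u.atoms.elements]
    else:
        elements = [_element_from_name(nm) for nm in u.atoms.names]
    positions = u.atoms.positions.astype(float)  # MDAnalysis is Angstrom-native
    resids = u.atoms.resids
    # dense molecule ids in order of first appearance
    order: dict[int, int] = {}
    molecule_ids = np.array([order.setdefault(int(r), len(order)) for r in resids])
    comps = np.empty(n, dtype=object)
    known = np.zeros(n, dtype=bool)
    for i, resname in enumerate(u.atoms.resnames):
        tag = RESNAME_TO_COMPONENT.get(resname.strip().upper())
        if tag is not None:
            comps[i] = tag.value
            known[i] = True
    if not known.all():
        fallback = default_components(np.array(elements, dtype=object), molecule_ids)
        comps[~known] = fallback[~known]
    bonds = detect_bonds(elements, positions)
    return ClusterModel(np.array(elements, dtype=object), positions, molecule_ids,
                        comps, bonds=bonds, provenance=f"read from {path.name}")


def _write_mda(model: ClusterModel, path: Path, fmt: str) -> None:
    import MDAnalysis as mda

    n = model.n_atoms
    mols = model.molecule_ids
    # one residue per molecule, resname from the molecule's component tag
    uniq = []
    seen = set()
    for m in mols:
        if int(m) not in seen:
            seen.add(int(m))
            uniq.append(int(m))
    res_index = {m: k for k, m in enumerate(uniq)}
    atom_res = np.array([res_index[int(m)] for m in mols])
    resnames = []
    for m in uniq:
        tag = model.molecule_component(m)
        resnames.append(COMPONENT_TO_RESNAME[tag])
    u = mda.Universe.empty(n_atoms=max(n, 1), n_residues=max(len(uniq), 1),
                           atom_resindex=atom_res if n else None,
                           trajectory=True)
    if n == 0:
        # header-only file for an empty model
        path.write_text("TITLE aushell empty model\nEND\n" if fmt == "pdb"
                        else "aushell empty model\n0\n   0.00000   0.00000   0.00000\n")
        return
    counters: dict[tuple[int, str], int] = {}
    names = []
    for i in range(n):
        key = (int(mols[i]), model.elements[i])
        counters[key] = counters.get(key, 0) + 1
        names.append(f"{model.elements[i]}{counters[key]}"[:4])
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("elements", [e for e in model.elements])
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", [m + 1 for m in range(len(uniq))])
    u.atoms.positions = model.positions
    u.dimensions = _bounding_box_dimensions(model.positions)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def _bounding_box_dimensions(positions: np.ndarray) -> np.ndarray:
    span = positions.max(axis=0) - positions.min(axis=0) + 20.0
    return np.array([*span, 90.0, 90.0, 90.0], dtype=np.float32)


def _read_sdf(path: Path) -> ClusterModel:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    mols = [m for m in supplier if m is not None]
    if not mols:
        raise ValueError(f"{path}: no molecules parsed from SDF")
    elements, positions, mol_ids, bonds = [], [], [], []
    offset = 0
    for mol_id, mol in enumerate(mols):
        conf = mol.GetConformer()
        for atom in mol.GetAtoms():
            elements.append(normalize_element(atom.GetSymbol()))
            p = conf.GetAtomPosition(atom.GetIdx())
            positions.append([p.x, p.y, p.z])
            mol_ids.append(mol_id)
        for b in mol.GetBonds():
            bonds.append((offset + b.GetBeginAtomIdx(), offset + b.GetEndAtomIdx()))
        offset += mol.GetNumAtoms()
    molecule_ids = np.array(mol_ids)
    elements_arr = np.array(elements, dtype=object)
    comps = default_components(elements_arr, molecule_ids)
    return ClusterModel(elements_arr, np.array(positions), molecule_ids, comps,
                        bonds=bonds, provenance=f"read from {path.name}")


# ---------------------------------------------------------------------------
# protective-unit (staple) detection


def detect_protective_units(model: ClusterModel,
                            au_s_cutoff: float = 2.6) -> list[StapleUnit]:
    """Find every RS-Au-SR staple: a gold atom bonded to exactly two
    sulfurs, each sulfur carrying one thiolate ligand (a bonded carbon).

    Returns units ordered by apex-gold atom index.  A sulfur claimed by two
    candidate apex golds indicates malformed geometry and raises.
    """
    gold = np.flatnonzero(model.elements == "Au")
    sulfur = np.flatnonzero(model.elements == "S")
    if len(gold) == 0 or len(sulfur) == 0:
        return []
    s_tree = cKDTree(model.positions[sulfur])
    neighbor_lists = s_tree.query_ball_point(model.positions[gold], au_s_cutoff)

    # sulfur qualifies only if it has a bonded carbon (it heads a thiolate)
    bonded_c = set()
    for i, j in model.bonds or detect_bonds(model.elements, model.positions):
        ei, ej = model.elements[i], model.elements[j]
        if {ei, ej} == {"S", "C"}:
            bonded_c.add(i if ei == "S" else j)

    units: list[StapleUnit] = []
    claimed: dict[int, int] = {}
    for g_local, neigh in enumerate(neighbor_lists):
        s_idx = [int(sulfur[k]) for k in neigh]
        s_idx = [s for s in s_idx if s in bonded_c]
        if len(s_idx) != 2:
            continue
        apex = int(gold[g_local])
        s_idx.sort()
        lig = tuple(int(model.molecule_ids[s]) for s in s_idx)
        if lig[0] == lig[1]:
            continue  # bidentate same-molecule bridge is not an exchangeable unit
        for s in s_idx:
            if s in claimed:
                raise ValueError(
                    f"sulfur atom {s} bridges two candidate apex golds "
                    f"({claimed[s]} and {apex}): malformed staple geometry"
                )
            claimed[s] = apex
        replaced = tuple(
            model.molecule_component(m) is not Component.OL for m in lig
        )
        units.append(StapleUnit(apex, (s_idx[0], s_idx[1]), lig, replaced))
    units.sort(key=lambda u: u.apex_gold)
    return units


# ---------------------------------------------------------------------------
# idealized reference cluster

# Idealized Au144 layout constants, Angstrom / degrees.  The metal core is
# the known 12 + 42 + 60 icosahedral arrangement (inner icosahedron, Mackay
# second shell, rhombicosidodecahedral outer shell) with 30 RS-Au-SR
# adatoms above the square-face (edge-midpoint) directions.  Near-neighbor
# Au-Au spacing ~2.75-2.8 A and a ~1.7 nm metal-core diameter fix the
# scale; the two thiolates of each staple lean toward each other so their
# aryl rings pair up face-to-face, the pi-stacked dimer motif aromatic
# ligand shells adopt, which closes the inter-ligand crevices.
_SHELL_SCALE = 2.78          # inner icosahedron radius; Mackay shell at 2x
_R60 = 7.10                  # rhombicosidodecahedral 60-shell radius
_R_ADATOM = 8.30             # staple adatom radius (max Au-Au = 16.6 A)
_AU_S_BOND = 2.33            # staple Au-S bond length
_S_LIFT = 12.0               # S tilt out of the tangent plane, degrees;
                             # keeps sulfurs > 2.6 A from core golds
_DIMER_TILT = 20.0           # per-ligand lean toward its staple partner
_RING_ROLL = 55.0            # ligand roll about its axis; staggers rings
_CLASH_LIMIT = 1.75          # hard minimum inter-molecular distance


def _core_positions(n_core: int, n_units: int = 0) -> np.ndarray:
    """First ``n_core`` metal-core positions, filled shell by shell.

    Adatom-shell directions not occupied by staples (beyond ``n_units``)
    serve as the outermost fill layer, so a bare 144-atom core is the full
    decorated layout minus ligands.
    """
    v = geom.icosahedron_vertices()
    edges = geom.icosahedron_edges(v)
    shell1 = _SHELL_SCALE * v
    shell2 = np.vstack([
        2.0 * _SHELL_SCALE * v,
        _SHELL_SCALE * np.array([v[i] + v[j] for i, j in edges]),
    ])
    shell3 = _R60 * geom.rhombicosidodecahedron_vertices()
    spare_adatoms = _R_ADATOM * geom.edge_midpoint_directions()[n_units:]
    all_pos = np.vstack([shell1, shell2, shell3, spare_adatoms])
    if n_core > len(all_pos):
        raise ValueError(
            f"metal cores larger than {len(all_pos)} golds are not supported "
            f"with {n_units} protective units (requested {n_core})"
        )
    return all_pos[:n_core]


def _place_template(template, s_position: np.ndarray, axis: np.ndarray,
                    roll_reference: np.ndarray) -> np.ndarray:
    """World coordinates for a ligand template: anchor sulfur moved to
    ``s_position`` with the S->C axis along ``axis``."""
    local = template.positions - template.positions[template.anchor_sulfur]
    sc = local[template.axis_carbon]
    frame_local = geom.frame_from_axis(sc)
    frame_world = geom.frame_from_axis(axis, roll_reference)
    rot = frame_world @ frame_local.T
    return (rot @ local.T).T + np.asarray(s_position)


def generate_reference_cluster(n_gold: int = 144, n_ligands: int = 60,
                               ligand=None) -> ClusterModel:
    """Build the idealized thiolate-protected reference cluster.

    Defaults give Au144(p-MBA)60: a 114-atom icosahedral metal core
    (12 + 42 + 60 shells), 30 gold adatoms forming RS-Au-SR staples above
    the edge-midpoint directions, and 60 p-MBA thiolates pointing radially
    outward.  The construction is geometric, not DFT-optimized; it
    reproduces the ~1.7 nm metal-core diameter and a clash-free ligand
    shell (all inter-molecular distances >= 1.75 A).

    Parameters
    ----------
    n_gold : total gold count including staple adatoms (default 144).
    n_ligands : thiolate count; must be even, two per staple (default 60).
    ligand : LigandTemplate for the protecting thiolate; default p-MBA.
    """
    if n_ligands % 2:
        raise ValueError("n_ligands must be even (two thiolates per staple)")
    n_units = n_ligands // 2
    if n_gold < n_units:
        raise ValueError("need at least one gold adatom per protective unit")
    if n_units > 30:
        raise ValueError("at most 30 protective units fit the idealized layout")
    if ligand is None:
        from .ligands import p_mba_template

        ligand = p_mba_template()

    n_core = n_gold - n_units
    core = _core_positions(n_core, n_units)

    elements: list[str] = ["Au"] * n_core
    positions: list[np.ndarray] = [p for p in core]
    molecule_ids: list[int] = [0] * n_core
    components: list[str] = [Component.GOLD_CORE.value] * n_core

    staple_dirs = geom.edge_midpoint_directions()[:n_units]
    tangents = geom.edge_tangents()[:n_units]
    cos_lift = np.cos(np.deg2rad(_S_LIFT))
    sin_lift = np.sin(np.deg2rad(_S_LIFT))
    staples: list[StapleUnit] = []
    next_mol = 1
    for u_dir, t in zip(staple_dirs, tangents):
        apex = _R_ADATOM * u_dir
        apex_idx = len(elements)
        elements.append("Au")
        positions.append(apex)
        molecule_ids.append(0)
        components.append(Component.GOLD_CORE.value)
        s_indices = []
        lig_mols = []
        for sign in (1.0, -1.0):
            s_pos = apex + _AU_S_BOND * (sign * cos_lift * t + sin_lift * u_dir)
            radial = s_pos / np.linalg.norm(s_pos)
            t_perp = t - (t @ radial) * radial
            t_perp /= np.linalg.norm(t_perp)
            # lean toward the staple partner to pair the rings face-to-face
            axis = (np.cos(np.deg2rad(_DIMER_TILT)) * radial
                    - sign * np.sin(np.deg2rad(_DIMER_TILT)) * t_perp)
            roll_ref = geom.rotation_about_axis(axis, _RING_ROLL) @ (sign * t)
            coords = _place_template(ligand, s_pos, axis, roll_ref)
            s_indices.append(len(elements) + ligand.anchor_sulfur)
            lig_mols.append(next_mol)
            for k in range(len(coords)):
                elements.append(ligand.elements[k])
                positions.append(coords[k])
                molecule_ids.append(next_mol)
                components.append(Component.OL.value)
            next_mol += 1
        staples.append(StapleUnit(apex_idx, (s_indices[0], s_indices[1]),
                                  (lig_mols[0], lig_mols[1])))

    model = ClusterModel(
        np.array(elements, dtype=object),
        np.array(positions),
        np.array(molecule_ids),
        np.array(components, dtype=object),
        bonds=[],
        staples=staples,
        provenance=f"aushell reference cluster n_gold={n_gold} n_ligands={n_ligands}",
    )
    model.bonds = detect_bonds(model.elements, model.positions)
    if n_units and model.n_molecules > 1:
        dmin = min_intermolecular_distance(model)
        if dmin < _CLASH_LIMIT - 1e-9:
            raise RuntimeError(
                f"idealized decoration produced an inter-molecular clash "
                f"({dmin:.3f} A < {_CLASH_LIMIT} A)"
            )
    return model


def core_diameter(model: ClusterModel) -> float:
    """Metal-core diameter: maximum pairwise Au-Au distance, nanometres."""
    gold = model.positions[model.elements == "Au"]
    if len(gold) < 2:
        raise ValueError("core_diameter needs at least two gold atoms")
    # pairwise max; cluster cores are small enough for the dense form
    d2 = ((gold[:, None, :] - gold[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max())) / 10.0
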