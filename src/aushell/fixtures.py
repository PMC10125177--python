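"""Synthetic fixtures: toy clusters, stand-in payloads, toy trajectories.

Everything here is generated, seeded, and reproducible byte-for-byte;
nothing is downloaded.  The payload molecules are deliberately simple
synthetic stand-ins (a rigid aromatic amine "drug", a short oligoglycine
"peptide") that exercise the conjugation and placement machinery without
modelling any real therapeutic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _geometry as geom
from .ligands import LigandTemplate, PayloadSpec, _zigzag_positions, _methylene_hydrogens
from .structures import (
    ClusterModel,
    Component,
    StapleUnit,
    detect_bonds,
    min_intermolecular_distance,
)


@dataclass
class FixtureSpec:
    """Declarative fixture request: a kind plus kind-specific parameters."""

    kind: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = {"reference_cluster", "toy_cluster", "toy_trajectory"}
        if self.kind not in known:
            raise ValueError(f"unknown fixture kind {self.kind!r}")


# ---------------------------------------------------------------------------
# toy cluster


def methylthiolate_template() -> LigandTemplate:
    """SCH3 thiolate in the local frame (anchor S at origin, C on +z)."""
    elements = ["S", "C", "H", "H", "H"]
    c = np.array([0.0, 0.0, 1.81])
    positions = [np.zeros(3), c]
    # three tetrahedral hydrogens around the S-C axis
    for k in range(3):
        th = np.deg2rad(120.0 * k)
        d = np.array([np.cos(th) * np.sin(np.deg2rad(70.5)),
                      np.sin(th) * np.sin(np.deg2rad(70.5)),
                      np.cos(np.deg2rad(70.5))])
        positions.append(c + 1.09 * d)
    bonds = [(0, 1), (1, 2), (1, 3), (1, 4)]
    return LigandTemplate(np.array(elements, dtype=object), np.array(positions),
                          anchor_sulfur=0, axis_carbon=1, bonds=bonds,
                          rotatable_bonds=[], backbone=[0, 1],
                          component=Component.OL, name="methylthiolate")


def make_toy_cluster(k_staples: int, seed: int = 0) -> ClusterModel:
    """Small test cluster: a 13-atom icosahedral gold core carrying
    ``k_staples`` RS-Au-SR units with methylthiolate ligands.

    The staple directions are a random subset of the 12 core vertex
    directions (seeded), so different seeds give different decorations
    with identical counts.  Raises when the requested decoration cannot
    be placed clash-free.
    """
    if k_staples < 0:
        raise ValueError("k_staples must be non-negative")
    if k_staples > 6:
        raise ValueError("at most 6 staples stay clash-free on the 13-atom core")
    r_core = 2.78
    verts = geom.icosahedron_vertices()
    core = np.vstack([np.zeros(3), r_core * verts])

    rng = np.random.default_rng(seed)
    dirs_idx = rng.choice(12, size=k_staples, replace=False)

    lig = methylthiolate_template()
    elements = ["Au"] * 13
    positions = [p for p in core]
    molecule_ids = [0] * 13
    components = [Component.GOLD_CORE.value] * 13
    staples: list[StapleUnit] = []
    next_mol = 1
    local = lig.positions - lig.positions[lig.anchor_sulfur]
    fl = geom.frame_from_axis(local[lig.axis_carbon])

    def staple_coords(w: np.ndarray, roll: float):
        """Apex plus both ligand coordinate blocks for one roll angle."""
        ref = geom.frame_from_axis(w)[:, 0]
        t = geom.rotation_about_axis(w, roll) @ ref
        apex = (r_core + 2.7) * w
        blocks = []
        for sign in (1.0, -1.0):
            s_pos = apex + 2.33 * (sign * np.cos(np.deg2rad(15)) * t
                                   + np.sin(np.deg2rad(15)) * w)
            axis = s_pos / np.linalg.norm(s_pos)
            fw = geom.frame_from_axis(axis, sign * t)
            blocks.append((fw @ fl.T @ local.T).T + s_pos)
        return apex, blocks

    for di in sorted(int(d) for d in dirs_idx):
        w = verts[di]
        start_roll = float(rng.uniform(0, 360))
        placed = None
        for attempt in range(24):  # deterministic roll retries, 15 deg apart
            apex, blocks = staple_coords(w, start_roll + 15.0 * attempt)
            new_atoms = np.vstack(blocks)
            existing = np.array(positions)
            d_env = np.linalg.norm(existing[:, None, :] - new_atoms[None], axis=-1).min()
            d_pair = np.linalg.norm(blocks[0][:, None, :] - blocks[1][None], axis=-1).min()
            d_apex = min(np.linalg.norm(b - apex, axis=1).min() for b in blocks)
            if min(d_env, d_pair) >= 1.75 and d_apex >= 1.75:
                placed = (apex, blocks)
                break
        if placed is None:
            raise RuntimeError(
                f"toy decoration with k={k_staples} could not be placed clash-free"
            )
        apex, blocks = placed
        apex_idx = len(elements)
        elements.append("Au")
        positions.append(apex)
        molecule_ids.append(0)
        components.append(Component.GOLD_CORE.value)
        s_indices, lig_mols = [], []
        for coords in blocks:
            s_indices.append(len(elements) + lig.anchor_sulfur)
            lig_mols.append(next_mol)
            for k in range(lig.n_atoms):
                elements.append(lig.elements[k])
                positions.append(coords[k])
                molecule_ids.append(next_mol)
                components.append(Component.OL.value)
            next_mol += 1
        staples.append(StapleUnit(apex_idx, tuple(s_indices), tuple(lig_mols)))

    model = ClusterModel(
        np.array(elements, dtype=object), np.array(positions),
        np.array(molecule_ids), np.array(components, dtype=object),
        staples=staples,
        provenance=f"aushell toy cluster k={k_staples} seed={seed}",
    )
    model.bonds = detect_bonds(model.elements, model.positions)
    if k_staples and model.n_molecules > 1:
        if min_intermolecular_distance(model) < 1.75:
            raise RuntimeError(
                f"toy decoration with k={k_staples} could not be placed clash-free"
            )
    return model


# ---------------------------------------------------------------------------
# synthetic payload stand-ins


def toy_drug_payload() -> PayloadSpec:
    """Synthetic rigid-ring 'drug': an aromatic amine (aniline-like).

    A stand-in used to exercise conjugation and placement; it does not
    model any real therapeutic.
    """
    ring_r = 1.39
    elements = ["N", "H", "H"]
    n_pos = np.zeros(3)
    positions = [n_pos,
                 np.array([0.4, 0.9, -0.4]),
                 np.array([0.4, -0.9, -0.4])]
    bonds = [(0, 1), (0, 2)]
    # ring attached to N along +z
    center = np.array([0.0, 0.0, 1.41 + ring_r])
    ring_start = len(elements)
    for k in range(6):
        th = np.deg2rad(60.0 * k)
        elements.append("C")
        positions.append(center + ring_r * np.array([np.sin(th), 0.0, -np.cos(th)]))
    bonds.append((0, ring_start))
    bonds += [(ring_start + k, ring_start + (k + 1) % 6) for k in range(6)]
    for k in range(1, 6):
        c = positions[ring_start + k]
        d = (c - center) / np.linalg.norm(c - center)
        elements.append("H")
        positions.append(c + 1.08 * d)
        bonds.append((ring_start + k, len(elements) - 1))
    model = ClusterModel(
        np.array(elements, dtype=object), np.array(positions),
        np.zeros(len(elements), dtype=int),
        np.array([Component.OL.value] * len(elements), dtype=object),
        bonds=bonds, provenance="synthetic rigid-ring drug stand-in",
    )
    return PayloadSpec(model, attach_atom=0, payload_class="drug", name="ringamine")


def toy_peptide_payload(n_residues: int = 5) -> PayloadSpec:
    """Synthetic oligoglycine 'peptide' with a free N-terminal amine.

    A stand-in: an all-anti glycine backbone (N-CA-C')_n with carbonyl
    oxygens and a terminal carboxyl, coupled through the N-terminus.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    chain = (["N", "C", "C"] * n_residues) + ["O"]
    backbone = _zigzag_positions(chain)
    elements: list[str] = []
    positions: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    bb_idx: list[int] = []
    for k, (el, p) in enumerate(zip(chain, backbone)):
        idx = len(elements)
        elements.append(el)
        positions.append(p)
        bb_idx.append(idx)
        if k > 0:
            bonds.append((bb_idx[k - 1], idx))
        role = k % 3  # 0=N, 1=CA, 2=C'
        if el == "N":
            # amide H (terminal N gets two)
            nxt = backbone[k + 1]
            prev = backbone[k - 1] if k else p + np.array([0.3, 0.8, -0.8])
            for h in _methylene_hydrogens(p, prev, nxt)[: (2 if k == 0 else 1)]:
                h_idx = len(elements)
                elements.append("H")
                positions.append(h)
                bonds.append((idx, h_idx))
        elif role == 1:  # CA with two hydrogens
            nxt = backbone[k + 1]
            for h in _methylene_hydrogens(p, backbone[k - 1], nxt):
                h_idx = len(elements)
                elements.append("H")
                positions.append(h)
                bonds.append((idx, h_idx))
        elif role == 2 and k < len(chain) - 1:
            # carbonyl O perpendicular to the (xz) backbone plane
            o_idx = len(elements)
            elements.append("O")
            positions.append(p + 1.23 * np.array([0.0, 1.0, 0.0]))
            bonds.append((idx, o_idx))
    # terminal O gets a hydroxyl hydrogen
    last_o = bb_idx[-1]
    d = positions[last_o] - positions[bb_idx[-2]]
    d /= np.linalg.norm(d)
    elements.append("H")
    positions.append(positions[last_o] + 0.97 * d)
    bonds.append((last_o, len(elements) - 1))

    model = ClusterModel(
        np.array(elements, dtype=object), np.array(positions),
        np.zeros(len(elements), dtype=int),
        np.array([Component.OL.value] * len(elements), dtype=object),
        bonds=bonds,
        provenance=f"synthetic {n_residues}-residue glycine peptide stand-in",
    )
    return PayloadSpec(model, attach_atom=0, payload_class="peptide",
                       name=f"gly{n_residues}")


# ---------------------------------------------------------------------------
# toy trajectories with known ground truth


def make_toy_trajectory(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write a toy multi-model PDB trajectory plus a ground-truth JSON.

    Kinds (``spec.parameters['kind']`` is ``toy_trajectory``; the flavor
    comes from ``parameters['flavor']``):

    ``rigid_translation``
        a copy of a small molecule rigidly translated per frame: the Rg is
        exactly constant across frames;
    ``ion_shell``
        static sulfur "anchors" plus ions placed on a spherical shell at a
        fixed radius from each anchor: the RDF has its mode at that radius;
    ``ideal_gas``
        two species uniformly random in a periodic box: g(r) ~ 1.

    Returns the ground-truth dictionary (also written as JSON).
    """
    if spec.kind != "toy_trajectory":
        raise ValueError("spec.kind must be 'toy_trajectory'")
    p = dict(spec.parameters)
    flavor = p.get("flavor", "rigid_translation")
    seed = int(p.get("seed", 0))
    n_frames = int(p.get("n_frames", 10))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    if flavor == "rigid_translation":
        base = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [0.0, 1.5, 0.0],
                         [0.0, 0.0, 1.5], [1.5, 1.5, 1.5]])
        elements = ["C"] * len(base)
        frames = [base + rng.uniform(-5, 5, size=3) for _ in range(n_frames)]
        box = np.array([40.0, 40.0, 40.0])
        r = base - base.mean(axis=0)
        truth = {"rg_nm": float(np.sqrt((r ** 2).sum(axis=1).mean()) / 10.0)}
    elif flavor == "ion_shell":
        shell_nm = float(p.get("shell_radius", 0.27))
        n_anchors = int(p.get("n_anchors", 4))
        box = np.array([60.0, 60.0, 60.0])
        anchors = rng.uniform(15.0, 45.0, size=(n_anchors, 3))
        elements = ["S"] * n_anchors + ["Na"] * n_anchors
        frames = []
        for _ in range(n_frames):
            u = rng.normal(size=(n_anchors, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            ions = anchors + shell_nm * 10.0 * u
            frames.append(np.vstack([anchors, ions]))
        truth = {"shell_radius_nm": shell_nm}
    elif flavor == "ideal_gas":
        n_a = int(p.get("n_a", 60))
        n_b = int(p.get("n_b", 60))
        box = np.array([50.0, 50.0, 50.0])
        elements = ["C"] * n_a + ["Na"] * n_b
        frames = [rng.uniform(0, 50.0, size=(n_a + n_b, 3))
                  for _ in range(n_frames)]
        truth = {"expected_g": 1.0}
    else:
        raise ValueError(f"unknown trajectory flavor {flavor!r}")

    pdb_path = out_dir / f"{flavor}.pdb"
    _write_multimodel_pdb(pdb_path, elements, frames, box)
    truth.update({"flavor": flavor, "seed": seed, "n_frames": n_frames,
                  "box_angstrom": box.tolist()})
    (out_dir / f"{flavor}.json").write_text(json.dumps(truth, indent=1))
    return truth


def _write_multimodel_pdb(path: Path, elements: list[str],
                          frames: list[np.ndarray], box: np.ndarray) -> None:
    lines = [f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
             f"  90.00  90.00  90.00 P 1           1"]
    for m, pos in enumerate(frames, start=1):
        lines.append(f"MODEL     {m:4d}")
        for i, (el, p) in enumerate(zip(elements, pos), start=1):
            name = el.upper().ljust(3)
            lines.append(
                f"ATOM  {i:5d}  {name}{'MOL':>4s} A{1:4d}    "
                f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}  1.00  0.00"
                f"          {el.upper():>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
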