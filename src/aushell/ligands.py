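"""Incoming-ligand templates: PEG thiol linkers and payload conjugates.

An incoming ligand is built in three steps mirroring the wet-lab route:

1. :func:`make_peg_linker` constructs a thiol PEG spacer
   HS-(CH2)_a-(O-CH2-CH2)_n-O-CH2-COOH with idealized bond geometry.  The
   long spacer (``n_eg=6``) carries targeting peptides, the short one
   (``n_eg=3``) carries drugs.
2. :func:`conjugate_payload` forms the amide bond between the linker
   carboxyl and a primary amine of the payload (carbodiimide-style
   coupling as a pure bond-topology operation: one water equivalent is
   lost, no charges or force-field typing).
3. :func:`elongate_conformer` sets every backbone dihedral anti so the
   conjugate maximizes its outreach from the cluster surface before
   placement.

Templates live in a local frame with the anchor (thiolate) sulfur that
will bind the staple gold, plus the first carbon defining the S->C axis
used by the placement sampler.  Thiol templates are stored in the
thiolate form (no S-H hydrogen), ready for attachment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._geometry import rotation_about_axis
from .structures import ClusterModel, Component, detect_bonds

# idealized geometry constants, Angstrom / degrees
BOND_LENGTH = {
    ("C", "C"): 1.54,
    ("C", "O"): 1.43,
    ("C", "S"): 1.81,
    ("C", "H"): 1.09,
    ("C", "N"): 1.47,
    ("H", "N"): 1.01,
    ("H", "O"): 0.97,
}
AMIDE_CN = 1.33
CARBONYL_CO = 1.21
CARBOXYL_CO = 1.34
TETRAHEDRAL = 109.47


def _blen(a: str, b: str) -> float:
    return BOND_LENGTH[tuple(sorted((a, b)))]


@dataclass
class LigandTemplate:
    """A ligand's local-frame geometry plus the attachment bookkeeping.

    ``anchor_sulfur`` indexes the thiolate sulfur, ``axis_carbon`` the
    carbon bonded to it (their direction is the placement alignment axis),
    ``backbone`` the ordered chain the rotatable dihedrals run along.
    """

    elements: np.ndarray
    positions: np.ndarray
    anchor_sulfur: int
    axis_carbon: int
    bonds: list[tuple[int, int]]
    rotatable_bonds: list[tuple[int, int]] = field(default_factory=list)
    backbone: list[int] = field(default_factory=list)
    component: Component = Component.OL
    name: str = ""

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.elements[self.anchor_sulfur] != "S":
            raise ValueError("anchor_sulfur must index a sulfur atom")
        pair = tuple(sorted((self.anchor_sulfur, self.axis_carbon)))
        if pair not in {tuple(sorted(b)) for b in self.bonds}:
            raise ValueError("axis_carbon must be bonded to anchor_sulfur")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def outreach(self) -> float:
        """Anchor-sulfur-to-farthest-atom distance, Angstrom."""
        d = np.linalg.norm(self.positions - self.positions[self.anchor_sulfur],
                           axis=1)
        return float(d.max())

    def copy(self) -> "LigandTemplate":
        return LigandTemplate(self.elements.copy(), self.positions.copy(),
                              self.anchor_sulfur, self.axis_carbon,
                              list(self.bonds), list(self.rotatable_bonds),
                              list(self.backbone), self.component, self.name)


@dataclass
class PayloadSpec:
    """A drug or peptide to be coupled onto a PEG linker.

    ``structure`` holds the payload geometry (one molecule, read from SDF
    or PDB); ``attach_atom`` indexes the primary-amine nitrogen that reacts
    in the coupling; ``payload_class`` is ``"peptide"`` or ``"drug"``.
    """

    structure: ClusterModel
    attach_atom: int
    payload_class: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.payload_class not in ("peptide", "drug"):
            raise ValueError("payload_class must be 'peptide' or 'drug'")
        s = self.structure
        if s.elements[self.attach_atom] != "N":
            raise ValueError("attach_atom must index a nitrogen")
        if not self._amine_hydrogens():
            raise ValueError("attach_atom nitrogen carries no hydrogen "
                             "(not a primary/secondary amine)")

    def _amine_hydrogens(self) -> list[int]:
        bonds = self.structure.bonds or detect_bonds(
            self.structure.elements, self.structure.positions)
        hs = []
        for i, j in bonds:
            if i == self.attach_atom and self.structure.elements[j] == "H":
                hs.append(j)
            elif j == self.attach_atom and self.structure.elements[i] == "H":
                hs.append(i)
        return sorted(hs)


# ---------------------------------------------------------------------------
# linker construction


def _zigzag_positions(chain: list[str]) -> np.ndarray:
    """All-anti backbone: planar zigzag in the xz plane, +z propagation."""
    half = np.deg2rad((180.0 - TETRAHEDRAL) / 2.0)
    pos = [np.zeros(3)]
    sign = 1.0
    for k in range(1, len(chain)):
        b = _blen(chain[k - 1], chain[k])
        step = np.array([sign * np.sin(half), 0.0, np.cos(half)]) * b
        pos.append(pos[-1] + step)
        sign = -sign
    return np.array(pos)


def _methylene_hydrogens(c: np.ndarray, prev: np.ndarray,
                         nxt: np.ndarray) -> list[np.ndarray]:
    u1 = (prev - c) / np.linalg.norm(prev - c)
    u2 = (nxt - c) / np.linalg.norm(nxt - c)
    bis = -(u1 + u2)
    bis /= np.linalg.norm(bis)
    perp = np.cross(u1, u2)
    perp /= np.linalg.norm(perp)
    out = []
    for s in (1.0, -1.0):
        d = bis + s * np.sqrt(2.0) * perp
        d /= np.linalg.norm(d)
        out.append(c + _blen("C", "H") * d)
    return out


def make_peg_linker(n_eg: int, alkyl_len: int = 11,
                    name: str | None = None) -> LigandTemplate:
    """Thiol PEG spacer HS-(CH2)_alkyl_len-(O-CH2-CH2)_n_eg-O-CH2-COOH.

    All-anti backbone with idealized bond lengths and tetrahedral angles;
    the terminal carboxyl is intact (protonated) and every backbone bond is
    recorded as rotatable.  ``n_eg=6``/``n_eg=3`` with the default C11
    alkyl reproduce the long (peptide) and short (drug) spacers.
    """
    if n_eg < 0 or alkyl_len < 1:
        raise ValueError("need n_eg >= 0 and alkyl_len >= 1")
    chain = ["S"] + ["C"] * alkyl_len
    for _ in range(n_eg):
        chain += ["O", "C", "C"]
    chain += ["O", "C", "C"]  # -O-CH2- then the carboxyl carbon
    backbone_pos = _zigzag_positions(chain)

    elements: list[str] = []
    positions: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    backbone_idx: list[int] = []
    for k, (el, p) in enumerate(zip(chain, backbone_pos)):
        idx = len(elements)
        elements.append(el)
        positions.append(p)
        backbone_idx.append(idx)
        if k > 0:
            bonds.append((backbone_idx[k - 1], idx))
        is_carboxyl_c = k == len(chain) - 1
        if el == "C" and not is_carboxyl_c:
            nxt = backbone_pos[k + 1] if k + 1 < len(chain) else \
                p + (p - backbone_pos[k - 1])
            for h in _methylene_hydrogens(p, backbone_pos[k - 1], nxt):
                h_idx = len(elements)
                elements.append("H")
                positions.append(h)
                bonds.append((idx, h_idx))

    # trigonal carboxyl in the backbone plane: C=O and C-O-H
    c7 = backbone_idx[-1]
    c_pos = positions[c7]
    prev = backbone_pos[len(chain) - 2]
    axis_in = (c_pos - prev) / np.linalg.norm(c_pos - prev)
    perp = np.cross(np.array([0.0, 1.0, 0.0]), axis_in)
    perp /= np.linalg.norm(perp)
    # sp2 substituent directions at +-120 degrees from the C->prev direction
    d_carbonyl = np.cos(np.deg2rad(120.0)) * -axis_in + np.sin(np.deg2rad(120.0)) * perp
    d_hydroxyl = np.cos(np.deg2rad(120.0)) * -axis_in - np.sin(np.deg2rad(120.0)) * perp
    o1 = len(elements)
    elements.append("O")
    positions.append(c_pos + CARBONYL_CO * d_carbonyl)
    bonds.append((c7, o1))
    o2 = len(elements)
    elements.append("O")
    positions.append(c_pos + CARBOXYL_CO * d_hydroxyl)
    bonds.append((c7, o2))
    h_o = len(elements)
    elements.append("H")
    oh_dir = (positions[o2] - c_pos) / np.linalg.norm(positions[o2] - c_pos)
    positions.append(positions[o2] + _blen("O", "H") * oh_dir)
    bonds.append((o2, h_o))

    rotatable = [(backbone_idx[k], backbone_idx[k + 1])
                 for k in range(len(backbone_idx) - 1)]
    if name is None:
        name = f"HS-C{alkyl_len}-(EG){n_eg}-OCH2-COOH"
    return LigandTemplate(
        np.array(elements, dtype=object), np.array(positions),
        anchor_sulfur=0, axis_carbon=backbone_idx[1], bonds=bonds,
        rotatable_bonds=rotatable, backbone=backbone_idx,
        component=Component.OL, name=name,
    )


def p_mba_template() -> LigandTemplate:
    """para-mercaptobenzoate (deprotonated p-MBA) in the local frame:
    anchor sulfur at the origin, ring axis along +z, carboxylate para."""
    ring_r = 1.39
    elements = ["S", "C", "C", "C", "C", "C", "C"]
    zc = 1.78 + ring_r
    positions = [np.zeros(3)]
    for k in range(6):
        th = np.deg2rad(60.0 * k)
        positions.append(np.array([ring_r * np.sin(th), 0.0,
                                   zc - ring_r * np.cos(th)]))
    bonds = [(0, 1)] + [(1 + k, 1 + (k + 1) % 6) for k in range(6)]
    # ring hydrogens on C2, C3, C5, C6 (indices 2,3,5,6)
    for k in (2, 3, 5, 6):
        c = positions[k]
        center = np.array([0.0, 0.0, zc])
        d = (c - center) / np.linalg.norm(c - center)
        elements.append("H")
        positions.append(c + 1.08 * d)
        bonds.append((k, len(elements) - 1))
    # carboxylate carbon para to sulfur, two equivalent C-O of 1.26 A
    c4 = positions[4]
    c7 = c4 + np.array([0.0, 0.0, 1.50])
    elements.append("C")
    positions.append(c7)
    bonds.append((4, len(elements) - 1))
    c7_idx = len(elements) - 1
    for s in (1.0, -1.0):
        d = np.array([s * np.sin(np.deg2rad(61.5)), 0.0, np.cos(np.deg2rad(61.5))])
        elements.append("O")
        positions.append(c7 + 1.26 * d)
        bonds.append((c7_idx, len(elements) - 1))
    return LigandTemplate(np.array(elements, dtype=object), np.array(positions),
                          anchor_sulfur=0, axis_carbon=1, bonds=bonds,
                          rotatable_bonds=[], backbone=[0, 1, 4, c7_idx],
                          component=Component.OL, name="p-MBA")


# ---------------------------------------------------------------------------
# conjugation


def _neighbors(bonds: list[tuple[int, int]], idx: int) -> list[int]:
    out = []
    for i, j in bonds:
        if i == idx:
            out.append(j)
        elif j == idx:
            out.append(i)
    return sorted(out)


def _find_carboxyl(template: LigandTemplate) -> tuple[int, int, int, int]:
    """(carboxyl C, carbonyl O, hydroxyl O, hydroxyl H) of a terminal -COOH."""
    for c in range(template.n_atoms):
        if template.elements[c] != "C":
            continue
        oxys = [n for n in _neighbors(template.bonds, c)
                if template.elements[n] == "O"]
        if len(oxys) != 2:
            continue
        for o_h in oxys:
            hs = [n for n in _neighbors(template.bonds, o_h)
                  if template.elements[n] == "H"]
            if hs:
                o_c = oxys[0] if o_h == oxys[1] else oxys[1]
                return c, o_c, o_h, hs[0]
    raise ValueError("template has no terminal carboxyl (-COOH) group")


def conjugate_payload(linker: LigandTemplate, payload: PayloadSpec,
                      clash_limit: float = 1.5) -> LigandTemplate:
    """Amide-couple a payload amine onto the linker carboxyl.

    The hydroxyl O-H leaves the linker and one amine hydrogen leaves the
    payload (net loss: one water equivalent; atom count = linker + payload
    - 3).  The payload is rigid-translated/rotated so the new C-N bond has
    the ideal amide length; if every rotation about the new bond leaves an
    intra-template clash below ``clash_limit`` (Angstrom), an error asks
    for conformer elongation first.
    """
    c7, o_carbonyl, o_h, h_o = _find_carboxyl(linker)
    n_idx = payload.attach_atom
    h_n = payload._amine_hydrogens()[0]
    struct = payload.structure

    # linker keeps everything but the hydroxyl O-H
    keep_l = [i for i in range(linker.n_atoms) if i not in (o_h, h_o)]
    lmap = {old: new for new, old in enumerate(keep_l)}
    elements = [linker.elements[i] for i in keep_l]
    positions = [linker.positions[i].copy() for i in keep_l]
    bonds = [(lmap[i], lmap[j]) for i, j in linker.bonds
             if i in lmap and j in lmap]

    # payload loses one amine hydrogen
    keep_p = [i for i in range(struct.n_atoms) if i != h_n]
    pmap = {old: new + len(keep_l) for new, old in enumerate(keep_p)}
    p_bonds = struct.bonds or detect_bonds(struct.elements, struct.positions)

    # target N position: ideal amide C-N along the former C->O(H) direction
    c_pos = linker.positions[c7]
    direction = linker.positions[o_h] - c_pos
    direction /= np.linalg.norm(direction)
    n_target = c_pos + AMIDE_CN * direction

    p_pos = struct.positions[keep_p] - struct.positions[n_idx]
    order_p = {old: k for k, old in enumerate(keep_p)}
    heavy = [i for i in keep_p if struct.elements[i] != "H" and i != n_idx]
    if heavy:
        centroid = struct.positions[heavy].mean(axis=0) - struct.positions[n_idx]
        norm = np.linalg.norm(centroid)
        if norm > 1e-8:
            # align N->payload-centroid with C->N so the payload points away
            a = centroid / norm
            b = direction
            v = np.cross(a, b)
            c_ab = float(a @ b)
            if np.linalg.norm(v) > 1e-10:
                vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]],
                               [-v[1], v[0], 0]])
                rot = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c_ab)) \
                    if c_ab > -1.0 + 1e-12 else -np.eye(3)
                p_pos = p_pos @ rot.T

    # re-idealize the surviving amine hydrogens around the new amide
    # nitrogen: perpendicular to the amide axis, away from the carbonyl
    n_neighbors = [order_p[x] for x in _neighbors(p_bonds, n_idx) if x in order_p]
    for row in n_neighbors:
        if struct.elements[keep_p[row]] != "H":
            continue
        h_dir = p_pos[row] - p_pos[order_p[n_idx]]
        perp = h_dir - (h_dir @ direction) * direction
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(direction, [1.0, 0.0, 0.0])
            if np.linalg.norm(perp) < 1e-8:
                perp = np.cross(direction, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        p_pos[row] = p_pos[order_p[n_idx]] + _blen("H", "N") * perp

    linker_pos = np.array(positions)
    exclude_l = {lmap[c7]} | {lmap[n] for n in _neighbors(linker.bonds, c7)
                              if n in lmap}
    n_row = order_p[n_idx]
    exclude_rows = {n_row} | set(n_neighbors)  # 1-2 and 1-3 across the bond
    placed = None
    for angle in np.arange(0.0, 360.0, 10.0):
        rot = rotation_about_axis(direction, float(angle))
        cand = p_pos @ rot.T + n_target
        dmat = np.linalg.norm(linker_pos[:, None, :] - cand[None, :, :], axis=-1)
        # the new amide bond and its 1-3 contacts are not clashes
        mask = np.ones_like(dmat, dtype=bool)
        for li in exclude_l:
            for pr in exclude_rows:
                mask[li, pr] = False
        if dmat[mask].min() >= clash_limit:
            placed = cand
            break
    if placed is None:
        raise ValueError(
            "payload cannot be attached without an intra-template clash; "
            "elongate the linker conformer first"
        )

    for old in keep_p:
        elements.append(struct.elements[old])
        positions.append(placed[order_p[old]])
    bonds += [(pmap[i], pmap[j]) for i, j in p_bonds
              if i in pmap and j in pmap]
    bonds.append((lmap[c7], pmap[n_idx]))

    component = Component.PL if payload.payload_class == "peptide" else Component.DL
    backbone = [lmap[b] for b in linker.backbone if b in lmap] + [pmap[n_idx]]
    rotatable = [(backbone[k], backbone[k + 1]) for k in range(len(backbone) - 1)]
    return LigandTemplate(
        np.array(elements, dtype=object),
        np.array(positions),
        anchor_sulfur=lmap[linker.anchor_sulfur],
        axis_carbon=lmap[linker.axis_carbon],
        bonds=bonds, rotatable_bonds=rotatable, backbone=backbone,
        component=component,
        name=f"{linker.name}+{payload.name or payload.payload_class}",
    )


# ---------------------------------------------------------------------------
# conformer elongation


def measure_dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                     p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(n1 @ n2)
    y = float(m @ n2)
    return float(np.rad2deg(np.arctan2(y, x)))


def _distal_atoms(n_atoms: int, bonds: list[tuple[int, int]],
                  i: int, j: int) -> set[int]:
    """Atoms on the ``j`` side after cutting bond (i, j)."""
    adj: dict[int, set[int]] = {k: set() for k in range(n_atoms)}
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)
    adj[i].discard(j)
    adj[j].discard(i)
    seen = {j}
    stack = [j]
    while stack:
        k = stack.pop()
        for nb in adj[k]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    if i in seen:
        raise ValueError(f"bond ({i}, {j}) lies on a cycle; not rotatable")
    return seen


def set_backbone_dihedral(template: LigandTemplate, k: int,
                          target_deg: float) -> None:
    """Rotate the distal side of backbone bond k..k+1 so the dihedral
    backbone[k-1]-backbone[k]-backbone[k+1]-backbone[k+2] equals target."""
    b = template.backbone
    p = template.positions
    current = measure_dihedral(p[b[k - 1]], p[b[k]], p[b[k + 1]], p[b[k + 2]])
    delta = target_deg - current
    if abs(((delta + 180.0) % 360.0) - 180.0) < 1e-10:
        return
    distal = _distal_atoms(template.n_atoms, template.bonds, b[k], b[k + 1])
    axis = p[b[k + 1]] - p[b[k]]
    # rotating the distal side by -delta about the k->k+1 axis advances the
    # measured dihedral by +delta (right-hand convention of measure_dihedral)
    rot = rotation_about_axis(axis, -delta)
    idx = sorted(distal)
    template.positions[idx] = (p[idx] - p[b[k]]) @ rot.T + p[b[k]]


def elongate_conformer(template: LigandTemplate) -> LigandTemplate:
    """All-anti conformer: every backbone dihedral set to 180 degrees.

    Bond lengths and angles are untouched (each step is a rigid rotation of
    one side of a single bond), so only the torsional state changes; the
    result is the maximal-outreach zigzag of the backbone and is
    deterministic.  Templates without rotatable bonds are returned as-is.
    """
    if not template.rotatable_bonds or len(template.backbone) < 4:
        return template.copy()
    out = template.copy()
    for k in range(1, len(out.backbone) - 2):
        set_backbone_dihedral(out, k, 180.0)
    return out


# ---------------------------------------------------------------------------
# template serialization (SDF with anchor bookkeeping in properties)


def write_template_sdf(template: LigandTemplate, path: str | Path) -> None:
    """Serialize a template to SDF; anchor/axis/backbone go to properties."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    mol = Chem.RWMol()
    for el in template.elements:
        mol.AddAtom(Chem.Atom(str(el)))
    for i, j in template.bonds:
        mol.AddBond(int(i), int(j), Chem.BondType.SINGLE)
    conf = Chem.Conformer(template.n_atoms)
    for i, p in enumerate(template.positions):
        conf.SetAtomPosition(i, Point3D(*map(float, p)))
    m = mol.GetMol()
    m.AddConformer(conf)
    m.SetProp("_Name", template.name)
    m.SetProp("anchor_sulfur", str(template.anchor_sulfur))
    m.SetProp("axis_carbon", str(template.axis_carbon))
    m.SetProp("component", template.component.value)
    m.SetProp("backbone", ",".join(map(str, template.backbone)))
    with Chem.SDWriter(str(path)) as w:
        w.SetKekulize(False)
        w.write(m)


def read_template_sdf(path: str | Path) -> LigandTemplate:
    """Read a template written by :func:`write_template_sdf`."""
    from rdkit import Chem

    mols = [m for m in Chem.SDMolSupplier(str(path), removeHs=False,
                                          sanitize=False) if m is not None]
    if not mols:
        raise ValueError(f"{path}: no molecule in SDF")
    m = mols[0]
    conf = m.GetConformer()
    elements = np.array([a.GetSymbol() for a in m.GetAtoms()], dtype=object)
    positions = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                           conf.GetAtomPosition(i).z]
                          for i in range(m.GetNumAtoms())])
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in m.GetBonds()]
    backbone = [int(t) for t in m.GetProp("backbone").split(",")] \
        if m.HasProp("backbone") and m.GetProp("backbone") else []
    rotatable = [(backbone[k], backbone[k + 1]) for k in range(len(backbone) - 1)]
    return LigandTemplate(
        elements, positions,
        anchor_sulfur=int(m.GetProp("anchor_sulfur")),
        axis_carbon=int(m.GetProp("axis_carbon")),
        bonds=bonds, rotatable_bonds=rotatable, backbone=backbone,
        component=Component(m.GetProp("component")) if m.HasProp("component")
        else Component.OL,
        name=m.GetProp("_Name") if m.HasProp("_Name") else "",
    )
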