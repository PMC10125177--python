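"""Ligand-shell analysis estimators over structures and trajectories.

These are the quantities used to judge a formulation's shell organisation:

* mass- or number-weighted radius of gyration (Rg),
* Shrake-Rupley solvent-accessible surface area attributed per shell
  component (original thiolates vs PEG-peptide vs PEG-drug conjugates),
* per-component average distance to the metal core over a trajectory
  (the three-level shell reading: p-MBA inner, drug middle, peptide outer),
* radial distribution functions, e.g. sodium counterions versus the
  staple sulfurs.

All results are reported in nanometres (nm, nm^2); inputs declare their
unit per frame.  Trajectory frames after an equilibration cutoff (default
30 ns, where shell metrics level off) enter the summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from ._geometry import fibonacci_sphere
from .elements import ATOMIC_MASS, VDW_RADIUS
from .structures import ClusterModel, Component, read_structure

#: Bondi van der Waals radii in nm (the table in elements.py is Angstrom)
DEFAULT_RADII_NM = {el: r / 10.0 for el, r in VDW_RADIUS.items()}


@dataclass
class Frame:
    """One trajectory frame: positions with a declared unit, an optional
    periodic box, and a time stamp in ns."""

    positions: np.ndarray
    unit: str = "nm"
    box: np.ndarray | None = None
    periodic: bool = False
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.unit not in ("nm", "angstrom"):
            raise ValueError("unit must be 'nm' or 'angstrom'")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if self.periodic and not np.all(self.box > 0):
                raise ValueError("periodic frames need positive box lengths")

    def positions_nm(self) -> np.ndarray:
        return self.positions if self.unit == "nm" else self.positions / 10.0

    def box_nm(self) -> np.ndarray | None:
        if self.box is None:
            return None
        return self.box if self.unit == "nm" else self.box / 10.0


@dataclass
class AnalysisConfig:
    """Estimator settings.

    probe_radius (nm) and n_sphere_points control the Shrake-Rupley
    surface; rdf_bin / rdf_rmax (nm) the RDF histogram;
    equilibration_cutoff (ns) which frames enter trajectory summaries;
    radii_table maps element to van der Waals radius in nm.
    """

    probe_radius: float = 0.14
    n_sphere_points: int = 960
    rdf_bin: float = 0.002
    rdf_rmax: float | None = None
    equilibration_cutoff: float = 30.0
    radii_table: dict = field(default_factory=lambda: dict(DEFAULT_RADII_NM))

    def __post_init__(self) -> None:
        if min(self.probe_radius, self.rdf_bin) <= 0:
            raise ValueError("probe_radius and rdf_bin must be positive")
        if self.n_sphere_points < 12:
            raise ValueError("n_sphere_points must be at least 12")
        if self.equilibration_cutoff < 0:
            raise ValueError("equilibration_cutoff must be non-negative")


@dataclass
class RdfResult:
    """g(r) on bin centers (nm), with bookkeeping counts."""

    bin_centers: np.ndarray
    g: np.ndarray
    n_pairs: int
    frames_used: int


# ---------------------------------------------------------------------------
# radius of gyration


def radius_of_gyration(frame: Frame, selection: np.ndarray | None = None,
                       masses: np.ndarray | None = None) -> float:
    """Radius of gyration of the selected atoms, nm.

    With ``masses`` given (one weight per selected atom) the Rg is
    mass-weighted, sqrt(sum m_i |r_i - r_com|^2 / sum m_i); with
    ``masses=None`` all atoms weigh equally (the geometric Rg).
    """
    pos = frame.positions_nm()
    if selection is not None:
        pos = pos[np.asarray(selection)]
    if len(pos) == 0:
        raise ValueError("empty selection")
    if masses is None:
        w = np.ones(len(pos))
    else:
        w = np.asarray(masses, dtype=float)
        if len(w) != len(pos):
            raise ValueError("one mass per selected atom required")
    com = (pos * w[:, None]).sum(axis=0) / w.sum()
    d2 = ((pos - com) ** 2).sum(axis=1)
    return float(np.sqrt((w * d2).sum() / w.sum()))


def masses_for(elements: Sequence[str]) -> np.ndarray:
    """Standard atomic masses for an element sequence."""
    return np.array([ATOMIC_MASS[e] for e in elements])


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA


def sasa_per_atom(frame: Frame, elements: Sequence[str],
                  config: AnalysisConfig | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area, nm^2 (Shrake-Rupley).

    Each atom is wrapped in a quasi-uniform shell of ``n_sphere_points``
    test points at radius (vdW + probe); a point is exposed when it lies
    outside every other atom's inflated sphere; the atom's area is the
    exposed fraction of 4 pi (vdW + probe)^2.
    """
    config = config or AnalysisConfig()
    pos = frame.positions_nm()
    n = len(pos)
    if n != len(elements):
        raise ValueError("one element per atom required")
    try:
        radii = np.array([config.radii_table[e] for e in elements])
    except KeyError as exc:
        raise ValueError(f"no van der Waals radius for element {exc.args[0]!r}") from exc
    inflated = radii + config.probe_radius
    sphere = fibonacci_sphere(config.n_sphere_points)
    tree = cKDTree(pos)
    max_r = inflated.max()
    areas = np.empty(n)
    for i in range(n):
        pts = pos[i] + inflated[i] * sphere
        neigh = tree.query_ball_point(pos[i], inflated[i] + max_r)
        neigh = [j for j in neigh if j != i]
        if neigh:
            d2 = ((pts[:, None, :] - pos[neigh][None, :, :]) ** 2).sum(-1)
            buried = (d2 < (inflated[neigh] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * inflated[i] ** 2
    return areas


def sasa_by_component(frame: Frame, elements: Sequence[str],
                      grouping: Sequence[str],
                      config: AnalysisConfig | None = None
                      ) -> tuple[dict[str, float], float]:
    """Shrake-Rupley SASA summed per component tag, plus the total (nm^2).

    ``grouping`` assigns each atom a component label (typically the
    ClusterModel ``components`` array); the total is exactly the sum of
    the per-component areas.
    """
    areas = sasa_per_atom(frame, elements, config)
    grouping = np.asarray(grouping)
    out: dict[str, float] = {}
    for tag in dict.fromkeys(grouping.tolist()):  # preserve first-seen order
        out[str(tag)] = float(areas[grouping == tag].sum())
    return out, float(areas.sum())


# ---------------------------------------------------------------------------
# component-core distances


def component_core_distance(
    frames: Sequence[Frame],
    copies: Sequence[np.ndarray],
    core: np.ndarray,
    masses: np.ndarray,
    config: AnalysisConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Average component-to-core distance over a trajectory.

    Per frame, for each ligand copy (an atom-index array), the distance
    between the copy's center of mass and the core's center of mass is
    computed; the frame value is the mean over copies.  The summary is the
    mean and sample sd over frames at or after the equilibration cutoff.

    Returns (times ns, per-frame distances nm, (mean, sd)).
    """
    config = config or AnalysisConfig()
    if not len(frames):
        raise ValueError("empty trajectory")
    if not len(copies) or not len(core):
        raise ValueError("component and core selections must be non-empty")
    copies = [np.asarray(c) for c in copies]
    core = np.asarray(core)
    masses = np.asarray(masses, dtype=float)

    def com(pos: np.ndarray, idx: np.ndarray) -> np.ndarray:
        w = masses[idx]
        return (pos[idx] * w[:, None]).sum(axis=0) / w.sum()

    times = np.array([f.time for f in frames])
    dists = np.empty(len(frames))
    for k, f in enumerate(frames):
        pos = f.positions_nm()
        core_com = com(pos, core)
        d = [float(np.linalg.norm(com(pos, c) - core_com)) for c in copies]
        dists[k] = float(np.mean(d))
    mean, sd = time_series_summary(times, dists, config.equilibration_cutoff)
    return times, dists, (mean, sd)


def component_copies(model: ClusterModel, component: Component | str) -> list[np.ndarray]:
    """Atom-index arrays, one per molecule tagged with ``component``."""
    return [model.molecule_atom_indices(m)
            for m in model.molecules_with_component(component)]


# ---------------------------------------------------------------------------
# radial distribution function


def rdf(frames: Sequence[Frame], group_a: np.ndarray, group_b: np.ndarray,
        config: AnalysisConfig | None = None,
        apply_cutoff: bool = True) -> RdfResult:
    """Radial distribution function g(r) between two disjoint atom groups.

    Pair distances (minimum-image under periodic boundaries) are binned in
    ``rdf_bin``-wide shells and normalized by shell volume and the average
    pair density, so an ideal gas gives g ~ 1.  Frames at or after the
    equilibration cutoff are averaged (set ``apply_cutoff=False`` to use
    all frames, e.g. for static snapshots).
    """
    config = config or AnalysisConfig()
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("groups must be disjoint")
    used = [f for f in frames
            if not apply_cutoff or f.time >= config.equilibration_cutoff]
    if not used:
        raise ValueError("no frames at or after the equilibration cutoff")

    first_box = used[0].box_nm()
    if used[0].periodic:
        if first_box is None:
            raise ValueError("periodic frames need a box")
        rmax = config.rdf_rmax or float(first_box.min()) / 2.0
        if rmax > first_box.min() / 2.0 + 1e-12:
            raise ValueError(
                f"rdf_rmax={rmax} nm exceeds half the smallest box edge "
                f"({first_box.min() / 2.0} nm)"
            )
    else:
        if config.rdf_rmax is None:
            raise ValueError("rdf_rmax is required for non-periodic frames")
        rmax = config.rdf_rmax

    nbins = int(np.ceil(rmax / config.rdf_bin))
    edges = np.arange(nbins + 1) * config.rdf_bin
    hist = np.zeros(nbins)
    n_pairs_total = 0
    for f in used:
        pos = f.positions_nm()
        delta = pos[group_a][:, None, :] - pos[group_b][None, :, :]
        if f.periodic:
            box = f.box_nm()
            delta -= box * np.round(delta / box)
        d = np.sqrt((delta ** 2).sum(-1)).ravel()
        n_pairs_total += d.size
        hist += np.histogram(d, bins=edges)[0]

    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    if used[0].periodic:
        volume = float(np.prod(used[0].box_nm()))
    else:
        volume = 4.0 / 3.0 * np.pi * rmax ** 3
    pair_density = len(group_a) * len(group_b) / volume
    g = hist / (len(used) * pair_density * shell_vol)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RdfResult(centers, g, int(n_pairs_total), len(used))


# ---------------------------------------------------------------------------
# time-series summary


def time_series_summary(times: np.ndarray, values: np.ndarray,
                        cutoff: float) -> tuple[float, float]:
    """Mean and sample standard deviation of values with time >= cutoff."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = times >= cutoff
    if not mask.any():
        raise ValueError(f"no samples at or after cutoff {cutoff}")
    sel = values[mask]
    sd = float(np.std(sel, ddof=1)) if len(sel) > 1 else 0.0
    return float(np.mean(sel)), sd


# ---------------------------------------------------------------------------
# trajectory reading


def read_trajectory(topology: str | Path, traj: str | Path | None = None,
                    time_per_frame: float = 1.0,
                    unit: str | None = None) -> tuple[ClusterModel, list[Frame]]:
    """Load a trajectory: multi-model PDB or concatenated XYZ.

    Returns the topology as a ClusterModel (first frame) and the list of
    frames.  Frame times are ``k * time_per_frame`` ns unless the source
    carries explicit times.  Positions are stored in Angstrom (converted
    from the reader) with any box attached; cubic boxes only.
    """
    topology = Path(topology)
    traj_path = Path(traj) if traj is not None else topology
    model = read_structure(topology)
    suffix = traj_path.suffix.lstrip(".").lower()
    frames: list[Frame] = []
    if suffix == "xyz":
        frames = _read_xyz_frames(traj_path, time_per_frame)
    else:
        import MDAnalysis as mda

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(topology), str(traj_path))
            for k, ts in enumerate(u.trajectory):
                box = None
                periodic = False
                if ts.dimensions is not None and ts.dimensions[:3].min() > 0:
                    box = np.array(ts.dimensions[:3], dtype=float)
                    periodic = True
                frames.append(Frame(ts.positions.astype(float).copy(),
                                    unit="angstrom", box=box, periodic=periodic,
                                    time=k * time_per_frame))
    return model, frames


def _read_xyz_frames(path: Path, time_per_frame: float) -> list[Frame]:
    lines = path.read_text().splitlines()
    frames = []
    k = 0
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        n = int(lines[ln].split()[0])
        comment = lines[ln + 1]
        box = None
        periodic = False
        for tok in comment.split():
            if tok.startswith("box="):
                box = np.array([float(x) for x in tok[4:].split(",")])
                periodic = True
        block = lines[ln + 2: ln + 2 + n]
        pos = np.array([[float(t) for t in l.split()[1:4]] for l in block])
        frames.append(Frame(pos, unit="angstrom", box=box, periodic=periodic,
                            time=k * time_per_frame))
        ln += 2 + n
        k += 1
    return frames
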