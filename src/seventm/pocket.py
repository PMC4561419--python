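"""Binding-cavity physicochemical profiling.

Three building blocks, composed by :func:`cavity_profile`:

* :func:`shrake_rupley_sasa` — solvent-accessible surface area by the
  Shrake-Rupley method: each atom's van der Waals sphere is inflated by the
  probe radius, sampled with a fixed deterministic point lattice, and the
  unoccluded fraction of points gives the exposed area.
* :func:`classify_residue` / :class:`ResidueClassScheme` — partition of the
  cavity-lining residues into hydrophilic, aromatic and aliphatic sets
  (hydrophobic = aromatic + aliphatic; glycine stays unclassified by default).
* :func:`pocket_volume` — grid-based enclosed-cavity volume: grid points that
  are outside every van der Waals sphere, inside the convex hull of the
  selection, and not reachable by bulk solvent (rolling-probe flood fill from
  the box boundary) are counted and multiplied by the voxel volume.

SASA is always computed on the *whole* structure so that the exposure of the
selected residues reflects their context in the intact receptor, then summed
over the selection per residue class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError, cKDTree

from .structure import Atom, Structure

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_SPHERE_POINTS = 960
DEFAULT_GRID_SPACING = 0.5


@dataclass(frozen=True)
class ResidueClassScheme:
    """Residue classes used to partition cavity SASA.

    Hydrophobic is defined as the union of aromatic and aliphatic; residues in
    none of the three sets (glycine by default) are reported as unclassified.
    """

    hydrophilic: frozenset[str] = frozenset(
        {"ARG", "LYS", "HIS", "ASP", "GLU", "ASN", "GLN", "SER", "THR", "CYS"})
    aromatic: frozenset[str] = frozenset({"PHE", "TYR", "TRP"})
    aliphatic: frozenset[str] = frozenset(
        {"ALA", "VAL", "LEU", "ILE", "MET", "PRO"})

    def __post_init__(self) -> None:
        if self.aromatic & self.aliphatic:
            raise ValueError("aromatic and aliphatic sets overlap")
        if self.hydrophilic & (self.aromatic | self.aliphatic):
            raise ValueError("hydrophilic set overlaps hydrophobic sets")

    @property
    def hydrophobic(self) -> frozenset[str]:
        return self.aromatic | self.aliphatic


def classify_residue(residue_name: str, scheme: Optional[ResidueClassScheme] = None,
                     known_residues: Optional[frozenset[str]] = None) -> str:
    """Class label for a 3-letter residue code.

    Returns one of ``hydrophilic``, ``aromatic``, ``aliphatic`` or
    ``unclassified``; unknown codes raise.
    """
    scheme = scheme or ResidueClassScheme()
    name = residue_name.upper()
    known = (known_residues or STANDARD_RESIDUES)
    if name not in known and name not in (scheme.hydrophilic | scheme.hydrophobic):
        raise ValueError(f"unknown residue code {residue_name!r}")
    if name in scheme.hydrophilic:
        return "hydrophilic"
    if name in scheme.aromatic:
        return "aromatic"
    if name in scheme.aliphatic:
        return "aliphatic"
    return "unclassified"


STANDARD_RESIDUES = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL"})


@dataclass(frozen=True)
class CavitySelection:
    """Residues lining a binding cavity, as (chain, residue_index) pairs."""

    structure_id: str
    residues: tuple[tuple[str, int], ...]
    note: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty cavity selection")


@dataclass(frozen=True)
class CavityProfile:
    """Volume plus class-partitioned SASA of a binding cavity."""

    structure_id: str
    volume: float
    sasa_total: float
    sasa_phil: float
    sasa_phob: float
    sasa_aliph: float
    sasa_arom: float
    sasa_unclassified: float
    pct_hydrophilicity: float

    def __post_init__(self) -> None:
        fields = (self.volume, self.sasa_total, self.sasa_phil, self.sasa_phob,
                  self.sasa_aliph, self.sasa_arom, self.sasa_unclassified)
        if any(v < -1e-9 for v in fields):
            raise ValueError("negative cavity-profile field")
        if abs(self.sasa_phob - (self.sasa_aliph + self.sasa_arom)) > 1e-6:
            raise ValueError("sasa_phob must equal sasa_aliph + sasa_arom")


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA


def sphere_lattice(n_points: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere lattice (golden spiral)."""
    k = np.arange(n_points, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n_points
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(structure: Structure,
                       probe_radius: float = DEFAULT_PROBE_RADIUS,
                       n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
                       include_hydrogens: bool = False,
                       ) -> tuple[np.ndarray, dict[tuple[str, int], float]]:
    """Per-atom and per-residue solvent-accessible surface area.

    Each atom's sphere of radius (vdW + probe) is sampled with a fixed
    golden-spiral lattice; lattice points strictly inside any neighbouring
    atom's expanded sphere are occluded.  The per-atom SASA is the unoccluded
    fraction times the expanded-sphere area; per-residue values sum atoms.
    The result is deterministic for a given ``n_sphere_points``.

    Returns ``(per_atom, per_residue)`` where ``per_atom`` follows the order
    of the (possibly hydrogen-stripped) atom list and ``per_residue`` is keyed
    by (chain, residue_index).  Hydrogens are excluded by default.
    """
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    if n_sphere_points < 24:
        raise ValueError("need at least 24 sphere points")
    st = structure if include_hydrogens else structure.without_hydrogens()
    atoms = st.atoms
    coords = np.array([a.coords for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms]) + probe_radius
    lattice = sphere_lattice(n_sphere_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    per_atom = np.zeros(len(atoms))
    for i, atom in enumerate(atoms):
        pts = coords[i] + radii[i] * lattice
        neighbours = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r)
                      if j != i]
        if neighbours:
            d2 = np.sum((pts[:, None, :] - coords[neighbours][None, :, :]) ** 2,
                        axis=2)
            occluded = (d2 < (radii[neighbours] ** 2)[None, :] - 1e-10).any(axis=1)
            exposed = np.count_nonzero(~occluded)
        else:
            exposed = n_sphere_points
        per_atom[i] = 4.0 * np.pi * radii[i] ** 2 * exposed / n_sphere_points
    per_residue: dict[tuple[str, int], float] = {}
    for atom, area in zip(atoms, per_atom):
        key = (atom.chain, atom.residue_index)
        per_residue[key] = per_residue.get(key, 0.0) + float(area)
    return per_atom, per_residue


def cavity_sasa(structure: Structure, selection: CavitySelection,
                scheme: Optional[ResidueClassScheme] = None,
                probe_radius: float = DEFAULT_PROBE_RADIUS,
                n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
                ) -> dict[str, float]:
    """Class-partitioned SASA of the cavity-lining residues.

    SASA is computed in the context of the whole structure, then summed over
    the selection per residue class.  Returns keys ``total``, ``hydrophilic``,
    ``hydrophobic``, ``aliphatic``, ``aromatic`` and ``unclassified``.
    """
    scheme = scheme or ResidueClassScheme()
    _, per_residue = shrake_rupley_sasa(structure, probe_radius, n_sphere_points)
    residue_names = {(a.chain, a.residue_index): a.residue_name
                     for a in structure.atoms}
    out = {"total": 0.0, "hydrophilic": 0.0, "hydrophobic": 0.0,
           "aliphatic": 0.0, "aromatic": 0.0, "unclassified": 0.0}
    for key in selection.residues:
        if key not in residue_names:
            raise ValueError(f"selection residue {key} absent from structure "
                             f"{structure.id!r}")
        area = per_residue.get(key, 0.0)
        label = classify_residue(residue_names[key], scheme)
        out["total"] += area
        out[label] += area
        if label in ("aliphatic", "aromatic"):
            out["hydrophobic"] += area
    return out


# ---------------------------------------------------------------------------
# cavity volume


def pocket_volume(structure: Structure, selection: CavitySelection,
                  grid_spacing: float = DEFAULT_GRID_SPACING,
                  probe_radius: float = DEFAULT_PROBE_RADIUS,
                  margin: float = 2.0,
                  return_grid: bool = False):
    """Enclosed cavity volume (A^3) bounded by the selected residues.

    A cubic grid spans the selection's bounding box plus ``margin``.  A voxel
    belongs to the cavity when its centre is

    1. outside every atom's van der Waals sphere,
    2. inside the convex hull of the selected atoms, and
    3. not part of the bulk-solvent region, where bulk is grown by flood fill
       from the box boundary through voxels a probe centre can occupy
       (distance >= vdW + probe from every atom) and then dilated by the
       probe radius to cover the solvent layer touching the atoms.

    The volume is the cavity voxel count times ``grid_spacing ** 3``;
    deterministic for a given spacing.
    """
    if not 0.2 < grid_spacing < 1.5:
        raise ValueError("grid spacing must be in (0.2, 1.5) A")
    sel_keys = set(selection.residues)
    sel_atoms = [a for a in structure.atoms
                 if (a.chain, a.residue_index) in sel_keys]
    if not sel_atoms:
        raise ValueError("selection matches no atoms")
    sel_coords = np.array([a.coords for a in sel_atoms])
    try:
        hull = Delaunay(sel_coords)
    except QhullError as exc:
        raise ValueError("degenerate (coplanar) cavity selection") from exc

    lo = sel_coords.min(axis=0) - margin
    hi = sel_coords.max(axis=0) + margin
    nx, ny, nz = (np.ceil((hi - lo) / grid_spacing).astype(int) + 1)
    gx = lo[0] + grid_spacing * np.arange(nx)
    gy = lo[1] + grid_spacing * np.arange(ny)
    gz = lo[2] + grid_spacing * np.arange(nz)
    pts = np.stack(np.meshgrid(gx, gy, gz, indexing="ij"), axis=-1).reshape(-1, 3)

    all_atoms = structure.without_hydrogens().atoms
    coords = np.array([a.coords for a in all_atoms])
    radii = np.array([a.vdw_radius for a in all_atoms])
    tree = cKDTree(coords)
    # distance from each voxel centre to the nearest atom *surface*
    max_r = radii.max()
    dist, idx = tree.query(pts, k=min(16, len(all_atoms)))
    if dist.ndim == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    surf_dist = (dist - radii[idx]).min(axis=1)
    # k-nearest by centre distance can miss the closest surface when radii
    # differ; guard by also checking atoms within (min surface dist + spread)
    spread = radii.max() - radii.min()
    if spread > 1e-9 and len(all_atoms) > 16:
        suspects = np.nonzero(surf_dist < probe_radius + spread)[0]
        for i in suspects:
            near = tree.query_ball_point(pts[i], dist[i].max() + spread)
            d = np.linalg.norm(coords[near] - pts[i], axis=1) - radii[near]
            surf_dist[i] = min(surf_dist[i], d.min())

    shape = (nx, ny, nz)
    free = (surf_dist > 0).reshape(shape)
    passable = (surf_dist >= probe_radius).reshape(shape)

    # flood fill bulk solvent from the box boundary through probe-passable voxels
    seed = np.zeros(shape, dtype=bool)
    seed[0, :, :] = seed[-1, :, :] = True
    seed[:, 0, :] = seed[:, -1, :] = True
    seed[:, :, 0] = seed[:, :, -1] = True
    seed &= passable
    structure6 = ndimage.generate_binary_structure(3, 1)
    reachable = ndimage.binary_propagation(seed, mask=passable,
                                           structure=structure6)
    # dilate the probe-centre region by the probe radius to get the full
    # solvent-occupied layer (voxels within probe_radius of a reachable voxel)
    dist_to_reach = ndimage.distance_transform_edt(
        ~reachable, sampling=(grid_spacing,) * 3)
    bulk = dist_to_reach <= probe_radius + 1e-9

    inside_hull = (hull.find_simplex(pts) >= 0).reshape(shape)
    cavity = free & inside_hull & ~bulk
    volume = float(np.count_nonzero(cavity)) * grid_spacing ** 3
    if return_grid:
        return volume, cavity
    return volume


def cavity_profile(structure: Structure, selection: CavitySelection,
                   scheme: Optional[ResidueClassScheme] = None,
                   probe_radius: float = DEFAULT_PROBE_RADIUS,
                   n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
                   grid_spacing: float = DEFAULT_GRID_SPACING) -> CavityProfile:
    """Assemble volume, class-partitioned SASA and percent hydrophilicity.

    Percent hydrophilicity is 100 x phil / (phil + phob); all raw fields are
    reported alongside so alternative conventions can be applied downstream.
    """
    sasa = cavity_sasa(structure, selection, scheme, probe_radius, n_sphere_points)
    volume = pocket_volume(structure, selection, grid_spacing, probe_radius)
    phil, phob = sasa["hydrophilic"], sasa["hydrophobic"]
    pct = 100.0 * phil / (phil + phob) if (phil + phob) > 0 else 0.0
    return CavityProfile(
        structure_id=structure.id, volume=volume,
        sasa_total=sasa["total"], sasa_phil=phil, sasa_phob=phob,
        sasa_aliph=sasa["aliphatic"], sasa_arom=sasa["aromatic"],
        sasa_unclassified=sasa["unclassified"],
        pct_hydrophilicity=pct)
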