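"""Structure I/O, atom selection, Kabsch superposition and selection RMSD.

Structures are read from PDB or mmCIF via gemmi and flattened into a simple
atom list with author residue numbering (matching literature residue numbers).
Alternate locations are resolved to the highest-occupancy conformer; waters
and other heteroatoms are retained but flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Bondi van der Waals radii (Angstrom); elements not listed fall back to 1.70.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80,
}
FALLBACK_VDW = 1.70


@dataclass(frozen=True)
class AtomRadiusTable:
    radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))
    fallback: float = FALLBACK_VDW

    def radius(self, element: str) -> float:
        return self.radii.get(element.upper(), self.fallback)


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain: str
    coords: tuple[float, float, float]
    vdw_radius: float
    hetero: bool = False

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} has non-finite coordinates")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial} has non-positive vdW radius")


@dataclass
class Structure:
    id: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"structure {self.id!r} has no atoms")

    def coords(self, atoms: Optional[Sequence[Atom]] = None) -> np.ndarray:
        return np.array([a.coords for a in (self.atoms if atoms is None else atoms)])

    def residue_atoms(self) -> dict[tuple[str, int], list[Atom]]:
        index: dict[tuple[str, int], list[Atom]] = {}
        for atom in self.atoms:
            index.setdefault((atom.chain, atom.residue_index), []).append(atom)
        return index

    def without_hydrogens(self) -> "Structure":
        atoms = [a for a in self.atoms if a.element.upper() != "H"]
        return Structure(id=self.id, atoms=atoms)


# ---------------------------------------------------------------------------
# I/O


def read_structure(path, fmt: Optional[str] = None,
                   radii: Optional[AtomRadiusTable] = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Format is auto-detected from the extension when ``fmt`` is None.  Only the
    first model is used; altlocs are collapsed to the highest-occupancy
    conformer.
    """
    path = Path(path)
    radii = radii or AtomRadiusTable()
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc
    st.remove_alternative_conformations()  # keeps highest-occupancy altloc
    atoms: list[Atom] = []
    serial = 0
    if len(st) == 0:
        raise IOError(f"no models in {path}")
    model = st[0]
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            for at in res:
                serial += 1
                elem = at.element.name or at.name[:1]
                atoms.append(Atom(
                    serial=serial, name=at.name, element=elem,
                    residue_name=res.name,
                    residue_index=res.seqid.num,  # author numbering
                    chain=chain.name,
                    coords=(at.pos.x, at.pos.y, at.pos.z),
                    vdw_radius=radii.radius(elem),
                    hetero=het))
    if not atoms:
        raise IOError(f"no atoms in {path}")
    return Structure(id=path.stem, atoms=atoms)


def write_pdb(structure: Structure, path) -> None:
    """Write a structure as PDB (single model, single conformer)."""
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for atom in structure.atoms:
        chain = chains.get(atom.chain)
        if chain is None:
            chain = gemmi.Chain(atom.chain)
            chains[atom.chain] = chain
            model.add_chain(chain)
            chain = model[len(model) - 1]
            chains[atom.chain] = chain
        if (len(chain) == 0
                or chain[len(chain) - 1].seqid.num != atom.residue_index
                or chain[len(chain) - 1].name != atom.residue_name):
            res = gemmi.Residue()
            res.name = atom.residue_name
            res.seqid = gemmi.SeqId(atom.residue_index, " ")
            res.het_flag = "H" if atom.hetero else "A"
            chain.add_residue(res)
        res = chain[len(chain) - 1]
        at = gemmi.Atom()
        at.name = atom.name
        at.element = gemmi.Element(atom.element)
        at.pos = gemmi.Position(*atom.coords)
        at.occ = 1.0
        res.add_atom(at)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# selection


class SelectionError(ValueError):
    """Raised when a selection matches nothing or misses requested terms."""


def select_atoms(structure: Structure,
                 chains: Optional[Sequence[str]] = None,
                 residue_indices: Optional[Sequence[int]] = None,
                 atom_names: Optional[Sequence[str] | str] = None,
                 include_hetero: bool = False) -> list[Atom]:
    """Atoms matching chain / residue-index / atom-name terms, in residue order.

    ``atom_names`` accepts the shorthands ``"backbone"`` ({N, CA, C, O}) and
    ``"CA"``; an explicit list is used verbatim.  Raises
    :class:`SelectionError` listing any chain or residue index that matched
    nothing.
    """
    if isinstance(atom_names, str):
        if atom_names.lower() == "backbone":
            names: Optional[set[str]] = set(BACKBONE_ATOMS)
        elif atom_names.lower() == "all":
            names = None
        else:
            names = {atom_names}
    elif atom_names is not None:
        names = set(atom_names)
    else:
        names = None

    chain_set = set(chains) if chains is not None else None
    index_set = set(residue_indices) if residue_indices is not None else None
    selected = []
    seen_chains: set[str] = set()
    seen_indices: set[int] = set()
    for atom in structure.atoms:
        if atom.hetero and not include_hetero:
            continue
        if chain_set is not None and atom.chain not in chain_set:
            continue
        seen_chains.add(atom.chain)
        if index_set is not None and atom.residue_index not in index_set:
            continue
        seen_indices.add(atom.residue_index)
        if names is not None and atom.name not in names:
            continue
        selected.append(atom)
    problems = []
    if chain_set is not None and chain_set - seen_chains:
        problems.append(f"chains not found: {sorted(chain_set - seen_chains)}")
    if index_set is not None and index_set - seen_indices:
        problems.append(f"residues not found: {sorted(index_set - seen_indices)}")
    if not selected:
        problems.append("selection matched no atoms")
    if problems:
        raise SelectionError("; ".join(problems))
    return selected


# ---------------------------------------------------------------------------
# superposition


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of ``mobile`` onto ``reference``.

    Classic SVD solution: centre both point sets, decompose the covariance,
    correct the sign so the rotation is proper (det +1), and report the RMSD
    after applying the transform.  Requires n >= 3 non-degenerate points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    x = mobile - mc
    y = reference - rc
    cov = x.T @ y
    if np.linalg.matrix_rank(cov) < 2:
        raise ValueError("degenerate (rank-deficient) point sets")
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    sign = np.diag([1.0, 1.0, d])
    rotation = vt.T @ sign @ u.T
    translation = rc - rotation @ mc
    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return SuperpositionResult(rotation=rotation, translation=translation,
                               rmsd=rmsd, n_atoms=n)


def selection_rmsd(a: Structure, b: Structure,
                   residue_indices: Optional[Sequence[int]] = None,
                   chains_a: Optional[Sequence[str]] = None,
                   chains_b: Optional[Sequence[str]] = None,
                   atom_set: str = "backbone",
                   superpose: bool = True,
                   chain_map: Optional[dict[str, str]] = None) -> float:
    """RMSD between two structures over a shared residue/atom selection.

    Atoms are matched across structures by (mapped chain, residue index,
    atom name); ``chain_map`` maps chains of ``a`` onto chains of ``b``
    (identity by default).  With ``superpose`` the matched coordinates are
    Kabsch-fitted first.  Unmatched atoms raise an error listing them.
    """
    atoms_a = select_atoms(a, chains=chains_a, residue_indices=residue_indices,
                           atom_names=atom_set)
    atoms_b = select_atoms(b, chains=chains_b, residue_indices=residue_indices,
                           atom_names=atom_set)
    chain_map = chain_map or {}
    keyed_b = {(at.chain, at.residue_index, at.name): at for at in atoms_b}
    pairs = []
    missing = []
    for at in atoms_a:
        key = (chain_map.get(at.chain, at.chain), at.residue_index, at.name)
        mate = keyed_b.get(key)
        if mate is None:
            missing.append(key)
        else:
            pairs.append((at, mate))
    if missing:
        raise SelectionError(f"atoms unmatched in {b.id!r}: {missing[:10]}"
                             + ("..." if len(missing) > 10 else ""))
    if len(pairs) != len(atoms_b):
        extra = set(keyed_b) - {(chain_map.get(at.chain, at.chain),
                                 at.residue_index, at.name) for at in atoms_a}
        raise SelectionError(f"atoms unmatched in {a.id!r}: {sorted(extra)[:10]}")
    ca = np.array([p[0].coords for p in pairs])
    cb = np.array([p[1].coords for p in pairs])
    if superpose:
        return kabsch_superpose(ca, cb).rmsd
    return float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, axis=1))))


def transform_structure(structure: Structure, result: SuperpositionResult) -> Structure:
    """A copy of the structure with the superposition transform applied."""
    moved = result.apply(np.array([a.coords for a in structure.atoms]))
    atoms = [replace(a, coords=tuple(c)) for a, c in zip(structure.atoms, moved)]
    return Structure(id=structure.id, atoms=atoms)
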