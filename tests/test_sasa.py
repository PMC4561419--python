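"""Shrake-Rupley solvent-accessible surface area."""

import math

import numpy as np
import pytest

from seventm.pocket import (ResidueClassScheme, cavity_sasa, classify_residue,
                            shrake_rupley_sasa, sphere_lattice)
from seventm.pocket import CavitySelection
from seventm.structure import Atom, Structure
from seventm.synth import make_cavity_fixture


def carbon(serial, coords, residue_index=None, name="LEU"):
    return Atom(serial=serial, name="C", element="C", residue_name=name,
                residue_index=residue_index or serial, chain="A",
                coords=tuple(coords), vdw_radius=1.70)


def test_isolated_carbon_matches_analytic_sphere_area():
    st = Structure("one", [carbon(1, (0.0, 0.0, 0.0))])
    per_atom, per_res = shrake_rupley_sasa(st, probe_radius=1.4,
                                           n_sphere_points=960)
    analytic = 4.0 * math.pi * (1.70 + 1.4) ** 2  # ~120.76
    assert per_atom[0] == pytest.approx(analytic, rel=0.02)
    assert per_res[("A", 1)] == pytest.approx(per_atom[0])


def test_fully_enclosed_atom_has_zero_sasa():
    shell = make_cavity_fixture(4.0, 350, check_enclosure=False)
    atoms = list(shell.atoms) + [carbon(999, (0.0, 0.0, 0.0),
                                        residue_index=999)]
    per_atom, _ = shrake_rupley_sasa(Structure("shell+centre", atoms))
    assert per_atom[-1] == 0.0


def test_coincident_atoms_have_equal_exposure():
    st = Structure("pair", [carbon(1, (0.0, 0.0, 0.0)),
                            carbon(2, (0.0, 0.0, 0.0))])
    per_atom, _ = shrake_rupley_sasa(st)
    assert per_atom[0] == pytest.approx(per_atom[1])


def test_lattice_refinement_changes_values_under_2pct(rng):
    coords = rng.uniform(0.0, 9.0, size=(25, 3))
    st = Structure("cluster", [carbon(i + 1, c) for i, c in enumerate(coords)])
    a, _ = shrake_rupley_sasa(st, n_sphere_points=960)
    b, _ = shrake_rupley_sasa(st, n_sphere_points=1920)
    scale = 4.0 * math.pi * 3.1 ** 2
    assert np.max(np.abs(a - b)) / scale < 0.02


def test_removing_an_atom_never_decreases_others(rng):
    coords = rng.uniform(0.0, 7.0, size=(15, 3))
    st = Structure("cluster", [carbon(i + 1, c) for i, c in enumerate(coords)])
    full, _ = shrake_rupley_sasa(st)
    reduced = Structure("minus", st.atoms[:-1])
    partial, _ = shrake_rupley_sasa(reduced)
    assert np.all(partial >= full[:-1] - 1e-9)


def test_matches_independent_implementation(rng):
    biotite = pytest.importorskip("biotite.structure")
    coords = rng.uniform(0.0, 8.0, size=(30, 3))
    st = Structure("cluster", [carbon(i + 1, c) for i, c in enumerate(coords)])
    ours, _ = shrake_rupley_sasa(st, probe_radius=1.4, n_sphere_points=960)
    arr = biotite.AtomArray(30)
    arr.coord = coords.astype(np.float32)
    arr.element = np.array(["C"] * 30)
    arr.atom_name = np.array(["C"] * 30)
    arr.res_id = np.arange(1, 31)
    arr.res_name = np.array(["LEU"] * 30)
    arr.chain_id = np.array(["A"] * 30)
    ref = biotite.sasa(arr, probe_radius=1.4, point_number=960,
                       vdw_radii=np.full(30, 1.70))
    assert np.allclose(ours, ref, rtol=5e-3, atol=0.5)


def test_residue_classification_defaults():
    assert classify_residue("TRP") == "aromatic"
    assert classify_residue("ARG") == "hydrophilic"
    assert classify_residue("GLY") == "unclassified"
    assert classify_residue("LEU") == "aliphatic"
    with pytest.raises(ValueError):
        classify_residue("XYZ")


def test_scheme_rejects_overlapping_classes():
    with pytest.raises(ValueError):
        ResidueClassScheme(aromatic=frozenset({"PHE"}),
                           aliphatic=frozenset({"PHE"}))


def test_all_leucine_selection_has_no_aromatic_or_philic_area(ca_bundle):
    st, truth = ca_bundle
    first = truth.helix_residue_ranges[1]
    sel = CavitySelection(st.id, tuple(("A", i)
                                       for i in range(first[0], first[1] + 1)))
    sasa = cavity_sasa(st, sel, n_sphere_points=240)
    assert sasa["aromatic"] == 0.0
    assert sasa["hydrophilic"] == 0.0
    assert sasa["hydrophobic"] == pytest.approx(sasa["aliphatic"])
    assert sasa["total"] > 0


def test_per_class_sums_match_independent_per_atom_summation(ca_bundle):
    """Independent oracle: sum raw per-atom areas per class by hand."""
    st, truth = ca_bundle
    first = truth.helix_residue_ranges[1]
    keys = tuple(("A", i) for i in range(first[0], first[1] + 1))
    sel = CavitySelection(st.id, keys)
    sasa = cavity_sasa(st, sel, n_sphere_points=240)
    per_atom, _ = shrake_rupley_sasa(st, n_sphere_points=240)
    by_hand = sum(area for atom, area in zip(st.atoms, per_atom)
                  if (atom.chain, atom.residue_index) in set(keys))
    assert sasa["total"] == pytest.approx(by_hand, abs=1e-9)


def test_sphere_lattice_is_deterministic_and_unit():
    a = sphere_lattice(960)
    b = sphere_lattice(960)
    assert np.array_equal(a, b)
    assert np.allclose(np.linalg.norm(a, axis=1), 1.0, atol=1e-12)
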