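"""Grid-based cavity volume and the assembled cavity profile."""

import math

import pytest

from seventm.pocket import (CavityProfile, CavitySelection, cavity_profile,
                            pocket_volume)
from seventm.structure import Atom, Structure
from seventm.synth import make_cavity_fixture


def selection_of(structure):
    return CavitySelection(structure.id,
                           tuple(("A", a.residue_index)
                                 for a in structure.atoms))


def test_hollow_sphere_matches_analytic_volume():
    shell = make_cavity_fixture(4.0, 350, check_enclosure=False)
    analytic = 4.0 / 3.0 * math.pi * 4.0 ** 3  # ~268.1
    vol = pocket_volume(shell, selection_of(shell), grid_spacing=0.5)
    assert vol == pytest.approx(analytic, rel=0.05)


def test_volume_converges_with_finer_grid():
    shell = make_cavity_fixture(4.0, 350, check_enclosure=False)
    sel = selection_of(shell)
    coarse = pocket_volume(shell, sel, grid_spacing=0.5)
    fine = pocket_volume(shell, sel, grid_spacing=0.25)
    assert abs(fine - coarse) / coarse < 0.05


def test_solid_cluster_has_no_cavity(rng):
    # tight cubic cluster of overlapping atoms leaves no interior void
    atoms = []
    serial = 0
    for x in range(4):
        for y in range(4):
            for z in range(4):
                serial += 1
                atoms.append(Atom(serial=serial, name="C", element="C",
                                  residue_name="LEU", residue_index=serial,
                                  chain="A", coords=(1.5 * x, 1.5 * y, 1.5 * z),
                                  vdw_radius=1.70))
    st = Structure("solid", atoms)
    assert pocket_volume(st, selection_of(st), grid_spacing=0.5) == 0.0


def test_sparse_shell_leaks():
    # a 12-atom shell cannot seal a 4 A cavity: bulk solvent floods the
    # interior, so only marginal crevice volume (if any) remains and the
    # fixture generator refuses to emit it
    shell = make_cavity_fixture(4.0, 350, check_enclosure=False)
    sparse = Structure("sparse", shell.atoms[::30])
    vol = pocket_volume(sparse, selection_of(sparse), grid_spacing=0.5)
    assert vol < 0.2 * (4.0 / 3.0) * math.pi * 4.0 ** 3
    with pytest.raises(ValueError, match="enclose"):
        make_cavity_fixture(4.0, 12, check_enclosure=True)


def test_degenerate_selection_rejected():
    atoms = [Atom(serial=i + 1, name="C", element="C", residue_name="LEU",
                  residue_index=i + 1, chain="A",
                  coords=(float(i), float(2 * i), 0.0), vdw_radius=1.70)
             for i in range(5)]
    st = Structure("flat", atoms)
    with pytest.raises(ValueError):
        pocket_volume(st, selection_of(st), grid_spacing=0.5)


def test_grid_spacing_bounds():
    shell = make_cavity_fixture(4.0, 350, check_enclosure=False)
    with pytest.raises(ValueError):
        pocket_volume(shell, selection_of(shell), grid_spacing=0.1)


def test_profile_identities_hold(ca_bundle):
    st, truth = ca_bundle
    lo = min(s for s, _ in truth.helix_residue_ranges.values())
    hi = max(e for _, e in truth.helix_residue_ranges.values())
    sel = CavitySelection(st.id, tuple(("A", i) for i in range(lo, hi + 1)))
    prof = cavity_profile(st, sel, n_sphere_points=240, grid_spacing=0.6)
    assert prof.sasa_phob == pytest.approx(prof.sasa_aliph + prof.sasa_arom,
                                           abs=1e-9)
    if prof.sasa_phil + prof.sasa_phob > 0:
        assert prof.pct_hydrophilicity == pytest.approx(
            100 * prof.sasa_phil / (prof.sasa_phil + prof.sasa_phob))


def test_profile_invariant_enforced():
    with pytest.raises(ValueError):
        CavityProfile(structure_id="x", volume=1.0, sasa_total=10.0,
                      sasa_phil=2.0, sasa_phob=9.0, sasa_aliph=5.0,
                      sasa_arom=3.0, sasa_unclassified=0.0,
                      pct_hydrophilicity=20.0)
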