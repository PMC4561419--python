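"""Synthetic-data generators: determinism and geometric ground truth."""

import math

import numpy as np
import pytest

from seventm.seq import match_motif
from seventm.structure import kabsch_superpose
from seventm.synth import (BundleSpec, make_cavity_fixture, make_ffa_like_trio,
                           make_gpcr_sequence, make_ideal_helix,
                           make_tm_bundle, perturb_structure)


def test_sequence_generator_deterministic_and_unique_matches(patterns):
    rec1, truth1 = make_gpcr_sequence(seed=7)
    rec2, _ = make_gpcr_sequence(seed=7)
    assert rec1.residues == rec2.residues
    for pattern in patterns:
        hits = match_motif(rec1, pattern)
        assert len(hits) == 1
        assert hits[0].anchor_position == truth1.anchors[pattern.helix_id]


def test_zero_length_fillers_concatenate_motifs(patterns):
    rec, truth = make_gpcr_sequence(
        seed=2, inter_motif_lengths=[0] * (len(patterns) + 1))
    spans = sorted(truth.motif_spans.values())
    for (_, e1), (s2, _) in zip(spans, spans[1:]):
        assert s2 == e1 + 1
    for pattern in patterns:
        assert len(match_motif(rec, pattern)) == 1


def test_all_motif_filler_alphabet_rejected():
    with pytest.raises(ValueError):
        make_gpcr_sequence(filler_alphabet="GN")


def test_trio_deterministic(ffa_trio):
    records, _ = ffa_trio
    again, _ = make_ffa_like_trio(seed=0)
    assert [r.residues for r in records] == [r.residues for r in again]
    different, _ = make_ffa_like_trio(seed=1)
    assert [r.residues for r in records] != [r.residues for r in different]


def test_ideal_helix_geometry():
    ca = make_ideal_helix(10)
    dists = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    expected = math.sqrt((2 * 2.3 * math.sin(math.radians(50))) ** 2 + 1.5 ** 2)
    assert np.allclose(dists, expected, atol=1e-9)
    assert expected == pytest.approx(3.83, abs=0.01)
    # screw symmetry: residues 1..n-1 superpose exactly onto 2..n
    res = kabsch_superpose(ca[:-1], ca[1:])
    assert res.rmsd < 1e-9


def test_degenerate_helix_rejected():
    with pytest.raises(ValueError):
        make_ideal_helix(5, rise=0.0, twist=0.0)
    with pytest.raises(ValueError):
        make_ideal_helix(1)


def test_bundle_axis_spacing_follows_chord_formula(ca_bundle):
    st, truth = ca_bundle
    xy = truth.axis_positions
    spacing = np.linalg.norm(xy[1] - xy[0])
    assert spacing == pytest.approx(2 * 12.0 * math.sin(math.pi / 7), abs=1e-9)
    assert spacing == pytest.approx(10.41, abs=0.01)


def test_single_helix_bundle_equals_ideal_helix():
    st, _ = make_tm_bundle(BundleSpec(n_helices=1, residues_per_helix=12))
    coords = np.array([a.coords for a in st.atoms])
    assert np.allclose(coords, make_ideal_helix(12), atol=1e-12)


def test_too_tight_ring_rejected():
    with pytest.raises(ValueError, match="overlap"):
        make_tm_bundle(BundleSpec(ring_radius=2.0))


def test_bundle_residue_numbering_continuous(ca_bundle):
    st, truth = ca_bundle
    indices = [a.residue_index for a in st.atoms]
    assert indices == list(range(1, 211))
    assert truth.helix_residue_ranges[7] == (181, 210)


def test_perturb_sigma_zero_and_determinism(ca_bundle):
    st, _ = ca_bundle
    same = perturb_structure(st, 0.0, seed=1)
    assert np.allclose([a.coords for a in same.atoms],
                       [a.coords for a in st.atoms])
    p1 = perturb_structure(st, 1.0, seed=4)
    p2 = perturb_structure(st, 1.0, seed=4)
    assert np.allclose([a.coords for a in p1.atoms],
                       [a.coords for a in p2.atoms])


def test_cavity_fixture_centre_occluded():
    shell = make_cavity_fixture(4.0, 350, check_enclosure=False)
    from seventm.pocket import shrake_rupley_sasa
    from seventm.structure import Atom, Structure

    centre = Atom(serial=9999, name="C", element="C", residue_name="LEU",
                  residue_index=9999, chain="A", coords=(0.0, 0.0, 0.0),
                  vdw_radius=1.70)
    per_atom, _ = shrake_rupley_sasa(
        Structure("probe", list(shell.atoms) + [centre]), n_sphere_points=240)
    assert per_atom[-1] == 0.0


def test_cavity_fixture_requires_inner_radius_above_probe():
    with pytest.raises(ValueError):
        make_cavity_fixture(1.0, 100)
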