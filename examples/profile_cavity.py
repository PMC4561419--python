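"""Binding-cavity profiling: SASA partition and enclosed volume.

Two inputs with known answers: a hollow atom shell whose cavity volume has a
closed form (4/3 pi r^3 = 268.1 A^3 for r = 4 A), and an all-leucine helix
bundle whose cavity-lining SASA must be purely aliphatic.
"""

import math

from seventm import CavitySelection, cavity_profile, pocket_volume
from seventm.synth import BundleSpec, make_cavity_fixture, make_tm_bundle

shell = make_cavity_fixture(inner_radius=4.0, shell_atoms=350, seed=0)
selection = CavitySelection(shell.id, tuple(("A", a.residue_index)
                                            for a in shell.atoms))
volume = pocket_volume(shell, selection, grid_spacing=0.5)
print(f"hollow shell volume: {volume:.1f} A^3 "
      f"(analytic {4 / 3 * math.pi * 4 ** 3:.1f})")

bundle, truth = make_tm_bundle(BundleSpec(seed=0))
lining = CavitySelection(bundle.id, tuple(("A", i) for i in range(1, 211)))
profile = cavity_profile(bundle, lining, n_sphere_points=240,
                         grid_spacing=0.6)
print(f"bundle cavity volume: {profile.volume:.1f} A^3")
print(f"SASA total {profile.sasa_total:.0f} A^2, "
      f"aliphatic {profile.sasa_aliph:.0f}, aromatic {profile.sasa_arom:.0f}, "
      f"hydrophilic {profile.sasa_phil:.0f}")
print(f"percent hydrophilicity: {profile.pct_hydrophilicity:.1f} % "
      "(all-leucine lining is 0 % hydrophilic by construction)")
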