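"""Build a reduced coarse-grained collagen fibril, pull it, and fit the
cartilage fibril coefficients to 70% of the resulting curve.

The fibril here is a desk-scale fixture (7 molecule tracks, two molecules
in series per track) so the run finishes in under a minute; the full
21.5-nm / 151-molecule construction is exercised by the builder alone.
"""

import numpy as np

from kneeland import cartilage, md
from kneeland.fibril import build_fibril
from kneeland.forcefield import ForceFieldParams

ff = ForceFieldParams()
fibril = build_fibril(diameter_nm=5.2, beta=1.0, molecule_length_nm=16.8,
                      bead_spacing_nm=1.4, n_axial=2, stagger_nm=4.2,
                      axial_gap_nm=4.2, seed=0)
print(f"fibril: {fibril.n_cross_section} tracks, {fibril.n_molecules} "
      f"molecules, {len(fibril.positions)} beads, "
      f"{len(fibril.crosslinks)} crosslinks (beta={fibril.beta:.0%})")

curve = md.tensile_test(fibril, ff, max_strain=0.18, n_levels=9, seed=0)
for e, s in zip(curve.strain, curve.stress):
    print(f"  strain {e:5.3f}  stress {s:8.1f} MPa")

fit = cartilage.fit_fibril_params_to_md(curve, scale=0.70)
print(f"fitted cartilage fibril coefficients at the 70% (collagen II) "
      f"scale: E0 = {fit.E0:.1f} MPa, E_eps = {fit.Ee:.1f} MPa "
      f"(rms residual {fit.residual:.2f} MPa)")
print("E0 is the initial fibril stiffness; E_eps the strain-stiffening "
      "coefficient entering sigma = E0*eps + E_eps*eps^2.")
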