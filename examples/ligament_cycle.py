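"""Ligament elastoplastic load/unload cycle with MD-tabulated hardening.

A fiber-aligned slip system yields once the fibril stress exceeds the
hardening curve; unloading leaves a permanent set, and the enclosed loop
area is the dissipated work.
"""

import numpy as np

from kneeland import ligament as lg
from kneeland.curve import StressStrainCurve

# hardening curve standing in for an MD fibril yield response
hardening = StressStrainCurve(np.linspace(0, 0.5, 26),
                              5.0 + 50.0 * np.linspace(0, 0.5, 26))
E = 1000.0   # MPa elastic unloading modulus

path = np.concatenate([np.linspace(0, 0.05, 60), np.linspace(0.05, 0.0, 60)])
stress, eps_p = lg.uniaxial_elastoplastic_cycle(path, hardening, E)
print(f"peak stress {stress.max():.2f} MPa at strain {path[np.argmax(stress)]:.3f}")
print(f"residual plastic strain after unload: {eps_p[-1]:.4f}")
print(f"dissipated work over the cycle: {np.trapezoid(stress, path):.4f} MPa")

p = lg.LigamentParams()
pre = lg.PreStrain(alpha0=1.05)
sig0 = lg.total_stress(np.eye(3), None, pre, p)
print(f"pre-strained (alpha0=1.05) ligament at rest carries "
      f"{sig0[0, 0]:.2f} MPa along the fiber - the in-situ tension that "
      "initial stretch encodes.")
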