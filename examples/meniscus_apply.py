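"""Apply a stress state to the transversely isotropic meniscus law."""

import numpy as np

from kneeland import meniscus as mn

p = mn.MeniscusParams()
print(f"Ec={p.Ec} MPa (circumferential), Et={p.Et} MPa (transverse), "
      f"nu_ct={p.nu_ct}, nu_ta={p.nu_ta}, G={p.G} MPa")

sigma = np.array([0.0, -1.0, 12.0, 0.0, 0.0, 0.5])   # MPa, Voigt 11..23
eps = mn.stress_to_strain(sigma, p)
for name, s, e in zip(mn.VOIGT_ORDER, sigma, eps):
    print(f"  sigma_{name} = {s:6.2f} MPa -> eps_{name} = {e:9.5f}")
print("Component 33 is the stiff circumferential (hoop-fiber) direction: "
      "12 MPa of hoop tension produces only 10% strain, while the same "
      "stress transversely would produce 60%.")
print(f"strain energy density: {mn.strain_energy_density(sigma, p):.4f} MPa")
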