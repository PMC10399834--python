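"""Static optimization of the 34-muscle toy fixture at one landing height.

Minimizes the sum of cubed muscle stresses subject to hip/knee/ankle
moment equilibrium and passive/maximum force bounds, then cross-checks the
genetic-algorithm route against the smooth solver.
"""

import numpy as np

from kneeland import muscles as mu
from kneeland import regression as rg
from kneeland import synthetic as sy

BODY_MASS = 66.2
msk = sy.gen_toy_musculoskeleton(n_dof=3, n_muscles=34, seed=0)
prof = rg.predict_profile(40.0)
M = BODY_MASS * np.array([prof.sagittal["hip_flex_moment"],
                          prof.sagittal["knee_flex_moment"],
                          prof.sagittal["ankle_dorsi_moment"]])
prob = mu.OptimizationProblem(msk.lever_arms, M, msk.pcsa,
                              msk.x_passive, msk.x_max)
sol = mu.solve(prob)
ga = mu.solve(prob, method="genetic", seed=1)
print(f"targets (hip/knee/ankle): {M.round(2)} N*m")
print(f"objective (sum of cubed stresses): nlp {sol.objective:.4f}, "
      f"genetic {ga.objective:.4f} "
      f"({abs(ga.objective - sol.objective) / sol.objective:.2%} apart)")
print(f"moment residual: {sol.equality_residual:.2e} N*m")
order = np.argsort(sol.forces)[::-1][:6]
print("most loaded muscles:")
for i in order:
    print(f"  {msk.muscle_names[i]:24s} {sol.forces[i]:7.1f} N "
          f"(stress {sol.forces[i] / msk.pcsa[i]:5.2f} N/cm^2)")
print("Cubing the muscle stress spreads load across synergists in "
      "proportion to their cross-sectional areas.")
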