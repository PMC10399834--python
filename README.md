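# kneeland

Multiscale drop-landing knee biomechanics at desk scale: from
coarse-grained collagen fibrils to the critical landing height at which
articular-cartilage damage initiates.

Landing from height is one of the activities most associated with acute
knee injury, yet the heights at which soft tissue actually fails are
unsafe to measure on people. `kneeland` is a research library for
exploring that question computationally. It chains together, with fully
synthetic and seeded inputs:

1. **Collagen fibril molecular dynamics** — a mesoscopic bead-spring model
   of tropocollagen (~300 nm x 1.6 nm molecules packed quasi-hexagonally,
   151 molecules in a 21.5-nm fibril, enzymatic crosslinks at a density
   β), with a breakable two-regime bond, Lennard-Jones adhesion, and a
   bending term:

   `E_inter = 4ε[(σ/r)¹² − (σ/r)⁶]`,
   `E_bond = K_T0/2 (r−r₀)² + C₁` for `r < r₁`, `K_T1/2 (r−r̄₁)² + C₂`
   for `r₁ ≤ r < r_b`, `0` beyond (bond broken),
   `E_angle = K_θ (θ−θ₀)²`.

   Tensile tests on the fibril produce stress–strain curves.
2. **Fibril-reinforced cartilage** — tension-only collagen bundles
   `σ_f = (η₀ₛ(z)/J)(E₀ε_f + E_ε ε_f²) n⊗n` in the logarithmic fiber
   strain, softened by an energy limiter Φ,
   `σ_fl = σ_f exp(−(W_fl/Φ)^m)`, over a neo-Hookean matrix, with
   depth-dependent composition `v_t(z) = 1.4z² − 1.1z + 0.59`,
   `η₀ₛ(z) = 0.1z + 0.1`. `(E₀, E_ε)` can be fitted to 70% of an MD
   fibril curve (the collagen II vs I stiffness reduction).
3. **Transversely isotropic meniscus** and a **hierarchical
   fiber/fibril hyper-elastoplastic ligament** model with pre-strain
   (initial stretch α₀) and a fiber-aligned slip system hardened by the
   MD fibril curve under Karush–Kuhn–Tucker loading/unloading.
4. **Landing-height regressions** — power / log / exponential models of
   sagittal joint angles, moments and vertical GRF against drop height
   (e.g. knee flexion `14.769 ln x − 15.237` deg, vGRF `0.4468 x^0.542`
   BW), with height-independent means for the coupled planes.
5. **Static muscle-force optimization** — minimize `Σ (xᵢ/PCSAᵢ)³`
   subject to `[R]{x} = {M}` and `x_p ≤ x ≤ x_max` (34-muscle toy
   fixture), with an iterative coupling loop converging when the required
   moments change by less than 1 N·m.
6. **Critical-height search** — an elastic-foundation contact surrogate
   distributes the joint load over medial/lateral compartments and
   covered (cartilage–cartilage) / uncovered (cartilage–meniscus)
   regions, the cartilage model is evaluated at five depths per node, and
   a coarse-to-fine walk (20/10/5/1-cm increments from a 1-m start) finds
   the first integer height whose damage indicator
   `1 − exp(−(W_fl/Φ)^m)` crosses its threshold.

The full finite-element knee of the original workflow is deliberately out
of scope: the contact surrogate preserves the structure of the analysis
(load sharing, depth-resolved damage, search schedule) rather than
absolute stress magnitudes.

## Worked example

```
$ python examples/find_critical_height.py
start 100 cm, schedule (20, 10, 5, 1), damage threshold 0.05
search trace (height, damaged):
   100 cm  ok
   120 cm  DAMAGE
   110 cm  DAMAGE
   105 cm  ok
   106 cm  ok
   107 cm  ok
   108 cm  ok
   109 cm  ok
critical landing height: 110 cm (8 pipeline evaluations)
at that height: joint load 7.25 BW, peak contact pressure 10.19 MPa, max damage indicator 0.062
```

Reading: at a 110-cm drop the combined ground reaction plus muscle
compression reaches 7.25 body weights; the elastic-foundation contact
peaks at 10.19 MPa; and in the superficial cartilage the most strained
fibril bundle's energy-limiter indicator (0.062) first exceeds the 0.05
threshold — one centimetre lower, it does not. The number characterizes
the shipped surrogate configuration, not a subject-specific prediction.

Other capabilities, one script each, under `examples/`:
`fibril_tensile.py` (build + pull a fibril, fit E₀/E_ε),
`cartilage_sweep.py`, `ligament_cycle.py`, `meniscus_apply.py`,
`predict_profile.py`, `solve_muscles.py`.

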