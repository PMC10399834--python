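# Methods

This note records the models implemented in `kneeland`, their assumptions,
the parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## Coarse-grained collagen (`forcefield`, `fibril`, `md`)

**Model.** A tropocollagen molecule is a straight chain of beads at 1.4-nm
spacing (215 beads at the full 300-nm length). Three potentials act:
12-6 Lennard-Jones between non-bonded beads (1-2 and 1-3 pairs excluded,
energy-shifted at a 2.5σ cutoff so the NVE Hamiltonian is continuous); a
two-regime breakable bond — a soft spring (K_T0) to r₁, a stiff spring
(K_T1) centered on r̄₁ to the rupture distance r_b, zero beyond; and a
harmonic angle about the straight configuration. r̄₁ is derived from force
continuity at r₁ and C₁/C₂ from energy continuity at r₁ and r_b, so the
only free bond inputs are the two stiffnesses and three distances. Bond
rupture is permanent, and angles lose a broken leg.

**Units and defaults.** Internal units are nm / kcal·mol⁻¹ / amu; one
stress unit is 6.9477 MPa. The shipped constants (ε = 6.87, σ = 1.472 nm,
K_T0 = 1713, K_T1 = 9766 kcal·mol⁻¹·nm⁻², r₀ = 1.40, r₁ = 1.82,
r_b = 2.10 nm, K_θ = 14.98 kcal·mol⁻¹·rad⁻², bead mass 1358.7 amu) follow
the magnitudes of published mesoscopic collagen bead-spring models; they
are editable on `ForceFieldParams` and should be treated as a working set,
not a literature-validated calibration.

**Fibril construction.** Molecule axes sit on a hexagonal lattice clipped
to the circular cross-section, grouped into 5-molecule microfibrils, with
a 5-phase axial stagger. The lattice pitch defaults to 1.67 nm, slightly
above the 1.6-nm molecule diameter; this pitch was fixed once so that the
21.5-nm cross-section holds exactly 151 axes (the count is flat in the
pitch over ≈1.64–1.72 nm, so this is a selection within a plateau, not a
sensitive calibration). Crosslinks: a fraction β of all molecule ends
(sampled without replacement, so β = 1 means every end, i.e. 2 connected
ends per molecule exactly) is bonded to the nearest non-end bead of a
different molecule; the crosslink bond reuses the two-regime form with its
rest length at the creation distance and shorter stiffening/rupture
offsets (0.12 / 0.24 nm), representing the locality of an enzymatic bond.

**Integration.** Velocity Verlet; Langevin runs use BAOAB with a seeded
generator (trajectories are bit-reproducible under a seed). The documented
stability heuristic dt ≤ 0.05·√(m/K_T0) ≈ 0.045 is enforced as a
precondition; production runs use dt = 0.01–0.02. NVE drift over 1000
steps on a perturbed 20-bead chain is below 0.1% (tested ≈ 1e-7).

**Tensile protocol.** Each lattice track is clamped over its outermost
two beads at both ends. The test is a *staircase*: ramp the moving clamp
at a fixed engineering strain rate to each strain level, hold at rest for
a set time, and average the boundary reaction force over the second half
of the hold. Measuring at rest matters: at desk scale the thermostat drag
on a continuously moving system is comparable to the elastic force, and a
continuous pull reports mostly that drag. Stress is force over the
initial cross-section π(d/2)² (engineering stress). A small residual
tension (a few % of peak) remains at zero strain from equilibration
against fixed clamps.

**Desk-scale fixture.** Full dynamics on the 151-molecule × 300-nm fibril
is out of reach for an interpreted MD loop, so the dynamic fixture is a
7-track fibril (5.2-nm diameter) of two 16.8-nm molecules in series per
track, junctions staggered, with the axial junction gap set beyond the LJ
cutoff. That gap forces the axial load path through crosslinks and
lateral shear — which is what makes stiffness grow with β at 5% strain
and produces a bond-breaking cascade with a post-peak stress drop when
pulled to ~45%. The 151-molecule build is exercised as a construction
test only. Problem sizes (182–570 beads, 10⁴–10⁵ steps) were chosen as
the smallest at which these phenomena are clean.

## Cartilage (`cartilage`)

Tension-only fibril bundles plus an isotropic matrix:
σ_c = Σᵢ v_f(i)·σ_fl(i) + (1 − v_t)·σ_nf. The intact fibril law is
σ_f = (η₀ₛ(z)/J)(E₀ε + E_ε ε²) n⊗n in the logarithmic fiber strain
ε = ln|F n₀| (zero for ε ≤ 0); its axial energy is
W_fl = η₀ₛ(E₀ε²/2 + E_ε ε³/3). The energy limiter replaces W_fl by the
incomplete-gamma form ψ = (Φ/m)[Γ(1/m) − Γ(1/m, (W_fl/Φ)^m)], whose
derivative is exactly the attenuation exp(−(W_fl/Φ)^m), so the softened
stress σ_fl = σ_f·exp(−(W_fl/Φ)^m) is the exact energy gradient; ψ
saturates at (Φ/m)Γ(1/m), which is what makes stress decay past a finite
maximum (material failure as softening hyperelasticity). Defaults:
E₀ = 8.121 MPa, E_ε = 5326.32 MPa, Φ = 82.326, m = 12, G_m = 0.723 MPa,
D = 1e-4. Φ is carried in the same units as W_fl (MPa); the source
material does not state its units, and this choice keeps the attenuation
dimensionless.

The printed non-fibrillar expression in the source is typographically
corrupted ("σnf = η0s −lnJ 6J Gm 3η0s lnJ η0s−1 −3J + η0s J −η0s−1 I +
GmJ FFT −J2/3I + 1D(J−1)2", preserved here verbatim for the record). The
implementation instead *declares* the energy
W_nf = η₀ₛ(z)·G_m/2·(Ī₁ − 3) + (1/D)(J − 1)², whose exact Cauchy stress
is η₀ₛ G_m/J · dev(B̄) + (2/D)(J − 1) I; stress = ∂W is the binding
contract and is finite-difference-tested to 1e-5 at random states.

Bundles: two primary directions (weight v_t·3/13 each) in the (e₁,e₃) and
(e₂,e₃) planes, tilting linearly in z from bone-perpendicular (z = 0) to
surface-parallel (z = 1), plus seven fixed secondary directions (weight
v_t·1/13 each; axes and body diagonals) — the 2·3/13 + 7·1/13 = 1 split
preserves the 3:1 primary:secondary ratio. Damage is defined as
1 − exp(−(max W_fl/Φ)^m) over the strain history (one minus the worst
attenuation), flagged above a configurable threshold (default 0.05); the
cartilage model is softening-hyperelastic, so this indicator is the
desk-scale analog of a plastic-strain damage map.

Fitting: `fit_fibril_params_to_md` least-squares the axial law against
`scale` × the pre-peak MD stress (default scale 0.70 for collagen II).
The default fit is the intact law, *linear* in (E₀, E_ε) — hence the
scaling rule scale×curve → scale×coefficients holds exactly; passing
(Φ, m) switches to a nonlinear fit of the softened law for curves with
visible softening.

## Meniscus (`meniscus`)

Transversely isotropic linear elasticity in local axes (1,2 transverse ≡
axial plane, 3 circumferential), Voigt order (11,22,33,12,13,23) with
engineering shears, a single shear modulus G in all three shear slots.
The printed compliance is asymmetric as typeset; symmetry is restored by
elastic reciprocity with the printed entries kept where unambiguous:
in-plane coupling −ν_ct/E_t, circumferential coupling −ν_ta/E_c. Defaults
E_c = 120, E_t = 20, ν_ct = 0.3, ν_ta = 0.2, G = 47 MPa give a positive
definite compliance (checked by leading minors, violating minor named on
error). A global-frame wrapper rotates stress/strain through the local
triad; frame objectivity is property-tested.

## Ligament and tendon (`ligament`)

Two-level rule of mixtures: fibrils (volume fraction v_fb) reinforce the
fiber, fibers (v_f) reinforce the tissue; each level adds a neo-Hookean
matrix term and a shear-interaction term. The fibril energy is
ψ_fb = ½μ_o tanh(a₁(Ī₄ₑ − 1)) + a₂ exp(a₃(Ī₄ₑ − I_o))(Ī₁ₑf − 3) with
Ī₁ₑf = Ī₄ₑ + 2 Ī₄ₑ^(−1/2). The printed shear-interaction ratios are
corrupted in the source; each is implemented as a single effective
mixing coefficient (χ_fiber, χ_tissue, default 1 — the printed
composite-cylinder ratio reduces to exactly 1 when the fibril shear
modulus equals μ_o). Volumetric term: ψ_vol = E_k/2 (J−1)², giving the
energy-consistent stress E_k(J−1)I (the printed variant carries an extra
J factor that would break stress–energy consistency). Fibrillar stress is
switched off whenever the *total* isochoric Ī₄ ≤ 1; in that regime the
energy freezes the fibril group at its reference value so energy and
stress stay consistent on either side of the switch.

Pre-strain enters as F_total = F·F₀ with F₀ = diag(α₀, α₀^(−1/2),
α₀^(−1/2)) by default (isochoric; the printed diag(α₀, α₀⁻¹, α₀⁻¹) is
selectable but not volume-preserving). Per-ligament α₀ defaults
(ACL 1.05, MCL/LCL 1.04, …) are placeholders — the source defers them to
other work. The fibril coefficients (μ_o = 12 MPa, I_o = 1.06, a₁ = 1.2,
a₂ = 0.8, a₃ = 8, matrix moduli 0.5/2.0 MPa, E_k = 1000 MPa) are likewise
working placeholders chosen for a physiological-looking toe + linear
response with J within 1% at 10% uniaxial strain; `calibrate_aggregate`
refits any declared-free subset to a target curve by least squares and
warns on unidentifiable subsets via the Jacobian condition number.

Plasticity: one fiber-aligned slip system, F = Fe·Fp with
Fp = λ_p n₀⊗n₀ + λ_p^(−1/2)(I − n₀⊗n₀) (isochoric). The yield stress is
interpolated from an MD-derived (or synthetic) hardening curve at the
accumulated slip; the return map solves the consistency equation by
bracketed root finding with an explicit elastic unloading modulus, and the
KKT conditions (Δγ ≥ 0, f ≤ tol, Δγ·f ≈ 0) hold at every converged step.

## Landing regressions (`regression`, `synthetic`)

Seven sagittal variables follow power/log/exponential models of drop
height; the shipped coefficients are the published table. Adopted
conventions the table leaves unstated: height in cm (the 20/40/60-cm
analysis heights), moments body-mass-normalized (N·m/kg — the printed
coefficient magnitudes are only plausible at that scale), vGRF in body
weights. Fitting linearizes in log space for the initializer and refines
with full nonlinear least squares; R² = 1 − SS_res/SS_tot (defined as 1
for an exactly saturated constant fit). Form selection takes the highest
R² with a deterministic power > log > exp tie-break at 1e-12. Heights
beyond the 60-cm measured range warn rather than fail: the headline
supra-physiological analyses are themselves extrapolations.

The landing-record generator draws sagittal values as mean·(1 + N(0, cv))
(multiplicative, matching the roughly symmetric spread of the literature
violins) and coupled-plane values as mean + N(0, cv·|mean|) about
height-independent means. The coupled means shipped here are **fixtures**:
the literature values are shown only graphically and are not tabulated
anywhere, so nothing downstream should be interpreted as reproducing
them. The generators are pure functions of their seeds.

What the synthetic data do *not* emulate: between-study heterogeneity,
subject covariates, trial-to-trial correlation structure, or bilateral
asymmetry — passing tests show the pipeline's internal consistency on
idealized inputs, not robustness to real literature data.

## Muscle optimization (`muscles`)

Minimize Σ(xᵢ/PCSAᵢ)³ s.t. Rx = M, x_p ≤ x ≤ x_max. The objective is
strictly convex and separable on x ≥ 0, so the KKT system has the closed
form xᵢ = clip(PCSAᵢ^{3/2}·√((Rᵀν)ᵢ/3), bounds); the primary solver runs
SLSQP from an LP-feasible point and then polishes by solving the n_dof
dual multipliers ν from that relation (machine-precision stationarity and
symmetric splits). The genetic route is a seeded real-coded GA (blend
crossover, Gaussian mutation, elitism, quadratic equality penalty)
followed by the same local polish — a standard memetic arrangement; both
routes agree to well under 1% objective on the 34-muscle fixture. An LP
pre-pass certifies feasibility and reports the reachable moment envelope
on failure. The coupling loop re-solves with targets updated by the joint
model's passive reaction moments until the update falls below 1 N·m
(configurable), returning the residual trace; passive force enters only
as the lower bound — computing it from muscle kinematics is out of scope.

## Reduced knee pipeline (`pipeline`)

height → regression profile → moments (× body mass, default 66.2 kg, the
literature mean) → muscle solve → axial joint load in BW (vGRF + axial
muscle components, default per-muscle axial fractions from the toy
fixture) → elastic-foundation contact → depth-resolved cartilage damage →
search.

Contact: per compartment (medial share 0.50 + 0.0025·(h−40), clipped to
[0.30, 0.70] — lateral dominance below 40 cm shifting medial above, a
qualitative mimic, not a calibrated claim) and per region (uncovered /
meniscus share 0.39), a rigid sphere (35-mm condyle) indents an elastic
foundation: p = k·penetration/thickness with k = 15 MPa (an instantaneous
aggregate stiffness), apex depth solved by bracketed root finding so each
region's integrated pressure balances its share to ~1e-12. Penetration is
capped at 95% of the thickness; exceeding it raises an error rather than
extrapolating the foundation.

Local tissue state: the foundation penetration sets λ_z = 1 − p/k and
incompressibility sets λ_r = λ_z^(−1/2) (laterally free axial
compression). A strictly confined state (λ_r = 1) was rejected because it
can never put any fibril bundle in tension — no damage could initiate and
the superficial-first pattern would be unrepresentable; the lateral bulge
is precisely what stretches the surface-parallel superficial fibrils, so
damage initiates at z = 1 (tested across loads). The cartilage model is
evaluated at z ∈ {0, 0.25, 0.5, 0.75, 1} per node (vectorized over nodes;
cross-checked against the tensor API).

Search: from 1 m, step up by 20 cm until the damage flag flips, restart
from the last undamaged height with 10, then 5, then 1 cm; the result is
the first damaged integer height, proven equal to an exhaustive 1-cm scan
for monotone damage laws (property-tested on randomized thresholds). A
start inside the damaged regime first walks down to an undamaged base.
With the shipped defaults the critical height lands near 1.1 m; this
number characterizes the surrogate configuration — absolute FE-level
magnitudes (contact stresses of tens of MPa, specific critical heights)
are expressly not reproduced by the foundation surrogate.

## Known limitations

- No poroelastic/biphasic transients, osmotic swelling, or matrix damage
  in cartilage; no viscoelasticity or 3-D insertion mechanics in
  ligaments; no meniscal hoop geometry.
- The CG force-field constants, ligament coefficients, pre-strains and
  coupled-plane means are placeholders or literature-magnitude defaults,
  not fitted to data shipped with the package.
- The contact surrogate conserves force and ordering (monotonicity in
  height) but not FE stress magnitudes or patterns.
- Desk-scale MD uses short molecules and low temperature; quantities that
  depend on molecule length (e.g. absolute fibril modulus, D-period
  mechanics) are not meaningful at this scale.
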