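"""Hierarchical fiber/fibril hyper-elastoplastic ligament and tendon model.

Fibrils reinforce fibers, fibers reinforce the tissue (a two-level rule of
mixtures with neo-Hookean matrices and an effective shear-interaction term
per level).  The fibril energy is

    psi_fb = 1/2 mu_o tanh(a1 (I4e - 1)) + a2 exp(a3 (I4e - Io)) (I1ef - 3),

with the fibril pseudo-invariant I1ef = I4e + 2 I4e^(-1/2).  Pre-strain
enters as an initial stretch alpha0 composed with the motion
(F_total = F F0); plasticity is a single fiber-aligned slip mechanism
(F = Fe Fp, det Fp = 1) with hardening tabulated from an MD-derived fibril
stress-strain curve under the Karush-Kuhn-Tucker loading/unloading
conditions.  The fibrillar stress is switched off whenever the total
isochoric fiber invariant I4 <= 1 (tension-only reinforcement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, least_squares

from .curve import StressStrainCurve


@dataclass
class LigamentParams:
    """Moduli in MPa; volume-fraction pairs each sum to one.

    Per-ligament alpha0 pre-strains and the fibril coefficients are not
    tabulated in the source literature; these defaults are working
    placeholders for desk-scale studies.
    """

    mu_o: float = 12.0        # fibril shear modulus
    I_o: float = 1.06         # secondary stiffening onset
    a1: float = 1.2
    a2: float = 0.8
    a3: float = 8.0
    mu_m: float = 0.5         # tissue matrix shear modulus
    mu_fm: float = 2.0        # fiber matrix shear modulus
    v_f: float = 0.65         # fiber fraction in tissue
    v_m: float = 0.35
    v_fb: float = 0.7         # fibril fraction in fiber
    v_mb: float = 0.3
    Ek: float = 1000.0        # volumetric penalty modulus
    chi_tissue: float = 1.0   # effective shear-mixing coefficient (tissue)
    chi_fiber: float = 1.0    # effective shear-mixing coefficient (fiber)
    n0: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def __post_init__(self) -> None:
        self.n0 = np.asarray(self.n0, dtype=float)
        self.n0 = self.n0 / np.linalg.norm(self.n0)
        if min(self.mu_o, self.mu_m, self.mu_fm, self.Ek) <= 0:
            raise ValueError("moduli must be positive")
        if abs(self.v_f + self.v_m - 1) > 1e-9 or abs(
                self.v_fb + self.v_mb - 1) > 1e-9:
            raise ValueError("volume-fraction pairs must sum to 1")


#: Per-ligament pre-strain placeholders (initial stretch alpha0).
DEFAULT_PRESTRAINS = {
    "ACL": 1.05, "PCL": 1.00, "MCL": 1.04, "LCL": 1.04,
    "LPL": 1.02, "MPL": 1.02, "PT": 1.02,
}


@dataclass
class PreStrain:
    alpha0: float = 1.0
    convention: str = "isochoric"   # or "printed"

    def __post_init__(self) -> None:
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be positive")
        if self.convention not in ("isochoric", "printed"):
            raise ValueError("convention must be 'isochoric' or 'printed'")


def prestrain_gradient(alpha0: float, n0=np.array([1.0, 0.0, 0.0]),
                       convention: str = "isochoric") -> np.ndarray:
    """Initial-stretch tensor F0: alpha0 along the fiber axis.

    Transverse entries are alpha0^(-1/2) (isochoric, det F0 = 1, default)
    or alpha0^(-1) (the printed variant, not volume preserving).
    """
    pre = PreStrain(alpha0, convention)
    n = np.asarray(n0, dtype=float)
    n = n / np.linalg.norm(n)
    P = np.outer(n, n)
    t = alpha0 ** (-0.5) if pre.convention == "isochoric" else alpha0 ** (-1.0)
    return alpha0 * P + t * (np.eye(3) - P)


@dataclass
class PlasticState:
    """Fiber-aligned isochoric plastic flow."""

    Fp: np.ndarray = field(default_factory=lambda: np.eye(3))
    accumulated_slip: float = 0.0
    yielding: bool = False

    def __post_init__(self) -> None:
        self.Fp = np.asarray(self.Fp, dtype=float)
        if abs(np.linalg.det(self.Fp) - 1.0) > 1e-8:
            raise ValueError("plastic flow must be isochoric (det Fp = 1)")


def plastic_gradient(lambda_p: float, n0) -> np.ndarray:
    """Fp = lambda_p n0 (x) n0 + lambda_p^(-1/2) (I - n0 (x) n0)."""
    n = np.asarray(n0, dtype=float)
    n = n / np.linalg.norm(n)
    P = np.outer(n, n)
    return lambda_p * P + lambda_p ** (-0.5) * (np.eye(3) - P)


# ---------------------------------------------------------------- invariants

def kinematic_invariants(F: np.ndarray, Fp: np.ndarray, n0: np.ndarray):
    """(I1e_bar, I4e_bar, I1ef_bar) of the isochoric elastic deformation.

    Fe = F Fp^(-1); the fibril direction in the intermediate configuration
    is Fp n0 / |Fp n0|; I1ef = I4e + 2 I4e^(-1/2).
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if J <= 0:
        raise ValueError("det(F) must be positive")
    Fp = np.asarray(Fp, dtype=float)
    try:
        Fpi = np.linalg.inv(Fp)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular plastic gradient") from exc
    Fe = F @ Fpi
    Be = Fe @ Fe.T
    I1e = J ** (-2.0 / 3.0) * np.trace(Be)
    nt = Fp @ np.asarray(n0, dtype=float)
    nt = nt / np.linalg.norm(nt)
    I4e = J ** (-2.0 / 3.0) * float(nt @ (Fe.T @ Fe) @ nt)
    I1ef = I4e + 2.0 / np.sqrt(I4e)
    return float(I1e), float(I4e), float(I1ef)


def total_fiber_invariant(F: np.ndarray, n0: np.ndarray) -> float:
    """Total isochoric I4 (drives the tension switch)."""
    J = np.linalg.det(F)
    v = F @ np.asarray(n0, dtype=float)
    return float(J ** (-2.0 / 3.0) * (v @ v))


# ------------------------------------------------------------------ energies

def fibril_energy(I1ef_bar: float, I4e_bar: float, p: LigamentParams) -> float:
    """psi_fb; zero at the reference state (I4e = 1, I1ef = 3)."""
    if I4e_bar <= 0:
        raise ValueError("I4e must be positive")
    return (0.5 * p.mu_o * np.tanh(p.a1 * (I4e_bar - 1.0))
            + p.a2 * np.exp(p.a3 * (I4e_bar - p.I_o)) * (I1ef_bar - 3.0))


def _dfibril_dI4e(I4e: float, p: LigamentParams) -> float:
    I1ef = I4e + 2.0 / np.sqrt(I4e)
    dI1ef = 1.0 - I4e ** (-1.5)
    e = np.exp(p.a3 * (I4e - p.I_o))
    return (0.5 * p.mu_o * p.a1 / np.cosh(p.a1 * (I4e - 1.0)) ** 2
            + p.a2 * p.a3 * e * (I1ef - 3.0) + p.a2 * e * dI1ef)


def fiber_energy(I1e_bar: float, I4e_bar: float, p: LigamentParams) -> float:
    """Fiber level: fibrils + fiber matrix + shear interaction."""
    I1ef = I4e_bar + 2.0 / np.sqrt(I4e_bar)
    return (p.v_fb * fibril_energy(I1ef, I4e_bar, p)
            + p.v_mb * 0.5 * p.mu_fm * (I1ef - 3.0)
            + 0.5 * p.mu_fm * p.chi_fiber * (I1e_bar - I1ef))


def tissue_energy(I1_bar: float, I1e_bar: float, I4e_bar: float, J: float,
                  p: LigamentParams) -> float:
    """Tissue level: fibers + tissue matrix + shear interaction + volumetric."""
    return (p.v_f * fiber_energy(I1e_bar, I4e_bar, p)
            + p.v_m * 0.5 * p.mu_m * (I1_bar - 3.0)
            + 0.5 * p.mu_m * p.chi_tissue * (I1_bar - I1e_bar)
            + 0.5 * p.Ek * (J - 1.0) ** 2)


def ligament_energy(F: np.ndarray, plastic: PlasticState | None = None,
                    pre: PreStrain | None = None,
                    p: LigamentParams | None = None) -> float:
    """Total strain-energy density at motion F (pre-strain composed inside).

    When the total fiber invariant I4 <= 1 the fibril group is frozen at
    its reference value, consistent with the zero fibrillar stress switch.
    """
    p = p or LigamentParams()
    plastic = plastic or PlasticState()
    Ft = F @ prestrain_gradient(pre.alpha0, p.n0, pre.convention) if pre else F
    J = float(np.linalg.det(Ft))
    I1 = J ** (-2.0 / 3.0) * float(np.trace(Ft @ Ft.T))
    I1e, I4e, _ = kinematic_invariants(Ft, plastic.Fp, p.n0)
    if total_fiber_invariant(Ft, p.n0) <= 1.0:
        I4e = 1.0
    return float(tissue_energy(I1, I1e, I4e, J, p))


# -------------------------------------------------------------------- stress

def _dev(t: np.ndarray) -> np.ndarray:
    return t - np.trace(t) / 3.0 * np.eye(3)


def stress_parts(F: np.ndarray, plastic: PlasticState | None = None,
                 pre: PreStrain | None = None,
                 p: LigamentParams | None = None):
    """(sigma_nf, sigma_f): exact Cauchy stress of :func:`ligament_energy`.

    sigma_nf carries the I1/I1e derivatives plus the volumetric term;
    sigma_f carries the I4e derivatives and obeys the tension switch.
    """
    p = p or LigamentParams()
    plastic = plastic or PlasticState()
    Ft = F @ prestrain_gradient(pre.alpha0, p.n0, pre.convention) if pre else F
    Ft = np.asarray(Ft, dtype=float)
    J = float(np.linalg.det(Ft))
    if J <= 0:
        raise ValueError("det(F) must be positive")
    Jm23 = J ** (-2.0 / 3.0)
    Bbar = Jm23 * (Ft @ Ft.T)
    Fpi = np.linalg.inv(plastic.Fp)
    Fe = Ft @ Fpi
    Bebar = Jm23 * (Fe @ Fe.T)
    I1e, I4e, _ = kinematic_invariants(Ft, plastic.Fp, p.n0)

    # constant invariant coefficients
    psi_1 = p.v_m * p.mu_m / 2.0 + p.mu_m * p.chi_tissue / 2.0
    psi_1e = p.v_f * p.mu_fm * p.chi_fiber / 2.0 - p.mu_m * p.chi_tissue / 2.0

    sig_nf = (2.0 / J) * (psi_1 * _dev(Bbar) + psi_1e * _dev(Bebar))
    sig_nf = sig_nf + p.Ek * (J - 1.0) * np.eye(3)

    if total_fiber_invariant(Ft, p.n0) <= 1.0:
        return sig_nf, np.zeros((3, 3))

    dI1ef = 1.0 - I4e ** (-1.5)
    psi_4e = p.v_f * (p.v_fb * _dfibril_dI4e(I4e, p)
                      + p.v_mb * 0.5 * p.mu_fm * dI1ef
                      - 0.5 * p.mu_fm * p.chi_fiber * dI1ef)
    nt = plastic.Fp @ p.n0
    nt = nt / np.linalg.norm(nt)
    w = J ** (-1.0 / 3.0) * (Fe @ nt)       # |w|^2 = I4e
    sig_f = (2.0 / J) * psi_4e * _dev(np.outer(w, w))
    return sig_nf, sig_f


def total_stress(F: np.ndarray, plastic: PlasticState | None = None,
                 pre: PreStrain | None = None,
                 p: LigamentParams | None = None) -> np.ndarray:
    """sigma_t = sigma_nf + sigma_f."""
    nf, fb = stress_parts(F, plastic, pre, p)
    return nf + fb


def uniaxial_stress(lam: float, p: LigamentParams | None = None,
                    pre: PreStrain | None = None,
                    plastic: PlasticState | None = None,
                    full: bool = False):
    """Axial Cauchy stress under stretch ``lam`` along the fiber with
    traction-free lateral faces (transverse stretch solved numerically)."""
    p = p or LigamentParams()

    def lateral(lt):
        F = np.diag([lam, lt, lt])
        return total_stress(F, plastic, pre, p)[1, 1]

    lo, hi = 0.4, 1.6
    flo, fhi = lateral(lo), lateral(hi)
    while flo * fhi > 0 and hi < 4.0:
        lo *= 0.8
        hi *= 1.2
        flo, fhi = lateral(lo), lateral(hi)
    lt = brentq(lateral, lo, hi, xtol=1e-12)
    F = np.diag([lam, lt, lt])
    sig = total_stress(F, plastic, pre, p)
    if full:
        return float(sig[0, 0]), F
    return float(sig[0, 0])


# ---------------------------------------------------------------- plasticity

def plastic_update(state: PlasticState, trial_fibril_stress: float,
                   yield_curve: StressStrainCurve, tol: float = 1e-8,
                   elastic_modulus: float = 1000.0,
                   n0=np.array([1.0, 0.0, 0.0]),
                   max_iter: int = 100) -> PlasticState:
    """Return-mapping on the single fiber-aligned slip system.

    The yield stress is read from the MD-derived hardening curve at the
    accumulated slip; an elastic step leaves the state unchanged.  At
    return the KKT conditions hold: slip increment >= 0, consistency
    |f| <= tol, and their product vanishes.
    """
    y = float(np.interp(state.accumulated_slip, yield_curve.strain,
                        yield_curve.stress))
    f = trial_fibril_stress - y
    if f <= tol:
        return PlasticState(state.Fp.copy(), state.accumulated_slip, False)

    def consistency(dg):
        yy = float(np.interp(state.accumulated_slip + dg, yield_curve.strain,
                             yield_curve.stress))
        return trial_fibril_stress - elastic_modulus * dg - yy

    hi = f / elastic_modulus
    it = 0
    while consistency(hi) > 0:
        hi *= 2.0
        it += 1
        if it > max_iter:
            raise RuntimeError(
                f"plastic return mapping failed to bracket; residual "
                f"{consistency(hi):.3g}")
    dg = brentq(consistency, 0.0, hi, xtol=tol, maxiter=max_iter)
    n = np.asarray(n0, dtype=float)
    n = n / np.linalg.norm(n)
    lam_p = float(n @ state.Fp @ n) * np.exp(dg)
    return PlasticState(plastic_gradient(lam_p, n),
                        state.accumulated_slip + dg, True)


def uniaxial_elastoplastic_cycle(strain_path, yield_curve: StressStrainCurve,
                                 elastic_modulus: float = 1000.0,
                                 tol: float = 1e-10):
    """1-D strain-driven elastoplastic loop (small-strain kinematics).

    Returns (stress array, plastic-strain array); tension-only yield.
    """
    eps_p = 0.0
    slip = 0.0
    state = PlasticState()
    stresses, plastics = [], []
    for eps in strain_path:
        trial = elastic_modulus * (eps - eps_p)
        if trial > 0:
            new = plastic_update(state, trial, yield_curve, tol=tol,
                                 elastic_modulus=elastic_modulus)
            dg = new.accumulated_slip - state.accumulated_slip
            eps_p += dg
            slip += dg
            state = new
        stresses.append(elastic_modulus * (eps - eps_p))
        plastics.append(eps_p)
    return np.asarray(stresses), np.asarray(plastics)


# --------------------------------------------------------------- calibration

_CALIBRATABLE = ("mu_o", "I_o", "a1", "a2", "a3", "mu_m", "mu_fm",
                 "chi_tissue", "chi_fiber", "Ek")


def calibrate_aggregate(target_curve: StressStrainCurve,
                        base: LigamentParams | None = None,
                        free: tuple = ("mu_o", "a2"),
                        pre: PreStrain | None = None):
    """Least-squares fit of the uniaxial model response over ``free``.

    Fibril parameters fixed from MD stay out of ``free``.  Returns
    (params, residual RMS, residual trace per evaluation).  An
    unidentifiable subset (flat or degenerate Jacobian) triggers a warning
    with the condition number.
    """
    base = base or LigamentParams()
    if not free:
        return base, 0.0, []
    for name in free:
        if name not in _CALIBRATABLE:
            raise ValueError(f"unknown calibratable parameter {name!r}")
    lams = 1.0 + np.asarray(target_curve.strain, dtype=float)
    target = np.asarray(target_curve.stress, dtype=float)
    trace = []

    def residuals(x):
        trial = replace(base, **{k: float(v) for k, v in zip(free, x)})
        out = np.array([uniaxial_stress(l, trial, pre) for l in lams])
        r = out - target
        trace.append(float(np.sqrt(np.mean(r ** 2))))
        return r

    x0 = np.array([0.8 * getattr(base, k) + 1e-3 for k in free])
    sol = least_squares(residuals, x0, bounds=(1e-6, np.inf),
                        xtol=1e-12, ftol=1e-12)
    sv = np.linalg.svd(sol.jac, compute_uv=False)
    cond = sv[0] / max(sv[-1], 1e-300)
    if cond > 1e8:
        warnings.warn(
            f"calibration subset may be unidentifiable: Jacobian condition "
            f"number {cond:.2e}", RuntimeWarning)
    fitted = replace(base, **{k: float(v) for k, v in zip(free, sol.x)})
    return fitted, float(np.sqrt(np.mean(sol.fun ** 2))), trace
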