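"""Fibril-reinforced incompressible hyperelastic cartilage with
depth-dependent composition and energy-limiter fibril softening.

The Cauchy stress splits into tension-only collagen-fibril bundles and an
isotropic non-fibrillar matrix,

    sigma_c = sum_i v_f(i) sigma_fl(i) + (1 - v_t) sigma_nf,

with the intact fibril law sigma_f = (eta0s(z)/J) (E0 eps + E_eps eps^2)
n (x) n in the logarithmic fiber strain eps = ln(stretch), softened by an
energy limiter Phi: sigma_fl = sigma_f exp(-(W_fl/Phi)^m), where W_fl is
the intact fibril strain energy.  The softened energy is the incomplete-
gamma form psi = (Phi/m) [Gamma(1/m) - Gamma(1/m, (W_fl/Phi)^m)], whose
derivative w.r.t. W_fl is exactly the attenuation factor.

Depth z is measured from the cartilage-bone junction and normalized to
[0, 1] (z = 1 at the articular surface).  Composition profiles:
v_t(z) = 1.4 z^2 - 1.1 z + 0.59, eta0s(z) = 0.1 z + 0.1; each of the two
primary bundles carries v_t * 3/13 and each of the seven secondary bundles
v_t * 1/13 (weights sum to v_t).  Primary fibrils rotate from
bone-perpendicular at z = 0 to surface-parallel at z = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gamma as gamma_fn
from scipy.special import gammainc

from .curve import StressStrainCurve

_PRIMARY_WEIGHT = 3.0 / 13.0
_SECONDARY_WEIGHT = 1.0 / 13.0


@dataclass
class CartilageParams:
    """Material constants; the shipped values are MD-fit/literature defaults."""

    E0: float = 8.121          # MPa, initial collagen coefficient
    Ee: float = 5326.32        # MPa, strain-dependent collagen coefficient
    phi: float = 82.326        # energy limiter (same units as W_fl, MPa)
    m: float = 12.0            # softening sharpness
    Gm: float = 0.723          # MPa, matrix shear modulus
    D: float = 1e-4            # incompressibility penalty
    vt_poly: tuple = (1.4, -1.1, 0.59)   # v_t(z) quadratic, high power first
    eta_poly: tuple = (0.1, 0.1)         # eta0s(z) linear, high power first

    def __post_init__(self) -> None:
        if min(self.E0, self.Ee, self.phi, self.Gm, self.D) <= 0:
            raise ValueError("moduli, Phi and D must be positive")
        if self.m < 1:
            raise ValueError("m must be >= 1")


@dataclass
class DeformationState:
    """Deformation gradient and its determinant."""

    F: np.ndarray
    J: float = field(init=False)

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float).reshape(3, 3)
        self.J = float(np.linalg.det(self.F))
        if self.J <= 0:
            raise ValueError("det(F) must be positive")


@dataclass
class FibrilBundleSet:
    """Unit fibril directions with their kind at one normalized depth."""

    directions: np.ndarray       # (n, 3) unit vectors
    kinds: list                  # 'primary' | 'secondary'
    z: float


def depth_profiles(z: float, p: CartilageParams = None):
    """(v_t, eta0s, v_f primary-per-bundle, v_f secondary-per-bundle) at z."""
    if not 0.0 <= z <= 1.0:
        raise ValueError("normalized depth z must lie in [0, 1]")
    p = p or CartilageParams()
    vt = np.polyval(p.vt_poly, z)
    eta = np.polyval(p.eta_poly, z)
    return vt, eta, vt * _PRIMARY_WEIGHT, vt * _SECONDARY_WEIGHT


_SECONDARY_DIRS = np.array([
    [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0],
    [1.0, 1.0, 1.0], [1.0, -1.0, 1.0], [-1.0, 1.0, 1.0], [-1.0, -1.0, 1.0],
])
_SECONDARY_DIRS = _SECONDARY_DIRS / np.linalg.norm(_SECONDARY_DIRS, axis=1,
                                                   keepdims=True)


def default_bundles(z: float) -> FibrilBundleSet:
    """Two primary + seven secondary bundles at depth z.

    Primary directions lie in the (e1,e3) and (e2,e3) planes, tilted from
    the depth axis e3 (bone-perpendicular, z=0) to the surface plane
    (z=1); the tilt interpolates linearly in z.
    """
    if not 0.0 <= z <= 1.0:
        raise ValueError("normalized depth z must lie in [0, 1]")
    ang = z * np.pi / 2.0
    prim = np.array([
        [np.sin(ang), 0.0, np.cos(ang)],
        [0.0, np.sin(ang), np.cos(ang)],
    ])
    dirs = np.vstack([prim, _SECONDARY_DIRS])
    kinds = ["primary"] * 2 + ["secondary"] * 7
    return FibrilBundleSet(dirs, kinds, z)


# --------------------------------------------------------------- fibril laws

def fiber_kinematics(F: np.ndarray, n0: np.ndarray):
    """(log strain, current unit direction) of a fibril with reference
    direction n0 under deformation gradient F."""
    v = F @ n0
    lam = float(np.linalg.norm(v))
    return np.log(lam), v / lam


def fibril_stress_intact(eps_f: float, z: float, dirn: np.ndarray, J: float,
                         p: CartilageParams) -> np.ndarray:
    """Intact (unsoftened) tension-only fibril Cauchy stress tensor."""
    if eps_f <= 0.0:
        return np.zeros((3, 3))
    _, eta, _, _ = depth_profiles(z, p)
    mag = eta / J * (p.E0 * eps_f + p.Ee * eps_f ** 2)
    d = np.asarray(dirn, dtype=float)
    return mag * np.outer(d, d)


def fibril_energy(eps_f: float, z: float, p: CartilageParams) -> float:
    """Intact fibril strain energy W_fl (axial integral of the fibril law
    at J = 1); zero in compression."""
    if eps_f <= 0.0:
        return 0.0
    _, eta, _, _ = depth_profiles(z, p)
    return eta * (p.E0 * eps_f ** 2 / 2.0 + p.Ee * eps_f ** 3 / 3.0)


def attenuation(W_fl, p: CartilageParams):
    """Energy-limiter factor exp(-(W_fl/Phi)^m)."""
    return np.exp(-np.power(np.asarray(W_fl, dtype=float) / p.phi, p.m))


def softened_fibril_stress(eps_f: float, z: float, dirn: np.ndarray, J: float,
                           p: CartilageParams) -> np.ndarray:
    """Fibril stress with energy-limiter softening."""
    if eps_f <= 0.0:
        return np.zeros((3, 3))
    w = fibril_energy(eps_f, z, p)
    return fibril_stress_intact(eps_f, z, dirn, J, p) * attenuation(w, p)


def softened_energy(W_fl, p: CartilageParams):
    """Limited strain energy psi(Phi, W_fl); saturates at (Phi/m) Gamma(1/m).

    d psi / d W_fl = exp(-(W_fl/Phi)^m), so differentiating recovers the
    softened stress from the intact one.
    """
    W_fl = np.asarray(W_fl, dtype=float)
    if np.any(W_fl < 0):
        raise ValueError("W_fl must be non-negative")
    s = 1.0 / p.m
    x = np.power(W_fl / p.phi, p.m)
    return (p.phi / p.m) * gamma_fn(s) * gammainc(s, x)


def softened_energy_saturation(p: CartilageParams) -> float:
    return (p.phi / p.m) * gamma_fn(1.0 / p.m)


# ------------------------------------------------------------------- matrix

def _isochoric_B(F: np.ndarray):
    J = float(np.linalg.det(F))
    return J, (J ** (-2.0 / 3.0)) * (F @ F.T)


def nonfibrillar_energy(state: DeformationState, z: float,
                        p: CartilageParams) -> float:
    """Compressible neo-Hookean matrix energy
    W_nf = eta0s(z) Gm/2 (I1_bar - 3) + (1/D)(J - 1)^2."""
    _, eta, _, _ = depth_profiles(z, p)
    J, Bbar = _isochoric_B(state.F)
    return eta * p.Gm / 2.0 * (np.trace(Bbar) - 3.0) + (J - 1.0) ** 2 / p.D


def nonfibrillar_stress(state: DeformationState, z: float,
                        p: CartilageParams) -> np.ndarray:
    """Exact Cauchy stress of the matrix energy:
    eta0s Gm/J dev(B_bar) + (2/D)(J-1) I."""
    _, eta, _, _ = depth_profiles(z, p)
    J, Bbar = _isochoric_B(state.F)
    dev = Bbar - np.trace(Bbar) / 3.0 * np.eye(3)
    return eta * p.Gm / J * dev + 2.0 / p.D * (J - 1.0) * np.eye(3)


# -------------------------------------------------------------- assembly

def total_cauchy_stress(state: DeformationState, z: float,
                        bundles: FibrilBundleSet | None = None,
                        p: CartilageParams = None) -> np.ndarray:
    """sigma_c = sum_i v_f(i) sigma_fl(i) + (1 - v_t) sigma_nf."""
    p = p or CartilageParams()
    bundles = bundles or default_bundles(z)
    vt, _, vf_p, vf_s = depth_profiles(z, p)
    sig = (1.0 - vt) * nonfibrillar_stress(state, z, p)
    for d, kind in zip(bundles.directions, bundles.kinds):
        eps, cur = fiber_kinematics(state.F, d)
        vf = vf_p if kind == "primary" else vf_s
        sig = sig + vf * softened_fibril_stress(eps, z, cur, state.J, p)
    return sig


def total_energy(state: DeformationState, z: float,
                 bundles: FibrilBundleSet | None = None,
                 p: CartilageParams = None) -> float:
    """Strain energy whose F-derivative is :func:`total_cauchy_stress`."""
    p = p or CartilageParams()
    bundles = bundles or default_bundles(z)
    vt, _, vf_p, vf_s = depth_profiles(z, p)
    W = (1.0 - vt) * nonfibrillar_energy(state, z, p)
    for d, kind in zip(bundles.directions, bundles.kinds):
        eps, _ = fiber_kinematics(state.F, d)
        vf = vf_p if kind == "primary" else vf_s
        if eps > 0.0:
            W += vf * float(softened_energy(fibril_energy(eps, z, p), p))
    return float(W)


# ------------------------------------------------------------------ fitting

@dataclass
class FibrilFit:
    E0: float
    Ee: float
    residual: float


def fit_fibril_params_to_md(curve: StressStrainCurve | None = None,
                            scale: float = 0.70,
                            phi: float | None = None,
                            m: float | None = None) -> FibrilFit:
    """Fit the axial fibril law to the pre-peak portion of an MD curve.

    The target is ``scale`` times the MD stress (the 70% default encodes
    the collagen II vs collagen I stiffness reduction).  With ``phi``/``m``
    omitted the intact quadratic law is fitted by linear least squares (so
    scaling the target scales the coefficients exactly); providing them
    switches to a nonlinear fit of the softened law.  With no curve the
    shipped defaults are returned.
    """
    if curve is None:
        d = CartilageParams()
        return FibrilFit(d.E0, d.Ee, 0.0)
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must lie in (0, 1]")
    pre = curve.prepeak()
    sel = pre.strain > 0
    eps = pre.strain[sel]
    sig = scale * pre.stress[sel]
    if eps.size < 3:
        raise ValueError("need at least 3 positive pre-peak samples")
    A = np.stack([eps, eps ** 2], axis=1)
    coef, res, *_ = np.linalg.lstsq(A, sig, rcond=None)
    if phi is None:
        r = sig - A @ coef
        return FibrilFit(float(coef[0]), float(coef[1]),
                         float(np.sqrt(np.mean(r ** 2))))
    m = 12.0 if m is None else m

    def model(c):
        w = c[0] * eps ** 2 / 2.0 + c[1] * eps ** 3 / 3.0
        return (c[0] * eps + c[1] * eps ** 2) * np.exp(-(w / phi) ** m)

    sol = least_squares(lambda c: model(c) - sig, x0=np.maximum(coef, 1e-6),
                        method="lm")
    r = sol.fun
    return FibrilFit(float(sol.x[0]), float(sol.x[1]),
                     float(np.sqrt(np.mean(r ** 2))))


# ------------------------------------------------------------------- damage

def damage_indicator(eps_f_history, p: CartilageParams = None,
                     z: float = 1.0) -> np.ndarray:
    """Energy-limiter damage indicator per bundle.

    ``eps_f_history`` is (T,) or (T, n_bundles) of log fibril strains; the
    indicator is 1 - exp(-(max W_fl over the history / Phi)^m), i.e. one
    minus the worst attenuation experienced.
    """
    p = p or CartilageParams()
    h = np.asarray(eps_f_history, dtype=float)
    if h.size == 0:
        raise ValueError("empty strain history")
    if h.ndim == 1:
        h = h[:, None]
    wmax = np.zeros(h.shape[1])
    for j in range(h.shape[1]):
        wmax[j] = max(fibril_energy(float(e), z, p) for e in h[:, j])
    return 1.0 - attenuation(wmax, p)


def damage_flag(eps_f_history, p: CartilageParams = None, z: float = 1.0,
                threshold: float = 0.05) -> bool:
    """True when any bundle's indicator exceeds the threshold."""
    return bool(np.any(damage_indicator(eps_f_history, p, z) > threshold))
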