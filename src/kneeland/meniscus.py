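"""Transversely isotropic linear-elastic meniscus.

Local axes: 1, 2 span the (isotropic) transverse-axial plane and 3 is the
circumferential fiber direction.  Voigt ordering is (11, 22, 33, 12, 13,
23) with engineering shear strains; a single shear modulus G fills all
three shear slots.  The compliance couples the circumferential direction
to the transverse plane through nu_ta/Ec and the transverse plane to
itself through nu_ct/Et; the matrix is symmetrized by elastic reciprocity
and checked for positive definiteness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VOIGT_ORDER = ("11", "22", "33", "12", "13", "23")


@dataclass
class MeniscusParams:
    """Defaults are the meniscus aggregate literature values."""

    Ec: float = 120.0     # MPa circumferential modulus
    Et: float = 20.0      # MPa transverse modulus (= axial)
    nu_ct: float = 0.3    # circumferential <-> transverse Poisson ratio
    nu_ta: float = 0.2    # in-plane (transverse-axial) Poisson ratio
    G: float = 47.0       # MPa shear modulus (all shear slots)
    local_axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    @property
    def Ea(self) -> float:
        return self.Et

    @property
    def nu_ca(self) -> float:
        return self.nu_ct

    def __post_init__(self) -> None:
        self.local_axes = np.asarray(self.local_axes, dtype=float)
        if min(self.Ec, self.Et, self.G) <= 0:
            raise ValueError("moduli must be positive")
        R = self.local_axes
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-10):
            raise ValueError("local_axes must be orthonormal")


def compliance_matrix(p: MeniscusParams | None = None) -> np.ndarray:
    """6x6 compliance in local axes (engineering shears)."""
    p = p or MeniscusParams()
    S = np.zeros((6, 6))
    S[0, 0] = S[1, 1] = 1.0 / p.Et
    S[2, 2] = 1.0 / p.Ec
    S[0, 1] = S[1, 0] = -p.nu_ct / p.Et
    S[0, 2] = S[2, 0] = -p.nu_ta / p.Ec
    S[1, 2] = S[2, 1] = -p.nu_ta / p.Ec
    S[3, 3] = S[4, 4] = S[5, 5] = 1.0 / p.G
    for k in range(1, 7):
        if np.linalg.det(S[:k, :k]) <= 0:
            raise ValueError(
                f"compliance not positive definite: leading minor of order "
                f"{k} is non-positive")
    return S


def stiffness_matrix(p: MeniscusParams | None = None) -> np.ndarray:
    return np.linalg.inv(compliance_matrix(p))


def _voigt_to_tensor(v, shear_factor: float = 1.0) -> np.ndarray:
    t = np.array([[v[0], v[3] / shear_factor, v[4] / shear_factor],
                  [v[3] / shear_factor, v[1], v[5] / shear_factor],
                  [v[4] / shear_factor, v[5] / shear_factor, v[2]]])
    return t


def _tensor_to_voigt(t, shear_factor: float = 1.0) -> np.ndarray:
    return np.array([t[0, 0], t[1, 1], t[2, 2],
                     shear_factor * t[0, 1], shear_factor * t[0, 2],
                     shear_factor * t[1, 2]])


def stress_to_strain(sigma, p: MeniscusParams | None = None,
                     frame: str = "local") -> np.ndarray:
    """Strain (engineering shears) from a stress 6-vector.

    ``frame='global'`` rotates the stress into local axes first and the
    strain back out.
    """
    p = p or MeniscusParams()
    sigma = np.asarray(sigma, dtype=float)
    S = compliance_matrix(p)
    if frame == "local":
        return S @ sigma
    if frame != "global":
        raise ValueError("frame must be 'local' or 'global'")
    R = p.local_axes
    sig_t = _voigt_to_tensor(sigma)
    sig_local = R @ sig_t @ R.T
    eps_local = S @ _tensor_to_voigt(sig_local)
    eps_t = _voigt_to_tensor(eps_local, shear_factor=2.0)
    eps_glob = R.T @ eps_t @ R
    return _tensor_to_voigt(eps_glob, shear_factor=2.0)


def strain_energy_density(sigma, p: MeniscusParams | None = None) -> float:
    """(1/2) sigma^T S sigma, positive for any nonzero stress."""
    sigma = np.asarray(sigma, dtype=float)
    return 0.5 * float(sigma @ compliance_matrix(p) @ sigma)
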