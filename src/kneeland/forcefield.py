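"""Mesoscopic collagen bead-spring force field.

Three energy terms act on a bead chain: a 12-6 Lennard-Jones potential
between non-bonded beads, a breakable two-regime harmonic bond (soft spring
up to ``r1``, stiff spring up to the rupture distance ``rb``, zero beyond),
and a harmonic bending angle about the straight configuration.

Internal units: length nm, energy kcal/mol, mass amu.  One internal time
unit is sqrt(amu nm^2 / (kcal/mol)) = 0.4889 ps.  A force of
1 (kcal/mol)/nm acting over 1 nm^2 corresponds to 6.9477 MPa, exposed as
:data:`STRESS_MPA_PER_INTERNAL`.

The numeric defaults below are NOT printed in the source study; they are
adapted from the mesoscopic collagen-fibril literature (Buehler-type
parameter sets) and are meant as a self-consistent working set, editable
through :class:`ForceFieldParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: MPa per internal stress unit ((kcal/mol)/nm^3).
STRESS_MPA_PER_INTERNAL = 6.9477

#: ps per internal time unit.
PS_PER_INTERNAL = 0.48888


@dataclass
class ForceFieldParams:
    """Parameters of the bead-spring collagen force field.

    ``c1``/``c2`` (energy continuity constants) and ``r1_bar`` (force
    continuity) are derived, not free inputs: ``r1_bar`` makes the bond
    force continuous at ``r1``, ``c2`` zeroes the energy at the breaking
    distance ``rb`` and ``c1`` makes the energy continuous at ``r1``.
    """

    eps_lj: float = 6.87          # kcal/mol, LJ well depth
    sigma_lj: float = 1.472       # nm, LJ zero-crossing distance
    lj_cutoff: float = 3.68       # nm (2.5 sigma), energy-shifted

    kT0: float = 1713.0           # kcal/mol/nm^2, first bond regime
    kT1: float = 9766.0           # kcal/mol/nm^2, second bond regime
    r0: float = 1.40              # nm, bond rest length
    r1: float = 1.82              # nm, onset of the stiff regime
    rb: float = 2.10              # nm, bond breaking distance

    k_theta: float = 14.98        # kcal/mol/rad^2
    theta0: float = np.pi         # straight chain

    m_bead: float = 1358.7        # amu

    # Crosslink bonds reuse the two-regime form with per-bond rest length
    # equal to the creation distance; these offsets set the stiffening
    # onset and rupture extension of a crosslink.
    xl_dr1: float = 0.12          # nm past rest length
    xl_drb: float = 0.24          # nm past rest length

    # derived, filled in __post_init__
    r1_bar: float = field(default=0.0)
    c1: float = field(default=0.0)
    c2: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not (self.r0 < self.r1 < self.rb):
            raise ValueError("require r0 < r1 < rb")
        if min(self.eps_lj, self.kT0, self.kT1, self.k_theta) <= 0:
            raise ValueError("energy/stiffness constants must be positive")
        # force continuity at r1: kT0 (r1-r0) = kT1 (r1-r1_bar)
        self.r1_bar = self.r1 - self.kT0 * (self.r1 - self.r0) / self.kT1
        # energy zero at rb and continuity at r1
        self.c2 = -0.5 * self.kT1 * (self.rb - self.r1_bar) ** 2
        e_right = 0.5 * self.kT1 * (self.r1 - self.r1_bar) ** 2 + self.c2
        self.c1 = e_right - 0.5 * self.kT0 * (self.r1 - self.r0) ** 2

    @property
    def dt_max(self) -> float:
        """Documented integrator stability heuristic: 0.05 sqrt(m/kT0)."""
        return 0.05 * np.sqrt(self.m_bead / self.kT0)

    def with_rest_length(self, r0: float) -> "ForceFieldParams":
        """Crosslink variant: same stiffnesses, shifted characteristic
        distances (rest at the creation distance)."""
        return replace(
            self,
            r0=r0,
            r1=r0 + self.xl_dr1,
            rb=r0 + self.xl_drb,
        )


def bond_energy_force(r, p: ForceFieldParams):
    """Two-regime breakable bond: energy and scalar force magnitude -dE/dr.

    Vectorized over ``r``.  Beyond ``rb`` both are zero (broken bond); the
    caller is responsible for flagging the break as permanent.
    """
    r = np.asarray(r, dtype=float)
    soft = r < p.r1
    hard = (r >= p.r1) & (r < p.rb)
    e = np.where(
        soft,
        0.5 * p.kT0 * (r - p.r0) ** 2 + p.c1,
        np.where(hard, 0.5 * p.kT1 * (r - p.r1_bar) ** 2 + p.c2, 0.0),
    )
    f = np.where(
        soft,
        -p.kT0 * (r - p.r0),
        np.where(hard, -p.kT1 * (r - p.r1_bar), 0.0),
    )
    return e, f


def lj_energy_force(r, p: ForceFieldParams):
    """12-6 Lennard-Jones, energy-shifted to zero at the cutoff.

    Returns (energy, force magnitude -dE/dr), vectorized over ``r``.
    """
    r = np.asarray(r, dtype=float)
    inside = r < p.lj_cutoff
    rr = np.where(inside, r, p.lj_cutoff)
    s6 = (p.sigma_lj / rr) ** 6
    sc6 = (p.sigma_lj / p.lj_cutoff) ** 6
    e_shift = 4.0 * p.eps_lj * (sc6 * sc6 - sc6)
    e = np.where(inside, 4.0 * p.eps_lj * (s6 * s6 - s6) - e_shift, 0.0)
    f = np.where(inside, 24.0 * p.eps_lj * (2.0 * s6 * s6 - s6) / rr, 0.0)
    return e, f


def angle_energy(theta, p: ForceFieldParams):
    """Harmonic bending energy K_theta (theta - theta0)^2."""
    theta = np.asarray(theta, dtype=float)
    return p.k_theta * (theta - p.theta0) ** 2


def angle_energy_forces(ri, rj, rk, p: ForceFieldParams):
    """Energy and per-bead forces of one angle triple (j is the vertex).

    Returns (E, Fi, Fj, Fk) with Fi = -dE/dri etc.  Near the straight
    configuration (theta -> theta0 = pi) the (theta-theta0)/sin(theta)
    ratio is finite; sin(theta) is floored to keep it numerically safe.
    """
    a = ri - rj
    b = rk - rj
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    cos_t = np.clip(a.dot(b) / (na * nb), -1.0, 1.0)
    theta = np.arccos(cos_t)
    e = p.k_theta * (theta - p.theta0) ** 2
    sin_t = max(np.sqrt(1.0 - cos_t * cos_t), 1e-9)
    # dE/dtheta, and dtheta/dcos = -1/sin
    pref = 2.0 * p.k_theta * (theta - p.theta0) / sin_t
    dcos_da = b / (na * nb) - cos_t * a / (na * na)
    dcos_db = a / (na * nb) - cos_t * b / (nb * nb)
    fi = pref * dcos_da
    fk = pref * dcos_db
    fj = -(fi + fk)
    return e, fi, fj, fk
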