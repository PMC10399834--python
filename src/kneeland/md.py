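"""Molecular dynamics for the coarse-grained fibril.

Velocity-Verlet integration (optionally with a BAOAB Langevin thermostat),
a KD-tree Verlet neighbor list for the Lennard-Jones term, permanently
breakable two-regime bonds, and a constant-strain-rate tensile test that
reports engineering stress (boundary reaction force over the initial
fibril cross-section).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .curve import StressStrainCurve
from .fibril import Fibril, Molecule
from .forcefield import (STRESS_MPA_PER_INTERNAL, ForceFieldParams,
                         angle_energy)


@dataclass
class SimulationState:
    """Bead positions/velocities plus the (mutable) bonded topology.

    ``bond_*`` arrays cover backbone bonds first, then crosslinks; broken
    bonds stay flagged forever and are excluded from force evaluation, and
    angles sharing a broken backbone bond are deactivated.
    """

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    bond_idx: np.ndarray              # (B, 2)
    bond_r0: np.ndarray
    bond_r1: np.ndarray
    bond_r1_bar: np.ndarray
    bond_rb: np.ndarray
    bond_kT0: np.ndarray
    bond_kT1: np.ndarray
    bond_c1: np.ndarray
    bond_c2: np.ndarray
    broken: np.ndarray                # (B,) bool
    angle_idx: np.ndarray             # (A, 3)
    angle_active: np.ndarray          # (A,) bool
    angle_bond: np.ndarray            # (A, 2) -> bond rows of the two legs
    excluded: np.ndarray              # sorted pair keys i*N+j, i<j
    time: float = 0.0
    thermostat_target: float = 0.0
    # neighbor-list cache
    _nl_pairs: np.ndarray = field(default=None, repr=False)
    _nl_ref: np.ndarray = field(default=None, repr=False)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def broken_bonds(self) -> set:
        return set(np.flatnonzero(self.broken).tolist())

    def copy(self) -> "SimulationState":
        s = SimulationState(
            self.positions.copy(), self.velocities.copy(), self.masses,
            self.bond_idx, self.bond_r0, self.bond_r1, self.bond_r1_bar,
            self.bond_rb, self.bond_kT0, self.bond_kT1, self.bond_c1,
            self.bond_c2, self.broken.copy(), self.angle_idx,
            self.angle_active.copy(), self.angle_bond, self.excluded,
            self.time, self.thermostat_target)
        return s


def _bond_constants(ff: ForceFieldParams, r0_arr: np.ndarray):
    r1 = r0_arr + (ff.r1 - ff.r0)
    rb = r0_arr + (ff.rb - ff.r0)
    r1_bar = r1 - ff.kT0 * (r1 - r0_arr) / ff.kT1
    c2 = -0.5 * ff.kT1 * (rb - r1_bar) ** 2
    c1 = 0.5 * ff.kT1 * (r1 - r1_bar) ** 2 + c2 - 0.5 * ff.kT0 * (r1 - r0_arr) ** 2
    return r1, r1_bar, rb, c1, c2


def make_state(obj, ff: ForceFieldParams,
               velocities: np.ndarray | None = None) -> SimulationState:
    """Build a simulation state from a :class:`Fibril` or :class:`Molecule`."""
    if isinstance(obj, Molecule):
        positions = obj.bead_positions.copy()
        bonds = obj.bonds
        angles = obj.angles
        xl = np.empty((0, 2), dtype=int)
        xl_rest = np.empty(0)
    elif isinstance(obj, Fibril):
        positions = obj.positions.copy()
        bonds = obj.bonds
        angles = obj.angles
        xl = obj.crosslinks
        xl_rest = obj.crosslink_rest
    else:
        raise TypeError("expected Molecule or Fibril")

    n = len(positions)
    nb = len(bonds)
    bond_idx = np.concatenate([bonds, xl]) if len(xl) else np.array(bonds)
    r0 = np.concatenate([np.full(nb, ff.r0), xl_rest])
    # backbone uses ff distances verbatim; crosslinks get the xl offsets
    r1 = np.concatenate([np.full(nb, ff.r1), xl_rest + ff.xl_dr1])
    rb = np.concatenate([np.full(nb, ff.rb), xl_rest + ff.xl_drb])
    r1_bar = r1 - ff.kT0 * (r1 - r0) / ff.kT1
    c2 = -0.5 * ff.kT1 * (rb - r1_bar) ** 2
    c1 = 0.5 * ff.kT1 * (r1 - r1_bar) ** 2 + c2 - 0.5 * ff.kT0 * (r1 - r0) ** 2

    # LJ exclusions: bonded (1-2, incl. crosslinks) and angle 1-3 pairs
    pairs = [bond_idx]
    if len(angles):
        pairs.append(angles[:, [0, 2]])
    pairs = np.concatenate(pairs)
    lo = np.minimum(pairs[:, 0], pairs[:, 1])
    hi = np.maximum(pairs[:, 0], pairs[:, 1])
    excluded = np.unique(lo.astype(np.int64) * n + hi)

    # angle -> backbone bond rows (consecutive beads, so rows are i and i+1
    # in the per-molecule bond numbering; recover via a lookup)
    bond_row = {}
    for row, (a, b) in enumerate(bonds):
        bond_row[(int(a), int(b))] = row
    angle_bond = np.zeros((len(angles), 2), dtype=int)
    for k, (a, b, c) in enumerate(angles):
        angle_bond[k, 0] = bond_row[(int(a), int(b))]
        angle_bond[k, 1] = bond_row[(int(b), int(c))]

    vel = np.zeros_like(positions) if velocities is None else velocities.copy()
    return SimulationState(
        positions=positions, velocities=vel,
        masses=np.full(n, ff.m_bead),
        bond_idx=bond_idx, bond_r0=r0, bond_r1=r1, bond_r1_bar=r1_bar,
        bond_rb=rb, bond_kT0=np.full(len(r0), ff.kT0),
        bond_kT1=np.full(len(r0), ff.kT1), bond_c1=c1, bond_c2=c2,
        broken=np.zeros(len(r0), dtype=bool),
        angle_idx=np.asarray(angles, dtype=int).reshape(-1, 3),
        angle_active=np.ones(len(angles), dtype=bool),
        angle_bond=angle_bond, excluded=excluded)


def _neighbor_pairs(state: SimulationState, cutoff: float, skin: float):
    """Verlet list: rebuild when any bead moved more than skin/2."""
    pos = state.positions
    if (state._nl_pairs is None or state._nl_ref is None or
            len(state._nl_ref) != len(pos) or
            (np.abs(pos - state._nl_ref).max() > skin / 2.0)):
        tree = cKDTree(pos)
        cand = tree.query_pairs(r=cutoff + skin, output_type="ndarray")
        if len(cand):
            keys = cand[:, 0].astype(np.int64) * len(pos) + cand[:, 1]
            cand = cand[~np.isin(keys, state.excluded)]
        state._nl_pairs = cand
        state._nl_ref = pos.copy()
    return state._nl_pairs


def compute_forces(state: SimulationState, ff: ForceFieldParams,
                   break_bonds: bool = True):
    """Forces and potential energy; flags newly broken bonds permanently.

    Returns (forces (N,3), potential energy, energy breakdown dict).
    """
    pos = state.positions
    forces = np.zeros_like(pos)

    # --- bonds (piecewise two-regime, breakable) ---
    alive = ~state.broken
    bi = state.bond_idx[alive]
    dr = pos[bi[:, 1]] - pos[bi[:, 0]]
    r = np.linalg.norm(dr, axis=1)
    if break_bonds:
        newly = r >= state.bond_rb[alive]
        if newly.any():
            rows = np.flatnonzero(alive)[newly]
            state.broken[rows] = True
            # deactivate angles whose legs include a broken backbone bond
            if len(state.angle_bond):
                bad = np.isin(state.angle_bond, rows).any(axis=1)
                state.angle_active[bad] = False
            alive = ~state.broken
            bi = state.bond_idx[alive]
            dr = pos[bi[:, 1]] - pos[bi[:, 0]]
            r = np.linalg.norm(dr, axis=1)
    r0 = state.bond_r0[alive]
    r1 = state.bond_r1[alive]
    r1b = state.bond_r1_bar[alive]
    rb = state.bond_rb[alive]
    soft = r < r1
    hard = (r >= r1) & (r < rb)
    kT0 = state.bond_kT0[alive]
    kT1 = state.bond_kT1[alive]
    e_bond = np.where(soft, 0.5 * kT0 * (r - r0) ** 2 + state.bond_c1[alive],
                      np.where(hard,
                               0.5 * kT1 * (r - r1b) ** 2 + state.bond_c2[alive],
                               0.0))
    fmag = np.where(soft, -kT0 * (r - r0), np.where(hard, -kT1 * (r - r1b), 0.0))
    unit = dr / np.maximum(r, 1e-12)[:, None]
    fvec = fmag[:, None] * unit                     # force on bead j
    np.add.at(forces, bi[:, 1], fvec)
    np.add.at(forces, bi[:, 0], -fvec)
    E_bond = float(e_bond.sum())

    # --- Lennard-Jones (shifted, cutoff) on the neighbor list ---
    E_lj = 0.0
    pairs = _neighbor_pairs(state, ff.lj_cutoff, skin=0.4)
    if len(pairs):
        dp = pos[pairs[:, 1]] - pos[pairs[:, 0]]
        rr = np.linalg.norm(dp, axis=1)
        inside = rr < ff.lj_cutoff
        if inside.any():
            p2 = pairs[inside]
            rr = rr[inside]
            dp = dp[inside]
            s6 = (ff.sigma_lj / rr) ** 6
            sc6 = (ff.sigma_lj / ff.lj_cutoff) ** 6
            e = 4.0 * ff.eps_lj * (s6 * s6 - s6) - 4.0 * ff.eps_lj * (sc6 * sc6 - sc6)
            fm = 24.0 * ff.eps_lj * (2.0 * s6 * s6 - s6) / rr
            fv = (fm / rr)[:, None] * dp            # on bead j, along +dp
            np.add.at(forces, p2[:, 1], fv)
            np.add.at(forces, p2[:, 0], -fv)
            E_lj = float(e.sum())

    # --- angles (vectorized three-body harmonic) ---
    E_angle = 0.0
    act = state.angle_active
    if act.any():
        tri = state.angle_idx[act]
        a = pos[tri[:, 0]] - pos[tri[:, 1]]
        b = pos[tri[:, 2]] - pos[tri[:, 1]]
        na = np.linalg.norm(a, axis=1)
        nb_ = np.linalg.norm(b, axis=1)
        cos_t = np.clip(np.einsum("ij,ij->i", a, b) / (na * nb_), -1.0, 1.0)
        theta = np.arccos(cos_t)
        E_angle = float(angle_energy(theta, ff).sum())
        sin_t = np.maximum(np.sqrt(1.0 - cos_t ** 2), 1e-9)
        pref = 2.0 * ff.k_theta * (theta - ff.theta0) / sin_t
        dcos_da = b / (na * nb_)[:, None] - (cos_t / na ** 2)[:, None] * a
        dcos_db = a / (na * nb_)[:, None] - (cos_t / nb_ ** 2)[:, None] * b
        fi = pref[:, None] * dcos_da
        fk = pref[:, None] * dcos_db
        np.add.at(forces, tri[:, 0], fi)
        np.add.at(forces, tri[:, 2], fk)
        np.add.at(forces, tri[:, 1], -(fi + fk))

    E = E_bond + E_lj + E_angle
    return forces, E, {"bond": E_bond, "lj": E_lj, "angle": E_angle}


def kinetic_energy(state: SimulationState) -> float:
    return 0.5 * float(np.sum(state.masses[:, None] * state.velocities ** 2))


def integrate(state: SimulationState, ff: ForceFieldParams, dt: float,
              n_steps: int, thermostat: str = "none", seed: int = 0,
              gamma: float = 1.0, kBT: float = 0.2,
              frozen: np.ndarray | None = None,
              frozen_velocity: np.ndarray | None = None,
              sample_every: int = 0):
    """Advance ``n_steps`` of velocity Verlet (BAOAB when Langevin).

    ``frozen`` beads follow ``frozen_velocity`` (default: held fixed) and
    feel no forces.  Returns (state, trace) where trace maps
    time/potential/kinetic arrays sampled every ``sample_every`` steps
    (empty arrays when 0).  Raises on numerical blow-up.
    """
    if thermostat not in ("none", "langevin"):
        raise ValueError("thermostat must be 'none' or 'langevin'")
    if dt > ff.dt_max:
        raise ValueError(
            f"dt={dt} exceeds the stability heuristic 0.05*sqrt(m/kT0)="
            f"{ff.dt_max:.4g}")
    state = state.copy()
    rng = np.random.default_rng(seed)
    n = state.n_beads
    if frozen is None:
        frozen = np.zeros(n, dtype=bool)
    free = ~frozen
    if frozen_velocity is None:
        frozen_velocity = np.zeros((n, 3))
    state.velocities[frozen] = frozen_velocity[frozen]
    m = state.masses[:, None]
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(1.0 - c1 * c1, 0.0) * kBT)
    state.thermostat_target = kBT if thermostat == "langevin" else 0.0

    F, E, _ = compute_forces(state, ff)
    times, e_pot, e_kin = [], [], []

    def sample(step):
        if sample_every and step % sample_every == 0:
            times.append(state.time)
            e_pot.append(E)
            e_kin.append(kinetic_energy(state))

    sample(0)
    for step in range(1, n_steps + 1):
        v = state.velocities
        v[free] += 0.5 * dt * F[free] / m[free]
        if thermostat == "langevin":
            state.positions[free] += 0.5 * dt * v[free]
            v[free] = c1 * v[free] + c2 / np.sqrt(m[free]) * rng.standard_normal(
                (int(free.sum()), 3))
            state.positions[free] += 0.5 * dt * v[free]
        else:
            state.positions[free] += dt * v[free]
        state.positions[frozen] += dt * frozen_velocity[frozen]
        F, E, _ = compute_forces(state, ff)
        v[free] += 0.5 * dt * F[free] / m[free]
        state.time += dt
        if not np.isfinite(state.positions).all():
            raise RuntimeError(
                f"numerical blow-up at step {step} (t={state.time:.4g}); "
                f"reduce dt (stability bound {ff.dt_max:.4g})")
        sample(step)

    trace = {"time": np.array(times), "potential": np.array(e_pot),
             "kinetic": np.array(e_kin)}
    return state, trace


def tensile_test(fibril: Fibril, ff: ForceFieldParams,
                 strain_rate: float = 1e-3, max_strain: float = 0.06,
                 dt: float = 0.02, seed: int = 0,
                 kBT: float = 0.05, gamma: float = 0.5,
                 n_equil: int = 400, n_levels: int = 10,
                 hold_tu: float = 15.0, n_clamp: int = 2) -> StressStrainCurve:
    """Staircase quasi-static fibril pull.

    Each lattice track is clamped over its first and last ``n_clamp``
    beads.  The right clamp ramps at engineering strain rate
    ``strain_rate`` to each of ``n_levels`` uniformly spaced strain
    levels, then holds at rest for ``hold_tu`` internal time units while
    the thermostat damps the ramp transient; the stress sample is the
    boundary reaction force averaged over the second half of the hold,
    divided by the initial cross-section area pi (d/2)^2 (engineering
    stress, MPa).  Measuring at rest removes the thermostat-drag bias a
    continuous pull would add to the boundary force.  On numerical
    blow-up the partial curve is returned (flagged in ``meta``).
    """
    if max_strain > 1.0:
        raise ValueError("max_strain must be <= 1")
    state = make_state(fibril, ff)
    n = state.n_beads

    left = np.zeros(n, dtype=bool)
    right = np.zeros(n, dtype=bool)
    n_axial = fibril.n_molecules // fibril.n_cross_section
    for s in range(fibril.n_cross_section):
        first_mol = s * n_axial
        last_mol = first_mol + n_axial - 1
        e0 = fibril.end_bead_ids[first_mol][0]
        e1 = fibril.end_bead_ids[last_mol][1]
        left[e0:e0 + n_clamp] = True
        right[e1 - n_clamp + 1:e1 + 1] = True
    frozen = left | right
    free = ~frozen

    x_left = state.positions[left, 0].mean()
    x_right = state.positions[right, 0].mean()
    L0 = x_right - x_left
    area = np.pi * (fibril.diameter / 2.0) ** 2

    state, _ = integrate(state, ff, dt, n_equil, thermostat="langevin",
                         seed=seed, gamma=gamma, kBT=kBT, frozen=frozen)

    rng = np.random.default_rng(seed + 1)
    m = state.masses[:, None]
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(1.0 - c1 * c1, 0.0) * kBT)
    nfree = int(free.sum())
    F = compute_forces(state, ff)[0]
    aborted = False

    def advance(n_steps: int, clamp_vx: float, collect: bool = False):
        """BAOAB steps with the right clamp moving at clamp_vx; optionally
        collect boundary-tension samples."""
        nonlocal F, aborted
        samples = []
        for _ in range(n_steps):
            v = state.velocities
            v[free] += 0.5 * dt * F[free] / m[free]
            state.positions[free] += 0.5 * dt * v[free]
            v[free] = c1 * v[free] + c2 / np.sqrt(m[free]) * \
                rng.standard_normal((nfree, 3))
            state.positions[free] += 0.5 * dt * v[free]
            if clamp_vx:
                state.positions[right, 0] += dt * clamp_vx
            F = compute_forces(state, ff)[0]
            v[free] += 0.5 * dt * F[free] / m[free]
            state.time += dt
            if not np.isfinite(state.positions).all():
                aborted = True
                return samples
            if collect:
                samples.append(-float(F[right, 0].sum()))
        return samples

    levels = np.linspace(0.0, max_strain, n_levels + 1)
    hold_steps = max(int(round(hold_tu / dt)), 2)
    clamp_vx = strain_rate * L0
    strains, stresses = [0.0], []
    s0 = advance(hold_steps, 0.0, collect=True)
    stresses.append(float(np.mean(s0[len(s0) // 2:])) / area
                    * STRESS_MPA_PER_INTERNAL if s0 else 0.0)
    for prev, lvl in zip(levels[:-1], levels[1:]):
        if aborted:
            break
        ramp_steps = max(int(round((lvl - prev) / (strain_rate * dt))), 1)
        advance(ramp_steps, clamp_vx)
        if aborted:
            break
        samples = advance(hold_steps, 0.0, collect=True)
        if not samples:
            break
        strains.append(float(lvl))
        stresses.append(float(np.mean(samples[len(samples) // 2:]))
                        / area * STRESS_MPA_PER_INTERNAL)

    meta = {"protocol": "staircase quasi-static clamp pull",
            "strain_rate": strain_rate, "dt": dt, "kBT": kBT,
            "gamma": gamma, "hold_tu": hold_tu,
            "beta": fibril.beta, "seed": seed, "aborted": aborted,
            "n_broken_bonds": int(state.broken.sum())}
    k = min(len(strains), len(stresses))
    return StressStrainCurve(np.asarray(strains[:k]), np.asarray(stresses[:k]),
                             meta)
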