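"""Desk-scale surrogate pipeline: landing height -> critical cartilage damage.

The chain is: height -> regression landing profile -> static muscle-force
optimization -> tibiofemoral axial load -> elastic-foundation contact on a
two-compartment toy geometry -> depth-resolved fibril-reinforced cartilage
evaluation -> energy-limiter damage indicator -> iterative critical-height
search with a coarse-to-fine refinement schedule (20/10/5/1 cm).

The full finite-element knee is deliberately replaced by an elastic
foundation (local pressure = k * penetration / thickness), so absolute
contact magnitudes are surrogate-level; load shares between compartments
and between the covered (cartilage-cartilage) and uncovered
(cartilage-meniscus) regions are configurable mimics of the FE trends
(medial share grows with height and crosses 50% above 40 cm; the meniscus /
uncovered pathway carries about 39%).

The per-node deformation state is a laterally free isochoric axial
compression: the foundation penetration sets the through-thickness stretch
lambda_z = 1 - delta/t and incompressibility gives the lateral stretch
lambda_r = lambda_z^(-1/2), which is what stretches the surface-parallel
superficial fibrils and lets damage initiate at the articular surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import brentq

from . import cartilage as cart
from . import muscles, regression, synthetic

G_ACCEL = 9.80665


@dataclass
class PipelineConfig:
    body_mass_kg: float = 66.2
    foundation_modulus_mpa: float = 15.0
    grid_n: int = 16
    thickness_mm: float = 2.5
    condyle_radius_mm: float = 35.0
    half_width_mm: float = 12.0
    uncovered_area_fraction: float = 0.45
    # load sharing
    medial_share_at_40: float = 0.50
    medial_share_slope_per_cm: float = 0.0025
    medial_share_limits: tuple = (0.30, 0.70)
    uncovered_force_share: float = 0.39
    # damage
    damage_threshold: float = 0.05
    z_depths: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    max_penetration_fraction: float = 0.95
    # search
    start_height_cm: float = 100.0
    schedule_cm: tuple = (20, 10, 5, 1)
    max_height_cm: float = 300.0
    # fixtures
    msk_seed: int = 0
    n_muscles: int = 34
    cartilage: cart.CartilageParams = field(default_factory=cart.CartilageParams)

    def medial_share(self, height_cm: float) -> float:
        s = (self.medial_share_at_40
             + self.medial_share_slope_per_cm * (height_cm - 40.0))
        return float(np.clip(s, *self.medial_share_limits))

    def geometry(self) -> synthetic.ToyArticularGeometry:
        return synthetic.gen_toy_articular_geometry(
            grid_n=self.grid_n, thickness_mm=self.thickness_mm,
            condyle_radius_mm=self.condyle_radius_mm,
            half_width_mm=self.half_width_mm,
            uncovered_fraction=self.uncovered_area_fraction)

    def musculoskeleton(self) -> synthetic.ToyMusculoskeleton:
        return synthetic.gen_toy_musculoskeleton(
            n_dof=3, n_muscles=self.n_muscles, seed=self.msk_seed)

    def to_yaml(self, path) -> None:
        d = {k: getattr(self, k) for k in (
            "body_mass_kg", "foundation_modulus_mpa", "grid_n",
            "thickness_mm", "condyle_radius_mm", "half_width_mm",
            "uncovered_area_fraction", "medial_share_at_40",
            "medial_share_slope_per_cm", "uncovered_force_share",
            "damage_threshold", "start_height_cm", "max_height_cm",
            "msk_seed", "n_muscles")}
        d["schedule_cm"] = list(self.schedule_cm)
        d["medial_share_limits"] = list(self.medial_share_limits)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "schedule_cm" in d:
            d["schedule_cm"] = tuple(d["schedule_cm"])
        if "medial_share_limits" in d:
            d["medial_share_limits"] = tuple(d["medial_share_limits"])
        return cls(**d)


# ----------------------------------------------------------------- axial load

def joint_axial_load(solution: muscles.MuscleSolution,
                     profile: regression.LandingProfile,
                     axial_components: np.ndarray,
                     body_mass_kg: float = 66.2) -> float:
    """Axial compressive joint force in body weights: the vertical GRF plus
    the axial components of the optimized muscle forces."""
    bw = body_mass_kg * G_ACCEL
    muscle_n = float(np.dot(axial_components, solution.forces))
    return float(profile.sagittal["vgrf"]) + muscle_n / bw


# -------------------------------------------------------------------- contact

@dataclass
class ContactResult:
    pressures: dict               # compartment -> (n_nodes,) MPa
    compartment_forces_bw: dict   # compartment -> BW
    region_forces_bw: dict        # (compartment, region) -> BW
    contact_area_mm2: float
    peak_pressure_mpa: float
    peak_location: tuple          # (compartment, node index)
    load_bw: float
    foundation_modulus_mpa: float


def _solve_region(x, y, t, area, target_n, k, rc_mm, max_frac):
    """Rigid sphere-on-foundation equilibrium over one node subset.

    Gaps grow quadratically away from the region's innermost node; the
    apex penetration d is solved so the integrated pressure balances the
    target load.  Returns nodal pressures in MPa (areas mm^2, forces N).
    """
    r = np.hypot(x, y)
    gap = (r ** 2 - r.min() ** 2) / (2.0 * rc_mm)

    def net(d):
        pen = np.clip(d - gap, 0.0, None)
        return float(np.sum(k * pen / t * area)) - target_n

    d_cap = max_frac * t.max() + gap.max()
    if net(d_cap) < 0.0:
        raise ValueError(
            "load exceeds the elastic-foundation capacity of this region; "
            "use a finer/larger grid or a stiffer foundation")
    d = 0.0 if target_n <= 0 else brentq(net, 0.0, d_cap, xtol=1e-12)
    pen = np.clip(d - gap, 0.0, None)
    if np.any(pen > max_frac * t):
        raise ValueError(
            "foundation penetration exceeded the allowed fraction of the "
            "cartilage thickness; use a finer grid or larger contact area")
    return k * pen / t


def contact_solve(load_bw: float, geometry: synthetic.ToyArticularGeometry,
                  config: PipelineConfig, height_cm: float | None = None,
                  medial_share: float | None = None) -> ContactResult:
    """Distribute the axial load over compartments and covered/uncovered
    regions, then solve each region's foundation equilibrium."""
    if load_bw < 0:
        raise ValueError("load must be non-negative")
    if medial_share is None:
        medial_share = config.medial_share(
            height_cm if height_cm is not None else 40.0)
    bw_n = config.body_mass_kg * G_ACCEL
    total_n = load_bw * bw_n
    k = config.foundation_modulus_mpa
    shares = {
        ("medial", "covered"): medial_share * (1 - config.uncovered_force_share),
        ("medial", "uncovered"): medial_share * config.uncovered_force_share,
        ("lateral", "covered"): (1 - medial_share) * (
            1 - config.uncovered_force_share),
        ("lateral", "uncovered"): (1 - medial_share) *
        config.uncovered_force_share,
    }
    pressures = {}
    region_forces = {}
    for comp_name, grid in geometry.compartments.items():
        p = np.zeros(grid.n_nodes)
        for region in ("covered", "uncovered"):
            sel = grid.region == region
            target = shares[(comp_name, region)] * total_n
            if not sel.any():
                if target > 0:
                    raise ValueError(f"region {region} empty in {comp_name}")
                continue
            p[sel] = _solve_region(
                grid.x_mm[sel], grid.y_mm[sel], grid.thickness_mm[sel],
                grid.area_mm2[sel], target, k, geometry.condyle_radius_mm,
                config.max_penetration_fraction)
            region_forces[(comp_name, region)] = float(
                np.sum(p[sel] * grid.area_mm2[sel])) / bw_n
        pressures[comp_name] = p
    comp_forces = {
        c: float(np.sum(pressures[c] * geometry.compartments[c].area_mm2)) / bw_n
        for c in pressures}
    area = float(sum(
        geometry.compartments[c].area_mm2[pressures[c] > 0].sum()
        for c in pressures))
    peak, loc = 0.0, ("medial", 0)
    for c, p in pressures.items():
        if p.size and p.max() > peak:
            peak = float(p.max())
            loc = (c, int(np.argmax(p)))
    return ContactResult(pressures, comp_forces, region_forces, area, peak,
                         loc, load_bw, k)


# --------------------------------------------------------------- tissue field

@dataclass
class TissueField:
    """Per-node, per-depth cartilage response."""

    sigma_zz_mpa: dict    # compartment -> (n_nodes, n_z)
    damage: dict          # compartment -> (n_nodes, n_z)
    fiber_strain: dict    # compartment -> (n_nodes, n_z) max tensile eps_f
    z_depths: np.ndarray

    @property
    def max_damage(self) -> float:
        return max((float(d.max()) if d.size else 0.0)
                   for d in self.damage.values())


def tissue_stress_field(contact: ContactResult,
                        geometry: synthetic.ToyArticularGeometry,
                        params: cart.CartilageParams | None = None,
                        z_depths=(0.0, 0.25, 0.5, 0.75, 1.0)) -> TissueField:
    """Convert nodal pressures to local deformation states and evaluate the
    cartilage model at each depth station.

    Foundation kinematics set the axial stretch (lambda_z = 1 - p/k) and
    incompressibility the lateral stretch; each fibril bundle's log strain,
    energy-limiter damage indicator and the axial Cauchy stress are
    evaluated per node and depth (vectorized over nodes).
    """
    params = params or cart.CartilageParams()
    zs = np.asarray(z_depths, dtype=float)
    k = contact.foundation_modulus_mpa
    sig_out, dmg_out, str_out = {}, {}, {}
    for comp_name, grid in geometry.compartments.items():
        p = contact.pressures[comp_name]
        lam_z = 1.0 - p / k
        lam_r = lam_z ** -0.5
        n_nodes = grid.n_nodes
        sig = np.zeros((n_nodes, len(zs)))
        dmg = np.zeros((n_nodes, len(zs)))
        fstr = np.zeros((n_nodes, len(zs)))
        for iz, z in enumerate(zs):
            vt, eta, vf_p, vf_s = cart.depth_profiles(z, params)
            bundles = cart.default_bundles(z)
            # matrix axial stress (J = 1)
            trB = 2.0 * lam_r ** 2 + lam_z ** 2
            sig_nf_zz = eta * params.Gm * (lam_z ** 2 - trB / 3.0)
            s_zz = (1.0 - vt) * sig_nf_zz
            wmax = np.zeros(n_nodes)
            emax = np.zeros(n_nodes)
            for d, kind in zip(bundles.directions, bundles.kinds):
                lam_f = np.sqrt((lam_r * d[0]) ** 2 + (lam_r * d[1]) ** 2
                                + (lam_z * d[2]) ** 2)
                eps = np.log(lam_f)
                tens = eps > 0
                w = np.where(tens, eta * (params.E0 * eps ** 2 / 2.0
                                          + params.Ee * eps ** 3 / 3.0), 0.0)
                mag = np.where(
                    tens,
                    eta * (params.E0 * eps + params.Ee * eps ** 2)
                    * cart.attenuation(w, params), 0.0)
                nz2 = (lam_z * d[2]) ** 2 / np.maximum(lam_f ** 2, 1e-12)
                vf = vf_p if kind == "primary" else vf_s
                s_zz = s_zz + vf * mag * nz2
                wmax = np.maximum(wmax, w)
                emax = np.maximum(emax, np.where(tens, eps, 0.0))
            sig[:, iz] = s_zz
            dmg[:, iz] = 1.0 - cart.attenuation(wmax, params)
            fstr[:, iz] = emax
        sig_out[comp_name] = sig
        dmg_out[comp_name] = dmg
        str_out[comp_name] = fstr
    return TissueField(sig_out, dmg_out, str_out, zs)


# ------------------------------------------------------------------ one pass

@dataclass
class HeightEvaluation:
    height_cm: float
    profile: regression.LandingProfile
    solution: muscles.MuscleSolution
    joint_load_bw: float
    contact: ContactResult
    tissue: TissueField

    @property
    def damaged(self) -> bool:
        return self.tissue.max_damage > 0.0  # threshold applied by caller


def evaluate_height(height_cm: float,
                    config: PipelineConfig | None = None) -> HeightEvaluation:
    """Run the full chain at one landing height."""
    config = config or PipelineConfig()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        profile = regression.predict_profile(height_cm)
    msk = config.musculoskeleton()
    targets = config.body_mass_kg * np.array([
        profile.sagittal["hip_flex_moment"],
        profile.sagittal["knee_flex_moment"],
        profile.sagittal["ankle_dorsi_moment"]])
    prob = muscles.OptimizationProblem(msk.lever_arms, targets, msk.pcsa,
                                       msk.x_passive, msk.x_max)
    sol = muscles.solve(prob)
    load = joint_axial_load(sol, profile, msk.axial_components,
                            config.body_mass_kg)
    geometry = config.geometry()
    contact = contact_solve(load, geometry, config, height_cm=height_cm)
    tissue = tissue_stress_field(contact, geometry, config.cartilage,
                                 config.z_depths)
    return HeightEvaluation(height_cm, profile, sol, load, contact, tissue)


def damage_scan(height_cm: float,
                config: PipelineConfig | None = None) -> bool:
    """True when any node/depth exceeds the damage threshold at this height."""
    config = config or PipelineConfig()
    if height_cm <= 0:
        raise ValueError("height must be positive")
    ev = evaluate_height(height_cm, config)
    return ev.tissue.max_damage > config.damage_threshold


# --------------------------------------------------------------------- search

@dataclass
class CriticalHeightResult:
    critical_height: int
    search_trace: list                 # (height, damaged) in evaluation order
    damage_map: TissueField | None = None
    n_evaluations: int = 0


def critical_height_search(start_cm: float | None = None,
                           schedule: tuple | None = None,
                           config: PipelineConfig | None = None,
                           damage_fn=None,
                           max_height_cm: float | None = None
                           ) -> CriticalHeightResult:
    """Coarse-to-fine bracketing walk for the first damaged integer height.

    From the start height, step upward by the current increment until the
    damage flag flips on, restart from the last undamaged height with the
    next smaller increment, and return the first damaged height at 1-cm
    resolution.  A start already inside the damaged regime first walks
    down to an undamaged base.  ``damage_fn`` (int cm -> bool) replaces the
    full pipeline when given (used for oracle checks and synthetic damage
    laws).
    """
    config = config or PipelineConfig()
    start = int(round(config.start_height_cm if start_cm is None else start_cm))
    schedule = tuple(int(s) for s in (schedule or config.schedule_cm))
    if any(b >= a for a, b in zip(schedule, schedule[1:])) or schedule[-1] != 1:
        raise ValueError("schedule must be strictly decreasing and end at 1 cm")
    max_h = int(round(max_height_cm if max_height_cm is not None
                      else config.max_height_cm))
    fn = damage_fn or (lambda h: damage_scan(float(h), config))

    cache = {}
    trace = []

    def damaged(h: int) -> bool:
        if h not in cache:
            cache[h] = bool(fn(h))
            trace.append((h, cache[h]))
        return cache[h]

    base = start
    if damaged(start):
        while base > 1 and damaged(base):
            base = max(1, base - schedule[0])
        if damaged(base):      # damaged all the way down to 1 cm
            return CriticalHeightResult(base, trace, None, len(trace))
    for inc in schedule:
        h = base + inc
        while h <= max_h and not damaged(h):
            base = h
            h += inc
        if h > max_h:
            raise RuntimeError(
                f"no damage flip found up to {max_h} cm with the current "
                "configuration")
    critical = base + 1
    dmap = None
    if damage_fn is None:
        dmap = evaluate_height(float(critical), config).tissue
    return CriticalHeightResult(critical, trace, dmap, len(trace))
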