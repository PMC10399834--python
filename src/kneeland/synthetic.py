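"""Synthetic inputs for every stage of the pipeline.

Everything here is generated, seeded and reproducible: literature-style
landing records drawn around the regression mean curves, toy
musculoskeletal fixtures (lever arms, PCSA, bounds) built feasible by
construction, toy two-compartment articular geometry, and noisy fibril
stress-strain curves for fit-recovery studies.

Noise model: sagittal variables get multiplicative Gaussian noise about
the regression mean (the literature violin spreads are roughly symmetric
about it); coupled-plane variables get additive Gaussian noise about
height-independent means.  The coupled means are placeholder fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .curve import StressStrainCurve
from .regression import (DEFAULT_COUPLED_MEANS, DEFAULT_MODELS,
                         SAGITTAL_VARIABLES, evaluate)

# ------------------------------------------------------------ landing records

HEIGHT_LIMITS = (10.0, 200.0)


@dataclass
class LandingRecord:
    """One drop-landing observation at the peak loading instance.

    Angles in degrees, moments in N*m/kg, vertical GRF in body weights,
    height in cm.
    """

    height: float
    hip_flex_angle: float
    knee_flex_angle: float
    ankle_dorsi_angle: float
    hip_flex_moment: float
    knee_flex_moment: float
    ankle_dorsi_moment: float
    vgrf: float
    coupled_planes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = [self.height, self.hip_flex_angle, self.knee_flex_angle,
                self.ankle_dorsi_angle, self.hip_flex_moment,
                self.knee_flex_moment, self.ankle_dorsi_moment, self.vgrf,
                *self.coupled_planes.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite landing record")
        if self.height <= 0 or self.vgrf <= 0:
            raise ValueError("height and vGRF must be positive")


def gen_landing_dataset(heights, n_per_height: int = 1,
                        noise_sd_fraction: float = 0.0, seed: int = 0,
                        coupled_means: dict | None = None) -> list:
    """Seeded landing records around the regression mean curves.

    Sagittal fields: mean(height) * (1 + N(0, noise_sd_fraction));
    coupled fields: mean + N(0, noise_sd_fraction * |mean|).
    """
    heights = np.atleast_1d(np.asarray(heights, dtype=float))
    if np.any(heights < HEIGHT_LIMITS[0]) or np.any(heights > HEIGHT_LIMITS[1]):
        raise ValueError(f"heights must lie within {HEIGHT_LIMITS} cm")
    if n_per_height < 1:
        raise ValueError("n_per_height must be >= 1")
    rng = np.random.default_rng(seed)
    means = dict(coupled_means or DEFAULT_COUPLED_MEANS)
    records = []
    for h in heights:
        for _ in range(n_per_height):
            sag = {}
            for name in SAGITTAL_VARIABLES:
                mu = float(evaluate(DEFAULT_MODELS[name], h))
                sag[name] = mu * (1.0 + noise_sd_fraction * rng.standard_normal())
            coup = {k: v + noise_sd_fraction * abs(v) * rng.standard_normal()
                    for k, v in means.items()}
            records.append(LandingRecord(height=float(h),
                                         coupled_planes=coup, **sag))
    return records


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"height_cm": r.height}
        row.update({f"{k}": getattr(r, k) for k in SAGITTAL_VARIABLES})
        row.update(r.coupled_planes)
        rows.append(row)
    return pd.DataFrame(rows)


def records_to_csv(records, path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def records_from_csv(path) -> list:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        coup = {k: row[k] for k in df.columns
                if k not in SAGITTAL_VARIABLES and k != "height_cm"}
        out.append(LandingRecord(
            height=row["height_cm"], coupled_planes=coup,
            **{k: row[k] for k in SAGITTAL_VARIABLES}))
    return out


# ------------------------------------------------------- musculoskeletal toys

#: 34 lower-limb actuators of the default fixture
DEFAULT_MUSCLE_NAMES = (
    "glut_max1", "glut_max2", "glut_max3", "glut_med1", "glut_med2",
    "glut_med3", "glut_min1", "glut_min2", "glut_min3", "iliacus", "psoas",
    "sartorius", "tensor_fasciae_latae", "rectus_femoris",
    "vastus_lateralis", "vastus_medialis", "vastus_intermedius",
    "semimembranosus", "semitendinosus", "biceps_fem_lh", "biceps_fem_sh",
    "gracilis", "adductor_longus", "adductor_brevis", "adductor_magnus1",
    "adductor_magnus2", "adductor_magnus3", "gastroc_medial",
    "gastroc_lateral", "soleus", "tibialis_anterior", "tibialis_posterior",
    "peroneus_longus", "peroneus_brevis",
)


@dataclass
class ToyMusculoskeleton:
    muscle_names: list
    pcsa: np.ndarray           # cm^2
    lever_arms: np.ndarray     # (n_dof, n_muscles), m
    x_passive: np.ndarray      # N
    x_max: np.ndarray          # N
    ground_truth_forces: np.ndarray | None = None
    axial_components: np.ndarray | None = None   # joint-compression fractions

    def __post_init__(self) -> None:
        if np.any(self.pcsa <= 0):
            raise ValueError("PCSA must be positive")
        if np.any(self.x_passive > self.x_max):
            raise ValueError("x_passive must not exceed x_max")
        if np.any(np.all(self.lever_arms == 0.0, axis=1)):
            raise ValueError("each DoF needs at least one nonzero lever arm")


def gen_toy_musculoskeleton(n_dof: int = 3, n_muscles: int = 34,
                            seed: int = 0,
                            with_ground_truth: bool = False,
                            max_stress_n_per_cm2: float = 60.0
                            ) -> ToyMusculoskeleton:
    """Random feasible static-optimization fixture.

    Lever arms are 2-8 cm with random sign, each muscle spanning one or
    two DoF; when ``with_ground_truth`` the targets implied by
    ``lever_arms @ ground_truth_forces`` are feasible by construction for
    an interior point.
    """
    if not n_muscles >= n_dof >= 1:
        raise ValueError("need n_muscles >= n_dof >= 1")
    rng = np.random.default_rng(seed)
    names = (list(DEFAULT_MUSCLE_NAMES[:n_muscles])
             if n_muscles <= len(DEFAULT_MUSCLE_NAMES)
             else [f"muscle_{i}" for i in range(n_muscles)])
    pcsa = rng.uniform(3.0, 40.0, n_muscles)
    R = np.zeros((n_dof, n_muscles))
    for j in range(n_muscles):
        spanned = rng.choice(n_dof, size=min(n_dof, rng.integers(1, 3)),
                             replace=False)
        R[spanned, j] = rng.uniform(0.02, 0.08, len(spanned)) * rng.choice(
            [-1.0, 1.0], len(spanned))
    for d in range(n_dof):               # every DoF actuated both ways
        if not np.any(R[d] > 0):
            R[d, rng.integers(0, n_muscles)] = rng.uniform(0.02, 0.08)
        if not np.any(R[d] < 0):
            R[d, rng.integers(0, n_muscles)] = -rng.uniform(0.02, 0.08)
    x_passive = rng.uniform(0.0, 15.0, n_muscles)
    x_max = x_passive + pcsa * max_stress_n_per_cm2
    gt = None
    if with_ground_truth:
        gt = x_passive + rng.uniform(0.2, 0.6, n_muscles) * (x_max - x_passive)
    axial = rng.uniform(0.4, 0.8, n_muscles)
    return ToyMusculoskeleton(names, pcsa, R, x_passive, x_max, gt, axial)


# -------------------------------------------------------- fibril fit fixtures

def gen_synthetic_fibril_curve(E0_true: float, Ee_true: float,
                               phi_true: float = 1e9, m_true: float = 12.0,
                               noise_sd: float = 0.0, n_points: int = 40,
                               seed: int = 0,
                               max_strain: float = 0.12) -> StressStrainCurve:
    """Sample the softened axial fibril law with known parameters.

    A very large ``phi_true`` reproduces the intact quadratic law (the
    energy-limiter limit); noise is additive Gaussian on the stress.
    """
    if n_points < 10:
        raise ValueError("need at least 10 samples")
    rng = np.random.default_rng(seed)
    eps = np.linspace(0.0, max_strain, n_points)
    w = E0_true * eps ** 2 / 2.0 + Ee_true * eps ** 3 / 3.0
    sig = (E0_true * eps + Ee_true * eps ** 2) * np.exp(-(w / phi_true) ** m_true)
    sig = sig + noise_sd * rng.standard_normal(n_points)
    sig[0] = 0.0
    return StressStrainCurve(eps, sig, {
        "generator": "synthetic softened fibril law",
        "E0": E0_true, "Ee": Ee_true, "phi": phi_true, "m": m_true,
        "noise_sd": noise_sd, "seed": seed})


# ------------------------------------------------------------- toy geometry

@dataclass
class CompartmentGrid:
    """Square surface grid of one tibial compartment."""

    x_mm: np.ndarray          # (n,) node coordinates
    y_mm: np.ndarray
    thickness_mm: np.ndarray
    area_mm2: np.ndarray      # tributary node areas
    region: np.ndarray        # 'covered' (cartilage-cartilage) | 'uncovered'
    z_depths: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.25, 0.5, 0.75, 1.0]))

    @property
    def n_nodes(self) -> int:
        return len(self.x_mm)

    @property
    def r_mm(self) -> np.ndarray:
        return np.hypot(self.x_mm, self.y_mm)


@dataclass
class ToyArticularGeometry:
    medial: CompartmentGrid
    lateral: CompartmentGrid
    condyle_radius_mm: float

    @property
    def compartments(self) -> dict:
        return {"medial": self.medial, "lateral": self.lateral}


def gen_toy_articular_geometry(grid_n: int = 16, thickness_mm: float = 2.5,
                               condyle_radius_mm: float = 35.0,
                               half_width_mm: float = 12.0,
                               uncovered_fraction: float = 0.45,
                               seed: int = 0) -> ToyArticularGeometry:
    """Two convex-on-flat compartment grids with covered/uncovered labels.

    The central disc (nearest the condyle apex) is the covered
    cartilage-cartilage region; the outer ring (area fraction
    ``uncovered_fraction``) is the uncovered cartilage-meniscus region.
    Depth is sampled at five normalized stations from bone (z=0) to
    surface (z=1).
    """
    if grid_n < 4:
        raise ValueError("grid_n must be >= 4")
    if not 0.0 <= uncovered_fraction <= 1.0:
        raise ValueError("uncovered_fraction must lie in [0, 1]")

    def one() -> CompartmentGrid:
        g = np.linspace(-half_width_mm, half_width_mm, grid_n)
        X, Y = np.meshgrid(g, g)
        x, y = X.ravel(), Y.ravel()
        r = np.hypot(x, y)
        if uncovered_fraction == 0.0:
            region = np.full(x.shape, "covered", dtype=object)
        elif uncovered_fraction == 1.0:
            region = np.full(x.shape, "uncovered", dtype=object)
        else:
            cut = np.quantile(r, 1.0 - uncovered_fraction)
            region = np.where(r <= cut, "covered", "uncovered").astype(object)
        da = (g[1] - g[0]) ** 2
        return CompartmentGrid(x, y, np.full(x.shape, float(thickness_mm)),
                               np.full(x.shape, da), region)

    return ToyArticularGeometry(one(), one(), float(condyle_radius_mm))


# ----------------------------------------------------------------- config IO

def generator_config_to_yaml(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def generator_config_from_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
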