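"""Nonlinear landing-height regression models and landing profiles.

Sagittal-plane lower-limb kinematics/kinetics and vertical ground reaction
force at the peak loading instance of a drop landing are modeled as
power (y = a x^b), natural-log (y = a ln x + b) or exponential
(y = a e^(bx)) functions of the drop height x in cm.  The shipped
coefficient table covers seven variables (three joint angles in degrees,
three body-mass-normalized joint moments in N*m/kg, and the vertical GRF
in body weights; the height unit and the moment/GRF normalizations are
adopted conventions, as the source table prints none).

Coupled-plane (frontal/transversal) quantities depend only weakly on
height and are carried as height-independent means.  The shipped means are
placeholder fixtures - the literature values are shown only in violin
plots and never tabulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

FORMS = ("power", "log", "exp")

#: default validity range of the regressions (cm)
HEIGHT_RANGE = (10.0, 150.0)
#: measurements behind the fits stop here; beyond is extrapolation
MEASURED_MAX = 60.0


@dataclass
class RegressionModel:
    form: str
    a: float
    b: float
    variable_name: str = ""
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}")
        if self.r_squared is not None and not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")


#: shipped coefficient table: variable -> (form, a, b, published R^2)
DEFAULT_MODELS = {
    "hip_flex_angle": RegressionModel("power", 3.3896, 0.557,
                                      "hip_flex_angle", 0.9418),
    "knee_flex_angle": RegressionModel("log", 14.769, -15.237,
                                       "knee_flex_angle", 0.9082),
    "ankle_dorsi_angle": RegressionModel("exp", 8.1108, 0.0068,
                                         "ankle_dorsi_angle", 0.9811),
    "hip_flex_moment": RegressionModel("power", 0.0096, 0.7563,
                                       "hip_flex_moment", 0.9486),
    "knee_flex_moment": RegressionModel("power", 0.0699, 0.3704,
                                        "knee_flex_moment", 0.9129),
    "ankle_dorsi_moment": RegressionModel("log", 0.1086, -0.2315,
                                          "ankle_dorsi_moment", 0.9187),
    "vgrf": RegressionModel("power", 0.4468, 0.542, "vgrf", 0.9463),
}

SAGITTAL_VARIABLES = tuple(DEFAULT_MODELS)

#: placeholder height-independent coupled-plane means
DEFAULT_COUPLED_MEANS = {
    "hip_add_angle": 6.0, "hip_rot_angle": 5.0,
    "knee_abd_angle": 4.5, "knee_rot_angle": 6.5,
    "ankle_ev_angle": 4.0,
    "hip_add_moment": 0.45, "knee_abd_moment": 0.40,
    "ankle_ev_moment": 0.15,
}


def evaluate(model: RegressionModel, height: float):
    """Model value at a drop height in cm (vectorized over height)."""
    x = np.asarray(height, dtype=float)
    if np.any(x <= 0):
        raise ValueError("height must be positive")
    if model.form == "power":
        return model.a * x ** model.b
    if model.form == "log":
        return model.a * np.log(x) + model.b
    return model.a * np.exp(model.b * x)


def _r_squared(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res < 1e-12 else 0.0
    return 1.0 - ss_res / ss_tot


def fit(records, form: str, variable_name: str = "") -> RegressionModel:
    """Nonlinear least squares with a log-linearized initializer.

    ``records`` is an iterable of (height, value) pairs; at least three
    distinct heights are required.
    """
    data = np.asarray(list(records), dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("records must be (height, value) pairs")
    x, y = data[:, 0], data[:, 1]
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct heights")
    if np.any(x <= 0):
        raise ValueError("heights must be positive")
    if form == "log":
        A = np.stack([np.log(x), np.ones_like(x)], axis=1)
        (a, b), *_ = np.linalg.lstsq(A, y, rcond=None)
        model = RegressionModel("log", float(a), float(b), variable_name)
        model.r_squared = max(0.0, min(1.0, _r_squared(y, evaluate(model, x))))
        return model
    if form not in FORMS:
        raise ValueError(f"unknown form {form!r}")
    # linearized initializer needs positive values; fall back when it can't
    pos = y > 0
    if pos.sum() >= 2:
        ly = np.log(y[pos])
        lx = np.log(x[pos]) if form == "power" else x[pos]
        A = np.stack([lx, np.ones_like(lx)], axis=1)
        (b0, la0), *_ = np.linalg.lstsq(A, ly, rcond=None)
        p0 = (float(np.exp(la0)), float(b0))
    else:
        p0 = (1.0, 0.1)
    fn = ((lambda xx, a, b: a * xx ** b) if form == "power"
          else (lambda xx, a, b: a * np.exp(b * xx)))
    try:
        with warnings.catch_warnings():
            # degenerate (e.g. constant) data makes the covariance singular
            warnings.simplefilter("ignore")
            (a, b), _ = curve_fit(fn, x, y, p0=p0, maxfev=20000)
    except RuntimeError:
        a, b = p0
    model = RegressionModel(form, float(a), float(b), variable_name)
    model.r_squared = max(0.0, min(1.0, _r_squared(y, evaluate(model, x))))
    return model


def select_best_form(records, variable_name: str = ""):
    """Fit all three forms; return (best model, {form: R^2}).

    Ties within 1e-12 break deterministically power > log > exp.
    """
    fits = {f: fit(records, f, variable_name) for f in FORMS}
    scores = {f: fits[f].r_squared for f in FORMS}
    best = max(FORMS, key=lambda f: (scores[f], -FORMS.index(f)))
    for f in FORMS:       # explicit deterministic tie-break
        if scores[f] >= scores[best] - 1e-12:
            best = f
            break
    return fits[best], scores


@dataclass
class LandingProfile:
    """Complete per-height driver set: regressed sagittal values plus
    height-independent coupled-plane means."""

    height: float
    sagittal: dict
    coupled: dict

    def __post_init__(self) -> None:
        missing = set(SAGITTAL_VARIABLES) - set(self.sagittal)
        if missing:
            raise ValueError(f"profile missing sagittal variables {missing}")


def predict_profile(height: float, coupled_means: dict | None = None,
                    models: dict | None = None) -> LandingProfile:
    """All seven sagittal regressions evaluated at ``height`` (cm).

    Heights beyond the measured range (60 cm) or the configured validity
    window trigger an extrapolation warning, not an error - the headline
    supra-physiological analyses are themselves extrapolations.
    """
    if height <= 0:
        raise ValueError("height must be positive")
    models = models or DEFAULT_MODELS
    if height > MEASURED_MAX or not (
            HEIGHT_RANGE[0] <= height <= HEIGHT_RANGE[1]):
        warnings.warn(
            f"height {height:g} cm is outside the measured range "
            f"(<= {MEASURED_MAX:g} cm); regression values are extrapolated",
            UserWarning, stacklevel=2)
    sag = {k: float(evaluate(m, height)) for k, m in models.items()}
    return LandingProfile(height, sag,
                          dict(coupled_means or DEFAULT_COUPLED_MEANS))


def models_to_frame(models: dict | None = None) -> pd.DataFrame:
    """Coefficient table (variable, form, a, b, R^2) as a DataFrame."""
    models = models or DEFAULT_MODELS
    return pd.DataFrame(
        [{"variable": k, "form": m.form, "a": m.a, "b": m.b,
          "r_squared": m.r_squared} for k, m in models.items()])
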