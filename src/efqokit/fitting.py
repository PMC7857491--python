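"""Downstream model fits: Michaelis–Menten, IC50, pH and thermal profiles.

All fits are scikit-learn-style estimators (``fit(x, y)`` → fitted
attributes with trailing underscores, ``predict(x)``) built on
deterministically initialized nonlinear least squares
(:func:`scipy.optimize.curve_fit`).  Thin module-level functions return
plain result dataclasses for scripting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import FitError

__all__ = [
    "MMFit", "DoseResponseFit", "ProfileEstimate",
    "MichaelisMentenRegressor", "FourParamLogistic",
    "GaussianProfile", "ThermalDecline",
    "fit_mm", "fit_4pl", "estimate_ph_optimum", "estimate_thermal_midpoint",
    "relative_inhibition",
]


@dataclass
class MMFit:
    Km: float
    Vmax: float
    Km_stderr: float
    Vmax_stderr: float
    r_squared: float
    n_points: int


@dataclass
class DoseResponseFit:
    ic50: float
    hill: float
    top: float
    bottom: float
    ic50_stderr: float
    hill_stderr: float
    r_squared: float
    n_doses: int

    def predict(self, dose):
        dose = np.asarray(dose, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (dose / self.ic50) ** self.hill
        )


@dataclass
class ProfileEstimate:
    optimum: float
    params: dict
    method: str                   # "fit" or "argmax"
    uncertainty: float | None
    boundary_flag: bool
    r_squared: float | None = None


def _x1d(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError("expected a 1-D array (or a single-column 2-D array)")
    return x


def _r_squared(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


class MichaelisMentenRegressor(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares fit of rate = Vmax·S/(Km+S).

    Initialization is deterministic: Vmax₀ = max observed rate, Km₀ = the
    substrate concentration at half-maximal rate (linearly interpolated).
    Requires ≥ 4 distinct substrate concentrations spanning a ≥ 4-fold
    range.
    """

    @staticmethod
    def _model(S, Vmax, Km):
        return Vmax * S / (Km + S)

    def fit(self, X, y):
        S = _x1d(X)
        rate = np.asarray(y, dtype=float).reshape(-1)
        if len(S) != len(rate):
            raise ValueError("S and rate must have equal length")
        distinct = np.unique(S[S > 0])
        if len(distinct) < 4:
            raise ValueError("Michaelis-Menten fit needs >= 4 distinct S0 values")
        if distinct.max() / distinct.min() < 4:
            raise ValueError("S0 values must span at least a 4-fold range")
        vmax0 = float(np.max(rate))
        if vmax0 <= 0:
            raise FitError("all rates are non-positive; nothing to fit")
        order = np.argsort(S)
        km0 = float(np.interp(vmax0 / 2.0, rate[order], S[order]))
        km0 = max(km0, distinct.min() / 10.0)
        try:
            popt, pcov = curve_fit(
                self._model, S, rate, p0=[vmax0, km0],
                bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000,
            )
        except RuntimeError as exc:
            raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
        self.Vmax_, self.Km_ = map(float, popt)
        perr = np.sqrt(np.diag(pcov))
        self.Vmax_stderr_, self.Km_stderr_ = map(float, perr)
        self.r_squared_ = _r_squared(rate, self._model(S, *popt))
        self.n_points_ = len(S)
        return self

    def predict(self, X):
        return self._model(_x1d(X), self.Vmax_, self.Km_)

    def to_result(self) -> MMFit:
        return MMFit(self.Km_, self.Vmax_, self.Km_stderr_, self.Vmax_stderr_,
                     self.r_squared_, self.n_points_)


class FourParamLogistic(BaseEstimator, RegressorMixin):
    """Four-parameter logistic dose–response with IC50.

    Model: a(d) = bottom + (top − bottom) / (1 + (d/IC50)^h), fitted by
    least squares with the Hill slope bounded to ``hill_bounds`` (default
    (0.2, 5)).  Zero doses anchor the top: they are included with dose
    replaced by a value 100× below the smallest nonzero dose.  A response
    whose spread is below ``flat_tol`` × |mean| (or absolutely tiny) makes
    the IC50 undefined and raises :class:`FitError`.
    """

    def __init__(self, hill_bounds: tuple = (0.2, 5.0), flat_tol: float = 1e-3):
        self.hill_bounds = hill_bounds
        self.flat_tol = flat_tol

    @staticmethod
    def _model(logd, log_ic50, hill, top, bottom):
        return bottom + (top - bottom) / (1.0 + np.exp(hill * (logd - log_ic50)))

    def fit(self, X, y):
        dose = _x1d(X)
        act = np.asarray(y, dtype=float).reshape(-1)
        if len(dose) != len(act):
            raise ValueError("doses and activities must have equal length")
        if np.any(dose < 0):
            raise ValueError("doses must be >= 0")
        if len(dose) < 5:
            raise ValueError("dose-response fit needs >= 5 doses")
        nonzero = dose[dose > 0]
        if len(nonzero) == 0:
            raise ValueError("at least one nonzero dose is required")
        dose = dose.copy()
        self.zero_dose_placeholder_ = float(nonzero.min() / 100.0)
        dose[dose == 0] = self.zero_dose_placeholder_
        spread = float(np.max(act) - np.min(act))
        scale = max(abs(float(np.mean(act))), float(np.max(np.abs(act))), 1e-300)
        if spread <= self.flat_tol * scale:
            raise FitError("response is flat across doses; IC50 undefined")
        logd = np.log(dose)
        top0, bot0 = float(np.max(act)), float(np.min(act))
        # initial IC50: dose at half-way response, interpolated on the
        # dose-sorted curve
        order = np.argsort(logd)
        half = (top0 + bot0) / 2.0
        li0 = float(np.interp(half, act[order][::-1], logd[order][::-1]))
        lo_h, hi_h = self.hill_bounds
        p0 = [li0, 1.0, top0, bot0]
        bounds = (
            [logd.min() - 10.0, lo_h, -np.inf, -np.inf],
            [logd.max() + 10.0, hi_h, np.inf, np.inf],
        )
        try:
            popt, pcov = curve_fit(self._model, logd, act, p0=p0, bounds=bounds,
                                   maxfev=20000)
        except RuntimeError as exc:
            raise FitError(f"dose-response fit did not converge: {exc}") from exc
        log_ic50, hill, top, bottom = popt
        perr = np.sqrt(np.diag(pcov))
        self.ic50_ = float(np.exp(log_ic50))
        self.hill_ = float(hill)
        self.top_ = float(top)
        self.bottom_ = float(bottom)
        self.ic50_stderr_ = float(self.ic50_ * perr[0])  # delta method on log scale
        self.hill_stderr_ = float(perr[1])
        self.r_squared_ = _r_squared(act, self._model(logd, *popt))
        self.n_doses_ = len(dose)
        if self.top_ < self.bottom_:
            raise FitError("fitted top below bottom; response is not inhibitory")
        return self

    def predict(self, X):
        dose = np.maximum(_x1d(X), self.zero_dose_placeholder_)
        return self._model(np.log(dose), np.log(self.ic50_), self.hill_,
                           self.top_, self.bottom_)

    def to_result(self) -> DoseResponseFit:
        return DoseResponseFit(self.ic50_, self.hill_, self.top_, self.bottom_,
                               self.ic50_stderr_, self.hill_stderr_,
                               self.r_squared_, self.n_doses_)


class GaussianProfile(BaseEstimator, RegressorMixin):
    """Gaussian-bell activity profile (used for the pH optimum).

    Model: a(x) = A·exp(−(x−μ)²/(2σ²)); the optimum is the fitted mean μ.
    Falls back to the argmax of the observed activities (``method_ =
    "argmax"``) when the fit fails, and sets ``boundary_flag_`` when the
    optimum lies at the edge of the sampled range (profile not peaked
    within range).
    """

    @staticmethod
    def _model(x, A, mu, sigma):
        return A * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))

    def fit(self, X, y):
        x = _x1d(X)
        a = np.asarray(y, dtype=float).reshape(-1)
        if len(x) < 5:
            raise ValueError("profile fit needs >= 5 points")
        i0 = int(np.argmax(a))
        p0 = [float(a[i0]), float(x[i0]), float(np.ptp(x)) / 4.0 or 1.0]
        try:
            popt, pcov = curve_fit(self._model, x, a, p0=p0, maxfev=20000)
            if popt[2] == 0 or not np.all(np.isfinite(popt)):
                raise RuntimeError("degenerate parameters")
            self.amplitude_, self.optimum_, self.width_ = (
                float(popt[0]), float(popt[1]), float(abs(popt[2])))
            self.uncertainty_ = float(np.sqrt(np.diag(pcov))[1])
            self.method_ = "fit"
            self.r_squared_ = _r_squared(a, self._model(x, *popt))
        except (RuntimeError, ValueError):
            self.amplitude_ = float(a[i0])
            self.optimum_ = float(x[i0])
            self.width_ = float("nan")
            self.uncertainty_ = None
            self.method_ = "argmax"
            self.r_squared_ = None
        self.boundary_flag_ = not (float(np.min(x)) < self.optimum_ < float(np.max(x)))
        if self.boundary_flag_:
            # clamp so the reported optimum stays inside the sampled range
            self.optimum_ = float(np.clip(self.optimum_, np.min(x), np.max(x)))
        return self

    def predict(self, X):
        if self.method_ == "argmax":
            raise FitError("no parametric curve available (argmax fallback)")
        return self._model(_x1d(X), self.amplitude_, self.optimum_, self.width_)

    def to_result(self) -> ProfileEstimate:
        return ProfileEstimate(
            optimum=self.optimum_,
            params={"amplitude": self.amplitude_, "width": self.width_},
            method=self.method_,
            uncertainty=self.uncertainty_,
            boundary_flag=self.boundary_flag_,
            r_squared=self.r_squared_,
        )


class ThermalDecline(BaseEstimator, RegressorMixin):
    """Descending-logistic heat-inactivation profile.

    Model: a(T) = A / (1 + exp((T − T½)/w)); the midpoint T½ is the
    temperature of half-maximal activity.  ``boundary_flag_`` is set when
    the profile shows no decline within the sampled range (midpoint at or
    beyond the range edge, or an essentially flat response).
    """

    @staticmethod
    def _model(T, A, mid, width):
        return A / (1.0 + np.exp((T - mid) / width))

    def fit(self, X, y):
        T = _x1d(X)
        a = np.asarray(y, dtype=float).reshape(-1)
        if len(T) < 5:
            raise ValueError("thermal profile fit needs >= 5 points")
        amax = float(np.max(a))
        flat = amax <= 0 or (np.ptp(a) <= 1e-3 * abs(amax))
        if flat:
            self.amplitude_ = amax
            self.midpoint_ = float(np.max(T))
            self.width_ = float("nan")
            self.uncertainty_ = None
            self.method_ = "argmax"
            self.r_squared_ = None
            self.boundary_flag_ = True
            return self
        half = amax / 2.0
        order = np.argsort(T)
        mid0 = float(np.interp(half, a[order][::-1], T[order][::-1]))
        p0 = [amax, mid0, max(float(np.ptp(T)) / 10.0, 0.5)]
        try:
            popt, pcov = curve_fit(self._model, T, a, p0=p0, maxfev=20000,
                                   bounds=([0.0, -np.inf, 1e-6], [np.inf, np.inf, np.inf]))
            self.amplitude_, self.midpoint_, self.width_ = map(float, popt)
            self.uncertainty_ = float(np.sqrt(np.diag(pcov))[1])
            self.method_ = "fit"
            self.r_squared_ = _r_squared(a, self._model(T, *popt))
        except (RuntimeError, ValueError):
            self.amplitude_ = amax
            self.midpoint_ = mid0
            self.width_ = float("nan")
            self.uncertainty_ = None
            self.method_ = "argmax"
            self.r_squared_ = None
        self.boundary_flag_ = not (float(np.min(T)) < self.midpoint_ < float(np.max(T)))
        if self.boundary_flag_:
            self.midpoint_ = float(np.clip(self.midpoint_, np.min(T), np.max(T)))
        return self

    def predict(self, X):
        if self.method_ == "argmax":
            raise FitError("no parametric curve available")
        return self._model(_x1d(X), self.amplitude_, self.midpoint_, self.width_)

    def to_result(self) -> ProfileEstimate:
        return ProfileEstimate(
            optimum=self.midpoint_,
            params={"amplitude": self.amplitude_, "width": self.width_},
            method=self.method_,
            uncertainty=self.uncertainty_,
            boundary_flag=self.boundary_flag_,
            r_squared=self.r_squared_,
        )


def fit_mm(S0_values, rates) -> MMFit:
    """Michaelis–Menten fit of rates against substrate concentrations."""
    return MichaelisMentenRegressor().fit(S0_values, rates).to_result()


def fit_4pl(doses, activities, hill_bounds=(0.2, 5.0)) -> DoseResponseFit:
    """Four-parameter-logistic dose–response fit; reports IC50."""
    return FourParamLogistic(hill_bounds=hill_bounds).fit(doses, activities).to_result()


def estimate_ph_optimum(pH_values, activities) -> ProfileEstimate:
    """pH optimum from a Gaussian-bell profile fit (argmax fallback)."""
    return GaussianProfile().fit(pH_values, activities).to_result()


def estimate_thermal_midpoint(temps, activities) -> ProfileEstimate:
    """Half-maximal heat-inactivation temperature (descending logistic)."""
    return ThermalDecline().fit(temps, activities).to_result()


def relative_inhibition(activities_by_condition: dict, control_label: str,
                        reference_inhibitor_label: str) -> dict:
    """Percent inhibition vs control and percent of a reference inhibitor.

    inhibition(c) = 100·(1 − a_c/a_control);
    relative(c) = 100·inhibition(c)/inhibition(reference).
    Raises on a non-positive control activity; a reference with zero
    inhibition leaves ``relative`` undefined (None) with a flag.
    """
    if control_label not in activities_by_condition:
        raise KeyError(f"control {control_label!r} missing")
    if reference_inhibitor_label not in activities_by_condition:
        raise KeyError(f"reference inhibitor {reference_inhibitor_label!r} missing")

    def mean_of(label):
        v = np.atleast_1d(np.asarray(activities_by_condition[label], dtype=float))
        return float(np.mean(v))

    a_ctrl = mean_of(control_label)
    if a_ctrl <= 0:
        raise ValueError(f"control activity must be > 0, got {a_ctrl:.3g}")
    inh_ref = 100.0 * (1.0 - mean_of(reference_inhibitor_label) / a_ctrl)
    out = {}
    for label in activities_by_condition:
        inh = 100.0 * (1.0 - mean_of(label) / a_ctrl)
        rel = 100.0 * inh / inh_ref if inh_ref != 0 else None
        out[label] = {
            "inhibition_pct": inh,
            "relative_to_reference_pct": rel,
            "reference_inhibition_undefined": inh_ref == 0,
        }
    return out
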