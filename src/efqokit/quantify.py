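"""EFQO quantification: drift correction, calibration, and activity.

The measured sample intensity I_M(t) is corrected for its own baseline and
for the linear drifts of the two control wells,

    I_C(t) = I_M(t) - I_M0 - (dI_S/dt + dI_E/dt) · t,

where I_M0 is the sample intensity at t = 0 (the first read after the
30-min preincubation) and dI_S/dt, dI_E/dt are the whole-trace OLS slopes
of the substrate-only and enzyme-only controls.  A calibration line fitted
to plateau intensities of fully digested substrate dilutions converts
fluorescence to moles: its slope is the fluorescence coefficient k
(AU·mol⁻¹), and activity is A = dI_C/dt · 1/k (mol released per minute),
with specific activity A per mg of lysate protein.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import CalibrationError, TraceValidationError
from .types import (
    ActivityResult,
    AggregatedActivity,
    CalibrationModel,
    CorrectedTrace,
    KineticTrace,
    PlateDataset,
    PlateLayout,
    WellRole,
)

__all__ = [
    "estimate_baseline",
    "estimate_drift",
    "correct_trace",
    "estimate_plateau",
    "FluorescenceCalibrator",
    "fit_calibration",
    "initial_rate",
    "compute_activity",
    "aggregate_replicates",
    "quantify_plate",
    "NonPlateauWarning",
]


class NonPlateauWarning(UserWarning):
    """The trace is still rising where a plateau was assumed."""


def estimate_baseline(trace: KineticTrace, m: int = 1) -> float:
    """Baseline I_M0: mean of the first ``m`` intensities (default: the
    t = 0 read alone, i.e. the first read after preincubation)."""
    if not (1 <= m <= trace.n_reads):
        raise ValueError(f"m must be in [1, {trace.n_reads}], got {m}")
    return float(np.mean(trace.intensities[:m]))


def estimate_drift(control: KineticTrace) -> tuple[float, float]:
    """Whole-trace OLS drift slope (AU/min) of a control well.

    Returns ``(slope, stderr)``.  Only substrate-only and enzyme-only
    controls are meaningful here; other roles are rejected.
    """
    if control.role not in (WellRole.SUBSTRATE_CONTROL, WellRole.ENZYME_CONTROL):
        raise TraceValidationError(
            f"drift estimation expects a control well, got role {control.role.value!r}"
        )
    if control.n_reads < 3:
        raise TraceValidationError("drift estimation needs >= 3 reads")
    res = stats.linregress(control.times, control.intensities)
    return float(res.slope), float(res.stderr)


def correct_trace(sample: KineticTrace, baseline: float,
                  drift_substrate_slope: float, drift_enzyme_slope: float) -> CorrectedTrace:
    """Apply the baseline/control-drift correction to a sample trace."""
    if sample.role != WellRole.SAMPLE:
        raise TraceValidationError(
            f"correction applies to sample wells, got role {sample.role.value!r}"
        )
    if not np.isfinite([baseline, drift_substrate_slope, drift_enzyme_slope]).all():
        raise ValueError("baseline and drift slopes must be finite")
    corrected = (
        sample.intensities
        - baseline
        - (drift_substrate_slope + drift_enzyme_slope) * sample.times
    )
    return CorrectedTrace(
        well_id=sample.well_id,
        times=sample.times.copy(),
        corrected=corrected,
        baseline=float(baseline),
        drift_substrate_slope=float(drift_substrate_slope),
        drift_enzyme_slope=float(drift_enzyme_slope),
    )


def _values_times(trace) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trace, CorrectedTrace):
        return trace.times, trace.corrected
    return trace.times, trace.intensities


def estimate_plateau(trace, m: int = 6) -> float:
    """Plateau intensity I_max: mean of the last ``m`` values.

    Warns (:class:`NonPlateauWarning`) when the OLS slope over those last
    ``m`` points exceeds 5% of the trace's maximal rolling-window slope —
    i.e. the curve is still visibly rising and I_max underestimates the
    fully-digested signal.
    """
    t, y = _values_times(trace)
    n = len(t)
    if not (1 <= m <= n):
        raise ValueError(f"m must be in [1, {n}], got {m}")
    plateau = float(np.mean(y[-m:]))
    if m >= 3:
        tail = stats.linregress(t[-m:], y[-m:]).slope
        max_slope = 0.0
        for i in range(n - m + 1):
            s = stats.linregress(t[i:i + m], y[i:i + m]).slope
            max_slope = max(max_slope, abs(s))
        if max_slope > 0 and abs(tail) > 0.05 * max_slope:
            warnings.warn(
                f"well {getattr(trace, 'well_id', '?')}: last {m} reads still "
                f"rising (slope {tail:.3g} AU/min); plateau may be underestimated",
                NonPlateauWarning, stacklevel=2,
            )
    return plateau


class FluorescenceCalibrator(BaseEstimator, RegressorMixin):
    """Linear calibration of plateau fluorescence against substrate amount.

    Fits I_max = k·amount + intercept by OLS with a free intercept.  The
    slope ``k_`` is the fluorescence coefficient (AU per mole of hydrolyzed
    substrate); dividing a corrected-fluorescence rate by ``k_`` yields a
    molar turnover rate.

    Attributes
    ----------
    k_ : float
        Fitted slope, AU/mol.
    intercept_ : float
        Fitted intercept, AU.
    r_squared_ : float
    n_points_ : int
    """

    def fit(self, X, y):
        amounts = np.asarray(X, dtype=float).reshape(-1)
        imax = np.asarray(y, dtype=float).reshape(-1)
        if amounts.shape != imax.shape:
            raise ValueError("amounts and imax must have equal length")
        if np.any(amounts < 0):
            raise ValueError("substrate amounts must be >= 0")
        if len(np.unique(amounts)) < 2:
            raise CalibrationError("calibration needs >= 2 distinct substrate amounts")
        res = stats.linregress(amounts, imax)
        if not res.slope > 0:
            raise CalibrationError(
                f"calibration slope must be positive, got {res.slope:.3g} AU/mol"
            )
        self.k_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        self.n_points_ = len(amounts)
        self.substrate_amounts_ = amounts.copy()
        self.imax_values_ = imax.copy()
        return self

    def predict(self, X):
        amounts = np.asarray(X, dtype=float).reshape(-1)
        return self.k_ * amounts + self.intercept_

    def to_model(self) -> CalibrationModel:
        return CalibrationModel(
            k=self.k_,
            intercept=self.intercept_,
            r_squared=self.r_squared_,
            substrate_amounts=self.substrate_amounts_,
            imax_values=self.imax_values_,
            n_points=self.n_points_,
        )


def fit_calibration(amounts: Sequence[float], imax: Sequence[float]) -> CalibrationModel:
    """OLS calibration line; slope = fluorescence coefficient k (AU/mol)."""
    return FluorescenceCalibrator().fit(amounts, imax).to_model()


def initial_rate(corrected: CorrectedTrace, policy: str = "initial_window",
                 window: int = 12) -> tuple[float, tuple[float, float], float]:
    """Estimate dI_C/dt (AU/min) from a corrected trace.

    ``initial_window`` fits an OLS slope over the first ``window`` reads
    (default 12 = 1 h at 5-min reads, inside the substrate-excess regime);
    ``max_rolling`` returns the maximal OLS slope over all contiguous
    windows of that width.  Returns ``(slope, (t_start, t_end), r²)``.
    """
    t, y = corrected.times, corrected.corrected
    n = len(t)
    if n < 4:
        raise TraceValidationError("initial-rate estimation needs >= 4 reads")
    if policy not in ("initial_window", "max_rolling"):
        raise ValueError("policy must be 'initial_window' or 'max_rolling'")
    w = int(window)
    if w < 4:
        raise ValueError("window must be >= 4 reads")
    if w > n:
        warnings.warn(
            f"window of {w} reads exceeds trace length {n}; using all reads",
            stacklevel=2,
        )
        w = n
    if policy == "initial_window":
        lo = 0
    else:
        slopes = [stats.linregress(t[i:i + w], y[i:i + w]).slope for i in range(n - w + 1)]
        lo = int(np.argmax(slopes))
    res = stats.linregress(t[lo:lo + w], y[lo:lo + w])
    r2 = float(res.rvalue**2) if np.std(y[lo:lo + w]) > 0 else 1.0
    return float(res.slope), (float(t[lo]), float(t[lo + w - 1])), r2


def compute_activity(corrected: CorrectedTrace, calibration: CalibrationModel,
                     protein_mass: float | None = None,
                     policy: str = "initial_window", window: int = 12,
                     condition: str | None = None) -> ActivityResult:
    """Convert a corrected trace to molar activity.

    A = dI_C/dt / k (mol/min per reaction); specific activity = A divided
    by lysate protein mass (mg); integrated activity = trapezoidal AUC of
    I_C(t) divided by k (mol·min).  A negative fitted slope is reported
    as-is with a below-detection flag (no truncation to zero).
    """
    if not (calibration.k > 0):
        raise CalibrationError("calibration with non-positive k is invalid")
    slope, win, r2 = initial_rate(corrected, policy=policy, window=window)
    activity = slope / calibration.k
    below = slope < 0
    specific = None
    if protein_mass is not None:
        if protein_mass <= 0:
            raise ValueError("protein_mass must be > 0 when given")
        specific = activity / protein_mass
    auc = float(np.trapezoid(corrected.corrected, corrected.times))
    return ActivityResult(
        well_id=corrected.well_id,
        condition=condition,
        activity=float(activity),
        specific_activity=specific,
        integrated_activity=auc / calibration.k,
        rate_slope=float(slope),
        fit_window=win,
        fit_r_squared=r2,
        below_detection=bool(below),
    )


def aggregate_replicates(results: Sequence[ActivityResult],
                         layout: PlateLayout | None = None,
                         by: str = "condition") -> list[AggregatedActivity]:
    """Aggregate per-well results into per-condition mean ± SEM.

    Grouping uses each result's ``condition`` label, falling back to the
    layout column ``by`` when a result carries none.  SEM = sd/√n is
    reported only for n ≥ 2.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to aggregate")

    def label(r: ActivityResult) -> str:
        if r.condition is not None and not (isinstance(r.condition, float) and np.isnan(r.condition)):
            return str(r.condition)
        if layout is not None and r.well_id in layout.wells:
            val = layout.table.loc[r.well_id, by]
            if pd.notna(val):
                return str(val)
        return r.well_id

    groups: dict[str, list[ActivityResult]] = {}
    for r in results:
        groups.setdefault(label(r), []).append(r)

    out = []
    for cond in sorted(groups):
        rs = groups[cond]
        a = np.array([r.activity for r in rs], dtype=float)
        n = len(a)
        sem = float(np.std(a, ddof=1) / np.sqrt(n)) if n >= 2 else None
        spec = np.array([r.specific_activity for r in rs
                         if r.specific_activity is not None], dtype=float)
        integ = np.array([r.integrated_activity for r in rs], dtype=float)
        out.append(AggregatedActivity(
            condition=cond,
            mean=float(np.mean(a)),
            sem=sem,
            n=n,
            mean_specific=float(np.mean(spec)) if len(spec) == n else None,
            sem_specific=(float(np.std(spec, ddof=1) / np.sqrt(n))
                          if len(spec) == n and n >= 2 else None),
            mean_integrated=float(np.mean(integ)),
        ))
    return out


def quantify_plate(dataset: PlateDataset, calibration: CalibrationModel,
                   policy: str = "initial_window", window: int = 12,
                   baseline_m: int = 1) -> list[ActivityResult]:
    """Run the full correction/activity chain on every sample well.

    Control drifts are pooled plate-wide: the substrate-control and
    enzyme-control slopes are each averaged over all wells of that role.
    Each sample well uses its own first-read baseline.
    """
    sub_controls = dataset.by_role(WellRole.SUBSTRATE_CONTROL)
    enz_controls = dataset.by_role(WellRole.ENZYME_CONTROL)
    if not sub_controls or not enz_controls:
        raise TraceValidationError(
            "quantification requires at least one substrate_control and one "
            "enzyme_control well"
        )
    s_S = float(np.mean([estimate_drift(c)[0] for c in sub_controls]))
    s_E = float(np.mean([estimate_drift(c)[0] for c in enz_controls]))
    layout = dataset.layout
    results = []
    for tr in dataset.by_role(WellRole.SAMPLE):
        baseline = estimate_baseline(tr, m=baseline_m)
        corr = correct_trace(tr, baseline, s_S, s_E)
        row = layout.table.loc[tr.well_id]
        protein = row.get("protein_mg")
        protein = float(protein) if pd.notna(protein) and float(protein) > 0 else None
        cond = row.get("condition")
        cond = str(cond) if pd.notna(cond) else None
        results.append(compute_activity(
            corr, calibration, protein_mass=protein,
            policy=policy, window=window, condition=cond,
        ))
    return results
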