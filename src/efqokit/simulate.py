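"""Forward simulation of EFQO plate-reader experiments.

The generative model is a single-substrate irreversible Michaelis–Menten
progress curve: substrate S(t) obeys dS/dt = -Vmax·S/(Km+S) with the
closed-form solution expressed through the Wright omega function.  A
sample well's fluorescence combines residual (incompletely quenched)
intact-substrate signal, released-fluorophore signal, a linear background
drift, an additive offset and i.i.d. Gaussian read noise:

    I(t) = bg + (1-q)·k_AU·S(t)·V + k_AU·(S0-S(t))·V + a·t + ε(t)

Substrate-only control wells carry the intact-substrate signal plus the
substrate drift a_S; enzyme-only controls carry only background plus the
lysate drift a_E.  Under the default ``sum_of_controls`` policy the sample
drift is exactly a_S + a_E, which makes the downstream control-subtraction
correction unbiased by construction.  Condition effects (inhibitors,
activators such as EDTA, pH, temperature, substrate chemistry) enter as
multiplicative factors on Vmax.
"""

from __future__ import annotations

import itertools
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.special import wrightomega

from .errors import TraceValidationError
from .types import (
    LAYOUT_COLUMNS,
    WELL_RE,
    ConditionModifier,
    KineticTrace,
    OligoSubstrate,
    PlateDataset,
    PlateLayout,
    SimulationConfig,
    WellRole,
)

__all__ = [
    "integrated_mm_substrate",
    "modifier_factor",
    "simulate_trace",
    "simulate_plate",
    "all_wells",
]


def integrated_mm_substrate(S0: float, Km: float, Vmax: float, t) -> "float | np.ndarray":
    """Remaining substrate concentration under Michaelis–Menten decay.

    Solves dS/dt = -Vmax·S/(Km+S), S(0) = S0, i.e. the implicit relation
    Km·ln(S0/S) + (S0 - S) = Vmax·t, via the principal-branch identity
    S = Km·ω(ln(S0/Km) + (S0 - Vmax·t)/Km) where ω is the Wright omega
    function (ω(y) = W₀(eʸ)), which is overflow-free for any argument.

    Parameters
    ----------
    S0, Km : mol/L
    Vmax : mol/(L·min)
    t : minutes (scalar or array)

    Returns
    -------
    S(t) in mol/L, clipped to [0, S0] against rounding.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    if S0 < 0 or Km < 0 or Vmax < 0 or np.any(t < 0):
        raise ValueError("S0, Km, Vmax and t must all be >= 0")
    if Vmax > 0 and Km <= 0:
        raise ValueError("Km must be > 0 when Vmax > 0")
    if S0 == 0 or Vmax == 0:
        out = np.full_like(t, S0, dtype=float)
        return float(out) if scalar else out
    y = np.log(S0 / Km) + (S0 - Vmax * t) / Km
    S = Km * np.real(wrightomega(y))
    if not np.all(np.isfinite(S)):
        raise ArithmeticError("integrated MM evaluation did not converge")
    S = np.clip(S, 0.0, S0)
    return float(S) if scalar else S


def modifier_factor(mod: ConditionModifier, substrate: OligoSubstrate | None = None) -> float:
    """Combined multiplicative factor on Vmax for a condition.

    factor = activation × inhibition × pH bell × thermal logistic ×
    substrate-chemistry factors.  Inhibition is 1/(1+(c/IC50)^h) unless a
    fixed inhibited fraction overrides it; the pH term is a Gaussian bell
    around the optimum; the thermal term is a descending logistic around
    the heat-inactivation midpoint.  pH/thermal terms require their
    optimum/midpoint to be set, otherwise they are exactly 1.
    """
    factor = mod.activation_factor
    if mod.fixed_inhibition_fraction is not None:
        factor *= 1.0 - mod.fixed_inhibition_fraction
    elif mod.inhibitor_conc > 0:
        factor *= 1.0 / (1.0 + (mod.inhibitor_conc / mod.inhibitor_ic50) ** mod.hill)
    if mod.pH_optimum is not None and mod.pH is not None:
        factor *= float(np.exp(-((mod.pH - mod.pH_optimum) ** 2) / (2.0 * mod.pH_width**2)))
    if mod.thermal_midpoint is not None:
        factor *= float(
            1.0 / (1.0 + np.exp((mod.temperature - mod.thermal_midpoint) / mod.thermal_width))
        )
    if substrate is not None:
        factor *= substrate.rate_factor
    return factor


def _time_grid(config: SimulationConfig) -> np.ndarray:
    n = int(np.floor(config.duration / config.read_interval + 1e-9)) + 1
    return np.arange(n) * config.read_interval


def simulate_trace(
    config: SimulationConfig,
    role: "WellRole | str" = WellRole.SAMPLE,
    seed: "int | np.random.SeedSequence | None" = None,
    well_id: str = "A01",
) -> KineticTrace:
    """Simulate one well's fluorescence time series.

    ``role`` selects the generative branch: sample (enzyme + substrate),
    substrate_control (no enzyme), or enzyme_control (no substrate).
    Noise is reproducible from ``seed`` (defaults to ``config.seed``).
    """
    role = WellRole(role)
    if role not in (WellRole.SAMPLE, WellRole.SUBSTRATE_CONTROL, WellRole.ENZYME_CONTROL):
        raise TraceValidationError(f"cannot simulate role {role.value!r}")
    t = _time_grid(config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sig = config.k_AU * config.volume
    q = config.quench_efficiency
    if role == WellRole.SUBSTRATE_CONTROL:
        mean = config.background + (1.0 - q) * sig * config.S0 + config.drift_substrate * t
    elif role == WellRole.ENZYME_CONTROL:
        mean = config.background + config.drift_enzyme * t
    else:
        vmax_eff = config.Vmax * modifier_factor(config.modifiers, config.substrate)
        S = integrated_mm_substrate(config.S0, config.Km, vmax_eff, t)
        if config.sample_drift_policy == "sum_of_controls":
            drift = config.drift_substrate + config.drift_enzyme
        else:
            drift = config.custom_sample_drift
        mean = (
            config.background
            + (1.0 - q) * sig * S
            + sig * (config.S0 - S)
            + drift * t
        )
    noise = rng.normal(0.0, config.noise_sd, size=t.shape) if config.noise_sd > 0 else 0.0
    return KineticTrace(well_id=well_id, times=t, intensities=mean + noise, role=role)


def all_wells() -> list[str]:
    """The 96 well ids in row-major order (A01 … H12)."""
    return [f"{r}{c:02d}" for r, c in itertools.product("ABCDEFGH", range(1, 13))]


def _well_index(well_id: str) -> int:
    return (ord(well_id[0]) - ord("A")) * 12 + int(well_id[1:]) - 1


def simulate_plate(
    design: Sequence[tuple],
    base_config: SimulationConfig | None = None,
    seed: int = 0,
) -> PlateDataset:
    """Simulate a plate from a design of (well_id, role, overrides) entries.

    ``overrides`` is a dict applied to ``base_config`` via
    :meth:`SimulationConfig.with_` (nested dicts allowed for ``modifiers``
    and ``substrate``); the layout-only keys ``condition``, ``enzyme`` and
    ``replicate`` annotate the plate layout without touching the
    simulation.  Per-well noise streams derive deterministically from the
    master ``seed`` and the well position, so a design is reproducible
    regardless of entry order.
    """
    base = base_config if base_config is not None else SimulationConfig()
    if len(design) > 96:
        raise TraceValidationError("a plate holds at most 96 wells")
    seen: set[str] = set()
    traces: list[KineticTrace] = []
    rows: list[dict[str, Any]] = []
    for entry in design:
        well_id, role, overrides = entry[0], WellRole(entry[1]), dict(entry[2] if len(entry) > 2 else {})
        if not WELL_RE.match(well_id):
            raise TraceValidationError(f"invalid well id: {well_id!r}")
        if well_id in seen:
            raise TraceValidationError(f"duplicate well id: {well_id!r}")
        seen.add(well_id)
        condition = overrides.pop("condition", None)
        enzyme = overrides.pop("enzyme", None)
        replicate = overrides.pop("replicate", None)
        config = base.with_(**overrides)
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(_well_index(well_id),))
        traces.append(simulate_trace(config, role, seed=ss, well_id=well_id))
        mod = config.modifiers
        rows.append({
            "well": well_id,
            "role": role.value,
            "condition": condition,
            "enzyme": enzyme,
            "protein_mg": config.protein_mass,
            "substrate": config.substrate.sequence,
            "substrate_conc_M": config.S0,
            "inhibitor": mod.inhibitor_name or None,
            "inhibitor_conc_M": mod.inhibitor_conc,
            "pH": mod.pH,
            "temp_C": mod.temperature,
            "replicate": replicate,
        })
    layout = PlateLayout(pd.DataFrame(rows, columns=LAYOUT_COLUMNS)) if rows else PlateLayout(
        pd.DataFrame(columns=LAYOUT_COLUMNS)
    )
    traces.sort(key=lambda tr: tr.well_id)
    meta = {"simulator_seed": seed, "source": "efqokit.simulate"}
    return PlateDataset(traces=traces, layout=layout, metadata=meta)
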