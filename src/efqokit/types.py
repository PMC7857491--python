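"""Core data containers for EFQO assay analysis.

The assay: a 30-nt single-stranded DNA carries a 5' FAM fluorophore and a
3' quencher.  Intact substrate is dark; an acid 5' exonuclease (PLD3/PLD4)
releases the terminal fluorophore-coupled nucleotide, and the fluorescence
increase read in a 96-well plate is a direct, quantitative readout of
5'-exonuclease activity.  The containers here hold raw well traces, plate
annotation, corrected traces, the fluorescence-to-moles calibration, and
per-well activity results.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Any

import numpy as np
import pandas as pd

from .errors import TraceValidationError

__all__ = [
    "WellRole",
    "OligoSubstrate",
    "ConditionModifier",
    "SimulationConfig",
    "KineticTrace",
    "PlateLayout",
    "PlateDataset",
    "CorrectedTrace",
    "CalibrationModel",
    "ActivityResult",
    "AggregatedActivity",
    "standard_substrate",
    "standard_config",
    "LAYOUT_COLUMNS",
]

WELL_RE = re.compile(r"^[A-H](0[1-9]|1[0-2])$")

#: canonical layout columns, in file order
LAYOUT_COLUMNS = [
    "well", "role", "condition", "enzyme", "protein_mg", "substrate",
    "substrate_conc_M", "inhibitor", "inhibitor_conc_M", "pH", "temp_C",
    "replicate",
]


class WellRole(str, Enum):
    """What a well contributes to the analysis.

    ``sample`` wells contain enzyme + substrate; ``substrate_control`` has
    substrate but no lysate (captures substrate-autohydrolysis / photobleach
    drift); ``enzyme_control`` has lysate but no substrate (captures lysate
    autofluorescence drift); ``blank`` wells are ignored.
    """

    SAMPLE = "sample"
    SUBSTRATE_CONTROL = "substrate_control"
    ENZYME_CONTROL = "enzyme_control"
    BLANK = "blank"


def _as_role(role: "WellRole | str") -> WellRole:
    try:
        return WellRole(role)
    except ValueError:
        raise TraceValidationError(f"unknown well role: {role!r}") from None


@dataclass(frozen=True)
class OligoSubstrate:
    """An end-labeled fluorescence-quenched oligonucleotide substrate.

    Parameters
    ----------
    sequence
        5'→3' DNA sequence over {A, C, G, T}, length ≥ 2.
    five_prime_label
        Fluorophore on the 5'-terminal nucleotide ("FAM" or "none").
    three_prime_quencher
        Whether a quencher is coupled to the 3'-terminal nucleotide.
    pto_linkages
        0-based internucleotide phosphorothioate linkage indices; linkage
        ``i`` joins nucleotides ``i`` and ``i+1``.
    pto_rate_factor
        Multiplier (0, 1] on the hydrolysis rate when the 5'-terminal
        linkage (index 0) is phosphorothioate-protected.
    five_prime_base_factor
        Multiplier (> 0) expressing the 5'-terminal-base preference of the
        enzyme (T released most efficiently, then A, G, C).
    """

    sequence: str
    five_prime_label: str = "FAM"
    three_prime_quencher: bool = True
    pto_linkages: frozenset = frozenset()
    pto_rate_factor: float = 1.0
    five_prime_base_factor: float = 1.0

    def __post_init__(self):
        if len(self.sequence) < 2:
            raise ValueError("substrate sequence must have length >= 2")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
        if self.five_prime_label not in ("FAM", "none"):
            raise ValueError("five_prime_label must be 'FAM' or 'none'")
        object.__setattr__(self, "pto_linkages", frozenset(self.pto_linkages))
        n_link = len(self.sequence) - 1
        for i in self.pto_linkages:
            if not (0 <= int(i) < n_link):
                raise ValueError(f"linkage index {i} out of range (< {n_link})")
        if not (0.0 < self.pto_rate_factor <= 1.0):
            raise ValueError("pto_rate_factor must be in (0, 1]")
        if self.five_prime_base_factor <= 0:
            raise ValueError("five_prime_base_factor must be > 0")

    @property
    def rate_factor(self) -> float:
        """Combined multiplier on the hydrolysis rate for this substrate.

        The PTO factor applies only when linkage 0 (the 5'-terminal bond)
        is protected: 3'-end phosphorothioates merely block cleavage from
        the wrong end and leave the 5'-exonucleolytic rate unchanged.
        """
        f = self.five_prime_base_factor
        if 0 in self.pto_linkages:
            f *= self.pto_rate_factor
        return f


#: qualitative 5'-terminal-base preference (T > A > G > C)
DEFAULT_BASE_FACTORS = {"T": 1.0, "A": 0.75, "G": 0.5, "C": 0.3}

#: the 30-nt assay substrate; the three unambiguous internal 3'-terminal
#: linkages are phosphorothioate-protected to block 3'-side attack
STANDARD_SEQUENCE = "ACCATGACGTTCCTGATGCTAAGTATGCAC"


def standard_substrate(**overrides: Any) -> OligoSubstrate:
    """The standard 5'-FAM / 3'-quencher assay substrate."""
    kwargs: dict[str, Any] = dict(
        sequence=STANDARD_SEQUENCE,
        five_prime_label="FAM",
        three_prime_quencher=True,
        pto_linkages=frozenset({26, 27, 28}),
    )
    kwargs.update(overrides)
    return OligoSubstrate(**kwargs)


@dataclass(frozen=True)
class ConditionModifier:
    """Multiplicative condition effects on the catalytic rate.

    Each active term multiplies Vmax: logistic inhibition
    ``1/(1+(c/IC50)^h)`` (or an explicit fixed inhibited fraction),
    an activation factor (>1 for activators such as EDTA), a Gaussian
    pH-dependence bell, and a descending-logistic thermal-stability term.
    pH and thermal terms are active only when their optimum/midpoint is
    set; the default modifier is exactly neutral (factor 1).
    """

    inhibitor_name: str = ""
    inhibitor_conc: float = 0.0          # mol/L
    inhibitor_ic50: float = 1.0          # mol/L
    hill: float = 1.0
    fixed_inhibition_fraction: float | None = None
    activation_factor: float = 1.0
    pH: float | None = None
    pH_optimum: float | None = None
    pH_width: float = 1.0
    temperature: float = 37.0            # °C
    thermal_midpoint: float | None = None
    thermal_width: float = 2.0           # °C

    def __post_init__(self):
        if self.inhibitor_ic50 <= 0:
            raise ValueError("inhibitor_ic50 must be > 0")
        if self.hill <= 0:
            raise ValueError("hill must be > 0")
        if self.pH_width <= 0:
            raise ValueError("pH_width must be > 0")
        if self.thermal_width <= 0:
            raise ValueError("thermal_width must be > 0")
        if self.fixed_inhibition_fraction is not None and not (
            0.0 <= self.fixed_inhibition_fraction <= 1.0
        ):
            raise ValueError("fixed_inhibition_fraction must lie in [0, 1]")
        if self.activation_factor < 0:
            raise ValueError("activation_factor must be >= 0")
        if self.inhibitor_conc < 0:
            raise ValueError("inhibitor_conc must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative parameter set for one simulated well.

    Defaults mirror the standard assay: 1 μM substrate in a 100-μl
    reaction, 0.5 μg lysate protein per well (5 ng/μl), reads every 5 min
    for 12 h at 37 °C after a 30-min preincubation.
    """

    S0: float = 1e-6                 # mol/L substrate
    volume: float = 1e-4             # L (100 μl)
    Km: float = 1e-6                 # mol/L
    Vmax: float = 1e-8               # mol/(L·min), uninhibited reference
    k_AU: float = 1e13               # AU per mol released fluorophore
    quench_efficiency: float = 0.95  # fraction of intact-substrate signal suppressed
    background: float = 50.0         # AU
    drift_substrate: float = 0.05    # AU/min, substrate-control drift
    drift_enzyme: float = 0.02       # AU/min, enzyme-control drift
    sample_drift_policy: str = "sum_of_controls"
    custom_sample_drift: float | None = None
    noise_sd: float = 2.0            # AU
    read_interval: float = 5.0       # min
    duration: float = 720.0          # min
    preincubation: float = 30.0      # min
    protein_mass: float = 5e-4       # mg per well (5 ng/μl × 100 μl)
    seed: int = 0
    modifiers: ConditionModifier = field(default_factory=ConditionModifier)
    substrate: OligoSubstrate = field(default_factory=standard_substrate)

    def __post_init__(self):
        for name in ("S0", "volume", "Km", "Vmax", "k_AU", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.Vmax > 0 and self.Km <= 0:
            raise ValueError("Km must be > 0 when Vmax > 0")
        if not (0.0 < self.quench_efficiency <= 1.0):
            raise ValueError("quench_efficiency must be in (0, 1]")
        if self.read_interval <= 0:
            raise ValueError("read_interval must be > 0")
        if self.duration < self.read_interval:
            raise ValueError("duration must be >= read_interval")
        if self.sample_drift_policy not in ("sum_of_controls", "custom"):
            raise ValueError("sample_drift_policy must be 'sum_of_controls' or 'custom'")
        if self.sample_drift_policy == "custom" and self.custom_sample_drift is None:
            raise ValueError("custom policy requires custom_sample_drift")

    def with_(self, **overrides: Any) -> "SimulationConfig":
        """Return a copy with fields replaced (nested dicts allowed for
        ``modifiers`` and ``substrate``)."""
        overrides = dict(overrides)
        mod = overrides.get("modifiers")
        if isinstance(mod, dict):
            overrides["modifiers"] = replace(self.modifiers, **mod)
        sub = overrides.get("substrate")
        if isinstance(sub, dict):
            base = self.substrate
            kwargs = {
                "sequence": base.sequence,
                "five_prime_label": base.five_prime_label,
                "three_prime_quencher": base.three_prime_quencher,
                "pto_linkages": base.pto_linkages,
                "pto_rate_factor": base.pto_rate_factor,
                "five_prime_base_factor": base.five_prime_base_factor,
            }
            kwargs.update(sub)
            overrides["substrate"] = OligoSubstrate(**kwargs)
        return replace(self, **overrides)


def standard_config(**overrides: Any) -> SimulationConfig:
    """A SimulationConfig at the standard assay conditions."""
    return SimulationConfig().with_(**overrides)


@dataclass
class KineticTrace:
    """One well's fluorescence time series.

    ``times`` are minutes since the first post-preincubation read (t = 0);
    ``intensities`` are relative fluorescence units (emission 528 nm /
    excitation 485 nm).
    """

    well_id: str
    times: np.ndarray
    intensities: np.ndarray
    role: WellRole = WellRole.SAMPLE

    def __post_init__(self):
        self.role = _as_role(self.role)
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.intensities.ndim != 1:
            raise TraceValidationError("times and intensities must be 1-D")
        if len(self.times) != len(self.intensities):
            raise TraceValidationError(
                f"well {self.well_id}: times and intensities differ in length"
            )
        if len(self.times) < 2:
            raise TraceValidationError(f"well {self.well_id}: need >= 2 reads")
        if not np.all(np.diff(self.times) > 0):
            raise TraceValidationError(
                f"well {self.well_id}: times must be strictly increasing"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise TraceValidationError(
                f"well {self.well_id}: non-finite intensity values"
            )

    @property
    def n_reads(self) -> int:
        return len(self.times)


class PlateLayout:
    """Per-well annotation mapping wells to experimental conditions.

    Wraps a DataFrame indexed by well id with at least the canonical
    columns (role, condition, enzyme, protein_mg, substrate,
    substrate_conc_M, inhibitor, inhibitor_conc_M, pH, temp_C, replicate);
    extra columns are preserved as opaque metadata.
    """

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if "well" in table.columns:
            table = table.set_index("well")
        table.index.name = "well"
        if table.index.duplicated().any():
            dups = sorted(set(table.index[table.index.duplicated()]))
            raise TraceValidationError(f"duplicate well record(s): {dups}")
        for w in table.index:
            if not WELL_RE.match(str(w)):
                raise TraceValidationError(f"invalid well id: {w!r}")
        for col in LAYOUT_COLUMNS[1:]:
            if col not in table.columns:
                table[col] = np.nan
        table["role"] = [_as_role(r).value if pd.notna(r) else WellRole.BLANK.value
                         for r in table["role"]]
        self.table = table.sort_index()

    @property
    def wells(self) -> list[str]:
        return list(self.table.index)

    def role_of(self, well: str) -> WellRole:
        return WellRole(self.table.loc[well, "role"])

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlateLayout):
            return NotImplemented
        a, b = self.table, other.table
        if list(a.index) != list(b.index):
            return False
        common = [c for c in a.columns if c in b.columns]
        # normalize null-likes (None vs NaN) before comparison
        aa = a[common].where(a[common].notna(), np.nan)
        bb = b[common].where(b[common].notna(), np.nan)
        try:
            pd.testing.assert_frame_equal(
                aa, bb, check_dtype=False, check_like=True,
                rtol=1e-9, atol=0,
            )
        except AssertionError:
            return False
        return True


@dataclass
class PlateDataset:
    """Kinetic traces plus layout plus provenance metadata."""

    traces: list[KineticTrace]
    layout: PlateLayout
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        wells = {t.well_id for t in self.traces}
        missing = wells - set(self.layout.wells)
        if missing:
            raise TraceValidationError(
                f"trace well(s) absent from layout: {sorted(missing)}"
            )
        if self.traces:
            t0 = self.traces[0].times
            for tr in self.traces[1:]:
                if len(tr.times) != len(t0) or not np.allclose(tr.times, t0):
                    raise TraceValidationError(
                        "all traces must share one time grid "
                        f"(well {tr.well_id} differs)"
                    )

    def trace(self, well_id: str) -> KineticTrace:
        for t in self.traces:
            if t.well_id == well_id:
                return t
        raise KeyError(well_id)

    def by_role(self, role: "WellRole | str") -> list[KineticTrace]:
        role = _as_role(role)
        return [t for t in self.traces if t.role == role]


@dataclass
class CorrectedTrace:
    """Drift- and baseline-corrected sample fluorescence I_C(t)."""

    well_id: str
    times: np.ndarray
    corrected: np.ndarray
    baseline: float                 # I_M0, AU
    drift_substrate_slope: float    # AU/min
    drift_enzyme_slope: float       # AU/min


@dataclass
class CalibrationModel:
    """Fluorescence coefficient k (AU per mole of hydrolyzed substrate)."""

    k: float
    intercept: float
    r_squared: float
    substrate_amounts: np.ndarray   # mol
    imax_values: np.ndarray         # AU
    n_points: int

    def to_moles(self, intensity: "float | np.ndarray"):
        """Convert corrected fluorescence (AU) to moles released."""
        return (np.asarray(intensity, dtype=float) - self.intercept) / self.k


@dataclass
class ActivityResult:
    """Absolute, specific, and integrated activity for one well."""

    well_id: str
    condition: str | None
    activity: float                      # A, mol/min per reaction
    specific_activity: float | None      # mol/min/mg protein
    integrated_activity: float           # mol·min (AUC of I_C / k)
    rate_slope: float                    # AU/min
    fit_window: tuple[float, float]      # (t_start, t_end) min
    fit_r_squared: float
    below_detection: bool = False


@dataclass
class AggregatedActivity:
    """Replicate-aggregated activity for one condition (mean ± SEM)."""

    condition: str
    mean: float
    sem: float | None
    n: int
    mean_specific: float | None = None
    sem_specific: float | None = None
    mean_integrated: float | None = None

    def __post_init__(self):
        if self.n < 2:
            self.sem = None
            self.sem_specific = None
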