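"""Constant-flow perfusion QC: calibration, outflow facility, inclusion.

Enucleated whole globes are perfused with synthetic aqueous humour at a
constant 2.4 ul/min while a transducer records pressure at the cannulation
point.  Outflow facility is the ratio of flow to driving pressure,

    C = Flow / IOP        [ul min^-1 mmHg^-1]

with no episcleral venous pressure term (there is none ex vivo).  Eyes are
admitted to study only if facility stays stably inside a physiological band
over a stability window: 0.18-0.35 for pig, and an expanded 0.18-0.40 band
for scarce human donor globes.  Tissue viability is probed by injecting an
actin-disrupting agent (cytochalasin D) into one eye of a pair and comparing
the facility fold change against the contralateral control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "PerfusionRecord",
    "InclusionCriteria",
    "PIG_CRITERIA",
    "HUMAN_CRITERIA",
    "calibrate_transducer",
    "outflow_facility",
    "facility_series",
    "check_inclusion",
    "facility_response",
    "read_trace_csv",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear transducer calibration: pressure_mmHg = slope * volts + intercept."""

    slope: float
    intercept: float
    r_squared: float

    def to_pressure(self, voltage):
        return self.slope * np.asarray(voltage, dtype=float) + self.intercept


@dataclass
class PerfusionRecord:
    """One eye's constant-flow perfusion trace.

    ``intervention_time_min`` marks a treatment (e.g. an anterior-chamber
    drug injection) if one occurred; ``facility_series`` is filled lazily.
    """

    eye_id: str
    species: str
    flow_rate: float  # ul/min
    times: np.ndarray  # min, strictly increasing
    pressures: np.ndarray  # mmHg
    intervention_time_min: float | None = None
    facility: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pressures = np.asarray(self.pressures, dtype=float)
        if self.times.shape != self.pressures.shape:
            raise ValueError("times and pressures must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.flow_rate <= 0:
            raise ValueError(f"flow rate must be positive, got {self.flow_rate}")


@dataclass(frozen=True)
class InclusionCriteria:
    """Facility band plus stability requirement for admitting an eye.

    ``max_relative_drift`` bounds the facility trend over the final
    ``stability_window`` minutes: |mean of last third - mean of first
    third| / window mean.  A trend measure is used rather than the raw
    peak-to-peak range so that sensor noise is not mistaken for
    instability.
    """

    facility_min: float
    facility_max: float
    stability_window: float = 30.0  # min
    max_relative_drift: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.facility_min < self.facility_max:
            raise ValueError("need 0 < facility_min < facility_max")


#: Pig inclusion band (stable physiological IOP at 2.4 ul/min).
PIG_CRITERIA = InclusionCriteria(facility_min=0.18, facility_max=0.35)
#: Expanded band used for human donor globes.
HUMAN_CRITERIA = InclusionCriteria(facility_min=0.18, facility_max=0.40)

CRITERIA_BY_SPECIES = {"pig": PIG_CRITERIA, "human": HUMAN_CRITERIA,
                       "cyno": HUMAN_CRITERIA}


def calibrate_transducer(voltages, reference_pressures) -> CalibrationCurve:
    """Least-squares line mapping transducer volts to mmHg.

    Requires at least two distinct voltages; a degenerate design (all
    voltages equal) cannot define a slope and raises ``ValueError``.
    """
    v = np.asarray(voltages, dtype=float)
    p = np.asarray(reference_pressures, dtype=float)
    if v.size != p.size or v.size < 2:
        raise ValueError("need >= 2 paired calibration points")
    if np.ptp(v) == 0:
        raise ValueError("degenerate calibration: all voltages identical")
    fit = stats.linregress(v, p)
    return CalibrationCurve(slope=float(fit.slope), intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue**2))


def outflow_facility(flow: float, pressure: float) -> float:
    """C = Flow / IOP for an enucleated eye (no EVP term).

    Units: ul min^-1 mmHg^-1.  Raises on non-positive pressure.
    """
    if pressure <= 0:
        raise ValueError(f"pressure must be positive, got {pressure}")
    return flow / pressure


def facility_series(record: PerfusionRecord) -> np.ndarray:
    """Element-wise facility along a trace; cached on the record.

    Non-positive pressures (transient depressurization during aqueous
    sampling) yield NaN at that index rather than an error.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        fac = np.where(record.pressures > 0,
                       record.flow_rate / record.pressures, np.nan)
    record.facility = fac
    return fac


def _window_mask(times: np.ndarray, start: float, stop: float) -> np.ndarray:
    return (times >= start) & (times <= stop)


def check_inclusion(record: PerfusionRecord,
                    criteria: InclusionCriteria) -> tuple[bool, list[str]]:
    """Gate an eye on facility band and stability over the final window.

    Returns ``(passed, reasons)``; ``reasons`` lists every violated rule.
    Raises ``ValueError`` when the record is shorter than the stability
    window.
    """
    if record.times.size == 0 or (record.times[-1] - record.times[0]
                                  < criteria.stability_window):
        raise ValueError(
            f"record spans {0 if record.times.size == 0 else record.times[-1] - record.times[0]:.1f} min, "
            f"shorter than the {criteria.stability_window:.0f} min stability window"
        )
    fac = facility_series(record)
    mask = _window_mask(record.times, record.times[-1] - criteria.stability_window,
                        record.times[-1])
    window = fac[mask]
    window = window[np.isfinite(window)]
    reasons: list[str] = []
    if window.size == 0:
        return False, ["no valid facility samples in stability window"]
    if np.min(window) < criteria.facility_min:
        reasons.append(
            f"facility fell below {criteria.facility_min} "
            f"(min {np.min(window):.3f})")
    if np.max(window) > criteria.facility_max:
        reasons.append(
            f"facility exceeded {criteria.facility_max} "
            f"(max {np.max(window):.3f})")
    third = max(window.size // 3, 1)
    drift = float(abs(np.mean(window[-third:]) - np.mean(window[:third]))
                  / np.mean(window))
    if drift > criteria.max_relative_drift:
        reasons.append(
            f"facility drift {drift:.2f} exceeds {criteria.max_relative_drift}")
    return len(reasons) == 0, reasons


def facility_response(treated: PerfusionRecord, control: PerfusionRecord,
                      baseline_window: float = 30.0) -> float:
    """Treated-vs-contralateral facility fold change.

    Each record's post/pre ratio is the mean facility after its
    intervention timestamp divided by the mean over the ``baseline_window``
    minutes immediately before it; the result is treated ratio / control
    ratio.  A flat control with a doubled treated facility gives 2.0.
    """
    ratios = []
    for rec in (treated, control):
        if rec.intervention_time_min is None:
            raise ValueError(f"record {rec.eye_id} has no intervention timestamp")
        t0 = rec.intervention_time_min
        if rec.times[0] > t0 - baseline_window:
            raise ValueError(
                f"record {rec.eye_id} lacks {baseline_window:.0f} min of baseline")
        fac = facility_series(rec)
        pre = fac[_window_mask(rec.times, t0 - baseline_window, t0)]
        post = fac[rec.times > t0]
        pre = pre[np.isfinite(pre)]
        post = post[np.isfinite(post)]
        if pre.size == 0 or post.size == 0:
            raise ValueError(f"record {rec.eye_id} has an empty pre or post window")
        base = float(np.mean(pre))
        if base <= 0:
            raise ValueError(f"record {rec.eye_id} has non-positive baseline facility")
        ratios.append(float(np.mean(post)) / base)
    return ratios[0] / ratios[1]


def read_trace_csv(path: str | Path, *, eye_id: str | None = None,
                   species: str = "pig", flow_ul_min: float = 2.4,
                   calibration: CalibrationCurve | None = None) -> PerfusionRecord:
    """Load a pressure trace CSV into a PerfusionRecord.

    The file must contain ``time_min`` and either ``pressure_mmHg`` or raw
    ``voltage_V`` (the latter requires a calibration curve).
    """
    df = pd.read_csv(path)
    if "time_min" not in df.columns:
        raise ValueError(f"{path}: missing required column time_min")
    if "pressure_mmHg" in df.columns:
        pressures = df["pressure_mmHg"].to_numpy(dtype=float)
    elif "voltage_V" in df.columns:
        if calibration is None:
            raise ValueError(f"{path}: raw voltage trace needs a calibration curve")
        pressures = calibration.to_pressure(df["voltage_V"].to_numpy(dtype=float))
    else:
        raise ValueError(f"{path}: need pressure_mmHg or voltage_V column")
    return PerfusionRecord(
        eye_id=eye_id or Path(path).stem,
        species=species,
        flow_rate=flow_ul_min,
        times=df["time_min"].to_numpy(dtype=float),
        pressures=pressures,
    )
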