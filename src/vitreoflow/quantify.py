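"""Microbead fluorescence quantification and dispersion-rate estimation.

A 1:1 mixture of 20 nm (green) and 2000 nm (red) fluorescent polystyrene
microbeads is injected into the vitreous; aqueous humour sampled from the
anterior chamber at 2 h and 4 h carries whatever fraction of each size has
dispersed anteriorly.  Quantification proceeds through

1. bead stock arithmetic — ``beads_per_ml = 6 S 1e12 / (rho pi phi^3)``
   with S the solids concentration (g/ml), rho the polymer density (g/ml)
   and phi the bead diameter (um);
2. serial-dilution fluorescence standard curves, fit per channel;
3. inversion of plate readings to concentrations;
4. percent-of-injected-dose normalization;
5. linear regression of concentration on sampling time — the anterior
   dispersion rate (beads ml^-1 h^-1) — and species fold ratios.

Note the vendor-stated stock concentrations (4.143e13 /ml for 20 nm,
1.326e8 /ml for 2000 nm) are stored as data on the reference BeadSpec
objects; the stock formula above, evaluated at nominal 2% solids and
polystyrene density 1.055 g/ml, does not reproduce them (it is exact only
for the exact solids loading of each lot).  Both routes are exposed and
kept independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BeadSpec",
    "StandardCurve",
    "AqueousSample",
    "DispersionEstimate",
    "GREEN_20NM",
    "RED_2000NM",
    "beads_per_ml",
    "injected_dose",
    "make_dilution_series",
    "fit_standard_curve",
    "reading_to_concentration",
    "apply_standard_curve",
    "percent_injected",
    "dispersion_rate",
    "species_fold_ratio",
    "read_plate_csv",
]


@dataclass(frozen=True)
class BeadSpec:
    """Physical constants of one fluorescent microbead product."""

    diameter_phi: float  # um
    channel: str  # "green" or "red"
    solids_fraction_S: float  # g/ml of suspension
    polymer_density_rho: float  # g/ml
    stock_concentration: float  # beads/ml, vendor-stated

    def __post_init__(self) -> None:
        if self.diameter_phi <= 0:
            raise ValueError("bead diameter must be positive")
        if not 0 < self.solids_fraction_S < 1:
            raise ValueError("solids fraction must be in (0, 1)")
        if self.polymer_density_rho <= 0:
            raise ValueError("polymer density must be positive")


#: 20 nm green FluoSphere stock (vendor-stated count).
GREEN_20NM = BeadSpec(diameter_phi=0.02, channel="green", solids_fraction_S=0.02,
                      polymer_density_rho=1.055, stock_concentration=4.143e13)
#: 2000 nm red FluoSphere stock (vendor-stated count).
RED_2000NM = BeadSpec(diameter_phi=2.0, channel="red", solids_fraction_S=0.02,
                      polymer_density_rho=1.055, stock_concentration=1.326e8)


@dataclass
class StandardCurve:
    """Per-channel fluorescence calibration: reading = slope*conc + intercept."""

    channel: str
    concentrations: np.ndarray
    readings: np.ndarray
    slope: float
    intercept: float
    r_squared: float

    @property
    def usable(self) -> bool:
        return self.slope > 0


@dataclass
class AqueousSample:
    """One timed anterior-chamber aqueous draw.

    ``readings`` maps channel -> fluorescence (a.u.); ``concentration`` is
    filled per channel after inversion against that channel's standard
    curve.  ``below_background`` flags channels whose reading fell below
    the curve intercept (clamped to zero concentration).
    """

    eye_id: str
    species: str
    time_h: float
    volume_ul: float
    readings: dict[str, float]
    concentration: dict[str, float] = field(default_factory=dict)
    below_background: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError("sample time must be non-negative")
        if self.volume_ul <= 0:
            raise ValueError("sample volume must be positive")


@dataclass(frozen=True)
class DispersionEstimate:
    """Fitted anterior accumulation rate for one species x bead size."""

    species: str
    size: str
    rate: float  # beads ml^-1 h^-1
    intercept: float  # beads/ml
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a dispersion estimate needs >= 2 points")


def beads_per_ml(S: float, rho: float, phi: float) -> float:
    """Bead count per ml of suspension from solids loading.

    ``6 S 1e12 / (rho pi phi^3)`` — the mass of suspended polymer divided
    by the mass of one sphere of diameter ``phi`` um.
    """
    if S < 0 or rho <= 0 or phi <= 0:
        raise ValueError("need S >= 0, rho > 0, phi > 0")
    return 6.0 * S * 1e12 / (rho * math.pi * phi**3)


def injected_dose(spec: BeadSpec, injected_volume_ul: float,
                  mix_fraction: float = 0.5) -> float:
    """Beads delivered by an injection of a stock mixture.

    ``mix_fraction`` is this stock's volume fraction in the injectate
    (0.5 for a 1:1 two-colour mix).
    """
    if not 0 < mix_fraction <= 1:
        raise ValueError("mix_fraction must be in (0, 1]")
    if injected_volume_ul < 0:
        raise ValueError("injected volume must be non-negative")
    return spec.stock_concentration * injected_volume_ul * mix_fraction / 1000.0


def make_dilution_series(stock: float, factor: float, n: int) -> np.ndarray:
    """Geometric serial dilution: stock/factor**k for k = 1..n."""
    if factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    if n < 1:
        raise ValueError("need at least one dilution")
    return stock / factor ** np.arange(1, n + 1, dtype=float)


def fit_standard_curve(concentrations, readings,
                       channel: str = "") -> StandardCurve:
    """OLS line through a serial-dilution standard series.

    Fit with a free intercept: plate readers have nonzero background, so
    forcing the line through the origin would bias low-concentration
    inversions.
    """
    conc = np.asarray(concentrations, dtype=float)
    reads = np.asarray(readings, dtype=float)
    if conc.size != reads.size or conc.size < 3:
        raise ValueError("need >= 3 paired standard points")
    if np.any(conc < 0):
        raise ValueError("standard concentrations must be non-negative")
    if np.ptp(conc) == 0:
        raise ValueError("degenerate standard design: all concentrations equal")
    fit = stats.linregress(conc, reads)
    return StandardCurve(channel=channel, concentrations=conc, readings=reads,
                         slope=float(fit.slope), intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue**2))


def reading_to_concentration(curve: StandardCurve,
                             reading: float) -> tuple[float, bool]:
    """Invert a plate reading against a standard curve.

    Returns ``(concentration, below_background)``.  Readings at or below
    the curve intercept clamp to zero concentration with the flag set;
    negative bead counts are not physical.
    """
    if curve.slope <= 0:
        raise ValueError(
            f"standard curve for channel {curve.channel!r} has non-positive "
            "slope and cannot be inverted")
    conc = (reading - curve.intercept) / curve.slope
    if conc <= 0:
        return 0.0, True
    return float(conc), False


def percent_injected(concentration: float, compartment_volume_ul: float,
                     dose: float) -> float:
    """Compartment bead content as a percentage of the injected dose.

    ``compartment_volume_ul`` is the anterior-chamber volume; it must be
    supplied explicitly (a species-level literature value, roughly
    250-300 ul for pig and human — this is deliberately not defaulted).
    """
    if dose <= 0:
        raise ValueError("injected dose must be positive")
    if compartment_volume_ul <= 0:
        raise ValueError("compartment volume must be positive")
    return 100.0 * concentration * compartment_volume_ul / 1000.0 / dose


def apply_standard_curve(samples: list[AqueousSample],
                         curves: dict[str, StandardCurve]) -> None:
    """Invert every sample reading in place against its channel's curve."""
    for sample in samples:
        for channel, reading in sample.readings.items():
            if channel not in curves:
                continue
            conc, flagged = reading_to_concentration(curves[channel], reading)
            sample.concentration[channel] = conc
            if flagged:
                sample.below_background.add(channel)


def dispersion_rate(samples: list[AqueousSample], channel: str, *,
                    species: str | None = None, size: str | None = None,
                    anchor_origin: bool = False) -> DispersionEstimate:
    """Anterior dispersion rate: OLS slope of concentration vs time.

    Fits only the sampled timepoints by default (the measured design is
    2 h and 4 h draws); set ``anchor_origin`` to include an implicit
    (0 h, 0 beads/ml) point for a pre-injection baseline.
    """
    pts = [(s.time_h, s.concentration[channel]) for s in samples
           if channel in s.concentration]
    if anchor_origin:
        pts.append((0.0, 0.0))
    if len(pts) < 2 or len({t for t, _ in pts}) < 2:
        raise ValueError("dispersion regression needs >= 2 distinct timepoints")
    t = np.array([p[0] for p in pts])
    c = np.array([p[1] for p in pts])
    fit = stats.linregress(t, c)
    sp = species or (samples[0].species if samples else "unknown")
    return DispersionEstimate(species=sp, size=size or channel,
                              rate=float(fit.slope),
                              intercept=float(fit.intercept),
                              n_points=len(pts))


def species_fold_ratio(rate_a: DispersionEstimate,
                       rate_b: DispersionEstimate) -> float:
    """Ratio of two dispersion rates (e.g. pig over human, same bead size)."""
    if rate_b.rate == 0:
        raise ValueError("denominator dispersion rate is zero")
    return rate_a.rate / rate_b.rate


def read_plate_csv(path: str | Path) -> tuple[dict[str, StandardCurve],
                                              list[AqueousSample]]:
    """Load a plate-reader CSV into fitted curves and samples.

    Expected columns: well, channel, reading_au, role {standard, sample};
    known_concentration for standards; eye_id, time_h, volume_ul for
    samples.  Standards are fit per channel; samples are returned with
    concentrations already inverted.
    """
    df = pd.read_csv(path)
    required = {"channel", "reading_au", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    curves: dict[str, StandardCurve] = {}
    standards = df[df["role"] == "standard"]
    for channel, grp in standards.groupby("channel"):
        curves[str(channel)] = fit_standard_curve(
            grp["known_concentration"], grp["reading_au"], channel=str(channel))

    samples: list[AqueousSample] = []
    rows = df[df["role"] == "sample"]
    for (eye_id, time_h), grp in rows.groupby(["eye_id", "time_h"]):
        readings = dict(zip(grp["channel"].astype(str), grp["reading_au"]))
        volume = float(grp["volume_ul"].iloc[0]) if "volume_ul" in grp else 30.0
        species = str(grp["species"].iloc[0]) if "species" in grp else "unknown"
        samples.append(AqueousSample(eye_id=str(eye_id), species=species,
                                     time_h=float(time_h), volume_ul=volume,
                                     readings=readings))
    samples.sort(key=lambda s: (s.eye_id, s.time_h))
    apply_standard_curve(samples, curves)
    return curves, samples
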