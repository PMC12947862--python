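"""Condensate partition coefficients and saturation concentrations.

The partition coefficient of a small molecule across a condensate boundary
is the dense-phase/light-phase signal ratio, with the dense-phase signal
corrected by the dilution factor introduced when the condensates are
resuspended for analysis:

    P = (dense_signal * dilution_factor) / light_signal

Saturation concentrations (c_sat) come from a linear calibration curve
relating known concentrations to chromatographic peak integrals, applied
to the dilute-phase (supernatant) signal.  Peak integration itself happens
upstream in the chromatography software; this module consumes scalar
signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class PhaseMeasurement:
    """Light/dense phase signals for one condition.

    ``quantitation_mode`` records whether peak areas or peak heights were
    used (heights are preferred when peak-shape deviations bias areas);
    both phases must use the same mode.
    """

    light_signal: float
    dense_signal: float
    dilution_factor: float = 1.0
    quantitation_mode: str = "area"
    condition: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.light_signal < 0 or self.dense_signal < 0:
            raise ValueError("signals must be non-negative")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.quantitation_mode not in ("area", "height"):
            raise ValueError("quantitation_mode must be 'area' or 'height'")


@dataclass
class PartitionCoefficient:
    p: float  # dimensionless dense/light ratio; NaN when undefined
    condition: dict = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return math.isfinite(self.p)


def partition_coefficient(meas: PhaseMeasurement) -> PartitionCoefficient:
    """P = dense * dilution / light; undefined (NaN) when light = 0."""
    if meas.light_signal == 0:
        return PartitionCoefficient(math.nan, meas.condition)
    p = meas.dense_signal * meas.dilution_factor / meas.light_signal
    return PartitionCoefficient(p, meas.condition)


@dataclass
class CalibrationCurve:
    """Linear concentration-vs-signal calibration, fitted on construction."""

    concentrations: np.ndarray
    signals: np.ndarray
    slope: float = field(init=False)
    intercept: float = field(init=False)
    r_squared: float = field(init=False)

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if len(self.concentrations) < 3:
            raise ValueError("need >= 3 calibration points")
        fit = stats.linregress(self.concentrations, self.signals)
        if fit.slope <= 0:
            raise ValueError("calibration slope must be positive")
        self.slope = float(fit.slope)
        self.intercept = float(fit.intercept)
        self.r_squared = float(fit.rvalue ** 2)


@dataclass
class CalibratedConcentration:
    concentration: float
    extrapolated: bool


def calibrate_concentration(
    curve: CalibrationCurve, signal: float
) -> CalibratedConcentration:
    """Invert the calibration line; flags signals outside the fitted range.

    Signals beyond twice the calibrated signal range are rejected as out
    of the curve's validity; signals outside but within 2x are returned
    with an extrapolation flag.
    """
    lo, hi = curve.signals.min(), curve.signals.max()
    span = hi - lo
    if signal > hi + span or signal < lo - span:
        raise ValueError(
            f"signal {signal} outside 2x the calibration range [{lo}, {hi}]"
        )
    conc = (signal - curve.intercept) / curve.slope
    return CalibratedConcentration(float(conc), not (lo <= signal <= hi))


def saturation_concentration(
    curve: CalibrationCurve, supernatant_signal: float
) -> CalibratedConcentration:
    """c_sat = calibrated concentration of the dilute-phase signal.

    A reduced c_sat relative to the reference condition indicates enhanced
    condensation.
    """
    return calibrate_concentration(curve, supernatant_signal)


@dataclass
class ReplicateSummary:
    mean: float
    sd: float
    n: int


def replicate_summary(values) -> ReplicateSummary:
    """Mean and sample SD over replicate measurements (n >= 3 recommended)."""
    v = np.asarray(list(values), dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return ReplicateSummary(math.nan, math.nan, 0)
    sd = float(v.std(ddof=1)) if len(v) > 1 else math.nan
    return ReplicateSummary(float(v.mean()), sd, len(v))
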