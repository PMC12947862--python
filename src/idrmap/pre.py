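"""Paramagnetic relaxation enhancement (PRE) analysis.

Per-residue transverse relaxation rates R₂ are obtained by fitting
mono-exponential decays I(t) = I₀·exp(−R₂·t) to signal intensities
measured at a series of relaxation delays (default grid 1, 2, 5, 10, 20
and 60 ms).  The PRE is the rate difference between paramagnetic and
diamagnetic samples, Γ₂ = R₂(para) − R₂(dia), with its uncertainty taken
in quadrature from the two fit standard errors.  Intensity-ratio profiles
(I_para/I_dia at a fixed delay) provide a model-free readout with
first-order error propagation.

Delays are supplied in ms; all rates are reported in s⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

#: Default relaxation-delay grid in ms.
DEFAULT_DELAYS_MS = (1.0, 2.0, 5.0, 10.0, 20.0, 60.0)

#: Built-in region definitions, inclusive construct coordinates.
REGIONS = {"h2": (391, 403), "h3": (433, 437), "cterm": (479, 558)}


@dataclass
class DecaySeries:
    """Intensity versus relaxation delay for one residue in one condition."""

    residue_index: int
    delays_ms: np.ndarray
    intensities: np.ndarray
    condition: str = "para"
    sigma: float | None = None  # intensity noise floor, same units as I

    def __post_init__(self):
        self.delays_ms = np.asarray(self.delays_ms, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.delays_ms) != len(self.intensities):
            raise ValueError("delays and intensities differ in length")
        if len(np.unique(self.delays_ms)) < 3:
            raise ValueError("need >= 3 distinct delays")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite intensities")


@dataclass
class R2Fit:
    residue_index: int
    i0: float
    r2: float  # s^-1
    stderr_r2: float
    converged: bool


def _decay(t, i0, r2):
    return i0 * np.exp(-r2 * t)


def fit_exponential_r2(series: DecaySeries) -> R2Fit:
    """Least-squares mono-exponential fit; rate bounded at zero.

    Initial guesses: I₀ from the first point, R₂ from the log ratio of the
    first and last intensities.  Non-convergence returns an unconverged fit
    that downstream steps exclude.
    """
    order = np.argsort(series.delays_ms)
    t = series.delays_ms[order] / 1e3  # s
    y = series.intensities[order]
    if y[0] <= 0:
        return R2Fit(series.residue_index, math.nan, math.nan, math.nan, False)
    i0_guess = y[0]
    span = t[-1] - t[0]
    if y[-1] > 0 and span > 0:
        r2_guess = max(0.0, math.log(y[0] / y[-1]) / span)
    else:
        r2_guess = 100.0
    try:
        popt, pcov = curve_fit(
            _decay, t, y,
            p0=[i0_guess, r2_guess],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=10_000,
        )
    except (RuntimeError, ValueError):
        return R2Fit(series.residue_index, math.nan, math.nan, math.nan, False)
    stderr = float(np.sqrt(np.diag(pcov))[1]) if np.all(np.isfinite(pcov)) \
        else math.nan
    return R2Fit(series.residue_index, float(popt[0]), float(popt[1]),
                 stderr, True)


@dataclass
class PREProfile:
    """Per-residue Γ₂ (s⁻¹) with propagated standard errors."""

    residues: np.ndarray
    gamma2: np.ndarray
    stderr: np.ndarray
    condition: str = "apo"

    def as_dict(self) -> dict[int, float]:
        return {int(r): float(g) for r, g in zip(self.residues, self.gamma2)
                if np.isfinite(g)}


def compute_gamma2(para: R2Fit, dia: R2Fit) -> tuple[float, float]:
    """Γ₂ = R₂(para) − R₂(dia) and its quadrature standard error."""
    if para.residue_index != dia.residue_index:
        raise ValueError("residue mismatch between para and dia fits")
    if not (para.converged and dia.converged):
        return math.nan, math.nan
    gamma2 = para.r2 - dia.r2
    stderr = math.sqrt(para.stderr_r2 ** 2 + dia.stderr_r2 ** 2)
    return gamma2, stderr


def gamma2_profile(
    para_fits: list[R2Fit], dia_fits: list[R2Fit], condition: str = "apo"
) -> PREProfile:
    """Pair para/dia fits by residue and compute the Γ₂ profile.

    Residues where either fit is absent or unconverged are NaN.
    """
    dia_by_res = {f.residue_index: f for f in dia_fits}
    residues, gamma2, stderr = [], [], []
    for pf in para_fits:
        df = dia_by_res.get(pf.residue_index)
        residues.append(pf.residue_index)
        if df is None:
            gamma2.append(math.nan)
            stderr.append(math.nan)
        else:
            g, s = compute_gamma2(pf, df)
            gamma2.append(g)
            stderr.append(s)
    return PREProfile(np.array(residues), np.array(gamma2), np.array(stderr),
                      condition)


@dataclass
class IntensityRatioProfile:
    residues: np.ndarray
    ratio: np.ndarray
    stderr: np.ndarray
    delay_ms: float


def intensity_ratio_profile(
    para: list[DecaySeries],
    dia: list[DecaySeries],
    delay_ms: float = 1.0,
) -> IntensityRatioProfile:
    """I_para/I_dia at a fixed delay with first-order error propagation.

    σ_ratio = ratio * sqrt((σ_para/I_para)² + (σ_dia/I_dia)²) using each
    series' noise floor; NaN stderr when no noise floor is supplied.
    Residues with non-positive diamagnetic intensity are undefined.
    """
    def at_delay(series: DecaySeries) -> float | None:
        hit = np.isclose(series.delays_ms, delay_ms)
        return float(series.intensities[hit][0]) if hit.any() else None

    dia_by_res = {s.residue_index: s for s in dia}
    residues, ratios, stderrs = [], [], []
    for ps in para:
        ds = dia_by_res.get(ps.residue_index)
        if ds is None:
            continue
        ip, id_ = at_delay(ps), at_delay(ds)
        if ip is None or id_ is None:
            continue
        residues.append(ps.residue_index)
        if id_ <= 0:
            ratios.append(math.nan)
            stderrs.append(math.nan)
            continue
        r = ip / id_
        ratios.append(r)
        if ps.sigma is not None and ds.sigma is not None and ip != 0:
            stderrs.append(abs(r) * math.sqrt(
                (ps.sigma / ip) ** 2 + (ds.sigma / id_) ** 2))
        else:
            stderrs.append(math.nan)
    return IntensityRatioProfile(
        np.array(residues), np.array(ratios), np.array(stderrs), delay_ms
    )


@dataclass
class RegionAverage:
    region: str
    residue_range: tuple[int, int]
    mean: float
    n: int
    quantity: str = "gamma2"


def region_average(
    profile: PREProfile,
    region: str | tuple[int, int],
    quantity: str = "gamma2",
) -> RegionAverage:
    """Unweighted mean over defined residues in an inclusive coordinate range.

    ``region`` is a built-in name ("h2", "h3", "cterm") or an explicit
    (start, stop) tuple.  NaN mean when no residue in the range is defined.
    """
    if isinstance(region, str):
        name, (lo, hi) = region, REGIONS[region]
    else:
        lo, hi = region
        name = f"{lo}-{hi}"
    inside = (profile.residues >= lo) & (profile.residues <= hi)
    vals = profile.gamma2[inside]
    vals = vals[np.isfinite(vals)]
    mean = float(vals.mean()) if len(vals) else math.nan
    return RegionAverage(name, (lo, hi), mean, len(vals), quantity)


def delta_gamma2(holo: PREProfile, apo: PREProfile) -> PREProfile:
    """Residue-wise ΔΓ₂ = Γ₂(holo) − Γ₂(apo) with quadrature errors."""
    apo_map = {int(r): (g, s) for r, g, s in
               zip(apo.residues, apo.gamma2, apo.stderr)}
    residues, diff, stderr = [], [], []
    for r, g, s in zip(holo.residues, holo.gamma2, holo.stderr):
        residues.append(int(r))
        if int(r) in apo_map and np.isfinite(g):
            ga, sa = apo_map[int(r)]
            diff.append(g - ga)
            stderr.append(math.sqrt(s ** 2 + sa ** 2)
                          if np.isfinite(s) and np.isfinite(sa) else math.nan)
        else:
            diff.append(math.nan)
            stderr.append(math.nan)
    return PREProfile(np.array(residues), np.array(diff), np.array(stderr),
                      condition="delta")
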