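"""Equilibrium fits: cysteine pKa, Hill binding isotherms, cloud points.

Three closed-form response models:

* pKa from pH-dependent ¹³Cβ chemical shifts of a cysteine,
  δ(pH) = 1 / (1 + 10^(pKa − pH)) + δ_offset, on a min-max normalized
  shift scale; 95% confidence intervals by Monte-Carlo residual
  resampling.
* Dissociation constant from a thermophoresis binding isotherm via the
  Hill equation F(c) = F_unbound + (F_bound − F_unbound)/(1 + (Kd/c)^n),
  optionally anchoring the bound plateau at the highest measured
  concentration.
* Cloud temperature Tc of a turbidity ramp as the interior peak of the
  (optionally smoothed) first derivative of absorbance vs temperature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


# ---------------------------------------------------------------------------
# Cysteine pKa
# ---------------------------------------------------------------------------


def pka_model(ph: np.ndarray, pka: float, offset: float) -> np.ndarray:
    """Normalized titration sigmoid: 1/(1 + 10^(pKa − pH)) + offset."""
    return 1.0 / (1.0 + 10.0 ** (pka - ph)) + offset


@dataclass
class PKaFit:
    pka: float
    offset: float
    ci_low: float
    ci_high: float
    n_mc: int
    seed: int
    residual_rms: float


def normalize_shifts(shifts: np.ndarray) -> np.ndarray:
    """Min-max normalization of the shift axis onto [0, 1]."""
    shifts = np.asarray(shifts, dtype=float)
    lo, hi = shifts.min(), shifts.max()
    if hi == lo:
        raise ValueError("flat titration: no transition to normalize")
    return (shifts - lo) / (hi - lo)


def fit_pka(
    ph: np.ndarray,
    shifts: np.ndarray,
    normalize: str | bool = "auto",
    n_mc: int = 1000,
    seed: int = 0,
) -> PKaFit:
    """Fit the titration sigmoid and bootstrap a 95% CI for the pKa.

    ``normalize``: "minmax" (or True) rescales raw shifts onto [0, 1]
    before fitting the unit-amplitude sigmoid; "none" (or False) fits the
    data as given; "auto" (default) normalizes only when the data do not
    already span a unit-amplitude scale.

    The Monte-Carlo interval refits ``n_mc`` synthetic datasets built from
    the fitted curve plus Gaussian noise with SD equal to the dof-corrected
    residual SD, and quotes pKa ± t(0.975, n-2) times the SD of the refit
    pKa values (the Student-t factor accounts for the noise scale being
    estimated from few points).
    """
    ph = np.asarray(ph, dtype=float)
    y = np.asarray(shifts, dtype=float)
    if len(ph) < 5:
        raise ValueError("need >= 5 titration points")
    if np.any((ph <= 0) | (ph >= 14)):
        raise ValueError("pH values must lie strictly within (0, 14)")
    if normalize == "auto":
        span = y.max() - y.min()
        normalize = not (0.5 <= span <= 1.5)
    if normalize in (True, "minmax"):
        y = normalize_shifts(y)
    elif normalize not in (False, "none"):
        raise ValueError(f"unknown normalize mode {normalize!r}")

    mid = y.min() + 0.5 * (y.max() - y.min())
    p0 = [float(ph[np.argmin(np.abs(y - mid))]), float(y.min())]
    try:
        popt, _ = curve_fit(pka_model, ph, y, p0=p0, maxfev=10_000)
    except RuntimeError as err:
        raise RuntimeError("pKa fit did not converge; no transition "
                           "within the sampled pH range?") from err
    resid = y - pka_model(ph, *popt)
    # residual SD with dof correction (2 fitted parameters) so the
    # resampling noise matches the data noise without downward bias
    rms = float(np.sqrt(np.sum(resid ** 2) / max(len(ph) - 2, 1)))

    rng = np.random.default_rng(seed)
    samples = []
    yhat = pka_model(ph, *popt)
    for _ in range(n_mc):
        ysim = yhat + rng.normal(0.0, rms if rms > 0 else 1e-12, size=len(ph))
        try:
            psim, _ = curve_fit(pka_model, ph, ysim, p0=popt, maxfev=5_000)
        except RuntimeError:
            continue
        samples.append(psim[0])
    if len(samples) > 1:
        from scipy import stats

        half = stats.t.ppf(0.975, max(len(ph) - 2, 1)) * \
            float(np.std(samples, ddof=1))
        ci_low, ci_high = popt[0] - half, popt[0] + half
    else:
        ci_low = ci_high = math.nan
    return PKaFit(float(popt[0]), float(popt[1]), float(ci_low),
                  float(ci_high), n_mc, seed, rms)


# ---------------------------------------------------------------------------
# Hill binding isotherm
# ---------------------------------------------------------------------------


def hill_model(c, kd, n, f_unbound, f_bound):
    """F(c) = F_u + (F_b − F_u) / (1 + (Kd/c)^n)."""
    c = np.asarray(c, dtype=float)
    return f_unbound + (f_bound - f_unbound) / (1.0 + (kd / c) ** n)


@dataclass
class HillFit:
    kd: float  # same units as the concentration axis
    hill_n: float
    f_unbound: float
    f_bound: float
    stderr_kd: float
    stderr_n: float
    anchored: bool


def fit_hill(
    concentrations: np.ndarray,
    f_norm: np.ndarray,
    anchor_bound: bool = True,
) -> HillFit:
    """Fit the Hill equation to a (concentration, F_norm) isotherm.

    With ``anchor_bound`` (default) the bound-plateau response is fixed to
    the F_norm value at the highest concentration, mirroring titrations
    truncated at a solubility limit; otherwise it is a free parameter.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(f_norm, dtype=float)
    if len(c) < 5:
        raise ValueError("need >= 5 concentrations")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    order = np.argsort(c)
    c, y = c[order], y[order]
    if abs(y[-1] - y[0]) < 1e-12:
        raise ValueError("degenerate isotherm: plateaus coincide")
    diffs = np.diff(y)
    if np.any(diffs * (y[-1] - y[0]) < -3 * np.std(diffs)):
        warnings.warn("isotherm is non-monotonic beyond noise", stacklevel=2)

    kd0 = float(np.sqrt(c[0] * c[-1]))
    fu0, fb0 = float(y[0]), float(y[-1])
    if anchor_bound:
        fb = float(y[-1])

        def model(cc, kd, n, fu):
            return hill_model(cc, kd, n, fu, fb)

        popt, pcov = curve_fit(
            model, c, y, p0=[kd0, 1.0, fu0],
            bounds=([1e-12, 0.05, -np.inf], [np.inf, 20.0, np.inf]),
            maxfev=20_000,
        )
        kd, n, fu = popt
    else:
        popt, pcov = curve_fit(
            hill_model, c, y, p0=[kd0, 1.0, fu0, fb0],
            bounds=([1e-12, 0.05, -np.inf, -np.inf],
                    [np.inf, 20.0, np.inf, np.inf]),
            maxfev=20_000,
        )
        kd, n, fu, fb = popt
    err = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else \
        np.full(len(popt), np.nan)
    return HillFit(float(kd), float(n), float(fu), float(fb),
                   float(err[0]), float(err[1]), anchor_bound)


# ---------------------------------------------------------------------------
# Cloud point from turbidity
# ---------------------------------------------------------------------------


@dataclass
class CloudPoint:
    tc: float  # deg C
    at_boundary: bool
    derivative: np.ndarray
    smooth_window: int


def cloud_point(
    temperatures: np.ndarray,
    absorbance: np.ndarray,
    smooth_window: int = 5,
    refine: bool = True,
) -> CloudPoint:
    """Cloud temperature = peak of the first derivative of A(T).

    The centered finite-difference derivative is smoothed with a centered
    moving average (``smooth_window`` points, 1 disables smoothing) before
    peak picking; ties break toward lower temperature.  With ``refine``
    (default) the interior peak is localized below the grid resolution by
    the vertex of a quadratic fitted to the smoothed derivative around the
    argmax.  ``at_boundary`` is set when the maximum falls on the first or
    last grid point, indicating no interior transition (no refinement is
    attempted there).
    """
    t = np.asarray(temperatures, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if len(t) < 10:
        raise ValueError("need >= 10 temperature points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("temperature grid must be strictly increasing")
    deriv = np.gradient(a, t)
    if smooth_window > 1:
        w = smooth_window
        kernel = np.ones(w) / w
        # centered moving average with edge shrinkage
        padded = np.convolve(deriv, kernel, mode="same")
        norm = np.convolve(np.ones_like(deriv), kernel, mode="same")
        deriv = padded / norm
    # ties (within float noise of the max) break toward lower temperature
    m = deriv.max()
    tol = 1e-9 * max(1.0, abs(m))
    idx = int(np.argmax(deriv >= m - tol))
    at_boundary = idx in (0, len(t) - 1)
    tc = float(t[idx])
    if refine and not at_boundary:
        half = max(smooth_window, 2)
        lo, hi = max(0, idx - half), min(len(t), idx + half + 1)
        if hi - lo >= 3:
            coeff = np.polyfit(t[lo:hi], deriv[lo:hi], 2)
            if coeff[0] < 0:
                vertex = -coeff[1] / (2 * coeff[0])
                if t[lo] <= vertex <= t[hi - 1]:
                    tc = float(vertex)
    return CloudPoint(
        tc=tc,
        at_boundary=at_boundary,
        derivative=deriv,
        smooth_window=smooth_window,
    )
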