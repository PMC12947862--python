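"""Chemical shift perturbation (CSP) profiles and summary statistics.

A :class:`ShiftTable` holds per-residue amide assignments (δ¹H, δ¹⁵N) for
one construct in one condition.  Comparing two conditions yields a
:class:`CSPProfile` with the combined perturbation

    CSP_i = sqrt( (Δδ¹H_i)² + (Δδ¹⁵N_i / 5)² )

where the ¹⁵N difference is down-weighted by 5 to place both nuclei on a
comparable ppm scale.  Missing assignments (overlap, broadening, prolines)
are encoded as NaN and excluded from every statistic — never as zeros.

The significance threshold follows the first-quartile rule: the mean of the
lowest 25% of defined CSPs plus five times their standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Scaling divisor applied to the ¹⁵N shift difference.
NITROGEN_SCALE = 5.0

SHIFT_COLUMNS = ["residue_index", "residue_type", "dH_ppm", "dN_ppm"]


@dataclass
class ShiftTable:
    """Per-residue amide shift assignments for one construct/condition.

    ``data`` columns: residue_index (int, unique, 1-based construct
    coordinates), residue_type (one-letter), dH_ppm, dN_ppm (NaN = missing).
    """

    construct_id: str
    condition: str
    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in SHIFT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"shift table missing columns: {missing}")
        if self.data["residue_index"].duplicated().any():
            dup = self.data.loc[
                self.data["residue_index"].duplicated(), "residue_index"
            ].tolist()
            raise ValueError(f"duplicate residue rows: {dup}")
        self.data = self.data.sort_values("residue_index").reset_index(drop=True)

    def assigned(self) -> pd.DataFrame:
        """Rows where both shifts are present."""
        m = self.data["dH_ppm"].notna() & self.data["dN_ppm"].notna()
        return self.data[m]


@dataclass
class CSPProfile:
    """Per-residue CSP values (ppm) on a contiguous construct coordinate range.

    ``values[i]`` corresponds to construct coordinate ``start + i``; NaN
    marks residues unassigned in either condition.
    """

    construct_id: str
    start: int
    values: np.ndarray
    reference_condition: str = "apo"
    perturbed_condition: str = "holo"

    @property
    def residues(self) -> np.ndarray:
        return np.arange(self.start, self.start + len(self.values))

    def defined(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]

    def __len__(self) -> int:
        return len(self.values)


def compute_csp(
    reference: ShiftTable,
    perturbed: ShiftTable,
    construct_range: tuple[int, int] | None = None,
    nitrogen_scale: float = NITROGEN_SCALE,
) -> CSPProfile:
    """Combined ¹H/¹⁵N chemical shift perturbation per residue.

    Residues missing in either table are NaN in the profile.  The profile
    spans ``construct_range`` (inclusive) when given, otherwise the union
    of residue indices present in the two tables.
    """
    if reference.construct_id != perturbed.construct_id:
        raise ValueError(
            f"construct mismatch: {reference.construct_id!r} vs "
            f"{perturbed.construct_id!r}"
        )
    ref = reference.assigned().set_index("residue_index")
    per = perturbed.assigned().set_index("residue_index")
    common = ref.index.intersection(per.index)
    if len(common) == 0:
        raise ValueError("no residues assigned in both conditions")
    if construct_range is None:
        lo = int(min(reference.data["residue_index"].min(),
                     perturbed.data["residue_index"].min()))
        hi = int(max(reference.data["residue_index"].max(),
                     perturbed.data["residue_index"].max()))
    else:
        lo, hi = construct_range
        if hi < lo:
            raise ValueError("empty construct range")
    values = np.full(hi - lo + 1, np.nan)
    dH = (per.loc[common, "dH_ppm"] - ref.loc[common, "dH_ppm"]).to_numpy()
    dN = (per.loc[common, "dN_ppm"] - ref.loc[common, "dN_ppm"]).to_numpy()
    csp = np.sqrt(dH ** 2 + (dN / nitrogen_scale) ** 2)
    inside = (common >= lo) & (common <= hi)
    values[common.to_numpy()[inside] - lo] = csp[inside]
    return CSPProfile(
        construct_id=reference.construct_id,
        start=lo,
        values=values,
        reference_condition=reference.condition,
        perturbed_condition=perturbed.condition,
    )


def significance_threshold(
    profile: CSPProfile | np.ndarray, sd: str = "sample"
) -> float:
    """First-quartile significance threshold: mean(Q1) + 5 * SD(Q1).

    Q1 is the floor(n/4) smallest defined CSPs (at least 2); SD is the
    sample (n-1) standard deviation by default, population via
    ``sd="population"``.
    """
    values = profile.defined() if isinstance(profile, CSPProfile) else \
        np.asarray(profile, dtype=float)
    values = values[np.isfinite(values)]
    n = len(values)
    if n < 4:
        raise ValueError(f"need >= 4 defined CSP values, got {n}")
    q = max(2, n // 4)
    q1 = np.sort(values)[:q]
    ddof = 1 if sd == "sample" else 0
    return float(q1.mean() + 5.0 * q1.std(ddof=ddof))


@dataclass
class CSPSummary:
    """Mean CSP over residues at or above the significance threshold."""

    threshold: float
    retained_residues: np.ndarray
    mean_csp: float
    sem: float
    n_retained: int = field(default=0)


def summarize_csp(profile: CSPProfile, sd: str = "sample") -> CSPSummary:
    """Threshold the profile and average the retained residues.

    SEM = SD(retained, n-1) / sqrt(n_retained); NaN when fewer than two
    residues are retained (mean NaN when none are).
    """
    threshold = significance_threshold(profile, sd=sd)
    finite = np.isfinite(profile.values)
    keep = finite & (profile.values >= threshold)
    retained = profile.values[keep]
    n = len(retained)
    if n == 0:
        return CSPSummary(threshold, profile.residues[keep], math.nan,
                          math.nan, 0)
    mean = float(retained.mean())
    sem = float(retained.std(ddof=1) / np.sqrt(n)) if n > 1 else math.nan
    return CSPSummary(threshold, profile.residues[keep], mean, sem, n)
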