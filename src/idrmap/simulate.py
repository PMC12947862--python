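"""Synthetic inputs with planted ground truth for every analysis stage.

Generators emulate the experimental observables the analysis modules
consume: IDR-like sequences with a tunable aromatic-clustering target,
reciprocal-titration shift tables with planted interacting segments,
mono-exponential PRE decay sets with a planted Γ₂ profile, and the three
closed-form response curves (pH titration, Hill isotherm, turbidity ramp).
Every generator is a pure function of its parameters and seed.

Default noise levels reflect the corresponding measurements: additive
Gaussian noise on chemical shifts (~0.002 ppm on ¹H, scaled 5x on ¹⁵N),
multiplicative noise on NMR signal intensities (~1%), and additive noise
on absorbance and normalized fluorescence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .csp import ShiftTable, compute_csp
from .cspmatrix import ReciprocalTitration
from .fits import hill_model, pka_model
from .pre import DEFAULT_DELAYS_MS, DecaySeries
from .sequences import AROMATIC, ProteinSequence, aromatic_clustering, \
    ideal_positions

#: Activation-domain-like residue composition (polar/P/G rich, low charge,
#: sparse aromatics) used when no composition is supplied.
DEFAULT_COMPOSITION = {
    "S": 0.12, "Q": 0.10, "G": 0.08, "P": 0.08, "A": 0.10, "T": 0.06,
    "N": 0.04, "H": 0.02, "C": 0.005, "L": 0.08, "I": 0.03, "V": 0.05,
    "M": 0.02, "F": 0.03, "Y": 0.02, "W": 0.005, "K": 0.04, "R": 0.03,
    "D": 0.04, "E": 0.05,
}


def _counts_from_composition(length: int, composition: dict[str, float]):
    """Largest-remainder rounding of fractional composition to counts."""
    total = sum(composition.values())
    raw = {r: f / total * length for r, f in composition.items()}
    counts = {r: int(np.floor(v)) for r, v in raw.items()}
    short = length - sum(counts.values())
    remainders = sorted(raw, key=lambda r: raw[r] - counts[r], reverse=True)
    for r in remainders[:short]:
        counts[r] += 1
    return {r: c for r, c in counts.items() if c > 0}


def gen_sequence(
    length: int = 150,
    composition: dict[str, float] | None = None,
    omega_band: tuple[float, float] | None = None,
    seed: int = 0,
    seq_id: str = "sim",
    numbering_offset: int = 1,
    max_tries: int = 2000,
) -> ProteinSequence:
    """Composition-constrained random sequence, optional clustering target.

    The composition (fractions or counts) is met exactly after
    largest-remainder rounding.  When ``omega_band`` is given, aromatic
    placements are rejection-sampled until the normalized aromatic
    clustering score falls inside the band; if sampling fails, placements
    interpolated between the ideally spaced and fully clustered reference
    arrangements are scanned deterministically.
    """
    rng = np.random.default_rng(seed)
    counts = _counts_from_composition(length, composition or
                                      DEFAULT_COMPOSITION)
    letters = [r for r, c in counts.items() for _ in range(c)]
    rng.shuffle(letters)
    if omega_band is None:
        return ProteinSequence(seq_id, "".join(letters), numbering_offset)

    lo, hi = omega_band
    aromatics = [r for r in letters if r in AROMATIC]
    others = [r for r in letters if r not in AROMATIC]
    k = len(aromatics)
    if k < 2:
        raise ValueError("composition yields <2 aromatics; no clustering "
                         "target is definable")

    def build(positions: np.ndarray) -> str:
        out = [""] * length
        rng2 = np.random.default_rng(seed + 1)
        aro = list(aromatics)
        rng2.shuffle(aro)
        oth = list(others)
        rng2.shuffle(oth)
        posset = set(int(p) for p in positions)
        ai = 0
        oi = 0
        for i in range(length):
            if (i + 1) in posset:
                out[i] = aro[ai]
                ai += 1
            else:
                out[i] = oth[oi]
                oi += 1
        return "".join(out)

    def norm_of(positions: np.ndarray) -> float:
        seq = ProteinSequence(seq_id, build(positions), numbering_offset)
        return aromatic_clustering(seq).norm

    for _ in range(max_tries):
        positions = np.sort(rng.choice(length, size=k, replace=False)) + 1
        v = norm_of(positions)
        if np.isfinite(v) and lo <= v <= hi:
            return ProteinSequence(seq_id, build(positions), numbering_offset)

    # deterministic fallback: interpolate ideal -> clustered placements
    ideal = ideal_positions(length, k).astype(float)
    block0 = max(1, (length - k) // 2 + 1)
    clustered = np.arange(block0, block0 + k, dtype=float)
    for t in np.linspace(0.0, 1.0, 201):
        pos = np.round((1 - t) * ideal + t * clustered).astype(int)
        pos = np.clip(pos, 1, length)
        for i in range(1, k):  # resolve rounding collisions
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
        if pos[-1] > length:
            continue
        v = norm_of(pos)
        if np.isfinite(v) and lo <= v <= hi:
            return ProteinSequence(seq_id, build(pos), numbering_offset)
    raise ValueError(f"no aromatic arrangement found in band ({lo}, {hi})")


# ---------------------------------------------------------------------------
# Reciprocal titration pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Construct:
    """A construct: id plus inclusive residue range in domain coordinates."""

    id: str
    start: int
    length: int

    @property
    def stop(self) -> int:
        return self.start + self.length - 1


def gaussian_bump(
    length: int, start: int, segment: tuple[int, int], amplitude: float
) -> np.ndarray:
    """Gaussian-shaped CSP bump centered on a residue segment.

    ``segment`` is inclusive construct coordinates; the bump SD is a
    quarter of the segment length so the perturbation is localized.
    """
    coords = np.arange(start, start + length)
    center = 0.5 * (segment[0] + segment[1])
    sd = max((segment[1] - segment[0] + 1) / 4.0, 0.5)
    return amplitude * np.exp(-0.5 * ((coords - center) / sd) ** 2)


@dataclass
class SimulatedTitrationPair:
    """Reciprocal titration tables with the planted truth attached."""

    reference_a: ShiftTable
    perturbed_a: ShiftTable
    reference_b: ShiftTable
    perturbed_b: ShiftTable
    pair: ReciprocalTitration
    true_csp_a: np.ndarray
    true_csp_b: np.ndarray
    segment_a: tuple[int, int]
    segment_b: tuple[int, int]


def _shift_tables_for(
    construct: Construct,
    true_csp: np.ndarray,
    noise_sd: float,
    n_missing_runs: int,
    missing_run_length: int,
    rng: np.random.Generator,
    condition: str,
) -> tuple[ShiftTable, ShiftTable]:
    n = construct.length
    residues = np.arange(construct.start, construct.start + n)
    types = rng.choice(list("ACDEFGHIKLMNQRSTVWY"), size=n)  # no prolines
    dh = rng.uniform(7.8, 8.6, size=n)
    dn = rng.uniform(108.0, 128.0, size=n)
    # split the planted CSP between the two nuclei at a random angle
    theta = rng.uniform(0.0, np.pi / 2, size=n)
    sign_h = rng.choice([-1.0, 1.0], size=n)
    sign_n = rng.choice([-1.0, 1.0], size=n)
    ddh = sign_h * true_csp * np.cos(theta)
    ddn = sign_n * 5.0 * true_csp * np.sin(theta)
    dh_pert = dh + ddh + rng.normal(0.0, noise_sd, size=n)
    dn_pert = dn + ddn + rng.normal(0.0, 5.0 * noise_sd, size=n)

    missing = np.zeros(n, dtype=bool)
    for _ in range(n_missing_runs):
        if n <= missing_run_length:
            break
        s = rng.integers(0, n - missing_run_length)
        missing[s:s + missing_run_length] = True
    dh = np.where(missing, np.nan, dh)
    dn = np.where(missing, np.nan, dn)
    dh_pert = np.where(missing, np.nan, dh_pert)
    dn_pert = np.where(missing, np.nan, dn_pert)

    def table(h, nn, cond):
        return ShiftTable(
            construct.id, cond,
            pd.DataFrame({
                "residue_index": residues,
                "residue_type": types,
                "dH_ppm": h,
                "dN_ppm": nn,
            }),
        )

    return table(dh, dn, "reference"), table(dh_pert, dn_pert, condition)


def gen_titration_pair(
    construct_a: Construct = Construct("A", 1, 80),
    construct_b: Construct = Construct("B", 101, 60),
    segment_a: tuple[int, int] | None = None,
    segment_b: tuple[int, int] | None = None,
    amplitude: float = 0.03,
    noise_sd: float = 0.002,
    n_missing_runs: int = 1,
    missing_run_length: int = 5,
    seed: int = 0,
    condition: str = "mixed",
) -> SimulatedTitrationPair:
    """Reciprocal titration with planted interacting segments.

    Each construct's CSP profile carries a Gaussian bump (peak ``amplitude``
    ppm, localized on its interacting segment — default a 10-residue window
    in the middle of the construct) over shift noise applied to the
    perturbed spectra only.  Zero amplitude yields pure-noise profiles
    whose CSPs follow a Rayleigh law with scale ``noise_sd``.
    """
    if segment_a is None:
        mid = construct_a.start + construct_a.length // 2
        segment_a = (mid - 5, mid + 4)
    if segment_b is None:
        mid = construct_b.start + construct_b.length // 2
        segment_b = (mid - 5, mid + 4)
    for seg, con in ((segment_a, construct_a), (segment_b, construct_b)):
        if seg[0] < con.start or seg[1] > con.stop:
            raise ValueError(f"segment {seg} outside construct "
                             f"{con.id} ({con.start}-{con.stop})")
    rng = np.random.default_rng(seed)
    true_a = gaussian_bump(construct_a.length, construct_a.start, segment_a,
                           amplitude)
    true_b = gaussian_bump(construct_b.length, construct_b.start, segment_b,
                           amplitude)
    ref_a, pert_a = _shift_tables_for(
        construct_a, true_a, noise_sd, n_missing_runs, missing_run_length,
        rng, condition)
    ref_b, pert_b = _shift_tables_for(
        construct_b, true_b, noise_sd, n_missing_runs, missing_run_length,
        rng, condition)
    profile_a = compute_csp(ref_a, pert_a,
                            construct_range=(construct_a.start,
                                             construct_a.stop))
    profile_b = compute_csp(ref_b, pert_b,
                            construct_range=(construct_b.start,
                                             construct_b.stop))
    return SimulatedTitrationPair(
        reference_a=ref_a, perturbed_a=pert_a,
        reference_b=ref_b, perturbed_b=pert_b,
        pair=ReciprocalTitration(profile_a, profile_b),
        true_csp_a=true_a, true_csp_b=true_b,
        segment_a=segment_a, segment_b=segment_b,
    )


# ---------------------------------------------------------------------------
# PRE decay sets
# ---------------------------------------------------------------------------


def gen_pre_decays(
    residues: np.ndarray | None = None,
    gamma2: np.ndarray | float = 40.0,
    r2_dia: np.ndarray | float = 30.0,
    i0: float = 1.0,
    delays_ms: tuple[float, ...] = DEFAULT_DELAYS_MS,
    noise_frac: float = 0.01,
    seed: int = 0,
) -> tuple[list[DecaySeries], list[DecaySeries]]:
    """Paired para/dia decay sets from a planted Γ₂ profile.

    Intensities follow I(t) = I₀·exp(−R₂ t) with multiplicative Gaussian
    noise of fractional SD ``noise_frac``; R₂(para) = R₂(dia) + Γ₂.
    """
    if residues is None:
        residues = np.arange(1, 51)
    residues = np.asarray(residues)
    gamma2 = np.broadcast_to(np.asarray(gamma2, dtype=float),
                             residues.shape).copy()
    r2_dia = np.broadcast_to(np.asarray(r2_dia, dtype=float),
                             residues.shape).copy()
    t = np.asarray(delays_ms, dtype=float) / 1e3
    rng = np.random.default_rng(seed)
    para, dia = [], []
    for res, g, rd in zip(residues, gamma2, r2_dia):
        for rate, cond, bucket in ((rd + g, "para", para), (rd, "dia", dia)):
            clean = i0 * np.exp(-rate * t)
            noisy = clean * (1.0 + rng.normal(0.0, noise_frac, size=len(t)))
            bucket.append(DecaySeries(int(res), np.asarray(delays_ms), noisy,
                                      cond, sigma=noise_frac * i0))
    return para, dia


# ---------------------------------------------------------------------------
# Closed-form response curves
# ---------------------------------------------------------------------------


def gen_ph_titration(
    pka: float = 9.5,
    offset: float = 0.0,
    ph: np.ndarray | None = None,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized ¹³Cβ titration from the two-state sigmoid plus noise."""
    if ph is None:
        ph = np.arange(6.0, 12.01, 0.5)
    ph = np.asarray(ph, dtype=float)
    rng = np.random.default_rng(seed)
    y = pka_model(ph, pka, offset) + rng.normal(0.0, noise_sd, size=len(ph))
    return ph, y


def gen_isotherm(
    kd: float = 100.0,
    hill_n: float = 1.0,
    f_unbound: float = 0.0,
    f_bound: float = 1.0,
    concentrations: np.ndarray | None = None,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Hill-equation isotherm on a log-spaced grid up to 500 (µM) + noise."""
    if concentrations is None:
        concentrations = np.geomspace(0.5, 500.0, 12)
    c = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    y = hill_model(c, kd, hill_n, f_unbound, f_bound)
    y = y + rng.normal(0.0, noise_sd, size=len(c))
    return c, y


def gen_turbidity(
    tc: float = 30.0,
    width: float = 1.5,
    baseline: float = 0.02,
    amplitude: float = 1.0,
    temperatures: np.ndarray | None = None,
    noise_sd: float = 0.005,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sigmoidal A340 turbidity ramp with inflection at ``tc`` plus noise."""
    if temperatures is None:
        temperatures = np.arange(20.0, 45.01, 0.25)
    t = np.asarray(temperatures, dtype=float)
    rng = np.random.default_rng(seed)
    a = baseline + amplitude / (1.0 + np.exp(-(t - tc) / width))
    a = a + rng.normal(0.0, noise_sd, size=len(t))
    return t, a


@dataclass
class GeneratorConfig:
    """Bundled generator parameters; every output is a function of
    (config, seed)."""

    seed: int = 0
    sequence: dict = field(default_factory=dict)
    titration: dict = field(default_factory=dict)
    pre: dict = field(default_factory=dict)
    ph: dict = field(default_factory=dict)
    isotherm: dict = field(default_factory=dict)
    turbidity: dict = field(default_factory=dict)
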