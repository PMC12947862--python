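"""Sequence-grammar metrics for intrinsically disordered regions.

Composition fractions over residue-class groupings, charge patterning
(FCR, NCPR, kappa), proline/charge segregation (omega), a length-normalized
aromatic clustering score, rolling property profiles and patterning z-scores
against composition-preserving shuffle nulls.

All coordinates are 1-based in construct numbering: a sequence carries an
explicit ``numbering_offset`` giving the construct coordinate of its first
residue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Side-chain charge at pH 7.4 (His treated as neutral).
CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}

POSITIVE = frozenset("KR")
NEGATIVE = frozenset("DE")
AROMATIC = frozenset("FYW")
AROMATIC_WITH_HIS = frozenset("FYWH")

#: Disorder-promoting residues (Dunker/Campen convention).
DISORDER_PROMOTING = frozenset("TAGRDHQKSEP")


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence in construct coordinates.

    ``numbering_offset`` is the 1-based construct coordinate of the first
    residue (e.g. 330 for a fragment spanning residues 330-448).
    """

    id: str
    residues: str
    numbering_offset: int = 1

    def __post_init__(self):
        if not self.residues:
            raise ValueError("empty sequence")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-canonical residues: {sorted(bad)}")
        if self.numbering_offset < 1:
            raise ValueError("numbering_offset must be >= 1")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> np.ndarray:
        """Construct coordinates of each residue."""
        n = len(self.residues)
        return np.arange(self.numbering_offset, self.numbering_offset + n)


@dataclass(frozen=True)
class ResidueGrouping:
    """An ordered, disjoint partition of (a subset of) the 20-letter alphabet.

    Residues not covered by any class are reported under an explicit
    ``other`` fraction, never silently dropped.
    """

    name: str
    classes: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self):
        seen: set[str] = set()
        for label, members in self.classes:
            if seen & members:
                raise ValueError(f"class {label!r} overlaps another class")
            seen |= members

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.classes]

    def covered(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.classes:
            out |= members
        return frozenset(out)


#: Eight-class grouping used for patterning z-scores.
EIGHT_CLASS = ResidueGrouping(
    "eight",
    (
        ("polar", frozenset("QSHTCN")),
        ("hydrophobic", frozenset("ILMV")),
        ("positive", frozenset("KR")),
        ("negative", frozenset("DE")),
        ("aromatic", frozenset("FYW")),
        ("alanine", frozenset("A")),
        ("proline", frozenset("P")),
        ("glycine", frozenset("G")),
    ),
)

#: Six-class composition grouping (G and P fall under "other").
SIX_CLASS = ResidueGrouping(
    "six",
    (
        ("polar", frozenset("QSHTN")),
        ("cys", frozenset("C")),
        ("positive", frozenset("KR")),
        ("negative", frozenset("DE")),
        ("aromatic", frozenset("FYW")),
        ("hydrophobic", frozenset("ILMVA")),
    ),
)


def composition_fractions(
    seq: ProteinSequence, grouping: ResidueGrouping = SIX_CLASS
) -> dict[str, float]:
    """Per-class residue fractions; uncovered residues under ``"other"``."""
    n = len(seq)
    fractions = {}
    covered = 0
    for label, members in grouping.classes:
        count = sum(1 for r in seq.residues if r in members)
        fractions[label] = count / n
        covered += count
    if covered < n or grouping.covered() != frozenset(AMINO_ACIDS):
        fractions["other"] = (n - covered) / n
    return fractions


def fcr_ncpr(seq: ProteinSequence) -> tuple[float, float]:
    """Fraction of charged residues and net charge per residue at pH 7.4."""
    charges = [CHARGE.get(r, 0.0) for r in seq.residues]
    n = len(charges)
    fcr = sum(1 for c in charges if c != 0) / n
    ncpr = sum(charges) / n
    return fcr, ncpr


def mean_hydropathy(seq: ProteinSequence) -> float:
    return float(np.mean([KYTE_DOOLITTLE[r] for r in seq.residues]))


def disorder_promoting_fraction(
    seq: ProteinSequence, promoting: frozenset[str] = DISORDER_PROMOTING
) -> float:
    return sum(1 for r in seq.residues if r in promoting) / len(seq)


# ---------------------------------------------------------------------------
# kappa / omega: blob-wise segregation statistics (Das-Pappu convention,
# blob sizes 5 and 6, delta_max by deterministic construction).
# ---------------------------------------------------------------------------

_BLOB_SIZES = (5, 6)


def _sigma_ternary(plus: np.ndarray, minus: np.ndarray) -> np.ndarray:
    """Charge-asymmetry sigma = (f+ - f-)^2 / (f+ + f-), 0 where uncharged."""
    tot = plus + minus
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(tot > 0, (plus - minus) ** 2 / np.where(tot > 0, tot, 1), 0.0)
    return out


def _window_fractions(indicator: np.ndarray, g: int) -> np.ndarray:
    """Sliding-window means of a 0/1 indicator, window g, step 1."""
    c = np.concatenate([[0.0], np.cumsum(indicator, dtype=float)])
    return (c[g:] - c[:-g]) / g


def _delta_ternary(plus: np.ndarray, minus: np.ndarray, g: int) -> float:
    fp = _window_fractions(plus, g)
    fm = _window_fractions(minus, g)
    sig = _sigma_ternary(fp, fm)
    sig_all = _sigma_ternary(
        np.array([plus.mean()]), np.array([minus.mean()])
    )[0]
    return float(np.mean((sig - sig_all) ** 2))


def _ternary_arrangements(n_plus: int, n_minus: int, n_zero: int):
    """Deterministic candidate arrangements for the delta_max normalizer."""
    import itertools

    blocks = {"+": n_plus, "-": n_minus, "0": n_zero}
    for order in itertools.permutations("+-0"):
        yield "".join(s * blocks[s] for s in order)
    # neutrals split half at each end around the segregated charge blocks
    h = n_zero // 2
    yield "0" * h + "+" * n_plus + "-" * n_minus + "0" * (n_zero - h)
    yield "0" * h + "-" * n_minus + "+" * n_plus + "0" * (n_zero - h)


def _delta_max_ternary(n_plus: int, n_minus: int, n_zero: int, g: int) -> float:
    best = 0.0
    for arr in _ternary_arrangements(n_plus, n_minus, n_zero):
        plus = np.array([1.0 if c == "+" else 0.0 for c in arr])
        minus = np.array([1.0 if c == "-" else 0.0 for c in arr])
        best = max(best, _delta_ternary(plus, minus, g))
    return best


def kappa(seq: ProteinSequence) -> float:
    """Charge-patterning kappa in [0, 1]; NaN when undefined.

    Undefined when the sequence lacks positive or negative residues or is
    shorter than the largest blob.
    """
    plus = np.array([1.0 if r in POSITIVE else 0.0 for r in seq.residues])
    minus = np.array([1.0 if r in NEGATIVE else 0.0 for r in seq.residues])
    return _segregation_ternary(plus, minus)


def _segregation_ternary(plus: np.ndarray, minus: np.ndarray) -> float:
    n = len(plus)
    n_plus, n_minus = int(plus.sum()), int(minus.sum())
    if n_plus == 0 or n_minus == 0 or n < max(_BLOB_SIZES):
        return math.nan
    ratios = []
    for g in _BLOB_SIZES:
        dmax = _delta_max_ternary(n_plus, n_minus, n - n_plus - n_minus, g)
        if dmax == 0:
            return math.nan
        ratios.append(_delta_ternary(plus, minus, g) / dmax)
    return float(np.mean(ratios))


def omega_pro(seq: ProteinSequence) -> float:
    """Segregation of {charged + proline} versus all other residues.

    Two-class variant of kappa; NaN when the sequence has no residues in
    the {D, E, K, R, P} class (or none outside it).
    """
    in_class = np.array(
        [1.0 if (r in POSITIVE or r in NEGATIVE or r == "P") else 0.0
         for r in seq.residues]
    )
    return _segregation_binary(in_class)


def _delta_binary(mask: np.ndarray, g: int) -> float:
    f = _window_fractions(mask, g)
    sig = (2 * f - 1) ** 2
    sig_all = (2 * mask.mean() - 1) ** 2
    return float(np.mean((sig - sig_all) ** 2))


def _segregation_binary(mask: np.ndarray) -> float:
    n = len(mask)
    k = int(mask.sum())
    if k == 0 or k == n or n < max(_BLOB_SIZES):
        return math.nan
    ratios = []
    for g in _BLOB_SIZES:
        block = np.concatenate([np.ones(k), np.zeros(n - k)])
        dmax = _delta_binary(block, g)
        if dmax == 0:
            return math.nan
        ratios.append(_delta_binary(mask, g) / dmax)
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# Aromatic clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AromaticClustering:
    raw: float
    ideal: float
    clustered: float
    norm: float


def _mean_inverse_distance(positions: np.ndarray) -> float:
    """Mean of 1/|i-j| over all unordered position pairs."""
    d = np.abs(positions[:, None] - positions[None, :])
    iu = np.triu_indices(len(positions), k=1)
    return float(np.mean(1.0 / d[iu]))


def ideal_positions(length: int, k: int) -> np.ndarray:
    """Evenly spaced reference positions: round((j + 0.5) * L / k), 1-based."""
    pos = np.round((np.arange(k) + 0.5) * length / k).astype(int)
    pos = np.clip(pos, 1, length)
    # guard against rounding collisions on short sequences
    for i in range(1, k):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    return pos


def aromatic_clustering(
    seq: ProteinSequence, include_his: bool = False
) -> AromaticClustering:
    """Aromatic clustering score normalized between reference arrangements.

    raw: mean inverse pair distance of the aromatic residues; ideal: same
    statistic for evenly spaced aromatics of identical count and length;
    clustered: one contiguous block.  norm = (raw - ideal)/(clustered - ideal)
    so that an ideally spaced arrangement scores 0 and a single block 1.
    """
    aro = AROMATIC_WITH_HIS if include_his else AROMATIC
    positions = np.array(
        [i + 1 for i, r in enumerate(seq.residues) if r in aro]
    )
    k = len(positions)
    nan = math.nan
    if k < 2:
        return AromaticClustering(nan, nan, nan, nan)
    raw = _mean_inverse_distance(positions)
    ideal = _mean_inverse_distance(ideal_positions(len(seq), k))
    clustered = _mean_inverse_distance(np.arange(1, k + 1))
    if clustered == ideal:
        return AromaticClustering(raw, ideal, clustered, nan)
    norm = (raw - ideal) / (clustered - ideal)
    return AromaticClustering(raw, ideal, clustered, norm)


# ---------------------------------------------------------------------------
# Rolling property profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatterningProfile:
    property_name: str
    window: int
    centers: np.ndarray  # construct coordinates (fractional for even windows)
    values: np.ndarray


_PROPERTY_SCALES = {
    "hydropathy": KYTE_DOOLITTLE,
    "charge": CHARGE,
    "aromatic": {r: 1.0 for r in AROMATIC},
}


def rolling_profile(
    seq: ProteinSequence,
    prop: str | dict[str, float] = "hydropathy",
    window: int = 30,
) -> PatterningProfile:
    """Unweighted rolling mean of a per-residue property scale."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(seq):
        raise ValueError(f"window {window} exceeds sequence length {len(seq)}")
    if isinstance(prop, str):
        try:
            scale = _PROPERTY_SCALES[prop]
        except KeyError:
            raise ValueError(f"unknown property {prop!r}") from None
        name = prop
    else:
        scale, name = prop, "custom"
    values = np.array([scale.get(r, 0.0) for r in seq.residues])
    means = _window_fractions(values, window) * 1.0  # cumsum-based mean
    starts = np.arange(len(means)) + seq.numbering_offset
    centers = starts + (window - 1) / 2.0
    return PatterningProfile(name, window, centers, means)


# ---------------------------------------------------------------------------
# Patterning z-scores against composition-preserving shuffles
# ---------------------------------------------------------------------------


@dataclass
class ZScoreMatrix:
    """Symmetric matrix of pairwise patterning z-scores.

    Diagonal entries are the self-pair (omega-type segregation) features;
    off-diagonal entries the cross-pair (delta-type mixing) features.
    Entries are NaN where undefined (class absent, or zero null variance);
    ``degenerate`` marks zero-variance nulls specifically.
    """

    labels: list[str]
    z: np.ndarray
    observed: np.ndarray
    n_shuffles: int
    seed: int
    degenerate: np.ndarray = field(default=None)

    @property
    def n_features(self) -> int:
        k = len(self.labels)
        return k * (k + 1) // 2

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.z, index=self.labels, columns=self.labels)


def _pair_statistics(idx: np.ndarray, k: int) -> np.ndarray:
    """All k(k+1)/2 blocky-ness statistics for a class-index sequence.

    Returns a symmetric (k, k) matrix: diagonal = self-pair segregation of
    class a against everything else; off-diagonal = mean-square deviation
    of the windowed class-fraction difference from its global value
    (blob sizes 5 and 6 averaged).
    """
    n = len(idx)
    indicators = np.zeros((k, n))
    indicators[idx, np.arange(n)] = 1.0
    global_frac = indicators.mean(axis=1)
    out = np.zeros((k, k))
    for g in _BLOB_SIZES:
        c = np.concatenate(
            [np.zeros((k, 1)), np.cumsum(indicators, axis=1)], axis=1
        )
        fw = (c[:, g:] - c[:, :-g]) / g  # (k, n-g+1) window fractions
        # cross-pair: ((f_a - f_b) - (F_a - F_b))^2 averaged over windows
        dev = fw - global_frac[:, None]
        # E[(dev_a - dev_b)^2] = E[dev_a^2] + E[dev_b^2] - 2 E[dev_a dev_b]
        m2 = (dev ** 2).mean(axis=1)
        cross = dev @ dev.T / dev.shape[1]
        out += m2[:, None] + m2[None, :] - 2 * cross
        # self-pair: binary sigma of class a vs rest
        sig = (2 * fw - 1) ** 2
        sig_all = (2 * global_frac - 1) ** 2
        np.fill_diagonal(out, np.diag(out) + ((sig - sig_all[:, None]) ** 2).mean(axis=1))
    return out / len(_BLOB_SIZES)


def patterning_zscores(
    seq: ProteinSequence,
    grouping: ResidueGrouping = EIGHT_CLASS,
    n_shuffles: int = 10_000,
    seed: int = 0,
) -> ZScoreMatrix:
    """Blockiness z-scores of all class pairs vs composition-matched shuffles.

    For each feature, z = (observed - null mean)/null SD over ``n_shuffles``
    random permutations of the sequence.  Positive z means the two classes
    are arranged more blocky than random; negative means better mixed.
    Deterministic under a fixed seed.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    covered = grouping.covered()
    if set(seq.residues) - covered:
        raise ValueError("grouping does not cover all residues in sequence")
    k = len(grouping.classes)
    lookup = {}
    for ci, (_, members) in enumerate(grouping.classes):
        for r in members:
            lookup[r] = ci
    idx = np.array([lookup[r] for r in seq.residues])
    counts = np.bincount(idx, minlength=k)

    observed = _pair_statistics(idx, k)
    rng = np.random.default_rng(seed)
    null = np.empty((n_shuffles, k, k))
    work = idx.copy()
    for s in range(n_shuffles):
        rng.shuffle(work)
        null[s] = _pair_statistics(work, k)
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = (observed - null_mean) / null_sd
    degenerate = null_sd == 0
    z[degenerate] = np.nan
    absent = counts == 0
    z[absent, :] = np.nan
    z[:, absent] = np.nan
    return ZScoreMatrix(
        labels=grouping.labels,
        z=z,
        observed=observed,
        n_shuffles=n_shuffles,
        seed=seed,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Bundled metrics
# ---------------------------------------------------------------------------


@dataclass
class SequenceMetrics:
    fractions: dict[str, float]
    fcr: float
    ncpr: float
    kappa: float
    omega_pro: float
    omega_aro_raw: float
    omega_aro_ideal: float
    omega_aro_clust: float
    omega_aro_norm: float
    mean_hydropathy: float
    frac_disorder_promoting: float


def compute_metrics(
    seq: ProteinSequence,
    grouping: ResidueGrouping = SIX_CLASS,
    include_his_aromatic: bool = False,
) -> SequenceMetrics:
    """All scalar sequence-grammar metrics in one pass."""
    fcr, ncpr = fcr_ncpr(seq)
    aro = aromatic_clustering(seq, include_his=include_his_aromatic)
    return SequenceMetrics(
        fractions=composition_fractions(seq, grouping),
        fcr=fcr,
        ncpr=ncpr,
        kappa=kappa(seq),
        omega_pro=omega_pro(seq),
        omega_aro_raw=aro.raw,
        omega_aro_ideal=aro.ideal,
        omega_aro_clust=aro.clustered,
        omega_aro_norm=aro.norm,
        mean_hydropathy=mean_hydropathy(seq),
        frac_disorder_promoting=disorder_promoting_fraction(seq),
    )
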