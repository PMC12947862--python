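"""Reciprocal-titration CSP² contact matrices.

For a pair of constructs A and B, two reciprocal experiments (labeled A +
unlabeled B, and labeled B + unlabeled A) yield two CSP profiles.  Their
outer product is an m x n matrix of CSP² values (ppm²): entry (i, j) is
large only when residue i of A and residue j of B both report perturbation,
so smoothed maxima flag interacting segment pairs.  Self-pairs place the
squared CSP on the diagonal.

Difference maps between conditions (e.g. ligand-bound minus apo) use a
strict masking rule: any position that is missing or zero in either input
matrix is exactly zero in the difference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .csp import CSPProfile


@dataclass
class ReciprocalTitration:
    """The two CSP profiles of a reciprocal titration of constructs A and B.

    ``profile_a`` is observed on labeled A in the presence of unlabeled B;
    ``profile_b`` the reverse.  For a self-pair (A == B) one experiment
    fills both roles.
    """

    profile_a: CSPProfile
    profile_b: CSPProfile

    @property
    def self_pair(self) -> bool:
        return self.profile_a.construct_id == self.profile_b.construct_id


@dataclass
class CSPSquaredMatrix:
    """Dense CSP² matrix (ppm²) in construct coordinates; NaN = missing."""

    row_id: str
    row_start: int
    col_id: str
    col_start: int
    values: np.ndarray
    sigma: float | None = None  # smoothing width applied, residues

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def row_residues(self) -> np.ndarray:
        return np.arange(self.row_start, self.row_start + self.values.shape[0])

    @property
    def col_residues(self) -> np.ndarray:
        return np.arange(self.col_start, self.col_start + self.values.shape[1])


def build_pair_matrix(pair: ReciprocalTitration) -> CSPSquaredMatrix:
    """Outer product of the two reciprocal CSP profiles.

    entry(i, j) = CSP_A(i) * CSP_B(j); NaN where either factor is missing.
    Self-pairs are symmetrized off-diagonal as (M + Mᵀ)/2 and carry the
    squared CSP on the diagonal.
    """
    a, b = pair.profile_a, pair.profile_b
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty CSP profile")
    values = np.outer(a.values, b.values)
    if pair.self_pair:
        off = 0.5 * (values + values.T)
        np.fill_diagonal(off, a.values ** 2)
        values = off
    return CSPSquaredMatrix(
        row_id=a.construct_id,
        row_start=a.start,
        col_id=b.construct_id,
        col_start=b.start,
        values=values,
    )


def smooth_matrix(
    matrix: CSPSquaredMatrix, sigma: float = 2.0, truncate: float = 6.0
) -> CSPSquaredMatrix:
    """Missing-data-aware Gaussian smoothing (normalized convolution).

    Missing entries carry zero weight and the kernel is renormalized over
    the present entries, so gaps are averaged out rather than pulled toward
    zero.  Positions reached by no weight remain missing.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    v = matrix.values
    finite = np.isfinite(v)
    if not finite.any():
        raise ValueError("matrix has no defined entries")
    filled = np.where(finite, v, 0.0)
    num = ndimage.gaussian_filter(
        filled, sigma=sigma, mode="constant", cval=0.0, truncate=truncate
    )
    den = ndimage.gaussian_filter(
        finite.astype(float), sigma=sigma, mode="constant", cval=0.0,
        truncate=truncate,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 1e-12, num / np.where(den > 1e-12, den, 1.0), np.nan)
    return replace(matrix, values=out, sigma=sigma)


def assemble_composite(
    pairs: list[ReciprocalTitration],
    full_length: int,
    overlap_rule: str | None = "mean",
    mirror: bool = True,
) -> CSPSquaredMatrix:
    """Tile fragment-pair blocks into a full-domain square matrix.

    Each pair contributes its block at the coordinates given by the two
    profiles' numbering offsets; with ``mirror`` (default) the transposed
    block is placed as well, so the composite is symmetric by construction.
    Cells covered by more than one block are resolved by ``overlap_rule``
    ("mean", "max" or "first"); ``None`` raises on any conflict.
    """
    if overlap_rule not in ("mean", "max", "first", None):
        raise ValueError(f"unknown overlap rule {overlap_rule!r}")
    acc = np.zeros((full_length, full_length))
    count = np.zeros((full_length, full_length), dtype=int)
    best = np.full((full_length, full_length), np.nan)

    def place(block: np.ndarray, r0: int, c0: int):
        rs = slice(r0 - 1, r0 - 1 + block.shape[0])
        cs = slice(c0 - 1, c0 - 1 + block.shape[1])
        if rs.stop > full_length or cs.stop > full_length or r0 < 1 or c0 < 1:
            raise ValueError("block extends outside the full-domain range")
        defined = np.isfinite(block)
        sub_count = count[rs, cs]
        if overlap_rule is None and (sub_count[defined] > 0).any():
            raise ValueError("overlapping blocks and no overlap rule configured")
        if overlap_rule == "first":
            take = defined & (sub_count == 0)
        else:
            take = defined
        acc[rs, cs][take] += block[take]
        with np.errstate(invalid="ignore"):
            best[rs, cs][take] = np.fmax(best[rs, cs][take], block[take])
        count[rs, cs][take] += 1

    for pair in pairs:
        block = build_pair_matrix(pair).values
        r0, c0 = pair.profile_a.start, pair.profile_b.start
        place(block, r0, c0)
        if mirror and not (pair.self_pair and r0 == c0):
            place(block.T, c0, r0)

    covered = count > 0
    if overlap_rule == "max":
        values = np.where(covered, best, np.nan)
    else:
        with np.errstate(invalid="ignore"):
            values = np.where(covered, acc / np.where(covered, count, 1), np.nan)
    row_id = pairs[0].profile_a.construct_id if pairs else "composite"
    return CSPSquaredMatrix(
        row_id=row_id, row_start=1, col_id=row_id, col_start=1, values=values
    )


@dataclass
class DifferenceMatrix:
    """Signed ΔCSP² map; masked positions are exactly zero."""

    row_id: str
    row_start: int
    col_id: str
    col_start: int
    values: np.ndarray
    masked_count: int


def difference_matrix(
    holo: CSPSquaredMatrix, apo: CSPSquaredMatrix
) -> DifferenceMatrix:
    """ΔCSP² = holo − apo with the missing-or-zero masking rule.

    Positions where either input is missing (NaN) or exactly zero are set
    to 0 in the output.
    """
    if holo.shape != apo.shape or holo.row_start != apo.row_start \
            or holo.col_start != apo.col_start:
        raise ValueError("matrix coordinates do not match")
    valid = (
        np.isfinite(holo.values) & np.isfinite(apo.values)
        & (holo.values != 0) & (apo.values != 0)
    )
    values = np.where(valid, holo.values - apo.values, 0.0)
    return DifferenceMatrix(
        row_id=holo.row_id,
        row_start=holo.row_start,
        col_id=holo.col_id,
        col_start=holo.col_start,
        values=values,
        masked_count=int((~valid).sum()),
    )


def argmax_position(matrix: CSPSquaredMatrix) -> tuple[int, int]:
    """Construct coordinates (row, col) of the largest defined entry."""
    v = matrix.values
    if not np.isfinite(v).any():
        raise ValueError("matrix has no defined entries")
    flat = np.nanargmax(v)
    i, j = np.unravel_index(flat, v.shape)
    return matrix.row_start + int(i), matrix.col_start + int(j)
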