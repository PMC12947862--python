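"""File formats: FASTA sequences and TSV tables for all analysis stages.

All tabular formats are tab-separated with explicit headers and a
locale-independent decimal point.  Metadata (construct id, condition)
travels in ``# key=value`` comment lines at the top of shift tables.
Sequence records use the FASTA description to carry the construct
numbering offset as ``id offset=N``.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .csp import SHIFT_COLUMNS, CSPProfile, ShiftTable
from .cspmatrix import CSPSquaredMatrix
from .pre import DecaySeries
from .sequences import ProteinSequence

_OFFSET_RE = re.compile(r"\boffset=(\d+)\b")


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read sequences; an ``offset=N`` token in the description sets the
    construct numbering offset (default 1).  Lower-case input is upper-cased.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _OFFSET_RE.search(rec.description)
        offset = int(m.group(1)) if m else 1
        out.append(ProteinSequence(rec.id, str(rec.seq).upper(), offset))
    return out


def write_fasta(path: str | Path, sequences: list[ProteinSequence]) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=f"offset={s.numbering_offset}")
        for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def _read_metadata(path: Path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, val = line[1:].split("=", 1)
                meta[key.strip()] = val.strip()
    return meta


def read_shift_table(path: str | Path) -> ShiftTable:
    """Read a per-residue shift table (TSV).

    Required columns: residue_index, residue_type, dH_ppm, dN_ppm.
    Empty cells become missing-flags (NaN); ``# construct_id=...`` and
    ``# condition=...`` comment lines supply metadata.
    """
    path = Path(path)
    meta = _read_metadata(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in SHIFT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["residue_index"] = df["residue_index"].astype(int)
    for col in ("dH_ppm", "dN_ppm"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return ShiftTable(
        construct_id=meta.get("construct_id", path.stem),
        condition=meta.get("condition", "unknown"),
        data=df[SHIFT_COLUMNS],
    )


def write_shift_table(path: str | Path, table: ShiftTable) -> None:
    with open(path, "w") as fh:
        fh.write(f"# construct_id={table.construct_id}\n")
        fh.write(f"# condition={table.condition}\n")
        table.data.to_csv(fh, sep="\t", index=False)


def read_decay_table(path: str | Path) -> list[DecaySeries]:
    """Read a long-format PRE decay table.

    Columns: residue_index, condition, delay_ms, intensity and optionally
    sigma_intensity (a constant noise floor per residue/condition).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["residue_index", "condition", "delay_ms", "intensity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for (res, cond), grp in df.groupby(["residue_index", "condition"],
                                       sort=True):
        sigma = None
        if "sigma_intensity" in grp.columns and grp["sigma_intensity"].notna().any():
            sigma = float(grp["sigma_intensity"].dropna().iloc[0])
        out.append(DecaySeries(
            int(res),
            grp["delay_ms"].to_numpy(dtype=float),
            grp["intensity"].to_numpy(dtype=float),
            str(cond),
            sigma=sigma,
        ))
    return out


def write_decay_table(path: str | Path, series: list[DecaySeries]) -> None:
    rows = []
    for s in series:
        for t, i in zip(s.delays_ms, s.intensities):
            rows.append({
                "residue_index": s.residue_index,
                "condition": s.condition,
                "delay_ms": t,
                "intensity": i,
                "sigma_intensity": s.sigma if s.sigma is not None else np.nan,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_profile(path: str | Path, profile: CSPProfile) -> None:
    pd.DataFrame({
        "residue_index": profile.residues,
        "csp_ppm": profile.values,
    }).to_csv(path, sep="\t", index=False)


def read_profile(path: str | Path, construct_id: str = "profile") -> CSPProfile:
    df = pd.read_csv(path, sep="\t", comment="#")
    residues = df["residue_index"].astype(int).to_numpy()
    if len(residues) == 0:
        raise ValueError(f"{path}: empty profile")
    start, stop = int(residues.min()), int(residues.max())
    values = np.full(stop - start + 1, np.nan)
    values[residues - start] = pd.to_numeric(df["csp_ppm"],
                                             errors="coerce").to_numpy()
    return CSPProfile(construct_id, start, values)


def write_matrix(path: str | Path, matrix: CSPSquaredMatrix) -> None:
    """Dense TSV with row/column residue coordinates as headers."""
    df = pd.DataFrame(matrix.values,
                      index=matrix.row_residues,
                      columns=matrix.col_residues)
    with open(path, "w") as fh:
        fh.write(f"# row_id={matrix.row_id}\n")
        fh.write(f"# col_id={matrix.col_id}\n")
        if matrix.sigma is not None:
            fh.write(f"# sigma={matrix.sigma}\n")
        df.to_csv(fh, sep="\t", index_label="residue")


def read_matrix(path: str | Path) -> CSPSquaredMatrix:
    path = Path(path)
    meta = _read_metadata(path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    rows = df.index.astype(int)
    cols = df.columns.astype(int)
    sigma = float(meta["sigma"]) if "sigma" in meta else None
    return CSPSquaredMatrix(
        row_id=meta.get("row_id", path.stem),
        row_start=int(rows.min()),
        col_id=meta.get("col_id", path.stem),
        col_start=int(cols.min()),
        values=df.to_numpy(dtype=float),
        sigma=sigma,
    )


def read_xy(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column (x, y) TSV used by the equilibrium fits."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns")
    return (df.iloc[:, 0].to_numpy(dtype=float),
            df.iloc[:, 1].to_numpy(dtype=float))
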