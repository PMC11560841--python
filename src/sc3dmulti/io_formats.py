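"""On-disk formats and coordinate conventions.

Internal convention is 0-based, half-open everywhere.  Files follow the
convention of their format: allc and contact TSVs are 1-based (positions),
BED/BEDPE are 0-based half-open.  ``pos_to_bin`` is the single place where
base-pair coordinates are converted to bin indices; no other module does
coordinate arithmetic on raw bp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

ALLC_COLUMNS = ["chrom", "pos", "strand", "context", "mc", "cov", "methylated"]
CONTACT_COLUMNS = ["cell_id", "chrom", "pos1", "pos2"]


class FormatError(ValueError):
    """Raised when an on-disk record violates a format invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )


def pos_to_bin(pos, resolution: int):
    """Map a 1-based bp position to a 0-based bin index.

    Bins are half-open at ``resolution`` bp: position ``resolution`` is the
    last base of bin 0, position ``resolution + 1`` the first of bin 1.
    """
    pos = np.asarray(pos)
    if np.any(pos < 1):
        raise FormatError("positions are 1-based and must be >= 1")
    return (pos - 1) // resolution


def bin_to_interval(chrom: str, bin_index: int, resolution: int) -> GenomicInterval:
    """0-based half-open interval covered by a bin."""
    start = int(bin_index) * resolution
    return GenomicInterval(chrom, start, start + resolution)


# ---------------------------------------------------------------------------
# allc tables
# ---------------------------------------------------------------------------

def validate_allc(table: pd.DataFrame) -> None:
    bad = table.index[table["mc"] > table["cov"]]
    if len(bad):
        raise FormatError(f"mc > cov at line {int(bad[0]) + 1}")
    if (table["pos"] < 1).any():
        raise FormatError("allc positions must be >= 1")


def read_allc(path) -> pd.DataFrame:
    table = pd.read_csv(
        path, sep="\t", header=None, names=ALLC_COLUMNS,
        dtype={"chrom": str, "pos": np.int64, "strand": str, "context": str,
               "mc": np.int64, "cov": np.int64, "methylated": np.int64},
    )
    validate_allc(table)
    return table


def write_allc(table: pd.DataFrame, path) -> None:
    validate_allc(table)
    table.to_csv(path, sep="\t", header=False, index=False, columns=ALLC_COLUMNS)


# ---------------------------------------------------------------------------
# contact lists
# ---------------------------------------------------------------------------

def validate_contacts(table: pd.DataFrame) -> None:
    if (table["pos2"] < table["pos1"]).any():
        raise FormatError("contacts must be stored with pos1 <= pos2")
    if (table["pos1"] < 1).any():
        raise FormatError("contact positions are 1-based and must be >= 1")


def read_contacts(path) -> pd.DataFrame:
    table = pd.read_csv(
        path, sep="\t", header=None, names=CONTACT_COLUMNS,
        dtype={"cell_id": str, "chrom": str, "pos1": np.int64, "pos2": np.int64},
    )
    validate_contacts(table)
    return table


def write_contacts(table: pd.DataFrame, path) -> None:
    validate_contacts(table)
    table.to_csv(path, sep="\t", header=False, index=False, columns=CONTACT_COLUMNS)


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def intervals_to_frame(intervals: Iterable[GenomicInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        [(iv.chrom, iv.start, iv.end, iv.name, iv.score, iv.strand)
         for iv in intervals],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )


def read_intervals(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = table.shape[1]
    names = ["chrom", "start", "end", "name", "score", "strand"][:ncol]
    table.columns = names
    if "name" not in table:
        table["name"] = "."
    if "score" not in table:
        table["score"] = 0.0
    if "strand" not in table:
        table["strand"] = "."
    if (table["start"] >= table["end"]).any():
        bad = table.index[table["start"] >= table["end"]][0]
        raise FormatError(f"BED start >= end at line {int(bad) + 1}")
    table["chrom"] = table["chrom"].astype(str)
    return table


def write_intervals(table: pd.DataFrame, path, columns=None) -> None:
    if (table["start"] >= table["end"]).any():
        raise FormatError("BED start >= end")
    if columns is None:
        columns = [c for c in ["chrom", "start", "end", "name", "score", "strand"]
                   if c in table.columns]
    table.to_csv(path, sep="\t", header=False, index=False, columns=columns)


# ---------------------------------------------------------------------------
# loops (BEDPE-like, both anchors as bin-derived intervals + stat columns)
# ---------------------------------------------------------------------------

LOOP_ANCHOR_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]


def loops_to_bedpe(loops: pd.DataFrame, resolution: int) -> pd.DataFrame:
    """Expand ``chrom/bin1/bin2`` loop rows into a BEDPE-style frame.

    Extra columns of ``loops`` are carried through as named stat columns.
    """
    out = pd.DataFrame({
        "chrom1": loops["chrom"], "start1": loops["bin1"] * resolution,
        "end1": (loops["bin1"] + 1) * resolution,
        "chrom2": loops["chrom"], "start2": loops["bin2"] * resolution,
        "end2": (loops["bin2"] + 1) * resolution,
    })
    for col in loops.columns:
        if col not in ("chrom", "bin1", "bin2"):
            out[col] = loops[col].to_numpy()
    return out


def write_loops(loops: pd.DataFrame, path, resolution: int) -> None:
    loops_to_bedpe(loops, resolution).to_csv(path, sep="\t", index=False)


def read_loops(path, resolution: int) -> pd.DataFrame:
    bedpe = pd.read_csv(path, sep="\t")
    loops = pd.DataFrame({
        "chrom": bedpe["chrom1"].astype(str),
        "bin1": bedpe["start1"] // resolution,
        "bin2": bedpe["start2"] // resolution,
    })
    for col in bedpe.columns:
        if col not in LOOP_ANCHOR_COLUMNS:
            loops[col] = bedpe[col].to_numpy()
    return loops


# ---------------------------------------------------------------------------
# JSON helpers (configs and truth ledgers)
# ---------------------------------------------------------------------------

def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)!r}")
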