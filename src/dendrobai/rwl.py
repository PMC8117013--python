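"""Readers and writers for ring-width series.

Two formats are supported:

* the Tucson decadal (``.rwl``) format, in the two dominant dialects —
  widths stored as integers in units of 0.01 mm with series terminator
  ``999``, or in units of 0.001 mm with terminator ``-9999``.  The dialect
  is auto-detected per series from the terminator;
* a long-form CSV with one row per (tree, year) and an optional metadata
  CSV carrying species, stand type and pith geometry.

The readers validate rather than repair: non-contiguous decade lines,
duplicate (tree, year) rows and missing terminators raise ``RwlParseError``
naming the offending line.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .series import RingWidthSeries, TreeMetadata

__all__ = [
    "RwlParseError",
    "read_rwl",
    "write_rwl",
    "read_long_csv",
    "write_long_csv",
    "read_metadata_csv",
    "write_metadata_csv",
]


class RwlParseError(ValueError):
    """Raised when a ring-width file violates the format contract."""


# ---------------------------------------------------------------------------
# Tucson / .rwl


def write_rwl(series: Sequence[RingWidthSeries], path: Union[str, Path],
              precision: float = 0.01) -> None:
    """Write series in Tucson decadal format.

    ``precision=0.01`` stores round(width*100) with terminator ``999``;
    ``precision=0.001`` stores round(width*1000) with terminator ``-9999``.
    """
    if precision == 0.01:
        scale, terminator = 100, 999
    elif precision == 0.001:
        scale, terminator = 1000, -9999
    else:
        raise ValueError("precision must be 0.01 or 0.001")

    lines = []
    for s in series:
        if len(s.tree_id) > 8:
            raise ValueError(f"tree_id {s.tree_id!r} longer than 8 characters")
        values = [int(round(w * scale)) for w in s.widths_mm] + [terminator]
        i = 0
        while i < len(values):
            year = s.first_year + i
            # each line runs to the end of the calendar decade
            n_slot = 10 - (year % 10)
            chunk = values[i:i + n_slot]
            lines.append(f"{s.tree_id:<8}{year:>4}" +
                         "".join(f"{v:>6d}" for v in chunk))
            i += len(chunk)
        # the terminator occupies the slot after the last width
    Path(path).write_text("\n".join(lines) + "\n")


def read_rwl(path: Union[str, Path],
             metadata: Optional[Mapping[str, TreeMetadata]] = None,
             species: str = "black_spruce",
             stand_type: str = "PBS") -> list[RingWidthSeries]:
    """Read a Tucson decadal file.

    Widths are restored in mm; the storage unit is auto-detected per
    series (terminator ``-9999`` means 0.001 mm, a final ``999`` means
    0.01 mm).  Species and stand type are taken from ``metadata`` when a
    matching ``tree_id`` entry exists, else from the defaults.
    """
    raw: dict[str, list[tuple[int, list[int], int]]] = {}
    order: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        tree_id = line[:8].strip()
        if not tree_id:
            raise RwlParseError(f"line {lineno}: missing series id")
        tokens = line[8:].split()
        if len(tokens) < 2:
            raise RwlParseError(f"line {lineno}: expected a year and values")
        try:
            year = int(tokens[0])
            values = [int(t) for t in tokens[1:]]
        except ValueError as exc:
            raise RwlParseError(f"line {lineno}: non-integer field ({exc})") from None
        raw.setdefault(tree_id, [])
        if tree_id not in order:
            order.append(tree_id)
        raw[tree_id].append((year, values, lineno))

    out = []
    for tree_id in order:
        chunks = raw[tree_id]
        first_year = chunks[0][0]
        values: list[int] = []
        expect_year = first_year
        for year, vals, lineno in chunks:
            if year != expect_year:
                raise RwlParseError(
                    f"line {lineno}: series {tree_id!r} year {year} "
                    f"not contiguous (expected {expect_year})")
            values.extend(vals)
            expect_year = first_year + len(values)
        if -9999 in values:
            stop = values.index(-9999)
            if stop != len(values) - 1:
                raise RwlParseError(
                    f"series {tree_id!r}: data after -9999 terminator")
            widths = np.asarray(values[:stop], dtype=float) / 1000.0
        elif values and values[-1] == 999:
            widths = np.asarray(values[:-1], dtype=float) / 100.0
        else:
            raise RwlParseError(
                f"series {tree_id!r}: missing terminator (999 or -9999)")
        if widths.size == 0:
            raise RwlParseError(f"series {tree_id!r}: no ring widths before terminator")
        if np.any(widths < 0):
            raise RwlParseError(f"series {tree_id!r}: negative ring width")
        md = (metadata or {}).get(tree_id)
        out.append(RingWidthSeries(
            tree_id=tree_id,
            species=md.species if md else species,
            stand_type=md.stand_type if md else stand_type,
            first_year=first_year,
            widths_mm=widths,
        ))
    return out


# ---------------------------------------------------------------------------
# long-form CSV

_META_COLS = ["tree_id", "species", "stand_type", "dbh_cm",
              "has_pith", "arc_chord_mm", "arc_height_mm"]


def write_long_csv(series: Sequence[RingWidthSeries], path: Union[str, Path]) -> None:
    """Write (tree_id, year, width_mm) rows, one per ring."""
    frames = [pd.DataFrame({"tree_id": s.tree_id, "year": s.years,
                            "width_mm": s.widths_mm}) for s in series]
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=["tree_id", "year", "width_mm"]))
    df.to_csv(path, index=False)


def write_metadata_csv(series: Sequence[RingWidthSeries], path: Union[str, Path],
                       dbh_cm: Optional[Mapping[str, float]] = None) -> None:
    rows = []
    for s in series:
        rows.append({
            "tree_id": s.tree_id, "species": s.species, "stand_type": s.stand_type,
            "dbh_cm": (dbh_cm or {}).get(s.tree_id),
            "has_pith": s.has_pith,
            "arc_chord_mm": s.arc_chord_mm, "arc_height_mm": s.arc_height_mm,
        })
    pd.DataFrame(rows, columns=_META_COLS).to_csv(path, index=False)


def read_metadata_csv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "tree_id" not in df.columns:
        raise RwlParseError("metadata CSV must have a tree_id column")
    if df["tree_id"].duplicated().any():
        dup = df.loc[df["tree_id"].duplicated(), "tree_id"].iloc[0]
        raise RwlParseError(f"duplicate tree_id {dup!r} in metadata")
    return df.set_index("tree_id")


def read_long_csv(path: Union[str, Path],
                  metadata_path: Optional[Union[str, Path]] = None,
                  species: str = "black_spruce",
                  stand_type: str = "PBS") -> list[RingWidthSeries]:
    """Read long-form (tree_id, year, width_mm) rows back into series.

    Rejects duplicate (tree_id, year) pairs and non-consecutive years.
    An optional metadata CSV supplies species, stand type, pith flag and
    arc geometry per tree.
    """
    df = pd.read_csv(Path(path))
    required = {"tree_id", "year", "width_mm"}
    if not required.issubset(df.columns):
        raise RwlParseError(f"long CSV must have columns {sorted(required)}")
    if df.empty:
        return []
    dups = df.duplicated(subset=["tree_id", "year"])
    if dups.any():
        r = df.loc[dups].iloc[0]
        raise RwlParseError(f"duplicate (tree_id, year) = ({r.tree_id!r}, {int(r.year)})")
    meta = read_metadata_csv(metadata_path) if metadata_path is not None else None

    out = []
    for tree_id, grp in df.groupby("tree_id", sort=False):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy(dtype=int)
        if not np.all(np.diff(years) == 1):
            raise RwlParseError(f"series {tree_id!r}: years not consecutive")
        kw = dict(species=species, stand_type=stand_type, has_pith=False,
                  arc_chord_mm=None, arc_height_mm=None)
        if meta is not None and tree_id in meta.index:
            row = meta.loc[tree_id]
            kw["species"] = row.get("species", species)
            kw["stand_type"] = row.get("stand_type", stand_type)
            if "has_pith" in row.index and not pd.isna(row["has_pith"]):
                kw["has_pith"] = bool(row["has_pith"])
            for col in ("arc_chord_mm", "arc_height_mm"):
                if col in row.index and not pd.isna(row[col]):
                    kw[col] = float(row[col])
        out.append(RingWidthSeries(
            tree_id=str(tree_id), first_year=int(years[0]),
            widths_mm=grp["width_mm"].to_numpy(dtype=float), **kw))
    return out
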