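"""Core per-tree data containers.

A :class:`RingWidthSeries` holds one increment core: calendar-dated annual
ring widths in millimetres plus the geometry needed to locate the pith
(either the core reached the pith, or the curvature of the innermost
visible ring is recorded as an arc chord/height pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

SPECIES = ("black_spruce", "trembling_aspen")
STAND_TYPES = ("PBS", "M", "PTA")


@dataclass
class RingWidthSeries:
    """Annual ring widths of a single tree (one radius).

    Parameters
    ----------
    tree_id : str
        Unique identifier (max 8 characters for Tucson interoperability).
    species : str
        One of ``black_spruce`` or ``trembling_aspen``.
    stand_type : str
        Stand composition type: ``PBS`` (pure black spruce), ``M`` (mixed)
        or ``PTA`` (pure trembling aspen).
    first_year : int
        Calendar year of the innermost measured ring.
    widths_mm : array-like of float
        Ring widths in mm, innermost first, strictly consecutive years.
        Widths must be positive; a locally absent (missing) ring may be
        encoded as exactly 0.
    has_pith : bool
        True when the core reached the pith, i.e. the innermost measured
        ring is the first ring the tree formed.
    arc_chord_mm, arc_height_mm : float, optional
        Chord and height of the innermost-ring arc, used to estimate the
        distance to pith when ``has_pith`` is False.
    est_pith_offset_mm : float, optional
        Externally supplied pith offset estimate (mm).
    """

    tree_id: str
    species: str
    stand_type: str
    first_year: int
    widths_mm: np.ndarray
    has_pith: bool = False
    arc_chord_mm: Optional[float] = None
    arc_height_mm: Optional[float] = None
    est_pith_offset_mm: Optional[float] = None

    def __post_init__(self) -> None:
        self.widths_mm = np.asarray(self.widths_mm, dtype=float)
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.stand_type not in STAND_TYPES:
            raise ValueError(f"unknown stand_type {self.stand_type!r}")
        if self.widths_mm.ndim != 1 or self.widths_mm.size == 0:
            raise ValueError("widths_mm must be a non-empty 1-d array")
        if np.any(self.widths_mm < 0):
            raise ValueError("ring widths must be >= 0 (0 encodes a missing ring)")
        if (self.arc_chord_mm is None) != (self.arc_height_mm is None):
            raise ValueError("arc chord and height must be given together")
        if self.arc_chord_mm is not None:
            if self.arc_chord_mm <= 0 or self.arc_height_mm <= 0:
                raise ValueError("arc chord and height must be > 0")
        self.first_year = int(self.first_year)

    @property
    def n_rings(self) -> int:
        return int(self.widths_mm.size)

    @property
    def last_year(self) -> int:
        return self.first_year + self.n_rings - 1

    @property
    def years(self) -> np.ndarray:
        """Calendar years of the rings (ring year = year of formation)."""
        return np.arange(self.first_year, self.last_year + 1)

    def __len__(self) -> int:
        return self.n_rings


@dataclass
class TreeMetadata:
    """Stand/tree attributes recorded at coring."""

    tree_id: str
    species: str
    stand_type: str
    dbh_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.stand_type not in STAND_TYPES:
            raise ValueError(f"unknown stand_type {self.stand_type!r}")


def group_label(species: str, stand_type: str) -> str:
    """Short chronology-group label, e.g. ``BS_PBS`` or ``TA_M``."""
    code = {"black_spruce": "BS", "trembling_aspen": "TA"}[species]
    return f"{code}_{stand_type}"


def parse_group_label(label: str) -> tuple[str, str]:
    code, stand = label.split("_", 1)
    species = {"BS": "black_spruce", "TA": "trembling_aspen"}[code]
    if stand not in STAND_TYPES:
        raise ValueError(f"unknown stand type in label {label!r}")
    return species, stand
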