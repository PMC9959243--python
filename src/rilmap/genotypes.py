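"""Core containers for biparental RIL genotype data.

Calls are coded by parental origin on the common-parent convention used
throughout the pipeline: ``A`` is the common-parent (Koshihikari-role)
homozygote, ``B`` the founder homozygote, ``H`` a residual heterozygote and
``NA`` a missing call.  Internally calls live in an ``int8`` matrix with one
row per marker and one column per line (the rotated layout genotype files
use on disk).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# int8 call codes
A: int = 0
B: int = 1
H: int = 2
NA: int = -1

CODE_TO_SYMBOL = {A: "A", B: "B", H: "H", NA: "-"}
SYMBOL_TO_CODE = {"A": A, "B": B, "H": H, "-": NA, "NA": NA}

VALID_MARKER_TYPES = ("SNP", "AMP")
VALID_PLATFORMS = ("GRASDI", "GOLDENGATE")


def chrom_sort_key(chrom: str) -> tuple:
    """Sort chromosome labels numerically when fully numeric, else as text."""
    s = str(chrom)
    if s.isdigit():
        return (0, int(s), "")
    return (1, 0, s)


@dataclass(frozen=True)
class MarkerDef:
    """A mapped marker: identity, physical location, type and platform.

    ``pos_bp`` is 1-based.  Dominant presence/absence amplicon markers
    (``AMP``) only arise from random-amplicon sequencing (``GRASDI``);
    SNPs may come from either platform.
    """

    name: str
    chrom: str
    pos_bp: int
    marker_type: str = "SNP"
    platform: str = "GRASDI"

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"marker {self.name}: pos_bp must be >= 1, got {self.pos_bp}")
        if self.marker_type not in VALID_MARKER_TYPES:
            raise ValueError(f"marker {self.name}: unknown marker_type {self.marker_type!r}")
        if self.platform not in VALID_PLATFORMS:
            raise ValueError(f"marker {self.name}: unknown platform {self.platform!r}")
        if self.marker_type == "AMP" and self.platform != "GRASDI":
            raise ValueError(f"marker {self.name}: AMP markers only arise from GRASDI")
        object.__setattr__(self, "chrom", str(self.chrom))

    @property
    def sort_key(self) -> tuple:
        return (*chrom_sort_key(self.chrom), self.pos_bp, self.name)

    def renamed(self, name: str) -> "MarkerDef":
        return replace(self, name=name)


def sort_markers(markers: Iterable[MarkerDef]) -> list[MarkerDef]:
    """Stable total order by (chromosome, physical position)."""
    return sorted(markers, key=lambda m: m.sort_key)


class GenotypeMatrix:
    """Lines x markers call grid over {A, B, H, NA}.

    Stored marker-major: ``calls[i, j]`` is the call of line ``j`` at
    marker ``i``.  Marker order is whatever the constructor received;
    callers that need physical order sort the markers first.
    """

    def __init__(
        self,
        line_ids: Sequence[str],
        markers: Sequence[MarkerDef],
        calls: np.ndarray,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(markers), len(line_ids)):
            raise ValueError(
                f"call grid shape {calls.shape} does not match "
                f"{len(markers)} markers x {len(line_ids)} lines"
            )
        bad = ~np.isin(calls, (A, B, H, NA))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(f"invalid call code {calls[i, j]} at marker row {i}, line column {j}")
        names = [m.name for m in markers]
        if len(set(names)) != len(names):
            seen: set[str] = set()
            dup = next(n for n in names if n in seen or seen.add(n))
            raise ValueError(f"duplicate marker name {dup!r}")
        self.line_ids = list(line_ids)
        self.markers = list(markers)
        self.calls = calls
        self._name_to_row = {m.name: i for i, m in enumerate(self.markers)}

    # -- basic geometry -------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def row(self, name: str) -> np.ndarray:
        return self.calls[self._name_to_row[name]]

    def marker(self, name: str) -> MarkerDef:
        return self.markers[self._name_to_row[name]]

    # -- subsetting -----------------------------------------------------
    def take_markers(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = list(index)
        return GenotypeMatrix(
            self.line_ids, [self.markers[i] for i in index], self.calls[index]
        )

    def select_markers(self, names: Iterable[str]) -> "GenotypeMatrix":
        return self.take_markers([self._name_to_row[n] for n in names])

    def sorted_by_position(self) -> "GenotypeMatrix":
        order = sorted(range(self.n_markers), key=lambda i: self.markers[i].sort_key)
        return self.take_markers(order)

    def reorder_lines(self, line_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {l: j for j, l in enumerate(self.line_ids)}
        missing = [l for l in line_ids if l not in pos]
        if missing:
            raise ValueError(f"unknown line ids: {missing[:5]}")
        cols = [pos[l] for l in line_ids]
        return GenotypeMatrix(list(line_ids), self.markers, self.calls[:, cols])

    # -- summaries ------------------------------------------------------
    def missing_counts(self) -> np.ndarray:
        return (self.calls == NA).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Rotated layout: one row per marker, one column per line."""
        sym = np.empty(self.calls.shape, dtype=object)
        for code, s in CODE_TO_SYMBOL.items():
            sym[self.calls == code] = s
        return pd.DataFrame(sym, index=self.marker_names, columns=self.line_ids)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.line_ids == other.line_ids
            and self.markers == other.markers
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:  # pragma: no cover - debug convenience
        return f"GenotypeMatrix({self.n_markers} markers x {self.n_lines} lines)"


@dataclass
class PhenotypeTable:
    """Per-line quantitative trait values (e.g. days to heading)."""

    line_ids: list[str]
    values: np.ndarray
    trait_name: str = "days_to_heading"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.line_ids),):
            raise ValueError("phenotype values must align 1:1 with line_ids")

    def aligned_to(self, line_ids: Sequence[str]) -> np.ndarray:
        """Values reordered to ``line_ids``; unknown lines become NaN."""
        pos = {l: i for i, l in enumerate(self.line_ids)}
        out = np.full(len(line_ids), np.nan)
        for j, l in enumerate(line_ids):
            if l in pos:
                out[j] = self.values[pos[l]]
        return out
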