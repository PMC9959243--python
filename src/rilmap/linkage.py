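"""Genetic map construction for selfing RIL populations.

Markers are kept in physical (reference-genome) order; map distances come
from two-point recombination fractions between physically adjacent markers.
Because an F7 RIL accumulates recombination over repeated selfing rounds,
the observed fraction of recombinant lines R overstates the per-meiosis
recombination fraction r.  For selfed RILs the two are related by the
Haldane-Waddington limit

    R = 2r / (1 + 2r)        <=>        r = R / (2 (1 - R)),

and r is then converted to centimorgans with Kosambi's mapping function

    d = 25 ln((1 + 2r) / (1 - 2r)),      r = tanh(d / 50) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import A, B, NA, GenotypeMatrix, MarkerDef, chrom_sort_key

R_CLAMP = 0.4999


# ---------------------------------------------------------------------------
# distance transforms
# ---------------------------------------------------------------------------

def kosambi(r):
    """Map distance in cM for recombination fraction ``r`` (Kosambi)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d_cM):
    """Recombination fraction for a Kosambi map distance in cM."""
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


def ril_correct(R):
    """Meiotic r from the observed selfing-RIL fraction R = 2r/(1+2r)."""
    R = np.asarray(R, dtype=float)
    if np.any(R < 0) or np.any(R >= 0.5):
        raise ValueError("observed RIL recombination fraction must lie in [0, 0.5)")
    r = R / (2.0 * (1.0 - R))
    return float(r) if r.ndim == 0 else r


def ril_observed(r):
    """Forward Haldane-Waddington relation: expected RIL fraction for meiotic r."""
    r = np.asarray(r, dtype=float)
    R = 2.0 * r / (1.0 + 2.0 * r)
    return float(R) if R.ndim == 0 else R


# ---------------------------------------------------------------------------
# two-point estimation
# ---------------------------------------------------------------------------

@dataclass
class RfEstimate:
    """Two-point recombination estimate between a marker pair.

    ``R`` is the observed fraction of recombinant lines among co-non-missing
    homozygous calls (clamped below 0.5), ``r`` the RIL-corrected meiotic
    fraction and ``d_cM`` its Kosambi distance.  ``valid`` is False when
    fewer than two informative lines exist or the raw fraction reached 0.5
    (unlinked-looking pair).
    """

    R: float
    n_informative: int
    r: float = np.nan
    d_cM: float = np.nan
    valid: bool = True


def pairwise_rf(calls_i: np.ndarray, calls_j: np.ndarray) -> tuple[float, int]:
    """Raw (R, n) between two call vectors; hets and missing excluded."""
    hom_i = (calls_i == A) | (calls_i == B)
    hom_j = (calls_j == A) | (calls_j == B)
    both = hom_i & hom_j
    n = int(both.sum())
    if n == 0:
        return np.nan, 0
    disc = int((calls_i[both] != calls_j[both]).sum())
    return disc / n, n


def estimate_rf(
    gm: GenotypeMatrix,
    marker_i: str,
    marker_j: str,
    ril_correction: bool = True,
) -> RfEstimate:
    """Two-point estimate between two named markers of ``gm``."""
    R_raw, n = pairwise_rf(gm.row(marker_i), gm.row(marker_j))
    if n < 2:
        return RfEstimate(R=np.nan, n_informative=n, valid=False)
    if R_raw >= 0.5:
        return RfEstimate(R=R_CLAMP, n_informative=n, valid=False)
    R = min(R_raw, R_CLAMP)
    r = ril_correct(R) if ril_correction else R
    return RfEstimate(R=R, n_informative=n, r=r, d_cM=kosambi(min(r, R_CLAMP)))


# ---------------------------------------------------------------------------
# map construction
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Ordered cM positions per chromosome (physical marker order).

    ``table`` has one row per marker with columns
    ``name, chrom, pos_bp, cM, marker_type, platform``; within each
    chromosome rows are in physical order and the first marker sits at 0 cM.
    """

    table: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def chromosomes(self) -> list[str]:
        seen: list[str] = []
        for c in self.table["chrom"]:
            if c not in seen:
                seen.append(c)
        return seen

    def chrom_table(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == str(chrom)]

    def positions(self, chrom: str) -> np.ndarray:
        return self.chrom_table(chrom)["cM"].to_numpy(dtype=float)

    def length(self, chrom: str) -> float:
        pos = self.positions(chrom)
        return float(pos.max() - pos.min()) if len(pos) else 0.0


def build_map(
    gm: GenotypeMatrix,
    min_informative: int = 2,
    ril_correction: bool = True,
) -> GeneticMap:
    """Cumulative Kosambi map over physically ordered markers.

    Adjacent pairs with no valid two-point estimate (too few informative
    lines, or an observed fraction at/above 0.5) are bridged: the distance
    for the incoming marker is taken from the nearest earlier marker on the
    chromosome that does give a valid estimate, anchored at that marker's
    position (never placing the marker before its left neighbour).  A
    chromosome in which no adjacency at all can be estimated is dropped
    with a warning record.
    """
    gm = gm.sorted_by_position()
    rows = []
    warnings: list[str] = []
    chroms: list[str] = []
    for m in gm.markers:
        if m.chrom not in chroms:
            chroms.append(m.chrom)
    for chrom in chroms:
        idx = [i for i, m in enumerate(gm.markers) if m.chrom == chrom]
        markers = [gm.markers[i] for i in idx]
        calls = gm.calls[idx]
        if len(markers) == 0:
            continue
        pos = np.zeros(len(markers))
        n_valid = 0
        for k in range(1, len(markers)):
            placed = False
            for j in range(k - 1, -1, -1):
                R_raw, n = pairwise_rf(calls[j], calls[k])
                if n >= min_informative and not np.isnan(R_raw) and R_raw < 0.5:
                    R = min(R_raw, R_CLAMP)
                    r = ril_correct(R) if ril_correction else R
                    pos[k] = max(pos[j] + kosambi(r), pos[k - 1])
                    n_valid += 1
                    placed = True
                    break
            if not placed:
                pos[k] = pos[k - 1]
                warnings.append(
                    f"chrom {chrom}: no valid estimate for {markers[k].name}; "
                    "placed at left neighbour"
                )
        if len(markers) >= 2 and n_valid == 0:
            warnings.append(f"chrom {chrom}: all adjacencies invalid; chromosome dropped")
            continue
        for m, p in zip(markers, pos):
            rows.append(
                dict(name=m.name, chrom=m.chrom, pos_bp=m.pos_bp, cM=float(p),
                     marker_type=m.marker_type, platform=m.platform)
            )
    table = pd.DataFrame(rows, columns=["name", "chrom", "pos_bp", "cM", "marker_type", "platform"])
    return GeneticMap(table=table, warnings=warnings)


# ---------------------------------------------------------------------------
# Table-2-style summaries
# ---------------------------------------------------------------------------

@dataclass
class MapSummary:
    """Per-chromosome map statistics plus genome totals.

    ``per_chrom`` columns: chrom, n_markers, total_length_cM,
    avg_interval_cM, largest_gap_cM, gap_marker_left, gap_marker_right,
    gap_left_mb, gap_right_mb, gap_span_mb.

    Genome-total average marker interval is reported in two conventions:
    ``weighted_avg_interval_cM`` = sum(lengths) / sum(n_i - 1) and
    ``unweighted_avg_interval_cM`` = mean of per-chromosome averages
    (printed map tables in the field use either).
    """

    per_chrom: pd.DataFrame
    n_markers: int
    total_length_cM: float
    weighted_avg_interval_cM: float
    unweighted_avg_interval_cM: float

    @classmethod
    def from_per_chrom(cls, per_chrom: pd.DataFrame) -> "MapSummary":
        if len(per_chrom) == 0:
            raise ValueError("empty chromosome set")
        n = int(per_chrom["n_markers"].sum())
        total = float(per_chrom["total_length_cM"].sum())
        denom = float((per_chrom["n_markers"] - 1).sum())
        weighted = total / denom if denom > 0 else np.nan
        unweighted = float(per_chrom["avg_interval_cM"].mean())
        return cls(per_chrom.reset_index(drop=True), n, total, weighted, unweighted)

    def largest_gap(self, chrom: str) -> float:
        row = self.per_chrom[self.per_chrom["chrom"] == str(chrom)]
        if len(row) != 1:
            raise KeyError(f"chromosome {chrom} not in summary")
        return float(row["largest_gap_cM"].iloc[0])


def summarize_map(gmap: GeneticMap) -> MapSummary:
    """Per-chromosome marker counts, lengths, mean intervals and largest gaps."""
    if len(gmap.table) == 0:
        raise ValueError("empty map")
    rows = []
    for chrom in gmap.chromosomes():
        sub = gmap.chrom_table(chrom)
        n = len(sub)
        pos = sub["cM"].to_numpy(dtype=float)
        length = float(pos.max() - pos.min())
        avg = length / (n - 1) if n > 1 else 0.0
        if n > 1:
            gaps = np.diff(pos)
            g = int(np.argmax(gaps))
            left, right = sub.iloc[g], sub.iloc[g + 1]
            largest = float(gaps[g])
            gm_l, gm_r = left["name"], right["name"]
            mb_l = left["pos_bp"] / 1e6
            mb_r = right["pos_bp"] / 1e6
            span = mb_r - mb_l
        else:
            largest, gm_l, gm_r, mb_l, mb_r, span = 0.0, "", "", np.nan, np.nan, np.nan
        rows.append(
            dict(chrom=chrom, n_markers=n, total_length_cM=length,
                 avg_interval_cM=avg, largest_gap_cM=largest,
                 gap_marker_left=gm_l, gap_marker_right=gm_r,
                 gap_left_mb=mb_l, gap_right_mb=mb_r, gap_span_mb=span)
        )
    per_chrom = pd.DataFrame(rows)
    per_chrom = per_chrom.sort_values(
        "chrom", key=lambda s: s.map(lambda c: chrom_sort_key(c))
    ).reset_index(drop=True)
    return MapSummary.from_per_chrom(per_chrom)


def marker_spacing_kb(n_markers: int, genome_size_bp: float) -> float:
    """Mean physical spacing implied by n markers on a genome, in kb."""
    if n_markers <= 0:
        raise ValueError("need at least one marker")
    return genome_size_bp / n_markers / 1e3
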