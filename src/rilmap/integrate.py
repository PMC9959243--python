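"""Cross-platform marker integration and map comparison.

Merging the dominant-amplicon/SNP set from random-amplicon sequencing with
an array-SNP set over the same lines densifies the map; two diagnostics
quantify how well the platforms agree and what the extra markers buy:

* the correspondence ratio — each amplicon-platform marker is paired with
  the physically nearest array SNP within 50 kb and their calls compared
  line by line;
* largest-gap narrowing — per chromosome, the change in the longest
  marker-free interval between the array-only and the integrated map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import A, B, NA, GenotypeMatrix, MarkerDef, sort_markers
from .linkage import MapSummary


def integrate_markers(
    gm_grasdi: GenotypeMatrix,
    gm_golden: GenotypeMatrix,
) -> tuple[GenotypeMatrix, list[MarkerDef]]:
    """Column-wise union of two platforms' matrices over the same lines.

    Lines are aligned by id (order may differ); marker name collisions get
    a platform suffix.  The union is sorted by (chromosome, position) and
    is ready for re-QC (co-localized dedup) and map building.
    """
    if set(gm_grasdi.line_ids) != set(gm_golden.line_ids):
        raise ValueError("platforms genotyped different line sets")
    gm_golden = gm_golden.reorder_lines(gm_grasdi.line_ids)
    names_g = set(gm_grasdi.marker_names)
    names_o = set(gm_golden.marker_names)
    clash = names_g & names_o

    def fix(markers, platform_tag):
        return [
            m.renamed(f"{m.name}|{platform_tag}") if m.name in clash else m
            for m in markers
        ]

    markers = fix(gm_grasdi.markers, "GRASDI") + fix(gm_golden.markers, "GOLDENGATE")
    calls = np.vstack([gm_grasdi.calls, gm_golden.calls])
    merged = GenotypeMatrix(gm_grasdi.line_ids, markers, calls).sorted_by_position()
    return merged, merged.markers


@dataclass
class CorrespondenceResult:
    """Agreement between platform calls at markers paired within a window.

    ``ratio_cellwise`` counts agreeing co-non-missing cells over all
    compared cells; ``ratio_markerwise`` counts paired markers whose
    compared cells all agree.  Both are NaN when nothing could be paired.
    """

    n_pairs: int
    cells_compared: int
    cells_agreeing: int
    ratio_cellwise: float
    ratio_markerwise: float
    window_bp: int
    pairs: pd.DataFrame


def correspondence_ratio(
    gm_grasdi: GenotypeMatrix,
    gm_golden: GenotypeMatrix,
    window_bp: int = 50_000,
) -> CorrespondenceResult:
    """Pair each amplicon-platform marker with its nearest array SNP within
    ``window_bp`` on the same chromosome and measure call agreement."""
    if set(gm_grasdi.line_ids) != set(gm_golden.line_ids):
        raise ValueError("platforms genotyped different line sets")
    gm_golden = gm_golden.reorder_lines(gm_grasdi.line_ids)
    by_chrom: dict[str, list[int]] = {}
    for j, m in enumerate(gm_golden.markers):
        by_chrom.setdefault(m.chrom, []).append(j)

    rows = []
    cells_compared = cells_agreeing = 0
    n_perfect = 0
    for i, m in enumerate(gm_grasdi.markers):
        cand = by_chrom.get(m.chrom, [])
        if not cand:
            continue
        dists = np.array([abs(gm_golden.markers[j].pos_bp - m.pos_bp) for j in cand])
        order = np.lexsort((np.array([gm_golden.markers[j].pos_bp for j in cand]), dists))
        best = cand[order[0]]
        if dists[order[0]] > window_bp:
            continue
        x, y = gm_grasdi.calls[i], gm_golden.calls[best]
        # only co-homozygous cells are comparable: dominant amplicons cannot
        # express a het, so an H on either side is uninformative, not a clash
        both = np.isin(x, (A, B)) & np.isin(y, (A, B))
        n = int(both.sum())
        agree = int((x[both] == y[both]).sum())
        cells_compared += n
        cells_agreeing += agree
        if n > 0 and agree == n:
            n_perfect += 1
        rows.append(
            dict(grasdi=m.name, goldengate=gm_golden.markers[best].name,
                 distance_bp=int(dists[order[0]]), cells=n, agreeing=agree)
        )
    n_pairs = len(rows)
    return CorrespondenceResult(
        n_pairs=n_pairs,
        cells_compared=cells_compared,
        cells_agreeing=cells_agreeing,
        ratio_cellwise=cells_agreeing / cells_compared if cells_compared else np.nan,
        ratio_markerwise=n_perfect / n_pairs if n_pairs else np.nan,
        window_bp=window_bp,
        pairs=pd.DataFrame(rows, columns=["grasdi", "goldengate", "distance_bp",
                                          "cells", "agreeing"]),
    )


@dataclass
class GapComparison:
    """Per-chromosome change in the largest marker-free interval."""

    per_chrom: pd.DataFrame  # chrom, gap_before_cM, gap_after_cM, reduction_cM
    max_reduction_cM: float
    chromosomes_narrowed: list[str]
    chromosomes_widened: list[str]


def compare_gaps(summary_before: MapSummary, summary_after: MapSummary) -> GapComparison:
    """Signed largest-gap reduction per chromosome (before minus after)."""
    before = summary_before.per_chrom.set_index("chrom")["largest_gap_cM"]
    after = summary_after.per_chrom.set_index("chrom")["largest_gap_cM"]
    if set(before.index) != set(after.index):
        raise ValueError("chromosome sets differ between summaries")
    after = after.reindex(before.index)
    red = before - after
    per_chrom = pd.DataFrame(
        dict(chrom=before.index, gap_before_cM=before.values,
             gap_after_cM=after.values, reduction_cM=red.values)
    ).reset_index(drop=True)
    return GapComparison(
        per_chrom=per_chrom,
        max_reduction_cM=float(red.max()),
        chromosomes_narrowed=[c for c, v in red.items() if v > 0],
        chromosomes_widened=[c for c, v in red.items() if v < 0],
    )
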