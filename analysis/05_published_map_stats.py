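#!/usr/bin/env python
"""Recompute the published map statistics from the transcribed tables.

From the per-chromosome marker counts, map lengths and largest gaps of the
four rice RIL populations (integrated and array-only maps), recomputes:
genome-wide mean marker intervals, implied physical marker spacing at the
~373 Mb reference genome size, and the per-population maximum largest-gap
reduction after integrating the random-amplicon markers.

Output: results/published_map_stats.tsv
"""

import sys
from pathlib import Path

import pandas as pd

from rilmap.integrate import compare_gaps
from rilmap.linkage import marker_spacing_kb
from rilmap.published import GENOME_SIZE_BP, POPULATIONS, load_published_summary

OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for pop in POPULATIONS:
        integrated = load_published_summary(pop, "integrated")
        array_only = load_published_summary(pop, "goldengate")
        gaps = compare_gaps(array_only, integrated)
        best = gaps.per_chrom.loc[gaps.per_chrom["reduction_cM"].idxmax()]
        rows.append(dict(
            population=pop.upper(),
            n_markers_integrated=integrated.n_markers,
            n_markers_array=array_only.n_markers,
            mean_interval_integrated_cM=round(integrated.weighted_avg_interval_cM, 1),
            mean_interval_unweighted_cM=round(integrated.unweighted_avg_interval_cM, 2),
            mean_interval_array_cM=round(array_only.weighted_avg_interval_cM, 1),
            spacing_kb=round(marker_spacing_kb(integrated.n_markers, GENOME_SIZE_BP)),
            max_gap_reduction_cM=round(best["reduction_cM"], 1),
            max_gap_reduction_chrom=best["chrom"],
            n_chrom_widened=len(gaps.chromosomes_widened),
        ))
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "published_map_stats.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print("\nintegrating the random-amplicon markers roughly halves the mean "
          "marker interval in every population; a few chromosomes' largest "
          "gaps widen slightly, as the source tables also show")


if __name__ == "__main__":
    sys.exit(main())
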