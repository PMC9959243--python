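#!/usr/bin/env python
"""Build Kosambi linkage maps for both platforms in physical marker order.

Adjacent-marker recombination fractions are corrected for selfing-RIL
accumulation (R = 2r/(1+2r)) before the Kosambi transform; per-chromosome
marker counts, lengths, mean intervals and largest gaps are written as
Table-2-style summaries.

Outputs under results/:
    map_grasdi.tsv, map_goldengate.tsv,
    map_summary_grasdi.tsv, map_summary_goldengate.tsv
"""

import sys
from pathlib import Path

from rilmap import io as rio
from rilmap.linkage import build_map, summarize_map

OUT = Path("results")


def main() -> None:
    for tag in ("grasdi", "goldengate"):
        gm, _ = rio.read_cross_csv(OUT / f"genotypes_{tag}_qc.csv")
        gmap = build_map(gm)
        summary = summarize_map(gmap)
        rio.write_map_tsv(gmap, OUT / f"map_{tag}.tsv")
        rio.write_map_summary(summary, OUT / f"map_summary_{tag}.tsv")
        for w in gmap.warnings:
            print(f"  warning ({tag}): {w}")
        print(f"{tag}: {summary.n_markers} markers, "
              f"{summary.total_length_cM:.0f} cM total, "
              f"mean interval {summary.weighted_avg_interval_cM:.1f} cM")


if __name__ == "__main__":
    sys.exit(main())
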