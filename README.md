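# rilmap

Linkage-map construction and QTL mapping for biparental **recombinant
inbred line (RIL)** populations genotyped with a mix of **dominant
presence/absence amplicon markers** and **codominant SNPs** — the situation
that arises when closely related cultivars (e.g. Japanese *japonica* rice
lines sharing Koshihikari as a common parent) are genotyped by random
amplicon sequencing alongside a fixed-content SNP array.

## What it computes

Genotypes are coded by parental origin: `A` (common-parent homozygote),
`B` (founder homozygote), `H` (residual heterozygote), `-` (missing).

1. **Marker calling** (`rilmap.calling`) — amplicon loci present in exactly
   one parent are scored per line by read count (present / absent /
   too-few-reads → missing); SNP allele pairs are recoded to parental
   origin. Markers are named `AMP/chrom/pos` and `SNP/chrom/pos`.
2. **QC cascade** (`rilmap.qc`) — monomorphic markers, excess
   heterozygosity, physically close pairs that still "recombine"
   (alignment artifacts), markers failing the 1:1 A:B chi-square a RIL must
   satisfy, and co-localized duplicates (one representative kept).
3. **Map construction** (`rilmap.linkage`) — markers stay in reference
   order; adjacent-pair recombination fractions *R* are corrected for
   selfing-RIL accumulation (Haldane–Waddington, R = 2r/(1+2r)) and
   converted to cM with Kosambi's function d = 25 ln((1+2r)/(1−2r)).
   Summaries report per-chromosome marker counts, lengths, mean intervals
   and the largest marker-free gap.
4. **Platform integration** (`rilmap.integrate`) — cross-platform
   correspondence ratio (markers paired within 50 kb), merged maps, and
   per-chromosome largest-gap narrowing.
5. **Composite interval mapping** (`rilmap.qtl`) — two-state
   forward–backward genotype probabilities on a 1 cM grid, Haley–Knott
   regression with forward-selected marker cofactors (3 cM exclusion
   window), genome-wide LOD thresholds from phenotype permutations, peaks
   with 1-LOD support intervals.
6. **Synthetic populations** (`rilmap.simulate`) — F7 single-seed-descent
   RILs under a no-interference crossover model, amplicon read counts, array
   calls with error/missingness, additive QTL phenotypes. Every stage of
   the pipeline is testable without external data.

The per-chromosome map tables published for the four rice RIL populations
(RIL71/RIL98/RIL16/RIL91, integrated and array-only maps) ship as data
under `rilmap.published` and drive the map-arithmetic analyses.

## Worked example

```python
import numpy as np
from rilmap.simulate import (SimConfig, rice_genome, simulate_ril_population,
                             uniform_marker_loci)
from rilmap.linkage import build_map, summarize_map

genome = rice_genome()                      # 12 chromosomes, ~1515 cM
cfg = SimConfig(n_lines=96, final_generation=7, seed=1)
truth = simulate_ril_population(genome, cfg)
loci = uniform_marker_loci(genome, 38)      # 38 markers per chromosome
gmap = build_map(truth.calls_at(loci))
s = summarize_map(gmap)
print(f"{s.n_markers} markers, {s.total_length_cM:.0f} cM, "
      f"mean interval {s.weighted_avg_interval_cM:.1f} cM")
```

prints

```
456 markers, 1406 cM, mean interval 3.2 cM
```

i.e. a 96-line F7 population with 456 retained markers yields a ~1,400 cM
genome at a 3.2 cM mean marker interval — the marker density and map scale
of a real integrated rice RIL map of this size (the estimate sits a little
under the simulated 1,515 cM truth because the outermost markers do not
reach the chromosome tips).

The numbered scripts under `analysis/` run the full study flow on a
simulated RIL98-style population (96 lines) and on the published map
tables; run them in order from the repository root:

```bash
python analysis/01_simulate_population.py   # raw evidence under results/sim/
python analysis/02_call_and_qc.py           # calling + QC cascade
python analysis/03_build_maps.py            # Kosambi maps per platform
python analysis/04_integrate_maps.py        # correspondence + gap narrowing
python analysis/05_published_map_stats.py   # published-table arithmetic
python analysis/06_qtl_scan.py              # CIM + 1000 permutations
python analysis/07_threshold_calibration.py # null type-I calibration
```

A `rilmap` console command exposes the same stages
(`rilmap simulate|call|qc|map|integrate|qtlscan|report`).

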