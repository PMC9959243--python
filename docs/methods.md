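# Methods

## Population model

The simulator produces biparental RILs by literal single seed descent: the
F1 is heterozygous everywhere; each generation every line is advanced by
one selfed offspring (two independent gametes from the same plant).  At
F_t the expected per-locus heterozygosity is (1/2)^(t−1) — 1.56% at the
default t = 7 — and the test suite checks the halving across t = 2..7.

Meiosis uses a no-interference model: the crossover count per chromosome is
Poisson(L/100) for a chromosome of L cM with i.i.d. uniform positions.
This choice keeps closed-form oracles available: two loci d cM apart
recombine per meiosis with the Haldane fraction r = (1 − e^(−2d/100))/2,
and recombinant lines accumulate in the finished RIL toward the
Haldane–Waddington limit R = 2r/(1+2r).  At F7 the observed fraction sits
slightly (~0.007 absolute) below that limit; the convergence property is
therefore tested near fixation (t = 15), while F7-level behaviour
(heterozygosity, genotype frequencies) is tested at t = 7.  Kosambi's
function is used downstream purely as the named distance transform; the
simulator itself is Haldane-consistent, which costs a few percent of map
length in round trips but keeps every expectation computable by hand.

Physical coordinates are linear in cM within a chromosome (a fixed
bp-per-cM per chromosome).  The default genome is rice-scale: 12
chromosomes, ~1,515 cM, ~372 Mb (IRGSP-scale physical lengths).  Presets
mirror the four study populations' sizes (190/96/95/94 lines).

## Marker evidence

*Dominant amplicons.*  Each amplicon locus is carried by exactly one
parent.  Carrier lines (presence homozygotes and heterozygotes) emit
Poisson(λ) reads, zeroed with a dropout probability; absence homozygotes
emit structural zeros.  Defaults: λ = 20, dropout = 0.002.

*Codominant SNPs.*  True calls are flipped A↔B with probability 0.001 and
masked with probability 0.02, independently per cell.

The error/dropout defaults were fixed so that a default joint simulation of
the two platforms agrees at the ~99.5–99.8% level when paired within 50 kb,
matching the agreement scale reported for real data of this design.  The
generator does **not** emulate: PCR amplification bias, alignment artifacts
and reference errors (the QC cascade is exercised by injected defects
instead), segregation-distortion hotspots beyond drift, or linkage between
platform error and genotype.  Passing tests therefore demonstrate the
pipeline's statistical behaviour under the stated stochastic model, not
robustness to every failure mode of real amplicon sequencing.

## Calling and QC

Amplicon calling keeps loci where exactly one parent shows ≥ `min_reads`
reads (default 2 — separates Poisson noise from dropout at λ ≥ 10, the
threshold is exposed because only "low read count" is specified in the
source protocol).  Offspring: count ≥ min_reads → presence parent; 0 →
absence parent; in between → missing.  A heterozygous line at an amplicon
locus is indistinguishable from a presence homozygote and is coded as one —
a documented dominant-marker limitation left to QC.

QC stages, in order, each a pure column filter (no call rewritten):

| stage | rule | default |
|---|---|---|
| monomorphic | single non-missing symbol | — |
| excess het | het fraction among non-missing > threshold | 0.10 (F7 expectation 1.6% plus slack) |
| local recombinants | adjacent pair within window disagreeing among co-homozygous calls | 50 kb window, 5% mismatch |
| segregation | chi-square 1:1 on A:B counts, 1 df | α = 0.01 per marker, no multiplicity correction; < 10 informative calls → flagged, kept |
| co-localized dedup | adjacent markers with identical co-observed calls | keep fewest-missing; ties SNP > AMP > smaller bp |

The adjacency-dependent stages (local recombinants, dedup) loop to a fixed
point, and the cascade re-runs them after segregation removals so the whole
pipeline is idempotent.  Deterministic tie-breaks make output independent of
input order.

## Map construction

Marker order is physical (reference) order — order is never re-estimated,
which makes maps deterministic and reflects how such maps are actually
assembled when a reference genome exists.  For each adjacent pair the
observed recombinant fraction R (hets excluded, pairwise-complete lines,
clamped below 0.5) is corrected to meiotic r = R/(2(1−R)) and transformed
by Kosambi; positions are the cumulative sums, first marker at 0.  The RIL
correction is on by default (without it RIL distances inflate roughly
two-fold) and can be disabled for comparison with tools that skip it.
Pairs with no valid estimate (fewer than 2 informative lines or R ≥ 0.5)
are bridged from the nearest earlier marker that does give one, never
placing a marker before its left neighbour; a chromosome with no estimable
adjacency at all is dropped with a warning.

Summaries report, per chromosome: marker count, length, mean interval
(length/(n−1)) and the largest gap with flanking markers and physical Mb
positions.  Genome-total mean interval is emitted in **both** conventions —
Σ lengths / Σ (n_i − 1) (weighted) and the unweighted mean of
per-chromosome averages — because published map tables use either, and the
four transcribed populations demonstrably mix them (three totals match the
weighted form, one the unweighted).  Report rounding: cM one decimal, Mb
two.

## Platform integration

The correspondence diagnostic pairs each amplicon-platform marker with the
physically nearest array SNP within 50 kb on the same chromosome and counts
agreement over co-homozygous cells only — dominant amplicons cannot express
a het, so an H on the codominant side is uninformative rather than a
disagreement.  Both a cellwise ratio (agreeing cells / compared cells; the
headline) and a markerwise ratio (pairs whose cells all agree / pairs) are
reported.  Integration takes the column-wise union over id-aligned lines,
suffixes name collisions by platform, re-runs the co-localized dedup, and
rebuilds the map.  Gap comparison is exact signed arithmetic per
chromosome; widened gaps are reported as negative reductions, not
suppressed.

## Composite interval mapping

Hidden parental origin along each chromosome is a two-state {AA, BB}
Markov chain: residual heterozygotes are ≲1.6% at F7 and dominant markers
cannot observe them, so H is treated as an uninformative emission like
missing rather than a third state.  Transition probability between points
d cM apart is the RIL-accumulated 2r/(1+2r) with r = kosambi⁻¹(d);
emissions flip the true state with error ε (default 0.002).  The
forward–backward pass is exact and, at ε = 0, interpolates observed
homozygous markers exactly.

The scan is Haley–Knott-style regression of phenotype on the expected
dosage E[x] = P(AA) − P(BB) plus cofactor codings (A = +1, B = −1, H = 0,
missing = column mean), at every grid point (default walk 1 cM);
LOD = (n/2)·log₁₀(RSS_reduced/RSS_full).  Regression rather than an EM
mixture keeps the scan deterministic and fast; for near-homozygous RILs the
approximation is standard.  Cofactors (default 3; forward selection by RSS
reduction) are excluded when within half the window width (default window
3 cM) of the test position on the same chromosome.  Rank-deficient cofactor
blocks are handled by projecting onto an orthonormal basis of the actual
column space, so collinear cofactors degrade gracefully.

Permutation thresholds re-run the **entire** procedure — cofactor
reselection included — on each permuted phenotype and take the empirical
(1−α) quantile of genome-wide maximum LODs; thresholds are monotone in α by
construction and reproducible from the seed.  Detected peaks are local
maxima above threshold; support intervals are the maximal contiguous grid
run with LOD ≥ peak − 1, expanded outward by one grid point on a side whose
boundary is still strictly above the cut (the true crossing lies beyond
it); peaks with overlapping intervals merge to the higher one.

## Problem sizes used in the checks

The calibration experiment uses 100 null datasets of 96 lines on 3
chromosomes × 30 markers with 200 permutations each at α = 5%; accepted
within two binomial standard errors of nominal (±4.4 points).  QTL interval
coverage uses 100 replicates of a single a/σ = 1 QTL in 200 lines on a
51-marker chromosome, requiring ≥ 90% 1-LOD coverage.  Chromosome-length
recovery uses 50 replicates of a 120 cM, 50-marker, 96-line chromosome,
requiring the mean estimate within 15% of truth.  These sizes give binomial
noise comfortably inside the stated tolerances while each experiment stays
in the tens of seconds.

## Known limitations

- Dominant amplicon hets are miscalled as presence homozygotes by design;
  at F7 this inflates adjacent-pair recombination slightly (maps run a few
  percent long in simulation, as they visibly do in real integrated maps).
- Two-point cumulative maps ignore multipoint information; no ordering or
  grouping is attempted, so a wrong reference order would propagate.
- 1-LOD support intervals are a support convention, not calibrated
  confidence intervals; with linked cofactors their coverage hovers near,
  not above, the conventional 90–95% band.
- The permutation threshold assumes exchangeable lines under the null —
  true for RILs without family structure, not for structured panels.
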