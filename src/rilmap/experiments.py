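"""Repeatable simulation experiments over the pipeline.

These drive whole-procedure properties that single-function unit tests
cannot see: calibration of the permutation threshold's genome-wide type-I
error under a null (no-QTL) phenotype, and coverage of a planted QTL by
its 1-LOD support interval.  Both are used by the analysis scripts and the
acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .qtl import (
    CIMScanner,
    cim_scan,
    detect_qtl,
    genotype_probabilities,
    select_cofactors,
)
from .simulate import (
    ChromosomeSpec,
    GenomeSpec,
    QTL,
    QTLModel,
    SimConfig,
    simulate_phenotype,
    simulate_ril_population,
    true_genetic_map,
    uniform_marker_loci,
)


def small_genome(n_chrom: int = 3, length_cM: float = 100.0,
                 length_bp: int = 30_000_000) -> GenomeSpec:
    """A reduced genome for scan experiments (full 12-chromosome rice runs
    carry no extra information for calibration purposes)."""
    return GenomeSpec(
        [ChromosomeSpec(str(i + 1), length_cM, length_bp) for i in range(n_chrom)]
    )


@dataclass
class CalibrationResult:
    n_datasets: int
    n_exceed: int
    alpha: float

    @property
    def type_i_error_pct(self) -> float:
        return 100.0 * self.n_exceed / self.n_datasets


def null_type_i_error(
    n_datasets: int = 100,
    n_perm: int = 200,
    n_lines: int = 96,
    n_chrom: int = 3,
    n_markers_per_chrom: int = 30,
    chrom_length_cM: float = 100.0,
    alpha: float = 0.05,
    seed: int = 0,
    n_cofactors: int = 3,
    window_cM: float = 3.0,
    step_cM: float = 1.0,
) -> CalibrationResult:
    """Genome-wide type-I error of the permutation threshold under the null.

    For each dataset an F7 RIL population is simulated, a standard-normal
    phenotype independent of genotype is drawn, the nominal-level threshold
    is computed from within-dataset permutations (cofactors reselected per
    permutation), and the dataset counts as a false positive when its
    observed maximum LOD exceeds its own threshold.
    """
    genome = small_genome(n_chrom, chrom_length_cM)
    loci = uniform_marker_loci(genome, n_markers_per_chrom)
    gmap_template = None
    ss = np.random.SeedSequence(seed)
    n_exceed = 0
    for child in ss.spawn(n_datasets):
        rng = np.random.default_rng(child)
        cfg = SimConfig(n_lines=n_lines, final_generation=7, seed=0)
        truth = simulate_ril_population(genome, cfg, rng=rng)
        gm = truth.calls_at(loci)
        gmap = true_genetic_map(genome, loci)
        probs = genotype_probabilities(gmap, gm, step_cM)
        scanner = CIMScanner(probs, gm, gmap, window_cM, n_cofactors)
        y = rng.normal(size=n_lines)
        observed = scanner.max_lod(y)
        maxima = np.empty(n_perm)
        for p in range(n_perm):
            maxima[p] = scanner.max_lod(rng.permutation(y))
        threshold = float(np.quantile(maxima, 1.0 - alpha))
        if observed > threshold:
            n_exceed += 1
    return CalibrationResult(n_datasets, n_exceed, alpha)


@dataclass
class RecoveryResult:
    n_sims: int
    n_covered: int
    peak_positions: np.ndarray

    @property
    def coverage_pct(self) -> float:
        return 100.0 * self.n_covered / self.n_sims


def qtl_interval_coverage(
    n_sims: int = 100,
    n_lines: int = 200,
    effect: float = 1.0,
    residual_sd: float = 1.0,
    qtl_pos_cM: float = 50.0,
    chrom_length_cM: float = 100.0,
    n_markers: int = 51,
    seed: int = 0,
    n_cofactors: int = 3,
    window_cM: float = 3.0,
    step_cM: float = 1.0,
    lod_floor: float = 3.0,
) -> RecoveryResult:
    """How often the 1-LOD support interval covers a planted additive QTL.

    One chromosome, a dense map (true marker positions), a single QTL of
    size ``effect`` against ``residual_sd``; each replicate scans with CIM
    and checks whether the highest peak's 1-LOD interval contains the true
    position.  Replicates whose maximum LOD stays below ``lod_floor`` are
    counted as non-covering (nothing detectable to report).
    """
    genome = small_genome(1, chrom_length_cM)
    loci = uniform_marker_loci(genome, n_markers)
    gmap = true_genetic_map(genome, loci)
    model = QTLModel([QTL("1", qtl_pos_cM, effect)], residual_sd=residual_sd)
    ss = np.random.SeedSequence(seed)
    n_cov = 0
    peaks = []
    for child in ss.spawn(n_sims):
        rng = np.random.default_rng(child)
        cfg = SimConfig(n_lines=n_lines, final_generation=7, seed=0)
        truth = simulate_ril_population(genome, cfg, rng=rng)
        gm = truth.calls_at(loci)
        pheno = simulate_phenotype(truth, model, rng)
        probs = genotype_probabilities(gmap, gm, step_cM)
        y = pheno.values
        cof = select_cofactors(gm, y, n_cofactors)
        scan = cim_scan(probs, gm, gmap, y, cof, window_cM)
        found = detect_qtl(scan, lod_floor)
        if not found:
            continue
        best = max(found, key=lambda p: p.lod)
        peaks.append(best.pos_cM)
        if best.interval_cM[0] <= qtl_pos_cM <= best.interval_cM[1]:
            n_cov += 1
    return RecoveryResult(n_sims, n_cov, np.asarray(peaks))
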