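"""End-to-end orchestration: simulate -> call -> QC -> map -> integrate -> QTL.

Every stage reads and writes only the documented text formats, so stages
are independently re-runnable; all randomness derives from one seed and
each output file records the seed and a config hash in its header.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as rio
from .calling import call_amplicon_markers, write_read_table
from .genotypes import GenotypeMatrix
from .integrate import compare_gaps, correspondence_ratio, integrate_markers
from .linkage import build_map, summarize_map
from .qc import QCParams, dedup_colocalized, run_qc
from .qtl import (
    CIMScanner,
    cim_scan,
    detect_qtl,
    genotype_probabilities,
    permutation_threshold,
    select_cofactors,
)
from .simulate import (
    QTLModel,
    SimConfig,
    heading_date_model,
    rice_genome,
    simulate_goldengate,
    simulate_phenotype,
    simulate_reads,
    simulate_ril_population,
    uniform_marker_loci,
)

log = logging.getLogger("rilmap")

_ALLOWED_KEYS = {
    "outdir", "seed", "n_lines", "final_generation", "n_chromosomes",
    "n_grasdi_snp_per_chrom", "n_amp_per_chrom", "n_goldengate_per_chrom",
    "missing_rate", "genotype_error_rate", "amplicon_read_mean",
    "amplicon_dropout", "min_reads", "max_het_frac", "window_bp",
    "max_mismatch_frac", "segregation_alpha", "step_cM", "window_cM",
    "n_perm", "n_cofactors", "alphas", "qtl_effect", "qtl_residual_sd",
    "make_plots",
}


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; ``seed`` is mandatory."""

    outdir: str
    seed: int
    # population / genome
    n_lines: int = 96
    final_generation: int = 7
    n_chromosomes: int = 12
    n_grasdi_snp_per_chrom: int = 40
    n_amp_per_chrom: int = 46
    n_goldengate_per_chrom: int = 24
    # evidence noise
    missing_rate: float = 0.02
    genotype_error_rate: float = 0.001
    amplicon_read_mean: float = 20.0
    amplicon_dropout: float = 0.002
    # calling / QC
    min_reads: int = 2
    max_het_frac: float = 0.10
    window_bp: int = 50_000
    max_mismatch_frac: float = 0.05
    segregation_alpha: float = 0.01
    # QTL scan
    step_cM: float = 1.0
    window_cM: float = 3.0
    n_perm: int = 1000
    n_cofactors: int = 3
    alphas: tuple[float, ...] = (0.01, 0.05, 0.10)
    qtl_effect: float = 2.0
    qtl_residual_sd: float = 2.5
    make_plots: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in d:
            raise ValueError("seed is mandatory")
        d = dict(d)
        if "alphas" in d:
            d["alphas"] = tuple(d["alphas"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def hash(self) -> str:
        # the hash identifies the run's parameters; the output path is not one
        d = {k: v for k, v in asdict(self).items() if k != "outdir"}
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:10]

    def header(self) -> list[str]:
        return [f"seed={self.seed}", f"config_hash={self.hash()}"]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the in-memory artifacts and writes files.

    Stage failures raise with the stage name attached; outputs written by
    completed stages are left in place.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    hdr = config.header()
    artifacts: dict = {}
    stage = "setup"
    try:
        ss = np.random.SeedSequence(config.seed)
        rngs = [np.random.default_rng(s) for s in ss.spawn(6)]
        genome = rice_genome(config.n_chromosomes)
        sim = SimConfig(
            n_lines=config.n_lines, final_generation=config.final_generation,
            seed=config.seed, missing_rate=config.missing_rate,
            genotype_error_rate=config.genotype_error_rate,
            amplicon_read_mean=config.amplicon_read_mean,
            amplicon_dropout=config.amplicon_dropout,
        )

        stage = "simulate"
        truth = simulate_ril_population(genome, sim, rng=rngs[0])
        amp_loci = uniform_marker_loci(genome, config.n_amp_per_chrom, "AMP",
                                       "GRASDI", rng=rngs[1])
        snp_loci = uniform_marker_loci(genome, config.n_grasdi_snp_per_chrom,
                                       "SNP", "GRASDI", rng=rngs[1])
        gg_loci = uniform_marker_loci(genome, config.n_goldengate_per_chrom,
                                      "SNP", "GOLDENGATE", rng=rngs[1], prefix="GG")
        reads = simulate_reads(truth, amp_loci, sim, rng=rngs[2])
        gm_grasdi_snp = simulate_goldengate(truth, snp_loci, sim, rng=rngs[2])
        gm_golden = simulate_goldengate(truth, gg_loci, sim, rng=rngs[2])
        model = heading_date_model(config.qtl_effect, config.qtl_residual_sd)
        present = {c.label for c in genome.chromosomes}
        model.qtls = [q for q in model.qtls if q.chrom in present]
        pheno = simulate_phenotype(truth, model, rngs[3])
        write_read_table(reads, out / "amplicon_reads.tsv", hdr)
        rio.write_phenotype_table(pheno, out / "phenotype.tsv", hdr)
        artifacts.update(truth=truth, reads=reads, phenotype=pheno, qtl_model=model)
        log.info("simulate: %d lines, %d amp + %d SNP + %d array loci",
                 config.n_lines, len(amp_loci), len(snp_loci), len(gg_loci))

        stage = "call"
        gm_amp, rejects = call_amplicon_markers(reads, config.min_reads)
        merged = GenotypeMatrix(
            gm_amp.line_ids,
            gm_amp.markers + gm_grasdi_snp.markers,
            np.vstack([gm_amp.calls, gm_grasdi_snp.calls]),
        ).sorted_by_position()
        rejects.to_csv(out / "amplicon_rejections.tsv", sep="\t", index=False)
        rio.write_cross_csv(merged, out / "genotypes_grasdi_raw.csv", header_comments=hdr)
        rio.write_cross_csv(gm_golden, out / "genotypes_goldengate_raw.csv",
                            header_comments=hdr)
        artifacts["gm_grasdi_raw"] = merged
        log.info("call: %d GRAS-Di markers (%d rejected amplicon loci)",
                 merged.n_markers, len(rejects))

        stage = "qc"
        qcp = QCParams(
            max_het_frac=config.max_het_frac, window_bp=config.window_bp,
            max_mismatch_frac=config.max_mismatch_frac,
            segregation_alpha=config.segregation_alpha,
        )
        gm_grasdi, report_g = run_qc(merged, qcp)
        gm_gg, report_o = run_qc(gm_golden, qcp)
        (out / "qc_grasdi.json").write_text(report_g.to_json())
        (out / "qc_goldengate.json").write_text(report_o.to_json())
        artifacts.update(gm_grasdi=gm_grasdi, gm_goldengate=gm_gg,
                         qc_reports=(report_g, report_o))
        log.info("qc: retained %d GRAS-Di / %d array markers",
                 gm_grasdi.n_markers, gm_gg.n_markers)

        stage = "map"
        map_g = build_map(gm_grasdi)
        map_o = build_map(gm_gg)
        sum_g, sum_o = summarize_map(map_g), summarize_map(map_o)
        rio.write_map_tsv(map_g, out / "map_grasdi.tsv")
        rio.write_map_tsv(map_o, out / "map_goldengate.tsv")
        rio.write_map_summary(sum_g, out / "map_summary_grasdi.tsv")
        rio.write_map_summary(sum_o, out / "map_summary_goldengate.tsv")
        artifacts.update(map_grasdi=map_g, map_goldengate=map_o)

        stage = "integrate"
        corr = correspondence_ratio(gm_grasdi, gm_gg, config.window_bp)
        gm_int, _ = integrate_markers(gm_grasdi, gm_gg)
        gm_int, _ = dedup_colocalized(gm_int)
        map_int = build_map(gm_int)
        sum_int = summarize_map(map_int)
        gaps = compare_gaps(sum_o, sum_int)
        rio.write_cross_csv(gm_int, out / "genotypes_integrated.csv",
                            gmap=map_int, header_comments=hdr)
        rio.write_map_summary(sum_int, out / "map_summary_integrated.tsv")
        gaps.per_chrom.to_csv(out / "gap_comparison.tsv", sep="\t", index=False)
        (out / "correspondence.json").write_text(json.dumps(
            dict(n_pairs=corr.n_pairs, cells_compared=corr.cells_compared,
                 cells_agreeing=corr.cells_agreeing,
                 ratio_cellwise=corr.ratio_cellwise,
                 ratio_markerwise=corr.ratio_markerwise,
                 window_bp=corr.window_bp), indent=2))
        artifacts.update(gm_integrated=gm_int, map_integrated=map_int,
                         summary_integrated=sum_int, summary_goldengate=sum_o,
                         correspondence=corr, gap_comparison=gaps)
        log.info("integrate: %d markers, correspondence %.4f, max gap cut %.1f cM",
                 gm_int.n_markers, corr.ratio_cellwise, gaps.max_reduction_cM)

        stage = "qtlscan"
        probs = genotype_probabilities(map_int, gm_int, config.step_cM)
        y = pheno.aligned_to(gm_int.line_ids)
        cof = select_cofactors(gm_int, y, config.n_cofactors)
        scan = cim_scan(probs, gm_int, map_int, y, cof, config.window_cM)
        thresholds, maxima = permutation_threshold(
            probs, gm_int, map_int, y, n_perm=config.n_perm,
            alphas=config.alphas, seed=config.seed,
            n_cofactors=config.n_cofactors, window_cM=config.window_cM,
        )
        scan.thresholds = thresholds
        scan.peaks = detect_qtl(scan, thresholds[min(config.alphas, key=lambda a: abs(a - 0.05))])
        scan.table.to_csv(out / "scan.tsv", sep="\t", index=False)
        (out / "thresholds.json").write_text(json.dumps(
            {str(a): t for a, t in thresholds.items()}, indent=2))
        qtl_rows = [
            dict(chrom=p.chrom, pos_cM=p.pos_cM, lod=p.lod,
                 ci_low_cM=p.interval_cM[0], ci_high_cM=p.interval_cM[1],
                 additive_effect=p.additive_effect)
            for p in scan.peaks
        ]
        import pandas as pd

        pd.DataFrame(qtl_rows, columns=["chrom", "pos_cM", "lod", "ci_low_cM",
                                        "ci_high_cM", "additive_effect"]).to_csv(
            out / "qtl_table.tsv", sep="\t", index=False)
        artifacts.update(scan=scan, thresholds=thresholds, perm_maxima=maxima)
        log.info("qtlscan: %d QTLs above the %s threshold", len(scan.peaks),
                 thresholds)

        if config.make_plots:
            stage = "plots"
            plot_lod_profile(scan, out / "lod_profile.png")
        return artifacts
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def plot_lod_profile(scan, path) -> None:
    """LOD curves per chromosome with dashed threshold lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(scan.table["chrom"].unique())
    fig, axes = plt.subplots(1, len(chroms), figsize=(2.2 * len(chroms), 3),
                             sharey=True, squeeze=False)
    for ax, c in zip(axes[0], chroms):
        prof = scan.chrom_profile(c)
        ax.plot(prof["cM"], prof["lod"], lw=1)
        for a, t in scan.thresholds.items():
            ax.axhline(t, ls="--", lw=0.8, color="grey")
        ax.set_title(f"chr {c}", fontsize=8)
        ax.set_xlabel("cM", fontsize=7)
    axes[0][0].set_ylabel("LOD")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
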