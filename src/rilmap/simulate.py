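"""Forward simulation of biparental selfing RIL populations.

The generator emulates the data-generating process behind a
Koshihikari-style rice RIL study: an F1 between two inbred parents is
selfed to F7 by single seed descent (one selfed offspring carried per line
per generation), so each line is a near-homozygous random mosaic of the two
parental genomes with expected residual heterozygosity (1/2)^(t-1) at
generation F_t (1.56% at F7).

Crossovers follow a no-interference model: the count per meiosis is
Poisson(length_cM / 100) and positions are i.i.d. uniform along the
chromosome, so two loci d cM apart recombine per meiosis with the Haldane
fraction r = (1 - exp(-2d/100)) / 2 and accumulate in the finished RIL to
R = 2r / (1 + 2r).  The bp <-> cM relation is linear per chromosome.

Marker evidence is generated for two platforms: dominant presence/absence
amplicons (per-line read counts, Poisson(lambda) for carriers with a
dropout probability, structural zero for absence homozygotes) and
codominant array SNPs (direct calls with symmetric A<->B error and missing
data).  Phenotypes follow an additive QTL model
y = mu + sum_i a_i x_i + Normal(0, sigma^2) with x = +1/-1/0 for the
A-homozygote / B-homozygote / heterozygote at each QTL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

import pandas as pd

from .calling import ReadPresenceTable
from .genotypes import A, B, H, NA, GenotypeMatrix, MarkerDef, PhenotypeTable
from .linkage import GeneticMap

__all__ = [
    "ChromosomeSpec", "GenomeSpec", "SimConfig", "QTL", "QTLModel",
    "Haplotype", "TrueGenotypes", "simulate_meiosis", "simulate_ril_population",
    "simulate_reads", "simulate_goldengate", "simulate_phenotype",
    "rice_genome", "uniform_marker_loci", "study_config", "STUDY_N_LINES",
]


# ---------------------------------------------------------------------------
# genome & configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromosomeSpec:
    label: str
    length_cM: float
    length_bp: int

    def cm_to_bp(self, cm) -> np.ndarray:
        cm = np.asarray(cm, dtype=float)
        bp = np.rint(cm / self.length_cM * (self.length_bp - 1)).astype(int) + 1
        return bp

    def bp_to_cm(self, bp) -> np.ndarray:
        bp = np.asarray(bp, dtype=float)
        return (bp - 1) / (self.length_bp - 1) * self.length_cM


@dataclass
class GenomeSpec:
    chromosomes: list[ChromosomeSpec]

    def __post_init__(self) -> None:
        for c in self.chromosomes:
            if c.length_cM <= 0 or c.length_bp < 2:
                raise ValueError(f"chromosome {c.label}: invalid lengths")

    def chrom(self, label: str) -> ChromosomeSpec:
        for c in self.chromosomes:
            if c.label == str(label):
                return c
        raise KeyError(f"no chromosome {label!r}")

    @property
    def total_bp(self) -> int:
        return sum(c.length_bp for c in self.chromosomes)

    @property
    def total_cM(self) -> float:
        return sum(c.length_cM for c in self.chromosomes)


@dataclass
class SimConfig:
    """Generation parameters for one simulated population.

    ``final_generation`` t means F_t; t = 7 matches the study populations.
    """

    n_lines: int = 96
    final_generation: int = 7
    seed: int = 0
    missing_rate: float = 0.02
    genotype_error_rate: float = 0.001
    amplicon_read_mean: float = 20.0
    amplicon_dropout: float = 0.002

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if self.final_generation < 2:
            raise ValueError("final_generation must be >= 2 (F2 or later)")
        for p in (self.missing_rate, self.genotype_error_rate, self.amplicon_dropout):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.amplicon_read_mean <= 0:
            raise ValueError("amplicon_read_mean must be positive")

    @property
    def het_residual_expected(self) -> float:
        return 0.5 ** (self.final_generation - 1)


#: final progeny numbers of the four study populations
STUDY_N_LINES = {"ril71": 190, "ril98": 96, "ril16": 95, "ril91": 94}


def study_config(population: str, seed: int = 0, **overrides) -> SimConfig:
    """Preset matching one of the study populations' sample sizes."""
    key = population.lower()
    if key not in STUDY_N_LINES:
        raise ValueError(f"unknown population {population!r}")
    kw = dict(n_lines=STUDY_N_LINES[key], final_generation=7, seed=seed)
    kw.update(overrides)
    return SimConfig(**kw)


# Per-chromosome genetic lengths follow the integrated RIL71 map; physical
# lengths follow the IRGSP-1.0 rice reference assembly (~373 Mb total).
_RICE_CM = [202.0, 158.3, 157.3, 131.2, 132.5, 121.4,
            116.2, 116.3, 85.8, 81.7, 113.0, 99.3]
_RICE_MB = [43.27, 35.94, 36.41, 35.50, 29.96, 31.25,
            29.70, 28.44, 23.01, 23.21, 29.02, 25.52]


def rice_genome(n_chromosomes: int = 12) -> GenomeSpec:
    """A 12-chromosome rice-scale genome (~1,515 cM, ~372 Mb)."""
    chroms = [
        ChromosomeSpec(str(i + 1), _RICE_CM[i], int(_RICE_MB[i] * 1e6))
        for i in range(n_chromosomes)
    ]
    return GenomeSpec(chroms)


def uniform_marker_loci(
    genome: GenomeSpec,
    n_per_chrom: int,
    marker_type: str = "SNP",
    platform: str = "GRASDI",
    rng: np.random.Generator | None = None,
    prefix: str | None = None,
) -> list[MarkerDef]:
    """Marker loci per chromosome: evenly spaced, or uniform-random if an
    ``rng`` is given.  Names follow TYPE/chromosome/physical-position."""
    prefix = prefix or marker_type
    loci: list[MarkerDef] = []
    for c in genome.chromosomes:
        if rng is None:
            cm = np.linspace(0.0, c.length_cM, n_per_chrom)
        else:
            cm = np.sort(rng.uniform(0.0, c.length_cM, size=n_per_chrom))
        bp = c.cm_to_bp(cm)
        # nudge bp collisions apart so names stay unique
        for k in range(1, len(bp)):
            if bp[k] <= bp[k - 1]:
                bp[k] = bp[k - 1] + 1
        for p in bp:
            loci.append(MarkerDef(f"{prefix}/{c.label}/{p}", c.label, int(p),
                                  marker_type, platform))
    return loci


def true_genetic_map(genome: GenomeSpec, loci: list[MarkerDef]) -> GeneticMap:
    """The simulator's own map: marker cM positions from the linear bp<->cM
    relation (useful as ground truth for scan and recovery experiments)."""
    from .genotypes import sort_markers

    rows = []
    for m in sort_markers(loci):
        spec = genome.chrom(m.chrom)
        rows.append(dict(name=m.name, chrom=m.chrom, pos_bp=m.pos_bp,
                         cM=float(spec.bp_to_cm(m.pos_bp)),
                         marker_type=m.marker_type, platform=m.platform))
    return GeneticMap(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# haplotype mosaics & meiosis
# ---------------------------------------------------------------------------

@dataclass
class Haplotype:
    """Parental-origin mosaic of one chromosome copy.

    ``ends`` are strictly increasing segment end positions in cM (the last
    equals the chromosome length); ``origins`` give the parental origin
    (0 or 1) of each segment.
    """

    ends: np.ndarray
    origins: np.ndarray

    def origin_at(self, cm) -> np.ndarray:
        idx = np.searchsorted(self.ends, np.asarray(cm, dtype=float), side="right")
        idx = np.minimum(idx, len(self.origins) - 1)
        return self.origins[idx]


def _pure_haplotype(origin: int, length_cM: float) -> Haplotype:
    return Haplotype(np.array([length_cM]), np.array([origin], dtype=np.int8))


def _merge_segments(ends: list[float], origins: list[int]) -> Haplotype:
    out_e: list[float] = []
    out_o: list[int] = []
    for e, o in zip(ends, origins):
        if out_o and out_o[-1] == o:
            out_e[-1] = e
        else:
            out_e.append(e)
            out_o.append(o)
    return Haplotype(np.asarray(out_e), np.asarray(out_o, dtype=np.int8))


def simulate_meiosis(
    pair: tuple[Haplotype, Haplotype],
    length_cM: float,
    rng: np.random.Generator,
) -> Haplotype:
    """One gamete from a chromosome pair under the no-interference model.

    The crossover count is Poisson(length_cM / 100) with i.i.d. uniform
    positions; the starting copy is chosen with probability 1/2.
    """
    if length_cM <= 0:
        raise ValueError("length_cM must be positive")
    n_xo = rng.poisson(length_cM / 100.0)
    active = int(rng.integers(2))
    if n_xo == 0:
        h = pair[active]
        return Haplotype(h.ends.copy(), h.origins.copy())
    xo = np.sort(rng.uniform(0.0, length_cM, size=n_xo))
    bounds = np.concatenate(([0.0], xo, [length_cM]))
    ends: list[float] = []
    origins: list[int] = []
    for k in range(len(bounds) - 1):
        a, b = bounds[k], bounds[k + 1]
        h = pair[active]
        i = int(np.searchsorted(h.ends, a, side="right"))
        while True:
            seg_end = min(float(h.ends[i]), b)
            if seg_end > a:
                ends.append(seg_end)
                origins.append(int(h.origins[i]))
                a = seg_end
            if seg_end >= b:
                break
            i += 1
        active = 1 - active
    ends[-1] = length_cM  # guard against float drift at the right edge
    return _merge_segments(ends, origins)


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------

@dataclass
class TrueGenotypes:
    """Phased parental-origin mosaics for every line, per chromosome."""

    genome: GenomeSpec
    line_ids: list[str]
    #: haplotypes[line][chrom_label] -> (Haplotype, Haplotype)
    haplotypes: list[dict[str, tuple[Haplotype, Haplotype]]]

    def calls_at(self, loci: list[MarkerDef]) -> GenotypeMatrix:
        """True A/B/H calls of every line at the given marker loci."""
        n = len(self.line_ids)
        calls = np.empty((len(loci), n), dtype=np.int8)
        by_chrom: dict[str, list[int]] = {}
        for i, m in enumerate(loci):
            by_chrom.setdefault(m.chrom, []).append(i)
        for chrom, idx in by_chrom.items():
            spec = self.genome.chrom(chrom)
            cm = spec.bp_to_cm(np.array([loci[i].pos_bp for i in idx]))
            for j in range(n):
                h1, h2 = self.haplotypes[j][chrom]
                o1, o2 = h1.origin_at(cm), h2.origin_at(cm)
                g = np.where(o1 == o2, np.where(o1 == 0, A, B), H).astype(np.int8)
                calls[idx, j] = g
        return GenotypeMatrix(self.line_ids, loci, calls)

    def dosage_at(self, chrom: str, pos_cM: float) -> np.ndarray:
        """QTL dosage x per line: +1 (A hom), -1 (B hom), 0 (het)."""
        out = np.empty(len(self.line_ids))
        for j in range(len(self.line_ids)):
            h1, h2 = self.haplotypes[j][str(chrom)]
            o1 = int(h1.origin_at(pos_cM))
            o2 = int(h2.origin_at(pos_cM))
            out[j] = 0.0 if o1 != o2 else (1.0 if o1 == 0 else -1.0)
        return out

    def het_fraction(self, loci: list[MarkerDef]) -> float:
        gm = self.calls_at(loci)
        return float((gm.calls == H).mean())


def simulate_ril_population(genome: GenomeSpec, config: SimConfig,
                            rng: np.random.Generator | None = None) -> TrueGenotypes:
    """Single-seed-descent RILs: F1 fully heterozygous, then t-1 selfing
    rounds carrying one offspring per line."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    line_ids = [f"L{j + 1:03d}" for j in range(config.n_lines)]
    lines: list[dict[str, tuple[Haplotype, Haplotype]]] = []
    for _ in range(config.n_lines):
        plant = {
            c.label: (_pure_haplotype(0, c.length_cM), _pure_haplotype(1, c.length_cM))
            for c in genome.chromosomes
        }
        for _gen in range(config.final_generation - 1):  # F1 -> F_t
            plant = {
                label: (
                    simulate_meiosis(pair, genome.chrom(label).length_cM, rng),
                    simulate_meiosis(pair, genome.chrom(label).length_cM, rng),
                )
                for label, pair in plant.items()
            }
        lines.append(plant)
    return TrueGenotypes(genome, line_ids, lines)


# ---------------------------------------------------------------------------
# marker evidence
# ---------------------------------------------------------------------------

def simulate_reads(
    truth: TrueGenotypes,
    amp_loci: list[MarkerDef],
    config: SimConfig,
    parent_presence: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> ReadPresenceTable:
    """Dominant amplicon read counts per line and locus.

    ``parent_presence[i]`` ("P1" or "P2") says which parent carries the
    amplified sequence at locus i (default alternating).  Carrier lines
    (presence homozygotes and heterozygotes) emit Poisson(lambda) reads,
    zeroed with the dropout probability; absence homozygotes emit 0.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    if parent_presence is None:
        parent_presence = ["P1" if i % 2 == 0 else "P2" for i in range(len(amp_loci))]
    if len(parent_presence) != len(amp_loci):
        raise ValueError("parent_presence must align with amp_loci")
    true_gm = truth.calls_at(amp_loci)
    lam = config.amplicon_read_mean
    counts = np.zeros(true_gm.calls.shape, dtype=np.int64)
    parent_counts = np.zeros((len(amp_loci), 2), dtype=np.int64)
    for i, pres in enumerate(parent_presence):
        pres_code = A if pres == "P1" else B
        carrier = (true_gm.calls[i] == pres_code) | (true_gm.calls[i] == H)
        n_car = int(carrier.sum())
        c = rng.poisson(lam, size=n_car)
        if config.amplicon_dropout > 0:
            c[rng.random(n_car) < config.amplicon_dropout] = 0
        counts[i, carrier] = c
        parent_counts[i, 0 if pres == "P1" else 1] = max(1, rng.poisson(lam))
    return ReadPresenceTable(
        line_ids=list(truth.line_ids),
        amp_loci=list(amp_loci),
        counts=counts,
        parent_counts=parent_counts,
    )


def simulate_goldengate(
    truth: TrueGenotypes,
    snp_loci: list[MarkerDef],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Codominant SNP calls: truth with symmetric A<->B error and missing
    cells, each applied independently per cell."""
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    gm = truth.calls_at(snp_loci)
    calls = gm.calls.copy()
    eps, miss = config.genotype_error_rate, config.missing_rate
    if eps > 0:
        flip = (rng.random(calls.shape) < eps) & ((calls == A) | (calls == B))
        calls[flip] = np.where(calls[flip] == A, B, A)
    if miss > 0:
        calls[rng.random(calls.shape) < miss] = NA
    return GenotypeMatrix(gm.line_ids, gm.markers, calls)


# ---------------------------------------------------------------------------
# phenotype model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QTL:
    chrom: str
    pos_cM: float
    additive_effect: float


@dataclass
class QTLModel:
    """Additive architecture: y = mu + sum a_i x_i + Normal(0, sigma^2)."""

    qtls: list[QTL] = field(default_factory=list)
    residual_sd: float = 1.0
    trait_mean: float = 0.0

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")


def heading_date_model(effect_scale: float = 2.0, residual_sd: float = 2.5,
                       trait_mean: float = 100.0) -> QTLModel:
    """A five-QTL heading-date architecture: two QTLs on chromosome 3, two
    on chromosome 6, one on chromosome 7 (the pattern recovered in rice
    RILs as Hd6/Hd16, Hd17/Hd1 and Hd2)."""
    qtls = [
        QTL("3", 10.0, effect_scale),
        QTL("3", 110.0, effect_scale),
        QTL("6", 10.0, effect_scale),
        QTL("6", 70.0, effect_scale),
        QTL("7", 95.0, effect_scale),
    ]
    return QTLModel(qtls=qtls, residual_sd=residual_sd, trait_mean=trait_mean)


def simulate_phenotype(
    truth: TrueGenotypes,
    model: QTLModel,
    rng: np.random.Generator,
    trait_name: str = "days_to_heading",
) -> PhenotypeTable:
    for q in model.qtls:
        spec = truth.genome.chrom(q.chrom)
        if not 0.0 <= q.pos_cM <= spec.length_cM:
            raise ValueError(f"QTL at {q.chrom}:{q.pos_cM} outside chromosome")
    y = np.full(len(truth.line_ids), model.trait_mean, dtype=float)
    for q in model.qtls:
        y += q.additive_effect * truth.dosage_at(q.chrom, q.pos_cM)
    y += rng.normal(0.0, model.residual_sd, size=len(y))
    return PhenotypeTable(list(truth.line_ids), y, trait_name)
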