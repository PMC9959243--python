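"""Readers and writers for the pipeline's on-disk formats.

The canonical genotype file is a rotated "cross" CSV: one row per marker,
first three columns ``name, chrom, cM`` (cM blank when no map is attached),
then one column per line with calls in {A, B, H, -}.  Missing calls are
written ``-``; ``NA`` is accepted on input.  Lines starting with ``#`` are
comments (used to record the generating seed/config) and are skipped.

Marker definition tables, phenotype tables, genetic maps and map summaries
are plain TSV.  SNP ingest from externally called variants reads VCF via
pysam.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .genotypes import (
    NA,
    A,
    B,
    CODE_TO_SYMBOL,
    H,
    SYMBOL_TO_CODE,
    GenotypeMatrix,
    MarkerDef,
    PhenotypeTable,
    sort_markers,
)
from .linkage import GeneticMap, MapSummary


# ---------------------------------------------------------------------------
# marker tables
# ---------------------------------------------------------------------------

MARKER_COLUMNS = ["name", "chrom", "pos_bp", "marker_type", "platform"]


def read_marker_table(path) -> list[MarkerDef]:
    """Read a marker TSV (name, chrom, pos_bp, marker_type, platform).

    Returns markers stably sorted by (chromosome, physical position);
    duplicate names are rejected.
    """
    markers: list[MarkerDef] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(MARKER_COLUMNS)] != MARKER_COLUMNS:
            raise ValueError(f"{path}: expected header {MARKER_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
            name, chrom, pos_bp, mtype, platform = fields[:5]
            try:
                pos = int(pos_bp)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad pos_bp {pos_bp!r}") from exc
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate marker name {name!r}")
            seen.add(name)
            try:
                markers.append(MarkerDef(name, chrom, pos, mtype, platform))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return sort_markers(markers)


def write_marker_table(markers, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MARKER_COLUMNS) + "\n")
        for m in markers:
            fh.write(f"{m.name}\t{m.chrom}\t{m.pos_bp}\t{m.marker_type}\t{m.platform}\n")


def _marker_from_name(name: str, chrom: str, row_index: int) -> MarkerDef:
    """Best-effort MarkerDef from a PREFIX/chrom/pos style name.

    AMP/... are dominant amplicons, GG/... array SNPs; any other prefix with
    a numeric position is treated as an amplicon-platform SNP.  Names that
    do not encode a position keep file order within their chromosome.
    """
    parts = name.split("/")
    mtype, platform, pos = "SNP", "GRASDI", None
    if len(parts) == 3:
        try:
            pos = int(parts[2])
        except ValueError:
            pos = None
        if pos is not None:
            if parts[0] == "AMP":
                mtype = "AMP"
            elif parts[0] == "GG":
                platform = "GOLDENGATE"
    if pos is None:
        pos = row_index + 1  # preserves file order within a chromosome
    return MarkerDef(name, chrom, pos, mtype, platform)


# ---------------------------------------------------------------------------
# cross CSV (rotated genotype layout)
# ---------------------------------------------------------------------------

def read_cross_csv(path, markers: list[MarkerDef] | None = None):
    """Read a rotated cross CSV.

    Returns ``(GenotypeMatrix, GeneticMap | None)``; the map is present when
    the cM column is populated.  When ``markers`` is given, marker metadata
    (position, type, platform) is joined by name; otherwise it is inferred
    from TYPE/chrom/pos style names where possible.
    """
    lookup = {m.name: m for m in markers} if markers else {}
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip() and not l.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split(",")
    if header[:3] != ["name", "chrom", "cM"]:
        raise ValueError(f"{path}: first three columns must be name,chrom,cM")
    line_ids = header[3:]
    mdefs: list[MarkerDef] = []
    cms: list[float] = []
    have_cm = False
    calls = np.empty((len(lines) - 1, len(line_ids)), dtype=np.int8)
    for i, raw in enumerate(lines[1:], start=0):
        fields = raw.split(",")
        if len(fields) != 3 + len(line_ids):
            raise ValueError(
                f"{path}: row {i + 2} has {len(fields)} fields, expected {3 + len(line_ids)}"
            )
        name, chrom, cm = fields[0], fields[1], fields[2]
        if name in lookup:
            mdefs.append(lookup[name])
        else:
            mdefs.append(_marker_from_name(name, chrom, i))
        if cm != "":
            have_cm = True
            cms.append(float(cm))
        else:
            cms.append(np.nan)
        for j, sym in enumerate(fields[3:]):
            try:
                calls[i, j] = SYMBOL_TO_CODE[sym]
            except KeyError:
                raise ValueError(
                    f"{path}: unknown call symbol {sym!r} at row {i + 2} "
                    f"(marker {name}), column {j + 4} (line {line_ids[j]})"
                ) from None
    gm = GenotypeMatrix(line_ids, mdefs, calls)
    gmap = None
    if have_cm:
        table = pd.DataFrame(
            dict(
                name=[m.name for m in mdefs],
                chrom=[m.chrom for m in mdefs],
                pos_bp=[m.pos_bp for m in mdefs],
                cM=cms,
                marker_type=[m.marker_type for m in mdefs],
                platform=[m.platform for m in mdefs],
            )
        )
        gmap = GeneticMap(table=table)
    return gm, gmap


def _format_cm(x: float) -> str:
    s = f"{x:.6f}".rstrip("0").rstrip(".")
    return s if s else "0"


def write_cross_csv(gm: GenotypeMatrix, path, gmap: GeneticMap | None = None,
                    header_comments: list[str] | None = None) -> None:
    """Write the rotated cross CSV; inverse of :func:`read_cross_csv`."""
    cm_by_name = {}
    if gmap is not None:
        cm_by_name = dict(zip(gmap.table["name"], gmap.table["cM"]))
    with open(path, "w") as fh:
        for c in header_comments or []:
            fh.write(f"# {c}\n")
        fh.write(",".join(["name", "chrom", "cM", *gm.line_ids]) + "\n")
        for i, m in enumerate(gm.markers):
            cm = _format_cm(cm_by_name[m.name]) if m.name in cm_by_name else ""
            syms = [CODE_TO_SYMBOL[c] for c in gm.calls[i]]
            fh.write(",".join([m.name, m.chrom, cm, *syms]) + "\n")


# ---------------------------------------------------------------------------
# VCF ingest
# ---------------------------------------------------------------------------

def read_vcf_biallelic(path, parent1_id: str, parent2_id: str):
    """Recode a biparental VCF to parental-origin calls.

    Only biallelic SNP records where the two parents are opposite
    homozygotes are used; offspring matching ``parent1_id`` become A,
    matching ``parent2_id`` become B, heterozygotes H, anything else NA.
    Returns ``(GenotypeMatrix, n_skipped)`` where ``n_skipped`` counts
    records dropped for being non-biallelic, non-SNP or parent-uninformative.
    """
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    for p in (parent1_id, parent2_id):
        if p not in samples:
            raise ValueError(f"parent sample {p!r} absent from VCF")
    offspring = [s for s in samples if s not in (parent1_id, parent2_id)]
    mdefs: list[MarkerDef] = []
    rows: list[np.ndarray] = []
    skipped = 0
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            skipped += 1
            continue
        if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            skipped += 1
            continue
        g1 = rec.samples[parent1_id]["GT"]
        g2 = rec.samples[parent2_id]["GT"]
        if None in (g1 or (None,)) or None in (g2 or (None,)):
            skipped += 1
            continue
        a1, a2 = set(g1), set(g2)
        if len(a1) != 1 or len(a2) != 1 or a1 == a2:
            skipped += 1  # parents not opposite homozygotes
            continue
        p1_allele, p2_allele = next(iter(a1)), next(iter(a2))
        row = np.full(len(offspring), NA, dtype=np.int8)
        for j, s in enumerate(offspring):
            gt = rec.samples[s]["GT"]
            if gt is None or None in gt:
                continue
            alleles = set(gt)
            if alleles == {p1_allele}:
                row[j] = A
            elif alleles == {p2_allele}:
                row[j] = B
            elif alleles == {p1_allele, p2_allele}:
                row[j] = H
        chrom = str(rec.chrom)
        mdefs.append(MarkerDef(f"SNP/{chrom}/{rec.pos}", chrom, rec.pos, "SNP", "GRASDI"))
        rows.append(row)
    if not rows:
        warnings.warn("no informative biallelic SNP records; empty matrix")
        return GenotypeMatrix(offspring, [], np.empty((0, len(offspring)), dtype=np.int8)), skipped
    gm = GenotypeMatrix(offspring, mdefs, np.vstack(rows)).sorted_by_position()
    return gm, skipped


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------

def read_phenotype_table(path, trait_name: str = "days_to_heading") -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"line_id": str})
    if "line_id" not in df.columns or "value" not in df.columns:
        raise ValueError(f"{path}: phenotype TSV needs columns line_id, value")
    return PhenotypeTable(df["line_id"].tolist(), df["value"].to_numpy(float), trait_name)


def write_phenotype_table(pheno: PhenotypeTable, path,
                          header_comments: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for c in header_comments or []:
            fh.write(f"# {c}\n")
        fh.write("line_id\tvalue\n")
        for l, v in zip(pheno.line_ids, pheno.values):
            fh.write(f"{l}\t{'' if np.isnan(v) else format(v, 'g')}\n")


# ---------------------------------------------------------------------------
# genetic maps & summaries
# ---------------------------------------------------------------------------

def write_map_tsv(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


def read_map_tsv(path) -> GeneticMap:
    table = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "name": str})
    return GeneticMap(table=table)


SUMMARY_COLUMNS = [
    "chrom", "n_markers", "total_length_cM", "avg_interval_cM", "largest_gap_cM",
    "gap_marker_left", "gap_marker_right", "gap_left_mb", "gap_right_mb", "gap_span_mb",
]


def write_map_summary(summary: MapSummary, path) -> None:
    """Table-2-style TSV: per-chromosome rows then a genome-total row.

    cM values are printed to 1 decimal, Mb to 2 decimals.
    """
    if len(summary.per_chrom) == 0:
        raise ValueError("empty chromosome set")

    def f1(x):
        return "" if pd.isna(x) else f"{x:.1f}"

    def f2(x):
        return "" if pd.isna(x) else f"{x:.2f}"

    with open(path, "w") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for _, r in summary.per_chrom.iterrows():
            fh.write(
                "\t".join([
                    str(r["chrom"]), str(int(r["n_markers"])),
                    f1(r["total_length_cM"]), f1(r["avg_interval_cM"]),
                    f1(r["largest_gap_cM"]), str(r["gap_marker_left"]),
                    str(r["gap_marker_right"]), f2(r["gap_left_mb"]),
                    f2(r["gap_right_mb"]), f2(r["gap_span_mb"]),
                ]) + "\n"
            )
        fh.write(
            "\t".join([
                "Total", str(summary.n_markers), f1(summary.total_length_cM),
                f1(summary.weighted_avg_interval_cM), "", "", "", "", "", "",
            ]) + "\n"
        )
        fh.write(f"# unweighted_avg_interval_cM\t{summary.unweighted_avg_interval_cM:.2f}\n")


def read_map_summary(path) -> MapSummary:
    """Read a per-chromosome summary TSV (published-table transcriptions or
    files written by :func:`write_map_summary`; a trailing Total row is
    ignored and recomputed)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    df = df[df["chrom"].str.lower() != "total"].copy()
    for col in ("n_markers",):
        df[col] = df[col].astype(int)
    return MapSummary.from_per_chrom(df.reset_index(drop=True))
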