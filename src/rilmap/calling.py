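"""Genotype calling from marker evidence.

Two marker classes are supported:

* dominant presence/absence amplicons — a locus is informative when the
  amplified sequence is present in exactly one parent; offspring are scored
  by read count (present / absent / too-few-reads -> missing);
* codominant SNPs — offspring allele pairs are recoded to parental origin
  where the parents are opposite homozygotes.

Both callers emit parental-origin-coded matrices: A = common parent,
B = founder.  A heterozygous line at a dominant amplicon locus is
indistinguishable from a presence homozygote and is coded as the
presence parent; downstream QC owns that limitation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import A, B, H, NA, GenotypeMatrix, MarkerDef


@dataclass
class ReadPresenceTable:
    """Amplicon read counts per line and locus plus both parents' counts.

    ``parent_counts[i] = (common-parent count, founder count)`` at locus i.
    """

    line_ids: list[str]
    amp_loci: list[MarkerDef]
    counts: np.ndarray
    parent_counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.parent_counts = np.asarray(self.parent_counts, dtype=np.int64)
        if self.counts.shape != (len(self.amp_loci), len(self.line_ids)):
            raise ValueError("count grid does not match loci x lines")
        if self.parent_counts.shape != (len(self.amp_loci), 2):
            raise ValueError("parent_counts must be (n_loci, 2)")
        if (self.counts < 0).any() or (self.parent_counts < 0).any():
            raise ValueError("read counts must be non-negative")


def write_read_table(table: ReadPresenceTable, path,
                     header_comments: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for c in header_comments or []:
            fh.write(f"# {c}\n")
        fh.write("\t".join(["name", "chrom", "pos_bp", "parent1", "parent2",
                            *table.line_ids]) + "\n")
        for i, m in enumerate(table.amp_loci):
            row = [m.name, m.chrom, str(m.pos_bp),
                   str(table.parent_counts[i, 0]), str(table.parent_counts[i, 1]),
                   *map(str, table.counts[i])]
            fh.write("\t".join(row) + "\n")


def read_read_table(path) -> ReadPresenceTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "name": str})
    line_ids = list(df.columns[5:])
    loci = [
        MarkerDef(r["name"], r["chrom"], int(r["pos_bp"]), "AMP", "GRASDI")
        for _, r in df.iterrows()
    ]
    counts = df[line_ids].to_numpy(dtype=np.int64)
    parent_counts = df[["parent1", "parent2"]].to_numpy(dtype=np.int64)
    return ReadPresenceTable(line_ids, loci, counts, parent_counts)


def call_amplicon_markers(
    table: ReadPresenceTable,
    min_reads: int = 2,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Score dominant amplicon markers from read presence/absence.

    A locus is kept only when exactly one parent shows the amplicon
    (count >= ``min_reads``); the carrying parent defines the "presence"
    genotype.  Offspring with count >= ``min_reads`` get the presence
    parent's code, count 0 the absence parent's code, and ambiguous low
    counts (0 < count < min_reads) become missing.  Retained markers are
    renamed AMP/chromosome/physical-position.

    Returns the called matrix and a rejection report (locus, reason).
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    keep: list[int] = []
    presence_code: list[int] = []
    rejects: list[dict] = []
    for i, m in enumerate(table.amp_loci):
        p1 = table.parent_counts[i, 0] >= min_reads
        p2 = table.parent_counts[i, 1] >= min_reads
        if p1 and p2:
            rejects.append(dict(locus=m.name, reason="present in both parents"))
        elif not p1 and not p2:
            rejects.append(dict(locus=m.name, reason="absent in both parents"))
        else:
            keep.append(i)
            presence_code.append(A if p1 else B)
    markers = []
    calls = np.empty((len(keep), len(table.line_ids)), dtype=np.int8)
    for row, (i, pres) in enumerate(zip(keep, presence_code)):
        m = table.amp_loci[i]
        markers.append(MarkerDef(f"AMP/{m.chrom}/{m.pos_bp}", m.chrom, m.pos_bp,
                                 "AMP", "GRASDI"))
        c = table.counts[i]
        absent = B if pres == A else A
        calls[row] = np.where(c >= min_reads, pres, np.where(c == 0, absent, NA))
    gm = GenotypeMatrix(table.line_ids, markers, calls)
    report = pd.DataFrame(rejects, columns=["locus", "reason"])
    return gm, report


def call_snp_genotypes(
    loci: list[MarkerDef],
    line_ids: list[str],
    raw_calls: np.ndarray,
    parent_alleles: list[tuple[str, str]],
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Recode raw SNP allele pairs to parental origin.

    ``raw_calls[i, j]`` is line j's two-letter allele-pair string at locus i
    (e.g. ``"AG"``; ``"--"`` or ``""`` for missing); ``parent_alleles[i]``
    the two parents' homozygous bases.  Loci whose parents are identical are
    excluded and counted in the report.  Retained markers are renamed
    SNP/chromosome/physical-position.
    """
    raw_calls = np.asarray(raw_calls, dtype=object)
    if raw_calls.shape != (len(loci), len(line_ids)):
        raise ValueError("raw_calls must be (n_loci, n_lines)")
    if len(parent_alleles) != len(loci):
        raise ValueError("parent_alleles must align with loci")
    markers: list[MarkerDef] = []
    rows: list[np.ndarray] = []
    rejects: list[dict] = []
    for i, m in enumerate(loci):
        p1, p2 = parent_alleles[i]
        if p1 == p2:
            rejects.append(dict(locus=m.name, reason="parents identical"))
            continue
        row = np.full(len(line_ids), NA, dtype=np.int8)
        for j in range(len(line_ids)):
            g = raw_calls[i, j]
            if not g or "-" in g or len(g) != 2:
                continue
            pair = frozenset(g)
            if pair == {p1}:
                row[j] = A
            elif pair == {p2}:
                row[j] = B
            elif pair == {p1, p2}:
                row[j] = H
        markers.append(MarkerDef(f"SNP/{m.chrom}/{m.pos_bp}", m.chrom, m.pos_bp,
                                 "SNP", m.platform))
        rows.append(row)
    calls = np.vstack(rows) if rows else np.empty((0, len(line_ids)), dtype=np.int8)
    gm = GenotypeMatrix(line_ids, markers, calls)
    return gm, pd.DataFrame(rejects, columns=["locus", "reason"])
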