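"""Genotype quality control for RIL marker matrices.

The cascade removes, in order:

1. monomorphic markers (all non-missing calls one symbol — typically
   alignment artifacts or parent-specific amplification);
2. markers with excess heterozygosity (an F7 RIL should show ~1.6%
   residual hets; far more indicates a paralog collapse or miscall);
3. local recombinants — physically near-adjacent marker pairs that still
   disagree in many lines cannot both be genuine (a double crossover
   inside tens of kb is vanishingly rare in one generation ladder);
4. markers whose A:B segregation departs from the 1:1 a biparental RIL
   must show (chi-square goodness of fit);
5. co-localized duplicates — runs of physically adjacent markers with
   identical calls carry no extra mapping information; the most complete
   (fewest missing) representative is kept.

Every filter only drops marker columns; no call is ever rewritten, so the
cascade is idempotent and stage counts always reconcile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import A, B, H, NA, GenotypeMatrix


@dataclass
class QCParams:
    max_het_frac: float = 0.10
    window_bp: int = 50_000
    max_mismatch_frac: float = 0.05
    segregation_alpha: float = 0.01
    min_informative: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_het_frac <= 1.0:
            raise ValueError("max_het_frac must lie in [0, 1]")
        if not 0.0 < self.segregation_alpha < 1.0:
            raise ValueError("segregation_alpha must lie in (0, 1)")


@dataclass
class QCReport:
    """Per-stage accounting of the QC cascade."""

    stages: list[dict] = field(default_factory=list)
    fates: dict[str, str] = field(default_factory=dict)
    flagged: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def add_stage(self, name: str, n_input: int, removed: list[str]) -> None:
        for stage in self.stages:
            if stage["stage"] == name:  # stabilization re-runs fold in here
                stage["n_removed"] += len(removed)
                stage["n_retained"] -= len(removed)
                break
        else:
            self.stages.append(
                dict(stage=name, n_input=n_input, n_removed=len(removed),
                     n_retained=n_input - len(removed))
            )
        for m in removed:
            self.fates[m] = name

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)

    def to_json(self) -> str:
        return json.dumps(
            dict(stages=self.stages, flagged=self.flagged, params=self.params),
            indent=2,
        )

    def removed_total(self) -> int:
        return sum(s["n_removed"] for s in self.stages)


def _finish(gm: GenotypeMatrix, keep: np.ndarray, report: QCReport | None,
            stage: str) -> tuple[GenotypeMatrix, QCReport]:
    report = report if report is not None else QCReport()
    removed = [m.name for m, k in zip(gm.markers, keep) if not k]
    report.add_stage(stage, gm.n_markers, removed)
    return gm.take_markers(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------

def filter_monomorphic(gm: GenotypeMatrix, report: QCReport | None = None):
    """Drop markers whose non-missing calls are a single symbol (or all
    missing)."""
    keep = np.zeros(gm.n_markers, dtype=bool)
    for i in range(gm.n_markers):
        vals = np.unique(gm.calls[i][gm.calls[i] != NA])
        keep[i] = len(vals) > 1
    return _finish(gm, keep, report, "monomorphic")


def filter_excess_het(gm: GenotypeMatrix, max_het_frac: float = 0.10,
                      report: QCReport | None = None):
    """Drop markers whose heterozygote fraction among non-missing calls
    exceeds ``max_het_frac``."""
    non_missing = (gm.calls != NA).sum(axis=1)
    hets = (gm.calls == H).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(non_missing > 0, hets / np.maximum(non_missing, 1), 0.0)
    keep = frac <= max_het_frac
    return _finish(gm, keep, report, "excess_het")


def _mismatch_frac(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    hom = ((x == A) | (x == B)) & ((y == A) | (y == B))
    n = int(hom.sum())
    if n == 0:
        return 0.0, 0
    return float((x[hom] != y[hom]).mean()), n


def filter_local_recombinants(gm: GenotypeMatrix, window_bp: int = 50_000,
                              max_mismatch_frac: float = 0.05,
                              report: QCReport | None = None):
    """Drop one member of physically close adjacent pairs that disagree.

    For adjacent markers within ``window_bp`` on the same chromosome, the
    pairwise mismatch fraction over co-non-missing homozygous calls is
    computed; above ``max_mismatch_frac`` the member with more missing
    calls is removed (ties: AMP before SNP, then the larger position).
    Passes repeat until no pair triggers, so the filter is idempotent.
    """
    gm = gm.sorted_by_position()
    removed_names: list[str] = []
    n_input = gm.n_markers
    while True:
        drop: set[int] = set()
        for i in range(gm.n_markers - 1):
            if i in drop:
                continue
            m1, m2 = gm.markers[i], gm.markers[i + 1]
            if m1.chrom != m2.chrom or m2.pos_bp - m1.pos_bp > window_bp:
                continue
            frac, n = _mismatch_frac(gm.calls[i], gm.calls[i + 1])
            if n == 0 or frac <= max_mismatch_frac:
                continue
            miss1 = int((gm.calls[i] == NA).sum())
            miss2 = int((gm.calls[i + 1] == NA).sum())
            if miss1 != miss2:
                victim = i if miss1 > miss2 else i + 1
            elif (m1.marker_type == "AMP") != (m2.marker_type == "AMP"):
                victim = i if m1.marker_type == "AMP" else i + 1
            else:
                victim = i + 1  # larger pos_bp
            drop.add(victim)
        if not drop:
            break
        removed_names += [gm.markers[i].name for i in sorted(drop)]
        gm = gm.take_markers([i for i in range(gm.n_markers) if i not in drop])
    report = report if report is not None else QCReport()
    report.add_stage("local_recombinant", n_input, removed_names)
    return gm, report


def segregation_test(gm: GenotypeMatrix, alpha: float = 0.01,
                     min_informative: int = 10,
                     report: QCReport | None = None):
    """Chi-square 1:1 test of A:B counts (hets and missing excluded, 1 df).

    Markers with p < ``alpha`` are removed.  Markers with fewer than
    ``min_informative`` homozygous calls cannot be tested; they are flagged
    in the report but retained.
    """
    n_a = (gm.calls == A).sum(axis=1).astype(float)
    n_b = (gm.calls == B).sum(axis=1).astype(float)
    n = n_a + n_b
    keep = np.ones(gm.n_markers, dtype=bool)
    flagged: list[str] = []
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(n > 0, (n_a - n_b) ** 2 / np.maximum(n, 1), 0.0)
    pvals = stats.chi2.sf(chi2, df=1)
    for i in range(gm.n_markers):
        if n[i] < min_informative:
            flagged.append(gm.markers[i].name)
        elif pvals[i] < alpha:
            keep[i] = False
    out, report = _finish(gm, keep, report, "segregation")
    report.flagged.extend(flagged)
    return out, report


def _colocal_groups(gm: GenotypeMatrix) -> list[list[int]]:
    """Runs of physically adjacent markers with identical co-observed calls."""
    groups: list[list[int]] = []
    for i in range(gm.n_markers):
        if groups:
            j = groups[-1][-1]
            prev, cur = gm.markers[j], gm.markers[i]
            if prev.chrom == cur.chrom:
                both = (gm.calls[j] != NA) & (gm.calls[i] != NA)
                if not both.any() or np.array_equal(
                    gm.calls[j][both], gm.calls[i][both]
                ):
                    groups[-1].append(i)
                    continue
        groups.append([i])
    return groups


def dedup_colocalized(gm: GenotypeMatrix, report: QCReport | None = None):
    """Keep one representative per run of call-identical adjacent markers.

    Within each group the marker with fewest missing calls wins; ties go
    to SNP over AMP, then the smallest physical position.  Repeats until
    stable so representatives of merged neighbouring groups cannot remain
    duplicated.
    """
    gm = gm.sorted_by_position()
    n_input = gm.n_markers
    removed_names: list[str] = []
    while True:
        groups = _colocal_groups(gm)
        if all(len(g) == 1 for g in groups):
            break
        keep_idx: list[int] = []
        for g in groups:
            best = min(
                g,
                key=lambda i: (
                    int((gm.calls[i] == NA).sum()),
                    0 if gm.markers[i].marker_type == "SNP" else 1,
                    gm.markers[i].pos_bp,
                ),
            )
            keep_idx.append(best)
            removed_names += [gm.markers[i].name for i in g if i != best]
        gm = gm.take_markers(sorted(keep_idx))
    report = report if report is not None else QCReport()
    report.add_stage("dedup_colocalized", n_input, removed_names)
    return gm, report


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------

def run_qc(gm: GenotypeMatrix, params: QCParams | None = None):
    """Apply the full cascade in its documented order.

    After the first pass, the adjacency-dependent stages (local
    recombinants, co-localized dedup) are re-run until stable — removals in
    later stages create new physical adjacencies the earlier stage must see.
    Extra removals fold into their stage's counts.
    """
    params = params or QCParams()
    report = QCReport(params=params.__dict__.copy())
    gm = gm.sorted_by_position()
    gm, report = filter_monomorphic(gm, report)
    gm, report = filter_excess_het(gm, params.max_het_frac, report)
    gm, report = filter_local_recombinants(
        gm, params.window_bp, params.max_mismatch_frac, report
    )
    gm, report = segregation_test(
        gm, params.segregation_alpha, params.min_informative, report
    )
    gm, report = dedup_colocalized(gm, report)
    while True:
        n_before = gm.n_markers
        gm, report = filter_local_recombinants(
            gm, params.window_bp, params.max_mismatch_frac, report
        )
        gm, report = dedup_colocalized(gm, report)
        if gm.n_markers == n_before:
            break
    if gm.n_markers == 0:
        raise ValueError("all markers filtered")
    return gm, report
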