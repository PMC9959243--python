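"""Composite interval mapping (CIM) for RIL populations.

The scan works on a cM grid (the "walk speed").  Hidden parental-origin
states along each chromosome are reconstructed with a two-state
forward-backward pass ({AA, BB}; residual heterozygotes are rare at F7 and
dominant amplicon markers cannot express a het, so H is treated as an
uninformative emission like missing).  The transition probability between
points d cM apart is the RIL-accumulated fraction 2r/(1+2r) with
r = kosambi_inverse(d); emissions flip the true state with a genotyping
error probability epsilon.

At each grid position the phenotype is regressed on the expected QTL dosage
E[x] = P(AA) - P(BB) plus marker cofactor codings (Haley-Knott style
regression), excluding cofactors within half the window width of the test
position on the same chromosome;

    LOD = (n / 2) * log10(RSS_reduced / RSS_full).

Genome-wide significance comes from permutations of the phenotype; the
cofactor set is reselected inside every permutation so the threshold
reflects the full procedure.  Peaks above threshold are reported with
1-LOD support intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orth

from .genotypes import A, B, H, NA, GenotypeMatrix
from .linkage import GeneticMap, kosambi_inverse, ril_observed

_DEN_TOL = 1e-10


# ---------------------------------------------------------------------------
# genotype probabilities
# ---------------------------------------------------------------------------

@dataclass
class GenotypeProbGrid:
    """P(AA) per line on a cM grid, per chromosome.

    ``positions[c]`` are the evaluation points (the regular grid plus every
    marker position); ``p_aa[c]`` is (n_positions, n_lines).  P(BB) is the
    complement.
    """

    line_ids: list[str]
    chromosomes: list[str]
    positions: dict[str, np.ndarray]
    p_aa: dict[str, np.ndarray]
    step_cM: float
    epsilon: float

    def expected_dosage(self, chrom: str) -> np.ndarray:
        """E[x] = P(AA) - P(BB) = 2 P(AA) - 1, shape (n_positions, n_lines)."""
        return 2.0 * self.p_aa[chrom] - 1.0

    def stacked(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(chrom_labels, cM positions, dosage matrix (n_lines, n_total))."""
        chroms, cms, cols = [], [], []
        for c in self.chromosomes:
            chroms += [c] * len(self.positions[c])
            cms.append(self.positions[c])
            cols.append(self.expected_dosage(c).T)
        return np.array(chroms), np.concatenate(cms), np.hstack(cols)


def _transition_prob(d_cM: np.ndarray) -> np.ndarray:
    """Chance the parental origin differs between points d cM apart in a
    finished selfing RIL."""
    return ril_observed(kosambi_inverse(d_cM))


def genotype_probabilities(
    gmap: GeneticMap,
    gm: GenotypeMatrix,
    step_cM: float = 1.0,
    epsilon: float = 0.002,
) -> GenotypeProbGrid:
    """Forward-backward over the 2-state origin chain along each chromosome."""
    if step_cM <= 0:
        raise ValueError("step_cM must be positive")
    name_to_row = {m.name: i for i, m in enumerate(gm.markers)}
    n_lines = gm.n_lines
    positions: dict[str, np.ndarray] = {}
    p_aa: dict[str, np.ndarray] = {}
    chroms = gmap.chromosomes()
    for chrom in chroms:
        sub = gmap.chrom_table(chrom)
        sub = sub[sub["name"].isin(name_to_row)]
        mk_pos = sub["cM"].to_numpy(dtype=float)
        mk_rows = [name_to_row[n] for n in sub["name"]]
        lo = float(mk_pos.min()) if len(mk_pos) else 0.0
        hi = float(mk_pos.max()) if len(mk_pos) else 0.0
        grid = np.arange(lo, hi + step_cM * 0.5, step_cM) if hi > lo else np.array([lo])
        pos = np.unique(np.concatenate([grid, mk_pos]))
        # emission products per position (n_pos, n_lines, 2)
        emit = np.ones((len(pos), n_lines, 2))
        idx_of = np.searchsorted(pos, mk_pos)
        for k, row in zip(idx_of, mk_rows):
            calls = gm.calls[row]
            e = np.ones((n_lines, 2))
            e[calls == A] = (1.0 - epsilon, epsilon)
            e[calls == B] = (epsilon, 1.0 - epsilon)
            emit[k] *= e
        # transition matrices between consecutive positions
        d = np.diff(pos)
        Rt = _transition_prob(d)
        # forward
        alpha = np.empty_like(emit)
        a = 0.5 * emit[0]
        a = _normalize(a)
        alpha[0] = a
        for k in range(1, len(pos)):
            stay, move = 1.0 - Rt[k - 1], Rt[k - 1]
            pred = np.empty_like(a)
            pred[:, 0] = a[:, 0] * stay + a[:, 1] * move
            pred[:, 1] = a[:, 0] * move + a[:, 1] * stay
            a = _normalize(pred * emit[k])
            alpha[k] = a
        # backward
        b = np.ones((n_lines, 2))
        post = np.empty_like(emit)
        post[-1] = _normalize(alpha[-1] * b)
        for k in range(len(pos) - 2, -1, -1):
            stay, move = 1.0 - Rt[k], Rt[k]
            eb = emit[k + 1] * b
            nb = np.empty_like(b)
            nb[:, 0] = eb[:, 0] * stay + eb[:, 1] * move
            nb[:, 1] = eb[:, 0] * move + eb[:, 1] * stay
            b = _normalize(nb)
            post[k] = _normalize(alpha[k] * b)
        positions[chrom] = pos
        p_aa[chrom] = post[:, :, 0]
    return GenotypeProbGrid(
        line_ids=list(gm.line_ids), chromosomes=chroms, positions=positions,
        p_aa=p_aa, step_cM=step_cM, epsilon=epsilon,
    )


def _normalize(x: np.ndarray) -> np.ndarray:
    s = x.sum(axis=1, keepdims=True)
    bad = s[:, 0] <= 0
    if bad.any():
        x = x.copy()
        x[bad] = 0.5
        s = x.sum(axis=1, keepdims=True)
    return x / s


# ---------------------------------------------------------------------------
# cofactor machinery
# ---------------------------------------------------------------------------

def numeric_coding(gm: GenotypeMatrix) -> np.ndarray:
    """Markers as regression covariates: A=+1, B=-1, H=0, NA=column mean.

    Returns (n_lines, n_markers).
    """
    x = np.zeros(gm.calls.shape, dtype=float)
    x[gm.calls == A] = 1.0
    x[gm.calls == B] = -1.0
    miss = gm.calls == NA
    if miss.any():
        with np.errstate(invalid="ignore"):
            means = np.where(
                (~miss).sum(axis=1) > 0,
                np.where(miss, 0.0, x).sum(axis=1) / np.maximum((~miss).sum(axis=1), 1),
                0.0,
            )
        x = np.where(miss, means[:, None], x)
    return x.T


def select_cofactors(
    gm: GenotypeMatrix,
    phenotype: np.ndarray,
    n_cofactors: int = 3,
) -> list[str]:
    """Forward selection of marker covariates on the phenotype.

    Greedy residual-sum-of-squares reduction, stopping after
    ``n_cofactors`` markers (all markers, with a warning, if fewer exist).
    """
    y = np.asarray(phenotype, dtype=float)
    ok = ~np.isnan(y)
    X = numeric_coding(gm)[ok]
    y = y[ok]
    names = gm.marker_names
    if n_cofactors <= 0:
        return []
    if gm.n_markers <= n_cofactors:
        import warnings

        warnings.warn("fewer markers than requested cofactors; returning all")
        return list(names)
    idx = _forward_select(X, y, n_cofactors)
    return [names[i] for i in idx]


def _forward_select(X: np.ndarray, y: np.ndarray, k: int) -> list[int]:
    n = len(y)
    Q = np.ones((n, 1)) / np.sqrt(n)
    ry = y - Q @ (Q.T @ y)
    Xr = X - Q @ (Q.T @ X)
    chosen: list[int] = []
    for _ in range(k):
        num = Xr.T @ ry
        den = (Xr * Xr).sum(axis=0)
        gain = np.where(den > _DEN_TOL, num**2 / np.maximum(den, _DEN_TOL), 0.0)
        gain[chosen] = 0.0
        j = int(np.argmax(gain))
        if gain[j] <= 0:
            break
        q = Xr[:, j] / np.sqrt(den[j])
        ry = ry - q * (q @ ry)
        Xr = Xr - np.outer(q, q @ Xr)
        chosen.append(j)
    return chosen


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

@dataclass
class QTLPeak:
    chrom: str
    pos_cM: float
    lod: float
    interval_cM: tuple[float, float]
    additive_effect: float


@dataclass
class ScanResult:
    """LOD profile on the scan grid, with thresholds and detected peaks."""

    table: pd.DataFrame  # chrom, cM, lod, effect
    cofactors: list[str]
    window_cM: float
    thresholds: dict[float, float] = field(default_factory=dict)
    peaks: list[QTLPeak] = field(default_factory=list)

    def max_lod(self) -> float:
        return float(self.table["lod"].max())

    def chrom_profile(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == str(chrom)]


class CIMScanner:
    """Precomputed scan machinery shared between the observed scan and its
    permutations (the genotype side never changes under permutation)."""

    def __init__(
        self,
        probs: GenotypeProbGrid,
        gm: GenotypeMatrix,
        gmap: GeneticMap,
        window_cM: float = 3.0,
        n_cofactors: int = 3,
    ) -> None:
        self.window_cM = float(window_cM)
        self.n_cofactors = int(n_cofactors)
        self.chroms, self.pos_cM, self.X = probs.stacked()
        self.line_ids = probs.line_ids
        gm = gm.reorder_lines(probs.line_ids)
        self.marker_names = gm.marker_names
        self.codings = numeric_coding(gm)  # (n_lines, n_markers)
        cm = dict(zip(gmap.table["name"], gmap.table["cM"]))
        ch = dict(zip(gmap.table["name"], gmap.table["chrom"]))
        self.marker_cM = np.array([cm.get(n, np.nan) for n in self.marker_names])
        self.marker_chrom = np.array([ch.get(n, "") for n in self.marker_names])

    # -- pieces ---------------------------------------------------------
    def select(self, y: np.ndarray) -> list[int]:
        ok = ~np.isnan(y)
        return _forward_select(self.codings[ok], y[ok], self.n_cofactors)

    def scan(self, y: np.ndarray, cofactor_idx: list[int]):
        """LOD and additive-effect estimate at every grid position."""
        ok = ~np.isnan(y)
        y = y[ok]
        n = len(y)
        X = self.X[ok]
        C = self.codings[ok][:, cofactor_idx] if cofactor_idx else np.empty((n, 0))
        half = self.window_cM / 2.0
        # active-cofactor mask per position
        excl = np.zeros((len(self.pos_cM), len(cofactor_idx)), dtype=bool)
        for k, ci in enumerate(cofactor_idx):
            c_chrom, c_cm = self.marker_chrom[ci], self.marker_cM[ci]
            if not np.isnan(c_cm):
                excl[:, k] = (self.chroms == c_chrom) & (
                    np.abs(self.pos_cM - c_cm) < half
                )
        lod = np.zeros(len(self.pos_cM))
        effect = np.zeros(len(self.pos_cM))
        ones = np.ones((n, 1))
        for row in np.unique(excl, axis=0) if len(cofactor_idx) else [np.zeros(0, bool)]:
            mask = (
                np.all(excl == row, axis=1)
                if len(cofactor_idx)
                else np.ones(len(self.pos_cM), dtype=bool)
            )
            D = np.hstack([ones, C[:, ~row]]) if C.shape[1] else ones
            Q = orth(D)
            ry = y - Q @ (Q.T @ y)
            rss_red = float(ry @ ry)
            Xg = X[:, mask]
            Xr = Xg - Q @ (Q.T @ Xg)
            num = Xr.T @ ry
            den = (Xr * Xr).sum(axis=0)
            good = den > _DEN_TOL
            beta = np.where(good, num / np.maximum(den, _DEN_TOL), 0.0)
            rss_full = rss_red - np.where(good, num**2 / np.maximum(den, _DEN_TOL), 0.0)
            rss_full = np.maximum(rss_full, 1e-300)
            with np.errstate(divide="ignore"):
                l = 0.5 * n * np.log10(np.maximum(rss_red, 1e-300) / rss_full)
            lod[mask] = np.maximum(l, 0.0)
            effect[mask] = beta
        return lod, effect

    def max_lod(self, y: np.ndarray) -> float:
        lod, _ = self.scan(y, self.select(y))
        return float(lod.max())


def cim_scan(
    probs: GenotypeProbGrid,
    gm: GenotypeMatrix,
    gmap: GeneticMap,
    phenotype: np.ndarray,
    cofactors: list[str] | None = None,
    window_cM: float = 3.0,
) -> ScanResult:
    """Cofactor-adjusted LOD scan on the probability grid.

    ``phenotype`` must be aligned to ``probs.line_ids``; ``cofactors`` is a
    list of marker names (empty list = plain interval mapping).
    """
    cofactors = cofactors or []
    scanner = CIMScanner(probs, gm, gmap, window_cM=window_cM,
                         n_cofactors=len(cofactors))
    name_to_idx = {n: i for i, n in enumerate(scanner.marker_names)}
    idx = [name_to_idx[c] for c in cofactors]
    y = np.asarray(phenotype, dtype=float)
    lod, effect = scanner.scan(y, idx)
    table = pd.DataFrame(
        dict(chrom=scanner.chroms, cM=scanner.pos_cM, lod=lod, effect=effect)
    )
    return ScanResult(table=table, cofactors=list(cofactors), window_cM=window_cM)


def permutation_threshold(
    probs: GenotypeProbGrid,
    gm: GenotypeMatrix,
    gmap: GeneticMap,
    phenotype: np.ndarray,
    n_perm: int = 1000,
    alphas: tuple[float, ...] = (0.05,),
    seed: int = 0,
    n_cofactors: int = 3,
    window_cM: float = 3.0,
) -> tuple[dict[float, float], np.ndarray]:
    """Genome-wide empirical LOD thresholds from phenotype permutations.

    Each permutation reselects cofactors and redoes the full scan; the
    threshold at level alpha is the empirical (1 - alpha) quantile of the
    permuted genome-wide maximum LODs.  Returns (thresholds, maxima).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    scanner = CIMScanner(probs, gm, gmap, window_cM=window_cM,
                         n_cofactors=n_cofactors)
    y = np.asarray(phenotype, dtype=float)
    maxima = np.empty(n_perm)
    for p in range(n_perm):
        maxima[p] = scanner.max_lod(rng.permutation(y))
    thresholds = {a: float(np.quantile(maxima, 1.0 - a)) for a in alphas}
    return thresholds, maxima


def support_interval(
    scan: ScanResult, chrom: str, peak_cM: float, drop: float = 1.0
) -> tuple[float, float]:
    """1-LOD (by default) support interval around a peak position.

    The maximal contiguous run of grid points with LOD >= peak - drop is
    found first; when the profile is still strictly above the cut at a run
    boundary, the true crossing lies beyond it, so the interval is expanded
    to the flanking grid point on that side.
    """
    prof = scan.chrom_profile(chrom).sort_values("cM")
    pos = prof["cM"].to_numpy()
    lod = prof["lod"].to_numpy()
    i = int(np.argmin(np.abs(pos - peak_cM)))
    cut = lod[i] - drop
    lo = i
    while lo > 0 and lod[lo - 1] >= cut:
        lo -= 1
    hi = i
    while hi < len(pos) - 1 and lod[hi + 1] >= cut:
        hi += 1
    if lo > 0 and lod[lo] > cut:
        lo -= 1
    if hi < len(pos) - 1 and lod[hi] > cut:
        hi += 1
    return float(pos[lo]), float(pos[hi])


def detect_qtl(scan: ScanResult, threshold: float, drop: float = 1.0) -> list[QTLPeak]:
    """Local LOD maxima above threshold, merged when support intervals
    overlap (the higher peak wins)."""
    peaks: list[QTLPeak] = []
    for chrom in scan.table["chrom"].unique():
        prof = scan.chrom_profile(chrom).sort_values("cM")
        pos = prof["cM"].to_numpy()
        lod = prof["lod"].to_numpy()
        eff = prof["effect"].to_numpy()
        cand = [
            i for i in range(len(pos))
            if lod[i] >= threshold
            and (i == 0 or lod[i] >= lod[i - 1])
            and (i == len(pos) - 1 or lod[i] >= lod[i + 1])
        ]
        chrom_peaks: list[QTLPeak] = []
        for i in cand:
            iv = support_interval(scan, chrom, pos[i], drop=drop)
            chrom_peaks.append(QTLPeak(str(chrom), float(pos[i]), float(lod[i]),
                                       iv, float(eff[i])))
        chrom_peaks.sort(key=lambda p: p.pos_cM)
        merged: list[QTLPeak] = []
        for p in chrom_peaks:
            if merged and p.interval_cM[0] <= merged[-1].interval_cM[1]:
                if p.lod > merged[-1].lod:
                    merged[-1] = p
            else:
                merged.append(p)
        peaks.extend(merged)
    return peaks
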