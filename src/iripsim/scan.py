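"""Single- and two-locus genome scans with M1 / M2 / M2vs1 statistics.

Markers are fully informative for founder origin, so a marker genotype is
the unordered pair of founder labels carried by a line.  The single-locus
model is a one-way ANOVA of phenotype on marker genotype classes (omnibus
F-test); the two-locus model adds both markers as categorical factors with
no interaction, tested against the intercept-only model.  Scans report
-log10 P.

Both tests are computed from sufficient statistics (per-class counts and
phenotype sums) rather than per-marker model fits, which makes genome-wide
null simulation with thousands of phenotype replicates practical.

Scan summaries over a search region:

* ``M2`` — max over marker pairs (s != t) of the two-locus -log10 P;
* ``M1`` — max single-locus -log10 P over markers on the chromosome(s) of
  the maximizing pair;
* ``M2vs1 = M2 - M1`` — the improvement of the two-QTL model over the best
  single-QTL model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, special, stats

from .genmap import Locus, MarkerGrid
from .meiosis import Population

__all__ = [
    "GenotypeMatrix",
    "ScanResult",
    "MStatistics",
    "genotype_matrix",
    "single_locus_pvalue",
    "two_locus_pvalue",
    "scan_single",
    "scan_pairs",
    "m_statistics",
    "detect_single",
    "detect_two",
    "location_error",
]

_LN10 = np.log(10.0)


def _neglog10_sf_f(F: np.ndarray, df1: np.ndarray, df2: np.ndarray) -> np.ndarray:
    """-log10 of the F survival function, safe for extreme statistics."""
    F = np.asarray(F, dtype=float)
    p = special.fdtrc(df1, df2, F)
    with np.errstate(divide="ignore"):
        out = -np.log10(p)
    # fall back to the log survival function where fdtrc underflowed
    bad = ~np.isfinite(out)
    if np.any(bad):
        out = np.asarray(out)
        out[bad] = -stats.f.logsf(F[bad], np.broadcast_to(df1, F.shape)[bad],
                                  np.broadcast_to(df2, F.shape)[bad]) / _LN10
    return out


@dataclass
class GenotypeMatrix:
    """Founder-origin marker genotypes of a population on a marker grid.

    ``codes[i, m]`` is the genotype-class index (0..n_groups[m]-1) of line i
    at marker m; classes are the distinct unordered founder-label pairs
    observed at the marker, including rare residual-heterozygote classes.
    """

    grid: MarkerGrid
    labels1: np.ndarray            # (n_lines, n_markers) hap1 founder labels
    labels2: np.ndarray            # (n_lines, n_markers) hap2 founder labels
    codes: np.ndarray              # (n_lines, n_markers) genotype class codes
    n_groups: np.ndarray           # (n_markers,)
    _indicator: sparse.csr_array | None = field(default=None, repr=False)
    _offsets: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_lines(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def indicator(self) -> tuple[sparse.csr_array, np.ndarray]:
        """Stacked one-hot class indicator over all markers, plus offsets."""
        if self._indicator is None:
            n, m = self.codes.shape
            offsets = np.concatenate(([0], np.cumsum(self.n_groups)))
            cols = (self.codes + offsets[:-1][None, :]).ravel()
            rows = np.repeat(np.arange(n), m)
            data = np.ones(n * m, dtype=np.float64)
            mat = sparse.csr_array((data, (rows, cols)), shape=(n, int(offsets[-1])))
            self._indicator = mat
            self._offsets = offsets
        return self._indicator, self._offsets


def genotype_matrix(pop: Population, grid: MarkerGrid) -> GenotypeMatrix:
    """Read founder labels off every haplotype at every marker."""
    n = len(pop)
    m = grid.n_markers
    cid = np.asarray(grid.chrom_ids)
    pos = np.asarray(grid.positions)
    labels1 = np.empty((n, m), dtype=np.int16)
    labels2 = np.empty((n, m), dtype=np.int16)
    for ci, (chrom_id, _) in enumerate(pop.gmap.chromosomes):
        cols = np.flatnonzero(cid == chrom_id)
        if cols.size == 0:
            continue
        p = pos[cols]
        for i, ind in enumerate(pop.individuals):
            labels1[i, cols] = ind.hap1.chroms[ci].labels_at(p)
            labels2[i, cols] = ind.hap2.chroms[ci].labels_at(p)
    lo = np.minimum(labels1, labels2).astype(np.int32)
    hi = np.maximum(labels1, labels2).astype(np.int32)
    pair = lo * 256 + hi
    codes = np.empty((n, m), dtype=np.int32)
    n_groups = np.empty(m, dtype=np.int64)
    for j in range(m):
        uniq, inv = np.unique(pair[:, j], return_inverse=True)
        codes[:, j] = inv
        n_groups[j] = len(uniq)
    return GenotypeMatrix(grid, labels1, labels2, codes, n_groups)


# ---------------------------------------------------------------------------
# single-locus scan
# ---------------------------------------------------------------------------

def single_locus_pvalue(genotypes: np.ndarray, phenotypes: np.ndarray) -> float:
    """One-way ANOVA omnibus -log10 P of phenotype on genotype classes.

    `genotypes` is any integer labelling of the classes at one marker.
    Markers with a single class or no residual degrees of freedom yield NaN
    (flagged; excluded from scan maxima).
    """
    g = np.asarray(genotypes)
    y = np.asarray(phenotypes, dtype=float)
    if g.shape != y.shape:
        raise ValueError("genotype and phenotype lengths differ")
    _, codes = np.unique(g, return_inverse=True)
    k = int(codes.max()) + 1
    n = len(y)
    if k < 2 or n - k < 1:
        return float("nan")
    counts = np.bincount(codes, minlength=k).astype(float)
    sums = np.bincount(codes, weights=y, minlength=k)
    T = y.sum()
    sst = float(y @ y) - T * T / n
    ssb = float(np.sum(sums * sums / counts)) - T * T / n
    if sst <= 0:
        return 0.0
    sse = max(sst - ssb, 0.0)
    if sse == 0.0:
        return float(_neglog10_sf_f(np.inf, k - 1, n - k))
    F = (ssb / (k - 1)) / (sse / (n - k))
    return float(_neglog10_sf_f(max(F, 0.0), k - 1, n - k))


def scan_single(gm: GenotypeMatrix, Y: np.ndarray) -> np.ndarray:
    """Single-locus -log10 P for every marker and phenotype replicate.

    `Y` has shape (n_replicates, n_lines); the result has shape
    (n_replicates, n_markers) with NaN at monomorphic markers.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = gm.n_lines
    if Y.shape[1] != n:
        raise ValueError("phenotype length does not match the population")
    ind, offsets = gm.indicator()
    counts = np.asarray(ind.sum(axis=0)).ravel()
    S = (ind.T @ Y.T).T                      # (reps, K_total) group sums
    T = Y.sum(axis=1, keepdims=True)
    sst = np.einsum("ij,ij->i", Y, Y)[:, None] - T**2 / n
    contrib = S * S / counts[None, :]
    ssb = np.add.reduceat(contrib, offsets[:-1], axis=1) - T**2 / n
    k = gm.n_groups.astype(float)[None, :]
    df1 = k - 1
    df2 = n - k
    sse = np.maximum(sst - ssb, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df1) / (sse / df2)
    out = np.where(sst > 0, _neglog10_sf_f(np.where(np.isfinite(F), F, np.inf),
                                           df1, df2), 0.0)
    out[:, (gm.n_groups < 2) | (n - gm.n_groups < 1)] = np.nan
    return out


# ---------------------------------------------------------------------------
# two-locus scan
# ---------------------------------------------------------------------------

def _two_locus_from_stats(cell_counts: np.ndarray, cell_sums: np.ndarray,
                          yy: float, n: int) -> float:
    """Overall F-test of the additive two-factor model from cell statistics."""
    ks, kt = cell_counts.shape
    ns = cell_counts.sum(axis=1)
    nt = cell_counts.sum(axis=0)
    Ss = cell_sums.sum(axis=1)
    St = cell_sums.sum(axis=0)
    T = float(cell_sums.sum())
    p = 1 + (ks - 1) + (kt - 1)
    xtx = np.zeros((p, p))
    xty = np.zeros(p)
    xtx[0, 0] = n
    xtx[0, 1:ks] = xtx[1:ks, 0] = ns[:-1]
    xtx[0, ks:] = xtx[ks:, 0] = nt[:-1]
    xtx[1:ks, 1:ks] = np.diag(ns[:-1])
    xtx[1:ks, ks:] = cell_counts[:-1, :-1]
    xtx[ks:, 1:ks] = cell_counts[:-1, :-1].T
    xtx[ks:, ks:] = np.diag(nt[:-1])
    xty[0] = T
    xty[1:ks] = Ss[:-1]
    xty[ks:] = St[:-1]
    b, _, rank, _ = np.linalg.lstsq(xtx, xty, rcond=None)
    dfm = rank - 1
    dfr = n - rank
    if dfm < 1 or dfr < 1:
        return float("nan")
    explained = float(b @ xty)
    ssm = explained - T * T / n
    sst = yy - T * T / n
    if sst <= 0:
        return 0.0
    sse = max(yy - explained, 0.0)
    if sse == 0.0:
        return float(_neglog10_sf_f(np.inf, dfm, dfr))
    F = (ssm / dfm) / (sse / dfr)
    return float(_neglog10_sf_f(max(F, 0.0), dfm, dfr))


def two_locus_pvalue(genotypes_s: np.ndarray, genotypes_t: np.ndarray,
                     phenotypes: np.ndarray) -> float:
    """-log10 P of the additive two-marker model versus the intercept.

    The two markers enter as categorical factors with no interaction.
    Confounded pairs whose additive model is not estimable beyond a single
    factor with no residual df yield NaN.
    """
    gs = np.asarray(genotypes_s)
    gt = np.asarray(genotypes_t)
    y = np.asarray(phenotypes, dtype=float)
    if gs is genotypes_t or (gs.shape == gt.shape and np.array_equal(gs, gt)):
        raise ValueError("two-locus model requires two distinct markers (s != t)")
    _, cs = np.unique(gs, return_inverse=True)
    _, ct = np.unique(gt, return_inverse=True)
    ks, kt = int(cs.max()) + 1, int(ct.max()) + 1
    cell = cs * kt + ct
    n = len(y)
    counts = np.bincount(cell, minlength=ks * kt).reshape(ks, kt).astype(float)
    sums = np.bincount(cell, weights=y, minlength=ks * kt).reshape(ks, kt)
    return _two_locus_from_stats(counts, sums, float(y @ y), n)


def scan_pairs(gm: GenotypeMatrix, y: np.ndarray,
               marker_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-locus -log10 P over all marker pairs within `marker_idx`.

    Returns (pairs, values): pairs is (n_pairs, 2) of marker indices with
    s < t, values the corresponding -log10 P (NaN where not estimable).
    """
    y = np.asarray(y, dtype=float)
    marker_idx = np.asarray(marker_idx)
    marker_idx = marker_idx[gm.n_groups[marker_idx] >= 2]  # skip monomorphic
    if marker_idx.size < 2:
        raise ValueError("pair scan needs at least two polymorphic markers")
    yy = float(y @ y)
    n = len(y)
    codes = [gm.codes[:, j] for j in marker_idx]
    kk = [int(gm.n_groups[j]) for j in marker_idx]
    pairs = []
    vals = []
    for a in range(len(marker_idx)):
        ca, ka = codes[a], kk[a]
        for b in range(a + 1, len(marker_idx)):
            cb, kb = codes[b], kk[b]
            cell = ca * kb + cb
            counts = np.bincount(cell, minlength=ka * kb).reshape(ka, kb).astype(float)
            sums = np.bincount(cell, weights=y, minlength=ka * kb).reshape(ka, kb)
            pairs.append((marker_idx[a], marker_idx[b]))
            vals.append(_two_locus_from_stats(counts, sums, yy, n))
    return np.asarray(pairs), np.asarray(vals)


# ---------------------------------------------------------------------------
# scan results and detection rules
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Per-marker (and optionally per-pair) -log10 P surfaces."""

    grid: MarkerGrid
    neglog10p: np.ndarray                      # (n_markers,)
    pair_index: np.ndarray | None = None       # (n_pairs, 2) marker indices
    pair_neglog10p: np.ndarray | None = None   # (n_pairs,)
    region_marker_idx: np.ndarray | None = None


@dataclass(frozen=True)
class MStatistics:
    m1: float
    m2: float
    m2vs1: float
    argmax_pair: tuple[int, int]    # marker indices of the M2 maximizer


def run_scan(gm: GenotypeMatrix, y: np.ndarray,
             pair_region_idx: np.ndarray | None = None) -> ScanResult:
    """Single-locus scan of one phenotype vector, plus an optional
    region-restricted pair scan."""
    single = scan_single(gm, y[None, :])[0]
    res = ScanResult(gm.grid, single)
    if pair_region_idx is not None:
        res.pair_index, res.pair_neglog10p = scan_pairs(gm, y, pair_region_idx)
        res.region_marker_idx = np.asarray(pair_region_idx)
    return res


def m_statistics(scan: ScanResult,
                 region_idx: np.ndarray | None = None) -> MStatistics:
    """M1, M2 and M2vs1 over a search region.

    M2 maximizes the pair surface; M1 maximizes the single-locus surface
    over the region's markers on the chromosome(s) of the maximizing pair;
    M2vs1 is their difference.
    """
    if scan.pair_neglog10p is None:
        raise ValueError("scan has no two-locus surface")
    if region_idx is None:
        region_idx = scan.region_marker_idx
    region_idx = np.asarray(region_idx)
    if region_idx.size == 0:
        raise ValueError("empty search region")
    vals = scan.pair_neglog10p
    if np.all(np.isnan(vals)):
        raise ValueError("no estimable marker pair in the region")
    best = int(np.nanargmax(vals))
    s, t = (int(v) for v in scan.pair_index[best])
    m2 = float(vals[best])
    cid = np.asarray(scan.grid.chrom_ids)
    chroms = {cid[s], cid[t]}
    on_chrom = region_idx[np.isin(cid[region_idx], list(chroms))]
    m1 = float(np.nanmax(scan.neglog10p[on_chrom]))
    return MStatistics(m1=m1, m2=m2, m2vs1=m2 - m1, argmax_pair=(s, t))


def detect_single(scan: ScanResult, t1: float, true_locus: Locus,
                  window: float = 20.0) -> bool:
    """True iff the single-locus peak within +-window cM of the true
    position exceeds the genome-wide threshold."""
    idx = scan.grid.marker_indices(true_locus.chrom_id,
                                   true_locus.position - window,
                                   true_locus.position + window)
    if idx.size == 0:
        return False
    vals = scan.neglog10p[idx]
    if np.all(np.isnan(vals)):
        return False
    return bool(np.nanmax(vals) > t1)


def detect_two(scan: ScanResult, t2: float, t2vs1: float) -> bool:
    """Two-QTL separation rule: M2 > T2 and M2vs1 > T2vs1 over the scan's
    pair-search region."""
    ms = m_statistics(scan)
    return bool(ms.m2 > t2 and ms.m2vs1 > t2vs1)


def location_error(scan: ScanResult, true_locus: Locus,
                   region_idx: np.ndarray | None = None) -> float:
    """|peak position - true position| of the single-locus scan, in cM.

    Ties resolve to the smallest (chromosome, position) because markers are
    stored in map order.
    """
    if region_idx is None:
        region_idx = scan.grid.marker_indices(true_locus.chrom_id)
    region_idx = np.asarray(region_idx)
    vals = scan.neglog10p[region_idx]
    if np.all(np.isnan(vals)):
        raise ValueError("no informative marker in the region")
    best = region_idx[int(np.nanargmax(vals))]
    return abs(float(np.asarray(scan.grid.positions)[best]) - true_locus.position)
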