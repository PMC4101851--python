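import numpy as np
import pandas as pd
import pytest
from scipy import stats

from iripsim.genmap import Locus, marker_grid
from iripsim.scan import (GenotypeMatrix, ScanResult, detect_single, detect_two,
                          genotype_matrix, location_error, m_statistics,
                          run_scan, scan_pairs, scan_single,
                          single_locus_pvalue, two_locus_pvalue)


def _anova_oracle(groups, y):
    """Brute-force sum-of-squares one-way ANOVA -log10 P."""
    y = np.asarray(y, float)
    labels = np.unique(groups)
    n, k = len(y), len(labels)
    grand = y.mean()
    ssb = sum(len(y[groups == g]) * (y[groups == g].mean() - grand) ** 2
              for g in labels)
    sse = sum(((y[groups == g] - y[groups == g].mean()) ** 2).sum()
              for g in labels)
    F = (ssb / (k - 1)) / (sse / (n - k))
    return -np.log10(stats.f.sf(F, k - 1, n - k))


def _ols_two_factor_oracle(gs, gt, y):
    """Overall F-test of y ~ C(s) + C(t) via statsmodels."""
    from statsmodels.formula.api import ols
    df = pd.DataFrame({"y": y, "s": gs.astype(str), "t": gt.astype(str)})
    fit = ols("y ~ C(s) + C(t)", df).fit()
    return -np.log10(fit.f_pvalue)


class TestSingleLocus:
    def test_constant_phenotype_gives_zero(self):
        g = np.repeat(np.arange(4), 4)
        assert single_locus_pvalue(g, np.ones(16)) == 0.0

    def test_matches_sum_of_squares_oracle_on_16_lines(self):
        rng = np.random.default_rng(0)
        g = np.repeat(np.arange(8), 2)
        y = rng.normal(size=16)
        assert single_locus_pvalue(g, y) == pytest.approx(_anova_oracle(g, y),
                                                          abs=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_f_oneway_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 30))
        k = int(rng.integers(2, 6))
        g = rng.integers(0, k, size=n)
        while len(np.unique(g)) < 2:
            g = rng.integers(0, k, size=n)
        y = rng.normal(size=n) + 0.4 * g
        expected = -np.log10(stats.f_oneway(
            *[y[g == v] for v in np.unique(g)]).pvalue)
        assert single_locus_pvalue(g, y) == pytest.approx(expected, abs=1e-8)

    def test_monomorphic_marker_flagged(self):
        assert np.isnan(single_locus_pvalue(np.zeros(10), np.arange(10.0)))

    def test_invariant_to_phenotype_shift_and_scale(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 5, 40)
        y = rng.normal(size=40)
        base = single_locus_pvalue(g, y)
        assert single_locus_pvalue(g, 3.7 * y - 11.0) == pytest.approx(base, abs=1e-9)

    def test_null_pvalues_uniform(self):
        # 8 balanced groups, many noise replicates: P ~ Uniform(0, 1)
        rng = np.random.default_rng(2)
        codes = np.repeat(np.arange(8), 25)[None, :].T
        gm = GenotypeMatrix(grid=None, labels1=None, labels2=None,
                            codes=codes.astype(np.int32),
                            n_groups=np.array([8]))
        Y = rng.normal(size=(10_000, 200))
        neglog = scan_single(gm, Y)[:, 0]
        pvals = 10.0 ** (-neglog)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3


class TestTwoLocus:
    def test_same_marker_rejected(self):
        g = np.repeat(np.arange(4), 4)
        with pytest.raises(ValueError):
            two_locus_pvalue(g, g, np.arange(16.0))

    def test_constant_phenotype_gives_zero(self):
        rng = np.random.default_rng(3)
        gs, gt = rng.integers(0, 3, 20), rng.integers(0, 4, 20)
        assert two_locus_pvalue(gs, gt, np.full(20, 2.0)) == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_least_squares_oracle(self, seed):
        rng = np.random.default_rng(seed + 100)
        n = int(rng.integers(12, 30))
        gs = rng.integers(0, 3, n)
        gt = rng.integers(0, 4, n)
        if len(np.unique(gs)) < 2 or len(np.unique(gt)) < 2:
            pytest.skip("degenerate draw")
        y = rng.normal(size=n) + 0.5 * gs - 0.3 * gt
        assert two_locus_pvalue(gs, gt, y) == pytest.approx(
            _ols_two_factor_oracle(gs, gt, y), abs=1e-8)

    def test_collinear_pair_reduces_to_shared_factor(self):
        # completely confounded markers: model equals the one-factor fit
        rng = np.random.default_rng(4)
        gs = rng.integers(0, 3, 60)
        y = rng.normal(size=60) + gs
        pairs, vals = None, None
        v2 = two_locus_pvalue(gs, gs + 10, y)  # same partition, distinct labels
        assert v2 == pytest.approx(single_locus_pvalue(gs, y), abs=1e-9)


class TestGenotypeMatrix:
    def test_founder_population_is_monomorphic(self, small_map, small_grid):
        from iripsim.meiosis import Population, founder_individual
        pop = Population([founder_individual(small_map, 3, id=i) for i in range(5)],
                         small_map)
        gm = genotype_matrix(pop, small_grid)
        assert np.all(gm.labels1 == 3) and np.all(gm.labels2 == 3)
        assert np.all(gm.n_groups == 1)

    def test_marker_columns_match_grid(self, small_inbred_pop, small_grid):
        gm = genotype_matrix(small_inbred_pop, small_grid)
        assert gm.n_markers == small_grid.n_markers
        assert gm.n_lines == len(small_inbred_pop)
        assert np.all(gm.codes >= 0)
        assert np.all(gm.codes.max(axis=0) + 1 == gm.n_groups)

    def test_vectorized_scan_equals_per_marker_anova(self, small_inbred_pop,
                                                     small_grid):
        rng = np.random.default_rng(5)
        gm = genotype_matrix(small_inbred_pop, small_grid)
        y = rng.normal(size=gm.n_lines)
        surface = scan_single(gm, y[None, :])[0]
        for j in range(gm.n_markers):
            expected = single_locus_pvalue(gm.codes[:, j], y)
            if np.isnan(expected):
                assert np.isnan(surface[j])
            else:
                assert surface[j] == pytest.approx(expected, abs=1e-9)


class TestMStatistics:
    def _toy_scan(self, rng, n=120, markers=5):
        """Synthetic genotype matrix on a 5-marker grid of one chromosome."""
        from iripsim.genmap import GeneticMap
        gmap = GeneticMap(((1, 50.0),))
        grid = marker_grid(gmap, 10.0)
        codes = rng.integers(0, 4, size=(n, markers)).astype(np.int32)
        labels = (codes + 1).astype(np.int16)
        return GenotypeMatrix(grid, labels, labels, codes,
                              np.full(markers, 4, dtype=np.int64)), grid

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(6)
        gm, grid = self._toy_scan(rng)
        y = rng.normal(size=120)
        idx = np.arange(5)
        pairs, vals = scan_pairs(gm, y, idx)
        # brute force over all pairs
        best = -1.0
        for a in range(5):
            for b in range(a + 1, 5):
                v = two_locus_pvalue(gm.codes[:, a] + 10, gm.codes[:, b], y)
                best = max(best, v)
        assert np.nanmax(vals) == pytest.approx(best, abs=1e-9)
        scan = ScanResult(grid, scan_single(gm, y[None, :])[0], pairs, vals, idx)
        ms = m_statistics(scan)
        assert ms.m2 == pytest.approx(best, abs=1e-9)
        assert ms.m2vs1 == pytest.approx(ms.m2 - ms.m1, abs=1e-12)
        assert ms.m1 == pytest.approx(np.nanmax(scan.neglog10p[idx]), abs=1e-12)

    def test_two_additive_qtls_raise_m2_above_m1(self):
        rng = np.random.default_rng(7)
        gm, grid = self._toy_scan(rng)
        y = (1.0 * (gm.codes[:, 0] == 0) + 1.0 * (gm.codes[:, 3] == 1)
             + 0.3 * rng.normal(size=120))
        pairs, vals = scan_pairs(gm, y, np.arange(5))
        scan = ScanResult(grid, scan_single(gm, y[None, :])[0], pairs, vals,
                          np.arange(5))
        ms = m_statistics(scan)
        assert ms.m2 > ms.m1

    def test_empty_region_rejected(self):
        rng = np.random.default_rng(8)
        gm, grid = self._toy_scan(rng)
        y = rng.normal(size=120)
        pairs, vals = scan_pairs(gm, y, np.arange(5))
        scan = ScanResult(grid, scan_single(gm, y[None, :])[0], pairs, vals,
                          np.arange(5))
        with pytest.raises(ValueError):
            m_statistics(scan, region_idx=np.array([], dtype=int))


class TestDetectionRules:
    def test_infinite_threshold_never_detects(self, small_inbred_pop, small_grid):
        rng = np.random.default_rng(9)
        gm = genotype_matrix(small_inbred_pop, small_grid)
        y = rng.normal(size=gm.n_lines)
        scan = run_scan(gm, y, pair_region_idx=np.arange(4))
        assert not detect_single(scan, np.inf, Locus(1, 30.0))
        assert not detect_two(scan, np.inf, np.inf)

    def test_detects_obvious_signal(self, small_inbred_pop, small_grid):
        rng = np.random.default_rng(10)
        gm = genotype_matrix(small_inbred_pop, small_grid)
        # huge effect at the marker nearest 30 cM on chromosome 1
        j = small_grid.marker_indices(1, 30.0, 30.0)[0]
        y = 5.0 * (gm.codes[:, j] == gm.codes[0, j]) + rng.normal(size=gm.n_lines)
        scan = run_scan(gm, y)
        assert detect_single(scan, 3.0, Locus(1, 30.0))
        assert location_error(scan, Locus(1, 30.0)) <= 10.0

    def test_location_error_zero_for_clean_marker_signal(self, small_inbred_pop,
                                                         small_grid):
        gm = genotype_matrix(small_inbred_pop, small_grid)
        j = small_grid.marker_indices(1, 25.0, 25.0)[0]
        y = (gm.codes[:, j] == gm.codes[0, j]).astype(float)
        scan = run_scan(gm, y)
        assert location_error(scan, Locus(1, 25.0)) == 0.0

    def test_flat_scan_tie_breaks_to_smallest_position(self, small_grid):
        vals = np.zeros(small_grid.n_markers)
        scan = ScanResult(small_grid, vals)
        assert location_error(scan, Locus(1, 0.0)) == 0.0
        # true position at the far end: argmax is still the first marker
        far = small_grid.loci()[small_grid.marker_indices(1)[-1]]
        assert location_error(scan, far) == far.position
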