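import numpy as np
import pytest

from iripsim.genmap import Locus
from iripsim.meiosis import Population, cross, founder_individual
from iripsim.qtl import (EXPERIMENT_LOCI, AllelePattern, Qtl, QtlModel,
                         build_experiment, genetic_variance, genotypic_value,
                         pattern_effects, scale_for_pve, scale_for_variance,
                         simulate_phenotypes)

from .table_data import TABLE_PVE, TABLE_VARIANCE


class TestPatternEffects:
    def test_biallelic_levels_are_scale_and_zero(self):
        assert pattern_effects("4:4", 0.5).tolist() == [0.5] * 4 + [0.0] * 4

    def test_zero_scale_gives_zero_vector(self):
        assert pattern_effects("2:2:2:2", 0.0).tolist() == [0.0] * 8

    def test_levels_equally_spaced_down_to_zero(self):
        e = pattern_effects("1:1:1:1:1:1:1:1", 0.7)
        assert np.allclose(np.diff(e), -0.1)
        assert e[-1] == 0.0

    def test_assignment_permutes_founders(self):
        pat = AllelePattern("1:7", assignment=(5, 1, 2, 3, 4, 6, 7, 8))
        e = pattern_effects(pat, 0.68)
        assert e[4] == pytest.approx(0.68)
        assert np.count_nonzero(e) == 1

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError):
            AllelePattern("5:3")


class TestVarianceCalibration:
    @pytest.mark.parametrize("pattern", ["4:4", "2:6", "1:7", "3:2:3",
                                         "2:4:2", "2:2:2:2", "1:1:1:1:1:1:1:1"])
    @pytest.mark.parametrize("scale", [0.3, 0.68, 1.7])
    def test_variance_matches_enumeration_oracle(self, pattern, scale):
        e = pattern_effects(pattern, scale)
        oracle = sum(v * v for v in e) / 8 - (sum(e) / 8) ** 2
        assert genetic_variance(pattern, scale) == pytest.approx(oracle, abs=1e-12)

    def test_biallelic_variance_is_p_one_minus_p_a_squared(self):
        # 4:4 -> 0.25 a^2 ; 1:7 -> (7/64) a^2
        assert genetic_variance("4:4", 0.35) == pytest.approx(0.25 * 0.35**2)
        assert genetic_variance("1:7", 0.68) == pytest.approx(7 / 64 * 0.68**2)

    @pytest.mark.parametrize("pattern,target,expected", [
        ("1:7", 0.05, 0.68),
        ("2:6", 0.03, 0.40),
        ("4:4", 0.03, 0.35),
    ])
    def test_scale_for_variance_matches_table(self, pattern, target, expected):
        assert round(scale_for_variance(pattern, target), 2) == expected

    def test_scale_for_variance_inverts_variance(self, rng):
        for pattern in ("3:2:3", "1:1:1:1:1:1:1:1"):
            target = rng.uniform(0.001, 0.5)
            s = scale_for_variance(pattern, target)
            assert genetic_variance(pattern, s) == pytest.approx(target, rel=1e-12)

    def test_zero_targets(self):
        assert scale_for_variance("2:4:2", 0.0) == 0.0
        assert scale_for_pve("2:4:2", 0.0, 1.0) == 0.0


class TestPveCalibration:
    @pytest.mark.parametrize("pattern,pve,expected", [
        ("1:7", 0.06, 0.76),
        ("4:4", 0.02, 0.2857),   # prints as 0.28 in 2-dp tables
        ("4:4", 0.04, 0.41),
    ])
    def test_known_calibration_points(self, pattern, pve, expected):
        assert scale_for_pve(pattern, pve, 1.0) == pytest.approx(expected, abs=0.005)

    def test_pve_identity(self):
        # Vg / (Vg + Ve) equals the requested PVE
        for pve in (0.02, 0.12):
            s = scale_for_pve("2:2:2:2", pve, noise_variance=2.0)
            vg = genetic_variance("2:2:2:2", s)
            assert vg / (vg + 2.0) == pytest.approx(pve, rel=1e-12)

    def test_rejects_pve_of_one(self):
        with pytest.raises(ValueError):
            scale_for_pve("4:4", 1.0, 1.0)


class TestEffectTables:
    """Round-trip of the published 2-dp effect rows from the generating rule."""

    @pytest.mark.parametrize("pve,pattern,expected", TABLE_PVE)
    def test_pve_rows(self, pve, pattern, expected):
        e = pattern_effects(pattern, scale_for_pve(pattern, pve, 1.0))
        assert np.max(np.abs(e - np.asarray(expected))) <= 0.0100001

    @pytest.mark.parametrize("variance,pattern,expected", TABLE_VARIANCE)
    def test_variance_rows_exact_at_two_decimals(self, variance, pattern, expected):
        e = pattern_effects(pattern, scale_for_variance(pattern, variance))
        assert np.round(e, 2).tolist() == list(expected)


class TestGenotypicValues:
    def test_homozygote_gets_full_effect(self, small_map):
        line = founder_individual(small_map, 1)
        qtl = Qtl(Locus(1, 10.0), (0.53, 0, 0, 0, 0, 0, 0, 0))
        assert genotypic_value(line, qtl) == pytest.approx(0.53)

    def test_heterozygote_gets_midpoint(self, small_map, rng):
        f1 = cross(founder_individual(small_map, 1),
                   founder_individual(small_map, 5), rng)
        qtl = Qtl(Locus(1, 10.0), (0.53, 0, 0, 0, 0, 0, 0, 0))
        assert genotypic_value(f1, qtl) == pytest.approx(0.265)

    def test_zero_effects_give_zero(self, small_map):
        line = founder_individual(small_map, 7)
        qtl = Qtl(Locus(2, 5.0), (0.0,) * 8)
        assert genotypic_value(line, qtl) == 0.0


class TestPhenotypeSimulation:
    def test_no_qtl_no_noise_gives_zeros(self, small_inbred_pop, rng):
        model = QtlModel((), noise_variance=0.0)
        y = simulate_phenotypes(small_inbred_pop, model, rng)
        assert np.all(y == 0.0)

    def test_empirical_pve_matches_target(self, small_map):
        # idealized inbred population: founder lines at equal frequency
        rng = np.random.default_rng(31)
        lines = [founder_individual(small_map, f, id=i)
                 for i, f in enumerate(rng.integers(1, 9, size=4000))]
        pop = Population(lines, small_map)
        scale = scale_for_pve("4:4", 0.06, 1.0)
        model = QtlModel((Qtl(Locus(1, 30.0), tuple(pattern_effects("4:4", scale))),),
                         noise_variance=1.0)
        g = simulate_phenotypes(pop, QtlModel(model.qtls, 0.0), rng)
        y = simulate_phenotypes(pop, model, rng)
        pve = g.var() / y.var()
        assert pve == pytest.approx(0.06, abs=0.015)

    def test_qtl_outside_map_rejected(self, small_inbred_pop, rng):
        model = QtlModel((Qtl(Locus(1, 99.0), (0.5,) * 8),), 1.0)
        with pytest.raises(ValueError):
            simulate_phenotypes(small_inbred_pop, model, rng)


class TestExperiments:
    def test_experiment_1_layout(self, rng):
        model = build_experiment(1, rng)
        assert len(model.qtls) == 11
        assert model.qtls[0].locus == Locus(1, 140.0)
        assert model.noise_variance == 0.5

    def test_experiment_2_uses_heading_date_positions(self, rng):
        model = build_experiment(2, rng)
        assert [(q.locus.chrom_id, q.locus.position) for q in model.qtls] \
            == [(c, float(p)) for c, p in EXPERIMENT_LOCI[2]]

    def test_experiment_variance_multisets(self, rng):
        for exp_id, expected in [(1, {0.03: 1, 0.04: 5, 0.05: 3, 0.06: 2}),
                                 (2, {0.04: 2, 0.05: 2, 0.06: 3, 0.07: 2}),
                                 (3, {0.04: 2, 0.05: 6, 0.06: 2})]:
            model = build_experiment(exp_id, rng)
            variances = [round(float(np.mean(np.asarray(q.effects) ** 2)
                                     - np.mean(q.effects) ** 2), 2)
                         for q in model.qtls]
            got = {}
            for v in variances:
                got[v] = got.get(v, 0) + 1
            assert got == expected

    def test_experiment_3_mostly_biallelic(self, rng):
        model = build_experiment(3, rng)
        assert len(model.qtls) == 10
        biallelic = sum(len({round(e, 6) for e in q.effects}) == 2
                        for q in model.qtls)
        assert biallelic >= 8

    def test_invalid_experiment_rejected(self, rng):
        with pytest.raises(ValueError):
            build_experiment(4, rng)


class TestCalibrationProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(pattern=st.sampled_from(["4:4", "2:6", "1:7", "3:2:3", "2:4:2",
                                    "2:2:2:2", "1:1:1:1:1:1:1:1"]),
           target=st.floats(min_value=1e-4, max_value=2.0))
    def test_variance_calibration_round_trip(self, pattern, target):
        s = scale_for_variance(pattern, target)
        assert genetic_variance(pattern, s) == pytest.approx(target, rel=1e-10)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(pattern=st.sampled_from(["4:4", "1:7", "2:2:2:2"]),
           pve=st.floats(min_value=0.0, max_value=0.9),
           noise=st.floats(min_value=0.1, max_value=4.0))
    def test_pve_calibration_round_trip(self, pattern, pve, noise):
        s = scale_for_pve(pattern, pve, noise)
        vg = genetic_variance(pattern, s)
        assert vg / (vg + noise) == pytest.approx(pve, abs=1e-10)
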