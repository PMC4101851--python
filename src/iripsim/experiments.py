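"""Headline simulation experiments at desk scale.

These functions bundle the standard study conditions — the rice map,
an 8-way design with a crossing population of 100 and 800 final inbred
lines, 1-cM fully informative markers, seven selfing generations — into
single calls used by the command-line examples, the acceptance checks, and
the test suite.  Replicate counts are arguments so that desk-scale runs
(tens to hundreds of replicates) and larger runs use the same code path.
"""

from __future__ import annotations

import numpy as np

from .breeding import BreedingDesign, make_founders, mixing_stage, recurrent_cycle
from .genmap import build_rice_map
from .metrics import drift_fraction, segment_stats
from .power import PowerConfig, estimate_power, relative_power, run_multi_qtl_experiment
from .thresholds import (fit_gev, reference_thresholds, simulate_null_maxima,
                         threshold_from_gev)

__all__ = [
    "STANDARD_DESIGN",
    "drift_time_course",
    "segment_length_after_cycles",
    "estimate_t1_threshold",
    "coupling_separation_power",
    "repulsion_relative_power",
    "experiment_mean_detected",
]

#: crossing population 100, 800 inbred lines, 7 selfing generations
STANDARD_DESIGN = BreedingDesign(8, 100, 0, 800, 7)


def _design(n_cycles: int) -> BreedingDesign:
    return BreedingDesign(8, 100, n_cycles, 800, 7)


def drift_time_course(eval_cycles: tuple[int, ...], n_reps: int,
                      rng: np.random.Generator,
                      n_crossing: int = 100) -> dict[int, float]:
    """Mean drift percentage (bins with < 8 founder alleles) by cycle.

    Each replicate runs the 8-way mixing stage to `n_crossing` individuals
    and then recurrent crossing up to max(eval_cycles), evaluating the
    0.1-cM-bin drift fraction of the crossing population at each requested
    cycle count.
    """
    gmap = build_rice_map()
    design = BreedingDesign(8, n_crossing, 0, max(n_crossing, 800), 7)
    sums = {c: 0.0 for c in eval_cycles}
    for _ in range(n_reps):
        pop = mixing_stage(make_founders(gmap, 8), design, rng)
        if 0 in sums:
            sums[0] += drift_fraction(pop, 8).fraction_lost
        for cycle in range(1, max(eval_cycles) + 1):
            pop = recurrent_cycle(pop, rng)
            if cycle in sums:
                sums[cycle] += drift_fraction(pop, 8).fraction_lost
    return {c: s / n_reps for c, s in sums.items()}


def segment_length_after_cycles(n_cycles: int, n_reps: int,
                                rng: np.random.Generator) -> float:
    """Mean non-recombinant segment length (cM) of final inbred lines."""
    from .breeding import simulate_irip
    gmap = build_rice_map()
    total = 0.0
    for _ in range(n_reps):
        pop = simulate_irip(_design(n_cycles), rng, gmap=gmap)
        total += segment_stats(pop).mean_length
    return total / n_reps


def estimate_t1_threshold(n_reps: int, rng: np.random.Generator,
                          n_cycles: int = 0) -> float:
    """GEV-fitted 95th percentile of genome-wide null M1 maxima.

    One 8-way IRIP of 800 lines is simulated; each replicate draws fresh
    Normal(0, 1) phenotypes and records the genome-wide maximum -log10 P of
    the 1-cM single-locus scan.
    """
    null = simulate_null_maxima(_design(n_cycles), n_reps, rng)
    return threshold_from_gev(fit_gev(null.m1), 0.95)


def coupling_separation_power(x: float, n_reps: int, rng: np.random.Generator,
                              scale: float = 0.27, n_cycles: int = 0,
                              arrangement: str = "highest") -> float:
    """Percent of replicates in which the two-QTL rule separates a pair of
    small coupling-phase QTLs x cM apart (thresholds: reference set)."""
    ts = reference_thresholds("8way_n800", n_cycles)
    cfg = PowerConfig(_design(n_cycles), "coupling", ts, n_replicates=n_reps,
                      scale=scale, x=x, arrangement=arrangement, rule="two")
    return 100.0 * estimate_power(cfg, rng).power


def repulsion_relative_power(x: float, n_reps: int, rng: np.random.Generator,
                             scale: float = 0.53,
                             n_cycles: int = 0) -> dict[str, float]:
    """Relative power (linked vs unlinked, %) of the single-QTL-model scan
    for a repulsion pair, per carrier arrangement."""
    ts = reference_thresholds("8way_n800", n_cycles)
    out = {}
    for arrangement in ("highest", "lowest"):
        linked = estimate_power(
            PowerConfig(_design(n_cycles), "repulsion", ts, n_replicates=n_reps,
                        scale=scale, x=x, arrangement=arrangement), rng)
        unlinked = estimate_power(
            PowerConfig(_design(n_cycles), "repulsion", ts, n_replicates=n_reps,
                        scale=scale, x=x, arrangement=arrangement,
                        unlinked=True), rng)
        out[arrangement] = relative_power(linked, unlinked)
    return out


def experiment_mean_detected(experiment_id: int, n_reps: int,
                             rng: np.random.Generator,
                             n_cycles: int = 0) -> tuple[float, float]:
    """Mean and SD of the number of detected QTLs in a multi-QTL experiment
    on the 8-way design with the reference thresholds."""
    ts = reference_thresholds("8way_n800", n_cycles)
    res = run_multi_qtl_experiment(experiment_id, _design(n_cycles), ts,
                                   n_reps, rng)
    return res.mean_detected, res.sd_detected
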