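"""Power experiments: single, linked, and multiple QTL detection.

Each experiment repeats (simulate population, simulate phenotypes, scan,
apply the detection rule) and reports the detection proportion.  Detection
rules:

* single-QTL model — the single-locus peak within 20 cM of a true QTL
  position exceeds T1;
* two-QTL separation — M2 > T2 and M2vs1 > T2vs1 over the chromosome-1
  search range 70..(110 + x) cM, where x is the QTL spacing.

Linked-QTL configurations place QTL1 at chromosome 1, 90 cM and QTL2 at
90 + x cM, in repulsion (opposite signs) or coupling (same signs), with the
carrier alleles either on founders P1, P3, P5, P7 ("highest frequency" of
recombinant carriers through the funnel) or on P1..P4 ("lowest").  The
unlinked baseline moves QTL2 to chromosome 2, 90 cM, keeping the effects.

Because meiosis treats chromosomes independently and mating is
genotype-independent, only the chromosomes an experiment scans are
simulated; this is an exact marginalization, not an approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .breeding import BreedingDesign, mixing_stage, recurrent_cycle, \
    selfing_stage, simulate_irip
from .genmap import GeneticMap, Locus, build_rice_map, marker_grid
from .meiosis import founder_individual
from .qtl import EXPERIMENT_LOCI, Qtl, QtlModel, build_experiment, simulate_phenotypes
from .scan import (detect_single, detect_two, genotype_matrix, location_error,
                   run_scan)
from .thresholds import ThresholdSet

__all__ = [
    "PowerConfig",
    "PowerResult",
    "linked_qtl_model",
    "estimate_power",
    "relative_power",
    "run_multi_qtl_experiment",
    "write_report",
]

HIGHEST_CARRIERS = (1, 3, 5, 7)
LOWEST_CARRIERS = (1, 2, 3, 4)
DETECTION_WINDOW_CM = 20.0


@dataclass(frozen=True)
class PowerConfig:
    """One power experiment: design, QTL configuration, rule, thresholds."""

    design: BreedingDesign
    mode: str                        # "single" | "repulsion" | "coupling"
    thresholds: ThresholdSet
    n_replicates: int = 400
    scale: float = 0.53              # homozygous carrier effect
    x: float | None = None           # QTL spacing in cM (linked modes)
    arrangement: str = "highest"     # "highest" | "lowest"
    unlinked: bool = False           # move QTL2 to chromosome 2
    rule: str = "single"             # "single" | "two"
    noise_variance: float = 1.0
    record_location_error: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("single", "repulsion", "coupling"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode != "single" and self.x is None:
            raise ValueError("linked modes need a QTL spacing x")
        if self.arrangement not in ("highest", "lowest"):
            raise ValueError("arrangement must be 'highest' or 'lowest'")
        if self.rule not in ("single", "two"):
            raise ValueError("rule must be 'single' or 'two'")
        if self.rule == "two" and (self.thresholds.t2 is None
                                   or self.thresholds.t2vs1 is None):
            raise ValueError("two-QTL rule needs T2 and T2vs1 thresholds")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass
class PowerResult:
    """Detection proportion with its binomial standard error."""

    n_detected: int
    n_replicates: int
    power: float
    se: float
    location_errors: np.ndarray | None = None
    mean_detected: float | None = None     # multi-QTL runs
    sd_detected: float | None = None
    n_qtls: int | None = None


def _carrier_effects(carriers: tuple[int, ...], scale: float,
                     n_founders: int = 8) -> tuple[float, ...]:
    e = [0.0] * n_founders
    for c in carriers:
        e[c - 1] = scale
    return tuple(e)


def linked_qtl_model(mode: str, scale: float, x: float, arrangement: str,
                     unlinked: bool = False,
                     noise_variance: float = 1.0) -> QtlModel:
    """Two-QTL model for the repulsion/coupling experiments."""
    carriers = HIGHEST_CARRIERS if arrangement == "highest" else LOWEST_CARRIERS
    e1 = _carrier_effects(carriers, scale)
    sign = -1.0 if mode == "repulsion" else 1.0
    e2 = tuple(sign * v for v in e1)
    loc2 = Locus(2, 90.0) if unlinked else Locus(1, 90.0 + x)
    return QtlModel((Qtl(Locus(1, 90.0), e1), Qtl(loc2, e2)),
                    noise_variance=noise_variance)


def _single_qtl_model(config: PowerConfig) -> QtlModel:
    carriers = (HIGHEST_CARRIERS if config.arrangement == "highest"
                else LOWEST_CARRIERS)
    return QtlModel((Qtl(Locus(1, 90.0), _carrier_effects(carriers, config.scale)),),
                    noise_variance=config.noise_variance)


def _experiment_map(config: PowerConfig) -> GeneticMap:
    rice = build_rice_map()
    chroms = {1}
    if config.mode != "single" and config.unlinked:
        chroms.add(2)
    return rice.subset(sorted(chroms))


def estimate_power(config: PowerConfig, rng: np.random.Generator) -> PowerResult:
    """Monte-Carlo detection power under one configuration."""
    gmap = _experiment_map(config)
    grid = marker_grid(gmap, 1.0)
    if config.mode == "single":
        model = _single_qtl_model(config)
    else:
        model = linked_qtl_model(config.mode, config.scale, config.x,
                                 config.arrangement, config.unlinked,
                                 config.noise_variance)
    x = config.x or 0.0
    region_idx = (grid.marker_indices(1, 70.0, 110.0 + (0.0 if config.unlinked else x))
                  if config.rule == "two" else None)
    detected = 0
    loc_errors = [] if config.record_location_error else None
    for _ in range(config.n_replicates):
        pop = simulate_irip(config.design, rng, gmap=gmap)
        y = simulate_phenotypes(pop, model, rng)
        gm = genotype_matrix(pop, grid)
        scan = run_scan(gm, y, pair_region_idx=region_idx)
        if config.rule == "single":
            hit = any(detect_single(scan, config.thresholds.t1, q.locus,
                                    DETECTION_WINDOW_CM) for q in model.qtls)
        else:
            hit = detect_two(scan, config.thresholds.t2, config.thresholds.t2vs1)
        detected += bool(hit)
        if loc_errors is not None:
            win = grid.marker_indices(1, 70.0, 110.0)
            loc_errors.append(location_error(scan, model.qtls[0].locus, win))
    p = detected / config.n_replicates
    se = math.sqrt(p * (1 - p) / config.n_replicates)
    return PowerResult(detected, config.n_replicates, p, se,
                       location_errors=(np.asarray(loc_errors)
                                        if loc_errors is not None else None))


def relative_power(linked: PowerResult, unlinked: PowerResult) -> float:
    """100 * power(linked) / power(unlinked), in percent."""
    if unlinked.power <= 0:
        raise ZeroDivisionError("unlinked baseline has zero power")
    return 100.0 * linked.power / unlinked.power


def _two_way_founder_pairs() -> tuple[tuple[int, int], ...]:
    return ((1, 2), (3, 4), (5, 6), (7, 8))


def run_multi_qtl_experiment(experiment_id: int, design: BreedingDesign,
                             thresholds: ThresholdSet, n_replicates: int,
                             rng: np.random.Generator,
                             two_way: bool = False) -> PowerResult:
    """Mean (+- SD) number of detected QTLs in a multi-QTL experiment.

    With ``two_way=True`` the comparison design is run instead: four
    disjoint two-way populations (P1xP2, P3xP4, P5xP6, P7xP8), and a QTL
    counts as detected when at least one of the four populations shows a
    significant signal within 20 cM of its position.
    """
    loci = EXPERIMENT_LOCI[experiment_id]
    chroms = sorted({c for c, _ in loci})
    gmap = build_rice_map().subset(chroms)
    grid = marker_grid(gmap, 1.0)
    counts = np.empty(n_replicates)
    for rep in range(n_replicates):
        model = build_experiment(experiment_id, rng)
        scans = []
        if two_way:
            # four two-way populations of 200 lines each (4 x 200 = 800)
            design2 = BreedingDesign(2, design.n_crossing, design.n_cycles,
                                     200, design.n_selfing_generations)
            for f1, f2 in _two_way_founder_pairs():
                founders = [founder_individual(gmap, f1, id=f1),
                            founder_individual(gmap, f2, id=f2)]
                pop = mixing_stage(founders, design2, rng)
                for _ in range(design2.n_cycles):
                    pop = recurrent_cycle(pop, rng)
                pop = selfing_stage(pop, design2, rng)
                y = simulate_phenotypes(pop, model, rng)
                scans.append(run_scan(genotype_matrix(pop, grid), y))
        else:
            pop = simulate_irip(design, rng, gmap=gmap)
            y = simulate_phenotypes(pop, model, rng)
            scans.append(run_scan(genotype_matrix(pop, grid), y))
        counts[rep] = sum(
            any(detect_single(s, thresholds.t1, q.locus, DETECTION_WINDOW_CM)
                for s in scans)
            for q in model.qtls)
    n_qtls = len(loci)
    detected = int((counts > 0).sum())
    p = detected / n_replicates
    return PowerResult(detected, n_replicates, p,
                       math.sqrt(p * (1 - p) / n_replicates),
                       mean_detected=float(counts.mean()),
                       sd_detected=float(counts.std(ddof=1)),
                       n_qtls=n_qtls)


def write_report(results: dict[str, PowerResult], path) -> None:
    """Tidy TSV report: one row per (label, metric)."""
    with open(path, "w") as fh:
        fh.write("label\tmetric\tvalue\n")
        for label, r in results.items():
            fh.write(f"{label}\tpower\t{r.power!r}\n")
            fh.write(f"{label}\tse\t{r.se!r}\n")
            fh.write(f"{label}\tn_replicates\t{r.n_replicates}\n")
            if r.mean_detected is not None:
                fh.write(f"{label}\tmean_detected\t{r.mean_detected!r}\n")
                fh.write(f"{label}\tsd_detected\t{r.sd_detected!r}\n")
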