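"""Construction of intermated recombinant inbred populations (IRIPs).

The breeding scheme has three stages:

1. *Mixing*: founder genomes are combined by single crosses.  Eight founders
   go through a fixed funnel (P1xP2, P3xP4, P5xP6, P7xP8, then the four-way
   crosses (P1P2)x(P3P4) and (P5P6)x(P7P8), then the eight-way cross of the
   two funnel halves).  A two-way design has no mixing stage: the population
   starts from F1 plants.
2. *Recurrent crossing*: `n_cycles` generations of disjoint random mating.
   The population is randomly split into pairs and each pair leaves exactly
   two progeny, so the size stays constant.
3. *Selfing*: seven generations of inbreeding by default.  The first selfing
   generation uses multiple-seed descent to expand the population to
   `n_final` lines; later generations use single-seed descent.  Seven
   generations fix more than 99% of the genome (expected residual
   heterozygosity 0.5**7 ~ 0.78%).

Cycle-0 and cycle-2 eight-way designs correspond to the rice MAGIC and
"MAGIC plus" populations respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genmap import GeneticMap, build_rice_map
from .meiosis import (Individual, Population, cross, founder_individual,
                      make_gamete, self_cross)

__all__ = [
    "BreedingDesign",
    "make_founders",
    "mixing_stage",
    "recurrent_cycle",
    "selfing_stage",
    "simulate_irip",
]


@dataclass(frozen=True)
class BreedingDesign:
    """Parameters of an IRIP construction run."""

    n_founders: int = 8
    n_crossing: int = 100
    n_cycles: int = 0
    n_final: int = 800
    n_selfing_generations: int = 7

    def __post_init__(self) -> None:
        if self.n_founders not in (2, 8):
            raise ValueError("designs support 2 or 8 founders")
        if self.n_crossing <= 0 or self.n_crossing % 2:
            raise ValueError("n_crossing must be a positive even count")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")
        if self.n_final < self.n_crossing:
            raise ValueError("n_final must be >= n_crossing (selfing only expands)")
        if self.n_selfing_generations < 0:
            raise ValueError("n_selfing_generations must be >= 0")


def make_founders(gmap: GeneticMap, n_founders: int) -> list[Individual]:
    """Fully homozygous founders labelled 1..n_founders."""
    return [founder_individual(gmap, f, id=f) for f in range(1, n_founders + 1)]


def mixing_stage(founders: list[Individual], design: BreedingDesign,
                 rng: np.random.Generator) -> Population:
    """Funnel the founders into `n_crossing` mixed individuals (cycle 0).

    Founders are inbred, so all F1 plants of a pair are genetically
    identical; independent meioses begin at the four-way generation.  For
    eight founders each cycle-0 individual carries one gamete from a
    (P1..P4) four-way plant and one from a (P5..P8) four-way plant.
    """
    if len(founders) != design.n_founders:
        raise ValueError("founder count does not match design")
    for f in founders:
        for c1, c2 in zip(f.hap1.chroms, f.hap2.chroms):
            if len(c1.labels) != 1 or c1.labels[0] != c2.labels[0]:
                raise ValueError("founders must be fully homozygous")
    gmap = founders[0].gmap
    n = design.n_crossing
    if design.n_founders == 2:
        f1 = cross(founders[0], founders[1], rng, generation="F1")
        inds = [Individual(f1.hap1, f1.hap2, gmap, id=i, generation="F1")
                for i in range(n)]
        return Population(inds, gmap, stage="mixing")
    # eight-way funnel
    f1 = [cross(founders[i], founders[i + 1], rng, generation="F1")
          for i in (0, 2, 4, 6)]
    left = [cross(f1[0], f1[1], rng, generation="4way") for _ in range(n)]
    right = [cross(f1[2], f1[3], rng, generation="4way") for _ in range(n)]
    inds = [Individual(make_gamete(left[i], rng), make_gamete(right[i], rng),
                       gmap, id=i, generation="8way")
            for i in range(n)]
    return Population(inds, gmap, stage="mixing")


def recurrent_cycle(pop: Population, rng: np.random.Generator) -> Population:
    """One generation of disjoint random mating, two progeny per pair."""
    n = len(pop)
    if n % 2:
        raise ValueError("recurrent crossing needs an even population size")
    order = rng.permutation(n)
    offspring: list[Individual] = []
    for i in range(0, n, 2):
        mother = pop.individuals[order[i]]
        father = pop.individuals[order[i + 1]]
        offspring.append(cross(mother, father, rng, id=i, generation="cycle"))
        offspring.append(cross(mother, father, rng, id=i + 1, generation="cycle"))
    return Population(offspring, pop.gmap, stage="cycle", seed=pop.seed)


def selfing_stage(pop: Population, design: BreedingDesign,
                  rng: np.random.Generator) -> Population:
    """Inbreed to `n_final` lines over `n_selfing_generations` generations.

    Generation 1 uses multiple-seed descent (ceil(n_final/n) seeds per
    plant, truncated uniformly at random to exactly n_final); subsequent
    generations use single-seed descent.
    """
    n = len(pop)
    if design.n_final < n:
        raise ValueError("n_final smaller than the current population")
    gens = design.n_selfing_generations
    if gens == 0:
        return Population(list(pop.individuals), pop.gmap, stage="selfing_0",
                          seed=pop.seed)
    seeds_per_plant = math.ceil(design.n_final / n)
    expanded: list[Individual] = []
    for plant in pop.individuals:
        for _ in range(seeds_per_plant):
            expanded.append(self_cross(plant, rng, generation="selfing_1"))
    if len(expanded) > design.n_final:
        keep = rng.choice(len(expanded), size=design.n_final, replace=False)
        expanded = [expanded[i] for i in np.sort(keep)]
    lines = expanded
    for g in range(2, gens + 1):
        lines = [self_cross(line, rng, id=i, generation=f"selfing_{g}")
                 for i, line in enumerate(lines)]
    for i, line in enumerate(lines):
        line.id = i
    return Population(lines, pop.gmap, stage=f"selfing_{gens}", seed=pop.seed)


def simulate_irip(design: BreedingDesign, rng: np.random.Generator,
                  gmap: GeneticMap | None = None,
                  seed: int | None = None) -> Population:
    """Full IRIP construction: mixing, recurrent cycles, then selfing."""
    if gmap is None:
        gmap = build_rice_map()
    founders = make_founders(gmap, design.n_founders)
    pop = mixing_stage(founders, design, rng)
    for _ in range(design.n_cycles):
        pop = recurrent_cycle(pop, rng)
    pop = selfing_stage(pop, design, rng)
    pop.stage = "inbred"
    pop.seed = seed
    return pop
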