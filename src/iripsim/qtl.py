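"""QTL effect models, effect-size calibration, and phenotype simulation.

Every QTL is purely additive: each founder allele carries a homozygous
genotypic value, heterozygotes take the midpoint, and dominance and
epistasis are zero.  Allele-distribution patterns such as ``"4:4"`` or
``"2:2:2:2"`` partition the eight founders into effect classes; the class
levels are equally spaced from a top value `a` (the *scale*) down to 0,
e.g. ``2:2:2:2`` gives levels a, 2a/3, a/3, 0.

Two calibrations are supported:

* a target genetic variance ``V`` of the QTL under equal founder
  frequencies in fully inbred lines: ``Var(g) = V``, where ``g`` runs over
  the eight founder values (for a bi-allelic QTL with carrier frequency p
  this is the classical p(1-p)a^2);
* a target proportion of variance explained (PVE) ``v`` against an
  environmental variance ``Ve``: ``Var(g) = Ve * v / (1 - v)``, so that
  Var(g) / (Var(g) + Ve) = v.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genmap import GeneticMap, Locus
from .meiosis import Population

__all__ = [
    "PATTERNS",
    "AllelePattern",
    "Qtl",
    "QtlModel",
    "pattern_effects",
    "genetic_variance",
    "scale_for_variance",
    "scale_for_pve",
    "genotypic_value",
    "qtl_genotype_labels",
    "simulate_phenotypes",
    "build_experiment",
    "EXPERIMENT_LOCI",
]

#: founder-class sizes for each supported allele-frequency pattern
PATTERNS: dict[str, tuple[int, ...]] = {
    "4:4": (4, 4),
    "2:6": (2, 6),
    "1:7": (1, 7),
    "3:2:3": (3, 2, 3),
    "2:4:2": (2, 4, 2),
    "2:2:2:2": (2, 2, 2, 2),
    "1:1:1:1:1:1:1:1": (1,) * 8,
    "1:1": (1, 1),  # two-way designs
}


@dataclass(frozen=True)
class AllelePattern:
    """An allele-frequency pattern plus the founder-to-class assignment.

    `assignment` permutes founder labels onto pattern classes: founder
    ``assignment[i]`` receives the i-th entry of the effect vector.  The
    identity assignment reproduces the canonical effect rows (highest
    effects on the lowest-numbered founders).
    """

    pattern: str
    assignment: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown allele pattern {self.pattern!r}")

    @property
    def class_sizes(self) -> tuple[int, ...]:
        return PATTERNS[self.pattern]

    @property
    def n_founders(self) -> int:
        return sum(self.class_sizes)


def pattern_effects(pattern: AllelePattern | str, scale: float) -> np.ndarray:
    """Per-founder homozygous effects for a pattern at a given top value.

    Classes receive equally spaced descending levels
    ``scale * (c - 1 - j) / (c - 1)`` for class j of c classes (bi-allelic:
    scale and 0), replicated according to the class sizes.
    """
    if isinstance(pattern, str):
        pattern = AllelePattern(pattern)
    sizes = pattern.class_sizes
    c = len(sizes)
    levels = [scale * (c - 1 - j) / (c - 1) for j in range(c)]
    canonical = np.repeat(levels, sizes)
    if pattern.assignment is None:
        return canonical
    out = np.empty_like(canonical)
    out[np.asarray(pattern.assignment) - 1] = canonical
    return out


def genetic_variance(pattern: AllelePattern | str, scale: float) -> float:
    """Variance of the founder genotypic values at equal frequencies."""
    e = pattern_effects(pattern, scale)
    return float(np.mean(e**2) - np.mean(e) ** 2)


def scale_for_variance(pattern: AllelePattern | str, target_variance: float) -> float:
    """Top effect value giving the requested genetic variance."""
    if target_variance < 0:
        raise ValueError("target variance must be >= 0")
    unit = genetic_variance(pattern, 1.0)
    return math.sqrt(target_variance / unit)


def scale_for_pve(pattern: AllelePattern | str, target_pve: float,
                  noise_variance: float = 1.0) -> float:
    """Top effect value giving the requested PVE against `noise_variance`."""
    if not 0.0 <= target_pve < 1.0:
        raise ValueError("PVE must lie in [0, 1)")
    return scale_for_variance(pattern, noise_variance * target_pve / (1.0 - target_pve))


@dataclass(frozen=True)
class Qtl:
    """A locus plus its per-founder homozygous genotypic values."""

    locus: Locus
    effects: tuple[float, ...]

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.effects)):
            raise ValueError("QTL effects must be finite")


@dataclass(frozen=True)
class QtlModel:
    """A set of QTLs and the environmental noise variance."""

    qtls: tuple[Qtl, ...]
    noise_variance: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_variance < 0:
            raise ValueError("noise variance must be >= 0")

    def validate(self, gmap: GeneticMap) -> None:
        for q in self.qtls:
            q.locus.validate(gmap)


def qtl_genotype_labels(pop: Population, locus: Locus) -> tuple[np.ndarray, np.ndarray]:
    """Founder labels of both haplotypes of every line at a locus."""
    ci = pop.gmap.index_of(locus.chrom_id)
    pos = np.array([locus.position])
    a = np.empty(len(pop), dtype=np.int64)
    b = np.empty(len(pop), dtype=np.int64)
    for i, ind in enumerate(pop.individuals):
        a[i] = ind.hap1.chroms[ci].labels_at(pos)[0]
        b[i] = ind.hap2.chroms[ci].labels_at(pos)[0]
    return a, b


def genotypic_value(ind, qtl: Qtl) -> float:
    """Additive genotypic value of one individual at one QTL."""
    ci = ind.gmap.index_of(qtl.locus.chrom_id)
    pos = np.array([qtl.locus.position])
    e = np.asarray(qtl.effects)
    a = int(ind.hap1.chroms[ci].labels_at(pos)[0])
    b = int(ind.hap2.chroms[ci].labels_at(pos)[0])
    return 0.5 * (e[a - 1] + e[b - 1])


def simulate_phenotypes(pop: Population, model: QtlModel,
                        rng: np.random.Generator) -> np.ndarray:
    """Phenotypes: summed genotypic values plus Normal(0, noise_variance)."""
    model.validate(pop.gmap)
    y = np.zeros(len(pop))
    for q in model.qtls:
        e = np.asarray(q.effects)
        a, b = qtl_genotype_labels(pop, q.locus)
        y += 0.5 * (e[a - 1] + e[b - 1])
    if model.noise_variance > 0:
        y += rng.normal(0.0, math.sqrt(model.noise_variance), size=len(pop))
    return y


# ---------------------------------------------------------------------------
# multi-QTL experiments on known rice QTL positions
# ---------------------------------------------------------------------------

#: (chromosome, cM) positions of the simulated QTLs, by experiment:
#: 1 = blast resistance (11 loci), 2 = heading date (9 loci),
#: 3 = seed morphology (10 loci).
EXPERIMENT_LOCI: dict[int, tuple[tuple[int, float], ...]] = {
    1: ((1, 140), (2, 156), (4, 53), (6, 56), (6, 67), (8, 22), (9, 32),
        (11, 33), (11, 91), (11, 117), (12, 50)),
    2: ((3, 6), (3, 144), (6, 10), (6, 12), (6, 51), (6, 59), (7, 50),
        (8, 35), (10, 43)),
    3: ((1, 87), (2, 37), (3, 83), (3, 102), (4, 59), (5, 28), (5, 36),
        (6, 91), (7, 43), (8, 106)),
}

#: assignable patterns and variance multisets for each experiment
_RANDOM_PATTERNS = ("4:4", "2:6", "1:7", "3:2:3", "2:4:2", "2:2:2:2",
                    "1:1:1:1:1:1:1:1")
_EXPERIMENT_PATTERNS: dict[int, tuple[str | None, ...]] = {
    1: ("4:4",) * 4 + ("1:1:1:1:1:1:1:1",) * 4 + (None,) * 3,
    2: ("4:4",) * 2 + ("2:6",) * 2 + ("1:7",) * 2 + ("3:2:3", "2:4:2", "2:2:2:2"),
    3: ("4:4",) * 8 + (None,) * 2,
}
_EXPERIMENT_VARIANCES: dict[int, tuple[float, ...]] = {
    1: (0.03,) + (0.04,) * 5 + (0.05,) * 3 + (0.06,) * 2,
    2: (0.04,) * 2 + (0.05,) * 2 + (0.06,) * 3 + (0.07,) * 2,
    3: (0.04,) * 2 + (0.05,) * 6 + (0.06,) * 2,
}
#: environmental noise variance used in the multi-QTL experiments
EXPERIMENT_NOISE_VARIANCE = 0.5


def build_experiment(experiment_id: int, rng: np.random.Generator) -> QtlModel:
    """One realization of a multi-QTL experiment.

    QTL positions are fixed per experiment; allele patterns and genetic
    variances are drawn from the experiment's stated multisets, paired at
    random, with a fresh uniform founder-to-class permutation per locus.
    """
    if experiment_id not in EXPERIMENT_LOCI:
        raise ValueError("experiment_id must be 1, 2, or 3")
    loci = EXPERIMENT_LOCI[experiment_id]
    patterns = [p if p is not None else _RANDOM_PATTERNS[rng.integers(len(_RANDOM_PATTERNS))]
                for p in _EXPERIMENT_PATTERNS[experiment_id]]
    rng.shuffle(patterns)
    variances = list(_EXPERIMENT_VARIANCES[experiment_id])
    rng.shuffle(variances)
    qtls = []
    for (chrom, pos), pat_name, var in zip(loci, patterns, variances):
        assignment = tuple(rng.permutation(8) + 1)
        pat = AllelePattern(pat_name, assignment)
        effects = pattern_effects(pat, scale_for_variance(pat_name, var))
        qtls.append(Qtl(Locus(chrom, float(pos)), tuple(effects)))
    return QtlModel(tuple(qtls), noise_variance=EXPERIMENT_NOISE_VARIANCE)
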