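"""Gamete formation under a no-interference (Poisson) crossover model.

Genomes are founder-origin mosaics stored in breakpoint-segment form: per
chromosome, an ascending array of segment end positions (the last entry is
the chromosome length) and a parallel array of founder labels.  Crossover
counts per chromosome are Poisson with mean L/100 (the map length in
Morgans, so that 100 cM corresponds to one expected crossover per gamete),
and crossover positions are i.i.d. uniform along the chromosome.  There is
no chiasma interference: chromosomes recombine independently, and the
haplotype a gamete starts from is a fair coin per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genmap import GeneticMap

__all__ = [
    "ChromSegments",
    "Haplotype",
    "Individual",
    "Population",
    "founder_individual",
    "sample_crossover_positions",
    "make_gamete",
    "cross",
    "self_cross",
]


class ChromSegments:
    """One chromosome of a haplotype: segment end positions + founder labels.

    Segment j covers (bounds[j-1], bounds[j]] with bounds[-1] == chromosome
    length; labels of adjacent segments differ after normalization.
    Instances are treated as immutable and may be shared between haplotypes.
    """

    __slots__ = ("bounds", "labels")

    def __init__(self, bounds: np.ndarray, labels: np.ndarray):
        self.bounds = bounds
        self.labels = labels

    @classmethod
    def uniform(cls, length: float, label: int) -> "ChromSegments":
        return cls(np.array([length], dtype=np.float64), np.array([label], dtype=np.int16))

    def labels_at(self, positions: np.ndarray) -> np.ndarray:
        """Founder labels at the given cM positions (vectorized)."""
        idx = np.searchsorted(self.bounds, positions, side="left")
        idx = np.minimum(idx, len(self.labels) - 1)
        return self.labels[idx]

    def segment_lengths(self) -> np.ndarray:
        return np.diff(self.bounds, prepend=0.0)

    def validate(self, length: float) -> None:
        b = self.bounds
        if len(b) != len(self.labels) or len(b) == 0:
            raise ValueError("bounds/labels mismatch")
        if not np.all(np.diff(b) > 0):
            raise ValueError("segment bounds not strictly increasing")
        if abs(b[-1] - length) > 1e-9:
            raise ValueError("segments do not partition the chromosome")
        if np.any(self.labels[1:] == self.labels[:-1]):
            raise ValueError("adjacent segments share a label (not normalized)")


@dataclass
class Haplotype:
    """A full gametic genome: one ChromSegments per map chromosome."""

    chroms: list[ChromSegments]

    def validate(self, gmap: GeneticMap) -> None:
        if len(self.chroms) != gmap.n_chromosomes:
            raise ValueError("haplotype does not match map")
        for seg, (_, length) in zip(self.chroms, gmap.chromosomes):
            seg.validate(length)


@dataclass
class Individual:
    """A diploid plant: two haplotypes on a shared genetic map."""

    hap1: Haplotype
    hap2: Haplotype
    gmap: GeneticMap
    id: int = 0
    generation: str = ""


@dataclass
class Population:
    """A list of individuals plus breeding-stage bookkeeping."""

    individuals: list[Individual]
    gmap: GeneticMap
    stage: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.individuals:
            raise ValueError("population must be nonempty")

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def size(self) -> int:
        return len(self.individuals)


def founder_individual(gmap: GeneticMap, label: int, id: int = 0) -> Individual:
    """A fully homozygous founder carrying `label` across the genome."""
    def hap() -> Haplotype:
        return Haplotype([ChromSegments.uniform(l, label) for _, l in gmap.chromosomes])
    return Individual(hap(), hap(), gmap, id=id, generation="founder")


def sample_crossover_positions(chrom_length: float, rng: np.random.Generator) -> np.ndarray:
    """Sorted crossover positions on one chromosome for one meiosis.

    The count is Poisson(chrom_length / 100); positions are uniform on
    (0, chrom_length).
    """
    if chrom_length < 0:
        raise ValueError("chromosome length must be non-negative")
    if chrom_length == 0:
        return np.empty(0)
    k = rng.poisson(chrom_length / 100.0)
    if k == 0:
        return np.empty(0)
    return np.sort(rng.uniform(0.0, chrom_length, size=k))


def _recombine(a: ChromSegments, b: ChromSegments, cuts: np.ndarray,
               start_with_a: bool, length: float) -> ChromSegments:
    """Splice two parental chromosomes at the given sorted cut positions."""
    sources = (a, b) if start_with_a else (b, a)
    out_bounds: list[float] = []
    out_labels: list[int] = []
    lo = 0.0
    n_cuts = len(cuts)
    for i in range(n_cuts + 1):
        hi = cuts[i] if i < n_cuts else length
        if hi <= lo:  # duplicate cut positions collapse the interval
            continue
        src = sources[i % 2]
        sb = src.bounds
        j0 = sb.searchsorted(lo, side="right")
        j1 = sb.searchsorted(hi, side="left")
        if j1 >= len(sb):
            j1 = len(sb) - 1
        out_bounds.extend(sb[j0:j1])
        out_bounds.append(hi)
        out_labels.extend(src.labels[j0:j1 + 1])
        lo = hi
    # normalize: merge adjacent segments with equal labels
    m = len(out_labels)
    if m > 1:
        keep = [out_labels[j] != out_labels[j + 1] for j in range(m - 1)]
        keep.append(True)
        if not all(keep):
            out_bounds = [v for v, k in zip(out_bounds, keep) if k]
            out_labels = [v for v, k in zip(out_labels, keep) if k]
    return ChromSegments(np.asarray(out_bounds, dtype=np.float64),
                         np.asarray(out_labels, dtype=np.int16))


_LAM_CACHE: dict[tuple, np.ndarray] = {}


def _poisson_means(gmap: GeneticMap) -> np.ndarray:
    lam = _LAM_CACHE.get(gmap.chromosomes)
    if lam is None:
        lam = np.asarray(gmap.lengths) / 100.0
        _LAM_CACHE[gmap.chromosomes] = lam
    return lam


def _same_chromosome(a: ChromSegments, b: ChromSegments) -> bool:
    if a is b:
        return True
    la, lb = a.labels, b.labels
    return (la.shape == lb.shape and bool((la == lb).all())
            and bool((a.bounds == b.bounds).all()))


def make_gamete(parent: Individual, rng: np.random.Generator) -> Haplotype:
    """One recombinant gamete from a diploid parent."""
    gmap = parent.gmap
    n = gmap.n_chromosomes
    ks = rng.poisson(_poisson_means(gmap))
    coins = rng.random(n) < 0.5
    chroms: list[ChromSegments] = []
    h1, h2 = parent.hap1.chroms, parent.hap2.chroms
    for ci in range(n):
        a, b = h1[ci], h2[ci]
        k = int(ks[ci])
        if k == 0:
            chroms.append(a if coins[ci] else b)
        elif _same_chromosome(a, b):
            # homozygous chromosome: recombination returns the same mosaic
            chroms.append(a)
        else:
            length = gmap.chromosomes[ci][1]
            cuts = np.sort(rng.uniform(0.0, length, size=k))
            chroms.append(_recombine(a, b, cuts, coins[ci], length))
    return Haplotype(chroms)


def cross(mother: Individual, father: Individual, rng: np.random.Generator,
          id: int = 0, generation: str = "") -> Individual:
    """Offspring from one gamete of each parent."""
    if mother.gmap is not father.gmap and mother.gmap != father.gmap:
        raise ValueError("parents are not on the same genetic map")
    return Individual(make_gamete(mother, rng), make_gamete(father, rng),
                      mother.gmap, id=id, generation=generation)


def self_cross(plant: Individual, rng: np.random.Generator,
               id: int = 0, generation: str = "") -> Individual:
    """Selfed offspring: two independent gametes from the same plant."""
    return Individual(make_gamete(plant, rng), make_gamete(plant, rng),
                      plant.gmap, id=id, generation=generation)
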