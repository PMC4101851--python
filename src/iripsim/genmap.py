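"""Genetic maps, loci, and marker grids.

Coordinates are continuous centimorgans (cM), 0-based at the start of each
chromosome.  The built-in rice map carries the 12 chromosome lengths from the
Harushima et al. high-density rice linkage map, which total 1526.8 cM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GeneticMap",
    "Locus",
    "MarkerGrid",
    "RICE_CHROMOSOME_LENGTHS",
    "build_rice_map",
    "marker_grid",
]

#: Rice chromosome lengths in cM (chromosomes 1..12).
RICE_CHROMOSOME_LENGTHS: dict[int, float] = {
    1: 181.8,
    2: 157.9,
    3: 166.4,
    4: 129.6,
    5: 122.3,
    6: 124.4,
    7: 118.6,
    8: 121.1,
    9: 93.5,
    10: 83.8,
    11: 117.9,
    12: 109.5,
}


@dataclass(frozen=True)
class GeneticMap:
    """An ordered set of chromosomes with genetic lengths in cM."""

    chromosomes: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("a genetic map needs at least one chromosome")
        for chrom_id, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {chrom_id} has non-positive length {length}")
        ids = [c for c, _ in self.chromosomes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate chromosome ids")

    @property
    def chrom_ids(self) -> tuple[int, ...]:
        return tuple(c for c, _ in self.chromosomes)

    @property
    def lengths(self) -> tuple[float, ...]:
        return tuple(l for _, l in self.chromosomes)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def total_length(self) -> float:
        return float(sum(self.lengths))

    def length_of(self, chrom_id: int) -> float:
        for c, l in self.chromosomes:
            if c == chrom_id:
                return l
        raise KeyError(f"chromosome {chrom_id} not on map")

    def index_of(self, chrom_id: int) -> int:
        for i, (c, _) in enumerate(self.chromosomes):
            if c == chrom_id:
                return i
        raise KeyError(f"chromosome {chrom_id} not on map")

    def subset(self, chrom_ids: Iterable[int]) -> "GeneticMap":
        """Map restricted to the given chromosomes (original order kept).

        Meiosis treats chromosomes independently, so simulations on a subset
        map reproduce the exact marginal distribution of those chromosomes.
        """
        wanted = set(chrom_ids)
        kept = tuple((c, l) for c, l in self.chromosomes if c in wanted)
        missing = wanted - {c for c, _ in kept}
        if missing:
            raise KeyError(f"chromosomes not on map: {sorted(missing)}")
        return GeneticMap(kept)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom_id\tlength_cM\n")
            for c, l in self.chromosomes:
                fh.write(f"{c}\t{l!r}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneticMap":
        chroms = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("chrom_id"):
                raise ValueError("expected header 'chrom_id\\tlength_cM'")
            for line in fh:
                if not line.strip():
                    continue
                c, l = line.split("\t")
                chroms.append((int(c), float(l)))
        return cls(tuple(chroms))


@dataclass(frozen=True)
class Locus:
    """A genetic position: chromosome id plus cM offset from the start."""

    chrom_id: int
    position: float

    def validate(self, gmap: GeneticMap) -> "Locus":
        length = gmap.length_of(self.chrom_id)
        if not 0.0 <= self.position <= length:
            raise ValueError(
                f"position {self.position} outside [0, {length}] on chromosome {self.chrom_id}"
            )
        return self


@dataclass(frozen=True)
class MarkerGrid:
    """Evenly spaced, fully informative markers along a genetic map.

    Markers sit at 0, spacing, 2*spacing, ... up to the last multiple of the
    spacing that does not exceed the chromosome length.
    """

    gmap: GeneticMap
    spacing: float
    chrom_ids: tuple[int, ...] = field(default=())  # per-marker chromosome
    positions: tuple[float, ...] = field(default=())

    @property
    def n_markers(self) -> int:
        return len(self.positions)

    def loci(self) -> list[Locus]:
        return [Locus(c, p) for c, p in zip(self.chrom_ids, self.positions)]

    def marker_indices(self, chrom_id: int, lo: float | None = None, hi: float | None = None) -> np.ndarray:
        """Indices of markers on one chromosome, optionally within [lo, hi] cM."""
        cid = np.asarray(self.chrom_ids)
        pos = np.asarray(self.positions)
        mask = cid == chrom_id
        if lo is not None:
            mask &= pos >= lo
        if hi is not None:
            mask &= pos <= hi
        return np.flatnonzero(mask)


def build_rice_map() -> GeneticMap:
    """The 12-chromosome rice map used throughout (1526.8 cM total)."""
    return GeneticMap(tuple(RICE_CHROMOSOME_LENGTHS.items()))


def marker_grid(gmap: GeneticMap, spacing: float) -> MarkerGrid:
    """Place markers every `spacing` cM on each chromosome, starting at 0."""
    if spacing <= 0:
        raise ValueError(f"marker spacing must be positive, got {spacing}")
    chrom_ids: list[int] = []
    positions: list[float] = []
    for chrom_id, length in gmap.chromosomes:
        # +1e-9 guards float representation of lengths like 83.8
        n = int(math.floor(length / spacing + 1e-9)) + 1
        chrom_ids.extend([chrom_id] * n)
        positions.extend(i * spacing for i in range(n))
    return MarkerGrid(gmap, spacing, tuple(chrom_ids), tuple(positions))
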