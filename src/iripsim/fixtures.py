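"""Deterministic miniature datasets for tests and demonstrations."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .breeding import BreedingDesign, simulate_irip
from .genmap import GeneticMap
from . import io as iio

__all__ = ["tiny_map", "make_fixture"]


def tiny_map() -> GeneticMap:
    """Two chromosomes of 60 and 40 cM (100 cM total)."""
    return GeneticMap(((1, 60.0), (2, 40.0)))


def toy_anova(seed: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """16 lines in 8 balanced genotype groups with Normal phenotypes."""
    rng = np.random.default_rng(seed)
    groups = np.repeat(np.arange(8), 2)
    y = rng.normal(size=16) + 0.5 * groups
    return groups, y


def tiny_pop(seed: int = 1):
    """A 16-line two-way inbred population on the tiny map."""
    rng = np.random.default_rng(seed)
    design = BreedingDesign(2, 16, 1, 16, 3)
    return simulate_irip(design, rng, gmap=tiny_map(), seed=seed)


def gev_sample(seed: int = 7, n: int = 10_000) -> np.ndarray:
    """Gumbel(0, 1) draws for extreme-value fitting tests."""
    rng = np.random.default_rng(seed)
    return rng.gumbel(0.0, 1.0, size=n)


def make_fixture(kind: str, seed: int, out: str | Path) -> None:
    if kind == "tiny-map":
        tiny_map().to_tsv(out)
    elif kind == "tiny-pop":
        iio.write_population(tiny_pop(seed), out)
    elif kind == "toy-anova":
        groups, y = toy_anova(seed)
        with open(out, "w") as fh:
            fh.write("line_id\tgroup\tvalue\n")
            for i, (g, v) in enumerate(zip(groups, y)):
                fh.write(f"{i}\t{g}\t{v!r}\n")
    elif kind == "gev-sample":
        np.savetxt(out, gev_sample(seed), header="value", comments="# ")
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
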