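"""Shared fixtures: small deterministic maps and populations."""

from __future__ import annotations

import numpy as np
import pytest

from iripsim.breeding import BreedingDesign, simulate_irip
from iripsim.fixtures import tiny_map
from iripsim.genmap import build_rice_map, marker_grid
from iripsim.meiosis import founder_individual


@pytest.fixture(scope="session")
def rice_map():
    return build_rice_map()


@pytest.fixture(scope="session")
def small_map():
    return tiny_map()  # 2 chromosomes, 60 + 40 cM


@pytest.fixture()
def rng():
    return np.random.default_rng(20240427)


@pytest.fixture(scope="session")
def small_inbred_pop(small_map):
    """8-way inbred population of 64 lines on the tiny map."""
    rng = np.random.default_rng(7)
    design = BreedingDesign(8, 32, 1, 64, 6)
    return simulate_irip(design, rng, gmap=small_map, seed=7)


@pytest.fixture(scope="session")
def small_grid(small_map):
    return marker_grid(small_map, 5.0)


@pytest.fixture(scope="session")
def founder_line(rice_map):
    return founder_individual(rice_map, 3, id=3)
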