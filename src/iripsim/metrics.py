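"""Genome-structure summaries: segments, genetic drift, heterozygosity.

Non-recombinant genome segments are maximal runs of a single founder label.
Genetic drift is measured as the percentage of 0.1-cM genome bins at which
fewer than the full complement of founder alleles survives in the
population (both haplotypes of every individual are inspected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meiosis import Population

__all__ = [
    "SegmentStats",
    "DriftReport",
    "segment_stats",
    "drift_fraction",
    "heterozygosity_fraction",
    "DRIFT_BIN_CM",
]

#: bin size (cM) on which drift is evaluated
DRIFT_BIN_CM = 0.1


@dataclass(frozen=True)
class SegmentStats:
    """Per-population summary of non-recombinant segment structure."""

    counts: np.ndarray          # segments per individual (one haplotype each)
    lengths: np.ndarray         # all segment lengths, pooled over individuals
    mean_count: float
    mean_length: float
    median_length: float


@dataclass(frozen=True)
class DriftReport:
    """Fraction of genome bins at which founder alleles have been lost."""

    fraction_lost: float        # percent of bins with < n_founders labels
    n_bins: int
    n_founders: int


def segment_stats(pop: Population) -> SegmentStats:
    """Count and measure single-founder segments, one haplotype per line.

    Inbred lines are essentially homozygous, so one haplotype represents the
    line; residual heterozygous stretches are reported separately by
    :func:`heterozygosity_fraction`.
    """
    counts = np.empty(len(pop), dtype=np.int64)
    all_lengths: list[np.ndarray] = []
    for i, ind in enumerate(pop.individuals):
        c = 0
        for seg in ind.hap1.chroms:
            c += len(seg.labels)
            all_lengths.append(seg.segment_lengths())
        counts[i] = c
    lengths = np.concatenate(all_lengths)
    return SegmentStats(
        counts=counts,
        lengths=lengths,
        mean_count=float(counts.mean()),
        mean_length=float(lengths.mean()),
        median_length=float(np.median(lengths)),
    )


def drift_fraction(pop: Population, n_founders: int) -> DriftReport:
    """Percent of 0.1-cM bins where fewer than `n_founders` labels remain."""
    lost = 0
    total = 0
    for ci, (_, length) in enumerate(pop.gmap.chromosomes):
        n_bins = int(round(length / DRIFT_BIN_CM))
        centers = (np.arange(n_bins) + 0.5) * DRIFT_BIN_CM
        present = np.zeros((n_founders + 1, n_bins), dtype=bool)
        for ind in pop.individuals:
            for hap in (ind.hap1, ind.hap2):
                labels = hap.chroms[ci].labels_at(centers)
                present[labels, np.arange(n_bins)] = True
        n_labels = present[1:].sum(axis=0)
        lost += int((n_labels < n_founders).sum())
        total += n_bins
    return DriftReport(fraction_lost=100.0 * lost / total, n_bins=total,
                       n_founders=n_founders)


def heterozygosity_fraction(pop: Population) -> float:
    """Mean genome fraction at which the two haplotypes carry different labels."""
    total_len = pop.gmap.total_length
    het = 0.0
    for ind in pop.individuals:
        for c1, c2 in zip(ind.hap1.chroms, ind.hap2.chroms):
            if c1 is c2:
                continue
            bounds = np.union1d(c1.bounds, c2.bounds)
            widths = np.diff(bounds, prepend=0.0)
            mids = bounds - widths / 2
            het += float(widths[c1.labels_at(mids) != c2.labels_at(mids)].sum())
    return het / (total_len * len(pop))
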