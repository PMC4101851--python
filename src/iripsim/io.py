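"""Delimited-text readers and writers for the simulation objects.

All tables are tab-separated UTF-8 with one header row; floats are written
at full precision (``repr``) so that files round-trip exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genmap import GeneticMap, Locus
from .meiosis import ChromSegments, Haplotype, Individual, Population
from .qtl import Qtl, QtlModel
from .scan import GenotypeMatrix, ScanResult
from .thresholds import ThresholdSet

__all__ = [
    "write_population", "read_population",
    "write_phenotypes", "read_phenotypes",
    "write_qtl_model", "read_qtl_model",
    "write_genotype_matrix",
    "write_scan", "write_thresholds",
]


def write_population(pop: Population, path: str | Path) -> None:
    """Segment-format haplotype table:
    individual, haplotype, chrom_id, start_cM, end_cM, founder_label."""
    with open(path, "w") as fh:
        fh.write("individual\thaplotype\tchrom_id\tstart_cM\tend_cM\tfounder\n")
        for ind in pop.individuals:
            for h, hap in ((1, ind.hap1), (2, ind.hap2)):
                for (chrom_id, _), seg in zip(pop.gmap.chromosomes, hap.chroms):
                    start = 0.0
                    for end, label in zip(seg.bounds, seg.labels):
                        fh.write(f"{ind.id}\t{h}\t{chrom_id}\t{start!r}\t{float(end)!r}\t{label}\n")
                        start = float(end)


def read_population(path: str | Path, gmap: GeneticMap,
                    stage: str = "") -> Population:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    individuals = []
    for ind_id, g in df.groupby("individual", sort=True):
        haps = []
        for h in (1, 2):
            chroms = []
            gh = g[g["haplotype"] == h]
            for chrom_id, _ in gmap.chromosomes:
                gc = gh[gh["chrom_id"] == chrom_id].sort_values("start_cM")
                chroms.append(ChromSegments(
                    gc["end_cM"].to_numpy(dtype=np.float64),
                    gc["founder"].to_numpy(dtype=np.int16)))
            haps.append(Haplotype(chroms))
        individuals.append(Individual(haps[0], haps[1], gmap, id=int(ind_id)))
    return Population(individuals, gmap, stage=stage)


def write_phenotypes(y: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("line_id\tvalue\n")
        for i, v in enumerate(np.asarray(y, dtype=float)):
            fh.write(f"{i}\t{float(v)!r}\n")


def read_phenotypes(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return df.sort_values("line_id")["value"].to_numpy(dtype=float)


def write_qtl_model(model: QtlModel, path: str | Path) -> None:
    n = len(model.qtls[0].effects) if model.qtls else 8
    cols = "\t".join(f"e_P{i}" for i in range(1, n + 1))
    with open(path, "w") as fh:
        fh.write(f"# noise_variance={model.noise_variance!r}\n")
        fh.write(f"chrom\tposition_cM\t{cols}\n")
        for q in model.qtls:
            eff = "\t".join(repr(float(e)) for e in q.effects)
            fh.write(f"{q.locus.chrom_id}\t{float(q.locus.position)!r}\t{eff}\n")


def read_qtl_model(path: str | Path) -> QtlModel:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# noise_variance="):
            raise ValueError("missing noise_variance header")
        noise = float(first.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    qtls = []
    effect_cols = [c for c in df.columns if c.startswith("e_P")]
    for _, row in df.iterrows():
        qtls.append(Qtl(Locus(int(row["chrom"]), float(row["position_cM"])),
                        tuple(float(row[c]) for c in effect_cols)))
    return QtlModel(tuple(qtls), noise_variance=noise)


def write_genotype_matrix(gm: GenotypeMatrix, path: str | Path) -> None:
    """line_id followed by per-marker 'i|j' founder-label pairs."""
    cid = gm.grid.chrom_ids
    pos = gm.grid.positions
    header = "line_id\t" + "\t".join(f"c{c}_{p:g}" for c, p in zip(cid, pos))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for i in range(gm.n_lines):
            cells = "\t".join(f"{a}|{b}" for a, b in zip(gm.labels1[i], gm.labels2[i]))
            fh.write(f"{i}\t{cells}\n")


def write_scan(scan: ScanResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tposition_cM\tneglog10P\n")
        for c, p, v in zip(scan.grid.chrom_ids, scan.grid.positions, scan.neglog10p):
            fh.write(f"{c}\t{float(p)!r}\t{float(v)!r}\n")


def write_thresholds(ts: ThresholdSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("statistic\tthreshold\n")
        fh.write(f"T1\t{float(ts.t1)!r}\n")
        if ts.t2 is not None:
            fh.write(f"T2\t{float(ts.t2)!r}\n")
        if ts.t2vs1 is not None:
            fh.write(f"T2vs1\t{float(ts.t2vs1)!r}\n")


def read_thresholds(path: str | Path) -> ThresholdSet:
    df = pd.read_csv(path, sep="\t").set_index("statistic")["threshold"]
    return ThresholdSet(t1=float(df["T1"]),
                        t2=float(df["T2"]) if "T2" in df.index else None,
                        t2vs1=float(df["T2vs1"]) if "T2vs1" in df.index else None)
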