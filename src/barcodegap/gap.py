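"""Barcoding-gap analysis: intra/inter distance partitions and diagnostics.

A locus is a usable barcode when the distribution of within-species
(intraspecific) distances is separated from the distribution of
between-species (interspecific) distances — the "barcoding gap".  This module
partitions a distance matrix by species-label equality, summarises the two
distributions (overall means, per-species theta = mean intraspecific distance,
per-species coalescent depth = maximum intraspecific distance), locates the
extremes (largest intraspecific, smallest interspecific pair), and bins both
sets into plotting-ready histograms.

Undefined distances never enter the partition; conservation laws
(|intra| + |inter| == defined pair count; histogram counts sum to partition
sizes) hold by construction and are property-tested.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .distance import DistanceMatrix

__all__ = [
    "IntraPair",
    "InterPair",
    "DistancePartition",
    "GapReport",
    "HistogramTable",
    "partition",
    "gap_report",
    "histogram",
]

logger = logging.getLogger(__name__)


class IntraPair(NamedTuple):
    species: str
    ids: tuple[str, str]
    distance: float


class InterPair(NamedTuple):
    species_pair: tuple[str, str]  # sorted
    ids: tuple[str, str]
    distance: float


@dataclass
class DistancePartition:
    """Defined pairwise distances split into intra- and inter-specific sets."""

    intra: list[IntraPair]
    inter: list[InterPair]
    species_counts: dict[str, int]  # individuals per species in the matrix
    n_undefined: int = 0

    @property
    def intra_distances(self) -> np.ndarray:
        return np.array([p.distance for p in self.intra], dtype=float)

    @property
    def inter_distances(self) -> np.ndarray:
        return np.array([p.distance for p in self.inter], dtype=float)

    @property
    def singletons(self) -> list[str]:
        return sorted(s for s, c in self.species_counts.items() if c == 1)


def partition(dm: DistanceMatrix) -> DistancePartition:
    """Assign every defined off-diagonal pair to intra or inter by species."""
    intra: list[IntraPair] = []
    inter: list[InterPair] = []
    n_undef = 0
    species_with_intra: dict[str, bool] = defaultdict(bool)
    for i in range(dm.n - 1):
        for j in range(i + 1, dm.n):
            d = dm.values[i, j]
            si, sj = dm.species[i], dm.species[j]
            if math.isnan(d):
                n_undef += 1
                continue
            pair_ids = (dm.ids[i], dm.ids[j])
            if si == sj:
                intra.append(IntraPair(si, pair_ids, float(d)))
                species_with_intra[si] = True
            else:
                sp = tuple(sorted((si, sj)))
                inter.append(InterPair(sp, pair_ids, float(d)))
    counts = Counter(dm.species)
    for sp, c in counts.items():
        if c >= 2 and not species_with_intra[sp]:
            logger.warning(
                "species %r: all intraspecific distances undefined", sp
            )
    return DistancePartition(
        intra=intra, inter=inter, species_counts=dict(counts), n_undefined=n_undef
    )


@dataclass
class GapReport:
    """Barcoding-gap diagnostics for one region.

    Distances are stored raw (substitutions/site); formatters may render
    them as percentages.  Intra-derived fields are ``None`` when the matrix
    contains no intraspecific pair (e.g. all species are singletons).
    """

    mean_intra_all: float | None
    mean_inter: float | None
    theta_by_species: dict[str, float]
    mean_theta: float | None
    coalescent_depth_by_species: dict[str, float]
    mean_coalescent_depth: float | None
    max_intra: float | None
    max_intra_species: str | None
    min_inter: float | None
    min_inter_species_pair: tuple[str, str] | None
    gap_present: bool | None
    per_species_gap: dict[str, float]
    singletons: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["min_inter_species_pair"] = (
            list(self.min_inter_species_pair) if self.min_inter_species_pair else None
        )
        return d


def gap_report(p: DistancePartition) -> GapReport:
    """Summarise a distance partition into barcoding-gap diagnostics.

    Species with fewer than two individuals are excluded from theta and
    coalescent depth and listed as singletons.  ``per_species_gap[s]`` is the
    smallest distance from any individual of *s* to a heterospecific
    individual minus the largest intraspecific distance within *s* (positive
    = locally gapped).
    """
    by_species: dict[str, list[float]] = defaultdict(list)
    for pr in p.intra:
        by_species[pr.species].append(pr.distance)
    theta = {s: float(np.mean(v)) for s, v in sorted(by_species.items())}
    coal = {s: float(np.max(v)) for s, v in sorted(by_species.items())}

    intra_d = p.intra_distances
    inter_d = p.inter_distances

    if len(intra_d):
        imax = int(np.argmax(intra_d))
        max_intra = float(intra_d[imax])
        max_intra_species = p.intra[imax].species
    else:
        max_intra = max_intra_species = None

    if len(inter_d):
        jmin = int(np.argmin(inter_d))
        min_inter = float(inter_d[jmin])
        min_inter_pair = p.inter[jmin].species_pair
    else:
        min_inter = min_inter_pair = None

    nearest_hetero: dict[str, float] = {}
    for pr in p.inter:
        for s in pr.species_pair:
            if s not in nearest_hetero or pr.distance < nearest_hetero[s]:
                nearest_hetero[s] = pr.distance
    per_species_gap = {
        s: nearest_hetero[s] - coal[s]
        for s in coal
        if s in nearest_hetero
    }

    return GapReport(
        mean_intra_all=float(np.mean(intra_d)) if len(intra_d) else None,
        mean_inter=float(np.mean(inter_d)) if len(inter_d) else None,
        theta_by_species=theta,
        mean_theta=float(np.mean(list(theta.values()))) if theta else None,
        coalescent_depth_by_species=coal,
        mean_coalescent_depth=float(np.mean(list(coal.values()))) if coal else None,
        max_intra=max_intra,
        max_intra_species=max_intra_species,
        min_inter=min_inter,
        min_inter_species_pair=min_inter_pair,
        gap_present=(
            min_inter > max_intra
            if (min_inter is not None and max_intra is not None)
            else None
        ),
        per_species_gap=per_species_gap,
        singletons=p.singletons,
    )


@dataclass
class HistogramTable:
    """Frequency distribution of intra/inter distances in fixed-width bins.

    Bins are left-closed right-open intervals ``[k*w, (k+1)*w)`` starting at
    zero; a value exactly on an edge falls in the upper bin.
    """

    bin_width: float
    bin_edges: np.ndarray  # length n_bins + 1
    counts_intra: np.ndarray
    counts_inter: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count_intra": self.counts_intra,
                "count_inter": self.counts_inter,
            }
        )


def histogram(p: DistancePartition, bin_width: float) -> HistogramTable:
    """Bin intra and inter distances separately with a shared bin grid."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    intra_d = p.intra_distances
    inter_d = p.inter_distances
    top = max(intra_d.max(initial=0.0), inter_d.max(initial=0.0))
    n_bins = int(np.floor(top / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width

    def _bin(values: np.ndarray) -> np.ndarray:
        counts = np.zeros(n_bins, dtype=int)
        if len(values):
            idx = np.floor(values / bin_width).astype(int)
            np.add.at(counts, idx, 1)
        return counts

    return HistogramTable(
        bin_width=bin_width,
        bin_edges=edges,
        counts_intra=_bin(intra_d),
        counts_inter=_bin(inter_d),
    )
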