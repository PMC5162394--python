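"""Similarity-based species identification (Best Match / Best Close Match /
All Species Barcodes).

These are the three leave-one-out identification criteria popularised by the
TaxonDNA/SpeciesIdentifier program.  Every sequence is treated in turn as a
query against all other sequences of the same dataset:

* **Best Match (BM)** — the query takes the species of its nearest non-self
  neighbour.  If the nearest neighbours (ties within a tolerance) span both
  conspecific and allospecific sequences the verdict is *ambiguous*; all
  conspecific = *correct*; all allospecific = *incorrect*.
* **Best Close Match (BCM)** — BM restricted to neighbours within a distance
  threshold, by default the 95th percentile (nearest-rank) of all
  intraspecific distances; a query with no neighbour inside the threshold is
  *no match*.
* **All Species Barcodes (ASB)** — stricter: *correct* only when every
  conspecific sequence is closer to the query than any allospecific sequence
  (max conspecific distance < min allospecific distance); equality within
  tolerance is *ambiguous*; otherwise *incorrect*.

Singleton queries (no other representative of their species) cannot be
identified correctly: they are *incorrect* under BM/ASB and *incorrect* or
*no match* under BCM, and are counted in the denominator (flagged in the
summary).  Distance ties are compared with an absolute tolerance because the
distances are floating-point computations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .distance import DistanceMatrix
from .gap import DistancePartition

__all__ = [
    "IdentificationResult",
    "IdentificationSummary",
    "bcm_threshold",
    "best_match",
    "best_close_match",
    "all_species_barcodes",
    "evaluate",
    "summary_table",
]

logger = logging.getLogger(__name__)

Method = Literal["BM", "BCM", "ASB"]
Verdict = Literal["correct", "ambiguous", "incorrect", "no_match"]

#: Absolute tolerance for treating two computed distances as tied.
TIE_TOLERANCE = 1e-10


@dataclass(frozen=True)
class IdentificationResult:
    query: str
    method: Method
    verdict: Verdict
    best_distance: float | None
    matched_species: frozenset[str]
    is_singleton: bool


@dataclass(frozen=True)
class IdentificationSummary:
    """Percentage table for one method over all evaluable queries."""

    method: Method
    n_queries: int
    n_singletons: int
    n_excluded: int  # queries with no defined distance to any other record
    pct_correct: float
    pct_ambiguous: float
    pct_incorrect: float
    pct_no_match: float

    def as_row(self) -> dict:
        return {
            "method": self.method,
            "n_queries": self.n_queries,
            "n_singletons": self.n_singletons,
            "n_excluded": self.n_excluded,
            "correct_pct": round(self.pct_correct, 2),
            "ambiguous_pct": round(self.pct_ambiguous, 2),
            "incorrect_pct": round(self.pct_incorrect, 2),
            "no_match_pct": round(self.pct_no_match, 2),
        }


def bcm_threshold(p: DistancePartition, percentile: float = 0.95) -> float:
    """Nearest-rank percentile of the sorted intraspecific distances.

    With n intraspecific distances the nearest-rank p-th percentile is the
    ``ceil(p * n)``-th smallest value; ``percentile=1.0`` gives the maximum.
    """
    if not 0 < percentile <= 1:
        raise ValueError("percentile must be in (0, 1]")
    intra = np.sort(p.intra_distances)
    if len(intra) == 0:
        raise ValueError(
            "no intraspecific distances: supply an explicit BCM threshold"
        )
    rank = max(1, math.ceil(percentile * len(intra)))
    return float(intra[rank - 1])


def _query_row(dm: DistanceMatrix, qi: int) -> tuple[np.ndarray, np.ndarray]:
    """Distances from query to all records and the defined-non-self mask."""
    d = dm.values[qi].astype(float)
    mask = ~np.isnan(d)
    mask[qi] = False
    return d, mask


def _is_singleton(dm: DistanceMatrix, qi: int) -> bool:
    sp = dm.species[qi]
    return sum(1 for j, s in enumerate(dm.species) if j != qi and s == sp) == 0


def _bm_verdict(
    dm: DistanceMatrix,
    qi: int,
    candidate_mask: np.ndarray,
    d: np.ndarray,
    method: Method,
    tol: float,
) -> IdentificationResult:
    """Shared BM/BCM nearest-neighbour logic over a candidate set."""
    singleton = _is_singleton(dm, qi)
    if not candidate_mask.any():
        # BCM with empty candidate set -> no_match; BM callers guarantee
        # a non-empty set.
        return IdentificationResult(
            dm.ids[qi], method, "no_match", None, frozenset(), singleton
        )
    best = float(d[candidate_mask].min())
    at_best = candidate_mask & (d <= best + tol)
    species = frozenset(dm.species[j] for j in np.flatnonzero(at_best))
    qsp = dm.species[qi]
    if species == {qsp}:
        verdict: Verdict = "correct"
    elif qsp in species:
        verdict = "ambiguous"
    else:
        verdict = "incorrect"
    return IdentificationResult(dm.ids[qi], method, verdict, best, species, singleton)


def best_match(
    query: str | int, dm: DistanceMatrix, tol: float = TIE_TOLERANCE
) -> IdentificationResult | None:
    """BM verdict for one query; ``None`` when the query has no defined
    distance to any other record (excluded from summaries)."""
    qi = dm.index_of(query) if isinstance(query, str) else query
    d, mask = _query_row(dm, qi)
    if not mask.any():
        logger.warning("query %r: all distances undefined; excluded", dm.ids[qi])
        return None
    return _bm_verdict(dm, qi, mask, d, "BM", tol)


def best_close_match(
    query: str | int,
    dm: DistanceMatrix,
    threshold: float,
    tol: float = TIE_TOLERANCE,
) -> IdentificationResult | None:
    """BCM verdict: BM restricted to candidates within *threshold*."""
    qi = dm.index_of(query) if isinstance(query, str) else query
    d, mask = _query_row(dm, qi)
    if not mask.any():
        logger.warning("query %r: all distances undefined; excluded", dm.ids[qi])
        return None
    close = mask & (d <= threshold + tol)
    return _bm_verdict(dm, qi, close, d, "BCM", tol)


def all_species_barcodes(
    query: str | int, dm: DistanceMatrix, tol: float = TIE_TOLERANCE
) -> IdentificationResult | None:
    """ASB verdict: correct iff every conspecific is nearer than every
    allospecific sequence."""
    qi = dm.index_of(query) if isinstance(query, str) else query
    d, mask = _query_row(dm, qi)
    if not mask.any():
        logger.warning("query %r: all distances undefined; excluded", dm.ids[qi])
        return None
    qsp = dm.species[qi]
    species_arr = np.array(dm.species)
    cons = mask & (species_arr == qsp)
    allo = mask & (species_arr != qsp)
    singleton = _is_singleton(dm, qi)
    if not allo.any():
        # Single-species dataset: trivially correct when conspecifics exist.
        dc = float(d[cons].max()) if cons.any() else None
        return IdentificationResult(
            dm.ids[qi], "ASB", "correct", dc, frozenset({qsp}), singleton
        )
    da = float(d[allo].min())
    nearest_allo = frozenset(
        species_arr[j] for j in np.flatnonzero(allo & (d <= da + tol))
    )
    if not cons.any():
        # Singleton (or conspecific distances all undefined): cannot be correct.
        return IdentificationResult(
            dm.ids[qi], "ASB", "incorrect", da, nearest_allo, singleton
        )
    dc = float(d[cons].max())
    if dc < da - tol:
        return IdentificationResult(
            dm.ids[qi], "ASB", "correct", dc, frozenset({qsp}), singleton
        )
    if dc <= da + tol:
        return IdentificationResult(
            dm.ids[qi], "ASB", "ambiguous", da, nearest_allo | {qsp}, singleton
        )
    return IdentificationResult(
        dm.ids[qi], "ASB", "incorrect", da, nearest_allo, singleton
    )


def evaluate(
    dm: DistanceMatrix,
    method: Method,
    threshold: float | None = None,
    tol: float = TIE_TOLERANCE,
) -> tuple[IdentificationSummary, list[IdentificationResult]]:
    """Apply one criterion to every record as query and tabulate percentages.

    *threshold* is required for BCM.  Queries whose distances are all
    undefined are excluded from the denominator and counted in
    ``n_excluded``.
    """
    if method == "BCM" and threshold is None:
        raise ValueError("BCM requires a threshold (see bcm_threshold)")
    results: list[IdentificationResult] = []
    n_excluded = 0
    for qi in range(dm.n):
        if method == "BM":
            r = best_match(qi, dm, tol)
        elif method == "BCM":
            r = best_close_match(qi, dm, threshold, tol)  # type: ignore[arg-type]
        elif method == "ASB":
            r = all_species_barcodes(qi, dm, tol)
        else:
            raise ValueError(f"unknown method {method!r}")
        if r is None:
            n_excluded += 1
        else:
            results.append(r)
    n = len(results)
    if n == 0:
        raise ValueError("no evaluable queries (all distances undefined)")
    counts = {v: sum(1 for r in results if r.verdict == v)
              for v in ("correct", "ambiguous", "incorrect", "no_match")}
    summary = IdentificationSummary(
        method=method,
        n_queries=n,
        n_singletons=sum(1 for r in results if r.is_singleton),
        n_excluded=n_excluded,
        pct_correct=100.0 * counts["correct"] / n,
        pct_ambiguous=100.0 * counts["ambiguous"] / n,
        pct_incorrect=100.0 * counts["incorrect"] / n,
        pct_no_match=100.0 * counts["no_match"] / n,
    )
    return summary, results


def summary_table(summaries: list[IdentificationSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_row() for s in summaries])


def results_table(results: list[IdentificationResult], species: dict[str, str]) -> pd.DataFrame:
    """Per-query results as a tidy table (one row per query x method)."""
    return pd.DataFrame(
        {
            "query": r.query,
            "species": species.get(r.query, ""),
            "method": r.method,
            "verdict": r.verdict,
            "best_distance": r.best_distance,
            "matched_species": ";".join(sorted(r.matched_species)),
            "is_singleton": r.is_singleton,
        }
        for r in results
    )
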