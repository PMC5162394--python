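"""Alignment summary statistics for barcode-candidate comparison.

The quantities computed here are the standard descriptors used to compare
candidate barcode loci: G+C content, the fraction of columns identical across
all sequences, mean pairwise identity, and the counts of variable and
parsimony-informative sites.

Conventions (each chosen to match common barcoding practice; the variability
convention is switchable):

* G+C content is taken over unambiguous bases only (gaps, N and IUPAC
  ambiguity codes excluded from numerator and denominator).
* "Identical sites" treats the gap as an ordinary character: a column is
  identical iff every sequence shows the same character.
* Pairwise identity counts gap-vs-residue as a (non-identical) comparison and
  drops gap-vs-gap comparisons entirely.
* Variability and parsimony-informativeness consider unambiguous bases only
  (gaps treated as missing data).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .alignment import AlignedMatrix

__all__ = [
    "AlignmentSummary",
    "gc_content",
    "identical_sites_fraction",
    "pairwise_identity",
    "variable_and_informative_sites",
    "summarize",
    "summary_table",
]

_BASES = np.array([b"A", b"C", b"G", b"T"])
_GAP = b"-"


@dataclass(frozen=True)
class AlignmentSummary:
    """Summary statistics of one region's aligned matrix."""

    region: str
    length: int
    n_records: int
    n_species: int
    gc_fraction: float
    identical_sites_fraction: float
    pairwise_identity: float
    n_variable: int
    n_parsimony_informative: int

    @property
    def variable_fraction(self) -> float:
        return self.n_variable / self.length

    @property
    def parsimony_fraction(self) -> float:
        return self.n_parsimony_informative / self.length

    def __post_init__(self) -> None:
        assert self.n_parsimony_informative <= self.n_variable <= self.length


def gc_content(m: AlignedMatrix) -> float:
    """(#G + #C) / (#A + #C + #G + #T) over all residues of all records.

    Gaps and ambiguity codes are excluded from numerator and denominator.
    """
    arr = m.to_array()
    unambiguous = np.isin(arr, _BASES)
    total = int(unambiguous.sum())
    if total == 0:
        raise ValueError("matrix has no unambiguous A/C/G/T bases")
    gc = int(np.isin(arr, np.array([b"G", b"C"])).sum())
    return gc / total


def identical_sites_fraction(m: AlignedMatrix) -> float:
    """Fraction of columns where every record shows the same character.

    Gaps count as a character: an all-gap column is identical.
    """
    arr = m.to_array()
    identical = (arr == arr[0]).all(axis=0)
    return float(identical.sum()) / m.length


def pairwise_identity(m: AlignedMatrix) -> float:
    """Mean pairwise residue identity over all unordered record pairs.

    Per pair, gap-vs-gap columns are dropped; gap-vs-residue counts as a
    non-identical comparison.  Pairs with zero comparable columns contribute
    nothing; if every pair is empty, raises ``ValueError``.
    """
    arr = m.to_array()
    n = m.n_records
    is_gap = arr == _GAP
    n_identical = 0
    n_compared = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            comparable = ~(is_gap[i] & is_gap[j])
            n_compared += int(comparable.sum())
            n_identical += int((comparable & (arr[i] == arr[j])).sum())
    if n_compared == 0:
        raise ValueError("no comparable residue pairs (all pairs gap-vs-gap)")
    return n_identical / n_compared


def variable_and_informative_sites(m: AlignedMatrix) -> tuple[int, int]:
    """Counts of variable and parsimony-informative columns.

    Only unambiguous bases are considered (gaps/N/IUPAC treated as missing).
    A column is variable iff >=2 distinct bases are present; it is
    parsimony-informative iff >=2 distinct bases are each present in >=2
    records.
    """
    arr = m.to_array()
    counts = np.stack([(arr == b).sum(axis=0) for b in _BASES])  # (4, L)
    n_states = (counts > 0).sum(axis=0)
    n_variable = int((n_states >= 2).sum())
    n_informative = int(((counts >= 2).sum(axis=0) >= 2).sum())
    return n_variable, n_informative


def summarize(m: AlignedMatrix) -> AlignmentSummary:
    """Compute the full :class:`AlignmentSummary` for one matrix."""
    n_var, n_pi = variable_and_informative_sites(m)
    return AlignmentSummary(
        region=m.region,
        length=m.length,
        n_records=m.n_records,
        n_species=len(m.species_set),
        gc_fraction=gc_content(m),
        identical_sites_fraction=identical_sites_fraction(m),
        pairwise_identity=pairwise_identity(m),
        n_variable=n_var,
        n_parsimony_informative=n_pi,
    )


def summary_table(summaries: list[AlignmentSummary]) -> pd.DataFrame:
    """One row per region with fractions also rendered as percentages."""
    rows = []
    for s in summaries:
        d = asdict(s)
        d["gc_pct"] = round(100 * s.gc_fraction, 2)
        d["identical_sites_pct"] = round(100 * s.identical_sites_fraction, 2)
        d["pairwise_identity_pct"] = round(100 * s.pairwise_identity, 2)
        d["variable_sites_pct"] = round(100 * s.variable_fraction, 2)
        d["parsimony_sites_pct"] = round(100 * s.parsimony_fraction, 2)
        rows.append(d)
    return pd.DataFrame(rows)
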