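"""Kimura 2-parameter pairwise distances with pairwise deletion.

The K2P model corrects observed divergence for multiple hits while
distinguishing transitions (A<->G, C<->T) from transversions:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

where P and Q are the observed proportions of transitional and transversional
differences among the sites compared.  "Pairwise deletion" means each pair of
sequences is compared only at columns where *both* show an unambiguous base;
gaps, N and IUPAC ambiguity codes are treated as missing data.

A pair can be *undefined*: when no columns are comparable, or when divergence
saturates the logarithms (1-2P-Q <= 0 or 1-2Q <= 0).  Undefined distances are
flagged (NaN in the matrix, with an explicit mask) and excluded from all
downstream summaries — never silently zeroed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .alignment import AlignedMatrix

__all__ = [
    "SiteClassCounts",
    "DistanceMatrix",
    "count_site_classes",
    "k2p",
    "k2p_from_counts",
    "p_distance",
    "distance_matrix",
]

logger = logging.getLogger(__name__)

# Byte codes: A=0, C=1, G=2, T=3; everything else (gap/N/IUPAC) = -1 (missing).
_CODE_TABLE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_TABLE[_b] = _i
_CODE_TABLE[ord("a")] = 0
_CODE_TABLE[ord("c")] = 1
_CODE_TABLE[ord("g")] = 2
_CODE_TABLE[ord("t")] = 3

#: purine flags for codes 0..3 (A, C, G, T)
_IS_PURINE = np.array([True, False, True, False])


def encode(residues: str | np.ndarray) -> np.ndarray:
    """Map residues to int8 codes A=0 C=1 G=2 T=3, missing=-1."""
    if isinstance(residues, str):
        raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    else:
        raw = residues.view(np.uint8) if residues.dtype == "S1" else residues
        raw = raw.reshape(residues.shape)
    return _CODE_TABLE[raw]


class SiteClassCounts(NamedTuple):
    """Comparable-site and difference-class counts for one sequence pair."""

    n_compared: int
    n_transitions: int
    n_transversions: int


def count_site_classes(a: str, b: str) -> SiteClassCounts:
    """Classify aligned columns of a pair after pairwise deletion.

    A column is compared iff both characters are unambiguous bases; each
    difference is a transition (A<->G, C<->T) or a transversion.
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal (aligned) lengths")
    ca, cb = encode(a), encode(b)
    both = (ca >= 0) & (cb >= 0)
    diff = both & (ca != cb)
    ts = diff & (_IS_PURINE[np.clip(ca, 0, 3)] == _IS_PURINE[np.clip(cb, 0, 3)])
    n_ts = int(ts.sum())
    return SiteClassCounts(int(both.sum()), n_ts, int(diff.sum()) - n_ts)


def k2p_from_counts(c: SiteClassCounts) -> float:
    """K2P distance from site-class counts; NaN when undefined."""
    if c.n_compared == 0:
        return math.nan
    P = c.n_transitions / c.n_compared
    Q = c.n_transversions / c.n_compared
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p(a: str, b: str) -> float:
    """Pairwise K2P distance (substitutions/site); NaN when undefined.

    Undefined means no comparable columns, or saturation (a log argument
    <= 0).  Callers detect it with ``math.isnan``.
    """
    return k2p_from_counts(count_site_classes(a, b))


def p_distance(a: str, b: str) -> float:
    """Observed proportion of differing sites after pairwise deletion."""
    c = count_site_classes(a, b)
    if c.n_compared == 0:
        return math.nan
    return (c.n_transitions + c.n_transversions) / c.n_compared


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with an undefined-entry mask.

    ``values[i, j]`` is NaN exactly where the pair's distance is undefined;
    the diagonal is zero and always defined.
    """

    ids: list[str]
    species: list[str]
    values: np.ndarray  # (n, n) float64, NaN = undefined

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if len(self.species) != n:
            raise ValueError("species labels do not match ids")
        if not np.all(np.diag(self.values) == 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        defined = ~np.isnan(self.values)
        if not np.array_equal(defined, defined.T) or not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values).T
        ):
            raise ValueError("distance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(self.n, k=1)
        return int(np.isnan(self.values[iu]).sum())

    def index_of(self, record_id: str) -> int:
        try:
            return self.ids.index(record_id)
        except ValueError:
            raise KeyError(f"record id {record_id!r} not in distance matrix") from None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        """Square TSV with NaN rendered as 'NA' for undefined pairs."""
        self.to_dataframe().to_csv(path, sep="\t", na_rep="NA")

    def write_phylip(self, path: str | Path) -> None:
        """Lower-triangular PHYLIP distance format (undefined -> -1.0)."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, rid in enumerate(self.ids):
                vals = " ".join(
                    f"{(-1.0 if math.isnan(v) else v):.6f}" for v in self.values[i, :i]
                )
                fh.write(f"{rid[:50]:<50s} {vals}".rstrip() + "\n")


def _pairwise_k2p_from_codes(codes: np.ndarray) -> np.ndarray:
    """All-pairs K2P distances from an (n, L) code array (NaN = undefined)."""
    valid = codes >= 0
    pur = _IS_PURINE[np.clip(codes, 0, 3)] & valid
    both = valid[:, None, :] & valid[None, :, :]
    diff = both & (codes[:, None, :] != codes[None, :, :])
    same_family = pur[:, None, :] == pur[None, :, :]
    n_comp = both.sum(axis=-1).astype(float)
    n_ts = (diff & same_family).sum(axis=-1).astype(float)
    n_tv = diff.sum(axis=-1) - n_ts
    with np.errstate(divide="ignore", invalid="ignore"):
        P = n_ts / n_comp
        Q = n_tv / n_comp
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    d[(n_comp == 0) | (w1 <= 0) | (w2 <= 0)] = np.nan
    np.fill_diagonal(d, 0.0)
    return d


def distance_matrix(
    m: AlignedMatrix, *, max_undefined_frac: float = 0.5
) -> DistanceMatrix:
    """Compute all-pairs K2P distances for a matrix.

    Undefined pairs are logged; the computation fails only when more than
    *max_undefined_frac* of the pairs are undefined.
    """
    codes = encode(m.to_array())
    d = _pairwise_k2p_from_codes(codes)
    dm = DistanceMatrix(ids=m.ids, species=m.species, values=d)
    n_pairs = m.n_records * (m.n_records - 1) // 2
    if dm.n_undefined_pairs:
        logger.warning(
            "%d of %d pairwise K2P distances undefined (no comparable sites "
            "or saturated divergence); they are excluded downstream",
            dm.n_undefined_pairs,
            n_pairs,
        )
    if n_pairs and dm.n_undefined_pairs / n_pairs > max_undefined_frac:
        raise ValueError(
            f"{dm.n_undefined_pairs}/{n_pairs} pairwise distances undefined "
            f"(> {max_undefined_frac:.0%}); check the alignment"
        )
    return dm
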