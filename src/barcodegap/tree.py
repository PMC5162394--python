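"""Tree-based evaluation: NJ construction, bootstrap support, monophyly.

The tree stage asks whether each species' individuals form an exclusive
group on a phylogeny built from (or supplied alongside) the barcode data:

* :func:`neighbor_joining` builds the Saitou–Nei NJ tree from a K2P distance
  matrix (negative branch lengths clamped to zero, deficit logged).
* :func:`bootstrap` resamples alignment columns with replacement, rebuilds
  the distance matrix and NJ tree per pseudo-replicate, and annotates each
  internal edge of the original tree with the percentage of replicates that
  contain the same bipartition.
* :func:`monophyly` scores species monophyly on any tree (NJ output or an
  externally inferred Newick, e.g. from ML/Bayesian runs) and reports
  per-individual and per-species discrimination rates.

Trees are :class:`skbio.TreeNode` objects; Newick round-trips preserve
topology, branch lengths and support values (written as internal-node
labels).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj

from .alignment import AlignedMatrix
from .distance import DistanceMatrix, _pairwise_k2p_from_codes, encode

__all__ = [
    "neighbor_joining",
    "bootstrap",
    "BootstrapInfo",
    "read_newick",
    "write_newick",
    "bipartitions",
    "monophyly",
    "MonophylyReport",
]

logger = logging.getLogger(__name__)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor-joining tree from a fully defined distance matrix.

    Raises ``ValueError`` when fewer than 3 records are present or any
    pairwise distance is undefined (impute or drop records first).  Negative
    branch lengths produced by the agglomeration are clamped to zero and the
    total deficit logged.
    """
    if dm.n < 3:
        raise ValueError("neighbor joining needs at least 3 records")
    if dm.n_undefined_pairs:
        iu = np.triu_indices(dm.n, k=1)
        bad = [
            (dm.ids[i], dm.ids[j])
            for i, j in zip(*iu)
            if math.isnan(dm.values[i, j])
        ][:5]
        raise ValueError(
            f"{dm.n_undefined_pairs} undefined pairwise distance(s), e.g. "
            f"{bad}; remove records or impute before tree building"
        )
    # symmetrise away float-epsilon asymmetry before skbio's strict check
    values = (dm.values + dm.values.T) / 2.0
    tree = _skbio_nj(_SkbioDM(values, ids=dm.ids))
    deficit = 0.0
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            deficit += -node.length
            node.length = 0.0
    if deficit > 0:
        logger.info("clamped negative NJ branch lengths (total deficit %.6f)", deficit)
    return tree


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (unrooted) tree.

    Each bipartition is normalised as the tip-name side *not* containing the
    lexicographically smallest tip, so rootings do not matter.  Only splits
    with at least two tips on each side are returned.
    """
    tips = frozenset(t.name for t in tree.tips())
    ref = min(tips)
    out: set[frozenset[str]] = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = tips - side
        if 2 <= len(side) <= len(tips) - 2:
            out.add(side)
    return out


@dataclass
class BootstrapInfo:
    n_replicates: int
    n_skipped: int  # replicates with undefined distances

    @property
    def n_valid(self) -> int:
        return self.n_replicates - self.n_skipped


def bootstrap(
    m: AlignedMatrix,
    n_reps: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[TreeNode, BootstrapInfo]:
    """NJ tree with bootstrap support on internal edges.

    Columns are resampled with replacement *n_reps* times; each replicate's
    K2P matrix and NJ tree are rebuilt and the support of each internal edge
    of the original tree is the percentage of valid replicates containing the
    same bipartition (stored on ``node.support``).  Replicates yielding any
    undefined distance are skipped and counted; a warning is emitted when
    more than 20% are skipped.  With ``n_reps=0`` the original tree is
    returned without supports.
    """
    from .distance import distance_matrix  # local import to avoid cycle noise

    dm = distance_matrix(m)
    tree = neighbor_joining(dm)
    if n_reps == 0:
        return tree, BootstrapInfo(0, 0)
    if rng is None:
        if seed is None:
            raise ValueError("bootstrap requires a seed (or an explicit rng)")
        rng = np.random.default_rng(seed)

    codes = encode(m.to_array())
    L = m.length
    # node lookup by normalised bipartition of the original tree
    tips = frozenset(m.ids)
    ref = min(tips)
    node_by_split: dict[frozenset[str], TreeNode] = {}
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        key = tips - side if ref in side else side
        if 2 <= len(key) <= len(tips) - 2:
            node_by_split[key] = node

    counts: dict[frozenset[str], int] = {k: 0 for k in node_by_split}
    n_skipped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        d = _pairwise_k2p_from_codes(codes[:, cols])
        if np.isnan(d[np.triu_indices(dm.n, k=1)]).any():
            n_skipped += 1
            continue
        rep_tree = _skbio_nj(_SkbioDM(d, ids=dm.ids))
        for split in bipartitions(rep_tree):
            if split in counts:
                counts[split] += 1
    info = BootstrapInfo(n_reps, n_skipped)
    if n_skipped > 0.2 * n_reps:
        logger.warning(
            "%d/%d bootstrap replicates skipped (undefined distances)",
            n_skipped,
            n_reps,
        )
    denom = max(info.n_valid, 1)
    for split, node in node_by_split.items():
        node.support = 100.0 * counts[split] / denom
    return tree, info


# -- Newick I/O ---------------------------------------------------------------


def read_newick(
    path: str | Path, expected_ids: set[str] | None = None
) -> TreeNode:
    """Read a Newick tree; numeric internal-node labels become supports.

    Raises ``ValueError`` on duplicate tip labels or (when *expected_ids* is
    given) tip labels that do not resolve to known record ids.
    """
    tree = TreeNode.read(str(path), format="newick")
    names = [t.name for t in tree.tips()]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ValueError(f"duplicate tip labels in tree: {dupes}")
    if expected_ids is not None:
        unknown = sorted(set(names) - expected_ids)
        if unknown:
            raise ValueError(f"tip labels not resolvable to record ids: {unknown}")
    tree.assign_supports()
    return tree


def newick_string(tree: TreeNode) -> str:
    """Serialise to Newick (``node.support`` becomes the internal label)."""
    import io

    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write Newick; ``node.support`` values become internal-node labels."""
    Path(path).write_text(newick_string(tree))


# -- monophyly scoring --------------------------------------------------------


@dataclass
class MonophylyReport:
    """Per-species monophyly verdicts and overall discrimination rates.

    ``per_species`` maps species -> (n_individuals, status) with status one of
    ``"yes"``, ``"no"``, ``"singleton"``.  Rates are fractions in [0, 1];
    whether singleton species count as discriminated is set by
    *singleton_policy* (they are always flagged separately).
    """

    per_species: dict[str, tuple[int, str]]
    discrimination_rate_individuals: float
    discrimination_rate_species: float
    singleton_policy: str

    @property
    def n_singletons(self) -> int:
        return sum(1 for _, st in self.per_species.values() if st == "singleton")

    def to_dict(self) -> dict:
        return {
            "per_species": {
                s: {"n_individuals": n, "monophyletic": st}
                for s, (n, st) in self.per_species.items()
            },
            "discrimination_rate_individuals": self.discrimination_rate_individuals,
            "discrimination_rate_species": self.discrimination_rate_species,
            "singleton_policy": self.singleton_policy,
        }


def monophyly(
    tree: TreeNode,
    species: Mapping[str, str],
    rooted: bool = False,
    singleton_policy: Literal["discriminated", "not_discriminated"] = "discriminated",
) -> MonophylyReport:
    """Score per-species monophyly on a tree.

    For unrooted scoring a species with >=2 tips is monophyletic iff some
    edge bipartition has exactly that species' tips on one side (equivalently
    some clade tip set, under any rooting, equals the species' tips or their
    complement).  For rooted trees only clade equality counts.  *species*
    maps every tip label to its species; unlabelled tips are an error.
    """
    tip_names = [t.name for t in tree.tips()]
    missing = sorted(set(tip_names) - set(species))
    if missing:
        raise ValueError(f"tips without species labels: {missing}")
    all_tips = frozenset(tip_names)
    clades: set[frozenset[str]] = {all_tips}
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            clades.add(frozenset({node.name}))
        else:
            clades.add(frozenset(t.name for t in node.tips()))

    groups: dict[str, set[str]] = {}
    for tip in tip_names:
        groups.setdefault(species[tip], set()).add(tip)

    per_species: dict[str, tuple[int, str]] = {}
    for sp, tips in sorted(groups.items()):
        fs = frozenset(tips)
        if len(fs) == 1:
            per_species[sp] = (1, "singleton")
            continue
        mono = fs in clades or (not rooted and (all_tips - fs) in clades)
        per_species[sp] = (len(fs), "yes" if mono else "no")

    single_ok = singleton_policy == "discriminated"
    disc_tips = sum(
        n for n, st in per_species.values() if st == "yes" or (single_ok and st == "singleton")
    )
    disc_species = sum(
        1 for n, st in per_species.values() if st == "yes" or (single_ok and st == "singleton")
    )
    return MonophylyReport(
        per_species=per_species,
        discrimination_rate_individuals=disc_tips / len(tip_names),
        discrimination_rate_species=disc_species / len(per_species),
        singleton_policy=singleton_policy,
    )
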