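"""Aligned-matrix container and FASTA I/O with species labelling.

Every downstream stage (summary statistics, K2P distances, barcoding-gap
analysis, similarity identification, tree building) consumes an
:class:`AlignedMatrix`: an ordered collection of equal-length, species-labelled
sequences for one barcode region (e.g. ITS1, ITS2 or their concatenation).

Species identity is normally encoded in FASTA headers.  The default parsing
rule takes the first two underscore-separated tokens of the record id as
``Genus_species`` (stopping at ``|``, so headers like ``Senna_tora|KJ638426``
yield ``Senna_tora``).  A custom callable or an external two-column id→species
mapping can override it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "AlignedMatrix",
    "AlignmentError",
    "default_label_rule",
    "delimiter_label_rule",
    "read_alignment",
    "write_alignment",
    "read_species_map",
    "concatenate",
]

#: Characters accepted in aligned DNA residues (after normalisation).
VALID_RESIDUES = frozenset("ACGTNRYSWKMBDHV-")

#: Alignment-dialect characters normalised to the gap character on read.
_GAP_ALIASES = str.maketrans({".": "-", "?": "-"})


class AlignmentError(ValueError):
    """Invalid alignment input: ragged rows, bad residues, bad headers."""


def normalize_residues(residues: str, *, where: str = "") -> str:
    """Upper-case residues, map '.'/'?' to '-', reject anything non-IUPAC."""
    s = residues.upper().translate(_GAP_ALIASES)
    bad = set(s) - VALID_RESIDUES
    if bad:
        raise AlignmentError(
            f"invalid residue character(s) {sorted(bad)}"
            + (f" in record {where!r}" if where else "")
        )
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence with its species label.

    Parameters
    ----------
    id : str
        Unique record identifier (e.g. a GenBank accession-bearing header).
    species : str
        Species label, typically a binomial such as ``Senna_tora``.
    residues : str
        Aligned characters over A/C/G/T, IUPAC ambiguity codes, N and ``-``.
    region : str
        Barcode-region tag (``ITS1``, ``ITS2``, ``ITS1+2`` or ``other``).
    """

    id: str
    species: str
    residues: str
    region: str = "other"

    def __post_init__(self) -> None:
        if not self.id:
            raise AlignmentError("record id must be non-empty")
        if not self.species:
            raise AlignmentError(f"record {self.id!r}: species label must be non-empty")


class AlignedMatrix:
    """Equal-length, species-labelled sequences for one barcode region."""

    def __init__(self, records: Sequence[SequenceRecord], region: str | None = None):
        records = tuple(records)
        if len(records) < 2:
            raise AlignmentError("an aligned matrix needs at least 2 records")
        length = len(records[0].residues)
        for r in records:
            if len(r.residues) != length:
                raise AlignmentError(
                    f"ragged alignment: record {r.id!r} has length "
                    f"{len(r.residues)}, expected {length}"
                )
        seen: set[str] = set()
        for r in records:
            if r.id in seen:
                raise AlignmentError(f"duplicate record id {r.id!r}")
            seen.add(r.id)
        self.records = records
        self.region = region if region is not None else records[0].region
        self._array: np.ndarray | None = None

    # -- basic introspection -------------------------------------------------

    @property
    def length(self) -> int:
        """Alignment column count (bp)."""
        return len(self.records[0].residues)

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def species(self) -> list[str]:
        """Per-record species labels, parallel to :attr:`ids`."""
        return [r.species for r in self.records]

    @property
    def species_set(self) -> set[str]:
        return set(self.species)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlignedMatrix):
            return NotImplemented
        return self.records == other.records and self.region == other.region

    def __repr__(self) -> str:
        return (
            f"AlignedMatrix({self.n_records} records x {self.length} columns, "
            f"{len(self.species_set)} species, region={self.region!r})"
        )

    def to_array(self) -> np.ndarray:
        """Residues as an (n_records, length) array of single bytes."""
        if self._array is None:
            buf = "".join(r.residues for r in self.records).encode("ascii")
            self._array = np.frombuffer(buf, dtype="S1").reshape(
                self.n_records, self.length
            )
        return self._array

    def with_region(self, region: str) -> "AlignedMatrix":
        return AlignedMatrix(
            [replace(r, region=region) for r in self.records], region=region
        )


# -- species label rules -----------------------------------------------------

_BINOMIAL_RE = re.compile(r"^([^_|\s]+)_([^_|\s]+)")


def default_label_rule(record_id: str) -> str:
    """First two underscore-separated tokens of the id, joined by ``_``.

    Stops at ``|`` or whitespace, so ``Senna_tora|KJ638426`` -> ``Senna_tora``.
    """
    m = _BINOMIAL_RE.match(record_id)
    if m is None:
        raise AlignmentError(
            f"cannot parse species from header {record_id!r}: expected at least "
            "two underscore-separated tokens (Genus_species...)"
        )
    return f"{m.group(1)}_{m.group(2)}"


def delimiter_label_rule(delimiter: str = "_", n_tokens: int = 2) -> Callable[[str], str]:
    """Build a label rule splitting on *delimiter* and joining *n_tokens*."""

    def rule(record_id: str) -> str:
        tokens = record_id.split("|")[0].split(delimiter)
        if len(tokens) < n_tokens or any(not t for t in tokens[:n_tokens]):
            raise AlignmentError(
                f"cannot parse species from header {record_id!r} with "
                f"delimiter {delimiter!r}"
            )
        return delimiter.join(tokens[:n_tokens])

    return rule


def read_species_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``record_id<TAB>species`` mapping file."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise AlignmentError(
                f"{path}: line {lineno}: expected 'record_id<TAB>species'"
            )
        mapping[parts[0]] = parts[1]
    return mapping


# -- I/O ----------------------------------------------------------------------


def read_alignment(
    path: str | Path,
    label_rule: Callable[[str], str] | None = None,
    species_map: Mapping[str, str] | None = None,
    region: str = "other",
) -> AlignedMatrix:
    """Read an aligned multi-FASTA file into an :class:`AlignedMatrix`.

    Species labels come from *species_map* when given (every record id must be
    present in it), otherwise from *label_rule* applied to the record id
    (default: :func:`default_label_rule`).

    Raises
    ------
    AlignmentError
        On ragged sequence lengths (naming the offending record), unparseable
        headers, invalid residue characters or duplicate ids.
    """
    rule = label_rule or default_label_rule
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if species_map is not None:
            try:
                species = species_map[rid]
            except KeyError:
                raise AlignmentError(
                    f"record id {rid!r} missing from species mapping"
                ) from None
        else:
            species = rule(rid)
        residues = normalize_residues(str(rec.seq), where=rid)
        records.append(SequenceRecord(rid, species, residues, region))
    if not records:
        raise AlignmentError(f"{path}: no FASTA records found")
    return AlignedMatrix(records, region=region)


def write_alignment(m: AlignedMatrix, path: str | Path) -> None:
    """Write the matrix as aligned multi-FASTA (record ids as headers).

    Round-trips: reading the file back under the same label rule reproduces
    the matrix (gaps preserved verbatim).
    """
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in m.records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# -- region concatenation ------------------------------------------------------


def concatenate(a: AlignedMatrix, b: AlignedMatrix) -> AlignedMatrix:
    """Concatenate two region alignments record-wise (join on record id).

    Every id in *a* must have exactly one partner in *b*; record order follows
    *a*.  The result's length is ``a.length + b.length`` and its region tag is
    ``ITS1+2`` when joining ITS1 with ITS2, else ``<a.region>+<b.region>``.
    """
    b_by_id = {r.id: r for r in b.records}
    missing = [r.id for r in a.records if r.id not in b_by_id]
    extra = [rid for rid in b_by_id if rid not in set(a.ids)]
    if missing or extra:
        raise AlignmentError(
            "cannot concatenate: unmatched record ids "
            f"(missing from second matrix: {missing[:5]}; "
            f"only in second matrix: {extra[:5]})"
        )
    if {a.region, b.region} == {"ITS1", "ITS2"}:
        region = "ITS1+2"
    else:
        region = f"{a.region}+{b.region}"
    records = []
    for ra in a.records:
        rb = b_by_id[ra.id]
        if ra.species != rb.species:
            raise AlignmentError(
                f"record {ra.id!r} has conflicting species labels "
                f"({ra.species!r} vs {rb.species!r})"
            )
        records.append(
            SequenceRecord(ra.id, ra.species, ra.residues + rb.residues, region)
        )
    return AlignedMatrix(records, region=region)
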