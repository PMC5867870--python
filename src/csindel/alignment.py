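"""Protein multiple-sequence alignments and column-level utilities.

This module owns the in-memory alignment container used throughout the
pipeline, file IO for the two common alignment formats (FASTA and Clustal,
via Bio.AlignIO), per-column conservation scoring, and the mapping between
alignment columns and ungapped positions of a designated reference protein
— the coordinate system in which signature regions are reported (e.g.
"421–514" in the reference homolog's numbering).

Conventions
-----------
* Gap character is ``'-'``; ``'.'`` (a Clustal dialect) is normalised to
  ``'-'`` on read.
* Input residues are upper-cased; ``'X'`` is accepted as an unknown residue
  but never counts toward a column majority.
* Alignment columns are 0-based internally; reference-protein positions are
  1-based and ungapped in every report.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .errors import (
    AlignmentShapeError,
    CharacterError,
    InputError,
    LookupError_,
    ParameterError,
    PartitionError,
)

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Characters legal in an aligned residue string.
ALPHABET = frozenset(AMINO_ACIDS + "X" + GAP)

_FORMATS = {"fasta": "fasta", "clustal": "clustal"}


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence: a unique id, an organism label and residues."""

    id: str
    residues: str
    taxon: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("sequence record with empty id")
        if not self.residues:
            raise InputError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - ALPHABET
        if bad:
            col = min(i for i, c in enumerate(self.residues) if c in bad)
            raise CharacterError(
                f"illegal character {self.residues[col]!r} in sequence "
                f"{self.id!r} at column {col}"
            )

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


class Alignment:
    """An ordered collection of equal-length gapped sequences.

    Parameters
    ----------
    records:
        At least two :class:`SequenceRecord` with identical residue-string
        lengths and unique ids.  Record order is preserved.
    name:
        Optional label (typically the protein family), used in reports.
    """

    def __init__(self, records: Iterable[SequenceRecord], name: str = "") -> None:
        self.records: list[SequenceRecord] = list(records)
        self.name = name
        if len(self.records) < 2:
            raise InputError("an alignment needs at least 2 sequences")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            detail = ", ".join(
                f"{r.id}:{len(r.residues)}" for r in self.records
            )
            raise AlignmentShapeError(
                f"unequal sequence lengths in alignment ({detail})"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise InputError(f"duplicate sequence ids: {sorted(dupes)}")
        self.length: int = lengths.pop()
        self._index = {r.id: i for i, r in enumerate(self.records)}
        # residue matrix, one row per record — the workhorse for column ops
        self._matrix = np.array(
            [list(r.residues) for r in self.records], dtype="<U1"
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, rec_id: str) -> SequenceRecord:
        try:
            return self.records[self._index[rec_id]]
        except KeyError:
            raise LookupError_(f"no sequence {rec_id!r} in alignment") from None

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def matrix(self, ids: Sequence[str] | None = None) -> np.ndarray:
        """Residue matrix (rows in record order, or the given id subset)."""
        if ids is None:
            return self._matrix
        return self._matrix[[self._index[i] for i in ids]]

    def row(self, rec_id: str) -> np.ndarray:
        try:
            return self._matrix[self._index[rec_id]]
        except KeyError:
            raise LookupError_(f"no sequence {rec_id!r} in alignment") from None


@dataclass(frozen=True)
class TaxonPartition:
    """In-group/out-group membership plus the reference sequence id.

    The in-group is the clade whose specific signatures are sought; the
    reference (a member of the in-group) supplies the protein numbering in
    which regions are reported.
    """

    ingroup_ids: frozenset[str]
    outgroup_ids: frozenset[str]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.ingroup_ids or not self.outgroup_ids:
            raise PartitionError("both in-group and out-group must be non-empty")
        if self.ingroup_ids & self.outgroup_ids:
            raise PartitionError(
                f"ids in both groups: {sorted(self.ingroup_ids & self.outgroup_ids)}"
            )
        if self.reference_id not in self.ingroup_ids:
            raise PartitionError(
                f"reference {self.reference_id!r} is not in the in-group"
            )

    def validate_against(self, aln: Alignment) -> None:
        missing = (self.ingroup_ids | self.outgroup_ids) - set(aln.ids)
        if missing:
            raise PartitionError(
                f"partition ids absent from alignment: {sorted(missing)}"
            )


@dataclass
class ConservationProfile:
    """Per-column majority residue, majority fraction and conservation flag.

    The majority fraction counts gaps (and ``'X'``) in the denominator, so a
    column is conserved only when a single amino acid dominates *all*
    sequences, matching the visual criterion used when alignments are
    inspected by eye.
    """

    majority_residue: np.ndarray  # '<U1', '-' when no non-gap residue occurs
    majority_fraction: np.ndarray  # float in (0, 1]
    is_conserved: np.ndarray  # bool
    threshold: float

    def __len__(self) -> int:
        return len(self.is_conserved)


def conservation_profile(
    aln: Alignment,
    threshold: float = 0.8,
    ids: Sequence[str] | None = None,
) -> ConservationProfile:
    """Score every column for conservation.

    A column is conserved iff one non-gap, non-``X`` residue occurs in at
    least ``threshold`` of the rows considered (all records by default, or
    the subset ``ids``).

    Raises
    ------
    ParameterError
        If ``threshold`` is outside ``(0, 1]``.
    """
    if not 0 < threshold <= 1:
        raise ParameterError(f"conservation threshold {threshold} not in (0, 1]")
    m = aln.matrix(ids)
    n = m.shape[0]
    best_res = np.full(aln.length, GAP, dtype="<U1")
    best_cnt = np.zeros(aln.length, dtype=int)
    for aa in AMINO_ACIDS:
        cnt = (m == aa).sum(axis=0)
        better = cnt > best_cnt
        best_res[better] = aa
        best_cnt[better] = cnt[better]
    gap_cnt = (m == GAP).sum(axis=0)
    frac = np.where(best_cnt > 0, best_cnt, gap_cnt) / n
    conserved = (best_cnt / n >= threshold) & (best_cnt > 0)
    return ConservationProfile(best_res, frac, conserved, threshold)


def map_column_to_reference(aln: Alignment, reference_id: str, column: int) -> int:
    """1-based ungapped reference position of an alignment column.

    Returns the number of non-gap reference characters in columns
    ``0..column`` inclusive.  When the reference carries a gap at ``column``
    this equals the position of the nearest preceding reference residue
    (0 if there is none).
    """
    if not 0 <= column < aln.length:
        raise ParameterError(
            f"column {column} outside alignment of length {aln.length}"
        )
    row = aln.row(reference_id)
    return int((row[: column + 1] != GAP).sum())


def reference_positions(aln: Alignment, reference_id: str) -> np.ndarray:
    """Vectorised :func:`map_column_to_reference` for all columns."""
    row = aln.row(reference_id)
    return np.cumsum(row != GAP)


# ---------------------------------------------------------------------------
# file IO


def _normalise(residues: str) -> str:
    return residues.upper().replace(".", GAP)


def read_alignment(path: str | Path, format: str = "fasta", name: str = "") -> Alignment:
    """Read a gapped protein alignment from FASTA or Clustal.

    Record order follows the file.  Lower-case residues are upper-cased and
    ``'.'`` gaps normalised to ``'-'``.
    """
    if format not in _FORMATS:
        raise ParameterError(f"unknown alignment format {format!r}")
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise InputError(f"empty alignment file: {path}")
    try:
        msa = AlignIO.read(str(path), _FORMATS[format])
    except ValueError as exc:
        # Bio.AlignIO refuses ragged FASTA "alignments" with a ValueError
        msg = str(exc).lower()
        if "length" in msg:
            raise AlignmentShapeError(f"{path}: {exc}") from exc
        raise InputError(f"{path}: {exc}") from exc
    records = [
        SequenceRecord(
            id=rec.id,
            residues=_normalise(str(rec.seq)),
            taxon=(rec.description[len(rec.id):].strip()
                   if rec.description.startswith(rec.id) else rec.description),
        )
        for rec in msa
    ]
    if not records:
        raise InputError(f"no sequences in {path}")
    return Alignment(records, name=name or path.stem)


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write an alignment in FASTA or Clustal; inverse of :func:`read_alignment`."""
    if format not in _FORMATS:
        raise ParameterError(f"unknown alignment format {format!r}")
    msa = MultipleSeqAlignment(
        BioSeqRecord(Seq(r.residues), id=r.id, description=r.taxon)
        for r in aln.records
    )
    with open(path, "w") as fh:
        AlignIO.write(msa, fh, _FORMATS[format])


def read_partition(path: str | Path) -> TaxonPartition:
    """Read a three-column TSV partition file: id, group, is_reference.

    ``group`` is ``ingroup`` or ``outgroup``; ``is_reference`` is 1/0 (or
    true/false) and must mark exactly one in-group id.
    """
    ingroup: set[str] = set()
    outgroup: set[str] = set()
    reference: list[str] = []
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise InputError(f"{path}:{lineno}: expected 3 tab-separated fields")
        rec_id, group, is_ref = (p.strip() for p in parts)
        if group == "ingroup":
            ingroup.add(rec_id)
        elif group == "outgroup":
            outgroup.add(rec_id)
        else:
            raise InputError(
                f"{path}:{lineno}: group must be 'ingroup' or 'outgroup', got {group!r}"
            )
        if is_ref.lower() in {"1", "true", "yes"}:
            reference.append(rec_id)
    if len(reference) != 1:
        raise InputError(
            f"{path}: exactly one reference id required, found {len(reference)}"
        )
    return TaxonPartition(frozenset(ingroup), frozenset(outgroup), reference[0])


def write_partition(part: TaxonPartition, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec_id in sorted(part.ingroup_ids):
            flag = "1" if rec_id == part.reference_id else "0"
            fh.write(f"{rec_id}\tingroup\t{flag}\n")
        for rec_id in sorted(part.outgroup_ids):
            fh.write(f"{rec_id}\toutgroup\t0\n")
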