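"""Detection of clade-specific conserved signature indels (CSIs).

A CSI is an insertion or deletion in a protein alignment that is restricted
to a monophyletic in-group and flanked on both sides by conserved sequence,
so that it can serve as a molecular marker for the clade.  Detection
proceeds in three stages:

1. :func:`find_gap_blocks` — locate maximal runs of alignment columns whose
   gap pattern separates the in-group from the out-group (residues in the
   in-group over gaps in the out-group for an insertion; the converse for a
   deletion).
2. :func:`evaluate_flanks` — require a minimum number of conserved columns
   in a fixed window on each side of the candidate, evidence that the
   region is truly homologous across all sequences.
3. :func:`evaluate_specificity` — check which sequences actually carry the
   indel, yielding a strict verdict (all in-group, no out-group), a
   tolerant verdict listing isolated exceptions, or a rejection.

:func:`detect_csis` composes the stages and emits one :class:`CsiRecord`
per surviving candidate, carrying the catalogue row (type, size range,
region in reference-protein coordinates, flank evidence, specificity), a
publication-style signature block and an ungapped validation segment
suitable for external homology screening.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .alignment import (
    GAP,
    Alignment,
    ConservationProfile,
    TaxonPartition,
    conservation_profile,
    map_column_to_reference,
    reference_positions,
)
from .errors import ParameterError, PartitionError

IndelType = Literal["insertion", "deletion"]

#: Character printed in a signature block where a row has a gap opposite a
#: reference residue (distinct from '-', which encodes identity).
ABSENT = "."
_SEPARATOR = "=" * 8


@dataclass(frozen=True)
class DetectionParams:
    """Tunable thresholds of the CSI detector.

    Defaults encode the working criteria for a signature indel: flanked on
    both sides by at least ``min_conserved_flank`` (5) conserved residues
    within ``flank_window`` (35) neighbouring columns, strict clade
    specificity, and a 60–100 residue validation segment for external
    screening (default 80).

    ``max_ingroup_missing`` / ``max_outgroup_sharing`` relax "all in-group /
    no out-group" to "most / almost none": each is the tolerated fraction of
    records on the wrong side of the gap pattern.  ``allow_isolated_exception``
    additionally permits a single out-group sequence to share the indel
    regardless of out-group size, reported by id rather than silently.
    """

    min_indel_size: int = 1
    max_indel_size: int = 10_000
    flank_window: int = 35
    min_conserved_flank: int = 5
    conservation_threshold: float = 0.8
    max_ingroup_missing: float = 0.0
    max_outgroup_sharing: float = 0.0
    allow_isolated_exception: bool = False
    validation_segment_length: int = 80
    conservation_scope: Literal["both", "ingroup"] = "both"

    def __post_init__(self) -> None:
        if self.min_indel_size < 1:
            raise ParameterError("min_indel_size must be >= 1")
        if self.max_indel_size < self.min_indel_size:
            raise ParameterError("max_indel_size < min_indel_size")
        if self.flank_window < self.min_conserved_flank:
            raise ParameterError("flank_window must be >= min_conserved_flank")
        if not 0 < self.conservation_threshold <= 1:
            raise ParameterError("conservation_threshold not in (0, 1]")
        for name in ("max_ingroup_missing", "max_outgroup_sharing"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} not in [0, 1]")
        if not 60 <= self.validation_segment_length <= 100:
            raise ParameterError("validation_segment_length must be in 60..100")
        if self.conservation_scope not in ("both", "ingroup"):
            raise ParameterError("conservation_scope must be 'both' or 'ingroup'")


@dataclass(frozen=True)
class IndelCandidate:
    """A maximal group-differential gap block, before flank/specificity checks.

    ``columns`` is the half-open alignment-column interval ``[start, end)``.
    ``per_sequence_lengths`` maps each record id to its non-gap residue
    count inside the interval; ``size_min``/``size_max`` summarise the
    residue-bearing group (the in-group for insertions, the out-group for
    deletions), so a ragged in-group insert of 5–7 residues reports 5–7.
    """

    start: int
    end: int
    indel_type: IndelType
    per_sequence_lengths: dict[str, int]
    size_min: int
    size_max: int

    @property
    def columns(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class FlankReport:
    left_count: int
    right_count: int
    passed: bool


@dataclass(frozen=True)
class SpecificityVerdict:
    verdict: Literal["strict", "tolerant", "rejected"]
    ingroup_missing: tuple[str, ...] = ()
    outgroup_sharing: tuple[str, ...] = ()

    @property
    def exceptions(self) -> tuple[str, ...]:
        return self.ingroup_missing + self.outgroup_sharing


@dataclass(frozen=True)
class CsiRecord:
    """One catalogue row: a validated clade-specific signature indel."""

    protein_name: str
    indel_type: IndelType
    size_min: int
    size_max: int
    region_start: int  # 1-based reference positions, flank-to-flank
    region_end: int
    indel_ref_start: int  # reference position of the first indel column
    indel_ref_end: int
    columns: tuple[int, int]  # alignment columns [start, end)
    flank_report: FlankReport
    specificity: SpecificityVerdict
    signature_text: str
    validation_segment: str


def _tolerated_counts(part: TaxonPartition, params: DetectionParams) -> tuple[int, int]:
    """(allowed in-group missing, allowed out-group sharing) as record counts."""
    allowed_in = int(params.max_ingroup_missing * len(part.ingroup_ids))
    allowed_out = int(params.max_outgroup_sharing * len(part.outgroup_ids))
    if params.allow_isolated_exception:
        allowed_out = max(allowed_out, 1)
    return allowed_in, allowed_out


def _column_masks(
    aln: Alignment, part: TaxonPartition, params: DetectionParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-column qualification masks for insertion and deletion patterns."""
    in_ids = sorted(part.ingroup_ids)
    out_ids = sorted(part.outgroup_ids)
    in_gap = aln.matrix(in_ids) == GAP
    out_gap = aln.matrix(out_ids) == GAP
    n_in, n_out = len(in_ids), len(out_ids)
    allowed_in, allowed_out = _tolerated_counts(part, params)
    # insertion column: the out-group is gapped up to the sharing tolerance
    # and at least one in-group sequence holds a residue there
    ins_cols = (out_gap.sum(axis=0) >= n_out - allowed_out) & ((~in_gap).any(axis=0))
    # deletion column: the converse pattern
    del_cols = (in_gap.sum(axis=0) >= n_in - allowed_in) & ((~out_gap).any(axis=0))
    return ins_cols, del_cols, in_gap, out_gap


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean vector, as half-open intervals."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def find_gap_blocks(
    aln: Alignment, part: TaxonPartition, params: DetectionParams | None = None
) -> list[IndelCandidate]:
    """Locate maximal group-differential gap blocks.

    A block is a maximal run of columns that all satisfy the per-column
    pattern for one indel type (see :func:`_column_masks`).  A block is kept
    only if, at interval level, the fraction of residue-bearing-group
    records *lacking* any residue in the interval (insertions: in-group;
    deletions: out-group) stays within the corresponding tolerance, and the
    size range intersects ``[min_indel_size, max_indel_size]``.

    Candidates are returned sorted by start column, insertions before
    deletions at equal start.
    """
    params = params or DetectionParams()
    part.validate_against(aln)
    in_ids = sorted(part.ingroup_ids)
    out_ids = sorted(part.outgroup_ids)
    if not in_ids or not out_ids:
        raise PartitionError("empty group after id intersection")
    ins_cols, del_cols, in_gap, out_gap = _column_masks(aln, part, params)

    allowed_in, allowed_out = _tolerated_counts(part, params)

    candidates: list[IndelCandidate] = []
    for indel_type, mask in (("insertion", ins_cols), ("deletion", del_cols)):
        bearer_ids = in_ids if indel_type == "insertion" else out_ids
        bearer_gap = in_gap if indel_type == "insertion" else out_gap
        allowed_missing = allowed_in if indel_type == "insertion" else allowed_out
        for start, end in _runs(mask):
            counts = (~bearer_gap[:, start:end]).sum(axis=1)
            missing = int((counts == 0).sum())
            if missing > allowed_missing:
                continue
            carried = counts[counts > 0]
            size_min, size_max = int(carried.min()), int(carried.max())
            if size_max < params.min_indel_size or size_min > params.max_indel_size:
                continue
            per_seq = {
                rid: int((aln.row(rid)[start:end] != GAP).sum()) for rid in aln.ids
            }
            candidates.append(
                IndelCandidate(start, end, indel_type, per_seq, size_min, size_max)
            )
    candidates.sort(key=lambda c: (c.start, c.indel_type))
    return candidates


def evaluate_flanks(
    aln: Alignment,
    candidate: IndelCandidate,
    part: TaxonPartition,
    params: DetectionParams | None = None,
    profile: ConservationProfile | None = None,
) -> FlankReport:
    """Count conserved columns in the windows flanking a candidate.

    Windows span up to ``flank_window`` columns immediately left of the
    candidate and immediately right of it, truncated at the alignment
    edges; the candidate interval itself is excluded.  Conservation is
    scored over all records (or the in-group only, per
    ``conservation_scope``).
    """
    params = params or DetectionParams()
    if profile is None:
        ids = sorted(part.ingroup_ids) if params.conservation_scope == "ingroup" else None
        profile = conservation_profile(aln, params.conservation_threshold, ids)
    left_lo = max(0, candidate.start - params.flank_window)
    left = int(profile.is_conserved[left_lo:candidate.start].sum())
    right_hi = min(aln.length, candidate.end + params.flank_window)
    right = int(profile.is_conserved[candidate.end:right_hi].sum())
    passed = left >= params.min_conserved_flank and right >= params.min_conserved_flank
    return FlankReport(left, right, passed)


def evaluate_specificity(
    aln: Alignment,
    candidate: IndelCandidate,
    part: TaxonPartition,
    params: DetectionParams | None = None,
) -> SpecificityVerdict:
    """Judge clade specificity of a candidate at interval level.

    A sequence *carries* an insertion if it holds at least one residue in
    the interval, and carries a deletion if it holds none.  The verdict is
    ``strict`` when every in-group record carries the indel and no
    out-group record does; ``tolerant`` when the violations stay within the
    configured tolerances (violating ids are listed); ``rejected``
    otherwise.
    """
    params = params or DetectionParams()
    s, e = candidate.columns

    def carries(rid: str) -> bool:
        n_res = candidate.per_sequence_lengths.get(
            rid, int((aln.row(rid)[s:e] != GAP).sum())
        )
        return n_res > 0 if candidate.indel_type == "insertion" else n_res == 0

    in_missing = tuple(sorted(r for r in part.ingroup_ids if not carries(r)))
    out_sharing = tuple(sorted(r for r in part.outgroup_ids if carries(r)))
    if not in_missing and not out_sharing:
        return SpecificityVerdict("strict")
    allowed_in, allowed_out = _tolerated_counts(part, params)
    if len(in_missing) <= allowed_in and len(out_sharing) <= allowed_out:
        return SpecificityVerdict("tolerant", in_missing, out_sharing)
    return SpecificityVerdict("rejected", in_missing, out_sharing)


def format_signature(
    aln: Alignment,
    part: TaxonPartition,
    columns: tuple[int, int],
    region: tuple[int, int] | None = None,
    protein_name: str = "",
) -> str:
    """Render a signature block in the dash-for-identity display convention.

    The reference sequence is printed in full on the top line; every other
    row prints ``'-'`` where it matches the top line, the residue letter
    where it differs, and ``'.'`` where it has a gap opposite a reference
    residue.  In-group rows precede a separator line, out-group rows follow.
    The header carries the reference-coordinate span of the excerpt.
    """
    s, e = columns
    ref_row = aln.row(part.reference_id)[s:e]
    if region is None:
        region = (
            map_column_to_reference(aln, part.reference_id, s),
            map_column_to_reference(aln, part.reference_id, e - 1),
        )
    name = protein_name or aln.name or "signature"
    lines = [f"# {name} | reference {part.reference_id} positions {region[0]}-{region[1]}"]
    width = max(len(i) for i in aln.ids) + 2

    def encode(rid: str) -> str:
        row = aln.row(rid)[s:e]
        out = np.where(row == ref_row, "-", row)
        out[(row == GAP) & (ref_row != GAP)] = ABSENT
        return "".join(out)

    lines.append(f"{part.reference_id:<{width}}" + "".join(ref_row))
    for rid in aln.ids:
        if rid in part.ingroup_ids and rid != part.reference_id:
            lines.append(f"{rid:<{width}}" + encode(rid))
    lines.append(_SEPARATOR)
    for rid in aln.ids:
        if rid in part.outgroup_ids:
            lines.append(f"{rid:<{width}}" + encode(rid))
    return "\n".join(lines) + "\n"


def signature_to_residues(text: str) -> dict[str, str]:
    """Invert :func:`format_signature`: recover each row's aligned residues."""
    rows: dict[str, str] = {}
    top: str | None = None
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith(_SEPARATOR):
            continue
        rec_id, encoded = line.split(None, 1)
        if top is None:
            top = encoded
            rows[rec_id] = encoded
            continue
        decoded = [
            t if c == "-" else (GAP if c == ABSENT else c)
            for c, t in zip(encoded, top)
        ]
        rows[rec_id] = "".join(decoded)
    return rows


def export_validation_segment(
    aln: Alignment,
    part: TaxonPartition,
    candidate: IndelCandidate,
    params: DetectionParams | None = None,
) -> str:
    """Ungapped reference subsequence centred on the indel.

    The segment has ``validation_segment_length`` residues unless truncated
    by the protein ends, always contains the full indel (for insertions;
    for deletions it brackets the deletion point), and is intended for
    external homology screening of the signature region.
    """
    params = params or DetectionParams()
    ref = aln[part.reference_id].ungapped
    n = len(ref)
    s, e = candidate.columns
    ref_pos = reference_positions(aln, part.reference_id)
    # 1-based reference span of the indel (for deletions the span collapses
    # onto the residue preceding the deletion point)
    span_start = max(1, int(ref_pos[s - 1]) + 1 if s > 0 else 1)
    span_end = max(span_start, int(ref_pos[e - 1]))
    want = max(params.validation_segment_length, span_end - span_start + 1)
    if want >= n:
        return ref
    centre = (span_start + span_end) // 2
    lo = centre - want // 2
    lo = min(max(1, lo), n - want + 1)
    hi = lo + want - 1
    # guarantee full indel containment after clamping
    if span_start < lo:
        lo, hi = span_start, span_start + want - 1
    if span_end > hi:
        hi = span_end
        lo = max(1, hi - want + 1)
    return ref[lo - 1 : hi]


def detect_csis(
    aln: Alignment,
    part: TaxonPartition,
    params: DetectionParams | None = None,
    protein_name: str = "",
) -> list[CsiRecord]:
    """Full CSI detection: gap blocks → flank check → specificity → records.

    Emitted records are sorted by ``region_start``.  The reported region is
    the reference span from the leftmost conserved column in the passing
    left flank window to the rightmost conserved column in the right one —
    a reproducible stand-in for the hand-chosen excerpt bounds of published
    signature figures.
    """
    params = params or DetectionParams()
    name = protein_name or aln.name or "protein"
    ids = sorted(part.ingroup_ids) if params.conservation_scope == "ingroup" else None
    profile = conservation_profile(aln, params.conservation_threshold, ids)
    ref_pos = reference_positions(aln, part.reference_id)
    records: list[CsiRecord] = []
    for cand in find_gap_blocks(aln, part, params):
        flanks = evaluate_flanks(aln, cand, part, params, profile)
        if not flanks.passed:
            continue
        spec = evaluate_specificity(aln, cand, part, params)
        if spec.verdict == "rejected":
            continue
        s, e = cand.columns
        left_lo = max(0, s - params.flank_window)
        left_cons = np.flatnonzero(profile.is_conserved[left_lo:s]) + left_lo
        right_hi = min(aln.length, e + params.flank_window)
        right_cons = np.flatnonzero(profile.is_conserved[e:right_hi]) + e
        region = (
            int(ref_pos[left_cons[0]]),
            int(ref_pos[right_cons[-1]]),
        )
        if cand.indel_type == "insertion":
            indel_ref_start = int(ref_pos[s - 1]) + 1 if s > 0 else 1
            indel_ref_end = max(indel_ref_start, int(ref_pos[e - 1]))
        else:
            # a deletion has no reference residues: report the flanking
            # positions (last residue before / first residue after the gap)
            indel_ref_start = int(ref_pos[s - 1]) if s > 0 else 0
            indel_ref_end = indel_ref_start + 1
        sig = format_signature(
            aln, part, (left_cons[0], right_cons[-1] + 1), region, name
        )
        seg = export_validation_segment(aln, part, cand, params)
        records.append(
            CsiRecord(
                protein_name=name,
                indel_type=cand.indel_type,
                size_min=cand.size_min,
                size_max=cand.size_max,
                region_start=region[0],
                region_end=region[1],
                indel_ref_start=indel_ref_start,
                indel_ref_end=indel_ref_end,
                columns=cand.columns,
                flank_report=flanks,
                specificity=spec,
                signature_text=sig,
                validation_segment=seg,
            )
        )
    records.sort(key=lambda r: (r.region_start, r.columns))
    return records


def csi_table(records: Sequence[CsiRecord]):
    """Catalogue of detected CSIs as a DataFrame (one row per record)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "protein": r.protein_name,
                "indel_type": r.indel_type,
                "size_min": r.size_min,
                "size_max": r.size_max,
                "region_start": r.region_start,
                "region_end": r.region_end,
                "flank_left": r.flank_report.left_count,
                "flank_right": r.flank_report.right_count,
                "specificity": r.specificity.verdict,
                "exceptions": ",".join(r.specificity.exceptions),
            }
            for r in records
        ],
        columns=[
            "protein", "indel_type", "size_min", "size_max", "region_start",
            "region_end", "flank_left", "flank_right", "specificity", "exceptions",
        ],
    )
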