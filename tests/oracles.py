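"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain Python loops over the definitions, with
no reliance on the vectorised code paths it checks.
"""

from __future__ import annotations

import numpy as np

from csindel.alignment import GAP, Alignment, TaxonPartition
from csindel.csi import DetectionParams


def conservation_oracle(aln: Alignment, threshold: float, ids=None):
    """Per-column (majority_residue, fraction, is_conserved) by direct count."""
    rows = [aln[i].residues for i in (ids if ids is not None else aln.ids)]
    out = []
    for c in range(aln.length):
        col = [r[c] for r in rows]
        counts: dict[str, int] = {}
        for ch in col:
            if ch not in (GAP, "X"):
                counts[ch] = counts.get(ch, 0) + 1
        if counts:
            best = max(sorted(counts), key=lambda k: counts[k])
            frac = counts[best] / len(col)
            out.append((best, frac, frac >= threshold))
        else:
            out.append((GAP, col.count(GAP) / len(col), False))
    return out


def _allowed(part: TaxonPartition, params: DetectionParams) -> tuple[int, int]:
    allowed_in = int(params.max_ingroup_missing * len(part.ingroup_ids))
    allowed_out = int(params.max_outgroup_sharing * len(part.outgroup_ids))
    if params.allow_isolated_exception:
        allowed_out = max(allowed_out, 1)
    return allowed_in, allowed_out


def gap_block_oracle(aln: Alignment, part: TaxonPartition, params: DetectionParams):
    """Enumerate candidate gap blocks column by column, naively.

    Returns a list of (start, end, indel_type, size_min, size_max) matching
    the contract of ``find_gap_blocks``: maximal runs of qualifying columns,
    interval-level coverage tolerance on the residue-bearing group, and a
    size-range filter.
    """
    in_ids = sorted(part.ingroup_ids)
    out_ids = sorted(part.outgroup_ids)
    allowed_in, allowed_out = _allowed(part, params)

    def col_qualifies(c: int, indel_type: str) -> bool:
        in_res = [aln[i].residues[c] != GAP for i in in_ids]
        out_res = [aln[i].residues[c] != GAP for i in out_ids]
        if indel_type == "insertion":
            n_gapped = sum(not r for r in out_res)
            return n_gapped >= len(out_res) - allowed_out and any(in_res)
        n_gapped = sum(not r for r in in_res)
        return n_gapped >= len(in_res) - allowed_in and any(out_res)

    results = []
    for indel_type in ("insertion", "deletion"):
        bearer = in_ids if indel_type == "insertion" else out_ids
        allowed_missing = allowed_in if indel_type == "insertion" else allowed_out
        c = 0
        while c < aln.length:
            if not col_qualifies(c, indel_type):
                c += 1
                continue
            start = c
            while c < aln.length and col_qualifies(c, indel_type):
                c += 1
            end = c
            counts = [
                sum(ch != GAP for ch in aln[i].residues[start:end]) for i in bearer
            ]
            missing = sum(1 for x in counts if x == 0)
            if missing > allowed_missing:
                continue
            carried = [x for x in counts if x > 0]
            size_min, size_max = min(carried), max(carried)
            if size_max < params.min_indel_size or size_min > params.max_indel_size:
                continue
            results.append((start, end, indel_type, size_min, size_max))
    results.sort(key=lambda t: (t[0], t[2]))
    return results


def cxxc_oracle(seq: str, overlapping: bool = True, strict_x: bool = False):
    """All-positions (or greedy non-overlapping) CXXC scan by direct loops."""
    seq = seq.upper()
    positions = []
    i = 0
    while i <= len(seq) - 4:
        window = seq[i : i + 4]
        hit = window[0] == "C" and window[3] == "C"
        if hit and strict_x and "C" in window[1:3]:
            hit = False
        if hit:
            positions.append(i + 1)
            if not overlapping:
                i += 4
                continue
        i += 1
    return positions


def random_alignment(rng: np.random.Generator, max_seqs: int = 8, max_cols: int = 40):
    """A random gapped alignment plus partition, for oracle comparisons."""
    from csindel.alignment import SequenceRecord

    n = int(rng.integers(4, max_seqs + 1))
    n_in = int(rng.integers(2, n - 1))
    length = int(rng.integers(5, max_cols + 1))
    letters = np.array(list("ACDEG-"))
    probs = np.array([0.16, 0.16, 0.16, 0.16, 0.16, 0.2])
    records = []
    for i in range(n):
        res = "".join(rng.choice(letters, size=length, p=probs))
        if set(res) == {GAP}:  # all-gap rows are legal but dull; keep one residue
            res = "A" + res[1:]
        records.append(SequenceRecord(id=f"s{i:02d}", residues=res))
    aln = Alignment(records)
    ids = aln.ids
    part = TaxonPartition(
        frozenset(ids[:n_in]), frozenset(ids[n_in:]), reference_id=ids[0]
    )
    return aln, part
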