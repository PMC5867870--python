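"""CXXC motif scanning in protein sequences.

The Cys-X-X-Cys tetrapeptide is the redox-active/metal-binding unit of
thioredoxin-fold oxidoreductases and of zinc fingers, and a prime target
for oxidative damage; counting the motifs per protein is how candidate
redox-sensitive repair proteins are flagged.  By default the two middle
positions admit any residue including cysteine (so ``CCCC`` scores two
overlapping hits) and overlapping hits are all reported; a strict mode
excludes cysteine from the X positions, and a non-overlapping mode keeps a
greedy left-to-right selection instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .alignment import GAP
from .errors import InputError


@dataclass(frozen=True)
class MotifHit:
    """One CXXC occurrence; ``position`` is the 1-based index of the first C."""

    sequence_id: str
    position: int
    tetrapeptide: str


def scan_cxxc(
    seq: str,
    sequence_id: str = "",
    overlapping: bool = True,
    strict_x: bool = False,
) -> list[MotifHit]:
    """All CXXC motifs in an ungapped protein sequence.

    ``strict_x`` excludes cysteine at the two middle positions.  With
    ``overlapping=False`` hits are selected greedily left to right so that
    no two selected tetrapeptides share a residue.
    """
    if GAP in seq:
        raise InputError(
            f"sequence {sequence_id or '<anonymous>'} contains gap characters; "
            "degap before motif scanning"
        )
    seq = seq.upper()
    hits: list[MotifHit] = []
    last_end = -1  # exclusive end (0-based) of last selected hit
    for i in range(len(seq) - 3):
        if seq[i] != "C" or seq[i + 3] != "C":
            continue
        if strict_x and "C" in seq[i + 1 : i + 3]:
            continue
        if not overlapping and i < last_end:
            continue
        hits.append(MotifHit(sequence_id, i + 1, seq[i : i + 4]))
        last_end = i + 4
    return hits


def count_motifs(
    proteins: Mapping[str, str],
    overlapping: bool = True,
    strict_x: bool = False,
) -> pd.DataFrame:
    """Per-protein CXXC counts, sorted by descending count then id.

    Zero-count proteins are retained — absence of the motif is itself
    informative when surveying a repair proteome.
    """
    rows = [
        {
            "sequence_id": sid,
            "length": len(seq),
            "cxxc_count": len(scan_cxxc(seq, sid, overlapping, strict_x)),
        }
        for sid, seq in proteins.items()
    ]
    df = pd.DataFrame(rows, columns=["sequence_id", "length", "cxxc_count"])
    if len(df):
        df = df.sort_values(
            ["cxxc_count", "sequence_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


def hits_table(proteins: Mapping[str, str], **kwargs) -> pd.DataFrame:
    """Flat table of every hit across a set of proteins."""
    rows = [
        {"sequence_id": h.sequence_id, "position": h.position,
         "tetrapeptide": h.tetrapeptide}
        for sid, seq in proteins.items()
        for h in scan_cxxc(seq, sid, **kwargs)
    ]
    return pd.DataFrame(rows, columns=["sequence_id", "position", "tetrapeptide"])


def read_fasta_proteins(path) -> dict[str, str]:
    """Plain protein FASTA → id→sequence mapping (order preserved)."""
    from Bio import SeqIO

    proteins: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in proteins:
            raise InputError(f"duplicate sequence id {rec.id!r} in {path}")
        proteins[rec.id] = str(rec.seq).upper()
    return proteins
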