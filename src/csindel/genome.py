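"""Gene neighborhoods, intergenic distances and operon prediction.

Bacterial genes that are co-transcribed sit in tandem on the same strand
with short intergenic gaps.  This module parses genome annotations, applies
the standard distance/strand heuristics for operon membership — consecutive
same-strand genes closer than a linkage threshold (default <200 bp) belong
to one transcription unit, overlapping coding regions always do, and two
adjacent predicted units separated by less than a merge threshold (default
<100 bp) are very likely one operon — and compares the gene arrangement
around an anchor family across genomes, the analysis used to establish that
a cluster such as uvrA1–dCSP-1–dsbA–dsbB is conserved across a clade.

Coordinates are 1-based inclusive throughout (GFF/GenBank convention); the
intergenic distance between genes *a* before *b* is ``start(b) − end(a) − 1``,
so abutting genes score 0 and overlapping genes score negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ComparabilityError, InputError, ParameterError

Strand = str  # '+' or '-'


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene: locus, placement, strand and family label."""

    locus_id: str
    genome_id: str
    contig: str
    strand: Strand
    start: int
    end: int
    family: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InputError(f"gene {self.locus_id!r}: strand must be '+' or '-'")
        if self.start < 1:
            raise InputError(f"gene {self.locus_id!r}: start must be >= 1")
        if self.end < self.start:
            raise InputError(
                f"gene {self.locus_id!r}: end {self.end} < start {self.start}"
            )


class GenomeAnnotation:
    """Ordered gene records of one genome, sorted by (contig, start)."""

    def __init__(self, genome_id: str, genes: Iterable[GeneRecord]) -> None:
        self.genome_id = genome_id
        self.genes = sorted(genes, key=lambda g: (g.contig, g.start, g.end))
        ids = [g.locus_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"{genome_id}: duplicate locus ids {dupes}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def contigs(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g.contig, None)
        return list(seen)

    def by_contig(self, contig: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.contig == contig]

    def find_family(self, family: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.family == family]


@dataclass
class OperonCall:
    """A predicted transcription unit: consecutive same-strand genes."""

    genome_id: str
    contig: str
    loci: list[str]
    families: list[str]
    strand: Strand
    gaps: list[int]  # intergenic bp between consecutive members; may be negative
    merged: bool = False

    def __len__(self) -> int:
        return len(self.loci)


@dataclass(frozen=True)
class Neighborhood:
    """Gene context around an anchor, orientation-normalised.

    ``context`` lists (family, strand, gap-to-previous) left-to-right with
    the anchor transcribed rightward; strands are relative to genomic '+'
    after normalisation, so the anchor always reads '+'.  ``found`` is
    False when the anchor family is absent from the genome.
    """

    genome_id: str
    anchor_family: str
    found: bool
    context: tuple[tuple[str, Strand, int | None], ...] = ()
    anchor_index: int = -1

    def arrangement(self) -> tuple[tuple[str, Strand], ...]:
        return tuple((fam, st) for fam, st, _ in self.context)


@dataclass(frozen=True)
class ArrangementSummary:
    reference: tuple[tuple[str, Strand], ...]
    matches: dict[str, bool]

    @property
    def n_match(self) -> int:
        return sum(self.matches.values())

    @property
    def n_total(self) -> int:
        return len(self.matches)


# ---------------------------------------------------------------------------
# annotation IO

_TSV_COLUMNS = ["genome", "contig", "locus", "family", "strand", "start", "end"]


def read_annotation(
    path: str | Path,
    format: str = "tsv",
    genome_id: str | None = None,
    family_map: Mapping[str, str] | None = None,
) -> GenomeAnnotation:
    """Read one genome's gene table from GFF3, an NCBI feature table, or TSV.

    ``family_map`` assigns ortholog-family labels by locus id when the file
    itself carries none.  Records lacking coordinates or strand raise an
    error naming the locus; unsorted input is sorted, not rejected.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if format == "tsv":
        return _read_tsv(path, genome_id, family_map)
    if format == "gff3":
        return _read_gff3(path, genome_id, family_map)
    if format == "genbank_feature_table":
        return _read_feature_table(path, genome_id, family_map)
    raise ParameterError(f"unknown annotation format {format!r}")


def _apply_family(locus: str, fam: str, family_map: Mapping[str, str] | None) -> str:
    if family_map and locus in family_map:
        return family_map[locus]
    return fam


def _read_tsv(
    path: Path, genome_id: str | None, family_map: Mapping[str, str] | None
) -> GenomeAnnotation:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        if pd.isna(row.strand) or pd.isna(row.start) or pd.isna(row.end):
            raise InputError(f"{path}: locus {row.locus!r} lacks strand/coordinates")
        genes.append(
            GeneRecord(
                locus_id=row.locus,
                genome_id=genome_id or row.genome,
                contig=row.contig,
                strand=row.strand,
                start=int(row.start),
                end=int(row.end),
                family=_apply_family(row.locus, row.family or "", family_map),
            )
        )
    gid = genome_id or (genes[0].genome_id if genes else path.stem)
    return GenomeAnnotation(gid, genes)


def _read_gff3(
    path: Path, genome_id: str | None, family_map: Mapping[str, str] | None
) -> GenomeAnnotation:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    gid = genome_id or path.stem
    genes = []
    for feat in db.features_of_type(("gene", "CDS")):
        if feat.featuretype == "CDS" and any(
            p.featuretype == "gene" for p in db.parents(feat)
        ):
            continue  # gene line already covers it
        locus = (
            feat.attributes.get("locus_tag", [None])[0]
            or feat.attributes.get("ID", [feat.id])[0]
        )
        if feat.strand not in ("+", "-"):
            raise InputError(f"{path}: locus {locus!r} lacks a strand")
        fam = (
            feat.attributes.get("family", [""])[0]
            or feat.attributes.get("gene", [""])[0]
        )
        genes.append(
            GeneRecord(
                locus_id=locus,
                genome_id=gid,
                contig=feat.seqid,
                strand=feat.strand,
                start=feat.start,
                end=feat.end,
                family=_apply_family(locus, fam, family_map),
            )
        )
    return GenomeAnnotation(gid, genes)


def _read_feature_table(
    path: Path, genome_id: str | None, family_map: Mapping[str, str] | None
) -> GenomeAnnotation:
    """NCBI assembly *_feature_table.txt (tab-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lstrip("# ") for c in df.columns]
    needed = {"feature", "genomic_accession", "start", "end", "strand", "locus_tag"}
    missing = needed - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing feature-table columns {sorted(missing)}")
    df = df[df["feature"] == "gene"]
    gid = genome_id or path.stem
    genes = []
    for row in df.itertuples(index=False):
        if pd.isna(row.strand) or pd.isna(row.start) or pd.isna(row.end):
            raise InputError(f"{path}: locus {row.locus_tag!r} lacks strand/coordinates")
        fam = getattr(row, "symbol", "") or ""
        if pd.isna(fam):
            fam = ""
        genes.append(
            GeneRecord(
                locus_id=row.locus_tag,
                genome_id=gid,
                contig=row.genomic_accession,
                strand=row.strand,
                start=int(row.start),
                end=int(row.end),
                family=_apply_family(row.locus_tag, fam, family_map),
            )
        )
    return GenomeAnnotation(gid, genes)


def write_annotation_tsv(ann: GenomeAnnotation, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "genome": g.genome_id,
                "contig": g.contig,
                "locus": g.locus_id,
                "family": g.family,
                "strand": g.strand,
                "start": g.start,
                "end": g.end,
            }
            for g in ann.genes
        ],
        columns=_TSV_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# analyses


def intergenic_distance(a: GeneRecord, b: GeneRecord) -> int:
    """Base pairs between ``a`` and the following gene ``b``.

    ``start(b) − end(a) − 1``: 0 for abutting genes, negative when the
    coding regions overlap (itself a strong operon signal).
    """
    if a.contig != b.contig or a.genome_id != b.genome_id:
        raise ComparabilityError(
            f"{a.locus_id} and {b.locus_id} are on different contigs/genomes"
        )
    return b.start - a.end - 1


def predict_operons(
    ann: GenomeAnnotation, linkage_bp: int = 200, merge_bp: int = 100
) -> list[OperonCall]:
    """Partition each contig's genes into predicted transcription units.

    Two consecutive genes stay in one unit iff they share a strand and
    their intergenic distance is strictly below ``linkage_bp`` (overlaps,
    i.e. negative distances, always link).  ``merge_bp`` is not applied
    here — it governs :func:`merge_adjacent_operons`, which joins adjacent
    externally supplied units — so a strand-consistent gap of
    ``linkage_bp`` or more always starts a new call.
    """
    if linkage_bp <= 0:
        raise ParameterError("linkage_bp must be positive")
    calls: list[OperonCall] = []
    for contig in ann.contigs():
        genes = ann.by_contig(contig)
        run: list[GeneRecord] = []
        gaps: list[int] = []
        for gene in genes:
            if run:
                gap = intergenic_distance(run[-1], gene)
                if gene.strand == run[-1].strand and gap < linkage_bp:
                    run.append(gene)
                    gaps.append(gap)
                    continue
                calls.append(_call_from_run(ann.genome_id, contig, run, gaps))
            run, gaps = [gene], []
        if run:
            calls.append(_call_from_run(ann.genome_id, contig, run, gaps))
    return calls


def _call_from_run(
    genome_id: str, contig: str, run: list[GeneRecord], gaps: list[int]
) -> OperonCall:
    return OperonCall(
        genome_id=genome_id,
        contig=contig,
        loci=[g.locus_id for g in run],
        families=[g.family for g in run],
        strand=run[0].strand,
        gaps=gaps,
    )


def merge_adjacent_operons(
    ann: GenomeAnnotation, calls: Sequence[OperonCall], merge_bp: int = 100
) -> list[OperonCall]:
    """Join adjacent predicted units separated by less than ``merge_bp``.

    Externally predicted operon tables sometimes split one transcription
    unit in two; when the neighbouring units share contig and strand and
    the boundary gap is under ``merge_bp``, they very likely form a single
    operon.  Joined calls carry ``merged=True``.
    """
    by_locus = {g.locus_id: g for g in ann.genes}
    merged: list[OperonCall] = []
    for call in calls:
        if merged:
            prev = merged[-1]
            if prev.contig == call.contig and prev.strand == call.strand:
                gap = intergenic_distance(by_locus[prev.loci[-1]], by_locus[call.loci[0]])
                if gap < merge_bp:
                    merged[-1] = OperonCall(
                        genome_id=prev.genome_id,
                        contig=prev.contig,
                        loci=prev.loci + call.loci,
                        families=prev.families + call.families,
                        strand=prev.strand,
                        gaps=prev.gaps + [gap] + call.gaps,
                        merged=True,
                    )
                    continue
        merged.append(call)
    return merged


def extract_neighborhood(
    ann: GenomeAnnotation, anchor_family: str, k: int = 3
) -> list[Neighborhood]:
    """Gene context (up to ``k`` genes each side) around every anchor copy.

    The window is taken in genomic order on the anchor's contig and then
    orientation-normalised: when the anchor lies on '−', the window is
    reversed and strands flipped so that the anchor reads left-to-right —
    downstream genes therefore always appear to the anchor's right.
    """
    anchors = ann.find_family(anchor_family)
    if not anchors:
        return [Neighborhood(ann.genome_id, anchor_family, found=False)]
    results = []
    for anchor in anchors:
        contig_genes = ann.by_contig(anchor.contig)
        idx = contig_genes.index(anchor)
        lo, hi = max(0, idx - k), min(len(contig_genes), idx + k + 1)
        window = contig_genes[lo:hi]
        between = [intergenic_distance(a, b) for a, b in zip(window, window[1:])]
        if anchor.strand == "-":
            # flip so the anchor reads left-to-right: reverse order and strands
            window = window[::-1]
            between = between[::-1]
            flip = {"+": "-", "-": "+"}
            strands = [flip[g.strand] for g in window]
            anchor_idx = len(window) - 1 - (idx - lo)
        else:
            strands = [g.strand for g in window]
            anchor_idx = idx - lo
        gaps: list[int | None] = [None] + between
        context = tuple(
            (g.family, st, gap) for g, st, gap in zip(window, strands, gaps)
        )
        results.append(
            Neighborhood(ann.genome_id, anchor_family, True, context, anchor_idx)
        )
    return results


def compare_arrangements(
    neighborhoods: Mapping[str, Neighborhood],
    reference: Sequence[tuple[str, Strand]],
    anchored: bool = True,
) -> ArrangementSummary:
    """Count genomes whose (family, strand) arrangement equals the reference.

    With ``anchored=True`` (the default, and the usual survey question:
    "is the cluster organised identically downstream of the anchor?") the
    genome's arrangement is taken from the anchor onward and must equal
    the reference exactly, element for element.  With ``anchored=False``
    the entire extracted window must match.  An empty reference matches
    every genome vacuously; genomes lacking the anchor never match
    otherwise.
    """
    ref = tuple((f, s) for f, s in reference)
    matches = {}
    for genome_id, nb in neighborhoods.items():
        if not ref:
            matches[genome_id] = True
            continue
        if not nb.found:
            matches[genome_id] = False
            continue
        arr = nb.arrangement()
        if anchored:
            arr = arr[nb.anchor_index : nb.anchor_index + len(ref)]
        matches[genome_id] = arr == ref
    return ArrangementSummary(ref, matches)


def operon_table(calls: Sequence[OperonCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome": c.genome_id,
                "contig": c.contig,
                "strand": c.strand,
                "n_genes": len(c),
                "loci": ",".join(c.loci),
                "families": ",".join(c.families),
                "gaps_bp": ",".join(str(g) for g in c.gaps),
                "merged": c.merged,
            }
            for c in calls
        ],
        columns=[
            "genome", "contig", "strand", "n_genes", "loci", "families",
            "gaps_bp", "merged",
        ],
    )


def arrangement_table(summary: ArrangementSummary) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"genome": g, "matches_reference": m}
            for g, m in sorted(summary.matches.items())
        ],
        columns=["genome", "matches_reference"],
    )
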