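"""Ground-truthed synthetic inputs for every pipeline stage.

Real signature-indel surveys start from database retrievals that cannot be
reproduced offline, so verification here rests on simulators whose planted
signals are known exactly:

* :func:`gen_family_alignment` — a protein-family alignment with invariant
  ("conserved") columns, per-sequence substitution noise in the variable
  columns, and an optional planted clade-restricted insertion or deletion
  wrapped in forced-conserved flanks; the layout mimics what a curated
  signature alignment looks like (conserved blocks surrounding a
  group-differential gap region).
* :func:`gen_genome_set` — a set of genome gene tables in which a chosen
  subset of genomes carries a same-strand gene cluster with small
  intergenic gaps downstream of an anchor gene, and the rest carry the
  anchor with a different neighborhood (mirroring the minority genomes in
  which a conserved operon is rearranged).
* :func:`gen_proteome_with_motifs` — proteins whose CXXC count is exact by
  construction (background residues exclude cysteine).

Each generator is a pure function of its config, including the seed, and
returns a truth object sufficient to verify detection output exactly.

The i.i.d. column model is deliberately simple — invariant columns plus
independent per-sequence substitutions, no phylogeny, no indel drift — so
ground truth stays exact; see the methods note for what this does and does
not exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .alignment import AMINO_ACIDS, GAP, Alignment, SequenceRecord, TaxonPartition
from .errors import ConfigError
from .genome import GeneRecord, GenomeAnnotation

_AA = np.array(list(AMINO_ACIDS))
_AA_NO_C = np.array([a for a in AMINO_ACIDS if a != "C"])


@dataclass(frozen=True)
class PlantedIndel:
    """Specification of a clade-restricted indel to plant.

    ``reference_position`` is the 1-based position, in the *residue-bearing*
    protein, of the first indel residue (the in-group reference for an
    insertion; the out-group sequence for a deletion).  ``ragged_range``
    draws per-in-group-sequence insert lengths uniformly from an inclusive
    range (gap-padded on the right), emulating inserts whose length varies
    within the clade.
    """

    indel_type: Literal["insertion", "deletion"] = "insertion"
    reference_position: int = 300
    length: int = 30
    ragged_range: tuple[int, int] | None = None


@dataclass(frozen=True)
class FamilySimConfig:
    """Study conditions for one simulated protein family.

    Defaults model a typical curated signature alignment: 24 in-group and
    12 out-group homologs, a 600-residue protein, half the columns
    invariant, and a 0.3 per-sequence substitution probability in variable
    columns.  ``flank_conserved_run`` columns on each side of a planted
    indel are forced invariant so the planted signal satisfies the flank
    criterion by construction.  ``shared_gap_blocks`` plants gap blocks
    carried by half of *each* group — gaps that exist but are not
    group-differential, the null case for the detector.
    """

    seed: int = 0
    n_ingroup: int = 24
    n_outgroup: int = 12
    protein_length: int = 600
    conserved_fraction: float = 0.5
    substitution_prob: float = 0.3
    planted_indel: PlantedIndel | None = PlantedIndel()
    flank_conserved_run: int = 6
    shared_gap_blocks: int = 0
    shared_gap_length: int = 4

    def __post_init__(self) -> None:
        if self.n_ingroup < 2 or self.n_outgroup < 2:
            raise ConfigError("need at least 2 sequences per group")
        if not 0 <= self.conserved_fraction <= 1:
            raise ConfigError("conserved_fraction not in [0, 1]")
        if not 0 <= self.substitution_prob <= 1:
            raise ConfigError("substitution_prob not in [0, 1]")
        p = self.planted_indel
        if p is not None:
            if p.length < 1:
                raise ConfigError("planted indel length must be >= 1")
            if p.reference_position < 1:
                raise ConfigError("planted indel position must be >= 1")
            if p.indel_type == "insertion" and (
                p.reference_position + p.length - 1 > self.protein_length
            ):
                raise ConfigError("planted insertion overruns the protein")
            if p.indel_type == "deletion" and p.reference_position > self.protein_length:
                raise ConfigError("planted deletion point outside the protein")
            if p.ragged_range is not None:
                lo, hi = p.ragged_range
                if not 1 <= lo <= hi <= p.length:
                    raise ConfigError("ragged_range must satisfy 1 <= lo <= hi <= length")


@dataclass(frozen=True)
class FamilyTruth:
    """Exact record of the planted signal in one simulated family."""

    seed: int
    columns: tuple[int, int] | None  # half-open alignment columns of the indel
    indel_type: str | None
    size_min: int | None
    size_max: int | None
    reference_position: int | None  # 1-based in-group-reference coordinate
    per_sequence_lengths: dict[str, int] = field(default_factory=dict)


def gen_family_alignment(
    cfg: FamilySimConfig,
) -> tuple[Alignment, TaxonPartition, FamilyTruth]:
    """Simulate a gapped protein-family alignment with exact ground truth.

    Insertions occupy alignment columns that are reference-protein
    positions (out-group rows gapped); deletions add extra columns carried
    by the out-group only, placed after ``reference_position`` of the
    in-group reference.  Identical configs give byte-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    p = cfg.planted_indel
    n_in, n_out = cfg.n_ingroup, cfg.n_outgroup
    n_seq = n_in + n_out

    if p is None:
        n_cols = cfg.protein_length
        indel_cols: tuple[int, int] | None = None
    elif p.indel_type == "insertion":
        n_cols = cfg.protein_length
        start = p.reference_position - 1
        indel_cols = (start, start + p.length)
    else:  # deletion: out-group carries extra columns after the ref position
        n_cols = cfg.protein_length + p.length
        indel_cols = (p.reference_position, p.reference_position + p.length)

    # column scaffold: base residue everywhere, then choose invariant columns
    base = rng.choice(_AA, size=n_cols)
    free = np.ones(n_cols, dtype=bool)
    if indel_cols is not None:
        s, e = indel_cols
        free[s:e] = False
        run = cfg.flank_conserved_run
        forced_lo = max(0, s - run)
        forced_hi = min(n_cols, e + run)
    else:
        forced_lo = forced_hi = 0

    n_conserved = int(round(cfg.conserved_fraction * n_cols))
    conserved = np.zeros(n_cols, dtype=bool)
    if indel_cols is not None:
        conserved[forced_lo:indel_cols[0]] = True
        conserved[indel_cols[1]:forced_hi] = True
    pool = np.flatnonzero(free & ~conserved)
    extra = max(0, n_conserved - int(conserved.sum()))
    if extra and len(pool):
        pick = rng.choice(pool, size=min(extra, len(pool)), replace=False)
        conserved[pick] = True

    # substitution noise: common random numbers so that raising
    # substitution_prob only ever adds substitutions
    u = rng.random((n_seq, n_cols))
    shift = rng.integers(1, len(_AA), size=(n_seq, n_cols))
    base_idx = np.searchsorted(_AA, base)
    sub_idx = (base_idx[None, :] + shift) % len(_AA)
    matrix = np.tile(base, (n_seq, 1))
    mutate = (u < cfg.substitution_prob) & ~conserved[None, :]
    if indel_cols is not None:
        mutate[:, indel_cols[0]:indel_cols[1]] = False
    matrix[mutate] = _AA[sub_idx[mutate]]

    in_ids = [f"in{i+1:02d}" for i in range(n_in)]
    out_ids = [f"out{i+1:02d}" for i in range(n_out)]
    ref_id = in_ids[0]
    truth_lengths: dict[str, int] = {}
    ref_position: int | None = None

    if indel_cols is not None:
        s, e = indel_cols
        length = e - s
        if p.indel_type == "insertion":
            # in-group carries residues, out-group is gapped
            if p.ragged_range is not None:
                lo, hi = p.ragged_range
                lens = rng.integers(lo, hi + 1, size=n_in)
                lens[0] = hi  # the reference always spans the full interval
            else:
                lens = np.full(n_in, length)
            for row, L in enumerate(lens):
                matrix[row, s + int(L):e] = GAP
                truth_lengths[in_ids[row]] = int(L)
            matrix[n_in:, s:e] = GAP
            for oid in out_ids:
                truth_lengths[oid] = 0
            size_min, size_max = int(lens.min()), int(lens.max())
            ref_position = p.reference_position
        else:
            # out-group carries residues, in-group is gapped
            matrix[:n_in, s:e] = GAP
            for iid in in_ids:
                truth_lengths[iid] = 0
            for oid in out_ids:
                truth_lengths[oid] = length
            size_min = size_max = length
            ref_position = p.reference_position  # residue preceding the gap

    # shared (non-differential) gap blocks: carried by half of each group
    if cfg.shared_gap_blocks:
        usable = np.flatnonzero(free & ~conserved)
        if indel_cols is not None:
            s, e = indel_cols
            usable = usable[(usable < forced_lo - cfg.shared_gap_length)
                            | (usable >= forced_hi + cfg.shared_gap_length)]
        for _ in range(cfg.shared_gap_blocks):
            if not len(usable):
                break
            c0 = int(rng.choice(usable))
            c1 = min(c0 + cfg.shared_gap_length, n_cols)
            carriers = np.concatenate([
                rng.choice(n_in, size=n_in // 2, replace=False),
                n_in + rng.choice(n_out, size=n_out // 2, replace=False),
            ])
            matrix[carriers, c0:c1] = GAP
            usable = usable[(usable < c0 - cfg.shared_gap_length)
                            | (usable >= c1 + cfg.shared_gap_length)]

    records = [
        SequenceRecord(id=rid, residues="".join(matrix[i]), taxon="ingroup")
        for i, rid in enumerate(in_ids)
    ] + [
        SequenceRecord(id=rid, residues="".join(matrix[n_in + i]), taxon="outgroup")
        for i, rid in enumerate(out_ids)
    ]
    aln = Alignment(records, name=f"family_seed{cfg.seed}")
    part = TaxonPartition(frozenset(in_ids), frozenset(out_ids), ref_id)
    truth = FamilyTruth(
        seed=cfg.seed,
        columns=indel_cols,
        indel_type=p.indel_type if p else None,
        size_min=size_min if indel_cols else None,
        size_max=size_max if indel_cols else None,
        reference_position=ref_position,
        per_sequence_lengths=truth_lengths,
    )
    return aln, part, truth


# ---------------------------------------------------------------------------
# genome sets


@dataclass(frozen=True)
class GenomeSimConfig:
    """Study conditions for a simulated genome panel.

    Defaults emulate a 26-genome clade survey in which 24 genomes carry a
    conserved four-gene same-strand cluster (anchor + three downstream
    partners) with intergenic gaps of 5–99 bp, while the remaining genomes
    keep the anchor linked to the second family only, followed by
    genome-specific genes — the pattern seen when a conserved operon is
    partially rearranged in a minority of genomes.
    """

    seed: int = 0
    n_genomes: int = 26
    n_with_cluster: int = 24
    cluster_families: tuple[tuple[str, str], ...] = (
        ("uvrA1", "+"), ("dCSP-1", "+"), ("dsbA", "+"), ("dsbB", "+"),
    )
    intergenic_gap_range: tuple[int, int] = (5, 99)
    background_genes_per_genome: int = 8
    background_gap_range: tuple[int, int] = (200, 1500)
    gene_length_range: tuple[int, int] = (300, 1800)
    overlap_gap: int | None = None  # plant this (negative) gap at one pair
    overlap_pair_index: int = 0
    flip_strand_genomes: tuple[int, ...] = ()  # cluster on '-' in these genomes

    def __post_init__(self) -> None:
        if self.n_with_cluster > self.n_genomes:
            raise ConfigError("n_with_cluster exceeds n_genomes")
        if len(self.cluster_families) < 2:
            raise ConfigError("cluster needs at least 2 families")
        lo, hi = self.intergenic_gap_range
        if lo > hi or (lo < 0 and self.overlap_gap is None):
            raise ConfigError("bad intergenic_gap_range")
        if self.overlap_gap is not None and not (
            0 <= self.overlap_pair_index < len(self.cluster_families) - 1
        ):
            raise ConfigError("overlap_pair_index outside the cluster")


@dataclass(frozen=True)
class GenomeTruth:
    """Planted layout of a simulated genome panel."""

    seed: int
    cluster_genomes: tuple[str, ...]
    cluster_gaps: dict[str, tuple[int, ...]]
    reference_arrangement: tuple[tuple[str, str], ...]


def gen_genome_set(cfg: GenomeSimConfig) -> tuple[list[GenomeAnnotation], GenomeTruth]:
    """Simulate a genome panel with a planted conserved gene cluster."""
    rng = np.random.default_rng(cfg.seed)
    anchor_family = cfg.cluster_families[0][0]
    genomes: list[GenomeAnnotation] = []
    cluster_gaps: dict[str, tuple[int, ...]] = {}
    genome_ids = [f"G{i+1:02d}" for i in range(cfg.n_genomes)]
    cluster_ids = genome_ids[: cfg.n_with_cluster]

    for gi, gid in enumerate(genome_ids):
        has_cluster = gi < cfg.n_with_cluster
        flipped = gi in cfg.flip_strand_genomes
        if has_cluster:
            inner = list(cfg.cluster_families)
        else:
            # anchor keeps only its immediate partner; the rest is replaced
            # by genome-specific decoys
            inner = [cfg.cluster_families[0], cfg.cluster_families[1]] + [
                (f"{gid}_orf{j}", "+") for j in range(len(cfg.cluster_families) - 2)
            ]
        gaps = [
            int(rng.integers(cfg.intergenic_gap_range[0],
                             cfg.intergenic_gap_range[1] + 1))
            for _ in range(len(inner) - 1)
        ]
        if has_cluster and cfg.overlap_gap is not None:
            gaps[cfg.overlap_pair_index] = cfg.overlap_gap
        if has_cluster:
            cluster_gaps[gid] = tuple(gaps)

        n_bg = cfg.background_genes_per_genome
        n_up = n_bg // 2
        layout: list[tuple[str, str, int | None]] = []  # (family, strand, gap-before)
        for j in range(n_up):
            layout.append((f"{gid}_bg{j}", "+" if rng.random() < 0.5 else "-", None))
        for j, (fam, st) in enumerate(inner):
            layout.append((fam, st, gaps[j - 1] if j > 0 else None))
        for j in range(n_up, n_bg):
            layout.append((f"{gid}_bg{j}", "+" if rng.random() < 0.5 else "-", None))

        if flipped:
            # place the whole neighborhood on the reverse strand: reverse
            # order and complement strands, keeping physical gaps
            flip = {"+": "-", "-": "+"}
            rev = [(fam, flip[st]) for fam, st, _ in layout][::-1]
            fwd_gaps = [g for _, _, g in layout][1:]
            all_gaps = [
                g if g is not None else int(rng.integers(*cfg.background_gap_range))
                for g in fwd_gaps
            ][::-1]
            layout = [(rev[0][0], rev[0][1], None)] + [
                (fam, st, gap) for (fam, st), gap in zip(rev[1:], all_gaps)
            ]

        pos = 1 + int(rng.integers(0, 5000))
        genes = []
        for k, (fam, st, gap) in enumerate(layout):
            if k > 0:
                gap = gap if gap is not None else int(
                    rng.integers(*cfg.background_gap_range)
                )
                pos = genes[-1].end + gap + 1
            length = int(rng.integers(*cfg.gene_length_range))
            genes.append(
                GeneRecord(
                    locus_id=f"{gid}_{k+1:04d}",
                    genome_id=gid,
                    contig="chr",
                    strand=st,
                    start=pos,
                    end=pos + length - 1,
                    family=fam,
                )
            )
        genomes.append(GenomeAnnotation(gid, genes))

    truth = GenomeTruth(
        seed=cfg.seed,
        cluster_genomes=tuple(cluster_ids),
        cluster_gaps=cluster_gaps,
        reference_arrangement=tuple(cfg.cluster_families),
    )
    return genomes, truth


# ---------------------------------------------------------------------------
# proteomes with planted CXXC counts


def gen_proteome_with_motifs(
    seed: int, spec: Mapping[str, tuple[int, int]]
) -> tuple[dict[str, str], dict[str, tuple[int, ...]]]:
    """Proteins with exactly the requested CXXC counts.

    ``spec`` maps protein id → (motif count, length).  Background residues
    exclude cysteine and motifs are planted on disjoint 4-residue tiles, so
    the planted count is the true count under any scanning policy.

    Returns the id→sequence mapping and a truth mapping id → planted
    1-based motif start positions.
    """
    rng = np.random.default_rng(seed)
    proteins: dict[str, str] = {}
    truth: dict[str, tuple[int, ...]] = {}
    for pid, (count, length) in spec.items():
        if count < 0 or length < 1 or 4 * count > length:
            raise ConfigError(
                f"{pid}: cannot fit {count} disjoint CXXC motifs in {length} residues"
            )
        seq = rng.choice(_AA_NO_C, size=length)
        n_tiles = length // 4
        tiles = rng.choice(n_tiles, size=count, replace=False)
        positions = []
        for t in sorted(int(x) for x in tiles):
            i = 4 * t
            seq[i] = "C"
            seq[i + 3] = "C"
            positions.append(i + 1)
        proteins[pid] = "".join(seq)
        truth[pid] = tuple(positions)
    return proteins, truth
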