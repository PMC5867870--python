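"""Generate the synthetic study inputs for the downstream analyses.

Writes, under results/data/:
  * three protein-family alignments (FASTA) with planted clade-specific
    insertions of 1, 16 and 30 residues — the size spectrum of published
    repair-protein signature indels — plus partition files and truth JSON;
  * a 26-genome panel in which 24 genomes carry the conserved
    uvrA1–dCSP-1–dsbA–dsbB cluster (same strand, 5–99 bp gaps) and two do
    not, plus truth JSON;
  * a proteome whose CXXC counts are planted (0–5 per protein).

Run: python analysis/01_simulate_inputs.py [--seed 1] [--outdir results/data]
"""

import argparse
import json
from pathlib import Path

from csindel.alignment import write_alignment, write_partition
from csindel.genome import write_annotation_tsv
from csindel.simulate import (
    FamilySimConfig,
    GenomeSimConfig,
    PlantedIndel,
    gen_family_alignment,
    gen_genome_set,
    gen_proteome_with_motifs,
)

FAMILIES = (  # (label, indel type, reference position, size)
    ("uvsE_like", "insertion", 80, 1),
    ("uvrC_like", "insertion", 470, 16),
    ("uvrA1_like", "insertion", 421, 30),
)

PROTEOME_SPEC = {  # planted CXXC count, protein length
    "repairA": (5, 1000),
    "repairB": (2, 420),
    "repairC": (1, 350),
    "repairD": (0, 280),
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    truths = {}
    for i, (label, indel_type, pos, size) in enumerate(FAMILIES):
        cfg = FamilySimConfig(seed=args.seed * 100 + i,
                              planted_indel=PlantedIndel(indel_type, pos, size))
        aln, part, truth = gen_family_alignment(cfg)
        aln.name = label
        write_alignment(aln, out / f"{label}.fasta", "fasta")
        write_partition(part, out / f"{label}.partition.tsv")
        truths[label] = {"indel_type": truth.indel_type, "size": truth.size_max,
                         "reference_position": truth.reference_position,
                         "columns": truth.columns}
        print(f"family {label}: planted {size} aa {indel_type} at reference "
              f"position {pos}")
    (out / "families.truth.json").write_text(json.dumps(truths, indent=1))

    genomes, gtruth = gen_genome_set(GenomeSimConfig(seed=args.seed))
    gdir = out / "genomes"
    gdir.mkdir(exist_ok=True)
    for ann in genomes:
        write_annotation_tsv(ann, gdir / f"{ann.genome_id}.genes.tsv")
    (out / "genomes.truth.json").write_text(json.dumps({
        "cluster_genomes": list(gtruth.cluster_genomes),
        "cluster_gaps": {g: list(v) for g, v in gtruth.cluster_gaps.items()},
        "reference_arrangement": [list(t) for t in gtruth.reference_arrangement],
    }, indent=1))
    print(f"genome panel: {len(genomes)} genomes, "
          f"{len(gtruth.cluster_genomes)} carrying the planted cluster")

    proteins, ptruth = gen_proteome_with_motifs(args.seed, PROTEOME_SPEC)
    with open(out / "proteome.fasta", "w") as fh:
        for pid, seq in proteins.items():
            fh.write(f">{pid}\n{seq}\n")
    (out / "proteome.truth.json").write_text(json.dumps(
        {p: list(v) for p, v in ptruth.items()}, indent=1))
    print(f"proteome: {len(proteins)} proteins, planted CXXC counts "
          f"{ {p: c for p, (c, _) in PROTEOME_SPEC.items()} }")
    print(f"inputs written to {out}")


if __name__ == "__main__":
    main()
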