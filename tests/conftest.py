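import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the shared oracles module

from csindel.alignment import Alignment, SequenceRecord, TaxonPartition


def make_alignment(rows: dict[str, str], name: str = "toy") -> Alignment:
    """Build an alignment from an id→residues mapping (order preserved)."""
    return Alignment(
        [SequenceRecord(id=k, residues=v) for k, v in rows.items()], name=name
    )


def make_partition(ingroup, outgroup, reference=None) -> TaxonPartition:
    return TaxonPartition(
        frozenset(ingroup), frozenset(outgroup), reference or sorted(ingroup)[0]
    )


@pytest.fixture
def toy_family():
    """5 in-group + 3 out-group, 30-residue backbone, 4-residue in-group insert.

    Columns 13..17 carry residues in the in-group only; everything else is
    invariant, so flanks are maximally conserved.
    """
    backbone = "MKLVADERTGWYN" + "FHQS" + "PCILMKAVDERTG"
    gapped = backbone[:13] + "----" + backbone[17:]
    rows = {f"in{i}": backbone for i in range(1, 6)}
    rows.update({f"out{i}": gapped for i in range(1, 4)})
    aln = make_alignment(rows, name="toy_family")
    part = make_partition([f"in{i}" for i in range(1, 6)],
                          [f"out{i}" for i in range(1, 4)], reference="in1")
    return aln, part
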