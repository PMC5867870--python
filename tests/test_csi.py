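"""Signature-indel detection: gap blocks, flanks, specificity, reporting."""

import numpy as np
import pytest

from csindel.csi import (
    DetectionParams,
    detect_csis,
    evaluate_flanks,
    evaluate_specificity,
    export_validation_segment,
    find_gap_blocks,
    format_signature,
    signature_to_residues,
)
from csindel.errors import ParameterError, PartitionError
from csindel.simulate import FamilySimConfig, PlantedIndel, gen_family_alignment
from conftest import make_alignment, make_partition
from oracles import gap_block_oracle, random_alignment


def _block_alignment(n_in=4, n_out=3, length=60, block=(10, 40)):
    """All-invariant backbone; columns block[0]:block[1] gapped in the out-group."""
    backbone = ("MKLVADERTGWYNFHQSPCI" * ((length + 19) // 20))[:length]
    s, e = block
    gapped = backbone[:s] + "-" * (e - s) + backbone[e:]
    rows = {f"in{i}": backbone for i in range(n_in)}
    rows.update({f"out{i}": gapped for i in range(n_out)})
    aln = make_alignment(rows)
    part = make_partition([f"in{i}" for i in range(n_in)],
                          [f"out{i}" for i in range(n_out)], "in0")
    return aln, part


class TestFindGapBlocks:
    def test_constructed_insertion_block(self):
        aln, part = _block_alignment(block=(10, 40))
        cands = find_gap_blocks(aln, part)
        assert len(cands) == 1
        c = cands[0]
        assert (c.start, c.end, c.indel_type) == (10, 40, "insertion")
        assert (c.size_min, c.size_max) == (30, 30)

    def test_ragged_ingroup_sizes(self):
        # one in-group sequence holds 5 of the 7 insert columns: range 5-7
        aln, part, truth = gen_family_alignment(
            FamilySimConfig(seed=11, planted_indel=PlantedIndel(
                "insertion", 300, 7, ragged_range=(5, 7)))
        )
        cands = find_gap_blocks(aln, part)
        assert len(cands) == 1
        assert (cands[0].size_min, cands[0].size_max) == (truth.size_min, truth.size_max)

    def test_no_differential_gaps(self):
        aln = make_alignment({"a": "MKLV", "b": "MKLV", "c": "MKLV", "d": "MKLV"})
        part = make_partition(["a", "b"], ["c", "d"])
        assert find_gap_blocks(aln, part) == []

    def test_partition_must_cover_alignment(self):
        aln, _ = _block_alignment()
        part = make_partition(["in0", "ghost"], ["out0"])
        with pytest.raises(PartitionError):
            find_gap_blocks(aln, part)

    def test_size_filter(self):
        aln, part = _block_alignment(block=(10, 40))
        assert find_gap_blocks(aln, part, DetectionParams(min_indel_size=31)) == []
        assert find_gap_blocks(
            aln, part, DetectionParams(min_indel_size=1, max_indel_size=29)
        ) == []

    @pytest.mark.parametrize(
        "params",
        [
            DetectionParams(),
            DetectionParams(max_ingroup_missing=0.3, max_outgroup_sharing=0.3),
            DetectionParams(allow_isolated_exception=True),
        ],
        ids=["strict", "tolerant", "isolated-exception"],
    )
    def test_matches_brute_force_enumeration(self, params):
        rng = np.random.default_rng(7)
        for _ in range(100):
            aln, part = random_alignment(rng)
            got = [
                (c.start, c.end, c.indel_type, c.size_min, c.size_max)
                for c in find_gap_blocks(aln, part, params)
            ]
            assert got == gap_block_oracle(aln, part, params)


class TestFlanks:
    def test_fully_conserved_flanks(self):
        aln, part = _block_alignment(length=110, block=(40, 70))
        cand = find_gap_blocks(aln, part)[0]
        rep = evaluate_flanks(aln, cand, part)
        assert rep.passed and (rep.left_count, rep.right_count) == (35, 35)

    @pytest.mark.parametrize("n_conserved,expected", [(5, True), (4, False)])
    def test_threshold_boundary(self, n_conserved, expected):
        # left flank of 35 columns with exactly n_conserved invariant ones;
        # the rest are split 50/50 and cannot reach the 0.8 threshold
        rng = np.random.default_rng(3)
        length, s, e = 110, 40, 70
        base = list("MKLVADERTGWYNFHQSPCI" * 6)[:length]
        rows = {}
        variable_left = rng.choice(np.arange(5, 40), size=35 - n_conserved, replace=False)
        for i in range(6):
            res = base.copy()
            for c in variable_left:
                res[c] = "A" if i % 2 else "G"
            rows[f"s{i}"] = "".join(res)
        for i in range(6, 9):
            res = base.copy()
            for c in variable_left:
                res[c] = "A" if i % 2 else "G"
            res[s:e] = "-" * (e - s)
            rows[f"s{i}"] = "".join(res)
        aln = make_alignment(rows)
        part = make_partition([f"s{i}" for i in range(6)],
                              [f"s{i}" for i in range(6, 9)], "s0")
        cand = find_gap_blocks(aln, part)[0]
        rep = evaluate_flanks(aln, cand, part)
        assert rep.left_count == n_conserved
        assert rep.passed is expected

    def test_edge_truncation_fails_left(self):
        aln, part = _block_alignment(length=60, block=(0, 10))
        cand = find_gap_blocks(aln, part)[0]
        rep = evaluate_flanks(aln, cand, part)
        assert rep.left_count == 0 and not rep.passed


class TestSpecificity:
    def test_strict_when_clean(self):
        aln, part = _block_alignment(n_in=24, n_out=12)
        cand = find_gap_blocks(aln, part)[0]
        assert evaluate_specificity(aln, cand, part).verdict == "strict"

    def test_isolated_exception_listed(self):
        aln, part = _block_alignment(n_in=6, n_out=12, block=(10, 40))
        # give one out-group sequence the insert too
        rows = {r.id: r.residues for r in aln}
        rows["out0"] = rows["in0"]
        aln2 = make_alignment(rows)
        params = DetectionParams(allow_isolated_exception=True)
        cand = find_gap_blocks(aln2, part, params)[0]
        verdict = evaluate_specificity(aln2, cand, part, params)
        assert verdict.verdict == "tolerant"
        assert verdict.outgroup_sharing == ("out0",)

    def test_rejected_beyond_tolerance(self):
        aln, part = _block_alignment(n_in=6, n_out=12, block=(10, 40))
        rows = {r.id: r.residues for r in aln}
        for k in range(3):
            rows[f"out{k}"] = rows["in0"]
        aln2 = make_alignment(rows)
        cand = find_gap_blocks(aln2, part, DetectionParams(max_outgroup_sharing=0.5))[0]
        assert evaluate_specificity(aln2, cand, part).verdict == "rejected"


class TestDetect:
    def test_recovers_planted_insertion(self):
        aln, part, truth = gen_family_alignment(
            FamilySimConfig(seed=5, planted_indel=PlantedIndel("insertion", 250, 16))
        )
        recs = detect_csis(aln, part)
        assert len(recs) == 1
        r = recs[0]
        assert r.indel_type == "insertion"
        assert (r.size_min, r.size_max) == (16, 16)
        assert r.indel_ref_start == truth.reference_position
        assert r.columns == truth.columns
        assert r.region_start <= r.indel_ref_start <= r.indel_ref_end <= r.region_end
        assert r.specificity.verdict == "strict"

    def test_recovers_planted_deletion(self):
        aln, part, truth = gen_family_alignment(
            FamilySimConfig(seed=6, planted_indel=PlantedIndel("deletion", 180, 2))
        )
        recs = detect_csis(aln, part)
        assert len(recs) == 1
        assert recs[0].indel_type == "deletion"
        assert (recs[0].size_min, recs[0].size_max) == (2, 2)
        assert recs[0].indel_ref_start == truth.reference_position

    def test_fully_conserved_alignment_yields_nothing(self):
        aln = make_alignment({f"s{i}": "MKLVADERTG" * 5 for i in range(6)})
        part = make_partition(["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert detect_csis(aln, part) == []

    def test_monotone_in_conservation_threshold(self):
        counts = []
        for thr in (0.6, 0.7, 0.8, 0.9, 1.0):
            n = 0
            for seed in range(6):
                aln, part, _ = gen_family_alignment(FamilySimConfig(
                    seed=seed, substitution_prob=0.35,
                    planted_indel=PlantedIndel("insertion", 200, 16)))
                n += len(detect_csis(aln, part,
                                     DetectionParams(conservation_threshold=thr)))
            counts.append(n)
        assert counts == sorted(counts, reverse=True)

    def test_monotone_in_min_conserved_flank(self):
        counts = []
        for k in (3, 5, 10, 20, 35):
            n = 0
            for seed in range(6):
                aln, part, _ = gen_family_alignment(FamilySimConfig(
                    seed=seed, substitution_prob=0.35, conserved_fraction=0.3,
                    planted_indel=PlantedIndel("insertion", 200, 16)))
                n += len(detect_csis(aln, part,
                                     DetectionParams(min_conserved_flank=k)))
            counts.append(n)
        assert counts == sorted(counts, reverse=True)


class TestValidationSegment:
    def test_centred_on_indel(self):
        aln, part, _ = gen_family_alignment(FamilySimConfig(
            seed=9, protein_length=400,
            planted_indel=PlantedIndel("insertion", 100, 30)))
        cand = find_gap_blocks(aln, part)[0]
        seg = export_validation_segment(aln, part, cand)
        ref = aln[part.reference_id].ungapped
        assert len(seg) == 80
        assert seg in ref
        # contains the full indel (reference positions 100-129)
        offset = ref.index(seg)
        assert offset + 1 <= 100 and offset + len(seg) >= 129

    def test_truncated_at_protein_start(self):
        aln, part = _block_alignment(length=200, block=(0, 10))
        cand = find_gap_blocks(aln, part)[0]
        seg = export_validation_segment(aln, part, cand)
        ref = aln[part.reference_id].ungapped
        assert seg == ref[:80]

    def test_short_protein_returns_whole_protein(self):
        aln, part = _block_alignment(length=60, block=(20, 30))
        cand = find_gap_blocks(aln, part)[0]
        seg = export_validation_segment(aln, part, cand)
        assert seg == aln[part.reference_id].ungapped

    def test_segment_length_clamped(self):
        with pytest.raises(ParameterError):
            DetectionParams(validation_segment_length=50)
        with pytest.raises(ParameterError):
            DetectionParams(validation_segment_length=120)


class TestSignature:
    def test_identical_row_is_all_dashes(self):
        aln = make_alignment({"ref": "MKLVADER", "twin": "MKLVADER",
                              "diff": "MKLVQDER"})
        part = make_partition(["ref", "twin"], ["diff"], "ref")
        text = format_signature(aln, part, (0, 8))
        lines = {l.split()[0]: l.split()[1] for l in text.splitlines()[1:]
                 if l and not l.startswith("=")}
        assert lines["twin"] == "-" * 8
        assert lines["diff"].count("Q") == 1
        assert sum(c != "-" for c in lines["diff"]) == 1

    def test_round_trip_reconstructs_residues(self):
        for seed in range(5):
            aln, part, _ = gen_family_alignment(FamilySimConfig(
                seed=seed, protein_length=300,
                planted_indel=PlantedIndel("insertion", 150, 12)))
            for rec in detect_csis(aln, part):
                rows = signature_to_residues(rec.signature_text)
                s, e = rec.columns
                assert set(rows) == set(aln.ids)
                for rid, residues in rows.items():
                    assert residues in aln[rid].residues
                    # the decoded excerpt must cover the indel columns
                    assert aln[rid].residues.index(residues) <= s

    def test_gap_opposite_reference_residue_uses_absent_char(self):
        aln = make_alignment({"ref": "MKLV", "hole": "MK-V"})
        part = make_partition(["ref"], ["hole"], "ref")
        text = format_signature(aln, part, (0, 4))
        row = [l for l in text.splitlines() if l.startswith("hole")][0].split()[1]
        assert row == "--.-"
        assert signature_to_residues(text)["hole"] == "MK-V"
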