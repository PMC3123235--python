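"""Unit splitting, per-unit alignment, indel classification, merge round trip."""

import shutil

import pytest

from mtphylo.alignment import Alignment
from mtphylo.annotation import ReferenceAnnotation, StructuralUnit
from mtphylo.partition import (IndelCall, UnitSlice, align_unit,
                               classify_indels, merge_units, split_by_units)
from mtphylo.pairwise import edit_distance, global_align
from mtphylo.sequences import Sequence
from mtphylo.synthdata import SynthSpec, generate


def toy_annotation():
    """60 bp reference: CR part, one 9-bp gene, gap, gene, CR part."""
    ref = Sequence("ref", "ACGTACGTAC" "GATTACAGGT" "TTTT"
                   "CCGGAATTCCGGAATTCCGGAATTCC" "ACGTACGTAC")
    units = [
        StructuralUnit("cr1", "control_region_part", 1, 10),
        StructuralUnit("geneA", "gene", 11, 19, coding=True),
        StructuralUnit("nc1", "noncoding_gap", 20, 24),
        StructuralUnit("geneB", "gene", 25, 50, coding=True),
        StructuralUnit("cr2", "control_region_part", 51, 60),
    ]
    return ReferenceAnnotation(ref, units, circular=True)


class TestSplit:
    def test_reference_split_against_itself_gives_annotated_substrings(self):
        ann = toy_annotation()
        ref = ann.reference
        slices = split_by_units(ref, ann)
        assert len(slices) == len(ann.units)
        for sl, u in zip(slices, ann.units):
            assert sl.residues == ref.residues[u.start - 1:u.end]

    def test_insertion_lengthens_only_its_unit(self):
        ann = toy_annotation()
        ref = ann.reference.residues
        # 3-bp insertion inside geneB (after reference position 30)
        seq = Sequence("q", ref[:30] + "AAA" + ref[30:])
        slices = {sl.unit_name: sl for sl in split_by_units(seq, ann)}
        base = {u.name: ref[u.start - 1:u.end] for u in ann.units}
        assert len(slices["geneB"].residues) == len(base["geneB"]) + 3
        for name in ("cr1", "geneA", "nc1", "cr2"):
            assert slices[name].residues == base[name]

    def test_missing_control_region_yields_empty_flagged_slices(self):
        ann = toy_annotation()
        ref = ann.reference.residues
        seq = Sequence("q", ref[10:50])  # control region absent
        slices = {sl.unit_name: sl for sl in split_by_units(seq, ann)}
        assert slices["cr1"].empty and slices["cr2"].empty
        assert not slices["geneA"].empty

    def test_declared_adjacent_overlap_is_carried_in_both_slices(self):
        ref = Sequence("ref", "A" * 30)
        ann = ReferenceAnnotation(ref, [
            StructuralUnit("g1", "gene", 1, 12, coding=True),
            StructuralUnit("g2", "gene", 10, 30, coding=True),
        ])
        slices = split_by_units(ref, ann)
        assert slices[0].right_overlap == 3
        assert slices[1].left_overlap == 3
        assert len(slices[0].residues) == 12
        assert len(slices[1].residues) == 21


class TestAlignUnit:
    def _slices(self, residues_list):
        return [UnitSlice(f"s{i}", "u", r) for i, r in enumerate(residues_list)]

    def test_identical_slices_align_gap_free(self):
        aln = align_unit(self._slices(["ACGTACGT"] * 4))
        assert all("-" not in row for row in aln.rows.values())

    def test_single_substitution_stays_gap_free(self):
        aln = align_unit(self._slices(["ACGTACGT", "ACGTACAT"]))
        assert all("-" not in row for row in aln.rows.values())
        assert edit_distance(aln.rows["s0"], aln.rows["s1"]) == 1

    def test_rows_degap_to_inputs(self):
        slices = self._slices(["ACGTAACGT", "ACGTACGT", "ACGGT"])
        aln = align_unit(slices)
        for sl in slices:
            assert aln.degapped(sl.sequence_id) == sl.residues

    @pytest.mark.skipif(shutil.which("mafft") is None,
                        reason="external aligner not installed")
    def test_internal_engine_cost_close_to_external(self, rng):
        # paired comparison on generated unit-sized data
        ratios = []
        for seed in range(5):
            res = generate(SynthSpec(n_leaves=10, seed=seed))
            ref = res.annotation.reference
            unit = res.annotation.unit("gene2")
            slices = [UnitSlice(s.id, "gene2",
                                s.residues[unit.start - 1:unit.end])
                      for s in res.clean_dataset]
            slices.append(UnitSlice(ref.id, "gene2",
                                    ref.residues[unit.start - 1:unit.end]))
            internal = align_unit(slices, center_id=ref.id)
            external = align_unit(slices, engine="mafft")

            def cost(aln):
                ids = aln.ids
                return sum(edit_distance(aln.rows[a], aln.rows[b])
                           for i, a in enumerate(ids) for b in ids[i + 1:])

            ext = cost(external)
            ratios.append(cost(internal) / max(ext, 1))
        assert max(ratios) <= 1.2

    def test_missing_external_engine_suggests_fallback(self):
        with pytest.raises(RuntimeError, match="internal"):
            align_unit(self._slices(["ACGT", "ACGA"]),
                       engine="definitely_not_an_aligner")

    def test_fewer_than_two_nonempty_slices_rejected(self):
        with pytest.raises(ValueError):
            align_unit([UnitSlice("a", "u", "ACGT"), UnitSlice("b", "u", "")])


class TestClassifyIndels:
    def _unit(self):
        return StructuralUnit("g", "gene", 1, 9, coding=True)

    def test_codon_sized_gap_at_codon_start_is_codon_full(self):
        aln = Alignment.from_rows([("ref", "ACGTTTACG"),
                                   ("q", "ACG---ACG")])
        calls = classify_indels(aln, self._unit(), "ref")
        assert calls == [IndelCall("g", "q", 4, 3, "codon_full")]

    def test_two_bp_gap_is_frameshift(self):
        aln = Alignment.from_rows([("ref", "ACGTTTACG"),
                                   ("q", "ACGT--ACG")])
        calls = classify_indels(aln, self._unit(), "ref")
        assert calls[0].kind == "frameshift" and calls[0].length == 2

    def test_codon_sized_gap_off_boundary_is_frameshift(self):
        # hand-checked on this 9-bp toy gene: run starts mid-codon (pos 5)
        aln = Alignment.from_rows([("ref", "ACGTTTACG"),
                                   ("q", "ACGT---CG")])
        calls = classify_indels(aln, self._unit(), "ref")
        assert calls == [IndelCall("g", "q", 5, 3, "frameshift")]

    def test_insertion_between_codons_is_codon_full(self):
        aln = Alignment.from_rows([("ref", "ACG---TTTACG"),
                                   ("q", "ACGAAATTTACG")])
        calls = classify_indels(aln, self._unit(), "ref")
        assert calls == [IndelCall("g", "q", 3, 3, "codon_full",
                                   insertion=True)]

    def test_noncoding_unit_events_are_noncoding(self):
        unit = StructuralUnit("nc", "noncoding_gap", 1, 9)
        aln = Alignment.from_rows([("ref", "ACGTTTACG"),
                                   ("q", "ACG---ACG")])
        calls = classify_indels(aln, unit, "ref")
        assert calls[0].kind == "noncoding"

    def test_kinds_partition_all_gap_runs(self, rng):
        unit = StructuralUnit("g", "gene", 1, 30, coding=True)
        ref = "".join(rng.choice(list("ACGT"), 30))
        rows = [("ref", ref)]
        total_runs = 0
        for i in range(4):
            row = list(ref)
            start = int(rng.integers(0, 26))
            width = int(rng.integers(1, 5))
            row[start:start + width] = "-" * width
            total_runs += 1
            rows.append((f"s{i}", "".join(row)))
        calls = classify_indels(Alignment.from_rows(rows), unit, "ref")
        assert len(calls) == total_runs
        assert all(c.kind in ("codon_full", "frameshift") for c in calls)


class TestMerge:
    def test_disjoint_units_concatenate_widths(self):
        ref = Sequence("ref", "A" * 30)
        ann = ReferenceAnnotation(ref, [
            StructuralUnit("u1", "gene", 1, 10),
            StructuralUnit("u2", "gene", 11, 30),
        ])
        alns = {"u1": Alignment.from_rows([("ref", "A" * 10), ("q", "A" * 10)]),
                "u2": Alignment.from_rows([("ref", "A" * 20), ("q", "A" * 20)])}
        merged = merge_units(alns, ann, "ref")
        assert merged.ncols == 30
        assert merged.colmap == list(range(1, 31))

    def test_overlap_keeps_left_columns_and_verifies_agreement(self):
        ref = Sequence("ref", "ACGTACGTACGTACGTACGT")
        ann = ReferenceAnnotation(ref, [
            StructuralUnit("u1", "gene", 1, 12),
            StructuralUnit("u2", "gene", 10, 20),
        ])
        r = ref.residues
        alns = {"u1": Alignment.from_rows([("ref", r[:12]), ("q", r[:12])]),
                "u2": Alignment.from_rows([("ref", r[9:]), ("q", r[9:])])}
        merged = merge_units(alns, ann, "ref")
        assert merged.ncols == 20
        assert merged.rows["q"] == r

    def test_overlap_disagreement_names_sequence_and_units(self):
        ref = Sequence("ref", "ACGTACGTACGTACGTACGT")
        ann = ReferenceAnnotation(ref, [
            StructuralUnit("u1", "gene", 1, 12),
            StructuralUnit("u2", "gene", 10, 20),
        ])
        r = ref.residues
        bad = "TTT" + r[12:]
        alns = {"u1": Alignment.from_rows([("ref", r[:12]), ("q", r[:12])]),
                "u2": Alignment.from_rows([("ref", r[9:]), ("q", bad)])}
        with pytest.raises(ValueError, match="'q'.*u1.*u2"):
            merge_units(alns, ann, "ref")

    def test_absent_row_is_gap_filled_and_masked(self):
        ref = Sequence("ref", "A" * 30)
        ann = ReferenceAnnotation(ref, [
            StructuralUnit("u1", "gene", 1, 10),
            StructuralUnit("u2", "gene", 11, 30),
        ])
        alns = {"u1": Alignment.from_rows([("ref", "A" * 10), ("q", "A" * 10)]),
                "u2": Alignment.from_rows([("ref", "A" * 20)])}
        merged = merge_units(alns, ann, "ref")
        assert merged.rows["q"] == "A" * 10 + "-" * 20
        assert merged.unsequenced["q"][10:].all()
        assert not merged.unsequenced["q"][:10].any()

    @pytest.mark.parametrize("seed", range(6))
    def test_split_align_merge_round_trip_is_residue_exact(self, seed):
        res = generate(SynthSpec(n_leaves=8, seed=seed))
        ann = res.annotation
        ref = ann.reference
        unit_slices = {u.name: [UnitSlice(ref.id, u.name,
                                          ref.residues[u.start - 1:u.end])]
                       for u in ann.units}
        for s in res.clean_dataset:
            for sl in split_by_units(s, ann):
                if not sl.empty:
                    unit_slices[sl.unit_name].append(sl)
        alns = {name: align_unit(slices, center_id=ref.id)
                for name, slices in unit_slices.items()}
        merged = merge_units(alns, ann, ref.id)
        assert merged.degapped(ref.id) == ref.residues
        for s in res.clean_dataset:
            assert merged.degapped(s.id) == s.residues, s.id
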