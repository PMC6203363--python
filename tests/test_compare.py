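import numpy as np
import pytest

from mircompare.compare import (
    AcceptedLocus,
    assemble_annotation,
    classify_table,
    classify_variant,
    cnv,
    load_bovine_pair_table,
)
from mircompare.seqio import Annotation, BedRecord, Mature, MiRNARecord


class TestClassifyVariant:
    def test_single_seed_substitution(self):
        v = classify_variant(
            "AAGTTCGTTCGGATTTTTCC", "AAGTTCATTCGGATTTTTCC", "miR-2284e"
        )
        assert [tuple(s) for s in v.substitutions] == [(7, "G", "A")]
        assert v.regions == {"seed"}

    def test_three_substitutions(self):
        v = classify_variant(
            "CAGGCTAGGAGGTGTGTGTGGATG", "CAGGCTAGGAGGTAAGAGTGGATG", "miR-664a"
        )
        assert v.n_subs == 3
        assert v.regions == {"mature"}

    def test_identity(self):
        v = classify_variant("ACGTACGTACGTACGTACGT", "ACGTACGTACGTACGTACGT")
        assert v.n_subs == 0 and not v.indels
        assert v.regions == frozenset()
        assert not v.is_polymorphic

    def test_length_difference_yields_indel(self):
        v = classify_variant("AAGTTCGTTCGGATTTTTCC", "AAGTTCGTTCGGATTTTCC")
        assert len(v.indels) == 1
        assert v.indels[0].kind == "del"

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            classify_variant("", "ACGT")

    def test_antisymmetry(self, rng):
        """Swapping ref/target preserves positions and swaps the alleles."""
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), 22))
            b = list(a)
            for p in rng.choice(22, size=rng.integers(1, 4), replace=False):
                b[p] = rng.choice([x for x in "ACGT" if x != a[p]])
            b = "".join(b)
            fwd = classify_variant(a, b)
            rev = classify_variant(b, a)
            assert [(s.position, s.ref_base, s.alt_base) for s in fwd.substitutions] \
                == [(s.position, s.alt_base, s.ref_base) for s in rev.substitutions]


class TestClassifyTable:
    def test_published_pair_table_counts(self):
        """The 18 published taurine/indicine pairs: all polymorphic; with the
        2-9 seed window the printed sequences put 10 pairs in the seed class
        (the table's own region labels disagree with its sequences for
        several rows; the sequences win here)."""
        df = load_bovine_pair_table()
        assert len(df) == 18
        summary = classify_table(
            list(zip(df.mature_name, df.seq_taurine, df.seq_indicine))
        )
        assert summary.n_polymorphic == 18
        assert summary.n_seed == 10

    def test_empty_input(self):
        s = classify_table([])
        assert (s.n_polymorphic, s.n_seed) == (0, 0)

    def test_seed_never_exceeds_polymorphic(self, rng):
        for _ in range(10):
            pairs = []
            for i in range(8):
                a = "".join(rng.choice(list("ACGT"), 21))
                b = list(a)
                if rng.random() < 0.7:
                    p = int(rng.integers(0, 21))
                    b[p] = rng.choice([x for x in "ACGT" if x != a[p]])
                pairs.append((f"m{i}", a, "".join(b)))
            s = classify_table(pairs)
            assert s.n_seed <= s.n_polymorphic

    def test_configurable_seed_range(self):
        pairs = [("m", "AAGTTCGTTCGGATTTTTCC", "AAGTTCATTCGGATTTTTCC")]  # pos 7
        assert classify_table(pairs, seed_range=(2, 9)).n_seed == 1
        assert classify_table(pairs, seed_range=(2, 6)).n_seed == 0


class TestCnv:
    def test_reduced_copy_family(self):
        recs = cnv(
            ["mir-2345-1", "mir-2345-2", "mir-2345-3", "mir-2345-4"],
            [("mir-2345-1", "chr19", 100, 160, "+")],
        )
        assert [(r.family, r.copies_ref, r.copies_target, r.delta) for r in recs] \
            == [("mir-2345", 4, 1, -3)]

    def test_equal_counts_no_record(self):
        assert cnv(["mir-x"], [("mir-x", "chr1", 0, 60, "+")]) == []

    def test_letter_suffixes_stay_distinct(self):
        recs = cnv(
            ["mir-2284z", "mir-2284y"],
            [("mir-2284z", "chr1", 0, 60, "+"),
             ("mir-2284z-2", "chr2", 0, 60, "+"),
             ("mir-2284y", "chr3", 0, 60, "+")],
        )
        assert [(r.family, r.delta) for r in recs] == [("mir-2284z", 1)]

    def test_genome_against_itself_all_zero(self, rng):
        names = [f"syn-mir-{c}" for c in "abcde"]
        loci = [(n, "chr1", 100 * i, 100 * i + 60, "+") for i, n in enumerate(names)]
        assert cnv(names, loci) == []

    def test_synthetic_plan_recovered(self, dataset, annotation_result):
        got = {c.family: c.delta for c in annotation_result.cnv_records}
        expected = {
            fam: t - r for fam, (r, t) in dataset.truth.cnv_plan.items() if t != r
        }
        assert got == expected


def _mk_ref(n=3):
    return [
        MiRNARecord(f"syn-mir-{c}", "G" * 40 + "AAAA" + "C" * 40,
                    (Mature(f"syn-miR-{c}", 0, 20),))
        for c in "abcdefg"[:n]
    ]


class TestAssembleAnnotation:
    def test_arm_hypothesis_duplicates_collapse(self):
        loci = [
            AcceptedLocus("syn-mir-a", "chr1", "+", 100, 170, -1.2, "A" * 20),
            AcceptedLocus("syn-mir-a", "chr1", "+", 102, 170, -1.3, "A" * 20),
        ]
        ann, acc, kept = assemble_annotation(loci, None, _mk_ref(1))
        assert len(kept) == 1
        assert kept[0].mfei == -1.3  # lowest MFEI wins

    def test_exonic_locus_excluded_and_counted_not_found(self):
        loci = [AcceptedLocus("syn-mir-a", "chr1", "+", 100, 170, -1.2)]
        exons = Annotation([BedRecord("chr1", 150, 400, "exon", 0, "+")])
        ann, acc, kept = assemble_annotation(loci, exons, _mk_ref(1))
        assert len(kept) == 0
        assert acc.not_found == 1 and acc.conserved == 0

    def test_accounting_partition_invariant(self, dataset, annotation_result):
        acc = annotation_result.accounting
        assert acc.conserved + acc.not_found == acc.total

    def test_synthetic_accounting_matches_truth(self, dataset, annotation_result):
        truth = dataset.truth
        acc = annotation_result.accounting
        assert acc.total == len(dataset.reference)
        # the only reference precursors without a locus are the lost CNV copies
        expected_not_found = sum(
            max(0, r - t) for r, t in truth.cnv_plan.values()
        )
        assert acc.not_found == expected_not_found
        assert acc.conserved == acc.total - expected_not_found
        assert acc.polymorphic == len(truth.planted_mutations)
        assert acc.seed_mutated == sum(
            1 for m in truth.planted_mutations if m.region == "seed"
        )

    def test_no_annotation_overlaps_exons(self, dataset, annotation_result):
        for rec in annotation_result.annotation:
            for ex in dataset.exons:
                assert not (
                    rec.chrom == ex.chrom
                    and min(rec.end, ex.end) > max(rec.start, ex.start)
                )

    def test_planted_mutations_all_classified(self, dataset, annotation_result):
        got = {
            v.mirna_name: v for v in annotation_result.variants if v.is_polymorphic
        }
        for m in dataset.truth.planted_mutations:
            v = got[m.mature_name]
            assert [tuple(s) for s in v.substitutions] \
                == [(m.position, m.ref_base, m.alt_base)]
            assert ("seed" in v.regions) == (m.region == "seed")
        assert len(got) == len(dataset.truth.planted_mutations)

    def test_seed_mutations_never_leak_to_mature_class(self, dataset, annotation_result):
        for v in annotation_result.variants:
            for s in v.substitutions:
                in_seed = 2 <= s.position <= 9
                assert ("seed" if in_seed else "mature") in v.regions
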