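import numpy as np
import pytest

from mircompare.homology import (
    align_precursor,
    bin_coverage,
    excise_flanks,
    GenomeHit,
    map_matures,
)
from mircompare.seqio import GenomeSequence, revcomp
from mircompare.synthetic_data import _random_dna, make_hairpin

from .oracles import naive_exact_scan


class TestBinCoverage:
    @pytest.mark.parametrize(
        "coverage,expected",
        [
            (1.0, "100"),
            (0.997, "100"),
            (0.99, "80-99"),
            (0.85, "80-99"),
            (0.80, "80-99"),
            (0.75, "70-79"),
            (0.70, "70-79"),
            (0.65, "rejected"),
            (0.0, "rejected"),
        ],
    )
    def test_bin_edges(self, coverage, expected):
        assert bin_coverage(coverage) == expected

    def test_monotone(self):
        order = {"rejected": 0, "70-79": 1, "80-99": 2, "100": 3}
        grid = np.linspace(0, 1, 201)
        ranks = [order[bin_coverage(c)] for c in grid]
        assert ranks == sorted(ranks)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_coverage(1.2)


class TestMapMatures:
    def test_single_plus_strand_hit(self):
        mature = "AAGTTCATTCGGATTTTTCC"
        g = [GenomeSequence("c", "TTTT" + mature + "GGGG")]
        (hit,) = map_matures([("m", mature)], g)
        assert (hit.chrom, hit.strand, hit.start, hit.end) == ("c", "+", 4, 24)
        assert hit.query_coverage == hit.identity == 1.0

    def test_minus_strand_equals_brute_force(self, rng):
        mature = "ACGGATCGTTAGCCATAGGC"
        bg = _random_dna(rng, 400, 0.5)
        seq = bg[:100] + revcomp(mature) + bg[100:]
        g = [GenomeSequence("c", seq)]
        hits = map_matures([("m", mature)], g)
        expected = naive_exact_scan(mature, "c", seq)
        assert [(h.chrom, h.strand, h.start, h.end) for h in hits] == expected
        assert hits[0].strand == "-"

    def test_one_mismatch_everywhere_means_zero_hits(self):
        mature = "AAGTTCATTCGGATTTTTCC"
        mutated = "AAGTTCCTTCGGATTTTTCC"
        g = [GenomeSequence("c", "TT" + mutated + "TT" + mutated)]
        assert map_matures([("m", mature)], g) == []

    def test_random_genomes_match_naive_scan(self):
        """Exact mapping agrees with the O(n*m) both-strand oracle."""
        rng = np.random.default_rng(5)
        for trial in range(10):
            seq = _random_dna(rng, 3000, 0.5)
            mature = _random_dna(rng, 18, 0.5)
            # plant a few copies in both orientations
            for pos, flip in ((200, False), (900, True), (1500, False)):
                ins = revcomp(mature) if flip else mature
                seq = seq[:pos] + ins + seq[pos + len(ins):]
            got = map_matures([("m", mature)], [GenomeSequence("c", seq)])
            expected = naive_exact_scan(mature, "c", seq)
            assert [(h.chrom, h.strand, h.start, h.end) for h in got] == expected

    def test_short_mature_rejected(self):
        with pytest.raises(ValueError):
            map_matures([("m", "ACGTACGTACGT")], [GenomeSequence("c", "A" * 50)])


class TestAlignPrecursor:
    @pytest.fixture()
    def precursor(self, rng):
        return make_hairpin(rng, 30, 10, 21, name="p").precursor_seq

    def test_verbatim_precursor_bin_100(self, rng, precursor):
        bg = _random_dna(rng, 4000, 0.42)
        g = [GenomeSequence("c", bg[:2000] + precursor + bg[2000:])]
        hits = align_precursor("p", precursor, g)
        best = max(hits, key=lambda h: h.score)
        assert best.bin == "100"
        assert best.identity == 1.0
        assert (best.start, best.end) == (2000, 2000 + len(precursor))

    def test_truncated_precursor_bins_80_99(self, rng, precursor):
        cut = int(0.15 * len(precursor))
        bg = _random_dna(rng, 4000, 0.42)
        g = [GenomeSequence("c", bg[:2000] + precursor[cut:] + bg[2000:])]
        hits = align_precursor("p", precursor, g)
        best = max(hits, key=lambda h: h.score)
        assert best.bin == "80-99"
        assert best.query_coverage == pytest.approx(1 - cut / len(precursor), abs=0.03)

    def test_minor_fragment_rejected_bin(self, rng, precursor):
        frag = precursor[: int(0.6 * len(precursor))]
        bg = _random_dna(rng, 4000, 0.42)
        g = [GenomeSequence("c", bg[:2000] + frag + bg[2000:])]
        hits = align_precursor("p", precursor, g)
        best = max(hits, key=lambda h: h.score)
        assert best.bin == "rejected"

    def test_minus_strand_recovered(self, rng, precursor):
        bg = _random_dna(rng, 4000, 0.42)
        g = [GenomeSequence("c", bg[:1500] + revcomp(precursor) + bg[1500:])]
        hits = align_precursor("p", precursor, g)
        best = max(hits, key=lambda h: h.score)
        assert best.strand == "-"
        assert (best.start, best.end) == (1500, 1500 + len(precursor))

    def test_score_symmetric_under_reverse_complement(self, rng, precursor):
        bg = _random_dna(rng, 3000, 0.42)
        seq = bg[:1000] + precursor + bg[1000:]
        fwd = align_precursor("p", precursor, [GenomeSequence("c", seq)])
        rev = align_precursor("p", precursor, [GenomeSequence("c", revcomp(seq))])
        assert sorted(h.score for h in fwd) == sorted(h.score for h in rev)

    def test_multicopy_hits_all_kept(self, rng, precursor):
        bg = _random_dna(rng, 6000, 0.42)
        seq = bg[:1000] + precursor + bg[1000:3000] + precursor + bg[3000:]
        hits = align_precursor("p", precursor, [GenomeSequence("c", seq)])
        perfect = [h for h in hits if h.bin == "100"]
        assert len(perfect) == 2

    def test_seeded_path_matches_full_sw(self, rng, precursor):
        """The k-mer seeded search over a large chromosome finds the same
        perfect loci as full Smith-Waterman over a small one."""
        bg = _random_dna(rng, 60_000, 0.42)  # above the full-SW size limit
        seq = bg[:10_000] + precursor + bg[10_000:40_000] + revcomp(precursor) + bg[40_000:]
        hits = align_precursor("p", precursor, [GenomeSequence("c", seq)])
        perfect = {(h.start, h.end, h.strand) for h in hits if h.bin == "100"}
        assert (10_000, 10_000 + len(precursor), "+") in perfect
        rc_pos = 10_000 + len(precursor) + 30_000
        assert (rc_pos, rc_pos + len(precursor), "-") in perfect


class TestExciseFlanks:
    def _genome(self, n=1000):
        return {"c": GenomeSequence("c", "ACGT" * (n // 4))}

    def test_window_arithmetic(self):
        hit = GenomeHit("m", "c", "+", 200, 221, 1.0, 1.0, "100")
        w5, w3 = excise_flanks(hit, self._genome())
        assert (w5.start, w5.end) == (185, 371)
        assert (w3.start, w3.end) == (50, 236)
        assert w5.mature_offset == 15
        assert w3.mature_offset == 150

    def test_clamped_at_chromosome_start(self):
        hit = GenomeHit("m", "c", "+", 5, 26, 1.0, 1.0, "100")
        windows = excise_flanks(hit, self._genome())
        assert all(w.start == 0 for w in windows)

    def test_minus_strand_window_contains_mature(self, rng):
        mature = "ACGGATCGTTAGCCATAGGC"
        bg = _random_dna(rng, 1000, 0.5)
        seq = bg[:500] + revcomp(mature) + bg[500:]
        genome = {"c": GenomeSequence("c", seq)}
        hit = GenomeHit("m", "c", "-", 500, 520, 1.0, 1.0, "100")
        for w in excise_flanks(hit, genome):
            assert mature in w.sequence
            assert w.sequence[w.mature_offset : w.mature_offset + 20] == mature

    def test_window_with_n_discarded(self):
        seq = "A" * 300 + "N" + "A" * 700
        genome = {"c": GenomeSequence("c", seq)}
        hit = GenomeHit("m", "c", "+", 290, 311, 1.0, 1.0, "100")
        with pytest.warns(UserWarning, match="contains N"):
            windows = excise_flanks(hit, genome)
        assert windows == []
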