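"""Recover reference miRNAs in a target genome by homology.

Two complementary searches mirror the usual annotation workflow:

* matures are mapped exactly (zero mismatches, full length) on both
  strands — the stringent path that anchors flank excision;
* precursors are aligned locally (Smith-Waterman, BLASTN-like scoring:
  match +2, mismatch -3, gap open -5, extend -2) and the query coverage
  of each alignment is binned: >=99.5% -> "100", 80-99 -> "80-99",
  70-79 -> "70-79", below 70% -> rejected.

Around each mature anchor two 150-nt flank windows are excised — one per
arm hypothesis (the mature could sit on the 5' or the 3' arm of its
precursor) — and handed to the folding gate.  Minus-strand windows are
reverse-complemented so the mature always reads 5'->3' inside them.

For large genomes the local alignment is fronted by an exact k-mer
seed-and-extend step (the quadratic full scan is used directly for small
sequences, and is what the equivalence tests exercise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

from Bio import Align

from .seqio import GenomeSequence, revcomp

COVERAGE_BINS = ("100", "80-99", "70-79", "rejected")

#: below this size a chromosome is aligned by full Smith-Waterman
FULL_SW_LIMIT = 50_000
SEED_K = 11

#: loop-side headroom added beyond the mature so both arm hypotheses fold
FLANK_LOOP = 15
FLANK_FAR = 150


class GenomeHit(NamedTuple):
    query_name: str
    chrom: str
    strand: str
    start: int  # genome-forward, 0-based half-open
    end: int
    query_coverage: float
    identity: float
    bin: str
    score: float = 0.0


@dataclass(frozen=True)
class CandidateWindow:
    query_name: str
    chrom: str
    strand: str
    start: int  # genome-forward coordinates of the window
    end: int
    arm_hypothesis: str  # '5p' (mature on 5' arm) or '3p'
    sequence: str  # oriented 5'->3' (reverse-complemented for '-' hits)
    mature_offset: int  # mature start within `sequence`
    mature_length: int


def bin_coverage(coverage: float) -> str:
    """Coverage bin; >=0.995 counts as perfect to tolerate one clipped base."""
    if not 0.0 <= coverage <= 1.0:
        raise ValueError(f"coverage {coverage} outside [0,1]")
    if coverage >= 0.995:
        return "100"
    if coverage >= 0.80:
        return "80-99"
    if coverage >= 0.70:
        return "70-79"
    return "rejected"


def map_matures(
    matures: Iterable[tuple[str, str]], genome: Iterable[GenomeSequence]
) -> list[GenomeHit]:
    """Every exact, full-length occurrence of each mature on either strand.

    Minus-strand hits are located through the reverse complement and
    reported on the forward coordinate axis.
    """
    genome = list(genome)
    hits: list[GenomeHit] = []
    for name, seq in matures:
        if len(seq) < 16:
            raise ValueError(f"mature {name} shorter than 16 nt")
        fwd, rev = seq.upper(), revcomp(seq.upper())
        for chrom in genome:
            for strand, probe in (("+", fwd), ("-", rev)):
                p = chrom.residues.find(probe)
                while p != -1:
                    hits.append(
                        GenomeHit(name, chrom.id, strand, p, p + len(probe),
                                  1.0, 1.0, "100", 2.0 * len(probe))
                    )
                    p = chrom.residues.find(probe, p + 1)
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand, h.query_name))
    return hits


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def _alignment_stats(alignment, qlen: int):
    qa = alignment.aligned[1]  # query blocks (target is the genome window)
    ta = alignment.aligned[0]
    qspan = qa[-1][1] - qa[0][0]
    coverage = min(1.0, qspan / qlen)
    matches = 0
    columns = 0
    tseq, qseq = alignment.target, alignment.query
    prev_t = prev_q = None
    for (t0, t1), (q0, q1) in zip(ta, qa):
        if prev_t is not None:  # internal gap columns
            columns += (t0 - prev_t) + (q0 - prev_q)
        for k in range(t1 - t0):
            columns += 1
            if tseq[t0 + k] == qseq[q0 + k]:
                matches += 1
        prev_t, prev_q = t1, q1
    identity = matches / columns if columns else 0.0
    t_start, t_end = ta[0][0], ta[-1][1]
    return coverage, identity, t_start, t_end


def _sw_hits(query: str, window: str, min_score: float):
    """Non-overlapping local alignments of query vs window, best first."""
    aligner = _aligner()
    out = []
    masked = window
    for _ in range(8):  # a handful of copies per window is plenty
        alignments = aligner.align(masked, query)
        if len(alignments) == 0 or alignments[0].score < min_score:
            break
        aln = alignments[0]
        cov, ident, t0, t1 = _alignment_stats(aln, len(query))
        out.append((aln.score, cov, ident, t0, t1))
        masked = masked[:t0] + "N" * (t1 - t0) + masked[t1:]
    return out


def _seed_positions(query: str, chrom_seq: str, k: int = SEED_K):
    positions = []
    step = max(1, k // 2)
    for q0 in range(0, len(query) - k + 1, step):
        kmer = query[q0 : q0 + k]
        if "N" in kmer:
            continue
        p = chrom_seq.find(kmer)
        while p != -1:
            positions.append(p - q0)  # approximate hit start (diagonal)
            p = chrom_seq.find(kmer, p + 1)
    return positions


def _cluster_diagonals(starts: list[int], span: int) -> list[int]:
    starts = sorted(starts)
    reps: list[int] = []
    for s in starts:
        if not reps or s - reps[-1] > span:
            reps.append(s)
    return reps


def align_precursor(
    precursor_name: str,
    precursor_seq: str,
    genome: Iterable[GenomeSequence],
    min_coverage_report: float = 0.5,
) -> list[GenomeHit]:
    """Local alignments of one precursor on both strands of every chromosome.

    Per chromosome and strand the maximal-score non-overlapping alignments
    are kept; equal-score overlapping alignments resolve left-most-first,
    then plus strand.
    """
    query = precursor_seq.upper()
    qlen = len(query)
    if qlen < 52:
        raise ValueError(f"precursor {precursor_name} shorter than 52 nt")
    min_score = 2.0 * qlen * min_coverage_report * 0.6
    hits: list[GenomeHit] = []
    for chrom in genome:
        for strand in ("+", "-"):
            oriented = query if strand == "+" else revcomp(query)
            if chrom.length <= FULL_SW_LIMIT:
                regions = [(0, chrom.length)]
            else:
                diag = _seed_positions(oriented, chrom.residues)
                reps = _cluster_diagonals(diag, qlen)
                regions = [
                    (max(0, s - qlen), min(chrom.length, s + 2 * qlen))
                    for s in reps
                ]
            for r0, r1 in regions:
                window = chrom.residues[r0:r1]
                for score, cov, ident, t0, t1 in _sw_hits(oriented, window, min_score):
                    start, end = r0 + t0, r0 + t1
                    hits.append(
                        GenomeHit(precursor_name, chrom.id, strand, start, end,
                                  cov, ident, bin_coverage(cov), float(score))
                    )
    # resolve overlaps: keep maximal score, tie-break left-most then '+'
    hits.sort(key=lambda h: (-h.score, h.chrom, h.start, 0 if h.strand == "+" else 1))
    kept: list[GenomeHit] = []
    for h in hits:
        clash = any(
            k.chrom == h.chrom and min(k.end, h.end) > max(k.start, h.start)
            for k in kept
        )
        if not clash:
            kept.append(h)
    kept.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return kept


def excise_flanks(
    mature_hit: GenomeHit, genome: dict[str, GenomeSequence] | Iterable[GenomeSequence]
) -> list[CandidateWindow]:
    """The two arm-hypothesis windows around a mature-level hit.

    Window A assumes the mature on the 5' arm: [start-15, end+150);
    window B assumes the 3' arm: [start-150, end+15).  Both are clamped
    to the chromosome and oriented so the mature reads 5'->3'; windows
    containing N are discarded with a warning.
    """
    if not isinstance(genome, dict):
        genome = {g.id: g for g in genome}
    chrom = genome[mature_hit.chrom]
    s, e = mature_hit.start, mature_hit.end
    plans = (
        ("5p", max(0, s - FLANK_LOOP), min(chrom.length, e + FLANK_FAR)),
        ("3p", max(0, s - FLANK_FAR), min(chrom.length, e + FLANK_LOOP)),
    )
    out: list[CandidateWindow] = []
    for arm, w0, w1 in plans:
        seq = chrom.residues[w0:w1]
        if "N" in seq:
            warnings.warn(
                f"{mature_hit.query_name}: window {chrom.id}:{w0}-{w1} contains N; discarded"
            )
            continue
        if mature_hit.strand == "-":
            seq = revcomp(seq)
            m_off = w1 - e
            # on the reverse strand the arm hypothesis flips sides
            arm_oriented = {"5p": "3p", "3p": "5p"}[arm]
        else:
            m_off = s - w0
            arm_oriented = arm
        out.append(
            CandidateWindow(
                query_name=mature_hit.query_name,
                chrom=chrom.id, strand=mature_hit.strand,
                start=w0, end=w1,
                arm_hypothesis=arm_oriented,
                sequence=seq,
                mature_offset=m_off,
                mature_length=e - s,
            )
        )
    return out
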