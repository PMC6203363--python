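"""Strand-specific positional clustering of miRNA loci and polycistron calling.

Loci on the same chromosome and strand chain into one cluster when each
intergenic gap (end-to-start distance, bedtools ``cluster -d`` semantics)
is at most the window ``d``; singletons are clusters of size one.  A
multi-member cluster is called polycistronic when a promoter motif scores
at or above the threshold (default 0.80, normalized) in the strand-aware
upstream window of its 5'-most member and *no* qualifying promoter sits
in any intergenic gap — the single-promoter signature of a co-transcribed
block.

The promoter model is a pluggable position weight matrix (log-odds
against a uniform background, normalized so the best possible match
scores 1.0); the default PWM derives from the generator's planted
consensus motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import Annotation, BedRecord, GenomeSequence, revcomp
from .synthetic_data import PROMOTER_CONSENSUS

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PromoterScorer:
    """Normalized PWM scorer: 1.0 = perfect consensus match."""

    pwm: np.ndarray  # shape (width, 4), log2-odds vs uniform background
    threshold: float = 0.80

    @classmethod
    def from_consensus(
        cls, consensus: str = PROMOTER_CONSENSUS,
        p_match: float = 0.85, threshold: float = 0.80,
    ) -> "PromoterScorer":
        w = len(consensus)
        probs = np.full((w, 4), (1 - p_match) / 3)
        for i, b in enumerate(consensus):
            probs[i, _BASE_IDX[b]] = p_match
        return cls(np.log2(probs / 0.25), threshold)

    @property
    def width(self) -> int:
        return self.pwm.shape[0]

    def _normalize(self, raw: float) -> float:
        hi = self.pwm.max(axis=1).sum()
        lo = self.pwm.min(axis=1).sum()
        return (raw - lo) / (hi - lo)

    def best_hit(self, seq: str) -> tuple[int | None, float]:
        """Best normalized score and its offset over one 5'->3' reading."""
        w = self.width
        if len(seq) < w:
            return None, 0.0
        best_pos, best = 0, -np.inf
        for p in range(len(seq) - w + 1):
            s = 0.0
            ok = True
            for k in range(w):
                b = _BASE_IDX.get(seq[p + k])
                if b is None:
                    ok = False
                    break
                s += self.pwm[k, b]
            if ok and s > best:
                best, best_pos = s, p
        if best == -np.inf:
            return None, 0.0
        return best_pos, self._normalize(best)


@dataclass
class MiRNACluster:
    chrom: str
    strand: str
    members: list[BedRecord]  # sorted by start
    window_d: int
    polycistronic: bool = False
    promoter: tuple[int, float] | None = None  # forward-axis position, score

    @property
    def span(self) -> tuple[int, int]:
        return self.members[0].start, self.members[-1].end

    @property
    def member_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.members)

    def __len__(self) -> int:
        return len(self.members)


def cluster(annotation: Annotation, window_d: int) -> list[MiRNACluster]:
    """Single-linkage chaining per chromosome+strand at gap <= window_d."""
    groups: dict[tuple[str, str], list[BedRecord]] = {}
    for rec in annotation:
        groups.setdefault((rec.chrom, rec.strand), []).append(rec)
    out: list[MiRNACluster] = []
    for (chrom, strand), recs in sorted(groups.items()):
        recs.sort(key=lambda r: (r.start, r.end, r.name))
        current = [recs[0]]
        for rec in recs[1:]:
            if rec.start - current[-1].end <= window_d:
                current.append(rec)
            else:
                out.append(MiRNACluster(chrom, strand, current, window_d))
                current = [rec]
        out.append(MiRNACluster(chrom, strand, current, window_d))
    return out


def promoter_scan(
    genome: dict[str, GenomeSequence] | list[GenomeSequence],
    chrom: str,
    start: int,
    end: int,
    strand: str,
    scorer: PromoterScorer,
) -> tuple[int | None, float]:
    """Best promoter hit in [start,end) read 5'->3' on the given strand.

    The returned position is on the forward axis (motif start)."""
    if not isinstance(genome, dict):
        genome = {g.id: g for g in genome}
    g = genome[chrom]
    start, end = max(0, start), min(g.length, end)
    if end - start < scorer.width:
        return None, 0.0
    seq = g.residues[start:end]
    if strand == "-":
        seq = revcomp(seq)
    pos, score = scorer.best_hit(seq)
    if pos is None:
        return None, 0.0
    if strand == "-":
        fwd = end - pos - scorer.width
    else:
        fwd = start + pos
    return fwd, score


def call_polycistrons(
    clusters_: list[MiRNACluster],
    genome: dict[str, GenomeSequence] | list[GenomeSequence],
    scorer: PromoterScorer | None = None,
    upstream: int = 500,
) -> list[MiRNACluster]:
    """Flag clusters with a single qualifying promoter upstream of the
    5'-most member and none inside any intergenic gap."""
    scorer = scorer or PromoterScorer.from_consensus()
    if not isinstance(genome, dict):
        genome = {g.id: g for g in genome}
    for cl in clusters_:
        cl.polycistronic = False
        cl.promoter = None
        if len(cl) < 2:
            continue
        s0, s1 = cl.span
        if cl.strand == "-":
            up = (s1, s1 + upstream)
        else:
            up = (s0 - upstream, s0)
        pos, score = promoter_scan(genome, cl.chrom, *up, cl.strand, scorer)
        if score < scorer.threshold:
            continue
        gap_clean = True
        for a, b in zip(cl.members, cl.members[1:]):
            if b.start - a.end < scorer.width:
                continue
            _, gscore = promoter_scan(
                genome, cl.chrom, a.end, b.start, cl.strand, scorer
            )
            if gscore >= scorer.threshold:
                gap_clean = False
                break
        if gap_clean:
            cl.polycistronic = True
            cl.promoter = (pos, score)
    return clusters_
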