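"""Genome-wide rule-based hairpin scanning for novel miRNA candidates.

Overlapping windows (default 160 nt every 20 nt, covering the 52-148 nt
precursor range with dense overlap) are folded on both strands; windows
passing the structural gate — single stem-loop, 52-148 nt trimmed stem,
MFEI <= -0.85, a well-paired putative mature on one arm — are trimmed to
their maximal stem span and merged (overlapping candidates keep the
lowest MFEI; ties prefer the longer stem, then the left-most).  Exonic
candidates are removed when an exon annotation is supplied, and
candidates containing a known mature verbatim are labelled
"matches-known" rather than "novel".

The mature call itself is purely structural: the ~21-nt window on either
arm maximising its paired fraction (ties: 5' arm, then left-most).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

from .folding import (
    DEFAULT_MODEL,
    EnergyModel,
    FoldThresholds,
    HairpinStructure,
    StemComponent,
    accept_hairpin,
    candidate_stems,
    fold,
)
from .seqio import Annotation, GenomeSequence, revcomp

MATURE_CALL_LEN = 21


@dataclass
class DenovoCandidate:
    chrom: str
    strand: str
    start: int  # trimmed stem span, genome-forward coordinates
    end: int
    structure: HairpinStructure
    mfei: float  # MFEI of the trimmed stem
    putative_mature: tuple[int, int]  # within the oriented stem sequence
    novelty: str = "novel"  # 'novel' | 'matches-known'

    @property
    def sequence(self) -> str:
        # oriented 5'->3' stem sequence
        s0, s1 = self.structure.stem_span
        return self.structure.sequence[s0:s1].replace("U", "T")


def putative_mature_call(
    structure: HairpinStructure, stem: StemComponent | None = None
) -> tuple[int, int]:
    """Best-paired ~21-nt window on either arm of an accepted hairpin.

    Ties resolve to the 5' arm, then left-most; an arm shorter than 21 nt
    contributes its full length as the window.
    """
    if stem is None:
        if structure.stem_span is None or structure.loop is None:
            raise ValueError("mature call requires a folded stem-loop")
        s0, s1 = structure.stem_span
        l0, l1 = structure.loop
        paired = {i for p in structure.pairs for i in p}
    else:
        s0, s1 = stem.span
        l0, l1 = stem.terminal_loop
        paired = {i for p in stem.pairs for i in p}
    best: tuple[float, int, int, tuple[int, int]] | None = None
    for arm_rank, (a0, a1) in enumerate(((s0, l0), (l1, s1))):
        arm_len = a1 - a0
        if arm_len <= 0:
            continue
        w = min(MATURE_CALL_LEN, arm_len)
        for st in range(a0, a1 - w + 1):
            frac = sum(1 for i in range(st, st + w) if i in paired) / w
            key = (-frac, arm_rank, st)
            if best is None or key < best[:3]:
                best = (*key, (st, st + w))
    assert best is not None
    return best[3]


def _window_starts(length: int, window: int, step: int) -> list[int]:
    if length <= window:
        return [0]
    starts = list(range(0, length - window + 1, step))
    if starts[-1] != length - window:
        starts.append(length - window)
    return starts


def scan(
    genome: Iterable[GenomeSequence],
    window: int = 160,
    step: int = 20,
    model: EnergyModel = DEFAULT_MODEL,
    thresholds: FoldThresholds = FoldThresholds(),
    exons: Annotation | None = None,
    known_matures: Iterable[tuple[str, str]] = (),
) -> list[DenovoCandidate]:
    """Slide, fold, gate, trim, merge and filter over a whole genome."""
    if window < 60:
        raise ValueError("window must be at least 60 nt")
    accepted: list[DenovoCandidate] = []
    for chrom in genome:
        for strand in ("+", "-"):
            for w0 in _window_starts(chrom.length, window, step):
                seq = chrom.residues[w0 : w0 + window]
                if "N" in seq:
                    continue
                if strand == "-":
                    seq = revcomp(seq)
                st = fold(seq, model)
                if st.stem_span is None:
                    continue
                wlen = len(seq)
                for stem in candidate_stems(st):
                    s0, s1 = stem.span
                    if not (thresholds.min_precursor_len
                            <= s1 - s0 <= thresholds.max_precursor_len):
                        continue
                    mature = putative_mature_call(st, stem)
                    dec = accept_hairpin(st, mature, thresholds, model, stem=stem)
                    if not dec.accepted:
                        continue
                    if strand == "+":
                        g0, g1 = w0 + s0, w0 + s1
                    else:
                        g0, g1 = w0 + wlen - s1, w0 + wlen - s0
                    accepted.append(
                        DenovoCandidate(
                            chrom=chrom.id, strand=strand, start=g0, end=g1,
                            structure=st, mfei=dec.span_mfei,
                            putative_mature=(mature[0] - s0, mature[1] - s0),
                        )
                    )
    merged = _merge(accepted)
    if exons is not None:
        merged = [
            c for c in merged
            if not any(
                e.chrom == c.chrom and min(e.end, c.end) > max(e.start, c.start)
                for e in exons
            )
        ]
    return assign_novelty(merged, known_matures)


def _stem_len(c: DenovoCandidate) -> int:
    return c.end - c.start


def _merge(cands: list[DenovoCandidate]) -> list[DenovoCandidate]:
    """Collapse overlapping accepted candidates, keeping lowest MFEI, then
    longer stem, then left-most.  Merging ignores strand: a hairpin's
    reverse complement is itself a hairpin, so the same physical locus
    surfaces from both strand scans."""
    cands = sorted(cands, key=lambda c: (c.mfei, -_stem_len(c), c.chrom, c.start))
    kept: list[DenovoCandidate] = []
    for c in cands:
        clash = any(
            k.chrom == c.chrom and min(k.end, c.end) > max(k.start, c.start)
            for k in kept
        )
        if not clash:
            kept.append(c)
    kept.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return kept


def assign_novelty(
    candidates: list[DenovoCandidate], known_matures: Iterable[tuple[str, str]]
) -> list[DenovoCandidate]:
    """Exact-substring containment of any known mature marks a candidate as known."""
    known = [seq.upper().replace("U", "T") for _, seq in known_matures]
    out = []
    for c in candidates:
        seq = c.sequence
        label = "matches-known" if any(k in seq for k in known) else "novel"
        out.append(replace(c, novelty=label))
    return out
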