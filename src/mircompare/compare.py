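"""The comparative layer: mature-variant classification, copy-number variation,
and assembly of the final annotation with exon/redundancy filtering.

Mature variants are read off a global alignment of the two alleles
(match +1, mismatch -1, gap -2) with substitution positions indexed
1-based on the reference mature.  A variant touches the *seed region*
when any substitution falls in positions 2-9 from the 5' end (the wider
mutation-region window; the 2-8 heptamer used for target sites lives in
:mod:`mircompare.targets`).  Region labels are always derived from the
sequences themselves, never taken from upstream annotations — where a
published table's labels disagree with its printed sequences, the
sequences win.

Copy-number variation compares per-family locus counts between the two
genomes; the family key strips one trailing ``-<digits>`` copy suffix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, NamedTuple

import pandas as pd
from Bio import Align

from .seqio import Annotation, BedRecord, MiRNARecord, strip_copy_suffix

DEFAULT_SEED_RANGE = (2, 9)  # 1-based, inclusive


class Substitution(NamedTuple):
    position: int  # 1-based on the reference mature
    ref_base: str
    alt_base: str


class Indel(NamedTuple):
    position: int  # 1-based reference position it touches
    kind: str  # 'ins' | 'del'
    base: str


@dataclass(frozen=True)
class MatureVariant:
    mirna_name: str
    seq_ref: str
    seq_target: str
    substitutions: tuple[Substitution, ...]
    indels: tuple[Indel, ...]
    seed_range: tuple[int, int] = DEFAULT_SEED_RANGE

    @property
    def n_subs(self) -> int:
        return len(self.substitutions)

    @property
    def regions(self) -> frozenset[str]:
        lo, hi = self.seed_range
        out = set()
        for s in self.substitutions:
            out.add("seed" if lo <= s.position <= hi else "mature")
        return frozenset(out)

    @property
    def is_polymorphic(self) -> bool:
        return bool(self.substitutions) or bool(self.indels)


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def classify_variant(
    seq_ref: str,
    seq_target: str,
    name: str = "",
    seed_range: tuple[int, int] = DEFAULT_SEED_RANGE,
) -> MatureVariant:
    """Align two mature alleles and read substitutions/indels off the columns."""
    if not seq_ref or not seq_target:
        raise ValueError("mature sequences must be non-empty")
    a = seq_ref.upper().replace("U", "T")
    b = seq_target.upper().replace("U", "T")
    if a == b:
        return MatureVariant(name, a, b, (), (), seed_range)
    aln = _global_aligner().align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    subs: list[Substitution] = []
    indels: list[Indel] = []
    ref_pos = 0
    for ca, cb in zip(ga, gb):
        if ca != "-":
            ref_pos += 1
        if ca == "-":
            indels.append(Indel(ref_pos, "ins", cb))
        elif cb == "-":
            indels.append(Indel(ref_pos, "del", ca))
        elif ca != cb:
            subs.append(Substitution(ref_pos, ca, cb))
    return MatureVariant(name, a, b, tuple(subs), tuple(indels), seed_range)


@dataclass
class TableSummary:
    n_polymorphic: int
    n_seed: int
    variants: list[MatureVariant]


def classify_table(
    pairs: Iterable[tuple[str, str, str]],
    seed_range: tuple[int, int] = DEFAULT_SEED_RANGE,
) -> TableSummary:
    """Classify (name, seq_ref, seq_target) pairs; count polymorphic and
    seed-touching pairs."""
    variants = [classify_variant(r, t, n, seed_range) for n, r, t in pairs]
    n_poly = sum(1 for v in variants if v.is_polymorphic)
    n_seed = sum(1 for v in variants if "seed" in v.regions)
    return TableSummary(n_poly, n_seed, variants)


def load_bovine_pair_table() -> pd.DataFrame:
    """The packaged taurine/indicine mature-pair table (18 published pairs)."""
    with resources.files("mircompare.data").joinpath(
        "mature_variants_bta_bind.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


class CopyNumberRecord(NamedTuple):
    family: str
    copies_ref: int
    copies_target: int
    delta: int
    loci_target: tuple[tuple[str, int, int, str], ...]


def cnv(
    ref_names: Iterable[str],
    target_loci: Iterable[tuple[str, str, int, int, str]],
) -> list[CopyNumberRecord]:
    """Per-family copy-number deltas; only families with delta != 0 are emitted.

    ``ref_names`` are the reference precursor names (one per reference copy);
    ``target_loci`` are accepted, deduplicated loci as
    (name, chrom, start, end, strand).
    """
    ref_counts: dict[str, int] = {}
    for n in ref_names:
        fam = strip_copy_suffix(n)
        ref_counts[fam] = ref_counts.get(fam, 0) + 1
    tgt: dict[str, list[tuple[str, int, int, str]]] = {}
    for name, chrom, start, end, strand in target_loci:
        fam = strip_copy_suffix(name)
        tgt.setdefault(fam, []).append((chrom, start, end, strand))
    out: list[CopyNumberRecord] = []
    for fam in sorted(set(ref_counts) | set(tgt)):
        r = ref_counts.get(fam, 0)
        t = len(tgt.get(fam, []))
        # a family absent from one side is "not found" there, not a copy-
        # number variant; CNV requires presence in both genomes
        if r != t and r > 0 and t > 0:
            out.append(CopyNumberRecord(fam, r, t, t - r, tuple(tgt.get(fam, []))))
    return out


class AcceptedLocus(NamedTuple):
    """One folding-validated genomic locus of a reference precursor."""

    name: str  # reference precursor (copy) name
    chrom: str
    strand: str
    start: int
    end: int
    mfei: float
    mature_target_seq: str = ""

    @property
    def family(self) -> str:
        return strip_copy_suffix(self.name)


@dataclass
class PipelineAccounting:
    """Distribution of the reference set across the recovery categories.

    ``conserved`` and ``not_found`` partition the reference precursors
    (so conserved + not_found == total always); cnv / polymorphic /
    seed_mutated are non-exclusive flags counted over families or mature
    pairs respectively.
    """

    total: int = 0
    conserved: int = 0
    not_found: int = 0
    cnv: int = 0
    polymorphic: int = 0
    seed_mutated: int = 0

    def check(self) -> None:
        if self.conserved + self.not_found != self.total:
            raise AssertionError("accounting violated: conserved+not_found != total")


def _overlap(a: BedRecord | AcceptedLocus, b: BedRecord | AcceptedLocus) -> int:
    return min(a.end, b.end) - max(a.start, b.start)


def _reciprocal(a, b) -> float:
    inter = _overlap(a, b)
    if inter <= 0:
        return 0.0
    return min(inter / (a.end - a.start), inter / (b.end - b.start))


def assemble_annotation(
    accepted: Iterable[AcceptedLocus],
    exons: Annotation | None,
    reference: Iterable[MiRNARecord],
    variants: Iterable[MatureVariant] = (),
    min_reciprocal: float = 0.9,
) -> tuple[Annotation, PipelineAccounting, list[AcceptedLocus]]:
    """Exon filter, redundancy collapse, and Table-1-style accounting.

    Any locus overlapping an exon by >=1 bp (either strand) is dropped;
    duplicates (same chrom+strand, reciprocal overlap >= ``min_reciprocal``)
    collapse keeping the lowest (most negative) MFEI.
    """
    loci = list(accepted)
    if exons is not None:
        loci = [
            l for l in loci
            if not any(e.chrom == l.chrom and _overlap(l, e) > 0 for e in exons)
        ]
    loci.sort(key=lambda l: (l.mfei, l.chrom, l.start))
    kept: list[AcceptedLocus] = []
    for l in loci:
        dup = any(
            k.chrom == l.chrom and k.strand == l.strand
            and _reciprocal(k, l) >= min_reciprocal
            for k in kept
        )
        if not dup:
            kept.append(l)
    kept.sort(key=lambda l: (l.chrom, l.start, l.strand))

    reference = list(reference)
    ref_by_family: dict[str, int] = {}
    for r in reference:
        ref_by_family[r.family] = ref_by_family.get(r.family, 0) + 1
    found_by_family: dict[str, int] = {}
    for l in kept:
        found_by_family[l.family] = found_by_family.get(l.family, 0) + 1

    acc = PipelineAccounting(total=len(reference))
    for fam, r in ref_by_family.items():
        t = found_by_family.get(fam, 0)
        acc.conserved += min(r, t)
        acc.not_found += max(0, r - t)
        if t != r:
            acc.cnv += 1
    variants = list(variants)
    acc.polymorphic = sum(1 for v in variants if v.is_polymorphic)
    acc.seed_mutated = sum(1 for v in variants if "seed" in v.regions)
    acc.check()

    ann = Annotation(
        [BedRecord(l.chrom, l.start, l.end, l.name, 0.0, l.strand) for l in kept]
    ).sorted()
    return ann, acc, kept
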