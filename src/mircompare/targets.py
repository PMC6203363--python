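"""Canonical seed-match target-site scanning of 3'UTRs and ortholog target-set diffs.

Site classes follow the standard seed-complementarity hierarchy: with the
seed heptamer s = mature positions 2-8 (5'->3'),

* 7mer-m8: the UTR carries the reverse complement of positions 2-8;
* 7mer-A1: the UTR carries the reverse complement of positions 2-7
  followed by an A (opposite mature position 1, regardless of pairing);
* 8mer: both at once;
* 6mer: the reverse complement of positions 2-7 only.

Only the single highest class is reported per locus.  A UTR counts as a
target of a mature when it carries at least one site of class 7mer or
better (6mers alone are too noisy for target calls); the cutoff class is
configurable.  The seed heptamer used for sites (2-8) is deliberately a
separate constant from the wider 2-9 mutation-region window used when
classifying mature variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

from .seqio import GenomeSequence, revcomp

SITE_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_RANK = {c: r for r, c in enumerate(SITE_CLASSES)}  # 0 strongest


class TargetSite(NamedTuple):
    utr_id: str
    mirna_name: str
    site_type: str
    start: int  # 0-based half-open on the UTR
    end: int
    matched_seed: str


def seed_heptamer(mature: str) -> str:
    """Mature positions 2-8 (1-based), 5'->3'."""
    if len(mature) < 8:
        raise ValueError("mature must be at least 8 nt for seed matching")
    return mature[1:8].upper().replace("U", "T")


def site_sequence_8mer(mature: str) -> str:
    """UTR-sense 8mer site for a mature: revcomp(positions 2-8) + A."""
    return revcomp(seed_heptamer(mature)) + "A"


def scan_sites(
    mature_name: str, mature: str, utrs: Iterable[GenomeSequence]
) -> list[TargetSite]:
    """All seed-match sites of one mature across a UTR set (sense strand only)."""
    hept = seed_heptamer(mature)  # positions 2..8
    core6 = hept[:6]  # positions 2..7
    rc_core = revcomp(core6)  # 6 nt; preceded (5') by complement of pos 8
    m8_base = revcomp(hept)[0]  # complement of mature position 8
    sites: list[TargetSite] = []
    for utr in utrs:
        seq = utr.residues
        p = seq.find(rc_core)
        while p != -1:
            has_m8 = p >= 1 and seq[p - 1] == m8_base
            has_a1 = p + 6 < len(seq) and seq[p + 6] == "A"
            if has_m8 and has_a1:
                stype, s, e = "8mer", p - 1, p + 7
            elif has_m8:
                stype, s, e = "7mer-m8", p - 1, p + 6
            elif has_a1:
                stype, s, e = "7mer-A1", p, p + 7
            else:
                stype, s, e = "6mer", p, p + 6
            sites.append(TargetSite(utr.id, mature_name, stype, s, e, hept))
            p = seq.find(rc_core, p + 1)
    return sites


def target_utrs(
    mature_name: str,
    mature: str,
    utrs: Iterable[GenomeSequence],
    min_class: str = "7mer-A1",
) -> set[str]:
    """UTR ids carrying at least one site of the cutoff class or better."""
    cutoff = _RANK[min_class]
    return {
        s.utr_id
        for s in scan_sites(mature_name, mature, utrs)
        if _RANK[s.site_type] <= cutoff
    }


@dataclass(frozen=True)
class TargetDiff:
    mirna_name: str
    common: frozenset[str]
    lost: frozenset[str]  # targets of the reference allele only
    gained: frozenset[str]  # targets of the variant allele only


def diff_targets(
    mirna_name: str,
    mature_ref: str,
    mature_target: str,
    utrs: Iterable[GenomeSequence],
    min_class: str = "7mer-A1",
) -> TargetDiff:
    """Common/lost/gained target sets between two alleles of one mature."""
    utr_list = list(utrs)
    ref = target_utrs(mirna_name, mature_ref, utr_list, min_class)
    alt = target_utrs(mirna_name, mature_target, utr_list, min_class)
    return TargetDiff(
        mirna_name=mirna_name,
        common=frozenset(ref & alt),
        lost=frozenset(ref - alt),
        gained=frozenset(alt - ref),
    )
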