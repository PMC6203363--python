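"""Synthetic genomes with planted miRNA structure, and the truth tables to score recovery.

The generator emulates the inputs of a two-genome miRNA comparison: a
reference miRNA set (precursors + matures, miRBase-style names) and a
target genome in which each reference hairpin has been planted — some
with controlled substitutions in or outside the seed region, some with
gained/lost copies (CNV), some arranged in sub-kilobase same-strand
clusters behind a single planted promoter motif, and some duplicated
inside planted exons as decoys that the annotation filters must remove.
A set of 3'UTR sequences carries planted seed-match sites.

Background sequence is i.i.d. with configurable GC fraction (default
0.42, bovine-like — low enough that spurious windows rarely pass the
MFEI gate).  Everything is a pure function of the RNG seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .seqio import (
    Annotation,
    BedRecord,
    GenomeSequence,
    Mature,
    MiRNARecord,
    revcomp,
)

#: fixed 15-nt promoter stand-in motif; the default PWM is built from it
PROMOTER_CONSENSUS = "TATAAAGGCCGCATC"

_BASES = np.array(list("ACGT"))


class PlantedLocus(NamedTuple):
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    family: str


class PlantedMutation(NamedTuple):
    mature_name: str
    position: int  # 1-based from the mature 5' end
    ref_base: str
    alt_base: str
    region: str  # 'seed' | 'mature'


class ClusterPlan(NamedTuple):
    members: tuple[str, ...]
    max_gap: int
    promoter_planted: bool
    strand: str
    chrom: str


class UTRSite(NamedTuple):
    utr_id: str
    mature_name: str
    site_type: str
    allele: str  # 'ref' | 'target'


@dataclass
class SyntheticTruth:
    planted_loci: list[PlantedLocus] = field(default_factory=list)
    planted_mutations: list[PlantedMutation] = field(default_factory=list)
    cnv_plan: dict[str, tuple[int, int]] = field(default_factory=dict)
    cluster_plan: list[ClusterPlan] = field(default_factory=list)
    exon_decoys: Annotation = field(default_factory=Annotation)
    decoy_loci: list[PlantedLocus] = field(default_factory=list)
    utr_sites: list[UTRSite] = field(default_factory=list)
    promoter_positions: list[tuple[str, int, str]] = field(default_factory=list)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the default synthetic bed (all counts per genome)."""

    seed: int = 1
    genome_size: int = 1_000_000
    n_chromosomes: int = 4
    n_mirnas: int = 20
    n_seed_mutations: int = 3
    n_mature_mutations: int = 3
    n_cnv_families: int = 2
    n_clusters: int = 2
    cluster_size: int = 3
    cluster_gap: int = 800
    n_exon_decoys: int = 5
    n_utrs: int = 30
    utr_length: int = 600
    gc_background: float = 0.42
    stem_gc: float = 0.75
    seed_range: tuple[int, int] = (2, 9)
    species_ref: str = "bta"
    species_target: str = "bind"

    def __post_init__(self) -> None:
        counts = (
            self.n_mirnas, self.n_seed_mutations, self.n_mature_mutations,
            self.n_cnv_families, self.n_clusters, self.n_exon_decoys, self.n_utrs,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        if self.n_seed_mutations + self.n_mature_mutations > self.n_mirnas:
            raise ValueError("more mutations requested than miRNAs")


@dataclass
class SyntheticDataset:
    genome: list[GenomeSequence]
    reference: list[MiRNARecord]
    target_records: list[MiRNARecord]
    exons: Annotation
    utrs: list[GenomeSequence]
    truth: SyntheticTruth
    config: GeneratorConfig


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _family_name(i: int) -> str:
    # letter suffixes so that the numeric copy-suffix stripping never
    # collapses distinct families
    letters = string.ascii_lowercase
    tag = ""
    i0 = i
    while True:
        tag = letters[i0 % 26] + tag
        i0 = i0 // 26 - 1
        if i0 < 0:
            break
    return f"syn-mir-{tag}"


def make_hairpin(
    rng: np.random.Generator,
    stem_len: int,
    loop_len: int,
    mature_len: int,
    *,
    stem_gc: float = 0.75,
    n_mismatches: int = 1,
    mature_arm: str | None = None,
    name: str = "syn-mir-a",
) -> MiRNARecord:
    """Construct a precursor that folds into a single stem-loop by design.

    The 5' arm is reverse-complement-paired to the 3' arm except for up to
    ``n_mismatches`` injected defects (placed away from the mature and the
    helix ends); the loop is drawn from {A,C} so it cannot pair with itself.
    """
    total = 2 * stem_len + loop_len
    if loop_len < 3:
        raise ValueError("loop must be at least 3 nt")
    if not 52 <= total <= 148:
        raise ValueError(f"precursor length {total} outside [52,148]")
    if mature_len > stem_len:
        raise ValueError("mature does not fit on one arm")
    if n_mismatches > 2:
        raise ValueError("at most 2 injected mismatches")

    arm5 = _random_dna(rng, stem_len, stem_gc)
    loop = "".join(np.array(list("AC"))[rng.integers(0, 2, size=loop_len)])
    arm3 = list(revcomp(arm5))

    arm = mature_arm or ("5p" if rng.random() < 0.5 else "3p")
    if arm == "5p":
        m_offset = int(rng.integers(0, stem_len - mature_len + 1))
        protected = range(0, 0)  # mature not on arm3
    else:
        rel = int(rng.integers(0, stem_len - mature_len + 1))
        m_offset = stem_len + loop_len + rel
        protected = range(rel, rel + mature_len)

    candidates = [
        k for k in range(3, stem_len - 3)
        if k not in protected
    ]
    rng.shuffle(candidates)
    swap = {"A": "C", "C": "A", "G": "A", "T": "C"}  # breaks WC and GU pairing
    for k in candidates[:n_mismatches]:
        arm3[k] = swap[arm3[k]]
    precursor = arm5 + loop + "".join(arm3)
    mature = Mature(name.replace("mir", "miR", 1), m_offset, mature_len)
    return MiRNARecord(name, precursor, (mature,))


def _plant_segments(rng, chrom_names, chrom_sizes, requests, gc, min_gap=200):
    """Lay out segment requests on chromosomes with random background between."""
    per_chrom: dict[str, list] = {c: [] for c in chrom_names}
    order = list(range(len(requests)))
    rng.shuffle(order)
    for qi, idx in enumerate(order):
        per_chrom[chrom_names[qi % len(chrom_names)]].append(requests[idx])
    sequences = {}
    placements = {}  # request id -> (chrom, start)
    for cname, csize in zip(chrom_names, chrom_sizes):
        reqs = per_chrom[cname]
        used = sum(len(r["segment"]) for r in reqs)
        n_gaps = len(reqs) + 1
        free = csize - used - min_gap * n_gaps
        if free < 0:
            raise ValueError("genome too small to host all planted segments disjointly")
        cuts = np.sort(rng.integers(0, free + 1, size=n_gaps - 1)) if n_gaps > 1 else np.array([], dtype=int)
        gaps = np.diff(np.concatenate([[0], cuts, [free]])) + min_gap
        parts = []
        pos = 0
        for r, gap in zip(reqs, gaps[:-1]):
            parts.append(_random_dna(rng, int(gap), gc))
            pos += int(gap)
            placements[r["id"]] = (cname, pos)
            parts.append(r["segment"])
            pos += len(r["segment"])
        parts.append(_random_dna(rng, int(gaps[-1]), gc))
        sequences[cname] = "".join(parts)
    return sequences, placements


def _mutate(seq: str, pos0: int, rng: np.random.Generator) -> tuple[str, str, str]:
    ref = seq[pos0]
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return seq[:pos0] + alt + seq[pos0 + 1 :], ref, alt


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Build the full synthetic bed: genome, reference set, exons, UTRs, truth."""
    rng = np.random.default_rng(config.seed)
    truth = SyntheticTruth()
    lo, hi = config.seed_range

    # --- reference hairpins -------------------------------------------------
    families: list[MiRNARecord] = []
    for i in range(config.n_mirnas):
        stem = int(rng.integers(26, 41))
        loop = int(rng.integers(8, 15))
        mat = int(rng.integers(20, 24))
        families.append(
            make_hairpin(
                rng, stem, loop, mat,
                stem_gc=config.stem_gc, n_mismatches=0,
                name=_family_name(i),
            )
        )

    # --- role assignment (disjoint, deterministic) --------------------------
    idx = list(range(config.n_mirnas))
    cursor = 0
    cnv_fams = idx[cursor : cursor + config.n_cnv_families]
    cursor += config.n_cnv_families
    seed_mut = idx[cursor : cursor + config.n_seed_mutations]
    cursor += config.n_seed_mutations
    mat_mut = idx[cursor : cursor + config.n_mature_mutations]
    cursor += config.n_mature_mutations
    cluster_members: list[list[int]] = []
    for _ in range(config.n_clusters):
        cluster_members.append(idx[cursor : cursor + config.cluster_size])
        cursor += config.cluster_size
    if cursor > config.n_mirnas:
        raise ValueError("not enough miRNAs for the requested roles")

    # CNV plan: alternate gains and losses, starting with (+2, -1)
    for k, fi in enumerate(cnv_fams):
        fam = families[fi].precursor_name
        copies_ref, copies_target = ((1, 3), (2, 1))[k % 2]
        truth.cnv_plan[fam] = (copies_ref, copies_target)

    # --- reference records (CNV families appear copies_ref times) -----------
    reference: list[MiRNARecord] = []
    for fi, rec in enumerate(families):
        fam = rec.precursor_name
        copies_ref = truth.cnv_plan.get(fam, (1, 1))[0]
        if copies_ref == 1:
            reference.append(
                MiRNARecord(fam, rec.precursor_seq, rec.matures, config.species_ref)
            )
        else:
            for c in range(copies_ref):
                reference.append(
                    MiRNARecord(
                        f"{fam}-{c + 1}",
                        rec.precursor_seq,
                        (Mature(f"{rec.matures[0].name}-{c + 1}",
                                rec.matures[0].offset, rec.matures[0].length),),
                        config.species_ref,
                    )
                )

    # --- target-side sequences: apply planted mutations ----------------------
    target_seqs: dict[str, str] = {
        r.precursor_name: r.precursor_seq for r in families
    }
    for fi in seed_mut + mat_mut:
        rec = families[fi]
        m = rec.matures[0]
        if fi in seed_mut:
            pos = int(rng.integers(lo, hi + 1))  # 1-based within mature
            region = "seed"
        else:
            pos = int(rng.integers(10, m.length))
            region = "mature"
        pos0 = m.offset + pos - 1
        mutated, ref_b, alt_b = _mutate(rec.precursor_seq, pos0, rng)
        target_seqs[rec.precursor_name] = mutated
        truth.planted_mutations.append(
            PlantedMutation(m.name, pos, ref_b, alt_b, region)
        )

    target_records = [
        MiRNARecord(
            r.precursor_name, target_seqs[r.precursor_name], r.matures,
            config.species_target,
        )
        for r in families
    ]

    # --- build plant requests ------------------------------------------------
    requests: list[dict] = []
    clustered = {fi for mem in cluster_members for fi in mem}
    for fi, rec in enumerate(families):
        if fi in clustered:
            continue
        fam = rec.precursor_name
        copies_target = truth.cnv_plan.get(fam, (1, 1))[1]
        for c in range(copies_target):
            strand = "+" if rng.random() < 0.5 else "-"
            seq = target_seqs[fam]
            name = fam if copies_target == 1 and fam not in truth.cnv_plan else f"{fam}-{c + 1}"
            requests.append({
                "id": f"locus:{name}",
                "segment": seq if strand == "+" else revcomp(seq),
                "kind": "locus", "name": name, "family": fam,
                "strand": strand, "length": len(seq),
            })

    # cluster blocks: members laid out 5'->3' in transcription order with
    # intergenic gaps <= cluster_gap and (optionally) one promoter motif
    # upstream of the 5'-most member only
    for ci, mem in enumerate(cluster_members):
        strand = "+" if ci % 2 == 0 else "-"
        promoter = ci % 2 == 0  # odd clusters are promoterless decoys
        gaps = [int(rng.integers(200, config.cluster_gap - 50)) for _ in mem[:-1]]
        upstream_gap = int(rng.integers(150, 400))
        parts: list[tuple[str, str | None]] = []  # (seq, member name or None)
        if promoter:
            parts.append((PROMOTER_CONSENSUS, "__promoter__"))
            parts.append((_random_dna(rng, upstream_gap, config.gc_background), None))
        for k, fi in enumerate(mem):
            parts.append((target_seqs[families[fi].precursor_name],
                          families[fi].precursor_name))
            if k < len(mem) - 1:
                parts.append((_random_dna(rng, gaps[k], config.gc_background), None))
        if strand == "-":
            parts = [(revcomp(s), n) for s, n in reversed(parts)]
        block = "".join(s for s, _ in parts)
        offsets = []
        pos = 0
        for s, n in parts:
            if n is not None:
                offsets.append((n, pos, pos + len(s)))
            pos += len(s)
        requests.append({
            "id": f"cluster:{ci}", "segment": block, "kind": "cluster",
            "strand": strand, "offsets": offsets,
            "members": tuple(families[fi].precursor_name for fi in mem),
            "promoter": promoter, "max_gap": max(gaps) if gaps else 0,
        })

    # exon decoys: plain exons plus two holding a duplicated precursor
    decoy_source = [fi for fi in idx if fi not in clustered and fi not in cnv_fams]
    for ei in range(config.n_exon_decoys):
        exon_len = int(rng.integers(800, 1500))
        embed = None
        if ei < 2 and decoy_source:
            embed = families[decoy_source[ei % len(decoy_source)]]
        if embed is None:
            seg = _random_dna(rng, exon_len, config.gc_background)
            offsets = []
        else:
            pre = target_seqs[embed.precursor_name]
            pad5 = int(rng.integers(100, exon_len - len(pre) - 100))
            pad3 = exon_len - len(pre) - pad5
            seg = (_random_dna(rng, pad5, config.gc_background) + pre
                   + _random_dna(rng, pad3, config.gc_background))
            offsets = [(embed.precursor_name, pad5, pad5 + len(pre))]
        requests.append({
            "id": f"exon:{ei}", "segment": seg, "kind": "exon",
            "offsets": offsets, "name": f"exon-{ei}",
        })

    # --- place everything ----------------------------------------------------
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    base = config.genome_size // config.n_chromosomes
    chrom_sizes = [base] * config.n_chromosomes
    sequences, placements = _plant_segments(
        rng, chrom_names, chrom_sizes, requests, config.gc_background
    )
    genome = [GenomeSequence(c, sequences[c]) for c in chrom_names]

    exon_records = []
    for r in requests:
        chrom, start = placements[r["id"]]
        if r["kind"] == "locus":
            truth.planted_loci.append(
                PlantedLocus(r["name"], chrom, start, start + r["length"],
                             r["strand"], r["family"])
            )
        elif r["kind"] == "cluster":
            for name, o0, o1 in r["offsets"]:
                if name == "__promoter__":
                    truth.promoter_positions.append((chrom, start + o0, r["strand"]))
                else:
                    truth.planted_loci.append(
                        PlantedLocus(name, chrom, start + o0, start + o1,
                                     r["strand"], name)
                    )
            truth.cluster_plan.append(
                ClusterPlan(r["members"], r["max_gap"], r["promoter"],
                            r["strand"], chrom)
            )
        else:  # exon
            end = start + len(r["segment"])
            exon_records.append(BedRecord(chrom, start, end, r["name"], 0.0, "+"))
            for name, o0, o1 in r["offsets"]:
                truth.decoy_loci.append(
                    PlantedLocus(f"{name}::decoy", chrom, start + o0,
                                 start + o1, "+", name)
                )
    truth.exon_decoys = Annotation(exon_records).sorted()

    # --- UTRs with planted seed-match sites ----------------------------------
    utrs = [
        GenomeSequence(f"utr-{u:03d}", _random_dna(rng, config.utr_length,
                                                   config.gc_background))
        for u in range(config.n_utrs)
    ]
    from .targets import seed_heptamer, site_sequence_8mer  # avoids an import cycle

    planted_at: dict[int, list[tuple[int, int]]] = {}

    def plant_site(ui: int, site: str) -> None:
        utr = utrs[ui]
        pos = int(rng.integers(50, utr.length - 50 - len(site)))
        seq = utr.residues[:pos] + site + utr.residues[pos + len(site):]
        utrs[ui] = GenomeSequence(utr.id, seq)
        planted_at.setdefault(ui, []).append((pos, pos + len(site)))

    alleles: list[str] = []  # matures whose site content must be exact
    if config.n_utrs >= 5:
        avail = list(range(config.n_utrs))
        rng.shuffle(avail)
        take = 0
        for fi in seed_mut:
            rec = families[fi]
            mat_ref = rec.mature_seq()
            mat_alt = target_seqs[rec.precursor_name][
                rec.matures[0].offset : rec.matures[0].offset + rec.matures[0].length
            ]
            alleles += [mat_ref, mat_alt]
            for _ in range(3):  # sites the reference allele recognises
                u = avail[take % len(avail)]; take += 1
                plant_site(u, site_sequence_8mer(mat_ref))
                truth.utr_sites.append(
                    UTRSite(utrs[u].id, rec.matures[0].name, "8mer", "ref")
                )
            for _ in range(2):  # sites only the mutated allele recognises
                u = avail[take % len(avail)]; take += 1
                plant_site(u, site_sequence_8mer(mat_alt))
                truth.utr_sites.append(
                    UTRSite(utrs[u].id, rec.matures[0].name, "8mer", "target")
                )
        # scrub chance seed-cores of the tracked alleles from the background,
        # so the truth table is the complete site inventory for them
        cores = {revcomp(seed_heptamer(m)[:6]) for m in alleles}
        for ui in range(config.n_utrs):
            keep = planted_at.get(ui, [])
            for _ in range(8):  # a scrub can create a new core; iterate
                seq = utrs[ui].residues
                dirty = False
                for core in cores:
                    p = seq.find(core)
                    while p != -1:
                        if not any(k0 <= p and p + 6 <= k1 for k0, k1 in keep):
                            for b in "ACGT":
                                cand = seq[: p + 3] + b + seq[p + 4 :]
                                window = cand[max(0, p - 5) : p + 11]
                                if b != seq[p + 3] and not any(
                                    c in window for c in cores
                                ):
                                    seq = cand
                                    dirty = True
                                    break
                        p = seq.find(core, p + 1)
                utrs[ui] = GenomeSequence(utrs[ui].id, seq)
                if not dirty:
                    break

    return SyntheticDataset(
        genome=genome, reference=reference, target_records=target_records,
        exons=truth.exon_decoys, utrs=utrs, truth=truth, config=config,
    )


@dataclass
class RecoveryReport:
    sensitivity: float
    n_planted: int
    n_recovered: int
    false_discoveries: int
    n_exon_overlapping: int
    per_category: dict[str, tuple[int, int]]  # category -> (recovered, planted)


def _reciprocal_overlap(a0, a1, b0, b1) -> float:
    inter = min(a1, b1) - max(a0, b0)
    if inter <= 0:
        return 0.0
    return min(inter / (a1 - a0), inter / (b1 - b0))


def score_recovery(annotation: Annotation, truth: SyntheticTruth) -> RecoveryReport:
    """Overlap-based scoring: a planted locus is recovered when an accepted
    annotation overlaps it >=50% reciprocally on the same strand."""
    clustered = {m for cp in truth.cluster_plan for m in cp.members}
    mutated = {pm.mature_name.replace("miR", "mir", 1) for pm in truth.planted_mutations}

    def category(locus: PlantedLocus) -> str:
        if locus.family in truth.cnv_plan:
            return "cnv"
        if locus.name in clustered:
            return "clustered"
        if locus.name in mutated or locus.family in mutated:
            return "mutated"
        return "plain"

    recovered = 0
    cat: dict[str, list[int]] = {}
    matched_pred: set[int] = set()
    for locus in truth.planted_loci:
        hit = False
        for pi, rec in enumerate(annotation):
            if rec.chrom == locus.chrom and rec.strand == locus.strand:
                if _reciprocal_overlap(rec.start, rec.end, locus.start, locus.end) >= 0.5:
                    hit = True
                    matched_pred.add(pi)
        c = category(locus)
        cat.setdefault(c, [0, 0])
        cat[c][1] += 1
        if hit:
            recovered += 1
            cat[c][0] += 1
    # predictions explained by decoys still are not planted-locus recoveries
    decoy_pred: set[int] = set()
    for locus in truth.decoy_loci:
        for pi, rec in enumerate(annotation):
            if rec.chrom == locus.chrom and rec.strand == locus.strand:
                if _reciprocal_overlap(rec.start, rec.end, locus.start, locus.end) >= 0.5:
                    decoy_pred.add(pi)
    false = len(annotation) - len(matched_pred | decoy_pred)
    n_exon = 0
    for rec in annotation:
        for ex in truth.exon_decoys:
            if rec.chrom == ex.chrom and min(rec.end, ex.end) > max(rec.start, ex.start):
                n_exon += 1
                break
    n_planted = len(truth.planted_loci)
    return RecoveryReport(
        sensitivity=recovered / n_planted if n_planted else 1.0,
        n_planted=n_planted,
        n_recovered=recovered,
        false_discoveries=false,
        n_exon_overlapping=n_exon,
        per_category={k: (v[0], v[1]) for k, v in cat.items()},
    )
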