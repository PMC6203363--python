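"""End-to-end orchestration: simulate -> homology -> fold -> compare ->
cluster -> targets -> phylo, with provenance headers on every output.

The central step, :func:`annotate_target_genome`, recovers each
reference precursor in the target genome (local alignment, coverage
binning), anchors its mature, excises the two arm-hypothesis flank
windows, folds them, and keeps the best window passing the hairpin gate.
Loci are then exon-filtered, de-duplicated, and fed to the variant, CNV
and accounting layers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
from Bio import Align

from . import __version__
from .clusters import MiRNACluster, PromoterScorer, call_polycistrons, cluster
from .compare import (
    AcceptedLocus,
    MatureVariant,
    PipelineAccounting,
    assemble_annotation,
    classify_variant,
    cnv,
    CopyNumberRecord,
)
from .folding import DEFAULT_MODEL, EnergyModel, FoldThresholds, accept_hairpin, fold
from .homology import (
    CandidateWindow,
    GenomeHit,
    align_precursor,
    bin_coverage,
    excise_flanks,
    map_matures,
)
from .phylo import align_and_distance, bootstrap
from .seqio import Annotation, GenomeSequence, MiRNARecord, revcomp, write_bed
from .synthetic_data import GeneratorConfig, SyntheticDataset, generate
from .targets import TargetDiff, diff_targets, scan_sites


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one pipeline run; defaults mirror the analysis constants
    (MFEI <= -0.85, 52-148 nt precursors, 150-nt flanks, seed region 2-9,
    1-kb cluster window, promoter score 0.80)."""

    seed: int = 1
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    thresholds: FoldThresholds = field(default_factory=FoldThresholds)
    seed_range: tuple[int, int] = (2, 9)
    window_d: int = 1000
    promoter_threshold: float = 0.80
    upstream: int = 500
    bootstrap_replicates: int = 1000
    max_tree_taxa: int = 25

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _mature_locator() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def locate_mature(oriented_locus: str, mature: str) -> tuple[int, int] | None:
    """Best local placement of a mature inside an oriented locus sequence."""
    aligner = _mature_locator()
    alignments = aligner.align(oriented_locus, mature)
    if len(alignments) == 0:
        return None
    aln = alignments[0]
    t = aln.aligned[0]
    q = aln.aligned[1]
    t0, t1 = int(t[0][0]), int(t[-1][1])
    if (t1 - t0) < 0.8 * len(mature):
        return None
    # a terminal mismatch gets clipped by local alignment; extend to the
    # full mature footprint where the locus allows it
    t0 = max(0, t0 - int(q[0][0]))
    t1 = min(len(oriented_locus), t1 + (len(mature) - int(q[-1][1])))
    return t0, t1


@dataclass
class AnnotationResult:
    annotation: Annotation
    accounting: PipelineAccounting
    loci: list[AcceptedLocus]
    variants: list[MatureVariant]
    cnv_records: list[CopyNumberRecord]
    mature_hits: list[GenomeHit]
    precursor_hits: list[GenomeHit]


def annotate_target_genome(
    genome: list[GenomeSequence],
    reference: list[MiRNARecord],
    exons: Annotation | None = None,
    model: EnergyModel = DEFAULT_MODEL,
    thresholds: FoldThresholds = FoldThresholds(),
    seed_range: tuple[int, int] = (2, 9),
) -> AnnotationResult:
    """Recover, fold-validate and compare every reference miRNA in a genome."""
    genome_by_id = {g.id: g for g in genome}
    matures = [(m.name, r.mature_seq(m.name)) for r in reference for m in r.matures]
    mature_hits = map_matures(matures, genome)

    accepted: list[AcceptedLocus] = []
    precursor_hits: list[GenomeHit] = []
    for rec in reference:
        hits = align_precursor(rec.precursor_name, rec.precursor_seq, genome)
        precursor_hits.extend(hits)
        mat = rec.matures[0]
        mat_seq = rec.mature_seq(mat.name)
        for hit in hits:
            if hit.bin == "rejected":
                continue
            locus = genome_by_id[hit.chrom].residues[hit.start : hit.end]
            oriented = locus if hit.strand == "+" else revcomp(locus)
            placed = locate_mature(oriented, mat_seq)
            if placed is None:
                continue
            o0, o1 = placed
            if hit.strand == "+":
                m_start, m_end = hit.start + o0, hit.start + o1
            else:
                m_start, m_end = hit.end - o1, hit.end - o0
            pseudo = GenomeHit(
                rec.precursor_name, hit.chrom, hit.strand, m_start, m_end,
                hit.query_coverage, hit.identity, hit.bin, hit.score,
            )
            windows = excise_flanks(pseudo, genome_by_id)
            # also fold the precursor hit span itself (plus small margins):
            # flank windows can let a precursor arm pair into background,
            # while the mapped span alone folds as the hairpin it is
            chrom_len = genome_by_id[hit.chrom].length
            p0, p1 = max(0, hit.start - 10), min(chrom_len, hit.end + 10)
            span_seq = genome_by_id[hit.chrom].residues[p0:p1]
            if "N" not in span_seq:
                if hit.strand == "-":
                    span_seq = revcomp(span_seq)
                    sm_off = p1 - m_end
                else:
                    sm_off = m_start - p0
                windows.append(
                    CandidateWindow(
                        query_name=rec.precursor_name, chrom=hit.chrom,
                        strand=hit.strand, start=p0, end=p1,
                        arm_hypothesis="precursor-span", sequence=span_seq,
                        mature_offset=sm_off, mature_length=m_end - m_start,
                    )
                )
            best: tuple[float, AcceptedLocus] | None = None
            for window in windows:
                st = fold(window.sequence, model)
                span = (window.mature_offset,
                        window.mature_offset + window.mature_length)
                dec = accept_hairpin(st, span, thresholds)
                if not dec.accepted:
                    continue
                s0, s1 = dec.stem_span
                if window.strand == "+":
                    g0, g1 = window.start + s0, window.start + s1
                else:
                    g0, g1 = window.end - s1, window.end - s0
                locus_rec = AcceptedLocus(
                    name=rec.precursor_name, chrom=window.chrom,
                    strand=window.strand, start=g0, end=g1,
                    mfei=dec.span_mfei,
                    mature_target_seq=window.sequence[span[0] : span[1]],
                )
                if best is None or dec.span_mfei < best[0]:
                    best = (dec.span_mfei, locus_rec)
            if best is not None:
                accepted.append(best[1])

    # mature variants: one pair per reference mature that was recovered
    seen: set[str] = set()
    variants: list[MatureVariant] = []
    for rec in reference:
        mat = rec.matures[0]
        if mat.name in seen:
            continue
        loci = [l for l in accepted if l.name == rec.precursor_name]
        if not loci:
            continue
        seen.add(mat.name)
        # report the variant allele when any recovered copy carries one
        tgt = min((l.mature_target_seq for l in loci), key=lambda s: s == rec.mature_seq())
        variants.append(
            classify_variant(rec.mature_seq(), tgt, mat.name, seed_range)
        )

    annotation, accounting, kept = assemble_annotation(
        accepted, exons, reference, variants
    )
    cnv_records = cnv(
        (r.precursor_name for r in reference),
        ((l.name, l.chrom, l.start, l.end, l.strand) for l in kept),
    )
    return AnnotationResult(
        annotation, accounting, kept, variants, cnv_records,
        mature_hits, precursor_hits,
    )


def _header(config: RunConfig) -> str:
    return (
        f"# mircompare {__version__}\n"
        f"# seed={config.seed} config={config.config_hash()}\n"
    )


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig, outdir: str | Path,
                 dataset: SyntheticDataset | None = None) -> dict:
    """Execute every stage on the (synthetic) dataset and write the run
    directory: annotation.bed, variants.tsv, cnv.tsv, clusters.tsv,
    sites.tsv, diff.tsv, tree.nwk, accounting.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = dataset or generate(config.generator)

    result = annotate_target_genome(
        ds.genome, ds.reference, exons=ds.exons,
        thresholds=config.thresholds, seed_range=config.seed_range,
    )
    write_bed(result.annotation, outdir / "annotation.bed")

    _write_tsv(pd.DataFrame(
        [(v.mirna_name, v.seq_ref, v.seq_target, v.n_subs,
          ";".join(sorted(v.regions)),
          ";".join(f"{s.position}{s.ref_base}>{s.alt_base}" for s in v.substitutions))
         for v in result.variants],
        columns=["name", "seq_ref", "seq_target", "n_subs", "regions", "substitutions"],
    ), outdir / "variants.tsv", config)

    _write_tsv(pd.DataFrame(
        [(c.family, c.copies_ref, c.copies_target, c.delta) for c in result.cnv_records],
        columns=["family", "copies_ref", "copies_target", "delta"],
    ), outdir / "cnv.tsv", config)

    acc = result.accounting
    _write_tsv(pd.DataFrame(
        [(acc.total, acc.conserved, acc.not_found, acc.cnv,
          acc.polymorphic, acc.seed_mutated)],
        columns=["total", "conserved", "not_found", "cnv_families",
                 "polymorphic", "seed_mutated"],
    ), outdir / "accounting.tsv", config)

    scorer = PromoterScorer.from_consensus(threshold=config.promoter_threshold)
    clusters_ = call_polycistrons(
        cluster(result.annotation, config.window_d), ds.genome, scorer,
        upstream=config.upstream,
    )
    _write_tsv(pd.DataFrame(
        [(c.chrom, c.strand, c.window_d, len(c), ",".join(c.member_names),
          c.span[0], c.span[1], c.polycistronic,
          c.promoter[0] if c.promoter else -1,
          round(c.promoter[1], 4) if c.promoter else 0.0)
         for c in clusters_],
        columns=["chrom", "strand", "window_d", "n_members", "members",
                 "start", "end", "polycistronic", "promoter_pos", "promoter_score"],
    ), outdir / "clusters.tsv", config)

    # seed-mutated matures: target-set diffs against the reference allele
    ref_mat = {r.matures[0].name: r.mature_seq() for r in ds.reference}
    site_rows, diff_rows = [], []
    diffs: list[TargetDiff] = []
    for v in result.variants:
        if "seed" not in v.regions:
            continue
        for s in scan_sites(v.mirna_name, v.seq_ref, ds.utrs):
            site_rows.append((s.utr_id, s.mirna_name, "ref", s.site_type, s.start, s.end))
        for s in scan_sites(v.mirna_name, v.seq_target, ds.utrs):
            site_rows.append((s.utr_id, s.mirna_name, "target", s.site_type, s.start, s.end))
        d = diff_targets(v.mirna_name, v.seq_ref, v.seq_target, ds.utrs)
        diffs.append(d)
        diff_rows.append((v.mirna_name, len(d.common), len(d.lost), len(d.gained),
                          ",".join(sorted(d.lost)), ",".join(sorted(d.gained))))
    _write_tsv(pd.DataFrame(
        site_rows, columns=["utr_id", "mirna", "allele", "site_type", "start", "end"]
    ), outdir / "sites.tsv", config)
    _write_tsv(pd.DataFrame(
        diff_rows, columns=["mirna", "n_common", "n_lost", "n_gained", "lost", "gained"]
    ), outdir / "diff.tsv", config)

    tree = None
    named = [(m.name, r.mature_seq(m.name)) for r in ds.reference for m in r.matures]
    if 3 <= len(named) <= config.max_tree_taxa:
        alignment, _ = align_and_distance(named)
        tree = bootstrap(alignment, config.bootstrap_replicates, seed=config.seed)
        with open(outdir / "tree.nwk", "w") as fh:
            fh.write(tree.to_newick() + "\n")

    return {
        "result": result,
        "clusters": clusters_,
        "diffs": diffs,
        "tree": tree,
        "dataset": ds,
        "outdir": outdir,
    }
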