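"""Readers/writers for the formats the pipeline consumes and the internal record model.

Everything downstream works on :class:`GenomeSequence`, :class:`MiRNARecord`
and :class:`Annotation` instances produced here.  DNA is the canonical
internal alphabet (genomes are DNA); RNA appears only at the folding
boundary.  All coordinates are 0-based half-open; 1-based numbers occur only
in human-readable reports (e.g. mature substitution positions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


class SeqIOError(ValueError):
    """Malformed sequence input (duplicate id, empty record, bad alphabet)."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named chromosome/contig: uppercase DNA over {A,C,G,T,N}."""

    id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


class Mature(NamedTuple):
    name: str
    offset: int  # 0-based start within the precursor
    length: int


@dataclass(frozen=True)
class MiRNARecord:
    """A named precursor with its mature sequence(s) located inside it."""

    precursor_name: str
    precursor_seq: str
    matures: tuple[Mature, ...]
    species_tag: str = ""

    def __post_init__(self) -> None:
        if not self.precursor_name:
            raise SeqIOError("precursor name must be non-empty")
        for m in self.matures:
            if not m.name:
                raise SeqIOError(f"{self.precursor_name}: mature name empty")
            if m.offset < 0 or m.offset + m.length > len(self.precursor_seq):
                raise SeqIOError(
                    f"{self.precursor_name}: mature {m.name} "
                    f"[{m.offset},{m.offset + m.length}) outside precursor"
                )

    def mature_seq(self, name: str | None = None) -> str:
        m = self.matures[0] if name is None else next(
            x for x in self.matures if x.name == name
        )
        return self.precursor_seq[m.offset : m.offset + m.length]

    @property
    def family(self) -> str:
        return strip_copy_suffix(self.precursor_name)


def strip_copy_suffix(name: str) -> str:
    """Family key: drop one trailing ``-<digits>`` copy suffix.

    Letter suffixes denote distinct families (mir-2284z vs mir-2284y), so
    only numeric copy counters are stripped (mir-2284z-1 -> mir-2284z).
    A bare family number is not a copy suffix: mir-219 stays mir-219
    (the component before a true copy counter carries the family id).
    """
    stem, sep, tail = name.rpartition("-")
    if sep and tail.isdigit() and not stem.lower().endswith(("mir", "let")):
        return stem
    return name


class BedRecord(NamedTuple):
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    name: str
    score: float
    strand: str


@dataclass
class Annotation:
    """An ordered list of BED6-style stranded intervals."""

    records: list[BedRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def sorted(self) -> "Annotation":
        return Annotation(sorted(self.records, key=lambda r: (r.chrom, r.start, r.end)))


def _clean_residues(raw: str, rec_id: str, *, allow_n: bool = True) -> str:
    residues = raw.upper().replace("U", "T")
    bad = set(residues) - VALID_BASES
    if bad or (not allow_n and "N" in residues):
        raise SeqIOError(f"record {rec_id!r}: illegal characters {sorted(bad)}")
    if not residues:
        raise SeqIOError(f"record {rec_id!r}: empty sequence")
    return residues


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a multi-record FASTA; uppercase, U->T, reject duplicates/empties."""
    out: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append(GenomeSequence(rec.id, _clean_residues(str(rec.seq), rec.id)))
    return out


def write_fasta(records: Iterable[GenomeSequence | tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            rid, seq = (rec.id, rec.residues) if isinstance(rec, GenomeSequence) else rec
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_mirna_set(
    fasta_precursors: str | Path,
    fasta_matures: str | Path,
    index_table: str | Path,
    species_tag: str = "",
) -> list[MiRNARecord]:
    """Assemble MiRNARecords from precursor/mature FASTAs plus a mature index.

    The index is tab-separated with columns precursor_name, mature_name and
    optionally offset and length; missing offsets are recovered by substring
    search of the mature inside its precursor.  A mature that is not a
    substring of its precursor drops the whole record with a warning (the
    same redundancy discipline the annotation filters apply).
    """
    precursors = {g.id: g.residues for g in read_fasta(fasta_precursors)}
    matures = {g.id: g.residues for g in read_fasta(fasta_matures)}
    idx = pd.read_csv(index_table, sep="\t", comment="#", dtype=str)
    required = {"precursor_name", "mature_name"}
    if not required <= set(idx.columns):
        raise SeqIOError(f"index table missing columns {required - set(idx.columns)}")

    by_precursor: dict[str, list[Mature]] = {}
    dropped: set[str] = set()
    for row in idx.itertuples(index=False):
        pname, mname = row.precursor_name, row.mature_name
        if pname not in precursors:
            raise SeqIOError(f"index names unknown precursor {pname!r}")
        if mname not in matures:
            raise SeqIOError(f"index names unknown mature {mname!r}")
        pseq, mseq = precursors[pname], matures[mname]
        offset = getattr(row, "offset", None)
        if offset is None or pd.isna(offset):
            offset = pseq.find(mseq)
        else:
            offset = int(offset)
            if pseq[offset : offset + len(mseq)] != mseq:
                offset = pseq.find(mseq)  # stated offset stale; re-derive
        if offset < 0:
            warnings.warn(
                f"mature {mname} absent from precursor {pname}; record dropped"
            )
            dropped.add(pname)
            continue
        by_precursor.setdefault(pname, []).append(Mature(mname, offset, len(mseq)))

    out = []
    for pname, pseq in precursors.items():
        if pname in dropped or pname not in by_precursor:
            continue
        out.append(
            MiRNARecord(pname, pseq, tuple(by_precursor[pname]), species_tag)
        )
    return out


def write_mirna_index(records: Iterable[MiRNARecord], path: str | Path) -> None:
    rows = [
        (r.precursor_name, m.name, m.offset, m.length)
        for r in records
        for m in r.matures
    ]
    pd.DataFrame(
        rows, columns=["precursor_name", "mature_name", "offset", "length"]
    ).to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> Annotation:
    recs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 else 0.0
            strand = parts[5] if len(parts) > 5 else "+"
            if not 0 <= start < end:
                raise SeqIOError(f"bad BED interval {chrom}:{start}-{end}")
            recs.append(BedRecord(chrom, start, end, name, score, strand))
    return Annotation(recs)


def write_bed(annotation: Annotation, path: str | Path) -> None:
    """BED6, tab-separated, 0-based half-open. No track lines."""
    with open(path, "w") as fh:
        for r in annotation:
            if not 0 <= r.start < r.end:
                raise SeqIOError(f"bad BED interval {r.chrom}:{r.start}-{r.end}")
            score = int(r.score) if float(r.score).is_integer() else r.score
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{score}\t{r.strand}\n")


def read_gff3_exons(path: str | Path) -> Annotation:
    """Exon features from a GFF3; attribute parsing limited to ID."""
    recs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8 or parts[2].lower() != "exon":
                continue
            chrom, start, end, strand = parts[0], int(parts[3]) - 1, int(parts[4]), parts[6]
            name = "."
            if len(parts) > 8:
                for kv in parts[8].split(";"):
                    if kv.startswith("ID="):
                        name = kv[3:]
            recs.append(BedRecord(chrom, start, end, name, 0.0, strand))
    return Annotation(recs)


def write_newick(tree, path: str | Path) -> None:
    """Serialize a phylo tree (anything with ``to_newick()``) to a file."""
    text = tree.to_newick() if hasattr(tree, "to_newick") else str(tree)
    with open(path, "w") as fh:
        fh.write(text.rstrip() + "\n")


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U").replace("t", "u")


def translate_to_dna(seq: Seq | str) -> str:
    return str(seq).upper().replace("U", "T")
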