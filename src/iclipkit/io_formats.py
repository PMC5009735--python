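"""Readers and writers for every external format the pipeline touches.

Coordinate contract: everything in memory is 0-based half-open. BED and
bedGraph are written 0-based half-open; GTF is converted from/to 1-based
closed on read/write. FASTQ qualities are Sanger-encoded and preserved
byte-exact through a round trip.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from .annotation import FeatureInterval, Gene, GenomeAnnotation, Transcript

logger = logging.getLogger(__name__)

_DNA = set("ACGTN")
_UMI_RE = re.compile(r"_([ACGT]{4})$")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - _DNA
        if bad:
            raise ValueError(f"non-nucleotide characters in {self.id}: {sorted(bad)}")


@dataclass(frozen=True)
class ReadRecord:
    id: str
    sequence: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise FormatError(
                f"read {self.id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str
    umi: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad alignment span [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if len(self.umi) != 4 or set(self.umi) - set("ACGT"):
            raise ValueError(f"bad UMI {self.umi!r}")


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")


@dataclass
class AlignmentParseResult:
    records: list[AlignmentRecord]
    n_unmapped: int = 0
    n_secondary: int = 0
    n_missing_umi: int = 0


# ---------------------------------------------------------------- FASTA/FASTQ


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into uppercase :class:`SequenceRecord` objects."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(f"{path}:{lineno}: expected FASTA header line")
                break
    return [SequenceRecord(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Read 4-line FASTQ records; qualities are kept byte-exact."""
    out = []
    try:
        with open(path) as fh:
            for title, seq, qual in FastqGeneralIterator(fh):
                out.append(ReadRecord(title.split()[0], seq, qual))
    except ValueError as exc:  # Biopython signals truncation/length mismatch
        raise FormatError(f"{path}: {exc}") from exc
    return out


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{rec.qualities}\n")


# ----------------------------------------------------------------- alignments


def _umi_from_name(name: str) -> str | None:
    m = _UMI_RE.search(name)
    return m.group(1) if m else None


def read_alignments(path: str | Path, on_missing_umi: str = "error") -> AlignmentParseResult:
    """Read SAM/BAM or 6-column BED alignments into the internal convention.

    The UMI travels as a ``_<UMI>`` suffix on the read name (SAM) or on the
    BED name column. Unmapped and secondary/supplementary records are skipped
    and counted. ``on_missing_umi`` is ``"error"`` or ``"skip"``.
    """
    if on_missing_umi not in ("error", "skip"):
        raise ValueError("on_missing_umi must be 'error' or 'skip'")
    path = Path(path)
    result = AlignmentParseResult(records=[])
    if path.suffix.lower() in (".sam", ".bam"):
        mode = "rb" if path.suffix.lower() == ".bam" else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
            for aln in fh:
                if aln.is_unmapped:
                    result.n_unmapped += 1
                    continue
                if aln.is_secondary or aln.is_supplementary:
                    result.n_secondary += 1
                    continue
                umi = _umi_from_name(aln.query_name)
                if umi is None:
                    if on_missing_umi == "error":
                        raise FormatError(f"{path}: read {aln.query_name} lacks _UMI suffix")
                    result.n_missing_umi += 1
                    logger.warning("skipping %s: missing UMI suffix", aln.query_name)
                    continue
                result.records.append(
                    AlignmentRecord(
                        read_id=aln.query_name,
                        chrom=aln.reference_name,
                        start=aln.reference_start,
                        end=aln.reference_end,
                        strand="-" if aln.is_reverse else "+",
                        umi=umi,
                    )
                )
        return result
    # BED6 dialect
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, start, end, name, _score, strand = fields[:6]
            umi = _umi_from_name(name)
            if umi is None:
                if on_missing_umi == "error":
                    raise FormatError(f"{path}:{lineno}: name {name!r} lacks _UMI suffix")
                result.n_missing_umi += 1
                logger.warning("skipping %s: missing UMI suffix", name)
                continue
            result.records.append(
                AlignmentRecord(name, chrom, int(start), int(end), strand, umi)
            )
    return result


def write_alignments_bed(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tname\tscore\tstrand\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.read_id}\t0\t{r.strand}\n")


# ----------------------------------------------------------------- BED tracks


def write_bed(intervals: list[Interval], path: str | Path) -> None:
    """Write BED6; unsorted input is sorted internally (and logged)."""
    keys = [(iv.chrom, iv.start) for iv in intervals]
    if keys != sorted(keys):
        logger.info("write_bed: sorting %d unsorted intervals", len(intervals))
        intervals = sorted(intervals, key=lambda iv: (iv.chrom, iv.start))
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tname\tscore\tstrand\n")
        for iv in intervals:
            score = int(iv.score) if float(iv.score).is_integer() else iv.score
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n")


def read_bed(path: str | Path) -> list[Interval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED columns")
            out.append(
                Interval(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=fields[3],
                    score=float(fields[4]),
                    strand=fields[5],
                )
            )
    return out


def crosslinks_to_intervals(table: pd.DataFrame) -> list[Interval]:
    cols = ["chrom", "position", "strand", "count", "sample"]
    return [
        Interval(chrom=chrom, start=int(pos), end=int(pos) + 1, name=str(sample),
                 score=int(cnt), strand=strand)
        for chrom, pos, strand, cnt, sample in table[cols].itertuples(index=False, name=None)
    ]


def write_crosslinks_bed(table: pd.DataFrame, path: str | Path) -> None:
    """Serialize a crosslink table as BED6 (score = unique cDNA count)."""
    write_bed(crosslinks_to_intervals(table), path)


def read_crosslinks_bed(path: str | Path) -> pd.DataFrame:
    from .crosslinks import make_crosslink_table  # local import: avoid cycle

    ivs = read_bed(path)
    return make_crosslink_table(
        [(iv.chrom, iv.start, iv.strand, int(iv.score), iv.name) for iv in ivs]
    )


def write_bedgraph(table: pd.DataFrame, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write per-strand bedGraph coverage (``.plus``/``.minus`` files).

    One line per crosslink position; positions never overlap because the
    table is keyed by position.
    """
    path_prefix = Path(path_prefix)
    paths = (path_prefix.with_suffix(".plus.bedgraph"), path_prefix.with_suffix(".minus.bedgraph"))
    for strand, out in zip("+-", paths):
        sub = table[table["strand"] == strand].sort_values(["chrom", "position"])
        with open(out, "w") as fh:
            fh.write(f"# bedGraph strand {strand}\n")
            for chrom, pos, cnt in sub[["chrom", "position", "count"]].itertuples(
                index=False, name=None
            ):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{cnt}\n")
    return paths


# ------------------------------------------------------------------------ GTF

_CLASS_TO_GTF = {"5UTR": "five_prime_utr", "ORF": "CDS", "3UTR": "three_prime_utr", "ncRNA": "ncRNA"}
_GTF_TO_CLASS = {v: k for k, v in _CLASS_TO_GTF.items()}


def write_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write the annotation as GTF (1-based closed coordinates).

    Intron features are implicit (gaps between exonic feature intervals of a
    transcript) and are reconstructed on read.
    """
    with open(path, "w") as fh:
        for g in annotation.genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\ticlipkit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{g.chrom}\ticlipkit\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                    f"{g.strand}\t.\t{tattrs}\n"
                )
                for f in sorted(t.features, key=lambda f: f.start):
                    if f.cls == "intron":
                        continue
                    fh.write(
                        f"{g.chrom}\ticlipkit\t{_CLASS_TO_GTF[f.cls]}\t{f.start + 1}\t"
                        f"{f.end}\t.\t{g.strand}\t.\t{tattrs}\n"
                    )


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path: str | Path, chrom_lengths: dict[str, int] | None = None) -> GenomeAnnotation:
    """Parse GTF (keys gene_id/transcript_id) into a :class:`GenomeAnnotation`.

    Coordinates are converted from 1-based closed to 0-based half-open.
    When ``chrom_lengths`` is not given, each chromosome length is inferred
    as the maximum annotated end.
    """
    genes: dict[str, Gene] = {}
    transcripts: dict[tuple[str, str], Transcript] = {}
    max_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, feature, start1, end1, _score, strand, _frame, attr_str = fields
            start, end = int(start1) - 1, int(end1)
            attrs = dict(_ATTR_RE.findall(attr_str))
            gid = attrs.get("gene_id")
            if gid is None:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            max_end[chrom] = max(max_end.get(chrom, 0), end)
            if feature == "gene":
                genes[gid] = Gene(
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    biotype=attrs.get("gene_biotype", "protein_coding"),
                )
            elif feature == "transcript":
                tid = attrs["transcript_id"]
                transcripts[(gid, tid)] = Transcript(transcript_id=tid, features=[])
            elif feature in _GTF_TO_CLASS or feature == "exon":
                if feature == "exon":
                    continue  # exon structure is implied by the typed features
                tid = attrs["transcript_id"]
                t = transcripts.setdefault((gid, tid), Transcript(transcript_id=tid, features=[]))
                t.features.append(FeatureInterval(_GTF_TO_CLASS[feature], start, end))
            else:
                raise FormatError(f"{path}:{lineno}: unsupported feature {feature!r}")
    for (gid, _tid), t in transcripts.items():
        # reconstruct introns as gaps between sorted exonic features
        feats = sorted(t.features, key=lambda f: f.start)
        introns = [
            FeatureInterval("intron", a.end, b.start)
            for a, b in zip(feats, feats[1:])
            if b.start > a.end
        ]
        t.features = sorted(feats + introns, key=lambda f: f.start)
        if gid not in genes:
            raise FormatError(f"transcript {t.transcript_id} references unknown gene {gid}")
        genes[gid].transcripts.append(t)
    lengths = dict(chrom_lengths) if chrom_lengths else max_end
    return GenomeAnnotation(list(genes.values()), lengths)
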