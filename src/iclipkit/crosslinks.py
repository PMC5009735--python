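"""Demultiplexing, UMI deduplication and crosslink-site extraction.

The crosslink site is the nucleotide at position -1 of the aligned read start
in transcript direction: for a + strand alignment starting at s (0-based) the
crosslink is s-1 on +; for a - strand alignment with half-open end e it is e
on -. PCR duplicates are alignments identical in (chrom, crosslink position,
strand, UMI); each surviving distinct UMI is one unique cDNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import AlignmentRecord, ReadRecord

logger = logging.getLogger(__name__)

CROSSLINK_COLUMNS = ["chrom", "position", "strand", "count", "sample"]


def make_crosslink_table(rows: list[tuple]) -> pd.DataFrame:
    """Build a validated crosslink table from (chrom, pos, strand, count, sample) rows."""
    df = pd.DataFrame(rows, columns=CROSSLINK_COLUMNS)
    validate_crosslink_table(df)
    return df.sort_values(["chrom", "position", "strand"]).reset_index(drop=True)


def empty_crosslink_table() -> pd.DataFrame:
    return pd.DataFrame(columns=CROSSLINK_COLUMNS)


def validate_crosslink_table(df: pd.DataFrame) -> None:
    if list(df.columns) != CROSSLINK_COLUMNS:
        raise ValueError(f"crosslink table must have columns {CROSSLINK_COLUMNS}")
    if len(df):
        if (df["count"] < 1).any():
            raise ValueError("unique cDNA counts must be >= 1")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be + or -")
        if df.duplicated(["chrom", "position", "strand", "sample"]).any():
            raise ValueError("one row per (chrom, position, strand, sample) required")


@dataclass
class DemuxResult:
    by_sample: dict[str, list[ReadRecord]]
    unassigned: list[ReadRecord] = field(default_factory=list)


def demultiplex(reads: list[ReadRecord], sample_codes: list[str]) -> DemuxResult:
    """Assign reads to samples by bases 1-3 and record bases 4-7 as the UMI.

    All 7 barcode bases are trimmed from sequence and qualities; the UMI is
    recorded as a ``_<UMI>`` suffix on the read id. Reads shorter than 8 nt or
    with an unknown sample code go to the unassigned bucket untouched.
    """
    codes = list(sample_codes)
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate sample codes")
    for code in codes:
        if len(code) != 3:
            raise ValueError(f"sample code {code!r} is not 3 bases")
    result = DemuxResult(by_sample={c: [] for c in codes})
    for read in reads:
        code = read.sequence[:3]
        if len(read.sequence) < 8 or code not in result.by_sample:
            result.unassigned.append(read)
            continue
        umi = read.sequence[3:7]
        result.by_sample[code].append(
            ReadRecord(f"{read.id}_{umi}", read.sequence[7:], read.qualities[7:])
        )
    return result


def crosslink_position(aln: AlignmentRecord) -> tuple[str, int, str]:
    """(chrom, position, strand) of the crosslinked nucleotide for an alignment."""
    if aln.strand == "+":
        return aln.chrom, aln.start - 1, "+"
    return aln.chrom, aln.end, "-"


def extract_crosslinks(
    alignments: list[AlignmentRecord],
    chrom_lengths: dict[str, int] | None = None,
    sample: str = "S",
) -> pd.DataFrame:
    """Collapse PCR duplicates and count unique cDNAs per crosslink site.

    Duplicates are identical (chrom, crosslink position, strand, UMI);
    unique_cdna_count is the number of distinct UMIs at a site. Alignments
    whose crosslink falls off the chromosome (position -1 on +, or position ==
    chromosome length on -) are dropped with a counter logged.
    """
    seen: set[tuple[str, int, str, str]] = set()
    counts: dict[tuple[str, int, str], int] = {}
    n_off = 0
    for aln in alignments:
        chrom, pos, strand = crosslink_position(aln)
        if pos < 0 or (chrom_lengths is not None and pos >= chrom_lengths.get(chrom, pos + 1)):
            n_off += 1
            continue
        key = (chrom, pos, strand, aln.umi)
        if key in seen:
            continue
        seen.add(key)
        counts[(chrom, pos, strand)] = counts.get((chrom, pos, strand), 0) + 1
    if n_off:
        logger.info("extract_crosslinks: dropped %d off-chromosome crosslinks", n_off)
    return make_crosslink_table(
        [(c, p, s, n, sample) for (c, p, s), n in counts.items()]
    ) if counts else empty_crosslink_table()


def merge_replicates(tables: list[pd.DataFrame], sample: str = "merged") -> pd.DataFrame:
    """Sum unique cDNA counts per site across replicate crosslink tables."""
    nonempty = [t for t in tables if len(t)]
    if not nonempty:
        return empty_crosslink_table()
    chrom_sets = [set(t["chrom"]) for t in nonempty]
    union = set.union(*chrom_sets)
    # replicates must come from one genome: a chromosome name present in some
    # tables but absent from a table that has sites is fine (no sites there),
    # so only genuinely conflicting dialects (e.g. "chr1" vs "1") are flagged
    bare = {c.removeprefix("chr") for c in union}
    if len(bare) < len(union):
        offenders = sorted(c for c in union if "chr" + c.removeprefix("chr") in union and not c.startswith("chr"))
        raise ValueError(f"conflicting chromosome naming across replicates: {offenders}")
    merged = (
        pd.concat(nonempty, ignore_index=True)
        .groupby(["chrom", "position", "strand"], as_index=False)["count"]
        .sum()
    )
    merged["sample"] = sample
    return make_crosslink_table(list(merged[["chrom", "position", "strand", "count", "sample"]].itertuples(index=False, name=None)))
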