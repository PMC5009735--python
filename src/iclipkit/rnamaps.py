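"""Junction-centered positional metaprofiles (RNA maps) of crosslink sites.

Profiles are computed around ORF-3'UTR and 3'UTR-intergenic junctions over
transcript-directional offsets -flank..+flank (negative = toward the 5' end).
Offset 0 is the first nucleotide of the 3'UTR (ORF-3'UTR) or the first
nucleotide after the transcript end (3'UTR-intergenic). The raw per-offset sum
of crosslink counts is normalized by the total number of crosslinks used and
by the number of junctions whose transcript covers that offset (the length
correction); an alternative normalization by all crosslinks in the table is
emitted alongside. Smoothing is a centered running mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation

JUNCTION_TYPES = ("ORF-3UTR", "3UTR-intergenic")


@dataclass(frozen=True)
class Junction:
    chrom: str
    position: int  # genomic coordinate of offset 0
    strand: str
    gene_id: str
    upstream_coverage: int  # nt covered by the transcript at offsets < 0
    downstream_coverage: int  # nt covered at offsets >= 0


@dataclass
class MetaProfile:
    junction_type: str
    table: pd.DataFrame  # offset, sense_raw, antisense_raw, densities, smoothed
    n_junctions: int
    n_crosslinks_used: int


def collect_junctions(annotation: GenomeAnnotation, junction_type: str) -> list[Junction]:
    """One junction per gene, from the transcript with the longest 3'UTR.

    Genes without a 3'UTR are skipped.
    """
    if junction_type not in JUNCTION_TYPES:
        raise ValueError(f"junction_type must be one of {JUNCTION_TYPES}")
    out = []
    for gene in annotation.genes:
        best, best_len = None, -1
        for t in gene.transcripts:
            utr3 = t.features_of("3UTR")
            if not utr3:
                continue
            length = sum(len(f) for f in utr3)
            if length > best_len:
                best, best_len = (t, utr3), length
        if best is None:
            continue
        t, utr3 = best
        # the 3'UTR interval closest to the transcript 3' end
        f = max(utr3, key=lambda f: f.end) if gene.strand == "+" else min(utr3, key=lambda f: f.start)
        tx_len = t.end - t.start
        if junction_type == "ORF-3UTR":
            if gene.strand == "+":
                jpos = f.start
                up = jpos - t.start
                down = t.end - jpos
            else:
                jpos = f.end - 1
                up = t.end - 1 - jpos
                down = jpos - t.start + 1
        else:  # first nucleotide after the transcript end
            if gene.strand == "+":
                jpos = t.end
                up = tx_len
            else:
                jpos = t.start - 1
                up = tx_len
            down = 10**9  # intergenic side is always covered
        out.append(Junction(gene.chrom, jpos, gene.strand, gene.gene_id, up, down))
    return out


def rna_map(
    table: pd.DataFrame,
    junctions: list[Junction],
    flank: int = 300,
    smooth_window: int = 15,
    junction_type: str = "ORF-3UTR",
) -> MetaProfile:
    """Positional crosslink density around a set of junctions.

    Crosslinks within +/- flank of a junction contribute their unique cDNA
    count at their transcript-direction offset, split into sense and antisense
    relative to the junction's gene strand.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if not junctions:
        raise ValueError("no junctions")
    n_off = 2 * flank + 1
    offsets = np.arange(-flank, flank + 1)
    sense_raw = np.zeros(n_off)
    antisense_raw = np.zeros(n_off)
    coverage = np.zeros(n_off)
    for j in junctions:
        covered = ((offsets < 0) & (-offsets <= j.upstream_coverage)) | (
            (offsets >= 0) & (offsets < j.downstream_coverage)
        )
        coverage += covered

    if len(table):
        by_chrom = {c: sub for c, sub in table.groupby("chrom")}
        for j in junctions:
            sub = by_chrom.get(j.chrom)
            if sub is None:
                continue
            near = sub[(sub["position"] >= j.position - flank) & (sub["position"] <= j.position + flank)]
            for pos, strand, cnt in near[["position", "strand", "count"]].itertuples(
                index=False, name=None
            ):
                d = int(pos) - j.position if j.strand == "+" else j.position - int(pos)
                if abs(d) > flank:
                    continue
                if strand == j.strand:
                    sense_raw[d + flank] += cnt
                else:
                    antisense_raw[d + flank] += cnt

    n_used = int(sense_raw.sum() + antisense_raw.sum())
    n_total = int(table["count"].sum()) if len(table) else 0

    def normalize(raw: np.ndarray, denom_counts: int) -> np.ndarray:
        out = np.zeros_like(raw)
        if denom_counts:
            mask = coverage > 0
            out[mask] = raw[mask] / (denom_counts * coverage[mask])
        return out

    sense_norm = normalize(sense_raw, n_used)
    antisense_norm = normalize(antisense_raw, n_used)
    sense_norm_total = normalize(sense_raw, n_total)

    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(sense_norm, kernel, mode="same")

    df = pd.DataFrame({
        "offset": offsets,
        "sense_raw": sense_raw,
        "antisense_raw": antisense_raw,
        "n_covering_junctions": coverage.astype(int),
        "sense_density": sense_norm,
        "antisense_density": antisense_norm,
        "sense_density_total_norm": sense_norm_total,
        "smoothed_density": smoothed,
    })
    return MetaProfile(junction_type, df, len(junctions), n_used)
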