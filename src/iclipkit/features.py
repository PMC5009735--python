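"""Genomic-feature assignment of crosslink sites and class-level statistics.

A crosslink in a same-strand protein-coding gene is assigned a single class
with the priority 3UTR > 5UTR > ORF > intron across overlapping transcripts;
ncRNA genes give "ncRNA"; a site inside a gene on the opposite strand only is
"antisense" (excluded from 3'UTR statistics); anything else is "intergenic".
"""

from __future__ import annotations

import pandas as pd

from .annotation import GenomeAnnotation

_PRIORITY = ("3UTR", "5UTR", "ORF", "intron")


def assign_feature(annotation: GenomeAnnotation, chrom: str, pos: int, strand: str) -> str:
    genes = annotation.genes_overlapping(chrom, pos)
    sense = [g for g in genes if g.strand == strand]
    if not sense:
        return "antisense" if genes else "intergenic"
    classes: set[str] = set()
    for g in sense:
        if g.biotype == "ncRNA":
            classes.add("ncRNA")
            continue
        hit = False
        for t in g.transcripts:
            for f in t.features:
                if f.start <= pos < f.end:
                    classes.add(f.cls)
                    hit = True
        if not hit:
            classes.add("intron")  # inside the gene span but between features
    for cls in _PRIORITY:
        if cls in classes:
            return cls
    return "ncRNA" if "ncRNA" in classes else "intergenic"


def annotate_crosslinks(table: pd.DataFrame, annotation: GenomeAnnotation) -> pd.DataFrame:
    """Crosslink table with ``feature`` and ``gene_id`` columns added."""
    out = table.copy()
    feats, gids = [], []
    for chrom, pos, strand in out[["chrom", "position", "strand"]].itertuples(
        index=False, name=None
    ):
        feats.append(assign_feature(annotation, chrom, int(pos), strand))
        gene = annotation.gene_for_site(chrom, int(pos), strand)
        gids.append(gene.gene_id if gene is not None else ".")
    out["feature"] = feats
    out["gene_id"] = gids
    return out


def feature_distribution(table: pd.DataFrame, annotation: GenomeAnnotation) -> pd.DataFrame:
    """Per-class unique-cDNA sums, fractions, lengths, densities, enrichments.

    Fractions are weighted by unique cDNA count; density is count per
    annotated nt of the class, and enrichment is the class density over the
    genome-wide mean density (total count / total genome length).
    """
    if len(table) == 0:
        raise ValueError("no crosslinks")
    ann = annotate_crosslinks(table, annotation)
    counts = ann.groupby("feature")["count"].sum()
    total = float(counts.sum())
    lengths = annotation.class_lengths()
    gene_nt = sum(g.length for g in annotation.genes)
    lengths["antisense"] = gene_nt  # antisense space mirrors the gene space
    genome_len = sum(annotation.chrom_lengths.values())
    mean_density = total / genome_len if genome_len else 0.0
    classes = ["5UTR", "ORF", "3UTR", "intron", "ncRNA", "intergenic", "antisense"]
    recs = []
    for cls in classes:
        n = float(counts.get(cls, 0))
        length = lengths.get(cls, 0)
        density = n / length if length else 0.0
        recs.append({
            "feature": cls,
            "count": n,
            "fraction": n / total,
            "length_nt": length,
            "density": density,
            "enrichment": density / mean_density if mean_density else 0.0,
        })
    return pd.DataFrame(recs)


def define_targets(
    table: pd.DataFrame,
    annotation: GenomeAnnotation,
    min_unique_cdna: int = 2,
    region: str | None = None,
) -> set[str]:
    """Genes whose summed unique cDNA count reaches ``min_unique_cdna``.

    With ``region`` (e.g. ``"3UTR"``) only crosslinks assigned to that class
    count toward the gene total. The default of 2 keeps genes with more than
    one unique cDNA.
    """
    ann = annotate_crosslinks(table, annotation)
    ann = ann[ann["gene_id"] != "."]
    if region is not None:
        ann = ann[ann["feature"] == region]
    sums = ann.groupby("gene_id")["count"].sum()
    return set(sums[sums >= min_unique_cdna].index)


def overlap_sets(set_a: set, set_b: set, set_c: set | None = None) -> dict[str, int]:
    """Exclusive/shared region counts for a 2- or 3-way Venn diagram."""
    if set_c is None:
        return {
            "a_only": len(set_a - set_b),
            "b_only": len(set_b - set_a),
            "ab": len(set_a & set_b),
        }
    return {
        "a_only": len(set_a - set_b - set_c),
        "b_only": len(set_b - set_a - set_c),
        "c_only": len(set_c - set_a - set_b),
        "ab": len((set_a & set_b) - set_c),
        "ac": len((set_a & set_c) - set_b),
        "bc": len((set_b & set_c) - set_a),
        "abc": len(set_a & set_b & set_c),
    }
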