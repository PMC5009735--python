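"""Hierarchical interval model of genes and transcript features on a genome.

All coordinates are 0-based half-open. A :class:`GenomeAnnotation` holds a
list of non-overlapping (per strand) genes, each with one or more transcripts
whose feature intervals partition the transcribed span into the classes
``5UTR``, ``ORF``, ``3UTR`` and ``intron`` (protein-coding genes) or a single
``ncRNA`` body (non-coding genes).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

FEATURE_CLASSES = ("5UTR", "ORF", "3UTR", "intron", "ncRNA")
#: site classes reported by feature assignment, beyond transcript features
SITE_CLASSES = FEATURE_CLASSES + ("antisense", "intergenic")


@dataclass(frozen=True)
class FeatureInterval:
    cls: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.cls not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.cls!r}")
        if not self.start < self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    transcript_id: str
    features: list[FeatureInterval]

    @property
    def start(self) -> int:
        return min(f.start for f in self.features)

    @property
    def end(self) -> int:
        return max(f.end for f in self.features)

    def features_of(self, cls: str) -> list[FeatureInterval]:
        return [f for f in self.features if f.cls == cls]


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str  # "protein_coding" | "ncRNA"
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomeAnnotation:
    """Indexed gene annotation supporting point-overlap queries."""

    def __init__(self, genes: list[Gene], chrom_lengths: dict[str, int]):
        self.genes = sorted(genes, key=lambda g: (g.chrom, g.start))
        self.chrom_lengths = dict(chrom_lengths)
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        self._starts = {c: [g.start for g in gs] for c, gs in self._by_chrom.items()}
        self._max_span = {
            c: max((g.length for g in gs), default=0) for c, gs in self._by_chrom.items()
        }

    def __len__(self) -> int:
        return len(self.genes)

    def gene_by_id(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def genes_overlapping(self, chrom: str, pos: int) -> list[Gene]:
        """Genes whose span contains ``pos`` (either strand)."""
        gs = self._by_chrom.get(chrom, [])
        if not gs:
            return []
        idx = bisect_right(self._starts[chrom], pos)
        hits = []
        j = idx - 1
        # genes starting more than the longest span before pos cannot overlap
        while j >= 0 and gs[j].start > pos - self._max_span[chrom]:
            if gs[j].start <= pos < gs[j].end:
                hits.append(gs[j])
            j -= 1
        hits.reverse()
        return hits

    def gene_for_site(self, chrom: str, pos: int, strand: str) -> Gene | None:
        """Same-strand gene containing ``pos``, or None."""
        for g in self.genes_overlapping(chrom, pos):
            if g.strand == strand:
                return g
        return None

    def features_of_class(self, cls: str) -> list[tuple[Gene, FeatureInterval]]:
        out = []
        for g in self.genes:
            for t in g.transcripts:
                for f in t.features:
                    if f.cls == cls:
                        out.append((g, f))
        return out

    def class_lengths(self) -> dict[str, int]:
        """Total annotated nt per feature class, plus intergenic remainder.

        Overlap between transcripts of the same gene is counted once per
        class (positions are unioned within a class).
        """
        lengths = {cls: 0 for cls in FEATURE_CLASSES}
        gene_nt = 0
        for g in self.genes:
            per_class: dict[str, set[int]] = {}
            for t in g.transcripts:
                for f in t.features:
                    per_class.setdefault(f.cls, set()).update(range(f.start, f.end))
            for cls, positions in per_class.items():
                lengths[cls] += len(positions)
            gene_nt += g.length
        total = sum(self.chrom_lengths.values())
        lengths["intergenic"] = total - gene_nt
        return lengths
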