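"""Synthetic genome, iCLIP-read, and differential-expression generator.

Generates a toy single-chromosome genome with annotated protein-coding genes
(5'UTR / ORF / optional intron / 3'UTR) and ncRNAs, plants AU-rich elements
(``WWW(AUUUA)WWW``, W = A or U) in the 3'UTRs of a chosen set of target genes
together with a poly(A) signal (AAUAAA) 20-30 nt upstream of each transcript
end, and emits truncation-model iCLIP reads: the genomic start of each signal
read is one nucleotide downstream (in transcript direction) of the crosslinked
nucleotide, so extracting "position -1" recovers the planted site exactly.
Reads carry a 7-nt 5' barcode (3 sample bases + 4 random UMI bases) and PCR
duplicates copy both position and UMI. Everything is a pure function of
(inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .annotation import FeatureInterval, Gene, GenomeAnnotation, Transcript
from .io_formats import AlignmentRecord, ReadRecord, SequenceRecord

_BASES = np.array(list("ACGT"))
_RC = str.maketrans("ACGTN", "TGCAN")

#: fraction of signal reads emitted at planted 3'UTR sites (the remainder is
#: redistributed into the gene's ORF), emulating the stronger 3'UTR
#: association of the non-phosphorylatable mutant
UTR3_SIGNAL_SHARE = {"wildtype": 0.6, "AA": 0.95}


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class ConfigError(ValueError):
    """Raised when simulation parameter ranges are incompatible."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated experiment.

    Length ranges are inclusive on both ends, in nucleotides.
    """

    seed: int = 0
    n_genes: int = 100
    n_ncrnas: int = 5
    utr5_length_range: tuple[int, int] = (30, 100)
    orf_length_range: tuple[int, int] = (300, 900)
    utr3_length_range: tuple[int, int] = (150, 400)
    intron_rate: float = 0.3
    intron_length_range: tuple[int, int] = (60, 200)
    ncrna_length_range: tuple[int, int] = (200, 600)
    gap_length_range: tuple[int, int] = (150, 400)
    target_fraction: float = 0.2
    are_repeats_range: tuple[int, int] = (1, 2)
    #: distance of a planted motif's 3' end upstream of the transcript end;
    #: concentrates binding near the poly(A) region as observed for this RBP
    are_end_distance_range: tuple[int, int] = (10, 100)
    polya_signal_offset_range: tuple[int, int] = (20, 30)
    reads_per_target: int = 50
    background_reads: int = 500
    background_intergenic_fraction: float = 0.1
    pcr_duplication_rate: float = 0.3
    read_length: int = 50
    barcode_sample_codes: tuple[str, ...] = ("AGT",)
    affinity_mode: str = "wildtype"
    de_shift_abundance: float = -1.0
    de_shift_translation: float = -0.8
    de_translated_fraction: float = 0.5
    de_noise_sd: float = 0.3
    de_se: float = 0.15
    chrom_name: str = "chr1"

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_ncrnas, self.reads_per_target, self.background_reads) < 0:
            raise ConfigError("counts must be >= 0")
        for p in (self.intron_rate, self.target_fraction, self.pcr_duplication_rate,
                  self.background_intergenic_fraction, self.de_translated_fraction):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.read_length < 20:
            raise ConfigError("read_length must be >= 20")
        if self.affinity_mode not in UTR3_SIGNAL_SHARE:
            raise ConfigError(f"affinity_mode must be one of {sorted(UTR3_SIGNAL_SHARE)}")
        for code in self.barcode_sample_codes:
            if len(code) != 3 or set(code) - set("ACGT"):
                raise ConfigError(f"bad 3-base sample code {code!r}")
        if len(set(self.barcode_sample_codes)) != len(self.barcode_sample_codes):
            raise ConfigError("duplicate sample codes")
        if self.utr3_length_range[0] < self.polya_signal_offset_range[1] + 6:
            raise ConfigError("3'UTRs too short to hold the poly(A) signal at its offset")
        if self.orf_length_range[0] < 6:
            raise ConfigError("ORF must hold at least a start and a stop codon")


@dataclass(frozen=True)
class PlantedSite:
    chrom: str
    position: int  # genomic coordinate of the crosslinked nucleotide
    strand: str
    motif: str  # planted motif in transcript orientation (DNA alphabet)
    gene_id: str


@dataclass(frozen=True)
class ReadEmission:
    read_id: str
    chrom: str
    position: int  # crosslink position the read was emitted from
    strand: str
    umi: str
    kind: str  # "signal" | "background" | "duplicate"


@dataclass
class GroundTruth:
    target_genes: set[str] = field(default_factory=set)
    planted_sites: list[PlantedSite] = field(default_factory=list)
    de_truth: dict[str, tuple[float, float]] = field(default_factory=dict)
    all_genes: list[str] = field(default_factory=list)
    read_emissions: list[ReadEmission] = field(default_factory=list)


def _rand_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(_BASES[rng.integers(0, 4, n)])


def _rand_int(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def simulate_genome(
    config: SimConfig,
) -> tuple[list[SequenceRecord], GenomeAnnotation, GroundTruth]:
    """Generate the toy genome, its annotation and the ground truth."""
    rng = np.random.default_rng(config.seed)
    n_targets = int(round(config.n_genes * config.target_fraction))
    target_idx = set(
        int(i) for i in rng.choice(config.n_genes, size=n_targets, replace=False)
    ) if n_targets else set()

    order = [("coding", i) for i in range(config.n_genes)]
    order += [("ncRNA", j) for j in range(config.n_ncrnas)]
    order = [order[k] for k in rng.permutation(len(order))] if order else []

    chrom = config.chrom_name
    pieces: list[str] = []
    cursor = 0
    genes: list[Gene] = []
    truth = GroundTruth()

    for kind, idx in order:
        gap = _rand_int(rng, config.gap_length_range)
        pieces.append("".join(_rand_seq(rng, gap)))
        cursor += gap
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "ncRNA":
            gid = f"nc{idx:04d}"
            body_len = _rand_int(rng, config.ncrna_length_range)
            seq = "".join(_rand_seq(rng, body_len))
            gene = Gene(gid, chrom, strand, cursor, cursor + body_len, "ncRNA",
                        [Transcript(gid + ".t1", [FeatureInterval("ncRNA", cursor, cursor + body_len)])])
            genes.append(gene)
            truth.all_genes.append(gid)
            pieces.append(seq if strand == "+" else reverse_complement(seq))
            cursor += body_len
            continue

        gid = f"g{idx:04d}"
        is_target = idx in target_idx
        utr5_len = _rand_int(rng, config.utr5_length_range)
        lo, hi = config.orf_length_range
        orf_len = 3 * int(rng.integers((lo + 2) // 3, hi // 3 + 1))
        utr3_len = _rand_int(rng, config.utr3_length_range)

        orf = _rand_seq(rng, orf_len)
        orf[:3], orf[-3:] = list("ATG"), list("TAA")
        utr3 = _rand_seq(rng, utr3_len)
        polya_off = _rand_int(rng, config.polya_signal_offset_range)
        polya_span = (utr3_len - polya_off - 6, utr3_len - polya_off)
        utr3[polya_span[0] : polya_span[1]] = list("AATAAA")

        motif_sites: list[tuple[int, str]] = []  # (crosslink offset in 3'UTR, motif)
        if is_target:
            occupied = [polya_span]
            d_hi = min(config.are_end_distance_range[1], utr3_len - 11)
            d_lo = min(config.are_end_distance_range[0], d_hi)
            for _ in range(_rand_int(rng, config.are_repeats_range)):
                for _try in range(100):
                    d = int(rng.integers(d_lo, d_hi + 1))
                    span = (utr3_len - d - 11, utr3_len - d)
                    if all(span[1] <= a or span[0] >= b for a, b in occupied):
                        occupied.append(span)
                        # W flanks are U-biased: the modal planted element is
                        # then the ideal ARE UU(AUUUA)UU in a U-rich context
                        w = _BASES[3 * (rng.random(6) < 0.75).astype(int)]
                        motif = "".join(w[:3]) + "ATTTA" + "".join(w[3:])
                        utr3[span[0] : span[1]] = list(motif)
                        # crosslink at the central U of the AUUUA core
                        motif_sites.append((span[0] + 5, motif))
                        break

        intron_len = 0
        intron_at = None
        if config.intron_rate > 0 and rng.random() < config.intron_rate:
            intron_len = _rand_int(rng, config.intron_length_range)
            intron_at = 3 * int(rng.integers(1, orf_len // 3))  # codon boundary
        unspliced = (
            _rand_seq(rng, utr5_len)
            + (orf[:intron_at] + _rand_seq(rng, intron_len) + orf[intron_at:]
               if intron_at is not None else orf)
            + utr3
        )
        total = len(unspliced)
        feats_u: list[tuple[str, int, int]] = [("5UTR", 0, utr5_len)]
        if intron_at is not None:
            feats_u += [
                ("ORF", utr5_len, utr5_len + intron_at),
                ("intron", utr5_len + intron_at, utr5_len + intron_at + intron_len),
                ("ORF", utr5_len + intron_at + intron_len, utr5_len + orf_len + intron_len),
            ]
        else:
            feats_u.append(("ORF", utr5_len, utr5_len + orf_len))
        utr3_off = utr5_len + orf_len + intron_len
        feats_u.append(("3UTR", utr3_off, total))

        gstart = cursor
        if strand == "+":
            feats = [FeatureInterval(c, gstart + a, gstart + b) for c, a, b in feats_u]
            tx = "".join(unspliced)
        else:
            feats = [FeatureInterval(c, gstart + total - b, gstart + total - a)
                     for c, a, b in feats_u]
            tx = reverse_complement("".join(unspliced))
        gene = Gene(gid, chrom, strand, gstart, gstart + total, "protein_coding",
                    [Transcript(gid + ".t1", sorted(feats, key=lambda f: f.start))])
        genes.append(gene)
        truth.all_genes.append(gid)
        if is_target:
            truth.target_genes.add(gid)
            for off3, motif in motif_sites:
                u = utr3_off + off3
                p = gstart + u if strand == "+" else gstart + total - 1 - u
                truth.planted_sites.append(PlantedSite(chrom, p, strand, motif, gid))
        pieces.append(tx)
        cursor += total

    tail = _rand_int(rng, config.gap_length_range)
    pieces.append("".join(_rand_seq(rng, tail)))
    cursor += tail

    # planted direction/effect sizes for the differential-expression tables
    targets_sorted = sorted(truth.target_genes)
    n_tr = int(round(len(targets_sorted) * config.de_translated_fraction))
    translated = set(
        targets_sorted[int(i)] for i in rng.choice(len(targets_sorted), n_tr, replace=False)
    ) if n_tr else set()
    for gid in truth.all_genes:
        if gid in truth.target_genes:
            truth.de_truth[gid] = (
                config.de_shift_abundance,
                config.de_shift_translation if gid in translated else 0.0,
            )
        else:
            truth.de_truth[gid] = (0.0, 0.0)

    genome = [SequenceRecord(chrom, "".join(pieces))]
    annotation = GenomeAnnotation(genes, {chrom: cursor})
    return genome, annotation, truth


def simulate_iclip_reads(
    genome: list[SequenceRecord],
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    config: SimConfig,
) -> tuple[list[ReadRecord], GroundTruth]:
    """Emit truncation-model iCLIP reads with barcodes, UMIs and duplicates.

    Signal reads start +1 of a planted crosslink (transcript direction);
    background reads start +1 of positions drawn uniformly from gene spans
    (plus a configurable intergenic fraction). Duplicates copy sequence,
    position and UMI. Emission records are appended to ``truth``.
    """
    if config.reads_per_target > 0 and not truth.planted_sites:
        raise ValueError("reads_per_target > 0 requires planted sites")
    rng = np.random.default_rng([config.seed, 1])
    seqs = {rec.id: rec.sequence for rec in genome}
    body_len = config.read_length - 7
    share = UTR3_SIGNAL_SHARE[config.affinity_mode]
    qual = "I" * config.read_length
    codes = config.barcode_sample_codes

    sites_by_gene: dict[str, list[PlantedSite]] = {}
    for s in truth.planted_sites:
        sites_by_gene.setdefault(s.gene_id, []).append(s)

    n_resampled = 0

    def build_read(chrom: str, p: int, strand: str) -> tuple[str, str] | None:
        """Read body from crosslink p, or None if it runs off the chromosome."""
        seq = seqs[chrom]
        if strand == "+":
            s = p + 1
            if s < 0 or s + body_len > len(seq):
                return None
            return seq[s : s + body_len], strand
        e = p
        if e - body_len < 0 or e > len(seq):
            return None
        return reverse_complement(seq[e - body_len : e]), strand

    reads: list[ReadRecord] = []
    emissions: list[ReadEmission] = []
    idx = 0

    def emit(chrom: str, p: int, strand: str, kind: str) -> None:
        nonlocal idx, n_resampled
        body = build_read(chrom, p, strand)
        if body is None:
            n_resampled += 1
            return
        umi = "".join(_BASES[rng.integers(0, 4, 4)])
        code = codes[int(rng.integers(0, len(codes)))]
        rid = f"r{idx:06d}"
        idx += 1
        reads.append(ReadRecord(rid, code + umi + body[0], qual))
        emissions.append(ReadEmission(rid, chrom, p, strand, umi, kind))

    gene_list = annotation.genes
    gene_weights = None
    if gene_list:
        gene_weights = np.array([g.length for g in gene_list], dtype=float)
        gene_weights /= gene_weights.sum()

    # signal reads not placed at a planted 3'UTR site model the diffuse
    # transcriptome-wide binding of the phosphorylatable protein: they land
    # uniformly in a random (length-weighted) gene rather than clustering
    for gid in sorted(truth.target_genes):
        sites = sites_by_gene.get(gid, [])
        for _ in range(config.reads_per_target):
            if sites and rng.random() < share:
                site = sites[int(rng.integers(0, len(sites)))]
                emit(site.chrom, site.position, site.strand, "signal")
            else:
                g = gene_list[int(rng.choice(len(gene_list), p=gene_weights))]
                p = int(rng.integers(g.start, g.end))
                emit(g.chrom, p, g.strand, "signal")
    if config.background_reads and gene_list:
        intergenic: list[tuple[str, int, int]] = []
        for chrom, clen in annotation.chrom_lengths.items():
            edge = 0
            for g in (x for x in gene_list if x.chrom == chrom):
                if g.start > edge:
                    intergenic.append((chrom, edge, g.start))
                edge = max(edge, g.end)
            if clen > edge:
                intergenic.append((chrom, edge, clen))
        ig_w = np.array([e - s for _, s, e in intergenic], dtype=float)
        ig_w /= ig_w.sum()
        emitted = 0
        while emitted < config.background_reads:
            before = len(reads)
            if intergenic and rng.random() < config.background_intergenic_fraction:
                c, s, e = intergenic[int(rng.choice(len(intergenic), p=ig_w))]
                p = int(rng.integers(s, e))
                strand = "+" if rng.random() < 0.5 else "-"
                emit(c, p, strand, "background")
            else:
                g = gene_list[int(rng.choice(len(gene_list), p=gene_weights))]
                p = int(rng.integers(g.start, g.end))
                emit(g.chrom, p, g.strand, "background")
            if len(reads) > before:
                emitted += 1

    # PCR duplication: each read spawns further copies geometrically
    out: list[ReadRecord] = []
    out_emissions: list[ReadEmission] = []
    for read, em in zip(reads, emissions):
        out.append(read)
        out_emissions.append(em)
        k = 0
        while config.pcr_duplication_rate > 0 and rng.random() < config.pcr_duplication_rate:
            k += 1
            dup_id = f"{read.id}.d{k}"
            out.append(ReadRecord(dup_id, read.sequence, read.qualities))
            out_emissions.append(replace(em, read_id=dup_id, kind="duplicate"))

    truth.read_emissions.extend(out_emissions)
    return out, truth


@dataclass
class PlacementResult:
    records: list[AlignmentRecord]
    n_multihit: int = 0
    n_unplaced: int = 0


def place_reads_exact(
    reads: list[ReadRecord],
    genome: list[SequenceRecord],
    barcode_len: int = 7,
) -> PlacementResult:
    """Place reads by exact sequence match (test stand-in for an aligner).

    The first ``barcode_len`` bases are stripped (bases 4-7 become the UMI;
    with ``barcode_len=0`` the UMI is parsed from a ``_<UMI>`` id suffix).
    Reads matching zero or more than one locus are dropped and counted,
    emulating unique mapping.
    """
    result = PlacementResult(records=[])
    chroms = [(rec.id, rec.sequence, reverse_complement(rec.sequence)) for rec in genome]
    for read in reads:
        if barcode_len >= 7:
            umi, body = read.sequence[3:7], read.sequence[barcode_len:]
        else:
            from .io_formats import _umi_from_name

            umi = _umi_from_name(read.id)
            body = read.sequence[barcode_len:]
            if umi is None:
                raise ValueError(f"read {read.id}: no UMI suffix and no barcode")
        hits: list[tuple[str, int, int, str]] = []
        for chrom, fwd, rev in chroms:
            L = len(fwd)
            for hay, strand in ((fwd, "+"), (rev, "-")):
                start = hay.find(body)
                while start != -1 and len(hits) < 2:
                    if strand == "+":
                        hits.append((chrom, start, start + len(body), "+"))
                    else:
                        hits.append((chrom, L - start - len(body), L - start, "-"))
                    start = hay.find(body, start + 1)
                if len(hits) >= 2:
                    break
            if len(hits) >= 2:
                break
        if not hits:
            result.n_unplaced += 1
        elif len(hits) > 1:
            result.n_multihit += 1
        else:
            chrom, s, e, strand = hits[0]
            name = read.id if barcode_len < 7 else f"{read.id}_{umi}"
            result.records.append(AlignmentRecord(name, chrom, s, e, strand, umi))
    return result


def simulate_de_tables(truth: GroundTruth, config: SimConfig):
    """Differential-expression tables (abundance, translation) from truth.

    Per-gene log2 fold change = planted shift + Gaussian noise; the p-value
    comes from a two-sided normal test of the drawn value at standard error
    ``de_se``; adjusted p-values are Benjamini-Hochberg.
    """
    import pandas as pd

    from .peaks import benjamini_hochberg

    rng = np.random.default_rng([config.seed, 2])
    genes = list(truth.all_genes)
    tables = []
    for mod_i, modality in enumerate(("abundance", "translation")):
        shift = np.array([truth.de_truth[g][mod_i] for g in genes], dtype=float)
        noise = rng.normal(0.0, config.de_noise_sd, len(genes)) if config.de_noise_sd > 0 else 0.0
        lfc = shift + noise
        if config.de_se > 0:
            pvals = 2.0 * stats.norm.sf(np.abs(lfc) / config.de_se)
        else:
            pvals = np.where(lfc != 0.0, 0.0, 1.0)
        padj = benjamini_hochberg(pvals) if len(genes) else np.array([])
        df = pd.DataFrame(
            {"gene_id": genes, "log2fc": lfc, "pvalue": pvals, "padj": padj}
        )
        from .integration import DETable

        tables.append(DETable(df, modality=modality, contrast="AA_vs_TTP"))
    return tables[0], tables[1]
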