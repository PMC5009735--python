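"""Run configuration and the end-to-end demo pipeline.

``run_pipeline`` chains simulate → extract → peaks → annotate → kmers →
rnamap → integrate on the synthetic data, writing every stage output under
``outdir`` plus a manifest with a content digest per file; re-running the
same configuration reproduces identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import crosslinks as xl
from . import features, integration, io_formats, kmers, peaks, rnamaps, synthetic

logger = logging.getLogger("iclipkit")

_STAGE_DEFAULTS = {
    "peaks": {"n_perm": 100, "half_width": 15, "fdr_threshold": 0.05, "perm_domain": "gene"},
    "kmers": {"feature_class": "3UTR", "k": 5, "window": (-50, 50), "n_random": 100},
    "rnamap": {"junction_type": "3UTR-intergenic", "flank": 300, "smooth_window": 15},
    "annotate": {"min_unique_cdna": 2, "region": "3UTR"},
    "integrate": {"padj_threshold": 0.05},
}


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "iclipkit_demo"
    log_level: str = "INFO"
    sim: dict = field(default_factory=dict)
    peaks: dict = field(default_factory=dict)
    kmers: dict = field(default_factory=dict)
    rnamap: dict = field(default_factory=dict)
    annotate: dict = field(default_factory=dict)
    integrate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sim_fields = {f.name for f in dataclasses.fields(synthetic.SimConfig)}
        unknown = set(self.sim) - sim_fields
        if unknown:
            raise ValueError(f"unknown sim keys: {sorted(unknown)}")
        for stage, defaults in _STAGE_DEFAULTS.items():
            block = getattr(self, stage)
            unknown = set(block) - set(defaults)
            if unknown:
                raise ValueError(f"unknown {stage} keys: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def stage_params(self, stage: str) -> dict:
        params = dict(_STAGE_DEFAULTS[stage])
        params.update(getattr(self, stage))
        return params


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineResult:
    status: int
    manifest: dict[str, str]
    failed_stage: str | None = None


def run_pipeline(config: RunConfig) -> PipelineResult:
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    seed = config.seed

    def record(*paths: Path) -> None:
        for p in paths:
            manifest[str(p.relative_to(outdir))] = _digest(p)

    def log(stage: str, msg: str) -> None:
        logger.info("[stage=%s seed=%d] %s", stage, seed, msg)

    stage = "simulate"
    try:
        sim_cfg = synthetic.SimConfig(**{"seed": seed, **config.sim})
        genome, annotation, truth = synthetic.simulate_genome(sim_cfg)
        reads, truth = synthetic.simulate_iclip_reads(genome, annotation, truth, sim_cfg)
        de_rna, de_ribo = synthetic.simulate_de_tables(truth, sim_cfg)
        fa, gtf, fq = outdir / "genome.fa", outdir / "annotation.gtf", outdir / "reads.fastq"
        io_formats.write_fasta(genome, fa)
        io_formats.write_gtf(annotation, gtf)
        io_formats.write_fastq(reads, fq)
        sites_tsv = outdir / "truth_sites.tsv"
        with open(sites_tsv, "w") as fh:
            fh.write("chrom\tposition\tstrand\tmotif\tgene_id\n")
            for s in truth.planted_sites:
                fh.write(f"{s.chrom}\t{s.position}\t{s.strand}\t{s.motif}\t{s.gene_id}\n")
        rna_tsv, ribo_tsv = outdir / "de_abundance.tsv", outdir / "de_translation.tsv"
        integration.write_de_table(de_rna, rna_tsv)
        integration.write_de_table(de_ribo, ribo_tsv)
        record(fa, gtf, fq, sites_tsv, rna_tsv, ribo_tsv)
        log(stage, f"{len(reads)} reads, {len(truth.planted_sites)} planted sites")

        stage = "extract"
        demux = xl.demultiplex(reads, list(sim_cfg.barcode_sample_codes))
        trimmed = [r for code in sim_cfg.barcode_sample_codes for r in demux.by_sample[code]]
        placed = synthetic.place_reads_exact(trimmed, genome, barcode_len=0)
        table = xl.extract_crosslinks(placed.records, annotation.chrom_lengths)
        bed = outdir / "crosslinks.bed"
        io_formats.write_crosslinks_bed(table, bed)
        bg_plus, bg_minus = io_formats.write_bedgraph(table, outdir / "crosslinks")
        record(bed, bg_plus, bg_minus)
        log(stage, f"{len(table)} crosslink sites, {int(table['count'].sum())} unique cDNAs")

        stage = "peaks"
        calls = peaks.call_peaks(table, annotation, seed=seed, **config.stage_params("peaks"))
        peaks_tsv = outdir / "peaks.tsv"
        calls.to_csv(peaks_tsv, sep="\t", index=False)
        sig = calls[calls["significant"]]
        peaks_bed = outdir / "peaks.bed"
        io_formats.write_bed(
            [io_formats.Interval(chrom=r.chrom, start=int(r.position),
                                 end=int(r.position) + 1, strand=r.strand,
                                 name=r.gene_id, score=int(r.window_score))
             for r in sig.itertuples()],
            peaks_bed,
        )
        record(peaks_tsv, peaks_bed)
        log(stage, f"{len(sig)}/{len(calls)} sites significant")

        stage = "annotate"
        ann_params = config.stage_params("annotate")
        dist = features.feature_distribution(table, annotation)
        dist_tsv = outdir / "feature_distribution.tsv"
        dist.to_csv(dist_tsv, sep="\t", index=False)
        targets = features.define_targets(
            table, annotation,
            min_unique_cdna=ann_params["min_unique_cdna"], region=ann_params["region"],
        )
        targets_txt = outdir / "targets.txt"
        targets_txt.write_text("".join(f"{g}\n" for g in sorted(targets)))
        record(dist_tsv, targets_txt)
        log(stage, f"{len(targets)} binding targets")

        stage = "kmers"
        kparams = config.stage_params("kmers")
        kdf = kmers.kmer_scores(
            table, annotation, genome, seed=seed,
            feature_class=kparams["feature_class"], k=kparams["k"],
            window=tuple(kparams["window"]), n_random=kparams["n_random"],
        )
        kmers_tsv = outdir / "kmers.tsv"
        kdf.to_csv(kmers_tsv, sep="\t", index=False)
        record(kmers_tsv)
        log(stage, f"top k-mer {kdf['kmer'].iloc[0]} z={kdf['z'].iloc[0]:.2f}")

        stage = "rnamap"
        rparams = config.stage_params("rnamap")
        junctions = rnamaps.collect_junctions(annotation, rparams["junction_type"])
        profile = rnamaps.rna_map(
            table, junctions, flank=rparams["flank"],
            smooth_window=rparams["smooth_window"], junction_type=rparams["junction_type"],
        )
        map_tsv = outdir / "rna_map.tsv"
        profile.table.to_csv(map_tsv, sep="\t", index=False)
        record(map_tsv)
        log(stage, f"{profile.n_junctions} junctions, {profile.n_crosslinks_used} crosslinks used")

        stage = "integrate"
        summary = integration.summarize_de_overlap(
            de_rna, de_ribo, targets, **config.stage_params("integrate")
        )
        summary_tsv = outdir / "de_overlap.tsv"
        summary.as_frame().to_csv(summary_tsv, sep="\t", index=False)
        record(summary_tsv)
        log(stage, f"{summary.n_de_total} DE genes, {summary.n_iclip_de} also bound")
    except Exception:
        logger.exception("[stage=%s seed=%d] stage failed", stage, seed)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return PipelineResult(1, manifest, failed_stage=stage)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(0, manifest)
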