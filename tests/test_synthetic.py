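import re

import numpy as np
import pytest

import iclipkit as ik
from iclipkit.synthetic import ConfigError, reverse_complement
from conftest import run_sim_pipeline


class TestSimulateGenome:
    def test_empty_configuration_gives_intergenic_only(self):
        cfg = ik.SimConfig(seed=0, n_genes=0, n_ncrnas=0, background_reads=0)
        genome, annotation, truth = ik.simulate_genome(cfg)
        assert len(annotation) == 0
        assert len(genome[0].sequence) > 0
        assert truth.target_genes == set() and truth.planted_sites == []

    def test_determinism_byte_identical(self, tmp_path):
        out = []
        for run in range(2):
            genome, annotation, _ = ik.simulate_genome(ik.SimConfig(seed=7))
            fa, gtf = tmp_path / f"g{run}.fa", tmp_path / f"a{run}.gtf"
            ik.write_fasta(genome, fa)
            ik.write_gtf(annotation, gtf)
            out.append((fa.read_bytes(), gtf.read_bytes()))
        assert out[0] == out[1]

    def test_exact_target_count_without_replacement(self):
        cfg = ik.SimConfig(seed=1, n_genes=100, target_fraction=0.2)
        _, _, truth = ik.simulate_genome(cfg)
        assert len(truth.target_genes) == 20

    def test_gene_anatomy(self, sim_run):
        genome, annotation, *_ = sim_run
        seq = genome[0].sequence
        for gene in annotation.genes:
            if gene.biotype != "protein_coding":
                continue
            (t,) = gene.transcripts
            orf_len = sum(len(f) for f in t.features_of("ORF"))
            assert orf_len % 3 == 0
            # transcript-oriented sequence starts the ORF with ATG, ends with a stop
            orf_feats = sorted(t.features_of("ORF"), key=lambda f: f.start)
            if gene.strand == "+":
                start_codon = seq[orf_feats[0].start : orf_feats[0].start + 3]
                stop_codon = seq[orf_feats[-1].end - 3 : orf_feats[-1].end]
            else:
                start_codon = reverse_complement(seq[orf_feats[-1].end - 3 : orf_feats[-1].end])
                stop_codon = reverse_complement(seq[orf_feats[0].start : orf_feats[0].start + 3])
            assert start_codon == "ATG" and stop_codon in ("TAA", "TAG", "TGA")

    def test_polya_signal_at_configured_offset(self, sim_run, default_config):
        genome, annotation, *_ = sim_run
        seq = genome[0].sequence
        lo, hi = default_config.polya_signal_offset_range
        for gene in annotation.genes:
            if gene.biotype != "protein_coding":
                continue
            (t,) = gene.transcripts
            (utr3,) = t.features_of("3UTR")
            if gene.strand == "+":
                region = seq[utr3.end - hi - 6 : utr3.end - lo]
            else:
                region = reverse_complement(seq[utr3.start + lo : utr3.start + hi + 6])
            assert "AATAAA" in region

    def test_planted_sites_inside_target_3utrs_with_motif(self, sim_run):
        genome, annotation, truth, *_ = sim_run
        seq = genome[0].sequence
        for site in truth.planted_sites:
            assert site.gene_id in truth.target_genes
            gene = annotation.gene_by_id(site.gene_id)
            (t,) = gene.transcripts
            (utr3,) = t.features_of("3UTR")
            assert utr3.start <= site.position < utr3.end
            assert re.fullmatch(r"[AT]{3}ATTTA[AT]{3}", site.motif)
            # crosslink sits at the central T of the planted core
            if gene.strand == "+":
                window = seq[site.position - 5 : site.position + 6]
            else:
                window = reverse_complement(seq[site.position - 5 : site.position + 6])
            assert site.motif in window

    def test_incompatible_ranges_raise_config_error(self):
        with pytest.raises(ConfigError):
            ik.SimConfig(utr3_length_range=(20, 30))
        with pytest.raises(ConfigError):
            ik.SimConfig(read_length=10)
        with pytest.raises(ConfigError):
            ik.SimConfig(target_fraction=1.5)


class TestSimulateReads:
    def test_no_reads_requested_gives_empty_set(self):
        cfg = ik.SimConfig(seed=0, reads_per_target=0, background_reads=0)
        genome, annotation, truth = ik.simulate_genome(cfg)
        reads, _ = ik.simulate_iclip_reads(genome, annotation, truth, cfg)
        assert reads == []

    def test_read_structure_barcode_umi_body(self, default_config):
        cfg = ik.SimConfig(seed=2, background_reads=0)
        genome, annotation, truth = ik.simulate_genome(cfg)
        reads, truth = ik.simulate_iclip_reads(genome, annotation, truth, cfg)
        em = {e.read_id: e for e in truth.read_emissions}
        seq = genome[0].sequence
        for read in reads[:50]:
            assert len(read.sequence) == cfg.read_length
            assert read.sequence[:3] in cfg.barcode_sample_codes
            e = em[read.id]
            assert read.sequence[3:7] == e.umi
            body = read.sequence[7:]
            if e.strand == "+":
                assert seq[e.position + 1 : e.position + 1 + len(body)] == body
            else:
                assert reverse_complement(seq[e.position - len(body) : e.position]) == body

    def test_no_duplication_identity(self):
        cfg = ik.SimConfig(seed=3, pcr_duplication_rate=0.0)
        genome, annotation, truth = ik.simulate_genome(cfg)
        reads, truth = ik.simulate_iclip_reads(genome, annotation, truth, cfg)
        pairs = {(e.position, e.strand, e.umi) for e in truth.read_emissions}
        assert len(reads) == len(truth.read_emissions)
        assert all(e.kind != "duplicate" for e in truth.read_emissions)
        # distinct (position, UMI) pairs can only fall short by UMI collisions
        assert len(pairs) <= len(reads)

    def test_duplicate_replay_oracle(self):
        """Unique cDNAs downstream equal the distinct (pos, strand, UMI)
        triples of the generator's own emission record."""
        cfg = ik.SimConfig(seed=7, n_genes=20, target_fraction=0.2,
                           reads_per_target=10, background_reads=200,
                           pcr_duplication_rate=0.5)
        genome, annotation, truth, reads, placed, table = run_sim_pipeline(cfg)
        expected = len({(e.chrom, e.position, e.strand, e.umi) for e in truth.read_emissions})
        assert int(table["count"].sum()) == expected

    def test_conservation_of_emissions(self, sim_run, default_config):
        *_, truth, reads, _, _ = sim_run
        kinds = [e.kind for e in truth.read_emissions]
        assert len(reads) == len(kinds)
        assert kinds.count("background") == default_config.background_reads

    def test_affinity_mode_shifts_utr3_share(self):
        fracs = {}
        for mode in ("wildtype", "AA"):
            cfg = ik.SimConfig(seed=5, affinity_mode=mode)
            _, annotation, _, _, _, table = run_sim_pipeline(cfg)
            dist = ik.feature_distribution(table, annotation)
            fracs[mode] = float(dist.loc[dist["feature"] == "3UTR", "fraction"].iloc[0])
        assert fracs["AA"] > fracs["wildtype"]


class TestPlaceReads:
    def test_known_read_placement(self):
        rng = np.random.default_rng(0)
        seq = "".join(np.random.default_rng(4).choice(list("ACGT"), 500))
        genome = [ik.SequenceRecord("chr1", seq)]
        body = seq[100:143]
        read = ik.ReadRecord("r1", "ACG" + "TTTT" + body, "I" * 50)
        res = ik.place_reads_exact([read], genome)
        (rec,) = res.records
        assert (rec.start, rec.end, rec.strand, rec.umi) == (100, 143, "+", "TTTT")

    def test_multi_hit_dropped_and_counted(self):
        seq = "ATCGGCTA" * 10 + "AAAATTTTCCCCGGGG" + "ATCGGCTA" * 10
        genome = [ik.SequenceRecord("chr1", seq)]
        read = ik.ReadRecord("r1", "ACGTTTT" + "ATCGGCTAATCGGCTA", "I" * 23)
        res = ik.place_reads_exact([read], genome)
        assert res.records == [] and res.n_multihit == 1

    def test_full_simulation_placements_match_truth(self, sim_run):
        *_, truth, _, placed, _ = sim_run
        em = {e.read_id: e for e in truth.read_emissions}
        assert placed.n_multihit == 0 and placed.n_unplaced == 0
        for rec in placed.records:
            e = em[rec.read_id.rsplit("_", 1)[0]]
            crosslink = rec.start - 1 if rec.strand == "+" else rec.end
            assert (rec.chrom, crosslink, rec.strand, rec.umi) == (
                e.chrom, e.position, e.strand, e.umi,
            )


class TestDeTables:
    def test_zero_shift_zero_noise_gives_zero_lfc(self):
        cfg = ik.SimConfig(seed=0, de_shift_abundance=0.0, de_shift_translation=0.0,
                           de_noise_sd=0.0)
        _, _, truth = ik.simulate_genome(cfg)
        rna, ribo = ik.simulate_de_tables(truth, cfg)
        assert (rna.df["log2fc"] == 0).all() and (ribo.df["log2fc"] == 0).all()

    def test_determinism(self):
        cfg = ik.SimConfig(seed=9)
        _, _, truth = ik.simulate_genome(cfg)
        a1, b1 = ik.simulate_de_tables(truth, cfg)
        a2, b2 = ik.simulate_de_tables(truth, cfg)
        assert a1.df.equals(a2.df) and b1.df.equals(b2.df)

    def test_target_mean_lfc_within_sampling_bound(self):
        cfg = ik.SimConfig(seed=3, n_genes=500, n_ncrnas=0, target_fraction=0.2,
                           de_shift_abundance=-1.0, de_noise_sd=0.3,
                           reads_per_target=0, background_reads=0)
        _, _, truth = ik.simulate_genome(cfg)
        rna, _ = ik.simulate_de_tables(truth, cfg)
        sub = rna.df[rna.df["gene_id"].isin(truth.target_genes)]
        n = len(sub)
        assert abs(sub["log2fc"].mean() - (-1.0)) <= 3 * 0.3 / np.sqrt(n)
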