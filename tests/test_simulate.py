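import math

import numpy as np
import pytest

from ervkit import io as eio
from ervkit.distribution import bin_distances, observed_distances
from ervkit.methylation import dedup_clones, methylation_fraction
from ervkit.model import distance_between
from ervkit.simulate import (
    CapacityError,
    SimulationConfig,
    clones_to_reads,
    make_bisulfite_reference,
    make_genome_and_genes,
    sample_insertions,
    simulate_bisulfite_clones,
    simulate_ct_table,
    simulate_signal_tracks,
    write_simulation,
)


def small_config(**overrides):
    base = {
        "seed": 11, "n_chromosomes": 2, "chrom_length": 500_000, "n_genes": 40,
        "erv": {"n_per_family": {"ETn/MusD": 50, "IAP": 50}},
    }
    base.update(overrides)
    return SimulationConfig.from_dict(base)


class TestGenomeAndGenes:
    def test_cgi_fraction_matches_binomial(self):
        cfg = small_config(n_genes=100, cgi_promoter_fraction=0.6,
                           chrom_length=2_000_000)
        _, genes, cgis, _ = make_genome_and_genes(cfg)
        n_cgi = sum(g.promoter_is_cgi for g in genes)
        sigma = math.sqrt(100 * 0.6 * 0.4)
        assert abs(n_cgi - 60) <= 3 * sigma
        assert len(cgis) == n_cgi

    def test_zero_cgi_fraction(self):
        cfg = small_config(cgi_promoter_fraction=0.0)
        _, genes, cgis, _ = make_genome_and_genes(cfg)
        assert not cgis
        assert not any(g.promoter_is_cgi for g in genes)

    def test_genes_do_not_overlap(self):
        cfg = small_config(n_genes=60)
        _, genes, _, _ = make_genome_and_genes(cfg)
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
                assert e0 <= s1

    def test_determinism(self, tmp_path):
        cfg = small_config()
        for sub in ("a", "b"):
            d = tmp_path / sub
            write_simulation(cfg, d)
        for name in ("genes.bed", "cgis.bed", "ervs.bed", "expression.tsv",
                     "ct_table.tsv", "tracks/h3k4me3.bedgraph"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_capacity_error(self):
        cfg = small_config(n_chromosomes=1, chrom_length=60_000, n_genes=50,
                           gene_length_range=(5_000, 6_000))
        with pytest.raises(CapacityError):
            make_genome_and_genes(cfg)


class TestInsertions:
    def test_uniform_coverage_no_selection(self):
        # one gene on one chromosome: analytic bin fraction ~ 2w/L both sides
        cfg = SimulationConfig.from_dict({
            "seed": 5, "n_chromosomes": 1, "chrom_length": 1_000_000, "n_genes": 1,
            "gene_length_range": (10_000, 10_001),
            "erv": {"n_per_family": {"IAP": 4000, "ETn/MusD": 0},
                    "full_length_fraction": 0.0, "solo_span": 2},
            "selection": {"kind": "none"}})
        genome, genes, _, _ = make_genome_and_genes(cfg)
        ervs = sample_insertions(cfg, genome, genes)
        dists = np.array([d for _, d, _ in observed_distances(ervs, genes, "tss")])
        w, L, n = 500, 1_000_000, len(dists)
        counts = bin_distances(dists, w, 10_000)
        p = 2 * w / L
        sigma = math.sqrt(n * p * (1 - p))
        for c in counts:
            assert abs(c - n * p) <= 3.5 * sigma

    def test_hard_exclusion(self):
        cfg = small_config(selection={"kind": "hard_exclusion", "d_sel": 1500})
        genome, genes, _, _ = make_genome_and_genes(cfg)
        ervs = sample_insertions(cfg, genome, genes)
        assert len(ervs) == 100
        for _, dist, _ in observed_distances(ervs, genes, "tss"):
            assert dist >= 1500

    def test_ltr_substructure(self):
        cfg = small_config()
        genome, genes, _, _ = make_genome_and_genes(cfg)
        for erv in sample_insertions(cfg, genome, genes):
            if erv.element_type == "full_length":
                assert erv.ltr5 is not None and erv.ltr3 is not None
            else:
                assert erv.solo_ltr == (erv.start, erv.end)

    def test_logistic_selection_depletes_near_tss(self):
        cfg_none = small_config(selection={"kind": "none"},
                                erv={"n_per_family": {"IAP": 400, "ETn/MusD": 0}})
        cfg_sel = small_config(selection={"kind": "logistic", "d50": 2000,
                                          "slope": 0.01},
                               erv={"n_per_family": {"IAP": 400, "ETn/MusD": 0}})
        genome, genes, _, _ = make_genome_and_genes(cfg_none)
        near = {}
        for name, cfg in (("none", cfg_none), ("sel", cfg_sel)):
            ervs = sample_insertions(cfg, genome, genes)
            dists = [d for _, d, _ in observed_distances(ervs, genes, "tss")]
            near[name] = sum(d < 1000 for d in dists)
        assert near["sel"] < near["none"]


class TestBisulfiteSimulation:
    def test_reference_has_requested_cpgs(self):
        rng = np.random.default_rng(0)
        ref = make_bisulfite_reference(400, 20, rng)
        n_cpg = sum(1 for i in range(len(ref) - 1) if ref[i:i + 2] == "CG")
        assert n_cpg == 20
        # non-CpG cytosines must exist for conversion QC
        assert any(ref[i] == "C" and ref[i + 1] != "G" for i in range(len(ref) - 1))

    def test_full_methylation_no_errors(self):
        cfg = small_config(bisulfite={"conversion_failure_rate": 0.0,
                                      "duplicate_rate": 0.0})
        clone_set, _ = simulate_bisulfite_clones(cfg, "r1", 1.0)
        for clone in clone_set.clones:
            assert all(clone.cpg_calls)
            assert not clone.nonconversion_positions

    def test_binomial_recovery(self):
        cfg = small_config(bisulfite={"clones_per_region": 50,
                                      "cpgs_per_region": 20,
                                      "duplicate_rate": 0.0})
        clone_set, _ = simulate_bisulfite_clones(cfg, "r1", 0.8)
        frac = methylation_fraction(dedup_clones(clone_set)).fraction
        n = 50 * 20
        sigma = math.sqrt(0.8 * 0.2 / n)
        assert abs(frac - 0.8) <= 3 * sigma

    def test_dedup_recovers_ground_truth_duplicates(self):
        cfg = small_config(bisulfite={"clones_per_region": 20,
                                      "duplicate_rate": 0.5,
                                      "cpgs_per_region": 20})
        clone_set, truth = simulate_bisulfite_clones(cfg, "r1", 0.5)
        n_duplicates = sum(1 for v in truth["duplicate_of"].values() if v)
        assert n_duplicates > 0
        deduped = dedup_clones(clone_set)
        originals = {cid for cid, src in truth["duplicate_of"].items() if src is None}
        retained = {c.clone_id for c in deduped.clones}
        assert retained == originals

    def test_reads_round_trip(self):
        cfg = small_config()
        clone_set, truth = simulate_bisulfite_clones(cfg, "r1", 0.6)
        from ervkit.methylation import bisulfite_from_reads
        reads = clones_to_reads(truth["reference"], clone_set)
        recovered = bisulfite_from_reads(truth["reference"], reads,
                                         region_id="r1", tissue="liver")
        for orig, back in zip(clone_set.clones, recovered.clones):
            assert orig.cpg_calls == back.cpg_calls
            assert orig.nonconversion_positions == back.nonconversion_positions


class TestCtSimulation:
    def test_noise_free_full_methylation(self):
        cfg = small_config(ct={"noise_sd": 0.0, "capture_scale": 1.0, "floor": 0.0})
        df = simulate_ct_table(cfg, [("r1", "liver", 1.0)])
        row = df[~df.is_spike].iloc[0]
        spike = df[df.is_spike].iloc[0]
        score = (row.efficiency ** (row.ct_input - row.ct_ip)
                 / spike.efficiency ** (spike.ct_input - spike.ct_ip))
        assert score == pytest.approx(1.0)

    def test_noise_free_low_level_classified_unmethylated(self):
        cfg = small_config(ct={"noise_sd": 0.0, "capture_scale": 1.0, "floor": 0.0})
        df = simulate_ct_table(cfg, [("r1", "liver", 0.1)])
        from ervkit.methylation import MedipMeasurement, medip_score
        spike_row = df[df.is_spike].iloc[0]
        row = df[~df.is_spike].iloc[0]
        spike = MedipMeasurement("spike", "spike", spike_row.ct_input,
                                 spike_row.ct_ip, spike_row.efficiency, "batch1")
        m = MedipMeasurement("r1", "liver", row.ct_input, row.ct_ip,
                             row.efficiency, "batch1")
        call = medip_score(m, spike)
        assert call.score == pytest.approx(0.1)
        assert call.call == "unmethylated"

    def test_zero_level_requires_floor(self):
        cfg = small_config(ct={"noise_sd": 0.0, "floor": 0.0})
        with pytest.raises(ValueError):
            simulate_ct_table(cfg, [("r1", "liver", 0.0)])


class TestSignalSimulation:
    def _setup(self, **signal):
        cfg = small_config(n_chromosomes=1, chrom_length=200_000, n_genes=6,
                           erv={"n_per_family": {"IAP": 5, "ETn/MusD": 0}},
                           signal={"background_sd": 0.0, "decay_length": 500,
                                   "tss_peak_height": 10.0, **signal})
        genome, genes, _, expr = make_genome_and_genes(cfg)
        ervs = sample_insertions(cfg, genome, genes)
        tracks = simulate_signal_tracks(cfg, genome, genes, ervs, expr,
                                        cfg.tissues[0])
        return cfg, genes, expr, tracks

    def test_silent_gene_no_peak(self):
        cfg, genes, expr, tracks = self._setup()
        silent = [g for g in genes if not expr.is_expressed(g.gene_id, cfg.tissues[0])]
        expressed = [g for g in genes if expr.is_expressed(g.gene_id, cfg.tissues[0])]
        assert silent and expressed
        for g in silent:
            # no other expressed TSS nearby -> signal should be ~0
            if all(abs(g.tss - e.tss) > 6 * 500 for e in expressed):
                assert tracks["h3k4me3"].query(g.chrom, g.tss) == pytest.approx(0.0, abs=1e-9)

    def test_decay_profile(self):
        cfg, genes, expr, tracks = self._setup()
        expressed = [g for g in genes if expr.is_expressed(g.gene_id, cfg.tissues[0])]
        g = next(g for g in expressed
                 if all(o is g or abs(g.tss - o.tss) > 10_000 for o in expressed))
        peak = tracks["h3k4me3"].window_mean(g.chrom, g.tss - 12, g.tss + 13)
        at_d = tracks["h3k4me3"].window_mean(g.chrom, g.tss + 500 - 12, g.tss + 500 + 13)
        assert at_d == pytest.approx(peak / math.e, rel=0.15)

    def test_same_seed_identical_bedgraph(self, tmp_path):
        for sub in ("a", "b"):
            cfg, genes, expr, tracks = self._setup()
            eio.write_bedgraph(tmp_path / f"{sub}.bedgraph", tracks["ctcf"])
        assert (tmp_path / "a.bedgraph").read_bytes() == (tmp_path / "b.bedgraph").read_bytes()


class TestWriteSimulation:
    def test_outputs_parse_with_readers(self, tmp_path):
        cfg = small_config(erv={"n_per_family": {"ETn/MusD": 10, "IAP": 10}})
        paths = write_simulation(cfg, tmp_path / "sim")
        genome = eio.read_genome(paths["genome"])
        genes = eio.read_features(paths["genes"], "gene")
        cgis = eio.read_features(paths["cgis"], "cgi")
        ervs = eio.read_features(paths["ervs"], "erv")
        expr = eio.read_expression_table(paths["expression"])
        assert len(genes) == cfg.n_genes
        assert len(ervs) == 20
        assert genome.names == ("chr1", "chr2")
        assert set(expr.tissues) == set(cfg.tissues)
        # ground-truth sidecars exist
        assert paths["truth_methylation"].exists()
        assert paths["truth_selection"].exists()
        assert paths["truth_duplicates"].exists()
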