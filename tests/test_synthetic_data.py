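import json

import numpy as np

import pytest

from epicoord import io as eio
from epicoord import synthetic_data as sd
from epicoord.enrichment import normalize_pair


class TestConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            sd.SimConfig(chrom_length=1001)        # not a bin multiple
        with pytest.raises(ValueError):
            sd.SimConfig(frac_null=1.5)
        with pytest.raises(ValueError):
            sd.SimConfig(effect_size=-1)
        with pytest.raises(ValueError):
            sd.SimConfig(n_marks=99)

    def test_unknown_enhancer_mark_rejected(self):
        with pytest.raises(ValueError):
            sd.SimConfig(n_marks=3)   # panel no longer covers the six marks


class TestGenome:
    def test_zero_genes_gives_empty_table(self):
        cfg = sd.SimConfig(seed=0, n_genes=0, n_enhancers=0)
        genes, chrom_sizes = sd.simulate_genome(cfg)
        assert genes.empty
        assert len(chrom_sizes) == cfg.n_chroms

    def test_deterministic_given_seed(self, small_config):
        g1, _ = sd.simulate_genome(small_config)
        g2, _ = sd.simulate_genome(small_config)
        assert g1.equals(g2)

    def test_gene_lengths_and_strands(self, small_genome):
        genes, chrom_sizes = small_genome
        assert ((genes["txEnd"] - genes["txStart"]) >= 1200).all()
        assert set(genes["strand"]) == {"+", "-"}
        for chrom, sub in genes.groupby("chrom"):
            assert sub["txEnd"].max() <= chrom_sizes[chrom]

    def test_too_many_genes_for_chromosome_rejected(self):
        cfg = sd.SimConfig(seed=0, chrom_length=400_000, n_genes=100,
                           n_enhancers=0)
        with pytest.raises(ValueError, match="too short"):
            sd.simulate_genome(cfg)


class TestTracks:
    def test_deterministic_given_seed(self, small_config, small_genome):
        genes, _ = small_genome
        t1, m1 = sd.simulate_tracks(genes, small_config)
        t2, m2 = sd.simulate_tracks(genes, small_config)
        for key in t1:
            for c in t1[key].data:
                assert np.array_equal(t1[key].data[c], t2[key].data[c])
        assert m1.gene_clusters == m2.gene_clusters

    def test_library_size_factor_scales_totals(self, small_genome):
        genes, _ = small_genome
        cfg = sd.SimConfig(seed=3, library_factor=2.0, effect_size=0.0,
                           frac_null=1.0, n_chroms=2, chrom_length=2_000_000,
                           n_genes=40, n_enhancers=0)
        genes, _ = sd.simulate_genome(cfg)
        tracks, _ = sd.simulate_tracks(genes, cfg)
        e = tracks[("H3K9me3", "epithelial")].total()
        m = tracks[("H3K9me3", "mesenchymal")].total()
        assert m / e == pytest.approx(2.0, rel=0.05)

    def test_planted_gain_positive_expected_difference(self, small_study):
        tracks, truth = small_study["tracks"], small_study["truth"]
        sde = {}
        for mk in ("H3K27ac", "H3K4me1"):
            _, _, s, _ = normalize_pair(tracks[(mk, "epithelial")],
                                        tracks[(mk, "mesenchymal")])
            sde[mk] = s
        diffs = []
        for e in truth.enhancers:
            if e["direction"] != "gain":
                continue
            b = e["anchor_bin"]
            diffs.append(sum(sde[mk].data[e["chrom"]][b - 5:b + 6].sum()
                             for mk in sde))
        assert np.mean(diffs) > 0

    def test_null_configuration_exchangeable(self):
        """With nothing planted, the two conditions differ only by library
        size: after normalization the SDE has mean ~0 everywhere."""
        cfg = sd.SimConfig(seed=5, n_chroms=1, chrom_length=2_000_000,
                           n_genes=20, n_enhancers=0, effect_size=0.0,
                           frac_null=1.0)
        genes, _ = sd.simulate_genome(cfg)
        tracks, truth = sd.simulate_tracks(genes, cfg)
        _, _, sde, _ = normalize_pair(tracks[("H3K27ac", "epithelial")],
                                      tracks[("H3K27ac", "mesenchymal")])
        vals = sde.data["chr1"]
        gain = vals[vals > 0].sum()
        loss = -vals[vals < 0].sum()
        assert gain / loss == pytest.approx(1.0, abs=0.1)

    def test_unknown_mark_rejected(self):
        with pytest.raises(ValueError, match="enhancer marks"):
            sd.SimConfig(enhancer_marks=("H3K27ac", "H3K_nonsense"))


class TestExpression:
    def test_zero_noise_single_probe_reproduces_truth(self, small_genome,
                                                      small_config):
        genes, _ = small_genome
        _, truth = sd.simulate_tracks(genes, small_config)
        cfg = sd.SimConfig(seed=7, probes_per_gene=1, probe_noise_sd=0.0,
                           n_chroms=2, chrom_length=2_000_000, n_genes=40,
                           n_enhancers=30)
        probes = sd.simulate_expression(genes, truth, cfg)
        for row in probes.itertuples(index=False):
            assert row.log2fc == truth.gene_log2fc[row.gene_id]

    def test_probe_count_per_gene(self, small_genome, small_study):
        genes, _ = small_genome
        probes = sd.simulate_expression(genes, small_study["truth"],
                                        small_study["config"])
        counts = probes.groupby("gene_id").size()
        assert (counts == small_study["config"].probes_per_gene).all()

    def test_probe_mean_near_planted_value(self, small_genome):
        genes, _ = small_genome
        truth = sd.TruthManifest(gene_log2fc={g: -3.0
                                              for g in genes["gene_id"]})
        cfg = sd.SimConfig(seed=9, probes_per_gene=50, probe_noise_sd=0.1,
                           n_chroms=2, chrom_length=2_000_000, n_genes=40,
                           n_enhancers=30)
        probes = sd.simulate_expression(genes.iloc[:1], truth, cfg)
        se = 0.1 / np.sqrt(50)
        assert abs(probes["log2fc"].mean() + 3.0) < 3 * se


class TestAnnotations:
    def test_planted_terms_enriched_in_their_cluster(self, small_genome,
                                                     small_study):
        genes = small_study["genes"]
        truth = small_study["truth"]
        terms, tfbs, ppi = sd.simulate_annotations(genes, truth,
                                                   small_study["config"])
        from epicoord.functional import enrich_terms
        for term, cluster in truth.term_clusters.items():
            members = [g for g, c in truth.gene_clusters.items()
                       if c == cluster]
            out = enrich_terms(members, genes["gene_id"].tolist(),
                               {term: terms[term]})
            assert out.loc[0, "fold"] > 1

    def test_disconnected_ppi_blocks_recover_as_modules(self, small_study):
        from epicoord import network as net
        cfg = sd.SimConfig(seed=11, n_chroms=2, chrom_length=2_000_000,
                           n_genes=40, n_enhancers=30, n_ppi_modules=2,
                           ppi_module_size=8, ppi_p_in=1.0,
                           n_ppi_background_edges=0)
        genes, _ = sd.simulate_genome(cfg)
        _, truth = sd.simulate_tracks(genes, cfg)
        _, _, ppi = sd.simulate_annotations(genes, truth, cfg)
        g = net.load_interactions(ppi)
        comps = sorted(map(sorted, __import__("networkx").connected_components(g)))
        assert len(comps) == 2
        for comp in comps:
            assert len({truth.ppi_modules[x] for x in comp}) == 1

    def test_some_ppi_confidences_below_cutoff(self, small_study):
        _, _, ppi = sd.simulate_annotations(small_study["genes"],
                                            small_study["truth"],
                                            small_study["config"])
        assert (ppi["confidence"] < 400).any()
        assert (ppi["confidence"] >= 400).any()

    def test_activated_tf_sites_inside_gain_enhancers(self, small_study):
        truth = small_study["truth"]
        _, tfbs, _ = sd.simulate_annotations(small_study["genes"], truth,
                                             small_study["config"])
        act = tfbs[tfbs["name"] == "TF_ACT"]
        gain_iv = [(e["chrom"], e["position"] - 1000, e["position"] + 1200)
                   for e in truth.enhancers if e["direction"] == "gain"]
        inside = 0
        for row in act.itertuples(index=False):
            if any(c == row.chrom and s <= row.start < e_
                   for c, s, e_ in gain_iv):
                inside += 1
        assert inside >= len(act) - 10   # all but the background sites


class TestRoundTrip:
    def test_written_files_reload_consistently(self, tmp_path, small_config):
        out = sd.write_all(small_config, tmp_path)
        genes = eio.read_genes(tmp_path / "genes.tsv")
        assert genes.equals(out["genes"])
        cs = eio.read_chrom_sizes(tmp_path / "chrom.sizes")
        assert cs == out["chrom_sizes"]
        track = eio.read_bedgraph(tmp_path / "re_H3K27ac_M.bedgraph", cs,
                                  mark="H3K27ac", condition="mesenchymal")
        orig = out["tracks"][("H3K27ac", "mesenchymal")]
        for c in cs:
            assert np.array_equal(track.data[c], orig.data[c])
        terms = eio.read_gmt(tmp_path / "terms.gmt")
        assert terms == out["terms"]
        truth = sd.TruthManifest.from_json(tmp_path / "truth.json")
        assert truth.gene_clusters == {
            k: v for k, v in out["manifest"].gene_clusters.items()}
        ppi = eio.read_ppi(tmp_path / "ppi.tsv")
        assert len(ppi) == len(out["ppi"])
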