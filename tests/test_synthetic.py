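"""Generator contracts: determinism, conservation, calibration, geometry."""
import numpy as np
import pandas as pd
import pytest

from strandtx.errors import ConfigurationError
from strandtx.io import write_cleavage_bed, write_gtf
from strandtx.synthetic import (
    EffectSpec,
    SimConfig,
    default_effects,
    generate_catalog,
    simulate_alignments,
    simulate_counts,
)


class TestGenerateCatalog:
    def test_minimal_catalog(self):
        cfg = SimConfig(
            genes_per_class={"coding": 1},
            isoforms_per_coding_gene=(1, 1),
            cleavage_sites_per_gene=(2, 2),
        )
        catalog, sites = generate_catalog(cfg)
        assert len(catalog) == 1
        assert len(catalog.gene_ids) == 1
        assert len(sites) == 2

    def test_novel_loci_mostly_single_exon(self):
        cfg = SimConfig(genes_per_class={"coding": 1, "novel_locus": 100})
        catalog, _ = generate_catalog(cfg)
        loci = catalog.by_class("novel_locus")
        single = sum(1 for t in loci if t.chain.n_exons == 1)
        assert len(loci) == 100 and single >= 97

    def test_same_seed_byte_identical_output(self, tmp_path):
        cfg = SimConfig(seed=17, genes_per_class={"coding": 10, "lncRNA": 4,
                                                  "novel_locus": 20})
        paths = []
        for tag in ("a", "b"):
            catalog, sites = generate_catalog(cfg)
            gtf = tmp_path / f"{tag}.gtf"
            bed = tmp_path / f"{tag}.bed"
            write_gtf(catalog, gtf)
            write_cleavage_bed(sites, bed)
            paths.append((gtf.read_bytes(), bed.read_bytes()))
        assert paths[0] == paths[1]

    def test_classes_do_not_overlap_except_neighbors(self, small_sim):
        cfg, catalog, _, _, _ = small_sim
        from intervaltree import IntervalTree

        trees = {}
        for t in catalog:
            if t.major_class in ("lncRNA", "novel_isoform"):
                continue  # deliberately placed near/within coding genes
            tree = trees.setdefault(t.chain.chrom, IntervalTree())
            for s, e in t.chain.exons:
                hits = {iv.data for iv in tree.overlap(s, e)}
                assert hits <= {t.gene_id}, f"{t.transcript_id} overlaps another gene"
            for s, e in t.chain.exons:
                tree.addi(s, e, t.gene_id)

    def test_required_class_missing_raises(self):
        with pytest.raises(ConfigurationError, match="coding"):
            SimConfig(genes_per_class={"coding": 0, "novel_isoform": 5})


class TestSimulateCounts:
    def test_poisson_limit_at_zero_dispersion(self):
        # 300 samples so the chi-square noise of var/mean fits a +/-20% band
        cfg = SimConfig(
            seed=19, n_control=150, n_case=150,
            genes_per_class={"novel_locus": 1000}, nb_dispersion=0.0,
            baseline_mean_range=(100.0, 100.0), library_size_cv=0.0,
        )
        catalog, _ = generate_catalog(cfg)
        sim, _ = simulate_counts(catalog, cfg, EffectSpec())
        ratio = sim.sense.var(axis=1, ddof=1) / sim.sense.mean(axis=1)
        assert (ratio.between(0.8, 1.2).mean()) >= 0.95

    def test_per_gene_log2fc_definition(self):
        cfg = SimConfig(
            seed=23, genes_per_class={"novel_locus": 50}, nb_dispersion=0.0,
            baseline_mean_range=(500.0, 500.0), library_size_cv=0.0,
        )
        catalog, _ = generate_catalog(cfg)
        gene = catalog.gene_ids[0]
        sim, truth = simulate_counts(catalog, cfg, EffectSpec(per_gene_de=[(gene, 2.0)]))
        ctrl = [s for s in sim.sense.columns if s.startswith("ctrl")]
        case = [s for s in sim.sense.columns if s.startswith("case")]
        ratio = sim.sense.loc[gene, case].mean() / sim.sense.loc[gene, ctrl].mean()
        assert 3.5 < ratio < 4.5
        assert truth.true_de == {gene: 2.0}

    def test_class_effect_calibration_over_seeds(self):
        """Monte-Carlo check of the generator against its own parameter: an
        injected pri-miRNA log2fc of +0.465 realizes a pooled case/control
        ratio within 10% of 1.38 (library factors divided out)."""
        ratios = []
        for seed in range(20):
            cfg = SimConfig(
                seed=100 + seed,
                genes_per_class={"coding": 1, "smallRNA:priMiRNA": 20},
                baseline_mean_range=(50.0, 150.0),
            )
            catalog, _ = generate_catalog(cfg)
            eff = EffectSpec(class_log2fc={"smallRNA:priMiRNA": 0.465})
            sim, truth = simulate_counts(catalog, cfg, eff)
            lib = pd.Series(truth.library_factors)
            adj = sim.sense.div(lib, axis=1)
            mirs = [t.transcript_id for t in catalog.by_class("smallRNA:priMiRNA")]
            ctrl = [s for s in adj.columns if s.startswith("ctrl")]
            case = [s for s in adj.columns if s.startswith("case")]
            ratios.append(
                (adj.loc[mirs, case].values.mean()) / (adj.loc[mirs, ctrl].values.mean())
            )
        assert np.mean(ratios) == pytest.approx(1.38, rel=0.10)

    def test_null_class_ratios_converge_to_one(self):
        """Calibration invariant: with no effects, pooled class ratios sit
        within 3 Monte-Carlo SE of 1 across seeds."""
        ratios = []
        for seed in range(20):
            cfg = SimConfig(
                seed=300 + seed, genes_per_class={"novel_locus": 50},
                baseline_mean_range=(50.0, 150.0),
            )
            catalog, _ = generate_catalog(cfg)
            sim, truth = simulate_counts(catalog, cfg, EffectSpec())
            lib = pd.Series(truth.library_factors)
            adj = sim.sense.div(lib, axis=1)
            ctrl = [s for s in adj.columns if s.startswith("ctrl")]
            case = [s for s in adj.columns if s.startswith("case")]
            ratios.append(adj[case].values.mean() / adj[ctrl].values.mean())
        mc_se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(np.mean(ratios) - 1.0) < 3 * mc_se

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(nb_dispersion=-0.1)

    def test_unknown_effect_ids_rejected(self, small_sim):
        cfg, catalog, sites, _, _ = small_sim
        with pytest.raises(ConfigurationError, match="unknown gene"):
            simulate_counts(catalog, cfg, EffectSpec(per_gene_de=[("nope", 1.0)]))


class TestSimulateAlignments:
    def test_conservation_per_sample(self, small_sim):
        cfg, catalog, sites, counts, _ = small_sim
        aln = simulate_alignments(catalog, counts, cfg, sites=sites)
        per_sample = aln.groupby("sample_id").size().sort_index()
        expected = (counts.sense.sum(axis=0) + counts.antisense.sum(axis=0)).sort_index()
        assert (per_sample.values == expected.values).all()

    def test_exact_record_count_per_transcript(self):
        cfg = SimConfig(
            seed=29, n_control=2, n_case=2,
            genes_per_class={"lncRNA": 0, "novel_locus": 5},
            baseline_mean_range=(5.0, 10.0),
        )
        cfg.genes_per_class["coding"] = 1
        catalog, sites = generate_catalog(cfg)
        sim, _ = simulate_counts(catalog, cfg, EffectSpec(antisense_fraction=0.0), sites=sites)
        aln = simulate_alignments(catalog, sim, cfg, sites=sites)
        locus = catalog.by_class("novel_locus")[0]
        s, e = locus.chain.exons[0]
        for sample in sim.sense.columns:
            c = int(sim.sense.loc[locus.transcript_id, sample])
            sub = aln[(aln["sample_id"] == sample) & (aln["chrom"] == "chr4")
                      & (aln["start"] >= s) & (aln["end"] <= e)]
            assert len(sub) == c

    def test_antisense_reads_within_gene_span_opposite_strand(self, small_sim):
        cfg, catalog, sites, counts, _ = small_sim
        aln = simulate_alignments(catalog, counts, cfg, sites=sites)
        gene = counts.antisense.index[0]
        rep = catalog.transcripts_of_gene(gene)[0]
        flipped = "-" if rep.chain.strand == "+" else "+"
        span = aln[(aln["chrom"] == rep.chain.chrom)
                   & (aln["start"] >= rep.chain.start) & (aln["end"] <= rep.chain.end)
                   & (aln["strand"] == flipped)]
        assert len(span) == counts.antisense.loc[gene].sum()

    def test_read_longer_than_transcript_rejected(self):
        cfg = SimConfig(genes_per_class={"coding": 1, "smallRNA:snoRNA_CD": 3},
                        read_length=5000)
        catalog, sites = generate_catalog(cfg)
        sim, _ = simulate_counts(catalog, cfg, EffectSpec())
        with pytest.raises(ConfigurationError, match="read_length"):
            simulate_alignments(catalog, sim, cfg, sites=sites)


class TestDefaultEffects:
    def test_effects_reference_existing_ids(self, small_sim):
        cfg, catalog, sites, _, _ = small_sim
        eff = default_effects(catalog, sites, seed=1, n_de=6, n_apa=(2, 2),
                              n_isoform_shifts=3, n_target_sets=2, target_set_size=5)
        genes = set(catalog.gene_ids)
        assert all(g in genes for g, _ in eff.per_gene_de)
        assert all(g in genes for g, _, _ in eff.apa_shifts)
        assert all(g in genes and i in catalog for g, i, _ in eff.isoform_shifts)
        for lst in eff.target_sets.values():
            assert set(lst) <= genes
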