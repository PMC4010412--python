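import numpy as np
import pytest

from strandtx.catalog import ExonChain, TranscriptCatalog, TranscriptModel
from strandtx.synthetic import EffectSpec, SimConfig, generate_catalog, simulate_counts


def make_transcript(tid, gene, chrom, strand, exons, rna_class="coding"):
    return TranscriptModel(tid, gene, ExonChain(chrom, strand, tuple(exons)), rna_class)


@pytest.fixture
def hand_catalog():
    """A tiny hand-built catalog exercising every assignment rule.

    chr1: +strand coding gene gA with two isoforms (shared exons at
    [100,200) and [500,600); isoform 2 also has [800,900)); a -strand lncRNA
    at [2000,2500); a +strand repeat at [3000,3300) overlapping nothing; and a
    +strand repeat at [560,700) overlapping gA's second exon (multi-class trap).
    """
    cat = TranscriptCatalog()
    cat.add(make_transcript("gA.1", "gA", "chr1", "+", [(100, 200), (500, 600)]))
    cat.add(make_transcript("gA.2", "gA", "chr1", "+", [(100, 200), (500, 600), (800, 900)]))
    cat.add(make_transcript("lnc1", "lnc1", "chr1", "-", [(2000, 2500)], "lncRNA"))
    cat.add(make_transcript("rep1", "rep1", "chr1", "+", [(3000, 3300)], "repeat:SINE_Alu"))
    cat.add(make_transcript("rep2", "rep2", "chr1", "+", [(560, 700)], "repeat:L1"))
    return cat


@pytest.fixture(scope="session")
def small_sim():
    """One small end-to-end simulation shared across tests (no effects)."""
    cfg = SimConfig(
        seed=42,
        genes_per_class={
            "coding": 25,
            "lncRNA": 12,
            "smallRNA:priMiRNA": 8,
            "smallRNA:snoRNA_CD": 5,
            "repeat:ERV1": 6,
            "repeat:SINE_Alu": 6,
            "novel_locus": 40,
            "novel_isoform": 5,
        },
        baseline_mean_range=(10.0, 80.0),
    )
    catalog, sites = generate_catalog(cfg)
    counts, truth = simulate_counts(catalog, cfg, EffectSpec(), sites=sites)
    return cfg, catalog, sites, counts, truth
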