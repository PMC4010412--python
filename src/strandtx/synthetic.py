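"""Synthetic annotation, count and alignment generator with known ground truth.

The generator emulates a strand-specific total-RNA monocyte-style experiment:
two groups of libraries (8 control / 9 case by default), a multi-class
annotation (coding genes with isoforms and several 3' cleavage sites, lncRNAs
placed at controlled distances around coding genes, small-RNA subclasses,
repeat subclasses including ERV families, mostly single-exon novel loci, and
novel isoforms of coding genes), negative-binomial counts with configurable
class-level and per-gene effects, and 50-base strand-specific reads positioned
so that cleavage-site window counting recovers the injected
proximal/distal usage.

Counts follow NB(mean = baseline x library factor x 2^(group effect),
var = mu + phi*mu^2), drawn as a gamma-Poisson mixture.  Library-size factors
are log-normal with the configured coefficient of variation: they are the
nuisance that total-count normalization downstream is meant to remove.
Correlation structure (sense-antisense coupling, lncRNA-neighbor
co-expression) is injected through shared log-normal latent factors per coding
gene and sample; the latent multiplier is switched off when no correlation is
requested so that marginal counts stay exactly negative binomial.

Genomic layout: each class lives in its own coordinate region, so classes
never overlap except the deliberately placed lncRNA neighbors (and antisense
reads, which are an attribute of coding genes rather than separate
transcripts).  All randomness flows from one integer seed; identical
(config, effects, seed) give byte-identical serialized outputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .apa import CleavageSite
from .catalog import (
    ExonChain,
    REPEAT_SUBCLASSES,
    SMALL_RNA_SUBCLASSES,
    TranscriptCatalog,
    TranscriptModel,
)
from .errors import ConfigurationError

DEFAULT_GENES_PER_CLASS: Dict[str, int] = {
    "coding": 120,
    "lncRNA": 60,
    "smallRNA:priMiRNA": 30,
    "smallRNA:snoRNA_CD": 15,
    "smallRNA:snoRNA_HACA": 15,
    "smallRNA:scaRNA": 10,
    **{f"repeat:{s}": 12 for s in REPEAT_SUBCLASSES},
    "novel_locus": 150,
    "novel_isoform": 30,
}

_LNC_DISTANCES = (2_000, 8_000, 15_000, 30_000, 40_000, 60_000, 80_000, 95_000)
_LNC_GEOMETRY = (
    ("upstream", "same"),
    ("upstream", "opposite"),
    ("downstream", "same"),
    ("downstream", "opposite"),
)
_TERRITORY = 400_000  # coordinate slot per coding gene, hosting its lncRNA neighbors


@dataclass
class SimConfig:
    """Study-design parameters of the simulation."""

    seed: int = 0
    n_control: int = 8
    n_case: int = 9
    genes_per_class: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENES_PER_CLASS)
    )
    isoforms_per_coding_gene: Tuple[int, int] = (1, 3)
    cleavage_sites_per_gene: Tuple[int, int] = (2, 4)
    nb_dispersion: float = 0.1
    baseline_mean_range: Tuple[float, float] = (20.0, 200.0)
    library_size_cv: float = 0.15
    read_length: int = 50
    latent_sd: float = 0.6  # scale of shared latent factors when correlations injected
    fc_bias_slope: float = 0.0  # log2FC per log10-baseline, for loess-adjustment testing

    def __post_init__(self):
        if self.n_control < 2 or self.n_case < 2:
            raise ConfigurationError("need at least 2 samples per group")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if self.library_size_cv < 0:
            raise ConfigurationError("library_size_cv must be >= 0")
        if any(v < 0 for v in self.genes_per_class.values()):
            raise ConfigurationError("gene counts must be >= 0")
        if self.baseline_mean_range[0] <= 0:
            raise ConfigurationError("baseline means must be positive")
        n_coding = self.genes_per_class.get("coding", 0)
        for needs_coding in ("novel_isoform",):
            if self.genes_per_class.get(needs_coding, 0) > 0 and n_coding == 0:
                raise ConfigurationError(
                    f"class 'coding' is required by requested class {needs_coding!r} "
                    "but zero coding genes were configured"
                )
        if self.genes_per_class.get("lncRNA", 0) > 0 and n_coding == 0:
            raise ConfigurationError(
                "class 'coding' is required for lncRNA neighbor placement "
                "but zero coding genes were configured"
            )

    @property
    def samples(self) -> List[str]:
        return [f"ctrl_{i+1}" for i in range(self.n_control)] + [
            f"case_{i+1}" for i in range(self.n_case)
        ]

    @property
    def groups(self) -> Dict[str, str]:
        return {
            s: ("control" if s.startswith("ctrl") else "case") for s in self.samples
        }


@dataclass
class EffectSpec:
    """Injected between-group effects and correlation structure."""

    class_log2fc: Dict[str, float] = field(default_factory=dict)
    per_gene_de: List[Tuple[str, float]] = field(default_factory=list)
    apa_shifts: List[Tuple[str, str, float]] = field(default_factory=list)
    isoform_shifts: List[Tuple[str, str, float]] = field(default_factory=list)
    antisense_fraction: float = 1.0 / 30.0
    sense_antisense_corr: float = 0.0
    lnc_neighbor_corr: float = 0.0
    target_sets: Dict[str, List[str]] = field(default_factory=dict)
    target_extra_log2fc: float = 0.0

    def __post_init__(self):
        for gene, direction, ratio in self.apa_shifts:
            if direction not in ("longer", "shorter"):
                raise ConfigurationError(f"APA direction must be longer|shorter, got {direction!r}")
            if ratio <= 1:
                raise ConfigurationError("APA shift ratios must be > 1")
        for gene, iso, delta in self.isoform_shifts:
            if abs(delta) > 1:
                raise ConfigurationError("|isoform proportion delta| must be <= 1")
        if not 0 <= self.antisense_fraction <= 1:
            raise ConfigurationError("antisense_fraction must be in [0, 1]")
        for rho in (self.sense_antisense_corr, self.lnc_neighbor_corr):
            if not -1 < rho < 1:
                raise ConfigurationError("correlations must be in (-1, 1)")


@dataclass
class GroundTruth:
    """The injected effects, kept as the recovery target for downstream tests."""

    groups: Dict[str, str]
    library_factors: Dict[str, float]
    class_log2fc: Dict[str, float]
    true_de: Dict[str, float]  # gene -> injected log2fc (per-gene effects only)
    true_apa: Dict[str, Tuple[str, float]]  # gene -> (direction, ratio)
    true_isoform_shifts: Dict[str, Tuple[str, float]]  # gene -> (isoform, delta)
    target_sets: Dict[str, List[str]]
    target_extra_log2fc: float
    sense_antisense_corr: float
    antisense_fraction: float
    lnc_pairs: List[Dict[str, object]]  # lnc, gene, distance, position, strand, rho
    baselines: Dict[str, float]  # transcript -> baseline mean (control, no library factor)


@dataclass
class SimulatedCounts:
    """Transcript-level sense and coding-gene antisense count matrices."""

    sense: pd.DataFrame
    antisense: pd.DataFrame
    groups: Dict[str, str]
    apa_usage: Dict[str, Dict[str, np.ndarray]]  # gene -> group -> site weights by rank


# ------------------------------------------------------------------ catalog


def _coding_gene(rng: np.random.Generator, gene_id: str, offset: int,
                 config: SimConfig) -> Tuple[List[TranscriptModel], List[Tuple[int, int]], str]:
    """One coding gene: full-chain isoform plus exon-skipping isoforms."""
    strand = "+" if rng.integers(2) == 0 else "-"
    n_exons = int(rng.integers(4, 9))
    final_len = 1500
    exons: List[Tuple[int, int]] = []
    pos = offset
    for i in range(n_exons):
        length = final_len if (i == n_exons - 1 and strand == "+") or (
            i == 0 and strand == "-"
        ) else int(rng.integers(120, 301))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(400, 1501))

    lo, hi = config.isoforms_per_coding_gene
    n_iso = int(rng.integers(lo, hi + 1))
    transcripts = [
        TranscriptModel(f"{gene_id}.1", gene_id, ExonChain("chr1", strand, tuple(exons)), "coding")
    ]
    # extra isoforms skip one internal exon each (never the terminal exons)
    skippable = list(range(1, n_exons - 1))
    for k in range(1, n_iso):
        skip = skippable[(k - 1) % len(skippable)]
        chain = tuple(e for i, e in enumerate(exons) if i != skip)
        transcripts.append(
            TranscriptModel(f"{gene_id}.{k+1}", gene_id, ExonChain("chr1", strand, chain), "coding")
        )
    return transcripts, exons, strand


def _cleavage_sites(rng: np.random.Generator, gene_id: str, exons: List[Tuple[int, int]],
                    strand: str, config: SimConfig) -> List[CleavageSite]:
    lo, hi = config.cleavage_sites_per_gene
    k = int(rng.integers(lo, hi + 1))
    sites = []
    if strand == "+":
        fs, fe = exons[-1]
        for r in range(1, k + 1):
            sites.append(CleavageSite(gene_id, "chr1", fs + 250 * r, "+", r))
    else:
        fs, fe = exons[0]
        for r in range(1, k + 1):
            sites.append(CleavageSite(gene_id, "chr1", fe - 250 * r, "-", r))
    return sites


def generate_catalog(
    config: SimConfig, seed: Optional[int] = None
) -> Tuple[TranscriptCatalog, List[CleavageSite]]:
    """Generate the annotation: a transcript catalog and its cleavage-site DB.

    Coding genes (with isoforms and cleavage sites) and their lncRNA neighbors
    share chr1; small RNAs, repeats and novel loci occupy chr2-chr4.  At least
    97% of novel loci are single-exon.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    gpc = config.genes_per_class
    catalog = TranscriptCatalog()
    sites: List[CleavageSite] = []

    n_coding = gpc.get("coding", 0)
    coding_info: List[Tuple[str, List[Tuple[int, int]], str, int]] = []
    for i in range(n_coding):
        gene_id = f"CG{i+1:04d}"
        offset = i * _TERRITORY + 200_000
        transcripts, exons, strand = _coding_gene(rng, gene_id, offset, config)
        for t in transcripts:
            catalog.add(t)
        sites.extend(_cleavage_sites(rng, gene_id, exons, strand, config))
        coding_info.append((gene_id, exons, strand, offset))

    # novel isoforms: an extra exon dropped into the first intron of a coding gene
    for j in range(gpc.get("novel_isoform", 0)):
        gene_id, exons, strand, _ = coding_info[j % n_coding]
        if f"{gene_id}_nov" in catalog:
            continue
        (s0, e0), (s1, _) = exons[0], exons[1]
        mid = (e0 + s1) // 2
        extra = (mid - 75, mid + 75)
        chain = tuple(sorted(list(exons) + [extra]))
        catalog.add(
            TranscriptModel(f"{gene_id}_nov", gene_id, ExonChain("chr1", strand, chain),
                            "novel_isoform")
        )

    # lncRNA neighbors of coding genes, cycling geometry and distance
    for j in range(gpc.get("lncRNA", 0)):
        gene_id, exons, strand, offset = coding_info[j % n_coding]
        position, relation = _LNC_GEOMETRY[j % len(_LNC_GEOMETRY)]
        distance = _LNC_DISTANCES[j % len(_LNC_DISTANCES)]
        if (j + 1) % 10 == 0:
            distance = 150_000  # deliberately beyond the neighbor window
        g_start, g_end = exons[0][0], exons[-1][1]
        length = 1500
        lnc_strand = strand if relation == "same" else ("-" if strand == "+" else "+")
        if strand == "+":
            tss, tes = g_start, g_end
            if position == "upstream":
                # anchor: lnc TSS at distance `distance` from the coding TSS
                if lnc_strand == "+":
                    start = tss - distance
                else:
                    start = tss - distance - length
            else:
                start = tes + distance
        else:
            tss, tes = g_end, g_start
            if position == "upstream":
                if lnc_strand == "-":
                    start = tss + distance - length
                else:
                    start = tss + distance
            else:
                start = tes - distance - length
        lid = f"LNC{j+1:04d}"
        catalog.add(
            TranscriptModel(lid, lid, ExonChain("chr1", lnc_strand, ((start, start + length),)),
                            "lncRNA")
        )

    # small RNAs on chr2
    pos = 10_000
    length_ranges = {
        "priMiRNA": (800, 2000),
        "snoRNA_CD": (100, 300),
        "snoRNA_HACA": (100, 300),
        "scaRNA": (200, 400),
    }
    prefixes = {"priMiRNA": "MIR", "snoRNA_CD": "SNOCD", "snoRNA_HACA": "SNOHACA",
                "scaRNA": "SCA"}
    for sub in SMALL_RNA_SUBCLASSES:
        for i in range(gpc.get(f"smallRNA:{sub}", 0)):
            lo, hi = length_ranges[sub]
            length = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.integers(2) == 0 else "-"
            gid = f"{prefixes[sub]}{i+1:04d}"
            catalog.add(
                TranscriptModel(gid, gid, ExonChain("chr2", strand, ((pos, pos + length),)),
                                f"smallRNA:{sub}")
            )
            pos += length + 5_000

    # repeat elements on chr3
    pos = 10_000
    repeat_lengths = {
        "ERV1": (1000, 6000), "ERVK": (1000, 6000), "ERVL": (1000, 6000),
        "LTR_other": (400, 800), "L1": (2000, 5000),
        "SINE_Alu": (250, 350), "SINE1_7SL": (280, 320),
    }
    for sub in REPEAT_SUBCLASSES:
        for i in range(gpc.get(f"repeat:{sub}", 0)):
            lo, hi = repeat_lengths[sub]
            length = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.integers(2) == 0 else "-"
            gid = f"RPT_{sub}_{i+1:04d}"
            catalog.add(
                TranscriptModel(gid, gid, ExonChain("chr3", strand, ((pos, pos + length),)),
                                f"repeat:{sub}")
            )
            pos += length + 3_000

    # novel loci on chr4; every 50th gets a second exon (>= 97% single-exon)
    pos = 10_000
    for i in range(gpc.get("novel_locus", 0)):
        strand = "+" if rng.integers(2) == 0 else "-"
        gid = f"NL{i+1:04d}"
        if (i + 1) % 50 == 0:
            exons = ((pos, pos + 300), (pos + 800, pos + 1100))
            pos += 1100 + 10_000
        else:
            length = int(rng.integers(300, 1501))
            exons = ((pos, pos + length),)
            pos += length + 10_000
        catalog.add(TranscriptModel(gid, gid, ExonChain("chr4", strand, exons), "novel_locus"))

    return catalog, sites


# ------------------------------------------------------------------- counts


def _gene_full_class(catalog: TranscriptCatalog, gene_id: str) -> str:
    for t in catalog.transcripts_of_gene(gene_id):
        if t.major_class != "novel_isoform":
            return t.rna_class
    return "novel_isoform"


def _class_lfc(class_log2fc: Mapping[str, float], full_class: str) -> float:
    if full_class in class_log2fc:
        return class_log2fc[full_class]
    return class_log2fc.get(full_class.split(":", 1)[0], 0.0)


def simulate_counts(
    catalog: TranscriptCatalog,
    config: SimConfig,
    effects: EffectSpec,
    seed: Optional[int] = None,
    sites: Optional[Sequence[CleavageSite]] = None,
) -> Tuple[SimulatedCounts, GroundTruth]:
    """Draw NB count matrices and record the injected ground truth.

    Effects referencing genes or isoforms absent from the catalog raise a
    configuration error.  Cleavage-site usage weights per gene and group
    (driving read placement and hence APA recovery) are attached to the
    returned counts.
    """
    if config.nb_dispersion < 0:
        raise ConfigurationError("nb_dispersion must be >= 0")
    gene_ids = set(catalog.gene_ids)
    for gene, _ in effects.per_gene_de:
        if gene not in gene_ids:
            raise ConfigurationError(f"per_gene_de references unknown gene {gene!r}")
    for gene, _, _ in effects.apa_shifts:
        if gene not in gene_ids:
            raise ConfigurationError(f"apa_shifts references unknown gene {gene!r}")
    for gene, iso, _ in effects.isoform_shifts:
        if gene not in gene_ids or iso not in catalog:
            raise ConfigurationError(f"isoform_shifts references unknown {gene!r}/{iso!r}")

    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    rng = np.random.default_rng(ss)
    samples = config.samples
    groups = config.groups
    n_s = len(samples)
    is_case = np.array([groups[s] == "case" for s in samples])

    # library factors: log-normal, unit mean, configured CV
    if config.library_size_cv > 0:
        sigma = math.sqrt(math.log(1 + config.library_size_cv**2))
        lib = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n_s))
    else:
        lib = np.ones(n_s)

    per_gene = dict()
    for gene, lfc in effects.per_gene_de:
        per_gene[gene] = per_gene.get(gene, 0.0) + lfc
    target_genes: Dict[str, float] = {}
    for mirna, genes in effects.target_sets.items():
        for g in genes:
            if g not in gene_ids:
                raise ConfigurationError(
                    f"target set {mirna!r} references unknown gene {g!r}"
                )
            target_genes[g] = effects.target_extra_log2fc

    lo, hi = config.baseline_mean_range
    phi = config.nb_dispersion

    # per-gene baselines and isoform proportions
    gene_baseline: Dict[str, float] = {}
    iso_props: Dict[str, Tuple[List[str], np.ndarray, np.ndarray]] = {}
    shift_by_gene = {g: (iso, d) for g, iso, d in effects.isoform_shifts}
    for gene in catalog.gene_ids:
        gene_baseline[gene] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        tids = [t.transcript_id for t in catalog.transcripts_of_gene(gene)]
        if len(tids) == 1:
            iso_props[gene] = (tids, np.ones(1), np.ones(1))
            continue
        pi = rng.dirichlet(np.full(len(tids), 5.0))
        pi_case = pi.copy()
        if gene in shift_by_gene:
            iso, delta = shift_by_gene[gene]
            i = tids.index(iso)
            others = pi_case.sum() - pi_case[i]
            new_i = min(max(pi_case[i] + delta, 0.0), 1.0)
            scale = (1.0 - new_i) / others if others > 0 else 0.0
            pi_case = pi_case * scale
            pi_case[i] = new_i
        iso_props[gene] = (tids, pi, pi_case)

    # latent factors for injected correlation structure
    use_latent = effects.sense_antisense_corr != 0 or effects.lnc_neighbor_corr != 0
    sd = config.latent_sd if use_latent else 0.0
    coding_genes = [g for g in catalog.gene_ids if catalog.gene_class(g) == "coding"]
    latent_u = {g: rng.normal(size=n_s) for g in coding_genes} if use_latent else {}

    def _latent_mult(z: np.ndarray) -> np.ndarray:
        return np.exp(sd * z - 0.5 * sd**2)

    # ground-truth lncRNA pair table with injected correlation strengths
    from .correlate import find_neighbor_pairs

    lnc_pairs = []
    lnc_latent: Dict[str, np.ndarray] = {}
    if use_latent and effects.lnc_neighbor_corr != 0:
        pair_frame = find_neighbor_pairs(catalog, max_distance=100_000)
        for row in pair_frame.itertuples(index=False):
            if row.position == "upstream":
                rho = effects.lnc_neighbor_corr * (1.0 - row.distance / 100_000)
            elif row.strand_relation == "same":
                rho = effects.lnc_neighbor_corr
            else:
                rho = 0.0
            lnc_pairs.append(
                {
                    "lnc_id": row.lnc_id,
                    "gene_id": row.gene_id,
                    "distance": int(row.distance),
                    "position": row.position,
                    "strand_relation": row.strand_relation,
                    "rho": float(rho),
                }
            )
            if row.lnc_id not in lnc_latent and row.gene_id in latent_u:
                u = latent_u[row.gene_id]
                eps = rng.normal(size=n_s)
                lnc_latent[row.lnc_id] = rho * u + math.sqrt(max(0.0, 1 - rho**2)) * eps

    # per-transcript mean matrix
    tids = [t.transcript_id for t in catalog]
    mean = np.zeros((len(tids), n_s))
    baselines: Dict[str, float] = {}
    lfc_center = 0.5 * (np.log10(lo) + np.log10(hi))
    for i, t in enumerate(catalog):
        gene = t.gene_id
        g_tids, pi, pi_case = iso_props[gene]
        j = g_tids.index(t.transcript_id)
        base = gene_baseline[gene]
        full_class = _gene_full_class(catalog, gene)
        lfc = _class_lfc(effects.class_log2fc, full_class)
        lfc += per_gene.get(gene, 0.0)
        lfc += target_genes.get(gene, 0.0)
        if config.fc_bias_slope != 0:
            lfc += config.fc_bias_slope * (np.log10(base) - lfc_center)
        mu_ctrl = base * pi[j]
        mu_case = base * pi_case[j] * 2.0**lfc
        row = np.where(is_case, mu_case, mu_ctrl) * lib
        if use_latent:
            if t.major_class == "lncRNA" and t.transcript_id in lnc_latent:
                row = row * _latent_mult(lnc_latent[t.transcript_id])
            elif gene in latent_u:
                row = row * _latent_mult(latent_u[gene])
        mean[i] = row
        baselines[t.transcript_id] = float(base * pi[j])

    def _draw(mu: np.ndarray) -> np.ndarray:
        if phi == 0:
            return rng.poisson(mu)
        lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
        return rng.poisson(lam)

    sense = pd.DataFrame(_draw(mean), index=tids, columns=samples)

    # antisense counts for coding genes
    anti_lfc = effects.class_log2fc.get("antisense", 0.0)
    anti_mean = np.zeros((len(coding_genes), n_s))
    rho_sa = effects.sense_antisense_corr
    for i, gene in enumerate(coding_genes):
        base = gene_baseline[gene] * effects.antisense_fraction
        row = base * np.where(is_case, 2.0**anti_lfc, 1.0) * lib
        if use_latent:
            eps = rng.normal(size=n_s)
            v = rho_sa * latent_u[gene] + math.sqrt(max(0.0, 1 - rho_sa**2)) * eps
            row = row * _latent_mult(v)
        anti_mean[i] = row
    antisense = pd.DataFrame(_draw(anti_mean), index=coding_genes, columns=samples)

    # APA site-usage weights per gene and group
    site_ranks: Dict[str, List[int]] = {}
    for s in sites or ():
        site_ranks.setdefault(s.gene_id, []).append(s.rank)
    for ranks in site_ranks.values():
        ranks.sort()
    apa_by_gene = {g: (d, r) for g, d, r in effects.apa_shifts}
    for gene in apa_by_gene:
        if sites is not None and gene not in site_ranks:
            raise ConfigurationError(f"apa_shifts references gene {gene!r} without cleavage sites")
    apa_usage: Dict[str, Dict[str, np.ndarray]] = {}
    for gene, ranks in site_ranks.items():
        k = len(ranks)
        w_ctrl = np.full(k, 1.0 / k)
        w_case = w_ctrl.copy()
        if gene in apa_by_gene:
            direction, ratio = apa_by_gene[gene]
            w_case = w_ctrl.copy()
            if direction == "shorter":
                w_case[0] *= ratio  # boost the most proximal site in cases
            else:
                w_case[-1] *= ratio  # boost the most distal site
            w_case /= w_case.sum()
        apa_usage[gene] = {"control": w_ctrl, "case": w_case}

    truth = GroundTruth(
        groups=dict(groups),
        library_factors={s: float(f) for s, f in zip(samples, lib)},
        class_log2fc=dict(effects.class_log2fc),
        true_de=dict(per_gene),
        true_apa={g: (d, float(r)) for g, d, r in effects.apa_shifts},
        true_isoform_shifts={g: (iso, float(d)) for g, iso, d in effects.isoform_shifts},
        target_sets={k: list(v) for k, v in effects.target_sets.items()},
        target_extra_log2fc=effects.target_extra_log2fc,
        sense_antisense_corr=effects.sense_antisense_corr,
        antisense_fraction=effects.antisense_fraction,
        lnc_pairs=lnc_pairs,
        baselines=baselines,
    )
    return SimulatedCounts(sense=sense, antisense=antisense, groups=dict(groups),
                           apa_usage=apa_usage), truth


# ---------------------------------------------------------------- alignments


def simulate_alignments(
    catalog: TranscriptCatalog,
    counts: SimulatedCounts,
    config: SimConfig,
    seed: Optional[int] = None,
    sites: Optional[Sequence[CleavageSite]] = None,
) -> pd.DataFrame:
    """Emit one alignment record per counted read.

    Sense reads of coding genes with cleavage sites are placed in the 200-base
    windows upstream of their cleavage points, multinomially over the gene's
    group-specific site-usage weights; all other sense reads fall uniformly
    inside one exon (length-weighted among exons long enough to hold a read).
    Antisense counts become reads within the gene's exons on the opposite
    strand.  Per-sample record totals equal the count-matrix column totals
    exactly.
    """
    read_len = config.read_length
    for t in catalog:
        if t.chain.length < read_len:
            raise ConfigurationError(
                f"read_length {read_len} exceeds transcript length of {t.transcript_id!r}"
            )
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed if seed is None else seed, 1))
    )
    site_by_gene: Dict[str, List[CleavageSite]] = {}
    for s in sites or ():
        site_by_gene.setdefault(s.gene_id, []).append(s)
    for g in site_by_gene:
        site_by_gene[g].sort(key=lambda s: s.rank)

    chroms: List[np.ndarray] = []
    starts: List[np.ndarray] = []
    ends: List[np.ndarray] = []
    strands: List[np.ndarray] = []
    sample_ids: List[np.ndarray] = []

    def _emit(chrom: str, s: np.ndarray, e: np.ndarray, strand: str, sample: str):
        k = len(s)
        if k == 0:
            return
        chroms.append(np.full(k, chrom, dtype=object))
        starts.append(s)
        ends.append(e)
        strands.append(np.full(k, strand, dtype=object))
        sample_ids.append(np.full(k, sample, dtype=object))

    samples = list(counts.sense.columns)
    sense_mat = counts.sense.values
    tids = list(counts.sense.index)
    for i, tid in enumerate(tids):
        t = catalog.get(tid)
        chain = t.chain
        gene_sites = site_by_gene.get(t.gene_id)
        eligible = [(s, e) for s, e in chain.exons if e - s >= read_len]
        weights = np.array([e - s for s, e in eligible], dtype=float)
        weights /= weights.sum()
        for j, sample in enumerate(samples):
            c = int(sense_mat[i, j])
            if c == 0:
                continue
            if gene_sites is not None:
                gene_usage = counts.apa_usage.get(t.gene_id)
                if gene_usage is None:  # counts simulated without a site DB
                    k = len(gene_sites)
                    gene_usage = {"control": np.full(k, 1 / k), "case": np.full(k, 1 / k)}
                usage = gene_usage[counts.groups[sample]]
                alloc = rng.multinomial(c, usage)
                for site, k in zip(gene_sites, alloc):
                    if k == 0:
                        continue
                    lo, hi = site.window()
                    if chain.strand == "+":
                        s0 = rng.integers(lo, hi, size=k)
                        _emit(chain.chrom, s0, s0 + read_len, "+", sample)
                    else:
                        five = rng.integers(lo, hi, size=k)  # 5' base = end - 1
                        e0 = five + 1
                        _emit(chain.chrom, e0 - read_len, e0, "-", sample)
            else:
                ei = rng.choice(len(eligible), size=c, p=weights)
                s0 = np.empty(c, dtype=np.int64)
                for x, (es, ee) in enumerate(eligible):
                    m = ei == x
                    s0[m] = rng.integers(es, ee - read_len + 1, size=int(m.sum()))
                _emit(chain.chrom, s0, s0 + read_len, chain.strand, sample)

    # antisense reads over coding-gene exons, opposite strand
    anti_mat = counts.antisense.values
    for i, gene in enumerate(counts.antisense.index):
        rep = catalog.transcripts_of_gene(gene)[0]
        chain = rep.chain
        flipped = "-" if chain.strand == "+" else "+"
        eligible = [(s, e) for s, e in chain.exons if e - s >= read_len]
        weights = np.array([e - s for s, e in eligible], dtype=float)
        weights /= weights.sum()
        for j, sample in enumerate(samples):
            c = int(anti_mat[i, j])
            if c == 0:
                continue
            ei = rng.choice(len(eligible), size=c, p=weights)
            s0 = np.empty(c, dtype=np.int64)
            for x, (es, ee) in enumerate(eligible):
                m = ei == x
                s0[m] = rng.integers(es, ee - read_len + 1, size=int(m.sum()))
            _emit(chain.chrom, s0, s0 + read_len, flipped, sample)

    if not chroms:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "strand", "sample_id", "unique"]
        )
    frame = pd.DataFrame(
        {
            "chrom": np.concatenate(chroms),
            "start": np.concatenate(starts).astype(np.int64),
            "end": np.concatenate(ends).astype(np.int64),
            "strand": np.concatenate(strands),
            "sample_id": np.concatenate(sample_ids),
            "unique": True,
        }
    )
    return frame


# ------------------------------------------------------------- default runs


def default_effects(
    catalog: TranscriptCatalog,
    sites: Sequence[CleavageSite],
    seed: int = 0,
    n_de: int = 20,
    de_log2fc: float = 2.0,
    n_apa: Tuple[int, int] = (6, 5),
    apa_ratio: float = 3.0,
    n_isoform_shifts: int = 8,
    isoform_delta: float = 0.2,
    n_target_sets: int = 3,
    target_set_size: int = 25,
    target_extra_log2fc: float = -0.25,
) -> EffectSpec:
    """Effect specification emulating the observed study conditions.

    Class-level shifts: coding and antisense transcription down ~15%
    (log2 -0.234), novel loci up ~45%, small RNAs down ~5% overall with
    pri-miRNAs up 38% (log2 0.465) and all snoRNA classes down, ERV families
    consistently down, other repeats mixed with SINE1/7SL up.  Per-gene,
    APA, isoform-shift and miRNA-target effects are assigned to deterministic
    pseudo-random gene subsets.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    class_log2fc = {
        "coding": -0.234,
        "antisense": -0.234,
        "novel_locus": 0.546,
        "novel_isoform": -0.234,
        "lncRNA": 0.0,
        "smallRNA": -0.074,
        "smallRNA:priMiRNA": 0.465,
        "smallRNA:snoRNA_CD": -0.4,
        "smallRNA:snoRNA_HACA": -0.4,
        "smallRNA:scaRNA": -0.3,
        "repeat:ERV1": -0.45,
        "repeat:ERVK": -0.6,
        "repeat:ERVL": -0.35,
        "repeat:LTR_other": -0.25,
        "repeat:L1": -0.2,
        "repeat:SINE_Alu": -0.1,
        "repeat:SINE1_7SL": 0.2,
    }
    coding = [g for g in catalog.gene_ids if catalog.gene_class(g) == "coding"]
    pool = list(coding)
    rng.shuffle(pool)

    def _take(n: int) -> List[str]:
        taken, rest = pool[:n], pool[n:]
        del pool[:]
        pool.extend(rest)
        return taken

    # keep per-gene DE to at most a quarter of coding genes so that APA and
    # target-set assignment still have a pool on small catalogs
    de_genes = _take(min(n_de, max(2, len(coding) // 4)))
    per_gene_de = [
        (g, de_log2fc if i % 2 == 0 else -de_log2fc) for i, g in enumerate(de_genes)
    ]

    multi_site = sorted({s.gene_id for s in sites if sum(x.gene_id == s.gene_id for x in sites) >= 2})
    apa_pool = [g for g in multi_site if g not in de_genes]
    rng.shuffle(apa_pool)
    n_short, n_long = n_apa
    apa_shifts = [(g, "shorter", apa_ratio) for g in apa_pool[:n_short]]
    apa_shifts += [(g, "longer", apa_ratio) for g in apa_pool[n_short:n_short + n_long]]

    multi_iso = [g for g in coding if len(catalog.transcripts_of_gene(g)) >= 2]
    rng.shuffle(multi_iso)
    isoform_shifts = []
    for g in multi_iso[:n_isoform_shifts]:
        isos = catalog.transcripts_of_gene(g)
        gaining = max(isos, key=lambda t: (t.chain.n_exons, t.transcript_id))
        isoform_shifts.append((g, gaining.transcript_id, isoform_delta))

    target_sets = {}
    for m in range(n_target_sets):
        size = min(target_set_size, max(3, len(pool) // max(1, n_target_sets - m)))
        target_sets[f"mir_{m+1}"] = _take(min(size, len(pool)))

    return EffectSpec(
        class_log2fc=class_log2fc,
        per_gene_de=per_gene_de,
        apa_shifts=apa_shifts,
        isoform_shifts=isoform_shifts,
        antisense_fraction=1.0 / 30.0,
        sense_antisense_corr=0.19,
        lnc_neighbor_corr=0.4,
        target_sets=target_sets,
        target_extra_log2fc=target_extra_log2fc,
    )
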