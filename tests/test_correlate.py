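"""Fisher-z combining identities and the three correlation applications."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from strandtx.correlate import (
    NeighborBinSpec,
    combine_correlation,
    find_neighbor_pairs,
    neighbor_correlation,
    sense_antisense_profile,
    target_set_shift,
)


def _paired_samples(rng, r, n):
    z = rng.normal(size=n)
    e = rng.normal(size=n)
    x = z
    y = r * z + math.sqrt(1 - r**2) * e
    return x, y


def _make_xy(r_control, r_case, n_control=8, n_case=9, seed=0):
    """Data whose within-group sample correlations are exactly r_control/r_case."""
    rng = np.random.default_rng(seed)

    def exact_corr(r, n):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        # orthogonalize then mix for an exact sample correlation
        x = (x - x.mean()) / x.std()
        y = y - y.mean()
        y -= x * (x @ y) / (x @ x)
        y /= np.sqrt((y @ y) / n)
        return x, r * x + math.sqrt(1 - r**2) * y

    xc, yc = exact_corr(r_control, n_control)
    xk, yk = exact_corr(r_case, n_case)
    x = np.concatenate([xc, xk])
    y = np.concatenate([yc, yk])
    groups = ["control"] * n_control + ["case"] * n_case
    return x, y, groups


class TestCombineCorrelation:
    def test_idempotence(self):
        x, y, g = _make_xy(0.5, 0.5)
        rec = combine_correlation(x, y, g)
        assert rec.r_combined == pytest.approx(0.5, abs=1e-10)

    def test_antisymmetry(self):
        x, y, g = _make_xy(0.3, -0.3)
        rec = combine_correlation(x, y, g)
        assert rec.r_combined == pytest.approx(0.0, abs=1e-10)

    def test_formula_value(self):
        x, y, g = _make_xy(0.2, 0.6)
        rec = combine_correlation(x, y, g)
        expected = math.tanh((math.atanh(0.2) + math.atanh(0.6)) / 2)
        assert rec.r_combined == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(0.4202, abs=5e-5)

    def test_group_symmetry(self):
        x, y, g = _make_xy(0.1, 0.7)
        swapped = ["case" if v == "control" else "control" for v in g]
        a = combine_correlation(x, y, g)
        b = combine_correlation(x, y, swapped)
        assert a.r_combined == pytest.approx(b.r_combined)

    def test_combined_never_exceeds_strongest_group(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.normal(size=17)
            y = rng.normal(size=17)
            g = ["control"] * 8 + ["case"] * 9
            rec = combine_correlation(x, y, g)
            assert abs(rec.r_combined) <= max(abs(rec.r_control), abs(rec.r_case)) + 1e-12

    def test_zero_variance_group_flagged(self):
        x = np.concatenate([np.ones(8), np.arange(9.0)])
        y = np.arange(17.0)
        rec = combine_correlation(x, y, ["control"] * 8 + ["case"] * 9)
        assert rec.valid is False and np.isnan(rec.r_combined)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            combine_correlation([1, 2, 3, 4], [1, 2, 3, 4],
                                ["control", "control", "case", "case"])

    @given(st.floats(min_value=-5, max_value=5))
    @settings(max_examples=200, deadline=None)
    def test_atanh_tanh_round_trip(self, z):
        assert math.atanh(math.tanh(z)) == pytest.approx(z, abs=1e-12)


class TestSenseAntisense:
    def _norm(self, rng, n_genes=60):
        cols = [f"c{i}" for i in range(8)] + [f"p{i}" for i in range(9)]
        groups = {c: ("control" if c.startswith("c") else "case") for c in cols}
        sense = pd.DataFrame(
            rng.poisson(200, size=(n_genes, 17)),
            index=[f"g{i}" for i in range(n_genes)], columns=cols,
        )
        return sense, groups

    def test_antisense_copy_gives_r_one(self):
        rng = np.random.default_rng(4)
        sense, groups = self._norm(rng)
        frame, summary = sense_antisense_profile(sense, sense.copy(), groups)
        assert summary["mean_r_combined"] == pytest.approx(1.0, abs=1e-9)

    def test_independent_null_mean_near_zero(self):
        rng = np.random.default_rng(5)
        sense, groups = self._norm(rng, n_genes=400)
        anti = pd.DataFrame(
            rng.poisson(50, size=sense.shape), index=sense.index, columns=sense.columns
        )
        frame, summary = sense_antisense_profile(sense, anti, groups)
        # null combined r has SE ~ 1/sqrt(n-3) per pair, averaged over 400 pairs
        mc_se = (1 / math.sqrt(8 - 3) + 1 / math.sqrt(9 - 3)) / 2 / math.sqrt(400)
        assert abs(summary["mean_r_combined"]) < 3 * mc_se

    def test_missing_genes_skipped_with_tally(self):
        rng = np.random.default_rng(6)
        sense, groups = self._norm(rng, n_genes=10)
        anti = sense.iloc[:6].copy()
        frame, summary = sense_antisense_profile(sense, anti, groups)
        assert summary["n_pairs"] + summary["n_invalid"] == 6
        assert summary["n_skipped"] == 4

    def test_injected_correlation_recovered(self):
        """High-depth, Poisson-noise generator run: measured mean combined r
        converges to the injected latent correlation."""
        from strandtx.synthetic import EffectSpec, SimConfig, generate_catalog, simulate_counts
        from strandtx.diffexp import normalize_totals

        cfg = SimConfig(
            seed=31,
            genes_per_class={"coding": 150},
            isoforms_per_coding_gene=(1, 1),
            nb_dispersion=0.0,
            baseline_mean_range=(500.0, 1000.0),
            library_size_cv=0.0,
            latent_sd=1.0,
        )
        catalog, sites = generate_catalog(cfg)
        eff = EffectSpec(sense_antisense_corr=0.2, antisense_fraction=0.5)
        sim, truth = simulate_counts(catalog, cfg, eff, sites=sites)
        norm, _ = normalize_totals(sim.sense)
        gene_sense = norm.copy()
        gene_sense.index = [t[:-2] for t in norm.index]  # single-isoform: drop ".1"
        frame, summary = sense_antisense_profile(gene_sense, sim.antisense, cfg.groups)
        # per-pair SE of combined r is ~0.19; with 150 pairs the mean has SE ~0.016
        assert summary["mean_r_combined"] == pytest.approx(0.2, abs=0.05)


class TestNeighborCorrelation:
    def test_distant_lnc_excluded(self, small_sim):
        cfg, catalog, _, _, _ = small_sim
        pairs = find_neighbor_pairs(catalog, max_distance=100_000)
        lnc_far = [t.transcript_id for t in catalog.by_class("lncRNA")]
        # generator places every 10th lncRNA at 150 kb: never in the pair table
        placed = set(pairs["lnc_id"])
        far = {f"LNC{j+1:04d}" for j in range(len(lnc_far)) if (j + 1) % 10 == 0}
        assert placed.isdisjoint(far)
        assert (pairs["distance"] <= 100_000).all()

    def test_injected_decay_monotone_and_baseline_null(self):
        from strandtx.synthetic import EffectSpec, SimConfig, generate_catalog, simulate_counts
        from strandtx.diffexp import normalize_totals

        cfg = SimConfig(
            seed=33,
            genes_per_class={"coding": 80, "lncRNA": 72},
            isoforms_per_coding_gene=(1, 1),
            nb_dispersion=0.0,
            baseline_mean_range=(500.0, 1000.0),
            library_size_cv=0.0,
            latent_sd=1.0,
        )
        catalog, sites = generate_catalog(cfg)
        eff = EffectSpec(lnc_neighbor_corr=0.6)
        sim, truth = simulate_counts(catalog, cfg, eff, sites=sites)
        norm, _ = normalize_totals(sim.sense)
        coding = [g for g in catalog.gene_ids if catalog.gene_class(g) == "coding"]
        gene_expr = norm.loc[[f"{g}.1" for g in coding]]
        gene_expr.index = coding
        lnc_ids = [t.transcript_id for t in catalog.by_class("lncRNA")]
        binned, baseline, _ = neighbor_correlation(
            catalog, norm.loc[lnc_ids], gene_expr, cfg.groups, seed=1
        )
        up = binned[(binned["position"] == "upstream") & (binned["n"] > 0)]
        means = up.groupby("bin_lo")["mean_r"].mean().sort_index()
        # injected rho decays linearly with distance: allow one SE of slack
        ses = up.groupby("bin_lo")["se_r"].mean().sort_index()
        for i in range(len(means) - 1):
            assert means.iloc[i + 1] <= means.iloc[i] + 2 * ses.iloc[i]
        assert means.iloc[0] > means.iloc[-1]
        assert abs(baseline) < 0.1

    def test_empty_bins_reported_missing(self, small_sim):
        cfg, catalog, _, counts, _ = small_sim
        from strandtx.diffexp import normalize_totals

        norm, _ = normalize_totals(counts.sense)
        coding = [g for g in catalog.gene_ids if catalog.gene_class(g) == "coding"]
        gene_expr = pd.DataFrame(
            {g: norm.loc[[t.transcript_id for t in catalog.transcripts_of_gene(g)]].sum()
             for g in coding}
        ).T
        lnc_ids = [t.transcript_id for t in catalog.by_class("lncRNA")]
        binned, _, _ = neighbor_correlation(
            catalog, norm.loc[lnc_ids], gene_expr, cfg.groups,
            NeighborBinSpec(n_random_pairs=50), seed=2,
        )
        empty = binned[binned["n"] == 0]
        assert len(empty) > 0 and empty["mean_r"].isna().all()


class TestTargetSetShift:
    def test_null_lists_give_uniform_p(self):
        """Target lists drawn from the background give approximately uniform
        p-values (KS check over 200 resamples)."""
        rng = np.random.default_rng(8)
        stat = pd.Series(rng.normal(size=400), index=[f"g{i}" for i in range(400)])
        ps = []
        for i in range(200):
            genes = list(rng.choice(stat.index, size=20, replace=False))
            ps.append(target_set_shift({"l": genes}, stat).loc["l", "p"])
        from scipy import stats as sps

        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_depressed_targets_detected(self):
        rng = np.random.default_rng(9)
        stat = pd.Series(rng.normal(0, 0.1, size=400), index=[f"g{i}" for i in range(400)])
        targets = [f"g{i}" for i in range(30)]
        stat[targets] -= 0.2
        res = target_set_shift({"mir": targets}, stat)
        assert res.loc["mir", "mean"] < res.loc["mir", "background_mean"]
        assert res.loc["mir", "p"] < 0.01

    def test_small_list_flagged_low_power(self):
        stat = pd.Series(np.arange(20.0), index=[f"g{i}" for i in range(20)])
        res = target_set_shift({"l": ["g0", "g1"]}, stat)
        assert bool(res.loc["l", "low_power"]) is True

    def test_empty_background_raises(self):
        stat = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="background"):
            target_set_shift({"l": ["a", "b"]}, stat)
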