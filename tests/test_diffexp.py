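"""Expression filter, loess adjustment, NB exact test, dispersion, BH, class changes."""
import math

import numpy as np
import pandas as pd
import pytest

from strandtx.diffexp import (
    ExpressionFilter,
    bh_fdr,
    class_change,
    de_table,
    estimate_common_dispersion,
    filter_expressed,
    loess_adjust,
    nb_exact_test,
    normalize_totals,
)


def _frame(rows, n_samples=17):
    return pd.DataFrame(
        rows, index=[f"t{i}" for i in range(len(rows))],
        columns=[f"s{j}" for j in range(n_samples)],
    )


class TestExpressionFilter:
    def test_three_reads_in_three_samples_retained(self):
        counts = _frame([[3, 3, 3] + [0] * 14])
        assert list(filter_expressed(counts)) == ["t0"]

    def test_per_sample_threshold_unmet(self):
        counts = _frame([[2] * 17])
        assert list(filter_expressed(counts)) == []

    def test_sample_breadth_unmet(self):
        counts = _frame([[100, 0, 0] + [0] * 14])
        assert list(filter_expressed(counts)) == []


class TestLoessAdjust:
    def test_null_trend_is_small(self):
        rng = np.random.default_rng(0)
        baseline = pd.Series(rng.uniform(1, 3, 2000))
        lfc = pd.Series(rng.normal(0, 0.3, 2000))
        adjusted, trend = loess_adjust(lfc, baseline)
        # nothing to remove: the fitted trend stays within Monte-Carlo noise
        mc_se = 0.3 / math.sqrt(2000 * 0.25)  # rough per-window SE
        assert trend.abs().max() < 3 * mc_se * 3

    def test_constant_offset_centred_to_zero(self):
        rng = np.random.default_rng(1)
        baseline = pd.Series(rng.uniform(1, 3, 500))
        lfc = pd.Series(np.full(500, 0.7) + rng.normal(0, 0.01, 500))
        adjusted, _ = loess_adjust(lfc, baseline)
        assert abs(adjusted.mean()) < 0.01

    def test_injected_slope_removed(self):
        rng = np.random.default_rng(2)
        baseline = pd.Series(rng.uniform(1, 3, 3000))
        lfc = pd.Series(0.2 * baseline.values + rng.normal(0, 0.3, 3000))
        r_before = np.corrcoef(lfc, baseline)[0, 1]
        adjusted, _ = loess_adjust(lfc, baseline)
        r_after = np.corrcoef(adjusted, baseline)[0, 1]
        assert r_before > 0.2
        assert abs(r_after) < 0.02  # independently recomputed correlation

    def test_too_few_ids_raises(self):
        with pytest.raises(ValueError, match=">= 50"):
            loess_adjust(pd.Series([0.1] * 10), pd.Series([1.0] * 10))


class TestNbExactTest:
    def test_extreme_split_phi_zero(self):
        # binomial enumeration oracle: p = 2 * (1/2)^10
        assert nb_exact_test([0], [10], 0.0) == pytest.approx(2 * 0.5**10, abs=1e-15)

    def test_identical_totals_give_p_one(self):
        assert nb_exact_test([5, 5], [5, 5], 0.0) == 1.0
        assert nb_exact_test([5, 5], [5, 5], 0.3) == 1.0

    def test_all_zero_convention(self):
        assert nb_exact_test([0, 0], [0, 0], 0.1) == 1.0

    @pytest.mark.parametrize(
        "a,b,phi,expected",
        [
            # independent oracle: edgeR 4.0.16 exactTest(rejection.region="smallp"),
            # equal library sizes, computed one gene at a time via Rscript
            ([12, 18, 9, 30], [25, 40, 33], 0.1, 0.0249093000089),
            ([5, 3, 7, 2], [60, 80, 70], 0.1, 8.64993943116e-18),
            ([0, 0], [4, 6], 0.2, 0.00922395944885),
            ([10, 12, 8], [11, 9, 10, 12], 0.05, 0.923205454804),
        ],
    )
    def test_matches_edgeR_smallp(self, a, b, phi, expected):
        assert nb_exact_test(a, b, phi) == pytest.approx(expected, rel=1e-9)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test([1], [2], -0.1)

    def test_power_monotone_in_effect_size(self):
        """Larger injected fold changes give smaller p at fixed phi and depth."""
        rng = np.random.default_rng(3)
        phi, mu, n = 0.1, 100, 8
        med_ps = []
        for lfc in (0.5, 1.0, 2.0):
            ps = []
            for _ in range(200):
                a = rng.poisson(rng.gamma(1 / phi, phi * mu, n))
                b = rng.poisson(rng.gamma(1 / phi, phi * mu * 2**lfc, n))
                ps.append(nb_exact_test(a, b, phi))
            med_ps.append(np.median(ps))
        assert med_ps[0] > med_ps[1] > med_ps[2]


class TestDispersionEstimate:
    def _nb_counts(self, rng, phi, mu, shape):
        if phi == 0:
            return rng.poisson(mu, size=shape)
        return rng.poisson(rng.gamma(1 / phi, phi * mu, size=shape))

    def _frame(self, rng, phi, n_t=2000):
        counts = np.hstack(
            [self._nb_counts(rng, phi, 100, (n_t, 8)), self._nb_counts(rng, phi, 100, (n_t, 9))]
        )
        cols = [f"c{i}" for i in range(8)] + [f"p{i}" for i in range(9)]
        return pd.DataFrame(counts, columns=cols), {
            c: ("control" if c.startswith("c") else "case") for c in cols
        }

    def test_poisson_data_gives_near_zero(self):
        rng = np.random.default_rng(4)
        counts, groups = self._frame(rng, 0.0)
        assert estimate_common_dispersion(counts, groups) < 0.01

    def test_recovers_known_dispersion(self):
        rng = np.random.default_rng(5)
        estimates = []
        for _ in range(10):
            counts, groups = self._frame(rng, 0.2)
            estimates.append(estimate_common_dispersion(counts, groups))
        assert 0.15 <= np.median(estimates) <= 0.25

    def test_invariant_to_transcript_order(self):
        rng = np.random.default_rng(6)
        counts, groups = self._frame(rng, 0.1, n_t=300)
        shuffled = counts.sample(frac=1, random_state=1)
        assert estimate_common_dispersion(counts, groups) == pytest.approx(
            estimate_common_dispersion(shuffled, groups)
        )

    def test_single_sample_group_raises(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        groups = {"a": "control", "b": "case", "c": "case"}
        with pytest.raises(ValueError, match="phi"):
            estimate_common_dispersion(counts, groups)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_step_up(self):
        # q_i = p_i * m / i, then cumulative minimum from the largest rank
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        assert bh_fdr(p[perm]) == pytest.approx(bh_fdr(p)[perm])


class TestClassChange:
    def test_percent_change_arithmetic(self, small_sim):
        cfg, catalog, _, counts, _ = small_sim
        norm, _ = normalize_totals(counts.sense)
        cc = class_change(norm, catalog, "coding", cfg.groups)
        members = [t.transcript_id for t in catalog.by_class("coding")]
        ctrl = [s for s in norm.columns if cfg.groups[s] == "control"]
        case = [s for s in norm.columns if cfg.groups[s] == "case"]
        expected = (norm.loc[members, case].values.sum() / len(case)) / (
            norm.loc[members, ctrl].values.sum() / len(ctrl)
        ) - 1
        assert cc.percent_change == pytest.approx(expected)

    def test_empty_class_raises(self, small_sim):
        cfg, catalog, _, counts, _ = small_sim
        norm, _ = normalize_totals(counts.sense)
        with pytest.raises(ValueError, match="smallRNA:scaRNA"):
            class_change(norm, catalog, "smallRNA:scaRNA", cfg.groups)


class TestDeTable:
    def test_per_gene_log2fc_definition(self):
        """log2fc = 2 injected on one transcript -> observed group ratio near 4."""
        from strandtx.synthetic import EffectSpec, SimConfig, generate_catalog, simulate_counts

        cfg = SimConfig(
            seed=13,
            genes_per_class={"novel_locus": 300},
            nb_dispersion=0.05,
            baseline_mean_range=(100.0, 200.0),
            library_size_cv=0.0,
        )
        catalog, _ = generate_catalog(cfg)
        gene = catalog.gene_ids[0]
        sim, _ = simulate_counts(catalog, cfg, EffectSpec(per_gene_de=[(gene, 2.0)]))
        tab = de_table(sim.sense, cfg.groups, adjust=False)
        ratio = tab.loc[f"{gene}", "mean_case"] / tab.loc[f"{gene}", "mean_control"]
        assert 3.0 < ratio < 5.3
        assert tab.loc[gene, "q"] < 0.05
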