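"""Generator contracts: determinism, planted bookkeeping, sampling laws."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from braincyto.config import ConfigurationError, SimulationConfig
from braincyto.simulate import (
    _draw_fractions,
    dirichlet_proportions,
    simulate_bulk_cohort,
    simulate_mixtures,
    simulate_perturbagens,
    simulate_reference,
)


class TestReference:
    def test_fixed_seed_gives_identical_matrices(self):
        cfg = SimulationConfig(n_genes=200, n_cells_per_type=20, seed=42)
        a = simulate_reference(cfg)
        b = simulate_reference(cfg)
        np.testing.assert_array_equal(a.counts, b.counts)
        np.testing.assert_array_equal(a.cell_type, b.cell_type)

    def test_mislabeled_cells_are_exactly_as_planted(self):
        cfg = SimulationConfig(
            n_genes=150, n_cells_per_type=25, n_mislabeled_cells=3, seed=5
        )
        ref = simulate_reference(cfg)
        assert (ref.true_type != ref.cell_type).sum() == 3

    def test_type_means_converge_to_baseline_in_noiseless_limit(self):
        """With dispersion 0 and fixed library scale, per-type sample means
        track the generating rates to within 5% at n=2000 cells."""
        cfg = SimulationConfig(
            n_genes=100, n_cells_per_type=2000, sc_dispersion=0.0, seed=3,
            frac_mito_genes=0.0,
        )
        ref = simulate_reference(cfg, library_sigma=0.0)
        rates = cfg.base_rates()
        content = cfg.content_vector()
        for j, t in enumerate(cfg.cell_types):
            mu = rates[:, j] * cfg.sc_mean_library * content[j] / rates[:, j].sum()
            observed = ref.counts[:, ref.cell_type == t].mean(axis=1)
            big = mu >= 5  # relative tolerance is meaningless for near-zero means
            rel = np.abs(observed[big] - mu[big]) / mu[big]
            assert rel.max() < 0.05

    def test_degenerate_cells_have_tiny_libraries_and_high_mito(self):
        cfg = SimulationConfig(
            n_genes=300, n_cells_per_type=40, frac_degenerate_cells=0.05, seed=9
        )
        ref = simulate_reference(cfg)
        lib = ref.counts.sum(axis=0)
        mito = ref.counts[ref.mito_flag].sum(axis=0) / np.maximum(lib, 1)
        bad = ref.degenerate
        assert bad.sum() == round(0.05 * ref.n_cells)
        assert lib[bad].max() < lib[~bad].min()
        assert mito[bad].min() > mito[~bad].max()

    def test_invalid_dimensions_raise_configuration_error(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_genes=0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_cells_per_type=0)


class TestBulkCohort:
    def test_fixed_seed_reproducible_and_truth_attached(self, small_config, small_reference):
        a = simulate_bulk_cohort(small_config, small_reference, "ad")
        b = simulate_bulk_cohort(small_config, small_reference, "ad_discovery")
        np.testing.assert_array_equal(a.values, b.values)
        assert a.truth is not None
        assert set(a.truth["effect_class"]) <= {
            "systemic", "composition_driven", "interaction", "covariate_only", "null"
        }

    def test_unknown_disease_kind_raises(self, small_config, small_reference):
        with pytest.raises(ConfigurationError):
            simulate_bulk_cohort(small_config, small_reference, "huntington")

    def test_null_gene_has_zero_planted_disease_coefficient(self, small_config, small_reference):
        cohort = simulate_bulk_cohort(small_config, small_reference, "ad")
        nulls = cohort.truth[cohort.truth["effect_class"] == "null"]
        assert (nulls["disease_lfc"] == 0).all()
        assert (nulls["interaction_lfc"] == 0).all()

    def test_systemic_gene_doubles_expected_expression_at_equal_composition(self):
        """A +1 log2 systemic effect forces a diseased/control expected-CPM
        ratio of 2 once composition is held fixed (expected matrix, no noise)."""
        cfg = SimulationConfig(n_genes=400, n_cells_per_type=30, seed=21)
        ref = simulate_reference(cfg)
        cohort = simulate_bulk_cohort(cfg, ref, "pd")  # equal-composition arms
        truth = cohort.truth
        up = truth.index[(truth["effect_class"] == "systemic") & (truth["sign"] > 0)]
        gi = [list(cohort.gene_names).index(g) for g in up]
        disease = cohort.metadata["disease"].to_numpy() == 1
        fr = cohort.true_fractions.to_numpy()
        # pick the diseased/control pair with the most similar composition
        d_idx = np.flatnonzero(disease)
        c_idx = np.flatnonzero(~disease)
        dists = ((fr[d_idx][:, None, :] - fr[c_idx][None, :, :]) ** 2).sum(axis=2)
        i, j = np.unravel_index(dists.argmin(), dists.shape)
        # renormalize away the per-sample CPM denominator before comparing
        exp = cohort.expected
        base = exp[truth["effect_class"].to_numpy() == "null"].sum(axis=0)
        ratio = (exp[gi, d_idx[i]] / base[d_idx[i]]) / (exp[gi, c_idx[j]] / base[c_idx[j]])
        assert np.allclose(ratio, 2.0, rtol=0.06)

    def test_ad_arms_have_shifted_neuronal_fractions(self, small_config):
        """Empirical means of 1e4 Dirichlet draws match the configured
        0.60-vs-0.70 neuronal means within Monte-Carlo error."""
        design = small_config.cohorts["ad_discovery"]
        rng = np.random.default_rng(0)
        dis = _draw_fractions(rng, design, small_config, True, 10_000)
        ctl = _draw_fractions(rng, design, small_config, False, 10_000)
        j = list(small_config.cell_types).index("neuron")
        mc = 3 * dis[:, j].std() / 100.0
        assert abs(dis[:, j].mean() - 0.60) < mc
        assert abs(ctl[:, j].mean() - 0.70) < mc
        assert dis[:, j].mean() < ctl[:, j].mean()

    def test_fraction_rows_live_on_the_simplex(self, small_config, small_reference):
        for kind in ("ad", "pd", "pd_validation"):
            cohort = simulate_bulk_cohort(small_config, small_reference, kind)
            fr = cohort.true_fractions.to_numpy()
            assert (fr >= 0).all()
            np.testing.assert_allclose(fr.sum(axis=1), 1.0, atol=1e-12)


class TestMixtures:
    def test_counts_conserve_depth_exactly(self, small_reference):
        P = dirichlet_proportions(10, small_reference.cell_types, seed=1)
        mix = simulate_mixtures(small_reference, P, depth=50_000, seed=2)
        np.testing.assert_array_equal(mix.values.sum(axis=0), 50_000)

    def test_pure_neuron_mixture_matches_pool_profile(self, small_reference):
        P = np.array([[0.0, 0.0, 1.0, 0.0]])
        mix = simulate_mixtures(small_reference, P, depth=1_000_000, seed=3)
        pool = small_reference.counts[:, small_reference.cell_type == "neuron"].sum(axis=1)
        freq = pool / pool.sum()
        expected = freq * 1_000_000
        keep = expected >= 10  # chi-square validity
        chi2 = ((mix.values[keep, 0] - expected[keep]) ** 2 / expected[keep]).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01

    def test_scaled_depth_preserves_expected_gene_shares(self, small_reference):
        """300 mixtures at the scaled-down depth keep per-gene expected
        shares within 2% of the analytic pool expectation."""
        P = dirichlet_proportions(300, small_reference.cell_types, seed=4)
        mix = simulate_mixtures(small_reference, P, depth=350_000, seed=5)
        pools = np.stack(
            [
                small_reference.counts[:, small_reference.cell_type == t].sum(axis=1)
                for t in small_reference.cell_types
            ],
            axis=1,
        ).astype(float)
        freq = pools / pools.sum(axis=0)
        expected = (freq @ P.T) * 350_000  # genes x mixtures
        tot_obs = mix.values.sum(axis=1)
        tot_exp = expected.sum(axis=1)
        big = tot_exp > 300 * 100
        rel = np.abs(tot_obs[big] - tot_exp[big]) / tot_exp[big]
        assert rel.max() < 0.02

    def test_bad_proportion_rows_raise(self, small_reference):
        with pytest.raises(ValueError):
            simulate_mixtures(small_reference, np.array([[0.5, 0.5, 0.5, 0.0]]), 1000)
        with pytest.raises(ValueError):
            simulate_mixtures(small_reference, np.array([[0.25] * 4]), 0)


class TestPerturbagens:
    def _scores(self, n=500, seed=0):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"G{i:04d}" for i in range(n)])
        return (
            pd.Series(rng.normal(size=n), index=idx),
            pd.Series(rng.normal(size=n), index=idx),
        )

    def test_zero_noise_reverser_is_exact_anti_rank(self):
        cfg = SimulationConfig(seed=31)
        cfg.perturbagens.noise_sd = 0.0
        d, n = self._scores()
        panel = simulate_perturbagens(cfg, d, n)
        rev = next(c for c, r in panel.planted_roles.items() if r == "reverser")
        col = panel.conditions.index[panel.conditions["compound"] == rev][0]
        rho = stats.spearmanr(panel.zscores[col], d).statistic
        assert rho == pytest.approx(-1.0)

    def test_neutral_compounds_are_uncorrelated_at_large_n(self):
        cfg = SimulationConfig(seed=32)
        cfg.perturbagens.n_compounds = 30
        cfg.perturbagens.n_cell_lines = 1
        d, n = self._scores(n=10_000, seed=1)
        panel = simulate_perturbagens(cfg, d, n)
        neutral = [c for c, r in panel.planted_roles.items() if r == "neutral"]
        cols = panel.conditions.index[panel.conditions["compound"].isin(neutral)]
        rhos = [stats.spearmanr(panel.zscores[c], d).statistic for c in cols]
        # null rho has SD ~ 1e-2 at n = 1e4: 0.05 is a 5-sigma bound
        assert np.max(np.abs(rhos)) < 0.05

    def test_cell_line_replication_shares_compound_id(self):
        cfg = SimulationConfig(seed=33)
        cfg.perturbagens.n_cell_lines = 3
        d, n = self._scores()
        panel = simulate_perturbagens(cfg, d, n)
        counts = panel.conditions.groupby("compound").size()
        assert (counts == 3).all()
        one = panel.conditions[panel.conditions["compound"] == counts.index[0]]
        assert one["cell_line"].nunique() == 3

    def test_too_few_genes_rejected(self):
        cfg = SimulationConfig(seed=34)
        d = pd.Series(np.arange(50, dtype=float))
        with pytest.raises(ValueError):
            simulate_perturbagens(cfg, d, d)
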