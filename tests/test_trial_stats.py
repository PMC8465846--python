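import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heterowheat.trial_stats import (TrialStatsError, VarianceComponents,
                                     estimate_variance_components, fit_blues,
                                     heritability,
                                     variance_components_moments)


def _design(genos, blocks, values, location="L1"):
    """Build (traits_long, plots) for a single-trait layout."""
    traits, plots = [], []
    for i, (g, b, v) in enumerate(zip(genos, blocks, values)):
        pid = f"{location}-{i:03d}"
        plots.append({"plot_id": pid, "location": location, "block": b,
                      "genotype_id": g})
        traits.append({"unit": pid, "location": location, "trait": "YLD",
                       "value": v, "level": "plot"})
    return pd.DataFrame(traits), pd.DataFrame(plots)


class TestBlues:
    def test_balanced_design_equals_raw_means(self, rng):
        genos = [f"G{i}" for i in range(4)] * 3
        blocks = [b for b in (1, 2, 3) for _ in range(4)]
        vals = rng.normal(10, 1, 12)
        traits, plots = _design(genos, blocks, vals)
        blues = fit_blues(traits, plots, scope="single_location")
        raw = pd.Series(vals, index=genos).groupby(level=0).mean()
        for row in blues.itertuples():
            assert row.value == pytest.approx(raw[row.unit], abs=1e-9)

    def test_augmented_recovers_truth_with_block_effects(self):
        """Noiseless augmented layout with additive block effects: adjusted
        means return the true genotype values exactly."""
        true = {"CHK": 10.0, "A": 11.0, "B": 9.0, "C": 12.0, "D": 8.5}
        beff = {1: 0.7, 2: -0.4, 3: 1.1}
        genos, blocks, vals = [], [], []
        layout = {1: ["CHK", "A", "B"], 2: ["CHK", "C"], 3: ["CHK", "D"]}
        for b, gs in layout.items():
            for g in gs:
                genos.append(g)
                blocks.append(b)
                vals.append(true[g] + beff[b])
        traits, plots = _design(genos, blocks, vals)
        blues = fit_blues(traits, plots, scope="single_location")
        est = {r.unit: r.value for r in blues.itertuples()}
        # adjusted means are defined up to the marginal block average; genotype
        # differences are what the design identifies
        for a in true:
            for b in true:
                assert est[a] - est[b] == pytest.approx(true[a] - true[b],
                                                        abs=1e-8)

    def test_single_genotype_single_block(self):
        traits, plots = _design(["G1"], [1], [7.25])
        blues = fit_blues(traits, plots, scope="single_location")
        assert blues["value"].iloc[0] == pytest.approx(7.25)

    def test_confounded_design_rejected(self):
        # two genotypes fully aliased with their blocks
        traits, plots = _design(["A", "A", "B", "B"], [1, 1, 2, 2],
                                [1.0, 1.1, 2.0, 2.2])
        with pytest.raises(TrialStatsError, match="alias"):
            fit_blues(traits, plots, scope="single_location")

    def test_block_shift_equivariance(self, rng):
        """Adding a constant to every observation in one block leaves all
        genotype contrasts unchanged."""
        genos = [f"G{i}" for i in range(5)] * 2 + ["G0", "G1"]
        blocks = [1] * 5 + [2] * 5 + [3, 3]
        vals = rng.normal(10, 1, 12)
        traits, plots = _design(genos, blocks, list(vals))
        b1 = fit_blues(traits, plots, scope="single_location")
        shifted = traits.copy()
        in_b2 = [p["plot_id"] for p in plots.to_dict("records")
                 if p["block"] == 2]
        shifted.loc[shifted["unit"].isin(in_b2), "value"] += 5.0
        b2 = fit_blues(shifted, plots, scope="single_location")
        v1 = b1.set_index("unit")["value"]
        v2 = b2.set_index("unit")["value"]
        d1 = v1 - v1["G0"]
        d2 = v2 - v2["G0"]
        pd.testing.assert_series_equal(d1, d2, atol=1e-8, rtol=0)

    def test_combined_scope_requires_two_locations(self):
        traits, plots = _design(["A", "B"], [1, 1], [1.0, 2.0])
        with pytest.raises(TrialStatsError):
            fit_blues(traits, plots, scope="combined")


class TestVarianceComponents:
    def test_moments_oracle_agrees_with_reml_balanced(self, rng):
        genos = [f"G{i}" for i in range(25) for _ in range(3)]
        blocks = [1, 2, 3] * 25
        truth_g = dict(zip([f"G{i}" for i in range(25)],
                           rng.normal(0, 1.0, 25)))
        vals = [10 + truth_g[g] + rng.normal(0, 0.7) for g in genos]
        traits, plots = _design(genos, blocks, vals)
        df = traits.merge(plots, left_on="unit", right_on="plot_id")
        mom = variance_components_moments(
            df[["genotype_id", "value"]].assign(value=df["value"]))
        reml = estimate_variance_components(traits, plots, "YLD",
                                            scope="single_location")
        # same data, two estimators: they should agree within estimator noise
        assert reml.sigma2_g == pytest.approx(mom.sigma2_g, abs=0.35)
        assert reml.sigma2_res == pytest.approx(mom.sigma2_res, abs=0.2)

    def test_zero_noise_limit(self):
        genos = [f"G{i}" for i in range(10) for _ in range(2)]
        blocks = [1, 2] * 10
        gvals = np.linspace(8, 12, 10)
        vals = [gvals[int(g[1:])] for g in genos]
        traits, plots = _design(genos, blocks, vals)
        vc = estimate_variance_components(traits, plots, "YLD",
                                          scope="single_location")
        assert vc.sigma2_res == pytest.approx(0.0, abs=1e-6)
        assert vc.sigma2_g == pytest.approx(np.var(gvals, ddof=1), rel=0.15)

    def test_constant_observations(self):
        traits, plots = _design(["A", "B", "A", "B"], [1, 1, 2, 2],
                                [5.0, 5.0, 5.0, 5.0])
        vc = estimate_variance_components(traits, plots, "YLD",
                                          scope="single_location")
        assert vc.sigma2_g == 0.0 and vc.sigma2_res == 0.0


class TestHeritability:
    def test_no_residual_gives_one(self):
        vc = VarianceComponents(1.0, np.nan, 0.0, 3.0, 1)
        assert heritability(vc, scope="single_location").h2 == 1.0

    def test_combined_arithmetic(self):
        vc = VarianceComponents(1.0, 1.0, 1.0, 2.0, 3)
        est = heritability(vc, scope="combined")
        assert est.h2 == pytest.approx(1 / (1 + 1 / 3 + 1 / 6), rel=1e-12)

    def test_zero_genetic_variance(self):
        vc = VarianceComponents(0.0, np.nan, 1.0, 2.0, 1)
        assert heritability(vc, scope="single_location").h2 == 0.0

    @given(st.floats(0.01, 50), st.floats(0.0, 50), st.floats(1.0, 20))
    @settings(max_examples=100, deadline=None)
    def test_single_site_is_combined_specialisation(self, s2g, s2r, n_bar):
        """The one-site formula is the combined formula at l=1 without GxL."""
        single = heritability(
            VarianceComponents(s2g, np.nan, s2r, n_bar, 1),
            scope="single_location").h2
        combined = heritability(
            VarianceComponents(s2g, 0.0, s2r, n_bar, 1),
            scope="combined").h2
        assert single == pytest.approx(combined, rel=1e-12)

    @given(st.floats(0.1, 20), st.floats(0.1, 20), st.floats(1.0, 10))
    @settings(max_examples=100, deadline=None)
    def test_monotonicity(self, s2g, s2r, n_bar):
        base = heritability(VarianceComponents(s2g, np.nan, s2r, n_bar, 1),
                            scope="single_location").h2
        more_g = heritability(VarianceComponents(s2g * 1.5, np.nan, s2r,
                                                 n_bar, 1),
                              scope="single_location").h2
        more_r = heritability(VarianceComponents(s2g, np.nan, s2r * 1.5,
                                                 n_bar, 1),
                              scope="single_location").h2
        more_n = heritability(VarianceComponents(s2g, np.nan, s2r,
                                                 n_bar * 1.5, 1),
                              scope="single_location").h2
        assert more_g >= base >= more_r
        assert more_n >= base

    def test_consistency_with_components(self):
        vc = VarianceComponents(2.0, 0.5, 1.0, 1.2, 3)
        est = heritability(vc, scope="combined")
        denom = vc.sigma2_g + vc.sigma2_gxl / vc.l + vc.sigma2_res / (
            vc.n_bar * vc.l)
        assert est.h2 * denom == pytest.approx(vc.sigma2_g, rel=1e-12)


class TestStudyShapedRecovery:
    def test_combined_reml_recovers_known_components(self):
        """Three-site augmented trial with known variance components: the
        REML estimates land near the truth (tight check lives in the
        acceptance suite at 200 replicates)."""
        from heterowheat.simulate import (DEFAULT_SITES, SimulationConfig,
                                          TraitArchitecture, simulate_panel,
                                          simulate_trial)
        h2s, g_, r_ = [], [], []
        arch = TraitArchitecture(10.0, 1.0, 0.0, 0.5, 1.0)
        for seed in range(5):
            cfg = SimulationConfig(seed=seed)
            cfg.traits = dict(cfg.traits)
            cfg.traits["YLD"] = arch
            panel, ped, truth = simulate_panel(cfg)
            plots, traits, _ = simulate_trial(cfg, panel, truth, DEFAULT_SITES)
            plots_df = pd.DataFrame([{"plot_id": p.plot_id,
                                      "location": p.location,
                                      "block": p.block,
                                      "genotype_id": p.genotype_id}
                                     for p in plots])
            vc = estimate_variance_components(traits.frame, plots_df, "YLD",
                                              scope="combined")
            g_.append(vc.sigma2_g)
            r_.append(vc.sigma2_res)
            h2s.append(heritability(vc, scope="combined").h2)
        # truth: s2g ~ 1 among parents (hybrids shrink the panel average a bit)
        assert 0.5 < np.mean(g_) < 1.3
        assert 0.7 < np.mean(r_) < 1.4
        assert 0.4 < np.mean(h2s) < 0.95
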