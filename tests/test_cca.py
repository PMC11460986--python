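"""Joint predator analysis: decomposition identity, canonical correlation
against the multiple-regression oracle, Wilks' chain, margins and the
competition gap."""

import dataclasses
import math

import numpy as np
import pytest
import statsmodels.api as sm

import predprey as pp
from predprey.cca import PredatorDecomposition


def _records_from_logs(lt, lr, lx):
    """Build biomass records whose decomposition equals the given log10
    columns (T = 10^lt, total = 10^(lt+lr))."""
    out = []
    for i, (a, b, c) in enumerate(zip(lt, lr, lx)):
        T = 10.0**a
        total = 10.0 ** (a + b)
        out.append(pp.ParkYearBiomass(park=f"p{i}", year=2022, T=T, L=total - T, x=10.0**c))
    return out


def _random_decomp(seed, n=15):
    rng = np.random.default_rng(seed)
    lx = rng.uniform(2, 3.7, n)
    lt = -1.8 + 0.9 * lx + rng.normal(0, 0.3, n)
    lr = np.abs(rng.normal(0.15, 0.08, n)) + 0.01
    return pp.decompose_predators(_records_from_logs(lt, lr, lx))


class TestDecomposition:
    def test_identity_exact(self, synthetic_biomass):
        d = pp.decompose_predators(synthetic_biomass)
        total = np.log10([r.predator_total for r in synthetic_biomass])
        np.testing.assert_allclose(d.log_tiger + d.log_ratio, total, rtol=0, atol=1e-12)
        assert np.all(d.log_ratio >= 0)

    def test_equal_biomass_gives_log2(self):
        (r,) = [pp.ParkYearBiomass(park="p", year=1, T=3.3, L=3.3, x=100.0)]
        d = pp.decompose_predators([r])
        assert d.log_ratio[0] == pytest.approx(math.log10(2.0), abs=1e-12)

    def test_no_leopard_gives_zero_ratio(self):
        d = pp.decompose_predators([pp.ParkYearBiomass(park="p", year=1, T=5.0, L=0.0, x=100.0)])
        assert d.log_ratio[0] == 0.0

    def test_worked_example(self):
        d = pp.decompose_predators(
            [pp.ParkYearBiomass(park="CNP", year=2022, T=7.308, L=2.1, x=5442.9)]
        )
        assert d.log_tiger[0] == pytest.approx(0.8638, abs=1e-4)
        assert d.log_ratio[0] == pytest.approx(0.1097, abs=1e-4)
        assert d.log_tiger[0] + d.log_ratio[0] == pytest.approx(0.9735, abs=1e-4)

    def test_zero_tiger_rejected(self):
        with pytest.raises(ValueError, match=r"\(p0, 2022\)"):
            pp.decompose_predators([pp.ParkYearBiomass(park="p0", year=2022, T=0.0, L=1.0, x=10.0)])

    def test_leopard_missing_excluded_with_warning(self, synthetic_biomass):
        records = list(synthetic_biomass)
        records[0] = dataclasses.replace(records[0], leopard_missing=True)
        with pytest.warns(UserWarning, match="excluded from the joint analysis"):
            d = pp.decompose_predators(records)
        assert d.n == len(records) - 1


class TestFitCCA:
    def test_rho_equals_multiple_correlation_oracle(self):
        """For q = 1 the canonical correlation must equal sqrt(R^2) of the
        regression of log prey on the two predator components."""
        for seed in (1, 2, 3, 4):
            d = _random_decomp(seed)
            fit = pp.fit_cca(d)
            Z = sm.add_constant(np.column_stack([d.log_tiger, d.log_ratio]))
            r2 = sm.OLS(d.log_prey, Z).fit().rsquared
            assert fit.rho == pytest.approx(math.sqrt(r2), abs=1e-10)

    def test_exact_linear_combination_gives_rho_one(self, rng):
        lt = rng.uniform(0, 1, 12)
        lr = np.abs(rng.uniform(0.05, 0.3, 12))
        lx = 0.4 * lt + 1.1 * lr + 2.0
        d = pp.decompose_predators(_records_from_logs(lt, lr, lx))
        assert pp.fit_cca(d).rho == pytest.approx(1.0, abs=1e-8)

    def test_rho_invariant_to_affine_rescaling(self):
        d = _random_decomp(6)
        fit = pp.fit_cca(d)
        d2 = PredatorDecomposition(
            log_tiger=3.0 * d.log_tiger - 1.0,
            log_ratio=0.5 * d.log_ratio + 2.0,
            log_prey=2.0 * d.log_prey + 0.3,
            parks=d.parks, years=d.years,
        )
        assert pp.fit_cca(d2).rho == pytest.approx(fit.rho, abs=1e-10)

    def test_predator_variate_sd_matches_prey_variate_sd(self):
        """Matched-sd normalization: sd(alpha1*logT + alpha2*logRatio) equals
        sd(k*logx)."""
        d = _random_decomp(8)
        fit = pp.fit_cca(d)
        variate = fit.alpha1 * d.log_tiger + fit.alpha2 * d.log_ratio
        assert np.std(variate, ddof=1) == pytest.approx(
            abs(fit.k) * np.std(d.log_prey, ddof=1), rel=1e-10
        )

    def test_regression_correlation_identity(self):
        """rho = beta * sd(x) / sd(y) for the regression of the predator
        variate on the prey variate."""
        d = _random_decomp(9)
        fit = pp.fit_cca(d)
        y = fit.alpha1 * d.log_tiger + fit.alpha2 * d.log_ratio
        x = fit.k * d.log_prey
        beta = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert fit.rho == pytest.approx(beta * np.std(x, ddof=1) / np.std(y, ddof=1), abs=1e-10)

    def test_collinear_components_raise(self, rng):
        lt = rng.uniform(0.2, 1, 10)
        d = pp.decompose_predators(_records_from_logs(lt, 0.5 * lt, rng.uniform(2, 3, 10)))
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            pp.fit_cca(d)

    def test_too_few_observations_raise(self):
        d = _random_decomp(10)
        small = PredatorDecomposition(
            log_tiger=d.log_tiger[:3], log_ratio=d.log_ratio[:3], log_prey=d.log_prey[:3],
            parks=d.parks[:3], years=d.years[:3],
        )
        with pytest.raises(ValueError, match="more than 3"):
            pp.fit_cca(small)


def _printed_cca(n=15):
    """CCAFit assembled from the study's printed coefficients, used for the
    algebraic margin checks."""
    return pp.CCAFit(
        alpha1=0.83, alpha2=0.93, rho=0.81, k=0.71, n=n,
        mean_log_tiger=0.5, mean_log_ratio=0.2, mean_log_prey=3.5,
        sd_log_prey=0.4, log_prey_range=(3.0, 3.9),
    )


class TestWilks:
    def test_null_case(self):
        w = pp.wilks_test(0.0, 15)
        assert (w.lambda_, w.chisq, w.pvalue) == (1.0, 0.0, 1.0)

    def test_hand_computed_case(self):
        w = pp.wilks_test(0.5, 20)
        assert w.lambda_ == pytest.approx(0.75)
        assert w.chisq == pytest.approx(4.8906, abs=1e-3)
        assert w.df == 2
        assert w.pvalue == pytest.approx(0.0867, abs=1e-3)

    def test_perfect_correlation(self):
        w = pp.wilks_test(1.0, 15)
        assert math.isinf(w.chisq) and w.pvalue == 0.0

    def test_validation(self):
        with pytest.raises(ValueError, match="too small"):
            pp.wilks_test(0.5, 4)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            pp.wilks_test(1.2, 15)


class TestScaledRelationship:
    def test_identity_line_when_rho_k_one_and_zero_means(self):
        cca = pp.CCAFit(alpha1=1.0, alpha2=1.0, rho=1.0, k=1.0, n=10,
                        mean_log_tiger=0.0, mean_log_ratio=0.0, mean_log_prey=0.0,
                        sd_log_prey=1.0, log_prey_range=(-1, 1))
        rel = pp.scaled_relationship(cca)
        assert rel.slope == 1.0 and rel.intercept == 0.0

    def test_printed_slope_product(self):
        rel = pp.scaled_relationship(_printed_cca())
        assert rel.slope == pytest.approx(0.575, abs=1e-3)

    def test_mismatched_observation_sets_rejected(self, synthetic_biomass, small_mcmc):
        d = pp.decompose_predators(synthetic_biomass)
        cca = pp.fit_cca(d)
        other = pp.fit_power_law(
            [r.x for r in synthetic_biomass[:10]],
            [r.predator_total for r in synthetic_biomass[:10]], mcmc=small_mcmc,
        )
        with pytest.raises(ValueError, match="different observation sets"):
            pp.scaled_relationship(cca, other)


class TestMargins:
    def test_printed_values_reproduce_study_margins(self):
        m = pp.margins(_printed_cca())
        assert m.tiger_slope == pytest.approx(0.6929, abs=5e-4)
        assert m.leopard_slope == pytest.approx(0.6184, abs=5e-4)

    def test_forced_identity_slope_one(self):
        cca = dataclasses.replace(_printed_cca(), alpha1=0.81 * 0.71)
        assert pp.margins(cca).tiger_slope == pytest.approx(1.0)

    def test_zero_coefficient_reported_undefined(self):
        cca = dataclasses.replace(_printed_cca(), alpha2=0.0)
        m = pp.margins(cca)
        assert math.isnan(m.leopard_slope)
        assert any("alpha2" in note for note in m.notes)

    def test_margin_lines_anchored_at_sample_means(self):
        """With logRatio at zero the tiger margin line passes through the
        point implied by the centering constants."""
        d = _random_decomp(12)
        cca = pp.fit_cca(d)
        m = pp.margins(cca)
        at_mean = m.predict_log_tiger(np.array([cca.mean_log_prey]))[0]
        expected = (cca.predator_variate_mean
                    - cca.alpha2 * 0.0) / cca.alpha1  # variate mean with logRatio = 0
        assert at_mean == pytest.approx(expected, abs=1e-12)

    def test_tiger_margin_matches_single_species_slope_when_leopard_negligible(self):
        """With a tiny, prey-independent leopard share the tiger margin must
        coincide with the tiger-only regression slope (up to sampling noise)."""
        cfg = pp.SyntheticConfig(n_parks=150, n_years=1, seed=31,
                                 tiger_share_baseline=0.97, tiger_share_slope=0.0,
                                 tiger_share_noise_sd=0.05)
        bio = pp.generate_biomass(cfg)
        d = pp.decompose_predators(bio)
        m = pp.margins(pp.fit_cca(d))
        ols_slope = np.polyfit(d.log_prey, d.log_tiger, 1)[0]
        assert m.tiger_slope == pytest.approx(ols_slope, abs=0.05)

    def test_margin_slope_matches_regression_under_prey_independent_shares(self):
        """When the predator split does not depend on prey biomass, the
        margin slope and the single-species regression slope estimate the
        same quantity; in large samples they coincide. (The margin LEVEL
        still sits above the regression by the competitor's mean share —
        removing a competitor frees its biomass share regardless of how the
        split varies with prey.)"""
        for seed in (51, 52):
            cfg = pp.SyntheticConfig(n_parks=300, n_years=1, seed=seed,
                                     tiger_share_slope=0.0)
            bio = pp.generate_biomass(cfg)
            d = pp.decompose_predators(bio)
            m = pp.margins(pp.fit_cca(d))
            ols_slope = np.polyfit(d.log_prey, d.log_tiger, 1)[0]
            assert m.tiger_slope == pytest.approx(ols_slope, abs=0.05)

    def test_sensitivity_slope_independent_of_reference(self):
        table = pp.leopard_margin_sensitivity(_printed_cca(), [0.5, 1.0, 2.0], 4000.0)
        assert table["leopard_margin_slope"].nunique() == 1
        assert len(table) == 3


class TestCompetitionGap:
    def test_zero_gap_when_margin_and_regression_coincide(self, small_mcmc):
        d = _random_decomp(14)
        cca = pp.fit_cca(d)
        m = pp.margins(cca)
        # single-species fit on noiseless points lying exactly on the margin line
        xs = 10.0 ** np.linspace(*cca.log_prey_range, 10)
        ys = 10.0 ** m.predict_log_tiger(np.log10(xs))
        fit = pp.fit_power_law(xs, ys, mcmc=small_mcmc, label="tiger")
        comp = pp.competition_gap(m, fit, xs)
        assert np.all(np.abs(comp.grid["gap"]) < 0.02 * comp.grid["regression_pred"])

    def test_extrapolation_flagged_and_empty_grid_rejected(self, small_mcmc):
        d = _random_decomp(15)
        m = pp.margins(pp.fit_cca(d))
        fit = pp.fit_power_law(10 ** d.log_prey, 10 ** d.log_tiger,
                               mcmc=small_mcmc, label="tiger")
        lo, hi = m.cca.log_prey_range
        comp = pp.competition_gap(m, fit, [10 ** (lo - 1), 10 ** ((lo + hi) / 2)])
        assert list(comp.grid["extrapolated"]) == [True, False]
        with pytest.raises(ValueError, match="empty"):
            pp.competition_gap(m, fit, [])
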