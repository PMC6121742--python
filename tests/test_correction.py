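"""The correction cascade: apparent values, backgrounds, factor fits, finalize."""

import numpy as np
import pandas as pd
import pytest

import fretkit as fk
from fretkit.correction import (
    IllConditionedFitError,
    PopulationError,
    StageOrderError,
    clipped_mean,
    fit_gaussian_mean,
    gamma_beta_from_line,
)

from conftest import stage_i_table, stage_ii_table


class TestApparentES:
    def test_direct_arithmetic(self):
        es = fk.apparent_es(stage_i_table([(60, 40, 100)]))
        assert es["E_app"].iloc[0] == pytest.approx(0.40)
        assert es["S_app"].iloc[0] == pytest.approx(0.50)

    def test_zero_acceptor_signal(self):
        es = fk.apparent_es(stage_i_table([(80, 0, 50)]))
        assert es["E_app"].iloc[0] == 0.0

    def test_donor_only_signature(self):
        es = fk.apparent_es(stage_i_table([(80, 20, 0)]))
        assert es["S_app"].iloc[0] == 1.0

    def test_zero_total_flagged_undefined(self):
        es = fk.apparent_es(stage_i_table([(0, 0, 0)]))
        assert bool(es["undefined"].iloc[0])


class TestSubtractBackground:
    def test_zero_background_is_identity(self):
        table = stage_i_table([(60, 40, 100)])
        out = fk.subtract_background(table, (0, 0, 0))
        assert out["I_DemDex"].iloc[0] == 60
        assert out.attrs["stage"] == "ii"

    def test_exposure_scales_subtraction(self):
        """5 bins at 0.6 photons/ms remove 3 photons from a count of 103."""
        table = stage_i_table([(103, 40, 100)], exposure=5)
        out = fk.subtract_background(table, (0.6, 0, 0))
        assert out["I_DemDex"].iloc[0] == pytest.approx(100.0)

    def test_oversubtraction_flagged(self):
        table = stage_i_table([(3, 40, 100)])
        out = fk.subtract_background(table, (10, 0, 0))
        assert bool(out["flag_negative"].iloc[0])
        assert out["I_DemDex"].iloc[0] < 0  # retained, not clipped

    def test_stage_enforced(self):
        table = stage_ii_table([(60, 40, 100)])
        with pytest.raises(StageOrderError):
            fk.subtract_background(table, (0, 0, 0))


class TestLeakageDirectFit:
    @staticmethod
    def _population_table(n_do=60, n_ao=60, e_do=0.05, s_ao=0.15):
        """Constructed DO and AO populations with exact window means."""
        do = [(100 * (1 - e_do), 100 * e_do, 0.0)] * n_do
        x = 100.0
        dex = s_ao / (1 - s_ao) * x
        ao = [(0.0, dex, x)] * n_ao
        return stage_ii_table(do + ao)

    def test_zero_do_efficiency_gives_zero_alpha(self):
        alpha, _ = fk.fit_leakage_direct(self._population_table(e_do=0.0))
        assert alpha == 0.0

    def test_window_means_recovered(self):
        alpha, delta = fk.fit_leakage_direct(self._population_table())
        assert alpha == pytest.approx(0.05 / 0.95)  # 0.0526
        assert delta == pytest.approx(0.15 / 0.85)

    def test_closed_forms(self):
        from fretkit.correction import (
            direct_excitation_from_ao_mean,
            leakage_from_do_mean,
        )

        assert leakage_from_do_mean(0.05) == pytest.approx(0.0526, abs=2e-4)
        assert direct_excitation_from_ao_mean(0.20) == pytest.approx(0.25)

    def test_missing_population_raises_with_guidance(self):
        table = stage_ii_table([(50, 50, 100)] * 100)  # FRET events only
        with pytest.raises(PopulationError):
            fk.fit_leakage_direct(table)

    def test_do_centers_at_zero_after_correction(self, mixture_truth):
        """After (alpha, delta), DO mean E = 0 and AO mean S = 0 within
        standard error on a simulated mixture."""
        stream, _ = fk.simulate_confocal_stream(mixture_truth, 2500)
        bg = fk.estimate_background_confocal(stream)
        table = fk.bursts_to_table(fk.find_bursts(stream, criterion="all"))
        table_ii = fk.subtract_background(table, bg)
        alpha, delta = fk.fit_leakage_direct(table_ii)
        df3 = fk.intermediate_es(table_ii, alpha, delta)
        do = (df3["S_app"] > 0.8) & (df3["E_app"] < 0.5)
        ao = df3["S_app"] < 0.2
        assert clipped_mean(df3.loc[do, "E_app"]) == pytest.approx(0.0, abs=0.01)
        assert clipped_mean(df3.loc[ao, "S_app"]) == pytest.approx(0.0, abs=0.01)


class TestIntermediateES:
    def test_zero_factors_reduce_to_stage_ii(self):
        table = stage_ii_table([(60, 40, 100)])
        df3 = fk.intermediate_es(table, 0.0, 0.0)
        es2 = fk.apparent_es(table)
        assert df3["E_app"].iloc[0] == es2["E_app"].iloc[0]

    def test_sensitized_emission_arithmetic(self):
        df3 = fk.intermediate_es(stage_ii_table([(60, 40, 100)]), 0.1, 0.1)
        assert df3["F_AD"].iloc[0] == pytest.approx(24.0)
        assert df3["E_app"].iloc[0] == pytest.approx(24.0 / 84.0)

    def test_pure_donor_event_zeroed_by_construction(self):
        alpha = 0.08
        df3 = fk.intermediate_es(stage_ii_table([(100, 100 * alpha, 0)]), alpha, 0.1)
        assert df3["F_AD"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert df3["E_app"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_stage_enforced(self):
        with pytest.raises(StageOrderError):
            fk.intermediate_es(stage_i_table([(60, 40, 100)]), 0.1, 0.1)


class TestGammaBetaFit:
    def test_ideal_factors_put_all_populations_at_half(self):
        """gamma = beta = 1 implies S = 0.5 at every E; the fit returns (1, 1)."""
        gamma, beta = fk.fit_gamma_beta_global([(0.2, 0.5), (0.6, 0.5)])
        assert gamma == pytest.approx(1.0)
        assert beta == pytest.approx(1.0)

    def test_exact_recovery_from_generated_points(self):
        gamma_t, beta_t = 0.7, 1.3
        pts = []
        for e in (0.2, 0.6):
            s = 1.0 / (1.0 + gamma_t * beta_t + (1.0 - gamma_t) * beta_t * e)
            pts.append((e, s))
        gamma, beta = fk.fit_gamma_beta_global(pts)
        assert gamma == pytest.approx(gamma_t, rel=1e-12)
        assert beta == pytest.approx(beta_t, rel=1e-12)

    def test_closed_form_from_line(self):
        gamma, beta = gamma_beta_from_line(a=2.0, b=-0.5)
        assert beta == pytest.approx(0.5)
        assert gamma == pytest.approx(2.0)

    def test_indistinguishable_populations_rejected(self):
        with pytest.raises(IllConditionedFitError):
            fk.fit_gamma_beta_global([(0.40, 0.5), (0.41, 0.5)])

    def test_single_species_mode_on_broad_population(self):
        """Burstwise regression recovers the factors when efficiency spread
        comes from genuine distance fluctuations."""
        rng = np.random.default_rng(2)
        gamma_t, beta_t = 0.8, 1.1
        e = rng.uniform(0.15, 0.75, 4000)
        s = 1.0 / (1.0 + gamma_t * beta_t + (1.0 - gamma_t) * beta_t * e)
        d = 1000.0 * (1 - e)
        f_ad = 1000.0 * e
        x = (f_ad + d) * (1.0 / s - 1.0)
        table = stage_ii_table(np.column_stack([d, f_ad, x]))
        df3 = fk.intermediate_es(table, 0.0, 0.0)
        gamma, beta = fk.fit_gamma_beta_single(df3)
        assert gamma == pytest.approx(gamma_t, rel=0.02)
        assert beta == pytest.approx(beta_t, rel=0.02)

    def test_shot_noise_only_spread_refused(self):
        rng = np.random.default_rng(3)
        e = 0.5 + rng.normal(0, 0.02, 500)
        s = np.full_like(e, 0.5)
        d = 100 * (1 - e)
        f = 100 * e
        x = (f + d) * (1.0 / s - 1.0)
        df3 = fk.intermediate_es(stage_ii_table(np.column_stack([d, f, x])), 0.0, 0.0)
        with pytest.raises(IllConditionedFitError):
            fk.fit_gamma_beta_single(df3)


class TestFinalize:
    def test_ideal_factors_reduce_to_apparent(self):
        rng = np.random.default_rng(1)
        triples = rng.integers(20, 200, size=(50, 3)).astype(float)
        table = stage_ii_table(triples)
        out = fk.corrected_es(table, fk.CorrectionFactors())
        expected = triples[:, 1] / (triples[:, 1] + triples[:, 0])
        np.testing.assert_allclose(out["E"], expected)

    def test_hand_evaluated_example(self):
        f = fk.CorrectionFactors(alpha=0.1, beta=0.8, gamma=1.2, delta=0.1)
        out = fk.corrected_es(stage_ii_table([(60, 40, 100)]), f)
        assert out["E"].iloc[0] == pytest.approx(0.25)
        assert out["S"].iloc[0] == pytest.approx(96.0 / 221.0)

    def test_mean_from_gaussian_fit(self):
        rng = np.random.default_rng(4)
        e = rng.normal(0.4, 0.05, 3000)
        d = 200 * (1 - e)
        a = 200 * e
        x = 200 * np.ones_like(e)
        table = stage_ii_table(np.column_stack([d, a, x]))
        _, res = fk.finalize_es_and_mean(table, fk.CorrectionFactors())
        assert res.mean_E == pytest.approx(0.4, abs=0.005)
        assert res.fit_converged
        assert res.in_gaussian_range

    def test_out_of_gaussian_range_flagged(self):
        rng = np.random.default_rng(5)
        e = np.clip(rng.normal(0.97, 0.01, 500), 0.01, 0.999)
        d = 500 * (1 - e)
        a = 500 * e
        x = 500 * np.ones_like(e)
        _, res = fk.finalize_es_and_mean(
            stage_ii_table(np.column_stack([d, a, x])), fk.CorrectionFactors()
        )
        assert not res.in_gaussian_range

    def test_empty_window_raises(self):
        table = stage_ii_table([(100, 5, 0)] * 10)  # S = 1, outside window
        with pytest.raises(PopulationError):
            fk.finalize_es_and_mean(table, fk.CorrectionFactors())


class TestCascadeInvariants:
    def test_order_enforced_by_stage_tags(self):
        final = fk.corrected_es(stage_ii_table([(60, 40, 100)]), fk.CorrectionFactors())
        with pytest.raises(StageOrderError):
            fk.corrected_es(final, fk.CorrectionFactors())

    def test_iteration_converges(self, mixture_truth):
        """Repeating (alpha, delta) <-> (gamma, beta) changes factors by
        < 1e-6 within 10 iterations on simulated data."""
        from fretkit.correction import iterate_alpha_delta_gamma_beta
        from fretkit.pipeline import _da_population_mean

        truth = fk.GroundTruth(
            species=[
                fk.SpeciesSpec("DA", E_true=0.2, fraction=0.35),
                fk.SpeciesSpec("DA", E_true=0.6, fraction=0.35),
                fk.SpeciesSpec("DO", fraction=0.2),
                fk.SpeciesSpec("AO", fraction=0.1),
            ],
            factors=mixture_truth.factors,
            seed=17,
        )
        stream, _ = fk.simulate_confocal_stream(truth, 2000)
        bg = fk.estimate_background_confocal(stream)
        table_ii = fk.subtract_background(
            fk.bursts_to_table(fk.find_bursts(stream, criterion="all")), bg
        )

        def populations(df3):
            da = df3[(df3["S_app"] > 0.3) & (df3["S_app"] < 0.8)]
            lo = da[da["E_app"] < 0.4].copy()
            hi = da[da["E_app"] >= 0.4].copy()
            lo.attrs["stage"] = hi.attrs["stage"] = "iii"
            return [
                _da_population_mean(lo, (0.0, 1.0)),
                _da_population_mean(hi, (0.0, 1.0)),
            ]

        factors = iterate_alpha_delta_gamma_beta(table_ii, populations)
        assert factors.provenance == "fitted-global"
        assert factors.gamma == pytest.approx(0.8, rel=0.1)


class TestHelpers:
    def test_clipped_mean_rejects_far_outliers(self):
        rng = np.random.default_rng(0)
        v = np.r_[rng.normal(0.05, 0.02, 1000), np.full(10, 0.4)]
        assert clipped_mean(v) == pytest.approx(0.05, abs=0.005)

    def test_gaussian_fit_fallback_on_degenerate_data(self):
        mu, sigma, converged = fit_gaussian_mean(np.full(50, 0.3))
        assert mu == pytest.approx(0.3)
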