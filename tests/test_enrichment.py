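"""Inverse problem: fraction-new and enrichment estimation, flux comparison."""

import inspect

import numpy as np
import pytest
from scipy import stats

from sterolflux.enrichment import (
    compare_flux,
    fit_enrichment,
    fit_fraction_new,
    mass_shift_index,
    relative_quantity,
)
from sterolflux.isotopes import IsotopologueDistribution, natural_mid
from sterolflux.labeling import LabelingModelParams, labeled_mid, mixture_mid

P, N_EXCH, K = 0.3, 25, 8


def observed_mixture(formula, f, p=P, n_exch=N_EXCH, k=K):
    natural = natural_mid(formula, k_max=k)
    labelled = labeled_mid(formula, LabelingModelParams(p=p, n_exch=n_exch), k_max=k)
    return mixture_mid(f, natural, labelled)


class TestFitFractionNew:
    def test_noiseless_inversion(self, lanosterol_ion):
        obs = observed_mixture(lanosterol_ion, 0.4)
        est = fit_fraction_new(obs, lanosterol_ion, P, N_EXCH)
        assert est.f_hat == pytest.approx(0.4, abs=1e-6)
        assert not est.at_boundary

    @pytest.mark.parametrize("f", [0.0, 1.0])
    def test_boundary_noiseless_unbiased_and_flagged(self, lanosterol_ion, f):
        obs = observed_mixture(lanosterol_ion, f)
        est = fit_fraction_new(obs, lanosterol_ion, P, N_EXCH)
        assert est.f_hat == pytest.approx(f, abs=1e-9)
        assert est.at_boundary

    def test_natural_envelope_gives_zero(self, lanosterol_ion):
        est = fit_fraction_new(natural_mid(lanosterol_ion, K), lanosterol_ion, P, N_EXCH)
        assert est.f_hat == pytest.approx(0.0, abs=1e-9)
        assert est.shift_index == pytest.approx(0.0, abs=1e-12)

    def test_monte_carlo_mean_recovery(self, lanosterol_ion, rng):
        """500 noisy replicates at f=0.25 recover the truth within 0.01."""
        truth = observed_mixture(lanosterol_ion, 0.25).abundances
        fits = []
        for _ in range(500):
            noisy = truth * rng.lognormal(0, 0.01, size=truth.size)
            est = fit_fraction_new(
                IsotopologueDistribution(noisy), lanosterol_ion, P, N_EXCH
            )
            fits.append(est.f_hat)
        assert np.mean(fits) == pytest.approx(0.25, abs=0.01)

    def test_replicate_ci_brackets_truth(self, lanosterol_ion, rng):
        truth = observed_mixture(lanosterol_ion, 0.3).abundances
        reps = [
            IsotopologueDistribution(truth * rng.lognormal(0, 0.01, size=truth.size))
            for _ in range(6)
        ]
        est = fit_fraction_new(reps, lanosterol_ion, P, N_EXCH)
        assert est.n_replicates == 6
        assert 0 <= est.ci_lo <= est.f_hat <= est.ci_hi <= 1
        assert est.ci_lo <= 0.3 <= est.ci_hi

    def test_recovery_grid(self, lanosterol_ion, rng):
        """Median |f_hat - f| <= 0.02 over the (f, p, nExch) grid, 1% noise."""
        errors = []
        for f in np.arange(0.0, 0.91, 0.1):
            for p in (0.2, 0.3):
                for n_exch in (20, 25):
                    truth = observed_mixture(lanosterol_ion, f, p, n_exch).abundances
                    reps = [
                        IsotopologueDistribution(
                            truth * rng.lognormal(0, 0.01, size=truth.size)
                        )
                        for _ in range(5)
                    ]
                    est = fit_fraction_new(reps, lanosterol_ion, p, n_exch)
                    errors.append(abs(est.f_hat - f))
        assert np.median(errors) <= 0.02

    def test_empty_input_rejected(self, lanosterol_ion):
        with pytest.raises(ValueError, match="no observed"):
            fit_fraction_new([], lanosterol_ion, P, N_EXCH)


class TestFitEnrichment:
    def test_noiseless_recovery_of_study_enrichment(self, lanosterol_ion):
        obs = labeled_mid(lanosterol_ion, LabelingModelParams(p=0.30, n_exch=N_EXCH), K)
        result = fit_enrichment(obs, lanosterol_ion, N_EXCH)
        assert result["p_hat"] == pytest.approx(0.30, abs=1e-6)

    def test_unlabelled_envelope_gives_zero(self, lanosterol_ion):
        obs = labeled_mid(lanosterol_ion, LabelingModelParams(p=0.0, n_exch=N_EXCH), K)
        result = fit_enrichment(obs, lanosterol_ion, N_EXCH)
        assert result["p_hat"] == pytest.approx(0.0, abs=1e-6)

    def test_joint_fit_recovers_both(self, lanosterol_ion):
        obs = labeled_mid(lanosterol_ion, LabelingModelParams(p=0.30, n_exch=N_EXCH), K)
        result = fit_enrichment(obs, lanosterol_ion, N_EXCH, f_fixed=None)
        assert result["identifiable"]
        assert result["p_hat"] == pytest.approx(0.30, abs=0.005)
        assert result["f_hat"] == pytest.approx(1.0, abs=0.005)

    def test_corrected_mode_round_trip(self, lanosterol_ion):
        from sterolflux.labeling import build_correction_matrix, correct_mid

        obs = labeled_mid(lanosterol_ion, LabelingModelParams(p=0.30, n_exch=N_EXCH), K)
        matrix = build_correction_matrix(lanosterol_ion, K)
        corrected = correct_mid(obs, matrix)
        result = fit_enrichment(corrected, lanosterol_ion, N_EXCH, corrected=True)
        assert result["p_hat"] == pytest.approx(0.30, abs=1e-6)


class TestMassShiftIndex:
    def test_identical_envelopes_give_zero(self, lanosterol_ion):
        natural = natural_mid(lanosterol_ion, K)
        assert mass_shift_index(natural, natural) == 0.0

    def test_unit_delta_shift(self):
        delta0 = IsotopologueDistribution([1, 0, 0])
        delta1 = IsotopologueDistribution([0, 1, 0])
        assert mass_shift_index(delta1, delta0) == pytest.approx(1.0)

    def test_linear_in_fraction_new(self, lanosterol_ion):
        natural = natural_mid(lanosterol_ion, K)
        labelled = labeled_mid(lanosterol_ion, LabelingModelParams(p=P, n_exch=N_EXCH), K)
        full = mass_shift_index(labelled, natural)
        for f in (0.1, 0.4, 0.7):
            mix = mixture_mid(f, natural, labelled)
            assert mass_shift_index(mix, natural) == pytest.approx(f * full, abs=1e-12)

    def test_never_consumes_n_exch(self):
        assert "n_exch" not in inspect.signature(mass_shift_index).parameters


class TestRelativeQuantity:
    def test_equal_inputs_give_unit_ratio(self):
        rel, summary = relative_quantity([2, 2], [2, 2], ["a", "a"])
        assert np.allclose(rel, 1.0)
        assert summary["a"] == (1.0, 1.0, 1.0)

    def test_twofold_areas(self):
        rel, summary = relative_quantity([2, 2, 2, 1, 1, 1], [1] * 6,
                                         ["a"] * 3 + ["b"] * 3)
        assert summary["a"][0] / summary["b"][0] == pytest.approx(2.0)

    def test_simulated_ratio_recovery(self, rng):
        # resistant/sensitive true concentration ratio 0.6, 5% noise
        a = rng.lognormal(np.log(1.0), 0.05, 5)
        b = rng.lognormal(np.log(0.6), 0.05, 5)
        rel, summary = relative_quantity(
            np.concatenate([a, b]), np.ones(10), ["CEM"] * 5 + ["R2"] * 5
        )
        assert summary["R2"][0] / summary["CEM"][0] == pytest.approx(0.6, rel=0.1)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            relative_quantity([1, 0], [1, 1])


class TestCompareFlux:
    def test_reduction_percentages(self):
        result = compare_flux([0.1] * 3, [0.4] * 3, [0.2] * 3, [0.4] * 3)
        assert result.reduction_a_pct == pytest.approx(75.0)
        assert result.reduction_b_pct == pytest.approx(50.0)
        assert result.degenerate and np.isnan(result.p_value)

    def test_equal_groups_null(self, rng):
        shared = rng.normal(0.4, 0.02, 6)
        result = compare_flux(shared, [0.4] * 6, shared, [0.4] * 6)
        assert result.p_value == pytest.approx(1.0)
        assert result.t_statistic == pytest.approx(0.0)

    def test_power_against_noncentral_t_oracle(self, rng):
        """Detection rate of a between-line difference matches the
        noncentral-t oracle: ~0.61 at a 2-SD effect (n=4), >=0.8 at 3 SD."""
        for effect, expected in ((2.0, 0.61), (3.0, 0.91)):
            hits = 0
            sims = 400
            for _ in range(sims):
                result = compare_flux(
                    rng.normal(0.3, 0.05, 4), [1.0] * 4,
                    rng.normal(0.3 - effect * 0.05, 0.05, 4), [1.0] * 4,
                )
                hits += result.p_value < 0.05
            assert hits / sims == pytest.approx(expected, abs=0.07)
        assert hits / sims >= 0.8  # the 3-SD case

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            compare_flux([0.1], [0.4, 0.4], [0.2, 0.2], [0.4, 0.4])
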