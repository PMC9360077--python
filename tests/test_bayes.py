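import math

import numpy as np
import pytest
from scipy.integrate import quad

import nanopbpk as npk
from nanopbpk import bayes
from nanopbpk.data import BiodistributionDataset, ObservationRecord


def dataset_with_values(design, organ, time_h, values):
    records = tuple(
        ObservationRecord(design.dataset_id, organ, time_h, f"r{i}", v)
        for i, v in enumerate(values)
    )
    return BiodistributionDataset(design=design, records=records)


class TestLogLikelihood:
    def test_perfect_fit_gives_zero(
        self, noisefree_paca, phys, fixed, theta_paca_low
    ):
        ll = npk.log_likelihood(theta_paca_low, noisefree_paca, phys, fixed)
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_single_record_ratio_e(self, phys, fixed, designs, theta_paca_low):
        """predicted/observed = e makes the mean squared log ratio exactly 1."""
        design = designs["paca_low"]
        pred = bayes.predictions_for(
            theta_paca_low,
            dataset_with_values(design, "liver", 24.0, [1.0]),
            phys,
            fixed,
        )[0]
        ds = dataset_with_values(design, "liver", 24.0, [pred / math.e])
        ll = npk.log_likelihood(theta_paca_low, ds, phys, fixed)
        assert ll == pytest.approx(-1.0, abs=1e-9)

    def test_four_records_all_ratio_ten(self, phys, fixed, designs, theta_paca_low):
        design = designs["paca_low"]
        probe = dataset_with_values(design, "spleen", 48.0, [1.0])
        pred = bayes.predictions_for(theta_paca_low, probe, phys, fixed)[0]
        ds = dataset_with_values(design, "spleen", 48.0, [pred / 10.0] * 4)
        ll = npk.log_likelihood(theta_paca_low, ds, phys, fixed)
        assert ll == pytest.approx(-math.log(10.0) ** 2, abs=1e-9)
        assert ll == pytest.approx(-5.30190, abs=1e-4)

    def test_invariant_to_record_order(self, noisy_paca, phys, fixed, theta_paca_low):
        shuffled = BiodistributionDataset(
            design=noisy_paca.design, records=tuple(reversed(noisy_paca.records))
        )
        assert npk.log_likelihood(
            theta_paca_low, shuffled, phys, fixed
        ) == pytest.approx(npk.log_likelihood(theta_paca_low, noisy_paca, phys, fixed))

    def test_invariant_to_common_rescaling(self, phys, fixed, designs, theta_paca_low):
        """Doubling dose doubles predictions; doubling observations likewise
        leaves every predicted/observed ratio — and the likelihood — unchanged."""
        base = designs["paca_low"]
        ds1 = npk.generate_synthetic(theta_paca_low, base, phys, fixed, 0.2, seed=5)
        import dataclasses

        design2 = dataclasses.replace(base, dose_per_bw=2 * base.dose_per_bw)
        ds2 = BiodistributionDataset(
            design=design2,
            records=tuple(
                dataclasses.replace(r, value=2 * r.value) for r in ds1.records
            ),
        )
        ll1 = npk.log_likelihood(theta_paca_low, ds1, phys, fixed)
        ll2 = npk.log_likelihood(theta_paca_low, ds2, phys, fixed)
        assert ll2 == pytest.approx(ll1, rel=1e-6)

    def test_never_positive(self, noisy_paca, phys, fixed, theta_paca_low):
        assert npk.log_likelihood(theta_paca_low, noisy_paca, phys, fixed) <= 0.0


class TestLogPrior:
    def test_out_of_bounds_is_minus_infinity(self, bounds_paca):
        theta = npk.ParameterVector(16.0, 1.0, 10.0, 0.1, 0.1, 0.01)  # chi > 15
        assert npk.log_prior(theta, bounds_paca) == -math.inf

    def test_factor_ten_shift_changes_log_prior_by_ln_ten(self, bounds_paca):
        a = npk.ParameterVector(1.0, 1.0, 10.0, 0.1, 0.1, 0.01)
        b = npk.ParameterVector(1.0, 10.0, 10.0, 0.1, 0.1, 0.01)
        diff = npk.log_prior(a, bounds_paca) - npk.log_prior(b, bounds_paca)
        assert diff == pytest.approx(math.log(10.0), abs=1e-12)

    def test_normalized_one_dimensional_density_integrates_to_one(self):
        lo, hi = 3.3e-2, 30.0
        norm = math.log(hi / lo)
        integral, err = quad(lambda x: 1.0 / (x * norm), lo, hi)
        assert integral == pytest.approx(1.0, abs=1e-9)


class TestLogPosterior:
    def test_out_of_bounds_short_circuits_simulation(
        self, noisy_paca, bounds_paca, phys, fixed, monkeypatch
    ):
        calls = {"n": 0}
        original = bayes.predictions_for

        def counting(*args, **kwargs):
            calls["n"] += 1
            return original(*args, **kwargs)

        monkeypatch.setattr(bayes, "predictions_for", counting)
        theta = npk.ParameterVector(16.0, 1.0, 10.0, 0.1, 0.1, 0.01)
        density = npk.log_posterior(theta, noisy_paca, bounds_paca, phys, fixed)
        assert density.value == -math.inf
        assert calls["n"] == 0

    def test_components_sum(self, noisy_paca, bounds_paca, phys, fixed, theta_paca_low):
        density = npk.log_posterior(
            theta_paca_low, noisy_paca, bounds_paca, phys, fixed
        )
        assert density.value == pytest.approx(
            density.log_prior + density.log_likelihood, abs=1e-12
        )

    def test_larger_residuals_lower_the_posterior(
        self, phys, fixed, designs, bounds_paca, theta_paca_low
    ):
        """Nested residuals: scaling all observations away from the predictions
        strictly decreases the posterior at fixed prior value."""
        design = designs["paca_low"]
        clean = npk.generate_synthetic(theta_paca_low, design, phys, fixed, 0.0, seed=1)
        import dataclasses

        worse = BiodistributionDataset(
            design=design,
            records=tuple(
                dataclasses.replace(r, value=r.value * 1.5) for r in clean.records
            ),
        )
        v_clean = npk.log_posterior(theta_paca_low, clean, bounds_paca, phys, fixed)
        v_worse = npk.log_posterior(theta_paca_low, worse, bounds_paca, phys, fixed)
        assert v_worse.value < v_clean.value
        assert v_worse.log_prior == v_clean.log_prior


class TestPrintedBounds:
    def test_paca_limits(self):
        b = npk.published_bounds("PACA-Cbz")
        assert (b.lower["k_kidneyEl"], b.upper["k_kidneyEl"]) == (1.0, 900.0)
        assert (b.lower["chi_rich"], b.upper["chi_rich"]) == (1.67e-2, 15.0)
        assert (b.lower["P"], b.upper["P"]) == (3.3e-2, 30.0)
        assert (b.lower["k_ab0"], b.upper["k_ab0"]) == (1.16e-2, 10.5)
        assert (b.lower["k_sab0"], b.upper["k_sab0"]) == (1.67e-2, 15.0)

    def test_lipimage_limits(self):
        b = npk.published_bounds("LipImage")
        assert (b.lower["P"], b.upper["P"]) == (1.67e-3, 1.5)
        assert (b.lower["chi_rich"], b.upper["chi_rich"]) == (1.67e-1, 150.0)
        assert (b.lower["k_kidneyEl"], b.upper["k_kidneyEl"]) == (3.3e-2, 30.0)

    def test_release_rate_limits_shared_between_families(self):
        paca = npk.published_bounds("PACA-Cbz")
        lip = npk.published_bounds("lipimage_high")  # dataset ids resolve too
        assert (paca.lower["k_de"], paca.upper["k_de"]) == (3.3e-5, 0.03)
        assert (lip.lower["k_de"], lip.upper["k_de"]) == (3.3e-5, 0.03)

    def test_unknown_family_rejected(self):
        with pytest.raises(KeyError, match="unknown dataset family"):
            npk.published_bounds("Doxil")
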