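import numpy as np
import pandas as pd
import pytest

from enterochron.amr import (
    SplineTrendAR1,
    DerivativeBand,
    fit_penalized_spline_ar1,
    significance_windows,
    standardize_gene_copies,
    qpcr_age_models,
)

AGES = np.array([3, 6, 10, 12, 22, 32, 49, 50, 53], float)


def _panel(n_pigs=10):
    age = np.tile(AGES, n_pigs)
    pig = np.repeat(np.arange(n_pigs), len(AGES))
    return age, pig


def _ar1_noise(rng, age, pig, phi, sd):
    e = np.zeros(len(age))
    for p in np.unique(pig):
        idx = np.flatnonzero(pig == p)
        tt = age[idx]
        ee = np.zeros(len(idx))
        ee[0] = sd * rng.standard_normal()
        for i in range(1, len(idx)):
            rho = phi ** (tt[i] - tt[i - 1])
            ee[i] = rho * ee[i - 1] + sd * np.sqrt(1 - rho**2) * rng.standard_normal()
        e[idx] = ee
    return e


class TestSplineFit:
    def test_noiseless_line_reproduced_exactly(self):
        age, pig = _panel()
        fit = SplineTrendAR1(1.0 + 0.2 * age, age, pig=pig).fit()
        grid = np.linspace(3, 53, 101)
        assert np.abs(fit.predict(grid) - (1 + 0.2 * grid)).max() < 1e-6
        assert fit.phi == pytest.approx(0.0, abs=1e-6)
        band = fit.derivative_band(grid)
        assert np.abs(band.estimate - 0.2).max() < 1e-6
        assert (band.upper - band.lower).max() < 1e-6

    def test_forced_large_lambda_gives_best_line(self):
        age, pig = _panel()
        y = 5 - 0.15 * age + 0.003 * age**2
        fit = SplineTrendAR1(y, age, pig=pig).fit(lambda_=1e12)
        grid = np.linspace(3, 53, 50)
        d = fit.derivative_band(grid).estimate
        assert d.max() - d.min() < 1e-6  # derivative constant: a line

    def test_phi_recovered_from_ar1_noise(self):
        age, pig = _panel(n_pigs=100)
        phis = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            y = np.sin(age / 8) + _ar1_noise(rng, age, pig, 0.6, 0.5)
            phis.append(SplineTrendAR1(y, age, pig=pig).fit().phi)
        assert np.mean(phis) == pytest.approx(0.6, abs=0.15)

    def test_cohort_term_recovered(self):
        age, pig = _panel(n_pigs=40)
        cohort = np.where(pig < 20, 1, 2)
        rng = np.random.default_rng(1)
        y = 4 + 0.05 * age + 0.8 * (cohort - 1) + rng.standard_normal(len(age)) * 0.2
        fit = SplineTrendAR1(y, age, cohort=cohort, pig=pig).fit()
        assert fit.cohort_effect == pytest.approx(0.8, abs=0.15)

    def test_censored_values_dropped_or_substituted(self):
        age, pig = _panel()
        y = 3.0 + 0.1 * age
        y[5] = np.nan
        fit = SplineTrendAR1(y, age, pig=pig).fit()
        assert len(fit.model.y) == len(age) - 1
        fit2 = SplineTrendAR1(y, age, pig=pig, censor_substitute=0.85).fit()
        assert len(fit2.model.y) == len(age)
        assert 0.85 in fit2.model.y

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            SplineTrendAR1(np.ones(6), np.arange(6.0), n_knots=9)

    def test_single_age_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            SplineTrendAR1(np.ones(20), np.full(20, 3.0))


class TestDerivativeBand:
    def test_matches_finite_differences_of_fit(self):
        age, pig = _panel(n_pigs=20)
        rng = np.random.default_rng(2)
        y = np.sin(age / 10) + rng.standard_normal(len(age)) * 0.1
        fit = SplineTrendAR1(y, age, pig=pig).fit()
        grid = np.linspace(4, 52, 200)
        band = fit.derivative_band(grid)
        h = 1e-6
        fd = (fit.predict(grid + h) - fit.predict(grid - h)) / (2 * h)
        scale = np.abs(fd).max()
        np.testing.assert_allclose(band.estimate, fd, atol=1e-6 * max(scale, 1.0))

    def test_wider_level_widens_band_everywhere(self):
        age, pig = _panel(n_pigs=15)
        rng = np.random.default_rng(3)
        y = 0.05 * age + rng.standard_normal(len(age)) * 0.4
        fit = SplineTrendAR1(y, age, pig=pig).fit()
        grid = np.linspace(3, 53, 60)
        b95 = fit.derivative_band(grid, level=0.95)
        b99 = fit.derivative_band(grid, level=0.99)
        assert ((b99.upper - b99.lower) > (b95.upper - b95.lower) - 1e-12).all()
        assert (b95.lower <= b95.estimate + 1e-12).all()
        assert (b95.estimate <= b95.upper + 1e-12).all()

    def test_extrapolation_rejected(self):
        age, pig = _panel()
        fit = SplineTrendAR1(0.1 * age, age, pig=pig).fit()
        with pytest.raises(ValueError, match="range"):
            fit.derivative_band(np.array([1.0, 10.0]))


class TestSignificanceWindows:
    def test_band_straddling_zero_gives_no_windows(self):
        grid = np.linspace(0, 10, 11)
        band = DerivativeBand(
            grid=grid,
            estimate=np.zeros(11),
            lower=-np.ones(11),
            upper=np.ones(11),
            level=0.95,
        )
        assert significance_windows(band) == []

    def test_constructed_increasing_window_interpolated(self):
        # lower bound crosses zero at exactly 12 and 32
        grid = np.linspace(2, 42, 401)
        lower = -np.abs(grid - 22) / 10 + 1.0  # positive on (12, 32)
        band = DerivativeBand(
            grid=grid,
            estimate=lower + 1,
            lower=lower,
            upper=lower + 2,
            level=0.95,
        )
        wins = significance_windows(band)
        assert len(wins) == 1
        w = wins[0]
        assert w.direction == "increasing"
        assert w.start == pytest.approx(12.0, abs=0.2)
        assert w.end == pytest.approx(32.0, abs=0.2)

    def test_decline_then_rise_recovered(self):
        curve = {3: 6.0, 6: 5.0, 10: 3.8, 12: 3.9, 22: 5.0, 32: 5.6, 49: 5.3,
                 50: 5.2, 53: 5.1}
        age, pig = _panel(n_pigs=100)
        mu = np.array([curve[int(a)] for a in age])
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            y = mu + rng.standard_normal(len(age)) * 0.5
            wins = SplineTrendAR1(y, age, pig=pig).fit().significance_windows()
            dec = any(
                w.direction == "decreasing" and w.start < 10 and w.end > 5
                for w in wins
            )
            inc = any(
                w.direction == "increasing" and w.start < 32 and w.end > 12
                for w in wins
            )
            hits += dec and inc
        assert hits >= 2


class TestQpcr:
    def test_standardization_examples(self):
        qpcr = pd.DataFrame(
            {
                "sample_id": ["s1", "s1", "s2", "s2"],
                "gene": ["tetA", "16S", "tetA", "16S"],
                "copies_per_g": [1e7, 1e10, 5e8, 5e8],
            }
        )
        out = standardize_gene_copies(qpcr).set_index("sample_id")
        assert out.loc["s1", "log10_standardized"] == pytest.approx(-3.0)
        assert out.loc["s2", "log10_standardized"] == pytest.approx(0.0)

    def test_missing_16s_flagged(self):
        qpcr = pd.DataFrame(
            {
                "sample_id": ["s1"],
                "gene": ["tetA"],
                "copies_per_g": [1e7],
            }
        )
        with pytest.warns(UserWarning, match="16S"):
            out = standardize_gene_copies(qpcr)
        assert out.missing_16s.iloc[0]
        assert np.isnan(out.log10_standardized.iloc[0])

    def test_age_models_detect_decline(self):
        from enterochron.simulate import CohortConfig, generate_design, generate_qpcr_observations

        cfg = CohortConfig(seed=3)
        design = generate_design(cfg)
        qpcr = generate_qpcr_observations(design, cfg)
        meta = pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in design],
                "pig_id": [r.pig_id for r in design],
                "cohort": [r.cohort for r in design],
                "age_weeks": [r.age_weeks for r in design],
            }
        )
        fits = qpcr_age_models(qpcr, meta)
        fit = fits[("tetA", "absolute")]
        j = fit.exog_names.index("age_10")
        # the week-10 contrast against week 3 reflects the configured drop
        assert fit.params[j] == pytest.approx(5.40 - 7.10, abs=0.4)
        assert fit.pvalues[j] < 0.01
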