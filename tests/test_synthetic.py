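import numpy as np
import pytest

from docseer import calendars as cal
from docseer.synthetic import (
    ClimateConfig,
    SkillStructure,
    build_hindcast_archive,
    generate_ensemble,
    generate_truth_weather,
    monthly_climatology,
    sample_doc_observations,
)


class TestTruthWeather:
    def test_deterministic_under_seed(self, climate):
        a = generate_truth_weather(climate, 3, seed=7)
        b = generate_truth_weather(climate, 3, seed=7)
        for sc in ("C1", "C2"):
            assert np.array_equal(a[sc].temperature, b[sc].temperature)
            assert np.array_equal(a[sc].precipitation, b[sc].precipitation)

    def test_zero_wet_probability_gives_dry_series(self):
        cfg = ClimateConfig(wet_prob=np.zeros(12))
        truth = generate_truth_weather(cfg, 2, seed=1)
        assert np.all(truth["C2"].precipitation == 0)

    def test_noise_free_temperature_is_pure_annual_cycle(self):
        cfg = ClimateConfig(temp_ar1=0.0, temp_noise_sd=0.0)
        truth = generate_truth_weather(cfg, 1, seed=0)
        doys = np.arange(365)
        cycle = cfg.temp_mean + cfg.temp_amplitude * np.cos(
            2 * np.pi * (doys - cfg.temp_peak_doy) / 365
        )
        np.testing.assert_allclose(truth["C2"].temperature, cycle, atol=1e-12)

    def test_upstream_subcatchment_is_colder(self, truth10):
        assert truth10["C1"].temperature.mean() < truth10["C2"].temperature.mean()

    def test_nonpositive_years_rejected(self, climate):
        with pytest.raises(ValueError):
            generate_truth_weather(climate, 0, seed=1)

    def test_mediterranean_seasonality(self, truth10):
        """Autumn is wetter than summer; precipitation is never negative."""
        p = truth10["C2"].precipitation
        months = truth10["C2"].months
        autumn = p[np.isin(months, (9, 10, 11))].mean()
        summer = p[np.isin(months, (6, 7, 8))].mean()
        assert autumn > summer
        assert np.all(p >= 0)


class TestEnsemble:
    def test_perfect_skill_reproduces_truth_exactly(self, truth10):
        for var in ("temperature", "precipitation"):
            fc = generate_ensemble(
                truth10["C2"], var, 1994, 3, 4, SkillStructure.perfect(), seed=5
            )
            assert fc.members.shape == (4, 215)
            window = truth10["C2"].window(1994, 3, 215)
            for member in fc.members:
                np.testing.assert_array_equal(member, window.variable(var))

    def test_member_count_51(self, truth10):
        fc = generate_ensemble(
            truth10["C2"], "temperature", 1995, 1, 51, SkillStructure(), seed=2
        )
        assert fc.n_members == 51

    def test_zero_skill_members_uncorrelated_with_truth(self, truth10):
        """lambda = 0: Monte-Carlo mean member–truth anomaly correlation ≈ 0."""
        truth = truth10["C2"]
        clim = monthly_climatology(truth.temperature, truth.months)
        window = truth.window(1993, 1, 215)
        t_anom = window.temperature - clim[window.months - 1]
        corrs = []
        for seed in range(60):
            fc = generate_ensemble(
                truth, "temperature", 1993, 1, 1, SkillStructure.no_skill(), seed=seed
            )
            m_anom = fc.members[0] - clim[window.months - 1]
            corrs.append(np.corrcoef(t_anom, m_anom)[0, 1])
        assert abs(np.mean(corrs)) < 0.05

    def test_skill_decay_in_member_truth_correlation(self, truth10):
        """Strictly decreasing lambda(lead) → non-increasing mean anomaly correlation."""
        truth = truth10["C2"]
        skill = SkillStructure()  # strictly decreasing defaults
        clim = monthly_climatology(truth.temperature, truth.months)
        window = truth.window(1993, 1, 215)
        t_anom = window.temperature - clim[window.months - 1]
        leads = generate_ensemble(truth, "temperature", 1993, 1, 1, skill, 0).leads
        acc = {ld: [] for ld in range(1, 8)}
        for seed in range(100):
            fc = generate_ensemble(truth, "temperature", 1993, 1, 1, skill, seed)
            m_anom = fc.members[0] - clim[window.months - 1]
            for ld in range(1, 8):
                sel = leads == ld
                acc[ld].append(np.corrcoef(t_anom[sel], m_anom[sel])[0, 1])
        means = [np.mean(acc[ld]) for ld in range(1, 8)]
        assert means[0] > 0.5
        assert np.all(np.diff(means) < 0.05)  # non-increasing up to Monte-Carlo error

    def test_precipitation_members_nonnegative_and_biased(self, truth10):
        skill = SkillStructure(bias_by_lead=np.full(7, 1.5))
        fc = generate_ensemble(truth10["C1"], "precipitation", 1994, 9, 8, skill, seed=3)
        assert np.all(fc.members >= 0)
        raw = generate_ensemble(
            truth10["C1"], "precipitation", 1994, 9, 8, SkillStructure(), seed=3
        )
        assert fc.members.mean() > raw.members.mean()

    def test_window_too_short_rejected(self, truth10):
        with pytest.raises(ValueError):
            generate_ensemble(
                truth10["C2"], "temperature", 1997, 12, 2, SkillStructure(), seed=1
            )

    def test_lead_assignment(self, truth10):
        fc = generate_ensemble(truth10["C2"], "temperature", 1994, 11, 1,
                               SkillStructure(), seed=1)
        assert fc.leads[0] == 1
        assert fc.months[0] == 11
        # December starts at day 30 (lead 2), January at day 61 (lead 3)
        assert fc.leads[30] == 2 and fc.months[30] == 12
        assert fc.leads[61] == 3 and fc.months[61] == 1


class TestArchive:
    def test_cardinality(self, truth10):
        arch = build_hindcast_archive(
            truth10, [1994, 1995], [1, 6], 2, SkillStructure(), seed=4
        )
        for sc in ("C1", "C2"):
            for var in ("temperature", "precipitation"):
                assert arch.member_series_count(var, sc) == 2 * 2 * 2

    def test_deterministic_under_seed(self, truth10):
        a = build_hindcast_archive(truth10, [1994], [1], 3, SkillStructure(), seed=9)
        b = build_hindcast_archive(truth10, [1994], [1], 3, SkillStructure(), seed=9)
        k = ("temperature", "C2", 1994, 1)
        assert np.array_equal(a.forecasts[k].members, b.forecasts[k].members)

    def test_empty_dimensions_rejected(self, truth10):
        with pytest.raises(ValueError):
            build_hindcast_archive(truth10, [], [1], 2, SkillStructure(), seed=1)
        with pytest.raises(ValueError):
            build_hindcast_archive(truth10, [1994], [], 2, SkillStructure(), seed=1)

    def test_coverage_exceeded_rejected(self, truth10):
        with pytest.raises(ValueError):
            build_hindcast_archive(truth10, [1997], [12], 2, SkillStructure(), seed=1)


class TestObservations:
    def test_noise_free_samples_equal_simulation(self):
        sim = np.linspace(1, 5, 365)
        obs = sample_doc_observations(sim, cadence=30, noise_cv=0.0, seed=1)
        assert len(obs.values) == 13  # days 0, 30, ..., 360
        np.testing.assert_array_equal(obs.values, sim[obs.day_indices])

    def test_noise_is_multiplicative_and_positive(self):
        sim = np.full(365, 4.0)
        obs = sample_doc_observations(sim, cadence=7, noise_cv=0.3, seed=2)
        assert np.all(obs.values > 0)
        assert obs.values.std() > 0

    def test_deterministic_under_seed(self):
        sim = np.random.default_rng(0).uniform(1, 10, 200)
        a = sample_doc_observations(sim, 14, 0.2, seed=5)
        b = sample_doc_observations(sim, 14, 0.2, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            sample_doc_observations(np.array([]), 30, 0.1, seed=1)
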