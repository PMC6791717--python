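"""Unit and property tests for the pulse-chase population simulator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import labelchase as lc
from labelchase.errors import ConfigError, ScheduleCoverageError

from conftest import constant_schedule


def binomial_se(p, n):
    return math.sqrt(p * (1 - p) / n)


class TestRateSchedule:
    def test_paper_schedule_intervals(self):
        assert lc.PAPER_SCHEDULE.intervals == (
            (0.0, 7.0), (7.0, 14.0), (14.0, 21.0), (21.0, 80.0), (80.0, 600.0),
        )

    def test_rate_lookup_is_left_closed(self):
        assert lc.PAPER_SCHEDULE.rate_at(0) == 0.19
        assert lc.PAPER_SCHEDULE.rate_at(6.999) == 0.19
        assert lc.PAPER_SCHEDULE.rate_at(7) == 0.09

    def test_uncovered_day_raises(self):
        with pytest.raises(ScheduleCoverageError):
            lc.PAPER_SCHEDULE.rate_at(600)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(breakpoints=(0, 7), rates=(0.1, 0.2)),
            dict(breakpoints=(0, 7, 7), rates=(0.1, 0.2)),
            dict(breakpoints=(0, 7), rates=(1.5,)),
        ],
    )
    def test_invalid_schedules_rejected(self, bad):
        with pytest.raises(ConfigError):
            lc.RateSchedule(**bad)

    @given(st.floats(min_value=0.0, max_value=0.99))
    def test_spine_calibration_round_trips(self, p):
        k = lc.k_from_agent_probability(p)
        assert lc.agent_probability_from_k(k) == pytest.approx(p, abs=1e-12)


class TestBuildPopulation:
    def test_degenerate_distribution_is_exact(self):
        config = lc.SimConfig(
            n_cells=10_000, labeled_fraction_at_start=1.0, seed=1
        ).noise_free()
        pop = lc.build_population(config)
        assert pop.population_size == 10_000
        assert np.all(pop.intensity_au == 1.0e5)
        assert np.all(pop.divisions == 0)
        assert not pop.brdu_labeled.any()

    def test_default_labeled_fraction_matches_pulse_efficiency(self):
        # labeling efficiency at the end of the pulse: 93.6 % of cells
        config = lc.SimConfig(n_cells=20_000, seed=5)
        pop = lc.build_population(config)
        frac = pop.labeled_at_pulse.mean()
        assert abs(frac - 0.936) < 3 * binomial_se(0.936, 20_000)

    def test_leaky_labeling_without_pulse(self):
        # no-Dox control: only leaky expression, well below 1 %
        config = lc.SimConfig(n_cells=40_000, labeled_fraction_at_start=0.0, seed=9)
        protocol = lc.PulseChaseProtocol(sample_days=(0,), leak_fraction=0.005)
        pop = lc.build_population(config, protocol=protocol)
        frac = pop.labeled_at_pulse.mean()
        assert abs(frac - 0.005) < 3 * binomial_se(0.005, 40_000)

    def test_subpop_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            lc.build_population(
                lc.SimConfig(n_cells=10),
                subpops=(lc.SubpopulationSpec(0.5), lc.SubpopulationSpec(0.4)),
            )

    def test_unlabeled_cells_sit_at_autofluorescence_scale(self):
        config = lc.SimConfig(n_cells=30_000, labeled_fraction_at_start=0.5, seed=2)
        pop = lc.build_population(config)
        med_unlab = np.median(pop.intensity_au[~pop.labeled_at_pulse])
        med_lab = np.median(pop.intensity_au[pop.labeled_at_pulse])
        assert med_unlab == pytest.approx(100.0, rel=0.05)
        assert med_lab == pytest.approx(1.0e5, rel=0.05)


class TestAdvanceDay:
    def test_zero_rate_leaves_population_unchanged(self, noise_free_config, homogeneous, rng):
        pop = lc.build_population(noise_free_config, homogeneous, rng=rng)
        out = lc.advance_day(
            pop, constant_schedule(0.0), noise_free_config, homogeneous, rng=rng
        )
        assert out.day == 1.0
        assert out.population_size == pop.population_size
        np.testing.assert_array_equal(out.intensity_au, pop.intensity_au)
        np.testing.assert_array_equal(out.divisions, pop.divisions)

    def test_certain_division_halves_intensity(self, homogeneous, rng):
        config = lc.SimConfig(n_cells=1, labeled_fraction_at_start=1.0).noise_free()
        pop = lc.build_population(config, homogeneous, rng=rng)
        out = lc.advance_day(
            pop, constant_schedule(1.0), config, homogeneous, rng=rng
        )
        assert out.population_size == 2
        assert np.all(out.intensity_au == 5.0e4)
        assert np.all(out.divisions == 1)

    def test_expected_growth_matches_branching_process(self, homogeneous):
        # E[N_T] = n (1+p)^T for Bernoulli division with prob p
        p, days, n = 0.2, 10, 10_000
        config = lc.SimConfig(n_cells=n, seed=13).noise_free()
        rng = np.random.default_rng(13)
        pop = lc.build_population(config, homogeneous, rng=rng)
        for _ in range(days):
            pop = lc.advance_day(pop, constant_schedule(p), config, homogeneous, rng=rng)
        expected = n * (1 + p) ** days
        # Galton-Watson variance: sigma^2 m^(T-1) (m^T - 1)/(m - 1) per founder
        m, var_off = 1 + p, p * (1 - p)
        var_founder = var_off * m ** (days - 1) * (m**days - 1) / (m - 1)
        assert abs(pop.population_size - expected) < 3 * math.sqrt(n * var_founder)

    def test_death_removes_cells(self, homogeneous, rng):
        config = lc.SimConfig(n_cells=10_000, death_prob_per_day=0.5, seed=3).noise_free()
        pop = lc.build_population(config, homogeneous, rng=rng)
        out = lc.advance_day(pop, constant_schedule(0.0), config, homogeneous, rng=rng)
        assert abs(out.population_size - 5000) < 3 * math.sqrt(10_000 * 0.25)

    def test_brdu_window_marks_both_daughters(self, homogeneous, rng):
        config = lc.SimConfig(n_cells=500, seed=4).noise_free()
        protocol = lc.PulseChaseProtocol(sample_days=(0,), brdu_windows=((0.0, 1.0),))
        pop = lc.build_population(config, homogeneous, protocol, rng)
        out = lc.advance_day(
            pop, constant_schedule(1.0), config, homogeneous, protocol, rng
        )
        assert out.brdu_labeled.all()
        # next day lies outside the window: new daughters stay unlabeled
        pop2 = lc.build_population(config, homogeneous, protocol, rng)
        out2 = lc.advance_day(
            pop2.copy(), constant_schedule(1.0), config, homogeneous,
            lc.PulseChaseProtocol(sample_days=(0,), brdu_windows=((5.0, 6.0),)), rng,
        )
        assert not out2.brdu_labeled.any()


class TestRunPulseChase:
    def test_single_day_returns_initial_population(self, noise_free_config, homogeneous):
        snaps = lc.run_pulse_chase(
            noise_free_config,
            constant_schedule(0.3),
            homogeneous,
            lc.PulseChaseProtocol(sample_days=(0,)),
        )
        assert len(snaps) == 1
        assert snaps[0].day == 0.0
        direct = lc.build_population(
            noise_free_config,
            homogeneous,
            rng=np.random.default_rng(np.random.SeedSequence(noise_free_config.seed)),
        )
        np.testing.assert_array_equal(snaps[0].intensity_au, direct.intensity_au)

    def test_snapshots_at_requested_days(self, noise_free_config, homogeneous):
        protocol = lc.PulseChaseProtocol(sample_days=(0, 3, 5))
        snaps = lc.run_pulse_chase(
            noise_free_config, constant_schedule(0.1), homogeneous, protocol
        )
        assert [s.day for s in snaps] == [0.0, 3.0, 5.0]

    def test_label_conservation_exact(self, homogeneous):
        # total label is invariant under division: daughters get f*I and (1-f)*I
        config = lc.SimConfig(n_cells=2000, partition_cv=0.3, seed=17,
                              initial_intensity_cv=0.5)
        snaps = lc.run_pulse_chase(
            config, constant_schedule(0.25), homogeneous,
            lc.PulseChaseProtocol(sample_days=(0, 12)),
        )
        np.testing.assert_allclose(
            snaps[1].total_intensity, snaps[0].total_intensity, rtol=1e-12
        )

    def test_lineage_law_exact_halving(self, homogeneous):
        # with partition_cv = 0, intensity = I0 * 2^(-divisions) exactly
        config = lc.SimConfig(n_cells=500, labeled_fraction_at_start=1.0, seed=19).noise_free()
        snaps = lc.run_pulse_chase(
            config, constant_schedule(0.3), homogeneous,
            lc.PulseChaseProtocol(sample_days=(0, 8)),
        )
        final = snaps[1]
        np.testing.assert_array_equal(
            final.intensity_au, 1.0e5 * 2.0 ** (-final.divisions.astype(float))
        )
        assert final.divisions.min() >= 0

    def test_spine_law_division_counts(self, homogeneous):
        # a uniformly sampled cell's divisions after T days ~ Binomial(T, 2p/(1+p))
        from scipy import stats

        p, days, n = 0.2, 8, 30_000
        config = lc.SimConfig(n_cells=n, seed=23).noise_free()
        snaps = lc.run_pulse_chase(
            config, constant_schedule(p), homogeneous,
            lc.PulseChaseProtocol(sample_days=(0, days)),
        )
        rng = np.random.default_rng(23)
        sampled = rng.choice(snaps[1].divisions, size=10_000, replace=True)
        q = 2 * p / (1 + p)
        observed = np.bincount(sampled, minlength=days + 1)
        expected = stats.binom.pmf(np.arange(days + 1), days, q) * len(sampled)
        keep = expected > 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        chi2 += (observed[~keep].sum() - expected[~keep].sum()) ** 2 / expected[~keep].sum()
        crit = stats.chi2.ppf(0.99, keep.sum())  # pooled tail adds ~1 cell
        assert chi2 < crit

    def test_mean_field_dilutes_median_exactly(self):
        config = lc.SimConfig(
            n_cells=1000, labeled_fraction_at_start=1.0, mode="mean-field", seed=29
        ).noise_free()
        snaps = lc.run_pulse_chase(
            config, lc.PAPER_SCHEDULE,
            protocol=lc.PulseChaseProtocol(sample_days=(0, 7, 14)),
        )
        med = [float(np.median(s.intensity_au)) for s in snaps]
        assert med[0] == 1.0e5
        assert med[1] == pytest.approx(1.0e5 * math.exp(-0.19 * 7), rel=1e-12)
        assert med[2] == pytest.approx(med[1] * math.exp(-0.09 * 7), rel=1e-12)

    def test_reproducibility_bit_identical(self, homogeneous):
        config = lc.SimConfig(n_cells=800, seed=31, partition_cv=0.2)
        protocol = lc.PulseChaseProtocol(sample_days=(0, 5))
        a = lc.run_pulse_chase(config, constant_schedule(0.2), homogeneous, protocol)
        b = lc.run_pulse_chase(config, constant_schedule(0.2), homogeneous, protocol)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.intensity_au, s2.intensity_au)
            np.testing.assert_array_equal(s1.divisions, s2.divisions)


class TestMeasureFlow:
    def test_noise_free_measurement_is_identity(self, noise_free_config, homogeneous, rng):
        pop = lc.build_population(noise_free_config, homogeneous, rng=rng)
        sample = lc.measure_flow(pop, noise_free_config, rng)
        np.testing.assert_array_equal(
            np.sort(sample.analysis_intensities()), np.sort(pop.intensity_au)
        )

    def test_contaminant_share(self, homogeneous, rng):
        config = lc.SimConfig(n_cells=10_000, contaminant_fraction=0.1, seed=37)
        pop = lc.build_population(config, homogeneous, rng=rng)
        sample = lc.measure_flow(pop, config, rng)
        tendon = sample.events[
            (sample.events["sample_role"] == "tendon") & ~sample.events["is_bead"]
        ]
        share = tendon["is_contaminant"].mean()
        assert abs(share - 0.1) < 3 * binomial_se(0.1, len(tendon))

    def test_bead_events_at_standard_intensity(self, rng, homogeneous):
        config = lc.SimConfig(n_cells=100, bead_cv=0.0, bead_intensity=5e3, seed=41)
        pop = lc.build_population(config, homogeneous, rng=rng)
        sample = lc.measure_flow(pop, config, rng)
        beads = sample.bead_intensities()
        assert len(beads) == config.n_bead_events
        assert float(np.median(beads)) == 5e3

    def test_negative_control_attached(self, default_flow_sample):
        assert len(default_flow_sample.negative_intensities()) > 0

    def test_empty_population_rejected(self, noise_free_config):
        empty = lc.PopulationSnapshot(
            0.0, np.empty(0), np.empty(0, np.int64), np.empty(0, bool),
            np.empty(0, np.int64), np.empty(0, bool),
        )
        with pytest.raises(ConfigError):
            lc.measure_flow(empty, noise_free_config)


@settings(max_examples=25, deadline=None)
@given(
    p=st.floats(min_value=0.0, max_value=0.5),
    partition_cv=st.floats(min_value=0.0, max_value=0.5),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_label_conservation_property(p, partition_cv, seed):
    """Total label is exactly invariant for any rate and partition noise."""
    config = lc.SimConfig(n_cells=300, partition_cv=partition_cv, seed=seed)
    subpops = (lc.SubpopulationSpec(1.0),)
    snaps = lc.run_pulse_chase(
        config, constant_schedule(p), subpops,
        lc.PulseChaseProtocol(sample_days=(0, 4)),
    )
    np.testing.assert_allclose(
        snaps[-1].total_intensity, snaps[0].total_intensity, rtol=1e-12
    )
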