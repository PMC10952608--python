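"""Tests for the synthetic assay-data generator."""

import numpy as np
import pytest

from protcoop import (
    ModelParameters,
    ScenarioConfig,
    Trajectory,
    generate_study,
    nonproducer_proportion,
    observe_cfu,
    observe_od,
    observe_protease,
    solve_scenario,
    total_yield,
)
from protcoop.synth import (
    HOURS_PER_MODEL_TIME,
    choose_dilution,
    estimate_nonproducer_fraction,
    estimate_spore_fraction,
)


def constant_trajectory(state, t_end=100.0):
    """Stub trajectory frozen at one state, for sampling-noise checks."""
    state = np.asarray(state, dtype=float)
    sc = ScenarioConfig(
        W0=state[0], C0=state[1], A0=state[6], B0=state[4], t_end=t_end
    )
    times = np.linspace(0.0, t_end, 11)
    return Trajectory(
        times=times,
        states=np.tile(state, (11, 1)),
        params=ModelParameters(),
        scenario=sc,
        dense_eval=lambda t: np.broadcast_to(
            state.reshape((8,) + (1,) * np.ndim(t)), (8,) + np.shape(t)
        ).copy(),
    )


class TestObserveOd:
    def test_noiseless_reading_is_proportional_to_yield(self, bsa_coculture):
        times_h = [6.0, 24.0, 48.0]
        od = observe_od(bsa_coculture, times_h, noise_cv=0.0, od_scale=2.0)
        truth = [2.0 * total_yield(bsa_coculture, t / HOURS_PER_MODEL_TIME) for t in times_h]
        np.testing.assert_allclose(od, truth, rtol=1e-12)

    def test_reproducible_under_seed(self, bsa_coculture):
        a = observe_od(bsa_coculture, [12.0, 48.0], 0.1, seed=7)
        b = observe_od(bsa_coculture, [12.0, 48.0], 0.1, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_lognormal_noise_has_the_requested_cv(self, bsa_coculture):
        rng = np.random.default_rng(11)
        truth = total_yield(bsa_coculture, 48.0 / HOURS_PER_MODEL_TIME)
        draws = np.array(
            [observe_od(bsa_coculture, [48.0], 0.1, seed=rng)[0] for _ in range(1000)]
        )
        cv = draws.std() / draws.mean()
        assert 0.08 <= cv <= 0.12
        assert draws.mean() == pytest.approx(truth, rel=0.02)

    def test_negative_cv_rejected(self, bsa_coculture):
        with pytest.raises(ValueError):
            observe_od(bsa_coculture, [12.0], noise_cv=-0.1)

    def test_time_outside_horizon_rejected(self, bsa_coculture):
        with pytest.raises(ValueError):
            observe_od(bsa_coculture, [49.0], 0.0)  # maps past t_end = 100


class TestObserveCfu:
    def test_no_spores_means_zero_spore_count(self):
        traj = constant_trajectory([0.1, 0.1, 0.0, 0.0, 0, 0, 1.0, 0])
        for seed in range(20):
            assert observe_cfu(traj, 24.0, seed=seed)["cfu_spores"] == 0

    def test_spore_fraction_recovery_is_unbiased(self):
        """Mean estimated spore share over 500 seeded plates is within
        2 percentage points of the true 80%."""
        traj = constant_trajectory([0.15, 0.05, 0.6, 0.2, 0, 0, 0, 0.1])
        rng = np.random.default_rng(3)
        fracs = []
        for _ in range(500):
            counts = observe_cfu(traj, 24.0, seed=rng)
            fracs.append(counts["cfu_spores"] / counts["cfu_total"])
        assert abs(np.mean(fracs) - 0.8) < 0.02

    def test_nonproducer_monoculture_on_polymer_is_mostly_spores(self, d8_bsa):
        # a single plate's Poisson noise gives the ratio an ~8% CV, so
        # judge the >90% sporulation claim on the mean over plates
        rng = np.random.default_rng(0)
        ratios = []
        for _ in range(50):
            counts = observe_cfu(d8_bsa, 48.0, seed=rng)
            ratios.append(counts["cfu_spores"] / counts["cfu_total"])
        assert np.mean(ratios) > 0.9

    def test_uncountable_density_raises(self):
        traj = constant_trajectory([0, 0, 0, 0, 0, 0, 1.0, 0])
        with pytest.raises(ValueError, match="countable"):
            observe_cfu(traj, 24.0, cells_per_unit=10.0)

    def test_dilution_selection(self):
        assert choose_dilution(2.5e6) == 1e4
        with pytest.raises(ValueError, match="countable"):
            choose_dilution(5.0)


class TestObserveProtease:
    def test_no_enzyme_means_zero_activity(self):
        traj = constant_trajectory([0.1, 0, 0.1, 0, 0, 0, 0.5, 0.0])
        activity, _ = observe_protease(traj, 24.0, gain=100.0, seed=1)
        assert activity == 0.0

    def test_reproducible_under_seed(self, bsa_coculture):
        assert observe_protease(bsa_coculture, 24.0, seed=5) == observe_protease(
            bsa_coculture, 24.0, seed=5
        )

    def test_activity_per_od_similar_across_media(self, wt_ga, wt_bsa):
        """The producer secretes to a similar OD-normalized level in both
        media contexts (within a factor of two at the matched endpoint)."""
        _, per_od_ga = observe_protease(wt_ga, 48.0, noise_cv=0.0)
        _, per_od_bsa = observe_protease(wt_bsa, 48.0, noise_cv=0.0)
        ratio = per_od_ga / per_od_bsa
        assert 0.5 <= ratio <= 2.0


class TestGenerateStudy:
    def test_empty_study_keeps_schema(self, params):
        tables = generate_study(params, ratios=[0.5], n_replicates=0, seed=1)
        assert tables == []

    def test_deterministic_under_seed(self, params):
        kwargs = dict(media=["BSA_GLY"], ratios=[0.25], n_replicates=2, seed=9)
        a = generate_study(params, **kwargs)
        b = generate_study(params, **kwargs)
        assert len(a) == len(b) == 2
        for ta, tb in zip(a, b):
            assert ta.seed == tb.seed
            assert ta.data.equals(tb.data)
        # replicates use independent sub-seeds
        assert a[0].seed != a[1].seed
        assert not a[0].data.equals(a[1].data)

    def test_noiseless_roundtrip_reproduces_trajectory_metrics(self, params):
        """With noise off, observation-derived quantities equal the model's
        to 1e-6: OD -> total yield, marked colonies -> lineage share,
        heat-treated counts -> spore share."""
        (table,) = generate_study(
            params,
            media=["BSA_GLY"],
            ratios=[0.25],
            n_replicates=1,
            seed=0,
            noise_cv=0.0,
            count_noise=False,
        )
        traj = solve_scenario(params, ScenarioConfig.for_medium("BSA_GLY", 0.25))
        t_model = 48.0 / HOURS_PER_MODEL_TIME
        row = table.data[table.data.time_h == 48.0].iloc[0]
        assert row.od600 == pytest.approx(total_yield(traj, t_model), rel=1e-6)
        assert estimate_nonproducer_fraction(table, 48.0) == pytest.approx(
            nonproducer_proportion(traj, t_model), rel=1e-6
        )
        y = traj.evaluate(t_model)
        assert estimate_spore_fraction(table, 48.0) == pytest.approx(
            (y[2] + y[3]) / (y[0] + y[1] + y[2] + y[3]), rel=1e-6
        )

    def test_noisy_proportion_estimates_track_the_model(self, params):
        """At default noise, the per-strain CFU estimate of the final
        non-producer share lands within 5 percentage points of the
        trajectory value at every mixing ratio (mean over replicate
        plates; one ~300-colony plate has a ~3 pp standard error)."""
        ratios = [0.05, 0.25, 0.75]
        tables = generate_study(
            params, media=["BSA_GLY"], ratios=ratios, n_replicates=6, seed=123
        )
        for ratio in ratios:
            traj = solve_scenario(
                params, ScenarioConfig.for_medium("BSA_GLY", ratio)
            )
            truth = nonproducer_proportion(traj, 48.0 / HOURS_PER_MODEL_TIME)
            estimates = [
                estimate_nonproducer_fraction(t, 48.0)
                for t in tables
                if t.init_frac_C == ratio
            ]
            assert abs(np.mean(estimates) - truth) < 0.05
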