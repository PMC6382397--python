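import math
from dataclasses import replace

import numpy as np
import pytest

from ethosleep import (
    LifespanConfig,
    SimConfig,
    score_ethogram,
    simulate_cohort,
    simulate_deprivation,
    simulate_fly,
    zt,
)
from ethosleep.simulate import (
    ConfigError,
    calibrate_quiescence_rate,
    circadian_gain,
    expected_scored_sleep_fraction,
)
from conftest import spawn_seeds


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(duration_h=0.5), "duration_h"),
            (dict(compliance=1.5), "compliance"),
            (dict(circadian_amplitude=-1), "circadian_amplitude"),
            (dict(sex="yes"), "sex"),
            (dict(state_rates={"quiescence": 0, "micromovement": 0, "walking": 0}), "state_rates"),
        ],
    )
    def test_errors_name_the_field(self, kwargs, msg):
        with pytest.raises(ConfigError, match=msg):
            SimConfig(**kwargs).validate()

    def test_trigger_unresolvable_at_epoch_resolution(self):
        with pytest.raises(ConfigError, match="trigger_s"):
            simulate_deprivation(SimConfig(seed=0), trigger_s=10.0)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(seed=7, duration_h=6, sex="male")
        a, b = simulate_fly(cfg), simulate_fly(cfg)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.v_max, b.v_max)

    def test_different_seed_differs(self):
        a = simulate_fly(SimConfig(seed=7, duration_h=6))
        b = simulate_fly(SimConfig(seed=8, duration_h=6))
        assert not np.array_equal(a.x, b.x)

    def test_infinite_trigger_sentinel_identical_to_undisturbed(self):
        cfg = SimConfig(seed=3, duration_h=12)
        series, log = simulate_deprivation(cfg, math.inf)
        plain = simulate_fly(cfg)
        assert len(log) == 0
        assert np.array_equal(series.x, plain.x)
        assert np.array_equal(series.v_max, plain.v_max)


class TestGenerativeStructure:
    def test_zero_quiescence_weight_means_zero_sleep(self):
        cfg = SimConfig(
            seed=1,
            duration_h=24,
            state_rates={"quiescence": 0.0, "micromovement": 1.0, "walking": 1.0},
        )
        eth = score_ethogram(simulate_fly(cfg))
        assert eth.sleep_min_total() == 0.0

    def test_flat_profile_when_amplitude_zero(self):
        """Circular-shift permutation finds no phase-locked structure at
        amplitude 0 but detects the bimodal drive at amplitude 1.

        Day profiles are shifted circularly (preserving the bout
        autocorrelation that makes naive chi-square anticonservative) and
        the variance of the mean profile is compared with the shifted null.
        """

        def day_profiles(eth):
            active = (eth.minute_states != 0).astype(float)
            days = (eth.minute_t // 86400).astype(int)
            bins = np.floor(zt(eth.minute_t) * 4).astype(int) % 96
            return np.array(
                [
                    [active[(days == d) & (bins == b)].mean() for b in range(96)]
                    for d in range(days.max() + 1)
                ]
            )

        def shift_p(profiles, n_perm=300, seed=3):
            rng = np.random.default_rng(seed)
            obs = np.var(profiles.mean(axis=0))
            nb = profiles.shape[1]
            null = np.array(
                [
                    np.var(
                        np.stack(
                            [np.roll(row, rng.integers(nb)) for row in profiles]
                        ).mean(axis=0)
                    )
                    for _ in range(n_perm)
                ]
            )
            return (1 + np.sum(null >= obs)) / (n_perm + 1)

        p_by_amp = {}
        for amp in (0.0, 1.0):
            profs = [
                day_profiles(
                    score_ethogram(
                        simulate_fly(
                            SimConfig(seed=11 + i, duration_h=240, circadian_amplitude=amp)
                        )
                    )
                )
                for i in range(4)
            ]
            p_by_amp[amp] = shift_p(np.vstack(profs))
        assert p_by_amp[0.0] > 0.01
        assert p_by_amp[1.0] < 0.01

    def test_females_micromove_more_than_males(self):
        from ethosleep import summarize

        mm = {}
        for sex in ("female", "male"):
            vals = []
            for seed in spawn_seeds(50, 8):
                eth = score_ethogram(
                    simulate_fly(SimConfig(seed=seed, duration_h=24, sex=sex))
                )
                vals.append(summarize(eth).micromovement_min_per_day)
            mm[sex] = np.mean(vals)
        assert mm["female"] > mm["male"]

    def test_sleep_fraction_calibration(self):
        cfg = calibrate_quiescence_rate(0.30, SimConfig(seed=0, duration_h=48))
        got = expected_scored_sleep_fraction(
            cfg, quiescence_rate=cfg.state_rates["quiescence"]
        )
        assert got == pytest.approx(0.30, abs=1e-6)
        with pytest.raises(ConfigError, match="unreachable"):
            calibrate_quiescence_rate(0.99, SimConfig(seed=0))

    def test_circadian_gain_flat_at_zero_amplitude(self):
        g = circadian_gain(np.linspace(0, 24, 97), 0.0)
        assert np.allclose(g, 1.0)


class TestClosedLoop:
    def test_forced_cycle_gives_exact_rotation_count(self):
        # quiescence-only animal, compliance 1, no arousal: 20-s immobility
        # + 1-s rotation cycles exactly floor(3600/21) times in one hour
        cfg = SimConfig(
            seed=5,
            duration_h=1,
            compliance=1.0,
            post_rotation_arousal_s=0.0,
            state_rates={"quiescence": 1.0, "micromovement": 0.0, "walking": 0.0},
        )
        _, log = simulate_deprivation(cfg, 20.0)
        assert len(log) == 171
        np.testing.assert_allclose(np.diff(log.t_onset), 21.0)

    def test_every_rotation_preceded_by_exactly_trigger_immobility(self):
        trig = 60.0
        cfg = SimConfig(seed=21, duration_h=24, compliance=0.8)
        _, log, segments = simulate_deprivation(cfg, trig, return_segments=True)
        assert len(log) > 10
        # merge contiguous quiescence (a rotation breaks contiguity, and the
        # immobility clock restarts after a non-compliant one)
        runs: list[list[float]] = []
        for kind, t0, t1 in segments:
            if kind != "Q":
                continue
            if runs and math.isclose(runs[-1][1], t0):
                runs[-1][1] = t1
            else:
                runs.append([t0, t1])
        length_at_end = {round(t1, 6): t1 - t0 for t0, t1 in runs}
        for onset in log.t_onset:
            assert round(float(onset), 6) in length_at_end
            assert length_at_end[round(float(onset), 6)] == pytest.approx(trig)

    def test_rotations_confined_to_window(self):
        cfg = SimConfig(seed=2, duration_h=48)
        win = (36.0 * 3600, 48.0 * 3600)
        _, log = simulate_deprivation(cfg, 120.0, window=win)
        assert len(log) > 0
        assert (log.t_onset >= win[0]).all() and (log.t_onset < win[1]).all()


class TestCohort:
    def test_single_fly_deterministic(self):
        cfg = SimConfig(seed=99, duration_h=24)
        a = simulate_cohort(1, cfg)
        b = simulate_cohort(1, cfg)
        assert a.equals(b) and len(a) == 1

    def test_seed_split_stable_under_append(self):
        cfg = SimConfig(seed=99, duration_h=24)
        small = simulate_cohort(2, cfg)
        big = simulate_cohort(3, cfg)
        assert small.equals(big.iloc[:2].reset_index(drop=True))

    def test_no_censoring_when_rate_zero(self):
        coh = simulate_cohort(5, SimConfig(seed=1, duration_h=24), LifespanConfig())
        assert not coh["censored"].any()
        assert (coh["lifespan_days"] > 0).all()

    def test_censor_rate_produces_censored_rows(self):
        coh = simulate_cohort(
            20, SimConfig(seed=1, duration_h=24), LifespanConfig(censor_rate=0.5)
        )
        assert 0 < coh["censored"].sum() < 20

    def test_invalid_n(self):
        with pytest.raises(ConfigError, match="n"):
            simulate_cohort(0, SimConfig(seed=0, duration_h=24))
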