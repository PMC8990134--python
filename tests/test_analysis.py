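import numpy as np
import pandas as pd
import pytest

from lfpdecode.analysis import (
    GaitCycleSet,
    cadence_analysis,
    compare_groups,
    cycle_average,
    mi_analysis,
    mi_matrix,
    mutual_information,
    phase_shuffled_excursion,
    segment_gait_cycles,
    session_envelopes,
)
from lfpdecode.preprocess import EnvelopeSeries
from lfpdecode.synth import (
    CouplingSpec,
    GaitModel,
    NoiseSpec,
    SynthConfig,
    generate_session,
)


def gaussian_mi_bits(rho: float) -> float:
    return -0.5 * np.log(1 - rho**2) / np.log(2)


class TestMutualInformation:
    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(0)
        mi = mutual_information(rng.standard_normal(10_000), rng.standard_normal(10_000))
        assert mi <= 0.05

    @pytest.mark.parametrize("rho", [0.3, 0.6, 0.9])
    def test_gaussian_closed_form(self, rho):
        rng = np.random.default_rng(42)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=50_000)
        mi = mutual_information(z[:, 0], z[:, 1])
        assert mi == pytest.approx(gaussian_mi_bits(rho), abs=0.1)

    def test_identity_grows_with_n(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(50_000)
        assert mutual_information(x, x) > 3.0

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(5000)
        y = 0.5 * x + rng.standard_normal(5000)
        assert mutual_information(x, y) == pytest.approx(
            mutual_information(y, x), abs=0.05
        )

    def test_non_negative_and_constant_inputs(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(2000)
        assert mutual_information(x, np.ones(2000)) == 0.0
        assert mutual_information(np.ones(2000), x) == 0.0
        assert mutual_information(x, rng.standard_normal(2000)) >= 0.0

    def test_nonlinear_dependence_detected(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(20_000)
        y = x**2 + 0.1 * rng.standard_normal(20_000)
        assert mutual_information(x, y) > 0.5


class TestGaitCycles:
    def test_synthetic_cycle_count(self):
        s = generate_session(
            SynthConfig(duration=60.0, gait=GaitModel(cadence=0.75), seed=0)
        )
        cycles = segment_gait_cycles(session=s)
        assert abs(cycles.n_cycles - 45) <= 1

    def test_constant_kinematics_raise(self):
        with pytest.raises(ValueError):
            segment_gait_cycles(kinematics=np.ones((6, 3000)), fs=50.0)

    def test_sinusoidal_hip_peak_intervals(self):
        t = np.arange(6000) / 50.0
        hip = 100 + 15 * np.cos(2 * np.pi * 0.6 * t)
        cycles = segment_gait_cycles(kinematics=hip[None, :], fs=50.0)
        intervals = np.diff(cycles.boundaries)
        assert np.allclose(intervals, 1 / 0.6, rtol=0.02)

    def test_phase_resets_at_boundaries(self):
        cycles = GaitCycleSet(boundaries=np.array([0.0, 1.0, 2.0, 3.0]))
        phase = cycles.phase_of(np.array([0.0, 0.5, 1.0, 2.999, 3.5]))
        assert phase[0] == 0.0
        assert phase[1] == 0.5
        assert phase[2] == 0.0
        assert phase[3] == pytest.approx(0.999)
        assert np.isnan(phase[4])


def theta_modulated_config(seed=0, depth=0.8, psi=np.pi / 2, duration=600.0):
    """Theta strongly modulated at a known phase; other bands unmodulated."""
    m = np.zeros((8, 6))
    m[:, 1] = depth
    return SynthConfig(
        duration=duration,
        seed=seed,
        coupling=CouplingSpec(depth=m, phase=np.full((8, 6), psi)),
        noise=NoiseSpec(white_sd=0.2, pink_amplitude=0.2),
        cadence_theta_slope=None,
    )


class TestCycleAverage:
    @pytest.fixture(scope="class")
    def theta_session(self):
        s = generate_session(theta_modulated_config())
        envs, _, _ = session_envelopes(s)
        cycles = segment_gait_cycles(session=s)
        return s, envs, cycles

    def test_percent_change_bins_average_to_zero(self, theta_session):
        _, envs, cycles = theta_session
        tf = cycle_average(envs, cycles)
        means = tf.percent_change.mean(axis=2)
        assert np.allclose(means, 0.0, atol=1e-9)

    def test_theta_peak_near_ground_truth_phase(self, theta_session):
        # psi = pi/2 -> peak at 25% of the cycle
        _, envs, cycles = theta_session
        tf = cycle_average(envs, cycles)
        for c in range(8):
            peak = tf.peak_bin(c, 1)
            dist = min(abs(peak - 25), 100 - abs(peak - 25))
            assert dist <= 10

    def test_scale_invariance(self, theta_session):
        _, envs, cycles = theta_session
        tf1 = cycle_average(envs, cycles)
        doubled = EnvelopeSeries(envs.values * 2, envs.times, envs.bands)
        tf2 = cycle_average(doubled, cycles)
        np.testing.assert_allclose(tf1.percent_change, tf2.percent_change, atol=1e-9)

    def test_unmodulated_band_within_surrogate_bound(self, theta_session):
        _, envs, cycles = theta_session
        tf = cycle_average(envs, cycles)
        # ripple (band 5) carries no modulation
        observed = np.abs(tf.percent_change[0, 5]).max()
        bound = phase_shuffled_excursion(
            envs, cycles, channel=0, band=5, n_shuffles=100, seed=0
        )
        assert observed <= bound

    def test_too_few_cycles_raise(self, theta_session):
        _, envs, _ = theta_session
        with pytest.raises(ValueError):
            GaitCycleSet(boundaries=np.array([0.0, 1.0]))


class TestMIAnalysis:
    def test_theta_ranks_first_when_only_theta_is_coupled(self):
        m = np.full((8, 6), 0.1)
        m[:, 1] = 0.8
        s = generate_session(
            SynthConfig(
                duration=60.0,
                seed=5,
                coupling=CouplingSpec(depth=m),
                noise=NoiseSpec(white_sd=0.2, pink_amplitude=0.2),
                cadence_theta_slope=None,
            )
        )
        mat = mi_matrix(s)
        band_avg = mat.band_average()[:6]
        assert int(np.argmax(band_avg)) == 1

    def test_alfp_aggregates_broadband_modulation(self):
        # every band modulated in phase -> ALFP collects all of it
        s = generate_session(
            SynthConfig(
                duration=60.0,
                seed=6,
                coupling=CouplingSpec(
                    depth=np.full((8, 6), 0.7), phase=np.zeros((8, 6))
                ),
                noise=NoiseSpec(white_sd=0.1, pink_amplitude=0.1),
                cadence_theta_slope=None,
            )
        )
        mat = mi_matrix(s)
        band_avg = mat.band_average()
        assert band_avg[6] >= band_avg[:6].max()

    def test_uncoupled_band_matches_shuffled_control(self):
        s = generate_session(theta_modulated_config(seed=7, duration=60.0))
        envs, _, targets = session_envelopes(s)
        rng = np.random.default_rng(0)
        ripple = envs.values[:, 0, 5]
        mi_obs = mutual_information(ripple, targets[0])
        controls = [
            mutual_information(rng.permutation(ripple), targets[0])
            for _ in range(20)
        ]
        assert mi_obs <= np.quantile(controls, 0.99) + 0.05

    def test_average_over_sessions(self):
        sessions = [
            generate_session(theta_modulated_config(seed=s, duration=30.0))
            for s in (0, 1)
        ]
        mats, avg = mi_analysis(sessions)
        assert len(mats) == 2
        np.testing.assert_allclose(
            avg.values, (mats[0].values + mats[1].values) / 2
        )
        assert (avg.values >= 0).all()

    def test_empty_session_list_raises(self):
        with pytest.raises(ValueError):
            mi_analysis([])


class TestCompareGroups:
    def test_identical_groups_not_rejected(self):
        vals = np.tile(np.arange(10.0), 2)
        df = pd.DataFrame({"v": vals, "g": ["a"] * 10 + ["b"] * 10})
        res = compare_groups(df, "v", "g")
        assert res.anova.loc["C(g)", "PR(>F)"] > 0.9
        assert res.significant_pairs("g") == []

    def test_large_shift_detected(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "v": np.concatenate(
                    [rng.normal(0, 1, 20), rng.normal(5, 1, 20)]
                ),
                "g": ["a"] * 20 + ["b"] * 20,
            }
        )
        res = compare_groups(df, "v", "g")
        assert res.anova.loc["C(g)", "PR(>F)"] < 0.05
        assert res.significant_pairs("g") == [("a", "b")]

    def test_tukey_flags_only_shifted_group(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "v": np.concatenate(
                    [
                        rng.normal(0, 1, 15),
                        rng.normal(0, 1, 15),
                        rng.normal(8, 1, 15),
                    ]
                ),
                "g": ["a"] * 15 + ["b"] * 15 + ["c"] * 15,
            }
        )
        res = compare_groups(df, "v", "g")
        pairs = set(res.significant_pairs("g"))
        assert pairs == {("a", "c"), ("b", "c")}

    def test_two_way_anova(self):
        rng = np.random.default_rng(2)
        rows = []
        for band in ("theta", "ripple"):
            for region in ("dorsal", "lateral"):
                shift = 3.0 if band == "theta" else 0.0
                for v in rng.normal(shift, 1, 10):
                    rows.append({"v": v, "band": band, "region": region})
        res = compare_groups(pd.DataFrame(rows), "v", ["band", "region"])
        assert res.anova.loc["C(band)", "PR(>F)"] < 0.001
        assert res.anova.loc["C(region)", "PR(>F)"] > 0.05

    def test_degenerate_design_raises(self):
        df = pd.DataFrame({"v": [1.0, 2.0], "g": ["a", "a"]})
        with pytest.raises(ValueError):
            compare_groups(df, "v", "g")


def cadence_sessions(rng, n_per_group=3, duration=40.0, base_seed=0):
    sessions = []
    for i in range(n_per_group):
        for lo, hi, idx in ((0.59, 0.67, 0), (0.73, 0.80, 1)):
            cad = float(rng.uniform(lo, hi))
            sessions.append(
                generate_session(
                    SynthConfig(
                        duration=duration,
                        seed=base_seed + 100 * idx + i,
                        gait=GaitModel(cadence=cad),
                        noise=NoiseSpec(white_sd=0.2, pink_amplitude=0.2),
                    )
                )
            )
    return sessions


class TestCadenceAnalysis:
    def test_theta_power_linkage_recovered(self):
        rng = np.random.default_rng(0)
        res = cadence_analysis(cadence_sessions(rng, n_per_group=3))
        assert "theta" in res.significant_bands
        row = res.table.set_index("band").loc["theta"]
        assert row["mean_higher"] > row["mean_lower"]

    def test_identical_groups_mostly_clean(self):
        # sessions drawn with the linkage disabled: no band should be flagged
        rng = np.random.default_rng(1)
        sessions = []
        for i, cad in enumerate((0.60, 0.63, 0.65, 0.74, 0.76, 0.79)):
            sessions.append(
                generate_session(
                    SynthConfig(
                        duration=30.0,
                        seed=50 + i,
                        gait=GaitModel(cadence=cad),
                        cadence_theta_slope=None,
                    )
                )
            )
        res = cadence_analysis(sessions)
        assert len(res.significant_bands) <= 1  # allow one false positive

    def test_empty_group_raises(self):
        s = generate_session(
            SynthConfig(duration=20.0, gait=GaitModel(cadence=0.62))
        )
        with pytest.raises(ValueError):
            cadence_analysis([s])
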