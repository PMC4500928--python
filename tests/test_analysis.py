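import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seqstop.analysis import (
    VINCENT_PROBS,
    Z_GRID,
    NormalizedDistribution,
    denormalize,
    iri_crosscorrelation,
    iri_profile,
    ks_statistic,
    mean_ssrt_simple,
    normalize_distribution,
    robust_skew,
    trend_analysis,
    vincent_average,
)
from seqstop.gap import GapDistribution
from seqstop.grid import BinnedDensity, bin_edges
from seqstop.simulate import IriSpec, generate_iri_sequence
from seqstop.trials import PressTrial, TrialSet


def gaussian_density(mean, sd):
    cdf = stats.norm.cdf(bin_edges(), loc=mean, scale=sd)
    probs = np.diff(cdf)
    return BinnedDensity(probs / probs.sum())


def make_trial(trial_id, presses, go_period=1200.0):
    return PressTrial(trial_id, go_period, np.asarray(presses, dtype=float))


class TestMeanSsrtSimple:
    def test_arithmetic(self):
        ts = TrialSet([make_trial(i, [200.0, 1370.0]) for i in range(5)])
        assert mean_ssrt_simple(ts, GapDistribution.point_mass(15.0)) == pytest.approx(
            185.0
        )
        assert mean_ssrt_simple(ts, GapDistribution.point_mass(0.0)) == pytest.approx(
            170.0
        )

    def test_no_presses_raises(self):
        with pytest.raises(ValueError, match="last press"):
            mean_ssrt_simple(
                TrialSet([make_trial(0, [])]), GapDistribution.point_mass(0.0)
            )


class TestNormalize:
    def test_density_has_zero_mean_unit_sd_in_z(self):
        nd = normalize_distribution(gaussian_density(190.0, 30.0))
        w = nd.values / nd.values.sum()
        assert np.sum(w * Z_GRID) == pytest.approx(0.0, abs=0.01)
        assert np.sqrt(np.sum(w * Z_GRID**2)) == pytest.approx(1.0, abs=0.01)

    def test_shift_invariance_exact_on_grid(self):
        # 4 ms shift = exactly one bin, so the normalized curves coincide
        a = normalize_distribution(gaussian_density(190.0, 30.0), kind="cdf")
        b = normalize_distribution(gaussian_density(194.0, 30.0), kind="cdf")
        assert np.max(np.abs(a.values - b.values)) < 1e-6

    def test_scale_invariance_up_to_binning(self):
        a = normalize_distribution(gaussian_density(190.0, 30.0), kind="cdf")
        b = normalize_distribution(gaussian_density(250.0, 60.0), kind="cdf")
        assert np.max(np.abs(a.values - b.values)) < 0.02

    def test_source_moments_recorded(self):
        nd = normalize_distribution(gaussian_density(190.0, 30.0))
        assert nd.source_mean_ms == pytest.approx(190.0, abs=0.1)
        assert nd.source_sd_ms == pytest.approx(30.0, abs=0.2)

    def test_zero_sd_rejected(self):
        p = np.zeros(300)
        p[150] = 1.0
        with pytest.raises(ValueError, match="zero-SD"):
            normalize_distribution(BinnedDensity(p))


def _norm_cdf(shift=0.0):
    return NormalizedDistribution(
        values=stats.norm.cdf(Z_GRID - shift),
        kind="cdf",
        source_mean_ms=190.0,
        source_sd_ms=30.0,
    )


class TestVincentAverage:
    def test_identity_on_single_input(self):
        avg = vincent_average([_norm_cdf()])
        window = np.abs(Z_GRID) < 3
        assert np.max(np.abs(avg.values[window] - _norm_cdf().values[window])) < 2e-3

    def test_average_of_shifted_pair_is_midpoint(self):
        avg = vincent_average([_norm_cdf(-0.5), _norm_cdf(0.5)])
        window = np.abs(Z_GRID) < 3
        assert np.max(np.abs(avg.values[window] - _norm_cdf().values[window])) < 5e-3

    def test_mirror_pair_gives_symmetric_average(self):
        skewed = NormalizedDistribution(
            values=stats.skewnorm.cdf(Z_GRID, a=4),
            kind="cdf",
            source_mean_ms=190.0,
            source_sd_ms=30.0,
        )
        mirror = NormalizedDistribution(
            values=1.0 - skewed.values[::-1],
            kind="cdf",
            source_mean_ms=190.0,
            source_sd_ms=30.0,
        )
        avg = vincent_average([skewed, mirror])
        window = np.abs(Z_GRID) < 3
        sym_defect = avg.values + avg.values[::-1] - 1.0
        assert np.max(np.abs(sym_defect[window])) < 5e-3

    def test_density_inputs_rejected(self):
        nd = normalize_distribution(gaussian_density(190.0, 30.0), kind="density")
        with pytest.raises(ValueError, match="CDF-form"):
            vincent_average([nd])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            vincent_average([])


class TestDenormalize:
    def test_axis_arithmetic(self):
        nd = _norm_cdf()
        axis, vals = denormalize(nd, [100.0, 200.0], [900.0, 1600.0])
        np.testing.assert_allclose(axis, Z_GRID * np.sqrt(1250.0) + 150.0)
        np.testing.assert_array_equal(vals, nd.values)

    def test_round_trip_recovers_source_scale(self):
        nd = normalize_distribution(gaussian_density(190.0, 30.0), kind="cdf")
        axis, vals = denormalize(nd, [nd.source_mean_ms], [nd.source_sd_ms**2])
        # median of the denormalized CDF sits at the source mean
        med = np.interp(0.5, vals + 1e-12 * np.arange(vals.size), axis)
        assert med == pytest.approx(190.0, abs=3.0)


class TestRobustSkew:
    def test_symmetric_distribution_zero(self):
        grid = np.linspace(-5, 5, 2001)
        assert robust_skew(grid, stats.norm.cdf(grid)) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("u, expected", [(0.25, 0.2619), (0.1, 0.4650)])
    def test_unit_exponential_closed_form(self, u, expected):
        # Q(p) = -ln(1-p): Bowley/Kelley skew has a closed form
        grid = np.linspace(0, 20, 20001)
        cdf = 1.0 - np.exp(-grid)
        assert robust_skew(grid, cdf, u=u) == pytest.approx(expected, abs=1e-3)

    @pytest.mark.parametrize("u", [0.0, 0.5, -0.1, 0.7])
    def test_invalid_u_rejected(self, u):
        grid = np.linspace(-5, 5, 101)
        with pytest.raises(ValueError, match="strictly between"):
            robust_skew(grid, stats.norm.cdf(grid), u=u)

    def test_degenerate_rejected(self):
        grid = np.linspace(0, 1, 101)
        cdf = np.ones(101)  # all mass below the grid: zero quantile spread
        with pytest.raises(ValueError, match="degenerate"):
            robust_skew(grid, cdf)


class TestKsStatistic:
    def test_identical_is_zero(self):
        grid = np.linspace(-5, 5, 501)
        c = stats.norm.cdf(grid)
        assert ks_statistic(c, c) == 0.0

    def test_separated_point_masses_is_one(self):
        grid = np.linspace(0, 10, 101)
        a = (grid >= 2).astype(float)
        b = (grid >= 8).astype(float)
        assert ks_statistic(a, b) == 1.0

    def test_two_gaussians_closed_form(self):
        # sup |Phi((t-190)/30) - Phi((t-194)/30)| = 2 Phi(2/30) - 1
        grid = np.linspace(0, 400, 40001)
        a = stats.norm.cdf(grid, 190, 30)
        b = stats.norm.cdf(grid, 194, 30)
        expected = 2 * stats.norm.cdf(2 / 30) - 1
        assert ks_statistic(a, b) == pytest.approx(expected, abs=1e-4)

    def test_union_grid_interpolation(self):
        g1 = np.linspace(0, 400, 801)
        g2 = np.linspace(0, 400, 1201)
        a = stats.norm.cdf(g1, 190, 30)
        b = stats.norm.cdf(g2, 190, 30)
        assert ks_statistic(a, b, grid1=g1, grid2=g2) < 1e-3

    def test_shape_mismatch_without_grids(self):
        with pytest.raises(ValueError, match="common grid"):
            ks_statistic(np.zeros(10), np.zeros(11))


PATTERN = [20.0, 30.0, 40.0, 30.0]


def patterned_trials(n_trials=5, n_cycles=6, go_rt=200.0):
    iris = np.tile(PATTERN, n_cycles)
    presses = go_rt + np.concatenate([[0.0], np.cumsum(iris)])
    return TrialSet([make_trial(i, presses) for i in range(n_trials)])


class TestIriProfile:
    def test_first_alignment_reproduces_pattern(self):
        prof = iri_profile(patterned_trials(), align="first", max_positions=8)
        np.testing.assert_array_equal(prof.positions, np.arange(1, 9))
        np.testing.assert_allclose(prof.mean_iri_ms, np.tile(PATTERN, 2))
        assert np.all(prof.n == 5)

    def test_last_alignment_reverses_pattern(self):
        prof = iri_profile(patterned_trials(), align="last", max_positions=4)
        np.testing.assert_array_equal(prof.positions, [-4, -3, -2, -1])
        # pattern read backwards from the final interval
        np.testing.assert_allclose(prof.mean_iri_ms, [20.0, 30.0, 40.0, 30.0])

    def test_constant_iri_flat_profile(self):
        iris = np.full(20, 30.0)
        presses = 200.0 + np.concatenate([[0.0], np.cumsum(iris)])
        ts = TrialSet([make_trial(0, presses)])
        for align in ("first", "last"):
            prof = iri_profile(ts, align=align)
            np.testing.assert_allclose(prof.mean_iri_ms, 30.0)

    def test_last_before_event_is_length_biased(self):
        """Alternating 10/50 ms intervals: a uniformly random event lands
        in the 50 ms interval 5 times out of 6, so the interval *ending*
        at the anchor press is the short one 5 times out of 6:
        E[IRI at -1] = (5/6)*10 + (1/6)*50 = 16.67 ms."""
        iris = np.tile([10.0, 50.0], 30)
        presses = 200.0 + np.concatenate([[0.0], np.cumsum(iris)])
        ts = TrialSet([make_trial(0, presses, go_period=2100.0)])
        # events tile ten full 60 ms cycles at 0.5 ms spacing
        events = np.arange(500.25, 1100.25, 0.5)
        prof = iri_profile(
            ts, align="last_before_event", event_times_go=events, max_positions=1
        )
        expected = (5 / 6) * 10.0 + (1 / 6) * 50.0
        assert prof.positions.tolist() == [-1]
        assert prof.mean_iri_ms[0] == pytest.approx(expected, abs=0.01)

    def test_last_before_event_requires_events(self):
        with pytest.raises(ValueError, match="event times"):
            iri_profile(patterned_trials(), align="last_before_event")

    def test_unknown_alignment(self):
        with pytest.raises(ValueError, match="unknown alignment"):
            iri_profile(patterned_trials(), align="median")

    def test_empty_profile_raises(self):
        ts = TrialSet([make_trial(0, [200.0])])  # one press, no IRI
        with pytest.raises(ValueError, match="no trial contributes"):
            iri_profile(ts)


def _spec_trials(spec, n_trials, seed, duration=3200.0):
    rng = np.random.default_rng(seed)
    trials = []
    for i in range(n_trials):
        iris = generate_iri_sequence(spec, duration, rng)
        presses = 200.0 + np.concatenate([[0.0], np.cumsum(iris)])
        trials.append(make_trial(i, presses, go_period=4000.0))
    return TrialSet(trials)


class TestIriCrosscorrelation:
    def test_lag_zero_is_one(self):
        ts = _spec_trials(IriSpec(), 50, seed=2)
        df = iri_crosscorrelation(ts, mode="mean_first40")
        assert df["correlation"].iloc[0] == pytest.approx(1.0)

    def test_iid_iris_show_no_structure(self):
        ts = _spec_trials(IriSpec(), 400, seed=3)
        df = iri_crosscorrelation(ts, mode="mean_first40")
        assert abs(df.loc[df["lag"] == 8, "correlation"].iloc[0]) < 0.5

    def test_phase_locked_rhythm_peaks_at_period(self):
        spec = IriSpec(modulation_depth=0.3)
        ts = _spec_trials(spec, 200, seed=4)
        df = iri_crosscorrelation(ts, mode="mean_first40")
        lag8 = df.loc[df["lag"] == 8, "correlation"].iloc[0]
        lag4 = df.loc[df["lag"] == 4, "correlation"].iloc[0]
        assert lag8 > 0.5
        assert lag4 < 0.0

    def test_random_phase_rhythm_found_only_single_trial(self):
        spec = IriSpec(modulation_depth=0.3, random_phase=True)
        ts = _spec_trials(spec, 300, seed=5)
        mean_mode = iri_crosscorrelation(ts, mode="mean_first40")
        single_mode = iri_crosscorrelation(ts, mode="singletrial_17to80")
        lag8_mean = mean_mode.loc[mean_mode["lag"] == 8, "correlation"].iloc[0]
        lag8_single = single_mode.loc[single_mode["lag"] == 8, "correlation"].iloc[0]
        lag4_single = single_mode.loc[single_mode["lag"] == 4, "correlation"].iloc[0]
        # the single-trial mode shows the period-8 signature clearly ...
        assert lag8_single > 0.15
        assert lag4_single < lag8_single - 0.2
        # ... while the position-mean mode shows no phase-locked peak
        # (its ACF is dominated by residual noise of the 40-point profile)
        assert lag8_mean < 0.5

    def test_short_trials_rejected(self):
        ts = patterned_trials(n_cycles=2)  # 8 IRIs per trial
        with pytest.raises(ValueError, match="no trial covers"):
            iri_crosscorrelation(ts, mode="singletrial_17to80")

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="unknown mode"):
            iri_crosscorrelation(patterned_trials(), mode="fft")


def _step_trials(go_rts, tn=170.0):
    """One trial per GoRT with constant T_N (last press at 1200 + tn)."""
    return [make_trial(i, [g, 1200.0 + tn]) for i, g in enumerate(go_rts)]


X15 = GapDistribution.point_mass(15.0)


class TestTrendAnalysis:
    def test_deciles_without_metadata(self):
        go = np.where(np.arange(100) < 50, 200.0, 240.0)
        ts = TrialSet(_step_trials(go))
        df = trend_analysis(ts, "deciles", X15)
        subj = df[df["subject"] == "s0"]
        assert len(subj) == 10
        np.testing.assert_allclose(subj["n"], 10)
        np.testing.assert_allclose(
            subj.sort_values("bin")["mean_goRT_ms"], [200.0] * 5 + [240.0] * 5
        )
        # constant T_N: the simple SSRT estimate is flat at 170 + 15
        np.testing.assert_allclose(subj["mean_ssrt_ms"], 185.0)
        overall = df[df["subject"] == "(all)"]
        assert len(overall) == 10

    def test_session_blocks_and_overall_rows(self):
        trials = _step_trials([200.0] * 4 + [240.0] * 4 + [220.0] * 4 + [260.0] * 4)
        meta = pd.DataFrame(
            {
                "subject": ["m1"] * 8 + ["m2"] * 8,
                "session": 1,
                "block": ([1] * 4 + [2] * 4) * 2,
            },
            index=np.arange(16),
        )
        df = trend_analysis(TrialSet(trials, metadata=meta), "session_blocks", X15)
        b1_m1 = df[(df["subject"] == "m1") & (df["bin"] == 1)]["mean_goRT_ms"].iloc[0]
        b1_all = df[(df["subject"] == "(all)") & (df["bin"] == 1)][
            "mean_goRT_ms"
        ].iloc[0]
        assert b1_m1 == pytest.approx(200.0)
        assert b1_all == pytest.approx((200.0 + 220.0) / 2)

    def test_within_block_thirds_detects_drift(self):
        # within every 6-trial block, GoRT rises 200 -> 210 -> 220
        block_go = [200.0, 200.0, 210.0, 210.0, 220.0, 220.0]
        trials = _step_trials(block_go * 3)
        meta = pd.DataFrame(
            {
                "subject": "m1",
                "session": 1,
                "block": np.repeat([1, 2, 3], 6),
            },
            index=np.arange(18),
        )
        df = trend_analysis(TrialSet(trials, metadata=meta), "within_block_thirds", X15)
        subj = df[df["subject"] == "m1"].sort_values("bin")
        np.testing.assert_allclose(subj["mean_goRT_ms"], [200.0, 210.0, 220.0])

    def test_metadata_required_for_blocks(self):
        ts = TrialSet(_step_trials([200.0] * 10))
        with pytest.raises(ValueError, match="metadata"):
            trend_analysis(ts, "session_blocks", X15)

    def test_unknown_scheme(self):
        meta = pd.DataFrame({"subject": "m1"}, index=np.arange(10))
        ts = TrialSet(_step_trials([200.0] * 10), metadata=meta)
        with pytest.raises(ValueError, match="unknown scheme"):
            trend_analysis(ts, "typo", X15)

    def test_missing_columns_reported(self):
        meta = pd.DataFrame({"subject": "m1"}, index=np.arange(10))
        ts = TrialSet(_step_trials([200.0] * 10), metadata=meta)
        with pytest.raises(ValueError, match="session"):
            trend_analysis(ts, "session_blocks", X15)
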