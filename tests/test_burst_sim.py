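"""Telegraph-model simulator: exactness, moments, derived quantities."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from burstmosaic.burst_sim import (
    BurstParams,
    CellRecord,
    ForceMap,
    ParameterError,
    ats_count,
    calibrate,
    force_from_mutant_fraction,
    simulate_cell,
    simulate_population,
    steady_state_moments,
    trajectory_summary,
)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k_on": 0.0, "k_off": 1, "k_tx": 1, "d_m": 1},
            {"k_on": 1, "k_off": -1, "k_tx": 1, "d_m": 1},
            {"k_on": 1, "k_off": 1, "k_tx": -1, "d_m": 1},
            {"k_on": 1, "k_off": 1, "k_tx": 1, "d_m": 0},
            {"k_on": 1, "k_off": 1, "k_tx": 1, "d_m": 1, "k_p": 1, "d_p": 0},
            {"k_on": 1, "k_off": 1, "k_tx": 1, "d_m": 1, "ploidy": 0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            BurstParams(**kwargs)

    def test_continuous_limit_is_allowed(self):
        p = BurstParams(k_on=1, k_off=0.0, k_tx=5, d_m=1)
        assert steady_state_moments(p)["p_on"] == 1.0


class TestMoments:
    def test_poisson_limit(self):
        m = steady_state_moments(BurstParams(k_on=2, k_off=0.0, k_tx=30, d_m=3))
        assert m["p_on"] == 1.0
        assert m["fano"] == 1.0
        assert m["mean_mrna_per_allele"] == pytest.approx(10.0)

    def test_reference_kinetics(self, telegraph_params):
        m = steady_state_moments(telegraph_params)
        assert m["p_on"] == 0.25
        assert m["mean_mrna_per_allele"] == 10.0
        assert m["fano"] == 7.0
        assert m["var_mrna_per_allele"] == 70.0

    def test_fano_increases_with_k_off_in_bursty_onset(self):
        # overdispersion grows with k_off while switching stays slower
        # than k_on + d_m (for very fast switching the bursts average out
        # again, so the trend is not global)
        fanos = [
            steady_state_moments(BurstParams(k_on=1, k_off=k, k_tx=40, d_m=1))["fano"]
            for k in (0.0, 0.1, 0.3, 0.6, 1.0)
        ]
        assert fanos[0] == 1.0
        assert all(b > a for a, b in zip(fanos, fanos[1:]))


class TestSimulateCell:
    def test_no_source_leaves_no_mrna(self):
        p = BurstParams(k_on=1, k_off=1, k_tx=0.0, d_m=1)
        traj = simulate_cell(p, t_end=50, seed=3)
        assert (traj["total_mrna"] == 0).all()

    def test_identical_seed_identical_trajectory(self, telegraph_params):
        a = simulate_cell(telegraph_params, 100, seed=7)
        b = simulate_cell(telegraph_params, 100, seed=7)
        c = simulate_cell(telegraph_params, 100, seed=8)
        assert a.equals(b)
        assert not a.equals(c)

    def test_time_average_matches_analytic_mean(self, telegraph_params):
        # ergodic average over a long trajectory -> p_on * k_tx / d_m = 10
        traj = simulate_cell(
            telegraph_params, 1e5, seed=11,
            sample_times=np.arange(100.0, 1e5, 5.0),
        )
        assert traj["mrna_a"].mean() == pytest.approx(10.0, abs=0.5)

    def test_t_end_must_be_positive(self, telegraph_params):
        with pytest.raises(ParameterError):
            simulate_cell(telegraph_params, 0.0)


class TestSimulatePopulation:
    def test_empty_population_rejected(self, telegraph_params):
        with pytest.raises(ParameterError):
            simulate_population(telegraph_params, 0)

    def test_symmetric_alleles_mean_fraction_half(self, telegraph_population):
        frac = telegraph_population.cells["mut_mrna_frac"].dropna()
        se = frac.std() / math.sqrt(len(frac))
        assert abs(frac.mean() - 0.5) < 4 * se

    def test_population_moments_match_closed_form(self, telegraph_population):
        m = steady_state_moments(telegraph_population.params)
        x = telegraph_population.cells["mrna_a"].to_numpy(dtype=float)
        se_mean = x.std(ddof=1) / math.sqrt(len(x))
        assert abs(x.mean() - m["mean_mrna_per_allele"]) < 3 * se_mean

    def test_fraction_distribution_symmetric(self, telegraph_population):
        # f and 1-f should be exchangeable for identical allele kinetics
        from burstmosaic.stats_core import mann_whitney_u

        f = telegraph_population.cells["mut_mrna_frac"].dropna().to_numpy()
        res = mann_whitney_u(f[:500], 1.0 - f[500:1000])
        assert res["p_two_sided"] > 0.05

    def test_short_burn_in_warns(self, telegraph_params):
        with pytest.warns(UserWarning, match="burn-in"):
            simulate_population(telegraph_params, 10, burn_in=0.1, seed=0)

    def test_nmd_mode_zeroes_mutant_protein_only(self):
        p = BurstParams(
            k_on=0.5, k_off=0.5, k_tx=20, d_m=1, k_p=0.5, d_p=0.2, nmd=True
        )
        snap = simulate_population(p, 300, seed=5)
        assert (snap.cells["protein_b"] == 0).all()
        assert (snap.cells["mrna_b"] == 0).all()
        assert snap.cells["protein_a"].var() > 0
        assert (snap.cells["on_b"] > 0).any()  # promoter still bursts (visible aTS)

    def test_ats_bounded_by_allele_copies(self):
        p = BurstParams(k_on=5, k_off=1, k_tx=1, d_m=1, ploidy=2)
        snap = simulate_population(p, 200, seed=9)
        assert snap.cells["ats"].max() <= 4
        assert snap.cells["ats"].min() >= 0


class TestAtsCount:
    def _cell(self, on, nascent=None, ploidy=1):
        return CellRecord(
            time=0.0, on=on, mrna=(0, 0), protein=(0, 0), ploidy=ploidy, nascent=nascent
        )

    def test_both_off_is_zero(self):
        assert ats_count(self._cell((0, 0))) == 0

    def test_diploid_both_on_threshold_zero(self):
        assert ats_count(self._cell((1, 1))) == 2

    def test_negative_threshold_rejected(self):
        with pytest.raises(ParameterError):
            ats_count(self._cell((1, 0)), detection_threshold=-1)

    def test_threshold_filters_dim_sites(self):
        cell = self._cell((1, 1), nascent=(10, 2))
        assert ats_count(cell, detection_threshold=5) == 1

    def test_threshold_without_nascent_counts_rejected(self):
        with pytest.raises(ParameterError):
            ats_count(self._cell((1, 1)), detection_threshold=3)


class TestForceMap:
    def test_half_maximal_at_wt_midpoint(self):
        fmap = ForceMap(pca50_wt=5.55, delta_pca50=-0.10, n_h=2.0)
        assert force_from_mutant_fraction(0.0, fmap, 5.55) == pytest.approx(0.5)

    def test_full_mutant_midpoint_shifted(self):
        fmap = ForceMap(pca50_wt=5.55, delta_pca50=-0.10, n_h=2.0)
        assert force_from_mutant_fraction(1.0, fmap, 5.45) == pytest.approx(0.5)

    def test_hand_computed_value(self):
        fmap = ForceMap(pca50_wt=5.55, delta_pca50=-0.10, n_h=2.0)
        force = force_from_mutant_fraction(0.5, fmap, 5.24)
        assert force == pytest.approx(1.0 / (1.0 + 10 ** (2 * (5.24 - 5.50))), abs=1e-12)
        assert force == pytest.approx(0.768, abs=5e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            ForceMap(n_h=0.0)
        with pytest.raises(ParameterError):
            force_from_mutant_fraction(1.5, ForceMap(), 5.5)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone_in_mutant_fraction(self, f1, f2):
        # delta < 0 (desensitisation): more mutant protein, less force
        fmap = ForceMap(pca50_wt=5.55, delta_pca50=-0.10, n_h=2.0)
        lo, hi = sorted((f1, f2))
        assert force_from_mutant_fraction(hi, fmap, 5.4) <= force_from_mutant_fraction(
            lo, fmap, 5.4
        )


class TestCalibrate:
    def test_quarter_zero_fraction_gives_half_on(self):
        p = calibrate({"fraction_zero_aTS": 0.25, "mean_total_mRNA": 100})
        assert p.k_on / (p.k_on + p.k_off) == pytest.approx(0.5)

    def test_donor_zero_fraction(self):
        p = calibrate({"fraction_zero_aTS": 0.61, "mean_total_mRNA": 552})
        p_on = p.k_on / (p.k_on + p.k_off)
        assert p_on == pytest.approx(1 - math.sqrt(0.61), rel=1e-9)
        assert p_on == pytest.approx(0.219, abs=5e-4)
        m = steady_state_moments(p)
        assert 2 * m["mean_mrna_per_allele"] == pytest.approx(552.0)

    @pytest.mark.parametrize("fz", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_fraction_rejected(self, fz):
        with pytest.raises(ParameterError):
            calibrate({"fraction_zero_aTS": fz, "mean_total_mRNA": 100})


class TestTrajectorySummary:
    def test_constant_counts_constant_fractions(self):
        import pandas as pd

        traj = pd.DataFrame(
            {
                "time": [0.0, 1.0, 2.0],
                "mrna_a": [3, 3, 3],
                "mrna_b": [1, 1, 1],
                "protein_a": [0, 0, 0],
                "protein_b": [0, 0, 0],
            }
        )
        s = trajectory_summary(traj)
        assert (s["mut_mrna_frac"] == 0.25).all()
        assert s["undefined_protein_frac"].all()
        assert s["mut_protein_frac"].isna().all()

    def test_single_point_rejected(self):
        import pandas as pd

        with pytest.raises(ParameterError):
            trajectory_summary(pd.DataFrame({"time": [0.0]}))

    def test_protein_fraction_lags_mrna_fraction(self):
        # slow protein turnover (d_p < d_m) low-pass filters the mRNA
        # fraction, so the cross-correlation peaks at a positive lag
        p = BurstParams(
            k_on=0.2, k_off=0.2, k_tx=20, d_m=1.0, k_p=1.0, d_p=0.2
        )
        traj = simulate_cell(
            p, 6000, seed=21, sample_times=np.arange(100.0, 6000.0, 1.0)
        )
        s = trajectory_summary(traj)
        ok = ~(s["undefined_mrna_frac"] | s["undefined_protein_frac"])
        m = s.loc[ok, "mut_mrna_frac"].to_numpy()
        q = s.loc[ok, "mut_protein_frac"].to_numpy()
        m -= m.mean()
        q -= q.mean()
        lags = range(-30, 31)
        cc = [np.mean(m[30:-31] * q[30 + lag : len(q) - 31 + lag]) for lag in lags]
        assert list(lags)[int(np.argmax(cc))] > 0
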