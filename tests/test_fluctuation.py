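"""Enthalpy-fluctuation heat capacities: variance protocols and dCp."""

import numpy as np
import pytest

from mmrtfluct import (
    EnergyTrajectory,
    StateEnsemble,
    cluster_weighted_variance,
    delta_cp,
    energy_histogram,
    moving_window_variance,
    partial_cp,
    state_variance,
    variance_cp,
    window_scan,
)
from mmrtfluct.constants import R_KJ
from mmrtfluct.fluctuation import (
    DegenerateClusterError,
    InsufficientDataError,
)
from mmrtfluct.synthetic import SwitchingSpec, gen_state_ensemble, gen_switching_energy


def make_traj(energies, T=300.0, state="reactant", labels=None, regions=None,
              rep="r0"):
    energies = np.asarray(energies, dtype=float)
    return EnergyTrajectory(
        times=np.arange(energies.size) * 10.0,
        energies=energies,
        temperature=T,
        state=state,
        cluster_labels=labels,
        region_energies=regions or {},
        replicate_id=rep,
    )


def make_ensemble(series, T=300.0, state="reactant", burn_in=0.0, regions=None):
    trajs = [
        make_traj(s, T=T, state=state, rep=f"{state}_{i}",
                  regions=None if regions is None else regions[i])
        for i, s in enumerate(series)
    ]
    return StateEnsemble(trajectories=trajs, burn_in_fraction=burn_in)


class TestVarianceCp:
    def test_constant_series_has_zero_heat_capacity(self):
        est = variance_cp(np.full(100, 5.0), T=300.0)
        assert est.value == 0.0
        assert est.sd == 0.0

    def test_gaussian_with_variance_RT2_gives_unit_cp(self, rng):
        n = 100_000
        sigma2 = R_KJ * 300.0**2  # 748.3 (kJ/mol)^2
        x = rng.normal(0.0, np.sqrt(sigma2), n)
        est = variance_cp(x, T=300.0)
        assert est.value == pytest.approx(1.0, abs=4 * np.sqrt(2.0 / (n - 1)))

    def test_two_level_series_matches_direct_arithmetic(self):
        x = np.concatenate([np.zeros(500), np.full(500, 10.0)])
        est = variance_cp(x, T=300.0)
        expected_var = np.var(x, ddof=1)  # ~25.0 (kJ/mol)^2
        assert expected_var == pytest.approx(25.0, rel=2e-3)
        assert est.value == pytest.approx(expected_var / (R_KJ * 300.0**2))

    def test_quadratic_scaling_and_shift_invariance(self, rng):
        x = rng.standard_normal(2000) * 5.0
        base = variance_cp(x, 300.0).value
        assert variance_cp(3.0 * x, 300.0).value == pytest.approx(9.0 * base)
        assert variance_cp(x + 42.0, 300.0).value == pytest.approx(base)

    def test_insufficient_samples_raise(self):
        with pytest.raises(InsufficientDataError):
            variance_cp(np.array([1.0]), 300.0)


class TestClusterWeightedVariance:
    def test_single_cluster_collapses_to_plain_variance(self, rng):
        x = rng.standard_normal(500)
        v, table = cluster_weighted_variance(x, np.zeros(500, dtype=int))
        assert v == pytest.approx(np.var(x, ddof=1))
        assert table.occupancy_pct.iloc[0] == 100.0

    def test_between_cluster_term_is_removed(self, rng):
        """Two equal clusters, variances 4/16, means 0/10: weighted=10, naive~35."""
        n = 200_000
        a = rng.normal(0.0, 2.0, n)
        b = rng.normal(10.0, 4.0, n)
        x = np.concatenate([a, b])
        lab = np.repeat([0, 1], n)
        v, _ = cluster_weighted_variance(x, lab)
        assert v == pytest.approx(10.0, rel=0.02)
        assert np.var(x, ddof=1) == pytest.approx(35.0, rel=0.02)

    def test_law_of_total_variance_is_exact_with_ddof0(self, rng):
        for _ in range(20):
            n = rng.integers(50, 500)
            k = rng.integers(1, 6)
            x = rng.standard_normal(n) * rng.uniform(0.5, 20.0)
            lab = rng.integers(0, k, n)
            # ensure every present cluster has >= 2 members
            vals, counts = np.unique(lab, return_counts=True)
            lab[np.isin(lab, vals[counts < 2])] = vals[counts.argmax()]
            within, table = cluster_weighted_variance(x, lab, ddof=0)
            f = table.n_frames.to_numpy() / n
            mu = table["mean"].to_numpy()
            between = float(f @ (mu - f @ mu) ** 2)
            assert within + between == pytest.approx(
                np.var(x), rel=1e-12, abs=1e-12
            )

    def test_generator_labels_recover_within_state_variance(self):
        spec = SwitchingSpec(
            means=(0.0, 20.0), variances=(400.0, 600.0),
            dwell_frames=(500.0, 500.0), ar1_phi=0.0,
            n_frames=100_000, temperature_K=300.0, seed=3,
        )
        traj, truth = gen_switching_energy(spec)
        v, _ = cluster_weighted_variance(traj.energies, traj.cluster_labels)
        assert v == pytest.approx(truth["within_variance"], rel=0.05)

    def test_degenerate_cluster_is_named_in_the_error(self):
        x = np.arange(10.0)
        lab = np.array([0] * 9 + [7])
        with pytest.raises(DegenerateClusterError, match="7"):
            cluster_weighted_variance(x, lab)


class TestMovingWindowVariance:
    def test_full_length_window_equals_plain_variance_exactly(self, rng):
        x = rng.standard_normal(1000) * 12.0 + 3.0
        assert moving_window_variance(x, window=1000, stride=1000) == pytest.approx(
            np.var(x, ddof=1), rel=1e-12
        )

    def test_unbiased_for_iid_gaussian_at_any_window(self, rng):
        x = rng.normal(0.0, 10.0, 100_000)
        for w in (10, 100, 1000):
            assert moving_window_variance(x, window=w) == pytest.approx(
                100.0, rel=0.02
            )

    def test_short_windows_suppress_between_substate_variance(self):
        """Dwell 1e4 frames, window 1e2: estimate ~within-cluster variance."""
        spec = SwitchingSpec(
            means=(0.0, 40.0), variances=(100.0, 100.0),
            dwell_frames=(10_000.0, 10_000.0), ar1_phi=0.0,
            n_frames=100_000, temperature_K=300.0, seed=11,
        )
        traj, truth = gen_switching_energy(spec)
        mw = moving_window_variance(traj.energies, window=100)
        assert mw == pytest.approx(truth["within_variance"], rel=0.10)
        assert mw < 0.5 * np.var(traj.energies, ddof=1)

    def test_window_longer_than_series_raises(self):
        with pytest.raises(ValueError):
            moving_window_variance(np.zeros(10), window=11)


class TestStateVariance:
    def test_identical_constant_replicates_have_zero_mean_and_sd(self):
        ens = make_ensemble([np.full(100, 7.0)] * 10)
        sv = state_variance(ens)
        assert sv.mean == 0.0 and sv.sd == 0.0

    def test_iid_replicates_match_chi2_sampling_theory(self, rng):
        n, reps, sigma2 = 20_000, 10, 500.0
        ens = make_ensemble(
            [rng.normal(0, np.sqrt(sigma2), n) for _ in range(reps)]
        )
        sv = state_variance(ens)
        assert sv.mean == pytest.approx(sigma2, rel=0.01)
        # sd of a sample variance: sigma2 * sqrt(2/(n-1))
        theory = sigma2 * np.sqrt(2.0 / (n - 1))
        assert sv.sd < 4 * theory

    def test_heterogeneous_replicates_aggregate_by_direct_arithmetic(self, rng):
        series = []
        for i in range(10):
            s2 = 250.0 if i % 2 == 0 else 750.0
            x = rng.standard_normal(400_0)
            x *= np.sqrt(s2) / x.std(ddof=1)  # exact per-replicate variance
            series.append(x)
        sv = state_variance(make_ensemble(series))
        assert sv.mean == pytest.approx(500.0, rel=1e-9)
        assert sv.sd == pytest.approx(263.52, rel=1e-3)

    def test_burn_in_discards_initial_frames(self):
        x = np.concatenate([np.full(100, 100.0), np.zeros(900)])
        ens = make_ensemble([x], burn_in=0.1)
        assert state_variance(ens).mean == 0.0


class TestDeltaCp:
    def test_identical_ensembles_give_zero(self, rng):
        x = rng.standard_normal(1000)
        vr = state_variance(make_ensemble([x] * 3, state="reactant"))
        vt = state_variance(make_ensemble([x] * 3, state="ts_analogue"))
        assert delta_cp(vr, vt).value == 0.0

    def test_analytic_variance_difference_maps_to_minus_one(self, rng):
        target = R_KJ * 300.0**2
        rs, ts = [], []
        for _ in range(5):
            a = rng.standard_normal(50_00)
            a *= np.sqrt(2 * target) / a.std(ddof=1)
            b = rng.standard_normal(50_00)
            b *= np.sqrt(target) / b.std(ddof=1)
            rs.append(a)
            ts.append(b)
        est = delta_cp(
            state_variance(make_ensemble(rs, state="reactant")),
            state_variance(make_ensemble(ts, state="ts_analogue")),
        )
        assert est.value == pytest.approx(-1.0, rel=1e-9)

    def test_antisymmetry_under_state_swap(self, rng):
        vr = state_variance(
            make_ensemble([rng.standard_normal(500) * 3 for _ in range(4)])
        )
        vt = state_variance(
            make_ensemble(
                [rng.standard_normal(500) for _ in range(4)], state="ts_analogue"
            )
        )
        fwd, rev = delta_cp(vr, vt), delta_cp(vt, vr)
        assert fwd.value == pytest.approx(-rev.value)
        assert fwd.sd == pytest.approx(rev.sd)

    def test_temperature_mismatch_rejected(self, rng):
        vr = state_variance(make_ensemble([rng.standard_normal(100)], T=300.0))
        vt = state_variance(
            make_ensemble([rng.standard_normal(100)], T=320.0, state="ts_analogue")
        )
        with pytest.raises(ValueError):
            delta_cp(vr, vt)


class TestWindowScan:
    def test_iid_ensembles_give_a_flat_scan_with_plateau(self, rng):
        rs = make_ensemble([rng.normal(0, 20, 8000) for _ in range(5)])
        ts = make_ensemble(
            [rng.normal(0, 10, 8000) for _ in range(5)], state="ts_analogue"
        )
        scan = window_scan(rs, ts, [2.0, 4.0, 8.0, 16.0])
        assert scan.plateau_value is not None
        plain = delta_cp(state_variance(rs), state_variance(ts))
        assert scan.plateau_value == pytest.approx(plain.value, rel=0.05)

    def test_switching_generator_plateau_recovers_within_state_dcp(self):
        """Dwell 20 ns; windows below the dwell scale plateau on truth."""
        T = 320.0
        kw = dict(dwell_frames=(2000.0, 2000.0), ar1_phi=0.5,
                  n_frames=30_000, temperature_K=T)
        rs_spec = SwitchingSpec(means=(0.0, 30.0), variances=(3000.0, 3000.0),
                                seed=0, **kw)
        ts_spec = SwitchingSpec(means=(0.0, 30.0), variances=(1500.0, 1500.0),
                                seed=1, **kw)
        rs = gen_state_ensemble(rs_spec, 6, "reactant", seed=5)
        ts = gen_state_ensemble(ts_spec, 6, "ts_analogue", seed=6)
        scan = window_scan(rs, ts, [2.0, 4.0, 6.0, 8.0, 10.0])
        true_dcp = (1500.0 - 3000.0) / (R_KJ * T**2)
        assert scan.plateau_value is not None
        assert scan.plateau_value == pytest.approx(true_dcp, rel=0.10)

    def test_window_exceeding_trajectory_raises(self, rng):
        rs = make_ensemble([rng.standard_normal(100)])
        ts = make_ensemble([rng.standard_normal(100)], state="ts_analogue")
        with pytest.raises(ValueError):
            window_scan(rs, ts, [100.0])  # 100 ns >> 1 ns of data


class TestPartialCp:
    def two_region_ensembles(self, rng, cov):
        """Regions with per-state covariance matrices; total = exact sum."""
        def build(Sigma, state, n=40_000, reps=4):
            L = np.linalg.cholesky(Sigma)
            regions, series = [], []
            for _ in range(reps):
                z = rng.standard_normal((n, 2)) @ L.T
                regions.append({"a": z[:, 0], "b": z[:, 1]})
                series.append(z.sum(axis=1))
            return make_ensemble(series, state=state, regions=regions)

        return build(cov[0], "reactant"), build(cov[1], "ts_analogue")

    def test_region_identical_to_total_reproduces_total(self, rng):
        x = [rng.standard_normal(2000) * 5 for _ in range(3)]
        rs = make_ensemble(x, regions=[{"all": xi} for xi in x])
        y = [rng.standard_normal(2000) * 2 for _ in range(3)]
        ts = make_ensemble(y, state="ts_analogue", regions=[{"all": yi} for yi in y])
        total = delta_cp(state_variance(rs), state_variance(ts))
        part = partial_cp(rs, ts, "all")
        assert part.value == pytest.approx(total.value)
        assert part.region == "all"

    def test_independent_regions_sum_to_total(self, rng):
        S_rs = np.diag([300.0, 400.0])
        S_ts = np.diag([150.0, 250.0])
        rs, ts = self.two_region_ensembles(rng, (S_rs, S_ts))
        pa = partial_cp(rs, ts, "a").value
        pb = partial_cp(rs, ts, "b").value
        total = delta_cp(state_variance(rs), state_variance(ts)).value
        assert pa + pb == pytest.approx(total, rel=0.05)

    def test_covariance_breaks_additivity_by_twice_the_cross_term(self, rng):
        S_rs = np.array([[300.0, -100.0], [-100.0, 400.0]])
        S_ts = np.array([[300.0, 50.0], [50.0, 400.0]])
        rs, ts = self.two_region_ensembles(rng, (S_rs, S_ts))
        pa = partial_cp(rs, ts, "a").value
        pb = partial_cp(rs, ts, "b").value
        total = delta_cp(state_variance(rs), state_variance(ts)).value
        gap_theory = 2.0 * (50.0 - (-100.0)) / (R_KJ * 300.0**2)
        assert total - (pa + pb) == pytest.approx(gap_theory, rel=0.25)

    def test_missing_region_column_is_a_schema_error(self, rng):
        rs = make_ensemble([rng.standard_normal(100)])
        ts = make_ensemble([rng.standard_normal(100)], state="ts_analogue")
        with pytest.raises(KeyError, match="loop"):
            partial_cp(rs, ts, "loop")


class TestEnergyHistogram:
    def test_constant_series_occupies_a_single_bin(self):
        ens = make_ensemble([np.full(100, 5.0)] * 2)
        h = energy_histogram(ens, bins=10)
        assert (h["pooled"] > 0).sum() == 1

    def test_gaussian_moments_match_the_generator(self, rng):
        mu, sd = 12.0, 4.0
        ens = make_ensemble([rng.normal(mu, sd, 50_000) for _ in range(3)])
        h = energy_histogram(ens, bins=80)
        centers = 0.5 * (h["bin_edges"][:-1] + h["bin_edges"][1:])
        width = np.diff(h["bin_edges"])
        m = np.sum(centers * h["pooled"] * width)
        v = np.sum((centers - m) ** 2 * h["pooled"] * width)
        assert m == pytest.approx(mu, abs=0.1)
        assert v == pytest.approx(sd**2, rel=0.05)

    def test_separated_clusters_make_the_pooled_histogram_bimodal(self, rng):
        x = np.concatenate(
            [rng.normal(0, 2, 20_000), rng.normal(30, 2, 20_000)]
        )
        ens = make_ensemble([x] * 2)
        h = energy_histogram(ens, bins=60)
        p = h["pooled"]
        interior_maxima = np.sum(
            (p[1:-1] > p[:-2]) & (p[1:-1] > p[2:]) & (p[1:-1] > 0.2 * p.max())
        )
        assert interior_maxima == 2


class TestEnsembleValidation:
    def test_mixed_temperatures_rejected(self):
        t1 = make_traj(np.zeros(10), T=300.0)
        t2 = make_traj(np.zeros(10), T=320.0)
        with pytest.raises(ValueError):
            StateEnsemble(trajectories=[t1, t2])

    def test_nonuniform_time_step_rejected(self):
        with pytest.raises(ValueError):
            EnergyTrajectory(
                times=np.array([0.0, 10.0, 25.0]),
                energies=np.zeros(3),
                temperature=300.0,
            )
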