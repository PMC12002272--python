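"""Case construction, the simulation-summary distance, and the ABC-SMC engine."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from demicdyn import (ABCBudget, CaseConfig, ParameterSet, Priors, build_case,
                      distance, hpdi, multi_start, rejection_stage,
                      simulate_candidate, smc_run, summarize)
from demicdyn.config import SAMPLED_NAMES
from demicdyn.inference import ObservedCase, _perturb, fit
from demicdyn.radiocarbon import SPD
from demicdyn.synthetic import generate_dataset, identity_curve

TINY = ABCBudget(n_sims=300, keep=40, stages=2, starts=1, batch=128)


@pytest.fixture(scope="module")
def known_theta(priors):
    mid = priors.midpoint()
    return ParameterSet.from_dict({k: mid[k] for k in
                                   ("gamma_hg", "gamma_f", "mu", "delta_hg",
                                    "delta_f", "eta")})


@pytest.fixture(scope="module")
def synth_case(known_theta, ident_curve):
    rng = np.random.default_rng(101)
    dates, truth = generate_dataset(known_theta, 0.25, 100, 800, ident_curve, rng)
    case = build_case(dates, ident_curve, CaseConfig(), rng)
    return case, truth


class TestBuildCase:
    def test_window_opens_100y_before_earliest_farming_date(self, sharp_curve):
        # two precise farming dates and matching foragers; identity curve with
        # negligible error makes the median calibrated year ~ the CRA itself
        dates = pd.DataFrame({
            "lab_id": ["f1", "f2", "h1", "h2", "h3"],
            "cra": [7550.0, 7200.0, 7500.0, 7300.0, 7100.0],
            "sd": [20.0] * 5,
            "label": ["farmer", "farmer", "hg", "hg", "hg"],
        })
        case = build_case(dates, sharp_curve, CaseConfig(end_bp=7000.0),
                          np.random.default_rng(0))
        assert case.window[0] == pytest.approx(7650.0, abs=1.0)
        assert case.window[1] == 7000.0

    def test_kf_ratio_follows_spd_peak_heights(self, synth_case):
        case, _ = synth_case
        assert case.kf_ratio == pytest.approx(
            case.spd_f.density.max() / case.spd_hg.density.max())
        assert case.kf_ratio > 0

    def test_overlong_errors_filtered_out_entirely(self, sharp_curve):
        dates = pd.DataFrame({
            "lab_id": ["f1", "h1"], "cra": [7500.0, 7400.0],
            "sd": [150.0, 40.0], "label": ["farmer", "hg"],
        })
        with pytest.raises(ValueError):
            build_case(dates, sharp_curve, CaseConfig(end_bp=7000.0))

    def test_needs_at_least_one_farming_date(self, sharp_curve):
        dates = pd.DataFrame({"lab_id": ["h1"], "cra": [7400.0],
                              "sd": [40.0], "label": ["hg"]})
        with pytest.raises(ValueError):
            build_case(dates, sharp_curve)


class TestDistance:
    def _spd(self, dens):
        dens = np.asarray(dens, dtype=float)
        grid = np.arange(6000, 6000 - len(dens), -1, dtype=float)
        return SPD(cal_bp=grid, density=dens, n_dates=1)

    def test_identity_gives_zero(self):
        a = self._spd([0.1, 0.4, 0.2])
        assert distance((a, a), (a, a)) == 0.0

    def test_single_coordinate_difference(self):
        a = self._spd([0.1, 0.4, 0.2])
        b = self._spd([0.1, 0.4, 0.2 + 0.07])
        assert distance((a, b), (a, a)) == pytest.approx(0.07)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(2)
        v = [rng.random(30) for _ in range(4)]
        eps = distance((self._spd(v[0]), self._spd(v[1])),
                       (self._spd(v[2]), self._spd(v[3])))
        brute = (np.sqrt(np.sum((v[0] - v[2]) ** 2))
                 + np.sqrt(np.sum((v[1] - v[3]) ** 2)))
        assert eps == pytest.approx(brute, rel=1e-12)

    def test_grid_mismatch_rejected(self):
        a = self._spd([0.1, 0.4, 0.2])
        b = self._spd([0.1, 0.4])
        with pytest.raises(ValueError):
            distance((a, a), (b, b))


class TestSimulateCandidate:
    def test_zero_initial_farmers_give_empty_farmer_spd(self, synth_case, known_theta):
        case, _ = synth_case
        _, spd_f = simulate_candidate(known_theta, rho=0.0, case=case,
                                      rng=np.random.default_rng(0))
        assert np.all(spd_f.density == 0.0)

    def test_deterministic_under_seed(self, synth_case, known_theta):
        case, _ = synth_case
        a = simulate_candidate(known_theta, 0.25, case, np.random.default_rng(7))
        b = simulate_candidate(known_theta, 0.25, case, np.random.default_rng(7))
        assert np.array_equal(a[0].density, b[0].density)
        assert np.array_equal(a[1].density, b[1].density)

    def test_large_sample_converges_to_model_density(self, ident_curve, known_theta):
        """With many dates and tiny errors the simulated SPD approaches the
        normalised trajectory density."""
        from demicdyn import InitialConditions, integrate

        rho, hg0 = 0.25, 1.0
        horizon = 600
        start_bp = 8000.0
        grid = np.arange(start_bp, start_bp - horizon - 1, -1)
        placeholder = SPD(cal_bp=grid, density=np.zeros(len(grid)), n_dates=10_000)
        case = ObservedCase(curve=ident_curve, window=(start_bp, start_bp - horizon),
                            spd_hg=placeholder, spd_f=placeholder,
                            n_dates=10_000, kf_ratio=1.5,
                            sd_pool=np.array([2.0]))
        sims = []
        for rep in range(25):  # average replicates to push down sampling noise
            spd_hg, spd_f = simulate_candidate(known_theta, rho, case,
                                               np.random.default_rng(12 + rep),
                                               hg0=hg0)
            sims.append(spd_hg.density[::-1] + spd_f.density[::-1])
        traj = integrate(known_theta, InitialConditions(hg0=hg0, f0=rho * hg0,
                                                        k_hg=hg0, k_f=1.5),
                         horizon)
        # calibrated mass leaks across the window edges (a property of any
        # windowed SPD), so convergence to the model density is assessed on
        # the interior, away from the edge kernels
        core = slice(60, -60)
        total_model = (traj.hg + traj.f)[core]
        total_model = total_model / total_model.sum()
        total_sim = np.mean(sims, axis=0)[core]
        total_sim /= total_sim.sum()
        assert np.abs(total_sim - total_model).sum() < 0.05


class TestRejection:
    def test_all_retained_when_budget_equals_keep(self, synth_case):
        case, _ = synth_case
        out = rejection_stage(case, n_sims=50, keep=50,
                              rng=np.random.default_rng(0))
        assert len(out) == 50
        assert (out["stage"] == 0).all()

    def test_keep_one_returns_global_minimum(self, synth_case):
        case, _ = synth_case
        rng_a = np.random.default_rng(5)
        best = rejection_stage(case, n_sims=200, keep=1, rng=rng_a)
        rng_b = np.random.default_rng(5)
        full = rejection_stage(case, n_sims=200, keep=200, rng=rng_b)
        assert best["epsilon"].iloc[0] == pytest.approx(full["epsilon"].min())

    def test_retained_distances_dominate_below_prior_distances(self, synth_case):
        case, _ = synth_case
        rng = np.random.default_rng(6)
        kept = rejection_stage(case, n_sims=600, keep=60, rng=rng)
        reference = rejection_stage(case, n_sims=300, keep=300,
                                    rng=np.random.default_rng(7))
        test = stats.mannwhitneyu(kept["epsilon"], reference["epsilon"],
                                  alternative="less")
        assert test.pvalue < 0.01

    def test_particles_respect_prior_support(self, synth_case, priors):
        case, _ = synth_case
        out = rejection_stage(case, n_sims=200, keep=100,
                              rng=np.random.default_rng(8))
        for name in SAMPLED_NAMES:
            assert priors.contains(name, out[name]).all()


class TestSMC:
    def test_thresholds_non_increasing_and_support_closed(self, synth_case, priors):
        case, _ = synth_case
        rng = np.random.default_rng(9)
        cands = rejection_stage(case, n_sims=TINY.n_sims, keep=TINY.keep, rng=rng)
        particles, hist = smc_run(case, cands, stages=3, rng=rng, batch=TINY.batch)
        eps = hist["epsilon_threshold"].to_numpy()
        assert np.all(np.diff(eps) <= 0)
        assert (particles["epsilon"] < eps[-1]).all()
        for name in SAMPLED_NAMES:
            assert priors.contains(name, particles[name]).all()

    def test_kernel_moves_zero_valued_parameters(self, priors):
        """The multiplicative kernel is degenerate at 0; the jitter floor
        keeps such particles mobile while staying inside the prior."""
        rng = np.random.default_rng(10)
        out = _perturb(np.zeros(500), priors.bounds("delta_hg"),
                       priors.width("delta_hg"), rng)
        assert (out >= 0).all() and (out <= 0.04).all()
        assert np.count_nonzero(out) > 0
        assert out.max() <= 1e-4 * priors.width("delta_hg")

    def test_stall_raises_with_diagnostics(self, synth_case):
        case, _ = synth_case
        rng = np.random.default_rng(11)
        cands = rejection_stage(case, n_sims=120, keep=30, rng=rng)
        cands.loc[:, "epsilon"] = 0.0  # impossible tolerance: nothing can beat it
        with pytest.raises(RuntimeError, match="stalled"):
            smc_run(case, cands, stages=1, rng=rng, batch=64,
                    max_attempts_per_stage=300)


class TestMultiStart:
    def test_single_start_equals_direct_run(self, synth_case):
        case, _ = synth_case
        pooled, hist = multi_start(case, seed=3, budget=TINY)
        from demicdyn.config import child_rngs

        direct, _ = fit(case, child_rngs(3, 1)[0], TINY)
        assert np.allclose(np.sort(pooled["epsilon"]), np.sort(direct["epsilon"]))

    def test_pooled_best_dominates_every_start(self, synth_case):
        case, _ = synth_case
        budget = ABCBudget(n_sims=300, keep=40, stages=2, starts=3, batch=128)
        pooled, hist = multi_start(case, seed=4, budget=budget)
        assert len(pooled) == budget.keep
        assert hist["start"].nunique() == 3
        per_start_best = hist.groupby("start").size()  # all starts contributed stages
        assert (per_start_best == budget.stages).all()


class TestSummaries:
    def test_hpdi_matches_normal_quantiles(self):
        rng = np.random.default_rng(12)
        lo, hi = hpdi(rng.normal(size=100_000), 0.95)
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_degenerate_particles_give_zero_width(self, synth_case):
        case, _ = synth_case
        row = {name: 0.01 for name in SAMPLED_NAMES}
        row.update(rho=0.2, hg0=1.0, epsilon=0.1, stage=1)
        particles = pd.DataFrame([row] * 10)
        out = summarize(particles, case, np.random.default_rng(0), n_predictive=0)
        tbl = out.params
        assert (tbl["hpdi_hi"] - tbl["hpdi_lo"] == 0).all()

    def test_certain_extinction_reported_as_one(self, synth_case):
        case, _ = synth_case
        # overwhelming HG mortality with no HG growth: extinction in-window
        row = dict(gamma_hg=0.001, gamma_f=0.035, mu=0.035, delta_hg=0.04,
                   delta_f=0.0, eta=0.3, rho=0.4, hg0=1.0, epsilon=0.1, stage=1)
        particles = pd.DataFrame([row] * 5)
        out = summarize(particles, case, np.random.default_rng(0), n_predictive=0)
        assert out.extinction_fraction == 1.0
        assert (out.event_times["t_overtake"] >= 1).all()

    def test_predictive_bands_cover_observed_on_fitted_case(self, synth_case):
        case, _ = synth_case
        particles, _ = multi_start(case, seed=5, budget=TINY)
        out = summarize(particles, case, np.random.default_rng(1),
                        n_predictive=len(particles))
        pred = out.predictive
        inside_hg = ((pred["hg_obs"] >= pred["hg_lo"])
                     & (pred["hg_obs"] <= pred["hg_hi"])).mean()
        inside_f = ((pred["f_obs"] >= pred["f_lo"])
                    & (pred["f_obs"] <= pred["f_hi"])).mean()
        assert inside_hg > 0.9
        assert inside_f > 0.9
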