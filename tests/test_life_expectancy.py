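import numpy as np
import pytest

from conftest import random_params
from needsmsm.estimation import fit_msm
from needsmsm.intensities import ModelSpec, TransitionParams
from needsmsm.life_expectancy import (
    LE_QUANTITIES,
    initial_state_distribution,
    le_confidence_intervals,
    life_expectancies,
    occupancy,
    percent_unmet,
    state_specific_le,
)
from needsmsm.panel import panel_from_records
from needsmsm.simulate import SimulationConfig, generate_panel

Z0 = np.zeros(5)


def _death_only(lam: float) -> TransitionParams:
    """Single living state in effect: no needs transitions, no unmet-death."""
    return TransitionParams.from_dicts(
        {(2, 3): np.log(lam), (1, 2): -300.0, (2, 1): -300.0, (1, 3): -300.0}
    )


def test_occupancy_stays_put_without_intensities():
    p = TransitionParams(beta0=np.full(4, -300.0), xi=np.zeros(4), beta=np.zeros((4, 5)))
    grid = occupancy(p, Z0, 60.0, h=0.5, max_age=80.0)
    assert np.allclose(grid.occ[:, 0, 0], 1.0)
    assert np.allclose(grid.occ[:, 1, 1], 1.0)


def test_death_only_survival_matches_exponential():
    lam = 0.05
    grid = occupancy(_death_only(lam), Z0, 60.0, h=0.05, max_age=115.0)
    t = grid.ages - 60.0
    assert np.abs(grid.occ[:, 1, 1] - np.exp(-lam * t)).max() < 1e-6


def test_truncated_exponential_life_expectancy_closed_form():
    lam, T = 0.05, 55.0
    grid = occupancy(_death_only(lam), Z0, 60.0, h=0.02, max_age=115.0)
    le = state_specific_le(grid, 2, 2)
    expected = (1 - np.exp(-lam * T)) / lam  # ~18.721 years
    assert le == pytest.approx(expected, rel=1e-6)
    assert expected == pytest.approx(18.721, abs=5e-4)


def test_zero_hazard_life_expectancy_hits_truncation_bound():
    p = TransitionParams(beta0=np.full(4, -300.0), xi=np.zeros(4), beta=np.zeros((4, 5)))
    grid = occupancy(p, Z0, 60.0, h=0.5, max_age=115.0)
    assert state_specific_le(grid, 1, 1) == pytest.approx(55.0, rel=1e-12)
    assert state_specific_le(grid, 2, 2) == pytest.approx(55.0, rel=1e-12)


def test_state_specific_les_add_to_total_survival_integral(rng):
    p = random_params(rng)
    grid = occupancy(p, Z0, 60.0, h=0.25, max_age=115.0)
    for r in (1, 2):
        total = state_specific_le(grid, r, 1) + state_specific_le(grid, r, 2)
        survival = np.trapezoid(grid.occ[:, r - 1, :2].sum(axis=1), grid.ages)
        assert total == pytest.approx(survival, rel=1e-12)


def test_occupancy_h_halving_converges_second_order(rng):
    p = random_params(rng)
    ref = occupancy(p, Z0, 60.0, h=1 / 64, max_age=90.0)
    errs = []
    for h in (2.0, 1.0, 0.5):
        g = occupancy(p, Z0, 60.0, h=h, max_age=90.0)
        idx = np.searchsorted(ref.ages, g.ages[:-1])
        errs.append(np.abs(g.occ[:-1] - ref.occ[idx]).max())
    assert errs[0] / errs[1] > 2.5
    assert errs[1] / errs[2] > 2.5


def test_initial_distribution_degenerate_baseline():
    panel = panel_from_records(
        [dict(subject_id=s, wave=0, age=60 + i, state=2) for i, s in enumerate("abcd")]
    )
    assert initial_state_distribution(panel, 65.0) == (0.0, 1.0)


def test_initial_distribution_recovers_logistic_rule():
    rng = np.random.default_rng(7)
    ages = rng.uniform(45, 85, size=4000)
    logit = -3.0 + 0.02 * ages
    unmet = rng.random(4000) < 1 / (1 + np.exp(-logit))
    panel = panel_from_records(
        [dict(subject_id=f"s{i}", wave=0, age=a, state=1 if u else 2)
         for i, (a, u) in enumerate(zip(ages, unmet))]
    )
    for age in (50.0, 60.0, 80.0):
        pi1, pi2 = initial_state_distribution(panel, age)
        true = 1 / (1 + np.exp(3.0 - 0.02 * age))
        assert pi1 + pi2 == pytest.approx(1.0, abs=1e-12)
        assert pi1 == pytest.approx(true, abs=0.03)


def test_life_expectancy_identities(fitted, sim_panel):
    z = sim_panel.covariate_means().as_array()
    le = life_expectancies(fitted, sim_panel, z, 60.0)
    assert le.total == pytest.approx(le.marginal_unmet + le.marginal_met, rel=1e-12)
    assert le.pct_unmet == pytest.approx(100 * le.marginal_unmet / le.total, rel=1e-12)
    assert (le.e >= 0).all()
    assert le.total <= 55.0
    assert le.pi.sum() == pytest.approx(1.0)


def test_life_expectancy_accepts_explicit_initial_distribution(fitted):
    le = life_expectancies(fitted, (0.3, 0.7), Z0, 60.0)
    assert np.allclose(le.pi, [0.3, 0.7])
    assert le.marginal_unmet == pytest.approx(0.3 * le.e[0, 0] + 0.7 * le.e[1, 0], rel=1e-12)


def test_percent_unmet_requires_positive_total():
    assert percent_unmet(4.2, 23.6) == pytest.approx(17.8, abs=0.05)
    with pytest.raises(ValueError):
        percent_unmet(1.0, 0.0)


def test_fine_grid_reference_for_homogeneous_two_state_model(rng):
    """At h = 0.5 the LEs sit within 0.01 years of an h = 0.001 reference."""
    p = TransitionParams.from_dicts(
        {(1, 2): np.log(0.3), (2, 1): np.log(0.1), (1, 3): np.log(0.04), (2, 3): np.log(0.02)}
    )
    fine = occupancy(p, Z0, 60.0, h=0.001, max_age=100.0)
    coarse = occupancy(p, Z0, 60.0, h=0.5, max_age=100.0)
    for r in (1, 2):
        for s in (1, 2):
            assert state_specific_le(coarse, r, s) == pytest.approx(
                state_specific_le(fine, r, s), abs=0.01
            )


def test_higher_death_intensities_reduce_total_le(rng):
    p = random_params(rng)
    worse = TransitionParams(
        beta0=p.beta0 + np.array([0.0, 0.0, 0.7, 0.7]), xi=p.xi, beta=p.beta
    )
    le = life_expectancies(p, (0.2, 0.8), Z0, 60.0)
    le_worse = life_expectancies(worse, (0.2, 0.8), Z0, 60.0)
    assert le_worse.total < le.total


def test_riskier_starting_state_shortens_life(rng):
    """When the unmet state carries the higher death intensity, starting
    in it yields the shorter total residual life."""
    p = TransitionParams.from_dicts(
        {(1, 2): np.log(0.3), (2, 1): np.log(0.1), (1, 3): np.log(0.15), (2, 3): np.log(0.03)}
    )
    le = life_expectancies(p, (0.5, 0.5), Z0, 60.0)
    assert le.e[0].sum() < le.e[1].sum()


def test_pct_unmet_invariant_to_time_rescaling(rng):
    """Measuring time in months instead of years leaves %UMLE unchanged."""
    p = random_params(rng)
    hom = TransitionParams(beta0=p.beta0, xi=np.zeros(4), beta=p.beta)
    monthly = TransitionParams(beta0=hom.beta0 - np.log(12.0), xi=np.zeros(4), beta=hom.beta)
    le_y = life_expectancies(hom, (0.2, 0.8), Z0, 60.0, h=0.5, max_age=115.0)
    le_m = life_expectancies(monthly, (0.2, 0.8), Z0, 60.0 * 12, h=6.0, max_age=115.0 * 12)
    assert le_m.total == pytest.approx(12 * le_y.total, rel=1e-9)
    assert le_m.pct_unmet == pytest.approx(le_y.pct_unmet, rel=1e-9)


def test_zero_vcov_collapses_cis_to_point(fitted, sim_panel):
    z = sim_panel.covariate_means().as_array()
    degenerate = type(fitted)(
        spec=fitted.spec, params=fitted.params, theta=fitted.theta,
        vcov=np.zeros_like(fitted.vcov), minus2loglik=fitted.minus2loglik,
        k=fitted.k, converged=True, gradient_norm=0.0,
        n_subjects=fitted.n_subjects, n_pairs=fitted.n_pairs, cfg=fitted.cfg,
    )
    ci = le_confidence_intervals(degenerate, sim_panel, z, 60.0, B=50, seed=1)
    for q in LE_QUANTITIES:
        assert ci.lower[q] == pytest.approx(ci.point[q], abs=1e-9)
        assert ci.upper[q] == pytest.approx(ci.point[q], abs=1e-9)


def test_quadrupled_vcov_roughly_doubles_ci_width(sim_panel):
    """Delta-method check on a smooth, well-identified model: scaling the
    covariance by 4 about doubles the simulation CI widths."""
    fit = fit_msm(sim_panel, ModelSpec.homogeneous(), maxiter=80)
    z = sim_panel.covariate_means().as_array()
    wide = type(fit)(
        spec=fit.spec, params=fit.params, theta=fit.theta,
        vcov=4.0 * fit.vcov, minus2loglik=fit.minus2loglik,
        k=fit.k, converged=True, gradient_norm=0.0,
        n_subjects=fit.n_subjects, n_pairs=fit.n_pairs, cfg=fit.cfg,
    )
    ci1 = le_confidence_intervals(fit, sim_panel, z, 60.0, B=4000, seed=9)
    ci2 = le_confidence_intervals(wide, sim_panel, z, 60.0, B=4000, seed=9)
    w1 = ci1.upper["total"] - ci1.lower["total"]
    w2 = ci2.upper["total"] - ci2.lower["total"]
    assert w2 / w1 == pytest.approx(2.0, rel=0.2)


def test_ci_requires_enough_draws_and_psd_vcov(fitted, sim_panel):
    z = sim_panel.covariate_means().as_array()
    with pytest.raises(ValueError, match="B"):
        le_confidence_intervals(fitted, sim_panel, z, 60.0, B=1)
    broken = type(fitted)(
        spec=fitted.spec, params=fitted.params, theta=fitted.theta,
        vcov=fitted.vcov - 1e-3 * np.eye(fitted.k), minus2loglik=fitted.minus2loglik,
        k=fitted.k, converged=True, gradient_norm=0.0,
        n_subjects=fitted.n_subjects, n_pairs=fitted.n_pairs, cfg=fitted.cfg,
    )
    with pytest.raises(ValueError, match="positive semi-definite"):
        le_confidence_intervals(broken, sim_panel, z, 60.0, B=50, seed=0)
    # the repair flag clips the spectrum and proceeds
    le_confidence_intervals(broken, sim_panel, z, 60.0, B=50, seed=0, repair_vcov=True)


def test_simulation_ci_covers_true_total_le():
    """Simulation-based 95% CIs attain roughly nominal coverage for the
    total LE over repeated small studies (homogeneous, covariate-free)."""
    truth = TransitionParams.from_dicts(
        {(1, 2): np.log(0.6), (2, 1): np.log(0.12), (1, 3): np.log(0.05), (2, 3): np.log(0.025)}
    )
    pi = (0.15, 0.85)
    true_total = life_expectancies(truth, pi, Z0, 60.0, h=0.25).total
    spec = ModelSpec.homogeneous()
    cfg = SimulationConfig(
        n_subjects=500, true_params=truth,
        p_edu=(1.0, 0.0, 0.0), p_multimorbidity=(1.0, 0.0, 0.0), p_female=0.0,
    )
    hits = 0
    R = 25
    for r in range(R):
        panel, _ = generate_panel(cfg, seed=1000 + r)
        fit = fit_msm(panel, spec, maxiter=80)
        ci = le_confidence_intervals(fit, pi, Z0, 60.0, B=400, seed=r, h=0.25)
        if ci.lower["total"] <= true_total <= ci.upper["total"]:
            hits += 1
    assert hits / R >= 0.80  # nominal 0.95 minus 3 binomial SDs at R = 25
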