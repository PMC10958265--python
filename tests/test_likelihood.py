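import numpy as np
import pytest
import scipy.integrate
import scipy.linalg

from conftest import random_params
from needsmsm.intensities import TRANSITIONS, TransitionParams, build_generator
from needsmsm.likelihood import (
    BandingConfig,
    _expm_living,
    _expm_living_grad,
    expm_probability,
    interval_probability,
    pair_log_likelihood,
    pair_log_likelihoods,
    total_neg2_loglik,
)
from needsmsm.panel import Observation, panel_from_records

Z0 = np.zeros(5)


def _random_generator(rng):
    q = rng.uniform(0.01, 1.0, size=4)
    p = TransitionParams.from_dicts({t: np.log(r) for t, r in zip(TRANSITIONS, q)})
    return build_generator(p, 60.0, Z0)


def test_expm_probability_at_zero_is_identity(rng):
    Q = _random_generator(rng)
    assert np.allclose(expm_probability(Q, 0.0).P, np.eye(3))


def test_expm_probability_death_only_closed_form():
    p = TransitionParams.from_dicts(
        {(2, 3): np.log(0.1), (1, 2): -300, (2, 1): -300, (1, 3): -300}
    )
    Q = build_generator(p, 60.0, Z0)
    P = expm_probability(Q, 2.0)
    assert P[2, 3] == pytest.approx(1 - np.exp(-0.2), rel=1e-9)


def test_expm_probability_rejects_negative_time(rng):
    with pytest.raises(ValueError):
        expm_probability(_random_generator(rng), -0.5)


def test_expm_matches_kolmogorov_forward_integration(rng):
    """Matrix exponential vs an ODE solve of dP/dt = P Q."""
    for _ in range(20):
        Q = _random_generator(rng)
        P = expm_probability(Q, 2.0).P
        sol = scipy.integrate.solve_ivp(
            lambda t, y: (y.reshape(3, 3) @ Q).ravel(),
            (0.0, 2.0),
            np.eye(3).ravel(),
            rtol=1e-11, atol=1e-12, dense_output=False,
        )
        P_ode = sol.y[:, -1].reshape(3, 3)
        assert np.abs(P - P_ode).max() < 1e-8


def test_closed_form_living_block_matches_scipy_expm(rng):
    """The vectorised 2x2 exponential agrees with the general dense path."""
    rates = rng.uniform(0.001, 2.0, size=(50, 4))
    dt = rng.uniform(0.0, 3.0, size=50)
    E = _expm_living(rates[:, 0], rates[:, 1], rates[:, 2], rates[:, 3], dt)
    for i in range(50):
        q12, q21, q13, q23 = rates[i]
        A = np.array([[-(q12 + q13), q12], [q21, -(q21 + q23)]])
        assert np.allclose(E[i], scipy.linalg.expm(dt[i] * A), atol=1e-12)


def test_living_block_gradient_matches_finite_differences(rng):
    rates = rng.uniform(0.01, 1.5, size=(20, 4))
    dt = rng.uniform(0.1, 2.0, size=20)
    _, dE = _expm_living_grad(rates[:, 0], rates[:, 1], rates[:, 2], rates[:, 3], dt)
    eps = 1e-7
    for k in range(4):
        bumped = rates.copy()
        bumped[:, k] += eps
        Ep = _expm_living(bumped[:, 0], bumped[:, 1], bumped[:, 2], bumped[:, 3], dt)
        bumped[:, k] -= 2 * eps
        Em = _expm_living(bumped[:, 0], bumped[:, 1], bumped[:, 2], bumped[:, 3], dt)
        fd = (Ep - Em) / (2 * eps)
        assert np.abs(dE[k] - fd).max() < 1e-6


def test_interval_probability_zero_length_is_identity(rng):
    p = random_params(rng)
    P = interval_probability(p, Z0, 63.0, 63.0)
    assert np.allclose(P.P, np.eye(3))


def test_interval_probability_homogeneous_shortcut_is_exact(rng):
    p = random_params(rng)
    hom = TransitionParams(beta0=p.beta0, xi=np.zeros(4), beta=p.beta)
    P = interval_probability(hom, Z0, 60.0, 67.3)
    Q = build_generator(hom, 60.0, Z0)
    assert np.abs(P.P - expm_probability(Q, 7.3).P).max() < 1e-12


def test_interval_probability_converges_at_second_order(rng):
    """Midpoint freezing: halving h shrinks the error roughly 4-fold."""
    p = random_params(rng)
    ref = interval_probability(p, Z0, 60.0, 64.0, BandingConfig(h_lik=1 / 256)).P
    errs = []
    for h in (2.0, 1.0, 0.5, 0.25):
        P = interval_probability(p, Z0, 60.0, 64.0, BandingConfig(h_lik=h)).P
        errs.append(np.abs(P - ref).max())
    rates = [errs[i] / errs[i + 1] for i in range(3)]
    assert all(2.5 < r < 6.0 for r in rates), rates
    assert errs[-1] < 1e-5


def test_chapman_kolmogorov_at_band_boundary(rng):
    p = random_params(rng)
    cfg = BandingConfig(h_lik=1.0)
    P_ab = interval_probability(p, Z0, 60.0, 62.0, cfg).P
    P_bc = interval_probability(p, Z0, 62.0, 65.0, cfg).P
    P_ac = interval_probability(p, Z0, 60.0, 65.0, cfg).P
    assert np.abs(P_ab @ P_bc - P_ac).max() < 1e-10


def test_death_probability_monotone_in_interval_length(rng):
    p = random_params(rng)
    hom = TransitionParams(beta0=p.beta0, xi=np.zeros(4), beta=p.beta)
    last = 0.0
    for t in np.linspace(0.1, 8.0, 25):
        P = interval_probability(hom, Z0, 60.0, 60.0 + t)
        assert P[1, 3] >= last - 1e-12
        last = P[1, 3]


def _obs(sid, wave, age, state, ddk=None):
    return Observation(subject_id=sid, wave=wave, age=age, state=state, death_date_known=ddk)


def test_pair_zero_length_same_state_is_log_one(rng):
    p = random_params(rng)
    ll = pair_log_likelihood(_obs("a", 0, 60.0, 2), _obs("a", 1, 60.0, 2), p)
    assert ll == pytest.approx(0.0, abs=1e-12)


def test_pair_from_dead_state_raises(rng):
    p = random_params(rng)
    with pytest.raises(ValueError, match="living"):
        pair_log_likelihood(_obs("a", 0, 60.0, 3, True), _obs("a", 1, 62.0, 3, True), p)


def test_exact_death_density_is_derivative_of_cumulative(rng):
    """d/dt P_r3(t) = sum_s P_rs(t) q_s3(t): the exact-death contribution
    equals the central difference of the interval death probability.
    Uses the time-homogeneous model, for which the interval probability
    is a single exact matrix exponential."""
    p = random_params(rng)
    hom = TransitionParams(beta0=p.beta0, xi=np.zeros(4), beta=p.beta)
    cfg = BandingConfig(h_lik=0.25)
    t0, t1 = 60.0, 63.7
    ll = pair_log_likelihood(_obs("a", 0, t0, 2), _obs("a", 1, t1, 3, True), hom, cfg)
    eps = 1e-5
    hi = interval_probability(hom, Z0, t0, t1 + eps, cfg)[2, 3]
    lo = interval_probability(hom, Z0, t0, t1 - eps, cfg)[2, 3]
    assert np.exp(ll) == pytest.approx((hi - lo) / (2 * eps), rel=1e-6)


def test_censored_alive_sums_living_probabilities(rng):
    p = random_params(rng)
    ll = pair_log_likelihood(_obs("a", 0, 60.0, 1), _obs("a", 1, 62.0, 0), p)
    P = interval_probability(p, Z0, 60.0, 62.0)
    assert np.exp(ll) == pytest.approx(P[1, 1] + P[1, 2], rel=1e-10)


def test_interval_death_convention_uses_cumulative_probability(rng):
    p = random_params(rng)
    cfg = BandingConfig(death_convention="interval")
    ll = pair_log_likelihood(_obs("a", 0, 60.0, 2), _obs("a", 1, 62.0, 3, True), p, cfg)
    P = interval_probability(p, Z0, 60.0, 62.0)
    assert np.exp(ll) == pytest.approx(P[2, 3], rel=1e-10)


def _tiny_panel():
    rows = [
        dict(subject_id="a", wave=0, age=61.0, state=2),
        dict(subject_id="a", wave=1, age=63.1, state=1),
        dict(subject_id="a", wave=2, age=65.0, state=1),
        dict(subject_id="b", wave=0, age=72.0, state=1),
        dict(subject_id="b", wave=1, age=74.2, state=3, death_date_known=1),
        dict(subject_id="c", wave=0, age=55.5, state=2),
        dict(subject_id="c", wave=1, age=57.4, state=2),
    ]
    return panel_from_records(rows)


def test_total_neg2_loglik_single_pair_and_additivity(rng):
    p = random_params(rng)
    panel = _tiny_panel()
    pairs = panel.pairs()
    per_pair = pair_log_likelihoods(pairs, p)
    assert total_neg2_loglik(panel, p) == pytest.approx(-2 * per_pair.sum(), rel=1e-12)
    # additivity over subjects
    total = 0.0
    for sid in panel.subject_ids():
        sub = panel.df[panel.df.subject_id == sid]
        from needsmsm.panel import PanelDataset

        total += total_neg2_loglik(PanelDataset(sub), p)
    assert total == pytest.approx(total_neg2_loglik(panel, p), rel=1e-12)


def test_total_neg2_loglik_matches_fine_discrete_chain(rng):
    """Brute-force oracle: a discrete-time chain with step 0.001 years,
    transition matrix I + Q dt at each step, reproduces each pair's
    probability and hence the panel's -2 log-likelihood."""
    p = random_params(rng)
    panel = _tiny_panel()
    pairs = panel.pairs()
    dt = 0.001

    def chain_prob(age0, age1, z):
        P = np.eye(3)
        steps = int(round((age1 - age0) / dt))
        for k in range(steps):
            Q = build_generator(p, age0 + (k + 0.5) * dt, z)
            P = P @ (np.eye(3) + Q * dt)
        return P

    ll = 0.0
    for i in range(pairs.n):
        P = chain_prob(pairs.from_age[i], pairs.to_age[i], pairs.z[i])
        r = pairs.from_state[i]
        s = pairs.to_state[i]
        if s in (1, 2):
            ll += np.log(P[r - 1, s - 1])
        else:  # exactly dated death: density at the end age
            q13 = float(np.exp(p.beta0[2] + p.xi[2] * (pairs.to_age[i] - 60) + p.beta[2] @ pairs.z[i]))
            q23 = float(np.exp(p.beta0[3] + p.xi[3] * (pairs.to_age[i] - 60) + p.beta[3] @ pairs.z[i]))
            ll += np.log(P[r - 1, 0] * q13 + P[r - 1, 1] * q23)
    oracle = -2 * ll
    ours = total_neg2_loglik(panel, p, BandingConfig(h_lik=0.5))
    assert ours == pytest.approx(oracle, rel=2e-4)


def test_analytic_gradient_matches_batched_finite_differences(rng):
    """The reverse-mode gradient agrees with central differences of the
    batch likelihood evaluator on a small simulated panel."""
    from needsmsm.intensities import ModelSpec
    from needsmsm.likelihood import batch_neg_loglik, neg_loglik_and_grad
    from needsmsm.simulate import SimulationConfig, generate_panel

    panel, _ = generate_panel(SimulationConfig(n_subjects=150), seed=6)
    pairs = panel.pairs()
    spec = ModelSpec()
    theta = spec.pack(SimulationConfig().true_params) + rng.normal(scale=0.2, size=28)
    b0, xi, be = spec.unpack_batch(theta[None, :])
    nll, g0, gx, gb = neg_loglik_and_grad(pairs, b0[0], xi[0], be[0])
    g = np.concatenate([np.concatenate([[g0[i]], [gx[i]], gb[i]]) for i in range(4)])

    h = 1e-6 * np.maximum(1.0, np.abs(theta))
    pts = np.concatenate([theta + np.diag(h), theta - np.diag(h)])
    B0, XI, BE = spec.unpack_batch(pts)
    vals = batch_neg_loglik(pairs, B0, XI, BE)
    g_fd = (vals[:28] - vals[28:]) / (2 * h)
    assert nll == pytest.approx(batch_neg_loglik(pairs, b0, xi, be)[0], rel=1e-12)
    assert np.abs(g - g_fd).max() < 1e-5


def test_impossible_pair_reports_infinite_likelihood():
    # intensities below the underflow threshold: reaching state 1 has
    # numerically zero probability
    p = TransitionParams(beta0=np.full(4, -700.0), xi=np.zeros(4), beta=np.zeros((4, 5)))
    panel = panel_from_records(
        [dict(subject_id="a", wave=0, age=60.0, state=2),
         dict(subject_id="a", wave=1, age=62.0, state=1)]
    )
    with pytest.warns(RuntimeWarning, match="subject a"):
        assert total_neg2_loglik(panel, p) == np.inf
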