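"""Interval-censored panel likelihood for the three-state model.

Transition probabilities over an interval come from the matrix
exponential of the generator; with Gompertz (age-varying) intensities the
interval is split into bands of width at most ``h_lik`` and Q is frozen
at each band's midpoint age (piecewise-constant approximation, second
order in the band width).

Because state 3 is absorbing, the generator has the block form
``[[A, -A.1], [0, 0]]`` with A the 2x2 living-state block, and
``expm(tQ)`` reduces to the closed-form exponential of a 2x2 matrix.
That closed form, vectorised over observation pairs, is the package's
computational core; the general 3x3 path goes through
:func:`scipy.linalg.expm` and serves as an independent cross-check.

Per-pair contributions:

(a) living endpoint s: ``P[r,s](t0, t1)``;
(b) exactly dated death: ``sum_s P[r,s](t0, t1) * q_s3(t1)`` -- the death
    time is exact but the living state just before death is unknown;
(c) alive-censored, state unknown: ``sum_s P[r,s](t0, t1)``;
and, under the interval death convention or for an undated death,
``P[r,3](t0, t1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.linalg

from .intensities import AGE_REF, TransitionParams
from .panel import (
    STATE_CENSORED_ALIVE,
    STATE_DEAD,
    LIVING_STATES,
    Observation,
    PairArrays,
    PanelDataset,
)

_TINY = 1e-300
_MAX_LP = 200.0  # cap on log intensities: e^200/yr is already "instantaneous"


@dataclass(frozen=True)
class BandingConfig:
    """Numerical settings of the likelihood.

    ``h_lik``: band width (years) of the piecewise-constant approximation.
    ``death_convention``: ``"exact"`` treats dated deaths as exactly
    observed in time (contribution (b) above); ``"interval"`` treats every
    death as having occurred somewhere in the observation interval.
    Deaths whose date is flagged unknown are always interval-censored.
    """

    h_lik: float = 1.0
    death_convention: Literal["exact", "interval"] = "exact"

    def __post_init__(self) -> None:
        if self.h_lik <= 0:
            raise ValueError("h_lik must be positive")
        if self.death_convention not in ("exact", "interval"):
            raise ValueError("death_convention must be 'exact' or 'interval'")


@dataclass(frozen=True)
class ProbabilityMatrix:
    """A 3x3 transition probability matrix over an age interval."""

    P: np.ndarray
    interval: tuple[float, float]

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        object.__setattr__(self, "P", P)
        if P.shape != (3, 3):
            raise ValueError("P must be 3x3")
        if (P < -1e-10).any() or (P > 1 + 1e-10).any():
            raise ValueError("entries must lie in [0, 1]")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("rows must sum to 1")
        if not np.allclose(P[2], [0.0, 0.0, 1.0], atol=1e-12):
            raise ValueError("death row must be (0, 0, 1)")

    def __getitem__(self, idx) -> float:
        r, s = idx
        return float(self.P[r - 1, s - 1])


# -- matrix exponentials -------------------------------------------------

def expm_probability(Q: np.ndarray, t: float) -> ProbabilityMatrix:
    """P = expm(tQ) for a 3x3 generator (general path via scipy)."""
    if t < 0:
        raise ValueError("t must be non-negative")
    Q = np.asarray(Q, dtype=float)
    P = scipy.linalg.expm(t * Q)
    P = np.clip(P, 0.0, 1.0)
    P /= P.sum(axis=1, keepdims=True)
    return ProbabilityMatrix(P=P, interval=(0.0, float(t)))


def _expm_living(q12, q21, q13, q23, dt) -> np.ndarray:
    """Closed-form exp(dt*A) for the 2x2 living block, vectorised.

    A = [[-(q12+q13), q12], [q21, -(q21+q23)]] indexed (unmet, met).
    Uses the traceless decomposition A = (trA/2) I + M with M^2 = Delta^2 I,
    so exp(dt A) = e^{tr} (cosh(Delta) I + sinch(Delta) M); both exponents
    in e^{tr +/- Delta} are <= 0, so the evaluation cannot overflow.
    """
    q12, q21, q13, q23, dt = np.broadcast_arrays(q12, q21, q13, q23, dt)
    a = -(q12 + q13)
    d = -(q21 + q23)
    half_tr = 0.5 * (a + d) * dt
    delta = 0.5 * dt * np.sqrt((a - d) ** 2 + 4.0 * q12 * q21)
    # both exponents are <= 0 in exact arithmetic; clamp the rounding
    # residue that huge rates leave after the cancellation
    e_plus = np.exp(np.minimum(half_tr + delta, 0.0))
    e_minus = np.exp(np.minimum(half_tr - delta, 0.0))
    ch = 0.5 * (e_plus + e_minus)
    small = delta < 1e-6
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(
            small,
            np.exp(half_tr) * (1.0 + delta**2 / 6.0),
            (e_plus - e_minus) / np.maximum(2.0 * delta, _TINY),
        )
    E = np.empty(np.shape(q12) + (2, 2))
    E[..., 0, 0] = ch + s * (a * dt - half_tr)
    E[..., 0, 1] = s * dt * q12
    E[..., 1, 0] = s * dt * q21
    E[..., 1, 1] = ch + s * (d * dt - half_tr)
    return np.clip(E, 0.0, 1.0)


def _expm_living_grad(q12, q21, q13, q23, dt):
    """E = exp(dt*A) and its partials dE/dq for the four rates.

    Writes E = ch I + s M with M = [[g, u2], [u3, -g]], g = dt(a-d)/2,
    u2 = dt q12, u3 = dt q21 and Delta^2 = g^2 + u2 u3; all Delta
    dependence enters through even functions of Delta, so derivatives are
    taken against Delta^2 and stay smooth at coincident eigenvalues.

    Returns (E, dE) with shapes (n, 2, 2) and (4, n, 2, 2); the leading
    axis of dE follows the transition order (1->2, 2->1, 1->3, 2->3).
    """
    q12, q21, q13, q23, dt = np.broadcast_arrays(q12, q21, q13, q23, dt)
    a = -(q12 + q13)
    d = -(q21 + q23)
    half_tr = 0.5 * (a + d) * dt
    g = 0.5 * (a - d) * dt
    u2 = dt * q12
    u3 = dt * q21
    delta2 = g * g + u2 * u3
    delta = np.sqrt(delta2)
    e_plus = np.exp(np.minimum(half_tr + delta, 0.0))
    e_minus = np.exp(np.minimum(half_tr - delta, 0.0))
    ch = 0.5 * (e_plus + e_minus)
    small = delta < 1e-4
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(
            small,
            np.exp(half_tr) * (1.0 + delta2 / 6.0 + delta2 * delta2 / 120.0),
            (e_plus - e_minus) / np.maximum(2.0 * delta, _TINY),
        )
        # w2 = (ch - s) / Delta^2, smooth with limit e^{tr/2}/3
        w2 = np.where(
            small,
            np.exp(half_tr) * (1.0 / 3.0 + delta2 / 30.0),
            (ch - s) / np.maximum(delta2, _TINY),
        )
    n = q12.shape
    E = np.empty(n + (2, 2))
    E[..., 0, 0] = ch + s * g
    E[..., 0, 1] = s * u2
    E[..., 1, 0] = s * u3
    E[..., 1, 1] = ch - s * g

    # per-rate primitives: d(half_tr) = -dt/2 for every rate;
    # d(g)/dq = -dt/2 for rates leaving state 1, +dt/2 for state 2
    dE = np.empty((4,) + n + (2, 2))
    half_dt = 0.5 * dt
    for k, (dg_sign, du2, du3) in enumerate(
        ((-1.0, dt, 0.0), (+1.0, 0.0, dt), (-1.0, 0.0, 0.0), (+1.0, 0.0, 0.0))
    ):
        dg = dg_sign * half_dt
        ddelta2 = 2.0 * g * dg + u2 * du3 + u3 * du2
        dch = -ch * half_dt + 0.5 * s * ddelta2
        ds = -s * half_dt + 0.5 * w2 * ddelta2
        dE[k, ..., 0, 0] = dch + ds * g + s * dg
        dE[k, ..., 0, 1] = ds * u2 + s * du2
        dE[k, ..., 1, 0] = ds * u3 + s * du3
        dE[k, ..., 1, 1] = dch - ds * g - s * dg
    return E, dE


def _n_bands(dt, h: float, homogeneous: bool) -> np.ndarray:
    dt = np.asarray(dt, dtype=float)
    if homogeneous:
        return np.ones(dt.shape, dtype=int)
    return np.maximum(1, np.ceil(dt / h - 1e-12).astype(int))


def _living_products(
    beta0: np.ndarray,  # (T, 4)
    xi: np.ndarray,     # (T, 4)
    beta: np.ndarray,   # (T, 4, 5)
    z: np.ndarray,      # (n, 5)
    age0: np.ndarray,
    age1: np.ndarray,
    h: float,
) -> np.ndarray:
    """(T, n, 2, 2) band-product matrices, batched over parameter vectors.

    The batch axis T lets finite-difference gradients and Hessians reuse
    one vectorised pass instead of T separate likelihood evaluations.
    """
    if (age1 < age0 - 1e-12).any():
        raise ValueError("interval end age precedes start age")
    T = beta0.shape[0]
    n = len(age0)
    dt_total = np.maximum(age1 - age0, 0.0)
    nb = _n_bands(dt_total, h, homogeneous=not np.any(xi))
    dtb = dt_total / nb
    lp0 = beta0[:, :, None] + np.einsum("tkc,nc->tkn", beta, z)  # (T, 4, n)
    out = np.broadcast_to(np.eye(2), (T, n, 2, 2)).copy()
    for j in range(int(nb.max())):
        act = np.flatnonzero(nb > j)
        mid = age0[act] + (j + 0.5) * dtb[act]
        q = np.exp(np.minimum(lp0[:, :, act] + xi[:, :, None] * (mid - AGE_REF), _MAX_LP))  # (T, 4, m)
        E = _expm_living(q[:, 0], q[:, 1], q[:, 2], q[:, 3], dtb[act])
        out[:, act] = np.einsum("tnij,tnjk->tnik", out[:, act], E)
    return out


def _living_interval_matrix(
    p: TransitionParams, z: np.ndarray, age0: np.ndarray, age1: np.ndarray, cfg: BandingConfig
) -> np.ndarray:
    """(n, 2, 2) product of band exponentials over [age0, age1] per pair."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    age0 = np.atleast_1d(np.asarray(age0, dtype=float))
    age1 = np.atleast_1d(np.asarray(age1, dtype=float))
    return _living_products(
        p.beta0[None, :], p.xi[None, :], p.beta[None, :, :], z, age0, age1, cfg.h_lik
    )[0]


def interval_probability(
    p: TransitionParams, z, age0: float, age1: float, cfg: BandingConfig | None = None
) -> ProbabilityMatrix:
    """3x3 transition probability matrix over the age interval.

    Product of per-band matrix exponentials with Q frozen at each band's
    midpoint age; a single exact exponential when the model is
    time-homogeneous (all age slopes zero).
    """
    cfg = cfg or BandingConfig()
    from .panel import CovariateProfile

    if isinstance(z, CovariateProfile):
        z = z.as_array()
    L = _living_interval_matrix(p, np.asarray(z, float)[None, :], [age0], [age1], cfg)[0]
    P = np.zeros((3, 3))
    P[:2, :2] = L
    P[:2, 2] = np.clip(1.0 - L.sum(axis=1), 0.0, 1.0)
    P[2, 2] = 1.0
    P[:2] /= P[:2].sum(axis=1, keepdims=True)
    return ProbabilityMatrix(P=P, interval=(float(age0), float(age1)))


# -- likelihood contributions --------------------------------------------

def batch_neg_loglik(
    pairs: PairArrays,
    beta0: np.ndarray,
    xi: np.ndarray,
    beta: np.ndarray,
    cfg: BandingConfig | None = None,
    *,
    max_chunk: int = 128,
) -> np.ndarray:
    """Negative log-likelihood for a batch of parameter vectors.

    ``beta0``/``xi`` are (T, 4) and ``beta`` is (T, 4, 5); returns (T,).
    The batch is processed in chunks to bound memory.  This is the fast
    path behind finite-difference gradients and Hessians.
    """
    cfg = cfg or BandingConfig()
    T = beta0.shape[0]
    out = np.empty(T)
    n = pairs.n
    rows = np.arange(n)
    living = np.isin(pairs.to_state, LIVING_STATES)
    cens = pairs.to_state == STATE_CENSORED_ALIVE
    dead = pairs.to_state == STATE_DEAD
    exact = dead & pairs.death_date_known & (cfg.death_convention == "exact")
    interval_death = dead & ~exact
    for t0 in range(0, T, max_chunk):
        sl = slice(t0, min(t0 + max_chunk, T))
        L = _living_products(
            beta0[sl], xi[sl], beta[sl], pairs.z, pairs.from_age, pairs.to_age, cfg.h_lik
        )
        v = L[:, rows, pairs.from_state - 1, :]  # (t, n, 2)
        lik = np.empty((L.shape[0], n))
        lik[:, living] = v[:, living, :][
            :, np.arange(living.sum()), pairs.to_state[living] - 1
        ]
        lik[:, cens] = v[:, cens, :].sum(axis=2)
        if exact.any():
            lp = (
                beta0[sl][:, :, None]
                + np.einsum("tkc,nc->tkn", beta[sl], pairs.z[exact])
                + xi[sl][:, :, None] * (pairs.to_age[exact] - AGE_REF)
            )
            q = np.exp(lp)  # (t, 4, m)
            lik[:, exact] = v[:, exact, 0] * q[:, 2] + v[:, exact, 1] * q[:, 3]
        lik[:, interval_death] = np.clip(
            1.0 - v[:, interval_death, :].sum(axis=2), 0.0, 1.0
        )
        out[sl] = -np.log(np.maximum(lik, _TINY)).sum(axis=1)
    return out


def neg_loglik_and_grad(
    pairs: PairArrays,
    beta0: np.ndarray,
    xi: np.ndarray,
    beta: np.ndarray,
    cfg: BandingConfig | None = None,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Negative log-likelihood and its exact gradient in one reverse pass.

    Forward: accumulate the living-state occupancy vector v through the
    band products, storing per-band rates and matrices.  Backward:
    propagate the adjoint of v through the transposed products and chain
    each band's dE/dq into the (beta0, xi, beta) gradients via
    dq/d(linear predictor) = q.  Costs a small multiple of one
    likelihood evaluation, independent of the parameter count.

    Returns (nll, g_beta0 (4,), g_xi (4,), g_beta (4, 5)).
    """
    cfg = cfg or BandingConfig()
    n = pairs.n
    z = pairs.z
    age0, age1 = pairs.from_age, pairs.to_age
    dt_total = np.maximum(age1 - age0, 0.0)
    homogeneous = not np.any(xi)
    nb = _n_bands(dt_total, cfg.h_lik, homogeneous)
    dtb = dt_total / nb
    lp0 = beta0[:, None] + beta @ z.T  # (4, n)

    v = np.zeros((n, 2))
    v[np.arange(n), pairs.from_state - 1] = 1.0
    tape = []  # (act, mid, q, E, dE, v_before)
    for j in range(int(nb.max())):
        act = np.flatnonzero(nb > j)
        mid = age0[act] + (j + 0.5) * dtb[act]
        q = np.exp(np.minimum(lp0[:, act] + xi[:, None] * (mid - AGE_REF), _MAX_LP))  # (4, m)
        E, dE = _expm_living_grad(q[0], q[1], q[2], q[3], dtb[act])
        tape.append((act, mid, q, E, dE, v[act].copy()))
        v[act] = np.einsum("ni,nij->nj", v[act], E)

    # terminal likelihood values and adjoint of v
    lik = np.empty(n)
    w = np.zeros((n, 2))  # dloglik/dv
    living = np.isin(pairs.to_state, LIVING_STATES)
    idx_liv = np.flatnonzero(living)
    lik[idx_liv] = v[idx_liv, pairs.to_state[idx_liv] - 1]
    cens = pairs.to_state == STATE_CENSORED_ALIVE
    lik[cens] = v[cens].sum(axis=1)
    dead = pairs.to_state == STATE_DEAD
    exact = dead & pairs.death_date_known & (cfg.death_convention == "exact")
    interval_death = dead & ~exact
    if exact.any():
        lp_end = lp0[:, exact] + xi[:, None] * (pairs.to_age[exact] - AGE_REF)
        q_end = np.exp(np.minimum(lp_end, _MAX_LP))  # (4, m)
        lik[exact] = v[exact, 0] * q_end[2] + v[exact, 1] * q_end[3]
    lik[interval_death] = np.clip(1.0 - v[interval_death].sum(axis=1), 0.0, 1.0)
    lik_safe = np.maximum(lik, _TINY)

    # adjoint floor is far above _TINY: near-impossible pairs only need a
    # strong (finite) descent signal, not an exact gradient
    inv = 1.0 / np.maximum(lik, 1e-100)
    w[idx_liv, pairs.to_state[idx_liv] - 1] = inv[idx_liv]
    w[cens] = inv[cens, None]
    if exact.any():
        with np.errstate(over="ignore"):
            w[exact, 0] = np.clip(np.nan_to_num(q_end[2] * inv[exact]), 0.0, 1e100)
            w[exact, 1] = np.clip(np.nan_to_num(q_end[3] * inv[exact]), 0.0, 1e100)
    w[interval_death] = -inv[interval_death, None]

    g_beta0 = np.zeros(4)
    g_xi = np.zeros(4)
    g_beta = np.zeros((4, beta.shape[1]))
    if exact.any():
        # direct dependence of the death density on the end-age rates
        with np.errstate(over="ignore", invalid="ignore"):
            dlp = np.zeros((4, int(exact.sum())))
            dlp[2] = v[exact, 0] * q_end[2] * inv[exact]
            dlp[3] = v[exact, 1] * q_end[3] * inv[exact]
            dlp = np.clip(np.nan_to_num(dlp), -1e12, 1e12)
        g_beta0 += dlp.sum(axis=1)
        g_xi += dlp @ (pairs.to_age[exact] - AGE_REF)
        g_beta += dlp @ z[exact]

    with np.errstate(over="ignore", invalid="ignore"):
        for act, mid, q, E, dE, v_before in reversed(tape):
            w_act = w[act]
            Ebar = v_before[:, :, None] * w_act[:, None, :]  # (m, 2, 2)
            dLdq = np.einsum("knij,nij->kn", dE, Ebar)  # (4, m)
            dlp = np.clip(np.nan_to_num(dLdq * q), -1e12, 1e12)
            g_beta0 += dlp.sum(axis=1)
            g_xi += dlp @ (mid - AGE_REF)
            g_beta += dlp @ z[act]
            w[act] = np.einsum("nij,nj->ni", E, w_act)

    nll = -float(np.log(lik_safe).sum())
    clip = lambda g: np.clip(np.nan_to_num(g), -1e15, 1e15)
    return nll, clip(-g_beta0), clip(-g_xi), clip(-g_beta)


def pair_log_likelihoods(
    pairs: PairArrays, p: TransitionParams, cfg: BandingConfig | None = None
) -> np.ndarray:
    """Vector of per-pair log-likelihood contributions."""
    cfg = cfg or BandingConfig()
    if not np.isin(pairs.from_state, LIVING_STATES).all():
        raise ValueError("pair starts from the absorbing state")
    L = _living_interval_matrix(p, pairs.z, pairs.from_age, pairs.to_age, cfg)
    n = pairs.n
    v = L[np.arange(n), pairs.from_state - 1, :]  # (n, 2) living occupancy row
    lik = np.empty(n)

    living = np.isin(pairs.to_state, LIVING_STATES)
    lik[living] = v[living, pairs.to_state[living] - 1]

    cens = pairs.to_state == STATE_CENSORED_ALIVE
    lik[cens] = v[cens].sum(axis=1)

    dead = pairs.to_state == STATE_DEAD
    exact = dead & pairs.death_date_known & (cfg.death_convention == "exact")
    if exact.any():
        lp = p.beta0[:, None] + p.beta @ pairs.z[exact].T + p.xi[:, None] * (
            pairs.to_age[exact] - AGE_REF
        )
        q = np.exp(lp)  # (4, m); rows: q12, q21, q13, q23 at the death age
        lik[exact] = v[exact, 0] * q[2] + v[exact, 1] * q[3]
    interval_death = dead & ~exact
    lik[interval_death] = np.clip(1.0 - v[interval_death].sum(axis=1), 0.0, 1.0)

    return np.log(np.maximum(lik, _TINY))


def pair_log_likelihood(
    from_obs: Observation,
    to_obs: Observation,
    p: TransitionParams,
    cfg: BandingConfig | None = None,
) -> float:
    """Log-likelihood contribution of one consecutive observation pair."""
    if from_obs.state not in LIVING_STATES:
        raise ValueError("pair must start in a living state")
    if to_obs.age < from_obs.age:
        raise ValueError("observation ages must be non-decreasing within a pair")
    pairs = PairArrays(
        from_state=np.array([from_obs.state]),
        to_state=np.array([to_obs.state]),
        from_age=np.array([from_obs.age], dtype=float),
        to_age=np.array([to_obs.age], dtype=float),
        death_date_known=np.array([bool(to_obs.death_date_known)]),
        z=from_obs.covariates.as_array()[None, :],
        subject_id=np.array([from_obs.subject_id], dtype=object),
    )
    return float(pair_log_likelihoods(pairs, p, cfg)[0])


def total_neg2_loglik(
    panel: PanelDataset | PairArrays,
    p: TransitionParams,
    cfg: BandingConfig | None = None,
) -> float:
    """-2 log-likelihood of the panel under the Markov assumption.

    Consecutive observation pairs are conditionally independent given the
    earlier state, so the total is a straight sum.  A structurally
    impossible pair (probability zero) makes the total infinite; the
    offending subject is reported in a warning.
    """
    pairs = panel.pairs() if isinstance(panel, PanelDataset) else panel
    ll = pair_log_likelihoods(pairs, p, cfg)
    degenerate = ll <= np.log(_TINY) + 1.0
    if degenerate.any():
        i = int(np.flatnonzero(degenerate)[0])
        warnings.warn(
            f"zero-probability pair for subject {pairs.subject_id[i]} "
            f"(ages {pairs.from_age[i]:.2f}-{pairs.to_age[i]:.2f}); "
            "-2loglik is infinite",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(np.inf)
    return float(-2.0 * ll.sum())
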