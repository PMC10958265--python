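"""Maximum-likelihood fitting of the three-state model and Wald inference.

The packed parameter vector follows :class:`~needsmsm.intensities.ModelSpec`
ordering.  Optimisation runs quasi-Newton (L-BFGS-B) on the negative
log-likelihood with exact reverse-mode gradients, then polishes with
damped Newton steps; the covariance matrix is the inverse of the
finite-difference Hessian of that gradient at the optimum.  Starting
values are crude occurrence/exposure rates from the observed pair
counts, with covariate coefficients at zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.optimize

from .intensities import TRANSITIONS, ModelSpec, TransitionParams
from .likelihood import (
    BandingConfig,
    ProbabilityMatrix,
    interval_probability,
    neg_loglik_and_grad,
)
from .panel import STATE_DEAD, CovariateProfile, PanelDataset

#: 95% normal quantile, the reporting convention for all Wald intervals
Z95 = 1.96

_BOUND_BETA0 = (-14.0, 4.0)
_BOUND_XI = (-2.0, 2.0)
_BOUND_BETA = (-8.0, 8.0)


class FittingError(RuntimeError):
    pass


@dataclass
class FittedModel:
    spec: ModelSpec
    params: TransitionParams
    theta: np.ndarray
    vcov: np.ndarray | None
    minus2loglik: float
    k: int
    converged: bool
    gradient_norm: float
    n_subjects: int
    n_pairs: int
    cfg: BandingConfig = field(default_factory=BandingConfig)

    @property
    def aic(self) -> float:
        return self.minus2loglik + 2 * self.k

    def param_names(self) -> list[str]:
        return self.spec.param_names()

    def se(self) -> np.ndarray:
        if self.vcov is None:
            raise FittingError("fit has no covariance matrix")
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))

    # -- plain-text fit archive -----------------------------------------
    def to_json(self) -> str:
        payload = {
            "spec": {
                "covariates": {f"{r}->{s}": list(self.spec.covariates[(r, s)]) for r, s in TRANSITIONS},
                "include_age": {f"{r}->{s}": self.spec.include_age[(r, s)] for r, s in TRANSITIONS},
            },
            "param_names": self.param_names(),
            "theta": self.theta.tolist(),
            "vcov": None if self.vcov is None else self.vcov.tolist(),
            "minus2loglik": self.minus2loglik,
            "aic": self.aic,
            "k": self.k,
            "converged": self.converged,
            "gradient_norm": self.gradient_norm,
            "n_subjects": self.n_subjects,
            "n_pairs": self.n_pairs,
            "h_lik": self.cfg.h_lik,
            "death_convention": self.cfg.death_convention,
        }
        return json.dumps(payload, indent=2)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "FittedModel":
        d = json.loads(text)
        spec = ModelSpec(
            covariates={
                (int(k[0]), int(k[3])): tuple(v) for k, v in d["spec"]["covariates"].items()
            },
            include_age={
                (int(k[0]), int(k[3])): bool(v) for k, v in d["spec"]["include_age"].items()
            },
        )
        theta = np.asarray(d["theta"], dtype=float)
        return cls(
            spec=spec,
            params=spec.unpack(theta),
            theta=theta,
            vcov=None if d["vcov"] is None else np.asarray(d["vcov"], dtype=float),
            minus2loglik=float(d["minus2loglik"]),
            k=int(d["k"]),
            converged=bool(d["converged"]),
            gradient_norm=float(d["gradient_norm"]),
            n_subjects=int(d["n_subjects"]),
            n_pairs=int(d["n_pairs"]),
            cfg=BandingConfig(h_lik=float(d["h_lik"]), death_convention=d["death_convention"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "FittedModel":
        return cls.from_json(Path(path).read_text())


def crude_initial_values(panel: PanelDataset, spec: ModelSpec) -> np.ndarray:
    """Occurrence/exposure starting values on the log scale.

    Counts of observed pair transitions divided by person-years of
    exposure per origin state (deaths attributed to the origin state of
    the pair); covariate and age coefficients start at zero.
    """
    pairs = panel.pairs()
    py = {1: 0.0, 2: 0.0}
    counts = {t: 0 for t in TRANSITIONS}
    dt = pairs.to_age - pairs.from_age
    for r in (1, 2):
        py[r] = float(dt[pairs.from_state == r].sum())
    for r, s in TRANSITIONS:
        if s == STATE_DEAD:
            n = int(((pairs.from_state == r) & (pairs.to_state == STATE_DEAD)).sum())
        else:
            n = int(((pairs.from_state == r) & (pairs.to_state == s)).sum())
        counts[(r, s)] = n
    beta0 = {}
    for r, s in TRANSITIONS:
        rate = counts[(r, s)] / py[r] if py[r] > 0 else 0.0
        beta0[(r, s)] = float(np.log(max(rate, 1e-4)))
    params = TransitionParams.from_dicts(beta0)
    return spec.pack(params)


def _bounds(spec: ModelSpec) -> list[tuple[float, float]]:
    bounds = []
    for t in TRANSITIONS:
        bounds.append(_BOUND_BETA0)
        if spec.include_age[t]:
            bounds.append(_BOUND_XI)
        bounds.extend([_BOUND_BETA] * len(spec.covariates[t]))
    return bounds


def _value_and_grad_fn(pairs, spec: ModelSpec, cfg: BandingConfig):
    """Objective returning (nll, packed gradient) via the reverse pass."""
    b0_pos, xi_pos, beta_pos = spec._index_maps()

    def f(theta: np.ndarray) -> tuple[float, np.ndarray]:
        beta0, xi, beta = spec.unpack_batch(theta[None, :])
        nll, g0, gx, gb = neg_loglik_and_grad(pairs, beta0[0], xi[0], beta[0], cfg)
        g = np.empty_like(theta)
        for j, i in b0_pos:
            g[j] = g0[i]
        for j, i in xi_pos:
            g[j] = gx[i]
        for j, i, c in beta_pos:
            g[j] = gb[i, c]
        return nll, g

    return f


def _fd_hessian(value_and_grad, theta: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Hessian by central differences of the analytic gradient."""
    k = len(theta)
    h = step * np.maximum(1.0, np.abs(theta))
    H = np.empty((k, k))
    for i in range(k):
        e = np.zeros(k)
        e[i] = h[i]
        _, gp = value_and_grad(theta + e)
        _, gm = value_and_grad(theta - e)
        H[i] = (gp - gm) / (2.0 * h[i])
    return 0.5 * (H + H.T)


def _projected_gradient(theta, g, lo, hi, tol=1e-9):
    """KKT residual for box constraints: at an active bound only the
    inward-pointing gradient component counts."""
    pg = g.copy()
    at_lo = theta <= lo + tol
    at_hi = theta >= hi - tol
    pg[at_lo] = np.minimum(g[at_lo], 0.0)
    pg[at_hi] = np.maximum(g[at_hi], 0.0)
    return pg


def _newton_polish(vg, theta: np.ndarray, bounds, gtol: float, max_steps: int = 30):
    """Damped Newton refinement with backtracking, staying inside bounds.

    L-BFGS gets close on this ill-conditioned surface but crawls near the
    optimum; Newton steps with the finite-difference Hessian of the
    analytic gradient finish the job in a handful of iterations.  Returns
    (theta, nll, grad, H) with H the Hessian at the final point.
    """
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    f0, g = vg(theta)
    H = None
    decrement = np.inf
    for _ in range(max_steps):
        H = _fd_hessian(vg, theta)
        pg = _projected_gradient(theta, g, lo, hi)
        # restrict the Newton system to coordinates that are free to move
        free = np.flatnonzero(((theta > lo + 1e-9) | (pg < 0)) & ((theta < hi - 1e-9) | (pg > 0)))
        step = np.zeros_like(theta)
        if len(free):
            w, V = np.linalg.eigh(H[np.ix_(free, free)])
            w = np.maximum(w, 1e-8 * max(w.max(), 1.0))  # keep the step a descent direction
            step[free] = -(V * (1.0 / w)) @ (V.T @ pg[free])
        # Newton decrement: the scale-invariant estimate of the remaining
        # improvement in the negative log-likelihood
        decrement = float(-pg @ step)
        if decrement <= gtol:
            break
        t = 1.0
        for _ in range(40):
            cand = np.clip(theta + t * step, lo, hi)
            f1, g1 = vg(cand)
            if f1 < f0 - 1e-13 * max(1.0, abs(f0)):
                theta, f0, g = cand, f1, g1
                break
            t *= 0.5
        else:
            break  # no improvement possible at machine precision
    if H is None:  # pragma: no cover
        H = _fd_hessian(vg, theta)
    return theta, f0, g, H, decrement


def fit_msm(
    panel: PanelDataset,
    spec: ModelSpec | None = None,
    cfg: BandingConfig | None = None,
    *,
    start: np.ndarray | None = None,
    maxiter: int = 150,
    gtol: float = 1e-6,
    n_starts: int = 1,
    seed: int | None = None,
    compute_vcov: bool = True,
) -> FittedModel:
    """Fit the multistate model by maximum likelihood.

    Quasi-Newton (L-BFGS-B) on the negative log-likelihood with exact
    reverse-mode gradients, then damped Newton polishing; ``gtol`` bounds
    the Newton decrement (the predicted remaining improvement of the
    negative log-likelihood) at the reported optimum.  ``n_starts > 1``
    adds randomly perturbed restarts (seeded) as a guard against local
    optima, keeping the best optimum.  ``converged`` is reported
    honestly: False when the decrement stays above tolerance or the
    curvature over the free (non-bound-pinned) coordinates is not
    positive definite.
    """
    spec = spec or ModelSpec()
    cfg = cfg or BandingConfig()
    pairs = panel.pairs()
    if pairs.n == 0:
        raise FittingError("panel contains no likelihood pairs")

    vg = _value_and_grad_fn(pairs, spec, cfg)

    theta0 = np.asarray(start, dtype=float) if start is not None else crude_initial_values(panel, spec)
    if not np.isfinite(vg(theta0)[0]):
        raise FittingError(
            "non-finite likelihood at the starting values; consider crude-rate initialisation"
        )

    starts = [theta0]
    if n_starts > 1:
        rng = np.random.default_rng(seed)
        starts += [theta0 + rng.normal(scale=0.3, size=theta0.shape) for _ in range(n_starts - 1)]

    bounds = _bounds(spec)
    best = None
    for s0 in starts:
        res = scipy.optimize.minimize(
            vg,
            s0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": gtol},
        )
        if best is None or res.fun < best.fun:
            best = res

    theta, nll, grad, H, decrement = _newton_polish(
        vg, np.asarray(best.x, dtype=float), bounds, gtol
    )
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    gradient_norm = float(np.linalg.norm(_projected_gradient(theta, grad, lo, hi)))
    # converged when the predicted remaining improvement in the negative
    # log-likelihood is negligible (scale-invariant Newton decrement)
    converged = decrement <= max(gtol, 1e-5)

    vcov = None
    if compute_vcov:
        # the curvature check applies to the coordinates that are free at
        # the optimum; a parameter pinned at its bound has no Wald theory
        free = (theta > lo + 1e-9) & (theta < hi - 1e-9)
        eigmin_free = float(np.linalg.eigvalsh(H[np.ix_(free, free)]).min()) if free.any() else 1.0
        if eigmin_free <= 0:
            converged = False
        eigmin = float(np.linalg.eigvalsh(H).min())
        vcov = np.linalg.inv(H) if eigmin > 0 else np.linalg.pinv(H)
        vcov = 0.5 * (vcov + vcov.T)

    return FittedModel(
        spec=spec,
        params=spec.unpack(theta),
        theta=theta,
        vcov=vcov,
        minus2loglik=float(2.0 * nll),
        k=spec.n_params,
        converged=converged,
        gradient_norm=gradient_norm,
        n_subjects=panel.n_subjects,
        n_pairs=pairs.n,
        cfg=cfg,
    )


def hazard_ratio_table(fit: FittedModel) -> "pd.DataFrame":
    """Hazard ratios with log-symmetric 95% Wald intervals.

    One row per transition and term (age slope and covariates; the
    baseline intensity is not a ratio and is omitted).  ``hr`` equals the
    geometric mean of the interval endpoints by construction.
    """
    import pandas as pd

    if fit.vcov is None:
        raise FittingError("fit has no covariance matrix; rerun with compute_vcov=True")
    se = fit.se()
    names = fit.param_names()
    rows = []
    for i, name in enumerate(names):
        label, term = name.split(":")
        if term == "baseline":
            continue
        beta = fit.theta[i]
        rows.append(
            {
                "transition": label,
                "term": term,
                "hr": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - Z95 * se[i])),
                "ci_high": float(np.exp(beta + Z95 * se[i])),
                "se_log": float(se[i]),
            }
        )
    return pd.DataFrame(rows)


def wald_intervals(fit: FittedModel) -> "pd.DataFrame":
    """95% Wald intervals for every free parameter on the coefficient scale."""
    import pandas as pd

    se = fit.se()
    return pd.DataFrame(
        {
            "name": fit.param_names(),
            "estimate": fit.theta,
            "se": se,
            "ci_low": fit.theta - Z95 * se,
            "ci_high": fit.theta + Z95 * se,
        }
    )


def predict_transition_probabilities(
    fit: FittedModel,
    z: CovariateProfile | np.ndarray,
    age: float,
    horizon: float,
) -> ProbabilityMatrix:
    """Transition probability matrix over ``[age, age + horizon]`` at a
    covariate profile, which may hold fractional dummy means."""
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    return interval_probability(fit.params, z, age, age + horizon, fit.cfg)
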