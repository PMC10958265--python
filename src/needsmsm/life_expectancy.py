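"""Total, marginal and state-specific residual life expectancies.

State occupancy from a starting age is accumulated by forward products
of per-band transition matrices (generator frozen at band midpoints,
default band 0.5 years, truncation at max-age 115), and life
expectancies are trapezoid-rule integrals of occupancy over age:

    e_rs(a)     expected years in living state s before max-age for a
                subject in living state r at age a;
    marginal_s  sum_r pi_r(a) e_rs(a), weighting by the living-state
                distribution at age a;
    TLE         marginal_1 + marginal_2;
    %UMLE       100 * marginal_unmet / TLE.

Confidence intervals are simulation-based: parameter vectors are drawn
from the multivariate normal defined by the ML estimate and its
covariance, every quantity is recomputed per draw, and percentile
intervals are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import FittedModel
from .intensities import AGE_REF, ModelSpec, TransitionParams
from .likelihood import _expm_living
from .panel import STATE_UNMET, CovariateProfile, PanelDataset

DEFAULT_MAX_AGE = 115.0
DEFAULT_H = 0.5

LE_QUANTITIES = (
    "total",
    "marginal_unmet",
    "marginal_met",
    "pct_unmet",
    "e_from_unmet_in_unmet",
    "e_from_unmet_in_met",
    "e_from_met_in_unmet",
    "e_from_met_in_met",
)


def _as_z(z) -> np.ndarray:
    if isinstance(z, CovariateProfile):
        return z.as_array()
    return np.asarray(z, dtype=float)


@dataclass(frozen=True)
class OccupancyGrid:
    """State occupancy P_{r.}(start_age -> age) on an age grid.

    ``occ`` has shape (n_ages, 2, 3): axis 1 is the starting living state
    (unmet, met), axis 2 the occupied state (unmet, met, dead).
    """

    start_age: float
    ages: np.ndarray
    occ: np.ndarray
    h: float
    max_age: float

    def __post_init__(self) -> None:
        if not np.allclose(self.occ.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("occupancy rows must sum to 1")
        if (np.diff(self.occ[:, :, 2], axis=0) < -1e-10).any():
            raise ValueError("death occupancy must be non-decreasing")


@dataclass(frozen=True)
class LifeExpectancySet:
    """Life expectancies at one starting age and covariate profile.

    ``e[r-1, s-1]`` is the state-specific LE in living state s starting
    from living state r; marginal, total and %UMLE follow by identity.
    """

    e: np.ndarray                 # (2, 2) state-specific LEs, years
    pi: np.ndarray                # (2,) initial living-state distribution
    profile: np.ndarray
    start_age: float

    @property
    def marginal(self) -> np.ndarray:
        return self.pi @ self.e

    @property
    def marginal_unmet(self) -> float:
        return float(self.marginal[0])

    @property
    def marginal_met(self) -> float:
        return float(self.marginal[1])

    @property
    def total(self) -> float:
        return float(self.marginal.sum())

    @property
    def pct_unmet(self) -> float:
        return percent_unmet(self.marginal_unmet, self.total)

    def as_dict(self) -> dict[str, float]:
        return {
            "total": self.total,
            "marginal_unmet": self.marginal_unmet,
            "marginal_met": self.marginal_met,
            "pct_unmet": self.pct_unmet,
            "e_from_unmet_in_unmet": float(self.e[0, 0]),
            "e_from_unmet_in_met": float(self.e[0, 1]),
            "e_from_met_in_unmet": float(self.e[1, 0]),
            "e_from_met_in_met": float(self.e[1, 1]),
        }


def percent_unmet(marginal_unmet: float, total: float) -> float:
    """%UMLE: marginal LE with unmet needs as a percentage of total LE."""
    if total <= 0:
        raise ValueError("total life expectancy must be positive")
    return 100.0 * marginal_unmet / total


@dataclass(frozen=True)
class SimulationCI:
    """Percentile intervals for LE quantities from B parameter draws."""

    point: dict[str, float]
    lower: dict[str, float]
    upper: dict[str, float]
    B: int
    seed: int | None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quantity": list(self.point),
                "estimate": list(self.point.values()),
                "ci_low": [self.lower[q] for q in self.point],
                "ci_high": [self.upper[q] for q in self.point],
            }
        )


# -- occupancy and integration -------------------------------------------

def _occupancy_products(
    beta0: np.ndarray, xi: np.ndarray, zb: np.ndarray, ages: np.ndarray
) -> np.ndarray:
    """Living-state occupancy matrices along an age grid, vectorised over
    parameter draws.

    ``beta0``, ``xi``, ``zb`` have shape (B, 4) (``zb`` is the covariate
    contribution beta @ z per draw); returns (n_ages, B, 2, 2).
    """
    B = beta0.shape[0]
    out = np.empty((len(ages), B, 2, 2))
    cur = np.broadcast_to(np.eye(2), (B, 2, 2)).copy()
    out[0] = cur
    base = beta0 + zb  # (B, 4)
    for g in range(len(ages) - 1):
        dt = ages[g + 1] - ages[g]
        mid = 0.5 * (ages[g] + ages[g + 1])
        q = np.exp(base + xi * (mid - AGE_REF))  # (B, 4)
        E = _expm_living(q[:, 0], q[:, 1], q[:, 2], q[:, 3], np.full(B, dt))
        cur = np.einsum("bij,bjk->bik", cur, E)
        out[g + 1] = cur
    return out


def occupancy(
    fit: FittedModel | TransitionParams,
    z,
    start_age: float,
    h: float = DEFAULT_H,
    max_age: float = DEFAULT_MAX_AGE,
) -> OccupancyGrid:
    """Occupancy probabilities from ``start_age`` to ``max_age``."""
    if start_age >= max_age:
        raise ValueError("start_age must precede max_age")
    if h <= 0:
        raise ValueError("h must be positive")
    p = fit.params if isinstance(fit, FittedModel) else fit
    zarr = _as_z(z)
    n_bands = int(np.ceil((max_age - start_age) / h - 1e-12))
    ages = np.minimum(start_age + h * np.arange(n_bands + 1), max_age)
    zb = (p.beta @ zarr)[None, :]
    living = _occupancy_products(p.beta0[None, :], p.xi[None, :], zb, ages)[:, 0]
    occ = np.empty((len(ages), 2, 3))
    occ[:, :, :2] = living
    occ[:, :, 2] = np.clip(1.0 - living.sum(axis=2), 0.0, 1.0)
    occ /= occ.sum(axis=2, keepdims=True)
    return OccupancyGrid(start_age=float(start_age), ages=ages, occ=occ, h=float(h), max_age=float(max_age))


def state_specific_le(grid: OccupancyGrid, from_state: int, in_state: int) -> float:
    """Trapezoid-rule integral of occupancy: expected years in living
    state ``in_state`` for a subject in ``from_state`` at the grid start."""
    if from_state not in (1, 2) or in_state not in (1, 2):
        raise ValueError("states must be living (1 or 2)")
    y = grid.occ[:, from_state - 1, in_state - 1]
    return float(np.trapezoid(y, grid.ages))


def initial_state_distribution(
    panel: PanelDataset,
    age: float,
    z=None,
    *,
    include_covariates: bool = False,
) -> tuple[float, float]:
    """(pi_unmet, pi_met) at an age, from a baseline logistic model.

    Fits logit P(baseline state = unmet) on baseline age (and the five
    covariates when ``include_covariates``), then evaluates at ``age``
    (and profile ``z``).  Degenerate baselines (a single observed state)
    yield the corresponding point mass.
    """
    import statsmodels.api as sm

    base = panel.baseline()
    base = base[base["state"].isin([1, 2])]
    y = (base["state"] == STATE_UNMET).to_numpy(dtype=float)
    if y.sum() == 0:
        return (0.0, 1.0)
    if y.sum() == len(y):
        return (1.0, 0.0)
    cols = [base["age"].to_numpy()]
    if include_covariates:
        from .panel import COVARIATES

        cols += [base[c].to_numpy() for c in COVARIATES]
    X = sm.add_constant(np.column_stack(cols))
    fit = sm.Logit(y, X).fit(disp=0)
    xrow = [1.0, float(age)]
    if include_covariates:
        xrow += list(_as_z(z if z is not None else np.zeros(5)))
    p1 = float(fit.predict(np.asarray(xrow)[None, :])[0])
    return (p1, 1.0 - p1)


def life_expectancies(
    fit: FittedModel | TransitionParams,
    panel: PanelDataset | tuple[float, float],
    z,
    start_age: float,
    h: float = DEFAULT_H,
    max_age: float = DEFAULT_MAX_AGE,
    *,
    include_covariates_in_pi: bool = False,
) -> LifeExpectancySet:
    """Compose occupancy, integration and the initial-state distribution.

    ``panel`` may be replaced by an explicit ``(pi_unmet, pi_met)`` tuple
    when the initial distribution is known or fixed externally.
    """
    grid = occupancy(fit, z, start_age, h, max_age)
    e = np.array(
        [[state_specific_le(grid, r, s) for s in (1, 2)] for r in (1, 2)]
    )
    if isinstance(panel, PanelDataset):
        pi = initial_state_distribution(
            panel, start_age, z, include_covariates=include_covariates_in_pi
        )
    else:
        pi = panel
    pi = np.asarray(pi, dtype=float)
    if not np.isclose(pi.sum(), 1.0):
        raise ValueError("initial state distribution must sum to 1")
    return LifeExpectancySet(e=e, pi=pi, profile=_as_z(z), start_age=float(start_age))


def _le_from_thetas(
    thetas: np.ndarray,
    spec: ModelSpec,
    z: np.ndarray,
    pi: np.ndarray,
    start_age: float,
    h: float,
    max_age: float,
) -> np.ndarray:
    """LE quantity matrix (B, 8) in LE_QUANTITIES order, vectorised."""
    B = thetas.shape[0]
    beta0 = np.empty((B, 4))
    xi = np.empty((B, 4))
    zb = np.empty((B, 4))
    for b in range(B):
        p = spec.unpack(thetas[b])
        beta0[b] = p.beta0
        xi[b] = p.xi
        zb[b] = p.beta @ z
    n_bands = int(np.ceil((max_age - start_age) / h - 1e-12))
    ages = np.minimum(start_age + h * np.arange(n_bands + 1), max_age)
    living = _occupancy_products(beta0, xi, zb, ages)  # (G, B, 2, 2)
    e = np.trapezoid(living, ages, axis=0)  # (B, 2, 2)
    marginal = np.einsum("r,brs->bs", pi, e)  # (B, 2)
    total = marginal.sum(axis=1)
    pct = 100.0 * marginal[:, 0] / total
    return np.column_stack(
        [total, marginal[:, 0], marginal[:, 1], pct, e[:, 0, 0], e[:, 0, 1], e[:, 1, 0], e[:, 1, 1]]
    )


def le_confidence_intervals(
    fit: FittedModel,
    panel: PanelDataset | tuple[float, float],
    z,
    start_age: float,
    B: int = 1000,
    seed: int | None = None,
    h: float = DEFAULT_H,
    max_age: float = DEFAULT_MAX_AGE,
    *,
    repair_vcov: bool = False,
) -> SimulationCI:
    """Simulation-based 95% CIs for all LE quantities.

    Draws ``B`` parameter vectors from N(theta_hat, vcov), recomputes the
    LE set per draw, and reports 2.5/97.5 percentiles.  The initial-state
    distribution is held fixed at its point estimate.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    if fit.vcov is None:
        raise ValueError("fit has no covariance matrix")
    vcov = np.asarray(fit.vcov, dtype=float)
    eigmin = float(np.linalg.eigvalsh(0.5 * (vcov + vcov.T)).min())
    if eigmin < -1e-10:
        if not repair_vcov:
            raise ValueError(
                "covariance matrix is not positive semi-definite; "
                "pass repair_vcov=True to clip negative eigenvalues"
            )
        w, V = np.linalg.eigh(0.5 * (vcov + vcov.T))
        vcov = (V * np.clip(w, 0.0, None)) @ V.T

    point_set = life_expectancies(fit, panel, z, start_age, h, max_age)
    pi = point_set.pi
    zarr = _as_z(z)
    rng = np.random.default_rng(seed)
    thetas = rng.multivariate_normal(fit.theta, vcov, size=B, method="eigh")
    # keep draws inside the admissible box so intensities stay finite
    lo = np.array([b[0] for b in _spec_bounds(fit.spec)])
    hi = np.array([b[1] for b in _spec_bounds(fit.spec)])
    thetas = np.clip(thetas, lo, hi)
    Q = _le_from_thetas(thetas, fit.spec, zarr, pi, start_age, h, max_age)
    low = np.percentile(Q, 2.5, axis=0)
    high = np.percentile(Q, 97.5, axis=0)
    point = point_set.as_dict()
    return SimulationCI(
        point=point,
        lower={q: float(v) for q, v in zip(LE_QUANTITIES, low)},
        upper={q: float(v) for q, v in zip(LE_QUANTITIES, high)},
        B=B,
        seed=seed,
    )


def _spec_bounds(spec: ModelSpec):
    from .estimation import _bounds

    return _bounds(spec)
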