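"""Gompertz proportional transition intensities and the generator matrix.

Each allowed transition r->s carries a log-linear intensity

    q_rs(age, z) = exp( beta0_rs + xi_rs * (age - 60) + beta_rs . z )

with ``beta0`` the log baseline intensity per year at the reference
profile and age 60, ``xi`` the Gompertz log-linear age slope per year of
age, and ``beta`` log hazard ratios aligned with the covariate order
``(female, edu_mid, edu_high, multi_P, multi_PM)``.  Setting ``xi = 0``
for every transition gives the time-homogeneous model in which age acts
only through the covariates included in ``beta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import COVARIATES, CovariateProfile

#: age at which the linear predictor is centred (numerical conditioning;
#: reported baseline intensities refer to this age)
AGE_REF = 60.0

#: the four estimable transitions of the three-state structure, in the
#: fixed order used for parameter packing
TRANSITIONS: tuple[tuple[int, int], ...] = ((1, 2), (2, 1), (1, 3), (2, 3))

TRANSITION_LABELS = {
    (1, 2): "unmet->met",
    (2, 1): "met->unmet",
    (1, 3): "unmet->death",
    (2, 3): "met->death",
}


class TransitionSpecError(ValueError):
    """A disallowed transition was requested."""


def _check_transition(transition: tuple[int, int]) -> tuple[int, int]:
    transition = (int(transition[0]), int(transition[1]))
    if transition not in TRANSITIONS:
        raise TransitionSpecError(
            f"transition {transition[0]}->{transition[1]} is not estimable; "
            f"allowed: {', '.join(TRANSITION_LABELS.values())}"
        )
    return transition


@dataclass(frozen=True)
class ModelSpec:
    """Which terms each transition's intensity carries.

    ``covariates`` maps each transition to the tuple of covariate names
    with a free coefficient; ``include_age`` switches the Gompertz age
    slope per transition.  The default is the full model: age slope plus
    all five covariates on each of the four transitions (k = 28).
    """

    covariates: dict[tuple[int, int], tuple[str, ...]] = field(
        default_factory=lambda: {t: tuple(COVARIATES) for t in TRANSITIONS}
    )
    include_age: dict[tuple[int, int], bool] = field(
        default_factory=lambda: {t: True for t in TRANSITIONS}
    )

    def __post_init__(self) -> None:
        for t in TRANSITIONS:
            for c in self.covariates.get(t, ()):
                if c not in COVARIATES:
                    raise ValueError(f"unknown covariate {c!r} in spec for {t}")

    @classmethod
    def null(cls) -> "ModelSpec":
        """Age slope only (the covariate-free Gompertz model, k = 8)."""
        return cls(covariates={t: () for t in TRANSITIONS})

    @classmethod
    def single(cls, covariate: str) -> "ModelSpec":
        """Age slope plus one covariate on every transition (unadjusted fits)."""
        return cls(covariates={t: (covariate,) for t in TRANSITIONS})

    @classmethod
    def homogeneous(cls, covariates: tuple[str, ...] = ()) -> "ModelSpec":
        return cls(
            covariates={t: tuple(covariates) for t in TRANSITIONS},
            include_age={t: False for t in TRANSITIONS},
        )

    @property
    def n_params(self) -> int:
        return sum(
            1 + int(self.include_age[t]) + len(self.covariates[t]) for t in TRANSITIONS
        )

    def param_names(self) -> list[str]:
        names = []
        for t in TRANSITIONS:
            lab = TRANSITION_LABELS[t]
            names.append(f"{lab}:baseline")
            if self.include_age[t]:
                names.append(f"{lab}:age")
            names.extend(f"{lab}:{c}" for c in self.covariates[t])
        return names

    # -- packing ---------------------------------------------------------
    def pack(self, params: "TransitionParams") -> np.ndarray:
        theta = []
        for i, t in enumerate(TRANSITIONS):
            theta.append(params.beta0[i])
            if self.include_age[t]:
                theta.append(params.xi[i])
            for c in self.covariates[t]:
                theta.append(params.beta[i, COVARIATES.index(c)])
        return np.array(theta, dtype=float)

    def _index_maps(self):
        """Positions of each packed coefficient in (beta0, xi, beta) storage."""
        b0_pos, xi_pos, beta_pos = [], [], []
        j = 0
        for i, t in enumerate(TRANSITIONS):
            b0_pos.append((j, i))
            j += 1
            if self.include_age[t]:
                xi_pos.append((j, i))
                j += 1
            for c in self.covariates[t]:
                beta_pos.append((j, i, COVARIATES.index(c)))
                j += 1
        return b0_pos, xi_pos, beta_pos

    def unpack_batch(self, thetas: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorised unpack: (T, k) -> beta0 (T, 4), xi (T, 4), beta (T, 4, 5)."""
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        T = thetas.shape[0]
        beta0 = np.zeros((T, 4))
        xi = np.zeros((T, 4))
        beta = np.zeros((T, 4, len(COVARIATES)))
        b0_pos, xi_pos, beta_pos = self._index_maps()
        for j, i in b0_pos:
            beta0[:, i] = thetas[:, j]
        for j, i in xi_pos:
            xi[:, i] = thetas[:, j]
        for j, i, c in beta_pos:
            beta[:, i, c] = thetas[:, j]
        return beta0, xi, beta

    def unpack(self, theta: np.ndarray) -> "TransitionParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(f"expected {self.n_params} parameters, got {theta.shape}")
        beta0 = np.zeros(4)
        xi = np.zeros(4)
        beta = np.zeros((4, len(COVARIATES)))
        j = 0
        for i, t in enumerate(TRANSITIONS):
            beta0[i] = theta[j]
            j += 1
            if self.include_age[t]:
                xi[i] = theta[j]
                j += 1
            for c in self.covariates[t]:
                beta[i, COVARIATES.index(c)] = theta[j]
                j += 1
        return TransitionParams(beta0=beta0, xi=xi, beta=beta)


@dataclass(frozen=True)
class TransitionParams:
    """Intensity parameters for the four transitions, in TRANSITIONS order.

    ``beta0``: (4,) log baseline intensities; ``xi``: (4,) Gompertz age
    slopes; ``beta``: (4, 5) covariate log hazard ratios (columns follow
    :data:`~needsmsm.panel.COVARIATES`; excluded terms are zero).
    """

    beta0: np.ndarray
    xi: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta0", np.asarray(self.beta0, dtype=float))
        object.__setattr__(self, "xi", np.asarray(self.xi, dtype=float))
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        if self.beta0.shape != (4,) or self.xi.shape != (4,):
            raise ValueError("beta0 and xi must have shape (4,)")
        if self.beta.shape != (4, len(COVARIATES)):
            raise ValueError(f"beta must have shape (4, {len(COVARIATES)})")
        for arr, name in ((self.beta0, "beta0"), (self.xi, "xi"), (self.beta, "beta")):
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite value in {name}")

    @classmethod
    def from_dicts(cls, beta0: dict, xi: dict | None = None, beta: dict | None = None) -> "TransitionParams":
        """Build from mappings keyed by transition tuples, e.g.
        ``TransitionParams.from_dicts({(1, 2): np.log(0.5), ...})``."""
        b0 = np.full(4, -np.inf)
        x = np.zeros(4)
        b = np.zeros((4, len(COVARIATES)))
        for i, t in enumerate(TRANSITIONS):
            b0[i] = float(beta0[t])
            if xi:
                x[i] = float(xi.get(t, 0.0))
            if beta:
                for c, v in beta.get(t, {}).items():
                    b[i, COVARIATES.index(c)] = float(v)
        return cls(beta0=b0, xi=x, beta=b)

    @property
    def is_homogeneous(self) -> bool:
        return bool(np.all(self.xi == 0.0))

    def index(self, transition: tuple[int, int]) -> int:
        return TRANSITIONS.index(_check_transition(transition))


def _as_z(z) -> np.ndarray:
    if isinstance(z, CovariateProfile):
        return z.as_array()
    z = np.asarray(z, dtype=float)
    if z.shape[-1] != len(COVARIATES):
        raise ValueError(f"covariate vector must have length {len(COVARIATES)}")
    return z


def linear_predictors(p: TransitionParams, age, z) -> np.ndarray:
    """Log intensities for all four transitions; broadcasts over age/z.

    Returns an array with a leading axis of length 4 (TRANSITIONS order).
    """
    zarr = np.atleast_2d(_as_z(z))
    age = np.asarray(age, dtype=float)
    return p.beta0[:, None] + p.xi[:, None] * (age - AGE_REF) + p.beta @ zarr.T


def transition_intensity(p: TransitionParams, transition: tuple[int, int], age, z) -> float | np.ndarray:
    """Intensity q_rs(age, z) in events per year.

    Multiplicative (proportional-intensity) in the covariates:
    ``rate(z) / rate(0) = exp(beta_rs . z)``.
    """
    i = p.index(transition)
    zarr = _as_z(z)
    lp = p.beta0[i] + p.xi[i] * (np.asarray(age, dtype=float) - AGE_REF) + zarr @ p.beta[i]
    out = np.exp(lp)
    if np.ndim(out) == 0:
        return float(out)
    return out


def intensity_rates(p: TransitionParams, age, z) -> np.ndarray:
    """All four intensities at once: array (4,) or (4, n)."""
    return np.exp(linear_predictors(p, age, z)).squeeze()


def build_generator(p: TransitionParams, age: float, z) -> np.ndarray:
    """Assemble the 3x3 generator Q at one age and covariate profile.

    Off-diagonals hold the allowed intensities, disallowed cells are zero,
    rows sum to zero and the death row is identically zero.
    """
    q = np.exp(
        p.beta0 + p.xi * (float(age) - AGE_REF) + p.beta @ _as_z(z)
    )  # (4,) in TRANSITIONS order
    if not np.isfinite(q).all():
        bad = TRANSITION_LABELS[TRANSITIONS[int(np.flatnonzero(~np.isfinite(q))[0])]]
        raise FloatingPointError(f"non-finite intensity for transition {bad}")
    Q = np.zeros((3, 3))
    for rate, (r, s) in zip(q, TRANSITIONS):
        Q[r - 1, s - 1] = rate
    np.fill_diagonal(Q, 0.0)
    Q[0, 0] = -(Q[0, 1] + Q[0, 2])
    Q[1, 1] = -(Q[1, 0] + Q[1, 2])
    return Q
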