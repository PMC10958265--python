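"""Report tables: transition probabilities, hazard ratios, life expectancies.

The three table builders mirror the standard presentation of a
three-state needs/death analysis: 2-year transition probabilities by
multimorbidity group (covariates at dummy means), unadjusted and
adjusted hazard ratios per transition, and total/marginal/state-specific
life expectancies with %UMLE by subgroup.  Interval estimates for
probabilities and life expectancies use the same parameter-simulation
sampler (multivariate-normal draws around the ML estimate).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimation import FittedModel, fit_msm, hazard_ratio_table
from .intensities import ModelSpec
from .life_expectancy import (
    DEFAULT_H,
    DEFAULT_MAX_AGE,
    le_confidence_intervals,
    life_expectancies,
)
from .likelihood import interval_probability
from .panel import COVARIATES, PanelDataset

MULTIMORBIDITY_GROUPS = {"none": (0.0, 0.0), "P": (1.0, 0.0), "PM": (0.0, 1.0)}

_PROB_ROWS = (
    ("unmet->met", 1, 2),
    ("met->unmet", 2, 1),
    ("unmet->death", 1, 3),
    ("met->death", 2, 3),
    ("met->met", 2, 2),
    ("unmet->unmet", 1, 1),
)


def _group_profile(panel: PanelDataset, group: str) -> np.ndarray:
    """Dummy means for sex/education with multimorbidity set to a group."""
    z = panel.covariate_means().as_array().copy()
    z[3], z[4] = MULTIMORBIDITY_GROUPS[group]
    return z


def transition_probability_table(
    fit: FittedModel,
    panel: PanelDataset,
    age: float | None = None,
    horizon: float = 2.0,
    B: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Transition/persistence probabilities over a horizon by multimorbidity.

    Age defaults to the baseline mean age; the remaining covariates are
    fixed at their baseline dummy means.  CIs are percentile intervals
    over ``B`` multivariate-normal parameter draws.
    """
    if age is None:
        age = float(panel.baseline()["age"].mean())
    rng = np.random.default_rng(seed)
    if fit.vcov is None:
        raise ValueError("fit has no covariance matrix")
    thetas = rng.multivariate_normal(fit.theta, fit.vcov, size=B, method="eigh")
    rows = []
    for group in MULTIMORBIDITY_GROUPS:
        z = _group_profile(panel, group)
        P = interval_probability(fit.params, z, age, age + horizon, fit.cfg)
        draws = np.empty((B, len(_PROB_ROWS)))
        for b in range(B):
            p_b = fit.spec.unpack(thetas[b])
            Pb = interval_probability(p_b, z, age, age + horizon, fit.cfg)
            draws[b] = [Pb[r, s] for _, r, s in _PROB_ROWS]
        lo = np.percentile(draws, 2.5, axis=0)
        hi = np.percentile(draws, 97.5, axis=0)
        for (label, r, s), l, u in zip(_PROB_ROWS, lo, hi):
            rows.append(
                {
                    "multimorbidity": group,
                    "transition": label,
                    "estimate": P[r, s],
                    "ci_low": float(l),
                    "ci_high": float(u),
                }
            )
    return pd.DataFrame(rows)


def hazard_ratio_report(
    panel: PanelDataset,
    fit_full: FittedModel,
    *,
    include_unadjusted: bool = True,
    maxiter: int = 300,
) -> pd.DataFrame:
    """Adjusted (full-model) and optionally unadjusted hazard ratios.

    Unadjusted rows come from single-covariate refits through the same
    fitting path (the age row from the covariate-free Gompertz model).
    """
    adj = hazard_ratio_table(fit_full).rename(
        columns={"hr": "hr_adjusted", "ci_low": "ci_low_adjusted", "ci_high": "ci_high_adjusted"}
    )
    adj = adj.drop(columns=["se_log"])
    if not include_unadjusted:
        return adj
    frames = []
    for cov in [None, *COVARIATES]:
        spec = ModelSpec.null() if cov is None else ModelSpec.single(cov)
        f = fit_msm(panel, spec, fit_full.cfg, maxiter=maxiter)
        tab = hazard_ratio_table(f)
        tab = tab[tab["term"] == ("age" if cov is None else cov)]
        frames.append(tab)
    unadj = pd.concat(frames, ignore_index=True).rename(
        columns={"hr": "hr_unadjusted", "ci_low": "ci_low_unadjusted", "ci_high": "ci_high_unadjusted"}
    )
    unadj = unadj.drop(columns=["se_log"])
    return unadj.merge(adj, on=["transition", "term"], how="outer")


def life_expectancy_table(
    fit: FittedModel,
    panel: PanelDataset,
    ages: tuple[float, ...] = (60.0,),
    h: float = DEFAULT_H,
    max_age: float = DEFAULT_MAX_AGE,
    B: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """LE summary rows: overall and by sex, education and multimorbidity.

    Each subgroup profile overrides its own dummies and keeps the other
    covariates at baseline dummy means.  Columns carry TLE, marginal LEs,
    %UMLE and the four state-specific LEs, each with simulation CIs.
    """
    means = panel.covariate_means().as_array()
    profiles: dict[str, np.ndarray] = {"overall": means.copy()}
    for label, female in (("male", 0.0), ("female", 1.0)):
        z = means.copy()
        z[0] = female
        profiles[label] = z
    for label, (mid, high) in (("edu_low", (0, 0)), ("edu_mid", (1, 0)), ("edu_high", (0, 1))):
        z = means.copy()
        z[1], z[2] = mid, high
        profiles[label] = z
    for group, (mp, mpm) in MULTIMORBIDITY_GROUPS.items():
        z = means.copy()
        z[3], z[4] = mp, mpm
        profiles[f"multi_{group}"] = z

    ss = np.random.SeedSequence(seed)
    rows = []
    for age in ages:
        for label, z in profiles.items():
            ci = le_confidence_intervals(
                fit, panel, z, age, B=B,
                seed=int(ss.spawn(1)[0].generate_state(1)[0] % (2**31)),
                h=h, max_age=max_age, repair_vcov=True,
            )
            row = {"age": age, "group": label}
            for q, v in ci.point.items():
                row[q] = v
                row[f"{q}_ci_low"] = ci.lower[q]
                row[f"{q}_ci_high"] = ci.upper[q]
            rows.append(row)
    return pd.DataFrame(rows)


def marginal_le_by_age(
    fit: FittedModel,
    panel: PanelDataset,
    ages: np.ndarray | tuple[float, ...] = tuple(range(50, 95, 5)),
    groups: tuple[str, ...] = ("none", "P", "PM"),
    h: float = DEFAULT_H,
    max_age: float = DEFAULT_MAX_AGE,
) -> pd.DataFrame:
    """Marginal LEs and %UMLE across estimation ages (figure-style export)."""
    rows = []
    for group in groups:
        z = _group_profile(panel, group)
        for age in ages:
            le = life_expectancies(fit, panel, z, float(age), h, max_age)
            rows.append(
                {
                    "group": group,
                    "age": float(age),
                    "marginal_unmet": le.marginal_unmet,
                    "marginal_met": le.marginal_met,
                    "total": le.total,
                    "pct_unmet": le.pct_unmet,
                }
            )
    return pd.DataFrame(rows)
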