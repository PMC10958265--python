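"""Run configuration (YAML) and the end-to-end pipeline.

A run configuration names the input panel, the model settings and the
life-expectancy settings; :func:`run_full_pipeline` executes
validate -> (optional) impute -> fit -> predict -> life expectancies,
writing a fit archive, three CSV tables and a log.  Every artefact is
stamped with the configuration hash and seed; deterministic stages are
bit-identical on rerun, stochastic stages are identical under the same
seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .estimation import fit_msm
from .intensities import ModelSpec, TRANSITIONS
from .likelihood import BandingConfig
from .panel import COVARIATES, read_panel, transition_count_table, validate_panel
from .simulate import impute_death_dates

log = logging.getLogger("needsmsm")


@dataclass
class RunConfig:
    panel: str
    out_dir: str = "needsmsm_out"
    # model
    covariates: tuple[str, ...] = COVARIATES
    include_age: bool = True
    h_lik: float = 1.0
    death_convention: str = "exact"
    impute_missing_death_dates: bool = True
    maxiter: int = 150
    include_unadjusted_hr: bool = False
    # predictions
    prob_horizon: float = 2.0
    # life expectancy
    le_ages: tuple[float, ...] = (60.0,)
    le_h: float = 0.5
    max_age: float = 115.0
    B: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("h_lik", "le_h", "max_age", "B", "prob_horizon", "maxiter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.covariates) - set(COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates in config: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("covariates", "le_ages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            covariates={t: tuple(self.covariates) for t in TRANSITIONS},
            include_age={t: self.include_age for t in TRANSITIONS},
        )

    def banding(self) -> BandingConfig:
        return BandingConfig(h_lik=self.h_lik, death_convention=self.death_convention)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_full_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the whole analysis; returns the paths of the written artefacts."""
    from .reporting import (
        hazard_ratio_report,
        life_expectancy_table,
        transition_probability_table,
    )

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stamp = {"config_hash": cfg.digest(), "seed": cfg.seed}
    paths: dict[str, Path] = {}
    try:
        log.info("pipeline start: %s", stamp)
        stage = "validate"
        panel = read_panel(cfg.panel, strict=False)
        report = validate_panel(panel)
        if report:
            raise ValueError(f"panel failed validation: {report[0]} (+{len(report) - 1} more)")
        log.info("panel: %d subjects, %d observations, %d pairs",
                 panel.n_subjects, panel.n_obs, panel.n_pairs)
        log.info("transition count table:\n%s", transition_count_table(panel))

        stage = "impute"
        if cfg.impute_missing_death_dates:
            panel = impute_death_dates(panel, seed=cfg.seed)
            log.info("imputed death dates for %d subjects",
                     len(getattr(panel, "imputed_subjects", [])))

        stage = "fit"
        t0 = time.time()
        fit = fit_msm(panel, cfg.model_spec(), cfg.banding(), maxiter=cfg.maxiter)
        log.info("fit: -2loglik=%.2f AIC=%.2f k=%d converged=%s grad_norm=%.2e (%.1fs)",
                 fit.minus2loglik, fit.aic, fit.k, fit.converged,
                 fit.gradient_norm, time.time() - t0)
        paths["fit"] = out / "fit.json"
        payload = json.loads(fit.to_json())
        payload.update(stamp)
        paths["fit"].write_text(json.dumps(payload, indent=2))

        stage = "hazard-ratios"
        hr = hazard_ratio_report(panel, fit, include_unadjusted=cfg.include_unadjusted_hr)
        paths["hr"] = out / "hazard_ratios.csv"
        hr.to_csv(paths["hr"], index=False)

        stage = "predict"
        probs = transition_probability_table(
            fit, panel, horizon=cfg.prob_horizon, B=cfg.B, seed=cfg.seed
        )
        paths["probs"] = out / "transition_probabilities.csv"
        probs.to_csv(paths["probs"], index=False)

        stage = "life-expectancy"
        le = life_expectancy_table(
            fit, panel, ages=cfg.le_ages, h=cfg.le_h, max_age=cfg.max_age,
            B=cfg.B, seed=cfg.seed,
        )
        paths["le"] = out / "life_expectancy.csv"
        le.to_csv(paths["le"], index=False)
        log.info("pipeline complete: %s", {k: str(v) for k, v in paths.items()})
    except Exception:
        log.exception("pipeline failed at stage %r", stage)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return paths
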