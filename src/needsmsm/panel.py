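"""Long-format interval-censored panel data for the three-state needs model.

States
------
1   unmet healthcare needs (living)
2   met healthcare needs (living)
3   dead (absorbing)
0   alive at contact but living state unknown (right-censoring marker;
    admissible only as the final record of a subject)

Observations are wave-based: living states are known only at interview
ages (interval censoring), deaths carry an exact or imputed age, and a
terminal state-0 record encodes "known alive, state unknown".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STATE_UNMET = 1
STATE_MET = 2
STATE_DEAD = 3
STATE_CENSORED_ALIVE = 0

LIVING_STATES = (STATE_UNMET, STATE_MET)
OBSERVABLE_STATES = (STATE_CENSORED_ALIVE, STATE_UNMET, STATE_MET, STATE_DEAD)

#: covariate columns, in the fixed order used throughout the package
COVARIATES = ("female", "edu_mid", "edu_high", "multi_P", "multi_PM")

PANEL_COLUMNS = ("subject_id", "wave", "age", "state", "death_date_known") + COVARIATES


class PanelSchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


class PanelValidationError(ValueError):
    """The panel violates a structural invariant (raised on strict reads)."""


@dataclass(frozen=True)
class CovariateProfile:
    """Binary covariates relative to reference male / low education / no
    multimorbidity.  Fractional values are allowed only in prediction
    contexts (dummy means), never in data records."""

    female: float = 0.0
    edu_mid: float = 0.0
    edu_high: float = 0.0
    multi_P: float = 0.0
    multi_PM: float = 0.0

    def __post_init__(self) -> None:
        if self.edu_mid + self.edu_high > 1 + 1e-9:
            raise ValueError("edu_mid + edu_high must be <= 1")
        if self.multi_P + self.multi_PM > 1 + 1e-9:
            raise ValueError("multi_P + multi_PM must be <= 1")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in COVARIATES], dtype=float)

    @classmethod
    def from_mapping(cls, m) -> "CovariateProfile":
        return cls(**{c: float(m.get(c, 0.0)) for c in COVARIATES})


@dataclass(frozen=True)
class Observation:
    subject_id: str
    wave: int
    age: float
    state: int
    death_date_known: bool | None = None
    covariates: CovariateProfile = field(default_factory=CovariateProfile)

    def __post_init__(self) -> None:
        if self.state not in OBSERVABLE_STATES:
            raise ValueError(f"state must be one of {OBSERVABLE_STATES}, got {self.state}")
        if self.age <= 0:
            raise ValueError("age must be positive")


@dataclass(frozen=True)
class Violation:
    subject_id: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] subject {self.subject_id}: {self.message}"


@dataclass
class PairArrays:
    """Consecutive-observation pairs flattened to numpy arrays.

    One entry per likelihood contribution; ``z`` holds the covariates of
    the pair's left endpoint (piecewise-constant covariates between waves).
    """

    from_state: np.ndarray  # int, in {1,2}
    to_state: np.ndarray    # int, in {0,1,2,3}
    from_age: np.ndarray
    to_age: np.ndarray
    death_date_known: np.ndarray  # bool, meaningful when to_state == 3
    z: np.ndarray           # (n_pairs, 5)
    subject_id: np.ndarray  # object, for diagnostics

    @property
    def n(self) -> int:
        return len(self.from_state)


class PanelDataset:
    """Validated long-format panel, one row per subject-wave.

    Wraps a :class:`pandas.DataFrame` sorted by (subject_id, age) with the
    columns of :data:`PANEL_COLUMNS`.  Covariates are stored per row, so a
    time-varying multimorbidity status is simply a covariate value that
    changes across a subject's rows.
    """

    def __init__(self, df: pd.DataFrame, *, validate: bool = True):
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise PanelSchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        df = df.loc[:, list(PANEL_COLUMNS)].copy()
        df["subject_id"] = df["subject_id"].astype(str)
        df["wave"] = df["wave"].astype(int)
        df["age"] = df["age"].astype(float)
        df["state"] = df["state"].astype(int)
        df["death_date_known"] = pd.array(df["death_date_known"], dtype="Int64")
        for c in COVARIATES:
            df[c] = df[c].astype(float)
        # canonical order is the observation sequence; age monotonicity
        # along it is a validation rule, not a sorting artefact
        df = df.sort_values(["subject_id", "wave"], kind="stable").reset_index(drop=True)
        self.df = df
        if validate:
            report = validate_panel(self)
            if report:
                raise PanelValidationError(
                    "; ".join(str(v) for v in report[:5])
                    + (f" (+{len(report) - 5} more)" if len(report) > 5 else "")
                )

    # -- basic accessors -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.df["subject_id"].nunique()

    @property
    def n_obs(self) -> int:
        return len(self.df)

    def subject_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["subject_id"]))

    def observations(self) -> Iterable[Observation]:
        for row in self.df.itertuples(index=False):
            yield Observation(
                subject_id=row.subject_id,
                wave=row.wave,
                age=row.age,
                state=row.state,
                death_date_known=None if pd.isna(row.death_date_known) else bool(row.death_date_known),
                covariates=CovariateProfile(
                    row.female, row.edu_mid, row.edu_high, row.multi_P, row.multi_PM
                ),
            )

    def baseline(self) -> pd.DataFrame:
        """First record of each subject (used for prevalence modelling)."""
        return self.df.groupby("subject_id", sort=False).head(1)

    def covariate_means(self) -> CovariateProfile:
        """Baseline dummy means, the profile used for table-style predictions."""
        base = self.baseline()
        return CovariateProfile(*(float(base[c].mean()) for c in COVARIATES))

    # -- likelihood plumbing --------------------------------------------
    def pairs(self) -> PairArrays:
        """All consecutive-record pairs whose left endpoint is a living state."""
        df = self.df
        sid = df["subject_id"].to_numpy()
        same = sid[:-1] == sid[1:]
        left_alive = np.isin(df["state"].to_numpy()[:-1], LIVING_STATES)
        idx = np.flatnonzero(same & left_alive)
        ddk = df["death_date_known"].to_numpy(dtype=object)[idx + 1]
        return PairArrays(
            from_state=df["state"].to_numpy()[idx],
            to_state=df["state"].to_numpy()[idx + 1],
            from_age=df["age"].to_numpy()[idx],
            to_age=df["age"].to_numpy()[idx + 1],
            death_date_known=np.array([bool(x) if x is not None and not pd.isna(x) else False for x in ddk]),
            z=df[list(COVARIATES)].to_numpy()[idx],
            subject_id=sid[idx],
        )

    @property
    def n_pairs(self) -> int:
        return self.pairs().n

    def __eq__(self, other) -> bool:
        if not isinstance(other, PanelDataset):
            return NotImplemented
        a, b = self.df, other.df
        if a.shape != b.shape:
            return False
        if not (a["subject_id"].to_numpy() == b["subject_id"].to_numpy()).all():
            return False
        num = list(PANEL_COLUMNS[1:])
        return bool(
            np.allclose(a[num].astype(float).fillna(-1), b[num].astype(float).fillna(-1))
        )


# -- validation ----------------------------------------------------------

def validate_panel(panel: PanelDataset | pd.DataFrame) -> list[Violation]:
    """Structural validation; violations are data, not exceptions.

    Rules checked: state codes, positive ages, strictly increasing ages
    within subject, death absorbing (single, final state-3 record),
    censored-alive terminal, binary covariate values in records, and the
    education/multimorbidity dummy exclusivity.
    """
    df = panel.df if isinstance(panel, PanelDataset) else panel
    out: list[Violation] = []
    bad_state = df.loc[~df["state"].isin(OBSERVABLE_STATES)]
    for sid, st in zip(bad_state["subject_id"], bad_state["state"]):
        out.append(Violation(str(sid), "state-code", f"state {st} not in {OBSERVABLE_STATES}"))
    bad_age = df.loc[df["age"] <= 0]
    for sid in bad_age["subject_id"]:
        out.append(Violation(str(sid), "age-positive", "non-positive age"))
    for c in COVARIATES:
        if df[c].isna().any():
            for sid in df.loc[df[c].isna(), "subject_id"].unique():
                out.append(Violation(str(sid), "covariate-missing", f"missing value for {c}"))
        bad = df.loc[~df[c].isin([0.0, 1.0]) & df[c].notna(), "subject_id"]
        for sid in bad.unique():
            out.append(Violation(str(sid), "covariate-binary", f"{c} not in {{0,1}} in a data record"))
    if ((df["edu_mid"] + df["edu_high"]) > 1).any():
        for sid in df.loc[(df["edu_mid"] + df["edu_high"]) > 1, "subject_id"].unique():
            out.append(Violation(str(sid), "education-exclusive", "edu_mid + edu_high > 1"))
    if ((df["multi_P"] + df["multi_PM"]) > 1).any():
        for sid in df.loc[(df["multi_P"] + df["multi_PM"]) > 1, "subject_id"].unique():
            out.append(Violation(str(sid), "multimorbidity-exclusive", "multi_P + multi_PM > 1"))

    for sid, g in df.groupby("subject_id", sort=False):
        g = g.sort_values("wave", kind="stable")
        ages = g["age"].to_numpy()
        states = g["state"].to_numpy()
        waves = g["wave"].to_numpy()
        if len(waves) > 1 and not (np.diff(waves) > 0).all():
            out.append(Violation(str(sid), "wave-order", "duplicate or non-increasing wave indices"))
        if len(ages) > 1 and not (np.diff(ages) > 0).all():
            out.append(Violation(str(sid), "age-monotone", "ages not strictly increasing across waves"))
        dead = np.flatnonzero(states == STATE_DEAD)
        if len(dead) > 1:
            out.append(Violation(str(sid), "death-absorbing", "more than one death record"))
        elif len(dead) == 1 and dead[0] != len(states) - 1:
            out.append(Violation(str(sid), "death-absorbing", "observation recorded after death"))
        cens = np.flatnonzero(states == STATE_CENSORED_ALIVE)
        if len(cens) and (len(cens) > 1 or cens[0] != len(states) - 1):
            out.append(Violation(str(sid), "censored-terminal", "state-0 record must be the single final record"))
    return out


# -- I/O ------------------------------------------------------------------

def read_panel(path: str | Path, *, strict: bool = True) -> PanelDataset:
    """Read a long-format CSV panel.

    The header ``subject_id,wave,age,state,death_date_known,female,edu_mid,
    edu_high,multi_P,multi_PM`` is mandatory; ``death_date_known`` may be
    ``NA`` for living states.  With ``strict=True`` (default) structural
    violations raise :class:`PanelValidationError`; otherwise they are left
    to :func:`validate_panel`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, na_values=["NA", ""], dtype={"subject_id": str})
    except (ValueError, OSError) as exc:
        raise PanelSchemaError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelSchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    for i, (col, ok) in enumerate(
        [("age", df["age"].notna()), ("state", df["state"].notna())]
    ):
        if not ok.all():
            lines = (np.flatnonzero(~ok.to_numpy()) + 2).tolist()  # +2: header + 1-based
            raise PanelSchemaError(f"{path}: malformed {col} at line(s) {lines[:10]}")
    return PanelDataset(df, validate=strict)


def write_panel(panel: PanelDataset, path: str | Path) -> None:
    df = panel.df.copy()
    df["death_date_known"] = df["death_date_known"].astype(object)
    df.loc[df["death_date_known"].isna(), "death_date_known"] = "NA"
    df.to_csv(path, index=False)


def panel_from_records(records: Sequence[dict]) -> PanelDataset:
    """Build a panel from plain dicts (mainly for tests and examples)."""
    df = pd.DataFrame.from_records(records)
    if "death_date_known" not in df.columns:
        df["death_date_known"] = pd.NA
    for c in COVARIATES:
        if c not in df.columns:
            df[c] = 0.0
    return PanelDataset(df)


# -- descriptive statistics ----------------------------------------------

def transition_count_table(panel: PanelDataset) -> pd.DataFrame:
    """3x3 table of consecutive-wave observed state-pair counts.

    Counts ordered pairs (state at wave w, state at wave w+1) over all
    subjects; pairs spanning a skipped wave and pairs involving a
    censored-alive marker are excluded.  The grand total equals the number
    of consecutive observed wave pairs.
    """
    df = panel.df
    sid = df["subject_id"].to_numpy()
    wave = df["wave"].to_numpy()
    state = df["state"].to_numpy()
    ok = (
        (sid[:-1] == sid[1:])
        & (wave[1:] == wave[:-1] + 1)
        & np.isin(state[:-1], LIVING_STATES)
        & (state[1:] != STATE_CENSORED_ALIVE)
    )
    idx = np.flatnonzero(ok)
    table = np.zeros((3, 3), dtype=int)
    for a, b in zip(state[idx], state[idx + 1]):
        table[a - 1, b - 1] += 1
    labels = ["unmet", "met", "dead"]
    return pd.DataFrame(table, index=labels, columns=labels)
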