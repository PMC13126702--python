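"""Coefficient ("beta") matrices driving action choice and depression effects.

Two matrix roles exist, each estimated per lockdown type (partial/full)
from logistic regressions on cohort data and consumed here as plain CSV:

* ``action_choice`` — rows are daily actions, columns are an intercept
  plus the one-hot baseline features; the row dotted with an agent's
  feature vector is the log-odds that the agent takes that action that
  day.  With all coefficients zero the sigmoid gives 0.5, so
  action-choice intercepts are conventionally an explicit zero column.
* ``depression_effect`` — same layout plus an ``action`` column holding
  the action's own coefficient (the key independent variable in the
  underlying regression: symptoms ~ action + baseline features).  The
  row's contribution enters an agent's daily depression log-odds only on
  days the agent takes that action.

Estimation of the coefficients from cohort data is out of scope here; a
parameter-recovery refit for synthetic data lives in
:mod:`lockdownsim.synthetic_fixtures`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .synthpop import FeatureSchema

Role = Literal["action_choice", "depression_effect"]
LockdownType = Literal["partial", "full"]

INTERCEPT = "intercept"
ACTION_COL = "action"

#: The nine daily actions modeled (contracting COVID-19 is handled by the
#: infection module, not as a choice).
DEFAULT_ACTIONS: tuple[str, ...] = (
    "stay_home",
    "work_from_home",
    "exercise",
    "sedentary",
    "socially_connected",
    "feel_isolated",
    "positive_coping",
    "seek_help_network",
    "excess_drinking",
)


@dataclass(frozen=True)
class ActionCatalog:
    """Ordered action names plus the action forced during infection."""

    actions: tuple[str, ...] = DEFAULT_ACTIONS
    forced_when_infected: str = "stay_home"

    def __post_init__(self) -> None:
        if len(set(self.actions)) != len(self.actions):
            raise ValueError("action names must be unique")
        if self.forced_when_infected not in self.actions:
            raise ValueError(
                f"forced action {self.forced_when_infected!r} not in catalog"
            )

    @property
    def forced_index(self) -> int:
        return self.actions.index(self.forced_when_infected)


@dataclass
class BetaMatrix:
    """Validated coefficient matrix for one role and one lockdown type.

    ``table`` is indexed by action name; columns are ``intercept``,
    optionally ``action`` (depression_effect role only), then the one-hot
    feature columns in schema order.  Reference categories carry explicit
    zero columns rather than being dropped, because rows are dotted
    against full one-hot vectors.
    """

    role: Role
    lockdown_type: LockdownType
    table: pd.DataFrame

    def validate(self, schema: FeatureSchema, catalog: ActionCatalog) -> "BetaMatrix":
        cols = list(self.table.columns)
        expected = [INTERCEPT]
        if self.role == "depression_effect":
            expected.append(ACTION_COL)
        expected += list(schema.onehot_columns)
        missing = [c for c in expected if c not in cols]
        if missing:
            raise ValueError(
                f"{self.role}/{self.lockdown_type} matrix missing columns: {missing}"
            )
        extra = [c for c in self.table.columns if c not in expected]
        if extra:
            raise ValueError(
                f"{self.role}/{self.lockdown_type} matrix has columns not in the "
                f"schema: {extra}"
            )
        unknown = [a for a in self.table.index if a not in catalog.actions]
        if unknown:
            raise ValueError(f"unknown action rows: {unknown}")
        if self.table.index.duplicated().any():
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate action rows: {dupes}")
        if not np.isfinite(self.table.to_numpy(dtype=float)).all():
            raise ValueError("non-finite coefficient values")
        # canonical column/row order
        order = [a for a in catalog.actions if a in self.table.index]
        canon = self.table.loc[order, expected]
        canon.index.name = None
        object.__setattr__(self, "table", canon)
        return self

    def dense(self, schema: FeatureSchema, catalog: ActionCatalog) -> np.ndarray:
        """Coefficients as (n_actions, 1 + [1] + n_onehot) float array.

        Column 0 is the intercept; for the depression_effect role column 1
        is the action's own coefficient; remaining columns follow
        ``schema.onehot_columns``.  Rows follow catalog order; actions
        absent from the table get all-zero rows.
        """
        ncols = 1 + (self.role == "depression_effect") + len(schema.onehot_columns)
        out = np.zeros((len(catalog.actions), ncols))
        for i, a in enumerate(catalog.actions):
            if a in self.table.index:
                out[i] = self.table.loc[a].to_numpy(dtype=float)
        return out

    def write(self, path: str | Path) -> None:
        # shortest round-trip repr keeps full float precision in text
        self.table.to_csv(
            path, index_label="action_name",
            float_format=lambda v: repr(float(v)),
        )


def read_beta_matrix(
    path: str | Path,
    role: Role,
    lockdown_type: LockdownType,
    schema: FeatureSchema,
    catalog: ActionCatalog,
) -> BetaMatrix:
    """Read and validate a coefficient CSV (first column = action name)."""
    df = pd.read_csv(path, index_col=0)
    try:
        df = df.astype(float)
    except ValueError as err:
        raise ValueError(f"non-numeric coefficient in {path}: {err}") from err
    return BetaMatrix(role=role, lockdown_type=lockdown_type, table=df).validate(
        schema, catalog
    )


def default_depression_effect_betas() -> dict[str, dict[LockdownType, float]]:
    """Action-specific depression coefficients for the six reported actions.

    These are the per-action coefficients (the ``action`` column) from the
    depression-effect regressions: negative values protect, positive
    values raise the daily log-odds of depressive symptoms.  Feeling
    isolated is notably more harmful under a full lockdown, while the
    protective effect of exercise and social connection shrinks.
    """
    return {
        "exercise": {"partial": -0.52, "full": -0.40},
        "socially_connected": {"partial": -0.51, "full": -0.30},
        "positive_coping": {"partial": -0.18, "full": -0.06},
        "feel_isolated": {"partial": 0.68, "full": 1.18},
        "sedentary": {"partial": 0.19, "full": 0.29},
        "excess_drinking": {"partial": 0.15, "full": 0.38},
    }
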