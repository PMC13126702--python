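"""Daily depressive-symptom probability and status updates.

Each day the actions an agent actually took contribute to a depression
log-odds: for every taken action, the depression-effect row supplies an
intercept, the action's own coefficient, and feature-interaction terms
dotted with the agent's one-hot vector; rows of untaken actions
contribute nothing.  The summed log-odds passes through the sigmoid to a
daily probability.  When an agent takes no action, or the contributions
cancel out exactly, there is no behavioral signal: the probability is
instead drawn from the small positive baseline-drift distribution
N(0.002, 0.0005), truncated to [0, 1].

Symptomatic status is re-evaluated daily as a Bernoulli draw on the
current probability (non-absorbing), so the population symptomatic share
tracks the mean daily probability.  An absorbing variant — once
symptomatic, always symptomatic — is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import sigmoid
from .parameters import ActionCatalog, BetaMatrix
from .synthpop import FeatureSchema

#: |summed log-odds| below this is treated as "effects cancelled out".
ZERO_SIGNAL_TOL = 1e-12


@dataclass(frozen=True)
class BaselineEffect:
    """Normal distribution of the daily probability absent any action signal."""

    mean: float = 0.002
    sd: float = 0.0005

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    def draw(self, rng: np.random.Generator, size=None) -> np.ndarray | float:
        """Truncated-to-[0,1] normal draw (negative tail clamped to 0)."""
        out = np.clip(rng.normal(self.mean, self.sd, size=size), 0.0, 1.0)
        return out if size is not None else float(out)


def depression_logit(
    actions: np.ndarray,
    features: np.ndarray,
    betas: BetaMatrix,
    schema: FeatureSchema,
    catalog: ActionCatalog,
) -> np.ndarray:
    """Summed depression log-odds over taken actions.

    ``actions`` is a 0/1 vector (n_actions,) or matrix (n_agents,
    n_actions); ``features`` matches in first dimension.  Agents with no
    taken action get NaN — the no-signal sentinel consumed by
    :func:`daily_probability`.
    """
    if betas.role != "depression_effect":
        raise ValueError("depression_logit requires a depression_effect matrix")
    a = np.atleast_2d(np.asarray(actions, dtype=float))
    x = np.atleast_2d(np.asarray(features, dtype=float))
    k = len(schema.onehot_columns)
    if x.shape[1] != k:
        raise ValueError(f"feature vector length {x.shape[1]} != {k}")
    if a.shape[1] != len(catalog.actions):
        raise ValueError(
            f"action vector length {a.shape[1]} != {len(catalog.actions)}"
        )
    dense = betas.dense(schema, catalog)  # (A, 2 + k)
    # per-agent per-action row value: intercept + action beta + features
    row_val = dense[:, 0] + dense[:, 1] + x @ dense[:, 2:].T  # (n, A)
    total = (a * row_val).sum(axis=1)
    total[a.sum(axis=1) == 0] = np.nan
    return total if np.asarray(actions).ndim == 2 else float(total[0])


def daily_probability(
    logits,
    baseline: BaselineEffect,
    rng: np.random.Generator,
):
    """Map summed log-odds to the daily depressive-symptom probability.

    NaN (no action taken) or an exactly-cancelled signal triggers the
    baseline draw; otherwise the sigmoid of the log-odds is used.
    Baseline draws are consumed for every agent regardless of signal so
    the random stream is independent of the action pattern.
    """
    arr = np.atleast_1d(np.asarray(logits, dtype=float))
    no_signal = np.isnan(arr) | (np.abs(arr) < ZERO_SIGNAL_TOL)
    base = np.atleast_1d(baseline.draw(rng, size=arr.shape))
    p = np.where(no_signal, base, sigmoid(np.nan_to_num(arr)))
    return p if np.asarray(logits).ndim >= 1 else float(p[0])


def update_status(
    symptomatic: np.ndarray,
    p,
    rng: np.random.Generator,
    absorbing: bool = False,
) -> np.ndarray:
    """Daily Bernoulli re-evaluation of symptomatic status.

    With ``absorbing=True`` an agent who was ever symptomatic stays so.
    """
    cur = np.atleast_1d(np.asarray(symptomatic, dtype=bool))
    prob = np.broadcast_to(np.atleast_1d(np.asarray(p, dtype=float)), cur.shape)
    if np.any((prob < 0) | (prob > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    new = rng.random(cur.shape) < prob
    if absorbing:
        new = new | cur
    return new if np.asarray(symptomatic).ndim >= 1 else bool(new[0])
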