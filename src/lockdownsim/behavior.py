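"""Daily action choice: feature vector x coefficient matrix -> sampled actions.

For each agent and day, every action's log-odds is the action-choice
matrix row dotted with the agent's one-hot features (plus intercept); the
sigmoid maps it to a probability and an independent Bernoulli draw per
action decides whether the agent takes it.  Actions do not compete: an
agent may, for example, both work from home and exercise on the same day.
Infected agents get no choice — the stay-home action is forced to 1 and
every other action to 0.
"""

from __future__ import annotations

import numpy as np

from .parameters import ActionCatalog, BetaMatrix
from .synthpop import FeatureSchema

#: logits are clipped here before exponentiation; sigmoid is saturated far
#: beyond double precision well before this point.
LOGIT_CLIP = 500.0


def sigmoid(x):
    """Logistic transform 1/(1+e^(-x)), elementwise, overflow-safe."""
    x = np.clip(np.asarray(x, dtype=float), -LOGIT_CLIP, LOGIT_CLIP)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def action_logits(
    features: np.ndarray,
    betas: BetaMatrix,
    schema: FeatureSchema,
    catalog: ActionCatalog,
) -> np.ndarray:
    """Per-action log-odds for one agent or a population.

    ``features`` is a one-hot vector of length ``len(schema.onehot_columns)``
    or an (n_agents, n_onehot) matrix.  Returns shape (n_actions,) or
    (n_agents, n_actions): ``logit[a] = b0_a + sum_i beta_ai * x_i``.
    """
    if betas.role != "action_choice":
        raise ValueError("action_logits requires an action_choice matrix")
    x = np.atleast_2d(np.asarray(features, dtype=float))
    k = len(schema.onehot_columns)
    if x.shape[1] != k:
        raise ValueError(f"feature vector length {x.shape[1]} != {k}")
    dense = betas.dense(schema, catalog)  # (A, 1 + k)
    logits = x @ dense[:, 1:].T + dense[:, 0]
    return logits if np.asarray(features).ndim == 2 else logits[0]


def sample_actions(
    probs: np.ndarray,
    infected,
    rng: np.random.Generator,
    catalog: ActionCatalog,
) -> np.ndarray:
    """Independent Bernoulli draw per action; infection forces stay-home.

    ``probs`` is (n_actions,) or (n_agents, n_actions); ``infected`` a bool
    or bool vector.  Uniform draws are consumed for every agent/action in
    order (including infected agents) so the random stream does not depend
    on who is infected.
    """
    p = np.atleast_2d(np.asarray(probs, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("action probabilities must lie in [0, 1]")
    taken = (rng.random(p.shape) < p).astype(np.int8)
    mask = np.atleast_1d(np.asarray(infected, dtype=bool))
    if mask.size == 1 and p.shape[0] > 1:
        mask = np.repeat(mask, p.shape[0])
    taken[mask] = 0
    taken[mask, catalog.forced_index] = 1
    return taken if np.asarray(probs).ndim == 2 else taken[0]
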