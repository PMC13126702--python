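"""Synthetic population generation by iterative proportional fitting.

A target population is described by cross-tabulated categorical marginal
tables (e.g. counts by gender, by age group, by gender x age group).  A
full cross-classification weight table is raked axis-by-axis until every
supplied marginal is reproduced (multidimensional IPF), and agents are
then sampled with replacement with cell probability proportional to the
fitted weight.  Fidelity of a sampled population to the targets is
checked with Pearson chi-square tests per marginal.

"Unknown" levels are ordinary categories: high, not-at-random missingness
in survey data is represented as its own level rather than imputed, so the
synthesis preserves it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class ConvergenceError(RuntimeError):
    """IPF failed to reach the requested tolerance within ``max_iter`` sweeps."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered categorical features defining the one-hot agent encoding.

    Parameters
    ----------
    features
        Ordered ``(feature_name, categories)`` pairs.  Category order is
        meaningful: it fixes the one-hot column order and the axis order
        of weight tables.
    baseline_feature, baseline_category
        Optional tag naming the feature/category combination that marks an
        agent as having depressive symptoms at baseline (two or more
        endorsed symptoms on the 8-item MINI screener).
    """

    features: tuple[tuple[str, tuple[str, ...]], ...]
    baseline_feature: str | None = None
    baseline_category: str | None = None

    def __post_init__(self) -> None:
        if len(self.features) < 1:
            raise ValueError("schema needs at least one feature")
        names = [name for name, _ in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names")
        for name, cats in self.features:
            if len(cats) < 2:
                raise ValueError(f"feature {name!r} needs >=2 categories")
            if len(set(cats)) != len(cats):
                raise ValueError(f"duplicate categories in feature {name!r}")
        if self.baseline_feature is not None:
            if self.baseline_feature not in names:
                raise ValueError(
                    f"baseline feature {self.baseline_feature!r} not in schema"
                )
            cats = dict(self.features)[self.baseline_feature]
            if self.baseline_category not in cats:
                raise ValueError(
                    f"baseline category {self.baseline_category!r} not a level "
                    f"of {self.baseline_feature!r}"
                )

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.features)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(cats) for _, cats in self.features)

    def categories(self, feature: str) -> tuple[str, ...]:
        return dict(self.features)[feature]

    @property
    def onehot_columns(self) -> tuple[str, ...]:
        """Columns of the one-hot expansion, named ``feature=category``."""
        return tuple(
            f"{name}={cat}" for name, cats in self.features for cat in cats
        )

    def to_dict(self) -> dict:
        return {
            "features": [
                {"name": name, "categories": list(cats)}
                for name, cats in self.features
            ],
            "baseline_feature": self.baseline_feature,
            "baseline_category": self.baseline_category,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls(
            features=tuple(
                (f["name"], tuple(f["categories"])) for f in d["features"]
            ),
            baseline_feature=d.get("baseline_feature"),
            baseline_category=d.get("baseline_category"),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "FeatureSchema":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class MarginalTable:
    """Target totals on a subset of features (one axis or a cross-tab).

    ``counts`` has one dimension per feature in ``axis``, in schema
    category order.
    """

    axis: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != len(self.axis):
            raise ValueError("counts dimensionality must match axis length")
        if np.any(counts < 0):
            raise ValueError("marginal counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class WeightTable:
    """Full cross-classification of all schema features with a weight per cell."""

    schema: FeatureSchema
    weights: np.ndarray

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        if weights.shape != self.schema.shape:
            raise ValueError(
                f"weights shape {weights.shape} != schema shape {self.schema.shape}"
            )
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
        self.weights = weights

    @classmethod
    def uniform(cls, schema: FeatureSchema) -> "WeightTable":
        """All-ones seed: the maximum-entropy starting point."""
        return cls(schema, np.ones(schema.shape))

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    def marginal(self, axis: Sequence[str]) -> np.ndarray:
        """Sum the weights down to the given axis (schema feature order kept)."""
        names = self.schema.feature_names
        keep = [names.index(a) for a in axis]
        drop = tuple(i for i in range(len(names)) if i not in keep)
        out = self.weights.sum(axis=drop)
        # sum() keeps remaining axes in schema order; transpose to axis order
        kept_sorted = sorted(keep)
        perm = [kept_sorted.index(k) for k in keep]
        return np.transpose(out, perm) if perm != list(range(len(perm))) else out


def _check_marginals(schema: FeatureSchema, marginals: Iterable[MarginalTable]) -> None:
    names = schema.feature_names
    totals = []
    for m in marginals:
        for a in m.axis:
            if a not in names:
                raise ValueError(f"marginal axis feature {a!r} not in schema")
        expect = tuple(len(schema.categories(a)) for a in m.axis)
        if m.counts.shape != expect:
            raise ValueError(
                f"marginal on {m.axis} has shape {m.counts.shape}, expected {expect}"
            )
        totals.append(m.total)
    if not totals:
        raise ValueError("at least one marginal table is required")
    ref = totals[0]
    tol = 1e-6 * max(ref, 1.0)
    if any(abs(t - ref) > tol for t in totals):
        raise ValueError(
            f"marginal grand totals are inconsistent: {sorted(set(totals))}"
        )


def fit_ipf(
    seed_weights: WeightTable,
    marginals: Sequence[MarginalTable],
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> WeightTable:
    """Rake a weight table to match every marginal (multidimensional IPF).

    Each sweep rescales the table proportionally along every marginal's
    axis in turn.  Convergence is declared when the maximum absolute
    relative deviation of any fitted marginal from its target is below
    ``tol``; cells whose target is zero are compared absolutely against
    ``tol`` times the grand total.

    Raises
    ------
    ValueError
        Inconsistent marginal grand totals or axis/shape mismatches.
    ConvergenceError
        Tolerance not reached within ``max_iter`` sweeps (e.g. a
        structural zero in the seed conflicts with a positive marginal).
    """
    schema = seed_weights.schema
    _check_marginals(schema, marginals)
    w = seed_weights.weights.copy()
    names = schema.feature_names
    grand = marginals[0].total

    axis_info = []
    for m in marginals:
        keep = [names.index(a) for a in m.axis]
        drop = tuple(i for i in range(len(names)) if i not in keep)
        # broadcast shape putting the marginal back over the full table
        kept_sorted = sorted(keep)
        perm_to_schema = [m.axis.index(names[k]) for k in kept_sorted]
        bshape = tuple(
            len(schema.categories(names[i])) if i in keep else 1
            for i in range(len(names))
        )
        target_schema_order = np.transpose(m.counts, perm_to_schema)
        axis_info.append((drop, bshape, target_schema_order))

    for _ in range(max_iter):
        for drop, bshape, target in axis_info:
            cur = w.sum(axis=drop)
            with np.errstate(divide="ignore", invalid="ignore"):
                factor = np.where(cur > 0, target / np.where(cur > 0, cur, 1.0), 0.0)
            w *= factor.reshape(bshape)
        worst = 0.0
        for drop, _, target in axis_info:
            cur = w.sum(axis=drop)
            scale = np.where(target > 0, target, grand)
            worst = max(worst, float(np.max(np.abs(cur - target) / scale)))
        if worst < tol:
            return WeightTable(schema, w)
    raise ConvergenceError(
        f"IPF did not converge below tol={tol} in {max_iter} sweeps "
        f"(worst relative deviation {worst:.3g}); check for structural zeros "
        "conflicting with positive marginals"
    )


def sample_population(
    weights: WeightTable,
    n: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw ``n`` agents with replacement, cell probability proportional to weight.

    Returns an agent table with ``agent_id``, one column per one-hot
    indicator named ``feature=category`` (0/1), and ``baseline_depressive``
    (0/1, derived from the schema's tagged baseline feature; all zeros if
    the schema does not tag one).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    schema = weights.schema
    flat = weights.weights.ravel()
    total = flat.sum()
    if total <= 0:
        raise ValueError("total weight must be positive to sample agents")
    cells = rng.choice(flat.size, size=n, p=flat / total)
    idx = np.unravel_index(cells, weights.weights.shape)

    data: dict[str, np.ndarray] = {"agent_id": np.arange(n, dtype=int)}
    for j, (name, cats) in enumerate(schema.features):
        codes = idx[j] if n else np.array([], dtype=int)
        for k, cat in enumerate(cats):
            data[f"{name}={cat}"] = (codes == k).astype(np.int8)
    if schema.baseline_feature is not None:
        col = f"{schema.baseline_feature}={schema.baseline_category}"
        data["baseline_depressive"] = data[col].astype(np.int8)
    else:
        data["baseline_depressive"] = np.zeros(n, dtype=np.int8)
    return pd.DataFrame(data)


def agent_category_codes(agents: pd.DataFrame, schema: FeatureSchema) -> np.ndarray:
    """Integer category index per agent per feature, shape (n, n_features)."""
    cols = []
    for name, cats in schema.features:
        onehot = agents[[f"{name}={c}" for c in cats]].to_numpy()
        if not np.all(onehot.sum(axis=1) == 1):
            raise ValueError(f"feature {name!r} is not exactly-one-hot")
        cols.append(onehot.argmax(axis=1))
    return np.column_stack(cols) if cols else np.empty((len(agents), 0), int)


def chi2_fidelity(
    agents: pd.DataFrame,
    marginals: Sequence[MarginalTable],
    schema: FeatureSchema,
) -> pd.DataFrame:
    """Pearson chi-square test of the sampled population against each marginal.

    Expected counts are the marginal proportions scaled to the agent count.
    Categories with expected count zero are excluded; if such a category
    has observed agents it is flagged with a warning (the sample contains a
    combination the target says cannot occur).

    Returns a frame with one row per marginal: axis, statistic, p_value, dof.
    """
    if len(agents) == 0:
        raise ValueError("agent table is empty")
    _check_marginals(schema, marginals)
    n = len(agents)
    codes = agent_category_codes(agents, schema)
    names = schema.feature_names
    rows = []
    for m in marginals:
        shape = m.counts.shape
        ax_idx = [names.index(a) for a in m.axis]
        obs = np.zeros(shape)
        flat_codes = np.ravel_multi_index(
            tuple(codes[:, i] for i in ax_idx), shape
        )
        np.add.at(obs.ravel(), flat_codes, 1)
        exp = m.counts / m.total * n
        keep = exp.ravel() > 0
        bad = (~keep) & (obs.ravel() > 0)
        if bad.any():
            warnings.warn(
                f"marginal on {m.axis}: {int(bad.sum())} categor(ies) with "
                "expected count 0 but observed agents; excluded from the test",
                stacklevel=2,
            )
        o, e = obs.ravel()[keep], exp.ravel()[keep]
        e = e * o.sum() / e.sum()  # renormalize after exclusions
        if keep.sum() < 2:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.chisquare(o, e)
        rows.append(
            {
                "axis": "x".join(m.axis),
                "statistic": float(stat),
                "p_value": float(p),
                "dof": int(keep.sum() - 1),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# delimited-text I/O

def write_marginals(
    marginals: Sequence[MarginalTable], schema: FeatureSchema, path: str | Path
) -> None:
    """Write one-way marginals as a single long-format CSV with labels."""
    recs = []
    for m in marginals:
        if len(m.axis) != 1:
            raise ValueError("file format supports one-way marginals only")
        cats = schema.categories(m.axis[0])
        for cat, cnt in zip(cats, m.counts):
            recs.append({"feature": m.axis[0], "category": cat, "count": cnt})
    pd.DataFrame(recs).to_csv(path, index=False)


def read_marginals(path: str | Path, schema: FeatureSchema) -> list[MarginalTable]:
    """Read one-way marginals from long-format CSV (feature,category,count)."""
    df = pd.read_csv(path, dtype={"feature": str, "category": str})
    missing = {"feature", "category", "count"} - set(df.columns)
    if missing:
        raise ValueError(f"marginal file missing columns: {sorted(missing)}")
    out = []
    for feat, grp in df.groupby("feature", sort=False):
        cats = schema.categories(str(feat))
        lookup = dict(zip(grp["category"], grp["count"]))
        unknown = set(grp["category"]) - set(cats)
        if unknown:
            raise ValueError(f"unknown categories for {feat!r}: {sorted(unknown)}")
        counts = np.array([float(lookup.get(c, 0.0)) for c in cats])
        out.append(MarginalTable(axis=(str(feat),), counts=counts))
    return out
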