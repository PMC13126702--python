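"""Self-contained synthetic inputs for the full pipeline.

Real runs consume three external artifacts: cohort cross-tabulations (to
synthesize the population), four estimated coefficient matrices, and a
municipal case series.  None of those can ship with the package, so this
module generates statistically plausible stand-ins from a seeded spec:

* marginal tables over the ten baseline features used in the underlying
  cohort work (gender, age group, education, income, children, living
  alone, critical-sector employment, preexisting depression diagnosis,
  physical health, housing/financial difficulties — most with an
  "unknown" level for not-at-random missingness) plus a tagged baseline
  depressive-symptom indicator;
* coefficient matrices whose six published action-effect coefficients
  are inserted exactly and whose remaining cells are drawn from a
  configurable range, with depression-effect intercepts calibrated so
  typical action patterns yield daily probabilities near 0.1;
* a two-wave case curve at Dutch-province magnitude, so that scaling to
  a 1,000-agent population yields single-digit daily infections.

A parameter-recovery harness refits the generative logistic models on
simulated agent-days to confirm the coefficients are identifiable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import covid, synthpop
from .behavior import sigmoid
from .covid import CaseSeries
from .parameters import (
    ACTION_COL,
    DEFAULT_ACTIONS,
    INTERCEPT,
    ActionCatalog,
    BetaMatrix,
    default_depression_effect_betas,
)
from .synthpop import FeatureSchema, MarginalTable

#: Baseline features with category labels; "unknown" is an ordinary level.
DEFAULT_FEATURES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("gender", ("female", "male", "unknown")),
    ("age_group", ("24-34", "35-44", "45-54", "55-64")),
    ("education", ("low", "medium", "high", "unknown")),
    ("income", ("low", "medium", "high", "unknown")),
    ("has_children", ("no", "yes", "unknown")),
    ("lives_alone", ("no", "yes", "unknown")),
    ("critical_sector", ("no", "yes", "unknown")),
    ("preexisting_depression", ("no", "yes", "unknown")),
    ("physical_health", ("poor", "fair", "good", "unknown")),
    ("housing_financial_difficulties", ("no", "yes", "unknown")),
)

BASELINE_FEATURE = "depressive_baseline"


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic-input generator (all reproducible from seed)."""

    total: int = 52378  # grand total of every marginal (cohort-sample scale)
    baseline_depressive_share: float = 0.0349  # share symptomatic at day 0
    beta_range: float = 0.5  # unspecified coefficients ~ U(-range, +range)
    # Per-row intercept of the depression-effect matrices.  Summed over the
    # ~4.5 actions a typical agent takes per day this puts the daily
    # log-odds near -2.2, i.e. a mean daily probability near 0.1.
    depression_intercept: float = -0.5
    feature_beta_scale: float = 0.15  # depression feature-interaction spread
    real_population_n: int = 585_000  # province-scale N for case scaling
    case_peak: float = 600.0  # peak daily positives of each wave
    case_noise: float = 0.1  # multiplicative lognormal-ish noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline_depressive_share <= 1.0:
            raise ValueError("baseline share must lie in [0, 1]")
        if self.case_peak < 0 or self.total <= 0:
            raise ValueError("case_peak and total must be nonnegative/positive")


def default_schema() -> FeatureSchema:
    """Ten baseline features plus the tagged depressive-status indicator."""
    return FeatureSchema(
        features=DEFAULT_FEATURES + ((BASELINE_FEATURE, ("no", "yes")),),
        baseline_feature=BASELINE_FEATURE,
        baseline_category="yes",
    )


def _integer_split(total: int, props: np.ndarray) -> np.ndarray:
    """Largest-remainder rounding of proportions to integers summing to total."""
    raw = props / props.sum() * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(raw - base)[::-1]
    base[order[:short]] += 1
    return base


def generate_marginals(
    spec: FixtureSpec = FixtureSpec(),
) -> tuple[FeatureSchema, list[MarginalTable]]:
    """One-way marginal tables over the default schema, equal grand totals.

    Category proportions are Dirichlet draws biased toward a small
    "unknown" share, except the tagged depressive indicator whose "yes"
    share is pinned to the configured baseline share.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))
    schema = default_schema()
    marginals = []
    for name, cats in schema.features:
        if name == BASELINE_FEATURE:
            p = np.array(
                [1 - spec.baseline_depressive_share, spec.baseline_depressive_share]
            )
        else:
            alpha = np.full(len(cats), 8.0)
            if cats[-1] == "unknown":
                alpha[-1] = 2.0  # unknown is a real but smaller level
            p = rng.dirichlet(alpha)
        counts = _integer_split(spec.total, p)
        marginals.append(MarginalTable(axis=(name,), counts=counts.astype(float)))
    return schema, marginals


def generate_beta_matrices(
    spec: FixtureSpec = FixtureSpec(),
    catalog: ActionCatalog = ActionCatalog(),
) -> dict[tuple[str, str], BetaMatrix]:
    """Four coefficient matrices keyed by (role, lockdown_type).

    The six published action-effect coefficients are inserted exactly in
    the depression-effect matrices' ``action`` column; all other cells
    are seeded draws within ``spec.beta_range`` (action choice) or a
    smaller spread (depression feature interactions).  The unspecified
    cells are drawn once and shared between the partial and full
    matrices, so the only lockdown-specific quantities are the published
    coefficients: the fixture isolates the lockdown contrast in exactly
    the values that are known, instead of burying it in unknowable
    random differences.  Depression-effect intercepts sit well below
    zero so that typical 4-5-action days land near a 10% daily
    probability.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1,)))
    schema = default_schema()
    onehot = list(schema.onehot_columns)
    anchors = default_depression_effect_betas()
    ac_shared = rng.uniform(-spec.beta_range, spec.beta_range,
                            (len(catalog.actions), len(onehot)))
    de_shared = rng.normal(0.0, spec.feature_beta_scale,
                           (len(catalog.actions), len(onehot)))
    unanchored = {
        a: float(rng.uniform(-0.2, 0.2))
        for a in catalog.actions
        if a not in anchors
    }
    out: dict[tuple[str, str], BetaMatrix] = {}
    for ld in ("partial", "full"):
        ac = pd.DataFrame(ac_shared.copy(), index=list(catalog.actions),
                          columns=onehot)
        ac.insert(0, INTERCEPT, 0.0)
        out[("action_choice", ld)] = BetaMatrix(
            role="action_choice", lockdown_type=ld, table=ac
        ).validate(schema, catalog)

        de = pd.DataFrame(de_shared.copy(), index=list(catalog.actions),
                          columns=onehot)
        action_beta = pd.Series(
            {
                a: anchors[a][ld] if a in anchors else unanchored[a]
                for a in catalog.actions
            }
        )
        de.insert(0, ACTION_COL, action_beta)
        de.insert(0, INTERCEPT, spec.depression_intercept)
        out[("depression_effect", ld)] = BetaMatrix(
            role="depression_effect", lockdown_type=ld, table=de
        ).validate(schema, catalog)
    return out


def generate_case_curve(
    spec: FixtureSpec = FixtureSpec(), days: int = 366
) -> CaseSeries:
    """Two-wave synthetic daily incidence at province magnitude.

    Two raised-cosine waves (autumn larger than summer) plus seeded
    multiplicative noise, truncated at zero and rounded to whole cases.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(2,)))
    t = np.arange(days)
    wave1 = 0.4 * np.clip(np.cos((t - 0.25 * days) / days * 4 * np.pi), 0, None)
    wave2 = 1.0 * np.clip(np.cos((t - 0.65 * days) / days * 4 * np.pi), 0, None)
    curve = spec.case_peak * (wave1 + wave2)
    noise = rng.normal(1.0, spec.case_noise, days)
    daily = np.maximum(np.rint(curve * np.clip(noise, 0, None)), 0).astype(int)
    dates = pd.date_range("2020-06-11", periods=days, freq="D")
    return CaseSeries(
        dates=dates, new_cases=daily, real_population_n=spec.real_population_n
    )


def write_fixture_directory(
    outdir: str | Path, spec: FixtureSpec = FixtureSpec(), days: int = 366
) -> dict[str, Path]:
    """Write a complete runnable input directory; returns the path map.

    Contents: ``schema.json``, ``marginals.csv``, four beta CSVs, a
    cumulative-dialect ``cases.csv`` and a ready ``config.yaml``.
    """
    from .scenario_engine import ScenarioConfig  # local import, avoids cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    schema, marginals = generate_marginals(spec)
    schema.write(outdir / "schema.json")
    synthpop.write_marginals(marginals, schema, outdir / "marginals.csv")
    paths: dict[str, Path] = {
        "schema": outdir / "schema.json",
        "marginals": outdir / "marginals.csv",
    }
    betas = generate_beta_matrices(spec)
    beta_paths = {}
    for (role, ld), bm in betas.items():
        p = outdir / f"betas_{role}_{ld}.csv"
        bm.write(p)
        beta_paths[f"{role}_{ld}"] = str(p)
        paths[f"{role}_{ld}"] = p
    cases = generate_case_curve(spec, days=days)
    covid.write_case_series(cases, outdir / "cases.csv")
    paths["cases"] = outdir / "cases.csv"
    config = ScenarioConfig(
        seed=spec.seed,
        schema_path=str(paths["schema"]),
        marginals_path=str(paths["marginals"]),
        beta_paths=beta_paths,
        cases_path=str(paths["cases"]),
        real_population_n=spec.real_population_n,
        start_date=str(cases.dates[0].date()),
        end_date=str(cases.dates[-1].date()),
    )
    config.to_yaml(outdir / "config.yaml")
    paths["config"] = outdir / "config.yaml"
    return paths


# ---------------------------------------------------------------------------
# parameter recovery


def simulate_agent_days(
    n_agent_days: int,
    betas: BetaMatrix,
    action: str,
    schema: FeatureSchema,
    catalog: ActionCatalog,
    rng: np.random.Generator,
    take_probability: float = 0.5,
) -> pd.DataFrame:
    """Simulate agent-days from one action's depression-effect model.

    Features are drawn uniformly per category; the action indicator is
    Bernoulli(``take_probability``); the symptom outcome is Bernoulli of
    ``sigmoid(intercept + action_beta * taken + features . betas)`` —
    exactly the logistic model the matrices were estimated with.
    """
    codes = {
        name: rng.integers(len(cats), size=n_agent_days)
        for name, cats in schema.features
    }
    X = np.column_stack(
        [
            (codes[name] == k).astype(float)
            for name, cats in schema.features
            for k in range(len(cats))
        ]
    )
    taken = (rng.random(n_agent_days) < take_probability).astype(float)
    row = betas.dense(schema, catalog)[catalog.actions.index(action)]
    logit = row[0] + row[1] * taken + X @ row[2:]
    y = (rng.random(n_agent_days) < sigmoid(logit)).astype(int)
    df = pd.DataFrame(X, columns=list(schema.onehot_columns))
    df.insert(0, "taken", taken)
    df["symptomatic"] = y
    return df


def recover_betas(
    table: pd.DataFrame,
    true_betas: BetaMatrix,
    action: str,
    schema: FeatureSchema,
    catalog: ActionCatalog,
    se_flag_threshold: float = 10.0,
) -> pd.DataFrame:
    """Refit the logistic model on simulated agent-days and compare to truth.

    The refit drops each feature's first category (reference coding), so
    recovered feature coefficients are contrasts against the reference;
    true contrasts are computed the same way.  Coefficients with a
    standard error above ``se_flag_threshold`` (quasi-separation) are
    flagged and excluded from the error summary.

    Returns a frame with columns term, true, fitted, se, abs_error,
    separation_flag.
    """
    keep_cols, ref = [], {}
    for name, cats in schema.features:
        ref[name] = cats[0]
        keep_cols += [f"{name}={c}" for c in cats[1:]]
    X = sm.add_constant(table[["taken"] + keep_cols].to_numpy(dtype=float))
    y = table["symptomatic"].to_numpy(dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    row = true_betas.dense(schema, catalog)[catalog.actions.index(action)]
    onehot = list(schema.onehot_columns)
    true_map = dict(zip(onehot, row[2:]))
    terms = ["intercept", "taken"] + keep_cols
    # under reference coding the intercept absorbs every reference-category beta
    ref_offset = sum(true_map[f"{name}={ref[name]}"] for name in ref)
    truths = [row[0] + ref_offset, row[1]]
    for col in keep_cols:
        name = col.split("=", 1)[0]
        truths.append(true_map[col] - true_map[f"{name}={ref[name]}"])
    out = pd.DataFrame(
        {
            "term": terms,
            "true": truths,
            "fitted": fit.params,
            "se": fit.bse,
        }
    )
    out["separation_flag"] = out["se"] > se_flag_threshold
    out["abs_error"] = np.where(
        out["separation_flag"], np.nan, np.abs(out["fitted"] - out["true"])
    )
    return out
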