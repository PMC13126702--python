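"""Scenario driver: day loop over a lockdown schedule, replicates, summaries.

A scenario is a dated window covered by contiguous partial/full lockdown
segments.  Each simulated day the engine (1) selects the active
lockdown's coefficient matrices, (2) assigns new infections scaled from
the real case series, (3) samples every agent's actions (forced
stay-home while infected), (4) converts taken actions into a daily
depressive-symptom probability, (5) re-evaluates symptomatic status, and
(6) advances recovery countdowns.  A scenario is run as R independent
replicates; the reported outcome is the cross-replicate mean share of
symptomatic agents per day with a normal-approximation 95% confidence
interval (mean +/- 1.96 * sd / sqrt(R)).

Reproducibility: replicate r draws from a generator seeded with
``SeedSequence(master_seed, spawn_key=(r + 1,))``; the synthetic
population itself uses ``spawn_key=(0,)``.  Within a day, draws are
consumed in a fixed order (infection selection, recovery durations,
action uniforms, baseline draws, status uniforms), with agents in id
order and actions in catalog order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import covid, mental_health, synthpop
from .behavior import sample_actions, sigmoid
from .covid import CaseSeries, InfectionStates, RecoveryDistribution
from .mental_health import BaselineEffect
from .parameters import ActionCatalog, BetaMatrix, LockdownType, read_beta_matrix
from .synthpop import FeatureSchema, MarginalTable

#: Dutch policy segments of the 11 Jun 2020 - 11 Jun 2021 study year.
ACTUAL_SEGMENTS: tuple[tuple[str, str, LockdownType], ...] = (
    ("2020-06-11", "2020-11-03", "partial"),
    ("2020-11-04", "2021-03-25", "full"),
    ("2021-03-26", "2021-06-11", "partial"),
)


@dataclass(frozen=True)
class LockdownSegment:
    start: pd.Timestamp
    end: pd.Timestamp  # inclusive
    kind: LockdownType

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if self.end < self.start:
            raise ValueError("segment end precedes start")
        if self.kind not in ("partial", "full"):
            raise ValueError(f"unknown lockdown type {self.kind!r}")

    @property
    def days(self) -> int:
        return (self.end - self.start).days + 1


@dataclass(frozen=True)
class LockdownSchedule:
    """Ordered, contiguous, non-overlapping segments covering the run window."""

    segments: tuple[LockdownSegment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start != a.end + pd.Timedelta(days=1):
                raise ValueError(
                    f"segments not contiguous at {a.end.date()} -> {b.start.date()}"
                )

    @property
    def start(self) -> pd.Timestamp:
        return self.segments[0].start

    @property
    def end(self) -> pd.Timestamp:
        return self.segments[-1].end

    @property
    def days(self) -> int:
        return (self.end - self.start).days + 1

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="D")

    def day_types(self) -> np.ndarray:
        """Lockdown type per day, length ``self.days``."""
        out = np.empty(self.days, dtype=object)
        for seg in self.segments:
            i = (seg.start - self.start).days
            out[i : i + seg.days] = seg.kind
        return out


def build_schedule(
    preset: Literal["actual", "partial_only", "full_only"],
    start: str | pd.Timestamp,
    end: str | pd.Timestamp,
) -> LockdownSchedule:
    """Build a schedule preset over an inclusive date window.

    ``actual`` reproduces the dated Dutch partial/full/partial sequence
    and requires the window to fall inside it; ``partial_only`` and
    ``full_only`` are single year-long-or-otherwise segments.
    """
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if end < start:
        raise ValueError("window end precedes start")
    if preset in ("partial_only", "full_only"):
        kind: LockdownType = "partial" if preset == "partial_only" else "full"
        return LockdownSchedule((LockdownSegment(start, end, kind),))
    if preset != "actual":
        raise ValueError(f"unknown preset {preset!r}")
    segs = [
        LockdownSegment(pd.Timestamp(s), pd.Timestamp(e), k)
        for s, e, k in ACTUAL_SEGMENTS
    ]
    if start < segs[0].start or end > segs[-1].end:
        raise ValueError(
            f"window {start.date()}..{end.date()} not covered by the actual "
            f"schedule {segs[0].start.date()}..{segs[-1].end.date()}"
        )
    clipped = [
        LockdownSegment(max(s.start, start), min(s.end, end), s.kind)
        for s in segs
        if s.end >= start and s.start <= end
    ]
    return LockdownSchedule(tuple(clipped))


@dataclass
class ScenarioInputs:
    """Everything a scenario run consumes, already loaded and validated."""

    schema: FeatureSchema
    weights: synthpop.WeightTable
    params: Mapping[tuple[str, LockdownType], BetaMatrix]
    cases: CaseSeries
    catalog: ActionCatalog = ActionCatalog()
    baseline_effect: BaselineEffect = BaselineEffect()
    recovery: RecoveryDistribution = RecoveryDistribution()


@dataclass
class ScenarioConfig:
    """Run configuration (mirrors the YAML config file)."""

    n_agents: int = 1000
    replicates: int = 30
    seed: int = 0
    start_date: str = "2020-06-11"
    end_date: str = "2021-06-11"
    preset: str = "actual"
    absorbing_status: bool = False
    reinfection: bool = False
    retain_history: bool = False
    # file paths (optional when inputs are passed as objects)
    schema_path: str | None = None
    marginals_path: str | None = None
    beta_paths: dict[str, str] = field(default_factory=dict)
    cases_path: str | None = None
    municipality: str | None = None
    real_population_n: int | None = None
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )


def load_inputs(config: ScenarioConfig) -> ScenarioInputs:
    """Read schema, marginals, beta matrices and case series from config paths."""
    if config.schema_path is None:
        raise ValueError("config has no schema_path")
    schema = FeatureSchema.read(config.schema_path)
    catalog = ActionCatalog()
    marginals = synthpop.read_marginals(config.marginals_path, schema)
    weights = synthpop.fit_ipf(synthpop.WeightTable.uniform(schema), marginals)
    params = {}
    for key, path in config.beta_paths.items():
        role, _, ld = key.rpartition("_")  # e.g. "action_choice_partial"
        params[(role, ld)] = read_beta_matrix(path, role, ld, schema, catalog)
    needed = {
        ("action_choice", t) for t in ("partial", "full")
    } | {("depression_effect", t) for t in ("partial", "full")}
    missing = needed - set(params)
    if missing:
        raise ValueError(f"config missing beta matrices for: {sorted(missing)}")
    if config.real_population_n is None:
        raise ValueError("config has no real_population_n")
    cases = covid.read_case_series(
        config.cases_path,
        real_population_n=config.real_population_n,
        start=config.start_date,
        end=config.end_date,
        municipality=config.municipality,
    )
    return ScenarioInputs(
        schema=schema, weights=weights, params=params, cases=cases,
        catalog=catalog,
    )


@dataclass
class SimulationResult:
    """Per-replicate daily trajectories plus the cross-replicate summary."""

    replicates: list[pd.DataFrame]
    summary: pd.DataFrame
    baseline_share: float

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def days(self) -> int:
        return len(self.summary)

    @property
    def final(self) -> dict[str, float]:
        """Prevalence summary (fractions): final-day share with CI, plus the
        mean share over the last lockdown segment and over the whole run,
        and the final-day mean agent probability."""
        last = self.summary.iloc[-1]
        last_kind = last["lockdown_type"]
        seg = self.summary["lockdown_type"].to_numpy()
        boundary = np.flatnonzero(seg != last_kind)
        seg_start = int(boundary[-1]) + 1 if boundary.size else 0
        return {
            "mean": float(last["mean"]),
            "ci_low": float(last["ci_low"]),
            "ci_high": float(last["ci_high"]),
            "mean_probability": float(last["mean_probability"]),
            "mean_last_segment": float(
                self.summary["mean"].iloc[seg_start:].mean()
            ),
            "mean_over_run": float(self.summary["mean"].mean()),
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for r, df in enumerate(self.replicates):
            df.to_csv(outdir / f"replicate_{r:03d}.csv", index=False)
        self.summary.to_csv(outdir / "summary.csv", index=False)


def run_replicate(
    agents: pd.DataFrame,
    schedule: LockdownSchedule,
    inputs: ScenarioInputs,
    rng: np.random.Generator,
    absorbing: bool = False,
    reinfection: bool = False,
    retain_history: bool = False,
) -> pd.DataFrame:
    """Simulate one replicate; returns a per-day frame.

    Columns: day (1-based), date, lockdown_type, symptomatic_share,
    mean_probability, new_infections, infected, recovered — plus, with
    ``retain_history``, a ``probabilities`` column holding per-agent
    daily probability arrays.
    """
    if len(inputs.cases) != schedule.days:
        raise ValueError(
            f"case series length {len(inputs.cases)} != schedule days "
            f"{schedule.days}"
        )
    schema, catalog = inputs.schema, inputs.catalog
    n = len(agents)
    X = agents[list(schema.onehot_columns)].to_numpy(dtype=float)
    symptomatic = agents["baseline_depressive"].to_numpy(dtype=bool).copy()
    states = InfectionStates(n)
    day_types = schedule.day_types()

    dense = {}
    for (role, ld), bm in inputs.params.items():
        d = bm.dense(schema, catalog)
        if role == "action_choice":
            dense[(role, ld)] = (d[:, 0], X @ d[:, 1:].T)  # intercepts, feature part
        else:
            dense[(role, ld)] = d[:, 0] + d[:, 1] + X @ d[:, 2:].T  # (n, A)

    rows = []
    for day in range(schedule.days):
        ld = day_types[day]
        if ("action_choice", ld) not in inputs.params:
            raise ValueError(f"no action_choice matrix for lockdown type {ld!r}")
        m_cases = int(inputs.cases.new_cases[day])
        target = covid.scale_cases(n, inputs.cases.real_population_n, m_cases)
        new_inf = covid.assign_infections(states, target, rng, inputs.recovery)

        b0, feat = dense[("action_choice", ld)]
        probs = sigmoid(feat + b0)
        actions = sample_actions(probs, states.infected, rng, catalog)

        row_val = dense[("depression_effect", ld)]
        total = (actions * row_val).sum(axis=1)
        total[actions.sum(axis=1) == 0] = np.nan
        p = mental_health.daily_probability(total, inputs.baseline_effect, rng)
        symptomatic = mental_health.update_status(symptomatic, p, rng, absorbing)

        covid.step_recovery(states, reinfection)
        _, n_inf, n_rec = states.counts()
        rec = {
            "day": day + 1,
            "date": schedule.dates[day],
            "lockdown_type": ld,
            "symptomatic_share": float(symptomatic.mean()),
            "mean_probability": float(p.mean()),
            "new_infections": new_inf,
            "infected": n_inf,
            "recovered": n_rec,
        }
        if retain_history:
            rec["probabilities"] = p.copy()
        rows.append(rec)
    return pd.DataFrame(rows)


def summarize_replicates(replicates: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Per-day cross-replicate mean and 95% CI of the symptomatic share."""
    shares = np.column_stack([df["symptomatic_share"].to_numpy() for df in replicates])
    probs = np.column_stack([df["mean_probability"].to_numpy() for df in replicates])
    r = shares.shape[1]
    mean = shares.mean(axis=1)
    sd = shares.std(axis=1, ddof=1) if r > 1 else np.zeros_like(mean)
    half = 1.96 * sd / np.sqrt(r)
    first = replicates[0]
    return pd.DataFrame(
        {
            "day": first["day"],
            "date": first["date"],
            "lockdown_type": first["lockdown_type"],
            "mean": mean,
            "ci_low": mean - half,
            "ci_high": mean + half,
            "mean_probability": probs.mean(axis=1),
            "n_replicates": r,
        }
    )


def run_scenario(
    config: ScenarioConfig,
    inputs: ScenarioInputs,
    agents: pd.DataFrame | None = None,
) -> SimulationResult:
    """Run R replicates of a scenario and summarize.

    The synthetic population is sampled once (seed stream 0) and shared
    across replicates; each replicate r uses an independent stream r+1.
    """
    schedule = build_schedule(config.preset, config.start_date, config.end_date)
    if agents is None:
        pop_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(0,))
        )
        agents = synthpop.sample_population(inputs.weights, config.n_agents, pop_rng)
    reps = []
    for r in range(config.replicates):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(r + 1,))
        )
        reps.append(
            run_replicate(
                agents,
                schedule,
                inputs,
                rng,
                absorbing=config.absorbing_status,
                reinfection=config.reinfection,
                retain_history=config.retain_history,
            )
        )
    result = SimulationResult(
        replicates=reps,
        summary=summarize_replicates(reps),
        baseline_share=float(agents["baseline_depressive"].mean()),
    )
    if config.output_dir:
        result.write(config.output_dir)
    return result


def compare_scenarios(
    results: Mapping[str, SimulationResult],
) -> pd.DataFrame:
    """Final-day comparison table with pairwise CI-overlap flags.

    One row per scenario: final mean, CI bounds, rank (1 = lowest final
    prevalence), and ``distinct_from`` listing scenarios whose final-day
    95% CIs do not overlap this one's.
    """
    if len(results) < 2:
        raise ValueError("need at least two scenarios to compare")
    reps = {name: res.n_replicates for name, res in results.items()}
    if len(set(reps.values())) != 1:
        raise ValueError(f"replicate counts differ: {reps}")
    days = {name: res.days for name, res in results.items()}
    if len(set(days.values())) != 1:
        raise ValueError(f"simulation horizons differ: {days}")
    rows = []
    names = list(results)
    for name in names:
        f = results[name].final
        rows.append({"scenario": name, **{k: f[k] for k in ("mean", "ci_low", "ci_high")}})
    df = pd.DataFrame(rows)
    df["rank"] = df["mean"].rank(method="min").astype(int)
    distinct = []
    for i, a in df.iterrows():
        others = [
            df.loc[j, "scenario"]
            for j, b in df.iterrows()
            if j != i
            and (a["ci_low"] > b["ci_high"] or a["ci_high"] < b["ci_low"])
        ]
        distinct.append(",".join(others))
    df["distinct_from"] = distinct
    return df.sort_values("mean").reset_index(drop=True)
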