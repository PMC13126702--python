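# Methods

`lockdownsim` is a discrete-time, agent-level microsimulation of how
lockdown policy regimes shape daily behaviors and, through them, the
population prevalence of sub-clinical depressive symptoms, with COVID-19
incidence acting as an exogenous constraint on behavior rather than a
transmission process. This note records the model, its assumptions, the
parameters that matter, and the design decisions taken where the design
was genuinely open.

## Model overview

Each agent carries a fixed vector of one-hot categorical baseline
features (gender, age group, education, income, having children, living
alone, critical-sector employment, preexisting depression diagnosis,
physical health, housing/financial difficulties) and two dynamic states:
an infection state (susceptible / infected / recovered) and a
depressive-symptom state. Time advances in daily steps over a dated run
window covered by contiguous lockdown segments, each typed `partial` or
`full`. Each day, per agent:

1. **Infection.** The day's real-world incidence M in a reference
   population of size N is scaled to the simulated population of size n
   as `cases = round(n/N · M)`, and that many susceptible agents are
   infected uniformly at random — infection is independent of features
   and actions. Each infection is assigned, at onset, a long-COVID flag
   (probability 0.20) and a whole-day recovery duration:
   `max(10, round(Gamma(shape 5, scale 3)))` for standard recovery, or
   `max(35, round(Gamma(shape 9, scale 70/8)))` for long COVID. The
   long-COVID gamma's unclamped mode is (shape−1)·scale = 70 days. (The
   standard gamma's mode is 12 days, sometimes loosely described as
   peaking near 10; the distribution parameters are taken as
   authoritative.) Recovered agents are immune for the rest of the run
   unless the reinfection flag is set.
2. **Action choice.** For each of nine daily actions (stay home, work
   from home, exercise, be sedentary, feel socially connected, feel
   isolated, cope positively, seek help from one's network, drink to
   excess), the active lockdown's action-choice coefficient matrix row
   is dotted with the agent's one-hot features (plus intercept) to give
   a log-odds; the sigmoid `p = 1/(1+e^(−x))` maps it to a probability,
   and an independent Bernoulli draw per action decides whether the
   agent takes it. Actions do not compete with one another. Infected
   agents get no choice: stay-home is forced to 1 and all other actions
   to 0.
3. **Depressive-symptom probability.** Each *taken* action's
   depression-effect row contributes its intercept, the action's own
   coefficient, and feature-interaction terms dotted with the agent's
   one-hot vector; untaken actions contribute nothing. The summed
   log-odds passes through the sigmoid. If the agent took no action, or
   the contributions cancel exactly (|sum| < 1e−12), there is no
   behavioral signal and the probability is instead drawn from
   N(0.002, 0.0005) truncated to [0, 1] — a small positive drift.
4. **Status update.** Symptomatic status is a Bernoulli draw on the
   day's probability, re-evaluated daily (non-absorbing). Agents flagged
   depressive at baseline (two or more endorsed symptoms on the 8-item
   MINI screener) start symptomatic on day 0.

A scenario runs R independent replicates; the reported outcome is the
cross-replicate mean symptomatic share per day with a 95% normal
approximation confidence interval, mean ± 1.96·sd/√R.

## Population synthesis

The target population is described by cross-tabulated categorical
marginal tables. A full cross-classification weight table (all-ones seed
by default — the maximum-entropy start; a user seed table is accepted)
is raked axis-by-axis with multidimensional iterative proportional
fitting until every supplied marginal is reproduced. Convergence is the
maximum absolute relative deviation of any fitted marginal below `tol`
(default 1e−6, at most 1,000 sweeps); inconsistent marginal totals are a
validation error, and a structural zero conflicting with a positive
marginal surfaces as a non-convergence report. Agents are sampled with
replacement with cell probability proportional to fitted weight —
zero-weight cells are legal and never sampled. "Unknown" categories are
ordinary levels throughout: high, plausibly not-at-random missingness is
synthesized as such, not imputed away. Fidelity is checked with a
Pearson chi-square test per marginal; categories with expected count
zero are excluded (with a warning if agents were observed there).

Note that a pass-all-marginals criterion at significance α is only
meaningful for a handful of simultaneous marginals: under the null the
pass-all probability is (1−α)^k, ≈0.90 for eleven marginals at α=0.01,
so calibration checks are run on two- and three-feature problems.

## Status model: why non-absorbing

How a daily symptom likelihood becomes a reported prevalence is a
genuine modeling choice. The default treats status as a daily Bernoulli
re-evaluation, so the population symptomatic share tracks the mean daily
sigmoid output — the only reading under which a ~0.1 daily probability
yields a ~10% prevalence after a simulated year rather than compounding
toward saturation. An absorbing variant (once symptomatic, always
symptomatic) is available behind `absorbing_status` for sensitivity
analysis. A consequence of the memoryless default: two scenarios that
share a seed and end on the same lockdown type report identical
final-day shares (e.g. a partial/full/partial schedule versus
partial-only). The result object therefore also exports the mean share
over the last lockdown segment and over the whole run, which do
distinguish such schedules.

## Coefficient matrices

Matrices are plain CSV, rows = actions, columns = intercept (+ the
action's own coefficient for the depression-effect role) + one
column per one-hot feature category. Reference categories carry explicit
zero columns rather than being dropped, because rows are dotted against
full one-hot vectors; a constant shift between a feature's categories is
therefore unidentified in any refit, which reports reference-coded
contrasts instead. Action-choice intercepts are conventionally zero — an
agent whose features contribute nothing takes each action with
probability 0.5. Files must contain the intercept column explicitly;
text round-trips preserve full float precision (shortest round-trip
repr).

The six published lockdown-specific action effects are built in as
anchors: exercise −0.52/−0.40, feeling socially connected −0.51/−0.30,
positive coping −0.18/−0.06, feeling isolated +0.68/+1.18, sedentary
+0.19/+0.29, excess drinking +0.15/+0.38 (partial/full).

## Synthetic inputs: what they emulate and what they do not

Real runs require three external artifacts that cannot ship with the
package: cohort cross-tabulations, the four estimated coefficient
matrices, and a municipal cumulative-cases series. The fixture generator
produces seeded stand-ins:

- **Marginals**: one-way tables over the ten baseline features (grand
  total 52,378, the scale of the underlying cohort sample) with
  Dirichlet-drawn proportions, a deliberately smaller "unknown" share,
  and a tagged baseline depressive indicator pinned at 3.49%.
- **Coefficients**: unspecified action-choice cells ~ U(−0.5, 0.5),
  depression feature interactions ~ N(0, 0.15), and per-row
  depression intercepts of −0.5 — with ~4.5 of 9 actions taken per day
  this puts the daily log-odds near −2.2, i.e. a mean daily probability
  near 0.1, matching the intended magnitude of outcomes. Unspecified
  cells are drawn **once and shared across lockdown types**, so the only
  partial/full contrast in the fixture is the six published action
  effects. This isolates the lockdown effect in the known quantities and
  makes the full ≥ partial prevalence ordering a structural consequence
  of the published coefficients (their full-minus-partial sum is +1.28)
  rather than an artifact of unknowable random cells; it also means the
  fixture *understates* between-lockdown behavioral differences relative
  to real estimated matrices.
- **Case curve**: two raised-cosine waves (autumn wave larger) peaking
  at 600 daily cases in a reference population of 585,000 — Dutch
  province magnitude — with 10% multiplicative noise, so a
  1,000-agent run sees single-digit daily infections. A cumulative
  dialect writer mirrors the public-dashboard format the loader parses
  (day-over-day differenced, negative reporting corrections clamped
  to 0).

Passing tests on these fixtures demonstrate the machinery and the
directional lockdown contrast; they do not validate the published
headline prevalences (10.92% actual / 11.44% full / 10.63% partial),
which require the actual estimated coefficient tables and the real
municipal series as inputs. With those supplied via the run config, the
same engine reproduces that comparison at the published scale (1,000
agents, 30 replicates, the 11 June 2020 – 11 June 2021 window — 366
days inclusive).

The parameter-recovery harness simulates agent-days from one action's
generative logistic model (features uniform per category, action taken
with probability 0.5) and refits it with maximum likelihood; at 50,000
agent-days the action coefficient is recovered within ±0.1, and
coefficients with standard errors above 10 are flagged as
quasi-separated and excluded from error summaries.

## Reproducibility and numerics

All randomness flows from a master seed through named `SeedSequence`
spawn keys: stream 0 samples the population, stream r+1 drives
replicate r. Within a day, draws are consumed in a fixed order
(infection selection, long-COVID flags, recovery durations, action
uniforms in agent-id × catalog order, baseline draws, status uniforms),
and uniforms are consumed for every agent/action regardless of infection
status so the stream does not depend on who is infected. Runs are
bit-identical under a fixed seed. Sigmoid inputs are clipped to ±500 and
evaluated in the numerically stable branch form; probabilities are exact
to double precision over the clipped range. Scaled case counts use
half-up rounding; gamma recovery draws are rounded to whole days before
the minimum clamp.

Default problem sizes used by the test suite and acceptance script —
up to 1,000 agents (10,000 for the scale-robustness check), 30
replicates, 366-day windows, 100,000-draw distributional checks, 50,000
agent-day refits — were chosen as the smallest sizes at which the
binomial/CLT error bounds quoted in the tests are decisive.

## Known limitations

- No behavioral inertia: actions are conditionally independent across
  days given features and lockdown type.
- No transmission model, mortality, or vaccination; incidence is
  exogenous and reinfection is off by default.
- Long COVID affects outcomes only through a longer forced stay-home
  spell; there is no direct infection→depression effect.
- Coefficient estimation from cohort microdata is out of scope; the
  package consumes coefficient matrices and offers only the synthetic
  recovery harness.
- The memoryless status model makes final-day prevalence insensitive to
  schedule history (see above); use the exported segment/run means or
  the absorbing variant when history matters.
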