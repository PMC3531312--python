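# Methods

This note records the models, conventions and numerical choices behind
`vaxdss`, and what the synthetic-data generator does and does not emulate.

## Data model conventions

- **Day coordinates.**  Immunization schedules use integer days with day 0
  at the first inoculation; protocols are canonically shifted so the
  earliest inoculation sits at day 0 and stable-sorted by day (two
  inoculations on one day are allowed and keep input order).  Challenge
  observation days are 0-based at challenge administration and strictly
  increasing.
- **Inheritance.**  Resolved individual attributes are experiment defaults
  overwritten by group overrides overwritten by individual-level values;
  the resolution is a pure function, so shuffling input order cannot change
  it.
- **Revision stamps.**  A plain integer counter rather than a timestamp, so
  behaviour is deterministic and testable.  Every mutating call (adding a
  group, any manual edit — including rewriting an identical value, the
  simplest consistent rule) increments it, resets quality statuses to NC
  and clears readiness flags.  Template *import* is the automatic entry
  path and does not count as a manual edit: it leaves the stamp unchanged
  and instead triggers quality control.
- **Group types.**  Five types are modelled; `OTHER` completes the arity
  and is excluded from all normalization and evaluation arithmetic.
  Normalization always uses the naive/control group (empty vector); the
  negative-control type (no immunization) is stored and reported but never
  substitutes as the normalization baseline.

## Quality control

Statuses are a pure function of the severity multiset: fatal → R, else
serious → P, else A; U is reachable only by explicit user decision from P
(recorded with a free-text audit note).  MINOR and WARNING are both
non-blocking and kept only for reporting.  Group and experiment statuses
are derived independently at their own levels; the experiment-level report
aggregates all messages.

The default registry covers: required laboratory and date (fatal), presence
of a naive control group (serious), minimum group size (serious; default 3,
configurable), percent-range checks on all four T-cell fields (fatal), and
acceptable ranges for naive-group responses (minor; default 0–10%, a
placeholder standing in for expert-defined reference bounds, configurable
per deployment).  Predicates are a fixed parameterized vocabulary — no
user-scripted rules.

Readiness flags are recomputed from group statuses: E-ready needs a
validated (A/U) naive group plus a validated internal-standard or vaccine
group; EC-ready needs all three of naive, internal standard and vaccine
validated, so EC-ready implies E-ready by construction.

## T-cell analysis

Per-day group summaries use the arithmetic mean and sample standard
deviation over reporting individuals only (no imputation; a single reporter
yields sd 0 with n = 1 as the flag).  Normalization against the naive group
defaults to mean subtraction floored at 0: ratios of raw percentages are
unstable near 0, and the floor encodes "no response below baseline" on a
percent scale.  A ratio mode (group/naive) is available by flag.  When a
group lacks data at the requested day the nearest *earlier* measured day is
used — never interpolation — a conservative, reproducible choice.

Internal-standard ratios divide naive-normalized values; a parameter on
which the standard normalizes to 0 has no meaningful ratio and is reported
missing rather than infinite.  Cross-experiment comparison requires the
compared group's experiment to carry an internal-standard group immunized
under the same protocol as the reference standard.  The radar-polygon area
over K equally spaced axes, ½·sin(2π/K)·Σ vᵢ·vᵢ₊₁ (indices mod K), is the
scalar profile summary; missing axes are dropped, reducing K (minimum 3).

## B-cell analysis

The titration model is the four-parameter logistic in dilution-factor
space, y(d) = bottom + (top − bottom)/(1 + 10^(s·log10(EC50/d))); labels
like 1/20 map to d = 20.  The slope sign is unconstrained; the synthetic
truth uses positive s, under which neutralization rises with d.

Fitting is nonlinear least squares (scipy `least_squares`, trf) in
(top, bottom, s, log10 EC50), from three starts: a logit-linearization
initializer, its mirrored-slope twin, and a flat start (top = bottom = mean)
that resolves near-constant series.  Default bounds: bottom ∈ [−10, 50],
top ∈ [50, 110], s ∈ [−20, 20], EC50 within the observed dilution range
widened one decade each way.  Tolerances 1e-13 with 800 evaluations per
start recover noiseless 8-point series to ~1e-15 relative.  Among
near-equal-cost solutions the smaller asymptote span wins: when EC50 drifts
outside the observed window the span is unidentifiable, and this tie-break
resolves the degeneracy toward the parsimonious curve.  Non-convergence
returns best-effort parameters flagged `converged=False`, never an
exception.

Assay-specificity checks on antigen-irrelevant control (CTR-pp) series use
wide asymptote bounds (both in [−10, 110]) — the default bounds would force
a flat series' asymptotes at least apart to 50 − bottom — and confine EC50
to the tested dilutions, since a half-maximum outside the tested range is
not evidence of neutralization and lets the span extrapolate without limit.

Group and experiment fits pool all data points of all individuals in scope
into one fit, so individuals with more points weigh proportionally more
("points equally" rather than "individuals equally").  The titer is the
closed-form inversion of the fitted curve at a threshold strictly inside
(bottom, top); the default midpoint threshold makes titer ≡ EC50, with a
fixed-percentage alternative available.  Fits are cached keyed by series
identity and experiment stamp, so unchanged data is never refitted and any
revision invalidates the cache.

## Molecular signature

Per-gene group means (arithmetic by default; log-scale geometric mean by
flag) give the vaccinated/control ratio.  The threshold filter is two-sided
by default — a gene is excluded when max(r, 1/r) < threshold — because up-
and down-regulation are equally informative; a one-sided mode exists.
Genes with a zero control mean go to an "undefined ratio" bucket, never
silently dropped or treated as infinite.  Mixing array platforms within one
comparison is rejected; platform-level preprocessing (chip normalization,
probe mapping) is out of scope — profiles are generic gene → value maps.
Signatures order retained genes by |log₂ ratio| descending with gene-id
tie-break, making extraction deterministic.

## Challenge

Survival is endpoint status at fixed observation days: proportion alive =
alive count / group size per day, with dead-then-alive sequences rejected
at the record level.  There is deliberately no censoring or time-to-event
machinery (Kaplan–Meier would add assumptions the fixed-day design does not
support).  Viremia is stored and exported but not analyzed.

## Evaluation

Per-module scores for a candidate group against the internal standard:
T-cell — mean over parameters of min(1, IS ratio); B-cell — min(1,
titer/titer_IS); molecular signature — Jaccard similarity of the two
signatures (both vs naive; two empty signatures count as identical, 1.0);
challenge — the group's final survival proportion.  Clipping at 1 encodes
"as good as the standard or better".  Each scorer sits behind a strategy
table (`evaluation.SCORERS`) so alternatives can be registered.  The global
score is the weighted mean over modules with available scores — absent
modules are excluded and weights renormalized, since absence of evidence is
not failure — making it monotone in every score, invariant to weight
rescaling, and independent of zero-weighted modules.  Grades use
configurable descending bins, default A ≥ 0.8, B ≥ 0.65, C ≥ 0.5, D ≥ 0.35,
E ≥ 0.2, else F.

## Synthetic studies

`synthgen` emulates the structure of a multi-group vaccine-platform study:
a naive group (empty vector), an internal-standard group (reference
vector), and two candidates — one generated as strong as the standard, one
weaker.  Defaults: 5 individuals per group; T-cell measurement days
0/7/14/28 with baseline 2% plus per-group offsets after day 0 and additive
Gaussian noise sd 2 truncated to [0, 100]; sera S0 (day 0, pre-immune) and
S1 (day 14) titrated on an 8-point three-fold dilution grid from 1/20 with
Gaussian noise sd 2 (antigen series from per-group 4PL truths, control
series flat at 2%); 1,000 genes with 50 planted regulated genes at fold 4
under multiplicative log-normal noise (σ = 0.10); challenge observation at
days 0/3/7/10/14 with per-group cumulative survival curves (naive ending at
0.2, standard and strong candidate at 1.0, weak candidate at 0.8).

Each measurement family draws from its own child stream of the master seed,
so reconfiguring one family never perturbs another's draws.  Challenge
outcomes compare one uniform threshold per individual against the
cumulative survival curve, making death monotone by construction; the
noiseless mode places thresholds at the (i+0.5)/n quantiles, and default
survival levels are multiples of 1/n so the noiseless limit reproduces the
configured curve exactly.

What the generator does *not* emulate: assay-specific measurement error
structure (heteroscedasticity, plate effects), inter-individual biological
variation beyond iid noise, correlated gene modules, batch or laboratory
effects, and any mechanistic immune dynamics — the truth is
phenomenological.  Passing tests therefore demonstrate that the analysis
pipeline recovers known inputs under idealized noise, not that it is robust
to the full error structure of real assay data.

## Problem sizes

The test suite and acceptance script run replicated simulations at sizes
chosen to make the statistical assertions stable while keeping a full run
in tens of seconds: 10,000 draws for formula fidelity, 200 seeds for noisy
EC50 recovery, 100 seeds for signature recall, 1,000 random experiments for
flag logic, 500 random configurations for the evaluation algebra, and 125
replicated cohorts for group-mean calibration.

## Known limitations

- The exact normalization, titer and scoring arithmetic of the original
  decision-support system is unpublished; the defaults here are declared,
  configurable choices (subtraction-vs-ratio normalization, midpoint-vs-
  fixed titer threshold, the per-module scoring strategies and grade bins).
- Expression comparison is ratio filtering only — no hypothesis testing,
  no multiple-testing control.
- Single-user store; no roles, sharing or concurrent writes.
- Reports are plain text + JSON; no PDF rendering.
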