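# vaxdss

Decision support for genetic-vaccine development: a single-user Python
library and CLI for storing standardized immunization experiments, checking
their quality with a declarative rule engine, analyzing T-cell, B-cell
(neutralization), gene-expression and pathogen-challenge readouts against
naive and internal-standard reference groups, and condensing everything into
a weighted multicriteria score and an A–F grade per vaccine candidate.

It is aimed at immunologists and analysts who run vaccine-candidate
experiments in animal models and want their results stored in a uniform
shape, quality-controlled before analysis, and comparable across
experiments and laboratories through shared internal-standard groups.

## The data model in one paragraph

An **experiment** is the unit of assessment.  It carries default individual
attributes (animal model, sex, age) inherited by its **experimental
groups** — each a set of uniform **individuals** immunized following one
protocol — unless overridden.  Groups are typed: *experimental vaccine*,
*naive/control* (empty vector, no antigen), *negative control* (no
immunization), *internal standard* (a benchmark vector shared across
laboratories), or *other*.  Every mutating edit bumps an integer revision
**stamp** and resets the quality status to *not checked*; data entry goes
through generated spreadsheet templates stamped at generation time, so a
template older than the experiment is rejected on import.

## The core quantitative pieces

**Quality control.**  Numbered rules (scoped per module and level of
application) emit messages with severities *warning / minor / serious /
fatal*.  The status derives from the worst severity: fatal → **R**ejected,
serious → **P**ending (user may force **U**ser-validated or Rejected),
otherwise **A**uto-validated.  An experiment is *E-ready* when a naive and
an internal-standard-or-vaccine group are validated, and *EC-ready*
(cross-comparable) when a naive, an internal-standard and a vaccine group
all are.

**T-cell.**  Four percent-scale parameters (antigen-specific expansion,
memory phenotype, CTL activation, cytotoxicity) are summarized per group
and day, normalized against the naive group (mean subtraction, floored at
0), and expressed as ratios against the internal standard; a radar-polygon
area (½·Σᵢ vᵢ·vᵢ₊₁·sin(2π/K)) condenses the profile into one number.

**B-cell.**  Serum titration series are fitted with the four-parameter
logistic

```
y(d) = bottom + (top − bottom) / (1 + 10^(HillSlope · log10(EC50 / d)))
```

where *d* is the dilution factor and EC50 the dilution giving neutralization
halfway between the asymptotes.  The antibody titer is read off the fitted
curve (midpoint threshold by default, i.e. titer ≡ EC50).  Fits are cached
per experiment stamp; *virtual sera* align series sampled on different days
in different experiments.

**Molecular signature.**  Per-gene group means give vaccinated/control
ratios; genes with fold change below a threshold (two-sided by default) are
filtered out and the rest, ordered by |log₂ ratio|, form the signature.

**Challenge.**  Survival proportions per observation day and a per-group
table linking antibody titers to final survival.

**Evaluation.**  Module scores in [0, 1] (internal-standard ratios clipped
at 1; survival proportion for challenge) are combined as a weighted mean
with user-adjustable weights and mapped onto grades A (≥ 0.8) … F.

## Worked example

Generate a synthetic study (one naive, one internal-standard and two
candidate groups with known ground truth), run QC, and grade the candidates:

```
$ vaxdss synth --store demo.json --seed 42
synthetic experiment E-SYN1 written to demo.json

$ vaxdss qc --store demo.json --experiment E-SYN1
...
derived status: A
flags: ['EC_READY', 'E_READY']

$ vaxdss evaluate --store demo.json --experiment E-SYN1 --protocol CH-1
Evaluation scorecard
--------------------
       group         tcell         bcell        molsig     challenge        global         grade
      G-VAC1         1.000         1.000         1.000         1.000         1.000             A
      G-VAC2         0.548         0.442         1.000         0.800         0.698             B
```

G-VAC1 was generated as strong as the internal standard on every axis, so
each module score clips at 1.0 and it grades A.  G-VAC2 was generated
weaker (smaller T-cell offsets, EC50 120 vs the standard's 300, 80%
survival), which the scores reflect.  The underlying 4PL fit for G-VAC1:

```
$ vaxdss bcell --store demo.json --experiment E-SYN1 --serum S1 --group G-VAC1
{
 "params": { "top": 99.71, "bottom": 0.47, "hill_slope": 1.196, "ec50": 567.3, ... },
 "titer": 567.2928360770046
}
```

The generating truth for this group was EC50 = 600 with noise sd 2
percentage points on 40 pooled points, so the pooled-fit titer of 567 is a
~5% error.  The same analyses are available as library calls
(`vaxdss.bcell.fit_group`, `vaxdss.tcell.normalize_vs_naive`,
`vaxdss.evaluation.evaluate_experiment`, …).

## Layout

- `src/vaxdss/core.py` — domain entities, store, revision stamps
- `src/vaxdss/qc.py` — rule registry, status derivation, readiness flags
- `src/vaxdss/tcell.py`, `bcell.py`, `molsig.py`, `challenge.py` — analyses
- `src/vaxdss/evaluation.py` — multicriteria scoring and grading
- `src/vaxdss/io_store.py` — templates, imports, persistence, reports
- `src/vaxdss/synthgen.py` — seeded synthetic studies with ground truth
- `src/vaxdss/cli.py` — the `vaxdss` command
- `docs/methods.md` — models, parameters and design notes
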