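"""Multicriteria evaluation of vaccine candidates.

Each analysis module contributes a score in [0, 1] for a candidate group,
benchmarked against the experiment's internal-standard group where a
benchmark is meaningful:

* T-cell: mean over the four response parameters of the internal-standard
  ratio, clipped at 1 ("as good as the standard or better").
* B-cell: candidate titer / internal-standard titer, clipped at 1.
* Molecular signature: Jaccard similarity of the candidate's gene signature
  to the internal standard's (both vs the naive group).
* Challenge: final survival proportion of the candidate group.

The global score is the weighted mean over the modules with available
scores (user-adjustable weights; modules without data are excluded and the
weights renormalized), and is mapped onto a letter grade from A (highest)
to F (lowest) through configurable descending bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

from .core import Experiment, ExperimentalGroup, EC_READY, GroupType, Particle, VaxError
from . import bcell, challenge as challenge_mod, molsig, tcell

MODULES = ("TCELL", "BCELL", "MOLSIG", "CHALLENGE")

GRADES = ("A", "B", "C", "D", "E", "F")

DEFAULT_GRADE_BINS = (0.8, 0.65, 0.5, 0.35, 0.2)


@dataclass
class EvaluationConfig:
    """User-adjustable module weights and grade bins."""

    weights: dict[str, float] = field(
        default_factory=lambda: {m: 1.0 for m in MODULES}
    )
    grade_bins: tuple[float, ...] = DEFAULT_GRADE_BINS

    def __post_init__(self):
        unknown = set(self.weights) - set(MODULES)
        if unknown:
            raise VaxError(f"unknown modules in weights: {sorted(unknown)}")
        if any(w < 0 for w in self.weights.values()):
            raise VaxError("weights must be non-negative")
        if not any(w > 0 for w in self.weights.values()):
            raise VaxError("at least one weight must be positive")
        bins = tuple(self.grade_bins)
        if len(bins) != 5 or any(b >= a for a, b in zip(bins, bins[1:])) or not all(
            0 < b < 1 for b in bins
        ):
            raise VaxError("grade bins must be 5 strictly decreasing thresholds in (0,1)")
        self.grade_bins = bins


@dataclass
class EvaluationResult:
    group_id: str
    module_scores: dict[str, float]
    global_score: float
    grade: str

    def to_dict(self) -> dict:
        return {
            "group_id": self.group_id,
            "module_scores": dict(self.module_scores),
            "global_score": self.global_score,
            "grade": self.grade,
        }


def grade_from_score(score: float, bins: tuple[float, ...] = DEFAULT_GRADE_BINS) -> str:
    """Letter grade from the global score: a non-increasing step function."""
    for letter, threshold in zip(GRADES, bins):
        if score >= threshold:
            return letter
    return GRADES[-1]


def aggregate(scores: Mapping[str, float], config: EvaluationConfig) -> EvaluationResult:
    """Weighted mean of available module scores; absent modules are excluded
    with weight renormalization (absence of evidence is not failure)."""
    usable = {
        m: s for m, s in scores.items() if s is not None and config.weights.get(m, 0.0) > 0
    }
    total_w = sum(config.weights[m] for m in usable)
    if total_w <= 0:
        raise VaxError("no module with positive weight has an available score")
    global_score = sum(config.weights[m] * min(1.0, max(0.0, s)) for m, s in usable.items()) / total_w
    return EvaluationResult(
        group_id="",
        module_scores={m: min(1.0, max(0.0, s)) for m, s in usable.items()},
        global_score=global_score,
        grade=grade_from_score(global_score, config.grade_bins),
    )


@dataclass
class EvaluationContext:
    """Inputs the per-module scorers need beyond the experiment itself."""

    at_day: int | None = None  # T-cell comparison day (default: latest measured)
    serum_label: str | None = None  # B-cell serum (default: latest declared)
    organ: str = "spleen"
    cell_type: str = "dendritic"
    molsig_threshold: float = 2.0
    challenge_protocol: object | None = None
    fit_cache: bcell.FitCache | None = None


def _latest_tcell_day(experiment: Experiment) -> int | None:
    days = [m.day for g in experiment.groups for i in g.individuals for m in i.tcell]
    return max(days) if days else None


def _score_tcell(experiment, group, is_group, ctx) -> float | None:
    day = ctx.at_day if ctx.at_day is not None else _latest_tcell_day(experiment)
    if day is None:
        return None
    try:
        ratios = tcell.ratio_vs_internal_standard(
            [(experiment, group)], (experiment, is_group), day
        )[0].ratios
    except VaxError:
        return None
    defined = [r for r in ratios.values() if r is not None]
    if not defined:
        return None
    return sum(min(1.0, r) for r in defined) / len(defined)


def _score_bcell(experiment, group, is_group, ctx) -> float | None:
    label = ctx.serum_label
    if label is None and experiment.sera:
        label = max(experiment.sera, key=experiment.sera.get)
    if label is None:
        return None
    try:
        t_group = bcell.titer_from_fit(
            bcell.fit_group(experiment, label, Particle.AG_PP, group.id, cache=ctx.fit_cache)
        )
        t_is = bcell.titer_from_fit(
            bcell.fit_group(experiment, label, Particle.AG_PP, is_group.id, cache=ctx.fit_cache)
        )
    except VaxError:
        return None
    if t_is <= 0:
        return None
    return min(1.0, t_group / t_is)


def _score_molsig(experiment, group, is_group, ctx) -> float | None:
    controls = experiment.groups_of_type(GroupType.NAIVE_CONTROL)
    if not controls:
        return None
    try:
        sig_group = {
            g
            for g, _ in molsig.extract_signature(
                molsig.compare_expression(
                    group, controls[0], ctx.organ, ctx.cell_type, ctx.molsig_threshold
                )
            )
        }
        sig_is = {
            g
            for g, _ in molsig.extract_signature(
                molsig.compare_expression(
                    is_group, controls[0], ctx.organ, ctx.cell_type, ctx.molsig_threshold
                )
            )
        }
    except VaxError:
        return None
    union = sig_group | sig_is
    if not union:  # two empty signatures are identical
        return 1.0
    return len(sig_group & sig_is) / len(union)


def _score_challenge(experiment, group, is_group, ctx) -> float | None:
    if ctx.challenge_protocol is None:
        return None
    try:
        return challenge_mod.survival_curve(group, ctx.challenge_protocol).final_survival
    except VaxError:
        return None


Scorer = Callable[[Experiment, ExperimentalGroup, ExperimentalGroup, EvaluationContext], "float | None"]

#: Per-module scoring strategies; alternatives can be registered by name.
SCORERS: dict[str, Scorer] = {
    "TCELL": _score_tcell,
    "BCELL": _score_bcell,
    "MOLSIG": _score_molsig,
    "CHALLENGE": _score_challenge,
}


def score_module(
    experiment: Experiment,
    module: str,
    is_group: ExperimentalGroup,
    group: ExperimentalGroup,
    context: EvaluationContext | None = None,
) -> float | None:
    """Score one module for ``group`` against the internal standard.

    Returns ``None`` when the module's data is absent, in which case the
    module is excluded from the global score.  Internal-standard-based
    scoring requires the experiment to carry the EC-ready flag.
    """
    if module not in SCORERS:
        raise VaxError(f"unknown module {module!r}")
    if EC_READY not in experiment.flags:
        raise VaxError(
            f"experiment {experiment.id!r} is not EC-ready; run quality control first"
        )
    ctx = context or EvaluationContext()
    score = SCORERS[module](experiment, group, is_group, ctx)
    if score is None:
        return None
    return min(1.0, max(0.0, score))


def evaluate_experiment(
    experiment: Experiment,
    config: EvaluationConfig | None = None,
    group_id: str | None = None,
    is_group_id: str | None = None,
    context: EvaluationContext | None = None,
) -> EvaluationResult:
    """Full multicriteria evaluation of one candidate group.

    Defaults: first experimental-vaccine group as candidate and first
    internal-standard group as benchmark.
    """
    config = config or EvaluationConfig()
    if group_id is None:
        vaccines = experiment.groups_of_type(GroupType.EXPERIMENTAL_VACCINE)
        if not vaccines:
            raise VaxError(f"experiment {experiment.id!r} has no vaccine group to evaluate")
        group = vaccines[0]
    else:
        group = experiment.get_group(group_id)
    if is_group_id is None:
        standards = experiment.groups_of_type(GroupType.INTERNAL_STANDARD)
        if not standards:
            raise VaxError(f"experiment {experiment.id!r} has no internal-standard group")
        is_group = standards[0]
    else:
        is_group = experiment.get_group(is_group_id)

    scores = {
        m: score_module(experiment, m, is_group, group, context) for m in MODULES
    }
    result = aggregate({m: s for m, s in scores.items() if s is not None}, config)
    result.group_id = group.id
    return result


def render_scorecard(results: list[EvaluationResult]) -> str:
    """Plain-text scorecard: per-module scores, global score and grade."""
    lines = ["Evaluation scorecard", "--------------------"]
    header = ["group"] + [m.lower() for m in MODULES] + ["global", "grade"]
    lines.append("  ".join(f"{h:>12s}" for h in header))
    for r in results:
        cells = [f"{r.group_id:>12s}"]
        for m in MODULES:
            s = r.module_scores.get(m)
            cells.append(f"{s:12.3f}" if s is not None else f"{'-':>12s}")
        cells.append(f"{r.global_score:12.3f}")
        cells.append(f"{r.grade:>12s}")
        lines.append("  ".join(cells))
    return "\n".join(lines)
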