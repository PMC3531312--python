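"""Rule-based quality control of experiments and groups.

Every rule has a unique number, a module scope (T-cell, B-cell, molecular
signature, challenge or general), a level of application (experiment, group,
individual or single value) and a severity.  Running QC evaluates each
applicable rule once per matching entity and collects categorized messages;
statuses derive from the worst severity present:

    fatal error   -> R (rejected; data must be corrected)
    serious error -> P (pending; user may force U or R)
    otherwise     -> A (auto-validated)

Experiments additionally gain readiness flags: E-ready when at least one
naive and one internal-standard-or-vaccine group are validated (status A or
U), EC-ready when a naive, an internal-standard and a vaccine group all are.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Mapping

from .core import (
    EC_READY,
    E_READY,
    TCELL_PARAMETERS,
    VALIDATED_STATUSES,
    Experiment,
    ExperimentalGroup,
    GroupType,
    QualityStatus,
    VaxError,
)


class Severity(str, Enum):
    WARNING = "WARNING"
    MINOR = "MINOR"
    SERIOUS = "SERIOUS"
    FATAL = "FATAL"


class ModuleScope(str, Enum):
    TCELL = "TCELL"
    BCELL = "BCELL"
    MOLSIG = "MOLSIG"
    CHALLENGE = "CHALLENGE"
    GENERAL = "GENERAL"


class RuleLevel(str, Enum):
    EXPERIMENT = "EXPERIMENT"
    GROUP = "GROUP"
    INDIVIDUAL = "INDIVIDUAL"
    VALUE = "VALUE"


@dataclass(frozen=True)
class QualityRule:
    """One declarative check; ``predicate`` names a registered check."""

    rule_id: int
    module_scope: ModuleScope
    level: RuleLevel
    severity: Severity
    predicate: str
    params: Mapping = field(default_factory=dict)
    message_template: str = "{predicate} failed at {target}"


@dataclass(frozen=True)
class QCMessage:
    rule_id: int
    severity: Severity
    target_path: str
    text: str


@dataclass
class QCReport:
    messages: list[QCMessage]

    @property
    def counts(self) -> dict[Severity, int]:
        tally = Counter(m.severity for m in self.messages)
        return {s: tally.get(s, 0) for s in Severity}

    @property
    def derived_status(self) -> QualityStatus:
        return derive_status(self)

    def to_dict(self) -> dict:
        return {
            "messages": [
                {
                    "rule_id": m.rule_id,
                    "severity": m.severity.value,
                    "target_path": m.target_path,
                    "text": m.text,
                }
                for m in self.messages
            ],
            "counts": {s.value: n for s, n in self.counts.items()},
            "derived_status": self.derived_status.value,
        }

    def render(self) -> str:
        lines = ["Quality control report", "----------------------"]
        for m in self.messages:
            lines.append(f"[{m.severity.value}] rule {m.rule_id} @ {m.target_path}: {m.text}")
        counts = ", ".join(f"{s.value.lower()}={n}" for s, n in self.counts.items())
        lines.append(f"counts: {counts}")
        lines.append(f"derived status: {self.derived_status.value}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Predicate vocabulary
# ---------------------------------------------------------------------------

# A predicate inspects an experiment (and optionally a single group) and
# yields (target_path, detail) pairs for every violation it finds.
Predicate = Callable[[QualityRule, Experiment, "ExperimentalGroup | None"], Iterable[tuple[str, str]]]

_PREDICATES: dict[str, Predicate] = {}


def predicate(name: str) -> Callable[[Predicate], Predicate]:
    def register(fn: Predicate) -> Predicate:
        _PREDICATES[name] = fn
        return fn

    return register


def _groups(experiment: Experiment, group) -> list[ExperimentalGroup]:
    return [group] if group is not None else list(experiment.groups)


@predicate("required_field")
def _required_field(rule, experiment, group):
    name = rule.params["field"]
    value = getattr(experiment, name, None)
    if value in (None, ""):
        yield f"experiment:{experiment.id}", f"required field {name!r} is missing"


@predicate("control_group_present")
def _control_group_present(rule, experiment, group):
    wanted = GroupType(rule.params.get("group_type", GroupType.NAIVE_CONTROL))
    if not experiment.groups_of_type(wanted):
        yield f"experiment:{experiment.id}", f"no {wanted.value} group defined"


@predicate("min_group_size")
def _min_group_size(rule, experiment, group):
    n_min = int(rule.params.get("n", 3))
    for g in _groups(experiment, group):
        if len(g.individuals) < n_min:
            yield (
                f"experiment:{experiment.id}/group:{g.id}",
                f"group has {len(g.individuals)} individuals, fewer than {n_min}",
            )


@predicate("percentage_range")
def _percentage_range(rule, experiment, group):
    lo = float(rule.params.get("low", 0.0))
    hi = float(rule.params.get("high", 100.0))
    for g in _groups(experiment, group):
        for ind in g.individuals:
            for m in ind.tcell:
                for p in TCELL_PARAMETERS:
                    v = getattr(m, p)
                    if v is not None and not (lo <= v <= hi):
                        yield (
                            f"experiment:{experiment.id}/group:{g.id}/individual:{ind.id}/day:{m.day}/{p}",
                            f"{p}={v} outside [{lo}, {hi}]",
                        )


@predicate("naive_range")
def _naive_range(rule, experiment, group):
    """Expert-defined acceptable bounds on naive-group response values."""
    lo = float(rule.params.get("low", 0.0))
    hi = float(rule.params.get("high", 10.0))
    for g in _groups(experiment, group):
        if g.group_type is not GroupType.NAIVE_CONTROL:
            continue
        for ind in g.individuals:
            for m in ind.tcell:
                for p in TCELL_PARAMETERS:
                    v = getattr(m, p)
                    if v is not None and not (lo <= v <= hi):
                        yield (
                            f"experiment:{experiment.id}/group:{g.id}/individual:{ind.id}/day:{m.day}/{p}",
                            f"naive {p}={v} outside expert range [{lo}, {hi}]",
                        )


@predicate("has_measurements")
def _has_measurements(rule, experiment, group):
    kind = rule.params.get("kind", "tcell")
    for g in _groups(experiment, group):
        if not any(getattr(ind, kind) for ind in g.individuals):
            yield (
                f"experiment:{experiment.id}/group:{g.id}",
                f"group has no {kind} measurements",
            )


def default_registry(
    min_group_size: int = 3,
    naive_bounds: tuple[float, float] = (0.0, 10.0),
) -> list[QualityRule]:
    """The checks shipped by default.

    The naive-group acceptable range is an expert-configurable bound; the
    default (0-10 %) is a conservative placeholder for percentage scales.
    """
    return [
        QualityRule(1, ModuleScope.GENERAL, RuleLevel.EXPERIMENT, Severity.FATAL,
                    "required_field", {"field": "laboratory"},
                    "Have the laboratory of the experiment been provided?"),
        QualityRule(2, ModuleScope.GENERAL, RuleLevel.EXPERIMENT, Severity.FATAL,
                    "required_field", {"field": "date"},
                    "Has the date of the experiment been provided?"),
        QualityRule(3, ModuleScope.GENERAL, RuleLevel.EXPERIMENT, Severity.SERIOUS,
                    "control_group_present", {"group_type": "NAIVE_CONTROL"},
                    "Have experimental control groups been created?"),
        QualityRule(4, ModuleScope.GENERAL, RuleLevel.GROUP, Severity.SERIOUS,
                    "min_group_size", {"n": min_group_size},
                    "Is each experimental group large enough for statistical analysis?"),
        QualityRule(5, ModuleScope.TCELL, RuleLevel.VALUE, Severity.FATAL,
                    "percentage_range", {"low": 0.0, "high": 100.0},
                    "Are T-cell response values provided as percentages?"),
        QualityRule(6, ModuleScope.TCELL, RuleLevel.VALUE, Severity.MINOR,
                    "naive_range", {"low": naive_bounds[0], "high": naive_bounds[1]},
                    "Are the naive experimental group results in acceptable ranges?"),
        QualityRule(7, ModuleScope.TCELL, RuleLevel.GROUP, Severity.WARNING,
                    "has_measurements", {"kind": "tcell"},
                    "Does each group carry T-cell measurements?"),
    ]


def load_registry(path: str | Path) -> list[QualityRule]:
    """Load a rule registry from a JSON (or YAML, if available) config file."""
    text = Path(path).read_text()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError:
        import yaml

        raw = yaml.safe_load(text)
    rules = [
        QualityRule(
            rule_id=int(r["rule_id"]),
            module_scope=ModuleScope(r.get("module_scope", "GENERAL")),
            level=RuleLevel(r.get("level", "EXPERIMENT")),
            severity=Severity(r["severity"]),
            predicate=r["predicate"],
            params=dict(r.get("params", {})),
            message_template=r.get("message_template", ""),
        )
        for r in raw
    ]
    ids = [r.rule_id for r in rules]
    if len(ids) != len(set(ids)):
        raise VaxError("rule ids must be unique across the registry")
    return rules


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------


def run_qc(
    target: Experiment | ExperimentalGroup,
    registry: Iterable[QualityRule] | None = None,
    experiment: Experiment | None = None,
) -> QCReport:
    """Evaluate every applicable rule against ``target`` and collect messages.

    A failing rule yields a message, never an exception.  When ``target`` is a
    group, experiment-level rules are skipped and the owning ``experiment``
    must be supplied for context.
    """
    registry = list(default_registry() if registry is None else registry)
    if not registry:
        raise VaxError("rule registry must be non-empty")
    ids = [r.rule_id for r in registry]
    if len(ids) != len(set(ids)):
        raise VaxError("rule ids must be unique across the registry")

    if isinstance(target, Experiment):
        exp, group = target, None
    else:
        if experiment is None:
            raise VaxError("group-level QC needs the owning experiment for context")
        exp, group = experiment, target

    messages: list[QCMessage] = []
    for rule in registry:
        if group is not None and rule.level is RuleLevel.EXPERIMENT:
            continue
        check = _PREDICATES.get(rule.predicate)
        if check is None:
            raise VaxError(f"unknown QC predicate {rule.predicate!r}")
        for target_path, detail in check(rule, exp, group):
            text = rule.message_template or detail
            messages.append(QCMessage(rule.rule_id, rule.severity, target_path, f"{text} ({detail})"))
    return QCReport(messages=messages)


def derive_status(report: QCReport, user_decision: str | None = None) -> QualityStatus:
    """Worst-severity status derivation with optional manual override.

    ``user_decision`` (``"to_U"`` or ``"to_R"``) is only legal from the
    pending state, i.e. when serious (but no fatal) errors are present.
    """
    severities = {m.severity for m in report.messages}
    if Severity.FATAL in severities:
        status = QualityStatus.R
    elif Severity.SERIOUS in severities:
        status = QualityStatus.P
    else:
        status = QualityStatus.A
    if user_decision is not None:
        if status is not QualityStatus.P:
            raise VaxError(f"manual decision only allowed from P, status is {status.value}")
        if user_decision == "to_U":
            return QualityStatus.U
        if user_decision == "to_R":
            return QualityStatus.R
        raise VaxError(f"unknown user decision {user_decision!r}")
    return status


def compute_flags(experiment: Experiment) -> set[str]:
    """Readiness flags from validated (A or U) group statuses.

    E-ready: >=1 naive and >=1 internal-standard-or-vaccine group validated.
    EC-ready: >=1 naive, >=1 internal standard and >=1 vaccine group
    validated; EC-ready therefore implies E-ready.
    """
    def any_validated(*types: GroupType) -> bool:
        return any(
            g.quality_status in VALIDATED_STATUSES
            for t in types
            for g in experiment.groups_of_type(t)
        )

    naive_ok = any_validated(GroupType.NAIVE_CONTROL)
    is_ok = any_validated(GroupType.INTERNAL_STANDARD)
    vaccine_ok = any_validated(GroupType.EXPERIMENTAL_VACCINE)

    flags: set[str] = set()
    if naive_ok and (is_ok or vaccine_ok):
        flags.add(E_READY)
    if naive_ok and is_ok and vaccine_ok:
        flags.add(EC_READY)
    return flags


@dataclass
class UserDecision:
    """A manual status override with a free-text audit note (who / when)."""

    decision: str  # "to_U" | "to_R"
    note: str = ""


def qc_experiment(
    experiment: Experiment,
    registry: Iterable[QualityRule] | None = None,
    group_decisions: Mapping[str, UserDecision] | None = None,
) -> QCReport:
    """Run QC over every group and the experiment; set statuses and flags.

    Group statuses are derived from group-level reports (applying any manual
    decision supplied per group id); the experiment report aggregates all
    messages and drives the experiment status.  Readiness flags are recomputed
    from the resulting group statuses.
    """
    registry = list(default_registry() if registry is None else registry)
    group_decisions = dict(group_decisions or {})
    for group in experiment.groups:
        g_report = run_qc(group, registry, experiment=experiment)
        decision = group_decisions.get(group.id)
        group.quality_status = derive_status(g_report, decision.decision if decision else None)
    report = run_qc(experiment, registry)
    experiment.quality_status = derive_status(report)
    experiment.flags = compute_flags(experiment)
    return report
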