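"""Vector challenge analysis: survival of challenged individuals.

After immunization, individuals are challenged with live pathogen and their
survival recorded at the challenge protocol's observation days.  The group
summary is the proportion alive per observation day; the experiment summary
links per-group antibody titers (from the B-cell module) with final survival,
mirroring the combined titer/survival view used to judge protection.

Survival is endpoint status at fixed observation days; there is no censoring
model and no time-to-event machinery.  Viremia values are stored and exported
but not analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .core import (
    ChallengeProtocol,
    Experiment,
    ExperimentalGroup,
    GroupType,
    Particle,
    VaxError,
)
from . import bcell


@dataclass
class SurvivalCurve:
    """Proportion of a group alive at each observation day (non-increasing)."""

    group_id: str
    days: list[int]
    proportion_alive: list[float]
    n_at_risk: list[int]

    @property
    def final_survival(self) -> float:
        return self.proportion_alive[-1]


def survival_curve(group: ExperimentalGroup, protocol: ChallengeProtocol) -> SurvivalCurve:
    """Proportion alive per protocol observation day.

    Every individual must report an outcome at every observation day;
    missing or extraneous days are hard errors here (the QC layer surfaces
    them as messages before analysis is attempted).
    """
    if not any(ind.challenge for ind in group.individuals):
        raise VaxError(f"group {group.id!r} has no challenge outcomes")
    days = list(protocol.observation_days)
    n = len(group.individuals)
    proportions: list[float] = []
    for day in days:
        alive = 0
        for ind in group.individuals:
            by_day = {o.day: o for o in ind.challenge}
            extraneous = set(by_day) - set(days)
            if extraneous:
                raise VaxError(
                    f"individual {ind.id!r} has outcomes at days {sorted(extraneous)} "
                    "not in the challenge protocol"
                )
            if day not in by_day:
                raise VaxError(f"individual {ind.id!r} missing outcome at day {day}")
            alive += int(by_day[day].alive)
        proportions.append(alive / n)
    return SurvivalCurve(group.id, days, proportions, [n] * len(days))


@dataclass
class ChallengeSummaryRow:
    group_id: str
    vector_protocol_id: str
    titers: dict[int, float | None] = field(default_factory=dict)  # day -> titer
    final_survival: float | None = None


def challenge_summary(
    experiment: Experiment,
    protocol: ChallengeProtocol,
    titer_days: Sequence[int] = (),
    serum_for_day: dict[int, str] | None = None,
    cache: bcell.FitCache | None = None,
) -> list[ChallengeSummaryRow]:
    """Per-group table of antibody titers at requested days + final survival.

    ``serum_for_day`` maps each requested titer day to the serum label
    sampled that day; when omitted, the experiment's declared sera are
    searched for a label with a matching day.  Groups without titration data
    carry absent titer cells; groups without challenge data are excluded
    (their absence is noted by the caller's report).  Rows are ordered by
    group id.
    """
    serum_for_day = dict(serum_for_day or {})
    for day in titer_days:
        if day not in serum_for_day:
            label = next((lbl for lbl, d in experiment.sera.items() if d == day), None)
            if label is not None:
                serum_for_day[day] = label

    rows: list[ChallengeSummaryRow] = []
    for group in sorted(experiment.groups, key=lambda g: g.id):
        if group.group_type is GroupType.OTHER:
            continue
        if not any(ind.challenge for ind in group.individuals):
            continue
        row = ChallengeSummaryRow(
            group_id=group.id, vector_protocol_id=group.immunization_protocol_id
        )
        row.final_survival = survival_curve(group, protocol).final_survival
        for day in titer_days:
            titer: float | None = None
            label = serum_for_day.get(day)
            if label is not None:
                try:
                    params = bcell.fit_group(
                        experiment, label, Particle.AG_PP, group_id=group.id, cache=cache
                    )
                    titer = bcell.titer_from_fit(params)
                except VaxError:
                    titer = None
            row.titers[day] = titer
        rows.append(row)
    return rows
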