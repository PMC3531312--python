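"""T-cell response analysis.

Four parameters describe the T-lymphocyte response over time, all on percent
scales: antigen-specific T-cell expansion, memory phenotype, CTL activation
(intracellular IFN-gamma-positive CD8+ T-cells) and cytotoxicity (specific
lysis).  Group summaries average individuals per day; group values are then
normalized against the naive/control group (empty vector, no antigen), and
cross-experiment comparison expresses normalized values as ratios against an
internal-standard group immunized with a common benchmark protocol.  A radar
chart condenses the four normalized axes; its polygon area is the scalar
summary (bigger area = better response).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import (
    TCELL_PARAMETERS,
    Experiment,
    ExperimentalGroup,
    GroupType,
    VaxError,
)


@dataclass
class GroupTimecourse:
    """Per-day mean/sd/n of one parameter over a group's individuals.

    Missing individual values are simply excluded (no imputation); with a
    single reporter the sd is reported as 0 and flagged via ``n == 1``.
    """

    group_id: str
    parameter: str
    days: list[int]
    mean: list[float]
    sd: list[float]
    n: list[int]

    def at_day(self, day: int) -> tuple[float, float, int]:
        i = self.days.index(day)
        return self.mean[i], self.sd[i], self.n[i]


@dataclass
class NormalizedResponse:
    """Group response after normalization against the naive group."""

    group_id: str
    reference: str  # naive group id
    day_used: dict[str, int] = field(default_factory=dict)
    values: dict[str, float] = field(default_factory=dict)  # parameter -> value


@dataclass
class ISRatio:
    """Normalized group values as ratios against the internal standard.

    A parameter on which the internal standard normalizes to 0 has no
    meaningful ratio and is reported as missing (``None``), never infinity.
    """

    group_id: str
    is_group_id: str
    ratios: dict[str, float | None] = field(default_factory=dict)


def summarize_group(group: ExperimentalGroup, parameter: str) -> GroupTimecourse:
    """Per-day mean, sample sd and reporter count for one T-cell parameter."""
    if parameter not in TCELL_PARAMETERS:
        raise VaxError(f"unknown T-cell parameter {parameter!r}")
    by_day: dict[int, list[float]] = {}
    for ind in group.individuals:
        for m in ind.tcell:
            v = getattr(m, parameter)
            if v is not None:
                by_day.setdefault(m.day, []).append(v)
    if not by_day:
        raise VaxError(f"group {group.id!r} has no data for {parameter!r}")
    days = sorted(by_day)
    means, sds, ns = [], [], []
    for d in days:
        vals = np.asarray(by_day[d], dtype=float)
        means.append(float(vals.mean()))
        sds.append(float(vals.std(ddof=1)) if vals.size > 1 else 0.0)
        ns.append(int(vals.size))
    return GroupTimecourse(group.id, parameter, days, means, sds, ns)


def _mean_at(course: GroupTimecourse, at_day: int) -> float | None:
    """Group mean at ``at_day``, falling back to the nearest earlier day."""
    eligible = [d for d in course.days if d <= at_day]
    if not eligible:
        return None
    return course.at_day(max(eligible))[0]


def _group_means(group: ExperimentalGroup, at_day: int) -> dict[str, float]:
    means: dict[str, float] = {}
    for p in TCELL_PARAMETERS:
        try:
            course = summarize_group(group, p)
        except VaxError:
            continue
        m = _mean_at(course, at_day)
        if m is not None:
            means[p] = m
    return means


def normalize_vs_naive(
    experiment: Experiment,
    at_day: int,
    naive_group_id: str | None = None,
    mode: str = "subtract",
) -> list[NormalizedResponse]:
    """Normalize each analyzable group against the naive group at ``at_day``.

    ``mode="subtract"`` (default) reports max(0, group mean - naive mean);
    subtraction floored at zero is stable on percent scales near zero.
    ``mode="ratio"`` reports group mean / naive mean (requires naive > 0).
    Groups typed OTHER are excluded.  When a group lacks data exactly at
    ``at_day`` the nearest earlier measured day is used; never interpolated.
    """
    if mode not in ("subtract", "ratio"):
        raise VaxError(f"unknown normalization mode {mode!r}")
    naives = experiment.groups_of_type(GroupType.NAIVE_CONTROL)
    if naive_group_id is not None:
        naives = [g for g in naives if g.id == naive_group_id]
    if not naives:
        raise VaxError(f"experiment {experiment.id!r} has no naive/control group")
    naive = naives[0]
    naive_means = _group_means(naive, at_day)
    if not naive_means:
        raise VaxError(f"naive group {naive.id!r} has no data at or before day {at_day}")

    out: list[NormalizedResponse] = []
    for group in experiment.groups:
        if group.group_type is GroupType.OTHER:
            continue
        means = _group_means(group, at_day)
        resp = NormalizedResponse(group_id=group.id, reference=naive.id)
        for p, m in means.items():
            if p not in naive_means:
                continue
            if group is naive:
                resp.values[p] = 0.0 if mode == "subtract" else 1.0
            elif mode == "subtract":
                resp.values[p] = max(0.0, m - naive_means[p])
            else:
                if naive_means[p] <= 0:
                    continue
                resp.values[p] = m / naive_means[p]
        if resp.values:
            out.append(resp)
    return out


def ratio_vs_internal_standard(
    groups: Sequence[tuple[Experiment, ExperimentalGroup]],
    is_pair: tuple[Experiment, ExperimentalGroup],
    at_day: int,
    mode: str = "subtract",
) -> list[ISRatio]:
    """Express normalized group values as ratios against an internal standard.

    Each compared group is first normalized against its own experiment's
    naive group; the ratio is then group value / internal-standard value per
    parameter.  Comparison is only legal when the compared group's experiment
    carries an internal-standard group immunized following the same
    immunization protocol as the reference internal standard.
    """
    is_exp, is_group = is_pair
    if is_group.group_type is not GroupType.INTERNAL_STANDARD:
        raise VaxError(f"group {is_group.id!r} is not an internal standard")
    is_norm = {r.group_id: r for r in normalize_vs_naive(is_exp, at_day, mode=mode)}
    if is_group.id not in is_norm:
        raise VaxError(f"internal standard {is_group.id!r} has no normalized values")
    is_values = is_norm[is_group.id].values

    out: list[ISRatio] = []
    for exp, group in groups:
        if exp is is_exp:
            local_is = is_group
        else:
            candidates = exp.groups_of_type(GroupType.INTERNAL_STANDARD)
            local_is = next(
                (g for g in candidates
                 if g.immunization_protocol_id == is_group.immunization_protocol_id),
                None,
            )
            if local_is is None:
                raise VaxError(
                    f"experiment {exp.id!r} has no internal standard following "
                    f"protocol {is_group.immunization_protocol_id!r}"
                )
        norm = {r.group_id: r for r in normalize_vs_naive(exp, at_day, mode=mode)}
        if group.id not in norm:
            raise VaxError(f"group {group.id!r} has no normalized values at day {at_day}")
        ratios: dict[str, float | None] = {}
        for p, v in norm[group.id].values.items():
            denom = is_values.get(p)
            ratios[p] = None if denom in (None, 0.0) else v / denom
        out.append(ISRatio(group_id=group.id, is_group_id=is_group.id, ratios=ratios))
    return out


def radar_area_score(values: Iterable[float | None]) -> float:
    """Area of the radar-chart polygon spanned by K non-negative axis values.

    Axes are equally spaced; a missing value (``None``) drops its axis and
    reduces K.  The area is the sum of the K triangles between consecutive
    axes: (1/2) * sum_i v_i * v_{i+1 mod K} * sin(2*pi/K).  Larger area means
    a stronger response profile.
    """
    vals = [v for v in values if v is not None]
    if len(vals) < 3:
        raise VaxError("radar area needs at least 3 axes with values")
    if any((not math.isfinite(v)) or v < 0 for v in vals):
        raise VaxError("radar values must be finite and non-negative")
    k = len(vals)
    s = math.sin(2.0 * math.pi / k)
    return 0.5 * s * sum(vals[i] * vals[(i + 1) % k] for i in range(k))
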