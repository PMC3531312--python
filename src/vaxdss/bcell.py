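"""B-cell neutralization analysis: 4PL titration curves and antibody titers.

Serum titration series (% neutralization against antigen-specific or control
pseudoparticles across a dilution grid) are fitted with the four-parameter
logistic model

    y(d) = bottom + (top - bottom) / (1 + 10^(HillSlope * log10(EC50 / d)))

where ``d`` is the dilution factor (serum diluted 1/d), ``top`` and
``bottom`` the asymptotes and EC50 the dilution producing neutralization
halfway between them.  The antibody titer is the reciprocal dilution read off
the fitted curve at a threshold (midpoint by default, making titer == EC50).

Fits are cached keyed by series identity and the experiment revision stamp,
so unchanged data is never refitted and any manual edit invalidates the
cache.  *Virtual sera* align titration series sampled on different days in
different experiments onto one comparable axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .core import (
    Experiment,
    ExperimentalGroup,
    Particle,
    Store,
    TitrationPoint,
    UnknownIdError,
    VaxError,
    ValidationError,
)

#: Default parameter bounds; ``log_ec50_pad`` widens the EC50 range this many
#: decades beyond the observed dilution window (tenfold each way by default).
DEFAULT_BOUNDS = {"bottom": (-10.0, 50.0), "top": (50.0, 110.0),
                  "hill_slope": (-20.0, 20.0), "log_ec50_pad": 1.0}

#: Bounds used when assessing assay specificity (antigen-irrelevant control
#: series): free asymptotes — the default top/bottom bounds would force a
#: flat series apart — and EC50 confined to the tested dilutions, since a
#: half-maximum outside the tested range is not evidence of neutralization
#: and lets the asymptote span extrapolate without limit.
WIDE_BOUNDS = {"bottom": (-10.0, 110.0), "top": (-10.0, 110.0),
               "hill_slope": (-20.0, 20.0), "log_ec50_pad": 0.0}


@dataclass
class SigmoidParams:
    """Fitted 4PL parameters with diagnostics."""

    top: float
    bottom: float
    hill_slope: float
    ec50: float
    rss: float = float("nan")
    n_points: int = 0
    converged: bool = True

    def __post_init__(self):
        if self.ec50 <= 0:
            raise ValidationError("EC50 must be positive")
        if self.top < self.bottom:
            raise ValidationError("top asymptote must be >= bottom")

    def to_dict(self) -> dict:
        return {
            "top": self.top,
            "bottom": self.bottom,
            "hill_slope": self.hill_slope,
            "ec50": self.ec50,
            "rss": self.rss,
            "n_points": self.n_points,
            "converged": self.converged,
        }


def eval_4pl(params: SigmoidParams, dilution: float) -> float:
    """Neutralization (%) predicted by the 4PL model at a dilution factor."""
    if dilution <= 0:
        raise VaxError("dilution factor must be positive")
    expo = params.hill_slope * math.log10(params.ec50 / dilution)
    return params.bottom + (params.top - params.bottom) / (1.0 + 10.0 ** expo)


def _model(theta: np.ndarray, d: np.ndarray) -> np.ndarray:
    top, bottom, slope, log_ec50 = theta
    return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (log_ec50 - np.log10(d))))


def _logit_init(d: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Starting values from a logit linearization of the rescaled response."""
    ymin, ymax = float(y.min()), float(y.max())
    span = max(ymax - ymin, 1e-6)
    z = np.clip((y - ymin + 0.02 * span) / (span * 1.04), 1e-4, 1 - 1e-4)
    # log10(1/z - 1) = slope*log10(ec50) - slope*log10(d)
    logd = np.log10(d)
    lhs = np.log10(1.0 / z - 1.0)
    a, b = np.polyfit(logd, lhs, 1)  # lhs = a*logd + b
    slope = -a if abs(a) > 1e-8 else 1.0
    log_ec50 = b / slope if abs(slope) > 1e-8 else float(np.median(logd))
    return ymax, ymin, float(slope), float(log_ec50)


def fit_4pl(
    points: Sequence[TitrationPoint],
    bounds: dict | None = None,
) -> SigmoidParams:
    """Nonlinear least-squares fit of the 4PL model to one titration series.

    Requires at least four points over at least four distinct dilution
    factors.  Starting values come from a logit linearization; both slope
    signs are tried and the lower-cost solution kept.  Non-convergence is
    reported via ``converged=False`` with best-effort parameters, never an
    exception.
    """
    pts = list(points)
    d = np.asarray([p.dilution_factor for p in pts], dtype=float)
    y = np.asarray([p.neutralization_pct for p in pts], dtype=float)
    if len(pts) < 4 or len(np.unique(d)) < 4:
        raise VaxError("4PL fit needs >=4 points over >=4 distinct dilutions")

    b = dict(DEFAULT_BOUNDS, **(bounds or {}))
    pad = float(b["log_ec50_pad"])
    log_lo = math.log10(d.min()) - pad
    log_hi = math.log10(d.max()) + pad
    lo = np.array([b["top"][0], b["bottom"][0], b["hill_slope"][0], log_lo])
    hi = np.array([b["top"][1], b["bottom"][1], b["hill_slope"][1], log_hi])

    top0, bottom0, slope0, log_ec50_0 = _logit_init(d, y)
    log_mid = float(np.median(np.log10(d)))
    ymean = float(y.mean())
    starts = [
        (top0, bottom0, slope0, log_ec50_0),
        (top0, bottom0, -slope0, log_ec50_0),
        # flat start: resolves near-constant series (e.g. control particles)
        (ymean, ymean, 1.0, log_mid),
    ]
    best = None
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lo + 1e-9, hi - 1e-9)
        res = least_squares(
            lambda th: _model(th, d) - y,
            x0,
            bounds=(lo, hi),
            method="trf",
            xtol=1e-13,
            ftol=1e-13,
            gtol=1e-13,
            max_nfev=800,
        )
        if best is None or res.cost < best.cost * (1.0 - 1e-6):
            best = res
        elif res.cost < best.cost * (1.0 + 1e-6):
            # cost tie: the asymptote span is unidentifiable when EC50 sits
            # outside the observed window; prefer the smaller-span solution
            if abs(res.x[0] - res.x[1]) < abs(best.x[0] - best.x[1]):
                best = res
    top, bottom, slope, log_ec50 = best.x
    if top < bottom:  # canonicalize: swap asymptotes and flip the slope sign
        top, bottom, slope = bottom, top, -slope
    return SigmoidParams(
        top=float(top),
        bottom=float(bottom),
        hill_slope=float(slope),
        ec50=float(10.0 ** log_ec50),
        rss=float(2.0 * best.cost),
        n_points=len(pts),
        converged=bool(best.success),
    )


def titer_from_fit(params: SigmoidParams, threshold_pct: float | None = None) -> float:
    """Reciprocal dilution at which the fitted curve crosses a threshold.

    The default threshold is the midpoint (top+bottom)/2, making the titer
    identical to EC50; a fixed absolute threshold strictly inside
    (bottom, top) is inverted in closed form.
    """
    if not params.converged:
        raise VaxError("titer requires a converged fit")
    if threshold_pct is None:
        return params.ec50
    if not (params.bottom < threshold_pct < params.top):
        raise VaxError(
            f"threshold {threshold_pct} outside open interval "
            f"({params.bottom}, {params.top})"
        )
    ratio = (params.top - params.bottom) / (threshold_pct - params.bottom) - 1.0
    return params.ec50 * ratio ** (-1.0 / params.hill_slope)


class FitCache:
    """Fit results keyed by (series identity, experiment stamp).

    Sigmoid fitting is computed once on first request; any experiment
    revision changes the stamp and thus invalidates every cached fit for it.
    """

    def __init__(self) -> None:
        self._cache: dict[tuple, SigmoidParams] = {}
        self.hits = 0
        self.misses = 0

    def get_or_fit(self, key: tuple, stamp: int, points: Sequence[TitrationPoint]) -> SigmoidParams:
        full_key = (key, stamp)
        if full_key in self._cache:
            self.hits += 1
            return self._cache[full_key]
        self.misses += 1
        params = fit_4pl(points)
        self._cache[full_key] = params
        return params


def series_points(
    scope: ExperimentalGroup | Experiment,
    serum_label: str,
    particle: Particle | str,
) -> list[TitrationPoint]:
    """Union of all individuals' points for one serum/particle in scope."""
    particle = Particle(particle)
    groups = scope.groups if isinstance(scope, Experiment) else [scope]
    return [
        p
        for g in groups
        for ind in g.individuals
        for p in ind.titration
        if p.serum_label == serum_label and p.particle is particle
    ]


def fit_group(
    experiment: Experiment,
    serum_label: str,
    particle: Particle | str = Particle.AG_PP,
    group_id: str | None = None,
    cache: FitCache | None = None,
) -> SigmoidParams:
    """Average sigmoid of a group (or whole experiment when no group given).

    All data points of all individuals in scope enter one pooled fit, so
    individuals with more points weigh proportionally more.
    """
    scope: ExperimentalGroup | Experiment
    scope = experiment if group_id is None else experiment.get_group(group_id)
    points = series_points(scope, serum_label, particle)
    if cache is not None:
        key = (experiment.id, group_id, serum_label, Particle(particle).value)
        return cache.get_or_fit(key, experiment.stamp, points)
    return fit_4pl(points)


# ---------------------------------------------------------------------------
# Virtual sera
# ---------------------------------------------------------------------------


@dataclass
class VirtualSerumMap:
    """User-declared correspondence of sera across experiments.

    Each entry maps (experiment, group, serum label, sampling day) onto one
    shared virtual label, e.g. matching day 14 of one experiment with day 15
    of another.  At most one entry per (experiment, group).
    """

    virtual_label: str
    entries: list[tuple[str, str, str, int]] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for exp_id, group_id, _label, _day in self.entries:
            key = (exp_id, group_id)
            if key in seen:
                raise ValidationError(
                    f"virtual serum {self.virtual_label!r}: duplicate entry for {key}"
                )
            seen.add(key)


def align_virtual_sera(
    maps: Iterable[VirtualSerumMap],
    experiments: Iterable[Experiment] | Store,
) -> dict[str, dict[tuple[str, str], list[TitrationPoint]]]:
    """Resolve virtual-serum maps to side-by-side titration series.

    Returns ``{virtual_label: {(experiment_id, group_id): points}}`` keeping
    only antigen-specific and control points whose serum label and day match
    the mapped entry.  A map with fewer than two entries is passed through
    with a warning (nothing to compare); an entry resolving to no data is an
    error.
    """
    if isinstance(experiments, Store):
        index = dict(experiments.experiments)
    else:
        index = {e.id: e for e in experiments}
    out: dict[str, dict[tuple[str, str], list[TitrationPoint]]] = {}
    for vs in maps:
        if len(vs.entries) < 2:
            warnings.warn(
                f"virtual serum {vs.virtual_label!r} maps fewer than two series; "
                "nothing to compare",
                stacklevel=2,
            )
        aligned: dict[tuple[str, str], list[TitrationPoint]] = {}
        for exp_id, group_id, serum_label, day in vs.entries:
            if exp_id not in index:
                raise UnknownIdError(f"virtual serum entry references unknown experiment {exp_id!r}")
            group = index[exp_id].get_group(group_id)
            points = [
                p
                for ind in group.individuals
                for p in ind.titration
                if p.serum_label == serum_label and p.day == day
            ]
            if not points:
                raise VaxError(
                    f"virtual serum {vs.virtual_label!r}: no titration data for "
                    f"({exp_id}, {group_id}, {serum_label}, day {day})"
                )
            aligned[(exp_id, group_id)] = points
        out[vs.virtual_label] = aligned
    return out
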