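"""Molecular signature extraction from gene-expression profiles.

The module characterizes the change of gene expression in vaccinated
individuals against control individuals: per-gene means over each group's
profiles, a fold-change ratio per gene, and a threshold filter removing genes
whose expression ratio (in either direction, i.e. max(r, 1/r)) stays below a
threshold.  The retained genes ordered by |log2 ratio| form the *molecular
signature* — a candidate marker set of vaccine activity.  Signatures from
several experiments can be laid side by side in a gene x experiment matrix.

Platform-level preprocessing (chip normalization, probe-to-gene mapping) is
out of scope: profiles are generic gene -> value matrices, and mixing
platforms within one comparison is rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Experiment, ExperimentalGroup, GroupType, VaxError, ValidationError


@dataclass
class GeneList:
    """A named, user-owned set of genes of interest."""

    name: str
    genes: set[str]
    owner: str = ""

    def __post_init__(self):
        self.genes = set(self.genes)
        if not self.genes:
            raise ValidationError("gene list must be non-empty")

    def to_dict(self) -> dict:
        return {"name": self.name, "genes": sorted(self.genes), "owner": self.owner}

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneList":
        return cls(d["name"], set(d["genes"]), d.get("owner", ""))


@dataclass
class ExpressionComparison:
    """Per-gene comparison of a vaccinated group against a control group."""

    vaccinated_group_id: str
    control_group_id: str
    threshold: float
    # gene -> (mean_vaccinated, mean_control, ratio)
    genes: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    excluded: set[str] = field(default_factory=set)
    # genes whose control mean is 0: ratio undefined, reported separately
    undefined_ratio: dict[str, tuple[float, float]] = field(default_factory=dict)

    def retained(self) -> dict[str, tuple[float, float, float]]:
        return {g: t for g, t in self.genes.items() if g not in self.excluded}


def _group_profile_means(
    group: ExperimentalGroup, organ: str, cell_type: str, log_scale: bool
) -> tuple[pd.Series, set[str]]:
    frames = []
    platforms = set()
    for ind in group.individuals:
        for prof in ind.expression:
            if prof.organ == organ and prof.cell_type == cell_type:
                frames.append(pd.Series(prof.values, dtype=float))
                platforms.add(prof.platform)
    if not frames:
        raise VaxError(
            f"group {group.id!r} has no expression profile for ({organ!r}, {cell_type!r})"
        )
    mat = pd.concat(frames, axis=1)
    if log_scale:
        means = np.exp(np.log(mat.where(mat > 0)).mean(axis=1))
    else:
        means = mat.mean(axis=1)
    return means, platforms


def compare_expression(
    vaccinated_group: ExperimentalGroup,
    control_group: ExperimentalGroup,
    organ: str,
    cell_type: str,
    threshold: float,
    gene_list: GeneList | None = None,
    two_sided: bool = True,
    log_scale_means: bool = False,
) -> ExpressionComparison:
    """Per-gene fold-change comparison with threshold filtering.

    ``threshold >= 1`` excludes genes whose fold change stays below it; with
    ``two_sided`` (default) the fold change is max(ratio, 1/ratio), so up-
    and down-regulation are filtered symmetrically.  Genes with a zero
    control mean have an undefined ratio and are reported separately, never
    silently dropped.
    """
    if threshold < 1:
        raise VaxError("threshold must be >= 1")
    v_means, v_platforms = _group_profile_means(vaccinated_group, organ, cell_type, log_scale_means)
    c_means, c_platforms = _group_profile_means(control_group, organ, cell_type, log_scale_means)
    if len(v_platforms | c_platforms) > 1:
        raise VaxError(f"mixed platforms in one comparison: {sorted(v_platforms | c_platforms)}")

    shared = v_means.index.intersection(c_means.index)
    if gene_list is not None:
        shared = shared.intersection(sorted(gene_list.genes))
    if shared.empty:
        raise VaxError("no genes shared by both groups (after gene-list restriction)")

    comp = ExpressionComparison(
        vaccinated_group_id=vaccinated_group.id,
        control_group_id=control_group.id,
        threshold=threshold,
    )
    for gene in shared:
        mv, mc = float(v_means[gene]), float(c_means[gene])
        if mc <= 0:
            comp.undefined_ratio[gene] = (mv, mc)
            continue
        r = mv / mc
        comp.genes[gene] = (mv, mc, r)
        fold = max(r, 1.0 / r) if (two_sided and r > 0) else r
        if fold < threshold:
            comp.excluded.add(gene)
    return comp


def extract_signature(comparison: ExpressionComparison) -> list[tuple[str, float]]:
    """Retained genes ordered by |log2 ratio| descending, ties by gene id."""
    rows = []
    for gene, (_mv, _mc, r) in comparison.retained().items():
        if r <= 0:
            continue
        rows.append((gene, math.log2(r)))
    rows.sort(key=lambda t: (-abs(t[1]), t[0]))
    return rows


def cross_experiment_matrix(
    comparisons: Mapping[str, ExpressionComparison],
    gene_list: GeneList | None = None,
) -> pd.DataFrame:
    """Gene x experiment matrix of log2 ratios of retained genes.

    Rows are the union of genes retained in any comparison (restricted to
    ``gene_list`` when given); a gene not retained in some experiment leaves
    that cell absent (NaN).
    """
    if not comparisons:
        raise VaxError("need at least one valid comparison")
    columns: dict[str, dict[str, float]] = {}
    for exp_id, comp in comparisons.items():
        columns[exp_id] = dict(extract_signature(comp))
    matrix = pd.DataFrame(columns)
    if gene_list is not None:
        matrix = matrix.loc[matrix.index.intersection(sorted(gene_list.genes))]
    return matrix.sort_index()


def compare_experiment(
    experiment: Experiment,
    organ: str,
    cell_type: str,
    threshold: float,
    vaccinated_group_id: str | None = None,
    control_group_id: str | None = None,
    **kwargs,
) -> ExpressionComparison:
    """Convenience wrapper: vaccinated (default first vaccine group) vs
    control (default first naive group) within one experiment."""
    if vaccinated_group_id is None:
        vaccinated = experiment.groups_of_type(GroupType.EXPERIMENTAL_VACCINE)
        if not vaccinated:
            raise VaxError(f"experiment {experiment.id!r} has no vaccine group")
        vac = vaccinated[0]
    else:
        vac = experiment.get_group(vaccinated_group_id)
    if control_group_id is None:
        controls = experiment.groups_of_type(GroupType.NAIVE_CONTROL)
        if not controls:
            raise VaxError(f"experiment {experiment.id!r} has no naive/control group")
        ctl = controls[0]
    else:
        ctl = experiment.get_group(control_group_id)
    return compare_expression(vac, ctl, organ, cell_type, threshold, **kwargs)
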