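"""Seeded generator of complete synthetic immunization experiments.

The generator emulates the structure of a multi-group vaccine-platform
study: one naive/control group (empty vector), one internal-standard group
(reference vector) and candidate experimental-vaccine groups, each with
T-cell time courses, serum titration series (antigen-specific and control
pseudoparticles), gene-expression profiles and challenge survival records —
all drawn from a configured ground truth that is returned alongside the
experiment, so every analysis module can be checked against known answers.

Noise models: additive Gaussian on percent scales (T-cell values truncated
to [0, 100]), multiplicative log-normal on expression, and per-individual
uniform thresholds against the survival curve for challenge outcomes (which
makes death monotone by construction).  Each measurement family draws from
its own child stream of the master seed, so enabling or reconfiguring one
family never perturbs the draws of another.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import (
    ChallengeOutcome,
    ChallengeProtocol,
    Experiment,
    ExpressionProfile,
    GroupType,
    ImmunizationProtocol,
    Inoculation,
    Particle,
    Store,
    TCellMeasurement,
    TitrationPoint,
    ValidationError,
    VectorRecord,
    TCELL_PARAMETERS,
)


@dataclass
class GroupSpec:
    """Configured truth for one experimental group."""

    group_id: str
    group_type: GroupType
    protocol_id: str
    n_individuals: int = 5
    #: additive offsets over the naive baseline, per T-cell parameter
    tcell_offsets: dict[str, float] = field(default_factory=dict)
    #: 4PL truth per serum label: (top, bottom, hill_slope, ec50)
    bcell_truth: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)
    #: fold change applied to planted genes in this group's profiles
    expression_fold: float = 1.0
    #: cumulative survival probability at each challenge observation day
    survival: list[float] = field(default_factory=list)


#: Pre-immune (day 0) titration truth shared by every group.
PREIMMUNE_BCELL = (55.0, 0.0, 1.2, 25.0)


def _default_groups() -> list[GroupSpec]:
    naive_offsets = {p: 0.0 for p in TCELL_PARAMETERS}
    is_offsets = {
        "expansion_pct": 20.0,
        "memory_pct": 15.0,
        "ctl_activation_pct": 10.0,
        "cytotoxicity_pct": 12.0,
    }
    vac1_offsets = {
        "expansion_pct": 30.0,
        "memory_pct": 22.0,
        "ctl_activation_pct": 16.0,
        "cytotoxicity_pct": 18.0,
    }
    vac2_offsets = {
        "expansion_pct": 12.0,
        "memory_pct": 8.0,
        "ctl_activation_pct": 6.0,
        "cytotoxicity_pct": 7.0,
    }
    return [
        GroupSpec(
            "G-NAIVE", GroupType.NAIVE_CONTROL, "P-EMPTY",
            tcell_offsets=naive_offsets,
            bcell_truth={"S0": PREIMMUNE_BCELL, "S1": (55.0, 0.0, 1.2, 25.0)},
            expression_fold=1.0,
            survival=[1.0, 0.8, 0.6, 0.4, 0.2],
        ),
        GroupSpec(
            "G-IS", GroupType.INTERNAL_STANDARD, "P-REF",
            tcell_offsets=is_offsets,
            bcell_truth={"S0": PREIMMUNE_BCELL, "S1": (100.0, 0.0, 1.2, 300.0)},
            expression_fold=4.0,
            survival=[1.0, 1.0, 1.0, 1.0, 1.0],
        ),
        GroupSpec(
            "G-VAC1", GroupType.EXPERIMENTAL_VACCINE, "P-CAND",
            tcell_offsets=vac1_offsets,
            bcell_truth={"S0": PREIMMUNE_BCELL, "S1": (100.0, 0.0, 1.2, 600.0)},
            expression_fold=4.0,
            survival=[1.0, 1.0, 1.0, 1.0, 1.0],
        ),
        GroupSpec(
            "G-VAC2", GroupType.EXPERIMENTAL_VACCINE, "P-CAND",
            tcell_offsets=vac2_offsets,
            bcell_truth={"S0": PREIMMUNE_BCELL, "S1": (90.0, 0.0, 1.2, 120.0)},
            expression_fold=2.5,
            survival=[1.0, 1.0, 0.8, 0.8, 0.8],
        ),
    ]


@dataclass
class SynthConfig:
    """Study conditions for one synthetic experiment."""

    seed: int = 0
    experiment_id: str = "E-SYN1"
    laboratory: str = "SynthLab"
    creator: str = "synthgen"
    date: str = "2011-06-01"
    groups: list[GroupSpec] = field(default_factory=_default_groups)
    # T-cell
    tcell_days: list[int] = field(default_factory=lambda: [0, 7, 14, 28])
    tcell_baseline: float = 2.0
    tcell_noise_sd: float = 2.0
    # B-cell: serum label -> sampling day; three-fold dilution grid
    sera: dict[str, int] = field(default_factory=lambda: {"S0": 0, "S1": 14})
    dilutions: list[float] = field(
        default_factory=lambda: [20.0 * 3.0 ** k for k in range(8)]
    )
    bcell_noise_sd: float = 2.0
    ctr_pp_level: float = 2.0
    # Molecular signature
    n_genes: int = 1000
    n_planted: int = 50
    base_expression: float = 100.0
    expression_noise_sd: float = 0.10  # log-normal sigma (natural log scale)
    organ: str = "spleen"
    cell_type: str = "dendritic"
    platform: str = "Illumina"
    # Challenge
    challenge_days: list[int] = field(default_factory=lambda: [0, 3, 7, 10, 14])
    challenge_stochastic: bool = True

    def __post_init__(self):
        if min(self.tcell_noise_sd, self.bcell_noise_sd, self.expression_noise_sd) < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        for spec in self.groups:
            if any(not (0.0 <= p <= 1.0) for p in spec.survival):
                raise ValidationError("survival probabilities must lie in [0, 1]")
        if not (0 <= self.n_planted <= self.n_genes):
            raise ValidationError("planted gene set must fit in the gene universe")

    def noiseless(self) -> "SynthConfig":
        """Copy of this config with every noise source switched off."""
        cfg = dataclasses.replace(
            self,
            tcell_noise_sd=0.0,
            bcell_noise_sd=0.0,
            expression_noise_sd=0.0,
            challenge_stochastic=False,
        )
        cfg.groups = [dataclasses.replace(g) for g in self.groups]
        return cfg


@dataclass
class GroundTruth:
    """Configured truth plus realized latent values of a generated bundle."""

    config: SynthConfig
    #: group -> parameter -> day -> expected (noise-free) T-cell value
    tcell_expected: dict[str, dict[str, dict[int, float]]]
    #: (group, serum) -> (top, bottom, hill_slope, ec50)
    bcell_truth: dict[tuple[str, str], tuple[float, float, float, float]]
    planted_genes: set[str]
    #: group -> expected survival proportion per observation day
    survival_expected: dict[str, list[float]]
    #: group -> realized survival proportion per observation day
    survival_realized: dict[str, list[float]]


@dataclass
class SynthBundle:
    store: Store
    experiment: Experiment
    truth: GroundTruth


def _tcell_expected(cfg: SynthConfig, spec: GroupSpec, parameter: str, day: int) -> float:
    # Responses appear after the first inoculation: baseline at day 0,
    # baseline + group offset on every later measurement day.
    offset = spec.tcell_offsets.get(parameter, 0.0) if day > 0 else 0.0
    return min(100.0, cfg.tcell_baseline + offset)


def synth_experiment(config: SynthConfig | None = None) -> SynthBundle:
    """Generate a complete experiment bundle with known ground truth.

    Identical configs (including the seed) produce byte-identical bundles.
    """
    cfg = config or SynthConfig()
    streams = np.random.SeedSequence(cfg.seed).spawn(5)
    rng_tcell = np.random.default_rng(streams[0])
    rng_bcell = np.random.default_rng(streams[1])
    rng_molsig = np.random.default_rng(streams[2])
    rng_chal = np.random.default_rng(streams[3])
    rng_genes = np.random.default_rng(streams[4])

    store = Store()
    platform_cat = store.category_root.add_child("viral")
    platform_cat.add_child("reference")
    store.add_vector(VectorRecord("V-EMPTY", "empty vector", producer="SynthLab",
                                  production_type="plasmid", antigen=""))
    store.add_vector(VectorRecord("V-REF", "reference vector", ["viral", "reference"],
                                  producer="consortium", production_type="viral",
                                  antigen="gp33", expected_response_type="CTL"))
    store.add_vector(VectorRecord("V-CAND", "candidate vector", ["viral"],
                                  producer="SynthLab", production_type="viral",
                                  antigen="gp33", expected_response_type="CTL"))
    store.add_immunization_protocol(ImmunizationProtocol(
        "P-EMPTY", "empty vector, prime only", [Inoculation(0, "V-EMPTY", 1.0, "ug", "i.m.")]))
    store.add_immunization_protocol(ImmunizationProtocol(
        "P-REF", "reference prime-boost",
        [Inoculation(0, "V-REF", 1.0, "ug", "i.m."), Inoculation(14, "V-REF", 1.0, "ug", "i.m.")]))
    store.add_immunization_protocol(ImmunizationProtocol(
        "P-CAND", "candidate prime-boost",
        [Inoculation(0, "V-CAND", 1.0, "ug", "i.m."), Inoculation(14, "V-CAND", 1.0, "ug", "i.m.")]))
    store.add_challenge_protocol(ChallengeProtocol(
        "CH-1", "live virus", list(cfg.challenge_days), {"survival", "viremia"}))

    exp = store.create_experiment(
        cfg.experiment_id, cfg.laboratory, cfg.creator, cfg.date,
        defaults={"animal_model": "mouse", "sex": "F", "age": 6, "age_unit": "weeks"},
        sera=cfg.sera, dilutions=cfg.dilutions,
    )
    for spec in cfg.groups:
        store.add_group(exp, spec.group_id, spec.group_type, spec.protocol_id,
                        spec.n_individuals)

    gene_ids = [f"g{i + 1:04d}" for i in range(cfg.n_genes)]
    planted_mask = np.zeros(cfg.n_genes, dtype=bool)
    if cfg.n_planted:
        planted_mask[rng_genes.choice(cfg.n_genes, cfg.n_planted, replace=False)] = True
    planted = {g for g, m in zip(gene_ids, planted_mask) if m}

    tcell_expected: dict[str, dict[str, dict[int, float]]] = {}
    bcell_truth: dict[tuple[str, str], tuple] = {}
    survival_expected: dict[str, list[float]] = {}
    survival_realized: dict[str, list[float]] = {}

    for spec in cfg.groups:
        group = exp.get_group(spec.group_id)
        n = spec.n_individuals

        # T-cell time courses -------------------------------------------
        tcell_expected[spec.group_id] = {
            p: {d: _tcell_expected(cfg, spec, p, d) for d in cfg.tcell_days}
            for p in TCELL_PARAMETERS
        }
        for ind in group.individuals:
            for day in cfg.tcell_days:
                values = {}
                for p in TCELL_PARAMETERS:
                    mu = tcell_expected[spec.group_id][p][day]
                    noise = rng_tcell.normal(0.0, cfg.tcell_noise_sd) if cfg.tcell_noise_sd else 0.0
                    values[p] = float(np.clip(mu + noise, 0.0, 100.0))
                ind.tcell.append(TCellMeasurement(day=day, **values))

        # Titration series ----------------------------------------------
        for serum, day in cfg.sera.items():
            truth = spec.bcell_truth.get(serum, PREIMMUNE_BCELL)
            bcell_truth[(spec.group_id, serum)] = truth
            top, bottom, slope, ec50 = truth
            for ind in group.individuals:
                for d in cfg.dilutions:
                    mu = bottom + (top - bottom) / (1.0 + 10.0 ** (slope * np.log10(ec50 / d)))
                    noise = rng_bcell.normal(0.0, cfg.bcell_noise_sd) if cfg.bcell_noise_sd else 0.0
                    ind.titration.append(TitrationPoint(serum, day, d, Particle.AG_PP,
                                                        float(mu + noise)))
                    ctr_noise = rng_bcell.normal(0.0, cfg.bcell_noise_sd) if cfg.bcell_noise_sd else 0.0
                    ind.titration.append(TitrationPoint(serum, day, d, Particle.CTR_PP,
                                                        float(cfg.ctr_pp_level + ctr_noise)))

        # Expression profiles --------------------------------------------
        if cfg.n_genes:
            fold_vec = np.where(planted_mask, spec.expression_fold, 1.0)
            for ind in group.individuals:
                vals = cfg.base_expression * fold_vec
                if cfg.expression_noise_sd:
                    vals = vals * rng_molsig.lognormal(0.0, cfg.expression_noise_sd,
                                                       size=cfg.n_genes)
                ind.expression.append(ExpressionProfile(
                    cfg.organ, cfg.cell_type, cfg.platform,
                    dict(zip(gene_ids, map(float, vals)))))

        # Challenge outcomes ---------------------------------------------
        surv = list(spec.survival) if spec.survival else [1.0] * len(cfg.challenge_days)
        if len(surv) != len(cfg.challenge_days):
            raise ValidationError(
                f"group {spec.group_id!r}: survival curve length differs from "
                "the challenge observation days"
            )
        survival_expected[spec.group_id] = surv
        if cfg.challenge_stochastic:
            thresholds = rng_chal.uniform(0.0, 1.0, size=n)
        else:
            # deterministic quantile placement: realized proportions match the
            # configured curve as closely as a group of n individuals can
            thresholds = (np.arange(n) + 0.5) / n
        realized = []
        for k, day in enumerate(cfg.challenge_days):
            alive_flags = thresholds < surv[k]
            realized.append(float(alive_flags.mean()))
            for ind, alive in zip(group.individuals, alive_flags):
                ind.challenge.append(ChallengeOutcome(day=day, alive=bool(alive)))
        survival_realized[spec.group_id] = realized
        for ind in group.individuals:
            ind.set_challenge(ind.challenge)

    truth = GroundTruth(
        config=cfg,
        tcell_expected=tcell_expected,
        bcell_truth=bcell_truth,
        planted_genes=planted,
        survival_expected=survival_expected,
        survival_realized=survival_realized,
    )
    return SynthBundle(store=store, experiment=exp, truth=truth)
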