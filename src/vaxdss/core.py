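"""Standardized domain model for immunization experiments.

An *experiment* is the basic assessment unit: it groups uniform individuals
into typed experimental groups (experimental vaccine, naive/control, negative
control, internal standard), each immunized following a declared protocol.
Experiment-level default attributes (animal model, sex, age) are inherited by
groups and individuals unless explicitly overridden.

Every mutating edit bumps an integer revision *stamp* on the experiment and
resets its quality status to not-checked; generated data-entry templates carry
the stamp at generation time so stale templates can be rejected on import.
"""

from __future__ import annotations

import copy
import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Callable, Iterable, Mapping


class VaxError(Exception):
    """Base class for all domain errors."""


class ValidationError(VaxError):
    """An entity violates one of its structural invariants."""


class DuplicateIdError(VaxError):
    pass


class UnknownIdError(VaxError):
    pass


class StaleTemplateError(VaxError):
    """A template generated before the most recent experiment revision."""


class GroupType(str, Enum):
    """Role of an experimental group within an experiment.

    ``OTHER`` completes the five-way typing; it is stored and reported but
    excluded from all normalization and evaluation arithmetic.
    """

    EXPERIMENTAL_VACCINE = "EXPERIMENTAL_VACCINE"
    NAIVE_CONTROL = "NAIVE_CONTROL"
    NEGATIVE_CONTROL = "NEGATIVE_CONTROL"
    INTERNAL_STANDARD = "INTERNAL_STANDARD"
    OTHER = "OTHER"


class QualityStatus(str, Enum):
    """Quality state of an experiment or group.

    NC not checked, R rejected, P pending (manual decision required),
    U user-validated, A auto-validated.  A and U mean "valid, analyzable".
    """

    NC = "NC"
    R = "R"
    P = "P"
    U = "U"
    A = "A"


#: Statuses treated as validated / ready for analysis.
VALIDATED_STATUSES = frozenset({QualityStatus.A, QualityStatus.U})

#: Experiment readiness flags (see :mod:`vaxdss.qc`).
E_READY = "E_READY"
EC_READY = "EC_READY"


class Particle(str, Enum):
    """Pseudoparticle used in a neutralization assay.

    AG_PP carries the vaccine antigen; CTR_PP is the antigen-irrelevant
    control gauging assay specificity.
    """

    AG_PP = "AG_PP"
    CTR_PP = "CTR_PP"


#: The four monitored T-cell response parameters, all on a 0-100 % scale.
TCELL_PARAMETERS = (
    "expansion_pct",
    "memory_pct",
    "ctl_activation_pct",
    "cytotoxicity_pct",
)

#: Readouts a challenge protocol may track.
CHALLENGE_READOUTS = frozenset({"viremia", "tcell_response", "bcell_response", "survival"})


# ---------------------------------------------------------------------------
# Dictionaries: vector hierarchy, vectors, protocols
# ---------------------------------------------------------------------------


class VectorCategoryNode:
    """Node of the vaccine-vector category tree (acyclic, sibling-unique names)."""

    def __init__(self, name: str, parent: "VectorCategoryNode | None" = None):
        if not name:
            raise ValidationError("category name must be non-empty")
        self.name = name
        self.parent = parent
        self.children: list[VectorCategoryNode] = []
        if parent is not None:
            parent._attach(self)

    def _attach(self, child: "VectorCategoryNode") -> None:
        if any(c.name == child.name for c in self.children):
            raise ValidationError(
                f"sibling category named {child.name!r} already exists under {self.name!r}"
            )
        node: VectorCategoryNode | None = self
        while node is not None:
            if node is child:
                raise ValidationError("category tree must stay acyclic")
            node = node.parent
        self.children.append(child)

    def add_child(self, name: str) -> "VectorCategoryNode":
        return VectorCategoryNode(name, parent=self)

    def path(self) -> list[str]:
        names: list[str] = []
        node: VectorCategoryNode | None = self
        while node is not None:
            names.append(node.name)
            node = node.parent
        return names[::-1]

    def find(self, path: Iterable[str]) -> "VectorCategoryNode | None":
        """Resolve ``path`` (excluding this root's own name) to a descendant."""
        node = self
        for name in path:
            nxt = next((c for c in node.children if c.name == name), None)
            if nxt is None:
                return None
            node = nxt
        return node

    def to_dict(self) -> dict:
        return {"name": self.name, "children": [c.to_dict() for c in self.children]}

    @classmethod
    def from_dict(cls, data: Mapping, parent: "VectorCategoryNode | None" = None):
        node = cls(data["name"], parent=parent)
        for child in data.get("children", []):
            cls.from_dict(child, parent=node)
        return node


@dataclass
class VectorRecord:
    """A vaccine vector with its standardized description."""

    id: str
    name: str
    category_path: list[str] = field(default_factory=list)
    producer: str = ""
    production_type: str = ""
    antigen: str = ""
    expected_response_type: str = ""

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "name": self.name,
            "category_path": list(self.category_path),
            "producer": self.producer,
            "production_type": self.production_type,
            "antigen": self.antigen,
            "expected_response_type": self.expected_response_type,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "VectorRecord":
        return cls(**dict(d))


@dataclass
class Inoculation:
    """One inoculation stage: schedule day, vector, dose and route."""

    day: int
    vector_id: str
    dose: float = 1.0
    dose_unit: str = ""
    route: str = ""

    def __post_init__(self):
        if self.day < 0:
            raise ValidationError("inoculation day must be >= 0")
        if self.dose <= 0:
            raise ValidationError("dose must be positive")

    def to_dict(self) -> dict:
        return {
            "day": int(self.day),
            "vector_id": self.vector_id,
            "dose": float(self.dose),
            "dose_unit": self.dose_unit,
            "route": self.route,
        }


@dataclass
class ImmunizationProtocol:
    """An ordered inoculation schedule; day 0 is the first inoculation.

    The schedule is canonically shifted so the earliest inoculation sits at
    day 0, and stable-sorted by day (same-day inoculations keep input order).
    """

    id: str
    name: str
    inoculations: list[Inoculation]

    def __post_init__(self):
        if not self.inoculations:
            raise ValidationError("immunization protocol needs at least one inoculation")
        shift = min(i.day for i in self.inoculations)
        if shift:
            self.inoculations = [
                Inoculation(i.day - shift, i.vector_id, i.dose, i.dose_unit, i.route)
                for i in self.inoculations
            ]
        self.inoculations = sorted(self.inoculations, key=lambda i: i.day)

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "name": self.name,
            "inoculations": [i.to_dict() for i in self.inoculations],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ImmunizationProtocol":
        return cls(d["id"], d["name"], [Inoculation(**i) for i in d["inoculations"]])


@dataclass
class ChallengeProtocol:
    """Pathogen challenge schedule: observation days and tracked readouts."""

    id: str
    pathogen: str
    observation_days: list[int]
    tracked_readouts: set[str] = field(default_factory=lambda: {"survival"})

    def __post_init__(self):
        days = list(self.observation_days)
        if not days:
            raise ValidationError("challenge protocol needs observation days")
        if any(d < 0 for d in days):
            raise ValidationError("observation days must be >= 0")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError("observation days must be strictly increasing")
        unknown = set(self.tracked_readouts) - CHALLENGE_READOUTS
        if unknown:
            raise ValidationError(f"unknown challenge readouts: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "pathogen": self.pathogen,
            "observation_days": [int(d) for d in self.observation_days],
            "tracked_readouts": sorted(self.tracked_readouts),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ChallengeProtocol":
        return cls(d["id"], d["pathogen"], list(d["observation_days"]), set(d["tracked_readouts"]))


# ---------------------------------------------------------------------------
# Measurements
# ---------------------------------------------------------------------------


def _check_pct(name: str, value: float | None) -> float | None:
    if value is None:
        return None
    if not (0.0 <= value <= 100.0):
        raise ValidationError(f"{name}={value} outside [0, 100]")
    return float(value)


@dataclass
class TCellMeasurement:
    """T-cell response readout for one individual on one day (percent scales)."""

    day: int
    expansion_pct: float | None = None
    memory_pct: float | None = None
    ctl_activation_pct: float | None = None
    cytotoxicity_pct: float | None = None

    def __post_init__(self):
        for p in TCELL_PARAMETERS:
            setattr(self, p, _check_pct(p, getattr(self, p)))

    def to_dict(self) -> dict:
        return {"day": int(self.day), **{p: getattr(self, p) for p in TCELL_PARAMETERS}}


@dataclass
class TitrationPoint:
    """One serum-titration observation: % neutralization at dilution 1/d."""

    serum_label: str
    day: int
    dilution_factor: float
    particle: Particle
    neutralization_pct: float

    def __post_init__(self):
        if self.dilution_factor <= 0:
            raise ValidationError("dilution factor must be positive")
        self.particle = Particle(self.particle)

    def to_dict(self) -> dict:
        return {
            "serum_label": self.serum_label,
            "day": int(self.day),
            "dilution_factor": float(self.dilution_factor),
            "particle": self.particle.value,
            "neutralization_pct": float(self.neutralization_pct),
        }


@dataclass
class ExpressionProfile:
    """Gene-expression profile of one individual for one organ / cell type."""

    organ: str
    cell_type: str
    platform: str
    values: dict[str, float]

    def __post_init__(self):
        if any(not g for g in self.values):
            raise ValidationError("gene ids must be non-empty")
        bad = [g for g, v in self.values.items() if v < 0]
        if bad:
            raise ValidationError(f"negative expression for genes {bad[:3]}")

    def to_dict(self) -> dict:
        return {
            "organ": self.organ,
            "cell_type": self.cell_type,
            "platform": self.platform,
            "values": {g: float(v) for g, v in sorted(self.values.items())},
        }


@dataclass
class ChallengeOutcome:
    """Survival / viremia record for one individual at one observation day."""

    day: int
    alive: bool
    viremia: float | None = None

    def __post_init__(self):
        if self.viremia is not None and self.viremia < 0:
            raise ValidationError("viremia must be non-negative")

    def to_dict(self) -> dict:
        return {"day": int(self.day), "alive": bool(self.alive), "viremia": self.viremia}


def validate_outcomes(outcomes: Iterable[ChallengeOutcome]) -> list[ChallengeOutcome]:
    """Sort outcomes by day and reject any dead-then-alive sequence."""
    ordered = sorted(outcomes, key=lambda o: o.day)
    dead = False
    for o in ordered:
        if dead and o.alive:
            raise ValidationError(f"individual recorded alive at day {o.day} after death")
        dead = dead or not o.alive
    return ordered


# ---------------------------------------------------------------------------
# Individuals, groups, experiments
# ---------------------------------------------------------------------------

#: Individual attributes that participate in default inheritance.
INHERITABLE_ATTRIBUTES = ("animal_model", "sex", "age", "age_unit")


@dataclass
class Individual:
    id: str
    animal_model: str | None = None
    sex: str | None = None
    age: float | None = None
    age_unit: str | None = None
    tcell: list[TCellMeasurement] = field(default_factory=list)
    titration: list[TitrationPoint] = field(default_factory=list)
    expression: list[ExpressionProfile] = field(default_factory=list)
    challenge: list[ChallengeOutcome] = field(default_factory=list)

    def set_challenge(self, outcomes: Iterable[ChallengeOutcome]) -> None:
        self.challenge = validate_outcomes(outcomes)

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "animal_model": self.animal_model,
            "sex": self.sex,
            "age": self.age,
            "age_unit": self.age_unit,
            "tcell": [m.to_dict() for m in self.tcell],
            "titration": [t.to_dict() for t in self.titration],
            "expression": [e.to_dict() for e in self.expression],
            "challenge": [c.to_dict() for c in self.challenge],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Individual":
        ind = cls(
            id=d["id"],
            animal_model=d.get("animal_model"),
            sex=d.get("sex"),
            age=d.get("age"),
            age_unit=d.get("age_unit"),
            tcell=[TCellMeasurement(**m) for m in d.get("tcell", [])],
            titration=[TitrationPoint(**t) for t in d.get("titration", [])],
            expression=[ExpressionProfile(**e) for e in d.get("expression", [])],
        )
        ind.set_challenge(ChallengeOutcome(**c) for c in d.get("challenge", []))
        return ind


@dataclass
class ExperimentalGroup:
    """A set of uniform individuals immunized following one protocol."""

    id: str
    group_type: GroupType
    immunization_protocol_id: str
    individuals: list[Individual] = field(default_factory=list)
    overrides: dict[str, Any] = field(default_factory=dict)
    quality_status: QualityStatus = QualityStatus.NC

    def __post_init__(self):
        self.group_type = GroupType(self.group_type)
        self.quality_status = QualityStatus(self.quality_status)

    def get_individual(self, individual_id: str) -> Individual:
        for ind in self.individuals:
            if ind.id == individual_id:
                return ind
        raise UnknownIdError(f"no individual {individual_id!r} in group {self.id!r}")

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "group_type": self.group_type.value,
            "immunization_protocol_id": self.immunization_protocol_id,
            "individuals": [i.to_dict() for i in self.individuals],
            "overrides": dict(self.overrides),
            "quality_status": self.quality_status.value,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentalGroup":
        return cls(
            id=d["id"],
            group_type=GroupType(d["group_type"]),
            immunization_protocol_id=d["immunization_protocol_id"],
            individuals=[Individual.from_dict(i) for i in d.get("individuals", [])],
            overrides=dict(d.get("overrides", {})),
            quality_status=QualityStatus(d.get("quality_status", "NC")),
        )


@dataclass
class Experiment:
    """A vaccination experiment: header, defaults, groups and revision stamp."""

    id: str
    laboratory: str
    creator: str
    date: _dt.date
    defaults: dict[str, Any] = field(default_factory=dict)
    groups: list[ExperimentalGroup] = field(default_factory=list)
    stamp: int = 0
    quality_status: QualityStatus = QualityStatus.NC
    flags: set[str] = field(default_factory=set)
    # B-cell prerequisites: serum label -> sampling day, and the dilution grid.
    sera: dict[str, int] = field(default_factory=dict)
    dilutions: list[float] = field(default_factory=list)

    def __post_init__(self):
        if isinstance(self.date, str):
            try:
                self.date = _dt.date.fromisoformat(self.date)
            except ValueError as exc:
                raise ValidationError(f"malformed date {self.date!r}") from exc
        self.quality_status = QualityStatus(self.quality_status)
        bad = set(self.defaults) - set(INHERITABLE_ATTRIBUTES)
        if bad:
            raise ValidationError(f"unknown default attributes {sorted(bad)}")

    def get_group(self, group_id: str) -> ExperimentalGroup:
        for g in self.groups:
            if g.id == group_id:
                return g
        raise UnknownIdError(f"no group {group_id!r} in experiment {self.id!r}")

    def groups_of_type(self, group_type: GroupType) -> list[ExperimentalGroup]:
        return [g for g in self.groups if g.group_type is group_type]

    def resolve_attributes(self, group: ExperimentalGroup, individual: Individual) -> dict:
        """Defaults <- group overrides <- individual-level values."""
        resolved = dict.fromkeys(INHERITABLE_ATTRIBUTES)
        resolved.update({k: v for k, v in self.defaults.items() if v is not None})
        resolved.update({k: v for k, v in group.overrides.items() if v is not None})
        for attr in INHERITABLE_ATTRIBUTES:
            value = getattr(individual, attr)
            if value is not None:
                resolved[attr] = value
        return resolved

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "laboratory": self.laboratory,
            "creator": self.creator,
            "date": self.date.isoformat(),
            "defaults": dict(self.defaults),
            "groups": [g.to_dict() for g in self.groups],
            "stamp": int(self.stamp),
            "quality_status": self.quality_status.value,
            "flags": sorted(self.flags),
            "sera": {k: int(v) for k, v in self.sera.items()},
            "dilutions": [float(d) for d in self.dilutions],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Experiment":
        return cls(
            id=d["id"],
            laboratory=d["laboratory"],
            creator=d["creator"],
            date=d["date"],
            defaults=dict(d.get("defaults", {})),
            groups=[ExperimentalGroup.from_dict(g) for g in d.get("groups", [])],
            stamp=int(d.get("stamp", 0)),
            quality_status=QualityStatus(d.get("quality_status", "NC")),
            flags=set(d.get("flags", [])),
            sera=dict(d.get("sera", {})),
            dilutions=list(d.get("dilutions", [])),
        )


# ---------------------------------------------------------------------------
# Store and operations
# ---------------------------------------------------------------------------


class Store:
    """In-memory registry of dictionaries and experiments.

    Persistence (JSON / SQLite) lives in :mod:`vaxdss.io_store`; the store
    itself only guarantees id uniqueness and referential integrity.
    """

    def __init__(self) -> None:
        self.category_root = VectorCategoryNode("vectors")
        self.vectors: dict[str, VectorRecord] = {}
        self.immunization_protocols: dict[str, ImmunizationProtocol] = {}
        self.challenge_protocols: dict[str, ChallengeProtocol] = {}
        self.experiments: dict[str, Experiment] = {}
        self.gene_lists: dict[str, "GeneList"] = {}

    # -- dictionaries -----------------------------------------------------
    def add_vector(self, vector: VectorRecord) -> VectorRecord:
        if vector.id in self.vectors:
            raise DuplicateIdError(f"vector id {vector.id!r} already used")
        if vector.category_path and self.category_root.find(vector.category_path) is None:
            raise ValidationError(f"category path {vector.category_path} does not resolve")
        self.vectors[vector.id] = vector
        return vector

    def add_immunization_protocol(self, protocol: ImmunizationProtocol) -> ImmunizationProtocol:
        if protocol.id in self.immunization_protocols:
            raise DuplicateIdError(f"protocol id {protocol.id!r} already used")
        unknown = sorted({i.vector_id for i in protocol.inoculations} - set(self.vectors))
        if unknown:
            raise UnknownIdError(f"protocol references unknown vectors {unknown}")
        self.immunization_protocols[protocol.id] = protocol
        return protocol

    def add_challenge_protocol(self, protocol: ChallengeProtocol) -> ChallengeProtocol:
        if protocol.id in self.challenge_protocols:
            raise DuplicateIdError(f"challenge protocol id {protocol.id!r} already used")
        self.challenge_protocols[protocol.id] = protocol
        return protocol

    # -- experiments ------------------------------------------------------
    def create_experiment(
        self,
        id: str,
        laboratory: str,
        creator: str,
        date: str | _dt.date,
        defaults: Mapping[str, Any] | None = None,
        sera: Mapping[str, int] | None = None,
        dilutions: Iterable[float] | None = None,
    ) -> Experiment:
        """Register a new experiment with stamp 0 and status not-checked."""
        if id in self.experiments:
            raise DuplicateIdError(f"experiment id {id!r} already used")
        exp = Experiment(
            id=id,
            laboratory=laboratory,
            creator=creator,
            date=date,
            defaults=dict(defaults or {}),
            sera=dict(sera or {}),
            dilutions=list(dilutions or []),
        )
        self.experiments[id] = exp
        return exp

    def get_experiment(self, experiment_id: str) -> Experiment:
        try:
            return self.experiments[experiment_id]
        except KeyError:
            raise UnknownIdError(f"unknown experiment {experiment_id!r}") from None

    def add_group(
        self,
        experiment: Experiment | str,
        group_id: str,
        group_type: GroupType | str,
        protocol_id: str,
        n_individuals: int,
        overrides: Mapping[str, Any] | None = None,
    ) -> ExperimentalGroup:
        """Add a group of ``n_individuals`` fresh individuals; bumps the stamp."""
        exp = self.get_experiment(experiment) if isinstance(experiment, str) else experiment
        if protocol_id not in self.immunization_protocols:
            raise UnknownIdError(f"unknown immunization protocol {protocol_id!r}")
        if n_individuals < 1:
            raise ValidationError("a group needs at least one individual")
        if any(g.id == group_id for g in exp.groups):
            raise DuplicateIdError(f"group id {group_id!r} already used in {exp.id!r}")
        overrides = dict(overrides or {})
        bad = set(overrides) - set(INHERITABLE_ATTRIBUTES)
        if bad:
            raise ValidationError(f"unknown override attributes {sorted(bad)}")
        group = ExperimentalGroup(
            id=group_id,
            group_type=GroupType(group_type),
            immunization_protocol_id=protocol_id,
            overrides=overrides,
            individuals=[Individual(id=f"{group_id}-I{i + 1}") for i in range(n_individuals)],
        )

        def mutation(e: Experiment) -> None:
            e.groups.append(group)

        self.revise(exp, mutation)
        return group

    def revise(self, experiment: Experiment | str, mutation: Callable[[Experiment], None]) -> Experiment:
        """Apply ``mutation`` as a manual edit: stamp +1, quality back to NC.

        Any revision — including one that rewrites an identical value —
        counts: statuses of the experiment and all groups reset to NC and
        readiness flags are cleared, so QC must be re-run.
        """
        exp = self.get_experiment(experiment) if isinstance(experiment, str) else experiment
        mutation(exp)
        exp.stamp += 1
        exp.quality_status = QualityStatus.NC
        exp.flags.clear()
        for group in exp.groups:
            group.quality_status = QualityStatus.NC
        return exp

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "categories": self.category_root.to_dict(),
            "vectors": [v.to_dict() for v in sorted(self.vectors.values(), key=lambda v: v.id)],
            "immunization_protocols": [
                p.to_dict() for p in sorted(self.immunization_protocols.values(), key=lambda p: p.id)
            ],
            "challenge_protocols": [
                p.to_dict() for p in sorted(self.challenge_protocols.values(), key=lambda p: p.id)
            ],
            "experiments": [e.to_dict() for e in sorted(self.experiments.values(), key=lambda e: e.id)],
            "gene_lists": [g.to_dict() for g in sorted(self.gene_lists.values(), key=lambda g: g.name)],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Store":
        from .molsig import GeneList  # local import to avoid a cycle

        store = cls()
        store.category_root = VectorCategoryNode.from_dict(d.get("categories", {"name": "vectors"}))
        for v in d.get("vectors", []):
            store.vectors[v["id"]] = VectorRecord.from_dict(v)
        for p in d.get("immunization_protocols", []):
            store.immunization_protocols[p["id"]] = ImmunizationProtocol.from_dict(p)
        for p in d.get("challenge_protocols", []):
            store.challenge_protocols[p["id"]] = ChallengeProtocol.from_dict(p)
        for e in d.get("experiments", []):
            store.experiments[e["id"]] = Experiment.from_dict(e)
        for g in d.get("gene_lists", []):
            store.gene_lists[g["name"]] = GeneList.from_dict(g)
        return store

    def copy(self) -> "Store":
        return copy.deepcopy(self)


def protocol_timeline(
    protocol: ImmunizationProtocol | ChallengeProtocol,
) -> list[tuple[int, dict]]:
    """Time-chart events of a protocol, ordered ascending by day.

    Immunization events carry vector/dose/route; challenge events carry the
    tracked readouts.  Same-day inoculations keep their input order.
    """
    if isinstance(protocol, ImmunizationProtocol):
        return [
            (i.day, {"vector_id": i.vector_id, "dose": i.dose, "dose_unit": i.dose_unit, "route": i.route})
            for i in protocol.inoculations
        ]
    if isinstance(protocol, ChallengeProtocol):
        return [(d, {"readouts": sorted(protocol.tracked_readouts)}) for d in protocol.observation_days]
    raise TypeError(f"unsupported protocol type {type(protocol).__name__}")
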