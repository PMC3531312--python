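"""Templates, persistence and report rendering.

Data entry follows a template workflow: the system generates a tabular
skeleton (XLSX, or a directory of CSVs sharing the same schema) with one row
per expected measurement cell and identifiers pre-filled; the user pastes
values in and imports the file back.  Both the template and the experiment
are stamped at generation time; since every manual edit bumps the experiment
stamp, a template older than the experiment is rejected wholesale — no
partial writes from stale files.  Valid rows of a current template are
inserted (re-imported cells replace existing values) and quality control is
triggered automatically.

Persistence is a single-file canonical JSON export, a JSON-lines directory
or a single-file SQLite database, selected by the target path.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .core import (
    ChallengeOutcome,
    ChallengeProtocol,
    Experiment,
    ExpressionProfile,
    GroupType,
    Particle,
    StaleTemplateError,
    Store,
    TCellMeasurement,
    TitrationPoint,
    TCELL_PARAMETERS,
    UnknownIdError,
    ValidationError,
    VaxError,
)
from . import qc as qc_mod

TEMPLATE_MODULES = ("TCELL", "BCELL", "MOLSIG", "CHALLENGE")

_COLUMNS = {
    "TCELL": ["group_id", "individual_id", "day", *TCELL_PARAMETERS],
    "BCELL": ["group_id", "individual_id", "serum_label", "day", "dilution_factor",
              "particle", "neutralization_pct"],
    "MOLSIG": ["group_id", "individual_id", "organ", "cell_type", "platform",
               "gene_id", "value"],
    "CHALLENGE": ["group_id", "individual_id", "day", "alive", "viremia"],
}


@dataclass
class Template:
    """A tabular data-entry skeleton stamped at generation time."""

    module_scope: str
    experiment_id: str
    stamp_at_generation: int
    sheets: dict[str, pd.DataFrame] = field(default_factory=dict)


def generate_template(
    experiment: Experiment,
    module: str,
    days: Iterable[int] | None = None,
    challenge_protocol: ChallengeProtocol | None = None,
    genes: Iterable[str] | None = None,
    organ: str = "",
    cell_type: str = "",
    platform: str = "",
) -> Template:
    """One sheet per group, one row per expected measurement cell.

    T-cell templates need the measurement ``days``; challenge templates take
    their days from the ``challenge_protocol``; expression templates need the
    ``genes`` to be measured.  A B-cell template requires the experiment's
    serum descriptions and dilutions to be declared beforehand.
    """
    module = module.upper()
    if module not in TEMPLATE_MODULES:
        raise VaxError(f"no template for module {module!r}")
    if not experiment.groups:
        raise VaxError("define groups and individuals before generating a template")
    sheets: dict[str, pd.DataFrame] = {}
    cols = _COLUMNS[module]
    for group in experiment.groups:
        rows: list[dict] = []
        if module == "TCELL":
            if days is None:
                raise VaxError("a T-cell template needs the measurement days")
            for ind in group.individuals:
                for day in days:
                    rows.append({"group_id": group.id, "individual_id": ind.id,
                                 "day": int(day)})
        elif module == "BCELL":
            if not experiment.sera or not experiment.dilutions:
                raise VaxError(
                    "declare serum descriptions and dilutions on the experiment "
                    "before generating a B-cell template"
                )
            for ind in group.individuals:
                for serum, day in experiment.sera.items():
                    for d in experiment.dilutions:
                        for particle in (Particle.AG_PP, Particle.CTR_PP):
                            rows.append({
                                "group_id": group.id, "individual_id": ind.id,
                                "serum_label": serum, "day": int(day),
                                "dilution_factor": float(d),
                                "particle": particle.value,
                            })
        elif module == "MOLSIG":
            if genes is None:
                raise VaxError("an expression template needs the gene ids")
            for ind in group.individuals:
                for gene in genes:
                    rows.append({
                        "group_id": group.id, "individual_id": ind.id,
                        "organ": organ, "cell_type": cell_type,
                        "platform": platform, "gene_id": gene,
                    })
        elif module == "CHALLENGE":
            if challenge_protocol is None:
                raise VaxError("a challenge template needs the challenge protocol")
            for ind in group.individuals:
                for day in challenge_protocol.observation_days:
                    rows.append({"group_id": group.id, "individual_id": ind.id,
                                 "day": int(day)})
        sheets[group.id] = pd.DataFrame(rows).reindex(columns=cols)
    return Template(module, experiment.id, experiment.stamp, sheets)


def write_template(template: Template, path: str | Path) -> Path:
    """Write a template as XLSX (``.xlsx`` path) or a directory of CSVs."""
    path = Path(path)
    meta = {
        "module_scope": template.module_scope,
        "experiment_id": template.experiment_id,
        "stamp_at_generation": template.stamp_at_generation,
    }
    if path.suffix.lower() == ".xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            pd.DataFrame([meta]).to_excel(writer, sheet_name="_meta", index=False)
            for name, df in template.sheets.items():
                df.to_excel(writer, sheet_name=name[:31], index=False)
    else:
        path.mkdir(parents=True, exist_ok=True)
        (path / "_meta.json").write_text(json.dumps(meta, sort_keys=True, indent=1))
        for name, df in template.sheets.items():
            df.to_csv(path / f"{name}.csv", index=False)
    return path


def read_template(path: str | Path) -> Template:
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        book = pd.read_excel(path, sheet_name=None)
        meta = book.pop("_meta").iloc[0].to_dict()
        sheets = book
    else:
        meta = json.loads((path / "_meta.json").read_text())
        sheets = {
            p.stem: pd.read_csv(p) for p in sorted(path.glob("*.csv"))
        }
    return Template(
        module_scope=str(meta["module_scope"]),
        experiment_id=str(meta["experiment_id"]),
        stamp_at_generation=int(meta["stamp_at_generation"]),
        sheets=sheets,
    )


@dataclass
class ImportReport:
    experiment_id: str
    module_scope: str
    inserted: int = 0
    rejected: list[tuple[str, int, str]] = field(default_factory=list)  # sheet, row, reason
    qc_report: "qc_mod.QCReport | None" = None

    def to_dict(self) -> dict:
        return {
            "experiment_id": self.experiment_id,
            "module_scope": self.module_scope,
            "inserted": self.inserted,
            "rejected": [
                {"sheet": s, "row": r, "reason": why} for s, r, why in self.rejected
            ],
            "qc": self.qc_report.to_dict() if self.qc_report else None,
        }


def _to_float(value, column: str) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"non-numeric value {value!r} in column {column!r}") from None


def _insert_tcell(ind, row) -> None:
    day = int(row["day"])
    values = {p: _to_float(row.get(p), p) for p in TCELL_PARAMETERS}
    if all(v is None for v in values.values()):
        raise ValidationError("row carries no measurement values")
    probe = TCellMeasurement(day=day, **values)  # validates percent ranges
    existing = next((m for m in ind.tcell if m.day == day), None)
    if existing is None:
        ind.tcell.append(probe)
    else:  # replace semantics for re-imported cells
        for p, v in values.items():
            if v is not None:
                setattr(existing, p, v)


def _insert_bcell(ind, row) -> None:
    value = _to_float(row.get("neutralization_pct"), "neutralization_pct")
    if value is None:
        raise ValidationError("row carries no measurement values")
    point = TitrationPoint(
        serum_label=str(row["serum_label"]),
        day=int(row["day"]),
        dilution_factor=float(row["dilution_factor"]),
        particle=Particle(str(row["particle"])),
        neutralization_pct=value,
    )
    ind.titration = [
        p for p in ind.titration
        if not (p.serum_label == point.serum_label and p.day == point.day
                and p.dilution_factor == point.dilution_factor
                and p.particle is point.particle)
    ]
    ind.titration.append(point)


def _insert_molsig(ind, row) -> None:
    value = _to_float(row.get("value"), "value")
    if value is None:
        raise ValidationError("row carries no measurement values")
    organ, cell_type = str(row["organ"]), str(row["cell_type"])
    platform = str(row.get("platform", ""))
    profile = next(
        (p for p in ind.expression if p.organ == organ and p.cell_type == cell_type),
        None,
    )
    if profile is None:
        profile = ExpressionProfile(organ, cell_type, platform, {})
        ind.expression.append(profile)
    if value < 0:
        raise ValidationError(f"negative expression value {value}")
    profile.values[str(row["gene_id"])] = value


def _insert_challenge(ind, row) -> None:
    alive_raw = row.get("alive")
    if alive_raw is None or (isinstance(alive_raw, float) and pd.isna(alive_raw)):
        raise ValidationError("row carries no measurement values")
    token = str(alive_raw).strip().lower()
    if token in ("true", "yes"):
        alive = True
    elif token in ("false", "no"):
        alive = False
    else:
        try:
            numeric = float(token)
        except ValueError:
            raise ValidationError(f"alive must be 0/1, got {alive_raw!r}") from None
        if numeric not in (0.0, 1.0):
            raise ValidationError(f"alive must be 0/1, got {alive_raw!r}")
        alive = bool(numeric)
    viremia = _to_float(row.get("viremia"), "viremia")
    outcome = ChallengeOutcome(day=int(row["day"]), alive=alive, viremia=viremia)
    kept = [o for o in ind.challenge if o.day != outcome.day]
    ind.set_challenge(kept + [outcome])


_INSERTERS = {
    "TCELL": _insert_tcell,
    "BCELL": _insert_bcell,
    "MOLSIG": _insert_molsig,
    "CHALLENGE": _insert_challenge,
}


def import_template(
    template: Template | str | Path,
    store: Store,
    registry: Iterable[qc_mod.QualityRule] | None = None,
    run_quality_control: bool = True,
) -> ImportReport:
    """Validate and insert a filled template; reject stale templates whole.

    A template generated before the experiment's latest revision raises
    :class:`StaleTemplateError` before anything is written.  Otherwise rows
    are validated individually: structurally valid rows are inserted
    (replacing any previous value of the same cell), invalid rows are listed
    with reasons.  Quality control runs automatically afterwards.
    """
    if not isinstance(template, Template):
        template = read_template(template)
    exp = store.get_experiment(template.experiment_id)
    if template.stamp_at_generation < exp.stamp:
        raise StaleTemplateError(
            f"template stamped {template.stamp_at_generation} is older than "
            f"experiment revision {exp.stamp}; regenerate the template"
        )
    inserter = _INSERTERS.get(template.module_scope.upper())
    if inserter is None:
        raise VaxError(f"cannot import module {template.module_scope!r}")

    report = ImportReport(exp.id, template.module_scope)
    for sheet_name, df in template.sheets.items():
        for idx, row in enumerate(df.to_dict("records")):
            try:
                group = exp.get_group(str(row["group_id"]))
                ind = group.get_individual(str(row["individual_id"]))
                inserter(ind, row)
                report.inserted += 1
            except (VaxError, KeyError, TypeError) as exc:
                report.rejected.append((sheet_name, idx, str(exc)))
    if run_quality_control:
        report.qc_report = qc_mod.qc_experiment(exp, registry)
    return report


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def canonical_json(entity) -> str:
    """Stable canonical JSON of any entity exposing ``to_dict``."""
    data = entity.to_dict() if hasattr(entity, "to_dict") else entity
    return json.dumps(data, sort_keys=True, separators=(",", ":"))


def save_store(store: Store, path: str | Path) -> Path:
    """Persist a store: ``.json`` file, ``.sqlite``/``.db`` database, or a
    JSON-lines directory for any other path."""
    path = Path(path)
    suffix = path.suffix.lower()
    data = store.to_dict()
    if suffix == ".json":
        path.write_text(json.dumps(data, sort_keys=True, indent=1))
    elif suffix in (".sqlite", ".db"):
        with sqlite3.connect(path) as con:
            con.execute("DROP TABLE IF EXISTS entities")
            con.execute("CREATE TABLE entities (kind TEXT, id TEXT, body TEXT, PRIMARY KEY (kind, id))")
            con.execute("INSERT INTO entities VALUES ('categories', 'root', ?)",
                        (canonical_json(data["categories"]),))
            for kind in ("vectors", "immunization_protocols", "challenge_protocols",
                         "experiments", "gene_lists"):
                for item in data[kind]:
                    key = item.get("id") or item.get("name")
                    con.execute("INSERT INTO entities VALUES (?, ?, ?)",
                                (kind, key, canonical_json(item)))
    else:
        path.mkdir(parents=True, exist_ok=True)
        (path / "categories.json").write_text(canonical_json(data["categories"]))
        for kind in ("vectors", "immunization_protocols", "challenge_protocols",
                     "experiments", "gene_lists"):
            lines = [canonical_json(item) for item in data[kind]]
            (path / f"{kind}.jsonl").write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def load_store(path: str | Path) -> Store:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".json":
        return Store.from_dict(json.loads(path.read_text()))
    if suffix in (".sqlite", ".db"):
        data: dict = {k: [] for k in ("vectors", "immunization_protocols",
                                      "challenge_protocols", "experiments", "gene_lists")}
        with sqlite3.connect(path) as con:
            for kind, _key, body in con.execute("SELECT kind, id, body FROM entities ORDER BY kind, id"):
                if kind == "categories":
                    data["categories"] = json.loads(body)
                else:
                    data[kind].append(json.loads(body))
        return Store.from_dict(data)
    data = {"categories": json.loads((path / "categories.json").read_text())}
    for kind in ("vectors", "immunization_protocols", "challenge_protocols",
                 "experiments", "gene_lists"):
        f = path / f"{kind}.jsonl"
        data[kind] = [json.loads(line) for line in f.read_text().splitlines() if line] if f.exists() else []
    return Store.from_dict(data)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

REPORT_SECTIONS = ("qc", "tcell", "bcell", "molsig", "challenge", "evaluation")


def render_report(
    experiment: Experiment,
    sections: Iterable[str] = REPORT_SECTIONS,
    challenge_protocol: ChallengeProtocol | None = None,
    registry: Iterable[qc_mod.QualityRule] | None = None,
    organ: str = "spleen",
    cell_type: str = "dendritic",
    molsig_threshold: float = 2.0,
) -> tuple[str, dict]:
    """Deterministic text + JSON report over the requested sections.

    Sections whose inputs are absent are annotated rather than failing.
    """
    from . import bcell as bcell_mod, challenge as challenge_mod
    from . import evaluation as eval_mod, molsig as molsig_mod, tcell as tcell_mod

    sections = [s.lower() for s in sections]
    unknown = set(sections) - set(REPORT_SECTIONS)
    if unknown:
        raise VaxError(f"unknown report sections {sorted(unknown)}")
    doc: dict = {"experiment": experiment.id, "stamp": experiment.stamp,
                 "status": experiment.quality_status.value, "flags": sorted(experiment.flags)}
    lines = [f"Report for experiment {experiment.id} (stamp {experiment.stamp}, "
             f"status {experiment.quality_status.value}, flags {sorted(experiment.flags)})"]

    if "qc" in sections:
        report = qc_mod.run_qc(experiment, registry)
        doc["qc"] = report.to_dict()
        lines += ["", report.render()]

    if "tcell" in sections:
        try:
            day = max(m.day for g in experiment.groups for i in g.individuals for m in i.tcell)
            normalized = tcell_mod.normalize_vs_naive(experiment, day)
            doc["tcell"] = {
                r.group_id: {p: round(v, 6) for p, v in sorted(r.values.items())}
                for r in normalized
            }
            lines += ["", f"T-cell responses normalized vs naive at day {day}:"]
            for r in normalized:
                vals = ", ".join(f"{p}={v:.2f}" for p, v in sorted(r.values.items()))
                lines.append(f"  {r.group_id}: {vals}")
        except (VaxError, ValueError) as exc:
            doc["tcell"] = {"unavailable": str(exc)}
            lines += ["", f"T-cell section unavailable: {exc}"]

    if "bcell" in sections:
        fits = {}
        for group in experiment.groups:
            for serum in sorted(experiment.sera):
                try:
                    params = bcell_mod.fit_group(experiment, serum, Particle.AG_PP, group.id)
                    fits[f"{group.id}/{serum}"] = {
                        k: round(v, 4) for k, v in params.to_dict().items()
                        if isinstance(v, float)
                    }
                except VaxError:
                    continue
        doc["bcell"] = fits if fits else {"unavailable": "no titration data"}
        lines += ["", "B-cell 4PL fits (antigen pseudoparticles):"]
        for key, p in fits.items():
            lines.append(f"  {key}: EC50={p['ec50']:.1f} top={p['top']:.1f} "
                         f"bottom={p['bottom']:.1f} slope={p['hill_slope']:.2f}")

    if "molsig" in sections:
        try:
            comp = molsig_mod.compare_experiment(experiment, organ, cell_type, molsig_threshold)
            signature = molsig_mod.extract_signature(comp)
            doc["molsig"] = {
                "vaccinated": comp.vaccinated_group_id,
                "control": comp.control_group_id,
                "threshold": comp.threshold,
                "signature_size": len(signature),
                "top_genes": [[g, round(l2, 4)] for g, l2 in signature[:10]],
            }
            lines += ["", f"Molecular signature ({comp.vaccinated_group_id} vs "
                          f"{comp.control_group_id}, threshold {molsig_threshold}): "
                          f"{len(signature)} genes"]
        except VaxError as exc:
            doc["molsig"] = {"unavailable": str(exc)}
            lines += ["", f"Molecular signature section unavailable: {exc}"]

    if "challenge" in sections:
        if challenge_protocol is None:
            doc["challenge"] = {"unavailable": "no challenge protocol supplied"}
            lines += ["", "Challenge section unavailable: no challenge protocol supplied"]
        else:
            curves = {}
            for group in experiment.groups:
                try:
                    c = challenge_mod.survival_curve(group, challenge_protocol)
                    curves[group.id] = dict(zip(map(str, c.days), c.proportion_alive))
                except VaxError:
                    continue
            doc["challenge"] = curves if curves else {"unavailable": "no challenge outcomes"}
            lines += ["", "Challenge survival (proportion alive per day):"]
            for gid, c in curves.items():
                lines.append("  " + gid + ": " + ", ".join(f"d{d}={p:.2f}" for d, p in c.items()))

    if "evaluation" in sections:
        try:
            ctx = eval_mod.EvaluationContext(
                organ=organ, cell_type=cell_type,
                molsig_threshold=molsig_threshold,
                challenge_protocol=challenge_protocol,
            )
            results = [
                eval_mod.evaluate_experiment(experiment, group_id=g.id, context=ctx)
                for g in experiment.groups_of_type(GroupType.EXPERIMENTAL_VACCINE)
            ]
            doc["evaluation"] = [r.to_dict() for r in results]
            lines += ["", eval_mod.render_scorecard(results)]
        except VaxError as exc:
            doc["evaluation"] = {"unavailable": str(exc)}
            lines += ["", f"Evaluation section unavailable: {exc}"]

    return "\n".join(lines) + "\n", doc
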