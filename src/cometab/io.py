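"""Model and diet I/O.

The canonical on-disk format is a documented JSON dialect (metabolites,
reactions, bounds, couplings, objective); SBML Level 3 + fbc is supported
read/write for interoperability (couplings are not part of SBML-fbc and
are carried only by the JSON dialect).  Diets are TSV with columns
``metabolite_id`` and ``flux_mmol_per_person_per_day``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .core import (
    CouplingConstraint,
    DietSpec,
    Metabolite,
    MetabolicModel,
    ModelValidationError,
    Reaction,
)

__all__ = [
    "read_model",
    "write_model",
    "read_diet",
    "write_diet",
]


# ---------------------------------------------------------------------------
# JSON dialect

def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "compartments": sorted(model.compartments),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "charge": m.charge,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "subsystem": r.subsystem,
                "gene_ids": r.gene_ids,
            }
            for r in model.reactions.values()
        ],
        "couplings": [
            {
                "reaction": c.coupled_reaction_id,
                "anchor": c.anchor_reaction_id,
                "factor": c.factor,
            }
            for c in model.couplings
        ],
        "objective": model.objective_id,
    }


def _model_from_dict(d: dict) -> MetabolicModel:
    model = MetabolicModel(id=d.get("id", "model"))
    model.compartments = set(d.get("compartments", []))
    try:
        for m in d["metabolites"]:
            model.add_metabolite(
                Metabolite(
                    id=m["id"],
                    name=m.get("name", ""),
                    compartment=m.get("compartment", ""),
                    formula=m.get("formula"),
                    charge=m.get("charge"),
                )
            )
        declared = set(model.metabolites)
        for r in d["reactions"]:
            missing = set(r["stoichiometry"]) - declared
            if missing:
                raise ModelValidationError(
                    f"reaction {r['id']!r}: dangling metabolite reference(s) {sorted(missing)}"
                )
            model.add_reaction(
                Reaction(
                    id=r["id"],
                    stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                    lower_bound=float(r.get("lower_bound", 0.0)),
                    upper_bound=float(r.get("upper_bound", 1000.0)),
                    subsystem=r.get("subsystem"),
                    gene_ids=list(r.get("gene_ids", [])),
                )
            )
    except KeyError as exc:
        raise ModelValidationError(f"malformed model JSON: missing key {exc}") from exc
    for c in d.get("couplings", []):
        model.couplings.append(
            CouplingConstraint(
                coupled_reaction_id=c["reaction"],
                anchor_reaction_id=c["anchor"],
                factor=float(c.get("factor", 400.0)),
            )
        )
    model.objective_id = d.get("objective")
    model.validate()
    return model


# ---------------------------------------------------------------------------
# SBML L3 + fbc

def _write_sbml(model: MetabolicModel, path: str) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sanitize(model.id))
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    for comp in sorted(model.compartments):
        c = sm.createCompartment()
        c.setId(_sanitize(comp))
        c.setConstant(True)

    for met in model.metabolites.values():
        s = sm.createSpecies()
        s.setId(_sanitize(met.id))
        s.setName(met.name or met.id)
        s.setCompartment(_sanitize(met.compartment))
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)

    bound_ids: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_ids:
            pid = f"fb_{len(bound_ids)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_ids[value] = pid
        return bound_ids[value]

    for rxn in model.reactions.values():
        r = sm.createReaction()
        r.setId(_sanitize(rxn.id))
        r.setReversible(rxn.lower_bound < 0)
        r.setFast(False)
        for mid, coef in rxn.stoichiometry.items():
            ref = r.createReactant() if coef < 0 else r.createProduct()
            ref.setSpecies(_sanitize(mid))
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(_bound_param(rxn.upper_bound))

    if model.objective_id is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(_sanitize(model.objective_id))
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


_SAN = str.maketrans({"[": "__", "]": "__"})


def _sanitize(sid: str) -> str:
    """SBML SIds cannot contain brackets; map ``for[u]`` -> ``for__u__``."""
    out = sid.translate(_SAN)
    if out and out[0].isdigit():
        out = "_" + out
    return out


def _unsanitize(sid: str) -> str:
    if sid.startswith("_") and len(sid) > 1 and sid[1].isdigit():
        sid = sid[1:]
    if sid.endswith("__"):
        head, _, comp = sid[:-2].rpartition("__")
        if head:
            return f"{head}[{comp}]"
    return sid


def _read_sbml(path: str) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelValidationError(f"SBML parse failure in {path}: {err.getMessage()}")
    sm = doc.getModel()
    if sm is None:
        raise ModelValidationError(f"SBML file {path} contains no model")
    model = MetabolicModel(id=sm.getId() or "model")
    for i in range(sm.getNumCompartments()):
        model.compartments.add(_unsanitize(sm.getCompartment(i).getId()))
    params = {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }
    for i in range(sm.getNumSpecies()):
        s = sm.getSpecies(i)
        model.add_metabolite(
            Metabolite(
                id=_unsanitize(s.getId()),
                name=s.getName(),
                compartment=_unsanitize(s.getCompartment()),
            )
        )
    for i in range(sm.getNumReactions()):
        r = sm.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            mid = _unsanitize(ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            mid = _unsanitize(ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        rplug = r.getPlugin("fbc")
        lb, ub = -1000.0, 1000.0
        if rplug is not None:
            lb = params.get(rplug.getLowerFluxBound(), lb)
            ub = params.get(rplug.getUpperFluxBound(), ub)
        model.add_reaction(
            Reaction(id=_unsanitize(r.getId()), stoichiometry=stoich, lower_bound=lb, upper_bound=ub)
        )
    mplug = sm.getPlugin("fbc")
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getObjective(0)
        if obj.getNumFluxObjectives() > 0:
            model.objective_id = _unsanitize(obj.getFluxObjective(0).getReaction())
    model.validate()
    return model


# ---------------------------------------------------------------------------
# public API

def _infer_format(path: str) -> str:
    suffix = Path(path).suffix.lower()
    return "sbml" if suffix in (".xml", ".sbml") else "json"


def read_model(path: str, format: str | None = None) -> MetabolicModel:
    """Read a model from JSON (canonical dialect) or SBML L3+fbc."""
    fmt = format or _infer_format(path)
    if fmt == "json":
        with open(path) as fh:
            try:
                d = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ModelValidationError(f"JSON parse failure in {path}: {exc}") from exc
        return _model_from_dict(d)
    if fmt == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path: str, format: str | None = None) -> None:
    fmt = format or _infer_format(path)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1, sort_keys=False)
    elif fmt == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


def read_diet(path: str) -> DietSpec:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"metabolite_id", "flux_mmol_per_person_per_day"} <= set(df.columns):
        raise ValueError(
            f"diet table {path} must have columns metabolite_id, flux_mmol_per_person_per_day"
        )
    return DietSpec(
        dict(zip(df["metabolite_id"].astype(str), df["flux_mmol_per_person_per_day"].astype(float)))
    )


def write_diet(diet: DietSpec, path: str) -> None:
    pd.DataFrame(
        {
            "metabolite_id": list(diet.entries),
            "flux_mmol_per_person_per_day": list(diet.entries.values()),
        }
    ).to_csv(path, sep="\t", index=False)
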