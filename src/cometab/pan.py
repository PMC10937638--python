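"""Pan-species reconstructions: the union of strain-level models.

A pan-species model carries every reaction and metabolite present in any
strain of the species, with duplicate reactions merged keeping the
widest bounds (so the pan model's feasible set dominates each strain's).
The pan biomass reaction is, by default, the arithmetic mean of the
strain biomass stoichiometries over the union of precursors, which keeps
growth magnitudes comparable across species; ``biomass_mode="first"``
keeps the first strain's biomass instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import DietSpec, MetabolicModel, ModelValidationError, Reaction, apply_diet, solve_fba

__all__ = ["PanModel", "ViabilityError", "build_pan_model", "check_growth"]

BIOMASS_PREFIX = "biomass"


class ViabilityError(RuntimeError):
    """A pan-species model cannot grow under the given diet."""


@dataclass
class PanModel:
    species_name: str
    model: MetabolicModel
    source_strain_ids: list[str] = field(default_factory=list)
    biomass_id: str = ""


def _find_biomass(model: MetabolicModel) -> str:
    hits = sorted(r for r in model.reactions if r.startswith(BIOMASS_PREFIX))
    if not hits:
        raise ModelValidationError(f"strain {model.id!r} has no biomass reaction ('{BIOMASS_PREFIX}*')")
    return hits[0]


def build_pan_model(
    strain_models: list[MetabolicModel],
    species_name: str,
    biomass_mode: str = "mean",
) -> PanModel:
    """Union of strain reconstructions of one species.

    Duplicate reaction ids are merged keeping the widest bound interval.
    Strain biomass reactions are replaced by a single designated pan
    biomass (mean stoichiometry over the union of precursors; an absent
    precursor contributes 0), so the pan model has exactly one biomass.
    """
    if not strain_models:
        raise ValueError("build_pan_model needs at least one strain model")
    if biomass_mode not in ("mean", "first"):
        raise ValueError("biomass_mode must be 'mean' or 'first'")

    strain_biomass = [_find_biomass(s) for s in strain_models]
    pan = MetabolicModel(id=f"pan_{species_name}")
    for strain in strain_models:
        for met in strain.metabolites.values():
            if met.id not in pan.metabolites:
                pan.add_metabolite(type(met)(**vars(met)))
    for strain, bid in zip(strain_models, strain_biomass):
        for rxn in strain.reactions.values():
            if rxn.id == bid:
                continue
            if rxn.id in pan.reactions:
                have = pan.reactions[rxn.id]
                have.lower_bound = min(have.lower_bound, rxn.lower_bound)
                have.upper_bound = max(have.upper_bound, rxn.upper_bound)
            else:
                pan.add_reaction(
                    Reaction(
                        id=rxn.id,
                        stoichiometry=dict(rxn.stoichiometry),
                        lower_bound=rxn.lower_bound,
                        upper_bound=rxn.upper_bound,
                        subsystem=rxn.subsystem,
                        gene_ids=list(rxn.gene_ids),
                    )
                )

    # designated pan biomass
    ids = set(strain_biomass)
    pan_biomass_id = strain_biomass[0] if len(ids) == 1 else f"{BIOMASS_PREFIX}_{species_name}"
    if biomass_mode == "first" or len(strain_models) == 1:
        src = strain_models[0].reactions[strain_biomass[0]]
        stoich = dict(src.stoichiometry)
        lb, ub = src.lower_bound, src.upper_bound
    else:
        precursors: set[str] = set()
        for strain, bid in zip(strain_models, strain_biomass):
            precursors |= set(strain.reactions[bid].stoichiometry)
        stoich = {
            mid: sum(
                strain.reactions[bid].stoichiometry.get(mid, 0.0)
                for strain, bid in zip(strain_models, strain_biomass)
            )
            / len(strain_models)
            for mid in sorted(precursors)
        }
        lb = min(s.reactions[b].lower_bound for s, b in zip(strain_models, strain_biomass))
        ub = max(s.reactions[b].upper_bound for s, b in zip(strain_models, strain_biomass))
    pan.add_reaction(Reaction(id=pan_biomass_id, stoichiometry=stoich, lower_bound=lb, upper_bound=ub))
    pan.objective_id = pan_biomass_id
    pan.validate()
    return PanModel(
        species_name=species_name,
        model=pan,
        source_strain_ids=[s.id for s in strain_models],
        biomass_id=pan_biomass_id,
    )


def check_growth(pan: PanModel, diet: DietSpec, min_growth: float = 1e-6) -> float:
    """Max biomass flux under the diet; raises ViabilityError if below threshold."""
    constrained = apply_diet(pan.model, diet)
    out = solve_fba(constrained, pan.biomass_id, "max")
    if out.status != "optimal" or out.objective_value < min_growth:
        grown = "infeasible" if out.status != "optimal" else f"{out.objective_value:.3g}"
        raise ViabilityError(
            f"pan-species model {pan.species_name!r} cannot grow under the diet "
            f"(max biomass {grown} < {min_growth})"
        )
    return float(out.objective_value)
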