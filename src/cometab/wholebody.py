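"""Attaching microbiome communities to a whole-body-style host model.

The community's own diet/faecal plumbing is removed and every metabolite
shared between the microbial lumen ``luM`` and the host's
large-intestinal lumen ``luLI`` gets exactly one reversible *bridge*
reaction (written luM -> luLI, positive = microbe-to-host).  Diet then
enters exclusively through the host's dietary exchanges.  The germ-free
host is simply the bare :class:`HostModel`.

In attached mode the community biomass lower bound is relaxed to 0 by
default, so the microbiome can always be idled and the personalised
urine maximum dominates the germ-free one; the original community
biomass bounds can be kept via ``keep_biomass_bounds=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .community import CommunityModel
from .core import (
    DietSpec,
    MetabolicModel,
    ModelValidationError,
    Reaction,
    apply_diet,
    solve_fba,
    split_met_id,
)

__all__ = [
    "HostModel",
    "HostMicrobiomeModel",
    "attach_community",
    "max_urine_secretion",
    "microbial_secretion_flux",
    "bridge_id",
]

BRIDGE_BOUND = 1e4


def bridge_id(base: str) -> str:
    return f"Bridge_{base}"


@dataclass
class HostModel:
    model: MetabolicModel
    sex: str = "male"

    def __post_init__(self) -> None:
        if not self.model.exchange_ids("u"):
            raise ModelValidationError(f"host {self.model.id!r} has no urine exchange")


@dataclass
class HostMicrobiomeModel:
    host: HostModel
    community: CommunityModel
    model: MetabolicModel = None  # assembled joint model
    bridges: dict[str, str] = field(default_factory=dict)  # base -> reaction id

    @property
    def sex(self) -> str:
        return self.host.sex


def attach_community(
    host: HostModel,
    community: CommunityModel,
    keep_biomass_bounds: bool = False,
) -> HostMicrobiomeModel:
    """Embed a community model in the host's large-intestinal lumen."""
    if "luLI" not in host.model.compartments:
        raise ModelValidationError(f"host {host.model.id!r} lacks a luLI compartment")
    joint = host.model.copy()
    com = community.model

    strip_prefixes = ("DUt_", "UFEt_")

    def _kept(rid: str, rxn) -> bool:
        if rxn.is_exchange:
            (mid,) = rxn.stoichiometry
            if split_met_id(mid)[1] in ("d", "fe"):
                return False  # community plumbing replaced by bridges
        return not any(rid.startswith(p) for p in strip_prefixes)

    kept_rxns = {rid: rxn for rid, rxn in com.reactions.items() if _kept(rid, rxn)}
    kept_mets = {
        mid for mid, met in com.metabolites.items() if met.compartment not in ("d", "fe")
    }
    collisions = (set(kept_rxns) & set(joint.reactions)) | (kept_mets & set(joint.metabolites))
    if collisions:
        raise ModelValidationError(f"id collisions between host and community: {sorted(collisions)}")

    for rid, rxn in kept_rxns.items():
        joint.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=dict(rxn.stoichiometry),
                lower_bound=rxn.lower_bound,
                upper_bound=rxn.upper_bound,
                subsystem=rxn.subsystem,
                gene_ids=list(rxn.gene_ids),
            )
        )
    # prune community metabolites that lost all their reactions (d/fe sides)
    joint.compartments |= com.compartments - {"d", "fe"} | {"luM"}
    for met in com.metabolites.values():
        if met.id not in joint.metabolites and met.compartment not in ("d", "fe"):
            joint.add_metabolite(type(met)(**vars(met)))
    joint.couplings = list(joint.couplings) + list(com.couplings)

    bridges: dict[str, str] = {}
    for mid in list(joint.metabolites):
        base, comp = split_met_id(mid)
        if comp != "luM":
            continue
        counterpart = f"{base}[luLI]"
        if counterpart in joint.metabolites:
            bid = bridge_id(base)
            joint.add_reaction(
                Reaction(bid, {mid: -1.0, counterpart: 1.0}, -BRIDGE_BOUND, BRIDGE_BOUND)
            )
            bridges[base] = bid

    if not keep_biomass_bounds:
        joint.reactions[community.community_biomass_id].lower_bound = 0.0
    joint.validate()
    return HostMicrobiomeModel(host=host, community=community, model=joint, bridges=bridges)


def _resolve_model(m) -> MetabolicModel:
    if isinstance(m, HostMicrobiomeModel):
        return m.model
    if isinstance(m, HostModel):
        return m.model
    raise TypeError(f"expected HostModel or HostMicrobiomeModel, got {type(m).__name__}")


def max_urine_secretion(m, metabolite_base: str, diet: DietSpec) -> float:
    """Maximum urine exchange flux of a metabolite under a diet.

    Pass a bare :class:`HostModel` for the germ-free value.
    """
    model = _resolve_model(m)
    rid = f"EX_{metabolite_base}[u]"
    if rid not in model.reactions:
        raise KeyError(f"no urine exchange {rid!r} in model {model.id!r}")
    constrained = apply_diet(model, diet, compartment="d")
    out = solve_fba(constrained, rid, "max")
    if out.status != "optimal":
        raise RuntimeError(f"urine maximisation for {metabolite_base!r} ended {out.status}")
    return float(out.objective_value)


def microbial_secretion_flux(m: HostMicrobiomeModel, metabolite_base: str, diet: DietSpec) -> float:
    """Maximal microbe-to-host transfer of a metabolite (nonnegative).

    Optimises the luM->luLI bridge reaction in the microbe-to-host
    direction and reports the magnitude.
    """
    if not isinstance(m, HostMicrobiomeModel):
        raise TypeError("microbial secretion requires an attached host-microbiome model")
    if metabolite_base not in m.bridges:
        raise KeyError(f"no lumen bridge for metabolite {metabolite_base!r}")
    constrained = apply_diet(m.model, diet, compartment="d")
    out = solve_fba(constrained, m.bridges[metabolite_base], "max")
    if out.status != "optimal":
        raise RuntimeError(f"bridge maximisation for {metabolite_base!r} ended {out.status}")
    return max(0.0, float(out.objective_value))
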