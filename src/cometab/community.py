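"""Per-sample microbiome community models.

Each member pan-species model is embedded with a species tag on all of
its reaction/metabolite ids; its extracellular exchanges are rewired
into reversible transfer reactions against a shared lumen compartment
``luM``, which is in turn connected to a diet compartment ``d`` (uptake)
and a faecal compartment ``fe`` (secretion).  Every member reaction is
coupled to that member's biomass with a community coupling factor
(default 400), so a species can only carry flux when it grows, and an
abundance-weighted community biomass reaction consumes the member
biomass metabolites with coefficients equal to the relative abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    CouplingConstraint,
    DietSpec,
    FVAOutcome,
    InfeasibleModelError,
    Metabolite,
    MetabolicModel,
    Reaction,
    apply_diet,
    run_fva,
    split_met_id,
)
from .pan import PanModel

__all__ = ["CommunityMember", "CommunityModel", "build_community", "secretion_profile"]

TRANSFER_BOUND = 1e4
COMMUNITY_BIOMASS_ID = "communityBiomass"


@dataclass
class CommunityMember:
    species_name: str
    abundance: float
    tag: str
    biomass_id: str = ""
    biomass_met: str = ""


@dataclass
class CommunityModel:
    model: MetabolicModel
    members: list[CommunityMember] = field(default_factory=list)
    community_biomass_id: str = COMMUNITY_BIOMASS_ID
    biomass_bounds: tuple[float, float] = (0.4, 1.0)

    @property
    def sample_id(self) -> str:
        return self.model.id

    def faecal_exchange_ids(self) -> list[str]:
        return self.model.exchange_ids("fe")

    def member_reaction_ids(self, species_name: str) -> list[str]:
        member = next(m for m in self.members if m.species_name == species_name)
        return [r for r in self.model.reactions if r.startswith(member.tag)]


def _tag_met(tag: str, mid: str) -> str:
    return f"{tag}{mid}"


def build_community(
    pans: list[PanModel] | dict[str, PanModel],
    abundances: dict[str, float],
    coupling_factor: float = 400.0,
    biomass_bounds: tuple[float, float] = (0.4, 1.0),
    sample_id: str = "community",
    transfer_bound: float = TRANSFER_BOUND,
) -> CommunityModel:
    """Assemble a community model from pan models and relative abundances."""
    if isinstance(pans, list):
        pans = {p.species_name: p for p in pans}
    if len(set(abundances)) != len(abundances):  # dict keys are unique by construction
        raise ValueError("duplicate species in abundances")
    missing = [s for s in abundances if s not in pans]
    if missing:
        raise ValueError(f"species with abundance but no pan model: {missing}")
    vals = list(abundances.values())
    if any(a <= 0 for a in vals):
        raise ValueError("abundances must be positive")
    total = sum(vals)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"abundances sum to {total}, not 1 (tolerance 1e-6)")
    abundances = {s: a / total for s, a in abundances.items()}

    com = MetabolicModel(id=sample_id)
    com.compartments |= {"d", "luM", "fe"}
    members: list[CommunityMember] = []
    lumen_bases: set[str] = set()

    for species in sorted(abundances):
        pan = pans[species]
        tag = f"{species}__"
        member = CommunityMember(species_name=species, abundance=abundances[species], tag=tag)
        src = pan.model

        for met in src.metabolites.values():
            com.add_metabolite(
                Metabolite(
                    id=_tag_met(tag, met.id),
                    name=met.name,
                    compartment=met.compartment,
                    formula=met.formula,
                    charge=met.charge,
                )
            )
            com.compartments.add(met.compartment)

        member_rxns: list[str] = []
        for rxn in src.reactions.values():
            if rxn.is_exchange:
                (mid,) = rxn.stoichiometry
                base, comp = split_met_id(mid)
                if comp == "e":
                    # rewired below into a lumen transfer
                    lumen_bases.add(base)
                    lum = f"{base}[luM]"
                    if lum not in com.metabolites:
                        com.add_metabolite(Metabolite(id=lum, compartment="luM"))
                    tid = f"{tag}IEX_{base}"
                    com.add_reaction(
                        Reaction(
                            id=tid,
                            stoichiometry={_tag_met(tag, mid): -1.0, lum: 1.0},
                            lower_bound=-transfer_bound,
                            upper_bound=transfer_bound,
                        )
                    )
                    member_rxns.append(tid)
                    continue
            rid = f"{tag}{rxn.id}"
            com.add_reaction(
                Reaction(
                    id=rid,
                    stoichiometry={_tag_met(tag, m): c for m, c in rxn.stoichiometry.items()},
                    lower_bound=rxn.lower_bound,
                    upper_bound=rxn.upper_bound,
                    subsystem=rxn.subsystem,
                    gene_ids=list(rxn.gene_ids),
                )
            )
            member_rxns.append(rid)

        # member biomass must produce a biomass metabolite for the
        # community biomass reaction to consume
        member.biomass_id = f"{tag}{pan.biomass_id}"
        bio = com.reactions[member.biomass_id]
        bio_met = next(
            (m for m, c in bio.stoichiometry.items() if c > 0 and "biomass" in m.lower()),
            None,
        )
        if bio_met is None:
            bio_met = f"{tag}biomass[c]"
            if bio_met not in com.metabolites:
                com.add_metabolite(Metabolite(id=bio_met, compartment="c"))
            bio.stoichiometry[bio_met] = 1.0
        member.biomass_met = bio_met

        for rid in member_rxns:
            if rid == member.biomass_id:
                continue
            com.couplings.append(
                CouplingConstraint(
                    coupled_reaction_id=rid,
                    anchor_reaction_id=member.biomass_id,
                    factor=coupling_factor,
                )
            )
        members.append(member)

    # shared-lumen plumbing: diet in, faeces out
    for base in sorted(lumen_bases):
        for mid, comp in ((f"{base}[d]", "d"), (f"{base}[fe]", "fe")):
            if mid not in com.metabolites:
                com.add_metabolite(Metabolite(id=mid, compartment=comp))
        com.add_reaction(
            Reaction(f"EX_{base}[d]", {f"{base}[d]": -1.0}, -1000.0, 1000.0)
        )
        com.add_reaction(
            Reaction(f"DUt_{base}", {f"{base}[d]": -1.0, f"{base}[luM]": 1.0}, 0.0, transfer_bound)
        )
        com.add_reaction(
            Reaction(f"UFEt_{base}", {f"{base}[luM]": -1.0, f"{base}[fe]": 1.0}, 0.0, transfer_bound)
        )
        com.add_reaction(
            Reaction(f"EX_{base}[fe]", {f"{base}[fe]": -1.0}, 0.0, 1e6)
        )

    # abundance-weighted community biomass
    stoich = {m.biomass_met: -m.abundance for m in members}
    com.add_reaction(
        Reaction(
            COMMUNITY_BIOMASS_ID,
            stoich,
            lower_bound=biomass_bounds[0],
            upper_bound=biomass_bounds[1],
        )
    )
    com.objective_id = COMMUNITY_BIOMASS_ID
    com.validate()
    return CommunityModel(
        model=com,
        members=members,
        community_biomass_id=COMMUNITY_BIOMASS_ID,
        biomass_bounds=tuple(biomass_bounds),
    )


def secretion_profile(
    community: CommunityModel,
    diet: DietSpec,
    metabolites: list[str] | None = None,
    fix_biomass_at_upper: bool = False,
) -> FVAOutcome:
    """Maximum net secretion capacity over the faecal exchanges (FVA).

    A zero maximum means the community cannot secrete the metabolite
    under the diet.  ``fix_biomass_at_upper`` pins community biomass to
    its upper bound instead of allowing the whole configured range.
    """
    model = apply_diet(community.model, diet, compartment="d")
    if fix_biomass_at_upper:
        bio = model.reactions[community.community_biomass_id]
        bio.lower_bound = bio.upper_bound
    targets = (
        community.faecal_exchange_ids()
        if metabolites is None
        else [f"EX_{b}[fe]" for b in metabolites]
    )
    try:
        return run_fva(model, targets)
    except InfeasibleModelError as exc:
        raise InfeasibleModelError(
            f"community {community.sample_id!r} infeasible under the diet"
        ) from exc
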