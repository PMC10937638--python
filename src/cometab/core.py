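"""Constraint-based metabolic model data structures and LP machinery.

A :class:`MetabolicModel` is a stoichiometric network with bounded
reactions, compartmented metabolites and optional *coupling constraints*
(|v_r| <= c * v_biomass) of the kind used when embedding microbial
reconstructions in community models.  Flux balance analysis (FBA) and
flux variability analysis (FVA) are solved as linear programmes over

    S v = 0,   lb <= v <= ub,   v_r - c v_b <= 0,   v_r + c v_b >= 0

with scipy's HiGHS backend.  All fluxes are carried in mmol/person/day
end-to-end.  Exchange reactions follow the conventional form
``EX_met[comp]: met[comp] <-> ∅`` with negative flux meaning uptake.
"""

from __future__ import annotations

import copy as _copy
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import coo_matrix

__all__ = [
    "Metabolite",
    "Reaction",
    "CouplingConstraint",
    "MetabolicModel",
    "DietSpec",
    "FluxOutcome",
    "FVAOutcome",
    "ModelValidationError",
    "InfeasibleModelError",
    "solve_fba",
    "run_fva",
    "apply_diet",
    "delete_reactions",
    "split_met_id",
]

#: default assertion-level tolerance for mass balance and bound checks
FLUX_TOL = 1e-6

_MET_ID_RE = re.compile(r"^(?P<base>.+)\[(?P<comp>[^\[\]]+)\]$")


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


class InfeasibleModelError(RuntimeError):
    """Raised when an operation requires a feasible model but the LP is not."""


def split_met_id(met_id: str) -> tuple[str, str]:
    """Split ``"base[comp]"`` into ``(base, comp)``.

    >>> split_met_id("for[u]")
    ('for', 'u')
    """
    m = _MET_ID_RE.match(met_id)
    if m is None:
        raise ValueError(f"metabolite id {met_id!r} is not of the form 'base[compartment]'")
    return m.group("base"), m.group("comp")


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: str | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if not self.compartment:
            try:
                self.compartment = split_met_id(self.id)[1]
            except ValueError:
                pass


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    subsystem: str | None = None
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > upper_bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id}: empty stoichiometry")

    @property
    def is_exchange(self) -> bool:
        """Exchange reactions by convention: ``EX_`` prefix, one metabolite."""
        return self.id.startswith("EX_") and len(self.stoichiometry) == 1

    @property
    def is_boundary(self) -> bool:
        """Any single-metabolite boundary reaction (EX_, DM_, sink)."""
        return len(self.stoichiometry) == 1


@dataclass
class CouplingConstraint:
    """Ties a reaction's flux to a biomass (anchor) reaction.

    Encodes v_coupled <= c * v_anchor and v_coupled >= -c * v_anchor, so
    the coupled reaction can only carry flux if the anchor does.
    """

    coupled_reaction_id: str
    anchor_reaction_id: str
    factor: float = 400.0

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ModelValidationError("coupling factor must be positive")


@dataclass
class MetabolicModel:
    id: str
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    couplings: list[CouplingConstraint] = field(default_factory=list)
    objective_id: str | None = None
    compartments: set[str] = field(default_factory=set)
    notes: dict = field(default_factory=dict)

    # -- construction helpers -------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met
        if met.compartment:
            self.compartments.add(met.compartment)
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        for mid in rxn.stoichiometry:
            if mid not in self.metabolites:
                base, comp = split_met_id(mid)
                self.add_metabolite(Metabolite(id=mid, compartment=comp))
        self.reactions[rxn.id] = rxn
        return rxn

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rxn.id}: dangling metabolite reference {mid!r}"
                    )
        for met in self.metabolites.values():
            if not met.compartment:
                raise ModelValidationError(f"metabolite {met.id}: empty compartment tag")
            if self.compartments and met.compartment not in self.compartments:
                raise ModelValidationError(
                    f"metabolite {met.id}: compartment {met.compartment!r} not declared"
                )
        rids = self.reactions.keys()
        for c in self.couplings:
            if c.coupled_reaction_id not in rids or c.anchor_reaction_id not in rids:
                raise ModelValidationError(
                    f"coupling ({c.coupled_reaction_id}, {c.anchor_reaction_id}) "
                    "references a missing reaction"
                )
        if self.objective_id is not None and self.objective_id not in rids:
            raise ModelValidationError(f"objective {self.objective_id!r} not in model")

    # -- matrix view ----------------------------------------------------------

    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    def stoichiometric_matrix(self):
        """Return ``(S, met_ids, rxn_ids)`` with S sparse (mets x rxns)."""
        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        m_index = {m: i for i, m in enumerate(met_ids)}
        rows, cols, vals = [], [], []
        for j, rid in enumerate(rxn_ids):
            for mid, coef in self.reactions[rid].stoichiometry.items():
                rows.append(m_index[mid])
                cols.append(j)
                vals.append(float(coef))
        S = coo_matrix((vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids)))
        return S.tocsr(), met_ids, rxn_ids

    def coupling_matrix(self, rxn_ids: list[str]):
        """Inequality rows G v <= 0 encoding all coupling constraints."""
        idx = {r: j for j, r in enumerate(rxn_ids)}
        rows, cols, vals = [], [], []
        for k, c in enumerate(self.couplings):
            j_r, j_b = idx[c.coupled_reaction_id], idx[c.anchor_reaction_id]
            # v_r - c v_b <= 0
            rows += [2 * k, 2 * k]
            cols += [j_r, j_b]
            vals += [1.0, -c.factor]
            # -v_r - c v_b <= 0
            rows += [2 * k + 1, 2 * k + 1]
            cols += [j_r, j_b]
            vals += [-1.0, -c.factor]
        G = coo_matrix((vals, (rows, cols)), shape=(2 * len(self.couplings), len(rxn_ids)))
        return G.tocsr()

    def exchange_ids(self, compartment: str | None = None) -> list[str]:
        out = []
        for rid, rxn in self.reactions.items():
            if not rxn.is_exchange:
                continue
            if compartment is not None:
                (mid,) = rxn.stoichiometry
                if split_met_id(mid)[1] != compartment:
                    continue
            out.append(rid)
        return out


@dataclass
class DietSpec:
    """Maximal uptake per diet metabolite base id, in mmol/person/day."""

    entries: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.entries.items():
            if v < 0:
                raise ValueError(f"diet entry {k!r}: uptake {v} must be >= 0")

    def with_entry(self, base: str, value: float) -> "DietSpec":
        new = dict(self.entries)
        new[base] = float(value)
        return DietSpec(new)

    def with_bile_acids(self, amount: float = 1.0) -> "DietSpec":
        """Supplement with cholic and chenodeoxycholic acid."""
        return self.with_entry("cholate", amount).with_entry("chenodeoxycholate", amount)


@dataclass
class FluxOutcome:
    status: str  # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)


@dataclass
class FVAOutcome:
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, rid: str) -> tuple[float, float]:
        return self.ranges[rid]


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _lp_arrays(model: MetabolicModel):
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    n = len(rxn_ids)
    bounds = [(model.reactions[r].lower_bound, model.reactions[r].upper_bound) for r in rxn_ids]
    G = model.coupling_matrix(rxn_ids) if model.couplings else None
    return S, G, bounds, rxn_ids


def _solve(model: MetabolicModel, c: np.ndarray, arrays=None) -> tuple[str, np.ndarray | None, list[str]]:
    S, G, bounds, rxn_ids = arrays if arrays is not None else _lp_arrays(model)
    kw = {}
    if G is not None and G.shape[0]:
        kw["A_ub"] = G
        kw["b_ub"] = np.zeros(G.shape[0])
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        **kw,
    )
    status = _STATUS.get(res.status, "numerical")
    if status == "optimal" and res.x is None:  # pragma: no cover - defensive
        status = "numerical"
    return status, (res.x if res.x is not None else None), rxn_ids


def solve_fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    sense: str = "max",
) -> FluxOutcome:
    """Flux balance analysis: optimise one reaction flux over the feasible region.

    Parameters
    ----------
    model : MetabolicModel
    objective_id : reaction id; defaults to ``model.objective_id``.
    sense : ``"max"`` or ``"min"``.
    """
    if objective_id is None:
        objective_id = model.objective_id
    if objective_id is None or objective_id not in model.reactions:
        raise KeyError(f"objective reaction {objective_id!r} not in model {model.id!r}")
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    arrays = _lp_arrays(model)
    rxn_ids = arrays[3]
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective_id)] = -1.0 if sense == "max" else 1.0
    status, x, _ = _solve(model, c, arrays)
    if status != "optimal":
        return FluxOutcome(status=status, objective_value=None)
    fluxes = dict(zip(rxn_ids, x))
    return FluxOutcome(status="optimal", objective_value=float(fluxes[objective_id]), fluxes=fluxes)


def run_fva(model: MetabolicModel, reaction_ids: list[str] | None = None) -> FVAOutcome:
    """Flux variability analysis: [min, max] flux per reaction.

    The feasible region is shaped solely by bounds, mass balance, and
    coupling constraints; no fraction-of-optimum constraint is imposed,
    matching a "maximum net secretion capacity" reading of FVA.
    """
    if reaction_ids is None:
        reaction_ids = model.reaction_ids()
    for rid in reaction_ids:
        if rid not in model.reactions:
            raise KeyError(f"reaction {rid!r} not in model {model.id!r}")
    arrays = _lp_arrays(model)
    rxn_ids = arrays[3]
    # feasibility check before the per-reaction loop
    status, _, _ = _solve(model, np.zeros(len(rxn_ids)), arrays)
    if status != "optimal":
        raise InfeasibleModelError(f"model {model.id!r} is {status}; FVA undefined")
    out = FVAOutcome()
    index = {r: j for j, r in enumerate(rxn_ids)}
    for rid in reaction_ids:
        c = np.zeros(len(rxn_ids))
        c[index[rid]] = 1.0
        st_min, x_min, _ = _solve(model, c, arrays)
        c[index[rid]] = -1.0
        st_max, x_max, _ = _solve(model, c, arrays)
        if st_min == "optimal" and st_max == "optimal":
            out.ranges[rid] = (float(x_min[index[rid]]), float(x_max[index[rid]]))
            out.status[rid] = "optimal"
        else:
            out.ranges[rid] = (np.nan, np.nan)
            out.status[rid] = st_min if st_min != "optimal" else st_max
    return out


def _dietary_compartment(model: MetabolicModel) -> str:
    return "d" if "d" in model.compartments else "e"


def apply_diet(
    model: MetabolicModel,
    diet: DietSpec,
    unlisted_policy: str = "closed",
    compartment: str | None = None,
) -> MetabolicModel:
    """Constrain dietary exchange lower bounds from a diet table.

    For each diet entry ``m -> q`` the exchange ``EX_m[comp]`` gets lower
    bound ``-q`` (uptake-negative convention).  With
    ``unlisted_policy="closed"`` all other dietary exchange uptakes are
    shut (lower bound 0); secretion (upper) bounds are untouched.  Diet
    entries with no matching exchange are skipped with a warning; the
    skipped list is recorded under ``model.notes["diet_skipped"]``.
    """
    if unlisted_policy not in ("closed", "keep"):
        raise ValueError("unlisted_policy must be 'closed' or 'keep'")
    comp = compartment or _dietary_compartment(model)
    new = model.copy()
    dietary = set(new.exchange_ids(comp))
    skipped = []
    touched = set()
    for base, qty in diet.entries.items():
        rid = f"EX_{base}[{comp}]"
        if rid not in dietary:
            skipped.append(base)
            continue
        rxn = new.reactions[rid]
        rxn.lower_bound = -float(qty)
        if rxn.upper_bound < rxn.lower_bound:  # pathological stored bound
            rxn.upper_bound = rxn.lower_bound
        touched.add(rid)
    if unlisted_policy == "closed":
        for rid in dietary - touched:
            rxn = new.reactions[rid]
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    if skipped:
        warnings.warn(
            f"{len(skipped)} diet entr{'y' if len(skipped) == 1 else 'ies'} had no "
            f"matching dietary exchange in model {model.id!r} and were skipped",
            stacklevel=2,
        )
    new.notes = dict(new.notes)
    new.notes["diet_skipped"] = skipped
    return new


def delete_reactions(model: MetabolicModel, ids: list[str]) -> MetabolicModel:
    """Return a copy with both bounds of each listed reaction set to 0.

    Reactions are retained (for indexing) but cannot carry flux.  The
    original model is unchanged.  Unknown ids raise ``KeyError``.
    """
    for rid in ids:
        if rid not in model.reactions:
            raise KeyError(f"reaction {rid!r} not in model {model.id!r}")
    new = model.copy()
    for rid in ids:
        new.reactions[rid].lower_bound = 0.0
        new.reactions[rid].upper_bound = 0.0
    return new
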