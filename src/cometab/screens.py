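"""In-silico experiments on the host-microbiome models.

Three screens quantify where urinary formate (or any urine metabolite)
comes from:

* **co-metabolism decomposition** — the personalised-minus-germ-free
  urine maximum is compared with the community's own secretion of the
  metabolite; any excess implicates other microbially derived
  precursors metabolised by the host;
* **diet supplementation** — candidate microbial metabolites are added
  one at a time to the germ-free diet (default 300 mmol/d) and the
  urine maximum re-solved;
* **reaction deletion** — single knockouts of candidate host reactions,
  the fraction reducing the urine maximum by more than a threshold
  (default 10%), and the smallest deletion set reaching a target
  reduction (default 85%), found by exhaustive smallest-first search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import pandas as pd

from .community import CommunityModel
from .core import DietSpec, FluxOutcome, delete_reactions
from .wholebody import (
    HostMicrobiomeModel,
    HostModel,
    attach_community,
    max_urine_secretion,
    microbial_secretion_flux,
)

__all__ = [
    "DecompositionRecord",
    "ScreenRecord",
    "MinimalSetResult",
    "decompose_contributions",
    "high_secretion_metabolites",
    "diet_supplementation_screen",
    "single_knockout_screen",
    "find_minimal_deletion_set",
    "annotate_reactions_with_genes",
]

_TOL = 1e-6


@dataclass
class DecompositionRecord:
    sample_id: str
    urine_max_personalised: float
    urine_max_germfree: float
    delta: float
    microbial_secretion: float
    co_metabolism_excess: float

    @property
    def has_co_metabolism(self) -> bool:
        return self.co_metabolism_excess > _TOL


@dataclass
class ScreenRecord:
    perturbation_id: str
    baseline: float
    perturbed: float
    percent_change: float | None  # None when baseline ~ 0 (undefined)
    flag: str = ""  # e.g. "not_applicable"


@dataclass
class MinimalSetResult:
    found: bool
    reactions: tuple[str, ...]
    reduction_pct: float | None
    n_evaluated: int
    method: str = "exhaustive"


def _pct_change(baseline: float, perturbed: float) -> float | None:
    if abs(baseline) <= _TOL:
        return None
    return 100.0 * (perturbed - baseline) / baseline


def decompose_contributions(
    host: HostModel,
    community: CommunityModel | HostMicrobiomeModel,
    diet: DietSpec,
    metabolite: str,
    sample_id: str | None = None,
) -> DecompositionRecord:
    """Split the urine maximum into germ-free, direct microbial, and
    co-metabolic contributions (three LP solves)."""
    attached = (
        community
        if isinstance(community, HostMicrobiomeModel)
        else attach_community(host, community)
    )
    try:
        germfree = max_urine_secretion(host, metabolite, diet)
    except RuntimeError as exc:
        raise RuntimeError(f"germ-free solve failed: {exc}") from exc
    try:
        personalised = max_urine_secretion(attached, metabolite, diet)
    except RuntimeError as exc:
        raise RuntimeError(f"personalised solve failed: {exc}") from exc
    try:
        secretion = microbial_secretion_flux(attached, metabolite, diet)
    except KeyError:
        secretion = 0.0  # community cannot even transfer the metabolite
    except RuntimeError as exc:
        raise RuntimeError(f"microbial secretion solve failed: {exc}") from exc
    delta = personalised - germfree
    return DecompositionRecord(
        sample_id=sample_id or attached.community.sample_id,
        urine_max_personalised=personalised,
        urine_max_germfree=germfree,
        delta=delta,
        microbial_secretion=secretion,
        co_metabolism_excess=delta - secretion,
    )


def high_secretion_metabolites(
    flux_solutions: list[FluxOutcome],
    threshold: float = 30.0,
    exclude: str | None = None,
    bridge_prefix: str = "Bridge_",
) -> list[str]:
    """Microbial metabolites whose mean lumen-bridge secretion across the
    given flux solutions exceeds ``threshold`` (mmol/person/day),
    excluding the target metabolite itself."""
    if not flux_solutions:
        raise ValueError("no flux solutions given")
    sums: dict[str, float] = {}
    for sol in flux_solutions:
        for rid, v in sol.fluxes.items():
            if rid.startswith(bridge_prefix):
                sums[rid] = sums.get(rid, 0.0) + v
    out = []
    for rid, total in sums.items():
        base = rid[len(bridge_prefix):]
        if exclude is not None and base == exclude:
            continue
        if total / len(flux_solutions) > threshold:
            out.append(base)
    return sorted(out)


def diet_supplementation_screen(
    host: HostModel,
    diet: DietSpec,
    candidates: list[str],
    metabolite: str,
    bound: float = 300.0,
) -> list[ScreenRecord]:
    """Open each candidate's dietary uptake to ``bound`` mmol/d on the
    germ-free host and re-solve the urine maximum."""
    baseline = max_urine_secretion(host, metabolite, diet)
    records = []
    for cand in candidates:
        rid = f"EX_{cand}[d]"
        if rid not in host.model.reactions:
            records.append(ScreenRecord(cand, baseline, baseline, None, flag="not_applicable"))
            continue
        supplemented = diet.with_entry(cand, max(bound, diet.entries.get(cand, 0.0)))
        perturbed = max_urine_secretion(host, metabolite, supplemented)
        records.append(ScreenRecord(cand, baseline, perturbed, _pct_change(baseline, perturbed)))
    return records


def single_knockout_screen(
    host: HostModel,
    diet: DietSpec,
    candidates: list[str],
    metabolite: str,
    threshold_pct: float = 10.0,
) -> tuple[list[ScreenRecord], list[str]]:
    """Delete each candidate reaction alone; flag reductions beyond the
    threshold.  Returns ``(records, flagged_ids)``."""
    baseline = max_urine_secretion(host, metabolite, diet)
    if baseline <= _TOL:
        raise RuntimeError("knockout screen undefined: baseline urine maximum is zero")
    records, flagged = [], []
    for cand in candidates:
        perturbed_host = HostModel(delete_reactions(host.model, [cand]), host.sex)
        perturbed = max_urine_secretion(perturbed_host, metabolite, diet)
        pct = _pct_change(baseline, perturbed)
        records.append(ScreenRecord(cand, baseline, perturbed, pct))
        if pct is not None and -pct > threshold_pct:
            flagged.append(cand)
    return records, flagged


def find_minimal_deletion_set(
    host: HostModel,
    diet: DietSpec,
    candidates: list[str],
    metabolite: str,
    reduction_target_pct: float = 85.0,
    max_size: int = 6,
    method: str = "auto",
    exhaustive_limit: int = 200_000,
) -> MinimalSetResult:
    """Smallest deletion set reaching the target reduction.

    Exhaustive smallest-first search; among equally small achieving
    sets the lexicographically first (by sorted ids) wins, which is
    what ``itertools.combinations`` over sorted candidates yields.  For
    candidate lists too large to enumerate a greedy heuristic is used
    (and labelled as such in the result).
    """
    if not candidates:
        raise ValueError("no candidate reactions")
    baseline = max_urine_secretion(host, metabolite, diet)
    if baseline <= _TOL:
        raise RuntimeError("deletion-set search undefined: baseline is zero")
    if reduction_target_pct <= 0:
        return MinimalSetResult(True, (), 0.0, 0)
    cand = sorted(candidates)

    def reduction(subset: tuple[str, ...]) -> float:
        perturbed_host = HostModel(delete_reactions(host.model, list(subset)), host.sex)
        val = max_urine_secretion(perturbed_host, metabolite, diet)
        return 100.0 * (baseline - val) / baseline

    n_subsets = sum(comb(len(cand), k) for k in range(1, max_size + 1))
    if method == "auto":
        method = "exhaustive" if n_subsets <= exhaustive_limit else "greedy"

    evaluated = 0
    if method == "exhaustive":
        for size in range(1, max_size + 1):
            for subset in combinations(cand, size):
                evaluated += 1
                red = reduction(subset)
                if red >= reduction_target_pct:
                    return MinimalSetResult(True, subset, red, evaluated)
        return MinimalSetResult(False, (), None, evaluated)

    # greedy heuristic: repeatedly add the single best reaction
    chosen: list[str] = []
    while len(chosen) < max_size:
        best, best_red = None, -1.0
        for c in cand:
            if c in chosen:
                continue
            evaluated += 1
            red = reduction(tuple(chosen + [c]))
            if red > best_red:
                best, best_red = c, red
        chosen.append(best)
        if best_red >= reduction_target_pct:
            return MinimalSetResult(
                True, tuple(sorted(chosen)), best_red, evaluated, method="greedy"
            )
    return MinimalSetResult(False, (), None, evaluated, method="greedy")


def annotate_reactions_with_genes(
    reactions: list[str],
    gene_map: pd.DataFrame,
    association_table: pd.DataFrame,
    flagged_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Join screen reactions to genes and disease-association evidence.

    ``gene_map``: columns ``reaction_id``, ``gene``; ``association_table``:
    columns ``gene``, ``association`` (and optionally ``direction``).
    Returns the annotated per-reaction table and summary counts, incl.
    reactions that are both gene-associated and screen-flagged.
    """
    for df, cols in ((gene_map, {"reaction_id", "gene"}), (association_table, {"gene"})):
        if not cols <= set(df.columns):
            raise ValueError(f"table missing required columns {cols}")
    flagged = set(flagged_ids or [])
    assoc_by_gene = association_table.set_index("gene")
    rows = []
    for rid in reactions:
        genes = gene_map.loc[gene_map["reaction_id"] == rid, "gene"].tolist()
        hits = [g for g in genes if g in assoc_by_gene.index]
        directions = sorted(
            {
                str(assoc_by_gene.loc[g, "direction"])
                for g in hits
                if "direction" in assoc_by_gene.columns
            }
        )
        rows.append(
            {
                "reaction_id": rid,
                "genes": ";".join(genes) if genes else "no gene",
                "associated_genes": ";".join(hits),
                "n_associated_genes": len(hits),
                "direction": ";".join(directions),
                "flagged": rid in flagged,
            }
        )
    table = pd.DataFrame(rows)
    counts = {
        "n_reactions": len(reactions),
        "n_associated": int((table["n_associated_genes"] > 0).sum()),
        "n_associated_and_flagged": int(
            ((table["n_associated_genes"] > 0) & table["flagged"]).sum()
        ),
    }
    return table, counts
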