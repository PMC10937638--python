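"""Seeded generators for every input the pipeline consumes.

The generators emulate, at desk scale, the structure of the real inputs:
fermenting gut strains with species-specific secretion repertoires, a
whole-body-style host carrying the known formate-producing routes, a
two-group gOTU count table with planted compositional shifts, and a
creatinine-normalised urine metabolome with covariate effects and
zero-inflation.  Identical config + seed give byte-identical outputs,
and every generator returns a *truth record* so recovery tests never
re-derive ground truth from generator internals.

Toy host network
----------------
The host contains collapsed analogue reactions for the routes that feed
urinary formate (ids follow the field's VMH naming):

* 3-phosphoglycerate -> serine (``PGCD``, ``PSERT``, ``PSP_L``), with a
  small dietary phosphoserine entry so the phosphatase is the committed
  endpoint of the branch;
* serine/glycine -> one-carbon folate pool -> formate (``SHMT``,
  ``GLYCL``, ``MTHFD``, ``MTHFC``, ``FTHFL``), each step present as a
  cytosolic/mitochondrial isoform pair so no single intermediate
  deletion severs the branch (mirroring isozyme redundancy);
* choline -> betaine -> dimethylglycine -> sarcosine (peroxisomal
  ``SARCOXp``) and methanol, both yielding formaldehyde, which is
  detoxified via S-formylglutathione (``FALDH``/``FALDH2``) and
  hydrolysed to formate by ``SFGTH``;
* tryptophan -> N-formylkynurenine (``TRPO2``) -> formate (``FKYNH``,
  duplicated);
* a methionine-salvage cycle whose degradation step ``DKMPPD`` releases
  formate; the cycle is closed by a transamination consuming ammonium,
  so ammonium acts as a nitrogen-only formate precursor.

The four unique endpoints ``PSP_L``, ``SFGTH``, ``TRPO2``, ``DKMPPD``
jointly control most of the maximal urine formate secretion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import CountTable
from .core import DietSpec, Metabolite, MetabolicModel, Reaction
from .wholebody import HostModel

__all__ = [
    "SynthConfig",
    "species_names",
    "make_toy_strains",
    "make_toy_host",
    "host_diet",
    "community_diet",
    "make_abundance_counts",
    "make_metabolome",
    "HOST_KO_CANDIDATES",
    "SUPPLEMENT_CANDIDATES",
    "PLANTED_MINIMAL_SET",
]

#: reactions implicated in host formate metabolism (screen candidates),
#: including the three organelle transport reactions
HOST_KO_CANDIDATES = [
    "PGCD", "PSERT", "PSP_L",
    "SHMT", "SHMTm", "GLYCL", "GLYCLm",
    "MTHFD", "MTHFDm", "MTHFC", "MTHFCm", "FTHFL", "FTHFLm",
    "CYSCAT", "ORNCAT", "TYRCAT",
    "CHOLOX", "GBDM", "DMGDH", "SARCOXp", "MEOHDH",
    "FALDH", "FALDH2", "SFGTH",
    "TRPO2", "FKYNH", "FKYNH2",
    "MSALV", "DKMPPD", "KMBTA",
    "SARCStp", "GLYtp", "FALDtp",
]

#: microbially secretable metabolites tested as diet supplements
SUPPLEMENT_CANDIDATES = [
    "ser_L", "gly", "trp_L", "cys_L", "tyr_L", "orn", "glc_D", "nh4", "meoh",
    "ac", "lac_D", "his_L", "succ", "etoh",
]

#: the four endpoint reactions that jointly control urine formate
PLANTED_MINIMAL_SET = ("DKMPPD", "PSP_L", "SFGTH", "TRPO2")

_SECRETION_POOL = {
    "for": 2.0,
    "ac": 1.5,
    "ser_L": 1.0,
    "gly": 1.0,
    "trp_L": 0.5,
    "tyr_L": 0.5,
    "cys_L": 0.5,
    "orn": 0.5,
    "nh4": 1.0,
}


@dataclass
class SynthConfig:
    seed: int = 0
    n_species: int = 6
    n_samples_per_group: int = 24
    read_depth: int = 50_000
    # (species, fold) planted in the AD group before compositional closure
    planted_up: list[tuple[str, float]] | None = None
    planted_down: list[tuple[str, float]] | None = None
    n_gotus_per_species: int = 2
    n_unannotated_gotus: int = 2
    n_unmapped_species: int = 1
    # metabolome
    n_metabolites: int = 49
    n_detectable: int = 16
    metabolome_effects: dict[str, float] | None = None  # AD log-effects
    zero_rate_detectable: float = 0.05
    zero_rate_undetectable: float = 0.65
    noise_sd: float = 0.5
    group_sizes: dict[str, int] | None = None
    age_mean: float = 70.0
    age_sd: float = 6.0
    bmi_mean: float = 26.0
    bmi_sd: float = 4.0
    p_female: float = 0.5

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def species_names(n: int) -> list[str]:
    return [f"sp{i + 1:02d}" for i in range(n)]


# ---------------------------------------------------------------------------
# toy strains

def _strain(species: str, strain_no: int, products: dict[str, float]) -> MetabolicModel:
    m = MetabolicModel(id=f"{species}_strain{strain_no}")
    m.add_reaction(Reaction("EX_glc_D[e]", {"glc_D[e]": -1}, -1000, 1000))
    m.add_reaction(Reaction("GLCt", {"glc_D[e]": -1, "glc_D[c]": 1}, 0, 1e4))
    m.add_reaction(Reaction("EX_cellul[e]", {"cellul[e]": -1}, -1000, 1000))
    m.add_reaction(Reaction("CELLt", {"cellul[e]": -1, "cellul[c]": 1}, 0, 1e4))
    # biomass consumes glucose; the community layer attaches the biomass
    # metabolite it needs for abundance weighting
    m.add_reaction(Reaction(f"biomass_{species}", {"glc_D[c]": -1}, 0, 1000))
    for met, yld in sorted(products.items()):
        m.add_reaction(Reaction(f"FERM_{met}", {"cellul[c]": -1, f"{met}[c]": yld}, 0, 1e4))
        m.add_reaction(Reaction(f"T_{met}", {f"{met}[c]": -1, f"{met}[e]": 1}, 0, 1e4))
        m.add_reaction(Reaction(f"EX_{met}[e]", {f"{met}[e]": -1}, -1000, 1000))
    m.objective_id = f"biomass_{species}"
    m.validate()
    return m


def make_toy_strains(cfg: SynthConfig) -> dict[str, list[MetabolicModel]]:
    """Two fermenting strains per species, with species-specific secretions.

    The first species always secretes formate; the second secretes
    L-serine (and no formate), giving the pipeline one direct and one
    co-metabolic formate contributor.  Remaining repertoires are drawn
    from a fixed pool of fermentation products.
    """
    if cfg.n_species < 2:
        raise ValueError("need at least two species")
    rng = cfg.rng(1)
    names = species_names(cfg.n_species)
    pool = sorted(_SECRETION_POOL)
    out: dict[str, list[MetabolicModel]] = {}
    for i, sp in enumerate(names):
        if i == 0:
            reps = ["for", "ac"]
        elif i == 1:
            reps = ["ser_L", "ac"]
        else:
            k = int(rng.integers(2, 4))
            reps = sorted(rng.choice(pool, size=k, replace=False).tolist())
        products = {r: _SECRETION_POOL[r] for r in reps}
        # strain 1 gets the full repertoire, strain 2 a (possibly) proper subset
        sub = dict(list(sorted(products.items()))[: max(1, len(products) - 1)])
        out[sp] = [_strain(sp, 1, products), _strain(sp, 2, sub)]
    return out


# ---------------------------------------------------------------------------
# toy host

_HOST_DIET_ENTRIES = {
    "glc_D": 10.0,
    "pser_L": 5.0,
    "cys_L": 2.0,
    "gly": 2.0,
    "orn": 2.0,
    "chol": 3.0,
    "meoh": 10.0,
    "trp_L": 12.0,
    "nh4": 14.0,
    "glu_L": 100.0,
    "cellul": 40.0,
}

#: metabolites with dietary exchanges in the host (supplement candidates
#: plus the baseline diet constituents); cellulose has no absorption
#: reaction -- only gut microbes can ferment it
_HOST_DIET_METS = sorted(
    set(_HOST_DIET_ENTRIES) | set(SUPPLEMENT_CANDIDATES) | {"pser_L", "chol"}
)


def host_diet() -> DietSpec:
    """The host's baseline diet (mmol/person/day), a desk-scale stand-in
    for an average European diet."""
    return DietSpec(dict(_HOST_DIET_ENTRIES))


def community_diet(cfg: SynthConfig | None = None) -> DietSpec:
    """Diet applied to standalone community models."""
    return DietSpec({"glc_D": 10.0, "cellul": 40.0})


def make_toy_host(sex: str = "male") -> HostModel:
    """Whole-body-style toy host with the formate-producing routes.

    Compartments: diet ``d``, large-intestinal lumen ``luLI``, cytosol
    ``c`` (standing in for the organ interior), peroxisome ``p`` and
    urine ``u``.  The female variant differs from the male in a single
    flux bound (peroxisomal sarcosine oxidase capacity), giving the two
    sexes different urine formate maxima.
    """
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    m = MetabolicModel(id=f"toyhost_{sex}")
    m.compartments |= {"d", "luLI", "c", "p", "u"}

    for met in _HOST_DIET_METS:
        m.add_reaction(Reaction(f"EX_{met}[d]", {f"{met}[d]": -1}, -1000, 1000))
        m.add_reaction(Reaction(f"GIt_{met}", {f"{met}[d]": -1, f"{met}[luLI]": 1}, 0, 1e4))
        if met != "cellul":
            m.add_reaction(Reaction(f"ABS_{met}", {f"{met}[luLI]": -1, f"{met}[c]": 1}, 0, 1e4))
    # formate arrives in the lumen only via microbes; the host absorbs it
    m.add_metabolite(Metabolite("for[luLI]", compartment="luLI"))
    m.add_reaction(Reaction("ABS_for", {"for[luLI]": -1, "for[c]": 1}, 0, 1e4))

    def rxn(rid, stoich, lb=0.0, ub=1e4):
        m.add_reaction(Reaction(rid, {k: float(v) for k, v in stoich.items()}, lb, ub))

    # glycolysis to 3-phosphoglycerate and the serine branch
    rxn("GLYC", {"glc_D[c]": -1, "3pg[c]": 2})
    rxn("PGCD", {"3pg[c]": -1, "3php[c]": 1})
    rxn("PSERT", {"3php[c]": -1, "glu_L[c]": -1, "pser_L[c]": 1, "akg[c]": 1})
    rxn("DM_akg", {"akg[c]": -1})
    rxn("PSP_L", {"pser_L[c]": -1, "ser_L[c]": 1})
    # folate one-carbon chain, duplicated isoforms
    for suffix in ("", "m"):
        rxn(f"SHMT{suffix}", {"ser_L[c]": -1, "thf[c]": -1, "gly[c]": 1, "mlthf[c]": 1})
        rxn(f"GLYCL{suffix}", {"gly[c]": -1, "thf[c]": -1, "mlthf[c]": 1})
        rxn(f"MTHFD{suffix}", {"mlthf[c]": -1, "methf[c]": 1})
        rxn(f"MTHFC{suffix}", {"methf[c]": -1, "10fthf[c]": 1})
        rxn(f"FTHFL{suffix}", {"10fthf[c]": -1, "for[c]": 1, "thf[c]": 1})
    # collapsed amino-acid feeds into the serine/glycine pool
    rxn("CYSCAT", {"cys_L[c]": -1, "ser_L[c]": 1})
    rxn("ORNCAT", {"orn[c]": -1, "gly[c]": 1})
    rxn("TYRCAT", {"tyr_L[c]": -1, "for[c]": 1, "tyrw[c]": 1})
    rxn("DM_tyrw", {"tyrw[c]": -1})
    # choline demethylation chain to sarcosine (peroxisomal) and methanol
    rxn("CHOLOX", {"chol[c]": -1, "glyb[c]": 1})
    rxn("GBDM", {"glyb[c]": -1, "dmgly[c]": 1, "fald[c]": 1})
    rxn("DMGDH", {"dmgly[c]": -1, "sarcs[c]": 1, "fald[c]": 1})
    rxn("SARCStp", {"sarcs[c]": -1, "sarcs[p]": 1})
    rxn("SARCOXp", {"sarcs[p]": -1, "gly[p]": 1, "fald[p]": 1},
        ub=(1e4 if sex == "male" else 1.0))
    rxn("GLYtp", {"gly[p]": -1, "gly[c]": 1})
    rxn("FALDtp", {"fald[p]": -1, "fald[c]": 1})
    rxn("DM_sarcs", {"sarcs[c]": -1})
    rxn("MEOHDH", {"meoh[c]": -1, "fald[c]": 1})
    # formaldehyde detox via S-formylglutathione
    rxn("FALDH", {"fald[c]": -1, "gthrd[c]": -1, "Sfglth[c]": 1})
    rxn("FALDH2", {"fald[c]": -1, "gthrd[c]": -1, "Sfglth[c]": 1})
    rxn("SFGTH", {"Sfglth[c]": -1, "for[c]": 1, "gthrd[c]": 1})
    # tryptophan dioxygenase route
    rxn("TRPO2", {"trp_L[c]": -1, "Lfmkynr[c]": 1})
    rxn("FKYNH", {"Lfmkynr[c]": -1, "for[c]": 1, "Lkynr[c]": 1})
    rxn("FKYNH2", {"Lfmkynr[c]": -1, "for[c]": 1, "Lkynr[c]": 1})
    rxn("DM_Lkynr", {"Lkynr[c]": -1})
    # methionine salvage: formate release plus ammonium-consuming closure
    rxn("MSALV", {"met_L[c]": -1, "dkmpp[c]": 1})
    rxn("DKMPPD", {"dkmpp[c]": -1, "for[c]": 1, "2kmb[c]": 1})
    rxn("KMBTA", {"2kmb[c]": -1, "nh4[c]": -1, "met_L[c]": 1})
    # urine excretion
    rxn("FORt_u", {"for[c]": -1, "for[u]": 1})
    rxn("EX_for[u]", {"for[u]": -1}, 0.0, 1e6)

    m.objective_id = "EX_for[u]"
    m.validate()
    return HostModel(model=m, sex=sex)


# ---------------------------------------------------------------------------
# abundance counts

def make_abundance_counts(cfg: SynthConfig) -> tuple[CountTable, pd.DataFrame, dict]:
    """Two-group gOTU count table with planted compositional shifts.

    Returns ``(counts, covariates, truth)``.  The log-normal baseline
    composition is shared across samples; planted fold-changes multiply
    the AD group's expected abundances *before* compositional closure;
    reads are multinomial at the configured depth.  Some gOTUs carry no
    species annotation and one species is left out of the mappable set,
    exercising the collapse and mapping steps.
    """
    rng = cfg.rng(2)
    n = cfg.n_samples_per_group
    species = species_names(cfg.n_species)
    unmapped = [f"unk{i + 1:02d}" for i in range(cfg.n_unmapped_species)]
    all_species = species + unmapped

    planted_up = cfg.planted_up
    planted_down = cfg.planted_down
    if planted_up is None and planted_down is None and cfg.n_species >= 4:
        planted_up = [(species[-1], 3.0)]
        planted_down = [(species[-2], 1 / 3.0)]
    planted_up = planted_up or []
    planted_down = planted_down or []
    for _, f in planted_up + planted_down:
        if f <= 0:
            raise ValueError("fold-change must be positive")

    base = np.exp(rng.normal(0.0, 1.5, size=len(all_species)))
    base /= base.sum()
    fold = pd.Series(1.0, index=all_species)
    for sp, f in planted_up + planted_down:
        fold[sp] = f

    samples = [f"S{i + 1:03d}" for i in range(2 * n)]
    groups = ["HC"] * n + ["AD"] * n
    # each species is represented by a fixed split over its gOTUs
    splits = {}
    gotu_rows, gotu_species = [], {}
    for sp in all_species:
        w = rng.dirichlet(np.ones(cfg.n_gotus_per_species) * 5)
        splits[sp] = w
        for g in range(cfg.n_gotus_per_species):
            gid = f"G_{sp}_{g + 1}"
            gotu_rows.append(gid)
            gotu_species[gid] = sp
    for i in range(cfg.n_unannotated_gotus):
        gid = f"G_unann_{i + 1}"
        gotu_rows.append(gid)
        gotu_species[gid] = None

    counts = np.zeros((len(gotu_rows), len(samples)), dtype=int)
    row_index = {g: i for i, g in enumerate(gotu_rows)}
    for j, (s, grp) in enumerate(zip(samples, groups)):
        noise = np.exp(rng.normal(0.0, 0.5, size=len(all_species)))
        expect = base * noise
        if grp == "AD":
            expect = expect * fold.values
        # a small unannotated fraction of the reads
        p_unann = 0.02 * np.ones(cfg.n_unannotated_gotus) / max(cfg.n_unannotated_gotus, 1)
        expect = expect / expect.sum() * (1 - p_unann.sum())
        probs = []
        for sp, e in zip(all_species, expect):
            probs.extend(e * splits[sp])
        probs = np.concatenate([np.array(probs), p_unann])
        draw = rng.multinomial(cfg.read_depth, probs / probs.sum())
        counts[:, j] = draw

    covariates = pd.DataFrame(
        {
            "sample_id": samples,
            "group": groups,
            "apoe": rng.choice(["E3", "E3E4", "E4E4"], size=len(samples), p=[0.6, 0.3, 0.1]),
            "sex": rng.choice(["female", "male"], size=len(samples)),
            "age": np.round(rng.normal(cfg.age_mean, cfg.age_sd, size=len(samples)), 1),
        }
    ).set_index("sample_id")

    table = CountTable(
        counts=pd.DataFrame(counts, index=gotu_rows, columns=samples),
        taxonomy=gotu_species,
    )
    truth = {
        "model_species": set(species),
        "up": [sp for sp, _ in planted_up],
        "down": [sp for sp, _ in planted_down],
        "folds": {sp: f for sp, f in planted_up + planted_down},
    }
    return table, covariates, truth


# ---------------------------------------------------------------------------
# metabolome

def make_metabolome(cfg: SynthConfig):
    """Creatinine-normalised urine metabolome with planted AD effects.

    Returns ``(MetabolomeTable, truth)``.  Concentrations are log-normal
    with age/BMI effects on the log scale; a configurable subset of
    metabolites is zero-inflated past the detection filter's threshold.
    """
    from .stats import MetabolomeTable

    rng = cfg.rng(3)
    sizes = cfg.group_sizes or {"HC": 49, "SCD": 45, "MCI": 49, "AD": 34}
    effects = cfg.metabolome_effects
    if effects is None:
        effects = {"formate": -0.4, "fumarate": -0.4}

    names = ["formate", "fumarate"] + [f"met{i + 3:02d}" for i in range(cfg.n_metabolites - 2)]
    detectable = names[: cfg.n_detectable]

    groups = [g for g, k in sizes.items() for _ in range(k)]
    n = len(groups)
    samples = [f"U{i + 1:03d}" for i in range(n)]
    age = rng.normal(cfg.age_mean, cfg.age_sd, size=n)
    bmi = rng.normal(cfg.bmi_mean, cfg.bmi_sd, size=n)
    sex = rng.random(n) < cfg.p_female  # True = female

    mu = rng.normal(0.0, 1.0, size=len(names))
    beta_age = rng.normal(0.0, 0.01, size=len(names))
    beta_bmi = rng.normal(0.0, 0.01, size=len(names))
    beta_sex = rng.normal(0.0, 0.05, size=len(names))

    log_conc = (
        mu[None, :]
        + np.outer(age - cfg.age_mean, beta_age)
        + np.outer(bmi - cfg.bmi_mean, beta_bmi)
        + np.outer(sex.astype(float), beta_sex)
        + rng.normal(0.0, cfg.noise_sd, size=(n, len(names)))
    )
    is_ad = np.array([g == "AD" for g in groups])
    for met, eff in effects.items():
        j = names.index(met)
        log_conc[is_ad, j] += eff

    conc = np.exp(log_conc)
    for j, met in enumerate(names):
        rate = cfg.zero_rate_detectable if met in detectable else cfg.zero_rate_undetectable
        mask = rng.random(n) < rate
        conc[mask, j] = 0.0

    covariates = pd.DataFrame(
        {
            "sample_id": samples,
            "age": np.round(age, 1),
            "sex": np.where(sex, "female", "male"),
            "bmi": np.round(bmi, 1),
            "group": groups,
        }
    ).set_index("sample_id")
    table = MetabolomeTable(
        concentrations=pd.DataFrame(conc, index=samples, columns=names),
        covariates=covariates,
    )
    truth = {"planted": dict(effects), "detectable": detectable}
    return table, truth
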