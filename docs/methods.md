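# Methods

## Model and solver

All simulations are linear programmes over a stoichiometric network:
steady-state mass balance `S·v = 0`, flux bounds `lb ≤ v ≤ ub`, and —
inside communities — coupling constraints written as the two one-sided
inequalities `v_r − c·v_b ≤ 0` and `v_r + c·v_b ≥ 0` with coupling
factor `c = 400`. This form makes any member reaction's flux collapse to
zero whenever its biomass reaction carries none, which is the behaviour
the community construction relies on. LPs are solved with scipy's HiGHS
backend at its default (≈1e-9) feasibility/optimality tolerances; all
package-level assertions use 1e-6. Degenerate alternate optima are
accepted: only objective values are interpreted, never the uniqueness of
a flux vector.

FVA reports, per reaction, the [min, max] flux over the same feasible
region; no fraction-of-optimum constraint is imposed, so a faecal
exchange's FVA maximum reads directly as a *maximum net secretion
capacity*. Community-biomass bounds (default [0.4, 1.0]/day) are the
only growth requirement shaping that region, and can be pinned to the
upper bound via `secretion_profile(..., fix_biomass_at_upper=True)`.

Fluxes are carried in mmol/person/day end-to-end; diet tables are in the
same unit and map to negated exchange lower bounds (uptake-negative
convention, `EX_met[comp]: met[comp] ↔ ∅`). Host/community flux scales
are treated as already harmonised — a stated simplification, not a claim
about the original resources.

An exhaustive vertex-enumeration solver (`cometab.enumeration`) provides
an independent check for networks of ≤ ~10 reactions: it activates
subsets of the inequality constraints, solves the resulting linear
systems directly with numpy, and optimises by inspecting feasible
vertices. It shares no code path with the LP route and backs the
oracle-equivalence tests.

## Community and whole-body assembly

Each member pan-species model is embedded with a `species__` prefix on
all ids; its extracellular exchanges are rewired into reversible
transfer reactions against a shared lumen `[luM]` (bounds ±1e4,
effectively unlimited relative to coupling caps), and the lumen is
connected to diet `[d]` (uptake) and faecal `[fe]` (secretion-only)
compartments. The community biomass reaction consumes member biomass
metabolites with coefficients equal to the relative abundances, so each
member's growth is forced to `abundance × community growth`.

Pan-species models are reaction/metabolite unions over strains with the
widest bound interval kept on duplicates (the pan feasible set therefore
dominates every strain — the union-monotonicity property). Strain
biomass reactions are replaced by one designated pan biomass whose
stoichiometry is the arithmetic mean over strains (absent precursors
contribute zero); `biomass_mode="first"` keeps the first strain's
instead. Whether real pan reconstructions reconcile conflicting
directionalities beyond bound-widening is unknown; this package only
widens bounds.

Attachment to a host replaces the community's diet/faecal plumbing with
one reversible bridge reaction `base[luM] ↔ base[luLI]` per metabolite
present in both lumens (positive = microbe→host). Community lumen
metabolites absent from the host lumen become dead ends. Diet then
enters exclusively through the host's dietary exchanges. In attached
mode the community-biomass lower bound is relaxed to 0 so the microbiome
can always be idled; this guarantees the germ-free value is a lower
bound on the personalised one. The original bounds are selectable
(`keep_biomass_bounds=True`). "Microbial secretion" of a metabolite is
the maximum of its bridge flux in the microbe→host direction, reported
as a nonnegative magnitude; this convention is oracle-tested here but
not claimed identical to other toolchains' sign conventions.

## Screens

- *Decomposition*: three LP solves give germ-free maximum, personalised
  maximum, and maximal microbial secretion; the identity
  `delta = personalised − germ-free` holds by construction and
  `excess = delta − secretion > 0` flags precursor-mediated
  co-metabolism.
- *Supplementation*: each candidate's dietary uptake is opened to
  300 mmol/d (never tightened below an existing entry), a pure
  relaxation, so percent changes are provably nonnegative.
- *Knockouts*: deletion = both bounds set to zero, reaction retained.
  Single knockouts are flagged at >10% reduction of the urine maximum;
  sexes are screened separately against their own baselines.
- *Minimal deletion set*: exhaustive smallest-first subset search over
  the flagged candidates (default cap: subsets of size ≤ 6, ≤ 200k LPs);
  among equally small achieving sets the lexicographically first by
  sorted ids is returned, making the result deterministic. A greedy
  forward-selection fallback exists for larger candidate lists and is
  labelled `method="greedy"` in its result. The 85% default reduction
  target is configuration, not a claim about how "largely reduced"
  should be defined in general.

## Statistics

- *PQN*: per-sample dilution factor = median of metabolite-wise
  quotients against the median spectrum (zeros treated as missing).
  Exact scale-equivariance holds for a fixed reference; with the
  data-driven reference a rescaled sample shifts the median spectrum
  slightly, so equivariance holds to ~a few percent at realistic n.
- *Detection filter*: metabolites must be non-zero in strictly more than
  50% of samples (a metabolite at exactly 50% is removed); surviving
  zeros are recoded missing, since a zero NMR quantification need not
  mean absence.
- *Metabolome regressions*: OLS of natural-log concentration on group
  dummies + age + sex + BMI, HC3 robust covariance, a global Wald χ²
  over the group dummies and the AD-vs-reference contrast, BH-FDR across
  metabolites for both p-values. Metabolites with <10 usable
  observations are skipped with a warning; a conditionally constant
  response is reported as "nothing to test" (Wald p = 1) rather than a
  spurious 0/0.
- *Fractional abundance regressions*: quasi-binomial logit
  (Papke–Wooldridge) per taxon on case status + APOE dummies, after a
  ≥50% presence filter. The sandwich covariance is assembled in-package
  with an HC3-style leverage correction and a t(n−k) reference, because
  the plain robust sandwich is visibly anticonservative at n = 48
  (measured null false-positive rate ≈0.086 vs ≈0.055 with the
  correction).
- *Log-ratio test*: Welch t between groups on
  `log(Σ up-set counts / Σ down-set counts)` per sample; samples with a
  zero numerator or denominator are excluded and counted (a +pseudocount
  mode exists). Natural logs throughout.
- *Flux regressions*: OLS of each simulated flux on case status + APOE +
  sex with HC3 errors; fully confounded designs are flagged
  rank-deficient with undefined coefficients.
- Creatinine normalisation is assumed done upstream (inputs are ratio
  tables); `creatinine_normalise` is provided as a helper.

Calibration (`cometab.calibration`) verifies these choices by
simulation: under the global null the per-test type-I rate and the
family-wise BH discovery rate stay within twice their Monte-Carlo
standard errors of 5% (1000 reps at n = 180 for the metabolome, 200 reps
at n = 48 for abundances); planted effects (−0.5 log-units, 3-fold
abundance shifts) are recovered with high power. The flux-coefficient
check (±5 window around a planted 20-unit effect, sd 10, n = 48) has
nominal coverage ≈91% and is compared to its 90% target with the same
Monte-Carlo allowance.

## Synthetic data: what it emulates, and what it does not

The generators produce *desk-scale stand-ins*, not imitations of any
cohort:

- **Toy strains** (2 per species): glucose-fed biomass plus a
  species-specific repertoire of fermentation products drawn from
  {formate, acetate, serine, glycine, tryptophan, tyrosine, cysteine,
  ornithine, ammonium}, fermented from dietary cellulose — a substrate
  the host cannot absorb, which is what lets microbial fermentation add
  to host metabolism. Species 1 always secretes formate, species 2
  L-serine (no formate), giving one direct and one co-metabolic formate
  contributor. Every strain grows on the synthetic diet by construction.
- **Toy host**: a single "organ interior" compartment `[c]` (plus
  peroxisome, diet, large-intestinal lumen and urine compartments)
  carrying collapsed analogue reactions, VMH-style ids, for the known
  urinary-formate routes: glycolysis→3-phosphoglycerate→serine (`PGCD`,
  `PSERT`, `PSP_L`), the serine/glycine one-carbon folate chain (`SHMT*`,
  `GLYCL*`, `MTHFD*`, `MTHFC*`, `FTHFL*`, each as a cytosolic/
  mitochondrial isoform pair, mirroring the isozyme redundancy that
  makes single intermediate deletions ineffective in organ-resolved
  models), choline demethylation through peroxisomal sarcosine oxidase
  and methanol oxidation to formaldehyde, glutathione-mediated
  formaldehyde detox (`FALDH`/`FALDH2` → `SFGTH`), tryptophan
  dioxygenase (`TRPO2` → duplicated `FKYNH`), and a methionine-salvage
  cycle (`MSALV` → `DKMPPD` → ammonium-consuming `KMBTA`) that turns
  ammonium — carrying no carbon — into a formate precursor. Collapsed
  shortcut reactions (cysteine→serine, ornithine→glycine,
  tyrosine→formate) stand in for multi-step routes. The female host
  differs from the male in exactly one bound (sarcosine-oxidase
  capacity), so the sexes have different formate maxima only downstream
  of choline.

  Baseline diet (mmol/person/day): glucose 10, phosphoserine 5,
  cysteine 2, glycine 2, ornithine 2, choline 3, methanol 10,
  tryptophan 12, ammonium 14, glutamate 100, cellulose 40. These were
  fixed at design time so that the four route endpoints dominate the
  formate maximum through separate channels: serine branch 54 (40 from
  glucose, 10 from dietary phosphoserine, 4 from cysteine — the
  phosphoserine entry is what keeps the phosphatase `PSP_L`, not the
  upstream dehydrogenase/transaminase, the branch endpoint),
  glycine feeds 6 more, formaldehyde 19 + 3 chol-derived glycine,
  tryptophan 12, salvage 14; male total 106 (female 102). Under this
  accounting no 3-subset of the >10% single-knockout hits reaches an
  85% reduction and `{DKMPPD, PSP_L, SFGTH, TRPO2}` is the unique
  lexicographically-first achieving 4-subset — which the exhaustive
  search confirms rather than assumes.
- **Abundance counts**: a shared log-normal baseline composition,
  per-sample log-normal scatter (σ = 0.5), planted fold-changes applied
  to the case group *before* compositional closure, multinomial read
  sampling at 50,000 reads/sample (a desk-scale stand-in for multi-
  million-read shotgun depth), two gOTUs per species with a fixed
  Dirichlet split, a few unannotated gOTUs and one unmappable species
  to exercise the collapse/mapping bookkeeping.
- **Metabolome**: 49 log-normal metabolites over four groups with the
  unbalanced sizes 49/45/49/34 (n = 177), small random age/BMI/sex
  log-effects, planted negative AD effects on the formate/fumarate
  columns, and zero-inflation tuned so 16 metabolites pass the >50%
  detection filter.

What passing these tests does **not** show: the toys have none of the
scale (thousands of reactions per organ, hundreds of species), none of
the pathway crosstalk, no phylogenetic covariance among taxa, no NMR
peak-shape artefacts, and the flux-unit harmonisation between community
and host is assumed. Results on real AGORA2/whole-body inputs therefore
need the full resources, supplied by the user through the file
interfaces; nothing from those resources is bundled.

## Numerical and interface notes

- Problem sizes were chosen for interactive turnaround: reference
  networks ≤ 8 reactions (vertex enumeration is combinatorial), toy
  hosts ≈ 95 reactions, calibration at 1000/500/200/100 replicates; the
  full acceptance run takes about two minutes on one CPU.
- JSON is the canonical model format (it carries couplings); SBML L3+fbc
  read/write is provided for interoperability, with bracketed
  compartment ids mapped to SBML-safe SIds (`for[u]` ↔ `for__u__`) and
  couplings not represented. MAT-file whole-body models are a user-side
  conversion step, out of scope.
- Diet entries with no matching exchange are skipped with a warning and
  recorded in `model.notes["diet_skipped"]`, never a hard error: real
  diet tables routinely contain metabolites a given model lacks.
- Deletions keep the reaction (bounds zeroed) so indices and candidate
  lists stay stable across a screen.
- All generators derive their randomness from `(seed, stream)` pairs via
  numpy's `default_rng`; identical config + seed give byte-identical
  outputs, and truth records are returned alongside the data so recovery
  tests never reach into generator internals.
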