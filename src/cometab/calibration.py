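"""Simulation-based calibration of the statistical battery.

Monte-Carlo checks that the regression machinery controls its error
rates under the null and recovers planted effects with adequate power,
at the cohort sizes the pipeline targets (a four-group metabolome of
~180 urine samples; a two-group microbiome cohort of 48).  Every
function takes a base seed and derives per-replicate seeds from it, so
runs are exactly reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .abundance import collapse_to_species, map_filter_normalise
from .stats import (
    filter_detected,
    flux_group_regression,
    fractional_abundance_regression,
    logratio_test,
    metabolite_group_regression,
)
from .synth import SynthConfig, make_abundance_counts, make_metabolome

__all__ = [
    "metabolome_null_calibration",
    "metabolome_power",
    "abundance_null_calibration",
    "abundance_recovery",
    "logratio_power",
    "flux_regression_calibration",
]

_BALANCED_180 = {"HC": 45, "SCD": 45, "MCI": 45, "AD": 45}


def _null_cfg(seed: int) -> SynthConfig:
    return SynthConfig(
        seed=seed,
        n_metabolites=16,
        n_detectable=16,
        metabolome_effects={},
        zero_rate_detectable=0.0,
        group_sizes=dict(_BALANCED_180),
    )


def metabolome_null_calibration(n_reps: int = 1000, seed: int = 1) -> dict:
    """Type-I / FDR behaviour of the metabolome regressions under the
    global null (no group effects; n=180, 16 metabolites)."""
    p_hits = p_total = 0
    reps_with_fdr_discovery = 0
    for rep in range(n_reps):
        tab, _ = make_metabolome(_null_cfg(seed * 1_000_003 + rep))
        res = metabolite_group_regression(filter_detected(tab))
        p_hits += int((res["p_ad_vs_hc"] < 0.05).sum())
        p_total += len(res)
        reps_with_fdr_discovery += int((res["q_ad_vs_hc"] < 0.05).any())
    return {
        "n_reps": n_reps,
        "typeI_rate": p_hits / p_total,
        "typeI_mc_se": float(np.sqrt(0.05 * 0.95 / p_total)),
        "fdr_family_rate": reps_with_fdr_discovery / n_reps,
        "fdr_mc_se": float(np.sqrt(0.05 * 0.95 / n_reps)),
    }


def metabolome_power(
    n_reps: int = 500,
    seed: int = 1,
    effect: float = -0.5,
    metabolite: str = "formate",
) -> dict:
    """Power to detect a planted AD log-effect at n=180."""
    hits = 0
    for rep in range(n_reps):
        cfg = _null_cfg(seed * 2_000_003 + rep)
        cfg.metabolome_effects = {metabolite: effect}
        tab, _ = make_metabolome(cfg)
        res = metabolite_group_regression(filter_detected(tab))
        row = res.loc[metabolite]
        if row["p_ad_vs_hc"] < 0.05 and np.sign(row["coef_ad_vs_ref"]) == np.sign(effect):
            hits += 1
    return {"n_reps": n_reps, "power": hits / n_reps, "effect": effect}


def _abundance_cfg(seed: int, planted_up=(), planted_down=()) -> SynthConfig:
    return SynthConfig(
        seed=seed,
        n_species=40,
        n_samples_per_group=24,
        planted_up=list(planted_up),
        planted_down=list(planted_down),
    )


def _run_fractional(cfg: SynthConfig) -> tuple[pd.DataFrame, dict]:
    counts, cov, truth = make_abundance_counts(cfg)
    ab = map_filter_normalise(collapse_to_species(counts), truth["model_species"])
    res = fractional_abundance_regression(ab.abundances, cov["group"], cov["apoe"])
    return res, truth


def abundance_null_calibration(n_reps: int = 200, seed: int = 1) -> dict:
    """False-positive rate of the fractional regressions with no planted
    shifts (n=48, 40 taxa)."""
    hits = total = 0
    for rep in range(n_reps):
        res, _ = _run_fractional(_abundance_cfg(seed * 3_000_017 + rep))
        hits += int((res["p"] < 0.05).sum())
        total += len(res)
    return {
        "n_reps": n_reps,
        "typeI_rate": hits / total,
        "typeI_mc_se": float(np.sqrt(0.05 * 0.95 / total)),
    }


def abundance_recovery(
    n_reps: int = 100,
    seed: int = 1,
    fold: float = 3.0,
    n_planted: int = 2,
) -> dict:
    """Fraction of planted fold-changes flagged (p<0.05, correct sign)."""
    recovered = total = 0
    for rep in range(n_reps):
        planted_up = [(f"sp{40 - i:02d}", fold) for i in range(n_planted)]
        res, truth = _run_fractional(_abundance_cfg(seed * 4_000_037 + rep, planted_up=planted_up))
        for sp in truth["up"]:
            total += 1
            if sp in res.index and res.loc[sp, "p"] < 0.05 and res.loc[sp, "direction"] == "increased":
                recovered += 1
    return {"n_reps": n_reps, "recovery_rate": recovered / total, "fold": fold}


def logratio_power(n_reps: int = 500, seed: int = 11, fold: float = 3.0) -> dict:
    """Power of the compositional log-ratio Welch test for a planted
    up-set shift (n=48)."""
    hits = 0
    for rep in range(n_reps):
        cfg = _abundance_cfg(
            seed * 5_000_011 + rep,
            planted_up=[("sp40", fold), ("sp39", fold)],
            planted_down=[("sp38", 1.0 / fold), ("sp37", 1.0 / fold)],
        )
        counts, cov, truth = make_abundance_counts(cfg)
        sp = collapse_to_species(counts)
        res = logratio_test(sp.counts, truth["up"], truth["down"], cov["group"])
        if res.pvalue < 0.01 and res.statistic > 0:
            hits += 1
    return {"n_reps": n_reps, "power": hits / n_reps, "fold": fold}


def flux_regression_calibration(
    n_reps: int = 500,
    seed: int = 1,
    effect: float = 20.0,
    sd: float = 10.0,
    n: int = 48,
    tolerance: float = 5.0,
) -> dict:
    """Fraction of replicates estimating a planted flux group difference
    within +/- tolerance."""
    hits = 0
    idx = [f"S{i}" for i in range(n)]
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, 6_000_029, rep])
        group = pd.Series(["HC"] * (n // 2) + ["AD"] * (n - n // 2), index=idx)
        apoe = pd.Series(rng.choice(["E3", "E3E4", "E4E4"], n, p=[0.6, 0.3, 0.1]), index=idx)
        sex = pd.Series(rng.choice(["male", "female"], n), index=idx)
        flux = pd.DataFrame(
            {"flux": rng.normal(100.0, sd, n) + np.where(group == "AD", effect, 0.0)}, index=idx
        )
        res = flux_group_regression(flux, group, apoe, sex)
        if abs(res.loc["flux", "coef_case"] - effect) <= tolerance:
            hits += 1
    return {"n_reps": n_reps, "coverage": hits / n_reps, "effect": effect, "tolerance": tolerance}
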