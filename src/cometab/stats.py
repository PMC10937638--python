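"""Statistical analyses around the metabolic modelling.

Metabolome: probabilistic quotient normalisation (PQN), a detection
filter (metabolites must be non-zero in *more than* a given fraction of
samples; surviving zeros are recoded missing), and per-metabolite
multivariable linear regressions of log concentration on study group
with age, sex and BMI as covariates, heteroscedasticity-robust (HC3)
covariance, a global Wald test over the group dummies, the AD-vs-control
contrast, and Benjamini-Hochberg FDR across metabolites.

Abundances: fractional (quasi-binomial logit) regressions of relative
abundance on health status correcting for APOE genotype, with a 50%
presence filter, and a compositional log-ratio Welch test of planted
increased against decreased species on raw gOTU counts.

Fluxes: linear regressions of simulated secretion fluxes on health
status correcting for APOE and (host-model) sex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MetabolomeTable",
    "LogRatioResult",
    "normalize_pqn",
    "creatinine_normalise",
    "filter_detected",
    "metabolite_group_regression",
    "fractional_abundance_regression",
    "logratio_test",
    "flux_group_regression",
    "demographics_table",
]

GROUPS = ("HC", "SCD", "MCI", "AD")


@dataclass
class MetabolomeTable:
    """Samples x metabolites concentrations plus per-sample covariates.

    Concentrations are creatinine-normalised (unitless ratios); zeros
    are representable and convertible to missing.  Covariates must
    include ``age`` (years), ``sex``, ``bmi`` (kg/m²) and ``group``.
    """

    concentrations: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.concentrations.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("concentrations must be nonnegative")
        if not self.concentrations.index.equals(self.covariates.index):
            raise ValueError("concentrations and covariates must share the sample index")


def creatinine_normalise(raw: pd.DataFrame, creatinine: pd.Series) -> pd.DataFrame:
    """Divide each sample's row by its creatinine value (helper; the main
    pipeline assumes this was done upstream)."""
    if (creatinine <= 0).any():
        raise ValueError("creatinine values must be positive")
    return raw.div(creatinine, axis=0)


def normalize_pqn(table: MetabolomeTable, reference: pd.Series | None = None) -> MetabolomeTable:
    """Probabilistic quotient normalisation.

    Each sample is divided by the median of its metabolite-wise
    quotients against a reference spectrum (default: the median across
    samples); quotients are taken over metabolites non-missing (and
    non-zero) in both the sample and the reference.
    """
    conc = table.concentrations.replace(0.0, np.nan)
    if conc.notna().sum(axis=1).min() == 0:
        bad = conc.index[conc.notna().sum(axis=1) == 0].tolist()
        raise ValueError(f"samples with no usable measurements: {bad}")
    if len(conc) < 2:
        raise ValueError("PQN requires at least two samples")
    ref = conc.median(axis=0) if reference is None else reference
    quotients = conc.div(ref, axis=1)
    factors = quotients.median(axis=1)
    out = table.concentrations.div(factors, axis=0)
    return MetabolomeTable(concentrations=out, covariates=table.covariates.copy())


def filter_detected(table: MetabolomeTable, min_nonzero_frac: float = 0.5) -> MetabolomeTable:
    """Keep metabolites non-zero in *more than* the given fraction of
    samples; recode surviving zeros as missing."""
    if not (0 < min_nonzero_frac <= 1):
        raise ValueError("min_nonzero_frac must be in (0, 1]")
    conc = table.concentrations
    frac = (conc > 0).mean(axis=0)
    keep = frac[frac > min_nonzero_frac].index
    out = conc[keep].replace(0.0, np.nan)
    return MetabolomeTable(concentrations=out, covariates=table.covariates.copy())


def _group_design(cov: pd.DataFrame, groups: tuple[str, ...]) -> pd.DataFrame:
    present = [g for g in groups if g in set(cov["group"])]
    X = pd.DataFrame(index=cov.index)
    X["const"] = 1.0
    for g in present[1:]:
        X[f"group_{g}"] = (cov["group"] == g).astype(float)
    X["age"] = cov["age"].astype(float)
    X["sex_female"] = (cov["sex"].astype(str).str.lower().isin(["female", "f", "1"])).astype(float)
    X["bmi"] = cov["bmi"].astype(float)
    return X


def metabolite_group_regression(
    table: MetabolomeTable,
    groups: tuple[str, ...] = GROUPS,
    min_obs: int = 10,
    contrast_group: str = "AD",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-metabolite OLS of log concentration on group + age + sex + BMI.

    HC3 robust covariance; a global Wald test over the group dummies; the
    ``contrast_group``-vs-reference coefficient test; BH-FDR across
    metabolites for both p-values.
    """
    cov = table.covariates
    X_full = _group_design(cov, groups)
    group_cols = [c for c in X_full.columns if c.startswith("group_")]
    rows = []
    for met in table.concentrations.columns:
        y = table.concentrations[met]
        mask = y.notna() & (y > 0)  # zeros are treated as missing
        if mask.sum() < min_obs:
            warnings.warn(f"metabolite {met!r}: <{min_obs} non-missing observations, skipped")
            continue
        yy = np.log(y[mask].astype(float))
        XX = X_full.loc[mask]
        if np.linalg.matrix_rank(XX.to_numpy()) < XX.shape[1]:
            warnings.warn(f"metabolite {met!r}: rank-deficient design, skipped")
            continue
        res = sm.OLS(yy.to_numpy(), XX.to_numpy()).fit(cov_type="HC3")
        names = list(XX.columns)
        ccol = f"group_{contrast_group}"
        if res.ssr / mask.sum() < 1e-14:
            # degenerate: response (conditionally) constant, nothing to test
            wald_stat, wald_p = 0.0, 1.0
            coef, se, p_c = 0.0, 0.0, 1.0
        else:
            R = np.zeros((len(group_cols), len(names)))
            for i, g in enumerate(group_cols):
                R[i, names.index(g)] = 1.0
            wald = res.wald_test(R, scalar=True, use_f=False)
            wald_stat, wald_p = float(wald.statistic), float(wald.pvalue)
            if ccol in names:
                j = names.index(ccol)
                coef, se, p_c = res.params[j], res.bse[j], res.pvalues[j]
            else:
                coef = se = p_c = np.nan
        rows.append(
            {
                "metabolite": met,
                "n": int(mask.sum()),
                "coef_ad_vs_ref": coef,
                "se_robust": se,
                "wald_stat": wald_stat,
                "wald_p": wald_p,
                "p_ad_vs_hc": p_c,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_wald"] = multipletests(out["wald_p"], method="fdr_bh")[1]
        out["q_ad_vs_hc"] = multipletests(out["p_ad_vs_hc"].fillna(1.0), method="fdr_bh")[1]
        out["significant"] = out["q_ad_vs_hc"] < alpha
    return out.set_index("metabolite") if len(out) else out


def _fractional_logit_fit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quasi-binomial logit fit with a leverage-corrected (HC3-style)
    sandwich and t(n-k) p-values.

    statsmodels' GLM robust covariances apply no leverage correction,
    which is visibly anticonservative at the cohort sizes used here, so
    the sandwich is assembled directly from the quasi-likelihood score.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-integer Binomial endog
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    mu = res.fittedvalues
    w = mu * (1 - mu)
    n, k = X.shape
    bread = np.linalg.inv(X.T @ (w[:, None] * X))
    wx = np.sqrt(w)[:, None] * X
    leverage = np.clip(np.einsum("ij,jk,ik->i", wx, bread, wx), 0.0, 0.99)
    score = (y - mu) / (1 - leverage)
    meat = X.T @ (score[:, None] ** 2 * X)
    cov = bread @ meat @ bread
    se = np.sqrt(np.diag(cov))
    tval = res.params / se
    pval = 2 * sps.t.sf(np.abs(tval), n - k)
    return res.params, se, pval


def fractional_abundance_regression(
    abundances: pd.DataFrame,
    group: pd.Series,
    apoe: pd.Series | None = None,
    presence_frac: float = 0.5,
    case_label: str = "AD",
) -> pd.DataFrame:
    """Fractional (quasi-binomial logit) regression per taxon.

    ``abundances``: taxa x samples in [0, 1].  Taxa present in fewer
    than ``presence_frac`` of samples, or with constant abundance, are
    skipped.  Sandwich standard errors with an HC3-style leverage
    correction and a t reference (see :func:`_fractional_logit_fit`).
    """
    samples = abundances.columns
    y_case = (group.loc[samples].astype(str) == case_label).astype(float)
    X = pd.DataFrame({"const": 1.0, "case": y_case}, index=samples)
    if apoe is not None:
        dummies = pd.get_dummies(apoe.loc[samples].astype(str), prefix="apoe", drop_first=True)
        X = pd.concat([X, dummies.astype(float)], axis=1)
    Xa = X.to_numpy()
    j = list(X.columns).index("case")
    rows = []
    for taxon, ab in abundances.iterrows():
        present = (ab > 0).mean()
        if present < presence_frac:
            continue
        if ab.nunique() <= 1:
            warnings.warn(f"taxon {taxon!r}: constant abundance, skipped")
            continue
        params, se, pval = _fractional_logit_fit(ab.astype(float).to_numpy(), Xa)
        rows.append(
            {
                "taxon": taxon,
                "presence": float(present),
                "coef_case": float(params[j]),
                "se_robust": float(se[j]),
                "p": float(pval[j]),
                "direction": "increased" if params[j] > 0 else "decreased",
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.set_index("taxon") if len(out) else out


@dataclass
class LogRatioResult:
    statistic: float
    pvalue: float
    logratios: pd.Series
    n_excluded: int


def logratio_test(
    counts: pd.DataFrame,
    up_set: list[str],
    down_set: list[str],
    group: pd.Series,
    case_label: str = "AD",
    pseudocount: float = 0.0,
) -> LogRatioResult:
    """Welch t-test between groups on log(sum(up) / sum(down)) per sample.

    Samples with a zero numerator or denominator sum are excluded (or a
    pseudocount added when ``pseudocount > 0``).
    """
    up_set, down_set = list(up_set), list(down_set)
    if not up_set or not down_set:
        raise ValueError("up_set and down_set must be nonempty")
    if set(up_set) & set(down_set):
        raise ValueError("up_set and down_set must be disjoint")
    up = counts.loc[up_set].sum(axis=0) + pseudocount
    down = counts.loc[down_set].sum(axis=0) + pseudocount
    ok = (up > 0) & (down > 0)
    lr = np.log(up[ok] / down[ok])
    g = group.loc[lr.index].astype(str)
    a = lr[g == case_label]
    b = lr[g != case_label]
    if a.var(ddof=1) + b.var(ddof=1) < 1e-30:
        # both groups constant: no evidence of a shift
        t, p = (0.0, 1.0) if abs(a.mean() - b.mean()) < 1e-12 else (np.inf, 0.0)
    else:
        t, p = sps.ttest_ind(a, b, equal_var=False)
    return LogRatioResult(float(t), float(p), lr, int((~ok).sum()))


def flux_group_regression(
    fluxes: pd.DataFrame,
    group: pd.Series,
    apoe: pd.Series,
    sex: pd.Series,
    case_label: str = "AD",
) -> pd.DataFrame:
    """OLS of each simulated flux on health status + APOE + sex (HC3 SE)."""
    samples = fluxes.index
    X = pd.DataFrame(
        {
            "const": 1.0,
            "case": (group.loc[samples].astype(str) == case_label).astype(float),
        },
        index=samples,
    )
    X = pd.concat(
        [
            X,
            pd.get_dummies(apoe.loc[samples].astype(str), prefix="apoe", drop_first=True).astype(float),
            pd.get_dummies(sex.loc[samples].astype(str), prefix="sex", drop_first=True).astype(float),
        ],
        axis=1,
    )
    rows = []
    for col in fluxes.columns:
        y = fluxes[col].astype(float)
        if y.nunique() <= 1:
            warnings.warn(f"flux {col!r}: constant across samples, skipped")
            continue
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            warnings.warn(f"flux {col!r}: rank-deficient design (confounded covariates)")
            rows.append({"flux": col, "coef_case": np.nan, "se_robust": np.nan,
                         "p": np.nan, "flag": "rank_deficient"})
            continue
        res = sm.OLS(y.to_numpy(), X.to_numpy()).fit(cov_type="HC3")
        j = list(X.columns).index("case")
        rows.append(
            {
                "flux": col,
                "coef_case": float(res.params[j]),
                "se_robust": float(res.bse[j]),
                "p": float(res.pvalues[j]),
                "flag": "",
            }
        )
    out = pd.DataFrame(rows)
    if len(out) and out["p"].notna().any():
        out["q_bh"] = multipletests(out["p"].fillna(1.0), method="fdr_bh")[1]
    return out.set_index("flux") if len(out) else out


def demographics_table(covariates: pd.DataFrame, case_label: str = "AD") -> pd.DataFrame:
    """Convenience cohort table: Welch t for age/BMI, Fisher for sex/APOE4."""
    is_case = covariates["group"].astype(str) == case_label
    rows = []
    for col in ("age", "bmi"):
        if col not in covariates:
            continue
        a = covariates.loc[is_case, col].astype(float)
        b = covariates.loc[~is_case, col].astype(float)
        t, p = sps.ttest_ind(a, b, equal_var=False)
        rows.append({"variable": col, "test": "welch_t", "statistic": t, "p": p})
    for col in ("sex", "apoe4"):
        if col not in covariates:
            continue
        tab = pd.crosstab(is_case, covariates[col].astype(str))
        if tab.shape == (2, 2):
            odds, p = sps.fisher_exact(tab.to_numpy())
            rows.append({"variable": col, "test": "fisher", "statistic": odds, "p": p})
    return pd.DataFrame(rows).set_index("variable")
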