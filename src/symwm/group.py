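"""Group-level inference on subject GLM effects.

Random-intercept linear mixed models relate per-subject ROI (or
channel) hemodynamic effects to probe symmetry, encoded load, their
interaction, and optional behavioral covariates, with the subject as a
random effect (REML via statsmodels MixedLM).  The module also derives
the intraclass correlation and Nakagawa marginal/conditional R² from the
fit, runs channel-wise one-sample group contrasts with Benjamini-
Hochberg FDR control, and performs Tukey/Bonferroni post-hoc cell
comparisons.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests


@dataclass
class LmeFit:
    fixed_effects: pd.DataFrame     # term, beta, se, z, p
    sigma2_subject: float
    sigma2_resid: float
    icc: float
    r2_marginal: float
    r2_conditional: float
    converged: bool
    boundary: bool                  # sigma2_subject estimated at ~0
    n_obs: int
    n_subjects: int
    model_result: object = field(default=None, repr=False)


def _design_from_table(table: pd.DataFrame, covariates: list[str],
                       interaction: bool = True) -> tuple[np.ndarray, list[str]]:
    # treatment coding with asym/low reference
    probe = (table["probe"].astype(str) == "sym").astype(float).to_numpy()
    load = (table["load"].astype(str) == "high").astype(float).to_numpy()
    cols = [np.ones(len(table)), probe, load]
    names = ["intercept", "probe[sym]", "load[high]"]
    if interaction:
        cols.append(probe * load)
        names.append("probe[sym]:load[high]")
    for c in covariates:
        cols.append(table[c].to_numpy(float))
        names.append(c)
    # single-level factors contribute constant columns; drop them
    keep = [i for i, col in enumerate(cols)
            if i == 0 or np.ptp(col) > 0]
    return np.column_stack([cols[i] for i in keep]), [names[i] for i in keep]


def fit_random_intercept_lme(table: pd.DataFrame, effect_col: str = "effect",
                             subject_col: str = "subject",
                             covariates: list[str] | None = None,
                             interaction: bool = True) -> LmeFit:
    """REML random-intercept model: effect ~ probe * load (+ covariates).

    Factors are treatment coded with the asymmetric probe and low load
    as reference levels.  Fixed-effect p values are Wald z tests.  A
    subject variance estimated at (numerically) zero is reported as a
    boundary fit, not an error.
    """
    covariates = covariates or []
    if table.groupby(subject_col).size().min() < 2:
        raise ValueError("need at least 2 observations per subject")
    X, names = _design_from_table(table, covariates, interaction)
    y = table[effect_col].to_numpy(float)
    groups = table[subject_col].to_numpy()
    res = None
    last_err: Exception | None = None
    for method in ("lbfgs", "bfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = MixedLM(y, X, groups=groups)
                res = model.fit(reml=True, method=method)
            break
        except np.linalg.LinAlgError as err:  # optimizer hit a singular point
            last_err = err
    if res is None:
        raise RuntimeError(
            "mixed-model fit failed to converge (likely a boundary fit with "
            f"subject variance near zero): {last_err}")
    s2_b = float(np.squeeze(res.cov_re))
    s2_e = float(res.scale)
    beta = np.asarray(res.fe_params)
    se = np.asarray(res.bse_fe)
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    fe = pd.DataFrame({"term": names, "beta": beta, "se": se, "z": z, "p": p})
    icc = s2_b / (s2_b + s2_e) if (s2_b + s2_e) > 0 else 0.0
    var_fixed = float(np.var(X @ beta))
    denom = var_fixed + s2_b + s2_e
    r2m = var_fixed / denom if denom > 0 else 0.0
    r2c = (var_fixed + s2_b) / denom if denom > 0 else 0.0
    return LmeFit(fixed_effects=fe, sigma2_subject=s2_b, sigma2_resid=s2_e,
                  icc=float(icc), r2_marginal=float(r2m), r2_conditional=float(r2c),
                  converged=bool(res.converged), boundary=bool(s2_b < 1e-8),
                  n_obs=len(y), n_subjects=len(np.unique(groups)),
                  model_result=res)


def icc_and_r2(fit: LmeFit) -> tuple[float, float, float]:
    """(ICC, marginal R², conditional R²) of a random-intercept fit.

    ICC = σ²_subject / (σ²_subject + σ²_resid); the R² pair follows the
    Nakagawa decomposition with the fixed-prediction variance in the
    numerator(s) and total variance in the denominator.
    """
    return fit.icc, fit.r2_marginal, fit.r2_conditional


def bh_fdr(p: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (q values, rejection mask at ``alpha``)."""
    p = np.asarray(p, float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def group_channel_contrast(effects: pd.DataFrame, effect_col: str = "effect",
                           channel_col: str = "channel_id",
                           chroma_col: str = "chroma",
                           alpha: float = 0.05) -> pd.DataFrame:
    """Channel-wise one-sample group inference with per-chroma BH-FDR.

    For each channel and chromophore, the subject contrast effects are
    reduced to t = mean / (SD/sqrt(n)) (the random-intercept reduction
    for a single contrast per subject), mapped to a z score, and the p
    values are FDR-corrected across channels within each chromophore.
    Channels with fewer than 3 subjects are flagged untestable.
    """
    rows = []
    for (ch, chroma), grp in effects.groupby([channel_col, chroma_col]):
        x = grp[effect_col].to_numpy(float)
        n = len(x)
        if n < 3:
            rows.append({channel_col: ch, chroma_col: chroma, "n": n,
                         "effect": np.nan, "z": np.nan, "p": np.nan,
                         "testable": False})
            continue
        m, s = x.mean(), x.std(ddof=1)
        t = m / (s / np.sqrt(n)) if s > 0 else np.sign(m) * np.inf
        p = 2 * stats.t.sf(abs(t), n - 1)
        z = np.sign(t) * stats.norm.isf(max(p / 2, 1e-300))
        rows.append({channel_col: ch, chroma_col: chroma, "n": n,
                     "effect": m, "z": z, "p": p, "testable": True})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    out["significant"] = False
    for chroma, grp in out.groupby(chroma_col):
        ok = grp["testable"]
        if ok.any():
            q, rej = bh_fdr(grp.loc[ok, "p"].to_numpy(), alpha)
            out.loc[grp.index[ok], "q"] = q
            out.loc[grp.index[ok], "significant"] = rej
    return out


def posthoc_cellwise(table: pd.DataFrame, effect_col: str = "effect",
                     subject_col: str = "subject",
                     method: str = "tukey") -> pd.DataFrame:
    """Pairwise comparisons among the 4 probe x load cells.

    Cell means with a pooled within-subject error term; adjustment by
    Tukey's studentized range or Bonferroni multiplication over the 6
    comparisons.
    """
    if method not in ("tukey", "bonferroni"):
        raise ValueError(f"unknown method {method!r}")
    cells = table.assign(cell=table["probe"].astype(str) + "/" + table["load"].astype(str))
    piv = cells.pivot_table(index=subject_col, columns="cell",
                            values=effect_col, aggfunc="mean")
    if piv.isna().any().any():
        raise ValueError("incomplete subject x cell table")
    Y = piv.to_numpy()
    n, k = Y.shape
    resid = Y - Y.mean(1, keepdims=True) - Y.mean(0, keepdims=True) + Y.mean()
    df_err = (n - 1) * (k - 1)
    ms = float((resid ** 2).sum() / df_err)
    means = Y.mean(0)
    labels = list(piv.columns)
    pairs = list(itertools.combinations(range(k), 2))
    rows = []
    for i, j in pairs:
        diff = means[i] - means[j]
        se = np.sqrt(2 * ms / n)
        if method == "tukey":
            if ms > 0:
                qstat = abs(diff) / np.sqrt(ms / n)
                p_adj = float(stats.studentized_range.sf(qstat, k, df_err))
            else:
                p_adj = 1.0
        else:
            t = diff / se if se > 0 else 0.0
            p_adj = min(1.0, float(2 * stats.t.sf(abs(t), df_err)) * len(pairs)) \
                if se > 0 else 1.0
        rows.append({"contrast": f"{labels[i]} - {labels[j]}",
                     "m_difference": float(diff), "se": float(se),
                     "df": df_err, "p_adjusted": p_adj, "method": method})
    return pd.DataFrame(rows)
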