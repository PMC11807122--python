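"""Behavioral analysis: outlier filtering, error geometry, RM-ANOVA, correlations.

Implements the full behavioral chain for the symmetry working-memory
task: reaction-time outlier removal (mean +/- 2 SD per subject),
error-distance and arccos error-angle metrics on the dodecagon layout,
false-positive rates (errors landing on displayed distractor anchors),
fully-within repeated-measures ANOVA with Greenhouse-Geisser sphericity
correction and generalized eta-squared effect sizes, Bonferroni pairwise
comparisons with a pooled within-subject error term, per-subject accuracy
covariates, and Pearson complexity correlations with Fisher-z intervals.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .schedule import ExperimentSchedule, LocationLayout, TrialSpec
from .stimuli import ComplexityScore
from .synth_behavior import ResponseRecord, records_to_frame


# ---------------------------------------------------------------------------
# outlier filtering

def filter_rt_outliers(records: pd.DataFrame, subject_col: str = "subject_id",
                       rt_col: str = "rt_ms", correct_col: str = "correct",
                       n_sd: float = 2.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove correct trials whose RT falls outside mean +/- n_sd * SD.

    Bounds are computed per subject over that subject's correct responded
    trials.  Returns (filtered table, removal log).  Subjects with fewer
    than 3 correct trials are skipped with a warning.
    """
    df = records.copy()
    keep = np.ones(len(df), dtype=bool)
    removed = []
    for subj, sub in df.groupby(subject_col):
        corr = sub[sub[correct_col] & sub[rt_col].notna()]
        if len(corr) < 3:
            warnings.warn(f"subject {subj}: fewer than 3 correct trials, "
                          "outlier filter skipped")
            continue
        m, s = corr[rt_col].mean(), corr[rt_col].std(ddof=1)
        lo, hi = m - n_sd * s, m + n_sd * s
        bad = corr.index[(corr[rt_col] < lo) | (corr[rt_col] > hi)]
        keep[df.index.get_indexer(bad)] = False
        for i in bad:
            removed.append({"subject": subj, "row": i, "rt_ms": df.loc[i, rt_col],
                            "lower": lo, "upper": hi})
    return df[keep].copy(), pd.DataFrame(removed, columns=["subject", "row", "rt_ms",
                                                           "lower", "upper"])


# ---------------------------------------------------------------------------
# error geometry

def error_distance(response: ResponseRecord, trial: TrialSpec,
                   layout: LocationLayout) -> float:
    """Euclidean pixel distance between chosen and target anchors (0 if correct)."""
    if not (0 <= response.chosen_anchor < len(layout.anchors)):
        raise ValueError(f"chosen anchor {response.chosen_anchor} out of range")
    if not (0 <= trial.target_anchor < len(layout.anchors)):
        raise ValueError(f"target anchor {trial.target_anchor} out of range")
    d = layout.anchor(response.chosen_anchor) - layout.anchor(trial.target_anchor)
    return float(np.hypot(*d))


def error_angle(response: ResponseRecord, trial: TrialSpec,
                layout: LocationLayout) -> float:
    """Angle (degrees, [0, 180]) between chosen and target anchors seen from center.

    theta = arccos(u . v / (|u||v|)) with u, v the center-to-target and
    center-to-chosen vectors.
    """
    center = np.asarray(layout.center, dtype=float)
    u = layout.anchor(trial.target_anchor) - center
    v = layout.anchor(response.chosen_anchor) - center
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("anchor coincides with center: angle undefined")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def false_positive_rate(records: list[ResponseRecord] | pd.DataFrame,
                        schedule: ExperimentSchedule,
                        per_cell: bool = False) -> pd.DataFrame:
    """Proportion of incorrect responses that landed on a distractor anchor.

    The denominator is all incorrect responded trials; cells with no
    errors are flagged ``defined = False`` (rate NaN), not zero.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    trials = {t.trial_index: t for t in schedule.trials}
    rows = []
    for _, r in df.iterrows():
        if not r["responded"] or r["correct"]:
            continue
        tr = trials[r["trial_index"]]
        d_anchors = {a for sid, a in tr.item_locations.items() if sid != tr.probe_id}
        rows.append({"subject": r["subject_id"], "symmetry": tr.symmetry_label,
                     "load": tr.load_label,
                     "on_distractor": r["chosen_anchor"] in d_anchors})
    err = pd.DataFrame(rows, columns=["subject", "symmetry", "load", "on_distractor"])
    keys = ["subject", "symmetry", "load"] if per_cell else ["subject"]
    out = []
    if len(err):
        for key, grp in err.groupby(keys):
            key = key if isinstance(key, tuple) else (key,)
            out.append(dict(zip(keys, key))
                       | {"n_errors": len(grp),
                          "rate": grp["on_distractor"].mean(), "defined": True})
    return pd.DataFrame(out, columns=keys + ["n_errors", "rate", "defined"])


# ---------------------------------------------------------------------------
# repeated-measures ANOVA

@dataclass
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    p: float
    ges: float
    gg_epsilon: float
    p_gg: float


def _cell_array(table: pd.DataFrame, dv: str, within: list[str],
                subject: str) -> tuple[np.ndarray, list[str], list[list]]:
    """Subject x cell mean array (n, k1, k2, ...) with completeness check."""
    agg = table.groupby([subject] + within, observed=True)[dv].mean()
    subjects = sorted(table[subject].unique())
    levels = [sorted(table[f].unique()) for f in within]
    shape = (len(subjects),) + tuple(len(l) for l in levels)
    Y = np.full(shape, np.nan)
    for idx, val in agg.items():
        s, *cell = idx if isinstance(idx, tuple) else (idx,)
        pos = (subjects.index(s),) + tuple(l.index(c) for l, c in zip(levels, cell))
        Y[pos] = val
    if np.isnan(Y).any():
        bad = np.argwhere(np.isnan(Y))[0]
        cell = tuple(levels[j][bad[j + 1]] for j in range(len(within)))
        raise ValueError(f"missing cell for subject {subjects[bad[0]]}: {cell}")
    return Y, subjects, levels


def _effect_term(Y: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Interaction effect over the given axes by Moebius (inclusion-
    exclusion) combination of marginal means — the definitional
    within-subject decomposition."""
    all_axes = tuple(range(Y.ndim))
    e = np.zeros((1,) * Y.ndim)
    for r in range(len(axes) + 1):
        for sub in itertools.combinations(axes, r):
            drop = tuple(a for a in all_axes if a not in sub)
            m = Y.mean(axis=drop, keepdims=True) if drop else Y
            e = e + (-1) ** (len(axes) - len(sub)) * m
    return e


def _ss(Y: np.ndarray, axes: tuple[int, ...]) -> float:
    e = _effect_term(Y, axes)
    return float((np.broadcast_to(e, Y.shape) ** 2).sum())


def _orthonormal_contrast(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows orthogonal to the mean)."""
    basis = np.eye(k) - np.full((k, k), 1.0 / k)
    q, _ = np.linalg.qr(basis[:, : k - 1])
    return q.T[:, :] if k > 1 else np.empty((0, k))


def _gg_epsilon(Y2d: np.ndarray, within: list[str], levels: list[list],
                effect: tuple[str, ...]) -> float:
    """Greenhouse-Geisser epsilon for one effect from subject x cell means.

    The cell covariance is transformed by the effect's Kronecker contrast
    (orthonormal factor contrasts for factors in the effect, normalized
    means for the rest); epsilon = tr(S)^2 / (d * tr(S^2)).
    """
    C = np.ones((1, 1))
    for f, lev in zip(within, levels):
        k = len(lev)
        M = _orthonormal_contrast(k) if f in effect else np.full((1, k), 1 / np.sqrt(k))
        C = np.kron(C, M)
    d = C.shape[0]
    if d <= 1:
        return 1.0
    D = Y2d @ C.T
    S = np.cov(D, rowvar=False)
    eps = np.trace(S) ** 2 / (d * np.sum(S * S))
    return float(np.clip(eps, 1.0 / d, 1.0))


def rm_anova(table: pd.DataFrame, dv: str, within: list[str],
             subject: str = "subject") -> pd.DataFrame:
    """Fully within-subject repeated-measures ANOVA on subject x cell means.

    Returns one row per effect (main effects and all interactions of the
    ``within`` factors) with F, degrees of freedom, p, generalized
    eta-squared (subject variance in the denominator), the
    Greenhouse-Geisser epsilon from the cell covariance matrix, and the
    GG-corrected p value.  Two-level effects have epsilon = 1 exactly.
    """
    Y, subjects, levels = _cell_array(table, dv, within, subject)
    n = len(subjects)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    factor_axes = {f: i + 1 for i, f in enumerate(within)}
    ss_subject = _ss(Y, (0,))
    effects = []
    for r in range(1, len(within) + 1):
        effects += list(itertools.combinations(within, r))
    ss_err_total = sum(_ss(Y, (0,) + tuple(factor_axes[f] for f in eff))
                       for eff in effects)
    Y2d = Y.reshape(n, -1)
    rows = []
    for eff in effects:
        axes = tuple(factor_axes[f] for f in eff)
        ss_e = _ss(Y, axes)
        ss_err = _ss(Y, (0,) + axes)
        df_e = int(np.prod([Y.shape[a] - 1 for a in axes]))
        df_err = (n - 1) * df_e
        ms_e, ms_err = ss_e / df_e, ss_err / df_err
        F = ms_e / ms_err if ms_err > 0 else (0.0 if ss_e == 0 else np.inf)
        p = float(stats.f.sf(F, df_e, df_err))
        ges = ss_e / (ss_e + ss_subject + ss_err_total) if (
            ss_e + ss_subject + ss_err_total) > 0 else 0.0
        eps = _gg_epsilon(Y2d, within, levels, eff)
        p_gg = float(stats.f.sf(F, eps * df_e, eps * df_err))
        rows.append(AnovaResult(effect=":".join(eff), F=float(F), df_num=df_e,
                                df_den=df_err, p=p, ges=float(ges),
                                gg_epsilon=eps, p_gg=p_gg))
    return pd.DataFrame([vars(r) for r in rows])


# ---------------------------------------------------------------------------
# pairwise comparisons

@dataclass
class PairwiseResult:
    contrast: str
    m_difference: float
    se: float
    t: float
    df: int
    p: float
    p_adjusted: float
    correction: str


def pairwise_comparisons(table: pd.DataFrame, dv: str, within: list[str],
                         subject: str = "subject",
                         correction: str = "bonferroni",
                         contrasts: list[tuple] | None = None
                         ) -> pd.DataFrame:
    """All pairwise cell-mean comparisons with a pooled within-subject error.

    The error term pools every condition-by-subject interaction, giving
    df = (n-1)(k-1) for k cells; SE of a difference is sqrt(2 MS/n).
    Bonferroni multiplies p by the number of comparisons (capped at 1).
    """
    Y, subjects, levels = _cell_array(table, dv, within, subject)
    n = len(subjects)
    Y2d = Y.reshape(n, -1)
    k = Y2d.shape[1]
    cells = list(itertools.product(*levels))
    labels = ["/".join(map(str, c)) for c in cells]
    # pooled error: residual after removing subject and cell means
    resid = Y2d - Y2d.mean(1, keepdims=True) - Y2d.mean(0, keepdims=True) + Y2d.mean()
    df_err = (n - 1) * (k - 1)
    ms = float((resid ** 2).sum() / df_err)
    means = Y2d.mean(0)
    if contrasts is None:
        pairs = list(itertools.combinations(range(k), 2))
    else:
        lab2i = {l: i for i, l in enumerate(labels)}
        for a, b in contrasts:
            if a not in lab2i or b not in lab2i:
                raise ValueError(f"unknown cell label in contrast ({a}, {b}); "
                                 f"known: {labels}")
        pairs = [(lab2i[a], lab2i[b]) for a, b in contrasts]
    m = len(pairs)
    rows = []
    for i, j in pairs:
        diff = means[i] - means[j]
        se = np.sqrt(2 * ms / n)
        t = diff / se if se > 0 else 0.0
        p = float(2 * stats.t.sf(abs(t), df_err)) if se > 0 else 1.0
        if correction == "bonferroni":
            p_adj = min(1.0, p * m)
        else:
            raise ValueError(f"unknown correction {correction!r}")
        rows.append(PairwiseResult(contrast=f"{labels[i]} - {labels[j]}",
                                   m_difference=float(diff), se=float(se),
                                   t=float(t), df=df_err, p=p,
                                   p_adjusted=float(p_adj), correction=correction))
    return pd.DataFrame([vars(r) for r in rows])


# ---------------------------------------------------------------------------
# covariates & correlations

def accuracy_covariates(table: pd.DataFrame, subject: str = "subject",
                        acc: str = "correct") -> pd.DataFrame:
    """Per-subject accuracy differences (percentage points).

    ``acc_sym_minus_asym`` and ``acc_low_minus_high``, the behavioral
    covariates carried into the group-level hemodynamic models.
    """
    rows = []
    for subj, sub in table.groupby(subject):
        for col, lv in (("symmetry", ("sym", "asym")), ("load", ("low", "high"))):
            for l in lv:
                if not (sub[col] == l).any():
                    raise ValueError(f"subject {subj} missing {col} level {l!r}")
        a = sub.groupby("symmetry")[acc].mean() * 100
        b = sub.groupby("load")[acc].mean() * 100
        rows.append({"subject": subj,
                     "acc_sym_minus_asym": float(a["sym"] - a["asym"]),
                     "acc_low_minus_high": float(b["low"] - b["high"])})
    return pd.DataFrame(rows)


def pearson_with_ci(x: np.ndarray, y: np.ndarray, conf: float = 0.95) -> dict:
    """Pearson r with t-test and Fisher-z confidence interval."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if np.std(x) == 0 or np.std(y) == 0:
        return {"r": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                "t": np.nan, "df": n - 2, "p": np.nan, "defined": False}
    r, p = stats.pearsonr(x, y)
    t = r * np.sqrt((n - 2) / (1 - r * r)) if abs(r) < 1 else np.inf
    if n > 3:
        z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        zc = stats.norm.ppf(0.5 + conf / 2) / np.sqrt(n - 3)
        ci_low, ci_high = float(np.tanh(z - zc)), float(np.tanh(z + zc))
    else:
        ci_low = ci_high = float("nan")  # Fisher z needs n > 3
    return {"r": float(r), "ci_low": ci_low, "ci_high": ci_high, "t": float(t),
            "df": n - 2, "p": float(p), "defined": True}


def complexity_correlation(table: pd.DataFrame,
                           scores: list[ComplexityScore] | None = None,
                           bytes_col: str = "compression_bytes",
                           probe_col: str = "probe_id") -> dict:
    """Pearson correlation of stimulus compression size with accuracy and RT.

    Trials are aggregated per probe stimulus (accuracy in %, mean correct
    RT); compression bytes come from ``scores`` or an existing column.
    """
    df = table.copy()
    if scores is not None:
        by_id = {s.stimulus_id: s.encoded_bytes for s in scores}
        df[bytes_col] = df[probe_col].map(by_id)
    per_stim = df.groupby(probe_col).agg(
        bytes=(bytes_col, "first"),
        accuracy=("correct", lambda c: 100 * np.mean(c)),
    )
    rt = df[df["correct"]].groupby(probe_col)["rt_ms"].mean()
    per_stim = per_stim.join(rt.rename("rt_ms"))
    out = {"accuracy": pearson_with_ci(per_stim["bytes"], per_stim["accuracy"])}
    ok = per_stim["rt_ms"].notna()
    out["rt"] = pearson_with_ci(per_stim.loc[ok, "bytes"], per_stim.loc[ok, "rt_ms"])
    return out


# ---------------------------------------------------------------------------
# tidy trial table

def build_trial_table(schedule: ExperimentSchedule,
                      records: list[ResponseRecord] | pd.DataFrame,
                      layout: LocationLayout,
                      scores: list[ComplexityScore] | None = None
                      ) -> pd.DataFrame:
    """Tidy per-trial table joining schedule, responses, and error geometry."""
    rec = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    trials = {t.trial_index: t for t in schedule.trials}
    by_id = {s.stimulus_id: s.encoded_bytes for s in scores} if scores else {}
    rows = []
    for _, r in rec.iterrows():
        tr = trials[r["trial_index"]]
        responded = bool(r["responded"])
        d_anchors = {a for sid, a in tr.item_locations.items() if sid != tr.probe_id}
        resp = ResponseRecord(**{k: r[k] for k in
                                 ("subject_id", "block", "trial_index",
                                  "chosen_anchor", "rt_ms", "correct", "responded")})
        rows.append({
            "subject": r["subject_id"], "block": tr.block,
            "trial_index": tr.trial_index,
            "symmetry": tr.symmetry_label, "load": tr.load_label,
            "symmetry_type": tr.probe_class, "probe_id": tr.probe_id,
            "correct": bool(r["correct"]), "rt_ms": r["rt_ms"],
            "distance_px": error_distance(resp, tr, layout) if responded else np.nan,
            "angle_deg": error_angle(resp, tr, layout) if responded else np.nan,
            "is_false_positive": bool(responded and not r["correct"]
                                      and r["chosen_anchor"] in d_anchors),
            "compression_bytes": by_id.get(tr.probe_id, np.nan),
            "responded": responded,
        })
    return pd.DataFrame(rows)
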