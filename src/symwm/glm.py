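"""Subject-level AR(1)-prewhitened GLM for hemoglobin time series.

The design matrix carries, per condition, a canonical double-gamma HRF
regressor plus its temporal and dispersion derivatives (events modelled
as 250 ms boxcars at encoding onsets), a discrete-cosine drift set up to
0.03 Hz, a constant, the mean short-channel signal per chromophore, and
z-scored heart-rate and SpO2 nuisance regressors.  Fitting is ordinary
least squares followed by per-channel lag-1 residual autocorrelation
estimation (Yule-Walker), prewhitening, and a GLS refit; condition
effects are read from the canonical columns only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import signal as sig
from scipy import stats

from .montage import Montage
from .schedule import CONDITIONS, EVENT_DURATION_S

HP_CUTOFF_HZ = 0.03


def _double_gamma(t: np.ndarray, peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                  peak_disp: float = 1.0, undershoot_disp: float = 1.0,
                  ratio: float = 1.0 / 6.0) -> np.ndarray:
    h = stats.gamma.pdf(t, a=peak_delay / peak_disp, scale=peak_disp) \
        - ratio * stats.gamma.pdf(t, a=undershoot_delay / undershoot_disp,
                                  scale=undershoot_disp)
    return h


def canonical_hrf_basis(fs: float, duration_s: float = 32.0) -> np.ndarray:
    """Sampled canonical HRF, temporal derivative, dispersion derivative.

    The canonical kernel is a difference of two gamma densities (peak
    delay 6 s, undershoot delay 16 s, unit dispersions, undershoot ratio
    1/6) normalized to unit peak.  The temporal derivative is the finite
    difference under a 1 s onset shift; the dispersion derivative the
    finite difference under a 0.01 change of peak dispersion.  Returns an
    array of shape (n_samples, 3).
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if duration_s < 20:
        warnings.warn("HRF window shorter than 20 s truncates the undershoot")
    t = np.arange(0, duration_s, 1.0 / fs)
    h = _double_gamma(t)
    scale = h.max()
    h = h / scale
    shifted = _double_gamma(t - 1.0) / scale
    td = (h - shifted) / 1.0
    dd = (h - _double_gamma(t, peak_disp=1.01) / scale) / 0.01
    return np.column_stack([h, td, dd])


def cosine_drift(n_samples: int, fs: float, cutoff_hz: float = HP_CUTOFF_HZ) -> np.ndarray:
    """DCT-II drift basis: K = floor(2*T*cutoff) columns, orthogonal to constant."""
    T = n_samples / fs
    K = int(np.floor(2 * T * cutoff_hz))
    i = np.arange(n_samples)
    cols = [np.cos(np.pi * k * (2 * i + 1) / (2 * n_samples)) for k in range(1, K + 1)]
    return np.column_stack(cols) if cols else np.empty((n_samples, 0))


def condition_regressors(events: pd.DataFrame, n_samples: int, fs: float,
                         basis: np.ndarray | None = None, oversample: int = 20,
                         conditions: tuple[str, ...] = CONDITIONS) -> pd.DataFrame:
    """HRF-convolved condition regressors (canonical + derivatives).

    Boxcars of the event duration are laid out on an oversampled grid,
    convolved with each basis kernel, and decimated to the acquisition
    rate; one column triplet per condition.
    """
    fs_hi = fs * oversample
    n_hi = n_samples * oversample
    if basis is None:
        basis_hi = canonical_hrf_basis(fs_hi)
    else:
        basis_hi = basis
    cols = {}
    for cond in conditions:
        box = np.zeros(n_hi)
        for _, ev in events[events["condition"] == cond].iterrows():
            a = int(round(ev["onset_s"] * fs_hi))
            b = int(round((ev["onset_s"] + ev["duration_s"]) * fs_hi))
            if a >= n_hi:
                raise ValueError(f"event at {ev['onset_s']} s beyond recording span")
            box[a:max(b, a + 1)] = 1.0
        for j, suffix in enumerate(("", "_tderiv", "_ddisp")):
            conv = sig.fftconvolve(box, basis_hi[:, j])[:n_hi] / fs_hi
            cols[f"{cond}{suffix}"] = conv[::oversample]
    return pd.DataFrame(cols)


@dataclass
class DesignMatrix:
    frame: pd.DataFrame
    condition_columns: list[str]  # canonical columns, one per condition
    condition_number: float

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)


def make_design_matrix(events: pd.DataFrame, n_samples: int, fs: float,
                       short_hbo: np.ndarray | None = None,
                       short_hbr: np.ndarray | None = None,
                       heart_rate: np.ndarray | None = None,
                       spo2: np.ndarray | None = None,
                       cutoff_hz: float = HP_CUTOFF_HZ,
                       conditions: tuple[str, ...] = CONDITIONS) -> DesignMatrix:
    """Assemble the full subject-level design matrix.

    Nuisance regressors: mean across short channels per chromophore
    (demeaned/z-scored), z-scored instantaneous heart rate from ECG, and
    z-scored SpO2.  Raises on rank deficiency, naming collinear columns.
    """
    regs = condition_regressors(events, n_samples, fs, conditions=conditions)
    # conditions absent from the event stream contribute empty columns
    present = tuple(c for c in conditions
                    if (events["condition"] == c).any())
    keep_cols = [col for col in regs.columns
                 if any(col == c or col.startswith(f"{c}_") for c in present)]
    parts = [regs[keep_cols]]
    drift = cosine_drift(n_samples, fs, cutoff_hz)
    parts.append(pd.DataFrame(drift, columns=[f"drift_{k + 1}" for k in range(drift.shape[1])]))
    parts.append(pd.DataFrame({"constant": np.ones(n_samples)}))

    def z(x):
        x = np.asarray(x, float)
        s = x.std()
        return (x - x.mean()) / s if s > 0 else x - x.mean()

    for name, series in (("short_hbo", short_hbo), ("short_hbr", short_hbr),
                         ("heart_rate", heart_rate), ("spo2", spo2)):
        if series is not None:
            if len(series) != n_samples:
                raise ValueError(f"{name} length {len(series)} != n_samples {n_samples}")
            parts.append(pd.DataFrame({name: z(series)}))
    frame = pd.concat(parts, axis=1)
    X = frame.to_numpy()
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns by QR pivoting
        _, R, piv = sla.qr(X, mode="economic", pivoting=True)
        bad = [frame.columns[p] for p in piv[rank:]]
        raise ValueError(f"design matrix rank deficient; collinear columns: {bad}")
    svals = np.linalg.svd(X, compute_uv=False)
    cond_cols = [c for c in present if c in frame.columns]
    return DesignMatrix(frame=frame, condition_columns=cond_cols,
                        condition_number=float(svals[0] / svals[-1]))


@dataclass
class SubjectGlmResult:
    """Per-channel AR(1)-GLS estimates for one chromophore set."""

    beta: pd.DataFrame          # channels x columns (µM for condition columns)
    se: pd.DataFrame
    t: pd.DataFrame
    rho: pd.Series              # per-channel AR(1) coefficient
    dof: int
    cov_condition: np.ndarray   # (n_channels, n_cond, n_cond) canonical-column cov
    condition_columns: list[str]
    channel_ids: list[str] = field(default_factory=list)

    def condition_effects(self) -> pd.DataFrame:
        return self.beta[self.condition_columns]


def fit_ar1_glm(Y: np.ndarray, design: DesignMatrix,
                channel_ids: list[str] | None = None) -> SubjectGlmResult:
    """AR(1)-prewhitened GLM fit of each column of Y on the design matrix.

    OLS residuals give a per-channel lag-1 autocorrelation rho
    (Yule-Walker); rows are whitened (first row scaled by sqrt(1-rho^2),
    then y*_t = y_t - rho y_{t-1}) and the model refit by least squares
    on the whitened system.  dof = n_rows - n_columns.
    """
    X = design.values
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("Y and design matrix row counts differ")
    nch = Y.shape[1]
    if channel_ids is None:
        channel_ids = [f"ch{i}" for i in range(nch)]
    beta_ols, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta_ols
    num = (resid[1:] * resid[:-1]).sum(axis=0)
    den = (resid ** 2).sum(axis=0)
    rho = np.divide(num, den, out=np.zeros(nch), where=den > 0)
    if (np.abs(rho) >= 1).any():
        warnings.warn("AR(1) coefficient at or beyond unit root; clipped to 0.99")
        rho = np.clip(rho, -0.99, 0.99)
    cond_ix = [design.columns.index(c) for c in design.condition_columns]
    betas = np.empty((nch, p))
    ses = np.empty((nch, p))
    cov_cond = np.empty((nch, len(cond_ix), len(cond_ix)))
    dof = n - p
    # whitened normal equations from precomputed cross-products:
    # Xw'Xw = X1'X1 - r (X1'X0 + X0'X1) + r^2 X0'X0 + (1-r^2) x0 x0'
    X1, X0 = X[1:], X[:-1]
    x0 = X[0]
    A11 = X1.T @ X1
    A10 = X1.T @ X0
    A00 = X0.T @ X0
    A10s = A10 + A10.T
    Oxx = np.outer(x0, x0)
    Y1, Y0 = Y[1:], Y[:-1]
    C11 = X1.T @ Y1      # (p, nch)
    C10 = X1.T @ Y0
    C01 = X0.T @ Y1
    C00 = X0.T @ Y0
    yy11 = (Y1 * Y1).sum(axis=0)
    yy10 = (Y1 * Y0).sum(axis=0)
    yy00 = (Y0 * Y0).sum(axis=0)
    for j in range(nch):
        r = rho[j]
        s2 = 1 - r * r
        G = A11 - r * A10s + r * r * A00 + s2 * Oxx
        c = C11[:, j] - r * (C10[:, j] + C01[:, j]) + r * r * C00[:, j] \
            + s2 * x0 * Y[0, j]
        Ginv = np.linalg.inv(G)
        b = Ginv @ c
        ytyw = yy11[j] - 2 * r * yy10[j] + r * r * yy00[j] + s2 * Y[0, j] ** 2
        rss = max(float(ytyw - b @ c), 0.0)
        sigma2 = rss / dof
        cov = sigma2 * Ginv
        betas[j] = b
        ses[j] = np.sqrt(np.maximum(np.diag(cov), 0))
        cov_cond[j] = cov[np.ix_(cond_ix, cond_ix)]
    cols = design.columns
    beta_df = pd.DataFrame(betas, index=channel_ids, columns=cols)
    se_df = pd.DataFrame(ses, index=channel_ids, columns=cols)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_df = beta_df / se_df
    return SubjectGlmResult(beta=beta_df, se=se_df, t=t_df,
                            rho=pd.Series(rho, index=channel_ids), dof=dof,
                            cov_condition=cov_cond,
                            condition_columns=list(design.condition_columns),
                            channel_ids=list(channel_ids))


@dataclass(frozen=True)
class ContrastSpec:
    name: str
    weights: dict[str, float]   # condition column -> weight


#: standard contrasts over the four task conditions
SYMMETRY_CONTRAST = ContrastSpec("symmetry - asymmetry", {
    "sym_low": 0.5, "sym_high": 0.5, "asym_low": -0.5, "asym_high": -0.5})
LOAD_CONTRAST = ContrastSpec("high - low load", {
    "sym_high": 0.5, "asym_high": 0.5, "sym_low": -0.5, "asym_low": -0.5})
INTERACTION_CONTRAST = ContrastSpec("symmetry x load", {
    "sym_high": 1.0, "sym_low": -1.0, "asym_high": -1.0, "asym_low": 1.0})


def compute_contrast(result: SubjectGlmResult, spec: ContrastSpec) -> pd.DataFrame:
    """Per-channel contrast effect w'beta, its variance w'Cov(beta)w, and t."""
    missing = [c for c in spec.weights if c not in result.condition_columns]
    if missing:
        raise ValueError(f"contrast references unknown condition columns: {missing}")
    w = np.array([spec.weights.get(c, 0.0) for c in result.condition_columns])
    B = result.beta[result.condition_columns].to_numpy()
    eff = B @ w
    var = np.einsum("i,kij,j->k", w, result.cov_condition, w)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, eff / np.sqrt(var), 0.0)
    return pd.DataFrame({"channel_id": result.channel_ids, "effect": eff,
                         "variance": var, "t": t})


def roi_aggregate(result: SubjectGlmResult, montage: Montage,
                  values: pd.DataFrame | None = None) -> pd.DataFrame:
    """Unweighted ROI-group means of per-channel condition effects.

    ``values`` defaults to the canonical condition betas; empty ROI
    groups after exclusions are flagged with n_channels = 0 and NaN.
    """
    if values is None:
        values = result.condition_effects()
    grp_of = {c.channel_id: c.roi_group for c in montage.long_channels}
    rows = []
    groups = sorted({g for g in grp_of.values()})
    for g in groups:
        ids = [cid for cid in values.index if grp_of.get(cid) == g]
        if ids:
            m = values.loc[ids].mean(axis=0)
            rows.append({"roi_group": g, "n_channels": len(ids),
                         **{k: float(v) for k, v in m.items()}})
        else:
            rows.append({"roi_group": g, "n_channels": 0,
                         **{k: np.nan for k in values.columns}})
    return pd.DataFrame(rows)
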