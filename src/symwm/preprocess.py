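"""fNIRS preprocessing: OD conversion, SCI/CV quality control, TDDR, Beer-Lambert.

The chain converts raw dual-wavelength intensity to optical density,
scores optode-scalp coupling per channel (scalp coupling index from the
cardiac band; coefficient of variation of raw intensity), excludes bad
channels (and subjects with more than 20% bad channels), repairs spike
and baseline-shift motion artifacts with temporal derivative
distribution repair, and converts OD to oxy-/deoxyhemoglobin
concentration changes via the modified Beer-Lambert law with a partial
pathlength factor of 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sig

from .montage import Montage

#: molar extinction coefficients, cm^-1 M^-1 (Gratzer/Prahl compendium,
#: as tabulated in the HOMER GetExtinctions table), rows = (760, 850) nm,
#: columns = (HbO, HbR)
EXTINCTION_CM_M = np.array([
    [1486.5865, 3843.707],
    [2526.391, 1798.643],
])

SCI_BAND_HZ = (0.7, 1.5)
DEFAULT_SCI_THRESHOLD = 0.05
SUBJECT_BAD_FRACTION = 0.20


@dataclass
class ChannelQuality:
    channel_id: str
    sci: float
    cv_percent: tuple[float, float]  # per wavelength
    kept: bool = True
    reason: str = ""


def intensity_to_od(intensity: np.ndarray) -> np.ndarray:
    """Optical density: OD(t) = -log10(I(t) / mean_t I), per channel/wavelength.

    ``intensity`` has shape (time, channel, wavelength) and must be
    strictly positive; the reference is the whole-recording mean, which
    makes OD invariant to multiplicative intensity scaling.
    """
    I = np.asarray(intensity, dtype=float)
    if (I <= 0).any():
        bad = np.argwhere((I <= 0).any(axis=0))
        raise ValueError(f"nonpositive intensity in channel/wavelength {bad[0].tolist()}")
    return -np.log10(I / I.mean(axis=0, keepdims=True))


def _bandpass(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    nyq = fs / 2.0
    lo, hi = band
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band} outside (0, Nyquist={nyq:.3g}) Hz")
    sos = sig.butter(3, [lo / nyq, hi / nyq], btype="band", output="sos")
    return sig.sosfiltfilt(sos, x, axis=0)


def scalp_coupling_index(od: np.ndarray, fs: float,
                         band: tuple[float, float] = SCI_BAND_HZ) -> np.ndarray:
    """Cardiac-band cross-wavelength correlation per channel.

    The heartbeat is optical, not neural: if the optode couples to the
    scalp, both wavelengths carry the same cardiac oscillation, so their
    band-passed (0.7-1.5 Hz) OD traces correlate strongly.  Returns the
    zero-lag Pearson correlation per channel, in [-1, 1].
    """
    if od.shape[0] / fs <= 10:
        raise ValueError("recording shorter than 10 s: SCI unreliable")
    f = _bandpass(od, fs, band)
    a, b = f[:, :, 0], f[:, :, 1]
    a = a - a.mean(0)
    b = b - b.mean(0)
    denom = np.sqrt((a ** 2).sum(0) * (b ** 2).sum(0))
    with np.errstate(invalid="ignore"):
        return np.where(denom > 0, (a * b).sum(0) / denom, 0.0)


def coefficient_of_variation(intensity: np.ndarray) -> np.ndarray:
    """CV (%) = 100 * SD / mean of raw intensity, per channel and wavelength."""
    I = np.asarray(intensity, dtype=float)
    m = I.mean(axis=0)
    if (m == 0).any():
        raise ValueError("zero-mean intensity channel")
    return 100.0 * I.std(axis=0) / m


def compute_channel_quality(intensity: np.ndarray, fs: float,
                            montage: Montage) -> list[ChannelQuality]:
    od = intensity_to_od(intensity)
    sci = scalp_coupling_index(od, fs)
    cv = coefficient_of_variation(intensity)
    return [ChannelQuality(channel_id=c.channel_id, sci=float(sci[i]),
                           cv_percent=(float(cv[i, 0]), float(cv[i, 1])))
            for i, c in enumerate(montage.channels)]


def apply_quality_exclusion(quality: list[ChannelQuality],
                            sci_threshold: float = DEFAULT_SCI_THRESHOLD,
                            cv_rule: str = "adaptive",
                            cv_fixed_percent: float = 7.5,
                            combine: str = "or") -> tuple[list[ChannelQuality], bool]:
    """Partition channels into kept/excluded and flag subject-level exclusion.

    A channel fails when SCI < ``sci_threshold`` or its CV (worst of the
    two wavelengths) exceeds the across-channel CV distribution's
    mean + 2 SD (``cv_rule='adaptive'``) or a fixed percentage
    (``cv_rule='fixed'``).  ``combine='and'`` requires both failures.
    The subject is flagged for exclusion when more than 20% of channels
    fail.  Mutates and returns the quality records.
    """
    worst_cv = np.array([max(q.cv_percent) for q in quality])
    if cv_rule == "adaptive":
        cv_bound = worst_cv.mean() + 2 * worst_cv.std(ddof=0)
    elif cv_rule == "fixed":
        cv_bound = cv_fixed_percent
    else:
        raise ValueError(f"unknown cv_rule {cv_rule!r}")
    for q, cv in zip(quality, worst_cv):
        bad_sci = q.sci < sci_threshold
        bad_cv = cv > cv_bound
        bad = (bad_sci or bad_cv) if combine == "or" else (bad_sci and bad_cv)
        q.kept = not bad
        q.reason = "" if not bad else ";".join(
            s for s, b in (("sci", bad_sci), ("cv", bad_cv)) if b)
    frac_bad = np.mean([not q.kept for q in quality])
    return quality, bool(frac_bad > SUBJECT_BAD_FRACTION)


def tddr(od: np.ndarray, fs: float) -> np.ndarray:
    """Temporal derivative distribution repair of motion artifacts.

    Per channel: the signal is split at 0.5 Hz; on the low-frequency
    component's first differences an iterative robust scheme (Tukey
    biweight, tuning 4.685, scale 1.4826*MAD) downweights outlying
    derivatives; the weighted, centered derivatives are re-integrated,
    the initial value restored, and the high-frequency residual added
    back.  Spikes and baseline shifts produce extreme derivatives and
    are strongly attenuated; smooth signals pass through nearly
    unchanged.
    """
    x = np.asarray(od, dtype=float)
    single = x.ndim == 1
    flat = x.reshape(x.shape[0], -1)
    if flat.shape[0] < 3:
        raise ValueError("series too short for TDDR")
    out = np.empty_like(flat)
    nyq = fs / 2.0
    if 0.5 < nyq:
        sos = sig.butter(3, 0.5 / nyq, btype="low", output="sos")
        low = sig.sosfiltfilt(sos, flat, axis=0)
    else:
        low = flat.copy()
    high = flat - low
    tune = 4.685
    for j in range(flat.shape[1]):
        d = np.diff(low[:, j])
        w = np.ones_like(d)
        mu = 0.0
        for _ in range(50):
            mu = np.sum(w * d) / np.sum(w)
            r = d - mu
            sigma = 1.4826 * np.median(np.abs(r))
            if sigma == 0:
                w_new = np.ones_like(d)
                mu = 0.0
                break
            u = r / (tune * sigma)
            w_new = np.where(np.abs(u) < 1, (1 - u ** 2) ** 2, 0.0)
            if np.max(np.abs(w_new - w)) < 1e-6:
                w = w_new
                break
            w = w_new
        d_rep = w * (d - mu)
        rep = np.concatenate([[low[0, j]], low[0, j] + np.cumsum(d_rep)])
        out[:, j] = rep + high[:, j]
    return out[:, 0] if single else out.reshape(x.shape)


def modified_beer_lambert(od: np.ndarray, montage: Montage,
                          extinction: np.ndarray = EXTINCTION_CM_M,
                          ppf: float = 1.0,
                          channel_mask: np.ndarray | None = None,
                          which: str = "long"
                          ) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Convert OD to hemoglobin concentration changes (µM).

    For each channel, [dHbO; dHbR] = E^-1 @ [OD_760/(d*ppf); OD_850/(d*ppf)]
    with E the 2x2 extinction matrix (cm^-1 M^-1), d the source-detector
    separation in cm, solutions scaled from molar to µM.  ``which``
    selects long (default), short, or all channels; ``channel_mask``
    further restricts to kept channels.  Returns (hbo, hbr) arrays of
    shape (time, n_selected) and the montage indices of the included
    channels.
    """
    if which not in ("long", "short", "all"):
        raise ValueError(f"unknown channel selection {which!r}")
    E = np.asarray(extinction, dtype=float)
    if abs(np.linalg.det(E)) < 1e-12:
        raise ValueError("extinction matrix is singular")
    Einv = np.linalg.inv(E)
    idx = [i for i, c in enumerate(montage.channels)
           if (which == "all" or c.is_short == (which == "short"))
           and (channel_mask is None or channel_mask[i])]
    hbo = np.empty((od.shape[0], len(idx)))
    hbr = np.empty_like(hbo)
    for k, i in enumerate(idx):
        d_cm = montage.channels[i].separation_mm / 10.0
        rhs = od[:, i, :].T / (d_cm * ppf)        # (2, time)
        conc_m = Einv @ rhs                        # molar
        hbo[:, k] = conc_m[0] * 1e6
        hbr[:, k] = conc_m[1] * 1e6
    return hbo, hbr, idx


def forward_od(hbo_um: np.ndarray, hbr_um: np.ndarray, separation_mm: float,
               extinction: np.ndarray = EXTINCTION_CM_M, ppf: float = 1.0
               ) -> np.ndarray:
    """Forward Beer-Lambert: Hb (µM) -> OD per wavelength, shape (time, 2)."""
    d_cm = separation_mm / 10.0
    conc_m = np.stack([hbo_um, hbr_um], axis=-1) * 1e-6
    return conc_m @ np.asarray(extinction, float).T * d_cm * ppf
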