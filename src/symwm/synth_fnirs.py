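"""Forward simulation of dual-wavelength fNIRS recordings.

Given an experiment schedule and known per-channel condition amplitudes
(the ground truth), the simulator builds hemoglobin time series (HRF-
convolved condition responses on long channels, systemic physiology on
all channels), converts them to optical intensity through the Beer-
Lambert forward model, injects spike and baseline-shift motion
artifacts, and produces consistent auxiliary traces (heart rate from
ECG, SpO2, PPG).  Everything needed to test the preprocessing/GLM/group
chain by parameter recovery is logged in the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import condition_regressors
from .montage import (CONTROL_ROI_GROUPS, Montage, TASK_ROI_GROUPS,
                      build_default_montage)
from .preprocess import EXTINCTION_CM_M, forward_od
from .schedule import CONDITIONS

FS_HZ = 5.08

#: default condition HbO amplitudes (µM model units) per ROI kind.  Task
#: ROIs carry a symmetry x load interaction; control and other ROIs a
#: condition-independent response.
DEFAULT_TASK_BETAS = {"sym_low": 4.0, "sym_high": 10.0,
                      "asym_low": 5.0, "asym_high": 6.0}
DEFAULT_FLAT_BETAS = {c: 5.0 for c in CONDITIONS}
HBR_RATIO = -1.0 / 3.0


@dataclass
class PhysioParams:
    heart_rate_hz: float = 1.1
    heart_rate_wander_hz: float = 0.05   # slow modulation of the rate itself
    cardiac_amp_um: float = 0.4
    respiration_hz: float = 0.25
    respiration_amp_um: float = 0.25
    mayer_hz: float = 0.1
    mayer_amp_um: float = 0.3
    drift_amp_um: float = 0.5            # linear drift over the recording
    random_walk_um: float = 0.01         # per-step random walk SD
    noise_sd_um: float = 1.0             # white measurement noise (Hb scale)
    # pulsatile/systemic physiology co-modulates HbO and HbR with the
    # same sign (unlike the neurovascular -1/3 coupling of evoked responses)
    hbr_systemic_ratio: float = 0.3


@dataclass
class ArtifactParams:
    spike_rate_per_min: float = 0.5
    spike_amp_sd_mult: float = 10.0      # spike amplitude in noise-SD units
    spike_width_s: float = 2.0           # motion transients of ~1-2 s
    shift_rate_per_min: float = 0.2
    shift_amp_sd_mult: float = 8.0


@dataclass
class GroundTruth:
    """Known simulation parameters for parameter-recovery testing."""

    beta_true: pd.DataFrame              # channels x conditions, HbO µM
    hbr_ratio: float
    physio: PhysioParams
    artifacts: ArtifactParams
    artifact_log: pd.DataFrame = field(default_factory=pd.DataFrame)
    systemic_um: np.ndarray | None = field(default=None, repr=False)


@dataclass
class RawRecording:
    intensity: np.ndarray                # (time, channel, wavelength), a.u. > 0
    fs: float
    events: pd.DataFrame
    montage: Montage
    aux: dict[str, np.ndarray] = field(default_factory=dict)


def default_ground_truth(montage: Montage | None = None,
                         physio: PhysioParams | None = None,
                         artifacts: ArtifactParams | None = None) -> GroundTruth:
    """Default truth: interaction in dlPFC/OFC/PPC/LOC, flat response elsewhere."""
    montage = montage or build_default_montage()
    rows = []
    for c in montage.long_channels:
        betas = DEFAULT_TASK_BETAS if c.roi_group in TASK_ROI_GROUPS else DEFAULT_FLAT_BETAS
        rows.append({"channel_id": c.channel_id, **betas})
    beta = pd.DataFrame(rows).set_index("channel_id")
    return GroundTruth(beta_true=beta, hbr_ratio=HBR_RATIO,
                       physio=physio or PhysioParams(),
                       artifacts=artifacts or ArtifactParams())


def _systemic_components(n: int, fs: float, p: PhysioParams,
                         rng: np.random.Generator) -> dict[str, np.ndarray]:
    from scipy import signal as sig
    t = np.arange(n) / fs
    hr = p.heart_rate_hz + 0.05 * np.sin(2 * np.pi * p.heart_rate_wander_hz * t) \
        + 0.01 * rng.standard_normal(n).cumsum() / np.sqrt(n)
    hr = np.clip(hr, 0.6, 2.0)
    phase = 2 * np.pi * np.cumsum(hr) / fs
    cardiac = np.sin(phase)
    resp = np.sin(2 * np.pi * p.respiration_hz * t + rng.uniform(0, 2 * np.pi))
    # Mayer waves are a broadband low-frequency oscillation, not a pure
    # tone: band-limited noise centered on p.mayer_hz, unit SD
    lo, hi = max(p.mayer_hz - 0.05, 0.01), p.mayer_hz + 0.05
    sos = sig.butter(3, [lo / (fs / 2), hi / (fs / 2)], btype="band", output="sos")
    mayer = sig.sosfiltfilt(sos, rng.standard_normal(n))
    s = mayer.std()
    if s > 0:
        mayer = mayer / s
    return {"t": t, "heart_rate": hr, "cardiac": cardiac,
            "respiration": resp, "mayer": mayer}


def simulate_recording(montage: Montage, events: pd.DataFrame,
                       truth: GroundTruth, rng_seed: int,
                       fs: float = FS_HZ, tail_s: float = 25.0,
                       baseline_intensity: float = 1.0
                       ) -> tuple[RawRecording, GroundTruth]:
    """Simulate a raw dual-wavelength recording for one subject.

    Long channels carry condition-locked hemodynamic responses
    (beta_true x canonical HRF convolved with 250 ms event boxcars) plus
    shared systemic physiology (cardiac, respiration, Mayer wave, drift)
    and white noise; short channels carry systemic signal and noise
    only, so condition-locked variance in them is zero by construction.
    Hb series are pushed through the Beer-Lambert forward model to
    intensity; spike and baseline-shift artifacts are injected in OD
    space and logged.  Deterministic given ``rng_seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 31415]))
    p = truth.physio
    n = int(np.ceil((events["onset_s"].max() + tail_s) * fs))
    sysc = _systemic_components(n, fs, p, rng)
    # one condition-regressor set shared by all channels
    regs = condition_regressors(events, n, fs)
    R = regs[[c for c in CONDITIONS]].to_numpy()       # (n, 4) canonical only

    nch = len(montage.channels)
    hbo = np.zeros((n, nch))
    hbr = np.zeros((n, nch))
    long_ix = {c.channel_id: i for i, c in enumerate(montage.channels) if not c.is_short}
    t = sysc["t"]
    artifact_rows = []
    for i, ch in enumerate(montage.channels):
        gain = 1.0 + 0.2 * rng.standard_normal()
        systemic = (p.cardiac_amp_um * sysc["cardiac"]
                    + p.respiration_amp_um * sysc["respiration"]
                    + p.mayer_amp_um * sysc["mayer"]) * gain
        drift = p.drift_amp_um * (t / t[-1] - 0.5) * rng.standard_normal() \
            + p.random_walk_um * rng.standard_normal(n).cumsum()
        s_hbo = systemic + drift + p.noise_sd_um * rng.standard_normal(n)
        s_hbr = p.hbr_systemic_ratio * (systemic + drift) \
            + p.noise_sd_um / 3.0 * rng.standard_normal(n)
        if not ch.is_short:
            b = truth.beta_true.loc[ch.channel_id, list(CONDITIONS)].to_numpy(float)
            evoked = R @ b
            s_hbo = s_hbo + evoked
            s_hbr = s_hbr + truth.hbr_ratio * evoked
        hbo[:, i] = s_hbo
        hbr[:, i] = s_hbr

    # Beer-Lambert forward model to intensity
    intensity = np.empty((n, nch, 2))
    for i, ch in enumerate(montage.channels):
        od = forward_od(hbo[:, i], hbr[:, i], ch.separation_mm,
                        extinction=EXTINCTION_CM_M, ppf=1.0)
        intensity[:, i, :] = baseline_intensity * 10.0 ** (-od)

    # motion artifacts in OD space (shared across wavelengths, as motion is)
    a = truth.artifacts
    minutes = n / fs / 60.0
    od_sd = np.abs(np.log10(intensity / intensity.mean(0))).std()
    for i, ch in enumerate(montage.channels):
        n_spk = rng.poisson(a.spike_rate_per_min * minutes)
        n_shf = rng.poisson(a.shift_rate_per_min * minutes)
        for _ in range(n_spk):
            at = rng.integers(5, n - 5)
            width = max(1, int(a.spike_width_s * fs / 2))
            amp = a.spike_amp_sd_mult * od_sd * rng.choice([-1, 1])
            kern = amp * np.exp(-0.5 * ((np.arange(n) - at) / width) ** 2)
            intensity[:, i, :] *= 10.0 ** (-kern[:, None])
            artifact_rows.append({"channel_id": ch.channel_id, "kind": "spike",
                                  "time_s": at / fs, "amplitude_od": amp})
        for _ in range(n_shf):
            at = rng.integers(5, n - 5)
            amp = a.shift_amp_sd_mult * od_sd * rng.choice([-1, 1])
            step = np.zeros(n)
            step[at:] = amp
            intensity[:, i, :] *= 10.0 ** (-step[:, None])
            artifact_rows.append({"channel_id": ch.channel_id, "kind": "shift",
                                  "time_s": at / fs, "amplitude_od": amp})
    if (intensity <= 0).any():
        import warnings
        warnings.warn("nonpositive simulated intensity clipped")
        intensity = np.clip(intensity, 1e-9, None)

    spo2 = 98.0 + 0.5 * np.sin(2 * np.pi * 0.01 * t + rng.uniform(0, 2 * np.pi)) \
        + 0.1 * rng.standard_normal(n)
    aux = {"heart_rate": sysc["heart_rate"], "spo2": spo2,
           "ppg": sysc["cardiac"] + 0.05 * rng.standard_normal(n)}
    truth.artifact_log = pd.DataFrame(
        artifact_rows, columns=["channel_id", "kind", "time_s", "amplitude_od"])
    truth.systemic_um = (p.cardiac_amp_um * sysc["cardiac"]
                         + p.respiration_amp_um * sysc["respiration"]
                         + p.mayer_amp_um * sysc["mayer"])
    rec = RawRecording(intensity=intensity, fs=fs, events=events.copy(),
                       montage=montage, aux=aux)
    return rec, truth


def forward_hb_to_intensity(hbo_um: np.ndarray, hbr_um: np.ndarray,
                            montage: Montage, baseline_intensity: float = 1.0,
                            extinction: np.ndarray = EXTINCTION_CM_M,
                            ppf: float = 1.0) -> np.ndarray:
    """Noiseless Beer-Lambert forward model for all channels.

    ``hbo_um``/``hbr_um`` have shape (time, n_channels); returns
    intensity (time, n_channels, 2) with I = I0 * 10^(-OD).
    """
    if baseline_intensity <= 0:
        raise ValueError("baseline intensity must be positive")
    n, nch = hbo_um.shape
    out = np.empty((n, nch, 2))
    for i, ch in enumerate(montage.channels):
        od = forward_od(hbo_um[:, i], hbr_um[:, i], ch.separation_mm,
                        extinction=extinction, ppf=ppf)
        out[:, i, :] = baseline_intensity * 10.0 ** (-od)
    return out
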