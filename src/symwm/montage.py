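"""Channel montage for the whole-head dual-wavelength fNIRS setup.

116 channels at 760/850 nm: 100 long channels (30 mm source-detector
separation) assigned to regions of interest, plus 16 short-separation
channels (8 mm) that sample extracerebral scalp physiology only and are
used as nuisance regressors.
"""

from __future__ import annotations

from dataclasses import dataclass

WAVELENGTHS_NM = (760.0, 850.0)
LONG_SEPARATION_MM = 30.0
SHORT_SEPARATION_MM = 8.0

#: long-channel counts per ROI label; prefrontal sub-regions sum to 32,
#: PPC 15, LOC 13, motor 18, early visual 8, remainder "other"
ROI_COUNTS = {
    "dlPFC_L": 6, "dlPFC_R": 6, "vlPFC_L": 4, "vlPFC_R": 4, "mPFC": 4,
    "OFC_L": 4, "OFC_R": 4,
    "PPC_L": 8, "PPC_R": 7,
    "LOC_L": 7, "LOC_R": 6,
    "motor_L": 9, "motor_R": 9,
    "early_visual": 8,
    "other": 14,
}

#: laterality-collapsed grouping used by ROI-level group inference
ROI_GROUPS = {
    "dlPFC": ("dlPFC_L", "dlPFC_R"),
    "vlPFC": ("vlPFC_L", "vlPFC_R"),
    "mPFC": ("mPFC",),
    "OFC": ("OFC_L", "OFC_R"),
    "PPC": ("PPC_L", "PPC_R"),
    "LOC": ("LOC_L", "LOC_R"),
    "motor": ("motor_L", "motor_R"),
    "early_visual": ("early_visual",),
    "other": ("other",),
}

#: ROI groups carrying a true symmetry x load interaction in the default
#: simulation truth, and the control groups that do not
TASK_ROI_GROUPS = ("dlPFC", "OFC", "PPC", "LOC")
CONTROL_ROI_GROUPS = ("motor", "early_visual")


@dataclass(frozen=True)
class Channel:
    channel_id: str
    source_id: int
    detector_id: int
    separation_mm: float
    roi: str
    is_short: bool

    @property
    def roi_group(self) -> str:
        for g, members in ROI_GROUPS.items():
            if self.roi in members:
                return g
        return "other"


@dataclass
class Montage:
    channels: list[Channel]
    wavelengths: tuple[float, float] = WAVELENGTHS_NM

    def __len__(self) -> int:
        return len(self.channels)

    @property
    def long_channels(self) -> list[Channel]:
        return [c for c in self.channels if not c.is_short]

    @property
    def short_channels(self) -> list[Channel]:
        return [c for c in self.channels if c.is_short]

    def channels_in_group(self, group: str) -> list[Channel]:
        return [c for c in self.long_channels if c.roi_group == group]

    def index_of(self, channel_id: str) -> int:
        for i, c in enumerate(self.channels):
            if c.channel_id == channel_id:
                return i
        raise KeyError(channel_id)


def build_default_montage() -> Montage:
    """The default 116-channel montage: 100 long + 16 short channels.

    Source/detector indices are synthetic bookkeeping (32 sources, 32
    long detectors, 16 short detectors); ROI labels follow the stated
    per-region channel counts.
    """
    channels: list[Channel] = []
    ch = 0
    for roi, count in ROI_COUNTS.items():
        for _ in range(count):
            channels.append(Channel(
                channel_id=f"CH{ch + 1:03d}",
                source_id=ch % 32 + 1, detector_id=(ch * 7) % 32 + 1,
                separation_mm=LONG_SEPARATION_MM, roi=roi, is_short=False))
            ch += 1
    for k in range(16):
        channels.append(Channel(
            channel_id=f"SS{k + 1:02d}",
            source_id=(2 * k) % 32 + 1, detector_id=33 + k,
            separation_mm=SHORT_SEPARATION_MM, roi="short", is_short=True))
    return Montage(channels=channels)
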