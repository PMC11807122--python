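"""Binary matrix stimuli and compression-based complexity scoring.

Stimuli are 6x6 black-and-white grids with exactly 50% black cells
(18 of 36).  Symmetric stimuli are mirror-invariant across one axis
(vertical, horizontal, or the main diagonal); asymmetric stimuli are
invariant under no reflection.  Visual complexity is quantified by the
byte size of a lossy JPEG encoding of the rendered grid: symmetric
(redundant) patterns compress into smaller files than asymmetric ones.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import stats

GRID_SIZE = 6
N_CELLS = GRID_SIZE * GRID_SIZE
N_BLACK = N_CELLS // 2  # 50% black

SYMMETRY_CLASSES = ("asymmetric", "vertical", "horizontal", "diagonal")

#: default JPEG rendering parameters for complexity scoring
DEFAULT_ENCODER_SETTINGS = {
    "cell_px": 50,          # each cell rendered as a 50x50 block -> 300x300 image
    "quality": 75,
    "grayscale": True,
    "subsampling": 0,       # no chroma subsampling
}


@dataclass(frozen=True)
class StimulusMatrix:
    """A single 6x6 binary stimulus (0 = white, 1 = black)."""

    stimulus_id: str
    grid: np.ndarray
    symmetry_class: str

    def __post_init__(self):
        g = np.asarray(self.grid)
        if g.shape != (GRID_SIZE, GRID_SIZE):
            raise ValueError(f"grid must be {GRID_SIZE}x{GRID_SIZE}, got {g.shape}")
        if not np.isin(g, (0, 1)).all():
            raise ValueError("grid cells must be 0 or 1")
        object.__setattr__(self, "grid", g.astype(np.int8))


@dataclass
class StimulusSet:
    """The 72-stimulus experimental set: 36 asymmetric + 12 per symmetry axis."""

    stimuli: list[StimulusMatrix]
    rng_seed: int

    def by_class(self, symmetry_class: str) -> list[StimulusMatrix]:
        return [s for s in self.stimuli if s.symmetry_class == symmetry_class]

    def ids(self) -> list[str]:
        return [s.stimulus_id for s in self.stimuli]

    def __len__(self) -> int:
        return len(self.stimuli)


@dataclass(frozen=True)
class ComplexityScore:
    stimulus_id: str
    encoded_bytes: int
    encoder_settings: dict = field(default_factory=dict)


def classify_symmetry(grid: np.ndarray) -> dict:
    """Per-axis reflection-invariance flags and the derived symmetry class.

    Returns a dict with boolean flags ``vertical`` (left-right mirror),
    ``horizontal`` (top-bottom mirror), ``diag_main`` (transpose), and
    ``diag_anti`` (anti-transpose), plus ``symmetry_class``: ``asymmetric``
    when all flags are false, otherwise the first true axis in the order
    vertical, horizontal, diagonal.
    """
    g = np.asarray(grid)
    if g.shape != (GRID_SIZE, GRID_SIZE):
        raise ValueError(f"grid must be {GRID_SIZE}x{GRID_SIZE}, got {g.shape}")
    if not np.isin(g, (0, 1)).all():
        raise ValueError("grid cells must be 0 or 1")
    flags = {
        "vertical": bool(np.array_equal(g, g[:, ::-1])),
        "horizontal": bool(np.array_equal(g, g[::-1, :])),
        "diag_main": bool(np.array_equal(g, g.T)),
        "diag_anti": bool(np.array_equal(g, g[::-1, ::-1].T)),
    }
    if not any(flags.values()):
        cls = "asymmetric"
    elif flags["vertical"]:
        cls = "vertical"
    elif flags["horizontal"]:
        cls = "horizontal"
    else:
        cls = "diagonal"
    flags["symmetry_class"] = cls
    return flags


def _substream(rng_seed: int, *stream: int) -> np.random.Generator:
    # counter-based substream: set generation is order-independent
    return np.random.default_rng(np.random.SeedSequence([int(rng_seed), *stream]))


def _only_declared_axis(g: np.ndarray, axis: str) -> bool:
    f = classify_symmetry(g)
    wanted = {
        "vertical": ("vertical",),
        "horizontal": ("horizontal",),
        "diagonal": ("diag_main",),
    }[axis]
    for k in ("vertical", "horizontal", "diag_main", "diag_anti"):
        if f[k] != (k in wanted):
            return False
    return True


def _draw_vertical(rng: np.random.Generator) -> np.ndarray:
    # random 6x3 left half with exactly 9 black cells, mirrored left-right
    half = np.zeros(GRID_SIZE * 3, dtype=np.int8)
    half[rng.choice(half.size, size=N_BLACK // 2, replace=False)] = 1
    half = half.reshape(GRID_SIZE, 3)
    return np.hstack([half, half[:, ::-1]])


def _draw_horizontal(rng: np.random.Generator) -> np.ndarray:
    half = np.zeros(3 * GRID_SIZE, dtype=np.int8)
    half[rng.choice(half.size, size=N_BLACK // 2, replace=False)] = 1
    half = half.reshape(3, GRID_SIZE)
    return np.vstack([half, half[::-1, :]])


def _draw_diagonal(rng: np.random.Generator) -> np.ndarray:
    # fill upper triangle (incl. diagonal) and transpose-mirror;
    # diagonal black count d and off-diagonal pairs p satisfy d + 2p = 18
    d = int(rng.choice([0, 2, 4, 6]))
    p = (N_BLACK - d) // 2
    g = np.zeros((GRID_SIZE, GRID_SIZE), dtype=np.int8)
    diag_idx = rng.choice(GRID_SIZE, size=d, replace=False)
    g[diag_idx, diag_idx] = 1
    iu, ju = np.triu_indices(GRID_SIZE, k=1)
    off = rng.choice(iu.size, size=p, replace=False)
    g[iu[off], ju[off]] = 1
    g[ju[off], iu[off]] = 1
    return g


def _draw_asymmetric(rng: np.random.Generator) -> np.ndarray:
    g = np.zeros(N_CELLS, dtype=np.int8)
    g[rng.choice(N_CELLS, size=N_BLACK, replace=False)] = 1
    return g.reshape(GRID_SIZE, GRID_SIZE)


def generate_stimulus(
    rng_seed: int, symmetry_class: str, stimulus_id: str | None = None
) -> StimulusMatrix:
    """Generate one stimulus of the requested symmetry class.

    Deterministic given ``rng_seed``.  Degenerate draws (a grid that is
    accidentally invariant under an undeclared axis, or an asymmetric
    draw that lands on any axis) are rejected and redrawn from the same
    substream.
    """
    if symmetry_class not in SYMMETRY_CLASSES:
        raise ValueError(f"unknown symmetry class {symmetry_class!r}")
    rng = _substream(rng_seed, SYMMETRY_CLASSES.index(symmetry_class))
    draw = {
        "vertical": _draw_vertical,
        "horizontal": _draw_horizontal,
        "diagonal": _draw_diagonal,
        "asymmetric": _draw_asymmetric,
    }[symmetry_class]
    while True:
        g = draw(rng)
        if symmetry_class == "asymmetric":
            if classify_symmetry(g)["symmetry_class"] == "asymmetric":
                break
        elif _only_declared_axis(g, symmetry_class):
            break
    sid = stimulus_id or f"{symmetry_class[:4]}_{rng_seed:05d}"
    return StimulusMatrix(stimulus_id=sid, grid=g, symmetry_class=symmetry_class)


def generate_stimulus_set(rng_seed: int) -> StimulusSet:
    """Generate the 72-stimulus set: 36 asymmetric, 12 per symmetry axis.

    Stimuli within the set are drawn from per-stimulus substreams of
    ``rng_seed``, so the set is deterministic and order-independent.
    Duplicate grids are rejected.
    """
    plan = [("asymmetric", 36), ("vertical", 12), ("horizontal", 12), ("diagonal", 12)]
    stimuli: list[StimulusMatrix] = []
    seen: set[bytes] = set()
    for cls, count in plan:
        k = 0
        sub = 0
        while k < count:
            s = generate_stimulus(
                int(np.random.SeedSequence([rng_seed, SYMMETRY_CLASSES.index(cls), sub])
                    .generate_state(1)[0] % (2**31)),
                cls,
                stimulus_id=f"{cls[:4]}{k:02d}",
            )
            sub += 1
            key = s.grid.tobytes()
            if key in seen:
                continue
            seen.add(key)
            stimuli.append(s)
            k += 1
    return StimulusSet(stimuli=stimuli, rng_seed=rng_seed)


def render_image(stim: StimulusMatrix, cell_px: int = 50) -> Image.Image:
    """Render a stimulus as an 8-bit grayscale image (black=0, white=255)."""
    if cell_px <= 0:
        raise ValueError("cell_px must be positive")
    px = np.where(stim.grid == 1, 0, 255).astype(np.uint8)
    px = np.kron(px, np.ones((cell_px, cell_px), dtype=np.uint8))
    return Image.fromarray(px, mode="L")


def complexity_score(
    stim: StimulusMatrix, encoder_settings: dict | None = None
) -> ComplexityScore:
    """JPEG-encoded byte size of the rendered stimulus.

    Lossy compression discards redundant structure, so mirror-symmetric
    grids yield systematically smaller files than asymmetric grids of
    the same black-cell count; the byte count is therefore an indirect
    complexity measure.  Deterministic for fixed settings and encoder
    build (absolute byte values are encoder-dependent).
    """
    settings = dict(DEFAULT_ENCODER_SETTINGS)
    if encoder_settings:
        settings.update(encoder_settings)
    img = render_image(stim, cell_px=settings["cell_px"])
    buf = io.BytesIO()
    img.save(
        buf,
        format="JPEG",
        quality=settings["quality"],
        subsampling=settings["subsampling"],
    )
    return ComplexityScore(
        stimulus_id=stim.stimulus_id,
        encoded_bytes=buf.getbuffer().nbytes,
        encoder_settings=settings,
    )


def score_set(stimulus_set: StimulusSet, encoder_settings: dict | None = None
              ) -> list[ComplexityScore]:
    return [complexity_score(s, encoder_settings) for s in stimulus_set.stimuli]


def compare_complexity(stimulus_set: StimulusSet, scores: list[ComplexityScore]) -> dict:
    """Welch two-sample t-test of asymmetric vs symmetric encoded sizes.

    Returns t, Welch-Satterthwaite df, two-sided p, and per-group
    means/SDs (ddof=1), with the difference oriented asymmetric - symmetric.
    """
    by_id = {sc.stimulus_id: sc.encoded_bytes for sc in scores}
    missing = [s.stimulus_id for s in stimulus_set.stimuli if s.stimulus_id not in by_id]
    if missing:
        raise ValueError(f"missing complexity scores for stimuli: {missing}")
    asym = np.array([by_id[s.stimulus_id] for s in stimulus_set.stimuli
                     if s.symmetry_class == "asymmetric"], dtype=float)
    sym = np.array([by_id[s.stimulus_id] for s in stimulus_set.stimuli
                    if s.symmetry_class != "asymmetric"], dtype=float)
    res = stats.ttest_ind(asym, sym, equal_var=False)
    return {
        "t": float(res.statistic),
        "df": float(res.df),
        "p": float(res.pvalue),
        "mean_asymmetric": float(asym.mean()),
        "mean_symmetric": float(sym.mean()),
        "sd_asymmetric": float(asym.std(ddof=1)),
        "sd_symmetric": float(sym.std(ddof=1)),
    }
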