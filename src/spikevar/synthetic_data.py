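"""Synthetic benchmark generators: stairs spike patterns and a maze of
rate-coded room views.

The *stairs* task drives groups of visible neurons in a fixed cyclic
sequence: the active group fires at a high Poisson rate (700 Hz) and the
inactive groups at a low rate (1 Hz); each activation lasts a Gaussian
duration (mean 30 ms, sd 10 ms, truncated at zero).  Learning it requires
memory roughly three times longer than the membrane time constant plus the
group transition structure.

The *maze* task emulates an agent exploring rooms on a square lattice
where only neighboring rooms are accessible.  Each room has a fixed
gray-scale "view" image whose pixel values are mapped affinely onto firing
rates in [0.01, 9] Hz; while the agent sits in a room, the corresponding
visible neurons (one per pixel) emit independent Poisson spikes.  Time is
abstract here: one bin corresponds to a 100 ms step, and the network
constants are interpreted in steps.  A *test* maze is derived from the
target maze by replacing a few rooms with fresh views; everything else is
identical, so telling the mazes apart requires having learned the rooms
and their arrangement.

Room views default to procedurally generated digit-like glyphs (seeded
random strokes on the pixel grid) so that no external image data is
required; externally supplied images of the right shape can be passed in
instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core_dynamics import SpikeRaster, spike_probability

__all__ = [
    "StairsConfig",
    "stairs_raster",
    "MazeConfig",
    "Maze",
    "make_mazes",
    "random_walk",
    "trajectory_to_raster",
    "poisson_raster",
    "glyph_image",
]


def poisson_raster(rates_khz, n_bins: int, dt: float = 1.0, seed=None) -> SpikeRaster:
    """Independent Poisson spiking at per-neuron rates (kHz), one spike per
    bin at most (per-bin probability ``1 - exp(-rate*dt)``)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = np.atleast_1d(np.asarray(rates_khz, dtype=float))
    p = spike_probability(rates, dt)
    spikes = (rng.random((rates.size, n_bins)) < p[:, None]).astype(np.uint8)
    return SpikeRaster(spikes, dt=dt)


@dataclass(frozen=True)
class StairsConfig:
    """Parameters of the stairs pattern generator."""

    n_groups: int = 3
    group_size: int = 10
    rate_high: float = 0.7    # kHz (700 Hz)
    rate_low: float = 0.001   # kHz (1 Hz)
    duration_mean: float = 30.0  # ms
    duration_sd: float = 10.0    # ms

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.group_size < 1:
            raise ValueError("need at least one group of at least one neuron")
        if self.rate_high < 0 or self.rate_low < 0:
            raise ValueError("rates must be non-negative")

    @property
    def n_neurons(self) -> int:
        return self.n_groups * self.group_size


def _truncated_gaussian_duration(cfg: StairsConfig, rng: np.random.Generator) -> float:
    """Activation duration: Gaussian truncated at positive values, by rejection."""
    while True:
        d = rng.normal(cfg.duration_mean, cfg.duration_sd)
        if d > 0:
            return d


def stairs_raster(cfg: StairsConfig, duration_bins: int, dt: float = 1.0,
                  seed=None, start_group: int = 0) -> SpikeRaster:
    """Generate a stairs raster of ``duration_bins`` bins.

    Groups activate in fixed cyclic order (0 -> 1 -> ... -> 0); the active
    group fires at ``rate_high`` and all others at ``rate_low``.
    """
    if duration_bins < 1:
        raise ValueError("duration_bins must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_high = spike_probability(cfg.rate_high, dt)
    p_low = spike_probability(cfg.rate_low, dt)
    spikes = (rng.random((cfg.n_neurons, duration_bins)) < p_low).astype(np.uint8)
    g = start_group % cfg.n_groups
    t = 0
    while t < duration_bins:
        d_bins = max(1, int(round(_truncated_gaussian_duration(cfg, rng) / dt)))
        end = min(t + d_bins, duration_bins)
        rows = slice(g * cfg.group_size, (g + 1) * cfg.group_size)
        spikes[rows, t:end] = rng.random((cfg.group_size, end - t)) < p_high
        t = end
        g = (g + 1) % cfg.n_groups
    return SpikeRaster(spikes, dt=dt)


def glyph_image(shape=(28, 28), seed=None, n_strokes: int = 6,
                mean_level: float = 0.15) -> np.ndarray:
    """Procedural digit-like glyph: seeded random strokes on a pixel grid,
    lightly blurred, gray levels in [0, 1].  A text-free stand-in for
    handwritten-digit views.

    Images are normalized to a common mean gray level (handwritten digits
    carry roughly equal amounts of ink), so that different views drive
    comparable total spike counts and differ in *pattern*, not brightness.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = shape
    img = np.zeros(shape)
    for _ in range(n_strokes):
        r, c = rng.uniform(0.15 * h, 0.85 * h), rng.uniform(0.15 * w, 0.85 * w)
        angle = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.2, 0.6) * min(h, w)
        steps = max(2, int(length))
        dr, dc = np.sin(angle), np.cos(angle)
        curve = rng.uniform(-0.1, 0.1)
        for s in range(steps):
            angle += curve
            dr, dc = np.sin(angle), np.cos(angle)
            r += dr
            c += dc
            ri, ci = int(round(r)), int(round(c))
            if 0 <= ri < h and 0 <= ci < w:
                img[ri, ci] = 1.0
    # 3x3 box blur to give strokes width, as in low-resolution pen images
    padded = np.pad(img, 1)
    blurred = sum(padded[i:i + h, j:j + w] for i in range(3) for j in range(3)) / 9.0
    m = blurred.mean()
    if m > 0:
        blurred = np.clip(blurred * (mean_level / m), 0.0, 1.0)
    return blurred


@dataclass(frozen=True)
class MazeConfig:
    """Parameters of the maze environment."""

    grid_shape: tuple = (4, 4)
    image_shape: tuple = (28, 28)
    rate_min_hz: float = 0.01
    rate_max_hz: float = 9.0
    n_replaced_rooms: int = 3
    step_ms: float = 100.0      # duration of one abstract time step
    dwell_mean_steps: float = 5.0  # geometric mean dwell time per room

    def __post_init__(self) -> None:
        if self.n_replaced_rooms >= self.n_rooms:
            raise ValueError("cannot replace every room")
        if self.rate_min_hz <= 0 or self.rate_max_hz <= self.rate_min_hz:
            raise ValueError("need 0 < rate_min_hz < rate_max_hz")
        if self.dwell_mean_steps < 1:
            raise ValueError("dwell_mean_steps must be >= 1")

    @property
    def n_rooms(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    @property
    def n_pixels(self) -> int:
        return self.image_shape[0] * self.image_shape[1]


@dataclass
class Maze:
    """A lattice of rooms with per-room view images (gray levels in [0,1])."""

    config: MazeConfig
    images: np.ndarray  # (n_rooms, *image_shape)

    def neighbors(self, room: int) -> np.ndarray:
        rows, cols = self.config.grid_shape
        r, c = divmod(room, cols)
        out = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols:
                out.append(rr * cols + cc)
        return np.asarray(out)

    def room_rates_hz(self, room: int) -> np.ndarray:
        """Affine pixel -> rate map onto [rate_min, rate_max] Hz, flattened."""
        cfg = self.config
        img = self.images[room].ravel()
        return cfg.rate_min_hz + img * (cfg.rate_max_hz - cfg.rate_min_hz)

    def to_json(self) -> str:
        """Serialize grid, rates and room images (adjacency is implied by
        the lattice)."""
        from dataclasses import asdict
        cfg = asdict(self.config)
        cfg["grid_shape"] = list(self.config.grid_shape)
        cfg["image_shape"] = list(self.config.image_shape)
        return json.dumps({"config": cfg, "images": self.images.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "Maze":
        doc = json.loads(text)
        cfg = doc["config"]
        cfg["grid_shape"] = tuple(cfg["grid_shape"])
        cfg["image_shape"] = tuple(cfg["image_shape"])
        return cls(MazeConfig(**cfg), np.asarray(doc["images"], dtype=float))


def _match_palette(img: np.ndarray, palette: np.ndarray) -> np.ndarray:
    """Replace the image's intensities by the palette values, preserving
    the spatial rank order (histogram matching)."""
    flat = img.ravel()
    out = np.empty_like(flat)
    out[np.argsort(flat, kind="stable")] = palette
    return out.reshape(img.shape)


def make_mazes(cfg: MazeConfig, seed=None, images: Optional[np.ndarray] = None):
    """Build the target maze and a test maze differing only in
    ``n_replaced_rooms`` uniformly chosen rooms, whose views are replaced
    by fresh images.  ``images`` optionally supplies external room views
    of shape ``(n_rooms, *image_shape)`` for the target maze.

    All procedurally generated views (including the replacements) are
    histogram-matched to a single intensity palette: every room then
    drives the same distribution of firing rates and the mazes differ
    only in the spatial *arrangement* of intensities, so telling them
    apart requires having learned the views, not their gray-level
    statistics.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if images is None:
        raw = [glyph_image(cfg.image_shape, rng) for _ in range(cfg.n_rooms)]
        palette = np.sort(raw[0].ravel())
        imgs = np.stack([_match_palette(im, palette) for im in raw])
    else:
        imgs = np.asarray(images, dtype=float)
        if imgs.shape != (cfg.n_rooms, *cfg.image_shape):
            raise ValueError("images must have shape (n_rooms, *image_shape)")
        palette = None
    target = Maze(cfg, imgs.copy())
    replaced = rng.choice(cfg.n_rooms, size=cfg.n_replaced_rooms, replace=False)
    test_imgs = imgs.copy()
    for room in replaced:
        fresh = glyph_image(cfg.image_shape, rng)
        if palette is not None:
            fresh = _match_palette(fresh, palette)
        test_imgs[room] = fresh
    test = Maze(cfg, test_imgs)
    return target, test, np.sort(replaced)


def random_walk(maze: Maze, n_steps: int, seed=None,
                start_room: Optional[int] = None) -> np.ndarray:
    """Room sequence of a random exploration of ``n_steps`` time steps.

    At each change-point the agent moves to a uniformly chosen lattice
    neighbor (staying put is not a move); it then dwells in the room for a
    geometrically distributed number of steps (mean ``dwell_mean_steps``),
    emulating an agent that lingers between transitions.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cfg = maze.config
    room = int(rng.integers(cfg.n_rooms)) if start_room is None else start_room
    p_move = 1.0 / cfg.dwell_mean_steps
    path = np.empty(n_steps, dtype=int)
    for t in range(n_steps):
        path[t] = room
        if rng.random() < p_move:
            room = int(rng.choice(maze.neighbors(room)))
    return path


def trajectory_to_raster(maze: Maze, path: Sequence[int],
                         seed=None) -> SpikeRaster:
    """Visible raster of a room trajectory: one bin per time step, one
    neuron per pixel, independent Poisson spikes at each room's rates.

    The per-step spike probability is ``1 - exp(-rate * step)`` with the
    step duration from the maze config (abstract 100 ms steps).
    """
    path = np.asarray(path, dtype=int)
    if path.size == 0:
        raise ValueError("path must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cfg = maze.config
    step_s = cfg.step_ms / 1000.0
    spikes = np.empty((cfg.n_pixels, path.size), dtype=np.uint8)
    p_cache = {}
    for t, room in enumerate(path):
        if room not in p_cache:
            p_cache[room] = -np.expm1(-maze.room_rates_hz(room) * step_s)
        spikes[:, t] = rng.random(cfg.n_pixels) < p_cache[room]
    return SpikeRaster(spikes, dt=1.0)
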