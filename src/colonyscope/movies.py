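"""Synthetic fluorescence-movie generator with known ground truth.

Renders simulated colonies of fluorescently labelled nuclei into multi-frame
image stacks emulating the features that make real nuclear-label movies
non-trivial to track: bright, approximately Gaussian nuclear spots of
heterogeneous per-cell intensity (log-normal across founders, heritable with
jitter and halving of the label at division), a smooth paraboloid
illumination bias multiplying the whole frame, and shot-like noise.  Every
movie comes with a :class:`GroundTruth` table of per-frame cell positions,
identities, parent links and division events, which is what the tracking
module is evaluated against.

Cells live at offsets from the rigid colony centre; offsets are kept compact
and non-overlapping by a few relaxation sweeps per frame, so the colony
stays approximately circular while cells jiggle slightly and daughters
separate after a division.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .colony import GrowthParams, MigrationParams, gillespie_division_times, synchronized_cell_count
from .fov import FieldOfView

__all__ = ["RenderConfig", "GroundTruth", "place_cells_in_colony", "render_frame", "make_movie", "write_movie"]

logger = logging.getLogger(__name__)

NOISE_MODELS = ("poisson", "gaussian", "none")


@dataclass(frozen=True)
class RenderConfig:
    """Rendering parameters for synthetic fluorescence frames.

    psf_sigma : float
        Width (um) of the Gaussian nuclear spot; default 3 um, a nucleus-scale
        blob at a ~0.2 um pixel.
    brightness_median, brightness_gsd : float
        Log-normal per-founder total spot intensity (integrated counts):
        median 4e5 puts the median spot peak a few hundred counts above the
        background (comfortably above shot noise, well below 16-bit
        saturation), and geometric SD 1.8 emulates the strong cell-to-cell
        label heterogeneity that real nuclear reporters show (and that helps
        tracking).
    division_jitter_gsd : float
        At division each daughter inherits half the parent's current
        brightness times a log-normal jitter with this geometric SD, then
        re-accumulates label over its cycle (doubling per division interval,
        capped at one doubling) - the halve-and-recover dynamics of a
        histone-fusion reporter, which keeps the brightness distribution
        stationary across generations while leaving a clear halving
        signature at each division.
    illumination : tuple
        Multiplicative paraboloid bias ``c0 + cx*u + cy*v + cxx*u^2 +
        cxy*u*v + cyy*v^2`` over coordinates u, v normalised to [-1, 1]
        across the FOV.  The default is a centred dome (brighter middle,
        dimmer corners), the classic flat-field defect.
    background_level : float
        Uniform background (counts) before the bias is applied.
    noise_model : str
        ``"poisson"`` (default), ``"gaussian"`` or ``"none"``.
    """

    psf_sigma: float = 3.0
    brightness_median: float = 4.0e5
    brightness_gsd: float = 1.8
    division_jitter_gsd: float = 1.1
    illumination: tuple[float, float, float, float, float, float] = (1.1, 0.0, 0.0, -0.25, 0.0, -0.25)
    background_level: float = 100.0
    noise_model: str = "poisson"
    gaussian_sigma: float = 10.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.brightness_median <= 0 or self.brightness_gsd <= 0:
            raise ValueError("brightness parameters must be positive")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {NOISE_MODELS}")

    @property
    def max_value(self) -> float:
        return float(2**self.bit_depth - 1)

    def illumination_field(self, fov: FieldOfView) -> np.ndarray:
        """The paraboloid bias evaluated on the pixel grid (ny, nx)."""
        u, v = _normalized_grid(fov)
        c0, cx, cy, cxx, cxy, cyy = self.illumination
        return c0 + cx * u + cy * v + cxx * u * u + cxy * u * v + cyy * v * v


def _normalized_grid(fov: FieldOfView) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-centre coordinates normalised to [-1, 1] across the FOV (u=x, v=y)."""
    x = (np.arange(fov.n_pixels_x) + 0.5) * fov.pixel_size - fov.half_width
    y = (np.arange(fov.n_pixels_y) + 0.5) * fov.pixel_size - fov.half_height
    u = x[None, :] / fov.half_width
    v = y[:, None] / fov.half_height
    return np.broadcast_arrays(u, v)


def um_to_px(x_um: np.ndarray, y_um: np.ndarray, fov: FieldOfView) -> tuple[np.ndarray, np.ndarray]:
    """FOV-centred um coordinates to (col, row) pixel coordinates (0-based, pixel-centred)."""
    col = (np.asarray(x_um) + fov.half_width) / fov.pixel_size - 0.5
    row = (np.asarray(y_um) + fov.half_height) / fov.pixel_size - 0.5
    return col, row


@dataclass
class GroundTruth:
    """Per-frame cell census and the division forest of one synthetic movie.

    ``table`` has one row per (frame, cell): frame, cell_id, parent_id
    (-1 for founders), x_um, y_um, x_px, y_px, brightness.
    ``divisions`` lists (frame, parent_id, child_a, child_b), with ``frame``
    the first frame at which the daughters exist.
    """

    table: pd.DataFrame
    divisions: list[tuple[int, int, int, int]] = field(default_factory=list)

    def counts_per_frame(self) -> pd.Series:
        return self.table.groupby("frame")["cell_id"].count()

    def frame(self, index: int) -> pd.DataFrame:
        return self.table[self.table["frame"] == index]

    @property
    def n_frames(self) -> int:
        return int(self.table["frame"].max()) + 1

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GroundTruth":
        """Rebuild ground truth from a saved table; division events are
        reconstructed from each daughter pair's shared parent and birth frame."""
        table = pd.read_csv(path)
        divisions = []
        children = table[table["parent_id"] >= 0]
        births = children.groupby("cell_id")["frame"].min()
        parent_of = children.groupby("cell_id")["parent_id"].first()
        by_event: dict[tuple[int, int], list[int]] = {}
        for cell_id, f in births.items():
            by_event.setdefault((int(f), int(parent_of[cell_id])), []).append(int(cell_id))
        for (f, parent), kids in sorted(by_event.items()):
            if len(kids) == 2:
                divisions.append((f, parent, kids[0], kids[1]))
        return cls(table=table, divisions=divisions)


def place_cells_in_colony(
    n: int,
    center: tuple[float, float],
    r1: float,
    rng: np.random.Generator,
    tolerance: float = 0.05,
) -> np.ndarray:
    """Compact, approximately circular arrangement of ``n`` cell centres.

    Cells occupy the ``n`` hexagonal-lattice sites (spacing ``2 * r1``)
    closest to the colony centre, under a random lattice rotation, with a
    small positional jitter that preserves the pairwise-distance guarantee
    ``>= 2 * r1 * (1 - tolerance)``.  The enclosing radius is close to the
    area-equivalent ``r1 * sqrt(n)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return np.array([center], dtype=float)
    spacing = 2.0 * r1
    jitter = 0.4 * tolerance * spacing  # 2*jitter < tolerance*spacing keeps the guarantee
    m = int(math.ceil(math.sqrt(n / 0.9) )) + 2
    i, j = np.meshgrid(np.arange(-m, m + 1), np.arange(-m, m + 1), indexing="ij")
    px = spacing * (i + 0.5 * (j % 2))
    py = spacing * (math.sqrt(3.0) / 2.0) * j
    pts = np.stack([px.ravel(), py.ravel()], axis=1)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    rot = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
    pts = pts @ rot.T
    order = np.argsort(np.einsum("ij,ij->i", pts, pts), kind="stable")
    pts = pts[order[:n]]
    pts = pts - pts.mean(axis=0)
    pts = pts + rng.uniform(-jitter, jitter, size=pts.shape)
    return pts + np.asarray(center, dtype=float)


def _relax_offsets(offsets: np.ndarray, r1: float, n_sweeps: int = 2) -> np.ndarray:
    """Push overlapping cells apart and gently re-centre/compact the colony."""
    target = 1.9 * r1
    off = offsets.copy()
    n = len(off)
    if n == 1:
        return off - off.mean(axis=0)
    colony_r = r1 * math.sqrt(n)
    for _ in range(n_sweeps):
        d = off[:, None, :] - off[None, :, :]
        dist = np.hypot(d[:, :, 0], d[:, :, 1])
        np.fill_diagonal(dist, target)  # self-pairs never push
        too_close = dist < target
        if too_close.any():
            push = np.zeros_like(dist)
            np.divide(target - dist, np.maximum(dist, 1e-6), out=push, where=too_close)
            off += 0.5 * (d * push[:, :, None]).sum(axis=1)
        # pull stragglers back toward the colony edge to keep compactness
        rad = np.hypot(off[:, 0], off[:, 1])
        over = rad > colony_r
        if over.any():
            shrink = 1.0 - 0.5 * (rad[over] - colony_r) / rad[over]
            off[over] *= shrink[:, None]
        off -= off.mean(axis=0)
    return off


def render_frame(
    positions: np.ndarray,
    brightness: np.ndarray,
    fov: FieldOfView,
    config: RenderConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one fluorescence frame.

    ``positions`` is (n, 2) in FOV-centred um; each cell contributes a
    Gaussian spot whose discrete mass equals its ``brightness``.  The frame
    is ``clip(illumination * (background + spots) + noise)`` to the bit-depth
    range.  Cells outside the FOV are clipped silently - losing them is the
    phenomenon under study.
    """
    ny, nx = fov.n_pixels_y, fov.n_pixels_x
    spots = np.zeros((ny, nx))
    positions = np.atleast_2d(np.asarray(positions, dtype=float)) if len(positions) else np.empty((0, 2))
    brightness = np.atleast_1d(np.asarray(brightness, dtype=float))
    sigma_px = config.psf_sigma / fov.pixel_size
    half = int(math.ceil(4.0 * sigma_px))
    for (x_um, y_um), b in zip(positions, brightness):
        col, row = um_to_px(x_um, y_um, fov)
        c0, r0 = int(round(float(col))), int(round(float(row)))
        c_lo, c_hi = max(c0 - half, 0), min(c0 + half + 1, nx)
        r_lo, r_hi = max(r0 - half, 0), min(r0 + half + 1, ny)
        if c_lo >= c_hi or r_lo >= r_hi:
            continue
        cc = np.arange(c_lo, c_hi) - col
        rr = np.arange(r_lo, r_hi) - row
        g = np.exp(-(rr[:, None] ** 2 + cc[None, :] ** 2) / (2.0 * sigma_px**2))
        spots[r_lo:r_hi, c_lo:c_hi] += b / (2.0 * np.pi * sigma_px**2) * g
    signal = config.illumination_field(fov) * (config.background_level + spots)
    if config.noise_model == "poisson":
        if rng is None:
            raise ValueError("poisson noise requires an rng")
        image = rng.poisson(np.maximum(signal, 0.0)).astype(float)
    elif config.noise_model == "gaussian":
        if rng is None:
            raise ValueError("gaussian noise requires an rng")
        image = signal + rng.normal(0.0, config.gaussian_sigma, signal.shape)
    else:
        image = signal
    clipped = (image < 0) | (image > config.max_value)
    frac = clipped.mean()
    if frac > 0.001:
        logger.warning("%.2f%% of pixels clipped to the %d-bit range", 100 * frac, config.bit_depth)
    return np.clip(image, 0.0, config.max_value)


def make_movie(
    growth: GrowthParams,
    migration: MigrationParams,
    fov: FieldOfView,
    config: RenderConfig,
    duration_hr: float,
    seed: int | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Simulate and render a full movie; returns ``(stack, ground_truth)``.

    One frame per ``frame_interval``; divisions place two daughters at the
    parent's position +/- one cell radius with halved, jittered brightness.
    Deterministic (bit-identical stack) given ``seed``.
    """
    if duration_hr < 0:
        raise ValueError("duration must be non-negative")
    rng = np.random.default_rng(seed)
    duration_min = duration_hr * 60.0
    n_frames = int(round(duration_min / migration.frame_interval)) + 1
    times = np.arange(n_frames) * migration.frame_interval

    if growth.mode == "synchronized":
        counts = np.asarray(synchronized_cell_count(times, growth))
        # each division epoch splits every cell
        division_frames = {int(k): None for k in np.nonzero(np.diff(counts) > 0)[0] + 1}
    else:
        events = gillespie_division_times(duration_min, growth, rng)
        counts = 1 + np.searchsorted(events, times, side="right")
        division_frames = {}
        for t_ev in events:
            f = int(np.searchsorted(times, t_ev, side="left"))
            division_frames.setdefault(f, []).append(t_ev)

    offsets = np.zeros((1, 2))
    ids = np.array([0])
    parents = np.array([-1])
    birth_brightness = np.array(
        [config.brightness_median * rng.lognormal(0.0, math.log(config.brightness_gsd))]
    )
    birth_frame = np.array([0])
    next_id = 1
    center = np.zeros(2)
    jitter_ln = math.log(config.division_jitter_gsd)

    def current_brightness(f: int) -> np.ndarray:
        # label re-accumulation: doubling over one division interval, capped
        age = (f - birth_frame) * migration.frame_interval
        return birth_brightness * 2.0 ** np.minimum(age / growth.division_interval, 1.0)

    rows: list[tuple] = []
    divisions: list[tuple[int, int, int, int]] = []
    stack = np.empty((n_frames, fov.n_pixels_y, fov.n_pixels_x), dtype=np.uint16)

    for f in range(n_frames):
        if f > 0:
            theta = rng.uniform(0.0, 2.0 * np.pi, migration.steps_per_frame)
            center = center + migration.step_length * np.array([np.cos(theta).sum(), np.sin(theta).sum()])
            if f in division_frames:
                n_events = counts[f] - counts[f - 1]
                if growth.mode == "synchronized":
                    split = np.arange(len(ids))  # every cell divides
                else:
                    split = rng.choice(len(ids), size=n_events, replace=False)
                keep = np.setdiff1d(np.arange(len(ids)), split)
                cur_b = current_brightness(f)
                new_off, new_ids, new_par, new_bb, new_bf = (
                    [offsets[keep]],
                    [ids[keep]],
                    [parents[keep]],
                    [birth_brightness[keep]],
                    [birth_frame[keep]],
                )
                for k in split:
                    ang = rng.uniform(0.0, 2.0 * np.pi)
                    sep = growth.r1 * np.array([math.cos(ang), math.sin(ang)])
                    child_ids = (next_id, next_id + 1)
                    next_id += 2
                    new_off.append(np.array([offsets[k] + sep, offsets[k] - sep]))
                    new_ids.append(np.array(child_ids))
                    new_par.append(np.array([ids[k], ids[k]]))
                    new_bb.append(0.5 * cur_b[k] * rng.lognormal(0.0, jitter_ln, 2))
                    new_bf.append(np.array([f, f]))
                    divisions.append((f, int(ids[k]), *child_ids))
                offsets = np.concatenate(new_off)
                ids = np.concatenate(new_ids)
                parents = np.concatenate(new_par)
                birth_brightness = np.concatenate(new_bb)
                birth_frame = np.concatenate(new_bf)
                offsets = _relax_offsets(offsets, growth.r1, n_sweeps=20)
            # small within-colony jiggle, then keep cells apart
            offsets = offsets + rng.normal(0.0, 0.3, offsets.shape)
            offsets = _relax_offsets(offsets, growth.r1, n_sweeps=2)

        pos = center[None, :] + offsets
        col, row = um_to_px(pos[:, 0], pos[:, 1], fov)
        brightness = current_brightness(f)
        for k in range(len(ids)):
            rows.append((f, int(ids[k]), int(parents[k]), pos[k, 0], pos[k, 1], float(col[k]), float(row[k]), float(brightness[k])))
        frame = render_frame(pos, brightness, fov, config, rng)
        stack[f] = np.round(frame).astype(np.uint16)

    table = pd.DataFrame(
        rows, columns=["frame", "cell_id", "parent_id", "x_um", "y_um", "x_px", "y_px", "brightness"]
    )
    return stack, GroundTruth(table=table, divisions=divisions)


def write_movie(stack: np.ndarray, path, fov: FieldOfView) -> None:
    """Write a movie stack to a multi-frame TIFF with pixel-size metadata."""
    res = 1.0 / fov.pixel_size  # pixels per um
    tifffile.imwrite(
        path,
        np.asarray(stack),
        resolution=(res, res),
        metadata={"axes": "TYX", "unit": "um", "pixel_size_um": fov.pixel_size},
    )
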