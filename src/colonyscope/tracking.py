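"""Nucleus segmentation, frame-to-frame linking and lineage assembly.

The pipeline mirrors a classic intensity-based nuclear tracking procedure:

1. **Flat-field correction** - fit a 6-coefficient 2-D quadratic (paraboloid)
   to background (non-cell) pixel intensities and divide the image by it,
   leaving a flat background near level 1.
2. **Segmentation** - a pixel intensity threshold (Otsu by default) followed
   by connected components with a minimum-area filter; each component yields
   a :class:`Detection` with intensity-weighted centroid and summed
   intensity.
3. **Linking** - per frame pair, a globally optimal one-to-one assignment
   minimising ``w_pos * d^2 + w_int * |I_i - I_j| / (I_i + I_j)`` over
   matched pairs plus fixed costs for unmatched detections (births/deaths),
   with a hard distance gate.  Solved exactly with the Hungarian algorithm
   on the standard augmented (birth/death-padded) matrix.
4. **Discontinuity heuristics** - a track that dies next to a neighbour
   whose intensity roughly doubles is treated as a transient merge and both
   tracks are continued through the merged detections; a new track appearing
   next to a track whose intensity roughly halves is recorded as a division.

Coordinates are 0-based pixel-centred (row, col) internally, reported as
(x, y) = (col, row).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .movies import GroundTruth

__all__ = [
    "Detection",
    "Track",
    "Lineage",
    "LinkParams",
    "fit_paraboloid",
    "correct_illumination",
    "segment_cells",
    "link_frames",
    "build_tracks",
    "resolve_discontinuities",
    "track_movie",
    "lineage_capture_fraction",
    "evaluate_tracking",
    "tracks_to_frame",
    "lineage_to_json",
]


@dataclass(eq=False)
class Detection:
    """One segmented nucleus: frame index, centroid (x, y in px), intensity, area."""

    frame: int
    x: float
    y: float
    intensity: float
    area: int


@dataclass
class Track:
    """Detections of one cell over a contiguous frame range."""

    track_id: int
    detections: list[Detection] = field(default_factory=list)
    parent_id: int | None = None

    @property
    def start_frame(self) -> int:
        return self.detections[0].frame

    @property
    def end_frame(self) -> int:
        return self.detections[-1].frame

    def detection_at(self, frame: int) -> Detection | None:
        k = frame - self.start_frame
        if 0 <= k < len(self.detections):
            return self.detections[k]
        return None


@dataclass
class Lineage:
    """A forest of tracks plus the division events that connect them."""

    tracks: list[Track]
    divisions: list[tuple[int, int, int, int]] = field(default_factory=list)
    # each division: (frame, parent_track_id, child_track_id_a, child_track_id_b)

    def census(self, n_frames: int) -> np.ndarray:
        counts = np.zeros(n_frames, dtype=int)
        for t in self.tracks:
            counts[t.start_frame : t.end_frame + 1] += 1
        return counts


@dataclass(frozen=True)
class LinkParams:
    """Assignment-cost parameters: position weight (px^-2), intensity weight,
    distance gate (px) and birth/death fixed costs (default ``gate^2 * w_pos``)."""

    w_pos: float = 1.0
    w_int: float = 10.0
    max_distance: float = 30.0
    birth_cost: float | None = None
    death_cost: float | None = None

    @property
    def birth(self) -> float:
        return self.birth_cost if self.birth_cost is not None else self.max_distance**2 * self.w_pos

    @property
    def death(self) -> float:
        return self.death_cost if self.death_cost is not None else self.max_distance**2 * self.w_pos


# ---------------------------------------------------------------------------
# illumination correction


def _quad_basis(shape: tuple[int, int]) -> np.ndarray:
    # pixel-centred coordinates normalised to (-1, 1) across the image
    ny, nx = shape
    v, u = np.meshgrid(
        (np.arange(ny) + 0.5) / ny * 2.0 - 1.0,
        (np.arange(nx) + 0.5) / nx * 2.0 - 1.0,
        indexing="ij",
    )
    return np.stack([np.ones_like(u), u, v, u * u, u * v, v * v], axis=-1)


def fit_paraboloid(image: np.ndarray, mask: np.ndarray, max_pixels: int = 50_000) -> np.ndarray:
    """Least-squares 2-D quadratic fit to ``image`` over ``mask`` pixels.

    Returns the 6 coefficients (1, u, v, u^2, uv, v^2) on coordinates
    normalised to [-1, 1] over the image extent.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    basis = _quad_basis(image.shape)
    idx = np.flatnonzero(mask)
    if len(idx) < 6:
        raise ValueError("fewer background pixels than paraboloid coefficients")
    if len(idx) > max_pixels:
        idx = idx[np.linspace(0, len(idx) - 1, max_pixels).astype(int)]
    a = basis.reshape(-1, 6)[idx]
    b = image.ravel()[idx]
    coeffs, *_ = np.linalg.lstsq(a, b, rcond=None)
    return coeffs


def evaluate_paraboloid(coeffs: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    return _quad_basis(shape) @ np.asarray(coeffs, dtype=float)


def _robust_background_mask(image: np.ndarray) -> np.ndarray:
    """Pixels within ~3 robust SDs of the median - excludes spot cores *and*
    their dim skirts, which would otherwise tilt the paraboloid fit."""
    med = np.median(image)
    sigma = 1.4826 * np.median(np.abs(image - med))
    return image <= med + 3.0 * sigma


def correct_illumination(
    image: np.ndarray, cell_mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Flat-field correct one frame; returns ``(corrected, coefficients)``.

    If no cell mask is given, background pixels are first estimated with a
    coarse robust threshold (median + 3 MAD-based SDs), the fit is applied,
    and the estimate is refined once on the corrected image before the final
    fit.  The corrected image equals ``image / paraboloid``, so its
    background sits near level 1.
    """
    image = np.asarray(image, dtype=float)
    if cell_mask is None:
        bg = _robust_background_mask(image)
        coeffs = fit_paraboloid(image, bg)
        corrected = image / np.maximum(evaluate_paraboloid(coeffs, image.shape), 1e-9)
        bg = _robust_background_mask(corrected)
    else:
        bg = ~np.asarray(cell_mask, dtype=bool)
    coeffs = fit_paraboloid(image, bg)
    corrected = image / np.maximum(evaluate_paraboloid(coeffs, image.shape), 1e-9)
    return corrected, coeffs


# ---------------------------------------------------------------------------
# segmentation


def segment_cells(
    image: np.ndarray,
    threshold: float | None = None,
    min_area: int = 20,
    frame: int = 0,
) -> list[Detection]:
    """Threshold-and-label segmentation of one (corrected) frame.

    ``threshold=None`` selects Otsu's threshold on the frame.  Components
    smaller than ``min_area`` pixels are discarded.  Intensities are summed
    above a local background estimate (the image median) so that detection
    intensity tracks spot mass rather than component area.
    """
    image = np.asarray(image, dtype=float)
    if threshold is None:
        threshold = threshold_otsu(image)
    bg_level = float(np.median(image))
    labels = label(image > threshold)
    out: list[Detection] = []
    for region in regionprops(labels, intensity_image=image):
        if region.area < min_area:
            continue
        r, c = region.centroid_weighted
        total = float(region.image_intensity[region.image].sum() - bg_level * region.area)
        out.append(Detection(frame=frame, x=float(c), y=float(r), intensity=max(total, 0.0), area=int(region.area)))
    return out


# ---------------------------------------------------------------------------
# linking


@dataclass
class LinkResult:
    matches: list[tuple[int, int]]
    deaths: list[int]
    births: list[int]
    cost: float


def _pair_cost(a: Detection, b: Detection, params: LinkParams) -> float:
    d2 = (a.x - b.x) ** 2 + (a.y - b.y) ** 2
    if d2 > params.max_distance**2:
        return math.inf
    denom = a.intensity + b.intensity
    int_term = abs(a.intensity - b.intensity) / denom if denom > 0 else 0.0
    return params.w_pos * d2 + params.w_int * int_term


def link_frames(
    detections_a: list[Detection],
    detections_b: list[Detection],
    params: LinkParams | None = None,
) -> LinkResult:
    """Globally optimal assignment between two consecutive frames' detections.

    Minimises the summed pair cost plus ``death`` for every unmatched source
    and ``birth`` for every unmatched target, via the Hungarian algorithm on
    the augmented square matrix (dummy-dummy entries cost 0, so the problem
    is always feasible and the optimum is exact).
    """
    params = params or LinkParams()
    n, m = len(detections_a), len(detections_b)
    big = np.inf
    cost = np.zeros((n + m, n + m))
    cost[:n, :m] = [[_pair_cost(a, b, params) for b in detections_b] for a in detections_a] if n and m else 0.0
    cost[:n, m:] = big
    cost[np.arange(n), m + np.arange(n)] = params.death
    cost[n:, :m] = big
    cost[n + np.arange(m), np.arange(m)] = params.birth
    cost[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    matches, deaths, births = [], [], []
    total = 0.0
    for r, c in zip(rows, cols):
        total += cost[r, c]
        if r < n and c < m:
            matches.append((r, c))
        elif r < n:
            deaths.append(r)
        elif c < m:
            births.append(c)
    return LinkResult(matches=matches, deaths=deaths, births=births, cost=float(total))


def build_tracks(
    detections_per_frame: list[list[Detection]], params: LinkParams | None = None
) -> list[Track]:
    """Chain per-frame-pair optimal assignments into tracks."""
    params = params or LinkParams()
    tracks: list[Track] = []
    active: dict[int, Track] = {}
    next_id = 0
    for k, det in enumerate(detections_per_frame[0] if detections_per_frame else []):
        t = Track(track_id=next_id, detections=[det])
        tracks.append(t)
        active[k] = t
        next_id += 1
    for f in range(1, len(detections_per_frame)):
        prev, cur = detections_per_frame[f - 1], detections_per_frame[f]
        res = link_frames(prev, cur, params)
        new_active: dict[int, Track] = {}
        for i, j in res.matches:
            if i in active:
                active[i].detections.append(cur[j])
                new_active[j] = active[i]
        for j in res.births:
            t = Track(track_id=next_id, detections=[cur[j]])
            tracks.append(t)
            new_active[j] = t
            next_id += 1
        active = new_active
    return tracks


# ---------------------------------------------------------------------------
# discontinuity heuristics


def resolve_discontinuities(
    tracks: list[Track],
    n_frames: int,
    params: LinkParams | None = None,
    double_range: tuple[float, float] = (1.6, 2.6),
    halve_range: tuple[float, float] = (0.3, 0.7),
) -> Lineage:
    """Best-effort correction of track discontinuities.

    (a) *Transient merges*: a track ending while a gate-distance neighbour's
    intensity jumps by a factor in ``double_range`` is carried through the
    merged detections (each continued track gets an intensity-weighted share
    of the merged centroid); if a later birth next to the carrier drops the
    carrier's intensity back, the new track's detections are grafted onto
    the carried track.  (b) *Divisions*: a remaining new track appearing
    within the gate of a track whose intensity roughly halves (inverse of
    ``double_range``) is recorded as a division.  Unresolved events stay
    plain terminations/births.
    """
    params = params or LinkParams()
    gate = params.max_distance
    lo, hi = double_range
    tracks = list(tracks)
    consumed: set[int] = set()

    def neighbours_at(frame: int, x: float, y: float, exclude: Track) -> list[tuple[float, Track]]:
        out = []
        for t in tracks:
            if t is exclude or t.track_id in consumed:
                continue
            d = t.detection_at(frame)
            if d is None:
                continue
            dist = math.hypot(d.x - x, d.y - y)
            if dist <= gate:
                out.append((dist, t))
        return sorted(out, key=lambda p: p[0])

    # (a) transient merges
    for t in tracks:
        if t.track_id in consumed:
            continue
        while t.end_frame < n_frames - 1:
            f = t.end_frame
            last = t.detections[-1]
            carrier = None
            for _, cand in neighbours_at(f, last.x, last.y, t):
                before, after = cand.detection_at(f), cand.detection_at(f + 1)
                if before is None or after is None or before.intensity <= 0:
                    continue
                ratio = after.intensity / before.intensity
                if lo <= ratio <= hi:
                    carrier = cand
                    break
            if carrier is None:
                break
            share = last.intensity / max(last.intensity + carrier.detection_at(f).intensity, 1e-9)
            # carry through merged frames until the carrier's intensity drops back
            # or a nearby birth re-separates the pair
            g = f + 1
            resumed = False
            while g < n_frames:
                merged = carrier.detection_at(g)
                if merged is None:
                    break
                rebirth = None
                for other in tracks:
                    if other is t or other is carrier or other.track_id in consumed:
                        continue
                    if other.start_frame == g and other.parent_id is None:
                        d0 = other.detections[0]
                        if math.hypot(d0.x - merged.x, d0.y - merged.y) <= gate:
                            rebirth = other
                            break
                if rebirth is not None:
                    t.detections.extend(rebirth.detections)
                    consumed.add(rebirth.track_id)
                    resumed = True
                    break
                t.detections.append(
                    Detection(frame=g, x=merged.x, y=merged.y,
                              intensity=share * merged.intensity,
                              area=max(int(share * merged.area), 1))
                )
                g += 1
            if not resumed:
                break

    tracks = [t for t in tracks if t.track_id not in consumed]

    # (b) divisions; a track can parent at most one new track per frame (it
    # continues as the other daughter itself).  Candidate parents must show a
    # rough intensity halving; among them the true parent is identified by
    # division geometry (daughters straddle the parent's last position, so
    # their midpoint falls on it) plus label conservation (daughter +
    # remaining parent ~ parent before division) - both far more reliable
    # than raw distance when several cells divide in the same frame.
    candidates: list[tuple[float, int, Track, Track]] = []
    for t in tracks:
        if t.start_frame == 0 or t.parent_id is not None:
            continue
        f = t.start_frame
        d0 = t.detections[0]
        for dist, cand in neighbours_at(f, d0.x, d0.y, t):
            before, after = cand.detection_at(f - 1), cand.detection_at(f)
            if before is None or after is None or before.intensity <= 0:
                continue
            ratio = after.intensity / before.intensity
            if not (halve_range[0] <= ratio <= halve_range[1]):
                continue
            conservation = abs((after.intensity + d0.intensity) / before.intensity - 1.0)
            midpoint_miss = math.hypot(
                0.5 * (after.x + d0.x) - before.x, 0.5 * (after.y + d0.y) - before.y
            )
            candidates.append((midpoint_miss / gate + 0.5 * conservation, f, t, cand))
    divisions: list[tuple[int, int, int, int]] = []
    claimed: set[tuple[int, int]] = set()
    adopted: set[int] = set()
    for score, f, child, parent in sorted(candidates, key=lambda c: c[0]):
        if child.track_id in adopted or (parent.track_id, f) in claimed:
            continue
        claimed.add((parent.track_id, f))
        adopted.add(child.track_id)
        child.parent_id = parent.track_id
        divisions.append((f, parent.track_id, parent.track_id, child.track_id))
    divisions.sort()
    return Lineage(tracks=tracks, divisions=divisions)


def track_movie(
    stack: np.ndarray,
    threshold: float | None = None,
    min_area: int = 20,
    params: LinkParams | None = None,
) -> Lineage:
    """Full pipeline on an image stack: correct, segment, link, resolve."""
    stack = np.asarray(stack)
    detections = []
    for f in range(stack.shape[0]):
        corrected, _ = correct_illumination(stack[f])
        detections.append(segment_cells(corrected, threshold=threshold, min_area=min_area, frame=f))
    tracks = build_tracks(detections, params)
    return resolve_discontinuities(tracks, n_frames=stack.shape[0], params=params)


# ---------------------------------------------------------------------------
# capture statistic and evaluation against ground truth


def lineage_capture_fraction(
    lineage: Lineage,
    expected_counts: np.ndarray,
    thresholds: tuple[float, ...] = (0.5, 0.9),
) -> tuple[float, np.ndarray, dict[float, bool]]:
    """Tracked-cell fraction of the expected census, per frame.

    Returns ``(min_fraction, per_frame_fractions, classification)`` where the
    movie-level fraction is the minimum over frames ("throughout") and the
    classification compares it against each threshold.
    """
    expected = np.asarray(expected_counts, dtype=float)
    if np.any(expected <= 0):
        raise ValueError("expected cell counts must be positive at every frame")
    census = lineage.census(len(expected))
    frac = np.minimum(census / expected, 1.0)
    min_frac = float(frac.min())
    return min_frac, frac, {float(t): bool(min_frac >= t) for t in thresholds}


def _match_truth_to_detections(
    truth_frame: pd.DataFrame, detections: list[Detection], radius: float
) -> dict[int, Detection]:
    """One-to-one nearest matching of ground-truth cells to detections."""
    if len(truth_frame) == 0 or len(detections) == 0:
        return {}
    tx = truth_frame["x_px"].to_numpy()
    ty = truth_frame["y_px"].to_numpy()
    dx = np.array([d.x for d in detections])
    dy = np.array([d.y for d in detections])
    dist = np.hypot(tx[:, None] - dx[None, :], ty[:, None] - dy[None, :])
    cost = np.where(dist <= radius, dist, 1e6)
    rows, cols = linear_sum_assignment(cost)
    out = {}
    for r, c in zip(rows, cols):
        if dist[r, c] <= radius:
            out[int(truth_frame["cell_id"].iloc[r])] = detections[c]
    return out


def evaluate_tracking(
    lineage: Lineage,
    truth: GroundTruth,
    image_shape: tuple[int, int],
    match_radius: float = 8.0,
    margin: float = 5.0,
) -> dict[str, float]:
    """Compare tracker output against synthetic ground truth.

    *Link recovery*: the fraction of ground-truth frame-to-frame links (same
    cell in consecutive frames, both endpoints at least ``margin`` px inside
    the image) whose matched detections lie on the same track.  *Division
    recall*: the fraction of observable ground-truth divisions (parent and
    both daughters at least ``margin`` px inside the image) for which a
    division was called within one frame whose parent track sits within the
    match radius of the true parent.
    """
    ny, nx = image_shape
    det_track: dict[int, int] = {}
    det_by_frame: dict[int, list[Detection]] = {}
    for t in lineage.tracks:
        for d in t.detections:
            det_track[id(d)] = t.track_id
            det_by_frame.setdefault(d.frame, []).append(d)

    def in_view(row) -> bool:
        return margin <= row.x_px <= nx - 1 - margin and margin <= row.y_px <= ny - 1 - margin

    matches: dict[int, dict[int, Detection]] = {}
    for f in sorted(truth.table["frame"].unique()):
        matches[f] = _match_truth_to_detections(truth.frame(f), det_by_frame.get(f, []), match_radius)

    n_links = n_recovered = 0
    table = truth.table
    by_cell = table.groupby("cell_id")
    for cell_id, rows in by_cell:
        rows = rows.sort_values("frame")
        frames = rows["frame"].to_numpy()
        for a, b in zip(rows.itertuples(), rows.iloc[1:].itertuples()):
            if b.frame != a.frame + 1 or not (in_view(a) and in_view(b)):
                continue
            n_links += 1
            da = matches[a.frame].get(cell_id)
            db = matches[b.frame].get(cell_id)
            if da is not None and db is not None and det_track[id(da)] == det_track[id(db)]:
                n_recovered += 1

    n_div = n_div_found = 0
    truth_pos = table.set_index(["frame", "cell_id"])
    def _inside(row) -> bool:
        return bool(
            margin <= row["x_px"] <= nx - 1 - margin and margin <= row["y_px"] <= ny - 1 - margin
        )

    for f, parent, ca, cb in truth.divisions:
        prow = truth_pos.loc[(f - 1, parent)] if (f - 1, parent) in truth_pos.index else None
        kids = [truth_pos.loc[(f, c)] for c in (ca, cb) if (f, c) in truth_pos.index]
        if prow is None or len(kids) < 2 or not (_inside(prow) and all(_inside(k) for k in kids)):
            continue
        n_div += 1
        for df, ptrack, *_ in lineage.divisions:
            if abs(df - f) > 1:
                continue
            pd_det = next((t for t in lineage.tracks if t.track_id == ptrack), None)
            d = pd_det.detection_at(f - 1) if pd_det is not None else None
            if d is not None and math.hypot(d.x - prow["x_px"], d.y - prow["y_px"]) <= match_radius:
                n_div_found += 1
                break
    return {
        "n_links": n_links,
        "link_recovery": n_recovered / n_links if n_links else float("nan"),
        "n_divisions": n_div,
        "division_recall": n_div_found / n_div if n_div else float("nan"),
        "n_tracks": len(lineage.tracks),
    }


# ---------------------------------------------------------------------------
# serialisation


def tracks_to_frame(lineage: Lineage) -> pd.DataFrame:
    rows = []
    for t in lineage.tracks:
        for d in t.detections:
            rows.append(
                (d.frame, t.track_id, -1 if t.parent_id is None else t.parent_id, d.x, d.y, d.intensity, d.area)
            )
    return pd.DataFrame(rows, columns=["frame", "track_id", "parent_id", "x_px", "y_px", "intensity", "area"])


def lineage_from_frame(df: pd.DataFrame) -> Lineage:
    """Rebuild a :class:`Lineage` from a :func:`tracks_to_frame` table."""
    tracks = []
    for track_id, rows in df.groupby("track_id"):
        rows = rows.sort_values("frame")
        parent = int(rows["parent_id"].iloc[0])
        t = Track(
            track_id=int(track_id),
            parent_id=None if parent < 0 else parent,
            detections=[
                Detection(frame=int(r.frame), x=float(r.x_px), y=float(r.y_px),
                          intensity=float(r.intensity), area=int(r.area))
                for r in rows.itertuples()
            ],
        )
        tracks.append(t)
    divisions = [
        (t.start_frame, t.parent_id, t.parent_id, t.track_id)
        for t in tracks
        if t.parent_id is not None
    ]
    return Lineage(tracks=tracks, divisions=sorted(divisions))


def lineage_to_json(lineage: Lineage) -> str:
    forest = {
        "tracks": [
            {
                "track_id": t.track_id,
                "parent_id": t.parent_id,
                "start_frame": t.start_frame,
                "end_frame": t.end_frame,
            }
            for t in lineage.tracks
        ],
        "divisions": [list(d) for d in lineage.divisions],
    }
    return json.dumps(forest, indent=2)
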