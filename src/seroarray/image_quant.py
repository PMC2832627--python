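"""Quantification of scanned protein-macroarray images.

Converts an 8-bit grayscale scan of a spotted protein macroarray into one
autoantibody profile: a vector of per-antigen integer intensities in the
0-255 grayscale range. Each expressed protein is spotted in duplicate at
known grid positions; spots are dark, roughly circular features on a
brighter, noisy membrane background.

The pipeline, in order:

1. ``correct_rotation`` -- estimate and undo the slight global rotation a
   flatbed scan acquires, by maximizing the variance of row/column
   projection profiles over a scanned angle range.
2. ``crop_edges`` -- cut the image margins.
3. ``segment_grid`` -- split the array into regular subgrids and those into
   rectangular spot target areas, each expected to hold exactly one spot.
4. ``cluster_spot_pixels`` -- per target area, 2-cluster the pixel
   intensities into (dark) foreground and background.
5. ``adjust_spot_area`` -- optionally grow a target area whose foreground
   touches its border, so spots that overflow their cell are captured.
6. ``black_top_hat`` -- morphological closing minus the image with a square
   structuring element; turns dark spots into positive peaks on a flat
   baseline, removing the smooth background.
7. ``spot_intensity`` -- mean of the top-hat image over each spot's
   foreground pixels.
8. ``build_profile`` -- average the two duplicate spots per antigen and
   round half-up to an integer in [0, 255].

``quantify_image`` runs the whole chain.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

logger = logging.getLogger("seroarray")

__all__ = [
    "GridLayout",
    "ArrayImage",
    "SpotMeasurement",
    "AutoantibodyProfile",
    "correct_rotation",
    "estimate_rotation",
    "crop_edges",
    "segment_grid",
    "cluster_spot_pixels",
    "adjust_spot_area",
    "black_top_hat",
    "spot_intensity",
    "build_profile",
    "default_se_side",
    "quantify_image",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GridLayout:
    """Geometric model of a spotted array.

    Coordinates are 0-based pixel indices, row-major (y, x); rectangles are
    half-open ``(y0, x0, y1, x1)``. Every antigen maps to exactly two
    distinct spot positions (duplicate spotting); spot positions not
    assigned to any antigen carry antigen index ``-1``.

    Attributes
    ----------
    image_shape
        ``(height, width)`` of the image the coordinates refer to.
    antigen_ids
        Canonical antigen ordering; profiles follow this order.
    rects
        ``(n_spots, 4)`` int array of target-area rectangles.
    centers
        ``(n_spots, 2)`` float array of nominal spot centres ``(y, x)``.
    spot_antigen
        ``(n_spots,)`` int array: index into ``antigen_ids`` or ``-1``.
    antigen_spots
        ``(n_antigens, 2)`` int array of the two spot indices per antigen.
    subgrid_index
        ``(n_spots,)`` int array: which subgrid each spot belongs to.
    spot_diameter
        Expected spot diameter in pixels (drives the default structuring
        element size).
    pitch
        Centre-to-centre spot spacing in pixels.
    """

    image_shape: tuple[int, int]
    antigen_ids: list[str]
    rects: np.ndarray
    centers: np.ndarray
    spot_antigen: np.ndarray
    antigen_spots: np.ndarray
    subgrid_index: np.ndarray
    spot_diameter: float
    pitch: float

    def __post_init__(self) -> None:
        self.rects = np.asarray(self.rects, dtype=int)
        self.centers = np.asarray(self.centers, dtype=float)
        self.spot_antigen = np.asarray(self.spot_antigen, dtype=int)
        self.antigen_spots = np.asarray(self.antigen_spots, dtype=int)
        self.subgrid_index = np.asarray(self.subgrid_index, dtype=int)
        self.validate()

    @property
    def n_antigens(self) -> int:
        return len(self.antigen_ids)

    @property
    def n_spots(self) -> int:
        return len(self.rects)

    @property
    def occupied(self) -> np.ndarray:
        """Boolean mask over spot positions assigned to an antigen."""
        return self.spot_antigen >= 0

    def validate(self) -> None:
        if self.antigen_spots.shape != (self.n_antigens, 2):
            raise ValueError("antigen_spots must be (n_antigens, 2)")
        if np.any(self.antigen_spots[:, 0] == self.antigen_spots[:, 1]):
            raise ValueError("each antigen needs two distinct spot positions")
        # consistency between the two maps
        for a in range(self.n_antigens):
            for s in self.antigen_spots[a]:
                if self.spot_antigen[s] != a:
                    raise ValueError(
                        f"spot {s} not mapped back to antigen index {a}"
                    )
        counts = np.bincount(
            self.spot_antigen[self.occupied], minlength=self.n_antigens
        )
        if np.any(counts != 2):
            raise ValueError("every antigen must own exactly 2 spot positions")

    def shifted(self, dy: int, dx: int, image_shape: tuple[int, int]) -> "GridLayout":
        """Layout with all coordinates translated by ``(dy, dx)``."""
        return replace(
            self,
            image_shape=image_shape,
            rects=self.rects + np.array([dy, dx, dy, dx]),
            centers=self.centers + np.array([dy, dx], dtype=float),
        )

    # -- JSON round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "image_shape": list(self.image_shape),
            "antigen_ids": list(self.antigen_ids),
            "rects": self.rects.tolist(),
            "centers": self.centers.tolist(),
            "spot_antigen": self.spot_antigen.tolist(),
            "antigen_spots": self.antigen_spots.tolist(),
            "subgrid_index": self.subgrid_index.tolist(),
            "spot_diameter": self.spot_diameter,
            "pitch": self.pitch,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridLayout":
        return cls(
            image_shape=tuple(d["image_shape"]),
            antigen_ids=list(d["antigen_ids"]),
            rects=np.array(d["rects"]),
            centers=np.array(d["centers"]),
            spot_antigen=np.array(d["spot_antigen"]),
            antigen_spots=np.array(d["antigen_spots"]),
            subgrid_index=np.array(d["subgrid_index"]),
            spot_diameter=float(d["spot_diameter"]),
            pitch=float(d["pitch"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "GridLayout":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ArrayImage:
    """8-bit grayscale array scan with provenance metadata."""

    pixels: np.ndarray
    source: str | None = None
    rotation_corrected: float = 0.0
    crop_margins: tuple[int, int, int, int] = (0, 0, 0, 0)  # top, bottom, left, right

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("array image must be a 2-D raster")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SpotMeasurement:
    """Per-spot quantification result."""

    antigen_id: str
    spot_index: int
    rect: tuple[int, int, int, int]
    n_foreground: int
    raw_mean: float
    processed_mean: float
    adjusted: bool = False
    overlap: bool = False
    empty: bool = False


@dataclass
class AutoantibodyProfile:
    """Per-serum vector of per-antigen intensities.

    ``values`` are integers in [0, 255] straight after quantification and
    real-valued after normalization. ``flags`` marks antigens whose spots
    were empty or problematic.
    """

    serum_id: str
    antigen_ids: list[str]
    values: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.flags is None:
            self.flags = np.zeros(len(self.values), dtype=bool)
        self.flags = np.asarray(self.flags, dtype=bool)
        if len(self.values) != len(self.antigen_ids):
            raise ValueError("profile length must equal number of antigens")


# ---------------------------------------------------------------------------
# 1. Rotation correction
# ---------------------------------------------------------------------------


def _spot_centroids(pixels: np.ndarray, min_size: int = 4) -> np.ndarray | None:
    """Centroids of dark blobs: global 2-means threshold, size-filtered."""
    fg, empty = cluster_spot_pixels(pixels)
    if empty:
        return None
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return None
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(sizes >= min_size) + 1
    if len(keep) < 8:  # too few spots to define a grid orientation
        return None
    return np.array(ndimage.center_of_mass(fg, labels, keep), dtype=float)


def estimate_rotation(
    pixels: np.ndarray,
    max_angle: float = 5.0,
    step: float = 0.05,
) -> float | None:
    """Estimate the global rotation of a gridded array image.

    A grid-alignment criterion is maximized over a scanned angle range.
    Dark spot blobs are first detected (global 2-means threshold,
    connected components) to measure the spot pitch from nearest-neighbour
    centroid distances. Every pixel darker than the image median then
    votes with its darkness as weight: for each candidate angle the pixel
    coordinates are counter-rotated and scored by the magnitude of their
    weighted phase sum at the pitch frequency, i.e. how tightly the dark
    mass concentrates on a pitch-periodic lattice of rows and columns.
    Working on continuous pixel coordinates with graded weights avoids
    both the aliasing a rotate-and-project criterion suffers on pixel
    rasters and the integer-lattice snap-back of binarized centroids.

    Returns the estimated rotation in degrees (positive = counterclockwise,
    matching :func:`scipy.ndimage.rotate`), or ``None`` when no grid signal
    is detected (constant image, too few spots, flat criterion).
    """
    pixels = np.asarray(pixels)
    if np.ptp(pixels) == 0:
        return None
    pts = _spot_centroids(pixels)
    if pts is None:
        return None
    # pitch from the median nearest-neighbour centroid distance
    from scipy.spatial import cKDTree

    d, _ = cKDTree(pts).query(pts, k=2)
    pitch = float(np.median(d[:, 1]))
    if not np.isfinite(pitch) or pitch <= 1:
        return None

    darkness = np.clip(np.median(pixels).astype(float) - pixels, 0, None)
    ys, xs = np.nonzero(darkness > 0)
    wts = darkness[ys, xs]
    cy = np.average(ys, weights=wts)
    cx = np.average(xs, weights=wts)
    y = ys - cy
    x = xs - cx
    omega = 2 * np.pi / pitch
    angles = np.arange(-max_angle, max_angle + step / 2, step)
    scores = np.empty(len(angles))
    for i, a in enumerate(angles):
        r = np.deg2rad(a)
        yr = np.cos(r) * y + np.sin(r) * x
        xr = -np.sin(r) * y + np.cos(r) * x
        scores[i] = np.abs((wts * np.exp(1j * omega * yr)).sum()) + np.abs(
            (wts * np.exp(1j * omega * xr)).sum()
        )
    if np.ptp(scores) <= 1e-9 * max(1.0, scores.max()):
        return None
    return float(angles[int(np.argmax(scores))])


def correct_rotation(
    image: ArrayImage, max_angle: float = 5.0, step: float = 0.05
) -> ArrayImage:
    """Undo the estimated global rotation of the scan.

    When no grid signal is detected the input is returned unchanged with a
    warning. A zero estimate skips resampling entirely so unrotated images
    pass through bit-identically.
    """
    theta = estimate_rotation(image.pixels, max_angle=max_angle, step=step)
    if theta is None:
        logger.warning("rotation correction: no grid signal detected; image unchanged")
        return image
    if theta == 0.0:
        return replace(image, rotation_corrected=0.0)
    out = ndimage.rotate(
        image.pixels.astype(float), -theta, reshape=False, order=1, mode="nearest"
    )
    out = np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
    return replace(image, pixels=out, rotation_corrected=theta)


# ---------------------------------------------------------------------------
# 2. Edge cropping
# ---------------------------------------------------------------------------


def crop_edges(image: ArrayImage, margins: int | tuple[int, int, int, int]) -> ArrayImage:
    """Virtually cut the image edges.

    ``margins`` is a single pixel count applied to all four sides or a
    ``(top, bottom, left, right)`` tuple. Margins must leave a non-empty
    image (each pair strictly smaller than the corresponding extent).
    """
    if isinstance(margins, (int, np.integer)):
        top = bottom = left = right = int(margins)
    else:
        top, bottom, left, right = (int(m) for m in margins)
    if min(top, bottom, left, right) < 0:
        raise ValueError("margins must be non-negative")
    h, w = image.pixels.shape
    if top + bottom >= h or left + right >= w:
        raise ValueError(
            f"margins ({top},{bottom},{left},{right}) too large for image {h}x{w}"
        )
    if top == bottom == left == right == 0:
        return image
    prev = image.crop_margins
    return replace(
        image,
        pixels=image.pixels[top : h - bottom, left : w - right],
        crop_margins=(prev[0] + top, prev[1] + bottom, prev[2] + left, prev[3] + right),
    )


# ---------------------------------------------------------------------------
# 3. Grid segmentation
# ---------------------------------------------------------------------------


def segment_grid(image: ArrayImage, layout: GridLayout) -> np.ndarray:
    """Return the spot target-area rectangles, validated against the image.

    One rectangle per spot position, ``(y0, x0, y1, x1)`` half-open. Raises
    if any subgrid's target areas fall outside the image, listing the
    offending subgrids.
    """
    h, w = image.pixels.shape
    r = layout.rects
    bad = (r[:, 0] < 0) | (r[:, 1] < 0) | (r[:, 2] > h) | (r[:, 3] > w)
    if bad.any():
        subs = sorted(set(layout.subgrid_index[bad].tolist()))
        raise ValueError(
            f"layout exceeds image bounds ({h}x{w}) in subgrids {subs}"
        )
    return r.copy()


# ---------------------------------------------------------------------------
# 4. Foreground / background clustering
# ---------------------------------------------------------------------------


def cluster_spot_pixels(area: np.ndarray) -> tuple[np.ndarray, bool]:
    """Split a target area's pixels into dark foreground and background.

    Solves the two-cluster k-means objective on the 1-D pixel intensities
    exactly: for sorted values the optimal 2-partition is a contiguous
    split, so the global within-cluster sum-of-squares minimum is found by
    enumerating the n-1 admissible splits (ties kept together). The cluster
    with the darker centroid is the foreground -- spots are dark features on
    a bright membrane.

    Parameters
    ----------
    area
        Pixel block (any shape, >= 4 pixels).

    Returns
    -------
    fg_mask
        Boolean array, same shape as ``area``; True = foreground.
    empty
        True when the area has zero intensity variance, in which case the
        whole area is background and the spot is flagged as absent.
    """
    area = np.asarray(area)
    if area.size < 4:
        raise ValueError("target area must contain at least 4 pixels")
    v = area.astype(float).ravel()
    s = np.sort(v)
    n = v.size
    if s[0] == s[-1]:
        return np.zeros(area.shape, dtype=bool), True
    csum = np.cumsum(s)
    csq = np.cumsum(s * s)
    total_sum, total_sq = csum[-1], csq[-1]
    # admissible splits: k pixels in the low cluster, value change at the cut
    ks = np.flatnonzero(s[:-1] < s[1:]) + 1
    lo_sse = csq[ks - 1] - csum[ks - 1] ** 2 / ks
    hi_n = n - ks
    hi_sum = total_sum - csum[ks - 1]
    hi_sse = (total_sq - csq[ks - 1]) - hi_sum**2 / hi_n
    sse = lo_sse + hi_sse
    k = int(ks[np.argmin(sse)])  # argmin takes the first optimum: smaller foreground
    cut = s[k - 1]
    fg = (area.astype(float) <= cut)
    return fg, False


# ---------------------------------------------------------------------------
# 5. Spot-area adjustment
# ---------------------------------------------------------------------------


_CONN8 = np.ones((3, 3), dtype=int)


def _main_component(fg_mask: np.ndarray) -> np.ndarray:
    """Largest 8-connected foreground component (the spot blob).

    Ties break on the lowest label, i.e. the component encountered first
    in raster order -- deterministic.
    """
    labels, n = ndimage.label(fg_mask, structure=_CONN8)
    if n <= 1:
        return fg_mask
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(sizes)) + 1)


def adjust_spot_area(
    pixels: np.ndarray,
    rect: tuple[int, int, int, int],
    fg_mask: np.ndarray,
    blocked_centers: np.ndarray | None = None,
    max_iterations: int = 5,
) -> tuple[tuple[int, int, int, int], np.ndarray, bool, bool]:
    """Grow a target area whose spot overflows its border.

    Growth triggers when the *main* foreground component -- the largest
    8-connected blob, i.e. the spot itself -- touches the area border;
    scattered single foreground pixels from background noise do not. Each
    touched side is extended by one pixel per iteration (up to
    ``max_iterations``) and the area re-clustered. Growth is clipped to
    the image, and a side is blocked -- with the spot flagged for overlap
    -- if extending it would make the rectangle contain another spot's
    nominal centre.

    After any growth the foreground is restricted to the connected
    components that intersect the *original* target area, so a
    neighbouring spot swept up by the enlarged rectangle is not counted
    into this spot's pixels.

    Returns ``(rect, fg_mask, adjusted, overlap)``.
    """
    h, w = pixels.shape
    oy0, ox0, oy1, ox1 = (int(c) for c in rect)
    y0, x0, y1, x1 = oy0, ox0, oy1, ox1
    centers = (
        np.empty((0, 2)) if blocked_centers is None else np.asarray(blocked_centers)
    )
    adjusted = False
    overlap = False
    for _ in range(max_iterations):
        if not fg_mask.any():
            break
        main = _main_component(fg_mask)
        # a disc overflowing a side crosses it with a chord of >= 2 pixels;
        # single-pixel border contacts are noise and do not trigger growth
        grow_top = int(main[0, :].sum()) >= 2 and y0 > 0
        grow_bottom = int(main[-1, :].sum()) >= 2 and y1 < h
        grow_left = int(main[:, 0].sum()) >= 2 and x0 > 0
        grow_right = int(main[:, -1].sum()) >= 2 and x1 < w
        if not (grow_top or grow_bottom or grow_left or grow_right):
            break

        def blocked(ny0, nx0, ny1, nx1) -> bool:
            if centers.size == 0:
                return False
            inside = (
                (centers[:, 0] >= ny0)
                & (centers[:, 0] < ny1)
                & (centers[:, 1] >= nx0)
                & (centers[:, 1] < nx1)
            )
            return bool(inside.any())

        ny0, nx0, ny1, nx1 = y0, x0, y1, x1
        if grow_top:
            if blocked(y0 - 1, nx0, ny1, nx1):
                overlap = True
            else:
                ny0 = y0 - 1
        if grow_bottom:
            if blocked(ny0, nx0, y1 + 1, nx1):
                overlap = True
            else:
                ny1 = y1 + 1
        if grow_left:
            if blocked(ny0, x0 - 1, ny1, nx1):
                overlap = True
            else:
                nx0 = x0 - 1
        if grow_right:
            if blocked(ny0, nx0, ny1, x1 + 1):
                overlap = True
            else:
                nx1 = x1 + 1
        if (ny0, nx0, ny1, nx1) == (y0, x0, y1, x1):
            break  # all touching sides blocked
        y0, x0, y1, x1 = ny0, nx0, ny1, nx1
        adjusted = True
        fg_mask, empty = cluster_spot_pixels(pixels[y0:y1, x0:x1])
        if empty:
            break
    if adjusted and fg_mask.any():
        # keep only foreground components anchored in the original area
        labels, n = ndimage.label(fg_mask, structure=_CONN8)
        inner = np.zeros_like(fg_mask)
        inner[oy0 - y0 : inner.shape[0] - (y1 - oy1), ox0 - x0 : inner.shape[1] - (x1 - ox1)] = True
        keep = np.unique(labels[fg_mask & inner])
        fg_mask = np.isin(labels, keep[keep > 0])
    return (y0, x0, y1, x1), fg_mask, adjusted, overlap


# ---------------------------------------------------------------------------
# 6. Black top-hat
# ---------------------------------------------------------------------------


def black_top_hat(pixels: np.ndarray, se_side: int) -> np.ndarray:
    """Black top-hat with a square structuring element.

    The morphological closing of the image minus the image: dark features
    narrower than the ``se_side`` x ``se_side`` square become positive
    peaks; wide dark regions and the smooth background map to zero.
    """
    se_side = int(se_side)
    if se_side < 3 or se_side % 2 == 0:
        raise ValueError("structuring element side must be an odd integer >= 3")
    img = np.asarray(pixels, dtype=np.int16)
    closing = ndimage.grey_closing(img, size=(se_side, se_side), mode="reflect")
    return (closing - img).astype(float)


def default_se_side(layout: GridLayout, factor: float = 1.5) -> int:
    """Next odd integer >= ``factor`` x the layout's expected spot diameter."""
    side = int(math.ceil(factor * layout.spot_diameter))
    if side % 2 == 0:
        side += 1
    return max(side, 3)


# ---------------------------------------------------------------------------
# 7. Spot intensity
# ---------------------------------------------------------------------------


def spot_intensity(
    processed: np.ndarray,
    rect: tuple[int, int, int, int],
    fg_mask: np.ndarray,
) -> float:
    """Mean of the processed (top-hat) raster over a spot's foreground pixels.

    An empty foreground yields 0.0 -- the caller flags the spot as absent.
    """
    if not fg_mask.any():
        return 0.0
    y0, x0, y1, x1 = rect
    vals = processed[y0:y1, x0:x1][fg_mask]
    return float(np.clip(vals.mean(), 0.0, 255.0))


# ---------------------------------------------------------------------------
# 8. Duplicate averaging
# ---------------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def build_profile(
    measurements: list[SpotMeasurement],
    layout: GridLayout,
    serum_id: str = "serum",
) -> AutoantibodyProfile:
    """Average duplicate spots per antigen into an integer profile.

    Each protein is spotted twice; the profile value is the mean of the two
    replicate intensities rounded half-up to an integer in [0, 255]. A
    replicate flagged empty is dropped (the remaining one is used and the
    antigen flagged); an antigen with both replicates empty gets 0, flagged.
    """
    by_spot = {m.spot_index: m for m in measurements}
    values = np.zeros(layout.n_antigens, dtype=int)
    flags = np.zeros(layout.n_antigens, dtype=bool)
    for a in range(layout.n_antigens):
        reps = []
        problem = False
        for s in layout.antigen_spots[a]:
            m = by_spot.get(int(s))
            if m is None or m.empty:
                problem = True
                continue
            reps.append(m.processed_mean)
            if m.overlap:
                problem = True
        if reps:
            values[a] = min(255, max(0, _round_half_up(float(np.mean(reps)))))
        else:
            values[a] = 0
            problem = True
        flags[a] = problem
    return AutoantibodyProfile(
        serum_id=serum_id,
        antigen_ids=list(layout.antigen_ids),
        values=values,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def quantify_image(
    image: ArrayImage,
    layout: GridLayout,
    serum_id: str = "serum",
    se_side: int | None = None,
    adjust: bool = True,
    rotate: bool = True,
    crop_margins: int | tuple[int, int, int, int] = 0,
) -> tuple[AutoantibodyProfile, list[SpotMeasurement]]:
    """Run the full quantification chain on one scan.

    Foreground membership comes from clustering the *raw* (rotation-corrected,
    cropped) image; spot intensity is the mean of the *top-hat processed*
    image over those foreground pixels; duplicates are then averaged.

    Parameters
    ----------
    se_side
        Structuring-element side; default 1.5x the layout's expected spot
        diameter, rounded up to odd.
    adjust
        Enable spot-area adjustment for spots overflowing their target area.
    rotate
        Enable rotation estimation/correction.
    crop_margins
        Pixels to cut from the edges before gridding; the layout is shifted
        to match.
    """
    if rotate:
        image = correct_rotation(image)
    work_layout = layout
    if isinstance(crop_margins, (int, np.integer)):
        top = left = int(crop_margins)
        any_crop = top > 0
    else:
        top, _, left, _ = crop_margins
        any_crop = any(m > 0 for m in crop_margins)
    if any_crop:
        image = crop_edges(image, crop_margins)
        work_layout = layout.shifted(-top, -left, image.pixels.shape)

    rects = segment_grid(image, work_layout)
    if se_side is None:
        se_side = default_se_side(work_layout)
    pixels = image.pixels
    processed = black_top_hat(pixels, se_side)

    occupied = np.flatnonzero(work_layout.occupied)
    centers_int = np.floor(work_layout.centers + 0.5).astype(int)
    measurements: list[SpotMeasurement] = []
    for s in occupied:
        y0, x0, y1, x1 = (int(c) for c in rects[s])
        fg, empty = cluster_spot_pixels(pixels[y0:y1, x0:x1])
        rect = (y0, x0, y1, x1)
        adjusted = overlap = False
        if adjust and not empty:
            others = centers_int[np.arange(work_layout.n_spots) != s]
            rect, fg, adjusted, overlap = adjust_spot_area(
                pixels, rect, fg, blocked_centers=others
            )
        ry0, rx0, ry1, rx1 = rect
        raw_mean = (
            float(pixels[ry0:ry1, rx0:rx1][fg].mean()) if fg.any() else 0.0
        )
        measurements.append(
            SpotMeasurement(
                antigen_id=work_layout.antigen_ids[work_layout.spot_antigen[s]],
                spot_index=int(s),
                rect=rect,
                n_foreground=int(fg.sum()),
                raw_mean=raw_mean,
                processed_mean=spot_intensity(processed, rect, fg),
                adjusted=adjusted,
                overlap=overlap,
                empty=empty or not fg.any(),
            )
        )
    profile = build_profile(measurements, work_layout, serum_id=serum_id)
    return profile, measurements
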