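"""Synthetic macroarray scans and serum profiles with known ground truth.

Real seroreactivity screens probe membranes spotted with bacterially
expressed proteins (each in duplicate) using diluted patient serum, and the
membranes are digitized on a flatbed fluorescence scanner: dark, roughly
circular spots on a brighter, noisy background, with a slight global
rotation from the scan. No such raw data ships with this package, so this
module fabricates it: a grid layout, per-serum antigen reactivity profiles
with planted group differences, and rendered 8-bit scan images -- all
deterministic under a fixed seed, with the ground truth retained so the
quantification and statistics stages can be tested against what was planted.

The simulated measurement model, per serum ``s`` and antigen ``a``::

    depth[s, a] = scale_s * (base_a + effect * informative_a * group1_s + eps)

``base_a`` is an exponential baseline (most antigens weakly reactive, a few
strong), ``eps`` is Gaussian noise with sd ``noise_sd``, and ``scale_s`` is
a log-normal per-serum factor emulating the array-to-array intensity
effects quantile normalization must remove. Depths are rounded and clipped
to the 0-255 grayscale range; they are what the renderer subtracts from the
background at both duplicate spot positions.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_quant import ArrayImage, GridLayout
from .stats import ProfileMatrix

logger = logging.getLogger("seroarray")

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ConfigurationError",
    "generate_layout",
    "simulate_profiles",
    "render_image",
]


class ConfigurationError(ValueError):
    """Simulation geometry or parameters are infeasible."""


@dataclass
class SimulationConfig:
    """Parameters of a synthetic screening experiment.

    Geometry defaults accommodate a 1827-antigen panel spotted in duplicate
    (16 subgrids of 256 spots = 4096 positions); intensity defaults emulate
    an 8-bit grayscale scan of a membrane with dark spots on a bright
    background.
    """

    n_antigens: int = 1827
    n_subgrid_rows: int = 4
    n_subgrid_cols: int = 4
    spots_per_subgrid: int = 256
    spot_pitch: int = 10
    spot_radius: float = 3.0
    margin: int = 20
    subgrid_gap: int = 10
    background_level: float = 200.0
    background_gradient: float = 0.02
    noise_sd: float = 5.0
    rotation_deg: float = 0.5
    edge_softness: float = 0.0
    n_group1: int = 47
    n_group2: int = 80
    group_labels: tuple[str, str] = ("group1", "group2")
    frac_informative: float = 0.05
    effect_size: float = 30.0
    depth_scale: float = 40.0
    serum_scale_sigma: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_antigens < 1:
            raise ConfigurationError("need at least one antigen")
        if self.spot_radius >= self.spot_pitch / 2:
            raise ConfigurationError("spot_radius must be < spot_pitch / 2")
        for name in ("background_level", "noise_sd", "effect_size", "depth_scale"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ConfigurationError(f"{name}={v} outside [0, 255]")
        if not (0 <= self.frac_informative <= 1):
            raise ConfigurationError("frac_informative must be in [0, 1]")
        if self.n_group1 < 2 or self.n_group2 < 2:
            raise ConfigurationError("each serum group needs at least 2 sera")

    @property
    def n_sera(self) -> int:
        return self.n_group1 + self.n_group2

    @property
    def capacity(self) -> int:
        return self.n_subgrid_rows * self.n_subgrid_cols * self.spots_per_subgrid


@dataclass
class GroundTruth:
    """What the simulator planted, for recovery tests.

    ``true_spot_depths`` holds, per serum and antigen, the intensity depth
    below background actually drawn at both duplicate spots -- the quantity
    the image pipeline should recover.
    """

    true_spot_depths: pd.DataFrame
    informative_antigens: set[str]
    applied_rotation: float
    layout: GridLayout
    serum_scales: pd.Series = field(default=None)  # type: ignore[assignment]


def generate_layout(config: SimulationConfig) -> GridLayout:
    """Build the grid geometry for the configured antigen panel.

    Subgrids are laid out in an ``n_subgrid_rows x n_subgrid_cols``
    arrangement; within a subgrid, spots sit row-major on a near-square
    grid at ``spot_pitch`` spacing, each owning a pitch x pitch target
    rectangle (target areas tile the subgrid without overlap). Antigens
    fill consecutive spot positions in duplicate pairs.
    """
    need = 2 * config.n_antigens
    if config.capacity < need:
        raise ConfigurationError(
            f"{config.n_antigens} antigens need {need} spot positions in duplicate "
            f"but the grid only has {config.capacity}"
        )
    nspots = config.capacity
    sg_cols = math.ceil(math.sqrt(config.spots_per_subgrid))
    sg_rows = math.ceil(config.spots_per_subgrid / sg_cols)
    pitch = config.spot_pitch
    sub_h = sg_rows * pitch
    sub_w = sg_cols * pitch
    height = 2 * config.margin + config.n_subgrid_rows * sub_h + (
        config.n_subgrid_rows - 1
    ) * config.subgrid_gap
    width = 2 * config.margin + config.n_subgrid_cols * sub_w + (
        config.n_subgrid_cols - 1
    ) * config.subgrid_gap

    rects = np.empty((nspots, 4), dtype=int)
    centers = np.empty((nspots, 2), dtype=float)
    subgrid_index = np.empty(nspots, dtype=int)
    i = 0
    for gr in range(config.n_subgrid_rows):
        oy = config.margin + gr * (sub_h + config.subgrid_gap)
        for gc in range(config.n_subgrid_cols):
            ox = config.margin + gc * (sub_w + config.subgrid_gap)
            g = gr * config.n_subgrid_cols + gc
            for k in range(config.spots_per_subgrid):
                r, c = divmod(k, sg_cols)
                y0 = oy + r * pitch
                x0 = ox + c * pitch
                rects[i] = (y0, x0, y0 + pitch, x0 + pitch)
                centers[i] = (y0 + pitch / 2, x0 + pitch / 2)
                subgrid_index[i] = g
                i += 1

    antigen_ids = [f"ag{a + 1:05d}" for a in range(config.n_antigens)]
    spot_antigen = np.full(nspots, -1, dtype=int)
    antigen_spots = np.empty((config.n_antigens, 2), dtype=int)
    for a in range(config.n_antigens):
        antigen_spots[a] = (2 * a, 2 * a + 1)
        spot_antigen[2 * a] = a
        spot_antigen[2 * a + 1] = a

    return GridLayout(
        image_shape=(height, width),
        antigen_ids=antigen_ids,
        rects=rects,
        centers=centers,
        spot_antigen=spot_antigen,
        antigen_spots=antigen_spots,
        subgrid_index=subgrid_index,
        spot_diameter=2 * config.spot_radius,
        pitch=float(pitch),
    )


def simulate_profiles(
    config: SimulationConfig,
) -> tuple[ProfileMatrix, GroundTruth]:
    """Draw per-serum antigen reactivity profiles with planted group effects.

    A fraction ``frac_informative`` of antigens is shifted by
    ``effect_size`` in group-1 sera; every serum gets a log-normal
    multiplicative scale factor so inter-array effects are present and
    normalization is non-trivial. Values are integers in [0, 255], the
    output scale of the image-quantification stage.
    """
    rng = np.random.default_rng(config.seed)
    layout = generate_layout(config)
    n_a, n_s = config.n_antigens, config.n_sera

    n_inf = round(config.frac_informative * n_a)
    inf_idx = rng.choice(n_a, size=n_inf, replace=False) if n_inf else np.array([], int)
    informative = np.zeros(n_a, dtype=bool)
    informative[inf_idx] = True

    base = np.clip(rng.exponential(config.depth_scale, size=n_a), 0, 255)
    scales = rng.lognormal(mean=0.0, sigma=config.serum_scale_sigma, size=n_s)
    noise = rng.normal(0.0, config.noise_sd, size=(n_s, n_a))

    g1, g2 = config.group_labels
    groups = np.array([g1] * config.n_group1 + [g2] * config.n_group2)
    serum_ids = [
        f"{g1}_s{i + 1:03d}" for i in range(config.n_group1)
    ] + [f"{g2}_s{i + 1:03d}" for i in range(config.n_group2)]

    shift = np.where(informative, config.effect_size, 0.0)
    clean = base[None, :] + shift[None, :] * (groups == g1)[:, None]
    depths = scales[:, None] * (clean + noise)
    values = np.clip(np.floor(depths + 0.5), 0, 255).astype(int)

    frame = pd.DataFrame(values, index=serum_ids, columns=layout.antigen_ids)
    matrix = ProfileMatrix(
        values=frame, groups=pd.Series(groups, index=serum_ids, name="group")
    )
    truth = GroundTruth(
        true_spot_depths=frame.copy(),
        informative_antigens={layout.antigen_ids[a] for a in inf_idx},
        applied_rotation=config.rotation_deg,
        layout=layout,
        serum_scales=pd.Series(scales, index=serum_ids, name="scale"),
    )
    return matrix, truth


def _serum_seed(config: SimulationConfig, serum_id: str) -> int:
    # stable across processes (python str hash is salted)
    return (config.seed * 100003 + zlib.crc32(serum_id.encode())) % (2**31)


def render_image(
    profile_row: np.ndarray | pd.Series,
    truth: GroundTruth,
    config: SimulationConfig,
    serum_id: str = "serum",
    seed: int | None = None,
) -> ArrayImage:
    """Render one serum's profile as a synthetic 8-bit array scan.

    Spots are drawn as dark discs (pixel value = local background minus the
    antigen's depth) at both duplicate positions, on a background with a
    linear horizontal gradient. The scene is then rotated by
    ``truth.applied_rotation`` about the image centre (bilinear), Gaussian
    pixel noise is added, and the raster is re-quantized to 0-255 integers.
    Depths exceeding the local background clip to black with a warning.
    """
    layout = truth.layout
    depths = np.asarray(profile_row, dtype=float)
    if depths.shape != (layout.n_antigens,):
        raise ValueError("profile length does not match layout antigen count")
    if seed is None:
        seed = _serum_seed(config, serum_id)
    rng = np.random.default_rng(seed)

    h, w = layout.image_shape
    bg_row = config.background_level + config.background_gradient * (
        np.arange(w) - w / 2
    )
    bgmap = np.tile(bg_row, (h, 1))

    # depth layer: maximum depth at each pixel over all discs
    layer = np.zeros((h, w))
    r = config.spot_radius
    ri = int(math.ceil(r))
    for a in range(layout.n_antigens):
        d = depths[a]
        if d <= 0:
            continue
        for s in layout.antigen_spots[a]:
            cy, cx = layout.centers[s]
            y0, y1 = int(cy) - ri - 1, int(cy) + ri + 2
            x0, x1 = int(cx) - ri - 1, int(cx) + ri + 2
            yy, xx = np.mgrid[y0:y1, x0:x1]
            disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
            sub = layer[y0:y1, x0:x1]
            sub[disc] = np.maximum(sub[disc], d)
    if config.edge_softness > 0:
        layer = ndimage.gaussian_filter(layer, config.edge_softness)

    canvas = bgmap - layer
    if (depths > config.background_level).any():
        logger.warning(
            "render_image(%s): spot depth exceeds background level; clipped to 0",
            serum_id,
        )
    if truth.applied_rotation != 0.0:
        canvas = ndimage.rotate(
            canvas, truth.applied_rotation, reshape=False, order=1, mode="nearest"
        )
    if config.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, config.noise_sd, size=canvas.shape)
    pixels = np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8)
    return ArrayImage(pixels=pixels, source=f"synthetic:{serum_id}")
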