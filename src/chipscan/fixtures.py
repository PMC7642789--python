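"""Synthetic chip micrographs with ground truth.

Emulates IR transmission micrographs of protein crystals grown on a
crystallization chip: a bright, mildly textured background; crystals as
convex polygons (rectangles and elongated hexagons) with sharp darkened
edges and attenuated interiors; occasional clusters and small precipitate
debris.  Crystals "standing upright" on the chip appear foreshortened and
darker, as thicker material absorbs more of the transmitted light.

Every output is a deterministic function of the spec and its seed, and
ground truth (crystal polygons, tile positions) is returned alongside the
images, so every downstream stage — stitching, recognition, planning —
can be scored without any real data.

Coordinates: crystal truth polygons are stored in the montage frame
(µm, x right / y down, origin at the chip image's top-left pixel).  The
JSON writer converts to a lower-left-origin, y-up frame for export.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from .montage import ImageTile

__all__ = [
    "ChipSpec",
    "CrystalTruth",
    "GroundTruth",
    "sample_crystals",
    "render_chip_image",
    "render_chip",
    "render_beam_image",
    "write_tiles",
    "write_truth",
]


@dataclass
class ChipSpec:
    """Parameters of a synthetic chip scan.

    Defaults mirror the physical platform: a 20 × 20 mm crystallization
    window imaged at 2 µm/pixel (within the camera's 1–3 µm/pixel range),
    tiles overlapping by 15%, crystals with a 50–150 µm long axis (typical
    plates are ~50 × 50 × 100 µm), stage jitter up to 3 px, and 2% additive
    Gaussian noise.
    """

    window_mm: tuple[float, float] = (20.0, 20.0)  # (x, y) extent
    pixel_scale: float = 2.0  # µm per pixel
    tile_shape: tuple[int, int] = (512, 512)  # (rows, cols)
    overlap_fraction: float = 0.15
    n_crystals: int = 50
    crystal_size_range: tuple[float, float] = (50.0, 150.0)  # long axis, µm
    aspect_range: tuple[float, float] = (0.5, 0.9)
    hexagon_rate: float = 0.3  # fraction with chamfered (hexagonal) habit
    upright_rate: float = 0.2  # fraction standing upright on the chip
    foreshorten: float = 0.6  # projected-length factor for upright crystals
    cluster_rate: float = 0.1  # fraction grown overlapping a neighbour
    precipitate_rate: float = 0.2  # debris blobs per crystal
    noise_sigma: float = 0.02  # fraction of dynamic range, per tile
    jitter_px: int = 3  # max |stage error| in pixels (integer)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.overlap_fraction < 0.5):
            raise ValueError("overlap_fraction must be in (0, 0.5)")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        if self.n_crystals < 0:
            raise ValueError("n_crystals must be non-negative")

    @property
    def chip_shape(self) -> tuple[int, int]:
        """Chip image shape (rows, cols) in pixels."""
        return (
            int(round(self.window_mm[1] * 1000.0 / self.pixel_scale)),
            int(round(self.window_mm[0] * 1000.0 / self.pixel_scale)),
        )


@dataclass
class CrystalTruth:
    """Ground truth for one rendered crystal."""

    id: int
    polygon_um: np.ndarray  # (n, 2) vertices, montage frame (x right, y down)
    upright: bool
    cluster_id: int | None = None  # shared by overlapping crystals

    def polygon_px(self, pixel_scale: float) -> np.ndarray:
        return self.polygon_um / pixel_scale


@dataclass
class GroundTruth:
    """Ground truth for a whole rendered chip."""

    crystals: list[CrystalTruth]
    tile_origins_px: dict[tuple[int, int], tuple[int, int]]  # (row, col) true
    chip_shape: tuple[int, int]
    pixel_scale: float


# intensity model (fractions of dynamic range)
_BACKGROUND = 0.78
_EDGE_DARKEN = 0.28
_EDGE_WIDTH = 3  # px
_INTERIOR_FLAT = 0.10
_INTERIOR_UPRIGHT = 0.30  # 3x the flat attenuation
_PRECIP_DARKEN = 0.15


def _crystal_vertices(
    rng: np.random.Generator, spec: ChipSpec, center: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Vertices (µm) of one random crystal polygon centred at ``center``."""
    lo, hi = spec.crystal_size_range
    length = rng.uniform(lo, hi)
    width = length * rng.uniform(*spec.aspect_range)
    upright = rng.random() < spec.upright_rate
    if upright:
        length *= spec.foreshorten
    theta = rng.uniform(0.0, math.pi)
    hexagonal = rng.random() < spec.hexagon_rate
    hl, hw = length / 2.0, width / 2.0
    if hexagonal:
        c = 0.125 * length  # chamfer, keeps long edges at 0.75 * length
        pts = np.array(
            [
                (-hl, 0.0),
                (-hl + c, hw),
                (hl - c, hw),
                (hl, 0.0),
                (hl - c, -hw),
                (-hl + c, -hw),
            ]
        )
    else:
        pts = np.array([(-hl, hw), (hl, hw), (hl, -hw), (-hl, -hw)])
    rot = np.array(
        [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
    )
    return pts @ rot.T + center, upright


def sample_crystals(
    spec: ChipSpec, rng: np.random.Generator | None = None
) -> list[CrystalTruth]:
    """Draw crystal polygons for a chip without rasterizing anything.

    Used directly by planner-scale simulations where the image itself is
    not needed.  A ``cluster_rate`` fraction of crystals is placed
    overlapping an earlier one; members share a ``cluster_id``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    w_um = spec.window_mm[0] * 1000.0
    h_um = spec.window_mm[1] * 1000.0
    margin = spec.crystal_size_range[1]  # keep polygons inside the window
    if w_um <= 2 * margin or h_um <= 2 * margin:
        raise ValueError("window too small for the crystal size range")
    crystals: list[CrystalTruth] = []
    n_cluster = int(round(spec.cluster_rate * spec.n_crystals))
    for i in range(spec.n_crystals):
        clustered = i > 0 and len(crystals) > 0 and i >= spec.n_crystals - n_cluster
        if clustered:
            host = crystals[int(rng.integers(0, len(crystals)))]
            offset = rng.uniform(-1.0, 1.0, size=2)
            offset *= 0.4 * spec.crystal_size_range[0] / (np.linalg.norm(offset) + 1e-9)
            center = host.polygon_um.mean(axis=0) + offset
            center = np.clip(center, margin, [w_um - margin, h_um - margin])
            cluster_id = host.cluster_id if host.cluster_id is not None else host.id
            host.cluster_id = cluster_id
        else:
            center = rng.uniform([margin, margin], [w_um - margin, h_um - margin])
            cluster_id = None
        poly, upright = _crystal_vertices(rng, spec, center)
        poly = np.clip(poly, 1.0, [w_um - 1.0, h_um - 1.0])
        crystals.append(CrystalTruth(i, poly, upright, cluster_id))
    return crystals


def _paint_polygon(
    img: np.ndarray, poly_px: np.ndarray, interior: float, edge: float
) -> None:
    rr, cc = draw_polygon(poly_px[:, 1], poly_px[:, 0], shape=img.shape)
    if rr.size == 0:
        return
    r0, r1 = rr.min(), rr.max() + 1
    c0, c1 = cc.min(), cc.max() + 1
    mask = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    mask[rr - r0, cc - c0] = True
    core = ndimage.binary_erosion(mask, iterations=_EDGE_WIDTH)
    border = mask & ~core
    sub = img[r0:r1, c0:c1]
    sub[mask] -= interior
    sub[border] -= edge


def render_chip_image(
    spec: ChipSpec, apply_noise: bool = False
) -> tuple[np.ndarray, GroundTruth]:
    """Render the full chip image (float, [0, 1]) plus ground truth.

    The background carries stationary low-amplitude texture so that
    featureless overlap regions still correlate during stitching.  Tile
    origins in the returned truth are filled in by :func:`render_chip`.
    With ``apply_noise`` the spec's ``noise_sigma`` is added once to the
    whole image — the noise level of a single exposure, matching what a
    stitched montage of noisy tiles carries into recognition.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.chip_shape
    th, tw = spec.tile_shape
    if shape[0] < th + 2 * spec.jitter_px or shape[1] < tw + 2 * spec.jitter_px:
        raise ValueError("chip window smaller than a single tile")

    img = np.full(shape, _BACKGROUND)
    for factor, amp in ((32, 0.02), (6, 0.012)):
        coarse = rng.normal(
            0.0, 1.0, (shape[0] // factor + 2, shape[1] // factor + 2)
        )
        tex = ndimage.zoom(coarse, factor, order=1)[: shape[0], : shape[1]]
        img += amp * tex

    crystals = sample_crystals(spec, rng)
    for c in crystals:
        interior = _INTERIOR_UPRIGHT if c.upright else _INTERIOR_FLAT
        _paint_polygon(img, c.polygon_px(spec.pixel_scale), interior, _EDGE_DARKEN)

    n_precip = int(round(spec.precipitate_rate * spec.n_crystals))
    for _ in range(n_precip):
        center = rng.uniform([20.0, 20.0], [shape[1] - 20.0, shape[0] - 20.0])
        n_blob = int(rng.integers(2, 5))
        for _ in range(n_blob):
            bc = center + rng.normal(0.0, 4.0, size=2)
            radius = rng.uniform(2.0, 6.0)
            yy, xx = np.ogrid[
                max(0, int(bc[1] - radius - 1)) : min(shape[0], int(bc[1] + radius + 2)),
                max(0, int(bc[0] - radius - 1)) : min(shape[1], int(bc[0] + radius + 2)),
            ]
            disk = (yy - bc[1]) ** 2 + (xx - bc[0]) ** 2 <= radius**2
            img[
                max(0, int(bc[1] - radius - 1)) : min(shape[0], int(bc[1] + radius + 2)),
                max(0, int(bc[0] - radius - 1)) : min(shape[1], int(bc[0] + radius + 2)),
            ][disk] -= _PRECIP_DARKEN

    if apply_noise and spec.noise_sigma > 0:
        noise_rng = np.random.default_rng(spec.seed + 2)
        img += noise_rng.normal(0.0, spec.noise_sigma, img.shape)
    np.clip(img, 0.0, 1.0, out=img)
    truth = GroundTruth(
        crystals=crystals,
        tile_origins_px={},
        chip_shape=shape,
        pixel_scale=spec.pixel_scale,
    )
    return img, truth


def _grid_positions(extent: int, tile: int, overlap: float, jitter: int) -> list[int]:
    """Nominal tile origins covering ``extent`` px with the given overlap."""
    step = tile * (1.0 - overlap)
    usable = extent - tile - 2 * jitter
    n = max(1, int(math.ceil(usable / step)) + 1)
    if n == 1:
        return [jitter]
    return [jitter + int(round(i * usable / (n - 1))) for i in range(n)]


def render_chip(spec: ChipSpec) -> tuple[list[ImageTile], GroundTruth]:
    """Render the raster-scan tiles of a synthetic chip.

    Tiles are exact crops of the common chip image at nominal grid
    positions perturbed by integer stage jitter (≤ ``jitter_px``), plus
    per-tile Gaussian noise; with ``noise_sigma = 0`` the overlap strips of
    adjacent tiles are therefore pixel-identical.  Deterministic per seed.
    """
    img, truth = render_chip_image(spec)
    rng = np.random.default_rng(spec.seed + 1)  # independent of content stream
    th, tw = spec.tile_shape
    rows = _grid_positions(img.shape[0], th, spec.overlap_fraction, spec.jitter_px)
    cols = _grid_positions(img.shape[1], tw, spec.overlap_fraction, spec.jitter_px)
    tiles: list[ImageTile] = []
    for ir, r_nom in enumerate(rows):
        for ic, c_nom in enumerate(cols):
            jr = int(rng.integers(-spec.jitter_px, spec.jitter_px + 1))
            jc = int(rng.integers(-spec.jitter_px, spec.jitter_px + 1))
            r = int(np.clip(r_nom + jr, 0, img.shape[0] - th))
            c = int(np.clip(c_nom + jc, 0, img.shape[1] - tw))
            pixels = img[r : r + th, c : c + tw].copy()
            if spec.noise_sigma > 0:
                pixels = np.clip(
                    pixels + rng.normal(0.0, spec.noise_sigma, pixels.shape),
                    0.0,
                    1.0,
                )
            tiles.append(
                ImageTile(
                    pixels=pixels,
                    nominal_stage_mm=(
                        c_nom * spec.pixel_scale / 1000.0,
                        r_nom * spec.pixel_scale / 1000.0,
                    ),
                    grid_index=(ir, ic),
                )
            )
            truth.tile_origins_px[(ir, ic)] = (r, c)
    return tiles, truth


def render_beam_image(
    center: tuple[float, float],
    fwhm: float,
    noise_sigma: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (1024, 1024),
    amplitude: float = 0.8,
    background: float = 0.1,
) -> np.ndarray:
    """Synthetic direct-beam image: Gaussian spot + background + noise.

    ``center`` is (x, y) in pixels (sub-pixel allowed), ``fwhm`` in pixels.
    """
    cx, cy = center
    if not (0 <= cx < shape[1] and 0 <= cy < shape[0]):
        raise ValueError("beam center must lie inside the image")
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    img = background + amplitude * np.exp(
        -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma**2)
    )
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma, shape)
    return img


def write_tiles(tiles: list[ImageTile], out_dir: str | Path) -> list[Path]:
    """Write tiles as 16-bit TIFF files named ``tile_<row>_<col>.tif``."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in tiles:
        r, c = t.grid_index
        path = out / f"tile_{r:03d}_{c:03d}.tif"
        tifffile.imwrite(
            path, np.clip(t.pixels * 65535.0, 0, 65535).astype(np.uint16)
        )
        paths.append(path)
    return paths


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write ground truth as JSON (polygons in µm, lower-left origin, y up)."""
    h_um = truth.chip_shape[0] * truth.pixel_scale
    data = {
        "pixel_scale_um": truth.pixel_scale,
        "chip_shape_px": list(truth.chip_shape),
        "crystals": [
            {
                "id": c.id,
                "upright": c.upright,
                "cluster_id": c.cluster_id,
                "polygon_um": [
                    [float(x), float(h_um - y)] for x, y in c.polygon_um
                ],
            }
            for c in truth.crystals
        ],
        "tile_origins_px": {
            f"{r}_{c}": list(v) for (r, c), v in truth.tile_origins_px.items()
        },
    }
    Path(path).write_text(json.dumps(data, indent=1))
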