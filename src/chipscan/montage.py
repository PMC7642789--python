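"""Tile stitching and direct-beam registration.

A raster scan of the chip produces overlapping grayscale tiles at known
nominal stage positions; small stage errors (a few pixels) are recovered
by normalized cross-correlation of the overlap strips and a global
least-squares adjustment over the grid graph.  The direct-beam position
(from a fluorescence spot or burn mark) is fitted with a 2D elliptical
Gaussian to sub-pixel precision; together they let crystal pixel
coordinates be mapped to motor coordinates.

Pixel convention: origin at the top-left of the montage, x (= column)
right, y (= row) down, 0-based.  Public chip coordinates are in µm,
obtained by multiplying pixel coordinates by ``pixel_scale``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.feature import match_template

__all__ = [
    "ImageTile",
    "Montage",
    "BeamReference",
    "PairOffset",
    "pairwise_offset",
    "assemble",
    "fit_beam_center",
]


@dataclass
class ImageTile:
    """One raster-scan micrograph with its nominal stage position."""

    pixels: np.ndarray  # 2D float array, intensities in [0, 1]
    nominal_stage_mm: tuple[float, float]  # (x, y) of the tile origin
    grid_index: tuple[int, int]  # (row, col) on the raster grid

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("tile pixels must be a 2D array")


@dataclass
class Montage:
    """The stitched chip image and the solved per-tile pixel offsets."""

    pixels: np.ndarray
    tile_offsets: dict[tuple[int, int], tuple[float, float]]  # (row, col) px
    pixel_scale: float  # µm per pixel

    def px_to_um(self, p: tuple[float, float]) -> tuple[float, float]:
        """Convert (x, y) pixel coordinates to µm in the montage frame."""
        return (p[0] * self.pixel_scale, p[1] * self.pixel_scale)

    def um_to_px(self, p: tuple[float, float]) -> tuple[float, float]:
        return (p[0] / self.pixel_scale, p[1] / self.pixel_scale)


@dataclass
class BeamReference:
    """Sub-pixel direct-beam position from profile fitting."""

    center: tuple[float, float]  # (x, y) pixels
    fwhm: tuple[float, float]  # (x, y) pixels
    fit_residual: float  # rms residual / fitted amplitude


@dataclass
class PairOffset:
    """Measured offset of tile b relative to tile a (pixels, row/col)."""

    drow: float
    dcol: float
    confidence: float
    fallback: bool = False


_GAUSS_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


def _quadratic_peak(y_m: float, y_0: float, y_p: float) -> float:
    """Sub-sample offset of a parabola through three equally spaced points."""
    denom = y_m - 2.0 * y_0 + y_p
    if denom >= 0:  # not a maximum; leave at the integer peak
        return 0.0
    delta = 0.5 * (y_m - y_p) / denom
    return float(np.clip(delta, -0.5, 0.5))


def pairwise_offset(
    a: ImageTile,
    b: ImageTile,
    axis: str,
    overlap_fraction: float,
    pixel_scale: float | None = None,
    margin: int = 8,
    min_confidence: float = 0.3,
    smooth_sigma: float = 1.5,
) -> PairOffset:
    """Offset of tile ``b`` relative to ``a`` along ``axis`` by NCC.

    Both overlap strips are Gaussian low-passed (``smooth_sigma`` px)
    before correlating: per-tile sensor noise is uncorrelated between the
    two exposures while the scene texture is shared, so the low-pass
    raises the correlation peak without biasing its position.

    ``axis`` is ``"horizontal"`` (b to the right of a) or ``"vertical"``
    (b below a).  The normalized cross-correlation of the overlap strips is
    maximized, refined to sub-pixel by quadratic interpolation of the
    correlation peak; ``confidence`` is the peak correlation.  A peak below
    ``min_confidence`` (e.g. featureless overlap) triggers fallback to the
    nominal grid offset.

    The nominal along-axis shift comes from the tiles' nominal stage
    positions when ``pixel_scale`` (µm/px) is given; otherwise from
    ``overlap_fraction`` assuming a uniform grid.
    """
    pa, pb = a.pixels, b.pixels
    if pa.shape != pb.shape:
        raise ValueError("tiles must have identical shapes")
    transposed = axis == "vertical"
    if transposed:
        pa, pb = pa.T, pb.T
    elif axis != "horizontal":
        raise ValueError("axis must be 'horizontal' or 'vertical'")
    h, w = pa.shape
    if pixel_scale is not None:
        stage_axis = 1 if transposed else 0  # stage is (x, y); rows move y
        shift = int(
            round(
                (b.nominal_stage_mm[stage_axis] - a.nominal_stage_mm[stage_axis])
                * 1000.0
                / pixel_scale
            )
        )
        if not (0 < shift < w):
            raise ValueError("tiles do not overlap along the requested axis")
    else:
        shift = w - int(round(w * overlap_fraction))
    w_ov = w - shift  # nominal overlap width
    m = margin
    if w_ov <= 2 * m + 2 or h <= 2 * m + 2:
        raise ValueError("overlap too small for the requested margin")

    strip = pa[:, shift - m :]  # (h, w_ov + m)
    tmpl = pb[m : h - m, : w_ov - m]  # smaller in both dims
    if smooth_sigma > 0:
        strip = ndimage.gaussian_filter(strip, smooth_sigma)
        tmpl = ndimage.gaussian_filter(tmpl, smooth_sigma)
    nominal = PairOffset(0.0, float(shift), 0.0, fallback=True)
    if strip.std() < 1e-12 or tmpl.std() < 1e-12:
        result = nominal
    else:
        ncc = match_template(strip, tmpl)
        peak = np.unravel_index(int(np.argmax(ncc)), ncc.shape)
        conf = float(ncc[peak])
        if conf < min_confidence:
            result = PairOffset(0.0, float(shift), conf, fallback=True)
        else:
            pi, pj = int(peak[0]), int(peak[1])
            di = dj = 0.0
            if 0 < pi < ncc.shape[0] - 1:
                di = _quadratic_peak(
                    ncc[pi - 1, pj], ncc[pi, pj], ncc[pi + 1, pj]
                )
            if 0 < pj < ncc.shape[1] - 1:
                dj = _quadratic_peak(
                    ncc[pi, pj - 1], ncc[pi, pj], ncc[pi, pj + 1]
                )
            result = PairOffset(
                drow=(pi + di) - m,
                dcol=shift + (pj + dj) - m,
                confidence=conf,
            )
    if transposed:
        return PairOffset(result.dcol, result.drow, result.confidence, result.fallback)
    return result


def _solve_axis(
    n_tiles: int,
    measurements: list[tuple[int, int, float, float]],
) -> np.ndarray:
    """Weighted least squares for one offset coordinate on the grid graph.

    Each measurement (i, j, value, weight) asserts o_j - o_i = value; the
    anchor tile 0 is pinned at 0 by a heavy extra equation.
    """
    rows = len(measurements) + 1
    a = np.zeros((rows, n_tiles))
    y = np.zeros(rows)
    for r, (i, j, value, weight) in enumerate(measurements):
        wgt = max(weight, 1e-3)
        a[r, i] = -wgt
        a[r, j] = wgt
        y[r] = wgt * value
    a[-1, 0] = 1e3
    sol, *_ = np.linalg.lstsq(a, y, rcond=None)
    return sol - sol[0]


def assemble(
    tiles: list[ImageTile],
    overlap_fraction: float,
    pixel_scale: float,
    margin: int = 8,
    min_confidence: float = 0.3,
) -> Montage:
    """Stitch a complete rectangular grid of tiles into a montage.

    Pairwise offsets along both grid directions are combined by
    confidence-weighted least squares (tile (0, 0) anchored), then the
    tiles are composited with linear feathering across the overlaps.
    """
    if not tiles:
        raise ValueError("no tiles to assemble")
    by_index = {t.grid_index: t for t in tiles}
    if len(by_index) != len(tiles):
        raise ValueError("duplicate grid indices")
    n_rows = max(r for r, _ in by_index) + 1
    n_cols = max(c for _, c in by_index) + 1
    missing = [
        (r, c)
        for r in range(n_rows)
        for c in range(n_cols)
        if (r, c) not in by_index
    ]
    if missing:
        raise ValueError(f"incomplete tile grid; missing {missing}")

    order = [(r, c) for r in range(n_rows) for c in range(n_cols)]
    index_of = {rc: i for i, rc in enumerate(order)}
    meas_row: list[tuple[int, int, float, float]] = []
    meas_col: list[tuple[int, int, float, float]] = []
    for r, c in order:
        if c + 1 < n_cols:
            off = pairwise_offset(
                by_index[(r, c)], by_index[(r, c + 1)], "horizontal",
                overlap_fraction, pixel_scale, margin, min_confidence,
            )
            i, j = index_of[(r, c)], index_of[(r, c + 1)]
            meas_row.append((i, j, off.drow, off.confidence))
            meas_col.append((i, j, off.dcol, off.confidence))
        if r + 1 < n_rows:
            off = pairwise_offset(
                by_index[(r, c)], by_index[(r + 1, c)], "vertical",
                overlap_fraction, pixel_scale, margin, min_confidence,
            )
            i, j = index_of[(r, c)], index_of[(r + 1, c)]
            meas_row.append((i, j, off.drow, off.confidence))
            meas_col.append((i, j, off.dcol, off.confidence))

    n = len(order)
    if n == 1:
        tile = tiles[0]
        return Montage(tile.pixels.copy(), {tile.grid_index: (0.0, 0.0)}, pixel_scale)
    rows_sol = _solve_axis(n, meas_row)
    cols_sol = _solve_axis(n, meas_col)
    offsets = {
        rc: (float(rows_sol[i]), float(cols_sol[i])) for rc, i in index_of.items()
    }

    # composite with linear feathering
    th, tw = tiles[0].pixels.shape
    r0 = min(o[0] for o in offsets.values())
    c0 = min(o[1] for o in offsets.values())
    shifted = {rc: (o[0] - r0, o[1] - c0) for rc, o in offsets.items()}
    height = int(math.ceil(max(o[0] for o in shifted.values()))) + th
    width = int(math.ceil(max(o[1] for o in shifted.values()))) + tw
    acc = np.zeros((height, width))
    wacc = np.zeros((height, width))
    feather = int(round(tw * overlap_fraction))
    ramp_r = np.minimum(
        np.minimum(np.arange(1, th + 1), np.arange(th, 0, -1)), feather
    ).astype(float)
    ramp_c = np.minimum(
        np.minimum(np.arange(1, tw + 1), np.arange(tw, 0, -1)), feather
    ).astype(float)
    weight = np.outer(ramp_r, ramp_c)
    for rc, (orow, ocol) in shifted.items():
        ir, ic = int(round(orow)), int(round(ocol))
        acc[ir : ir + th, ic : ic + tw] += by_index[rc].pixels * weight
        wacc[ir : ir + th, ic : ic + tw] += weight
    pixels = np.divide(acc, wacc, out=np.zeros_like(acc), where=wacc > 0)
    return Montage(pixels, offsets, pixel_scale)


def _gauss2d(params: np.ndarray, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    amp, x0, y0, sx, sy, bg = params
    return amp * np.exp(
        -((xx - x0) ** 2 / (2 * sx**2) + (yy - y0) ** 2 / (2 * sy**2))
    ) + bg


def fit_beam_center(image: np.ndarray, crop: int = 96) -> BeamReference:
    """Fit a 2D elliptical Gaussian + constant to the direct-beam image.

    The fit runs on a window of half-size ``crop`` around the brightest
    (smoothed) pixel.  Raises ValueError when no dominant spot exists or
    the spot touches the image border.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("beam image must be 2D")
    bg = float(np.median(img))
    noise = float(np.median(np.abs(img - bg))) * 1.4826 + 1e-12
    peak_val = float(img.max())
    if peak_val - bg < max(6.0 * noise, 1e-6):
        raise ValueError("no dominant spot found in the beam image")
    pr, pc = np.unravel_index(int(np.argmax(img)), img.shape)
    if (
        pr < 3 or pc < 3 or pr > img.shape[0] - 4 or pc > img.shape[1] - 4
    ):
        raise ValueError("beam spot too close to the image border")

    r0 = max(0, pr - crop)
    r1 = min(img.shape[0], pr + crop + 1)
    c0 = max(0, pc - crop)
    c1 = min(img.shape[1], pc + crop + 1)
    win = img[r0:r1, c0:c1]
    yy, xx = np.mgrid[r0:r1, c0:c1].astype(float)

    excess = np.clip(win - bg, 0, None)
    total = excess.sum()
    cx = float((xx * excess).sum() / total)
    cy = float((yy * excess).sum() / total)
    sx = math.sqrt(max(float(((xx - cx) ** 2 * excess).sum() / total), 0.25))
    sy = math.sqrt(max(float(((yy - cy) ** 2 * excess).sum() / total), 0.25))
    p0 = np.array([peak_val - bg, cx, cy, sx, sy, bg])

    def residuals(p: np.ndarray) -> np.ndarray:
        return (_gauss2d(p, xx, yy) - win).ravel()

    res = optimize.least_squares(residuals, p0, method="lm", max_nfev=2000)
    amp, x0, y0, sx, sy, bgf = res.x
    if not res.success or amp <= 0:
        raise ValueError("beam profile fit did not converge")
    if not (c0 <= x0 <= c1 - 1 and r0 <= y0 <= r1 - 1):
        raise ValueError("fitted beam center outside the image")
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return BeamReference(
        center=(float(x0), float(y0)),
        fwhm=(abs(sx) * _GAUSS_FWHM, abs(sy) * _GAUSS_FWHM),
        fit_residual=rms / float(amp),
    )
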