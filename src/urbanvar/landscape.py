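"""Impervious-surface (ISA) quantification around nest boxes.

A raster of imperviousness density is summarized inside circular buffers of
100/250/1000 m radius centered on nest-box coordinates; per-location mean and
variance of the per-box proportions feed the gradient analysis, and the mean
at the 1000 m scale drives the forest/urban classification.

Conventions (documented, since zonal tooling differs): coordinates are planar
meters, the raster origin is the lower-left corner, storage is row-major with
row 0 the *bottom* row, and a pixel belongs to a buffer iff its center lies
within Euclidean distance ``radius_m`` of the point (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DimensionError,
    DomainError,
    EmptyBufferError,
    OutOfExtentError,
)

DEFAULT_SCALES_M = (100.0, 250.0, 1000.0)
FOREST_ISA_THRESHOLD = 0.05

Pattern = Literal["uniform_p", "blocks", "gradient"]


@dataclass(frozen=True)
class ISARaster:
    """Imperviousness grid in [0, 1] on a planar, regularly spaced lattice.

    Attributes
    ----------
    values:
        2-D array, shape ``(n_rows, n_cols)``; ``values[0, 0]`` is the
        bottom-left pixel.
    resolution_m:
        Pixel edge length in meters.
    origin:
        Planar ``(x, y)`` of the grid's lower-left corner, meters.
    """

    values: np.ndarray
    resolution_m: float = 10.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.size == 0:
            raise DimensionError("raster must be a non-empty 2-D grid")
        if self.resolution_m <= 0:
            raise DimensionError(f"resolution_m must be > 0, got {self.resolution_m}")
        if np.any(vals < 0) or np.any(vals > 1):
            raise DomainError("raster values must lie in [0, 1]")
        object.__setattr__(self, "values", vals)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the covered rectangle."""
        n_rows, n_cols = self.values.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + n_cols * self.resolution_m, y0 + n_rows * self.resolution_m)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of x-coordinates (per column) and y-coordinates (per row)."""
        n_rows, n_cols = self.values.shape
        half = self.resolution_m / 2.0
        xs = self.origin[0] + half + self.resolution_m * np.arange(n_cols)
        ys = self.origin[1] + half + self.resolution_m * np.arange(n_rows)
        return xs, ys

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return xmin <= x <= xmax and ymin <= y <= ymax


@dataclass(frozen=True)
class NestBox:
    """A sampling point (nest box) with planar coordinates in meters."""

    box_id: str
    location_id: str
    x_m: float
    y_m: float


@dataclass(frozen=True)
class SiteISA:
    """Per-location summary of per-box ISA proportions at one buffer scale."""

    location_id: str
    scale_m: float
    mean_isa: float
    var_isa: float
    n_boxes: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_isa <= 1.0:
            raise DomainError(f"mean_isa out of [0,1]: {self.mean_isa}")
        if self.var_isa < 0:
            raise DomainError(f"var_isa must be >= 0: {self.var_isa}")


def generate_synthetic_isa_raster(
    width_px: int,
    height_px: int,
    resolution_m: float = 10.0,
    pattern: Pattern = "blocks",
    seed: int = 0,
    *,
    p: float = 0.5,
    block_px: int = 8,
    fractional: bool = False,
    origin: tuple[float, float] = (0.0, 0.0),
) -> ISARaster:
    """Generate a reproducible synthetic imperviousness raster.

    Patterns
    --------
    ``uniform_p``
        Every cell is Bernoulli(``p``) (binary) or equal to ``p``
        (``fractional=True``).
    ``blocks``
        Square blocks of ``block_px`` pixels are switched on with
        probability ``p`` (sealed city blocks vs. open ground).
    ``gradient``
        Probability of imperviousness rises linearly from 0 (left edge)
        to 1 (right edge).
    """
    if width_px < 1 or height_px < 1:
        raise DimensionError(f"raster dimensions must be >= 1, got {width_px}x{height_px}")
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"p must lie in [0,1], got {p}")
    rng = np.random.default_rng(seed)
    shape = (height_px, width_px)
    if pattern == "uniform_p":
        if fractional:
            values = np.full(shape, float(p))
        elif p in (0.0, 1.0):  # degenerate corners stay exact
            values = np.full(shape, float(p))
        else:
            values = rng.random(shape) < p
    elif pattern == "blocks":
        if block_px < 1:
            raise DimensionError("block_px must be >= 1")
        n_br = -(-height_px // block_px)
        n_bc = -(-width_px // block_px)
        blocks = rng.random((n_br, n_bc)) < p
        values = np.kron(blocks, np.ones((block_px, block_px)))[:height_px, :width_px]
        if fractional:
            values = values * rng.uniform(0.5, 1.0, size=shape)
    elif pattern == "gradient":
        prob = np.linspace(0.0, 1.0, width_px)[None, :] * np.ones((height_px, 1))
        values = prob if fractional else (rng.random(shape) < prob)
    else:
        raise DomainError(f"unknown pattern {pattern!r}")
    return ISARaster(np.asarray(values, dtype=float), resolution_m, origin)


def isa_proportion_in_buffer(
    raster: ISARaster, point: tuple[float, float], radius_m: float
) -> float:
    """Proportion of impervious surface within a circular buffer.

    Returns the mean raster value over pixels whose *centers* lie within
    Euclidean distance ``radius_m`` (inclusive) of ``point``.
    """
    if radius_m <= 0:
        raise DomainError(f"radius_m must be > 0, got {radius_m}")
    x, y = point
    xs, ys = raster.pixel_centers()
    dx2 = (xs - x) ** 2
    dy2 = (ys - y) ** 2
    # Rectangular pre-crop keeps the mask O(buffer) instead of O(raster).
    ci = np.nonzero(dx2 <= radius_m**2)[0]
    ri = np.nonzero(dy2 <= radius_m**2)[0]
    if ci.size == 0 or ri.size == 0:
        raise EmptyBufferError(
            f"buffer of radius {radius_m} m at {point} contains no pixel centers"
        )
    inside = dy2[ri][:, None] + dx2[ci][None, :] <= radius_m**2
    n = int(inside.sum())
    if n == 0:
        raise EmptyBufferError(
            f"buffer of radius {radius_m} m at {point} contains no pixel centers"
        )
    sub = raster.values[np.ix_(ri, ci)]
    return float(sub[inside].sum() / n)


def site_isa_summary(
    raster: ISARaster, boxes: Sequence[NestBox], radius_m: float
) -> list[SiteISA]:
    """Per-location mean and sample variance (ddof=1; 0 when n=1) of box ISA."""
    if not boxes:
        raise DomainError("no nest boxes supplied")
    for box in boxes:
        if not raster.contains(box.x_m, box.y_m):
            raise OutOfExtentError(
                f"nest box {box.box_id!r} at ({box.x_m}, {box.y_m}) "
                f"lies outside the raster extent {raster.extent}"
            )
    props: dict[str, list[float]] = {}
    for box in boxes:
        value = isa_proportion_in_buffer(raster, (box.x_m, box.y_m), radius_m)
        props.setdefault(box.location_id, []).append(value)
    out = []
    for loc in sorted(props):
        vals = np.asarray(props[loc])
        var = float(np.var(vals, ddof=1)) if vals.size > 1 else 0.0
        out.append(
            SiteISA(
                location_id=loc,
                scale_m=float(radius_m),
                mean_isa=float(vals.mean()),
                var_isa=var,
                n_boxes=int(vals.size),
            )
        )
    return out


def classify_habitat(mean_isa_at_1000m: float) -> str:
    """``forest`` iff mean ISA at the 1000 m scale is below 5%; else ``urban``."""
    if not 0.0 <= mean_isa_at_1000m <= 1.0:
        raise DomainError(f"mean ISA must lie in [0,1], got {mean_isa_at_1000m}")
    return "forest" if mean_isa_at_1000m < FOREST_ISA_THRESHOLD else "urban"


# ---------------------------------------------------------------------------
# I/O: Esri ASCII grid, optional plain TIFF, nest-box CSV, site summaries
# ---------------------------------------------------------------------------

def write_ascii_grid(raster: ISARaster, path: str | Path) -> None:
    """Write an Esri ASCII grid (.asc). Rows are written top-down per spec."""
    n_rows, n_cols = raster.shape
    header = (
        f"ncols {n_cols}\n"
        f"nrows {n_rows}\n"
        f"xllcorner {raster.origin[0]}\n"
        f"yllcorner {raster.origin[1]}\n"
        f"cellsize {raster.resolution_m}\n"
        f"NODATA_value -9999\n"
    )
    body = raster.values[::-1]  # internal row 0 = bottom; file row 0 = top
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> ISARaster:
    """Read an Esri ASCII grid into an :class:`ISARaster`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    values = np.loadtxt(lines[i:])
    values = np.atleast_2d(values)[::-1]
    return ISARaster(
        values,
        resolution_m=header.get("cellsize", 10.0),
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
    )


def write_tiff(raster: ISARaster, path: str | Path) -> None:
    """Write the grid as a single-band TIFF (requires ``tifffile``)."""
    import tifffile

    tifffile.imwrite(str(path), raster.values[::-1].astype("float32"))


def read_tiff(
    path: str | Path,
    resolution_m: float = 10.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> ISARaster:
    """Read a single-band TIFF; georeferencing is supplied by the caller."""
    import tifffile

    values = np.asarray(tifffile.imread(str(path)), dtype=float)
    if values.ndim == 3:
        values = values[..., 0]
    return ISARaster(values[::-1], resolution_m=resolution_m, origin=origin)


def read_raster(path: str | Path, **kwargs) -> ISARaster:
    """Dispatch on file extension (.asc/.txt → ASCII grid, .tif/.tiff → TIFF)."""
    suffix = Path(path).suffix.lower()
    if suffix in {".tif", ".tiff"}:
        return read_tiff(path, **kwargs)
    return read_ascii_grid(path)


def read_nest_boxes(path: str | Path) -> list[NestBox]:
    """Read nest boxes from CSV with columns box_id, location_id, x_m, y_m."""
    df = pd.read_csv(path)
    required = {"box_id", "location_id", "x_m", "y_m"}
    missing = required - set(df.columns)
    if missing:
        from .errors import SchemaError

        raise SchemaError(f"nest-box CSV missing columns: {sorted(missing)}")
    return [
        NestBox(str(r.box_id), str(r.location_id), float(r.x_m), float(r.y_m))
        for r in df.itertuples()
    ]


def site_summaries_to_frame(summaries: Iterable[SiteISA]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "location_id": s.location_id,
                "scale_m": s.scale_m,
                "mean_isa": s.mean_isa,
                "var_isa": s.var_isa,
                "n_boxes": s.n_boxes,
            }
            for s in summaries
        ]
    )
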