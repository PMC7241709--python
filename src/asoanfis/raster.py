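"""Minimal georeferenced raster container and grid operations.

A :class:`Raster` is a 2-D float array plus an affine cell-center
georeference ``(x0, y0, dx, dy)``: the center of cell ``(row, col)`` sits at
``x = x0 + (col + 0.5) * dx`` and ``y = y0 + (row + 0.5) * dy``.  ``dy`` is
normally negative (north-up imagery).  Nodata is encoded as NaN; ``mask``
exposes the validity grid.

Stacks of named, co-registered rasters round-trip through plain multi-band
TIFF files with the georeference and band names embedded as JSON in the
image-description tag, so no GIS stack is required to read them back.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class Raster:
    data: np.ndarray
    transform: tuple[float, float, float, float]  # (x0, y0, dx, dy)
    crs: str = "EPSG:32648"  # WGS84 / UTM 48N unless stated otherwise

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        x0, y0, dx, dy = self.transform
        if dx == 0 or dy == 0:
            raise ValueError("cell sizes dx, dy must be nonzero")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def mask(self) -> np.ndarray:
        """True where the cell holds a valid value."""
        return np.isfinite(self.data)

    def rowcol_to_world(self, row, col):
        x0, y0, dx, dy = self.transform
        return x0 + (np.asarray(col) + 0.5) * dx, y0 + (np.asarray(row) + 0.5) * dy

    def world_to_rowcol(self, x, y):
        """Fractional (row, col); integer parts index the containing cell."""
        x0, y0, dx, dy = self.transform
        return (np.asarray(y) - y0) / dy - 0.5, (np.asarray(x) - x0) / dx - 0.5

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the cell-edge extent."""
        nr, nc = self.data.shape
        x0, y0, dx, dy = self.transform
        xs = sorted((x0, x0 + nc * dx))
        ys = sorted((y0, y0 + nr * dy))
        return xs[0], ys[0], xs[1], ys[1]

    def same_grid(self, other: "Raster", atol: float = 1e-9) -> bool:
        return self.shape == other.shape and np.allclose(
            self.transform, other.transform, atol=atol
        )

    def copy_with(self, data: np.ndarray) -> "Raster":
        return Raster(np.asarray(data, dtype=float), self.transform, self.crs)


def require_same_grid(*rasters: Raster) -> None:
    ref = rasters[0]
    for r in rasters[1:]:
        if not ref.same_grid(r):
            raise ValueError(
                f"rasters are not co-registered: transform {r.transform} / shape "
                f"{r.shape} vs reference {ref.transform} / {ref.shape}"
            )


def resample_to_reference(src: Raster, ref: Raster) -> Raster:
    """Bilinear resampling of ``src`` onto the grid of ``ref``.

    Any NaN cell with nonzero weight in the 2x2 support masks the output
    cell; target cells outside the source extent are masked too.
    """
    sxmin, symin, sxmax, symax = src.bounds()
    rxmin, rymin, rxmax, rymax = ref.bounds()
    if rxmin >= sxmax or rxmax <= sxmin or rymin >= symax or rymax <= symin:
        raise ValueError("source and reference extents are disjoint")

    nr, nc = ref.shape
    rows = np.arange(nr)[:, None] * np.ones((1, nc))
    cols = np.ones((nr, 1)) * np.arange(nc)[None, :]
    x, y = ref.rowcol_to_world(rows, cols)
    fr, fc = src.world_to_rowcol(x, y)

    sr, sc = src.shape
    r0 = np.floor(fr).astype(int)
    c0 = np.floor(fc).astype(int)
    tr = fr - r0
    tc = fc - c0

    out = np.full((nr, nc), np.nan)
    # valid support: all four neighbours inside the source grid (edge cells
    # use clamped duplicate rows/cols so the border remains usable)
    r0c = np.clip(r0, 0, sr - 1)
    r1c = np.clip(r0 + 1, 0, sr - 1)
    c0c = np.clip(c0, 0, sc - 1)
    c1c = np.clip(c0 + 1, 0, sc - 1)
    inside = (fr >= -0.5) & (fr <= sr - 0.5) & (fc >= -0.5) & (fc <= sc - 0.5)

    v00 = src.data[r0c, c0c]
    v01 = src.data[r0c, c1c]
    v10 = src.data[r1c, c0c]
    v11 = src.data[r1c, c1c]
    interp = (
        v00 * (1 - tr) * (1 - tc)
        + v01 * (1 - tr) * tc
        + v10 * tr * (1 - tc)
        + v11 * tr * tc
    )
    out[inside] = interp[inside]
    return ref.copy_with(out)


# ---------------------------------------------------------------------------
# TIFF round-trip for named stacks


def write_stack(path, bands: dict[str, Raster]) -> None:
    names = list(bands)
    require_same_grid(*bands.values())
    ref = bands[names[0]]
    cube = np.stack([bands[n].data for n in names]).astype("float32")
    meta = {"bands": names, "transform": list(ref.transform), "crs": ref.crs}
    kwargs = {"photometric": "minisblack"}
    if cube.shape[0] > 1:
        kwargs["planarconfig"] = "separate"
    tifffile.imwrite(str(path), cube, description=json.dumps(meta), **kwargs)


def read_stack(path) -> dict[str, Raster]:
    with tifffile.TiffFile(str(path)) as tif:
        cube = tif.asarray()
        meta = json.loads(tif.pages[0].tags["ImageDescription"].value)
    if cube.ndim == 2:
        cube = cube[None]
    transform = tuple(meta["transform"])
    return {
        name: Raster(cube[i].astype(float), transform, meta["crs"])
        for i, name in enumerate(meta["bands"])
    }
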