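"""Predictor-variable engineering for optical + SAR biomass mapping.

The predictor set holds 42 named variables: the four multispectral
reflectance bands (blue/green/red/NIR), the two dual-pol backscatter bands
(VV, VH in sigma-nought dB), four polarisation combinations, and 32 spectral
vegetation/soil/colour indices.  Index formulas live in a data-driven
registry (name -> expression over the symbols B, G, R, N plus the soil-line
constants a, b) so the set is auditable and overridable; the registry can be
serialised to and reloaded from JSON.

Two indices need a word of caution.  ``CIRED_EDGE`` is defined in the
literature on a red-edge band that 4-band sensors such as SPOT-6 lack; the
registry carries the NIR/red surrogate ``N/R - 1``.  ``VIN`` (simple ratio
``N/R``) is registered as an *extra* variable — it is not part of the
42-band stack but is available to feature-selection outputs that name it.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import Raster, require_same_grid

__all__ = [
    "MultispectralScene",
    "SarScene",
    "INDEX_REGISTRY",
    "SOIL_LINE",
    "STACK_BAND_NAMES",
    "compute_sar_combos",
    "compute_spectral_indices",
    "build_feature_stack",
    "extract_plot_features",
    "save_registry",
    "load_registry",
]

_DIV_EPS = 1e-12


@dataclass
class MultispectralScene:
    """Four co-registered surface-reflectance bands in [0, 1]."""

    blue: Raster
    green: Raster
    red: Raster
    nir: Raster

    def __post_init__(self) -> None:
        for name in ("blue", "green", "red", "nir"):
            if getattr(self, name) is None:
                raise ValueError(f"multispectral scene is missing the {name} band")
        require_same_grid(self.blue, self.green, self.red, self.nir)

    @property
    def grid(self) -> Raster:
        return self.nir


@dataclass
class SarScene:
    """Calibrated dual-pol backscatter (sigma-nought, dB)."""

    vv: Raster
    vh: Raster

    def __post_init__(self) -> None:
        if self.vv is None or self.vh is None:
            raise ValueError("SAR scene needs both VV and VH bands")
        require_same_grid(self.vv, self.vh)


# ---------------------------------------------------------------------------
# Index registry

SOIL_LINE = {"a": 1.22, "b": 0.03}  # soil-line slope / intercept

# Expressions over B, G, R, N (reflectances) and the soil-line constants.
# rb is the blue-corrected red used by the atmospherically resistant family.
INDEX_REGISTRY: dict[str, str] = {
    "ARVI": "(N - (2*R - B)) / (N + (2*R - B))",
    "ATSAVI": "a*(N - a*R - b) / (a*N + R - a*b + 0.08*(1 + a**2))",
    "AVI": "2*N - R",
    "BWDRVI": "(0.1*N - B) / (0.1*N + B)",
    "CI": "(R - B) / R",
    "CIGREEN": "N/G - 1",
    "CIRED_EDGE": "N/R - 1",  # red-edge surrogate on a 4-band sensor
    "CVI": "N * R / G**2",
    "DVI": "N - R",
    "EVI": "2.5*(N - R) / (N + 6*R - 7.5*B + 1)",
    "GI": "G / R",
    "GLI": "(2*G - R - B) / (2*G + R + B)",
    "GNDVI": "(N - G) / (N + G)",
    "GSAVI": "1.5*(N - G) / (N + G + 0.5)",
    "GRVI": "N / G",
    "I": "(R + G + B) / 3",
    "IF": "(2*R - G - B) / (G - B)",
    "MSAVI": "(2*N + 1 - sqrt((2*N + 1)**2 - 8*(N - R))) / 2",
    "NDVI": "(N - R) / (N + R)",
    "OSAVI": "(N - R) / (N + R + 0.16)",
    "PBI": "N / G",
    "PNDVI": "(N - (G + R + B)) / (N + (G + R + B))",
    "PVI": "(N - a*R - b) / sqrt(1 + a**2)",
    "RDVI": "(N - R) / sqrt(N + R)",
    "RI": "(R - G) / (R + G)",
    "SAVI": "1.5*(N - R) / (N + R + 0.5)",
    "SIPI3": "(N - B) / (N - R)",
    "TSARVI": "a*(N - a*(2*R - B) - b) / ((2*R - B) + a*N - a*b + 0.08*(1 + a**2))",
    "TSAVI": "a*(N - a*R - b) / (R + a*N - a*b)",
    "TVI": "sqrt((N - R)/(N + R) + 0.5)",
    "WDRVI": "(0.1*N - R) / (0.1*N + R)",
    "WDVI": "N - a*R",
}

#: Extra registered variables available to selection outputs but not stacked.
EXTRA_REGISTRY: dict[str, str] = {"VIN": "N / R"}

SAR_COMBO_NAMES = ["AVERAGE_vhvv", "DIFF_vvvh", "MULT_vhvv", "RATIO_vvvh"]
STACK_BAND_NAMES = (
    ["BLUE", "GREEN", "RED", "NIR", "VV", "VH"]
    + SAR_COMBO_NAMES
    + sorted(INDEX_REGISTRY)
)
assert len(STACK_BAND_NAMES) == 42


def save_registry(path, registry: dict[str, str] | None = None) -> None:
    payload = {
        "version": 1,
        "constants": SOIL_LINE,
        "formulas": dict(registry or INDEX_REGISTRY),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_registry(path) -> dict[str, str]:
    with open(path) as fh:
        payload = json.load(fh)
    return dict(payload["formulas"])


def _safe_divide(num, den):
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    out = np.asarray(out, dtype=float)
    out[np.abs(np.asarray(den, dtype=float)) < _DIV_EPS] = np.nan
    return out


def evaluate_formula(expr: str, B, G, R, N, constants=None):
    """Evaluate a registry expression on band arrays, masking zero divides.

    Division is rewritten through a guard so a vanishing denominator yields a
    masked (NaN) cell rather than an inf that would silently propagate.
    """
    env = {
        "B": np.asarray(B, float),
        "G": np.asarray(G, float),
        "R": np.asarray(R, float),
        "N": np.asarray(N, float),
        "sqrt": _nan_sqrt,
        "div": _safe_divide,
        **(constants or SOIL_LINE),
    }
    expr = _rewrite_divisions(expr)
    return np.asarray(eval(expr, {"__builtins__": {}}, env), dtype=float)


def _nan_sqrt(x):
    with np.errstate(invalid="ignore"):
        return np.sqrt(np.asarray(x, float))


def _rewrite_divisions(expr: str) -> str:
    """Rewrite top-level ``p / q`` into ``div(p, q)`` (left-assoc, paren-aware)."""
    import ast

    class Xform(ast.NodeTransformer):
        def visit_BinOp(self, node):
            self.generic_visit(node)
            if isinstance(node.op, ast.Div):
                return ast.Call(
                    func=ast.Name(id="div", ctx=ast.Load()),
                    args=[node.left, node.right],
                    keywords=[],
                )
            return node

    tree = ast.parse(expr, mode="eval")
    return ast.unparse(ast.fix_missing_locations(Xform().visit(tree)))


# ---------------------------------------------------------------------------
# Band computation


def compute_sar_combos(sar: SarScene, linear_power: bool = False) -> dict[str, Raster]:
    """Four polarisation combinations of VV and VH.

    Computed on the sigma-nought dB values as provided (the convention the
    variable names imply); set ``linear_power=True`` to convert to linear
    power first.
    """
    vv, vh = sar.vv.data, sar.vh.data
    if linear_power:
        vv = 10.0 ** (vv / 10.0)
        vh = 10.0 ** (vh / 10.0)
    grid = sar.vv
    return {
        "AVERAGE_vhvv": grid.copy_with((vh + vv) / 2.0),
        "DIFF_vvvh": grid.copy_with(vv - vh),
        "MULT_vhvv": grid.copy_with(vh * vv),
        "RATIO_vvvh": grid.copy_with(_safe_divide(vv, vh)),
    }


def compute_spectral_indices(
    ms: MultispectralScene, registry: dict[str, str] | None = None
) -> dict[str, Raster]:
    registry = registry or INDEX_REGISTRY
    B, G, R, N = ms.blue.data, ms.green.data, ms.red.data, ms.nir.data
    grid = ms.grid
    return {
        name: grid.copy_with(evaluate_formula(expr, B, G, R, N))
        for name, expr in registry.items()
    }


def build_feature_stack(ms: MultispectralScene, sar: SarScene) -> dict[str, Raster]:
    """Assemble the full 42-band predictor stack on the multispectral grid."""
    require_same_grid(ms.grid, sar.vv)
    stack = {
        "BLUE": ms.blue,
        "GREEN": ms.green,
        "RED": ms.red,
        "NIR": ms.nir,
        "VV": sar.vv,
        "VH": sar.vh,
    }
    stack.update(compute_sar_combos(sar))
    stack.update(compute_spectral_indices(ms))
    ordered = {name: stack[name] for name in STACK_BAND_NAMES}
    assert len(ordered) == 42
    return ordered


# ---------------------------------------------------------------------------
# Plot extraction


@dataclass
class PlotRecord:
    id: object
    x: float
    y: float
    area_m2: float
    agb: float | None = None

    def __post_init__(self) -> None:
        if self.area_m2 <= 0:
            raise ValueError("plot area must be positive")


def read_plot_table(path) -> list[PlotRecord]:
    df = pd.read_csv(path)
    return [
        PlotRecord(
            row["id"],
            float(row["x"]),
            float(row["y"]),
            float(row["area_m2"]),
            float(row["agb"]) if "agb" in df.columns and np.isfinite(row.get("agb", np.nan)) else None,
        )
        for _, row in df.iterrows()
    ]


def _window_weights(raster: Raster, x: float, y: float, side: float) -> tuple:
    """Area-overlap weights of an axis-aligned square window on the grid.

    Returns (row slice, col slice, weight grid) or None if the window misses
    the raster entirely.  Weights are the fractional overlap of each cell
    with the window, so a weighted mean equals the exact areal average of a
    piecewise-constant surface.
    """
    x0, y0, dx, dy = raster.transform
    nr, nc = raster.shape
    half = side / 2.0
    # window edges in fractional col/row units (cell edges at integers)
    c_lo = (x - half - x0) / dx
    c_hi = (x + half - x0) / dx
    r_lo = (y - half - y0) / dy
    r_hi = (y + half - y0) / dy
    c_lo, c_hi = sorted((c_lo, c_hi))
    r_lo, r_hi = sorted((r_lo, r_hi))
    ci0 = max(int(math.floor(c_lo)), 0)
    ci1 = min(int(math.ceil(c_hi)), nc)
    ri0 = max(int(math.floor(r_lo)), 0)
    ri1 = min(int(math.ceil(r_hi)), nr)
    if ci0 >= ci1 or ri0 >= ri1:
        return None
    cols = np.arange(ci0, ci1)
    rows = np.arange(ri0, ri1)
    wc = np.minimum(cols + 1, c_hi) - np.maximum(cols, c_lo)
    wr = np.minimum(rows + 1, r_hi) - np.maximum(rows, r_lo)
    w = np.clip(wr, 0, None)[:, None] * np.clip(wc, 0, None)[None, :]
    return slice(ri0, ri1), slice(ci0, ci1), w


def extract_plot_features(
    stack: dict[str, Raster], plots: list[PlotRecord], target_column: str = "agb"
) -> pd.DataFrame:
    """Per-plot area-weighted mean of every band over the plot's square window.

    The window is the axis-aligned square of area ``area_m2`` centred on the
    plot; cells are weighted by their fractional overlap with it.  Plots
    falling outside the raster (or on fully masked cells) are dropped with a
    warning.  Rows are ordered by plot id.
    """
    names = list(stack)
    require_same_grid(*stack.values())
    ref = stack[names[0]]
    cube = np.stack([stack[n].data for n in names])

    rows = []
    for plot in sorted(plots, key=lambda p: str(p.id)):
        win = _window_weights(ref, plot.x, plot.y, math.sqrt(plot.area_m2))
        if win is None:
            warnings.warn(f"plot {plot.id} lies outside the raster extent; skipped")
            continue
        rs, cs, w = win
        sub = cube[:, rs, cs]
        valid = np.isfinite(sub)
        wsum = (w[None] * valid).sum(axis=(1, 2))
        if np.any(wsum <= 0):
            warnings.warn(f"plot {plot.id} has no valid cells in some band; skipped")
            continue
        vals = np.nansum(sub * w[None], axis=(1, 2)) / wsum
        record = {"id": plot.id, **dict(zip(names, vals))}
        if plot.agb is not None:
            record[target_column] = plot.agb
        rows.append(record)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.set_index("id")
    return df
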