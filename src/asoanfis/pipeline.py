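"""Wall-to-wall mapping: AGB prediction rasters, class maps, area cross-tabs.

Once an ASO-ANFIS is trained on plot features, the same forward model is
applied per cell of the predictor stack to produce the biomass map, a
segment-level one-vs-rest classifier yields the six-class mangrove-type
map, and the two maps are crossed into an area table (hectares per class
and biomass bin).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anfis import predict_batch
from .raster import Raster, require_same_grid

__all__ = [
    "PipelineConfig",
    "DEFAULT_CLASS_REGISTRY",
    "predict_map",
    "classify_map",
    "crosstab_area",
]

DEFAULT_AGB_BIN_EDGES = (50.0, 100.0, 150.0, 200.0)  # Mg/ha, five ranges

DEFAULT_CLASS_REGISTRY = {
    1: "Natural Rhizophora forest",
    2: "Natural mixed Avicennia/Rhizophora forest",
    3: "Natural regeneration of Avicennia forest",
    4: "Rhizophora plantation forest",
    5: "Avicennia plantation forest",
    6: "Other mangrove forest and shrubs",
}


@dataclass
class PipelineConfig:
    n_rules: int = 5
    n_atoms: int = 30
    n_iterations: int = 200
    selection_method: str = "ga"
    split_seed: int = 0
    agb_bin_edges: tuple[float, ...] = DEFAULT_AGB_BIN_EDGES
    class_registry: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_REGISTRY))

    def __post_init__(self) -> None:
        edges = list(self.agb_bin_edges)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("AGB bin edges must be strictly increasing")


def predict_map(
    stack: dict[str, Raster],
    model,
    selected_features: list[str],
    mask: Raster | None = None,
) -> Raster:
    """Apply a fitted regressor cell-wise; masked cells become nodata.

    ``model`` is anything with a ``predict`` taking (n, m) arrays — the
    fitted estimator, so map and tabular predictions agree bitwise.
    """
    missing = [f for f in selected_features if f not in stack]
    if missing:
        raise KeyError(f"stack is missing required bands: {missing}")
    bands = [stack[f] for f in selected_features]
    require_same_grid(*bands)
    ref = bands[0]
    cube = np.stack([b.data for b in bands], axis=-1)  # (r, c, m)
    nr, nc, m = cube.shape

    valid = np.isfinite(cube).all(axis=-1)
    if mask is not None:
        require_same_grid(ref, mask)
        valid &= mask.mask & (mask.data > 0)
    out = np.full((nr, nc), np.nan)
    if valid.any():
        out[valid] = model.predict(cube[valid].reshape(-1, m))
    return ref.copy_with(out)


def classify_map(
    segment_features: pd.DataFrame,
    classifier,
    segment_raster: Raster,
    feature_columns: list[str] | None = None,
) -> Raster:
    """Per-segment classification rasterised by segment id.

    ``segment_features`` is indexed by segment id with one feature row per
    segment (segmentation itself is upstream); ``segment_raster`` holds the
    segment id per cell.  Returns the class-code raster.
    """
    feats = feature_columns or list(segment_features.columns)
    codes = classifier.predict(segment_features[feats].to_numpy(float))
    lookup = dict(zip(segment_features.index, codes))
    out = np.full(segment_raster.shape, np.nan)
    seg = segment_raster.data
    for sid, code in lookup.items():
        out[seg == sid] = code
    return segment_raster.copy_with(out)


def crosstab_area(
    class_map: Raster,
    agb_map: Raster,
    bin_edges: tuple[float, ...] = DEFAULT_AGB_BIN_EDGES,
    class_registry: dict | None = None,
) -> pd.DataFrame:
    """Hectares per (mangrove class, AGB bin), with row/column totals.

    Cell area comes from the class map's georeference.  Only cells valid in
    both maps are tallied, so the grand total equals the jointly unmasked
    area exactly.
    """
    require_same_grid(class_map, agb_map)
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    registry = class_registry or DEFAULT_CLASS_REGISTRY

    _, _, dx, dy = class_map.transform
    cell_ha = abs(dx * dy) / 10000.0
    valid = class_map.mask & agb_map.mask
    cls = class_map.data[valid].astype(int)
    agb = agb_map.data[valid]
    bins = np.digitize(agb, edges)  # 0..len(edges)

    full_edges = [0.0] + edges
    labels = [
        f"{full_edges[i]:g}-{edges[i]:g}" if i < len(edges) else f">{edges[-1]:g}"
        for i in range(len(edges) + 1)
    ]
    table = pd.DataFrame(
        0.0, index=[registry.get(c, str(c)) for c in sorted(registry)], columns=labels
    )
    for code in sorted(registry):
        name = registry.get(code, str(code))
        sel = cls == code
        for b in range(len(labels)):
            table.loc[name, labels[b]] = float(np.sum(sel & (bins == b))) * cell_ha
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    return table
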