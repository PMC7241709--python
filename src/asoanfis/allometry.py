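"""Species allometry: per-tree and per-plot aboveground biomass from DBH.

Each mangrove species carries a power law ``AGB = a * DBH**b`` giving dry
mass in kilograms per tree from the diameter at breast height in
centimetres.  Plot totals are converted to megagrams per hectare with the
plot area.  The five-species registry covers the two genera dominating
Ca Mau-type mangrove stands and can be overridden from JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "SpeciesAllometry",
    "TreeRecord",
    "PlotInventory",
    "ALLOMETRY_REGISTRY",
    "tree_agb",
    "plot_agb",
    "read_tree_inventory",
    "load_allometry_registry",
]


@dataclass(frozen=True)
class SpeciesAllometry:
    species: str
    a: float  # kg cm^-b
    b: float  # dimensionless exponent

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("allometric coefficients must be positive")

    def agb_kg(self, dbh_cm: float) -> float:
        if dbh_cm <= 0:
            raise ValueError("DBH must be positive")
        return self.a * dbh_cm**self.b


ALLOMETRY_REGISTRY: dict[str, SpeciesAllometry] = {
    s.species: s
    for s in [
        SpeciesAllometry("Avicennia marina", 0.308, 2.11),
        SpeciesAllometry("Avicennia alba", 0.131, 2.46),
        SpeciesAllometry("Rhizophora apiculata", 0.235, 2.42),
        SpeciesAllometry("Rhizophora mucronata", 0.169, 2.46),
        SpeciesAllometry("Bruguiera gymnorrhiza", 0.186, 2.31),
    ]
}


@dataclass
class TreeRecord:
    species: str
    dbh_cm: float


@dataclass
class PlotInventory:
    plot_id: object
    area_m2: float
    trees: list[TreeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.area_m2 <= 0:
            raise ValueError("plot area must be positive")


def _resolve_species(
    species: str, registry: dict[str, SpeciesAllometry], genus_fallback: bool
) -> SpeciesAllometry:
    if species in registry:
        return registry[species]
    if genus_fallback:
        genus = species.split()[0]
        congeners = [s for s in registry.values() if s.species.split()[0] == genus]
        if congeners:
            a = sum(s.a for s in congeners) / len(congeners)
            b = sum(s.b for s in congeners) / len(congeners)
            return SpeciesAllometry(species, a, b)
    raise KeyError(
        f"species {species!r} not in allometry registry "
        f"(known: {sorted(registry)})"
    )


def tree_agb(
    species: str,
    dbh_cm: float,
    registry: dict[str, SpeciesAllometry] | None = None,
    genus_fallback: bool = False,
) -> float:
    """Aboveground biomass of one tree in kg."""
    reg = registry or ALLOMETRY_REGISTRY
    return _resolve_species(species, reg, genus_fallback).agb_kg(dbh_cm)


def plot_agb(
    inventory: PlotInventory,
    registry: dict[str, SpeciesAllometry] | None = None,
    genus_fallback: bool = False,
) -> float:
    """Plot aboveground biomass density in Mg ha^-1.

    Sum of per-tree kg, over 1000 (kg -> Mg), scaled by 10000/area (m^2 ->
    ha).  An empty inventory yields 0 with a warning.
    """
    if not inventory.trees:
        warnings.warn(f"plot {inventory.plot_id} has no trees; AGB = 0")
        return 0.0
    total_kg = sum(
        tree_agb(t.species, t.dbh_cm, registry, genus_fallback) for t in inventory.trees
    )
    return total_kg / 1000.0 * (10000.0 / inventory.area_m2)


def read_tree_inventory(path, plot_areas: dict | None = None) -> list[PlotInventory]:
    """Read a ``plot_id,species,dbh_cm[,area_m2]`` CSV into inventories."""
    df = pd.read_csv(path)
    inventories = []
    for plot_id, group in df.groupby("plot_id", sort=True):
        if "area_m2" in group.columns:
            area = float(group["area_m2"].iloc[0])
        elif plot_areas and plot_id in plot_areas:
            area = float(plot_areas[plot_id])
        else:
            raise ValueError(f"no plot area available for plot {plot_id}")
        trees = [
            TreeRecord(str(r["species"]), float(r["dbh_cm"])) for _, r in group.iterrows()
        ]
        inventories.append(PlotInventory(plot_id, area, trees))
    return inventories


def load_allometry_registry(path) -> dict[str, SpeciesAllometry]:
    with open(path) as fh:
        payload = json.load(fh)
    return {
        name: SpeciesAllometry(name, float(v["a"]), float(v["b"]))
        for name, v in payload.items()
    }
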