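"""Seeded generators emulating the study's inputs.

Nothing from the original campaign is publicly deposited, so every upstream
input is simulated: a co-registered optical + SAR scene over a latent
aboveground-biomass (AGB) field, field plots with species/DBH inventories
whose allometric AGB tracks the latent field, and tabular datasets generated
from a known ANFIS truth for recovery experiments.

Design of the scene generator:

* the latent AGB is a smoothed Gaussian random field rescaled to the target
  envelope (default 40-340 Mg/ha, the field-observed range);
* C-band backscatter follows a saturating exponential
  ``s_min + (s_max - s_min) * (1 - exp(-AGB / lambda))`` plus noise, with
  ``lambda`` defaulting to 60 Mg/ha so sensitivity is mostly spent by
  50-70 Mg/ha — the canonical C-band saturation domain;
* NIR rises and red falls monotonically with the canopy proxy, so NDVI-type
  indices increase with biomass.

Plot inventories use the five-species allometry registry at the reported
stand structure (about 2,830 stems/ha, mean DBH between roughly 6.9 and
19 cm); the mean DBH at a location is chosen by inverting the mixture
power law so the plot's allometric AGB matches the latent field there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .allometry import ALLOMETRY_REGISTRY, PlotInventory, TreeRecord, plot_agb
from .anfis import AnfisConfig, AnfisParameters, predict_batch
from .features import MultispectralScene, PlotRecord, SarScene
from .raster import Raster

__all__ = [
    "SceneSpec",
    "TruthModel",
    "make_scene",
    "make_plots",
    "make_anfis_dataset",
    "random_anfis_parameters",
]

_SPECIES = list(ALLOMETRY_REGISTRY)
_SPECIES_PROBS = np.array([0.15, 0.15, 0.35, 0.20, 0.15])  # Rhizophora-dominated


@dataclass(frozen=True)
class SceneSpec:
    shape: tuple[int, int] = (64, 64)
    cell_size: float = 6.0  # m, multispectral grid
    correlation_length: float = 8.0  # cells, of the latent field
    agb_range: tuple[float, float] = (40.0, 340.0)  # Mg/ha envelope
    sar_saturation: float = 60.0  # lambda, Mg/ha; onset of C-band saturation
    vv_range_db: tuple[float, float] = (-17.0, -6.0)
    vh_range_db: tuple[float, float] = (-24.0, -13.0)
    sar_noise_db: float = 0.5
    reflectance_noise: float = 0.01
    origin: tuple[float, float] = (500000.0, 1000000.0)
    crs: str = "EPSG:32648"

    def __post_init__(self) -> None:
        if self.sar_saturation <= 0 or self.correlation_length <= 0:
            raise ValueError("scales must be positive")
        if self.agb_range[1] <= self.agb_range[0] or self.agb_range[0] < 0:
            raise ValueError("invalid AGB range")


@dataclass
class TruthModel:
    params: AnfisParameters
    noise_sd: float
    feature_names: list[str] = field(default_factory=list)


def _transform(spec: SceneSpec) -> tuple[float, float, float, float]:
    x0, ytop = spec.origin
    return (x0, ytop, spec.cell_size, -spec.cell_size)


def _random_field(shape, correlation_length, rng) -> np.ndarray:
    """Smoothed white noise rescaled to [0, 1]."""
    raw = gaussian_filter(rng.standard_normal(shape), sigma=correlation_length, mode="wrap")
    lo, hi = raw.min(), raw.max()
    return (raw - lo) / max(hi - lo, 1e-12)


def saturating_backscatter(agb, s_min, s_max, lam):
    """Sigma-nought (dB) as a saturating function of biomass."""
    return s_min + (s_max - s_min) * (1.0 - np.exp(-np.asarray(agb, float) / lam))


def make_scene(
    spec: SceneSpec = SceneSpec(), seed: int | None = 0
) -> tuple[MultispectralScene, SarScene, Raster]:
    """Generate (multispectral scene, SAR scene, latent AGB raster)."""
    rng = np.random.default_rng(seed)
    tf = _transform(spec)
    canopy = _random_field(spec.shape, spec.correlation_length, rng)  # in [0, 1]
    lo, hi = spec.agb_range
    agb = lo + canopy * (hi - lo)

    def band(x):
        return Raster(x, tf, spec.crs)

    vv = saturating_backscatter(agb, *spec.vv_range_db, spec.sar_saturation)
    vh = saturating_backscatter(agb, *spec.vh_range_db, spec.sar_saturation)
    vv = vv + spec.sar_noise_db * rng.standard_normal(spec.shape)
    vh = vh + spec.sar_noise_db * rng.standard_normal(spec.shape)

    noise = lambda: spec.reflectance_noise * rng.standard_normal(spec.shape)
    nir = np.clip(0.20 + 0.30 * canopy + noise(), 0.01, 1.0)
    red = np.clip(0.18 - 0.12 * canopy + noise(), 0.01, 1.0)
    green = np.clip(0.14 - 0.06 * canopy + noise(), 0.01, 1.0)
    blue = np.clip(0.10 - 0.04 * canopy + noise(), 0.01, 1.0)

    ms = MultispectralScene(blue=band(blue), green=band(green), red=band(red), nir=band(nir))
    sar = SarScene(vv=band(vv), vh=band(vh))
    return ms, sar, band(agb)


def _mixture_power_mean() -> tuple[float, float]:
    """Species-probability-weighted allometric coefficients (a-bar, b-bar)."""
    a = sum(p * ALLOMETRY_REGISTRY[s].a for s, p in zip(_SPECIES, _SPECIES_PROBS))
    b = sum(p * ALLOMETRY_REGISTRY[s].b for s, p in zip(_SPECIES, _SPECIES_PROBS))
    return a, b


def make_plots(
    latent_agb: Raster,
    n: int = 158,
    seed: int | None = 0,
    stem_density_ha: float = 2830.0,
    dbh_sd_cm: float = 1.5,
    areas: tuple[float, ...] = (100.0, 1000.0),
) -> tuple[list[PlotRecord], list[PlotInventory]]:
    """Random plots whose allometric AGB tracks the latent field.

    Each plot receives a Poisson stem count at the stand density, a species
    mix over the five-species registry, and DBH values around the mean
    diameter that makes the expected allometric plot AGB equal the latent
    AGB at the plot centre.  The observed AGB attached to each PlotRecord is
    the actual allometric aggregate of the simulated trees, so it carries
    realistic sampling noise around the latent value.
    """
    if n < 1:
        raise ValueError("need at least one plot")
    rng = np.random.default_rng(seed)
    nr, nc = latent_agb.shape
    abar, bbar = _mixture_power_mean()

    plots, inventories = [], []
    for i in range(n):
        row = rng.uniform(2, nr - 2)
        col = rng.uniform(2, nc - 2)
        x, y = latent_agb.rowcol_to_world(row, col)
        area = float(rng.choice(areas))
        target = float(latent_agb.data[int(row), int(col)])

        area_ha = area / 10000.0
        count = max(1, rng.poisson(stem_density_ha * area_ha))
        # invert the mixture power law: per-tree mean mass hitting the target
        mean_kg = target * area_ha * 1000.0 / count
        mean_dbh = (mean_kg / abar) ** (1.0 / bbar)
        lo_env, hi_env = latent_agb.data.min(), latent_agb.data.max()
        # sampling noise can spill outside the observed envelope; the field
        # campaign only reports plots inside it, so condition by redrawing
        for _ in range(25):
            species = rng.choice(_SPECIES, size=count, p=_SPECIES_PROBS)
            dbh = np.clip(rng.normal(mean_dbh, dbh_sd_cm, count), 2.0, 60.0)
            trees = [TreeRecord(str(s), float(d)) for s, d in zip(species, dbh)]
            inv = PlotInventory(plot_id=f"P{i:03d}", area_m2=area, trees=trees)
            agb = plot_agb(inv)
            if lo_env <= agb <= hi_env:
                break
        plots.append(PlotRecord(id=inv.plot_id, x=float(x), y=float(y), area_m2=area, agb=agb))
        inventories.append(inv)
    return plots, inventories


def random_anfis_parameters(
    m: int, k: int, seed: int | None = 0
) -> AnfisParameters:
    """A valid random parameter set over the unit feature cube."""
    rng = np.random.default_rng(seed)
    return AnfisParameters(
        a=rng.uniform(0.15, 0.45, (k, m)),
        b=np.full((k, m), 2.0),
        c=rng.uniform(0.15, 0.85, (k, m)),
        p0=rng.uniform(-1.5, 1.5, k),
        p=rng.uniform(-2.0, 2.0, (k, m)),
    )


def make_anfis_dataset(
    m: int,
    k: int,
    n: int,
    noise: float = 0.05,
    seed: int | None = 0,
):
    """Dataset from a known ANFIS truth: (feature table, truth model).

    Features are uniform on [0, 1]^m; the target is the truth model's
    prediction plus Gaussian noise with standard deviation ``noise`` times
    the clean target's SD (so ``noise`` is the relative noise level).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    params = random_anfis_parameters(m, k, seed=seed)
    X = rng.random((n, m))
    clean = predict_batch(X, params, AnfisConfig(n_features=m, n_rules=k))
    noise_sd = noise * float(np.std(clean))
    ytgt = clean + noise_sd * rng.standard_normal(n)
    names = [f"f{i + 1}" for i in range(m)]
    table = pd.DataFrame(X, columns=names)
    table["agb"] = ytgt
    return table, TruthModel(params=params, noise_sd=noise_sd, feature_names=names)
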