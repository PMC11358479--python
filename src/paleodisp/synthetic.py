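"""Synthetic study inputs.

Generates every input the pipeline consumes — paired stadial/interstadial
bioclim rasters, a site catalogue Bernoulli-sampled from a known truth niche
model, a periodic isotope series on the 20-yr proxy step, and topography
with a land mask — with the statistical structure the real data path
assumes, so the whole pipeline builds and tests without downloads.

Climate noise is a smooth Gaussian random field (seeded white noise run
through a Gaussian spectral filter and rescaled); the stadial regime differs
from the interstadial by configured offsets (colder, more seasonal, drier).
The generator makes no attempt to mimic actual European geography or the
real ice-core waveform, only the structure the method relies on: latitudinal
climate trends, a cold excursion deep enough to cross the a-priori
habitability bound over part of the domain, and suitability spanning the
unit interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .exceptions import ConfigurationError
from .grid import LandMask, LatLonGrid, ScalarField, build_grid
from .layers import IsotopeSeries, normalize_isotope
from .niche import PREDICTOR_NAMES, NicheModel, SiteCatalog, Standardization

__all__ = [
    "SyntheticScenario",
    "synth_bioclim",
    "synth_sites",
    "synth_isotope",
    "synth_topography",
]


def _smooth_noise(shape, sd, smoothing, rng):
    """Seeded smooth random field with pointwise s.d. ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    smooth = gaussian_filter(white, smoothing, mode="nearest")
    s = smooth.std()
    return smooth / s * sd if s > 0 else smooth


@dataclass
class SyntheticScenario:
    """Study conditions for the synthetic pipeline.

    Defaults define a 40 x 30-cell, 0.5-degree domain (0-20E, 34-49N) with a
    southern-edge interstadial annual temperature of 15.5 degC falling at
    0.8 degC per degree of latitude, so the whole domain is habitable under
    interstadial (GI) climate.  The stadial (GS) excursion of -12 degC — a
    Heinrich-like cold extreme — pushes roughly the northern half of the
    domain below the -2 degC a-priori habitability bound.  The truth niche
    model is a concave quadratic on scenario-standardized predictors peaking
    near the domain's mid-south.
    """

    lon_range: tuple[float, float] = (0.0, 20.0)
    lat_range: tuple[float, float] = (34.0, 49.0)
    resolution: float = 0.5
    seed: int = 0

    # interstadial climate trends
    t_south: float = 15.5  # degC at the southern edge
    t_lapse: float = 0.8  # degC per degree latitude
    ts_base: float = 6.0  # temperature seasonality, degC
    ts_gradient: float = 0.1
    rm_base: float = 110.0  # wettest-month precipitation, mm
    rm_zonal_amp: float = 25.0
    rs_base: float = 40.0  # precipitation seasonality, %

    # stadial minus interstadial offsets
    gs_t_offset: float = -12.0
    gs_ts_offset: float = 2.0
    gs_rm_offset: float = -30.0
    gs_rs_offset: float = 5.0

    noise_sd: dict = dfield(
        default_factory=lambda: {"T_m": 0.6, "T_delta": 0.4, "R_m": 8.0, "R_delta": 3.0}
    )
    noise_smoothing: float = 2.0  # cells

    # truth niche model on scenario-standardized predictors
    truth_A: np.ndarray = dfield(
        default_factory=lambda: np.diag([-1.2, -0.5, -0.6, -0.3])
    )
    truth_B: np.ndarray = dfield(default_factory=lambda: np.array([0.1, 0.0, 0.3, 0.0]))
    truth_C: float = 3.0

    site_target: int = 120

    # isotope series
    d18o_low: float = -44.0
    d18o_high: float = -36.0
    period_yr: float = 1000.0
    isotope_shape: str = "square"

    # topography
    base_elevation: float = 250.0  # m
    ridges: tuple = ()  # (lon_center_deg, height_m, width_deg) per ridge
    ocean_margin_cells: int = 0  # masked columns at the east/west edges

    def __post_init__(self) -> None:
        self.truth_A = np.asarray(self.truth_A, dtype=float)
        self.truth_B = np.asarray(self.truth_B, dtype=float)

    def grid(self) -> LatLonGrid:
        return build_grid(self.lon_range, self.lat_range, self.resolution)

    def truth_model(self) -> NicheModel:
        return NicheModel(self.truth_A, self.truth_B, self.truth_C)

    def truth_standardization(self, bioclim: dict) -> Standardization:
        """Standardization over interstadial land-free statistics."""
        gi = bioclim["GI"]
        means, stds = [], []
        for name in PREDICTOR_NAMES:
            vals = gi[name].values.ravel()
            means.append(vals.mean())
            stds.append(vals.std())
        return Standardization(np.array(means), np.array(stds))

    def truth_phi(self, bioclim: dict, regime: str) -> np.ndarray:
        """Truth-model Phi_E on the grid for one climate regime."""
        stats = self.truth_standardization(bioclim)
        raw = np.stack(
            [bioclim[regime][n].values.ravel() for n in PREDICTOR_NAMES], axis=-1
        )
        phi = self.truth_model().predict(stats.transform(raw))
        return phi.reshape(self.grid().shape)

    def validate_span(self, bioclim: dict) -> None:
        """Truth suitability must span (0.05, 0.95) across regimes."""
        phis = [self.truth_phi(bioclim, reg) for reg in ("GS", "GI")]
        lo = min(p.min() for p in phis)
        hi = max(p.max() for p in phis)
        if not (lo < 0.05 and hi > 0.95):
            raise ConfigurationError(
                f"truth suitability span ({lo:.3f}, {hi:.3f}) too narrow"
            )


def synth_bioclim(scenario: SyntheticScenario) -> dict:
    """Paired GS/GI predictor rasters.

    Returns ``{"GS": {name: ScalarField}, "GI": {...}}``; the interstadial is
    warmer than the stadial everywhere by the configured offsets, and the
    noise realisation is shared between regimes (the offsets are uniform).
    """
    grid = scenario.grid()
    rng = np.random.default_rng(scenario.seed)
    lon2, lat2 = grid.mesh()
    dlat = lat2 - scenario.lat_range[0]

    noise = {
        name: _smooth_noise(grid.shape, scenario.noise_sd.get(name, 0.0),
                            scenario.noise_smoothing, rng)
        for name in PREDICTOR_NAMES
    }
    gi = {
        "T_m": scenario.t_south - scenario.t_lapse * dlat + noise["T_m"],
        "T_delta": scenario.ts_base + scenario.ts_gradient * dlat + noise["T_delta"],
        "R_m": scenario.rm_base
        + scenario.rm_zonal_amp * np.sin(2 * np.pi * (lon2 - scenario.lon_range[0])
                                         / (scenario.lon_range[1] - scenario.lon_range[0]))
        + noise["R_m"],
        "R_delta": scenario.rs_base + noise["R_delta"],
    }
    offsets = {
        "T_m": scenario.gs_t_offset,
        "T_delta": scenario.gs_ts_offset,
        "R_m": scenario.gs_rm_offset,
        "R_delta": scenario.gs_rs_offset,
    }
    units = {"T_m": "degC", "T_delta": "degC", "R_m": "mm", "R_delta": "%"}
    out = {"GI": {}, "GS": {}}
    for name in PREDICTOR_NAMES:
        out["GI"][name] = ScalarField(grid, gi[name], units=units[name])
        out["GS"][name] = ScalarField(grid, gi[name] + offsets[name], units=units[name])
    return out


def synth_sites(
    scenario: SyntheticScenario,
    bioclim: dict,
    mask: LandMask,
    n_target: int | None = None,
    seed: int | None = None,
    thin: bool = True,
) -> SiteCatalog:
    """Bernoulli-sample presence cells from the truth suitability.

    Each land cell is marked present with probability Phi_E(truth, GI); one
    synthetic site is placed at each sampled cell center, then the catalogue
    is thinned (or resampled in further rounds) to about ``n_target`` sites.
    With ``thin=False`` a single Bernoulli round is returned untouched, so
    the site count keeps its binomial distribution.
    """
    rng = np.random.default_rng(scenario.seed + 1 if seed is None else seed)
    n_target = scenario.site_target if n_target is None else n_target
    grid = scenario.grid()
    phi = scenario.truth_phi(bioclim, "GI")
    phi = np.where(mask.land, phi, 0.0)
    if phi.max() <= 0:
        import warnings

        warnings.warn("truth suitability is zero everywhere; empty catalogue",
                      stacklevel=2)
    records = []
    if not thin or n_target > 0:
        rounds = 1 if not thin else 50
        for _round in range(rounds):
            draws = rng.random(grid.shape) < phi
            ii, jj = np.nonzero(draws)
            for i, j in zip(ii, jj):
                records.append(
                    {
                        "id": f"S{len(records):04d}",
                        "lon": grid.lon[j],
                        "lat": grid.lat[i],
                        "phase": "P1",
                    }
                )
            if len(records) >= n_target:
                break
        if thin and len(records) > n_target:
            keep = rng.choice(len(records), size=n_target, replace=False)
            records = [records[k] for k in sorted(keep)]
    df = pd.DataFrame(records, columns=["id", "lon", "lat", "phase"])
    df["id"] = [f"S{k:04d}" for k in range(len(df))]
    return SiteCatalog(df)


def synth_isotope(
    start_ka: float,
    end_ka: float,
    period_yr: float = 1000.0,
    shape: str = "square",
    low: float = -44.0,
    high: float = -36.0,
) -> IsotopeSeries:
    """Periodic proxy series on the 20-yr step, oldest first.

    ``square`` alternates half-period epochs between the interstadial (high)
    and stadial (low) end members, starting interstadial, so the normalised
    series is exactly 0/1; ``sine`` attains both extremes smoothly.
    """
    if start_ka <= end_ka:
        raise ConfigurationError("start must be older (larger ka) than end")
    step = 0.02  # ka
    n = int(round((start_ka - end_ka) / step)) + 1
    age = start_ka - step * np.arange(n)
    elapsed = (start_ka - age) * 1000.0
    if shape == "square":
        epoch = np.floor(elapsed / (period_yr / 2.0)).astype(int)
        val = np.where(epoch % 2 == 0, high, low)
    elif shape == "sine":
        val = 0.5 * (high + low) + 0.5 * (high - low) * np.cos(
            2 * np.pi * elapsed / period_yr
        )
    else:
        raise ConfigurationError(f"unknown isotope shape {shape!r}")
    # guarantee both extremes appear exactly (normalisation anchors)
    val = np.asarray(val, dtype=float)
    return normalize_isotope(age, val)


def synth_topography(
    scenario: SyntheticScenario,
) -> tuple[ScalarField, ScalarField, LandMask]:
    """Elevation, sub-grid elevation s.d. rasters and the land mask.

    The base is a low plain; each configured ridge is a meridional Gaussian
    wall ``(lon_center, height_m, width_deg)`` that can block the zonal
    corridor.  Sub-grid roughness scales with the local elevation above the
    plain.  ``ocean_margin_cells`` columns at the east and west edges are
    water.
    """
    grid = scenario.grid()
    lon2, _lat2 = grid.mesh()
    elev = np.full(grid.shape, scenario.base_elevation)
    for lon_c, height, width in scenario.ridges:
        elev = elev + height * np.exp(-0.5 * ((lon2 - lon_c) / width) ** 2)
    sub_sd = 20.0 + 0.15 * (elev - scenario.base_elevation)
    land = np.ones(grid.shape, dtype=bool)
    m = scenario.ocean_margin_cells
    if m > 0:
        land[:, :m] = False
        land[:, -m:] = False
    return (
        ScalarField(grid, elev, units="m"),
        ScalarField(grid, sub_sd, units="m"),
        LandMask(grid, land),
    )
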