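"""Summary diagnostics of dispersal runs.

Total population Lambda, the mobility index M (domain sum of population-flux
magnitudes), flux fields, first-arrival chronologies at a density threshold,
occupation contours and the comparison of simulated arrival times with dated
sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .exceptions import ConfigurationError
from .grid import LandMask, LatLonGrid, ScalarField, VectorField, gradient
from .solver import RunResult

__all__ = [
    "total_population",
    "population_flux",
    "flux_per_decade",
    "mobility_index",
    "ArrivalMap",
    "arrival_time_map",
    "occupation_contour",
    "compare_chronology",
]


def total_population(rho: ScalarField, areas: ScalarField | None = None) -> float:
    """Lambda = sum rho_ij * s_ij, in persons (rho per 100 km**2)."""
    s = rho.grid.cell_areas() if areas is None else areas.values
    return float((rho.values * s).sum() / 100.0)


def population_flux(
    rho: ScalarField, v: VectorField, D: np.ndarray | float
) -> VectorField:
    """Population flux ``f = v rho - D grad(rho)``, in P/km/yr.

    The drift term carries people with the bulk velocity, the diffusion term
    moves them down the density gradient; the 1/100 km**2 density convention
    is folded in so the result is per km of section per year.
    """
    g = gradient(rho)
    D = np.asarray(D, dtype=float)
    f_u = (v.u * rho.values - D * g.u) / 100.0
    f_v = (v.v * rho.values - D * g.v) / 100.0
    f_u = np.where(rho.mask, f_u, 0.0)
    f_v = np.where(rho.mask, f_v, 0.0)
    return VectorField(rho.grid, f_u, f_v, units="P/km/yr", mask=rho.mask.copy())


def flux_per_decade(flux: VectorField) -> VectorField:
    """Convert a per-year flux field to the per-decade reporting convention."""
    return VectorField(flux.grid, 10.0 * flux.u, 10.0 * flux.v,
                       units="P/km/10yr", mask=flux.mask.copy())


def mobility_index(flux: VectorField) -> float:
    """M = sum over unmasked cells of |f|."""
    mag = flux.magnitude()
    return float(mag[flux.mask].sum())


@dataclass
class ArrivalMap:
    """First time (ka BP) each cell reached the arrival threshold.

    ``times_ka`` holds NaN for never-reached cells (water cells always are).
    """

    grid: LatLonGrid
    times_ka: np.ndarray
    threshold: float

    def reached(self) -> np.ndarray:
        return np.isfinite(self.times_ka)


def arrival_time_map(run: RunResult, threshold: float = 0.4) -> ArrivalMap:
    """Earliest snapshot time per cell with ``rho >= threshold``.

    Resolution is the snapshot interval: a crossing between snapshots is
    dated to the first snapshot that sees it.
    """
    if run.n_snapshots < 1:
        raise ConfigurationError("run has no snapshots")
    arrival = np.full(run.grid.shape, np.nan)
    for t_ka, rho in zip(run.times_ka, run.rho):
        hit = np.isnan(arrival) & (rho >= threshold) & run.mask.land
        arrival[hit] = t_ka
    return ArrivalMap(run.grid, arrival, threshold)


def occupation_contour(
    rho: ScalarField, level: float = 1.0
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Cells at or above ``level`` plus marching-squares boundary polylines.

    Returns ``(cell_mask, contours)`` where each contour is an ``(m, 2)``
    array of (lon, lat) vertices.
    """
    inside = (rho.values >= level) & rho.mask
    values = np.where(rho.mask, rho.values, -np.inf)
    contours = []
    for c in measure.find_contours(values, level):
        lon = np.interp(c[:, 1], np.arange(rho.grid.nlon), rho.grid.lon)
        lat = np.interp(c[:, 0], np.arange(rho.grid.nlat), rho.grid.lat)
        contours.append(np.column_stack([lon, lat]))
    return inside, contours


def compare_chronology(
    arrival_maps: list[ArrivalMap],
    sites: pd.DataFrame,
) -> pd.DataFrame:
    """Per-site ensemble mean and s.d. of simulated first-arrival times.

    ``sites`` needs columns ``site``, ``lon``, ``lat`` and optionally
    ``dated_ka``.  Sites are binned to their containing cell; the statistics
    use the members whose run reached the cell (population s.d. convention);
    a site no member reached is reported with NaN and ``n_reached = 0``.
    """
    if not arrival_maps:
        raise ConfigurationError("need at least one ensemble member")
    grid = arrival_maps[0].grid
    rows = []
    for _, rec in sites.iterrows():
        i, j = grid.locate(rec["lon"], rec["lat"])  # raises if outside domain
        values = np.array([m.times_ka[i, j] for m in arrival_maps])
        ok = np.isfinite(values)
        rows.append(
            {
                "site": rec["site"],
                "lon": rec["lon"],
                "lat": rec["lat"],
                "dated_ka": rec.get("dated_ka", np.nan),
                "model_mean_ka": float(values[ok].mean()) if ok.any() else np.nan,
                "model_sd_ka": float(values[ok].std()) if ok.any() else np.nan,
                "n_reached": int(ok.sum()),
            }
        )
    return pd.DataFrame(rows)
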