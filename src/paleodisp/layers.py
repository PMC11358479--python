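"""HEP layer transforms and isotope-driven time interpolation.

The environment suitability Phi_E (a probability from the niche model) is
turned into three derived layers:

* accessible HEP ``Phi_Ac = Phi_E * g_ele * g_std * g_wat * ... * g_x`` —
  pointwise products with unit-interval accessibility modifiers for terrain
  elevation, sub-grid terrain roughness, water bodies and any extra named
  modifiers;
* carrying capacity ``rho_c = rho_c_max * Phi_Ac`` (persons per 100 km**2);
* available HEP ``Phi_Av``: population pressure enters through a Weibull
  density in ``x = rho / rho_c``, normalised by its maximum, so that
  ``Phi_Av`` rises from 0 (mutual support at low density), peaks at
  ``x = eps * ((eta - 1) / eta)**(1 / eta)`` and decays again as resources
  per person become scarce.  With scale ``eps = 0.4`` and shape
  ``eta = 1.6`` the maximum sits at ``rho ~= 0.2 rho_c``.

Time dependence comes from a normalised oxygen-isotope series: stadial (GS)
and interstadial (GI) end-member fields are blended linearly with the
normalised delta-18O value at the simulation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .exceptions import ConfigurationError, GridMismatchError, NormalizationError
from .grid import LandMask, LatLonGrid, ScalarField

__all__ = [
    "ModifierConfig",
    "HepStack",
    "IsotopeSeries",
    "ramp_down",
    "climate_exclusion_modifier",
    "accessible_hep",
    "carrying_capacity",
    "weibull_mode",
    "available_hep",
    "normalize_isotope",
    "hep_at_time",
]


def ramp_down(values: np.ndarray, start: float, end: float) -> np.ndarray:
    """1 below ``start``, linear to 0 at ``end``, 0 above. Requires start < end."""
    if not start < end:
        raise ConfigurationError("ramp start must be below ramp end")
    return np.clip((end - np.asarray(values, dtype=float)) / (end - start), 0.0, 1.0)


@dataclass
class ModifierConfig:
    """Accessibility modifier shapes.

    Elevation and sub-grid roughness ramps are in metres; both default to
    rudimentary piecewise-linear forms (full access below the ramp start,
    none above the ramp end).  ``extras`` holds additional named unit-interval
    modifier fields applied verbatim.
    """

    ele_ramp: tuple[float, float] = (1500.0, 2500.0)
    std_ramp: tuple[float, float] = (300.0, 600.0)
    extras: dict[str, np.ndarray] = dfield(default_factory=dict)

    def g_ele(self, elevation_m: np.ndarray) -> np.ndarray:
        return ramp_down(elevation_m, *self.ele_ramp)

    def g_std(self, elevation_sd_m: np.ndarray) -> np.ndarray:
        return ramp_down(elevation_sd_m, *self.std_ramp)


def climate_exclusion_modifier(
    t_m: ScalarField, r_m: np.ndarray | ScalarField,
    t_bounds: tuple[float, float] = (-2.0, 16.0),
    r_bounds: tuple[float, float] = (30.0, 250.0),
) -> np.ndarray:
    """Indicator modifier zeroing climatically uninhabitable cells.

    Applies the same a-priori habitability bounds used when labelling
    absences (annual mean temperature within ``t_bounds`` degC, wettest-month
    precipitation within ``r_bounds`` mm) to prediction-time climate, so that
    accessibility — and with it the carrying capacity — vanishes where the
    climate is outside the plausible envelope for the culture.
    """
    tv = t_m.values if isinstance(t_m, ScalarField) else np.asarray(t_m, float)
    rv = r_m.values if isinstance(r_m, ScalarField) else np.asarray(r_m, float)
    ok = (tv >= t_bounds[0]) & (tv <= t_bounds[1])
    ok &= (rv >= r_bounds[0]) & (rv <= r_bounds[1])
    return ok.astype(float)


def accessible_hep(
    phi_e: ScalarField,
    modifiers: ModifierConfig,
    elevation: ScalarField | None,
    elevation_sd: ScalarField | None,
    mask: LandMask,
) -> ScalarField:
    """Accessible HEP: pointwise product of Phi_E with every modifier."""
    g = phi_e.grid
    out = phi_e.values.copy()
    if elevation is not None:
        out = out * modifiers.g_ele(elevation.values)
    if elevation_sd is not None:
        out = out * modifiers.g_std(elevation_sd.values)
    out = out * mask.land.astype(float)  # g_wat
    for name, extra in modifiers.extras.items():
        extra = np.asarray(extra, dtype=float)
        if extra.shape != g.shape:
            raise GridMismatchError(f"extra modifier {name!r} shape mismatch")
        if np.nanmin(extra) < 0.0 or np.nanmax(extra) > 1.0:
            raise ConfigurationError(f"modifier {name!r} must map into [0, 1]")
        out = out * extra
    return ScalarField(g, out, units="1", mask=phi_e.mask & mask.land)


def carrying_capacity(phi_ac: ScalarField | np.ndarray, rho_c_max: float):
    """Local carrying capacity ``rho_c = rho_c_max * Phi_Ac`` (P/100 km**2)."""
    if rho_c_max <= 0:
        raise ConfigurationError("rho_c_max must be positive")
    if isinstance(phi_ac, ScalarField):
        return ScalarField(
            phi_ac.grid, rho_c_max * phi_ac.values, units="P/100km2",
            mask=phi_ac.mask.copy(),
        )
    return rho_c_max * np.asarray(phi_ac, dtype=float)


def weibull_mode(eps: float, eta: float) -> float:
    """Mode of the Weibull density with scale ``eps`` and shape ``eta > 1``."""
    if eta <= 1.0:
        raise ConfigurationError("shape parameter eta must exceed 1")
    return eps * ((eta - 1.0) / eta) ** (1.0 / eta)


def _weibull_density(x: np.ndarray, eps: float, eta: float) -> np.ndarray:
    z = np.asarray(x, dtype=float) / eps
    with np.errstate(over="ignore"):
        return (eta / eps) * z ** (eta - 1.0) * np.exp(-(z**eta))


def available_hep(
    rho: np.ndarray | ScalarField,
    rho_c: np.ndarray | ScalarField,
    eps: float,
    eta: float,
):
    """Available HEP ``Phi_Av = rho_c * w(rho / rho_c) / w_max``.

    ``w`` is the Weibull density with scale ``eps`` and shape ``eta``;
    ``w_max`` is its closed-form maximum over ``x >= 0`` (at the mode), so
    ``Phi_Av`` lies in ``[0, rho_c]``.  Cells with ``rho_c = 0`` get 0.
    """
    if eps <= 0 or eta <= 0:
        raise ConfigurationError("eps and eta must be positive")
    as_field = isinstance(rho, ScalarField)
    rv = rho.values if as_field else np.asarray(rho, dtype=float)
    cv = rho_c.values if isinstance(rho_c, ScalarField) else np.asarray(rho_c, float)
    if np.nanmin(rv) < 0:
        raise ValueError("population density must be non-negative")
    w_max = _weibull_density(weibull_mode(eps, eta), eps, eta)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(cv > 0, rv / np.where(cv > 0, cv, 1.0), np.inf)
    w = np.where(np.isfinite(x), _weibull_density(np.where(np.isfinite(x), x, 0.0), eps, eta), 0.0)
    out = np.where(cv > 0, cv * w / w_max, 0.0)
    if as_field:
        return ScalarField(rho.grid, out, units="P/100km2", mask=rho.mask.copy())
    return out


@dataclass(frozen=True)
class IsotopeSeries:
    """A delta-18O proxy series on a fixed 20-yr step, normalised to [0, 1].

    Ages are in ka BP, descending in simulation order (oldest first).
    ``d18o_n`` is 0 at the series minimum and 1 at the maximum within the
    study window.
    """

    age_ka: np.ndarray
    d18o: np.ndarray
    d18o_n: np.ndarray
    d18o_min: float
    d18o_max: float

    @property
    def step_ka(self) -> float:
        return float(abs(self.age_ka[0] - self.age_ka[1]))

    def index_at(self, t_ka: float) -> int:
        """Nearest-step index for a time inside the series coverage."""
        lo, hi = float(self.age_ka.min()), float(self.age_ka.max())
        tol = 0.5 * self.step_ka + 1e-9
        if not (lo - tol <= t_ka <= hi + tol):
            raise ValueError(f"time {t_ka} ka outside isotope series coverage {lo}..{hi}")
        return int(np.argmin(np.abs(self.age_ka - t_ka)))

    def value_at(self, t_ka: float) -> float:
        return float(self.d18o_n[self.index_at(t_ka)])


def normalize_isotope(age_ka: np.ndarray, d18o: np.ndarray) -> IsotopeSeries:
    """Affinely map a raw delta-18O series onto [0, 1] over its study window."""
    age = np.asarray(age_ka, dtype=float)
    val = np.asarray(d18o, dtype=float)
    if age.ndim != 1 or age.shape != val.shape or age.size < 2:
        raise ValueError("age and d18O must be 1-D arrays of equal length >= 2")
    if np.any(np.diff(age) >= 0):
        raise ValueError("ages must be strictly descending (oldest first)")
    vmin, vmax = float(val.min()), float(val.max())
    if vmax <= vmin:
        raise NormalizationError("isotope series is constant; cannot normalise")
    norm = (val - vmin) / (vmax - vmin)
    return IsotopeSeries(age, val, norm, vmin, vmax)


@dataclass
class HepStack:
    """Accessible-HEP end members per (phase, climate regime).

    ``fields`` maps ``(phase, regime)`` with phase in {"P1", "P2"} and regime
    in {"GS", "GI"} to arrays on one grid.  The phase switch is a hard
    boundary in time (default 38 ka): earlier times use P1, later P2.
    """

    grid: LatLonGrid
    fields: dict[tuple[str, str], np.ndarray]
    phase_boundary_ka: float = 38.0

    def __post_init__(self) -> None:
        for key in (("P1", "GS"), ("P1", "GI"), ("P2", "GS"), ("P2", "GI")):
            if key not in self.fields:
                raise ConfigurationError(f"HepStack missing field {key}")
        for key, arr in self.fields.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise GridMismatchError(f"HepStack field {key} shape mismatch")
            if np.nanmin(arr) < 0.0 or np.nanmax(arr) > 1.0:
                raise ConfigurationError(f"HepStack field {key} outside [0, 1]")
            self.fields[key] = arr

    def phase_at(self, t_ka: float) -> str:
        return "P1" if t_ka > self.phase_boundary_ka else "P2"


def hep_at_time(stack: HepStack, series: IsotopeSeries, t_ka: float) -> ScalarField:
    """Accessible HEP at time ``t_ka``: linear GS/GI blend by normalised d18O.

    ``Phi(t) = (1 - d18O_n(t)) * Phi_GS + d18O_n(t) * Phi_GI`` with the
    phase-appropriate end members and nearest-20-yr-step isotope value.
    """
    wgi = series.value_at(t_ka)
    phase = stack.phase_at(t_ka)
    blend = (1.0 - wgi) * stack.fields[(phase, "GS")] + wgi * stack.fields[(phase, "GI")]
    return ScalarField(stack.grid, blend, units="1")
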