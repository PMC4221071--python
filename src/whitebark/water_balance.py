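"""Monthly Thornthwaite-based dynamic water balance.

Given monthly mean/dewpoint temperature, precipitation, latitude, and a
soil available-water-capacity (AWC) raster, the model tracks two stores
per cell — snowpack (SWE) and a soil-moisture bucket — and emits monthly
potential evapotranspiration (PET), actual evapotranspiration (AET),
soil moisture, SWE, and vapor pressure deficit (VPD).

Structure of a monthly step, per cell:

1. precipitation is partitioned into rain and snow by a linear ramp in
   monthly mean temperature;
2. snowfall joins the pack, then a degree-month melt draws it down;
3. rain + melt (liquid input) meets PET demand in a Thornthwaite–Mather
   bucket: when input exceeds demand the soil recharges toward AWC and
   the overflow leaves as surplus (runoff/seepage); in a deficit month
   the soil dries along the exponential retention curve
   ``soil * exp(-deficit / awc)``.

Mass closure holds to machine precision every cell-month:
``ppt = d(swe) + d(soil) + aet + surplus``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import WaterBalanceParams
from .containers import DAYS_IN_MONTH, ClimateCube

logger = logging.getLogger(__name__)

__all__ = [
    "WaterBalanceOutput",
    "thornthwaite_pet",
    "day_length_correction",
    "partition_precip",
    "melt_snow",
    "soil_step",
    "vapor_pressure_deficit",
    "run_water_balance",
]

#: mid-month day of year, used for the solar-declination day length
_MID_MONTH_DOY = np.array([16, 45, 75, 105, 136, 166, 197, 228, 258, 289, 319, 350])


def day_length_correction(latitude_deg: float) -> np.ndarray:
    """Thornthwaite day-length/month-length correction factors, one per
    calendar month: (mean day length / 12 h) x (days in month / 30)."""
    if abs(latitude_deg) >= 66.5:
        raise ValueError("latitude must be equatorward of the polar circles")
    lat = np.deg2rad(latitude_deg)
    decl = np.deg2rad(-23.44) * np.cos(2 * np.pi * (_MID_MONTH_DOY + 10) / 365.0)
    cos_h = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    day_hours = 24.0 / np.pi * np.arccos(cos_h)
    return (day_hours / 12.0) * (DAYS_IN_MONTH / 30.0)


def thornthwaite_pet(
    tmean_monthly: np.ndarray,
    latitude_deg: float | None = None,
    correction: np.ndarray | None = None,
) -> np.ndarray:
    """Monthly potential evapotranspiration (mm), Thornthwaite 1948 form.

    Parameters
    ----------
    tmean_monthly
        Array of monthly mean temperatures with the month axis first,
        shape ``(12, ...)`` (trailing axes are spatial).
    latitude_deg
        Latitude for the day-length correction.  Ignored when an explicit
        ``correction`` vector is given; one of the two must be supplied.
    correction
        Optional per-month correction factors (e.g. all ones to obtain
        the unadjusted 30-day/12-hour PET).

    Notes
    -----
    Annual heat index ``I = sum over months with T > 0 of (T/5)^1.514``;
    exponent ``a = 6.75e-7 I^3 - 7.71e-5 I^2 + 1.792e-2 I + 0.49239``;
    unadjusted PET ``= 16 (10 T / I)^a`` mm per standard month, zero for
    ``T <= 0``.  Cells whose months are all freezing get all-zero PET.
    """
    t = np.asarray(tmean_monthly, dtype=float)
    if t.shape[0] != 12:
        raise ValueError("tmean_monthly must have 12 months on axis 0")
    if correction is None:
        if latitude_deg is None:
            raise ValueError("supply latitude_deg or an explicit correction")
        correction = day_length_correction(latitude_deg)
    correction = np.asarray(correction, dtype=float).reshape(
        (12,) + (1,) * (t.ndim - 1)
    )

    warm = t > 0.0
    heat = np.where(warm, (np.maximum(t, 0.0) / 5.0) ** 1.514, 0.0).sum(axis=0)
    a = 6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239
    with np.errstate(divide="ignore", invalid="ignore"):
        pet = 16.0 * (10.0 * np.maximum(t, 0.0) / heat) ** a
    pet = np.where(warm & (heat > 0.0), pet, 0.0)
    return pet * correction


def partition_precip(ppt_mm, tmean_c, t_snow_c: float = -2.0, t_rain_c: float = 4.0):
    """Split monthly precipitation into (rain, snow) by a linear ramp.

    All snow at or below ``t_snow_c``, all rain at or above ``t_rain_c``,
    linear in between; rain + snow equals the input exactly.
    """
    if t_snow_c >= t_rain_c:
        raise ValueError("t_snow_c must be below t_rain_c")
    ppt = np.asarray(ppt_mm, dtype=float)
    if np.any(ppt < 0):
        raise ValueError("precipitation must be non-negative")
    frac_snow = np.clip((t_rain_c - np.asarray(tmean_c, float)) / (t_rain_c - t_snow_c), 0.0, 1.0)
    snow = ppt * frac_snow
    return ppt - snow, snow


def melt_snow(swe_mm, tmean_c, melt_coeff_mm_per_c: float = 40.0):
    """Degree-month snowmelt: ``melt = min(swe, coeff * max(T, 0))``.

    Returns ``(melt, new_swe)``; melt joins the month's liquid input.
    """
    if melt_coeff_mm_per_c <= 0:
        raise ValueError("melt_coeff must be positive")
    swe = np.asarray(swe_mm, dtype=float)
    potential = melt_coeff_mm_per_c * np.maximum(np.asarray(tmean_c, float), 0.0)
    melt = np.minimum(swe, potential)
    return melt, swe - melt


def soil_step(soil_mm, liquid_in_mm, pet_mm, awc_mm):
    """One Thornthwaite–Mather soil-bucket update.

    Wet month (input >= PET): AET = PET, the excess recharges the soil to
    at most AWC, and the remainder is surplus.  Dry month: the soil dries
    along ``soil * exp(-(PET - input)/awc)`` and AET is the input plus
    the water given up by the soil; surplus is zero.

    Returns ``(aet, surplus, new_soil)``.
    """
    soil = np.asarray(soil_mm, dtype=float)
    liq = np.asarray(liquid_in_mm, dtype=float)
    pet = np.asarray(pet_mm, dtype=float)
    awc = np.asarray(awc_mm, dtype=float)
    if np.any(awc <= 0):
        raise ValueError("awc must be positive")

    wet = liq >= pet
    # wet branch
    recharge = np.minimum(awc - soil, liq - pet)
    soil_wet = soil + recharge
    surplus_wet = liq - pet - recharge
    # dry branch: exponential retention curve
    deficit = pet - liq
    soil_dry = soil * np.exp(-np.maximum(deficit, 0.0) / awc)
    aet_dry = liq + (soil - soil_dry)

    aet = np.where(wet, pet, aet_dry)
    surplus = np.where(wet, surplus_wet, 0.0)
    new_soil = np.where(wet, soil_wet, soil_dry)
    return aet, surplus, new_soil


def vapor_pressure_deficit(tmean_c, tdew_c):
    """VPD in kPa from the Tetens saturation curve.

    ``vpd = e_s(tmean) - e_s(tdew)`` with
    ``e_s(T) = 0.6108 exp(17.27 T / (T + 237.3))``; dewpoints above the
    air temperature are clipped, so the result is never negative.
    """
    t = np.asarray(tmean_c, dtype=float)
    td = np.minimum(np.asarray(tdew_c, dtype=float), t)
    return _tetens(t) - _tetens(td)


def _tetens(t_c):
    return 0.6108 * np.exp(17.27 * t_c / (t_c + 237.3))


@dataclass
class WaterBalanceOutput:
    """Monthly water-balance rasters, shape ``(n_years, 12, rows, cols)``.

    ``pack_mm`` is end-of-month SWE (so the April layer is the spring
    snowpack normal's input).  ``closure_max_mm`` is the largest absolute
    mass-balance residual over all cell-months.
    """

    years: np.ndarray
    pet_mm: np.ndarray
    aet_mm: np.ndarray
    soil_mm: np.ndarray
    pack_mm: np.ndarray
    vpd_kpa: np.ndarray
    surplus_mm: np.ndarray
    closure_max_mm: float


def run_water_balance(
    cube: ClimateCube,
    awc: np.ndarray,
    latitude_deg: float = 44.5,
    params: WaterBalanceParams | None = None,
) -> WaterBalanceOutput:
    """Run the sequential monthly water balance over a climate cube.

    The state is initialized with full soil (AWC) and no snow, then the
    first year is run ``params.spinup_years`` extra times and those
    passes discarded, so the reported series starts from a spun-up state.
    NaNs in the inputs propagate to the outputs and are counted in a log
    message rather than raised.
    """
    params = params or WaterBalanceParams()
    if params.spinup_years < 1:
        raise ValueError("at least one spin-up year is required")
    awc = np.asarray(awc, dtype=float)
    if awc.shape != cube.geometry.shape:
        raise ValueError("awc raster does not match cube geometry")

    n_nan = sum(int(np.isnan(a).sum()) for a in cube.data.values())
    if n_nan:
        logger.warning("water balance inputs contain %d NaN values; propagating", n_nan)

    correction = day_length_correction(latitude_deg)
    n_years = cube.n_years
    shape = cube.data["tmean"].shape
    out = {k: np.empty(shape) for k in ("pet", "aet", "soil", "pack", "vpd", "surplus")}

    soil = awc.copy()
    swe = np.zeros_like(awc)
    closure_max = 0.0

    year_seq = [0] * params.spinup_years + list(range(n_years))
    n_spin = params.spinup_years
    for step, yi in enumerate(year_seq):
        tmean_y = cube.data["tmean"][yi]
        pet_y = thornthwaite_pet(tmean_y, correction=correction)
        record = step >= n_spin
        for m in range(12):
            tm = tmean_y[m]
            ppt = cube.data["ppt"][yi, m]
            rain, snow = partition_precip(ppt, tm, params.t_snow_c, params.t_rain_c)
            melt, swe_new = melt_snow(swe + snow, tm, params.melt_coeff_mm_per_c)
            aet, surplus, soil_new = soil_step(soil, rain + melt, pet_y[m], awc)
            if record:
                residual = ppt - ((swe_new - swe) + (soil_new - soil) + aet + surplus)
                finite = residual[np.isfinite(residual)]
                if finite.size:
                    closure_max = max(closure_max, float(np.abs(finite).max()))
                out["pet"][yi, m] = pet_y[m]
                out["aet"][yi, m] = aet
                out["soil"][yi, m] = soil_new
                out["pack"][yi, m] = swe_new
                out["surplus"][yi, m] = surplus
                out["vpd"][yi, m] = vapor_pressure_deficit(tm, cube.data["tdew"][yi, m])
            swe, soil = swe_new, soil_new

    return WaterBalanceOutput(
        years=cube.years.copy(),
        pet_mm=out["pet"],
        aet_mm=out["aet"],
        soil_mm=out["soil"],
        pack_mm=out["pack"],
        vpd_kpa=out["vpd"],
        surplus_mm=out["surplus"],
        closure_max_mm=closure_max,
    )
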