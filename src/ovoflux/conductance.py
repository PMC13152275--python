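"""Eggshell water-vapor conductance from egg-mass time series.

An egg held in a desiccator at ~0% relative humidity loses water at a
rate proportional to the vapor-pressure difference ΔP across the shell.
Conductance is

    G_H2O = M_H2O / ΔP_H2O      [mg·day⁻¹·torr⁻¹]

where M_H2O is the daily water-loss rate (the magnitude of the slope of
an ordinary least-squares regression of egg mass on day, in mg/day) and
ΔP_H2O equals the saturation vapor pressure of water at the egg's
temperature (23.77 torr at 25 °C).  Eggs are retained only when the
regression is clean (R² > 0.8), mass is actually decreasing, and no
single-day drop suggests a shell fracture.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "EggMassSeries",
    "ConductanceRecord",
    "EggMorphometry",
    "ElevationBands",
    "DEFAULT_BANDS",
    "STANDARD_DELTAP_TORR",
    "saturation_vapor_pressure",
    "mass_loss_rate",
    "water_vapor_conductance",
    "qc_egg",
    "species_conductance",
    "egg_volume",
    "allometric_residuals",
    "elevation_category",
    "conductance_table",
]

#: ΔP convention used for cross-study comparability: saturation vapor
#: pressure at 25 °C, in torr.
STANDARD_DELTAP_TORR = 23.77

TORR_PER_HPA = 1.0 / 1.333224


@dataclass
class EggMassSeries:
    """Daily masses for one egg in a desiccator."""

    egg_id: str
    species: str
    station: str
    elevation_m: float
    temp_c: float
    days: np.ndarray     # day index, strictly increasing
    masses_g: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.masses_g = np.asarray(self.masses_g, dtype=float)
        if len(self.days) != len(self.masses_g):
            raise ValueError("days and masses must have equal length")
        if len(self.days) < 4:
            raise ValueError("need >= 4 time points")
        if not np.all(np.diff(self.days) > 0):
            raise ValueError("days must be strictly increasing")
        if not np.all(self.masses_g > 0):
            raise ValueError("masses must be positive")


@dataclass
class ConductanceRecord:
    egg_id: str
    species: str
    station: str
    elevation_m: float
    slope_mg_day: float   # signed raw slope
    m_h2o: float          # positive loss rate, mg/day
    deltap_torr: float
    g_h2o: float          # mg/day/torr
    r_squared: float
    qc_pass: bool
    qc_reasons: list[str] = field(default_factory=list)


@dataclass
class EggMorphometry:
    species: str
    length_cm: float
    width_cm: float
    mass_g: float

    @property
    def volume_cm3(self) -> float:
        return egg_volume(self.length_cm, self.width_cm)


def saturation_vapor_pressure(temp_c: float) -> float:
    """Saturation vapor pressure of water in torr (Buck equation).

    Valid for −10 ≤ T ≤ 60 °C; strictly increasing in T.  At 25 °C the
    value is 23.77 torr to within 0.05.
    """
    t = float(temp_c)
    if not -10.0 <= t <= 60.0:
        raise ValueError(f"temperature {t} °C outside supported range [-10, 60]")
    hpa = 6.1121 * math.exp((18.678 - t / 234.5) * (t / (257.14 + t)))
    return hpa * TORR_PER_HPA


def mass_loss_rate(series: EggMassSeries) -> tuple[float, float, float]:
    """OLS regression of egg mass (mg) on day.

    Returns ``(slope_mg_per_day, intercept_mg, r_squared)``.  The slope
    keeps its sign; a mass-losing egg has a negative slope.
    """
    d = series.days
    m_mg = series.masses_g * 1000.0
    if np.ptp(d) == 0:
        raise ValueError("zero variance in day values")
    if np.ptp(m_mg) == 0:
        return 0.0, float(m_mg[0]), 0.0
    res = stats.linregress(d, m_mg)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def water_vapor_conductance(
    slope_mg_day: float,
    temp_c: Optional[float] = None,
    deltap_torr: Optional[float] = None,
) -> float:
    """G_H2O = |slope| / ΔP for a mass-losing egg.

    ΔP comes from :func:`saturation_vapor_pressure` at ``temp_c`` unless
    an explicit ``deltap_torr`` override (e.g. the 23.77-torr standard)
    is given.
    """
    if not math.isfinite(slope_mg_day):
        raise ValueError("slope must be finite")
    if slope_mg_day >= 0:
        raise ValueError("egg not losing mass (slope >= 0); conductance undefined")
    if deltap_torr is None:
        if temp_c is None:
            raise ValueError("provide temp_c or deltap_torr")
        deltap_torr = saturation_vapor_pressure(temp_c)
    if deltap_torr <= 0:
        raise ValueError("deltaP must be positive")
    return abs(slope_mg_day) / deltap_torr


R2_THRESHOLD = 0.8
FRACTURE_DROP_FACTOR = 5.0


def qc_egg(
    slope_mg_day: float,
    r_squared: float,
    series: Optional[EggMassSeries] = None,
    r2_threshold: float = R2_THRESHOLD,
    fracture_factor: float = FRACTURE_DROP_FACTOR,
) -> tuple[bool, list[str]]:
    """Quality control for one egg's regression.

    Fails on R² ≤ threshold (``low_r2``), non-negative slope
    (``nonneg_slope``), or any single-day mass drop exceeding
    ``fracture_factor`` times the typical (median) daily loss
    (``fracture_suspect`` — a proxy for shell fracture).  The median
    drop, not the fitted slope, is the reference because a fracture's
    step inflates the fitted slope and would mask itself.
    """
    reasons: list[str] = []
    if r_squared <= r2_threshold:
        reasons.append("low_r2")
    if slope_mg_day >= 0:
        reasons.append("nonneg_slope")
    if series is not None:
        drops = -np.diff(series.masses_g * 1000.0) / np.diff(series.days)
        med = float(np.median(drops))
        if med > 0 and np.max(drops) > fracture_factor * med:
            reasons.append("fracture_suspect")
    return len(reasons) == 0, reasons


def conductance_record(
    series: EggMassSeries,
    deltap_torr: Optional[float] = None,
) -> ConductanceRecord:
    """Full per-egg pathway: regression, QC, and conductance."""
    slope, _, r2 = mass_loss_rate(series)
    ok, reasons = qc_egg(slope, r2, series)
    dp = deltap_torr if deltap_torr is not None else saturation_vapor_pressure(series.temp_c)
    g = abs(slope) / dp if slope < 0 else float("nan")
    return ConductanceRecord(
        egg_id=series.egg_id, species=series.species, station=series.station,
        elevation_m=series.elevation_m, slope_mg_day=slope, m_h2o=abs(slope),
        deltap_torr=dp, g_h2o=g, r_squared=r2, qc_pass=ok, qc_reasons=reasons,
    )


MAX_EGGS_PER_SPECIES = 3


def species_conductance(
    records: Sequence[ConductanceRecord],
    max_eggs: int = MAX_EGGS_PER_SPECIES,
) -> tuple[float, int]:
    """Mean conductance over QC-passing eggs of one species.

    At most ``max_eggs`` eggs contribute, taken in stable input order.
    Returns ``(mean_g, n_used)``; raises if no egg passes QC.
    """
    passing = [r for r in records if r.qc_pass]
    if not passing:
        raise ValueError("no QC-passing records for species")
    used = passing[:max_eggs]
    return float(np.mean([r.g_h2o for r in used])), len(used)


def conductance_table(
    all_records: Sequence[ConductanceRecord],
    max_eggs: int = MAX_EGGS_PER_SPECIES,
) -> pd.DataFrame:
    """Species-level conductance table from per-egg records.

    Species with zero QC-passing eggs are dropped with a log entry.
    """
    rows = []
    by_species: dict[str, list[ConductanceRecord]] = {}
    for r in all_records:
        by_species.setdefault(r.species, []).append(r)
    for sp, recs in by_species.items():
        try:
            g, n_used = species_conductance(recs, max_eggs=max_eggs)
        except ValueError:
            logger.info("species %s dropped: no QC-passing eggs", sp)
            continue
        rows.append({
            "species": sp,
            "station": recs[0].station,
            "elevation_m": recs[0].elevation_m,
            "g_h2o": g,
            "n_eggs": n_used,
        })
    return pd.DataFrame(rows)


def egg_volume(length_cm: float, width_cm: float) -> float:
    """Hoyt's empirical egg volume V = 0.51·L·W² (cm³)."""
    if width_cm <= 0 or length_cm < width_cm:
        raise ValueError("require L >= W > 0")
    return 0.51 * length_cm * width_cm ** 2


@dataclass
class AllometricFit:
    residuals: pd.Series
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    significant: bool  # if False, downstream analyses should use absolute values


def allometric_residuals(
    y: Mapping[str, float],
    x: Mapping[str, float],
    alpha: float = 0.05,
) -> AllometricFit:
    """OLS of (log) trait y on (log) size x; residuals keyed by species.

    When the slope is not significant at ``alpha`` the fit is flagged so
    callers can fall back to absolute trait values instead of residuals.
    """
    labels = [k for k in y if k in x]
    if len(labels) < 3:
        raise ValueError("need >= 3 species")
    xv = np.array([float(x[k]) for k in labels])
    yv = np.array([float(y[k]) for k in labels])
    if np.ptp(xv) == 0:
        raise ValueError("zero variance in predictor")
    res = stats.linregress(xv, yv)
    resid = yv - (res.intercept + res.slope * xv)
    return AllometricFit(
        residuals=pd.Series(resid, index=labels),
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2), p_value=float(res.pvalue),
        significant=bool(res.pvalue < alpha),
    )


# ---------------------------------------------------------------------------
# Elevation bands
# ---------------------------------------------------------------------------

#: Study-design elevation bands in metres (lower, upper).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "lowland": (340.0, 850.0),
    "mid": (1200.0, 2000.0),
    "highland": (2500.0, 3000.0),
}


@dataclass
class ElevationBands:
    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BANDS))

    def __post_init__(self) -> None:
        items = sorted(self.bands.items(), key=lambda kv: kv[1][0])
        for (_, (lo1, hi1)), (_, (lo2, _)) in zip(items, items[1:]):
            if lo2 < hi1:
                raise ValueError("elevation bands must not overlap")
        for name, (lo, hi) in items:
            if lo > hi:
                raise ValueError(f"band {name} has lower > upper")


def elevation_category(
    elevation_m: float,
    bands: Optional[ElevationBands] = None,
) -> str:
    """Assign an elevation to a band; gap values go to the nearest band
    boundary with a logged warning (the bands are approximate ranges with
    gaps between them)."""
    if elevation_m < 0:
        raise ValueError("elevation must be >= 0")
    b = (bands or ElevationBands()).bands
    for name, (lo, hi) in b.items():
        if lo <= elevation_m <= hi:
            return name
    dist = {name: min(abs(elevation_m - lo), abs(elevation_m - hi))
            for name, (lo, hi) in b.items()}
    nearest = min(dist, key=dist.get)
    logger.warning("elevation %.0f m falls between bands; assigned to nearest (%s)",
                   elevation_m, nearest)
    return nearest
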