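"""Per-population rates of temperature and land-cover change.

Temperature warming is the OLS slope of arithmetic annual-mean temperature
on year over a population's monitoring window (strong inter-annual
fluctuations make a regression necessary). Land-cover change, in contrast,
tends to be simply directional, so each class's rate is the arithmetic mean
of successive annual differences of its cover fraction — equal to
(last - first) / (years - 1) by telescoping.

Cover fractions come from categorical land-cover maps: each pixel code is
crosswalked to fractional contributions over 14 simplified classes, the
tree and shrub classes are grouped into single forest and shrubs classes
(8 final classes), and fractions are averaged over the pixels whose centers
fall inside a 1-km-radius circle around the population's location.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FINAL_CLASSES", "TemperatureTrend", "LandCoverTrend", "CrosswalkTable",
    "AsciiRaster", "read_ascii_grid", "annual_mean_temperature",
    "temperature_trend", "buffer_fractions", "landcover_rate",
]

#: The 8 final land-cover classes used as model covariates.
FINAL_CLASSES = ("forest", "shrubs", "natural_grass", "bare_soil",
                 "cropland", "snow_ice", "urban", "water")

#: The 14 simplified classes the crosswalk maps raster codes onto, and the
#: grouping that collapses them to the 8 final classes.
SIMPLIFIED_TO_FINAL = {
    "broadleaf_evergreen_trees": "forest",
    "broadleaf_deciduous_trees": "forest",
    "needleleaf_evergreen_trees": "forest",
    "needleleaf_deciduous_trees": "forest",
    "broadleaf_evergreen_shrubs": "shrubs",
    "broadleaf_deciduous_shrubs": "shrubs",
    "needleleaf_evergreen_shrubs": "shrubs",
    "needleleaf_deciduous_shrubs": "shrubs",
    "natural_grass": "natural_grass",
    "bare_soil": "bare_soil",
    "cropland": "cropland",
    "snow_ice": "snow_ice",
    "urban": "urban",
    "water": "water",
}

_EARTH_RADIUS_M = 6_371_008.8


@dataclass(frozen=True)
class TemperatureTrend:
    """Average annual warming rate over a population's window (degC/year)."""
    population_id: str | None
    delta_t: float
    window: tuple[int, int]
    n_years: int

    def __post_init__(self):
        if self.n_years < 2:
            raise ValueError("temperature trend needs >= 2 annual values")


@dataclass(frozen=True)
class LandCoverTrend:
    """Mean annual change rate of each final cover class (fraction/year)."""
    population_id: str | None
    rates: Mapping[str, float]
    window: tuple[int, int]

    def __post_init__(self):
        extra = set(self.rates) - set(FINAL_CLASSES)
        if extra:
            raise ValueError(f"unknown cover classes: {sorted(extra)}")


class CrosswalkTable:
    """Maps discrete raster codes to fractional simplified-class contributions.

    Built from a long table with columns ``code``, ``class``, ``fraction``;
    each code's fractions must sum to 1. ``final_vector`` collapses a code's
    contributions onto the 8 final classes (tree/shrub grouping applied).
    """

    def __init__(self, table: pd.DataFrame):
        required = {"code", "class", "fraction"}
        if not required.issubset(table.columns):
            raise ValueError(f"crosswalk needs columns {sorted(required)}")
        bad = set(table["class"]) - set(SIMPLIFIED_TO_FINAL)
        if bad:
            raise ValueError(f"unknown simplified classes: {sorted(bad)}")
        sums = table.groupby("code")["fraction"].sum()
        off = sums[(sums - 1.0).abs() > 1e-6]
        if len(off):
            raise ValueError(
                f"crosswalk fractions must sum to 1 per code; offending codes: "
                f"{list(off.index)}"
            )
        self.table = table.copy()
        self._final: dict[int, np.ndarray] = {}
        idx = {c: i for i, c in enumerate(FINAL_CLASSES)}
        for code, grp in table.groupby("code"):
            v = np.zeros(len(FINAL_CLASSES))
            for _, r in grp.iterrows():
                v[idx[SIMPLIFIED_TO_FINAL[r["class"]]]] += r["fraction"]
            self._final[int(code)] = v

    @classmethod
    def from_csv(cls, path) -> "CrosswalkTable":
        return cls(pd.read_csv(path))

    @classmethod
    def default(cls) -> "CrosswalkTable":
        """The packaged simplified ESA-LC-style crosswalk (users may replace)."""
        with resources.files("fastslow.data").joinpath(
                "default_crosswalk.csv").open() as fh:
            return cls(pd.read_csv(fh))

    @property
    def codes(self) -> set[int]:
        return set(self._final)

    def final_vector(self, code: int) -> np.ndarray:
        try:
            return self._final[int(code)]
        except KeyError:
            raise KeyError(f"land-cover code {code} not in crosswalk") from None


@dataclass(frozen=True)
class AsciiRaster:
    """A small categorical raster in geographic (lon/lat) coordinates.

    ``values[i, j]`` is the code of the pixel whose center is at
    ``lon = west + (j + 0.5) * cell``, ``lat = north - (i + 0.5) * cell``.
    """

    values: np.ndarray
    west: float
    north: float
    cell: float
    nodata: int | None = None

    def pixel_centers(self):
        nrow, ncol = self.values.shape
        lons = self.west + (np.arange(ncol) + 0.5) * self.cell
        lats = self.north - (np.arange(nrow) + 0.5) * self.cell
        return lats, lons

    def contains(self, lat: float, lon: float) -> bool:
        nrow, ncol = self.values.shape
        return (self.west <= lon <= self.west + ncol * self.cell
                and self.north - nrow * self.cell <= lat <= self.north)


def read_ascii_grid(path) -> AsciiRaster:
    """Read an ESRI ASCII grid (text raster: header lines then rows of codes)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: ASCII grid header missing {key}")
    values = np.array(rows)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: grid shape does not match header")
    cell = header["cellsize"]
    if "xllcorner" in header:
        west = header["xllcorner"]
        north = header["yllcorner"] + values.shape[0] * cell
    else:  # cell-center convention
        west = header["xllcenter"] - cell / 2
        north = header["yllcenter"] - cell / 2 + values.shape[0] * cell
    nodata = header.get("nodata_value")
    return AsciiRaster(values=values.astype(int), west=west, north=north,
                       cell=cell, nodata=None if nodata is None else int(nodata))


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def annual_mean_temperature(monthly: pd.DataFrame,
                            max_missing_months: int = 2) -> pd.DataFrame:
    """Arithmetic annual means from monthly temperatures.

    ``monthly`` has columns ``year``, ``month``, ``temperature`` (one site).
    Years with more than ``max_missing_months`` absent months are kept but
    flagged; empty years are simply absent from the output.
    """
    required = {"year", "month", "temperature"}
    if not required.issubset(monthly.columns):
        raise ValueError(f"monthly table needs columns {sorted(required)}")
    m = monthly.dropna(subset=["temperature"])
    if m.empty:
        raise ValueError("no monthly temperature values")
    g = m.groupby("year")["temperature"]
    out = pd.DataFrame({
        "year": g.mean().index.astype(int),
        "temperature": g.mean().to_numpy(),
        "n_months": g.count().to_numpy(),
    })
    out["flagged"] = out["n_months"] < 12 - max_missing_months
    if out["flagged"].any():
        warnings.warn(
            f"{int(out['flagged'].sum())} year(s) with more than "
            f"{max_missing_months} missing months", stacklevel=2)
    return out


def temperature_trend(annual: pd.DataFrame | Mapping[int, float],
                      window: tuple[int, int],
                      population_id: str | None = None) -> TemperatureTrend:
    """OLS slope of annual mean temperature on year, inside ``window``."""
    if isinstance(annual, Mapping):
        annual = pd.DataFrame({"year": list(annual), "temperature":
                               list(annual.values())})
    lo, hi = window
    sub = annual[(annual["year"] >= lo) & (annual["year"] <= hi)]
    if len(sub) < 2:
        raise ValueError(
            f"need >= 2 annual temperatures inside window {window}, "
            f"got {len(sub)}")
    x = sub["year"].to_numpy(dtype=float)
    y = sub["temperature"].to_numpy(dtype=float)
    slope = float(np.polyfit(x, y, 1)[0])
    return TemperatureTrend(population_id=population_id, delta_t=slope,
                            window=window, n_years=len(sub))


def _haversine_m(lat1, lon1, lat2, lon2):
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return 2 * _EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


def buffer_fractions(raster: AsciiRaster, latitude: float, longitude: float,
                     crosswalk: CrosswalkTable,
                     radius_m: float = 1000.0) -> dict[str, float]:
    """Final-class cover fractions inside a geodesic circle around a location.

    Pixel membership is decided by the great-circle distance of the pixel
    center from the location; each member pixel's code is crosswalked and the
    resulting vectors averaged. Fractions sum to 1.
    """
    if not raster.contains(latitude, longitude):
        raise ValueError(
            f"location ({latitude}, {longitude}) outside raster extent")
    lats, lons = raster.pixel_centers()
    lat_grid, lon_grid = np.meshgrid(lats, lons, indexing="ij")
    dist = _haversine_m(latitude, longitude, lat_grid, lon_grid)
    mask = dist <= radius_m
    if raster.nodata is not None:
        mask &= raster.values != raster.nodata
    if not mask.any():
        raise ValueError(
            "empty buffer: no pixel centers within the radius "
            f"({radius_m} m) of ({latitude}, {longitude})")
    codes = raster.values[mask]
    acc = np.zeros(len(FINAL_CLASSES))
    for code in codes:
        acc += crosswalk.final_vector(int(code))
    acc /= len(codes)
    return dict(zip(FINAL_CLASSES, acc))


def landcover_rate(fractions: pd.DataFrame, window: tuple[int, int],
                   population_id: str | None = None) -> LandCoverTrend:
    """Mean annual change of each class's cover fraction inside ``window``.

    ``fractions`` is indexed or keyed by ``year`` with one column per final
    class. The rate is the arithmetic mean of successive annual differences
    (no regression), which telescopes to (last - first)/(n_years - 1).
    """
    df = fractions.copy()
    if "year" in df.columns:
        df = df.set_index("year")
    df = df.sort_index()
    lo, hi = window
    df = df.loc[(df.index >= lo) & (df.index <= hi)]
    if len(df) < 2:
        raise ValueError(
            f"need >= 2 annual cover fraction vectors inside window {window}")
    rates = {}
    for cls in FINAL_CLASSES:
        if cls not in df.columns:
            raise ValueError(f"missing cover class column {cls!r}")
        rates[cls] = float(np.mean(np.diff(df[cls].to_numpy(dtype=float))))
    return LandCoverTrend(population_id=population_id, rates=rates,
                          window=window)
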