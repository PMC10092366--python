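"""Mean annual rates of population change (lambda statistics).

Implements the Living-Planet-style trend engine: zero replacement,
log10-scale gap imputation (linear regression for short series, penalized
regression spline GAM for longer ones), quality filtering on imputation R2
and series length, and the per-population annual and mean log10 rates of
change

    lambda_t   = log10(n_t / n_{t-1})
    lambda_bar = mean over the year-to-year transitions of lambda_t

Abundances enter on the log10 scale throughout, so lambda statistics are
invariant to rescaling a series by a positive constant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PopulationSeries", "ImputedSeries", "LambdaRecord",
    "replace_zeros", "impute_series", "filter_populations",
    "annual_lambda", "mean_lambda", "compute_trends",
    "read_populations_wide", "write_populations_wide",
]

#: GCV grid for the spline penalty (log-spaced; seedless and deterministic).
_ALPHA_GRID = 10.0 ** np.arange(-4.0, 5.0)


@dataclass(frozen=True)
class PopulationSeries:
    """One monitored population: abundance by year, with location and species.

    ``records`` maps year -> abundance; years need not be consecutive
    (gaps are imputed downstream). Abundances must be non-negative and at
    least two years must be recorded.
    """

    population_id: str
    species: str
    location_id: str
    latitude: float
    longitude: float
    records: Mapping[int, float]

    def __post_init__(self):
        recs = dict(sorted((int(y), float(v)) for y, v in self.records.items()))
        if len(recs) < 2:
            raise ValueError(
                f"population {self.population_id!r}: needs >= 2 recorded years, "
                f"got {len(recs)}"
            )
        for y, v in recs.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"population {self.population_id!r}: abundance in year {y} "
                    f"must be finite and >= 0, got {v}"
                )
        object.__setattr__(self, "records", recs)

    @property
    def years(self) -> np.ndarray:
        return np.array(list(self.records), dtype=int)

    @property
    def abundances(self) -> np.ndarray:
        return np.array(list(self.records.values()), dtype=float)


@dataclass(frozen=True)
class ImputedSeries:
    """A gap-free series spanning the first to the last real record.

    ``method`` is ``"none"`` when the input had no interior gaps,
    ``"linear"`` or ``"gam"`` otherwise; ``fit_r2`` is the coefficient of
    determination (linear) or proportion of deviance explained (GAM) of the
    imputation model, and is ``None`` when no model was needed.
    """

    population_id: str
    species: str
    location_id: str
    latitude: float
    longitude: float
    values: Mapping[int, float]
    method: str
    fit_r2: float | None
    n_real: int

    def __post_init__(self):
        vals = dict(sorted((int(y), float(v)) for y, v in self.values.items()))
        yrs = list(vals)
        if yrs != list(range(yrs[0], yrs[-1] + 1)):
            raise ValueError("imputed series must cover consecutive years")
        object.__setattr__(self, "values", vals)

    @property
    def years(self) -> np.ndarray:
        return np.array(list(self.values), dtype=int)

    def clipped(self, window: tuple[int, int]) -> dict[int, float]:
        """Values restricted to ``window`` (inclusive); stays consecutive."""
        lo, hi = window
        return {y: v for y, v in self.values.items() if lo <= y <= hi}


@dataclass(frozen=True)
class LambdaRecord:
    """Annual log10 rates of change and their mean for one population."""

    population_id: str
    lambdas: Mapping[int, float]  # year -> lambda_t (transition ending in year)
    mean_lambda: float
    T: int  # years from first to last estimate used

    def __post_init__(self):
        if not math.isfinite(self.mean_lambda):
            raise ValueError("mean_lambda must be finite")


def replace_zeros(series: PopulationSeries) -> PopulationSeries:
    """Replace zero counts by 1% of the mean of the non-zero abundances.

    The replacement value is computed from the population's own series only.
    A series with no non-zero abundance cannot be placed on the log scale
    and is rejected.
    """
    vals = series.abundances
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        raise ValueError(
            f"population {series.population_id!r}: no non-zero abundance"
        )
    if (vals == 0).sum() == 0:
        return series
    repl = 0.01 * float(nonzero.mean())
    new = {y: (repl if v == 0 else v) for y, v in series.records.items()}
    return _dc_replace(series, records=new)


def annual_lambda(values: Mapping[int, float] | Sequence[float]) -> np.ndarray:
    """Annual log10 rate of change for each adjacent pair of a complete series."""
    v = np.asarray(list(values.values()) if isinstance(values, Mapping) else values,
                   dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    if np.any(v <= 0):
        raise ValueError("non-positive abundance: replace zeros before lambda")
    return np.log10(v[1:] / v[:-1])


def mean_lambda(lambdas: Sequence[float] | np.ndarray) -> float:
    """Arithmetic mean of the annual rates (the per-population trend)."""
    lam = np.asarray(lambdas, dtype=float)
    if lam.size == 0:
        raise ValueError("empty lambda vector")
    return float(lam.mean())


def _linear_fit(years: np.ndarray, logy: np.ndarray):
    coef = np.polyfit(years, logy, 1)
    fitted = np.polyval(coef, years)
    ss_res = float(np.sum((logy - fitted) ** 2))
    ss_tot = float(np.sum((logy - logy.mean()) ** 2))
    if ss_tot < 1e-12:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    predict = lambda yy: np.polyval(coef, yy)
    return predict, r2


def _gam_fit(years: np.ndarray, logy: np.ndarray, basis_dim: int):
    # penalized regression spline of year; penalty by GCV over a fixed grid
    from statsmodels.gam.api import GLMGam, BSplines

    x = pd.DataFrame({"year": years.astype(float)})
    smoother = BSplines(x, df=[basis_dim], degree=[3])
    n = len(years)
    intercept = np.ones((n, 1))
    best = None
    for alpha in _ALPHA_GRID:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = GLMGam(logy, intercept, smoother=smoother, alpha=[alpha]).fit()
        edf = float(np.sum(res.edf))
        denom = max(n - edf, 1e-8)
        gcv = n * res.deviance / denom ** 2
        if best is None or gcv < best[0]:
            best = (gcv, res)
    res = best[1]
    null_dev = res.null_deviance
    r2 = 1.0 - res.deviance / null_dev if null_dev > 1e-12 else (
        1.0 if res.deviance < 1e-12 else 0.0)

    def predict(yy):
        xx = pd.DataFrame({"year": np.asarray(yy, dtype=float)})
        return res.predict(np.ones((len(xx), 1)), exog_smooth=xx)

    return predict, r2


def impute_series(series: PopulationSeries) -> ImputedSeries:
    """Fill interior gaps of a series by a log10-scale model of abundance on year.

    Fewer than six real observations: simple linear regression. Six or more:
    a GAM with a penalized regression spline of year whose basis dimension is
    half the series span (rounded up), capped at ``n_real - 1`` to keep the
    model identifiable. Real records are preserved exactly; no values are
    produced outside the first-to-last-record range. Complete series are
    returned untouched with ``method="none"``.
    """
    years = series.years
    vals = series.abundances
    if np.any(vals <= 0):
        raise ValueError(
            f"population {series.population_id!r}: non-positive abundance; "
            "run replace_zeros first"
        )
    n_real = len(years)
    first, last = int(years[0]), int(years[-1])
    full_years = np.arange(first, last + 1)
    meta = dict(
        population_id=series.population_id, species=series.species,
        location_id=series.location_id, latitude=series.latitude,
        longitude=series.longitude,
    )

    if len(full_years) == n_real:  # no interior gaps
        return ImputedSeries(values=dict(series.records), method="none",
                             fit_r2=None, n_real=n_real, **meta)

    logy = np.log10(vals)
    span = last - first + 1
    if n_real < 6:
        predict, r2 = _linear_fit(years.astype(float), logy)
        method = "linear"
    else:
        basis_dim = max(4, min(math.ceil(span / 2), n_real - 1))
        predict, r2 = _gam_fit(years, logy, basis_dim)
        method = "gam"

    fitted = np.asarray(predict(full_years.astype(float)), dtype=float)
    if not np.all(np.isfinite(fitted)):
        raise ValueError(
            f"population {series.population_id!r}: singular imputation fit"
        )
    values = {}
    for y, f in zip(full_years, fitted):
        values[int(y)] = series.records.get(int(y), float(10.0 ** f))
    return ImputedSeries(values=values, method=method, fit_r2=float(r2),
                         n_real=n_real, **meta)


def filter_populations(
    imputed: Iterable[ImputedSeries],
    min_length: int = 5,
    r2_threshold: float = 0.5,
    window: tuple[int, int] = (1992, 2018),
) -> tuple[list[ImputedSeries], pd.DataFrame]:
    """Quality filter: length inside the window and imputation accuracy.

    Retains series with at least ``min_length`` consecutive values inside
    ``window`` and, for series that required imputation, a model fit R2 of at
    least ``r2_threshold`` (complete series pass automatically). Returns the
    retained subset and a per-population report with exclusion reasons.
    """
    kept: list[ImputedSeries] = []
    rows = []
    for s in imputed:
        n_window = len(s.clipped(window))
        reason = ""
        if n_window < min_length:
            reason = "too short"
        elif s.method != "none" and (s.fit_r2 is None or s.fit_r2 < r2_threshold):
            reason = "low imputation R2"
        if not reason:
            kept.append(s)
        rows.append({
            "population_id": s.population_id, "species": s.species,
            "location_id": s.location_id, "method": s.method,
            "fit_r2": s.fit_r2, "n_real": s.n_real,
            "n_window": n_window, "retained": not reason,
            "exclusion_reason": reason or None,
        })
    return kept, pd.DataFrame(rows)


def compute_trends(
    populations: Iterable[PopulationSeries],
    min_length: int = 5,
    r2_threshold: float = 0.5,
    window: tuple[int, int] = (1992, 2018),
) -> pd.DataFrame:
    """Raw series to per-population lambda-bar, end to end.

    Runs zero replacement, imputation, the quality filter, and the lambda
    statistics on the window-clipped series. Returns one row per input
    population; excluded populations keep their exclusion reason and have
    NaN trend columns.
    """
    imputed: list[ImputedSeries] = []
    failures = []
    for pop in populations:
        try:
            imputed.append(impute_series(replace_zeros(pop)))
        except ValueError as e:
            failures.append({
                "population_id": pop.population_id, "species": pop.species,
                "location_id": pop.location_id, "method": None,
                "fit_r2": None, "n_real": len(pop.records),
                "n_window": 0, "retained": False, "exclusion_reason": str(e),
            })
    kept, report = filter_populations(imputed, min_length, r2_threshold, window)
    if failures:
        report = pd.concat([report, pd.DataFrame(failures)], ignore_index=True)

    trends = {}
    for s in kept:
        vals = s.clipped(window)
        lam = annual_lambda(vals)
        yrs = sorted(vals)
        trends[s.population_id] = {
            "mean_lambda": mean_lambda(lam),
            "first_year": yrs[0], "last_year": yrs[-1],
            "T": yrs[-1] - yrs[0] + 1,
            "latitude": s.latitude, "longitude": s.longitude,
        }
    out = report.set_index("population_id")
    for col in ("mean_lambda", "first_year", "last_year", "T",
                "latitude", "longitude"):
        out[col] = pd.Series({k: v[col] for k, v in trends.items()})
    return out.reset_index()


# ---------------------------------------------------------------------------
# LPD-dialect wide CSV I/O: metadata columns, then one column per year
# (blank cell = missing observation).

_META_COLS = ["population_id", "species", "location_id", "latitude", "longitude"]


def read_populations_wide(path) -> list[PopulationSeries]:
    df = pd.read_csv(path)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    year_cols = [c for c in df.columns if c not in _META_COLS]
    try:
        years = {c: int(c) for c in year_cols}
    except ValueError as e:
        raise ValueError(f"{path}: non-year data column: {e}") from None
    pops = []
    for i, row in df.iterrows():
        records = {years[c]: float(row[c]) for c in year_cols
                   if pd.notna(row[c])}
        try:
            pops.append(PopulationSeries(
                population_id=str(row["population_id"]),
                species=str(row["species"]),
                location_id=str(row["location_id"]),
                latitude=float(row["latitude"]),
                longitude=float(row["longitude"]),
                records=records,
            ))
        except ValueError as e:
            raise ValueError(f"{path}, row {i}: {e}") from None
    return pops


def write_populations_wide(pops: Sequence[PopulationSeries], path) -> None:
    all_years = sorted({y for p in pops for y in p.records})
    rows = []
    for p in pops:
        row = {"population_id": p.population_id, "species": p.species,
               "location_id": p.location_id, "latitude": p.latitude,
               "longitude": p.longitude}
        row.update({str(y): p.records.get(y, np.nan) for y in all_years})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
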