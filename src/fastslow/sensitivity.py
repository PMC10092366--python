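"""Robustness protocols: imputation-quality thresholds and percentile trimming.

Two scenario families probe how the fitted trend model depends on data
selection: (1) re-running the population filter at different imputation-R2
thresholds (larger thresholds keep fewer, better-imputed populations);
(2) trimming populations with extreme mean trends (below the 2.5th and/or
above the 97.5th percentile of lambda-bar) before refitting. Scenarios
refit the baseline-selected model by default so term-by-term comparisons
are well defined; full reselection is available via a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from fastslow.poptrends import ImputedSeries, filter_populations, annual_lambda, mean_lambda
from fastslow.trendmodel import (FitResult, ModelSpec, fit_lmm, pseudo_r2,
                                 stepwise_aicc, wald_type3)

__all__ = ["SensitivityReport", "r2_threshold_scan", "trim_extremes",
           "sensitivity_compare"]

TRIM_MODES = ("drop_lower", "drop_upper", "drop_both")


@dataclass
class SensitivityReport:
    """Per-scenario fits next to the baseline, with sign/significance flags."""

    baseline_name: str
    scenarios: dict[str, FitResult]
    n_populations: dict[str, int]
    table: pd.DataFrame  # term x scenario rows: estimate, chi2, p, flags

    def __post_init__(self):
        if self.baseline_name not in self.scenarios:
            raise ValueError("baseline scenario missing from report")


def trim_extremes(frame: pd.DataFrame, mode: str = "drop_both",
                  q: float = 0.025) -> pd.DataFrame:
    """Drop rows with extreme mean_lambda.

    ``drop_lower`` removes rows below the q quantile, ``drop_upper`` rows
    above the 1-q quantile, ``drop_both`` both; quantiles are empirical with
    linear interpolation, computed on the input frame. q=0 is the identity.
    """
    if mode not in TRIM_MODES:
        raise ValueError(f"mode must be one of {TRIM_MODES}")
    if not 0 <= q < 0.5:
        raise ValueError("q must be in [0, 0.5)")
    if q == 0:
        return frame.copy()
    if len(frame) < 1.0 / q:
        raise ValueError(f"frame has {len(frame)} rows, need >= {1 / q:.0f} "
                         f"for q={q}")
    lam = frame["mean_lambda"].to_numpy(dtype=float)
    keep = np.ones(len(frame), dtype=bool)
    if mode in ("drop_lower", "drop_both"):
        keep &= lam >= np.quantile(lam, q)
    if mode in ("drop_upper", "drop_both"):
        keep &= lam <= np.quantile(lam, 1 - q)
    return frame.loc[keep].copy()


def _window_lambda(series: ImputedSeries, window: tuple[int, int]) -> float:
    vals = series.clipped(window)
    return mean_lambda(annual_lambda(vals))


def r2_threshold_scan(
    imputed: Iterable[ImputedSeries],
    frame_builder,
    spec: ModelSpec,
    thresholds: Sequence[float] = (0.3, 0.5, 0.7, 0.9),
    baseline_threshold: float = 0.5,
    min_length: int = 5,
    window: tuple[int, int] = (1992, 2018),
) -> SensitivityReport:
    """Refilter populations at each R2 threshold and refit the selected model.

    ``frame_builder`` maps a list of retained :class:`ImputedSeries` to a
    model frame (it closes over the environment and life-history tables).
    Scenarios that leave too few rows to fit are flagged in the table but do
    not abort the scan.
    """
    imputed = list(imputed)
    fits: dict[str, FitResult] = {}
    npops: dict[str, int] = {}
    baseline_name = f"r2>={baseline_threshold}"
    for thr in sorted(set([*thresholds, baseline_threshold])):
        name = f"r2>={thr}"
        kept, _ = filter_populations(imputed, min_length=min_length,
                                     r2_threshold=thr, window=window)
        frame = frame_builder(kept)
        npops[name] = len(frame)
        try:
            fits[name] = fit_lmm(frame, spec, method="reml")
        except (ValueError, RuntimeError, KeyError):
            continue
    if baseline_name not in fits:
        raise RuntimeError("baseline scenario failed to fit")
    return sensitivity_compare(baseline_name, fits, npops)


def trim_scenarios(frame: pd.DataFrame, spec: ModelSpec, q: float = 0.025,
                   reselect: bool = False,
                   full_spec: ModelSpec | None = None) -> SensitivityReport:
    """The three percentile-trimming datasets plus the untrimmed baseline."""
    fits: dict[str, FitResult] = {}
    npops: dict[str, int] = {}
    for name, sub in [("baseline", frame),
                      *[(m, trim_extremes(frame, m, q)) for m in TRIM_MODES]]:
        npops[name] = len(sub)
        if reselect:
            if full_spec is None:
                raise ValueError("full_spec required when reselect=True")
            _, fits[name], _ = stepwise_aicc(sub, full_spec)
        else:
            fits[name] = fit_lmm(sub, spec, method="reml")
    return sensitivity_compare("baseline", fits, npops)


def sensitivity_compare(baseline_name: str,
                        scenario_fits: Mapping[str, FitResult],
                        n_populations: Mapping[str, int] | None = None,
                        alpha: float = 0.05) -> SensitivityReport:
    """Tabulate estimates, Wald tests, pseudo-R2, and per-term sign and
    significance agreement of every scenario against the baseline."""
    if baseline_name not in scenario_fits:
        raise ValueError(f"no scenario named {baseline_name!r}")
    base = wald_type3(scenario_fits[baseline_name]).set_index("term")
    rows = []
    for name, fit in scenario_fits.items():
        w = wald_type3(fit).set_index("term")
        marg, cond = pseudo_r2(fit)
        for term, r in w.iterrows():
            in_base = term in base.index
            rows.append({
                "scenario": name, "term": term,
                "estimate": r["estimate"], "se": r["se"],
                "chi2": r["chi2"], "p": r["p"],
                "significant": r["p"] < alpha,
                "sign_flip": bool(in_base and
                                  np.sign(r["estimate"])
                                  != np.sign(base.loc[term, "estimate"])),
                "significance_change": bool(
                    in_base and (r["p"] < alpha)
                    != (base.loc[term, "p"] < alpha)),
                "marginal_r2": marg, "conditional_r2": cond,
            })
    table = pd.DataFrame(rows)
    npops = dict(n_populations or {name: f.nobs
                                   for name, f in scenario_fits.items()})
    return SensitivityReport(baseline_name=baseline_name,
                             scenarios=dict(scenario_fits),
                             n_populations=npops, table=table)
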