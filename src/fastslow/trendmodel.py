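"""Linear mixed model of population trends on environmental change and
life history.

The full model regresses each population's mean log10 rate of change
(lambda-bar) on the temperature-warming rate (delta_t), the fast-slow
score (pc1), the eight land-cover change rates, and all two- and three-way
interactions of {delta_t, pc1} with each cover rate and each other (no
cover x cover terms), with crossed random intercepts for location and
species:

    mean_lambda ~ delta_t + pc1 + sum_i lc_i
                + delta_t:pc1 + sum_i lc_i:pc1 + sum_i lc_i:delta_t
                + sum_i lc_i:pc1:delta_t + (1|location) + (1|species)

Model reduction is backward stepwise on AICc (small-sample-corrected AIC)
under maximum likelihood, respecting marginality; the selected model is
refit with REML. Fixed effects are tested with type-III Wald chi-square
statistics and fit is summarized with Nakagawa-style marginal and
conditional pseudo-R2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from fastslow.envchange import FINAL_CLASSES

__all__ = [
    "ModelSpec", "FitResult", "assemble_model_frame", "build_full_spec",
    "fit_lmm", "aicc", "stepwise_aicc", "wald_type3", "wald_single",
    "pseudo_r2", "COVER_COLS",
]

#: Land-cover covariate columns in the model frame.
COVER_COLS = tuple(f"lc_{c}" for c in FINAL_CLASSES)

RANDOM_FACTORS = ("location_id", "species")


def _components(term: str) -> tuple[str, ...]:
    return tuple(term.split(":"))


def _parents(term: str) -> list[str]:
    """Immediate lower-order terms an interaction marginalizes over."""
    comps = _components(term)
    if len(comps) == 1:
        return []
    return [":".join(c for j, c in enumerate(comps) if j != i)
            for i in range(len(comps))]


@dataclass(frozen=True)
class ModelSpec:
    """An ordered fixed-effect term list plus the random intercept factors.

    Terms are ``":"``-joined products of covariate column names (all
    numeric); marginality (every interaction's lower-order terms present)
    is enforced at construction.
    """

    fixed_terms: tuple[str, ...]
    random_factors: tuple[str, ...] = RANDOM_FACTORS

    def __post_init__(self):
        have = set(self.fixed_terms)
        if len(have) != len(self.fixed_terms):
            raise ValueError("duplicate fixed-effect terms")
        for t in self.fixed_terms:
            for p in _parents(t):
                if p not in have:
                    raise ValueError(
                        f"marginality violated: {t!r} present without {p!r}")

    def droppable(self) -> list[str]:
        """Terms that are not parents of any retained interaction."""
        needed = {p for t in self.fixed_terms for p in _parents(t)}
        return [t for t in self.fixed_terms if t not in needed]

    def without(self, term: str) -> "ModelSpec":
        if term not in self.fixed_terms:
            raise ValueError(f"term {term!r} not in spec")
        return ModelSpec(tuple(t for t in self.fixed_terms if t != term),
                         self.random_factors)


@dataclass
class FitResult:
    """A converged mixed-model fit: estimates, covariance, variance
    components, and likelihood, with the spec and data sizes needed for
    AICc, Wald tests, and pseudo-R2.

    ``aliased`` lists terms whose design columns were linearly dependent on
    earlier ones and were dropped from estimation (closed cover fractions
    make the per-class rates sum to zero, so the full cover blocks carry one
    exact dependency each)."""

    spec: ModelSpec
    params: pd.Series            # includes "Intercept"
    se: pd.Series
    cov: pd.DataFrame
    vcomp: dict[str, float]      # per random factor + "residual"
    llf: float
    method: str                  # "ml" | "reml"
    nobs: int
    fixed_predictor_var: float   # population variance of X beta
    converged: bool = True
    aliased: tuple[str, ...] = ()

    @property
    def k(self) -> int:
        """Parameter count for AICc: fixed effects + variance components."""
        return len(self.params) + len(self.vcomp)

    def __post_init__(self):
        if any(v < -1e-8 for v in self.vcomp.values()):
            raise ValueError("negative variance component")


def assemble_model_frame(lambdas: pd.DataFrame, env: pd.DataFrame,
                         scores: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge trend, environment, and life-history tables into the analysis frame.

    ``lambdas`` has population_id, species, location_id, mean_lambda;
    ``env`` has population_id, delta_t and the lc_* columns; ``scores`` has
    species and pc1. Inner join; rows with any missing covariate are dropped
    and reported. Returns (frame, drop report).
    """
    for name, df, key in (("lambdas", lambdas, "population_id"),
                          ("env", env, "population_id")):
        if df[key].duplicated().any():
            dups = df.loc[df[key].duplicated(), key].tolist()
            raise ValueError(f"duplicate {key} in {name}: {dups[:5]}")
    if scores.index.name == "species":
        scores = scores.reset_index()
    merged = lambdas.merge(env, on="population_id", how="left", suffixes=("", "_env"))
    merged = merged.merge(scores[["species", "pc1"]], on="species", how="left")
    needed = ["mean_lambda", "delta_t", "pc1", *COVER_COLS]
    missing_cols = [c for c in needed if c not in merged.columns]
    if missing_cols:
        raise ValueError(f"model frame missing columns: {missing_cols}")
    bad = merged[needed].isna().any(axis=1)
    report = merged.loc[bad, ["population_id", "species"]].copy()
    report["reason"] = [
        "missing " + ",".join(c for c in needed if pd.isna(row[c]))
        for _, row in merged.loc[bad].iterrows()
    ]
    frame = merged.loc[~bad, ["population_id", "species", "location_id",
                              *needed]].reset_index(drop=True)
    return frame, report.reset_index(drop=True)


def build_full_spec(frame: pd.DataFrame | None = None,
                    cover_cols: Sequence[str] = COVER_COLS) -> ModelSpec:
    """The full fixed-effect structure: with N cover classes, N+2 main
    effects, 2N+1 two-way and N three-way interactions (no cover x cover)."""
    if frame is not None:
        cover_cols = [c for c in frame.columns if c.startswith("lc_")]
        needed = {"delta_t", "pc1"}
        if not needed.issubset(frame.columns) or not cover_cols:
            raise ValueError("frame lacks the fixed covariates")
    terms = ["delta_t", "pc1", *cover_cols]
    terms += ["delta_t:pc1"]
    terms += [f"pc1:{c}" for c in cover_cols]
    terms += [f"delta_t:{c}" for c in cover_cols]
    terms += [f"delta_t:pc1:{c}" for c in cover_cols]
    return ModelSpec(tuple(terms))


def _design(frame: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    X = pd.DataFrame({"Intercept": np.ones(len(frame))}, index=frame.index)
    for t in spec.fixed_terms:
        cols = _components(t)
        v = np.ones(len(frame))
        for c in cols:
            v = v * frame[c].to_numpy(dtype=float)
        X[t] = v
    return X


def _estimable_columns(X: np.ndarray, tol: float = 1e-7) -> list[int]:
    """Greedy left-to-right selection of linearly independent columns.

    Earlier (lower-order, spec-order) terms win over later ones, so in the
    compositional cover blocks the last class of each block is the one
    aliased; marginality of the retained set follows from the term ordering.
    """
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    Z = X / norms
    keep: list[int] = []
    basis = np.empty((X.shape[0], 0))
    for j in range(Z.shape[1]):
        z = Z[:, j]
        if basis.shape[1]:
            z = z - basis @ (basis.T @ z)
        nz = np.linalg.norm(z)
        if nz > tol:
            keep.append(j)
            basis = np.hstack([basis, (z / nz)[:, None]])
    return keep


def fit_lmm(frame: pd.DataFrame, spec: ModelSpec,
            method: str = "reml") -> FitResult:
    """Fit the mixed model with crossed random intercepts.

    ``method`` is ``"reml"`` (final fits) or ``"ml"`` (AICc comparisons of
    fixed structures). Non-convergence is flagged on the result, never
    silent.
    """
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import VCSpec
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    if method not in ("ml", "reml"):
        raise ValueError("method must be 'ml' or 'reml'")
    for f in spec.random_factors:
        if frame[f].nunique() < 2:
            raise ValueError(f"random factor {f!r} needs >= 2 levels")
    y = frame["mean_lambda"].to_numpy(dtype=float)
    X_full = _design(frame, spec)
    keep = _estimable_columns(X_full.to_numpy())
    aliased = tuple(c for i, c in enumerate(X_full.columns) if i not in keep)
    X = X_full.iloc[:, keep]

    # crossed intercepts: a single group containing everything, each factor
    # a variance component with an indicator matrix
    names, mats, colnames = [], [], []
    for f in spec.random_factors:
        d = pd.get_dummies(frame[f].astype(str)).to_numpy(dtype=float)
        names.append(f)
        mats.append([d])
        colnames.append([list(pd.get_dummies(frame[f].astype(str)).columns)])
    vcs = VCSpec(names, colnames, mats)
    groups = np.zeros(len(frame))

    model = sm.MixedLM(y, X.to_numpy(), groups=groups, exog_vc=vcs)
    model.data.param_names = None  # silence unused name bookkeeping
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            res = model.fit(reml=(method == "reml"), method="lbfgs",
                            maxiter=500)
        except np.linalg.LinAlgError as e:
            raise RuntimeError(f"mixed model fit failed: {e}") from None
    converged = bool(getattr(res, "converged", True))

    k_fe = X.shape[1]
    params = pd.Series(np.asarray(res.fe_params, dtype=float), index=X.columns)
    cov = pd.DataFrame(np.asarray(res.cov_params())[:k_fe, :k_fe],
                       index=X.columns, columns=X.columns)
    # at a variance-component boundary the numerical covariance can carry
    # tiny negative diagonals; clip rather than emit NaN standard errors
    se = pd.Series(np.sqrt(np.clip(np.diag(cov), 0.0, None)),
                   index=X.columns)
    vcomp = {f: float(max(v, 0.0))
             for f, v in zip(spec.random_factors, res.vcomp)}
    vcomp["residual"] = float(res.scale)
    eta = X.to_numpy() @ params.to_numpy()
    return FitResult(spec=spec, params=params, se=se, cov=cov, vcomp=vcomp,
                     llf=float(res.llf), method=method, nobs=len(frame),
                     fixed_predictor_var=float(np.var(eta)),
                     converged=converged, aliased=aliased)


def aicc(fit: FitResult | float, n: int | None = None,
         k: int | None = None) -> float:
    """Small-sample-corrected AIC: -2 logLik + 2k + 2k(k+1)/(n-k-1).

    ``k`` counts fixed effects plus variance components (residual included).
    """
    if isinstance(fit, FitResult):
        llf, n_, k_ = fit.llf, fit.nobs, fit.k
        n = n if n is not None else n_
        k = k if k is not None else k_
    else:
        llf = float(fit)
        if n is None or k is None:
            raise ValueError("n and k required with a bare log-likelihood")
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def stepwise_aicc(frame: pd.DataFrame, full_spec: ModelSpec,
                  ) -> tuple[ModelSpec, FitResult, list[dict]]:
    """Backward elimination on AICc with marginality.

    At each step the droppable term (one whose removal keeps every retained
    interaction's parents) giving the largest AICc decrease is removed; ties
    break deterministically toward the term later in spec order. Model
    comparisons use ML fits; the winning structure is refit with REML.
    Returns (final spec, REML fit, elimination path).
    """
    spec = full_spec
    current = fit_lmm(frame, spec, method="ml")
    current_aicc = aicc(current)
    path = [{"action": "start", "term": None, "aicc": current_aicc,
             "n_terms": len(spec.fixed_terms)}]
    while True:
        candidates = []
        for term in spec.droppable():
            try:
                trial = fit_lmm(frame, spec.without(term), method="ml")
            except RuntimeError:
                continue
            candidates.append((aicc(trial), term, trial))
        if not candidates:
            break
        best_aicc = min(a for a, _, _ in candidates)
        if best_aicc >= current_aicc - 1e-9:
            break
        # tie-break: later spec-order term among those within 1e-9 of best
        order = {t: i for i, t in enumerate(spec.fixed_terms)}
        tied = [c for c in candidates if c[0] <= best_aicc + 1e-9]
        _, term, trial = max(tied, key=lambda c: order[c[1]])
        spec = spec.without(term)
        current, current_aicc = trial, aicc(trial)
        path.append({"action": "drop", "term": term, "aicc": current_aicc,
                     "n_terms": len(spec.fixed_terms)})
    # aliased droppable terms carry no likelihood: removing them leaves AICc
    # unchanged, so clean them up explicitly
    while True:
        dead = [t for t in spec.droppable() if t in current.aliased]
        if not dead:
            break
        term = dead[-1]
        spec = spec.without(term)
        current = fit_lmm(frame, spec, method="ml")
        current_aicc = aicc(current)
        path.append({"action": "drop_aliased", "term": term,
                     "aicc": current_aicc, "n_terms": len(spec.fixed_terms)})
    final = fit_lmm(frame, spec, method="reml")
    path.append({"action": "final_reml", "term": None, "aicc": aicc(final),
                 "n_terms": len(spec.fixed_terms)})
    return spec, final, path


def wald_single(estimate: float, se: float) -> tuple[float, float]:
    """Wald chi-square (1 df) and p-value for a single coefficient."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    chi2 = (estimate / se) ** 2
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def wald_type3(fit: FitResult, include_intercept: bool = True) -> pd.DataFrame:
    """Type-III Wald chi-square test per fixed-effect term.

    Each term's coefficients b with covariance C give
    chi2 = b' C^-1 b on df = number of coefficients; with one coefficient
    this is (estimate/SE)^2. All terms here are single numeric columns.
    """
    rows = []
    terms = list(fit.params.index)
    if not include_intercept:
        terms = [t for t in terms if t != "Intercept"]
    for t in terms:
        b = np.atleast_1d(fit.params[t])
        C = np.atleast_2d(fit.cov.loc[t, t])
        try:
            chi2 = float(b @ np.linalg.solve(C, b))
        except np.linalg.LinAlgError:
            raise RuntimeError(f"singular covariance for term {t!r}") from None
        df = b.size
        rows.append({"term": t, "estimate": float(fit.params[t]),
                     "se": float(fit.se[t]), "chi2": chi2, "df": df,
                     "p": float(stats.chi2.sf(chi2, df))})
    return pd.DataFrame(rows)


def pseudo_r2(fit: FitResult) -> tuple[float, float]:
    """Marginal and conditional pseudo-R2 (variance-decomposition form).

    marginal = var(fixed predictor) / total; conditional adds the random
    intercept variances to the numerator; total = fixed + random + residual.
    """
    var_f = fit.fixed_predictor_var
    var_re = sum(v for kf, v in fit.vcomp.items() if kf != "residual")
    total = var_f + var_re + fit.vcomp["residual"]
    if total <= 0:
        raise ValueError("zero total variance")
    return var_f / total, (var_f + var_re) / total
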