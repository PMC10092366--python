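"""Fast-slow life-history scores from raw trait records.

The pipeline: harmonize taxonomy against a local synonym table; aggregate
multi-source trait records per species by geometric mean; decompose the
phylogeny's patristic distance matrix into eigenvectors; fill trait gaps by
iterative random-forest imputation (phylogenetic eigenvectors plus
class/order/family as predictors); remove body-mass allometry and taxonomic
kinship by mixed-model residualization; and ordinate the four adjusted
traits by PCA. The first principal component, oriented so that fecundity
traits load positively, is the fast-slow continuum: high scores mean
short-lived, highly fecund ("fast") species, low scores long-lived,
late-maturing ("slow") species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRAITS", "ADJUSTED_TRAITS", "LifeHistoryScores",
    "harmonize_taxonomy", "aggregate_traits", "phylo_eigenvectors",
    "impute_traits", "mass_adjust", "fast_slow_pca", "scores_pipeline",
]

#: The five life-history traits (all strictly positive where observed).
TRAITS = ("longevity", "maturity", "reproductive_events", "offspring",
          "body_mass")
#: The four traits that are mass-adjusted and enter the PCA.
ADJUSTED_TRAITS = TRAITS[:4]

TAXONOMY_COLS = ("class", "order", "family")


@dataclass(frozen=True)
class LifeHistoryScores:
    """Per-species PCA scores over the mass-adjusted traits.

    ``scores`` has columns pc1..pc3 indexed by species; ``loadings`` is the
    trait x axis matrix and ``variance_explained`` the per-axis variance
    fraction over all four axes (sums to 1).
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray

    def __post_init__(self):
        ve = np.asarray(self.variance_explained, dtype=float)
        if np.any(np.diff(ve) > 1e-9):
            raise ValueError("variance_explained must be non-increasing")


def harmonize_taxonomy(records: pd.DataFrame,
                       synonyms: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Map raw binomials onto accepted names and attach higher taxonomy.

    ``synonyms`` columns: ``raw_name``, ``accepted``, ``class``, ``order``,
    ``family``. Records whose raw name is absent from the table are dropped
    and returned in the unmatched report rather than silently discarded; a
    raw name mapping to two different accepted names is an error.
    """
    required = {"raw_name", "accepted", "class", "order", "family"}
    if not required.issubset(synonyms.columns):
        raise ValueError(f"synonym table needs columns {sorted(required)}")
    dup = synonyms.groupby("raw_name")["accepted"].nunique()
    conflicts = dup[dup > 1]
    if len(conflicts):
        raise ValueError(
            f"conflicting synonym mappings for: {list(conflicts.index)}")
    table = synonyms.drop_duplicates("raw_name").set_index("raw_name")
    if "species" not in records.columns:
        raise ValueError("records need a 'species' column")
    known = records["species"].isin(table.index)
    unmatched = sorted(records.loc[~known, "species"].unique())
    out = records.loc[known].copy()
    out["species"] = out["species"].map(table["accepted"])
    for col in TAXONOMY_COLS:
        out[col] = records.loc[known, "species"].map(table[col]).to_numpy()
    return out, unmatched


def aggregate_traits(records: pd.DataFrame) -> pd.DataFrame:
    """One row per species: geometric mean of each trait across records.

    Values are log-transformed, averaged, and back-transformed, so repeated
    estimates of a trait combine multiplicatively; missing entries are
    ignored, and a trait observed in no record stays missing. Non-positive
    observed values are rejected.
    """
    present = [t for t in TRAITS if t in records.columns]
    if not present:
        raise ValueError("no trait columns found")
    for t in present:
        bad = records[t].dropna() <= 0
        if bad.any():
            raise ValueError(
                f"non-positive value(s) in trait {t!r}: rows "
                f"{list(records.index[records[t].notna()][bad])}")
    keep_tax = [c for c in TAXONOMY_COLS if c in records.columns]

    def _agg(grp: pd.DataFrame) -> pd.Series:
        out = {}
        for t in present:
            v = grp[t].dropna().to_numpy(dtype=float)
            out[t] = float(np.exp(np.mean(np.log(v)))) if v.size else np.nan
        for c in keep_tax:
            out[c] = grp[c].iloc[0]
        return pd.Series(out)

    agg = records.groupby("species", sort=True).apply(_agg, include_groups=False)
    agg.index.name = "species"
    return agg


def phylo_eigenvectors(tree, species: Sequence[str],
                       n_eigen: int = 10) -> pd.DataFrame:
    """Leading principal coordinates of the patristic distance matrix.

    ``tree`` is a Newick string, a path to one, or a ``dendropy.Tree``.
    Returns one row per requested species with columns ``phylo_ev1..k``
    ordered by eigenvalue; species absent from the tree get NaN rows (they
    rely on the taxonomy factors downstream). Trees without branch lengths
    are rejected.
    """
    import dendropy
    from skbio import DistanceMatrix
    from skbio.stats.ordination import pcoa

    if isinstance(tree, dendropy.Tree):
        t = tree
    else:
        data = str(tree)
        if "(" not in data:  # a path, not newick text
            t = dendropy.Tree.get(path=data, schema="newick")
        else:
            t = dendropy.Tree.get(data=data, schema="newick")
    edges = [e for e in t.preorder_edge_iter() if e.head_node.parent_node]
    if any(e.length is None for e in edges):
        raise ValueError("tree must have branch lengths on all edges")

    pdm = t.phylogenetic_distance_matrix()
    taxa = sorted(t.taxon_namespace, key=lambda x: x.label)
    labels = [x.label for x in taxa]
    n = len(labels)
    if n < n_eigen + 1:
        raise ValueError(
            f"need >= {n_eigen + 1} species on the tree for {n_eigen} "
            f"eigenvectors, got {n}")
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            dm[i, j] = dm[j, i] = d
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # negative-eigenvalue advisory
        ord_res = pcoa(DistanceMatrix(dm, ids=labels), number_of_dimensions=n_eigen)
    ev = ord_res.samples.iloc[:, :n_eigen]
    ev.columns = [f"phylo_ev{k + 1}" for k in range(n_eigen)]
    return ev.reindex(species)


def impute_traits(table: pd.DataFrame, eigenvectors: pd.DataFrame | None,
                  seed: int = 0, n_trees: int = 100,
                  max_iter: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Iterative random-forest imputation of missing trait values.

    missForest-style: gaps are initialized with column medians (on the log
    scale), then each incomplete trait, in order of increasing missingness,
    is refit as a random forest on the other traits plus the phylogenetic
    eigenvectors and class/order/family factors, and its gaps re-predicted;
    iteration stops when the change in the imputed matrix increases or
    ``max_iter`` is reached, returning the previous iterate. Observed values
    are never altered. Returns the completed table and a boolean
    imputed-flag frame.
    """
    from sklearn.ensemble import RandomForestRegressor

    traits = [t for t in TRAITS if t in table.columns]
    if not traits:
        raise ValueError("no trait columns to impute")
    miss = table[traits].isna()
    all_missing = [t for t in traits if miss[t].all()]
    if all_missing:
        raise ValueError(
            f"trait(s) entirely missing, cannot impute: {all_missing}")
    if not miss.any().any():
        return table.copy(), miss

    # log scale for the positive traits
    X = np.log(table[traits].to_numpy(dtype=float))
    obs = ~np.isnan(X)
    col_median = np.nanmedian(X, axis=0)
    Ximp = np.where(obs, X, col_median)

    # fixed predictor block: eigenvectors + one-hot taxonomy
    blocks = []
    if eigenvectors is not None:
        ev = eigenvectors.reindex(table.index).to_numpy(dtype=float)
        ev = np.where(np.isnan(ev), 0.0, ev)  # off-tree species: neutral 0
        blocks.append(ev)
    tax_cols = [c for c in TAXONOMY_COLS if c in table.columns]
    if tax_cols:
        blocks.append(pd.get_dummies(table[tax_cols].astype(str))
                      .to_numpy(dtype=float))
    extra = np.hstack(blocks) if blocks else np.empty((len(table), 0))

    order = np.argsort(miss[traits].sum().to_numpy())
    rng = np.random.default_rng(seed)
    prev_delta = np.inf
    prev_X = Ximp.copy()
    for _ in range(max_iter):
        X_old = Ximp.copy()
        for ti in order:
            m = ~obs[:, ti]
            if not m.any():
                continue
            others = [k for k in range(len(traits)) if k != ti]
            pred = np.hstack([Ximp[:, others], extra])
            rf = RandomForestRegressor(
                n_estimators=n_trees, random_state=int(rng.integers(2 ** 31)),
                n_jobs=1)
            rf.fit(pred[~m], Ximp[~m, ti])
            Ximp[m, ti] = rf.predict(pred[m])
        delta = float(np.sum((Ximp - X_old) ** 2) / max(np.sum(Ximp ** 2), 1e-12))
        if delta >= prev_delta:
            Ximp = prev_X  # last improving iterate
            break
        prev_delta = delta
        prev_X = Ximp.copy()

    out = table.copy()
    filled = np.exp(Ximp)
    for k, t in enumerate(traits):
        col = table[t].to_numpy(dtype=float)
        col = np.where(obs[:, k], col, filled[:, k])
        out[t] = col
    return out, miss


def _nested_lmm_residuals(df: pd.DataFrame, trait: str) -> np.ndarray:
    """Conditional residuals of log(trait) ~ log(body_mass) with nested
    random intercepts family-in-order-in-class; degrades gracefully when a
    grouping level is singular."""
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    d = pd.DataFrame({
        "y": np.log(df[trait].to_numpy(dtype=float)),
        "logmass": np.log(df["body_mass"].to_numpy(dtype=float)),
        "cls": df["class"].astype(str).to_numpy(),
        "order": df["order"].astype(str).to_numpy(),
        "family": df["family"].astype(str).to_numpy(),
    })
    attempts = [
        {"order": "0 + C(order)", "family": "0 + C(family)"},
        {"order": "0 + C(order)"},
        None,
    ]
    for vc in attempts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                warnings.simplefilter("ignore", UserWarning)
                if vc is None and d["cls"].nunique() < 2:
                    raise ValueError("single class level")
                m = smf.mixedlm("y ~ logmass", d, groups="cls",
                                re_formula="1", vc_formula=vc)
                r = m.fit(reml=True, method="lbfgs", maxiter=200)
            return np.asarray(d["y"] - r.fittedvalues, dtype=float)
        except (np.linalg.LinAlgError, ValueError):
            continue
    # last resort: plain OLS allometry
    import statsmodels.api as sm
    X = sm.add_constant(d["logmass"])
    return np.asarray(sm.OLS(d["y"], X).fit().resid, dtype=float)


def mass_adjust(table: pd.DataFrame) -> pd.DataFrame:
    """Remove body-mass allometry and kinship from the four non-mass traits.

    Each of longevity, maturity, reproductive_events, offspring is
    log-regressed on log body mass with family-within-order-within-class
    random intercepts; the conditional residuals (random intercepts
    subtracted) are the mass- and kinship-adjusted traits.
    """
    need = set(ADJUSTED_TRAITS) | {"body_mass"} | set(TAXONOMY_COLS)
    missing = need - set(table.columns)
    if missing:
        raise ValueError(f"mass_adjust needs columns {sorted(missing)}")
    if table[list(TRAITS)].isna().any().any():
        raise ValueError("mass_adjust needs a complete trait table")
    out = pd.DataFrame(index=table.index)
    for t in ADJUSTED_TRAITS:
        out[t] = _nested_lmm_residuals(table, t)
    return out


def fast_slow_pca(residuals: pd.DataFrame) -> LifeHistoryScores:
    """PCA of the adjusted traits, oriented so that fast species score high.

    Columns are centered and scaled to unit variance (correlation-matrix
    PCA). PC1's sign is fixed so offspring (fallback: reproductive_events)
    loads positively — high PC1 = fecund, short-lived, fast; remaining axes
    get a deterministic largest-loading-positive orientation.
    """
    from sklearn.decomposition import PCA

    cols = [t for t in ADJUSTED_TRAITS if t in residuals.columns]
    if len(cols) < 2 or len(residuals) < 4:
        raise ValueError("need >= 4 species and >= 2 adjusted traits")
    X = residuals[cols].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd < 1e-12):
        const = [c for c, s in zip(cols, sd) if s < 1e-12]
        raise ValueError(f"constant trait column(s): {const}")
    Z = (X - X.mean(axis=0)) / sd
    k = min(len(cols), len(residuals) - 1)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(Z)
    load = pca.components_.T  # trait x axis

    orient_trait = "offspring" if "offspring" in cols else "reproductive_events"
    oi = cols.index(orient_trait)
    for ax in range(k):
        if ax == 0:
            flip = load[oi, 0] < 0
        else:
            flip = load[np.argmax(np.abs(load[:, ax])), ax] < 0
        if flip:
            load[:, ax] *= -1
            scores[:, ax] *= -1

    axes = [f"pc{i + 1}" for i in range(k)]
    return LifeHistoryScores(
        scores=pd.DataFrame(scores[:, :3], index=residuals.index,
                            columns=axes[:3]),
        loadings=pd.DataFrame(load, index=cols, columns=axes),
        variance_explained=pca.explained_variance_ratio_,
    )


def scores_pipeline(records: pd.DataFrame, synonyms: pd.DataFrame,
                    tree, seed: int = 0) -> tuple[LifeHistoryScores, dict]:
    """Records-to-scores convenience wrapper; returns scores and run metadata."""
    harmonized, unmatched = harmonize_taxonomy(records, synonyms)
    table = aggregate_traits(harmonized)
    ev = phylo_eigenvectors(tree, list(table.index))
    completed, flags = impute_traits(table, ev, seed=seed)
    residuals = mass_adjust(completed)
    scores = fast_slow_pca(residuals)
    meta = {"unmatched": unmatched, "n_imputed": int(flags.to_numpy().sum()),
            "seed": seed}
    return scores, meta
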