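"""Synthetic populations, traits, phylogeny, and environment with known truth.

The generator is the inverse of the analysis: it draws a latent fast-slow
axis and body mass per species, builds traits from allometry plus opposing
fast-slow loadings (ageing traits load against fecundity traits), simulates
per-site temperature (linear trend + seasonal cycle + noise) and land-cover
fraction series (directional transfer between two classes, closed to sum 1),
and then grows each population's abundance multiplicatively,

    n_t = n_{t-1} * 10 ** (lambda_pop + eps_t),

where lambda_pop is the model's linear predictor evaluated at the true
covariates plus species and site random intercepts. Missing years (MCAR)
and zero counts are injected afterwards. Every drawn quantity is recorded
in :class:`GroundTruth` so downstream stages can be tested for recovery.
"""

from __future__ import annotations

import dataclasses
import json
import random as _pyrandom
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from fastslow.envchange import FINAL_CLASSES
from fastslow.poptrends import PopulationSeries, write_populations_wide

__all__ = ["SimConfig", "GroundTruth", "SimData", "generate_traits",
           "generate_environment", "generate_populations", "generate",
           "write_outputs"]

#: Trait loadings on the latent fast-slow axis (latent high = fast), at
#: tradeoff_strength 1. Ageing traits oppose fecundity traits.
TRAIT_LOADINGS = {"longevity": -0.5, "maturity": -0.5,
                  "reproductive_events": 0.5, "offspring": 0.5}

#: Allometric intercept and slope of each log trait on log body mass.
ALLOMETRY = {"longevity": (0.5, 0.20), "maturity": (-1.0, 0.25),
             "reproductive_events": (1.0, -0.15), "offspring": (1.0, -0.10)}

#: Default generating coefficients: the final-model structure of the study
#: system (trends respond to cropland and bare-soil change, the fast-slow
#: score, and their interactions; warming main effect near zero).
DEFAULT_BETA = {
    "Intercept": 0.0025,
    "delta_t": 0.0246,
    "pc1": 0.0052,
    "lc_cropland": -1.4974,
    "lc_bare_soil": 5.1349,
    "pc1:lc_cropland": 1.896,
    "pc1:lc_bare_soil": 2.7376,
    "delta_t:lc_bare_soil": -718.4483,
}


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the generative model; defaults are the study conditions."""

    n_species: int = 60
    n_populations: int = 300
    n_sites: int = 80
    year_range: tuple[int, int] = (1992, 2018)
    missing_rate: float = 0.15
    zero_rate: float = 0.03
    beta: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    sigma_species: float = 0.01
    sigma_site: float = 0.01
    sigma_resid: float = 0.02
    tradeoff_strength: float = 1.0
    trait_noise: float = 0.10
    trait_missing_rate: float = 0.0
    temp_slope_mean: float = 0.02
    temp_slope_sd: float = 0.02
    temp_noise: float = 0.5
    cover_change_sd: float = 0.004
    cover_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("missing_rate", "zero_rate", "trait_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("sigma_species", "sigma_site", "sigma_resid",
                     "tradeoff_strength", "trait_noise", "temp_noise",
                     "cover_change_sd", "cover_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.year_range
        if hi - lo + 1 < 5:
            raise ValueError("year_range must span >= 5 years")
        for name in ("n_species", "n_populations", "n_sites"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class GroundTruth:
    """Everything the generator drew, for recovery tests."""

    beta: dict[str, float]
    species_effects: dict[str, float] = field(default_factory=dict)
    site_effects: dict[str, float] = field(default_factory=dict)
    latent_fastslow: dict[str, float] = field(default_factory=dict)
    temp_slopes: dict[str, float] = field(default_factory=dict)
    cover_rates: dict[str, dict[str, float]] = field(default_factory=dict)
    pop_lambda: dict[str, float] = field(default_factory=dict)
    pop_assignments: dict[str, tuple[str, str]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["pop_assignments"] = {k: list(v) for k, v in
                                      self.pop_assignments.items()}
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class SimData:
    """Bundle returned by :func:`generate`."""

    config: SimConfig
    traits: pd.DataFrame
    tree_newick: str
    temperature: pd.DataFrame   # site_id, year, month, temperature
    landcover: pd.DataFrame     # site_id, year, lc_* fraction columns
    sites: pd.DataFrame         # site_id, latitude, longitude
    populations: list[PopulationSeries]
    synonyms: pd.DataFrame
    truth: GroundTruth


def _rngs(config: SimConfig, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(config.seed).spawn(n)]


def _species_names(n: int) -> list[str]:
    return [f"Genus{i // 4:03d} species{i:03d}" for i in range(n)]


def _taxonomy(names: list[str]) -> pd.DataFrame:
    classes = ["Aves", "Mammalia", "Reptilia"]
    rows = []
    for i, sp in enumerate(names):
        rows.append({
            "species": sp,
            "class": classes[i % 3],
            "order": f"Order{(i // 12) * 3 + i % 3:03d}",
            "family": f"Family{(i // 4) * 3 + i % 3:03d}",
        })
    return pd.DataFrame(rows).set_index("species")


def _simulate_tree(names: list[str], seed: int) -> str:
    import dendropy
    from dendropy.simulate import treesim

    tns = dendropy.TaxonNamespace(names)
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=len(names),
        taxon_namespace=tns, rng=_pyrandom.Random(seed))
    return tree.as_string(schema="newick").strip()


def generate_traits(config: SimConfig
                    ) -> tuple[pd.DataFrame, str, GroundTruth]:
    """Species trait table, ultrametric phylogeny, and the latent axis.

    Log traits are allometric in log body mass plus an opposing-loading
    contribution of the latent fast-slow value scaled by
    ``tradeoff_strength`` plus Gaussian noise; a fraction
    ``trait_missing_rate`` of non-mass entries is masked as missing.
    """
    if config.n_species < 4:
        raise ValueError("n_species must be >= 4 to generate traits")
    rng_lat, rng_mass, rng_noise, rng_tree, rng_mask = _rngs(config, 5)
    names = _species_names(config.n_species)
    latent = rng_lat.normal(0.0, 1.0, config.n_species)
    log_mass = rng_mass.normal(5.0, 2.0, config.n_species)

    table = _taxonomy(names)
    table["body_mass"] = np.exp(log_mass)
    for trait, (a, b) in ALLOMETRY.items():
        loading = TRAIT_LOADINGS[trait] * config.tradeoff_strength
        noise = (rng_noise.normal(0.0, config.trait_noise, config.n_species)
                 if config.trait_noise > 0 else 0.0)
        table[trait] = np.exp(a + b * log_mass + loading * latent + noise)

    if config.trait_missing_rate > 0:
        for trait in ALLOMETRY:
            mask = rng_mask.random(config.n_species) < config.trait_missing_rate
            table.loc[mask, trait] = np.nan

    newick = _simulate_tree(names, int(rng_tree.integers(2 ** 31)))
    truth = GroundTruth(beta=dict(config.beta),
                        latent_fastslow=dict(zip(names, latent.tolist())))
    cols = ["class", "order", "family", "longevity", "maturity",
            "reproductive_events", "offspring", "body_mass"]
    return table[cols], newick, truth


def generate_environment(config: SimConfig, truth: GroundTruth | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                                    GroundTruth]:
    """Per-site monthly temperatures and annual cover fractions.

    Temperature: site base level + true linear trend + seasonal cosine +
    noise. Cover: a Dirichlet baseline with a linear directional transfer
    between the two largest classes (per-class true rates sum to zero);
    fractions are renormalized to sum to 1 each year. Returns
    (temperature, landcover, sites, truth).
    """
    truth = truth or GroundTruth(beta=dict(config.beta))
    rng_site, rng_temp, rng_cov = _rngs(config, 8)[5:]
    y0, y1 = config.year_range
    years = np.arange(y0, y1 + 1)
    site_ids = [f"site{i:04d}" for i in range(config.n_sites)]
    sites = pd.DataFrame({
        "site_id": site_ids,
        "latitude": rng_site.uniform(-60, 70, config.n_sites),
        "longitude": rng_site.uniform(-180, 180, config.n_sites),
    })

    temp_rows, cov_rows = [], []
    for sid in site_ids:
        base = rng_temp.normal(10.0, 8.0)
        slope = rng_temp.normal(config.temp_slope_mean, config.temp_slope_sd)
        amp = rng_temp.uniform(3.0, 10.0)
        truth.temp_slopes[sid] = float(slope)
        for y in years:
            for m in range(1, 13):
                noise = (rng_temp.normal(0.0, config.temp_noise)
                         if config.temp_noise > 0 else 0.0)
                temp_rows.append((sid, int(y), m,
                                  base + slope * (y - y0)
                                  + amp * np.cos(2 * np.pi * (m - 7) / 12)
                                  + noise))

        f0 = rng_cov.dirichlet(np.ones(len(FINAL_CLASSES)) * 2.0)
        donor, recip = np.argsort(f0)[-2:]
        horizon = len(years) - 1
        r_max = 0.8 * min(f0[donor], 1 - f0[recip]) / horizon
        rate = float(np.clip(rng_cov.normal(0.0, config.cover_change_sd),
                             -r_max, r_max))
        true_rates = {c: 0.0 for c in FINAL_CLASSES}
        true_rates[FINAL_CLASSES[donor]] = -rate
        true_rates[FINAL_CLASSES[recip]] = rate
        truth.cover_rates[sid] = true_rates
        for k, y in enumerate(years):
            f = f0.copy()
            f[donor] -= rate * k
            f[recip] += rate * k
            if config.cover_noise > 0:
                f = np.clip(f + rng_cov.normal(0, config.cover_noise, f.size),
                            0, None)
            f = f / f.sum()
            cov_rows.append((sid, int(y), *f))

    temperature = pd.DataFrame(temp_rows, columns=["site_id", "year", "month",
                                                   "temperature"])
    landcover = pd.DataFrame(
        cov_rows, columns=["site_id", "year",
                           *[f"lc_{c}" for c in FINAL_CLASSES]])
    return temperature, landcover, sites, truth


def _linear_predictor(beta: Mapping[str, float], covars: Mapping[str, float]
                      ) -> float:
    total = float(beta.get("Intercept", 0.0))
    for term, b in beta.items():
        if term == "Intercept":
            continue
        x = 1.0
        for comp in term.split(":"):
            if comp not in covars:
                raise ValueError(f"beta term {term!r}: unknown covariate "
                                 f"{comp!r}")
            x *= covars[comp]
        total += b * x
    return total


def generate_populations(config: SimConfig, traits: pd.DataFrame,
                         sites: pd.DataFrame, truth: GroundTruth
                         ) -> tuple[list[PopulationSeries], GroundTruth]:
    """Abundance series from the generative trend model.

    Each population gets a species and a site; its expected annual log10
    rate is the linear predictor at the true covariates (warming slope,
    latent fast-slow value, true cover rates) plus species and site
    intercepts; yearly noise is applied on the log10 scale; missing years
    (first and last records protected, so the span is known) and zeros are
    injected afterwards.
    """
    (rng_assign, rng_eff, rng_walk, rng_miss, rng_zero) = [
        np.random.default_rng(s) for s in
        np.random.SeedSequence((config.seed, 17)).spawn(5)]
    species = list(traits.index)
    site_ids = list(sites["site_id"])
    site_pos = sites.set_index("site_id")

    truth.species_effects = {
        sp: float(rng_eff.normal(0, config.sigma_species)) for sp in species}
    truth.site_effects = {
        s: float(rng_eff.normal(0, config.sigma_site)) for s in site_ids}

    y0, y1 = config.year_range
    n_years = y1 - y0 + 1
    pops: list[PopulationSeries] = []
    for i in range(config.n_populations):
        pid = f"pop{i:05d}"
        sp = species[int(rng_assign.integers(len(species)))]
        sid = site_ids[int(rng_assign.integers(len(site_ids)))]
        covars = {"delta_t": truth.temp_slopes[sid],
                  "pc1": truth.latent_fastslow[sp]}
        covars.update({f"lc_{c}": r for c, r in truth.cover_rates[sid].items()})
        lam = (_linear_predictor(config.beta, covars)
               + truth.species_effects[sp] + truth.site_effects[sid])
        truth.pop_lambda[pid] = float(lam)
        truth.pop_assignments[pid] = (sp, sid)

        length = int(rng_assign.integers(6, n_years + 1))
        start = y0 + int(rng_assign.integers(0, n_years - length + 1))
        yrs = np.arange(start, start + length)
        log_n = np.empty(length)
        log_n[0] = rng_walk.normal(2.0, 0.5)
        steps = lam + (rng_walk.normal(0, config.sigma_resid, length - 1)
                       if config.sigma_resid > 0 else np.zeros(length - 1))
        log_n[1:] = log_n[0] + np.cumsum(steps)
        abundance = 10.0 ** log_n

        observed = np.ones(length, dtype=bool)
        if config.missing_rate > 0 and length > 2:
            interior = rng_miss.random(length - 2) < config.missing_rate
            observed[1:-1] = ~interior
        records = {}
        for y, a, obs in zip(yrs, abundance, observed):
            if not obs:
                continue
            if config.zero_rate > 0 and rng_zero.random() < config.zero_rate:
                records[int(y)] = 0.0
            else:
                records[int(y)] = float(a)
        pops.append(PopulationSeries(
            population_id=pid, species=sp, location_id=sid,
            latitude=float(site_pos.loc[sid, "latitude"]),
            longitude=float(site_pos.loc[sid, "longitude"]),
            records=records))
    return pops, truth


def simulate_model_frame(config: SimConfig,
                         lambda_noise_sd: float = 0.01) -> tuple[pd.DataFrame,
                                                                 GroundTruth]:
    """A ready-made analysis frame drawn from the generative trend model.

    Skips the abundance-series layer: the response is the population's
    expected trend (linear predictor + species and site intercepts) plus
    Gaussian noise with ``lambda_noise_sd`` (the sampling error a mean of
    yearly rates would carry). Used for estimator-calibration experiments
    where the series machinery is exercised separately.
    """
    traits, _, truth = generate_traits(config)
    _, _, sites, truth = generate_environment(config, truth)
    rng_frame = np.random.default_rng(
        np.random.SeedSequence((config.seed, 23)))
    species = list(traits.index)
    site_ids = list(sites["site_id"])
    truth.species_effects = {
        sp: float(rng_frame.normal(0, config.sigma_species)) for sp in species}
    truth.site_effects = {
        s: float(rng_frame.normal(0, config.sigma_site)) for s in site_ids}
    rows = []
    for i in range(config.n_populations):
        pid = f"pop{i:05d}"
        sp = species[int(rng_frame.integers(len(species)))]
        sid = site_ids[int(rng_frame.integers(len(site_ids)))]
        covars = {"delta_t": truth.temp_slopes[sid],
                  "pc1": truth.latent_fastslow[sp]}
        covars.update({f"lc_{c}": r for c, r in truth.cover_rates[sid].items()})
        lam = (_linear_predictor(config.beta, covars)
               + truth.species_effects[sp] + truth.site_effects[sid])
        truth.pop_lambda[pid] = float(lam)
        truth.pop_assignments[pid] = (sp, sid)
        row = {"population_id": pid, "species": sp, "location_id": sid,
               "mean_lambda": lam + rng_frame.normal(0, lambda_noise_sd),
               **covars}
        rows.append(row)
    return pd.DataFrame(rows), truth


def generate(config: SimConfig) -> SimData:
    """Run all three generators under one config (deterministic in seed)."""
    traits, newick, truth = generate_traits(config)
    temperature, landcover, sites, truth = generate_environment(config, truth)
    pops, truth = generate_populations(config, traits, sites, truth)
    synonyms = pd.DataFrame({
        "raw_name": traits.index, "accepted": traits.index,
        "class": traits["class"].to_numpy(),
        "order": traits["order"].to_numpy(),
        "family": traits["family"].to_numpy(),
    })
    return SimData(config=config, traits=traits, tree_newick=newick,
                   temperature=temperature, landcover=landcover, sites=sites,
                   populations=pops, synonyms=synonyms, truth=truth)


def write_outputs(data: SimData, outdir) -> dict[str, str]:
    """Write the bundle as plain-text files (CSV / Newick / JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "populations": out / "populations.csv",
        "traits": out / "traits.csv",
        "tree": out / "tree.nwk",
        "temperature": out / "temperature.csv",
        "landcover": out / "landcover.csv",
        "sites": out / "sites.csv",
        "synonyms": out / "synonyms.csv",
        "truth": out / "truth.json",
    }
    write_populations_wide(data.populations, paths["populations"])
    data.traits.to_csv(paths["traits"])
    paths["tree"].write_text(data.tree_newick + "\n")
    data.temperature.to_csv(paths["temperature"], index=False)
    data.landcover.to_csv(paths["landcover"], index=False)
    data.sites.to_csv(paths["sites"], index=False)
    data.synonyms.to_csv(paths["synonyms"], index=False)
    data.truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
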