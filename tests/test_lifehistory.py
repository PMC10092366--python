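"""Taxonomy harmonization, trait aggregation, imputation, mass adjustment,
and the fast-slow PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from fastslow.lifehistory import (
    aggregate_traits, fast_slow_pca, harmonize_taxonomy, impute_traits,
    mass_adjust, phylo_eigenvectors,
)
from fastslow.synthdata import SimConfig, generate_traits


@pytest.fixture(scope="module")
def trait_sim():
    cfg = SimConfig(n_species=40, seed=11, trait_noise=0.05)
    table, newick, truth = generate_traits(cfg)
    return table, newick, truth


class TestHarmonize:
    SYN = pd.DataFrame({
        "raw_name": ["Aus bus", "Aus cus", "Old name"],
        "accepted": ["Aus bus", "Aus cus", "Aus bus"],
        "class": ["Aves"] * 3, "order": ["O1"] * 3, "family": ["F1"] * 3,
    })

    def test_accepted_name_unchanged_and_synonym_mapped(self):
        rec = pd.DataFrame({"species": ["Aus bus", "Old name"],
                            "longevity": [4.0, 6.0]})
        out, unmatched = harmonize_taxonomy(rec, self.SYN)
        assert list(out["species"]) == ["Aus bus", "Aus bus"]
        assert unmatched == []

    def test_unknown_name_reported_not_dropped_silently(self):
        rec = pd.DataFrame({"species": ["Nemo nobody"], "longevity": [2.0]})
        out, unmatched = harmonize_taxonomy(rec, self.SYN)
        assert out.empty and unmatched == ["Nemo nobody"]

    def test_conflicting_mapping_rejected(self):
        bad = pd.concat([self.SYN, pd.DataFrame({
            "raw_name": ["Old name"], "accepted": ["Aus cus"],
            "class": ["Aves"], "order": ["O1"], "family": ["F1"]})])
        with pytest.raises(ValueError, match="conflicting"):
            harmonize_taxonomy(pd.DataFrame({"species": ["Old name"]}), bad)


class TestAggregate:
    def test_geometric_mean(self):
        rec = pd.DataFrame({"species": ["A a"] * 2, "longevity": [2.0, 8.0]})
        assert aggregate_traits(rec)["longevity"].iloc[0] == pytest.approx(4.0)

    def test_single_value_identity_and_constant(self):
        rec = pd.DataFrame({"species": ["A a", "B b", "B b", "B b"],
                            "offspring": [3.0, 5.0, 5.0, 5.0]})
        out = aggregate_traits(rec)
        assert out.loc["A a", "offspring"] == pytest.approx(3.0)
        assert out.loc["B b", "offspring"] == pytest.approx(5.0)

    def test_permutation_invariant_across_sources(self):
        rec = pd.DataFrame({"species": ["A a"] * 3, "source": ["x", "y", "z"],
                            "maturity": [1.0, 2.0, 4.0]})
        a = aggregate_traits(rec)
        b = aggregate_traits(rec.iloc[::-1].reset_index(drop=True))
        assert a["maturity"].iloc[0] == pytest.approx(b["maturity"].iloc[0])

    def test_nonpositive_rejected(self):
        rec = pd.DataFrame({"species": ["A a"], "body_mass": [-1.0]})
        with pytest.raises(ValueError, match="non-positive"):
            aggregate_traits(rec)


class TestPhyloEigenvectors:
    def test_two_clades_separated_by_sign(self):
        # brute-force oracle: Gower-centred -D^2/2 eigendecomposition
        nwk = ("((a:1,b:1):10,(c:1,(d:0.5,e:0.5):0.5):10):0;")
        species = list("abcde")
        ev = phylo_eigenvectors(nwk, species, n_eigen=3)
        first = ev["phylo_ev1"]
        assert set(np.sign(first[["a", "b"]])) != set(np.sign(first[["c", "d", "e"]]))

    def test_matches_brute_force_pcoa_on_six_taxa(self):
        import dendropy
        nwk = "((a:2,b:2):3,((c:1,d:1):1,(e:1,f:1):1):3):0;"
        species = list("abcdef")
        ev = phylo_eigenvectors(nwk, species, n_eigen=2)
        # independent oracle: patristic matrix by hand-coded path sums
        t = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        D = np.array([[pdm.patristic_distance(taxa[i], taxa[j])
                       for j in species] for i in species])
        A = -0.5 * D ** 2
        J = np.eye(6) - np.ones((6, 6)) / 6
        G = J @ A @ J
        w, v = np.linalg.eigh(G)
        lead = v[:, np.argmax(w)] * np.sqrt(w.max())
        got = ev["phylo_ev1"].to_numpy()
        assert np.allclose(np.abs(got), np.abs(lead), atol=1e-8)

    def test_missing_species_get_nan(self):
        nwk = "((a:1,b:1):1,(c:1,d:1):1):0;"
        ev = phylo_eigenvectors(nwk, ["a", "zz"], n_eigen=2)
        assert ev.loc["zz"].isna().all() and not ev.loc["a"].isna().any()

    def test_lengthless_tree_rejected(self):
        with pytest.raises(ValueError, match="branch lengths"):
            phylo_eigenvectors("((a,b),(c,d));", ["a"], n_eigen=2)


class TestImputeTraits:
    def test_complete_table_unchanged(self, trait_sim):
        table, newick, _ = trait_sim
        ev = phylo_eigenvectors(newick, list(table.index))
        out, flags = impute_traits(table, ev, seed=0)
        pd.testing.assert_frame_equal(out, table)
        assert not flags.to_numpy().any()

    def test_observed_never_altered_and_deterministic(self, trait_sim):
        table, newick, _ = trait_sim
        ev = phylo_eigenvectors(newick, list(table.index))
        rng = np.random.default_rng(5)
        masked = table.copy()
        mask = rng.random(table[["longevity", "offspring"]].shape) < 0.3
        masked.loc[:, ["longevity", "offspring"]] = table[
            ["longevity", "offspring"]].where(~mask)
        out1, flags = impute_traits(masked, ev, seed=3)
        out2, _ = impute_traits(masked, ev, seed=3)
        pd.testing.assert_frame_equal(out1, out2)
        obs = masked["longevity"].notna()
        assert (out1.loc[obs, "longevity"] == masked.loc[obs, "longevity"]).all()
        assert flags.loc[~obs, "longevity"].all()

    def test_beats_median_imputation_on_correlated_traits(self, trait_sim):
        """Masking experiment with known truth: RF imputation error is below
        that of column-median imputation."""
        table, newick, _ = trait_sim
        ev = phylo_eigenvectors(newick, list(table.index))
        rng = np.random.default_rng(8)
        masked = table.copy()
        cells = []
        for t in ("longevity", "maturity", "offspring"):
            m = rng.random(len(table)) < 0.2
            masked.loc[m, t] = np.nan
            cells.append((t, m))
        out, _ = impute_traits(masked, ev, seed=1)
        rf_err, med_err = 0.0, 0.0
        for t, m in cells:
            true = np.log(table.loc[m, t].to_numpy())
            rf_err += np.sum((np.log(out.loc[m, t].to_numpy()) - true) ** 2)
            med = np.nanmedian(np.log(masked[t].to_numpy(dtype=float)))
            med_err += np.sum((med - true) ** 2)
        assert rf_err < med_err

    def test_fully_missing_species_imputed_and_flagged(self, trait_sim):
        table, newick, _ = trait_sim
        ev = phylo_eigenvectors(newick, list(table.index))
        masked = table.copy()
        sp = masked.index[0]
        masked.loc[sp, list(masked.columns[3:])] = np.nan
        out, flags = impute_traits(masked, ev, seed=2)
        assert not out.loc[sp].isna().any()
        assert flags.loc[sp].all()

    def test_trait_missing_everywhere_rejected(self, trait_sim):
        table, newick, _ = trait_sim
        masked = table.copy()
        masked["maturity"] = np.nan
        with pytest.raises(ValueError, match="entirely missing"):
            impute_traits(masked, None, seed=0)


class TestMassAdjust:
    def test_pure_allometry_residuals_near_zero(self):
        cfg = SimConfig(n_species=30, seed=4, tradeoff_strength=0.0,
                        trait_noise=0.0)
        table, _, _ = generate_traits(cfg)
        res = mass_adjust(table)
        assert np.abs(res.to_numpy()).max() < 1e-6

    def test_residuals_uncorrelated_with_log_mass(self, trait_sim):
        table, _, _ = trait_sim
        res = mass_adjust(table)
        logm = np.log(table["body_mass"].to_numpy())
        for t in res.columns:
            assert abs(np.corrcoef(res[t], logm)[0, 1]) < 1e-6

    def test_family_offset_preserves_within_family_ordering(self, trait_sim):
        table, _, _ = trait_sim
        fam = table["family"].iloc[0]
        shifted = table.copy()
        shifted.loc[shifted["family"] == fam, "longevity"] *= 3.0
        base = mass_adjust(table)
        moved = mass_adjust(shifted)
        sel = table["family"] == fam
        assert (np.argsort(base.loc[sel, "longevity"].to_numpy()) ==
                np.argsort(moved.loc[sel, "longevity"].to_numpy())).all()


class TestFastSlowPCA:
    def test_latent_axis_recovered_with_fast_orientation(self, trait_sim):
        table, _, truth = trait_sim
        scores = fast_slow_pca(mass_adjust(table))
        # dominant first axis, fecundity loads positive, ageing negative
        assert scores.variance_explained[0] > 0.5
        assert scores.loadings.loc["offspring", "pc1"] > 0
        assert scores.loadings.loc["reproductive_events", "pc1"] > 0
        assert scores.loadings.loc["longevity", "pc1"] < 0
        assert scores.loadings.loc["maturity", "pc1"] < 0
        lat = pd.Series(truth.latent_fastslow).loc[scores.scores.index]
        rho = spearmanr(scores.scores["pc1"], lat)[0]
        assert rho > 0.9

    def test_variance_fractions_sum_to_one(self, trait_sim):
        table, _, _ = trait_sim
        scores = fast_slow_pca(mass_adjust(table))
        assert scores.variance_explained.sum() == pytest.approx(1.0)

    def test_scores_centred_and_orthogonal(self, trait_sim):
        table, _, _ = trait_sim
        s = fast_slow_pca(mass_adjust(table)).scores
        assert np.allclose(s.mean(), 0.0, atol=1e-9)
        c = np.cov(s.to_numpy().T)
        assert abs(c[0, 1]) < 1e-9 and abs(c[0, 2]) < 1e-9

    def test_mirrored_input_flips_scores_not_magnitudes(self, trait_sim):
        table, _, _ = trait_sim
        res = mass_adjust(table)
        a = fast_slow_pca(res)
        b = fast_slow_pca(-res)
        assert np.allclose(np.abs(a.scores["pc1"]), np.abs(b.scores["pc1"]),
                           atol=1e-9)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"longevity": [1.0] * 5,
                           "offspring": [0.1, 0.2, 0.3, 0.4, 0.5],
                           "maturity": [0.2, 0.1, 0.5, 0.3, 0.4],
                           "reproductive_events": [0.5, 0.1, 0.2, 0.4, 0.3]})
        with pytest.raises(ValueError, match="constant"):
            fast_slow_pca(df)
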