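"""Species partitioning, correction factors, expression filter, CPM/PCA, NB DE."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asoctools import (
    CocultureDE,
    CocultureSimConfig,
    SpeciesCountMatrix,
    cpm,
    expression_filter,
    fit_nb_de,
    pca_embed,
    represent_genes,
    simulate_coculture_counts,
    split_by_species,
)


def toy_matrix(counts, n_h, groups=("A", "A", "B", "B")):
    counts = pd.DataFrame(
        np.asarray(counts),
        index=[f"t{i}" for i in range(len(counts))],
        columns=[f"s{j}" for j in range(np.asarray(counts).shape[1])],
    )
    species = pd.Series(["human"] * n_h + ["mouse"] * (len(counts) - n_h),
                        index=counts.index)
    grp = pd.Series(list(groups), index=counts.columns)
    return SpeciesCountMatrix(counts=counts, species=species, groups=grp)


class TestSplitBySpecies:
    def test_partition_and_conservation(self):
        m = toy_matrix([[1, 2, 3, 4], [5, 6, 7, 8], [9, 10, 11, 12],
                        [2, 2, 2, 2], [1, 1, 1, 1]], n_h=3)
        h, mo, cf = split_by_species(m)
        assert h.shape[0] == 3 and mo.shape[0] == 2
        np.testing.assert_array_equal(
            h.sum(axis=0) + mo.sum(axis=0), m.counts.sum(axis=0))

    def test_equal_totals_give_unit_ratio(self):
        m = toy_matrix([[10, 20, 30, 40], [10, 20, 30, 40]], n_h=1)
        _, _, cf = split_by_species(m)
        np.testing.assert_allclose(cf.ratio, 1.0)

    def test_zero_species_total_names_sample(self):
        m = toy_matrix([[5, 5, 5, 5], [3, 0, 3, 3]], n_h=1)
        with pytest.raises(ValueError, match="s1"):
            split_by_species(m)

    def test_simulated_ratio_recovered(self):
        cfg = CocultureSimConfig(n_transcripts_h=3000, n_transcripts_m=3000,
                                 n_samples_per_group=3, ratio_mean=2.0,
                                 ratio_sd=0.0, frac_de_h=0, frac_de_m=0,
                                 nb_dispersion=0.02, dropout_prob=0.0, seed=4)
        m, truth = simulate_coculture_counts(cfg)
        _, _, cf = split_by_species(m)
        np.testing.assert_allclose(cf.ratio, 2.0, rtol=0.1)

    def test_missing_species_label_rejected(self):
        counts = pd.DataFrame([[1, 1, 1, 1]], index=["t0"],
                              columns=["s0", "s1", "s2", "s3"])
        with pytest.raises(ValueError, match="species label missing"):
            SpeciesCountMatrix(counts=counts,
                               species=pd.Series(dtype=object))


class TestExpressionFilter:
    def test_threshold_boundaries_on_nine_samples(self):
        counts = pd.DataFrame(
            [[1] * 6 + [0] * 3,     # 6/9 = 66.7% -> removed
             [1] * 7 + [0] * 2,     # 7/9 = 77.8% -> retained
             [0] * 9],              # never expressed -> removed
            index=["six", "seven", "zero"],
            columns=[f"s{j}" for j in range(9)],
        )
        kept = expression_filter(counts, 0.75)
        assert kept.index.tolist() == ["seven"]

    def test_exact_three_quarters_passes(self):
        counts = pd.DataFrame([[1, 1, 1, 0]], index=["t"],
                              columns=list("abcd"))
        assert len(expression_filter(counts, 0.75)) == 1


class TestCPM:
    def test_normalisation_identity(self):
        counts = pd.DataFrame({"s0": [10], "s1": [3]}, index=["t"])
        out = cpm(counts, library_sizes=pd.Series({"s0": 10, "s1": 3}))
        np.testing.assert_allclose(out.to_numpy(), [[1e6, 1e6]])

    def test_column_sums_to_one_million(self, rng):
        counts = pd.DataFrame(rng.integers(0, 100, size=(50, 4)))
        np.testing.assert_allclose(cpm(counts).sum(axis=0), 1e6)

    def test_scale_invariance(self, rng):
        counts = pd.DataFrame(rng.integers(1, 100, size=(30, 3)))
        pd.testing.assert_frame_equal(cpm(counts), cpm(counts * 2))

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s0": [0, 0]})
        with pytest.raises(ValueError, match="positive"):
            cpm(counts)


class TestPCA:
    def test_two_cluster_geometry(self):
        a = np.tile([[100.0], [10.0], [50.0]], (1, 3))
        b = np.tile([[10.0], [100.0], [50.0]], (1, 3))
        mat = pd.DataFrame(np.hstack([a, b]))
        coords, evr = pca_embed(mat, n_components=2, log_transform=False)
        pc1 = coords["PC1"].to_numpy()
        assert np.sign(pc1[:3]).tolist() != np.sign(pc1[3:]).tolist()
        assert evr[0] == pytest.approx(1.0)
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1 + 1e-9

    def test_identical_samples_zero_variance(self):
        mat = pd.DataFrame(np.tile([[5.0], [7.0], [1.0]], (1, 4)))
        _, evr = pca_embed(mat, n_components=2)
        np.testing.assert_allclose(evr, 0.0, atol=1e-12)

    def test_sample_count_guard(self):
        mat = pd.DataFrame([[1.0]])
        with pytest.raises(ValueError):
            pca_embed(mat, n_components=2)

    def test_planted_groups_separate_with_high_silhouette(self):
        from sklearn.metrics import silhouette_score

        cfg = CocultureSimConfig(n_transcripts_h=800, n_transcripts_m=600,
                                 frac_de_h=0.3, frac_de_m=0.3, log2fc=2.0,
                                 seed=12)
        m, _ = simulate_coculture_counts(cfg)
        model = CocultureDE().fit(m)
        score = silhouette_score(model.pca_.to_numpy(), m.groups.to_numpy())
        assert score > 0.5


class TestFitNBDE:
    def test_identical_counts_give_null_result(self):
        counts = pd.DataFrame(np.full((5, 6), 40),
                              columns=[f"s{j}" for j in range(6)])
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
        res = fit_nb_de(counts, groups)
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-8)
        np.testing.assert_allclose(res["p_value"], 1.0, atol=1e-8)

    def test_poisson_limit_matches_exact_binomial_oracle(self):
        # 2 samples per group, dispersion -> 0, equal offsets: conditional on
        # the total, the group-A sum is Binomial(total, 1/2) under H0
        counts = pd.DataFrame([[300, 290, 260, 270], [150, 145, 130, 138]],
                              columns=list("abcd"))
        groups = pd.Series(["A", "A", "B", "B"], index=counts.columns)
        res = fit_nb_de(counts, groups, offsets=pd.Series(0.0, index=counts.columns),
                        dispersion=0.0)
        for i in range(2):
            y = counts.iloc[i].to_numpy()
            x, n = y[:2].sum(), y.sum()
            p_oracle = stats.binomtest(int(x), int(n), 0.5).pvalue
            assert res["p_value"][i] == pytest.approx(p_oracle, rel=0.10)

    def test_group_size_guard_and_zero_rows(self):
        counts = pd.DataFrame(np.ones((3, 3)), columns=list("abc"))
        groups = pd.Series(["A", "A", "B"], index=counts.columns)
        with pytest.raises(ValueError, match=">= 2 samples"):
            fit_nb_de(counts, groups)
        counts4 = pd.DataFrame(
            [[5, 5, 5, 5], [0, 0, 0, 0]], columns=list("abcd"))
        res = fit_nb_de(counts4, pd.Series(["A", "A", "B", "B"],
                                           index=counts4.columns))
        assert len(res) == 1  # all-zero transcript excluded

    def test_planted_log2fc_recovered(self):
        cfg = CocultureSimConfig(n_transcripts_h=2000, n_transcripts_m=1500,
                                 seed=21)
        m, truth = simulate_coculture_counts(cfg)
        res = CocultureDE(group_order=("TT", "CC")).fit(m).results_
        merged = res.merge(truth["transcripts"], on="transcript_id",
                           suffixes=("", "_true"))
        de = merged[merged["is_de"]]
        aligned = (de["log2fc"] * np.sign(de["log2fc_true"])).mean()
        assert aligned == pytest.approx(1.0, abs=0.15)

    def test_type_one_error_calibrated_under_null(self):
        cfg = CocultureSimConfig(n_transcripts_h=3000, n_transcripts_m=2000,
                                 frac_de_h=0, frac_de_m=0, seed=31)
        m, _ = simulate_coculture_counts(cfg)
        res = CocultureDE().fit(m).results_
        frac = (res["p_value"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)
        assert res["significant"].sum() <= 5

    def test_fdr_control_with_planted_effects(self):
        fdps = []
        for seed in range(20):
            cfg = CocultureSimConfig(n_transcripts_h=600, n_transcripts_m=400,
                                     frac_de_h=0.1, frac_de_m=0.1, seed=seed)
            m, truth = simulate_coculture_counts(cfg)
            res = CocultureDE().fit(m).results_
            merged = res.merge(truth["transcripts"], on="transcript_id",
                               suffixes=("", "_true"))
            called = merged[merged["significant"]]
            fdps.append((~called["is_de"]).mean() if len(called) else 0.0)
        assert np.mean(fdps) <= 0.10

    def test_null_pvalues_uniform_after_label_permutation(self):
        cfg = CocultureSimConfig(n_transcripts_h=900, n_transcripts_m=600,
                                 frac_de_h=0, frac_de_m=0, dropout_prob=0.0,
                                 seed=41)
        m, _ = simulate_coculture_counts(cfg)
        rng = np.random.default_rng(7)
        perm = rng.permutation(m.counts.shape[1])
        m_perm = SpeciesCountMatrix(
            counts=m.counts, species=m.species,
            groups=pd.Series(m.groups.to_numpy()[perm], index=m.groups.index),
        )
        res = CocultureDE().fit(m_perm).results_
        ks = stats.kstest(res["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_composition_shift_invariance_with_species_offsets(self):
        cfg = CocultureSimConfig(n_transcripts_h=1200, n_transcripts_m=800,
                                 frac_de_h=0, frac_de_m=0, ratio_mean=0.5,
                                 nb_dispersion=0.005, dropout_prob=0.0, seed=11)
        m, _ = simulate_coculture_counts(cfg)
        perturbed = m.counts.copy()
        hmask = m.species == "human"
        perturbed.loc[hmask, perturbed.columns[0]] *= 3
        m2 = SpeciesCountMatrix(counts=perturbed, species=m.species,
                                groups=m.groups)

        def calls(mat, mode):
            model = CocultureDE(offset_mode=mode)
            # known dispersion isolates normalisation from variance estimation
            from asoctools.coculture import split_by_species as sbs
            h, mo, cf = sbs(mat)
            out = []
            for sp, block in (("human", h), ("mouse", mo)):
                kept = expression_filter(block)
                out.append(fit_nb_de(kept, mat.groups,
                                     offsets=cf.offsets(sp, mode=mode),
                                     dispersion=cfg.nb_dispersion))
            return pd.concat(out).set_index("transcript_id")["significant"]

        base = calls(m, "species")
        pert = calls(m2, "species")
        human_ids = m.species[m.species == "human"].index
        changed = base.reindex(human_ids).fillna(False) \
            != pert.reindex(human_ids).fillna(False)
        assert changed.sum() == 0
        # the single whole-library offset mis-normalises the shifted sample
        assert calls(m2, "whole").sum() >= 1


class TestRepresentGenes:
    def make_table(self):
        return pd.DataFrame({
            "transcript_id": ["t1", "t2", "t3", "t4"],
            "p_value": [0.01, 0.5, 0.2, 0.2],
            "mean_count": [5.0, 9.0, 2.0, 8.0],
        })

    def test_smallest_p_flagged(self):
        t2g = {"t1": "g1", "t2": "g1", "t3": "g2", "t4": "g2"}
        out = represent_genes(self.make_table(), t2g)
        rep = out[out["gene_representative"]].set_index("gene_id")
        assert rep.loc["g1", "transcript_id"] == "t1"

    def test_tie_broken_by_expression(self):
        t2g = {"t3": "g2", "t4": "g2"}
        out = represent_genes(self.make_table(), t2g)
        g2 = out[out["gene_id"] == "g2"]
        assert g2.loc[g2["gene_representative"], "transcript_id"].item() == "t4"

    def test_unmapped_transcripts_represent_themselves(self):
        out = represent_genes(self.make_table(), {})
        assert out["gene_representative"].all()
        assert (out["gene_id"] == out["transcript_id"]).all()
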