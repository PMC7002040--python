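"""Proteomics stack: filtering, imputation, s0 permutation test, ruler."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ribomito import proteomics, synth
from ribomito.errors import ConfigError, InputError


def _pg(rows, samples=("a_1", "a_2", "a_3", "b_1", "b_2", "b_3")):
    """Build a ProteinGroups from a list of row dicts."""
    defaults = dict(gene_name="G", mol_weight_kda=50.0, is_histone=False,
                    localisation="", go_terms="", reverse=False,
                    contaminant=False, site_only=False)
    full = []
    for i, row in enumerate(rows):
        r = {**defaults, "protein_id": f"P{i}", **row}
        for s in samples:
            r.setdefault(s, 100.0)
        full.append(r)
    return synth.ProteinGroups(table=pd.DataFrame(full),
                               intensity_cols=list(samples))


class TestFilter:
    def test_engineered_fixture_with_known_survivors(self):
        rows = [
            dict(reverse=True),                      # decoy
            dict(contaminant=True),                  # contaminant
            dict(go_terms="blood microparticle"),    # excluded GO
            dict(a_1=0.0, a_2=0.0, b_1=0.0, b_2=0.0),  # 4 zeros
            dict(),                                  # survivor
            dict(a_1=0.0),                           # 1 zero: survivor
        ]
        filt, removed = proteomics.filter_protein_groups(_pg(rows))
        assert removed == {"decoy_contaminant_site": 2, "excluded_go": 1,
                           "too_many_zeros": 1}
        assert list(filt.table.protein_id) == ["P4", "P5"]

    def test_more_than_max_zeros_removed(self):
        rows = [dict(a_1=0.0, a_2=0.0, a_3=0.0, b_1=0.0)]
        filt, removed = proteomics.filter_protein_groups(_pg(rows),
                                                         max_zeros=3)
        assert removed["too_many_zeros"] == 1 and filt.table.empty

    def test_exactly_max_zeros_kept(self):
        rows = [dict(a_1=0.0, a_2=0.0, a_3=0.0)]
        filt, _ = proteomics.filter_protein_groups(_pg(rows), max_zeros=3)
        assert len(filt.table) == 1

    def test_clean_table_unchanged(self):
        pg = _pg([dict(), dict()])
        filt, removed = proteomics.filter_protein_groups(
            pg, excluded_go=frozenset())
        assert sum(removed.values()) == 0
        pd.testing.assert_frame_equal(filt.table, pg.table)

    def test_unknown_sample_in_design_rejected(self):
        with pytest.raises(InputError, match="ghost"):
            proteomics.filter_protein_groups(_pg([dict()]),
                                             group_design={"ghost": "a"})


class TestLog2Transform:
    def test_values_and_missing_markers(self):
        mat = pd.DataFrame({"s1": [8.0, 0.0]})
        out = proteomics.log2_transform(mat)
        assert out.loc[0, "s1"] == 3.0
        assert np.isnan(out.loc[1, "s1"])

    def test_round_trip(self, rng):
        mat = pd.DataFrame(2.0 ** rng.uniform(10, 30, size=(50, 4)))
        out = proteomics.log2_transform(mat)
        np.testing.assert_allclose(2.0 ** out, mat, rtol=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            proteomics.log2_transform(pd.DataFrame({"s": [-1.0]}))


class TestImputation:
    def test_complete_matrix_unchanged(self, rng):
        mat = pd.DataFrame(rng.normal(25, 2, size=(100, 3)))
        res = proteomics.impute_downshifted(mat, seed=0)
        assert res.fraction_imputed == 0.0
        pd.testing.assert_frame_equal(res.matrix, mat)

    def test_downshifted_target_distribution(self, rng):
        # observed column: mean 25 sd 2 exactly; imputed cells must follow
        # Normal(25 - 1.8*2, (0.3*2)^2) = Normal(21.4, 0.6^2)
        obs = rng.normal(size=2000)
        obs = (obs - obs.mean()) / obs.std(ddof=1) * 2.0 + 25.0
        col = np.concatenate([obs, np.full(10000, np.nan)])
        mat = pd.DataFrame({"s1": col})
        res = proteomics.impute_downshifted(mat, seed=42)
        imputed = res.matrix.loc[res.mask["s1"], "s1"]
        assert imputed.mean() == pytest.approx(21.4, abs=0.05)
        assert imputed.std(ddof=1) == pytest.approx(0.6, abs=0.05)

    def test_imputed_cells_normally_distributed(self, rng):
        obs = rng.normal(size=500)
        obs = (obs - obs.mean()) / obs.std(ddof=1) * 2.0 + 25.0
        mat = pd.DataFrame({"s": np.concatenate([obs,
                                                 np.full(10000, np.nan)])})
        res = proteomics.impute_downshifted(mat, seed=7)
        imputed = res.matrix.loc[res.mask["s"], "s"]
        ks = stats.kstest(imputed, "norm", args=(21.4, 0.6))
        assert ks.pvalue > 0.01

    def test_fraction_report_equals_constructed_missingness(self, rng):
        # fixture built with exactly 6.68% missing cells
        n_rows, n_cols = 2500, 4
        total = n_rows * n_cols
        n_missing = round(total * 0.0668)
        mat = rng.normal(25, 2, size=total)
        idx = rng.choice(total, size=n_missing, replace=False)
        mat[idx] = np.nan
        df = pd.DataFrame(mat.reshape(n_rows, n_cols))
        res = proteomics.impute_downshifted(df, seed=1)
        assert res.fraction_imputed == pytest.approx(n_missing / total)
        assert res.fraction_imputed == pytest.approx(0.0668, abs=5e-4)
        assert res.mask.to_numpy().mean() == res.fraction_imputed

    def test_global_scope_uses_whole_matrix_stats(self, rng):
        obs = rng.normal(size=(4000, 2))
        obs = (obs - obs.mean()) / obs.std(ddof=1) * 2.0 + 25.0
        df = pd.DataFrame(obs)
        df.iloc[:2000, 0] = np.nan
        res = proteomics.impute_downshifted(df, scope="global", seed=3)
        imputed = res.matrix.to_numpy()[res.mask.to_numpy()]
        # global stats are approximately (25, 2) by construction
        assert imputed.mean() == pytest.approx(21.4, abs=0.1)

    def test_underobserved_column_rejected(self):
        mat = pd.DataFrame({"s": [1.0, np.nan, np.nan]})
        with pytest.raises(InputError, match="filter"):
            proteomics.impute_downshifted(mat, seed=0)

    def test_bad_scope_rejected(self):
        with pytest.raises(ConfigError):
            proteomics.impute_downshifted(pd.DataFrame({"s": [1.0, 2.0]}),
                                          scope="per_protein")


class TestS0PermutationTest:
    def test_s0_zero_equals_welch_t(self, null_matrix_3v3):
        mat, design = null_matrix_3v3
        res = proteomics.s0_permutation_test(mat, design, s0=0.0, seed=0)
        oracle = stats.ttest_ind(
            mat[["b_1", "b_2", "b_3"]], mat[["a_1", "a_2", "a_3"]],
            axis=1, equal_var=False)
        np.testing.assert_allclose(res.table["d"], oracle.statistic,
                                   atol=1e-10)

    def test_pooled_variance_matches_student_t(self, null_matrix_3v3):
        mat, design = null_matrix_3v3
        res = proteomics.s0_permutation_test(mat, design, s0=0.0,
                                             variance="pooled", seed=0)
        oracle = stats.ttest_ind(
            mat[["b_1", "b_2", "b_3"]], mat[["a_1", "a_2", "a_3"]],
            axis=1, equal_var=True)
        np.testing.assert_allclose(res.table["d"], oracle.statistic,
                                   atol=1e-10)

    def test_null_matrix_calibration(self, null_matrix_3v3):
        mat, design = null_matrix_3v3
        res = proteomics.s0_permutation_test(mat, design, s0=0.1, seed=1)
        assert (res.table["q"] < 0.05).mean() <= 0.06

    def test_q_monotone_in_abs_d(self, null_matrix_3v3):
        mat, design = null_matrix_3v3
        res = proteomics.s0_permutation_test(mat, design, s0=0.1, seed=2)
        ordered = res.table.reindex(
            res.table["d"].abs().sort_values(ascending=False).index)
        assert (np.diff(ordered["q"]) >= -1e-12).all()

    def test_spiked_effects_recovered(self, rng):
        mat = rng.normal(size=(2000, 6))
        spiked = np.zeros(2000, dtype=bool)
        spiked[:100] = True
        mat[spiked, 3:] += 4.0
        df = pd.DataFrame(mat, columns=["a_1", "a_2", "a_3",
                                        "b_1", "b_2", "b_3"])
        design = {c: c.split("_")[0] for c in df.columns}
        res = proteomics.s0_permutation_test(df, design, s0=2.0, seed=3)
        sig = res.table["significant"].to_numpy()
        recall = sig[spiked].mean()
        emp_fdr = sig[~spiked].sum() / max(sig.sum(), 1)
        assert recall >= 0.9
        assert emp_fdr <= 0.1

    def test_missing_values_rejected(self, null_matrix_3v3):
        mat, design = null_matrix_3v3
        mat = mat.copy()
        mat.iloc[0, 0] = np.nan
        with pytest.raises(InputError, match="impute"):
            proteomics.s0_permutation_test(mat, design)

    def test_negative_s0_rejected(self, null_matrix_3v3):
        mat, design = null_matrix_3v3
        with pytest.raises(ConfigError, match="s0"):
            proteomics.s0_permutation_test(mat, design, s0=-0.1)

    def test_single_replicate_group_rejected(self, rng):
        mat = pd.DataFrame(rng.normal(size=(10, 3)),
                           columns=["a_1", "a_2", "b_1"])
        with pytest.raises(InputError, match="replicates"):
            proteomics.s0_permutation_test(
                mat, {"a_1": "a", "a_2": "a", "b_1": "b"})


class TestProteomicRuler:
    def test_histone_only_table_recovers_dna_mass(self):
        intensity = pd.Series([1e6, 2e6], index=["h1", "h2"])
        mw = pd.Series([11.4, 13.9], index=intensity.index)
        res = proteomics.proteomic_ruler(
            intensity, mw, pd.Series([True, True], index=intensity.index),
            dna_mass_pg=6.5)
        assert res.total_mass_pg == pytest.approx(6.5)

    def test_worked_toy_example(self):
        # histone 1e6, protein X 2e6 at 50 kDa, DNA 6.5 pg:
        # mass_X = 13 pg and ~1.566e8 copies
        intensity = pd.Series([1e6, 2e6], index=["h", "x"])
        mw = pd.Series([11.4, 50.0], index=intensity.index)
        res = proteomics.proteomic_ruler(
            intensity, mw, pd.Series([True, False], index=intensity.index),
            dna_mass_pg=6.5)
        assert res.mass_pg["x"] == pytest.approx(13.0)
        assert res.copies["x"] == pytest.approx(1.566e8, rel=1e-3)

    def test_scale_invariance(self, rng):
        idx = [f"p{i}" for i in range(20)]
        intensity = pd.Series(rng.uniform(1e5, 1e7, size=20), index=idx)
        mw = pd.Series(rng.uniform(10, 200, size=20), index=idx)
        hist = pd.Series([True] * 3 + [False] * 17, index=idx)
        a = proteomics.proteomic_ruler(intensity, mw, hist, dna_mass_pg=6.5)
        b = proteomics.proteomic_ruler(2 * intensity, mw, hist,
                                       dna_mass_pg=6.5)
        pd.testing.assert_series_equal(a.mass_pg, b.mass_pg)
        pd.testing.assert_series_equal(a.copies, b.copies)

    def test_genome_size_route(self):
        # mouse-scale diploid genome: ~2 * 2.7e9 bp -> about 5.5 pg
        mass = proteomics.dna_mass_from_genome(2.7e9, ploidy=2)
        assert mass == pytest.approx(
            2.7e9 * 2 * 615.8771 / 6.02214076e23 * 1e12)
        assert 5.0 < mass < 6.0

    def test_zero_mw_skipped_with_warning(self):
        intensity = pd.Series([1e6, 1e6], index=["h", "bad"])
        mw = pd.Series([11.4, 0.0], index=intensity.index)
        with pytest.warns(UserWarning, match="molecular weight"):
            res = proteomics.proteomic_ruler(
                intensity, mw,
                pd.Series([True, False], index=intensity.index),
                dna_mass_pg=6.5)
        assert res.skipped == ["bad"]

    def test_no_histone_signal_rejected(self):
        intensity = pd.Series([1e6], index=["p"])
        with pytest.raises(InputError, match="histone"):
            proteomics.proteomic_ruler(
                intensity, pd.Series([50.0], index=["p"]),
                pd.Series([False], index=["p"]), dna_mass_pg=6.5)


class TestOrganelleFractions:
    def test_single_compartment_is_everything(self):
        mass = pd.Series([1.0, 2.0], index=["a", "b"])
        loc = pd.Series(["mitochondrion", "mitochondrion"],
                        index=mass.index)
        pct = proteomics.organelle_mass_fractions(mass, loc)
        assert pct["mitochondrion"] == pytest.approx(100.0)

    def test_two_equal_masses_split_50_50(self):
        mass = pd.Series([3.0, 3.0], index=["a", "b"])
        loc = pd.Series(["nucleus", "cytosol"], index=mass.index)
        pct = proteomics.organelle_mass_fractions(mass, loc)
        assert pct["nucleus"] == pytest.approx(50.0)
        assert pct["cytosol"] == pytest.approx(50.0)

    def test_dual_localised_splits_equally(self):
        # 4 to mito, 2 split between mito and nucleus, 2 unmapped:
        # mito 5/8, nucleus 1/8, unassigned 2/8
        mass = pd.Series([4.0, 2.0, 2.0], index=["a", "b", "c"])
        loc = pd.Series(["mitochondrion", "mitochondrion;nucleus", ""],
                        index=mass.index)
        pct = proteomics.organelle_mass_fractions(mass, loc)
        assert pct["mitochondrion"] == pytest.approx(62.5)
        assert pct["nucleus"] == pytest.approx(12.5)
        assert pct["unassigned"] == pytest.approx(25.0)

    def test_percentages_sum_to_100(self, rng):
        n = 50
        idx = [f"p{i}" for i in range(n)]
        mass = pd.Series(rng.uniform(0.1, 5.0, size=n), index=idx)
        labels = rng.choice(["mitochondrion", "nucleus;cytosol", "", "er"],
                            size=n)
        pct = proteomics.organelle_mass_fractions(
            mass, pd.Series(labels, index=idx))
        assert pct.sum() == pytest.approx(100.0, abs=1e-9)
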