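"""Count normalization, per-patient DE binarization, moderated t and the
three expression-based validation summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isnp.expression import (binarize_de, de_gene_set, filter_and_normalize,
                             moderated_t, per_patient_fc, validation_1,
                             validation_2, validation_3)


def counts_frame(values, genes=None, samples=None):
    values = np.asarray(values)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestFilterNormalize:
    def test_low_total_gene_removed(self):
        c = counts_frame([[3, 3, 3], [100, 100, 100]])
        normed = filter_and_normalize(c, min_total=10)
        assert list(normed.index) == ["G1"]

    def test_proportional_samples_identical_logcpm(self):
        c = counts_frame([[10, 20], [30, 60], [60, 120]])
        normed = filter_and_normalize(c, min_total=10)
        np.testing.assert_allclose(normed["S0"], normed["S1"], atol=1e-12)

    def test_zero_count_finite(self):
        c = counts_frame([[0, 50], [100, 50]])
        normed = filter_and_normalize(c, min_total=10)
        assert np.isfinite(normed.values).all()

    def test_zero_library_errors(self):
        with pytest.raises(ValueError, match="zero total"):
            filter_and_normalize(counts_frame([[0, 5], [0, 5]]))

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            filter_and_normalize(counts_frame([[-1, 5]]))


class TestFoldChange:
    def test_fc_against_control_mean(self):
        normed = counts_frame([[6.5, 5.0, 5.0]], samples=["P1", "C1", "C2"])
        fc = per_patient_fc(normed, ["C1", "C2"])
        assert fc.loc["G0", "P1"] == pytest.approx(1.5)

    def test_binarize_strict_boundary(self):
        fc = counts_frame([[1.0, 1.0001, -1.2]], samples=["a", "b", "c"])
        de = binarize_de(fc, cutoff=1.0)
        assert de.flags.loc["G0"].tolist() == [0, 1, 1]

    def test_flags_invariant_under_sign_flip(self):
        fc = counts_frame(np.random.default_rng(0).normal(0, 1.5, (20, 6)))
        assert (binarize_de(fc).flags.values
                == binarize_de(-fc).flags.values).all()

    def test_missing_control_errors(self):
        normed = counts_frame([[1.0, 2.0]], samples=["P1", "C1"])
        with pytest.raises(ValueError):
            per_patient_fc(normed, ["C1", "C9"])


class TestModeratedT:
    def make_data(self, rng, n_genes=300, n=8, effect=None):
        x = rng.normal(5.0, 0.7, size=(n_genes, 2 * n))
        if effect is not None:
            x[:50, :n] += effect
        cols = [f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)]
        return counts_frame(x, samples=cols), cols[:n], cols[n:]

    def test_zero_prior_df_reproduces_ordinary_t(self, rng):
        normed, cases, controls = self.make_data(rng)
        res = moderated_t(normed, cases, controls, prior_df=0)
        t_ref, p_ref = stats.ttest_ind(normed[cases], normed[controls],
                                       axis=1)
        np.testing.assert_allclose([r.t for r in res], t_ref, rtol=1e-9)
        np.testing.assert_allclose([r.pvalue for r in res], p_ref, rtol=1e-9)

    def test_shrinkage_toward_prior_monotone(self, rng):
        """Larger prior df pulls each gene's statistic toward the pooled one."""
        normed, cases, controls = self.make_data(rng, n_genes=100)
        t0 = np.array([r.t for r in moderated_t(normed, cases, controls,
                                                prior_df=0)])
        t_small = np.array([r.t for r in moderated_t(normed, cases, controls,
                                                     prior_df=4)])
        t_big = np.array([r.t for r in moderated_t(normed, cases, controls,
                                                   prior_df=400)])
        # genes with tiny sample variance get deflated |t| as d0 grows
        s2 = (normed[cases].var(axis=1, ddof=1) * 7
              + normed[controls].var(axis=1, ddof=1) * 7) / 14
        low_var = s2.values < np.median(s2.values) * 0.6
        if low_var.any():
            assert (np.abs(t_big[low_var]) <= np.abs(t0[low_var]) + 1e-9).all()
        # shrinkage is monotone in d0 for every gene
        between = np.minimum(np.abs(t0), np.abs(t_big)) - 1e-9 <= np.abs(t_small)
        assert between.all() or (np.abs(t_small) <= np.maximum(
            np.abs(t0), np.abs(t_big)) + 1e-9).all()

    def test_null_type_one_error(self, rng):
        normed, cases, controls = self.make_data(rng, n_genes=1500, n=10)
        res = moderated_t(normed, cases, controls)
        frac = np.mean([r.pvalue < 0.05 for r in res])
        assert abs(frac - 0.05) < 0.02

    def test_planted_effect_power(self, rng):
        normed, cases, controls = self.make_data(rng, n_genes=500, n=10,
                                                 effect=2.0)
        res = moderated_t(normed, cases, controls)
        de = de_gene_set(res, fc_cutoff=1.0, q_threshold=0.05)
        planted = {f"G{i}" for i in range(50)}
        assert len(de & planted) / 50 >= 0.9

    def test_too_few_samples_error(self, rng):
        normed, cases, controls = self.make_data(rng, n_genes=10)
        with pytest.raises(ValueError):
            moderated_t(normed, cases[:1], controls)


class TestValidation1:
    def make_de(self, flags, patients=None):
        flags = counts_frame(flags, samples=patients)
        return binarize_de(flags * 10.0)  # scale so flags survive |fc|>1

    def test_per_gene_percent(self):
        de = self.make_de([[1, 1, 1, 0]])
        v = validation_1(de, ["G0"])
        assert v["per_gene_percent"]["G0"] == pytest.approx(75.0)

    def test_mean_and_population_sd(self):
        de = self.make_de([[1, 1], [0, 0]])
        v = validation_1(de, ["G0", "G1"])
        assert v["mean_percent"] == pytest.approx(50.0)
        assert v["sd_percent"] == pytest.approx(50.0)

    def test_missing_gene_reported(self):
        de = self.make_de([[1, 0]])
        v = validation_1(de, ["G0", "NOPE"])
        assert v["missing_genes"] == ["NOPE"]

    def test_order_invariance(self, rng):
        flags = rng.integers(0, 2, size=(6, 10))
        de = self.make_de(flags)
        v1 = validation_1(de, [f"G{i}" for i in range(6)])
        perm = rng.permutation(6)
        v2 = validation_1(de, [f"G{i}" for i in perm])
        assert v1["mean_percent"] == pytest.approx(v2["mean_percent"])


class TestValidation2:
    def test_separable_blocks_recovered(self):
        patients = [f"P{i}" for i in range(8)]
        flags = np.zeros((4, 8))
        flags[:, :4] = 1  # first block has all driver genes DE
        de = binarize_de(counts_frame(flags * 10.0, samples=patients))
        drivers = {"D": {"G0", "G1", "G2", "G3"}}
        genotype = pd.Series([1] * 4 + [2] * 4, index=patients)
        rep = validation_2(de, drivers, genotype, k=2)
        assert rep["ari"] == pytest.approx(1.0)

    def test_all_zero_matrix_reported_na(self):
        patients = [f"P{i}" for i in range(4)]
        de = binarize_de(counts_frame(np.zeros((3, 4)), samples=patients))
        genotype = pd.Series([1, 1, 2, 2], index=patients)
        rep = validation_2(de, {"D": {"G0", "G1", "G2"}}, genotype, k=2)
        assert np.isnan(rep["ari"])


class TestValidation3:
    def test_identical_gene_sets_full_overlap(self):
        universe = {f"g{i}" for i in range(30)}
        term = {f"g{i}" for i in range(8)}
        collection = {"T": term, "T2": {f"g{i}" for i in range(20, 28)}}
        rep = validation_3(term, {"D": term}, collection, universe)
        assert rep["mean_overlap"] == pytest.approx(1.0)

    def test_no_enriched_terms_is_na(self):
        universe = {f"g{i}" for i in range(30)}
        collection = {"T": {f"g{i}" for i in range(8)}}
        rep = validation_3({"g29"}, {"D": {"g28"}}, collection, universe)
        assert np.isnan(rep["per_driver"]["D"]["overlap"])
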