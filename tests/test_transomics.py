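import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidprog import class_gene_sets, correlate_all, overlap_genes, rank_classes, spearman
from lipidprog.errors import ConstantVectorError, NoSharedSamplesError, UnknownClassError
from lipidprog.nomenclature import characteristic_table, parse_species
from tests.conftest import log10_matrix
from tests.oracles import spearman_exact_p_oracle, spearman_no_ties_oracle


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1.0, 2.0, 5.0, 9.0, 12.0]
        rho_up, _ = spearman(x, np.exp(x))
        rho_down, _ = spearman(x, -np.asarray(x) ** 3)
        assert rho_up == pytest.approx(1.0)
        assert rho_down == pytest.approx(-1.0)

    def test_rank_pearson_worked_example(self):
        """ranks of y are (2,1,4,3,5); sum d^2 = 4; rho = 1 - 24/120 = 0.8."""
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)
        assert rho == pytest.approx(spearman_no_ties_oracle([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        rho, p = spearman(x, y)
        rho2, p2 = spearman(np.exp(x), y**3 if (y > 0).all() else np.arctan(y))
        assert rho2 == pytest.approx(rho, abs=1e-12)
        assert p2 == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_exact_permutation_p_matches_enumeration(self, n):
        rng = np.random.default_rng(n)
        x = rng.permutation(n).astype(float)
        y = rng.permutation(n).astype(float)
        _, p = spearman(x, y)
        assert p == pytest.approx(spearman_exact_p_oracle(list(x), list(y)), abs=1e-12)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = x + rng.normal(0, 1.0, size=40)
        rho, p = spearman(x, y)
        ref_rho, ref_p = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref_rho, abs=1e-12)
        assert p == pytest.approx(ref_p, rel=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ConstantVectorError):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


def small_multiomics(seed=0, n=100, n_lipids=12, n_genes=20):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n)]
    names = [f"PC O-{30 + i}:1" for i in range(4)] + [f"PE O-{30 + i}:2" for i in range(4)] \
        + [f"TAG {48 + i}:0" for i in range(4)]
    lip = rng.normal(0, 1, size=(n_lipids, n))
    genes = rng.normal(0, 1, size=(n_genes, n))
    return samples, names, lip, genes, rng


class TestCorrelateAll:
    def test_driven_gene_detected(self):
        samples, names, lip, genes, rng = small_multiomics(seed=3)
        genes[0] = np.exp(lip[0] / 4) + rng.normal(0, 0.01, size=lip.shape[1])
        m = log10_matrix(lip, species=names, samples=samples)
        g = pd.DataFrame(genes, index=[f"G{i}" for i in range(len(genes))], columns=samples)
        corr = correlate_all(m, g)
        hit = corr[(corr.lipid_id == names[0]) & (corr.gene_id == "G0")].iloc[0]
        assert hit["significant"] and hit["rho"] > 0.95

    def test_identical_row_rho_one(self):
        samples, names, lip, genes, _ = small_multiomics(seed=4)
        genes[5] = lip[2]
        m = log10_matrix(lip, species=names, samples=samples)
        g = pd.DataFrame(genes, index=[f"G{i}" for i in range(len(genes))], columns=samples)
        corr = correlate_all(m, g)
        hit = corr[(corr.lipid_id == names[2]) & (corr.gene_id == "G5")].iloc[0]
        assert hit["rho"] == pytest.approx(1.0)
        assert hit["p_value"] < 1e-30

    def test_null_grid_rarely_significant(self):
        rng = np.random.default_rng(8)
        n = 50
        samples = [f"s{i}" for i in range(n)]
        m = log10_matrix(rng.normal(size=(200, n)), samples=samples)
        g = pd.DataFrame(rng.normal(size=(200, n)),
                         index=[f"G{i}" for i in range(200)], columns=samples)
        corr = correlate_all(m, g)
        assert corr["significant"].mean() < 0.01

    def test_no_shared_samples(self):
        samples, names, lip, genes, _ = small_multiomics()
        m = log10_matrix(lip, species=names, samples=samples)
        g = pd.DataFrame(genes, index=[f"G{i}" for i in range(len(genes))],
                         columns=[f"zz{i}" for i in range(len(samples))])
        with pytest.raises(NoSharedSamplesError):
            correlate_all(m, g)

    def test_counts_vs_log_detection(self):
        """A TPM-like matrix (max > 50) is log2(x+1)-transformed on ingest."""
        samples, names, lip, genes, rng = small_multiomics(seed=6)
        tpm = np.exp(rng.normal(3, 1, size=genes.shape))  # strictly positive, max >> 50
        m = log10_matrix(lip, species=names, samples=samples)
        g = pd.DataFrame(tpm, index=[f"G{i}" for i in range(len(tpm))], columns=samples)
        corr_auto = correlate_all(m, g)
        corr_off = correlate_all(m, g, log_genes=False)
        # Spearman is rank-based: transform must not change rho
        np.testing.assert_allclose(corr_auto["rho"], corr_off["rho"], atol=1e-12)


class TestClassSetsAndOverlap:
    @staticmethod
    def chars():
        names = ["PC O-30:1", "PC O-31:1", "PE O-30:2", "TAG 48:0"]
        return characteristic_table([parse_species(n) for n in names])

    def corr_frame(self, rows):
        return pd.DataFrame(rows, columns=["lipid_id", "gene_id", "rho", "p_value", "significant"])

    def test_no_significant_all_empty(self):
        corr = self.corr_frame([("PC O-30:1", "G1", 0.1, 0.9, False)])
        sets = class_gene_sets(corr, self.chars())
        assert all(len(s) == 0 for s in sets.values())

    def test_gene_counted_once_per_class(self):
        corr = self.corr_frame(
            [("PC O-30:1", "G1", 0.8, 0.001, True),
             ("PC O-31:1", "G1", -0.7, 0.002, True),
             ("PE O-30:2", "G2", 0.6, 0.01, True)]
        )
        sets = class_gene_sets(corr, self.chars())
        assert sets["PC O-"] == {"G1"}
        assert sets["PE O-"] == {"G2"}
        ranking = rank_classes(sets)
        assert ranking.iloc[0]["n_genes"] == 1

    def test_overlap_examples(self):
        sets = {"A": {"g1", "g2"}, "B": {"g2", "g3"}, "C": {"g2"}}
        assert overlap_genes(sets, ["A", "B", "C"]) == {"g2"}
        assert overlap_genes(sets, ["A"]) == sets["A"]  # single-class identity
        assert overlap_genes({**sets, "D": set()}, ["A", "D"]) == set()
        with pytest.raises(UnknownClassError):
            overlap_genes(sets, ["A", "nope"])

    def test_planted_module_recovered_via_ether_classes(self, small_clean):
        clean, genes, _, truth, chars = small_clean
        corr = correlate_all(clean, genes, significant_only=True)
        sets = class_gene_sets(corr, chars)
        ranking = rank_classes(sets)
        top = list(ranking["class"][:3])
        assert set(top) == {"PC O-", "PE O-", "LPE O-"}
        recovered = overlap_genes(sets, top) & set(truth.module_genes)
        assert len(recovered) >= 0.9 * len(truth.module_genes)
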