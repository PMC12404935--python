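"""Co-expression networks: soft threshold, TOM, modules, eigengenes,
module-trait correlation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from rewirenet import coexpress, synthgen


def frame(values, prefix="G"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(values,
                        index=[f"{prefix}{i:03d}" for i in range(values.shape[0])],
                        columns=[f"S{j:02d}" for j in range(values.shape[1])])


def block_matrix(n_blocks=2, block_size=30, n_background=0, n_samples=40,
                 cor=0.9, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    truth = []
    for b in range(n_blocks):
        factor = rng.normal(0, 1, size=n_samples)
        for _ in range(block_size):
            rows.append(np.sqrt(cor) * factor
                        + np.sqrt(1 - cor) * rng.normal(0, 1, n_samples))
            truth.append(b + 1)
    for _ in range(n_background):
        rows.append(rng.normal(0, 1, n_samples))
        truth.append(0)
    return frame(np.array(rows)), np.array(truth)


class TestSoftThreshold:
    def test_choice_rule_smallest_reaching_target(self):
        power, reached = coexpress.choose_power(
            (2, 4, 6, 8), (0.50, 0.75, 0.83, 0.90), target=0.80)
        assert power == 6 and reached

    def test_fallback_argmax_with_warning(self):
        with pytest.warns(UserWarning, match="argmax"):
            power, reached = coexpress.choose_power(
                (2, 4, 6), (0.3, 0.7, 0.5), target=0.80)
        assert power == 4 and not reached

    def test_fit_matches_independent_regression(self):
        # exact power-law degrees: frequency halves as connectivity doubles
        k = np.repeat([1.0, 2.0, 4.0, 8.0, 16.0], [160, 80, 40, 20, 10])
        r2 = coexpress.scale_free_fit(k, n_bins=10)

        edges = np.linspace(k.min(), k.max(), 11)
        edges[-1] += 1e-9
        idx = np.digitize(k, edges) - 1
        xs, ys = [], []
        for b in range(10):
            members = k[idx == b]
            if members.size:
                xs.append(np.log10(members.mean()))
                ys.append(np.log10(members.size / k.size))
        fit = stats.linregress(xs, ys)
        assert r2 == pytest.approx(-np.sign(fit.slope) * fit.rvalue ** 2,
                                   abs=1e-8)
        assert r2 > 0.9

    def test_report_on_structured_data(self):
        m, _ = block_matrix(n_blocks=3, block_size=25, n_background=100,
                            n_samples=40, cor=0.8, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = coexpress.pick_soft_threshold(m)
        assert set(report.table.columns) == {"power", "r_squared",
                                             "mean_connectivity"}
        assert report.power in report.table["power"].tolist()
        # higher powers shrink mean connectivity
        mc = report.table["mean_connectivity"].to_numpy()
        assert (np.diff(mc) < 0).all()


class TestTOM:
    def test_hand_worked_three_nodes(self):
        a = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=float)
        tom = coexpress.tom_from_adjacency(a)
        assert tom[1, 2] == pytest.approx(0.5)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_zero_adjacency_zero_overlap(self):
        tom = coexpress.tom_from_adjacency(np.zeros((4, 4)))
        off = tom[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0.0)

    def test_complete_graph_full_overlap(self):
        a = np.ones((5, 5)) - np.eye(5)
        np.testing.assert_allclose(coexpress.tom_from_adjacency(a), 1.0)

    def test_bounds_symmetry_diagonal(self, random_matrix):
        tom = coexpress.build_tom(random_matrix, 6).to_numpy()
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1 + 1e-12
        np.testing.assert_allclose(np.diag(tom), 1.0)

    def test_adjacency_monotone_in_power(self, random_matrix):
        a6 = coexpress.adjacency(random_matrix, 6)
        a8 = coexpress.adjacency(random_matrix, 8)
        assert (a8 <= a6 + 1e-12).all()


class TestDetectModules:
    def test_two_blocks_exactly_recovered(self):
        for seed in range(5):
            m, truth = block_matrix(n_blocks=2, block_size=30,
                                    n_samples=40, cor=0.9, seed=seed)
            tom = coexpress.build_tom(m, 6)
            part = coexpress.detect_modules(tom, m, min_module_size=20)
            assert adjusted_rand_score(truth, part.to_numpy()) == 1.0

    def test_correlated_eigengenes_merged(self):
        # two blocks driven by nearly identical factors (r ~ 0.95 > 0.80)
        rng = np.random.default_rng(3)
        f1 = rng.normal(0, 1, 60)
        f2 = 0.97 * f1 + np.sqrt(1 - 0.97 ** 2) * rng.normal(0, 1, 60)
        rows = [0.95 * f + np.sqrt(1 - 0.9) * rng.normal(0, 1, 60)
                for f in (f1, f2) for _ in range(25)]
        m = frame(np.array(rows))
        tom = coexpress.build_tom(m, 6)
        part = coexpress.detect_modules(tom, m, min_module_size=20,
                                        merge_cut_height=0.20)
        labels = part[part != 0]
        assert labels.nunique() == 1
        assert len(labels) == 50

    def test_identical_genes_single_module(self):
        profile = np.linspace(0, 1, 20)
        m = frame(np.tile(profile, (30, 1)))
        tom = coexpress.build_tom(m, 6)
        part = coexpress.detect_modules(tom, m, min_module_size=10)
        assert (part == 1).all()

    def test_no_large_cluster_all_unassigned(self, random_matrix):
        tom = coexpress.build_tom(random_matrix, 6)
        with pytest.warns(UserWarning, match="min_module_size"):
            part = coexpress.detect_modules(tom, random_matrix,
                                            min_module_size=200)
        assert (part == 0).all()

    def test_labels_ordered_by_size(self):
        rng = np.random.default_rng(4)
        big, _ = block_matrix(n_blocks=1, block_size=40, n_samples=50,
                              cor=0.9, seed=10)
        small, _ = block_matrix(n_blocks=1, block_size=25, n_samples=50,
                                cor=0.9, seed=11)
        m = pd.concat([
            small.set_index(pd.Index([f"A{i}" for i in range(25)])),
            big.set_index(pd.Index([f"B{i}" for i in range(40)])),
        ])
        tom = coexpress.build_tom(m, 6)
        part = coexpress.detect_modules(tom, m, min_module_size=20)
        sizes = part[part != 0].value_counts()
        assert list(sizes.index) == sorted(sizes.index)
        assert sizes.loc[1] >= sizes.loc[2]


class TestEigengenes:
    def test_identical_profiles_rank_one(self):
        profile = np.sin(np.linspace(0, 3, 25))
        m = frame(np.tile(profile, (8, 1)))
        part = pd.Series(1, index=m.index)
        eig, var_expl = coexpress.module_eigengenes(m, part)
        assert var_expl["ME1"] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(eig.loc["ME1"].to_numpy(), z, atol=1e-10)

    def test_matches_svd_oracle(self, random_matrix):
        block = random_matrix.iloc[:5]
        part = pd.Series(1, index=block.index)
        eig, _ = coexpress.module_eigengenes(block, part)
        x = block.to_numpy()
        z = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
        v = np.linalg.svd(z, full_matrices=False)[2][0]
        r = np.corrcoef(eig.loc["ME1"], v)[0, 1]
        assert abs(r) >= 0.9999

    def test_sign_alignment_contract(self, random_matrix):
        block = random_matrix.iloc[:6]
        part = pd.Series(1, index=block.index)
        for matrix in (block, -block):
            eig, _ = coexpress.module_eigengenes(matrix, part)
            x = matrix.to_numpy()
            z = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
            assert np.corrcoef(eig.loc["ME1"], z.mean(0))[0, 1] >= 0

    def test_unit_variance(self, random_matrix):
        part = pd.Series([1] * 20 + [2] * 20, index=random_matrix.index)
        eig, _ = coexpress.module_eigengenes(random_matrix, part)
        np.testing.assert_allclose(eig.std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_single_gene_module_is_standardised_gene(self, random_matrix):
        gene = random_matrix.iloc[[0]]
        part = pd.Series(1, index=gene.index)
        eig, var_expl = coexpress.module_eigengenes(gene, part)
        x = gene.to_numpy()[0]
        z = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(eig.loc["ME1"], z, atol=1e-10)

    def test_eigengene_maximality(self):
        # no random unit-norm combination of module genes explains more
        # sample variance than the first-PC weights behind the eigengene
        m, _ = block_matrix(n_blocks=1, block_size=15, n_samples=30,
                            cor=0.7, seed=6)
        x = m.to_numpy()
        z = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        pc_var = (u[:, 0] @ z).var(ddof=1)
        rng = np.random.default_rng(7)
        for _ in range(100):
            w = rng.normal(size=z.shape[0])
            w /= np.linalg.norm(w)
            assert (w @ z).var(ddof=1) <= pc_var + 1e-9


class TestModuleTrait:
    def test_eigengene_equal_to_trait_r_one(self):
        trait = np.array([1.0, 0, 1, 0, 1, 0, 1, 0])
        eig = pd.DataFrame([(trait - trait.mean()) / trait.std(ddof=1)],
                           index=["ME1"],
                           columns=[f"S{j}" for j in range(8)])
        traits = pd.DataFrame({"disease": trait},
                              index=[f"S{j}" for j in range(8)])
        out = coexpress.module_trait_correlation(eig, traits)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_orthogonal_trait_r_zero_p_one(self):
        e = np.array([1.0, -1, 1, -1, 1, -1])
        trait = np.array([1.0, 1, 0, 0, 1, 1])  # orthogonal to e
        eig = pd.DataFrame([e], index=["ME1"],
                           columns=[f"S{j}" for j in range(6)])
        traits = pd.DataFrame({"disease": trait},
                              index=[f"S{j}" for j in range(6)])
        out = coexpress.module_trait_correlation(eig, traits)
        assert out["r"].iloc[0] == pytest.approx(0.0, abs=1e-10)
        assert out["p"].iloc[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_scipy_pearsonr(self, random_matrix):
        rng = np.random.default_rng(12)
        part = pd.Series([1] * 20 + [2] * 20, index=random_matrix.index)
        eig, _ = coexpress.module_eigengenes(random_matrix, part)
        trait = rng.normal(size=eig.shape[1])
        traits = pd.DataFrame({"t": trait}, index=eig.columns)
        out = coexpress.module_trait_correlation(eig, traits)
        for _, row in out.iterrows():
            ref_r, ref_p = stats.pearsonr(eig.loc[row["module"]], trait)
            assert row["r"] == pytest.approx(ref_r, abs=1e-10)
            assert row["p"] == pytest.approx(ref_p, abs=1e-10)

    def test_constant_trait_reported_missing(self):
        eig = pd.DataFrame([[1.0, -1, 0, 0.5]], index=["ME1"],
                           columns=[f"S{j}" for j in range(4)])
        traits = pd.DataFrame({"sex": [1.0, 1, 1, 1]}, index=eig.columns)
        with pytest.warns(UserWarning, match="constant"):
            out = coexpress.module_trait_correlation(eig, traits)
        assert np.isnan(out["r"].iloc[0])


class TestPlantedRecoveryInvariant:
    def test_median_ari_high_on_planted_modules(self):
        # abbreviated version of the full 20-seed study (5 seeds here)
        aris = []
        for seed in range(5):
            cfg = synthgen.SimConfig(
                n_genes=400, n_samples_per_group=10, n_modules=4,
                module_size=50, module_cor=0.8, n_degs=0, n_rewired=0,
                n_tfs=0, seed=seed)
            m, _, truth = synthgen.simulate_expression(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report = coexpress.pick_soft_threshold(m)
                tom = coexpress.build_tom(m, report.power)
                part = coexpress.detect_modules(tom, m, min_module_size=20)
            labels = pd.Series(0, index=m.index)
            for g, lab in truth.module_assignments.items():
                labels[g] = lab
            aris.append(adjusted_rand_score(labels, part.to_numpy()))
        assert np.median(aris) >= 0.9
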