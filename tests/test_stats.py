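"""Diversity metrics, PCoA, Wilcoxon, and the association model, checked
against hand calculations and independent library implementations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from equimeta.stats import (alpha_diversity, associate, chao1, faith_pd,
                            gini, ice, pcoa_spearman, shannon, simpson,
                            wilcoxon_one_sided)


class TestAlphaMetrics:
    def test_chao1_hand_case(self):
        # S_obs = 5, f1 = 2, f2 = 1 -> 5 + 4/2 = 7
        assert chao1([1, 1, 2, 5, 12]) == pytest.approx(7.0)

    def test_chao1_no_doubletons_uses_corrected_form(self):
        # f1 = 3, f2 = 0 -> 4 + 3*2/2 = 7
        assert chao1([1, 1, 1, 9]) == pytest.approx(7.0)

    def test_chao1_matches_skbio_classic(self):
        import skbio.diversity.alpha as ska

        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(0, 30, size=25)
            if not (counts > 0).any():
                continue
            assert chao1(counts) == pytest.approx(
                ska.chao1(counts, bias_corrected=False))

    def test_ice_matches_skbio_ace(self):
        import skbio.diversity.alpha as ska

        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = rng.integers(0, 40, size=30)
            rare = counts[(counts > 0) & (counts <= 10)]
            # skbio ace requires a well-defined coverage
            if len(rare) < 2 or rare.sum() < 2 or (rare == 1).all():
                continue
            assert ice(counts) == pytest.approx(ska.ace(counts), rel=1e-9)

    def test_shannon_simpson_uniform(self):
        p = np.full(8, 1 / 8)
        assert shannon(p) == pytest.approx(np.log(8))
        assert simpson(p) == pytest.approx(1 - 1 / 8)

    def test_gini_uniform_zero_and_concentrated_near_one(self):
        assert gini(np.full(10, 0.1)) == pytest.approx(0.0)
        skewed = np.array([1e-9] * 9 + [1.0])
        assert gini(skewed) > 0.85
        with pytest.raises(ValueError):
            gini(np.zeros(3))

    def test_faith_pd_hand_tree(self):
        tree = "((A:1,B:2):3,C:10):0;"
        assert faith_pd(["A"], tree) == pytest.approx(4.0)
        assert faith_pd(["A", "B"], tree) == pytest.approx(6.0)
        assert faith_pd(["A", "B", "C"], tree) == pytest.approx(16.0)

    def test_faith_pd_matches_skbio(self):
        from skbio import TreeNode
        from skbio.diversity.alpha import faith_pd as sk_faith
        from io import StringIO

        nwk = "(((A:0.5,B:0.7):1.1,C:2.0):0.3,(D:0.9,E:0.4):1.2):0;"
        tree = TreeNode.read(StringIO(nwk))
        otus = ["A", "B", "C", "D", "E"]
        counts = [3, 0, 1, 0, 2]
        present = [o for o, c in zip(otus, counts) if c > 0]
        assert faith_pd(present, nwk) == pytest.approx(
            sk_faith(counts, taxa=otus, tree=tree))

    def test_faith_pd_missing_feature_raises(self):
        with pytest.raises(KeyError):
            faith_pd(["Z"], "((A:1,B:2):3,C:10):0;")

    def test_alpha_diversity_frame(self):
        matrix = pd.DataFrame({"a": [0.5, 0.2], "b": [0.4, 0.8],
                               "unassigned": [0.1, 0.0]},
                              index=["S1", "S2"])
        counts = pd.DataFrame({"a": [5, 2], "b": [4, 8]}, index=["S1", "S2"])
        out = alpha_diversity(matrix, counts=counts)
        assert out.loc["S1", "observed_species"] == 2
        # unassigned excluded, renormalized: p = (5/9, 4/9)
        p = np.array([5 / 9, 4 / 9])
        assert out.loc["S1", "shannon"] == pytest.approx(shannon(p))
        assert not np.isnan(out.loc["S1", "chao1"])
        assert np.isnan(out.loc["S1", "faith_pd"])  # no tree given


class TestPCoA:
    def _matrix(self, n=6, f=12, seed=0):
        rng = np.random.default_rng(seed)
        m = rng.dirichlet(np.ones(f), size=n)
        return pd.DataFrame(m, index=[f"S{i}" for i in range(n)],
                            columns=[f"sp{j}" for j in range(f)])

    def test_coordinates_reproduce_positive_part_of_gower_matrix(self):
        # 1 - Spearman is not guaranteed Euclidean (negative eigenvalues),
        # so the defining property is coords @ coords.T == the positive
        # semidefinite part of the double-centered matrix B
        matrix = self._matrix()
        with pytest.warns(UserWarning, match="negative eigenvalue"):
            coords, _ = pcoa_spearman(matrix)
        rho, _ = sps.spearmanr(matrix.to_numpy().T)
        d = 1.0 - rho
        n = d.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d ** 2) @ j
        evals, evecs = np.linalg.eigh((b + b.T) / 2)
        b_plus = (evecs * np.clip(evals, 0, None)) @ evecs.T
        c = coords.to_numpy()
        assert np.allclose(c @ c.T, b_plus, atol=1e-10)

    def test_matches_skbio_pcoa(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.ordination import pcoa as sk_pcoa

        matrix = self._matrix(seed=3)
        rho, _ = sps.spearmanr(matrix.to_numpy().T)
        dm = DistanceMatrix(1.0 - rho, ids=list(matrix.index))
        ours, explained = pcoa_spearman(matrix)
        theirs = sk_pcoa(dm, method="eigh")
        for k in range(2):
            a = ours.iloc[:, k].to_numpy()
            b = theirs.samples.iloc[:, k].to_numpy()
            # eigenvector sign is arbitrary
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)
        assert explained[0] == pytest.approx(
            theirs.proportion_explained.iloc[0], abs=1e-8)

    def test_explained_fractions_sum_to_one_and_decrease(self):
        _, explained = pcoa_spearman(self._matrix(seed=5))
        assert explained.sum() == pytest.approx(1.0)
        assert all(np.diff(explained) <= 1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            pcoa_spearman(self._matrix(n=2))

    def test_constant_sample_named_in_error(self):
        matrix = self._matrix()
        matrix.loc["S2"] = 1.0 / matrix.shape[1]
        with pytest.raises(ValueError, match="S2"):
            pcoa_spearman(matrix)


class TestWilcoxon:
    def test_exact_hand_case(self):
        # x entirely below y, n=m=3: only 1 of C(6,3)=20 assignments is as
        # extreme -> p = 0.05
        w, p = wilcoxon_one_sided([1, 2, 3], [4, 5, 6], "less")
        assert w == 6.0
        assert p == pytest.approx(1 / 20)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(0.5, size=6)
            for alt in ("less", "greater"):
                _, p = wilcoxon_one_sided(x, y, alt)
                ref = sps.mannwhitneyu(x, y, alternative=alt, method="exact")
                assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=15)
        y = rng.normal(0.8, size=18)
        _, p = wilcoxon_one_sided(x, y, "less")
        ref = sps.mannwhitneyu(x, y, alternative="less", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_swap_symmetry(self):
        x, y = [1.0, 3.0, 5.0, 7.0], [2.0, 4.0, 6.0]
        _, p_less = wilcoxon_one_sided(x, y, "less")
        _, p_greater = wilcoxon_one_sided(y, x, "greater")
        assert p_less == pytest.approx(p_greater)

    def test_identical_groups_warn_p_one(self):
        with pytest.warns(UserWarning):
            _, p = wilcoxon_one_sided([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_one_sided([], [1.0])


def _design(n_per_group, seed=0, sites=("X", "Y")):
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for habitat in ("domestic", "feral"):
        for _ in range(n_per_group):
            rows.append({"sample_id": f"S{i}", "site": rng.choice(sites),
                         "habitat": habitat})
            i += 1
    return pd.DataFrame(rows)


class TestAssociate:
    def _matrix(self, design, effect_feature=None, fold=4.0, seed=0, f=10):
        rng = np.random.default_rng(seed)
        base = rng.dirichlet(np.ones(f))
        rows = {}
        for r in design.itertuples():
            ab = base * np.exp(rng.normal(0, 0.3, size=f))
            if effect_feature is not None and r.habitat == "feral":
                ab[effect_feature] *= fold
            rows[r.sample_id] = ab / ab.sum()
        return pd.DataFrame(rows, index=[f"sp{j}" for j in range(f)]).T

    def test_spiked_feature_ranks_first_with_positive_sign(self):
        design = _design(12, seed=1)
        matrix = self._matrix(design, effect_feature=3, seed=1)
        out = associate(matrix, design, target="habitat")
        assert out.iloc[0]["feature"] == "sp3"
        # feral is the non-reference dummy level; 4x fold -> positive coef
        assert out.iloc[0]["coefficient"] > 0
        assert out.iloc[0]["significance"] in {"+", "++", "+++"}
        assert (out["trans_co"] == out["coefficient"]).all()

    def test_null_data_mostly_insignificant(self):
        design = _design(10, seed=2)
        matrix = self._matrix(design, seed=2)
        out = associate(matrix, design, target="habitat")
        assert (out["q_value"] < 0.05).sum() == 0

    def test_constant_feature_gets_p_one(self):
        design = _design(4, seed=3)
        matrix = self._matrix(design, seed=3)
        matrix["sp0"] = 0.1
        out = associate(matrix, design, target="habitat").set_index("feature")
        assert out.loc["sp0", "p_value"] == 1.0
        assert out.loc["sp0", "coefficient"] == 0.0

    def test_adjustment_covariate_accepted(self):
        design = _design(8, seed=4)
        matrix = self._matrix(design, effect_feature=1, seed=4)
        out = associate(matrix, design, target="habitat", adjust_for=["site"])
        assert out.iloc[0]["feature"] == "sp1"

    def test_confounded_design_rejected(self):
        design = _design(6, seed=5)
        design["site"] = np.where(design["habitat"] == "feral", "A", "B")
        matrix = self._matrix(design, seed=5)
        with pytest.raises(ValueError, match="confounded"):
            associate(matrix, design, target="habitat", adjust_for=["site"])

    def test_target_equal_adjustment_rejected(self):
        design = _design(4)
        matrix = self._matrix(design)
        with pytest.raises(ValueError):
            associate(matrix, design, target="habitat", adjust_for=["habitat"])

    def test_single_level_target_rejected(self):
        design = _design(4, seed=6)
        design["habitat"] = "domestic"
        matrix = self._matrix(design, seed=6)
        with pytest.raises(ValueError, match="single level"):
            associate(matrix, design, target="habitat")
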