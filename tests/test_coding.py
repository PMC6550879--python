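"""ROC/AUC category scoring, group comparison, PCA, and decoding harness."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lhcoding import coding, synthetic
from lhcoding.config import CodingParams
from lhcoding.datasets import CATEGORIES


def brute_force_auc(pos, neg):
    """Exhaustive pair counting with half-credit ties (independent oracle)."""
    wins = 0.0
    for p, n in itertools.product(pos, neg):
        wins += 1.0 if p > n else 0.5 if p == n else 0.0
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_identical_responses_give_half(self):
        assert coding.auc_score([2, 2], [2, 2, 2]) == pytest.approx(0.5)

    def test_perfect_separation(self):
        assert coding.auc_score([5, 6], [1, 2]) == pytest.approx(1.0)

    def test_pair_counting_example(self):
        assert coding.auc_score([2, 4], [1, 3]) == pytest.approx(0.75)

    @given(
        st.lists(st.integers(0, 5), min_size=1, max_size=4),
        st.lists(st.integers(0, 5), min_size=1, max_size=4),
    )
    @settings(deadline=None, max_examples=80)
    def test_matches_exhaustive_pair_counting(self, pos, neg):
        assert coding.auc_score(pos, neg) == pytest.approx(
            brute_force_auc(pos, neg)
        )

    @given(
        st.lists(st.floats(-5, 5), min_size=2, max_size=6),
        st.lists(st.floats(-5, 5), min_size=2, max_size=6),
    )
    @settings(deadline=None, max_examples=50)
    def test_label_flip_symmetry(self, pos, neg):
        a = coding.auc_score(pos, neg)
        b = coding.auc_score(neg, pos)
        assert a + b == pytest.approx(1.0)
        assert max(a, 1 - a) == pytest.approx(max(b, 1 - b))


class TestCategoryScores:
    def _responses(self, panel, favored="amine", strength=5.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = {}
        for t in ["T1", "T2"]:
            vals = rng.normal(0, 1, len(panel.test_odors))
            mask = panel.category_mask(favored).to_numpy()
            vals[mask] += strength
            rows[t] = vals
        return pd.DataFrame(rows, index=panel.test_odors).T

    def test_biased_type_is_informative(self):
        panel = synthetic.gen_odor_panel(36, seed=30)
        resp = self._responses(panel)
        scores = coding.auc_category_scores(resp, panel, n_shuffles=5, seed=31)
        assert scores.per_type["informative"].all()
        assert (scores.per_type["best_category"] == "amine").all()
        assert (scores.per_type["max_auc"] == 1.0).all()

    def test_flat_responses_not_informative(self):
        panel = synthetic.gen_odor_panel(36, seed=32)
        rng = np.random.default_rng(33)
        resp = pd.DataFrame(
            {f"T{i}": rng.normal(size=len(panel.test_odors)) for i in range(3)},
            index=panel.test_odors,
        ).T
        scores = coding.auc_category_scores(resp, panel, n_shuffles=5, seed=34)
        # unshuffled and shuffled maxima come from the same null: most types
        # cannot beat all five shuffles
        assert scores.per_type["informative"].mean() <= 0.5

    def test_category_bias_raises_auc_monotonically(self):
        """Generator invariant: category bias > 1 lifts that category's AUC."""
        panel = synthetic.gen_odor_panel(36, seed=35)

        def mean_auc(bias):
            rows = {}
            for s in range(6):
                tmpl = synthetic.lhon_template(
                    cell_type=f"T{s}", category_bias=bias
                )
                chosen = synthetic.template_responsive_odors(tmpl, panel, seed=s)
                rows[f"T{s}"] = [
                    10.0 if o in chosen else 0.0 for o in panel.test_odors
                ]
            resp = pd.DataFrame(rows, index=panel.test_odors).T
            scores = coding.auc_category_scores(resp, panel, seed=36)
            return scores.per_category["ester"].mean()

        assert mean_auc({"ester": 4.0}) > mean_auc({})


class TestGroupComparison:
    def test_exact_small_sample_p(self):
        scores = coding.CategoryScores(
            pd.DataFrame(
                {"max_auc": [0.1, 0.2, 0.3, 0.4]},
                index=["p1", "p2", "l1", "l2"],
            ),
            pd.DataFrame(),
            5,
        )
        groups = pd.Series({"p1": "PN", "p2": "PN", "l1": "LHON", "l2": "LHLN"})
        # direct enumeration oracle for {1,2} vs {3,4}, alternative greater:
        # all C(4,2)=6 assignments; observed U is maximal => p = 1/6
        from scipy.stats import mannwhitneyu

        res = mannwhitneyu([3, 4], [1, 2], alternative="greater")
        assert res.pvalue == pytest.approx(1 / 6)

    def test_identical_groups_no_effect(self):
        rng = np.random.default_rng(40)
        vals = rng.uniform(0.5, 1.0, 20)
        idx = [f"c{i}" for i in range(20)]
        scores = coding.CategoryScores(
            pd.DataFrame({"max_auc": vals}, index=idx), pd.DataFrame(), 5
        )
        groups = pd.Series(
            {c: g for c, g in zip(idx, ["PN", "LHLN", "LHON"] * 7)}
        )
        res = coding.group_category_comparison(scores, groups)
        assert (res["p_value"] > 0.05).all()

    def test_planted_effect_detected(self):
        """LHON-like category-biased scores beat PN-like at n = 20 types."""
        rng = np.random.default_rng(41)
        idx_pn = [f"pn{i}" for i in range(20)]
        idx_lhon = [f"on{i}" for i in range(20)]
        idx_lhln = [f"ln{i}" for i in range(20)]
        scores = coding.CategoryScores(
            pd.DataFrame(
                {
                    "max_auc": np.concatenate(
                        [
                            rng.uniform(0.5, 0.7, 20),  # PN
                            rng.uniform(0.75, 1.0, 20),  # LHON, planted shift
                            rng.uniform(0.5, 0.7, 20),  # LHLN
                        ]
                    )
                },
                index=idx_pn + idx_lhon + idx_lhln,
            ),
            pd.DataFrame(),
            5,
        )
        groups = pd.Series(
            {**{c: "PN" for c in idx_pn}, **{c: "LHON" for c in idx_lhon},
             **{c: "LHLN" for c in idx_lhln}}
        )
        res = coding.group_category_comparison(scores, groups)
        assert res.loc["LHON > PN", "p_value"] < 0.05


class TestPca:
    def test_one_axis_data_single_component(self):
        t = np.linspace(0, 1, 12)
        mat = pd.DataFrame(
            np.outer([1.0, 2.0, -1.0], t),
            index=["c1", "c2", "c3"],
            columns=pd.MultiIndex.from_product(
                [["o1", "o2", "o3"], range(4)], names=["odor_id", "bin_start"]
            ),
        )
        res = coding.pca_population(mat)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_known_covariance_eigenvalues(self):
        """2-D correlated toy data: eigenvalues match the analytic values."""
        rng = np.random.default_rng(50)
        cov = np.array([[3.0, 1.0], [1.0, 2.0]])
        L = np.linalg.cholesky(cov)
        obs = (L @ rng.normal(size=(2, 4000))).T  # (obs, 2 cells)
        mat = pd.DataFrame(
            obs.T,
            index=["c1", "c2"],
            columns=pd.MultiIndex.from_product(
                [[f"o{i}" for i in range(400)], range(10)],
                names=["odor_id", "bin_start"],
            ),
        )
        res = coding.pca_population(mat)
        emp = np.cov(obs, rowvar=False)
        expected = np.linalg.eigvalsh(emp)[::-1]
        ratio = res.explained_variance_ratio
        np.testing.assert_allclose(
            ratio, expected / expected.sum(), atol=1e-8
        )
        # analytic eigenvalues of the population covariance for reference
        analytic = np.linalg.eigvalsh(cov)[::-1]
        np.testing.assert_allclose(
            ratio, analytic / analytic.sum(), atol=0.05
        )

    def test_large_kappa_matches_unnormalized(self):
        rng = np.random.default_rng(51)
        mat = pd.DataFrame(
            rng.normal(size=(3, 20)),
            index=["c1", "c2", "c3"],
            columns=pd.MultiIndex.from_product(
                [["o1", "o2"], range(10)], names=["odor_id", "bin_start"]
            ),
        )
        plain = coding.pca_population(mat, normalize=False)
        soft = coding.pca_population(mat, normalize=True, kappa=1e9)
        np.testing.assert_allclose(
            plain.explained_variance_ratio, soft.explained_variance_ratio, atol=1e-6
        )

    def test_constant_matrix_rejected(self):
        mat = pd.DataFrame(
            np.ones((2, 12)),
            index=["c1", "c2"],
            columns=pd.MultiIndex.from_product(
                [["o1", "o2", "o3"], range(4)], names=["odor_id", "bin_start"]
            ),
        )
        with pytest.raises(ValueError):
            coding.pca_population(mat)


@pytest.fixture(scope="module")
def tiny_decode_setup():
    panel = synthetic.gen_odor_panel(6, seed=60)
    templates = [
        synthetic.lhon_template(cell_type=f"T{i}", category_bias={c: 4.0})
        for i, c in enumerate(CATEGORIES[:4])
    ]
    ds = synthetic.gen_spike_dataset(templates, 2, panel, seed=61)
    params = CodingParams(
        runs_per_size=6, response_bins=2, max_population=4,
        c_grid=tuple(10.0 ** e for e in range(-4, 2)),
    )
    return ds, params


class TestDecoding:

    def test_shuffled_identity_accuracy_at_chance(self, tiny_decode_setup):
        ds, params = tiny_decode_setup
        res = coding.population_decode(
            ds, task="identity", params=params, population_sizes=[3],
            seed=62, shuffle=True,
        )
        accs = res.accuracy["mean_accuracy"]
        # chance = 1/6; each estimate averages 3 eval runs of 4-fold CV on 24
        # trials; allow a generous binomial envelope
        assert (accs < res.chance + 0.22).all()

    def test_separable_responses_decode_well(self, tiny_decode_setup):
        """Distinct deterministic tuning: accuracy far above chance at N=4."""
        ds, params = tiny_decode_setup
        res = coding.population_decode(
            ds, task="identity", params=params, population_sizes=[4], seed=63
        )
        assert res.accuracy["mean_accuracy"].max() > 3 * res.chance

    def test_population_size_exceeding_types_rejected(self, tiny_decode_setup):
        ds, params = tiny_decode_setup
        with pytest.raises(ValueError, match="exceeds"):
            coding.population_decode(
                ds, params=params, population_sizes=[99], seed=64
            )

    def test_bookkeeping_responses_per_bin(self, tiny_decode_setup):
        ds, params = tiny_decode_setup
        res = coding.population_decode(
            ds, task="category", params=params, population_sizes=[1], seed=65
        )
        assert res.responses_per_cell_per_bin == 6 * 4
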