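"""Normalization, the exact test, clustering and cross-species correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirpipe.expression import (
    CountMatrix,
    _exact_nb_pvalue_impl,
    all_pairwise_tests,
    cpm,
    estimate_common_dispersion,
    exact_test_pair,
    hierarchical_cluster,
    log2_ratio_matrix,
    spearman_matrix,
    tmm_factors,
)
from mirpipe.io import Library, SampleSheet


def _sheet(stages=("egg", "larva"), reps=3):
    libs = [
        Library(f"{s}_r{r}", s, r) for s in stages for r in range(1, reps + 1)
    ]
    return SampleSheet(libs)


def _matrix(values, stages=("egg", "larva"), reps=3, index=None):
    sheet = _sheet(stages, reps)
    df = pd.DataFrame(
        values, columns=sheet.library_ids,
        index=index or [f"m{i}" for i in range(len(values))],
    )
    return CountMatrix(df, sheet)


class TestCpm:
    def test_single_column_values(self):
        sheet = SampleSheet([Library("L1", "egg", 1)])
        m = CountMatrix(pd.DataFrame({"L1": [5, 5]}, index=["a", "b"]), sheet)
        assert cpm(m)["L1"].tolist() == [500000.0, 500000.0]

    def test_depth_invariance(self):
        m1 = _matrix(np.tile([[10, 20, 30, 10, 20, 30]], (4, 1)) * [[1]])
        doubled = m1.counts.copy()
        doubled["egg_r1"] *= 2
        m2 = CountMatrix(doubled, m1.sheet)
        pd.testing.assert_series_equal(cpm(m1)["egg_r1"], cpm(m2)["egg_r1"])

    def test_norm_factor_divides(self):
        sheet = SampleSheet([Library("L1", "egg", 1)])
        m = CountMatrix(
            pd.DataFrame({"L1": [5, 5]}, index=["a", "b"]), sheet,
            norm_factors=pd.Series({"L1": 2.0}),
        )
        assert cpm(m)["L1"].tolist() == [250000.0, 250000.0]

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.integers(0, 500, size=(30, 6)))
        assert np.allclose(cpm(m, use_norm_factors=False).sum(axis=0), 1e6)

    def test_zero_column_rejected(self):
        m = _matrix(np.zeros((3, 6), dtype=int))
        with pytest.raises(ValueError):
            cpm(m)


def _tmm_oracle(obs, ref):
    """The TMM definition computed longhand (no trimming shortcuts)."""
    obs, ref = np.asarray(obs, float), np.asarray(ref, float)
    n_o, n_r = obs.sum(), ref.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2((obs / n_o) / (ref / n_r))
        a = 0.5 * np.log2((obs / n_o) * (ref / n_r))
    keep = np.isfinite(m) & np.isfinite(a)
    m, a, o, r = m[keep], a[keep], obs[keep], ref[keep]
    n = len(m)
    lo_m, hi_m = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
    lo_a, hi_a = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    w = (n_o - o) / (n_o * o) + (n_r - r) / (n_r * r)
    return 2 ** (np.sum(m[sel] / w[sel]) / np.sum(1 / w[sel]))


class TestTMM:
    def test_identical_columns_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.integers(1, 400, 50)
        df = pd.DataFrame({"a": col, "b": col})
        assert np.allclose(tmm_factors(df), 1.0)

    def test_pure_depth_difference_unit_factors(self):
        rng = np.random.default_rng(2)
        col = rng.integers(1, 400, 50)
        df = pd.DataFrame({"a": col, "b": col * 2})
        assert np.allclose(tmm_factors(df), 1.0, atol=1e-6)

    def test_compositional_shift_recovered(self):
        """10 % of genes 8-fold up in B: the factor ratio must absorb the
        compositional distortion to within 10 % of the longhand value."""
        rng = np.random.default_rng(3)
        base = rng.integers(50, 500, 200)
        b = base.copy()
        b[:20] *= 8
        df = pd.DataFrame({"A": base, "B": b})
        f = tmm_factors(df, ref_column="A")
        oracle_fb = _tmm_oracle(b, base)
        # same geometric-mean-1 rescale as the implementation
        expected = np.array([1.0, oracle_fb])
        expected /= np.exp(np.mean(np.log(expected)))
        assert f["B"] / f["A"] == pytest.approx(expected[1] / expected[0], rel=0.10)
        # direction: B's inflated composition deflates its effective size
        assert f["B"] < 1.0 < f["A"]

    def test_all_zero_column_warns_factor_one(self):
        df = pd.DataFrame({"a": [5, 9, 2], "b": [0, 0, 0]})
        with pytest.warns(UserWarning):
            f = tmm_factors(df)
        assert f["b"] == pytest.approx(1.0)


class TestExactTest:
    def test_identical_groups_p_one(self):
        vals = np.tile([[40, 40, 40, 40, 40, 40]], (5, 1))
        m = _matrix(vals)
        res = exact_test_pair(m, "egg", "larva", dispersion=0.0)
        assert all(r.p_value == 1.0 for r in res)
        assert all(r.log2_fold_change == 0.0 for r in res)

    def test_extreme_split_tiny_p(self):
        """1000 vs 0 in deep balanced libraries: exact binomial tail."""
        rng = np.random.default_rng(4)
        background = rng.integers(100, 200, size=(40, 6))
        vals = np.vstack([background, [[1000, 1000, 1000, 0, 0, 0]]])
        m = _matrix(vals)
        res = exact_test_pair(m, "egg", "larva", dispersion=0.0)
        assert res[-1].p_value < 1e-6
        assert res[-1].log2_fold_change > 5

    def test_binomial_limit_matches_longhand(self):
        """With dispersion 0 and equal depths the conditional law is
        Binomial(s, 1/2); compare one split against the closed form."""
        ya, yb = 30, 10
        p_mine = _exact_nb_pvalue_impl(ya, yb, 3, 3, 0.0)
        pmf = stats.binom.pmf(np.arange(41), 40, 0.5)
        p_hand = pmf[pmf <= pmf[30] + 1e-15].sum()
        assert p_mine == pytest.approx(p_hand, rel=1e-9)

    def test_symmetry_in_group_order(self):
        rng = np.random.default_rng(5)
        vals = rng.integers(0, 300, size=(25, 6))
        m = _matrix(vals)
        ab = exact_test_pair(m, "egg", "larva", dispersion=0.1)
        ba = exact_test_pair(m, "larva", "egg", dispersion=0.1)
        for x, y in zip(ab, ba):
            assert x.p_value == pytest.approx(y.p_value, rel=1e-9)
            assert x.log2_fold_change == pytest.approx(-y.log2_fold_change, rel=1e-9)

    def test_all_zero_gene(self):
        vals = np.vstack([np.tile([50], (1, 6)), np.zeros((1, 6), dtype=int)])
        m = _matrix(vals)
        res = exact_test_pair(m, "egg", "larva", dispersion=0.0)
        assert res[1].p_value == 1.0 and res[1].log2_fold_change == 0.0

    def test_bh_adjustment_by_hand(self):
        """BH on (0.01, 0.02, 0.04) -> (0.03, 0.03, 0.04)."""
        from statsmodels.stats.multitest import multipletests

        fdr = multipletests([0.01, 0.02, 0.04], method="fdr_bh")[1]
        assert np.allclose(fdr, [0.03, 0.03, 0.04])

    def test_bh_monotone_and_bounded(self):
        rng = np.random.default_rng(6)
        vals = rng.integers(0, 200, size=(60, 6))
        res = exact_test_pair(_matrix(vals), "egg", "larva", dispersion=0.1)
        df = pd.DataFrame({"p": [r.p_value for r in res], "q": [r.fdr for r in res]})
        df = df.sort_values("p")
        assert (df.q.diff().dropna() >= -1e-12).all()
        assert (df.q <= 1).all() and (df.q >= df.p - 1e-12).all()

    def test_dispersion_auto_moment_estimate(self):
        rng = np.random.default_rng(7)
        mu = rng.uniform(50, 500, 300)
        phi = 0.15
        r = 1 / phi
        vals = rng.negative_binomial(r, r / (r + mu[:, None]), size=(300, 6))
        m = _matrix(vals)
        est = estimate_common_dispersion(m)
        assert est == pytest.approx(phi, rel=0.5)


class TestRatiosAndClustering:
    def test_log2_ratio_values(self):
        # balanced library sizes so composition does not shift the cpm
        vals = np.array(
            [[40, 40, 40, 40, 40, 40],
             [80, 80, 80, 20, 20, 20],
             [20, 20, 20, 80, 80, 80]]
        )
        m = _matrix(vals)
        r = log2_ratio_matrix(m, [("egg", "larva")])
        assert r.iloc[0, 0] == pytest.approx(0.0, abs=1e-6)
        assert r.iloc[1, 0] == pytest.approx(2.0, abs=0.05)  # a ~= 4b
        rswap = log2_ratio_matrix(m, [("larva", "egg")])
        assert rswap.iloc[1, 0] == pytest.approx(-r.iloc[1, 0])

    def test_identical_rows_merge_first(self):
        df = pd.DataFrame(
            [[1, 2, 3], [1, 2, 3], [9, 9, 9]], index=["a", "b", "c"]
        )
        order, Z = hierarchical_cluster(df)
        # the identical pair merges first (zero height) and sits adjacent
        assert Z[0, 2] == 0.0 and {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert abs(order.index("a") - order.index("b")) == 1

    def test_planted_three_groups_recovered(self):
        """Three planted profile shapes come out as three clades at the
        3-cluster cut."""
        from scipy.cluster.hierarchy import fcluster

        rng = np.random.default_rng(8)
        shapes = {
            0: np.array([2.0, 2.5, 3.0, 1.0]),
            1: np.array([3.0, -2.5, -3.0, -1.0]),
            2: np.array([-3.0, -2.0, 3.0, 2.5]),
        }
        rows, labels = [], []
        for g, shape in shapes.items():
            for i in range(8):
                rows.append(shape + rng.normal(0, 0.25, 4))
                labels.append(g)
        df = pd.DataFrame(rows, index=[f"g{g}_{i}" for i, g in enumerate(labels)])
        _, Z = hierarchical_cluster(df)
        cut = fcluster(Z, t=3, criterion="maxclust")
        # each planted group maps to exactly one clade
        for g in shapes:
            clades = {cut[i] for i, l in enumerate(labels) if l == g}
            assert len(clades) == 1


class TestSpearman:
    def _grids(self, xa, xb):
        a = pd.DataFrame({"A1": xa})
        b = pd.DataFrame({"B1": xb})
        return spearman_matrix(a, b, [(i, i) for i in a.index])

    def test_identical_profiles_rho_one(self):
        x = np.arange(20).astype(float)
        g = self._grids(pd.Series(x), pd.Series(x * 3 + 1))
        assert g.rho[0] == pytest.approx(1.0)

    def test_reversed_ranks_rho_minus_one(self):
        x = pd.Series(np.arange(20).astype(float))
        g = self._grids(x, x[::-1].reset_index(drop=True))
        assert g.rho[0] == pytest.approx(-1.0)

    def test_too_few_pairs_flagged(self):
        x = pd.Series([1.0, 2.0, 3.0])
        g = self._grids(x, x)
        assert not g.defined[0] and np.isnan(g.rho[0])

    def test_independent_profiles_small_rho(self):
        """|rho| < 0.3 in >=95 % of seeds for independent 68-pair profiles."""
        ok = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            a = pd.DataFrame({"A1": rng.normal(size=68)})
            b = pd.DataFrame({"B1": rng.normal(size=68)})
            g = spearman_matrix(a, b, [(i, i) for i in a.index])
            if abs(g.rho[0]) < 0.3:
                ok += 1
        assert ok / n_seeds >= 0.95
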