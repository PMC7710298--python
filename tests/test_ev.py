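"""EV proteomics normalization, enrichment filter, PCA, blot statistics."""

import numpy as np
import pandas as pd
import pytest

from pxopipe.ev import (
    cd9_rescale,
    cohort_ks_report,
    enrichment_filter,
    ks_two_sample,
    log_quantile_normalize,
    pca_svd,
)


class TestQuantileNormalize:
    def test_identical_columns_unchanged_up_to_transform(self):
        df = pd.DataFrame({"a": [1.0, 3.0, 7.0], "b": [1.0, 3.0, 7.0]})
        out = log_quantile_normalize(df)
        np.testing.assert_allclose(out["a"], np.log2(df["a"] + 1))
        np.testing.assert_allclose(out["a"], out["b"])

    def test_permuted_columns_identical_multisets(self):
        df = pd.DataFrame({"a": [1.0, 5.0, 9.0, 2.0], "b": [9.0, 2.0, 1.0, 5.0]})
        out = log_quantile_normalize(df, log=False)
        assert sorted(out["a"]) == pytest.approx(sorted(out["b"]))

    def test_hand_computed_3x3(self):
        """Mean-rank profile computed by hand for a 3x3 matrix.

        Columns sorted: (2,4,6), (1,3,5), (3,6,9) -> mean profile (2,13/3,20/3);
        each value is replaced by the mean profile entry at its within-column
        rank.
        """
        df = pd.DataFrame(
            {"s1": [4.0, 2.0, 6.0], "s2": [1.0, 5.0, 3.0], "s3": [9.0, 6.0, 3.0]},
            index=["p1", "p2", "p3"],
        )
        out = log_quantile_normalize(df, log=False)
        profile = [2.0, 13.0 / 3.0, 20.0 / 3.0]
        expected = pd.DataFrame(
            {
                "s1": [profile[1], profile[0], profile[2]],
                "s2": [profile[0], profile[2], profile[1]],
                "s3": [profile[2], profile[1], profile[0]],
            },
            index=df.index,
        )
        pd.testing.assert_frame_equal(out, expected)

    def test_ties_get_average_quantile(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = log_quantile_normalize(df, log=False)
        profile = np.sort(df.to_numpy(), axis=0).mean(axis=1)  # (1.5, 2.5, 5.5)
        # the two tied values share the average of profile[0] and profile[1]
        assert out["a"].iloc[0] == pytest.approx((profile[0] + profile[1]) / 2)
        assert out["a"].iloc[0] == out["a"].iloc[1]

    def test_single_column_warns_noop(self):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            out = log_quantile_normalize(df, log=False)
        np.testing.assert_allclose(out["a"], df["a"])


def _matrix(tumor, ref):
    """Build a proteins x samples frame from per-protein tumor/ref rows."""
    tumor = np.atleast_2d(np.asarray(tumor, dtype=float))
    ref = np.atleast_2d(np.asarray(ref, dtype=float))
    cols = [f"T{i}" for i in range(tumor.shape[1])] + [
        f"R{i}" for i in range(ref.shape[1])
    ]
    data = np.hstack([tumor, ref])
    roles = {c: ("tumor" if c.startswith("T") else "reference") for c in cols}
    idx = [f"prot{i}" for i in range(data.shape[0])]
    return pd.DataFrame(data, index=idx, columns=cols), roles


class TestEnrichmentFilter:
    def test_planted_fold_kept(self):
        m, roles = _matrix([[40, 44, 38, 41, 39, 42]], [[10, 10]])
        assert enrichment_filter(m, roles) == ["prot0"]

    def test_unit_fold_removed(self):
        m, roles = _matrix([[10, 10, 10, 10, 10, 10]], [[10, 10]])
        assert enrichment_filter(m, roles) == []

    def test_boundary_four_of_six_at_exactly_twofold_kept(self):
        # detected in exactly 4/6 lines, mean tumor exactly 2x mean reference
        m, roles = _matrix([[30, 30, 30, 30, 0, 0]], [[10, 10]])
        assert m.loc["prot0", ["T0", "T1", "T2", "T3"]].mean() == 30
        assert enrichment_filter(m, roles, fold=2.0, prevalence=4) == ["prot0"]
        assert enrichment_filter(m, roles, fold=2.0, prevalence=5) == []

    def test_monotone_in_fold_and_prevalence(self):
        rng = np.random.default_rng(0)
        m, roles = _matrix(
            rng.uniform(5, 60, size=(40, 6)), rng.uniform(5, 30, size=(40, 2))
        )
        base = set(enrichment_filter(m, roles, fold=1.5, prevalence=3))
        assert set(enrichment_filter(m, roles, fold=2.5, prevalence=3)) <= base
        assert set(enrichment_filter(m, roles, fold=1.5, prevalence=5)) <= base

    def test_no_reference_rejected(self):
        m, roles = _matrix([[1, 1, 1, 1, 1, 1]], [[1.0]])
        roles = {k: "tumor" for k in roles}
        with pytest.raises(ValueError):
            enrichment_filter(m, roles)


class TestPCA:
    def test_two_samples_pc1_explains_all(self):
        df = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0], "s2": [2.0, 4.0, 1.0]}, index=list("abc")
        )
        res = pca_svd(df)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(6, 4)))
        res = pca_svd(df, scale=False)
        x = df.to_numpy().T
        x = x - x.mean(axis=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, x, atol=1e-10)

    def test_scores_match_covariance_eigendecomposition(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(5, 4)))
        res = pca_svd(df, scale=False)
        x = df.to_numpy().T
        x = x - x.mean(axis=0)
        cov = x.T @ x
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        svals = np.array(
            [res.scores.iloc[:, i].pow(2).sum() for i in range(res.scores.shape[1])]
        )
        np.testing.assert_allclose(svals, evals[: svals.size], atol=1e-8)

    def test_explained_variance_sums_to_one_nonincreasing(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(10, 5)))
        r = pca_svd(df).explained_variance_ratio
        assert r.sum() == pytest.approx(1.0)
        assert np.all(np.diff(r) <= 1e-12)

    def test_constant_matrix_rejected(self):
        df = pd.DataFrame(np.ones((4, 3)))
        with pytest.raises(ValueError):
            pca_svd(df)


class TestCD9Rescale:
    def _blot(self, ratios, cd9):
        patients = [f"p{i}" for i in range(len(cd9))]
        cd9 = np.asarray(cd9, dtype=float)
        data = {"CD9": cd9}
        for name, r in ratios.items():
            data[name] = np.asarray(r, dtype=float) * cd9
        return pd.DataFrame(data, index=patients).T

    def test_median_is_exactly_100_odd_cohort(self):
        blot = self._blot({"m": [0.3, 0.7, 1.1, 0.2, 0.9]}, [50, 80, 120, 60, 90])
        out = cd9_rescale(blot)
        assert float(out.loc["m"].median()) == 100.0

    def test_median_close_even_cohort(self):
        blot = self._blot({"m": [0.3, 0.7, 1.1, 0.2]}, [50, 80, 120, 60])
        out = cd9_rescale(blot)
        assert float(out.loc["m"].median()) == pytest.approx(100.0, rel=1e-12)

    def test_equal_patients_all_100(self):
        blot = self._blot({"m": [0.5, 0.5, 0.5]}, [70, 70, 70])
        out = cd9_rescale(blot)
        np.testing.assert_allclose(out.loc["m"], 100.0)

    def test_cd9_scale_invariance(self):
        ratios = {"m": [0.3, 0.7, 1.1, 0.2, 0.9]}
        b1 = self._blot(ratios, [50, 80, 120, 60, 90])
        b2 = b1.copy()
        b2.loc["CD9"] *= 2.0
        b2.loc["m"] *= 1.0  # marker signals unchanged; ratios halve
        o1, o2 = cd9_rescale(b1), cd9_rescale(b2)
        pd.testing.assert_frame_equal(o1, o2)

    def test_zero_cd9_rejected(self):
        blot = self._blot({"m": [0.5, 0.5]}, [70, 70])
        blot.loc["CD9", "p0"] = 0.0
        with pytest.raises(ValueError):
            cd9_rescale(blot)

    def test_missing_cd9_row_rejected(self):
        blot = self._blot({"m": [0.5, 0.5]}, [70, 70]).drop(index="CD9")
        with pytest.raises(ValueError):
            cd9_rescale(blot)


def brute_force_ks_p(x, y):
    """Exact two-sided p-value by enumerating all assignments of the pooled
    sample into groups of sizes |x| and |y| (permutation null, no ties)."""
    import itertools

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, m = x.size, y.size

    def d_stat(a, b):
        allv = np.sort(np.concatenate([a, b]))
        fa = np.searchsorted(np.sort(a), allv, side="right") / a.size
        fb = np.searchsorted(np.sort(b), allv, side="right") / b.size
        return np.max(np.abs(fa - fb))

    observed = d_stat(x, y)
    count = total = 0
    idx = range(n + m)
    for comb in itertools.combinations(idx, n):
        mask = np.zeros(n + m, dtype=bool)
        mask[list(comb)] = True
        d = d_stat(pooled[mask], pooled[~mask])
        count += d >= observed - 1e-12
        total += 1
    return count / total


class TestKS:
    def test_identical_samples(self):
        r = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0
        assert r.pvalue == 1.0

    def test_fully_separated_small_samples(self):
        r = ks_two_sample([1, 2, 3], [4, 5, 6], mode="exact")
        assert r.statistic == 1.0
        assert r.pvalue == pytest.approx(2.0 / 20.0)  # 2 / C(6,3)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_permutation_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=5)
        y = rng.normal(0.5, 1.0, size=6)
        r = ks_two_sample(x, y, mode="exact")
        assert r.pvalue == pytest.approx(brute_force_ks_p(x, y), abs=1e-10)

    def test_exact_close_to_asymptotic_at_n50(self):
        """Median relative gap between exact and asymptotic p under the null
        stays below 10% at n=m=50 (the asymptotic form is known to deviate
        more in the deep tail, hence the median over draws)."""
        rng = np.random.default_rng(7)
        rels = []
        for _ in range(30):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            pe = ks_two_sample(x, y, mode="exact").pvalue
            pa = ks_two_sample(x, y, mode="asymptotic").pvalue
            rels.append(abs(pa - pe) / pe)
        assert np.median(rels) < 0.10

    def test_null_rejection_rate_calibrated(self):
        """Type-I error ~5% under the null (coprime sizes densify the exact
        p-value lattice)."""
        rng = np.random.default_rng(0)
        rejections = 0
        for _ in range(500):
            x = rng.normal(size=29)
            y = rng.normal(size=37)
            rejections += ks_two_sample(x, y).pvalue < 0.05
        assert 0.03 <= rejections / 500 <= 0.07

    def test_pvalue_in_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            r = ks_two_sample(rng.normal(size=8), rng.normal(size=12))
            assert 0.0 <= r.pvalue <= 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestCohortReport:
    def test_report_shape_and_medians(self):
        patients = [f"p{i}" for i in range(10)]
        cohorts = {p: ("A" if i < 5 else "B") for i, p in enumerate(patients)}
        rng = np.random.default_rng(4)
        rescaled = pd.DataFrame(
            rng.uniform(50, 200, size=(2, 10)), index=["m1", "m2"], columns=patients
        )
        rep = cohort_ks_report(rescaled, cohorts, "A", "B")
        assert list(rep.index) == ["m1", "m2"]
        assert {"D", "pvalue", "median_A", "median_B"} <= set(rep.columns)
        assert ((rep["pvalue"] >= 0) & (rep["pvalue"] <= 1)).all()
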