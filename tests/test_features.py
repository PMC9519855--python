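"""Tests for KMO screening, imputation, PCA reduction and outlier masks."""

import numpy as np
import pandas as pd
import pytest

from rhythmcomp import features as feat


def kmo_oracle_3x3(R):
    """Independent oracle: 3-variable partial correlations in closed form."""
    idx = [0, 1, 2]
    partial = np.eye(3)
    for i in idx:
        for j in idx:
            if i == j:
                continue
            k = ({0, 1, 2} - {i, j}).pop()
            num = R[i, j] - R[i, k] * R[j, k]
            den = np.sqrt((1 - R[i, k] ** 2) * (1 - R[j, k] ** 2))
            partial[i, j] = num / den
    per_task = {}
    r2 = R**2 - np.eye(3)  # off-diagonal squares
    u2 = partial**2 - np.eye(3)
    for i in idx:
        per_task[i] = r2[i].sum() / (r2[i].sum() + u2[i].sum())
    overall = r2.sum() / (r2.sum() + u2.sum())
    return overall, per_task


class TestKMO:
    def test_two_task_battery_is_exactly_half(self):
        for r in (0.3, -0.6, 0.95):
            R = np.array([[1.0, r], [r, 1.0]])
            rep = feat.kmo(R)
            assert rep.overall_msa == pytest.approx(0.5, abs=1e-12)

    def test_three_task_fixture_matches_partial_correlation_oracle(self):
        R = np.array(
            [[1.0, 0.55, 0.30], [0.55, 1.0, 0.45], [0.30, 0.45, 1.0]]
        )
        rep = feat.kmo(R)
        overall, per_task = kmo_oracle_3x3(R)
        assert rep.overall_msa == pytest.approx(overall, abs=1e-10)
        for i, task in enumerate(rep.per_task_msa):
            assert rep.per_task_msa[task] == pytest.approx(per_task[i], abs=1e-10)

    def test_low_msa_task_listed_for_exclusion(self):
        # third variable nearly independent of a tight pair -> low MSA for it
        R = np.array([[1.0, 0.9, 0.05], [0.9, 1.0, 0.02], [0.05, 0.02, 1.0]])
        rep = feat.kmo(pd.DataFrame(R, columns=list("abc"), index=list("abc")))
        low = [t for t, m in rep.per_task_msa.items() if m < 0.5]
        assert set(rep.excluded_tasks) == set(low) and "c" in rep.excluded_tasks

    def test_msa_bounded_in_unit_interval(self, rng):
        for _ in range(10):
            A = rng.standard_normal((40, 5))
            R = np.corrcoef(A, rowvar=False)
            rep = feat.kmo(R)
            assert 0 <= rep.overall_msa <= 1
            assert all(0 <= m <= 1 for m in rep.per_task_msa.values())

    def test_non_symmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            feat.kmo(np.array([[1.0, 0.5], [0.2, 1.0]]))


class TestKnnImpute:
    def test_duplicate_row_donates_its_value(self):
        df = pd.DataFrame(
            {
                "a": [1.0, 1.0, 8.0, 4.0],
                "b": [2.0, 2.0, 9.0, 5.0],
                "c": [3.0, np.nan, 10.0, 6.0],
            }
        )
        out = feat.knn_impute(df, k=1)
        assert out.loc[1, "c"] == pytest.approx(3.0)

    def test_k_equal_all_complete_rows_gives_column_mean(self):
        df = pd.DataFrame(
            {
                "a": [1.0, 2.0, 3.0, 1.5],
                "b": [4.0, 5.0, 6.0, np.nan],
            }
        )
        out = feat.knn_impute(df, k=3)
        assert out.loc[3, "b"] == pytest.approx(np.mean([4.0, 5.0, 6.0]))

    def test_six_row_fixture_matches_brute_force_neighbour_search(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(6, 4)), columns=list("abcd"))
        df.loc[2, "c"] = np.nan
        out = feat.knn_impute(df, k=2)
        # brute force on z-scaled observed columns
        mu, sd = df.mean(), df.std(ddof=1)
        Z = (df - mu) / sd
        target = Z.loc[2, ["a", "b", "d"]].to_numpy()
        dists = {}
        for r in [0, 1, 3, 4, 5]:
            other = Z.loc[r, ["a", "b", "d"]].to_numpy()
            dists[r] = np.sqrt(np.mean((target - other) ** 2))
        nearest = sorted(dists, key=dists.get)[:2]
        assert out.loc[2, "c"] == pytest.approx(df.loc[nearest, "c"].mean())

    def test_no_complete_rows_rejected(self):
        df = pd.DataFrame({"a": [np.nan, 1.0], "b": [1.0, np.nan]})
        with pytest.raises(ValueError):
            feat.knn_impute(df, k=1)


class TestPCAReduce:
    def test_rank_one_battery(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        df = pd.DataFrame({"t1": x, "t2": 2 * x + 3})
        res = feat.pca_reduce(df)
        assert res.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-10)
        assert res.retained == 1

    def test_scale_invariance_of_correlation_pca(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        res1 = feat.pca_reduce(df)
        df2 = df.copy()
        df2["b"] *= 10.0
        res2 = feat.pca_reduce(df2)
        assert np.allclose(res1.eigenvalues, res2.eigenvalues)
        assert np.allclose(res1.scores.to_numpy(), res2.scores.to_numpy())

    def test_eigenvalues_match_svd_oracle(self):
        rng = np.random.default_rng(2)
        latent = rng.normal(size=(60, 2))
        df = pd.DataFrame(
            latent @ rng.normal(size=(2, 5)) + 0.4 * rng.normal(size=(60, 5)),
            columns=[f"t{i}" for i in range(5)],
        )
        res = feat.pca_reduce(df)
        Z = (df - df.mean()) / df.std(ddof=1)
        sv = np.linalg.svd(Z.to_numpy() / np.sqrt(len(df) - 1), compute_uv=False)
        assert np.allclose(np.sort(res.eigenvalues), np.sort(sv**2), atol=1e-8)
        # loadings agree with the oracle eigenvectors up to sign
        R = np.corrcoef(Z.to_numpy(), rowvar=False)
        for c in range(5):
            v = res.loadings[:, c]
            assert np.allclose(R @ v, res.eigenvalues[c] * v, atol=1e-8)

    def test_reconstruction_and_score_orthogonality(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(80, 5)), columns=list("abcde"))
        res = feat.pca_reduce(df, score_components=5)
        R = np.corrcoef(((df - df.mean()) / df.std(ddof=1)).to_numpy(), rowvar=False)
        recon = res.loadings @ np.diag(res.eigenvalues) @ res.loadings.T
        assert np.allclose(recon, R, atol=1e-8)
        S = res.scores.to_numpy()
        C = np.cov(S, rowvar=False)
        assert np.allclose(C - np.diag(np.diag(C)), 0, atol=1e-8)

    def test_eigenvalues_sum_to_task_count(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(30, 6)))
        res = feat.pca_reduce(df)
        assert res.eigenvalues.sum() == pytest.approx(6.0)

    def test_sign_orientation_convention(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        df = pd.DataFrame({f"t{i}": x + 0.3 * rng.normal(size=50) for i in range(4)})
        neg = feat.pca_reduce(df, orient="negative")
        pos = feat.pca_reduce(df, orient="positive")
        assert neg.loadings[:, 0].sum() <= 0 <= pos.loadings[:, 0].sum()

    def test_zero_variance_task_rejected_by_name(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "dead": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="dead"):
            feat.pca_reduce(df)


class TestLoadingCutoff:
    @pytest.mark.parametrize(
        "n,expected", [(5, 0.4472135954999579), (1, 1.0), (4, 0.5)]
    )
    def test_square_root_rule(self, n, expected):
        assert feat.loading_cutoff(n) == pytest.approx(expected, abs=1e-12)

    def test_five_tasks_rounds_to_045(self):
        assert round(feat.loading_cutoff(5), 2) == 0.45


class TestCiOutlierMask:
    def test_constant_vector_removes_nothing(self):
        assert feat.ci_outlier_mask(np.full(10, 3.0)).all()

    def test_far_outlier_removed(self, rng):
        x = rng.standard_normal(200)
        x[17] = 5.0 * x.std() + x.mean()
        keep = feat.ci_outlier_mask(x)
        assert not keep[17]

    def test_boundary_value_retained_under_strict_rule(self):
        from scipy.optimize import brentq

        base = np.array([-1.0, 1.0] * 8)

        def gap(c):
            v = np.append(base, c)
            return c - (v.mean() + 1.96 * v.std(ddof=1))

        c = brentq(gap, 1.0, 50.0)  # lands on mean + 1.96 SD
        just_inside = c * (1 - 1e-6)
        assert feat.ci_outlier_mask(np.append(base, just_inside))[-1]
        clearly_outside = c * 1.05
        assert gap(clearly_outside) > 0  # still beyond its own sample's bound
        assert not feat.ci_outlier_mask(np.append(base, clearly_outside))[-1]


class TestAssemblePredictors:
    @staticmethod
    def _inputs(n=30, seed=0):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"P{i:03d}" for i in range(n)], name="participant_id")
        perc = pd.DataFrame(rng.normal(size=(n, 5)), index=idx)
        tap = pd.DataFrame(rng.normal(size=(n, 8)), index=idx)
        p_pca = feat.pca_reduce(perc, score_components=2)
        t_pca = feat.pca_reduce(tap)
        unpaced = pd.Series(rng.normal(size=n) * 0.01 + 0.05, index=idx)
        return p_pca, t_pca, unpaced

    def test_unpaced_column_is_z_normalized(self):
        p_pca, t_pca, unpaced = self._inputs()
        res = feat.assemble_predictors(p_pca, t_pca, unpaced)
        col = res.predictors["unpaced_motor_var_z"]
        if not res.outlier_flags["unpaced_motor_var_z"].any():
            assert col.mean() == pytest.approx(0.0, abs=1e-10)
            assert col.std(ddof=1) == pytest.approx(1.0, rel=1e-9)

    def test_schema_has_exactly_four_predictors(self):
        res = feat.assemble_predictors(*self._inputs())
        assert tuple(res.predictors.columns) == feat.PREDICTOR_COLUMNS

    def test_participant_with_two_missing_predictors_excluded(self):
        p_pca, t_pca, unpaced = self._inputs()
        scores = p_pca.scores.copy()
        scores.loc[scores.index[0], ["PC1", "PC2"]] = np.nan
        broken = feat.PCAResult(
            tasks=p_pca.tasks,
            eigenvalues=p_pca.eigenvalues,
            loadings=p_pca.loadings,
            scores=scores,
            retained=p_pca.retained,
        )
        res = feat.assemble_predictors(broken, t_pca, unpaced)
        assert scores.index[0] in res.excluded_participants
        assert scores.index[0] not in res.predictors.index

    def test_single_missing_predictor_imputed(self):
        p_pca, t_pca, unpaced = self._inputs()
        scores = p_pca.scores.copy()
        scores.loc[scores.index[1], "PC2"] = np.nan
        broken = feat.PCAResult(
            tasks=p_pca.tasks, eigenvalues=p_pca.eigenvalues,
            loadings=p_pca.loadings, scores=scores, retained=p_pca.retained,
        )
        res = feat.assemble_predictors(broken, t_pca, unpaced)
        pid = scores.index[1]
        assert res.imputed_flags.loc[pid, "pc2_bat_perception"]
        assert not np.isnan(res.predictors.loc[pid, "pc2_bat_perception"])
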