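"""QC metrics: Fisher-z connectivity, QC-FC, distance-dependence, tDOF."""

import numpy as np
import pytest
from scipy import stats

from qcfcbench import (
    BoldSeries,
    compare_regimes,
    extract_roi_series,
    fc_matrix,
    qcfc_correlations,
    qcfc_distance_dependence,
    tdof_loss,
)
from qcfcbench.qc import edge_distances


class TestFCMatrix:
    def test_fisher_transform_of_half(self, rng):
        n = 2000
        x = rng.normal(size=n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=n)
        # exact value check on the transform itself
        assert np.arctanh(0.5) == pytest.approx(0.5493, abs=1e-4)
        fc = fc_matrix(np.vstack([x, y]))
        assert fc.z[0, 1] == pytest.approx(np.arctanh(np.corrcoef(x, y)[0, 1]))

    def test_identical_rows_clipped_not_infinite(self, rng):
        x = rng.normal(size=50)
        fc = fc_matrix(np.vstack([x, x]))
        assert np.isfinite(fc.z[0, 1])
        assert fc.z[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_small_r_limit_z_near_r(self, rng):
        X = rng.normal(size=(4, 5000))
        fc = fc_matrix(X)
        r = np.corrcoef(X)
        iu = np.triu_indices(4, 1)
        assert np.allclose(fc.z[iu], r[iu], atol=1e-3)

    def test_constant_row_names_the_roi(self):
        X = np.vstack([np.ones(10), np.arange(10, dtype=float)])
        with pytest.raises(ValueError, match="rows \\[0\\]"):
            fc_matrix(X)


class TestQCFC:
    def test_constant_mfd_rejected(self, rng):
        fcs = [_fcmat(_sym(rng, 3), str(i)) for i in range(5)]
        with pytest.raises(ValueError, match="zero variance"):
            qcfc_correlations(fcs, np.full(5, 0.2))

    def test_exact_linear_edge_has_r_one(self):
        mfd = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        fcs = [_fcmat(_edge3(2 * m), f"s{i}") for i, m in enumerate(mfd)]
        r, p = qcfc_correlations(fcs, mfd)
        assert r[0] == pytest.approx(1.0)
        assert p[0] < 1e-6

    def test_fewer_than_three_subjects_rejected(self):
        fcs = [_fcmat(_edge3(0.1), "a"), _fcmat(_edge3(0.2), "b")]
        with pytest.raises(ValueError, match="at least 3"):
            qcfc_correlations(fcs, np.array([0.1, 0.2]))

    def test_p_values_match_scipy_pearsonr(self, rng):
        n_sub, n_roi = 15, 6
        mfd = rng.uniform(0.05, 0.4, size=n_sub)
        fcs = [_fcmat(_sym(rng, n_roi), f"s{i}") for i in range(n_sub)]
        r, p = qcfc_correlations(fcs, mfd)
        E = np.vstack([f.edges() for f in fcs])
        for j in (0, 5, 10):
            rr, pp = stats.pearsonr(E[:, j], mfd)
            assert r[j] == pytest.approx(rr, abs=1e-12)
            assert p[j] == pytest.approx(pp, abs=1e-12)


class TestDistanceDependence:
    def test_monotone_decreasing_gives_minus_one(self, rng):
        coords = rng.normal(size=(8, 3)) * 50
        d = edge_distances(coords)
        qcfc = 1.0 - 0.001 * d  # strictly decreasing in distance
        assert qcfc_distance_dependence(qcfc, coords) == pytest.approx(-1.0)

    def test_permutation_null_near_zero(self, rng):
        coords = rng.normal(size=(101, 3)) * 50  # 5050 edges
        qcfc = rng.normal(size=101 * 100 // 2)
        assert abs(qcfc_distance_dependence(qcfc, coords)) < 0.1

    def test_matches_rank_pearson_oracle(self, rng):
        coords = rng.normal(size=(12, 3)) * 40
        qcfc = rng.normal(size=66)
        rho = qcfc_distance_dependence(qcfc, coords)
        # oracle: Pearson correlation of average ranks
        d = edge_distances(coords)
        oracle = np.corrcoef(stats.rankdata(d), stats.rankdata(qcfc))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)


class TestTdofLoss:
    def test_uniform_regressors(self):
        mean, sd = tdof_loss([(27, 0)] * 5)
        assert (mean, sd) == (27.0, 0.0)

    def test_scrubbing_adds_removed_volumes(self):
        mean, sd = tdof_loss([(27, 150)])
        assert mean == 177.0

    def test_six_hmp_only(self):
        mean, sd = tdof_loss([(6, 0)] * 3)
        assert (mean, sd) == (6.0, 0.0)


class TestExtractRoiSeries:
    def _series(self, data, grid):
        return BoldSeries(data=data, tr=2.0, space="voxel", grid_shape=grid)

    def test_uniform_weights_are_plain_means(self, rng):
        grid = (2, 2, 2)
        data = rng.normal(size=(8, 10))
        labels = np.array([1, 1, 2, 2, 2, 0, 0, 1]).reshape(grid)
        out, ids = extract_roi_series(self._series(data, grid), labels)
        assert ids == [1, 2]
        assert np.allclose(out[0], data[[0, 1, 7]].mean(axis=0))

    def test_weight_concentration_selects_voxel(self, rng):
        grid = (2, 2, 2)
        data = rng.normal(size=(8, 10))
        labels = np.ones(grid, dtype=int)
        w = np.zeros(8); w[3] = 1.0
        out, _ = extract_roi_series(self._series(data, grid), labels, w.reshape(grid))
        assert np.allclose(out[0], data[3])

    def test_matches_voxel_loop_oracle(self, rng):
        grid = (3, 3, 3)
        data = rng.normal(size=(27, 7))
        labels = rng.integers(0, 4, size=grid)
        gm = rng.random(grid)
        out, ids = extract_roi_series(self._series(data, grid), labels, gm)
        flat_l, flat_w = labels.reshape(-1), gm.reshape(-1)
        for row, roi in zip(out, ids):
            num = sum(flat_w[v] * data[v] for v in range(27) if flat_l[v] == roi)
            den = sum(flat_w[v] for v in range(27) if flat_l[v] == roi)
            assert np.allclose(row, num / den)


class TestCompareRegimes:
    def test_identical_groups_no_evidence(self):
        g = np.array([0.1, 0.2, 0.3, 0.4])
        out = compare_regimes({"a": g, "b": g.copy(), "c": g.copy()})
        assert out["H"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)
        assert all(p == 1.0 for p in out["pairwise"].values())

    def test_shifted_groups_detected(self, rng):
        groups = {
            "a": rng.normal(0.0, 1, 30),
            "b": rng.normal(0.8, 1, 30),
            "c": rng.normal(1.6, 1, 30),
        }
        out = compare_regimes(groups)
        assert out["p"] < 0.05

    def test_matches_hand_computed_rank_statistic(self):
        # 3 groups x 4 observations, no ties: H computed from first principles
        groups = {
            "a": np.array([1.0, 5.0, 8.0, 11.0]),
            "b": np.array([2.0, 6.0, 9.0, 12.0]),
            "c": np.array([3.0, 4.0, 7.0, 10.0]),
        }
        pooled = np.concatenate(list(groups.values()))
        ranks = stats.rankdata(pooled)
        n = pooled.size
        rank_sums = [ranks[i * 4:(i + 1) * 4].sum() for i in range(3)]
        H_hand = 12 / (n * (n + 1)) * sum(R**2 / 4 for R in rank_sums) - 3 * (n + 1)
        out = compare_regimes(groups)
        assert out["H"] == pytest.approx(H_hand, abs=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_regimes({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})


def test_zero_exclusion_regimes_reproduce_identical_reports():
    """When no subject is excluded, every regime's QC row is identical."""
    import warnings
    from qcfcbench import benchmark_pipelines
    from qcfcbench.pipeline import PipelineSpec
    from qcfcbench.synthetic import CohortSpec, simulate_cohort

    spec = CohortSpec(n_subjects=8, n_rois=12, n_volumes=150,
                      n_voxels_per_tissue=0,
                      motion_severity_range=(0.05, 0.3), seed=6)
    cohort = simulate_cohort(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = benchmark_pipelines(
            cohort, spec.roi_coords,
            registry=[PipelineSpec(name="6hmp", strategies=("6hmp",))],
        )
    assert all(len(v) == 0 for v in rep.attrs["excluded"].values())
    cols = ["n_subjects", "prop_sig", "median_abs_qcfc", "dist_dep_rho",
            "tdof_mean", "tdof_sd"]
    vals = rep.groupby("regime")[cols].first()
    assert (vals.nunique(axis=0) == 1).all()


# --- helpers ---------------------------------------------------------------

def _sym(rng, n):
    m = rng.normal(size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


def _edge3(z01):
    m = np.zeros((3, 3))
    m[0, 1] = m[1, 0] = z01
    return m


def _fcmat(z, sid=""):
    from qcfcbench.qc import FCMatrix

    return FCMatrix(z=z, subject_id=sid)
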