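"""Nuisance-regressor construction against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qcfcbench import (
    BoldSeries,
    RealignmentParams,
    assemble_design,
    compcor,
    erode_mask,
    expand_friston24,
    global_signal,
    scrub_mask,
    spike_regressors,
    tissue_mean_signals,
)
from qcfcbench.nuisance import hmp6

from conftest import roi_series


def voxel_series(data, grid, tr=2.0):
    return BoldSeries(data=np.asarray(data, float), tr=tr, space="voxel", grid_shape=grid)


class TestFriston24:
    def test_shape_and_name_order(self, pinned_motion):
        d = expand_friston24(pinned_motion)
        assert d.k == 24
        assert d.names[:6] == tuple(f"hmp.{p}" for p in ("tx", "ty", "tz", "rx", "ry", "rz"))
        assert d.names[6].startswith("hmp.lag.")
        assert d.names[12].startswith("hmp.sq.")
        assert d.names[18].startswith("hmp.sq.lag.")

    def test_quadratic_block_is_elementwise_square(self, pinned_motion):
        d = expand_friston24(pinned_motion)
        assert np.allclose(d.columns[:, 12:18], pinned_motion.values**2)

    def test_lag_block_shifts_by_one_volume(self, pinned_motion):
        d = expand_friston24(pinned_motion)
        lag = d.columns[:, 6:12]
        assert np.all(lag[0] == 0)
        assert np.allclose(lag[1:], pinned_motion.values[:-1])

    def test_zero_motion_rejected_as_degenerate(self):
        p = RealignmentParams(np.zeros((10, 6)))
        with pytest.raises(ValueError, match="degenerate"):
            expand_friston24(p)

    def test_derivative_variant_uses_backward_differences(self, pinned_motion):
        d = expand_friston24(pinned_motion, derivatives=True)
        dt = d.columns[:, 6:12]
        assert np.allclose(dt[1:], np.diff(pinned_motion.values, axis=0))


class TestSpikeRegressors:
    def test_hand_enumeration_at_quarter_millimetre_rule(self):
        d = spike_regressors(np.array([0.0, 0.30, 0.20, 0.26]), threshold=0.25)
        assert d.k == 2
        assert d.names == ("spike.00001", "spike.00003")
        expected = np.zeros((4, 2))
        expected[1, 0] = expected[3, 1] = 1.0
        assert np.array_equal(d.columns, expected)

    def test_no_flags_gives_empty_design(self):
        assert spike_regressors(np.full(10, 0.1)).k == 0

    def test_all_above_threshold_is_shifted_identity(self):
        fd = np.concatenate([[0.0], np.full(9, 0.5)])
        d = spike_regressors(fd)
        assert d.k == 9
        assert np.array_equal(d.columns[1:], np.eye(9))

    def test_threshold_is_strict(self):
        assert spike_regressors(np.array([0.0, 0.25])).k == 0


def brute_force_scrub(flags: np.ndarray, min_segment: int) -> np.ndarray:
    """Oracle: enumerate retained runs and drop the short ones."""
    keep = ~flags
    runs, start = [], None
    for i, k in enumerate(keep):
        if k and start is None:
            start = i
        if not k and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(keep)))
    out = np.zeros_like(keep)
    for a, b in runs:
        if b - a >= min_segment:
            out[a:b] = True
    return out


class TestScrubMask:
    def test_no_violations_keeps_everything(self):
        m = scrub_mask(np.zeros(20), np.zeros(20))
        assert m.n_kept == 20 and not m.reasons

    def test_short_between_flag_run_also_removed(self):
        fd = np.zeros(20)
        fd[[5, 8]] = 0.5
        m = scrub_mask(fd, np.zeros(20))
        assert not m.keep[5] and not m.keep[8]
        assert not m.keep[6] and not m.keep[7]  # run of 2 < 5
        assert m.reasons[6] == m.reasons[7] == "short_segment"
        assert m.keep[:5].all() and m.keep[9:].all()

    def test_reason_precedence_and_tags(self):
        fd = np.array([0.0, 0.5, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        dv = np.array([0.0, 3.0, 2.5, 0.0, 0.0, 0.0, 0.0, 0.0])
        m = scrub_mask(fd, dv, min_segment=1)
        assert m.reasons[1] == "fd_power"  # both violated; FD takes precedence
        assert m.reasons[2] == "dvars"

    def test_equals_brute_force_on_random_masks(self, rng):
        for _ in range(1000):
            n = rng.integers(5, 40)
            flags = rng.random(n) < rng.uniform(0.05, 0.5)
            fd = np.where(flags, 1.0, 0.0)
            m = scrub_mask(fd, np.zeros(n))
            assert np.array_equal(m.keep, brute_force_scrub(flags, 5))

    @given(st.integers(0, 2**31 - 1), st.integers(1, 8))
    @settings(max_examples=50, deadline=None)
    def test_run_length_invariant(self, seed, min_segment):
        r = np.random.default_rng(seed)
        n = int(r.integers(5, 60))
        fd = np.where(r.random(n) < 0.3, 1.0, 0.0)
        m = scrub_mask(fd, np.zeros(n), min_segment=min_segment)
        # every retained contiguous run is at least min_segment long
        run = 0
        for k in np.concatenate([m.keep, [False]]):
            if k:
                run += 1
            else:
                assert run == 0 or run >= min_segment
                run = 0


class TestErodeMask:
    def test_zero_cycles_is_identity(self, rng):
        m = rng.random((6, 6, 6)) > 0.5
        assert np.array_equal(erode_mask(m, 0), m)

    def test_cube_geometry(self):
        m = np.zeros((7, 7, 7), dtype=bool)
        m[1:6, 1:6, 1:6] = True  # 5x5x5 solid cube
        e1 = erode_mask(m, 1)
        assert e1.sum() == 27  # 3x3x3
        e2 = erode_mask(m, 2)
        assert e2.sum() == 1

    def test_composition(self, rng):
        m = rng.random((8, 8, 8)) > 0.3
        a, b = 1, 2
        lhs = erode_mask(m, a + b)
        rhs = erode_mask(erode_mask(m, a), b)
        if lhs.any() and rhs.any():
            assert np.array_equal(lhs, rhs)

    def test_stops_before_emptying_with_warning(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[1:3, 1:3, 1:3] = True
        with pytest.warns(UserWarning, match="empty"):
            out = erode_mask(m, 3)
        assert out.any()

    def test_eroded_is_subset(self, rng):
        m = rng.random((8, 8, 8)) > 0.4
        e = erode_mask(m, 1)
        assert not np.any(e & ~m)


class TestTissueMeanSignals:
    def test_uniform_block_returns_demeaned_series(self, rng):
        s = rng.normal(size=30) + 1000
        grid = (2, 2, 4)
        data = np.tile(s, (16, 1))
        series = voxel_series(data, grid)
        wm = np.zeros(grid, bool); wm[:, :, :2] = True
        csf = np.zeros(grid, bool); csf[:, :, 2:] = True
        d = tissue_mean_signals(series, wm, csf)
        assert d.names == ("phys.wm", "phys.csf")
        assert np.allclose(d.columns[:, 0], s - s.mean())

    def test_noise_averages_out_at_many_voxels(self, rng):
        s = rng.normal(size=100)
        nvox = 512
        grid = (8, 8, 16)
        wm_rows = s + rng.normal(scale=1.0, size=(nvox, 100))
        csf_rows = rng.normal(size=(nvox, 100))
        series = voxel_series(np.vstack([wm_rows, csf_rows]), grid)
        wm = np.zeros(grid, bool); wm[:, :, :8] = True
        csf = np.zeros(grid, bool); csf[:, :, 8:] = True
        d = tissue_mean_signals(series, wm, csf)
        r = np.corrcoef(d.columns[:, 0], s)[0, 1]
        assert abs(r) > 0.99

    def test_empty_mask_names_the_tissue(self, rng):
        series = voxel_series(rng.normal(size=(8, 10)), (2, 2, 2))
        with pytest.raises(ValueError, match="csf"):
            tissue_mean_signals(series, np.ones((2, 2, 2), bool), np.zeros((2, 2, 2), bool))


class TestCompCor:
    def _block(self, rows, grid=(2, 2, 2)):
        return voxel_series(rows, grid), np.ones(grid, bool)

    def test_rank_one_block_variance_mode(self, rng):
        s = rng.normal(size=50)
        loadings = rng.uniform(0.5, 2.0, size=8)
        series, mask = self._block(np.outer(loadings, s))
        d = compcor(series, mask, mode="variance")
        assert d.k == 1
        assert abs(np.corrcoef(d.columns[:, 0], s)[0, 1]) > 0.9999

    def test_rank_deficiency_warns_in_fixed_mode(self, rng):
        s = rng.normal(size=50)
        series, mask = self._block(np.outer(rng.uniform(0.5, 2, 8), s))
        with pytest.warns(UserWarning, match="rank"):
            d = compcor(series, mask, mode="fixed", n_components=5)
        assert d.k == 1

    def test_variance_mode_matches_svd_oracle(self, rng):
        X = rng.normal(size=(30, 80))
        series, mask = self._block(X, grid=(5, 3, 2))
        d = compcor(series, mask, mode="variance", variance_target=0.5)
        # oracle: brute-force SVD of the normalized matrix
        Xn = X - X.mean(axis=1, keepdims=True)
        Xn /= Xn.std(axis=1, keepdims=True)
        sv = np.linalg.svd(Xn, compute_uv=False)
        frac = np.cumsum(sv**2) / np.sum(sv**2)
        k_oracle = int(np.searchsorted(frac, 0.5 - 1e-12) + 1)
        assert d.k == k_oracle

    def test_components_orthonormal_and_variance_ordered(self, rng):
        X = rng.normal(size=(64, 100))
        series, mask = self._block(X, grid=(4, 4, 4))
        d = compcor(series, mask, mode="fixed", n_components=5)
        C = d.columns
        assert np.allclose(C.T @ C, np.eye(5), atol=1e-10)
        Xn = X - X.mean(axis=1, keepdims=True)
        Xn /= Xn.std(axis=1, keepdims=True)
        proj_var = np.array([np.sum((Xn @ C[:, i]) ** 2) for i in range(5)])
        assert np.all(np.diff(proj_var) <= 1e-8)


class TestGlobalSignal:
    def test_uniform_image_returns_demeaned_mean(self, rng):
        u = rng.normal(size=40)
        series = roi_series(np.tile(u, (6, 1)))
        d = global_signal(series)
        assert d.names == ("gsr",)
        assert np.allclose(d.columns[:, 0], u - u.mean())

    def test_zero_mean_spatial_pattern_invisible(self, rng):
        u = rng.normal(size=40)
        pattern = rng.normal(size=6)
        pattern -= pattern.mean()
        series = roi_series(np.tile(u, (6, 1)) + np.outer(pattern, rng.normal(size=40)))
        series2 = roi_series(np.tile(u, (6, 1)))
        # the added pattern averages to zero across rows at every volume
        d1 = global_signal(series)
        d2 = global_signal(series2)
        assert np.allclose(d1.columns, d2.columns, atol=1e-10)

    def test_matches_voxel_loop_oracle(self, rng):
        grid = (3, 3, 3)
        data = rng.normal(size=(27, 20)) + 1000
        series = voxel_series(data, grid)
        mask = rng.random(grid) > 0.3
        d = global_signal(series, mask)
        flat = mask.reshape(-1)
        oracle = np.array([
            np.mean([data[v, t] for v in range(27) if flat[v]])
            for t in range(20)
        ])
        assert np.allclose(d.columns[:, 0], oracle - oracle.mean())


class TestAssembleDesign:
    def test_column_counts_add(self, pinned_motion):
        from qcfcbench.motion import fd_jenkinson

        parts = [
            expand_friston24(pinned_motion),
            global_signal(roi_series(np.random.default_rng(0).normal(size=(5, 300)))),
        ]
        d = assemble_design(parts)
        assert d.k == 25
        spikes = spike_regressors(fd_jenkinson(pinned_motion))
        d2 = assemble_design(parts + [spikes])
        assert d2.k == 25 + spikes.k

    def test_duplicate_names_rejected(self, pinned_motion):
        d = hmp6(pinned_motion)
        with pytest.raises(ValueError, match="duplicate"):
            assemble_design([d, d])

    def test_empty_list_gives_k0(self):
        assert assemble_design([]).k == 0

    def test_length_mismatch_rejected(self, pinned_motion):
        short = hmp6(RealignmentParams(pinned_motion.values[:100]))
        with pytest.raises(ValueError, match="volume counts"):
            assemble_design([hmp6(pinned_motion), short])


def test_spike_columns_equal_volume_deletion(rng):
    """OLS with spike indicators reproduces, at unflagged volumes, the
    residuals of deleting the flagged volumes before regression."""
    from qcfcbench.pipeline import regress_nuisance
    from qcfcbench.types import DesignMatrix

    for _ in range(10):
        n, k = 40, 3
        X = rng.normal(size=(n, k))
        y = rng.normal(size=(4, n))
        flagged = rng.choice(n, size=4, replace=False)
        spikes = np.zeros((n, 4))
        spikes[flagged, np.arange(4)] = 1.0
        base = [f"x{i}" for i in range(k)]
        with_spikes = DesignMatrix(
            np.hstack([X, spikes]), tuple(base + [f"spike.{t:05d}" for t in sorted(flagged)])
        )
        res_full = regress_nuisance(roi_series(y), with_spikes)
        keep = np.ones(n, bool)
        keep[flagged] = False
        res_del = regress_nuisance(
            roi_series(y[:, keep]), DesignMatrix(X[keep], tuple(base))
        )
        assert np.allclose(res_full.data[:, keep], res_del.data, atol=1e-9)
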