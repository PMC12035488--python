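"""Metrics against brute-force oracles; significance testing; summaries."""

import itertools

import numpy as np
import pytest
from scipy import stats

from mrsisr.evaluation import (
    EvalRecord,
    LpipsUnavailable,
    SSIMParams,
    compute_record,
    error_map,
    lpips,
    mannwhitney_u,
    mse,
    psnr,
    register_lpips_backend,
    rmse,
    ssim,
    summarize,
)


# -- error maps -------------------------------------------------------------

def test_error_map_basics(rng):
    a = rng.random((8, 8))
    np.testing.assert_allclose(error_map(a, a), 0.0)
    em = error_map(np.full((4, 4), 0.75), np.ones((4, 4)))
    np.testing.assert_allclose(em, 0.25)
    b = rng.random((8, 8))
    np.testing.assert_allclose(error_map(a, b), -error_map(b, a))
    with pytest.raises(ValueError):
        error_map(a, np.zeros((4, 4)))


# -- MSE / RMSE / PSNR ------------------------------------------------------

def _loop_mse(a, b):
    total = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            total += (a[i, j] - b[i, j]) ** 2
    return total / a.size


def test_mse_rmse_against_loop_oracle(rng):
    a, b = rng.random((16, 16)), rng.random((16, 16))
    expected = _loop_mse(a, b)
    assert mse(a, b) == pytest.approx(expected, abs=1e-10)
    assert rmse(a, b) == pytest.approx(np.sqrt(expected), abs=1e-10)
    assert mse(a, a) == 0 and rmse(a, a) == 0
    d = np.full((8, 8), 0.04)
    assert mse(d, np.zeros((8, 8))) == pytest.approx(0.0016)


def test_psnr_formula():
    assert psnr(0.01, 1.0) == pytest.approx(20.0)
    assert psnr(0.0001, 1.0) == pytest.approx(40.0)
    assert psnr(1.0, 255.0) == pytest.approx(20 * np.log10(255), abs=1e-6)
    assert psnr(1.0, 255.0) == pytest.approx(48.13, abs=0.005)
    assert psnr(0.0) == np.inf
    with pytest.raises(ValueError):
        psnr(-1.0)


def test_psnr_mse_consistency(rng):
    for _ in range(3):
        m = float(rng.random()) + 1e-3
        assert psnr(m, 1.0) == pytest.approx(-10 * np.log10(m), abs=1e-12)


# -- SSIM -------------------------------------------------------------------

def _gaussian_kernel(radius, sigma):
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _loop_ssim(x, y, params: SSIMParams):
    """Naive sliding-window SSIM: weighted local stats at every position
    whose full window fits, averaged."""
    r = (params.window_size - 1) // 2
    k1d = _gaussian_kernel(r, params.sigma)
    w = np.outer(k1d, k1d)
    c1, c2 = params.c1, params.c2
    n = x.shape[0]
    vals = []
    for i in range(r, n - r):
        for j in range(r, n - r):
            wx = x[i - r:i + r + 1, j - r:j + r + 1]
            wy = y[i - r:i + r + 1, j - r:j + r + 1]
            ux = (w * wx).sum()
            uy = (w * wy).sum()
            vx = (w * wx * wx).sum() - ux * ux
            vy = (w * wy * wy).sum() - uy * uy
            vxy = (w * wx * wy).sum() - ux * uy
            vals.append(((2 * ux * uy + c1) * (2 * vxy + c2))
                        / ((ux ** 2 + uy ** 2 + c1) * (vx + vy + c2)))
    return float(np.mean(vals))


def test_ssim_against_loop_oracle(rng):
    params = SSIMParams()
    x = rng.random((16, 16))
    y = np.clip(x + 0.1 * rng.standard_normal((16, 16)), 0, 1)
    assert ssim(x, y, params) == pytest.approx(_loop_ssim(x, y, params), abs=1e-10)


def test_ssim_identity_and_symmetry(rng):
    x = rng.random((32, 32))
    y = rng.random((32, 32))
    assert ssim(x, x) == pytest.approx(1.0, abs=1e-12)
    assert ssim(x, y) == pytest.approx(ssim(y, x), abs=1e-12)
    assert ssim(x, y) < 1.0


def test_ssim_params_validation():
    with pytest.raises(ValueError):
        SSIMParams(k1=0.0)
    p = SSIMParams(k1=0.02, dynamic_range=2.0)
    assert p.c1 == pytest.approx((0.02 * 2.0) ** 2)


# -- LPIPS plug-in ----------------------------------------------------------

def _toy_backend(x_rgb, y_rgb):
    return float(np.mean((x_rgb - y_rgb) ** 2))


def test_lpips_requires_backend(rng):
    register_lpips_backend(None)
    with pytest.raises(LpipsUnavailable):
        lpips(rng.random((8, 8)), rng.random((8, 8)))


def test_lpips_with_backend(rng):
    x = rng.random((8, 8))
    noisy = np.clip(x + 0.3 * rng.standard_normal((8, 8)), 0, 1)
    assert lpips(x, x, backend=_toy_backend) == 0.0
    assert lpips(x, noisy, backend=_toy_backend) > lpips(x, x, backend=_toy_backend)


def test_record_omits_lpips_without_backend(rng):
    register_lpips_backend(None)
    x, y = rng.random((16, 16)), rng.random((16, 16))
    rec = compute_record("m", "id", x, y)
    assert rec.lpips is None


def test_record_includes_lpips_with_backend(rng):
    register_lpips_backend(_toy_backend)
    try:
        rec = compute_record("m", "id", rng.random((16, 16)), rng.random((16, 16)))
        assert rec.lpips is not None and rec.lpips >= 0
    finally:
        register_lpips_backend(None)


def test_failing_backend_warns_not_raises(rng):
    def broken(x, y):
        raise RuntimeError("boom")

    with pytest.warns(UserWarning):
        rec = compute_record("m", "id", rng.random((16, 16)), rng.random((16, 16)),
                             lpips_backend=broken)
    assert rec.lpips is None


# -- Mann-Whitney -----------------------------------------------------------

def test_u_statistic_complete_separation():
    u, p = mannwhitney_u([1, 2], [3, 4])
    assert u == 0.0


def test_identical_samples_p_near_one():
    u, p = mannwhitney_u([1, 2, 3], [1, 2, 3])
    assert p > 0.9


def test_u_identity_on_tie_free_samples(rng):
    a = rng.random(7)
    b = rng.random(5)
    ua, _ = mannwhitney_u(a, b)
    ub, _ = mannwhitney_u(b, a)
    assert ua + ub == pytest.approx(len(a) * len(b))


@pytest.mark.parametrize("na,nb", [(3, 3), (4, 5), (6, 6), (2, 6)])
def test_exact_branch_matches_scipy(na, nb, rng):
    for _ in range(3):
        a = rng.random(na)
        b = rng.random(nb) + 0.2
        u, p = mannwhitney_u(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


def test_exact_branch_matches_enumeration(rng):
    """p from the implementation equals a from-scratch enumeration of all
    rank assignments for small samples."""
    a, b = rng.random(4), rng.random(4)
    u_obs, p_obs = mannwhitney_u(a, b)
    combined = np.sort(np.concatenate([a, b]))
    n = len(a)
    us = []
    for subset in itertools.combinations(range(len(combined)), n):
        ranks = np.array(subset) + 1
        us.append(ranks.sum() - n * (n + 1) / 2)
    us = np.array(us)
    le = (us <= u_obs).sum() / len(us)
    ge = (us >= u_obs).sum() / len(us)
    assert p_obs == pytest.approx(min(1.0, 2 * min(le, ge)))


def test_asymptotic_branch_close_to_scipy(rng):
    a = rng.standard_normal(30)
    b = rng.standard_normal(25) + 0.5
    u, p = mannwhitney_u(a, b)
    ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    assert u == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue, rel=1e-6)


def test_ties_use_corrected_normal_approximation():
    a = [1, 1, 2, 2, 3]
    b = [2, 3, 3, 4, 4]
    u, p = mannwhitney_u(a, b)
    ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    assert u == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue, rel=1e-6)


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        mannwhitney_u([], [1.0])


# -- records and summaries --------------------------------------------------

def _record(method, map_id, m):
    return EvalRecord(method=method, map_id=map_id, mse=m,
                      rmse=float(np.sqrt(m)), psnr=psnr(m), ssim=0.9)


def test_record_invariants():
    with pytest.raises(ValueError):
        EvalRecord(method="m", map_id="x", mse=0.01, rmse=0.5, psnr=20, ssim=0.9)
    rec = _record("m", "x", 0.01)
    assert rec.rmse ** 2 == pytest.approx(rec.mse)


def test_summarize_mean_and_sample_sd():
    records = [_record("only", f"r{i}", m) for i, m in enumerate((1.0, 3.0))]
    report = summarize(records)
    assert report.summary.loc["only", "mse_mean"] == pytest.approx(2.0)
    assert report.summary.loc["only", "mse_sd"] == pytest.approx(np.sqrt(2.0))
    assert len(report.tests) == 0  # single method: no tests


def test_three_methods_three_pairwise_comparisons(rng):
    records = []
    for method, shift in (("a", 0.0), ("b", 0.05), ("c", 0.1)):
        for i in range(6):
            records.append(_record(method, f"r{i}", 0.01 + shift + 0.001 * i))
    report = summarize(records)
    per_metric = report.tests.groupby("metric").size()
    assert (per_metric == 3).all()


def test_shifted_distribution_flagged_significant(rng):
    records = []
    for i in range(20):
        records.append(_record("low", f"r{i}", 0.001 + 1e-5 * rng.random()))
        records.append(_record("high", f"r{i}", 0.01 + 1e-5 * rng.random()))
    report = summarize(records)
    row = report.tests[(report.tests.metric == "mse")].iloc[0]
    assert row["significant"] and row["p"] < 0.05
    assert "Mann-Whitney" in report.to_text()


def test_summarize_rejects_empty():
    with pytest.raises(ValueError):
        summarize([])
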