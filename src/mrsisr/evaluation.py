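"""Fidelity metrics, perceptual-metric plug-in and significance testing.

Per-map metrics: MSE, RMSE, PSNR (dB), SSIM (Gaussian-windowed, the
classic luminance/contrast/structure form) and — when an external
perceptual backend is registered — LPIPS.  Method-level summaries report
mean (sample standard deviation) per metric plus pairwise two-sided
Mann–Whitney U tests at a 0.05 significance threshold.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity

SIGNIFICANCE_LEVEL = 0.05
METRIC_NAMES = ("mse", "rmse", "psnr", "ssim", "lpips")
#: metrics where larger is better (for readers of the report; tests are two-sided)
HIGHER_IS_BETTER = {"psnr", "ssim"}


# ---------------------------------------------------------------------------
# error maps and scalar metrics

def error_map(upscaled: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Pixelwise difference ``truth - upscaled`` (positive where the
    upscaler underestimates)."""
    if upscaled.shape != truth.shape:
        raise ValueError("shapes disagree")
    return np.asarray(truth, dtype=np.float64) - np.asarray(upscaled, dtype=np.float64)


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared difference."""
    if a.shape != b.shape:
        raise ValueError("shapes disagree")
    d = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    return float(np.mean(d * d))


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root mean squared difference."""
    return float(np.sqrt(mse(a, b)))


def psnr(mse_value: float, max_i: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB: 20 log10(MAX) - 10 log10(MSE)."""
    if mse_value < 0:
        raise ValueError("MSE cannot be negative")
    if mse_value == 0:
        return float("inf")
    return float(20.0 * np.log10(max_i) - 10.0 * np.log10(mse_value))


@dataclass(frozen=True)
class SSIMParams:
    """Windowed-SSIM constants: c1 = (k1 L)^2, c2 = (k2 L)^2 stabilize the
    luminance and contrast terms; the window is Gaussian (side 11, sigma 1.5)."""

    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 1.0
    window_size: int = 11
    sigma: float = 1.5

    def __post_init__(self):
        if min(self.k1, self.k2, self.dynamic_range) <= 0:
            raise ValueError("k1, k2 and the dynamic range must be positive")

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2


def ssim(x: np.ndarray, y: np.ndarray, params: SSIMParams | None = None) -> float:
    """Mean structural similarity over Gaussian-windowed local statistics."""
    params = params or SSIMParams()
    if x.shape != y.shape:
        raise ValueError("shapes disagree")
    # truncation radius reproducing the requested window side
    radius = (params.window_size - 1) // 2
    truncate = radius / params.sigma
    return float(structural_similarity(
        np.asarray(x, dtype=np.float64), np.asarray(y, dtype=np.float64),
        gaussian_weights=True, sigma=params.sigma, truncate=truncate,
        use_sample_covariance=False, K1=params.k1, K2=params.k2,
        data_range=params.dynamic_range))


# ---------------------------------------------------------------------------
# LPIPS plug-in

class LpipsUnavailable(LookupError):
    """No perceptual backend is registered."""


_lpips_backend = None


def register_lpips_backend(backend) -> None:
    """Register a callable ``backend(x_rgb, y_rgb) -> float`` computing a
    perceptual distance on (3, H, W) arrays scaled to [-1, 1]; pass ``None``
    to unregister."""
    global _lpips_backend
    _lpips_backend = backend


def lpips(x: np.ndarray, y: np.ndarray, backend=None) -> float:
    """Perceptual distance between two single-channel maps (lower = more
    similar); requires a registered or explicitly passed backend."""
    backend = backend or _lpips_backend
    if backend is None:
        raise LpipsUnavailable("no LPIPS backend registered")

    def to_rgb(grid: np.ndarray) -> np.ndarray:
        g = np.asarray(grid, dtype=np.float64) * 2.0 - 1.0
        return np.repeat(g[None], 3, axis=0)

    return float(backend(to_rgb(x), to_rgb(y)))


# ---------------------------------------------------------------------------
# Mann-Whitney U

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: pairwise wins plus half-ties."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mannwhitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact enumeration of the U distribution for tie-free samples with both
    sizes <= 8; otherwise the normal approximation with tie correction and
    continuity correction.  Returns (U for sample_a, p-value).
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    n, m = a.size, b.size
    u = _u_statistic(a, b)
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size

    if max(n, m) <= 8 and not has_ties:
        # enumerate U over all rank assignments of sample a
        ranks = np.argsort(np.argsort(combined)) + 1  # 1-based, tie-free
        total = comb(n + m, n)
        le = ge = 0
        const = n * (n + 1) / 2.0
        all_ranks = np.arange(1, n + m + 1)
        for subset in itertools.combinations(all_ranks, n):
            u_perm = sum(subset) - const
            if u_perm <= u + 1e-12:
                le += 1
            if u_perm >= u - 1e-12:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return u, p

    mu = n * m / 2.0
    big_n = n + m
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (big_n * (big_n - 1))
    sigma2 = n * m / 12.0 * ((big_n + 1) - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    # continuity correction toward the mean
    z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return u, p


# ---------------------------------------------------------------------------
# records and reports

@dataclass
class EvalRecord:
    """Per-map metric values for one upscaling method."""

    method: str
    map_id: str
    mse: float
    rmse: float
    psnr: float
    ssim: float
    lpips: float | None = None

    def __post_init__(self):
        if self.mse < 0:
            raise ValueError("MSE cannot be negative")
        if abs(self.rmse ** 2 - self.mse) > 1e-9 * max(self.mse, 1.0):
            raise ValueError("rmse^2 must equal mse")


def compute_record(method: str, map_id: str, upscaled: np.ndarray,
                   truth: np.ndarray, ssim_params: SSIMParams | None = None,
                   max_i: float = 1.0, lpips_backend=None) -> EvalRecord:
    """All metrics for one upscaled map against its ground truth.

    LPIPS is included only when a backend is available; a backend failure
    is recorded as missing with a warning rather than aborting the run.
    """
    m = mse(upscaled, truth)
    lp = None
    if lpips_backend is not None or _lpips_backend is not None:
        try:
            lp = lpips(upscaled, truth, backend=lpips_backend)
        except LpipsUnavailable:
            lp = None
        except Exception as exc:  # backend failure: metric missing, run continues
            warnings.warn(f"LPIPS backend failed on {map_id}: {exc}", stacklevel=2)
            lp = None
    return EvalRecord(method=method, map_id=map_id, mse=m, rmse=float(np.sqrt(m)),
                      psnr=psnr(m, max_i=max_i),
                      ssim=ssim(upscaled, truth, ssim_params), lpips=lp)


@dataclass
class EvalReport:
    """Method-level metric summary and pairwise significance tests."""

    summary: pd.DataFrame            # index: method; columns: metric mean/sd
    tests: pd.DataFrame              # pairwise U statistics and p-values
    alpha: float = SIGNIFICANCE_LEVEL
    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_text(self) -> str:
        """Aligned mean (SD) table plus significant pairwise differences."""
        lines = ["Method-level results: mean (SD)", ""]
        metrics = [c[:-5] for c in self.summary.columns if c.endswith("_mean")]
        header = "method".ljust(10) + "".join(m.upper().rjust(18) for m in metrics)
        lines.append(header)
        for method, row in self.summary.iterrows():
            cells = [f"{row[m + '_mean']:.4f} ({row[m + '_sd']:.4f})" for m in metrics]
            lines.append(str(method).ljust(10) + "".join(c.rjust(18) for c in cells))
        if len(self.tests):
            lines += ["", f"Pairwise Mann-Whitney U tests (two-sided, alpha={self.alpha}):"]
            for _, t in self.tests.iterrows():
                star = " *" if t["significant"] else ""
                lines.append(f"  {t['metric']:>5}  {t['method_a']} vs {t['method_b']}: "
                             f"U={t['U']:.1f}, p={t['p']:.4g}{star}")
        return "\n".join(lines)


def summarize(records: list[EvalRecord], alpha: float = SIGNIFICANCE_LEVEL) -> EvalReport:
    """Aggregate per-map records into a method-level report.

    Means and sample (n-1) standard deviations per metric and method, and
    all pairwise Mann–Whitney tests per metric; with a single method the
    report carries no tests.
    """
    if not records:
        raise ValueError("no records to summarize")
    df = pd.DataFrame([{
        "method": r.method, "map_id": r.map_id, "mse": r.mse, "rmse": r.rmse,
        "psnr": r.psnr, "ssim": r.ssim, "lpips": r.lpips} for r in records])
    metrics = [m for m in METRIC_NAMES if df[m].notna().any()]
    rows = {}
    for method, grp in df.groupby("method", sort=False):
        row = {}
        for m in metrics:
            vals = grp[m].dropna()
            row[m + "_mean"] = vals.mean()
            row[m + "_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        rows[method] = row
    summary = pd.DataFrame.from_dict(rows, orient="index")

    tests = []
    methods = list(rows)
    for ma, mb in itertools.combinations(methods, 2):
        for metric in metrics:
            va = df.loc[df["method"] == ma, metric].dropna().to_numpy()
            vb = df.loc[df["method"] == mb, metric].dropna().to_numpy()
            if va.size == 0 or vb.size == 0:
                continue
            u, p = mannwhitney_u(va, vb)
            tests.append({"metric": metric, "method_a": ma, "method_b": mb,
                          "U": u, "p": p, "significant": p < alpha})
    return EvalReport(summary=summary, tests=pd.DataFrame(tests), alpha=alpha,
                      records=df)
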