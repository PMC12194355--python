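"""Image-quality metrics (MSE, PSNR, SSIM) and paired statistics.

PSNR follows the 8-bit convention PSNR = 10*log10(I_max^2 / MSE) with
I_max = 255 on the stored scale (an I_max = 1 preset serves the
normalized training scale). SSIM uses the Gaussian-window formulation
(11x11 window, sigma = 1.5, K1 = 0.01, K2 = 0.03, no sample-covariance
correction): local means, variances and covariance are Gaussian-filtered
moments, the per-pixel similarity map is averaged after discarding the
half-window border where the filter support is truncated.

The statistical layer mirrors a per-dose-level evaluation table: per-pair
metric records are grouped by dose fraction, averaged, and compared
original-vs-denoised with paired t-tests; a TOST procedure tests
equivalence of paired samples within +/- delta bounds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .dataio import DosePair, NormalizedImage
from .errors import ConfigurationError, DomainError, ShapeError


@dataclass(frozen=True)
class MetricConfig:
    data_range: float = 255.0
    ssim_window: int = 11
    ssim_sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03

    def __post_init__(self):
        if self.ssim_window % 2 == 0 or self.ssim_window < 3:
            raise ConfigurationError("ssim_window must be an odd integer >= 3")
        if self.data_range <= 0:
            raise ConfigurationError("data_range must be > 0")

    @property
    def c1(self) -> float:
        return (self.k1 * self.data_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.data_range) ** 2


#: stored 8-bit comparison scale
EIGHT_BIT = MetricConfig(data_range=255.0)
#: normalized [0, 1] scale used inside the training loss
NORMALIZED = MetricConfig(data_range=1.0)


def _check_shapes(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ShapeError(f"shape mismatch: {x.shape} vs {y.shape}")


def mse(x: np.ndarray, y: np.ndarray) -> float:
    """Mean squared pixel difference over all N pixels."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    _check_shapes(x, y)
    return float(np.mean((x - y) ** 2))


def psnr(x: np.ndarray, y: np.ndarray,
         config: MetricConfig = EIGHT_BIT) -> float:
    """Peak signal-to-noise ratio in dB; +inf sentinel for identical images."""
    err = mse(x, y)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(config.data_range ** 2 / err)


@dataclass
class SSIMComponents:
    """Local Gaussian-window statistics underlying the SSIM map."""
    mu_x: np.ndarray
    mu_y: np.ndarray
    var_x: np.ndarray
    var_y: np.ndarray
    cov_xy: np.ndarray
    ssim_map: np.ndarray


def ssim(x: np.ndarray, y: np.ndarray, config: MetricConfig = EIGHT_BIT,
         *, return_components: bool = False):
    """Mean structural similarity (symmetric in x and y, bounded by 1)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    _check_shapes(x, y)
    win = config.ssim_window
    if min(x.shape) < win:
        raise DomainError(
            f"image {x.shape} smaller than SSIM window {win}; use a "
            "smaller ssim_window")
    pad = (win - 1) // 2
    truncate = pad / config.ssim_sigma

    def blur(a):
        return ndimage.gaussian_filter(a, sigma=config.ssim_sigma,
                                       truncate=truncate)

    ux, uy = blur(x), blur(y)
    uxx, uyy, uxy = blur(x * x), blur(y * y), blur(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    c1, c2 = config.c1, config.c2
    s_map = ((2 * ux * uy + c1) * (2 * vxy + c2)) / \
            ((ux * ux + uy * uy + c1) * (vx + vy + c2))
    interior = s_map[pad:-pad, pad:-pad]
    value = float(interior.mean())
    if not return_components:
        return value
    comps = SSIMComponents(mu_x=ux, mu_y=uy, var_x=vx, var_y=vy,
                           cov_xy=vxy, ssim_map=s_map)
    return value, comps


# --------------------------------------------------------------------------
# per-pair evaluation records

@dataclass
class MetricRecord:
    pair_id: str
    dose_fraction: float
    psnr_original: float
    psnr_denoised: float
    ssim_original: float
    ssim_denoised: float


def evaluate_pairs(params, test_pairs: list[DosePair],
                   metric_config: MetricConfig = EIGHT_BIT, *,
                   denoiser=None, batch_size: int = 8) -> list[MetricRecord]:
    """Compute original-vs-full and denoised-vs-full metrics per test pair.

    ``params`` is a trained :class:`~scintidenoise.model.ModelParameters`;
    pass ``denoiser`` to substitute any callable mapping a list of
    :class:`NormalizedImage` to denoised images (e.g. the identity, for
    debugging).
    """
    if not test_pairs:
        raise ConfigurationError("evaluate_pairs requires a non-empty test set")
    if denoiser is None:
        if params is None:
            raise ConfigurationError("either trained params or an explicit "
                                     "denoiser is required")
        from .training import denoise
        outputs = denoise(params, params.config,
                          [p.low for p in test_pairs], batch_size=batch_size)
    else:
        outputs = denoiser([p.low for p in test_pairs])

    scale = metric_config.data_range
    records = []
    for pair, out in zip(test_pairs, outputs):
        lo = pair.low.values * scale
        fu = pair.full.values * scale
        de = out.values * scale
        records.append(MetricRecord(
            pair_id=pair.pair_id, dose_fraction=pair.low.dose_fraction,
            psnr_original=psnr(lo, fu, metric_config),
            psnr_denoised=psnr(de, fu, metric_config),
            ssim_original=ssim(lo, fu, metric_config),
            ssim_denoised=ssim(de, fu, metric_config)))
    return records


# --------------------------------------------------------------------------
# statistics

@dataclass
class StatResult:
    test: str
    statistic: float | None
    p_value: float | None
    n: int
    not_computable: bool = False
    reason: str = ""
    extra: dict = field(default_factory=dict)


def paired_t_test(a, b) -> StatResult:
    """Two-sided paired t-test, t = mean(d) / (sd(d)/sqrt(n)), d = a - b."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ShapeError("paired samples must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise DomainError("paired t-test requires n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        return StatResult(test="paired_t", statistic=None, p_value=None, n=n,
                          not_computable=True, reason="zero-variance differences")
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return StatResult(test="paired_t", statistic=t, p_value=p, n=n)


def tost_equivalence(a, b, delta: float = 1.0) -> StatResult:
    """Two one-sided paired t-tests of the mean difference against +/- delta.

    Overall p is the maximum of the two one-sided p-values; equivalence is
    concluded at p < 0.05. The default delta of 1.0 corresponds to +/- 1
    point on a five-point Likert scale.
    """
    if delta <= 0:
        raise ConfigurationError("equivalence bound delta must be > 0")
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ShapeError("paired samples must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise DomainError("TOST requires n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        inside = abs(float(d.mean())) < delta
        return StatResult(test="tost", statistic=None,
                          p_value=0.0 if inside else 1.0, n=n,
                          not_computable=False,
                          reason="zero-variance differences (degenerate)",
                          extra={"delta": delta})
    se = sd / math.sqrt(n)
    t_lower = (d.mean() + delta) / se       # H1: mean(d) > -delta
    t_upper = (d.mean() - delta) / se       # H1: mean(d) < +delta
    p_lower = float(stats.t.sf(t_lower, df=n - 1))
    p_upper = float(stats.t.cdf(t_upper, df=n - 1))
    p = max(p_lower, p_upper)
    return StatResult(test="tost", statistic=float(d.mean() / se), p_value=p,
                      n=n, extra={"delta": delta, "p_lower": p_lower,
                                  "p_upper": p_upper})


# --------------------------------------------------------------------------
# per-dose aggregation

@dataclass
class DoseLevelSummary:
    dose_fraction: float
    n: int
    ssim_original: float
    ssim_denoised: float
    ssim_p_value: float | None
    psnr_original: float
    psnr_denoised: float
    psnr_p_value: float | None


def _finite_mean(values: np.ndarray, label: str) -> float:
    finite = values[np.isfinite(values)]
    if finite.size < values.size:
        warnings.warn(f"{label}: excluded {values.size - finite.size} "
                      "infinite PSNR value(s) from the mean", RuntimeWarning)
    return float(finite.mean()) if finite.size else math.nan

def summarize_by_dose(records: list[MetricRecord]) -> list[DoseLevelSummary]:
    """Group records by dose fraction; means plus paired t-test p-values."""
    if not records:
        raise ConfigurationError("summarize_by_dose requires records")
    frame = pd.DataFrame([vars(r) for r in records])
    summaries = []
    for frac, grp in frame.groupby("dose_fraction", sort=True):
        n = len(grp)

        def p_of(col_a, col_b):
            a = grp[col_a].to_numpy()
            b = grp[col_b].to_numpy()
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 2:
                return None
            res = paired_t_test(a[ok], b[ok])
            return None if res.not_computable else res.p_value

        summaries.append(DoseLevelSummary(
            dose_fraction=float(frac), n=n,
            ssim_original=float(grp["ssim_original"].mean()),
            ssim_denoised=float(grp["ssim_denoised"].mean()),
            ssim_p_value=p_of("ssim_original", "ssim_denoised"),
            psnr_original=_finite_mean(
                grp["psnr_original"].to_numpy(), f"psnr_original@{frac:g}"),
            psnr_denoised=_finite_mean(
                grp["psnr_denoised"].to_numpy(), f"psnr_denoised@{frac:g}"),
            psnr_p_value=p_of("psnr_original", "psnr_denoised")))
    return summaries


def records_to_frame(records: list[MetricRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def summaries_to_frame(summaries: list[DoseLevelSummary]) -> pd.DataFrame:
    """Dose %, SSIM (original/denoised), p, PSNR (original/denoised), p."""
    return pd.DataFrame([{
        "dose_percent": int(round(s.dose_fraction * 100)),
        "ssim_original": s.ssim_original, "ssim_denoised": s.ssim_denoised,
        "ssim_p_value": s.ssim_p_value,
        "psnr_original": s.psnr_original, "psnr_denoised": s.psnr_denoised,
        "psnr_p_value": s.psnr_p_value, "n": s.n,
    } for s in summaries])
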