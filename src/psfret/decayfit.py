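"""Single-exponential photoswitching decay fitting, ROI-wise and per-pixel.

The model is ``y = a * exp(-b * t) + c``: amplitude ``a`` (photoelectrons),
off-switching rate constant ``b`` (s^-1) and offset ``c`` absorbing the
residual off-state brightness plus any baseline left after background
subtraction.  A deliberately simple model: multi-exponential components exist
in real photoswitching data, but the rate ratio that carries the FRET signal
is robust to the single-exponential approximation, and three parameters keep
per-pixel fitting tractable.

Goodness of fit is the weighted reduced chi-square used in photon-counting
work: residuals are weighted by the reciprocal of the observed signal (the
Poisson variance estimate in electron units), normalized so the weights
average to one, and compared against the weighted mean variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .iostacks import BackgroundSeries, ImageStack

__all__ = [
    "DecayTrace",
    "ExpFitResult",
    "RateMap",
    "FitConfig",
    "normalize_trace",
    "fit_single_exponential",
    "weighted_reduced_chi2",
    "fit_pixelwise",
    "bin_spatial",
    "rate_histogram",
    "illumination_uniformity",
]

_N_PARAMS = 3


@dataclass
class DecayTrace:
    """Paired time/intensity vectors for one ROI or one pixel."""

    times: np.ndarray
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.shape != self.times.shape:
            raise ValueError("times and values must be matching 1-D vectors")
        if self.times.size < _N_PARAMS + 1:
            raise ValueError(
                f"need at least {_N_PARAMS + 1} time points to fit {_N_PARAMS} parameters"
            )
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.times.size


@dataclass
class ExpFitResult:
    """Fitted ``a * exp(-b t) + c`` with goodness of fit.

    ``b`` is NaN when the optimizer failed to converge on a positive decay
    rate; downstream FRET arithmetic refuses NaN rates, so a non-converged
    pixel propagates as NaN rather than as a silently wrong efficiency.
    """

    a: float
    b: float
    c: float
    chi2_nu: float
    n: int
    converged: bool
    residuals: np.ndarray
    m: int = _N_PARAMS
    sse: float = float("nan")

    def fitted(self, times: np.ndarray) -> np.ndarray:
        return self.a * np.exp(-self.b * np.asarray(times, dtype=float)) + self.c

    def summary(self) -> str:
        lines = [
            "Single-exponential decay fit: y = a*exp(-b*t) + c",
            f"  a (amplitude, e-)   : {self.a:.6g}",
            f"  b (rate, s^-1)      : {self.b:.6g}",
            f"  c (offset, e-)      : {self.c:.6g}",
            f"  weighted red. chi2  : {self.chi2_nu:.4g}",
            f"  n points / m params : {self.n} / {self.m}",
            f"  converged           : {self.converged}",
        ]
        return "\n".join(lines)


@dataclass
class RateMap:
    """Per-pixel fit output: A0, rate, offset and chi-square images.

    Non-fitted pixels are NaN in all four planes; ``mask`` records which
    pixels were fitted.
    """

    a0_img: np.ndarray
    rate_img: np.ndarray
    offset_img: np.ndarray
    chi2_img: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        shapes = {
            self.a0_img.shape,
            self.rate_img.shape,
            self.offset_img.shape,
            self.chi2_img.shape,
            self.mask.shape,
        }
        if len(shapes) != 1:
            raise ValueError("all rate-map planes must share one shape")

    def to_planes(self) -> np.ndarray:
        """4-plane float32 array (A0, rate, offset, chi2) for TIFF export."""
        return np.stack(
            [self.a0_img, self.rate_img, self.offset_img, self.chi2_img]
        ).astype("float32")

    def summary_frame(self) -> pd.DataFrame:
        """One-row summary table over the fitted pixels."""
        def _stats(img: np.ndarray, name: str) -> dict:
            vals = img[self.mask]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                return {f"{name}_mean": np.nan, f"{name}_sd": np.nan}
            return {
                f"{name}_mean": float(vals.mean()),
                f"{name}_sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            }

        row = {"n_fitted": int(self.mask.sum())}
        for img, name in [
            (self.a0_img, "a0"),
            (self.rate_img, "rate"),
            (self.offset_img, "offset"),
            (self.chi2_img, "chi2"),
        ]:
            row.update(_stats(img, name))
        return pd.DataFrame([row])


@dataclass(frozen=True)
class FitConfig:
    """Controls thresholding, binning and the optimizer.

    ``threshold_e`` is the minimum first-frame signal (photoelectrons) for a
    pixel to be fitted; pixels below it are background and left NaN.
    ``bin_factor`` spatially averages ``factor x factor`` blocks before
    fitting, trading resolution for per-trace photon budget (the FLIM
    binning analogue).  ``init_tail_frac`` sets which tail fraction of the
    trace initializes the offset estimate.
    """

    threshold_e: float | None = None
    bin_factor: int = 1
    max_iter: int = 200
    rel_tol: float = 1e-12
    init_tail_frac: float = 0.05
    n_restarts: int = 6
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.bin_factor < 1:
            raise ValueError("bin_factor must be >= 1")
        if not 0 < self.init_tail_frac < 0.5:
            raise ValueError("init_tail_frac must be in (0, 0.5)")


def threshold_from_background(bg: BackgroundSeries, n_sigma: float = 3.0) -> float:
    """Default pixel threshold: background mean + n_sigma * background SD."""
    m = float(bg.means.mean())
    sd = float(bg.means.std(ddof=1)) if bg.means.size > 1 else np.sqrt(max(m, 1.0))
    return m + n_sigma * sd


def normalize_trace(trace: DecayTrace) -> DecayTrace:
    """Divide by the value at the start of the photoswitching cycle."""
    v0 = trace.values[0]
    if v0 <= 0:
        raise ValueError("cannot normalize: first time point is not positive")
    return DecayTrace(trace.times.copy(), trace.values / v0, normalized=True)


def _initial_guess(t: np.ndarray, y: np.ndarray, tail_frac: float) -> tuple[float, float, float]:
    n = y.size
    n_tail = max(1, int(round(tail_frac * n)))
    c0 = float(np.mean(y[-n_tail:]))
    a0 = float(y[0] - c0)
    span = float(t[-1] - t[0])
    if a0 <= 0:
        a0 = max(float(np.ptp(y)), np.finfo(float).eps)
        c0 = float(np.min(y))
    # log-linear regression over points clearly above the offset estimate
    sel = y > c0 + 0.1 * a0
    b0 = 1.0 / span
    if sel.sum() >= 2:
        z = np.log(np.maximum(y[sel] - c0, np.finfo(float).tiny))
        slope = np.polyfit(t[sel], z, 1)[0]
        if np.isfinite(slope) and slope < 0:
            b0 = max(-float(slope), np.finfo(float).eps)
    return a0, b0, c0


def _residuals(p: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    return y - (p[0] * np.exp(-p[1] * t) + p[2])


def _jac(p: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    e = np.exp(-p[1] * t)
    return np.stack([-e, p[0] * t * e, -np.ones_like(t)], axis=1)


def _solve(t, y, p0, cfg: FitConfig):
    lower = np.array([0.0, 0.0, -np.inf])
    upper = np.array([np.inf, np.inf, np.inf])
    p0 = np.clip(p0, lower + np.finfo(float).tiny, None)
    try:
        return least_squares(
            _residuals,
            p0,
            jac=_jac,
            bounds=(lower, upper),
            args=(t, y),
            xtol=cfg.rel_tol,
            ftol=cfg.rel_tol,
            gtol=None,
            max_nfev=cfg.max_iter * 10,
        )
    except Exception:  # singular Jacobian etc. -> treated as a failed start
        return None


def fit_single_exponential(trace: DecayTrace, cfg: FitConfig | None = None) -> ExpFitResult:
    """Least-squares fit of ``a * exp(-b t) + c`` to one decay trace.

    Initialization: the offset from the trace tail, the amplitude from the
    first point, the rate from a log-linear regression of the offset-free
    signal.  If the first solve fails or stalls, a deterministic lattice of
    restarts around the initial rate is tried; the best sum of squares wins.
    A constant (degenerate) trace returns a not-converged result with NaN
    rate and a warning.
    """
    cfg = cfg or FitConfig()
    t = trace.times
    y = trace.values
    scale = max(float(np.ptp(y)), abs(float(np.mean(y))), 1.0)
    if np.ptp(y) <= 16 * np.finfo(float).eps * scale:
        warnings.warn("degenerate (constant) trace; decay rate undefined", RuntimeWarning)
        res = np.zeros_like(y)
        return ExpFitResult(
            a=0.0, b=np.nan, c=float(np.mean(y)), chi2_nu=np.nan,
            n=y.size, converged=False, residuals=res, sse=0.0,
        )

    a0, b0, c0 = _initial_guess(t, y, cfg.init_tail_frac)
    best = _solve(t, y, np.array([a0, b0, c0]), cfg)
    span = float(t[-1] - t[0])
    need_restart = best is None or not best.success or best.x[1] <= 0
    if need_restart or cfg.n_restarts < 0:
        # deterministic restart lattice spanning rates around b0 and 1/span
        for mult in (0.25, 0.5, 2.0, 4.0, 8.0, 16.0)[: max(cfg.n_restarts, 0)]:
            for b_start in (b0 * mult, mult / span):
                cand = _solve(t, y, np.array([max(a0, scale * 0.1), b_start, c0]), cfg)
                if cand is None:
                    continue
                if best is None or cand.cost < best.cost:
                    best = cand

    if best is None or not np.all(np.isfinite(best.x)):
        warnings.warn("exponential fit failed to converge", RuntimeWarning)
        res = y - np.mean(y)
        return ExpFitResult(
            a=np.nan, b=np.nan, c=np.nan, chi2_nu=np.nan,
            n=y.size, converged=False, residuals=res, sse=float(res @ res),
        )

    a, b, c = (float(v) for v in best.x)
    residuals = _residuals(best.x, t, y)
    sse = float(residuals @ residuals)
    converged = bool(best.success) and b > 0 and np.all(np.isfinite(best.x))
    if not converged:
        b = np.nan
    result = ExpFitResult(
        a=a, b=b, c=c, chi2_nu=np.nan, n=y.size,
        converged=converged, residuals=residuals, sse=sse,
    )
    if converged and np.all(y > 0):
        result.chi2_nu = weighted_reduced_chi2(trace, result)
    return result


def weighted_reduced_chi2(trace: DecayTrace, fit: ExpFitResult) -> float:
    """Weighted reduced chi-square with observed-signal variance weights.

    With observed signal ``f_o`` and fit ``f_e`` at each time point,

        w_t      = (1 / f_o_t) / ((1/n) * sum 1/f_o_t)
        s^2      = 1/(n - m) * sum w_t * (f_o_t - f_e_t)^2
        sigma^2  = 1 / ((1/n) * sum 1/f_o_t)
        chi2_nu  = s^2 / sigma^2

    ``f_o`` itself serves as the variance estimate, which is the Poisson
    assumption in electron units; non-positive points carry no usable
    variance estimate and are excluded (with ``n`` reduced and a warning).
    """
    f_o = trace.values
    r = np.asarray(fit.residuals, dtype=float)
    if r.shape != f_o.shape:
        raise ValueError("fit residuals do not match this trace")
    ok = f_o > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} non-positive points excluded from chi-square weights",
            RuntimeWarning,
        )
        f_o, r = f_o[ok], r[ok]
    n = f_o.size
    if n <= fit.m:
        return float("nan")
    inv = 1.0 / f_o
    mean_inv = inv.mean()
    w = inv / mean_inv
    s2 = float((w * r**2).sum()) / (n - fit.m)
    sigma2 = 1.0 / mean_inv
    return s2 / sigma2


def bin_spatial(stack: ImageStack, factor: int) -> ImageStack:
    """Non-overlapping ``factor x factor`` block means per frame.

    The output extent is floor-divided; trailing rows/columns that do not
    fill a block are cropped.
    """
    if factor < 1:
        raise ValueError("bin factor must be >= 1")
    if factor == 1:
        return ImageStack(stack.data.copy(), stack.times.copy(), stack.channel, dict(stack.meta))
    T, Y, X = stack.data.shape
    ny, nx = Y // factor, X // factor
    if ny == 0 or nx == 0:
        raise ValueError(f"bin factor {factor} exceeds image extent {(Y, X)}")
    cropped = stack.data[:, : ny * factor, : nx * factor]
    binned = cropped.reshape(T, ny, factor, nx, factor).mean(axis=(2, 4))
    meta = dict(stack.meta)
    meta["bin_factor"] = meta.get("bin_factor", 1) * factor
    return ImageStack(binned, stack.times.copy(), stack.channel, meta)


def fit_pixelwise(stack: ImageStack, cfg: FitConfig) -> RateMap:
    """Treat each pixel as an ROI and fit its decay independently.

    Pixels whose first-frame signal is below ``cfg.threshold_e`` are skipped
    (left NaN) to avoid fitting background.  If ``cfg.bin_factor > 1`` the
    stack is spatially averaged first.  Fits are independent and order-free.
    """
    if cfg.threshold_e is None:
        raise ValueError("fit_pixelwise needs cfg.threshold_e (see threshold_from_background)")
    if cfg.bin_factor > 1:
        stack = bin_spatial(stack, cfg.bin_factor)
    first = stack.data[0]
    mask = np.isfinite(first) & (first >= cfg.threshold_e)
    shape = stack.frame_shape
    imgs = {k: np.full(shape, np.nan) for k in ("a0", "rate", "offset", "chi2")}
    if not mask.any():
        warnings.warn("no pixel above threshold; empty rate map", RuntimeWarning)
        return RateMap(imgs["a0"], imgs["rate"], imgs["offset"], imgs["chi2"], mask)
    times = stack.times
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        for yx in np.argwhere(mask):
            y, x = int(yx[0]), int(yx[1])
            trace = DecayTrace(times, stack.data[:, y, x])
            fit = fit_single_exponential(trace, cfg)
            imgs["a0"][y, x] = fit.a
            imgs["rate"][y, x] = fit.b
            imgs["offset"][y, x] = fit.c
            imgs["chi2"][y, x] = fit.chi2_nu
    return RateMap(imgs["a0"], imgs["rate"], imgs["offset"], imgs["chi2"], mask)


def rate_histogram(rmap: RateMap, bins: int | Sequence[float] = 50) -> pd.DataFrame:
    """Histogram of fitted rate constants (NaN excluded)."""
    vals = rmap.rate_img[rmap.mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("rate map has no fitted pixels")
    counts, edges = np.histogram(vals, bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def illumination_uniformity(rmap: RateMap, min_pixels: int = 10) -> float:
    """Coefficient of variation (SD/mean) of the rate image.

    The photoswitching rate scales with local excitation intensity, so on a
    uniform fluorophore field this CV is a direct illumination-flatness QC
    metric.
    """
    vals = rmap.rate_img[rmap.mask]
    vals = vals[np.isfinite(vals)]
    if vals.size < min_pixels:
        raise ValueError(f"need at least {min_pixels} fitted pixels, have {vals.size}")
    mean = float(vals.mean())
    if mean == 0:
        raise ValueError("mean rate is zero; CV undefined")
    return float(vals.std(ddof=1)) / mean
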