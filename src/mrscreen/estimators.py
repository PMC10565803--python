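"""Causal-effect estimators for two-sample Mendelian randomization.

Given k harmonized instruments with exposure effects βX_j (SE σX_j) and
outcome effects βY_j (SE σY_j), each estimator combines the per-SNP Wald
ratios θ_j = βY_j / βX_j into a single causal log-odds-ratio:

* ``wald_ratio`` — a single SNP's θ_j with first-order delta-method SE
  σY_j / |βX_j|.
* ``ivw`` — inverse-variance-weighted mean of the ratios, equivalently the
  slope of the zero-intercept weighted regression of βY on βX with weights
  1/σY².  The primary estimator.  SEs use a multiplicative random-effects
  scale max(1, sqrt(Q/(k−1))) over the fixed-effect SE, so heterogeneity
  widens the interval but can never shrink it.
* ``mr_egger`` — the same weighted regression with a free intercept.  The
  slope is the pleiotropy-adjusted causal effect; the intercept estimates
  the average direct (pleiotropic) effect and is the basis of the Egger
  pleiotropy test.  Instruments are oriented so βX_j ≥ 0 first (Egger is
  not orientation-invariant).  Inference uses t with k − 2 df and a
  residual-variance floor at 1.
* ``weighted_median`` — weighted 50th percentile of the ratios with weights
  βX_j²/σY_j²; consistent when valid instruments carry > 50% of the weight.
  SE by parametric bootstrap.

All estimates carry the odds-ratio transform OR = exp(β) with a 95% CI
exp(β ± 1.96·SE).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .harmonize import HarmonizedInstrument, HarmonizedSet

logger = logging.getLogger(__name__)

Z95 = 1.96  # CI multiplier for the reported 95% interval

METHODS = ("wald_ratio", "ivw", "mr_egger", "weighted_median")
_MIN_SNPS = {"wald_ratio": 1, "ivw": 2, "weighted_median": 2, "mr_egger": 3}


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log-odds scale with its OR transform."""

    method: str
    beta: float
    se: float
    pvalue: float
    or_: float
    ci_low: float
    ci_high: float
    n_snp: int

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.n_snp < _MIN_SNPS[self.method]:
            raise ValueError(
                f"{self.method} needs >= {_MIN_SNPS[self.method]} instruments, got {self.n_snp}"
            )
        if not (self.ci_low < self.or_ < self.ci_high):
            raise ValueError("CI must bracket the OR")


@dataclass(frozen=True)
class EggerIntercept:
    """MR-Egger intercept: average directional pleiotropic effect."""

    intercept: float
    se: float
    pvalue: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("intercept se must be > 0")


def _make_estimate(method: str, beta: float, se: float, n_snp: int,
                   pvalue: float | None = None) -> MREstimate:
    if pvalue is None:
        pvalue = 2.0 * stats.norm.sf(abs(beta) / se)
    return MREstimate(
        method=method, beta=float(beta), se=float(se), pvalue=float(pvalue),
        or_=math.exp(beta), ci_low=math.exp(beta - Z95 * se),
        ci_high=math.exp(beta + Z95 * se), n_snp=int(n_snp),
    )


def wald_ratio(inst: HarmonizedInstrument) -> MREstimate:
    """Single-SNP causal estimate βY/βX with delta-method SE σY/|βX|."""
    if inst.beta_exp == 0:
        raise ValueError(f"{inst.snp_id}: beta_exp = 0, Wald ratio undefined")
    beta = inst.beta_out / inst.beta_exp
    se = inst.se_out / abs(inst.beta_exp)
    return _make_estimate("wald_ratio", beta, se, 1)


def _ivw_fixed(bx: np.ndarray, by: np.ndarray, se_out: np.ndarray):
    """Fixed-effect IVW point estimate, SE and Cochran's Q (shared core)."""
    w = bx**2 / se_out**2
    beta = float(np.sum(bx * by / se_out**2) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    theta = by / bx
    q = float(np.sum(w * (theta - beta) ** 2))
    return beta, se_fixed, q, w


def ivw(h: HarmonizedSet) -> MREstimate:
    """Inverse-variance-weighted estimate over all instruments.

    Point estimate Σ βX_j βY_j/σY_j² / Σ βX_j²/σY_j²; reported SE is the
    multiplicative random-effects SE, the fixed-effect SE inflated by
    max(1, sqrt(Q/(k−1))).  Two-sided normal p-value.

    Raises
    ------
    ValueError
        With fewer than 2 instruments (use :func:`wald_ratio` for k = 1).
    """
    k = len(h)
    if k < 2:
        raise ValueError(f"ivw needs >= 2 instruments (got {k}); use wald_ratio for k = 1")
    if np.any(h.beta_exp == 0):
        raise ValueError("ivw undefined with beta_exp = 0 instruments")
    beta, se_fixed, q, _ = _ivw_fixed(h.beta_exp, h.beta_out, h.se_out)
    scale = max(1.0, math.sqrt(q / (k - 1)))
    return _make_estimate("ivw", beta, se_fixed * scale, k)


def ivw_fixed_effect(h: HarmonizedSet) -> MREstimate:
    """Fixed-effect IVW (no random-effects inflation); used by Cochran's Q
    and by callers that need the uninflated SE."""
    k = len(h)
    if k < 2:
        raise ValueError(f"ivw needs >= 2 instruments (got {k})")
    beta, se_fixed, _, _ = _ivw_fixed(h.beta_exp, h.beta_out, h.se_out)
    return _make_estimate("ivw", beta, se_fixed, k)


@dataclass(frozen=True)
class EggerFit:
    """Full MR-Egger weighted-regression fit, including per-instrument
    diagnostics needed by the pleiotropy-flagging rules."""

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    sigma2: float  # residual variance after the floor at 1
    residuals: np.ndarray  # raw residuals, oriented scale
    leverage: np.ndarray
    weights: np.ndarray  # 1/se_out^2
    df: int

    def studentized_residuals(self) -> np.ndarray:
        denom = np.sqrt(self.sigma2 * (1.0 - self.leverage) / self.weights)
        return self.residuals / denom


def _egger_fit(h: HarmonizedSet) -> EggerFit:
    k = len(h)
    if k < 3:
        raise ValueError(f"mr_egger needs >= 3 instruments, got {k}")
    # Orient every instrument to a non-negative exposure effect.
    sign = np.where(h.beta_exp < 0, -1.0, 1.0)
    bx = h.beta_exp * sign
    by = h.beta_out * sign
    if np.ptp(bx) == 0:
        raise ValueError("mr_egger: zero variance in |beta_exp|, slope unidentified")
    w = 1.0 / h.se_out**2

    X = np.column_stack([np.ones(k), bx])
    XtW = X.T * w
    A = XtW @ X
    coef = np.linalg.solve(A, XtW @ by)
    resid = by - X @ coef
    df = k - 2
    sigma2 = max(1.0, float(np.sum(w * resid**2) / df))
    cov = np.linalg.inv(A) * sigma2
    # Leverage of weighted least squares: diag of sqrt(W) X (X'WX)^-1 X' sqrt(W).
    leverage = np.einsum("ij,jk,ik->i", X, np.linalg.inv(A), X) * w
    return EggerFit(
        slope=float(coef[1]), slope_se=float(np.sqrt(cov[1, 1])),
        intercept=float(coef[0]), intercept_se=float(np.sqrt(cov[0, 0])),
        sigma2=sigma2, residuals=resid, leverage=leverage, weights=w, df=df,
    )


def mr_egger(h: HarmonizedSet) -> tuple[MREstimate, EggerIntercept]:
    """MR-Egger regression: causal slope and pleiotropy intercept.

    Weighted regression of βY on βX with a free intercept (weights 1/σY²)
    after orienting all instruments to βX ≥ 0.  Coefficient SEs use the
    weighted residual variance floored at 1 (multiplicative random effects);
    p-values from t with k − 2 df.
    """
    fit = _egger_fit(h)
    slope_p = 2.0 * stats.t.sf(abs(fit.slope) / fit.slope_se, fit.df)
    int_p = 2.0 * stats.t.sf(abs(fit.intercept) / fit.intercept_se, fit.df)
    estimate = _make_estimate("mr_egger", fit.slope, fit.slope_se, len(h), pvalue=float(slope_p))
    intercept = EggerIntercept(fit.intercept, fit.intercept_se, float(int_p))
    return estimate, intercept


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    """Weighted median by linear interpolation at cumulative-weight midpoints.

    With weights normalised to sum 1 and ratios sorted ascending, the
    cumulative midpoint of ratio j is s_j = Σ_{i<=j} w_i − w_j/2; the
    estimate interpolates θ linearly at s = 0.5, clamping to the first/last
    ratio outside [s_1, s_k].
    """
    return float(_weighted_median_rows(theta[None, :], w[None, :])[0])


def _weighted_median_rows(theta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise weighted median (shared by the bootstrap), clamped to the
    first/last ratio outside the cumulative-midpoint range."""
    order = np.argsort(theta, axis=1, kind="stable")
    th = np.take_along_axis(theta, order, axis=1)
    ws = np.take_along_axis(w, order, axis=1)
    ws = ws / ws.sum(axis=1, keepdims=True)
    s = np.cumsum(ws, axis=1) - ws / 2.0
    k = th.shape[1]
    j = np.sum(s < 0.5, axis=1)  # first midpoint >= 0.5
    rows = np.arange(th.shape[0])
    lo = np.clip(j - 1, 0, k - 1)
    hi = np.clip(j, 0, k - 1)
    s_lo, s_hi = s[rows, lo], s[rows, hi]
    th_lo, th_hi = th[rows, lo], th[rows, hi]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(s_hi > s_lo, (0.5 - s_lo) / (s_hi - s_lo), 0.0)
    est = th_lo + frac * (th_hi - th_lo)
    est = np.where(j == 0, th[:, 0], est)
    est = np.where(j == k, th[:, -1], est)
    return est


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int | None = None,
                    rng: np.random.Generator | None = None) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Ratios θ_j = βY_j/βX_j are weighted by βX_j²/σY_j² (the inverse Wald-
    ratio variances).  The SE is the standard deviation of the estimate over
    ``n_boot`` replicates resampling each βX_j ~ N(βX_j, σX_j) and
    βY_j ~ N(βY_j, σY_j).  Instruments with βX_j = 0 are dropped with a
    warning.  Pass ``seed`` (or an explicit ``rng``) for reproducibility.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if rng is None:
        if seed is None:
            raise ValueError("weighted_median requires a seed (or rng) for the bootstrap")
        rng = np.random.default_rng(seed)

    nonzero = h.beta_exp != 0
    if not nonzero.all():
        logger.warning(
            "%s: dropping %d instrument(s) with beta_exp = 0 from weighted median",
            h.exposure_id, int((~nonzero).sum()),
        )
    bx, by = h.beta_exp[nonzero], h.beta_out[nonzero]
    sx, sy = h.se_exp[nonzero], h.se_out[nonzero]
    k = bx.size
    if k == 0:
        raise ValueError("weighted_median: all instruments have beta_exp = 0")
    if k < 2:
        raise ValueError(f"weighted_median needs >= 2 usable instruments, got {k}")

    beta = _weighted_median(by / bx, bx**2 / sy**2)

    bx_star = rng.normal(bx, sx, size=(n_boot, k))
    by_star = rng.normal(by, sy, size=(n_boot, k))
    bx_star = np.where(bx_star == 0, np.finfo(float).tiny, bx_star)  # degenerate draw
    boot = _weighted_median_rows(by_star / bx_star, bx_star**2 / sy**2)
    if n_boot > 1:
        se = float(np.std(boot, ddof=1))
    else:
        # One-replicate scale estimate: half-normal mean-absolute-deviation.
        se = float(abs(boot[0] - beta)) * math.sqrt(math.pi / 2.0)
    se = max(se, 1e-12 * max(1.0, abs(beta)))  # keep the CI well-formed
    return _make_estimate("weighted_median", beta, se, k)
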