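"""Two-sample MR estimators on harmonized summary statistics.

All estimators consume a :class:`~mrpath.summary_data.HarmonizedSet` (exposure
and outcome betas aligned to a common effect allele) and return an
:class:`MREstimate` on the log scale (log odds per exposure unit for binary
outcomes).  Implemented:

* per-variant Wald ratios;
* multiplicative random-effects inverse-variance weighted (IVW) meta-analysis
  of the Wald ratios, with Cochran's Q and the I² heterogeneity statistic;
* MR-Egger weighted regression with intercept (average directional
  pleiotropy) and its intercept test;
* the weighted median, consistent when at least half the weight is on valid
  instruments;
* a weighted mode-based estimator (normal-kernel density argmax), consistent
  when the largest group of instruments is valid;
* multivariable MR (MVMR) for an exposure plus one mediator, giving each
  regressor's direct effect.

Inverse-variance weights are first-order throughout: w_j = beta_xj² / se_yj²,
equivalently 1/se(theta_j)² with se(theta_j) = se_yj / |beta_xj|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .summary_data import AnalysisError, HarmonizedSet

__all__ = ["RatioEstimates", "MREstimate", "OddsRatioView", "wald_ratios",
           "ivw", "egger", "weighted_median", "mode_based", "mvmr", "Z95"]

#: two-sided 95% normal quantile used for every confidence interval
Z95 = sps.norm.ppf(0.975)


@dataclass
class RatioEstimates:
    """Per-variant Wald ratios with first-order SEs and IV weights."""

    theta: np.ndarray
    se: np.ndarray

    @property
    def weights(self) -> np.ndarray:
        return 1.0 / self.se**2


@dataclass
class OddsRatioView:
    """A log-scale estimate re-expressed as an odds ratio with its CI."""

    or_: float
    or_low: float
    or_high: float


@dataclass
class MREstimate:
    """A causal-effect estimate with its uncertainty and heterogeneity.

    ``estimate`` is on the log scale; ``Q`` is Cochran's heterogeneity
    statistic (Rücker's Q' for Egger) and ``I2`` the percentage of variation
    attributable to heterogeneity, floored at 0.
    """

    method: str
    estimate: float
    se: float
    pval: float
    n_snps: int
    Q: float = 0.0
    I2: float = 0.0
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None
    scale: str = "log"

    @property
    def ci_low(self) -> float:
        return self.estimate - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.estimate + Z95 * self.se

    def odds_ratio(self) -> OddsRatioView:
        return OddsRatioView(float(np.exp(self.estimate)),
                             float(np.exp(self.ci_low)),
                             float(np.exp(self.ci_high)))


def _i2(Q: float, df: int) -> float:
    if df < 1 or Q <= 0:
        return 0.0
    return max(0.0, (Q - df) / Q) * 100.0


def _norm_p(z: float) -> float:
    return float(2 * sps.norm.sf(abs(z)))


def wald_ratios(h: HarmonizedSet) -> RatioEstimates:
    """Per-variant causal estimates theta_j = by_j / bx_j.

    Variants with bx = 0 are dropped with a warning; all-zero bx is an error.
    """
    bx, by, sy = h.bx, h.by, h.sy
    nz = bx != 0
    if not nz.any():
        raise AnalysisError("all exposure betas are zero; no Wald ratios")
    if not nz.all():
        warnings.warn(f"dropping {int((~nz).sum())} variant(s) with zero exposure beta")
    return RatioEstimates(by[nz] / bx[nz], sy[nz] / np.abs(bx[nz]))


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    """Weighted mean of Wald ratios; returns (estimate, fixed_se, Q, df)."""
    w = bx**2 / sy**2
    theta = by / bx
    est = float(np.sum(w * theta) / np.sum(w))
    fixed_se = float(np.sum(w) ** -0.5)
    Q = float(np.sum(w * (theta - est) ** 2))
    return est, fixed_se, Q, len(bx) - 1


def ivw(h: HarmonizedSet) -> MREstimate:
    """Multiplicative random-effects inverse-variance weighted estimate.

    The point estimate is the inverse-variance weighted mean of the Wald
    ratios (identical to weighted least squares of by on bx through the
    origin).  Under multiplicative random effects the fixed-effect SE is
    inflated by sqrt(max(1, Q/(J-1))), so the SE is never deflated below the
    fixed-effect one when the instruments are homogeneous.

    A single usable variant degrades gracefully to its Wald ratio.
    """
    r = wald_ratios(h)
    n = len(r.theta)
    if n == 1:
        est, se = float(r.theta[0]), float(r.se[0])
        return MREstimate("IVW", est, se, _norm_p(est / se), 1, Q=0.0, I2=0.0)
    nz = h.bx != 0
    est, fixed_se, Q, df = _ivw_core(h.bx[nz], h.by[nz], h.sy[nz])
    se = fixed_se * float(np.sqrt(max(1.0, Q / df)))
    return MREstimate("IVW", est, se, _norm_p(est / se), n, Q=Q, I2=_i2(Q, df))


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares via normal equations.

    Returns (coef, cov_unscaled, weighted RSS); SEs are the caller's business.
    """
    Xw = X * np.sqrt(w)[:, None]
    yw = y * np.sqrt(w)
    XtX = Xw.T @ Xw
    rank = np.linalg.matrix_rank(XtX)
    if rank < X.shape[1]:
        raise AnalysisError("collinear exposures: design matrix is rank-deficient")
    coef = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ coef
    rss = float(resid @ resid)
    cov = np.linalg.inv(XtX)
    return coef, cov, rss


def egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger weighted regression with intercept.

    Each variant is first oriented so its exposure beta is non-negative
    (negating bx and by jointly), then by is regressed on bx with an
    intercept, weighted by 1/sy².  The slope estimates the causal effect
    under the InSIDE assumption; the intercept estimates average directional
    pleiotropy, and its p-value below 0.05 is taken as evidence of horizontal
    pleiotropy.  SEs are inflated by sqrt(max(1, RSS_w/(J-2))) and p-values
    use the t distribution with J-2 df.
    """
    n = h.n_snps
    if n < 3:
        raise AnalysisError("MR-Egger requires at least 3 instruments")
    sign = np.where(h.bx < 0, -1.0, 1.0)
    bx, by, sy = h.bx * sign, h.by * sign, h.sy
    if np.allclose(bx.std(), 0):
        raise AnalysisError("oriented exposure betas have zero variance (collinear)")
    X = np.column_stack([np.ones(n), bx])
    coef, cov, rss = _wls(X, by, 1.0 / sy**2)
    df = n - 2
    scale = max(1.0, rss / df)
    ses = np.sqrt(np.diag(cov) * scale)
    slope, slope_se = float(coef[1]), float(ses[1])
    icpt, icpt_se = float(coef[0]), float(ses[0])
    p_slope = float(2 * sps.t.sf(abs(slope / slope_se), df))
    p_icpt = float(2 * sps.t.sf(abs(icpt / icpt_se), df))
    return MREstimate("Egger", slope, slope_se, p_slope, n, Q=rss,
                      I2=_i2(rss, df), egger_intercept=icpt,
                      egger_intercept_p=p_icpt)


def _weighted_median_core(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta, kind="mergesort")
    th, wt = theta[order], w[order]
    cum = np.cumsum(wt) - wt / 2
    cum /= wt.sum()
    return float(np.interp(0.5, cum, th))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000,
                    seed: int | None = 0) -> MREstimate:
    """Weighted median of the Wald ratios, SE by parametric bootstrap.

    The estimate interpolates the inverse-variance-weighted cumulative
    distribution of the ordered ratios at probability 1/2; it is consistent
    when valid instruments carry at least half the total weight.  The SE is
    the standard deviation of the estimate over ``n_boot`` parametric
    resamples bx* ~ N(bx, sx), by* ~ N(by, sy).
    """
    if h.n_snps < 3:
        raise AnalysisError("weighted median requires at least 3 instruments")
    r = wald_ratios(h)
    est = _weighted_median_core(r.theta, r.weights)
    rng = np.random.default_rng(seed)
    bxs = rng.normal(h.bx, h.sx, size=(n_boot, h.n_snps))
    bys = rng.normal(h.by, h.sy, size=(n_boot, h.n_snps))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bx = bxs[i]
        nz = bx != 0
        th = bys[i][nz] / bx[nz]
        wt = (bx[nz] / h.sy[nz]) ** 2
        boots[i] = _weighted_median_core(th, wt)
    se = float(boots.std(ddof=1))
    return MREstimate("WeightedMedian", est, se,
                      _norm_p(est / se) if se > 0 else 0.0, h.n_snps)


def _mode_core(theta: np.ndarray, w: np.ndarray, phi: float,
               n_grid: int = 2000) -> float:
    n = len(theta)
    mad = np.median(np.abs(theta - np.median(theta)))
    s = phi * 0.9 * min(theta.std(ddof=1) if n > 1 else 0.0, 1.4826 * mad) * n ** (-0.2)
    if s <= 0:
        return float(theta[0]) if np.allclose(theta, theta[0]) else float(np.median(theta))
    grid = np.linspace(theta.min() - 3 * s, theta.max() + 3 * s, n_grid)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / s) ** 2)).sum(axis=1)
    return float(grid[int(np.argmax(dens))])  # first argmax -> smallest grid value


def mode_based(h: HarmonizedSet, phi: float = 1.0, n_boot: int = 1000,
               seed: int | None = 0) -> MREstimate:
    """Weighted mode of the Wald ratios via kernel-density argmax.

    A normal kernel with bandwidth 0.9·min(sd, 1.4826·MAD)·J^(-1/5), scaled
    by the tuning parameter ``phi``, is placed at each ratio with
    inverse-variance weight; the estimate is the density argmax over a dense
    grid.  Consistent when the largest group of instruments sharing one ratio
    is valid (ZEMPA).  SE by seeded parametric bootstrap.
    """
    if h.n_snps < 3:
        raise AnalysisError("mode-based estimator requires at least 3 instruments")
    r = wald_ratios(h)
    est = _mode_core(r.theta, r.weights, phi)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bx = rng.normal(h.bx, h.sx)
        by = rng.normal(h.by, h.sy)
        nz = bx != 0
        th = by[nz] / bx[nz]
        wt = (bx[nz] / h.sy[nz]) ** 2
        boots[i] = _mode_core(th, wt, phi)
    se = float(boots.std(ddof=1))
    return MREstimate("ModeBased", est, se,
                      _norm_p(est / se) if se > 0 else 0.0, h.n_snps)


def mvmr(bx_exposure: np.ndarray, bx_mediator: np.ndarray, by: np.ndarray,
         sy: np.ndarray, names: tuple[str, str] = ("exposure", "mediator"),
         ) -> dict[str, MREstimate]:
    """Multivariable MR for one exposure plus one mediator.

    Regresses the outcome betas jointly on both traits' variant betas with no
    intercept, weighted by 1/sy², over the union of both instrument sets
    (pre-pruned for mutual independence by the caller).  Each coefficient is
    that trait's direct effect holding the other fixed; the mediator's
    coefficient is the exposure-adjusted mediator→outcome effect used in
    mediation analysis.
    """
    bx1 = np.asarray(bx_exposure, dtype=float)
    bx2 = np.asarray(bx_mediator, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    n = len(by)
    if n < 3:
        raise AnalysisError("MVMR requires at least 3 instruments")
    X = np.column_stack([bx1, bx2])
    coef, cov, rss = _wls(X, by, 1.0 / sy**2)
    df = n - 2
    scale = max(1.0, rss / df)
    ses = np.sqrt(np.diag(cov) * scale)
    out = {}
    for k, name in enumerate(names):
        b, se = float(coef[k]), float(ses[k])
        p = float(2 * sps.t.sf(abs(b / se), df))
        out[name] = MREstimate("MVMR", b, se, p, n, Q=rss, I2=_i2(rss, df))
    return out
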