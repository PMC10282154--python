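"""Heterogeneity, leave-one-out, MR-PRESSO and the outlier-removal protocol.

MR-PRESSO is a Monte-Carlo residual-sum-of-squares test: the observed RSS of
each variant around the leave-one-out IVW fit is compared with its simulated
null distribution; variants with extreme residuals (Bonferroni-corrected) are
pleiotropic outliers, and a distortion test asks whether removing them moves
the estimate more than removing random variants would.

Outlier removal is not run unconditionally: the study protocol reruns IVW and
leave-one-out without outliers only when the MR-Egger intercept test signals
horizontal pleiotropy (p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import MREstimate, _ivw_core, ivw
from .summary_data import AnalysisError, HarmonizedSet

__all__ = ["LeaveOneOutResult", "PressoResult", "OutlierRerunResult",
           "cochran_q", "leave_one_out", "mr_presso",
           "remove_outliers_and_rerun"]


@dataclass
class LeaveOneOutResult:
    """IVW fit on all instruments except one."""

    excluded_variant: str
    estimate: float
    se: float
    pval: float


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss: float
    global_p: float
    outlier_p: np.ndarray          # Bonferroni-corrected, one per SNP
    outliers: list[str]
    distortion_p: float | None
    estimate_raw: MREstimate
    estimate_corrected: MREstimate | None


@dataclass
class OutlierRerunResult:
    """Pruned instrument set and refits after Egger-gated outlier removal."""

    triggered: bool
    pruned: HarmonizedSet
    ivw: MREstimate
    loo: list[LeaveOneOutResult]
    loo_flag: bool
    removed: list[str] = field(default_factory=list)


def cochran_q(h: HarmonizedSet) -> tuple[float, int, float]:
    """Cochran's Q over the Wald ratios, with df = J-1 and I² (floored at 0)."""
    if h.n_snps < 2:
        raise AnalysisError("heterogeneity needs at least 2 instruments")
    _, _, Q, df = _ivw_core(h.bx, h.by, h.sy)
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return Q, df, I2


def leave_one_out(h: HarmonizedSet) -> tuple[list[LeaveOneOutResult], bool]:
    """IVW refit omitting each instrument in turn.

    The flag is raised when the full-set IVW is significant (p <= 0.05) but at
    least one single-variant removal loses significance (p > 0.05) — the
    result relies on that particular variant.
    """
    if h.n_snps < 3:
        raise AnalysisError("leave-one-out needs at least 3 instruments")
    full = ivw(h)
    results = []
    for j in range(h.n_snps):
        sub = h.subset([i for i in range(h.n_snps) if i != j])
        fit = ivw(sub)
        results.append(LeaveOneOutResult(h.variants[j], fit.estimate, fit.se,
                                         fit.pval))
    flag = full.pval <= 0.05 and any(r.pval > 0.05 for r in results)
    return results, flag


def _loo_ivw_estimates(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Vectorized leave-one-out IVW point estimates, one per variant.

    Works on 2-D inputs too (rows = simulations), returning the same shape.
    """
    w = bx**2 / sy**2
    num = (w * (by / bx)).sum(axis=-1, keepdims=True)
    den = w.sum(axis=-1, keepdims=True)
    return (num - w * (by / bx)) / (den - w)


def mr_presso(h: HarmonizedSet, n_sim: int = 1000, seed: int | None = 0,
              outlier_alpha: float = 0.05) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    Observed RSS sums each variant's squared residual around the IVW fit of
    the other variants.  The null distribution is built by parametric
    simulation (by* ~ N(theta_loo·bx, sy), bx* ~ N(bx, sx)), recomputing the
    leave-one-out fits within each simulated dataset.  Empirical p-values use
    the (1+k)/(n+1) convention and the per-variant outlier p-values are
    Bonferroni-corrected by J.  The distortion p compares the raw-vs-corrected
    IVW difference against removals of random same-size variant subsets.
    """
    J = h.n_snps
    if J < 4:
        raise AnalysisError("PRESSO requires >= 4 instruments")
    if (h.bx == 0).any():
        raise AnalysisError("PRESSO requires nonzero exposure betas")
    rng = np.random.default_rng(seed)

    theta_loo = _loo_ivw_estimates(h.bx, h.by, h.sy)
    resid_obs = h.by - theta_loo * h.bx
    rss_obs = float((resid_obs**2).sum())

    bx_sim = rng.normal(h.bx, h.sx, size=(n_sim, J))
    by_sim = rng.normal(theta_loo * h.bx, h.sy, size=(n_sim, J))
    bad = bx_sim == 0
    if bad.any():  # ratio-safe: nudge exact zeros by a tiny amount
        bx_sim[bad] = 1e-12
    theta_loo_sim = _loo_ivw_estimates(bx_sim, by_sim, np.broadcast_to(h.sy, (n_sim, J)))
    resid_sim = by_sim - theta_loo_sim * bx_sim
    rss_sim = (resid_sim**2).sum(axis=1)

    global_p = float((1 + (rss_sim >= rss_obs).sum()) / (n_sim + 1))
    p_raw = (1 + (resid_sim**2 >= resid_obs[None, :] ** 2).sum(axis=0)) / (n_sim + 1)
    outlier_p = np.minimum(1.0, p_raw * J)
    out_idx = np.flatnonzero(outlier_p < outlier_alpha)
    outliers = [h.variants[i] for i in out_idx]

    raw = ivw(h)
    corrected = None
    distortion_p = None
    if outliers and len(outliers) < J - 1:
        kept = h.without(outliers)
        corrected = ivw(kept)
        obs_diff = abs(raw.estimate - corrected.estimate)
        n_rand = 1000
        diffs = np.empty(n_rand)
        idx_all = np.arange(J)
        for i in range(n_rand):
            drop = rng.choice(idx_all, size=len(outliers), replace=False)
            keep = np.setdiff1d(idx_all, drop)
            est, _, _, _ = _ivw_core(h.bx[keep], h.by[keep], h.sy[keep])
            diffs[i] = abs(raw.estimate - est)
        distortion_p = float((1 + (diffs >= obs_diff).sum()) / (n_rand + 1))
    elif outliers:
        raise AnalysisError("outlier removal would leave fewer than 2 instruments")

    return PressoResult(rss_obs, global_p, outlier_p, outliers, distortion_p,
                        raw, corrected)


def remove_outliers_and_rerun(h: HarmonizedSet, presso: PressoResult,
                              egger_intercept_p: float) -> OutlierRerunResult:
    """Egger-gated outlier removal with IVW and leave-one-out reruns.

    A no-op (returns the input set and its fits) unless the MR-Egger intercept
    test gives evidence of horizontal pleiotropy (p < 0.05); when triggered,
    the PRESSO outliers are removed, IVW and leave-one-out are rerun on the
    pruned set, and the removed variants are recorded.
    """
    triggered = egger_intercept_p < 0.05
    if not triggered or not presso.outliers:
        fit = ivw(h)
        loo, flag = leave_one_out(h) if h.n_snps >= 3 else ([], False)
        return OutlierRerunResult(triggered, h, fit, loo, flag, removed=[])
    pruned = h.without(presso.outliers)
    if pruned.n_snps < 2:
        raise AnalysisError("outlier removal would leave fewer than 2 instruments")
    fit = ivw(pruned)
    loo, flag = leave_one_out(pruned) if pruned.n_snps >= 3 else ([], False)
    return OutlierRerunResult(True, pruned, fit, loo, flag,
                              removed=list(presso.outliers))
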