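"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator emulates the statistical shape of consortium summary data used
in diet–migraine MR: per-variant effect estimates normally distributed around
true effects, standard errors from the usual 1/sqrt(2·n·maf·(1-maf))
approximation, binary-trait effects directly on the log-odds scale, optional
LD-blocked variant panels, configurable horizontal pleiotropy, and an
exposure → mediator → outcome causal chain whose ground truth (:class:`SimTruth`)
every recovery test can check against.

True variant–exposure effects are drawn half-normal (effect alleles oriented
exposure-increasing, as GWAS instrument lists conventionally are); this is
what makes *directional* pleiotropy actually directional for the ratio
estimators.  The three studies use independent noise draws (the two-sample
assumption); sample overlap is not simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .instruments import LDPanel
from .summary_data import SummaryStats

__all__ = ["SimConfig", "SimTruth", "simulate_two_sample",
           "simulate_mediation_triplet", "simulate_ld_panel"]

# non-palindromic allele pairs only, so harmonization never drops variants
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Generating parameters of one synthetic dataset.

    ``theta`` is the direct exposure→outcome effect on the log-odds scale;
    ``a`` and ``b`` the exposure→mediator and mediator→outcome effects, so the
    total effect is ``a·b + theta``.  ``gamma_sd`` scales the true per-variant
    exposure effects (half-normal), giving expected instrument strength
    F ≈ 2·n_exp·maf·(1-maf)·gamma_sd² (≈ 100 at the defaults).
    ``mediator_gamma_sd`` scales mediator-specific polygenic effects, which is
    what identifies the mediator's direct effect in MVMR.  A fraction
    ``pleiotropy_frac`` of variants get a direct outcome effect drawn
    N(pleiotropy_mean, pleiotropy_sd²): mean 0 is balanced pleiotropy,
    nonzero mean directional.
    """

    J: int = 100
    n_exp: int = 100_000
    n_out: int = 100_000
    n_med: int = 100_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    theta: float = 0.0
    a: float = 0.0
    b: float = 0.0
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    gamma_sd: float = 0.05
    mediator_gamma_sd: float = 0.02
    ld_blocks: list[tuple[int, float]] | None = None
    seed: int = 0
    exposure_name: str = "exposure"
    mediator_name: str = "mediator"
    outcome_name: str = "outcome"

    def __post_init__(self):
        if self.J < 1:
            raise ConfigError("J must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.pleiotropy_frac <= 1:
            raise ConfigError("pleiotropy_frac must be in [0, 1]")
        if min(self.n_exp, self.n_out, self.n_med) < 2:
            raise ConfigError("sample sizes must be >= 2")
        if self.ld_blocks is not None and sum(s for s, _ in self.ld_blocks) != self.J:
            raise ConfigError("ld_blocks sizes must sum to J")


@dataclass
class SimTruth:
    """Ground truth behind one synthetic dataset, for recovery tests."""

    gamma: np.ndarray            # true variant -> exposure effects
    alpha: np.ndarray            # direct (pleiotropic) variant -> outcome effects
    theta: float                 # direct exposure -> outcome effect
    a: float                     # exposure -> mediator
    b: float                     # mediator -> outcome
    theta_total: float           # a*b + theta
    proportion_true: float       # a*b / theta_total (nan when total is 0)
    delta: np.ndarray = field(default_factory=lambda: np.empty(0))
    # mediator-specific polygenic effects (empty for two-sample draws)

    def to_json(self, path) -> None:
        d = asdict(self)
        for k in ("gamma", "alpha", "delta"):
            d[k] = np.asarray(d[k]).tolist()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def _variant_frame(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Variant ids, positions and alleles; LD blocks sit within one clumping
    window, distinct blocks (or singleton variants) far apart."""
    J = cfg.J
    sizes = [s for s, _ in cfg.ld_blocks] if cfg.ld_blocks else [1] * J
    chrom, pos = [], []
    block_starts = {}
    for b_idx, size in enumerate(sizes):
        c = (b_idx % 22) + 1
        base = block_starts.get(c, 1_000_000)
        for k in range(size):
            chrom.append(str(c))
            pos.append(base + 10_000 * k)
        block_starts[c] = base + 10_000_000  # next block on this chrom: far away
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), J)]
    return pd.DataFrame({
        "variant_id": [f"rs{i:07d}" for i in range(1, J + 1)],
        "chrom": chrom, "pos": pos,
        "effect_allele": [p[0] for p in pairs],
        "other_allele": [p[1] for p in pairs],
    })


def _norm_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy.stats import norm
    return 2 * norm.sf(np.abs(beta / se))


def _study(frame: pd.DataFrame, maf: np.ndarray, true_beta: np.ndarray,
           n: int, name: str, trait_type: str,
           rng: np.random.Generator) -> SummaryStats:
    se = 1.0 / np.sqrt(2 * n * maf * (1 - maf))
    beta = rng.normal(true_beta, se)
    tbl = frame.copy()
    tbl["eaf"] = maf
    tbl["beta"] = beta
    tbl["se"] = se
    tbl["pval"] = _norm_p(beta, se)
    tbl["n"] = n
    return SummaryStats(name, trait_type, tbl)


def _draw_effects(cfg: SimConfig, rng: np.random.Generator):
    maf = rng.uniform(*cfg.maf_range, size=cfg.J)
    gamma = np.abs(rng.normal(0.0, cfg.gamma_sd, size=cfg.J))
    alpha = np.zeros(cfg.J)
    n_pleio = int(round(cfg.pleiotropy_frac * cfg.J))
    if n_pleio:
        idx = rng.choice(cfg.J, size=n_pleio, replace=False)
        alpha[idx] = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, n_pleio)
    return maf, gamma, alpha


def simulate_two_sample(cfg: SimConfig) -> tuple[SummaryStats, SummaryStats, SimTruth]:
    """Exposure and outcome summary statistics from non-overlapping samples.

    The outcome's true per-variant effect is theta_total·gamma_j + alpha_j
    with theta_total = a·b + theta (a = b = 0 unless a mediated path is being
    emulated without its mediator study).  Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    frame = _variant_frame(cfg, rng)
    maf, gamma, alpha = _draw_effects(cfg, rng)
    theta_total = cfg.a * cfg.b + cfg.theta
    exposure = _study(frame, maf, gamma, cfg.n_exp, cfg.exposure_name,
                      "continuous", rng)
    outcome = _study(frame, maf, theta_total * gamma + alpha, cfg.n_out,
                     cfg.outcome_name, "binary", rng)
    prop = cfg.a * cfg.b / theta_total if theta_total != 0 else float("nan")
    return exposure, outcome, SimTruth(gamma, alpha, cfg.theta, cfg.a, cfg.b,
                                       theta_total, prop)


def simulate_mediation_triplet(cfg: SimConfig,
                               ) -> tuple[SummaryStats, SummaryStats,
                                          SummaryStats, SimTruth]:
    """Exposure, mediator and outcome studies along an X→M→Y chain.

    Mediator true effects are a·gamma_j + delta_j, where delta_j ~
    N(0, mediator_gamma_sd²) are the mediator's own polygenic effects; outcome
    true effects are theta·gamma_j + b·(a·gamma_j + delta_j) + alpha_j.  The
    three studies draw independent estimation noise.
    """
    rng = np.random.default_rng(cfg.seed)
    frame = _variant_frame(cfg, rng)
    maf, gamma, alpha = _draw_effects(cfg, rng)
    delta = rng.normal(0.0, cfg.mediator_gamma_sd, size=cfg.J)
    mu = cfg.a * gamma + delta
    theta_total = cfg.a * cfg.b + cfg.theta
    true_out = cfg.theta * gamma + cfg.b * mu + alpha

    exposure = _study(frame, maf, gamma, cfg.n_exp, cfg.exposure_name,
                      "continuous", rng)
    mediator = _study(frame, maf, mu, cfg.n_med, cfg.mediator_name,
                      "binary", rng)
    outcome = _study(frame, maf, true_out, cfg.n_out, cfg.outcome_name,
                     "binary", rng)
    prop = cfg.a * cfg.b / theta_total if theta_total != 0 else float("nan")
    return exposure, mediator, outcome, SimTruth(gamma, alpha, cfg.theta,
                                                 cfg.a, cfg.b, theta_total,
                                                 prop, delta=delta)


def simulate_ld_panel(cfg: SimConfig) -> LDPanel:
    """Block-diagonal r² panel with AR(1) decay rho^|i-j| within blocks.

    ``cfg.ld_blocks`` must partition the J variants; ``None`` means no LD
    (identity matrix).  Variant ids match the summary-statistics generators
    run with the same config.
    """
    J = cfg.J
    blocks = cfg.ld_blocks or [(1, 0.0)] * J
    if sum(s for s, _ in blocks) != J:
        raise ConfigError("ld_blocks sizes must sum to J")
    r2 = np.zeros((J, J))
    start = 0
    for size, rho in blocks:
        idx = np.arange(start, start + size)
        lag = np.abs(idx[:, None] - idx[None, :])
        r2[np.ix_(idx, idx)] = np.float_power(rho, lag) ** 2
        start += size
    np.fill_diagonal(r2, 1.0)
    ids = [f"rs{i:07d}" for i in range(1, J + 1)]
    return LDPanel(ids, r2)
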