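"""Three-step network-MR mediation analysis with Delta-method intervals.

For an exposure X, candidate mediator M and outcome Y, three MR fits are run:

1. total effect TE of X on Y (IVW over X's instruments);
2. effect ``a`` of X on M (IVW over X's instruments);
3. effect ``b`` of M on Y adjusted for X, the mediator coefficient from
   multivariable MR over the re-pruned union of both traits' instruments.

M is declared a mediator only when all three steps show an association
(nominal p < 0.05 by default).  The natural indirect effect is the product
NIE = a·b, with first-order Delta SE assuming independent samples,

    se(NIE) = sqrt(a²·se_b² + b²·se_a²),

and the proportion mediated is NIE/TE on the log-odds scale with the
ratio-Delta variance

    var(prop) = se_NIE²/TE² + NIE²·se_TE²/TE⁴.

All products and ratios are taken on the log scale; odds-ratio columns are
exponentials for reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import Z95, MREstimate, ivw, mvmr
from .instruments import LDPanel, ld_clump, select_by_pvalue
from .summary_data import AnalysisError, SummaryStats, harmonize

__all__ = ["MediationResult", "step_effects", "indirect_effect",
           "proportion_mediated", "proportion_from_odds_ratios",
           "align_three", "run_mediation"]


@dataclass
class MediationResult:
    """Total, indirect and proportion-mediated estimates for one X→M→Y triplet.

    All effects are on the log scale; ``nie_or`` and its CI are odds-ratio
    views.  ``proportion`` is a fraction (0.134 for "13.4%") with a Delta CI.
    When the three-step gate fails, the product-path fields are None and
    ``gate_reason`` says which step failed.
    """

    exposure: str
    mediator: str
    outcome: str
    te: float
    se_te: float
    a: float
    se_a: float
    b: float
    se_b: float
    gated: bool = True
    gate_reason: str = ""
    nie: float | None = None
    se_nie: float | None = None
    nie_or: float | None = None
    nie_or_low: float | None = None
    nie_or_high: float | None = None
    proportion: float | None = None
    proportion_low: float | None = None
    proportion_high: float | None = None

    def to_row(self) -> dict:
        """One Table-style row: TE, NIE (95% CI), Proportion (95% CI)."""
        row = {"Exposure": self.exposure, "Mediator": self.mediator,
               "Outcome": self.outcome, "TE": np.exp(self.te),
               "gated": self.gated, "gate_reason": self.gate_reason}
        if self.gated and self.nie is not None:
            row["NIE (95% CI)"] = (f"{self.nie_or:.3f} "
                                   f"({self.nie_or_low:.3f}, {self.nie_or_high:.3f})")
            row["Proportion (95% CI)"] = (
                f"{100 * self.proportion:.2f}% "
                f"({100 * self.proportion_low:.2f}%, {100 * self.proportion_high:.2f}%)")
        else:
            row["NIE (95% CI)"] = row["Proportion (95% CI)"] = ""
        return row


def step_effects(te_fit: MREstimate, a_fit: MREstimate, b_fit: MREstimate,
                 exposure: str = "exposure", mediator: str = "mediator",
                 outcome: str = "outcome", alpha: float = 0.05) -> MediationResult:
    """Collect the three step estimates and apply the mediation gate.

    All three fits must be supplied on the log scale; mediation proceeds only
    when each is nominally significant at ``alpha``.
    """
    fits = {"total effect": te_fit, "exposure->mediator": a_fit,
            "mediator->outcome (MVMR)": b_fit}
    for label, fit in fits.items():
        if fit is None:
            raise AnalysisError(f"missing {label} fit")
        if fit.scale != "log":
            raise AnalysisError(
                f"{label} fit must be on the log scale, got {fit.scale!r}")
    failed = [label for label, fit in fits.items() if fit.pval >= alpha]
    return MediationResult(
        exposure, mediator, outcome,
        te=te_fit.estimate, se_te=te_fit.se,
        a=a_fit.estimate, se_a=a_fit.se,
        b=b_fit.estimate, se_b=b_fit.se,
        gated=not failed,
        gate_reason="" if not failed else "not significant: " + "; ".join(failed),
    )


def indirect_effect(a: float, se_a: float, b: float, se_b: float,
                    ) -> tuple[float, float]:
    """Product-method indirect effect a·b with first-order Delta SE."""
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    nie = a * b
    se_nie = float(np.sqrt(a**2 * se_b**2 + b**2 * se_a**2))
    return nie, se_nie


def proportion_mediated(te: float, se_te: float, nie: float, se_nie: float,
                        ) -> tuple[float, float, float]:
    """Proportion mediated NIE/TE (log scale) with a ratio-Delta 95% CI.

    Returns (proportion, ci_low, ci_high) as fractions; multiply by 100 for
    percentage reporting.
    """
    if te == 0:
        raise AnalysisError("undefined proportion: total effect is zero")
    prop = nie / te
    var = se_nie**2 / te**2 + nie**2 * se_te**2 / te**4
    half = Z95 * float(np.sqrt(var))
    return prop, prop - half, prop + half


def proportion_from_odds_ratios(te_or: float, nie_or: float) -> float:
    """Percentage mediated recomputed from odds-ratio-scale TE and NIE.

    The published mediation tables print TE and NIE as odds ratios; the
    proportion they report is the ratio of the log odds ratios,
    100·ln(NIE)/ln(TE).
    """
    if te_or <= 0 or nie_or <= 0:
        raise ValueError("odds ratios must be positive")
    if te_or == 1.0:
        raise AnalysisError("undefined proportion: total effect OR is 1")
    return float(100.0 * np.log(nie_or) / np.log(te_or))


def _union_stats(exposure_sel: SummaryStats, mediator_sel: SummaryStats) -> SummaryStats:
    """Union of two instrument tables for re-pruning; shared ids keep min p."""
    a = exposure_sel.table
    b = mediator_sel.table
    merged = pd.concat([a, b], ignore_index=True)
    merged = (merged.sort_values(["variant_id", "pval"], kind="mergesort")
              .drop_duplicates("variant_id", keep="first")
              .sort_values(["chrom", "pos"], kind="mergesort")
              .reset_index(drop=True))
    return SummaryStats("union", "continuous", merged)


def align_three(exposure: SummaryStats, mediator: SummaryStats,
                outcome: SummaryStats, variant_ids: list[str],
                palindromic_eaf_window: float = 0.08) -> pd.DataFrame:
    """Aligned MVMR table (variant, bx1, bx2, by, sy) over given variants.

    Mediator and outcome betas are both harmonized to the exposure's effect
    alleles; variants unresolvable in either pairing are dropped.
    """
    sub = exposure.subset(variant_ids)
    h_em = harmonize(sub, mediator, palindromic_eaf_window)
    h_eo = harmonize(sub, outcome, palindromic_eaf_window)
    em = h_em.to_frame().rename(columns={"bx": "bx1", "by": "bx2", "sy": "s_med"})
    eo = h_eo.to_frame()[["variant_id", "by", "sy"]]
    tbl = em.merge(eo, on="variant_id")
    return tbl[["variant_id", "bx1", "bx2", "by", "sy"]]


def run_mediation(exposure: SummaryStats, mediator: SummaryStats,
                  outcome: SummaryStats, panel: LDPanel,
                  p_threshold: float = 5e-6, window_bp: int = 1_000_000,
                  r2_max: float = 0.001, alpha: float = 0.05,
                  palindromic_eaf_window: float = 0.08) -> MediationResult:
    """Full three-step mediation analysis for one exposure–mediator–outcome triplet.

    Steps 1 and 2 use the exposure's clumped instruments; step 3 fits MVMR on
    the re-pruned union of exposure and mediator instruments.  The gate and
    the Delta-method NIE / proportion-mediated quantities follow the module
    docstring.
    """
    if mediator.trait_name == outcome.trait_name:
        raise AnalysisError("mediator and outcome must differ")
    if exposure.trait_name == mediator.trait_name:
        raise AnalysisError("exposure and mediator must differ")

    exp_sel = select_by_pvalue(exposure, p_threshold)
    if len(exp_sel) == 0:
        raise AnalysisError(f"no instruments for {exposure.trait_name}")
    exp_inst = ld_clump(exp_sel, panel, window_bp, r2_max, p_threshold)
    exp_stats = exposure.subset(exp_inst.variant_ids)

    te_fit = ivw(harmonize(exp_stats, outcome, palindromic_eaf_window))
    a_fit = ivw(harmonize(exp_stats, mediator, palindromic_eaf_window))

    med_sel = select_by_pvalue(mediator, p_threshold)
    if len(med_sel) == 0:
        raise AnalysisError(f"no instruments for {mediator.trait_name}")
    union = _union_stats(exp_sel.subset(exp_inst.variant_ids), med_sel)
    union_inst = ld_clump(union, panel, window_bp, r2_max, p_threshold)
    tbl = align_three(exposure, mediator, outcome, union_inst.variant_ids,
                      palindromic_eaf_window)
    fits = mvmr(tbl["bx1"].to_numpy(), tbl["bx2"].to_numpy(),
                tbl["by"].to_numpy(), tbl["sy"].to_numpy(),
                names=(exposure.trait_name, mediator.trait_name))
    b_fit = fits[mediator.trait_name]

    res = step_effects(te_fit, a_fit, b_fit, exposure.trait_name,
                       mediator.trait_name, outcome.trait_name, alpha)
    if res.gated:
        nie, se_nie = indirect_effect(res.a, res.se_a, res.b, res.se_b)
        prop, lo, hi = proportion_mediated(res.te, res.se_te, nie, se_nie)
        res.nie, res.se_nie = nie, se_nie
        res.nie_or = float(np.exp(nie))
        res.nie_or_low = float(np.exp(nie - Z95 * se_nie))
        res.nie_or_high = float(np.exp(nie + Z95 * se_nie))
        res.proportion, res.proportion_low, res.proportion_high = prop, lo, hi
    return res
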