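"""Orchestration of the full study design over many exposure–outcome pairs.

``run_forward`` applies the whole battery to each exposure–outcome pair:
instrument selection → harmonization → IVW plus every sensitivity estimator →
Egger-intercept-gated outlier removal and rerun → evidence grading.
``run_mediation_stage`` then runs the three-step mediation analysis for the
exposures that passed their subtype's Bonferroni threshold, and
``run_bidirectional`` repeats the battery with exposure and outcome roles
swapped.

Failures are per-analysis: one bad trait yields a status row, never a crashed
run.  All randomness flows from one root seed through ``numpy``'s
``SeedSequence`` spawning, so a rerun with the same plan is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import diagnostics, estimators, evidence
from .instruments import LDPanel, f_statistics, ld_clump, select_by_pvalue
from .mediation import run_mediation
from .summary_data import SummaryStats, harmonize

__all__ = ["AnalysisPlan", "run_forward", "run_mediation_stage",
           "run_bidirectional"]

log = logging.getLogger("mrpath")


@dataclass
class AnalysisPlan:
    """What to analyse and with which settings.

    ``exposures`` maps subtype label -> list of exposure SummaryStats (the
    subtype sizes are the Bonferroni denominators); ``outcomes`` and
    ``mediators`` are flat lists.
    """

    exposures: dict[str, list[SummaryStats]]
    outcomes: list[SummaryStats]
    mediators: list[SummaryStats] = field(default_factory=list)
    panel: LDPanel | None = None
    p_threshold: float = 5e-6
    reverse_p_threshold: float = 5e-8
    window_bp: int = 1_000_000
    r2_max: float = 0.001
    palindromic_eaf_window: float = 0.08
    n_boot: int = 1000
    presso_sims: int = 1000
    min_snps_presso: int = 4
    seed: int = 0
    mediation_gate: str = "bonferroni"   # or "nominal"

    @classmethod
    def settings_from_yaml(cls, path) -> dict:
        """Scalar settings (thresholds, seed...) read from a YAML mapping."""
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        allowed = {"p_threshold", "reverse_p_threshold", "window_bp", "r2_max",
                   "palindromic_eaf_window", "n_boot", "presso_sims",
                   "min_snps_presso", "seed", "mediation_gate"}
        unknown = set(cfg) - allowed
        if unknown:
            raise ValueError(f"unknown plan settings: {sorted(unknown)}")
        return cfg


def _spawn_seeds(root: int, n: int) -> list[int]:
    """Stable per-analysis integer seeds (below 2**31) from one root seed."""
    ss = np.random.SeedSequence(root)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _single_pair(exposure: SummaryStats, outcome: SummaryStats,
                 plan: AnalysisPlan, seed: int, p_threshold: float) -> dict:
    """Full estimator battery + grading for one pair; returns one result row."""
    row: dict = {"exposure": exposure.trait_name, "outcome": outcome.trait_name,
                 "seed": seed, "status": "ok"}
    sel = select_by_pvalue(exposure, p_threshold)
    if len(sel) == 0:
        row["status"] = "no_instruments"
        return row
    inst = ld_clump(sel, plan.panel, plan.window_bp, plan.r2_max, p_threshold)
    h = harmonize(exposure.subset(inst.variant_ids), outcome,
                  plan.palindromic_eaf_window)
    if h.n_snps < 3:
        row["status"] = "too_few_snps"
        row["n_snps"] = h.n_snps
        return row
    _, mean_F, weak = f_statistics(h)
    row["n_snps"], row["mean_F"], row["weak_instruments"] = h.n_snps, mean_F, weak

    fit_ivw = estimators.ivw(h)
    fit_egger = estimators.egger(h)
    fit_wm = estimators.weighted_median(h, plan.n_boot, seed)
    fit_mode = estimators.mode_based(h, 1.0, plan.n_boot, seed + 1)
    sens = [fit_egger, fit_wm, fit_mode]

    presso = None
    if h.n_snps >= plan.min_snps_presso:
        presso = diagnostics.mr_presso(h, plan.presso_sims, seed + 2)
        row["presso_global_p"] = presso.global_p
        row["presso_outliers"] = ",".join(presso.outliers)
    _, loo_flag = diagnostics.leave_one_out(h)

    post_ivw = fit_ivw
    removed: list[str] = []
    if presso is not None:
        rerun = diagnostics.remove_outliers_and_rerun(
            h, presso, fit_egger.egger_intercept_p)
        post_ivw, removed = rerun.ivw, rerun.removed
        if rerun.triggered and removed:
            loo_flag = rerun.loo_flag

    for fit in [fit_ivw] + sens:
        key = fit.method.lower()
        row[f"{key}_beta"] = fit.estimate
        row[f"{key}_se"] = fit.se
        row[f"{key}_p"] = fit.pval
    orv = fit_ivw.odds_ratio()
    row.update(ivw_or=orv.or_, ivw_or_low=orv.or_low, ivw_or_high=orv.or_high,
               Q=fit_ivw.Q, I2=fit_ivw.I2,
               egger_intercept=fit_egger.egger_intercept,
               egger_intercept_p=fit_egger.egger_intercept_p,
               outliers_removed=",".join(removed), loo_flag=loo_flag,
               post_removal_ivw_beta=post_ivw.estimate,
               post_removal_ivw_p=post_ivw.pval)
    row["_graded"] = (fit_ivw, sens, post_ivw, loo_flag)
    return row


def _battery(pairs, plan: AnalysisPlan, p_threshold: float) -> pd.DataFrame:
    """Run the estimator battery + grading over (exposure, subtype, outcome)."""
    pairs = list(pairs)
    seeds = _spawn_seeds(plan.seed, len(pairs))
    rows = []
    for (exposure, subtype, outcome), seed in zip(pairs, seeds):
        alpha = evidence.bonferroni_threshold(
            sum(1 for e, s, o in pairs
                if s == subtype and o.trait_name == outcome.trait_name))
        try:
            row = _single_pair(exposure, outcome, plan, seed, p_threshold)
        except Exception as err:  # per-analysis failure, keep going
            log.warning("pair %s -> %s failed: %s",
                        exposure.trait_name, outcome.trait_name, err)
            row = {"exposure": exposure.trait_name,
                   "outcome": outcome.trait_name, "seed": seed,
                   "status": f"error: {err}"}
        row["subtype"] = subtype
        row["alpha_bonf"] = alpha
        graded = row.pop("_graded", None)
        if graded is not None:
            fit_ivw, sens, post_ivw, loo_flag = graded
            g = evidence.grade(f"{exposure.trait_name}->{outcome.trait_name}",
                               fit_ivw, alpha, sens, loo_flag,
                               post_removal_ivw=post_ivw)
            row.update(criterion1=g.criterion1, criterion2=g.criterion2,
                       criterion3=g.criterion3, grade=g.grade)
        rows.append(row)
    return pd.DataFrame(rows)


def run_forward(plan: AnalysisPlan) -> pd.DataFrame:
    """Forward MR of every exposure on every outcome, with grading."""
    pairs = [(e, subtype, o)
             for subtype, exps in plan.exposures.items() for e in exps
             for o in plan.outcomes]
    log.info("forward MR: %d pairs, root seed %d", len(pairs), plan.seed)
    return _battery(pairs, plan, plan.p_threshold)


def run_mediation_stage(plan: AnalysisPlan,
                        forward: pd.DataFrame) -> pd.DataFrame:
    """Three-step mediation for forward hits, one row per X–M–Y triplet.

    A forward pair qualifies when its IVW p passes the subtype Bonferroni
    threshold (or nominal 0.05 with ``plan.mediation_gate == "nominal"``).
    """
    by_name = {s.trait_name: s
               for exps in plan.exposures.values() for s in exps}
    out_by_name = {o.trait_name: o for o in plan.outcomes}
    rows = []
    ok = forward[forward["status"] == "ok"] if len(forward) else forward
    for _, frow in ok.iterrows():
        thr = frow["alpha_bonf"] if plan.mediation_gate == "bonferroni" else 0.05
        if frow["ivw_p"] >= thr:
            continue
        exposure = by_name[frow["exposure"]]
        outcome = out_by_name[frow["outcome"]]
        for mediator in plan.mediators:
            try:
                res = run_mediation(exposure, mediator, outcome, plan.panel,
                                    plan.p_threshold, plan.window_bp,
                                    plan.r2_max, 0.05,
                                    plan.palindromic_eaf_window)
                rows.append(res.to_row())
            except Exception as err:
                log.warning("mediation %s/%s/%s failed: %s", frow["exposure"],
                            mediator.trait_name, frow["outcome"], err)
                rows.append({"Exposure": frow["exposure"],
                             "Mediator": mediator.trait_name,
                             "Outcome": frow["outcome"], "gated": False,
                             "gate_reason": f"error: {err}"})
    return pd.DataFrame(rows)


def run_bidirectional(plan: AnalysisPlan) -> pd.DataFrame:
    """Reverse-direction MR: each outcome as exposure of each exposure trait.

    Reverse instruments are selected at ``plan.reverse_p_threshold``
    (genome-wide significance by default, as outcome GWAS are typically
    well-powered).
    """
    pairs = [(o, "reverse", e)
             for o in plan.outcomes
             for exps in plan.exposures.values() for e in exps]
    log.info("bidirectional MR: %d pairs", len(pairs))
    return _battery(pairs, plan, plan.reverse_p_threshold)
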