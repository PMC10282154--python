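"""The synthetic study scenario shared by the numbered analysis scripts.

Six dietary-habit exposures in three subtypes (breads, drinks, cereals), one
binary outcome (migraine) and one binary mediator (insomnia).  Each exposure
gets its own variant panel (ids prefixed per exposure) so the combined
outcome and mediator studies behave like large GWAS covering every
instrument.  Ground truth per exposure: direct effect ``theta`` on migraine,
effect ``a`` on insomnia, and the shared insomnia→migraine effect ``b``, so
the total effect is ``theta + a·b``.

Everything is deterministic in the root seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from mrpath.instruments import LDPanel
from mrpath.pipeline import AnalysisPlan
from mrpath.summary_data import SummaryStats
from mrpath.synthetic import (SimConfig, simulate_ld_panel,
                              simulate_mediation_triplet, simulate_two_sample)

J_PER_EXPOSURE = 60
B_INSOMNIA = 0.5    # insomnia -> migraine log-odds

#: name -> (subtype, direct theta, exposure->insomnia a)
EXPOSURES: dict[str, tuple[str, float, float]] = {
    "white_bread": ("breads", 0.15, 0.40),
    "wholegrain_bread": ("breads", -0.15, -0.25),
    "red_wine": ("drinks", -0.30, -0.30),
    "coffee": ("drinks", -0.30, 0.00),
    "muesli": ("cereals", 0.00, 0.00),
    "cornflakes": ("cereals", 0.35, 0.00),
}

# two moderate-LD blocks per exposure panel to exercise clumping
LD_BLOCKS = [(5, 0.9), (5, 0.8)] + [(1, 0.0)] * (J_PER_EXPOSURE - 10)


def _rename(table: pd.DataFrame, prefix: str) -> pd.DataFrame:
    out = table.copy()
    out["variant_id"] = prefix + "_" + out["variant_id"]
    return out


def build_scenario(seed: int):
    """Returns (plan, truth) — an AnalysisPlan over the synthetic cohorts and
    a per-exposure ground-truth table."""
    exposures: dict[str, list[SummaryStats]] = {}
    med_parts, out_parts, panel_ids, panel_blocks, truth_rows = [], [], [], [], []
    for i, (name, (subtype, theta, a)) in enumerate(EXPOSURES.items()):
        cfg = SimConfig(J=J_PER_EXPOSURE, theta=theta, a=a, b=B_INSOMNIA,
                        ld_blocks=LD_BLOCKS, seed=seed * 1000 + i,
                        exposure_name=name, mediator_name="insomnia",
                        outcome_name="migraine")
        exp, med, out, tr = simulate_mediation_triplet(cfg)
        exp_tbl = _rename(exp.table, name)
        exposures.setdefault(subtype, []).append(
            SummaryStats(name, "continuous", exp_tbl))
        med_parts.append(_rename(med.table, name))
        out_parts.append(_rename(out.table, name))
        sub_panel = simulate_ld_panel(cfg)
        panel_ids += [f"{name}_{v}" for v in sub_panel.variant_ids]
        panel_blocks.append(sub_panel.r2)
        truth_rows.append({"exposure": name, "subtype": subtype,
                           "theta_direct": theta, "a": a, "b": B_INSOMNIA,
                           "theta_total": tr.theta_total,
                           "proportion_true": tr.proportion_true})

    # migraine's own susceptibility loci: affect migraine only, so they are
    # the clean instruments for the reverse (migraine -> diet) analyses
    own_cfg = SimConfig(J=J_PER_EXPOSURE, theta=0.0, seed=seed * 1000 + 99,
                        exposure_name="migraine")
    mig_own, _, _ = simulate_two_sample(own_cfg)
    own_tbl = _rename(mig_own.table, "migloc")
    out_parts.append(own_tbl)
    rng = np.random.default_rng(seed * 1000 + 999)
    null_template = own_tbl.copy()
    for k, name in enumerate(list(EXPOSURES) + ["insomnia"]):
        null = null_template.copy()
        null["beta"] = rng.normal(0.0, null["se"])
        null["pval"] = 2 * norm.sf(np.abs(null["beta"] / null["se"]))
        if name == "insomnia":
            med_parts.append(null)
        else:
            st = exposures[EXPOSURES[name][0]]
            idx = [i for i, s in enumerate(st) if s.trait_name == name][0]
            st[idx] = SummaryStats(name, "continuous",
                                   pd.concat([st[idx].table, null],
                                             ignore_index=True))
    panel_ids += [f"migloc_{v}" for v in mig_own.table["variant_id"]]
    panel_blocks.append(np.eye(J_PER_EXPOSURE))

    mediator = SummaryStats("insomnia", "binary",
                            pd.concat(med_parts, ignore_index=True))
    outcome = SummaryStats("migraine", "binary",
                           pd.concat(out_parts, ignore_index=True))
    n = len(panel_ids)
    r2 = np.zeros((n, n))
    start = 0
    for block in panel_blocks:
        k = block.shape[0]
        r2[start:start + k, start:start + k] = block
        start += k
    panel = LDPanel(panel_ids, r2)

    plan = AnalysisPlan(exposures=exposures, outcomes=[outcome],
                        mediators=[mediator], panel=panel, seed=seed)
    return plan, pd.DataFrame(truth_rows)
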