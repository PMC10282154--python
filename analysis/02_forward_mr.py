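"""Forward MR of every dietary habit on migraine, with evidence grading.

Runs the full battery per exposure — p < 5e-6 instrument selection, 1 Mb /
r² 0.001 clumping, harmonization, IVW + Egger + weighted median + mode,
MR-PRESSO, Egger-gated outlier removal, leave-one-out — then grades each
result against its subtype's Bonferroni threshold.  Writes
results/forward_mr.tsv and prints the graded table; IVW odds ratios should
track exp(theta_total) from results/data/truth.tsv.
"""

import argparse
import logging
from pathlib import Path

import sys
sys.path.insert(0, str(Path(__file__).parent))
from scenario import build_scenario

from mrpath.pipeline import run_forward


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path,
                    default=Path(__file__).parents[1] / "results")
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO)
    args.outdir.mkdir(parents=True, exist_ok=True)

    plan, truth = build_scenario(args.seed)
    fw = run_forward(plan)
    fw.to_csv(args.outdir / "forward_mr.tsv", sep="\t", index=False)

    view = fw.merge(truth[["exposure", "theta_total"]], on="exposure")
    cols = ["exposure", "subtype", "n_snps", "mean_F", "ivw_or", "ivw_or_low",
            "ivw_or_high", "ivw_p", "alpha_bonf", "I2", "egger_intercept_p",
            "grade", "theta_total"]
    print(view[cols].round(4).to_string(index=False))
    hits = view[view["ivw_p"] < view["alpha_bonf"]]["exposure"].tolist()
    print(f"\n{len(hits)} exposures pass their subtype Bonferroni threshold: "
          f"{', '.join(hits)}")


if __name__ == "__main__":
    main()
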