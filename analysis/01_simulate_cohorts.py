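"""Generate the synthetic GWAS cohorts and write them as summary-stats TSVs.

Six dietary exposures (three subtypes), an insomnia mediator and a migraine
outcome, each with known ground truth; the per-exposure truth table goes to
results/data/truth.tsv.  Later scripts re-derive the same cohorts from the
seed, so these files are for inspection and for demonstrating the I/O round
trip.
"""

import argparse
from pathlib import Path

import sys
sys.path.insert(0, str(Path(__file__).parent))
from scenario import build_scenario


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path,
                    default=Path(__file__).parents[1] / "results" / "data")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    plan, truth = build_scenario(args.seed)
    for subtype, studies in plan.exposures.items():
        for s in studies:
            s.to_tsv(args.outdir / f"{s.trait_name}.tsv")
    plan.mediators[0].to_tsv(args.outdir / "insomnia.tsv")
    plan.outcomes[0].to_tsv(args.outdir / "migraine.tsv")
    truth.to_csv(args.outdir / "truth.tsv", sep="\t", index=False)

    n_variants = sum(len(s) for ss in plan.exposures.values() for s in ss)
    print(f"wrote {len(truth)} exposure cohorts ({n_variants} variants total), "
          f"insomnia mediator and migraine outcome to {args.outdir}")
    print("\nground truth (log-odds):")
    print(truth.to_string(index=False))


if __name__ == "__main__":
    main()
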