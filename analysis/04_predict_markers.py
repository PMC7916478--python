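#!/usr/bin/env python
"""Molecular-marker prediction: correlation elimination by univariate AUC,
stratified 70/30 split, cumulative random-forest importance (top-20),
randomized model search over three learner families, repeated-split
re-evaluation of the top five, and a probability-averaging ensemble of the
VASARI and radiomics arms, validated externally with bootstrap AUC CIs.

Thin driver over glioscan.pipeline.
"""

import argparse
import json

from glioscan.pipeline import load_config, run


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results/study")
    ap.add_argument("--markers", nargs="*", default=["MGMT"])
    args = ap.parse_args()
    cfg = load_config(overrides={
        "seed": args.seed, "out_dir": args.out_dir,
        "predictive": {"markers": args.markers},
    })
    run(cfg, stages=["simulate", "extract", "predictive"])
    rep = json.load(open(f"{args.out_dir}/predictive_report.json"))
    for marker, arms in rep.items():
        print(f"{marker}: validation AUC (95% CI)")
        for arm, e in arms.items():
            if "validation_auc" not in e:
                continue
            lo, hi = e["validation_auc_ci95"]
            extra = f" [{e.get('winner_family', '')}]" if "winner_family" in e else ""
            print(f"  {arm:10s} {e['validation_auc']:.3f} ({lo:.3f}-{hi:.3f}){extra}")


if __name__ == "__main__":
    main()
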