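#!/usr/bin/env python
"""Parameter recovery with strong envelope-arousal coupling (kappa=0.8).

Checks that the pipeline finds what the generator planted: the SPoC-chosen
component's scalp pattern matches the planted mixing column, the
reconstructed target correlates negatively with the true ratings, and
both CSP cross-validation schemes decode well above chance.  Writes the
per-subject metrics to results/recovery.json.
"""

import argparse
import json
from pathlib import Path

from alphadec.studies import recovery_study


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n-subjects", type=int, default=20)
    parser.add_argument("--kappa", type=float, default=0.8)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/recovery.json"))
    args = parser.parse_args()

    rec = recovery_study(args.n_subjects, args.kappa, args.seed)
    out = {
        "n_subjects": rec["n_subjects"],
        "kappa": args.kappa,
        "pattern_similarity_median": rec["pattern_similarity_median"],
        "spoc_r_median": rec["spoc_r_median"],
        "csp_accuracy_median": rec["csp_accuracy_median"],
        "csp_auc_median": rec["csp_auc_median"],
        "pattern_similarities": rec["pattern_similarities"].tolist(),
        "spoc_rs": rec["spoc_rs"].tolist(),
        "csp_accuracies": rec["csp_accuracies"].tolist(),
        "csp_aucs": rec["csp_aucs"].tolist(),
    }
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(out, indent=2))
    print(f"recovery cohort n={rec['n_subjects']} (kappa={args.kappa}), medians:")
    print(f"  |pattern similarity|      {rec['pattern_similarity_median']:.3f}")
    print(f"  SPoC r(z, z_est)          {rec['spoc_r_median']:+.3f}")
    print(f"  CSP accuracy              {rec['csp_accuracy_median']:.3f}")
    print(f"  CSP sub-blocked ROC-AUC   {rec['csp_auc_median']:.3f}")
    print(f"-> {args.out}")


if __name__ == "__main__":
    main()
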