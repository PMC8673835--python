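#!/usr/bin/env python
"""Group-level model comparison on a simulated cohort.

Builds a subjects x {CSP, LSTM} x {coupled, weakly-coupled} accuracy table
(a synthetic analogue of a two-condition design), runs the 2x2
repeated-measures ANOVA and the Bonferroni-corrected cross-model
correlations.  The LSTM entries reuse the CSP fold structure.  Writes
results/group_stats.json.  Note: this driver trains LSTMs and is the
slowest of the analysis scripts (~1-2 min per subject-condition).
"""

import argparse
import json
from pathlib import Path

import numpy as np

from alphadec.csp import _stratified_folds, randomized_cv
from alphadec.evaluation import cross_model_correlation, group_mean_test, rm_anova_2x2
from alphadec.lstm import HPConfig, build_dataset, evaluate_cv
from alphadec.pipeline import _subject_seed
from alphadec.preprocess import EpochedData, tertile_labels
from alphadec.spoc import epoch_covariances
from alphadec.studies import subject_chain


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n-subjects", type=int, default=4)
    parser.add_argument("--kappas", type=float, nargs=2, default=(0.8, 0.5),
                        metavar=("COND_A", "COND_B"))
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/group_stats.json"))
    args = parser.parse_args()

    scores = np.full((args.n_subjects, 2, 2), np.nan)  # model x condition
    for sid in range(args.n_subjects):
        for ci, kappa in enumerate(args.kappas):
            chain = subject_chain(
                _subject_seed(args.seed, sid, 30 + ci), kappa=kappa,
                sensor_noise_sd=1.0,
            )
            if chain is None:
                continue
            labels = tertile_labels(chain["trace"])
            bin_tensor = chain["tensor"][labels.binary_mask]
            bin_labels = labels.binary_labels
            folds = _stratified_folds(
                bin_labels, 10, np.random.default_rng(_subject_seed(args.seed, sid, 40))
            )
            csp_acc = randomized_cv(
                epoch_covariances(bin_tensor), bin_labels,
                seed=_subject_seed(args.seed, sid, 40),
            ).mean_metric
            ds = build_dataset(EpochedData(tensor=chain["tensor"], fs=250.0), labels)
            lstm_acc, _ = evaluate_cv(
                ds, HPConfig(seed=_subject_seed(args.seed, sid, 41)), folds=folds
            )
            scores[sid, 0, ci] = csp_acc
            scores[sid, 1, ci] = lstm_acc
            print(f"subject {sid} kappa={kappa}: CSP {csp_acc:.3f}, LSTM {lstm_acc:.3f}")

    complete = ~np.isnan(scores).any(axis=(1, 2))
    scores = scores[complete]
    out = {"scores": scores.tolist(), "n_complete": int(complete.sum())}
    if scores.shape[0] >= 2:
        anova = rm_anova_2x2(scores)
        out["anova"] = {k: {"F": v[0], "p": v[1], "df": v[2]} for k, v in anova.items()}
        print("\n2x2 RM-ANOVA (model x condition):")
        for k, v in anova.items():
            print(f"  {k:12s} F({v[2][0]},{v[2][1]}) = {v[0]:.2f}, p = {v[1]:.3f}")
    if scores.shape[0] >= 3:
        corr = cross_model_correlation(
            {"csp": scores[:, 0, :].mean(axis=1), "lstm": scores[:, 1, :].mean(axis=1)}
        )
        out["cross_model"] = {f"{a}-{b}": {"r": r, "p_bonf": p}
                              for (a, b), (r, p) in corr.items()}
        t, p = group_mean_test(scores[:, 0, 0])
        out["csp_vs_chance"] = {"t": t, "p": p}
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(out, indent=2))
    print(f"-> {args.out}")


if __name__ == "__main__":
    main()
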