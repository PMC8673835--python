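"""Desk-scale simulation studies: null calibration and parameter recovery.

These drive the full per-subject chain (generator -> alpha peak -> SSD ->
component selection -> SPoC / CSP / LSTM) over simulated cohorts and
summarize the outcomes.  They are the computational backbone of the
``analysis/`` drivers and of ``scripts/acceptance.py``.

Study sizes default to what a single CPU handles in minutes: 100 null
subjects x 200 permutations for calibration, 20 subjects for recovery,
3 training seeds for the LSTM check.  The permutation count is reduced
from the 1000 used at full scale; the p-value granularity (1/201) is
ample for calibration at alpha = 0.05.
"""

from __future__ import annotations

import logging

import numpy as np

from .csp import block_permutation_test, randomized_cv, subblocked_cv
from .pipeline import _subject_seed, estimate_alpha_peak
from .preprocess import EpochedData, epoch, tertile_labels
from .spectral import ssd_bands
from .spoc import epoch_covariances, estimate_target, spoc_decompose, spoc_permutation_test
from .ssd import require_min_components, select_components, ssd_decompose
from .synth import SynthConfig, generate_subject, pattern_similarity

logger = logging.getLogger(__name__)

__all__ = [
    "structural_counts",
    "subject_chain",
    "null_calibration",
    "recovery_study",
    "lstm_study",
]


def structural_counts(seed: int = 0) -> dict:
    """The analytic/structural counts of the study design, computed by
    running the pipeline stages on one simulated subject."""
    from .preprocess import crop_experience
    from .synth import Recording

    cfg = SynthConfig(seed=seed)
    rec, trace, _ = generate_subject(cfg)

    # a raw-style recording (uncropped rides of 153/97 s, 35-s break)
    fs = int(rec.fs)
    raw = Recording(
        data=np.zeros((2, (153 + 35 + 97) * fs)),
        fs=rec.fs,
        channel_labels=("a", "b"),
        segment_marks=(153 * fs, (153 + 35) * fs),
        cropped=False,
    )
    cropped = crop_experience(raw)
    rides_only = crop_experience(raw, include_break=False)

    epochs = epoch(rec)
    labels = tertile_labels(trace)
    return {
        "analysed_duration_s": cropped.duration_s,
        "no_break_duration_s": rides_only.duration_s,
        "samples_per_epoch": epochs.tensor.shape[1],
        "n_epochs": epochs.n_epochs,
        "n_binary_epochs": int(labels.binary_mask.sum()),
        "n_per_class": int((labels.binary_labels == 1).sum()),
    }


def subject_chain(seed: int, kappa: float, **synth_overrides) -> dict | None:
    """Generator -> peak -> SSD -> selection for one subject; None if the
    subject fails the minimum-component rule."""
    cfg = SynthConfig(seed=seed, coupling_kappa=kappa, **synth_overrides)
    rec, trace, gt = generate_subject(cfg)
    peak = estimate_alpha_peak(rec)
    res = ssd_decompose(rec, ssd_bands(peak))
    selected = select_components(res, peak)
    if not require_min_components(selected):
        logger.info("seed %d: only %d components selected", seed, len(selected))
        return None
    tensor = epoch(res.components[selected], rec.fs).tensor
    return {
        "config": cfg,
        "recording": rec,
        "trace": trace,
        "truth": gt,
        "peak": peak,
        "ssd": res,
        "selected": selected,
        "tensor": tensor,
    }


def null_calibration(
    n_subjects: int = 100, n_perm: int = 200, seed: int = 0
) -> dict:
    """Type-I behaviour of the decoding chain with coupling_kappa = 0.

    For each uncoupled subject: the SPoC surrogate-permutation p-value,
    the CSP block-permutation p-value (randomized-CV accuracy metric) and
    the randomized-CV accuracy itself.  With no coupling, both p-value
    populations should be uniform and the accuracies centred on chance.
    """
    spoc_p, block_p, accs = [], [], []
    for s in range(n_subjects):
        chain = subject_chain(_subject_seed(seed, s, 0), kappa=0.0)
        if chain is None:
            continue
        cov = epoch_covariances(chain["tensor"])
        z = chain["trace"].z
        spoc_res = spoc_permutation_test(cov, z, n_perm=n_perm,
                                         seed=_subject_seed(seed, s, 1))
        spoc_p.append(spoc_res.p_value)

        labels = tertile_labels(chain["trace"])
        bin_covs = epoch_covariances(chain["tensor"][labels.binary_mask])
        cv_seed = _subject_seed(seed, s, 2)
        res = randomized_cv(bin_covs, labels.binary_labels, seed=cv_seed)
        accs.append(res.mean_metric)

        def acc_metric(c, l):
            return randomized_cv(c, l, seed=cv_seed).mean_metric

        _, p, _ = block_permutation_test(
            bin_covs, labels.binary_labels, acc_metric,
            n_perm=n_perm, seed=_subject_seed(seed, s, 3),
        )
        block_p.append(p)
    spoc_p, block_p, accs = map(np.asarray, (spoc_p, block_p, accs))
    return {
        "n_subjects": int(spoc_p.size),
        "spoc_p_values": spoc_p,
        "csp_block_p_values": block_p,
        "csp_accuracies": accs,
        "spoc_rejection_rate": float(np.mean(spoc_p < 0.05)),
        "csp_block_rejection_rate": float(np.mean(block_p < 0.05)),
        "csp_accuracy_median": float(np.median(accs)),
    }


def recovery_study(n_subjects: int = 20, kappa: float = 0.8, seed: int = 0) -> dict:
    """Parameter recovery with strong coupling and high in-band SNR.

    Medians over subjects of: |cosine| between the SPoC-chosen component's
    scalp pattern and the planted one; the SPoC target correlation r; the
    CSP randomized-CV accuracy; and the sub-blocked ROC-AUC.
    """
    sims, rs, accs, aucs = [], [], [], []
    for s in range(n_subjects):
        chain = subject_chain(
            _subject_seed(seed, s, 10), kappa=kappa, sensor_noise_sd=1.0
        )
        if chain is None:
            continue
        cov = epoch_covariances(chain["tensor"])
        z = chain["trace"].z
        spoc_res = estimate_target(spoc_decompose(cov, z), cov, z)
        chan_pattern = (
            chain["ssd"].patterns_A[:, chain["selected"]] @ spoc_res.chosen_pattern
        )
        sims.append(abs(pattern_similarity(chan_pattern, chain["truth"].alpha_pattern)))
        rs.append(spoc_res.r)

        labels = tertile_labels(chain["trace"])
        bin_covs = epoch_covariances(chain["tensor"][labels.binary_mask])
        accs.append(
            randomized_cv(bin_covs, labels.binary_labels,
                          seed=_subject_seed(seed, s, 11)).mean_metric
        )
        aucs.append(
            subblocked_cv(bin_covs, labels.binary_labels,
                          seed=_subject_seed(seed, s, 12)).mean_metric
        )
    return {
        "n_subjects": len(sims),
        "pattern_similarity_median": float(np.median(sims)),
        "spoc_r_median": float(np.median(rs)),
        "csp_accuracy_median": float(np.median(accs)),
        "csp_auc_median": float(np.median(aucs)),
        "pattern_similarities": np.asarray(sims),
        "spoc_rs": np.asarray(rs),
        "csp_accuracies": np.asarray(accs),
        "csp_aucs": np.asarray(aucs),
    }


def lstm_study(n_seeds: int = 3, seed: int = 0, subject_seed: int | None = None) -> dict:
    """LSTM sanity on one strongly coupled subject.

    Cross-validated accuracy (10-fold, pooled predictions over 180 epochs)
    for ``n_seeds`` training seeds, plus the exact one-sided binomial 95%
    chance band for n=180 to compare against.
    """
    from scipy.stats import binom

    from .lstm import HPConfig, build_dataset, evaluate_cv

    chain = subject_chain(
        subject_seed if subject_seed is not None else _subject_seed(seed, 0, 20),
        kappa=0.8, sensor_noise_sd=1.0,
    )
    if chain is None:  # pragma: no cover - strong coupling always passes
        raise RuntimeError("planted subject unexpectedly excluded")
    labels = tertile_labels(chain["trace"])
    ds = build_dataset(EpochedData(tensor=chain["tensor"], fs=250.0), labels)
    accs = []
    for s in range(n_seeds):
        hp = HPConfig(seed=_subject_seed(seed, s, 21))
        acc, _ = evaluate_cv(ds, hp, seed=hp.seed)
        accs.append(acc)
    n = ds.n_epochs
    threshold = binom.isf(0.05, n, 0.5) / n  # smallest acc with one-sided p < 0.05
    return {
        "accuracies": np.asarray(accs),
        "accuracy_median": float(np.median(accs)),
        "n_epochs": n,
        "chance_band_upper": float(threshold),
    }
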