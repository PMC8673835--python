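"""Subject- and group-level statistics and the break-exclusion control.

Per-subject decoding accuracies are tested against chance with exact
binomial tests (tail summation of the binomial pmf, no normal
approximation); group means with one-sided one-sample t-tests against 0.5;
the CSP-vs-LSTM x condition design with a 2x2 repeated-measures ANOVA; and
the with- vs without-break control with two-sided paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy import stats

__all__ = [
    "SubjectSummary",
    "exact_binomial_test",
    "group_mean_test",
    "rm_anova_2x2",
    "paired_comparison",
    "cross_model_correlation",
    "run_break_exclusion_control",
]


@dataclass
class SubjectSummary:
    """Per-subject decoding metrics across models, one condition."""

    subject: int
    condition: str = "simulated"
    excluded: bool = False
    n_selected_components: int = 0
    metrics: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        """Flat record using the released-table column names."""
        row = {
            "Subject": self.subject,
            "Condition": self.condition,
            "Excluded": self.excluded,
            "N_SSD_selected": self.n_selected_components,
            "SPOC_LAMBDA": self.metrics.get("spoc_lambda", np.nan),
            "SPOC_CORR": self.metrics.get("spoc_r", np.nan),
            "SPOC_Pvalue": self.p_values.get("spoc", np.nan),
            "CSP_acc": self.metrics.get("csp_acc", np.nan),
            "CSP_auc": self.metrics.get("csp_auc", np.nan),
            "CSP_Pvalues": self.p_values.get("csp", np.nan),
            "LSTM_acc": self.metrics.get("lstm_acc", np.nan),
            "LSTM_Pvalues": self.p_values.get("lstm", np.nan),
        }
        return row


def exact_binomial_test(
    n_correct: int, n_total: int = 180, p0: float = 0.5, sided: str = "two-sided"
) -> float:
    """Exact binomial test of observed correct predictions against chance.

    ``sided`` is "two-sided" (default; the null is simply "performance is
    at chance") or "greater" for the directed above-chance question.
    """
    if not 0 <= n_correct <= n_total:
        raise ValueError("n_correct must lie in [0, n_total]")
    return float(stats.binomtest(n_correct, n_total, p0, alternative=sided).pvalue)


def group_mean_test(metrics: NDArray[np.float64], mu0: float = 0.5) -> tuple[float, float]:
    """One-sided (upper tail) one-sample t-test of the mean decoding metric
    against the chance level ``mu0``."""
    metrics = np.asarray(metrics, dtype=float).ravel()
    if metrics.size < 3:
        raise ValueError("need at least 3 subjects")
    if metrics.std(ddof=1) == 0:
        raise ValueError("zero variance across subjects: t undefined")
    t, p = stats.ttest_1samp(metrics, mu0, alternative="greater")
    return float(t), float(p)


def rm_anova_2x2(scores: NDArray[np.float64]) -> dict[str, tuple[float, float, tuple[int, int]]]:
    """2x2 repeated-measures ANOVA on a subjects x 2 x 2 score array.

    Axis 1 is the model factor (e.g. CSP vs LSTM), axis 2 the condition
    factor.  For two-level within factors each effect's F(1, n-1) equals
    the squared paired t on the corresponding per-subject contrast:

        model:       mean over conditions of (model1 - model2)
        condition:   mean over models of (cond1 - cond2)
        interaction: (m1c1 - m1c2) - (m2c1 - m2c2)

    Returns {effect: (F, p, (df1, df2))}.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 3 or scores.shape[1:] != (2, 2):
        raise ValueError("scores must be subjects x 2 x 2")
    n = scores.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    contrasts = {
        "model": scores[:, 0, :].mean(axis=1) - scores[:, 1, :].mean(axis=1),
        "condition": scores[:, :, 0].mean(axis=1) - scores[:, :, 1].mean(axis=1),
        "interaction": (scores[:, 0, 0] - scores[:, 0, 1]) - (scores[:, 1, 0] - scores[:, 1, 1]),
    }
    out = {}
    for name, c in contrasts.items():
        sd = c.std(ddof=1)
        if sd == 0:
            F = 0.0 if np.allclose(c, 0) else np.inf
            p = 1.0 if F == 0.0 else 0.0
        else:
            t = c.mean() / (sd / np.sqrt(n))
            F = t**2
            p = float(stats.f.sf(F, 1, n - 1))
        out[name] = (float(F), float(p), (1, n - 1))
    return out


def paired_comparison(
    metric_with: NDArray[np.float64], metric_without: NDArray[np.float64]
) -> tuple[float, float]:
    """Two-sided paired t-test (e.g. decoding with vs without the break)."""
    a = np.asarray(metric_with, dtype=float).ravel()
    b = np.asarray(metric_without, dtype=float).ravel()
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    d = a - b
    if np.all(d == d[0]):
        if d[0] == 0:
            return 0.0, 1.0
        raise ValueError("zero-variance non-zero differences: t undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def cross_model_correlation(
    metric_table: dict[str, NDArray[np.float64]]
) -> dict[tuple[str, str], tuple[float, float]]:
    """Pairwise Pearson correlations between per-subject metrics of
    different models, Bonferroni-adjusted over the number of pairs."""
    names = sorted(metric_table)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    m = len(pairs)
    out = {}
    for a, b in pairs:
        x = np.asarray(metric_table[a], dtype=float)
        y = np.asarray(metric_table[b], dtype=float)
        if x.size != y.size or x.size < 3:
            raise ValueError("metrics must be paired with >= 3 subjects")
        if x.std() == 0 or y.std() == 0:
            raise ValueError(f"constant metric vector for {a if x.std() == 0 else b}")
        r, p = stats.pearsonr(x, y)
        out[(a, b)] = (float(r), float(min(1.0, m * p)))
    return out


def run_break_exclusion_control(
    recording,
    trace,
    alpha_peak_hz: float,
    n_perm: int = 200,
    seed: int = 0,
    refit_ssd: bool = True,
    ssd_result=None,
    ssd_kwargs: dict | None = None,
):
    """Re-run labelling, SPoC and sub-blocked CSP on the rides-only crop.

    The break is removed (240 s remain), the tertile split recalculated
    (80 per class) and, by default, SSD filters are refit on the 240-s
    data; pass ``refit_ssd=False`` with an existing ``ssd_result`` to
    reuse the full-experience filters instead.  Returns a dict of the
    without-break metrics suitable for :func:`paired_comparison` against a
    full-experience run.
    """
    # local imports keep the statistics module free of pipeline dependencies
    from .csp import block_permutation_test, subblocked_cv
    from .preprocess import crop_experience, epoch, tertile_labels
    from .spectral import ssd_bands
    from .spoc import epoch_covariances, spoc_permutation_test
    from .ssd import bandpass_filter, require_min_components, select_components, ssd_decompose
    from .synth import RatingTrace

    rec240 = crop_experience(recording, include_break=False)
    segs = recording.segments()
    fs_i = int(round(recording.fs))
    ride_secs = np.concatenate(
        [
            np.arange(segs[0][0] // fs_i, segs[0][1] // fs_i),
            np.arange(segs[2][0] // fs_i, segs[2][1] // fs_i),
        ]
    )
    trace240 = RatingTrace(values=trace.values[ride_secs], n_levels=trace.n_levels,
                           quantized=trace.quantized)

    bands = ssd_bands(alpha_peak_hz)
    if refit_ssd or ssd_result is None:
        ssd_result = ssd_decompose(rec240, bands, **(ssd_kwargs or {}))
        selected = select_components(ssd_result, alpha_peak_hz)
        comps = ssd_result.components[selected]
    else:
        raw240 = crop_experience(recording, include_break=False)
        comps = bandpass_filter(
            ssd_result.filters_W[:, ssd_result.selected].T @ raw240.data,
            recording.fs, *bands["signal"],
        )
        selected = ssd_result.selected

    out = {"n_selected": int(len(selected)), "kept": require_min_components(selected)}
    if not out["kept"]:
        return out

    tensor = epoch(comps, recording.fs).tensor
    z = trace240.z
    cov = epoch_covariances(tensor)
    spoc_res = spoc_permutation_test(cov, z, n_perm=max(100, n_perm), seed=seed)
    out["spoc_r"] = spoc_res.r
    out["spoc_p"] = spoc_res.p_value

    labels = tertile_labels(trace240)
    mask = labels.binary_mask
    bin_tensor = tensor[mask]
    bin_labels = labels.binary_labels
    csp_res = subblocked_cv(bin_tensor, bin_labels, seed=seed)
    out["csp_auc"] = csp_res.mean_metric

    def auc_metric(t, lab):
        return subblocked_cv(t, lab, seed=seed).mean_metric

    _, p_block, _ = block_permutation_test(
        bin_tensor, bin_labels, auc_metric, n_perm=n_perm, seed=seed
    )
    out["csp_block_p"] = p_block
    return out
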