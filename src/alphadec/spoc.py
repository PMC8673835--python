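"""Source power comodulation (SPoC) with surrogate-target permutation tests.

SPoC finds spatial filters whose per-epoch band-power (approximated by the
per-epoch variance of the filtered signal) maximally covaries with a
continuous, z-scored target z.  With per-epoch covariance matrices C(e) and
their mean C-bar, the filters solve the generalized eigenvalue problem of
(Cz, C-bar) where Cz = mean_e z(e) C(e); each eigenvalue lambda equals, by
construction, the covariance between z and the component's per-epoch power.
Under the hypothesis of an inverse alpha-power/arousal relation the
component with the *smallest* (most negative) lambda is retained.

Significance is assessed with phase-randomized surrogate targets: each
surrogate keeps the Fourier amplitude spectrum (hence autocorrelation) of z
but randomizes phases, the full decomposition is re-run, and the p-value is
the (+1-corrected) fraction of surrogate correlations below the observed
one (lower tail, matching the directed hypothesis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy import linalg, stats

__all__ = [
    "EpochCovariances",
    "SPoCResult",
    "epoch_covariances",
    "spoc_decompose",
    "estimate_target",
    "surrogate_target",
    "spoc_permutation_test",
    "spoc_group_test",
]


@dataclass
class EpochCovariances:
    """Per-epoch channel covariances of (SSD-space, band-filtered) data."""

    covs: NDArray[np.float64]  # epochs x k x k

    def __post_init__(self) -> None:
        self.covs = np.asarray(self.covs, dtype=float)
        if self.covs.ndim != 3 or self.covs.shape[1] != self.covs.shape[2]:
            raise ValueError("covs must be epochs x k x k")

    @property
    def n_epochs(self) -> int:
        return self.covs.shape[0]

    @property
    def mean(self) -> NDArray[np.float64]:
        return self.covs.mean(axis=0)


def epoch_covariances(tensor: NDArray[np.float64]) -> EpochCovariances:
    """Covariance per epoch from an epochs x samples x channels tensor."""
    tensor = np.asarray(tensor, dtype=float)
    if tensor.ndim != 3:
        raise ValueError("expected epochs x samples x channels")
    centred = tensor - tensor.mean(axis=1, keepdims=True)
    n = tensor.shape[1] - 1
    covs = np.einsum("etk,etl->ekl", centred, centred) / max(n, 1)
    return EpochCovariances(covs=covs)


@dataclass
class SPoCResult:
    filters_W: NDArray[np.float64]     # k x k, columns are filters
    patterns_A: NDArray[np.float64]    # k x k, columns are patterns
    lambdas: NDArray[np.float64]       # descending; covariance scale
    chosen_index: int
    z_est: NDArray[np.float64] = field(default_factory=lambda: np.array([]))
    r: float = np.nan
    p_value: float = np.nan
    null_r: NDArray[np.float64] = field(default_factory=lambda: np.array([]))

    @property
    def chosen_filter(self) -> NDArray[np.float64]:
        return self.filters_W[:, self.chosen_index]

    @property
    def chosen_pattern(self) -> NDArray[np.float64]:
        return self.patterns_A[:, self.chosen_index]


def _check_target(z: NDArray[np.float64], n_epochs: int) -> NDArray[np.float64]:
    z = np.asarray(z, dtype=float).ravel()
    if z.size != n_epochs:
        raise ValueError("target length must equal the number of epochs")
    if z.std() == 0:
        raise ValueError("degenerate target: zero variance after centring")
    return (z - z.mean()) / z.std()


def spoc_decompose(cov: EpochCovariances, z: NDArray[np.float64]) -> SPoCResult:
    """Solve the SPoC_lambda generalized eigenproblem.

    Filters are normalized so that w^T C-bar w = 1, which makes each
    eigenvalue equal the (population) covariance between z and the
    component's per-epoch variance.
    """
    z = _check_target(z, cov.n_epochs)
    k = cov.covs.shape[1]
    if cov.n_epochs < k:
        raise ValueError("fewer epochs than components: rank-deficient problem")
    Cbar = cov.mean
    Cz = np.tensordot(z, cov.covs, axes=1) / cov.n_epochs

    evals, evecs = linalg.eigh(Cz, Cbar)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    # normalize so w' Cbar w = 1 (eigh already returns B-orthonormal vectors,
    # renormalize defensively)
    scale = np.sqrt(np.einsum("ik,ij,jk->k", evecs, Cbar, evecs))
    W = evecs / scale
    lambdas = np.einsum("ik,ij,jk->k", W, Cz, W)
    patterns = np.linalg.pinv(W).T
    return SPoCResult(
        filters_W=W,
        patterns_A=patterns,
        lambdas=lambdas,
        chosen_index=int(np.argmin(lambdas)),
    )


def estimate_target(
    res: SPoCResult, cov: EpochCovariances, z: NDArray[np.float64]
) -> SPoCResult:
    """Fill in z_est (per-epoch power of the chosen component) and its
    Pearson correlation with the true target."""
    w = res.chosen_filter
    z_est = np.einsum("k,ekl,l->e", w, cov.covs, w)
    z = _check_target(z, cov.n_epochs)
    res.z_est = z_est
    # a constant power series carries no comodulation: r = 0 by convention
    res.r = 0.0 if np.ptp(z_est) == 0 else float(stats.pearsonr(z, z_est)[0])
    return res


def surrogate_target(
    z: NDArray[np.float64], seed: int | np.random.Generator = 0
) -> NDArray[np.float64]:
    """Phase-randomized surrogate with identical Fourier amplitude spectrum.

    DC and (for even length) Nyquist bins are preserved so the surrogate is
    exactly real-valued with the same mean, variance and autocorrelation.
    """
    z = np.asarray(z, dtype=float).ravel()
    n = z.size
    if n < 4:
        raise ValueError("need at least 4 samples")
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(z)
    n_interior = spec.size - 2 if n % 2 == 0 else spec.size - 1
    phases = rng.uniform(0.0, 2.0 * np.pi, n_interior)
    rotated = spec.copy()
    rotated[1 : 1 + n_interior] = np.abs(spec[1 : 1 + n_interior]) * np.exp(1j * phases)
    return np.fft.irfft(rotated, n)


def spoc_permutation_test(
    cov: EpochCovariances,
    z: NDArray[np.float64],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> SPoCResult:
    """Full SPoC with a surrogate-target permutation p-value.

    Each permutation re-runs the decomposition on a fresh phase-randomized
    surrogate and records the correlation of its own chosen component; the
    p-value is (#{r_perm < r_obs} + 1) / (n_perm + 1), lower-tailed for the
    hypothesized negative comodulation.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    res = estimate_target(spoc_decompose(cov, z), cov, z)
    null_r = np.empty(n_perm)
    for i in range(n_perm):
        z_perm = surrogate_target(z, rng)
        perm = estimate_target(spoc_decompose(cov, z_perm), cov, z_perm)
        null_r[i] = perm.r
    res.null_r = null_r
    res.p_value = (np.sum(null_r < res.r) + 1.0) / (n_perm + 1.0)
    return res


def spoc_group_test(
    r_values: NDArray[np.float64], null_means: NDArray[np.float64]
) -> tuple[float, float]:
    """Group-level test of negative comodulation: one-sample, one-tailed t
    on the per-subject differences (observed r - mean surrogate r), lower
    tail."""
    r_values = np.asarray(r_values, dtype=float).ravel()
    null_means = np.asarray(null_means, dtype=float).ravel()
    if r_values.shape != null_means.shape:
        raise ValueError("r_values and null_means must have equal length")
    if r_values.size < 3:
        raise ValueError("need at least 3 subjects")
    diffs = r_values - null_means
    if np.all(diffs == 0):
        return 0.0, 0.5
    t, p = stats.ttest_1samp(diffs, 0.0, alternative="less")
    return float(t), float(p)
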