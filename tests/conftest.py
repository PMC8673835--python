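"""Shared fixtures: the synthetic-subject -> SSD chain is expensive enough
to compute once per session for the coupled and the uncoupled case."""

from __future__ import annotations

import logging

import numpy as np
import pytest
from hypothesis import settings

import alphadec as ad

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from alphadec.pipeline import estimate_alpha_peak
from alphadec.preprocess import epoch, tertile_labels
from alphadec.spoc import epoch_covariances

# single-class AUC folds under permuted labels are expected; keep logs quiet
logging.getLogger("alphadec").setLevel(logging.ERROR)
logging.getLogger("alphadec.csp").setLevel(logging.ERROR)


def ssd_chain(seed: int, kappa: float, **synth_kwargs):
    """Generate a subject and run it through peak detection + SSD."""
    cfg = ad.SynthConfig(seed=seed, coupling_kappa=kappa, **synth_kwargs)
    rec, trace, gt = ad.generate_subject(cfg)
    peak = estimate_alpha_peak(rec)
    res = ad.ssd_decompose(rec, ad.ssd_bands(peak))
    sel = ad.select_components(res, peak)
    tensor = epoch(res.components[sel], rec.fs).tensor
    return {
        "config": cfg,
        "recording": rec,
        "trace": trace,
        "truth": gt,
        "peak": peak,
        "ssd": res,
        "selected": sel,
        "tensor": tensor,
    }


@pytest.fixture(scope="session")
def planted():
    """One strongly coupled subject (kappa=0.8) through the SSD stage."""
    return ssd_chain(seed=3, kappa=0.8)


@pytest.fixture(scope="session")
def null_subject():
    """One uncoupled subject (kappa=0) through the SSD stage."""
    return ssd_chain(seed=11, kappa=0.0)


@pytest.fixture(scope="session")
def planted_binary(planted):
    """Binary-labelled epoch covariances of the coupled subject."""
    labels = tertile_labels(planted["trace"])
    tensor = planted["tensor"][labels.binary_mask]
    return {
        "tensor": tensor,
        "covs": epoch_covariances(tensor),
        "labels": labels.binary_labels,
        "labelset": labels,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
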