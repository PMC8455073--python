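"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rescore.pin_io import PsmTable
from rescore.synthetic import SyntheticConfig, simulate_psms

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def oracle_tdc_qvalues(scores, is_target):
    """Brute-force q-values by threshold enumeration.

    For every distinct score s', FDR(s') = (D(s')+1)/max(T(s'),1) counting
    PSMs with score >= s'; the q-value of a target with score s is the
    minimum FDR over all thresholds s' <= s, clipped at 1. Independent of
    the production implementation (no sorting/cumulative tricks).
    """
    scores = np.asarray(scores, dtype=float)
    is_target = np.asarray(is_target, dtype=bool)
    thresholds = np.unique(scores)
    t_scores = scores[is_target]
    d_scores = scores[~is_target]
    fdrs = np.empty(len(thresholds))
    for i, s in enumerate(thresholds):
        D = int((d_scores >= s).sum())
        T = int((t_scores >= s).sum())
        fdrs[i] = (D + 1) / max(T, 1)
    out = np.empty(len(t_scores))
    for i, s in enumerate(t_scores):
        out[i] = min(fdrs[thresholds <= s].min(), 1.0)
    return out


def make_table(
    scores_or_features,
    is_target,
    peptides=None,
    scan_nr=None,
    rank=None,
    proteins=None,
    feature_names=None,
):
    """Hand-built PsmTable from plain lists, for small worked examples."""
    feats = np.atleast_2d(np.asarray(scores_or_features, dtype=float))
    if feats.shape[0] == 1 and len(is_target) > 1:
        feats = feats.T
    n = feats.shape[0]
    names = feature_names or [f"f{j}" for j in range(feats.shape[1])]
    is_target = np.asarray(is_target, dtype=bool)
    if peptides is None:
        peptides = [f"K.PEP{i}K.A" for i in range(n)]
    if proteins is None:
        proteins = [("prot%d" % (i % 3),) for i in range(n)]
    return PsmTable(
        spec_id=np.array([f"s{i}" for i in range(n)], dtype=object),
        is_target=is_target,
        scan_nr=np.arange(1, n + 1) if scan_nr is None else np.asarray(scan_nr),
        features=pd.DataFrame(feats, columns=names),
        peptide=np.array(peptides, dtype=object),
        proteins=proteins,
        rank=rank,
    )


@pytest.fixture(scope="session")
def small_experiment():
    """A default-condition synthetic experiment (n=4,000, pi1=1/3)."""
    return simulate_psms(SyntheticConfig(seed=101))


@pytest.fixture(scope="session")
def tiny_experiment():
    """A small synthetic experiment (n=600) for fast pipeline tests."""
    return simulate_psms(SyntheticConfig(n_targets=300, n_decoys=300, seed=7))
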