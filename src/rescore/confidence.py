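"""Target-decoy competition q-values at PSM and peptide level.

The q-value of a PSM is the minimal false-discovery-rate threshold at
which it is accepted.  With target counts ``T(s)`` and decoy counts
``D(s)`` at score threshold ``s``, the FDR estimate is
``(D(s) + 1) / max(T(s), 1)`` — the +1 pseudocount makes the estimator
conservative — and q-values are the running minimum of that estimate over
all thresholds at or below each score, clipped at 1.  At tied scores,
decoys are counted before targets (the conservative tie-break).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import RescoreError
from .pin_io import PsmTable

__all__ = [
    "ConfidenceResult",
    "tdc_qvalues",
    "assign_confidence",
    "count_accepted",
    "strip_flanks",
]

_FLANK_RE = re.compile(r"^(?:[A-Za-z*-]|\[[^\]]*\])\.(.+)\.(?:[A-Za-z*-]|\[[^\]]*\])$")


def strip_flanks(peptide: str) -> str:
    """Remove flanking residues (``K.PEPTIDER.S`` -> ``PEPTIDER``).

    Modifications inside the core sequence are preserved, so the result is
    the modification-aware peptide identity used for rollup.
    """
    m = _FLANK_RE.match(peptide)
    return m.group(1) if m else peptide


@dataclass
class ConfidenceResult:
    """Per-PSM and per-peptide scores and q-values for the target matches.

    ``psm_table`` holds one row per rank-1 target PSM; ``peptide_table``
    holds one row per distinct (modification-aware) target peptide, scored
    by its best PSM. Both have columns
    ``spec_id, peptide, proteins, score, qvalue``.
    """

    psm_table: pd.DataFrame
    peptide_table: pd.DataFrame
    eval_fdr: float = 0.01

    def accepted(self, level: str = "psm", threshold: float | None = None) -> pd.DataFrame:
        thr = self.eval_fdr if threshold is None else threshold
        frame = self._frame(level)
        return frame[frame["qvalue"] <= thr]

    def _frame(self, level: str) -> pd.DataFrame:
        if level == "psm":
            return self.psm_table
        if level == "peptide":
            return self.peptide_table
        raise ValueError(f"unknown level {level!r} (expected 'psm' or 'peptide')")


def tdc_qvalues(scores, is_target) -> np.ndarray:
    """q-values for the target entries, in their original input order.

    ``is_target`` may be a boolean vector or a vector of ``"target"`` /
    ``"decoy"`` strings. Raises on non-finite scores or zero targets.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(is_target)
    if labels.dtype.kind in "US":
        labels = labels == "target"
    labels = labels.astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-D vectors")
    if not np.isfinite(scores).all():
        raise RescoreError("scores contain non-finite values")
    if not labels.any():
        raise RescoreError("cannot estimate q-values without any target PSMs")

    # Descending score; at ties decoys sort first so D(s) counts them
    # before any tied target is reached.
    order = np.lexsort((labels.astype(np.int8), -scores))
    lab = labels[order]
    targets = np.cumsum(lab)
    decoys = np.cumsum(~lab)
    fdr = (decoys + 1.0) / np.maximum(targets, 1)
    qvals = np.minimum(np.minimum.accumulate(fdr[::-1])[::-1], 1.0)
    out = np.empty(len(scores), dtype=float)
    out[order] = qvals
    return out[labels]


def assign_confidence(table: PsmTable, scores, eval_fdr: float = 0.01) -> ConfidenceResult:
    """Compute PSM- and peptide-level q-values for a scored table.

    PSM-level q-values use only rank-1 PSMs. For the peptide level, PSMs
    are grouped by modification-aware peptide (flanking residues
    stripped); the best-scoring PSM per peptide is kept separately within
    targets and within decoys before target-decoy competition. Ties in the
    best-PSM selection break on the smaller spec_id.
    """
    if len(table) == 0:
        raise RescoreError("cannot assign confidence to an empty table")
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(table):
        raise ValueError("scores must be aligned with the table rows")

    r1 = table.rank == 1
    if not r1.any():
        raise RescoreError("table has no rank-1 PSMs")
    frame = pd.DataFrame(
        {
            "spec_id": table.spec_id[r1],
            "peptide": table.peptide[r1],
            "score": scores[r1],
            "is_target": table.is_target[r1],
        }
    )
    frame["proteins"] = [table.proteins[i] for i in np.flatnonzero(r1)]
    frame["pep_key"] = [strip_flanks(p) for p in frame["peptide"]]

    psm_q = tdc_qvalues(frame["score"].to_numpy(), frame["is_target"].to_numpy())
    psm_table = frame[frame["is_target"]][["spec_id", "peptide", "proteins", "score"]].copy()
    psm_table["qvalue"] = psm_q
    psm_table = psm_table.reset_index(drop=True)

    best = (
        frame.sort_values(["score", "spec_id"], ascending=[False, True], kind="mergesort")
        .drop_duplicates(["is_target", "pep_key"])
        .reset_index(drop=True)
    )
    pep_q = tdc_qvalues(best["score"].to_numpy(), best["is_target"].to_numpy())
    peptide_table = best[best["is_target"]][["spec_id", "peptide", "proteins", "score"]].copy()
    peptide_table["qvalue"] = pep_q
    peptide_table = peptide_table.reset_index(drop=True)

    return ConfidenceResult(psm_table=psm_table, peptide_table=peptide_table, eval_fdr=eval_fdr)


def count_accepted(result: ConfidenceResult, threshold: float, level: str = "psm") -> int:
    """Number of target entries with q-value <= ``threshold`` at a level."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return int((result._frame(level)["qvalue"] <= threshold).sum())
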