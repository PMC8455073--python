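"""Evaluation machinery: downsampling designs, multi-seed grids,
q-value concordance, and peptide-consistency summaries.

The downsampling study mirrors a standard power analysis for rescoring:
a base training set is repeatedly subsampled (either fewer *total* PSMs,
or fewer *confident* PSMs at constant total), each subsample is analyzed
with the dynamic pipeline under several random seeds, and every learned
model is exported in static form and applied to one common held-out test
set so the models are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import confidence as conf
from .engine import LinearModel, TrainConfig, brew
from .exceptions import RescoreError
from .pin_io import PsmTable
from .static_model import apply_static, average_fold_models

__all__ = [
    "DownsampleSpec",
    "GridCell",
    "ExperimentGrid",
    "PairedQValues",
    "downsample_total",
    "downsample_confident",
    "run_downsampling_study",
    "pairwise_qvalue_table",
    "accepted_count_summary",
    "shared_peptide_curve",
    "yield_matched_peptides",
]


@dataclass
class DownsampleSpec:
    """Design of a downsampling study.

    ``mode="total"`` shrinks the total PSM count to each entry of
    ``sizes``; ``mode="confident"`` fixes the total at ``constant_total``
    and shrinks the number of confident PSMs instead. ``n_seeds`` dynamic
    analyses are run per size.
    """

    mode: str
    sizes: list[int]
    constant_total: int | None = None
    n_seeds: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("total", "confident"):
            raise ValueError("mode must be 'total' or 'confident'")
        if not self.sizes or any(s <= 0 for s in self.sizes):
            raise ValueError("sizes must be positive")
        if list(self.sizes) != sorted(self.sizes, reverse=True):
            raise ValueError("sizes must be decreasing")
        if self.mode == "confident":
            if self.constant_total is None:
                raise ValueError("confident mode requires constant_total")
            if self.constant_total < max(self.sizes):
                raise ValueError("constant_total must be >= max(sizes)")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")


@dataclass
class GridCell:
    size: int
    seed_index: int
    brew_seed: int
    accepted: int
    model: LinearModel
    test_result: conf.ConfidenceResult


@dataclass
class ExperimentGrid:
    """One cell per (size, seed): accepted test-set counts at the
    evaluation FDR, the exported model, and the test-set q-values."""

    spec: DownsampleSpec
    eval_fdr: float
    cells: list[GridCell] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"size": c.size, "seed_index": c.seed_index, "accepted": c.accepted}
                for c in self.cells
            ]
        )


def downsample_total(table: PsmTable, n: int, seed: int) -> PsmTable:
    """Uniform sample of exactly ``n`` PSMs without replacement."""
    if n <= 0:
        raise RescoreError("sample size must be positive")
    if n > len(table):
        raise RescoreError(f"cannot sample {n} PSMs from a table of {len(table)}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(table), size=n, replace=False))
    return table.take(idx)


def downsample_confident(
    table: PsmTable,
    confident_ids,
    n_confident: int,
    total: int,
    seed: int,
) -> PsmTable:
    """Sample ``n_confident`` PSMs from the confident pool plus enough
    unconfident PSMs to reach exactly ``total`` rows."""
    confident_ids = set(confident_ids)
    in_pool = np.array([sid in confident_ids for sid in table.spec_id], dtype=bool)
    pool_idx = np.flatnonzero(in_pool)
    rest_idx = np.flatnonzero(~in_pool)
    n_rest = total - n_confident
    if n_confident < 0 or n_rest < 0:
        raise RescoreError("invalid confident/total combination")
    if n_confident > len(pool_idx):
        raise RescoreError(
            f"requested {n_confident} confident PSMs but pool has {len(pool_idx)}"
        )
    if n_rest > len(rest_idx):
        raise RescoreError(
            f"requested {n_rest} unconfident PSMs but pool has {len(rest_idx)}"
        )
    rng = np.random.default_rng(seed)
    chosen = np.concatenate(
        [
            rng.choice(pool_idx, size=n_confident, replace=False) if n_confident else [],
            rng.choice(rest_idx, size=n_rest, replace=False) if n_rest else [],
        ]
    ).astype(np.int64)
    return table.take(np.sort(chosen))


def _cell_seeds(base_seed: int, size_index: int, seed_index: int) -> tuple[int, int]:
    """Two independent sub-seeds (sampling, training) per grid cell."""
    ss = np.random.SeedSequence([int(base_seed), int(size_index), int(seed_index)])
    a, b = ss.generate_state(2)
    return int(a % 2**31), int(b % 2**31)


def run_downsampling_study(
    base: PsmTable,
    test: PsmTable,
    spec: DownsampleSpec,
    config: TrainConfig,
    eval_fdr: float = 0.01,
) -> ExperimentGrid:
    """Run the full downsampling evaluation.

    For each (size, seed): draw the subsample, run the dynamic pipeline
    on it, export the learned model in static form (fold-average), apply
    it to the common test set, and record accepted counts and q-values.
    In confident mode the confident pool is defined by analyzing the base
    table once with the dynamic pipeline and taking target PSMs accepted
    at ``eval_fdr``.
    """
    if set(base.spec_id) & set(test.spec_id):
        raise RescoreError("base and test sets must be disjoint by spec_id")
    confident_ids: set | None = None
    if spec.mode == "confident":
        base_result = brew(base, config, eval_fdr).confidence
        accepted = base_result.accepted(level="psm", threshold=eval_fdr)
        confident_ids = set(accepted["spec_id"])
        if max(spec.sizes) > len(confident_ids):
            raise RescoreError(
                f"confident pool has {len(confident_ids)} PSMs, fewer than "
                f"the largest requested size {max(spec.sizes)}"
            )

    grid = ExperimentGrid(spec=spec, eval_fdr=eval_fdr)
    for si, size in enumerate(spec.sizes):
        for ki in range(spec.n_seeds):
            sample_seed, brew_seed = _cell_seeds(config.seed, si, ki)
            if spec.mode == "total":
                sub = downsample_total(base, size, sample_seed)
            else:
                sub = downsample_confident(
                    base, confident_ids, size, spec.constant_total, sample_seed
                )
            result = brew(sub, replace(config, seed=brew_seed), eval_fdr)
            model = average_fold_models(result)
            test_result = apply_static(test, model, eval_fdr)
            grid.cells.append(
                GridCell(
                    size=size,
                    seed_index=ki,
                    brew_seed=brew_seed,
                    accepted=conf.count_accepted(test_result, eval_fdr, "psm"),
                    model=model,
                    test_result=test_result,
                )
            )
    return grid


@dataclass
class PairedQValues:
    """Inner join of two confidence results on spec_id, plus the 2x2
    agreement counts at a threshold."""

    frame: pd.DataFrame  # columns: spec_id, q_a, q_b

    def agreement(self, threshold: float = 0.01) -> dict:
        a = self.frame["q_a"] <= threshold
        b = self.frame["q_b"] <= threshold
        return {
            "both": int((a & b).sum()),
            "a_only": int((a & ~b).sum()),
            "b_only": int((~a & b).sum()),
            "neither": int((~a & ~b).sum()),
        }


def pairwise_qvalue_table(
    res_a: conf.ConfidenceResult, res_b: conf.ConfidenceResult, level: str = "psm"
) -> PairedQValues:
    """Join two results on spec_id for concordance analysis."""
    fa = res_a._frame(level)[["spec_id", "qvalue"]].rename(columns={"qvalue": "q_a"})
    fb = res_b._frame(level)[["spec_id", "qvalue"]].rename(columns={"qvalue": "q_b"})
    joined = fa.merge(fb, on="spec_id", how="inner")
    if joined.empty:
        raise RescoreError("the two results share no identifiers")
    return PairedQValues(frame=joined)


def accepted_count_summary(grid: ExperimentGrid, threshold: float) -> pd.DataFrame:
    """Across-seed mean and t-distribution 95% CI of accepted counts, per
    size. With a single seed the CI is undefined (NaN, flagged)."""
    rows = []
    frame = pd.DataFrame(
        [
            {
                "size": c.size,
                "count": conf.count_accepted(c.test_result, threshold, "psm"),
            }
            for c in grid.cells
        ]
    )
    for size, group in frame.groupby("size", sort=False):
        counts = group["count"].to_numpy(dtype=float)
        n = len(counts)
        mean = counts.mean()
        if n >= 2:
            sd = counts.std(ddof=1)
            half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
            rows.append(
                {"size": size, "n_seeds": n, "mean": mean, "sd": sd,
                 "ci_low": mean - half, "ci_high": mean + half, "ci_defined": True}
            )
        else:
            rows.append(
                {"size": size, "n_seeds": n, "mean": mean, "sd": np.nan,
                 "ci_low": np.nan, "ci_high": np.nan, "ci_defined": False}
            )
    return pd.DataFrame(rows)


def shared_peptide_curve(peptide_sets: list[set]) -> np.ndarray:
    """For k = 1..n_sets, the number of peptides present in >= k sets."""
    if not peptide_sets:
        raise ValueError("need at least one peptide set")
    counts: dict = {}
    for s in peptide_sets:
        for p in s:
            counts[p] = counts.get(p, 0) + 1
    n = len(peptide_sets)
    occ = np.bincount(list(counts.values()) or [0], minlength=n + 1)
    # peptides in >= k sets: reverse cumulative sum of occupancy histogram
    return np.cumsum(occ[::-1])[::-1][1 : n + 1]


def yield_matched_peptides(peptide_scores: pd.DataFrame, k: int) -> set:
    """The ``k`` best-scoring target peptides (ties by lexicographic
    peptide key), used to equalize yields before comparing consistency."""
    frame = peptide_scores.copy()
    if "pep_key" not in frame.columns:
        frame["pep_key"] = [conf.strip_flanks(p) for p in frame["peptide"]]
    frame = frame.drop_duplicates("pep_key")
    if k > len(frame):
        raise RescoreError(f"requested {k} peptides but only {len(frame)} available")
    frame = frame.sort_values(["score", "pep_key"], ascending=[False, True], kind="mergesort")
    return set(frame["pep_key"].iloc[:k])
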