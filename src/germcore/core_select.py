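"""Greedy genotype-coverage core-collection selection.

Coverage of a subset is measured against the full collection: for each
locus, the genotype classes (0/1/2, missing never counts) observed in the
whole panel form the target set; coverage is the percentage of all
(locus, class) targets that the subset also exhibits.  This is a monotone
submodular coverage function, so greedy selection carries the classical
(1 - 1/e) approximation guarantee and produces a non-increasing sequence
of marginal gains — both asserted at run time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_matrix import GenotypeMatrix


@dataclass
class CoreResult:
    """Ordered core selection with its coverage trajectory."""

    selected: list[str]
    coverage_trajectory: list[float]   # percent after each addition
    stop_rule: str
    final_coverage: float
    final_size: int

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected ids must be unique")
        traj = np.asarray(self.coverage_trajectory)
        if (np.diff(traj) < -1e-9).any():
            raise ValueError("coverage trajectory must be non-decreasing")


def _incidence(matrix: GenotypeMatrix) -> tuple[np.ndarray, int]:
    """Per-sample boolean incidence over the (locus, class) targets
    present in the full collection; returns (incidence, n_targets)."""
    present = np.stack(
        [matrix.dosages == c for c in (0, 1, 2)], axis=2
    )  # (samples, loci, 3)
    overall = present.any(axis=0)            # (loci, 3)
    target_cols = overall.reshape(-1)
    inc = present.reshape(matrix.n_samples, -1)[:, target_cols]
    return inc, int(target_cols.sum())


def coverage(matrix: GenotypeMatrix, subset) -> float:
    """Genotype-class coverage (percent) of ``subset`` relative to the
    full collection held in ``matrix``."""
    subset = list(subset)
    if not subset:
        raise ValueError("coverage of an empty subset is undefined")
    pos = {s: i for i, s in enumerate(matrix.sample_ids)}
    idx = [pos[s] for s in subset]
    inc, total = _incidence(matrix)
    return 100.0 * inc[idx].any(axis=0).sum() / total


def greedy_core(
    matrix: GenotypeMatrix,
    target_coverage: float | None = None,
    target_size: int | None = None,
    coverage_gain_floor: float | None = None,
) -> CoreResult:
    """Greedy coverage-maximizing core selection.

    Starts from the empty set and repeatedly adds the sample with the
    largest coverage gain (ties broken by smallest sample index).  Stops
    at whichever configured rule fires first: ``target_coverage``
    (percent), ``target_size`` (number of accessions) or
    ``coverage_gain_floor`` (stop when the best gain, in percentage
    points, falls below the floor).  With no rule given, the defaults are
    ``target_coverage=99`` with a secondary ``coverage_gain_floor=0.01``.
    """
    if target_coverage is None and target_size is None \
            and coverage_gain_floor is None:
        target_coverage, coverage_gain_floor = 99.0, 0.01
    if target_coverage is not None and target_coverage > 100.0:
        raise ValueError(f"target_coverage {target_coverage} is unreachable")
    if matrix.n_samples < 1:
        raise ValueError("empty matrix")

    inc, total = _incidence(matrix)
    covered = np.zeros(total, dtype=bool)
    selected: list[int] = []
    trajectory: list[float] = []
    stop_rule = "exhausted"
    last_gain = np.inf

    while len(selected) < matrix.n_samples:
        if target_size is not None and len(selected) >= target_size:
            stop_rule = "target_size"
            break
        gains = (inc & ~covered).sum(axis=1)
        gains[selected] = -1
        best = int(np.argmax(gains))         # first max = smallest index
        gain_pct = 100.0 * gains[best] / total
        if coverage_gain_floor is not None and gain_pct < coverage_gain_floor:
            stop_rule = "coverage_gain_floor"
            break
        # submodularity: marginal gains never increase along the greedy path
        assert gain_pct <= last_gain + 1e-9, "non-submodular gain sequence"
        last_gain = gain_pct
        selected.append(best)
        covered |= inc[best]
        trajectory.append(100.0 * covered.sum() / total)
        if target_coverage is not None and trajectory[-1] >= target_coverage:
            stop_rule = "target_coverage"
            break
    else:
        stop_rule = "exhausted"

    ids = [matrix.sample_ids[i] for i in selected]
    final = trajectory[-1] if trajectory else 0.0
    return CoreResult(
        selected=ids,
        coverage_trajectory=trajectory,
        stop_rule=stop_rule,
        final_coverage=final,
        final_size=len(ids),
    )
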