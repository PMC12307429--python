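"""Genetic-diversity indices and core-vs-noncore group comparison.

Per-locus indices over a sample group, from allele frequencies p_a
computed on non-missing calls within the group:

* Na — observed allele number, count of alleles with p_a > 0
* Ne — effective allele number, 1 / sum(p_a^2)
* Ho — observed heterozygosity, heterozygote fraction of non-missing calls
* He — expected heterozygosity (Nei's gene diversity), 1 - sum(p_a^2)
* I  — Shannon's information index, -sum(p_a ln p_a)
* H  — unbiased gene diversity, (2n / (2n - 1)) * He with n the
  non-missing sample count (the small-sample correction of He)

PLN is the percentage of loci polymorphic (Na >= 2) within the group.
Group comparisons use two-sided Welch t-tests over per-locus values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .genotype_matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

INDEX_COLUMNS = ("na", "ne", "ho", "he", "i", "h")


@dataclass
class DiversityReport:
    """Per-locus diversity indices for one sample group."""

    label: str
    n_samples: int
    per_locus: pd.DataFrame = field(repr=False)  # columns = INDEX_COLUMNS

    @property
    def means(self) -> pd.Series:
        return self.per_locus[list(INDEX_COLUMNS)].mean()

    @property
    def pln(self) -> float:
        """Percent of loci with >= 2 observed alleles in the group."""
        return float(100.0 * (self.per_locus["na"] >= 2).mean())

    def summary_row(self) -> dict:
        row = {"group": self.label, "n_samples": self.n_samples,
               "pln": self.pln}
        row.update({k.capitalize(): v for k, v in self.means.items()})
        return row


def locus_diversity(
    matrix: GenotypeMatrix, group=None, label: str = "all"
) -> DiversityReport:
    """Compute the six per-locus indices for a sample group.

    ``group`` is a list of sample ids (default: all samples).  Loci with
    no non-missing call in the group are skipped with a warning.
    """
    if group is None:
        sub = matrix
    else:
        group = list(group)
        if not group:
            raise ValueError("empty sample group")
        sub = matrix.take_samples(group)

    dos = sub.dosages
    valid = dos != MISSING
    n = valid.sum(axis=0).astype(float)
    empty = n == 0
    if empty.any():
        logger.warning("skipping %d all-missing loci in group %r",
                       int(empty.sum()), label)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(valid, dos, 0).sum(axis=0) / (2.0 * n)  # alt frequency
        q = 1.0 - p
        sum_p2 = p * p + q * q
        na = (p > 0).astype(float) + (q > 0).astype(float)
        ne = 1.0 / sum_p2
        ho = np.where(valid, dos == 1, False).sum(axis=0) / n
        he = 1.0 - sum_p2
        shannon = -(np.where(p > 0, p * np.log(p), 0.0)
                    + np.where(q > 0, q * np.log(q), 0.0))
        h = (2.0 * n / (2.0 * n - 1.0)) * he

    per_locus = pd.DataFrame(
        {"na": na, "ne": ne, "ho": ho, "he": he, "i": shannon, "h": h},
        index=matrix.loci.index,
    )[~empty]
    return DiversityReport(label=label, n_samples=sub.n_samples,
                           per_locus=per_locus)


def _welch(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch t statistic, degrees of freedom, two-sided p."""
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        return 0.0, float(nx + ny - 2), 1.0
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = float(2.0 * scipy.stats.t.sf(abs(t), df))
    return float(t), float(df), p


def compare_groups(
    report_a: DiversityReport, report_b: DiversityReport
) -> pd.DataFrame:
    """Two-sample Welch t-test per index over per-locus values.

    Both reports should cover the same locus set.  Returns a DataFrame
    indexed by index name with columns ``t``, ``df``, ``p``.
    """
    if len(report_a.per_locus) < 2 or len(report_b.per_locus) < 2:
        raise ValueError("need at least 2 loci per group for a t-test")
    rows = {}
    for col in INDEX_COLUMNS:
        x = report_a.per_locus[col].to_numpy(float)
        y = report_b.per_locus[col].to_numpy(float)
        t, df, p = _welch(x, y)
        rows[col] = {"t": t, "df": df, "p": p}
    return pd.DataFrame(rows).T[["t", "df", "p"]]


def sampling_evaluation(
    matrix: GenotypeMatrix,
    core_ids,
    proportions=(10, 25, 50, 75, 100),
    seed: int | None = None,
) -> pd.DataFrame:
    """Core-vs-noncore diversity table under random subsampling.

    For each proportion q, draws ``floor(q% * group size)`` samples
    uniformly without replacement from the core and from the non-core
    (q = 100 takes the whole group; truncation matches the printed
    group sizes of the reference evaluation design), and reports sample
    number, PLN and the six mean indices per draw.  Proportions yielding
    zero samples are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    core_ids = list(core_ids)
    core_set = set(core_ids)
    unknown = core_set - set(matrix.sample_ids)
    if unknown:
        raise ValueError(f"core ids not in matrix: {sorted(unknown)[:5]}")
    noncore_ids = [s for s in matrix.sample_ids if s not in core_set]

    rows = []
    for q in proportions:
        for label, ids in (("core", core_ids), ("noncore", noncore_ids)):
            size = len(ids) if q >= 100 else int(len(ids) * q / 100.0)
            if size == 0:
                logger.warning("skipping %s at q=%s%%: zero samples", label, q)
                continue
            draw = ids if size == len(ids) else sorted(
                rng.choice(ids, size, replace=False).tolist())
            rep = locus_diversity(matrix, draw, label=f"{label}@{q}%")
            row = {"proportion": q, "group": label,
                   "n_samples": rep.n_samples, "pln": rep.pln}
            row.update({k.upper(): v for k, v in rep.means.items()})
            rows.append(row)
    return pd.DataFrame(rows)
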