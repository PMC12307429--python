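"""Diploidized genotype-dosage matrix and population-genetics site filters.

The central in-memory container for the whole toolkit is a samples x loci
matrix of alternate-allele dosages (0, 1, 2) with an integer missing
sentinel, plus per-locus metadata (chromosome, position, ref/alt alleles,
SNP flag, allele count).  Genotypes are strictly diploid: polyploid
germplasm panels genotyped under a diploid model arrive here already
collapsed to three genotype classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing diploid call in the dosage matrix.
MISSING: int = -1

LOCUS_COLUMNS = ("chrom", "pos", "ref", "alt", "is_snp", "n_alleles")


def locus_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Canonical locus identifier, ``chrom:pos:ref:alt`` (1-based pos)."""
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass
class GenotypeMatrix:
    """Accessions x loci dosage matrix with locus metadata.

    Parameters
    ----------
    sample_ids
        Ordered accession identifiers (unique).
    loci
        DataFrame indexed by locus id with columns ``chrom``, ``pos``,
        ``ref``, ``alt``, ``is_snp``, ``n_alleles``.
    dosages
        ``(n_samples, n_loci)`` int8 array with values in
        ``{0, 1, 2, MISSING}``; dosage counts alternate alleles in the
        diploid call.
    """

    sample_ids: list[str]
    loci: pd.DataFrame
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x loci)")
        n_s, n_l = self.dosages.shape
        if n_s != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but {n_s} dosage rows"
            )
        if n_l != len(self.loci):
            raise ValueError(f"{len(self.loci)} loci but {n_l} dosage columns")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.loci.index.has_duplicates:
            raise ValueError("duplicate locus ids")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(
                f"dosages contain values outside {{0,1,2,{MISSING}}}"
            )
        missing_cols = [c for c in LOCUS_COLUMNS if c not in self.loci.columns]
        if missing_cols:
            raise ValueError(f"loci metadata missing columns {missing_cols}")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.loci.index)

    def alt_allele_frequency(self) -> np.ndarray:
        """Unfolded alternate-allele frequency per locus over non-missing
        calls; NaN where every call is missing."""
        valid = self.dosages != MISSING
        denom = 2.0 * valid.sum(axis=0)
        alt = np.where(valid, self.dosages, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, alt / denom, np.nan)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per locus, folded to <= 0.5."""
        p = self.alt_allele_frequency()
        return np.minimum(p, 1.0 - p)

    def locus_missing_rate(self) -> np.ndarray:
        return (self.dosages == MISSING).mean(axis=0)

    # ------------------------------------------------------------------
    def take_loci(self, mask_or_ids) -> "GenotypeMatrix":
        """Subset loci by boolean mask (positional) or list of ids."""
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            pos = {lid: i for i, lid in enumerate(self.loci.index)}
            idx = np.array([pos[l] for l in mask_or_ids], dtype=int)
        return GenotypeMatrix(
            self.sample_ids, self.loci.iloc[idx], self.dosages[:, idx]
        )

    def take_samples(self, ids) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = np.array([pos[s] for s in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample id {e.args[0]!r}") from None
        return GenotypeMatrix([self.sample_ids[i] for i in idx],
                              self.loci, self.dosages[idx])

    # ------------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write the dosage matrix as TSV (rows = accessions, columns =
        locus ids, missing = ``NA``)."""
        df = pd.DataFrame(
            self.dosages.astype(object), index=self.sample_ids,
            columns=self.loci.index,
        )
        df[self.dosages == MISSING] = "NA"
        df.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        """Read a dosage TSV written by :meth:`to_tsv`.

        Locus metadata is reconstructed from ``chrom:pos:ref:alt`` ids
        where possible, otherwise filled with placeholders.
        """
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        dos = df.to_numpy(dtype=float)
        dos = np.where(np.isnan(dos), MISSING, dos).astype(np.int8)
        meta = []
        for lid in df.columns:
            parts = str(lid).split(":")
            if len(parts) == 4:
                chrom, pos, ref, alt = parts
                pos = int(pos)
            else:
                chrom, pos, ref, alt = "?", 0, "N", "N"
            is_snp = len(ref) == 1 and all(
                len(a) == 1 for a in alt.split(","))
            meta.append((chrom, pos, ref, alt, is_snp,
                         1 + len(alt.split(","))))
        loci = pd.DataFrame(meta, columns=LOCUS_COLUMNS,
                            index=pd.Index(df.columns, name="locus_id"))
        return cls([str(s) for s in df.index], loci, dos)


# ----------------------------------------------------------------------
def from_vcf(records, samples) -> GenotypeMatrix:
    """Build a dosage matrix from parsed VCF records.

    Dosage is the count of non-reference alleles in the diploid call;
    ``./.`` becomes :data:`MISSING`.  Haploid or higher-ploidy calls are
    rejected upstream at parse time.
    """
    n_s = len(samples)
    n_l = len(records)
    dos = np.empty((n_s, n_l), dtype=np.int8)
    meta = []
    ids = []
    for j, rec in enumerate(records):
        gt = rec.genotypes  # (n_samples, 2), -1 = missing allele
        missing = (gt < 0).any(axis=1)
        d = (gt > 0).sum(axis=1, dtype=np.int8)
        d[missing] = MISSING
        dos[:, j] = d
        alt = ",".join(rec.alts)
        is_snp = len(rec.ref) == 1 and all(len(a) == 1 for a in rec.alts)
        ids.append(rec.id or locus_id(rec.chrom, rec.pos, rec.ref, alt))
        meta.append((rec.chrom, rec.pos, rec.ref, alt, is_snp,
                     1 + len(rec.alts)))
    loci = pd.DataFrame(meta, columns=LOCUS_COLUMNS,
                        index=pd.Index(ids, name="locus_id"))
    return GenotypeMatrix(list(samples), loci, dos)


def site_filter(
    matrix: GenotypeMatrix,
    maf_min: float = 0.05,
    max_missing: float = 0.20,
    biallelic_snps_only: bool = True,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Population-genetics site filter.

    Retains loci with MAF >= ``maf_min`` (loci *below* the threshold are
    dropped, so MAF exactly at the threshold passes), missing rate
    <= ``max_missing`` (only rates *exceeding* the threshold drop, so a
    rate exactly at the bound passes), and — when ``biallelic_snps_only``
    is set — biallelic SNP status.  MAF and missingness are both computed
    on the input matrix in a single pass.

    Returns
    -------
    (filtered, audit)
        ``filtered`` is a new matrix; ``audit`` is a DataFrame indexed by
        dropped locus id with a ``reason`` column naming the first failing
        rule in the order ``maf``, ``missing``, ``biallelic``.  An
        undefined MAF (all calls missing) counts as a MAF failure.
    """
    maf = matrix.maf()
    miss = matrix.locus_missing_rate()
    fail_maf = ~(maf >= maf_min)  # NaN-safe: NaN fails
    fail_miss = miss > max_missing
    if biallelic_snps_only:
        fail_bi = ~(matrix.loci["is_snp"].to_numpy()
                    & (matrix.loci["n_alleles"].to_numpy() == 2))
    else:
        fail_bi = np.zeros(matrix.n_loci, dtype=bool)
    keep = ~(fail_maf | fail_miss | fail_bi)

    reason = np.where(fail_maf, "maf",
                      np.where(fail_miss, "missing", "biallelic"))
    audit = pd.DataFrame(
        {"reason": reason[~keep]},
        index=pd.Index(matrix.loci.index[~keep], name="locus_id"),
    )
    filtered = matrix.take_loci(keep)
    if filtered.n_loci == 0:
        logger.warning("site_filter removed every locus (%d dropped)",
                       int((~keep).sum()))
    return filtered, audit


def maf(matrix: GenotypeMatrix, locus: str) -> float:
    """MAF of one locus (alt-allele frequency over non-missing calls,
    folded to <= 0.5); NaN when every call is missing."""
    if locus not in matrix.loci.index:
        raise KeyError(f"unknown locus {locus!r}")
    j = matrix.loci.index.get_loc(locus)
    return float(matrix.maf()[j])
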