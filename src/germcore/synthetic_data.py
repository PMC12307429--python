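"""Synthetic genotype panels with known population structure.

Generates diploid genotype datasets with the statistical features the
downstream analyses assume — a configurable number of diverged
subpopulations (Balding–Nichols drift model), a bounded-missingness MAF
spectrum, a minority of InDels of varied lengths, and pairwise-distinct
accession genotypes — and writes them as VCF v4.2 so that every pipeline
stage can be exercised end to end without external data.

The generator is seeded and fully reproducible: the same config produces
byte-identical VCF output (the file-date header line is off by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_matrix import LOCUS_COLUMNS, MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))

#: Streams for per-purpose child RNGs derived from the config seed.
_STREAM_FREQ, _STREAM_GENO, _STREAM_META, _STREAM_INFO = range(4)


@dataclass(frozen=True)
class PopulationConfig:
    """Knobs of the synthetic germplasm panel.

    ``divergence`` is the Balding–Nichols drift parameter F in (0, 1):
    subpopulation allele frequencies are Beta-distributed around the
    ancestral frequency with variance ``F * p * (1 - p)``, so F is (to
    first order) the expected FST between subpopulations.
    ``admixture_fraction`` of accessions receive locus-wise mixed
    ancestry with a minority component drawn uniformly from [0, 0.3).
    """

    n_accessions: int = 100
    n_snps: int = 5000
    n_indels: int = 500
    n_subpops: int = 2
    divergence: float = 0.1
    admixture_fraction: float = 0.1
    maf_floor: float = 0.05
    missing_rate: float = 0.05
    indel_max_len: int = 30
    chrom_count: int = 8
    chrom_length: int = 2_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.divergence < 1.0):
            raise ValueError("divergence F must lie in (0, 1)")
        if not (0.0 <= self.missing_rate < 0.2):
            raise ValueError("missing_rate must lie in [0, 0.2)")
        if not (0.0 <= self.maf_floor <= 0.5):
            raise ValueError("maf_floor must lie in [0, 0.5]")
        if self.n_subpops < 1:
            raise ValueError("need at least one subpopulation")
        if self.n_accessions < 1 or self.n_snps + self.n_indels < 1:
            raise ValueError("population must be non-empty")

    @property
    def n_loci(self) -> int:
        return self.n_snps + self.n_indels

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=(int(self.seed), stream)))


@dataclass
class FrequencyTable:
    """Ancestral and per-subpopulation allele frequencies per locus."""

    ancestral: np.ndarray          # (n_loci,)
    subpop: np.ndarray             # (n_subpops, n_loci)

    def to_frame(self) -> pd.DataFrame:
        cols = {"ancestral": self.ancestral}
        for k in range(self.subpop.shape[0]):
            cols[f"subpop{k}"] = self.subpop[k]
        return pd.DataFrame(cols)


def simulate_frequencies(config: PopulationConfig) -> FrequencyTable:
    """Draw ancestral and subpopulation allele frequencies.

    Ancestral frequency p ~ U[maf_floor, 1 - maf_floor] per locus; each
    subpopulation frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F), i.e. mean p
    and variance F·p·(1-p) (the Balding–Nichols parameterization).
    """
    rng = config.rng(_STREAM_FREQ)
    f = config.divergence
    p = rng.uniform(config.maf_floor, 1.0 - config.maf_floor, config.n_loci)
    a = p * (1.0 - f) / f
    b = (1.0 - p) * (1.0 - f) / f
    sub = rng.beta(a, b, size=(config.n_subpops, config.n_loci))
    # keep frequencies strictly inside (0,1) so binomial draws stay sane
    sub = np.clip(sub, 1e-9, 1.0 - 1e-9)
    return FrequencyTable(ancestral=p, subpop=sub)


def subpopulation_labels(config: PopulationConfig) -> np.ndarray:
    """Balanced subpopulation assignment (truth labels), by accession
    index: accession i belongs to subpop ``i * k // n``."""
    n, k = config.n_accessions, config.n_subpops
    return (np.arange(n) * k) // n


def sample_ids(config: PopulationConfig) -> list[str]:
    labels = subpopulation_labels(config)
    width = len(str(config.n_accessions))
    return [f"P{labels[i] + 1}_{i + 1:0{width}d}"
            for i in range(config.n_accessions)]


def _locus_metadata(config: PopulationConfig) -> pd.DataFrame:
    """Chromosome/position/allele metadata, sorted by (chrom, pos)."""
    rng = config.rng(_STREAM_META)
    L = config.n_loci
    chrom_idx = rng.integers(0, config.chrom_count, L)
    pos = np.empty(L, dtype=np.int64)
    for c in range(config.chrom_count):
        m = chrom_idx == c
        pos[m] = np.sort(
            rng.choice(config.chrom_length, m.sum(), replace=False) + 1)
    is_indel = np.zeros(L, dtype=bool)
    if config.n_indels:
        is_indel[rng.choice(L, config.n_indels, replace=False)] = True

    refs, alts = [], []
    for j in range(L):
        base = str(rng.choice(BASES))
        if not is_indel[j]:
            alt = str(rng.choice(BASES[BASES != base]))
            refs.append(base)
            alts.append(alt)
        else:
            length = int(rng.integers(1, config.indel_max_len + 1))
            tail = "".join(rng.choice(BASES, length))
            if rng.random() < 0.5:  # deletion
                refs.append(base + tail)
                alts.append(base)
            else:                   # insertion
                refs.append(base)
                alts.append(base + tail)

    order = np.lexsort((pos, chrom_idx))
    chrom = np.array([f"chr{c + 1}" for c in chrom_idx])
    ids = [f"{chrom[j]}:{pos[j]}:{refs[j]}:{alts[j]}" for j in order]
    df = pd.DataFrame(
        {
            "chrom": chrom[order],
            "pos": pos[order],
            "ref": np.array(refs, dtype=object)[order],
            "alt": np.array(alts, dtype=object)[order],
            "is_snp": ~is_indel[order],
            "n_alleles": 2,
        },
        index=pd.Index(ids, name="locus_id"),
    )
    assert list(df.columns) == list(LOCUS_COLUMNS)
    df.attrs["order"] = order  # original-locus -> sorted-row mapping
    return df


def simulate_genotypes(
    frequencies: FrequencyTable,
    config: PopulationConfig,
    max_retries: int = 20,
) -> GenotypeMatrix:
    """Draw the diploid dosage matrix from subpopulation frequencies.

    Accessions are split evenly across subpopulations; an
    ``admixture_fraction`` share (chosen at random) gets per-locus mixed
    ancestry with a minority weight ~ U[0, 0.3).  Dosages are
    Binomial(2, freq); missingness is injected independently per call.
    Duplicate genotype rows are re-drawn (the fingerprinting stage needs
    pairwise-distinct accessions); if distinctness cannot be reached in
    ``max_retries`` redraw rounds the config is degenerate and a
    ``RuntimeError`` is raised.
    """
    rng = config.rng(_STREAM_GENO)
    n, k, L = config.n_accessions, config.n_subpops, config.n_loci
    labels = subpopulation_labels(config)
    n_adm = int(round(config.admixture_fraction * n))
    admixed = rng.choice(n, n_adm, replace=False) if n_adm else np.array([], int)
    minority = rng.uniform(0.0, 0.3, n_adm)

    def draw_row(i: int) -> np.ndarray:
        own = labels[i]
        freq = frequencies.subpop[own].copy()
        adm_pos = np.flatnonzero(admixed == i)
        if adm_pos.size and k > 1:
            theta = minority[adm_pos[0]]
            foreign = rng.random(L) < theta
            others = [s for s in range(k) if s != own]
            src = rng.choice(others, L)
            freq[foreign] = frequencies.subpop[src[foreign], foreign]
        dos = rng.binomial(2, freq).astype(np.int8)
        if config.missing_rate > 0:
            dos[rng.random(L) < config.missing_rate] = MISSING
        return dos

    dosages = np.vstack([draw_row(i) for i in range(n)])

    for attempt in range(max_retries):
        _, inverse, counts = np.unique(
            dosages, axis=0, return_inverse=True, return_counts=True)
        if (counts == 1).all():
            break
        dup_rows = []
        seen: set[int] = set()
        for i in range(n):
            g = int(inverse[i])
            if counts[g] > 1:
                if g in seen:
                    dup_rows.append(i)   # keep the first of each group
                seen.add(g)
        for i in dup_rows:
            dosages[i] = draw_row(i)
    else:
        raise RuntimeError(
            "could not make accession genotypes pairwise distinct after "
            f"{max_retries} redraw rounds — degenerate configuration "
            "(too few loci or too little diversity)"
        )

    meta = _locus_metadata(config)
    order = meta.attrs["order"]
    return GenotypeMatrix(sample_ids(config), meta, dosages[:, order])


# ----------------------------------------------------------------------
# INFO annotation mixtures: uniform ranges bracketing the hard-filter
# thresholds, one pass range (satisfies both SNP and InDel expressions)
# and one fail range per clause and kind.
_PASS_RANGES = {
    "QD": (5.0, 35.0),
    "QUAL": (50.0, 1500.0),
    "SOR": (0.3, 2.5),
    "FS": (0.0, 25.0),
    "MQ": (45.0, 60.0),
    "MQRankSum": (-3.0, 3.0),
    "ReadPosRankSum": (-3.0, 3.0),
}
_FAIL_RANGES = {
    "snp": {
        "QD": (0.0, 1.9),
        "QUAL": (0.0, 29.0),
        "SOR": (3.5, 9.0),
        "FS": (70.0, 150.0),
        "MQ": (10.0, 39.0),
        "MQRankSum": (-25.0, -13.0),
        "ReadPosRankSum": (-12.0, -8.5),
    },
    "indel": {
        "QD": (0.0, 1.9),
        "QUAL": (0.0, 29.0),
        "FS": (210.0, 400.0),
        "MQ": (10.0, 39.0),
        "ReadPosRankSum": (-30.0, -20.5),
    },
}

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    genotypes: GenotypeMatrix,
    config: PopulationConfig,
    path,
    fail_fraction: float = 0.0,
    fail_clauses=None,
    timestamp: bool = False,
) -> pd.DataFrame:
    """Write the panel as VCF v4.2 with synthetic filter annotations.

    A ``fail_fraction`` share of records (chosen at random) is assigned
    one failing INFO/QUAL value — drawn from a uniform range beyond its
    kind's hard-filter threshold — while everything else is drawn from
    pass ranges, so downstream filter results have known truth.
    ``fail_clauses`` restricts which clauses may be chosen to fail (e.g.
    ``["QD"]``).  With ``timestamp=False`` (default) output is
    byte-deterministic for a given config.

    Returns the truth table: locus_id, kind, expected_pass and the
    assigned failing clause (empty string for passing records).
    """
    rng = config.rng(_STREAM_INFO)
    loci = genotypes.loci
    L = len(loci)
    is_snp = loci["is_snp"].to_numpy()
    kinds = np.where(is_snp, "snp", "indel")

    n_fail = int(round(fail_fraction * L))
    fail_idx = set(rng.choice(L, n_fail, replace=False).tolist()) if n_fail else set()

    fields = list(_PASS_RANGES)
    rows = []
    lines = []
    for j, (lid, meta) in enumerate(loci.iterrows()):
        kind = kinds[j]
        clause_pool = [c for c in _FAIL_RANGES[kind]
                       if fail_clauses is None or c in fail_clauses]
        values = {f: rng.uniform(*_PASS_RANGES[f]) for f in fields}
        failing = ""
        if j in fail_idx and clause_pool:
            failing = clause_pool[int(rng.integers(len(clause_pool)))]
            values[failing] = rng.uniform(*_FAIL_RANGES[kind][failing])
        qual = values.pop("QUAL")
        info = ";".join(f"{k}={values[k]:.3f}" for k in values)
        gts = "\t".join(_GT_STRINGS[int(d)] for d in genotypes.dosages[:, j])
        lines.append(
            f"{meta['chrom']}\t{meta['pos']}\t{lid}\t{meta['ref']}\t"
            f"{meta['alt']}\t{qual:.2f}\t.\t{info}\tGT\t{gts}"
        )
        rows.append((lid, kind, failing == "", failing))

    header = ["##fileformat=VCFv4.2"]
    if timestamp:
        import datetime

        header.append(
            "##fileDate=" + datetime.date.today().strftime("%Y%m%d"))
    header.append("##source=germcore.synthetic_data")
    for c in range(config.chrom_count):
        header.append(
            f"##contig=<ID=chr{c + 1},length={config.chrom_length}>")
    for key in ("QD", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum"):
        header.append(
            f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">')
    header.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(genotypes.sample_ids))

    try:
        with open(path, "w") as fh:
            fh.write("\n".join(header + lines) + "\n")
    except OSError as e:
        raise OSError(f"cannot write VCF to {path}: {e}") from e

    truth = pd.DataFrame(
        rows, columns=["locus_id", "kind", "expected_pass", "failed_clause"]
    ).set_index("locus_id")
    return truth


def simulate_panel(config: PopulationConfig) -> GenotypeMatrix:
    """Convenience: frequencies + genotypes in one call."""
    return simulate_genotypes(simulate_frequencies(config), config)


__all__ = [
    "PopulationConfig",
    "FrequencyTable",
    "simulate_frequencies",
    "simulate_genotypes",
    "simulate_panel",
    "subpopulation_labels",
    "sample_ids",
    "write_vcf",
]
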