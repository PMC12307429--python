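"""VCF input, hard-filter expressions and variant summary statistics.

Reading goes through :mod:`cyvcf2`; records are materialized into a small
:class:`VariantRecord` so downstream code never touches the htslib handle.
The hard filters are the standard GATK-style per-kind expressions used for
plant reduced-representation panels:

* SNP:   ``QD < 2.0 || QUAL < 30.0 || SOR > 3.0 || FS > 60.0 || MQ < 40.0
  || MQRankSum < -12.5 || ReadPosRankSum < -8.0``
* InDel: ``QD < 2.0 || QUAL < 30.0 || FS > 200.0 || MQ < 40.0
  || ReadPosRankSum < -20.0``

A record fails when *any* clause of its kind-specific expression is true;
clauses whose annotation is absent are skipped (they cannot fail), which
matches VariantFiltration's treatment of missing rank-sum annotations.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

INFO_KEYS = ("QD", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum")

#: clause name -> (annotation, comparator, threshold); "QUAL" reads the
#: QUAL column, everything else the INFO field of the same name.
SNP_FILTER: dict[str, tuple[str, object, float]] = {
    "QD": ("QD", operator.lt, 2.0),
    "QUAL": ("QUAL", operator.lt, 30.0),
    "SOR": ("SOR", operator.gt, 3.0),
    "FS": ("FS", operator.gt, 60.0),
    "MQ": ("MQ", operator.lt, 40.0),
    "MQRankSum": ("MQRankSum", operator.lt, -12.5),
    "ReadPosRankSum": ("ReadPosRankSum", operator.lt, -8.0),
}
INDEL_FILTER: dict[str, tuple[str, object, float]] = {
    "QD": ("QD", operator.lt, 2.0),
    "QUAL": ("QUAL", operator.lt, 30.0),
    "FS": ("FS", operator.gt, 200.0),
    "MQ": ("MQ", operator.lt, 40.0),
    "ReadPosRankSum": ("ReadPosRankSum", operator.lt, -20.0),
}

TRANSITIONS = frozenset({frozenset("AG"), frozenset("CT")})

SUBSTITUTION_CLASSES = ("A/G", "C/T", "A/C", "A/T", "C/G", "G/T")


class VcfParseError(ValueError):
    """Malformed VCF input; message carries path and record context."""


@dataclass
class VariantRecord:
    """One VCF site: alleles, filter annotations, per-sample diploid calls.

    ``genotypes`` is an ``(n_samples, 2)`` int8 array of allele indices
    with ``-1`` marking a missing allele.  ``info`` holds only the keys
    actually present in the record — an absent annotation is absent, never
    zero.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float | None
    info: dict[str, float]
    genotypes: np.ndarray = field(repr=False)
    id: str | None = None

    def __post_init__(self) -> None:
        self.alts = tuple(self.alts)
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref:
            raise ValueError("empty REF allele")
        if not self.alts:
            raise ValueError("record needs at least one ALT allele")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != 2:
            raise ValueError("genotypes must be (n_samples, 2)")
        if self.genotypes.max(initial=-1) > len(self.alts):
            raise ValueError("allele index out of range")

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    @property
    def is_biallelic_snp(self) -> bool:
        return (len(self.alts) == 1 and len(self.ref) == 1
                and len(self.alts[0]) == 1)


def iter_vcf(path):
    """Yield :class:`VariantRecord` objects from a VCF in file order.

    Raises :class:`VcfParseError` on malformed input, naming the file and
    the failing record.  Use :func:`read_vcf` for the materialized list.
    """
    import cyvcf2

    path = str(path)
    try:
        vcf = cyvcf2.VCF(path)
    except Exception as e:
        raise VcfParseError(f"{path}: cannot parse VCF header: {e}") from e
    try:
        for i, v in enumerate(vcf, start=1):
            info = {}
            for k in INFO_KEYS:
                val = v.INFO.get(k)
                if val is not None:
                    info[k] = float(val)
            gts = np.full((len(vcf.samples), 2), -1, dtype=np.int8)
            for s, call in enumerate(v.genotypes):
                alleles = call[:-1]  # trailing element is the phased flag
                if len(alleles) != 2:
                    raise VcfParseError(
                        f"{path}: record {i} ({v.CHROM}:{v.POS}): "
                        f"non-diploid call of ploidy {len(alleles)}"
                    )
                gts[s] = alleles
            yield VariantRecord(
                chrom=v.CHROM, pos=v.POS, ref=v.REF, alts=tuple(v.ALT),
                qual=None if v.QUAL is None else float(v.QUAL),
                info=info, genotypes=gts,
                id=None if v.ID in (None, ".") else v.ID,
            )
    except VcfParseError:
        raise
    except Exception as e:
        raise VcfParseError(f"{path}: malformed record: {e}") from e


def read_vcf(path) -> tuple[list[str], list[VariantRecord]]:
    """Read a whole VCF; returns ``(sample_names, records)``."""
    import cyvcf2

    try:
        samples = list(cyvcf2.VCF(str(path)).samples)
    except Exception as e:
        raise VcfParseError(f"{path}: cannot parse VCF header: {e}") from e
    return samples, list(iter_vcf(path))


def write_vcf_subset(in_path, keep_ids, out_path) -> int:
    """Copy a VCF keeping only records whose ID (or chrom:pos:ref:alt) is
    in ``keep_ids``; returns the number of records written."""
    import cyvcf2

    keep = set(keep_ids)
    vcf = cyvcf2.VCF(str(in_path))
    n = 0
    with open(out_path, "w") as out:
        out.write(vcf.raw_header)
        for v in vcf:
            key = v.ID if v.ID not in (None, ".") else (
                f"{v.CHROM}:{v.POS}:{v.REF}:{','.join(v.ALT)}")
            if key in keep:
                out.write(str(v))
                n += 1
    return n


# ----------------------------------------------------------------------
def classify_variant(record: VariantRecord) -> str:
    """Classify a record as ``snp``, ``insertion``, ``deletion`` or
    ``mixed``.

    SNP: ref and every alt of length 1.  Insertion / deletion: every alt
    strictly longer / shorter than ref.  Anything else (e.g. a SNP alt
    alongside an InDel alt) is ``mixed`` and is excluded from both SNP
    and InDel bookkeeping downstream.
    """
    lr = len(record.ref)
    lens = [len(a) for a in record.alts]
    if lr == 1 and all(l == 1 for l in lens):
        return "snp"
    if all(l > lr for l in lens):
        return "insertion"
    if all(l < lr for l in lens):
        return "deletion"
    return "mixed"


def ti_tv(record: VariantRecord) -> str:
    """``transition`` (A<->G, C<->T) or ``transversion`` for a biallelic
    SNP record; anything else is rejected."""
    if not record.is_biallelic_snp:
        raise ValueError(
            f"Ti/Tv is defined on biallelic SNPs only "
            f"({record.chrom}:{record.pos} is not one)"
        )
    pair = frozenset({record.ref.upper(), record.alts[0].upper()})
    return "transition" if pair in TRANSITIONS else "transversion"


@dataclass
class FilterResult:
    passed: bool
    failed_clauses: list[str]


def apply_hard_filters(record: VariantRecord, kind: str) -> FilterResult:
    """Evaluate the kind-specific hard-filter expression on one record.

    ``kind`` is ``"snp"`` or ``"indel"`` (the caller classifies).  All
    thresholds are strict inequalities exactly as printed in the
    expressions above, so e.g. QD == 2.0 passes.  Absent annotations are
    skipped — they never fail a clause.
    """
    kind = kind.lower()
    if kind == "snp":
        clauses = SNP_FILTER
    elif kind == "indel":
        clauses = INDEL_FILTER
    else:
        raise ValueError(f"unknown variant kind {kind!r}")
    failed = []
    for name, (key, cmp, thr) in clauses.items():
        value = record.qual if key == "QUAL" else record.info.get(key)
        if value is None:
            continue
        if cmp(value, thr):
            failed.append(name)
    return FilterResult(passed=not failed, failed_clauses=failed)


# ----------------------------------------------------------------------
INDEL_BINS = tuple(str(i) for i in range(1, 11)) + (">10",)


@dataclass
class VariantSummary:
    """Figure-1-style summary of a classified variant set."""

    snp_count: int
    insertion_count: int
    deletion_count: int
    mixed_count: int
    biallelic_fraction: float
    allele_count_histogram: dict[int, int]
    ti_count: int
    tv_count: int
    ti_tv_ratio: float | None
    substitution_type_fractions: dict[str, float]
    indel_length_histogram: dict[str, int]
    per_chromosome_counts: dict[str, int]
    per_chromosome_density_kb: dict[str, float] | None

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["allele_count_histogram"] = {
            str(k): v for k, v in self.allele_count_histogram.items()}
        return d


def _indel_bin(length: int) -> str:
    return str(length) if length <= 10 else ">10"


def summarize_variants(records, chromosome_lengths=None) -> VariantSummary:
    """Counts, Ti/Tv, substitution spectrum, InDel length histogram and
    per-chromosome densities over an iterable of records.

    Ti/Tv and the six-class substitution spectrum are computed on
    biallelic SNPs only; multiallelic SNPs still count toward
    ``biallelic_fraction`` and the allele-count histogram.  InDel lengths
    are ``|len(alt) - len(ref)|`` of the first alt, binned 1..10 and
    ">10"; one histogram entry per insertion/deletion record.  A zero
    transversion count yields ``ti_tv_ratio = None``, never infinity.
    ``chromosome_lengths`` (bases) enables per-kb densities.
    """
    counts = {"snp": 0, "insertion": 0, "deletion": 0, "mixed": 0}
    allele_hist: dict[int, int] = {}
    ti = tv = 0
    subst = {c: 0 for c in SUBSTITUTION_CLASSES}
    indel_hist = {b: 0 for b in INDEL_BINS}
    per_chrom: dict[str, int] = {}
    n_total = 0
    n_biallelic = 0
    for rec in records:
        n_total += 1
        cls = classify_variant(rec)
        counts[cls] += 1
        allele_hist[rec.n_alleles] = allele_hist.get(rec.n_alleles, 0) + 1
        if rec.n_alleles == 2:
            n_biallelic += 1
        per_chrom[rec.chrom] = per_chrom.get(rec.chrom, 0) + 1
        if cls == "snp" and rec.is_biallelic_snp:
            kind = ti_tv(rec)
            if kind == "transition":
                ti += 1
            else:
                tv += 1
            key = "/".join(sorted((rec.ref.upper(), rec.alts[0].upper())))
            if key in subst:
                subst[key] += 1
        elif cls in ("insertion", "deletion"):
            indel_hist[_indel_bin(abs(len(rec.alts[0]) - len(rec.ref)))] += 1

    n_snp_bi = ti + tv
    fractions = {c: (subst[c] / n_snp_bi if n_snp_bi else 0.0)
                 for c in SUBSTITUTION_CLASSES}
    density = None
    if chromosome_lengths is not None:
        density = {
            c: per_chrom.get(c, 0) / (length / 1000.0)
            for c, length in chromosome_lengths.items()
        }
    return VariantSummary(
        snp_count=counts["snp"],
        insertion_count=counts["insertion"],
        deletion_count=counts["deletion"],
        mixed_count=counts["mixed"],
        biallelic_fraction=(n_biallelic / n_total if n_total else 0.0),
        allele_count_histogram=dict(sorted(allele_hist.items())),
        ti_count=ti,
        tv_count=tv,
        ti_tv_ratio=(ti / tv if tv else None),
        substitution_type_fractions=fractions,
        indel_length_histogram=indel_hist,
        per_chromosome_counts=dict(sorted(per_chrom.items())),
        per_chromosome_density_kb=density,
    )


def read_chromosome_lengths(path) -> dict[str, int]:
    """Two-column TSV (chrom, length in bases) -> dict."""
    lengths = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        chrom, length = line.split("\t")[:2]
        lengths[chrom] = int(length)
    return lengths
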