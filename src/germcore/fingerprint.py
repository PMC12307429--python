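"""Minimal discriminating SNP panels for DNA fingerprinting.

Starting from zero-missing biallelic candidate SNPs, select a small locus
subset at which every pair of accessions differs in at least one genotype
class, giving each accession a unique code string ('A' = homozygous
reference, 'H' = heterozygous, 'B' = homozygous alternate).

Selection is a minimum set cover over accession pairs.  Three routes are
provided: a genetic algorithm (bitmask individuals, tournament selection,
uniform crossover, per-bit mutation, elitism, followed by a repair step
and a pruning pass that removes every single-locus redundancy), a greedy
set-cover baseline, and exhaustive enumeration for small instances.  Pair
resolution is evaluated on bit-packed pair-difference masks, so a fitness
evaluation is a handful of vectorized OR/popcount operations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_matrix import GenotypeMatrix

logger = logging.getLogger(__name__)

CODE = {0: "A", 1: "H", 2: "B"}


class UnresolvableAccessionsError(ValueError):
    """No discriminating set exists: some accessions are identical over
    the candidate loci.  Carries the offending pairs."""

    def __init__(self, pairs: list[tuple[str, str]]):
        self.pairs = pairs
        shown = ", ".join(f"{a}~{b}" for a, b in pairs[:5])
        more = "" if len(pairs) <= 5 else f" (+{len(pairs) - 5} more)"
        super().__init__(
            f"{len(pairs)} accession pair(s) share identical genotypes "
            f"over all candidate loci: {shown}{more}"
        )


@dataclass(frozen=True)
class GaParams:
    """Genetic-algorithm hyperparameters (all standard-GA knobs).

    ``mutation_rate`` and ``size_penalty`` default to ``1/n_candidates``
    when left as None.  The size penalty is small enough that any fully
    discriminating panel dominates any non-discriminating one.
    """

    population_size: int = 200
    generations: int = 300
    crossover_rate: float = 0.9
    mutation_rate: float | None = None
    tournament_size: int = 3
    elitism: int = 2
    size_penalty: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("crossover_rate",):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mutation_rate is not None and not (0 <= self.mutation_rate <= 1):
            raise ValueError("mutation_rate must lie in [0, 1]")


@dataclass
class FingerprintPanel:
    """A selected marker panel plus per-accession fingerprint codes."""

    loci: list[str]
    codes: dict[str, str]            # accession -> code string
    resolved_fraction: float
    method: str
    ga_generations: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.resolved_fraction >= 1.0:
            values = list(self.codes.values())
            if len(set(values)) != len(values):
                raise ValueError(
                    "fully resolving panel must yield distinct codes")


# ----------------------------------------------------------------------
def candidate_filter(matrix: GenotypeMatrix) -> list[str]:
    """Fingerprint candidate loci: biallelic SNPs with MAF >= 0.05 and a
    genotype missing rate of exactly zero."""
    maf = matrix.maf()
    miss = matrix.locus_missing_rate()
    bi = (matrix.loci["is_snp"].to_numpy()
          & (matrix.loci["n_alleles"].to_numpy() == 2))
    keep = bi & (miss == 0.0) & (maf >= 0.05)
    out = list(matrix.loci.index[keep])
    if not out:
        raise ValueError(
            "no fingerprint candidates (need biallelic SNPs with "
            "MAF >= 0.05 and zero missing calls) — provide a larger or "
            "less sparse input"
        )
    return out


def _pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu[0], iu[1]


def _pair_masks(matrix: GenotypeMatrix, candidates) -> np.ndarray:
    """Bit-packed pair-difference masks, one row per candidate locus.

    Bit p of row l is set when accession pair p differs at locus l.
    Rows are packed uint8, ``ceil(n_pairs / 8)`` bytes wide.
    """
    sub = matrix.take_loci(list(candidates))
    i_idx, j_idx = _pair_index(matrix.n_samples)
    diff = sub.dosages[i_idx] != sub.dosages[j_idx]   # (n_pairs, n_cand)
    return np.packbits(diff.T, axis=1)


def _popcount(mask: np.ndarray) -> int:
    return int(np.bitwise_count(mask).sum())


def resolved_pairs(matrix: GenotypeMatrix, locus_subset) -> tuple[int, int]:
    """Count accession pairs distinguished by a locus subset.

    A pair is resolved when its dosage vectors over the subset differ at
    one or more loci; returns ``(resolved, total_pairs)``.
    """
    subset = list(locus_subset)
    if not subset:
        raise ValueError("empty locus subset")
    masks = _pair_masks(matrix, subset)
    n = matrix.n_samples
    total = n * (n - 1) // 2
    return _popcount(np.bitwise_or.reduce(masks, axis=0)), total


def _unresolved_pair_names(matrix, candidates) -> list[tuple[str, str]]:
    masks = _pair_masks(matrix, candidates)
    union = np.bitwise_or.reduce(masks, axis=0)
    bits = np.unpackbits(union)
    i_idx, j_idx = _pair_index(matrix.n_samples)
    out = []
    for p in np.flatnonzero(bits[: len(i_idx)] == 0):
        out.append((matrix.sample_ids[i_idx[p]], matrix.sample_ids[j_idx[p]]))
    return out


def _prune(masks: np.ndarray, panel: list[int], full: np.ndarray) -> list[int]:
    """Drop every locus whose removal keeps the panel fully resolving.

    Repeated sweeps in ascending locus order until stable; the result has
    no single-locus redundancy.
    """
    panel = sorted(panel)
    changed = True
    while changed and len(panel) > 1:
        changed = False
        for locus in list(panel):
            rest = [l for l in panel if l != locus]
            union = np.bitwise_or.reduce(masks[rest], axis=0)
            if np.array_equal(union, full):
                panel = rest
                changed = True
    return panel


def _greedy_indices(masks: np.ndarray, full: np.ndarray) -> list[int]:
    """Greedy set cover on pair-difference masks (tie -> smallest index)."""
    uncovered = full.copy()
    panel: list[int] = []
    while uncovered.any():
        gains = np.bitwise_count(masks & uncovered).sum(axis=1)
        best = int(np.argmax(gains))
        if gains[best] == 0:  # pragma: no cover - caller checks solvability
            break
        panel.append(best)
        uncovered &= ~masks[best]
    return panel


def _check_solvable(matrix, candidates, masks) -> np.ndarray:
    """Full-coverage target mask; raises when accessions are identical."""
    n = matrix.n_samples
    n_pairs = n * (n - 1) // 2
    full = np.packbits(np.ones(n_pairs, dtype=np.uint8))
    union = np.bitwise_or.reduce(masks, axis=0)
    if not np.array_equal(union, full):
        raise UnresolvableAccessionsError(
            _unresolved_pair_names(matrix, candidates))
    return full


def _make_panel(matrix, candidates, panel_idx, method, seed=None,
                generations=None) -> FingerprintPanel:
    loci = [candidates[i] for i in sorted(panel_idx)]
    resolved, total = resolved_pairs(matrix, loci)
    sub = matrix.take_loci(loci)
    codes = {
        s: "".join(CODE[int(d)] for d in sub.dosages[i])
        for i, s in enumerate(matrix.sample_ids)
    }
    return FingerprintPanel(
        loci=loci, codes=codes, resolved_fraction=resolved / total,
        method=method, ga_generations=generations, seed=seed,
    )


# ----------------------------------------------------------------------
def greedy_select(matrix: GenotypeMatrix, candidates) -> FingerprintPanel:
    """Greedy set-cover panel: repeatedly add the locus resolving the most
    still-unresolved pairs, then prune single-locus redundancies."""
    candidates = list(candidates)
    masks = _pair_masks(matrix, candidates)
    full = _check_solvable(matrix, candidates, masks)
    panel = _greedy_indices(masks, full)
    panel = _prune(masks, panel, full)
    return _make_panel(matrix, candidates, panel, "greedy")


def ga_select(
    matrix: GenotypeMatrix, candidates, params: GaParams | None = None
) -> FingerprintPanel:
    """Genetic-algorithm panel selection.

    Individuals are bitmasks over the candidate loci with fitness
    ``resolved_fraction - size_penalty * panel_size``.  Tournament
    selection, uniform crossover, per-bit mutation and elitism; the run
    stops early after 80 generations without best-fitness improvement.
    The best individual is repaired (greedy completion) if it is not
    fully discriminating, then pruned, so the returned panel always
    resolves every pair whenever a discriminating set exists.
    """
    params = params or GaParams()
    candidates = list(candidates)
    n_cand = len(candidates)
    masks = _pair_masks(matrix, candidates)
    full = _check_solvable(matrix, candidates, masks)
    n = matrix.n_samples
    total_pairs = n * (n - 1) // 2
    mut = params.mutation_rate if params.mutation_rate is not None \
        else 1.0 / n_cand
    lam = params.size_penalty if params.size_penalty is not None \
        else 1.0 / n_cand

    rng = np.random.default_rng(params.seed)
    pop_size = params.population_size
    init_p = min(0.5, max(4.0, 0.03 * n_cand) / n_cand)
    pop = rng.random((pop_size, n_cand)) < init_p

    def fitness(rows: np.ndarray) -> np.ndarray:
        out = np.empty(len(rows))
        for i, row in enumerate(rows):
            sel = np.flatnonzero(row)
            if sel.size == 0:
                out[i] = -1.0
                continue
            union = np.bitwise_or.reduce(masks[sel], axis=0)
            out[i] = (np.bitwise_count(union).sum() / total_pairs
                      - lam * sel.size)
        return out

    fit = fitness(pop)
    best_fit = -np.inf
    best_row = pop[0]
    stall = 0
    gens_used = 0
    for gen in range(params.generations):
        gens_used = gen + 1
        top = int(np.argmax(fit))
        if fit[top] > best_fit + 1e-12:
            best_fit = fit[top]
            best_row = pop[top].copy()
            stall = 0
        else:
            stall += 1
            if stall >= 80:
                break
        elite_idx = np.argsort(fit)[::-1][: params.elitism]
        n_children = pop_size - params.elitism
        # tournament selection for both parent slots
        t = rng.integers(0, pop_size, (2, n_children, params.tournament_size))
        winners = np.take_along_axis(
            t, np.argmax(fit[t], axis=2)[..., None], axis=2)[..., 0]
        p1, p2 = pop[winners[0]], pop[winners[1]]
        cross = rng.random(n_children) < params.crossover_rate
        mask = rng.random((n_children, n_cand)) < 0.5
        children = np.where(cross[:, None] & mask, p2, p1)
        flip = rng.random((n_children, n_cand)) < mut
        children ^= flip
        pop = np.vstack([pop[elite_idx], children])
        fit = np.concatenate([fit[elite_idx], fitness(children)])

    # repair: greedily complete a non-discriminating best individual
    panel = list(np.flatnonzero(best_row))
    union = (np.bitwise_or.reduce(masks[panel], axis=0) if panel
             else np.zeros_like(full))
    if not np.array_equal(union & full, full):
        uncovered = full & ~union
        while uncovered.any():
            gains = np.bitwise_count(masks & uncovered).sum(axis=1)
            gains[panel] = 0
            best = int(np.argmax(gains))
            panel.append(best)
            uncovered &= ~masks[best]
    panel = _prune(masks, panel, full)
    return _make_panel(matrix, candidates, panel, "ga",
                       seed=params.seed, generations=gens_used)


def exhaustive_min(matrix: GenotypeMatrix, candidates,
                   max_candidates: int = 20) -> FingerprintPanel:
    """Smallest discriminating panel by increasing-size enumeration.

    Guarded to ``max_candidates`` (default 20) candidate loci; among
    equal-size solutions the lexicographically smallest locus-index tuple
    wins (enumeration order).  Raises
    :class:`UnresolvableAccessionsError` when no panel can work.
    """
    candidates = list(candidates)
    if len(candidates) > max_candidates:
        raise ValueError(
            f"exhaustive search guarded to {max_candidates} candidates, "
            f"got {len(candidates)}"
        )
    n = matrix.n_samples
    n_pairs = n * (n - 1) // 2
    packed = _pair_masks(matrix, candidates)
    ints = [int.from_bytes(row.tobytes(), "big") for row in packed]
    full = int.from_bytes(
        np.packbits(np.ones(n_pairs, dtype=np.uint8)).tobytes(), "big")
    union_all = 0
    for v in ints:
        union_all |= v
    if union_all != full:
        raise UnresolvableAccessionsError(
            _unresolved_pair_names(matrix, candidates))
    for k in range(1, len(candidates) + 1):
        for combo in itertools.combinations(range(len(candidates)), k):
            acc = 0
            for c in combo:
                acc |= ints[c]
                if acc == full:
                    break
            if acc == full:
                return _make_panel(matrix, candidates, list(combo),
                                   "exhaustive")
    raise AssertionError("unreachable: union covers all pairs")


# ----------------------------------------------------------------------
def fingerprint_table(matrix: GenotypeMatrix,
                      panel: FingerprintPanel) -> pd.DataFrame:
    """Fingerprint matrix: rows = panel loci, columns = accessions, cells
    = genotype code letters ('A'/'H'/'B')."""
    missing = [l for l in panel.loci if l not in matrix.loci.index]
    if missing:
        raise KeyError(f"panel loci absent from matrix: {missing[:5]}")
    sub = matrix.take_loci(panel.loci)
    data = np.empty((len(panel.loci), matrix.n_samples), dtype=object)
    for j in range(len(panel.loci)):
        for i in range(matrix.n_samples):
            data[j, i] = CODE[int(sub.dosages[i, j])]
    return pd.DataFrame(data, index=panel.loci, columns=matrix.sample_ids)


def plot_fingerprint(table: pd.DataFrame, path) -> None:
    """Categorical heatmap of a fingerprint table (one color per genotype
    class), written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    level = table.replace({"A": 0, "H": 1, "B": 2}).to_numpy(dtype=float)
    fig, ax = plt.subplots(
        figsize=(max(6, table.shape[1] * 0.12), max(3, table.shape[0] * 0.3)))
    cmap = ListedColormap(["#4c72b0", "#dd8452", "#55a868"])
    ax.imshow(level, aspect="auto", cmap=cmap, vmin=0, vmax=2)
    ax.set_yticks(range(table.shape[0]), table.index, fontsize=6)
    ax.set_xlabel("accession")
    ax.set_title("SNP fingerprint (A=ref hom, H=het, B=alt hom)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
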