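"""Population structure: genetic distances, NJ tree, GRM and PCA.

The distance is the normalized mean squared dosage difference,
``d(i,j) = mean_l ((g_il - g_jl)/2)^2`` over loci non-missing in both
samples, which is bounded in [0, 1] and monotone in allele sharing.
Neighbor joining is the Saitou–Nei agglomeration with the
Studier–Keppler Q criterion; the genomic relationship matrix follows the
GCTA/VanRaden standardized-genotype cross-product and feeds an
eigen-decomposition PCA.

Trees are :class:`dendropy.Tree` objects (unrooted), so Newick IO,
bipartition encoding and tree comparison come from dendropy; the NJ
agglomeration itself is implemented here because the tie-breaking and
branch-length clamping rules are part of this package's contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import scipy.linalg

from .genotype_matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Pairwise genetic distances with per-pair locus counts."""

    sample_ids: list[str]
    values: np.ndarray = field(repr=False)
    pair_loci: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)


def _pairwise_squared(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Core distance kernel on an int dosage array with MISSING sentinel.

    Returns ``(distances, shared-locus counts)``; pairs sharing no locus
    get NaN distance (caller decides whether that is an error).
    """
    valid = dosages != MISSING
    a = np.where(valid, dosages, 0).astype(np.float64)
    m = valid.astype(np.float64)
    counts = m @ m.T
    cross = a @ a.T
    sq = (a * a) @ m.T
    num = sq + sq.T - 2.0 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(counts > 0, num / (4.0 * counts), np.nan)
    np.fill_diagonal(d, 0.0)
    # exact symmetry despite float summation order
    d = (d + d.T) / 2.0
    return d, counts


def squared_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Normalized mean squared dosage distance between all sample pairs.

    Loci missing in either member of a pair are excluded from that
    pair's mean; a pair with no shared non-missing locus is an error
    naming the pair.
    """
    d, counts = _pairwise_squared(matrix.dosages)
    bad = np.argwhere(np.isnan(d))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"samples {matrix.sample_ids[i]!r} and {matrix.sample_ids[j]!r} "
            "share no non-missing locus"
        )
    return DistanceMatrix(list(matrix.sample_ids), d, counts.astype(np.int64))


# ----------------------------------------------------------------------
def nj(dist: DistanceMatrix,
       taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with the Studier–Keppler Q criterion.

    Ties in Q are broken by the lexicographically smallest pair of node
    indices (leaves are numbered in input order, internal nodes in
    creation order), making the output deterministic.  Negative branch
    lengths are clamped to zero with the deficit logged.  Returns an
    unrooted :class:`dendropy.Tree`.
    """
    n = dist.n
    if n < 3:
        raise ValueError(f"neighbor joining needs >= 3 samples, got {n}")
    if taxon_namespace is None:
        taxon_namespace = dendropy.TaxonNamespace(dist.sample_ids)
    tns = taxon_namespace

    def clamp(x: float, context: str) -> float:
        if x < 0:
            logger.debug("clamped negative branch length %.3g at %s", x, context)
            return 0.0
        return x

    nodes: list[dendropy.Node] = []
    for name in dist.sample_ids:
        nd = dendropy.Node(taxon=tns.get_taxon(name))
        nodes.append(nd)
    active = list(range(n))          # indices into `nodes`, ascending id
    D = dist.values.astype(np.float64).copy()

    while len(active) > 3:
        m = len(active)
        r = D.sum(axis=1)
        q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # row-major argmin == lexicographically smallest (i, j) among ties
        i, j = divmod(int(np.argmin(q)), m)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        vi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dij - vi
        parent = dendropy.Node()
        parent.add_child(nodes[active[i]])
        parent.add_child(nodes[active[j]])
        nodes[active[i]].edge.length = clamp(vi, f"join({i},{j})")
        nodes[active[j]].edge.length = clamp(vj, f"join({i},{j})")
        nodes.append(parent)

        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [x for x in range(m) if x not in (i, j)]
        D = np.pad(D[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        D[-1, :-1] = dnew[keep]
        D[:-1, -1] = dnew[keep]
        active = [active[x] for x in keep] + [len(nodes) - 1]

    # closed-form star join of the last three nodes
    (a, b, c) = active
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    center = dendropy.Node()
    for node_id, ln in ((a, (dab + dac - dbc) / 2.0),
                        (b, (dab + dbc - dac) / 2.0),
                        (c, (dac + dbc - dab) / 2.0)):
        center.add_child(nodes[node_id])
        nodes[node_id].edge.length = clamp(ln, "final-join")

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


def _internal_bipartitions(tree: dendropy.Tree) -> dict[int, dendropy.Edge]:
    """Non-trivial split bitmask -> edge, for an unrooted tree."""
    tree.encode_bipartitions()
    out = {}
    n_taxa = len(tree.taxon_namespace)
    for edge in tree.preorder_edge_iter():
        head = edge.head_node
        if head.parent_node is None or head.is_leaf():
            continue
        size = bin(edge.bipartition.leafset_bitmask).count("1")
        if size in (0, 1, n_taxa - 1, n_taxa):
            continue
        out[edge.bipartition.split_bitmask] = edge
    return out


def bootstrap_support(
    matrix: GenotypeMatrix, n_reps: int = 1000, seed: int | None = None
) -> dendropy.Tree:
    """NJ tree with internal-edge bootstrap supports from locus resampling.

    Loci (columns) are resampled with replacement ``n_reps`` times; the
    support of an internal edge of the main tree is the percentage of
    replicate trees containing the same bipartition, stored both as
    ``edge.head_node.label`` (Newick-visible) and
    ``edge.head_node.support``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    main_dist = squared_distance(matrix)
    tns = dendropy.TaxonNamespace(matrix.sample_ids)
    main = nj(main_dist, taxon_namespace=tns)
    edges = _internal_bipartitions(main)
    counts = {split: 0 for split in edges}

    L = matrix.n_loci
    ids = list(matrix.sample_ids)
    for _ in range(n_reps):
        cols = rng.integers(0, L, L)
        d, cnt = _pairwise_squared(matrix.dosages[:, cols])
        if np.isnan(d).any():  # pragma: no cover - needs pathological missing
            continue
        rep = nj(DistanceMatrix(ids, d, cnt.astype(np.int64)),
                 taxon_namespace=tns)
        for split in _internal_bipartitions(rep):
            if split in counts:
                counts[split] += 1

    for split, edge in edges.items():
        support = 100.0 * counts[split] / n_reps
        edge.head_node.label = f"{support:g}"
        edge.head_node.support = support
    return main


# ----------------------------------------------------------------------
def grm(matrix: GenotypeMatrix) -> np.ndarray:
    """GCTA-style genomic relationship matrix.

    ``G(i,j) = (1/m) * sum_l (g_il - 2 p_l)(g_jl - 2 p_l) / (2 p_l (1 - p_l))``
    with ``p_l`` the alternate-allele frequency over non-missing calls;
    missing dosages are mean-imputed to ``2 p_l``.  Monomorphic loci are
    rejected (zero variance).
    """
    p = matrix.alt_allele_frequency()
    mono = ~((p > 0.0) & (p < 1.0))
    if mono.any():
        j = int(np.flatnonzero(mono)[0])
        raise ValueError(
            f"monomorphic or all-missing locus {matrix.loci.index[j]!r} in "
            "GRM input — filter first"
        )
    x = matrix.dosages.astype(np.float64)
    x = np.where(matrix.dosages == MISSING, 2.0 * p, x)
    z = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    g = (z @ z.T) / matrix.n_loci
    return (g + g.T) / 2.0


@dataclass
class PcaResult:
    """Sample coordinates and per-component variance fractions."""

    coordinates: np.ndarray          # (n_samples, k)
    variance_explained: np.ndarray   # (k,)
    sample_ids: list[str]


def pca(relationship: np.ndarray, k: int = 10,
        sample_ids: list[str] | None = None) -> PcaResult:
    """Top-k eigen-decomposition of a relationship matrix.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue) (clamped at
    zero); ``variance_explained`` is eigenvalue / trace.
    """
    g = np.asarray(relationship, float)
    n = g.shape[0]
    if g.shape != (n, n) or not np.allclose(g, g.T, atol=1e-8):
        raise ValueError("relationship matrix must be square symmetric")
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    evals, evecs = scipy.linalg.eigh(g)
    order = np.argsort(evals)[::-1][:k]
    lam = evals[order]
    vec = evecs[:, order]
    coords = vec * np.sqrt(np.clip(lam, 0.0, None))
    var = lam / np.trace(g)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    return PcaResult(coords, var, list(sample_ids))
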