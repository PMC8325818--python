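"""Gene–gene colocalization by neighborhood enrichment.

A k-nearest-neighbor graph links each read to its spatial neighbors, and
the number of gene–gene connections observed is compared with a null built
by repeatedly shuffling read identities while keeping every position fixed.
For each gene pair the result is a Z-score

    Z = (x - mu) / sigma

where x is the observed (symmetrized) connection count and mu, sigma are
the mean and standard deviation of the count across permutations.  Pairs
colocalizing more than chance get positive Z; mutually exclusive pairs get
negative Z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SpotTable

__all__ = [
    "NeighborGraph",
    "ColocResult",
    "build_neighbor_graph",
    "connection_counts",
    "neighborhood_enrichment",
]

# Above this size the kd-tree path is used; below it, a brute-force sort
# that implements the documented lower-index tie-break exactly.
_BRUTE_FORCE_MAX = 4000


@dataclass
class NeighborGraph:
    """Exact k nearest neighbors per read (Euclidean, no self-links).

    Ties in distance are broken by read index (lower index wins) so the
    graph is deterministic.
    """

    neighbors: np.ndarray  # (n, k) int indices
    k: int

    @property
    def n(self) -> int:
        return self.neighbors.shape[0]

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat (source, target) arrays of all n*k directed links."""
        src = np.repeat(np.arange(self.n), self.k)
        return src, self.neighbors.ravel()


@dataclass
class ColocResult:
    """Observed counts, permutation null and Z-scores, genes × genes."""

    genes: list[str]
    observed: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    z: pd.DataFrame
    n_permutations: int
    k: int
    seed: int

    def to_csv(self, prefix: str) -> None:
        self.z.to_csv(f"{prefix}.Z.csv")
        self.observed.to_csv(f"{prefix}.observed.csv")
        self.null_mean.to_csv(f"{prefix}.null_mean.csv")
        self.null_sd.to_csv(f"{prefix}.null_sd.csv")


def build_neighbor_graph(spots: SpotTable, k: int = 5) -> NeighborGraph:
    """k nearest neighbors of every read by Euclidean distance.

    Requires n > k.  The graph depends only on positions, so it is built
    once and reused across label permutations.
    """
    xy = spots.xy
    n = len(xy)
    if not (1 <= k < n):
        raise ValueError(f"need n > k >= 1, got n={n}, k={k}")
    if n <= _BRUTE_FORCE_MAX:
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        # stable sort on distance keeps lower indices first among ties
        order = np.argsort(d2, axis=1, kind="stable")
        nbrs = order[:, :k]
    else:
        from scipy.spatial import cKDTree

        tree = cKDTree(xy)
        _, idx = tree.query(xy, k=k + 1)
        nbrs = np.empty((n, k), dtype=np.int64)
        for i in range(n):
            row = idx[i][idx[i] != i][:k]
            nbrs[i] = row
    return NeighborGraph(neighbors=nbrs.astype(np.int64), k=k)


def _count_codes(codes_src: np.ndarray, codes_dst: np.ndarray, g: int) -> np.ndarray:
    """Directed gene-pair link counts as a g × g matrix via bincount."""
    flat = np.bincount(codes_src * g + codes_dst, minlength=g * g)
    return flat.reshape(g, g)


def _symmetrize(directed: np.ndarray) -> np.ndarray:
    """Off-diagonal pairs summed both ways; diagonal kept as-is."""
    sym = directed + directed.T
    np.fill_diagonal(sym, np.diag(directed))
    return sym


def connection_counts(
    graph: NeighborGraph, labels: np.ndarray, genes: list[str] | None = None
) -> pd.DataFrame:
    """Symmetrized gene × gene connection counts over the kNN graph.

    The total of directed links is always n * k (conservation); the
    returned matrix sums off-diagonal links twice by construction.
    """
    labels = np.asarray(labels)
    if len(labels) != graph.n:
        raise ValueError("labels length must equal number of reads")
    if genes is None:
        genes = sorted(map(str, pd.unique(labels)))
    code = pd.Categorical(labels, categories=genes).codes.astype(np.int64)
    src, dst = graph.edge_arrays()
    directed = _count_codes(code[src], code[dst], len(genes))
    return pd.DataFrame(_symmetrize(directed), index=genes, columns=genes)


def neighborhood_enrichment(
    spots: SpotTable,
    *,
    k: int = 5,
    n_permutations: int = 500,
    seed: int = 0,
    graph: NeighborGraph | None = None,
) -> ColocResult:
    """Permutation neighborhood-enrichment test for every gene pair.

    Positions are fixed; each permutation shuffles the gene-label vector
    uniformly at random (single seeded RNG stream, so results are
    bit-reproducible and independent of thread count).  The diagonal is
    reported too: it measures spatial self-clustering of a gene.
    """
    if n_permutations < 10:
        raise ValueError("need at least 10 permutations")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations: null moments will be noisy")
    labels = spots.genes.astype(str)
    genes = sorted(pd.unique(labels))
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    if graph is None:
        graph = build_neighbor_graph(spots, k=k)
    g = len(genes)
    code = pd.Categorical(labels, categories=genes).codes.astype(np.int64)
    src, dst = graph.edge_arrays()
    observed = _symmetrize(_count_codes(code[src], code[dst], g)).astype(float)

    rng = np.random.default_rng(seed)
    s = np.zeros((g, g))
    ss = np.zeros((g, g))
    for _ in range(n_permutations):
        perm = rng.permutation(code)
        c = _symmetrize(_count_codes(perm[src], perm[dst], g)).astype(float)
        s += c
        ss += c * c
    mu = s / n_permutations
    var = np.maximum(ss / n_permutations - mu * mu, 0.0)
    sd = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (observed - mu) / sd, np.nan)
    if (sd == 0).any():
        warnings.warn("pair(s) with zero null sd: Z flagged NaN")

    def df(m: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(m, index=genes, columns=genes)

    return ColocResult(
        genes=genes, observed=df(observed), null_mean=df(mu), null_sd=df(sd),
        z=df(z), n_permutations=n_permutations, k=graph.k, seed=seed,
    )
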