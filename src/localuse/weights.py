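"""k-nearest-neighbor spatial weights and global spatial autocorrelation.

Weights are built from point coordinates (population-weighted centroids in
the analysis pipeline) as a row-standardized k-nearest-neighbor matrix:
each unit's row has exactly ``k`` nonzero entries of value ``1/k``.  kNN
graphs are generally asymmetric and nothing downstream assumes symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial.distance import cdist

__all__ = ["SpatialWeights", "knn_weights", "morans_i", "write_weights"]

_REAL_EIG_TOL = 1e-8


@dataclass
class SpatialWeights:
    """Row-standardized kNN spatial weights.

    Attributes
    ----------
    neighbors : (n, k) int array
        Neighbor indices per unit, nearest first.
    k : int
        Neighbors per unit.
    ids : (n,) array
        Unit identifiers, in row order.
    """

    neighbors: np.ndarray
    k: int
    ids: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n(self) -> int:
        return self.neighbors.shape[0]

    @property
    def matrix(self) -> sparse.csr_matrix:
        """The sparse row-standardized weight matrix W."""
        if "matrix" not in self._cache:
            n, k = self.neighbors.shape
            rows = np.repeat(np.arange(n), k)
            cols = self.neighbors.ravel()
            vals = np.full(n * k, 1.0 / k)
            self._cache["matrix"] = sparse.csr_matrix(
                (vals, (rows, cols)), shape=(n, n)
            )
        return self._cache["matrix"]

    def lag(self, z: np.ndarray) -> np.ndarray:
        """Spatial lag Wz (average of each unit's k neighbors)."""
        return self.matrix @ np.asarray(z, dtype=float)

    def eigenvalues(self) -> np.ndarray:
        """All eigenvalues of W (complex in general; cached)."""
        if "eigs" not in self._cache:
            from scipy.linalg import eigvals

            self._cache["eigs"] = eigvals(self.matrix.toarray())
        return self._cache["eigs"]

    def rho_interval(self) -> tuple[float, float]:
        """Feasible interval for the autoregressive parameter rho.

        For row-standardized W the largest eigenvalue is 1.  The lower
        bound is 1/lambda_min over real eigenvalues when a negative real
        eigenvalue exists, else -1.
        """
        eigs = self.eigenvalues()
        real = eigs[np.abs(eigs.imag) < _REAL_EIG_TOL].real
        neg = real[real < 0]
        lower = 1.0 / neg.min() if neg.size else -1.0
        return float(lower), 1.0

    def power_traces(self, q: int) -> np.ndarray:
        """tr(W^j) for j = 0..q (cached; dense matrix powers)."""
        have = self._cache.get("traces")
        if have is None or have.size < q + 1:
            Wd = self.matrix.toarray()
            traces = np.empty(q + 1)
            P = np.eye(self.n)
            traces[0] = self.n
            for j in range(1, q + 1):
                P = P @ Wd
                traces[j] = np.trace(P)
            self._cache["traces"] = traces
        return self._cache["traces"][: q + 1]


def knn_weights(coords: np.ndarray, k: int = 3, ids=None) -> SpatialWeights:
    """Build row-standardized k-nearest-neighbor weights.

    Parameters
    ----------
    coords : (n, 2) array
        Planar coordinates (km).
    k : int
        Number of neighbors; the study design default is 3.
    ids : sequence, optional
        Unit identifiers; distance ties are broken by ascending identifier
        (by row position when ids are omitted), so duplicate coordinates
        are handled deterministically.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array")
    n = coords.shape[0]
    if k < 1:
        raise ValueError("k must be positive")
    if n <= k:
        raise ValueError(f"need more than k={k} units, got n={n}")
    if ids is None:
        ids = np.arange(n)
    ids = np.asarray(ids)
    # tie-break: sort candidate neighbors by (distance, id); ids must map
    # to a sortable order -- use their argsort ranks
    id_rank = np.empty(n, dtype=int)
    id_rank[np.argsort(ids, kind="stable")] = np.arange(n)

    D = cdist(coords, coords)
    np.fill_diagonal(D, np.inf)  # self never a neighbor
    neighbors = np.empty((n, k), dtype=int)
    for i in range(n):
        order = np.lexsort((id_rank, D[i]))
        neighbors[i] = order[:k]
    return SpatialWeights(neighbors=neighbors, k=k, ids=ids)


def morans_i(z: np.ndarray, W: SpatialWeights) -> float:
    """Global Moran's I under row-standardized weights.

    I = (n / S0) * (z~' W z~) / (z~' z~), with z~ mean-centered and
    S0 the sum of all weights (equal to n for row-standardized W).
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or z.size != W.n:
        raise ValueError("z must be a vector of length W.n")
    zc = z - z.mean()
    denom = zc @ zc
    if denom <= 0:
        raise ValueError("Moran's I undefined for constant z")
    s0 = W.matrix.sum()
    return float((W.n / s0) * (zc @ W.lag(zc)) / denom)


def write_weights(W: SpatialWeights, path) -> None:
    """Write sparse weights as plain-text (unit_id, neighbor_id, weight) triples."""
    M = W.matrix.tocoo()
    with open(path, "w") as fh:
        fh.write("unit_id\tneighbor_id\tweight\n")
        for i, j, v in zip(M.row, M.col, M.data):
            fh.write(f"{W.ids[i]}\t{W.ids[j]}\t{v:.10g}\n")
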