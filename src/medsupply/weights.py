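"""Spatial weights matrices for city lattices.

Two construction schemes are provided, both standard for province/city data:

* **queen contiguity** — polygons are neighbors if they share any boundary
  point (edge or vertex); requires polygon geometry (shapely).
* **k-nearest neighbors** — directed k-NN on point coordinates, made
  symmetric by union; requires unique coordinates.

Weights are held as a dense/sparse-agnostic :class:`scipy.sparse.csr_matrix`
with zero diagonal.  Row standardization rescales every nonzero row to sum
to one, which makes the spatial lag a neighbor average — the convention the
Moran scatterplot and LISA statistics assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .errors import ConfigurationError, IslandError

__all__ = ["SpatialWeights", "knn_weights", "queen_weights", "build_weights"]


@dataclass(frozen=True)
class SpatialWeights:
    """An n-by-n nonnegative spatial weights matrix with unit identifiers.

    Attributes
    ----------
    ids : list
        Ordered unit identifiers; row/column ``i`` of ``matrix`` belongs to
        ``ids[i]``.
    matrix : scipy.sparse.csr_matrix
        Nonnegative weights with zero diagonal.
    scheme : str
        ``"queen-contiguity"``, ``"k-nearest"`` or ``"custom"``.
    standardized : bool
        Whether rows have been rescaled to sum to one.
    """

    ids: list = field(default_factory=list)
    matrix: sparse.csr_matrix = None
    scheme: str = "custom"
    standardized: bool = False

    def __post_init__(self) -> None:
        m = sparse.csr_matrix(self.matrix, dtype=float)
        if m.shape[0] != m.shape[1]:
            raise ConfigurationError("weights matrix must be square")
        if len(self.ids) != m.shape[0]:
            raise ConfigurationError("ids length must match matrix order")
        if m.diagonal().any():
            m = m.tolil()
            m.setdiag(0.0)
            m = m.tocsr()
        m.eliminate_zeros()
        if (m.data < 0).any():
            raise ConfigurationError("weights must be nonnegative")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "ids", list(self.ids))

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def s0(self) -> float:
        """Sum of all weights (the S0 normalizer of Moran's I)."""
        return float(self.matrix.sum())

    def cardinalities(self) -> np.ndarray:
        """Number of neighbors (nonzero entries) per row."""
        return np.diff(self.matrix.indptr)

    def islands(self) -> list:
        """Identifiers of zero-degree units."""
        card = self.cardinalities()
        return [self.ids[i] for i in np.flatnonzero(card == 0)]

    def standardize(self) -> "SpatialWeights":
        """Return a row-standardized copy (each nonzero row sums to 1)."""
        isl = self.islands()
        if isl:
            raise IslandError(
                f"cannot row-standardize: island units with no neighbors: {isl}"
            )
        rowsum = np.asarray(self.matrix.sum(axis=1)).ravel()
        d = sparse.diags(1.0 / rowsum)
        return replace(self, matrix=d @ self.matrix, standardized=True)

    def lag(self, values: Sequence[float]) -> np.ndarray:
        """Spatial lag W x (a neighbor average when row-standardized)."""
        x = np.asarray(values, dtype=float)
        if x.shape[0] != self.n:
            raise ConfigurationError("values length must match number of units")
        return self.matrix @ x

    def to_dense(self) -> np.ndarray:
        return self.matrix.toarray()

    # -- I/O ---------------------------------------------------------------

    def to_gal(self, path) -> None:
        """Write the neighbor structure in GAL format (binary adjacency)."""
        m = self.matrix.tocsr()
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, cid in enumerate(self.ids):
                nbrs = m.indices[m.indptr[i] : m.indptr[i + 1]]
                fh.write(f"{cid} {len(nbrs)}\n")
                fh.write(" ".join(str(self.ids[j]) for j in nbrs) + "\n")

    @classmethod
    def from_gal(cls, path, scheme: str = "custom") -> "SpatialWeights":
        with open(path) as fh:
            tokens = fh.read().split("\n")
        n = int(tokens[0].split()[0])
        ids, rows = [], {}
        line = 1
        for _ in range(n):
            cid, deg = tokens[line].split()
            nbrs = tokens[line + 1].split() if int(deg) > 0 else []
            if len(nbrs) != int(deg):
                raise ConfigurationError(f"GAL degree mismatch for unit {cid}")
            ids.append(cid)
            rows[cid] = nbrs
            line += 2
        index = {cid: i for i, cid in enumerate(ids)}
        mat = sparse.lil_matrix((n, n))
        for cid, nbrs in rows.items():
            for nb in nbrs:
                mat[index[cid], index[nb]] = 1.0
        return cls(ids=ids, matrix=mat.tocsr(), scheme=scheme, standardized=False)

    def to_edge_list(self, path) -> None:
        """Write weights as a delimited ``src,dst,weight`` edge list."""
        coo = self.matrix.tocoo()
        with open(path, "w") as fh:
            fh.write("src,dst,weight\n")
            for i, j, w in zip(coo.row, coo.col, coo.data):
                fh.write(f"{self.ids[i]},{self.ids[j]},{w!r}\n")


def knn_weights(
    coords: np.ndarray,
    ids: Sequence | None = None,
    k: int = 4,
    standardize: bool = True,
) -> SpatialWeights:
    """Symmetrized k-nearest-neighbor weights on point coordinates.

    The directed k-NN graph is made symmetric by union (i~j if i is among
    j's k nearest or vice versa), so no unit is an island for k >= 1.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if ids is None:
        ids = list(range(n))
    if n <= k:
        raise ConfigurationError(f"need more than k={k} units, got {n}")
    if len(np.unique(coords, axis=0)) != n:
        raise ConfigurationError("k-nearest weights require unique coordinates")
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k + 1)  # first hit is the point itself
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    adj = sparse.csr_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
    adj = adj.maximum(adj.T)  # union symmetrization
    adj.data[:] = 1.0
    w = SpatialWeights(ids=ids, matrix=adj, scheme="k-nearest", standardized=False)
    return w.standardize() if standardize else w


def queen_weights(
    polygons: Sequence,
    ids: Sequence | None = None,
    standardize: bool = True,
) -> SpatialWeights:
    """Queen-contiguity weights: polygons sharing any boundary point are neighbors."""
    from shapely.strtree import STRtree

    polys = list(polygons)
    n = len(polys)
    if ids is None:
        ids = list(range(n))
    tree = STRtree(polys)
    mat = sparse.lil_matrix((n, n))
    for i, poly in enumerate(polys):
        for j in tree.query(poly, predicate="intersects"):
            j = int(j)
            if j != i:
                mat[i, j] = 1.0
    w = SpatialWeights(
        ids=ids, matrix=mat.tocsr(), scheme="queen-contiguity", standardized=False
    )
    if standardize:
        return w.standardize()
    return w


def build_weights(
    coords: np.ndarray | None = None,
    polygons: Sequence | None = None,
    ids: Sequence | None = None,
    scheme: str | None = None,
    k: int = 4,
    standardize: bool = True,
) -> SpatialWeights:
    """Build spatial weights, defaulting to queen contiguity when polygons
    are supplied and symmetrized k-NN on coordinates otherwise."""
    if scheme is None:
        scheme = "queen-contiguity" if polygons is not None else "k-nearest"
    if scheme == "queen-contiguity":
        if polygons is None:
            raise ConfigurationError("queen contiguity requires polygon geometry")
        return queen_weights(polygons, ids=ids, standardize=standardize)
    if scheme == "k-nearest":
        if coords is None:
            raise ConfigurationError("k-nearest weights require coordinates")
        return knn_weights(coords, ids=ids, k=k, standardize=standardize)
    raise ConfigurationError(f"unknown weights scheme: {scheme!r}")
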