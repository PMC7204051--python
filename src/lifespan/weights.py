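"""Queen-contiguity spatial weights.

Two tracts are queen-contiguous neighbors when their polygon boundaries
share at least one point (an edge or a single vertex).  The resulting
adjacency is row-standardized (each neighbor of tract i gets weight
1/|N(i)|) so that the spatial lag Wx is the mean of neighbors' values.
Eigenvalues of the row-standardized W are obtained through the symmetric
similarity transform D^{-1/2} A D^{-1/2}, which guarantees a real
spectrum; for a connected graph the spectrum lies in (-1, 1].

Tract ordering is the canonical sort of tract identifiers everywhere, so
vectors, matrices and file round-trips stay aligned.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.linalg import eigh
from shapely.geometry import shape
from shapely.strtree import STRtree

__all__ = [
    "AdjacencyList",
    "SpatialWeights",
    "queen_contiguity",
    "grid_queen_contiguity",
    "row_standardize",
    "spatial_lag",
    "read_geojson_polygons",
    "read_gal",
    "write_gal",
]


@dataclass
class AdjacencyList:
    """Symmetric neighbor structure over canonically sorted tract ids."""

    ids: tuple[str, ...]
    neighbors: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        ids = tuple(sorted(self.ids, key=str))
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate tract ids")
        idset = set(ids)
        neigh = {i: frozenset(map(str, self.neighbors.get(i, ()))) for i in ids}
        for i, ns in neigh.items():
            if i in ns:
                raise ValueError(f"tract {i} listed as its own neighbor")
            for j in ns:
                if j not in idset:
                    raise ValueError(f"neighbor {j} of {i} is not a known tract")
                if i not in neigh[j]:
                    raise ValueError(f"asymmetric adjacency: {j} in N({i}) only")
        self.ids = ids
        self.neighbors = neigh

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def islands(self) -> tuple[str, ...]:
        return tuple(i for i in self.ids if not self.neighbors[i])

    def cardinalities(self) -> dict[str, int]:
        return {i: len(self.neighbors[i]) for i in self.ids}

    def subset(self, keep: set[str] | list[str]) -> "AdjacencyList":
        """Restrict to a subset of tracts, dropping links to removed tracts."""
        keep = set(map(str, keep))
        unknown = keep - set(self.ids)
        if unknown:
            raise ValueError(f"unknown tract ids in subset: {sorted(unknown)[:5]}")
        ids = tuple(i for i in self.ids if i in keep)
        return AdjacencyList(
            ids, {i: frozenset(self.neighbors[i] & keep) for i in ids}
        )


@dataclass
class SpatialWeights:
    """Row-standardized sparse weights over an adjacency structure."""

    adjacency: AdjacencyList
    weights: sparse.csr_matrix
    standardized: bool = True
    _eigenvalues: np.ndarray | None = field(default=None, repr=False)

    @property
    def ids(self) -> tuple[str, ...]:
        return self.adjacency.ids

    @property
    def n(self) -> int:
        return len(self.adjacency)

    @property
    def islands(self) -> tuple[str, ...]:
        return self.adjacency.islands

    @property
    def eigenvalues(self) -> np.ndarray:
        """Real spectrum of W, computed lazily via the symmetric similarity
        D^{-1/2} A D^{-1/2}; island rows contribute eigenvalue 0."""
        if self._eigenvalues is None:
            card = np.array(
                [len(self.adjacency.neighbors[i]) for i in self.ids], dtype=float
            )
            A = _binary_adjacency(self.adjacency).toarray()
            with np.errstate(divide="ignore"):
                dinv = np.where(card > 0, 1.0 / np.sqrt(card), 0.0)
            sym = dinv[:, None] * A * dinv[None, :]
            self._eigenvalues = np.sort(eigh(sym, eigvals_only=True))
        return self._eigenvalues

    def lag(self, x: np.ndarray) -> np.ndarray:
        return spatial_lag(self, x)

    def dense(self) -> np.ndarray:
        return self.weights.toarray()


def _binary_adjacency(adj: AdjacencyList) -> sparse.csr_matrix:
    pos = {t: i for i, t in enumerate(adj.ids)}
    rows, cols = [], []
    for t in adj.ids:
        for u in adj.neighbors[t]:
            rows.append(pos[t])
            cols.append(pos[u])
    data = np.ones(len(rows))
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(adj.ids), len(adj.ids))
    )


def queen_contiguity(
    polygons: dict[str, object], snap_tolerance: float = 0.0
) -> AdjacencyList:
    """Queen contiguity from shapely polygons keyed by tract id.

    Neighbors share at least one boundary point.  ``snap_tolerance``
    buffers geometries outward before testing, for shapefiles whose
    nominally shared borders do not coincide exactly (default 0: exact).
    """
    if not polygons:
        raise ValueError("empty polygon set")
    keyed = {str(k): v for k, v in polygons.items()}
    if len(keyed) != len(polygons):
        raise ValueError("duplicate tract ids")
    ids = sorted(keyed)
    geoms = []
    for i in ids:
        g = keyed[i]
        if g is None or g.is_empty or not g.is_valid:
            raise ValueError(f"invalid geometry for tract {i}")
        geoms.append(g.buffer(snap_tolerance) if snap_tolerance > 0 else g)
    tree = STRtree(geoms)
    neighbors: dict[str, set[str]] = {i: set() for i in ids}
    for a, b in tree.query(geoms, predicate="intersects").T:
        if a != b:
            neighbors[ids[a]].add(ids[b])
            neighbors[ids[b]].add(ids[a])
    return AdjacencyList(tuple(ids), {i: frozenset(s) for i, s in neighbors.items()})


def grid_queen_contiguity(rows: int, cols: int) -> AdjacencyList:
    """Queen adjacency of a rows x cols unit-square lattice, by index arithmetic.

    Tract ids are "r{row:03d}c{col:03d}" so canonical sorting follows the
    grid layout.
    """
    if rows < 1 or cols < 1:
        raise ValueError("grid dimensions must be positive")

    def tid(r: int, c: int) -> str:
        return f"r{r:03d}c{c:03d}"

    neighbors: dict[str, frozenset[str]] = {}
    for r in range(rows):
        for c in range(cols):
            ns = {
                tid(r + dr, c + dc)
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)
                and 0 <= r + dr < rows
                and 0 <= c + dc < cols
            }
            neighbors[tid(r, c)] = frozenset(ns)
    return AdjacencyList(tuple(neighbors), neighbors)


def row_standardize(adjacency: AdjacencyList) -> SpatialWeights:
    """w_ij = 1/|N(i)| for neighbors, 0 otherwise; islands keep zero rows."""
    islands = adjacency.islands
    if islands:
        warnings.warn(
            f"{len(islands)} island tract(s) with no neighbors: "
            f"{list(islands)[:5]}; their weight rows are zero",
            stacklevel=2,
        )
    A = _binary_adjacency(adjacency)
    card = np.asarray(A.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        inv = np.where(card > 0, 1.0 / card, 0.0)
    W = sparse.diags(inv) @ A
    return SpatialWeights(adjacency, W.tocsr(), standardized=True)


def spatial_lag(W: SpatialWeights, x: np.ndarray) -> np.ndarray:
    """Wx: under row standardization, each tract's mean of neighbor values."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != W.n:
        raise ValueError(f"value vector length {x.shape[0]} != {W.n} tracts")
    return W.weights @ x


# ---------------------------------------------------------------------------
# File formats


def read_geojson_polygons(path, id_property: str = "tract_id") -> dict[str, object]:
    """Polygons from a GeoJSON FeatureCollection, keyed by an id property."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    out: dict[str, object] = {}
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        if id_property not in props:
            raise ValueError(f"{path}: feature missing '{id_property}' property")
        tid = str(props[id_property])
        if tid in out:
            raise ValueError(f"{path}: duplicate tract id {tid}")
        out[tid] = shape(feat["geometry"])
    return out


def read_gal(path) -> AdjacencyList:
    """Read a GAL neighbor file (the spatial-econometrics exchange format)."""
    with open(path) as fh:
        tokens_by_line = [ln.split() for ln in fh if ln.strip()]
    header = tokens_by_line[0]
    n = int(header[0]) if len(header) == 1 else int(header[1])
    neighbors: dict[str, frozenset[str]] = {}
    li = 1
    for _ in range(n):
        tid, count = tokens_by_line[li][0], int(tokens_by_line[li][1])
        ns = tokens_by_line[li + 1] if count > 0 else []
        if len(ns) != count:
            raise ValueError(f"{path}: {tid} declares {count} neighbors, lists {len(ns)}")
        neighbors[tid] = frozenset(ns)
        li += 2 if count > 0 else 1
    return AdjacencyList(tuple(neighbors), neighbors)


def write_gal(adjacency: AdjacencyList, path) -> None:
    """Write GAL; neighbor lists are sorted so round-trips are byte-exact."""
    lines = [str(len(adjacency))]
    for tid in adjacency.ids:
        ns = sorted(adjacency.neighbors[tid])
        lines.append(f"{tid} {len(ns)}")
        if ns:
            lines.append(" ".join(ns))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
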