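"""Vietoris-Rips persistent homology of Euclidean point clouds.

The public scale unit throughout is the *radius* parameter epsilon: two
points are joined by an edge as soon as ``d(x_i, x_j) <= 2 * epsilon``, and a
higher simplex enters the filtration when all of its edges are present
(clique rule).  Consequently every simplex enters at half its vertex-set
diameter, and the default filtration horizon is

    maxsc = 1/2 * max_{x != y} d(x, y),

half the diameter of the cloud.  Features still alive at the horizon
("essential" classes — at least the last connected component) are reported
with their death truncated to the horizon and flagged ``capped``; capped
bars participate in lifespan totals, which keeps the totals finite and
makes the closed form

    total H0 lifespan = maxsc + 1/2 * sum(MST edge weights)

exact for a nonempty cloud.

Three engines are provided:

* :func:`h0_persistence_mst` — fast dimension-0 path via the minimum
  spanning tree (Vietoris-Rips H0 is single linkage);
* :func:`vr_persistence` — the general engine (H0 union-find + H1 boundary
  column reduction over F2 with bitset columns);
* :func:`brute_force_persistence` — an independent oracle for tiny clouds:
  full clique enumeration and textbook column reduction of the
  filtration-ordered boundary matrix.

Homology dimensions 0 and 1 are supported; dimension 2 (voids) is out of
scope for this package and requesting it raises :class:`UnsupportedError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence, Union

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PointCloud",
    "FiltrationParams",
    "PersistenceDiagram",
    "UnsupportedError",
    "max_scale",
    "vr_persistence",
    "h0_persistence_mst",
    "brute_force_persistence",
    "total_lifespan",
]

#: Hard cap on the oracle input size: clique enumeration is exponential.
_ORACLE_MAX_POINTS = 10


class UnsupportedError(ValueError):
    """Raised for filtration requests outside the supported H0/H1 range."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PointCloud:
    """A finite set of points in Euclidean space, as an ``(n, m)`` array.

    All coordinates must be finite and share the dimension ``m >= 1``.
    Degenerate clouds (zero or one point) are legal.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim == 1:
            pts = pts.reshape(-1, 1)
        if pts.ndim != 2:
            raise ValueError(f"points must be a 2-d array, got ndim={pts.ndim}")
        if pts.size and not np.isfinite(pts).all():
            raise ValueError("point cloud contains non-finite coordinates")
        pts = np.ascontiguousarray(pts)
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    @classmethod
    def from_coords(cls, coords: Union[Sequence, np.ndarray]) -> "PointCloud":
        """Build a cloud from a sequence of scalars (1-d) or vectors."""
        return cls(np.asarray(coords, dtype=float))

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1] if self.points.ndim == 2 else 1

    def with_point(self, point: Union[Sequence, np.ndarray, float]) -> "PointCloud":
        """Return a new cloud with ``point`` appended."""
        p = np.atleast_1d(np.asarray(point, dtype=float))
        if self.n_points and p.shape[0] != self.dim:
            raise ValueError(
                f"point has dimension {p.shape[0]}, cloud has dimension {self.dim}"
            )
        return PointCloud(np.vstack([self.points, p[None, :]]) if self.n_points else p[None, :])


@dataclass(frozen=True)
class FiltrationParams:
    """Filtration settings: highest homology dimension and radius horizon.

    ``max_scale`` is either an explicit nonnegative radius or ``"auto"``,
    meaning half the cloud diameter.
    """

    max_dimension: int = 1
    max_scale: Union[float, str] = "auto"

    def __post_init__(self) -> None:
        if self.max_dimension not in (0, 1, 2):
            raise UnsupportedError(
                f"max_dimension must be 0, 1 or 2, got {self.max_dimension}"
            )
        if isinstance(self.max_scale, str):
            if self.max_scale != "auto":
                raise ValueError(f"max_scale must be a number or 'auto', got {self.max_scale!r}")
        elif not (np.isfinite(self.max_scale) and self.max_scale >= 0):
            raise ValueError(f"explicit max_scale must be finite and >= 0, got {self.max_scale}")

    def resolve_max_scale(self, cloud: PointCloud) -> float:
        return max_scale(cloud) if self.max_scale == "auto" else float(self.max_scale)


@dataclass(frozen=True)
class PersistenceDiagram:
    """Persistence as an n x 3 table (dimension, birth, death) in radius units.

    ``capped`` marks rows whose death was truncated at the filtration
    horizon ``source_max_scale``.  Rows are stored in the canonical order
    (dim, birth, death, capped) so equal diagrams compare equal.
    """

    dims: np.ndarray
    births: np.ndarray
    deaths: np.ndarray
    capped: np.ndarray
    source_max_scale: float

    def __post_init__(self) -> None:
        dims = np.asarray(self.dims, dtype=int)
        births = np.asarray(self.births, dtype=float)
        deaths = np.asarray(self.deaths, dtype=float)
        capped = np.asarray(self.capped, dtype=bool)
        if not (dims.shape == births.shape == deaths.shape == capped.shape):
            raise ValueError("diagram columns must have identical shapes")
        order = np.lexsort((capped, deaths, births, dims))
        for name, col in (
            ("dims", dims[order]),
            ("births", births[order]),
            ("deaths", deaths[order]),
            ("capped", capped[order]),
        ):
            col.setflags(write=False)
            object.__setattr__(self, name, col)

    def __len__(self) -> int:
        return len(self.dims)

    def rows(self) -> list[tuple[int, float, float, bool]]:
        return list(zip(self.dims.tolist(), self.births.tolist(),
                        self.deaths.tolist(), self.capped.tolist()))

    def in_dims(self, dims: Iterable[int]) -> "PersistenceDiagram":
        mask = np.isin(self.dims, list(dims))
        return PersistenceDiagram(self.dims[mask], self.births[mask],
                                  self.deaths[mask], self.capped[mask],
                                  self.source_max_scale)

    def lifespans(self) -> np.ndarray:
        return self.deaths - self.births

    # -- CSV serialization (header dim,birth,death,capped; 17 sig. digits) --

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("dim,birth,death,capped\n")
            for d, b, dth, c in self.rows():
                fh.write(f"{d},{b:.17g},{dth:.17g},{int(c)}\n")

    @classmethod
    def from_csv(cls, path, source_max_scale: Union[float, None] = None) -> "PersistenceDiagram":
        data = np.genfromtxt(path, delimiter=",", names=True, dtype=None, encoding="utf-8")
        data = np.atleast_1d(data)
        deaths = np.asarray(data["death"], dtype=float)
        if source_max_scale is None:
            source_max_scale = float(deaths.max()) if deaths.size else 0.0
        return cls(np.asarray(data["dim"], dtype=int),
                   np.asarray(data["birth"], dtype=float),
                   deaths,
                   np.asarray(data["capped"], dtype=bool),
                   float(source_max_scale))


def _empty_diagram(horizon: float = 0.0) -> PersistenceDiagram:
    z = np.zeros(0)
    return PersistenceDiagram(z.astype(int), z, z, z.astype(bool), horizon)


def _make_diagram(rows: list[tuple[int, float, float, bool]],
                  horizon: float) -> PersistenceDiagram:
    if not rows:
        return _empty_diagram(horizon)
    arr = np.array([(d, b, dt) for d, b, dt, _ in rows], dtype=float)
    capped = np.array([c for *_, c in rows], dtype=bool)
    return PersistenceDiagram(arr[:, 0].astype(int), arr[:, 1], arr[:, 2], capped, horizon)


# ---------------------------------------------------------------------------
# scale
# ---------------------------------------------------------------------------


def max_scale(cloud: PointCloud) -> float:
    """Half the maximum pairwise distance of the cloud (0 for < 2 points)."""
    if cloud.n_points < 2:
        return 0.0
    return float(pdist(cloud.points).max()) / 2.0


# ---------------------------------------------------------------------------
# fast H0: single linkage / minimum spanning tree
# ---------------------------------------------------------------------------


def h0_persistence_mst(cloud: PointCloud) -> PersistenceDiagram:
    """Dimension-0 persistence via the minimum spanning tree.

    Components merge exactly at half the MST edge weights (Vietoris-Rips H0
    is single linkage); the surviving component is one capped bar at the
    auto horizon.  Row multiset equals ``vr_persistence`` restricted to
    dimension 0.
    """
    n = cloud.n_points
    if n == 0:
        return _empty_diagram()
    horizon = max_scale(cloud)
    rows: list[tuple[int, float, float, bool]] = []
    if n > 1:
        # +1 shift keeps zero-weight edges (duplicate points) in the sparse MST
        dense = squareform(pdist(cloud.points)) + 1.0
        np.fill_diagonal(dense, 0.0)
        tree = minimum_spanning_tree(dense)
        weights = np.sort(tree.data) - 1.0
        rows = [(0, 0.0, w / 2.0, False) for w in weights]
    rows.append((0, 0.0, horizon, True))
    return _make_diagram(rows, horizon)


def h0_total_lifespan(cloud: PointCloud) -> float:
    """Closed form: maxsc + 1/2 * sum of MST edge weights."""
    diagram = h0_persistence_mst(cloud)
    return float(np.sum(diagram.lifespans()))


# ---------------------------------------------------------------------------
# general engine
# ---------------------------------------------------------------------------


def _sorted_edges(dmat: np.ndarray, horizon: float):
    """Edges (i < j) with entry scale d/2 <= horizon, filtration order.

    Ties are broken by the lexicographic vertex pair, giving a
    deterministic simplexwise filtration.
    """
    n = dmat.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    scales = dmat[iu, ju] / 2.0
    keep = scales <= horizon
    iu, ju, scales = iu[keep], ju[keep], scales[keep]
    order = np.lexsort((ju, iu, scales))
    return iu[order], ju[order], scales[order]


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def vr_persistence(cloud: PointCloud, params: FiltrationParams = FiltrationParams()) -> PersistenceDiagram:
    """Persistence diagram of the Vietoris-Rips filtration up to ``max_dimension``.

    H0 comes from a union-find sweep over the sorted edges.  H1 pairs
    cycle-creating edges against triangles by column reduction of the
    triangle boundary matrix over F2 (columns held as Python-int bitsets,
    reduced in filtration order).  Creators never killed within the horizon
    are reported capped.  Zero-lifespan rows are retained.
    """
    if params.max_dimension >= 2:
        raise UnsupportedError("homology dimension 2 is not supported")
    n = cloud.n_points
    if n == 0:
        return _empty_diagram()
    horizon = params.resolve_max_scale(cloud)
    if n == 1:
        return _make_diagram([(0, 0.0, horizon, True)], horizon)

    dmat = squareform(pdist(cloud.points))
    ei, ej, escale = _sorted_edges(dmat, horizon)
    rows: list[tuple[int, float, float, bool]] = []

    # --- H0: union-find sweep; merging edges are deaths, others create cycles
    uf = _UnionFind(n)
    creator = np.zeros(len(escale), dtype=bool)
    for e in range(len(escale)):
        if uf.union(int(ei[e]), int(ej[e])):
            rows.append((0, 0.0, float(escale[e]), False))
        else:
            creator[e] = True
    n_components = len({uf.find(v) for v in range(n)})
    rows.extend((0, 0.0, horizon, True) for _ in range(n_components))

    if params.max_dimension >= 1 and len(escale):
        rows.extend(_h1_pairs(dmat, ei, ej, escale, creator, horizon))
    return _make_diagram(rows, horizon)


def _h1_pairs(dmat, ei, ej, escale, creator, horizon):
    """Pair cycle-creating edges with triangles by F2 column reduction."""
    n = dmat.shape[0]
    n_edges = len(escale)
    edge_index = {}
    for e in range(n_edges):
        edge_index[(int(ei[e]), int(ej[e]))] = e

    # adjacency under the horizon, for triangle enumeration
    adj = [np.flatnonzero((dmat[i] / 2.0 <= horizon)) for i in range(n)]
    tri_i, tri_j, tri_k, tri_scale = [], [], [], []
    half = dmat / 2.0
    for i in range(n):
        nbrs = adj[i][adj[i] > i]
        if len(nbrs) < 2:
            continue
        sub = half[np.ix_(nbrs, nbrs)]
        a, b = np.triu_indices(len(nbrs), k=1)
        ok = sub[a, b] <= horizon
        a, b = a[ok], b[ok]
        if not len(a):
            continue
        js, ks = nbrs[a], nbrs[b]
        sc = np.maximum(np.maximum(half[i, js], half[i, ks]), half[js, ks])
        tri_i.append(np.full(len(js), i))
        tri_j.append(js)
        tri_k.append(ks)
        tri_scale.append(sc)
    if not tri_i:
        # no triangles: every creator edge is an essential 1-cycle
        return [(1, float(escale[e]), horizon, True)
                for e in np.flatnonzero(creator)]

    ti = np.concatenate(tri_i)
    tj = np.concatenate(tri_j)
    tk = np.concatenate(tri_k)
    ts = np.concatenate(tri_scale)
    order = np.lexsort((tk, tj, ti, ts))
    ti, tj, tk, ts = ti[order], tj[order], tk[order], ts[order]

    pairs = []
    low_col: dict[int, int] = {}
    low_scale: dict[int, float] = {}
    for t in range(len(ts)):
        i, j, k = int(ti[t]), int(tj[t]), int(tk[t])
        col = ((1 << edge_index[(i, j)])
               | (1 << edge_index[(i, k)])
               | (1 << edge_index[(j, k)]))
        while col:
            low = col.bit_length() - 1
            other = low_col.get(low)
            if other is None:
                break
            col ^= other
        if col:
            low_col[low] = col
            low_scale[low] = float(ts[t])
    for low, death in low_scale.items():
        pairs.append((1, float(escale[low]), death, False))
    paired = set(low_col)
    pairs.extend((1, float(escale[e]), horizon, True)
                 for e in np.flatnonzero(creator) if int(e) not in paired)
    return pairs


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_persistence(cloud: PointCloud,
                            params: FiltrationParams = FiltrationParams()) -> PersistenceDiagram:
    """Exact diagram by textbook reduction of the full boundary matrix over F2.

    Enumerates every clique up to dimension ``max_dimension + 1`` with
    entry scale half its vertex-set diameter, orders simplices by
    (scale, dimension, lexicographic vertices) and performs the standard
    left-to-right column reduction.  Intended as an independent oracle:
    limited to 10 points.
    """
    if params.max_dimension >= 2:
        raise UnsupportedError("homology dimension 2 is not supported")
    n = cloud.n_points
    if n > _ORACLE_MAX_POINTS:
        raise ValueError(
            f"brute-force oracle accepts at most {_ORACLE_MAX_POINTS} points, got {n}"
        )
    if n == 0:
        return _empty_diagram()
    horizon = params.resolve_max_scale(cloud)
    dmat = squareform(pdist(cloud.points)) if n > 1 else np.zeros((1, 1))

    simplices: list[tuple[float, int, tuple[int, ...]]] = []
    for d in range(min(params.max_dimension + 1, n - 1) + 1):
        for verts in combinations(range(n), d + 1):
            scale = 0.0
            if d:
                scale = max(dmat[a, b] for a, b in combinations(verts, 2)) / 2.0
            if scale <= horizon:
                simplices.append((scale, d, verts))
    simplices.sort()
    index = {verts: i for i, (_, _, verts) in enumerate(simplices)}

    columns: list[int] = []
    for _, d, verts in simplices:
        col = 0
        if d:
            for face in combinations(verts, d):
                col |= 1 << index[face]
        columns.append(col)

    low_of: dict[int, int] = {}     # low row -> column index holding it
    reduced: list[int] = []
    for j, col in enumerate(columns):
        while col:
            low = col.bit_length() - 1
            other = low_of.get(low)
            if other is None:
                break
            col ^= reduced[other]
        reduced.append(col)
        if col:
            low_of[col.bit_length() - 1] = j

    rows: list[tuple[int, float, float, bool]] = []
    killed = set(low_of)
    for j, col in enumerate(reduced):
        if col:
            low = col.bit_length() - 1
            d = simplices[low][1]
            if d <= params.max_dimension:
                rows.append((d, simplices[low][0], simplices[j][0], False))
        elif j not in killed:
            d = simplices[j][1]
            if d <= params.max_dimension:
                rows.append((d, simplices[j][0], horizon, True))
    return _make_diagram(rows, horizon)


# ---------------------------------------------------------------------------
# lifespan totals
# ---------------------------------------------------------------------------


def total_lifespan(diagram: PersistenceDiagram, dims: Iterable[int] = (0,)) -> float:
    """Sum of (death - birth) over rows whose dimension lies in ``dims``.

    Capped rows contribute at their truncated death.
    """
    dims = frozenset(int(d) for d in dims)
    if not dims:
        raise ValueError("dims must be a nonempty set of homology dimensions")
    mask = np.isin(diagram.dims, list(dims))
    return float(np.sum(diagram.deaths[mask] - diagram.births[mask]))
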