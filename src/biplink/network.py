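"""Bipartite and temporal-bipartite network data model, I/O and primitives.

A :class:`BipartiteNetwork` holds two disjoint node sets V1 and V2 (opaque
strings) and a set of undirected cross-set links.  All neighbourhood and
path primitives used by the similarity indices live here:

* ``Γ(v)``  — :meth:`BipartiteNetwork.neighbors`, the opposite-side neighbour
  set of ``v``;
* ``Γ̂(v)`` — :meth:`BipartiteNetwork.second_neighbors`, the union of the
  neighbour sets of ``v``'s neighbours (same side as ``v``, may contain ``v``);
* length-3 paths ``x–d′–p′–y`` — :func:`enumerate_paths3`, the quadrangle
  building block of every path-based index.

Node identity is positional: V1 is whatever appeared in column 1 of the edge
list, V2 column 2; membership is never inferred from names.  Node order is
the sorted string order, which fixes the row/column order of the biadjacency
matrix and makes every downstream computation deterministic.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    BipartitenessError,
    FormatError,
    LabelError,
    NodeLookupError,
    ParseError,
    SideError,
    TemporalError,
)

logger = logging.getLogger(__name__)

Link = tuple[str, str]


class BipartiteNetwork:
    """Undirected bipartite graph with node sets V1, V2 and cross-set links.

    Parameters
    ----------
    v1_nodes, v2_nodes:
        Node identifiers for the two sides.  The sets must be disjoint.
        Nodes without links are kept (training networks need them).
    links:
        Iterable of ``(u, v)`` pairs with ``u`` in V1 and ``v`` in V2.
        Duplicates collapse to a single link.
    """

    __slots__ = ("_v1", "_v2", "_v1_set", "_v2_set", "_adj1", "_adj2", "_links", "generation_log")

    def __init__(self, v1_nodes: Iterable[str], v2_nodes: Iterable[str], links: Iterable[Link]):
        v1 = tuple(sorted({str(n) for n in v1_nodes}))
        v2 = tuple(sorted({str(n) for n in v2_nodes}))
        overlap = set(v1) & set(v2)
        if overlap:
            raise BipartitenessError(
                f"nodes appear on both sides of the bipartition: {sorted(overlap)[:5]}"
            )
        self._v1 = v1
        self._v2 = v2
        self._v1_set = frozenset(v1)
        self._v2_set = frozenset(v2)
        adj1: dict[str, set[str]] = {n: set() for n in v1}
        adj2: dict[str, set[str]] = {n: set() for n in v2}
        link_set: set[Link] = set()
        for u, v in links:
            u, v = str(u), str(v)
            if u not in self._v1_set or v not in self._v2_set:
                raise BipartitenessError(
                    f"link ({u!r}, {v!r}) does not join a V1 node to a V2 node"
                )
            link_set.add((u, v))
            adj1[u].add(v)
            adj2[v].add(u)
        self._adj1 = adj1
        self._adj2 = adj2
        self._links = frozenset(link_set)

    # -- basic accessors ---------------------------------------------------

    @property
    def v1_nodes(self) -> tuple[str, ...]:
        return self._v1

    @property
    def v2_nodes(self) -> tuple[str, ...]:
        return self._v2

    @property
    def links(self) -> frozenset[Link]:
        return self._links

    @property
    def n_links(self) -> int:
        return len(self._links)

    def side(self, v: str) -> int:
        """Return 1 or 2 for the side of ``v``; raise if unknown."""
        if v in self._v1_set:
            return 1
        if v in self._v2_set:
            return 2
        raise NodeLookupError(f"unknown node {v!r}")

    def has_node(self, v: str) -> bool:
        return v in self._v1_set or v in self._v2_set

    def has_link(self, u: str, v: str) -> bool:
        return (u, v) in self._links

    def require_sides(self, x: str, y: str) -> None:
        """Assert ``x`` ∈ V1 and ``y`` ∈ V2."""
        if x not in self._v1_set:
            raise SideError(f"{x!r} is not a V1 node")
        if y not in self._v2_set:
            raise SideError(f"{y!r} is not a V2 node")

    # -- neighbourhood primitives -----------------------------------------

    def neighbors(self, v: str) -> frozenset[str]:
        """Γ(v): the opposite-side neighbour set of ``v``."""
        if v in self._adj1:
            return frozenset(self._adj1[v])
        if v in self._adj2:
            return frozenset(self._adj2[v])
        raise NodeLookupError(f"unknown node {v!r}")

    def second_neighbors(self, v: str) -> frozenset[str]:
        """Γ̂(v) = ∪_{z∈Γ(v)} Γ(z): two-hop reach on v's own side (may include v)."""
        out: set[str] = set()
        for z in self.neighbors(v):
            out |= self.neighbors(z)
        return frozenset(out)

    def degree(self, v: str) -> int:
        """|Γ(v)|."""
        return len(self.neighbors(v))

    # -- matrix form -------------------------------------------------------

    def biadjacency(self) -> np.ndarray:
        """Dense |V1|×|V2| 0/1 matrix B in sorted node order."""
        B = np.zeros((len(self._v1), len(self._v2)), dtype=np.int64)
        col = {v: j for j, v in enumerate(self._v2)}
        for i, u in enumerate(self._v1):
            for v in self._adj1[u]:
                B[i, col[v]] = 1
        return B

    # -- derived networks --------------------------------------------------

    def with_link(self, u: str, v: str) -> "BipartiteNetwork":
        """Return a copy with the link (u∈V1, v∈V2) added."""
        self.require_sides(u, v)
        return BipartiteNetwork(self._v1, self._v2, self._links | {(u, v)})

    def subnetwork(self, links: Iterable[Link]) -> "BipartiteNetwork":
        """Same node sets, restricted link set (used for training networks)."""
        return BipartiteNetwork(self._v1, self._v2, links)

    def nonexistent_pairs(self) -> list[Link]:
        """E′ = U \\ E in deterministic (sorted) order."""
        return [
            (u, v) for u in self._v1 for v in self._v2 if (u, v) not in self._links
        ]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"BipartiteNetwork(|V1|={len(self._v1)}, |V2|={len(self._v2)}, "
            f"|E|={len(self._links)})"
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BipartiteNetwork):
            return NotImplemented
        return (
            self._v1 == other._v1 and self._v2 == other._v2 and self._links == other._links
        )

    def __hash__(self) -> int:
        return hash((self._v1, self._v2, self._links))


class TemporalBipartiteNetwork(BipartiteNetwork):
    """Bipartite network whose every link carries a diagnosis date.

    Removing the timestamps yields a plain :class:`BipartiteNetwork`
    (:meth:`static`).  V1 plays the role of patients, V2 of diseases.
    """

    __slots__ = ("_timestamps",)

    def __init__(
        self,
        v1_nodes: Iterable[str],
        v2_nodes: Iterable[str],
        links: Iterable[Link],
        timestamps: Mapping[Link, _dt.date],
    ):
        super().__init__(v1_nodes, v2_nodes, links)
        ts = {(str(u), str(v)): d for (u, v), d in timestamps.items()}
        missing = self.links - set(ts)
        if missing:
            raise TemporalError(f"{len(missing)} links lack timestamps, e.g. {sorted(missing)[0]}")
        for link, d in ts.items():
            if link not in self.links:
                raise TemporalError(f"timestamp for non-link {link}")
            if not isinstance(d, _dt.date):
                raise TemporalError(f"timestamp for {link} is not a date: {d!r}")
        self._timestamps = ts

    @property
    def timestamps(self) -> dict[Link, _dt.date]:
        return dict(self._timestamps)

    def timestamp(self, u: str, v: str) -> _dt.date:
        try:
            return self._timestamps[(u, v)]
        except KeyError:
            raise TemporalError(f"no timestamp for link ({u!r}, {v!r})") from None

    def static(self) -> BipartiteNetwork:
        """Drop the timestamps."""
        return BipartiteNetwork(self.v1_nodes, self.v2_nodes, self.links)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"TemporalBipartiteNetwork(|V1|={len(self.v1_nodes)}, "
            f"|V2|={len(self.v2_nodes)}, |E|={self.n_links})"
        )


@dataclass(frozen=True)
class Path3:
    """A length-3 path x–d′–p′–y between x ∈ V1 and y ∈ V2.

    The internal nodes d′ ∈ V2 and p′ ∈ V1 satisfy d′ ≠ y and p′ ≠ x, so the
    four nodes trace a quadrangle once the (x, y) link is added.
    """

    source: str
    via_v2: str
    via_v1: str
    target: str


@dataclass(frozen=True)
class NetworkStats:
    """Topological summary: node/link counts and per-side mean degrees."""

    n_nodes: int
    n_v1: int
    n_v2: int
    n_links: int
    mean_degree_v1: float
    mean_degree_v2: float


# ---------------------------------------------------------------------------
# loaders


def _read_table(path, delimiter: str, n_cols: int, header: bool) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=delimiter,
        header=0 if header else None,
        dtype=str,
        skip_blank_lines=True,
        comment="#",
    )
    if df.shape[1] != n_cols:
        raise ParseError(
            f"{path}: expected {n_cols} columns, found {df.shape[1]}"
        )
    bad = df.isna().any(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + (2 if header else 1)
        raise ParseError(f"{path}: malformed row at line {line}")
    return df


def load_edgelist(
    path,
    delimiter: str = "\t",
    temporal: bool = False,
    date_format: str = "%Y-%m-%d",
    header: bool = False,
) -> BipartiteNetwork | TemporalBipartiteNetwork:
    """Load a two-column (static) or three-column (temporal) edge list.

    Column 1 is V1 (source), column 2 is V2 (target), and for temporal files
    column 3 a date in ``date_format`` (ISO-8601 by default).  Duplicate rows
    collapse to one link; for temporal files the earliest date wins, since a
    link exists from the first diagnosis onward.  A node appearing in both
    columns raises :class:`BipartitenessError`.
    """
    n_cols = 3 if temporal else 2
    df = _read_table(path, delimiter, n_cols, header)
    sources = df.iloc[:, 0].astype(str)
    targets = df.iloc[:, 1].astype(str)
    overlap = set(sources) & set(targets)
    if overlap:
        raise BipartitenessError(
            f"{path}: node(s) appear in both columns: {sorted(overlap)[:5]}"
        )
    n_rows = len(df)
    if not temporal:
        links = set(zip(sources, targets))
        net = BipartiteNetwork(set(sources), set(targets), links)
        logger.info(
            "loaded %s: %d rows, %d links (%d duplicate rows), |V1|=%d |V2|=%d",
            path, n_rows, net.n_links, n_rows - net.n_links,
            len(net.v1_nodes), len(net.v2_nodes),
        )
        return net

    try:
        dates = pd.to_datetime(df.iloc[:, 2], format=date_format).dt.date
    except (ValueError, TypeError) as exc:
        raise TemporalError(f"{path}: unparseable date: {exc}") from None
    timestamps: dict[Link, _dt.date] = {}
    for u, v, d in zip(sources, targets, dates):
        key = (u, v)
        if key not in timestamps or d < timestamps[key]:
            timestamps[key] = d
    net = TemporalBipartiteNetwork(
        set(sources), set(targets), set(timestamps), timestamps
    )
    logger.info(
        "loaded %s: %d rows, %d links (%d duplicate rows), |V1|=%d |V2|=%d",
        path, n_rows, net.n_links, n_rows - net.n_links,
        len(net.v1_nodes), len(net.v2_nodes),
    )
    return net


def load_adjacency_tsv(path, delimiter: str = "\t") -> BipartiteNetwork:
    """Load a labeled dense 0/1 adjacency matrix (drug–target benchmark dialect).

    First row holds the V1 (column/drug) labels, first column the V2
    (row/target) labels; each cell is 0 or 1 and a 1 becomes a link.
    """
    df = pd.read_csv(path, sep=delimiter, header=0, index_col=0, dtype=str)
    col_labels = [str(c) for c in df.columns]
    row_labels = [str(r) for r in df.index]
    if len(set(col_labels)) != len(col_labels):
        raise LabelError(f"{path}: duplicate column label")
    if len(set(row_labels)) != len(row_labels):
        raise LabelError(f"{path}: duplicate row label")
    values = df.to_numpy()
    links: set[Link] = set()
    for i, target in enumerate(row_labels):
        for j, drug in enumerate(col_labels):
            cell = str(values[i, j]).strip()
            if cell == "1":
                links.add((drug, target))
            elif cell != "0":
                raise FormatError(
                    f"{path}: non-binary cell {cell!r} at row {target!r}, column {drug!r}"
                )
    net = BipartiteNetwork(col_labels, row_labels, links)
    logger.info(
        "loaded %s: %d×%d matrix, %d links", path, len(row_labels), len(col_labels), net.n_links
    )
    return net


# ---------------------------------------------------------------------------
# path primitives and summaries


def enumerate_paths3(net: BipartiteNetwork, x: str, y: str) -> list[Path3]:
    """All unique length-3 paths x–d′–p′–y, sorted by (d′, p′).

    d′ ranges over Γ(x)\\{y} and p′ over Γ(d′)\\{x} with the closing link
    (p′, y) required, so the four nodes are pairwise distinct within sides.
    """
    net.require_sides(x, y)
    gy = net.neighbors(y)
    paths: list[Path3] = []
    for d2 in sorted(net.neighbors(x)):
        if d2 == y:
            continue
        for p2 in sorted(net.neighbors(d2)):
            if p2 == x:
                continue
            if p2 in gy:
                paths.append(Path3(source=x, via_v2=d2, via_v1=p2, target=y))
    return paths


def count_paths3_matrix(net: BipartiteNetwork) -> np.ndarray:
    """|V1|×|V2| length-3 walk counts B·Bᵀ·B.

    For every *non-adjacent* cross-set pair this equals the number of unique
    length-3 paths (every walk between non-adjacent endpoints is a path); for
    adjacent pairs the walk count may exceed the path count because a walk
    may revisit an endpoint, so those entries are not a path oracle.
    """
    B = net.biadjacency()
    return B @ B.T @ B


def network_stats(net: BipartiteNetwork) -> NetworkStats:
    """Node/link counts and mean per-side degrees (Table-1-style summary)."""
    n1, n2, m = len(net.v1_nodes), len(net.v2_nodes), net.n_links
    return NetworkStats(
        n_nodes=n1 + n2,
        n_v1=n1,
        n_v2=n2,
        n_links=m,
        mean_degree_v1=m / n1 if n1 else 0.0,
        mean_degree_v2=m / n2 if n2 else 0.0,
    )


def filter_min_conditions(net: TemporalBipartiteNetwork, k: int) -> TemporalBipartiteNetwork:
    """Keep only patients (V1) diagnosed with at least ``k`` distinct diseases.

    Diseases (V2) left without any remaining link are dropped too.  This is
    the multimorbidity cohort filter (k=4 in the study protocol).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    keep_patients = {u for u in net.v1_nodes if net.degree(u) >= k}
    links = {(u, v) for (u, v) in net.links if u in keep_patients}
    keep_diseases = {v for (_, v) in links}
    ts = {link: net.timestamp(*link) for link in links}
    out = TemporalBipartiteNetwork(keep_patients, keep_diseases, links, ts)
    logger.info(
        "min-conditions filter k=%d: %d/%d patients kept, %d links",
        k, len(keep_patients), len(net.v1_nodes), out.n_links,
    )
    return out
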