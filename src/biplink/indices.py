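"""Static similarity indices for bipartite link prediction.

All indices score a candidate pair (x ∈ V1, y ∈ V2) from local structure
only.  The building blocks are the two one-sided common-neighbour sets

* ``side1 = Γ̂(x) ∩ Γ(y) ⊆ V1``  (V1 nodes on a quadrangle through x and y)
* ``side2 = Γ(x) ∩ Γ̂(y) ⊆ V2``

whose disjoint union is the bipartite common-neighbour set, and the local
community links (LCL): the links between Γ(y) and Γ(x), which for a
non-adjacent pair are in bijection with the unique length-3 paths x–d′–p′–y.

Index vocabulary
----------------
CN1, CN2      one-sided common-neighbour counts |side1|, |side2|
CN            |side1| + |side2| (the sets are disjoint)
JC            CN / |Γ̂(x) ∪ Γ(y) ∪ Γ(x) ∪ Γ̂(y)| (intersection over union)
AA            Σ_z 1/log2|Γ(z)| over the CN set
RA            Σ_z 1/|Γ(z)| over the CN set
PA            |Γ(x)| · |Γ(y)|
LCL           # local community links = # length-3 paths (non-adjacent pair)
CAR           CN · LCL
CAA, CRA      Σ_z γ(z)/log2|Γ(z)|, Σ_z γ(z)/|Γ(z)| with γ(z) the number of
              local community links incident to z
CJC           CAR / |union set as in JC|
CPA           e_x·e_y + e_x·CAR + e_y·CAR + CAR², with e_x = |Γ(x)\\side2|
              and e_y = |Γ(y)\\side1| the degrees outside the local community
PRA           Σ over length-3 paths of 1/(|Γ(p′)|·|Γ(d′)|)
RANDOM        i.i.d. uniform scores in [0, 1) — the null used to check that
              the evaluation machinery calibrates at AUC ≈ 0.5

Two routes are provided: per-pair set-based functions (the readable
reference) and :func:`score_matrix`, a vectorised engine producing the full
|V1|×|V2| score matrix, exact for every pair *not* in E (the only pairs ever
scored: candidates are missing or held-out links, absent from the training
network).  The test suite checks the two routes agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, VocabularyError
from .network import BipartiteNetwork, Link, enumerate_paths3

INDEX_NAMES: tuple[str, ...] = (
    "CN1", "CN2", "CN", "JC", "AA", "RA", "PA",
    "LCL", "CAR", "CJC", "CAA", "CRA", "CPA", "PRA", "RANDOM",
)


@dataclass(frozen=True)
class CommonNeighbourSet:
    """The two disjoint one-sided common-neighbour sets of a pair (x, y)."""

    side1: frozenset[str]  # Γ̂(x) ∩ Γ(y) ⊆ V1
    side2: frozenset[str]  # Γ(x) ∩ Γ̂(y) ⊆ V2


def cn_sets(net: BipartiteNetwork, x: str, y: str) -> CommonNeighbourSet:
    """Compute side1 = Γ̂(x)∩Γ(y) and side2 = Γ(x)∩Γ̂(y)."""
    net.require_sides(x, y)
    return CommonNeighbourSet(
        side1=net.second_neighbors(x) & net.neighbors(y),
        side2=net.neighbors(x) & net.second_neighbors(y),
    )


def score_cn1(net: BipartiteNetwork, x: str, y: str) -> int:
    return len(cn_sets(net, x, y).side1)


def score_cn2(net: BipartiteNetwork, x: str, y: str) -> int:
    return len(cn_sets(net, x, y).side2)


def score_cn(net: BipartiteNetwork, x: str, y: str) -> int:
    """Bipartite common neighbours: |side1| + |side2| (disjoint sides)."""
    s = cn_sets(net, x, y)
    return len(s.side1) + len(s.side2)


def _union_size(net: BipartiteNetwork, x: str, y: str) -> int:
    """|Γ̂(x) ∪ Γ(y)| + |Γ(x) ∪ Γ̂(y)| — the JC denominator."""
    u1 = net.second_neighbors(x) | net.neighbors(y)
    u2 = net.neighbors(x) | net.second_neighbors(y)
    return len(u1) + len(u2)


def score_jc(net: BipartiteNetwork, x: str, y: str) -> float:
    denom = _union_size(net, x, y)
    return score_cn(net, x, y) / denom if denom else 0.0


def score_aa(net: BipartiteNetwork, x: str, y: str) -> float:
    """Adamic–Adar over the CN set: Σ 1/log2|Γ(z)|.

    Every counted z has degree ≥ 2 for a non-adjacent pair (it touches one
    endpoint and an internal path node distinct from it), so the log never
    vanishes there.
    """
    s = cn_sets(net, x, y)
    return float(sum(1.0 / np.log2(net.degree(z)) for z in s.side1 | s.side2))


def score_ra(net: BipartiteNetwork, x: str, y: str) -> float:
    """Resource allocation over the CN set: Σ 1/|Γ(z)|."""
    s = cn_sets(net, x, y)
    return float(sum(1.0 / net.degree(z) for z in s.side1 | s.side2))


def score_pa(net: BipartiteNetwork, x: str, y: str) -> int:
    """Preferential attachment: |Γ(x)| · |Γ(y)|."""
    net.require_sides(x, y)
    return net.degree(x) * net.degree(y)


def _lcl_links(net: BipartiteNetwork, x: str, y: str) -> set[Link]:
    """Local community links {(u, v) ∈ E : u ∈ Γ(y), v ∈ Γ(x)}."""
    net.require_sides(x, y)
    gx, gy = net.neighbors(x), net.neighbors(y)
    return {(u, v) for u in gy for v in net.neighbors(u) if v in gx}


def score_lcl(net: BipartiteNetwork, x: str, y: str) -> int:
    """Local community links; equals the length-3 path count for (x,y) ∉ E."""
    return len(_lcl_links(net, x, y))


def score_car(net: BipartiteNetwork, x: str, y: str) -> int:
    """CAR: CN · LCL — common neighbours weighted by community cohesion."""
    return score_cn(net, x, y) * score_lcl(net, x, y)


def _gamma(net: BipartiteNetwork, x: str, y: str) -> dict[str, int]:
    """γ(z): number of local community links incident to each CN-set node."""
    lcl = _lcl_links(net, x, y)
    counts: dict[str, int] = {}
    for u, v in lcl:
        counts[u] = counts.get(u, 0) + 1
        counts[v] = counts.get(v, 0) + 1
    return counts


def score_caa(net: BipartiteNetwork, x: str, y: str) -> float:
    return float(
        sum(g / np.log2(net.degree(z)) for z, g in _gamma(net, x, y).items())
    )


def score_cra(net: BipartiteNetwork, x: str, y: str) -> float:
    return float(sum(g / net.degree(z) for z, g in _gamma(net, x, y).items()))


def score_cjc(net: BipartiteNetwork, x: str, y: str) -> float:
    denom = _union_size(net, x, y)
    return score_car(net, x, y) / denom if denom else 0.0


def score_cpa(net: BipartiteNetwork, x: str, y: str) -> float:
    """CAR-based preferential attachment with external degrees.

    e_x (resp. e_y) counts the links of x (resp. y) leaving the local
    community, i.e. not landing in side2 (resp. side1).
    """
    s = cn_sets(net, x, y)
    car = score_car(net, x, y)
    e_x = len(net.neighbors(x) - s.side2)
    e_y = len(net.neighbors(y) - s.side1)
    return float(e_x * e_y + e_x * car + e_y * car + car * car)


def score_pra(net: BipartiteNetwork, x: str, y: str) -> float:
    """Path-based resource allocation: Σ_paths 1/(|Γ(p′)|·|Γ(d′)|).

    Each length-3 path x–d′–p′–y contributes the reciprocal product of its
    internal nodes' degrees, so paths through low-degree (specific)
    intermediaries carry more weight.
    """
    total = 0.0
    for p in enumerate_paths3(net, x, y):
        total += 1.0 / (net.degree(p.via_v1) * net.degree(p.via_v2))
    return total


_PAIR_FUNCS = {
    "CN1": score_cn1,
    "CN2": score_cn2,
    "CN": score_cn,
    "JC": score_jc,
    "AA": score_aa,
    "RA": score_ra,
    "PA": score_pa,
    "LCL": score_lcl,
    "CAR": score_car,
    "CJC": score_cjc,
    "CAA": score_caa,
    "CRA": score_cra,
    "CPA": score_cpa,
    "PRA": score_pra,
}


def score_index(
    net: BipartiteNetwork, index: str, x: str, y: str, seed: int | None = None
) -> float:
    """Score a single pair with the named index (RANDOM needs a seed)."""
    if index == "RANDOM":
        net.require_sides(x, y)
        return float(np.random.default_rng(seed).random())
    try:
        func = _PAIR_FUNCS[index]
    except KeyError:
        raise VocabularyError(
            f"unknown index {index!r}; choose from {', '.join(INDEX_NAMES)}"
        ) from None
    return float(func(net, x, y))


# ---------------------------------------------------------------------------
# vectorised engine


def _safe_inv(deg: np.ndarray) -> np.ndarray:
    w = np.zeros_like(deg, dtype=float)
    nz = deg > 0
    w[nz] = 1.0 / deg[nz]
    return w


def _safe_invlog2(deg: np.ndarray) -> np.ndarray:
    w = np.zeros_like(deg, dtype=float)
    ok = deg >= 2
    w[ok] = 1.0 / np.log2(deg[ok])
    return w


def score_matrix(
    net: BipartiteNetwork,
    index: str,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Full |V1|×|V2| score matrix for ``index``.

    Entries are exact for every pair not in E; entries at existing links are
    not meaningful for the set-based definitions (a linked endpoint slips
    into its own common-neighbour set) and must not be consumed.
    """
    if index == "RANDOM":
        if rng is None:
            rng = np.random.default_rng()
        return rng.random((len(net.v1_nodes), len(net.v2_nodes)))
    if index not in _PAIR_FUNCS:
        raise VocabularyError(
            f"unknown index {index!r}; choose from {', '.join(INDEX_NAMES)}"
        )

    B = net.biadjacency().astype(float)
    deg1 = B.sum(axis=1)  # |Γ(x)| for x ∈ V1
    deg2 = B.sum(axis=0)  # |Γ(y)| for y ∈ V2

    if index == "PA":
        return np.outer(deg1, deg2)

    A1 = B @ B.T                      # shared-neighbour counts within V1
    A2 = B.T @ B                      # within V2
    N1 = (A1 > 0).astype(float)       # reachability: u ∈ Γ̂(x)
    N2 = (A2 > 0).astype(float)

    if index == "LCL":
        return B @ B.T @ B
    if index == "CN1":
        return N1 @ B
    if index == "CN2":
        return B @ N2
    if index in ("CN", "JC", "CAR", "CJC", "CPA"):
        cn1 = N1 @ B
        cn2 = B @ N2
        cn = cn1 + cn2
        if index == "CN":
            return cn
        if index in ("JC", "CJC"):
            # |Γ̂(x) ∪ Γ(y)| + |Γ(x) ∪ Γ̂(y)| by inclusion–exclusion
            g1 = N1.sum(axis=1)  # |Γ̂(x)|
            g2 = N2.sum(axis=1)  # |Γ̂(y)|
            union = (g1[:, None] + deg2[None, :] - cn1) + (
                deg1[:, None] + g2[None, :] - cn2
            )
            numer = cn if index == "JC" else cn * (B @ B.T @ B)
            out = np.zeros_like(union)
            nz = union > 0
            out[nz] = numer[nz] / union[nz]
            return out
        lcl = B @ B.T @ B
        car = cn * lcl
        if index == "CAR":
            return car
        # CPA: external degrees e_x = |Γ(x)| − |side2|, e_y = |Γ(y)| − |side1|
        e_x = deg1[:, None] - cn2
        e_y = deg2[None, :] - cn1
        return e_x * e_y + (e_x + e_y) * car + car * car
    if index in ("RA", "AA"):
        w1 = _safe_inv(deg1) if index == "RA" else _safe_invlog2(deg1)
        w2 = _safe_inv(deg2) if index == "RA" else _safe_invlog2(deg2)
        return N1 @ (B * w1[:, None]) + (B * w2[None, :]) @ N2
    if index in ("CRA", "CAA"):
        # γ for a side1 node u is |Γ(u) ∩ Γ(x)| = A1[x, u]; side2 analogous.
        w1 = _safe_inv(deg1) if index == "CRA" else _safe_invlog2(deg1)
        w2 = _safe_inv(deg2) if index == "CRA" else _safe_invlog2(deg2)
        return A1 @ (B * w1[:, None]) + (B * w2[None, :]) @ A2
    # PRA: Σ_{d′,p′} B[x,d′] B[p′,d′] B[p′,y] / (deg1[p′] · deg2[d′])
    W = B * _safe_inv(deg1)[:, None]
    return (B * _safe_inv(deg2)[None, :]) @ (W.T @ B)


# ---------------------------------------------------------------------------
# bulk scoring


@dataclass
class ScoreTable:
    """Deterministic list of scored candidate pairs for one index."""

    index: str
    pairs: list[Link]
    scores: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Rows source,target,score,index,rank; rank by score desc, pair asc."""
        df = pd.DataFrame(
            {
                "source": [p[0] for p in self.pairs],
                "target": [p[1] for p in self.pairs],
                "score": self.scores,
                "index": self.index,
            }
        )
        order = sorted(
            range(len(df)), key=lambda i: (-self.scores[i], self.pairs[i])
        )
        rank = np.empty(len(df), dtype=int)
        rank[order] = np.arange(1, len(df) + 1)
        df["rank"] = rank
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def score_all(
    net: BipartiteNetwork,
    index: str,
    candidates: Sequence[Link] | Literal["all-nonexistent"] = "all-nonexistent",
    seed: int | None = None,
    missing_only: bool = True,
) -> ScoreTable:
    """Score a candidate list (or every nonexistent pair E′ = U \\ E).

    With ``missing_only`` (the default) an explicit candidate already present
    in E raises :class:`ContractError` — existing links are not predictions.
    """
    if isinstance(candidates, str):
        if candidates != "all-nonexistent":
            raise VocabularyError(f"unknown candidate mode {candidates!r}")
        pairs = net.nonexistent_pairs()
    else:
        pairs = [(str(u), str(v)) for u, v in candidates]
        for u, v in pairs:
            net.require_sides(u, v)
            if missing_only and net.has_link(u, v):
                raise ContractError(f"candidate ({u!r}, {v!r}) is an existing link")
    if index not in INDEX_NAMES:
        raise VocabularyError(
            f"unknown index {index!r}; choose from {', '.join(INDEX_NAMES)}"
        )
    M = score_matrix(net, index, rng=np.random.default_rng(seed))
    row = {u: i for i, u in enumerate(net.v1_nodes)}
    col = {v: j for j, v in enumerate(net.v2_nodes)}
    scores = np.array([M[row[u], col[v]] for u, v in pairs], dtype=float)
    return ScoreTable(index=index, pairs=pairs, scores=scores)
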