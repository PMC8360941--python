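"""Temporal link prediction: disease-transition probabilities and TPRA.

The temporal index extends path-based resource allocation to time-stamped
patient–disease networks.  A disease×disease matrix M estimates

    M(i, j) = Pr(patient is later diagnosed with j | diagnosed with i)

and each length-3 path p–d′–p′–d is weighted by M(d′, d) on top of the
inverse internal-degree product:

    S_TPRA(p, d) = Σ_paths M(d′, d) / (|Γ(p′)| · |Γ(d′)|)

With M ≡ 1 the index reduces exactly to PRA.  M is always estimated from
*training* links only — estimating it from the full network would leak the
probe links being predicted.

Two estimation modes are supported:

* ``all_patients``: M(i,j) = #{patients with i whose j-diagnosis is strictly
  later} / #{patients with i}; low values may simply reflect patients never
  tested for j.
* ``both_diagnosed``: condition on patients carrying both diseases, so
  M(i,j) answers "given both, which came first?"; without same-date ties
  M(i,j) + M(j,i) = 1.

Same-date pairs carry no ordering evidence; by default they count in the
denominator only (``tie_policy="strict"``); ``"half"`` gives half credit to
both directions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, VocabularyError
from .indices import ScoreTable
from .network import BipartiteNetwork, Link, TemporalBipartiteNetwork, enumerate_paths3

Mode = Literal["all_patients", "both_diagnosed"]
MODES: tuple[str, ...] = ("all_patients", "both_diagnosed")


@dataclass
class CondProbMatrix:
    """Disease×disease conditional diagnosis-order probabilities.

    ``values[i, j]`` estimates the probability that a patient diagnosed with
    disease ``diseases[i]`` is later diagnosed with ``diseases[j]``.  The
    integer ``numerator``/``denominator`` count matrices that produced each
    entry are retained; entries with a zero denominator are 0, and the
    diagonal is 0 by convention (no self-transition).
    """

    diseases: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    mode: str
    numerator: np.ndarray = field(repr=False)
    denominator: np.ndarray = field(repr=False)
    tie_policy: str = "strict"
    smoothing: float = 0.0

    def __post_init__(self) -> None:
        d = len(self.diseases)
        assert self.values.shape == (d, d)
        assert np.all(self.values >= 0) and np.all(self.values <= 1)

    def index_of(self, disease: str) -> int:
        try:
            return self.diseases.index(disease)
        except ValueError:
            raise CoverageError(f"disease {disease!r} not covered by the matrix") from None

    def prob(self, i: str, j: str) -> float:
        return float(self.values[self.index_of(i), self.index_of(j)])

    @classmethod
    def uniform(cls, diseases: Sequence[str], value: float = 1.0) -> "CondProbMatrix":
        """Constant matrix (zero diagonal); value=1 makes TPRA collapse to PRA."""
        d = tuple(str(x) for x in diseases)
        vals = np.full((len(d), len(d)), float(value))
        np.fill_diagonal(vals, 0.0)
        return cls(
            diseases=d,
            values=vals,
            mode="uniform",
            numerator=np.zeros((len(d), len(d)), dtype=np.int64),
            denominator=np.zeros((len(d), len(d)), dtype=np.int64),
        )

    def to_csv(self, path, sidecar: "str | None" = None) -> None:
        """Write the matrix as labeled CSV, plus a JSON sidecar of metadata."""
        pd.DataFrame(self.values, index=self.diseases, columns=self.diseases).to_csv(path)
        if sidecar is not None:
            meta = {
                "mode": self.mode,
                "tie_policy": self.tie_policy,
                "smoothing": self.smoothing,
                "diseases": list(self.diseases),
                "numerator": self.numerator.tolist(),
                "denominator": self.denominator.tolist(),
            }
            with open(sidecar, "w") as fh:
                json.dump(meta, fh, indent=1)


def estimate_condprob(
    net: TemporalBipartiteNetwork,
    mode: Mode = "all_patients",
    tie_policy: str = "strict",
    smoothing: float = 0.0,
) -> CondProbMatrix:
    """Estimate the disease-transition matrix from a time-stamped network.

    Pass the *training* network during evaluation, never the full one.
    Optional additive ``smoothing`` is applied as (num + s) / (den + 2s)
    wherever the unsmoothed denominator is positive.
    """
    if mode not in MODES:
        raise VocabularyError(f"unknown mode {mode!r}; choose from {MODES}")
    if tie_policy not in ("strict", "half"):
        raise VocabularyError(f"unknown tie policy {tie_policy!r}")
    diseases = net.v2_nodes
    d = len(diseases)
    col = {v: j for j, v in enumerate(diseases)}
    num = np.zeros((d, d), dtype=float)
    if mode == "all_patients":
        den_i = np.zeros(d, dtype=np.int64)
    else:
        den = np.zeros((d, d), dtype=np.int64)

    for p in net.v1_nodes:
        diags = sorted(net.neighbors(p))
        idx = [col[v] for v in diags]
        dates = [net.timestamp(p, v) for v in diags]
        if mode == "all_patients":
            for i in idx:
                den_i[i] += 1
        for a in range(len(idx)):
            for b in range(len(idx)):
                if a == b:
                    continue
                i, j = idx[a], idx[b]
                if mode == "both_diagnosed":
                    den[i, j] += 1
                if dates[a] < dates[b]:
                    num[i, j] += 1.0
                elif dates[a] == dates[b] and tie_policy == "half":
                    num[i, j] += 0.5

    if mode == "all_patients":
        den = np.repeat(den_i[:, None], d, axis=1)
    num_int = np.round(num).astype(np.int64)  # counts; .5 halves round for record
    values = np.zeros((d, d), dtype=float)
    pos = den > 0
    if smoothing > 0:
        values[pos] = (num[pos] + smoothing) / (den[pos] + 2.0 * smoothing)
    else:
        values[pos] = num[pos] / den[pos]
    np.fill_diagonal(values, 0.0)
    return CondProbMatrix(
        diseases=diseases,
        values=values,
        mode=mode,
        numerator=num_int,
        denominator=np.asarray(den),
        tie_policy=tie_policy,
        smoothing=smoothing,
    )


# ---------------------------------------------------------------------------
# scoring


def score_tpra(
    net: BipartiteNetwork, M: CondProbMatrix, p: str, d: str
) -> float:
    """Temporal path-based resource allocation for patient p and disease d.

    Sums M(d′, d) / (|Γ(p′)|·|Γ(d′)|) over the unique length-3 paths
    p–d′–p′–d of the (training) network.
    """
    net.require_sides(p, d)
    j = M.index_of(d)
    total = 0.0
    for path in enumerate_paths3(net, p, d):
        i = M.index_of(path.via_v2)
        total += float(M.values[i, j]) / (
            net.degree(path.via_v1) * net.degree(path.via_v2)
        )
    return total


def tpra_matrix(net: BipartiteNetwork, M: CondProbMatrix) -> np.ndarray:
    """Vectorised |V1|×|V2| TPRA scores (exact for pairs not in E).

    TPRA[x, y] = Σ_{d′} (B/deg2)[x, d′] · ((B/deg1)ᵀ B)[d′, y] · M[d′, y].
    """
    for v in net.v2_nodes:
        M.index_of(v)
    B = net.biadjacency().astype(float)
    deg1 = B.sum(axis=1)
    deg2 = B.sum(axis=0)
    inv1 = np.zeros_like(deg1)
    inv1[deg1 > 0] = 1.0 / deg1[deg1 > 0]
    inv2 = np.zeros_like(deg2)
    inv2[deg2 > 0] = 1.0 / deg2[deg2 > 0]
    perm = [M.index_of(v) for v in net.v2_nodes]
    Msub = M.values[np.ix_(perm, perm)]  # rows/cols in this network's order
    W = B * inv1[:, None]
    return (B * inv2[None, :]) @ ((W.T @ B) * Msub)


@dataclass
class TemporalScoreTable(ScoreTable):
    """ScoreTable carrying the conditional-probability matrix used."""

    condprob: CondProbMatrix | None = None


def score_all_temporal(
    net: BipartiteNetwork,
    M: CondProbMatrix,
    candidates: "Sequence[Link] | str" = "all-nonexistent",
) -> TemporalScoreTable:
    """TPRA scores over a candidate list (or all nonexistent pairs)."""
    if isinstance(candidates, str):
        if candidates != "all-nonexistent":
            raise VocabularyError(f"unknown candidate mode {candidates!r}")
        pairs = net.nonexistent_pairs()
    else:
        pairs = [(str(u), str(v)) for u, v in candidates]
        for u, v in pairs:
            net.require_sides(u, v)
    S = tpra_matrix(net, M)
    row = {u: i for i, u in enumerate(net.v1_nodes)}
    col = {v: j for j, v in enumerate(net.v2_nodes)}
    scores = np.array([S[row[u], col[v]] for u, v in pairs], dtype=float)
    return TemporalScoreTable(index="TPRA", pairs=pairs, scores=scores, condprob=M)
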