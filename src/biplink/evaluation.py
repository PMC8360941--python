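"""Train/probe splitting, AUC/precision metrics, and repeated-run benchmarks.

The evaluation protocol hides a fraction of the observed links (the probe
set E^P), scores every candidate pair on the training network E^T, and asks
how well each index separates the hidden links from the never-observed
pairs E′ = U \\ E (U being the full |V1|×|V2| pair universe).

Two AUC routes are kept deliberately separate:

* :func:`auc_pairwise` — the pairwise-comparison estimator
  AUC = (n′ + 0.5 n″)/n over probe-vs-nonexistent score comparisons,
  exhaustive or sampled;
* :func:`auroc_full` — the rank-based ROC area over the full ranking,
  delegated to scikit-learn.

With exhaustive comparisons and midrank tie handling the two coincide
(the Mann–Whitney identity); the test suite asserts this.

For temporal networks the split respects causality: a probe link is always
its patient's latest-dated diagnosis, so the training data never contains
information from the future of a held-out link.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .errors import EvaluationError, ParameterError, TemporalError, VocabularyError
from .indices import INDEX_NAMES, score_matrix
from .network import BipartiteNetwork, Link, TemporalBipartiteNetwork
from .temporal import estimate_condprob, tpra_matrix

logger = logging.getLogger(__name__)

#: indices acceptable to run_benchmark (TPRA needs a temporal network)
BENCHMARK_INDICES: tuple[str, ...] = INDEX_NAMES + ("TPRA",)

EXHAUSTIVE_LIMIT = 10_000_000
SAMPLED_N = 1_000_000


@dataclass(frozen=True)
class LinkSplit:
    """Partition of observed links into training and probe sets.

    ``train`` ∪ ``probe`` = E with empty intersection; ``nonexistent`` is
    E′ = U \\ E.  Validated at construction.
    """

    train: frozenset[Link]
    probe: frozenset[Link]
    nonexistent: frozenset[Link]
    seed: int
    protocol: str

    def __post_init__(self) -> None:
        if self.train & self.probe:
            raise EvaluationError("train and probe sets overlap")
        observed = self.train | self.probe
        if observed & self.nonexistent:
            raise EvaluationError("nonexistent set intersects observed links")


def split_static(net: BipartiteNetwork, probe_fraction: float, seed: int) -> LinkSplit:
    """Uniformly random split with |E^P| = round(probe_fraction · |E|)."""
    if not 0.0 < probe_fraction < 1.0:
        raise ParameterError("probe_fraction must lie strictly between 0 and 1")
    links = sorted(net.links)
    n_probe = round(probe_fraction * len(links))
    if n_probe == 0 or n_probe == len(links):
        raise ParameterError(
            f"probe_fraction={probe_fraction} leaves an empty probe or training set"
        )
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(links))
    probe = frozenset(links[i] for i in idx[:n_probe])
    train = frozenset(links[i] for i in idx[n_probe:])
    return LinkSplit(
        train=train,
        probe=probe,
        nonexistent=frozenset(net.nonexistent_pairs()),
        seed=seed,
        protocol="static_random",
    )


def _latest_link(net: TemporalBipartiteNetwork, patient: str) -> Link:
    """The patient's latest-dated link; date ties broken by smallest disease id."""
    diseases = sorted(net.neighbors(patient))
    latest = max(net.timestamp(patient, v) for v in diseases)
    best = min(v for v in diseases if net.timestamp(patient, v) == latest)
    return (patient, best)


def split_temporal(
    net: TemporalBipartiteNetwork, probe_fraction: float, seed: int
) -> LinkSplit:
    """Leave-latest-diagnosis-out split.

    Patients (with at least two diagnoses) are drawn at random without
    replacement; each drawn patient contributes exactly its latest-dated
    link to the probe set, all its other links to training, until
    |E^P| = round(probe_fraction · |E|).  Links of undrawn patients all go
    to training.
    """
    if not 0.0 < probe_fraction < 1.0:
        raise ParameterError("probe_fraction must lie strictly between 0 and 1")
    n_probe = round(probe_fraction * net.n_links)
    if n_probe == 0:
        raise ParameterError("probe_fraction rounds to an empty probe set")
    eligible = [p for p in net.v1_nodes if net.degree(p) >= 2]
    if len(eligible) < n_probe:
        raise ParameterError(
            f"need {n_probe} patients with >= 2 diagnoses, only {len(eligible)} available"
        )
    rng = np.random.default_rng(seed)
    chosen = [eligible[i] for i in rng.permutation(len(eligible))[:n_probe]]
    probe = frozenset(_latest_link(net, p) for p in chosen)
    train = frozenset(net.links - probe)
    return LinkSplit(
        train=train,
        probe=probe,
        nonexistent=frozenset(net.nonexistent_pairs()),
        seed=seed,
        protocol="temporal_leave_latest",
    )


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class AUCResult:
    """Pairwise AUC with its comparison decomposition (n′ wins, n″ ties)."""

    n: int
    n_higher: float
    n_tied: float
    auc: float

    def __post_init__(self) -> None:
        assert 0.0 <= self.auc <= 1.0
        assert self.n_higher + self.n_tied <= self.n + 1e-9


def auc_pairwise(
    probe_scores: np.ndarray,
    nonexistent_scores: np.ndarray,
    n_comparisons: "int | str" = "exhaustive",
    seed: int | None = None,
) -> AUCResult:
    """AUC = (n′ + 0.5 n″)/n over probe-vs-nonexistent comparisons.

    ``"exhaustive"`` compares every pair (vectorised via sorted search);
    an integer draws that many independent uniform comparisons.
    """
    p = np.asarray(probe_scores, dtype=float)
    q = np.asarray(nonexistent_scores, dtype=float)
    if p.size == 0 or q.size == 0:
        raise EvaluationError("probe and nonexistent score sets must be non-empty")
    if n_comparisons == "exhaustive":
        qs = np.sort(q)
        lo = np.searchsorted(qs, p, side="left")   # strictly below each probe score
        hi = np.searchsorted(qs, p, side="right")
        n_higher = float(lo.sum())
        n_tied = float((hi - lo).sum())
        n = p.size * q.size
    elif isinstance(n_comparisons, (int, np.integer)) and n_comparisons >= 1:
        rng = np.random.default_rng(seed)
        n = int(n_comparisons)
        ps = p[rng.integers(0, p.size, n)]
        qs = q[rng.integers(0, q.size, n)]
        n_higher = float(np.count_nonzero(ps > qs))
        n_tied = float(np.count_nonzero(ps == qs))
    else:
        raise ParameterError(f"invalid n_comparisons: {n_comparisons!r}")
    return AUCResult(n=n, n_higher=n_higher, n_tied=n_tied, auc=(n_higher + 0.5 * n_tied) / n)


def auroc_full(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based ROC area (midrank ties) over the full candidate ranking."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise EvaluationError("labels must contain both classes")
    return float(roc_auc_score(labels.astype(int), np.asarray(scores, dtype=float)))


def precision_recall_f(
    scores: np.ndarray, labels: np.ndarray, k: int
) -> tuple[float, float, float]:
    """Top-k precision, recall and F-score (harmonic mean; 0 when p+r = 0).

    Ties are broken deterministically by candidate position, so the same
    inputs always select the same top-k set.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if k < 1 or k > scores.size:
        raise ParameterError(f"k={k} outside [1, {scores.size}]")
    order = np.lexsort((np.arange(scores.size), -scores))
    tp = int(labels[order[:k]].sum())
    n_pos = int(labels.sum())
    precision = tp / k
    recall = tp / n_pos if n_pos else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


# ---------------------------------------------------------------------------
# repeated-run benchmark


@dataclass
class EvalReport:
    """Per-index mean ± sd of each metric over repeated random splits."""

    runs: int
    seeds: list[int]
    k: int
    per_run: pd.DataFrame = field(repr=False)  # columns: run, index, metric values
    protocol: str = ""
    probe_fraction: float = 0.1

    def summary(self) -> pd.DataFrame:
        g = self.per_run.groupby("index", sort=False)
        means = g[["auc", "auroc", "precision", "recall", "f_score"]].mean()
        sds = g[["auc", "auroc", "precision", "recall", "f_score"]].std(ddof=0)
        out = means.join(sds, lsuffix="_mean", rsuffix="_sd")
        return out[sorted(out.columns)]

    def mean(self, index: str, metric: str = "auc") -> float:
        sub = self.per_run[self.per_run["index"] == index]
        if sub.empty:
            raise KeyError(index)
        return float(sub[metric].mean())

    def to_csv(self, path) -> None:
        self.summary().to_csv(path)

    def to_json(self, path) -> None:
        payload = {
            "runs": self.runs,
            "seeds": self.seeds,
            "k": self.k,
            "protocol": self.protocol,
            "probe_fraction": self.probe_fraction,
            "per_run": self.per_run.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _pair_indexer(net: BipartiteNetwork):
    row = {u: i for i, u in enumerate(net.v1_nodes)}
    col = {v: j for j, v in enumerate(net.v2_nodes)}

    def take(M: np.ndarray, pairs: list[Link]) -> np.ndarray:
        if not pairs:
            return np.empty(0)
        r = np.fromiter((row[u] for u, _ in pairs), dtype=np.intp, count=len(pairs))
        c = np.fromiter((col[v] for _, v in pairs), dtype=np.intp, count=len(pairs))
        return M[r, c]

    return take


def run_benchmark(
    net: "BipartiteNetwork | TemporalBipartiteNetwork",
    indices: list[str],
    probe_fraction: float = 0.1,
    runs: int = 100,
    seed: int = 0,
    k: int | None = None,
    condprob_mode: str = "all_patients",
    keep_splits: bool = False,
) -> EvalReport:
    """Benchmark indices over repeated train/probe splits.

    Every index is evaluated on the *same* split within a run; the
    conditional-probability matrix for TPRA is re-estimated from that run's
    training links.  AUC uses exhaustive comparisons when
    |E^P|·|E′| ≤ 10⁷, else 10⁶ sampled comparisons; ``k`` defaults to
    |E^P|.  Metrics are reported per run; a single run reports sd = 0.
    """
    if runs < 1:
        raise ParameterError("runs must be >= 1")
    temporal = isinstance(net, TemporalBipartiteNetwork)
    for ix in indices:
        if ix not in BENCHMARK_INDICES:
            raise VocabularyError(f"unknown index {ix!r}")
        if ix == "TPRA" and not temporal:
            raise TemporalError("TPRA requires a temporal network")

    master = np.random.default_rng(seed)
    run_seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=runs)]
    records: list[dict] = []
    splits: list[LinkSplit] = []
    for run, run_seed in enumerate(run_seeds):
        if temporal:
            split = split_temporal(net, probe_fraction, run_seed)
        else:
            split = split_static(net, probe_fraction, run_seed)
        if keep_splits:
            splits.append(split)
        train_net = net.subnetwork(split.train)
        probe = sorted(split.probe)
        nonexistent = sorted(split.nonexistent)
        take = _pair_indexer(train_net)
        labels = np.concatenate(
            [np.ones(len(probe), dtype=bool), np.zeros(len(nonexistent), dtype=bool)]
        )
        kk = k if k is not None else len(probe)
        exhaustive = len(probe) * len(nonexistent) <= EXHAUSTIVE_LIMIT
        if temporal and "TPRA" in indices:
            train_temporal = TemporalBipartiteNetwork(
                net.v1_nodes, net.v2_nodes, split.train,
                {l: net.timestamp(*l) for l in split.train},
            )
            M = estimate_condprob(train_temporal, mode=condprob_mode)
        rng = np.random.default_rng(run_seed + 1)
        for ix in indices:
            if ix == "TPRA":
                S = tpra_matrix(train_net, M)
            else:
                S = score_matrix(train_net, ix, rng=rng)
            sp = take(S, probe)
            sq = take(S, nonexistent)
            auc = auc_pairwise(
                sp, sq,
                "exhaustive" if exhaustive else SAMPLED_N,
                seed=run_seed + 2,
            ).auc
            all_scores = np.concatenate([sp, sq])
            auroc = auroc_full(all_scores, labels)
            p, r, f = precision_recall_f(all_scores, labels, kk)
            records.append(
                {
                    "run": run, "index": ix, "auc": auc, "auroc": auroc,
                    "precision": p, "recall": r, "f_score": f,
                }
            )
    report = EvalReport(
        runs=runs,
        seeds=run_seeds,
        k=k if k is not None else -1,
        per_run=pd.DataFrame.from_records(records),
        protocol="temporal_leave_latest" if temporal else "static_random",
        probe_fraction=probe_fraction,
    )
    if keep_splits:
        report.splits = splits  # type: ignore[attr-defined]
    return report


# ---------------------------------------------------------------------------
# degree-bias and coverage analyses


def _correct_predictions(
    pairs: list[Link], scores: np.ndarray, labels: np.ndarray
) -> list[Link]:
    """Probe links in ranked order (score desc, pair id asc tie-break)."""
    order = sorted(range(len(pairs)), key=lambda i: (-scores[i], pairs[i]))
    return [pairs[i] for i in order if labels[i]]


def degree_bias_analysis(
    pairs: list[Link],
    scores: np.ndarray,
    labels: np.ndarray,
    net: BipartiteNetwork,
) -> pd.DataFrame:
    """First-correct-prediction order vs degree rank, per disease.

    Walking the ranking from the top, the i-th correct prediction has order
    i; for each disease the order of its first correct prediction is
    reported against the disease's rank when all V2 nodes are sorted
    ascending by degree (rank 1 = lowest degree).  A method biased toward
    hubs fills the low orders with high degree ranks.
    """
    asc = sorted(net.v2_nodes, key=lambda v: (net.degree(v), v))
    degree_rank = {v: r + 1 for r, v in enumerate(asc)}
    rows = []
    seen: set[str] = set()
    for order, (_, disease) in enumerate(
        _correct_predictions(pairs, np.asarray(scores, float), np.asarray(labels, bool)),
        start=1,
    ):
        if disease not in seen:
            seen.add(disease)
            rows.append(
                {
                    "disease": disease,
                    "first_correct_order": order,
                    "degree_rank": degree_rank[disease],
                }
            )
    return pd.DataFrame(rows, columns=["disease", "first_correct_order", "degree_rank"])


def unique_disease_coverage(
    pairs: list[Link],
    scores: np.ndarray,
    labels: np.ndarray,
    net: BipartiteNetwork,
    top_fraction: float = 0.5,
) -> tuple[int, int]:
    """Distinct diseases among the top fraction of correct predictions.

    Returns ``(count, lowest_degree_rank)`` where the rank refers to the
    descending-degree ordering of V2 (rank 1 = highest degree); a large
    rank means the method reached down to rare diseases.  With no correct
    predictions returns (0, 0) and logs a warning.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ParameterError("top_fraction must lie in (0, 1]")
    correct = _correct_predictions(pairs, np.asarray(scores, float), np.asarray(labels, bool))
    if not correct:
        logger.warning("no correct predictions; coverage undefined")
        return (0, 0)
    top = correct[: int(np.ceil(top_fraction * len(correct)))]
    desc = sorted(net.v2_nodes, key=lambda v: (-net.degree(v), v))
    rank_desc = {v: r + 1 for r, v in enumerate(desc)}
    diseases = {v for (_, v) in top}
    return (len(diseases), max(rank_desc[v] for v in diseases))
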