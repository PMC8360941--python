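"""Synthetic networks and cohorts for testing and benchmarking.

Three generators:

* :func:`make_fig1_fixture` — the small worked-example graph used throughout
  the documentation (5 patients a–e, 3 diseases 1–3, 11 links).  The edge
  set is uniquely determined by the printed properties of the example (the
  one-sided common-neighbour counts 3 and 2 for the pair (e, 1), the four
  length-3 paths between e and 1, and the fact that adding the link (a, 3)
  creates exactly one new path while leaving the common-neighbour count at
  5); the constructor asserts every one of those properties.

* :func:`random_bipartite` — Erdős–Rényi-style bipartite graphs, the
  substrate for exhaustive oracle checks.

* :func:`simulate_cohort` — a temporal multimorbidity cohort with planted
  disease-transition structure.  Each patient walks through discrete time
  steps; at every step each not-yet-diagnosed disease j is acquired with
  probability  1 − (1 − baseline_j) · Π_{i∈current} (1 − T[i, j]),
  i.e. a per-step baseline hazard plus independent promotion by each disease
  already carried.  Acquisitions are dated sequentially (same-step
  acquisitions get distinct consecutive dates in disease-id order, so the
  strict-before tie policy is exercised but not degenerate; a ``same_day``
  mode collapses them onto one date to test tie handling).  Patients ending
  below ``min_conditions`` diagnoses are dropped, mirroring the cohort
  filter applied to real multimorbidity data.

The simulator is deliberately simple: no demographics, mortality or
censoring, and acquisition hazards are stationary in time.  What it shares
with real multimorbidity data is the bipartite patient–disease structure,
heterogeneous disease prevalence, and a directed transition signal that a
temporal index can exploit but a purely structural one cannot.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import SpecError
from .network import BipartiteNetwork, TemporalBipartiteNetwork

logger = logging.getLogger(__name__)

#: The 11 forced links of the worked-example graph.
FIG1_LINKS: frozenset[tuple[str, str]] = frozenset(
    {
        ("a", "1"), ("a", "2"),
        ("b", "1"), ("b", "2"), ("b", "3"),
        ("c", "2"), ("c", "3"),
        ("d", "1"), ("d", "3"),
        ("e", "2"), ("e", "3"),
    }
)


def make_fig1_fixture() -> BipartiteNetwork:
    """Build the 8-node, 11-link worked-example graph and verify it.

    Asserts, at construction, every printed property of the example:
    |Γ̂(e)∩Γ(1)| = 3, |Γ(e)∩Γ̂(1)| = 2, bipartite CN = 5, exactly the four
    paths {e,2,a,1}, {e,2,b,1}, {e,3,b,1}, {e,3,d,1} between e and 1, and
    that adding (a, 3) yields 5 paths while CN stays 5.
    """
    net = BipartiteNetwork("abcde", "123", FIG1_LINKS)
    assert len(net.v1_nodes) + len(net.v2_nodes) == 8 and net.n_links == 11
    assert not net.has_link("e", "1") and not net.has_link("a", "3")
    side1 = net.second_neighbors("e") & net.neighbors("1")
    side2 = net.neighbors("e") & net.second_neighbors("1")
    assert len(side1) == 3 and len(side2) == 2 and len(side1) + len(side2) == 5
    from .network import enumerate_paths3  # local import avoids cycle at module load

    paths = enumerate_paths3(net, "e", "1")
    assert [(p.via_v2, p.via_v1) for p in paths] == [
        ("2", "a"), ("2", "b"), ("3", "b"), ("3", "d")
    ]
    augmented = net.with_link("a", "3")
    assert len(enumerate_paths3(augmented, "e", "1")) == 5
    aug1 = augmented.second_neighbors("e") & augmented.neighbors("1")
    aug2 = augmented.neighbors("e") & augmented.second_neighbors("1")
    assert len(aug1) + len(aug2) == 5
    return net


def random_bipartite(
    n1: int, n2: int, link_probability: float, seed: int | None = None
) -> BipartiteNetwork:
    """Bipartite G(n1, n2, p): each cross-set pair linked independently."""
    if n1 < 1 or n2 < 1:
        raise ValueError("node counts must be >= 1")
    if not 0.0 <= link_probability <= 1.0:
        raise ValueError("link_probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n1)), len(str(n2)))
    v1 = [f"u{i:0{width}d}" for i in range(n1)]
    v2 = [f"w{j:0{width}d}" for j in range(n2)]
    mask = rng.random((n1, n2)) < link_probability
    links = {(v1[i], v2[j]) for i, j in zip(*np.nonzero(mask))}
    return BipartiteNetwork(v1, v2, links)


@dataclass
class CohortSpec:
    """Parameters of a synthetic temporal multimorbidity cohort.

    Attributes
    ----------
    n_patients:
        Cohort size before the minimum-conditions filter.
    diseases:
        Ordered disease identifiers.
    baseline_prevalence:
        Per-disease, per-step probability of spontaneous first diagnosis.
    transition:
        Planted matrix T with T[i, j] the per-step probability that carrying
        disease i promotes acquisition of disease j (zero diagonal).
    min_conditions:
        Patients with fewer distinct diagnoses are dropped (4 mirrors the
        multimorbidity study protocol).
    horizon:
        Number of discrete time steps simulated per patient.
    seed:
        Generator seed; identical spec + seed reproduces the cohort exactly.
    same_day:
        If True, same-step acquisitions share one date (tie-policy testing).
    """

    n_patients: int
    diseases: tuple[str, ...]
    baseline_prevalence: np.ndarray = field(repr=False)
    transition: np.ndarray = field(repr=False)
    min_conditions: int = 4
    horizon: int = 10
    seed: int = 0
    same_day: bool = False
    start_date: _dt.date = _dt.date(2000, 1, 1)

    def __post_init__(self) -> None:
        self.diseases = tuple(str(d) for d in self.diseases)
        self.baseline_prevalence = np.asarray(self.baseline_prevalence, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        d = len(self.diseases)
        if self.baseline_prevalence.shape != (d,):
            raise SpecError("baseline_prevalence must have one entry per disease")
        if self.transition.shape != (d, d):
            raise SpecError("transition must be |D|×|D|")
        if np.any(self.baseline_prevalence < 0) or np.any(self.baseline_prevalence > 1):
            raise SpecError("prevalence entries must lie in [0, 1]")
        if np.any(self.transition < 0) or np.any(self.transition > 1):
            raise SpecError("transition entries must lie in [0, 1]")
        if np.any(np.diag(self.transition) != 0):
            raise SpecError("transition diagonal must be zero")
        if self.horizon < self.min_conditions:
            raise SpecError("horizon must be >= min_conditions")

    def to_json(self, path) -> None:
        meta = {
            "n_patients": self.n_patients,
            "diseases": list(self.diseases),
            "baseline_prevalence": self.baseline_prevalence.tolist(),
            "transition": self.transition.tolist(),
            "min_conditions": self.min_conditions,
            "horizon": self.horizon,
            "seed": self.seed,
            "same_day": self.same_day,
            "start_date": self.start_date.isoformat(),
        }
        with open(path, "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CohortSpec":
        with open(path) as fh:
            meta = json.load(fh)
        meta["diseases"] = tuple(meta["diseases"])
        meta["start_date"] = _dt.date.fromisoformat(meta["start_date"])
        return cls(**meta)


def default_cohort_spec(n_patients: int = 500, seed: int = 0, **overrides) -> CohortSpec:
    """A 20-disease cohort with a planted transition backbone.

    Five common "entry" conditions (per-step baseline 0.05) seed disease
    careers; every disease strongly promotes one downstream disease
    (T = 0.40 along i → i+5) with a weak background hazard (0.01)
    elsewhere.  Eight steps with a minimum of four conditions keep the mean
    patient degree in the 6–7 range typical of filtered multimorbidity
    cohorts, so a 10% link probe draws only part of the patient pool and
    repeated splits genuinely differ.
    """
    d = 20
    diseases = tuple(f"d{i:02d}" for i in range(d))
    baseline = np.full(d, 0.01)
    baseline[:5] = 0.05
    T = np.zeros((d, d))
    for i in range(d - 5):
        T[i, i + 5] = 0.40
    spec = CohortSpec(
        n_patients=n_patients,
        diseases=diseases,
        baseline_prevalence=baseline,
        transition=T,
        min_conditions=4,
        horizon=8,
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(spec, k, v)
    spec.__post_init__()
    return spec


@dataclass
class GenerationLog:
    """Realized statistics of a simulated cohort.

    ``realized_num[i, j]`` counts retained patients diagnosed with disease i
    strictly before disease j; ``realized_den[i]`` counts retained patients
    with disease i.  Their ratio is the realized conditional frequency the
    estimator should recover.  Computed with plain per-patient loops over
    the event stream, independent of the network API.
    """

    realized_num: np.ndarray
    realized_den: np.ndarray
    n_generated: int
    n_dropped: int

    def realized_condprob(self) -> np.ndarray:
        out = np.zeros_like(self.realized_num, dtype=float)
        pos = self.realized_den > 0
        out[pos, :] = self.realized_num[pos, :] / self.realized_den[pos, None]
        np.fill_diagonal(out, 0.0)
        return out


def simulate_cohort(spec: CohortSpec) -> TemporalBipartiteNetwork:
    """Simulate a temporal patient–disease cohort from ``spec``.

    Returns a :class:`TemporalBipartiteNetwork` whose ``generation_log``
    attribute holds a :class:`GenerationLog` with the realized transition
    frequencies and drop counts.  Raises :class:`SpecError` when no patient
    can reach ``min_conditions`` (e.g. all hazards zero).
    """
    rng = np.random.default_rng(spec.seed)
    d = len(spec.diseases)
    max_reachable = float(np.sum((spec.baseline_prevalence > 0) | (spec.transition > 0).any(axis=0)))
    if max_reachable < spec.min_conditions:
        raise SpecError(
            f"at most {int(max_reachable)} diseases are ever acquirable; "
            f"min_conditions={spec.min_conditions} is unreachable"
        )

    links: dict[tuple[str, str], _dt.date] = {}
    patient_events: list[list[tuple[int, int]]] = []  # per retained patient: (disease idx, order)
    width = len(str(max(spec.n_patients - 1, 1)))
    n_dropped = 0
    retained_ids: list[str] = []
    for pnum in range(spec.n_patients):
        acquired: list[int] = []  # disease indices in acquisition order
        have = np.zeros(d, dtype=bool)
        order_of: dict[int, int] = {}
        counter = 0
        for step in range(spec.horizon):
            # acquisition hazard for each not-yet-diagnosed disease
            surv = 1.0 - spec.baseline_prevalence
            if acquired:
                surv = surv * np.prod(1.0 - spec.transition[acquired, :], axis=0)
            hazard = 1.0 - surv
            draws = rng.random(d)
            new = np.flatnonzero((~have) & (draws < hazard))
            for j in new:  # disease-id order == index order
                have[j] = True
                acquired.append(int(j))
                order_of[int(j)] = counter if not spec.same_day else step
                counter += 1
        if len(acquired) < spec.min_conditions:
            n_dropped += 1
            continue
        pid = f"p{pnum:0{width}d}"
        retained_ids.append(pid)
        patient_events.append([(j, order_of[j]) for j in acquired])
        # same_day mode dates by step (ties within a step); otherwise each
        # acquisition gets its own consecutive day in disease-id order
        for j in acquired:
            links[(pid, spec.diseases[j])] = spec.start_date + _dt.timedelta(
                days=order_of[j]
            )

    if not retained_ids:
        raise SpecError(
            f"no patient reached min_conditions={spec.min_conditions} "
            f"out of {spec.n_patients} simulated"
        )

    # realized conditional frequencies, straight from the event stream
    num = np.zeros((d, d), dtype=np.int64)
    den = np.zeros(d, dtype=np.int64)
    for events in patient_events:
        for i, oi in events:
            den[i] += 1
            for j, oj in events:
                if i != j and oi < oj:
                    num[i, j] += 1

    diseases_present = {v for (_, v) in links}
    net = TemporalBipartiteNetwork(retained_ids, diseases_present, set(links), links)
    net.generation_log = GenerationLog(
        realized_num=num,
        realized_den=den,
        n_generated=spec.n_patients,
        n_dropped=n_dropped,
    )
    logger.info(
        "simulated cohort: %d/%d patients retained, %d links, %d diseases",
        len(retained_ids), spec.n_patients, net.n_links, len(diseases_present),
    )
    return net


def write_edgelist(net: TemporalBipartiteNetwork, path, delimiter: str = "\t") -> None:
    """Write the standard three-column temporal edge list (sorted rows)."""
    with open(path, "w") as fh:
        for u, v in sorted(net.links):
            fh.write(f"{u}{delimiter}{v}{delimiter}{net.timestamp(u, v).isoformat()}\n")
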