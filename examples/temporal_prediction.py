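"""Predict future diagnoses on a synthetic multimorbidity cohort.

Simulates a 300-patient cohort with planted disease-transition structure,
estimates the disease-transition probability matrix from a training split,
and compares the temporal index TPRA with its static counterpart PRA on
the held-out latest diagnoses.
"""

import numpy as np

from biplink import (
    auroc_full,
    estimate_condprob,
    score_all,
    score_all_temporal,
    split_temporal,
)
from biplink.network import TemporalBipartiteNetwork
from biplink.synth import default_cohort_spec, simulate_cohort

net = simulate_cohort(default_cohort_spec(n_patients=300, seed=8))
print(f"cohort: {len(net.v1_nodes)} patients, {len(net.v2_nodes)} diseases, "
      f"{net.n_links} dated diagnoses")

split = split_temporal(net, probe_fraction=0.1, seed=1)
train = TemporalBipartiteNetwork(
    net.v1_nodes, net.v2_nodes, split.train,
    {l: net.timestamp(*l) for l in split.train},
)
print(f"split: {len(split.train)} training links, {len(split.probe)} probe links "
      f"(each a patient's latest diagnosis)")

# transition probabilities come from training data only
M = estimate_condprob(train, mode="all_patients")
strongest = np.unravel_index(np.argmax(M.values), M.values.shape)
print(f"strongest estimated transition: {M.diseases[strongest[0]]} -> "
      f"{M.diseases[strongest[1]]} with Pr = {M.values[strongest]:.2f}")

candidates = sorted(split.probe) + sorted(split.nonexistent)
labels = np.r_[np.ones(len(split.probe), bool), np.zeros(len(split.nonexistent), bool)]
tpra = score_all_temporal(train, M, candidates)
pra = score_all(train, "PRA", candidates, missing_only=False)

print(f"AUROC (probe vs never-linked):")
print(f"  TPRA: {auroc_full(tpra.scores, labels):.3f}   <- transition-weighted paths")
print(f"   PRA: {auroc_full(pra.scores, labels):.3f}   <- structure only")
print("the gap is the value of the temporal ordering information")
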