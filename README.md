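# biplink

Link prediction for **bipartite networks**, static and temporal, aimed at
biomedical problems where the two node sets are drugs/targets or
patients/diseases and the question is *which missing cross-set link is most
likely to exist (or to appear next)?* — predicting unknown drug–target
interactions, or the next diagnosis of a patient with multimorbidity.

## The indices

In a bipartite graph G = (V₁, V₂, E) two linked nodes never share a common
neighbour, so the classical unipartite indices are rebuilt from
**quadrangles** (4-cycles) and **paths of length 3**. With Γ(v) the
neighbour set of v and Γ̂(v) = ∪_{z∈Γ(v)} Γ(z) its two-hop reach, the
common-neighbour set of a candidate pair (x ∈ V₁, y ∈ V₂) is

    {Γ̂(x) ∩ Γ(y)} ∪ {Γ(x) ∩ Γ̂(y)}      (two disjoint one-sided parts)

and its size is the bipartite CN score. On top of it the package provides
JC, AA, RA and PA analogues, the local-community family (LCL, CAR, CAA,
CRA, CJC, CPA), and two path-based indices:

* **PRA** (path-based resource allocation):

      S_PRA(x, y) = Σ_{x–d′–p′–y} 1 / (|Γ(p′)| · |Γ(d′)|)

  summing over the unique length-3 paths between x and y, each weighted by
  the inverse degree product of its internal nodes;

* **TPRA**, the temporal extension for time-stamped patient–disease
  networks: each path p–d′–p′–d is additionally weighted by the estimated
  conditional probability that disease d follows disease d′,

      S_TPRA(p, d) = Σ_paths  M(d′, d) / (|Γ(p′)| · |Γ(d′)|)

  where M(i, j) = Pr(patient later diagnosed with j | diagnosed with i) is
  estimated from the training diagnoses only. With M ≡ 1, TPRA = PRA.

The evaluation module implements the matching protocol: random (static) or
leave-latest-diagnosis-out (temporal) train/probe splits, the pairwise AUC
(n′ + 0.5 n″)/n, rank-based AUROC, top-k precision/recall/F-score, and
repeated-run benchmarking with mean ± sd reports, plus degree-bias and
unique-disease-coverage analyses of the ranked predictions.

## Worked example

`examples/worked_example.py` builds the 8-node, 11-link demonstration graph
(V₁ = {a…e}, V₂ = {1,2,3}) and scores the absent pair (e, 1):

```
graph: 8 nodes (5+3), 11 links
common neighbours of (e,1): side1=['a', 'b', 'd'], side2=['2', '3']
length-3 paths e..1: ['e-2-a-1', 'e-2-b-1', 'e-3-b-1', 'e-3-d-1']
    CN: 5.0000
    ...
   LCL: 4.0000
   PRA: 0.4167
after adding (a,3):
    CN: 5 (unchanged)
   LCL: 5 (one new path)
```

The two one-sided common-neighbour counts are 3 (in V₁) and 2 (in V₂),
giving CN = 5; there are 4 unique length-3 paths, so LCL = 4 and
PRA = 1/8 + 1/12 + 1/12 + 1/8 = 5/12. Adding the link (a, 3) creates a
fifth path while CN stays 5 — path-based indices resolve structure that
neighbour counting cannot.

`examples/temporal_prediction.py` and `examples/benchmark_indices.py` run
the temporal pipeline on a synthetic multimorbidity cohort with planted
disease-transition structure; on such cohorts TPRA separates held-out
latest diagnoses from never-observed pairs far better than the purely
structural indices (AUROC ≈ 0.80 vs ≈ 0.64 for PRA and ≈ 0.45 for PA in
the example output), because it is the only index that uses the diagnosis
order.

## Command line

```bash
biplink stats    --network diagnoses.tsv --temporal --min-conditions 4
biplink score    --network edges.tsv --index PRA --out scores.csv
biplink condprob --network diagnoses.tsv --mode both_diagnosed --out M.csv
biplink evaluate --network diagnoses.tsv --temporal --indices CN,PA,PRA,TPRA \
                 --runs 100 --probe 0.1 --seed 7 --out report/
biplink simulate --spec cohort.json --out diagnoses.tsv
```

Edge lists are two-column (static) or three-column (temporal,
ISO-8601 dates) TSV/CSV; labeled 0/1 adjacency matrices in the drug–target
benchmark dialect load with `--adjacency`. Every command writes a
`run_meta.json` with the seed, resolved configuration and its hash, so any
run can be reproduced exactly.

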