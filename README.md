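# complexsampler

Prediction of possibly-overlapping protein complexes from a weighted
protein-protein interaction (PPI) network by regularized simulated
annealing, for computational biologists who work with reliability-scored
interaction data (WI-PHI-style compendia) and curated complex catalogues
(CYC2008-style gold standards).

## The method

A prediction is a set `X` of clusters (protein subsets, size >= 2,
overlaps allowed) plus a power-law exponent `gamma` for the cluster-size
distribution. The pair is scored by

    f(X, γ) = b(X) − Σ_x w(x)/√|x| + c_dis · Σ_{x,x'} h_dis(x, x')
              + c_size · Σ_s (ψ_X(s) − ψ_γ(s))² + c_hy (γ − γ₀)²
              + c_pro |∪x|²

where `b` enforces connectivity and a size cap (else `f = ∞`), `w(x)` is
the internal edge weight, `h_dis` charges allowed overlaps their Jaccard
index and forbids large ones, `ψ_γ(s) ∝ s^(−γ)` is a truncated power law
on `[2, S_max]` matching the long-tailed size distributions of curated
catalogues, and the remaining terms are priors on `γ` and on the number
of clustered proteins. A Metropolis–Hastings chain with four asymmetric
moves (add/remove a two-protein cluster, grow/shrink a cluster by one
protein; Hastings-corrected acceptance) and Gaussian `γ` steps samples
`exp(−f/T)` while `T` cools geometrically; the lowest-scoring state
visited is the prediction.

Predictions are evaluated by size-stratified matching: sizes 2 and 3
require exact identity, sizes >= 4 require Jaccard >= 0.5 — two random
dimers sharing a protein already reach Jaccard 1/3, so lenient thresholds
would hand out credit exactly where catalogues are densest.

A synthetic module plants power-law-sized complexes (heavy intra-complex
weights, light background noise, single-protein overlaps) so the whole
pipeline is testable without downloading any compendium.

See `docs/methods.md` for assumptions, parameter meanings and defaults,
numerical details, and limitations.

## Worked example

```sh
complexsampler simulate --n-complexes 10 --s-max 8 --seed 2 \
    --out-network net.tsv --out-truth truth.txt
complexsampler predict --network net.tsv --out pred.txt \
    --iterations 100000 --seed 1 --c-clu-size 18 --c-pro-num 2.5e-3 \
    --cooling-factor 0.99993 --move-probs 0.2 0.3 0.2 0.3
complexsampler evaluate --predicted pred.txt --known truth.txt
```

prints (abridged):

```
planted 10 complexes (sizes 2-5) on 46 proteins, 34 edges
predicted 9 clusters (best score -9.7623, gamma 2.514) -> pred.txt
# 9 predicted vs 10 known complexes (exact match for sizes 2-3, Jaccard >= 0.5 for >= 4)
precision	1.0000
recall	0.9000
f_measure	0.9474
```

Nine of the ten planted complexes are recovered exactly (precision 1).
The tenth is one member of the benchmark's planted *overlapping* pair:
at the default overlap penalty the two complexes cannot both be
predicted in full, so the sampler keeps one and forfeits the shared
protein from the other — the source method shows the same behavior at
genome scale.  `gamma 2.51` is the size-law exponent at the best state
(prior center 2.5; ten complexes carry little size information, so the
prior dominates).  The `--c-clu-size`/`--c-pro-num` values are the
desk-scale coefficients for a 10-complex, ~50-protein benchmark (see
`docs/methods.md`); the same pipeline is available from Python, and
`examples/` contains short scripts for scoring (`score_breakdown.py`),
prediction + evaluation (`predict_complexes.py`), and catalogue overlap
statistics (`catalogue_overlaps.py`).

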