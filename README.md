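# connebm

Data-driven sequencing of anatomical brain-connectivity change in
neurodegenerative disease.

`connebm` takes per-subject weighted connectomes (symmetric, zero-diagonal
adjacency matrices of anatomical connection density over a fixed
parcellation) together with a cohort table, computes graph-theory biomarkers
per region, screens them for disease signal, converts each retained
biomarker into event probabilities with a nonparametric mixture model, and
orders the resulting events with an event-based model (EBM) of disease
progression — including positional uncertainty from MCMC, cross-validation
by bootstrap, and cross-sectional patient staging. It is aimed at
researchers studying progressive connectivity decline (e.g. in Alzheimer's
disease) who have connectomes and diagnoses but no longitudinal follow-up.

## The model

An *event* is a biomarker becoming observably abnormal. The EBM assumes a
single sequence S = (s(1), ..., s(N)) in which the N events occur, and that
every subject sits at an unknown stage k: events s(1)..s(k) have happened,
the rest have not. With a uniform prior over stages, one subject's
measurements x contribute

    P(x | S) = 1/(N+1) * sum_{k=0}^{N}  prod_{i<=k} P(x_{s(i)} | E_{s(i)})
                                      * prod_{i>k}  P(x_{s(i)} | not E_{s(i)})

The conditional densities P(x | E) and P(x | not E) come from a
two-component mixture of kernel density estimates fitted per biomarker on
control-standardized, abnormality-increasing "c-scores". The
maximum-likelihood sequence is found by greedy pairwise-swap ascent with
restarts; uncertainty is summarized as a positional-variance diagram
(fraction of posterior samples placing each event at each position, from a
Metropolis chain over permutations); robustness is assessed by refitting the
sequence to bootstrap resamples; and each subject receives a posterior over
stages.

Nodal biomarkers (12 per region) follow Brain Connectivity Toolbox
conventions on weighted undirected graphs: degree, strength, within-module
degree z-score, local efficiency, characteristic path length, participation
coefficient, node betweenness, nodal edge betweenness, eigenvector
centrality, PageRank centrality, clustering coefficient and eccentricity;
plus four global metrics (density, global efficiency, transitivity,
assortativity). Regional biomarkers are screened with a two-sided
Mann-Whitney rank-sum test at a Bonferroni-corrected threshold
(alpha / 12 within each region; alpha / 4 for the global comparison).

Because real imaging cohorts of this kind are access-controlled, the package
ships a first-class synthetic-data module that plants a known event
ordering — staged cohorts with pre/post-event value distributions, and
connectomes whose connectivity degrades node by node with disease stage —
so every stage of the pipeline is testable against ground truth.

## Worked example

```python
import numpy as np
from connebm import (default_truth, generate_ebm_cohort, greedy_ascent,
                     mcmc_sample, positional_variance, stage_subjects)
from connebm.experiments import ebm_data_from_cohort

truth = default_truth(6)             # six events, pre N(0,1) -> post N(3,1)
cohort = generate_ebm_cohort(40, 80, truth, seed=42)
labels = (cohort["diagnosis"] == "AD").to_numpy()
data = ebm_data_from_cohort(cohort, truth.planted_sequence, labels, seed=42)

ml = greedy_ascent(data, seed=42)
print("ML sequence :", " -> ".join(ml.event_labels(data)))
print("log-likelihood:", round(ml.loglik, 2))

chain = mcmc_sample(data, ml, n_samples=20_000, seed=42)
pv = positional_variance(chain, ml)
print("diagonal of the positional-variance matrix:", np.round(np.diag(pv), 2))

post = stage_subjects(data, ml)      # (subjects, stages 0..6), rows sum to 1
```

prints

```
ML sequence : E01 -> E02 -> E03 -> E04 -> E05 -> E06
log-likelihood: -1290.45
diagonal of the positional-variance matrix: [1.   0.95 0.95 1.   0.97 0.97]
```

The recovered sequence matches the planted one exactly; the near-1 diagonal
of the positional-variance matrix says the posterior over orderings is
concentrated (a perfectly certain sequence is a black diagonal in the
grayscale diagram). The posterior-mean stage correlates with the true
planted stage at Spearman rho = 0.932 on this cohort.

The same analysis runs from the shell on a simulated study:

```bash
connebm simulate --out study/ --n-controls 50 --n-patients 100 --n-nodes 60 --seed 1
connebm run-all --cohort study/cohort.csv --connectome-dir study/connectomes \
                --out study/results --mcmc-samples 20000 --bootstrap 50 --seed 1
```

which writes, per EBM variant, `ml_sequence.txt`, `positional_variance.csv`,
`bootstrap_pv.csv`, `stages.csv` and grayscale positional-variance heatmaps.
Variants combine a fixed non-network biomarker set with network biomarker
categories (hubs / importance / segregation); a variant whose category has
no disease-signal survivors is skipped with a log entry.

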