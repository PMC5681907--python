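# Methods

This note records the modeling choices behind `connebm`: what the model
assumes, how each stage is computed, which defaults matter and why, what the
synthetic data do and do not emulate, and the limitations we know about.

## The event-based model

The pipeline treats disease progression as a fixed cascade of *events*,
each event being one biomarker's transition from its normal (pre-event) to
its abnormal (post-event) distribution. For a sequence S over N events and
a subject with measurements x, the likelihood marginalizes a uniform prior
over the N+1 possible stages k (number of events already experienced):

    P(x | S) = 1/(N+1) * sum_k prod_{i<=k} P(x_i | event) * prod_{i>k} P(x_i | no event)

Assumptions inherited from this form: a single ordering shared by all
subjects (no subtypes), conditional independence of biomarkers given the
stage, and cross-sectional sampling that covers the whole stage range. The
uniform stage prior includes stage 0, so unaffected controls are handled by
the same expression.

The staged sums are computed with prefix/suffix cumulative sums of log
densities — O(N) per subject — entirely in the log domain with a per-subject
scaling constant, so cohorts with ~40+ events do not underflow. Densities of
exactly zero are floored at the smallest positive double; a subject whose
likelihood is zero at *every* stage raises an error naming the subject.

### Fitting

*Maximum likelihood.* Greedy ascent over pairwise transpositions
(best-improvement; a swap of positions p < q only changes the staged terms
for k in p+1..q, giving an O(subjects) evaluation per candidate), restarted
from 10 start orders: one "informed" start that sorts events by decreasing
mean event-probability fraction across subjects (under the model, earlier
events are abnormal in more subjects) and nine random permutations, all
seeded.

*Uncertainty.* A Metropolis chain over permutations with uniform random
transposition proposals and acceptance min(1, exp(delta log-likelihood)).
Defaults: 50,000 recorded states after a 50% burn-in (100,000 proposals in
all). Every post-burn-in state is recorded, repeats included. The
positional-variance matrix — the fraction of samples placing each event at
each position, rows in maximum-likelihood order — is doubly stochastic by
construction. One sampler caveat: on an exactly flat likelihood the chain
accepts every proposal and therefore alternates permutation parity
deterministically; goodness-of-fit checks against the uniform law must thin
with an odd stride.

*Cross-validation.* The sequence (not the event measures) is refit to 100
bootstrap resamples of subjects; the spread of the resulting ML sequences is
summarized as a second positional-variance matrix.

*Staging.* Each subject's posterior over stages 0..N is the normalized
vector of staged products under the ML sequence. The sequence itself is fit
on the defined control + patient groups by default; all scored subjects can
be included via the pipeline's `fit_cohort="all"` switch (the intermediate
diagnostic groups are always scored and staged, they just do not drive the
fit).

## Biomarker preparation

Controls are cognitively-normal subjects below the amyloid-PET positivity
cut-point (SUVR 1.10; a value exactly at the cut-point counts as positive),
patients are clinically diagnosed subjects at or above it. Biomarkers are
adjusted for age, education and sex by ordinary least squares fit on
controls only (residuals kept for everyone; volumetric biomarkers also get
intracranial volume), then standardized to control mean 0 / sd 1 with the
sign chosen so the patient mean is non-negative ("c-scores": larger = more
abnormal; ties break toward +1).

Disease-signal screening uses the two-sided Mann-Whitney rank-sum test
(exact enumeration when both groups have <= 10 subjects, otherwise the
normal approximation with tie and continuity correction, via SciPy).
Regional biomarkers are kept at p < alpha/12 (Bonferroni within region
across the 12 nodal metrics); the four global metrics are compared at
alpha/4. At the reference group sizes (26 vs 38) the discrete null makes
the realized type-I error ~0.049 at nominal 0.05 — slightly conservative,
as expected for a rank test.

## Graph metrics

Weighted undirected conventions throughout, weights normalized to [0, 1] by
the matrix maximum after exact symmetrization; lengths are inverse weights.
Choices worth stating:

- **Distances** by Dijkstra (SciPy`s csgraph); disconnected pairs are +inf,
  excluded from nodal path-length means, contribute 0 to efficiency, and are
  ignored by eccentricity.
- **Betweenness** by Brandes accumulation with fractional counting of
  co-optimal geodesics (length equality tolerance 1e-12); each unordered
  pair counts once. The nodal edge-betweenness biomarker is the sum of edge
  betweenness over a node's incident edges.
- **Community structure** per subject by seeded Louvain (greedy local moves
  + aggregation, modularity-checked against the single-module partition).
  The within-module degree z-score uses the *sample* standard deviation
  (ddof=1) of within-module degrees — note this differs from the Brain
  Connectivity Toolbox, which uses the population sd; modules with zero
  spread score 0. A whole-network z-score variant is available via
  `within_module=False`.
- **Clustering / transitivity** use cube-root weight products (Onnela);
  **local efficiency** is the efficiency of a node's neighbor subgraph on
  cube-root lengths with cube-root incident-weight products. Both local
  efficiency and nodal global-efficiency views of "efficiency" exist in the
  literature; local efficiency is the biomarker here.
- **Eigenvector centrality** by power iteration with a positive diagonal
  shift (same eigenvectors; prevents the +/- lambda oscillation of
  bipartite components), reported nonnegative with max-norm 1. **PageRank**
  uses damping 0.85, strength-weighted transitions, dangling nodes
  teleporting uniformly; the vector sums to 1.
- **Assortativity** is the Pearson correlation of binary degrees at edge
  endpoints; it is NaN for empty or degree-regular graphs.

Every metric is checked against independent references (exhaustive
simple-path enumeration for distances/betweenness, closed-form loops,
dense eigendecomposition / linear solves, networkx for clustering and
assortativity) on random graphs of up to 8 nodes.

## KDE mixture event measures

P(x | event) and P(x | no event) are Gaussian-kernel density estimates over
the observed c-scores with soft per-point weights, alternating between an
E-step (posterior event responsibilities) and an M-step (refit both
weighted KDEs, bandwidths included, and the mixing weight). Bandwidths use
a weighted Silverman rule, 0.9 * min(sd, IQR/1.34) * n_eff^(-1/5), with
Kish's effective sample size n_eff.

A fully unconstrained two-KDE mixture is **not identifiable**: a single
nonparametric component can model the entire sample, so the alternation
drifts toward degenerate fits (the event component either empties out or
absorbs the patient bulk; which one depends on the starting point, and the
drift is not even monotone in likelihood, because bandwidth refitting
breaks the EM guarantee). The default fit therefore imposes three
constraints, each of which proved necessary on planted data:

1. **Warm start** from an anchored two-Gaussian EM (normal moments frozen
   to the controls; three starting locations for the event mean, best
   parametric likelihood wins; the event sd is floored at half the control
   sd to block spike degeneracies), plus a second start from a hard split
   at the widest gap in the upper half of the sample; the two fixed points
   are compared by mixture likelihood.
2. **Pinning**: controls, and any value at or below the control median,
   cannot carry event-density weight — a measurement less abnormal than the
   median control is no evidence of a post-event state.
3. **Monotonicity**: each E-step's responsibilities are projected (isotonic
   regression) onto non-decreasing in the c-score, encoding the convention
   that abnormality increases with the score.

The reported mixing weight is estimated after the densities converge:
group-specific mixing weights for patients and controls (who have different
event prevalence by design) are fit by exact EM with densities held fixed,
and pi is the mean posterior membership. Because the alternation is not an
exact EM, the log-likelihood trace can wiggle by a fraction of a unit;
convergence is declared at a responsibility fixed point.

The spec-style fully symmetric procedure (label initialization, no
constraints) remains available as `anchor="none"` — it is exactly
label/value mirror-symmetric and matches a single-KDE fit on no-effect
data, but it should not be trusted on unbalanced events. An intermediate
`anchor="low-controls"` pins only controls below the control median.

Known calibration: on balanced two-Gaussian data with a 4-sd separation the
recovered pi_normal is within ~0.01 of truth; at 3 sd the component overlap
leaves a bias of ~0.06 and posterior-label accuracy of ~0.89 (0.98 at 4 sd).

## Synthetic data

`generate_ebm_cohort` plants the exact generative structure the EBM
assumes: patients staged uniformly on {0..N}, controls at stage 0 with a
Bernoulli(0.1) leak into stage 1 (the model explicitly expects some
controls past the earliest events; the leak rate is a free test parameter,
not an empirical estimate), pre/post-event distributions Gaussian by
default (location 0 -> 3, unit scale) with a skew-normal option so the
nonparametric mixtures are exercised on asymmetric shapes. Demographics
(age 73 +/- 7, education, sex) and a diagnosis-consistent amyloid SUVR are
attached so the cohort filter and covariate adjustment have something to do.

`generate_connectome_cohort` draws one stochastic-block-model base graph
(4 modules, within/between edge densities 0.6/0.15, log-normal weights,
normalized to [0, 1]) and degrades it along a planted node ordering: at
stage k, every edge incident to the first k nodes is multiplied once by
`degradation_factor` (0.5). Per-subject measurement noise is multiplicative
log-normal on each edge; the default sigma is 0 (a subject's matrix is then
a deterministic function of its stage, which the determinism tests rely
on), while study-level simulations use sigma = 0.3, i.e. an edge-weight
coefficient of variation of ~31%, in line with reported between-subject and
test-retest variability of tractography connection densities. After noise,
the whole cohort is renormalized by a single common maximum: normalizing
each subject by its own maximum would tie every node's strength to whichever
edge happens to be that subject's largest and make strength non-monotone in
stage.

Two features of this generator are worth keeping in mind when interpreting
passing tests. First, the incident-edge construction couples a node's
strength to its *neighbors'* events, so pre-event strength drifts downward
with stage instead of being exactly control-like — a mild, realistic
violation of the EBM's step-change assumption. It caps end-to-end ordering
recovery: with oracle component assignments the recovered ordering reaches
Kendall tau ~0.95 against the planted one, while the per-biomarker mixtures
achieve ~0.65 (late events become genuinely hard to distinguish from
drift). Second, nothing here emulates imaging realism: no parcellation
geometry, no tractography biases, no site effects, no realistic
demographic confounding. Recovery results on these cohorts show the
machinery is correct under its own assumptions, not that real connectomes
will order this cleanly.

## Defaults that matter

| parameter | default | units | why |
|---|---|---|---|
| SUVR cut-point | 1.10 | ratio | literature amyloid-positivity threshold |
| alpha / regional divisor | 0.05 / 12 | — | Bonferroni within region over the 12 nodal metrics |
| global divisor | 4 | — | four global metrics |
| MCMC | 50,000 recorded, 50% burn-in | proposals | positional variance stable at N <= 40 |
| bootstrap B | 100 | resamples | sequence cross-validation |
| greedy restarts | 10 (1 informed + 9 random) | — | reaches the exhaustive optimum on all tested problems |
| PageRank damping | 0.85 | — | standard |
| responsibility floor | 1e-6 | — | keeps both KDE components populated |
| degradation factor | 0.5 | — | halves connection density at a node's event |
| edge noise sigma (study runs) | 0.3 | log scale | ~31% edge-weight CV, realistic for tractography |
| control leak | 0.1 | probability | free test parameter |

## Validation problem sizes

The shipped validation recomputes everything at these sizes: likelihood
oracle on 100 random density matrices with up to 6 events; graph-metric
oracle on 200 random graphs of up to 8 nodes (1e-8 agreement);
flat-likelihood MCMC with 50,000 recorded states at N=4; planted-sequence
recovery over 20 cohorts of 50+100 subjects with 10 events at 3 sd
separation; mixture recovery over 20 two-Gaussian samples at 4 sd;
rank-sum calibration over 10,000 null replicates at 26 vs 38; and one
end-to-end connectome study of 150 subjects over 60 nodes.

## Limitations

- One sequence for everyone: no subtyping, no longitudinal information.
- Conditional independence of biomarkers given stage is clearly false for
  overlapping graph metrics; the model tolerates but does not exploit the
  correlation.
- The KDE mixture's anchoring assumes abnormality is one-sided relative to
  controls after c-scoring; biomarkers with genuinely non-monotone
  abnormality would need a different constraint set.
- Metrics are not normalized against degree-preserving null models; graph
  comparisons across subjects rely on the shared parcellation and the
  common weight normalization.
- With very few post-event subjects (<5) an event's position is close to
  unidentifiable; the disease-signal screen usually, but not always,
  removes such biomarkers first.
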