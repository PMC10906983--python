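# Methods

## Analysis model

The package treats a PPI network as an undirected, unweighted graph of
gene-symbol nodes. Edge confidence scores gate which edges exist (kept
iff strictly greater than the cutoff, default 0.7) but are never used as
path lengths — shortest paths are hop counts, matching the convention of
the common desktop network analyzers. Node identity is the case-sensitive
gene symbol; no aliasing or identifier mapping is attempted, and an
attribute table with duplicate gene ids (e.g. unsummarized per-isoform
scores) is refused rather than silently aggregated. Duplicate undirected
edge rows keep the maximum confidence, which is conservative under the
strict `>` filter. All metrics require the connected analysis graph, so
the largest connected component is extracted first (ties broken by the
component containing the lexicographically smallest node id).

Topology metrics per node v of a connected n-node graph:

- ASPL(v) = (1/(n−1)) Σ_{u≠v} d(v,u), hop distance, self excluded; ≥ 1.
- BC(v) = Σ_{s≠v≠t} σ_st(v)/σ_st, endpoints excluded, normalized by
  (n−1)(n−2)/2 so BC ∈ [0,1]. Normalization is the default; a raw mode
  exists (`--raw-bc`) because some tools report unnormalized values.
- NC(v) = mean degree of v's neighbors; requires degree ≥ 1.

All three are exact (Brandes/BFS under the hood); no sampling
approximations are used at supported scales, so outputs are
deterministic for a given graph.

## Classification

Seeding uses percentile cuts: top ceil(0.01·n) nodes by BC → H, top
ceil(0.10·n) by NC → I, top ceil(0.10·n) by ASPL → P, with deterministic
tie-breaking (metric descending, then node id). The 1% hub cut reflects
how rare hubs are in heavy-tailed networks. A node clearing multiple
cuts takes the highest-priority label H > I > P: BC is the most specific
hub signal and hubs are the class that cannot afford losses. A constant
metric makes the cut degenerate and is an error.

Class balancing is SMOTE: each synthetic point is x + u·(x′ − x),
u ~ U(0,1), with x′ one of the k nearest same-class seeds (default
k = 5), generated in feature space standardized to zero mean/unit
variance *on the seeds only* — the standardization is reused at
prediction time, so no information leaks from unlabeled nodes. Every
class is raised to the majority count. When the hub seed class on a
small network has fewer than k+1 members, the orchestration layer
lowers k to (smallest class − 1) and logs it; the low-level routine
stays strict and raises.

The classifier is an RBF support-vector machine (C = 1,
gamma = 1/(n_features·Var)), one-vs-one, with Platt-sigmoid probability
calibration (cross-fitted). Decision support is the maximum calibrated
class probability; predictions below the threshold (default 0.5, a
config knob surfaced in all reports) are declassified as "uncertain"
but keep their pre-filter label for audit. Whether decision support
should be a calibrated probability or a raw margin was an open design
choice; the calibrated probability was chosen because it gives the
threshold a scale-free interpretation. Classifier quality is reported
by replicated 9-fold cross-validation on the training table, run both
plain and stratified to rule out residual imbalance effects. The library
default is 1000 replicates; the test suite and the acceptance script
run 20, which is ample to estimate a mean accuracy on a ≤ 200-row
training table.

## Statistics

The response (gene-level mean PhyloP) is normalized with the
ordered-quantile transform Φ⁻¹(rank/(n+1)) (average ranks on ties),
which makes the downstream linear models scale-free and robust to the
skew of raw PhyloP summaries. All-identical responses are an error.

- Metrics model: OLS `phylop_norm ~ aspl + bc + nc`, listwise deletion
  of incomplete rows (count logged). Uncertain-node inclusion is a flag:
  the metrics model defaults to including them (their metrics are
  well-defined even when their class is not), the category model
  necessarily excludes them.
- Category model: one-way ANOVA on H/I/P with Tukey-HSD pairwise
  contrasts.
- Focal-set (hibernation) model: additive OLS on category + direction.
  With ~18 genes an interaction is under-determined, so the model is
  additive by design; a factor observed at a single level is dropped
  with a warning. Post hoc contrasts are differences of estimated
  marginal means; the direction pair is a single contrast, and the
  category pairs are Holm-adjusted model t-contrasts (the studentized
  range underlying Tukey HSD is not defined for unbalanced two-factor
  EMMs without additional machinery, so Holm is used there; the one-way
  model keeps true Tukey).

Effect sizes: whole-model Cohen's f = √(R²/(1−R²)) (infinite for an
exact fit); pairwise Cohen's d with pooled SD and Sawilowsky's extended
magnitude ladder (|d| ≥ 2 huge, ≥ 1.2 very large, ≥ 0.8 large, ≥ 0.5
medium, ≥ 0.2 small, else negligible).

## Random-draw null

Each draw samples |focal| nodes uniformly without replacement from the
complete-case rows of the metrics(+constraint) table — the focal genes
remain in the sampling frame, and the frame is restricted to nodes with
non-missing values so every draw yields a defined mean. The statistic
is the mean (not median) per metric. Empirical
p = (1 + #{at least as extreme})/(n_draws + 1), never 0 and never > 1;
two-sided extremeness doubles the smaller tail, capped at 1.
Degree-matched sampling is deliberately not the default: the null being
tested is "an arbitrary same-sized gene set", not "a degree-matched
one".

## Synthetic generator

`SyntheticSpec` defaults define the study conditions: 5 hubs forming a
complete core, 50 intermediates each attached to 2–3 hubs (plus sparse
I–I edges), 200 peripherals forming trees hanging off the shell
(p = 0.55 of attaching to the shell vs deepening an existing fringe).
This three-layer design — rather than plain preferential attachment —
guarantees the separation the classifier relies on: hubs monopolize
shortest paths (highest BC), intermediates neighbor the high-degree
core (highest NC), fringes are far from everything (highest ASPL).
Edge confidences are 0.7 + 0.3·Beta(2.2, 1.2), i.e. all above the
high-confidence cut with median ≈ 0.9, the regime of a filtered
STRING network.

Constraint is Normal(μ_class, σ) with μ = 1.5/1.0/0.5 for H/I/P and
σ = 0.35 on the PhyloP scale — a clear but noisy gradient. The decline
is gradual rather than a three-level step: within the peripheral
fringe, constraint additionally decays by 0.15 per hop of fringe depth,
mean-centered so the class mean stays exactly μ_P. Without this
continuous component the ASPL partial coefficient in the metrics model
would be pure noise (BC and NC already absorb the class signal), and a
center-to-periphery *gradient* — the structure being emulated — implies
within-layer decline. The focal set defaults to 18 genes (10
accelerated, 8 decelerated), ~14 of them from intermediate nodes and
the rest peripheral; accelerated genes receive +0.5 constraint,
planting the "faster-evolving genes are more constrained" signal.

What the generator does **not** emulate: the human interactome's size
(~17k nodes) and exact degree sequence, correlated evidence scores,
gene families/paralogy, or missing constraint values. Passing tests
therefore demonstrate that the pipeline recovers planted structure of
realistic shape and magnitude at desk scale, not that any particular
organism shows the effect.

## Numerical and design choices

- Problem sizes: tests and the acceptance script use 255-node networks,
  20 CV replicates, 200-draw calibration nulls and 1,000-draw focal
  nulls — sizes chosen so the planted effects are comfortably detectable
  while the whole suite stays fast.
- One top-level seed fans out to per-stage seeds via CRC32 of
  "stage:seed", keeping stage randomness decoupled; all derived seeds
  are < 2³¹.
- Reruns with identical config and seed reproduce every output file
  byte-for-byte (sorted JSON keys, LF endings, fixed float formatting).
- Quantile seeding uses ceil(pct·n) with stable sorting rather than an
  interpolated quantile threshold, so seed-set sizes are exact and ties
  are deterministic.

## Limitations

- The classifier's H/I/P taxonomy presumes a heavy-tailed, roughly
  core-periphery network; on networks without that structure the seed
  percentiles still select nodes but the labels lose their meaning.
- The random-draw null conditions on nothing (not degree, not class);
  significance against it shows the focal set is non-random, not which
  topological feature drives the difference.
- OLS with listwise deletion assumes constraint values are missing at
  random with respect to topology.
- Empirical p-values are bounded below by 1/(n_draws+1); with 1,000
  draws, p < 0.001 is not resolvable.
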