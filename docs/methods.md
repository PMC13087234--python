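# Methods

This note documents the models and procedures the simulator implements, the
parameters that matter, what the synthetic data does and does not emulate,
and the design decisions taken where the design was genuinely open.

## Synthetic data

`CohortSpec` draws each hospital's table from an explicit generative model:
numeric features are Gaussian with stated means/sds (the default template is
a heart-failure-style schema: age, resting blood pressure, cholesterol,
maximum heart rate, ST-depression, sex, chest-pain type, fasting blood
sugar, exercise angina), categorical features are multinomial, and the
binary outcome is Bernoulli(sigmoid(η)) where η is linear in the z-scored
numerics plus per-category offsets. `label_scale` multiplies the
coefficients: 1.0 yields a noisy, clinically plausible outcome (Bayes
accuracy ≈ 0.83); the federation default of 6.0 yields a nearly separable
task (Bayes accuracy ≈ 0.96) so that federation quality — not label noise —
is what the end-to-end run measures. Missing cells are masked independently
per feature cell, never in the label; in CSV they are empty fields.

`PanelSpec` simulates a lag-ℓ linear autoregressive panel,
`x_tgt(t) = Σ c·x_src(t−ℓ) + ε`, with the planted edge list returned as
ground truth. The acceptance experiments plant edges whose sources are pure
noise nodes, so lagged dependence exists exactly on the planted pairs.

What the generator does **not** emulate: realistic inter-feature clinical
correlations, longitudinal visits per patient, site-specific measurement
bias, or covariate shift between hospitals. Passing tests therefore show
that the machinery is correct and behaves as designed under its stated
model, not that the classifier would reach the same accuracy on real EHR.

## Preprocessing

Imputation is column-wise over rows in given order ("vertical neighbours"):
a numeric gap takes the mean of the nearest non-missing values above and
below; boundary gaps copy the single available neighbour; categorical gaps
copy the nearer neighbour with ties resolved upward. A wholly missing
column is an error. One-hot encoding expands each categorical column into
lexicographically ordered indicators named `col=category`. Min–max
normalization maps each feature column through (x−min)/(max−min); a
constant column maps to zeros to keep the [0,1] contract. The per-column
min/max and the category vocabulary are stored on the fitted table;
`transform_like` maps unseen records with them (unknown category → all-zero
indicators; values clipped to [0,1]). Normalization statistics are
per-hospital — nothing is shared across sites.

## Temporal causal graph

Series are z-scored (sample sd, so a series against its own delayed copy
has weight ≤ 1) and the lagged weight for an ordered pair is the truncated
lagged inner product divided by n_T−1 — a lagged Pearson correlation. For
each ordered pair the single best lag ≤ `max_lag` (default 3) is kept. Raw
weights are normalized by the global maximum absolute weight; the adjacency
stores the normalized weight for edges whose **raw** |weight| clears
max(threshold, minimum edge weight). Thresholding on the raw correlation is
deliberate: the 0.3–0.6 operating band is meaningful on the correlation
scale, whereas thresholding the max-normalized weight would retain most
null pairs (the null maximum at n_T = 500 is ≈ 0.13, so 0.3 × max sits at
the null noise level). Defaults: threshold 0.3, minimum edge weight 0.05,
pruning off.

Cross-sectional EHR tables have no clock; pseudo-time is record order, and
weights are averaged over sliding windows (length 32, stride 1) when a
window is configured. This is a modelling convention, not a causal claim:
on exchangeable rows the construction yields a near-empty graph, which is
the correct degenerate behaviour.

Per-node features on the thresholded graph: in/out degree, weighted degree
(sum of |incident weights|), mean/max incident weight, edge confidence
(= max |incident normalized weight|, already in [0,1]), strongly-connected-
component size, longest causal chain length (via the condensation DAG;
inside a cycle a node contributes its SCC size − 1), and the 2-chain motif
count (in-degree × out-degree). The node matrix concatenates each record's
preprocessed features with the feature-value-weighted mean of the per-
feature graph profiles; an all-zero record gets a zero summary. The
weighting is the simplest deterministic rule that lets records inherit the
graph profile of the features that are active for them.

## MCN-GNN

Records of a batch are nodes of a cosine k-nearest-neighbour graph
(symmetrized, self-loops added; k default 8). A linear embedding maps the
input width to the hidden width (32); each of the 2–4 message-passing
layers (default 3) computes m = ReLU(W·(mean over neighbours of h) + b) and
updates h ← mcn(h + m), where mcn subtracts each feature's across-node
mean. Centering removes the shared drift that repeated neighbourhood
averaging accumulates — after any number of layers the column means are
exactly zero, and on unit-normalized features the nodes stay measurably
more distinct than in the uncentred stack (asserted in the tests). The
residual enters from the embedding onward so a node's own signal survives
aggregation; this is the reading of the node-update rule that makes the
first layer consistent with the rest. A ReLU readout and a 2-class softmax
head produce probabilities; a ReLU head cannot feed a cross-entropy loss,
so softmax is used and documented as a deviation.

Training: Adam (lr 0.001, β = 0.9/0.999), batch size 32, cross-entropy,
80/20 split with train count = floor(0.8·h). Forward and backward passes
are hand-written numpy (the centering Jacobian is I − (1/n)·11ᵀ per column;
aggregation backpropagates through the transposed averaging operator); a
finite-difference check in the tests pins the gradients to ~1e-10. The
"round gradient" R shipped to the server is the flattened parameter delta
of the round — the object a federated client actually transmits.

## Gradient protection

Robust log scaling x·ln(|x|/q + 1) (natural log, q = 1) is sign-preserving,
strictly monotone in |x| and sub-quadratic, compressing large magnitudes
before masking; the server inverts it by monotone bracketing (Brent, xtol
1e-9). Protection is seed-derived additive masking: SHA-256 in counter
mode, keyed by the secret seed and a fresh nonce, yields a uniform mask of
width 10³ × plaintext RMS added elementwise. Masked vectors add
coordinate-wise and the sum unmasks with the masks of all contributing
nonces — the additive homomorphism the aggregation relies on. The mask
width travels with the cipher record (the mask must be regenerable), which
deliberately leaks a coarse magnitude scale and nothing per-coordinate;
nonce reuse is refused. This is not lattice-based homomorphic encryption
and carries no formal security proof; it delivers the operational
properties the pipeline needs (exact round-trip, summability, per-
coordinate decorrelation ≤ 0.1 in the smoke test).

## Authentication

Hospital ids are encoded as big integers; γ = u + exp((int(T) mod p) mod
64) with p = 2⁶¹−1 and u = 1, evaluated at fixed precision (scale 10⁶, all
arithmetic on scaled integers) so verification is exact equality, never a
float comparison. The secondary mod-64 reduction bounds exp's argument; it
is a documented choice, since exponentiating a raw 61-bit residue
overflows. The signature D = num(T) + γ + num(ε) is recomputed server-side
from the registration record; inequality blocks the gradient (J²).
Registration stores a salted SHA-256 password digest.

## Cluster-wise aggregation

Candidate centroid sets (default 10) are sampled from the gradient
collection, scored by the Calinski–Harabasz index after one assignment
pass, and the best seeds a Lloyd loop under the Zhonghua distance: a
Huber-penalized (δ = 1.0), weighted deviation magnitude times a similarity
factor. The literal factor (1 + cosine) is the default for fidelity even
though it rewards similarity with larger distance; "minus" and "off"
variants are provided, and with the factor off and a large Huber width the
loop reproduces Euclidean k-means exactly (asserted against scikit-learn
from identical initial centroids). Because the centroid mean does not
minimize the ZD with the similarity factor, the loop can oscillate; it is
capped at 100 iterations and a final assignment pass keeps the output
optimal with respect to the final centroids. Empty clusters seize the point
farthest from its current centroid. Cluster aggregates are member means,
so Σ n_k·X_k equals the gradient total exactly.

## Continual update

ℜ(b) = 1/(1+λb)^τ with λ = 0.05, τ = 1: ℜ stays in [0.5, 1] over 20
rounds — a gentle decay chosen because no values are stated. The update is
params += ℜ·G + (1−ℜ)·Y (increment, i.e. gradient semantics; whether the
blend replaces or increments was open). The replay buffer (capacity 20)
stores **gradients**, not raw examples — example replay would contradict
the privacy premise — and weights each entry by ℜ(age) at sampling time, so
early-round entries lose influence rather than dominating. The warm-up
delta is excluded from the buffer: it is orders of magnitude larger than a
round delta and would swamp every later blend.

## Federation protocol

All hospitals share one architecture (identical parameter shapes — a
requirement for aggregating raw gradient vectors that the round design
takes as given); heterogeneity lives in the data. Every hospital warms up
locally (100 epochs, the configured training budget) before round 1, so
non-participants hold trained models. A round samples ceil(0.3·n)
hospitals; each trains 5 epochs, protects, signs and submits; the server
authenticates (excluded J² submissions are still ledgered), recovers
gradients, clusters them (p = 2 by default, capped at the participant
count), evaluates each cluster aggregate on a server-held validation cohort
(the "global prediction" — the evaluation data for this step was
unspecified, so a held-out synthetic cohort makes it measurable), and
dispatches each cluster's aggregate Y to its members for the continual
update. Participants keep their locally trained update and then apply the
blend on top. Non-IID partitioning (Dirichlet over class proportions,
α = 0.5 mild / 0.1 severe) is provided for single-dataset sharding
experiments.

Problem sizes of the default study: 5 hospitals × 500 records, 10 rounds,
validation cohort of 250 — sizes at which the full run, including warm-up,
completes in seconds while every stage still operates above its degenerate
regime. Determinism: all randomness flows from the configuration seed;
repeated runs are bit-identical including cipher digests.

## Metrics

Continual metrics operate on the task-accuracy matrix α[v, s] with a row 0
holding the accuracies of the randomly initialized (seeded) model — the
"before any training" row that forward transfer needs and that is otherwise
unspecified. Forward transfer sums s = 2..Tn−1 as printed, skipping the
last task; this is implemented literally and noted. Zero denominators in
the confusion-count ratios yield NaN ("undefined") rather than 0. The
silhouette assigns 0 to singleton-cluster points; the Davies–Bouldin index
returns +inf when a needed centroid separation is zero; both agree with
scikit-learn on non-degenerate instances and with literal-loop oracles to
1e-12. Security level is the W-weighted mean of five component percentages
with W defaulting to 0.2 each (no weights are given anywhere); wall-clock
timing helpers are deliberately excluded from any asserted result.

## Ledger

Single-writer hash chain standing in for a permissioned blockchain:
consensus, peers and throughput are deployment concerns outside this
simulator's scope, while the testable guarantees — integrity, order,
auditability — survive. Blocks hash (index ‖ prev_hash ‖ canonical JSON of
the transaction) with SHA-256; the genesis prev-hash is 64 zeros; the
persistence layer exposes only append and read, and any external mutation
is detected with its first bad index.

## Known limitations

- The GNN is CPU-bound numpy; it is a study instrument, not a production
  classifier.
- The masking scheme's security argument is operational, not cryptographic.
- Pseudo-time on cross-sectional tables makes the TCG stage a feature
  transform whose causal semantics hold only for genuinely temporal input.
- The two-task replay experiment uses sign-flipped label models as the
  "conflicting task"; milder task shifts would show smaller contrasts.
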