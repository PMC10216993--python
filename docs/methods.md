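# Methods

This note documents the model as implemented, the defaults and why, the
numerical choices, and what the synthetic experiments do and do not show.

## Nutrient scoring

Per-portion FSA thresholds (sodium 0.7 g, fat 21 g, sugar 27 g, saturated
fat 6 g) anchor all scores; a `salt` column in a nutrient table is
converted at ingest with 0.388 g sodium per gram of salt.  The content
score is linear, `NCS_k = content_k · 10 / threshold_k`, so NCS = 10 marks
the threshold exactly; bands are half-open: healthy `[0,4)`, moderate
`[4,10)`, unhealthy `[10,∞)`.

The intake score groups a user's historical NCS values by band and returns
the count-weighted average of within-band medians.  The median of an
even-sized group is the mean of the two central values; an empty band
contributes nothing.  NIS is therefore bounded by the history's extremes.
Users with no history cannot be scored directly (an error); when pools are
built for training they receive the population-mean NIS so a cold user
cannot silently poison a run.

The discrepancy score uses the shifted soft-plus
`softplus_mod(x) = ln(1 + e^{x−4})` (natural log, computed with
`logaddexp` so it neither overflows for large x nor underflows to zero for
small x).  This reading is pinned by an internal calibration: with intake
and content both 10 on a single nutrient, `NDS ≈ 6.0025² ≈ 36.03`, which
is the source of the 36 pool cutoff (`NDS ≥ 36` ⇒ health-negative, the
inequality inclusive).  Note that rounded case-study NDS values sometimes
quoted for this scoring scheme (e.g. 74.55 for the worked pair whose
equation value is 83.65) are not reproducible from the defining equations
under any consistent soft-plus reading that also satisfies the ≈ 36
calibration; the implementation and its tests follow the equations and pin
values to an independent term-by-term oracle, never to rounded quoted
figures.  The same applies to a few published content-score cells that are
inconsistent with the linear formula (e.g. sodium 28.81 for 2.01 g, where
the formula gives 28.71): only self-consistent cells are used as test
expectations.

## Graph construction

KG triples and user-recipe interactions are fused into one entity space:
KG entities first (original ids remapped to a contiguous block in sorted
order), users appended after, so one embedding table covers everything.
Interactions become an `interact` relation and every relation r gains a
materialised inverse r⁻¹ — messages must flow from recipes to users and
from tail entities back to heads, and explicit inverse edges are the
simplest way to get that with a single directed adjacency.  No self-loops
are added; an entity's own vector enters only through the aggregator.
Low-frequency entity/relation filtering is available but defaults to 0
(thresholds are a data-cleaning choice for large scraped graphs, not part
of the model); recipes referenced by interactions always survive
filtering.  Construction is fully deterministic: adjacency sorted by
(relation, neighbor), serialization byte-stable.

## Embedding and propagation

TransD: the mapping matrix `M_rx = v_rp v_xpᵀ + I` (I the rectangular
identity) is never materialised; the projection is computed as
`v_rp (v_xpᵀ v_x) + Ĩ v_x`, verified against the dense matrix to 1e-10.
Entity and relation spaces share one dimension by default (d = z = 64, a
single published embedding size), but the code supports d ≠ z.
Initialisation is Glorot-uniform per tensor (bound `√(6/(fan_in+fan_out))`
with the two tensor dimensions as fans, the convention of the usual
`xavier_uniform` initialisers), seeded.

The KG ranking loss corrupts tails only (head corruption is not part of
the training recipe; unfiltered sampling is the default for speed, a
filtered mode resamples corruptions that form existing edges).  One sign
convention deserves a note: with plausibility defined as a *negated*
squared residual, the pairwise loss must reward `g(pos) > g(neg)`; the
per-record loss here is `softplus(−(g_pos − g_neg))`, i.e. valid triples
are pushed to higher plausibility than their corruptions, matching the
semantics of the translation-embedding literature.  No hard norm clamp is
applied (the original TransD unit-ball constraint); regularisation is left
to the λ‖Θ‖² term of the recommendation objective.

Attention logits apply the TransD projection of the edge's relation to
*both* endpoints.  Because inverse relations are materialised, both
orientations of every edge exist, which resolves the otherwise ambiguous
question of which endpoint is "head": each entity attends over its
out-edges in the doubled graph.  Softmax is max-subtracted per
neighborhood; an isolated entity receives a zero message.  Attention
coefficients are recomputed once per epoch from the current embeddings and
then frozen during backpropagation — the standard stabilisation in
attentive collaborative-KG propagation, and it makes the recommendation
phase a fixed sparse linear operator per epoch.  LeakyReLU slope is 0.2 (a
conventional default; the activation's slope is not otherwise pinned).
Message dropout (inverted scaling, seeded) acts on each layer's output
during training only.  All layers keep dimension d, so the concatenated
final representation has length (L+1)·d.  No per-layer L2 normalisation is
applied by default.

## Training

Each epoch alternates: (A) minibatch KG ranking loss over the forward
(non-inverse) edge set, updating the four embedding/projection tables;
(B) attention refresh, then user minibatches of the multi-task objective
`λ_h·L_health + L_pref + λ‖Θ‖²`.  Per sampled user, one preference pair
(uniform positive from the interacted set, uniform negative from the
complement) and one health pair (uniform from H⁺ × H⁻, skipped when either
pool is empty); the health pair's weight `NDS⁻ − NDS⁺` is strictly
positive by pool construction and the trainer fails loudly if not.  Both
BPR terms are batch means (batch-size-independent scale); `−ln σ(x)` is
computed as `softplus(−x)` everywhere.  The L2 term covers the tensors
phase B trains (entity table + aggregator weights); λ defaults to 1e-5 (no
published value).  Gradients are hand-derived (attention frozen,
backpropagation through the L-layer sparse propagation) and checked
against central finite differences to 1e-4 relative error.  Optimiser:
hand-written mini-batch Adam (0.9/0.999), separate instances for the two
phases.  A non-finite loss aborts with diagnostics rather than training
through NaNs.

Randomness fans out from one master seed into independent named streams
(init, KG corruption, preference sampling, health sampling, dropout,
shuffling), so disabling the health task leaves every other stream
untouched — a λ_h = 0 run and a health-task-off ablation produce identical
parameters, which the tests assert.

Published-scale defaults are embedding 64, 3 layers, batch 2048, 300
epochs, learning rate 1e-4, dropout 0.1, λ_h 0.1.  The package's own
desk-scale protocol (used by the synthetic experiment and chosen once for
CPU-minute feasibility) is 300 users / 500 recipes, embedding 32, 20
epochs, batch 128, learning rate 0.01, evaluated at K = 20 with
high-intake groups of 50 (the top sixth of users per nutrient, standing in
for the published top-500-of-48k selection).

When a validation split is supplied, Recall@20 is tracked per epoch with
early stopping (patience 10) and the best-epoch parameters are returned;
otherwise the final epoch is used.

## Evaluation

Recall@K is micro-averaged (pooled hits over pooled test sizes) with the
per-user macro mean reported alongside; the two coincide when all test
sets are equal-sized.  Training items are excluded from candidate ranking
— leaving them in would inflate recall for any model that memorises its
training set.  Ranking ties break by ascending recipe id, making every
metric value deterministic.  Intake groups are per-nutrient top-g users by
NIS (ties by ascending user id) and may overlap across nutrients;
Nutrient@K is the group mean of per-user mean grams over top-K lists.

## Synthetic data

The generator emulates the structures the method needs, not any real
dataset's statistics.  Nutrient content is drawn as log-normal scores
(right-skewed, positive, like per-portion content) rescaled by the FSA
thresholds: the healthy component stays below NCS 10 on all four
nutrients, the unhealthy component pushes 1–4 nutrients above 10, and the
realised unhealthy fraction tracks the target within Bernoulli noise.  The
KG has Zipf-distributed ingredient popularity (≥ 3 ingredients per
recipe), plus type and cuisine edges from small vocabularies, so no recipe
is an orphan.  Interactions come from a latent-factor choice model; a
planted subgroup (default 30% of users) adds a bias b (default 2.0) to
unhealthy recipes' utilities, giving that subgroup a recoverably higher
NIS (ranking AUC > 0.8 at default bias).  The 9:1 per-user train/test
split is random within user — the synthetic world has no timestamps, so a
chronological split is not meaningful.

What passing the synthetic experiment shows: the health loss actually
steers exposure (every Nutrient@20 falls when λ_h rises from 0 to 0.2
while recall does not improve), i.e. the mechanism works end to end.  What
it does not show: performance on real interaction data, whose sparsity,
popularity skew, and KG noise the generator deliberately does not
replicate.

## Known limitations

Only the four FSA nutrients are modelled (no calories, fibre, allergens,
or dietary restrictions); full-graph propagation assumes the fused graph
fits in memory (desk scale — no neighborhood sampling); the KG phase and
recommendation phase alternate rather than sharing one joint objective;
and health pools are recomputed from training interactions only, so a
user's intake profile is frozen at fit time.
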