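# Methods

## Estimand and scale convention

All effects are differences of conditional outcome probabilities:
μᵢ(t) = E[Yᵢ(t) | Xᵢ] and τᵢ^{(a,b)} = μᵢ(a) − μᵢ(b). The simulator's
structural effect modifier (−1.5 + 0.08·(age − 50)) lives on the **logit**
scale and is stored as `tau_logit`; the benchmark ground truth is the
**probability-scale** contrast `tau_prob = p(1) − p(0)`, obtained by
setting T to each arm and propagating the change through the mediator
equation with every unit's noise draws held fixed (a total effect). The
probability scale is the only scale every component outputs, and it is what
PEHE, ATE error, R², coverage and the effect SD are computed on. Treatment
reduces the outcome probability in the generator, so the oracle ATE is
negative (≈ −0.39 at the default configuration); error-type metrics are
sign-free.

## Data-generating process

Ten exogenous covariates with fixed marginals (age N(50, 10²), two Bernoulli
comorbidity/geography indicators, standard-normal labs, a uniform behavior
score, a Poisson visit count); a latent health factor X7 that enters the
outcome but is withheld from the released data; a geography-driven binary
instrument with Pr(Z=1|X) = σ(0.8·X8 − 0.5); a logistic treatment assignment
with measured confounding (age, immune status, comorbidity) and the
instrument; a viral-load-like mediator M = 2 − 1.5·T + 0.5·X3 + ε_M; and a
logistic outcome combining covariates, mediator, latent factor, and the
age-modulated effect. The structural noise laws are not part of the printed
equations; they default to ε_T, ε_Y ~ N(0, 0.5²) on the logit scales and
ε_M ~ N(0, 1), chosen so the propensity stays smooth and essentially all
units respect overlap (a handful of covariate-tail units at n = 5000
necessarily exceed propensity 0.98 under the printed coefficients — with
zero noise included — so overlap is a 99.8%-of-units property, not a hard
bound). All noise is drawn per unit before any derived quantity, making
tables byte-identical across runs of the same configuration and unit order
irrelevant. `confound_scale` multiplies the confounder coefficients of the
treatment equation for robustness sweeps (0.1–0.8); sample size sweeps
1 000–10 000.

## Causal-graph discovery

1. **Candidate parents.** For each target column, a linear regression on the
   remaining columns gives exact Shapley attributions φⱼ = βⱼ(xⱼ − x̄ⱼ)
   (verified against full subset enumeration). Over B = 20 bootstrap
   resamples, features are summarized by (mean |φ|, SD φ), standardized, and
   DBSCAN-clustered (eps 0.5, min_samples 2; noise points act as singleton
   clusters). The cluster with the highest mean absolute attribution is
   marked as candidate parents **only if** it separates from the remaining
   features by ≥ 1 standardized unit and does not swallow every feature —
   without a separation requirement, featureless noise marks the same
   random feature in most bootstraps. Frequencies ≥ τ_sel = 0.5 enter the
   skeleton.
2. **Orientation.** For each skeleton edge, both variables are standardized
   and each is regressed on the other with a degree-3 polynomial; the
   direction whose residual is most independent of its predictor (biased
   HSIC V-statistic, Gaussian kernels, median-heuristic bandwidths) wins.
   A purely linear fit cannot expose the additive-noise asymmetry of a
   nonlinear mechanism (verified: 0/50 recovery on a cubic mechanism), so
   the orientation step uses the minimal nonlinear fit; the parent-
   identification step keeps the linear model. Ties within 1/n of HSIC —
   the statistic's null order — are ambiguous and dropped, which correctly
   flags the linear-Gaussian non-identifiable case.
3. **Cycle removal.** While a cycle exists (deterministic DFS from the
   lexicographically smallest node), the cycle edge with the largest
   Shapley discrepancy δ = 1 − corr²(φⱼ, Xᵢ) is deleted; ties break
   lexicographically.
4. **Roles and selection.** Confounders have directed paths to both
   treatment and outcome (the latter avoiding treatment); mediators sit on a
   treatment→outcome path; instruments are *parents* of the treatment with
   no outcome path except through it (the parent restriction keeps a
   cause-of-an-instrument from being classified as an instrument itself).
   Between an expert DAG and the discovered DAG, the one whose role sets are
   more stable (mean Jaccard similarity) under deletion of the direct
   treatment→outcome edge is selected; ties go to the expert graph.

Post-treatment variables (mediators) are excluded from every outcome-model
input and from the propensity model, so the neural branch's counterfactual
contrast targets the total effect — conditioning on the mediator would
estimate a direct effect and be structurally biased against the stored
ground truth.

## Attention predictor

Each unit's feature vector (selected covariates + treatment encoding;
one-hot for multi-arm) is treated as a length-p single-channel sequence: a
width-3 same-padded convolution projects to the hidden width, a learned
positional embedding is added, and L residual blocks of multi-head
self-attention and feed-forward sublayers (layer-normalized) contextualize
it. The mean-pooled representation passes a sigmoid gate that convexly
blends a global memory vector with the new representation (every memory
coordinate stays between its old value and the incoming one); the output
head concatenates representation and memory. Training minimizes mean binary
cross-entropy with Adam, early-stopping on validation loss with patience 4;
the memory updates batch-by-batch in a seeded shuffle order and is frozen
at inference. Counterfactual probabilities override the treatment input.
Dropout (rate 0.1567) applies after attention and feed-forward sublayers
and stays active on stochastic passes for Monte Carlo dropout. The tuned
full-size configuration is hidden 512 / 8 layers / 8 heads / 31 epochs /
batch 1024 / learning rate 1.75e-4; benchmark runs in this repository use a
reduced width (hidden 64, 6 layers, batch 512, learning rate 1e-3) that
preserves depth, dropout and training schedule. Memory is a single global
vector (one slot); per-neighborhood memory is not implemented.

The networks (and the agent below) run on a small reverse-mode autodiff
engine over numpy arrays included in the package.

## Doubly robust learner

Nuisances are cross-fitted over K = 5 stratified folds: per-arm
RandomForest outcome regressions (100 trees, depth 5, min leaf 50,
bootstrap) and one L2-regularized logistic propensity model (C = 1.0,
≤ 1000 iterations, tol 1e-4; multinomial for > 2 arms so generalized
propensities sum to one). Propensities are clipped to [0.01, 0.99]. The
binary pseudo-outcome and the multi-arm contrast (which reduces
algebraically to the binary form for two arms) are exposed separately; the
ATE is exactly the mean pseudo-outcome. The second-stage effect regression
uses a *smoother* forest (300 trees, depth 4, min leaf 200): pseudo-outcomes
carry inverse-propensity-weighted noise an order of magnitude above the
outcome scale, and reusing the outcome-model hyperparameters leaves most of
that noise in the effect function. Out-of-sample units receive fold-averaged
nuisance predictions; the treated-arm probability is the control prediction
plus the smoothed effect, so the branch's per-arm probabilities and its
effect function stay consistent.

## Blending agent

Each unit is a one-step episode whose successor state is the next unit in
the epoch's seeded order (the discount γ = 0.9193 is retained from the
tuned configuration). The deterministic actor (7→128→128→1, sigmoid) emits
α; the critic (8→128→128→1) learns Q(s, a) from TD targets with
Polyak-averaged target networks (τ = 0.0139, update every 2 steps); replay
sampling is uniform; exploration adds Ornstein-Uhlenbeck noise
(θ = 0.15, μ = 0, σ = 0.2, Δt = 1) to the actor output, clipped to [0, 1].
Output layers initialize near zero (uniform ±3e-3) so the policy starts at
the midpoint blend. The reward is
r = w_bce·(−BCE(ŷ, y)) + w_dr·r_eff + w_bal·r_bal with defaults (1, 1, 0.1).
The effect-error term r_eff = −(α·τ̂_att + (1−α)·τ̂_DR − τ_true)² scores the
agent's *blended* effect estimate against the known truth and is available
only in simulation mode (its weight is zeroed otherwise): putting the
blended estimate — rather than a fixed nuisance quantity — inside the
squared error is what makes the term a reward at all, since a term constant
in the action cannot steer any policy. r_bal is the negative sum of squared
standardized inverse-propensity-weighted covariate mean differences across
arms. Outside simulation mode the action-dependent reward reduces to the
factual cross-entropy, and the learned blend then optimizes predictive fit
rather than effect accuracy.

## Uncertainty and drift

Monte Carlo dropout (50 passes) gives predictive means and variances; the
variance splits into aleatoric (mean per-pass Bernoulli variance
μₜ(1 − μₜ) — no dedicated aleatoric head exists) and epistemic (variance of
per-pass means); the identity total = aleatoric + epistemic holds to
numerical precision. Per-unit 95% effect intervals use the percentile
method over Monte Carlo samples of the blended ITE, where the ensemble's
predictive distribution is the **α-gated mixture** of the branch
distributions: each pass draws the gate, pairing a dropout-active forward
contrast (neural branch) with one bootstrap tree of the second-stage effect
forest (DR branch). A convex combination of the draws would collapse
between-branch disagreement and systematically undercover. Dropout spread
under-disperses relative to the network's true effect error (a known
property of Monte Carlo dropout), so coverage is highest when the agent
leans toward the doubly robust branch, whose across-tree spread matches its
error well.

Drift detection flags ‖μ_train − μ_batch‖ > δ on standardized features; δ
defaults to the 99th percentile of the same distance over bootstrap
resamples of the training set drawn **at the deployment batch size**
(mean-vector noise scales with batch size; a threshold calibrated at the
training size flags every smaller batch). On drift the pipeline logs the
report; agent fine-tuning is a caller decision.

## Pipeline and evaluation

Splits are 64/16/20 (train / validation / test): nuisances cross-fit inside
the training portion, the validation split drives early stopping and agent
training, the test split is untouched until final metrics. Preprocessing
(fit on the training split only) median-imputes and robust-scales
continuous columns and mode-imputes + integer-encodes categorical ones; an
optional class-balanced resampling of the training split is off by default.
Ablation variants (no-RL = fixed α 0.5, single-branch, no-graph,
no-uncertainty, no-drift, MLP baseline with SiLU activations) toggle
components without touching the others' fitted parameters. Classification
metrics threshold the blended factual probability at 0.5; AUC uses the
midrank Mann-Whitney formulation (verified against all-pairs enumeration);
interval and causal metrics are computed against the released ground truth
on the test split.

## What the generator does and does not emulate

It reproduces measured confounding, an instrument, mediation, latent
outcome noise and age-modulated heterogeneity with full ground truth, so
tests can score causal recovery exactly. It does not emulate missing data,
label noise beyond Bernoulli sampling, time-varying treatment, interference
between units, or covariate distributions with heavy tails — passing tests
show correct recovery under the stated structural model, not robustness to
those real-data features.

## Problem sizes and known limitations

Benchmark runs use the reference n = 5000 with the reduced-width network;
test-suite simulations use n = 400–5000 and reduced epochs. Known
limitations: the effect ceiling is bounded by the latent health factor
(regressing the true contrast on observables caps R² near 0.72 at the
default noise); outside simulation mode the agent's reward sees only
factual fit, so the learned blend is not guaranteed to minimize PEHE there;
Monte Carlo-dropout intervals inherit dropout's under-dispersion on the
neural side; drift detection is a mean-vector rule and is blind to variance
or correlation shifts.
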