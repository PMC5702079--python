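# Methods

## Signal model

The hidden process is a Boolean network over d genes updated synchronously
and perturbed by flip noise: Xₖ = f(Xₖ₋₁) ⊕ nₖ with nₖ iid Bernoulli(p) per
gene, p ∈ [0, 0.5]. On the enumerated state space {0,1}ᵈ this is a Markov
chain with column-stochastic transition matrix
M[j,i] = p^h (1−p)^(d−h), h = Hamming(sⱼ, f(sᵢ)); p = 0 reduces M to the
deterministic network map and p = 0.5 to the uniform matrix. States are
indexed with gene 1 as the most significant bit (index = Σⱼ xⱼ·2^(d−j)),
i.e. lexicographically in the printed gene order, so posterior vectors are
comparable across runs.

Observations are conditionally independent across genes given the state.
Four channels are implemented; their parameters, defaults used in the demos,
and meaning:

* **Bernoulli(q)** — the Boolean read-out of each gene flips with
  probability q ∈ [0, 0.5]. q = 0 is allowed (noiseless read-out); a
  contradictory observation then has zero likelihood and the filters raise
  a dedicated error rather than return garbage.
* **Gaussian(μ₀, σ₀, μ₁, σ₁)** — continuous intensity, N(μ₀,σ₀²) when the
  gene is inactive and N(μ₁,σ₁²) when active. The demonstration setting
  μ₀=1, σ₀=2, μ₁=5, σ₁=2 separates the two states by two standard
  deviations, which is what "well separated" means throughout the tests.
* **Poisson(s, μ, δ)** — RNA-seq-style counts with log-linear mean
  λⱼ(x) = s·exp(μ + δⱼ·xⱼ): s is the sequencing depth, μ the scalar
  baseline log-expression of an inactive gene, δⱼ > 0 the per-gene
  differential expression (vector of length d).
* **Negative binomial(s, μ, δ, φ)** — same mean, variance λ + λ²/φⱼ with
  per-gene inverse dispersion φⱼ > 0; φ → ∞ recovers Poisson.

A NaN entry in an observation vector marks a gene as unmeasured at that
time point; its likelihood factor is dropped. All likelihood work is done
in log space; probabilities are exponentiated only inside normalized
updates, shifted by the maximum log-likelihood first (log-sum-exp), because
count likelihoods underflow double precision quickly.

## Network representation

Networks are parsed from the BoolNet "targets, factors" text dialect with a
hand-written tokenizer and recursive-descent parser (grammar: `!`, `&`, `|`,
parentheses, gene names, constants 0/1, with NOT > AND > OR precedence).
Errors carry line numbers; duplicate targets, references to undeclared
genes, and the probabilistic (trailing-probability) or temporal BoolNet
extensions are rejected explicitly — the hidden-state process requires one
deterministic update function. External inputs such as the p53 network's
DNA-damage signal are baked in as constants, which is why the example
network ships as two variants rather than with a dynamic-input API.

The bundled p53-MDM2 negative-feedback model (gene order ATM, p53, WIP1,
MDM2) uses the update rules ATM′ = ¬WIP1 ∧ u, p53′ = ATM ∧ ¬MDM2,
WIP1′ = p53, MDM2′ = ¬ATM ∧ (p53 ∨ WIP1) with the input u fixed to 0 or 1.
These rules reproduce the two hallmark behaviours of the circuit: with
u = 0 the all-zero state (all proteins inactive) is the attractor, and with
u = 1 the noiseless dynamics settle into a six-state cycle along which p53
oscillates. The attractor finder enumerates the functional graph of the
deterministic map (guarded to d ≤ 20) and reports fixed points, longer
cycles, and basin sizes.

## Filtering and smoothing

The Boolean Kalman filter is the exact forward recursion over the 2ᵈ
states: predict π⁻ = M·π, update π(i) ∝ P(y|sᵢ)·π⁻(i). The per-step
normalizers are the predictive likelihoods P(yₖ | y₁:ₖ₋₁); their logs are
returned and summed into the log marginal likelihood. The MMSE Boolean
estimate thresholds each posterior gene marginal at ½; a marginal of
exactly ½ maps to 1 — at a tie any rule is MMSE-optimal, and a fixed
deterministic rule keeps runs reproducible. The default prior is uniform
over all 2ᵈ states. The filter applies the transition before the first
update (the first observation is modelled as one step after the prior).

The smoother is standard fixed-interval forward–backward: backward
likelihood messages βₖ(i) = P(yₖ₊₁:ₙ | Xₖ = sᵢ), renormalized each step to
avoid underflow; smoothed posterior ∝ filtered × β. At the final step the
smoothed and filtered posteriors coincide by construction.

Exact filtering refuses d > 12 (dense 4096² algebra is the practical limit
on one core) and points to the particle filter instead.

## Particle approximation

The SIR filter is a bootstrap filter: the proposal is the transition
kernel, weights are multiplied by the observation likelihood, and the
ensemble is resampled to equal weights (log-weights reset to exactly
−log N) when the effective sample size 1/Σwᵢ² falls below α·N. Resampling
is systematic — one uniform draw, stratified positions — the lowest-variance
of the simple schemes. α = 0 never resamples (pure sequential importance
sampling) and α = 1 resamples every step. For d ≤ 12 particles are
propagated through a precomputed state-index map; above that the rules are
evaluated directly on the particle matrix, so cost scales with N·d, not 2ᵈ.
The per-step log mean incremental weight is returned as a consistent
estimate of the predictive likelihood.

## Multiple-model estimation

MMAE runs one BKF per candidate (network, p) pair. The bank is the
Cartesian product of the supplied networks and noise intensities (networks
on the outer axis) with a uniform prior by default, so the two use cases —
unknown topology, unknown noise — are the two degenerate axes of one
mechanism. Each model's log posterior accumulates its filter's per-step log
predictive likelihood; normalization across models uses log-sum-exp. The
threshold is checked after each update; the first step whose maximum
posterior reaches the threshold stops the procedure (argmax ties break to
the lowest model index). If the threshold is never crossed the full series
is processed and the final argmax is reported without declaring a
selection.

## Simulation

`simulate_network` draws the initial state uniformly over the 2ᵈ states
unless one is supplied — uniform matches the filters' uninformative prior —
then alternates noisy transitions and observation draws. One seed feeds
three independent sub-streams (initial state, process noise, observation
noise), so changing the observation channel leaves the hidden state path
bit-identical. Trajectories round-trip through tab-separated text plus a
JSON metadata sidecar; floats are re-read with round-trip precision so the
cycle is exact.

The simulator is also the test-data generator. It emulates the statistical
structure the estimators assume — known network, stationary noise
intensities, conditionally independent genes — and deliberately not the
complications of real transcriptomic data: unknown/misspecified topology,
correlated measurement noise across genes, batch effects, time-varying
parameters, unequal sampling intervals. Passing tests therefore demonstrate
correctness of the algorithms under their own model class, not robustness
to model misspecification.

## Verification strategy and problem sizes

The exact filter is checked elementwise (≤ 1e−12) against an independent
brute-force HMM forward recursion, and the smoother against exhaustive
enumeration of all state paths (d = 2, n ≤ 6; ≤ 1e−10), across all four
observation channels on randomly generated networks. The transition matrix
is checked against 10⁶ Monte-Carlo draws (3 standard errors). Particle
accuracy is measured as total-variation distance to the exact posterior
(median over steps; decreasing in N over 100/1000/10000). The model
identification experiment uses 100 replicates of length-100 series; with
the demonstration parameters the bank identifies the data-generating model
in well over 90 % of replicates, with a median crossing time of the 0.8
posterior threshold around 18–20 steps — most of that time is spent
separating p = 0.01 from the adjacent candidate p = 0.05, whose per-step
Kullback–Leibler separation under four genes is only ≈ 0.1 nat even before
observation noise attenuates it. Individual runs vary widely (interquartile
range roughly 13–27 steps).

## Known limitations

* Exact filtering is exponential in d; beyond 12 genes only the particle
  filter applies.
* Observation parameters are treated as known; MMAE identifies topology
  and process noise only, not measurement parameters, and there is no
  joint state-and-parameter estimation.
* Observation noise is independent across genes; correlated channels are
  out of scope.
* Only synchronous deterministic networks are supported (no probabilistic,
  asynchronous, or temporal rule classes).
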