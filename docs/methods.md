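# Methods

This note records the models, numerical choices and known limitations of
the `speceffect` pipeline in enough detail to reproduce or audit it.

## Fuzzy chemical classification

Components are assigned to ten mother-nucleus categories (Rh-01…Rh-10,
else `Others`) by a deterministic cascade on the neutral monoisotopic
mass, obtained from the observed adduct m/z with a proton shift of
±1.00728 Da (the electron mass, <0.5 mDa, is neglected — far below the
matching tolerance):

1. **Exact reference match** within `tol_ppm` (default 10 ppm; the value
   is a configurable convention typical for Q-TOF accuracy, not an
   instrument calibration).
2. **Neutral-loss rule**: the mass minus a registered loss — hexose
   162.052824 Da (C6H10O5), galloyl 152.010959 Da (C7H4O4), chains of up
   to two units — is matched against reference aglycones. A hit in the
   free-anthraquinone class maps the unknown to the combined
   (glycosylated) anthraquinone class; for all other classes the
   conjugate shares its aglycone's category.
3. **Category-network node**: per-category graphs whose nodes are member
   masses and whose edges are registered mass differences; a mass sitting
   on a node within tolerance adopts the node's category. With networks
   built from the reference set itself this rule is subsumed by rule 1;
   it exists so user-supplied, manually extended networks can act as an
   additional evidence layer.
4. Otherwise `Others` (evidence `unassigned`).

Ties are broken by smallest |ppm error|, then confirmed-reference status,
then name. The cascade is monotone in the tolerance: tightening `tol_ppm`
can only move components toward `Others`. Retention time is available as
an optional window filter only; no quantitative RT rule is encoded.

## Integration-effect scoring

Indicators are standardized and factors extracted by the
principal-component method: eigenvalues λ of the correlation matrix above
a threshold are retained (no rotation by default, since scoring
coefficients and variance proportions are defined on the initial
extraction; varimax is available). Loadings are `v·√λ`, scoring
coefficients `v/√λ`, factor scores `Z · coef`, and the composite is the
variance-proportion-weighted sum of retained factor scores with the
proportions renormalized to 1 — a single-factor model therefore returns
that factor's score unchanged. Conventional per-efficacy thresholds are
0.8 (E1), 0.7 (E2, E3) and 0.65 (E4, E5). Each factor is oriented so its
loadings align with the panel's healthier-is-higher indicator directions,
and the final composite is flipped if needed so that a higher composite
means a healthier animal; the flip removes a sign ambiguity that would
otherwise propagate silently into the downstream network target.

KMO is computed from the correlation and partial-correlation matrices
(pseudo-inverse, so rank-deficient panels degrade gracefully), Bartlett's
sphericity from the log-determinant. Normality screening is a one-sample
Kolmogorov–Smirnov test against a normal with the group's own mean and
SD (the SPSS-style procedure; with estimated parameters it is
conservative, which the calibration test quantifies). Group comparisons
are two-sided pooled-variance t-tests of each treated group versus the
model group and of model versus control, with 0.05/0.01/0.001 tiers and
no multiplicity correction by default (a Holm option is trivial to add at
the call site; none is applied in the reference workflow).

## Quantity–effect network

Inputs (component contents averaged over injection replicates) and the
target are min-max normalized per feature; constant features map to 0.5.
The network has 1–3 hidden layers (default 20, 20) of logistic-sigmoid
units and a linear output, with biases trained but excluded from the
attribution arithmetic. Weights initialize uniform(−0.5, 0.5)/√fan_in,
seeded.

Training is full-batch gradient descent on the MSE with a damped momentum
term (`dX = 0.9·dX_prev − 0.1·lr·g`) and an adaptive learning rate:
steps that worsen the training MSE by more than 4% are rejected (rate
×0.7, momentum cleared); improving steps grow the rate by 5%. The initial
rate is 0.02 and the epoch budget 1000. Plain fixed-rate descent is
available (`momentum=0, adaptive_lr=False`) and is the configuration
under which the training MSE is provably non-increasing at small rates;
with adaptive momentum the default configuration reaches MSE < 1e-3 on
noiseless linear 200×10 data within the budget, which a fixed rate of
0.02 cannot do.

Stopping rules, first to fire wins: training MSE ≤ 1e-7 (goal); epoch
budget; gradient norm < 1e-10; or six consecutive rises of the MSE on a
seeded random 15% validation holdout. Two numerical details matter for
the validation rule: checks run every 5 epochs and a "rise" must exceed
the previous check by 0.1% relative. Without them, the damped oscillation
that momentum produces around the output-mean plateau early in training
registers as six consecutive micro-rises and halts training on noiseless
data; with them, runaway validation error on unlearnable targets still
stops training early. The split mimics the study design in which all
sample groups train the network and named groups are singled out only for
relative-error reporting (`(predicted − true)/true`, undefined at
true = 0); a strict hold-out mode exists as well.

The hyperparameter sweep utility repeats trainings over a grid of depth,
width and learning rate with seeds derived from one master seed and
reports per-test-sample predicted/true/relative-error records plus
mean ± SD of |relative error| per grid point.

## Decision weights and category attribution

Each weight matrix becomes a share matrix `F = |w|/ΣΣ|w|` (grand-sum
normalization; an all-zero layer is an error). The input→output impact
sums over every hidden path — the product of the share matrices — and
`S_i` renormalizes that to sum exactly to 1 over inputs. The formulation
names each factor with free hidden indices; the path-sum reading is the
only one that yields one number per input, and the implementation is
verified against a literal nested-loop path enumeration to 1e-13. For a
single hidden layer the statistic reduces to the grand-sum
(connection-weights) variant of Garson's importance,
`S_i ∝ Σ_j |w_ij||v_j|`; note this differs from the variant that
normalizes within each hidden unit before summing. The decomposition is
invariant to per-layer sign flips and scalar rescaling.

Single-run decision weights inherit the training run's initialization
noise, so the recommended estimator averages `S` over independently
seeded trainings (default 20; divergent runs are excluded and reported).
Components with `S_i > 0.01` (the conventional contribution floor) are
summed per category and per efficacy; grand totals are row sums over
efficacies; ranks are per-efficacy descending with ties broken by larger
grand total then category code. A category is **universal** when it ranks
in the top `top_m` of every efficacy (default `top_m = 3`, the smallest
value at which the published contribution table yields its stated
universal pair of combined anthraquinones and flavanols), **individual**
where it reaches the top `top_m` in some efficacies only, and background
otherwise.

## Synthetic data: what it emulates and what it does not

* **Reference database** — per-category scaffolds are the classic
  high-content constituents (emodin-type anthraquinones, sennoside-like
  dianthrones, catechins, gallic acid, resveratrol, torachrysone,
  raspberry-ketone-type butyrylbenzenes, chromones, quercetin); variants
  add CH2/O units and conjugates attach hexose or galloyl residues to
  aglycones that are themselves in the set, so every neutral-loss rule is
  satisfiable by construction. Masses come from elemental formulas
  (pyteomics). Cross-category masses are kept ≥ 30 ppm apart (within-
  category isomers allowed), so the clean-mass classification benchmark
  is well-posed by design rather than by luck.
* **Peak table** — each component's content is a Gaussian bump over the
  ethanol fraction (optimum = category polarity optimum + per-component
  jitter, SD 0.15), scaled by a per-component long-decoction factor
  (lognormal around 1.2) and multiplicative lognormal replicate noise
  (σ = 0.1 by default; the replicate variability of the study is not
  published, so this is a convention typical of LC-MS peak areas, not an
  estimate). Observed m/z carry 2 ppm Gaussian mass error by default.
  No chromatographic peak shapes, isotope envelopes or raw spectra are
  simulated.
* **Index panels** — per-animal indicator vectors are
  `direction ⊙ (loadings · group factor scores) + N(0, σ)`; the planted
  per-group composite is stored. Real panels have correlated indicator
  noise and missing values; the generator has neither.
* **Planted effects** — a sparse signed linear (optionally tanh-
  saturating) model on min-max-normalized contents plus Gaussian noise.

**Identifiability limitation.** Under the condition-structured peak
table, components of one category are nearly collinear (their contents
are smooth functions of a single solvent variable), and no importance
measure can separate a driver from its correlated neighbours — decision
weights spread over the correlated set. Recovery experiments therefore
use the i.i.d. design of `generate_component_samples` (components vary
independently, lognormal with σ = 0.5 around per-component medians),
where the planted drivers are identifiable in principle; the acceptance
experiment uses 200 samples × 108 components, 5 drivers with |weights| in
[0.5, 1.5], effect noise SD 0.05, and 20-seed averaged weights. Passing
it shows the estimator recovers sparse drivers under independent
variation; it does not license per-component claims inside a tightly
co-extracted category on real data — there, category-level sums are the
meaningful unit, which is exactly why the pipeline aggregates to
categories.

## Problem sizes and degenerate inputs

Test and acceptance runs use the study-scale defaults (108 components, 18
groups × 3 replicates, panels of 10–16 indicators, 6–8 animals per group)
and scale repetition counts (100 seeds for calibrations, 20×20 trainings
for recovery) to keep a full run in minutes on one CPU. Degenerate inputs
fail loudly: empty reference sets, constant indicators, thresholds above
the largest eigenvalue, all-zero weight layers, fewer than three values
for a normality test, divergent trainings (non-finite loss raises with
the epoch number). Relative errors at true = 0 are returned as NaN rather
than raising.
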