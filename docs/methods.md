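# Methods

This note documents the models implemented in `molconf`, their
assumptions, the tunable parameters and their defaults, the synthetic-data
conditions under which the package validates itself, and the numerical
choices made where the design was genuinely open.

## Score calibration (E values)

**Model.** Per query, the scores x₁…xₙ of candidates from a very large
structure database are treated as draws from the incorrect-hit score
distribution ("proxy decoys" — true decoy structures do not exist for
small molecules). Scores are log-transformed (yᵢ = ln xᵢ) and their
density is estimated by a Gaussian KDE; modelling the log-scores with
normal kernels is mathematically equivalent to log-normal kernels on the
raw scale and accommodates both the roughly log-normal bulk and multimodal
score distributions. The E value of a hit with log-score y is m times the
KDE upper-tail probability, evaluated in closed form via the erf sum; m is
the candidate count of the *target* search database, which is typically
much smaller than the proxy database.

**Parameters.**

* Bandwidth: Silverman's rule of thumb, h = 1.059223841 · σ̂ · n^(−1/5),
  with the n−1 sample standard deviation. A zero-variance sample falls
  back to h = 10⁻⁶ with a warning; n < 2 is an error (the query is routed
  to the single-candidate model instead).
* Score positivity: scorers may emit non-positive scores; the default
  pre-transform shifts by 1 − min(sample) before the log. The shift is
  returned so it can be recorded and re-applied — calibration must use one
  fixed monotone transform per query.
* The hit score is excluded from the decoy sample by construction of
  `ScoreSample`.
* Confidence feature: −log₁₀(E + ε) with ε = 10⁻³⁰⁰, so better hits get
  larger values and E = 1 maps to 0.

**Assumptions and limits.** The proxy-decoy sample must be large enough
for the KDE to be meaningful (tens of candidates); E values inherit any
bias of the proxy database relative to the true incorrect-hit
distribution, which is one reason the calibrated score alone separates
poorly and is used as *one feature* of the confidence model rather than as
the final score.

## Confidence model

**Model.** A linear SVM with squared hinge loss and ℓ2 regularization over
standardized hit features, trained once on reference data (not re-trained
per dataset, unlike Percolator-style rescoring — incorrect small-molecule
hits are not random, and per-run retraining invites overfitting). Decision
values are mapped to (0,1) by a Platt sigmoid P(f) = 1/(1+exp(Af+B)). The
output orders annotations; it is explicitly not a calibrated probability
of correctness.

**Enforced directionality.** For each feature whose sensible weight sign
is known a priori (the raw hit score may only raise confidence, the
candidate count may only lower it), one synthetic positive training sample
is added with that feature at direction·β in standardized space and zeros
elsewhere. Any solution with a counter-intuitive weight then pays an
unbounded hinge penalty, so the optimum satisfies wⱼ·dⱼ ≥ 0 while an
off-the-shelf SVM solver remains usable. β defaults to 10⁷; 10⁸ and 10⁹
give numerically identical models (asserted in the tests), so the choice
is immaterial as long as β is large against the standardized feature
scale and small enough to avoid overflow.

**Numerical choices.**

* Solver: liblinear *dual* coordinate descent (scikit-learn `LinearSVC`,
  `dual=True`, tol 10⁻⁵). The augmentation rows give the kernel matrix a
  β² diagonal entry; the dual treats them as single variables with
  O(1/β²) steps and converges cleanly, whereas the primal trust-region
  Newton stalls on the β²-conditioned Hessian. The grid search for C runs
  on a capped iteration budget (2·10⁴; selection only compares held-out
  AUCs), the final refit and the out-of-fold decision values get 5·10⁵.
* Augmentation happens in standardized space, after capping, so ±β is
  unambiguous. Caps (training min/max per feature) are applied before
  standardization at scoring time.
* C ∈ {10⁻⁵,…,10⁵} selected by stratified 5-fold cross-validation on
  held-out ranking AUC (the augmentation rows are re-injected into every
  training fold).
* Platt (A, B) are fitted by the Lin–Weng Newton iteration with
  backtracking on out-of-fold decision values, with the standard
  prior-corrected targets t₊ = (N₊+1)/(N₊+2), t₋ = 1/(N₋+2). Degenerate
  (constant) decision values fall back to an intercept-only fit with a
  warning.
* Residual sign violations below 10⁻³ in absolute weight (solver noise on
  a flat objective; true boundary weights are pinned to ≈(1−b)/β ≈ 10⁻⁷
  by the augmentation row) are snapped to exactly 0; anything larger
  raises, since it would indicate a genuine constraint failure.
* Top-candidate ties during feature extraction break lexicographically by
  candidate id; candidate lists are filtered to the hit's molecular
  formula before the gap/count features.

**Regimes and model selection.** Per collision energy (10, 20, 40 eV,
"merged" pseudo-ramp spectra) two models exist: the multi-candidate model
with all features, and a single-candidate model without the features that
require ≥2 candidates (score gap, candidate count, calibrated score).
Multi-candidate training rows can be reused for the single-candidate model
by picking one candidate uniformly (seeded RNG). At application time the
model with the smallest collision-energy difference and the matching
regime is chosen (e.g. the 40-eV model for a 35-eV query); ties go to the
lower energy. Models serialize to JSON (schema version, weights, bias,
standardization, caps, Platt parameters, energy/regime tags) so capping
and standardization are reproducible at application time.

## FDR estimation and evaluation

With hits ordered by confidence and pⱼ = 1 − confidence read as posterior
error probabilities, FDR̂ₖ = (1/k)·Σⱼ≤ₖ pⱼ estimates the FDR of the top-k
list; because the pⱼ are non-decreasing the estimate is monotone and
equals the q-value estimate (a maximum-accumulate guards against float
noise). Exact FDR (100·FP/k) requires labels and exists for evaluation on
reference data. ROC curves/AUC follow the standard construction (score
direction fixed by the identification task — an AUC below 0.5 is reported,
not inverted). Hop curves plot TP/N against FP/N over thresholds with N
the total query count; tied scores enter as a block; the endpoint identity
x + y = 1 is exact integer counting. The threshold report returns, per
FDR level, the largest qualifying prefix, its correct-hit count and the
confidence cutoff. Empty lists report FDR 0 by convention (flagged), and
percent values print with two decimals by default.

Because the Platt sigmoid is fitted to reference data, q̂ estimates on
data from a different distribution tend to be conservative (q̂ ≥ q_exact);
the Q–Q utility reports the conservative fraction alongside the pairs.

## Noise model ("noisification")

Library spectra are cleaner than biological ones; the noise model distorts
a spectrum in four steps, in this order:

1. global mass bias: one draw δ* ~ N(0, σ_mb²) per spectrum, every mass
   m → m(1+δ*);
2. per-peak mass jitter: δ ~ N(0, σ_md²), m → m(1+δ);
3. intensity distortion: each intensity × ε, ε ~ N(1, σ_id²), clipped at
   0; then 0.03 × the (post-multiplication) maximum intensity is
   subtracted from every peak; peaks below 1/1000 of the maximum are
   discarded;
4. noise-peak injection: round(α·n) peaks drawn with replacement from a
   pool (n = current peak count). The pool holds peaks from donor spectra
   that have *no* subformula decomposition of the donor's precursor
   formula within 10 ppm (uniform random masses would be trivially
   recognisable); intensities are stored relative to the donor maximum and
   injected as relative intensity × receiving spectrum's maximum.

Presets: medium noise σ_mb = σ_md = (10/3)·10⁻⁶ (3σ = 10 ppm),
σ_id² = 1, α = 0.2; high noise σ_mb = (15/3)·10⁻⁶ (3σ = 15 ppm),
σ_md = (20/3)·10⁻⁶ (3σ = 20 ppm), σ_id² = 2, α = 0.4. The global bias is
drawn once *per spectrum* (the shift is shared by all peaks of one
spectrum, independent across spectra). Spectra left with ≤1 peak are
removed. `calibrate_noise_level` scales (σ_id², α) jointly by bisection
until the median original-vs-distorted cosine hits a user target; the
mass-jitter terms bound the achievable cosine from above (peaks drift out
of the 7-ppm matching window), so targets near 1 are infeasible by design.

Subformula decomposition enumerates element-count vectors bounded by the
precursor formula (CHNOPS + halogens, monoisotopic masses from the
pyteomics NIST table), pruned by the residual-mass window; the adduct
offset defaults to the proton mass ([M+H]⁺) and is configurable.

## Spectra

Peak matching is greedy one-to-one by ascending mass difference within a
ppm window (default 7 ppm, |Δm| ≤ tol·10⁻⁶·max(m_a, m_b)) — deterministic
and the common spectral-library convention; on well-separated random
spectra it attains the maximum matching cardinality (asserted against a
brute-force oracle). The cosine score L2-normalizes each spectrum's
intensity vector (optionally after square-rooting) and sums products over
matched pairs, so unmatched peaks penalize the score; peaks within 7 ppm
of the precursor m/z are excluded first. Pseudo-ramp merging normalizes
each input spectrum to maximum intensity 1 (so collision energies
contribute on equal footing), clusters peaks across inputs within 7 ppm,
and collapses each cluster to its intensity-weighted mean mass with summed
intensity.

## Structure comparison

Tanimoto is the Jaccard index of two molecular-property sets and is
fingerprint-agnostic (any binary property universe; two empty sets count
as identical). For highly similar molecules the MCES edge-deletion
distance is used instead: the minimum total number of edge deletions
making the two hydrogen-free, element- and bond-order-labelled molecular
graphs isomorphic, with no connectivity requirement on the common
subgraph. The solver is exact — descending search over common-subgraph
sizes k, testing k-edge subsets of the smaller graph for labelled
monomorphism into the larger — and refuses inputs beyond 30 combined
edges rather than falling back to a heuristic (the problem is
NP-complete; the intended use is pairs of near-identical small molecules).
Consequences of the convention: distance 0 iff isomorphic; equal-edge
non-isomorphic pairs have even distance ≥ 2 (e.g. the n-butane vs
isobutane carbon skeletons give exactly 2). 2D identity of structures is
canonical-SMILES equality after stereochemistry and isotope stripping
(local canonicalization in place of an external standardization service);
stereoisomers such as L- and D-threose count as identical.

## Synthetic data: what it emulates and what it does not

* `gen_scores` draws per-query candidate scores from a mixture of
  log-normals — the empirical shape of proxy-candidate score
  distributions (roughly log-normal, sometimes multimodal).
* `gen_hit_dataset` plants class separations along each feature's
  declared direction: incorrect-hit features are standard normal, correct
  hits are shifted by the effect size (defaults between 0.3 and 1.5 SD,
  strongest for the score-derived features — the ordering one expects
  from real hit features). Candidate counts are drawn from
  {1: 0.15, 5: 0.35, 20: 0.35, 100: 0.15}, so single-candidate queries
  occur at a realistic rate. Defaults: 1,000+ queries, 50% correct.
* `gen_spectrum` places peaks at masses of random subformulas of a
  precursor formula (decomposable by construction) with exponential
  intensities, optionally planting verified non-decomposable peaks.

These generators produce exchangeable Gaussian features and idealized
spectra. Passing tests therefore demonstrate the *mechanics* — constraint
enforcement, calibration identities, monotone FDR estimation, recovery of
planted signal, q̂/q agreement when posteriors are well specified — not
performance on real spectra, where feature correlations, instrument- and
compound-class-specific structure, and distribution shift between training
and application data dominate (and make q̂ conservative).

All generators take explicit seeds and never touch global RNG state; the
test suite and the acceptance script run at fixed problem sizes (2,000
queries for the end-to-end checks, 100×10,000 hits for the random-AUC
baseline), chosen so the statistical assertions have comfortable margins.

## Known limitations

* The confidence score is a ranking score; its Platt outputs are not
  calibrated probabilities, and FDR estimates derived from them are
  conservative on out-of-distribution data.
* The exact MCES solver is for small molecules only (≤30 combined edges).
* The shipped feature schema contains the eight features the model
  description names; additional features can be registered but their
  directions must be supplied by the user.
* Proxy-decoy score generation (running a scorer against a large
  database) and fingerprint prediction itself are out of scope; the
  package consumes their outputs.
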