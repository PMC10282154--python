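# Methods

`mrpath` implements the statistical machinery of a two-sample / bidirectional /
network Mendelian-randomization (MR) study of behavioural exposures (dietary
habits), candidate mediators (insomnia, depression) and a binary outcome
(migraine), exercised end-to-end on synthetic GWAS summary statistics with
known ground truth. This note records the models, the defaults and why, the
numerical choices, and what the synthetic benchmark does and does not show.

## Model and estimators

For variant *j*, let β̂_Xj (SE σ_Xj) be its estimated association with the
exposure and β̂_Yj (σ_Yj) with the outcome, from non-overlapping samples and
aligned to a common effect allele. Under the instrumental-variable
assumptions each variant gives a Wald ratio θ̂_j = β̂_Yj/β̂_Xj with
first-order SE σ_Yj/|β̂_Xj|. Binary traits are analysed on the log-odds
scale throughout; odds ratios are exponentials for reporting.

**IVW.** The headline estimator is the inverse-variance weighted mean of the
Wald ratios with weights w_j = β̂_Xj²/σ_Yj², identical to weighted least
squares of β̂_Y on β̂_X through the origin. Heterogeneity is summarized by
Cochran's Q and I² = max(0, (Q−df)/Q)·100. *Multiplicative random effects*:
the fixed-effect SE (Σw_j)^(−1/2) is inflated by √max(1, Q/(J−1)), so
overdispersion widens intervals but homogeneous data are never narrowed
below the fixed-effect solution.

**MR-Egger.** Variants are oriented so β̂_Xj ≥ 0, then β̂_Y is regressed on
β̂_X *with* an intercept (weights 1/σ_Y²). The slope is the causal estimate
under InSIDE; the intercept estimates average directional pleiotropy and its
t-test (J−2 df, SEs inflated by √max(1, RSS_w/(J−2))) at p < 0.05 is the
pleiotropy alarm that gates outlier removal.

**Weighted median.** Ratios are ordered; the estimate interpolates the
inverse-variance-weighted cumulative distribution at 1/2 using midpoint
cumulative weights p_j = (Σ_{k≤j}w'_k − w'_j/2)/Σw'_k. Consistent when valid
instruments carry ≥ 50% of the weight. SE by seeded parametric bootstrap
(β̂_X* ~ N(β̂_X, σ_X), β̂_Y* ~ N(β̂_Y, σ_Y); default 1000 replicates).

**Mode-based.** Inverse-variance-weighted normal-kernel density over the
ratios, bandwidth 0.9·min(sd, 1.4826·MAD)·J^(−1/5) scaled by φ (default 1);
the estimate is the density argmax over a 2000-point grid spanning
min(θ)−3s to max(θ)+3s, ties resolved to the smallest grid value. SE by the
same bootstrap. Degenerate case (all ratios equal) returns the common value.

**MVMR.** For mediation, the outcome betas are regressed jointly on the
exposure's and the mediator's variant betas (no intercept, weights 1/σ_Y²)
over the re-pruned union of both instrument sets; the mediator's coefficient
is its direct effect on the outcome holding the exposure fixed. Limited to
two regressors — exactly the mediation use case; general K is out of scope.

**MR-PRESSO.** The observed residual sum of squares around leave-one-out IVW
fits is compared against a parametric simulation of the no-pleiotropy null
(default 1000 draws); per-variant squared residuals give outlier p-values,
Bonferroni-corrected by J and flagged below 0.05. Empirical p-values use the
(1+k)/(n+1) convention so they are never zero. The distortion test compares
the raw-vs-corrected IVW change against 1000 random same-size removals.
Outlier removal and the IVW/leave-one-out rerun happen *only* when the Egger
intercept test fires — the protocol's gate, not an unconditional step.

## Mediation and the proportion mediated

Three steps per exposure–mediator–outcome triplet: (1) total effect TE of
exposure on outcome; (2) effect *a* of exposure on mediator; (3) MVMR-adjusted
effect *b* of mediator on outcome. Mediation is claimed only when all three
are nominally significant (p < 0.05; the threshold defining "an association
was observed" is a design choice, exposed as a parameter). Then

- NIE = a·b, se(NIE) = √(a²se_b² + b²se_a²) (first-order Delta method,
  independent samples);
- proportion mediated = NIE/TE on the log-odds scale, with ratio-Delta
  variance se_NIE²/TE² + NIE²·se_TE²/TE⁴ and a normal 95% CI.

The log-odds scale is essential: published mediation tables report TE and NIE
as odds ratios, and the printed proportions equal 100·ln(NIE)/ln(TE) (an
OR−1 scale does not reproduce them). The Delta variance ignores the
covariance between TE and NIE induced by the shared exposure instruments —
the standard product-method simplification — so the proportion CI is
approximate; the recovery simulations below measure its actual coverage.

## Instruments

Instrument selection relaxes genome-wide significance to p < 5×10⁻⁶ (a
power compromise for weakly heritable behavioural traits), then clumps
greedily at 1 Mb / r² > 0.001: repeatedly promote the most significant
remaining variant (ties broken lexicographically by id, making the result
row-order invariant) and discard same-chromosome variants within the window
in LD with it. Clumping consumes an explicit r² matrix rather than reference
genotypes, which keeps it deterministic and testable; cross-chromosome pairs
are never pruned. Instrument strength is F_j = (β̂_Xj/σ_Xj)², with mean
F < 10 (strict) flagging weak instruments.

Harmonization matches variants by id, flips outcome betas for swapped
alleles, resolves strand complements, and orients palindromic (A/T, C/G)
variants by allele frequency only when both studies' EAFs are outside
0.5 ± 0.08 (window configurable); otherwise they are dropped as ambiguous.
Frequency orientation with a drop window is standard practice; a window of
0.5 effectively drops all palindromic variants for users who prefer that.

## Evidence grading and multiple testing

Within each exposure subtype the Bonferroni threshold is 0.05/n_subtype.
Three criteria grade each analysis: (1) IVW p below the subtype threshold;
(2) after Egger-gated outlier removal, estimates stay sign-consistent and
IVW stays nominally significant; (3) all sensitivity estimators share IVW's
sign. All three → *reliable*; (2)+(3) with nominal-only significance →
*insufficient*; nominal + (3) without (2) → *weak*; otherwise *none*. A
leave-one-out dependence on a single variant (some removal losing nominal
significance while the full fit is significant) demotes one level. Because
the published mapping from criteria to levels is not spelled out
row-by-row, the table is implemented as an explicit pure function
(`grade_from_criteria`) and exhaustively tested; an optional strict mode
additionally demands nominal significance of every sensitivity method
(off by default — the mode and Egger estimators are low-precision).

## Synthetic data: what it emulates and what it does not

`simulate_two_sample` / `simulate_mediation_triplet` draw, per variant,
maf ~ U(0.05, 0.5), true exposure effects γ_j half-normal with scale
`gamma_sd`, and report β̂ ~ N(truth, se) with se = 1/√(2n·maf(1−maf)); p from
the two-sided normal. Mediator truth is a·γ_j + δ_j with mediator-specific
polygenic effects δ_j ~ N(0, `mediator_gamma_sd`²) — these identify the MVMR
mediator coefficient. Outcome truth is θγ_j + b(aγ_j + δ_j) + α_j with a
pleiotropic α_j ~ N(mean, sd²) on a configurable fraction of variants
(mean 0 = balanced, nonzero = directional). The three studies draw
independent noise (the two-sample assumption). LD panels are block-diagonal
with AR(1) decay r = ρ^|i−j| within blocks.

Defaults and why:

- `J = 100`, `n = 100 000` per study — consortium-scale precision at desk-scale
  compute.
- `gamma_sd = 0.05` — mean instrument F ≈ 2n·maf(1−maf)·γ² ≈ 100, i.e.
  strong instruments; weak-instrument attenuation of IVW is then ~1%,
  negligible against its SE.
- Half-normal γ (effect alleles oriented exposure-increasing, as GWAS
  instrument lists conventionally are): with symmetric γ a directional α
  would produce *no* IVW bias (E[γ]E[α]/E[γ²] = 0) and robustness
  comparisons would be vacuous.
- `mediator_gamma_sd = 0.02` — the mediator's own polygenicity, large enough
  to identify MVMR, small enough that step-2 heterogeneity does not defeat
  the mediation gate.
- Binary-trait effects are generated directly on the log-odds scale (the
  scale all estimates are reported on); case-control imbalance is folded
  into an effective n.

Not emulated: sample overlap between studies, realistic MAF spectra,
population stratification, genotype-level LD (the panel is an input), or
selection effects (winner's curse) — instrument selection in the recovery
suites operates on the full simulated panel. Passing tests therefore show
the estimators and the pipeline are correct and calibrated *under the
stated generative model*, not that any particular real diet–migraine
association holds.

## Calibration results the suite recomputes

The acceptance tests (and, smaller, `analysis/05_calibration.py`) verify on
each run: IVW 95% CI coverage in [93%, 97%] with |bias| < 0.005 under the
clean generator (θ = 0.25, 500 replicates); Egger intercept type-I error in
[3%, 7%] under fully balanced pleiotropy (1000 replicates); PRESSO outlier
flags on valid variants within the Bonferroni-corrected rate; weighted
median less biased than IVW under 30% directional pleiotropy (200
replicates); PRESSO recovery of a planted 10·SE outlier in ≥ 95% of runs;
and Delta-CI coverage ≥ 90% for the true proportion mediated (60%) in the
a = 0.3, b = 0.5, θ = 0.1 triplet design.

## Numerical conventions

95% intervals use the normal 1.959964 everywhere. Weighted regressions are
solved by normal equations on the √w-scaled design; rank deficiency raises
a "collinear exposures" error. Zero-β̂_X variants are dropped from ratio
estimators with a warning (all-zero is an error). A single-instrument IVW
degrades to the Wald ratio with its first-order SE. All Monte-Carlo
machinery (bootstraps, PRESSO, distortion test) takes an explicit seed, and
the pipeline derives per-analysis integer seeds from one root seed via
`SeedSequence`, so full runs are byte-reproducible.

## Known limitations

First-order (not second-order) Wald-ratio weights; no correlated-instrument
IVW, MR-RAPS, Steiger filtering or proxy lookup; MVMR limited to one
mediator at a time; the proportion-mediated CI ignores TE–NIE covariance;
the synthetic generator's simplifications listed above. The analysis
scenario in `analysis/` shows one structural caveat deliberately: when an
outcome's significant variants are mostly driven by forward causal paths,
reverse-direction MR is contaminated unless the outcome has instruments of
its own.
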