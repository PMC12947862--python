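# Methods

This note documents the models implemented in `idrmap`, the defaults and
units of the parameters that matter, what the synthetic-data generators do
and do not emulate, and the numerical choices made where the underlying
procedures left room for interpretation.

## Sequence grammar

Coordinates are 1-based construct coordinates throughout; a sequence
carries an explicit `numbering_offset` and is never silently renumbered.

**Compositions.** Two groupings are built in: a six-class composition
scheme (polar Q,S,H,T,N; Cys; positive K,R; negative D,E; aromatic F,Y,W;
hydrophobic I,L,M,V,A) in which G and P are reported under an explicit
`other` fraction, and the eight-class scheme used for patterning z-scores
(polar Q,S,H,T,C,N; hydrophobic I,L,M,V; positive; negative; aromatic;
Ala; Pro; Gly), which covers the full alphabet. Uncovered residues are
always reported, never dropped. Charges at pH 7.4: K,R = +1, D,E = −1,
His neutral.

**κ and Ω.** Both are blob-variance statistics averaged over window sizes
5 and 6. For κ the per-window charge asymmetry is
σ = (f₊ − f₋)²/(f₊ + f₋); the statistic is the mean squared deviation of
window σ from the sequence-wide σ, normalized by the same quantity for a
maximally segregated arrangement of identical composition. The normalizer
is computed deterministically as the maximum over the six block
permutations of (+|−|neutral) plus an arrangement with the neutrals split
half at each end; no stochastic search is involved, so κ is exactly
reproducible. Ω uses the binary partition {charged ∪ Pro} versus the rest
with σ = (2f − 1)², normalized by the two-block arrangement. Both return
NaN (never 0) when a class is empty, when the sequence is shorter than
the largest blob, or when the normalizer vanishes — an empty or full
class makes segregation meaningless, so sequences consisting entirely of
{charged ∪ Pro} residues have undefined Ω.

**Aromatic clustering.** Ω_aro is the mean of 1/|i−j| over all unordered
aromatic pairs (aromatic set F,Y,W by default; His can be included via
`include_his=True`). The normalized score maps the evenly spaced
reference (k aromatics at positions round((j+0.5)·L/k)) to 0 and the
contiguous-block reference to 1. Because the rounded even-spacing
construction is not always the true minimizer of the pair statistic,
arrangements slightly more dispersed than the reference can score
marginally below 0; values are reported as computed and not clamped.
Both references depend only on L and k, so the score is invariant under
sequence reversal and under substituting one aromatic letter for another.

**Patterning z-scores.** For each pair of classes (a, b) the blockiness
feature is the mean squared deviation of the windowed class-fraction
difference f_a − f_b from its sequence-wide value (windows 5 and 6
averaged); self-pairs use the binary σ statistic of class a versus
everything else. Each feature is compared to `n_shuffles`
composition-preserving random permutations: z = (observed − null mean) /
null SD, so positive z means blockier than random. The default is 10⁴
shuffles (configurable up to 10⁶; the statistical cost of 10⁴ is a null-SD
estimate good to ~1%, which is ample for screening). Features are NaN
when a class is absent or the null SD is zero (e.g. homopolymers, where
every shuffle is identical). The shuffle stream is a fixed-seed PCG64
generator, so results are bit-reproducible.

**Disorder-promoting fraction** uses the set {T,A,G,R,D,H,Q,K,S,E,P}
(Dunker/Campen convention), exposed as an argument.

## CSP analysis

CSP_i = sqrt((Δδ¹H)² + (Δδ¹⁵N/5)²) in ppm; the 1/5 scaling places the
¹⁵N axis on a comparable ppm scale. Residues missing in either condition
(prolines, overlap, exchange broadening) are NaN and excluded from every
statistic — encoding them as zero would drag down quartile statistics.

The significance threshold takes Q1 = the floor(n/4) smallest defined
CSPs (minimum 2) and returns mean(Q1) + 5·SD(Q1). The count-based
quartile avoids an interpolation-rule dependency; SD is the sample (n−1)
deviation by default with a population option, since the original rule's
convention is not recoverable from its description. Retained-set
summaries report mean and SEM = SD/√n over residues at or above the
threshold.

## CSP² matrices

`build_pair_matrix` forms entry (i, j) = CSP_A(i)·CSP_B(j) (ppm²), NaN
when either factor is missing; self-pairs are symmetrized off-diagonal as
(M + Mᵀ)/2 and carry CSP² on the diagonal, for both apo and ligand-bound
conditions.

Smoothing is a normalized (missing-data-aware) Gaussian convolution:
both the zero-filled values and the finite-mask are filtered and their
ratio taken, so gaps are averaged out by their neighbourhood rather than
pulled toward zero, previously missing cells become defined wherever any
kernel weight reaches them, and no smoothed value can exceed the
pre-smoothing maximum. The default width σ = 2.0 residues is of the order
of the shortest segment one would call a contiguous interaction element
and left configurable; the truncation radius is 6σ so interior stamps
match the closed-form kernel to float precision.

Composite full-domain maps place each fragment-pair block at the
coordinates given by the profiles' numbering offsets, mirror the
transposed block by default (making the composite symmetric by
construction), and resolve overlaps by arithmetic mean (max and
first-wins available; no rule configured means overlaps raise).

Difference maps apply the strict masking rule: positions missing **or
zero** in either condition are exactly 0 in ΔCSP², so spurious signs
cannot appear where one condition carries no information.

## PRE

Decays I(t) = I₀·exp(−R₂t) are fitted per residue by bounded
least-squares (R₂ ≥ 0); delays are supplied in ms (default grid 1, 2, 5,
10, 20, 60 ms) and rates reported in s⁻¹. Initialization uses I₀ = first
intensity and R₂ = log-ratio of first and last points, which is robust
for monotone decays; non-convergent residues are flagged and excluded
downstream rather than zeroed. Γ₂ = R₂(para) − R₂(dia) with the standard
error taken in quadrature from the two fit covariances. Intensity-ratio
profiles (I_para/I_dia at a fixed delay, default 1 ms) propagate the
per-spectrum noise floors to first order.

Region averages are unweighted means over defined residues in inclusive
ranges. Built-in regions: h2 = 391–403, h3 = 433–437, C-terminal
aromatic-rich region 479–558 (construct coordinates of the target
domain). The printed h2 motif spans 13 positions but lists 12 letters;
the inclusive 391–403 range is used and the discrepancy simply noted.

## Equilibrium fits

**pKa.** δ(pH) = 1/(1+10^(pKa−pH)) + δ_offset on a min-max normalized
shift scale. Normalization mode `auto` (default) rescales only when the
input does not already span a unit-amplitude scale, so already-normalized
data are fitted as-is. The 95% CI comes from Monte-Carlo refits: `n_mc`
(default 1000) synthetic datasets are drawn from the fitted curve plus
Gaussian noise with SD equal to the dof-corrected residual SD
(√(SS/(n−2))), and the interval is pKa ± t₀.₉₇₅,ₙ₋₂ · SD(refit pKa). The
Student-t factor accounts for the noise scale itself being estimated from
few points; with a plain percentile interval the empirical coverage at
13-point titrations was ~89%, with the t interval it is ~94%, matching
the nominal level. Resampling is seeded and deterministic.

**Hill.** F(c) = F_u + (F_b − F_u)/(1 + (K_d/c)^n) by least squares, K_d
and n with covariance-derived standard errors. With `anchor_bound=True`
(default, mirroring titrations truncated at a solubility limit) F_b is
fixed to the response at the highest concentration; note this
deliberately biases K_d downward when the isotherm is far from saturated
— it is the stated convention, not an estimator of choice. Recovery
tests therefore use the unanchored fit.

**Cloud point.** T_c is the interior peak of the centered
finite-difference derivative of A₃₄₀(T), smoothed by a centered moving
average (default 5 points); ties break toward lower temperature and a
peak on the grid boundary is flagged instead of trusted. The interior
peak is localized below the grid resolution by the vertex of a quadratic
fitted to the smoothed derivative around the argmax — without this
refinement, grid-level argmax under 0.005 AU noise missed the planted
transition by more than one 0.25 °C step in ~15% of simulations because
the derivative peak is flat relative to the grid; with it the miss rate
is below 1%.

## Partitioning

P = dense_signal · dilution_factor / light_signal, dimensionless;
light = 0 yields an explicit undefined flag rather than infinity. Peak
quantitation mode (area vs height) is carried as metadata, mirroring the
practice of switching to heights when peak-shape deviations bias areas.
Calibration curves are ordinary least-squares lines (slope required
positive); inverse calibration flags values outside the calibrated signal
range and refuses values beyond twice that range. Peak integration is
deliberately upstream: the module consumes scalar signals.

## Synthetic data

Each generator is a pure function of its parameters and seed (PCG64).

* `gen_sequence` meets a target composition exactly (largest-remainder
  rounding; default an activation-domain-like composition: polar/P/G-rich,
  ~15% charged, ~5% aromatic) and can target an Ω_aro,norm band by
  rejection sampling with a deterministic ideal→clustered interpolation
  fallback.
* `gen_titration_pair` plants Gaussian-shaped CSP bumps (default peak
  0.03 ppm, localized on 10-residue segments) on reciprocal constructs,
  splits each CSP between the ¹H and ¹⁵N axes at a random angle, adds
  shift noise to the perturbed spectra only (σ = 0.002 ppm on ¹H, 5σ on
  ¹⁵N) and masks contiguous missing-assignment runs (default one run of
  5), emulating stretches broadened beyond detection. With zero amplitude
  the resulting CSPs follow a Rayleigh(σ) law (mean σ√(π/2)), which the
  tests use as the pure-noise oracle.
* `gen_pre_decays` builds para/dia decay pairs from a planted Γ₂ profile
  over a base diamagnetic rate (default 30 s⁻¹) with multiplicative 1%
  intensity noise on the 6-point delay grid.
* `gen_ph_titration`, `gen_isotherm`, `gen_turbidity` draw from the three
  closed forms above with additive noise (0.02 on normalized shifts and
  fluorescence, 0.005 AU on absorbance) on realistic grids (pH 6–12 in
  0.5 steps; 12 log-spaced concentrations up to 500 µM; 20–45 °C in
  0.25 °C steps).

What the generators do **not** emulate: spectral lineshapes, exchange
broadening and peak overlap (missingness is planted, not emergent),
J-coupling or temperature drifts, correlated noise between residues, and
any structural origin of the planted hotspots. Passing recovery tests
therefore demonstrate that the estimators are correct and well calibrated
for the stated noise models — not that real spectra meet those models.

## Problem sizes in the regression suite

The recovery suites run at sizes chosen to make their statistical
assertions meaningful while staying light: 500 simulations for R₂
calibration and pKa CI coverage, 200 for hotspot localization, K_d and
T_c, 100 profile pairs for the outer-product oracle, 50 compositions for
the clustering extremes. The acceptance script mirrors these sizes
(300 titrations for pKa coverage).

## Known limitations

* κ's deterministic normalizer searches a fixed candidate family of
  segregated arrangements; exotic compositions could in principle admit a
  slightly larger delta, which would make κ marginally overshoot 1.
* Ω_aro,norm can fall slightly below 0 for arrangements more dispersed
  than the rounded even-spacing reference (see above).
* The patterning null uses the same blob sizes (5, 6) for all features;
  very short sequences (< 6 residues) are rejected rather than handled
  with reduced blobs.
* Hill K_d standard errors are Wald-type (fit covariance) and mildly
  undercover for strongly nonlinear isotherms (~90% observed for a
  nominal 95% two-SE interval); profile-likelihood intervals are out of
  scope.
* The CSP² matrix is a correlation-style statistic: a large entry (i, j)
  means both residues report perturbation in reciprocal experiments, not
  proof of a direct i–j contact.
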