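# Methods

This note documents the models behind `meatspec`, the choices made where
the design was genuinely open, and what the synthetic experiments do and do
not demonstrate about real FT-IR data.

## Spectral model

A pure tissue class is a sum of Gaussian (optionally Lorentzian) absorption
bands on a uniform descending wavenumber grid (default 4000→550 cm⁻¹,
3451 points, 1 cm⁻¹ spacing — the instrument output convention; all region
arithmetic is done in cm⁻¹ so point bookkeeping stays internal).  Band
centres follow the standard mid-IR assignments for meat tissue: lipid
carbonyl 1740/1726, amide I/II/III 1638/1548/1310, CH bending 1463/1399,
phosphodiester and C–O/polysaccharide bands between 1236 and 1032 cm⁻¹,
plus broad amide A and CH stretches above 2800 cm⁻¹.  The amide I band
(peak absorbance 1.0 a.u.) is the shared normalisation anchor of all seven
classes.

Class differences are deliberately confined to three fingerprint regions —
1765–1726, 1572–1359, 1179–1000 cm⁻¹ — so that feature-selection behaviour
can be checked against the generator's own declaration
(`DISCRIMINATIVE_REGIONS`).  The composition encodes the qualitative
structure of real offal fingerprints:

* livers (beef and pork) carry strong nucleic-acid/glycogen signatures
  (1098, 1032) and a weak lipid carbonyl, and are by far the most similar
  cross-species pair (profile correlation ≈ 0.995, versus ≈ 0.93 for
  beef liver vs omasum);
* the two bovine stomach tissues (omasum, honey-comb tripe) are
  collagen/lipid-rich, mutually similar, and unlike the livers;
* pork tissues additionally carry a species-linked signature — a higher
  1726/1740 carbonyl ratio with small amide-II and tyrosine-band offsets —
  so the beef/pork distinction survives dilution even for the liver pair;
* pork heart and kidney differ mainly inside 1180–1060 cm⁻¹, the region a
  Wilks'-λ selection on the pork branch actually retains (see below).

**Mixtures.** The noiseless mixture signal is the mass-fraction-weighted
convex combination of the two parents' true signals (Beer–Lambert
additivity); mixing precedes acquisition because physical mixing precedes
measurement.  Consequently every adulteration class is, geometrically, a
set of dilution rays leaving the beef-meat point — a property with strong
consequences for classifier design (below).

**Nuisance processes.**  Per biological replicate, band amplitudes receive
log-normal jitter with CV 1 % (log-normal keeps absorbance positive; the
mean is preserved).  Per acquisition: additive white noise (σ = 0.003 a.u.),
a smooth positive polynomial+sinusoid baseline (amplitude 0.05 a.u.), and a
multiplicative gain with σ = 0.5 %.  These defaults were calibrated once so
that the screening cascade reproduces the qualitative performance profile
expected of this assay — near-perfect authentication at 25 % w/w and above,
reliable detection at 10 %, unreliable detection below (the limit of
detection sits just under 10 % w/w), residual confusion concentrated in the
liver pair and the heart/kidney pair.  Mid-IR spectra of homogenised tissue
are highly reproducible, which is what the small jitter values emulate.
All randomness flows through explicit integer seeds; identical inputs give
bit-identical datasets.

What the generator does **not** emulate: atmospheric water/CO₂ lines, ATR
penetration-depth physics, detector nonlinearity, within-sample
heterogeneity between repeated crystal loadings, and any deviation from
exact additive mixing.  Because mixtures are exactly convex combinations,
the synthetic problem is in one respect *harder* than real data (classes
are perfectly collinear rays) and in others easier (no matrix effects).
Passing tests therefore demonstrate the correctness and internal
consistency of the workflow, not field performance.

## Preprocessing

* **Baseline**: asymmetric least squares (AsLS) — iteratively reweighted
  Whittaker smoothing with asymmetry p = 0.01 and 10 reweighting
  iterations, solved per spectrum via a banded Cholesky factorisation.
  The stiffness default is λ = 1e7: on a 1 cm⁻¹ grid the effective
  smoothing length λ^(1/4) must comfortably exceed the 20–40 cm⁻¹ band
  widths, and 1e7 keeps the distortion of an isolated band below 2 % of
  its height (1e5 distorts ~8 %, measurably eating narrow bands).
  Non-convergence flags the spectrum; it never aborts.
* **Derivative**: Savitzky–Golay 2nd derivative (window 9, polyorder 3 by
  default), exact for polynomials up to the polyorder, edges handled by the
  one-sided polynomial fit.  "Original spectra" — baseline-corrected,
  cropped, underivatised — are the pipeline default, since the underived
  fingerprint separates these classes better than its 2nd derivative.
* **Crop**: closed interval, order-insensitive; 1800–1000 cm⁻¹ keeps
  801 points at defaults.
* **Outliers**: per-class PCA (3 components) score Mahalanobis distance to
  the class centroid, cutoff 3 — the conventional cluster-separation
  cutoff.  A per-class/global switch is provided; per-class is the default.
* **Scaling**: none / mean-centre / auto-scale.  Scaler state is fitted on
  calibration rows only and re-applied verbatim; constant variables get
  unit scale and a flag.  Cross-validation refits the scaler inside every
  fold.

## Wilks' λ selection

For each wavenumber, λ = SS_within / SS_total from the one-way ANOVA
decomposition (so λ = SS_within / (SS_within + SS_between)); small λ means
class means separate relative to within-class spread.  Selection is strict
(λ < threshold; ties at the threshold excluded), with 0.5 as the working
criterion and 0.75 as the documented escalation when 0.5 selects nothing —
which is exactly what happens at the 3-class level here, because the
authentic class contributes few spectra and the adulteration classes carry
the full dilution spread within-class.  Selected indices are reported as
maximal runs of adjacent grid points in the descending "high~low cm⁻¹"
notation.  λ is invariant to per-variable affine rescaling.

In the trained cascade the thresholded selection is additionally capped at
half the number of calibration spectra (keeping the lowest-λ variables):
LDA requires fewer variables than observations, and on very clean data
nearly every variable passes the threshold.

## Classifiers

All five families share a contract: scaling mode + optional variable
selection stored in the model, deterministic fits, alphabetical tie-breaks.

* **LDA** (canonical variates): generalised eigenproblem of between-class
  versus ridge-regularised pooled within-class scatter
  (γ = 1e-6·trace/p — spectra are collinear), exactly g−1 canonical
  variables.  Assignment is Mahalanobis-to-centroid in canonical space.
  The covariance used for that distance is configurable.  The classical
  Fisher rule (pooled covariance, the default) is correct for classes of
  comparable dispersion — e.g. the three pork-offal types on the pork
  branch.  For the authentication step it fails structurally: the
  authentic class is a compact point while each adulteration class
  stretches along its dilution rays with centroid near mean fraction
  ≈ 0.5, so under *any* shared metric a low-fraction mixture lies closer
  to the meat centroid than to its own class centroid.  The 3-class
  authentication LDA therefore uses per-class canonical-space covariances,
  shrunk 10 % toward pooled for stability — standard unequal-dispersion
  class modelling.  Alternatives (log-determinant Gaussian discriminant,
  small-sample predictive covariance inflation, unit-count-scaled
  shrinkage) were evaluated in a controlled multi-seed experiment and
  performed worse.
* **PCA-DA**: PCA on calibration spectra, LDA on the leading scores
  (13/14 components for the 7-/3-class configurations).
* **PLS-DA**: PLS2 NIPALS against a one-hot class matrix, deterministic
  start from the maximal-variance response column, argmax assignment
  (dummy rows need not sum to one).
* **KNN**: brute-force, k = 3 Euclidean by default (Mahalanobis optional);
  vote ties resolved by smaller mean distance, then alphabetically.
* **SIMCA**: one PCA per class (per-class component counts, e.g. 2/6/3 for
  tripe/liver/omasum and 4 for the merged stomach class), combined reduced
  distance d_c = √((Q/Q₀)² + (T²/T²₀)²) with Q₀ and T²₀ the calibration
  means; `predict` force-assigns to argmin d_c so single-label confusion
  tables can be produced, while `accepts` retains the classic
  accept/reject output with a per-class 97.5th-percentile threshold.
  Requested component counts are clamped to the effective class rank so
  degenerate (duplicate-row) classes remain analysable.

## Quantification

PLS1 with explicit deflation; X and y always centred, optional
auto-scaling.  Coefficients for every truncation 1..A come from the
triangular weight recursion, so cross-validated component selection costs
one fit per fold.  `select_n_lv` minimises RMSECV with a one-standard-error
rule toward fewer components; 5- and 9-fold conventions are both supported
(default 5).  Predictions are reported raw and clamped to [0, 1] (the
physical range), with an extrapolation flag outside the training fraction
range ± 0.1.  Calibration R² is the squared Pearson correlation of fitted
vs true; cross-validation and prediction R² are 1 − SSE/SST (the
conventions are stated because they differ when a model is biased).
Quantifier calibrations include the pure-meat spectra (fraction 0) so the
regression is anchored at the authentic end; a flag disables this.

## The decision cascade

Classification strictly precedes quantification: a pooled all-offal
regression cannot predict accurately across adulterant types, so the
fraction model is chosen only after the branch (and, on the pork branch,
the tissue) is known.

1. 3-class LDA (Wilks threshold 0.75, non-scaled) → authentic /
   with-beef-offal / with-pork-offal.
2. Beef branch: pooled beef-offal PLSR (9 latent variables) quantifies;
   SIMCA (mean-centred, 2/6/3 components) reports the subtype.  The pooled
   quantifier is preferred because knowing the exact beef tissue adds
   little to the decision a regulator makes.
3. Pork branch: 3-class LDA (non-scaled, branch Wilks threshold 0.5)
   identifies the tissue, then the per-type PLSR (heart 10, kidney 9,
   liver 6 latent variables) quantifies.  Merged-class fallbacks
   (tripe+omasum SIMCA/PLSR, heart+kidney LDA/PLSR) are config-selectable.

A physical sample contributes several acquisitions; verdicts aggregate by
majority vote with ties resolved toward "adulterated" (protecting the
authentic-beef claim is the assay's priority), the subtype by majority
among the voted branch's spectra, and the fraction as the median
per-spectrum estimate.  The full per-spectrum trace (model, decision,
score) is kept so any verdict can be replayed.

## Known limitations

* An *unseen* biological replicate of pure meat is occasionally flagged
  adulterated: the authentication step estimates the meat-class covariance
  from only four biological replicates, which understates the spread of a
  fifth.  This is a small-sample property of the design (few pure-meat
  replicates versus hundreds of mixture spectra), not an implementation
  artifact; enlarging the meat covariance enough to absorb unseen
  replicates measurably costs low-fraction detection.
* At the 25 % w/w level a beef-liver mixture is sometimes routed to the
  pork branch (and vice versa): the liver pair is nearly identical by
  construction and the species signature dilutes linearly.
* Heart/kidney subtype confusion persists at low fractions; the merged
  heart+kidney configuration exists precisely for this regime.
* Simulation sizes follow the study design (625 spectra); all experiments
  in the test suite and the acceptance script run this size end-to-end.
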