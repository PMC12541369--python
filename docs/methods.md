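# Methods

## SMLM shape-model selection

A late recombination focus is a set of localizations (x, y, z) with
per-localization precision estimates (σ_xy, σ_z). Filtering retains
localizations with |z − median z| ≤ 300 nm, σ_xy ≤ 15 nm and σ_z ≤ 25 nm;
the bounds are inclusive because the exclusion rule is strict (>15 nm,
>25 nm). The z-window center is the cloud's median z — the source protocol
states only a 600 nm window, and the median is the natural robust center for
a single in-focus structure.

Fitting is 2-D. Foci are selected in frontal or near-frontal view, so z
carries no shape information and serves only to reject out-of-focus
emitters; 3-D fitting is out of scope.

Two generative models are compared, both with k = 5 parameters
(center c, semi-axes a ≥ b, rotation θ):

- **hollow ring** — a uniform line density along the ellipse perimeter,
  convolved with an isotropic Gaussian of SD equal to that localization's
  lateral precision. The ring has zero intrinsic width by default (its
  apparent width is all localization precision); an optional fixed Gaussian
  cross-section can be added in quadrature for robustness studies.
- **filled ellipse** — a uniform area density over the ellipse interior,
  convolved likewise. At exactly zero blur it reduces to the closed form
  1/(πab) inside the ellipse.

The likelihood is Σ_i log f(x_i, y_i; params, σ_i). Densities are evaluated
by quadrature: 256 equally spaced perimeter points with trapezoidal
arc-length weights for the ring, and a 32×32 grid (Gauss–Legendre in squared
radius × uniform angle, constant-Jacobian map) for the interior. At these
resolutions the density integrates to 1 over the plane to within 1% for the
blur regimes the pipeline sees (σ ≥ ~2 nm at focus scales of tens of nm).

Optimization is a derivative-free Nelder–Mead search from the stated
initialization — center at the coordinate-wise median, full axes 65/35 nm
(read as full lengths, i.e. semi-axes 32.5/17.5 nm; only the optimizer seed
depends on this reading, and it is configurable), θ from the principal
direction of the coordinates — with semi-axes bounded to [5, 500] nm and a
budget of 400 function evaluations (800 where tight parameter recovery is
the goal). Nelder–Mead never accepts a worse simplex best, so the converged
log-likelihood is never below the initialization. Non-convergence within
the budget is flagged on the returned fit rather than raised: the
best-so-far parameters remain a valid estimate. After convergence a ≥ b is
restored by swapping axes (θ rotated by π/2) and θ is reduced mod π.

Model choice uses the corrected, normalized Akaike criterion
normAICc = AICc / n with AICc = −2 ln L + 2k + 2k(k+1)/(n−k−1). The
normalization constant is a presentation choice: both models share n and k,
so the label ("filled" iff normAICc_filled < normAICc_hollow, exact ties
hollow per the strict rule) is provably identical to a plain likelihood
comparison — the test suite asserts this equivalence on every classified
cloud. A background/outlier mixture term is excluded from the default
likelihood; a uniform-background weight is available but off by default.
Fits require n > k + 1 = 6 localizations (AICc is undefined below that).

## Focus categorization

Spot detection is a generic two-stage pipeline: a difference-of-Gaussians
band-pass (inner scale = expected spot σ, outer 1.6×) thresholded at half
the response an ideal spot of the minimum amplitude would produce, followed
by least-squares refinement of an anisotropic 2-D Gaussian plus constant
offset in a local window (sub-pixel centers, σ in nm via the pixel pitch).
The detector is deliberately plain — the reusable content is the
categorization rules, not detector internals — and all thresholds live in
configuration.

Rules, with their canonical constants:

- elongation: a single fitted spot is an *elongated singlet* when
  σ_x ≥ 75.12 nm **or** σ_y ≥ 75.12 nm (inclusive). The threshold is stored
  verbatim as an opaque, tool-derived constant.
- anchoring: a spot joins a COSA-1 anchor site when its center lies within
  150 nm (inclusive — "within a radius"). A spot in range of several
  anchors joins the nearest; exact ties go to the lower anchor index (the
  source does not state a rule; nearest-with-index-tie-break is the simplest
  deterministic one). No spot is counted twice; anchors without members
  yield no site.
- categories: by multiplicity 1/2/3/≥4 → singlet/doublet/triplet/multi; in
  shape mode a lone member is classified by elongation and ≥2 members make
  a doublet (no upper member bound is imposed, none being stated).
- zones: normalized gonad positions in [0, 1] fall into equal-width bins
  (4 or 7), half-open except the last, 1-based from the distal end.
  Position 1.0 is zone n; 0.25 with four zones is zone 2.

Nucleus segmentation is out of scope; nuclei arrive as precomputed
normalized positions or ROI tables.

## Crossover mapping

Each progeny contributes exactly one scored chromatid (the maternal
chromosome V of the hybrid oocyte), so worms and chromatids coincide and the
overall denominator is the worm count. A crossover is a phase transition
between adjacent informative markers. When missing calls separate the pair,
the transition is assigned to the composite interval and the chromatid is
excluded from per-interval counts (it still counts as recombinant overall);
this missing-data rule is this package's choice. The overall recombination
frequency is the fraction of scored chromatids with ≥1 observed crossover —
the only definition consistent with the published 65/215 = 30.23%,
120/255 = 47.06% and 58/184 = 31.52%. Even numbers of exchanges within one
interval are invisible at marker resolution; the undercount is inherent and
documented, not corrected. Default marker coordinates are illustrative
placeholders (every computation in scope depends only on marker order).

## Statistics

Fisher's exact test is two-sided by the sum-of-≤-point-probability
convention (the convention of the mainstream stats packages, and the one
that reproduces the published p-values); mid-p and tail-doubling variants
would differ and are not used. The test suite checks the implementation
against exhaustive same-margin enumeration for every 2×2 table with total
≤ 20. Degenerate tables (a zero margin) are reported with p = 1 and an
explicit flag. Mann–Whitney uses the exact permutation null for tie-free
samples with max(n) ≤ 8 and otherwise the normal approximation with tie and
continuity corrections, U = min(U₁, U₂); the exact branch is verified
against full enumeration. Identical samples report p = 1 exactly. Viability
is 100 × larvae/brood per worm (unfertilized eggs excluded upstream); male
frequency uses hatched larvae as denominator, the source not stating one.
SDs use n − 1. No multiple-testing correction is applied (pairwise p-values
are reported unadjusted, matching the source analyses).

## Synthetic generators

The generators define the study conditions the tests probe:

- **localization clouds** — model points uniform on the perimeter (hollow)
  or interior (filled) of the focus ellipse, displaced by each
  localization's drawn precision; with probability `background_frac`
  (default 0) a localization is instead uniform on a square ROI of
  half-width 200 nm. Precisions are lognormal, median 8 nm lateral / 15 nm
  axial with log-SD 0.35, truncated at the 15/25 nm filter bounds —
  a realistic SMLM spread in which most localizations survive filtering.
  z is a Gaussian slab of SD 30 nm (frontal view). Localization counts per
  focus are not reported anywhere; n = 500 at 5 nm precision is a plausible
  dense-labelling regime, not a reproduced value.
- **spot fields** — anisotropic Gaussian emitters plus constant offset and
  Gaussian read noise on a 65 nm/px grid; the ground-truth tables are the
  oracle for detector tests. Camera-frame physics (EMCCD noise, blinking,
  PSF astigmatism) is out of scope.
- **genotype cohorts** — marker A uniform over {Bristol, Hawaiian}; each
  interval flips the phase independently with its probability. There is no
  crossover interference: only per-interval frequencies are published, and
  the double-crossover rate is a recoverable diagnostic rather than an
  input. Calls are masked to NA at a configurable rate.
- **zone counts** — Poisson per nucleus at the zone rate, or
  negative-binomial when over-dispersion is requested.

Identical configuration and seed give bit-identical output, and every
output records its seed in metadata.

What passing tests on these data do **not** show: robustness to structured
background (axis-associated localizations, neighbouring foci), to emitter
blinking statistics, to chromatin texture under the spots, or to crossover
interference — none of which the generators emulate.

## Problem sizes and numerical choices

Classification accuracy is assessed over 100 clouds per class at n = 500
localizations and 5 nm precision (the regime in which the two models are
reliably distinguishable); parameter recovery over 20 perimeter clouds of
n = 1000 at 1 nm declared precision; detector recall/precision over 25
synthetic fields of four emitters placed ≥ 600 nm apart (spots closer than
about two PSF widths merge by construction, which is a resolution limit,
not a detector defect). Generator-recovery checks use 10 000 progeny and
300 (or 91) nuclei per zone, with 3-SD/SE acceptance bands. Densities are
floored at 1e-300 before logs; Nelder–Mead tolerances are 0.2 nm in
parameters and 0.02 in negative log-likelihood.

## Known limitations

- The hollow/filled decision is calibrated only in the sense of model
  selection; no per-focus confidence is attached beyond the normAICc gap.
- The filled-model quadrature under-resolves blurs far below ~2 nm at
  typical focus sizes; the zero-blur closed form covers the limit exactly.
- Composite-interval crossovers are counted in no simple interval, so heavy
  missingness shrinks per-interval denominators quickly.
- The detector fits axis-aligned Gaussians; strongly tilted elongated foci
  report their σ along image axes.
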