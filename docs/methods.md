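# Methods

This note documents the models, numerical choices and limitations of the
seedmorph pipeline, in the order the data flow through it.

## Coordinate conventions

All geometry is handled in mathematical coordinates (x right, y up,
0-based pixel centers). When a mask of height H is read, image row r maps
to y = (H − 1) − r. Landmark files are expected to store y-up coordinates
(as the simulator writes them and as TPS digitizers conventionally do).
"Length" is the vertical bounding-box extent under the standard
acquisition orientation (hilum to the right, broader end down) — the
landmark 4–5 axis — and "width" the horizontal extent; the box is
axis-aligned by convention, not rotated to the major axis.

## Outline extraction

The largest connected foreground component is traced with marching
squares at the 0.5 iso-level, giving a sub-pixel closed polygon, forced
counterclockwise. Components touching the image border are kept but
flagged. Re-rasterizing a traced outline and re-tracing changes the
perimeter by <2% at ≥50 px object scale (tested); absolute staircase bias
against the underlying smooth curve is larger (~4%) but cancels in any
within-pipeline comparison, since every specimen passes through the same
tracer.

## Procrustes normalization

Superimposition parameters are estimated on the five-landmark
configurations — translation by the landmark centroid, scaling to unit
centroid size, rotation by iterative least-squares fit to the consensus
(tolerance 1e-10 on consensus displacement, max 100 iterations,
reflections disallowed) — and then applied to the full outlines. Running
GPA on landmarks rather than on outline points is a deliberate choice:
the five landmarks are the only homologous points, whereas dense outline
points have no point-to-point homology before the start-point is fixed.
After convergence the consensus is rotated so its landmark 4→5 axis
(top→bottom) is vertical; without this canonicalization the aligned frame
would inherit the first specimen's arbitrary orientation, and alignment
would not be invariant to re-acquiring specimens at different rotations
(an invariance the test suite verifies to 1e-6 on 100 random shapes).

Non-convergence warns and sets a flag rather than raising, so a long run
is not lost to one pathological specimen.

## Elliptic Fourier transform

The transform uses the piecewise-linear (chain-sum) formulation on the
polygon's own arc-length parameterization — exact for polygonal input and
the standard choice in outline morphometrics — rather than an FFT of
sampled coordinates. Outlines are resampled to 360 points at equal arc
length, starting at the on-curve point nearest landmark 2 (ties broken
toward the lower arc position), before decomposition.

Two properties of this parameterization matter for interpretation:

- The coefficients of an ellipse are *not* its semi-axes: arc-length
  parameterization slows through the high-curvature ends, so a 2:1
  ellipse yields a₁ ≈ 1.83, d₁ ≈ 1.07 (the tests pin these against direct
  numerical integration of the Fourier integrals).
- A truncated series is not automatically its own arc-length
  parameterization, so transform→reconstruct→transform is only an
  identity on shapes at the fixed point of that map. The test suite
  constructs such band-limited shapes by iterating the round trip; they
  recover coefficients to better than 1e-3 relative.

Because size, position and orientation are removed by the landmark-driven
GPA and the start point by landmark 2, no additional first-harmonic
normalization is applied: all four coefficients of harmonic 1 remain as
shape variables (20 variables at H = 5). The first harmonic then mostly
encodes the width/length aspect of the normalized outline.

### Harmonic retention

Retention uses cumulative harmonic power, with H\* the smallest count
whose population-mean cumulative fraction reaches the 95% threshold. The
pipeline computes this fraction over harmonics ≥ 2 (`drop_first=True`).
The reason is empirical and structural: under arc-length parameterization
harmonic 1 carries >99.8% of raw power for any realistic seed outline —
even a deeply reniform one — so a denominator that includes it makes the
rule insensitive to every feature beyond the gross ellipse and always
returns H\* = 1. Dropping the dominant first harmonic is the standard
calibration in outline-morphometrics software for exactly this reason.
`choose_harmonics` retains an include-all mode (`drop_first=False`),
which matches the plain arithmetic definition. With the default synthetic
populations the rule retains H\* = 5.

## Measurement error

%ME follows the variance-component definition: a one-way ANOVA with
individuals as groups gives s²within = MSwithin and
s²among = max(0, (MSamong − MSwithin)/m) for m repeats, and
%ME = 100·s²within/(s²within + s²among). The negative-component clamp is
the standard estimator guard; it makes %ME exactly 100 when individuals
are indistinguishable. The design must be balanced.

Which scalar the ANOVA should summarize a 20-dimensional shape by is
genuinely ambiguous. `shape_measurement_error` therefore reports %ME per
principal component of the repeated-measures coefficient matrix *and* a
pooled value obtained by summing the within- and among-individual
variance components across the retained PCs (those reaching 95%
explained variance). The pipeline reports the pooled value per taxon and
test, alongside PC1's F and p.

## Group statistics

- Kruskal–Wallis with tie correction (scipy), guarded to return
  (H = 0, p = 1) when all values are identical.
- Pairwise two-sided Wilcoxon rank-sum tests: exact for small tie-free
  samples, normal approximation with tie/continuity correction otherwise.
  Raw P-values are emitted by default; Bonferroni is available as an
  option but not applied.
- PCA is centered, not scaled (all coefficients share units after
  normalization). Unknown specimens are supplementary: centered with the
  training means and projected on the training loadings, so they never
  influence the axes. Component signs are fixed deterministically.
- The permutational MANOVA partitions the total sum of squared Euclidean
  distances between coefficient rows into between- and within-group
  parts; pseudo-F = (SSb/(g−1))/(SSw/(N−g)), r² = SSb/SStot, and
  adj. r² = 1 − (1−r²)(N−1)/(N−g) (the ordinary degrees-of-freedom
  penalty; reported alongside raw r² since "adjusted" is not uniquely
  defined for this statistic). P-values use the (1 + b)/(n_perm + 1)
  estimator with a seeded permutation stream; in one dimension the
  pseudo-F reduces exactly to the classical ANOVA F (tested), and the
  statistic is cross-checked against an independent implementation.
- UPGMA runs on Euclidean distances between per-taxon mean coefficient
  vectors; node heights are half the merge distance, so cophenetic
  distances reproduce ultrametric inputs exactly. Output is Newick with
  branch lengths, to be displayed unrooted.

## Classification

LDA is the classical shared-covariance Gaussian discriminant:
per-class means, pooled within-class covariance (divided by N − g), and
equal priors by default (the benchmark balances classes by construction;
proportional priors are a documented switch). A singular pooled
covariance — possible when shape variables outnumber a subsample — is
ridge-regularized with ε = 1e-8·trace(Σ)/p and a warning. Features are
not standardized (LDA is affine-equivariant); sizes enter as natural
logs.

LOOCV refits without each row via a rank-one downdate of the class sums
and pooled scatter instead of recomputing them, and is verified against
the literal refit-n-times oracle. The balanced benchmark subsamples every
over-represented class to 30 per permutation (smaller classes enter
whole), runs LOOCV per descriptor family on the same subsample, and
reports per-class accuracy distributions; 1000 permutations for the
modern-material benchmark and 100 for unknown assignment are the protocol
defaults. The shuffled-label baseline permutes labels within each
balanced subsample and reports the maximum per-class accuracy across
permutations — the extreme of a multinomial draw — as the chance ceiling.
Unknowns are assigned the modal class of their per-permutation
predictions; exact vote ties are flagged `ambiguous` rather than silently
broken (the lexicographically first tied class is reported).

## Synthetic populations

The generator parameterizes taxa directly in coefficient space, so the
ground truth of every downstream estimate is known. Since no quantitative
distributional parameters exist for the real material, the defaults were
chosen once for testability and plausibility, not biological fidelity:

- **Shape families** (unit scale, five harmonics, built from radial
  deformations of an ellipse): two elongated taxa (aspect 0.55/0.62), two
  strongly reniform taxa (deep hilum indentation, aspect 0.84/0.74), and
  three rounded taxa (aspect 0.93) sharing one base shape. The rounded
  triple's means differ by two roughly orthogonal deformation directions
  (deeper dent + egg asymmetry vs shallower dent + opposite asymmetry)
  scaled by a single `separation` factor: pairwise mean distances are
  exactly linear in it, all three collapse at 0, and the magnitude was
  calibrated once so that separation 3 yields >90% per-class LOOCV and
  separation 1 (the default study condition) leaves the triple strongly
  overlapping in shape while all descriptors combined still dominate each
  single family. Small angular-harmonic ripples give every taxon genuine
  content up to the fifth elliptic harmonic, so the retention rule has
  signal to find.
- **Sizes**: length and width are independent log-normals per taxon
  (log-SD 0.10 ≈ 10% coefficient of variation); the drawn outline is
  rescaled anisotropically to the drawn extents. Means span 0.65–1.20 mm
  (length), with the domesticated-type taxa largest and the close wild
  relative intermediate, so size alone separates the triple only
  partially.
- **Cell counts**: negative-binomial with dispersion 60 (mildly
  overdispersed; Poisson in the large-dispersion limit), means 40–95 with
  the designated lowest- and highest-count taxa at the extremes.
- **Within-taxon shape noise**: independent normal per coefficient, SD
  decaying by harmonic (0.015 for harmonic 1 down to 0.003 for harmonic
  5).
- **Acquisition noise**: in-plane rotation (positioning), a smooth
  low-angular-frequency radial field for outline perturbation
  (re-cleaning; marginal SD is the configured fraction of centroid size —
  white per-point noise would roughen the contour and inflate arc length
  in a way no plausible cleaning does), and landmark placement jitter.
  Rotation is removable by GPA *except* through its effect on automatic
  landmark placement — the top/bottom extremes and arc-fraction points of
  a rotated outline are different material points — which reproduces the
  real phenomenon that positioning error dominates reproducibility
  (pooled %ME ≈ 54% for the position test vs ≈ 10–12% for cleaning and
  landmarking under the defaults).
- **Landmark auto-placement**: landmarks 4/5 at the y-extremes, 1–3 at
  fixed arc fractions (0.45, 0.50, 0.55 of the perimeter from the top,
  counterclockwise) — a reproducible analogue of manual hilum-arch
  digitization; landmark 2 doubles as the outline start point.
- **Rendering**: outlines are polygon-filled at 100 px/mm (a ~1 mm seed
  spans ~100 px); spans below 16 px raise an explicit resolution error.

What the generator does **not** emulate: 3-D globoid projection effects
(rotation is purely in-plane), surface texture and cell boundaries (cell
counts are drawn, not measured from the image), taphonomic deformation of
archaeological material (waterlogging swell, charring), focus-stacking
artifacts, and correlated length–width draws. Consequently, passing tests
demonstrate that the pipeline recovers what this generative model encodes
— they do not certify accuracy figures on real seed photographs, whose
reference collections are not distributed with the package.

## Reproducibility

Every run requires an explicit RNG seed; each stage derives its own
substream from it (`SeedSequence.spawn`), so stages are individually
reproducible. Identical configs produce byte-identical `summary.json`
files (hash-checked in the tests). Permutation counts, the harmonic
threshold, the resampling density and the balancing size are all config
fields with the protocol defaults above.

## Problem sizes and runtimes

The reference experiment is 7 × 30 + 2 × 30 modern seeds plus 33
unknowns; the repeatability designs are 5 seeds × 3 taxa × 3 repeats per
test. The acceptance script runs the benchmark at 1000 permutations and
completes in a few minutes on one CPU; the test suite's end-to-end runs
use 100 permutations (and a reduced population for pure smoke tests),
finishing in about a minute. The type-I calibration tests use 2500 null
PERMANOVA datasets (199 permutations each) and 5000 null Kruskal–Wallis
datasets, sized so the 4–6% acceptance band is several standard errors
wide.
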