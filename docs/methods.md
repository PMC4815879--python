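# Methods

`sfxkit` implements the downstream data-reduction stages of serial
(femtosecond) crystallography: starting from per-snapshot indexed
reflection lists ("streams"), it resolves merohedral indexing
ambiguities, refines the per-crystal diffraction model (lattice basis,
beam centre, profile radius, resolution estimate), scales and merges the
partial intensities, and computes figures of merit.  A geometric
simulator generates complete synthetic datasets with recorded ground
truth so that every estimator can be scored quantitatively.

## Conventions

* Reciprocal vectors use the crystallographic 1/d convention (no 2π);
  `s = sinθ/λ = (1/d)/2`.
* Internal lengths are SI (m, m⁻¹); unit cells are expressed in Å and
  degrees at the API surface, streams store nm and nm⁻¹.
* The beam travels along +z; a single flat detector panel sits
  perpendicular at distance `camera_length`.  Pixels are 0-based with
  centres at integer coordinates.
* The excitation error of a reciprocal point q is
  `r = |q + k ẑ| − k` with `k = 1/λ`: negative inside the Ewald sphere,
  zero at the exact Bragg condition.  Built-in point groups cover the
  merohedral-ambiguity cases (1, -1, 2/m, mmm, 4/m, 4/mmm, 3, -3, 6/m,
  6/mmm, m-3); arbitrary groups can be supplied as explicit operator
  lists.  The canonical representative of a Miller index is its
  lexicographically greatest image under the group.

## Partiality model and simulator

A still snapshot records only a fraction of each reflection's full
intensity.  We model the scattering density around each reciprocal
lattice point as a sphere of profile radius `R`; the recorded fraction is
the volume of that sphere inside the Ewald sphere, approximated by the
flat-cut spherical cap:

    t = clamp((R − r) / 2R, 0, 1),   p = 3t² − 2t³,

so p(−R) = 1, p(0) = ½, p(+R) = 0.  The Ewald sphere is treated as
monochromatic; bandwidth and divergence are recorded in the
configuration but not used (set "to small values" in the diffraction
model this package follows).

The simulator draws, per crystal: a uniform random orientation
(quaternion method), a lognormal profile-radius jitter (σ = 0.1 about
R = 2·10⁷ m⁻¹), a lognormal linear scale G (µ = 0, σ = 0.3 in ln-space),
a normal Debye–Waller term B (5 ± 3 Å²), and optionally a mis-indexing
flip through a stated ambiguity operator (probability 0.5).  Reference
intensities are exponential (Wilson-like) draws whose mean decays as
`exp(−2·B_wilson·s²)` with B_wilson = 20 Å², I₀ = 1000, complete to the
stated d_min.  A reflection is recorded whenever `|r| < R`; its measured
intensity is `G · exp(−2Bs²) · p · I_ref` plus Gaussian noise with
`σ = max(σ_floor, c·√max(I,0))` (σ_floor = 2, c = 1 by default), so
negative measured intensities occur, as in real background-subtracted
data.  The default cell is tetragonal 40 × 40 × 60 Å (point group 4/m,
metric symmetry 4/mmm, ambiguity operator k,h,−l), giving ≈1000
symmetry-unique reflections to d_min = 3.7 Å and ≈90 recorded
reflections per snapshot on the default detector (λ = 1.3 Å,
camera length 80 mm, 100 µm pixels).

What the simulator does **not** emulate: pixel-level images and
integration errors, detector panel gaps and tilts, beam spectrum and
divergence, absorption, radiation damage, non-isomorphism beyond the
G/B/partiality model, and correlated (non-Gaussian) noise.  Passing
tests therefore demonstrate the correctness and statistical behaviour of
the algorithms under their own model assumptions, not performance on
real FEL data.

## Indexing-ambiguity resolution

One-dimensional correlation clustering: random initial binary
assignments; for each crystal in turn, f = mean pairwise Pearson CC
against same-assignment crystals and g = mean against
opposite-assignment crystals; swap if g > f strictly (ties stay, which
guarantees identical-data fixed points); pass over all crystals until no
assignment changes (safety cap 10 passes).  CCs are computed once, on
symmetry-merged (mean of duplicates) raw intensities restricted to a
resolution window (default 40–4 Å); pairs with fewer than 3 common
unique reflections or zero variance are undefined and excluded from the
means.  An all-pairs CC matrix over N crystals costs a handful of dense
matrix products (zero-filled masking), so N = 500 resolves in about a
second; a partner budget (`ncorr`) reduces O(N²) to O(nN) with partners
drawn once, seeded.

When the reindexing operator is known, f additionally includes the CCs
against opposite-assignment crystals after reindexing them.  We complete
this rule symmetrically: g includes the reindexed CCs against
same-assignment crystals, so f and g evaluate the two labelling
hypotheses over the same partner set.  Without the symmetric term, a
dataset containing no genuine flips oscillates indefinitely (f is
diluted by near-zero reindexed CCs) instead of collapsing into a single
class — the behaviour needed by the second pass of the double-ambiguity
strategy, which resolves two independent ambiguities by running the
algorithm twice and combining the labels.

A note on attainable correlations: with raw partial intensities and
sphere-cap partialities, the pairwise CC between two same-group crystals
is bounded by `E[p]² / E[p²] ≈ 0.67` (p varies independently per
crystal), and sits near 0.5 at the default conditions.  The clustering
succeeds regardless because f and g are means over hundreds of partner
CCs; the separation (f − g after convergence) is the meaningful signal.

## Prediction refinement

Spots are paired with reflections by back-projecting each detector peak
onto the Ewald sphere, solving for fractional Miller indices against the
crystal basis, rounding (however far from integral), and keeping the
pair only if the predicted position falls within ten pixels of the
observed spot.  Retained pairs are sorted by increasing |r| and the tail
truncated at the first gap exceeding 5× the median of the preceding
gaps, starting from position max(4, ⌈N/4⌉) — the "first abrupt increase
of r" rule.  We sort by |r| rather than signed r because outliers occur
on both sides of the Ewald sphere; both the constant K = 5 and the
minimum prefix are configurable interpretations of an intent-level rule.

The refinement minimises

    Σᵢ Îᵢ [ w·rᵢ² + (x_obs,i − x_calc,i)² + (y_obs,i − y_calc,i)² ]

over the nine basis components and two beam-centre coordinates, with
positions in metres, Î the spot intensity over the pattern maximum
(clamped at 0 for noise-negative spots), and w = 10⁻²² m⁴ by default so
that a typical excitation error (~10⁷ m⁻¹) weighs like a ~1-pixel
(10⁻⁴ m) position error.  Minimisation is a Levenberg–Marquardt loop
with forward-difference Jacobian over scaled parameters; damping is
adapted so the cost history is monotonically non-increasing, with
termination at relative change < 10⁻⁶ or 100 iterations.  Crystals with
fewer than ten paired spots are rejected.

Two intentional consequences of this residual are worth noting.  First,
the r-term pulls genuinely off-sphere (partial) reflections towards the
Ewald sphere, so for simulated data the minimiser sits slightly off the
generating basis; exact basis recovery holds only in the
position-dominated regime (small w).  Second, a small lattice rotation
nearly mimics a beam-centre translation over a limited 2θ range; the
joint fit therefore recovers the shift magnitude more precisely than its
direction (median magnitude error ≈ 0.07 px vs ≈ 0.12 px for the 2-D
vector at 0.2 px spot jitter, ~90 spots).

After refinement the profile radius is set to the nearest-rank 98th
percentile of |r| over the retained pairs, so ≥98% of paired spots are
predicted; the resolution estimate is the nearest-rank 98th percentile
of 1/d over "accounted" spots (all three fractional indices within 0.25
of integers).  Final prediction enumerates, from scratch, all hkl with
|r| < R and 1/d ≤ resolution estimate + push_res (push_res may be
negative; default no cutoff).

## Scaling and merging

Simple merging averages the measurements of each symmetry-unique
reflection (unweighted mean; merged σ = sample sd/√n for n ≥ 2, the
observation's own σ for n = 1 — a choice, since the model is silent on
singletons).  Optional per-crystal resolution cutoffs
(estimate + push_res) and an upstream-set saturation flag exclude
observations before averaging.  Two-pass scaling merges once, then fits
each crystal's least-squares-through-origin scale
`k = ΣI·I_ref / ΣI²` against that reference and merges k·I.

Iterative scaling fits, per crystal, the logarithmic residual model

    ln Iᵢ = ln G − 2B·sᵢ² + ln pᵢ + ln L + ln I_ref,i

with L = 1, p = 1 (fixed; partiality correction is deliberately not
performed — the p term remains in the interface for future
post-refinement) and unit weights; the fit is ordinary linear least
squares in (ln G, B), exact in one step.  Only reflections with I > 0
and I_ref > 0 can enter a logarithm; a seeded 5% free set is excluded
from the fit and pooled into a separately-reported free residual.
Crystals with |B| > 100 Å² (configurable) or with no more usable
reflections than parameters are excluded from all further processing.
The reference is the merge of all surviving crystals' scaled intensities
`I/(G·exp(−2Bs²))`; merge-then-fit cycles repeat a configured number of
times (default 3).  The log residual guarantees G > 0 and roughly equal
weight across resolution.

The gauge freedoms are real and tested: all G up to a global factor, all
B up to a global offset (absorbed into the reference); a uniform
intensity factor between dataset halves or labels is *exactly* a G gauge
and is correctly absorbed by scaling — only reflection-dependent
differences between custom-split groups survive, which is why splitting
is done after joint scaling on a shared reference.

Half-dataset splits assign whole crystals by seeded permutation (sizes
differ by at most one).  Identifier-based splitting merges per label on
the jointly-scaled intensities, plus half-splits per label and overall;
per-reflection measurement counts are conserved across a partition.

Polarization correction divides I and σ by
`P = f(1 − sin²2θ cos²φ) + (1−f)(1 − sin²2θ sin²φ)` (φ the detector
azimuth, f = 1 fully horizontal); the standard Thomson form, since only
the correction's existence, not its formula, is prescribed by the
method this package follows.  Reflections with P < 0.01 are dropped.

## Figures of merit

CC½ is the plain Pearson correlation of merged intensities over the
common unique reflections of two half-dataset merges (no σ–τ
correction); Rsplit = (1/√2)·Σ|I_A − I_B| / (½·Σ(I_A + I_B)).  Shells
hold equal numbers of unique reflections by default (binning is a free
choice here) and a shared `ShellScheme` guarantees identical boundaries
across statistics; overall values are pooled, never averaged over
shells.  Completeness counts observed unique reflections against an
exhaustive enumeration of the possible unique set for the cell, symmetry
and resolution range.  Undefined quantities (shells with n < 3, zero
denominators) are reported as NaN, not silently dropped.

## Cell statistics

`collect_cells` tabulates per-crystal cell parameters from a stream;
`fit_gaussian` is a maximum-likelihood normal fit (sample mean and sd)
of the values inside a user window — deliberately bin-independent,
rather than a curve fit to histogram bars — and `conditional_filter`
reproduces linked-histogram selection headlessly.

## Problem sizes and numerical choices

The test-suite and acceptance-script runs use: 500 crystals for
ambiguity resolution, 300 for G/B recovery (to d_min = 3.0 Å,
I₀ = 10⁴, c = 3.5, ≈5% median relative noise — chosen so the noise,
not the resolution lever arm, limits B precision), 10 × 120 crystals
for the CC½ ordering comparison, and 100 crystals at 0.2 px spot jitter
for beam-centre recovery; these sizes give stable statistics in seconds
per block.  Percentiles use the nearest-rank convention throughout.
Degenerate inputs fail loudly: cells without positive volume, singular
bases, datasets with no common reflections, and crystal sets in which no
pair shares enough reflections for a defined CC all raise typed errors.

## Known limitations

Single-panel perpendicular detector only; no image-level I/O or
integration; no post-refinement of orientations/partialities against the
reference (the scaling model keeps the hooks); Lorentz factor fixed at
1; no systematic-absence handling; the CLI is single-threaded (the
algorithms are deterministic for a fixed visiting order regardless).
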