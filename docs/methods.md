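# Methods

## Model and procedure

The engine treats a mental state as a point in voxel-activity space. A
localizer stage measures one anchor pattern per induced state; the analysis
stage compresses the anchors' pairwise dissimilarity structure into a 2-D or
3-D *semantic map*; the feedback stage places each new current-mental-state
(CMS) estimate into that map and renders it, together with a target-related
intensity value, as one of two display geometries.

**Dissimilarity metrics.** The default is the correlation distance
*d* = 1 − Pearson *r*, which normalizes out both mean and scale of a
pattern and is cheap enough for per-volume use. Patterns entering the
correlation metric are deliberately *not* z-scored first — the metric
already normalizes; z-scoring and percent-signal-change normalization are
offered for the Euclidean and Mahalanobis metrics, where scale carries
information. The Mahalanobis metric uses a diagonal noise covariance
estimated from residual patterns with shrinkage toward the scaled identity
(weight 0.3 by default, configurable): with far more voxels than trials the
full sample covariance is singular, and the shrunk diagonal is the simplest
estimator that is always positive definite. Constant (zero-variance)
patterns raise an error everywhere rather than returning a sentinel: a
silently wrong dissimilarity would corrupt the map.

**Embedding.** Classical (Torgerson) MDS: square the dissimilarities,
double-center, eigendecompose, retain the top *dims* strictly positive
eigenvalues, scale eigenvectors by √λ. Classical MDS is deterministic and
closed-form, and its eigenbasis is exactly what the landmark projection
needs; the trade-off is that it minimizes *strain*, not stress. RDM entries
are treated as distances (squared before double-centering), not as already
squared. Correlation RDMs are generally non-Euclidean; negative eigenvalues
are truncated and the retained-variance fraction is logged. If fewer than
*dims* eigenvalues are strictly positive the embedding errors, naming the
spectrum — which means a request is viable only when the anchor count
exceeds the dimensionality (n points span at most n − 1 positive
eigenvalues; degenerate cases such as two anchors embed at dims = 1).

**Landmark projection.** A new pattern's squared dissimilarities δ to the
anchors are centered against the column means μ of the squared
anchor-distance matrix and mapped through the eigenbasis,
*x* = ½ Λ^(−1/2) Vᵀ (μ − δ). The map is *fixed* after the localizer stage —
only the CMS point moves; online re-embedding is intentionally out of
scope. Anchor self-projection reproduces the anchor's own row (also on
truncated non-Euclidean maps), and for exactly realizable RDMs held-out
points are recovered to numerical precision.

**Orientation.** MDS output is unique only up to rotation/reflection. Maps
are canonicalized — anchor 1 on the nonnegative first axis, anchor 2 with
nonnegative second coordinate, anchor 3 (3-D) with nonnegative third — via
Gram–Schmidt on the first anchors, and the resulting orthogonal matrix is
stored and applied to projections too, so replays are bit-stable.
Degenerate configurations (anchor 1 at the origin, collinear anchors) pass
through unchanged or with a deterministic fallback axis, flagged in the
orientation tag.

**Stress.** Goodness of fit is Kruskal stress-1,
√(Σ_{i<j}(δ_ij − d̂_ij)² / Σ_{i<j} δ_ij²). For Euclidean-realizable RDMs
stress is non-increasing in the embedding dimension (the eigen-projection
only shrinks distances). For non-Euclidean RDMs under classical MDS this
monotonicity can fail — truncated negative eigenvalues let some embedded
distances overshoot — and the test suite asserts it only on Euclidean
inputs. This is a known property of strain minimization, not a defect of
the implementation.

**Pattern strength.** CMS and target (TMS) vectors are mean-centered before
the projection, so the similarity (the cosine of the angle θ between them)
coincides with the Pearson *r* used everywhere else; a raw-vector mode is
available behind a flag. Strength is the scalar projection coefficient
(CMS·TMS)/(TMS·TMS), giving the scale law strength(k·CMS) = k·strength and
the identity strength = r·‖CMS‖/‖TMS‖. Negative strength renders as
minimum marker size / empty thermometer rather than an inverted display.

**Circular display.** Thermometer placement is either generic (equal
spacing from the top of the circle, for fixed semantic schemes like
valence/arousal) or dissimilarity-driven. The dissimilarity mode needs a
discrete objective the formula alone does not supply: once adjacent gaps
are made proportional to adjacent dissimilarities, any ordering trivially
matches its own gaps. The objective used is therefore the mismatch over
*all* pairs between angular arc distance and the target separation
π·d_ij/d_max, minimized by exhaustive search over distinct necklace
orderings (bounded at n ≤ 8, i.e. ≤ 2520 orderings). This reproduces the
intended behaviours: an all-equal RDM yields equal spacing, and a single
dominant dissimilarity places that pair adjacent with the widest gap. The
central arrow uses dist = 1 − t/(t + nb) with target and neighbour
similarities clamped at zero first, because the printed formula misbehaves
for negative correlations; the neighbour is restricted to the two
layout-adjacent thermometers, and when no similarity is positive the arrow
pins to the target with a low-confidence flag. Since t ≥ nb ≥ 0 by
construction, dist ∈ [0, 0.5] and the arrow never leaves the
target–neighbour arc.

## Online CMS extraction

The driver supports a trial mode (each source row already is a CMS; the
loop is testable with no volume simulation) and a volume mode: the CMS at
volume *t* is the mean of the W volumes ending D volumes before *t*,
converted to percent signal change against the baseline mean, then
exponentially smoothed (est ← α·psc + (1 − α)·prev). Defaults W = 4,
D = 2 volumes (≈ 4 s at TR 2 s), α = 0.5 follow common real-time practice;
an incremental GLM would be the natural upgrade and is out of scope.
Feedback begins once the delay-shifted window lies entirely after the
baseline period (a window identical to the baseline gives an exactly zero
PSC pattern, whose correlation is undefined). Feedback can be continuous
(every step, the default) or intermittent via `feedback_every`.

Per frame the driver records the correlation distance between the CMS and
the *instructed* target anchor; the displayed target is separately chosen
as the most-similar anchor, so instructed/achieved mismatches (engaging
'sad' when told 'happy') are visible in the trajectory.

## Synthetic ground truth

The generator emulates the *measurable consequences* of emotion induction,
not the induction itself. Anchors are built by mixing i.i.d. standard-normal
voxel vectors through a matrix square root of a prescribed correlation
matrix; the achieved sample correlations are returned so tests compare
against what was actually realized. The default structure is a four-state
valence layout (within-valence r = 0.5, between-valence r = 0) at 500
voxels — a plausible ROI-scale localizer. Trials are
intensity·anchor + noise with noise SD 0.5 of the anchor SD by default
(strong single-trial noise that 20-trial condition means still average
out). Volume streams convolve block boxcars with the canonical double-gamma
HRF (peak 6 s, undershoot 16 s, ratio 1/6) at 2 % signal change and 0.2 %
noise.

The agent abstracts "engaging in an emotion" as movement on the anchor
simplex: w ← (1 − η)w + η·e_target, jittered (SD 0.02) and re-projected to
the simplex (Euclidean projection), emitting mixture patterns with emission
noise SD 0.3 of the mean anchor SD. The neutral start is the uniform
mixture. The two-run learning scenario keeps one continuous agent
navigating to a fixed target across the run boundary: run 1 contains the
geometric approach transient, run 2 the converged phase, so a positive
learning rate produces positive between-run improvement while a
zero-learning agent's improvement is centred on zero. What passing tests
show is that the engine *detects* this learning signature; they do not show
that human participants behave like the agent — real data add
physiological confounds, drift, head motion and non-simplex dynamics that
the generator deliberately omits.

## Numerical choices

- Eigenvalue positivity tolerance: 1e−10 relative to the leading
  eigenvalue; eigenvector signs fixed by making the largest-magnitude
  component positive before orientation.
- Landmark self-consistency, hold-out recovery and planted-configuration
  Procrustes residuals are tested at 1e−8; serialization round-trips at
  1e−12 (floats are written at 17 significant digits, i.e. exactly).
- Ties in target selection and voxel ranking break by declared order
  (anchor order, ascending voxel index) so outputs are stable.
- Test problem sizes (300–500 voxels, 20 trials per condition, 100-seed
  replicate sweeps, 20-step runs) are chosen as the smallest sizes at which
  the statistical claims are comfortably away from their thresholds.

## Known limitations

- Classical MDS minimizes strain; for strongly non-Euclidean RDMs a
  stress-majorization refinement would fit better and would also restore
  stress monotonicity in dims.
- The Mahalanobis estimator is diagonal-only; a full shrinkage covariance
  (and cross-validated crossnobis distances) are natural extensions.
- Voxel selection uses a per-voxel one-way F statistic as a deterministic
  stand-in for classifier-weight ranking.
- The circular layout's exhaustive necklace search is factorial and capped
  at 8 anchors; larger sets must use the generic layout.
- The volume-mode CMS estimator is a windowed average, not an incremental
  GLM; slow drifts and motion are not modelled.
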