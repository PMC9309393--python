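# Methods

## Scope and data model

The unit of analysis is a `Recording`: a channels × samples real matrix
with a sampling rate, ordered channel labels and a band tag. The package
assumes preliminary cleaning (artifact removal, re-referencing,
down-sampling) has already happened; it begins at band decomposition and
ends at scene export. Connectivity is undirected: every estimator is
symmetric in its arguments, matrices are stored dense and mirrored, and
the diagonal holds the metric's self-value (1 for the three base metrics,
0 for the comprehensive score).

## Band extraction by wavelet packets

A full wavelet packet tree of depth L splits [0, fs/2] into 2^L leaves of
nominal width fs/2^(L+1) once the leaves are re-ordered from natural
(tree) order to frequency order; `pywt`'s frequency ordering performs the
required Gray-code reordering. A band [lo, hi] is reconstructed from every
leaf whose nominal interval [k·fs/2^(L+1), (k+1)·fs/2^(L+1)) overlaps it.
Overlap (rather than containment) selection means adjacent bands share
boundary leaves; the four rhythm reconstructions therefore jointly cover
the 1–30 Hz content with no gaps, at the cost of slight double counting
at leaf boundaries.

Defaults: depth 6 (1.5625 Hz leaves at fs = 200 Hz) and the `db16`
wavelet. The wavelet length matters: very short filters (db4) have
transition bands wider than a leaf, which leaks a mid-alpha tone's energy
into neighbouring leaves and across the alpha/beta boundary — measured at
fs = 200, a 10 Hz tone keeps only ~80 % of its energy in the alpha
reconstruction and ~19 % appears in beta. With db16 the same tone keeps
95 % in alpha and 4 % leaks to beta, which is what the band-selectivity
tests require; longer filters sharpen this further but cost proportionally
more per transform. Both the wavelet and the depth are parameters.

Decomposition precedes windowing: dynamic frames are cut from one global
band-limited signal, so per-window filter transients never arise.

## Estimators

**PCC** is the textbook sample correlation; constant series raise rather
than return NaN. The sign is preserved throughout the pipeline because
negative correlations are styled distinctly in scenes.

**Band coherence** uses Welch auto-/cross-spectra (Hann window, 50 %
overlap, constant detrend). Per-bin magnitude-squared coherence is
averaged over the bins inside the band (mean, not max — a deliberate
choice: the band scalar should reflect the whole band, not one peak bin).
Fewer than two Welch segments is refused: single-segment coherence is
identically 1 at every bin. The known positive bias of magnitude-squared
coherence is about 1/(number of segments); tests on independent noise use
~64 segments accordingly.

**PLV** extracts instantaneous phases from the Hilbert analytic signal.
This is meaningful only for band-limited inputs, so the intended pipeline
is wavelet band extraction first. Explicit phase series can be passed
directly (`phase_input=True`), which the synthetic phase-coupled generator
uses for exact oracle comparisons.

## Comprehensive re-scoring

Degree weights per channel are the mean off-diagonal connectivity into
(w_in) and out of (w_out) the channel, divisor n−1; the self-term is
excluded because a constant self-value of 1 would inflate every degree
equally while carrying no connectivity information. The edge re-score is
d*_ab = ½(w_out(a) + w_in(b))·d_ab, which for the symmetric base metrics
equals ½(deg(a)+deg(b))·d_ab and is therefore orientation-independent.
Raw scores are min–max normalized over the off-diagonal entries to the
base metric's native range — [−1, 1] for a PCC base, [0, 1] for coherence
or PLV — then mean-centered so that above-average edges are positive and
below-average edges negative. The matrix meta records the raw extrema and
the centering mean, making the transform invertible from the sidecar.
A degenerate all-equal input normalizes to the range midpoint and centers
to an all-zero matrix: in a uniform graph no edge stands out.

Centering happens before fractional thresholding, so the threshold rule's
sign branches act on the centered scores.

Comprehensive scores are *within-network* contrasts; they are not used for
between-group aggregation, which always sums a base metric.

## Aggregation, comparison, dynamics

Between-group connectivity is the plain double sum of channel-pair
weights across the two groups; within-group (internal) connectivity sums
each unordered pair once, because a per-group total that counted ordered
pairs would silently double every number. Hemisphere sums exclude midline
electrodes; the region–hemisphere cross level (AFL, FR, …) is derived on
demand from the two indices and never stored. Summing the cross blocks
reproduces the hemisphere blocks exactly; this additivity is tested.

Condition comparison is the elementwise difference of two matrices with
identical labels, metric and band (positive = first condition stronger);
misaligned labels raise, and an explicit `reorder` is provided rather
than silent permutation. A ratio was rejected because the styling
semantics downstream are signed.

Dynamic connectivity slices the band-limited recording into fixed-length
windows (default 2 s, non-overlapping) and computes one matrix per
window. Only full windows are emitted. For stationary input the
frame-to-frame spread of an edge stays within a few multiples of the
estimator's sampling standard error ((1−ρ²)/√n for PCC), which is the
property the tests assert.

## Thresholding and scenes

One mean-split pass computes the mean of the surviving weights and keeps
the edges strictly above it when the mean is positive, strictly below it
when negative, and the strictly positive edges when the mean is exactly
zero (continuity with the positive branch). Modes 1/2 … 1/16 are 1–4
recursive passes; by construction each mode's edge set nests inside the
previous one. Strict inequalities make the rule deterministic under ties
(ties drop). Group-level matrices are thresholded by the identical rule.

Edges are styled by sign (golden-red for positive, black-white for
negative) and magnitude: thickness in [0.3, 3.0] scene units and opacity
in [0.15, 1] scale linearly with |w|/max|w|. Zero-weight edges are
omitted. Region and hemisphere polyhedra are convex hulls of the member
electrode coordinates (Qhull; joggled input for degenerate clouds, a
triangle fan for <4 points). Scenes serialize to a versioned JSON document
that round-trips losslessly, or to a static matplotlib 3D rendering.

The packaged montage has 81 extended 10–20 electrodes with template
coordinates in unitless scene units (only relative layout matters for
rendering). Nz and Iz belong to no region group but remain renderable
nodes; midline electrodes are excluded from both hemispheric groups.

## Synthetic data

The generators plant effects with closed-form expected values:

- `gen_correlated_pair`: y = ρx + √(1−ρ²)ε with x, ε i.i.d. standard
  Gaussian; E[pcc] = ρ, SE ≈ (1−ρ²)/√n.
- `gen_phase_coupled`: cosine carriers whose phase difference is i.i.d.
  von Mises(0, κ); asymptotic PLV = I₁(κ)/I₀(κ). A slow Wiener phase
  wander keeps the carrier realistic without touching the phase-difference
  statistics.
- `gen_structured_recording`: channel c in block k is
  √ρ_lo·g + √(ρ_hi−ρ_lo)·u_k + √(1−ρ_hi)·e_c from a global source g,
  block sources u_k and private noise, giving expected correlation ρ_hi
  within and ρ_lo between blocks; the mixture is then band-passed with one
  zero-phase Butterworth filter shared by all channels, which preserves
  the planted zero-lag correlations exactly in expectation. Labels are
  drawn from the packaged montage so aggregation paths are exercised.
  Defaults (8 channels in two blocks, fs = 200 Hz, 30–50 s, ρ_hi = 0.8,
  ρ_lo = 0.1, α carrier) mirror a clearly modular resting-style network at
  sample sizes where estimator noise is small relative to the planted gap.

What the generators do *not* emulate: 1/f background spectra, volume
conduction (shared sources at zero lag beyond the planted ones),
non-stationarity within a window, artifacts, or realistic electrode-wise
signal-to-noise gradients. Passing tests therefore demonstrate estimator
and pipeline correctness on signals with known ground truth, not
robustness to the confounds of real scalp EEG — in particular none of the
metrics here corrects for volume conduction.

## Numerical choices and edge cases

- Estimator outputs are clipped to their mathematical ranges to absorb
  float rounding (e.g. auto-coherence 1 + 1e−16).
- Welch default segment: min(256, largest power of two ≤ series length).
- Test problem sizes: n = 10⁴ samples for parameter-recovery checks
  (SE small enough that 3·SE bands are decisive), 30 s two-block
  recordings, 5×5 matrices for oracle equivalence at 1e−12.
- Statistical tests fix their seeds; tolerance bands are 3× the analytic
  standard error of the quantity, or ±0.03 where a Monte-Carlo oracle is
  the reference.
- Degenerate inputs have defined behaviour rather than NaNs: constant
  series raise, empty threshold survivor sets return empty edge sets,
  singleton groups score 0, all-equal comprehensive inputs map to the
  range midpoint.

## Known limitations

- Undirected metrics only; no effective-connectivity measures and no
  volume-conduction-robust variants (imaginary coherence, wPLI).
- The comprehensive score is a visualization aid, not a calibrated
  statistic; its normalization is per-matrix, so absolute values are not
  comparable across recordings (the meta sidecar carries the transform).
- Convex-hull region meshes ignore scalp curvature; they are display
  geometry, not anatomy.
- No statistical testing of condition differences; the comparison
  operator returns raw differences.
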