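# Methods

## Model

`coat2fcm` segments a 2-D grayscale image by clustering its pixels
(default: one intensity feature per pixel; optionally two spatial
channels) with interval type-2 intuitionistic fuzzy c-means, whose free
parameters — the C cluster centers and the fuzzifier pair (m₁, m₂) — are
selected by the Chimp Optimization Algorithm. The modelling assumptions
are:

* a lesion is a compact region whose intensity distribution is shifted
  upward relative to its surroundings, separable by intensity clustering;
* uncertainty about the "right" degree of membership softness is captured
  by an interval of memberships induced by two fuzzifiers rather than a
  single m;
* the brightest cluster centroid corresponds to the lesion (the
  `BRIGHTEST_CENTROID` rule; `LARGEST_MEAN_MEMBERSHIP` is available as an
  alternative).

## Membership bounds and the intuitionistic step

For centers V, each fuzzifier m ∈ {m₁, m₂} yields the standard FCM
membership u⁽ᵐ⁾_ij with exponent 2/(m−1); the interval bounds are the
elementwise min and max of the two matrices. A pattern at zero distance
from a center is assigned crisply (membership 1 there, 0 elsewhere), with
ties going to the lowest cluster index.

The intuitionistic component adds the Yager-class hesitation degree
π(u) = 1 − u − (1 − u^α)^(1/α) to both bounds (u ← u + π(u), clipped to
[0, 1]). α defaults to 2; α = 1 is the identity, and passing
`hesitation_alpha=None` disables the step, recovering plain IT2FCM.
Hesitation is applied *before* type reduction, so the Karnik–Mendel step
sees the widened bounds. Both choices (the Yager form, and the
before-reduction placement) are design decisions: they are the standard
construction and the order that lets hesitancy influence the centroids,
and disabling the step restores the plain algorithm exactly.

## Karnik–Mendel type reduction

For cluster j and feature ℓ the centroid interval endpoints are the
minimum and maximum of the weighted average Σ wᵢxᵢℓ / Σ wᵢ over
wᵢ ∈ [u̲_ij^m̄, u̅_ij^m̄], m̄ = (m₁+m₂)/2. The optimum always has the form
"upper weights below a switch point of the sorted xᵢℓ, lower above" (and
the mirror for the maximum), so the implementation sorts once per feature
and scores all N+1 switch points with prefix sums, taking the extreme
directly. This reaches the same fixed point as the classic iterative
Karnik–Mendel procedure — the test suite verifies equality with
exhaustive 2^N enumeration to 1e-9 on 100 seeded instances — in one
deterministic vectorized pass. Degenerate clusters (all weights zero)
raise an error rather than returning NaN.

The left/right membership of a pattern is the bound (lower or upper) the
extreme selected, averaged over features; crisp memberships are the
left/right midpoints with rows renormalized to sum to 1, and crisp
centroids the interval midpoints. With m₁ = m₂ every interval collapses
and the whole iteration reproduces classic FCM step for step; this
degenerate equivalence is tested to 1e-6 over 20 seeded mixtures.

## Objective and the swarm fitness

The clustering objective is J = Σ_ij u_ij^m̄ ‖xᵢ − v_j‖². Inside the
swarm search, a candidate (centers + fuzzifier pair) is expanded by one
inner membership/type-reduction pass and its resulting state is scored by
J evaluated at a *fixed reference exponent* m = 2 (`SCORE_FUZZIFIER`),
not at the candidate's own m̄. This is deliberate: since u < 1, the raw
J is monotone decreasing in the exponent, so scoring each candidate under
its own fuzzifiers rewards large (m₁, m₂) regardless of clustering
quality and drives the search to the fuzzifier upper bound, where
memberships are nearly uniform and the segmentation collapses. Scoring
every candidate's state on the common m = 2 scale removes that bias while
still letting the fuzzifiers act through the memberships and
type-reduction they induce. `score_fuzzifier=None` restores the raw
objective for study.

One inner pass per evaluation (rather than running to convergence) keeps
the swarm cheap; the winning vector is polished by up to 10 full IT2FCM
iterations (`final_refine_iters`) before labelling.

## Chimp optimizer

Defaults: pop 30, 100 iterations for standalone optimization; the
segmentation pipeline uses a 12-chimp, 30-iteration search, which on the
phantoms reaches the same Dice scores as larger budgets at a few seconds
per image. f decays linearly 2.5 → 0; coefficient vectors are drawn
independently per leader and per dimension; μ is drawn once per chimp,
with μ exactly at the 0.5 threshold taking the leader-guided branch
(fixed for determinism). The chaotic branch re-draws the position as
low + chaos·(high − low) per dimension — a bounded remap, so every
evaluated position stays inside the box. The chaotic source is the
logistic map x ← 4x(1−x) started at 0.7 (avoiding its fixed points);
tent and sine maps are selectable. The four leaders are the four best
solutions *ever* evaluated (elitism), which makes the best-so-far trace
provably non-increasing. Opposition-based initialization (also evaluate
low + high − x for each initial x, keep the better half) is available
behind a flag and off by default.

## Preprocessing

Intensity normalization z-scores the image and rescales affinely to
[0, 1024] — a strictly monotone map, idempotent to 1e-9. A constant
image raises a degenerate-input error. CC views are flipped when the top
half carries strictly more intensity mass (ties: no flip; odd row counts
drop the middle row). MLO views are flipped when the pectoral wedge —
the corner whose ⌈min(H,W)/4⌉-sized window has the greatest mean, ties
broken top-left first — lies in a bottom corner. Muscle removal is Otsu
thresholding plus the corner-connected bright component, zero-filled; it
never touches pixels outside the returned mask and is swappable behind
the single `remove_pectoral_muscle` operation.

## Phantoms and mixtures: what they do and do not show

The phantom generator emulates the gross structure of a mammogram the
segmenter relies on: a smooth low-frequency textured background (2–4
seeded sinusoids, amplitude ≈ 10 on a base of 120), elliptical lesions,
an optional bright pectoral triangle anchored top-left (intensity 40
above the lesions), and additive Gaussian noise. Lesion intensity is
defined as (mean non-lesion background) + contrast, so the noiseless
inside/outside mean difference equals the requested contrast exactly.
The default study condition is a 128×128 image, one lesion, contrast 30,
noise σ = 5, clustered with c = 3 (background / tissue-texture /
lesion).

Phantoms are *not* photorealistic: they lack scanner artifacts, skin
lines, calcifications, spiculated margins, and intensity inhomogeneity
beyond the smooth field. Passing phantom tests therefore shows the
algorithmic chain is correct and beats its baselines under controlled
contrast/noise, not that clinical-grade performance transfers to real
screening data.

The mixture generator draws balanced isotropic Gaussian clusters with
rejection-sampled centers at pairwise distance ≥ separation; the default
recovery condition (n = 600, c = 3, separation 8, noise 1) makes labels
recoverable by nearest-center assignment at ≥ 99%.

## Numerical choices

* Convergence: max absolute centroid displacement < tol (default 1e-5),
  max 100 iterations.
* Initialization: c distinct patterns sampled without replacement from
  the seeded generator when no centers are given.
* Fuzzifier search bounds [1.1, 5.0]; centroid bounds = per-feature data
  range.
* Undefined metrics (zero denominators, both masks empty) raise rather
  than return sentinels.
* All randomness flows from integer seeds through
  `numpy.random.default_rng`; equal seeds give bit-identical phantoms,
  fits, swarm traces and CLI outputs.

## Known limitations

* Single-image, 2-D, single-channel only; no batch training or 3-D.
* The k-means baseline is a plain Lloyd iteration (cross-checked against
  scikit-learn) — no k-means++ or restarts.
* The intuitionistic step is one hesitancy family (Yager); other
  generators of intuitionistic fuzzy complements are out of scope.
* The lesion rule assumes hyperintense lesions; hypointense findings
  would need the alternative rule or an inverted intensity channel.
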