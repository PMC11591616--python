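# Methods

## Topographic primitives

All topographic quantities are computed on average-referenced maps, so
they are invariant to the original recording reference. GFP uses the
population (1/N) normalization (the standard spatial-standard-deviation
definition). Spatial correlation is the Pearson correlation across
channels of two average-referenced maps: strength-independent and
**polarity-sensitive**. Polarity sensitivity is the evoked-response
convention: ERP components are defined by latency-locked polarity
(P1 vs N1), so a map and its inverse are different states here, unlike
in resting-state microstate work where the sign is ignored. Template
maps are stored zero-mean with unit GFP. Maps with GFP below 1e-12 µV
are treated as zero fields: they are excluded from clustering and
back-fitting rather than given an arbitrary label, and using one as a
correlation operand raises a distinct `ZeroFieldError`.

## Preprocessing

The band-pass is a 2nd-order Butterworth (0.5–40 Hz default, −12 dB/oct
per pass) run forward and backward, which cancels the phase shift and
squares the magnitude response. Because an IIR filter has no finite
impulse response, the reflective pre-padding is sized at three times
the *effective* impulse-response length, measured as the sample at
which the actual impulse response decays below 1e-4 of its peak.
Epochs span −100…+700 ms around each event with sample counts from
round-half-up of duration × sfreq (819 samples at 1024 Hz); windows are
half-open [start, end); the per-channel baseline mean (−100…0 ms) is
subtracted. Artifact rejection replaces by-eye inspection with a
deterministic rule — an epoch is dropped iff any channel's
peak-to-peak amplitude exceeds 150 µV (default) — because a
reproducible pipeline needs an algorithmic criterion. Grand averages
are unweighted means across subjects within a condition.

## Segmentation

Clustering runs on the concatenated post-stimulus (0–700 ms) analysis
window of the four condition grand averages, so one template set is
shared across conditions — required for comparing the same maps between
cells. The pre-stimulus baseline is excluded: it contains noise-only
maps that would pollute the templates.

AAHC starts from one cluster per GFP-normalized timepoint map. Each
step atomizes the cluster with the smallest GEV contribution (the sum
over members of (GFP · correlation-with-centroid)²) and reassigns each
freed map to the cluster whose centroid it best matches by signed
spatial correlation; centroids are GFP-normalized arithmetic means of
member maps (the first-principal-component alternative was rejected to
keep polarity meaningful). A solution is recorded at every cluster
count k ≤ k_max (default 20).

Two refinements stabilize the recorded solutions:

* **Polish.** Each recorded k-solution gets a deterministic
  winner-take-all refinement (reassign all frames to their best
  centroid, update centroids, keep the labeling with the highest GEV,
  at most 20 iterations, stopping rather than emptying a cluster).
  Plain greedy AAHC can fall well short of the attainable GEV on small
  or noisy inputs; the polish removes that gap without randomness.
* **Monotone sweep.** Solutions are finalized in ascending k; if a
  k-solution would explain less variance than the (k−1)-solution, the
  previous solution is split instead (worst-fitting frame of each
  cluster as a candidate new singleton, polished) so that total GEV is
  non-decreasing in k, as a sweep should be.

### Choice of k

Candidate cluster counts are the contiguous prefix of k's whose k-th
cluster still adds ≥ 1% of total explained variance — the parsimony
rule behind "maximum explained variance with a minimum number of
clusters"; clusters below that increment fit noise, and admitting them
both destabilizes the choice of k and (via back-fitting of noise maps)
inflates downstream false positives. Within the candidates, four
criteria are computed per k and the k with the best median rank wins,
ties toward smaller k:

* **cv** — predictive residual variance inflated by
  ((C−1)/(C−1−k))², minimized;
* **kl** — Krzanowski–Lai index on the dispersion curve
  W_k = (1 − GEV_k)·ΣGFP², with the denominator difference floored at
  1% of the mean per-step decline (the raw index explodes on the
  near-zero successive differences past the true k), maximized;
* **w_ratio** — dispersion ratio W_{k−1}/W_k, maximized;
* **silhouette** — simplified (centroid-based) silhouette on
  1 − correlation distances, GFP²-weighted to match the GEV objective,
  maximized. The full pairwise silhouette was rejected: within a
  quasi-stable ERP segment the topographies are nearly identical, and
  the pairwise form then *rewards* splitting such segments.

The membership of this criterion set is a documented package choice
(configurable via `SegmentationParams.criteria`), not a claim about any
other software's internals. It was validated against three behaviors:
recovery of a planted k = 4 (≥ 95% over 50 seeds), parsimony on pure
noise (selected k ≤ 3), and stability of the null-calibration results
below.

### Temporal constraint

Any labeled run shorter than 10 ms is dissolved, shortest first: each
of its samples moves to the better of the two flanking runs' maps by
signed spatial correlation, iterating until no short run remains. If
per-sample reassignment oscillates (it can recreate one-sample runs),
the remaining short runs are dissolved by the optimal contiguous split
between the two flanking maps, which terminates by construction. A
labeling that is entirely short runs collapses to the single best map.
Ties everywhere (equal correlations, equal ranks) resolve to the lowest
map or k index.

## Back-fitting and statistics

By default all selected templates compete over the full post-stimulus
window of each subject-condition ERP (`fit_scope="epoch"`); the
alternative `"grand_average_windows"` restricts each map to the windows
it occupies in that condition's grand-average segmentation. The default
avoids biasing durations toward the grand-average windows. Per map:
GEV (denominator over *all* window samples, so the per-cell sum is ≤ 1
and reaches 1 only for a fully labeled, perfectly fit ERP), mean GFP
over won samples, duration = won samples / sfreq. Maps that win nothing
score zero on all three.

The 2×2 repeated-measures ANOVA uses the classical within-subject
decomposition; each effect is tested against its own effect-by-subject
interaction with df (1, n−1), so no sphericity correction applies to
these 1-df effects. Both partial η² (SS_eff / (SS_eff + SS_err)) and
generalized η² (SS_eff / (SS_eff + all subject-related SS)) are
reported, since the two conventions differ materially and published
tables rarely say which they use. Sums of squares below 1e-12 of the
total are treated as zero; a zero error term yields F = +∞, p = 0,
flagged degenerate.

Power for the within-factors F test uses the noncentral F distribution
with λ = f²·n·m·ε/(1−ρ), df₁ = (m−1)ε, df₂ = (n−1)(m−1)ε (m repeated
measurements, one group); the minimal n is found by an upward integer
scan from 3. At the conventional α = 0.05, f = 0.25, power 0.8,
ρ = 0.5, ε = 1 and m = 4 this gives n = 24 (power 0.817, with 0.797 at
n = 23).

## Synthetic data

The generator emulates a 29-subject, 128-channel, 1024 Hz evoked study
with −100…+700 ms epochs. Signal = Σ windows template × envelope ×
condition multiplier × subject effect, plus sensor noise, then exact
baseline correction; the pre-stimulus interval carries noise only.

* **Timeline.** Four planted maps: 100–150 ms (P1-like, peak 3 µV),
  150–300 ms (N1-like, 4 µV), 300–400 ms (P2-like, 3 µV), 400–500 ms
  (N400-like, 2.5 µV) — typical component amplitudes.
* **Envelope.** Raised-cosine (half-cosine ramps) within each window;
  a band-pass would ring on step edges, and real components wax and
  wane smoothly.
* **Condition effects.** Defaults: N1 map ×1.3 for motor verbs in both
  languages; L2 multipliers on the P1 (1.2, and 1.4 in L2 non-motor,
  giving the P1 interaction), P2 (1.2) and N400 (1.3) maps.
* **Subject effects.** Per map, a mean-one log-normal multiplier per
  cell from a Gaussian copula with equicorrelation ρ = 0.5
  (multiplicative SD 0.2): strengths stay positive and a subject's
  cells are correlated as the power analysis assumes.
* **Noise.** Spatially white Gaussian, 1 µV per channel-sample at the
  evoked level; an optional angular-Gaussian spatial smoothing kernel
  exists but is off by default.
* **Templates.** Fields of 1–3 random upper-hemisphere dipoles in an
  infinite homogeneous medium, normalized, accepted only if pairwise
  |r| ≤ 0.5 — smooth and scalp-plausible, with no forward-model
  realism claimed. Montages are Fibonacci lattices on the upper
  hemisphere with a seeded rotation.

What the generator does **not** emulate: ocular/myogenic artifacts,
channel-correlated or temporally colored noise, latency jitter between
subjects, volume-conduction lead fields, or trial-level variability
(it works at the evoked level; the source study reports no surviving
trial counts). Passing tests therefore validate the algorithmic
pipeline and its statistical calibration under this generative model,
not robustness to every property of real recordings.

## Problem sizes in the test suite

Monte-Carlo tests run the full pipeline at 64 channels / 256 Hz
(smaller unit fixtures use 6–32 channels), keeping the design
parameters — 29 subjects, ρ = 0.5, default multipliers and noise — at
their defaults: 50 seeded runs for effect recovery, 500 null datasets
for type-I calibration, 50 seeds for k-recovery. The brute-force
partition oracle uses 10–12 frames × 6 channels, where exhaustive
enumeration (up to ~86k partitions) is feasible.

## Known limitations

* Templates are estimated from the same subjects' grand averages that
  are later back-fit (as in the emulated workflow); this mild
  circularity is why null calibration is checked explicitly, and it is
  the reason the parsimony rule matters — admitting noise maps into
  the template set visibly inflates the false-positive rate of the
  GEV and duration measures.
* AAHC with a deterministic polish is still a greedy heuristic; on
  structureless data (no planted clusters) it can sit well below the
  exhaustive-best GEV partition, which is immaterial for segmentation
  practice but worth knowing for benchmark comparisons.
* The duration measure is discrete at the sampling interval and
  zero-inflated for maps that rarely win; its ANOVA is the least
  normal-theory-friendly of the three measures.
* `fit_scope="grand_average_windows"` assigns by window membership
  only; it does not re-derive per-subject windows.
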