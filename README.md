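# topomicro

Topographic microstate analysis of event-related potentials (ERPs):
AAHC segmentation of condition grand averages, winner-take-all template
back-fitting, 2×2 repeated-measures statistics, and an a-priori power
calculator — with a synthetic multi-subject ERP generator so the whole
pipeline can be validated end-to-end against known ground truth.

It is written for EEG researchers who compare evoked responses between
crossed within-subject conditions at the level of whole scalp
topographies rather than single electrodes — here a 2×2 design with
factors *language* (L1 native / L2 second language) and *embodiment*
(motor vs non-motor verbs), the setting of word-recognition ERP studies
with components P1, N1, P2 and N400.

## The method

A scalp map **u** (channel vector, average-referenced) is summarized by
its **global field power**, the spatial standard deviation

GFP(u) = √( (1/N) Σᵢ (uᵢ − ū)² ),

and two maps are compared by the strength-independent **spatial
correlation** C(u, v) — the Pearson correlation across channels, which
is invariant to the recording reference and to map strength and keeps
the sign of polarity.

The pipeline:

1. **Segmentation.** The four condition grand averages are
   concatenated; every post-stimulus topography is GFP-normalized and
   clustered by **AAHC** (atomize–agglomerate hierarchical clustering):
   starting from singleton clusters, the cluster contributing least
   **global explained variance**

   GEV = Σₜ ( GFPₜ · C(uₜ, T_label(t)) )² / Σₜ GFPₜ²

   is repeatedly dissolved and its members reassigned by highest signed
   spatial correlation. One solution is recorded per k = 1…20; the
   optimal k is chosen by the convergence (best median rank) of four
   criteria — a cross-validation criterion, the Krzanowski–Lai index, a
   dispersion ratio and a GFP²-weighted silhouette. Segments shorter
   than 10 ms are dissolved into their temporal neighbours
   (sub-10 ms topographies are physiologically implausible).
2. **Back-fitting.** Each template map is fit to every subject's
   condition ERP by winner-take-all assignment; per map this yields
   GEV, mean GFP (µV) and total duration (ms).
3. **Statistics.** One 2×2 repeated-measures ANOVA per map × measure,
   F = MS_effect / MS_{effect×subject} with df (1, n−1), plus partial
   and generalized η². The companion power calculator inverts the
   noncentral-F power function with λ = f²·n·m·ε/(1−ρ).

The synthetic generator plants template topographies in P1/N1/P2/N400
time windows (100–150, 150–300, 300–400, 400–500 ms) with
condition-specific strength multipliers, correlated log-normal subject
effects and sensor noise, and returns the ground truth alongside the
data.

## Worked example

The numbered scripts under `analysis/` walk through the study. With the
reference synthetic dataset (29 subjects, 64 channels, 256 Hz, seed 1):

```sh
$ python analysis/03_segment_grand_averages.py
selected k = 4 (GEV 0.970; after temporal constraint 0.970)

planted map → recovered map (correlation, planted window):
  map 0 → 2  r = +0.984  (100–150 ms)
  map 1 → 3  r = +0.994  (150–300 ms)
  map 2 → 1  r = +0.990  (300–400 ms)
  map 3 → 0  r = +0.980  (400–500 ms)
```

The multi-criterion rule selects four maps, which explain 97% of the
GFP²-weighted variance and match the planted topographies at r ≥ 0.98;
the remaining 3% is sensor noise and the silent epoch stretches.
Back-fitting and the ANOVAs then recover every planted condition
effect:

```sh
$ python analysis/04_backfit_anova.py
planted effects (mean-GFP measure):
 * N1-window map: motor 1.3× (both languages): F(1,28) = 110.24, p = 3.2e-11, η²p = 0.797
 * P1-window map: L2 boost: F(1,28) = 43.18, p = 4e-07, η²p = 0.607
 * P2-window map: L2 1.2×: F(1,28) = 40.64, p = 6.7e-07, η²p = 0.592
 * N400-window map: L2 1.3×: F(1,28) = 49.32, p = 1.2e-07, η²p = 0.638
```

i.e. a motor-vs-non-motor (embodiment) effect on the N1-window map and
stronger L2 expression of the P1/P2/N400-window maps. Under a null
configuration with all multipliers equal,
`analysis/05_null_calibration.py` shows per-effect false-positive rates
of 0.057–0.067 against the nominal 0.05.

```sh
$ python analysis/01_power_analysis.py
minimal total n = 24 (achieved power 0.817)
power at n−1 = 0.797 (below target)
```

A CLI (`topomicro simulate|segment|backfit|anova|power|run`) exposes the
same steps for delimited-text evoked data; see `topomicro --help`.

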