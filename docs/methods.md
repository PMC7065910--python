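# Methods

## Physical model of the tether

A nicked duplex of `N` bp is held between two beads at constant force `F`.
Helicase-driven forks initiated at nicks convert duplex into one tensioned
ssDNA strand plus one relaxed coiled strand. Book-keeping is exact by
construction: `n_ds + n_ss = N` at all times, and each unwound bp adds one
nt to the coils (`n_coil = n_ss` for purely nick-initiated events). Coils
carry zero end-to-end extension, so the tether length is
`L = n_ds·x_ds(F) + n_ss·x_ss(F)`.

Force–extension models:

* ssDNA — extensible freely-jointed chain,
  `x_ss = L_c [coth(bF/kT) − kT/(bF)](1 + F/S)`; defaults
  `L_c = 0.56 nm/nt`, `b = 1.5 nm`, `S = 800 pN`. These are canonical
  literature values standing in for per-experiment force–extension fits;
  every serialized bundle carries an `elasticity_defaults_are_standins`
  flag, and `fit_force_extension` refits all three parameters from measured
  `(F, x)` points when they are available.
* dsDNA — extensible worm-like chain (Odijk),
  `x_ds = L_c [1 − ½√(kT/(F·P)) + F/S]`; defaults `L_c = 0.34 nm/bp`,
  `P = 50 nm`, `S = 1200 pN`. Valid for `½√(kT/(F·P)) < 1` and `F ≤ 60 pN`
  (overstretching excluded); outside the window the model raises rather
  than clamps.

Temperature is fixed at 298 K (`kT = 4.114 pN·nm`). Two estimators convert
signals to base pairs unwound: `ΔL / (x_ss − x_ds)` from the length channel
(ill-conditioned near the ≈6.04 pN crossover, where the code raises and
points to the other estimator) and `w_dark / x_ss` from the fluorescence
channel (valid at every force). Reports flag disagreement beyond 10% as a
QC warning.

On parameter identifiability: refitting the eFJC from force–extension
points with 2% multiplicative noise over 5–45 pN recovers `L_c` and `b` to
a few percent, but the stretch modulus enters only as a ≤6% correction in
that range and is weakly identified (tens of percent scatter). The tests
therefore pin `L_c`, `b` and the predicted extension curve (≤1%), not `S`.

## Synthetic-data generator

The generator is the study-condition definition, not a convenience: each
named fixture in `forktrack.conditions` encodes one measured condition as
the ground truth that the pipeline must recover through the full image
path.

* Fork velocities are Gaussian, truncated at zero. Unidirectional events
  draw a single fork velocity; bidirectional events draw two independent
  forks from `N(μ_bi/2, σ_bi/√2)` so their sum — the total dark-region
  expansion, which is what a single expanding dark region measures —
  follows the calibrated `N(μ_bi, σ_bi)`.
* Calibrations: helicase alone 60 ± 9 bp/s, all unidirectional,
  2.5 events/molecule; helicase+RPA 72 ± 24 (uni) and 117 ± 25 (bi total)
  bp/s with a 53% bidirectional mixture, 3.4 events/molecule; core helicase
  (RPA-interaction domains removed) 50 ± 17 / 85 ± 20 bp/s (ratio 1.7, 42%
  bidirectional) — the core enzyme's absolute rates are a package
  calibration choice (slower than the full-length enzyme; only the ratio is
  externally calibrated). Rewinding after protein removal proceeds at
  50 bp/s per fork.
* Initiation: each event samples a threshold force from the fixture's
  cumulative force→probability table (leftover mass never initiates —
  the "N.U." outcome); the event starts an exponential waiting time (mean
  10 s, a plausible single-rate initiation model) after the schedule first
  reaches the threshold.
* Nicks: explicit template nicks host one event each (presets
  `lambda_48502`, `nicked_6p4kbp` with its nick 2,200 bp from one end);
  otherwise nick count is Poisson with the fixture mean and positions are
  uniform over the interior 90%.
* Dynamics are stepped per scan line; forks clip at template ends
  (`template_end`), stop mutually where regions touch (`collision`), or
  run out the trace (`trace_end`). After an optional buffer-channel switch
  each fork with unwound DNA independently continues with probability
  `p_continue` or rewinds until its region closes; a fully rewound event
  restores the tether length to its pre-event value exactly.
* Imaging: duplex occupancy is deposited with sub-pixel coverage, blurred
  with a Gaussian PSF (σ = 0.15 µm), scaled to 50 counts/pixel over a
  5-count background, and Poisson-sampled per pixel. Beads are rendered as
  1 µm duplex-bright plateaus flanking the tether (real trap beads are
  micron-scale), which keeps the bright reference present even when
  unwinding darkens most of the tether and protects the raster margins.
  The optional RPA channel deposits a Gaussian spot at each fork edge with
  integrated counts proportional to that fork's coil (150 counts per kNT
  over a 2-count background). `noiseless=True` emits expected counts and a
  noise-free length series for oracle tests. Pixel 0.1 µm, line time 0.1 s
  — typical confocal line-scan values.
* Determinism: a single seed feeds named `SeedSequence` substreams (event
  plan, photons, series noise, switch decisions); identical (seed, config)
  give bit-identical outputs.

What the generator does not emulate: photobleaching, intercalator
binding/unbinding kinetics, bead Brownian motion spectra, drift,
sequence-dependent unwinding, and helicase pausing/back-stepping. Passing
benchmarks therefore demonstrate that the analysis correctly inverts the
stated image- and polymer-physics model, not that it is robust to every
instrumental pathology of real data.

## Image analysis

* Segmentation: per scan line, maximal runs below a threshold — absolute
  counts for noiseless oracles (half-amplitude, which the blurred edge
  crosses exactly at the true boundary), or 0.5 × the median of the
  duplex-bright pixels (pixels within a factor two of the line maximum) in
  noisy mode, robust to lamp gain. A 5-pixel bead margin is excluded and
  runs touching the trimmed boundary (background beyond the beads) are
  dropped. Edges are refined to subpixel by linear interpolation of the
  threshold crossing.
* Linking: greedy nearest-neighbour by interval center (≤5 px jump,
  ≤2-line gaps). A match is refused when the interval width jumps by more
  than the same gate: merging regions (colliding forks) must open a new
  candidate track instead of silently extending a parent, which would
  blend the neighbour's fork motion into the parent's edges. Tracks
  shorter than 5 lines or never reaching 3 px width are discarded.
* Duplex reference frame: above the crossover force, every unwound bp left
  of a point pushes it toward larger x by `x_ss − x_ds`, so even the
  static nick-side edge of a growing dark region translates in the lab
  frame — by its own event's width growth as well as its upstream
  neighbours'. Subtracting `(1 − x_ds/x_ss) ×` (dark length left of each
  edge, summed per line directly from the segmentation) yields coordinates
  equal to `bp × x_ds`: nick edges become static, every fork edge moves at
  `v·x_ds`, and all µm→bp conversions downstream use `x_ds`. (The raw dark
  width divided by `x_ss` and the duplex-frame width divided by `x_ds` are
  algebraically identical.)
* Spots: per-line local maxima above background + 3·√background, subpixel
  parabolic refinement, linked like intervals, and assigned to events in
  the lab frame (the frame they are detected in) by riding the event's
  dark interval.

## Event-level inference

* Classification: bidirectional iff both edges move outward beyond the
  motion threshold (0.3 µm ≈ 3 px — separates fork motion from edge
  jitter at the default noise) **or** a pair of spots rides the event's
  two edges while diverging; unidirectional iff exactly one edge
  qualifies; ambiguous otherwise. The spot criterion deliberately requires
  edge-tracking by both spots: a single coil spot at one moving fork, or a
  neighbour's spot inside a crowded region, must not qualify.
* Rates: fits run on the clean growth phase only. Two transients are
  excluded: (i) the detection onset — while the blurred dip is still
  deepening through the threshold the measured width races ahead of the
  true width, so samples below 0.4 µm duplex-frame width (≈4·σ_PSF in raw
  terms) are dropped; (ii) the post-stop tail — `growth_phase_end` cuts
  where the signal first nears its maximum. Within the clean phase the
  linear region is the longest contiguous window with R² ≥ 0.9 covering
  ≥50% of the samples, preferring windows anchored at the start (the
  initial linear region is the class-consistent rate when a fork later
  stops and kinks the slope; R² alone cannot detect such kinks). Slopes
  divide by `x_ds`. Per-side rates use each edge's outward series,
  truncated at its own stop; the total rate is the sum of the side rates
  (each side is single-sloped up to its own stop), falling back to the
  width fit when a side is unmeasurable. Events with no qualifying window
  are flagged unratable and excluded from condition means (logged).
* Events classified but unratable (fragments, too-short tracks) are
  excluded from class tallies as well; benchmark drivers additionally keep
  a single event per dark region (longest track) where linking splits
  produced duplicates.
* ΔL per event is referenced to the extrapolated initiation time (the
  zero-width intercept of the clean-phase width fit), so base pairs
  unwound before the region became detectable are counted by both
  estimators; events overlapping others in time are flagged
  `dL_confounded` since the length channel is shared.
* Required force: the plateau force of the first plateau containing an
  event initiation; "N.U." if none through the schedule maximum.
* Rewinding: after a channel switch, an event is rewound iff its binned
  width increments are significantly negative (sign test on ~12 bin means;
  per-line increments are noise-dominated for slow reannealing) and the
  tether-length trend opposes unwinding at that force; the rewind rate
  reuses the linear-region machinery on the shrinking width.
* Condition summaries: per-class mean ± SD (n−1), bidirectional fraction
  over classified ratable events with a Wilson 95% interval,
  pooled-variance two-sample Student's t test between classes (Welch
  behind a flag), events-per-molecule mean. Events are treated as
  independent (averaging over events, not molecules).

## Benchmark problem sizes and known limitations

Benchmarks observe molecules for 160 s at 30 pN — long enough that slow
forks (≳10 bp/s) clear the detection and clean-phase thresholds, so the
measured event sample is essentially velocity-unbiased (the residual
selection bias measured against ground truth is ≈1%). Rate suites collect
≥40 (helicase alone) or ≥60 (mixed condition) ratable classified events
across molecules; the bidirectional-fraction suite generates exactly 40
events to match the reference sample size, and its pass band is the exact
binomial 95% interval at the mixture probability — at n = 40 the sampling
width, not the classifier, dominates. The t-test power check runs 200
replicate 40-event samples drawn at the inference level (drawing fresh
velocities from the calibrated mixture), since its subject is the
statistical separation of the classes, not the imaging path.

Noise-free simulations recover event counts and classes exactly; rates
match the generating velocities to ≲2% at the image level (subpixel
interpolation and residual onset effects), and exactly (float precision)
at the track level. With default noise, median per-event rate error is
well under 15% and edge localization is sub-pixel RMS.

In crowded molecules, colliding events merge their dark regions; the
merge-gated linker ends both parent tracks there and the merged region
(ambiguous, typically unratable) is excluded, so very fast events in dense
traces can be censored shortly after detection. Measured class means in
the mixed conditions carry a small (~5%) downward residual from such
effects — within the tolerances of all recovery benchmarks, and of the
same nature as the event selection any finite observation imposes on real
recordings. Segmentation with the median-relative threshold is invariant
to multiplicative gain (lamp drift) but not to additive offsets; use
absolute thresholds for offset-dominated data.
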