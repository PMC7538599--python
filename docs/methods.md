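# Methods

`kymostates` converts high-speed AFM line-scanning (HS-AFM-LS)
kymographs of unlabeled membrane transporters into single-protomer
state sequences and transport kinetics.  This note documents the models
and estimators, the defaults and why they are set where they are, and
what the synthetic benchmarks do and do not demonstrate.

## The measurement model

In line-scanning mode the slow scan axis is disabled and one lateral
line is scanned repeatedly (default line period 3.3 ms).  Stacking the
lines gives a kymograph: each transporter protomer appears as a
vertical ridge whose apex height above the membrane baseline reports
the vertical position of its transport domain.  An elevator-type
transporter moves its transport domain across the membrane between an
outward-facing (high, ~2 nm above the membrane) and an inward-facing
(low) state, with an amplitude of ~1.2 nm and an optional intermediate
level midway.  Each protomer switches stochastically and independently;
dwell times within a state are exponential-mixture distributed.

The synthetic generator (`kymostates.simulate`) implements exactly this
forward model:

* **State sequences** are semi-Markov: the dwell in state *s* is drawn
  from that state's exponential mixture, the successor from a
  row-stochastic jump matrix with zero diagonal.  An optional
  `return_probability` makes exits from the intermediate state
  second-order (return to the side the excursion came from with that
  probability); the default of 2/3 reproduces the observed ~2:1 ratio
  of failed (out→int→out, in→int→in) to complete excursions.
* **Traces** sample the sequence once per line at `k * period`
  (`t < duration`; 60 s at 3.3 ms gives 18 182 samples) and add i.i.d.
  Gaussian noise.  SNR is defined throughout as the out–in amplitude
  divided by the noise sigma.
* **Kymographs** compose per-protomer lateral ridge profiles as an
  envelope (pixelwise maximum — an AFM tip contours the tallest
  surface) on a membrane baseline.  The ridge profile is a raised
  cosine of half-width 3 nm with a small flat apex (half-width 0.6 nm,
  the tip-broadened apex; it also guarantees that the pixel nearest the
  apex records the full protomer height, which makes noiseless
  end-to-end recovery exact).  X drift translates ridge positions
  linearly; Y drift multiplies apparent heights by the ridge
  cross-section at the drifted offset, so a protomer drifting off the
  scan line fades rather than shifts.
* **Topography images** place a connected disk-shaped protein-packed
  domain (pixel count matched exactly to the requested area fraction)
  at 7.7 nm on a 4.5 nm membrane, for the height-histogram packing
  analysis.

Two presets encode the study conditions.  Only printed numbers are
used: per-state mean dwells (apo: out 347 ms / in 328 ms /
intermediate 175 ms; transport: 510 / 341 / 297 ms), direct out↔in
pathway fractions (0.78 apo, 0.58 transport), active protomer fractions
(0.55 apo, 0.23 transport), elevator amplitude 1.2 nm with the
intermediate midway, inter-protomer spacing 5.7 nm, sub-Å to
tenths-of-nm noise, and stage drift in the 0.02–1.0 nm/s range.  Dwell
mixtures default to a single exponential at the printed mean because
the per-component decay constants are published only graphically;
multi-component mixtures are user-configurable.

## Tracking (`kymostates.tracking`)

1. `lowpass_time` — zero-phase moving average along time per column
   (default 33 ms ≈ 10 lines, well below the shortest mean dwell of
   175 ms; no cutoff is published, so the window is exposed in config).
2. `detect_peaks` — per line, local maxima above the membrane baseline
   plus `min_height` (default 0.5 nm, below the inward-facing level of
   0.8 nm so protomers remain trackable in the inward state), at least
   `min_separation` apart, refined to sub-pixel positions by 3-point
   parabolic interpolation.  Lines are first smoothed laterally with a
   small binomial kernel: the tip-broadened apex is locally flat and a
   raw 3-point parabola on a noisy plateau is degenerate, making the
   located maximum rattle across the apex.  The membrane baseline is
   the per-line median over protomer-free columns (columns whose
   temporal median is near the minimum), smoothed over 0.33 s; if no
   free columns exist a global baseline is used with a warning.
3. `link_tracks` — greedy nearest-neighbour association within a search
   radius (default 2 nm) of each track's drift-extrapolated position
   (incremental least-squares slope over the last 1 s of observations).
   A track that loses its candidate keeps looking forward for up to
   `max_gap` (default 1 s); unclaimed candidates seed new tracks unless
   they fall within the search radius of an existing track's prediction
   (such candidates are ridge shoulders or localisation outliers, and
   seeding them produces duplicate tracks that steal associations).  A
   protomer lost beyond the gap tolerance and refound is counted as a
   new track.
4. `extract_trace` — per line, the maximum of the *unfiltered*
   kymograph within ±1.5 nm of the tracked position, minus the per-line
   baseline.  Max-in-window read-out is robust to sub-pixel tracking
   error and, with the flat-apex profile, exact on noiseless data; a
   mean-in-window alternative exists but scales amplitudes by the
   profile shape.

`membrane_packing_analysis` thresholds a topography image at
3.5 / 6.1 / 10 nm by default and reports membrane and protein-domain
area fractions normalised to their sum.

## State assignment (`kymostates.states`)

The idealizer follows the step-transition-and-state-identification
(STaSI) recipe: t-test change-point detection, duration-weighted
agglomeration of segment means, and minimum-description-length (MDL)
selection of the state count.

**Noise.** `sigma = median(|x[i+1]-x[i]|) / (0.6745 * sqrt(2))`,
estimated once per trace; robust as long as transitions occupy a small
fraction of sample pairs.

**Change points.** Recursive bisection: within a segment the split
maximising `|mean_l - mean_r| / (sigma sqrt(1/n_l + 1/n_r))` is
accepted above `t_crit` when both sides keep `min_dwell = 2` samples
(the 6.6 ms detection floor: two lines at 3.3 ms).  Two additions
matter in this problem:

* *Bump scan.*  A single split is provably blind to a short excursion
  that returns to its starting level — the segment means on either side
  of any single cut stay equal.  Failed excursions are ~15% of out/in
  exits here, so segments with no acceptable split are additionally
  scanned for the best middle window (up to 150 samples) whose mean
  differs from the pooled flanks by more than `t_crit`.
* *Refinement.*  Greedy bisection mislocates steps; a cyclic
  one-at-a-time exact repositioning pass moves every change point to
  the residual-optimal sample between its neighbours, recovering the
  maximum-likelihood step position.

**Clustering.** Segments are ordered by mean; adjacent clusters merge
by minimal duration-weighted Ward cost
`w_a w_b/(w_a+w_b) (mean_a-mean_b)^2` — the exact increase in residual
sum of squares, so hierarchy levels are nested RSS-greedy partitions.
Weighting by duration is essential: with plain centroid distance, a
two-sample noise outlier segment survives to the top of the hierarchy
while genuine long-lived levels (intermediate vs outward) merge below
it.

**MDL.** For level *k*,
`DL(k) = RSS(k)/(2 sigma^2 ln 2) + (c_state k + c_trans T_k) log2 N`,
with `T_k` the transitions surviving after same-state neighbours merge.
The smallest-DL level wins; spurious change points inside one state are
removed and state heights refit.  Finally, fitted states closer than
`min_separation_sigma * sigma` (default 0.8) are merged: on 18k-sample
traces the likelihood term resolves mean offsets of a few hundredths of
a nanometre (drift-coupled read-out bias, pixel-phase effects), and
levels separated by far less than the per-sample noise are not
physically interpretable height states — consistent with the practice
of trusting three-state assignments only when each level separation is
of order sigma.

**Calibration.**  `t_crit = 4.0`, `c_state = 2.5`, `c_trans = 0.5` were
fixed by calibration on the synthetic three-state benchmark, trading
transition recall (favoured by a lower threshold) against false
intermediate-state visits (which corrupt dwell means and pathway
fractions at higher SNR).  At SNR 4 these defaults recover the apo
dwell means within ~4% and the direct-pathway fraction within half a
percentage point.

**Benchmark metrics.**  `benchmark_accuracy` reports greedy one-to-one
transition recall and precision at a ±3-sample tolerance, the fraction
of traces with the correct state count, and per-sample label accuracy
after optimal label matching.  At SNR 2 the three-state benchmark has a
hard ceiling for ±3-sample recall: out↔int steps are 1 sigma, and a
Monte-Carlo maximum-likelihood oracle localises an isolated 1-sigma
step within ±3 samples only ~72% of the time; with ~38% of transitions
involving the intermediate and ~6% of transitions flanking dwells
shorter than 4 samples, the metric ceiling is ~84%.  The pipeline
reaches ~75% recall with ~97–100% state-count accuracy at SNR 2;
pushing recall higher with a lower threshold degrades precision and, at
SNR 4, injects false intermediate dwells.  These numbers are what the
acceptance script reports — the implementation does not attempt to
reproduce benchmark figures that the metric, as defined here, cannot
attain.

## Dwell statistics (`kymostates.dwells`)

One `DwellRecord` per maximal constant-state run; first/last records
carry censoring flags and never enter means or fits, while their time
still counts toward total observation time (censored + uncensored
durations add up to the trace duration exactly).  Histograms are
log-binned (10 bins/decade) and displayed with the square-root-density
Sigworth transform, which peaks each exponential component at its time
constant.

`fit_exp_mixture` is maximum likelihood via EM with left truncation at
the 6.6 ms detection floor: by memorylessness the shifted durations are
again an exponential mixture with reweighted fractions, so truncation
biases neither the taus nor (after unweighting) the component
fractions.  Component count is guarded by reduced chi-square on the
log-binned histogram (bins with expected counts ≥ 5; an extra component
must reduce reduced chi-square by ≥ 20%).  Because extracted durations
are quantised to the line period, chi-square bin edges are snapped to
the half-sample grid — otherwise sub-quantum bins alternate empty/full
and inflate chi-square for any smooth model.

`transition_tiles` collects consecutive uncensored dwell pairs per
ordered transition (dwell–dwell correlation uses Pearson r on log
durations); `pathway_statistics` classifies every interior intermediate
visit by its flanking states into failed excursions and complete
crossings, with per-pathway intermediate and initial-state dwell means.

## Kinetic endpoint (`kymostates.kinetics`)

From uncensored dwell summaries: weighted rates
`k'(a→b) = n(a→b)/Σ_c n(a→c) / <tau_a>`; occupancies
`rho_a = n_a <tau_a> / Σ_b n_b <tau_b>`; energy differences
`dG(a↔b) = kB T ln(rho_a/rho_b)` in kB T units (antisymmetric by
construction; note the printed-form sign convention puts the positive
sign on the more occupied state).  The cycling rate counts out↔in
crossings through any pathway, halves them (a cycle is two crossings)
and divides by total active observation time including censored dwells;
this operationalisation is a package decision — the published 1.4 and
1.05 s⁻¹ values come from an unstated estimator, and the apo generator
yields ~1.1 s⁻¹ under this definition.  Occupancies describe dynamic
protomers only; `build_scheme(include_inactive_time=...)` folds
quiescent outward-facing observation time into the outward state for
the whole-population landscape.

## What the synthetic benchmarks show — and what they do not

Problem sizes (package choices): the idealizer benchmark uses 500
traces of 60 s at SNR 2; dwell recovery uses 200 traces per condition
at SNR 4; amplitude recovery uses 20 seven-protomer kymographs of 60 s
at SNR 2 with 0.05 nm/s X drift and no Y drift (the real workflow
drift-corrects kymographs and discards traces whose height fades with Y
drift, so rendering Y attenuation into the amplitude statistic would
mechanically depress it relative to the traces that are actually
analysed).

The generator reproduces the statistical structure the estimators
assume: piecewise-constant heights, exponential-mixture dwells,
Gaussian i.i.d. pixel noise, linear drift, fixed lateral profiles.
Real recordings violate all of these mildly — correlated scanner noise,
tip changes, baseline wander, protomer-specific contouring amplitudes
("each protomer had a different protrusion height"), membrane
fluctuations.  Passing recovery tests therefore demonstrates estimator
correctness and calibration under the stated model, not instrument-level
validity on real data.  Known limitations: the idealizer assumes a
global noise level per trace; the mixture fitter models no
heterogeneity between traces; the tracker assumes protomers never cross
laterally (true for packed trimers, with ambiguity flags when
competitors approach); state labels beyond three states are named by
height rank only.
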