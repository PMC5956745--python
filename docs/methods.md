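# Methods

This note documents the models, algorithms and numerical choices behind
epsckit, and what the synthetic-data validation does and does not show.

## The channel-gating event model

A quantal EPSC is modelled as `N` independent channels that all open at
event onset and close after i.i.d. exponential lifetimes with mean
τ_decay; the current is the unitary current *i* times the number of open
channels, multiplied by a deterministic activation envelope
`1 − exp(−t/τ_rise)`.  Consequences used throughout:

- the ensemble mean is `i·N·(1 − e^(−t/τ_rise))·e^(−t/τ_decay)`;
- at any decay time the open count is binomial, so the across-event
  variance as a function of mean current Ī is exactly the parabola
  `σ² = i·Ī − Ī²/N` (once the envelope is ≈ 1), which is the analytic
  oracle for the fluctuation analysis;
- because the rise envelope delays the observable peak to
  `t_pk = τ_rise·ln(1 + τ_decay/τ_rise)`, the expected number of channels
  still open at the peak is `N·e^(−t_pk/τ_decay)` — about 77% of `N`
  with the default τ_rise = 0.15 ms, τ_decay = 1.3 ms.  ps-NSFA measures
  channels open *at the peak*, and the recovery tests assert against this
  analytic value (or use a near-instant rise when the nominal `N` is the
  target).

There is no channel reopening, no multi-state gating, no temperature
dependence and no dendritic filtering.  The rise is deterministic because
the fluctuation analysis only uses the decay phase, where rise-phase
stochasticity would be an un-modelled nuisance.

Default working point (the "wild-type" reference used by the recovery
experiments): 20 channels of −0.69 pA at −60 mV (11.5 pS chord
conductance with E_rev = 0), τ_rise 0.15 ms, τ_decay 1.3 ms, baseline
noise SD 1 pA, event rate 3–4 Hz.

## Detection, screening, alignment

The detection threshold is `k × baseline noise SD` (default k = 3),
applied to the inward excursions of the baseline-subtracted trace.  The
noise SD comes from the median absolute deviation (×1.4826), which is
insensitive to sparse events.  The threshold comparison runs on a
boxcar-smoothed copy of the trace (default 0.5 ms): unsmoothed Gaussian
noise sampled at 20 kHz crosses 3 SD tens of times per second, whereas
after smoothing the effective threshold sits many SD above the smoothed
noise and the false-positive rate on pure noise falls below 0.1 events/s,
while events (τ_decay ≳ 1 ms) pass essentially unattenuated.  Amplitudes
and kinetics are always measured on the raw trace.

One event is produced per contiguous supra-threshold excursion;
excursions closer than 1 ms are merged.  The peak is the raw extremum of
the excursion — exact in the low-noise limit, and carrying a known ~+1 SD
extremum bias when noise is appreciable (see Limitations).  The onset is
the last pre-peak sample within one SD of baseline.

Screening flags (both are required for averaging and fluctuation
analysis):

- `monotonic_rise`: the 3-sample boxcar-smoothed trace has no slope sign
  reversal between onset and peak;
- `clean_decay`: no further event onset within the decay-fit window
  (default 10 ms) after the peak.

Events are aligned at the sample of steepest rise (maximum |dI/dt| of the
smoothed trace between onset and peak) and baseline-subtracted with a
local pre-onset median before averaging.

## Exponential decay fits

The post-peak decay is fitted by nonlinear least squares with a single or
double exponential.  Initialisation: τ_f from the first e-fold time,
τ_s = 4τ_f, amplitude split 0.7/0.3, plus five jittered restarts.  Both
amplitude components are constrained to the sign of the decay, which
keeps the fractional amplitudes in [0, 1] and excludes the degenerate
equal-τ/opposite-amplitude solution that plain bounds admit.  Model
selection is by BIC with the residual floor set at numerical precision so
that noiseless single-exponential data always select the single model;
ties favour the simpler model.  τ_w is the amplitude-weighted mean of the
time constants.  The fit window runs from the peak to the return within
one noise SD of baseline, capped at ~10 crude time constants so baseline
drift cannot dominate.

## Peak-scaled NSFA

Procedure: (1) the ensemble mean waveform is scaled to each event's peak,
the peak being measured as the 3-sample average around the ensemble peak
index; (2) only the decay phase (peak onward) is analysed; (3) decay
samples are assigned to 30 bins of equal amplitude of the mean; (4)
within each bin the variance of (event − scaled mean) is pooled across
events; (5) the (Ī, σ²) pairs are fitted with
`σ² = i·Ī − Ī²/N_p + σ²_B` by linear least squares with the constraints
N_p > 0 and σ²_B ≥ 0 (`scipy.optimize.lsq_linear`).  γ = |i/(V−E_rev)|
is reported in pS with E_rev = 0 by convention.

Numerical choices that matter:

- **Clamped-sample exclusion.**  The samples used to measure each event's
  peak have residuals forced to ≈ 0 by the scaling itself; including them
  presents the fit with a spurious zero-variance bin at the highest
  amplitude and inflates the fitted curvature (N_p biased ~25% low, γ ~9%
  high in recovery runs).  Those samples are excluded from the fit.
- **Plain least squares by default.**  Weighting bins by pooled sample
  count concentrates nearly all weight on the near-baseline tail bins
  (thousands of samples each, variance ≈ background), where event-overlap
  contamination tilts the fitted unitary current ~−10%.  Plain LS spreads
  the information across the amplitude range and recovered γ within
  ~3–7% in the same experiments; count-weighting remains available via
  `weighted=True` / `nsfa_weighted`.
- Bins with fewer than 5 pooled samples are excluded (reported as
  `excluded_bins`); fits with fewer than 10 events are refused outright
  (the parabola is not identifiable); non-positive curvature is reported
  with an `n_p_unbounded` flag rather than a fabricated N_p.
- σ²_B is a free parameter initialised implicitly by the fit; the
  directly measured pre-event baseline variance is reported alongside for
  comparison.

## Rectification

`RI_slope` divides OLS slope conductances fitted strictly within
+20..+40 mV and −40..−20 mV (inclusive edges, config-exposed).  The ramp
generator joins the two linear limbs with a C¹ Hermite blend inside
±20 mV, so the windows see exactly linear segments and the ground truth
is the conductance ratio.  `RI_CM` divides the mean peak conductance of
all events at +60 mV by that of the equally many largest-|amplitude|
events at −60 mV; ties at the selection cutoff are weighted fractionally
so the effective count is exact (largest by amplitude equals largest by
conductance at a fixed potential).

## Sr²⁺ quantal analysis and trains

Quantal counting uses every detected event peaking more than 10 ms after
the stimulus (any distinct peak); amplitude statistics additionally
require a monotonic rise but tolerate overlapping decays; kinetic
analysis requires both screens.  These are deliberately separate
predicates.  A failure sweep has no detected post-stimulus event at all.
The synchronous ("initial") EPSC amplitude is the largest-magnitude peak
inside the exclusion window, averaged over non-failure sweeps (the
all-sweep average, counting failures as zero, is reported alongside).

Train analysis measures per-pulse amplitudes in the inter-stimulus
windows after subtracting the preceding pulse's decay, extrapolated from
a single-exponential fit to the condition-mean trace; amplitudes are
normalised to the mean first-pulse amplitude of a reference condition and
PPR = amplitude₂/amplitude₁ is computed within condition.  The
minimal-stimulation screen (≈30% failure rate, invariant latency and
amplitude, tolerances config-exposed) is a boolean predicate, not an
analysis stage.

The rank-sum test wraps `scipy.stats.mannwhitneyu`: exact permutation
null when `n_x·n_y ≤ 10,000` with no ties, otherwise the mid-rank normal
approximation with continuity correction.  The statistic is the
Mann–Whitney count of (x > y) pairs (+½ per tie).  The test suite checks
the exact p-values against full enumeration for all sample sizes up to
6×6.

## EM morphometry

All geometry is 2-D (thin sections; no stereological correction) and in
nm; annotation files store raw pixel coordinates plus a nm-per-pixel
scale, converted on load.  Conventions: grid and proximity membership use
vesicle *centres*; membrane adjacency uses centre distance ≤ one
*diameter* (i.e. the vesicle edge within one of its own radii of the
active zone).  A grid square is valid only if fully inside the terminal
and intersecting no organelle — squares merely touching an active zone
are not excluded.  Each vesicle counts toward its nearest active zone
only; per-50-nm values are per-AZ counts divided by (AZ length / 50 nm),
averaged over AZs.  Grid density depends weakly on the grid origin for
finite patterns; `grid_density_profile` reports the estimate across four
origin offsets.

The terminal generator draws a homogeneous Poisson pattern (default
131.7 μm⁻² in a 10 μm² square terminal) with truncated-normal diameters
(default mean 33.5 nm, SD 3 nm, hard floor 10 nm), with optional
enrichment bands near active zones.

## What the synthetic validation shows — and what it does not

The generators share their waveform and geometry models with the
analysis assumptions, so recovery tests demonstrate *internal
consistency and correct implementation*: the chain recovers γ within
~15% from 500-event sessions, τ_w to 3 decimals from noiseless averages,
Poisson densities within 10%, diameters within 0.5 nm.  They do not test
robustness to features of real recordings that are not modelled: coloured
(filtered) noise, dendritic filtering and cable attenuation, channel
reopening/desensitisation, series-resistance error, multivesicular
release, non-stationary baselines, or EM segmentation error.  Problem
sizes in the recovery runs (500 events × 20 seeds; 20 terminals) were
chosen as typical desk-scale recordings of the kind summarised above.

## Known limitations

- Peak amplitudes from extremum picking are systematically ~+1 noise SD
  in magnitude at realistic noise; mean-waveform and fluctuation analyses
  are unaffected (they re-measure amplitude internally), but per-event
  amplitude distributions inherit the offset.
- ps-NSFA assumes latency-jitter-free decays after alignment; strong
  residual jitter appears as a variance term ∝ Ī² and inflates N_p.
- Overlapping events are flagged by the generator but not decomposed by
  the detector; at high event rates the fluctuation analysis degrades.
- The exact rank-sum path requires tie-free data; with ties the normal
  approximation is used regardless of sample size.
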