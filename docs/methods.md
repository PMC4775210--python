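# Methods

## The measurement and the model

`eatmap` analyzes point measurements of oxygen partial pressure (Po2) in
brain capillaries made by gated two-photon phosphorescence lifetime
microscopy (2PLM). The excitation beam is parked inside a capillary and
cycled at 4 kHz: a 24 µs on-phase excites an oxygen-sensitive
phosphorescent probe (PtP-C343 class) circulating in plasma, and during
the following 225 µs off-phase the emitted phosphorescence photons are
binned at 1.25 MHz (281 bins of 0.8 µs). Oxygen quenches the probe's
triplet state, so the decay lifetime reports Po2 through a Stern-Volmer
relation

    1/τ = 1/τ0 + kq · Po2 ,

with τ0 the unquenched lifetime and kq the quenching constant. Because
the probe is excluded from erythrocytes, the on-phase fluorescence dips
whenever a red blood cell (RBC) occupies the focus; those dips time-stamp
RBC transits, give RBC flux (complete transits per second) and hematocrit
(fraction of cycles acquired while a cell occupies the focus), and anchor
the *erythrocyte-associated transient* (EAT): capillary Po2 peaks at each
cell and relaxes toward the interstitial value in the plasma gap between
cells. Binning decays by time to the nearest RBC border yields

* **Po2RBC** — the fit over border-adjacent decays (oxygen at the cell),
* **Po2InterRBC** — the fit over mid-gap decays (interstitial proxy),
* **Po2Mean** — one fit over all decays (the EAT-blind average),

and hemoglobin saturation So2 from Po2RBC via the Hill equation
So2 = 100·Po2ⁿ/(Po2ⁿ + P50ⁿ) with n = 2.59, P50 = 40.2 mm Hg (mouse
hemoglobin).

No raw recordings are available, so correctness is established by
parameter recovery on a synthetic photon-stream generator whose ground
truth covers every quantity the pipeline estimates.

## Pipeline stages and numerical choices

**Baseline.** A rolling 80th-percentile of the fluorescence trace over a
centered 2001-cycle (0.5 s) window; an upper quantile rides over the dips
at any realistic occupancy. The quantile is evaluated every `window//40`
cycles and linearly interpolated between evaluation points (exact at
stride 1); the baseline varies on second scales, so the interpolation
error is far below Poisson noise. An all-zero or non-positive baseline
raises immediately.

**Transit detection.** The trace is smoothed by a centered 3-cycle
(0.75 ms) moving average, dips are candidate regions below 0.5 × baseline,
regions separated by ≤ 2 cycles are merged, regions shorter than 2 cycles
dropped. Borders are then refined to the full width at half maximum of
each dip — the crossing of (baseline + dip minimum)/2 — with sub-cycle
linear interpolation, because these borders time-stamp the decay binning.
Both thresholds are relative, so detection is invariant to uniform
scaling of the trace. Dips touching the trace ends are flagged truncated:
they count toward hematocrit occupancy (the cell really is in the focus)
but not toward flow (the transit is incomplete), and their clamped edge
is never used as a border.

**Lifetime fitting.** Decays are pooled (summed) over the selected cycles
and `A·exp(-t/τ) + C` is fitted by Levenberg-Marquardt with weights
`1/max(count, 1)` — the Poisson-variance approximation, which stabilizes
the low-count tail; an unweighted option exists. The first 6 bins
(~5 µs) after the on-phase are discarded (detector settling; configurable,
6-7 is typical). The constant offset C absorbs the uniform background
rather than pre-subtracting it, matching the generative model. Initial
values come from a log-linear regression on background-subtracted counts.
Convergence is the optimizer's relative-step tolerance (1e-8, ≤ 200
iterations); failure sets `converged = False` and is never silent —
downstream conversion raises naming the quantity that failed. τ standard
errors come from the fit covariance and are propagated to Po2 by the
delta method, po2_se = τ_se/(kq·τ²).

**Calibration.** τ0 = 50 µs and kq = 4 × 10⁻⁴ (µs·mm Hg)⁻¹ are defaults
plausible for the probe class, exposed in configuration; they are *not* a
measured instrument curve. Every quantitative claim in this package is a
round trip — the same curve converts Po2 to lifetime in the simulator and
lifetime to Po2 in the analysis — so recovery results are insensitive to
the default. Lifetimes within 1e-6 relative tolerance above τ0 clamp to
0 mm Hg; anything longer is unphysical and raises (or clamps with a flag
inside the extraction, where pooled noise can graze the limit).

**EAT windows.** The border window half-width defaults to 1.5 ms and the
mid-distance guard to twice that. Two border-window conventions are
implemented:

* `"inside"` (default): pool decays whose cycle lies *inside* the cell
  within 1.5 ms of a border. The Po2 profile plateaus at the erythrocyte
  value throughout the cell, so this reads the border value undiluted.
* `"symmetric"`: pool decays with |distance| ≤ 1.5 ms regardless of side.
  Its outside half averages over plasma that has already begun relaxing
  toward the interstitial value, which biases Po2RBC low by several
  mm Hg whenever the EAT relaxes on a millisecond scale — a closed-form
  design study of the fitted-lifetime mixture showed a 6-10 mm Hg deficit
  across plausible relaxation times. The mode is kept because it matches
  a straddling reading of "around the border" and because the
  window-dilution monotonicity property is only observable under it.

The mid-distance pool takes decays at least one guard width from both
borders of an interior inter-RBC gap, accumulated across *all* gaps of
the measurement; the cumulative eligible span must reach 5 ms, otherwise
the measurement is rejected as too fast-flowing for an interstitial
read-out. Pooling across gaps (rather than requiring one single ≥ 5 ms
gap) keeps fast-flow capillaries analyzable; at 30 cells/s and 35%
hematocrit the mean gap is ~22 ms, so the requirement is ordinarily slack.
Po2Mean is a single fit over all decays — deliberately *not* the average
of per-window Po2 values — because it represents the EAT-blind
measurement. The border and mid-distance pools are disjoint by
construction (guard ≥ half-width; asserted at run time) and every decay
enters the Po2Mean pool.

**EAT profile.** Decays grouped in 0.5 ms bins of signed border distance,
one independent fit per bin; bins pooling fewer than 500 decays are
masked rather than reported from an unstable fit.

## The synthetic generator

The generator emulates: (i) single-file RBC traffic as a renewal process
— the plasma gap between consecutive cells is gamma distributed (shape 4,
a regular-but-random spacing) with mean 1/flow − T_rbc, where the dwell
time T_rbc = hematocrit/(100·flow); entry-to-entry intervals then average
exactly 1/flow and long-run occupancy is exactly the hematocrit. Gaps
are attached to *spacings* rather than arrivals so cells can never
overlap, which is what single-file capillary flow looks like; occupancies
above 0.95 are rejected as unresolvable. (ii) The EAT profile: Po2 equals
the erythrocyte value inside the cell and relaxes exponentially with time
constant `eat_relax_time_ms` (default 1.5 ms) toward the interstitial
value in the gap. The true in-vivo profile shape is not known in this
functional form; the exponential is the simplest curve with the right
boundary behaviour and is isolated behind `po2_at` so it can be swapped.
The 1.5 ms default makes the transient > 95% complete 5 ms from the
border, consistent with treating mid-distance decays as an interstitial
plateau. (iii) Photon statistics: per cycle, fluorescence ~
Poisson(rate × (1 − dip_contrast·occupied)) with rate 50 photons/cycle
and dip contrast 0.8; each decay bin ~ Poisson of
amplitude·exp(−t/τ(Po2)) + background with amplitude 2.0 photons in the
first 0.8 µs bin and background 0.02 photons/bin. Po2 is evaluated once
per cycle at the cycle midpoint — EATs evolve three orders of magnitude
slower than a cycle. Everything is deterministic given the seed, which
is stored in the recording metadata and the study manifest.

The default study, used by the end-to-end recovery tests, is 5
capillaries × 4-8 measurements of 40,000 cycles (10 s) each — the scale
of one capillary's worth of session data. Capillary truths are drawn
uniformly: interstitial Po2 15-35 mm Hg, EAT amplitude 25-45 mm Hg, flow
20-50 cells/s, hematocrit 25-45% — ranges bracketing reported awake-mouse
capillary values; measurements within a capillary jitter by SD 2.6 mm Hg
(interstitial) and 5.4 mm Hg (erythrocyte), the magnitude of observed
within-capillary scatter, plus 10% relative flow and 3-point hematocrit
jitter.

**What the generator does not emulate** — and hence what passing recovery
tests cannot show about real data: probe photobleaching and flow-motion
artifacts; analog PMT pulse shapes (counts are ideal Poisson);
instrument-response distortion of the early decay (the discarded bins
model settling, not a measured IRF); oxygen diffusion kinetics (the EAT
shape is imposed, not solved); RBC shape and orientation effects on the
dip profile (dips are rectangular in expectation); and any mismatch
between the assumed and the true calibration curve, which round-trip
validation is structurally blind to.

## Aggregation conventions

Per-capillary summaries use the arithmetic mean and sample SD (n − 1);
SD is flagged undefined for single-measurement capillaries. Study-level
values are reported both pooled over measurements and as the mean of
capillary means (identical for balanced designs); bar-style group
contrasts report mean ± SEM while within-capillary fluctuation uses SD.
Cortical layers are assigned from depth only: < 60 µm layer I, 90-260 µm
layer II/III, > 340 µm layer IV, with the ambiguous bands [60, 90) and
(260, 340] left unclassified. Low-oxygen stratification splits
capillaries at a 15 mm Hg capillary-mean interstitial Po2. Spearman
correlation is the Pearson correlation of mid-ranks (average ranks on
ties), used descriptively; significance testing is out of scope.

## Known limitations

* Po2RBC from the inside-anchored window reads the *border plateau*; if
  real intracellular Po2 differed from the adjacent-plasma border value,
  this instrument could not distinguish them.
* The mid-distance read-out retains a small positive bias (≈ 1 mm Hg at
  default settings) from EAT tails that reach past the guard zone in
  short gaps; it grows with flow and with the relaxation time.
* Hematocrit is an occupancy fraction at one point, not a volume
  fraction; very short gaps (below the 2-cycle merge tolerance) merge
  into single detected transits and deflate flow slightly at occupancies
  approaching the rejection limit.
* Lifetime SEs assume independent Poisson bins; detector afterpulsing or
  correlated noise would make them anti-conservative.
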