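# Methods

## Scope and design

The package models a two-stage phenotypic cardiac screen on adult
*Drosophila*: a fast primary pass scoring every compound by a single
diastolic readout, then a validation pass on larger samples with
beat-resolved diameters and stricter statistics. The statistical stages are
organised as model objects (`PrimaryScreen`, `ValidationStudy`) whose
`fit()` returns a results object carrying the per-compound table, the
fitted parameters and a `summary()`; the imaging and simulation layers are
plain functions over small frozen containers (`MovieStack`, `MModeImage`,
`DiameterTrace`, `SimulationSpec`).

## Synthetic movie model

The generator renders a fluorescent heart tube seen side-on, extruded along
the frame's vertical axis, with per-frame lumen half-width

    r(t) = r_sys + (r_dia − r_sys) · s(t).

**Contraction waveform.** `s` holds a diastolic plateau at 1, falls through
a raised-cosine transition (0.15 of the beat), sits on a systolic plateau
at 0 for `systolic_fraction` of the beat (default 0.3), and rises again.
The plateaus matter numerically: sampled frames then hit the exact
diastolic and systolic diameters regardless of the frame-rate/heart-rate
phase relation, so peak/trough means are unbiased. A pure cosine pulse
would touch the systolic diameter only instantaneously and bias sampled
troughs by up to a few µm at 50 frames/s.

**Wall rendering.** Walls are flat-top intensity bands with
Gaussian-smoothed edges (sd `wall_thickness_sigma`, default 2 µm): the
inner edge tracks r(t) while the outer contour stays fixed at
r_dia + `wall_depth` (default 8 µm). This mirrors wall thickening during
systole (cross-section conservation in a contracting tube) and is what
makes the flattened-frame method well-posed: a position is bright at *all*
times iff it lies in the annulus between the diastolic lumen and the outer
contour, so the minimum (or robust percentile) projection over time shows a
dark gap spanning exactly the diastolic lumen. Had the wall been a thin
symmetric band moving with the lumen, the projection would be
background-dark everywhere and carry no diastolic information. The lumen
boundary is *defined* as the wall's half-intensity point, which is also
what the measurement threshold recovers — by construction, rendered and
measured geometry agree to sub-pixel accuracy on noise-free movies.

**Defaults and what they emulate.** 50 frames/s and 501 frames per movie
match the screen's acquisition; 1 µm/pixel so printed µm-scale diameters
map directly to pixels. Heart rate 2.5 beats/s with 5% per-beat log-normal
period jitter (typical adult-fly values; ~25 beats per 10-s movie), wall
peak 200 vs background 10 intensity units, Gaussian read noise sd 5
(Poisson shot noise with configurable gain is an option), and no transverse
drift by default (a well-anesthetized fly; a slow sinusoidal drift of
configurable amplitude is available). Heart rate, pixel scale and noise are
not quantities the screen's design fixes, so they remain configurable.

**Tabular records.** Per-fly EDD is log-normal with *median* equal to the
design value and CV `between_fly_cv` (default 0.10): diameters stay
positive and group medians — the only statistic the indexes consume —
converge exactly to the design values. ESD is drawn likewise, correlated
with EDD on the log scale (ρ = 0.6, a realistic covariation of diastolic
and systolic geometry) and truncated at EDD. `draw_group_diameters`
exposes the underlying standard-normal quantiles so two groups can be
drawn from common random numbers — a paired design that cancels between-fly
noise when the target quantity is a between-group contrast.

**Baseline conditions.** Control EDD/ESD medians default to 60/25 µm
(adult fly heart-tube scale; absolute diameters are otherwise
unconstrained) and the disease model to +81% EDD / +141% ESD over control.
A screen subset holds 70 untreated disease, 20 control and 12 treated flies
per compound; toxic-flagged compounds yield no treated flies.

**What the generator does not model** — photobleaching, optical PSF, 3D
tube geometry, GFP texture heterogeneity, cuticle scattering, arrhythmia.
Passing tests therefore demonstrate correctness of the measurement and
statistics *given* bright-wall/dark-lumen contrast and quasi-periodic
beating; they do not certify robustness to focus drift or segmentation
failure modes of real movies (those paths are exercised only via the
explicit edge-not-found/rejection tests).

## Diameter extraction

Profiles are smoothed with a 1-pixel Gaussian and thresholded at
`threshold_fraction` (default 0.5) of their dynamic range; the central
sub-threshold run — the one containing the interior intensity minimum — is
taken as the lumen, with sub-pixel linear interpolation of the two
threshold crossings. Rows of an M-mode without a detectable gap are
linearly interpolated from neighbours and flagged; a trace with more than
20% such rows is rejected. The measurement line defaults to the frame row
of maximal temporal variance (auto-locating the beating region).

Beat segmentation estimates the period from the trace autocorrelation's
first prominent peak, then finds peaks/troughs with minimum separation of
half a period and prominence ≥ 25% of the trace range (so noise dips on
the diastolic plateau are not counted as troughs). EDD/ESD are means of
peak/trough values of the lightly smoothed trace (smoothing sd scales as
period/20 so short-period traces are not flattened); with fewer than three
detected beats the estimates fall back to the 95th/5th percentiles. A flat
positive trace gives FS = 0; an all-zero trace is an error. The flattening
projection defaults to the 5th percentile over time, which tolerates
isolated corrupt frames where a strict minimum would not.

Measured accuracy on synthetic data: noise-free recovery of EDD/ESD/DD is
within one pixel (the residual ~0.4 µm comes from linear interpolation of
a curved edge profile); at default noise, relative errors stay below 1% per
fly. Because the dilatation indexes are affine in the diameters, the small
shared edge-localisation offset cancels between groups.

## Screen statistics

The index of cardiac dilatation uses group *medians* within each subset,
`ICD = (med T − med C)/(med D − med C)` — the unique affine form scoring
the untreated disease group 1 and controls 0, invariant under common
rescaling or shift. Treated vs untreated disease flies are compared with a
two-sided Mann–Whitney test (scipy; exact when sizes permit and no ties).
Z-scores are computed once over the full screen's ICDs with population sd;
the spread of a real screen is dominated by true compound effects, so this
is a conservative null scale. Selection: threshold arm (ICD < 0.7 or > 1.3
with P < 0.05) or |z| > 2; the Z-arm is two-sided by default (both
improving and worsening compounds are of interest) with a one-sided
option. P-values are deliberately uncorrected at this stage — the design
accepts primary false positives and defers confirmation to validation.
Compounds without treated flies (toxicity) are reported in a separate
exclusion list and never reach selection.

## Validation statistics

Experiments are aligned before pooling by a single multiplicative
coefficient per experiment, `N_i = grand median / experiment median` of
untreated-disease EDD (the largest group, present in every experiment),
applied to both diastolic and systolic diameters. Pooling happens after
normalization and indexes use medians over pooled flies, not means of
per-experiment medians. IDD/ISD follow the ICD formula on EDD/ESD.
Retention runs Kruskal–Wallis over the three groups and Dunn's post-hoc
comparison — implemented here as the pooled-rank z test with tie
correction, checked against a hand-computed example and a null-uniformity
simulation. The comparison of record is treated vs untreated disease
(all-pairs minimum is an option); Dunn P-values are reported per compound
without cross-compound adjustment, mirroring the per-compound 5×10⁻²
criterion. The retention metric defaults to EDD, the screen's headline
readout. Dose-response summaries report per-dose medians with s.e.m. and a
trend flag from the Spearman correlation of per-fly dose vs ESD.

## Numerical and degenerate-input choices

Zero denominator in an index (disease and control medians coincide),
zero-spread Z-scores, out-of-frame heart geometry (error names the first
offending frame), fully tied rank tests (P = 1 with a warning), experiments
without anchor flies, and subsets missing anchor groups (skipped and
reported; other subsets proceed) are all explicit errors or flagged paths
rather than silent NaNs. All simulation is driven by
`numpy.random.default_rng` seeds; identical inputs and seeds give
bit-identical movies, tables and output files.

## Problem sizes in the test suite

The suite exercises the full 1280-compound/16-subset tabular screen, a
planted 80-compound subset, 10⁴-repetition type-I calibrations of both the
rank-sum and retention tests, and movie-based rounds at the acquisition
shape (501 frames) or shortened stacks (201–251 frames, reduced frame
height) where only geometry per frame matters — chosen as desk-scale
fixtures that keep the statistical assertions well-powered.

## Known limitations

Single fixed measurement line per movie (no multi-segment heart analysis);
no rhythm statistics or arrhythmia index; the flattened-frame method
assumes the lumen is the darkest interior structure; normalization assumes
the untreated-disease anchor is exchangeable across experiments; the
generator's noise is pixel-independent (no structured background), so
real-data segmentation robustness is untested beyond the explicit failure
paths.
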