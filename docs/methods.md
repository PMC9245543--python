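# Methods

## Scope and data model

`vigilnet` analyzes source-space MEG/EEG ROI time series for the effect of
vigilance state on three families of measures: relative spectral power and
peak frequency, functional connectivity (phase lag index, PLI; corrected
amplitude envelope correlation, AECc), and minimum-spanning-tree (MST)
network topology.  The pipeline starts *after* source reconstruction: its
input is a labelled channels × samples matrix (by default 78 cortical AAL
regions, optionally one EOG channel) with an explicit sampling rate.
Acquisition, artifact suppression (tSSS), co-registration and beamforming
are out of scope.

Analyses operate on non-overlapping epochs of 4,096 samples.  At the
default rate of 312.5 Hz (1,250 Hz acquisition downsampled by 4) an epoch
lasts exactly 13.1072 s; the sampling rate is always stored explicitly and
never inferred.  Epoch grids start at sample 0 with trailing remainder
discarded; indices are 0-based, intervals half-open.

## Spectral analysis

Band decomposition uses a brickwall filter: FFT of the raw epoch, zeroing
of every bin outside the passband, inverse FFT.  No taper is applied; the
leakage of the finite epoch is part of the method being reproduced.  The
six canonical bands are delta 0.5–4, theta 4–8, alpha1 8–10, alpha2 10–13,
beta 13–30 and gamma 30–48 Hz under the half-open convention
[f_lo, f_hi) — bands share printed boundaries, so each FFT bin belongs to
exactly one band and boundary bins go to the upper band.  The DC bin is
excluded everywhere.

Band power is the Parseval-normalized sum of squared retained-bin
magnitudes (squared-amplitude spectra; the amplitude-vs-power choice was
open and squared is the standard reading).  Relative power divides by the
*six-band* total (0.5–48 Hz), not by total broadband power: the published
group tables this layout mirrors close to 1 across the six bands, which
forces that denominator.  Peak frequency is the frequency of the largest
power bin within 4–13 Hz inclusive, reported at bin resolution
(fs/n ≈ 0.076 Hz at the default sizes) with ties resolved to the lower
frequency.  Averaging is epochs → ROIs: per-ROI regional means over
epochs, then the global mean over the 78 regional values.

## Functional connectivity

Both measures start from the analytic signal (Hilbert transform) of the
brickwall-filtered epoch.

**PLI** = |mean_t sign(sin(φ_i − φ_j))| with sign(0) = 0 (sine magnitudes
below 1e−12 are treated as numerical zeros).  It indexes the asymmetry of
the phase-difference distribution: a constant non-zero lag gives 1, and
zero-lag or anti-phase coupling — the signature of volume conduction /
field spread — gives 0 by construction.  For band-limited signals the
finite-sample floor of the PLI is not √(2/(πn)) of the raw sample count:
autocorrelation within the band reduces the effective number of
independent phase samples, so the floor depends on the within-band
spectral shape.  This matters for null experiments (see the generator
notes below).

**AECc**: at every sample the component of one analytic signal collinear
with the other is removed (pairwise orthogonalization,
residual = Im(z_j · conj(z_i)/|z_i|)), the residual envelope is Pearson-
correlated with the reference envelope, the roles are swapped, and the two
coefficients are averaged.  The raw value in [−1, 1] is mapped to [0, 1]
as (r + 1)/2, so independent signals score ≈ 0.5; this matches the
published convention in which every AECc group mean sits near 0.50 even in
gamma, which is incompatible with a raw-correlation baseline of 0.
Envelopes are used raw (no log transform or downsampling), and the first
and last 1/16 of envelope samples are trimmed before correlating to
suppress Hilbert edge artifacts (fraction configurable).  A residual that
is pure floating-point residue of an exactly collinear pair (RMS below
1e−9 of the signal envelope) carries no envelope structure and contributes
a correlation of 0 by convention — hence a pure common source scores
exactly 0.5 rescaled.

Global FC is the mean over all off-diagonal matrix entries; regional FC is
the mean connectivity of one ROI to all others.

## Network topology

The "minimum spanning tree" of a connectivity matrix retains the n−1
*strongest* connections spanning all n nodes, i.e. the maximum-weight
spanning tree (Kruskal on descending weights; equivalent to an MST on
reciprocal weights).  Ties are broken by lexicographic edge order so
degenerate matrices still yield a reproducible tree.  Zero weights carry
no connection; a disconnected positive-weight graph is an error.

Metrics on the tree (n nodes, M = n−1 edges):

* leaf number L and leaf fraction Lf = L/M (2 ≤ L ≤ M; path → 2, star → M);
* betweenness centrality bc(u): the fraction of unordered node pairs (u
  not an endpoint) whose unique tree path passes through u, normalized by
  (n−1)(n−2)/2 so a star hub scores exactly 1 and every leaf 0.  Computed
  in O(n) from subtree sizes (deleting u splits the tree into components;
  transiting pairs have endpoints in different components); the test suite
  cross-checks this against explicit shortest-path counting;
* tree hierarchy Th = L / (2·M·bc_max).  The closed form is not printed in
  the source material; this form is pinned by its stated anchors — exactly
  0.5 for a star (L = M, bc_max = 1) and → 0 for a long path — and values
  above 0.5 are possible for intermediate trees.

## State scoring

The scorer operationalizes visual criteria as rules over per-epoch
features.  The alpha envelope is the Hilbert envelope of the 8–13 Hz
filtered posterior-mean signal, smoothed over 0.5 s.  "Dropout" samples
fall below half of the epoch's own median envelope (relative-to-self, so
robust across subjects).  An eyes-closed epoch is drowsy (D-EC) if any of
three criteria fires (logical OR, matching the "and/or" definition):

1. alpha dropout fraction in [0.2, 0.5) — see below for the 0.2 floor;
2. theta relative power ≥ 1.5 SD above the recording's eyes-closed epochs;
3. sub-1 Hz EOG power ≥ 3× the recording's median (slow roving eye
   movements).

Epochs with dropout ≥ 50% reach NREM1 sleep territory and are flagged
`SLEEP-BOUNDARY` and excluded from the drowsy class.  An eyes-closed epoch
without a visible posterior rhythm *and* with blink transients is a
protocol deviation (`EC-EYES-OPENED`).  Everything else is alert (A-EC);
epochs from the eyes-open block are EO.  The classifier is a pure function
of (features, thresholds).

Numerical choices.  A literal "any dropout sample" rule would label every
epoch drowsy: a narrowband envelope dips below half its median a few
percent of the time in fully alert epochs simply because of envelope
statistics, so the dropout criterion requires a minimum fraction
(`dropout_min_fraction`, default 0.2, roughly halfway between the alert
tail (< 0.13 in simulation) and the planted drowsy fraction 0.3).  PDR
visibility uses the *mean of per-ROI* posterior relative alpha power
(floor 0.15) rather than the posterior-mean signal's, because spatial
averaging suppresses incoherent noise but not a coherent rhythm and would
inflate the fraction.  Blink detection band-passes the EOG to 0.5–5 Hz and
counts peaks above 5× the recording's median absolute deviation with a
0.4 s refractory period.  Percentages in scoring reports round half-up
with the scored eyes-closed epochs as denominator.

## Statistics

Per subject and state the first `n_epochs_per_state` (default 5) epochs
enter; subjects short of that in any required state are excluded listwise
per contrast, with a logged reason.  Global metrics are compared between
states with two-sided paired (within-subject) t-tests; regional metrics
(78 per-ROI values for power, peak frequency, FC and BC) are tested per
ROI and corrected with the Benjamini–Hochberg step-up FDR ("FDR" was
unqualified; BH is the field default), significance q < 0.05.  Identical
paired samples return (t=0, p=1); non-zero differences with exactly zero
spread raise a degenerate-input error rather than returning an infinite
statistic.

## Synthetic data generator

Every downstream stage is validated against recordings with known ground
truth.  Each ROI-epoch is unit-variance 1/f noise (γ = 1, the standard
electrophysiological background; the spectrum's band integrals are the
no-oscillation baseline of relative power) plus state-scaled band-limited
oscillations:

* **~10 Hz rhythm** (8.5–11.5 Hz), weight 1.0 on the posterior
  (occipito-parietal) ROI set and 0.4 elsewhere.  Half of its variance is a
  zero-lag component shared across ROIs: a spatially coherent posterior
  dominant rhythm is what a visual scorer keys on, and the posterior-mean
  alpha envelope needs that coherence for the dropout detector to see the
  planted window.  A zero-lag shared component is invisible to the PLI by
  construction (and largely removed by AECc orthogonalization, though its
  residual raises the alpha-band AECc background — which is why coupling
  tests run in beta).
* **theta activity** spanning the full 4–8 Hz band on all ROIs,
  independent per ROI.  The full-band carrier is deliberate: theta
  amplitude then rescales the in-band spectrum without reshaping it, so
  the finite-sample PLI floor is the same in alert and drowsy states.  A
  narrow carrier would shift that floor with state and manufacture a
  connectivity difference that is purely an estimator artifact.
* **drowsy epochs** (D-EC): theta amplitude 0.9 vs 0.3 alert, alpha 0.8
  with one contiguous dropout window covering 30% of the epoch (cosine
  ramps, floor 5%), slow (0.2–0.5 Hz) roving EOG waves.  The dropout
  fraction must stay below 0.5 — at 0.5 the epoch meets the NREM1 boundary
  and is no longer drowsy by definition.
* **eyes-open epochs** (EO): alpha amplitude 0.15, Poisson blink
  transients (0.3/s, Gaussian pulses of σ = 80 ms) on frontal ROIs and the
  EOG.

These defaults reproduce, in direction, every group spectral contrast of
the study conditions (drowsy: theta up, alpha2/beta/peak frequency down;
eyes-open: alpha down, delta up, peak frequency down); effect *magnitudes*
are free parameters and intentionally larger than in real data, so only
directions are asserted.

Planted couplings give the connectivity estimators ground truth: a
*phase-lag* pair shares one narrowband carrier at a constant lag (π/2
default; 0 or π are permitted but flagged as PLI-invisible), and an
*envelope-share* pair carries quadrature carriers whose envelopes mix a
common slow (< 0.7 Hz) modulator with independent ones.  The mixing weight
is solved numerically (Brent) so the sample correlation of the planted
envelopes equals the target exactly.  Quadrature matters: a zero-lag
carrier pair is precisely the configuration pairwise orthogonalization is
designed to delete, and in the presence of background noise its envelope
correlation would vanish.

What the generator does *not* emulate: biophysical source mixing and
field-spread leakage with realistic cross-ROI covariance, sensor noise,
non-stationary 1/f slopes, sleep spindles/K-complexes (NREM2+ is outside
the studied states), and realistic effect sizes.  Passing tests therefore
show that the estimators and the study design behave correctly on signals
with the stated structure — not that the pipeline would reproduce the
study's group values on real recordings, which are not publicly available.

## Problem sizes used in validation

Simulation-backed checks are run at sizes chosen to keep the full suite
comfortably reproducible on one CPU: the type-I calibration uses 500 null
cohorts of 19 subjects × 10 epochs × 4 ROIs at 1,024-sample epochs
(observed rejection rate 0.058 at α = 0.05, inside the 0.03–0.07 binomial
band); the spectra-vs-connectivity dissociation uses one 19-subject cohort
with 20 ROIs, 2,048-sample epochs and theta-band PLI/AECc + MST; scorer
accuracy uses 20 sessions of 9 epochs at the full 78-ROI, 4,096-sample
geometry.  Estimator-level checks (PLI floor, AECc recovery) run at the
study's native epoch length of 4,096 samples.

## Known limitations

* AECc conventions (orthogonalization order, the [0,1] mapping) follow the
  published value ranges rather than a published formula; all AECc
  assertions are baseline- and recovery-based, not value-exact.
* The Th closed form is anchored to the star/path limits only; its
  supremum over trees is convention-dependent.
* The scorer's thresholds were designed against the generator's defaults;
  on real data they are starting points to be tuned per laboratory, and
  the theta-z and SEM criteria rarely fire when drowsy prevalence is near
  50% (the recording-relative statistics saturate).
* Regional tests assume per-ROI pairing within subject; with 19 subjects
  their power is limited and only large planted effects flag regions.
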