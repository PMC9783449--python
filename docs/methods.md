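# Methods

This note records the modeling assumptions, parameter choices, and numerical
conventions behind `iedmap`, and what the synthetic-data experiments do and
do not demonstrate.

## Signal model and forward physics

Sources are current dipoles inside a homogeneous conducting sphere (default
radius 9 cm, centred at the origin).  The magnetic field follows the Sarvas
closed form; two classical identities — a dipole at the sphere centre and
any radially oriented dipole are externally silent — hold to machine
precision and are exploited throughout: lead fields carry only the two
tangential moment components per voxel, with a deterministic tangential
basis (z-axis Gram–Schmidt-orthogonalized against the radial direction,
x-axis fallback within 1e-6 of the poles).  Sensors are point magnetometers
with radial orientation on a golden-angle hemisphere at head radius +
standoff (default 2 cm).  Real axial gradiometers and synthetic-gradiometer
noise suppression are not modeled; their effect is emulated by choosing the
white sensor-noise level directly.  A single sphere is used rather than
per-channel local spheres; all tested properties are preserved and the
geometry stays analytic.

## Synthetic study conditions

The generator defines the default conditions the benchmarks run under:

* **Runs**: 120 s at 1200 Hz, 64-channel array (clinical arrays are larger;
  synthetic arrays may be smaller without changing any contract).
* **Spike-wave events**: fixed template, smoothstep rise (12 ms) into an
  exponential falling phase (95 ms), giving a main deflection of ~70 ms
  full width at half maximum, followed by an opposite-polarity ~300 ms slow
  wave at 30% amplitude.  The steep rising phase matters: it is what places
  spike energy inside the 20–70 Hz analysis band, as in real interictal
  spikes.  A purely Gaussian deflection of the same width is essentially
  invisible to the band and to kurtosis mapping.
* **Polymorphic bursts**: 20–70 Hz Gaussian noise under a Tukey(0.5)
  envelope, independently redrawn per event (the defining property of
  polymorphic activity).
* **Event trains**: Poisson onsets with a refractory gap equal to the event
  duration (ground-truth intervals never overlap).  Default rate 0.2/s,
  amplitude 40 nAm.
* **Background**: 60 random tangential dipoles; 35% carry a waxing-waning
  8–12 Hz rhythm (mild smooth modulation, 1 + 0.5 × 0.3 Hz noise), the rest
  1/f-shaped noise; summed, then scaled so the median per-channel RMS is
  120 fT; plus 25 fT white sensor noise.  With the default 40 nAm source
  this yields a best-sensor spike SNR of ~5 broadband and ~5 within the
  20–70 Hz band — chosen once so that both analysis arms operate in a
  regime where noise matters but neither arm is hopeless, per the stated
  amplitude/SNR design target.  The modulation is deliberately signed and
  mild: heavy-tailed envelopes (e.g. rectified low-pass noise) make the
  rhythm's small 20–70 Hz spectral tail strongly non-Gaussian and corrupt
  kurtosis maps for reasons unrelated to epileptiform activity.
* **Propagation scenario**: two burst sources ~7 cm apart; every A event
  triggers a B event 0.25 s later (onset-to-onset; bursts last 0.40 s, so
  they overlap and cross-fade as real propagating activity does); B also
  fires alone at 0.04/s.  An A event whose triggered B event cannot be
  scheduled (run end, collision) is dropped, so "deterministic propagation"
  holds exactly in the ground truth.

All randomness flows from the scenario seed through named substreams
(events, waveforms, background, sensor noise, geometry); runs are bitwise
reproducible.

## Preprocessing

Zero-phase filtering throughout (both arms compare event timing at ±73 ms,
so group delay is unacceptable): 4th-order Butterworth band-pass applied
forward–backward, IIR notch with Q = 30, polyphase anti-aliased resampling.
The embedding lag count is the odd integer nearest `window · fs` (73 ms at
150 Hz → 11 lags, −5…+5); embedded rows are indexed to the lag-0 sample and
the `(n_lags−1)/2` edge samples are excluded from state assignment, keeping
the HMM and EKM time axes alignable in seconds.  Columns are standardized
before PCA by default (configurable); PCA components are sign-fixed by
their largest loading for determinism.  On the default synthetic runs, 50
components capture ~80% of embedded variance (reported per run for
reference; this fraction is a property of the synthetic background, not a
target).

## VB HMM

Full-covariance Gaussian observation model in PCA space with conjugate
priors: symmetric Dirichlet (α = 1; an optional diagonal boost provides
stickiness), and Normal–Wishart with β₀ = 1e−3, ν₀ = D + 2, and W₀ scaled so
the prior expected precision equals the inverse data covariance.  The
E-step runs scaled forward–backward recursions (numba-compiled) on the
geometric-mean parameterization exp E[log θ]; the free energy is computed
exactly as −(log Z̃ − KL(q‖p)) and is non-increasing at every iteration —
this is asserted in tests, not assumed.  Convergence: relative free-energy
change < 1e−6 or 200 iterations; 5 random-responsibility restarts, lowest
final free energy kept.  Singular scatter updates are retried with a
relative jitter before failing.

Binarization uses a strict threshold of 2/3 (> ½ ⇒ at most one active state
per sample).  Transition statistics come in two variants: the Dirichlet
posterior mean (model) and the visit-sequence matrix (empirical, counting
consecutive maximal active runs across all states).  The propagation
analysis uses the empirical variant because it is directly interpretable on
binarized visits.

## Beamforming and maps

"No regularization" is implemented as an eigenvalue-truncated pseudo-inverse
of the covariance at its recorded numerical rank (tolerance 1e−10 × largest
eigenvalue): filtered, resampled, or synthetic data are routinely
rank-deficient and a plain inverse would be meaningless.  The scalar
orientation is the smallest-eigenvalue eigenvector of Lᵀ C⁻¹ L (closed-form
2×2, deterministic sign), the standard choice maximizing unit-gain output
power.  Variance-ratio maps are computed from condition-wise channel
covariances pushed through the weights (never materializing voxel time
courses), with variance about each condition's own mean; a state needs at
least 0.5 s active and 0.5 s inactive.  Kurtosis maps stream voxel blocks.
The mapping band runs at 150 Hz; the 1–150 Hz virtual electrodes are
reconstructed from the original 1200 Hz data with their own-band
covariance, and state intervals are mapped across time bases in seconds.
Peak finding is greedy by descending value with a 20 mm separation rule and
index-order tie-breaks.  Unnormalized LCMV output power has the classical
depth bias (noise amplification at weak-leadfield voxels); the pipeline's
localizers — the variance *ratio* and excess kurtosis — are invariant to
weight scale, which is why neither needs noise normalization (normalized
variants are out of scope).

## State selection and ranking

On synthetic runs the epileptiform state is the one maximizing sample-level
F1 against ground-truth event intervals — a stand-in for the expert review
used clinically.  Without ground truth, states are ranked by the excess
kurtosis of their peak virtual electrode (restricted to active intervals
when at least 100 samples are available) weighted by the rank of the map
peak value; a run where no state shows super-Gaussian peak activity is
flagged low-confidence.  Final selection is deliberately left to the user.

## Benchmarks and problem sizes

The bundled spike-wave benchmark runs eight seeded 2-minute runs at full
4 mm / 5 mm grid resolution (~42k and ~21k voxels) with the default
configuration; this is the problem size at which the across-run agreement
statistics are quoted, and it completes in about ten minutes on one CPU.
The propagation study uses ten 90 s two-source runs and a three-state model
— the number of distinct spatiospectral patterns that scenario contains
(background plus two sources).  With surplus states the TDE-HMM dedicates a
state to the 73 ms embedding cross-fade at burst edges; that state
interposes between the A and B visits and the direct A→B visit transition
vanishes.  This is a real property of time-delay embedded models worth
knowing about, not a defect of the inference.  A hit is recorded when the
matched A→B element attains the maximum off-diagonal value of the empirical
visit-transition matrix; in a near-deterministic background→A→B→background
cycle several off-diagonal entries are structurally 1, so attainment rather
than a strict argmax is the well-defined reading.

## What passing tests do and do not show

The generator produces spatially correlated, spectrally plausible noise and
ground-truth events, but not real artifacts (ocular, muscle, mains
harmonics beyond a clean 60 Hz line, motion), head-geometry error, or the
waveform diversity of clinical discharges.  Agreement numbers obtained here
therefore validate the machinery — detection, localization, and the metrics
— under controlled conditions; they are not clinical performance estimates.
Expert review steps from clinical practice are replaced by ground-truth
selection (synthetic) and a ranking heuristic (general use).

## Known limitations

Single-sphere conductor; radial point magnetometers; no artifact rejection
or ICA; no statistical thresholding of maps (display thresholding only);
the EKM arm does not attempt bit-compatibility with commercial SAM(g2)
implementations, whose exact peak clustering and marker deduplication are
not public.
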