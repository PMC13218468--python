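# Methods

This note documents the models, the numerical choices, and the limits of
what the synthetic experiments demonstrate.

## Signal conditioning

All breathing channels are reduced to a common analysis representation:
max-abs normalization (divide by max |x|, so the RIP channel's arbitrary
units and the EMA distances' millimetres become comparable shapes),
polyphase rational resampling to 100 Hz with a Kaiser-windowed low-pass
(anti-aliasing; the exact reduced fraction of the rate ratio is used, so
44 100 → 100 Hz is 1/441), and a 1-D Gaussian kernel filter with σ = 5
samples at the analysis rate (50 ms), reflect-padded at the edges.
σ is deliberately interpreted in samples *after* resampling; applied at the
native rate it would be a 0.1 ms filter and do nothing.

EMA coordinates are resampled and filtered in mm first, the distance
measures are computed per the defining equations, and the *distance
channel* is then normalized. Normalizing each raw coordinate by its own
max |x| before subtraction would put the two operands of `chestmid − ref`
on different scales and make the subtraction meaningless; since every
downstream quantity (landmarks, durations, z-scored amplitude,
cross-correlation, z-scored trajectories) is invariant under positive
affine maps of a channel, this ordering changes no reported number.

Synchronization uses the clapperboard impulse recorded on both systems'
audio tracks: the impulse time is the first sample reaching 80 % of the
maximum absolute amplitude within the leading 5 s (the clap occurs at the
start of a recording; restricting the search keeps speech from masking it),
and each system's streams are re-timed so the clap is t = 0.

## Landmark detection

The velocity profile is the central-difference derivative of the filtered
signal (one-sided at the edges). Per utterance:

1. the velocity peak is the argmax of v(t) in a 2 s window centered on the
   acoustic onset (ties → earliest sample). If the peak velocity does not
   exceed a QC floor (default: 5 % of the signal's interquartile range per
   second), the utterance is flagged `no_inhalation` rather than erroring;
2. the inhalation onset is the last sample at/left of the peak with
   v ≤ θ·v_peak; the inhalation offset is the first sample right of the
   peak with v ≤ θ·v_peak;
3. the exhalation offset is the signal minimum from the velocity peak to
   the acoustic offset + 4 s, clipped to the signal end (ties → earliest).

θ (`zero_frac`, default 0.1) implements the "velocity zero crossing" with a
floor proportional to the local peak velocity. The reason is the σ = 5
filter: convolving a one-sided velocity bump with a truncated Gaussian
leaks a strictly positive velocity up to 4σ (200 ms) into the flat baseline,
so a literal v ≤ 0 rule lands far from the onset on clean signals. For a
raised-cosine inhalation of duration d samples, the smoothed velocity at
the true onset equals ≈ π σ φ(0)/d · v_peak ≈ 0.10·v_peak at d = 60,
σ = 5 — hence θ = 0.1 cancels the leak to within about one sample for
inhalations in the realistic 0.4–0.8 s range. θ = 0 restores the strict
rule, which is exact on unfiltered analytic waveforms. All decisions are
sample-resolution and deterministic (first-sample-of-plateau everywhere),
which is what makes exact equivalence with a brute-force oracle testable.

Manual corrections are programmatic only: `apply_corrections` replaces
named landmark times, re-validates onset < offset < exhalation-offset, and
sets a `manually_corrected` flag.

Screening removes speakers whose every utterance lacks a pre-target
inhalation on the reference (RIP) channel, then excludes remaining
utterances flagged on that channel; the exclusion fraction is reported
against the post-removal count.

## Per-cycle parameters

Durations are landmark differences in ms; they telescope (inhalation +
exhalation = full cycle). Δ_Sonja = acoustic onset − inhalation onset,
positive when the acoustics follow the inhalation. The inhalation
amplitude z-scores the samples from inhalation onset to exhalation offset
(sample SD, ddof = 1 — unspecified by convention, fixed here) and reports
z(offset) − z(onset); it is invariant under positive affine rescaling, so
RIP and EMA values share SD units.

Jensen–Shannon distances between parameter distributions use histograms on
a shared grid spanning the union of both samples, with a Freedman–Diaconis
bin count on the pooled sample clipped to [10, 512], and the base-2
Jensen–Shannon *distance* (square root of the divergence), bounded in
[0, 1]. With ~28 samples per cell a histogram JS runs higher than a
KDE-based one would; the values are comparable across channels within this
package but not directly against density-based numbers.

## Bayesian correlation model

Paired per-utterance parameters (x standardized, y standardized) are
modelled as bivariate normal with priors Normal(0, 1.5) on the means,
Exponential(1) on the SDs, and LKJ(η = 1) on the correlation matrix —
in two dimensions exactly the density p(ρ) ∝ (1 − ρ²)^(η−1), i.e. uniform
on (−1, 1) at η = 1. The likelihood is evaluated from sufficient statistics
(n, means, scatter matrix), so the cost per MCMC step is independent of n.
Sampling uses an affine-invariant ensemble sampler (20 walkers); the
configured budget maps `chains × tune` onto warm-up steps and
`chains × draws` onto retained steps across walkers, with the default
4 × (8000 + 8000) = 32 000 retained samples and a documented reduced
budget of 4 × (1000 + 1000) for the test suite and desk-scale runs (for a
5-parameter bivariate-normal posterior the reduced budget already gives a
Monte-Carlo error far below the reporting precision). Reported: posterior
mean ρ̂, the narrowest interval holding 95 % of the draws (HDI, computed by
the sorted-window method), Pr(ρ̂ > 0), and diagnostics. Walkers are treated
as chains for split-R̂, a deliberately conservative convention — an
ensemble's walkers are not independent chains, so short runs inflate R̂;
it is reported, not thresholded. Divergence counts are reported as 0 by
construction (the ensemble sampler has no divergence concept).

## HSGP trajectory contrast

Each kept cycle is windowed (inhalation onset − 1.5 s to exhalation offset
+ 1.5 s, the *RIP* landmarks applied to every channel so all channels share
one window), z-scored, and linearly interpolated at 50 equally spaced
steps. The two-channel model is

y = f_c(step) + a_speaker + ε,  ε ~ N(0, σ²),

with one mean function per channel and no global intercept. Each f_c is a
Hilbert-space GP: the step axis is mapped to u ∈ [−1, 1] and extended by
factor 2 (L = 2); the basis is φ_j(u) = sin(π j (u+L)/(2L))/√L, j = 1…50,
and the squared-exponential spectral density √S(ω_j) scales the
standard-normal weights. Priors: Exponential(2) on the GP amplitude
(trajectories are z-scored, so amplitudes are order 1), Exponential(3) on
the length scale (cycles rise sharply at their start), HalfNormal(1) on the
residual SD — the stated scale prior is applied to the SD, the natural
scale parameter — and HalfNormal(1) on the speaker-intercept SD (the
intercept prior is otherwise unspecified; with a single speaker the
intercept is dropped with a warning).

Conditional on the 5–6 positive hyperparameters the model is
linear-Gaussian, so the 100 basis weights and the speaker intercepts are
marginalized in closed form (Cholesky of the p×p information matrix;
X₀ᵀX₀ and X₀ᵀy are precomputed, and the hyperparameters enter only through
per-column scale factors). Only the hyperparameters are sampled; weights
are then drawn from their exact Gaussian conditional for ~400 retained
hyperparameter draws to form posterior curves. This is an exact
reformulation of the model, not an approximation, and it keeps a full fit
under a second at test budgets. The difference curve f_a − f_b excludes the
speaker intercepts (shared between channels); `nonzero_ranges` lists
maximal step runs where both bounds of the pointwise 95 % band share a
sign.

A calibration point that shaped the validation design: when two channels
are *independent* noisy realizations of one curve, a calibrated pointwise
95 % band excludes zero somewhere in roughly a quarter of datasets — that
is multiple comparisons, not a model defect. The study design pairs RIP and
EMA observations of the *same* breathing cycle, so the null checks generate
matched pairs (shared smooth per-utterance cycle + independent measurement
noise), under which full zero-containment is the stable, expected outcome.

## Synthetic sessions

One latent trajectory b(t) sums per-cycle kernels: a raised-cosine rise
from 0 to the cycle amplitude over the inhalation (zero slope at onset and
peak) and a quarter-cosine decay over the exhalation (zero slope at the
peak, maximal slope at the trough). The quarter-cosine is a deliberate
choice: a decay that lands with zero slope leaves the terminal trough flat
over several filter widths after smoothing, and the exhalation-offset
minimum becomes noise-dominated; the quarter-cosine keeps it a genuine
V-shaped minimum. The kernel shape is isolated in `breathing_kernel` and
swappable.

Channels: RIP = gain·b + N(0, σ_RIP) per sample at 44.1 kHz; each non-
reference sensor coordinate = baseline + gain·b + drift·t + N(0, σ_EMA) at
1250 Hz, with y-gains defaulting to half the x-gains (vertical chest motion
tracks breathing more weakly); the reference sensor carries baseline +
noise only; z is carried but uncoupled. Noise is i.i.d. per sample at the
native rate, so decimation to 100 Hz attenuates it by ≈ √(rate/100) — a
"2 % of amplitude" RIP noise is ~0.1 % at the analysis rate. Both audio
tracks hold exactly one clapperboard impulse, offset by the inter-system
clock offset; one utterance annotation per cycle starts a configurable lag
(default 0.5 s, matching the observed ~500 ms medians) after the
inhalation onset. A fixed seed yields bit-identical sessions.

The cohort emulation (`study.py`) reproduces the recorded design — 18
speakers × 4 sentence types × 2 repetitions, per-type median durations,
two speakers who never inhale before targets plus 14 further un-breathed
utterances as *design* facts the detector must rediscover — with log-normal
speaker (SD 0.08) and utterance (inhale 0.12 / exhale 0.10) duration
jitter and lag jitter SD 0.09 s, calibrated to the published IQR spreads.
Each utterance session ends with a 0.4 s + 4.0 s recovery breath: real
recordings continue past the target, and without the recovery inhalation
the exhalation-offset search window would border a flat signal tail whose
global minimum is noise-placed.

## What the synthetic experiments do and do not show

They demonstrate: exact sample-level correctness of the detector against
an exhaustive oracle; sub-filter-width (≤ 1–2 sample) landmark recovery
through the full conditioning chain at realistic noise; exact screening
accounting; unit cross-correlation ceilings for noise-free coupled
channels; posterior-mean accuracy and near-nominal HDI coverage for the
correlation model; and correct null/offset behaviour of the GP contrast.

They do not demonstrate realism of every distributional feature of speech
breathing. In particular, the two-parameter kernel produces nearly
constant z-scored inhalation amplitudes within a condition (the amplitude
is shape-determined, and the kernel's only shape degree of freedom is the
inhale/exhale ratio), so cohort amplitude-distribution JS distances
saturate near 1 and amplitude correlations are noise-dominated — unlike
real data, where cycle-shape variability is rich. Synthetic
cross-correlations (~0.97–1.0) likewise sit above the 0.85–0.96 seen with
real measurement conditions, because decimation suppresses the generator's
white noise. Timing results transfer; amplitude-distribution and
absolute-similarity levels should not be read as predictions for real
recordings. The generator also omits motion artifacts, posture drift
beyond a linear term, heteroscedastic noise, and abdominal contributions.

## Problem sizes

The test suite and the acceptance script use: the full 144-utterance
cohort at native device rates; 100 noisy sessions (×3 cycles) for recovery;
200 random signals for oracle equivalence; 50 simulations for HDI
coverage; reduced MCMC budgets of 4 × (1000 + 1000) for correlations and
4 × (500 + 500) for the GP. These sizes give Monte-Carlo error well below
every asserted tolerance while keeping a full run around a minute.
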