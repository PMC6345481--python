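# Methods

This note documents the models, numerical choices and validation logic
behind `medocular` — what each stage assumes, which knobs matter, and what
passing the test suite does and does not establish about real recordings.

## The synthetic forward model

Real closed-eye task EEG of this design is not publicly available, so the
package validates itself on a generative model with exact ground truth.
One simulated task segment is

```
data = A · s + ε
```

with channels on a 31-electrode 10/20-derived cap (positions from the
standard template, projected to the unit sphere) plus one periocular EOG
channel, sampled at 250 Hz for 420 s (the study protocol; a 120-s
test-scale profile is used in CI).

**Sources `s`.**

* *Vertical (VEM) and horizontal (HEM) ocular sources*: Poisson event
  trains convolved with a saccade-shaped kernel — 30 ms linear rise,
  exponential return with τ = 200 ms. Event amplitudes are lognormal
  (σ = 0.3) with random sign, scaled per subject (below). Event rates are
  0.20 Hz during focused-attention meditation (FAM) and 0.26 Hz during
  instructed mind-wandering (IMW). The FAM:IMW ratio (~1.27) mirrors the
  reported contrast in detected eye-movement counts; the base rates sit
  above the detected counts because a 3-SD detection criterion only counts
  the largest excursions, and spontaneous closed-eye saccade rates of a
  few tenths of a hertz are physiologically typical. Default amplitudes
  (200 µV for VEM, 100 µV for HEM at the source, i.e. ≈100 µV / 40 µV peak
  deflections at Fp1 / F7 after the topography weights) correspond to
  ordinary vertical/horizontal EOG deflections. The vertical–horizontal
  asymmetry makes VEM components easier to identify than HEM components,
  the asymmetry real data shows.
* *Neural background*: 8 sources of 1/f noise plus a 10 Hz alpha
  sinusoid with random phase, 15 µV RMS each, mixed through random
  unit-norm EEG-only columns.
* *Sensor noise* `ε`: white Gaussian, 2 µV per channel.

**Mixing `A`.** The ocular columns are the template topographies: a sum of
Gaussian bumps (width 0.55 in unit-sphere chord distance) centred on
Fp1/Fp2 for VEM — exactly left–right symmetric by construction — and a
difference of bumps on F7/F8 for HEM — exactly antisymmetric. The EOG row
mixes both ocular sources (gains 1.0 and 0.6): a single periocular
electrode sees combined vertical and horizontal movements.

**Cohort.** Weekly practice minutes and years since training are drawn
from normals truncated at zero with the reported cohort moments
(102.59 ± 67.60 min/week; 2.31 ± 1.60 y). The latent ocular amplitude
multiplier decays hyperbolically with the expertise index
(practice × years):

```
ocular_scale = 1 / (1 + index/1000) · Lognormal(0, 0.2)
```

This encodes the *direction* of the reported expertise–activity
association without asserting its magnitude.

**What the generator does not emulate:** muscular or cardiac artifacts,
channel drift or pops, blinks as a class distinct from vertical saccades,
head-model lead fields (topographies are declared, not computed from
physics), order/fatigue effects across the four segments, and any genuine
neural Task difference — by construction the only Task effect is ocular.
Passing tests therefore demonstrate that the pipeline recovers known
ocular structure through realistic noise, not that it would be robust to
every artifact class of real EEG.

## Preprocessing

Band-pass: windowed-sinc FIR (Hamming), edges 0.9 and 110 Hz, transition
widths 0.9 Hz (low) and 10 Hz (high), applied forward–backward for zero
phase. Notch: FIR band-stop of ±2 Hz around 50 and 100 Hz, same
application. Average reference is computed over EEG channels only — the
EOG channel is periocular and is left out. Each task segment loses its
first and last 3 s.

Artifact-section removal replaces manual inspection with a declared rule:
1-s windows whose peak robust z-score (median/MAD) exceeds a threshold on
any channel are excised and the survivors spliced, with each splice point
annotated. In the pipeline the z-score is computed on a 25–110 Hz copy of
the data with threshold 12: muscular artifacts are broadband
high-frequency events, whereas large slow ocular deflections — the very
signal under study — are the biggest *broadband* amplitudes in clean data
and must not be excised. (On the high-frequency copy, clean synthetic
data peaks near z ≈ 9 from saccade-rise leakage while simulated muscle
bursts exceed z ≈ 70, so the threshold separates them with a wide
margin.) The function's broadband default (z = 5) remains available for
generic outlier excision. Splicing is plain concatenation without
tapering, because the spectral stage never uses an epoch that crosses a
splice.

Subjects with more than 25% artifactual data in any one of their four
task recordings (strict inequality) are excluded from the EOG analysis.

## ICA and ocular-component identification

Data are centered and whitened by PCA to `rank` dimensions — default
channels − 1, because average referencing leaves the data rank-deficient —
then rotated by extended Infomax (sub/super-Gaussian switching; the update
loop is MNE's implementation), seeded and deterministic. One decomposition
is fitted per subject on the four concatenated cleaned segments, matching
the per-participant analysis of the original protocol and making component
identity consistent across segments. The scale indeterminacy is fixed by
normalizing mixing columns to unit norm (variance lives in the source);
sign and order remain free and nothing downstream depends on them.

Components are classified by absolute cosine similarity between their
mixing columns and the VEM/HEM templates, computed on **mean-centered**
vectors: average referencing centers every physical mixing column, so the
all-positive VEM template could never match re-referenced data otherwise.
Assignment is greedy — VEM first, then HEM among the remaining components —
and requires |cos| ≥ 0.80; otherwise the component is declared absent
and the subject is dropped listwise from that signal's analyses. The 0.80
threshold is a calibration choice standing in for classifier-assisted
visual scalp-map inspection; at the default signal-to-noise it accepts
essentially all true VEM maps (scores ≈ 0.99) and rejects neural maps
(scores ≲ 0.5).

The CI profile uses rank 12 (the model has 10 sources) and 100 iterations;
a full-rank decomposition of a 31-channel session costs minutes of CPU and
changes none of the test outcomes.

## Spectral summarization

Welch PSD: mean of per-epoch Hanning-windowed periodograms over
consecutive non-overlapping 1-s epochs (1 Hz resolution), with window
power normalization; an epoch containing a splice strictly in its
interior is dropped. Band powers are means over bins with
`low ≤ f < high` — half-open, so adjacent bands never share a bin —
excluding bins within ±2 Hz of 50 and 100 Hz, floored at 1e-12, then
log₁₀. Power is averaged linearly before the log. Both the half-open
convention and linear-then-log are declared choices where the protocol is
silent.

The eye-movement count band-passes the signal to 1–4 Hz (4th-order
Butterworth, zero phase — robust on short segments), computes the mean and
SD of the *filtered segment itself* (making the criterion invariant under
positive affine rescaling), and counts maximal runs with |x − μ| > 3σ,
merging runs separated by less than 100 ms. Absolute deviation (not
one-sided excursion) is the declared reading of the amplitude criterion.

## Inference

The repeated-measures ANOVA handles any number of fully-crossed within
factors on a balanced table (here Task × Condition × Band), by the
classical sums-of-squares identities; each effect is tested against its
own effect-by-subject interaction. Greenhouse–Geisser ε is estimated per
effect by passing the subject-level cell covariance through the effect's
orthonormal (Helmert) contrast space: ε = tr(CΣC′)² / (d·tr((CΣC′)²)),
clamped to [1/d, 1] — exactly 1 for two-level effects. η_P² =
SS_e/(SS_e+SS_err); η_G² treats all factors as manipulated, i.e. its
denominator adds the subject SS and every error SS to the effect SS. The
implementation is cross-checked against pingouin on the designs pingouin
supports (pingouin handles at most two within factors, hence the in-house
three-factor decomposition).

Post-hoc family for the Task × Band interaction: the five per-band
FAM-vs-IMW paired contrasts (conditions averaged per subject),
Holm-adjusted within that family. Paired t and Pearson tests are scipy's,
wrapped with the d_z = t/√n and df conventions used throughout.

## Sensitivity (MDE) analyses

Paired t: exact power from the noncentral t distribution, df = n − 1,
noncentrality d√n, against the two-tailed critical value; the MDE is the
bisection root of power = 0.80. Correlation: power is the integral of the
exact sampling density of the Pearson coefficient under bivariate
normality (hypergeometric form) beyond the two-tailed critical r. The
exact route is primary because the noncentral-t and Fisher-z
approximations are off in the second decimal at n ≈ 27–29 — the noncentral-t
form gives 0.50 where the exact value is 0.509 at n = 27 — and the exact
values agree with 4·10⁵-replicate Monte Carlo within 0.01. A generic
noncentral-F routine covers repeated-measures sensitivity with a declared
noncentrality convention (λ = f²·(df_den + df_num + 1)); repeated-measures
software differs in how it composes λ from the design, so no equivalence
with any particular program is claimed.

## Problem sizes used in validation

The statistical-recovery suite runs 50 seeded 24-subject cohorts at the
120-s test profile on the generator's ground-truth VEM source (no ICA),
isolating the generator → spectral → inference chain; at these sizes the
delta-band Task effect is significant with the correct direction (IMW >
FAM) in ≈98% of seeds and the expertise correlation is negative in all.
ICA recovery is validated separately: Amari-index recovery of Laplace
mixtures, and identification rates over 20 single-segment sessions at the
full 31-channel montage (VEM ≥ 90%, HEM ≥ 70% — the vertical/horizontal
asymmetry again). End-to-end runs (simulation through report) use small
montages and cohorts; a full-scale run (n = 24, 420 s, full rank) is a
few CPU-hours and is the configuration the defaults describe.

## Known limitations

* Template matching assumes roughly standard electrode placement; caps
  that deviate strongly from the 10/20 template would need their own
  topographies.
* The amplitude-rule artifact exciser is tuned to separate broadband
  muscle bursts from slow ocular events; artifacts that are both slow and
  large (electrode pops, movement drifts) would require an additional
  rule.
* The EDF writer targets plain continuous EDF (16-bit, 1-s records,
  integer sampling rates); EDF+ annotations and discontinuous records are
  out of scope.
* The rm-ANOVA requires a balanced complete table; unbalanced data should
  be analyzed with mixed models, which are deliberately out of scope.
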