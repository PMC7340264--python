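# Methods

## The problem

Deciding where to cut macromolecular diffraction data in resolution is a
model-quality question, not a data-quality question: weak high-resolution
shells can still improve a refined model, and strong-looking statistics can
accompany shells that only add noise. Paired refinement answers it
operationally. Starting from a model refined at resolution A, the model is
re-refined against data extended to a higher-resolution cutoff B, and the
two models are scored against the *same* data truncated at A. Because R
values at different cutoffs are not comparable, only these matched-
resolution differences (dRwork, dRfree) are meaningful. The ladder repeats
the step (B to C, and so on) until the highest processed resolution is
reached. The tool reports statistics and annotations; it deliberately
contains no decision rule and never truncates data itself.

## Monitoring statistics

- **Rwork / Rfree**: R = sum| |Fo| - k|Fc| | / sum|Fo| over working /
  held-out (free) reflections; k is a single overall least-squares scale,
  k = sum|Fo||Fc| / sum|Fc|^2, fitted on the work set only and applied to
  both. Per-shell scaling is intentionally absent: it would absorb exactly
  the per-shell misfit signal the protocol monitors.
- **Rgap = Rfree - Rwork**: the overfitting gap, reported at the starting
  resolution A for every ladder model so the curve is comparable across
  cutoffs.
- **CCwork / CCfree**: Pearson correlations between observed and calculated
  *intensities* (squared scaled amplitudes) on the work/free sets.
- **CC1/2**: Pearson correlation between mean intensities of two halves of
  the unmerged observations, per shell. Halves are drawn with a seeded RNG;
  doubly-observed reflections split deterministically (first observation to
  half A), so multiplicity-2 data have a unique CC1/2. Significance is a
  one-sided Student test on t = CC sqrt((n-2)/(1-CC^2)) at the 0.1% level.
- **CC\*** = sqrt(2 CC1/2 / (1 + CC1/2)): the model-independent estimate of
  the correlation between merged data and true signal. CCwork above CC* in
  a shell flags overfitting — the model agrees with the measured data
  better than the (unknown) truth could.
- **Merging residuals**: Rmerge, the multiplicity-corrected Rmeas
  (factor sqrt(n/(n-1)) per unique) and the precision-indicating Rpim
  (factor sqrt(1/(n-1))). Uniques observed once are excluded from these and
  from CC1/2 (the correction factors are undefined at n = 1) but count
  toward multiplicity and completeness.
- **The 0.42 flag**: a perfect model scored against pure-noise data yields
  R of about 0.42 under standard intensity-truncation conventions; shells
  with Rwork above that level are annotated as worse than noise for the
  current model. The level is a configurable report flag, never a filter.
  This package's own uncorrelated-amplitude regime sits near 0.586 (no
  negative-intensity truncation is applied), which the test suite checks;
  the 0.42 value is used only as the interpretive threshold.

## Complete cross-validation

A single free set makes dRfree a noisy, selection-dependent statistic. The
complete protocol repeats the whole ladder once per CCP4-style free-flag
set q = 0..k-1. To erase the memory of refinement against a previous free
set, the input model is modified before each run — coordinates perturbed by
a stated *mean* displacement (directions isotropic, magnitudes exponential;
the one-parameter exponential is chosen because only the mean is
prescribed), ADPs reset to their mean or a given value, or shifted — and
re-refined at A. Per step the tool reports the mean, sample SD, and
SEM = SD/sqrt(k) of dRwork, dRfree and Rgap across sets, plus counts of
rises and falls. Seeds derive from one master seed by a fixed spawn rule
(SeedSequence over [master, q]), so each fold is independently
reproducible.

## Toy refinement engine

The built-in backend minimizes sum_work (|Fo| - k|Fc|)^2 over a global
scale k (closed form each cycle), a global ADP shift (joint 2-parameter
Gauss-Newton with k), and optionally all atomic coordinates (damped
Gauss-Newton with step-halving; a singular normal matrix falls back to a
scale/ADP-only cycle). Free-flagged reflections of the active set never
enter the target, verified bitwise in the tests. The cycle budget defaults
to 20 with an early stop when the working residual's relative decrease
falls below `rtol` (default 1e-8); the residual trace is non-increasing by
construction. Scattering is point-atom: Fc(h) = sum_j o_j Z_j
exp(-B_j/(4 d^2)) exp(2 pi i h.x_j), i.e. constant form factors with a
Gaussian displacement falloff. This is non-physical (real form factors
decay with resolution) but preserves every statistical property the
protocol monitors while keeping an exact analytic oracle. There are no
geometry restraints, no bulk solvent and no likelihood target. An adapter
contract (`ExternalEngine`) runs a user-supplied command template for real
refinement programs; it is exercised only with mocks in the tests.

## Synthetic data and the planted limit

Simulation is at the intensity level (the protocol consumes nothing else).
From a known truth model in P1, every Friedel-unique index to d_min gets
m observations I = w(d) Itrue + (1-w) J + eps, where w tapers smoothly
(cosine, width `transition`) from 1 at the planted information limit
d_info to 0 beyond it, J is exponential noise scaled by the shell's mean
true intensity and drawn independently per observation (so half-datasets
decorrelate beyond the limit), and eps is Gaussian with
sigma = a|signal| + b<Itrue>_shell. Merged amplitudes are
|Fo| = sqrt(max(<I>, 0)) — no truncated-intensity (French-Wilson style)
conversion is applied, which is documented as out of scope. Free flags are
uniform over k = 20 sets, so each set holds 5% of reflections; a separate
free-fraction knob would be redundant and is not provided.

Defaults (the study conditions of all protocol tests): P1 cell
15 x 16 x 17 A, 60 carbon atoms with B uniform in 10-20 A^2, data to
1.2 A, d_info = 1.5 A with 0.05 A transition, multiplicity 4, noise
a = b = 0.05, 20 flag sets, coordinate perturbation 0.25 A with ADP reset
to the mean for the degraded starting model.

**Why this cell/atom pairing.** The dRfree signal of one added shell
scales with the ratio of model parameters to work reflections; its
detectability against free-set sampling noise works out to roughly
0.5 sqrt(p f m / k), with p parameters, f the shell's fraction of the
data, m free sets averaged and k the flag-set count — notably independent
of the absolute reflection count. Real refinements run at p/N of 0.1-0.2;
a sparse toy model in a large cell (p/N ~ 0.004) provably pushes every
per-shell signal below the sampling noise, so the defaults place the toy
system in the same data-limited regime as practice (p/N about 0.1) at desk
scale. For the same reason the recovery experiment averages dRfree over
all 20 free sets — the complete-cross-validation reading used for real
data — rather than trusting one free set.

What the generator does not emulate: detector images, partiality,
radiation damage, anisotropy, anomalous signal, space-group symmetry
beyond Friedel pairs, and solvent. Passing tests therefore demonstrate the
protocol's statistical machinery, not the behaviour of any particular real
crystal.

## Numerical choices and conventions

- Resolution shells are half-open: a reflection exactly on an interior
  edge belongs to the shell whose high-resolution (lower-d) boundary it
  is, and resolution truncation keeps d >= cutoff inclusively, so cutting
  at an edge keeps whole shells. The outermost low-d edge is inclusive.
- Friedel reduction canonicalizes (h,k,l) by making the first nonzero
  component positive; full space-group merging is out of scope and real
  data must arrive pre-reduced.
- Completeness is defined against the Friedel-unique P1 sphere enumerated
  to the scheme's d_min (bound |h| <= a/d per axis, then exact d filter).
- Undefined statistics (empty shells, n=1 uniques, degenerate variances)
  propagate as NaN, never as 0.
- Merged-data text I/O round-trips byte-exactly; all CSV reports are
  byte-identical across reruns at a fixed seed.
- The ladder refines cumulatively (each step starts from the previous
  step's model), matching the stepwise narrative of the protocol; a
  from-scratch-per-cutoff mode is available for sensitivity checks.
  Paired comparisons rescale each model on the truncated work set.
- Problem sizes in the recovery tests (ladder 1.55 to 1.35 A over the
  default cell, 10 master seeds, 20-cycle budget) are the package's
  desk-scale choice; they bracket the planted limit by two shells on
  either side.

## Known limitations

- Amplitude least squares with a single scale is far from a maximum-
  likelihood refinement; absolute R levels are not comparable to real
  programs, only the paired differences behave analogously.
- CC1/2 via random half-splits can differ in the third decimal from
  sigma-tau style estimators on the same data.
- The exponential displacement distribution for perturbation is a choice;
  only its mean is prescribed by the recipe it implements.
- The external-engine adapter treats the external program's Fc and scaling
  conventions as opaque; it is not validated against any real program
  here.
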