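# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## Simple protein predictor

The predictor treats translation and degradation as the only regulated
steps: dP/dt = s·M(t) − k(t)·P, with M(t) the measured absolute transcript
abundance.  M is interpolated with a natural cubic spline on ln(copies) and
exponentiated on evaluation, so it passes exactly through the data and is
strictly positive; zero measurements are floored at half the smallest
positive observation (with a warning) because the ln-spline requires
positivity.

The translation rate s = density(nt⁻¹) × elongation(nt·s⁻¹) × 3600 uses
6.6 ribosomes per kb of transcript and 3 codons/s, giving 213.84 proteins
mRNA⁻¹ h⁻¹ (0.0594 s⁻¹).  Under steady ribosome traversal the ORF length
cancels; the `density_basis` field records whether the density is read per
kb of ORF or of transcript (numerically identical), and the ORF length is
kept for auditability.  Light effects on translation are ignored;
degradation switches instantaneously between k_light and k_dark at
dawn/dusk, and integration restarts at every switch to avoid stiffness
artefacts at the discontinuity.

Initial conditions use a cyclic steady state: the first 24 h of input are
integrated repeatedly until the start-of-cycle protein level changes by
less than 0.1%, because entrained (not transient) behaviour is the object
of study.

The packaged per-gene kinetics table (`clockunits/data/kinetics_default.csv`)
contains plausible placeholder rates in the 0.2–0.8 h⁻¹ range and is
clearly non-canonical; analyses of real data must supply measured decay
rates.

## Clock circuit models

The engine integrates JSON-defined circuits with a stiff-capable LSODA
integrator, relative tolerance 1e-8, absolute tolerance 1e-6 copies/cell,
dense output on a 0.1 h grid.  Light is a binary step function with no
smoothing.  The standard protocol entrains ten 12L:12D cycles before
recording; entrainment is verified, not assumed — the recorded first and
second cycles are compared and a warning is raised above 0.5% relative
state difference.

The two packaged circuits are synthetic reconstructions of the
activation-based (U2019-style) and repression-based (U2020-style)
architectures: a dark accumulator gates an acute dawn induction of the
LHY/CCA1 transcript; the PRRs and TOC1 act as additive repressors of it;
LHY/CCA1 activates (U2019) or sequential PRR repression shapes (U2020) the
daytime wave; evening genes are repressed by LHY/CCA1 and by the Evening
Complex, which forms from LUX gated by ELF3 and is destabilised by light.
Hill coefficients are fixed at 2 throughout.  Parameters were chosen to
give an entrained oscillation with the canonical phase ordering (LHY/CCA1
peak in the first half of the light period, PRR9→PRR7→PRR5 through the
day, TOC1 and the evening genes around dusk, EC at night); they are not
the published values, so simulated copy numbers are illustrative.

**Scaling scheme.** Rate expressions are written in the absolute frame
with the three scale factors explicit (e.g. `(s_L*g5)**2/((s_L*g5)**2 +
cL**2)`), which makes rescaling a pure change of variables: the `.3`
model is the factors-at-1 case, `.4` sets fitted factor values, and `.5`
multiplies each flagged parameter by its factor and resets the factors to
1.  `.4` and `.5` are algebraically identical, and the `.4` protein
trajectories equal the `.3` trajectories times their factors — both
properties are asserted in tests.  One factor covers all four PRR-family
repressors because they enter the LHY/CCA1 promoter additively; the EC
components share s_LUX because complex stoichiometry couples their scales.

**Scaling fit.** The factors are estimated with a deterministic
Nelder-Mead simplex over log10-factors, started at 0 (factors 1), bounds
10^±5, with the model re-simulated inside the cost function (no
linearisation).  Residuals are computed on the linear copy-number scale by
default — mean-level mismatches in abundant proteins then dominate, which
is the behaviour that exposes under-scaled proteins; an ln-scale option
exists.  Targets are weighted equally unless per-target weights are given.
Because the scaling is an exact symmetry of the circuit, self-consistent
targets are recovered essentially exactly; the fit's cost never exceeds
the cost at factors 1 by construction.

**Kd extraction and ChIP recalibration.** In a `.5` model every
dissociation-constant parameter is in copies/cell; conversion to nM uses
conc = copies/(N_A·V_nuc).  The default nuclear volume, 1.1467e-13 L
(~115 fL), is back-derived as the mean over the twelve published
(copies/cell, nM) pairs shipped in `data/table2_kd.csv`, which agree to
~1% — every printed pair is reproduced within rounding.  Dividing a Kd by
the number of genome-wide ChIP-seq binding regions (defaults back-derived
from the same table: ~1543 for the dawn factor, ~48.3 for the EC) gives
the per-peak recalibrated column.

**Reporter injection.** A transcription-only duplicate of a target mRNA
(its transcription/degradation equation with the regulator's Kd parameter
replaced by a sequence-derived value, no protein production) is integrated
in a second pass, driven by the core solution's dense output.  Since the
reporter has no feedback by construction, the core trajectories are
bitwise unchanged — the invariance contract is exact rather than
tolerance-limited, and is tested at 1e-10.

## NanoLUC quantification

The spike-in standard curve (0, 1e2 … 1e6 monomers/cell, four replicates)
is fitted by ordinary least squares on (ln copies, ln signal) after
subtracting the mean zero-spike signal as background; zero-spike wells
never enter the regression.  Errors are treated as log-normal throughout.
In vivo series are detrended by an exponential fitted to whole-day bin
means (at least two full days, by default over the constant-light span,
where the substrate-decay attribution holds); the trend is divided out
around its midpoint so the overall mean and the peak times are preserved,
and the operation is idempotent to 1e-6.  In vivo→absolute scaling
equates means over the overlapping window with the cognate in vitro
series; the single multiplicative factor is reusable for other reporters
from the same run, and both raw and detrended segments can be used for the
mean matching since the original choice is not documented.

## PBM deconvolution (EMA) and Kd calibration

The EMA instantiation: 8-mer i has additive energy E_i = Σ_pos w[pos,
base]; the prior bound probability is σ(a − E_i); each class has a
Gaussian E-score error model evaluated as probability mass over 20
equal-occupancy bins.  EM alternates (i) posterior class membership, (ii)
weighted Gaussian updates, and (iii) a soft-label logistic regression for
(w, a) (scikit-learn, L2 C=100 to keep separable cases finite),
initialised from a median split of the scores; the bound class is defined
as the higher-score class, and the matrix gauge fixes each position's
minimum at 0 with the logistic intercept compensated, so gauge shifts
change no posterior.  The fit is deterministic for a given seed.

Site calling uses the logistic prior on a window's energy (threshold 0.5
by default — an explicit configuration choice, not an E-score cut), with
each window scored as the minimum energy of its two orientations because
PBM E-scores do not distinguish strands; scanning a sequence and its
reverse complement therefore yields mirrored site sets.  Per-site
K<sub>d</sub>'s map the window energy through a linear energy→E-score
regression (fitted during EMA) and then the anchor calibration line;
predictions are floored at 0.01 nM during scanning because a steep
calibration line can cross zero within the E-score range (flagged at
construction).  Total promoter K<sub>d</sub> sums affinities
(1/K_tot = Σ 1/K_i): independent parallel sites add association constants,
which also matches the observation that promoter totals fall about an
order of magnitude below single consensus-site values; a plain Kd sum
would move them the other way.  Zero sites yield an explicit no-binding
result, not a number.

## Synthetic data: what it emulates, and what it does not

* **RNA** — ln-cosine between ln(trough) and ln(peak) (up to ~1000-fold for
  the dawn genes), 24 h period, additive Gaussian noise in ln-space
  (log-normal errors dominate the assays), amplitude damped by a
  configurable ratio in constant light, 2 h sampling by default (the
  reporter sampling interval; the original spline-fit interval is not
  stated).  Real transcript waveforms are not sinusoidal — sharper rises
  and asymmetric troughs are not emulated, so spline-accuracy results
  transfer only approximately.
* **PBM** — class-conditional Gaussian E-scores (bound mean 0.42, unbound
  0.25 — the latter reproducing the "non-binding" mutated-probe artefact
  that motivates deconvolution), the lowest-energy 2% of sampled 8-mers
  labelled bound, reverse-complement pairs contributing at most one
  orientation.  Within a class the E-score carries no energy information,
  so per-site Kd resolution downstream is limited to the between-class
  trend; consequently haplotype Kd differences are small (site
  gain/loss dominates over per-site shifts).  Real E-scores correlate with
  affinity within the bound class, which would sharpen both.
* **Promoters** — uniform-random background with planted consensus sites
  and per-bp mutated haplotypes.  Background 8-mers hit the bound class at
  the null rate implied by the matrix (~2% per orientation), so scans of
  1 kb sequence legitimately contain dozens of weak sites; tests score
  recovery of the planted positions and check the null rate against
  brute-force enumeration of all 4^8 8-mers.
* **Calibration plates** — ln-linear signal plus a background added to
  every well; zero-spike wells are background-only, so the protocol's
  background subtraction recovers noiseless coefficients exactly.

Passing tests on these generators establish the estimators' correctness
and calibration under the stated error models; they do not establish
accuracy on real microarray, luminometry or qRT-PCR data, whose error
structure is richer.

## Known limitations

* The packaged circuits reproduce the published architecture but not the
  published parameter values, so published simulated protein levels (e.g.
  the combined LHY/CCA1 peak of ~104,000 copies/cell) are documented in
  the test suite as reference values and are not matched by the
  reconstruction.
* No nucleosome occupancy, competitive binding or in vivo accessibility in
  the promoter model; no furimazine kinetics, O₂ dependence or delayed
  fluorescence in the reporter model; deterministic ODEs only (no
  molecule-count stochasticity).
* The EMA likelihood is one consistent instantiation of the
  error-model-averaging idea (bin count, Gaussian error family and
  optimizer are configurable); other instantiations could differ in the
  inferred matrix scale, though not in the gauge-invariant content.
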