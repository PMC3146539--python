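# Methods

This note records the scientific and numerical choices behind the package:
the quantification pipeline, the kinetic model, the synthetic-data
generators, and the fitting machinery, together with their assumptions and
known limitations.

## Bead-event quantification

**Geometric MFI.** The per-sample summary of a fluorescence channel is the
geometric mean intensity over gated bead events, `exp(mean(log v))`. Events
with non-positive intensity are dropped before the log and their count is
recorded on the event table; acquisition floors are instrument artifacts,
and offsetting instead of dropping would change the estimator's meaning.
Geometric MFI is scale-equivariant, so channel ratios are invariant to a
common detector gain.

**Gating.** Gates are closed rectangles in (FSC, SSC). Polygonal gates add
nothing for the well-separated synthetic populations this package processes
and rectangles keep gating deterministic and configuration-friendly. A gate
that retains fewer than `min_events` events (default 5000, the assay's
acquisition target per sample) raises an explicit low-count error rather
than silently producing a noisy MFI.

**Background subtraction.** Net MFI is `max(sample − control, 0)`, with the
control the geometric MFI of a matched uncoupled-bead (autofluorescence)
population; flooring is flagged but not fatal. Subtraction happens at the
MFI level, not per event, matching how stain ratios are formed from
background-subtracted MFIs.

**Replicate statistics.** `%cv = 100·s/mean` and `sem = s/√n` use the n−1
sample standard deviation. For triplicates the sample sd is biased low by
the factor c₄(3) = √π/2 ≈ 0.886, so data generated at 5% multiplicative
noise average ≈4.4 %cv — inside the 4.0–7.2 band typical of the assay.
Tests assert the c₄-corrected expectation rather than the naive 5.

**File formats.** Event tables are CSV (one row per event, header = scatter
and channel names); layouts, gates and parameters are YAML. These plain
formats keep fixtures generatable and diffable.

## Absolute calibration

The standard curve is ordinary least squares of log₁₀(molecules) on
log₁₀(MFI) over the calibration-bead ladder (515, 5956, 26653 and 69045 PE
molecules per bead) — the regression predicts molecules from a measured
MFI, which is the direction the curve is used in. On a perfect power-law
ladder the correlation coefficient is 1 to machine precision. The curve is
an sklearn-style estimator (`StandardCurve.fit/predict`) so it composes
with sklearn tooling.

Saturating staining with one fluorophore per antibody is assumed, so
fluorophores per bead equal stained epitopes per bead; a per-antibody
`labelling_efficiency` scalar (default 1.0) divides predicted counts when
the conjugation ratio differs from one. Stoichiometries divide calibrated
counts: target molecules per complex = target / (reference subunit /
copies-per-complex), with two CD3ε copies per TCR-CD3 as the default
reference geometry. Standard errors propagate to ratios by the first-order
delta method (relative errors added in quadrature); a phospho count
exceeding its total is flagged, not fatal, since staining antibodies can
differ in efficiency.

## The ITAM-pair kinetic model

**State space.** Seven single-ITAM states (U, P1, P2, Z, Z319, Z319+493,
Z493). The seventh state, Z493 (pY493 retained after Y319
dephosphorylation), is the unique combinatorially consistent completion of
the species set: 3 ITAM-only phospho-states plus 4 modification states of a
bound ZAP70. Ordered pairs give 49 configurations; indistinguishability of
the two opposing ITAMs reduces the dynamics to the 28 unordered pairs
{(s,t): s ≤ t} = 7 + C(7,2). The reduction is exact, not an approximation:
a symmetric initial condition stays symmetric under the symmetric
generator, and the package verifies its 28-state generator against an
independently coded 49-state brute-force model (tests/oracle_49.py) to
1e-8 on all marginals and observables.

**Reactions.** Within a pair, each ITAM undergoes its single-site
transitions independently; symmetric states (s,s) carry a combinatorial
factor 2 (either site can react). The two tyrosines within an ITAM are
identical and phosphorylated in random order, hence U→P1 at 2·k_itam_p,
P1→P2 at k_itam_p, and the reverse dephosphorylations at k_itam_dp and
2·k_itam_dp. ZAP70 binds only the doubly phosphorylated ITAM (P2→Z at
k_on, pseudo-first-order with the abundant free pool absorbed) and unbinds
at k_off from *every* bound state — a ZAP70 leaving with its phosphates
rejoins the implicit free pool, which stays unphosphorylated and constant
by assumption. Y319 is phosphorylated by Lck (k_y319) and dephosphorylated
at k_y319_dp on both the Y493-free and Y493-bearing branches. Y493
trans-autophosphorylation (Z319→Z319+493 at k_y493) is the single
pair-context-dependent step: it requires the partner ITAM's ZAP70 to be
opened (pY319 present, i.e. in Z319 or Z319+493); Z493 counts as closed.
The catalyst's own Y493 status is irrelevant.

**Pervanadate.** Inhibition multiplies all dephosphorylation rate
constants (k_itam_dp, k_y319_dp, k_y493_dp) by g(t) = f_min +
(1−f_min)(1−exp(−Δt/τ_rec)), reset to f_min at each dose; k_off is a
dissociation constant, not a dephosphorylation, and is not modulated. The
exponential recovery form is the simplest monotone interpolation between
full inhibition and restored activity and sits behind a single function
(`phosphatase_activity`) should another form be wanted.

**Numerics.** The generator is assembled once per parameter set and split
as A_const + g(t)·A_deph. Trajectories integrate with LSODA (via
`scipy.integrate.odeint`, analytic Jacobian) restarting at every dose so no
step straddles the g discontinuity; reference tolerances are rtol 1e-9 /
atol 1e-11 (probability drift stays < 1e-8 and is reported on the
trajectory), and the fitting path relaxes to rtol 1e-6 / atol 1e-9 for
speed. The resting state is the normalized null vector of the g≡1
generator (SVD null space, residual enforced < 1e-10) with a long-time
integration fallback for degenerate rate sets. Time is in minutes
throughout.

**Reference parameters.** Rate constants are not published as machine-
readable values, so the package ships a reference set chosen once to
reproduce the characteristic response to a pervanadate dose: bound ZAP70
peaking near 10 min (at the defaults: ~12 min), bound pY319 near 20 min
(~18 min), a transient dip of the pY319/ZAP70 ratio below its resting
value around 2 min followed by an elevated ratio at 60 min, a small
resting pool of phosphorylated bound ZAP70, and delayed Y493
phosphorylation. These defaults define the synthetic "assay-like" study
conditions used across the tests; they are a reference point, not fitted
biology.

## Synthetic data

Generators emulate the pipeline's inputs with known ground truth. Bead
populations are lognormal per channel (geometric mean and geometric CV,
log-sd = √ln(1+cv²)) over an additive lognormal autofluorescence
background, with Gaussian scatter; a matched background-only control
population is available for subtraction tests. Two-plex mixtures
concatenate a small- and a large-bead population with hidden true labels;
centers closer than 4 combined scatter sd record a separation warning. The
calibration-ladder generator produces one lognormal population per rung
with geometric mean gain × molecules. Kinetic datasets multiply the model
observables by per-observation lognormal noise of a stated %cv (default
5%, triplicates, time grid {0, 2, 5, 10, 20, 60} min — the named
experimental time points; the exact acquisition grid is not published and
this grid is the package's stand-in). All seeds are explicit fields; fixed
seeds give byte-identical tables.

What the generators do *not* emulate: optical spillover/compensation
(channels are treated as pre-compensated), doublets and debris, day-to-day
staining drift, and any systematic (non-multiplicative) error. Passing
tests therefore demonstrate correctness of the estimators and the model
under the stated noise model, not robustness to real-world instrument
artifacts.

## Model fitting

The objective is the unweighted sum of squared residuals between every
replicate observation (bound-ZAP70 and bound-pY319 channels jointly) and
the scaled model observable; replicates enter individually, never as
means. A variance-weighted option exists but is off by default. Failed
simulations inside a search return a large finite penalty (1e12) so the
walk continues.

Parameters are searched in log₁₀ space (they span orders of magnitude;
default bounds 1e-4 to 1e3 per minute for rates). The annealer uses
geometric cooling (factor 0.95 per level, initial temperature set from the
starting objective), Gaussian log-space proposals whose step shrinks from
0.35 to 0.05 decades as the system cools, and records a trace of accepted
and best objectives. Because the least-squares landscape is multimodal,
the configuration supports independent restarts; each restart's best point
is refined by bounded trust-region least squares (`scipy.optimize.
least_squares`) and the best polished point wins. One numerical detail
matters: the polish's finite-difference step (`diff_step = 1e-4` in log
units) must exceed the ODE integration noise in the residuals, otherwise
the numerical Jacobian is meaningless and the refinement stalls.

**What "recovery" means.** With 12 data points per channel and 12 free
parameters the raw rate constants are not all identifiable; the acceptance
surface is recovery of the noiseless observable *curves*, plus any
identifiable combinations. The recovery criterion used in the tests: per
channel, the RMS deviation between the fitted and the true noiseless curve
over the data time grid must not exceed 2 × noise-cv × the channel's RMS
level (i.e. two noise standard deviations on the channel's scale). Under
the standard study conditions (triplicates, 5% noise, default time grid)
this holds in ≥8 of 10 seeded studies with the test-suite annealing budget
(3 restarts × 12 temperature levels × 60 proposals, plus polish).

**Predictions beyond the fitted channels.** `predict_unfitted` emits the
bound-pY493 time course (never used in fitting) and three directional
checks with pass/fail flags: Y493 time-to-peak ≥ Y319's (trans-
autophosphorylation requires prior Y319 opening), a second pervanadate
dose at 20 min raising bound pY319 at 60 min above the single-dose value
(possible only because phosphatase activity partially recovers), and the
resting bound pY319/ZAP70 ratio exceeding the total-pool ratio when the
constant free pool — unphosphorylated by construction — is included in the
denominator (free-pool size `free_pool`, default 10 ZAP70 equivalents per
ITAM pair; the direction is independent of its value).

## Known limitations

* All ITAMs are treated as identical and independent pairs; there is no
  receptor-level cooperativity, clustering, or distinct proximal/distal
  ITAM behaviour, and Lck activity is constant rather than dynamic.
* The free-ZAP70 pool is constant and unphosphorylated; unbound
  phospho-ZAP70 species are not tracked.
* Calibration assumes saturating one-to-one staining; no binding-curve
  correction is applied.
* Event-table input is CSV only; binary cytometer formats are out of
  scope.
* Point estimates only: the fitter reports no posterior or
  profile-likelihood uncertainty for the rate constants.
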