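# Methods

`stopvar` implements, end to end on synthetic data, a developmental
analysis of response-inhibition *variability*: how consistently people
stop, and how trial-to-trial variability of the stopping-related BOLD
response relates to it.

## The stop-signal task and its simulation

Participants respond to a left/right arrow; on 25% of trials the arrow
turns red after a stop-signal delay (SSD) and the response must be
withheld.  The simulated task uses two blocks of 128 trials (96 go, 32
stop), stop trials preceded by pseudo-randomised go-runs of length
1, 2, 4 or 5 (eight of each per block, shuffled), a 1500-ms response
deadline, inter-trial fixation jittered uniformly on 2000–4000 ms and
extended by (1500 − RT) ms after a response, so every trial occupies the
deadline plus the jitter.  The SSD starts at 250 ms and moves up 50 ms
after every successful stop and down 50 ms after every failed one
(floored at 0), which drives the long-run inhibition rate to 50%.

Behaviour follows the independent horse-race model.  The go process
finishes at an ex-Gaussian latency (parameters `mu_go, sigma_go,
tau_go`); on stop trials a stop process launches at the SSD with
ex-Gaussian latency (`mu_stop, sigma_stop, tau_stop`, the SSRT
distribution) unless a *trigger failure* occurs (probability `p_tf`), in
which case the trial behaves like a go trial.  A response is emitted iff
the go process wins.  Go finish times beyond the deadline are recorded
as omissions; wrong-direction responses occur with a small configurable
probability (default 2%) so that correct-go filtering is exercised.

Cohort defaults (all in ms; between-subject truncated-normal scales in
parentheses) were chosen once from the ranges hierarchical stop-signal
studies report: children (n = 19) go 450(30)/80(10)/150(20), stop
200(50)/50(15)/90(25); adults (n = 26) go 400(30)/60(10)/100(20), stop
200(50)/20(8)/40(12); `p_tf` 0.02(0.01) in both groups.  The groups
share the location of `mu_stop` and differ in `sigma_stop` and
`tau_stop`, the structure of interest.  Note that with matched `mu_stop`
and differing `tau_stop` the mean SSRT (`mu + tau`) necessarily differs
between groups; the "no mean difference" phenomenon in real data
reflects estimation noise at realistic effect sizes, not exact equality.

## Behavioral summaries

The integration SSRT rank-orders correct-go RTs ascending, takes the RT
at 1-based index `ceil(p·N)` where `p` is the failed-inhibition
proportion (no interpolation), and subtracts the mean SSD over all stop
trials.  Go omissions enter the pool at the deadline value (1500 ms) by
default — the treatment that limits omission bias — and wrong-direction
responses are excluded without substitution.  Sessions with fewer than
30% successful stops are excluded by QC.

## Hierarchical Bayesian SSRT-distribution estimation

Trial likelihoods: go RT `t` → `f_go(t)`; go omission → `S_go(1500)`
(right-censored); failed stop at SSD `d` → `f_go(t)·[p_tf + (1−p_tf)·
S_stop(t−d)]`; successful stop → `(1−p_tf)·∫ f_stop(s)·S_go(d+s) ds`.
The deadline term is omitted on stop trials; its mass is ~e⁻¹⁰ at
realistic parameters, and with this convention the outcome
probabilities conserve exactly.  The ex-Gaussian log-density is computed
with erfcx (`log f = −log 2τ − z²/2 + log erfcx(u/√2)`) and the survival
function via `S(t) = Φ(−z) + τ·f(t)`, both stable in log space.  The
successful-stop integral uses two Gauss–Legendre panels — 48 nodes over
`[μ−8σ, μ+8σ]` and 48 over the exponential tail out to `30τ` — accurate
to better than 1e−8 for response-time-realistic parameters (degrading
to ~1e−5 only in extreme broad-stop/sharp-go corners).

Subject parameters follow truncated-normal population distributions
(supports: μ on (0, 2000), σ and τ on (1, 500) ms); `p_tf` is modelled
on the probit scale with a normal population distribution.  Group
locations have uniform priors over the same supports and group scales
uniform (0.01, 500) (probit scale: location (−6, 6), scale (0.01, 3)).
Groups are always fitted separately.

Sampling is adaptive Metropolis-within-Gibbs: per-subject blocks (go
triplet, stop triplet, probit `p_tf`) and group-level location/scale
moves, with proposal scales adapted every 25 burn-in iterations toward
~30% acceptance and frozen afterwards.  Because the conditional of a
group location given subject values is far narrower than its marginal,
three families of *joint* moves are added: translations (shift a
parameter family and its group location together), stretches (rescale
the deviations together with the group scale, with the `γ^(S+1)`
Jacobian), and a mean-preserving `μ/τ` trade move along the flattest
posterior direction.  These restore group-level split-R̂ < 1.1 at the
chain lengths used in testing.  Default MCMC settings are 3 chains,
30,000 samples with 10,000 burn-in, thinning 10 (2,000 retained per
chain) and 1,000 posterior predictions, with trigger-failure estimation
on.  Point estimates are posterior medians with central 95% intervals.
Posterior predictions draw retained group-level states, sample a new
subject from the population distribution, and pool simulated SSRTs.

### What the data can and cannot identify

A consequence worth stating plainly, because the test suite reports it:
with 64 staircased stop trials per subject (the task's own yield), the
decomposition of the SSRT distribution into `mu/sigma/tau` is very
weakly identified.  The likelihood has a long flat ridge trading `mu`
down against `tau` up (and `sigma` along with it); the pooled maximum
likelihood converges to the generating values only at roughly two
orders of magnitude more stop trials (verified directly at 12,800 stop
trials).  At 20 subjects × 256 trials the group-level posteriors for
`sigma_stop` and `tau_stop` are wide (95% intervals spanning a factor of
~10) and their *medians* can sit 20–40% from the generating values even
with well-mixed chains, while `mu_stop` recovers to within ~5%.  The
recovery test asserts the 10% figure for all three parameters and is
expected to fail for `sigma`/`tau` — an honest statement of the
information limit, not an implementation defect.  A related
finite-sample effect appears in the twenty-cohort replication suite:
the `mu_stop` point estimates acquire a group-dependent bias (the ridge
geometry differs between wide and narrow SSRT distributions), so the
"no `mu` difference" ANOVA rejects far more often than its nominal
rate.  The structural findings (σ/τ group differences, BOLD-variability
differences, negative brain–behaviour correlation) replicate robustly.

## Synthetic BOLD and the difference of residuals

The synthetic "brain" is a 10×10×10 voxel grid with six disjoint 3×3×3
regions named for the inhibition network (right IFG pars triangularis,
caudate, putamen, thalamus, STN) and a right calcarine control; no
anatomy is implied.  Each voxel's signal is `baseline + Σ amplitude ·
HRF(t−onset) + AR(1) noise + drift` at TR 2.2 s; per-trial amplitudes
are Normal(condition mean, per-region/condition SD) and shared by the
region's voxels, so a region's ground-truth trial variability is
exactly its configured SD.  Defaults: baseline 100, amplitude mean 1,
noise SD 0.5 with AR(1) coefficient 0.3, linear-plus-sine drift of
amplitude 2, motion as a 6-parameter random walk (0.05 mm / 0.0005 rad
steps, giving mean FD ≈ 0.2 mm).  One run per task block; run duration
is derived from the last onset plus 24 s.  The generator couples each
subject's stop-locked amplitude SD in the network regions to their true
stopping consistency — SD × (group-typical √(σ²+τ²) / subject's
√(σ²+τ²)) — with group bases 0.8 (adults) and 0.3 (children); the
control region carries go-locked variability only.  The simulation does
not emulate spatial smoothness, physiological noise, susceptibility
artefacts or anatomy, so passing tests show the estimator's statistical
behaviour, not robustness to real acquisition artefacts.

The HRF is the canonical double-gamma (peak 6 s, undershoot 16 s,
dispersions 1 s, ratio 6, 32-s kernel, microtime TR/16,
peak-normalised), with a backward-difference temporal derivative
(δ = 1 s) and a dispersion-parameter derivative (δ = 0.01).  The
standard GLM has, per condition, the canonical regressor plus both
derivatives, one canonical regressor for error trials (failed stops,
wrong-direction and omitted responses pooled), discrete-cosine drift
columns (128-s cutoff), the six motion parameters, and an intercept.
The trialwise GLM replaces the condition of interest's canonical
regressor with one canonical regressor per trial, keeping derivatives
at condition level so the designs nest.  Estimation is plain OLS
without prewhitening; SSR maps are never divided by degrees of freedom,
because the trialwise df depends on each subject's success/failure
split.  `DoR = SSR_standard − SSR_trialwise ≥ 0` is computed for the
successful-stop condition; the orientation is chosen so the quantity is
the nonnegative variance uniquely captured by per-trial amplitudes
(the reverse subtraction would be everywhere ≤ 0).

Confound denoising (white-matter/CSF means, realignment parameters,
one indicator per flagged volume) is implemented as OLS residualisation
and unit-tested; the synthetic pipeline has no tissue compartments, so
it folds motion into the GLM nuisance block instead.  Mean framewise
displacement sums absolute backward differences of the six parameters,
rotations converted on a 50-mm sphere.

## Group statistics

ROI values are mask means of the DoR map; the network value pools
voxels across the five inhibition masks.  One-way ANOVAs report F, p
and η² = SS_between/SS_total.  The whole-grid group comparison is a
voxel-wise two-sample t map thresholded by two-sided Bonferroni
correction over in-mask voxels (a deliberate, more conservative
substitute for random-field FWE, which is out of scope) with a
≥10-voxel extent filter on 6-connectivity clusters.  Correlations are
Pearson; partial correlations residualise both variables on the
covariates and use n−2−k degrees of freedom.  Group differences between
correlations use the independent-samples Fisher r-to-z statistic
`z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))`.  The power
calculation finds the smallest equal per-group n for a two-sided
two-sample t test under the noncentral-t distribution; at d = 1.2,
α = .05, power = .80 it returns 12 per group (24 total).  In real
(MNI) space the ROI set is defined by the published centre coordinates
with 6-mm spheres (the radius is this package's choice).

## Problem sizes used in testing

Tests run reduced problem sizes chosen as this package's own testing
defaults: the recovery study uses 3 chains × 6,000 samples (2,000
burn-in, thinning 4); the twenty-cohort replication suite uses 1 chain
× 700 samples (300 burn-in, thinning 2) per group fit, which is enough
for stable point estimates though not for convergence diagnostics; the
staircase property is tested at 5,120 stop trials.  Reduced-length
multi-chain fits satisfy split-R̂ < 1.1 on the recovery problem.

## Known limitations

- The μ/σ/τ decomposition of the SSRT distribution is weakly identified
  at realistic trial counts (see above); group-level σ and τ point
  estimates carry large uncertainty that propagates to second-stage
  ANOVAs on shrunken subject estimates (anticonservative for matched
  parameters).
- BEESTS-equivalence is not claimed: priors and sampler are this
  package's documented choices; recovery of simulated truth is the
  contract.
- No prewhitening in the GLM; serial correlation is handled only through
  the AR(1)-aware simulation and drift/nuisance regression.
- The voxel-level Bonferroni correction is stricter than random-field
  FWE; cluster tables on real data would be conservative.
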