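# Methods

## The generative model

`cmcsd` models the complex cross-spectral density (CSD) observed at a
pair of cortical recording sites as the output of two coupled canonical
microcircuits.  Each circuit (cortical source) contains four neural-mass
populations — spiny stellate cells (SS, granular layer), superficial
pyramidal cells (SPC), inhibitory interneurons (II) and deep pyramidal
cells (DPC) — interacting through ten signed intrinsic connections.
Across sources, the SPC of the hierarchically lower source projects
forward onto the SS of the higher source (excitatory), and the DPC of
the higher source projects backward onto the SPC and II of the lower
source (inhibitory).  Every reciprocally connected pair carries one
excitatory and one inhibitory direction and all self-connections are
inhibitory; this anti-symmetry balances excitation against inhibition
and guarantees a fixed-point attractor.

Each population obeys synaptic convolution dynamics with time constant
`T` (rate constant `kappa = 1/T`):

    v'' = kappa * u - 2 * kappa * v' - kappa^2 * v

where `u` is the signed, weighted sum of presynaptic firing plus (for SS
only) the endogenous drive.  The impulse response is the alpha kernel
`kappa * t * exp(-kappa * t)`, peaking at `t = T`.  Depolarization maps
to firing through a centered logistic sigmoid `S(v) = 1/(1+exp(-s v)) -
1/2` with linearized gain `s/4`; the centering makes the origin the
fixed point of the noise-free system.

### Parameterization and priors

All parameters are log-scaling deviations around prior means,
`value = prior_mean * exp(theta)`, with Gaussian priors `theta ~ N(0, v)`.
This guarantees positivity; the fixed sign structure carries all
excitation/inhibition information.  Prior means of the ten intrinsic
gains are (4, 4, 4, 4, 4, 2, 4, 4, 2, 1) for SS→SS, SPC→SS, II→SS,
II→II, SS→II, DPC→II, SPC→SPC, SS→SPC, II→DPC and DPC→DPC respectively;
time constants are (2, 2, 16, 28) ms for SS, SPC, II, DPC; the
populations contribute to the recorded signal with weights
(0.2, 0.8, 0, 0.2) — superficial pyramidal cells dominate the LFP.
These priors deliberately endow the superficial population with
relatively more gamma-band power and the deep population with more
alpha/beta power, the laminar dissociation seen across layered cortical
recordings; the acceptance suite verifies this property rather than
assuming it.

Prior log-variances (all configurable): 1/8 for coupling gains,
electrode gains and noise amplitudes, 1/16 for time constants, sigmoid
slope and observation weights, 1/32 for the conduction delay and
spectral exponents.  The inhibitory-interneuron observation weight has
prior mean 0 and is clamped (log-scaling keeps it exactly zero).

### Units

The tabulated couplings are dimensionless.  Fixed unit scales convert
them into the drive units of the convolution dynamics: 800 for intrinsic
connections, 4000 for the forward projection and 4000/2000 for the
backward projections onto SPC/II.  With these scales the prior-mean
circuit produces a gamma resonance (forward transfer peaking near 40 Hz),
a beta-range backward transfer (near 15–17 Hz), and inter-areal
coherence reaching ~0.5 — the regime of the strongly gamma-coherent
site pairs this model is intended for.  The electrode gain unit of 1e4
puts the prior-mean channel autospectrum at O(1) power, so that data
normalization inside the fit is a small correction rather than a large
one.  Unit scales are structural constants, not estimated parameters.

### Spectral forward model

Linearizing at the fixed point gives the frequency response

    T(w) = L (i w I - J(w))^(-1) B

with the extrinsic conduction delay (prior mean 16 ms) applied as the
exact phase factor `exp(-i w delay)` on the extrinsic Jacobian entries —
exact for a linear delay system and cheaper and better conditioned than
delay-differential integration.  `B` injects each source's endogenous
fluctuations into its SS population; `L` reads out depolarizations.  The
predicted channel CSD is

    G_y(w) = M T(w) G_u(w) T(w)^H M^H + G_s(w) + G_c(w)

where `M` is the observation matrix (electrode gain × population
weights), `G_u` the diagonal endogenous-fluctuation spectra, `G_s`
diagonal channel-specific noise and `G_c` a rank-1 noise term common to
all channels.  Every spectral component is a power law
`amplitude * (f^-exponent + 1e-6)`; the white floor keeps densities
positive and the fit well conditioned.  Amplitudes multiply the spectral
density directly (power units).  Population-specific spectra use an
indicator observation vector (unit gain, no noise); "denoised" spectra
are posterior predictions with noise zeroed and gains set to one.

Parameter draws whose delay-free Jacobian has an eigenvalue with
nonnegative real part are rejected during sampling and treated as
invalid (infinitely penalized) proposals during optimization.

## Inversion

The observed CSD is reduced to a real feature vector: real parts of the
diagonal and real+imaginary parts of the upper off-diagonal entries,
per frequency, ordered by channel pair then frequency.  The likelihood
is Gaussian with diagonal precision, one log-precision hyperparameter
per channel-pair block, with the deliberately precise hyperprior
`N(6, 1/128)` ("precise priors on the precision"); before fitting, the
data are rescaled so the mean autospectral power is one, making that
hyperprior scale-meaningful.

Variational Laplace maximizes the free energy

    F = E_q[ln p(y|theta, lambda)] - KL(q(theta)||p(theta))
                                   - KL(q(lambda)||p(lambda))

by Gauss–Newton updates on the posterior mean with Levenberg–Marquardt
damping: a candidate step is accepted only if it increases F, otherwise
damping increases and the step shrinks, so the trace over accepted
iterations is nondecreasing by construction.  Gradients use central
finite differences (step 1e-3 in log space) and the Gauss–Newton
curvature `J' Pi J` — robustness over speed at desk scale.  The noise
log-precisions are updated by a few Newton steps per iteration (the
conditional objective is concave and the update is effectively closed
form under the tight hyperprior).  Convergence: `dF < 1e-2` on an
accepted step, or a local maximum (no improving step), with a cap of
128 iterations; hitting the cap flags the fit non-converged.
`accuracy - complexity = F` holds exactly by construction, and the
Laplace posterior is validated against dense-grid quadrature on a
2-parameter toy problem.  Because free-energy ascent is local, fits can
optionally restart from jittered initializations (``n_starts``), keeping
the solution with the highest free energy; model-comparison experiments
use 3 starts per fit.

Model comparison fits the veridical and reversed hierarchies to the same
data and compares free energies; `|dF| < 1e-6` is reported as a tie.  A
difference of 3 corresponds to posterior odds `exp(3) ≈ 20:1`.  The
reduced (accuracy-only) evidence of a channel pair,
`F_ij = -1/2 e' Pi e + 1/2 ln|Pi|`, is reported alongside for
comparisons between models of identical complexity; the Gaussian
constant is omitted there because it cancels between equal-dimension
models.  Evidence pools across datasets by summation.

## Synthetic data

The generator defines the study conditions.  CSD-level datasets are the
spectral prediction plus Gaussian noise on the real features (which
preserves Hermitian structure), scaled so that total signal variance /
noise variance = `exp(log precision)`; per-feature noise variance is
allocated proportionally to the mean signal power at that feature's
frequency, keeping relative SNR roughly flat across the spectrum.  The
face-validation condition is log precision 7.  Generative parameters for
that experiment are prior samples — the empirical posterior estimates
this stands in for do not ship with any public source.  Log precisions
of 30 or more are treated as exactly noiseless.

Time-domain simulations are the independent oracle for the analytic
spectra.  The linearized stochastic dynamics are integrated with an
exponential Euler–Maruyama scheme at dt = 0.5 ms: the intrinsic
(undelayed) part advances by its exact matrix exponential, while the
colored drive and the conduction-delayed extrinsic input are held
constant over each step.  A plain Euler step at this dt has ~25–30%
spectral bias at the 2 ms synapses (`kappa*dt = 0.25`); the exponential
scheme reduces the oracle error to a few percent.  The nonlinear option
(full sigmoid) uses plain Euler–Maruyama and is used to confirm that the
nonlinear model converges to the linear prediction as the drive
amplitude shrinks.  Colored drives come from frequency-domain amplitude
shaping of white Gaussian noise (circulant embedding), so their expected
one-sided PSDs match the parameterized forms exactly.  The extrinsic
delay uses a state ring buffer.

The oracle comparison estimates the simulated CSD with 2 s Welch
segments: at the default 0.5 s epochs the multitaper smoothing bandwidth
(±4 Hz) noticeably biases the sharp beta-band peak/notch structure of
the cross-spectrum, while much longer segments trade that bias for
estimator variance.  The data-analysis pathway keeps the 0.5 s epoch
default.

## CSD estimation from recordings

Epochs (default 0.5 s, non-overlapping) are z-scored per epoch and
channel; zero-variance epochs are dropped with a log entry.  The
estimator is multitaper with DPSS tapers (time-bandwidth 2, 3 tapers),
averaged over epochs and tapers, returned as one-sided densities and
interpolated onto the analysis grid.  Bipolar re-referencing, power-line
sinusoid regression and variance-threshold artifact rejection ship as
pure functions with conservative defaults: they document the intended
preprocessing of real recordings and are exercised only by unit tests on
synthetic signals, since no real data ship with the package.

## What the synthetic conditions do and do not show

Passing tests demonstrate internal consistency (analytic spectra match
simulations; inversion recovers self-generated parameters and
hierarchies at the stated SNR) under the model's own assumptions:
stationary fluctuations, a single stable fixed point, power-law drives
and noise, and exactly two sources observed without cross-talk.  Real
ECoG involves non-stationarity, volume conduction, more sources,
non-power-law noise and electrode artifacts; performance there is a
question of predictive validity that synthetic checks cannot settle.

## Problem sizes and numerical choices

Desk-scale defaults: inversions run on a 4–80 Hz grid at 4 Hz spacing
(20 frequencies, 80 features, 45 free parameters), the face-validity
experiment uses 5 prior-sampled datasets (the full design is 15, as in
the CLI `validate` subcommand), parameter recovery uses 10 jittered
restarts (initialization jitter sigma = 0.1 in log space — noise-free
self-generated data would otherwise start the optimizer exactly at the
optimum), and the selection-accuracy sweep over log precisions {1, 4, 7}
uses 20 datasets per level on a 5 Hz grid with a reduced iteration cap.
The simulation oracle integrates 600 s.  Tie-break conventions: model
selection reports ties below 1e-6; the asymmetry index is defined as 0
when both directed transfers vanish (a fully uncoupled network has no
direction to be asymmetric about).  Degenerate inputs (zero-variance
epochs, nonpositive time constants, unstable draws, grids beyond Nyquist
or below spectral resolution) raise informative errors rather than
propagating silently.

## Known limitations

- Exactly two sources; no volume-conduction forward model (LFP/ECoG
  observation only), no scalp EEG/MEG leadfields.
- Single-dataset inversions with offline pooling; no hierarchical
  (empirical Bayes) group model.
- Finite-difference gradients make each iteration O(parameters) forward
  evaluations; adequate at two sources, not tuned for large networks.
- The reversed model swaps only the forward/backward roles of the two
  sources; prior source assignments are otherwise untouched.
- Stationarity is assumed throughout; condition-specific (induced)
  changes in coupling are out of scope.
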