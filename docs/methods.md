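# Methods

## Model

Each parcellated region is a two-population neural mass: excitatory and
inhibitory synaptic gating variables (E, I) with NMDA/GABA-like decay times
(tau_E = 0.1 s, tau_I = 0.01 s), sigmoidal current-to-rate transfer
functions, and input currents squashed through a tanh so that they remain in
a biologically plausible range without projection steps. Long-range coupling
acts on the excitatory populations through the graph Laplacian L = D − C of
the subject's log-transformed, unit-normalized structural connectome; the
Laplacian annihilates the spatially uniform mode, so a uniform excitatory
state receives exactly zero network input. Because the field also commonly
writes the long-range term as a plain weighted sum of neighbor activity, a
`coupling_mode` flag selects `laplacian` (the default, matching the state
equations as implemented) or `adjacency` (Σ_j C_ij E_j); the flag is echoed
into every result and manifest, and the two conventions behave very
differently at desk scale (see *Identifiability*, below).

State noise is additive white Gaussian noise of standard deviation sigma on
both populations, integrated with Euler–Maruyama (noise scaled by sqrt(dt));
after each stochastic step E is clamped to [0, 1] and I to [0, ∞), and clamp
events are counted and reported (with sigma = 0 and default constants no
clamp ever fires).

The fixed biophysical constants are the canonical two-state values of the
model's standard derivation (a_E = 310 nC⁻¹, b_E = 125 Hz, d_E = 0.16 s,
a_I = 615, b_I = 177, d_I = 0.087, gamma = 0.641, I_0 = 0.382 nA, W_E = 1,
W_I = 0.7, sigma = 0.01); all are overridable through
`BiophysicalConstants`. The removable singularity of the transfer function
at a·I = b is evaluated by its series limit 1/d, and the implementation is
overflow-safe for arbitrarily large currents.

BOLD is generated per node by the Balloon–Windkessel model (kappa = 0.65 s⁻¹,
gamma_h = 0.41 s⁻¹, tau_h = 0.98 s, alpha = 0.32, rho = 0.34, V0 = 0.02,
k1 = 7·rho, k2 = 2, k3 = 2·rho − 0.2), driven by the excitatory gating
variable, integrated with deterministic Euler at the neural step and
decimated to the repetition time. The baseline state (0, 1, 1, 1) is a fixed
point with zero BOLD output, and the implementation raises (naming the time
index) if volume or deoxyhemoglobin ever reach zero.

## Variants and fitting

GM optimizes the four global gains (g, g_EI, g_IE, g_EE); LM keeps g global
and frees the three local gains per node (1 + 3N parameters); CM keeps all
four gains global and additionally optimizes the SC upper triangle
(4 + N(N−1)/2 parameters), with symmetry and the zero diagonal inherited
from the upper-triangular parametrization.

The loss per epoch is the negative Pearson correlation between the strictly
upper triangles of simulated and target FC, plus
`0.5 · ||SC_mod − SC_emp||²` over the upper triangle for CM (with SC_mod
clamped element-wise to [0, 1] after every optimizer step) and
`0.05 · Σ var_nodes(gain)` for LM. Gains are optimized as unconstrained
latents mapped through softplus, which keeps them positive without
projections; SC_mod is a direct parameter with clamping. ADAM (lr 0.05
default) with exponential learning-rate decay (0.995 per epoch) performs the
updates. A warm-up phase (default 20 epochs of simulated activity without
parameter updates) precedes optimization, and both neural and hemodynamic
states are carried across epochs so each epoch needs no fresh transient.
Fresh noise is drawn per epoch from the run's seed stream; since the noise
is additive and parameter-independent, gradients flow through the drift
only, and every run is exactly reproducible from its config and seed.

Gradients are computed by a hand-derived reverse-mode adjoint
(backpropagation through time across the Euler–Maruyama steps, the balloon
steps, the per-node z-scoring, the FC build, and the Pearson head), with the
step loops JIT-compiled by numba. The test suite holds every gradient path
(four gains, per-node gains, SC edges, and the loss head) to central finite
differences of the full simulator at 1e−3 relative tolerance or better; in
practice agreement is ~1e−7.

Numerical choices: integration step dt = 0.001 s by default for plain
simulation and 0.005 s in fitting configurations (both well inside the
stability region set by tau_I; the balloon stage converges at first order
and halving dt moves BOLD by < 1e−4 in relative norm); z-scoring uses a
1e−12 variance floor; rank ties in fingerprinting break by subject index
for cross-platform determinism.

## Synthetic cohorts

The generator emulates the structure of a resting-state modelling study:
sparse connected SCs (random spanning tree plus extra edges to a target
density) with heavy-tailed lognormal streamline weights; a cohort template
with small per-subject multiplicative edge jitter, mimicking the high
anatomical correlation between real subjects that makes fingerprinting
non-trivial; ground-truth gains jittered around the canonical values
(per-node for LM cohorts, per-edge coupling modifications for CM cohorts);
target FC computed from the forward model itself with observation noise
added on Fisher-z off-diagonals and projected back to a valid (symmetric,
unit-diagonal, positive-semidefinite) correlation matrix; and phenotypes
with configurable planted linear loadings on gain summaries.

What the generator does **not** emulate: spatial embedding and distance-
dependent connectivity, hemodynamic variability across regions, scanner
artifacts and motion, and the sheer dimensionality of real parcellations
(219 regions, 23k FC edges). Desk-scale cohorts (10 regions, 10-20
subjects) carry far less information per FC than real data, so passing
tests demonstrate the correctness and calibration of the machinery — not
that effect sizes or identification rates transfer quantitatively to real
cohorts.

## Identifiability at desk scale

Two findings from this package's own validation experiments shape the
canned study designs and are worth stating plainly.

First, under the Laplacian convention the uniform-mode null space removes
the mean-drive pathway of the global coupling: g acts only on fluctuations
around the (nearly uniform) operating point. At desk scale the resulting
resting FC is weakly reproducible (per-subject retest correlations of
simulated FC span −0.2 to +0.9 depending on the connectome realization), and
no variant can express stable individuality. Under the adjacency convention
the simulated FC is highly reproducible (retest r ≈ 0.9) and strongly
anatomy-driven, so the canned fingerprinting and recovery experiments run
with `coupling_mode="adjacency"`; the flag is recorded in their outputs.

Second, the FC-correlation objective is only weakly informative about g in
either convention: the expected per-epoch gradient at the true g is
non-restoring (under the Laplacian convention it rewards amplifying
SC-shared structure regardless of the true coupling; under the adjacency
convention it is biased low), and running the optimizer longer moves the
estimate toward the objective's true maximizer — away from the generating
value. The global-coupling recovery experiment therefore recovers g within
20 % in only about three quarters of replicates, and this is reported as
measured. This sloppiness is not an implementation artifact (the gradients
are verified against finite differences): it is a property of fitting a
near-uniform operating point through a scale-invariant correlation loss,
and it is consistent with the broader observation that the low-dimensional
variant explains little FC variance and carries little individual-specific
information. By contrast the connectivity variant, whose per-edge parameters
can absorb each subject's FC realization, individualizes strongly — the
fitted SC modifications, not the global gains, carry the subject
information.

## Node and network stability analysis

With coupling removed and noise off, each node is a planar system whose
fixed points are found by Newton iteration (analytic Jacobian) seeded from a
12×12 grid over [0, 1] × [0, I_max], with I_max set to twice the largest
tau_I·R_I scale; duplicates merge at 1e−6 and each root is labeled stable
iff both Jacobian eigenvalues have negative real parts (monostable /
bistable / no-stable-fixed-point regimes). An independent in-package oracle
(dense 400×400 sign-change scan polished by a MINPACK solver) must agree
with the Newton solver in the test battery. At the network level, a fixed
point of the full 2N-dimensional deterministic system is located from a
relaxed state and the stability margin m = −max Re eig(J) is reported
(m > 0 linearly stable); the analytically assembled 2N×2N Jacobian is
verified against finite differences at 1e−5. The margin refers to the fixed
point reached from the relaxed state — for multistable networks this is the
attractor the warmed-up simulation actually occupies, not a worst case over
all fixed points.

## Phenotype statistics

Associations between features (fitted parameters or FC edges) and
phenotypes use covariate-adjusted OLS with z-scored target and predictor
(standardized beta) for continuous targets and a covariate-adjusted ANOVA
with partial eta-squared for the binary target, with age, gender and site as
covariates of no interest (the target excluded from its own covariates).
P values are corrected across features within each target by
Benjamini–Yekutieli at q < 0.05 (not across targets). The strongest feature
per target carries a stratified BCa bootstrap CI (bias correction from the
bootstrap distribution, acceleration from the jackknife; resampling within
strata preserves group sizes) and single-predictor prediction summaries:
deconfounded logistic AUROC for the binary target, MAE / MAD / Spearman /
Pearson for continuous ones — MAE and standardized effect sizes are reported
side by side and never collapsed, since they capture different aspects of
predictive quality. Null calibration (BY rejection rate, BCa coverage) is
checked in the acceptance battery. A first-timepoint filter is available to
prevent leakage when exporting features for external ML frameworks; the full
multivariate ML benchmark itself is out of scope and served by a documented
CSV export instead.

## Known limitations

* Desk-scale cohorts cannot reproduce full-size effect sizes or
  identification rates; the battery checks mechanisms and calibration.
* The global gains are weakly identified from FC (see above); parameter
  interpretation should lean on the connectivity variant's edge estimates.
* The hemodynamic model is homogeneous across regions and its parameters
  are fixed, not fitted.
* The network stability margin is attractor-local (see above).
* Euler / Euler–Maruyama integration is first-order; dt must stay well
  below tau_I (the defaults do).
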