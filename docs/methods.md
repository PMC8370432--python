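# Methods

This note documents the generative model, the inference machinery, the
synthetic-cohort design and the numerical choices behind `dcmerf`, in the
spirit of a model-description appendix.

## 1. The cortical column

Each source is a mean-field column of six neuronal populations: layer-4
spiny stellate cells (`ss`), superficial pyramidal cells (`sp`) and
interneurons (`si`), deep cortico-cortical pyramidal cells (`dp`), deep
interneurons (`di`) and thalamic-projection pyramidal cells (`tp`).
Per population the hidden states are the mean membrane potential `V` (mV)
and three mean channel conductances `g_AMPA, g_NMDA, g_GABA`, expressed as
dimensionless multiples of the leak conductance:

    C dV/dt = (V_L − V) + g_A (V_E − V) + g_N m(V) (V_E − V)
              + g_G (V_I − V) + u(t)
    dg_k/dt = κ_k (ς_k − g_k)

`m(V) = 1/(1 + 0.2 e^{−0.06 V})` is the voltage-dependent magnesium gate
on the NMDA channel. Population firing is a logistic function of `V`
(threshold −55 mV, slope 0.2 mV⁻¹); the presynaptic drive `ς_k` is the
connectivity-weighted **rectified deviation of the rate from its resting
value**, `r(V) = max(σ(V) − σ(V_L), 0)`. This choice makes the resting
state (`V = V_L`, `g = 0`) an exact fixed point of the network and
guarantees conductances remain non-negative under integration; its cost is
that "tonic" inhibition is a response-gain control engaged during evoked
activity rather than a literal standing conductance.

Constants (all overridable via `MicrocircuitSpec`):

| quantity | value | note |
|---|---|---|
| V_L, V_E, V_I | −70, 60, −90 mV | leak / excitatory / inhibitory reversal |
| κ_AMPA, κ_GABA, κ_NMDA | 1/4, 1/16, 1/100 ms⁻¹ | inverse synaptic time constants |
| C | 16 ms (all populations) | membrane time constant in g_L units |
| sigmoid | threshold −55 mV, slope 0.2 mV⁻¹ | see below |
| m(V) | 1/(1+0.2e^{−0.06V}) | NMDA magnesium gate |

The firing threshold sits 15 mV above rest. With a far threshold (tens of
mV above rest) and evoked deflections of a few mV, all rates stay in the
deep tail of the sigmoid and the inhibitory parameters are essentially
invisible in the measured fields (ERF sensitivities of 10⁻³–10⁻⁴); since
the purpose of the model is laminar *inhibitory* inference, the default
regime is chosen so that interneurons engage during the response. Under
the defaults every GABAergic synapse has a relative ERF sensitivity of
0.015–0.34 and the dynamics remain stable for parameter draws spanning ±3
prior SD.

Intrinsic wiring: excitation follows the laminar cascade ss→{sp, si},
sp→{dp, si}, dp→{tp, di}, tp→{di, ss}; GABA-A comprises one tonic
self-connection per population (`tonic:<pop>`) and four phasic efferents
(`phasic:si->ss`, `phasic:si->sp`, `phasic:di->dp`, `phasic:di->tp`).
Off-diagonal GABA weights may originate only from `si`/`di`; this is
asserted on every constructed specification.

## 2. The six-source network

Sources lA1, rA1, lSTG, rSTG, lIFG, rIFG. Forward connections ascend
A1→STG→IFG per hemisphere (origin `sp`, terminating on `ss` and `si`),
backward connections descend the reverse edges (origin `dp`, terminating
on `sp`, `si`, `dp`, `di`), lateral connections couple homologous regions
(origin `dp`, terminating on `ss` and `dp`). Exogenous drive — the
auditory volley and a frontal "expectancy" input — is a Gaussian bump
(peak 60 ms, half-width 8 ms) into `ss` of bilateral A1 and IFG.

Every tunable quantity is a log-scaling parameter, `actual =
prior_mean · e^θ`, so `θ = 0` reproduces the prior-mean model bit-exactly
and Gaussian beliefs over θ respect positivity. Default free classes:
the ten GABAergic synapses (shared across sources), the eight
forward/backward gains, and the input amplitude and latency (20
parameters). Prior variances: 1/16 for synaptic and extrinsic log-gains,
1/32 for input parameters. The observation log-gain is frozen by default
because it is nearly collinear with input amplitude.

## 3. Observation and conditioning

The ERF of a source is a gain-scaled weighted sum of population
depolarizations (weights ss 0.2, sp 1.0, dp 0.6, tp 0.3 — pyramidal
dominated, shape not calibration; the free log-gain absorbs scale).
Simulated and "recorded" ERFs pass through identical conditioning: a
zero-phase 6th-order Butterworth low-pass at 48 Hz (DC retained; 60 Hz is
attenuated by >20 dB after forward-backward filtering) and a Tukey window
equal to exactly 1 on 50–350 ms with cosine tapers to the epoch edges
(−100 and 400 ms). Conditioned datasets carry a flag and pass through
unchanged on re-application, so the taper is never applied twice.

## 4. Variational inversion

Inversion maximizes the Laplace free energy

    F = −½ eᵀΠe + ½ ln|Π| − (n/2) ln2π − ½ (μ−m₀)ᵀΠ₀(μ−m₀) − ½ ln(|Σ₀|/|Σ|)

with per-source iid noise precisions `Π = diag(e^{λ_s})` and
`Σ = (JᵀΠJ + Π₀)⁻¹`. For a linear-Gaussian model this expression equals
the exact log marginal likelihood (the trace terms of the evidence bound
cancel at the Gauss–Newton Σ); accuracy and complexity are reported as
`E_q[ln p(y|θ)]` and `KL(q‖prior)`, which sum to F.

- **Likelihood grid.** Residuals are evaluated on a decimated time grid
  (every 10th sample, ≈100 Hz). Band-limiting at 48 Hz leaves about
  2 × 48 independent samples per second; treating every 1 kHz sample as
  independent would overstate the information tenfold and produce
  overconfident posteriors (this is visible as 2-posterior-SD coverage
  failing in recovery simulations; with decimation, coverage is nominal).
- **Optimizer.** Gauss–Newton with Levenberg–Marquardt damping: damping
  ×2 on rejection, ×½ on acceptance; candidates are pre-screened with the
  residual+prior score and accepted only if the fully recomputed F
  increases, so the accepted-F trace is monotone by construction.
  Convergence after 4 consecutive accepted steps with ΔF < 0.01 nats, or
  when no step is accepted and the Newton decrement predicts < 0.01 nats
  of improvement. Maximum 64 iterations; initialization at the prior
  mean; optional prior-jittered multistarts (best F wins).
- **Jacobians** by central finite differences (step 10⁻³ in θ), all
  2p + 1 simulations evaluated in a single batched integrator run.
- **Noise.** Per-source log-precisions with hyperprior N(4, 1), updated by
  a damped Newton MAP step between parameter updates and kept only if F
  does not decrease.
- Standard and deviant conditions are inverted separately; group analyses
  consume deviant-condition posteriors by default.

The integrator is fixed-step RK4 at dt = 1 ms over −100…400 ms; halving
the step changes prior-mean trajectories by ~10⁻⁶ relative L2. Trajectories
whose potential leaves V_L ± 150 mV are flagged as diverged (frozen, never
NaN); the fitted F is −∞ for such parameter points.

## 5. BMR and PEB

Bayesian model reduction computes the posterior and evidence of any model
differing only in its priors in closed form (precision algebra in
§`dcmerf.bmr`), never touching data; it is verified against brute-force
conjugate evidence differences to 10⁻⁶ and Savage–Dickey ratios to 10⁻⁴.
Greedy pruning switches off parameters whose removal does not lower the
evidence, largest gain first, ties broken by name.

PEB is implemented as exact empirical Bayes in information form: each
subject's likelihood is reconstructed from posterior and prior
(`Λᵢ = Pᵢ − P₀`, eigenvalue-clipped to PSD), the between-subject model
`θᵢ = Bᵀxᵢ + εᵢ`, `εᵢ ~ N(0, e^{−γ} diag(prior variances))` is integrated
analytically, and the scalar log-precision γ is optimised on the exact
marginal likelihood (γ prior N(ln 16, 4), bounds [−4, 16]). The prior on
each second-level effect equals the corresponding first-level prior
variance. Effect posterior probabilities come from BMR-pinning each β
element to zero: `Pp = 1/(1 + e^{ΔF})`. A third-level model treats the
second-level β posteriors as data with their own prior — `peb_of_pebs` is
literally `fit_peb` applied one level up, which yields group effects on
both the mean and the drug components (interactions). This differs from
the iterated-Gauss–Newton implementation common in neuroimaging toolboxes
but targets the same hierarchical Gaussian model; it is validated against
numerical quadrature of the hierarchical integrals.

The GABA-covariate analysis is restricted to the ten GABAergic synapses:
the model comparison adds a single standardized GABA column to the
group/drug design, and GABA × drug and GABA × group interactions are
estimated in a separate expanded model (mirroring the practice of testing
covariate interactions in their own design). Collinearity between GABA and
the group contrast (patients have lower GABA) is real and intended; the
comparison measures what the covariate explains beyond group membership.

## 6. Synthetic cohorts

The generator emulates a placebo-controlled, double-blind crossover
pharmaco-MEG study: 20 controls, 15 PSP, 17 bvFTD; sessions placebo and
tiagabine; conditions standard and deviant; an MRS-like GABA covariate in
arbitrary units (means 2.0 / 1.55 / 1.45 for control / PSP / bvFTD, SD
0.25 — ordering, not magnitudes, is the meaningful content). True
subject-session parameters follow a GLM: between-subject SD 0.1, session
jitter SD 0.02, plus injected effects coded ±1 with size expressed as the
per-unit-code deviation in prior-SD units (default 0.5, i.e. a full
between-condition difference of one prior SD). Default effect loci mirror
the phenomena the analysis is designed to detect: a patient deficit of the
left IFG→STG backward gain; a tiagabine increase of `tonic:di`; opposing
drug effects in PSP vs bvFTD at `phasic:si->ss`; GABA slopes positive on
`tonic:di`, `phasic:di->dp`, `phasic:di->tp` and negative on `tonic:dp`.
Deviant trials additionally scale the forward gains by e^0.1.

Observation noise is additive white Gaussian at amplitude SNR 8 for the
trial-averaged ERF at the baseline trial count (160 deviant / 120 standard
trials); noise variance scales as 1/n_trials. True parameters live in a
separate truth store that the inversion and PEB code paths never receive.

Two fidelities: `"erf"` simulates full ERF datasets through the generative
model (used for inversion studies); `"posterior"` draws first-level
Gaussian posteriors directly around the true parameters (posterior SD
0.05), the standard device for exercising the hierarchical machinery at
full cohort size without thousands of model inversions. What the
posterior-fidelity results show is the power and calibration of the
BMR/PEB stack given honestly-calibrated first-level uncertainty; they do
not test the inversion itself, which is assessed separately.

**What the generator does not emulate:** sensor-level MEG, head movement,
source-reconstruction leakage between sources, non-Gaussian artefacts,
between-subject variation in anatomy or observation gain, and session
order effects. Passing recovery tests therefore demonstrates correctness
of the inference machinery under the stated statistical assumptions, not
robustness to the full messiness of recorded MEG.

## 7. Problem sizes in the shipped checks

The acceptance script inverts 10 single-source subjects (self-consistency
and free-energy monotonicity) and 6 six-source subjects (pooled
truth-estimate correlation at the default SNR), runs 20 replicate default
cohorts plus 20 nulls for detection/calibration of the injected effects,
8 injected and 20 null cohorts plus 20 permutations for the GABA model
comparison, and checks 10⁵ roving-oddball tones. These sizes were chosen
so the whole script completes in minutes on a single core while keeping
Monte-Carlo error well below the decision margins.

## 8. Known limitations

- GABA-B conductances and explicit thalamic dynamics are not modelled
  (the `tp` population is the only thalamocortical element).
- The intrinsic prior-mean weights are package defaults calibrated for
  stability, realistic response latency (STG/IFG deflections peaking
  ~115–120 ms) and laminar observability — not fitted to any dataset.
- Tonic inhibition is response-contingent (see §1): the model cannot
  express changes in resting conductance, only in inhibitory gain.
- The PEB between-subject covariance is a single scaled diagonal; richer
  random-effects structure (per-class precisions, subject pairing across
  crossover sessions) is not modelled, which makes drug effects slightly
  conservative.
- Separate per-condition inversions ignore that standard and deviant
  responses share most parameters; a joint inversion with
  condition-modulation parameters would be more efficient but is out of
  scope.
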