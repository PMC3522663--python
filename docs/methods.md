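# Methods

`psyqsp` is a mechanistic quantitative-systems-pharmacology model that maps
an antipsychotic's receptor binding profile plus its PET-measured D2 target
engagement onto two clinical readouts: the predicted improvement on the
PANSS total score (Positive and Negative Syndrome Scale) and the
extra-pyramidal side-effect (EPS) liability, proxied by the fraction of
patients started on anticholinergic co-medication.  This note documents the
model, its assumptions, every calibrated number the package ships, and what
the synthetic-data experiments do and do not demonstrate.

## 1. Receptor competition at the synapse

Each transmitter system (dopamine, serotonin, acetylcholine,
norepinephrine) is modelled as a well-stirred synapse in which the
neurotransmitter (NT), the drug's molecular species and, for dopamine, the
PET tracer raclopride compete by mass action for receptor pools.  Release
is spike-driven: deterministic tonic firing (DA: 3 Hz) interrupted by
scheduled bursts (60 Hz for 0.5 s once per 10 s period), each spike adding
a fixed NT quantum to the cleft.  Binding follows
`db_i/dt = kon_i c_i (1 - sum_j b_j) - koff_i b_i` with a shared
association rate `kon = 1e-2 /nM/s` (1e7 M^-1 s^-1) and `koff = Ki * kon`,
so affinity differences appear purely as dissociation-rate differences: the
Ki = 220 nM selective antagonist has koff = 2.2 /s (responds within a
burst), the Ki = 1.22 nM antagonist koff = 0.0122 /s (effectively frozen
across the firing period).

### Two NT compartments

The dopamine synapse carries two free-NT pools sharing one release process:

* **extrasynaptic** (volume transmission): cleared by a *saturable*
  transporter (Michaelis-Menten, Km = 1278 nM) and carrying the D2
  autoreceptor pool and the tracer's binding pool.  Autoreceptor activation
  suppresses release through a descending sigmoid; an antagonist blocking
  autoreceptors therefore disinhibits release, and because the transporter
  is near saturation the extrasynaptic DA level rises steeply
  (super-linearly) with drug load.
* **cleft** (intrasynaptic): cleared first-order (diffusion-dominated,
  40 /s), feeding the postsynaptic *activation* pools at the high-affinity
  receptor state (DA Kd 100 nM).

This split is forced by an arithmetic identity: in any single-compartment
competition model, matching the calibration pair "80% tracer displacement
at 840 nM of a Ki = 220 nM drug" (drug load 3.82 < 0.80/0.20 = 4) requires
the DA level to rise enough that the time-averaged postsynaptic D2
activation cannot decrease — the therapeutic signal would vanish.  With
the compartments separated, the tracer sees the surging extrasynaptic DA
(reproducing the steep, Hill-coefficient ≈ 1.6 displacement curve) while
postsynaptic activation genuinely falls under blockade.

### Calibrated reference values

The DA synapse parameters (release quantum, autoreceptor gain/half/width
and Kd, transporter Km, cleft scale) are a stored one-time fit to the three
published displacement↔concentration calibration pairs of the selective
low-affinity D2 antagonist (55% ↔ 400 nM, 75% ↔ 700 nM, 80% ↔ 840 nM);
the shipped values reproduce all three to < 0.05 percentage points.  These
pairs are the anchor of the concentration scale, not independent
validation.  Inverting the ocaperidone moiety's 69% displacement yields
≈ 1.7 nM under this calibration (the published single-dose study reported
4.3 nM); the two are not jointly reproducible in this model family, and
the pairs of the selective antagonist were given priority.

The ventral (accumbens) synapse carries the hyperdopaminergic disease
state: doubled release per spike and a 30% lower transporter Vmax (DAT
density).  The dorsal (motor) variant uses the healthy base release, full
DAT, and half the autoreceptor feedback gain (lower D3 autoreceptor
level).  Activation summaries are time averages over the 10 s firing
period at the *periodic steady state* of the cycle map, found by a damped
Newton solve on the state after one period (slow ligands equilibrate over
minutes; transient simulation would never converge).  The drug's
activation contribution is weighted by `(1 + e)/2` where `e` in [-1, 1] is
intrinsic efficacy: a neutral antagonist (e = -1, the default) contributes
nothing, a full agonist everything.

The ACh / NE / 5-HT synapses are tonic-only (5, 1.5, 1.5 Hz), first-order
clearance, with release tuned so the drug-free activation of each coupled
receptor is 0.5.  They exist to convert off-target occupancies into
activation changes; no autoreceptor feedback is modelled there.

## 2. The MSN circuit (PANSS side)

A single-compartment Hodgkin-Huxley medium spiny neuron with transient
sodium, delayed-rectifier potassium, leak and an inward-rectifier (Kir2)
conductance

    g(V) = gmax / (1 + exp((V - Vh)/Vc)),  gmax = 1.2 mS/cm^2,
    Vh = -111 mV, Vc = -11 mV, E_K = -90 mV,

is driven by Poisson cortical afferent volleys (200 Hz before gating)
through an exponential synapse, gated by periodic hippocampal (2 s period,
60% duty) and amygdala (3.7 s, 50%) envelopes, plus a background current.
The readout is the number of action potentials (upward crossings of 0 mV,
2 ms refractory) over a fixed 21 s window.  Three populations — direct
(D1), indirect (D2) and mixed D1+D2 — are combined 47.5 : 47.5 : 5.

Ten coupling parameters scale multiplicative modulations `1 + c*u`
(clipped at 0.05) of circuit quantities by receptor-activation changes
`u`:

| coupling | target | populations |
|---|---|---|
| d1_kir | Kir2-type resting K | D1, mixed |
| d1_syn | afferent weight | D1, mixed |
| d2_gk | resting K | D2, mixed |
| d2_presyn | afferent weight (presynaptic D2 on glutamate) | all |
| m1_leak | leak | all |
| m2_gk | resting K | all |
| m2_presyn | afferent weight | all |
| a1_syn | afferent weight | all |
| a1_bg | background current | all |
| ht3_bg | background current | all |

The single-compartment reduction folds the different K channel types that
D1, D2 and M2 receptors target into the one resting (Kir2-type)
conductance, which is the circuit's dominant excitability lever.

Integration is exponential-Euler at dt = 0.2 ms with voltage-grid lookup
tables (0.02 mV) for the gate kinetics; the tables are exact reusable
functions of V only, so coupling evaluations pay only the arithmetic.

### Shipped calibration and link map

The hypofrontal disease state attenuates cortical drive by 0.85.  The
afferent weight is tuned so the drug-free (placebo) combined firing is 199
spikes / 21 s at the reference circuit realization (seed 1).  The ten
accumbens couplings are a reference calibration fitted so the shipped
drugs reproduce the published firing anchors: risperidone 4 mg → ~245,
olanzapine 15 mg (75% D2) → ~285, clozapine 210 mg → ~297, and the
selective antagonist at 80% engagement → ~268; comparator affinities
(olanzapine, risperidone, clozapine) are consensus values from public
receptor-screening data.  Firing maps to PANSS improvement through a
least-squares linear fit of the published anchor pairs
(199, 1.7), (245, 13.4), (286, 24.0), (297, 27.0) — maximum anchor
deviation 0.1 point.  The paper-reported sensitivity of predictions to a
±20% D2-coupling deviation is reproduced in magnitude (mean ≈ ±2.4-2.8
points) with D2 the dominant parameter; the sign depends on the coupling
convention and is positive here (stronger D2 coupling → larger predicted
improvement), which is the internally consistent direction when blockade
raises firing.

## 3. The EPS model

The motor side combines a dorsal-striatum MSN circuit (same parameters, no
accumbens pathology, its own reference coupling set — notably a *negative*
M1-leak coupling, so muscarinic blockade damps motor firing, the
anticholinergic-therapy mechanism) with a cortical threshold factor from a
12-compartment passive pyramidal cable: the minimal apical Poisson input
rate whose steady depolarization brings the soma to threshold, normalized
so the drug-free factor is 0.70.  5-HT2A blockade increases apical
synaptic gain (coupling -0.283, a stored fit anchoring olanzapine 10 mg at
0.62) and 5-HT1A activation lowers leak (-0.3), both lowering the factor.
The EPS score is `motor firing x threshold factor`; a two-parameter
logistic solved exactly on the calibration anchors (placebo score → 16%,
olanzapine 15 mg score → 23%) converts it to the anticholinergic-use
fraction.  The logistic anchors are recomputed per circuit seed, so the
calibrated fractions are exact for any afferent realization.  Under this
calibration the three doses of the selective antagonist come out at
≈ 27/28/29% — above olanzapine despite equal or lower D2 engagement,
because its negligible 5-HT2A affinity leaves the cortical threshold
high.  Clozapine's 5-HT1A entry is marked a partial agonist (e = 0.5),
reflecting its known pharmacology.

## 4. Calibration machinery

For a drug-dose dataset the evaluator precomputes per-point activation
vectors and afferent trains, then maps a coupling vector to firing numbers;
the objective is the squared Pearson correlation with the patient-weighted
clinical outcomes (affine-invariant; the outcome scale is recovered
afterwards by OLS, whose residual sd feeds normal-theory 95% prediction
intervals).  The readout averages spike counts over two afferent-train
realizations per point and population: with a single train the integer
quantization makes near-exact recovery ill-conditioned.

The classic coarse-grid + steepest-ascent pipeline is implemented and
exposed (`coarse_grid_search`, full factorial up to 4 free dimensions,
else seeded Latin hypercube; `steepest_descent_refine`, finite-difference
gradient with backtracking and a monotone r^2 trace).  Plain steepest
ascent, however, stalls near r^2 ≈ 0.99 on the curved ravines created by
couplings that share a circuit lever, so the production `calibrate()` uses
a correlation-maximizing Gauss-Newton method: each iteration linearizes
the firing vector (central differences, coarse-to-fine probe schedule) and
solves jointly for the coupling step and a free outcome scale, accepting
steps within a noise tolerance of the staircase floor and tracking the
best point; a final line search along the flattest curvature directions of
the normal matrix ("valley polish") resolves the near-degenerate
same-receptor coupling pairs.  An LHS screen provides a fallback start.

## 5. Synthetic-data experiments

The generator emulates the statistical structure of a retrospective trial
programme: 9 drugs (a selective-D2, olanzapine-like and clozapine-like
archetype, four single-channel probes that make each coupling identifiable,
and randomized sparse profiles), 4-5 concentration levels per drug spanning
30-85% naive D2 occupancy, 43 drug-dose points in all; outcomes are the
mechanistic model at a known coupling vector plus per-arm Gaussian noise
with sd `2 * sqrt(100/n)` PANSS points (arm sizes 50-400, 1-3 arms per
point), aggregated by patient-weighted averaging.

At these conditions the noise-free recovery experiment returns all ten
couplings within 10% (typically ≤ 6%) and r^2 ≈ 1 - 1e-5, decreasing
monotonically with outcome noise (≈ 0.995 at sd 2).  The residual 1e-5 is
a floor set by the integer spike-count readout: a single spike flip at one
point costs ~3e-7 in r^2 and the identifiability of the same-receptor
coupling pairs decays below that scale, so r^2 does not reach 1 to within
1e-6 in feasible time; extended polishing asymptotes near 1 - 4e-6.

What these experiments show: the calibration machinery is unbiased and
well-conditioned on data generated by its own mechanism.  What they do not
show: anything about real clinical data — there is no placebo-response
process, no between-trial heterogeneity, no scale nonlinearity, and drug
pharmacology is exactly known.  The linear occupancy-regression comparator
reaches r^2 ≈ 0.98 on the same noise-free data (strictly below the
mechanistic refit), mirroring — under far cleaner conditions — the
published gap between the mechanistic model and multivariate regression.

## 6. Numerical choices and degenerate inputs

* Synapse integration: dt = 1 ms, per-ligand exact exponential binding
  steps with Gauss-Seidel occupancy totals (stable when fast ligands
  equilibrate within a step); extrasynaptic NT capped at 1e9 nM in the
  fully disinhibited regime.
* Periodic steady state: damped Newton on the cycle-map drift restricted
  to dynamically active coordinates, FD step far above the slow-ligand
  drift (generic root finders mis-estimate that Jacobian); relaxation
  fallback.
* PET inversion: bisection on log-concentration, tolerance 0.025
  percentage points, error if the target is unreachable in bounds.
* Pyramidal threshold: 60-step bisection on the apical rate; error if the
  soma threshold is not bracketed.
* MSN spike detection: upward 0-mV crossings, 2 ms refractory; zero
  afferent drive yields zero spikes (the cell is not a pacemaker).
* Degenerate calibration inputs (constant outcomes or outputs) raise
  rather than return NaN.

## 7. Known limitations

* Absolute predictions are anchor-conditional: the retrospective clinical
  database behind the original calibration is unavailable, so couplings
  and link maps are fitted to the handful of published anchor values.
* The ocaperidone concentration scale disagrees with the published
  single-dose imaging study (Section 1); its absolute predictions (and the
  published occupancy-scenario values) are therefore not reproduced, though
  scenario monotonicity holds.
* Akathisia is outside the EPS model's scope; the threshold mechanism
  covers Parkinsonian-type liability only.
* Placebo response is not modelled; the placebo "prediction" is the
  drug-free circuit baseline mapped through the calibrated links.
* Rodent-derived affinities (ocaperidone/ND8295) are used as-is.
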