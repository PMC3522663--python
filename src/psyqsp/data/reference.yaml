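# Shipped reference configuration.
#
# The dopaminergic synapse parameters are a stored one-time fit anchoring the
# model to the published PET calibration pairs for the selective D2 antagonist
# (55% <-> 400 nM, 75% <-> 700 nM, 80% <-> 840 nM raclopride displacement);
# circuit couplings and link-map anchors reproduce the published reference
# firing/outcome pairs.  See docs/methods.md for the provenance of every
# number.

tracer:
  kd_nM: 1.5        # raclopride at D2
  conc_nM: 0.1      # trace dose

pathology:
  da_release_multiplier: 2.0   # hyperdopaminergic striatum (patients)
  dat_factor: 0.7              # 30% DAT density reduction
  d2_bp_factor: 0.7            # 30% D2 binding-potential reduction
  d3_autoreceptor_factor: 0.5  # lower D3 autoreceptor level, dorsal striatum
  cortical_drive_factor: 0.85  # hypofrontality: attenuated cortical afferents

synapses:
  # Striatal DA synapse of the (hyperdopaminergic) patient; carries the PET
  # tracer pool and the D1/D2 activation pools.  release_per_spike is the
  # healthy base value; the pathology multipliers above are already folded
  # into the ventral entry (release x2, clearance x0.7).
  DA_ventral:
    transmitter: DA
    tonic_rate: 3.0
    burst_rate: 60.0
    burst_schedule: [[9.0, 0.5]]
    period: 10.0
    release_per_spike: 936.3391188779896
    clearance_rate: 17.5
    clearance_km: 1278.2807422286435
    cleft_release_scale: 0.4591447923230837
    cleft_clearance_rate: 40.0
    autoreceptor_gain: 4.9400744338942175
    autoreceptor_half: 0.24562721871689097
    autoreceptor_width: 0.009777030742577594
    autoreceptor_kd: 29379.375058407208
    autoreceptor_receptor: D2
    primary_receptor: D2
    receptor_kd: {D2: 1600.0, D1: 1600.0, D3: 1600.0}
    cleft_receptor_kd: {D2: 100.0, D1: 100.0, D3: 100.0}
  # Dorsal (motor) striatum: no accumbens pathology (base release, full DAT),
  # lower D3 autoreceptor level -> halved feedback gain.
  DA_dorsal:
    transmitter: DA
    tonic_rate: 3.0
    burst_rate: 60.0
    burst_schedule: [[9.0, 0.5]]
    period: 10.0
    release_per_spike: 468.1695594389948
    clearance_rate: 25.0
    clearance_km: 1278.2807422286435
    cleft_release_scale: 0.4591447923230837
    cleft_clearance_rate: 40.0
    autoreceptor_gain: 2.4700372169471087
    autoreceptor_half: 0.24562721871689097
    autoreceptor_width: 0.009777030742577594
    autoreceptor_kd: 29379.375058407208
    autoreceptor_receptor: D2
    primary_receptor: D2
    receptor_kd: {D2: 1600.0, D1: 1600.0, D3: 1600.0}
    cleft_receptor_kd: {D2: 100.0, D1: 100.0, D3: 100.0}
  ACh:
    transmitter: ACh
    tonic_rate: 5.0              # tonically active interneurons
    burst_rate: 5.0
    burst_schedule: []
    period: 10.0
    release_per_spike: 786.5
    clearance_rate: 40.0
    autoreceptor_receptor: null
    primary_receptor: M1
    receptor_kd: {M1: 100.0, M2: 100.0}
    cleft_receptor_kd: {M1: 100.0, M2: 100.0}
  NE:
    transmitter: NE
    tonic_rate: 1.5              # locus coeruleus tone
    burst_rate: 1.5
    burst_schedule: []
    period: 10.0
    release_per_spike: 2779.6
    clearance_rate: 40.0
    autoreceptor_receptor: null
    primary_receptor: alpha1
    receptor_kd: {alpha1: 100.0, alpha2: 100.0}
    cleft_receptor_kd: {alpha1: 100.0, alpha2: 100.0}
  5-HT:
    transmitter: 5-HT
    tonic_rate: 1.5              # dorsal raphe tone
    burst_rate: 1.5
    burst_schedule: []
    period: 10.0
    release_per_spike: 2779.6
    clearance_rate: 40.0
    autoreceptor_receptor: null
    primary_receptor: 5-HT2A
    receptor_kd: {5-HT1A: 100.0, 5-HT2A: 100.0, 5-HT2C: 100.0, 5-HT3: 100.0, 5-HT6: 100.0}
    cleft_receptor_kd: {5-HT1A: 100.0, 5-HT2A: 100.0, 5-HT2C: 100.0, 5-HT3: 100.0, 5-HT6: 100.0}

# Receptor -> transmitter-system routing for activation computations.
receptor_systems:
  D1: DA
  D2: DA
  D3: DA
  M1: ACh
  M2: ACh
  alpha1: NE
  alpha2: NE
  5-HT1A: 5-HT
  5-HT2A: 5-HT
  5-HT2C: 5-HT
  5-HT3: 5-HT
  5-HT6: 5-HT

msn:
  cm: 1.0              # uF/cm^2
  g_na: 100.0          # mS/cm^2
  e_na: 50.0           # mV
  g_kdr: 80.0
  e_k: -90.0
  g_leak: 0.5
  e_leak: -67.0
  kir2_gmax: 1.2       # mS/cm^2
  kir2_vh: -111.0      # mV
  kir2_vc: -11.0       # mV
  tau_syn_ms: 3.0
  e_syn: 0.0
  syn_weight: 0.4785      # mS/cm^2 per afferent volley (placebo reference)
  afferent_rate: 200.0  # Hz, cortical volley rate before gating
  i_bg: 1.5            # uA/cm^2
  dt_ms: 0.2
  duration_s: 21.0
  spike_threshold_mv: 0.0
  refractory_ms: 2.0
  v0: -85.0
  hippocampal_gate: {period_s: 2.0, duty: 0.6, off_level: 0.25}
  amygdala_gate: {period_s: 3.7, duty: 0.5, off_level: 0.4}
  population_weights: {d1: 0.475, d2: 0.475, mixed: 0.05}

# The ten coupling parameters (accumbens / PANSS side), fitted to the
# published reference firing anchors.  Values multiply circuit quantities as
# factor = 1 + c * u(receptor), clipped at >= 0.05.
couplings_panss:
  d1_kir: -0.162467
  d1_syn: 0.0367559
  d2_gk: 0.340969
  d2_presyn: -0.0156304
  m1_leak: 0.660267
  m2_gk: 0.13574
  m2_presyn: -0.0107646
  a1_syn: 0.041986
  a1_bg: 0.0815065
  ht3_bg: -4.59959

couplings_motor:
  d1_kir: -0.00631187
  d1_syn: 0.0368462
  d2_gk: 0.348463
  d2_presyn: -0.0108707
  m1_leak: -0.368335
  m2_gk: 0.152131
  m2_presyn: -0.017145
  a1_syn: 0.0330329
  a1_bg: 0.0887447
  ht3_bg: -1.13872

coupling_bounds:
  d1_kir: [-2.0, 0.0]
  d1_syn: [0.0, 1.0]
  d2_gk: [0.0, 2.0]
  d2_presyn: [-1.0, 0.0]
  m1_leak: [-3.0, 3.0]
  m2_gk: [0.0, 2.0]
  m2_presyn: [-1.0, 0.0]
  a1_syn: [-0.5, 0.5]
  a1_bg: [-2.0, 2.0]
  ht3_bg: [-6.0, 0.0]

# Residual spreads of the reference calibration used for the shipped
# normal-theory 95% prediction intervals.
reference_intervals:
  panss_residual_sd: 3.0   # PANSS points
  eps_residual_sd: 0.04    # fraction

pyramidal:
  n_compartments: 12
  apical_compartments: [8, 9, 10, 11]
  g_leak: 0.05         # mS/cm^2 per compartment
  e_leak: -70.0        # mV
  g_axial: 2.0         # mS/cm^2 between neighbours
  e_syn: 0.0
  tau_syn_ms: 5.0
  syn_weight: 0.02     # mS/cm^2 per input spike (x rate x tau = conductance)
  soma_threshold_mv: -55.0
  ht2a_gain: -0.283253 # apical synaptic gain coupling to 5-HT2A activation
  ht1a_gain: -0.3      # leak coupling to 5-HT1A activation
  placebo_threshold_factor: 0.70   # calibration anchor (drug-free)

# Published reference anchors used to fit the outcome link maps.
panss_anchors:
  firing: [199, 245, 286, 297]
  panss: [1.7, 13.4, 24.0, 27.0]

eps_anchors:
  threshold: {placebo: 0.70, olanzapine_10mg: 0.62}
  fraction: {placebo: 0.16, olanzapine_15mg: 0.23}

# Reference drug arms: PET raclopride displacement per dose.
reference_arms:
  - {drug: JNJ37822681, dose_mg: 10, displacement_pct: 55.0}
  - {drug: JNJ37822681, dose_mg: 20, displacement_pct: 75.0}
  - {drug: JNJ37822681, dose_mg: 30, displacement_pct: 80.0}
  - {drug: olanzapine, dose_mg: 10, displacement_pct: 71.0}
  - {drug: olanzapine, dose_mg: 15, displacement_pct: 75.0}
  - {drug: risperidone, dose_mg: 4, displacement_pct: 74.0}
  - {drug: clozapine, dose_mg: 210, displacement_pct: 47.0}
  - {drug: clozapine, dose_mg: 250, displacement_pct: 50.0}
  - {drug: ocaperidone, dose_mg: 0.52, displacement_pct: 69.0}

mixtures:
  ocaperidone-moiety:
    - [ocaperidone, 0.75]
    - [ND8295, 0.25]
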