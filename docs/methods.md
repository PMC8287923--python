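# Methods

## The model

`pensense.circuit` integrates a deterministic kinetic model of a
PEN-toolbox bistable switch with transcription-factor-gated input
modules.  State variables (all deterministic ODEs, solved with LSODA at
rtol 1e-8 / atol 1e-10 and sampled on a 1-minute grid):

| species | meaning | units |
|---|---|---|
| `signal` | free signal strand (B11) | nM |
| `antisignal` | free complementary strand (aB11) | nM |
| `deactivated` | poly-T-tailed signal awaiting degradation | nM |
| `rt_dark` / `rt_lit` | unreported / reported reporter template | nM |
| ligand pools | one per declared ligand | µM (serine: mM) |

Template-mediated fluxes use a saturable Michaelis form
`k · T · s/(Km + s)`:

- **aT (autocatalysis)**: each extension/nick cycle nets one new signal
  strand, `v_amp = k_amp · aT · s/(km_amp + s)` — exponential growth with
  capacity `k_amp · aT`.
- **pT (threshold sink)**: deactivation
  `v_deact = k_deact · pT · s/(km_deact + s)`.  `km_deact ≪ km_amp`, so
  the sink outruns amplification at trace signal levels but saturates at
  a small capacity — this is what creates the concentration threshold and
  the OFF/ON bistability.  The constraint
  `k_deact/km_deact > k_amp/km_amp` is validated at construction.
- **rT (reporter)**: the signal is captured and extended on the hairpin,
  irreversibly converting `rt_dark → rt_lit`; `rt_lit` is the
  fluorescence observable, hence noise-free traces are non-decreasing and
  `rt_dark + rt_lit` is conserved.
- **sT / psT / pskT (sources)**: constitutive output at
  `k_source · (free template)`.  psT emits signal, pskT emits antisignal;
  signal and antisignal annihilate pairwise at `k_hyb · s · a`.
- **exonuclease**: first-order decay `k_degr` of free signal and
  antisignal strands.

### Transcription-factor layer

TF–operator binding is treated as quasi-equilibrium: binding and
unbinding are fast compared to the hour-scale switch dynamics, so the
occluded fraction of each sensing template is recomputed from the
instantaneous ligand concentration at every right-hand-side evaluation,
using the exact two-species binding quadratic (`template_occupancy`).
Each template equilibrates against the total TF dimer pool
independently; TF is in 10–100-fold excess over template in every
bundled assembly, so neglecting template–template competition for TF is
a sub-10% effect.

The allosteric response is an effective-affinity Hill scheme, not a full
MWC treatment:

- **corepressor** (TrpR-like): active TF = `TF_tot · Lʰ/(K_Lʰ + Lʰ)`;
  without ligand the TF cannot bind its operator at all.  Default
  `h = 2` for TrpR (two tryptophan sites per dimer).
- **inducer** (LacI-like): the TF is fully competent without ligand;
  ligand binding scales the operator Kd up by as much as
  `induction_fold` (default 1e4, i.e. four orders of magnitude) with a
  residual competence `1/induction_fold` at saturation.

### Enzyme layer

A ligand-producing enzyme (tryptophan-synthase-B-like) adds
`v = kcat · E · S₁/(Km₁+S₁) · S₂/(Km₂+S₂)` to its product ligand while
depleting both substrates (indole in µM, L-serine in mM).  Because the
product feeds the corepressor dynamically during integration, enzymatic
activity is read out as the switching time of the inverted TrpR circuit.
Enzyme concentrations above 10 µM flag the trace set with a
"non-specific disruption regime" warning rather than attempting to model
the disruption itself.  The substrate Km defaults (300 µM indole, 1 mM
serine) are order-of-magnitude placeholders, not measured values.

## Rate calibration

No kinetic rate constants are published for this family of circuits, so
`RateParameters` carries one frozen, documented calibration (time in
minutes, DNA in nM):

| parameter | default | role |
|---|---|---|
| `k_amp`, `km_amp` | 0.04 /min, 20 nM | autocatalysis on aT |
| `k_deact`, `km_deact` | 1.4e-5 /min, 2.7e-4 nM | pT sink (high affinity, minute capacity) |
| `k_report`, `km_report` | 0.1 /min, 50 nM | reporter capture |
| `k_source` | 0.004 /min | output per free source template |
| `k_degr` | 0.01 /min | exonuclease decay |
| `k_hyb` | 5 /nM/min | signal–antisignal annihilation |

The calibration was chosen once so that (i) the unrepressed 5 nM psT
assembly fires at Cq ≈ 67 min (inside the observed 60–120 min window),
(ii) the critical source flux that just saturates the 7 nM pT sink
corresponds to ≈ 8 pM of source template — the "minimally saturating"
sT concentration used with killer-template circuits — and (iii) the
bare aT/pT/rT switch is bistable in the initial signal concentration,
with a firing threshold near 1 pM located by bisection
(`switch_threshold`).  The effective pT Michaelis constant is far below
physical strand-binding scales; it is a lumped parameter standing in
for the real multi-step sequestration kinetics, and only the
slope/capacity pair it encodes is meaningful.

Operator affinities in the bundled fixtures are 0.04 nM (LacI) and
0.02 nM (TrpR), inside the 1 pM–100 nM span reported for natural
operators.  With the tightest (~1 pM) affinity, 110 nM of TF would
occlude the templates so completely that no ligand concentration below
1 mM could wake the circuit; the chosen values put all four
direct/inverted architectures' transitions inside the experimentally
used 0–1000 µM input span.  Ligand constants are the reported ones:
IPTG–LacI 23 µM, L-trp–TrpR 20 µM.

## The Cq statistic

`extract_cq` reproduces the trace-analysis workflow exactly: affine
normalization to [0, 1]; forward differences between points 10 minutes
apart (start points in the final 10 minutes excluded); Cq is the
earliest start time of the maximal difference (ties broken to the
earliest point, with a 1e-12 tolerance so exact ties survive float
rounding).  Flat-trace calling was a manual step in the original
workflow; here it is an explicit rule: a trace is flat when its raw
dynamic range is below 5% of the instrument full scale (total rT for
simulated data, carried on the `TraceSet`) **or** the maximal normalized
10-minute difference is below `flat_threshold` (default 0.05).  Flat
traces get 1/Cq = 0.  Non-uniform time grids are rejected rather than
resampled, keeping the statistic bit-stable.

## Dose–response and Hill fits

`assemble` averages replicate 1/Cq per concentration; the error bar is
the largest absolute single-replicate deviation across the whole
replicate set, applied uniformly to every point (the
maximum-single-point rule used for the original triplicates).  Flat
replicates enter the mean as 0.

`fit_hill` fits all four parameters (baseline, amplitude, Kd, n) by
unweighted least squares in linear concentration space (zero
concentrations are retained; logs are for plotting only).  Direction is
inferred from the Spearman sign unless supplied.  Because
high-cooperativity fits have narrow basins, the optimizer multi-starts
over n ∈ {1, 2, 8} × Kd ∈ {gm/3, gm, 3·gm} (gm = geometric mean of the
positive concentrations) and keeps the best converged solution;
noise-free model-generated curves are recovered to ≈ machine precision,
including n = 10.5 at Kd 69 or 500 µM.  Whether the original fits
floated baseline and amplitude is not recorded; this implementation
floats all four and documents it here.

## Classifier maps

`simulate_grid` evaluates 1/Cq over a 2-D log-spaced concentration grid
(defaults 6×6) and `fit_logsum` fits the plane
`1/Cq ≈ w₀ + wₓ log cₓ + w_y log c_y` over the non-flat cells only —
1/Cq = 0 is censoring, not a response level.  The expected weight sign
per axis is the product of template logic (psT +, pskT −) and TF mode
(inducer +, corepressor −); the four bundled two-input assemblies
realize the four sign patterns.  The default axes in the tests span
1–1000 µM for IPTG and 0.3–30 µM for L-trp, each straddling its
sensor's dynamic range under this calibration.

## Synthetic data: what it does and does not emulate

The simulator reproduces the phenomenology the analysis depends on:
sigmoidal switch activation whose timing shifts monotonically with
ligand input, flat traces for fully repressed circuits, direct/inverted
response polarity, titration-sharpened (ultrasensitive) inverted
responses, enzyme-activity-ordered switching and seeded multiplicative
measurement noise (`add_noise`, 2% default) plus optional linear drift.
`synthetic_switch_trace` additionally provides idealized logistic traces
with a prescribed Cq for estimator calibration independent of the
mechanistic model.

It deliberately does **not** model: template-independent (parasitic)
amplification, which the experimental analysis excludes; the
non-specific dsDNA dye channel; sequence-level thermodynamics (melting
temperatures, nicking-site placement); compartmentalization; or the
mechanism of high-enzyme disruption (flagged, not simulated).  Passing
tests therefore certify the analysis pipeline and the model's
qualitative mechanism, not quantitative agreement with any particular
wet-lab trace; simulated apparent Kd values depend on the rate
calibration and are only order-of-magnitude comparable to measured
ones, which is why estimator-accuracy checks use model-generated
curves rather than simulator output.

## Numerical choices and problem sizes

Integration failures raise with the condition's ligand inputs in the
message.  Grid and dose-response tests run noise-free (deterministic);
noisy-recovery checks use 50 seeds × 8 concentrations × 3 replicates at
2% multiplicative noise per Kd, sizes chosen to keep the full suite
under a minute on one CPU while leaving the median-error statistics
stable.  All randomness flows through explicit seeds
(`numpy.random.SeedSequence` spawning per-replicate streams), and the
pipeline manifests pin config hash, seed and stage parameters so reruns
are byte-identical (manifest timestamps are fixed rather than
wall-clock for that reason).

## Known limitations

- The rate calibration is a single self-consistent point, not a fit to
  data; absolute times and apparent Kd values from the simulator are
  illustrative.
- Quasi-equilibrium TF binding ignores binding/unbinding kinetics;
  circuits whose response hinges on slow TF exchange would need a
  dynamic binding layer.
- One shared `k_source` for sT, psT and pskT: whether self-priming
  turnover differs between them is unknown; the shared value is the
  simplest defensible choice.
- Enzyme substrate Km defaults are placeholders (flagged above).
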