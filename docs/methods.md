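# Methods

## ICcl input model

ICcl neurons are modelled as deterministic rate units, normalized to [0, 1]:

    r_i(ITD) = (exp(b_i cos(2π bf_i (ITD − ITD_i))) − exp(−b_i)) / (exp(b_i) − exp(−b_i))

with best frequency `bf_i` in kHz, best ITD `ITD_i` in µs (converted to ms
internally so `bf·ITD` is in cycles), and concentration parameter `b_i > 0`.
`b_i` is the smaller root of the quadratic
`2.8 b² − 17 b + (24.12 − 2.44 bf) = 0`, which reproduces the measured
dependence of ICcl half-width on best frequency: `b` falls from ≈ 2.1 at
0.5 kHz to ≈ 0 near 10 kHz, so low-frequency neurons have ITD curves much
narrower than a raised cosine and high-frequency neurons approach one. The
root becomes slightly negative for bf ≳ 9.9 kHz; it is clamped at
ε = 0.01, where the tuning degenerates gracefully to the raised-cosine
limit `(1 + cos)/2`. The four quadratic coefficients are exposed in
`QuadraticCoefficients`.

The default population is a grid of best frequencies 0.5–10 kHz in 0.1-kHz
steps with a single best-ITD column at 0 µs — the two-layer analyses
concern neurons whose inputs share a preferred ITD; a full
(bf × best-ITD) grid is supported but not used by the shipped analyses.
Tone responses multiply the ITD curve by a Gaussian frequency-tuning
factor (width 0.5 kHz by default) and a level factor in [0, 1]; ICcl ITD
tuning is treated as identical for tones and noise. Rates are
deterministic at this layer; stochasticity enters in the synthetic
recordings and the compartmental input trains.

## Two-layer ICx model

An ICx neuron has N = 10 dendritic subunits. Subunit j applies a static
nonlinearity to a Gaussian-weighted sum of ICcl rates,
`d_j = g(Σ_i w_ij r_i)` with `w_ij = exp(−((bf_i − cf_j)/σ)²/2)`; the soma
sums the subunit outputs, `V = Σ_j d_j`, and a spiking nonlinearity maps V
to a firing rate. Weights are deliberately unnormalized: broader σ
integrates more total input, and that drive-scale difference is what lets
one fixed sigmoid behave expansively at narrow bandwidth and suppressively
at broad bandwidth.

Subunit nonlinearities: identity; power law `x^p` (suppressive for p < 1,
expansive for p > 1); offset logistic `s3 + s0/(1 + exp(−s1(x − s2)))`.
Spiking nonlinearities: rectified-linear `max(0, a0 + a1 V)`, and a
thresholded sigmoid that is 0 below a hard threshold α and
`c0/(1 + exp(−c1(V − c2)))` above it. The sigmoid denominators are
logistic (`1 + e^{−·}`); a `1 − e^{−·}` form would diverge at the midpoint.

### Parameter-space maps

The feasibility map sweeps σ ∈ {0.1, …, 4.0} kHz (step 0.1), 25
log-spaced exponents p ∈ [0.1, 10], and subunit center-frequency spreads
{0, 1.25, 2.5} kHz with the 10 cfs equally spaced and centered at 5 kHz
(measured ICx neurons with frontal preferred ITDs prefer high
frequencies). Each cell's PSP ITD curve is evaluated on −250…250 µs in
5-µs steps (fine enough that interpolated half-width error is < 2 µs),
and SPS/HW are z-scored against the in vivo statistics (SPS
23.18 ± 12.27 %, HW 75.17 ± 17.12 µs). Per-subunit drives are rescaled by
their joint maximum before exponentiation — a pure output scaling that the
affine-invariant metrics ignore but that avoids overflow at p = 10.
Because drive scale cancels for power-law subunits, the z-maps are robust
to ICcl grid density (verified by a halved-density test); absolute drive
values are implementation-relative, so exact feasibility-boundary
positions depend mildly on discretization choices.

The fixed-sigmoid search exploits the same affine invariance: only the
logistic slope and midpoint shape the ITD curve, so the search is a
deterministic two-dimensional coarse grid (13 × 13, slope log-spaced
relative to the maximum drive, midpoint linear in it) with two geometric
refinement rounds around the incumbent; ties break lexicographically. A
candidate whose curve has undefined SPS or HW at any σ is scored infeasible
rather than perfect. The shipped objective is evaluated at
σ ∈ {0.5, 1.0, …, 4.0} kHz with CF spread zero.

## Tuning-curve metrics

The main peak is the global maximum, ties broken toward 0 µs (the recorded
sample prefers frontal ITDs). HW is the width at half height, with height
`max − min` over the −250…250 µs window and crossings located by linear
interpolation; an uncrossed side raises an error naming the side. SPS is
`100 (R_main − R_side)/(R_main − R_min)` with `R_side` the largest strict
interior local maximum other than the main peak (equally tall periodic
peaks therefore give SPS = 0, side peaks at baseline give 100). The
published definition of SPS lives in earlier work and may normalize by
`R_main` alone; that variant is available via `normalize_by_range=False`,
and z-score-based conclusions are insensitive to the choice in the regimes
explored here. Curves with no secondary local maximum in the window
produce a missing value (`SidePeakMissing`) rather than 100 %, so flat
saturated curves cannot masquerade as perfectly suppressed. Optional
3-point smoothing before peak detection is off by default.

## Fitting and model selection

Five model forms are fit by MSE minimization (see README for the forms).
Fitting is deterministic and organized so every linear-in-parameters block
is solved exactly:

- linear/quadratic: ordinary least squares;
- rectified-linear: every threshold interval between sorted x values
  defines a candidate active set, fit by least squares and scored with the
  rectification applied; the best candidate is polished by Nelder–Mead;
- thresholded sigmoid: the hard threshold α is scanned over the same
  interval midpoints; for each α a (slope × midpoint) grid is profiled
  with the exact least-squares amplitude; the incumbent is polished over
  (c0, log c1, c2) at fixed α;
- linear-plus-sigmoid: variable projection — (b0, b1, b2) solved exactly
  on a (b3, b4) grid (slopes log-spaced relative to the x span, midpoints
  at x quantiles), then a Nelder–Mead polish over (log b3, b4) with the
  profiled 3×3 normal equations.

Logistic slopes are bounded so the transition width stays between
~span/12 and ~8·span: below the lower bound the sigmoid column is
numerically collinear with {1, x} (amplitudes diverge), above it the term
degenerates into a step that chases individual residuals. Both
degeneracies were observed to let the 5-parameter model spuriously
dominate genuinely linear data. Positivity of slopes is enforced by log
parameterization; ties between candidates break lexicographically on the
parameter vector, so refits (including every LOOCV refit) are
bit-reproducible.

Adjusted R² is `1 − (RSS/(n−p−1))/(TSS/(n−1))`; LOOCV MSE refits the model
n times with the identical protocol. A winner is declared only when one
candidate strictly dominates on both metrics; otherwise the comparison is
"inconclusive". Fits are flagged (not excluded automatically) when fewer
than 8 distinct x bins have nonzero response or the best adjusted R² falls
below 0.2 — the analogue of excluding neurons with non-significant fits;
both thresholds are arguments.

The class-recovery study draws n = 30 points per replicate on a lightly
jittered regular grid over [0, 10] (emulating designed stimulus spacing),
adds Gaussian noise with SD 10 % of the clean range, and classifies 200
replicates per generating archetype (line; saturating concave parabola;
double-plateau sigmoid with a shallow linear trend). With the strict
double criterion and nested candidates, a flexible competitor dominates
truly linear data by chance in roughly a quarter of conclusive replicates
— a scale-free property of the selection rule, not of the noise level —
so accuracy is reported per class (≈ 0.75 / 0.83 / 1.00) and pooled
(≈ 0.88). The same behavior appears in the end-to-end synthetic
experiments, where the linear ground truth is the modal but not unanimous
winner across seeds.

## Synthetic intracellular recordings

Each trial is `baseline + gain·(V_true − offset) + OU noise` during the
100-ms stimulus and baseline outside it, sampled at 0.05 ms.
Ornstein–Uhlenbeck noise (τ = 5 ms, SD 1 mV by default; 0.5 mV in the
recovery studies) is generated by exact discretization and gives membrane
noise realistic autocorrelation without biophysical machinery. The gain
maps the dimensionless two-layer potential onto a 12-mV PSP range so that
spiking parameters can be stated in absolute mV against a −60 mV baseline.

Spikes are drawn per time bin with hazard `h = R/(1 − R·τ_r)` where
`R = f(V_inst)/T` is the instantaneous target rate, T = 100 ms the window
and τ_r = 2 ms the refractory period; the dead-time correction makes the
expected spike count per stimulus equal f(V) despite refractoriness, which
is what allows count-based parameter recovery to be unbiased. Each spike
adds a stereotyped 2-ms biphasic waveform (+40 mV peak, −6 mV
afterhyperpolarization) whose lobes are rank-balanced so the windowed
median is nearly unaffected by firing rate (residual bias ≈ −0.015 mV per
spike). Responses are summarized by the median potential over the 50 ms
starting 10 ms after onset, averaged over 5 trials.

Tone-combination components carry level 1/m for m components (matched
overall level), so V_stack < V_add at the main peak for every ground
truth; `V_add = Σ_k (V_k − v_min)` uses the experiment-wide minimum
trial-averaged PSP as reference (a per-stimulus reference is available via
the same function). The experimental design is two tones (4 and 6 kHz)
plus their stack at 17 ITDs (−240…240 µs in 30-µs steps), giving 51
stimuli for the subthreshold-to-spiking scatter.

What the generator does *not* emulate: ILD-pathway stimuli (in vivo
spiking-nonlinearity fits pooled ITD, ILD and frequency stimuli), sound
onset/offset dynamics, electrode artifacts, slow drift, and across-trial
adaptation. Passing recovery tests on this data therefore shows the
pipeline is correct and well-calibrated for stationary membrane noise with
realistic autocorrelation — not that real recordings meet those
assumptions.

## Compartmental model

Geometry: cylindrical soma (20 × 20 µm), four cylindrical dendrites
(5 × 150 µm, 5 compartments each) and, when synapses sit on spines, one
cylindrical spine per synapse (0.2 × 15 µm mean, ±10 % per-spine jitter).
All dimensions are validated against the anatomical ranges (soma 10–30 µm,
dendrites 4–20 × 50–300 µm, spines 0.1–0.4 × 2–80 µm), and extreme spine
shapes (thinnest-longest, thickest-shortest) are rejected. The membrane is
passive; `g_pas` is the total leak per named section in µS (0.0001–0.01),
spread uniformly over its compartments, with a specific-conductance
(S/cm²) mode available. Unprinted constants are package defaults, all
configurable: e_pas = −65 mV, e_syn = 0 mV (both receptors),
[Mg] = 1 mM, axial resistivity 150 Ω·cm, C_m = 1 µF/cm².

Synapses: AMPA is a single-exponential conductance (τ = 4.5 ms, additive
superposition). NMDA uses a two-state ligand-binding scheme — during a
1-ms transmitter pulse after each spike the bound fraction relaxes toward
`R_inf = cα/(α+β)` with time constant `1/(α+β)`; otherwise it decays at
rate β — gated by the magnesium block `1/(1 + exp(−0.062V)[Mg]/3.57)`;
α = 0.35 /ms, β = 0.015 /ms, c = 1. Input spike trains are homogeneous
Poisson with rate
`w1·itd_fac(b(f1), ITD)·gauss(f_pref − f1) + w2·(…f2…) + 1/int_max`
(int_max = 100 ms). The default weights w = 0.15 events/ms put the peak
inter-event interval at ≈ 6 ms, inside the intended 3–20 ms band. The
three rate components are drawn as independent Poisson trains with seeds
fixed by (seed, trial, synapse, component), so the tone-combination
condition is the exact superposition of the single-tone trains — which
makes the small-signal linearity limit hold trial by trial (the only
residual is the once-vs-twice-counted floor component, ≈ 2–3 %).

Integration: backward Euler at dt = 0.025 ms with synaptic and Mg-block
conductances evaluated at the previous step's voltage; the branched linear
system is solved per step by Hines elimination in a numba kernel.
Compartments are indexed so every parent precedes its children, making
elimination a reverse index sweep. Validation: resting equilibrium is
exact; steady-state input resistance of a soma+dendrite reduction matches
the sealed-end finite-cable closed form within 2 % (< 0.1 % at 41
segments); halving dt changes the soma trace by ≈ 0.01 mV RMS; weak-input
peak responses scale with synaptic weight within 2 % over a decade.

The tone-combination experiment runs 21 ITDs (−250…250 µs, 25-µs steps,
spanning a full period of the 4-kHz channel), three conditions, six trials
at ~1 ms of compute per 120-ms simulation. The three reference
configurations express the three integration classes through their
saturation level: AMPA on dendrites with high leak (w = 2·10⁻⁴ µS,
g_pas = 0.01) keeps deflections small and linear; AMPA on spines
(w = 2·10⁻³, g_pas = 0.001) saturates the upper end (quadratic); NMDA on
spines (w = 1.8·10⁻², g_pas = 0.001) adds the Mg-block lower plateau
(sigmoidal). Synaptic weights were calibrated once to place each
configuration inside its regime. At the shipped seed all three classify
as stated; across seeds the sigmoidal configuration is stable while the
linear and quadratic ones are modal-correct with occasional inconclusive
outcomes — the strict double-dominance rule applied to 21-point scatters,
as in the recovery study. Clustered versus interleaved placement of the
two frequency channels changes neither the class nor the stack curve
(< 1 mV RMS).

## Problem sizes and runtime

The shipped analyses use the full 3 000-cell subunit map (seconds), the
13×13+refinement sigmoid search (sub-second), 200 recovery replicates per
class (~2 min), 8–20-seed synthetic-recording studies (~1 min), and
three compartmental experiments at 21 ITDs × 3 conditions × 6 trials
(~10 s total). These sizes were chosen so the complete test suite and all
analysis drivers run comfortably on a single CPU.

## Known limitations

- Absolute drive scales in the two-layer model depend on the ICcl grid
  density; only affine-invariant conclusions (SPS/HW z-scores) are
  reported.
- The strict double-criterion selection has an irreducible chance of
  preferring a flexible nested competitor on truly linear data (~25 % of
  conclusive cases); treat single-dataset class labels accordingly.
- The spiking-nonlinearity threshold α is identifiable only up to the gap
  between the largest silent and smallest active stimulus.
- The compartmental model is subthreshold only (no spike-generating
  conductances), uses single-cylinder spines, and does not import
  reconstructed morphologies.
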