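# icxfreq — frequency integration and ITD tuning in barn-owl ICx neurons

Space-specific neurons in the external nucleus of the inferior colliculus
(ICx) of the barn owl compute sound direction from interaural time
difference (ITD). Their inputs, from the lateral shell of the central
nucleus (ICcl), are narrowly frequency tuned and therefore spatially
ambiguous: each ICcl ITD curve is periodic, with side peaks at multiples of
its best frequency's period. ICx resolves this ambiguity by integrating
across frequency, which suppresses side peaks (quantified as side-peak
suppression, SPS) and narrows the main peak (half-width, HW).

`icxfreq` is an analysis package for asking *how* that integration works at
the subthreshold level. It implements:

- **`icxfreq.iccl`** — the ICcl input population. Normalized rates follow

  `r_i(ITD) = (exp(b_i cos(2π bf_i (ITD − ITD_i))) − e^{−b_i}) / (e^{b_i} − e^{−b_i})`

  with the concentration parameter `b_i` tied to best frequency through a
  quadratic calibrated on measured ICcl half-widths.
- **`icxfreq.twolayer`** — the two-layer (dendritic-subunit) ICx model:
  subunit outputs `d_j = g(Σ_i w_ij r_i)` with Gaussian weights
  `w_ij = exp(−((bf_i − cf_j)/σ)²/2)`, somatic sum `V = Σ_j d_j`, and a
  spiking nonlinearity `f(V)` (rectified-linear or thresholded sigmoid).
  Includes the (σ × power × CF-spread) feasibility map and the search for a
  single fixed sigmoidal subunit nonlinearity.
- **`icxfreq.metrics`** — HW and SPS of ITD tuning curves and z-scores
  against the in vivo population statistics (SPS 23.18 ± 12.27 %,
  HW 75.17 ± 17.12 µs, n = 75 neurons).
- **`icxfreq.fitting`** — MSE fitting of candidate nonlinearities (linear,
  quadratic, rectified-linear, thresholded sigmoid, linear-plus-sigmoid)
  with model selection by the double criterion: a winner must have the
  largest adjusted R² **and** the smallest leave-one-out cross-validation
  MSE.
- **`icxfreq.recordings`** — a generator of synthetic intracellular
  recordings (100-ms tones and tone combinations at matched level, ITD in
  30-µs steps, 3–5 trials, OU membrane noise, stereotyped spikes) from a
  known two-layer ground truth, including the V_add/V_stack construction
  (tone-response sum vs combination response, both referenced to the
  experiment-wide minimum potential).
- **`icxfreq.compartmental`** — a passive multicompartment ICx neuron
  (soma, dendrites, cylindrical spines; AMPA and Mg-blocked NMDA synapses;
  Poisson inputs) with a built-in backward-Euler/Hines cable solver, and
  the tone-combination experiment that classifies dendritic integration as
  linear, quadratic or sigmoidal.

## Worked example

The analysis is organized as numbered drivers under `analysis/`, each a
thin script over the library that writes its tables to `results/`:

```sh
python analysis/01_subunit_map.py
python analysis/02_sigmoid_feasibility.py
python analysis/03_synthetic_recovery.py
python analysis/04_compartmental.py
```

`01_subunit_map.py` sweeps power-law subunits and prints

```
min SPS z-score over the map : -1.877 (never < -2)
broad+expansive corner (sigma=4, p=10, spread 0): SPS z = +6.26, HW z = -3.00
```

i.e. suppressive subunits can only push SPS toward zero (z bottoms out at
−1.9, inside the −2 bound), while expansive subunits combined with broad
frequency integration (σ = 4 kHz, p = 10) overshoot the +2 SPS bound and
produce over-narrow curves — that corner of parameter space is incompatible
with the recorded population.

`02_sigmoid_feasibility.py` then shows one fixed sigmoidal subunit
nonlinearity works at every bandwidth:

```
selected sigmoid: slope s1 = 0.0844, midpoint s2 = 3.28
max |z| over SPS and HW across sigma 0.5-4 kHz: 1.511 (<= 2)
```

`04_compartmental.py` reproduces the three mechanistic regimes on the
passive compartmental model:

```
linear    : classified linear        (expected linear);    V_add max  3.2 mV
quadratic : classified quadratic     (expected quadratic); V_add max 29.9 mV
sigmoidal : classified stack_sigmoid (expected sigmoidal); V_add max 65.3 mV
```

AMPA synapses on 5-µm dendrites combine linearly; moving the same input to
thin spines saturates the combination (quadratic); NMDA synapses on spines
add a magnesium-block plateau at weak drive (sigmoidal). Channel strengths
are matched at the main ITD peak and mismatched on side peaks (mismatched
fraction 0.2–0.4 vs 0.8 in the printed summary), which is where the
nonlinear combination appears.

`03_synthetic_recovery.py` validates the fitting pipeline on data with
known ground truth: pooled classification accuracy among conclusive
selections is 0.879 (428/487 at 200 replicates per class, 10 % noise), and
spiking-nonlinearity parameters are recovered from synthetic recordings at
0.5 mV noise with mean relative error 3.6 % (rectified-linear) and 7.5 %
(sigmoid).

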