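"""Synthetic in vivo-like intracellular recordings from a known ground truth.

The in vivo experiments this generator emulates presented 100-ms tones and
tone combinations at matched overall level while varying ITD in 30-us
steps, recorded membrane potential with sharp electrodes over 3-5 trials
per stimulus, and summarized each response by the median membrane potential
over the 50 ms starting 10 ms after sound onset (the median limits the
influence of action potentials).

Here the "neuron" is a two-layer model with known subunit and spiking
nonlinearities.  Each trial is baseline plus the deterministic model PSP,
plus Ornstein-Uhlenbeck membrane noise (tau = 5 ms), plus stereotyped spike
waveforms at inhomogeneous-Poisson times whose hazard is set so that the
expected spike count per stimulus equals the spiking nonlinearity's value
despite the 2-ms refractory dead time.  Everything is reproducible from a
single integer seed.

Tone-combination components carry level 1/m for m components (matched
overall stimulus level), which makes frequency integration sublinear
(V_stack < V_add) for every ground truth, as observed in vivo.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .iccl import ICclPopulation, build_population
from .metrics import ITDTuningCurve
from .fitting import ScatterData
from .twolayer import (
    LinearNL,
    PowerNL,
    SigmoidNL,
    SpikingNL,
    SubunitSpec,
    TwoLayerNeuron,
    spike_rate,
)

__all__ = [
    "StimulusSpec",
    "RecordingTrial",
    "RecordingSet",
    "ExperimentConfig",
    "ExperimentResult",
    "generate_trial",
    "median_psp",
    "trial_average",
    "v_add",
    "build_experiment",
    "DEFAULT_EXPERIMENT_ITDS",
]

#: Experimental ITD grid: 30-us steps covering the +/-250-us range.
DEFAULT_EXPERIMENT_ITDS = np.arange(-240.0, 240.0 + 1e-9, 30.0)

SAMPLING_INTERVAL_MS = 0.05
SPIKE_PEAK_MV = 40.0
SPIKE_DURATION_MS = 2.0
REFRACTORY_MS = 2.0
OU_TAU_MS = 5.0


@dataclass(frozen=True)
class StimulusSpec:
    """One auditory stimulus: a tone, a tone stack, or broadband noise."""

    kind: str  # tone | tone_stack | broadband
    freqs: tuple[float, ...]
    itd: float
    duration: float = 100.0
    level_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("tone", "tone_stack", "broadband"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.kind == "tone" and len(self.freqs) != 1:
            raise ValueError("tone stimuli need exactly one frequency")
        if self.kind == "tone_stack" and not 2 <= len(self.freqs) <= 3:
            raise ValueError("tone stacks need 2-3 frequencies")
        if len(set(self.freqs)) != len(self.freqs):
            raise ValueError("stack frequencies must be distinct")
        if not self.duration > 60.0:
            raise ValueError("duration must exceed the 60-ms analysis window")

    @property
    def key(self) -> tuple:
        return (self.kind, self.freqs, self.itd)


@dataclass(frozen=True)
class RecordingTrial:
    """One membrane-potential trace with detected spike times."""

    t: np.ndarray
    v: np.ndarray
    spike_times: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.v)):
            raise ValueError("membrane potential must be finite")


@dataclass
class RecordingSet:
    """Trials grouped by stimulus, with the generating ground truth."""

    stimuli: list[StimulusSpec]
    trials: dict[tuple, list[RecordingTrial]]
    ground_truth: TwoLayerNeuron

    def __post_init__(self) -> None:
        for stim in self.stimuli:
            k = len(self.trials.get(stim.key, []))
            if not 3 <= k <= 5:
                raise ValueError(f"stimulus {stim.key} has {k} trials; need 3-5")


def _true_rates(
    pop: ICclPopulation, stim: StimulusSpec, freq_tuning_width: float
) -> np.ndarray:
    """Deterministic ICcl rate vector for one stimulus."""
    itd = np.array([stim.itd])
    if stim.kind == "broadband":
        return stim.level_scale * pop.rates(itd)[0]
    m = len(stim.freqs)
    scale = stim.level_scale / m if stim.kind == "tone_stack" else stim.level_scale
    r = np.zeros(len(pop))
    for f in stim.freqs:
        r += pop.tone_rates(f, itd, scale, freq_tuning_width)[0]
    return r


def _true_psp(
    neuron: TwoLayerNeuron,
    pop: ICclPopulation,
    stim: StimulusSpec,
    freq_tuning_width: float,
) -> float:
    rates = _true_rates(pop, stim, freq_tuning_width)
    v = 0.0
    for sub in neuron.subunits:
        w = np.exp(-0.5 * ((pop.bf - sub.cf) / sub.sigma) ** 2)
        v += float(np.asarray(sub.nonlinearity(float(rates @ w))))
    return v


def _spike_waveform(dt: float) -> np.ndarray:
    """Stereotyped biphasic spike: sharp depolarization then a longer,
    shallower afterhyperpolarization.

    The lobes are balanced so a spike displaces roughly as many samples
    above the running median as below it, keeping the windowed median
    nearly unbiased by firing rate.
    """
    t = np.arange(0.0, SPIKE_DURATION_MS, dt)
    rise = np.exp(-((t - 0.3) ** 2) / (2 * 0.12**2))
    under = -0.15 * np.exp(-((t - 1.25) ** 2) / (2 * 0.45**2))
    return SPIKE_PEAK_MV * (rise + under)


def generate_trial(
    neuron: TwoLayerNeuron,
    pop: ICclPopulation,
    stim: StimulusSpec,
    noise_sd: float = 1.0,
    baseline: float = -60.0,
    seed: int | np.random.SeedSequence = 0,
    psp_gain: float = 1.0,
    psp_offset: float = 0.0,
    freq_tuning_width: float = 0.5,
    spiking_enabled: bool = True,
    dt: float = SAMPLING_INTERVAL_MS,
) -> RecordingTrial:
    """Simulate one intracellular trial.

    The trace is ``baseline`` outside the stimulus; during the stimulus it
    is ``baseline + gain*(V_true - offset) + OU noise``, with spikes drawn
    from an inhomogeneous Poisson process at a hazard derived from
    ``spike_rate`` of the instantaneous potential, each adding a 2-ms
    stereotyped waveform.  Identical seeds give identical traces.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    seq = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    seed_id = seq.entropy if isinstance(seq.entropy, int) else 0
    rng = np.random.default_rng(seq)

    total = stim.duration + 20.0
    t = np.arange(0.0, total + 1e-9, dt)
    v = np.full(t.size, baseline)
    in_stim = t < stim.duration
    n_stim = int(in_stim.sum())

    v_true = psp_gain * (_true_psp(neuron, pop, stim, freq_tuning_width) - psp_offset)
    v[in_stim] += v_true

    if noise_sd > 0:
        # exact OU discretization
        decay = np.exp(-dt / OU_TAU_MS)
        innov_sd = noise_sd * np.sqrt(1.0 - decay**2)
        eps = rng.normal(0.0, 1.0, n_stim)
        noise = np.empty(n_stim)
        x = rng.normal(0.0, noise_sd)
        for k in range(n_stim):
            x = x * decay + innov_sd * eps[k]
            noise[k] = x
        v[in_stim] += noise

    spike_times = np.empty(0)
    if spiking_enabled:
        target = spike_rate(neuron.spiking, v[in_stim])
        rate = np.asarray(target, dtype=float) / stim.duration  # spikes/ms
        # hazard correction so E[count] matches despite refractory dead time
        dead = np.clip(rate * REFRACTORY_MS, 0.0, 0.9)
        hazard = rate / (1.0 - dead)
        u = rng.random(n_stim)
        events = np.flatnonzero(u < hazard * dt)
        wf = _spike_waveform(dt)
        kept = []
        last = -np.inf
        for k in events:
            tk = t[k]
            if tk - last < REFRACTORY_MS:
                continue
            kept.append(tk)
            last = tk
            lo, hi = k, min(k + wf.size, v.size)
            v[lo:hi] += wf[: hi - lo]
        spike_times = np.array(kept)

    return RecordingTrial(t=t, v=v, spike_times=spike_times, seed=seed_id)


def median_psp(
    trial: RecordingTrial, onset: float = 10.0, window: float = 50.0
) -> float:
    """Median membrane potential over [onset, onset + window) ms.

    The median is robust to the brief spike waveforms riding on the PSP.
    """
    if trial.t[-1] < onset + window - 1e-9:
        raise ValueError("analysis window extends beyond the trace")
    mask = (trial.t >= onset) & (trial.t < onset + window)
    return float(np.median(trial.v[mask]))


def trial_average(
    recset: RecordingSet, stimulus: StimulusSpec
) -> tuple[float, float]:
    """(mean of per-trial median PSPs, mean spike count) for one stimulus."""
    trials = recset.trials.get(stimulus.key)
    if not trials or len(trials) < 3:
        raise ValueError(f"missing trials for stimulus {stimulus.key}")
    psps = [median_psp(tr) for tr in trials]
    counts = [tr.spike_times.size for tr in trials]
    return float(np.mean(psps)), float(np.mean(counts))


def v_add(tone_psps: Sequence[float], v_min: float) -> float:
    """Linear-combination reference: sum of tone PSPs relative to ``v_min``.

    ``v_min`` is the minimum trial-averaged PSP recorded anywhere in the
    experiment; every tone response must lie at or above it.
    """
    tone_psps = np.asarray(tone_psps, dtype=float)
    if np.any(tone_psps < v_min - 1e-9):
        raise ValueError("tone PSP below the experiment minimum v_min")
    return float(np.sum(tone_psps - v_min))


# ---------------------------------------------------------------------------
# end-to-end synthetic experiment

@dataclass(frozen=True)
class ExperimentConfig:
    """Ground truth and stimulus design of one synthetic experiment.

    ``subunit_kind`` selects the ground-truth subunit nonlinearity:
    ``linear``, ``power`` (exponent ``subunit_power``) or ``sigmoid``
    (saturating logistic whose midpoint sits at ``sigmoid_midpoint_frac``
    of the maximum drive).  Spiking is ``relu`` or ``sigmoid`` with
    parameters in absolute mV.
    """

    subunit_kind: str = "linear"
    subunit_power: float = 2.0
    sigmoid_slope_scale: float = 8.0
    sigmoid_midpoint_frac: float = 0.4
    sigma: float = 2.0
    n_subunits: int = 10
    spiking_kind: str = "relu"
    relu_a0: float = 69.6  # threshold -58 mV at slope 1.2
    relu_a1: float = 1.2
    sig_c0: float = 12.0
    sig_c1: float = 0.9
    sig_c2: float = -53.0
    sig_alpha: float = -59.0
    tone_freqs: tuple[float, ...] = (4.0, 6.0)
    itds: tuple[float, ...] = tuple(DEFAULT_EXPERIMENT_ITDS)
    n_trials: int = 5
    noise_sd: float = 1.0
    baseline: float = -60.0
    psp_range: float = 12.0
    freq_tuning_width: float = 0.5
    duration: float = 100.0


@dataclass
class ExperimentResult:
    """Everything the downstream fitting stages consume."""

    config: ExperimentConfig
    neuron: TwoLayerNeuron
    curves: dict[tuple, ITDTuningCurve]  # trial-averaged PSP vs ITD
    spike_curves: dict[tuple, np.ndarray]
    v_min: float
    vadd_vstack: ScatterData
    spiking_scatter: ScatterData
    psp_gain: float
    psp_offset: float
    recordings: RecordingSet | None = None


def _make_neuron(config: ExperimentConfig, drive_max: float) -> TwoLayerNeuron:
    if config.subunit_kind == "linear":
        nl: LinearNL | PowerNL | SigmoidNL = LinearNL()
    elif config.subunit_kind == "power":
        nl = PowerNL(config.subunit_power)
    elif config.subunit_kind == "sigmoid":
        nl = SigmoidNL(
            s0=1.0,
            s1=config.sigmoid_slope_scale / drive_max,
            s2=config.sigmoid_midpoint_frac * drive_max,
            s3=0.0,
        )
    else:
        raise ValueError(f"unknown subunit kind {config.subunit_kind!r}")
    subunits = tuple(
        SubunitSpec(cf=5.0, sigma=config.sigma, nonlinearity=nl)
        for _ in range(config.n_subunits)
    )
    if config.spiking_kind == "relu":
        spiking = SpikingNL(kind="relu", a0=config.relu_a0, a1=config.relu_a1)
    elif config.spiking_kind == "sigmoid":
        spiking = SpikingNL(
            kind="sigmoid",
            c0=config.sig_c0,
            c1=config.sig_c1,
            c2=config.sig_c2,
            alpha=config.sig_alpha,
        )
    else:
        raise ValueError(f"unknown spiking kind {config.spiking_kind!r}")
    return TwoLayerNeuron(subunits=subunits, spiking=spiking)


def _experiment_stimuli(config: ExperimentConfig) -> list[StimulusSpec]:
    stims = []
    for itd in config.itds:
        for f in config.tone_freqs:
            stims.append(StimulusSpec("tone", (f,), itd, duration=config.duration))
        stims.append(
            StimulusSpec(
                "tone_stack",
                tuple(config.tone_freqs),
                itd,
                duration=config.duration,
            )
        )
    return stims


def build_experiment(
    config: ExperimentConfig = ExperimentConfig(),
    seed: int = 0,
    keep_recordings: bool = False,
) -> ExperimentResult:
    """Run a full synthetic tone/tone-stack experiment.

    Generates per-trial recordings for every tone and the tone combination
    at every ITD, extracts trial-averaged median PSPs and spike counts, and
    assembles the V_add-V_stack scatter and the subthreshold-to-spiking
    scatter consumed by the fitting stages.  Deterministic in ``seed``.
    """
    pop = build_population()
    stimuli = _experiment_stimuli(config)

    # drive scale at the subunit (needed to place a sigmoid ground truth)
    w = np.exp(-0.5 * ((pop.bf - 5.0) / config.sigma) ** 2)
    drive_max = max(
        float(_true_rates(pop, stim, config.freq_tuning_width) @ w)
        for stim in stimuli
    )
    neuron = _make_neuron(config, drive_max)

    raw = np.array(
        [_true_psp(neuron, pop, stim, config.freq_tuning_width) for stim in stimuli]
    )
    lo, hi = raw.min(), raw.max()
    psp_gain = config.psp_range / max(hi - lo, 1e-12)
    psp_offset = float(lo)

    trials: dict[tuple, list[RecordingTrial]] = {}
    for si, stim in enumerate(stimuli):
        children = np.random.SeedSequence([seed, si]).spawn(config.n_trials)
        trials[stim.key] = [
            generate_trial(
                neuron,
                pop,
                stim,
                noise_sd=config.noise_sd,
                baseline=config.baseline,
                seed=child,
                psp_gain=psp_gain,
                psp_offset=psp_offset,
                freq_tuning_width=config.freq_tuning_width,
            )
            for child in children
        ]
    recset = RecordingSet(stimuli=stimuli, trials=trials, ground_truth=neuron)

    avg_psp: dict[tuple, float] = {}
    avg_count: dict[tuple, float] = {}
    for stim in stimuli:
        psp, cnt = trial_average(recset, stim)
        avg_psp[stim.key] = psp
        avg_count[stim.key] = cnt
    v_min = min(avg_psp.values())

    itds = np.asarray(config.itds)
    curves: dict[tuple, ITDTuningCurve] = {}
    spike_curves: dict[tuple, np.ndarray] = {}
    conditions = [("tone", (f,)) for f in config.tone_freqs]
    conditions.append(("tone_stack", tuple(config.tone_freqs)))
    for kind, freqs in conditions:
        vals = np.array([avg_psp[(kind, freqs, itd)] for itd in itds])
        cnts = np.array([avg_count[(kind, freqs, itd)] for itd in itds])
        curves[(kind, freqs)] = ITDTuningCurve(
            itds=itds, values=vals, meta=f"{kind} {freqs}"
        )
        spike_curves[(kind, freqs)] = cnts

    vadds = np.array(
        [
            v_add([avg_psp[("tone", (f,), itd)] for f in config.tone_freqs], v_min)
            for itd in itds
        ]
    )
    vstacks = np.array(
        [
            avg_psp[("tone_stack", tuple(config.tone_freqs), itd)] - v_min
            for itd in itds
        ]
    )

    xs = np.array([avg_psp[s.key] for s in stimuli])
    ys = np.array([avg_count[s.key] for s in stimuli])

    return ExperimentResult(
        config=config,
        neuron=neuron,
        curves=curves,
        spike_curves=spike_curves,
        v_min=v_min,
        vadd_vstack=ScatterData(vadds, vstacks),
        spiking_scatter=ScatterData(xs, ys),
        psp_gain=psp_gain,
        psp_offset=psp_offset,
        recordings=recset if keep_recordings else None,
    )
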