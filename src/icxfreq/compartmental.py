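"""Passive multicompartment ICx neuron with AMPA/NMDA synapses.

The cell is a soma with cylindrical dendrites and, optionally, cylindrical
spines carrying the synapses.  The membrane is passive (no
voltage-dependent channels producing action potentials); synaptic input is
the only nonlinearity besides the NMDA receptor's voltage-dependent
magnesium block.  Poisson input spike trains follow a rate equation that
combines the ICcl ITD-tuning curve for each of two stimulus frequencies
with Gaussian frequency selectivity of the presynaptic neuron and a floor
rate 1/int_max that caps the maximum inter-spike interval.

Synapse models:

* AMPA — single-exponential conductance, ``g(t) = w exp(-(t - t_sp)/tau)``
  with tau = 4.5 ms;
* NMDA — two-state ligand binding (during a fixed-duration transmitter
  pulse the bound fraction relaxes to ``R_inf = c a/(a+b)`` with time
  constant ``R_tau = 1/(a+b)``; afterwards it decays at rate ``b``), gated
  by the magnesium block ``1/(1 + exp(-0.062 V) [Mg]/3.57)``.

The cable equations are integrated with backward Euler; the branched
linear system solved each step by Hines elimination (children eliminated
into parents, then forward substitution), JIT-compiled with numba.
Synaptic and leak currents enter the implicit step with conductances
evaluated at the previous voltage, which for a passive tree is
unconditionally stable.

The headline experiment stimulates the model with two tones independently
and then simultaneously across ITD, summarizes each response by the
windowed median soma potential, and classifies the V_add-V_stack relation
as linear, quadratic or sigmoidal with the same selection protocol used
for the recorded neurons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .iccl import concentration_param
from .fitting import ModelComparison, ScatterData, compare_models
from .recordings import RecordingTrial, median_psp

__all__ = [
    "Cylinder",
    "Morphology",
    "SynapseSpec",
    "SimConfig",
    "CellModel",
    "CombinationResult",
    "input_rate",
    "poisson_train",
    "ampa_conductance",
    "mg_block",
    "nmda_conductance",
    "nmda_bound_fraction",
    "build_cell",
    "simulate",
    "stimulus_trains",
    "combination_experiment",
    "matched_mismatch_split",
    "place_synapses",
    "reference_configurations",
]


# ---------------------------------------------------------------------------
# morphology

@dataclass(frozen=True)
class Cylinder:
    """Cylindrical section: diameter and length in micrometers."""

    diameter_um: float
    length_um: float

    @property
    def area_cm2(self) -> float:
        """Lateral membrane area in cm^2."""
        return np.pi * self.diameter_um * self.length_um * 1e-8

    @property
    def cross_cm2(self) -> float:
        """Cross-sectional area in cm^2."""
        return np.pi * (self.diameter_um / 2.0) ** 2 * 1e-8


_SOMA_RANGE = (10.0, 30.0)
_DEND_DIAM = (4.0, 20.0)
_DEND_LEN = (50.0, 300.0)
_SPINE_DIAM = (0.1, 0.4)
_SPINE_LEN = (2.0, 80.0)


@dataclass(frozen=True)
class Morphology:
    """Soma, dendrites and mean spine dimensions.

    Spine dimensions are means; individual spines jitter uniformly within
    ``spine_jitter`` (fraction) of the mean.  Extreme spine shapes (minimum
    diameter with maximum length and vice versa) are rejected as
    unrealistic.
    """

    soma: Cylinder = Cylinder(20.0, 20.0)
    dendrites: tuple[Cylinder, ...] = tuple(Cylinder(5.0, 150.0) for _ in range(4))
    spine: Cylinder = Cylinder(0.2, 15.0)
    spine_jitter: float = 0.10

    def __post_init__(self) -> None:
        s = self.soma
        if not (
            _SOMA_RANGE[0] <= s.diameter_um <= _SOMA_RANGE[1]
            and _SOMA_RANGE[0] <= s.length_um <= _SOMA_RANGE[1]
        ):
            raise ValueError(f"soma dimensions out of range: {s}")
        if not self.dendrites:
            raise ValueError("need at least one dendrite")
        for d in self.dendrites:
            if not (
                _DEND_DIAM[0] <= d.diameter_um <= _DEND_DIAM[1]
                and _DEND_LEN[0] <= d.length_um <= _DEND_LEN[1]
            ):
                raise ValueError(f"dendrite dimensions out of range: {d}")
        sp = self.spine
        if not (
            _SPINE_DIAM[0] <= sp.diameter_um <= _SPINE_DIAM[1]
            and _SPINE_LEN[0] <= sp.length_um <= _SPINE_LEN[1]
        ):
            raise ValueError(f"spine dimensions out of range: {sp}")
        thin = sp.diameter_um <= _SPINE_DIAM[0] * 1.05
        thick = sp.diameter_um >= _SPINE_DIAM[1] * 0.95
        long = sp.length_um >= _SPINE_LEN[1] * 0.95
        short = sp.length_um <= _SPINE_LEN[0] * 1.05
        if (thin and long) or (thick and short):
            raise ValueError(
                "rejected unrealistic spine shape (extreme diameter/length combination)"
            )


@dataclass(frozen=True)
class SynapseSpec:
    """One synapse: receptor type, strength, location, input selectivity."""

    kind: str  # "ampa" | "nmda"
    weight: float  # uS (peak for AMPA, gmax for NMDA)
    site: tuple[int, float]  # (dendrite index, position along it in [0, 1])
    pref_freq: float  # kHz, in [2, 8]
    pref_itd: float = 0.0  # us, near zero
    on_spine: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("ampa", "nmda"):
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if not self.weight > 0:
            raise ValueError("synaptic weight must be > 0")
        if not 2.0 <= self.pref_freq <= 8.0:
            raise ValueError("preferred frequency must be in [2, 8] kHz")
        if not 0.0 <= self.site[1] <= 1.0:
            raise ValueError("site position must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Biophysical and numerical parameters.

    ``g_pas`` is the total leak conductance per named section (soma, each
    dendrite, each spine), in uS, spread uniformly over that section's
    compartments; set ``g_pas_mode='specific'`` to interpret it as S/cm^2
    instead.  Per-compartment leak reversal is ``e_pas``; both AMPA and
    NMDA reverse at ``e_syn``.
    """

    g_pas: float = 0.001
    g_pas_soma: float | None = None
    g_pas_dend: float | None = None
    g_pas_spine: float | None = None
    g_pas_mode: str = "total"  # "total" (uS/section) or "specific" (S/cm^2)
    e_pas: float = -65.0
    e_syn: float = 0.0
    mg_mM: float = 1.0
    dt: float = 0.025
    duration: float = 120.0
    stim_duration: float = 100.0
    w1: float = 0.15  # rate weights, events/ms at the preferred ITD
    w2: float = 0.15
    int_max: float = 100.0
    sigma_f: float = 0.5  # kHz, presynaptic frequency-tuning width
    tau_ampa: float = 4.5
    nmda_alpha: float = 0.35  # /ms binding
    nmda_beta: float = 0.015  # /ms unbinding
    nmda_c: float = 1.0
    nmda_pulse_ms: float = 1.0
    ra_ohm_cm: float = 150.0
    cm_uf_cm2: float = 1.0
    nseg_dend: int = 5

    def __post_init__(self) -> None:
        if self.g_pas_mode == "total" and not (1e-4 - 1e-12 <= self.g_pas <= 1e-2 + 1e-12):
            raise ValueError("g_pas (total, uS) must lie in [0.0001, 0.01]")
        if self.dt > 0.025 + 1e-12:
            raise ValueError("dt must be <= 0.025 ms")


# ---------------------------------------------------------------------------
# input statistics

def input_rate(
    syn: SynapseSpec,
    itd_in: float,
    fin1: float,
    fin2: float,
    w1: float,
    w2: float,
    sigma_f: float = 0.5,
    int_max: float = 100.0,
) -> float:
    """Mean Poisson input rate (events/ms) for one synapse.

    Each of the two stimulus frequencies contributes its ICcl ITD-tuning
    factor (concentration parameter from the frequency) times a Gaussian
    frequency-selectivity factor, weighted by ``w1``/``w2``; the floor
    ``1/int_max`` caps the maximum expected inter-spike interval.
    """
    if sigma_f <= 0:
        raise ValueError("sigma_f must be > 0")
    rate = 1.0 / int_max
    for w, fin in ((w1, fin1), (w2, fin2)):
        if w == 0.0:
            continue
        b = concentration_param(fin)
        phase = 2.0 * np.pi * fin * (syn.pref_itd - itd_in) * 1e-3
        itd_fac = (np.exp(b * np.cos(phase)) - np.exp(-b)) / (
            np.exp(b) - np.exp(-b)
        )
        freq_fac = np.exp(-0.5 * ((syn.pref_freq - fin) / sigma_f) ** 2)
        rate += w * itd_fac * freq_fac
    return float(rate)


def poisson_train(
    rate: float, duration: float, seed: int | np.random.Generator | np.random.SeedSequence = 0
) -> np.ndarray:
    """Homogeneous Poisson event times (ms) on [0, duration)."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, n))


def ampa_conductance(
    t: float | np.ndarray, t_spikes: float | np.ndarray, weight: float, tau: float = 4.5
) -> float | np.ndarray:
    """Superposed exponential AMPA conductance (uS) at time(s) ``t``."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    sp = np.atleast_1d(np.asarray(t_spikes, dtype=float))
    dt_mat = t_arr[:, None] - sp[None, :]
    g = np.where(dt_mat >= 0, weight * np.exp(-np.maximum(dt_mat, 0.0) / tau), 0.0)
    out = g.sum(axis=1)
    if np.isscalar(t):
        return float(out[0])
    return out


def mg_block(v: float | np.ndarray, mg: float = 1.0) -> float | np.ndarray:
    """Voltage-dependent magnesium block factor of the NMDA conductance."""
    if mg < 0:
        raise ValueError("magnesium concentration must be >= 0")
    out = 1.0 / (1.0 + np.exp(-0.062 * np.asarray(v, dtype=float)) * mg / 3.57)
    if np.isscalar(v):
        return float(out)
    return out


def nmda_conductance(
    v: float | np.ndarray, mg: float, bound_fraction: float, gmax: float
) -> float | np.ndarray:
    """NMDA conductance: ``gmax * bound_fraction * mg_block(v)``."""
    if not 0.0 <= bound_fraction <= 1.0:
        raise ValueError("bound_fraction must be in [0, 1]")
    return gmax * bound_fraction * mg_block(v, mg)


def nmda_bound_fraction(
    t_grid: np.ndarray,
    spike_times: np.ndarray,
    alpha: float = 0.35,
    beta: float = 0.015,
    c: float = 1.0,
    pulse_ms: float = 1.0,
) -> np.ndarray:
    """Bound-receptor fraction over time for the two-state pulse scheme.

    During a transmitter pulse the fraction relaxes toward
    ``R_inf = c a/(a+b)`` with time constant ``R_tau = 1/(a+b)``; outside
    pulses it decays at rate ``b``.  Reference implementation used by the
    simulator tests.
    """
    r_inf = c * alpha / (alpha + beta)
    r_tau = 1.0 / (alpha + beta)
    out = np.empty(t_grid.size)
    r = 0.0
    for i in range(t_grid.size):
        if i > 0:
            dt = t_grid[i] - t_grid[i - 1]
            pulsing = np.any(
                (spike_times <= t_grid[i - 1]) & (t_grid[i - 1] < spike_times + pulse_ms)
            )
            if pulsing:
                r = r_inf + (r - r_inf) * np.exp(-dt / r_tau)
            else:
                r = r * np.exp(-beta * dt)
        out[i] = r
    return out


# ---------------------------------------------------------------------------
# discretized cell

@dataclass
class CellModel:
    """Compartmentalized cell: arrays indexed by compartment.

    ``parent[i] < i`` for every non-root compartment (the soma is index 0),
    which makes child-before-parent Hines elimination a simple reverse
    index sweep.
    """

    parent: np.ndarray  # int32, -1 for the soma
    c_nF: np.ndarray
    g_leak_uS: np.ndarray
    g_ax_uS: np.ndarray  # coupling to parent; 0 for the soma
    syn_node: np.ndarray  # int32 compartment of each synapse
    synapses: tuple[SynapseSpec, ...]
    config: SimConfig
    morphology: Morphology
    spine_dims: tuple[Cylinder, ...] = ()

    @property
    def n_compartments(self) -> int:
        return self.parent.size


def _leak_for(g_section: float, seg_area_cm2: float, nseg: int, config: SimConfig) -> float:
    """Leak conductance (uS) of one compartment of a section."""
    if config.g_pas_mode == "total":
        return g_section / nseg
    return g_section * seg_area_cm2 * 1e6  # S/cm^2 -> uS for this compartment


def build_cell(
    morph: Morphology,
    synapses: Sequence[SynapseSpec],
    config: SimConfig = SimConfig(),
    seed: int = 0,
) -> CellModel:
    """Discretize the morphology and attach synapses (one spine each, when
    ``on_spine``); spine dimensions jitter deterministically from ``seed``."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E1]))
    ra = config.ra_ohm_cm
    cm = config.cm_uf_cm2
    g_soma = config.g_pas_soma if config.g_pas_soma is not None else config.g_pas
    g_dend = config.g_pas_dend if config.g_pas_dend is not None else config.g_pas
    g_spine = config.g_pas_spine if config.g_pas_spine is not None else config.g_pas

    parent: list[int] = [-1]
    c_nF: list[float] = [cm * morph.soma.area_cm2 * 1e3]
    g_leak: list[float] = [_leak_for(g_soma, morph.soma.area_cm2, 1, config)]
    g_ax: list[float] = [0.0]

    nseg = config.nseg_dend
    dend_nodes: list[list[int]] = []
    soma_axial_half = ra * (morph.soma.length_um * 1e-4 / 2.0) / morph.soma.cross_cm2
    for d in morph.dendrites:
        seg_len_cm = d.length_um * 1e-4 / nseg
        seg_area = np.pi * d.diameter_um * (d.length_um / nseg) * 1e-8
        r_seg = ra * seg_len_cm / d.cross_cm2  # ohm, center-to-center
        nodes = []
        for k in range(nseg):
            idx = len(parent)
            if k == 0:
                parent.append(0)
                r_conn = soma_axial_half + r_seg / 2.0
            else:
                parent.append(nodes[-1])
                r_conn = r_seg
            c_nF.append(cm * seg_area * 1e3)
            g_leak.append(_leak_for(g_dend, seg_area, nseg, config))
            g_ax.append(1e6 / r_conn)
            nodes.append(idx)
        dend_nodes.append(nodes)

    syn_node: list[int] = []
    spine_dims: list[Cylinder] = []
    for syn in synapses:
        di, pos = syn.site
        if not 0 <= di < len(morph.dendrites):
            raise ValueError(f"synapse references missing dendrite {di}")
        seg = min(int(pos * nseg), nseg - 1)
        attach = dend_nodes[di][seg]
        if syn.on_spine:
            jd = 1.0 + morph.spine_jitter * (2.0 * rng.random() - 1.0)
            jl = 1.0 + morph.spine_jitter * (2.0 * rng.random() - 1.0)
            sp = Cylinder(morph.spine.diameter_um * jd, morph.spine.length_um * jl)
            spine_dims.append(sp)
            d = morph.dendrites[di]
            r_conn = (
                ra * (sp.length_um * 1e-4 / 2.0) / sp.cross_cm2
                + ra * (d.length_um * 1e-4 / nseg / 2.0) / d.cross_cm2
            )
            idx = len(parent)
            parent.append(attach)
            c_nF.append(cm * sp.area_cm2 * 1e3)
            g_leak.append(_leak_for(g_spine, sp.area_cm2, 1, config))
            g_ax.append(1e6 / r_conn)
            syn_node.append(idx)
        else:
            syn_node.append(attach)

    return CellModel(
        parent=np.asarray(parent, dtype=np.int32),
        c_nF=np.asarray(c_nF),
        g_leak_uS=np.asarray(g_leak),
        g_ax_uS=np.asarray(g_ax),
        syn_node=np.asarray(syn_node, dtype=np.int32),
        synapses=tuple(synapses),
        config=config,
        morphology=morph,
        spine_dims=tuple(spine_dims),
    )


# ---------------------------------------------------------------------------
# integrator

@njit(cache=True)
def _run_kernel(
    parent,
    c_over_dt,
    g_leak,
    g_ax,
    static_diag,
    e_pas,
    e_syn,
    dt,
    nsteps,
    syn_node,
    syn_kind,  # 0 ampa, 1 nmda
    syn_w,
    ampa_decay,
    ampa_add,  # (n_syn, nsteps) conductance increments
    pulse_on,  # (n_syn, nsteps) uint8
    r_inf,
    e_rel,
    e_dec,
    mg,
    i_inj,  # (n,) constant current, nA
    v0,
):
    n = parent.size
    n_syn = syn_node.size
    v = np.full(n, v0)
    g_state = np.zeros(n_syn)
    r_state = np.zeros(n_syn)
    gsyn = np.zeros(n)
    rhs_syn = np.zeros(n)
    d = np.zeros(n)
    b = np.zeros(n)
    out = np.empty(nsteps + 1)
    out[0] = v[0]
    for step in range(nsteps):
        for i in range(n):
            gsyn[i] = 0.0
            rhs_syn[i] = 0.0
        for s in range(n_syn):
            if syn_kind[s] == 0:
                g_state[s] = g_state[s] * ampa_decay + ampa_add[s, step]
                geff = g_state[s]
            else:
                if pulse_on[s, step] == 1:
                    r_state[s] = r_inf + (r_state[s] - r_inf) * e_rel
                else:
                    r_state[s] = r_state[s] * e_dec
                vv = v[syn_node[s]]
                mgf = 1.0 / (1.0 + np.exp(-0.062 * vv) * mg / 3.57)
                geff = syn_w[s] * r_state[s] * mgf
            node = syn_node[s]
            gsyn[node] += geff
            rhs_syn[node] += geff * e_syn
        for i in range(n):
            d[i] = static_diag[i] + gsyn[i]
            b[i] = c_over_dt[i] * v[i] + g_leak[i] * e_pas + rhs_syn[i] + i_inj[i]
        # Hines elimination: children (higher index) into parents
        for i in range(n - 1, 0, -1):
            p = parent[i]
            ratio = g_ax[i] / d[i]
            d[p] -= ratio * g_ax[i]
            b[p] += ratio * b[i]
        v[0] = b[0] / d[0]
        for i in range(1, n):
            v[i] = (b[i] + g_ax[i] * v[parent[i]]) / d[i]
        out[step + 1] = v[0]
    return out


def simulate(
    cell: CellModel,
    trains: Sequence[np.ndarray],
    i_inj_soma_nA: float = 0.0,
    dt: float | None = None,
    duration: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the cell given per-synapse input spike trains.

    Returns ``(t, v_soma)`` at the integration step.  Raises on numerical
    blow-up (non-finite soma potential).
    """
    cfg = cell.config
    dt = cfg.dt if dt is None else dt
    duration = cfg.duration if duration is None else duration
    if len(trains) != len(cell.synapses):
        raise ValueError("need one spike train per synapse")
    nsteps = int(round(duration / dt))
    n_syn = len(cell.synapses)

    ampa_add = np.zeros((n_syn, nsteps))
    pulse_on = np.zeros((n_syn, nsteps), dtype=np.uint8)
    syn_kind = np.zeros(n_syn, dtype=np.int32)
    syn_w = np.zeros(n_syn)
    for s, syn in enumerate(cell.synapses):
        syn_w[s] = syn.weight
        times = np.asarray(trains[s], dtype=float)
        if syn.kind == "ampa":
            syn_kind[s] = 0
            for tsp in times:
                k = int(tsp / dt)
                if 0 <= k < nsteps:
                    ampa_add[s, k] += syn.weight
        else:
            syn_kind[s] = 1
            npulse = max(int(round(cfg.nmda_pulse_ms / dt)), 1)
            for tsp in times:
                k = int(tsp / dt)
                if k < nsteps:
                    pulse_on[s, max(k, 0) : min(k + npulse, nsteps)] = 1

    n = cell.n_compartments
    c_over_dt = cell.c_nF / dt
    static_diag = c_over_dt + cell.g_leak_uS + cell.g_ax_uS
    for i in range(1, n):
        static_diag[cell.parent[i]] += cell.g_ax_uS[i]
    i_inj = np.zeros(n)
    i_inj[0] = i_inj_soma_nA

    r_inf = cfg.nmda_c * cfg.nmda_alpha / (cfg.nmda_alpha + cfg.nmda_beta)
    r_tau = 1.0 / (cfg.nmda_alpha + cfg.nmda_beta)

    v_soma = _run_kernel(
        cell.parent,
        c_over_dt,
        cell.g_leak_uS,
        cell.g_ax_uS,
        static_diag,
        cfg.e_pas,
        cfg.e_syn,
        dt,
        nsteps,
        cell.syn_node,
        syn_kind,
        syn_w,
        np.exp(-dt / cfg.tau_ampa),
        ampa_add,
        pulse_on,
        r_inf,
        np.exp(-dt / r_tau),
        np.exp(-cfg.nmda_beta * dt),
        cfg.mg_mM,
        i_inj,
        cfg.e_pas,
    )
    if not np.all(np.isfinite(v_soma)):
        raise FloatingPointError(
            f"numerical instability (non-finite soma potential) with dt={dt}"
        )
    t = np.arange(nsteps + 1) * dt
    return t, v_soma


# ---------------------------------------------------------------------------
# stimulus-driven experiments

def stimulus_trains(
    synapses: Sequence[SynapseSpec],
    condition: str,  # "f1" | "f2" | "stack"
    fin1: float,
    fin2: float,
    itd: float,
    config: SimConfig,
    seed: int = 0,
    trial: int = 0,
) -> list[np.ndarray]:
    """Poisson input trains for one stimulus condition.

    Each synapse's rate has three additive components (the two frequency
    terms and the floor); each component is drawn as an independent Poisson
    train with a seed fixed by (seed, trial, synapse, component).  The
    ``stack`` condition is then the exact superposition of the trains that
    drive the single-tone conditions, plus one shared floor train, so that
    small-signal responses superpose trial by trial.
    """
    if condition not in ("f1", "f2", "stack"):
        raise ValueError(f"unknown condition {condition!r}")
    trains: list[np.ndarray] = []
    for s, syn in enumerate(synapses):
        parts = []
        comps: list[tuple[int, float, float]] = [(2, 0.0, 1.0 / config.int_max)]
        if condition in ("f1", "stack"):
            r1 = input_rate(
                syn, itd, fin1, fin2, config.w1, 0.0, config.sigma_f, config.int_max
            ) - 1.0 / config.int_max
            comps.append((0, r1, r1))
        if condition in ("f2", "stack"):
            r2 = input_rate(
                syn, itd, fin1, fin2, 0.0, config.w2, config.sigma_f, config.int_max
            ) - 1.0 / config.int_max
            comps.append((1, r2, r2))
        for comp_id, _, rate in comps:
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, trial, s, comp_id, int(round(itd * 1000)) & 0x7FFFFFFF])
            )
            parts.append(poisson_train(max(rate, 0.0), config.stim_duration, rng))
        trains.append(np.sort(np.concatenate(parts)))
    return trains


def matched_mismatch_split(
    v_f1: np.ndarray, v_f2: np.ndarray, threshold: float = 3.0
) -> np.ndarray:
    """Boolean mask: True where the single-tone responses are matched
    (strictly less than ``threshold`` mV apart, on the v_min-referenced
    scale)."""
    return np.abs(np.asarray(v_f1) - np.asarray(v_f2)) < threshold


@dataclass
class CombinationResult:
    """Per-ITD tone/tone-stack responses and their classification."""

    itds: np.ndarray
    v_f1: np.ndarray  # trial-averaged median soma PSP, mV
    v_f2: np.ndarray
    v_stack: np.ndarray
    v_min: float
    v_add: np.ndarray  # relative scale
    v_stack_rel: np.ndarray
    comparison: ModelComparison
    matched: np.ndarray

    @property
    def winner(self) -> str:
        return self.comparison.winner

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "itd_us": self.itds,
                "v_f1_mv": self.v_f1,
                "v_f2_mv": self.v_f2,
                "v_stack_mv": self.v_stack,
                "v_add_rel_mv": self.v_add,
                "v_stack_rel_mv": self.v_stack_rel,
                "matched": self.matched,
            }
        )


def _median_soma_psp(t: np.ndarray, v: np.ndarray) -> float:
    trial = RecordingTrial(t=t, v=v, spike_times=np.empty(0), seed=0)
    return median_psp(trial)


DEFAULT_COMBINATION_ITDS = np.arange(-250.0, 250.0 + 1e-9, 25.0)


def combination_experiment(
    morph: Morphology,
    synapses: Sequence[SynapseSpec],
    config: SimConfig = SimConfig(),
    fin1: float = 4.0,
    fin2: float = 6.0,
    itd_grid: np.ndarray = DEFAULT_COMBINATION_ITDS,
    n_trials: int = 2,
    seed: int = 0,
) -> CombinationResult:
    """Tone / tone-combination experiment on the compartmental model.

    For each ITD the model is driven by each tone independently and by
    both simultaneously; responses are summarized by the windowed median
    soma potential averaged over trials, referenced to the experiment-wide
    minimum, and the V_add-V_stack relation is classified among
    {linear, quadratic, sigmoidal}.
    """
    itd_grid = np.asarray(itd_grid, dtype=float)
    period = 1e3 / min(fin1, fin2)
    if itd_grid[-1] - itd_grid[0] < 2.0 * period - 1e-9:
        raise ValueError(
            "ITD grid must span at least +/- one period of the lower frequency"
        )
    cell = build_cell(morph, synapses, config, seed=seed)
    resp = {c: np.zeros(itd_grid.size) for c in ("f1", "f2", "stack")}
    for j, itd in enumerate(itd_grid):
        for cond in ("f1", "f2", "stack"):
            acc = 0.0
            for trial in range(n_trials):
                trains = stimulus_trains(
                    synapses, cond, fin1, fin2, itd, config, seed=seed, trial=trial
                )
                t, v = simulate(cell, trains)
                acc += _median_soma_psp(t, v)
            resp[cond][j] = acc / n_trials

    v_min = min(resp[c].min() for c in resp)
    v_add = (resp["f1"] - v_min) + (resp["f2"] - v_min)
    v_stack_rel = resp["stack"] - v_min
    comparison = compare_models(
        ScatterData(v_add, v_stack_rel), ("linear", "quadratic", "stack_sigmoid")
    )
    matched = matched_mismatch_split(resp["f1"] - v_min, resp["f2"] - v_min)
    return CombinationResult(
        itds=itd_grid,
        v_f1=resp["f1"],
        v_f2=resp["f2"],
        v_stack=resp["stack"],
        v_min=v_min,
        v_add=v_add,
        v_stack_rel=v_stack_rel,
        comparison=comparison,
        matched=matched,
    )


# ---------------------------------------------------------------------------
# reference configurations

def place_synapses(
    n_per_channel: int = 10,
    fin1: float = 4.0,
    fin2: float = 6.0,
    kind: str = "ampa",
    weight: float = 8e-4,
    on_spine: bool = False,
    arrangement: str = "interleaved",
    n_dendrites: int = 4,
) -> tuple[SynapseSpec, ...]:
    """Distribute two frequency channels of synapses over the dendrites.

    ``interleaved`` alternates the channels along every dendrite;
    ``clustered`` puts channel 1 on the first half of the dendrites and
    channel 2 on the rest.
    """
    if arrangement not in ("interleaved", "clustered"):
        raise ValueError(f"unknown arrangement {arrangement!r}")
    syns: list[SynapseSpec] = []
    total = 2 * n_per_channel
    for k in range(total):
        if arrangement == "interleaved":
            freq = fin1 if k % 2 == 0 else fin2
            dend = k % n_dendrites
        else:
            freq = fin1 if k < n_per_channel else fin2
            dend = (k * n_dendrites) // total
        pos = 0.25 + 0.5 * ((k // n_dendrites) / max(total // n_dendrites - 1, 1))
        syns.append(
            SynapseSpec(
                kind=kind,
                weight=weight,
                site=(dend, min(pos, 1.0)),
                pref_freq=freq,
                on_spine=on_spine,
            )
        )
    return tuple(syns)


def reference_configurations() -> dict[str, dict]:
    """The three canonical circuit configurations and their expected
    integration classes.

    * AMPA synapses on 5-um dendrites with high leak -> linear combination;
    * AMPA synapses on thin spines (lower leak, stronger weights) ->
      quadratic combination (saturation at high drive);
    * NMDA synapses on spines -> sigmoidal combination (Mg-block
      suppression at low drive plus saturation at high drive).
    """
    morph = Morphology()
    return {
        "linear": {
            "expected": "linear",
            "morph": morph,
            "synapses": place_synapses(kind="ampa", weight=2e-4, on_spine=False),
            "config": SimConfig(g_pas=0.01),
            "n_trials": 6,
        },
        "quadratic": {
            "expected": "quadratic",
            "morph": morph,
            "synapses": place_synapses(kind="ampa", weight=2e-3, on_spine=True),
            "config": SimConfig(g_pas=0.001),
            "n_trials": 6,
        },
        "sigmoidal": {
            "expected": "stack_sigmoid",
            "morph": morph,
            "synapses": place_synapses(kind="nmda", weight=1.8e-2, on_spine=True),
            "config": SimConfig(g_pas=0.001),
            "n_trials": 6,
        },
    }
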