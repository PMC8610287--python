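"""Two-layer (dendritic-subunit) functional model of ICx neurons.

An ICx neuron is modelled as a cascade: ICcl input rates are combined
within ``N`` dendritic subunits, each applying a static nonlinearity ``g``
to a weighted sum of inputs,

    d_j = g( sum_i w_ij r_ICcl,i ),      w_ij = exp(-((bf_i - cf_j)/sigma)^2 / 2),

the subunit outputs sum at the soma to give the subthreshold potential
``V = sum_j d_j``, and a spiking nonlinearity ``f(V)`` (rectified-linear or
thresholded sigmoid) maps the potential to a firing rate.

The module also implements the subunit parameter-space exploration: sweeping
the Gaussian weight width ``sigma`` (frequency integration bandwidth), the
power-law exponent ``p`` of the subunit nonlinearity, and the spread of
subunit center frequencies, scoring each configuration by z-scores of the
ITD-curve side-peak suppression and half-width against the in vivo
population statistics; and a deterministic search for one fixed sigmoidal
subunit nonlinearity that stays within two standard deviations of those
statistics over a wide range of bandwidths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .iccl import ICclPopulation, build_population
from .metrics import (
    ICX_POPULATION_STATS,
    ITDTuningCurve,
    PopulationStats,
    SidePeakMissing,
    half_width,
    side_peak_suppression,
    zscore,
)

__all__ = [
    "LinearNL",
    "PowerNL",
    "SigmoidNL",
    "SubunitSpec",
    "SpikingNL",
    "TwoLayerNeuron",
    "ZScoreMap",
    "DEFAULT_ITD_GRID",
    "connection_weights",
    "subunit_response",
    "psp_itd_curve",
    "spike_rate",
    "map_subunit_space",
    "sigmoid_subunit_feasibility",
    "evaluate_subunit_curve",
    "SigmoidSearchSpace",
]

#: Default ITD evaluation grid: -250..250 us in 5-us steps, fine enough that
#: half-width interpolation error is below 2 us.
DEFAULT_ITD_GRID = np.arange(-250.0, 250.0 + 1e-9, 5.0)


# ---------------------------------------------------------------------------
# subunit nonlinearities

@dataclass(frozen=True)
class LinearNL:
    """Identity subunit nonlinearity."""

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class PowerNL:
    """Power-law subunit nonlinearity ``g(x) = x**p``.

    Suppressive for ``p < 1``, expansive for ``p > 1``.
    """

    p: float

    def __post_init__(self) -> None:
        if not self.p > 0:
            raise ValueError("power exponent must be > 0")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError(
                "negative drive passed to power nonlinearity "
                "(drive is a sum of nonnegative terms; negativity signals an "
                "upstream bug)"
            )
        return x**self.p


@dataclass(frozen=True)
class SigmoidNL:
    """Offset-logistic subunit nonlinearity ``s3 + s0 / (1 + exp(-s1 (x - s2)))``.

    With a midpoint inside the drive range the same fixed curve is expansive
    for weak (narrow-bandwidth) input and suppressive for strong
    (broad-bandwidth) input.
    """

    s0: float = 1.0
    s1: float = 1.0
    s2: float = 0.0
    s3: float = 0.0

    def __post_init__(self) -> None:
        if not self.s1 > 0:
            raise ValueError("sigmoid slope s1 must be > 0")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.s3 + self.s0 / (1.0 + np.exp(-self.s1 * (x - self.s2)))


Nonlinearity = LinearNL | PowerNL | SigmoidNL


@dataclass(frozen=True)
class SubunitSpec:
    """One dendritic subunit: center frequency, weight width, nonlinearity."""

    cf: float
    sigma: float
    nonlinearity: Nonlinearity = field(default_factory=LinearNL)

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class SpikingNL:
    """Static spiking nonlinearity mapping potential (mV) to spikes/stimulus.

    ``kind='relu'``: ``f(V) = max(0, a0 + a1 V)`` with slope ``a1`` and
    threshold ``-a0/a1``.  ``kind='sigmoid'``: ``f(V) = 0`` for ``V < alpha``,
    else ``c0 / (1 + exp(-c1 (V - c2)))``.
    """

    kind: str
    a0: float = 0.0
    a1: float = 1.0
    c0: float = 1.0
    c1: float = 1.0
    c2: float = 0.0
    alpha: float = -np.inf

    def __post_init__(self) -> None:
        if self.kind not in ("relu", "sigmoid"):
            raise ValueError(f"unknown spiking nonlinearity kind: {self.kind!r}")
        if self.kind == "relu" and not self.a1 > 0:
            raise ValueError("relu slope a1 must be > 0")
        if self.kind == "sigmoid" and not (self.c0 > 0 and self.c1 > 0):
            raise ValueError("sigmoid c0 and c1 must be > 0")


@dataclass(frozen=True)
class TwoLayerNeuron:
    """Dendritic subunits plus a spiking nonlinearity."""

    subunits: tuple[SubunitSpec, ...]
    spiking: SpikingNL = SpikingNL(kind="relu", a0=0.0, a1=1.0)

    def __post_init__(self) -> None:
        if len(self.subunits) < 1:
            raise ValueError("need at least one subunit")


# ---------------------------------------------------------------------------
# forward computations

def connection_weights(subunit: SubunitSpec, pop: ICclPopulation) -> np.ndarray:
    """Gaussian connection weights from every ICcl neuron to one subunit.

    ``w_i = exp(-((bf_i - cf)/sigma)^2 / 2)``; weights are deliberately
    unnormalized, so a broader ``sigma`` integrates more total input.
    """
    if len(pop) == 0:
        raise ValueError("empty population")
    return np.exp(-0.5 * ((pop.bf - subunit.cf) / subunit.sigma) ** 2)


def subunit_response(
    subunit: SubunitSpec, pop: ICclPopulation, pop_rates: np.ndarray
) -> np.ndarray:
    """Subunit output ``g(sum_i w_i r_i)`` for rate vectors.

    ``pop_rates`` has the population ordering on its last axis; the return
    drops that axis.
    """
    pop_rates = np.asarray(pop_rates, dtype=float)
    if pop_rates.shape[-1] != len(pop):
        raise ValueError("rates not aligned with population ordering")
    drive = pop_rates @ connection_weights(subunit, pop)
    return subunit.nonlinearity(drive)


def psp_itd_curve(
    neuron: TwoLayerNeuron,
    pop: ICclPopulation,
    itd_grid: np.ndarray = DEFAULT_ITD_GRID,
) -> ITDTuningCurve:
    """Subthreshold ITD tuning curve ``V(ITD) = sum_j d_j(ITD)``.

    The grid must include 0 us and span at least one period of the lowest
    subunit center frequency; spacing above 30 us triggers a diagnostic
    warning because the main peak may be unresolved.
    """
    itd_grid = np.asarray(itd_grid, dtype=float)
    if not np.any(np.isclose(itd_grid, 0.0)):
        raise ValueError("ITD grid must include 0 us")
    lowest_cf = min(s.cf for s in neuron.subunits)
    period_us = 1e3 / lowest_cf
    if itd_grid[-1] - itd_grid[0] < period_us - 1e-9:
        raise ValueError(
            f"ITD grid spans {itd_grid[-1] - itd_grid[0]:.0f} us, less than one "
            f"period ({period_us:.0f} us) of the lowest subunit cf"
        )
    if np.max(np.diff(itd_grid)) > 30.0:
        warnings.warn(
            "ITD grid spacing exceeds 30 us; main peak may be unresolved",
            stacklevel=2,
        )
    rates = pop.rates(itd_grid)
    v = np.zeros(itd_grid.size)
    for sub in neuron.subunits:
        v += subunit_response(sub, pop, rates)
    return ITDTuningCurve(itds=itd_grid, values=v, meta="two-layer PSP")


def spike_rate(spiking: SpikingNL, v: float | np.ndarray) -> float | np.ndarray:
    """Spiking-nonlinearity output (spikes per stimulus) at potential ``v``."""
    v_arr = np.asarray(v, dtype=float)
    if spiking.kind == "relu":
        out = np.maximum(0.0, spiking.a0 + spiking.a1 * v_arr)
    else:
        out = np.where(
            v_arr < spiking.alpha,
            0.0,
            spiking.c0 / (1.0 + np.exp(-spiking.c1 * (v_arr - spiking.c2))),
        )
    if np.isscalar(v):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# parameter-space exploration

def _subunit_cfs(spread: float, n_subunits: int, center: float = 5.0) -> np.ndarray:
    """Equally spaced subunit center frequencies over the spread."""
    if spread == 0.0:
        return np.full(n_subunits, center)
    return np.linspace(center - spread / 2.0, center + spread / 2.0, n_subunits)


def _drive_matrix(
    pop: ICclPopulation,
    sigma: float,
    cfs: np.ndarray,
    itd_grid: np.ndarray,
    rates: np.ndarray | None = None,
) -> np.ndarray:
    """Per-subunit linear drives, shape (n_itd, n_subunits)."""
    if rates is None:
        rates = pop.rates(itd_grid)
    w = np.exp(-0.5 * ((pop.bf[:, None] - cfs[None, :]) / sigma) ** 2)
    return rates @ w


def _curve_metrics(
    itd_grid: np.ndarray, values: np.ndarray, stats: PopulationStats
) -> tuple[float, float, float, float]:
    """(sps, hw, sps_z, hw_z) for a curve; NaN where undefined."""
    curve = ITDTuningCurve(itds=itd_grid, values=values)
    try:
        sps = side_peak_suppression(curve)
        sps_z = zscore(sps, stats, "sps")
    except SidePeakMissing:
        sps, sps_z = np.nan, np.nan
    try:
        hw = half_width(curve)
        hw_z = zscore(hw, stats, "hw")
    except ValueError:
        hw, hw_z = np.nan, np.nan
    return sps, hw, sps_z, hw_z


@dataclass(frozen=True)
class ZScoreMap:
    """Z-scored SPS/HW over the (cf spread x sigma x power) grid.

    Arrays have shape (n_spread, n_sigma, n_power); NaN marks cells whose
    ITD window contains no secondary local maximum (SPS undefined).
    """

    sigma_grid: np.ndarray
    power_grid: np.ndarray
    cf_spreads: np.ndarray
    sps: np.ndarray
    hw: np.ndarray
    sps_z: np.ndarray
    hw_z: np.ndarray

    def __post_init__(self) -> None:
        for name in ("sigma_grid", "power_grid", "cf_spreads"):
            ax = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, ax)
            if ax.size > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError(f"{name} must be strictly increasing")

    @property
    def log10_power(self) -> np.ndarray:
        return np.log10(self.power_grid)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (sigma_khz, log10_power, cf_spread_khz, ...)."""
        spread, sig, pw = np.meshgrid(
            self.cf_spreads, self.sigma_grid, self.power_grid, indexing="ij"
        )
        return pd.DataFrame(
            {
                "sigma_khz": sig.ravel(),
                "log10_power": np.log10(pw.ravel()),
                "cf_spread_khz": spread.ravel(),
                "sps": self.sps.ravel(),
                "hw_us": self.hw.ravel(),
                "sps_z": self.sps_z.ravel(),
                "hw_z": self.hw_z.ravel(),
            }
        )


def map_subunit_space(
    pop: ICclPopulation | None = None,
    sigma_grid: np.ndarray | None = None,
    power_grid: np.ndarray | None = None,
    cf_spreads: Sequence[float] = (0.0, 1.25, 2.5),
    stats: PopulationStats = ICX_POPULATION_STATS,
    n_subunits: int = 10,
    itd_grid: np.ndarray = DEFAULT_ITD_GRID,
) -> ZScoreMap:
    """Sweep power-law subunit configurations and z-score their ITD tuning.

    For every (cf spread, sigma, power) cell a 10-subunit neuron is built,
    its PSP ITD curve evaluated on ``itd_grid``, and the side-peak
    suppression and half-width z-scored against ``stats``.  Deterministic.

    Defaults: sigma 0.1-4 kHz in 0.1 steps, 25 log-spaced powers in
    [0.1, 10], spreads {0, 1.25, 2.5} kHz centered at 5 kHz.
    """
    if pop is None:
        pop = build_population()
    if sigma_grid is None:
        sigma_grid = np.round(np.arange(1, 41) * 0.1, 10)
    if power_grid is None:
        power_grid = np.logspace(np.log10(0.1), np.log10(10.0), 25)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    power_grid = np.asarray(power_grid, dtype=float)
    cf_spreads = np.asarray(cf_spreads, dtype=float)
    itd_grid = np.asarray(itd_grid, dtype=float)

    shape = (cf_spreads.size, sigma_grid.size, power_grid.size)
    sps = np.full(shape, np.nan)
    hw = np.full(shape, np.nan)
    sps_z = np.full(shape, np.nan)
    hw_z = np.full(shape, np.nan)

    rates = pop.rates(itd_grid)
    for a, spread in enumerate(cf_spreads):
        cfs = _subunit_cfs(spread, n_subunits)
        for b, sigma in enumerate(sigma_grid):
            drive = _drive_matrix(pop, sigma, cfs, itd_grid, rates=rates)
            # common positive rescaling: harmless for power nonlinearities
            # (metrics are affine invariant) but avoids overflow at p = 10
            drive = drive / drive.max()
            for c, p in enumerate(power_grid):
                v = np.sum(drive**p, axis=1)
                sps[a, b, c], hw[a, b, c], sps_z[a, b, c], hw_z[a, b, c] = (
                    _curve_metrics(itd_grid, v, stats)
                )
    return ZScoreMap(
        sigma_grid=sigma_grid,
        power_grid=power_grid,
        cf_spreads=cf_spreads,
        sps=sps,
        hw=hw,
        sps_z=sps_z,
        hw_z=hw_z,
    )


# ---------------------------------------------------------------------------
# fixed sigmoidal subunit feasibility

def evaluate_subunit_curve(
    pop: ICclPopulation,
    sigma: float,
    nonlinearity: Nonlinearity,
    stats: PopulationStats = ICX_POPULATION_STATS,
    n_subunits: int = 10,
    itd_grid: np.ndarray = DEFAULT_ITD_GRID,
) -> tuple[float, float, float, float]:
    """(sps, hw, sps_z, hw_z) of a spread-zero subunit configuration."""
    cfs = _subunit_cfs(0.0, n_subunits)
    drive = _drive_matrix(pop, sigma, cfs, itd_grid)
    v = np.sum(nonlinearity(drive), axis=1)
    return _curve_metrics(itd_grid, v, stats)


@dataclass(frozen=True)
class SigmoidSearchSpace:
    """Deterministic coarse-to-fine grid over logistic slope and midpoint.

    The metrics are invariant to affine transforms of the subunit output, so
    only the slope ``s1`` and midpoint ``s2`` shape the ITD curve; ``s0`` and
    ``s3`` are fixed at 1 and 0.  ``None`` grids are derived from the drive
    scale at call time.
    """

    s1_grid: np.ndarray | None = None
    s2_grid: np.ndarray | None = None
    n_refine: int = 2
    refine_points: int = 9


def sigmoid_subunit_feasibility(
    pop: ICclPopulation | None = None,
    sigma_grid: np.ndarray | None = None,
    search_space: SigmoidSearchSpace | Sequence[SigmoidNL] | None = None,
    stats: PopulationStats = ICX_POPULATION_STATS,
    n_subunits: int = 10,
    itd_grid: np.ndarray = DEFAULT_ITD_GRID,
) -> tuple[SigmoidNL, float]:
    """Find one fixed sigmoidal subunit nonlinearity valid across bandwidths.

    Minimizes, over the search space, the maximum |z| of SPS and HW across
    all ``sigma`` in ``sigma_grid`` (cf spread zero).  A candidate whose
    curve has undefined SPS or HW at any sigma scores infinity.  The search
    is a deterministic coarse grid followed by geometric refinement around
    the incumbent; ties break lexicographically on (s1, s2).

    Returns the selected :class:`SigmoidNL` and its max |z|.
    """
    if pop is None:
        pop = build_population()
    if sigma_grid is None:
        sigma_grid = np.arange(0.5, 4.0 + 1e-9, 0.5)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    itd_grid = np.asarray(itd_grid, dtype=float)

    cfs = _subunit_cfs(0.0, n_subunits)
    rates = pop.rates(itd_grid)
    drives = [
        _drive_matrix(pop, s, cfs, itd_grid, rates=rates) for s in sigma_grid
    ]
    drive_max = max(d.max() for d in drives)

    def objective(s1: float, s2: float) -> float:
        worst = 0.0
        for drive in drives:
            v = np.sum(1.0 / (1.0 + np.exp(-s1 * (drive - s2))), axis=1)
            _, _, z_sps, z_hw = _curve_metrics(itd_grid, v, stats)
            if np.isnan(z_sps) or np.isnan(z_hw):
                return np.inf
            worst = max(worst, abs(z_sps), abs(z_hw))
        return worst

    # explicit candidate list: evaluate and return the argmin
    if search_space is not None and not isinstance(search_space, SigmoidSearchSpace):
        candidates = list(search_space)
        if not candidates:
            raise ValueError("empty search space")
        scored = [(objective(c.s1, c.s2), i) for i, c in enumerate(candidates)]
        best_score, best_i = min(scored)
        return candidates[best_i], float(best_score)

    space = search_space or SigmoidSearchSpace()
    s1_grid = (
        np.asarray(space.s1_grid, dtype=float)
        if space.s1_grid is not None
        else np.geomspace(0.5 / drive_max, 50.0 / drive_max, 13)
    )
    s2_grid = (
        np.asarray(space.s2_grid, dtype=float)
        if space.s2_grid is not None
        else np.linspace(0.02, 1.1, 13) * drive_max
    )
    if s1_grid.size == 0 or s2_grid.size == 0:
        raise ValueError("empty search space")

    best = (np.inf, np.inf, np.inf)  # (score, s1, s2)
    for s1 in s1_grid:
        for s2 in s2_grid:
            score = objective(s1, s2)
            if (score, s1, s2) < best:
                best = (score, float(s1), float(s2))

    s1_ratio = (s1_grid.max() / s1_grid.min()) ** (1.0 / max(s1_grid.size - 1, 1))
    s2_span = (s2_grid.max() - s2_grid.min()) / max(s2_grid.size - 1, 1)
    for _ in range(space.n_refine):
        _, s1c, s2c = best
        if not np.isfinite(s1c):
            break
        s1_lo, s1_hi = s1c / s1_ratio, s1c * s1_ratio
        s2_lo, s2_hi = s2c - s2_span, s2c + s2_span
        s1_ref = np.geomspace(s1_lo, s1_hi, space.refine_points)
        s2_ref = np.linspace(max(s2_lo, 1e-9), s2_hi, space.refine_points)
        for s1 in s1_ref:
            for s2 in s2_ref:
                score = objective(s1, s2)
                if (score, s1, s2) < best:
                    best = (score, float(s1), float(s2))
        s1_ratio = s1_ratio ** (2.0 / (space.refine_points - 1))
        s2_span = 2.0 * s2_span / (space.refine_points - 1)

    score, s1, s2 = best
    return SigmoidNL(s0=1.0, s1=s1, s2=s2, s3=0.0), float(score)
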